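"""Cross-species intersection of recurrent CNAs: the passenger filter.

Every human protein-coding gene is classified by whether its fish
ortholog(s) sit in recurrent fish alterations of the same polarity.  Genes
whose copy number changes in the same direction in both species are the
retained candidate drivers; the rest of the genes inside human CNAs are
filtered as likely passengers.  The module also produces the region-level
filtering summary (per human recurrent region: how many genes, how many in
the correspondence table, how many survive the fish filter), the
focal-focal candidate list, focal-by-large lists, and the chromosome
intersection matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Biotype, GeneRecord, Species, _chrom_key
from .recurrence import RecurrentRegion

__all__ = [
    "IntersectionRecord",
    "classify_genes",
    "region_summary",
    "summary_percentages",
    "focal_focal",
    "focal_by_large",
    "chrom_matrix",
    "round_half_away",
]


@dataclass
class IntersectionRecord:
    """Concordance classification of one human protein-coding gene."""

    human_gene_id: str
    human_chromosome: str
    fish_ortholog_ids: list[str]
    # per polarity ("gain"/"loss"): labels of the human regions holding the
    # gene; empty dict entry means not in a region of that polarity
    human_regions: dict[str, list[str]] = field(default_factory=dict)
    human_scopes: dict[str, set[str]] = field(default_factory=dict)
    # fish gene -> polarity -> (scopes, region labels)
    fish_regions: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    fish_scopes: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    concordance: str = "no_ortholog"

    def human_polarity(self, polarity: str) -> bool:
        return bool(self.human_regions.get(polarity))

    def fish_polarity(self, polarity: str, scope: str | None = None) -> bool:
        """Any fish ortholog in a fish region of this polarity (and scope)."""
        for fish_id in self.fish_ortholog_ids:
            scopes = self.fish_scopes.get(fish_id, {}).get(polarity, set())
            if scopes and (scope is None or scope in scopes):
                return True
        return False

    def concordant(self, polarity: str) -> bool:
        return self.human_polarity(polarity) and self.fish_polarity(polarity)


def _region_label(region: RecurrentRegion, index: int) -> str:
    return f"{region.chromosome}:{region.polarity}:{region.scope}:{index}"


def _membership(
    genes: Sequence[GeneRecord], regions: Sequence[RecurrentRegion]
) -> dict[str, dict[str, tuple[list[str], set[str]]]]:
    """gene_id -> polarity -> (region labels, scopes) by midpoint containment."""
    by_chrom: dict[str, list[tuple[int, RecurrentRegion, str]]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chromosome, []).append((i, r, _region_label(r, i)))
    out: dict[str, dict[str, tuple[list[str], set[str]]]] = {}
    for g in genes:
        hits: dict[str, tuple[list[str], set[str]]] = {}
        for _, r, label in by_chrom.get(g.chromosome, []):
            if r.start_bp <= g.midpoint <= r.end_bp:
                labels, scopes = hits.setdefault(r.polarity, ([], set()))
                labels.append(label)
                scopes.add(r.scope)
        if hits:
            out[g.gene_id] = hits
    return out


def classify_genes(
    human_regions: Sequence[RecurrentRegion],
    fish_regions: Sequence[RecurrentRegion],
    ortholog_table: pd.DataFrame,
    human_genes: Sequence[GeneRecord],
    fish_genes: Sequence[GeneRecord],
) -> list[IntersectionRecord]:
    """Classify every human protein-coding gene by cross-species concordance.

    Membership in a region means the gene midpoint falls inside the region
    span on the same chromosome.  A gene inside both a gain and a loss
    region carries both polarities; concordance for each polarity is judged
    against fish regions of that same polarity only (an opposite-polarity
    fish hit is recorded but does not veto).
    """
    for r in human_regions:
        if r.species != Species.HUMAN:
            raise ValueError("human_regions must be human-species regions")
    for r in fish_regions:
        if r.species != Species.FISH:
            raise ValueError("fish_regions must be fish-species regions")
    acc = ortholog_table[ortholog_table["accepted"]]
    fish_of: dict[str, list[str]] = {}
    for r in acc.itertuples(index=False):
        fish_of.setdefault(r.human_gene_id, []).append(r.fish_gene_id)
    human_pc = [g for g in human_genes if g.biotype == Biotype.PROTEIN_CODING]
    fish_pc = [g for g in fish_genes if g.biotype == Biotype.PROTEIN_CODING]
    human_hits = _membership(human_pc, human_regions)
    fish_hits = _membership(fish_pc, fish_regions)

    records: list[IntersectionRecord] = []
    for g in human_pc:
        orthologs = sorted(fish_of.get(g.gene_id, []))
        hh = human_hits.get(g.gene_id, {})
        rec = IntersectionRecord(
            human_gene_id=g.gene_id,
            human_chromosome=g.chromosome,
            fish_ortholog_ids=orthologs,
            human_regions={p: labels for p, (labels, _) in hh.items()},
            human_scopes={p: scopes for p, (_, scopes) in hh.items()},
        )
        for fish_id in orthologs:
            fh = fish_hits.get(fish_id, {})
            rec.fish_regions[fish_id] = {p: labels for p, (labels, _) in fh.items()}
            rec.fish_scopes[fish_id] = {p: scopes for p, (_, scopes) in fh.items()}
        if not orthologs:
            rec.concordance = "no_ortholog"
        elif rec.concordant("gain"):
            rec.concordance = "co_gained"
        elif rec.concordant("loss"):
            rec.concordance = "co_lost"
        elif any(
            rec.human_polarity(p) and rec.fish_polarity(_other(p))
            for p in ("gain", "loss")
        ):
            rec.concordance = "discordant"
        else:
            rec.concordance = "fish_neutral"
        records.append(rec)
    return records


def _other(polarity: str) -> str:
    return "loss" if polarity == "gain" else "gain"


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def summary_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach the derived percentage columns to a counts table.

    ``counts`` must have columns ``n_genes, n_in_table, n_overlap``;
    adds whole-percent ``pct_in_table`` (= n_in_table/n_genes) and
    ``pct_filtered`` (= 1 - n_overlap/n_in_table).  A region with no genes
    in the correspondence table gets a missing (NA) pct_filtered rather
    than 0.
    """
    out = counts.copy()
    out["pct_in_table"] = [
        round_half_away(100.0 * it / ng) if ng else pd.NA
        for ng, it in zip(out["n_genes"], out["n_in_table"])
    ]
    out["pct_filtered"] = [
        round_half_away(100.0 * (1 - ov / it)) if it else pd.NA
        for it, ov in zip(out["n_in_table"], out["n_overlap"])
    ]
    return out


def region_summary(
    records: Sequence[IntersectionRecord],
    human_regions: Sequence[RecurrentRegion],
) -> pd.DataFrame:
    """Per-region filtering summary in the style of the overlap table.

    For each human recurrent region (focal regions pooled into one
    "Focals" row per polarity) and for per-polarity totals:
    ``n_genes`` human protein-coding genes in the region, ``n_in_table``
    of them with an accepted fish ortholog, ``n_overlap`` with a
    same-polarity altered fish ortholog, plus the derived percentages.
    Totals de-duplicate genes shared between same-polarity regions.
    """
    by_id = {r.human_gene_id: r for r in records}
    label_of = {_region_label(r, i): (i, r) for i, r in enumerate(human_regions)}
    rows = []
    gene_sets: dict[str, dict[str, set[str]]] = {
        "gain": {}, "loss": {},
    }  # polarity -> row label -> gene ids
    for rec in records:
        for polarity, labels in rec.human_regions.items():
            for label in labels:
                i, region = label_of[label]
                row_label = (
                    "Focals" if region.scope == "focal" else f"{region.chromosome}:{i}"
                )
                gene_sets[polarity].setdefault(row_label, set()).add(
                    rec.human_gene_id
                )

    def count_row(polarity: str, label: str, gene_ids: set[str]):
        n_genes = len(gene_ids)
        in_table = [g for g in gene_ids if by_id[g].fish_ortholog_ids]
        overlap = [g for g in in_table if by_id[g].concordant(polarity)]
        return {
            "polarity": polarity,
            "region": label,
            "n_genes": n_genes,
            "n_overlap": len(overlap),
            "n_in_table": len(in_table),
        }

    for polarity in ("gain", "loss"):
        labels = sorted(
            gene_sets[polarity],
            key=lambda l: (l == "Focals", _chrom_key(l.split(":")[0]) if l != "Focals" else ()),
        )
        all_genes: set[str] = set()
        for label in labels:
            rows.append(count_row(polarity, label, gene_sets[polarity][label]))
            all_genes |= gene_sets[polarity][label]
        rows.append(count_row(polarity, "Total", all_genes))
    return summary_percentages(pd.DataFrame(rows))


def focal_focal(records: Sequence[IntersectionRecord]) -> pd.DataFrame:
    """Genes in focal alterations of the same polarity in both species,
    grouped by the human focal region holding them."""
    rows = []
    for rec in records:
        for polarity in ("gain", "loss"):
            if "focal" not in rec.human_scopes.get(polarity, set()):
                continue
            fish_focal = [
                fid
                for fid in rec.fish_ortholog_ids
                if "focal" in rec.fish_scopes.get(fid, {}).get(polarity, set())
            ]
            if not fish_focal:
                continue
            focal_labels = [
                label
                for label in rec.human_regions[polarity]
                if ":focal:" in label
            ]
            fish_chroms = sorted(
                {
                    label.split(":")[0]
                    for fid in fish_focal
                    for label in rec.fish_regions[fid].get(polarity, [])
                    if ":focal:" in label
                },
                key=_chrom_key,
            )
            rows.append(
                {
                    "human_region": focal_labels[0],
                    "polarity": polarity,
                    "human_gene_id": rec.human_gene_id,
                    "human_chromosome": rec.human_chromosome,
                    "fish_chromosomes": ",".join(fish_chroms),
                    "fish_gene_ids": ",".join(fish_focal),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "human_region",
            "polarity",
            "human_gene_id",
            "human_chromosome",
            "fish_chromosomes",
            "fish_gene_ids",
        ],
    )
    return df.sort_values(["polarity", "human_region", "human_gene_id"]).reset_index(
        drop=True
    )


def focal_by_large(
    records: Sequence[IntersectionRecord], direction: str
) -> pd.DataFrame:
    """Genes focally altered in one species and altered in the other.

    ``direction="human_focal_fish_any"``: human-focal genes with any
    concordant fish alteration, partitioned into fish-focal vs
    fish-large-only (column ``fish_scope``).
    ``direction="human_large_fish_focal"``: genes in human chromosome-scale
    regions whose fish ortholog is in a fish *focal* region of the same
    polarity.
    """
    if direction not in ("human_focal_fish_any", "human_large_fish_focal"):
        raise ValueError(f"unknown direction {direction!r}")
    rows = []
    for rec in records:
        for polarity in ("gain", "loss"):
            human_scopes = rec.human_scopes.get(polarity, set())
            if direction == "human_focal_fish_any":
                if "focal" not in human_scopes or not rec.fish_polarity(polarity):
                    continue
                scope = (
                    "focal"
                    if rec.fish_polarity(polarity, scope="focal")
                    else "large_only"
                )
            else:
                if "large" not in human_scopes or not rec.fish_polarity(
                    polarity, scope="focal"
                ):
                    continue
                scope = "focal"
            rows.append(
                {
                    "polarity": polarity,
                    "human_gene_id": rec.human_gene_id,
                    "human_chromosome": rec.human_chromosome,
                    "fish_scope": scope,
                }
            )
    df = pd.DataFrame(
        rows, columns=["polarity", "human_gene_id", "human_chromosome", "fish_scope"]
    )
    return df.sort_values(["polarity", "human_gene_id"]).reset_index(drop=True)


def chrom_matrix(
    records: Sequence[IntersectionRecord],
    fish_genes: Sequence[GeneRecord],
) -> dict[str, pd.DataFrame]:
    """Human x fish chromosome matrices of ortholog and concordance counts.

    Returns three integer matrices keyed ``"orthologs"``, ``"co_gained"``
    and ``"co_lost"``: cell (H, F) counts accepted ortholog pairs whose
    human gene is on H and fish gene on F -- all pairs, pairs where the
    human gene is concordantly gained, and concordantly lost.
    """
    fish_chrom = {g.gene_id: g.chromosome for g in fish_genes}
    human_chroms = sorted({r.human_chromosome for r in records}, key=_chrom_key)
    fish_chroms = sorted(set(fish_chrom.values()), key=_chrom_key)
    mats = {
        key: pd.DataFrame(
            0, index=human_chroms, columns=fish_chroms, dtype=int
        )
        for key in ("orthologs", "co_gained", "co_lost")
    }
    for rec in records:
        for fid in rec.fish_ortholog_ids:
            fc = fish_chrom.get(fid)
            if fc is None:
                continue
            mats["orthologs"].loc[rec.human_chromosome, fc] += 1
            if rec.concordance == "co_gained":
                mats["co_gained"].loc[rec.human_chromosome, fc] += 1
            elif rec.concordance == "co_lost":
                mats["co_lost"].loc[rec.human_chromosome, fc] += 1
    return mats
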