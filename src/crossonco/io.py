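"""Readers and writers for the pipeline's tab-separated formats.

Formats
-------
SEG (segmented copy number):
    ``sample  chrom  start  end  num_mark  seg_mean`` -- one row per segment,
    1-based inclusive coordinates, ``seg_mean`` a log2 ratio vs baseline
    ploidy.
Gene annotation:
    ``gene_id  chrom  start  end  strand  biotype``.
Similarity:
    ``human_gene_id  fish_gene_id  score`` -- a stand-in for protein
    similarity search bit scores; missing pairs mean score 0.

All writers emit deterministic output (fixed column order, fixed sort
order, fixed decimal formatting) so that identical inputs give
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import (
    Biotype,
    CohortMeta,
    GeneRecord,
    GenotypeGroup,
    SampleProfile,
    Segment,
    Species,
    assign_ordinals,
    _chrom_key,
)

__all__ = [
    "read_seg",
    "write_seg",
    "read_genes",
    "write_genes",
    "read_similarity",
    "write_similarity",
    "validate_cohort",
    "ValidationReport",
    "SegFormatError",
]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_mark", "seg_mean"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]
SIM_COLUMNS = ["human_gene_id", "fish_gene_id", "score"]


class SegFormatError(ValueError):
    """Raised when a SEG-like file violates the format's invariants."""


def read_seg(
    path: str | Path,
    baseline_ploidy: int = 3,
    genotype_group: GenotypeGroup | None = None,
    valid_chromosomes: Sequence[str] | None = None,
) -> list[SampleProfile]:
    """Parse a SEG-like TSV into one :class:`SampleProfile` per sample.

    Segments are sorted per chromosome and checked for overlaps; the
    offending rows are named in the error.  ``genotype_group`` may be None,
    in which case groups are inferred from sample-id prefixes where
    possible (``rp_d``/``tp53_d``/``tp53_t``/``nf1``) and default to the
    species-appropriate group otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise SegFormatError(f"{path}: missing columns {missing}")
    if valid_chromosomes is not None:
        bad = sorted(set(df["chrom"]) - set(valid_chromosomes), key=_chrom_key)
        if bad:
            raise SegFormatError(
                f"{path}: unknown chromosomes {bad}; valid names are "
                f"{list(valid_chromosomes)}"
            )
    profiles: list[SampleProfile] = []
    for sample_id, sub in df.groupby("sample", sort=True):
        segments: list[Segment] = []
        for chrom, rows in sub.groupby("chrom", sort=False):
            rows = rows.sort_values(["start", "end"])
            prev_end, prev_row = None, None
            for idx, row in rows.iterrows():
                if prev_end is not None and row["start"] <= prev_end:
                    raise SegFormatError(
                        f"{path}: overlapping segments for sample {sample_id} "
                        f"chr{chrom}: rows {prev_row} and {idx} "
                        f"(ends {prev_end}, starts {row['start']})"
                    )
                segments.append(
                    Segment(
                        chromosome=str(chrom),
                        start_bp=int(row["start"]),
                        end_bp=int(row["end"]),
                        n_markers=int(row["num_mark"]),
                        value=float(row["seg_mean"]),
                    )
                )
                prev_end, prev_row = int(row["end"]), idx
        group = genotype_group or _infer_group(str(sample_id), baseline_ploidy)
        profile = SampleProfile(
            sample_id=str(sample_id),
            genotype_group=group,
            baseline_ploidy=baseline_ploidy,
            segments=sorted(
                segments, key=lambda s: (_chrom_key(s.chromosome), s.start_bp)
            ),
        )
        profile.validate()
        profiles.append(profile)
    return profiles


def _infer_group(sample_id: str, baseline_ploidy: int) -> GenotypeGroup:
    for prefix, group in (
        ("rp_d", GenotypeGroup.RP_DIPLOID),
        ("tp53_d", GenotypeGroup.TP53_DIPLOID),
        ("tp53_t", GenotypeGroup.TP53_TRIPLOID),
        ("nf1", GenotypeGroup.HUMAN_NF1),
    ):
        if sample_id.startswith(prefix):
            return group
    return (
        GenotypeGroup.TP53_DIPLOID
        if baseline_ploidy == 3
        else GenotypeGroup.HUMAN_NF1
    )


def write_seg(profiles: Sequence[SampleProfile], path: str | Path) -> None:
    """Write profiles as a SEG-like TSV; empty input yields a header-only file."""
    rows = []
    for p in sorted(profiles, key=lambda p: p.sample_id):
        for s in sorted(
            p.segments, key=lambda s: (_chrom_key(s.chromosome), s.start_bp)
        ):
            rows.append(
                (p.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_markers, s.value)
            )
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for sample, chrom, start, end, nmark, mean in rows:
            fh.write(f"{sample}\t{chrom}\t{start}\t{end}\t{nmark}\t{mean:.6f}\n")


def read_genes(path: str | Path, species: Species) -> list[GeneRecord]:
    """Parse a gene annotation TSV and assign per-chromosome ordinals."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene ids {sorted(set(dup))}")
    genes = [
        GeneRecord(
            gene_id=str(r.gene_id),
            species=species,
            chromosome=str(r.chrom),
            start_bp=int(r.start),
            end_bp=int(r.end),
            strand=str(r.strand),
            biotype=Biotype(str(r.biotype)),
        )
        for r in df.itertuples()
    ]
    return assign_ordinals(genes)


def write_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in sorted(genes, key=lambda g: (_chrom_key(g.chromosome), g.ordinal)):
            fh.write(
                f"{g.gene_id}\t{g.chromosome}\t{g.start_bp}\t{g.end_bp}\t"
                f"{g.strand}\t{g.biotype.value}\n"
            )


def read_similarity(path: str | Path) -> pd.DataFrame:
    """Parse the cross-species similarity table.

    At most one score per ordered (human, fish) pair is allowed; duplicate
    pairs with conflicting scores raise.  Scores must be finite and >= 0.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SIM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.drop_duplicates()
    dup = df.duplicated(subset=["human_gene_id", "fish_gene_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["human_gene_id", "fish_gene_id"]].drop_duplicates()
        raise ValueError(
            f"{path}: conflicting scores for pairs {pairs.values.tolist()}"
        )
    if not ((df["score"] >= 0) & df["score"].apply(math.isfinite)).all():
        raise ValueError(f"{path}: scores must be finite and >= 0")
    return df.reset_index(drop=True)


def write_similarity(df: pd.DataFrame, path: str | Path) -> None:
    out = df[SIM_COLUMNS].sort_values(["human_gene_id", "fish_gene_id"])
    with open(path, "w") as fh:
        fh.write("\t".join(SIM_COLUMNS) + "\n")
        for r in out.itertuples(index=False):
            fh.write(f"{r.human_gene_id}\t{r.fish_gene_id}\t{r.score:.3f}\n")


@dataclass
class ValidationReport:
    """Outcome of checking a cohort against its expected shape."""

    group_counts: dict[GenotypeGroup, int]
    n_samples: int
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_cohort(
    profiles: Sequence[SampleProfile], meta: CohortMeta
) -> ValidationReport:
    """Report per-group sample counts and per-sample chromosome coverage.

    Never raises: all problems (missing chromosomes, unexpected group
    sizes) are listed in the report's ``failures``.
    """
    counts: dict[GenotypeGroup, int] = {g: 0 for g in meta.group_counts}
    failures: list[str] = []
    for p in profiles:
        counts[p.genotype_group] = counts.get(p.genotype_group, 0) + 1
        covered = {s.chromosome for s in p.segments}
        missing = [c for c in meta.chromosomes if c not in covered]
        if missing:
            failures.append(
                f"sample {p.sample_id}: no segments on chromosomes {missing}"
            )
    for group, expected in meta.group_counts.items():
        got = counts.get(group, 0)
        if got != expected:
            failures.append(
                f"group {group.value}: expected {expected} samples, found {got}"
            )
    return ValidationReport(
        group_counts=counts, n_samples=len(profiles), failures=failures
    )
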