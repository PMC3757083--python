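"""Packaged desk-scale fixtures: the published gene-overlap counts.

These small tables transcribe the study's printed region-level gene counts
and focal-focal gene lists, so the summary arithmetic (overlap and
filtering percentages, focal-focal group sizes) can be recomputed and
checked without the original genome-scale datasets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cross_species import IntersectionRecord

__all__ = [
    "load_table1_counts",
    "load_table2_genes",
    "table2_records",
    "REPORTED_CHROMOTHRIPSIS",
]

#: species -> (flagged chromosome count, n samples, n chromosomes per sample)
REPORTED_CHROMOTHRIPSIS = {"fish": (47, 147, 25), "human": (44, 23, 23)}


def _read(name: str) -> pd.DataFrame:
    with resources.files("crossonco.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"region": str})


def load_table1_counts() -> pd.DataFrame:
    """Region-level gene counts for human CNAs vs the fish filter.

    Columns: polarity, region (human chromosome or "Focals"/"Total"),
    n_genes (human protein-coding genes in the CNA), n_overlap (of those,
    genes whose fish ortholog is in a same-polarity fish CNA), n_in_table
    (genes present in the correspondence table), and the printed whole-
    percent columns for cross-checking.  Note the printed totals
    de-duplicate genes shared between a focal and a large region, so they
    are slightly below the per-region column sums.
    """
    return _read("table1_gene_counts.tsv")


def load_table2_genes() -> pd.DataFrame:
    """Genes focally amplified in both species, grouped by human focal region."""
    df = _read("table2_focal_focal_genes.tsv")
    return df.astype({"human_chrom": str, "fish_chrom": str})


def table2_records() -> list[IntersectionRecord]:
    """The focal-focal gene list as intersection records.

    Each gene is human-focally-gained and has one fish ortholog inside a
    fish focal gain, which is exactly the evidence pattern the
    :func:`crossonco.cross_species.focal_focal` report selects on.
    """
    records = []
    df = load_table2_genes()
    region_index = {r: i for i, r in enumerate(dict.fromkeys(df["human_region"]))}
    for row in df.itertuples(index=False):
        i = region_index[row.human_region]
        human_label = f"{row.human_region}:gain:focal:{i}"
        fish_label = f"{row.fish_chrom}:gain:focal:{i}"
        fish_id = f"fish:{row.gene}"
        rec = IntersectionRecord(
            human_gene_id=row.gene,
            human_chromosome=str(row.human_chrom),
            fish_ortholog_ids=[fish_id],
            human_regions={"gain": [human_label]},
            human_scopes={"gain": {"focal"}},
            fish_regions={fish_id: {"gain": [fish_label]}},
            fish_scopes={fish_id: {"gain": {"focal"}}},
            concordance="co_gained",
        )
        records.append(rec)
    return records
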