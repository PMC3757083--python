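"""Concordance classification, filtering summaries, and matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import crossonco as co
from crossonco.cross_species import round_half_away
from crossonco.fixtures import load_table1_counts, load_table2_genes, table2_records
from crossonco.model import GeneRecord, Species, assign_ordinals
from crossonco.recurrence import RecurrentRegion
from crossonco.simulate import regions_from_truth


def _genes(species, chrom_ids):
    genes = []
    for chrom, ids in chrom_ids.items():
        for k, gid in enumerate(ids):
            genes.append(
                GeneRecord(gid, species, chrom, k * 1000 + 1, k * 1000 + 500)
            )
    return assign_ordinals(genes)


def _region(species, chrom, start, end, polarity, scope, members=()):
    return RecurrentRegion(
        species=species,
        chromosome=chrom,
        start_bp=start,
        end_bp=end,
        polarity=polarity,
        scope=scope,
        peak_gene_ids=[],
        peak_q=0.0,
        member_gene_ids=list(members),
    )


def _ortho(pairs):
    return pd.DataFrame(
        [
            {"human_gene_id": h, "fish_gene_id": f, "score": 100.0,
             "rbh": True, "support": 0, "accepted": True}
            for h, f in pairs
        ],
        columns=["human_gene_id", "fish_gene_id", "score", "rbh", "support", "accepted"],
    )


@pytest.fixture(scope="module")
def classified_study(default_study, default_config):
    human, fish, similarity, _, _, truth = default_study
    table = co.refine_orthologs(similarity, human, fish)
    hr = regions_from_truth(truth, human, Species.HUMAN, default_config)
    fr = regions_from_truth(truth, fish, Species.FISH, default_config)
    records = co.classify_genes(hr, fr, table, human, fish)
    return records, hr, fr, table


class TestClassify:
    def test_no_fish_regions_all_filtered(self):
        human = _genes(Species.HUMAN, {"1": ["h0", "h1"]})
        fish = _genes(Species.FISH, {"1": ["f0", "f1"]})
        hr = [_region(Species.HUMAN, "1", 1, 5000, "gain", "large")]
        records = co.classify_genes(hr, [], _ortho([("h0", "f0"), ("h1", "f1")]),
                                    human, fish)
        assert all(r.concordance == "fish_neutral" for r in records)
        assert not any(r.concordant("gain") for r in records)

    def test_planted_shared_driver_co_gained(self):
        human = _genes(Species.HUMAN, {"1": ["h0"]})
        fish = _genes(Species.FISH, {"2": ["f0"]})
        hr = [_region(Species.HUMAN, "1", 1, 5000, "gain", "large")]
        fr = [_region(Species.FISH, "2", 1, 5000, "gain", "large")]
        (rec,) = co.classify_genes(hr, fr, _ortho([("h0", "f0")]), human, fish)
        assert rec.concordance == "co_gained"

    def test_opposite_fish_hit_recorded_but_not_vetoing(self):
        """A second paralog in a fish loss does not cancel a gain concordance."""
        human = _genes(Species.HUMAN, {"1": ["h0"]})
        fish = _genes(Species.FISH, {"1": ["f0a"], "2": ["f0b"]})
        hr = [_region(Species.HUMAN, "1", 1, 5000, "gain", "large")]
        fr = [
            _region(Species.FISH, "1", 1, 5000, "gain", "large"),
            _region(Species.FISH, "2", 1, 5000, "loss", "large"),
        ]
        (rec,) = co.classify_genes(
            hr, fr, _ortho([("h0", "f0a"), ("h0", "f0b")]), human, fish
        )
        assert rec.concordance == "co_gained"

    def test_species_mismatch_raises(self):
        human = _genes(Species.HUMAN, {"1": ["h0"]})
        fish = _genes(Species.FISH, {"1": ["f0"]})
        bad = [_region(Species.FISH, "1", 1, 5000, "gain", "large")]
        with pytest.raises(ValueError):
            co.classify_genes(bad, [], _ortho([]), human, fish)

    def test_counts_nested_and_null_chance_level(self, classified_study):
        records, hr, fr, table = classified_study
        summary = co.region_summary(records, hr)
        assert (summary["n_overlap"] <= summary["n_in_table"]).all()
        assert (summary["n_in_table"] <= summary["n_genes"]).all()
        # species were altered independently, so the co-gained fraction sits
        # at the chance level set by fish gain coverage of orthologed genes
        acc = table[table.accepted]
        fish_gain = [r for r in fr if r.polarity == "gain"]
        fish_genes = {g for g in acc["fish_gene_id"]}
        # coverage fraction q of accepted fish genes in gain regions
        member_ids = set()
        for r in fish_gain:
            member_ids.update(r.member_gene_ids)
        q = len(fish_genes & member_ids) / len(fish_genes)
        gain_recs = [r for r in records if r.human_polarity("gain") and r.fish_ortholog_ids]
        observed = np.mean([r.concordant("gain") for r in gain_recs])
        expected = np.mean(
            [1 - (1 - q) ** len(r.fish_ortholog_ids) for r in gain_recs]
        )
        var = np.mean(
            [
                (1 - (1 - q) ** len(r.fish_ortholog_ids))
                * (1 - q) ** len(r.fish_ortholog_ids)
                for r in gain_recs
            ]
        ) / len(gain_recs)
        assert abs(observed - expected) <= 3 * np.sqrt(var)


class TestSummary:
    def test_printed_percent_cells_reproduce_exactly(self):
        counts = load_table1_counts()
        out = co.summary_percentages(counts)
        assert (out["pct_in_table"] == counts["printed_pct_in_table"]).all()
        assert (out["pct_filtered"] == counts["printed_pct_filtered"]).all()

    def test_chr8_worked_example(self):
        df = co.summary_percentages(
            pd.DataFrame({"n_genes": [487], "n_in_table": [347], "n_overlap": [128]})
        )
        assert df["pct_filtered"].item() == 63
        assert df["pct_in_table"].item() == 71

    def test_zero_in_table_gives_missing_marker(self):
        df = co.summary_percentages(
            pd.DataFrame({"n_genes": [10], "n_in_table": [0], "n_overlap": [0]})
        )
        assert df["pct_filtered"].isna().all()

    def test_empty_records_empty_table(self):
        out = co.region_summary([], [])
        assert list(out["region"]) == ["Total", "Total"]
        assert (out["n_genes"] == 0).all()

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(62.5) == 63
        assert round_half_away(62.49) == 62
        assert round_half_away(-0.5) == -1


class TestFocalFocal:
    def test_fixture_totals(self):
        records = table2_records()
        out = co.focal_focal(records)
        assert len(out) == 34
        top = out[out["human_region"].str.startswith("4q:")]
        assert len(top) == 23
        assert (out["polarity"] == "gain").all()

    def test_losses_empty_on_fixture(self):
        out = co.focal_focal(table2_records())
        assert (out["polarity"] == "loss").sum() == 0

    def test_direction1_focal_partition_equals_focal_focal(self, classified_study):
        records, *_ = classified_study
        ff = co.focal_focal(records)
        d1 = co.focal_by_large(records, "human_focal_fish_any")
        focal_part = d1[d1["fish_scope"] == "focal"]
        assert set(zip(focal_part["polarity"], focal_part["human_gene_id"])) == set(
            zip(ff["polarity"], ff["human_gene_id"])
        )

    def test_direction2_empty_without_fish_focals(self):
        human = _genes(Species.HUMAN, {"1": ["h0"]})
        fish = _genes(Species.FISH, {"1": ["f0"]})
        hr = [_region(Species.HUMAN, "1", 1, 5000, "gain", "large")]
        fr = [_region(Species.FISH, "1", 1, 5000, "gain", "large")]
        records = co.classify_genes(hr, fr, _ortho([("h0", "f0")]), human, fish)
        assert co.focal_by_large(records, "human_large_fish_focal").empty

    def test_planted_human_large_fish_focal(self):
        human = _genes(Species.HUMAN, {"1": ["h0"]})
        fish = _genes(Species.FISH, {"1": ["f0"]})
        hr = [_region(Species.HUMAN, "1", 1, 5000, "gain", "large")]
        fr = [_region(Species.FISH, "1", 1, 5000, "gain", "focal")]
        records = co.classify_genes(hr, fr, _ortho([("h0", "f0")]), human, fish)
        out = co.focal_by_large(records, "human_large_fish_focal")
        assert list(out["human_gene_id"]) == ["h0"]


class TestChromMatrix:
    def test_conservation_and_dominance(self, classified_study, default_study):
        records, *_ , table = classified_study
        _, fish_genes, *_ = default_study
        mats = co.chrom_matrix(records, fish_genes)
        acc = table[table.accepted]
        # pairs whose human side is protein-coding and classified
        human_ids = {r.human_gene_id for r in records}
        n_pairs = sum(1 for h in acc["human_gene_id"] if h in human_ids)
        assert mats["orthologs"].to_numpy().sum() == n_pairs
        assert (mats["co_gained"].to_numpy() <= mats["orthologs"].to_numpy()).all()
        assert (mats["co_lost"].to_numpy() <= mats["orthologs"].to_numpy()).all()

    def test_unrearranged_toy_is_diagonal(self):
        human = _genes(Species.HUMAN, {"1": ["h0", "h1"], "2": ["h2", "h3"]})
        fish = _genes(Species.FISH, {"1": ["f0", "f1"], "2": ["f2", "f3"]})
        records = co.classify_genes(
            [], [], _ortho([(f"h{i}", f"f{i}") for i in range(4)]), human, fish
        )
        mat = co.chrom_matrix(records, fish)["orthologs"]
        assert mat.loc["1", "1"] == 2 and mat.loc["2", "2"] == 2
        assert mat.loc["1", "2"] == 0 and mat.loc["2", "1"] == 0
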