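"""RBH candidates, synteny arbitration, and block chaining."""

from __future__ import annotations

import numpy as np
import pandas as pd

import crossonco as co
from crossonco.model import GeneRecord, Species, assign_ordinals
from crossonco.simulate import SimilarityParams

from conftest import small_config


def _sim(rows):
    return pd.DataFrame(rows, columns=["human_gene_id", "fish_gene_id", "score"])


def _layout(species, chrom_genes):
    """chrom_genes: {chrom: [gene ids in order]} -> GeneRecords with ordinals."""
    genes = []
    for chrom, ids in chrom_genes.items():
        for k, gid in enumerate(ids):
            genes.append(
                GeneRecord(gid, species, chrom, k * 1000 + 1, k * 1000 + 500)
            )
    return assign_ordinals(genes)


class TestRBH:
    def test_identity_matrix_diagonal(self):
        rows = []
        for i in range(4):
            for j in range(4):
                rows.append((f"h{i}", f"f{j}", 100.0 if i == j else 10.0 + i + j))
        pairs = co.reciprocal_best_hits(_sim(rows))
        assert sorted((p.human_gene_id, p.fish_gene_id) for p in pairs) == [
            (f"h{i}", f"f{i}") for i in range(4)
        ]
        assert not any(p.ambiguous for p in pairs)

    def test_non_reciprocal_excluded(self):
        # h1's best is f1, but f1's best is h2: no candidate (h1, f1)
        rows = [("h1", "f1", 90.0), ("h2", "f1", 95.0), ("h2", "f2", 50.0)]
        pairs = co.reciprocal_best_hits(_sim(rows))
        assert ("h1", "f1") not in {(p.human_gene_id, p.fish_gene_id) for p in pairs}

    def test_exact_ties_flagged_ambiguous(self):
        rows = [("h1", "f1", 100.0), ("h1", "f2", 100.0)]
        pairs = co.reciprocal_best_hits(_sim(rows))
        assert len(pairs) == 2 and all(p.ambiguous for p in pairs)

    def test_empty_table(self):
        assert co.reciprocal_best_hits(_sim([])) == []


class TestSyntenySupport:
    def test_empty_assignments(self):
        human = _layout(Species.HUMAN, {"1": ["h0", "h1"]})
        fish = _layout(Species.FISH, {"1": ["f0", "f1"]})
        assert co.synteny_support("h0", "f0", [], human, fish) == 0

    def test_counts_concordant_neighbors(self):
        ids = [f"h{i}" for i in range(6)], [f"f{i}" for i in range(6)]
        human = _layout(Species.HUMAN, {"1": ids[0]})
        fish = _layout(Species.FISH, {"1": ids[1]})
        assignments = [(f"h{i}", f"f{i}") for i in range(6)]
        # 5 neighbors within the window support the pair; itself excluded
        assert co.synteny_support("h0", "f0", assignments, human, fish, window=100) == 5

    def test_neighbor_on_other_chromosome_contributes_zero(self):
        human = _layout(Species.HUMAN, {"1": ["h0"], "2": ["h1"]})
        fish = _layout(Species.FISH, {"1": ["f0", "f1"]})
        assert co.synteny_support("h0", "f0", [("h1", "f1")], human, fish) == 0


class TestRefine:
    def test_paralogs_both_attach_when_syntenic(self):
        """Two near-tied fish paralogs: RBH one plus a supported second copy."""
        human = _layout(Species.HUMAN, {"1": ["h0", "h1", "h2"]})
        fish = _layout(
            Species.FISH, {"1": ["f0a", "f1a", "f2a"], "2": ["f0b", "f1b", "f2b"]}
        )
        rows = []
        for i in range(3):
            rows.append((f"h{i}", f"f{i}a", 100.0))
            rows.append((f"h{i}", f"f{i}b", 96.0))
        table = co.refine_orthologs(_sim(rows), human, fish, tie_ratio=0.9)
        acc = set(
            zip(table[table.accepted]["fish_gene_id"], table[table.accepted]["human_gene_id"])
        )
        assert acc == {(f"f{i}a", f"h{i}") for i in range(3)} | {
            (f"f{i}b", f"h{i}") for i in range(3)
        }

    def test_no_synteny_gives_pure_rbh(self):
        """Single-gene chromosomes: the second paralog has no support and drops."""
        human = _layout(Species.HUMAN, {"1": ["h0"]})
        fish = _layout(Species.FISH, {"1": ["f0a"], "2": ["f0b"]})
        rows = [("h0", "f0a", 100.0), ("h0", "f0b", 96.0)]
        table = co.refine_orthologs(_sim(rows), human, fish)
        acc = table[table.accepted]
        assert list(acc["fish_gene_id"]) == ["f0a"]

    def test_accepted_is_function_and_deterministic(self, default_study):
        human, fish, similarity, _, _, _ = default_study
        t1 = co.refine_orthologs(similarity, human, fish)
        t2 = co.refine_orthologs(similarity, human, fish)
        pd.testing.assert_frame_equal(t1, t2)
        acc = t1[t1.accepted]
        assert acc["fish_gene_id"].is_unique
        # a human gene keeps at most its two post-duplication paralogs
        assert acc.groupby("human_gene_id").size().max() <= 2

    def test_zero_noise_recovers_all_truth_pairs(self):
        cfg = small_config(
            seed=6,
            similarity=SimilarityParams(
                ortholog_score_sd=0.0, paralog_penalty=1.0, missing_prob=0.2
            ),
        )
        human, fish, similarity, truth = co.simulate_genomes(cfg)
        table = co.refine_orthologs(similarity, human, fish)
        acc = set(
            zip(table[table.accepted]["fish_gene_id"], table[table.accepted]["human_gene_id"])
        )
        assert acc >= set(truth.ortholog_pairs.items())

    def test_moderate_noise_recovery(self, default_study):
        human, fish, similarity, _, _, truth = default_study
        table = co.refine_orthologs(similarity, human, fish)
        acc = set(
            zip(table[table.accepted]["fish_gene_id"], table[table.accepted]["human_gene_id"])
        )
        truth_pairs = set(truth.ortholog_pairs.items())
        assert len(acc & truth_pairs) / len(truth_pairs) >= 0.95
        assert len(acc - truth_pairs) / len(acc) <= 0.01


def _oracle_chain(pairs, window):
    """Independent re-implementation of greedy chaining for the oracle."""
    blocks, last = [], None
    for hc, ho, fc, fo in pairs:
        if (
            last
            and hc == last[0]
            and fc == last[2]
            and ho - last[1] <= window
            and abs(fo - last[3]) <= window
        ):
            blocks[-1] += 1
        else:
            blocks.append(1)
        last = (hc, ho, fc, fo)
    return blocks


class TestBlocks:
    def test_unrearranged_genomes_one_block_per_chromosome(self):
        human = _layout(Species.HUMAN, {"1": [f"h{i}" for i in range(30)]})
        fish = _layout(Species.FISH, {"1": [f"f{i}" for i in range(30)]})
        rows = [(f"h{i}", f"f{i}", 100.0) for i in range(30)]
        table = co.refine_orthologs(_sim(rows), human, fish)
        blocks = co.synteny_blocks(table, human, fish)
        assert len(blocks) == 1 and blocks[0].size == 30

    def test_single_pair_block_reported_as_size_one(self):
        human = _layout(Species.HUMAN, {"1": ["h0"]})
        fish = _layout(Species.FISH, {"1": ["f0"]})
        table = co.refine_orthologs(_sim([("h0", "f0", 50.0)]), human, fish)
        blocks = co.synteny_blocks(table, human, fish)
        hist = co.block_size_histogram(blocks)
        assert blocks[0].size == 1
        assert hist.loc[hist.size_bin == "1", "n_blocks"].item() == 1

    def test_chaining_matches_independent_oracle(self):
        cfg = small_config(seed=8, n_ancestral_genes=200)
        human, fish, similarity, _ = co.simulate_genomes(cfg)
        table = co.refine_orthologs(similarity, human, fish)
        blocks = co.synteny_blocks(table, human, fish, window=100)
        hidx = {g.gene_id: (g.chromosome, g.ordinal) for g in human}
        fidx = {g.gene_id: (g.chromosome, g.ordinal) for g in fish}
        acc = table[table.accepted]
        pairs = sorted(
            (hidx[h][0], hidx[h][1], fidx[f][0], fidx[f][1])
            for h, f in zip(acc["human_gene_id"], acc["fish_gene_id"])
        )
        assert [b.size for b in blocks] == _oracle_chain(pairs, 100)
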