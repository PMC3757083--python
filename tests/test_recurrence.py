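"""G-scores, permutation Q-values, focal mode, region calls, subgroup tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import crossonco as co
from crossonco.model import GeneRecord, GenotypeGroup, SampleProfile, Segment, Species
from crossonco.recurrence import GeneCNMatrix


def _genes(n, chrom="1", spacing=100_000, species=Species.FISH):
    return [
        GeneRecord(
            gene_id=f"g{i:03d}",
            species=species,
            chromosome=chrom,
            start_bp=i * spacing + 1,
            end_bp=i * spacing + 20_000,
            ordinal=i,
        )
        for i in range(n)
    ]


def _matrix(values, genes=None, species=Species.FISH):
    values = np.asarray(values, dtype=float)
    genes = genes or _genes(values.shape[0])
    return GeneCNMatrix(
        genes=genes,
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        species=species,
    )


class TestGeneLevelMatrix:
    def _profile(self, segments, sample="s1"):
        return SampleProfile(
            sample_id=sample,
            genotype_group=GenotypeGroup.TP53_DIPLOID,
            baseline_ploidy=3,
            segments=segments,
        )

    def test_single_segment_covers_genes(self):
        genes = _genes(3)
        prof = self._profile([Segment("1", 1, 400_000, 4, 0.5)])
        mat = co.gene_level_matrix([prof], genes, Species.FISH)
        assert np.allclose(mat.values[:, 0], 0.5)

    def test_midpoint_on_segment_start_takes_that_segment(self):
        genes = [
            GeneRecord("g0", Species.FISH, "1", 90_001, 110_001, ordinal=0)
        ]  # midpoint exactly 100_001
        prof = self._profile(
            [Segment("1", 1, 100_000, 1, -0.4), Segment("1", 100_001, 200_000, 1, 0.7)]
        )
        mat = co.gene_level_matrix([prof], genes, Species.FISH)
        assert mat.values[0, 0] == pytest.approx(0.7)

    def test_gap_fill_and_strict_mode(self):
        genes = _genes(2)
        prof = self._profile([Segment("1", 1, 50_000, 1, 0.3)])  # covers gene 0 only
        mat = co.gene_level_matrix([prof], genes, Species.FISH, gap_fill=True)
        assert mat.values[1, 0] == 0.0
        with pytest.raises(ValueError, match="not covered"):
            co.gene_level_matrix([prof], genes, Species.FISH, gap_fill=False)

    def test_matches_brute_force_interval_oracle(self, small_study):
        _, fish_genes, _, fish_profiles, _, _ = small_study
        profiles = fish_profiles[:5]
        mat = co.gene_level_matrix(profiles, fish_genes, Species.FISH)
        for j, prof in enumerate(profiles):
            for i, g in enumerate(mat.genes):
                expected = 0.0
                for s in prof.segments:  # brute-force scan of every segment
                    if s.chromosome == g.chromosome and s.contains(g.midpoint):
                        expected = s.value
                        break
                assert mat.values[i, j] == pytest.approx(expected)


class TestGScore:
    def test_null_matrix_zero(self):
        assert np.all(co.gscore(np.zeros((10, 5)), 0.2, "gain") == 0.0)

    def test_hand_arithmetic(self):
        values = np.zeros((1, 147))
        values[0, :60] = 0.415
        g = co.gscore(values, 0.2, "gain")
        assert g[0] == pytest.approx(60 * (0.415 - 0.2) / 147)

    def test_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 0.3, (20, 30))
        g1 = co.gscore(values, 0.2, "gain")
        g2 = co.gscore(values[:, rng.permutation(30)], 0.2, "gain")
        assert np.allclose(g1, g2)

    def test_zero_iff_no_sample_exceeds_theta(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 0.3, (50, 20))
        g = co.gscore(values, 0.2, "loss")
        exceeds = (-values > 0.2).any(axis=1)
        assert np.array_equal(g > 0, exceeds)

    def test_additivity_over_merged_cohorts(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.3, (30, 40))
        b = rng.normal(0.1, 0.3, (30, 20))
        merged = np.hstack([a, b])
        g = co.gscore(merged, 0.2, "gain")
        expected = (40 * co.gscore(a, 0.2, "gain") + 20 * co.gscore(b, 0.2, "gain")) / 60
        assert np.allclose(g, expected)


class TestFreq:
    def test_counting(self):
        values = np.zeros((1, 147))
        values[0, :74] = 0.5
        assert co.freq_track(values, 0.2, "gain")[0] == pytest.approx(74 / 147)

    def test_gain_loss_disjoint(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 0.5, (40, 30))
        total = co.freq_track(values, 0.2, "gain") + co.freq_track(values, 0.2, "loss")
        assert np.all(total <= 1.0)


class TestPermQ:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 0.3, (100, 30))
        p1, q1 = co.perm_qvalues(values, 0.2, "gain", n_perm=100, seed=9)
        p2, q2 = co.perm_qvalues(values, 0.2, "gain", n_perm=100, seed=9)
        assert np.array_equal(p1, p2) and np.array_equal(q1, q2)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.3, (200, 30))
        values[:10] += 0.5
        p, q = co.perm_qvalues(values, 0.2, "gain", n_perm=100, seed=1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_threshold_equivalence(self):
        """Q < 0.25 is the same set as -log10 Q > 0.602."""
        rng = np.random.default_rng(6)
        values = rng.normal(0, 0.3, (200, 40))
        values[:20] += 0.4
        mat = _matrix(values, genes=_genes(200))
        res = co.score_matrix(mat, 0.2, "gain", n_perm=100, seed=2)
        assert np.array_equal(res.q < 0.25, res.neglog10_q() > 0.602)

    def test_planted_gain_reaches_significance(self):
        """A 60%-frequency one-copy gain on one chromosome dominates the null."""
        rng = np.random.default_rng(7)
        genes = _genes(150, chrom="1") + [
            GeneRecord(f"h{i}", Species.FISH, "2", i * 100_000 + 1,
                       i * 100_000 + 20_000, ordinal=i)
            for i in range(350)
        ]
        values = rng.normal(0, 0.05, (500, 147))
        altered = rng.random(147) < 0.6
        values[:150, altered] += 0.415
        p, q = co.perm_qvalues(values, 0.2, "gain", n_perm=150, seed=3)
        assert np.all(q[:150] < 0.25)
        assert (q[150:] < 0.25).mean() < 0.02


class TestFocal:
    def test_transform_removes_whole_chromosome_background(self):
        values = np.zeros((30, 10))
        values[:, :6] = 0.415  # whole-chromosome gain in 6 samples
        mat = _matrix(values)
        corrected = co.focal_transform(mat)
        assert np.allclose(corrected.values, 0.0)

    def test_transform_median_zero_per_sample_chromosome(self, default_fish_matrix):
        corrected = co.focal_transform(default_fish_matrix)
        chroms = corrected.chromosomes
        for chrom in np.unique(chroms)[:5]:
            med = np.median(corrected.values[chroms == chrom], axis=0)
            assert np.allclose(med, 0.0, atol=1e-12)

    def _focal_matrix(self, centers, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 0.05, (300, 60))
        values[:, :40] += 0.415  # whole-chromosome gain riding underneath
        for center in centers:
            for j in range(60):
                if rng.random() < 0.5:
                    half = int(rng.integers(6, 12))
                    values[center - half : center + half + 1, j] += 1.0
        return _matrix(values, genes=_genes(300))

    def test_focal_recovered_on_top_of_chromosome_gain(self):
        mat = self._focal_matrix([150])
        peaks = co.focal_mode(mat, 0.2, "gain", 0.25, n_perm=100, seed=1)
        assert peaks
        top = peaks[0]
        idx = {g.gene_id: i for i, g in enumerate(mat.genes)}
        assert abs(idx[top.peak_gene_id] - 150) <= 5

    def test_two_disjoint_focals_give_two_peaks(self):
        mat = self._focal_matrix([80, 220], seed=2)
        peaks = co.focal_mode(mat, 0.2, "gain", 0.25, n_perm=100, seed=2)
        idx = {g.gene_id: i for i, g in enumerate(mat.genes)}
        found = sorted(idx[p.peak_gene_id] for p in peaks[:2])
        assert abs(found[0] - 80) <= 5 and abs(found[1] - 220) <= 5

    def test_pure_chromosome_gain_yields_no_focal_calls(self):
        values = np.zeros((100, 40))
        values[:, :25] = 0.415
        mat = _matrix(values, genes=_genes(100))
        peaks = co.focal_mode(mat, 0.2, "gain", 0.25, n_perm=100, seed=3)
        assert peaks == []


class TestCallRegions:
    def test_no_significant_genes_empty(self):
        rng = np.random.default_rng(8)
        mat = _matrix(rng.normal(0, 0.05, (100, 30)), genes=_genes(100))
        results = {
            pol: co.score_matrix(mat, 0.2, pol, n_perm=100, seed=4)
            for pol in ("gain", "loss")
        }
        regions = co.call_regions(mat, results, {}, co.PipelineConfig())
        assert regions == []

    def test_planted_whole_chromosome_and_focal_scopes(self):
        rng = np.random.default_rng(9)
        genes = _genes(150, chrom="1") + [
            GeneRecord(f"h{i}", Species.FISH, "2", i * 100_000 + 1,
                       i * 100_000 + 20_000, ordinal=i)
            for i in range(150)
        ]
        values = rng.normal(0, 0.05, (300, 147))
        values[:150, rng.random(147) < 0.6] += 0.415  # whole chr1 (15 Mb)
        values[200:220, rng.random(147) < 0.5] += 1.0  # 2 Mb amp on chr2
        mat = _matrix(values, genes=genes)
        results = {
            pol: co.score_matrix(mat, 0.2, pol, n_perm=150, seed=5)
            for pol in ("gain", "loss")
        }
        regions = co.call_regions(mat, results, {}, co.PipelineConfig())
        large = [r for r in regions if r.scope == "large"]
        focal = [r for r in regions if r.scope == "focal"]
        assert [r.chromosome for r in large] == ["1"]
        assert len(large[0].member_gene_ids) == 150
        assert any(
            r.chromosome == "2" and r.span_bp < 10_000_000 for r in focal
        )


class TestSubpeaks:
    def _region(self, mat, member_idx):
        return co.RecurrentRegion(
            species=Species.FISH,
            chromosome="1",
            start_bp=mat.genes[member_idx[0]].start_bp,
            end_bp=mat.genes[member_idx[-1]].end_bp,
            polarity="gain",
            scope="large",
            peak_gene_ids=[],
            peak_q=0.0,
            member_gene_ids=[mat.genes[i].gene_id for i in member_idx],
        )

    def test_monotone_track_single_peak_at_max(self):
        mat = _matrix(np.zeros((50, 4)), genes=_genes(50))
        res = co.GScoreResult(
            polarity="gain",
            g=np.zeros(50),
            p=np.linspace(0.5, 0.01, 50),
            q=np.linspace(0.5, 0.01, 50),
            freq=np.zeros(50),
        )
        peaks = co.find_subpeaks(res, self._region(mat, list(range(50))), mat)
        assert len(peaks) == 1
        assert peaks[0][0] == mat.genes[49].gene_id

    def test_flat_track_leftmost(self):
        mat = _matrix(np.zeros((30, 4)), genes=_genes(30))
        res = co.GScoreResult(
            polarity="gain", g=np.zeros(30), p=np.full(30, 0.1),
            q=np.full(30, 0.1), freq=np.zeros(30),
        )
        peaks = co.find_subpeaks(res, self._region(mat, list(range(30))), mat)
        assert peaks[0][0] == mat.genes[0].gene_id

    def test_two_planted_subpeaks(self):
        q = np.full(100, 0.2)
        q[30] = 1e-6
        q[70] = 1e-4
        mat = _matrix(np.zeros((100, 4)), genes=_genes(100))
        res = co.GScoreResult(
            polarity="gain", g=np.zeros(100), p=q.copy(), q=q, freq=np.zeros(100)
        )
        peaks = co.find_subpeaks(res, self._region(mat, list(range(100))), mat,
                                 min_prominence=0.5)
        names = [p[0] for p in peaks]
        assert names[:2] == [mat.genes[30].gene_id, mat.genes[70].gene_id]


class TestCohortTTest:
    def test_identical_groups_p_one(self):
        values = np.tile(np.linspace(-0.2, 0.2, 10), (20, 1))
        mat = _matrix(values, genes=_genes(20))
        out = co.cohort_ttest(mat, mat.sample_ids[:5], mat.sample_ids[5:])
        # both groups hold the same per-sample medians under the swap
        swapped = co.cohort_ttest(mat, mat.sample_ids[5:], mat.sample_ids[:5])
        assert np.allclose(np.abs(out["t"]), np.abs(swapped["t"]))

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(10)
        values = rng.normal(0, 0.1, (30, 40))
        values[:, 20:] += 1.0
        mat = _matrix(values, genes=_genes(30))
        out = co.cohort_ttest(mat, mat.sample_ids[:20], mat.sample_ids[20:])
        assert (out["p"] < 1e-6).all()

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(11)
        values = rng.normal(0, 0.3, (25, 24))
        mat = _matrix(values, genes=_genes(25))
        a_ids, b_ids = mat.sample_ids[:10], mat.sample_ids[10:]
        out = co.cohort_ttest(mat, a_ids, b_ids)
        med = np.median(values, axis=0)
        a, b = med[:10], med[10:]
        na, nb = len(a), len(b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        row = out.iloc[0]
        assert row["t"] == pytest.approx(t, abs=1e-12)
        assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_small_group_raises(self):
        mat = _matrix(np.zeros((5, 4)), genes=_genes(5))
        with pytest.raises(ValueError):
            co.cohort_ttest(mat, mat.sample_ids[:1], mat.sample_ids[1:])
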