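import numpy as np
import pytest

from hordeomics.differential import (
    bh_adjust,
    contrast_test,
    impute_half_minimum,
    normalize,
    pca,
    plsda_vip,
    summarize_counts,
    count_percent,
)
from hordeomics.io_core import AbundanceMatrix, Config, SampleDesign


def _matrix(values, genotypes):
    values = np.asarray(values, dtype=float)
    counts = {}
    design = []
    for g in genotypes:
        counts[g] = counts.get(g, 0) + 1
        design.append(SampleDesign(f"{g}_{counts[g]}", g, counts[g]))
    return AbundanceMatrix([f"p{i}" for i in range(values.shape[0])], design, values)


def bh_stepup_oracle(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


class TestNormalize:
    def test_constant_row_becomes_zero(self):
        m = _matrix([[100, 100, 100, 100]], ["WT", "WT", "BC", "BC"])
        assert np.allclose(normalize(m).values, 0.0)

    def test_log10_then_centre(self):
        m = _matrix([[1, 10, 100]], ["WT", "WT", "WT"])
        np.testing.assert_allclose(normalize(m).values, [[-1, 0, 1]], atol=1e-12)

    def test_row_means_zero_on_random_matrix(self, rng):
        m = _matrix(10 ** rng.uniform(1, 6, (30, 6)), ["WT"] * 3 + ["BC"] * 3)
        assert np.abs(normalize(m).values.mean(axis=1)).max() < 1e-12

    def test_nonpositive_directs_to_imputation(self):
        m = _matrix([[0, 1, 2]], ["WT", "WT", "WT"])
        with pytest.raises(ValueError, match="impute"):
            normalize(m)
        assert normalize(impute_half_minimum(m)).values.shape == (1, 3)


class TestBhAdjust:
    def test_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_executed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_independent_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 100)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestContrastTest:
    def test_identical_groups_unchanged(self):
        m = _matrix([[4, 4, 4, 4, 4, 4]], ["BC"] * 3 + ["WT"] * 3)
        (res,) = contrast_test(m, "BC", "WT")
        assert res.mean_log2_ratio == 0.0
        assert res.p_value == 1.0
        assert res.status == "unchanged"

    def test_eightfold_with_jitter_is_up(self, rng):
        base = np.array([[8, 8, 8, 1, 1, 1]], dtype=float)
        jitter = 1 + rng.normal(0, 1e-3, size=base.shape)
        m = _matrix(base * jitter, ["BC"] * 3 + ["WT"] * 3)
        (res,) = contrast_test(m, "BC", "WT")
        assert res.mean_log2_ratio == pytest.approx(3.0, abs=0.01)
        assert res.status == "up"

    def test_direction_swap_negates_ratios_and_swaps_status(self, rng):
        values = 10 ** rng.uniform(2, 6, (40, 6))
        values[:10, :3] *= 100  # strong ups in BC
        values[10:20, :3] /= 100
        m = _matrix(values, ["BC"] * 3 + ["WT"] * 3)
        fwd = contrast_test(m, "BC", "WT")
        rev = contrast_test(m, "WT", "BC")
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        for a, b in zip(fwd, rev):
            assert a.mean_log2_ratio == pytest.approx(-b.mean_log2_ratio, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
            assert swap[a.status] == b.status

    def test_missing_values_exclude_protein(self):
        values = np.array([[1, 2, 3, 4, 5, 6], [1, np.nan, 3, 4, 5, 6]], dtype=float)
        m = _matrix(values, ["BC"] * 3 + ["WT"] * 3)
        res = contrast_test(m, "BC", "WT")
        assert [r.protein_id for r in res] == ["p0"]

    def test_null_type_one_error(self, rng):
        """Type-I error at p<0.05 within 0.05 +/- 0.02 on null data."""
        n = 1000
        values = 10 ** rng.normal(4, 0.3, size=(n, 6))
        m = _matrix(values, ["BC"] * 3 + ["WT"] * 3)
        res = contrast_test(m, "BC", "WT")
        rate = np.mean([r.p_value < 0.05 for r in res])
        assert abs(rate - 0.05) < 0.02


class TestSummaries:
    def test_published_count_arithmetic(self):
        assert count_percent(296, 1907) == 15.5
        assert count_percent(151, 1907) == 7.9

    def test_zero_changed(self):
        assert summarize_counts([], n_quantified=100) == (0, 0, 0, 0.0)

    def test_up_plus_down(self, rng):
        values = 10 ** rng.uniform(2, 6, (20, 6))
        values[:5, :3] *= 1000
        values[5:9, :3] /= 1000
        m = _matrix(values, ["BC"] * 3 + ["WT"] * 3)
        res = contrast_test(m, "BC", "WT")
        n_up, n_down, n_changed, pct = summarize_counts(res)
        assert n_changed == n_up + n_down
        assert pct == round(100.0 * n_changed / 20, 1)


class TestPca:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 8)
        values = np.vstack([2 * t + 1, -3 * t + 5])  # 2 proteins, samples on a line
        m = _matrix(values, ["WT"] * 4 + ["BC"] * 4)
        m.values = m.values - m.values.mean(axis=1, keepdims=True)
        summary = pca(m, n_components=2)
        assert summary.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_gaussian_splits_evenly(self, rng):
        values = rng.normal(10, 1, size=(2, 2000))
        design = ["WT", "BC"] * 1000
        m = _matrix(values, design)
        summary = pca(m, n_components=2)
        assert summary.variance_fraction[0] == pytest.approx(0.5, abs=0.05)
        assert summary.variance_fraction[1] == pytest.approx(0.5, abs=0.05)

    def test_full_reconstruction(self, rng):
        values = rng.normal(10, 1, size=(10, 6))
        m = _matrix(values, ["WT"] * 3 + ["BC"] * 3)
        summary = pca(m, n_components=5)
        recon = summary.scores @ summary.loadings + summary.sample_mean
        np.testing.assert_allclose(recon, m.values.T, atol=1e-9)

    def test_fraction_invariant_to_sample_order(self, rng):
        values = rng.normal(10, 1, size=(10, 6))
        m1 = _matrix(values, ["WT"] * 3 + ["BC"] * 3)
        m2 = _matrix(values[:, ::-1], ["BC"] * 3 + ["WT"] * 3)
        np.testing.assert_allclose(
            pca(m1).variance_fraction, pca(m2).variance_fraction, atol=1e-12
        )


class TestPlsdaVip:
    def _labels(self, m):
        return {s.sample_id: (1 if s.genotype == "BC" else 0) for s in m.design}

    def test_identical_copies_of_discriminant_all_vip_one(self):
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        values = np.tile(y, (7, 1)) + 5
        m = _matrix(values, ["BC"] * 3 + ["WT"] * 3)
        m.values = m.values - m.values.mean(axis=1, keepdims=True)
        ranking = plsda_vip(m, self._labels(m))
        np.testing.assert_allclose(ranking.vip, 1.0, atol=1e-9)

    def test_mean_squared_vip_is_one(self, rng):
        values = rng.normal(10, 1, size=(50, 8))
        m = _matrix(values, ["BC"] * 4 + ["WT"] * 4)
        ranking = plsda_vip(m, self._labels(m))
        assert np.mean(ranking.vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_informative_predictor_ranks_first(self):
        """One informative + 9 noise predictors: informative VIP is the
        maximum in >= 95% of seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            y = np.array([1.0] * 5 + [-1.0] * 5)
            values = r.normal(10, 1, size=(10, 10))
            values[0] = 10 + y * 2 + r.normal(0, 0.2, 10)
            m = _matrix(values, ["BC"] * 5 + ["WT"] * 5)
            ranking = plsda_vip(m, self._labels(m))
            hits += np.argmax(ranking.vip) == 0
        assert hits / n_seeds >= 0.95

    def test_constant_predictor_gets_finite_vip(self, rng):
        values = rng.normal(10, 1, size=(5, 6))
        values[2] = 7.0
        m = _matrix(values, ["BC"] * 3 + ["WT"] * 3)
        ranking = plsda_vip(m, self._labels(m))
        assert np.all(np.isfinite(ranking.vip))

    def test_selection_caps_at_top_n(self, rng):
        y = np.array([1.0] * 3 + [-1.0] * 3)
        values = 5 + np.tile(y, (30, 1)) + rng.normal(0, 0.05, size=(30, 6))
        m = _matrix(values, ["BC"] * 3 + ["WT"] * 3)
        cfg = Config(vip_threshold=0.0, vip_top_n=10)
        ranking = plsda_vip(m, self._labels(m), cfg)
        assert ranking.selected.sum() == 10
        assert ranking.vip[ranking.selected].min() >= np.max(ranking.vip[~ranking.selected])
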