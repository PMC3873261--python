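import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from allelemap.core_io import MISSING
from allelemap.ld import (
    NOT_REACHED,
    background_ld,
    fit_decay,
    ld_scan,
    ld_summary,
    pairwise_r2,
)
from conftest import make_panel


def two_locus_panel(haplotypes):
    calls = np.array(haplotypes, dtype=np.int16)
    return make_panel(calls, positions=[0.0, 5.0])


class TestPairwiseR2:
    def test_complete_coupling(self):
        panel = two_locus_panel([[1, 1], [1, 1], [2, 2], [2, 2]])
        r2, _ = pairwise_r2(panel, "M1", "M2")
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_independence(self):
        panel = two_locus_panel([[1, 1], [1, 2], [2, 1], [2, 2]])
        r2, p = pairwise_r2(panel, "M1", "M2")
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_weighted_form_equals_plain_r2_for_biallelic(self):
        """With two alleles per locus all four collapses coincide, so the
        weighted average equals the plain squared correlation."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            calls = rng.integers(1, 3, size=(40, 2)).astype(np.int16)
            panel = make_panel(calls, positions=[0.0, 1.0])
            try:
                r2, _ = pairwise_r2(panel, "M1", "M2")
            except ValueError:
                continue
            x = (calls[:, 0] == 1).astype(float)
            y = (calls[:, 1] == 1).astype(float)
            plain = np.corrcoef(x, y)[0, 1] ** 2
            assert r2 == pytest.approx(plain, abs=1e-10)

    def test_symmetric_in_marker_order_and_relabeling(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(1, 4, size=(60, 2)).astype(np.int16)
        panel = make_panel(calls, positions=[0.0, 1.0])
        r2_ab, _ = pairwise_r2(panel, "M1", "M2", n_perm=200, seed=3)
        r2_ba, _ = pairwise_r2(panel, "M2", "M1", n_perm=200, seed=3)
        assert r2_ab == pytest.approx(r2_ba, abs=1e-12)
        relabeled = calls.copy()
        relabeled[:, 0] = {1: 3, 2: 1, 3: 2}[1] * (calls[:, 0] == 1) \
            + {1: 3, 2: 1, 3: 2}[2] * (calls[:, 0] == 2) \
            + {1: 3, 2: 1, 3: 2}[3] * (calls[:, 0] == 3)
        panel2 = make_panel(relabeled.astype(np.int16), positions=[0.0, 1.0])
        r2_rel, _ = pairwise_r2(panel2, "M1", "M2", n_perm=200, seed=3)
        assert r2_rel == pytest.approx(r2_ab, abs=1e-12)

    def test_rare_alleles_masked_before_frequencies(self):
        # allele 3 at locus A has frequency 1/30 < 0.05: its carrier drops out
        haps = [[1, 1]] * 15 + [[2, 2]] * 14 + [[3, 1]]
        panel = two_locus_panel(haps)
        r2, _ = pairwise_r2(panel, "M1", "M2")
        # after masking, the table is the perfectly coupled 15/14 panel
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_after_masking_raises(self):
        haps = [[1, 1]] * 30 + [[2, 2]]  # allele 2 at A is rare -> masked
        panel = two_locus_panel(haps)
        with pytest.raises(ValueError):
            pairwise_r2(panel, "M1", "M2")


def fisher_two_sided_oracle(table):
    """Exhaustive hypergeometric enumeration of 2x2 tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2_, c1 = a + b, c + d, a + c
    n = r1 + r2_

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2_, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    lo = max(0, c1 - r2_)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-10))


def test_fisher_p_matches_enumeration_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        table = rng.integers(0, 6, size=(2, 2))
        if table.sum() == 0 or table.sum() > 20:
            continue
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            continue
        _, p = stats.fisher_exact(table, alternative="two-sided")
        assert p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)


class TestBackgroundLd:
    def test_nearest_rank_on_grid(self):
        vals = np.arange(1, 101) / 1000.0  # 0.001 .. 0.100
        assert background_ld(vals) == pytest.approx(0.099)

    def test_constant_values(self):
        with pytest.warns(UserWarning):
            assert background_ld(np.full(50, 0.03)) == pytest.approx(0.03)

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(11)
        for n in (100, 1000, 10_000):
            vals = rng.random(n)
            expected = np.sort(vals)[int(np.ceil(0.99 * n)) - 1]
            assert background_ld(vals) == pytest.approx(expected)

    def test_robust_to_single_outlier(self):
        vals = np.concatenate([np.full(999, 0.01), [5.0]])
        assert background_ld(vals) == pytest.approx(0.01)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            background_ld(np.array([]))


class TestFitDecay:
    def _pairs(self, d, r2):
        import pandas as pd

        return pd.DataFrame({"r2": r2, "distance_cM": d,
                             "p_value": np.zeros(len(d)), "linked": True})

    def test_recovers_exact_log_curve(self):
        d = np.array([1.0, 2.0, 5.0, 10.0, 25.0])
        r2 = 0.5 - 0.1 * np.log(d)
        fit = fit_decay(self._pairs(d, r2), thresholds=(0.2,))
        assert fit.a == pytest.approx(0.5, abs=1e-10)
        assert fit.b == pytest.approx(-0.1, abs=1e-10)
        assert fit.crossings[0.2] == pytest.approx(np.exp(3.0), rel=1e-9)

    def test_threshold_above_intercept_not_reached(self):
        d = np.array([1.0, 3.0, 9.0])
        r2 = 0.3 - 0.05 * np.log(d)
        fit = fit_decay(self._pairs(d, r2), thresholds=(0.9,))
        assert fit.crossings[0.9] is NOT_REACHED

    def test_crossing_beyond_range_not_reached(self):
        d = np.array([1.0, 2.0, 4.0])
        r2 = 0.5 - 0.01 * np.log(d)  # crossing 0.1 at e^40, far beyond 10*max d
        fit = fit_decay(self._pairs(d, r2), thresholds=(0.1,))
        assert fit.crossings[0.1] is NOT_REACHED

    def test_identical_distances_raise(self):
        d = np.array([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            fit_decay(self._pairs(d, np.array([0.5, 0.4, 0.3])))

    def test_positive_slope_warns_and_reaches_nothing(self):
        d = np.array([1.0, 2.0, 8.0])
        r2 = 0.1 + 0.05 * np.log(d)
        with pytest.warns(UserWarning):
            fit = fit_decay(self._pairs(d, r2), thresholds=(0.2,))
        assert fit.crossings[0.2] is NOT_REACHED


def test_scan_and_summary_strata(sim_result):
    _, res = sim_result
    sub = res.panel.subset_markers(res.panel.marker_ids[:20])
    pairs = ld_scan(sub, n_perm=120, seed=5)
    assert set(pairs.columns) >= {"marker_a", "marker_b", "r2", "p_value",
                                  "linked", "distance_cM"}
    assert pairs["r2"].between(0, 1).all()
    assert pairs.loc[pairs["linked"], "distance_cM"].notna().all()
    assert pairs.loc[~pairs["linked"], "distance_cM"].isna().all()
    summary = ld_summary(pairs, alpha=0.01)
    total = summary[summary["stratum"] == "total"].iloc[0]
    assert total["n_pairs"] == len(pairs)


def test_summary_percent_significant():
    import pandas as pd

    pairs = pd.DataFrame({
        "r2": [0.3, 0.3], "p_value": [0.005, 0.5],
        "linked": [True, True], "distance_cM": [1.0, 2.0],
    })
    summary = ld_summary(pairs, alpha=0.01)
    linked = summary[summary["stratum"] == "linked"].iloc[0]
    assert linked["pct_significant"] == pytest.approx(50.0)
    assert linked["mean_r2"] == pytest.approx(0.3)
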