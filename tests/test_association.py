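import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelemap.association import (
    bonferroni_threshold,
    fit_null_mlm,
    fit_ols,
    marker_scan,
    scan_all,
    stability_filter,
    stability_summary,
)
from allelemap.core_io import MISSING, line_means
from allelemap.relatedness import (
    KinshipMatrix,
    estimate_Q_em,
    loiselle_kinship,
    structure_covariates,
)
from allelemap.synthetic_data import SimulationConfig, simulate_panel
from conftest import make_panel


@pytest.mark.parametrize(
    "m,alpha,expected",
    [(145, 0.05, 3.4624), (1, 0.05, 1.3010), (20, 0.05, 2.6021)],
)
def test_bonferroni_threshold(m, alpha, expected):
    assert bonferroni_threshold(m, alpha) == pytest.approx(expected, abs=1e-4)


def test_bonferroni_invalid_inputs():
    with pytest.raises(ValueError):
        bonferroni_threshold(0, 0.05)
    with pytest.raises(ValueError):
        bonferroni_threshold(10, 1.5)


def random_panel(rng, n=50, m=6, max_alleles=4):
    calls = rng.integers(1, max_alleles, size=(n, m)).astype(np.int16)
    return make_panel(calls, positions=list(range(m)))


def anova_oracle(y, calls):
    keep = calls != MISSING
    groups = [y[keep][calls[keep] == a] for a in np.unique(calls[keep])]
    groups = [g for g in groups if len(g)]
    return stats.f_oneway(*groups)[1]


class TestOlsOracleAgreement:
    def test_identity_kinship_matches_one_way_anova(self):
        """With V = I and intercept-only covariates the GLS marker test is a
        plain fixed-effects ANOVA."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            panel = random_panel(rng)
            y = pd.Series(rng.normal(size=panel.n_accessions),
                          index=panel.accession_ids)
            rec = marker_scan(fit_ols(y), panel)
            for _, r in rec.iterrows():
                oracle = anova_oracle(y.to_numpy(), panel.calls_for(r["marker"]))
                assert r["p_value"] == pytest.approx(oracle, abs=1e-8)

    def test_missing_calls_drop_per_marker(self):
        rng = np.random.default_rng(1)
        panel = random_panel(rng, n=40)
        calls = panel.calls.copy()
        calls[3:9, 2] = MISSING
        panel = make_panel(calls, positions=list(range(panel.n_markers)))
        y = pd.Series(rng.normal(size=40), index=panel.accession_ids)
        rec = marker_scan(fit_ols(y), panel).set_index("marker")
        oracle = anova_oracle(y.to_numpy(), panel.calls_for("M3"))
        assert rec.loc["M3", "p_value"] == pytest.approx(oracle, abs=1e-8)
        assert rec.loc["M3", "n_used"] == 34


def test_neg_log10_p_invariant_to_affine_rescaling():
    rng = np.random.default_rng(2)
    panel = random_panel(rng)
    y = pd.Series(rng.normal(size=panel.n_accessions), index=panel.accession_ids)
    r1 = marker_scan(fit_ols(y), panel)
    r2 = marker_scan(fit_ols(7.0 * y + 3.0), panel)
    assert np.allclose(r1["neg_log10_p"], r2["neg_log10_p"], atol=1e-8)


def test_monomorphic_marker_skipped():
    calls = np.ones((30, 2), dtype=np.int16)
    calls[:15, 0] = 2
    panel = make_panel(calls, positions=[0.0, 1.0])
    rng = np.random.default_rng(3)
    y = pd.Series(rng.normal(size=30), index=panel.accession_ids)
    rec = marker_scan(fit_ols(y), panel)
    assert list(rec["marker"]) == ["M1"]


def test_rare_allele_pooling_reduces_classes():
    rng = np.random.default_rng(4)
    calls = rng.integers(1, 3, size=(100, 1)).astype(np.int16)
    calls[:3, 0] = 3  # frequency 0.03 -> pooled
    panel = make_panel(calls, positions=[0.0])
    y = pd.Series(rng.normal(size=100), index=panel.accession_ids)
    rec_pool = marker_scan(fit_ols(y), panel, rare_policy="pool")
    rec_drop = marker_scan(fit_ols(y), panel, rare_policy="drop")
    assert rec_pool["n_classes"].iloc[0] == 3  # two common + pooled
    assert rec_drop["n_used"].iloc[0] == 97


class TestNullFit:
    def test_pure_noise_pushes_genetic_variance_to_boundary(self, sim_result):
        _, res = sim_result
        K = loiselle_kinship(res.panel).to_psd()
        ratios = []
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            y = pd.Series(rng.normal(size=res.panel.n_accessions),
                          index=res.panel.accession_ids)
            fit = fit_null_mlm(y, None, K)
            ratios.append(fit.sigma2_g / (fit.sigma2_g + fit.sigma2_e))
        ratios = np.asarray(ratios)
        # the REML null puts roughly half its mass exactly at zero and the
        # rest near it: most fits land at (or within noise of) the boundary
        assert (ratios < 0.1).mean() >= 0.8
        assert ratios.mean() < 0.15

    def test_non_psd_kinship_rejected(self):
        bad = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        K = KinshipMatrix(bad, ["a1", "a2", "a3"])
        y = pd.Series([0.1, -0.2, 0.5], index=["a1", "a2", "a3"])
        with pytest.raises(ValueError):
            fit_null_mlm(y, None, K)

    def test_too_few_cases_rejected(self):
        K = KinshipMatrix(np.eye(3), ["a1", "a2", "a3"])
        Q = pd.DataFrame({"Q1": [0.5, 0.5, 0.5], "Q2": [0.2, 0.2, 0.2]},
                         index=["a1", "a2", "a3"])
        y = pd.Series([0.1, -0.2, 0.5], index=["a1", "a2", "a3"])
        with pytest.raises(ValueError):
            fit_null_mlm(y, Q, K)


def test_causal_marker_detected_with_power():
    """A causal allele shifting the trait by half a residual SD at n=300
    clears the Bonferroni line in most seeds; a permuted copy of the same
    signal does not."""
    hits = 0
    n_seeds = 5
    for seed in range(n_seeds):
        cfg = SimulationConfig(
            n_accessions=300, n_loci=50, n_chromosomes=10, seed=seed,
            divergence_Fst=0.05, n_founder_haplotypes=60, qtl_spec=(),
        )
        res = simulate_panel(cfg)
        K = loiselle_kinship(res.panel).to_psd()
        marker = None  # need two common alleles for a well-posed test
        for m in res.panel.marker_ids:
            c = res.panel.calls_for(m)
            counts = np.bincount(c[c != MISSING])[1:]
            counts = counts[counts > 0]
            if len(counts) >= 2 and counts.min() >= 60:
                marker = m
                break
        calls = res.panel.calls_for(marker)
        rng = np.random.default_rng(seed)
        ref = calls[calls != MISSING][0]
        y_vals = 0.5 * (calls == ref) + rng.normal(size=300)
        y = pd.Series(y_vals, index=res.panel.accession_ids)
        threshold = bonferroni_threshold(res.panel.n_markers, 0.05)
        fit = fit_null_mlm(y, None, K)
        rec = marker_scan(fit, res.panel).set_index("marker")
        hits += rec.loc[marker, "neg_log10_p"] >= threshold
        perm = pd.Series(rng.permutation(y_vals), index=res.panel.accession_ids)
        rec_p = marker_scan(fit_null_mlm(perm, None, K), res.panel
                            ).set_index("marker")
        assert rec_p.loc[marker, "neg_log10_p"] < threshold
    assert hits >= 4


class TestStability:
    def _records(self, patterns):
        rows = []
        for i, envs in enumerate(patterns):
            for e in ("E1", "E2", "E3"):
                rows.append({"marker": f"M{i}", "trait": "T",
                             "environment": e,
                             "significant_bonferroni": e in envs})
        return pd.DataFrame(rows)

    def test_two_environments_is_stable(self):
        rec = stability_filter(self._records([{"E1", "E2"}]))
        assert rec["stable"].any()
        assert rec["n_env_significant"].max() == 2

    def test_single_environment_not_stable(self):
        rec = stability_filter(self._records([{"E2"}]))
        assert not rec["stable"].any()

    def test_all_three_counted(self):
        rec = stability_filter(self._records([{"E1", "E2", "E3"}]))
        assert rec["n_env_significant"].max() == 3
        assert rec["stable"].all()

    def test_summary_counts(self):
        rec = self._records([{"E1", "E2"}, {"E2"}, set()])
        s = stability_summary(rec)
        assert s["n_associations"] == 2
        assert s["n_stable"] == 1
        assert s["pct_stable"] == pytest.approx(50.0)


def test_scan_all_end_to_end(sim_result):
    cfg, res = sim_result
    K = loiselle_kinship(res.panel)
    Q, _ = estimate_Q_em(res.panel, 2, seed=0, max_iter=60)
    records = scan_all(res.panel, res.phenotypes, structure_covariates(Q), K,
                       traits=["LY"], environments=["E1", "E2"])
    assert set(records["environment"]) == {"E1", "E2"}
    assert records["neg_log10_p"].ge(0).all()
    assert records["marker_R2"].between(0, 1).all()
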