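import numpy as np
import pandas as pd
import pytest

from allelemap.core_io import MISSING
from allelemap.relatedness import (
    ADMIXED,
    assign_subpopulations,
    delta_k,
    estimate_Q_em,
    loiselle_kinship,
    select_structure_markers,
    structure_covariates,
)
from allelemap.synthetic_data import SimulationConfig, simulate_panel
from conftest import make_panel


class TestDeltaK:
    def test_hand_computed_example(self):
        runs = {1: [-100.0], 2: [-90.0, -92.0], 3: [-88.0]}
        dk, chosen = delta_k(runs)
        # |L(3) - 2 L(2) + L(1)| / sd = |-88 + 182 - 100| / 1.41421
        assert dk[2] == pytest.approx(6.0 / np.std([-90, -92], ddof=1), rel=1e-9)
        assert dk[2] == pytest.approx(4.2426, abs=1e-4)
        assert chosen == 2

    def test_linear_means_give_zero(self):
        runs = {k: [-100.0 + 5 * k + eps for eps in (0.0, 0.1)]
                for k in range(1, 6)}
        dk, _ = delta_k(runs)
        assert all(abs(v) < 1e-6 for v in dk.values())

    def test_increasing_lnp_with_curvature_at_two(self):
        # LnP(D) keeps rising, but the second difference peaks at k=2
        runs = {1: [-1000.0, -1001.0], 2: [-800.0, -801.0],
                3: [-790.0, -791.0], 4: [-780.0, -781.0]}
        dk, chosen = delta_k(runs)
        assert chosen == 2

    def test_zero_sd_raises_with_k_named(self):
        runs = {1: [-10.0], 2: [-8.0, -8.0], 3: [-7.0]}
        with pytest.raises(ValueError, match="k=2"):
            delta_k(runs)

    def test_too_few_k_raises(self):
        with pytest.raises(ValueError):
            delta_k({1: [-10.0], 2: [-9.0, -9.5]})

    def test_invariant_to_constant_shift(self):
        runs = {1: [-100.0], 2: [-90.0, -92.0], 3: [-88.0, -88.5],
                4: [-87.0, -87.5]}
        shifted = {k: [v + 500.0 for v in vals] for k, vals in runs.items()}
        dk1, c1 = delta_k(runs)
        dk2, c2 = delta_k(shifted)
        assert c1 == c2
        for k in dk1:
            assert dk1[k] == pytest.approx(dk2[k], rel=1e-9)


class TestAssign:
    def _q(self, rows):
        return pd.DataFrame(rows, columns=["Q1", "Q2"],
                            index=[f"a{i}" for i in range(len(rows))])

    def test_majority_assignment(self):
        asn = assign_subpopulations(self._q([[0.8, 0.2], [0.3, 0.7]]))
        assert list(asn) == ["Q1", "Q2"]

    def test_exact_half_is_admixed(self):
        asn = assign_subpopulations(self._q([[0.5, 0.5]]))
        assert list(asn) == [ADMIXED]

    def test_bad_row_sum_raises(self):
        with pytest.raises(ValueError):
            assign_subpopulations(self._q([[0.9, 0.3]]))


class TestEstimateQEm:
    def test_k1_closed_form_likelihood(self):
        panel = make_panel([[1, 1], [2, 1], [2, 2]])
        Q, lls = estimate_Q_em(panel, 1)
        assert np.allclose(Q.to_numpy(), 1.0)
        # pooled frequencies: M1 {1:1/3, 2:2/3}, M2 {1:2/3, 2:1/3}
        expected = (np.log(1 / 3) + 2 * np.log(2 / 3)
                    + 2 * np.log(2 / 3) + np.log(1 / 3))
        assert lls[-1] == pytest.approx(expected, rel=1e-9)

    def test_k_exceeding_n_raises(self):
        panel = make_panel([[1], [2]])
        with pytest.raises(ValueError):
            estimate_Q_em(panel, 3)

    def test_monomorphic_panel_flat_likelihood(self):
        panel = make_panel(np.ones((5, 3), dtype=np.int16))
        Q, lls = estimate_Q_em(panel, 2, max_iter=50)
        assert len(lls) <= 3
        assert np.allclose(Q.sum(axis=1), 1.0)

    def test_rows_sum_to_one_and_likelihood_monotone(self, sim_result):
        _, res = sim_result
        Q, lls = estimate_Q_em(res.panel, 2, seed=0, max_iter=60)
        assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-8)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_recovers_strong_subpopulations(self):
        """Fst 0.2 without admixture: >90% of lines assigned to truth."""
        hits = []
        for seed in range(3):
            cfg = SimulationConfig(
                n_accessions=120, n_loci=40, n_chromosomes=8, seed=seed,
                divergence_Fst=0.2, admixture_alpha=0.05,
            )
            res = simulate_panel(cfg)
            Q, _ = estimate_Q_em(res.panel, 2, seed=seed, max_iter=150)
            est = (Q.to_numpy()[:, 0] > 0.5).astype(int)
            truth = np.asarray(res.truth.subpop_membership)
            hits.append(max((est == truth).mean(), (est != truth).mean()))
        assert np.mean(hits) > 0.9


class TestLoiselleKinship:
    def test_single_biallelic_locus_hand_example(self):
        panel = make_panel([[1], [1], [2], [2]])
        K = loiselle_kinship(panel)
        # identical pair: sum_a (x-p)^2 = 0.5, denominator 0.5 -> 1.0
        assert K.values[0, 1] == pytest.approx(1.0)
        # opposite pair: raw -1.0, truncated at zero
        assert K.values[0, 2] == 0.0

    def test_duplicating_all_loci_leaves_kinship_unchanged(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(1, 4, size=(12, 5)).astype(np.int16)
        K1 = loiselle_kinship(make_panel(calls))
        K2 = loiselle_kinship(make_panel(np.hstack([calls, calls])))
        assert np.allclose(K1.values, K2.values)

    def test_symmetric_nonnegative(self, sim_result):
        _, res = sim_result
        K = loiselle_kinship(res.panel)
        assert np.allclose(K.values, K.values.T)
        assert np.nanmin(K.values) >= 0.0

    def test_pair_without_shared_locus_is_nan(self):
        calls = np.array([[1, MISSING], [MISSING, 1], [2, 2]], dtype=np.int16)
        with pytest.warns(UserWarning):
            K = loiselle_kinship(make_panel(calls))
        assert np.isnan(K.values[0, 1])

    def test_weakly_related_panel_mostly_below_0_05(self):
        """An information-rich panel of near-unrelated lines: >=80% of pairs
        under 0.05, the hallmark of a usable association panel."""
        fracs = []
        for seed in range(2):
            cfg = SimulationConfig(
                n_accessions=200, n_loci=150, n_chromosomes=20, seed=seed,
                divergence_Fst=0.02, admixture_alpha=1.0,
                n_founder_haplotypes=80, alleles_per_locus_range=(4, 9),
            )
            res = simulate_panel(cfg)
            K = loiselle_kinship(res.panel).values
            iu = np.triu_indices(cfg.n_accessions, 1)
            fracs.append((K[iu] < 0.05).mean())
        assert np.mean(fracs) >= 0.80

    def test_to_psd_clips_negative_eigenvalues(self, sim_result):
        _, res = sim_result
        K = loiselle_kinship(res.panel).to_psd()
        assert np.linalg.eigvalsh(K.values).min() >= -1e-9


def test_structure_marker_thinning_respects_spacing(sim_result):
    _, res = sim_result
    markers = select_structure_markers(res.panel, min_spacing_cM=20.0)
    gmap = res.panel.map
    for chrom, grp in gmap.frame[gmap.frame["marker_id"].isin(markers)].groupby(
        "chromosome"
    ):
        pos = np.sort(grp["position_cM"].to_numpy())
        assert (np.diff(pos) >= 20.0 - 1e-9).all()


def test_structure_covariates_drop_last_column():
    Q = pd.DataFrame([[0.7, 0.3], [0.2, 0.8]], columns=["Q1", "Q2"])
    assert list(structure_covariates(Q).columns) == ["Q1"]
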