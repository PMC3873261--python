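import numpy as np
import pandas as pd
import pytest

from allelemap.allele_mining import (
    allele_effect,
    allele_effects_table,
    favorable_alleles,
    representative_accessions,
    transmission_class,
    transmission_table,
    transmission_frame,
)
from allelemap.core_io import MISSING, AccessionMeta, line_means_wide
from conftest import make_panel


def wide(values, trait="LY", accessions=None):
    accessions = accessions or [f"A{i + 1}" for i in range(len(values))]
    return pd.DataFrame({trait: values}, index=accessions)


class TestAlleleEffect:
    def test_hand_example(self):
        panel = make_panel([[1], [1], [2], [2]])
        lm = wide([10.0, 12.0, 8.0, 6.0])
        a, n = allele_effect(lm, panel, "M1", 1, "LY")
        assert a == pytest.approx(2.0)  # 11 - 9
        assert n == 2

    def test_universal_allele_has_zero_effect(self):
        panel = make_panel([[1], [1], [1]])
        lm = wide([1.0, 2.0, 3.0])
        a, _ = allele_effect(lm, panel, "M1", 1, "LY")
        assert a == pytest.approx(0.0)

    def test_no_phenotyped_carrier_warns(self):
        panel = make_panel([[1], [2]])
        lm = wide([np.nan, 5.0])
        with pytest.warns(UserWarning):
            a, n = allele_effect(lm, panel, "M1", 1, "LY")
        assert np.isnan(a)
        assert n == 0

    def test_missing_genotype_still_counts_in_overall_mean(self):
        panel = make_panel([[1], [2], [MISSING]])
        lm = wide([10.0, 4.0, 1.0])
        a, _ = allele_effect(lm, panel, "M1", 1, "LY")
        assert a == pytest.approx(10.0 - 5.0)

    def test_carrier_weighted_effects_balance_to_zero(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(1, 4, size=(30, 1)).astype(np.int16)
        panel = make_panel(calls)
        lm = wide(list(rng.normal(size=30)))
        table = allele_effects_table(lm, panel, [("M1", "LY")])
        balance = (table["a_i"] * table["n_carriers"]).sum()
        assert balance == pytest.approx(0.0, abs=1e-10)


class TestFavorable:
    def _eff(self, trait, a_i):
        return pd.DataFrame([{"marker": "M1", "allele": 1, "trait": trait,
                              "a_i": a_i, "n_carriers": 5}])

    def test_positive_effect_on_maximized_trait(self):
        out = favorable_alleles(self._eff("LY", 2.0))
        assert out["favorable"].iloc[0]

    def test_negative_effect_on_minimized_trait(self):
        out = favorable_alleles(self._eff("SI", -0.17))
        assert out["favorable"].iloc[0]

    def test_zero_effect_is_not_favorable(self):
        out = favorable_alleles(self._eff("LY", 0.0))
        assert not out["favorable"].iloc[0]

    def test_missing_objective_raises(self):
        with pytest.raises(ValueError):
            favorable_alleles(self._eff("XX", 1.0))


class TestRepresentatives:
    def test_top3_largest(self):
        panel = make_panel([[1], [1], [1], [1]])
        lm = wide([30.0, 25.0, 28.0, 22.0])
        top = representative_accessions(panel, lm, "M1", 1, "LY", 3, +1)
        assert top == ["A1", "A3", "A2"]

    def test_minimized_trait_takes_smallest(self):
        panel = make_panel([[1], [1], [1], [1]])
        lm = wide([10.0, 8.0, 12.0, 9.0], trait="SI")
        top = representative_accessions(panel, lm, "M1", 1, "SI", 3, -1)
        assert top == ["A2", "A4", "A1"]

    def test_fewer_carriers_than_requested(self):
        panel = make_panel([[1], [2], [2]])
        lm = wide([5.0, 4.0, 3.0])
        top = representative_accessions(panel, lm, "M1", 1, "LY", 3, +1)
        assert top == ["A1"]

    def test_ties_break_lexicographically(self):
        panel = make_panel([[1], [1], [1]], accession_ids=["B", "A", "C"])
        lm = wide([7.0, 7.0, 7.0], accessions=["B", "A", "C"])
        top = representative_accessions(panel, lm, "M1", 1, "LY", 2, +1)
        assert top == ["A", "B"]


class TestTransmission:
    @pytest.mark.parametrize(
        "ck,groups,expected",
        [
            (1.0, [0.8462, 1.0, 1.0, 0.9759, 0.9840, 1.0], 1),
            (0.6667, [0.5769, 0.5385, 0.6154, 0.3976, 0.3040, 0.1020], 2),
            (0.0, [0.0, 0.0, 0.05, 0.0, 0.032, 0.0417], 3),
        ],
    )
    def test_worked_classifications(self, ck, groups, expected):
        assert transmission_class(ck, groups) == expected

    def _panel_with_groups(self):
        # CK: 2 lines, I: 3 lines, II: 3 lines
        calls = np.array([[1], [1], [1], [2], [2], [1], [1], [1]],
                         dtype=np.int16)
        panel = make_panel(calls)
        groups = ["CK", "CK", "I", "I", "I", "II", "II", "II"]
        meta = [AccessionMeta(a, g, "", is_founder=(g == "CK"))
                for a, g in zip(panel.accession_ids, groups)]
        return panel, meta

    def test_frequencies_and_total_consistency(self):
        panel, meta = self._panel_with_groups()
        rows = transmission_table(panel, meta, [("M1", 1)])
        row = rows[0]
        assert row.frequencies["CK"] == pytest.approx(1.0)
        assert row.frequencies["I"] == pytest.approx(1 / 3)
        assert row.frequencies["II"] == pytest.approx(1.0)
        # Total = carriers over all typed lines across groups
        assert row.frequencies["Total"] == pytest.approx(6 / 8)

    def test_class3_iff_absent_from_founders(self):
        panel, meta = self._panel_with_groups()
        rows = transmission_table(panel, meta, [("M1", 2)])
        assert rows[0].transmission_class == 3
        assert rows[0].frequencies["CK"] == 0.0

    def test_absent_allele_raises(self):
        panel, meta = self._panel_with_groups()
        with pytest.raises(ValueError):
            transmission_table(panel, meta, [("M1", 9)])

    def test_empty_ck_raises(self):
        panel, _ = self._panel_with_groups()
        meta = [AccessionMeta(a, "I", "") for a in panel.accession_ids]
        with pytest.raises(ValueError):
            transmission_table(panel, meta, [("M1", 1)])

    def test_frame_round_trip(self):
        panel, meta = self._panel_with_groups()
        frame = transmission_frame(transmission_table(panel, meta, [("M1", 1)]))
        assert "transmission_class" in frame.columns


def test_allele_effect_recovers_genetic_deviation(sim_result):
    """a_i tracks the true genetic carrier-mean deviation on a simulated QTL."""
    cfg, res = sim_result
    lm = line_means_wide(res.phenotypes)
    q = cfg.qtl_spec[0]  # LY QTL
    calls = res.panel.calls_for(q.marker_id)
    genetic = res.truth.genetic_values["LY"].to_numpy()
    a_est, n = allele_effect(lm, res.panel, q.marker_id, 1, "LY")
    carriers = calls == 1
    a_true = genetic[carriers].mean() - genetic.mean()
    assert n > 5
    assert a_est == pytest.approx(a_true, abs=0.6 * abs(a_true) + 0.3)
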