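"""Ct arithmetic: efficiencies, digestion QC, 3C frequencies, ddCt, t-tests.

Oracles are hand-computed closed forms evaluated independently in each test.
"""

import math

import numpy as np
import pytest

from loopcall4c.qpcr import (
    PrimerEfficiency,
    digestion_efficiency,
    digestion_qc,
    efficiency_from_standard,
    fold_change_test,
    mcrbc_allele_check,
    occupancy_fold,
    occupancy_profile,
    threec_frequency,
)


class TestEfficiencyFromStandard:
    def _curve(self, slope, intercept=30.0, xs=(-3, -2, -1, 0), dup=False):
        pts = []
        for x in xs:
            pts.append((x, slope * x + intercept))
            if dup:
                pts.append((x, slope * x + intercept))
        return pts

    def test_perfect_doubling_slope(self):
        eff = efficiency_from_standard(self._curve(-3.3219))
        assert eff.efficiency == pytest.approx(2.000, abs=1e-3)

    def test_half_efficiency_slope(self):
        eff = efficiency_from_standard(self._curve(-6.6439))
        assert eff.efficiency == pytest.approx(math.sqrt(2), abs=1e-3)

    def test_duplicates_with_zero_spread_pass_two_ct_check(self):
        eff = efficiency_from_standard(self._curve(-3.3219, dup=True))
        assert eff.max_ct_spread == 0.0
        assert eff.within_two_ct

    def test_large_spread_flagged(self):
        pts = [(-2, 26.0), (-2, 29.0), (-1, 23.0), (0, 20.0)]
        eff = efficiency_from_standard(pts)
        assert not eff.within_two_ct

    def test_shallow_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            efficiency_from_standard([(-2, 30.1), (-1, 30.05), (0, 30.0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            efficiency_from_standard([(-1, 25.0), (0, 22.0)])

    def test_efficiency_bounds_enforced(self):
        with pytest.raises(ValueError):
            PrimerEfficiency("t", 2.5)
        with pytest.raises(ValueError):
            PrimerEfficiency("t", 1.0)


class TestDigestionEfficiency:
    def test_five_ct_shift_is_96875_percent(self):
        pct, ok = digestion_efficiency(30.0, 25.0, 2.0)
        assert pct == pytest.approx(100 * (1 - 2**-5), rel=1e-12)
        assert ok

    def test_no_shift_zero_percent_fails(self):
        pct, ok = digestion_efficiency(25.0, 25.0, 2.0)
        assert pct == 0.0
        assert not ok

    def test_threshold_sits_at_log2_25(self):
        # 96% digested <=> delta Ct >= log2(25) at perfect doubling
        crit = math.log2(25)
        for delta in np.arange(3.0, 7.01, 0.25):
            pct, ok = digestion_efficiency(25.0 + delta, 25.0, 2.0)
            assert ok == (delta >= crit - 1e-12)

    def test_monotone_in_delta_ct(self):
        pcts = [digestion_efficiency(25 + d, 25.0, 2.0)[0] for d in np.linspace(0, 8, 30)]
        assert all(b > a for a, b in zip(pcts, pcts[1:]))

    def test_multi_site_qc_requires_every_site(self):
        sites = {"s1": (30.0, 25.0), "s2": (30.0, 25.2)}  # 96.9%, 96.4%
        table = digestion_qc(sites)
        assert table.attrs["qc_pass"]
        sites["s3"] = (29.0, 25.0)  # delta Ct 4 -> 93.75% only
        assert not digestion_qc(sites).attrs["qc_pass"]


class TestThreecFrequency:
    def test_equal_cts_equal_efficiencies_give_one(self):
        assert threec_frequency(25.0, 25.0, 2.0, 2.0) == pytest.approx(1.0)

    def test_three_ct_difference_is_one_eighth(self):
        assert threec_frequency(25.0, 22.0, 2.0, 2.0) == pytest.approx(0.125, rel=1e-12)

    def test_mixed_efficiencies_match_direct_evaluation(self):
        val = threec_frequency(25.0, 22.0, 1.9, 2.0)
        assert val == pytest.approx(1.9**-25.0 / 2.0**-22.0, rel=1e-12)

    def test_invariant_to_constant_ct_shift_at_equal_efficiency(self):
        a = threec_frequency(25.0, 22.0, 2.0, 2.0)
        b = threec_frequency(28.5, 25.5, 2.0, 2.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_bac_correction_divides(self):
        base = threec_frequency(25.0, 22.0)
        corrected = threec_frequency(25.0, 22.0, bac_correction=0.5)
        assert corrected == pytest.approx(base / 0.5, rel=1e-12)


class TestFoldChangeTest:
    def test_degenerate_two_fold_change(self):
        res = fold_change_test([1, 1, 1], [2, 2, 2])
        assert res.fold == pytest.approx(2.0)
        assert res.p_value < 1e-6

    def test_identical_groups(self):
        res = fold_change_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_t_statistic_matches_pooled_variance_formula(self):
        control = [1.0, 1.2, 0.8]
        mutant = [0.5, 0.6, 0.4]
        res = fold_change_test(control, mutant)
        # textbook pooled-variance two-sample t
        c, m = np.array(control), np.array(mutant)
        sp2 = ((c.size - 1) * c.var(ddof=1) + (m.size - 1) * m.var(ddof=1)) / (
            c.size + m.size - 2
        )
        t_hand = (m.mean() - c.mean()) / math.sqrt(sp2 * (1 / c.size + 1 / m.size))
        assert res.t_statistic == pytest.approx(t_hand, rel=1e-9)

    def test_symmetry_under_group_exchange(self):
        a, b = [1.0, 1.3, 0.9], [2.0, 2.5, 1.8]
        r1 = fold_change_test(a, b)
        r2 = fold_change_test(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.fold == pytest.approx(1 / r2.fold, rel=1e-12)

    def test_welch_option_changes_dof(self):
        a, b = [1.0, 1.01, 0.99], [2.0, 3.5, 0.6, 2.4]
        assert fold_change_test(a, b).p_value != pytest.approx(
            fold_change_test(a, b, equal_var=False).p_value
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            fold_change_test([1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            fold_change_test([1.0, -1.0], [2.0, 2.0])  # zero mean control


class TestOccupancy:
    def test_all_equal_cts_fold_one(self):
        fold = occupancy_fold(
            {"control": 25.0, "mutant": 25.0},
            {"control": (20.0, 21.0), "mutant": (20.0, 21.0)},
        )
        assert fold == pytest.approx(1.0)

    def test_one_cycle_drop_doubles_protection(self):
        fold = occupancy_fold(
            {"control": 25.0, "mutant": 24.0},
            {"control": (20.0, 21.0), "mutant": (20.0, 21.0)},
        )
        assert fold == pytest.approx(2.0, rel=1e-12)

    def test_full_ddct_matches_spreadsheet_oracle(self):
        import itertools
        import pandas as pd

        rng = np.random.default_rng(13)
        rows = []
        cts = {}
        for target, cond, rep in itertools.product(
            ["siteB", "Gapdh", "Actb"], ["control", "mutant"], ["r1", "r2", "r3"]
        ):
            ct = float(rng.uniform(20, 30))
            cts[(target, cond, rep)] = ct
            rows.append(
                {"target": target, "condition": cond, "replicate_id": rep, "ct": ct}
            )
        table = occupancy_profile(pd.DataFrame(rows))
        # spreadsheet-style: per replicate 2^-(Ct_t - mean(Ct_refs)), then
        # fold of means
        def quant(cond, rep):
            ref = (cts[("Gapdh", cond, rep)] + cts[("Actb", cond, rep)]) / 2
            return 2.0 ** -(cts[("siteB", cond, rep)] - ref)

        ctrl = np.mean([quant("control", r) for r in ["r1", "r2", "r3"]])
        mut = np.mean([quant("mutant", r) for r in ["r1", "r2", "r3"]])
        assert table.loc[table["target"] == "siteB", "fold"].iloc[0] == pytest.approx(
            mut / ctrl, rel=1e-9
        )

    def test_missing_reference_rows_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            [{"target": "siteB", "condition": "control", "replicate_id": "r1", "ct": 25.0}]
        )
        with pytest.raises(ValueError, match="reference"):
            occupancy_profile(df)


class TestMcrbcAlleleCheck:
    def test_complete_digestion_pure_maternal(self):
        rep = mcrbc_allele_check(1.0, 1.0, 0.0)
        assert rep["maternal_purity"] == pytest.approx(1.0)
        assert not rep["flagged"]

    def test_four_percent_retention(self):
        rep = mcrbc_allele_check(1.0, 1.0, 0.04)
        assert rep["maternal_purity"] == pytest.approx(1 / 1.04, rel=1e-12)
        assert not rep["flagged"]

    def test_no_digestion_flags_contamination(self):
        rep = mcrbc_allele_check(1.0, 1.0, 1.0)
        assert rep["maternal_purity"] == pytest.approx(0.5)
        assert rep["flagged"]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mcrbc_allele_check(-1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            mcrbc_allele_check(0.0, 0.0, 0.0)
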