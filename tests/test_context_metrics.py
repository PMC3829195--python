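"""Characteristic-type bookkeeping and facilitation / spread arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vsdcontext as v
from vsdcontext.context_metrics import _CELL_CONDITIONS, IncompleteConditionsError


def gauss(A=1.0, sx=2.0, sy=2.0, mu=(10.0, 10.0), rho=0.0) -> v.Gaussian2D:
    return v.Gaussian2D(A=A, mu_x=mu[0], mu_y=mu[1], sigma_x=sx, sigma_y=sy, rho=rho)


def fits_with_amplitudes(amps: dict[str, tuple[float, float]]) -> dict[str, v.TwoSpotFit]:
    """Build TwoSpotFit stubs with given (A_spotA, A_spotB) per condition."""
    return {
        cond: v.TwoSpotFit(gA=gauss(A=a), gB=gauss(A=b), r_fit=1.0,
                           residual_norm=0.0, converged=True)
        for cond, (a, b) in amps.items()
    }


def uniform_fits(a_dir=1.0, a_ind=0.1, a_coh=1.5, a_inc=1.2) -> dict[str, v.TwoSpotFit]:
    """All four cells see the same direct/indirect/coherent/incoherent peaks."""
    return fits_with_amplitudes({
        "A1": (a_dir, a_ind), "B1": (a_ind, a_dir),
        "A2": (a_dir, a_ind), "B2": (a_ind, a_dir),
        "A1B1": (a_coh, a_coh), "A2B2": (a_coh, a_coh),
        "A1B2": (a_inc, a_inc), "A2B1": (a_inc, a_inc),
    })


class TestBuildCharacteristics:
    def test_taxonomy_enumerated_by_hand(self):
        # distinct amplitudes let us verify every cell's condition mapping
        amps = {c: (i + 0.01, i + 0.02) for i, c in enumerate(v.STIMULUS_CONDITIONS, start=1)}
        fits = fits_with_amplitudes(amps)
        cs = v.build_characteristics(fits)
        expected = {
            ("A", 1): ("A1", "B1", "A1B1", "A1B2"),
            ("A", 2): ("A2", "B2", "A2B2", "A2B1"),
            ("B", 1): ("B1", "A1", "A1B1", "A2B1"),
            ("B", 2): ("B2", "A2", "A2B2", "A1B2"),
        }
        for cell, (dir_c, ind_c, coh_c, inc_c) in expected.items():
            loc = cell[0]
            types = cs.cells[cell]
            assert types["direct"].A == fits[dir_c].spot(loc).A
            assert types["indirect"].A == fits[ind_c].spot(loc).A
            assert types["coherent"].A == fits[coh_c].spot(loc).A
            assert types["incoherent"].A == fits[inc_c].spot(loc).A

    def test_b2_incoherent_comes_from_a1b2(self):
        assert _CELL_CONDITIONS[("B", 2)]["incoherent"] == "A1B2"

    def test_missing_pair_conditions_listed(self):
        singles_only = {c: f for c, f in uniform_fits().items() if c in ("A1", "B1", "A2", "B2")}
        with pytest.raises(IncompleteConditionsError) as err:
            v.build_characteristics(singles_only)
        for missing in ("A1B1", "A2B2", "A1B2", "A2B1"):
            assert missing in str(err.value)

    def test_matches_ground_truth_bookkeeping(self, experiment):
        # on synthetic data the mapped amplitudes equal the corresponding
        # condition fits' spot amplitudes, for all 4 (location, movie) cells
        cs = experiment.characteristics
        for (loc, movie), mapping in _CELL_CONDITIONS.items():
            for typ, cond in mapping.items():
                assert cs.cells[(loc, movie)][typ] is experiment.fits[cond].spot(loc)


class TestNormalizeByDirect:
    def test_direct_row_is_ones(self):
        table = v.normalize_by_direct(v.build_characteristics(uniform_fits()))
        direct = table[table["type"] == "direct"]
        np.testing.assert_allclose(direct[["A", "sigma_x", "sigma_y", "joint_spread"]], 1.0)

    def test_coherent_ratio(self):
        table = v.normalize_by_direct(v.build_characteristics(uniform_fits(a_dir=1.0, a_coh=1.5)))
        coh = table[table["type"] == "coherent"]
        np.testing.assert_allclose(coh["A"], 1.5)

    def test_median_matches_sorted_middle_oracle(self, rng):
        amps = {c: tuple(rng.uniform(0.5, 2.0, 2)) for c in v.STIMULUS_CONDITIONS}
        cs = v.build_characteristics(fits_with_amplitudes(amps))
        table = v.normalize_by_direct(cs)
        for typ in v.ACTIVATION_TYPES:
            vals = np.sort(table.loc[table["type"] == typ, "A"].to_numpy())
            brute = 0.5 * (vals[1] + vals[2])  # middle of 4 cells
            assert table.loc[table["type"] == typ, "A_median"].iloc[0] == pytest.approx(brute)

    def test_nonpositive_direct_cell_excluded(self):
        fits = uniform_fits()
        fits["A1"] = v.TwoSpotFit(gA=gauss(A=-0.5), gB=gauss(A=0.1), r_fit=1.0,
                                  residual_norm=0.0, converged=True)
        with pytest.warns(UserWarning, match="excluded"):
            table = v.normalize_by_direct(v.build_characteristics(fits))
        assert len(table) == 3 * len(v.ACTIVATION_TYPES)


class TestPercentChange:
    @pytest.mark.parametrize("ref,new,expected", [
        (6.67e-4, 7.86e-4, 17.84),  # the printed single -> coherent peak step
        (1.0, 1.0, 0.0),
        (1.0, 2.0, 100.0),
    ])
    def test_examples(self, ref, new, expected):
        assert v.percent_change(ref, new) == pytest.approx(expected, abs=0.01)

    def test_printed_peaks_round_to_eighteen_percent(self):
        assert round(v.percent_change(6.67e-4, 7.86e-4)) == 18

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            v.percent_change(0.0, 1.0)


class TestFacilitationMetrics:
    def test_forced_formula_example(self):
        # A_dir=1, A_ind=0.1, A_coh=1.5 -> total 50, superadd 40, linear 10
        metrics = v.facilitation_metrics([v.build_characteristics(uniform_fits())],
                                         n_boot=50, seed=0)
        assert metrics.estimates["total_fac_pct"].point == pytest.approx(50.0)
        assert metrics.estimates["superadd_pct"].point == pytest.approx(40.0)
        assert metrics.estimates["linear_pct"].point == pytest.approx(10.0)
        assert metrics.estimates["specificity_pct"].point == pytest.approx(25.0)

    @given(
        a_dir=st.floats(0.2, 3.0),
        a_ind=st.floats(-0.5, 0.5),
        a_coh=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_plus_superadd_is_total(self, a_dir, a_ind, a_coh):
        total = v.percent_change(a_dir, a_coh)
        superadd = 100.0 * (a_coh - (a_dir + a_ind)) / a_dir
        linear = 100.0 * a_ind / a_dir
        assert linear + superadd == pytest.approx(total, abs=1e-9)

    def test_identity_holds_per_cell_on_synthetic_fits(self, experiment):
        metrics = v.facilitation_metrics([experiment.characteristics], n_boot=50, seed=0)
        per_cell = metrics.per_cell
        np.testing.assert_allclose(per_cell["linear_pct"] + per_cell["superadd_pct"],
                                   per_cell["total_fac_pct"], atol=1e-9)

    def test_negative_indirect_sign_preserved(self):
        metrics = v.facilitation_metrics(
            [v.build_characteristics(uniform_fits(a_ind=-0.1))], n_boot=50, seed=0)
        assert metrics.estimates["linear_pct"].point == pytest.approx(-10.0)
        assert metrics.estimates["superadd_pct"].point == pytest.approx(60.0)

    def test_unusable_direct_cells_dropped_pairwise(self):
        fits = uniform_fits()
        fits["A1"] = v.TwoSpotFit(gA=gauss(A=-1.0), gB=gauss(A=0.1), r_fit=1.0,
                                  residual_norm=0.0, converged=True)
        with pytest.warns(UserWarning):
            metrics = v.facilitation_metrics([v.build_characteristics(fits)], n_boot=50, seed=0)
        assert metrics.n_excluded == 1
        assert metrics.estimates["total_fac_pct"].n == 3


class TestSpreadMetrics:
    def test_forced_anisotropic_arithmetic(self):
        # sigma_y * 1.2, sigma_x unchanged -> y +20%, x 0%, joint sqrt(1.2)-1
        fits = uniform_fits()
        for cond in ("A1B1", "A2B2"):
            fits[cond] = v.TwoSpotFit(gA=gauss(A=1.5, sy=2.4), gB=gauss(A=1.5, sy=2.4),
                                      r_fit=1.0, residual_norm=0.0, converged=True)
        metrics = v.spread_metrics([v.build_characteristics(fits)], n_boot=50, seed=0)
        assert metrics.estimates["spread_y_pct_coh_vs_dir"].point == pytest.approx(20.0)
        assert metrics.estimates["spread_x_pct_coh_vs_dir"].point == pytest.approx(0.0)
        assert metrics.estimates["spread_joint_pct_coh_vs_dir"].point == pytest.approx(
            100.0 * (np.sqrt(1.2) - 1.0))

    def test_identical_fits_give_zero_changes(self):
        metrics = v.spread_metrics([v.build_characteristics(uniform_fits())], n_boot=50, seed=0)
        for est in metrics.estimates.values():
            assert est.point == pytest.approx(0.0)

    def test_recovers_injected_anisotropic_widening(self, experiment, small_cfg):
        # generator widens sigma_y only in paired conditions
        metrics = v.spread_metrics([experiment.characteristics], n_boot=100, seed=0)
        injected_y = 100.0 * (small_cfg.spread_gain_coh[1] - 1.0)
        assert metrics.estimates["spread_y_pct_coh_vs_dir"].point == pytest.approx(injected_y, abs=6.0)
        assert abs(metrics.estimates["spread_x_pct_coh_vs_dir"].point) < 6.0
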