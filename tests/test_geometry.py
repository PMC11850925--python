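"""Element-design geometry: lamina/fraction relation, design recurrence,
flow-ratio theory."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import cifsim as cs
from cifsim.geometry import InfeasibleDesignError


class TestLaminaFraction:
    def test_no_flow_gives_zero_width(self):
        assert cs.lamina_width_from_fraction(0.0, 100.0) == 0.0

    def test_half_fraction_gives_half_width(self):
        # symmetry of the parabolic profile: F(1/2) = 1/2
        assert cs.lamina_width_from_fraction(0.5, 100.0) == pytest.approx(50.0)

    def test_small_fraction_matches_quadrature_oracle(self):
        # oracle: numerically integrate the parabolic flux profile and invert
        def flux_frac(d):
            val, _ = quad(lambda x: 6.0 * x * (1.0 - x), 0.0, d / 100.0)
            return val

        d = cs.lamina_width_from_fraction(1.0e-3, 100.0)
        assert d == pytest.approx(1.837, abs=5e-3)
        assert flux_frac(d) == pytest.approx(1.0e-3, rel=1e-8)

    def test_inverse_examples(self):
        assert cs.fraction_from_lamina_width(0.0, 100.0) == 0.0
        assert cs.fraction_from_lamina_width(50.0, 100.0) == pytest.approx(0.5)
        assert cs.fraction_from_lamina_width(1.837, 100.0) == pytest.approx(1.0e-3, rel=1e-2)

    @given(st.floats(1e-6, 0.5), st.floats(10.0, 1000.0))
    def test_round_trip(self, f, w):
        d = cs.lamina_width_from_fraction(f, w)
        assert cs.fraction_from_lamina_width(d, w) == pytest.approx(f, rel=1e-8)

    @given(st.floats(1e-5, 0.49))
    def test_strictly_increasing_in_fraction(self, f):
        d1 = cs.lamina_width_from_fraction(f, 100.0)
        d2 = cs.lamina_width_from_fraction(f * 1.01, 100.0)
        assert d2 > d1

    @pytest.mark.parametrize("profile", ["parabolic", "duct", "uniform"])
    def test_all_profiles_invert(self, profile):
        d = cs.lamina_width_from_fraction(2e-3, 150.0, profile=profile, depth=150.0)
        f = cs.fraction_from_lamina_width(d, 150.0, profile=profile, depth=150.0)
        assert f == pytest.approx(2e-3, rel=1e-8)

    def test_duct_profile_flatter_than_parabola(self):
        # side walls slow the duct profile near the wall less than the 2-D
        # parabola only in deep channels; for square-ish ducts the lamina for
        # a given fraction is wider (blunter profile near the wall)
        d_par = cs.lamina_width_from_fraction(1e-3, 100.0)
        d_duct = cs.lamina_width_from_fraction(1e-3, 100.0, profile="duct", depth=150.0)
        assert d_duct != pytest.approx(d_par, rel=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cs.lamina_width_from_fraction(0.6, 100.0)
        with pytest.raises(ValueError):
            cs.lamina_width_from_fraction(-0.1, 100.0)
        with pytest.raises(ValueError):
            cs.lamina_width_from_fraction(0.1, -5.0)
        with pytest.raises(ValueError):
            cs.fraction_from_lamina_width(60.0, 100.0)


class TestFlowRatioTheory:
    @pytest.mark.parametrize(
        "fr, loss, fold",
        [(20.0, 100.0 / 21.0, 21.0), (0.0, 100.0, 1.0), (21.1, 100.0 / 22.1, 22.1)],
    )
    def test_limits(self, fr, loss, fold):
        th = cs.flow_ratio_theory(fr)
        assert th.small_cell_loss_percent == pytest.approx(loss)
        assert th.max_concentration_fold == pytest.approx(fold)

    def test_negative_flow_ratio_rejected(self):
        with pytest.raises(ValueError):
            cs.flow_ratio_theory(-1.0)


class TestDesignElement:
    def test_zero_gaps_trivial(self):
        d = cs.design_element(1e-3, n_gaps=0)
        assert d.n_gaps == 0
        assert d.flow_ratio == 0.0
        assert d.retentate_flow_fraction == 1.0
        assert d.flow_schedule(100.0).q_gap.size == 0

    def test_constant_fraction_gap_count_closed_form(self, constant_f_design):
        # with fixed widths the fraction stays at 1e-3 per side, so the
        # retentate flow decays as (1-2e-3)^N; smallest N with FR >= 20
        n_expected = math.ceil(math.log(1.0 / 21.0) / math.log(1.0 - 2e-3))
        assert constant_f_design.n_gaps == n_expected == 1521
        assert np.allclose(constant_f_design.f_gap, 1e-3)
        assert constant_f_design.flow_ratio >= 20.0

    def test_four_study_designs_monotone_with_increasing_cutoffs(self):
        cutoffs = []
        for f_star in (0.72e-3, 1.00e-3, 1.28e-3, 1.70e-3):
            d = cs.design_element(f_star, target_fr=20.0)
            assert np.all(np.diff(d.f_gap) >= -1e-15)
            assert np.all(np.diff(d.w_r) <= 1e-12)
            assert np.all(d.w_r > 0)
            assert np.all(d.w_f > 0)
            assert np.all(np.diff(d.w_f) >= -1e-12)
            cutoffs.append(d.w_l_target)
        assert np.all(np.diff(cutoffs) > 0)

    def test_lamina_constancy(self, design2):
        realized = design2.realized_lamina_widths()
        assert np.max(np.abs(realized - design2.w_l_target)) / design2.w_l_target < 1e-6

    def test_volume_conservation_along_element(self, design2):
        sched = design2.flow_schedule(150.0)
        # retentate + cumulative filtrate = inlet at every station
        assert np.max(np.abs(sched.q_r[1:] + sched.q_fil_cum - 150.0)) < 1e-10 * 150.0
        # per-gap bookkeeping
        assert np.allclose(sched.q_r[:-1] - 2 * sched.q_gap, sched.q_r[1:], rtol=1e-12)

    def test_flow_ratio_consistent_product_vs_terminal(self, design2):
        sched = design2.flow_schedule(1.0)
        fr_flows = (sched.q_in - sched.q_r[-1]) / sched.q_r[-1]
        assert abs(fr_flows - design2.flow_ratio) / design2.flow_ratio < 1e-10

    def test_target_fr_is_minimal_gap_count(self, design2):
        shorter = cs.design_element(1e-3, n_gaps=design2.n_gaps - 1)
        assert shorter.flow_ratio < 20.0
        assert design2.flow_ratio >= 20.0

    @given(
        st.floats(0.4e-3, 3e-3),
        st.floats(120.0, 400.0),
        st.floats(2.0, 15.0),
    )
    def test_monotone_schedules_property(self, f_star, w_star, target_fr):
        d = cs.design_element(f_star, w_r_star=w_star, target_fr=target_fr)
        assert np.all(np.diff(d.f_gap) >= -1e-15)
        assert np.all(np.diff(d.w_r) <= 1e-12)
        assert np.all((d.f_gap > 0) & (d.f_gap < 0.5))
        realized = d.realized_lamina_widths()
        assert np.max(np.abs(realized - d.w_l_target)) / d.w_l_target < 1e-6

    def test_strict_minimum_width_raises_with_gap_index(self):
        with pytest.raises(InfeasibleDesignError) as exc:
            cs.design_element(1e-3, target_fr=20.0, strict_min_width=True)
        assert exc.value.gap_index > 0

    def test_infeasible_when_lamina_exhausts_channel(self):
        # a large starting fraction in a narrow channel drives w_r below
        # twice the lamina width before the target FR is reached
        with pytest.raises(InfeasibleDesignError):
            cs.design_element(0.05, w_r_star=50.0, min_width=1.0, target_fr=500.0)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            cs.design_element(0.2, n_gaps=5)  # f* above the valid range
        with pytest.raises(ValueError):
            cs.design_element(1e-3)  # neither stopping rule
        with pytest.raises(ValueError):
            cs.design_element(1e-3, n_gaps=5, target_fr=10.0)  # both

    def test_csv_json_round_trip(self, design2, tmp_path):
        csv, hdr = tmp_path / "d.csv", tmp_path / "d.json"
        design2.save(csv, hdr)
        back = cs.CIFElementDesign.load(csv, hdr)
        assert back.n_gaps == design2.n_gaps
        assert back.flow_ratio == pytest.approx(design2.flow_ratio, rel=1e-12)
        assert np.allclose(back.f_gap, design2.f_gap)
        assert np.allclose(back.w_r, design2.w_r)
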