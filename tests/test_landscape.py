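"""Reaction-coordinate conversion and free-energy feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transleak import (
    FreeEnergyProfile,
    SynthSpec,
    compare_profiles,
    energy_at,
    find_features,
    gen_pmf,
    radius_to_xi,
    xi_to_radius,
)


class TestConversion:
    @pytest.mark.parametrize(
        "xi,radius",
        [(2.48, 10.5), (1.18, 5.0), (1.83, 7.7), (1.0, 4.2)],
    )
    def test_known_radii_to_one_decimal(self, xi, radius):
        assert round(xi_to_radius(xi), 1) == radius

    def test_nucleation_regime_has_no_radius(self):
        assert np.isnan(xi_to_radius(0.87))

    def test_radius_below_reference_rejected(self):
        with pytest.raises(ValueError):
            radius_to_xi(1.0)

    def test_ten_angstrom_pore(self):
        assert radius_to_xi(10.0) == pytest.approx(2.37, abs=0.005)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(xi=st.floats(1.0, 5.0))
    def test_round_trip_identity(self, xi):
        assert radius_to_xi(xi_to_radius(xi)) == pytest.approx(xi, rel=1e-14)


class TestEnergyAt:
    def _parabola(self):
        xi = np.linspace(0.0, 3.0, 301)
        return FreeEnergyProfile(xi=xi, f=5.0 + 2.0 * (xi - 1.2) ** 2)

    def test_zero_at_global_minimum(self):
        prof = self._parabola()
        assert energy_at(prof, 1.2) == pytest.approx(0.0, abs=1e-12)

    def test_analytic_values_on_parabola(self):
        prof = self._parabola()
        assert energy_at(prof, 2.2) == pytest.approx(2.0, abs=1e-3)
        assert energy_at(prof, 0.2) == pytest.approx(2.0, abs=1e-3)

    def test_interpolated_value_bounded_by_neighbors(self):
        prof = self._parabola()
        lo = energy_at(prof, 2.00)
        hi = energy_at(prof, 2.01)
        assert min(lo, hi) <= energy_at(prof, 2.005) <= max(lo, hi)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            energy_at(self._parabola(), 3.5)


class TestFindFeatures:
    def test_stressed_profile_recovers_generator_truth(self):
        prof, truth = gen_pmf(SynthSpec())
        feats = find_features(prof)
        dx = truth["grid_spacing"]
        assert feats.global_min_xi == pytest.approx(truth["min_xi"], abs=dx + 1e-9)
        assert feats.shoulder_xi == pytest.approx(truth["shoulder_xi"], abs=dx + 1e-9)
        lo, hi = feats.metastable_window
        assert lo == pytest.approx(truth["plateau"][0], abs=dx + 1e-9)
        assert hi == pytest.approx(truth["plateau"][1], abs=dx + 1e-9)
        assert feats.local_min_xi == pytest.approx(truth["dip_xi"], abs=dx + 1e-9)
        assert feats.local_min_depth == pytest.approx(truth["dip_depth"], rel=0.2)

    def test_relaxed_convex_profile_has_no_metastable_features(self):
        from dataclasses import replace

        spec = SynthSpec()
        spec = replace(spec, pmf=replace(spec.pmf, plateau=None, dip_xi=None))
        prof, truth = gen_pmf(spec)
        feats = find_features(prof)
        assert feats.metastable_window is None
        assert feats.local_min_xi is None
        assert truth["plateau"] is None

    def test_constant_profile_flagged_degenerate(self):
        prof = FreeEnergyProfile(xi=np.linspace(0, 3, 50), f=np.full(50, 2.0))
        feats = find_features(prof)
        assert feats.global_min_xi is None
        assert any("degenerate" in f for f in feats.flags)

    def test_invariant_to_constant_energy_shift(self):
        prof, _ = gen_pmf(SynthSpec())
        shifted = FreeEnergyProfile(xi=prof.xi, f=prof.f + 123.4)
        a = find_features(prof)
        b = find_features(shifted)
        assert b.global_min_xi == a.global_min_xi
        assert b.shoulder_xi == a.shoulder_xi
        assert b.metastable_window == a.metastable_window
        assert b.local_min_xi == a.local_min_xi
        assert b.shoulder_energy == pytest.approx(a.shoulder_energy, abs=1e-9)
        assert b.cpp_energy == pytest.approx(a.cpp_energy, abs=1e-9)

    def test_invariant_to_grid_refinement_within_one_spacing(self):
        from dataclasses import replace

        coarse_spec = SynthSpec()
        fine_spec = replace(coarse_spec, pmf=replace(coarse_spec.pmf, n_points=289))
        fa = find_features(gen_pmf(coarse_spec)[0])
        fb = find_features(gen_pmf(fine_spec)[0])
        dx = 0.02
        assert fb.global_min_xi == pytest.approx(fa.global_min_xi, abs=dx + 1e-9)
        assert fb.shoulder_xi == pytest.approx(fa.shoulder_xi, abs=dx + 1e-9)
        for x, y in zip(fb.metastable_window, fa.metastable_window):
            assert x == pytest.approx(y, abs=dx + 1e-9)

    def test_too_few_samples_flagged(self):
        prof = FreeEnergyProfile(xi=np.linspace(0, 3, 5), f=np.arange(5.0))
        feats = find_features(prof)
        assert feats.global_min_xi is None
        assert any("few samples" in f for f in feats.flags)


class TestCompareProfiles:
    def test_identical_profiles_differ_by_zero(self):
        prof, _ = gen_pmf(SynthSpec())
        delta, err = compare_profiles(prof, prof, at_radius=10.0)
        assert delta == 0.0 and err is None

    def test_constant_offset_recovered_at_any_radius(self):
        prof, _ = gen_pmf(SynthSpec())
        other = FreeEnergyProfile(xi=prof.xi, f=prof.f + 4.5)
        for r in (5.0, 7.7, 10.0):
            delta, _ = compare_profiles(prof, other, at_radius=r)
            assert delta == pytest.approx(4.5, abs=1e-9)

    def test_min_reference_cancels_constant_offsets(self):
        prof, _ = gen_pmf(SynthSpec())
        other = FreeEnergyProfile(xi=prof.xi, f=prof.f + 4.5)
        delta, _ = compare_profiles(prof, other, at_radius=10.0, reference="min")
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_error_propagates_in_quadrature(self):
        xi = np.linspace(0.5, 3.0, 26)
        a = FreeEnergyProfile(xi=xi, f=xi**2, err=np.full(26, 0.3))
        b = FreeEnergyProfile(xi=xi, f=xi**2 + 1.0, err=np.full(26, 0.4))
        delta, err = compare_profiles(a, b, at_radius=10.0)
        assert delta == pytest.approx(1.0)
        assert err == pytest.approx(0.5)

    def test_mismatched_ranges_rejected(self):
        a = FreeEnergyProfile(xi=np.linspace(0.5, 3.0, 26), f=np.zeros(26))
        b = FreeEnergyProfile(xi=np.linspace(0.5, 2.0, 16), f=np.zeros(16))
        with pytest.raises(ValueError):
            compare_profiles(a, b, at_radius=10.0)
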