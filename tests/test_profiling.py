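"""Copy-number profiles, Fourier smoothing, peak and fired-origin calling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oristress.core import Origin, ValidationError
from oristress.profiling import (
    ReplicationProfile,
    call_fired_origins,
    call_peaks,
    compute_copy_number,
    fourier_smooth,
    interorigin_distances,
    peak_widths,
)

from conftest import make_track
from oracles import brute_force_peaks


def dct_mode(n_bins: int, k: int) -> np.ndarray:
    """Cosine mode that is symmetric under the filter's mirror padding.

    cos(pi k (i + 1/2) / n) survives mirror-pad + FFT exactly, so pass-band
    modes must come through at machine precision.
    """
    i = np.arange(n_bins)
    return np.cos(np.pi * k * (i + 0.5) / n_bins)


class TestComputeCopyNumber:
    def test_plain_ratio_without_anchoring(self):
        s = make_track([20.0, 40.0, 30.0])
        g1 = make_track([20.0, 20.0, 20.0])
        cn = compute_copy_number(s, g1, anchor="none", g1_reference="binwise")
        np.testing.assert_allclose(cn.data["chrI"], [1.0, 2.0, 1.5])

    def test_flat_reference_divides_by_chromosome_mean(self):
        s = make_track([30.0, 30.0, 30.0, 30.0])
        g1 = make_track([10.0, 20.0, 20.0, 30.0])  # mean 20
        cn = compute_copy_number(s, g1, anchor="none", g1_reference="flat")
        np.testing.assert_allclose(cn.data["chrI"], 1.5)

    def test_total_anchor_equalizes_library_depth(self):
        # S sampled 3x deeper than G1; totals anchoring removes the factor
        s = make_track([60.0, 60.0, 120.0, 60.0])
        g1 = make_track([20.0, 20.0, 20.0, 20.0])
        cn = compute_copy_number(s, g1, anchor="total", g1_reference="binwise")
        # scale = total(G1)/total(S) = 80/300
        np.testing.assert_allclose(cn.data["chrI"], np.array([60, 60, 120, 60]) * (80 / 300) / 20)

    def test_modal_anchor_puts_unreplicated_background_at_one(self):
        rng = np.random.default_rng(0)
        base = np.full(1000, 50.0)
        base[400:450] = 100.0  # a replicated island
        s = make_track(base * 2.0)  # deeper S library
        g1 = make_track(np.full(1000, 50.0))
        cn = compute_copy_number(s, g1, anchor="modal", g1_reference="binwise")
        assert np.median(cn.data["chrI"][:400]) == pytest.approx(1.0, abs=0.02)
        assert cn.data["chrI"][425] == pytest.approx(2.0, abs=0.05)

    def test_low_g1_bins_flagged_missing(self):
        s = make_track([10.0, 10.0])
        g1 = make_track([0.0, 10.0])
        cn = compute_copy_number(s, g1, anchor="none", g1_reference="binwise")
        assert np.isnan(cn.data["chrI"][0])
        assert cn.data["chrI"][1] == 1.0

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_copy_number(make_track([1.0]), make_track([1.0, 1.0]))


class TestFourierSmooth:
    def test_passband_mode_preserved_at_machine_precision(self):
        # wavelength 100 kb (mode 20 on 1000 bins of 1 kb) >> 20 kb cutoff
        y = 1.5 + 0.3 * dct_mode(1000, 20)
        sm = fourier_smooth(make_track(y), 20_000.0)
        np.testing.assert_allclose(sm.data["chrI"], y, atol=1e-10)

    def test_stopband_mode_removed(self):
        # wavelength 4 kb (mode 500) << 20 kb cutoff
        y = 1.5 + 0.3 * dct_mode(1000, 500)
        sm = fourier_smooth(make_track(y), 20_000.0)
        np.testing.assert_allclose(sm.data["chrI"], 1.5, atol=1e-10)

    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1.0, 2.0, 500)
        sm = fourier_smooth(make_track(y), 20_000.0)
        assert sm.data["chrI"].mean() == pytest.approx(y.mean(), abs=1e-9)

    def test_missing_bins_interpolated_then_reflagged(self):
        y = 1.5 + 0.3 * dct_mode(1000, 20)
        y_nan = y.copy()
        y_nan[100:110] = np.nan
        sm = fourier_smooth(make_track(y_nan), 20_000.0)
        assert np.all(np.isnan(sm.data["chrI"][100:110]))
        np.testing.assert_allclose(sm.data["chrI"][200:], y[200:], atol=1e-3)

    def test_cutoff_below_two_bins_rejected(self):
        with pytest.raises(ValidationError):
            fourier_smooth(make_track(np.ones(100)), 1500.0)


class TestCallPeaks:
    def test_triangular_peak_found_at_apex(self):
        y = np.concatenate([np.linspace(1.0, 2.0, 11), np.linspace(2.0, 1.0, 11)[1:]])
        y = np.concatenate([np.full(5, 1.0), y, np.full(5, 1.0)])
        # ramps are 10 steps either side of the apex (> 3 kb at 1 kb bins)
        peaks = call_peaks(make_track(y), persistence_bp=3000)
        assert len(peaks) == 1
        assert peaks[0].apex_bin == 15
        assert peaks[0].apex_value == pytest.approx(2.0)
        assert peaks[0].apex_pos == 15 * 1000 + 501

    def test_flat_profile_has_no_peaks(self):
        assert call_peaks(make_track(np.ones(100))) == []

    def test_monotone_profile_has_no_peaks(self):
        assert call_peaks(make_track(np.linspace(1, 2, 100))) == []

    def test_plateau_yields_single_midpoint_peak(self):
        # apex plateau over bins 10-13 (three zero-derivative steps), short
        # enough that both persistence windows still reach the ramps
        y = np.concatenate(
            [np.linspace(1.0, 2.0, 11), np.full(2, 2.0), np.linspace(2.0, 1.0, 11)]
        )
        peaks = call_peaks(make_track(y), persistence_bp=3000)
        assert len(peaks) == 1
        assert peaks[0].apex_bin == 11  # lower median of the qualifying run

    def test_wide_plateau_is_not_a_peak(self):
        # a 10-step flat top: no bin sees both a rise and a fall within the
        # persistence windows, so the profile has no + -> - change point
        y = np.concatenate(
            [np.linspace(1.0, 2.0, 11), np.full(9, 2.0), np.linspace(2.0, 1.0, 11)]
        )
        assert call_peaks(make_track(y), persistence_bp=3000) == []

    def test_spike_on_rising_background_rejected_by_persistence(self):
        # a one-bin spike on a rising profile breaks the non-positive
        # derivative requirement right after the would-be apex
        y = np.linspace(1.0, 1.5, 100)
        y[50] += 0.2
        assert call_peaks(make_track(y), persistence_bp=3000) == []

    def test_spike_on_flat_background_is_a_peak(self):
        # flat flanks count as non-negative before / non-positive after, so
        # sign persistence is satisfied; the definition is about derivative
        # sign, not about width
        y = np.ones(100)
        y[50] = 2.0
        (p,) = call_peaks(make_track(y), persistence_bp=3000)
        assert p.apex_bin == 50

    def test_peak_too_close_to_chromosome_end_not_called(self):
        y = np.concatenate([np.linspace(1.0, 2.0, 3), np.linspace(2.0, 1.0, 30)[1:]])
        # apex at bin 2 has only 2 pre-steps < the 4 required
        assert all(p.apex_bin != 2 for p in call_peaks(make_track(y), 3000))

    def test_extents_measure_sustained_derivative_sign(self):
        y = np.concatenate([np.full(5, 1.0), np.linspace(1.0, 2.0, 11),
                            np.linspace(2.0, 1.0, 11)[1:], np.full(5, 1.0)])
        p = call_peaks(make_track(y), 3000)[0]
        assert p.left_extent >= 10_000
        assert p.right_extent >= 10_000

    def test_matches_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(12)
        from oracles import piecewise_linear_profile

        for _ in range(25):
            y = piecewise_linear_profile(rng, 300)
            got = [p.apex_bin for p in call_peaks(make_track(y), 3000)]
            assert got == brute_force_peaks(y, 1000, 3000)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_oracle_agreement_property(self, seed):
        rng = np.random.default_rng(seed)
        from oracles import piecewise_linear_profile

        y = piecewise_linear_profile(rng, 120)
        got = [p.apex_bin for p in call_peaks(make_track(y), 3000)]
        assert got == brute_force_peaks(y, 1000, 3000)

    def test_nonpositive_persistence_rejected(self):
        with pytest.raises(ValidationError):
            call_peaks(make_track(np.ones(10)), 0)


def _profile_from(raw: np.ndarray, cutoff: float = 20_000.0) -> ReplicationProfile:
    t = make_track(raw)
    return ReplicationProfile(t, fourier_smooth(t, cutoff), cutoff)


class TestCallFiredOrigins:
    def test_fired_fraction_is_clamped_excess_copy_number(self):
        raw = np.ones(100)
        raw[40:61] = 1.6
        prof = _profile_from(raw)
        ori = Origin("o1", "chrI", 50_500, 20.0)
        (call,) = call_fired_origins(prof, [ori], window_bp=5000)
        assert call.copy_number == pytest.approx(1.6)
        assert call.fired_fraction == pytest.approx(0.6)
        assert call.fired

    def test_copy_number_below_one_clamps_to_zero(self):
        prof = _profile_from(np.full(100, 0.9))
        (call,) = call_fired_origins(prof, [Origin("o", "chrI", 50_000, 20.0)])
        assert call.fired_fraction == 0.0
        assert not call.fired

    def test_threshold_boundary_inclusive(self):
        # 1.25 and 0.25 are exact binary floats, so this probes equality
        prof = _profile_from(np.full(100, 1.25))
        (call,) = call_fired_origins(
            prof, [Origin("o", "chrI", 50_000, 20.0)], fired_threshold=0.25
        )
        assert call.fired_fraction == 0.25
        assert call.fired  # an origin exactly at threshold counts as fired

    def test_origin_matched_to_nearby_peak_only(self):
        raw = np.ones(200)
        raw[90:111] = np.linspace(1.0, 2.0, 11).tolist() + np.linspace(2.0, 1.0, 11)[1:].tolist()
        t = make_track(raw)
        prof = ReplicationProfile(t, t, 20_000.0)  # ringing-free smoothed stand-in
        near = Origin("near", "chrI", 101_000, 20.0)
        far = Origin("far", "chrI", 150_000, 20.0)
        calls = call_fired_origins(prof, [near, far], match_tol=5000)
        assert calls[0].matched_peak is not None
        assert calls[1].matched_peak is None

    def test_unknown_chromosome_rejected(self):
        prof = _profile_from(np.ones(10))
        with pytest.raises(ValidationError):
            call_fired_origins(prof, [Origin("o", "chrII", 5, 20.0)])


class TestInterOriginDistances:
    def _call(self, oid, pos, fired, chrom="chrI"):
        from oristress.profiling import FiredOriginCall

        return FiredOriginCall(Origin(oid, chrom, pos, 20.0), 1.5, 0.5, fired)

    def test_nearest_fired_neighbor_per_origin(self):
        calls = [
            self._call("a", 10_000, True),
            self._call("b", 30_000, True),
            self._call("c", 100_000, True),
            self._call("d", 55_000, False),  # unfired origins are invisible
        ]
        d = dict((o.id, dist) for o, dist in interorigin_distances(calls))
        assert d == {"a": 20_000, "b": 20_000, "c": 70_000}

    def test_lone_fired_origin_has_missing_distance(self):
        (pair,) = interorigin_distances([self._call("a", 10_000, True)])
        assert np.isnan(pair[1])

    def test_chromosomes_do_not_mix(self):
        calls = [
            self._call("a", 10_000, True),
            self._call("b", 20_000, True, chrom="chrII"),
        ]
        for _, dist in interorigin_distances(calls):
            assert np.isnan(dist)


class TestPeakWidths:
    def test_triangle_fwhm_interpolated(self):
        y = np.concatenate([np.full(10, 1.0), np.linspace(1.0, 2.0, 11),
                            np.linspace(2.0, 1.0, 11)[1:], np.full(10, 1.0)])
        t = make_track(y)
        prof = ReplicationProfile(t, t, 20_000.0)
        peaks = peak_widths(prof, call_peaks(t, 3000))
        (p,) = peaks
        # half height 1.5 is crossed 5 bins either side of the apex
        assert p.fwhm == pytest.approx(10_000.0, rel=0.01)
        assert not p.truncated
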