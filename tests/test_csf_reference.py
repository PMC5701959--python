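"""CSF reference selection criteria and the per-time-point shift."""

import numpy as np
import pytest

from dynqsm.config import (AcquisitionParams, PhysioConstants,
                           ReferenceConfig)
from dynqsm.csf_reference import (BASELINE_SLICE, candidate_roi,
                                  filter_by_signal_range, filter_by_tailpeak,
                                  peak_window, select_reference, shift_phase,
                                  shift_susceptibility)
from dynqsm.phantom import simulate_blood_curve, simulate_series
from dynqsm.qsm import FieldSeries, SusceptibilitySeries


@pytest.fixture(scope="module")
def noiseless_setup(phantom48):
    params = AcquisitionParams(n_timepoints=30)
    physio = PhysioConstants()
    blood = simulate_blood_curve(params, 5.0, 9.0, seed=0)
    series = simulate_series(phantom48, blood, params, physio, 0.0, seed=0)
    return phantom48, series


def synthetic_chi_series(phantom, nt=30, seed=0, spike=None):
    """A plausible unshifted susceptibility series: flat CSF, bolus-shaped
    tissue, optional spiked CSF pixels."""
    rng = np.random.default_rng(seed)
    t = np.arange(nt, dtype=float)
    bolus = np.where(t >= 14, np.exp(-((t - 18) / 4.0) ** 2) + 0.1, 0.0)
    chi = np.zeros(phantom.shape + (nt,))
    chi[phantom.masks["gm"], :] = 0.01 * bolus[None, :]
    chi[phantom.masks["wm"], :] = 0.005 * bolus[None, :]
    if spike is not None:
        idx = np.argwhere(phantom.masks["csf"])[:spike]
        for i, j, k in idx:
            chi[i, j, k, nt - 5:] += 0.2
    return SusceptibilitySeries(chi=chi, mask=phantom.masks["brain"],
                                reference_state="unshifted")


class TestCandidateROI:
    def test_equals_ventricular_label_inside_brain(self, phantom48):
        roi = candidate_roi(phantom48.masks)
        sel = np.zeros(phantom48.shape, dtype=bool)
        sel[tuple(roi.T)] = True
        assert np.array_equal(sel, phantom48.masks["csf"])
        assert (sel <= phantom48.masks["brain"]).all()
        assert not (sel & phantom48.masks["wm"]).any()
        assert not (sel & phantom48.masks["gm"]).any()

    def test_empty_csf_raises(self, phantom48):
        masks = dict(phantom48.masks)
        masks["csf"] = np.zeros(phantom48.shape, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            candidate_roi(masks)


class TestSignalRangeFilter:
    def test_threshold_100_keeps_all(self, noiseless_setup):
        phantom, series = noiseless_setup
        roi = candidate_roi(phantom.masks)
        cfg = ReferenceConfig(thresh_range=100.0)
        assert len(filter_by_signal_range(series, roi, cfg)) == len(roi)

    def test_rank_selection_smallest_range(self, noiseless_setup):
        phantom, series = noiseless_setup
        roi = candidate_roi(phantom.masks)[:10]
        cfg = ReferenceConfig(thresh_range=10.0)
        kept = filter_by_signal_range(series, roi, cfg)
        assert len(kept) == 1
        i, j, k = roi.T
        ranges = (series.magnitude[i, j, k, :].max(axis=1)
                  - series.magnitude[i, j, k, :].min(axis=1))
        assert ranges[np.where((roi == kept[0]).all(axis=1))[0][0]] == \
            ranges.min()

    def test_gm_decoys_never_selected_noiseless(self, noiseless_setup):
        """CSF curves are flat (cbv = 0); any GM pixel has larger range."""
        phantom, series = noiseless_setup
        roi = candidate_roi(phantom.masks)
        gm_decoys = np.argwhere(phantom.masks["gm"])[:50]
        mixed = np.vstack([roi, gm_decoys])
        cfg = ReferenceConfig(thresh_range=50.0)
        kept = filter_by_signal_range(series, mixed, cfg)
        kept_set = {tuple(p) for p in kept}
        assert not kept_set & {tuple(p) for p in gm_decoys}

    def test_selection_monotone_in_threshold(self, noiseless_setup):
        phantom, series = noiseless_setup
        roi = candidate_roi(phantom.masks)
        sizes = [len(filter_by_signal_range(
            series, roi, ReferenceConfig(thresh_range=tr)))
            for tr in (5, 10, 25, 50, 100)]
        assert sizes == sorted(sizes)


class TestTailPeakFilter:
    def test_zero_threshold_keeps_all(self, noiseless_setup, phantom48):
        phantom, series = noiseless_setup
        chi = synthetic_chi_series(phantom)
        cand = candidate_roi(phantom.masks)[:20]
        cfg = ReferenceConfig(thresh_tailpeak=0.0)
        sel = filter_by_tailpeak(chi, series, cand, phantom.masks["brain"],
                                 cfg)
        assert len(sel) == 20

    def test_symmetric_trim_counts(self, noiseless_setup):
        """20 candidates at 30% -> drop 3 highest + 3 lowest, keep 14."""
        phantom, series = noiseless_setup
        chi = synthetic_chi_series(phantom, seed=1)
        # make candidate ratios distinct via per-pixel perturbations
        cand = candidate_roi(phantom.masks)[:20]
        rng = np.random.default_rng(0)
        arr = chi.chi.copy()
        for m, (i, j, k) in enumerate(cand):
            arr[i, j, k, -5:] += rng.normal(0, 1e-3)
        chi2 = SusceptibilitySeries(chi=arr, mask=chi.mask,
                                    reference_state="unshifted")
        cfg = ReferenceConfig(thresh_tailpeak=30.0)
        sel = filter_by_tailpeak(chi2, series, cand,
                                 phantom.masks["brain"], cfg)
        assert len(sel) == 14

    def test_spiked_candidate_discarded_first(self, noiseless_setup):
        phantom, series = noiseless_setup
        chi = synthetic_chi_series(phantom, spike=2)
        cand = candidate_roi(phantom.masks)[:20]  # first 2 carry tail spikes
        cfg = ReferenceConfig(thresh_tailpeak=30.0)
        sel = filter_by_tailpeak(chi, series, cand,
                                 phantom.masks["brain"], cfg)
        kept = {tuple(p) for p in sel.pixel_indices}
        assert tuple(cand[0]) not in kept
        assert tuple(cand[1]) not in kept

    def test_all_discarded_raises_with_advice(self, noiseless_setup):
        phantom, series = noiseless_setup
        chi = synthetic_chi_series(phantom)
        cand = candidate_roi(phantom.masks)[:2]
        cfg = ReferenceConfig(thresh_tailpeak=99.0)
        with pytest.raises(ValueError, match="thresh_tailpeak"):
            filter_by_tailpeak(chi, series, cand, phantom.masks["brain"],
                               cfg)

    def test_selection_monotone_in_tailpeak(self, noiseless_setup):
        phantom, series = noiseless_setup
        chi = synthetic_chi_series(phantom, seed=2)
        cand = candidate_roi(phantom.masks)
        sizes = [len(filter_by_tailpeak(
            chi, series, cand, phantom.masks["brain"],
            ReferenceConfig(thresh_tailpeak=tp)))
            for tp in (0.0, 10.0, 30.0, 45.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_peak_window_centred_on_magnitude_minimum(self, noiseless_setup):
        phantom, series = noiseless_setup
        pw = peak_window(series.magnitude, phantom.masks["brain"], 5)
        curve = series.magnitude[phantom.masks["brain"]].mean(axis=0)
        tmin = int(np.argmin(curve))
        assert pw.start <= tmin < pw.stop
        assert pw.stop - pw.start == 5


class TestShift:
    def test_reference_flat_at_baseline_and_idempotent(self, noiseless_setup):
        phantom, series = noiseless_setup
        chi = synthetic_chi_series(phantom, seed=3)
        # add a global drift so there is something to remove
        drift = 0.002 * np.arange(chi.chi.shape[-1])
        chi = SusceptibilitySeries(chi=chi.chi + drift, mask=chi.mask,
                                   reference_state="unshifted")
        sel = select_reference(series, chi, phantom.masks, ReferenceConfig())
        shifted = shift_susceptibility(chi, sel)
        ref = sel.extract(shifted.chi).mean(axis=0)
        base = ref[BASELINE_SLICE].mean()
        assert np.allclose(ref - base, 0.0, atol=1e-12)
        twice = shift_susceptibility(shifted, sel)
        assert np.allclose(twice.chi, shifted.chi, atol=1e-12)
        assert shifted.reference_state == "csf_shifted"

    def test_spatial_differences_preserved(self, noiseless_setup):
        phantom, series = noiseless_setup
        chi = synthetic_chi_series(phantom, seed=4)
        sel = select_reference(series, chi, phantom.masks, ReferenceConfig())
        shifted = shift_susceptibility(chi, sel)
        a = (24, 24, 24)
        b = (20, 28, 22)
        assert np.allclose(chi.chi[a] - chi.chi[b],
                           shifted.chi[a] - shifted.chi[b], atol=1e-12)

    def test_phase_drift_removed(self, noiseless_setup):
        phantom, series = noiseless_setup
        nt = 30
        drift = 0.05 * np.arange(nt)  # linear drift, rad
        vals = np.zeros(phantom.shape + (nt,)) + drift
        fs = FieldSeries(values=vals, mask=phantom.masks["brain"],
                         stage="unwrapped", unit="rad")
        chi = synthetic_chi_series(phantom, seed=5)
        sel = select_reference(series, chi, phantom.masks, ReferenceConfig())
        out = shift_phase(fs, sel)
        csf_curves = sel.extract(out.values)
        assert np.allclose(csf_curves - csf_curves[:, :1], 0.0, atol=1e-10)
        # correction is one scalar per time point: all voxels move equally
        corr = out.diagnostics["csf_correction"]
        assert np.allclose(fs.values - out.values,
                           corr[None, None, None, :], atol=1e-12)

    def test_zero_drift_zero_correction(self, noiseless_setup):
        phantom, series = noiseless_setup
        vals = np.full(phantom.shape + (30,), 0.7)
        fs = FieldSeries(values=vals, mask=phantom.masks["brain"],
                         stage="unwrapped", unit="rad")
        chi = synthetic_chi_series(phantom, seed=6)
        sel = select_reference(series, chi, phantom.masks, ReferenceConfig())
        out = shift_phase(fs, sel)
        assert np.allclose(out.diagnostics["csf_correction"], 0.0,
                           atol=1e-12)

    def test_phase_shift_requires_unwrapped(self, noiseless_setup):
        phantom, series = noiseless_setup
        chi = synthetic_chi_series(phantom, seed=7)
        sel = select_reference(series, chi, phantom.masks, ReferenceConfig())
        fs = FieldSeries(values=np.zeros(phantom.shape + (30,)),
                         mask=phantom.masks["brain"],
                         stage="background-removed", unit="rad")
        with pytest.raises(ValueError, match="unwrapped"):
            shift_phase(fs, sel)
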