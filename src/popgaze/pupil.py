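"""Pupil preprocessing chain and derived measures.

Order of operations (fixed): per-eye moving-average smoothing, binocular
averaging with a dynamic left-right offset, validity recoding (absolute
range, +-3 SD about the trial mean, gaze-off-screen), linear interpolation of
short gaps, then window means — baseline (200 ms before sound onset),
response (2 s after visual onset), and dilation = response - baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gaze import interpolate_gaps
from .series import EyeSampleSeries


def smooth_pupil(t: np.ndarray, p: np.ndarray,
                 window_ms: float = 100.0,
                 fs: float | None = None) -> np.ndarray:
    """Centred moving average over valid samples within the window.

    The window spans ``window_ms`` inclusive of both endpoints (61 samples at
    600 Hz); edges use the truncated window; missing samples stay missing.
    """
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else math.nan
    half = int(round(window_ms / 1000.0 * fs / 2.0))
    n = p.size
    valid = np.isfinite(p)
    vals = np.where(valid, p, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, (csum[hi] - csum[lo]) / cnt, np.nan)
    out[~valid] = np.nan
    return out


def dynamic_offset_mean(t: np.ndarray, left: np.ndarray, right: np.ndarray,
                        ) -> tuple[np.ndarray, bool]:
    """Binocular mean that reconstructs a missing eye from the left-right
    size offset.

    Where both eyes are valid the output is (L+R)/2 and the offset
    d(t) = L - R is recorded; where one eye is valid the missing eye is
    reconstructed from the offset linearly interpolated (nearest-edge
    extrapolated) across surrounding both-valid samples, i.e. the output is
    L - d/2 or R + d/2.  Returns ``(series, used_fallback)``; the fallback is
    a plain available-eye mean when no both-valid sample exists.
    """
    t = np.asarray(t, float)
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    both = np.isfinite(left) & np.isfinite(right)
    only_l = np.isfinite(left) & ~np.isfinite(right)
    only_r = np.isfinite(right) & ~np.isfinite(left)
    out = np.full_like(left, np.nan)
    if not both.any():
        with np.errstate(invalid="ignore"):
            out = np.nanmean(np.vstack([left, right]), axis=0)
        return out, True
    out[both] = 0.5 * (left[both] + right[both])
    if only_l.any() or only_r.any():
        d_hat = np.interp(t, t[both], left[both] - right[both])
        out[only_l] = left[only_l] - 0.5 * d_hat[only_l]
        out[only_r] = right[only_r] + 0.5 * d_hat[only_r]
    return out, False


def recode_invalid(p: np.ndarray,
                   range_mm: tuple[float, float] = (1.5, 9.0),
                   sd_k: float = 3.0,
                   offscreen: np.ndarray | None = None) -> np.ndarray:
    """Recode invalid pupil samples to missing, in three passes applied in
    order: absolute range, +-``sd_k`` SD about the trial mean (mean/SD
    computed once after range recoding), then the gaze-off-screen mask."""
    out = np.asarray(p, float).copy()
    lo, hi = range_mm
    with np.errstate(invalid="ignore"):
        out[(out < lo) | (out > hi)] = np.nan
    if np.isfinite(out).sum() > 1:
        m = np.nanmean(out)
        s = np.nanstd(out)
        if s > 0:
            with np.errstate(invalid="ignore"):
                out[np.abs(out - m) > sd_k * s] = np.nan
    if offscreen is not None:
        out[np.asarray(offscreen, bool)] = np.nan
    return out


def interpolate_pupil(t: np.ndarray, p: np.ndarray,
                      max_gap_ms: float = 150.0) -> np.ndarray:
    """Linear interpolation over gaps shorter than ``max_gap_ms`` (same
    contract as the gaze channel interpolation)."""
    return interpolate_gaps(t, p, max_gap_ms)


def _window_mean(t: np.ndarray, p: np.ndarray,
                 start_s: float, end_s: float) -> tuple[float, float]:
    """(mean over valid samples, missing fraction) on [start_s, end_s)."""
    mask = (t >= start_s) & (t < end_s)
    if not mask.any():
        return math.nan, 1.0
    vals = p[mask]
    ok = np.isfinite(vals)
    frac_missing = float(np.mean(~ok))
    mean = float(np.mean(vals[ok])) if ok.any() else math.nan
    return mean, frac_missing


def baseline_pupil(t: np.ndarray, p: np.ndarray, sound_onset_s: float,
                   window_ms: float = 200.0) -> tuple[float, float]:
    """Mean interpolated pupil size in the window preceding sound onset
    (silent trials carry the equivalent marker)."""
    return _window_mean(t, p, sound_onset_s - window_ms / 1000.0, sound_onset_s)


def response_pupil(t: np.ndarray, p: np.ndarray, visual_onset_s: float,
                   window_s: float = 2.0) -> tuple[float, float]:
    """Mean interpolated pupil size in the first ``window_s`` seconds after
    visual-array onset."""
    return _window_mean(t, p, visual_onset_s, visual_onset_s + window_s)


def pupil_dilation(baseline_mm: float, response_mm: float) -> float:
    """Task-evoked dilation: response minus baseline (NaN if either is)."""
    return response_mm - baseline_mm


@dataclass
class PupilTrialResult:
    baseline_mm: float = math.nan
    response_mm: float = math.nan
    dilation_mm: float = math.nan
    prop_missing_baseline: float = math.nan
    prop_missing_response: float = math.nan
    prop_raw_missing: float = math.nan
    offset_fallback: bool = False


def process_pupil_trial(series: EyeSampleSeries,
                        offscreen: np.ndarray | None = None,
                        smooth_ms: float = 100.0,
                        range_mm: tuple[float, float] = (1.5, 9.0),
                        sd_k: float = 3.0,
                        max_gap_ms: float = 150.0,
                        baseline_ms: float = 200.0,
                        response_s: float = 2.0) -> PupilTrialResult:
    """Full pupil chain for one trial (see module docstring for the order)."""
    t = series.t
    fs = series.fs
    raw_missing = float(np.mean(~(np.isfinite(series.lp)
                                  | np.isfinite(series.rp)))) if series.n else math.nan
    sl = smooth_pupil(t, series.lp, smooth_ms, fs=fs)
    sr = smooth_pupil(t, series.rp, smooth_ms, fs=fs)
    merged, fallback = dynamic_offset_mean(t, sl, sr)
    merged = recode_invalid(merged, range_mm=range_mm, sd_k=sd_k,
                            offscreen=offscreen)
    merged = interpolate_pupil(t, merged, max_gap_ms)
    base, miss_b = baseline_pupil(t, merged, series.sound_onset_s, baseline_ms)
    resp, miss_r = response_pupil(t, merged, series.visual_onset_s, response_s)
    return PupilTrialResult(
        baseline_mm=base,
        response_mm=resp,
        dilation_mm=pupil_dilation(base, resp),
        prop_missing_baseline=miss_b,
        prop_missing_response=miss_r,
        prop_raw_missing=raw_missing,
        offset_fallback=fallback,
    )
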