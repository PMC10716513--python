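"""Gaze preprocessing: gap interpolation, binocular averaging, AOI coding,
first-entry latency, and missingness statistics.

The processing order follows the standard infant eye-tracking chain: each
eye's gaze channels are linearly interpolated over short tracking gaps
(< 150 ms), the two eyes are averaged into a cyclopean signal, gaze samples
are coded against square areas of interest (AOIs) around the four image
positions, and the latency of the first sustained AOI entry (>= 100 ms) from
visual-array onset is extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .series import EyeSampleSeries, GAZE_CHANNELS


# ---------------------------------------------------------------------------
# Gap interpolation (shared with the pupil channel)

def interpolate_gaps(t: np.ndarray, x: np.ndarray,
                     max_gap_ms: float = 150.0) -> np.ndarray:
    """Linearly interpolate NaN runs strictly shorter than ``max_gap_ms``.

    Gap duration is measured from the last valid sample to the next valid
    sample (exclusive of both); leading/trailing gaps are never filled.
    """
    t = np.asarray(t, float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("sample times must be strictly increasing")
    x = np.asarray(x, float)
    out = x.copy()
    valid = np.isfinite(x)
    if valid.sum() < 2 or valid.all():
        return out
    vi = np.flatnonzero(valid)
    # Interior NaN runs: between consecutive valid samples vi[k], vi[k+1].
    gap_len = np.diff(vi)            # >1 marks a gap
    max_gap_s = max_gap_ms / 1000.0
    fill_all = np.interp(t, t[vi], x[vi])
    for k in np.flatnonzero(gap_len > 1):
        i0, i1 = vi[k], vi[k + 1]
        if (t[i1] - t[i0]) < max_gap_s:
            out[i0 + 1:i1] = fill_all[i0 + 1:i1]
    return out


def interpolate_gaze(series: EyeSampleSeries,
                     max_gap_ms: float = 150.0) -> EyeSampleSeries:
    """Interpolate short gaps in each gaze channel of each eye separately."""
    out = series.copy()
    for name in GAZE_CHANNELS:
        setattr(out, name, interpolate_gaps(series.t, getattr(series, name),
                                            max_gap_ms))
    return out


def average_eyes(series: EyeSampleSeries) -> tuple[np.ndarray, np.ndarray]:
    """Cyclopean gaze: per-sample mean of the available eyes.

    Returns ``(x, y)`` arrays; a coordinate is NaN only where both eyes are
    missing.
    """
    return (_nanmean_pair(series.lx, series.rx),
            _nanmean_pair(series.ly, series.ry))


def _nanmean_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok_a, ok_b = np.isfinite(a), np.isfinite(b)
    cnt = ok_a.astype(int) + ok_b
    s = np.where(ok_a, a, 0.0) + np.where(ok_b, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, s / cnt, np.nan)


# ---------------------------------------------------------------------------
# AOIs

@dataclass(frozen=True)
class AOISet:
    """Square AOIs centred on the four image positions, plus the central
    attention-grabber region.

    With the default geometry (centres at (+-12, +-6) deg, 11 deg sides) the
    four image AOIs are pairwise disjoint: centre separations are 24 deg
    horizontally and 12 deg vertically against an 11 deg side.
    """

    centers: dict[str, tuple[float, float]]   # AOI name -> centre (deg)
    side_deg: float = 11.0
    central_side_deg: float = 6.0

    @property
    def half(self) -> float:
        return self.side_deg / 2.0

    def contains(self, name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Closed-square membership; NaN gaze is outside every AOI."""
        cx, cy = self.centers[name]
        with np.errstate(invalid="ignore"):
            inside = (np.abs(x - cx) <= self.half) & (np.abs(y - cy) <= self.half)
        return inside & np.isfinite(x) & np.isfinite(y)

    def in_central_area(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        h = self.central_side_deg / 2.0
        with np.errstate(invalid="ignore"):
            inside = (np.abs(x) <= h) & (np.abs(y) <= h)
        return inside & np.isfinite(x) & np.isfinite(y)


def aoi_set_for_trial(positions: dict[str, str],
                      layout: dict[str, tuple[float, float]],
                      side_deg: float = 11.0,
                      central_side_deg: float = 6.0) -> AOISet:
    """AOIs keyed by image category for one trial's position map."""
    centers = {cat: layout[pos] for cat, pos in positions.items()}
    return AOISet(centers=centers, side_deg=side_deg,
                  central_side_deg=central_side_deg)


def aoi_vectors(x: np.ndarray, y: np.ndarray,
                aois: AOISet) -> dict[str, np.ndarray]:
    """Binary per-sample indicator per AOI (missing gaze -> 0 everywhere)."""
    return {name: aois.contains(name, x, y) for name in aois.centers}


# ---------------------------------------------------------------------------
# First-entry latency

def first_entry_latency(t: np.ndarray,
                        indicators: dict[str, np.ndarray],
                        visual_onset_s: float,
                        visual_offset_s: float | None = None,
                        min_dwell_ms: float = 100.0,
                        fs: float | None = None) -> tuple[float, str] | None:
    """First AOI entry sustained for at least ``min_dwell_ms``.

    Entries are maximal runs of consecutive in-AOI samples within the visual
    presentation window; a run broken by even one missing/outside sample is
    broken.  Run duration is the sample count times the nominal sample
    period.  Returns ``(latency_s, aoi_name)`` relative to visual onset, or
    ``None`` when no entry qualifies.
    """
    t = np.asarray(t, float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else math.nan
    period = 1.0 / fs
    min_count = int(math.ceil(min_dwell_ms / 1000.0 / period - 1e-9))
    window = t >= visual_onset_s
    if visual_offset_s is not None:
        window &= t < visual_offset_s

    best: tuple[float, str] | None = None
    for name, ind in indicators.items():
        v = np.asarray(ind, bool) & window
        if not v.any():
            continue
        padded = np.concatenate([[False], v, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_count:
                onset = float(t[s] - visual_onset_s)
                if best is None or onset < best[0]:
                    best = (onset, name)
                break  # later runs of this AOI start later
    return best


# ---------------------------------------------------------------------------
# Missingness / on-screen statistics

def missingness_stats(raw: EyeSampleSeries,
                      interp_x: np.ndarray, interp_y: np.ndarray,
                      visual_onset_s: float, visual_offset_s: float,
                      screen_halfsize_deg: tuple[float, float] = (21.5, 12.5),
                      ) -> tuple[float, float]:
    """(proportion of raw missing samples over the whole trial,
    proportion of on-screen samples during visual presentation after
    interpolation).

    A raw sample is missing when neither eye provides a full (x, y) gaze
    coordinate; "on-screen" means the interpolated cyclopean gaze is present
    and within the screen bounds.
    """
    left_ok = np.isfinite(raw.lx) & np.isfinite(raw.ly)
    right_ok = np.isfinite(raw.rx) & np.isfinite(raw.ry)
    prop_raw_missing = float(np.mean(~(left_ok | right_ok))) if raw.n else math.nan

    win = raw.window_mask(visual_onset_s, visual_offset_s)
    if not win.any():
        return prop_raw_missing, math.nan
    hx, hy = screen_halfsize_deg
    with np.errstate(invalid="ignore"):
        onscreen = (np.isfinite(interp_x) & np.isfinite(interp_y)
                    & (np.abs(interp_x) <= hx) & (np.abs(interp_y) <= hy))
    return prop_raw_missing, float(np.mean(onscreen[win]))


def onscreen_mask(x: np.ndarray, y: np.ndarray,
                  screen_halfsize_deg: tuple[float, float] = (21.5, 12.5),
                  ) -> np.ndarray:
    """Per-sample on-screen indicator (present AND within bounds)."""
    hx, hy = screen_halfsize_deg
    with np.errstate(invalid="ignore"):
        return (np.isfinite(x) & np.isfinite(y)
                & (np.abs(x) <= hx) & (np.abs(y) <= hy))


def offscreen_mask(x: np.ndarray, y: np.ndarray,
                   screen_halfsize_deg: tuple[float, float] = (21.5, 12.5),
                   ) -> np.ndarray:
    """Gaze detected outside the screen (present but out of bounds).

    Missing gaze is *not* off-screen: it was not detected anywhere.
    """
    hx, hy = screen_halfsize_deg
    with np.errstate(invalid="ignore"):
        return (np.isfinite(x) & np.isfinite(y)
                & ((np.abs(x) > hx) | (np.abs(y) > hy)))


@dataclass
class GazeTrialResult:
    """Per-trial gaze measures."""

    latency_s: float = math.nan
    first_aoi: str | None = None
    time_in_aoi: dict[str, float] = field(default_factory=dict)
    prop_raw_missing: float = math.nan
    prop_onscreen_visual: float = math.nan


def process_gaze_trial(series: EyeSampleSeries, aois: AOISet,
                       max_gap_ms: float = 150.0,
                       min_dwell_ms: float = 100.0,
                       screen_halfsize_deg: tuple[float, float] = (21.5, 12.5),
                       ) -> tuple[GazeTrialResult, EyeSampleSeries,
                                  np.ndarray, np.ndarray]:
    """Full gaze chain for one trial.

    Returns the trial result, the interpolated series, and the cyclopean
    (x, y) arrays so downstream stages (QC, pupil off-screen recoding) reuse
    them without recomputation.
    """
    interp = interpolate_gaze(series, max_gap_ms)
    x, y = average_eyes(interp)
    ind = aoi_vectors(x, y, aois)
    vo, voff = series.visual_onset_s, series.visual_offset_s
    hit = first_entry_latency(series.t, ind, vo, voff,
                              min_dwell_ms=min_dwell_ms, fs=series.fs)
    period = 1.0 / series.fs
    win = series.window_mask(vo, voff)
    time_in = {name: float(np.sum(v & win)) * period for name, v in ind.items()}
    prop_missing, prop_onscreen = missingness_stats(
        series, x, y, vo, voff, screen_halfsize_deg)
    result = GazeTrialResult(
        latency_s=hit[0] if hit else math.nan,
        first_aoi=hit[1] if hit else None,
        time_in_aoi=time_in,
        prop_raw_missing=prop_missing,
        prop_onscreen_visual=prop_onscreen,
    )
    return result, interp, x, y
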