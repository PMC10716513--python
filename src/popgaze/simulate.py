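"""Synthetic binocular eye-tracking sessions with known ground truth.

Emulates 600 Hz recordings of the 56-trial paired-block experiment: each
trial holds gaze at the central attention-grabber, plays a sound cue (or
silence), shows the 4-image array after the inter-stimulus interval, and the
simulated infant saccades to one image.  The pupil trace is an infant
baseline (with a per-infant random intercept and slow "hippus" wandering)
plus an event-locked Erlang-shaped dilation response to the sound, observed
through two eyes separated by a constant size offset, with blinks and
tracking dropouts inserted as missing runs.

Injected effect structure (defaults mirror the hypotheses the analysis
stage is meant to detect):

* sound volume -> dilation: high-volume gain exceeds low-volume gain by
  0.02 mm, both exceed silence (0);
* age -> orienting speed: 10-month latencies are on average 0.09 s faster
  than 5-month latencies;
* age -> face selection: +0.94 log-odds of the first look landing on the
  face at 10 vs 5 months; dilation and (optionally) baseline pupil size
  enter the same logistic model.

The dilation gain is parameterized as the trial's response-window mean of
the smoothed kernel, so for clean signals the injected gain *is* the
dilation the preprocessing chain measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pupil import smooth_pupil
from .schedule import POSITIONS, DesignConfig, TrialSchedule, TrialSpec, generate_schedule
from .series import EyeSampleSeries


def _default_gains() -> dict[str, float]:
    return {"high": 0.09, "low": 0.07, "none": 0.0}


def _default_baseline() -> dict[int, float]:
    return {5: 4.2, 10: 4.4}


def _default_latency_mu() -> dict[int, float]:
    return {5: 0.45, 10: 0.36}


@dataclass
class FaceModel:
    """Logistic model for the first-look target (face vs distractor).

    The linear predictor is
    ``intercept + age*[10m] + vol_rep*[high & first] + dilation_slope*z(amp)
    + baseline_lin*(b - base_ref) + baseline_quad*(b - base_ref)^2 + u_i``
    where ``z(amp)`` standardizes the trial's true dilation amplitude with
    the fixed reference scale ``(amp_center, amp_scale)`` and ``u_i`` is a
    per-infant random intercept.
    """

    intercept: float = -1.1
    age: float = 0.94                 # log-odds, 10 vs 5 months
    vol_rep: float = 0.44             # high-volume cue, first occurrence
    dilation_slope: float = 0.09      # per SD of dilation amplitude
    amp_center: float = 0.08          # mm
    amp_scale: float = 0.18           # mm, reference SD for standardization
    baseline_lin: float = 0.0         # per mm of baseline pupil
    baseline_quad: float = 0.0        # per mm^2 (negative = inverted U)
    base_ref: float = 4.3             # mm, centring point for baseline terms
    re_sd: float = 0.3                # per-infant random intercept SD


@dataclass
class SimulationParams:
    """Cohort, signal, and effect-structure parameters (units in comments)."""

    # Cohort
    n_infants_per_age: int = 23
    ages: tuple[int, ...] = (5, 10)
    # Recording timeline
    fs: float = 600.0                  # Hz
    pre_sound_s: float = 0.75          # attention-grabber tail before sound
    visual_s: float = 3.0              # visual-array presentation
    post_visual_s: float = 0.5         # white screen after the array
    # Tonic pupil
    baseline_pupil_mean: dict[int, float] = field(default_factory=_default_baseline)  # mm
    random_intercept_sd: float = 0.3   # mm, per-infant baseline deviation
    tonic_trial_sd: float = 0.2        # mm, slow between-trial arousal drift
    drift_slope_sd: float = 0.075      # mm/s, slow within-trial tonic drift
    hippus_amp: float = 0.10           # mm, slow sinusoidal wandering
    hippus_freq: tuple[float, float] = (0.15, 0.4)   # Hz
    # Phasic dilation
    kernel_n: int = 10
    kernel_tau: float = 0.1            # s (peak at kernel_n * kernel_tau)
    gains: dict[str, float] = field(default_factory=_default_gains)  # mm by volume
    arousal_intercept_sd: float = 0.03  # mm, per-infant amplitude offset
    amp_noise_sd: float = 0.15         # mm, trial-to-trial amplitude noise
    dilation_noise_sd: float = 0.12    # mm, window noise in the table-level path
    smooth_ms: float = 100.0           # matches the preprocessing smoother
    response_s: float = 2.0            # response window for gain calibration
    # First-look latency (seconds): mu by age + symmetric truncated noise,
    # so the injected age contrast equals the realized mean difference.
    latency_mu: dict[int, float] = field(default_factory=_default_latency_mu)
    latency_sd: float = 0.05
    latency_trunc: float = 0.15        # |noise| bound, keeps latencies in bounds
    latency_re_sd: float = 0.03        # s, per-infant speed offset
    isi_slope: float = 0.0             # s per s of ISI (age-invariant part)
    isi_ref: float = 0.24              # s, centring for the ISI slope
    # Target selection
    face: FaceModel = field(default_factory=FaceModel)
    # Eyes and measurement noise
    eye_offset_mm: float = 0.3         # constant left - right pupil difference
    pupil_noise_sd: float = 0.05       # mm per eye per sample
    gaze_noise_sd: float = 0.5         # deg per eye per sample
    # Missingness / corruption
    blink_rate: float = 0.15           # events/s, binocular
    blink_dur_s: tuple[float, float] = (0.15, 0.06)   # mean, sd
    one_eye_drop_rate: float = 0.05    # events/s per eye
    one_eye_dur_s: float = 0.2
    offscreen_rate: float = 0.05       # probability per trial
    offscreen_dur_s: tuple[float, float] = (0.2, 0.6)  # uniform range
    distract_rate: float = 0.03        # P(no AOI look at all)
    latency_out_frac: float = 0.02     # P(latency outside the 0.2-1.0 s bounds)
    # Geometry
    layout: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(POSITIONS))

    def validate(self) -> None:
        for name in ("blink_rate", "one_eye_drop_rate", "offscreen_rate",
                     "distract_rate", "latency_out_frac", "amp_noise_sd",
                     "pupil_noise_sd", "gaze_noise_sd", "hippus_amp",
                     "random_intercept_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for age, b in self.baseline_pupil_mean.items():
            if not (1.5 <= b <= 9.0):
                raise ValueError(f"baseline pupil mean for age {age} outside "
                                 "the 1.5-9 mm validity range")
        g = self.gains
        if not (g.get("high", 0) >= g.get("low", 0) >= g.get("none", 0)):
            raise ValueError("kernel gains must be ordered high >= low >= none")

    def noise_free(self) -> "SimulationParams":
        """Copy with measurement noise, missingness, and trial-level
        amplitude/tonic variability switched off (ground-truth latencies and
        targets are still drawn)."""
        return replace(
            self,
            hippus_amp=0.0, arousal_intercept_sd=0.0, amp_noise_sd=0.0,
            pupil_noise_sd=0.0, gaze_noise_sd=0.0,
            blink_rate=0.0, one_eye_drop_rate=0.0, offscreen_rate=0.0,
            distract_rate=0.0, latency_out_frac=0.0,
            random_intercept_sd=0.0, latency_re_sd=0.0, tonic_trial_sd=0.0,
            drift_slope_sd=0.0, dilation_noise_sd=0.0,
        )


@dataclass
class InfantState:
    infant_id: str
    age_months: int
    sex: str                  # 'f' | 'm'
    baseline_mm: float        # tonic level incl. random intercept
    arousal_offset: float     # per-infant dilation amplitude offset (mm)
    latency_offset: float     # per-infant orienting-speed offset (s)
    face_u: float             # per-infant face-preference random intercept


def erlang_kernel(t_rel: np.ndarray, n: int = 10, tau: float = 0.1) -> np.ndarray:
    """Erlang-shaped impulse response, peak-normalized to 1 at t = n*tau."""
    t_rel = np.asarray(t_rel, float)
    out = np.zeros_like(t_rel)
    pos = t_rel > 0
    x = t_rel[pos] / (n * tau)
    out[pos] = x ** n * np.exp(n * (1.0 - x))
    return out


def _draw_latency(infant: "InfantState", isi_s: float,
                  params: SimulationParams,
                  rng: np.random.Generator) -> float:
    mu = (params.latency_mu[infant.age_months] + infant.latency_offset
          + params.isi_slope * (isi_s - params.isi_ref))
    if params.latency_sd <= 0:
        return mu
    while True:  # symmetric truncation preserves the mean exactly
        eps = rng.normal(0.0, params.latency_sd)
        if abs(eps) <= params.latency_trunc:
            return mu + eps


def _insert_gap(series_channels: list[np.ndarray], t: np.ndarray,
                start: float, dur: float) -> None:
    i0 = np.searchsorted(t, start)
    i1 = np.searchsorted(t, start + dur)
    for arr in series_channels:
        arr[i0:i1] = np.nan


def simulate_trial(trial: TrialSpec, infant: InfantState,
                   params: SimulationParams,
                   rng: np.random.Generator) -> tuple[EyeSampleSeries, dict]:
    """One trial's raw samples plus its ground-truth record."""
    params.validate()
    fs = params.fs
    isi_s = trial.isi_ms / 1000.0
    so = params.pre_sound_s
    vo = so + isi_s
    voff = vo + params.visual_s
    total = voff + params.post_visual_s
    n = int(round(total * fs))
    t = np.arange(n) / fs

    # ---- pupil ------------------------------------------------------------
    silent = trial.volume == "none"
    tonic = (rng.normal(0.0, params.tonic_trial_sd)
             if params.tonic_trial_sd > 0 else 0.0)
    amp = 0.0
    if not silent:
        amp = (params.gains[trial.volume] + infant.arousal_offset
               + (rng.normal(0.0, params.amp_noise_sd)
                  if params.amp_noise_sd > 0 else 0.0))
    if params.hippus_amp > 0:
        freq = rng.uniform(*params.hippus_freq)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        hippus = params.hippus_amp * np.sin(2.0 * math.pi * freq * t + phase)
    else:
        hippus = np.zeros(n)
    if params.drift_slope_sd > 0:
        hippus = hippus + rng.normal(0.0, params.drift_slope_sd) * (t - so)
    if silent:
        kernel = 0.0
    else:
        k = erlang_kernel(t - so, params.kernel_n, params.kernel_tau)
        # Calibrate the gain scale: unit gain = unit mean of the *smoothed*
        # kernel over this trial's response window, i.e. exactly what the
        # preprocessing chain measures as dilation on a clean signal.
        ks = smooth_pupil(t, k, params.smooth_ms, fs=fs)
        win = (t >= vo) & (t < vo + params.response_s)
        k_mean = float(np.mean(ks[win]))
        kernel = k / k_mean
    cyc = np.full(n, infant.baseline_mm + tonic) + hippus + amp * kernel
    half_off = params.eye_offset_mm / 2.0
    lp = cyc + half_off
    rp = cyc - half_off
    if params.pupil_noise_sd > 0:
        lp += rng.normal(0.0, params.pupil_noise_sd, n)
        rp += rng.normal(0.0, params.pupil_noise_sd, n)

    # ---- gaze -------------------------------------------------------------
    kind = "valid"
    u = rng.random()
    if u < params.distract_rate:
        kind = "distracted"
    elif u < params.distract_rate + params.latency_out_frac:
        kind = "latency_out"

    if kind == "latency_out":
        lat = (rng.uniform(0.05, 0.15) if rng.random() < 0.5
               else rng.uniform(1.05, 1.4))
    elif kind == "valid":
        lat = _draw_latency(infant, isi_s, params, rng)
    else:
        lat = math.nan

    # Target choice from the logistic face-preference model.
    fm = params.face
    base_true = infant.baseline_mm + tonic
    if np.ndim(hippus) and np.ptp(hippus) > 0:
        bwin = (t >= so - 0.2) & (t < so)
        base_true = base_true + float(np.mean(hippus[bwin]))
    lin = (fm.intercept
           + fm.age * (infant.age_months == max(params.ages))
           + fm.vol_rep * ((trial.volume == "high")
                           and (trial.order_in_pair == "first"))
           + fm.dilation_slope * (amp - fm.amp_center) / fm.amp_scale
           + fm.baseline_lin * (base_true - fm.base_ref)
           + fm.baseline_quad * (base_true - fm.base_ref) ** 2
           + infant.face_u)
    p_face = 1.0 / (1.0 + math.exp(-lin))
    if rng.random() < p_face:
        target = "face"
    else:
        target = str(rng.choice([c for c in trial.positions if c != "face"]))

    gx = np.zeros(n)
    gy = np.zeros(n)
    if kind == "distracted":
        # Wanders between the images (central column avoids every AOI).
        seg = max(1, int(round(0.5 * fs)))
        for s0 in range(int(round(vo * fs)), n, seg):
            gx[s0:s0 + seg] = rng.uniform(-4.0, 4.0)
            gy[s0:s0 + seg] = rng.uniform(-10.0, 10.0)
    else:
        tx, ty = params.layout[trial.positions[target]]
        i_sac = np.searchsorted(t, vo + lat)
        gx[i_sac:] = tx
        gy[i_sac:] = ty
    lx = gx.copy(); ly = gy.copy(); rx = gx.copy(); ry = gy.copy()
    if params.gaze_noise_sd > 0:
        for arr in (lx, ly, rx, ry):
            arr += rng.normal(0.0, params.gaze_noise_sd, n)

    # Off-screen excursion during the visual presentation.
    if params.offscreen_rate > 0 and rng.random() < params.offscreen_rate:
        dur = rng.uniform(*params.offscreen_dur_s)
        start = rng.uniform(vo, voff - dur)
        i0, i1 = np.searchsorted(t, [start, start + dur])
        lx[i0:i1] = rx[i0:i1] = 24.0
        ly[i0:i1] = ry[i0:i1] = 13.5

    # Blinks: binocular, hit gaze and pupil together.
    if params.blink_rate > 0:
        for _ in range(rng.poisson(params.blink_rate * total)):
            dur = max(0.03, rng.normal(*params.blink_dur_s))
            start = rng.uniform(0.0, total - dur)
            _insert_gap([lx, ly, rx, ry, lp, rp], t, start, dur)
    # Monocular tracking dropouts (gaze + pupil of one eye).
    if params.one_eye_drop_rate > 0:
        for chans in ([lx, ly, lp], [rx, ry, rp]):
            for _ in range(rng.poisson(params.one_eye_drop_rate * total)):
                dur = max(0.05, rng.normal(params.one_eye_dur_s, 0.05))
                start = rng.uniform(0.0, total - dur)
                _insert_gap(chans, t, start, dur)

    series = EyeSampleSeries(
        t=t, lx=lx, ly=ly, rx=rx, ry=ry, lp=lp, rp=rp,
        sound_onset_s=so, visual_onset_s=vo, visual_offset_s=voff,
        infant_id=infant.infant_id, trial_index=trial.trial_index,
    )
    truth = {
        "infant_id": infant.infant_id,
        "trial_index": trial.trial_index,
        "age_months": infant.age_months,
        "sex": infant.sex,
        "content": trial.sound.content,
        "volume": trial.volume,
        "order_in_pair": trial.order_in_pair,
        "isi_s": isi_s,
        "latency_true_s": lat,
        "first_aoi_true": target if kind != "distracted" else None,
        "dilation_true_mm": amp,
        "baseline_true_mm": base_true,
        "trial_kind": kind,
    }
    return series, truth


def draw_infants(params: SimulationParams,
                 rng: np.random.Generator) -> list[InfantState]:
    infants = []
    for age in params.ages:
        for j in range(params.n_infants_per_age):
            infants.append(InfantState(
                infant_id=f"a{age:02d}_{j:02d}",
                age_months=age,
                sex="m" if j % 2 == 0 else "f",
                baseline_mm=params.baseline_pupil_mean[age]
                + (rng.normal(0.0, params.random_intercept_sd)
                   if params.random_intercept_sd > 0 else 0.0),
                arousal_offset=(rng.normal(0.0, params.arousal_intercept_sd)
                                if params.arousal_intercept_sd > 0 else 0.0),
                latency_offset=(rng.normal(0.0, params.latency_re_sd)
                                if params.latency_re_sd > 0 else 0.0),
                face_u=(rng.normal(0.0, params.face.re_sd)
                        if params.face.re_sd > 0 else 0.0),
            ))
    return infants


def iter_cohort(params: SimulationParams, seed: int,
                design: DesignConfig | None = None):
    """Stream ``(infant, schedule, trial_spec, series, truth)`` tuples.

    Per-infant random state is spawned from ``seed`` so results do not depend
    on consumption order across infants; each infant gets their own
    randomized schedule, as in the experiment.
    """
    params.validate()
    ss = np.random.SeedSequence(seed)
    root = np.random.default_rng(ss.spawn(1)[0])
    infants = draw_infants(params, root)
    child_seeds = ss.spawn(len(infants))
    for infant, child in zip(infants, child_seeds):
        rng = np.random.default_rng(child)
        schedule = generate_schedule(int(rng.integers(2 ** 31)), design)
        for trial in schedule:
            series, truth = simulate_trial(trial, infant, params, rng)
            yield infant, schedule, trial, series, truth


@dataclass
class CohortData:
    """Materialized cohort: per-infant schedules, raw series, ground truth."""

    infants: list[InfantState]
    schedules: dict[str, TrialSchedule]
    sessions: dict[str, list[EyeSampleSeries]]
    truth: pd.DataFrame
    seed: int


def simulate_cohort(params: SimulationParams, seed: int,
                    design: DesignConfig | None = None) -> CohortData:
    """Generate and hold a full cohort in memory (use :func:`iter_cohort`
    for large cohorts)."""
    infants: dict[str, InfantState] = {}
    schedules: dict[str, TrialSchedule] = {}
    sessions: dict[str, list[EyeSampleSeries]] = {}
    truth_rows = []
    for infant, schedule, _trial, series, truth in iter_cohort(params, seed, design):
        infants[infant.infant_id] = infant
        schedules[infant.infant_id] = schedule
        sessions.setdefault(infant.infant_id, []).append(series)
        truth_rows.append(truth)
    return CohortData(
        infants=list(infants.values()),
        schedules=schedules,
        sessions=sessions,
        truth=pd.DataFrame(truth_rows),
        seed=seed,
    )


def simulate_features_table(params: SimulationParams, seed: int,
                            design: DesignConfig | None = None) -> pd.DataFrame:
    """Fast table-level draw from the same effect structure.

    Produces one row per trial with the columns of the analysis table,
    without synthesizing 600 Hz signals: dilation = volume gain + infant
    offset + amplitude noise (+ small measurement noise), baseline = infant
    tonic level + trial-level tonic noise, latency from the truncated-normal
    model, and the face indicator from the logistic face-preference model.
    All trials are valid.  Intended for model-stage studies (null
    calibration, quadratic-recovery) where the signal chain is not under
    test.
    """
    params.validate()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    infants = draw_infants(params, rng)
    fm = params.face
    rows = []
    for infant in infants:
        schedule = generate_schedule(int(rng.integers(2 ** 31)), design)
        for trial in schedule:
            isi_s = trial.isi_ms / 1000.0
            silent = trial.volume == "none"
            amp = 0.0
            if not silent:
                amp = (params.gains[trial.volume] + infant.arousal_offset
                       + (rng.normal(0.0, params.amp_noise_sd)
                          if params.amp_noise_sd > 0 else 0.0))
            base = infant.baseline_mm + (rng.normal(0.0, params.tonic_trial_sd)
                                         if params.tonic_trial_sd > 0 else 0.0)
            lat = _draw_latency(infant, isi_s, params, rng)
            lin = (fm.intercept
                   + fm.age * (infant.age_months == max(params.ages))
                   + fm.vol_rep * ((trial.volume == "high")
                                   and (trial.order_in_pair == "first"))
                   + fm.dilation_slope * (amp - fm.amp_center) / fm.amp_scale
                   + fm.baseline_lin * (base - fm.base_ref)
                   + fm.baseline_quad * (base - fm.base_ref) ** 2
                   + infant.face_u)
            face = int(rng.random() < 1.0 / (1.0 + math.exp(-lin)))
            rows.append({
                "infant_id": infant.infant_id,
                "trial_index": trial.trial_index,
                "age_months": infant.age_months,
                "sex": infant.sex,
                "content": trial.sound.content,
                "volume": trial.volume,
                "order_in_pair": trial.order_in_pair,
                "repetition": int(trial.order_in_pair == "second"),
                "isi_s": isi_s,
                "dilation_mm": amp + (rng.normal(0.0, params.dilation_noise_sd)
                                      if params.dilation_noise_sd > 0 else 0.0),
                "baseline_mm": base,
                "latency_s": lat + rng.uniform(0.0, 1.0 / params.fs),
                "first_look_face": face,
                "prop_raw_missing": 0.0,
                "prop_onscreen_visual": 1.0,
            })
    df = pd.DataFrame(rows)
    df["n_valid_trials"] = df.groupby("infant_id")["trial_index"].transform("count")
    return df
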