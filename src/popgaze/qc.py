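"""Trial-validity screening and assembly of the analysis-ready trial table.

A trial is rejected when any of five criteria is violated:

1. interpolated gaze was not within the central attention-grabbing area for
   more than 40% of the 500 ms before sound onset;
2. interpolated gaze was never within the central area during the 200 ms
   before visual-array onset;
3. gaze was missing or off-screen during the 500 ms after visual onset
   (first clause; reading configurable), or for more than 25% of the
   subsequent 500 ms;
4. no AOI entry lasting at least 100 ms occurred during the visual
   presentation;
5. the first-AOI latency was below 200 ms or above 1 s.

Participants contributing fewer than 70% valid trials are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze import AOISet, GazeTrialResult, onscreen_mask
from .series import EyeSampleSeries

CRITERION_NAMES = ("c1_center_before_sound", "c2_center_before_visual",
                   "c3_missing_after_visual", "c4_no_aoi_entry",
                   "c5_latency_bounds")


@dataclass
class ValidityFlags:
    """Outcome of the five rejection criteria (True = violated)."""

    c1: bool = False
    c2: bool = False
    c3: bool = False
    c4: bool = False
    c5: bool = False

    @property
    def valid(self) -> bool:
        return not (self.c1 or self.c2 or self.c3 or self.c4 or self.c5)

    @property
    def reject_reason(self) -> str | None:
        for name, flag in zip(CRITERION_NAMES,
                              (self.c1, self.c2, self.c3, self.c4, self.c5)):
            if flag:
                return name
        return None

    def as_dict(self) -> dict:
        return {"c1": self.c1, "c2": self.c2, "c3": self.c3,
                "c4": self.c4, "c5": self.c5, "valid": self.valid,
                "reject_reason": self.reject_reason}


def apply_trial_criteria(gaze_result: GazeTrialResult,
                         series: EyeSampleSeries,
                         interp_x: np.ndarray, interp_y: np.ndarray,
                         aois: AOISet,
                         center_frac: float = 0.40,
                         c3_frac: float = 0.25,
                         c3_mode: str = "any",
                         latency_bounds: tuple[float, float] = (0.2, 1.0),
                         screen_halfsize_deg: tuple[float, float] = (21.5, 12.5),
                         ) -> ValidityFlags:
    """Evaluate all five criteria on a preprocessed trial.

    ``interp_x``/``interp_y`` is the interpolated cyclopean gaze on the
    series' time grid.  ``c3_mode`` selects the reading of criterion 3's
    first clause: ``"any"`` (default; any missing/off-screen sample in the
    first 500 ms rejects), ``"all"`` (rejects only if the entire window is
    missing/off-screen), or ``"proportion"`` (rejects above ``c3_frac`` like
    the second clause).
    """
    t = series.t
    so, vo = series.sound_onset_s, series.visual_onset_s
    central = aois.in_central_area(interp_x, interp_y)

    w1 = (t >= so - 0.5) & (t < so)
    c1 = not (w1.any() and float(np.mean(central[w1])) > center_frac)

    w2 = (t >= vo - 0.2) & (t < vo)
    c2 = not (w2.any() and bool(central[w2].any()))

    bad = ~onscreen_mask(interp_x, interp_y, screen_halfsize_deg)
    w3a = (t >= vo) & (t < vo + 0.5)
    w3b = (t >= vo + 0.5) & (t < vo + 1.0)
    if not w3a.any():
        first_clause = True
    elif c3_mode == "any":
        first_clause = bool(bad[w3a].any())
    elif c3_mode == "all":
        first_clause = bool(bad[w3a].all())
    elif c3_mode == "proportion":
        first_clause = float(np.mean(bad[w3a])) > c3_frac
    else:
        raise ValueError(f"unknown c3_mode {c3_mode!r}")
    second_clause = (not w3b.any()) or float(np.mean(bad[w3b])) > c3_frac
    c3 = first_clause or second_clause

    c4 = not math.isfinite(gaze_result.latency_s)
    lo, hi = latency_bounds
    c5 = (math.isfinite(gaze_result.latency_s)
          and not (lo <= gaze_result.latency_s <= hi))
    return ValidityFlags(c1=c1, c2=c2, c3=c3, c4=c4, c5=c5)


def include_participant(flags: list[ValidityFlags] | pd.Series,
                        threshold: float = 0.70) -> tuple[bool, dict]:
    """Participant-level inclusion: valid-trial fraction >= ``threshold``.

    Accepts a list of :class:`ValidityFlags` or a boolean Series of per-trial
    validity.  Returns ``(included, summary)``.
    """
    if isinstance(flags, pd.Series):
        valid = flags.astype(bool).to_numpy()
    else:
        valid = np.array([f.valid for f in flags], dtype=bool)
    n = valid.size
    frac = float(valid.mean()) if n else 0.0
    return frac >= threshold, {"n_trials": int(n),
                               "n_valid": int(valid.sum()),
                               "frac_valid": frac}


def assemble_trial_table(features: pd.DataFrame,
                         flags: pd.DataFrame,
                         participants: pd.DataFrame,
                         include_threshold: float = 0.70,
                         standardize: str | None = "global",
                         ) -> pd.DataFrame:
    """Merge per-trial features, validity flags, and participant metadata
    into the analysis table (one row per valid trial of each included
    participant).

    ``features`` must carry ``infant_id``/``trial_index`` plus the derived
    measures; ``flags`` the per-trial ``valid`` column; ``participants`` one
    row per infant with ``infant_id``, ``age_months``, ``sex``.  Raises on id
    mismatches.  ``standardize`` adds a z-scored dilation column
    (``"global"``: across all valid trials of all included participants;
    ``"per_infant"``: within infant; ``None``: skip).
    """
    f_ids = set(features["infant_id"])
    if f_ids != set(flags["infant_id"]):
        raise ValueError("features/flags infant ids do not match")
    if not f_ids <= set(participants["infant_id"]):
        raise ValueError("participants table is missing infants present in "
                         "the features table")
    df = features.merge(flags[["infant_id", "trial_index", "valid"]],
                        on=["infant_id", "trial_index"], validate="1:1")
    df = df.merge(participants[[c for c in ("infant_id", "age_months", "sex")
                                if c in participants.columns]],
                  on="infant_id", how="left", suffixes=("", "_meta"))

    n_valid = df.groupby("infant_id")["valid"].sum()
    n_total = df.groupby("infant_id")["valid"].size()
    frac = n_valid / n_total
    included = frac[frac >= include_threshold].index
    df = df[df["infant_id"].isin(included) & df["valid"]].copy()
    df["n_valid_trials"] = df["infant_id"].map(n_valid).astype(int)

    if "first_aoi" in df.columns and "first_look_face" not in df.columns:
        df["first_look_face"] = (df["first_aoi"] == "face").astype(int)
    if "order_in_pair" in df.columns and "repetition" not in df.columns:
        df["repetition"] = (df["order_in_pair"] == "second").astype(int)

    if standardize and "dilation_mm" in df.columns:
        if standardize == "global":
            mu = df["dilation_mm"].mean()
            sd = df["dilation_mm"].std()
            df["dilation_z"] = (df["dilation_mm"] - mu) / sd if sd > 0 else 0.0
        elif standardize == "per_infant":
            grp = df.groupby("infant_id")["dilation_mm"]
            df["dilation_z"] = (df["dilation_mm"] - grp.transform("mean")) \
                / grp.transform("std")
        else:
            raise ValueError(f"unknown standardization mode {standardize!r}")
    return df.reset_index(drop=True)


def rejection_summary(flags: pd.DataFrame) -> dict:
    """Per-criterion rejection counts over a flags table."""
    out = {name: int(flags[short].sum())
           for short, name in zip(("c1", "c2", "c3", "c4", "c5"),
                                  CRITERION_NAMES)}
    out["n_trials"] = int(len(flags))
    out["n_valid"] = int(flags["valid"].sum())
    return out
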