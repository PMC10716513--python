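"""End-to-end orchestration: preprocess trials, screen them, assemble the
analysis table, and fit the study's models.

The per-trial path is: gaze interpolation -> binocular averaging -> AOI
coding/latency -> validity criteria; in parallel the pupil chain (smooth ->
dynamic-offset mean -> recoding -> interpolation -> window means) shares the
interpolated gaze for its off-screen recoding.  Pupil features are computed
for gaze-valid trials and retained with their missingness covariates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .gaze import aoi_set_for_trial, offscreen_mask, process_gaze_trial
from .models import ModelSpec, fit_mixed
from .pupil import process_pupil_trial
from .qc import apply_trial_criteria, assemble_trial_table, rejection_summary
from .series import EyeSampleSeries
from .simulate import SimulationParams, iter_cohort
from . import io as pio


def preprocess_trial(series: EyeSampleSeries, trial_info: dict,
                     config: RunConfig) -> tuple[dict, dict]:
    """One trial through the gaze + pupil chains and the QC criteria.

    ``trial_info`` carries the condition labels and the trial's
    category->position map (``pos_face`` etc.).  Returns
    ``(feature_row, flag_row)``.
    """
    positions = {cat: trial_info[f"pos_{cat}"]
                 for cat in ("face", "manmade", "natural", "shape")}
    aois = aoi_set_for_trial(positions, config.layout,
                             side_deg=config.aoi_side_deg,
                             central_side_deg=config.central_side_deg)
    gaze_res, interp, x, y = process_gaze_trial(
        series, aois,
        max_gap_ms=config.max_gap_ms,
        min_dwell_ms=config.min_dwell_ms,
        screen_halfsize_deg=config.screen_halfsize_deg)
    flags = apply_trial_criteria(
        gaze_res, series, x, y, aois,
        center_frac=config.center_frac, c3_frac=config.c3_frac,
        c3_mode=config.c3_mode, latency_bounds=config.latency_bounds,
        screen_halfsize_deg=config.screen_halfsize_deg)
    off = offscreen_mask(x, y, config.screen_halfsize_deg)
    pupil_res = process_pupil_trial(
        series, offscreen=off,
        smooth_ms=config.smooth_ms, range_mm=config.pupil_range_mm,
        sd_k=config.sd_k, max_gap_ms=config.max_gap_ms,
        baseline_ms=config.baseline_ms, response_s=config.response_s)

    feature_row = {
        "infant_id": series.infant_id,
        "trial_index": series.trial_index,
        "content": trial_info.get("content"),
        "volume": trial_info.get("volume"),
        "order_in_pair": trial_info.get("order_in_pair"),
        "isi_s": trial_info.get("isi_s", math.nan),
        "latency_s": gaze_res.latency_s,
        "first_aoi": gaze_res.first_aoi,
        "baseline_mm": pupil_res.baseline_mm,
        "response_mm": pupil_res.response_mm,
        "dilation_mm": pupil_res.dilation_mm,
        "prop_raw_missing": gaze_res.prop_raw_missing,
        "prop_onscreen_visual": gaze_res.prop_onscreen_visual,
        "prop_missing_baseline": pupil_res.prop_missing_baseline,
        "prop_missing_response": pupil_res.prop_missing_response,
        "time_in_aoi_face": gaze_res.time_in_aoi.get("face", math.nan),
    }
    flag_row = {"infant_id": series.infant_id,
                "trial_index": series.trial_index, **flags.as_dict()}
    return feature_row, flag_row


def preprocess_cohort(stream, config: RunConfig,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Consume ``(infant, schedule, trial, series, truth)`` tuples (as from
    :func:`popgaze.simulate.iter_cohort`) and produce the features, flags,
    and participants tables without holding raw signals in memory."""
    feat_rows, flag_rows = [], []
    participants: dict[str, dict] = {}
    for infant, _schedule, trial, series, _truth in stream:
        info = {"content": trial.sound.content, "volume": trial.volume,
                "order_in_pair": trial.order_in_pair,
                "isi_s": trial.isi_ms / 1000.0,
                **{f"pos_{cat}": pos for cat, pos in trial.positions.items()}}
        f, g = preprocess_trial(series, info, config)
        feat_rows.append(f)
        flag_rows.append(g)
        participants[infant.infant_id] = {
            "infant_id": infant.infant_id,
            "age_months": infant.age_months, "sex": infant.sex}
    return (pd.DataFrame(feat_rows), pd.DataFrame(flag_rows),
            pd.DataFrame(participants.values()))


def analyze_simulated_cohort(params: SimulationParams, seed: int,
                             config: RunConfig | None = None,
                             ) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort, run the full preprocessing + QC chain, and return
    the analysis table plus per-criterion rejection counts."""
    config = config or RunConfig()
    features, flags, participants = preprocess_cohort(
        iter_cohort(params, seed), config)
    table = assemble_trial_table(features, flags, participants,
                                 include_threshold=config.include_threshold,
                                 standardize=config.standardize)
    summary = rejection_summary(flags)
    summary["n_participants"] = int(len(participants))
    summary["n_participants_included"] = int(table["infant_id"].nunique())
    return table, summary


def add_model_columns(table: pd.DataFrame,
                      ages: tuple[int, int] = (5, 10)) -> pd.DataFrame:
    """Derived analysis columns: the older-age indicator and sex coding."""
    out = table.copy()
    out["age10"] = (out["age_months"] == max(ages)).astype(int)
    if out["sex"].dtype == object:
        out["sex_m"] = (out["sex"] == "m").astype(int)
    return out


#: Model specifications mirroring the study's three headline analyses.
def headline_specs() -> dict[str, ModelSpec]:
    return {
        "volume_dilation": ModelSpec(
            "dilation_mm", ("C(volume, Treatment(reference='low'))",),
            family="gaussian"),
        "age_latency": ModelSpec("latency_s", ("age10",), family="gaussian"),
        "age_face": ModelSpec("first_look_face", ("age10",),
                              family="binomial"),
    }


def recover_effects(table: pd.DataFrame) -> dict[str, float]:
    """Fit the three headline models on an analysis table and extract the
    injected-effect estimates: the high-vs-low volume contrast on dilation
    (mm), the 10-vs-5-month effect on latency (s), and the 10-vs-5-month
    log-odds on face selection."""
    table = add_model_columns(table)
    specs = headline_specs()
    out: dict[str, float] = {}
    fit = fit_mixed(specs["volume_dilation"], table)
    (high_name,) = [c for c in fit.params.index if "[T.high]" in c]
    out["volume_dilation_mm"] = float(fit.params[high_name])
    fit = fit_mixed(specs["age_latency"], table)
    out["age_latency_s"] = float(fit.params["age10"])
    fit = fit_mixed(specs["age_face"], table)
    out["age_face_logodds"] = float(fit.params["age10"])
    return out


@dataclass
class PipelineResult:
    features: pd.DataFrame
    flags: pd.DataFrame
    table: pd.DataFrame
    rejections: dict
    effects: dict


def run_pipeline(config: RunConfig | None = None,
                 params: SimulationParams | None = None,
                 indir=None, outdir=None, seed: int | None = None,
                 fit_models: bool = True) -> PipelineResult:
    """Run the pipeline end to end.

    Either simulate a cohort (``params``) or read ``samples.tsv`` /
    ``events.tsv`` / ``participants.tsv`` from ``indir``.  Deterministic
    given the seeds; writes the stage tables and a JSON log of per-stage
    counts when ``outdir`` is given.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    if (params is None) == (indir is None):
        raise ValueError("provide exactly one of `params` (simulate) or "
                         "`indir` (read recorded tables)")
    if params is not None:
        features, flags, participants = preprocess_cohort(
            iter_cohort(params, seed), config)
    else:
        indir = Path(indir)
        events = pio.read_events(indir / "events.tsv")
        series_list = pio.read_samples(indir / "samples.tsv", events)
        participants = pio.read_table(indir / "participants.tsv")
        info = {(r["infant_id"], r["trial_index"]): r.to_dict()
                for _, r in events.iterrows()}
        feat_rows, flag_rows = [], []
        for s in series_list:
            f, g = preprocess_trial(s, info[(s.infant_id, s.trial_index)],
                                    config)
            feat_rows.append(f)
            flag_rows.append(g)
        features, flags = pd.DataFrame(feat_rows), pd.DataFrame(flag_rows)

    table = assemble_trial_table(features, flags, participants,
                                 include_threshold=config.include_threshold,
                                 standardize=config.standardize)
    rejections = rejection_summary(flags)
    rejections["n_participants"] = int(len(participants))
    rejections["n_participants_included"] = int(table["infant_id"].nunique())
    effects = recover_effects(table) if fit_models and len(table) else {}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_table(outdir / "features.tsv", features)
        pio.write_table(outdir / "flags.tsv", flags)
        pio.write_table(outdir / "analysis_table.tsv", table)
        with open(outdir / "pipeline_log.json", "w") as fh:
            json.dump({"rejections": rejections, "effects": effects,
                       "seed": seed}, fh, indent=2)
    return PipelineResult(features=features, flags=flags, table=table,
                          rejections=rejections, effects=effects)
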