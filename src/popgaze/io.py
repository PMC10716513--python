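"""Readers and writers for the long-format sample, event, and feature TSVs.

All artifacts are tab-separated text with an explicit ``NA`` missing-value
token; times are seconds, gaze in screen-centered visual degrees, pupil in
millimetres.  The sample/event writers round-trip losslessly (within float
formatting) with the readers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series import CHANNELS, EyeSampleSeries

SAMPLE_COLUMNS = ("infant_id", "trial_index", "t") + CHANNELS
EVENT_COLUMNS = ("infant_id", "trial_index", "sound_onset_s",
                 "visual_onset_s", "visual_offset_s")


def samples_frame(series_list: list[EyeSampleSeries]) -> pd.DataFrame:
    parts = []
    for s in series_list:
        parts.append(pd.DataFrame({
            "infant_id": s.infant_id, "trial_index": s.trial_index, "t": s.t,
            **{c: getattr(s, c) for c in CHANNELS}}))
    return pd.concat(parts, ignore_index=True)


def write_samples(path, series_list: list[EyeSampleSeries],
                  float_format: str = "%.6f") -> None:
    samples_frame(series_list).to_csv(path, sep="\t", index=False,
                                      na_rep="NA", float_format=float_format)


def events_frame(series_list: list[EyeSampleSeries],
                 trial_info: dict | None = None) -> pd.DataFrame:
    """One row per trial with markers; ``trial_info`` maps
    ``(infant_id, trial_index)`` to extra condition columns."""
    rows = []
    for s in series_list:
        row = {"infant_id": s.infant_id, "trial_index": s.trial_index,
               "sound_onset_s": s.sound_onset_s,
               "visual_onset_s": s.visual_onset_s,
               "visual_offset_s": s.visual_offset_s}
        if trial_info:
            row.update(trial_info.get((s.infant_id, s.trial_index), {}))
        rows.append(row)
    return pd.DataFrame(rows)


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} lacks columns {sorted(missing)}")
    return df


def read_samples(path, events: pd.DataFrame) -> list[EyeSampleSeries]:
    """Parse a long-format sample TSV into per-trial series.

    Columns may appear in any order as long as the header names are right.
    Raises with the offending trial on schema violations or non-monotone
    time stamps.
    """
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample file {path} lacks columns {sorted(missing)}")
    ev = events.set_index(["infant_id", "trial_index"])
    out = []
    for (infant, trial), grp in df.groupby(["infant_id", "trial_index"],
                                           sort=False):
        t = grp["t"].to_numpy(float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(
                f"non-monotone time in infant {infant!r} trial {trial} "
                f"(sample row {bad})")
        try:
            marks = ev.loc[(infant, trial)]
        except KeyError:
            raise ValueError(f"no event row for infant {infant!r} trial "
                             f"{trial}") from None
        out.append(EyeSampleSeries(
            t=t, **{c: grp[c].to_numpy(float) for c in CHANNELS},
            sound_onset_s=float(marks["sound_onset_s"]),
            visual_onset_s=float(marks["visual_onset_s"]),
            visual_offset_s=float(marks["visual_offset_s"]),
            infant_id=str(infant), trial_index=int(trial)))
    return out


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def write_cohort(outdir, cohort, float_format: str = "%.4f") -> None:
    """Write a simulated cohort as samples/events/participants/truth TSVs.

    The ground-truth table is a simulation artifact; the pipeline never
    reads it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_series = [s for sess in cohort.sessions.values() for s in sess]
    info = {}
    for infant_id, schedule in cohort.schedules.items():
        for tr in schedule:
            row = {"content": tr.sound.content, "volume": tr.volume,
                   "order_in_pair": tr.order_in_pair, "isi_s": tr.isi_ms / 1000.0}
            row.update({f"pos_{cat}": pos for cat, pos in tr.positions.items()})
            info[(infant_id, tr.trial_index)] = row
    write_samples(outdir / "samples.tsv", all_series, float_format)
    write_events(outdir / "events.tsv", events_frame(all_series, info))
    participants = pd.DataFrame(
        [{"infant_id": i.infant_id, "age_months": i.age_months, "sex": i.sex}
         for i in cohort.infants])
    write_table(outdir / "participants.tsv", participants)
    write_table(outdir / "truth.tsv", cohort.truth)
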