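"""Experiment-schedule construction for the paired-block audio-visual design.

The experiment presents 56 trials: a sound cue (or silence), a short
inter-stimulus interval, then a 4-image visual array (one face, one man-made
object, one natural object, one geometric shape).  Trials come in pairs that
repeat the same sound at the same volume; pairs are arranged in two blocks of
14 pairs, and the two blocks share the sound sequence with volume levels
exchanged, so every sound is heard once at each volume.  Each of the 224
images is shown exactly once, and no image category occupies the same screen
position on two consecutive trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("face", "manmade", "natural", "shape")

#: Default screen layout: image midpoints 12 deg horizontally and 6 deg
#: vertically from the monitor midpoint (four corners of that rectangle).
POSITIONS: dict[str, tuple[float, float]] = {
    "UL": (-12.0, 6.0),
    "UR": (12.0, 6.0),
    "LL": (-12.0, -6.0),
    "LR": (12.0, -6.0),
}

SILENT_SOUND_ID = "silence"


@dataclass(frozen=True)
class SoundSpec:
    """One auditory cue: 6 social + 6 non-social recordings, or silence."""

    sound_id: str
    content: str  # 'social' | 'nonsocial' | 'silent'
    duration_ms: float

    def __post_init__(self) -> None:
        if self.content not in ("social", "nonsocial", "silent"):
            raise ValueError(f"unknown sound content {self.content!r}")
        if self.content == "silent":
            if self.duration_ms != 0.0:
                raise ValueError("silent sound must have zero duration")
        elif not (506.0 <= self.duration_ms <= 989.0):
            raise ValueError("sound duration must lie in [506, 989] ms")


SILENT = SoundSpec(SILENT_SOUND_ID, "silent", 0.0)


def default_sound_inventory() -> tuple[SoundSpec, ...]:
    """Six social (infant-directed speech tokens, two voices) and six
    non-social (everyday object) recordings; durations spread over the
    506-989 ms range."""
    ids = [f"social_{v}{i}" for v in ("f", "m") for i in (1, 2, 3)]
    ids += [f"nonsocial_{i}" for i in range(1, 7)]
    durations = np.linspace(506.0, 989.0, len(ids))
    return tuple(
        SoundSpec(sid, "social" if sid.startswith("social") else "nonsocial",
                  float(d))
        for sid, d in zip(ids, durations)
    )


@dataclass(frozen=True)
class DesignConfig:
    """Tunable description of the experiment design."""

    sounds: tuple[SoundSpec, ...] = field(default_factory=default_sound_inventory)
    volumes: tuple[str, str] = ("high", "low")
    isi_range_ms: tuple[float, float] = (80.0, 400.0)
    n_silent_pairs_per_block: int = 2
    images_per_category: int = 56
    categories: tuple[str, ...] = CATEGORIES
    positions: tuple[str, ...] = tuple(POSITIONS)

    @property
    def n_sound_pairs_per_block(self) -> int:
        return len(self.sounds)

    @property
    def n_pairs_per_block(self) -> int:
        return self.n_sound_pairs_per_block + self.n_silent_pairs_per_block

    @property
    def n_trials(self) -> int:
        return 4 * self.n_pairs_per_block  # 2 blocks x 2 trials per pair


@dataclass
class TrialSpec:
    """One trial of the schedule."""

    trial_index: int          # 1-based over the whole experiment
    block: str                # 'A' | 'B'
    pair_index: int           # 1-based over the whole experiment
    order_in_pair: str        # 'first' | 'second'
    sound: SoundSpec
    volume: str               # 'high' | 'low' | 'none'
    isi_ms: float
    image_ids: dict[str, str]     # category -> image id
    positions: dict[str, str]     # category -> position label


@dataclass
class TrialSchedule:
    trials: list[TrialSpec]
    seed: int
    design: DesignConfig = field(default_factory=DesignConfig)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def assign_positions(seed, n_trials: int,
                     categories: tuple[str, ...] = CATEGORIES,
                     position_labels: tuple[str, ...] = tuple(POSITIONS),
                     max_retries: int = 1000) -> list[dict[str, str]]:
    """Random category->position maps, one per trial, such that no category
    keeps its position across consecutive trials.

    Rejection sampling: permutations are redrawn until the assignment is a
    derangement of the previous trial's (one always exists for 4 positions,
    so exhausting ``max_retries`` signals a bug).
    """
    if len(categories) != len(position_labels):
        raise ValueError("need as many positions as categories")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(position_labels, dtype=object)
    out: list[dict[str, str]] = []
    prev: np.ndarray | None = None
    for _ in range(n_trials):
        for _try in range(max_retries):
            perm = rng.permutation(labels)
            if prev is None or not np.any(perm == prev):
                break
        else:
            raise RuntimeError("position constraint unsatisfied after "
                               f"{max_retries} retries (bug)")
        out.append(dict(zip(categories, perm)))
        prev = perm
    return out


def generate_schedule(seed: int, design: DesignConfig | None = None) -> TrialSchedule:
    """Build one participant's randomized, counterbalanced schedule.

    Deterministic given ``seed``.  Raises if the image pool cannot cover one
    fresh image per category per trial.
    """
    design = design or DesignConfig()
    if design.images_per_category < design.n_trials:
        raise ValueError(
            f"image pool has {design.images_per_category} images per category "
            f"but {design.n_trials} trials need one each")
    rng = np.random.default_rng(seed)

    # Volume assignment for block A, balanced within social/non-social content
    # so the (content x volume) cells are equal; block B flips every volume.
    vol_a: dict[str, str] = {}
    for content in ("social", "nonsocial"):
        ids = [s.sound_id for s in design.sounds if s.content == content]
        rng.shuffle(ids)
        half = len(ids) // 2
        for sid in ids[:half]:
            vol_a[sid] = "high"
        for sid in ids[half:]:
            vol_a[sid] = "low"

    # Pair sequence shared by both blocks: every sound once plus silent pairs,
    # interleaved at random positions.
    pair_sounds: list[SoundSpec] = list(design.sounds) + \
        [SILENT] * design.n_silent_pairs_per_block
    order = rng.permutation(len(pair_sounds))
    pair_sequence = [pair_sounds[i] for i in order]

    # Fresh image per category per trial.
    image_deal: dict[str, list[str]] = {}
    for cat in design.categories:
        pool = [f"{cat}_{i:03d}" for i in range(1, design.images_per_category + 1)]
        rng.shuffle(pool)
        image_deal[cat] = pool

    position_maps = assign_positions(rng, design.n_trials, design.categories,
                                     design.positions)

    trials: list[TrialSpec] = []
    lo, hi = design.isi_range_ms
    trial_i = itertools.count(1)
    pair_i = itertools.count(1)
    for block, flip in (("A", False), ("B", True)):
        for sound in pair_sequence:
            if sound.content == "silent":
                volume = "none"
            else:
                volume = vol_a[sound.sound_id]
                if flip:
                    volume = "low" if volume == "high" else "high"
            p = next(pair_i)
            for order_in_pair in ("first", "second"):
                ti = next(trial_i)
                trials.append(TrialSpec(
                    trial_index=ti,
                    block=block,
                    pair_index=p,
                    order_in_pair=order_in_pair,
                    sound=sound,
                    volume=volume,
                    isi_ms=float(rng.uniform(lo, hi)),
                    image_ids={cat: image_deal[cat][ti - 1]
                               for cat in design.categories},
                    positions=position_maps[ti - 1],
                ))
    return TrialSchedule(trials=trials, seed=seed, design=design)


def validate_schedule(schedule: TrialSchedule) -> list[str]:
    """Check every design invariant; returns a list of human-readable
    violations (empty iff the schedule is valid)."""
    design = schedule.design
    trials = schedule.trials
    violations: list[str] = []

    n_expected = design.n_trials
    if len(trials) != n_expected:
        violations.append(f"trial-count: {len(trials)} trials, expected {n_expected}")

    counts = {"social": 0, "nonsocial": 0, "silent": 0}
    vols = {"high": 0, "low": 0, "none": 0}
    for tr in trials:
        counts[tr.sound.content] += 1
        vols[tr.volume] += 1
        if (tr.sound.content == "silent") != (tr.volume == "none"):
            violations.append(
                f"silent-volume: trial {tr.trial_index} silent/volume mismatch")
        if not (design.isi_range_ms[0] <= tr.isi_ms <= design.isi_range_ms[1]):
            violations.append(f"isi-range: trial {tr.trial_index} isi {tr.isi_ms}")

    n_sound_trials_per_content = 2 * design.n_sound_pairs_per_block
    if counts["social"] != n_sound_trials_per_content:
        violations.append(f"content-count: {counts['social']} social trials, "
                          f"expected {n_sound_trials_per_content}")
    if counts["nonsocial"] != n_sound_trials_per_content:
        violations.append(f"content-count: {counts['nonsocial']} non-social trials, "
                          f"expected {n_sound_trials_per_content}")
    n_silent = 4 * design.n_silent_pairs_per_block
    if counts["silent"] != n_silent:
        violations.append(f"silent-count: {counts['silent']} silent trials, "
                          f"expected {n_silent}")
    n_per_volume = n_sound_trials_per_content  # 24 with the default inventory
    if vols["high"] != n_per_volume or vols["low"] != n_per_volume:
        violations.append(f"volume-count: {vols['high']} high / {vols['low']} low, "
                          f"expected {n_per_volume} each among non-silent trials")

    # Pair symmetry and block sizes.
    by_pair: dict[int, list[TrialSpec]] = {}
    by_block: dict[str, list[TrialSpec]] = {"A": [], "B": []}
    for tr in trials:
        by_pair.setdefault(tr.pair_index, []).append(tr)
        by_block.setdefault(tr.block, []).append(tr)
    for p, members in by_pair.items():
        if len(members) != 2:
            violations.append(f"pair-size: pair {p} has {len(members)} trials")
            continue
        a, b = members
        if (a.sound.sound_id, a.volume) != (b.sound.sound_id, b.volume):
            violations.append(f"pair-symmetry: pair {p} mixes sound/volume")
        if {a.order_in_pair, b.order_in_pair} != {"first", "second"}:
            violations.append(f"pair-order: pair {p} order labels wrong")
    for blk in ("A", "B"):
        if len(by_block.get(blk, [])) != 2 * design.n_pairs_per_block:
            violations.append(f"block-size: block {blk} has "
                              f"{len(by_block.get(blk, []))} trials")

    # Cross-block volume swap: (sound_id, volume) multiset of block A equals
    # block B with volumes exchanged.
    def vol_multiset(block: str, flip: bool):
        swap = {"high": "low", "low": "high", "none": "none"}
        return sorted((tr.sound.sound_id, swap[tr.volume] if flip else tr.volume)
                      for tr in by_block.get(block, []))
    if vol_multiset("A", False) != vol_multiset("B", True):
        violations.append("volume-swap: block A/B sound-volume assignment is "
                          "not a volume exchange")

    # Image uniqueness: every image id appears exactly once, one per category
    # per trial.
    seen: dict[str, int] = {}
    for tr in trials:
        if set(tr.image_ids) != set(design.categories):
            violations.append(f"image-categories: trial {tr.trial_index} does "
                              "not carry one image per category")
        for img in tr.image_ids.values():
            seen[img] = seen.get(img, 0) + 1
    dupes = [img for img, c in seen.items() if c > 1]
    if dupes:
        violations.append(f"image-uniqueness: images used more than once: "
                          f"{sorted(dupes)[:5]}")

    # Position bijection per trial + no consecutive category-position repeat.
    prev: dict[str, str] | None = None
    for tr in sorted(trials, key=lambda x: x.trial_index):
        if sorted(tr.positions.values()) != sorted(design.positions):
            violations.append(f"position-bijection: trial {tr.trial_index}")
        if prev is not None:
            for cat in design.categories:
                if tr.positions.get(cat) == prev.get(cat):
                    violations.append(
                        f"position-repeat: category {cat} keeps position "
                        f"{tr.positions.get(cat)} on trials "
                        f"{tr.trial_index - 1}-{tr.trial_index}")
        prev = tr.positions
    return violations


# ---------------------------------------------------------------------------
# TSV serialization

def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    design = schedule.design
    rows = []
    for tr in schedule:
        row = {
            "trial_index": tr.trial_index,
            "block": tr.block,
            "pair_index": tr.pair_index,
            "order_in_pair": tr.order_in_pair,
            "sound_id": tr.sound.sound_id,
            "content": tr.sound.content,
            "duration_ms": tr.sound.duration_ms,
            "volume": tr.volume,
            "isi_ms": tr.isi_ms,
        }
        for cat in design.categories:
            row[f"image_{cat}"] = tr.image_ids[cat]
            row[f"pos_{cat}"] = tr.positions[cat]
        rows.append(row)
    return pd.DataFrame(rows)


def write_schedule(path, schedule: TrialSchedule) -> None:
    schedule_to_frame(schedule).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_schedule(path, design: DesignConfig | None = None,
                  seed: int = -1) -> TrialSchedule:
    design = design or DesignConfig()
    df = pd.read_csv(path, sep="\t", na_values="NA")
    trials = []
    for _, r in df.iterrows():
        sound = (SILENT if r["content"] == "silent" else
                 SoundSpec(r["sound_id"], r["content"], float(r["duration_ms"])))
        trials.append(TrialSpec(
            trial_index=int(r["trial_index"]),
            block=str(r["block"]),
            pair_index=int(r["pair_index"]),
            order_in_pair=str(r["order_in_pair"]),
            sound=sound,
            volume=str(r["volume"]),
            isi_ms=float(r["isi_ms"]),
            image_ids={cat: r[f"image_{cat}"] for cat in design.categories},
            positions={cat: r[f"pos_{cat}"] for cat in design.categories},
        ))
    return TrialSchedule(trials=trials, seed=seed, design=design)
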