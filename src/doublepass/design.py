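"""Stimulus sampling and double-pass trial sequences.

A stimulus is a pitch-shift profile: one shift (in cents) per temporal
segment of the base utterance, drawn independently from a zero-mean
Gaussian with SD ``noise_sd_cents`` and bounded at ``clip_sd`` standard
deviations.  Trials are 2AFC pairs of such profiles; a double-pass
sequence repeats the pairs of one block verbatim in a later block so
that response consistency across the two passes can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "StimulusConfig",
    "SequenceDesign",
    "TrialPair",
    "sample_profile",
    "make_sequence",
    "sequence_to_frame",
    "frame_to_sequence",
    "write_manifest",
    "read_manifest",
    "write_bpf",
    "bpf_times",
]


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the stimulus (external) noise.

    Parameters
    ----------
    n_segments : int
        Number of temporal segments per utterance (each carries one
        independent pitch-shift breakpoint).
    segment_ms : float
        Segment duration in milliseconds.
    noise_sd_cents : float
        Standard deviation of the per-segment pitch shift, in cents
        (1 cent = 1/100 semitone).
    clip_sd : float
        Bound on each shift, in units of ``noise_sd_cents``.
    clip_mode : {"resample", "hard"}
        How the bound is enforced.  ``"resample"`` redraws out-of-range
        values (a truncated Gaussian, smooth density); ``"hard"`` clips
        them to the bound (puts point mass at the edges).  The two modes
        have different moments: the truncated SD is
        ``noise_sd_cents * sd(truncnorm(-clip_sd, clip_sd))``, the
        hard-clipped SD is slightly larger.
    """

    n_segments: int = 6
    segment_ms: float = 71.0
    noise_sd_cents: float = 70.0
    clip_sd: float = 2.2
    clip_mode: str = "resample"

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not self.noise_sd_cents > 0:
            raise ValueError("noise_sd_cents must be > 0")
        if not self.clip_sd > 0:
            raise ValueError("clip_sd must be > 0")
        if self.segment_ms <= 0:
            raise ValueError("segment_ms must be > 0")
        if self.clip_mode not in ("resample", "hard"):
            raise ValueError("clip_mode must be 'resample' or 'hard'")

    @property
    def clip_cents(self) -> float:
        """Absolute bound on a single shift, in cents."""
        return self.clip_sd * self.noise_sd_cents


@dataclass(frozen=True)
class SequenceDesign:
    """Block structure of a double-pass trial sequence.

    ``n_repeats`` pairs from block ``repeat_source_block`` reappear
    verbatim at the start of block ``repeat_target_block`` (same interval
    order, same within-block positions unless ``shuffle_repeats``).
    """

    n_blocks: int = 3
    block_size: int = 50
    repeat_source_block: int = 0
    repeat_target_block: int = 2
    n_repeats: int = 50
    shuffle_repeats: bool = False

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be >= 1")
        if not (0 < self.n_repeats <= self.block_size):
            raise ValueError("n_repeats must satisfy 0 < n_repeats <= block_size")
        for name in ("repeat_source_block", "repeat_target_block"):
            b = getattr(self, name)
            if not (0 <= b < self.n_blocks):
                raise ValueError(f"{name} must be a valid block id in [0, n_blocks)")
        if self.repeat_source_block == self.repeat_target_block:
            raise ValueError("repeat source and target blocks must differ")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_size


@dataclass
class TrialPair:
    """One 2AFC trial: an ordered pair of pitch-shift profiles.

    ``stimuli`` has shape (2, n_segments); row 0 is interval 1.
    ``repeat_of`` is the 0-based index of the earlier trial this one
    duplicates, or ``None`` for a fresh trial.
    """

    index: int
    block: int
    stimuli: np.ndarray
    repeat_of: Optional[int] = None

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        if self.stimuli.ndim != 2 or self.stimuli.shape[0] != 2:
            raise ValueError("stimuli must have shape (2, n_segments)")


def _sample_shifts(config: StimulusConfig, rng: np.random.Generator, size) -> np.ndarray:
    """Draw clipped Gaussian shifts (cents) of the given shape."""
    out = rng.normal(0.0, config.noise_sd_cents, size=size)
    bound = config.clip_cents
    if config.clip_mode == "hard":
        np.clip(out, -bound, bound, out=out)
        return out
    # rejection-resample out-of-range values; acceptance ~97% per draw
    bad = np.abs(out) > bound
    while np.any(bad):
        out[bad] = rng.normal(0.0, config.noise_sd_cents, size=int(bad.sum()))
        bad = np.abs(out) > bound
    return out


def sample_profile(config: StimulusConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample one pitch-shift profile (vector of length ``n_segments``, cents)."""
    return _sample_shifts(config, rng, config.n_segments)


def make_sequence(
    design: SequenceDesign,
    config: StimulusConfig,
    rng: np.random.Generator,
) -> list[TrialPair]:
    """Assemble a double-pass trial sequence.

    All trials get freshly sampled stimulus pairs, then the first
    ``n_repeats`` positions of the target block are overwritten with exact
    copies of the corresponding source-block pairs (``repeat_of`` set).
    With ``shuffle_repeats`` the assignment of source trials to those
    positions is permuted; interval order is never swapped.
    """
    n = design.n_trials
    shifts = _sample_shifts(config, rng, (n, 2, config.n_segments))
    trials = [
        TrialPair(index=i, block=i // design.block_size, stimuli=shifts[i])
        for i in range(n)
    ]
    src0 = design.repeat_source_block * design.block_size
    tgt0 = design.repeat_target_block * design.block_size
    source_ids = np.arange(src0, src0 + design.n_repeats)
    if design.shuffle_repeats:
        source_ids = rng.permutation(source_ids)
    for k, src in enumerate(source_ids):
        t = trials[tgt0 + k]
        t.stimuli = trials[src].stimuli.copy()
        t.repeat_of = int(src)
    return trials


# ---------------------------------------------------------------------------
# sequence manifest (CSV, one row per interval)

def sequence_to_frame(trials: list[TrialPair]) -> pd.DataFrame:
    n_seg = trials[0].stimuli.shape[1]
    rows = []
    for t in trials:
        for interval in (1, 2):
            row = {"trial": t.index, "block": t.block, "interval": interval}
            for s in range(n_seg):
                row[f"shift_{s + 1}"] = t.stimuli[interval - 1, s]
            row["repeat_of"] = -1 if t.repeat_of is None else t.repeat_of
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_sequence(df: pd.DataFrame) -> list[TrialPair]:
    shift_cols = sorted(
        (c for c in df.columns if c.startswith("shift_")),
        key=lambda c: int(c.split("_")[1]),
    )
    trials = []
    for trial_id, grp in df.groupby("trial", sort=True):
        grp = grp.sort_values("interval")
        stimuli = grp[shift_cols].to_numpy(dtype=float)
        rep = int(grp["repeat_of"].iloc[0])
        trials.append(
            TrialPair(
                index=int(trial_id),
                block=int(grp["block"].iloc[0]),
                stimuli=stimuli,
                repeat_of=None if rep < 0 else rep,
            )
        )
    return trials


def write_manifest(trials: list[TrialPair], path) -> None:
    sequence_to_frame(trials).to_csv(path, index=False)


def read_manifest(path) -> list[TrialPair]:
    return frame_to_sequence(pd.read_csv(path))


# ---------------------------------------------------------------------------
# breakpoint-file (BPF) export for external pitch-shifting tools

def bpf_times(config: StimulusConfig) -> np.ndarray:
    """Breakpoint times in seconds: the midpoint of each segment."""
    return (np.arange(config.n_segments) + 0.5) * config.segment_ms / 1000.0


def write_bpf(profile: np.ndarray, config: StimulusConfig, path) -> None:
    """Write one profile as a tab-separated ``time_s<TAB>shift_cents`` file.

    The continuous pitch curve is obtained downstream by linear
    interpolation between these anchors; analysis here always operates on
    the breakpoint values themselves.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (config.n_segments,):
        raise ValueError("profile length does not match config.n_segments")
    times = bpf_times(config)
    lines = [f"{t:.6f}\t{v:.6f}" for t, v in zip(times, profile)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
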