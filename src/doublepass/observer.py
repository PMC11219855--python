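"""Two-stage simulated observer: linear template matching plus internal noise.

The observer compares each stimulus pair against a prosodic template
(its internal representation) and picks the interval whose projection is
larger, after perturbing the decision variable with additive Gaussian
internal noise.  On each trial the evidence is

    e = u . (s1 - s2) / sigma_ext

where ``u`` is the unit-norm template, ``s1, s2`` the two shift profiles
in cents and ``sigma_ext`` the stimulus-noise SD.  The response is
interval 1 iff ``e + z > criterion`` with ``z ~ N(0, sigma_internal)``.

Units contract
--------------
Internal noise is added at the decision-variable stage and expressed in
units of the stimulus-noise SD *as seen through the unit-norm template*.
For untruncated stimulus noise the evidence then has variance 2 (the
difference of two independent unit-variance projections); the noise
estimator (:mod:`doublepass.noise`) relies on this same convention, so
do not change one without the other.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    SequenceDesign,
    StimulusConfig,
    TrialPair,
    frame_to_sequence,
    make_sequence,
    sequence_to_frame,
)

__all__ = [
    "ObserverParams",
    "ExperimentLog",
    "GroupSpec",
    "final_rise_template",
    "decide",
    "simulate_experiment",
    "generate_cohort",
]


def final_rise_template(n_segments: int = 6) -> np.ndarray:
    """Canonical interrogative template: flat, then a terminal pitch rise.

    Zeros everywhere except the last two segments, which ramp up (0.5
    then 1.0 before unit normalization) — the final-rise contour that
    marks questions in French.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments for a final rise")
    t = np.zeros(n_segments)
    t[-2] = 0.5
    t[-1] = 1.0
    return t / np.linalg.norm(t)


@dataclass(frozen=True)
class ObserverParams:
    """Template, internal-noise SD and decision criterion of one observer.

    ``template`` may have arbitrary scale (it is normalized to unit
    Euclidean norm before use).  ``sigma_internal`` and ``criterion`` are
    in units of the stimulus-noise SD at the decision stage.
    """

    template: np.ndarray
    sigma_internal: float = 1.0
    criterion: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.template, dtype=float)
        if t.ndim != 1 or not np.any(t):
            raise ValueError("template must be a non-zero 1-D vector")
        if not np.all(np.isfinite(t)):
            raise ValueError("template must be finite")
        object.__setattr__(self, "template", t)
        if self.sigma_internal < 0:
            raise ValueError("sigma_internal must be >= 0")

    @property
    def unit_template(self) -> np.ndarray:
        return self.template / np.linalg.norm(self.template)


def _evidence(
    params: ObserverParams, stimuli: np.ndarray, noise_sd_cents: float
) -> np.ndarray:
    """Decision-stage evidence for stimuli of shape (..., 2, n_segments)."""
    u = params.unit_template
    if stimuli.shape[-1] != u.shape[0]:
        raise ValueError(
            f"template length {u.shape[0]} does not match "
            f"profile length {stimuli.shape[-1]}"
        )
    diff = stimuli[..., 0, :] - stimuli[..., 1, :]
    return diff @ u / noise_sd_cents


def decide(
    params: ObserverParams,
    pair: TrialPair,
    config: StimulusConfig,
    rng: np.random.Generator,
) -> int:
    """Respond to one trial: 1 or 2 (ties broken toward 2)."""
    e = _evidence(params, pair.stimuli, config.noise_sd_cents)
    z = rng.normal(0.0, params.sigma_internal) if params.sigma_internal > 0 else 0.0
    return 1 if e + z > params.criterion else 2


@dataclass
class ExperimentLog:
    """One participant's session: trials plus aligned binary responses."""

    trials: list[TrialPair]
    responses: np.ndarray
    participant: str = "sim"
    config: StimulusConfig = field(default_factory=StimulusConfig)
    design: Optional[SequenceDesign] = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        if len(self.trials) != len(self.responses):
            raise ValueError("trials and responses must have equal length")
        if len(self.responses) and not np.isin(self.responses, (1, 2)).all():
            raise ValueError("responses must be 1 or 2")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def stimuli(self) -> np.ndarray:
        """All stimuli, shape (n_trials, 2, n_segments)."""
        return np.stack([t.stimuli for t in self.trials])

    # -- delimited-text round trip -------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = sequence_to_frame(self.trials)
        df["response"] = np.repeat(self.responses, 2)
        return df

    def write_csv(self, path) -> None:
        header = {
            "participant": self.participant,
            "config": vars(self.config),
            "design": None if self.design is None else vars(self.design),
        }
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# {json.dumps(header)}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "ExperimentLog":
        text = Path(path).read_text(encoding="utf-8")
        meta: dict = {}
        if text.startswith("#"):
            headerline, _, text = text.partition("\n")
            meta = json.loads(headerline.lstrip("# "))
        df = pd.read_csv(io.StringIO(text))
        trials = frame_to_sequence(df)
        responses = df.sort_values(["trial", "interval"]) \
                      .groupby("trial", sort=True)["response"].first().to_numpy()
        design = meta.get("design")
        return cls(
            trials=trials,
            responses=responses,
            participant=meta.get("participant", "unknown"),
            config=StimulusConfig(**meta["config"]) if "config" in meta else StimulusConfig(),
            design=SequenceDesign(**design) if design else None,
        )


def simulate_experiment(
    params: ObserverParams,
    sequence: list[TrialPair],
    config: StimulusConfig,
    rng: np.random.Generator,
    participant: str = "sim",
    design: Optional[SequenceDesign] = None,
) -> ExperimentLog:
    """Run the observer over a whole sequence.

    Internal noise is drawn fresh on every presentation — including the
    repeated double-pass trials, which is precisely what makes response
    consistency across passes informative about its SD.
    """
    stimuli = np.stack([t.stimuli for t in sequence])
    e = _evidence(params, stimuli, config.noise_sd_cents)
    z = (
        rng.normal(0.0, params.sigma_internal, size=len(sequence))
        if params.sigma_internal > 0
        else np.zeros(len(sequence))
    )
    responses = np.where(e + z > params.criterion, 1, 2)
    return ExperimentLog(
        trials=sequence,
        responses=responses,
        participant=participant,
        config=config,
        design=design,
    )


@dataclass(frozen=True)
class GroupSpec:
    """A simulated group: n observers sharing a template, with internal
    noise drawn per participant from N(sigma_mean, sigma_sd^2) truncated
    at zero (resampled)."""

    name: str
    n: int
    template: np.ndarray
    sigma_mean: float
    sigma_sd: float
    criterion: float = 0.0

    def draw_sigmas(self, rng: np.random.Generator) -> np.ndarray:
        s = rng.normal(self.sigma_mean, self.sigma_sd, size=self.n)
        while np.any(s < 0):
            bad = s < 0
            s[bad] = rng.normal(self.sigma_mean, self.sigma_sd, size=int(bad.sum()))
        return s


def generate_cohort(
    groups: Sequence[GroupSpec],
    design: SequenceDesign,
    config: StimulusConfig,
    seed: int,
) -> list[ExperimentLog]:
    """Simulate every participant of every group, reproducibly.

    Each participant gets an independent child RNG (spawned from the
    master seed), their own freshly sampled double-pass sequence and an
    internal-noise SD drawn from the group distribution.
    """
    logs: list[ExperimentLog] = []
    master = np.random.SeedSequence(seed)
    for group in groups:
        g_rng = np.random.default_rng(master.spawn(1)[0])
        sigmas = group.draw_sigmas(g_rng)
        children = master.spawn(group.n)
        for i, (sig, child) in enumerate(zip(sigmas, children)):
            rng = np.random.default_rng(child)
            params = ObserverParams(
                template=group.template,
                sigma_internal=float(sig),
                criterion=group.criterion,
            )
            sequence = make_sequence(design, config, rng)
            logs.append(
                simulate_experiment(
                    params,
                    sequence,
                    config,
                    rng,
                    participant=f"{group.name}_{i:02d}",
                    design=design,
                )
            )
    return logs
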