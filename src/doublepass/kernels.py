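"""Classification images: per-segment internal-representation estimates.

The kernel (classification image) of a participant is the mean shift
profile of the stimuli they classified as interrogative minus the mean
profile of the stimuli they rejected; in 2AFC every trial contributes
its chosen stimulus to the first average and its unchosen stimulus to
the second.  Kernels are RMS-normalized before comparison, and
"representation typicality" is the mean squared error between a
normalized kernel and a normalized reference (typically the control
group's average kernel) — higher MSE means a less typical
representation.  The MSE is reported raw; no similarity relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .observer import ExperimentLog

__all__ = [
    "Kernel",
    "DegenerateKernelError",
    "ClassificationImage",
    "compute_kernel",
    "normalize_kernel",
    "typicality",
    "group_average_kernel",
    "truncate_log",
    "cosine_similarity",
    "kernels_to_frame",
    "write_kernel_matrix",
]

#: RMS below this (cents) is treated as a degenerate kernel rather than
#: silently divided by — random responders at tiny n can land here.
RMS_EPS = 1e-9


class DegenerateKernelError(ValueError):
    """Raised when a kernel's RMS is too close to zero to normalize."""


@dataclass(frozen=True)
class Kernel:
    """Per-segment classification-image weights.

    Unnormalized weights are contrasts in cents; after RMS normalization
    they are dimensionless with root-mean-square exactly 1.
    """

    weights: np.ndarray
    n_trials: int
    normalized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be 1-D")
        object.__setattr__(self, "weights", w)

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.weights**2)))


def compute_kernel(log: ExperimentLog) -> Kernel:
    """Raw (unnormalized) classification image of one session."""
    if len(log) == 0:
        raise ValueError("empty experiment log")
    stimuli = log.stimuli  # (n, 2, k)
    chosen_idx = log.responses - 1
    rows = np.arange(len(log))
    chosen = stimuli[rows, chosen_idx]
    unchosen = stimuli[rows, 1 - chosen_idx]
    weights = chosen.mean(axis=0) - unchosen.mean(axis=0)
    return Kernel(weights=weights, n_trials=len(log), normalized=False)


def normalize_kernel(kernel: Kernel, eps: float = RMS_EPS) -> Kernel:
    """Divide the weights by their root mean square (idempotent)."""
    rms = kernel.rms
    if rms <= eps:
        raise DegenerateKernelError(
            f"kernel RMS {rms:.3e} below {eps:.0e}; cannot normalize"
        )
    return Kernel(
        weights=kernel.weights / rms, n_trials=kernel.n_trials, normalized=True
    )


def typicality(kernel: Kernel, reference: Kernel) -> float:
    """Mean squared error between two RMS-normalized kernels (>= 0).

    Identical kernels score 0; an exactly sign-flipped kernel scores 4
    (since both have unit RMS).  Higher means less typical.
    """
    if not (kernel.normalized and reference.normalized):
        raise ValueError("typicality requires RMS-normalized kernels")
    if kernel.weights.shape != reference.weights.shape:
        raise ValueError("kernels must have equal length")
    return float(np.mean((kernel.weights - reference.weights) ** 2))


def group_average_kernel(
    kernels: Sequence[Kernel], leave_out: Optional[int] = None
) -> Kernel:
    """Segment-wise mean of normalized kernels, re-normalized.

    ``leave_out`` excludes one kernel by position — used when scoring a
    control participant against their own group so the reference does
    not contain their own data.
    """
    kept = [k for i, k in enumerate(kernels) if i != leave_out]
    if not kept:
        raise ValueError("no kernels to average")
    if not all(k.normalized for k in kept):
        raise ValueError("group average requires normalized kernels")
    mean = np.mean([k.weights for k in kept], axis=0)
    avg = Kernel(weights=mean, n_trials=sum(k.n_trials for k in kept))
    return normalize_kernel(avg)


def truncate_log(log: ExperimentLog, n_trials: int) -> ExperimentLog:
    """Keep the first ``n_trials`` in presentation order.

    Used to score long sessions on the same number of trials as short
    ones, so kernel noise levels are comparable across participants.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return ExperimentLog(
        trials=log.trials[:n_trials],
        responses=log.responses[:n_trials],
        participant=log.participant,
        config=log.config,
        design=log.design,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class ClassificationImage(BaseEstimator):
    """Classification-image estimator with a scikit-learn interface.

    Parameters
    ----------
    normalize : bool, default True
        Whether ``weights_`` holds the RMS-normalized kernel.
    eps : float
        Degenerate-kernel guard on the RMS before normalization.

    Attributes
    ----------
    raw_weights_ : ndarray of shape (n_segments,)
        Chosen-minus-unchosen mean shift contrast, in cents.
    weights_ : ndarray of shape (n_segments,)
        The kernel (RMS-normalized if ``normalize``).
    n_trials_ : int

    Examples
    --------
    >>> ci = ClassificationImage().fit(X, y)   # X: (n, 2, k), y in {1, 2}
    >>> ci.weights_
    """

    def __init__(self, normalize: bool = True, eps: float = RMS_EPS):
        self.normalize = normalize
        self.eps = eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_trials, 2, n_segments)")
        if X.shape[0] != y.shape[0] or X.shape[0] == 0:
            raise ValueError("X and y must be non-empty and aligned")
        if not np.isin(y, (1, 2)).all():
            raise ValueError("y must contain only 1 and 2")
        rows = np.arange(len(y))
        contrast = X[rows, y - 1].mean(axis=0) - X[rows, 2 - y].mean(axis=0)
        self.raw_weights_ = contrast
        self.n_trials_ = int(len(y))
        kernel = Kernel(weights=contrast, n_trials=self.n_trials_)
        self.kernel_ = normalize_kernel(kernel, self.eps) if self.normalize else kernel
        self.weights_ = self.kernel_.weights
        return self

    def fit_log(self, log: ExperimentLog) -> "ClassificationImage":
        """Fit from an :class:`ExperimentLog` instead of raw arrays."""
        return self.fit(log.stimuli, log.responses)


# ---------------------------------------------------------------------------
# tabular output

def kernels_to_frame(kernel: Kernel) -> pd.DataFrame:
    return pd.DataFrame(
        {"segment": np.arange(1, len(kernel.weights) + 1), "weight": kernel.weights}
    )


def write_kernel_matrix(
    kernels: Sequence[Kernel], participants: Sequence[str], path
) -> None:
    """Cohort kernel matrix (participants x segments), CSV."""
    n_seg = len(kernels[0].weights)
    df = pd.DataFrame(
        [k.weights for k in kernels],
        index=pd.Index(participants, name="participant"),
        columns=[f"segment_{i + 1}" for i in range(n_seg)],
    )
    df.to_csv(path)
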