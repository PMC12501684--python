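"""Temporal averaging of ASL difference series.

Pre-averaging merges every ``n_av_pre`` raw time points before denoising;
post-averaging merges every ``n_av_post`` denoised volumes afterwards.  Two
grouping schemes exist: *windowed* averages contiguous blocks (equivalent to
a shorter scan) and *interleaved* averages time points spaced evenly across
the whole acquisition.  With a full chain, n_av_pre * n_av_post equals the
number of time points and a single grand-mean volume remains; with partial
chains several averaged *instances* remain and metrics are averaged across
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "DivisibilityError",
    "AveragingPlan",
    "group_indices",
    "pre_average",
    "post_average",
    "count_instances",
]

Scheme = Literal["windowed", "interleaved"]


class DivisibilityError(ValueError):
    """Raised when an averaging factor does not divide the series length."""


def _check_divides(n_t: int, n_av: int, what: str = "n_av") -> None:
    if n_av < 1 or n_t < 1:
        raise DivisibilityError(f"{what}={n_av} and n_t={n_t} must be >= 1")
    if n_t % n_av:
        raise DivisibilityError(
            f"{what}={n_av} does not divide the series length {n_t}")


@dataclass(frozen=True)
class AveragingPlan:
    """A validated (scheme, n_av_pre, n_av_post) combination.

    ``n_av_pre`` must divide ``n_timepoints`` and ``n_av_post`` must divide
    the number of pre-averaged volumes.
    """

    scheme: Scheme = "windowed"
    n_av_pre: int = 1
    n_av_post: int = 1
    n_timepoints: int = 32

    def __post_init__(self):
        if self.scheme not in ("windowed", "interleaved"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        _check_divides(self.n_timepoints, self.n_av_pre, "n_av_pre")
        _check_divides(self.n_timepoints // self.n_av_pre,
                       self.n_av_post, "n_av_post")

    @property
    def n_instances(self) -> int:
        return count_instances(self.n_timepoints, self.n_av_pre,
                               self.n_av_post)


def group_indices(n_t: int, n_av: int, scheme: Scheme) -> list[list[int]]:
    """Partition 0..n_t-1 into n_t/n_av groups of size n_av.

    windowed: group g = [g*n_av, ..., g*n_av + n_av - 1]
    interleaved: group g = [g, g + n_groups, g + 2*n_groups, ...] with
    n_groups = n_t / n_av, i.e. members spaced evenly across the scan.
    """
    _check_divides(n_t, n_av)
    n_groups = n_t // n_av
    if scheme == "windowed":
        return [list(range(g * n_av, (g + 1) * n_av)) for g in range(n_groups)]
    if scheme == "interleaved":
        return [list(range(g, n_t, n_groups)) for g in range(n_groups)]
    raise ValueError(f"unknown scheme {scheme!r}")


def pre_average(series: np.ndarray, plan: AveragingPlan) -> np.ndarray:
    """Average the raw series by the plan's pre-averaging groups.

    Returns a stack of n_t / n_av_pre volumes in group order.
    """
    if series.ndim != 4:
        raise ValueError("series must be 4D (t, x, y, z)")
    if series.shape[0] != plan.n_timepoints:
        raise ValueError(
            f"series has {series.shape[0]} time points, plan expects "
            f"{plan.n_timepoints}")
    groups = group_indices(plan.n_timepoints, plan.n_av_pre, plan.scheme)
    return np.stack([series[g].mean(axis=0) for g in groups])


def post_average(volumes: np.ndarray, n_av_post: int) -> np.ndarray:
    """Average consecutive disjoint groups of denoised volumes.

    Returns all resulting instances (count = n_volumes / n_av_post) so that
    metrics can be averaged across them.
    """
    if volumes.ndim != 4:
        raise ValueError("volumes must be 4D (n, x, y, z)")
    n = volumes.shape[0]
    _check_divides(n, n_av_post, "n_av_post")
    return volumes.reshape(n // n_av_post, n_av_post,
                           *volumes.shape[1:]).mean(axis=1)


def count_instances(n_t: int, n_av_pre: int, n_av_post: int) -> int:
    """Number of final averaged instances: n_t / (n_av_pre * n_av_post)."""
    _check_divides(n_t, n_av_pre, "n_av_pre")
    _check_divides(n_t // n_av_pre, n_av_post, "n_av_post")
    return n_t // (n_av_pre * n_av_post)
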