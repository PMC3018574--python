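"""Group-level aggregation of per-subject metric maps.

Subjects in a cohort share a template source space, so group statistics are
computed vertex-wise on the template index: grand averages, between-method
difference maps, across-subject standard deviations, and paired two-tailed
t-tests.  Vertices whose paired differences have zero variance (which happens
by construction, e.g. for CTF-mode contrasts between row-normalized
estimators) are handled deterministically instead of producing NaNs: the
t statistic is 0 and p = 1 when the mean difference is also zero, otherwise
t carries the sign of the mean with p = 0 (and the vertex is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .metrics import MetricMaps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupResult:
    """Vertex-wise group statistics for one method contrast."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    t_map: np.ndarray
    p_map: np.ndarray
    contrast: tuple  # (method_A, method_B, metric, mode)
    n_subjects: int

    def __post_init__(self) -> None:
        if np.any(self.sd_map < 0):
            raise ValueError("sd_map must be non-negative")
        if np.any((self.p_map < 0) | (self.p_map > 1)):
            raise ValueError("p_map must lie in [0, 1]")


def _stack(maps: Sequence[MetricMaps], metric: str, mode: str) -> np.ndarray:
    """(n_subjects, n_vertices) array for one metric, with shape checks."""
    if len(maps) < 1:
        raise ValueError("need at least one subject")
    rows = []
    n_vertices = None
    for m in maps:
        if m.mode != mode:
            raise ValueError(f"map mode {m.mode} does not match requested {mode}")
        v = m.metric(metric)
        if n_vertices is None:
            n_vertices = v.shape[0]
        elif v.shape[0] != n_vertices:
            raise ValueError("subjects have mismatched vertex counts")
        rows.append(v)
    return np.asarray(rows)


def grand_average(maps: Sequence[MetricMaps], metric: str, mode: str) -> np.ndarray:
    """Vertex-wise arithmetic mean across subjects."""
    return _stack(maps, metric, mode).mean(axis=0)


def difference_map(
    maps_a: Sequence[MetricMaps],
    maps_b: Sequence[MetricMaps],
    metric: str,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject A - B difference maps and their grand average.

    Returns ``(per_subject, mean)`` with shapes (n_subjects, n_vertices) and
    (n_vertices,).
    """
    a = _stack(maps_a, metric, mode)
    b = _stack(maps_b, metric, mode)
    if a.shape != b.shape:
        raise ValueError("method A and B cohorts have mismatched shapes")
    for ma, mb in zip(maps_a, maps_b):
        if ma.subject_id != mb.subject_id:
            raise ValueError("subject order differs between methods")
    diff = a - b
    return diff, diff.mean(axis=0)


def across_subject_sd(difference_maps: np.ndarray) -> np.ndarray:
    """Vertex-wise sample standard deviation (n-1 denominator) of differences."""
    d = np.asarray(difference_maps, dtype=float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need difference maps from at least 2 subjects")
    return d.std(axis=0, ddof=1)


def paired_ttest_map(
    maps_a: Sequence[MetricMaps],
    maps_b: Sequence[MetricMaps],
    metric: str,
    mode: str,
) -> GroupResult:
    """Vertex-wise paired two-tailed t-test of method A against method B.

    t = mean(diff) / (sd(diff)/sqrt(n)); p is the two-tailed tail probability
    of Student's t with n-1 degrees of freedom.
    """
    diff, mean = difference_map(maps_a, maps_b, metric, mode)
    n = diff.shape[0]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    sd_map = across_subject_sd(diff)

    t_map = np.zeros_like(mean)
    p_map = np.ones_like(mean)
    ok = sd_map > 0
    t_map[ok] = mean[ok] / (sd_map[ok] / np.sqrt(n))
    p_map[ok] = 2.0 * stats.t.sf(np.abs(t_map[ok]), df=n - 1)

    degenerate = ~ok & (mean != 0)
    if np.any(degenerate):
        logger.warning(
            "%d vertices have zero-variance nonzero differences; p set to 0",
            int(degenerate.sum()),
        )
        t_map[degenerate] = np.sign(mean[degenerate]) * np.inf
        p_map[degenerate] = 0.0

    method_a = maps_a[0].method
    method_b = maps_b[0].method
    return GroupResult(
        mean_map=mean,
        sd_map=sd_map,
        t_map=t_map,
        p_map=p_map,
        contrast=(method_a, method_b, metric, mode),
        n_subjects=n,
    )


def significance_mask(result: GroupResult, alpha: float = 0.05,
                      bonferroni: bool = False) -> np.ndarray:
    """Boolean mask of vertices with p below alpha (optionally Bonferroni-corrected)."""
    thr = alpha / result.p_map.size if bonferroni else alpha
    return result.p_map < thr


__all__ = [
    "GroupResult",
    "grand_average",
    "difference_map",
    "across_subject_sd",
    "paired_ttest_map",
    "significance_mask",
]
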