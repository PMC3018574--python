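"""Resolution matrices, point-spread/cross-talk functions, and their metrics.

The resolution matrix R = G L maps the true source distribution to the
estimated one.  Its columns are point-spread functions (PSF: how a point
source is smeared by the estimator) and its rows are cross-talk functions
(CTF: how every source leaks into one location's estimate).

Three scalar metrics summarize each PSF/CTF ``F`` for a target source ``i``:

* DLE (dipole localization error): Euclidean distance, in cm, between the
  peak of |F| and the true source position.
* SD (spatial dispersion): sqrt( sum_j d_ij F_j^2 / sum_j F_j^2 ), with
  ``d_ij`` the distance in cm between sources j and i — an
  amplitude-weighted spread, reported in sqrt-cm.
* OA (overall amplitude): sum_j |F_j|; when assembled into per-subject maps
  it is normalized to its maximum, since only relative amplitudes between
  locations are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import SourceSpace
from .forward import Leadfield
from .inverse import InverseOperator

logger = logging.getLogger(__name__)

MODES = ("PSF", "CTF")
METRIC_NAMES = ("DLE", "SD", "OA")


@dataclass(frozen=True)
class ResolutionMatrix:
    """R = G L for one estimator; columns are PSFs, rows are CTFs."""

    matrix: np.ndarray
    method: str
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("resolution matrix contains non-finite entries")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("resolution matrix must be square")

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[0]

    def symmetry_residual(self) -> float:
        """max|R - R^T| / max|R| — near zero for the MNE operator."""
        return float(np.max(np.abs(self.matrix - self.matrix.T))
                     / np.max(np.abs(self.matrix)))


@dataclass(frozen=True)
class MetricMaps:
    """Per-source DLE/SD/OA values for one estimator, mode and subject."""

    mode: str
    dle: np.ndarray      # cm
    sd: np.ndarray       # sqrt-cm
    oa: np.ndarray       # normalized, max = 1
    method: str
    subject_id: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if np.any(self.dle < 0) or np.any(self.sd < 0):
            raise ValueError("DLE and SD must be non-negative")

    def metric(self, name: str) -> np.ndarray:
        return {"DLE": self.dle, "SD": self.sd, "OA": self.oa}[name]


def resolution_matrix(op: InverseOperator, leadfield: Leadfield) -> ResolutionMatrix:
    """R = G L; raises on incompatible shapes."""
    if op.n_channels != leadfield.n_channels:
        raise ValueError("operator and leadfield disagree on channel count")
    if op.n_sources != leadfield.n_sources:
        raise ValueError("operator and leadfield disagree on source count")
    return ResolutionMatrix(matrix=op.matrix @ leadfield.matrix, method=op.method)


def psf(resmat: ResolutionMatrix, i: int) -> np.ndarray:
    """Point-spread function of source i: column i of R."""
    if not 0 <= i < resmat.n_sources:
        raise IndexError(f"source index {i} out of range")
    return resmat.matrix[:, i].copy()


def ctf(resmat: ResolutionMatrix, i: int) -> np.ndarray:
    """Cross-talk function of source i: row i of R."""
    if not 0 <= i < resmat.n_sources:
        raise IndexError(f"source index {i} out of range")
    return resmat.matrix[i, :].copy()


def _check_distribution(distribution: np.ndarray) -> np.ndarray:
    f = np.asarray(distribution, dtype=float)
    if not np.any(f != 0.0):
        raise ValueError("distribution is identically zero")
    return f


def dle(distribution: np.ndarray, true_index: int, source_space: SourceSpace) -> float:
    """Dipole localization error in cm: distance of the |F| peak from the truth.

    Ties at the peak are broken toward the lowest index (and logged); exact
    ties have measure zero for continuous inputs but the rule keeps the
    metric deterministic.
    """
    f = _check_distribution(distribution)
    absf = np.abs(f)
    peak = int(np.argmax(absf))
    if np.count_nonzero(absf == absf[peak]) > 1:
        logger.info("peak tie at source %d broken toward lowest index", true_index)
    delta = source_space.positions[peak] - source_space.positions[true_index]
    return float(100.0 * np.sqrt((delta**2).sum()))


def sd(
    distribution: np.ndarray,
    true_index: int,
    source_space: SourceSpace,
    weight_exponent: int = 2,
) -> float:
    """Spatial dispersion in sqrt-cm: amplitude-weighted spread around the truth.

    sqrt( sum_j d_ij |F_j|^p / sum_j |F_j|^p ) with distances in cm and
    ``p = weight_exponent`` (default 2, squared-amplitude weighting).
    """
    f = _check_distribution(distribution)
    w = np.abs(f) ** weight_exponent
    d_cm = 100.0 * np.linalg.norm(
        source_space.positions - source_space.positions[true_index], axis=1
    )
    return float(np.sqrt((d_cm * w).sum() / w.sum()))


def oa(distribution: np.ndarray) -> float:
    """Overall amplitude: sum of absolute values (unnormalized)."""
    return float(np.abs(np.asarray(distribution, dtype=float)).sum())


def metric_maps(
    resmat: ResolutionMatrix,
    mode: str,
    source_space: SourceSpace,
    subject_id: int = 0,
    sd_weight_exponent: int = 2,
) -> MetricMaps:
    """All three metrics for every PSF (columns) or CTF (rows) of R.

    The OA map is normalized to its per-subject maximum here, at the map
    level, so only relative amplitudes between locations survive.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if resmat.n_sources != source_space.n_sources:
        raise ValueError("resolution matrix does not match source space")

    # F[j, i] = value at source j of the PSF/CTF of target source i
    F = resmat.matrix if mode == "PSF" else resmat.matrix.T
    absF = np.abs(F)
    col_max = absF.max(axis=0)
    if np.any(col_max == 0.0):
        bad = int(np.argmin(col_max))
        raise ValueError(f"{mode} of source {bad} is identically zero")

    d_cm = source_space.pairwise_distances_cm()  # d_cm[j, i]

    peaks = absF.argmax(axis=0)
    delta = source_space.positions[peaks] - source_space.positions
    dle_map = 100.0 * np.sqrt((delta**2).sum(axis=1))

    w = absF**sd_weight_exponent
    sd_map = np.sqrt((d_cm * w).sum(axis=0) / w.sum(axis=0))

    oa_raw = absF.sum(axis=0)
    oa_map = oa_raw / oa_raw.max()

    return MetricMaps(
        mode=mode, dle=dle_map, sd=sd_map, oa=oa_map,
        method=resmat.method, subject_id=subject_id,
    )


__all__ = [
    "ResolutionMatrix",
    "MetricMaps",
    "MODES",
    "METRIC_NAMES",
    "resolution_matrix",
    "psf",
    "ctf",
    "dle",
    "sd",
    "oa",
    "metric_maps",
]
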