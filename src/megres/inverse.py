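"""Minimum-norm inverse operators and their noise-normalized variants.

The classical L2 minimum-norm estimate (MNE) is

    G_MNE = L^T (L L^T + lambda * C)^{-1}

with leadfield ``L``, noise covariance ``C`` and regularization parameter
``lambda``.  dSPM and sLORETA are obtained by scaling each row of G_MNE by a
positive weight:

* dSPM divides each source estimate by its projected noise standard
  deviation, ``w_i = 1 / sqrt([G (C / n_averages) G^T]_ii)``,
* sLORETA divides by the square root of the corresponding diagonal entry of
  the resolution matrix, ``w_i = 1 / sqrt([G L]_ii)``, which gives it a
  point-spread function that always peaks at the true source.

Because both are pure row scalings, they change the shapes of point-spread
functions (columns of the resolution matrix) but only the amplitudes of
cross-talk functions (rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .cohort import NoiseCovariance
from .forward import Leadfield

logger = logging.getLogger(__name__)

METHODS = ("MNE", "dSPM", "sLORETA")


@dataclass(frozen=True)
class InverseOperator:
    """Linear source estimator: sources x channels matrix plus provenance.

    ``weights`` holds the diagonal row-normalization applied on top of the
    MNE operator (all ones for MNE itself); it is stored explicitly rather
    than re-derived so every operator's provenance is auditable.
    """

    matrix: np.ndarray
    method: str
    lambda_value: float
    snr: float
    weights: np.ndarray
    noise_ref: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.lambda_value < 0:
            raise ValueError("lambda_value must be >= 0")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive and finite")

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


def regularization_lambda(leadfield: Leadfield, noise: NoiseCovariance, snr: float) -> float:
    """Regularization parameter from a target signal-to-noise ratio.

    lambda = trace(L L^T) / (trace(C) * snr^2): the regularizing term
    ``lambda * C`` then carries 1/snr^2 of the average sensor power of the
    signal term ``L L^T``.  A convenient corollary is that the resulting
    operator is invariant to the overall scale of ``C``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    trace_c = float(np.trace(noise.matrix))
    if trace_c <= 0:
        raise ValueError("noise covariance has non-positive trace")
    trace_llt = float((leadfield.matrix**2).sum())
    return trace_llt / (trace_c * snr**2)


def mne_operator(
    leadfield: Leadfield,
    noise: NoiseCovariance,
    lambda_value: float,
    snr: float = float("nan"),
) -> InverseOperator:
    """Classical minimum-norm operator G = L^T (L L^T + lambda C)^{-1}.

    Solves the symmetric system rather than forming an explicit inverse.  If
    the Cholesky factorization fails, a diagonal loading of 1e-10 times the
    mean diagonal is applied once (and logged) before falling back to a
    general solve.
    """
    L = leadfield.matrix
    M = L @ L.T + lambda_value * noise.matrix
    cond = np.linalg.cond(M)
    logger.info("MNE system condition number: %.3g", cond)
    try:
        G = scipy.linalg.solve(M, L, assume_a="pos").T
    except np.linalg.LinAlgError:
        load = 1e-10 * float(np.mean(np.diag(M)))
        logger.warning("system not SPD; applying diagonal loading %.3g", load)
        try:
            G = scipy.linalg.solve(M + load * np.eye(M.shape[0]), L, assume_a="gen").T
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular MNE system (condition number {cond:.3g})"
            ) from err
    return InverseOperator(
        matrix=G,
        method="MNE",
        lambda_value=float(lambda_value),
        snr=float(snr),
        weights=np.ones(L.shape[1]),
    )


def dspm_weights(mne_op: InverseOperator, noise: NoiseCovariance) -> np.ndarray:
    """Per-source dSPM weights: inverse projected-noise standard deviations.

    w_i = 1 / sqrt([G (C / n_averages) G^T]_ii), with ``n_averages`` taken
    from the covariance record (the trial-averaging divisor).
    """
    if mne_op.method != "MNE":
        raise ValueError("dSPM weights must be derived from the MNE operator")
    G = mne_op.matrix
    c_eff = noise.matrix / noise.n_averages
    diag = np.einsum("ij,jk,ik->i", G, c_eff, G)
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise ValueError(f"source {bad} has non-positive projected noise variance")
    return 1.0 / np.sqrt(diag)


def sloreta_weights(mne_op: InverseOperator, leadfield: Leadfield) -> np.ndarray:
    """Per-source sLORETA weights: inverse square roots of diag(G L)."""
    if mne_op.method != "MNE":
        raise ValueError("sLORETA weights must be derived from the MNE operator")
    diag = np.einsum("ij,ji->i", mne_op.matrix, leadfield.matrix)
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise ValueError(
            f"diag(G L) non-positive at source {bad} ({diag[bad]:.3g}); "
            "system matrix is not positive definite"
        )
    return 1.0 / np.sqrt(diag)


def apply_normalization(
    mne_op: InverseOperator, weights: np.ndarray, method_tag: str
) -> InverseOperator:
    """Row-scale the MNE operator by per-source weights and re-tag it."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (mne_op.n_sources,):
        raise ValueError("weights length must equal the number of sources")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and strictly positive")
    return InverseOperator(
        matrix=w[:, None] * mne_op.matrix,
        method=method_tag,
        lambda_value=mne_op.lambda_value,
        snr=mne_op.snr,
        weights=w,
        noise_ref=mne_op.noise_ref,
    )


def apply_inverse(op: InverseOperator, data_vector: np.ndarray) -> np.ndarray:
    """Source estimate j_hat = G d for a sensor data vector (or matrix of columns)."""
    d = np.asarray(data_vector, dtype=float)
    if d.shape[0] != op.n_channels:
        raise ValueError(
            f"data length {d.shape[0]} does not match {op.n_channels} channels"
        )
    return op.matrix @ d


def make_inverse_operator(
    leadfield: Leadfield,
    noise: NoiseCovariance,
    method: str,
    snr: float = 3.0,
    lambda_value: float | None = None,
) -> InverseOperator:
    """Convenience constructor: MNE with lambda from ``snr``, then normalize.

    ``lambda_value`` overrides the SNR-derived regularization when given.
    """
    lam = regularization_lambda(leadfield, noise, snr) if lambda_value is None \
        else float(lambda_value)
    mne = mne_operator(leadfield, noise, lam, snr=snr)
    if method == "MNE":
        return mne
    if method == "dSPM":
        return apply_normalization(mne, dspm_weights(mne, noise), "dSPM")
    if method == "sLORETA":
        return apply_normalization(mne, sloreta_weights(mne, leadfield), "sLORETA")
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


__all__ = [
    "InverseOperator",
    "METHODS",
    "regularization_lambda",
    "mne_operator",
    "dspm_weights",
    "sloreta_weights",
    "apply_normalization",
    "apply_inverse",
    "make_inverse_operator",
]
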