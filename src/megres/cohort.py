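"""Synthetic MEG study cohorts: sensor helmets, folded source spaces, noise covariances.

This module generates the geometric and statistical raw material for a
simulated multi-subject MEG resolution study:

* a helmet-shaped array of magnetometers and planar gradiometers,
* a source space on a radially "folded" spherical shell whose corrugations
  stand in for gyri and sulci (so that source depth varies systematically),
* a cohort of subjects sharing a template source space, each perturbed by a
  small rigid rotation plus vertex-wise positional jitter,
* sample noise-covariance matrices estimated from simulated trial-structured
  baseline noise (white sensor noise mixed with leadfield-projected "brain
  noise").

All generators are pure functions of their seed and parameters; repeated
calls with the same arguments return bitwise-identical arrays.  Geometry is
in meters, head-centered, with the conductor sphere at the origin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: channel-type labels
MAGNETOMETER = "magnetometer"
PLANAR_GRADIOMETER = "planar_gradiometer"

#: default separation of the two integration points of a planar gradiometer
DEFAULT_GRADIOMETER_BASELINE = 0.0168  # m

#: default clearance between the conductor surface and the shallowest source
DEFAULT_SHELL_MARGIN = 0.01  # m


@dataclass(frozen=True)
class SensorArray:
    """MEG sensor helmet: magnetometers and planar gradiometers.

    Attributes
    ----------
    positions : (n_channels, 3) float array
        Sensor integration-point centers in meters, head-centered.
    orientations : (n_channels, 3) float array
        Unit pickup directions (field component each channel measures).
        For this helmet geometry the pickup direction is radial.
    types : (n_channels,) str array
        ``"magnetometer"`` or ``"planar_gradiometer"`` per channel.
    grad_axes : (n_channels, 3) float array
        Unit tangential axis along which a planar gradiometer takes its
        two-point finite difference; zero vectors for magnetometers.
    gradiometer_baseline : float
        Separation of the two gradiometer integration points in meters.
    """

    positions: np.ndarray
    orientations: np.ndarray
    types: np.ndarray
    grad_axes: np.ndarray
    gradiometer_baseline: float = DEFAULT_GRADIOMETER_BASELINE

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.all(np.abs(norms - 1.0) < 1e-12):
            raise ValueError("channel orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def mag_mask(self) -> np.ndarray:
        return self.types == MAGNETOMETER

    @property
    def grad_mask(self) -> np.ndarray:
        return self.types == PLANAR_GRADIOMETER


@dataclass(frozen=True)
class SourceSpace:
    """Dipole source space on a folded spherical shell.

    Attributes
    ----------
    positions : (n_sources, 3) float array
        Dipole positions in meters, strictly inside the conductor sphere.
    orientations : (n_sources, 3) float array
        Unit surface normals of the folded shell (fixed dipole orientations).
    depth : (n_sources,) float array
        Radial distance of each source below the conductor surface, meters.
    conductor_radius : float
        Radius of the spherical conductor the space lives in, meters.
    template_id : str
        Identifier linking per-subject spaces to the shared cohort template.
    """

    positions: np.ndarray
    orientations: np.ndarray
    depth: np.ndarray
    conductor_radius: float
    template_id: str = "template"

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.all(np.abs(norms - 1.0) < 1e-12):
            raise ValueError("source orientations must be unit vectors")
        radii = np.linalg.norm(self.positions, axis=1)
        if not np.all(radii < self.conductor_radius):
            raise ValueError("all sources must lie strictly inside the conductor")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def pairwise_distances_cm(self) -> np.ndarray:
        """Full (n, n) matrix of Euclidean inter-source distances in cm."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return 100.0 * np.sqrt((diff**2).sum(axis=-1))


@dataclass(frozen=True)
class NoiseCovariance:
    """Sample sensor-noise covariance with trial-averaging bookkeeping.

    ``n_averages`` is the divisor applied to the covariance when estimating
    per-source noise for dSPM weighting (the effective number of averaged
    trials in the evoked response the operator will be applied to).
    """

    matrix: np.ndarray
    n_samples_used: int
    n_averages: int = 100

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be square")
        if np.max(np.abs(self.matrix - self.matrix.T)) != 0.0:
            raise ValueError("covariance must be exactly symmetric")
        eigvals = np.linalg.eigvalsh(self.matrix)
        if eigvals.min() < -1e-10 * np.trace(self.matrix):
            raise ValueError("covariance is not positive semi-definite")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class GeometryConfig:
    """Template geometry of one synthetic subject.

    Defaults mirror a 306-channel whole-head system (102 magnetometers and
    204 planar gradiometers) around a 9 cm conductor sphere, with shell
    corrugations deep enough to span a realistic superficial-to-deep range
    of cortical sources.
    """

    n_mag: int = 102
    n_grad: int = 204
    n_sources: int = 1000
    conductor_radius: float = 0.09
    helmet_radius: float = 0.12
    fold_depth: float = 0.03
    fold_frequency: float = 6.0
    gradiometer_baseline: float = DEFAULT_GRADIOMETER_BASELINE
    shell_margin: float = DEFAULT_SHELL_MARGIN


@dataclass(frozen=True)
class Subject:
    """One cohort member: perturbed copies of the template geometry."""

    subject_id: int
    sensors: SensorArray
    sources: SourceSpace


def _fibonacci_directions(n: int, z_lo: float, z_hi: float) -> np.ndarray:
    """Quasi-uniform unit vectors with z in (z_lo, z_hi), golden-angle spiral."""
    i = np.arange(n, dtype=float)
    z = z_hi - (z_hi - z_lo) * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _tangential_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangent vectors for each unit radial direction u."""
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(u), 1))
    ref[np.abs(u[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    t1 = ref - (ref * u).sum(axis=1, keepdims=True) * u
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(u, t1)
    return t1, t2


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis. angle=0 returns the exact identity."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    c, s = math.cos(angle), math.sin(angle)
    K = np.array(
        [[0.0, -ax[2], ax[1]], [ax[2], 0.0, -ax[0]], [-ax[1], ax[0], 0.0]]
    )
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(ax, ax)


def make_sensor_array(
    n_mag: int,
    n_grad: int,
    helmet_radius: float,
    seed: int,
    gradiometer_baseline: float = DEFAULT_GRADIOMETER_BASELINE,
) -> SensorArray:
    """Build a helmet of magnetometers and planar gradiometers.

    Sensor sites are spread quasi-uniformly over the upper hemisphere of a
    sphere of radius ``helmet_radius`` and given a small seeded tangential
    jitter (radius preserved exactly).  Gradiometers are laid down in
    co-located pairs with orthogonal tangential difference axes; when
    ``n_grad == 2 * n_mag`` every site carries one magnetometer plus one
    orthogonal gradiometer pair, mimicking a triple-sensor whole-head layout.

    Channel ordering is by site: magnetometer first, then the site's
    gradiometer pair.
    """
    if n_mag < 1:
        raise ValueError("n_mag must be >= 1")
    if n_grad < 0:
        raise ValueError("n_grad must be >= 0")
    if helmet_radius <= 0:
        raise ValueError("helmet_radius must be positive")
    if gradiometer_baseline <= 0:
        raise ValueError("gradiometer_baseline must be positive")

    n_grad_sites = (n_grad + 1) // 2
    n_sites = max(n_mag, n_grad_sites)

    u = _fibonacci_directions(n_sites, z_lo=0.05, z_hi=1.0)
    # seeded tangential jitter, then re-projection onto the helmet sphere
    rng = np.random.default_rng([int(seed), 0])
    jitter = rng.normal(scale=0.01, size=(n_sites, 3))
    jitter -= (jitter * u).sum(axis=1, keepdims=True) * u
    u = u + jitter  # tangential displacement on the unit sphere
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    t1, t2 = _tangential_basis(u)

    positions, orientations, types, axes = [], [], [], []
    grads_placed = 0
    for s in range(n_sites):
        if s < n_mag:
            positions.append(helmet_radius * u[s])
            orientations.append(u[s])
            types.append(MAGNETOMETER)
            axes.append(np.zeros(3))
        for t in (t1[s], t2[s]):
            if grads_placed < n_grad:
                positions.append(helmet_radius * u[s])
                orientations.append(u[s])
                types.append(PLANAR_GRADIOMETER)
                axes.append(t)
                grads_placed += 1

    return SensorArray(
        positions=np.asarray(positions),
        orientations=np.asarray(orientations),
        types=np.asarray(types),
        grad_axes=np.asarray(axes),
        gradiometer_baseline=gradiometer_baseline,
    )


def make_source_space(
    n_sources: int,
    conductor_radius: float,
    fold_depth: float,
    fold_frequency: float,
    seed: int,
    shell_margin: float = DEFAULT_SHELL_MARGIN,
    template_id: str = "template",
) -> SourceSpace:
    """Build a folded-shell source space with surface-normal dipole orientations.

    The shell radius is modulated as

        r(theta, phi) = (R - margin) - fold_depth * (1 + sin(k*theta) * sin(k*phi)) / 2

    with ``R`` the conductor radius and ``k = fold_frequency``; the
    corrugations emulate gyral crowns (shallow) and sulcal valleys (deep).
    Dipole orientations are the outward normals of this folded surface, so
    sources on fold walls acquire tangential components, as cortical sources
    on sulcal banks do.  Sampling directions come from a golden-angle spiral
    rotated by a seeded random rotation.
    """
    if n_sources < 2:
        raise ValueError("n_sources must be >= 2")
    if not 0.0 <= fold_depth < conductor_radius:
        raise ValueError("fold_depth must satisfy 0 <= fold_depth < conductor_radius")
    if conductor_radius - shell_margin - fold_depth <= 0:
        raise ValueError("folds would push sources through the sphere center")

    u = _fibonacci_directions(n_sources, z_lo=-1.0, z_hi=1.0)
    rng = np.random.default_rng([int(seed), 1])
    axis = rng.normal(size=3)
    angle = rng.uniform(0.0, 2.0 * math.pi)
    u = u @ _rotation_matrix(axis, angle).T

    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    k = fold_frequency
    base = conductor_radius - shell_margin
    fold = 0.5 * (1.0 + np.sin(k * theta) * np.sin(k * phi))
    r = base - fold_depth * fold
    positions = r[:, None] * u

    # analytic outward normal of the surface S(theta, phi) = r(theta, phi) * u
    dr_dtheta = -0.5 * fold_depth * k * np.cos(k * theta) * np.sin(k * phi)
    dr_dphi = -0.5 * fold_depth * k * np.sin(k * theta) * np.cos(k * phi)
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    u_theta = np.column_stack([ct * cp, ct * sp, -st])
    u_phi = np.column_stack([-st * sp, st * cp, np.zeros_like(phi)])
    S_theta = dr_dtheta[:, None] * u + r[:, None] * u_theta
    S_phi = dr_dphi[:, None] * u + r[:, None] * u_phi
    normals = np.cross(S_theta, S_phi)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    flip = (normals * u).sum(axis=1) < 0
    normals[flip] *= -1.0

    radii = np.linalg.norm(positions, axis=1)
    if not np.all(radii < conductor_radius):
        raise ValueError("generated sources fall outside the conductor")

    return SourceSpace(
        positions=positions,
        orientations=normals,
        depth=conductor_radius - radii,
        conductor_radius=conductor_radius,
        template_id=template_id,
    )


def make_cohort(
    n_subjects: int,
    base_config: GeometryConfig,
    jitter_scale: float,
    seed: int,
) -> list[Subject]:
    """Generate a cohort of subjects sharing one template geometry.

    Each subject is the template plus (a) a seeded random rigid rotation of
    the whole head/sensor assembly about the conductor center, with angular
    scale ``jitter_scale / conductor_radius`` radians, and (b) independent
    vertex-wise Gaussian positional jitter of standard deviation
    ``jitter_scale`` on the source positions.  Vertex ``i`` of every subject
    corresponds to vertex ``i`` of the template, which is what group
    statistics operate on.  Per-subject random streams are keyed by
    ``(seed, stage, subject_index)`` so adding a subject never perturbs the
    draws of existing ones.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (group statistics need df >= 1)")
    if jitter_scale < 0:
        raise ValueError("jitter_scale must be >= 0")

    cfg = base_config
    template_sensors = make_sensor_array(
        cfg.n_mag, cfg.n_grad, cfg.helmet_radius, seed,
        gradiometer_baseline=cfg.gradiometer_baseline,
    )
    template_sources = make_source_space(
        cfg.n_sources, cfg.conductor_radius, cfg.fold_depth, cfg.fold_frequency,
        seed, shell_margin=cfg.shell_margin,
    )

    subjects = []
    for s in range(n_subjects):
        rng_rigid = np.random.default_rng([int(seed), 2, s])
        axis = rng_rigid.normal(size=3)
        angle = rng_rigid.normal() * (jitter_scale / cfg.conductor_radius)
        R = _rotation_matrix(axis, angle)

        rng_vertex = np.random.default_rng([int(seed), 3, s])
        vertex_jitter = rng_vertex.normal(scale=jitter_scale, size=(cfg.n_sources, 3)) \
            if jitter_scale > 0 else np.zeros((cfg.n_sources, 3))

        src_pos = template_sources.positions @ R.T + vertex_jitter
        src_ori = template_sources.orientations @ R.T
        radii = np.linalg.norm(src_pos, axis=1)
        if not np.all(radii < cfg.conductor_radius):
            worst = radii.max()
            raise ValueError(
                f"jitter pushed a source outside the conductor "
                f"(radius {worst:.4f} >= {cfg.conductor_radius})"
            )

        sensors = SensorArray(
            positions=template_sensors.positions @ R.T,
            orientations=template_sensors.orientations @ R.T,
            types=template_sensors.types,
            grad_axes=template_sensors.grad_axes @ R.T,
            gradiometer_baseline=cfg.gradiometer_baseline,
        )
        sources = SourceSpace(
            positions=src_pos,
            orientations=src_ori / np.linalg.norm(src_ori, axis=1, keepdims=True),
            depth=cfg.conductor_radius - radii,
            conductor_radius=cfg.conductor_radius,
            template_id=template_sources.template_id,
        )
        subjects.append(Subject(subject_id=s, sensors=sensors, sources=sources))
    return subjects


def simulate_noise_covariance(
    sensor_array: SensorArray,
    leadfield,
    n_trials: int,
    baseline_duration: float,
    sampling_rate: float,
    brain_noise_fraction: float,
    seed: int,
    sensor_noise_sd: float = 1.0,
    n_averages: int = 100,
) -> NoiseCovariance:
    """Estimate a sample covariance from simulated trial-structured baseline noise.

    Draws ``n_trials * round(sampling_rate * baseline_duration)`` samples of

        x = sensor_noise_sd * ( sqrt(1-f) * w  +  sqrt(f) * L q / sqrt(v) )

    where ``w`` is i.i.d. unit white sensor noise, ``q`` i.i.d. unit source
    activity, ``f = brain_noise_fraction`` and ``v = trace(L L^T)/n_channels``
    normalizes the projected brain noise to unit average channel power.  The
    expected covariance is therefore
    ``sensor_noise_sd^2 * ((1-f) I + f L L^T / v)``; the returned matrix is
    the two-pass (mean-subtracted) sample covariance of the concatenated
    baseline samples, as one would estimate from real pre-stimulus data.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= brain_noise_fraction <= 1.0:
        raise ValueError("brain_noise_fraction must lie in [0, 1]")
    n_per_trial = int(round(sampling_rate * baseline_duration))
    if n_per_trial < 1:
        raise ValueError("sampling_rate * baseline_duration must be >= 1 sample")
    n_samples = n_trials * n_per_trial

    L = leadfield.matrix if hasattr(leadfield, "matrix") else np.asarray(leadfield)
    n_ch = sensor_array.n_channels
    if L.shape[0] != n_ch:
        raise ValueError("leadfield channel count does not match sensor array")

    rng = np.random.default_rng([int(seed), 4])
    f = brain_noise_fraction
    x = math.sqrt(1.0 - f) * rng.standard_normal((n_ch, n_samples))
    if f > 0:
        v = float((L**2).sum()) / n_ch
        q = rng.standard_normal((L.shape[1], n_samples))
        x += math.sqrt(f) / math.sqrt(v) * (L @ q)
    x *= sensor_noise_sd

    C = np.cov(x, ddof=1)
    C = 0.5 * (C + C.T)  # enforce exact symmetry against rounding
    cond = np.linalg.cond(C)
    if cond > 1e12:
        logger.warning("noise covariance badly conditioned (cond=%.3g)", cond)

    return NoiseCovariance(matrix=C, n_samples_used=n_samples, n_averages=n_averages)


__all__ = [
    "SensorArray",
    "SourceSpace",
    "NoiseCovariance",
    "GeometryConfig",
    "Subject",
    "make_sensor_array",
    "make_source_space",
    "make_cohort",
    "simulate_noise_covariance",
    "MAGNETOMETER",
    "PLANAR_GRADIOMETER",
]
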