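"""Analytic spherical-conductor MEG forward model.

The magnetic field of a current dipole inside a homogeneous spherical
conductor has a closed form (the Sarvas formula) that is independent of the
sphere's radius and conductivity.  It preserves the two properties the
resolution analysis rests on: field strength falls off steeply with source
depth, and radially oriented dipoles are magnetically silent.

Magnetometers measure the field component along their pickup direction;
planar gradiometers are modelled as a two-point finite difference of that
component across their baseline.  The leadfield matrix collects, per
channel, the response to a unit dipole at each source oriented along its
surface normal (fixed-orientation model, no depth weighting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import SensorArray, SourceSpace

logger = logging.getLogger(__name__)

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix: channels x sources, field per unit dipole moment.

    Units are tesla per ampere-meter for magnetometer rows and tesla/meter
    per ampere-meter for planar-gradiometer rows.
    """

    matrix: np.ndarray
    sensor_ref: str = ""
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("leadfield contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


def sarvas_field(
    dipole_position,
    dipole_moment,
    field_point,
    sphere_center=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Magnetic field of a current dipole in a homogeneous spherical conductor.

    Parameters are in meters and ampere-meters; the result is in tesla.
    ``field_point`` may be a single 3-vector or an (..., 3) array of external
    points; the dipole is a single position/moment pair.  The field is exactly
    zero for a dipole at the sphere center and for radially oriented dipoles.

    Raises ``ValueError`` if any field point is not strictly farther from the
    center than the dipole (such a point cannot be outside any conducting
    sphere that contains the dipole), or coincides with the dipole.
    """
    center = np.asarray(sphere_center, dtype=float)
    r0 = np.asarray(dipole_position, dtype=float) - center
    q = np.asarray(dipole_moment, dtype=float)
    r = np.asarray(field_point, dtype=float) - center

    a_vec = r - r0
    a = np.sqrt((a_vec**2).sum(axis=-1))
    rn = np.sqrt((r**2).sum(axis=-1))
    r0n = np.sqrt((r0**2).sum())
    if np.any(rn <= r0n):
        raise ValueError("field point not strictly outside the conductor sphere")
    if np.any(a == 0.0):
        raise ValueError("field point coincides with the dipole")

    f = a * (rn * a + rn**2 - (r * r0).sum(axis=-1))
    adotr = (a_vec * r).sum(axis=-1)
    grad_f = (
        (a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn)[..., None] * r
        - (a + 2.0 * rn + adotr / a)[..., None] * r0
    )
    q_x_r0 = np.cross(q, r0)
    b = (MU0_OVER_4PI / f[..., None] ** 2) * (
        f[..., None] * q_x_r0 - ((q_x_r0 * r).sum(axis=-1))[..., None] * grad_f
    )
    return b


def _integration_points(sensor_array: SensorArray):
    """Field-evaluation points for every channel.

    Magnetometers contribute one point; planar gradiometers two points at
    position +/- (baseline/2) along their tangential axis.  Returns the
    stacked (n_points, 3) array plus, per channel, the index of its first
    point (gradiometers own two consecutive points).
    """
    pts, first = [], []
    half = 0.5 * sensor_array.gradiometer_baseline
    for c in range(sensor_array.n_channels):
        first.append(len(pts))
        if sensor_array.types[c] == "magnetometer":
            pts.append(sensor_array.positions[c])
        else:
            axis = sensor_array.grad_axes[c]
            pts.append(sensor_array.positions[c] + half * axis)
            pts.append(sensor_array.positions[c] - half * axis)
    return np.asarray(pts), np.asarray(first)


def _responses_from_fields(sensor_array: SensorArray, b: np.ndarray, first: np.ndarray) -> np.ndarray:
    """Project per-point fields onto pickup directions; difference gradiometer pairs."""
    out = np.empty(sensor_array.n_channels)
    mag = sensor_array.mag_mask
    grad = sensor_array.grad_mask
    out[mag] = (b[first[mag]] * sensor_array.orientations[mag]).sum(axis=-1)
    g_ori = sensor_array.orientations[grad]
    g_first = first[grad]
    out[grad] = (
        (b[g_first] * g_ori).sum(axis=-1) - (b[g_first + 1] * g_ori).sum(axis=-1)
    ) / sensor_array.gradiometer_baseline
    return out


def channel_response(
    sensor_array: SensorArray,
    channel_index: int,
    dipole_position,
    dipole_moment,
    sphere_center=(0.0, 0.0, 0.0),
) -> float:
    """Response of one channel to one dipole.

    Magnetometer: field projected onto the pickup direction.  Planar
    gradiometer: difference of the projected fields at the two integration
    points divided by the baseline.
    """
    c = int(channel_index)
    ori = sensor_array.orientations[c]
    if sensor_array.types[c] == "magnetometer":
        b = sarvas_field(dipole_position, dipole_moment, sensor_array.positions[c], sphere_center)
        return float((b * ori).sum(axis=-1))
    half = 0.5 * sensor_array.gradiometer_baseline
    axis = sensor_array.grad_axes[c]
    b_plus = sarvas_field(dipole_position, dipole_moment,
                          sensor_array.positions[c] + half * axis, sphere_center)
    b_minus = sarvas_field(dipole_position, dipole_moment,
                           sensor_array.positions[c] - half * axis, sphere_center)
    return float(((b_plus * ori).sum(axis=-1) - (b_minus * ori).sum(axis=-1))
                 / sensor_array.gradiometer_baseline)


def build_leadfield(sensor_array: SensorArray, source_space: SourceSpace) -> Leadfield:
    """Leadfield for unit dipoles along the source-space surface normals.

    Orientation vectors are re-normalized before use so that the fixed
    orientation carries no amplitude.  Column ``j`` equals the per-channel
    responses to a unit dipole at source ``j``.
    """
    radii = np.linalg.norm(source_space.positions, axis=1)
    if not np.all(radii < source_space.conductor_radius):
        raise ValueError("source outside conductor")
    sens_radii = np.linalg.norm(sensor_array.positions, axis=1)
    if not np.all(sens_radii > source_space.conductor_radius):
        raise ValueError("sensor integration center inside the conductor")

    pts, first = _integration_points(sensor_array)
    n_ch, n_src = sensor_array.n_channels, source_space.n_sources
    L = np.empty((n_ch, n_src))
    for j in range(n_src):
        ori = source_space.orientations[j]
        moment = ori / np.sqrt((ori**2).sum())
        b = sarvas_field(source_space.positions[j], moment, pts)
        L[:, j] = _responses_from_fields(sensor_array, b, first)
    return Leadfield(matrix=L)


def sensitivity_map(leadfield: Leadfield, normalize: bool = False) -> np.ndarray:
    """Per-source sum of squares of the leadfield columns.

    With ``normalize=True`` the map is divided by its maximum, which is how
    such maps are usually displayed.
    """
    L = leadfield.matrix
    if L.size == 0:
        raise ValueError("empty leadfield")
    s = (L**2).sum(axis=0)
    if normalize:
        m = s.max()
        if m == 0.0:
            raise ValueError("cannot normalize an all-zero sensitivity map")
        s = s / m
    return s


__all__ = [
    "Leadfield",
    "sarvas_field",
    "channel_response",
    "build_leadfield",
    "sensitivity_map",
    "MU0_OVER_4PI",
]
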