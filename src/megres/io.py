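"""Delimited-text and structured-binary I/O for matrices, maps and geometry.

Text matrices are tab-separated with an optional ``#``-prefixed header row of
column identifiers and values printed to 17 significant digits, which makes
text round-trips faithful to the last ulp and byte-for-byte reproducible
across runs.  Binary archives are NumPy ``.npz`` files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import NoiseCovariance, SensorArray, SourceSpace, Subject
from .group import GroupResult
from .metrics import MetricMaps

FLOAT_FMT = "%.17g"


def write_matrix(path, matrix: np.ndarray, column_ids=None) -> None:
    """Write a 2-D matrix as TSV (17 significant digits) or, for ``.npz``, binary."""
    path = Path(path)
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    if path.suffix == ".npz":
        np.savez(path, matrix=m)
        return
    header = "\t".join(str(c) for c in column_ids) if column_ids is not None else ""
    np.savetxt(path, m, fmt=FLOAT_FMT, delimiter="\t", header=header)


def read_matrix(path) -> np.ndarray:
    """Read a matrix written by :func:`write_matrix` (TSV or ``.npz``)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as archive:
            return archive["matrix"]
    if path.stat().st_size == 0:
        raise ValueError(f"matrix file {path} is empty")
    try:
        m = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    except ValueError as err:
        raise ValueError(f"malformed matrix file {path}: {err}") from err
    if m.size == 0:
        raise ValueError(f"matrix file {path} is empty")
    return m


def write_metric_maps_tsv(path, maps: MetricMaps, source_space: SourceSpace) -> None:
    """Per-source metric table: source_id, position, depth, mode, method, metrics."""
    pos = source_space.positions
    df = pd.DataFrame(
        {
            "source_id": np.arange(source_space.n_sources),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "depth": source_space.depth,
            "mode": maps.mode,
            "method": maps.method,
            "dle_cm": maps.dle,
            "sd_sqrtcm": maps.sd,
            "oa_norm": maps.oa,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_group_result_tsv(path, result: GroupResult, source_space: SourceSpace) -> None:
    """Vertex-wise group-contrast table with mean difference, SD, t and p."""
    method_a, method_b, metric, mode = result.contrast
    pos = source_space.positions
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(len(result.mean_map)),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "metric": metric,
            "mode": mode,
            "contrast": f"{method_a}-{method_b}",
            "mean_diff": result.mean_map,
            "sd": result.sd_map,
            "t": result.t_map,
            "p": result.p_map,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_sensor_array_tsv(path, sensors: SensorArray) -> None:
    """One row per channel: type, position, pickup orientation, gradient axis."""
    df = pd.DataFrame(
        {
            "channel_id": np.arange(sensors.n_channels),
            "type": sensors.types,
            "x": sensors.positions[:, 0],
            "y": sensors.positions[:, 1],
            "z": sensors.positions[:, 2],
            "ox": sensors.orientations[:, 0],
            "oy": sensors.orientations[:, 1],
            "oz": sensors.orientations[:, 2],
            "ax": sensors.grad_axes[:, 0],
            "ay": sensors.grad_axes[:, 1],
            "az": sensors.grad_axes[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_source_space_tsv(path, sources: SourceSpace) -> None:
    """One row per source: position, orientation, depth."""
    df = pd.DataFrame(
        {
            "source_id": np.arange(sources.n_sources),
            "x": sources.positions[:, 0],
            "y": sources.positions[:, 1],
            "z": sources.positions[:, 2],
            "ox": sources.orientations[:, 0],
            "oy": sources.orientations[:, 1],
            "oz": sources.orientations[:, 2],
            "depth": sources.depth,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_cohort_archive(path, subjects: list[Subject],
                         covariances: list[NoiseCovariance] | None = None) -> None:
    """Single structured binary archive for a whole cohort (geometry + covariances)."""
    payload: dict[str, np.ndarray] = {"n_subjects": np.array(len(subjects))}
    for subj in subjects:
        tag = f"s{subj.subject_id}"
        payload[f"{tag}_sensor_pos"] = subj.sensors.positions
        payload[f"{tag}_sensor_ori"] = subj.sensors.orientations
        payload[f"{tag}_sensor_types"] = subj.sensors.types.astype("U32")
        payload[f"{tag}_sensor_axes"] = subj.sensors.grad_axes
        payload[f"{tag}_grad_baseline"] = np.array(subj.sensors.gradiometer_baseline)
        payload[f"{tag}_source_pos"] = subj.sources.positions
        payload[f"{tag}_source_ori"] = subj.sources.orientations
        payload[f"{tag}_source_depth"] = subj.sources.depth
        payload[f"{tag}_conductor_radius"] = np.array(subj.sources.conductor_radius)
        if covariances is not None:
            payload[f"{tag}_cov"] = covariances[subj.subject_id].matrix
            payload[f"{tag}_cov_n_samples"] = np.array(
                covariances[subj.subject_id].n_samples_used)
            payload[f"{tag}_cov_n_averages"] = np.array(
                covariances[subj.subject_id].n_averages)
    np.savez(path, **payload)


def read_cohort_archive(path):
    """Inverse of :func:`write_cohort_archive`.

    Returns ``(subjects, covariances)``; ``covariances`` is ``None`` when the
    archive holds geometry only.
    """
    with np.load(path) as archive:
        n = int(archive["n_subjects"])
        subjects, covs = [], []
        for s in range(n):
            tag = f"s{s}"
            sensors = SensorArray(
                positions=archive[f"{tag}_sensor_pos"],
                orientations=archive[f"{tag}_sensor_ori"],
                types=archive[f"{tag}_sensor_types"],
                grad_axes=archive[f"{tag}_sensor_axes"],
                gradiometer_baseline=float(archive[f"{tag}_grad_baseline"]),
            )
            sources = SourceSpace(
                positions=archive[f"{tag}_source_pos"],
                orientations=archive[f"{tag}_source_ori"],
                depth=archive[f"{tag}_source_depth"],
                conductor_radius=float(archive[f"{tag}_conductor_radius"]),
            )
            subjects.append(Subject(subject_id=s, sensors=sensors, sources=sources))
            if f"{tag}_cov" in archive:
                covs.append(NoiseCovariance(
                    matrix=archive[f"{tag}_cov"],
                    n_samples_used=int(archive[f"{tag}_cov_n_samples"]),
                    n_averages=int(archive[f"{tag}_cov_n_averages"]),
                ))
    return subjects, (covs if covs else None)


__all__ = [
    "write_matrix",
    "read_matrix",
    "write_metric_maps_tsv",
    "write_group_result_tsv",
    "write_sensor_array_tsv",
    "write_source_space_tsv",
    "write_cohort_archive",
    "read_cohort_archive",
    "FLOAT_FMT",
]
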