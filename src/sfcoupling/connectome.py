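"""Functional connectivity construction, SC normalization, within-network
summaries, and the head-motion QC exclusion rule.

FC is the Fisher z-transform of the ROI-to-ROI Pearson correlation matrix of
preprocessed BOLD time series.  Structural weights are seed-based connection
probabilities: streamlines from source ROI *i* reaching target *j*, divided
by the streamlines sampled in *i*.  Time series are assumed already
band-pass filtered and nuisance-regressed upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parcellation_io import ParcellationScheme, SubjectConnectome

#: |r| clamp applied before atanh so perfectly coupled synthetic series
#: produce a large finite z instead of an infinity.
R_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class NetworkSummary:
    """Within-network mean connectivity for one network.

    ``within_sc`` averages the directed weights over ordered off-diagonal
    ROI pairs of the network (equivalent to averaging the symmetrized
    matrix); ``within_fc`` averages Fisher-z values over unordered pairs.
    Singleton networks yield NaN sentinels.
    """

    network: str
    within_sc: float
    within_fc: float
    n_roi: int


@dataclass(frozen=True)
class MotionRecord:
    """Per-subject head-motion summary: mean framewise displacement (mm),
    and the three translation (mm) and three rotation (degree) parameters
    as maxima of absolute values over frames."""

    mean_fd: float
    translations: tuple[float, float, float]
    rotations: tuple[float, float, float]

    def __post_init__(self) -> None:
        vals = (self.mean_fd, *self.translations, *self.rotations)
        if any(v < 0 for v in vals):
            raise ValueError("motion parameters must be nonnegative")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str | None = None


def fc_from_timeseries(ts: np.ndarray) -> np.ndarray:
    """Fisher-z functional connectivity from a T x n_roi time-series matrix.

    z_ij = atanh(r_ij) with r the Pearson correlation of columns i and j,
    |r| clamped to ``R_CLAMP``.  The diagonal is set to 0 and is by
    convention never consumed downstream.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D T x n_roi array")
    T, n = ts.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    constant = np.flatnonzero(ts.max(axis=0) - ts.min(axis=0) == 0)
    if constant.size:
        raise ValueError(
            f"constant time series for ROI(s) {(constant + 1).tolist()} "
            "(1-based); correlation undefined"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def normalize_sc(
    streamline_counts: np.ndarray, samples_per_seed: np.ndarray
) -> np.ndarray:
    """Connection probabilities from raw streamline counts.

    sc[i, j] = counts[i, j] / samples_per_seed[i], with the diagonal forced
    to zero.  ``samples_per_seed`` is typically 5000 x (seed voxel count).
    """
    counts = np.asarray(streamline_counts, dtype=float)
    samples = np.asarray(samples_per_seed, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("streamline_counts must be square")
    if samples.shape != (counts.shape[0],):
        raise ValueError("samples_per_seed must have one entry per ROI")
    if (samples <= 0).any():
        raise ValueError("samples_per_seed must be positive")
    if (counts < 0).any():
        raise ValueError("streamline counts must be nonnegative")
    if (counts > samples[:, None]).any():
        i, j = np.argwhere(counts > samples[:, None])[0]
        raise ValueError(
            f"count at ({i + 1}, {j + 1}) exceeds streamlines sampled from seed {i + 1}"
        )
    sc = counts / samples[:, None]
    np.fill_diagonal(sc, 0.0)
    return sc


def within_network_summaries(
    connectome: SubjectConnectome, scheme: ParcellationScheme
) -> list[NetworkSummary]:
    """Mean within-network SC (ordered pairs) and FC (unordered pairs)."""
    if connectome.sc is None or connectome.fc is None:
        raise ValueError("connectome must carry both sc and fc")
    sc, fc = connectome.sc, connectome.fc
    out: list[NetworkSummary] = []
    for lab in scheme.network_labels:
        idx = scheme.members(lab)
        m = idx.size
        if m < 2:
            warnings.warn(f"network {lab} has a single ROI; summaries undefined")
            out.append(NetworkSummary(lab, np.nan, np.nan, m))
            continue
        block_sc = sc[np.ix_(idx, idx)]
        block_fc = fc[np.ix_(idx, idx)]
        off = ~np.eye(m, dtype=bool)
        within_sc = float(block_sc[off].mean())
        iu = np.triu_indices(m, k=1)
        within_fc = float(block_fc[iu].mean())
        out.append(NetworkSummary(lab, within_sc, within_fc, m))
    return out


def motion_qc(
    record: MotionRecord,
    fd_threshold: float = 0.5,
    motion_threshold: float = 3.0,
) -> QCResult:
    """Exclusion rule: fail iff mean FD > 0.5 mm or any of the six motion
    parameters > 3 mm/degree.  Both inequalities are strict, so a subject
    sitting exactly at a threshold is retained."""
    if record.mean_fd > fd_threshold:
        return QCResult(False, f"mean FD {record.mean_fd:g} > {fd_threshold:g} mm")
    for axis, v in zip("xyz", record.translations):
        if v > motion_threshold:
            return QCResult(False, f"translation {axis} = {v:g} > {motion_threshold:g} mm")
    for axis, v in zip("xyz", record.rotations):
        if v > motion_threshold:
            return QCResult(
                False, f"rotation {axis} = {v:g} > {motion_threshold:g} degrees"
            )
    return QCResult(True)


def motion_qc_table(
    motion: pd.DataFrame,
    fd_threshold: float = 0.5,
    motion_threshold: float = 3.0,
) -> pd.DataFrame:
    """Apply :func:`motion_qc` to a motion CSV.

    Expects columns ``subject_id, mean_fd, tx, ty, tz, rx, ry, rz``; returns
    the table with ``qc_pass`` and ``qc_reason`` columns appended.
    """
    required = {"subject_id", "mean_fd", "tx", "ty", "tz", "rx", "ry", "rz"}
    missing = required - set(motion.columns)
    if missing:
        raise ValueError(f"motion table missing columns: {sorted(missing)}")
    passes, reasons = [], []
    for row in motion.itertuples(index=False):
        rec = MotionRecord(
            mean_fd=float(row.mean_fd),
            translations=(abs(row.tx), abs(row.ty), abs(row.tz)),
            rotations=(abs(row.rx), abs(row.ry), abs(row.rz)),
        )
        res = motion_qc(rec, fd_threshold, motion_threshold)
        passes.append(res.passed)
        reasons.append(res.reason or "")
    out = motion.copy()
    out["qc_pass"] = passes
    out["qc_reason"] = reasons
    return out
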