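"""Parcellation scheme, per-subject connectome containers, and file I/O.

All matrix files are plain delimited text without header: row *i* of the
structural matrix holds the outgoing connection probabilities of ROI *i*
(source ROI convention from seed-based probabilistic tractography).  The
parcellation lookup table is a delimited table with columns
``roi_id, roi_name, network, hemisphere``; ROI ids are 1-based and must be
contiguous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical 7-network labels of the 400-parcel resting-state parcellation:
#: frontoparietal, dorsal attention, default mode, limbic, somatomotor,
#: ventral attention and visual networks.
CANONICAL_NETWORKS: tuple[str, ...] = ("FPN", "DAN", "DMN", "LMN", "SMN", "VAN", "VIN")

#: ROI counts per network used by :func:`default_scheme` for ``n_roi=400``,
#: mirroring the membership sizes of the standard 400-parcel assignment.
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "VIN": 61,
    "SMN": 77,
    "DAN": 46,
    "VAN": 47,
    "LMN": 26,
    "FPN": 52,
    "DMN": 91,
}


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


@dataclass(frozen=True)
class ParcellationScheme:
    """ROI-to-network assignment defining the aggregation units.

    Parameters
    ----------
    roi_ids
        1-based contiguous integer labels, one per ROI, in matrix order.
    roi_names
        Human-readable ROI names.
    networks
        Network label per ROI, drawn from a closed label set.
    hemispheres
        ``"L"`` or ``"R"`` per ROI.
    """

    roi_ids: np.ndarray
    roi_names: tuple[str, ...]
    networks: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = np.asarray(self.roi_ids, dtype=int)
        object.__setattr__(self, "roi_ids", ids)
        n = ids.size
        if n == 0:
            raise FormatError("parcellation has no ROIs")
        if len(set(ids.tolist())) != n:
            dupes = sorted({int(i) for i in ids if (ids == i).sum() > 1})
            raise FormatError(f"duplicate roi_id values: {dupes}")
        if not np.array_equal(np.sort(ids), np.arange(1, n + 1)):
            missing = sorted(set(range(1, n + 1)) - set(ids.tolist()))
            raise FormatError(f"roi_ids must be contiguous 1..{n}; missing {missing}")
        if len(self.roi_names) != n or len(self.networks) != n or len(self.hemispheres) != n:
            raise FormatError("roi_names/networks/hemispheres length mismatch")
        bad_hemi = {h for h in self.hemispheres if h not in ("L", "R")}
        if bad_hemi:
            raise FormatError(f"hemisphere labels must be L or R, got {sorted(bad_hemi)}")
        counts: dict[str, int] = {}
        for lab in self.networks:
            counts[lab] = counts.get(lab, 0) + 1
        small = [lab for lab, c in counts.items() if c < 2]
        if small:
            raise FormatError(f"networks with fewer than 2 member ROIs: {sorted(small)}")

    @property
    def n_roi(self) -> int:
        return int(self.roi_ids.size)

    @property
    def network_labels(self) -> tuple[str, ...]:
        """Distinct network labels in first-appearance order."""
        seen: list[str] = []
        for lab in self.networks:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def members(self, network: str) -> np.ndarray:
        """0-based ROI indices belonging to ``network``."""
        idx = np.flatnonzero(np.asarray(self.networks) == network)
        if idx.size == 0:
            raise KeyError(f"unknown network {network!r}")
        return idx

    def network_of(self) -> Mapping[int, str]:
        """Map roi_id -> network label."""
        return {int(i): lab for i, lab in zip(self.roi_ids, self.networks)}


def default_scheme(
    n_roi: int = 400, network_sizes: Mapping[str, int] | None = None
) -> ParcellationScheme:
    """Build a scheme with the canonical 7 networks and given member counts.

    With the defaults this reproduces the 400-ROI / 7-network layout; member
    counts are configurable, and a genuine atlas assignment can instead be
    loaded from a lookup table with :func:`read_parcellation`.
    """
    if network_sizes is None:
        if n_roi == 400:
            network_sizes = dict(DEFAULT_NETWORK_SIZES)
        else:
            base, extra = divmod(n_roi, len(CANONICAL_NETWORKS))
            network_sizes = {
                lab: base + (1 if k < extra else 0)
                for k, lab in enumerate(CANONICAL_NETWORKS)
            }
    if sum(network_sizes.values()) != n_roi:
        raise ValueError("network_sizes must sum to n_roi")
    names: list[str] = []
    networks: list[str] = []
    hemis: list[str] = []
    for lab, size in network_sizes.items():
        for k in range(size):
            hemi = "L" if k < size // 2 else "R"
            names.append(f"{hemi}_{lab}_{k + 1}")
            networks.append(lab)
            hemis.append(hemi)
    return ParcellationScheme(
        roi_ids=np.arange(1, n_roi + 1),
        roi_names=tuple(names),
        networks=tuple(networks),
        hemispheres=tuple(hemis),
    )


def read_parcellation(
    path: str | Path,
    allowed_networks: Sequence[str] = CANONICAL_NETWORKS,
) -> ParcellationScheme:
    """Read and validate a parcellation lookup table (TSV or CSV).

    Label fields are whitespace-normalized before validation; a network
    label outside ``allowed_networks`` raises :class:`FormatError` naming
    the offending row.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"roi_id", "roi_name", "network", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"lookup table missing columns: {sorted(missing)}")
    for col in ("roi_name", "network", "hemisphere"):
        df[col] = df[col].astype(str).str.strip()
    try:
        roi_ids = df["roi_id"].astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-integer roi_id: {exc}") from exc
    allowed = set(allowed_networks)
    for row_idx, lab in enumerate(df["network"]):
        if lab not in allowed:
            raise FormatError(
                f"row {row_idx + 1} (roi_id={roi_ids[row_idx]}): unknown network "
                f"label {lab!r}; allowed: {sorted(allowed)}"
            )
    order = np.argsort(roi_ids, kind="stable")
    df = df.iloc[order]
    return ParcellationScheme(
        roi_ids=roi_ids[order],
        roi_names=tuple(df["roi_name"]),
        networks=tuple(df["network"]),
        hemispheres=tuple(df["hemisphere"]),
    )


def write_parcellation(scheme: ParcellationScheme, path: str | Path) -> None:
    """Write a scheme back to its TSV lookup-table form."""
    pd.DataFrame(
        {
            "roi_id": scheme.roi_ids,
            "roi_name": scheme.roi_names,
            "network": scheme.networks,
            "hemisphere": scheme.hemispheres,
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class SubjectConnectome:
    """One subject's structural and functional connectivity.

    ``sc`` holds directed connection probabilities w_ij in [0, 1] with zero
    diagonal (row = source/seed ROI).  ``fc`` is the symmetric Fisher-z
    functional connectivity matrix; its diagonal is set to 0 and never enters
    any computation.  ``timeseries`` optionally carries the T x n_roi BOLD
    series the FC was (or can be) built from.
    """

    subject_id: str
    sc: np.ndarray | None = None
    fc: np.ndarray | None = None
    timeseries: np.ndarray | None = None

    def validate(self, scheme: ParcellationScheme, atol: float = 1e-8) -> "SubjectConnectome":
        n = scheme.n_roi
        if self.sc is not None:
            sc = np.asarray(self.sc, dtype=float)
            if sc.shape != (n, n):
                raise ValueError(
                    f"sc shape {sc.shape} does not match scheme n_roi={n}"
                )
            if not np.isfinite(sc).all():
                raise ValueError("sc contains non-finite entries")
            if (sc < 0).any():
                i, j = np.argwhere(sc < 0)[0]
                raise ValueError(f"negative SC weight at ({i + 1}, {j + 1})")
            if (sc > 1).any():
                i, j = np.argwhere(sc > 1)[0]
                raise ValueError(f"SC weight > 1 at ({i + 1}, {j + 1})")
            if np.abs(np.diag(sc)).max(initial=0.0) > atol:
                raise ValueError("sc diagonal must be zero")
            self.sc = sc
        if self.fc is not None:
            fc = np.asarray(self.fc, dtype=float)
            if fc.shape != (n, n):
                raise ValueError(
                    f"fc shape {fc.shape} does not match scheme n_roi={n}"
                )
            if not np.isfinite(fc).all():
                raise ValueError("fc contains non-finite entries")
            if np.abs(fc - fc.T).max() > 1e-6:
                raise ValueError("fc is not symmetric")
            np.fill_diagonal(fc, 0.0)  # diagonal is never consumed
            self.fc = fc
        if self.timeseries is not None:
            ts = np.asarray(self.timeseries, dtype=float)
            if ts.ndim != 2 or ts.shape[1] != n:
                raise ValueError(
                    f"timeseries shape {ts.shape} does not match scheme n_roi={n}"
                )
            if not np.isfinite(ts).all():
                raise ValueError("timeseries contains non-finite entries")
            self.timeseries = ts
        return self


def _read_matrix(path: str | Path) -> np.ndarray:
    try:
        mat = np.loadtxt(path, delimiter="\t")
    except ValueError:
        mat = np.loadtxt(path, delimiter=",")
    return np.atleast_2d(np.asarray(mat, dtype=float))


def read_connectome(
    subject_id: str,
    scheme: ParcellationScheme,
    sc_path: str | Path | None = None,
    fc_path: str | Path | None = None,
    ts_path: str | Path | None = None,
) -> SubjectConnectome:
    """Read delimited SC/FC matrices and/or a time-series file for one subject.

    When only a time series is supplied the returned connectome has an empty
    ``fc``; build it downstream with :func:`sfcoupling.fc_from_timeseries`.
    """
    if sc_path is None and fc_path is None and ts_path is None:
        raise ValueError("at least one of sc_path, fc_path, ts_path is required")
    sc = _read_matrix(sc_path) if sc_path is not None else None
    fc = _read_matrix(fc_path) if fc_path is not None else None
    ts = _read_matrix(ts_path) if ts_path is not None else None
    return SubjectConnectome(subject_id=subject_id, sc=sc, fc=fc, timeseries=ts).validate(
        scheme
    )


def write_matrix(mat: np.ndarray, path: str | Path) -> None:
    """Write a matrix as headerless TSV at full double precision."""
    np.savetxt(path, np.asarray(mat, dtype=float), delimiter="\t", fmt="%.17g")


def write_results(
    results: Iterable[object],
    path: str | Path,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write a collection of result dataclasses (or dicts) to a tidy CSV.

    One row per result; list-valued fields (e.g. covariates) are joined with
    ``;``.  Floats are written with 17 significant digits so a read-back
    round-trips losslessly.  Refuses to clobber an existing file unless
    ``overwrite`` is set, and refuses to write an empty collection.
    """
    rows: list[dict] = []
    for item in results:
        if dataclasses.is_dataclass(item) and not isinstance(item, type):
            row = dataclasses.asdict(item)
        elif isinstance(item, Mapping):
            row = dict(item)
        else:
            raise TypeError(f"cannot serialize result of type {type(item).__name__}")
        for key, val in list(row.items()):
            if isinstance(val, (list, tuple)):
                row[key] = ";".join(str(v) for v in val)
            elif isinstance(val, np.ndarray):
                row[key] = ";".join(repr(float(v)) for v in val)
        rows.append(row)
    if not rows:
        raise ValueError("refusing to write an empty result collection")
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a tidy results CSV produced by :func:`write_results`."""
    return pd.read_csv(path)
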