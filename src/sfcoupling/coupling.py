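"""ROI-wise structure-function coupling and its network aggregation.

For each ROI the coupling statistic is the Spearman rank correlation between
that ROI's structural connectivity profile (its row of edge weights, self
edge excluded) and the corresponding functional connectivity profile, over
the selected (nonzero-SC by default) edges.  Network coupling is the mean of
the defined ROI-wise values across member ROIs.  Undefined correlations
(too few selected edges, or a constant selected vector) propagate as NaN
sentinels, never as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parcellation_io import ParcellationScheme, SubjectConnectome

EDGE_POLICIES = ("sc_nonzero", "both_nonzero")
SC_MODES = ("directed", "symmetric")


@dataclass
class CouplingProfile:
    """Per-ROI Spearman rho and per-network means for one subject."""

    subject_id: str
    roi_rho: np.ndarray  # NaN where undefined
    network_rho: dict[str, float]
    n_edges_used: np.ndarray


def roi_coupling(
    sc_profile: np.ndarray,
    fc_profile: np.ndarray,
    min_edges: int = 3,
    policy: str = "sc_nonzero",
) -> tuple[float, int]:
    """Spearman coupling of one ROI's SC and FC edge profiles.

    Profiles exclude the self edge and are aligned by target ROI.  Edges are
    selected by ``policy`` (``sc_nonzero``: SC > 0; ``both_nonzero``: SC > 0
    and FC != 0).  Returns ``(rho, n_edges_used)`` with ``rho = NaN`` when
    fewer than ``min_edges`` edges survive selection or either selected
    vector is constant.  Ties are handled with midranks.
    """
    sc = np.asarray(sc_profile, dtype=float)
    fc = np.asarray(fc_profile, dtype=float)
    if sc.shape != fc.shape or sc.ndim != 1:
        raise ValueError(
            f"misaligned profiles: sc {sc.shape} vs fc {fc.shape}"
        )
    if policy not in EDGE_POLICIES:
        raise ValueError(f"unknown edge policy {policy!r}; choose from {EDGE_POLICIES}")
    mask = sc > 0
    if policy == "both_nonzero":
        mask &= fc != 0
    k = int(mask.sum())
    if k < min_edges:
        return float("nan"), k
    x, y = sc[mask], fc[mask]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), k
    rho = stats.spearmanr(x, y).statistic
    return float(rho), k


def subject_coupling(
    connectome: SubjectConnectome,
    scheme: ParcellationScheme,
    policy: str = "sc_nonzero",
    sc_mode: str = "directed",
    min_edges: int = 3,
) -> CouplingProfile:
    """ROI-wise coupling for every ROI, then network means.

    ``sc_mode='directed'`` uses ROI *i*'s outgoing weights (row i), matching
    the seed-region framing of probabilistic tractography;
    ``'symmetric'`` uses the symmetrized mean (w_ij + w_ji) / 2.  ROIs with
    undefined rho are dropped from (not zero-filled into) network means; a
    network with no defined member yields a NaN sentinel with a warning.
    """
    if connectome.sc is None or connectome.fc is None:
        raise ValueError("connectome must carry both sc and fc")
    if sc_mode not in SC_MODES:
        raise ValueError(f"unknown sc_mode {sc_mode!r}; choose from {SC_MODES}")
    sc = connectome.sc
    if sc_mode == "symmetric":
        sc = (sc + sc.T) / 2.0
    fc = connectome.fc
    n = scheme.n_roi
    rho = np.full(n, np.nan)
    n_used = np.zeros(n, dtype=int)
    keep = ~np.eye(n, dtype=bool)
    for i in range(n):
        rho[i], n_used[i] = roi_coupling(
            sc[i, keep[i]], fc[i, keep[i]], min_edges=min_edges, policy=policy
        )
    network_rho: dict[str, float] = {}
    for lab in scheme.network_labels:
        member_rho = rho[scheme.members(lab)]
        defined = member_rho[~np.isnan(member_rho)]
        if defined.size == 0:
            warnings.warn(
                f"subject {connectome.subject_id}: no defined ROI coupling in {lab}"
            )
            network_rho[lab] = float("nan")
        else:
            network_rho[lab] = float(defined.mean())
    return CouplingProfile(connectome.subject_id, rho, network_rho, n_used)


def cohort_coupling(
    connectomes: list[SubjectConnectome],
    scheme: ParcellationScheme,
    policy: str = "sc_nonzero",
    sc_mode: str = "directed",
    min_edges: int = 3,
) -> pd.DataFrame:
    """Long-format coupling table over a cohort.

    Columns: ``subject_id, network, rho, n_rois_defined``; rows are sorted by
    (subject_id, network) so output is independent of input order.
    """
    if not connectomes:
        raise ValueError("need at least one connectome")
    ids = [c.subject_id for c in connectomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject_id: {dupes}")
    rows = []
    for con in connectomes:
        prof = subject_coupling(
            con, scheme, policy=policy, sc_mode=sc_mode, min_edges=min_edges
        )
        for lab in scheme.network_labels:
            member_rho = prof.roi_rho[scheme.members(lab)]
            rows.append(
                {
                    "subject_id": prof.subject_id,
                    "network": lab,
                    "rho": prof.network_rho[lab],
                    "n_rois_defined": int(np.sum(~np.isnan(member_rho))),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["subject_id", "network"], kind="stable").reset_index(drop=True)
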