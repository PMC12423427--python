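"""Synthetic cohort and connectome generator with known effect sizes.

The generator emits the statistical structure the analysis pipeline assumes:
sparse nonnegative structural connectivity matrices, functional connectivity
whose per-network rank agreement with SC is set by a coupling knob kappa,
log-normal WMH volumes with rule-consistent Fazekas severity, and cognitive
scores produced by standardized linear models with configurable effects.
Defaults reproduce the cohort conditions the analysis is designed for:
617 subjects (mean age 61 +/- 7, 46.5% female), WMH volume log-normal with
mean ~3.8 mL, a ~60/40 mild/severe split, and standardized effects 0.136
(WMH volume -> target-network coupling, mild stratum), 0.110 (coupling ->
baseline digit span, mild) and 0.245 (coupling -> follow-up digit span,
mild).  Every draw is reproducible from the mandatory seed.

The kappa knob is calibrated on the Spearman scale: FC edge values mix the
normal scores of the SC ranks with independent Gaussian noise using weight
w = 2 sin(pi * kappa / 6), so in the noise-free bivariate-normal limit the
population Spearman correlation of an edge profile equals kappa itself
(inverting rho_S = (6/pi) arcsin(w/2)).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .cohort_stats import add_severity
from .parcellation_io import ParcellationScheme, SubjectConnectome, default_scheme

#: Per-network baseline coupling levels (also the default kappa targets for
#: connectome generation): lowest in the frontoparietal network, highest in
#: the somatomotor network, matching the unimodal-to-transmodal gradient.
DEFAULT_KAPPA: dict[str, float] = {
    "FPN": 0.15,
    "DAN": 0.28,
    "DMN": 0.22,
    "LMN": 0.18,
    "SMN": 0.35,
    "VAN": 0.28,
    "VIN": 0.30,
}

DEFAULT_PREVALENCES: dict[str, float] = {
    "hypertension": 0.729,
    "diabetes": 0.222,
    "hypercholesterolemia": 0.428,
    "smoking": 0.376,
    "drinking": 0.441,
}

RISK_FACTORS = tuple(DEFAULT_PREVALENCES)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_subjects: int = 617
    n_roi: int = 400
    network_sizes: dict[str, int] | None = None
    sparsity: float = 0.6
    kappa: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_KAPPA))
    coupling_sd: float = 0.05
    target_network: str = "FPN"
    beta_wmh_coupling: float = 0.136
    beta_coupling_cognition: float = 0.110
    beta_longitudinal: float = 0.245
    age_mean: float = 61.0
    age_sd: float = 7.0
    female_prop: float = 0.465
    education_mean: float = 9.0
    education_sd: float = 3.5
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    # log-normal WMH volume: exp(mu + sigma * burden); mean ~3.8 mL, SD ~8 mL
    wmhv_log_mu: float = 0.48
    wmhv_log_sigma: float = 1.30
    # Fazekas thresholds on jittered latent burden, calibrated so that the
    # severity rule (PWMH = 3 or DWMH >= 2) marks ~39% of subjects severe
    pwmh_cuts: tuple[float, float, float] = (-1.0, 0.0, 0.445)
    dwmh_cuts: tuple[float, float, float] = (-1.2, 0.445, 1.3)
    fazekas_jitter: float = 0.3
    burden_age_corr: float = 0.35
    follow_up_fraction: float = 123.0 / 617.0
    follow_up_duration_mean: float = 2.0
    follow_up_duration_sd: float = 0.3
    autocorr_baseline: float = 0.6
    T: int = 200
    fc_scale: float = 0.25
    fc_center: float = 0.30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.sparsity < 1.0:
            raise ValueError("sparsity must lie in (0, 1)")
        for lab, k in self.kappa.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"kappa[{lab!r}] = {k} outside [0, 1]")
        if self.network_sizes is not None and sum(self.network_sizes.values()) != self.n_roi:
            raise ValueError("network_sizes must sum to n_roi")

    def scheme(self) -> ParcellationScheme:
        return default_scheme(self.n_roi, self.network_sizes)


def mixing_weight(kappa: float) -> float:
    """Gaussian-copula mixing weight giving population Spearman = kappa."""
    return float(2.0 * np.sin(np.pi * np.clip(kappa, 0.0, 1.0) / 6.0))


def gen_sc(
    n_roi: int,
    sparsity: float,
    rng: np.random.Generator,
    symmetric: bool = True,
    min_edges: int = 3,
    lognorm_sigma: float = 1.0,
) -> np.ndarray:
    """Sparse nonnegative SC matrix with log-normal weights.

    Each off-diagonal edge is retained with probability ``1 - sparsity``
    (so ~(1 - sparsity)(n - 1) nonzero targets per profile); retained
    weights are log-normal and normalized into (0, 1]: per-row in directed
    mode (seed-based probabilities summing to <= 1), by the largest row sum
    in symmetric mode (which preserves symmetry and ranks).
    """
    if symmetric:
        iu = np.triu_indices(n_roi, k=1)
        keep = rng.random(iu[0].size) < (1.0 - sparsity)
        w = np.zeros(iu[0].size)
        w[keep] = rng.lognormal(mean=0.0, sigma=lognorm_sigma, size=int(keep.sum()))
        sc = np.zeros((n_roi, n_roi))
        sc[iu] = w
        sc = sc + sc.T
        row_sums = sc.sum(axis=1)
        sc /= row_sums.max()
    else:
        sc = np.zeros((n_roi, n_roi))
        k = int(round((1.0 - sparsity) * (n_roi - 1)))
        for i in range(n_roi):
            targets = rng.choice(
                np.delete(np.arange(n_roi), i), size=k, replace=False
            )
            sc[i, targets] = rng.lognormal(mean=0.0, sigma=lognorm_sigma, size=k)
        sc /= np.maximum(sc.sum(axis=1, keepdims=True), 1e-300)
    nonzero_per_row = (sc > 0).sum(axis=1)
    if (nonzero_per_row < min_edges).any():
        bad = int(np.argmin(nonzero_per_row))
        raise ValueError(
            f"sparsity {sparsity} left ROI {bad + 1} with "
            f"{int(nonzero_per_row[bad])} < {min_edges} nonzero edges"
        )
    return sc


def gen_fc(
    sc: np.ndarray,
    kappa: dict[str, float] | float,
    networks: list[str] | None,
    rng: np.random.Generator,
    fc_scale: float = 0.25,
    fc_center: float = 0.30,
    return_timeseries: bool = False,
    T: int = 200,
) -> tuple[np.ndarray, np.ndarray | None]:
    """FC with controllable rank agreement to a symmetric SC matrix.

    For nonzero edges, the z value mixes the normal scores of the global SC
    ranks with independent Gaussian noise (weight from :func:`mixing_weight`,
    per-edge kappa = mean of the two endpoint networks' kappas); zero-SC
    edges get pure noise.  With kappa = 1 the FC profile of every ROI is a
    strictly monotone function of its SC profile, so measured ROI coupling
    is exactly 1; with kappa = 0 the expected coupling is 0.

    When ``return_timeseries`` is set, a T x n_roi series is built by an
    exact factor construction (requires T >= n_roi + 2): the target z-matrix
    is mapped to a correlation matrix, eigen-clipped to positive definite,
    and the returned FC is recomputed from that projected matrix so that
    ``fc_from_timeseries(ts)`` reproduces it to numerical precision.
    """
    sc = np.asarray(sc, dtype=float)
    n = sc.shape[0]
    if networks is None:
        kap = np.full(n, float(kappa) if np.isscalar(kappa) else 0.5)
    else:
        if np.isscalar(kappa):
            kap = np.full(n, float(kappa))
        else:
            kap = np.array([kappa[lab] for lab in networks], dtype=float)

    iu = np.triu_indices(n, k=1)
    vals = sc[iu]
    nz = vals > 0
    g = np.zeros(vals.size)
    if nz.sum() > 0:
        ranks = stats.rankdata(vals[nz])
        g[nz] = stats.norm.ppf((ranks - 0.5) / nz.sum())
    kappa_e = (kap[iu[0]] + kap[iu[1]]) / 2.0
    w = 2.0 * np.sin(np.pi * kappa_e / 6.0)
    eps = rng.normal(size=vals.size)
    z_edges = np.where(
        nz,
        w * g + np.sqrt(np.maximum(1.0 - w**2, 0.0)) * eps,
        eps,
    )
    fc = np.zeros((n, n))
    fc[iu] = fc_center + fc_scale * z_edges
    fc = fc + fc.T

    if not return_timeseries:
        return fc, None

    if T < n + 2:
        raise ValueError(f"time-series factor construction needs T >= n_roi + 2, got T={T}")
    r = np.tanh(fc)
    np.fill_diagonal(r, 1.0)
    evals, evecs = np.linalg.eigh(r)
    evals = np.maximum(evals, 1e-4)
    r_pd = evecs @ np.diag(evals) @ evecs.T
    d = np.sqrt(np.diag(r_pd))
    r_pd = r_pd / np.outer(d, d)
    r_pd = (r_pd + r_pd.T) / 2.0
    np.fill_diagonal(r_pd, 1.0)
    fc_out = np.arctanh(np.clip(r_pd, -(1 - 1e-7), 1 - 1e-7))
    fc_out = (fc_out + fc_out.T) / 2.0
    np.fill_diagonal(fc_out, 0.0)

    Z = rng.normal(size=(T, n))
    Z -= Z.mean(axis=0)
    C = Z.T @ Z / (T - 1)
    Z = Z @ np.linalg.inv(np.linalg.cholesky(C)).T  # empirical cov = I
    ts = Z @ np.linalg.cholesky(r_pd).T  # empirical corr = r_pd exactly
    return fc_out, ts


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _residual_sd(systematic: np.ndarray) -> float:
    """Residual SD targeting unit total variance for a generated outcome."""
    v = float(np.var(systematic, ddof=1))
    if v > 0.95:
        raise ValueError(
            f"infeasible effect sizes: systematic variance {v:.3f} implies R^2 > 0.95"
        )
    return float(np.sqrt(1.0 - v))


def gen_cohort(
    config: SimulationConfig,
    with_connectomes: bool = False,
) -> tuple[pd.DataFrame, dict[str, SubjectConnectome] | None]:
    """Generate a linked cohort table (and optionally connectomes).

    The cohort table carries demographics, vascular risk flags, Fazekas
    scores and WMH volume from a shared latent burden (so severity labels
    are rule-consistent by construction), per-network coupling columns, and
    cognitive scores with the configured standardized effects.  When
    ``with_connectomes`` is set, each subject also gets an SC/FC pair whose
    target-network kappa equals that subject's coupling column, tying the
    two surfaces together (at the cost of estimation noise in measured
    coupling).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    scheme = cfg.scheme()
    nets = scheme.network_labels

    z_age = rng.normal(size=n)
    burden = cfg.burden_age_corr * z_age + np.sqrt(
        1.0 - cfg.burden_age_corr**2
    ) * rng.normal(size=n)
    age = cfg.age_mean + cfg.age_sd * z_age
    sex = np.where(rng.random(n) < cfg.female_prop, "female", "male")
    education = np.clip(
        np.round(cfg.education_mean + cfg.education_sd * rng.normal(size=n)), 0, 22
    )
    log_wmhv = cfg.wmhv_log_mu + cfg.wmhv_log_sigma * burden
    wmh_volume = np.exp(log_wmhv)

    jit = cfg.fazekas_jitter
    sp = burden + jit * rng.normal(size=n)
    sd_lat = burden + jit * rng.normal(size=n)
    pwmh = np.searchsorted(np.asarray(cfg.pwmh_cuts), sp)
    dwmh = np.searchsorted(np.asarray(cfg.dwmh_cuts), sd_lat)
    both_zero = (pwmh == 0) & (dwmh == 0)
    dwmh[both_zero] = 1  # inclusion requires Fazekas > 0

    risks = {}
    for name, prev in cfg.prevalences.items():
        if name == "hypertension":
            p = expit(logit(prev) + 0.35 * burden)
        else:
            p = np.full(n, prev)
        risks[name] = (rng.random(n) < p).astype(int)

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{k + 1:04d}" for k in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            **risks,
            "pwmh": pwmh,
            "dwmh": dwmh,
            "wmh_volume": wmh_volume,
        }
    )
    df = add_severity(df)
    mild = (df["severity"] == "mild").to_numpy()
    z_edu = _standardize(education.astype(float))

    # per-network coupling: baseline level + burden effect in the target
    # network within the mild stratum only
    for lab in nets:
        cz = rng.normal(size=n)
        if lab == cfg.target_network and mild.sum() >= 3:
            b = cfg.beta_wmh_coupling
            x_mild = _standardize(log_wmhv[mild])
            cz[mild] = b * x_mild + np.sqrt(1.0 - b**2) * rng.normal(size=int(mild.sum()))
        df[f"coupling_{lab}"] = cfg.kappa.get(lab, 0.25) + cfg.coupling_sd * cz

    # cognition (z scale, then affine to test units); coupling effect in the
    # mild stratum, direct WMH deficit in the severe stratum
    cz_t = df[f"coupling_{cfg.target_network}"].to_numpy()
    y = np.empty(n)
    for is_mild, idx in ((True, np.flatnonzero(mild)), (False, np.flatnonzero(~mild))):
        if idx.size < 3:
            y[idx] = rng.normal(size=idx.size)
            continue
        czs = _standardize(cz_t[idx])
        xs = _standardize(log_wmhv[idx])
        b_cog = cfg.beta_coupling_cognition if is_mild else 0.0
        b_wmh = 0.0 if is_mild else -0.20
        sys = b_cog * czs + b_wmh * xs - 0.15 * z_age[idx] + 0.25 * z_edu[idx]
        y[idx] = sys + _residual_sd(sys) * rng.normal(size=idx.size)
    df["digit_span_forward"] = 11.9 + 2.7 * y

    x_all = _standardize(log_wmhv)
    for col, b_wmh, loc, sdv in (("mmse", -0.11, 26.3, 3.3), ("moca", -0.07, 21.9, 4.7)):
        sys = b_wmh * x_all - 0.15 * z_age + 0.25 * z_edu
        df[col] = loc + sdv * (sys + _residual_sd(sys) * rng.normal(size=n))

    # follow-up subset with the longitudinal coupling effect (mild stratum)
    n_fu = int(round(cfg.follow_up_fraction * n))
    fu_idx = np.sort(rng.choice(n, size=n_fu, replace=False))
    fu = np.zeros(n, dtype=bool)
    fu[fu_idx] = True
    duration = np.full(n, np.nan)
    duration[fu] = np.clip(
        rng.normal(cfg.follow_up_duration_mean, cfg.follow_up_duration_sd, size=n_fu),
        0.5,
        None,
    )
    y_fu = np.full(n, np.nan)
    for is_mild in (True, False):
        idx = np.flatnonzero(fu & (mild == is_mild))
        if idx.size < 3:
            if idx.size:
                y_fu[idx] = rng.normal(size=idx.size)
            continue
        czs = _standardize(cz_t[idx])
        b_long = cfg.beta_longitudinal if is_mild else 0.0
        sys = (
            cfg.autocorr_baseline * _standardize(y[idx])
            + b_long * czs
            - 0.05 * _standardize(duration[idx])
        )
        y_fu[idx] = sys + _residual_sd(sys) * rng.normal(size=idx.size)
    df["digit_span_forward_fu"] = 11.9 + 2.7 * y_fu
    df["follow_up_duration"] = duration

    connectomes = None
    if with_connectomes:
        connectomes = {}
        for k in range(n):
            srng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.seed) % (2**31), k])
            )
            sc = gen_sc(cfg.n_roi, cfg.sparsity, srng, symmetric=True)
            subj_kappa = {
                lab: float(np.clip(df.at[k, f"coupling_{lab}"], 0.0, 1.0))
                for lab in nets
            }
            fc, _ = gen_fc(
                sc,
                subj_kappa,
                list(scheme.networks),
                srng,
                fc_scale=cfg.fc_scale,
                fc_center=cfg.fc_center,
            )
            sid = df.at[k, "subject_id"]
            connectomes[sid] = SubjectConnectome(sid, sc=sc, fc=fc).validate(scheme)
    return df, connectomes


def coupling_long(table: pd.DataFrame, networks: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Reshape a cohort table's ``coupling_*`` columns into the long format
    produced by :func:`sfcoupling.cohort_coupling`."""
    cols = [c for c in table.columns if c.startswith("coupling_")]
    if networks is not None:
        cols = [f"coupling_{lab}" for lab in networks]
    long = table.melt(
        id_vars=["subject_id"],
        value_vars=cols,
        var_name="network",
        value_name="rho",
    )
    long["network"] = long["network"].str.removeprefix("coupling_")
    long["n_rois_defined"] = -1  # not applicable for table-level coupling
    return long.sort_values(["subject_id", "network"], kind="stable").reset_index(
        drop=True
    )


def null_config(seed: int, **overrides) -> SimulationConfig:
    """Config with every generating effect set to zero (null calibration)."""
    return dataclasses.replace(
        SimulationConfig(seed=seed),
        beta_wmh_coupling=0.0,
        beta_coupling_cognition=0.0,
        beta_longitudinal=0.0,
        **overrides,
    )
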