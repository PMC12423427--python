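"""End-to-end orchestration: severity split, per-stratum association
batteries, across-network ANOVA, quartile ROC, cohort summary, manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import (
    AssociationResult,
    add_severity,
    apply_fdr,
    compare_groups,
    covariate_sets,
    linear_assoc,
    rm_anova_networks,
    zscore_battery,
)
from .prognosis import longitudinal_assoc, quartile_labels, roc_analysis

STRATA = ("all", "mild", "severe")

#: cognitive test columns entered into the cross-sectional battery when present
DEFAULT_TESTS = ("digit_span_forward", "mmse", "moca")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Reproducibility record emitted next to every result bundle."""

    config_hash: str
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    version: str = "0.1.0"
    timestamp: str = ""

    @staticmethod
    def from_config(config: dict, seeds: dict | None = None, inputs: dict | None = None) -> "RunManifest":
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        digests = {}
        for name, path in (inputs or {}).items():
            digests[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        return RunManifest(
            config_hash=hashlib.sha256(blob).hexdigest(),
            seeds=dict(seeds or {}),
            input_digests=digests,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )


def _stratum_table(table: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return table
    sub = table[table["severity"] == stratum]
    if sub.empty:
        raise PipelineError(f"stratum {stratum!r} is empty")
    return sub


def _assoc_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dataclasses.asdict(r)
        row["covariates"] = ";".join(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(table: pd.DataFrame, tests: tuple[str, ...] = DEFAULT_TESTS) -> pd.DataFrame:
    """Table-1-style per-stratum summary with between-stratum p values.

    Percentages are always recomputed from counts, never stored; binary
    variables report ``n (%)`` and continuous ones ``mean (SD)``.
    """
    table = table if "severity" in table.columns else add_severity(table)
    binaries = ["hypertension", "diabetes", "hypercholesterolemia", "smoking", "drinking"]
    continuous = ["age", "education", "wmh_volume"] + [
        t for t in tests if t in table.columns
    ]
    variables = (
        ["sex_female"]
        + [b for b in binaries if b in table.columns]
        + [c for c in continuous if c in table.columns]
    )
    work = table.copy()
    work["sex_female"] = (work["sex"] == "female").astype(int)
    comp = compare_groups(work, variables).set_index("variable")["p"]

    rows = []
    for stratum in STRATA:
        sub = work if stratum == "all" else work[work["severity"] == stratum]
        n = len(sub)
        row: dict = {"stratum": stratum, "n": n}
        row["pct_of_cohort"] = 100.0 * n / len(work) if len(work) else 0.0
        for var in variables:
            if n == 0:
                row[var] = ""
                continue
            x = sub[var].dropna()
            if var == "sex_female" or var in binaries:
                cnt = int(x.sum())
                row[var] = f"{cnt} ({100.0 * cnt / len(x):.1f}%)" if len(x) else "0"
            else:
                row[var] = f"{x.mean():.2f} ({x.std(ddof=1):.2f})"
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.set_index("stratum")
    for var in variables:
        out.loc["all", f"p_{var}"] = comp[var]
    return out.reset_index()


def run_pipeline(
    cohort: pd.DataFrame,
    coupling: pd.DataFrame,
    target_network: str = "FPN",
    tests: tuple[str, ...] = DEFAULT_TESTS,
    wmh_transform: str = "log",
    sens_floor: float = 0.90,
    out_dir: str | Path | None = None,
    config: dict | None = None,
) -> dict:
    """Run the full cross-sectional and longitudinal battery.

    ``coupling`` is the long table (subject_id, network, rho, ...).  WMH
    volume enters regressions log-transformed by default (its distribution
    is strongly right-skewed); pass ``wmh_transform='raw'`` for untransformed
    mL.  Returns a dict of DataFrames/result objects; when ``out_dir`` is
    given, tidy CSVs and a manifest are written there.
    """
    stage = "validate"
    try:
        cohort = cohort if "severity" in cohort.columns else add_severity(cohort)
        for stratum in ("mild", "severe"):
            if not (cohort["severity"] == stratum).any():
                raise PipelineError(f"stratum {stratum!r} is empty")
        n_input = len(cohort)
        wide = coupling.pivot(index="subject_id", columns="network", values="rho")
        networks = list(wide.columns)
        if target_network not in networks:
            raise ValueError(f"target network {target_network!r} not in coupling table")
        data = cohort.merge(
            wide.add_prefix("net_").reset_index(), on="subject_id", how="inner"
        )
        dropped = n_input - len(data)
        if data.empty:
            raise ValueError("no subjects shared between cohort and coupling tables")
        if wmh_transform == "log":
            data["wmh_predictor"] = np.log(data["wmh_volume"])
        elif wmh_transform == "raw":
            data["wmh_predictor"] = data["wmh_volume"]
        else:
            raise ValueError(f"unknown wmh_transform {wmh_transform!r}")

        stage = "summary"
        summary = summarize_cohort(data, tests)

        stage = "rm_anova"
        complete = data[[f"net_{lab}" for lab in networks]].dropna()
        anova = rm_anova_networks(
            complete.rename(columns=lambda c: c.removeprefix("net_"))
        )

        stage = "wmhv_coupling"
        wmhv_results: list[AssociationResult] = []
        covs = covariate_sets("wmh_coupling")
        for stratum in STRATA:
            sub = _stratum_table(data, stratum)
            for lab in networks:
                wmhv_results.append(
                    linear_assoc(sub, f"net_{lab}", "wmh_predictor", covs, stratum)
                )
        apply_fdr(wmhv_results)

        stage = "coupling_cognition"
        cog_results: list[AssociationResult] = []
        covs_cog = covariate_sets("coupling_cognition")
        present_tests = [t for t in tests if t in data.columns]
        zdata = zscore_battery(data, present_tests)
        for test in present_tests:
            fam: list[AssociationResult] = []
            for stratum in STRATA:
                sub = _stratum_table(zdata, stratum)
                for lab in networks:
                    fam.append(linear_assoc(sub, test, f"net_{lab}", covs_cog, stratum))
            apply_fdr(fam)
            cog_results.extend(fam)

        stage = "longitudinal"
        long_results: list[AssociationResult] = []
        fu_col = "digit_span_forward_fu"
        roc = None
        if fu_col in data.columns and data[fu_col].notna().any():
            for stratum in STRATA:
                sub = _stratum_table(data, stratum)
                if sub[fu_col].notna().sum() >= 10:
                    long_results.append(
                        longitudinal_assoc(
                            sub,
                            fu_col,
                            f"net_{target_network}",
                            "digit_span_forward",
                            stratum,
                        )
                    )
            apply_fdr(long_results)

            stage = "roc"
            mild_fu = data[(data["severity"] == "mild") & data[fu_col].notna()]
            if len(mild_fu) >= 8:
                labels = quartile_labels(mild_fu[fu_col].to_numpy())
                roc = roc_analysis(
                    mild_fu[f"net_{target_network}"].to_numpy(),
                    labels,
                    sens_floor=sens_floor,
                )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest.from_config(
        {
            "target_network": target_network,
            "tests": list(tests),
            "wmh_transform": wmh_transform,
            "sens_floor": sens_floor,
            **(config or {}),
        }
    )
    bundle = {
        "summary": summary,
        "anova": anova,
        "wmhv_coupling": _assoc_to_frame(wmhv_results),
        "coupling_cognition": _assoc_to_frame(cog_results),
        "longitudinal": _assoc_to_frame(long_results) if long_results else pd.DataFrame(),
        "roc": roc,
        "manifest": manifest,
        "n_input": n_input,
        "n_analyzed": len(data),
        "n_dropped_no_coupling": dropped,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        bundle["wmhv_coupling"].to_csv(out / "associations.csv", index=False)
        bundle["coupling_cognition"].to_csv(out / "cognition.csv", index=False)
        if long_results:
            bundle["longitudinal"].to_csv(out / "longitudinal.csv", index=False)
        pd.DataFrame(
            [
                {
                    "F": anova.F,
                    "df1": anova.df1,
                    "df2": anova.df2,
                    "epsilon": anova.epsilon,
                    "p": anova.p,
                }
            ]
        ).to_csv(out / "anova.csv", index=False)
        anova.posthoc.to_csv(out / "anova_posthoc.csv", index=False)
        if roc is not None:
            pd.DataFrame([
                {
                    "auc": roc.auc,
                    "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high,
                    "cutoff": roc.cutoff,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "n_pos": roc.n_pos,
                    "n_neg": roc.n_neg,
                }
            ]).to_csv(out / "roc.csv", index=False)
            roc.curve.to_csv(out / "roc_curve.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2)
        )
    return bundle
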