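"""Orchestration: subject-level ALPS computation and the cohort analysis.

``run_subject`` chains image loading, tensor fitting and ROI extraction
into one QC-flagged row per subject. ``run_cohort`` reproduces the
four-table cohort analysis: univariate group comparisons, backward
stepwise logistic regression for cognitive impairment with odds ratios,
ROC curves (combined model, WML alone, ALPS alone), and adjusted linear
models for all seven cognitive scores with variance inflation factors.

Single-predictor ROC curves use the raw predictor as score; the combined
model uses the fitted logistic probability. Every emitted table carries
its analysed n, and a provenance log records each operation call.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alps import AlpsMeasurement, AlpsRoi, compute_alps
from .dwi_io import load_dwi
from .stats import (
    LinearFit,
    LogisticFit,
    RocCurve,
    StatsError,
    StepwiseTrace,
    backward_stepwise,
    chi_square,
    linear_fit,
    logistic_fit,
    mann_whitney,
    roc_auc,
)
from .tensor import fit_tensor_volume

logger = logging.getLogger("dtialps")

__all__ = ["RoiConfig", "CohortReport", "run_subject", "run_cohort", "write_report"]

#: predictors adjusted for in the vascular-risk linear models
VASCULAR_SET = ["age", "education", "hypertension", "diabetes", "smoking", "alcohol"]
#: predictors adjusted for in the imaging-marker linear models
IMAGING_SET = ["wml_sum", "lacunes", "pvs_moderate_severe", "cmbs"]
#: candidate terms of the stepwise model for cognitive impairment
STEPWISE_CANDIDATES = [
    "alps_index", "wml_sum", "age", "education", "hypertension", "diabetes",
    "smoking", "alcohol", "lacunes", "cmbs", "pvs_moderate_severe",
]
COGNITIVE_SCORES = ["moca", "tmt_b_a", "avlt_sum", "sdmt", "vft", "bnt", "rcft_c"]
CONTINUOUS_TABLE1 = ["age", "education", "lacunes", "cmbs", "alps_index"] + COGNITIVE_SCORES
BINARY_TABLE1 = ["male", "hypertension", "diabetes", "smoking", "alcohol",
                 "pvs_moderate_severe"]


@dataclass(frozen=True)
class RoiConfig:
    """World-mm ROI placement for the ALPS computation."""

    projection_center_mm: tuple[float, float, float]
    association_center_mm: tuple[float, float, float]
    diameter_mm: float = 5.0
    min_fa: float = 0.2
    min_fraction: float = 0.5


def run_subject(
    subject_id: str,
    image_path,
    bval_path,
    bvec_path,
    roi: RoiConfig,
) -> dict:
    """Compute one subject's ALPS row: load -> fit tensors -> ROI means.

    Deterministic: rerunning on the same inputs yields an identical row.
    """
    volume, table = load_dwi(image_path, bval_path, bvec_path)
    maps = fit_tensor_volume(volume, table)
    meas: AlpsMeasurement = compute_alps(
        maps,
        AlpsRoi(roi.projection_center_mm, "projection", roi.diameter_mm),
        AlpsRoi(roi.association_center_mm, "association", roi.diameter_mm),
        min_fa=roi.min_fa,
        min_fraction=roi.min_fraction,
    )
    return {
        "subject_id": subject_id,
        "Dxproj": meas.dx_proj,
        "Dyproj": meas.dy_proj,
        "Dxassoc": meas.dx_assoc,
        "Dzassoc": meas.dz_assoc,
        "alps_index": meas.alps_index,
        "n_voxels_proj": meas.n_voxels_proj,
        "n_voxels_assoc": meas.n_voxels_assoc,
        "qc_projection_ok": meas.qc["projection"].passed,
        "qc_association_ok": meas.qc["association"].passed,
    }


def run_subjects(subject_inputs: list[dict], roi: RoiConfig) -> pd.DataFrame:
    """Batch subject processing; failures are logged and skipped so one
    corrupt input does not abort the run."""
    rows, failures = [], []
    for inp in subject_inputs:
        sid = inp["subject_id"]
        try:
            rows.append(run_subject(sid, inp["image"], inp["bval"], inp["bvec"], roi))
        except Exception as exc:  # noqa: BLE001 -- per-subject isolation
            logger.error("subject %s failed: %s", sid, exc)
            failures.append({"subject_id": sid, "error": str(exc)})
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    return df


@dataclass
class CohortReport:
    """Bundle of the four cohort-level result tables plus ROC curves."""

    table1: pd.DataFrame
    stepwise_fit: LogisticFit
    stepwise_trace: StepwiseTrace
    table2: pd.DataFrame
    roc: dict[str, RocCurve]
    table3: dict[str, LinearFit]
    table4: dict[str, LinearFit]
    provenance: list = field(default_factory=list)


def _table1(df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Univariate CN-vs-CI comparisons: Mann–Whitney for continuous
    variables, chi-square (with automatic continuity correction) for
    binary ones, and a 4x2 chi-square over WML categories."""
    cn = df[df.group == "CN"]
    ci = df[df.group == "CI"]
    rows, prov = [], []
    for var in CONTINUOUS_TABLE1:
        res = mann_whitney(cn[var], ci[var], variable=var)
        n = res.summaries["n"]
        rows.append({
            "variable": var, "test": res.test,
            "cn_summary": f"{res.summaries['mean'][0]:.2f} ± {res.summaries['sd'][0]:.3f}",
            "ci_summary": f"{res.summaries['mean'][1]:.2f} ± {res.summaries['sd'][1]:.3f}",
            "n_cn": n[0], "n_ci": n[1], "p": res.p_value,
        })
        prov.append(("mann_whitney", var, n))
    for var in BINARY_TABLE1:
        sub = df[[var, "group"]].dropna()
        counts = pd.crosstab(sub[var], sub["group"]).reindex(
            index=[0, 1], columns=["CN", "CI"], fill_value=0
        )
        res = chi_square(counts.to_numpy(), variable=var)
        n = res.summaries["n"]
        pct = res.summaries["percent"]
        rows.append({
            "variable": var, "test": res.test,
            "cn_summary": f"{counts.iloc[1, 0]} ({pct[1][0]:.1f}%)",
            "ci_summary": f"{counts.iloc[1, 1]} ({pct[1][1]:.1f}%)",
            "n_cn": n[0], "n_ci": n[1], "p": res.p_value,
        })
        prov.append((res.test, var, n))
    wml = pd.crosstab(df["wml_sum"], df["group"]).reindex(
        index=[3, 4, 5, 6], columns=["CN", "CI"], fill_value=0
    )
    res = chi_square(wml.to_numpy(), variable="wml_sum")
    rows.append({
        "variable": "wml_sum (3/4/5/6)", "test": res.test,
        "cn_summary": "/".join(str(v) for v in wml["CN"]),
        "ci_summary": "/".join(str(v) for v in wml["CI"]),
        "n_cn": int(wml["CN"].sum()), "n_ci": int(wml["CI"].sum()),
        "p": res.p_value,
    })
    prov.append((res.test, "wml_sum", res.summaries["n"]))
    return pd.DataFrame(rows), prov


def run_cohort(
    df: pd.DataFrame,
    alpha_remove: float = 0.10,
    candidates: list[str] | None = None,
) -> CohortReport:
    """Run the full cohort analysis on a clinical table.

    ``df`` must contain the clinical column dictionary columns (group,
    ALPS index, markers, scores). Raises on missing columns or fewer than
    two subjects per group.
    """
    candidates = candidates or STEPWISE_CANDIDATES
    required = set(candidates) | {"group", "alps_index", "wml_sum"} | set(COGNITIVE_SCORES)
    missing = sorted(required - set(df.columns))
    if missing:
        raise StatsError(f"missing required columns: {', '.join(missing)}")
    counts = df["group"].value_counts()
    if counts.get("CN", 0) < 2 or counts.get("CI", 0) < 2:
        raise StatsError("need at least two subjects per group")
    prov: list = []

    table1, p1 = _table1(df)
    prov += p1

    y = (df["group"] == "CI").astype(float)
    fit, trace = backward_stepwise(df[candidates], y, alpha_remove=alpha_remove)
    prov.append(("backward_stepwise", tuple(fit.terms), fit.n_obs))
    table2 = fit.summary_frame() if fit.terms else pd.DataFrame()

    # ROC: combined fitted probability vs single raw predictors
    roc: dict[str, RocCurve] = {}
    if fit.terms:
        x = df[list(fit.terms)].dropna()
        yy = y.loc[x.index]
        refit = logistic_fit(x, yy)
        lin = refit.coef[0] + x.to_numpy() @ refit.coef[1:]
        prob = 1.0 / (1.0 + np.exp(-lin))
        roc["combined"] = roc_auc(prob, yy, direction="higher")
        prov.append(("roc_auc", "combined", len(yy)))
    for name, col in (("wml", "wml_sum"), ("alps", "alps_index")):
        sub = df[[col]].join(y.rename("y")).dropna()
        roc[name] = roc_auc(sub[col], sub["y"], direction="auto")
        logger.info("ROC %s: direction=%s auc=%.3f", name, roc[name].direction, roc[name].auc)
        prov.append(("roc_auc", name, len(sub)))

    table3, table4 = {}, {}
    for score in COGNITIVE_SCORES:
        design3 = df[["alps_index"] + VASCULAR_SET]
        table3[score] = linear_fit(design3, df[score])
        prov.append(("linear_fit", (score, "vascular"), table3[score].n_obs))
        design4 = df[["alps_index"] + IMAGING_SET]
        table4[score] = linear_fit(design4, df[score])
        prov.append(("linear_fit", (score, "imaging"), table4[score].n_obs))

    return CohortReport(
        table1=table1,
        stepwise_fit=fit,
        stepwise_trace=trace,
        table2=table2,
        roc=roc,
        table3=table3,
        table4=table4,
        provenance=prov,
    )


def write_report(report: CohortReport, out_dir) -> dict[str, str]:
    """Write the report bundle as delimited text plus a JSON sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _save(name: str, frame: pd.DataFrame):
        p = os.path.join(out_dir, name)
        frame.to_csv(p, sep="\t", index=True)
        paths[name] = p

    _save("table1_group_comparison.tsv", report.table1.set_index("variable"))
    if not report.table2.empty:
        _save("table2_stepwise_logistic.tsv", report.table2)
    for label, fits in (("table3_vascular", report.table3), ("table4_imaging", report.table4)):
        frames = []
        for score, fit in fits.items():
            f = fit.summary_frame()
            f.insert(0, "score", score)
            f.insert(1, "n", fit.n_obs)
            frames.append(f)
        _save(f"{label}_adjusted_linear.tsv", pd.concat(frames))
    roc_rows = {
        name: {"auc": rc.auc, "direction": rc.direction, "n_points": len(rc.fpr)}
        for name, rc in report.roc.items()
    }
    sidecar = {
        "auroc": roc_rows,
        "stepwise_removals": [
            {"term": t, "p": p} for t, p in report.stepwise_trace.removals
        ],
        "stepwise_final_terms": list(report.stepwise_fit.terms),
        "stepwise_n": report.stepwise_fit.n_obs,
        "provenance": [
            {"op": op, "target": str(tgt), "n": str(n)} for op, tgt, n in report.provenance
        ],
    }
    p = os.path.join(out_dir, "report.json")
    with open(p, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    paths["report.json"] = p
    return paths
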