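"""End-to-end flows: phantom/scan quantification and cohort statistics.

`run_quantification` maps a set of CT volumes (NIfTI) with per-scan sidecar
metadata (manual carina slice, radiologist PPFE-presence flag) to one
CPPFEResult row per scan; individual failures are logged and do not stop
the run. `run_cohort_analysis` composes the visual-score, FVC-decline and
survival modules into a single report bundle stamped with the configuration
hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .fvc import (apply_cohort_eligibility, apply_fvc_eligibility,
                  decline_table, fit_fvc_lme, regress_decline)
from .quantify import CPPFEParams, compute_cppfe, gate_by_radiologist
from .roc import compare_auc_delong, roc_auc
from .segmentation import SegmentationError, detect_carina, segment_lungs, upper_zone
from .survival import cindex_bootstrap, confusion_at_horizon, fit_cox, km_analysis
from .volume import CTVolume

COX_ADJUSTMENTS = ["age", "male", "ever_smoker", "antifibrotic", "dlco_ppred"]


@dataclass
class PipelineConfig:
    cppfe_params: CPPFEParams = field(default_factory=CPPFEParams)
    horizon_years: float = 2.0
    bootstrap_iterations: int = 500
    seed: int = 0
    cohort_mode: str = "derivation"  # derivation | validation | combined

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_quantification(scans: list[dict],
                       config: PipelineConfig | None = None) -> pd.DataFrame:
    """Quantify cPPFE for each scan record.

    Each record needs: scan_id; either volume (CTVolume) or volume_path
    (NIfTI); vppfe_present (bool); optionally carina_slice (manual).
    Failed scans get status="error" rows; the run continues.
    """
    if not scans:
        raise ValueError("empty input set")
    config = config or PipelineConfig()
    rows = []
    for rec in scans:
        sid = rec.get("scan_id", "?")
        try:
            vol = rec.get("volume")
            if vol is None:
                vol = CTVolume.from_nifti(rec["volume_path"])
            mask = segment_lungs(vol)
            carina = detect_carina(vol, manual_override=rec.get("carina_slice"))
            zone = upper_zone(mask, carina)
            res = compute_cppfe(vol, mask, zone, config.cppfe_params)
            res = gate_by_radiologist(res, bool(rec["vppfe_present"]))
            rows.append(
                {
                    "scan_id": sid,
                    "status": "ok",
                    "carina_slice": carina,
                    "shell_voxels": res.shell_voxels_total["pooled"],
                    "dense_voxels": res.shell_voxels_dense["pooled"],
                    "cppfe_percent": res.cppfe_percent,
                    "gated_percent": res.gated_percent,
                    "dichotomised": res.dichotomised,
                    "error": "",
                }
            )
        except (SegmentationError, ValueError, KeyError, OSError) as exc:
            rows.append(
                {"scan_id": sid, "status": "error", "carina_slice": None,
                 "shell_voxels": None, "dense_voxels": None,
                 "cppfe_percent": None, "gated_percent": None,
                 "dichotomised": None, "error": str(exc)}
            )
    out = pd.DataFrame(rows)
    out.attrs["config_hash"] = config.config_hash()
    return out


def _with_ppfe_dummies(subjects: pd.DataFrame) -> pd.DataFrame:
    df = subjects.copy()
    df["moderate_vppfe"] = (df["ppfe_category"] == "moderate").astype(int)
    df["marked_vppfe"] = (df["ppfe_category"] == "marked").astype(int)
    df["vppfe_presence"] = (df["ppfe_category"] != "absent").astype(int)
    if "cppfe_ge_cutpoint" not in df.columns and "cppfe_percent" in df.columns:
        df["cppfe_ge_cutpoint"] = (df["cppfe_percent"] >= 2.5).astype(int)
    return df


def run_cohort_analysis(subjects: pd.DataFrame, fvc_long: pd.DataFrame,
                        survival: pd.DataFrame,
                        config: PipelineConfig | None = None) -> dict:
    """Full statistical report bundle on a cohort.

    Sections: exclusion logs, decline regressions (visual categories,
    continuous and dichotomised cPPFE), multivariable Cox tables with
    C-index bootstrap, KM summaries, fixed-horizon confusion metrics, and
    the paired AUC comparison of the continuous computerised score against
    the 7-point visual score.
    """
    config = config or PipelineConfig()
    for col in ("subject_id", "ppfe_category"):
        if col not in subjects.columns:
            raise ValueError(f"subjects table lacks required column {col}")
    subjects = _with_ppfe_dummies(subjects)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_input_subjects": len(subjects),
    }

    subjects_ok, cohort_log = apply_cohort_eligibility(subjects, require_dlco=True)
    fvc_ok, fvc_log = apply_fvc_eligibility(
        fvc_long[fvc_long["subject_id"].isin(subjects_ok["subject_id"])]
    )
    report["exclusions"] = {"cohort": cohort_log, "fvc": fvc_log}

    # --- LME decline stage ---
    fit = fit_fvc_lme(fvc_ok, subjects_ok)
    declines = decline_table(fit)
    report["n_decline_subjects"] = len(declines)
    decline_models = {}
    mode = "validation" if config.cohort_mode == "validation" else "derivation"
    for label, terms in (
        ("vppfe_category", ["moderate_vppfe", "marked_vppfe"]),
        ("vppfe_presence", ["vppfe_presence"]),
        ("cppfe_continuous", ["cppfe_percent"]),
        ("cppfe_dichotomised", ["cppfe_ge_cutpoint"]),
    ):
        try:
            rep = regress_decline(declines, subjects_ok, terms, mode=mode)
            decline_models[label] = {
                "table": rep.table.to_dict(orient="records"),
                "r_squared": rep.r_squared,
                "breusch_pagan_p": rep.breusch_pagan_p,
                "n": rep.n,
            }
        except (ValueError, KeyError) as exc:
            decline_models[label] = {"inestimable": str(exc)}
    report["decline_models"] = decline_models

    # --- survival stage ---
    surv = subjects_ok.merge(survival, on="subject_id", how="inner")
    frailty = "centre" if config.cohort_mode in ("validation", "combined") else None
    cox_models = {}
    for label, terms in (
        ("vppfe_category", ["moderate_vppfe", "marked_vppfe"]),
        ("cppfe_dichotomised", ["cppfe_ge_cutpoint"]),
    ):
        covs = terms + COX_ADJUSTMENTS
        try:
            rep = fit_cox(surv, covs, frailty_group=frailty)
            boot = cindex_bootstrap(surv, covs,
                                    iterations=config.bootstrap_iterations,
                                    seed=config.seed)
            cox_models[label] = {
                "table": rep.table.to_dict(orient="records"),
                "c_index": rep.c_index,
                "c_index_bootstrap": boot,
                "schoenfeld_global_p": rep.schoenfeld_global_p,
                "frailty_variance": rep.frailty_variance,
            }
        except (ValueError, RuntimeError) as exc:
            cox_models[label] = {"inestimable": str(exc)}
    report["cox_models"] = cox_models

    # --- KM / classification stage ---
    surv["cppfe_group"] = np.select(
        [surv["ppfe_category"] == "absent", surv["cppfe_ge_cutpoint"] == 1],
        ["no PPFE", "cPPFE >= 2.5%"], default="cPPFE < 2.5%",
    )
    km_sections = {}
    for label, col in (("vppfe", "ppfe_category"), ("cppfe", "cppfe_group")):
        km = km_analysis(surv, col)
        km_sections[label] = {
            "groups": [vars(g) for g in km.groups],
            "logrank_p": km.logrank_p,
        }
    report["km"] = km_sections

    conf = {}
    surv["marked_flag"] = surv["marked_vppfe"].astype(bool)
    surv["cppfe_flag"] = surv["cppfe_ge_cutpoint"].astype(bool)
    for label, col in (("cppfe_ge_cutpoint", "cppfe_flag"),
                       ("marked_vppfe", "marked_flag")):
        cm = confusion_at_horizon(surv, col, horizon=config.horizon_years)
        conf[label] = cm.to_dict()
    report["confusion_2y"] = conf

    outcome = ((surv["event"] == 1) &
               (surv["time_years"] < config.horizon_years)).astype(int)
    usable = (outcome == 1) | (surv["time_years"] >= config.horizon_years)
    if "vppfe_seven_point" in surv.columns and usable.sum() > 2:
        o = outcome[usable].to_numpy()
        if o.min() != o.max():
            cont = roc_auc(surv.loc[usable, "cppfe_percent"], o)
            seven = roc_auc(surv.loc[usable, "vppfe_seven_point"], o)
            comp = compare_auc_delong(surv.loc[usable, "cppfe_percent"],
                                      surv.loc[usable, "vppfe_seven_point"], o)
            report["auc_2y"] = {
                "cppfe_continuous": vars(cont),
                "vppfe_seven_point": vars(seven),
                "comparison": vars(comp),
            }
    return report
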