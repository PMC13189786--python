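"""End-to-end orchestration: load -> QC -> MCA screen -> clustering comparison
-> selection -> Firth -> resampling validation -> subgroup risk differences,
plus the MP-exclusion sensitivity rerun.

All randomness is fanned out from a single master seed by stable hashing of
(master seed, stage name), so a stage keeps its stream when other stages are
toggled, and a full rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, DataDictionary, load_cohort
from .clusters import average_silhouette, gower_dissimilarity, hierarchical_fit, kmodes_fit
from .firth import DesignSpec, build_design, firth_fit, vif, wald_summary
from .lca import (
    LCAFit,
    bootstrap_lrt,
    fit_lca,
    information_criteria,
    lmr_adjusted_test,
    name_patterns,
    relative_entropy,
)
from .mca import fit_mca, screen_features
from .resampling import rare_event_bootstrap, stratified_kfold_cv
from .riskdiff import default_profiles, risk_difference_table
from .selection import Candidate, SelectionReport, SelectionRules, select_solution

__all__ = ["PipelineConfig", "run_pipeline", "sensitivity_rerun", "stage_seed", "report_hash", "validate_report"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of (master seed, stage name), below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Tunable knobs of the full analysis run."""

    seed: int = 0
    lca_classes: tuple[int, ...] = (1, 2, 3, 4, 5)
    cluster_ks: tuple[int, ...] = (2, 3, 4, 5)
    n_starts: int = 50
    em_tol: float = 1e-8
    em_max_iter: int = 5000
    blrt_B: int = 99
    bootstrap_B: int = 10_000
    cv_k: int = 10
    rd_B: int = 10_000
    mca_n_dims: int = 5
    mca_threshold_pct: float = 2.0
    mca_force_keep: tuple[str, ...] = ()
    rules: SelectionRules = field(default_factory=SelectionRules)
    pattern_anchor: str = "angular_margins"
    run_bootstrap: bool = True
    run_cv: bool = True
    run_risk_differences: bool = True
    run_blrt: bool = True
    fast: bool = False

    def __post_init__(self) -> None:
        if self.fast:
            self.n_starts = min(self.n_starts, 10)
            self.blrt_B = min(self.blrt_B, 39)  # keeps the attainable p floor (1/(B+1)) under alpha
            self.bootstrap_B = min(self.bootstrap_B, 500)
            self.rd_B = min(self.rd_B, 200)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        rules = SelectionRules(**doc.pop("rules", {}))
        for key in ("lca_classes", "cluster_ks", "mca_force_keep"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(rules=rules, **doc)


def _anchor_pattern_b(
    labels: np.ndarray, cohort: Cohort, anchor: str, fit: LCAFit | None = None
) -> tuple[np.ndarray, dict]:
    """0/1 pattern-B indicator for a two-group labeling.

    Pattern A is the group with the higher prevalence of the anchor feature
    (model-based prevalence for an LCA fit, empirical otherwise).
    """
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("pattern naming needs exactly two groups")
    if fit is not None and fit.n_classes == 2:
        naming = name_patterns(fit, cohort.feature_names, anchor=anchor)
        mapping = {groups[i]: naming[i] for i in range(2)}
    else:
        x = cohort.data[anchor].to_numpy()
        prev = [float(np.mean(x[labels == g] == 1)) for g in groups]
        a = int(np.argmax(prev))
        mapping = {groups[a]: "A", groups[1 - a]: "B"}
    pattern_b = np.array([1 if mapping[g] == "B" else 0 for g in labels])
    return pattern_b, {str(k): v for k, v in mapping.items()}


def _lca_stage(cohort: Cohort, cfg: PipelineConfig, base_seed: int) -> tuple[dict, dict[int, LCAFit], list[dict]]:
    fits: dict[int, LCAFit] = {}
    rows = []
    for C in cfg.lca_classes:
        fits[C] = fit_lca(
            cohort.features,
            C,
            n_starts=cfg.n_starts,
            tol=cfg.em_tol,
            max_iter=cfg.em_max_iter,
            seed=stage_seed(base_seed, f"lca_C{C}"),
        )
    N = cohort.n
    for C in cfg.lca_classes:
        fit = fits[C]
        aic, bic, abic = information_criteria(-2.0 * fit.log_likelihood, fit.n_params, N)
        ent = relative_entropy(fit.posteriors) if C >= 2 else None
        lmrt_p = (
            lmr_adjusted_test(fit, fits[C - 1], N) if C >= 2 and (C - 1) in fits else None
        )
        blrt_p = (
            bootstrap_lrt(
                cohort.features,
                C,
                B=cfg.blrt_B,
                seed=stage_seed(base_seed, f"blrt_C{C}"),
            )
            if cfg.run_blrt and C >= 2
            else None
        )
        rows.append(
            {
                "classes": C,
                "log_likelihood": fit.log_likelihood,
                "n_params": fit.n_params,
                "aic": aic,
                "bic": bic,
                "abic": abic,
                "entropy": ent,
                "lmrt_p": lmrt_p,
                "blrt_p": blrt_p,
                "converged": fit.converged,
            }
        )
    return {"fit_table": rows}, fits, rows


def _candidates(
    cohort: Cohort,
    fits: dict[int, LCAFit],
    fit_rows: list[dict],
    cfg: PipelineConfig,
    base_seed: int,
) -> list[Candidate]:
    from .selection import external_validity_test

    y = cohort.outcome
    out: list[Candidate] = []
    by_C = {r["classes"]: r for r in fit_rows}
    for C, fit in fits.items():
        labels = fit.modal_assignment
        shares = np.bincount(labels, minlength=C) / cohort.n
        ext = external_validity_test(labels, y) if C >= 2 else (None, None, None)
        r = by_C[C]
        out.append(
            Candidate(
                method="lca",
                k=C,
                class_shares=shares,
                external_stat=ext[0],
                external_p=ext[2],
                bic=r["bic"],
                entropy=r["entropy"],
                lmrt_p=r["lmrt_p"],
                blrt_p=r["blrt_p"],
                labels=labels,
            )
        )
    dissim = gower_dissimilarity(cohort.features)
    for k in cfg.cluster_ks:
        km = kmodes_fit(cohort.features, k, seed=stage_seed(base_seed, f"kmodes_k{k}"))
        km.silhouette = average_silhouette(km.labels, dissim)
        stat, _, p = external_validity_test(km.labels, y)
        out.append(
            Candidate(
                method="kmodes",
                k=k,
                class_shares=km.shares(),
                external_stat=stat,
                external_p=p,
                silhouette=km.silhouette,
                labels=km.labels,
            )
        )
        hc = hierarchical_fit(dissim, k)
        hc.silhouette = average_silhouette(hc.labels, dissim)
        stat, _, p = external_validity_test(hc.labels, y)
        out.append(
            Candidate(
                method="hierarchical",
                k=k,
                class_shares=hc.shares(),
                external_stat=stat,
                external_p=p,
                silhouette=hc.silhouette,
                labels=hc.labels,
            )
        )
    return out


def _class_profile(fit: LCAFit, cohort: Cohort, naming: dict) -> dict:
    """Per-feature, per-pattern category probabilities (profile-plot data)."""
    inv = {v: int(k) for k, v in naming.items()}
    profile = {}
    for j, name in enumerate(cohort.feature_names):
        m = fit.rho_feature(j)  # C x K
        profile[name] = {pat: m[inv[pat]].tolist() for pat in ("A", "B")}
    return profile


def run_pipeline(
    cohort: Cohort | str | Path,
    config: PipelineConfig | None = None,
    dictionary: DataDictionary | None = None,
) -> dict:
    """Execute the full analysis and return the report bundle as a dict.

    ``cohort`` may be a validated :class:`Cohort` or a path to a delimited
    table (then ``dictionary`` is required). Disabled stages contribute an
    explicit ``{"skipped": true}`` section, never an absent one.
    """
    cfg = config or PipelineConfig()
    if not isinstance(cohort, Cohort):
        if dictionary is None:
            raise ValueError("loading from a path requires a data dictionary")
        cohort = load_cohort(cohort, dictionary)
    seed = cfg.seed

    report: dict = {"qc": cohort.qc_report()}

    mca = fit_mca(cohort.features)
    retained, screen = screen_features(
        mca,
        n_dims=cfg.mca_n_dims,
        threshold_pct=cfg.mca_threshold_pct,
        force_keep=list(cfg.mca_force_keep),
    )
    report["mca"] = {
        "total_inertia": mca.total_inertia,
        "cumulative_explained_pct": mca.cumulative_explained_pct(cfg.mca_n_dims),
        "n_retained": len(retained),
        "retained": retained,
        "screen": json.loads(screen.to_json(orient="index")),
    }
    if len(retained) == len(cohort.feature_names):
        screened = cohort
    else:
        sub_dict = DataDictionary({k: cohort.dictionary.levels[k] for k in retained})
        screened = Cohort(cohort.data.copy(), sub_dict, dict(cohort.meta))

    lca_section, fits, fit_rows = _lca_stage(screened, cfg, seed)
    report["lca"] = lca_section
    cands = _candidates(screened, fits, fit_rows, cfg, seed)
    sel: SelectionReport = select_solution(cands, cfg.rules)
    report["selection"] = {
        "audit": sel.audit,
        "selected": sel.selected.tag() if sel.admissible else None,
        "note": "clinical interpretability is a manual criterion recorded via config overrides",
    }
    if not sel.admissible:
        report["error"] = "no admissible clustering solution"
        report["meta"] = _meta(cfg)
        return report

    chosen = sel.selected
    fit = fits.get(chosen.k) if chosen.method == "lca" else None
    pattern_b, naming = _anchor_pattern_b(chosen.labels, screened, cfg.pattern_anchor, fit)
    share_b = float(np.mean(pattern_b))
    report["patterns"] = {
        "method": chosen.tag(),
        "naming": naming,
        "share_a": 1.0 - share_b,
        "share_b": share_b,
        "counts": {"A": int(np.sum(pattern_b == 0)), "B": int(np.sum(pattern_b == 1))},
    }
    if fit is not None and fit.n_classes == 2:
        report["class_profile"] = _class_profile(fit, screened, naming)
    else:
        report["class_profile"] = {"skipped": True, "reason": "selected solution is not a two-class LCA"}

    spec = DesignSpec()
    X = build_design(cohort.data, pattern_b, spec)
    report["vif"] = {k: (None if not np.isfinite(v) else float(v)) for k, v in vif(X).items()}
    ffit = firth_fit(X, cohort.outcome)
    report["firth"] = {
        "converged": ffit.converged,
        "or_table": json.loads(wald_summary(ffit).to_json(orient="records")),
    }

    if cfg.run_cv:
        cv = stratified_kfold_cv(X, cohort.outcome, k=cfg.cv_k, seed=stage_seed(seed, "cv"))
        report["cv"] = {
            "k": cv.k,
            "folds": json.loads(cv.folds.to_json(orient="records")),
            "fold_events": cv.fold_events,
        }
    else:
        report["cv"] = {"skipped": True}

    if cfg.run_bootstrap:
        bs = rare_event_bootstrap(
            X, cohort.outcome, B=cfg.bootstrap_B, seed=stage_seed(seed, "bootstrap")
        )
        report["bootstrap"] = {
            "B": bs.B,
            "n_failed": bs.n_failed,
            "n_significant_models": bs.n_significant_models,
            "table": json.loads(bs.table().to_json(orient="records")),
        }
    else:
        report["bootstrap"] = {"skipped": True}

    if cfg.run_risk_differences:
        rd = risk_difference_table(
            cohort, pattern_b, default_profiles(), spec=spec, B=cfg.rd_B, seed=stage_seed(seed, "rd")
        )
        report["risk_differences"] = json.loads(rd.to_json(orient="records"))
    else:
        report["risk_differences"] = {"skipped": True}

    report["meta"] = _meta(cfg)
    return report


def sensitivity_rerun(cohort: Cohort, config: PipelineConfig | None = None, main_report: dict | None = None) -> dict:
    """Repeat the analysis on the RCB-assessed subset (MP cases excluded).

    Re-clusters at the class count the main run selected (two by default),
    re-runs Firth + CV + bootstrap + risk differences, and compares the
    class profiles with the main run. With no MP cases present the rerun is
    a flagged no-op.
    """
    cfg = config or PipelineConfig()
    if "assessment_system" not in cohort.data.columns:
        raise ValueError("cohort records carry no assessment_system column")
    mp_mask = (cohort.data["assessment_system"] == "MP").to_numpy()
    n_mp = int(mp_mask.sum())
    if n_mp == 0:
        report = run_pipeline(cohort, cfg)
        report["sensitivity"] = {"no_op": True, "reason": "no MP-assessed cases"}
        return report

    excluded_events = int(cohort.outcome[mp_mask].sum())
    sub = cohort.subset(~mp_mask)
    selected_C = 2
    if main_report is not None and main_report.get("selection", {}).get("selected", "").startswith("lca"):
        selected_C = int(main_report["selection"]["selected"].split("=")[1])

    seed = cfg.seed
    fit = fit_lca(
        sub.features,
        selected_C,
        n_starts=cfg.n_starts,
        tol=cfg.em_tol,
        max_iter=cfg.em_max_iter,
        seed=stage_seed(seed, "sens_lca"),
    )
    pattern_b, naming = _anchor_pattern_b(fit.modal_assignment, sub, cfg.pattern_anchor, fit)
    spec = DesignSpec()
    X = build_design(sub.data, pattern_b, spec)
    ffit = firth_fit(X, sub.outcome)
    out: dict = {
        "no_op": False,
        "n_excluded": n_mp,
        "n_excluded_events": excluded_events,
        "n": sub.n,
        "n_events": sub.n_events,
        "patterns": {"naming": naming, "share_b": float(np.mean(pattern_b))},
        "class_profile": _class_profile(fit, sub, naming) if selected_C == 2 else {"skipped": True},
        "firth": {
            "converged": ffit.converged,
            "or_table": json.loads(wald_summary(ffit).to_json(orient="records")),
        },
    }
    if cfg.run_cv:
        cv = stratified_kfold_cv(X, sub.outcome, k=cfg.cv_k, seed=stage_seed(seed, "sens_cv"))
        out["cv"] = {"k": cv.k, "folds": json.loads(cv.folds.to_json(orient="records"))}
    if cfg.run_bootstrap:
        bs = rare_event_bootstrap(X, sub.outcome, B=cfg.bootstrap_B, seed=stage_seed(seed, "sens_bootstrap"))
        out["bootstrap"] = {
            "B": bs.B,
            "n_significant_models": bs.n_significant_models,
            "table": json.loads(bs.table().to_json(orient="records")),
        }
    if cfg.run_risk_differences:
        rd = risk_difference_table(sub, pattern_b, default_profiles(), spec=spec, B=cfg.rd_B, seed=stage_seed(seed, "sens_rd"))
        out["risk_differences"] = json.loads(rd.to_json(orient="records"))
    if main_report is not None and isinstance(main_report.get("class_profile"), dict) and "skipped" not in main_report["class_profile"]:
        diffs = []
        for name, pats in main_report["class_profile"].items():
            if name in out["class_profile"]:
                for pat in ("A", "B"):
                    a = np.asarray(pats[pat])
                    b = np.asarray(out["class_profile"][name][pat])
                    diffs.append(float(np.abs(a - b).max()))
        out["profile_comparison"] = {
            "max_abs_prob_diff": max(diffs) if diffs else None,
            "mean_abs_prob_diff": float(np.mean(diffs)) if diffs else None,
        }
    return out


def _meta(cfg: PipelineConfig) -> dict:
    cfg_doc = asdict(cfg)
    cfg_hash = hashlib.sha256(json.dumps(cfg_doc, sort_keys=True, default=str).encode()).hexdigest()[:16]
    return {"seed": cfg.seed, "config_hash": cfg_hash, "version": __version__}


def report_hash(report: dict) -> str:
    """Stable content hash of a report bundle (determinism checks)."""
    return hashlib.sha256(json.dumps(report, sort_keys=True, default=str).encode()).hexdigest()


def validate_report(report: dict) -> None:
    """Structural validation against the shipped report schema.

    Checks required sections and their basic types; raises ValueError on the
    first violation.
    """
    schema = json.loads(resources.files("sonopattern").joinpath("report_schema.json").read_text())
    for key, spec in schema["properties"].items():
        required = key in schema.get("required", [])
        if key not in report:
            if required:
                raise ValueError(f"report is missing required section {key!r}")
            continue
        expected = spec.get("type")
        value = report[key]
        type_map = {"object": dict, "array": list, "string": str, "number": (int, float)}
        allowed = expected if isinstance(expected, list) else [expected]
        pytypes = tuple(type_map[t] for t in allowed if t in type_map)
        if pytypes and not isinstance(value, pytypes):
            raise ValueError(f"report section {key!r} should be {expected}")
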