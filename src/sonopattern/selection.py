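"""External-validity testing and the combined model-selection rule.

Candidates (latent-class solutions at several class counts, K-modes and
hierarchical cuts at several k) are screened by internal criteria —
enumeration tests and entropy for the model-based solutions, a silhouette
floor for the distance-based ones, and a minimum-class-share rule against
degenerate clusters — then ranked by external validity (association of
cluster membership with pathological non-response) and BIC. Every rejection
carries a machine-readable reason; an empty survivor set is an explicit
outcome, never a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency

__all__ = ["Candidate", "SelectionRules", "SelectionReport", "external_validity_test", "select_solution"]


def external_validity_test(labels, outcome) -> tuple[float, int, float]:
    """Pearson chi-square of the labels x outcome contingency table.

    Returns (statistic, df, p) with df = (#groups - 1) for the binary
    outcome. Raises if any label group is empty of patients.
    """
    labels = np.asarray(labels)
    y = np.asarray(outcome)
    if labels.shape != y.shape:
        raise ValueError("labels and outcome must have equal length")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two label groups")
    table = np.array([[np.sum((labels == g) & (y == v)) for v in (1, 0)] for g in groups])
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("empty label group")
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # outcome constant: no association testable
        return 0.0, groups.size - 1, 1.0
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


@dataclass
class Candidate:
    """One clustering solution entered into model selection."""

    method: str                      # "lca" | "kmodes" | "hierarchical"
    k: int
    class_shares: np.ndarray
    external_stat: float | None = None
    external_p: float | None = None
    bic: float | None = None
    entropy: float | None = None     # LCA only (None for C=1)
    lmrt_p: float | None = None      # LCA only, C >= 2
    blrt_p: float | None = None      # LCA only, C >= 2
    silhouette: float | None = None  # distance-based only
    labels: np.ndarray | None = None

    @property
    def is_lca(self) -> bool:
        return self.method == "lca"

    def tag(self) -> str:
        return f"{self.method}/k={self.k}"


@dataclass(frozen=True)
class SelectionRules:
    """Thresholds of the combined selection rule (all configurable)."""

    alpha: float = 0.05
    entropy_min: float = 0.7
    min_class_share: float = 0.02    # degenerate-class rule
    silhouette_min: float = 0.30     # "weak structure" floor for distance methods
    require_external: bool = True


@dataclass
class SelectionReport:
    selected: Candidate | None
    audit: list[dict] = field(default_factory=list)

    @property
    def admissible(self) -> bool:
        return self.selected is not None


def _screen(c: Candidate, rules: SelectionRules) -> list[str]:
    reasons: list[str] = []
    if c.is_lca:
        if c.k >= 2:
            # a criterion whose statistic was not computed (None, e.g. the
            # enumeration test stage was disabled) is not applied
            if c.entropy is None or c.entropy <= rules.entropy_min:
                reasons.append(f"entropy<={rules.entropy_min}")
            if c.lmrt_p is not None and c.lmrt_p >= rules.alpha:
                reasons.append("lmrt_not_significant")
            if c.blrt_p is not None and c.blrt_p >= rules.alpha:
                reasons.append("blrt_not_significant")
        else:
            reasons.append("single_class_uninformative")
    else:
        if c.silhouette is None or c.silhouette < rules.silhouette_min:
            reasons.append(f"silhouette<{rules.silhouette_min}")
    if np.min(c.class_shares) < rules.min_class_share:
        reasons.append(f"class_share<{rules.min_class_share}")
    return reasons


def select_solution(candidates: list[Candidate], rules: SelectionRules | None = None) -> SelectionReport:
    """Apply the selection rule and return the winner with a full audit trail.

    Order of application: (1) internal admissibility (enumeration tests +
    entropy for LCA; silhouette floor for distance methods; degenerate-class
    rule for all); (2) among survivors, prefer significant external
    validity; (3) break ties by lowest BIC, then by fewer classes.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rules = rules or SelectionRules()
    audit = []
    survivors = []
    for c in candidates:
        reasons = _screen(c, rules)
        audit.append(
            {
                "candidate": c.tag(),
                "method": c.method,
                "k": c.k,
                "entropy": c.entropy,
                "lmrt_p": c.lmrt_p,
                "blrt_p": c.blrt_p,
                "silhouette": c.silhouette,
                "bic": c.bic,
                "external_p": c.external_p,
                "min_class_share": float(np.min(c.class_shares)),
                "rejected_for": reasons,
            }
        )
        if not reasons:
            survivors.append(c)
    if not survivors:
        return SelectionReport(selected=None, audit=audit)

    def sort_key(c: Candidate):
        ext_sig = c.external_p is not None and c.external_p < rules.alpha
        bic = c.bic if c.bic is not None else np.inf
        return (0 if ext_sig or not rules.require_external else 1, bic, c.k)

    winner = min(survivors, key=sort_key)
    for row in audit:
        row["selected"] = row["candidate"] == winner.tag()
    return SelectionReport(selected=winner, audit=audit)
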