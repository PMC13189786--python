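"""Multiple correspondence analysis of the categorical feature table.

Indicator-matrix MCA: correspondence analysis of the N x (sum K_j) one-hot
table. Principal inertias are the squared singular values of the
standardized residual matrix; the total inertia equals (sum K_j)/J - 1.
Feature screening keeps a variable when the summed contribution of its
categories exceeds a percentage threshold on at least one of the leading
dimensions (the reading under which a screen at 2% over five dimensions can
retain every variable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MCAResult", "fit_mca", "screen_features"]


@dataclass
class MCAResult:
    feature_names: list[str]
    eigenvalues: np.ndarray            # principal inertias, non-increasing
    total_inertia: float
    feature_contrib_pct: pd.DataFrame  # features x dims, each column sums to 100
    explained_pct: np.ndarray          # per-dimension % of total inertia
    benzecri: bool = False

    @property
    def n_dims(self) -> int:
        return self.eigenvalues.size

    def cumulative_explained_pct(self, n_dims: int) -> float:
        return float(self.explained_pct[:n_dims].sum())


def fit_mca(features, n_dims: int | None = None, benzecri: bool = False) -> MCAResult:
    """Indicator-matrix MCA of a table of categorical codes.

    ``benzecri`` applies the Benzecri inertia correction to the *explained*
    percentages only (contributions are unaffected); the default reports raw
    principal inertias.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy().astype(int)
    else:
        x = np.asarray(features).astype(int)
        names = [f"f{j}" for j in range(x.shape[1])]
    n, J = x.shape
    if J < 2:
        raise ValueError("MCA needs at least 2 features")
    n_levels = x.max(axis=0) + 1
    for j in range(J):
        if len(np.unique(x[:, j])) < 2:
            raise ValueError(f"feature {names[j]!r} is constant (zero variance)")
    offsets = np.concatenate([[0], np.cumsum(n_levels)])
    Ktot = int(offsets[-1])
    Z = np.zeros((n, Ktot))
    for j in range(J):
        Z[np.arange(n), offsets[j] + x[:, j]] = 1.0

    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    _, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # drop numerically-null axes (the indicator table has J structural zeros)
    keep = sv > 1e-10
    sv, Vt = sv[keep], Vt[keep]
    eig = sv**2
    max_dims = eig.size
    if n_dims is None:
        n_dims = max_dims
    n_dims = min(n_dims, max_dims)

    # contribution of column k to axis s = v_ks^2 (columns of V are unit)
    col_contrib = Vt.T**2  # Ktot x dims
    feat_contrib = np.zeros((J, max_dims))
    for j in range(J):
        feat_contrib[j] = col_contrib[offsets[j]:offsets[j + 1]].sum(axis=0)
    contrib = pd.DataFrame(
        100.0 * feat_contrib[:, :n_dims],
        index=names,
        columns=[f"dim{s + 1}" for s in range(n_dims)],
    )

    total = Ktot / J - 1.0
    if benzecri:
        thr = 1.0 / J
        adj = np.where(eig > thr, (J / (J - 1.0) * (eig - thr)) ** 2, 0.0)
        explained = 100.0 * adj / adj.sum() if adj.sum() > 0 else np.zeros_like(adj)
    else:
        explained = 100.0 * eig / total
    return MCAResult(
        feature_names=names,
        eigenvalues=eig[:n_dims],
        total_inertia=total,
        feature_contrib_pct=contrib,
        explained_pct=explained[:n_dims],
        benzecri=benzecri,
    )


def screen_features(
    mca: MCAResult,
    n_dims: int = 5,
    threshold_pct: float = 2.0,
    require_all_dims: bool = False,
    force_keep: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the contribution screen over the first ``n_dims`` dimensions.

    A feature is retained when its contribution exceeds ``threshold_pct`` in
    at least one leading dimension (set ``require_all_dims`` for the
    stricter all-dimensions reading). ``force_keep`` is the manual
    expert-review override list. Returns (retained names, per-feature report).
    """
    if mca.n_dims < n_dims:
        raise ValueError(f"MCA result has only {mca.n_dims} dimensions, need {n_dims}")
    block = mca.feature_contrib_pct.iloc[:, :n_dims]
    hits = block.gt(threshold_pct)
    keep = hits.all(axis=1) if require_all_dims else hits.any(axis=1)
    if force_keep:
        keep = keep | block.index.isin(force_keep)
    report = block.copy()
    report["retained"] = keep
    return list(block.index[keep]), report
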