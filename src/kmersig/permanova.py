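"""Distance-based permutational multivariate ANOVA (PERMANOVA) with
sequential term decomposition and unique/shared variance partitioning.

The implementation follows the classical construction: the distance
matrix is Gower-centered into an inner-product matrix ``G``; model terms
enter sequentially (Type-I), each term's sum of squares being the increase
in ``tr(H G)`` as the hat projector ``H`` expands over the design columns
(categorical factors one-hot encoded, quantitative covariates as single
centered columns).  Significance is assessed by unrestricted permutation
of observations, recomputing each term's pseudo-F.

Model strings of the form ``"D ~ A*B*C"`` are interpreted as sequential
main-effect entry of the named metadata columns (no interaction expansion),
matching how conditional percentages are read off such models.

The unique/shared ("commonality") partition of two correlated factors A, B:

    unique(A) = R2(A | B),  unique(B) = R2(B | A),
    shared(A, B) = R2(A alone) - unique(A) = R2(B alone) - unique(B),

where the two shared computations agree exactly; shared may be negative
(suppression) and is reported as-is.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multivariate import DistanceMatrix

logger = logging.getLogger(__name__)


def gower_center(D: DistanceMatrix) -> np.ndarray:
    """G = -1/2 J A J with A = (d_ij^2) and J the centering projector.

    G is symmetric with zero row sums; tr(G) is the total sum of squares.
    """
    d2 = D.values**2
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * (J @ d2 @ J)


def _orthonormal_basis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of X via SVD."""
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > tol * max(X.shape) * (S[0] if len(S) else 1.0)))
    return U[:, :rank]


def _term_columns(values: pd.Series) -> np.ndarray:
    """Design columns for one term: one-hot for categorical, centered single
    column for numeric covariates (e.g. GC fraction)."""
    if pd.api.types.is_numeric_dtype(values):
        x = values.to_numpy(dtype=float)
        return (x - x.mean())[:, None]
    levels = pd.unique(values)
    return np.column_stack([(values == lv).to_numpy(float) for lv in levels])


@dataclass
class PermanovaResult:
    model: str
    table: pd.DataFrame  # per term: df, SS, R2, F, p (+ residual, total rows)
    n_permutations: int
    seed: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def permanova_sequential(
    D: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 9999,
    seed: int = 0,
    model: str = "",
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA of ``D`` on the listed metadata columns.

    ``metadata`` must be indexable by the distance matrix ids (an ``id``
    column or matching index).  p-values are ``(1 + #{F_perm >= F_obs}) /
    (1 + n_perm)`` under unrestricted permutation of observations, shared
    across terms; ``n_perm=0`` skips the permutation test (p = NaN).
    """
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    missing = [i for i in D.ids if i not in meta.index]
    if missing:
        raise ValueError(f"metadata missing ids: {missing[:5]}")
    meta = meta.loc[D.ids]
    for t in terms:
        if t not in meta.columns:
            raise ValueError(f"unknown metadata column {t!r}")

    G = gower_center(D)
    n = D.n
    ss_total = float(np.trace(G))

    # expanding orthonormal bases: intercept, then one per added term
    design = [np.ones((n, 1))]
    bases = [_orthonormal_basis(np.hstack(design))]
    kept_terms: list[str] = []
    dfs: list[int] = []
    for t in terms:
        design.append(_term_columns(meta[t]))
        basis = _orthonormal_basis(np.hstack(design))
        df_t = basis.shape[1] - bases[-1].shape[1]
        if df_t == 0:
            logger.warning("term %r adds no degrees of freedom; dropped", t)
            design.pop()
            continue
        kept_terms.append(t)
        dfs.append(df_t)
        bases.append(basis)
    df_res = n - bases[-1].shape[1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_ss(Gmat: np.ndarray) -> tuple[np.ndarray, float]:
        # tr(H G) with H = B B' computed as sum(B * (G B)), O(n^2 df)
        traces = [float(np.sum(B * (Gmat @ B))) for B in bases]
        ss = np.diff(traces)
        ss_res = float(np.trace(Gmat)) - traces[-1]
        return ss, ss_res

    ss_obs, ss_res_obs = term_ss(G)
    dfs_arr = np.array(dfs, dtype=float)
    f_obs = (ss_obs / dfs_arr) / (ss_res_obs / df_res)

    p = np.full(len(kept_terms), np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(kept_terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            ss_p, ss_res_p = term_ss(Gp)
            f_p = (ss_p / dfs_arr) / (ss_res_p / df_res)
            exceed += f_p >= f_obs - 1e-12
        p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, t in enumerate(kept_terms):
        rows.append(
            {
                "term": t,
                "df": dfs[i],
                "SS": ss_obs[i],
                "R2": ss_obs[i] / ss_total,
                "F": f_obs[i],
                "p": p[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "SS": ss_res_obs,
            "R2": ss_res_obs / ss_total,
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows).set_index("term")
    model = model or f"D ~ {'*'.join(kept_terms)}"
    return PermanovaResult(model=model, table=table, n_permutations=n_perm, seed=seed)


def permanova_formula(
    D: DistanceMatrix,
    metadata: pd.DataFrame,
    formula: str,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """Fit a model given as ``"response ~ TermA*TermB"`` (sequential entry)."""
    m = re.match(r"^\s*(\S+)\s*~\s*(.+)$", formula)
    if not m:
        raise ValueError(f"cannot parse model string {formula!r}")
    terms = [t.strip() for t in m.group(2).split("*") if t.strip()]
    return permanova_sequential(D, metadata, terms, n_perm=n_perm, seed=seed, model=formula)


@dataclass
class CommonalityPartition:
    factor_a: str
    factor_b: str
    unique_a: float
    unique_b: float
    shared: float

    @property
    def total(self) -> float:
        return self.unique_a + self.unique_b + self.shared


def commonality(
    D: DistanceMatrix, metadata: pd.DataFrame, factor_a: str, factor_b: str
) -> CommonalityPartition:
    """Unique and shared ("indistinguishable") explained-variance partition
    of two factors, from the four sequential fits they define."""
    def conditional_r2(first: str, second: str) -> float:
        res = permanova_sequential(D, metadata, [first, second], n_perm=0)
        # a term fully confounded with the first is dropped: unique R2 = 0
        return res.r2(second) if second in res.table.index else 0.0

    r2_a = permanova_sequential(D, metadata, [factor_a], n_perm=0).r2(factor_a)
    r2_b = permanova_sequential(D, metadata, [factor_b], n_perm=0).r2(factor_b)
    unique_a = conditional_r2(factor_b, factor_a)
    unique_b = conditional_r2(factor_a, factor_b)
    shared_via_a = r2_a - unique_a
    shared_via_b = r2_b - unique_b
    if abs(shared_via_a - shared_via_b) > 1e-9:
        raise AssertionError(
            f"shared-variance computations disagree: {shared_via_a} vs {shared_via_b}"
        )
    return CommonalityPartition(factor_a, factor_b, unique_a, unique_b, shared_via_a)
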