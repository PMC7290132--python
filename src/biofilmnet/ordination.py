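"""Distance-based ordination: PCoA, dbRDA, envfit and variation
partitioning.

dbRDA here is the two-stage construction: principal-coordinate analysis
of a (Bray-Curtis) dissimilarity matrix, followed by redundancy analysis
of the coordinate matrix on standardized environmental variables.  The
constrained proportion is the fraction of total (corrected) inertia
captured by the fitted values of that regression.

Negative PCoA eigenvalues, which arise because Bray-Curtis is not
Euclidean-embeddable, are discarded with a warning by default; a Lingoes
additive correction is available.

``envfit`` projects each environmental variable onto the first two
ordination axes and assesses its squared correlation by free permutation
of sample labels.  Variation partitioning decomposes the community
variance into unique and shared fractions of two or three named variable
groups using Ezekiel-adjusted R-squared; negative adjusted fractions are
reported as-is, as is conventional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .exceptions import ConfigError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinationResult",
    "pcoa",
    "dbrda",
    "envfit",
    "variation_partitioning",
]


@dataclass
class OrdinationResult:
    """Site coordinates with eigenvalue bookkeeping.

    ``proportion_explained`` is relative to the total (corrected)
    inertia, so for a constrained ordination the per-axis proportions
    sum to ``constrained_proportion``.
    """

    site_coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    constrained_proportion: float | None = None
    total_inertia: float = field(default=np.nan)

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValidationError("eigenvalues must be non-increasing")


def _gower_center(d_sq: np.ndarray) -> np.ndarray:
    n = d_sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d_sq @ J


def pcoa(
    d: DistanceMatrix, negative_eigen_correction: str = "discard"
) -> OrdinationResult:
    """Principal-coordinate analysis of a distance matrix.

    ``negative_eigen_correction`` is one of ``discard`` (drop negative
    eigenvalues, warn), ``none`` (keep them in the reported spectrum but
    build coordinates from positive axes only) or ``lingoes`` (additive
    constant on squared off-diagonal distances).
    """
    if negative_eigen_correction not in ("discard", "none", "lingoes"):
        raise ConfigError(
            f"unknown negative-eigenvalue policy {negative_eigen_correction!r}"
        )
    dmat = np.asarray(d.data, dtype=float)
    ids = list(d.ids)
    n = dmat.shape[0]
    G = _gower_center(dmat**2)
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if negative_eigen_correction == "lingoes" and eigvals[-1] < -1e-12:
        c1 = -eigvals[-1]
        d_sq = dmat**2 + 2.0 * c1 * (1 - np.eye(n))
        G = _gower_center(d_sq)
        eigvals, eigvecs = np.linalg.eigh(G)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    pos = eigvals > tol
    if negative_eigen_correction == "discard" and (eigvals < -tol).any():
        logger.warning(
            "discarding %d negative PCoA eigenvalues (min %.3g)",
            int((eigvals < -tol).sum()),
            eigvals.min(),
        )
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if negative_eigen_correction == "none":
        reported = eigvals
        total = eigvals[pos].sum()
    else:
        reported = eigvals[pos]
        total = reported.sum()
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        site_coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=reported,
        proportion_explained=np.clip(reported, 0, None) / total,
        constrained_proportion=None,
        total_inertia=float(total),
    )


def _design_matrix(meta: pd.DataFrame, variables: list[str], ids) -> np.ndarray:
    meta = meta.loc[list(ids)]
    missing = [v for v in variables if v not in meta.columns]
    if missing:
        raise ValidationError(f"metadata lacks variables {missing}")
    X = meta[variables].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("missing values in constraining variables")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [v for v, s in zip(variables, sd) if s == 0]
        raise ValidationError(f"constant variables cannot constrain: {const}")
    X = (X - X.mean(axis=0)) / sd
    if np.linalg.cond(X) > 1e10:
        raise ValidationError(
            f"collinear constraining variables (condition number > 1e10): {variables}"
        )
    return X


def dbrda(
    d: DistanceMatrix,
    meta: pd.DataFrame,
    variables: list[str],
    negative_eigen_correction: str = "discard",
) -> OrdinationResult:
    """Distance-based redundancy analysis.

    PCoA site scores are regressed on the standardized variables; the
    constrained axes are the principal axes of the fitted values.  With
    no variables this reduces to plain PCoA.
    """
    base = pcoa(d, negative_eigen_correction)
    if not variables:
        return base
    n = base.site_coordinates.shape[0]
    if n <= len(variables) + 1:
        raise ValidationError(
            f"need more samples ({n}) than variables+1 ({len(variables) + 1})"
        )
    Y = base.site_coordinates.to_numpy()
    X = _design_matrix(meta, variables, base.site_coordinates.index)
    Q, _ = np.linalg.qr(X)
    Yfit = Q @ (Q.T @ Y)
    total = base.total_inertia
    constrained = float((Yfit**2).sum())
    U, s, _ = np.linalg.svd(Yfit, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size else 0
    eig = (s[:rank] ** 2)
    coords = U[:, :rank] * s[:rank]
    axes = [f"dbRDA{i + 1}" for i in range(rank)]
    return OrdinationResult(
        site_coordinates=pd.DataFrame(
            coords, index=base.site_coordinates.index, columns=axes
        ),
        eigenvalues=eig,
        proportion_explained=eig / total,
        constrained_proportion=constrained / total,
        total_inertia=total,
    )


def envfit(
    ord_result: OrdinationResult,
    meta: pd.DataFrame,
    variables: list[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit environmental vectors onto the first two ordination axes.

    For each variable: least-squares direction cosines on axes 1-2, the
    squared multiple correlation R2, and a permutation p-value
    ``(1 + #{R2* >= R2}) / (1 + n_permutations)`` under free shuffling
    of sample labels.  Constant variables are flagged and excluded.
    """
    coords = ord_result.site_coordinates
    if coords.shape[1] < 2:
        raise ValidationError("envfit needs an ordination with >=2 axes")
    A = coords.iloc[:, :2].to_numpy()
    A = A - A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    meta = meta.loc[coords.index]
    rows = []
    for var in variables:
        y = meta[var].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.warning("envfit: variable %s is constant; excluded", var)
            rows.append((var, np.nan, np.nan, np.nan, np.nan, True))
            continue
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        r2 = float(((Q.T @ yc) ** 2).sum() / ss_tot)
        b, *_ = np.linalg.lstsq(A, yc, rcond=None)
        norm = np.linalg.norm(b)
        cos = b / norm if norm > 0 else b
        perm_idx = np.array([rng.permutation(n) for _ in range(n_permutations)])
        Yp = yc[perm_idx]  # (n_perm, n)
        num = ((Yp @ Q) ** 2).sum(axis=1)
        r2_star = num / ss_tot
        p = (1 + int((r2_star >= r2).sum())) / (1 + n_permutations)
        rows.append((var, float(cos[0]), float(cos[1]), r2, p, False))
    return pd.DataFrame(
        rows, columns=["variable", "axis1", "axis2", "r2", "p", "degenerate"]
    )


def _ezekiel(r2: float, n: int, m: int) -> float:
    """Ezekiel-adjusted R-squared for m predictors at n observations."""
    if n - m - 1 <= 0:
        raise ValidationError("too few samples for adjusted R2")
    return 1 - (1 - r2) * (n - 1) / (n - m - 1)


def variation_partitioning(
    d: DistanceMatrix,
    meta: pd.DataFrame,
    groups: dict[str, list[str]],
    negative_eigen_correction: str = "discard",
) -> pd.DataFrame:
    """Partition community variance among 2 or 3 variable groups.

    Unique and shared fractions are obtained by inclusion-exclusion of
    Ezekiel-adjusted dbRDA R2 values.  Returns a tidy table of named
    fractions; ``residual`` completes the partition to 1.
    """
    names = list(groups)
    if len(names) not in (2, 3):
        raise ConfigError("variation partitioning takes 2 or 3 groups")
    all_vars: list[str] = []
    for g in names:
        for v in groups[g]:
            if v in all_vars:
                raise ValidationError(f"variable {v!r} appears in multiple groups")
            all_vars.append(v)
    n = len(d.ids)

    def adj(varlist: list[str]) -> float:
        res = dbrda(d, meta, varlist, negative_eigen_correction)
        return _ezekiel(res.constrained_proportion, n, len(varlist))

    rows = []
    if len(names) == 2:
        a_name, b_name = names
        rA, rB = adj(groups[a_name]), adj(groups[b_name])
        rAB = adj(groups[a_name] + groups[b_name])
        rows = [
            (f"unique[{a_name}]", rAB - rB),
            (f"unique[{b_name}]", rAB - rA),
            (f"shared[{a_name},{b_name}]", rA + rB - rAB),
            ("residual", 1 - rAB),
        ]
    else:
        a, b, c = names
        rA, rB, rC = adj(groups[a]), adj(groups[b]), adj(groups[c])
        rAB = adj(groups[a] + groups[b])
        rAC = adj(groups[a] + groups[c])
        rBC = adj(groups[b] + groups[c])
        rABC = adj(groups[a] + groups[b] + groups[c])
        g_all = rA + rB + rC - rAB - rAC - rBC + rABC
        rows = [
            (f"unique[{a}]", rABC - rBC),
            (f"unique[{b}]", rABC - rAC),
            (f"unique[{c}]", rABC - rAB),
            (f"shared[{a},{b}]", rA + rB - rAB - g_all),
            (f"shared[{a},{c}]", rA + rC - rAC - g_all),
            (f"shared[{b},{c}]", rB + rC - rBC - g_all),
            (f"shared[{a},{b},{c}]", g_all),
            ("residual", 1 - rABC),
        ]
    return pd.DataFrame(rows, columns=["fraction", "adjusted_r2"])
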