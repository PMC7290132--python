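"""Mantel and partial Mantel tests relating network-module
subcommunities to environmental variables.

Each module's "taxonomic dissimilarity" is the Bray–Curtis distance
between samples restricted to the module's OTU columns of the
whole-community relative-abundance table (no renormalization, so a
module contributing little abundance to two samples still registers a
distance).  Environmental distance is the absolute difference of a
single variable.  Significance is by permutation of one matrix's
rows+columns jointly, one-sided 'greater' as in vegan; the partial
variant controls a third matrix (altitude in the study design) through
first-order partial correlation recomputed per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

__all__ = [
    "MantelResult",
    "module_subcommunity_distance",
    "env_distance",
    "mantel",
    "partial_mantel",
    "module_env_screen",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    alternative: str = "greater"
    control: str | None = None


def module_subcommunity_distance(
    rel_table: pd.DataFrame, partition: dict, module_id
) -> DistanceMatrix:
    """Bray–Curtis over the module's OTU columns only.

    Sample pairs with no module abundance at all on either side are
    assigned the maximal distance 1 (the limit of disjoint support).
    """
    otus = [o for o, m in partition.items() if m == module_id and o in rel_table.columns]
    if len(otus) < 2:
        raise ValidationError(
            f"module {module_id!r} has fewer than 2 OTUs in the table"
        )
    X = rel_table[otus].to_numpy(dtype=float)
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        tot = (X[i] + X[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(tot > 0, diff / np.where(tot > 0, tot, 1), 1.0)
        d[i, i + 1 :] = vals
        d[i + 1 :, i] = vals
    return DistanceMatrix(d, ids=[str(s) for s in rel_table.index])


def env_distance(meta: pd.DataFrame, variable: str) -> DistanceMatrix:
    """Pairwise absolute differences of one environmental variable."""
    if variable not in meta.columns:
        raise ValidationError(f"metadata lacks variable {variable!r}")
    x = meta[variable].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError(f"missing values in variable {variable!r}")
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(d, ids=[str(s) for s in meta.index])


def _tri(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _check_conformal(*mats: DistanceMatrix) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValidationError("distance matrices must share labels and order")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValidationError("constant distance vector: correlation undefined")
    return float(xc @ yc / denom)


def _permuted_tri(mat: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    """Lower-triangle vectors of mat with rows+columns jointly permuted.

    perm_idx has shape (n_perm, n); the result is (n_perm, n_pairs).
    """
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    return mat[perm_idx[:, iu], perm_idx[:, ju]]


def _row_corr(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Yc @ xc) / denom


def mantel(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix correlation.

    r is the Pearson correlation of the off-diagonal triangles; p comes
    from jointly permuting rows and columns of ``dB``:
    ``p = (1 + #{r* >= r}) / (1 + n_permutations)`` (one-sided greater
    by default, vegan's convention; ``two-sided`` compares |r*| >= |r|).
    """
    _check_conformal(dA, dB)
    A, B = np.asarray(dA.data), np.asarray(dB.data)
    x, y = _tri(A), _tri(B)
    r = _pearson(x, y)
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    perm_idx = np.array([rng.permutation(n) for _ in range(n_permutations)])
    r_star = _row_corr(x, _permuted_tri(B, perm_idx))
    if alternative == "greater":
        hits = int(np.nansum(r_star >= r))
    elif alternative == "two-sided":
        hits = int(np.nansum(np.abs(r_star) >= abs(r)))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    p = (1 + hits) / (1 + n_permutations)
    return MantelResult(r=r, p=p, n_permutations=n_permutations, alternative=alternative)


def _partial_r(r_ab: np.ndarray, r_ac, r_bc: np.ndarray) -> np.ndarray:
    denom = np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (r_ab - r_ac * r_bc) / denom


def partial_mantel(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    dC: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel test of dA vs dB controlling dC.

    Statistic: first-order partial correlation
    ``(r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))`` on the
    triangle vectors.  dB is permuted; r_AB and r_BC are recomputed per
    permutation while r_AC stays fixed.
    """
    _check_conformal(dA, dB, dC)
    A, B, C = (np.asarray(m.data) for m in (dA, dB, dC))
    x, y, z = _tri(A), _tri(B), _tri(C)
    if np.ptp(z) == 0:
        raise ValidationError("constant control matrix: partial correlation undefined")
    r_ab, r_ac, r_bc = _pearson(x, y), _pearson(x, z), _pearson(y, z)
    if abs(r_ac) >= 1 or abs(r_bc) >= 1:
        raise ValidationError("perfectly correlated control: partial r undefined")
    r = float(_partial_r(np.array(r_ab), r_ac, np.array(r_bc)))
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    perm_idx = np.array([rng.permutation(n) for _ in range(n_permutations)])
    Yp = _permuted_tri(B, perm_idx)
    r_ab_star = _row_corr(x, Yp)
    r_bc_star = _row_corr(z, Yp)
    r_star = _partial_r(r_ab_star, r_ac, r_bc_star)
    if alternative == "greater":
        hits = int(np.nansum(r_star >= r))
    elif alternative == "two-sided":
        hits = int(np.nansum(np.abs(r_star) >= abs(r)))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    p = (1 + hits) / (1 + n_permutations)
    return MantelResult(
        r=r, p=p, n_permutations=n_permutations, alternative=alternative, control="dC"
    )


def module_env_screen(
    rel_table: pd.DataFrame,
    partition: dict,
    meta: pd.DataFrame,
    variables: list[str],
    control: str = "Altitude",
    min_module_size: int = 50,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel + partial Mantel screen of major modules against
    environmental variables.

    Only modules with more than ``min_module_size`` member OTUs are
    tested.  The partial test controls the distance matrix of
    ``control`` and is not applicable (NaN) when the variable *is* the
    control.  BH adjustment runs across the whole module x variable
    grid, separately for the plain and the partial test.
    """
    meta = meta.loc[rel_table.index]
    sizes = pd.Series(list(partition.values())).value_counts()
    major = sorted(m for m, s in sizes.items() if s > min_module_size)
    d_control = env_distance(meta, control)
    ss = np.random.SeedSequence(seed)
    rows = []
    for module_id in major:
        d_mod = module_subcommunity_distance(rel_table, partition, module_id)
        for var in variables:
            d_env = env_distance(meta, var)
            s1, s2 = (int(s % (2**31)) for s in ss.generate_state(2))
            ss = ss.spawn(1)[0]
            plain = mantel(d_mod, d_env, n_permutations, seed=s1)
            if var == control:
                rows.append(
                    (module_id, var, plain.r, plain.p, np.nan, np.nan)
                )
            else:
                part = partial_mantel(d_mod, d_env, d_control, n_permutations, seed=s2)
                rows.append(
                    (module_id, var, plain.r, plain.p, part.r, part.p)
                )
    out = pd.DataFrame(
        rows,
        columns=["module", "variable", "mantel_r", "mantel_p", "partial_r", "partial_p"],
    )
    out["mantel_p_adjusted"] = multipletests(out["mantel_p"], method="fdr_bh")[1]
    out["partial_p_adjusted"] = np.nan
    ok = out["partial_p"].notna()
    if ok.any():
        out.loc[ok, "partial_p_adjusted"] = multipletests(
            out.loc[ok, "partial_p"], method="fdr_bh"
        )[1]
    return out
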