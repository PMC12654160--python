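"""Mantel tests, taxa-environment correlation panels, and the yield GLM.

The Mantel statistic is the correlation between the strictly-lower-triangle
entries of two distance matrices; its null distribution is built by
simultaneously permuting rows and columns of the second matrix.  The
reported p-value is one-sided ("greater"):

    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)

For small matrices (n <= 7 by default) an exhaustive mode enumerates every
label permutation instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .core import ValidationError


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    seed: int | None
    exhaustive: bool = False


def _tri(mat: np.ndarray) -> np.ndarray:
    idx = np.tril_indices(mat.shape[0], k=-1)
    return mat[idx]


def _check_distance(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(mat, mat.T):
        raise ValidationError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValidationError(f"{name} must have a zero diagonal")
    return mat


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        return float(sps.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def mantel(dist_a, dist_b, method: str = "pearson", n_perm: int = 999,
           seed: int | None = 0, exhaustive: bool | None = None
           ) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    ``exhaustive=True`` (default for n <= 7) enumerates all n! label
    permutations and reports the exact enumeration fraction.
    """
    if isinstance(dist_a, pd.DataFrame):
        dist_a = dist_a.to_numpy()
    if isinstance(dist_b, pd.DataFrame):
        dist_b = dist_b.to_numpy()
    a = _check_distance(dist_a, "dist_a")
    b = _check_distance(dist_b, "dist_b")
    n = a.shape[0]
    if b.shape[0] != n:
        raise ValidationError("distance matrices differ in dimension")
    if n < 4:
        raise ValidationError("need at least 4 samples")
    va, vb = _tri(a), _tri(b)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValidationError("constant distance matrix: r undefined")
    r_obs = _corr(va, vb, method)

    if exhaustive is None:
        exhaustive = n <= 7
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            pb = b[np.ix_(perm, perm)]
            if _corr(va, _tri(pb), method) >= r_obs - 1e-12:
                count += 1
            total += 1
        # identity permutation is part of the enumeration
        return MantelResult(r=r_obs, p=count / total, n_perm=total - 1,
                            method=method, seed=None, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pb = b[np.ix_(perm, perm)]
        if _corr(va, _tri(pb), method) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, method=method, seed=seed)


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_panel(taxa_summary: pd.DataFrame, env: pd.DataFrame,
                      method: str = "pearson", min_pairs: int = 4
                      ) -> pd.DataFrame:
    """Pairwise correlation panel (long format: row, col, coef, p, stars).

    Rows of both frames are samples; missing pairs are dropped pairwise.
    Constant columns yield NaN coefficients flagged 'undefined'.
    """
    common = taxa_summary.index.intersection(env.index)
    ts = taxa_summary.loc[common]
    ev = env.loc[common]
    records = []
    for rcol in ts.columns:
        for ccol in ev.columns:
            pair = pd.concat([ts[rcol], ev[ccol]], axis=1).dropna()
            rec = {"row": rcol, "col": ccol, "n": len(pair)}
            if len(pair) < min_pairs:
                rec.update(coef=math.nan, p=math.nan, stars="",
                           note="too few pairs")
            else:
                x = pair.iloc[:, 0].to_numpy(dtype=float)
                y = pair.iloc[:, 1].to_numpy(dtype=float)
                if np.std(x) == 0 or np.std(y) == 0:
                    rec.update(coef=math.nan, p=math.nan, stars="",
                               note="undefined")
                else:
                    if method == "pearson":
                        res = sps.pearsonr(x, y)
                    else:
                        res = sps.spearmanr(x, y)
                    coef = float(res.statistic)
                    p = float(res.pvalue)
                    rec.update(coef=coef, p=p, stars=stars(p), note="")
            records.append(rec)
    return pd.DataFrame.from_records(records)


def yield_glm(yield_values, som, ap) -> pd.DataFrame:
    """OLS of yield on centred SOM, AP and their interaction.

    Returns a per-term coefficient table (coef, se, t, p).  Centring leaves
    the interaction coefficient untouched and makes the main effects the
    average marginal slopes.
    """
    y = np.asarray(yield_values, dtype=float)
    som = np.asarray(som, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if len(y) <= 4:
        raise ValidationError("need n > 4 observations")
    som_c = som - som.mean()
    ap_c = ap - ap.mean()
    x = pd.DataFrame({"SOM": som_c, "AP": ap_c, "SOM:AP": som_c * ap_c})
    x = sm.add_constant(x)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        cond = np.linalg.cond(x.to_numpy())
        raise ValidationError(
            f"design matrix rank deficient (rank {rank} < {x.shape[1]}, "
            f"condition number {cond:.3g})")
    fit = sm.OLS(y, x).fit()
    return pd.DataFrame({"coef": fit.params, "se": fit.bse,
                         "t": fit.tvalues, "p": fit.pvalues})


def environment_distance(env: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between samples on z-scored environmental columns."""
    z = (env - env.mean()) / env.std(ddof=0)
    z = z.dropna(axis=1, how="any")
    arr = z.to_numpy(dtype=float)
    d = np.sqrt(((arr[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=env.index, columns=env.index)
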