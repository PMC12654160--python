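"""Partial least squares path modelling and random-forest importance.

PLS-PM estimates latent variables from reflective (mode A) indicator
blocks by alternating outer and inner approximation:

1. standardize indicators; start with equal outer weights;
2. outer estimation: latent score = standardized weighted sum of its block;
3. inner estimation: each latent's inner proxy is the weighted sum of its
   inner-model neighbours (centroid scheme: weights are the signs of the
   latent correlations; factorial scheme: the correlations themselves);
4. outer update (mode A): weights = correlations of each indicator with
   the block's inner proxy;
5. iterate until the largest weight change falls below ``tol``.

Path coefficients are then OLS regressions of each endogenous latent on
its predecessors; quality indices are R^2 per endogenous block, indicator
communalities (squared loadings), and GoF = sqrt(mean communality x mean
R^2).  Bootstrap significance resamples rows, refits, sign-aligns to the
full-data solution and reports two-sided percentile p-values for each path.

Random-forest importance is %IncMSE - the percent increase in out-of-bag
MSE when one predictor is permuted - with significance from refitting on
response-permuted datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .core import ValidationError


@dataclass
class PlsPmSpec:
    blocks: dict[str, list[str]]          # latent name -> indicator columns
    paths: list[tuple[str, str]]          # (source latent, target latent)
    scheme: str = "centroid"              # centroid | factorial
    max_iter: int = 300
    tol: float = 1e-7
    bootstrap_n: int = 199
    seed: int = 0

    def __post_init__(self) -> None:
        names = list(self.blocks)
        for block, cols in self.blocks.items():
            if not cols:
                raise ValidationError(f"block {block!r} has no indicators")
        for src, dst in self.paths:
            if src not in names or dst not in names:
                raise ValidationError(f"path {src}->{dst} names unknown block")
        # acyclicity via topological sort
        order = self.topological_order()
        pos = {b: i for i, b in enumerate(order)}
        for src, dst in self.paths:
            if pos[src] >= pos[dst]:
                raise ValidationError("inner path matrix must be acyclic")

    def topological_order(self) -> list[str]:
        names = list(self.blocks)
        preds = {b: [s for s, d in self.paths if d == b] for b in names}
        order, placed = [], set()
        while len(order) < len(names):
            progress = False
            for b in names:
                if b in placed:
                    continue
                if all(p in placed for p in preds[b]):
                    order.append(b)
                    placed.add(b)
                    progress = True
            if not progress:
                raise ValidationError("inner path matrix contains a cycle")
        return order

    def predecessors(self, block: str) -> list[str]:
        return [s for s, d in self.paths if d == block]

    def endogenous(self) -> list[str]:
        return [b for b in self.blocks if self.predecessors(b)]


@dataclass
class PlsPmModel:
    spec: PlsPmSpec
    outer_weights: pd.Series          # per indicator
    loadings: pd.Series               # per indicator
    scores: pd.DataFrame              # samples x latents, unit variance
    path_coefficients: pd.DataFrame   # rows (source, target, coef)
    r_squared: dict[str, float]
    communalities: pd.Series
    gof: float
    n_iter: int

    def path(self, src: str, dst: str) -> float:
        m = self.path_coefficients
        row = m[(m["source"] == src) & (m["target"] == dst)]
        if row.empty:
            raise KeyError(f"no path {src}->{dst}")
        return float(row["coef"].iloc[0])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValidationError("zero-variance indicator")
    return (x - x.mean(axis=0)) / sd


def plspm_fit(data: pd.DataFrame, spec: PlsPmSpec) -> PlsPmModel:
    """Fit a reflective PLS path model."""
    cols = [c for block in spec.blocks.values() for c in block]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"data missing indicator columns: {missing}")
    if data[cols].isna().any().any():
        raise ValidationError("indicators contain missing values")
    n = len(data)
    if n <= len(spec.blocks):
        raise ValidationError("need more samples than blocks")

    blocks = list(spec.blocks)
    x = {b: _standardize(data[spec.blocks[b]].to_numpy(dtype=float))
         for b in blocks}
    weights = {b: np.ones(len(spec.blocks[b])) for b in blocks}

    # inner-model neighbours (paths are treated as undirected links here)
    neighbours = {b: set() for b in blocks}
    for s, d in spec.paths:
        neighbours[s].add(d)
        neighbours[d].add(s)

    def scores_from(wts):
        out = {}
        for b in blocks:
            s = x[b] @ wts[b]
            sd = s.std(ddof=0)
            if sd == 0:
                raise ValidationError(f"degenerate latent scores for {b!r}")
            out[b] = (s - s.mean()) / sd
        return out

    scores = scores_from(weights)
    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        # inner approximation
        inner = {}
        for b in blocks:
            z = np.zeros(n)
            for nb in neighbours[b]:
                r = float(np.corrcoef(scores[b], scores[nb])[0, 1])
                e = np.sign(r) if spec.scheme == "centroid" else r
                if e == 0:
                    e = 1.0
                z += e * scores[nb]
            if not neighbours[b]:
                z = scores[b].copy()
            sd = z.std(ddof=0)
            inner[b] = (z - z.mean()) / sd if sd > 0 else scores[b]
        # outer update, mode A
        new_weights = {}
        max_delta = 0.0
        for b in blocks:
            w = x[b].T @ inner[b] / n
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValidationError(f"outer weights collapsed for {b!r}")
            w = w / norm
            old = weights[b] / np.linalg.norm(weights[b])
            if np.dot(w, old) < 0:   # fix sign indeterminacy per block
                w = -w
            max_delta = max(max_delta, float(np.max(np.abs(w - old))))
            new_weights[b] = w
        weights = new_weights
        scores = scores_from(weights)
        if max_delta < spec.tol:
            break
    else:
        raise ValidationError(
            f"PLS-PM failed to converge in {spec.max_iter} iterations "
            f"(last max weight change {max_delta:.3g})")

    # orient each latent to correlate positively with its first indicator
    for b in blocks:
        r = float(np.corrcoef(scores[b], x[b][:, 0])[0, 1])
        if r < 0:
            scores[b] = -scores[b]
            weights[b] = -weights[b]

    score_df = pd.DataFrame({b: scores[b] for b in blocks}, index=data.index)

    loadings, communal, w_series = {}, {}, {}
    for b in blocks:
        for k, col in enumerate(spec.blocks[b]):
            lo = float(np.corrcoef(x[b][:, k], scores[b])[0, 1])
            loadings[col] = lo
            communal[col] = lo ** 2
            w_series[col] = float(weights[b][k])

    path_rows = []
    r2 = {}
    for b in spec.endogenous():
        preds = spec.predecessors(b)
        xmat = np.column_stack([scores[p] for p in preds])
        beta, *_ = np.linalg.lstsq(xmat, scores[b], rcond=None)
        fitted = xmat @ beta
        r2[b] = float(np.var(fitted) / np.var(scores[b]))
        for p, coef in zip(preds, beta):
            path_rows.append({"source": p, "target": b, "coef": float(coef)})

    mean_comm = float(np.mean(list(communal.values())))
    mean_r2 = float(np.mean(list(r2.values()))) if r2 else 0.0
    gof = float(np.sqrt(mean_comm * mean_r2))

    return PlsPmModel(
        spec=spec,
        outer_weights=pd.Series(w_series),
        loadings=pd.Series(loadings),
        scores=score_df,
        path_coefficients=pd.DataFrame(path_rows,
                                       columns=["source", "target", "coef"]),
        r_squared=r2,
        communalities=pd.Series(communal),
        gof=gof,
        n_iter=n_iter,
    )


@dataclass
class PlsPmBootstrap:
    paths: pd.DataFrame   # source, target, coef, ci_low, ci_high, p
    n_boot: int
    seed: int


def plspm_bootstrap(data: pd.DataFrame, spec: PlsPmSpec) -> PlsPmBootstrap:
    """Bootstrap path-coefficient significance (row resampling).

    Two-sided p from the percentile of zero in the sign-aligned bootstrap
    distribution; aborts if more than 10% of resamples fail to converge.
    """
    full = plspm_fit(data, spec)
    rng = np.random.default_rng(spec.seed)
    keys = [(r["source"], r["target"])
            for _, r in full.path_coefficients.iterrows()]
    boot = {k: [] for k in keys}
    failures = 0
    n = len(data)
    for _ in range(spec.bootstrap_n):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            m = plspm_fit(sample, spec)
        except ValidationError:
            failures += 1
            continue
        for k in keys:
            boot[k].append(m.path(*k))
    if failures > 0.1 * spec.bootstrap_n:
        raise ValidationError(
            f"{failures}/{spec.bootstrap_n} bootstrap resamples failed")

    rows = []
    for k in keys:
        draws = np.array(boot[k])
        b = len(draws)
        obs = full.path(*k)
        share_le0 = (1 + np.sum(draws <= 0)) / (b + 1)
        share_ge0 = (1 + np.sum(draws >= 0)) / (b + 1)
        p = min(1.0, 2.0 * min(share_le0, share_ge0))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append({"source": k[0], "target": k[1], "coef": obs,
                     "ci_low": float(lo), "ci_high": float(hi), "p": float(p)})
    return PlsPmBootstrap(paths=pd.DataFrame(rows), n_boot=spec.bootstrap_n,
                          seed=spec.seed)


def default_plspm_spec(inner: str = "organic") -> PlsPmSpec:
    """Default latent structure: fertilization dose acting on P fractions,
    enzyme activity and the microbial community, all feeding yield."""
    blocks = {
        "fertilization": ["fert_dose"],
        "p_fractions": ["Citrate_P", "Enzyme_P", "HCl_P"],
        "enzymes": ["BG", "CBH", "NAG"],
        "community": ["shannon", "NMDS1"],
        "yield": ["yield"],
    }
    paths = [
        ("fertilization", "p_fractions"),
        ("fertilization", "enzymes"),
        ("fertilization", "community"),
        ("p_fractions", "enzymes"),
        ("p_fractions", "yield"),
        ("enzymes", "yield"),
        ("community", "yield"),
    ]
    return PlsPmSpec(blocks=blocks, paths=paths)


# ---------------------------------------------------------------------------
# Random-forest permutation importance

@dataclass
class RfImportanceResult:
    table: pd.DataFrame    # per predictor: inc_mse_pct, p
    n_trees: int
    n_perm: int
    seed: int
    oob_mse: float


def _forest_inc_mse(x: np.ndarray, y: np.ndarray, n_trees: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """%IncMSE per predictor for one regression forest (own bagging so
    out-of-bag indices are explicit)."""
    n, p = x.shape
    mtry = max(1, p // 3)
    sum_base = np.zeros(n)
    cnt_base = np.zeros(n)
    sum_perm = np.zeros((p, n))
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        m = len(oob)
        if m == 0:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry,
            random_state=int(rng.integers(0, 2 ** 31 - 1)))
        tree.fit(x[boot], y[boot])
        # one stacked predict: the OOB block plus p permuted copies of it
        stacked = np.tile(x[oob], (p + 1, 1))
        for j in range(p):
            block = stacked[(j + 1) * m:(j + 2) * m]
            block[:, j] = block[rng.permutation(m), j]
        pred = tree.predict(stacked)
        sum_base[oob] += pred[:m]
        cnt_base[oob] += 1
        for j in range(p):
            sum_perm[j, oob] += pred[(j + 1) * m:(j + 2) * m]
    seen = cnt_base > 0
    mse_base = float(np.mean((sum_base[seen] / cnt_base[seen] - y[seen]) ** 2))
    inc = np.empty(p)
    for j in range(p):
        mse_j = float(np.mean(
            (sum_perm[j, seen] / cnt_base[seen] - y[seen]) ** 2))
        inc[j] = 100.0 * (mse_j - mse_base) / mse_base
    return inc, mse_base


def rf_importance(features: pd.DataFrame, response, n_trees: int = 1000,
                  n_perm: int = 200, seed: int = 0) -> RfImportanceResult:
    """Permutation importance (%IncMSE) with response-permutation p-values.

    The observed importances come from one forest; the null distribution
    per predictor comes from refitting the forest on ``n_perm`` datasets
    with the response permuted, and p = (1 + #{null >= obs})/(n_perm + 1).
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if len(y) < 10:
        raise ValidationError("need at least 10 samples")
    if np.std(y) == 0:
        raise ValidationError("constant response")
    rng = np.random.default_rng(seed)
    obs, oob_mse = _forest_inc_mse(x, y, n_trees, rng)
    null_ge = np.zeros(x.shape[1])
    for _ in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        null, _ = _forest_inc_mse(x, y_perm, n_trees, rng)
        null_ge += null >= obs
    p = (1 + null_ge) / (n_perm + 1)
    table = pd.DataFrame({"inc_mse_pct": obs, "p": p},
                         index=features.columns).sort_values(
        "inc_mse_pct", ascending=False)
    return RfImportanceResult(table=table, n_trees=n_trees, n_perm=n_perm,
                              seed=seed, oob_mse=oob_mse)
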