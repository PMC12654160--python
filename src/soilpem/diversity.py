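"""Alpha diversity, Bray-Curtis dissimilarity and NMDS ordination."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from sklearn.manifold import MDS

from .core import FeatureTable, ValidationError


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over nonzero taxa."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValidationError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValidationError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    c = np.asarray(counts)
    if c.sum() <= 0:
        raise ValidationError("all-zero count vector")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum min(a_i,b_i) / (sum a + sum b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("length mismatch")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValidationError("empty sample")
    return float(_braycurtis(a, b))


def bray_curtis_matrix(table: FeatureTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    ids = table.sample_ids
    mat = table.counts.to_numpy(dtype=float).T
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _braycurtis(mat[i], mat[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def alpha_diversity_table(table: FeatureTable) -> pd.DataFrame:
    """Shannon and Chao1 per sample."""
    rows = {s: {"shannon": shannon(table.counts[s]),
                "chao1": chao1(table.counts[s])}
            for s in table.sample_ids}
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0
           ) -> FeatureTable:
    """Seeded rarefaction (subsampling without replacement) to a common depth."""
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    totals = counts.sum(axis=0)
    depth = int(depth if depth is not None else totals.min())
    if (totals < depth).any():
        raise ValidationError("a sample is shallower than the rarefaction depth")
    out = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        pool = np.repeat(np.arange(counts.shape[0]), counts[:, j])
        picked = rng.choice(pool, size=depth, replace=False)
        out[:, j] = np.bincount(picked, minlength=counts.shape[0])
    df = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return FeatureTable(df, table.domain.copy(), table.taxonomy.copy())


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float              # Kruskal stress-1, in [0, 1]
    converged: bool
    seed: int


def nmds(dist: pd.DataFrame | np.ndarray, k: int = 2, seed: int = 0,
         n_init: int = 4, max_iter: int = 300) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Iterative stress minimization from seeded starts (library-backed
    optimizer); reported stress is normalized Kruskal stress-1.
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        mat = dist.to_numpy(dtype=float)
    else:
        mat = np.asarray(dist, dtype=float)
        ids = [f"s{i}" for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValidationError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    model = MDS(n_components=k, metric="precomputed", metric_mds=False,
                init="random", random_state=seed, n_init=n_init,
                max_iter=max_iter, normalized_stress=True)
    coords = model.fit_transform(mat)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        stress=float(model.stress_),
        converged=model.n_iter_ < max_iter,
        seed=seed,
    )
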