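"""One-way ANOVA, Duncan's multiple range test, and percent-change summaries.

Duncan's test compares the range of every ordered stretch of p group means
against a least significant range R_p = q(alpha_p, p, df) * sqrt(MSE / n),
where q is the upper studentized-range quantile at Duncan's protection
level alpha_p = 1 - (1 - alpha)^(p - 1).  Groups whose stretch range stays
below R_p share a letter; letters are assigned in descending mean order
starting at 'a'.  Unbalanced groups use the harmonic mean of group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    f: float
    p: float
    mse: float
    df_error: int
    df_between: int


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA decomposition."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    parts = [values[groups == g] for g in labels]
    if any(len(p) < 2 for p in parts):
        raise ValueError("need at least two observations per group")
    grand = values.mean()
    ss_between = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in parts)
    df_b = len(labels) - 1
    df_e = len(values) - len(labels)
    msb = ss_between / df_b
    mse = ss_within / df_e
    if mse == 0.0:
        if msb == 0.0:
            return AnovaResult(0.0, 1.0, 0.0, df_e, df_b)
        return AnovaResult(np.inf, 0.0, 0.0, df_e, df_b)
    f = msb / mse
    p = float(sps.f.sf(f, df_b, df_e))
    if ss_between == 0.0:
        f, p = 0.0, 1.0
    return AnovaResult(float(f), p, float(mse), df_e, df_b)


@dataclass
class DuncanResult:
    table: pd.DataFrame   # index group, columns: mean, se, n, letters
    alpha: float
    mse: float
    df_error: int

    def letters(self) -> dict[str, str]:
        return dict(self.table["letters"])


def _least_significant_ranges(n_means: int, mse: float, n_harm: float,
                              df_error: int, alpha: float) -> np.ndarray:
    """R_p for spans p = 2..n_means (index p-2)."""
    spans = np.arange(2, n_means + 1)
    protection = 1.0 - (1.0 - alpha) ** (spans - 1)
    q = sps.studentized_range.ppf(1.0 - protection, spans, df_error)
    return q * np.sqrt(mse / n_harm)


def _range_significant(means_desc: np.ndarray, lsr: np.ndarray) -> np.ndarray:
    """Pairwise significance matrix over descending-ordered means.

    Pair (i, j) spans p = j - i + 1 means; it is significant when the
    difference exceeds R_p and no enclosing stretch has already been
    declared homogeneous (Duncan's protection of nested ranges).
    """
    k = len(means_desc)
    sig = np.zeros((k, k), dtype=bool)
    homogeneous = np.zeros((k, k), dtype=bool)
    # Evaluate longest spans first so nested stretches inherit homogeneity.
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = means_desc[i] - means_desc[j]
            enclosed = any(homogeneous[a, b]
                           for a in range(0, i + 1)
                           for b in range(j, k)
                           if (a, b) != (i, j))
            if diff > lsr[span - 2] and not enclosed:
                sig[i, j] = sig[j, i] = True
            else:
                homogeneous[i, j] = True
    return sig


def _assign_letters(sig: np.ndarray) -> list[str]:
    """Letters from maximal homogeneous stretches of the ordered means.

    The protected range test makes non-significance interval-closed over
    the descending ordering, so each letter is a maximal index interval
    [i, j] whose endpoints are not significantly different; intervals
    contained in an earlier one are absorbed.
    """
    k = sig.shape[0]
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i, j + 1]:
            j += 1
        if not intervals or intervals[-1][1] < j or intervals[-1][0] > i:
            if intervals and intervals[-1][0] <= i and intervals[-1][1] >= j:
                continue  # absorbed
            intervals.append((i, j))
    letters = ["" for _ in range(k)]
    for idx, (i, j) in enumerate(intervals):
        ch = chr(ord("a") + idx)
        for m in range(i, j + 1):
            letters[m] += ch
    return letters


def duncan_letters(values, groups, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with letter grouping."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    anova = one_way_anova(values, groups)
    labels = pd.unique(groups)
    means = np.array([values[groups == g].mean() for g in labels])
    ns = np.array([(groups == g).sum() for g in labels])
    ses = np.array([values[groups == g].std(ddof=1) / np.sqrt(n)
                    for g, n in zip(labels, ns)])
    return duncan_from_summary(labels, means, ses, ns, mse=anova.mse,
                               df_error=anova.df_error, alpha=alpha)


def duncan_from_summary(labels, means, ses, ns, mse: float | None = None,
                        df_error: int | None = None, alpha: float = 0.05
                        ) -> DuncanResult:
    """Duncan letters from per-group summaries.

    When ``mse`` is not given it is reconstructed from the standard errors
    as mean(n * SE^2) under homoscedasticity, which lets published
    mean +/- SE tables be re-lettered without raw data.
    """
    labels = np.asarray(labels)
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    if mse is None:
        mse = float(np.mean(ns * ses ** 2))
    if df_error is None:
        df_error = int(ns.sum() - k)
    n_harm = k / np.sum(1.0 / ns)

    order = np.argsort(-means, kind="stable")  # descending; ties by input order
    means_desc = means[order]
    if mse == 0.0:
        sig = ~np.isclose(means_desc[:, None], means_desc[None, :])
    else:
        lsr = _least_significant_ranges(k, mse, n_harm, df_error, alpha)
        sig = _range_significant(means_desc, lsr)
    letters_desc = _assign_letters(sig)
    letters = np.empty(k, dtype=object)
    letters[order] = letters_desc

    table = pd.DataFrame({"mean": means, "se": ses, "n": ns.astype(int),
                          "letters": letters}, index=pd.Index(labels, name="group"))
    return DuncanResult(table=table, alpha=alpha, mse=float(mse),
                        df_error=int(df_error))


def percent_change(treatment_value: float, reference_value: float) -> float:
    """Percent change of a treatment value relative to a reference."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (treatment_value - reference_value) / reference_value


def treatment_summary(values, groups, alpha: float = 0.05,
                      reference: str = "CK") -> pd.DataFrame:
    """Per-group mean, SE, Duncan letters and percent change vs a reference."""
    res = duncan_letters(values, groups, alpha=alpha)
    tab = res.table.copy()
    if reference in tab.index and tab.loc[reference, "mean"] > 0:
        base = tab.loc[reference, "mean"]
        tab["pct_vs_" + reference] = [percent_change(m, base) for m in tab["mean"]]
    return tab
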