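"""Chronosequence statistics: ANOVA with Tukey letters, OLS model selection,
collinearity screening and relative-importance decomposition.

The statistical layer mirrors a common ecology workflow: transect contrasts
by one-way ANOVA with Tukey grouping letters; flux-vs-stocks linkage by
multiple linear regression with backward deletion under AIC; collinearity
screened by variance inflation factors; and the explained variance of the
final model decomposed into per-predictor shares by the LMG method
(incremental R2 averaged over all predictor orderings).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_letters: dict   # group label -> letter string, e.g. "ab"
    pairwise_p: dict      # frozenset({g1, g2}) -> Tukey adjusted p


@dataclass(frozen=True)
class ModelFit:
    """OLS fit summary.

    AIC uses the Gaussian form n*ln(RSS/n) + 2*(p+2) with p predictors
    (p+1 mean parameters plus the error variance); it differs from R's
    ``AIC()`` by the additive constant n + n*ln(2*pi), which cancels in
    every model comparison.
    """

    response: str
    predictors: tuple
    coefficients: dict
    intercept: float
    multiple_r2: float
    aic: float
    residual_se: float
    n: int


def one_way_anova(groups: dict[str, np.ndarray], alpha: float = 0.05,
                  ) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD compact letter display.

    Pairwise comparisons use the studentized range on the within-group
    mean square, with the harmonic mean of the two group sizes when the
    design is unbalanced.  Groups sharing a letter are not significantly
    different at ``alpha``.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(groups[k], dtype=float) for k in labels}
    for k, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    k = len(labels)
    n_total = sum(len(v) for v in data.values())
    grand = np.mean(np.concatenate(list(data.values())))
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, n_total - k
    msw = ssw / df_w
    if msw == 0.0:
        f_stat = 0.0 if ssb == 0.0 else float("inf")
        p_value = 1.0 if ssb == 0.0 else 0.0
    else:
        f_stat = (ssb / df_b) / msw
        p_value = float(sps.f.sf(f_stat, df_b, df_w))

    pairwise: dict[frozenset, float] = {}
    for g1, g2 in itertools.combinations(labels, 2):
        v1, v2 = data[g1], data[g2]
        if msw == 0.0:
            p = 1.0 if v1.mean() == v2.mean() else 0.0
        else:
            n_h = 2.0 / (1.0 / len(v1) + 1.0 / len(v2))   # harmonic mean size
            q = abs(v1.mean() - v2.mean()) / math.sqrt(msw / n_h)
            p = float(sps.studentized_range.sf(q, k, df_w))
        pairwise[frozenset((g1, g2))] = p

    letters = compact_letter_display(labels, pairwise, alpha)
    return AnovaResult(f_stat=float(f_stat), df_between=df_b, df_within=df_w,
                       p_value=p_value, group_letters=letters,
                       pairwise_p=pairwise)


def compact_letter_display(labels: list[str], pairwise_p: dict,
                           alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Guarantees: two groups share a letter iff they are connected by a
    chain of non-significant pairs within one letter set, and every
    non-significant pair shares at least one letter.
    """
    # letter sets start as one set containing everything, then each
    # significant pair splits every set containing both
    sets: list[set] = [set(labels)]
    for pair, p in sorted(pairwise_p.items(), key=lambda kv: tuple(sorted(kv[0]))):
        if p >= alpha:
            continue
        g1, g2 = sorted(pair)
        new_sets = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.append(s - {g1})
                new_sets.append(s - {g2})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [s for s in new_sets
                if not any(s < t for t in new_sets) and s]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: sorted(s))
    out = {g: "" for g in labels}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in sorted(s):
            out[g] += letter
    return out


def _design(X: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    return sm.add_constant(X, has_constant="add")


def ols_fit(y, X: pd.DataFrame, response: str = "y") -> ModelFit:
    """Multiple linear regression by ordinary least squares."""
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if p and np.linalg.matrix_rank(_design(X).to_numpy()) < p + 1:
        raise ValueError(
            f"rank-deficient design; collinear columns among {list(X.columns)}")
    res = sm.OLS(y, _design(X)).fit()
    rss = float(res.ssr)
    aic = n * math.log(rss / n) + 2 * (p + 2) if rss > 0 else -math.inf
    return ModelFit(
        response=response, predictors=tuple(X.columns),
        coefficients={c: float(res.params[c]) for c in X.columns},
        intercept=float(res.params["const"]),
        multiple_r2=float(res.rsquared) if p else 0.0,
        aic=aic,
        residual_se=float(np.sqrt(rss / (n - p - 1))),
        n=n)


def backward_aic(y, X: pd.DataFrame, response: str = "y") -> ModelFit:
    """Backward deletion under AIC.

    Repeatedly removes the predictor whose removal lowers AIC most and
    stops when no removal lowers AIC.  Ties break deterministically by
    predictor name order.  The result never has higher AIC than the full
    model.
    """
    X = pd.DataFrame(X)
    current = ols_fit(y, X, response)
    kept = list(X.columns)
    while len(kept) > 1:
        candidates = []
        for col in sorted(kept):
            reduced = ols_fit(y, X[[c for c in kept if c != col]], response)
            candidates.append((reduced.aic, col, reduced))
        best_aic, best_col, best_fit = min(candidates, key=lambda t: (t[0], t[1]))
        if best_aic < current.aic:
            current = best_fit
            kept = [c for c in kept if c != best_col]
        else:
            break
    return current


def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1/(1 - R2_j).

    R2_j is from regressing predictor j (with intercept) on the others.
    Perfect collinearity is reported as ``inf`` rather than raised.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        res = sm.OLS(X[col].to_numpy(), _design(others)).fit()
        r2 = float(res.rsquared)
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _r2_subset(y: np.ndarray, Xv: np.ndarray, cols: tuple) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n)] + [Xv[:, j] for j in cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid ** 2).sum() / tss if tss > 0 else 0.0


@dataclass(frozen=True)
class LmgShares:
    shares: dict          # predictor -> share of R2
    total: float          # = multiple R2 of the full model

    def normalized(self) -> dict:
        return {k: v / self.total for k, v in self.shares.items()}


def lmg_shares(y, X: pd.DataFrame) -> LmgShares:
    """LMG relative-importance decomposition of the full-model R2.

    Equals the average over all p! predictor orderings of each predictor's
    incremental R2; computed via the equivalent subset-weighted sum over
    the 2^p submodels.  Shares are non-negative for standard designs and
    sum exactly to the full-model R2.  Refuses p > 10 (exponential cost).
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    p = len(cols)
    if p > 10:
        raise ValueError("LMG enumeration limited to p <= 10; use a subset")
    if p == 0:
        raise ValueError("need at least one predictor")
    Xv = X.to_numpy()
    r2_cache: dict[tuple, float] = {(): 0.0}
    for size in range(1, p + 1):
        for subset in itertools.combinations(range(p), size):
            r2_cache[subset] = _r2_subset(y, Xv, subset)
    shares = {}
    for j in range(p):
        rest = [i for i in range(p) if i != j]
        total = 0.0
        for size in range(p):
            w = (math.factorial(size) * math.factorial(p - size - 1)
                 / math.factorial(p))
            for subset in itertools.combinations(rest, size):
                with_j = tuple(sorted(subset + (j,)))
                total += w * (r2_cache[with_j] - r2_cache[subset])
        shares[cols[j]] = total
    return LmgShares(shares=shares, total=r2_cache[tuple(range(p))])


def export_mixed_model_design(df: pd.DataFrame, response: str,
                              fixed: list[str], random: list[str],
                              path) -> pd.DataFrame:
    """Assemble and write the long-format design for external mixed-model
    fitting (e.g. lme4); mixed models themselves are out of scope here."""
    cols = [response] + list(fixed) + list(random)
    out = df[cols].copy()
    out.to_csv(path, index=False)
    return out
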