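"""The inferential battery for postvaccination fever comparisons.

* Welch two-sample t tests (antipyretic vs no-antipyretic contrasts);
* one-way ANOVA across vaccines with a Levene homogeneity check (absolute
  deviations from group means);
* Dunnett T3 post hoc pairwise comparisons — Welch-type standardized mean
  differences referred to the studentized maximum modulus (SMM)
  distribution with ``k(k-1)/2`` comparisons and per-pair Satterthwaite
  degrees of freedom — chosen when Levene rejects homogeneity;
* binary logistic regression of high fever (Tmax >= 39.0 °C) on age,
  weight and sex, with Wald intervals and a variance-inflation-factor
  screen for the collinear age/weight pair.

Sex is coded female = 0 (reference), male = 1. Confidence intervals use the
normal quantile 1.959964, i.e. ``exp(B ± 1.96·SE)`` on the odds-ratio scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

Z_975 = 1.959964  # normal 97.5% quantile used for all Wald intervals


class SeparationError(RuntimeError):
    """Perfect separation: the likelihood has no finite maximiser."""


class ConvergenceError(RuntimeError):
    """Iteratively reweighted least squares failed to converge."""


# ---------------------------------------------------------------------------
# Welch t test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    mean_difference: float
    t_statistic: float
    df: float
    p_value: float
    degenerate: bool = False


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    Uses the Satterthwaite degrees-of-freedom approximation. When both
    samples have zero variance and equal means the statistic is undefined;
    the result is reported as t = 0, p = 1 with ``degenerate=True``.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    ma, mb = float(np.mean(a)), float(np.mean(b))
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    na, nb = len(a), len(b)
    diff = ma - mb
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if diff == 0.0:
            return TTestResult(ma, mb, 0.0, 0.0, na, nb, 0.0, 0.0,
                               float(na + nb - 2), 1.0, degenerate=True)
        return TTestResult(ma, mb, 0.0, 0.0, na, nb, diff,
                           math.copysign(math.inf, diff), float(na + nb - 2),
                           0.0, degenerate=True)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = diff / math.sqrt(se2)
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(ma, mb, math.sqrt(va), math.sqrt(vb), na, nb, diff, t, df, p)


# ---------------------------------------------------------------------------
# One-way ANOVA with Levene check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    levene_statistic: float
    levene_p: float
    group_means: Dict[str, float]
    group_sds: Dict[str, float]
    group_ns: Dict[str, int]
    degenerate: bool = False


def oneway_anova_with_levene(groups: Dict[str, Sequence[float]]) -> AnovaResult:
    """Classic one-way F test plus Levene's homogeneity-of-variance test.

    Levene's statistic uses absolute deviations from the group *means*.
    All-constant identical groups are degenerate: F is reported as 0 with
    ``degenerate=True``.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    values = list(arrays.values())
    means = {k: float(np.mean(a)) for k, a in arrays.items()}
    sds = {k: float(np.std(a, ddof=1)) for k, a in arrays.items()}
    ns = {k: len(a) for k, a in arrays.items()}
    df_b = len(arrays) - 1
    df_w = sum(ns.values()) - len(arrays)
    if all(np.ptp(a) == 0 for a in values) :
        within_zero = True
    else:
        within_zero = False
    if within_zero and len({float(np.mean(a)) for a in values}) <= 1:
        return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 1.0, means, sds, ns, degenerate=True)
    f, p = sps.f_oneway(*values)
    if not math.isfinite(f):
        f, p, degen = 0.0, 1.0, True
    else:
        degen = False
    lev, lev_p = sps.levene(*values, center="mean")
    if not math.isfinite(lev):
        lev, lev_p = 0.0, 1.0
    return AnovaResult(float(f), df_b, df_w, float(p), float(lev), float(lev_p),
                       means, sds, ns, degenerate=degen)


# ---------------------------------------------------------------------------
# Dunnett T3 post hoc
# ---------------------------------------------------------------------------

def smm_sf(t: float, n_comparisons: int, df: float, n_quad: int = 400) -> float:
    """Survival function of the studentized maximum modulus distribution.

    ``P(max_i |Z_i| / S >= t)`` for ``n_comparisons`` independent standard
    normals over a common chi scale ``S = sqrt(chi2_df / df)``, evaluated by
    Gauss–Legendre quadrature on the probability transform of the chi-square
    scale.
    """
    if t <= 0:
        return 1.0
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (nodes + 1.0)          # (0, 1)
    w = 0.5 * weights
    s = np.sqrt(sps.chi2.ppf(u, df) / df)
    inner = (2.0 * sps.norm.cdf(t * s) - 1.0) ** n_comparisons
    cdf = float(np.sum(w * inner))
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def smm_sf_mc(
    t: float, n_comparisons: int, df: float,
    n_draws: int = 1_000_000, seed: int = 0,
    _cache: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Seeded Monte Carlo estimate of :func:`smm_sf` (cross-check route)."""
    if _cache is None:
        rng = np.random.default_rng(seed)
        maxabs = np.max(np.abs(rng.standard_normal((n_draws, n_comparisons))), axis=1)
        u = rng.random(n_draws)
    else:
        maxabs, u = _cache
    s = np.sqrt(sps.chi2.ppf(u, df) / df)
    return float(np.mean(maxabs >= t * s))


@dataclass(frozen=True)
class PostHocResult:
    """All pairwise Dunnett T3 comparisons and the induced grouping."""

    pairs: pd.DataFrame            # group_a, group_b, mean_diff, se, t3, df, p_welch, p_adjusted, significant
    partition: List[List[str]]     # significance blocks, ordered by mean descending
    alpha: float
    n_comparisons: int


def dunnett_t3(
    groups: Dict[str, Sequence[float]],
    alpha: float = 0.05,
    method: str = "quadrature",
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> PostHocResult:
    """Dunnett T3 pairwise post hoc test for unequal variances.

    For each pair the statistic is the Welch-type standardized mean
    difference; its adjusted p value refers to the studentized maximum
    modulus distribution with ``k(k-1)/2`` comparisons and the pair's
    Satterthwaite degrees of freedom (``method='quadrature'`` integrates the
    SMM distribution numerically; ``method='mc'`` uses a seeded Monte Carlo
    with ``n_draws`` draws). Adjusted p values are never reported below the
    pair's unadjusted Welch p (multiplicity bound).

    The returned partition groups levels that are mutually non-significant
    at ``alpha``, ordered by group mean descending.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use welch_t_test for two groups")
    if method not in ("quadrature", "mc"):
        raise ValueError("method must be 'quadrature' or 'mc'")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    names = list(arrays.keys())
    k = len(names)
    m = k * (k - 1) // 2

    cache = None
    if method == "mc":
        rng = np.random.default_rng(seed)
        maxabs = np.max(np.abs(rng.standard_normal((n_draws, m))), axis=1)
        cache = (maxabs, rng.random(n_draws))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            welch = welch_t_test(arrays[names[i]], arrays[names[j]])
            t3 = abs(welch.t_statistic)
            if method == "quadrature":
                p_adj = smm_sf(t3, m, welch.df)
            else:
                p_adj = smm_sf_mc(t3, m, welch.df, _cache=cache)
            p_adj = min(1.0, max(p_adj, welch.p_value))
            rows.append(dict(
                group_a=names[i], group_b=names[j],
                mean_diff=welch.mean_difference,
                se=abs(welch.mean_difference / welch.t_statistic) if welch.t_statistic else
                   math.sqrt(welch.sd_a ** 2 / welch.n_a + welch.sd_b ** 2 / welch.n_b),
                t3=t3, df=welch.df, p_welch=welch.p_value, p_adjusted=p_adj,
                significant=p_adj < alpha,
            ))
    pairs = pd.DataFrame(rows)

    # union-find over non-significant pairs -> homogeneity blocks
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for r in rows:
        if not r["significant"]:
            ra, rb = find(r["group_a"]), find(r["group_b"])
            if ra != rb:
                parent[ra] = rb
    blocks: Dict[str, List[str]] = {}
    for n in names:
        blocks.setdefault(find(n), []).append(n)
    means = {n: float(np.mean(arrays[n])) for n in names}
    partition = sorted(blocks.values(), key=lambda b: -np.mean([means[n] for n in b]))
    for b in partition:
        b.sort(key=lambda n: -means[n])
    return PostHocResult(pairs, partition, alpha, m)


# ---------------------------------------------------------------------------
# Variance inflation factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VifReport:
    table: pd.DataFrame  # predictor, vif, flagged
    vif_limit: float

    @property
    def any_flagged(self) -> bool:
        return bool(self.table["flagged"].any())


def compute_vif(design: pd.DataFrame, vif_limit: float = 10.0) -> VifReport:
    """VIF per predictor via auxiliary least-squares regressions.

    ``VIF_j = 1 / (1 - R²_j)`` where ``R²_j`` is from regressing predictor
    ``j`` on the remaining predictors plus an intercept. Exactly collinear
    predictors are reported as ``inf`` and flagged.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 predictors")
    X = design.to_numpy(float)
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("predictors must be non-constant")
    rows = []
    for j, name in enumerate(cols):
        y = X[:, j]
        others = sm.add_constant(np.delete(X, j, axis=1))
        res = sm.OLS(y, others).fit()
        r2 = float(res.rsquared)
        vif = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append(dict(predictor=name, vif=vif,
                         flagged=(not math.isfinite(vif)) or vif >= vif_limit))
    return VifReport(pd.DataFrame(rows), vif_limit)


# ---------------------------------------------------------------------------
# Logistic regression for high fever
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Per-predictor estimates from the high-fever logistic model."""

    table: pd.DataFrame   # term, coef, se, wald_z, p_value, odds_ratio, ci_low, ci_high
    converged: bool
    n: int
    n_events: int
    log_likelihood: float
    vif: VifReport


def odds_ratio_from_coef(b: float, se: float) -> Tuple[float, float, float]:
    """Adjusted odds ratio and 95% Wald CI from a coefficient and its SE."""
    return math.exp(b), math.exp(b - Z_975 * se), math.exp(b + Z_975 * se)


def _separating_predictor(X: pd.DataFrame, y: np.ndarray) -> Optional[str]:
    for c in X.columns:
        x = X[c].to_numpy(float)
        if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
            return c
    return None


def fit_high_fever_logistic(
    data: pd.DataFrame,
    outcome: str = "high_fever",
    predictors: Sequence[str] = ("age_months", "weight_kg", "sex"),
    vif_limit: float = 10.0,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary high-fever outcome.

    ``data`` needs the outcome column (0/1 or boolean) and the predictor
    columns; a ``sex`` predictor is recoded female = 0, male = 1. Fitting is
    Newton-type iteratively reweighted least squares (likelihood tolerance
    ``tol``, at most ``maxiter`` iterations) with Wald standard errors from
    the inverse observed information. VIFs are computed on the design matrix
    before fitting.

    Raises
    ------
    SeparationError
        On perfect separation (names the separating predictor if one alone
        is responsible).
    ConvergenceError
        If the iteration limit is reached without convergence.
    """
    y = data[outcome].astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome needs at least one event and one non-event")
    X = pd.DataFrame(index=data.index)
    for p in predictors:
        if p == "sex":
            X["sex_male"] = (data["sex"] == "male").astype(float)
        else:
            X[p] = data[p].astype(float)
    if np.any(np.ptp(X.to_numpy(float), axis=0) == 0):
        raise ValueError("predictors must be non-constant")
    vif = compute_vif(X, vif_limit=vif_limit)

    design = sm.add_constant(X, prepend=True)
    model = sm.Logit(y, design)
    import warnings
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=PerfectSeparationWarning)
            res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=False)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        culprit = _separating_predictor(X, y)
        raise SeparationError(
            "perfect separation"
            + (f" by predictor {culprit!r}" if culprit else "")) from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"IRLS did not converge: {res.mle_retvals}")

    rows = []
    for term in design.columns:
        b = float(res.params[term])
        se = float(res.bse[term])
        orr, lo, hi = odds_ratio_from_coef(b, se)
        z = b / se if se > 0 else math.inf
        rows.append(dict(term=term, coef=b, se=se, wald_z=z,
                         p_value=2.0 * float(sps.norm.sf(abs(z))),
                         odds_ratio=orr, ci_low=lo, ci_high=hi))
    table = pd.DataFrame(rows)
    return LogisticFit(table, bool(res.mle_retvals["converged"]), len(y),
                       int(y.sum()), float(res.llf), vif)
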