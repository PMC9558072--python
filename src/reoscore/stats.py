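"""Survival and association statistics used to evaluate gene-pair signatures.

Implements the Mantel–Haenszel log-rank test (also in a form vectorised over
many candidate pairs, which the discovery survival screen relies on), the
Kaplan–Meier product-limit estimator, Cox proportional-hazards regression with
Breslow tie handling, the Wilcoxon–Mann–Whitney rank-sum test, 2x2 odds
ratios with Woolf confidence intervals, cross-platform pair-score concordance
and score–marker rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "KmCurve",
    "LogrankResult",
    "CoxFit",
    "logrank_test",
    "logrank_test_matrix",
    "km_estimate",
    "odds_ratio",
    "response_table",
    "rank_sum_test",
    "cox_multivariate",
    "cox_partial_loglik",
    "platform_concordance",
    "score_marker_correlation",
    "group_score_comparison",
    "bh_adjust",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return sps.false_discovery_control(np.asarray(p, dtype=float), method="bh")


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float


def logrank_test_matrix(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mantel–Haenszel log-rank for many binary groupings of one cohort.

    ``groups`` is a (P, n) 0/1 array; row p splits the n subjects into group 1
    (entries 1) versus group 0. Returns ``(chi2, p, valid)`` arrays of length
    P; rows whose hypergeometric variance is zero (e.g. a constant grouping)
    are marked invalid with NaN statistics.

    At each distinct event time t the observed group-1 events d1 are compared
    with the expectation d * n1 / n under the hypergeometric draw of d events
    from the risk set (n at risk, n1 of them in group 1); the statistic is
    ``(sum d1 - sum d*n1/n)^2 / sum Var`` on 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.atleast_2d(np.asarray(groups, dtype=np.int8))
    n = time.size
    if event.size != n or groups.shape[1] != n:
        raise ValidationError("time, event and groups must agree in length")
    if event.sum() == 0:
        raise ValidationError("log-rank needs at least one event")

    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(bool), groups[:, order]

    # group-1 at-risk counts: suffix sums over the time-sorted cohort
    n1_suffix = np.cumsum(g[:, ::-1].astype(np.int64), axis=1)[:, ::-1]

    uniq_t, first_idx = np.unique(t, return_index=True)
    tid = np.searchsorted(uniq_t, t)
    d = np.bincount(tid[e], minlength=uniq_t.size).astype(float)
    has_ev = d > 0

    # group-1 events per distinct event time
    ev_tid = tid[e]
    onehot = np.zeros((ev_tid.size, uniq_t.size))
    onehot[np.arange(ev_tid.size), ev_tid] = 1.0
    d1 = g[:, e].astype(float) @ onehot  # (P, T)

    n_at = (n - first_idx).astype(float)
    n1_at = n1_suffix[:, first_idx].astype(float)

    d, n_at = d[has_ev], n_at[has_ev]
    d1, n1_at = d1[:, has_ev], n1_at[:, has_ev]

    frac = n1_at / n_at
    o1 = d1.sum(axis=1)
    e1 = (d * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vt = d * frac * (1.0 - frac) * (n_at - d) / (n_at - 1.0)
    vt = np.where(n_at > 1.0, vt, 0.0)
    v = vt.sum(axis=1)

    valid = v > 0
    chi2 = np.full(groups.shape[0], np.nan)
    p = np.full(groups.shape[0], np.nan)
    chi2[valid] = (o1[valid] - e1[valid]) ** 2 / v[valid]
    p[valid] = sps.chi2.sf(chi2[valid], df=1)
    return chi2, p, valid


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group Mantel–Haenszel log-rank test.

    ``group`` holds exactly two distinct labels; each group needs at least two
    subjects and the pooled data at least one event.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {labels.size}")
    ind = (group == labels[1]).astype(np.int8)
    if ind.sum() < 2 or (1 - ind).sum() < 2:
        raise ValidationError("each group needs at least 2 subjects")
    chi2, p, valid = logrank_test_matrix(time, event, ind[None, :])
    if not valid[0]:
        # identical event pattern in both groups at every time -> no variance;
        # by symmetry there is no evidence of a difference
        return LogrankResult(0.0, 1.0)
    return LogrankResult(float(chi2[0]), float(p[0]))


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate: survival probability after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): probability of surviving beyond time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(time, event) -> KmCurve:
    """Kaplan–Meier product-limit estimator.

    Censored subjects leave the risk set without contributing a step; with no
    events the curve is flat at 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValidationError("need at least one subject")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order].astype(bool)
    uniq_t, first_idx = np.unique(t, return_index=True)
    tid = np.searchsorted(uniq_t, t)
    d = np.bincount(tid[e], minlength=uniq_t.size)
    n_at = t.size - first_idx
    has_ev = d > 0
    et, dd, nn = uniq_t[has_ev], d[has_ev], n_at[has_ev]
    surv = np.cumprod(1.0 - dd / nn)
    return KmCurve(event_times=et, survival=surv, at_risk=nn, n_events=dd)


# ---------------------------------------------------------------------------
# 2x2 tables / odds ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out rows = {high, low} score group, columns = {responder, non-responder}.

    ``a``: high & responder, ``b``: high & non-responder,
    ``c``: low & responder, ``d``: low & non-responder.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValidationError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("table must contain at least one subject")

    @property
    def responder_high_fraction(self) -> float:
        """Fraction of responders falling in the high-score group."""
        if self.a + self.c == 0:
            raise ValidationError("no responders in table")
        return self.a / (self.a + self.c)

    @property
    def non_responder_low_fraction(self) -> float:
        if self.b + self.d == 0:
            raise ValidationError("no non-responders in table")
        return self.d / (self.b + self.d)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None


def odds_ratio(table: ContingencyTable2x2) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with a Woolf 95% confidence interval.

    A zero in ``b`` or ``c`` leaves the odds ratio infinite/undefined and
    raises; no continuity correction is applied. The CI is omitted (None) when
    any cell is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        raise ValidationError("odds ratio undefined/infinite: zero in cell b or c")
    or_ = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        return OddsRatioResult(or_, None, None)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return OddsRatioResult(
        or_, float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))
    )


def response_table(strata: pd.Series, response: pd.Series) -> ContingencyTable2x2:
    """Build the high/low x responder/non-responder table from labelled series.

    ``strata`` holds 'high'/'low', ``response`` holds 'responder'/'non_responder';
    samples with a missing response are dropped.
    """
    df = pd.DataFrame({"s": strata, "r": response}).dropna()
    return ContingencyTable2x2(
        a=int(((df.s == "high") & (df.r == "responder")).sum()),
        b=int(((df.s == "high") & (df.r == "non_responder")).sum()),
        c=int(((df.s == "low") & (df.r == "responder")).sum()),
        d=int(((df.s == "low") & (df.r == "non_responder")).sum()),
    )


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 20


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney test; returns (U of x, p).

    For pooled sample sizes up to 20 the null distribution is enumerated
    exactly (full permutation enumeration when ties are present); larger
    samples use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= _EXACT_MAX_N:
        if has_ties:
            method = sps.PermutationMethod(n_resamples=250_000, rng=0)
        else:
            method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def group_score_comparison(scores: pd.Series, labels: pd.Series) -> dict:
    """Compare signature scores between two labelled groups (rank-sum test).

    Returns group means, the Mann–Whitney U and p, and which group scores
    higher on average.
    """
    df = pd.DataFrame({"score": scores, "label": labels}).dropna()
    groups = sorted(df.label.unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    g0 = df.score[df.label == groups[0]].to_numpy()
    g1 = df.score[df.label == groups[1]].to_numpy()
    u, p = rank_sum_test(g0, g1)
    means = {groups[0]: float(g0.mean()), groups[1]: float(g1.mean())}
    if means[groups[0]] == means[groups[1]]:
        higher = None
    else:
        higher = max(means, key=means.get)
    return {"means": means, "statistic": u, "p_value": p, "higher_group": higher}


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit.

    ``summary`` rows are covariates with columns coef, hazard_ratio, se, z,
    p_value. When the fit is flagged (non-convergence / monotone likelihood)
    hazard ratios are not reported (NaN).
    """

    summary: pd.DataFrame
    converged: bool
    iterations: int
    log_likelihood: float
    flag: str | None = None


def _cox_sufficient(time, event, X):
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order].astype(bool), X[order]
    uniq_t, first_idx = np.unique(t, return_index=True)
    tid = np.searchsorted(uniq_t, t)
    return t, e, x, uniq_t, first_idx, tid


def cox_partial_loglik(time, event, X, beta) -> float:
    """Breslow partial log-likelihood at ``beta`` (exposed for diagnostics)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != time.size:
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, float))
    t, e, x, uniq_t, first_idx, tid = _cox_sufficient(time, event, X)
    eta = x @ beta
    w = np.exp(eta)
    s0_suffix = np.cumsum(w[::-1])[::-1]
    ll = 0.0
    for j in np.flatnonzero(e):
        ll += eta[j] - np.log(s0_suffix[first_idx[tid[j]]])
    return float(ll)


def cox_multivariate(
    time,
    event,
    covariates: pd.DataFrame,
    *,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Multivariate Cox regression via Newton–Raphson on the Breslow partial likelihood.

    Covariates must be numeric (binary-coded where categorical). Requires at
    least 10 events. Convergence is declared when the largest score-gradient
    component (on the internally standardised scale) falls below ``tol``;
    non-convergence or a monotone likelihood (perfect separation) flags the
    fit and suppresses hazard ratios.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(covariates)
    names = list(covariates.columns)
    X = covariates.to_numpy(dtype=float)
    n, p = X.shape
    if n != time.size:
        raise ValidationError("covariate rows must match subjects")
    if event.sum() < 10:
        raise ValidationError("Cox fit requires at least 10 events")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant covariates: {bad}")
    center = X.mean(axis=0)
    Z = (X - center) / sd

    t, e, z, uniq_t, first_idx, tid = _cox_sufficient(time, event, Z)
    ev_idx = np.flatnonzero(e)
    ev_first = first_idx[tid[ev_idx]]  # risk-set start row for each event

    def derivatives(beta):
        eta = z @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * z)[::-1], axis=0)[::-1]
        zz = z[:, :, None] * z[:, None, :]
        s2 = np.cumsum((w[:, None, None] * zz)[::-1], axis=0)[::-1]
        ll = float(np.sum(eta[ev_idx] - np.log(s0[ev_first])))
        mean_z = s1[ev_first] / s0[ev_first, None]
        grad = z[ev_idx].sum(axis=0) - mean_z.sum(axis=0)
        cov = s2[ev_first] / s0[ev_first, None, None] - mean_z[:, :, None] * mean_z[:, None, :]
        hess = -cov.sum(axis=0)
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = derivatives(beta)
    converged = False
    flag = None
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            flag = "singular information matrix"
            break
        # step-halving if the likelihood does not improve
        scale_step = 1.0
        for _ in range(30):
            cand = beta + scale_step * step
            ll_new, grad_new, hess_new = derivatives(cand)
            if ll_new >= ll - 1e-12:
                break
            scale_step /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 10.0:
            flag = "monotone likelihood (possible perfect separation)"
            break
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    if converged and np.max(np.abs(beta)) > 10.0:
        converged = False
        flag = flag or "monotone likelihood (possible perfect separation)"
    if not converged and flag is None:
        flag = "did not converge"

    coef = beta / sd
    if converged:
        info = -hess
        se_std = np.sqrt(np.diag(np.linalg.inv(info)))
        se = se_std / sd
        zval = coef / se
        pval = 2.0 * sps.norm.sf(np.abs(zval))
        hr = np.exp(coef)
    else:
        se = np.full(p, np.nan)
        zval = np.full(p, np.nan)
        pval = np.full(p, np.nan)
        hr = np.full(p, np.nan)
        coef = np.full(p, np.nan)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hazard_ratio": hr,
            "se": se,
            "z": zval,
            "p_value": pval,
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxFit(
        summary=summary,
        converged=converged,
        iterations=it,
        log_likelihood=ll,
        flag=flag,
    )


# ---------------------------------------------------------------------------
# cross-platform concordance & marker correlation
# ---------------------------------------------------------------------------

def platform_concordance(
    pairs_x: pd.DataFrame,
    pairs_y: pd.DataFrame,
    *,
    threshold: float = 0.7,
) -> tuple[pd.Series, dict]:
    """Per-pair agreement of 0/1 pair scores between two platforms.

    Both inputs are pair-by-sample 0/1 tables over the same signature and the
    same (matched) samples. Per pair, concordance is the fraction of samples
    whose score agrees on both platforms; the summary reports the fraction of
    pairs with concordance strictly above ``threshold`` (0.7 by default, the
    customary reporting cut for cross-platform agreement).
    """
    if set(pairs_x.index) != set(pairs_y.index):
        raise ValidationError("pair sets differ between platforms")
    if set(pairs_x.columns) != set(pairs_y.columns):
        raise ValidationError("matched sample sets differ between platforms")
    if pairs_x.shape[1] == 0:
        raise ValidationError("need at least one matched sample")
    y = pairs_y.loc[pairs_x.index, pairs_x.columns]
    conc = (pairs_x.to_numpy() == y.to_numpy()).mean(axis=1)
    per_pair = pd.Series(conc, index=pairs_x.index, name="concordance")
    summary = {
        "n_pairs": int(per_pair.size),
        "n_samples": int(pairs_x.shape[1]),
        "threshold": threshold,
        "frac_pairs_above_threshold": float((per_pair > threshold).mean()),
        "mean_concordance": float(per_pair.mean()),
    }
    return per_pair, summary


def score_marker_correlation(
    scores: pd.Series, expr, marker_genes
) -> pd.DataFrame:
    """Spearman correlation between the signature score and each marker gene.

    Missing markers and constant markers are reported with a reason instead of
    a coefficient; BH adjustment runs across the testable markers.
    """
    rows = []
    samples = [s for s in scores.index if s in set(expr.sample_ids)]
    if not samples:
        raise ValidationError("no overlap between scored samples and expression matrix")
    sc = scores.loc[samples].to_numpy(dtype=float)
    col_idx = [expr.sample_ids.index(s) for s in samples]
    for g in marker_genes:
        if not expr.has_gene(g):
            rows.append({"marker": g, "rho": np.nan, "p_value": np.nan, "note": "missing"})
            continue
        v = expr.row(g)[col_idx]
        if np.unique(v).size == 1:
            rows.append({"marker": g, "rho": np.nan, "p_value": np.nan, "note": "constant"})
            continue
        rho, p = sps.spearmanr(sc, v)
        rows.append({"marker": g, "rho": float(rho), "p_value": float(p), "note": ""})
    out = pd.DataFrame(rows).set_index("marker")
    testable = out["p_value"].notna()
    out["fdr"] = np.nan
    if testable.any():
        out.loc[testable, "fdr"] = bh_adjust(out.loc[testable, "p_value"].to_numpy())
    return out
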