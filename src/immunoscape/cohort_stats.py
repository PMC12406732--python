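"""Cohort-level biomarker statistics and survival machinery.

Conventions follow common clinical-imaging practice: Mann-Whitney tests are
two-sided by default (exact when sample sizes allow and no ties are present,
normal approximation with tie correction otherwise); Pearson correlations
are computed within outcome groups; outliers can be excluded by a
ROUT-style robust-regression/FDR procedure (median/MAD location-scale,
FDR-controlled flagging at rate Q); survival curves are product-limit
estimates compared by the Gehan-Breslow-Wilcoxon weighted log-rank test with
Mantel-Haenszel hazard ratios.  Significance is declared at P ≤ 0.05 with no
multiplicity correction; every report states the number of tests performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_LEVEL = 0.05
EXACT_MW_MAX_PRODUCT = 10_000


def ratio_biomarker(numerator, denominator) -> np.ndarray:
    """Element-wise per-sample ratio; zero or non-finite denominator → NaN."""
    num, den = np.broadcast_arrays(np.asarray(numerator, float),
                                   np.asarray(denominator, float))
    out = np.full(num.shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
    out[ok] = num[ok] / den[ok]
    return out


def mann_whitney(a, b, sides: int = 2) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of the first sample, P).

    Exact null enumeration when n_a·n_b ≤ 10,000 and the pooled data are
    tie-free; otherwise the normal approximation with tie correction.
    Identical samples return P = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs at least one value")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= EXACT_MW_MAX_PRODUCT and not ties) \
        else "asymptotic"
    alternative = "two-sided" if sides == 2 else "less"
    if sides == 1:
        # one-tailed in the direction of the observed shift
        alternative = "greater" if np.median(a) > np.median(b) else "less"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with t-distribution P (n−2 df); degenerate input → NaN."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def robust_outlier_exclusion(values, q_percent: float = 1.0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """ROUT-style outlier exclusion: robust location/scale + FDR flagging.

    Residuals from the median are scaled by the MAD-derived robust SD
    (1.4826·MAD); two-sided t-tail probabilities (n−1 df) are flagged by
    Benjamini-Hochberg at rate Q (percent).  Fewer than 5 values → nothing
    excluded.  Returns (kept values, excluded integer indices); the
    exclusion set is invariant to input order.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 5:
        return v.copy(), np.array([], dtype=int)
    med = np.median(v)
    resid = np.abs(v - med)
    rsd = 1.4826 * np.median(resid)
    if rsd == 0:
        flags = resid > 0
    else:
        t = resid / rsd
        p = 2.0 * stats.t.sf(t, df=n - 1)
        order = np.argsort(p, kind="stable")
        q = q_percent / 100.0
        thresh = q * (np.arange(1, n + 1)) / n
        passed = p[order] <= thresh
        flags = np.zeros(n, bool)
        if passed.any():
            kmax = np.max(np.flatnonzero(passed))
            flags[order[:kmax + 1]] = True
    return v[~flags], np.flatnonzero(flags)


# --------------------------------------------------------------------------
# survival

@dataclass
class SurvivalResult:
    curves: dict                     # group -> DataFrame(time, survival)
    gbw_statistic: float
    gbw_p: float
    hazard_ratio: float              # first group vs second (sorted labels)
    hr_ci: tuple[float, float]
    groups: tuple[str, str]
    n_events: int


def _logrank_tables(times, events, mask1):
    """Per-event-time 2×2 quantities for the log-rank family.

    Returns arrays (d1, d, n1, n) at each distinct event time.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    mask1 = np.asarray(mask1, bool)
    ts = np.unique(times[events == 1])
    d1 = np.zeros(len(ts))
    d = np.zeros(len(ts))
    n1 = np.zeros(len(ts))
    n = np.zeros(len(ts))
    for k, t in enumerate(ts):
        at_risk = times >= t
        n[k] = at_risk.sum()
        n1[k] = (at_risk & mask1).sum()
        dead = (times == t) & (events == 1)
        d[k] = dead.sum()
        d1[k] = (dead & mask1).sum()
    return d1, d, n1, n


def mantel_haenszel_hr(times, events, groups) -> tuple[float, tuple[float, float]]:
    """Mantel-Haenszel hazard ratio of group₁ vs group₂ with 95% CI.

    HR = exp((O₁−E₁)/V) with the log-rank expectation E₁ and variance V;
    CI = exp((O₁−E₁)/V ± 1.96/√V).  No events → NaN.
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError("hazard ratio requires exactly two groups")
    mask1 = groups == labels[0]
    d1, d, n1, n = _logrank_tables(times, events, mask1)
    if d.sum() == 0:
        return float("nan"), (float("nan"), float("nan"))
    e1 = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    v = np.nan_to_num(v)
    V = v.sum()
    if V == 0:
        return float("nan"), (float("nan"), float("nan"))
    z = (d1.sum() - e1.sum()) / V
    hr = float(np.exp(z))
    half = 1.96 / np.sqrt(V)
    return hr, (float(np.exp(z - half)), float(np.exp(z + half)))


def km_survival(times, events, groups) -> SurvivalResult:
    """Product-limit curves + Gehan-Breslow-Wilcoxon test + MH hazard ratio.

    The GBW test is the log-rank test weighted by the number at risk,
    sensitive to early differences.  Curves start at S(0)=1 and are
    monotone nonincreasing.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need ≥ 2 groups")
    if (times < 0).any():
        raise ValueError("negative survival time")
    curves = {}
    for g in labels:
        m = groups == g
        kmf = KaplanMeierFitter().fit(times[m], events[m])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf.iloc[:, 0].to_numpy()})
    m1 = groups == labels[0]
    res = logrank_test(times[m1], times[~m1], events[m1], events[~m1],
                       weightings="wilcoxon")
    hr, ci = mantel_haenszel_hr(times, events, groups) if len(labels) == 2 \
        else (float("nan"), (float("nan"), float("nan")))
    return SurvivalResult(curves=curves,
                          gbw_statistic=float(res.test_statistic),
                          gbw_p=float(res.p_value),
                          hazard_ratio=hr, hr_ci=ci,
                          groups=(labels[0], labels[-1]),
                          n_events=int(events.sum()))


# --------------------------------------------------------------------------
# cohort report

@dataclass
class BiomarkerResult:
    metric: str
    group_values: dict
    test: str
    statistic: float
    p_value: float
    significant: bool
    excluded_ids: list = field(default_factory=list)


def cohort_report(cohort: pd.DataFrame, metric_cols: list[str],
                  group_col: str = "group",
                  correlation_pairs: list[tuple[str, str]] | None = None,
                  outlier_q_percent: float | None = None,
                  one_tailed_metrics: tuple[str, ...] = (),
                  ) -> dict:
    """Deceased-vs-alive comparison of every metric plus within-group
    correlations.

    Each metric gets a Mann-Whitney test (two-sided unless listed in
    ``one_tailed_metrics``); correlations are Pearson, computed within each
    group separately.  NaN sentinels are dropped per metric; optional
    ROUT-style outlier exclusion (rate Q percent) is applied per group and
    every exclusion is reported.  No multiplicity correction is applied
    (flagging at P ≤ 0.05); the report carries the number of tests.
    """
    groups = sorted(cohort[group_col].dropna().unique().tolist())
    if len(groups) < 2:
        raise ValueError("cohort report requires ≥ 2 groups")
    ga, gb = groups[0], groups[1]
    results: list[BiomarkerResult] = []
    for metric in metric_cols:
        parts = {}
        excluded: list = []
        for g in (ga, gb):
            vals = cohort.loc[cohort[group_col] == g, metric].to_numpy(float)
            ids = cohort.loc[cohort[group_col] == g].index.to_numpy()
            keep = np.isfinite(vals)
            vals, ids = vals[keep], ids[keep]
            if outlier_q_percent is not None and len(vals) >= 5:
                kept, out_idx = robust_outlier_exclusion(vals, outlier_q_percent)
                excluded.extend(ids[out_idx].tolist())
                vals = kept
            parts[g] = vals
        if len(parts[ga]) < 2 or len(parts[gb]) < 2:
            raise ValueError(f"metric {metric!r}: need ≥ 2 samples per group")
        sides = 1 if metric in one_tailed_metrics else 2
        u, p = mann_whitney(parts[ga], parts[gb], sides=sides)
        results.append(BiomarkerResult(
            metric=metric, group_values={g: v.tolist() for g, v in parts.items()},
            test=f"mann_whitney_{sides}sided", statistic=u, p_value=p,
            significant=bool(p <= SIGNIFICANCE_LEVEL),
            excluded_ids=excluded))

    correlations = []
    for xa, xb in (correlation_pairs or []):
        for g in (ga, gb):
            sub = cohort[cohort[group_col] == g]
            r, p = pearson(sub[xa], sub[xb])
            correlations.append({"x": xa, "y": xb, "group": g, "r": r,
                                 "p_value": p,
                                 "significant": bool(np.isfinite(p)
                                                     and p <= SIGNIFICANCE_LEVEL)})
    n_tests = len(results) + len(correlations)
    return {"results": results, "correlations": correlations,
            "n_tests": n_tests, "alpha": SIGNIFICANCE_LEVEL,
            "multiplicity_correction": "none (per-test P ≤ 0.05)"}
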