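"""Group comparisons, correlations and ROI connectivity statistics.

Thin, explicitly-conventioned wrappers: pooled-variance two-sample t
(two-tailed), Pearson correlation with the t-based two-tailed p, the
first-order partial correlation controlling for one covariate (age in
the intended use), the Fisher z (arctanh) transform, and Pearson + z
for ROI time-course pairs.  Results are returned as small dataclasses
and can be assembled into a tidy one-row-per-test table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["TTestResult", "CorrelationResult", "two_sample_ttest", "pearson",
           "partial_correlation", "fisher_z", "roi_connectivity",
           "correlation_table"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    controlled: tuple = ()
    fisher_z: float | None = None

    @property
    def df(self) -> int:
        return self.n - 2 - len(self.controlled)


def two_sample_ttest(a, b, welch: bool = False) -> TTestResult:
    """Two-sample t-test, two-tailed; pooled-variance (Student) by
    default, Welch's unequal-variance form on request.

    Degenerate case: zero pooled variance gives t=0, p=1 for equal means
    and a signed infinite t, p=0 for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    n1, n2 = len(a), len(b)
    if welch:
        res = _sps.ttest_ind(a, b, equal_var=False)
        return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                           df=int(np.floor(res.df)),
                           mean_a=float(a.mean()), mean_b=float(b.mean()))
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, p=1.0, df=df,
                               mean_a=float(a.mean()), mean_b=float(b.mean()))
        return TTestResult(t=float(np.sign(diff) * np.inf), p=0.0, df=df,
                           mean_a=float(a.mean()), mean_b=float(b.mean()))
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), p=float(p), df=df,
                       mean_a=float(a.mean()), mean_b=float(b.mean()))


def _r_to_p(r: float, df: int) -> float:
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * _sps.t.sf(abs(t), df))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-tailed t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, p=_r_to_p(r, n - 2), n=n)


def partial_correlation(x, y, z) -> CorrelationResult:
    """First-order partial correlation of x and y controlling z:

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

    identical to correlating the residuals of simple linear fits on z;
    p uses df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == n and len(z) == n):
        raise ValueError("inputs must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    r_xy = pearson(x, y).r
    r_xz = pearson(x, z).r
    r_yz = pearson(y, z).r
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise ValueError("covariate is collinear with an input; "
                         "partial correlation degenerate")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    return CorrelationResult(r=float(r), p=_r_to_p(float(r), n - 3), n=n,
                             controlled=("z",))


def fisher_z(r: float) -> float:
    """Variance-stabilizing arctanh transform; odd in r.  |r| = 1 maps
    to a signed infinity with a warning."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        warnings.warn("|r| = 1: Fisher z is infinite", stacklevel=2)
        return float(np.sign(r) * np.inf)
    return float(np.arctanh(r))


def roi_connectivity(tc1, tc2) -> CorrelationResult:
    """Pearson correlation of two ROI time courses plus its Fisher z."""
    tc1 = np.asarray(tc1, dtype=float)
    tc2 = np.asarray(tc2, dtype=float)
    if len(tc1) != len(tc2):
        raise ValueError("time courses must have equal length")
    res = pearson(tc1, tc2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = fisher_z(res.r)
    return CorrelationResult(r=res.r, p=res.p, n=res.n, fisher_z=z)


def correlation_table(rows) -> "pandas.DataFrame":
    """Tidy table from (name_x, name_y, CorrelationResult | TTestResult)
    triples, one row per test, with Benjamini-Hochberg adjusted p-values
    reported alongside for transparency (no correction is applied to the
    per-test decisions of the exploratory battery)."""
    import pandas as pd
    recs = []
    for name_x, name_y, res in rows:
        if isinstance(res, TTestResult):
            recs.append({"x": name_x, "y": name_y, "test": "t",
                         "stat": res.t, "df": res.df, "r": np.nan, "p": res.p,
                         "n": res.df + 2, "covariates": ""})
        else:
            recs.append({"x": name_x, "y": name_y, "test": "pearson"
                         if not res.controlled else "partial",
                         "stat": np.nan, "df": res.df, "r": res.r, "p": res.p,
                         "n": res.n, "covariates": ",".join(res.controlled)})
    df = pd.DataFrame(recs)
    if len(df):
        p = df["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            adj[i] = running
        df["p_bh"] = adj
    return df
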