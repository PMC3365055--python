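"""Microarray arm: quantile normalization and an empirical-Bayes moderated t-test.

The moderated test shrinks each gene's residual variance s2_g (pooled over the
two groups, d_g = n1 + n2 - 2 df) toward a prior s0^2 with d0 prior df:

    s~2_g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g)
    t~_g  = (mean2_g - mean1_g) / (s~_g * sqrt(1/n1 + 1/n2))

with p-values from a t distribution on d0 + d_g degrees of freedom.  The
hyperparameters (d0, s0^2) are estimated from the empirical distribution of
log s2_g by moment matching on the digamma/trigamma scale; when the trigamma
equation has no positive solution the prior is infinitely informative
(d0 = inf, every s~2 = s0^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .tables_io import IntensityMatrix, TableValidationError

log = logging.getLogger(__name__)


@dataclass
class ModeratedTResult:
    df: pd.DataFrame            # per-gene statistics; index = gene/probe id
    d0: float                   # prior degrees of freedom (may be inf)
    s0_sq: float                # prior variance
    group_a: str
    group_b: str

    @property
    def contrast(self) -> str:
        return f"{self.group_b}_vs_{self.group_a}"


def quantile_normalize(intens: IntensityMatrix) -> IntensityMatrix:
    """Force every sample onto the mean empirical distribution.

    Each sample's sorted vector becomes the across-sample mean of sorted
    vectors; ranks within a sample are preserved.  Tied values receive the
    average of the normalized values over the tied ranks.
    """
    vals = intens.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise TableValidationError("NaN/inf in intensity matrix")
    n, k = vals.shape
    sorted_cols = np.sort(vals, axis=0)
    mean_sorted = sorted_cols.mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(mean_sorted)])
    out = np.empty_like(vals)
    for j in range(k):
        uniq, inverse, counts = np.unique(vals[:, j], return_inverse=True,
                                          return_counts=True)
        ends = np.cumsum(counts)
        starts = ends - counts
        group_means = (csum[ends] - csum[starts]) / counts
        out[:, j] = group_means[inverse]
    df = pd.DataFrame(out, index=intens.values.index, columns=intens.values.columns)
    return IntensityMatrix(df, dict(intens.groups), intens.log2_scale)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, d_g: float) -> tuple[float, float]:
    """(d0, s0^2) from the empirical distribution of log s2 (moment matching).

    e_g = log s2_g - digamma(d_g/2) + log(d_g/2) is unbiased for log sigma2_g;
    its excess variance over trigamma(d_g/2) identifies trigamma(d0/2).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq[s_sq > 0]
    if pos.size < 20:
        warnings.warn(f"only {pos.size} positive variances for hyperparameter "
                      "estimation; prior will be unstable", stacklevel=2)
    if pos.size < 2:
        return np.inf, float(pos.mean()) if pos.size else 0.0
    e = np.log(pos) - digamma(d_g / 2.0) + np.log(d_g / 2.0)
    excess = e.var(ddof=1) - polygamma(1, d_g / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0_sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(norm: IntensityMatrix, group_a: str, group_b: str,
                d0: float | None = None, s0_sq: float | None = None
                ) -> ModeratedTResult:
    """Moderated two-sample t statistics for ``group_b`` vs ``group_a``.

    Pass d0/s0_sq explicitly to fix the prior (d0 = 0 recovers the ordinary
    pooled t-test); by default both are estimated from the data.
    """
    sa = norm.samples_in_group(group_a)
    sb = norm.samples_in_group(group_b)
    n1, n2 = len(sa), len(sb)
    if n1 < 2 or n2 < 2:
        raise TableValidationError(
            f"both groups need >= 2 samples (got {n1} vs {n2})")
    a = norm.values[sa].to_numpy(dtype=float)
    b = norm.values[sb].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    d_g = n1 + n2 - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / d_g

    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_prior(s_sq, d_g)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d_g * s_sq) / (d0 + d_g)
        df_total = d0 + d_g

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    delta = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        t_tilde = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        t_tilde = np.where((se == 0) & (delta != 0),
                           np.sign(delta) * np.inf, t_tilde)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_tilde))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_tilde), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    df = pd.DataFrame({
        f"mean_{group_a}": mean_a,
        f"mean_{group_b}": mean_b,
        "log2fc": delta,
        "s_sq": s_sq,
        "s_tilde_sq": s_tilde_sq,
        "t_tilde": t_tilde,
        "df_total": df_total,
        "p": p,
        "call": "none",
    }, index=norm.values.index)
    return ModeratedTResult(df=df, d0=float(d0), s0_sq=float(s0_sq),
                            group_a=group_a, group_b=group_b)


def call_array_de(result: ModeratedTResult, fold: float = 2.0,
                  p: float = 0.05) -> ModeratedTResult:
    """Apply the calling rule: linear fold change > ``fold`` and p < ``p``.

    The input log2FC is converted to a linear fold (so fold > 2 means
    |log2FC| > 1); both thresholds are strict.  Returns the result with the
    ``call`` and ``fold_change`` columns filled in.
    """
    df = result.df.copy()
    lfc = df["log2fc"].to_numpy()
    df["fold_change"] = np.power(2.0, np.abs(lfc))
    passed = (df["fold_change"].to_numpy() > fold) & (df["p"].to_numpy() < p)
    df["call"] = np.where(passed, np.where(lfc > 0, "up", "down"), "none")
    return ModeratedTResult(df=df, d0=result.d0, s0_sq=result.s0_sq,
                            group_a=result.group_a, group_b=result.group_b)


def collapse_probes(intens: IntensityMatrix, probe_to_symbol: pd.Series,
                    method: str = "max_mean") -> IntensityMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    ``max_mean`` keeps the probe with the largest mean intensity per symbol;
    ``mean`` averages all probes of a symbol.
    """
    sym = probe_to_symbol.reindex(intens.values.index).fillna("").astype(str).str.upper()
    keep = sym != ""
    vals = intens.values[keep]
    sym = sym[keep]
    if method == "max_mean":
        means = vals.mean(axis=1)
        order = means.groupby(sym.to_numpy()).idxmax()
        out = vals.loc[order.to_numpy()]
        out.index = order.index
    elif method == "mean":
        out = vals.groupby(sym.to_numpy()).mean()
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    out = out.sort_index()
    out.index.name = "symbol"
    return IntensityMatrix(out, dict(intens.groups), intens.log2_scale)
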