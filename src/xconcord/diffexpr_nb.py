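"""Negative-binomial differential expression without replicates.

The procedure mirrors the classic size-factor / pooled-variance approach for
count data: all samples are pooled into one "blind" pseudo-condition to
estimate a mean-variance relation v(m) = m + alpha * m^2 on the normalized
scale, deliberately over- rather than under-estimating within-condition
variation.  A gene's two condition totals are then compared with an exact-style
conditional test: given the total K = K_A + K_B, the p-value is the
probability, under independent NB models for the two conditions with a common
normalized mean, of any split (a, b), a + b = K, that is no more likely than
the observed one,

    p = sum_{P(a,b) <= P(obs)} P(a,b) / sum_{a+b=K} P(a,b).

Calling rules: a gene is differential when |log2FC| exceeds the logFC
threshold (default 2), the larger group base mean exceeds 10 (strict), and —
when replicates or grouped samples make the p-value meaningful — p < 0.05.
Single-sample contrasts may use the fold-only mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import CountMatrix
from .rnaseq_quant import normalized_counts

log = logging.getLogger(__name__)


@dataclass
class VarianceModel:
    """Mean-variance relation v(m) = m + alpha*m^2 on the normalized-count scale."""

    alpha: float
    n_genes: int
    method: str = "pooled-moments"

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")

    def variance(self, mean):
        """Raw variance at normalized mean ``mean`` (never below Poisson)."""
        m = np.asarray(mean, dtype=float)
        return m + self.alpha * m * m


@dataclass
class DEThresholds:
    logfc: float = 2.0          # |log2FC| must be strictly greater
    p: float = 0.05             # strict less-than (fc_and_p mode only)
    base_mean: float = 10.0     # max group base mean strictly greater
    epsilon: float = 1.0        # pseudocount on normalized means for log2FC


@dataclass
class DEResult:
    """Per-gene differential-expression table for one two-group contrast."""

    df: pd.DataFrame            # index gene_id; see call_de for columns
    contrast: str               # "B_vs_A"
    group_a: str
    group_b: str
    mode: str = "fc_and_p"

    def called(self, direction: str | None = None) -> set[str]:
        calls = self.df["call"]
        if direction is None:
            return set(self.df.index[calls != "none"])
        return set(self.df.index[calls == direction])


def fit_variance(counts: CountMatrix | pd.DataFrame, factors: pd.Series,
                 min_mean: float = 10.0) -> VarianceModel:
    """Estimate the dispersion alpha by pooling all samples as one condition.

    Method of moments: for each gene the cross-sample variance of normalized
    counts w_g has expectation m_g * mean(1/s_j) + alpha * m_g^2, so
    (w_g - m_g*xi) / m_g^2 estimates alpha gene-wise; these are combined by a
    regression of (w - m*xi) on m^2 weighted by 1/m^4 (equivalently the mean
    of the per-gene ratios), restricted to genes with normalized mean >= 10
    where the moment estimate is informative.  Clipped at zero.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("variance fitting needs at least 2 samples")
    if df.shape[0] < 50:
        warnings.warn(f"only {df.shape[0]} genes for variance fitting; "
                      "alpha estimate will be unstable", stacklevel=2)
    q = (df / factors).to_numpy(dtype=float)
    n = q.shape[1]
    m = q.mean(axis=1)
    w = q.var(axis=1, ddof=1)
    xi = float((1.0 / factors).mean())
    use = m >= min_mean
    if not use.any():
        use = m > 0
    m_, w_ = m[use], w[use]
    # m^2 - w/n is the unbiased moment for mu^2 (E[m^2] = mu^2 + v/n);
    # floored at a tenth of m^2 to keep degenerate genes from exploding
    denom = np.maximum(m_ * m_ - w_ / n, 0.1 * m_ * m_)
    ratios = (w_ - m_ * xi) / denom
    alpha = float(np.clip(ratios.mean(), 0.0, None)) if ratios.size else 0.0
    return VarianceModel(alpha=alpha, n_genes=int(use.sum()))


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of an NB (or Poisson when var <= mean) with given mean/variance."""
    k = np.asarray(k)
    if mean <= 0:
        out = np.full(k.shape, -np.inf, dtype=float)
        out[k == 0] = 0.0
        return out
    if var <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def _condition_moments(q_hat: float, factors: np.ndarray, alpha: float
                       ) -> tuple[float, float]:
    """Mean and variance of the summed counts of one condition at common
    normalized mean q_hat: totals of independent per-sample NB draws."""
    s = np.asarray(factors, dtype=float)
    mean = q_hat * s.sum()
    var = q_hat * s.sum() + alpha * q_hat * q_hat * (s * s).sum()
    return mean, var


def nb_test(counts_a, counts_b, factors_a, factors_b, model: VarianceModel) -> float:
    """Conditional NB test p-value for one gene.

    ``counts_a``/``counts_b`` are the per-sample counts of the two conditions
    (scalars or sequences), ``factors_a``/``factors_b`` the matching size
    factors.  Exactly symmetric under exchanging conditions (term
    probabilities are accumulated in sorted order).  K = 0 returns 1.
    """
    ka = int(np.sum(counts_a))
    kb = int(np.sum(counts_b))
    if ka < 0 or kb < 0:
        raise ValueError("counts must be non-negative")
    total = ka + kb
    if total == 0:
        return 1.0
    fa = np.atleast_1d(np.asarray(factors_a, dtype=float))
    fb = np.atleast_1d(np.asarray(factors_b, dtype=float))
    q_hat = total / (fa.sum() + fb.sum())
    mean_a, var_a = _condition_moments(q_hat, fa, model.alpha)
    mean_b, var_b = _condition_moments(q_hat, fb, model.alpha)

    a = np.arange(total + 1)
    logp = _nb_logpmf(a, mean_a, var_a) + _nb_logpmf(total - a, mean_b, var_b)
    log_obs = logp[ka]
    if not np.isfinite(log_obs):
        return 1.0
    shift = logp.max()
    probs = np.exp(logp - shift)
    # sorted accumulation => bit-identical result under condition exchange
    denom = float(np.sort(probs).sum())
    sel = probs[logp <= log_obs + 1e-10]
    numer = float(np.sort(sel).sum())
    return min(numer / denom, 1.0)


def call_de(gene_counts: CountMatrix, factors: pd.Series, model: VarianceModel,
            group_a: str, group_b: str,
            thresholds: DEThresholds | None = None,
            mode: str = "fc_and_p",
            symbols: pd.Series | None = None) -> DEResult:
    """Per-gene DE table for the contrast ``group_b`` vs ``group_a``.

    log2FC = log2((m_B + eps)/(m_A + eps)) on size-factor-normalized group
    means; calls require |log2FC| > logfc threshold, the larger group base
    mean > base_mean threshold, and (fc_and_p mode) p < p threshold.  A
    Benjamini-Hochberg q-value column is emitted for information only; the
    calling rule uses raw p.
    """
    if mode not in {"fc_only", "fc_and_p"}:
        raise ValueError(f"unknown mode {mode!r}")
    thr = thresholds or DEThresholds()
    samples_a = gene_counts.samples_in_group(group_a)
    samples_b = gene_counts.samples_in_group(group_b)
    if len(samples_a) == 1 and len(samples_b) == 1 and mode == "fc_and_p":
        log.warning("single-sample contrast %s vs %s: p-values rely entirely on the "
                    "blind variance fit and may be poorly calibrated",
                    group_b, group_a)

    q = normalized_counts(gene_counts, factors)
    m_a = q[samples_a].mean(axis=1)
    m_b = q[samples_b].mean(axis=1)
    base = q.mean(axis=1)
    eps = thr.epsilon
    log2fc = np.log2((m_b + eps) / (m_a + eps))

    counts_df = gene_counts.counts
    fa = factors[samples_a].to_numpy()
    fb = factors[samples_b].to_numpy()
    arr_a = counts_df[samples_a].to_numpy()
    arr_b = counts_df[samples_b].to_numpy()
    pvals = np.ones(len(counts_df))
    for i in range(len(counts_df)):
        pvals[i] = nb_test(arr_a[i], arr_b[i], fa, fb, model)
    bh = multipletests(pvals, method="fdr_bh")[1]

    expressed = np.maximum(m_a, m_b) > thr.base_mean
    big = np.abs(log2fc) > thr.logfc
    sig = (pvals < thr.p) if mode == "fc_and_p" else np.ones(len(pvals), bool)
    call = np.where(expressed & big & sig,
                    np.where(log2fc > 0, "up", "down"), "none")

    df = pd.DataFrame({
        "symbol": (symbols.reindex(counts_df.index).fillna("")
                   if symbols is not None else ""),
        "base_mean": base,
        f"base_mean_{group_a}": m_a,
        f"base_mean_{group_b}": m_b,
        "log2fc": log2fc,
        "p": pvals,
        "bh_q": bh,
        "call": call,
    }, index=counts_df.index)
    df.index.name = "gene_id"
    return DEResult(df=df, contrast=f"{group_b}_vs_{group_a}",
                    group_a=group_a, group_b=group_b, mode=mode)
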