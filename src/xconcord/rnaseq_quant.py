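"""RNA-seq quantification: RPKM, expression gating, size factors, base means,
and transcript-level screens (presence/absence, fold filters, MA values).

RPKM = 1e9 * C / (L * N) with C the transcript's read count, L its length in
bp and N the sample's total aligned reads.  Size factors follow the
median-of-ratios convention: each sample's counts are compared to a
geometric-mean pseudo-reference built from transcripts observed in every
sample, and the median ratio is that sample's factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CountMatrix, TranscriptAnnotation, TableValidationError

DEFAULT_RPKM_GATE = 2.0     # RPKM at or above this counts as expressed
DEFAULT_EPSILON = 1.0       # pseudocount (RPKM units) for fold/log operations


@dataclass
class ExpressionMatrix:
    """RPKM values with the expression gate applied as a boolean mask."""

    rpkm: pd.DataFrame          # ids x samples, non-negative reals
    groups: dict[str, str]
    gate: float = DEFAULT_RPKM_GATE

    def __post_init__(self) -> None:
        if (self.rpkm.to_numpy() < 0).any():
            raise TableValidationError("negative RPKM value")

    @property
    def expressed_mask(self) -> pd.DataFrame:
        return self.rpkm >= self.gate

    @property
    def sample_ids(self) -> list[str]:
        return self.rpkm.columns.tolist()

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.sample_ids if self.groups[s] == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out

    def group_means(self, group_order: list[str] | None = None) -> pd.DataFrame:
        """Per-group mean RPKM (samples averaged within each group)."""
        if group_order is None:
            seen: list[str] = []
            for s in self.sample_ids:
                g = self.groups[s]
                if g not in seen:
                    seen.append(g)
            group_order = seen
        cols = {g: self.rpkm[self.samples_in_group(g)].mean(axis=1) for g in group_order}
        return pd.DataFrame(cols)


def rpkm(counts: CountMatrix, annotation: TranscriptAnnotation,
         gate: float = DEFAULT_RPKM_GATE) -> ExpressionMatrix:
    """Length- and depth-normalize counts to RPKM and apply the expression gate."""
    totals = counts.counts.sum(axis=0).astype(float)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise TableValidationError(f"samples with zero total counts: {zero}")
    lengths = annotation.lengths().reindex(counts.counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise TableValidationError(f"transcripts without annotated length: {missing[:5]}")
    vals = (counts.counts.to_numpy(dtype=float) * 1e9
            / lengths.to_numpy(dtype=float)[:, None]
            / totals.to_numpy()[None, :])
    df = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionMatrix(df, dict(counts.groups), gate)


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The geometric-mean pseudo-reference uses only rows with positive counts in
    every sample; raises if no such row exists.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise TableValidationError(
            "no transcript with positive counts in all samples; cannot estimate size factors")
    logs = np.log(arr[positive])
    ref = logs.mean(axis=1, keepdims=True)       # log geometric mean per row
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalized_counts(counts: CountMatrix | pd.DataFrame,
                      factors: pd.Series) -> pd.DataFrame:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    return df / factors


def base_mean(counts: CountMatrix, factors: pd.Series
              ) -> tuple[pd.Series, pd.DataFrame]:
    """Mean of size-factor-normalized counts, overall and per group."""
    q = normalized_counts(counts, factors)
    overall = q.mean(axis=1)
    overall.name = "base_mean"
    per_group = pd.DataFrame(
        {g: q[counts.samples_in_group(g)].mean(axis=1) for g in counts.group_labels})
    return overall, per_group


def collapse_to_genes(counts: CountMatrix, annotation: TranscriptAnnotation
                      ) -> tuple[CountMatrix, pd.Series]:
    """Sum transcript counts within genes; returns gene-level counts and a
    gene_id -> symbol map (upper-case; empty string where unannotated)."""
    gene_of = annotation.gene_of().reindex(counts.counts.index)
    gene_counts = counts.counts.groupby(gene_of).sum()
    gene_counts.index.name = "gene_id"
    return (CountMatrix(gene_counts, dict(counts.groups)),
            annotation.symbol_of_gene())


def presence_partition(expr: ExpressionMatrix, sample_a: str, sample_b: str
                       ) -> dict[str, set[str]]:
    """Partition ids into only_a / only_b / both / neither by the expression gate."""
    for s in (sample_a, sample_b):
        if s not in expr.rpkm.columns:
            raise KeyError(f"unknown sample id {s!r}")
    mask = expr.expressed_mask
    a = mask[sample_a].to_numpy()
    b = mask[sample_b].to_numpy()
    ids = expr.rpkm.index
    return {
        "only_a": set(ids[a & ~b]),
        "only_b": set(ids[~a & b]),
        "both": set(ids[a & b]),
        "neither": set(ids[~a & ~b]),
    }


def fold_filter(expr: ExpressionMatrix, sample_a: str, sample_b: str,
                min_fold: float, eps: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """ids where (rpkm_a + eps)/(rpkm_b + eps) >= min_fold and a is expressed.

    Returns a frame with columns rpkm_a, rpkm_b, fold sorted by descending fold.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    ra = expr.rpkm[sample_a].astype(float)
    rb = expr.rpkm[sample_b].astype(float)
    fold = (ra + eps) / (rb + eps)
    keep = (fold >= min_fold) & expr.expressed_mask[sample_a]
    out = pd.DataFrame({"rpkm_a": ra[keep], "rpkm_b": rb[keep], "fold": fold[keep]})
    return out.sort_values("fold", ascending=False)


def ma_values(expr: ExpressionMatrix, tumor_groups: list[str],
              reference_group: str, eps: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Per-id MA-plot quantities.

    A = mean over all groups of log2(group-mean RPKM + eps);
    M = mean over tumor groups of log2(RPKM + eps) minus log2 of the reference.
    """
    if not tumor_groups:
        raise ValueError("need at least one tumor group")
    gm = expr.group_means([reference_group] + list(tumor_groups))
    logs = np.log2(gm + eps)
    a_vals = logs.mean(axis=1)
    m_vals = logs[list(tumor_groups)].mean(axis=1) - logs[reference_group]
    return pd.DataFrame({"A": a_vals, "M": m_vals})
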