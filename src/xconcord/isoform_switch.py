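"""Isoform-switch detection via the within-gene correlation-range statistic.

For every gene annotated with two or more transcript isoforms, each expressed
transcript's per-group RPKM profile is correlated (Pearson by default) with
the gene's mean profile over its expressed transcripts.  The range

    RC = max(correlations) - min(correlations)        (in [0, 2])

flags differential isoform usage when RC > 1: at least one isoform must run
against the direction of the gene's overall profile.  Multi-isoform genes are
partitioned exhaustively into four categories:

    not_expressed      no transcript passes the RPKM gate anywhere considered
    single_transcript  exactly one transcript passes the gate
    differential       RC > threshold
    same_direction     RC <= threshold, or RC undefined (fewer than two
                       transcripts with a computable correlation)

With only four group points the statistic is intrinsically noisy; see the
methods note for what the synthetic benchmarks do and do not establish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import TranscriptAnnotation
from .rnaseq_quant import ExpressionMatrix

CATEGORIES = ("not_expressed", "single_transcript", "differential", "same_direction")
DEFAULT_GROUP_ORDER = ("HP", "XE", "MM", "UM")


@dataclass
class SpliceResult:
    """Per-gene RC values and category partition over the multi-isoform set."""

    df: pd.DataFrame            # index gene_id; see classify_genes for columns
    rc_threshold: float = 1.0

    def category_counts(self) -> pd.Series:
        return self.df["category"].value_counts().reindex(CATEGORIES, fill_value=0)

    def genes_in(self, category: str) -> set[str]:
        if category not in CATEGORIES:
            raise KeyError(f"unknown category {category!r}")
        return set(self.df.index[self.df["category"] == category])


def select_multi_isoform(annotation: TranscriptAnnotation) -> list[str]:
    """Genes annotated with two or more transcript isoforms."""
    n = annotation.transcripts_per_gene()
    return n[n >= 2].index.tolist()


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either profile has zero variance."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    r = stats.spearmanr(x, y).statistic
    return float(r) if np.isfinite(r) else np.nan


_CORR = {"pearson": _pearson, "spearman": _spearman}


def gene_mean_profile(profiles: pd.DataFrame) -> np.ndarray:
    """Mean per-group profile over the given transcript profiles (rows)."""
    if profiles.empty:
        raise ValueError("gene has no transcript profiles")
    return profiles.to_numpy(dtype=float).mean(axis=0)


def transcript_group_profiles(expr: ExpressionMatrix,
                              group_order: tuple[str, ...] = DEFAULT_GROUP_ORDER
                              ) -> pd.DataFrame:
    """Transcripts x groups RPKM (each group's samples averaged first)."""
    return expr.group_means(list(group_order))


def rc_gene(profiles: pd.DataFrame, correlation: str = "pearson"
            ) -> tuple[float, dict[str, float]]:
    """RC = max - min of per-transcript correlations to the gene-mean profile.

    ``profiles`` holds the expressed transcripts only (rows = transcripts,
    columns = ordered groups).  Transcripts whose profile (or the gene mean)
    has zero variance get an undefined correlation and are dropped from the
    range; RC is NaN when fewer than two defined correlations remain.
    """
    corr_fn = _CORR[correlation]
    mean_profile = gene_mean_profile(profiles)
    corrs = {t: corr_fn(profiles.loc[t].to_numpy(dtype=float), mean_profile)
             for t in profiles.index}
    defined = [c for c in corrs.values() if np.isfinite(c)]
    rc = (max(defined) - min(defined)) if len(defined) >= 2 else np.nan
    return rc, corrs


def classify_genes(expr: ExpressionMatrix, annotation: TranscriptAnnotation,
                   group_order: tuple[str, ...] = DEFAULT_GROUP_ORDER,
                   rc_threshold: float = 1.0,
                   correlation: str = "pearson",
                   expression_scope: str = "any_group",
                   tumor_groups: tuple[str, ...] = ("XE", "MM", "UM"),
                   include_unexpressed_in_mean: bool = False) -> SpliceResult:
    """Compute RC and the four-way category for every multi-isoform gene.

    ``expression_scope`` controls where a transcript must pass the RPKM gate
    to count as expressed: in any group ("any_group") or in the tumor groups
    only ("tumor_groups_only").  By default transcripts failing the gate are
    excluded from both the correlation set and the gene mean;
    ``include_unexpressed_in_mean`` keeps them in the mean only.
    """
    if correlation not in _CORR:
        raise ValueError(f"unknown correlation {correlation!r}")
    if expression_scope not in {"any_group", "tumor_groups_only"}:
        raise ValueError(f"unknown expression_scope {expression_scope!r}")

    genes = select_multi_isoform(annotation)
    profiles = transcript_group_profiles(expr, group_order)
    gate_groups = list(group_order) if expression_scope == "any_group" else [
        g for g in group_order if g in tumor_groups]
    gate_samples = [s for g in gate_groups for s in expr.samples_in_group(g)]
    expressed_t = expr.expressed_mask[gate_samples].any(axis=1)

    gene_of = annotation.gene_of()
    symbol_of = annotation.symbol_of_gene()
    by_gene = annotation.table.groupby("gene_id").groups

    rows = []
    for gene in genes:
        transcripts = [t for t in by_gene[gene] if t in profiles.index]
        n_annot = len(by_gene[gene])
        expressed = [t for t in transcripts if expressed_t.get(t, False)]
        n_expr = len(expressed)
        rc = np.nan
        corrs: dict[str, float] = {}
        if n_expr == 0:
            category = "not_expressed"
        elif n_expr == 1:
            category = "single_transcript"
        else:
            corr_set = profiles.loc[expressed]
            if include_unexpressed_in_mean:
                mean_profile = gene_mean_profile(profiles.loc[transcripts])
                corr_fn = _CORR[correlation]
                corrs = {t: corr_fn(corr_set.loc[t].to_numpy(dtype=float), mean_profile)
                         for t in corr_set.index}
                defined = [c for c in corrs.values() if np.isfinite(c)]
                rc = (max(defined) - min(defined)) if len(defined) >= 2 else np.nan
            else:
                rc, corrs = rc_gene(corr_set, correlation)
            category = ("differential" if np.isfinite(rc) and rc > rc_threshold
                        else "same_direction")
        rows.append({
            "gene_id": gene,
            "symbol": symbol_of.get(gene, ""),
            "n_isoforms_annotated": n_annot,
            "n_isoforms_expressed": n_expr,
            "rc_gene": rc,
            "category": category,
            "correlations": ";".join(
                f"{t}:{corrs[t]:.6g}" if np.isfinite(corrs[t]) else f"{t}:NA"
                for t in sorted(corrs)),
        })
    df = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["symbol", "n_isoforms_annotated", "n_isoforms_expressed",
                 "rc_gene", "category", "correlations"])
    return SpliceResult(df=df, rc_threshold=rc_threshold)
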