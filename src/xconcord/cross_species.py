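"""Cross-species concordance: symbol joins, conserved signatures, motif
overlaps and hypergeometric over-representation.

Fish (RNA-seq) and human (microarray) differential-expression results are
joined through an ortholog table that maps each fish gene to at most one
human symbol; teleost genome duplication makes the reverse map one-to-many,
so several fish paralogs may collapse onto one human symbol under a
configurable policy.  From the joined table the conserved signature is the
pair of symbol sets called in the same direction in both species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import OrthologTable, SignatureSet
from .diffexpr_nb import DEResult
from .microarray_de import ModeratedTResult

log = logging.getLogger(__name__)

CONSERVED_STATUSES = ("common_up", "common_down", "discordant",
                      "fish_only", "human_only", "neither")
PARALOG_POLICIES = ("any_call", "max_fold", "best_p")


@dataclass
class ConcordanceTable:
    """Symbol-joined fish/human logFC + call table."""

    df: pd.DataFrame            # index human symbol
    fish_contrast: str
    human_contrast: str
    paralog_policy: str

    def status_counts(self) -> pd.Series:
        return self.df["status"].value_counts().reindex(CONSERVED_STATUSES, fill_value=0)


@dataclass
class OverlapReport:
    """Signature-vs-dataset overlap with a direction/fold counting rule."""

    name: str
    n_signature: int
    n_shared: int
    n_meeting: int
    fold: float
    direction: str
    quantifier: str             # "all" or "any" over the supplied contrasts
    meeting_symbols: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.n_meeting <= self.n_shared <= self.n_signature):
            raise ValueError("overlap counts must satisfy meeting <= shared <= signature")

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "signature": self.name, "n_signature": self.n_signature,
            "n_shared": self.n_shared, "n_meeting": self.n_meeting,
            "fold": self.fold, "direction": self.direction,
            "quantifier": self.quantifier,
        }])


def _collapse_paralogs(group: pd.DataFrame, policy: str) -> pd.Series:
    """Collapse the fish rows of one human symbol to a single representative."""
    calls = group["call"]
    called = group[calls != "none"]
    if policy == "best_p" and "p" in group:
        pool = called if len(called) else group
        rep = pool.loc[pool["p"].idxmin()]
    else:  # any_call and max_fold both represent by the strongest fold
        pool = called if (policy == "any_call" and len(called)) else group
        rep = pool.loc[pool["log2fc"].abs().idxmax()]
    out = rep.copy()
    if policy == "any_call" and len(called):
        directions = set(called["call"])
        if directions == {"up"}:
            out["call"] = "up"
        elif directions == {"down"}:
            out["call"] = "down"
        # both directions present: keep the strongest paralog's call (rep)
    return out


def join_on_symbols(fish: DEResult, human: ModeratedTResult,
                    orthologs: OrthologTable,
                    paralog_policy: str = "any_call") -> ConcordanceTable:
    """One row per human symbol present in both species' results.

    Fish genes are mapped to human symbols through the ortholog table (rows
    without a mapping are dropped and counted in the log); paralog groups are
    collapsed per ``paralog_policy``.
    """
    if paralog_policy not in PARALOG_POLICIES:
        raise ValueError(f"unknown paralog_policy {paralog_policy!r}")
    fish_df = fish.df.copy()
    mapping = orthologs.human_symbol_of()
    fish_df["human_symbol"] = mapping.reindex(fish_df.index)
    unmapped = int(fish_df["human_symbol"].isna().sum())
    fish_df = fish_df.dropna(subset=["human_symbol"])

    human_df = human.df.copy()
    human_df.index = human_df.index.astype(str).str.upper()

    collapsed = (fish_df.groupby("human_symbol")
                 .apply(_collapse_paralogs, policy=paralog_policy,
                        include_groups=False))
    common = collapsed.index.intersection(human_df.index)
    if len(common) == 0:
        raise ValueError("no symbols common to fish and human results")
    log.info("symbol join: %d fish genes (%d unmapped), %d human symbols, "
             "%d common", len(fish.df), unmapped, len(human_df), len(common))

    f = collapsed.loc[common]
    h = human_df.loc[common]
    fish_called = f["call"] != "none"
    human_called = h["call"] != "none"
    status = np.select(
        [fish_called & human_called & (f["call"] == h["call"]) & (f["call"] == "up"),
         fish_called & human_called & (f["call"] == h["call"]) & (f["call"] == "down"),
         fish_called & human_called,
         fish_called & ~human_called,
         ~fish_called & human_called],
        ["common_up", "common_down", "discordant", "fish_only", "human_only"],
        default="neither")
    df = pd.DataFrame({
        "fish_log2fc": f["log2fc"].astype(float),
        "fish_call": f["call"],
        "fish_p": f["p"].astype(float) if "p" in f else np.nan,
        "human_log2fc": h["log2fc"].astype(float),
        "human_call": h["call"],
        "human_p": h["p"].astype(float),
        "status": status,
    }, index=common)
    df.index.name = "symbol"
    return ConcordanceTable(df=df, fish_contrast=fish.contrast,
                            human_contrast=human.contrast,
                            paralog_policy=paralog_policy)


def conserved_signature(table: ConcordanceTable) -> tuple[set[str], set[str]]:
    """(commonly-up symbols, commonly-down symbols) from the joined table."""
    df = table.df
    return (set(df.index[df["status"] == "common_up"]),
            set(df.index[df["status"] == "common_down"]))


def _fish_symbol_folds(contrasts: list[DEResult]) -> pd.DataFrame:
    """Per (upper-case) symbol, the extreme log2FC per contrast over paralogs.

    Returns a frame symbols x contrasts of signed log2FC picked as the value
    of maximal magnitude among the symbol's fish genes in that contrast.
    """
    cols = {}
    for i, de in enumerate(contrasts):
        df = de.df
        sym = df["symbol"].astype(str).str.upper()
        keep = sym != ""
        sub = pd.DataFrame({"symbol": sym[keep], "log2fc": df.loc[keep, "log2fc"]})
        idx = sub.groupby("symbol")["log2fc"].apply(lambda s: s.abs().idxmax())
        # positional keys: callers may legitimately pass same-named contrasts
        cols[f"{i}:{de.contrast}"] = sub.loc[idx.to_numpy(), "log2fc"].set_axis(idx.index)
    return pd.DataFrame(cols)


def motif_overlap(contrasts: list[DEResult], signature: SignatureSet,
                  fold: float = 2.0, direction: str | None = None,
                  quantifier: str = "all") -> OverlapReport:
    """Count signature genes regulated beyond ``fold`` in the fish contrasts.

    shared   = signature symbols present in the fish dataset;
    meeting  = shared symbols whose linear fold change is strictly greater
               than ``fold`` in the required direction in all (or, with
               quantifier="any", at least one) of the supplied contrasts.
    Unsigned signatures default to counting upregulation.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    if quantifier not in {"all", "any"}:
        raise ValueError(f"unknown quantifier {quantifier!r}")
    direction = direction or (signature.direction
                              if signature.direction != "unsigned" else "up")
    folds = _fish_symbol_folds(contrasts)
    shared = sorted(signature.symbols & set(folds.index))
    log2_thr = np.log2(fold)
    sub = folds.loc[shared]
    hits = (sub > log2_thr) if direction == "up" else (sub < -log2_thr)
    meets = hits.all(axis=1) if quantifier == "all" else hits.any(axis=1)
    meeting = frozenset(sub.index[meets])
    return OverlapReport(name=signature.name, n_signature=len(signature),
                         n_shared=len(shared), n_meeting=len(meeting),
                         fold=fold, direction=direction, quantifier=quantifier,
                         meeting_symbols=meeting)


def zebrafish_compare(contrasts: list[DEResult], signature_up: SignatureSet,
                      signature_down: SignatureSet, fold: float = 2.0
                      ) -> tuple[OverlapReport, OverlapReport]:
    """Signed-signature overlap with the "at least one tumor type" quantifier."""
    up = motif_overlap(contrasts, signature_up, fold=fold,
                       direction="up", quantifier="any")
    down = motif_overlap(contrasts, signature_down, fold=fold,
                         direction="down", quantifier="any")
    return up, down


def over_representation(gene_list: set[str], pathways: dict[str, set[str]],
                        universe: set[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per pathway.

    For a list of n genes drawn from a universe of N, a pathway with K
    universe members and k observed list members has expectation n*K/N and
    p = P(X >= k) under the hypergeometric null.
    """
    universe = {s.upper() for s in universe}
    if not universe:
        raise ValueError("empty universe")
    gene_list = {s.upper() for s in gene_list}
    if not gene_list <= universe:
        raise ValueError("gene list must be a subset of the universe")
    n = len(gene_list)
    n_universe = len(universe)
    rows = []
    for name, members in pathways.items():
        members = {s.upper() for s in members} & universe
        k_in_pathway = len(members)
        k_obs = len(members & gene_list)
        expected = n * k_in_pathway / n_universe
        p = float(stats.hypergeom.sf(k_obs - 1, n_universe, k_in_pathway, n))
        rows.append({"pathway": name, "N_universe": n_universe,
                     "K_pathway": k_in_pathway, "n_list": n, "k_observed": k_obs,
                     "expected": expected, "p": min(p, 1.0)})
    return pd.DataFrame(rows).set_index("pathway")
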