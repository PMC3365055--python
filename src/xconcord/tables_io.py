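"""Readers, writers and validated in-memory containers for every table the pipeline touches.

All interchange is TAB-separated text with "." as decimal point; floats are
written with 12 significant digits so read-write-read is an identity at that
precision.  Gene symbols are upper-cased at read time: the fish annotation
carries lower-case symbols, the human arrays upper-case ones, and every
symbol-level operation downstream compares them case-insensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


class TableValidationError(ValueError):
    """A table failed validation; the message names the offending field."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Transcript x sample integer read counts plus a sample->group map."""

    counts: pd.DataFrame            # index: transcript_id, columns: sample_id
    groups: dict[str, str]          # sample_id -> group label

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate transcript_id: {dups}")
        cols = self.counts.columns
        if cols.duplicated().any():
            raise TableValidationError(
                f"duplicate sample_id: {cols[cols.duplicated()].unique().tolist()}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0) or np.any(~np.isfinite(arr.astype(float))):
                r, c = np.argwhere((frac != 0) | ~np.isfinite(arr.astype(float)))[0]
                raise TableValidationError(
                    f"non-integer count at transcript {idx[r]!r}, sample {cols[c]!r}")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"negative count at transcript {idx[r]!r}, sample {cols[c]!r}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise TableValidationError(f"samples without group label: {missing}")

    @property
    def transcript_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.sample_ids if self.groups[s] == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def relabel_groups(self, mapping: dict[str, str]) -> "CountMatrix":
        """Return a copy with group labels merged/renamed (e.g. XE,MM,UM -> TUM)."""
        groups = {s: mapping.get(g, g) for s, g in self.groups.items()}
        return CountMatrix(self.counts.copy(), groups)


@dataclass
class TranscriptAnnotation:
    """transcript -> (gene_id, gene_symbol, length_bp); symbols upper-cased, may be empty."""

    table: pd.DataFrame             # index: transcript_id; columns gene_id, gene_symbol, length_bp

    def __post_init__(self) -> None:
        need = {"gene_id", "gene_symbol", "length_bp"}
        missing = need - set(self.table.columns)
        if missing:
            raise TableValidationError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate transcript_id in annotation: {dups}")
        self.table = self.table.copy()
        self.table["gene_symbol"] = (
            self.table["gene_symbol"].fillna("").astype(str).str.upper())
        lengths = self.table["length_bp"]
        bad = lengths[(~np.isfinite(lengths.astype(float))) | (lengths < 1)]
        if len(bad):
            raise TableValidationError(
                f"length_bp must be >= 1; offending transcripts: {bad.index.tolist()[:5]}")
        self.table["length_bp"] = lengths.astype(np.int64)

    @property
    def transcript_ids(self) -> list[str]:
        return self.table.index.tolist()

    def lengths(self) -> pd.Series:
        return self.table["length_bp"]

    def gene_of(self) -> pd.Series:
        return self.table["gene_id"]

    def symbol_of_gene(self) -> pd.Series:
        """gene_id -> symbol (first annotated symbol; empty string if none)."""
        return self.table.groupby("gene_id")["gene_symbol"].first()

    def transcripts_per_gene(self) -> pd.Series:
        return self.table.groupby("gene_id").size()


@dataclass
class OrthologTable:
    """(fish_gene_id, fish_symbol, human_symbol) rows; one fish gene -> at most one
    human symbol, one human symbol -> possibly several fish paralogs."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"fish_gene_id", "fish_symbol", "human_symbol"}
        missing = need - set(self.table.columns)
        if missing:
            raise TableValidationError(f"ortholog table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["fish_symbol"] = t["fish_symbol"].fillna("").astype(str).str.upper()
        t["human_symbol"] = t["human_symbol"].fillna("").astype(str).str.upper()
        if (t["human_symbol"] == "").any():
            raise TableValidationError("ortholog table has rows with empty human_symbol")
        t = t.drop_duplicates()
        pairs = t[["fish_gene_id", "human_symbol"]]
        if pairs.duplicated().any():
            raise TableValidationError(
                "duplicate (fish_gene_id, human_symbol) pairs after dedup")
        multi = t.groupby("fish_gene_id")["human_symbol"].nunique()
        conflicted = multi[multi > 1].index.tolist()
        if conflicted:
            raise TableValidationError(
                f"fish genes mapped to more than one human symbol: {conflicted[:5]}")
        self.table = t.reset_index(drop=True)
        if len(t) == 0:
            raise TableValidationError("ortholog table is empty")

    def n_one_to_many(self) -> int:
        """Number of human symbols hit by more than one fish paralog."""
        counts = self.table.groupby("human_symbol").size()
        return int((counts > 1).sum())

    def human_symbol_of(self) -> pd.Series:
        return self.table.set_index("fish_gene_id")["human_symbol"]


@dataclass
class SignatureSet:
    """Named gene-symbol set with an optional direction (up/down/unsigned)."""

    name: str
    symbols: frozenset[str]
    direction: str = "unsigned"

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down", "unsigned"}:
            raise TableValidationError(f"bad signature direction {self.direction!r}")
        syms = frozenset(s.upper() for s in self.symbols if s)
        if not syms:
            raise TableValidationError(f"signature {self.name!r} is empty")
        object.__setattr__(self, "symbols", syms)

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class IntensityMatrix:
    """Probe-or-gene x sample microarray intensities with a two-group design."""

    values: pd.DataFrame            # index: probe/gene ids, columns: sample ids
    groups: dict[str, str]          # sample -> group (e.g. nevus / melanoma)
    log2_scale: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise TableValidationError("duplicate row ids in intensity matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise TableValidationError(
                f"non-finite intensity at row {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise TableValidationError(f"samples without group label: {missing}")
        labels = {self.groups[s] for s in self.values.columns}
        for g in labels:
            n = sum(self.groups[s] == g for s in self.values.columns)
            if n < 2:
                raise TableValidationError(f"group {g!r} has {n} sample(s); need >= 2")
        if len(labels) < 2:
            raise TableValidationError("intensity matrix needs two groups")
        if not self.log2_scale and float(np.nanmax(arr)) > 50:
            # heuristic: raw-scale values this large are linear intensities
            log.info("intensities exceed 50 and log2 flag unset; treating as linear scale")

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.values.columns if self.groups[s] == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    return pd.read_csv(path, sep="\t", **kw)


def read_groups(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path)
    need = {"sample_id", "group"}
    if not need <= set(df.columns):
        raise TableValidationError(f"groups file must have columns {sorted(need)}")
    if df["sample_id"].duplicated().any():
        raise TableValidationError("duplicate sample_id in groups file")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


def read_count_table(
    path: str | Path, annotation_path: str | Path, groups_path: str | Path
) -> tuple[CountMatrix, TranscriptAnnotation]:
    """Read counts + annotation + groups, cross-validated.

    Every transcript present in the count table must be annotated; offenders
    are reported by id.
    """
    df = _read_tsv(path)
    if df.columns[0] != "transcript_id":
        raise TableValidationError(
            f"count table must start with a 'transcript_id' column, got {df.columns[0]!r}")
    df = df.set_index("transcript_id")
    groups = read_groups(groups_path)
    counts = CountMatrix(df, groups)

    ann_df = _read_tsv(annotation_path)
    if "transcript_id" not in ann_df.columns:
        raise TableValidationError("annotation must have a transcript_id column")
    annotation = TranscriptAnnotation(ann_df.set_index("transcript_id"))

    unannotated = [t for t in counts.transcript_ids
                   if t not in annotation.table.index]
    if unannotated:
        raise TableValidationError(
            f"transcripts present in counts but missing from annotation: "
            f"{unannotated[:10]}{'...' if len(unannotated) > 10 else ''}")
    return counts, annotation


def read_ortholog_table(path: str | Path) -> OrthologTable:
    df = _read_tsv(path)
    table = OrthologTable(df)
    log.info("ortholog table: %d rows, %d one-to-many human symbols",
             len(table.table), table.n_one_to_many())
    return table


def read_signature(path: str | Path, name: str, direction: str = "unsigned") -> SignatureSet:
    """One symbol per line; '#'-prefixed lines and blanks skipped; case-normalized."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signature file not found: {path}")
    symbols = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.add(line.upper())
    return SignatureSet(name=name, symbols=frozenset(symbols), direction=direction)


def read_intensity_table(
    path: str | Path, groups_path: str | Path, log2_scale: bool = True
) -> IntensityMatrix:
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str).str.upper()
    return IntensityMatrix(df.astype(float), read_groups(groups_path), log2_scale)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> Path:
    """Write any result frame as TSV with 12-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index=index_label is not None, index_label=index_label)
    return path


def read_result_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    df = _read_tsv(path)
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_result_table(result, path: str | Path) -> Path:
    """Dispatch writer for DEResult / SpliceResult / ConcordanceTable-like objects.

    Anything with a ``.df`` attribute is written as that frame; bare DataFrames
    are written directly.  Column order is the frame's own (fixed by each
    producing module).
    """
    df = getattr(result, "df", result)
    if not isinstance(df, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    return write_table(df, path)


def write_count_matrix(counts: CountMatrix, path: str | Path, groups_path: str | Path) -> None:
    out = counts.counts.copy()
    out.insert(0, "transcript_id", out.index)
    out.to_csv(Path(path), sep="\t", index=False)
    gdf = pd.DataFrame({"sample_id": counts.sample_ids,
                        "group": [counts.groups[s] for s in counts.sample_ids]})
    gdf.to_csv(Path(groups_path), sep="\t", index=False)


def write_annotation(annotation: TranscriptAnnotation, path: str | Path) -> None:
    out = annotation.table.copy()
    out.insert(0, "transcript_id", out.index)
    out.to_csv(Path(path), sep="\t", index=False)


def write_ortholog_table(orthologs: OrthologTable, path: str | Path) -> None:
    orthologs.table.to_csv(Path(path), sep="\t", index=False)


def write_intensity_matrix(
    intens: IntensityMatrix, path: str | Path, groups_path: str | Path
) -> None:
    out = intens.values.copy()
    out.insert(0, "id", out.index)
    out.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FORMAT)
    gdf = pd.DataFrame({"sample_id": list(intens.values.columns),
                        "group": [intens.groups[s] for s in intens.values.columns]})
    gdf.to_csv(Path(groups_path), sep="\t", index=False)
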