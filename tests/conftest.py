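"""Shared fixtures: tiny hand-written tables plus session-scoped simulations."""

import numpy as np
import pandas as pd
import pytest

from xconcord.synthetic_data import SimConfig, simulate, null_config
from xconcord.tables_io import (CountMatrix, IntensityMatrix,
                                TranscriptAnnotation)


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    """3 transcripts x 4 samples, one sample per fish group."""
    df = pd.DataFrame(
        {"HP": [10, 0, 5], "XE": [20, 2, 5], "MM": [30, 4, 5], "UM": [40, 8, 5]},
        index=pd.Index(["t1", "t2", "t3"], name="transcript_id"))
    return CountMatrix(df, {g: g for g in ("HP", "XE", "MM", "UM")})


@pytest.fixture()
def tiny_annotation() -> TranscriptAnnotation:
    df = pd.DataFrame({
        "gene_id": ["g1", "g1", "g2"],
        "gene_symbol": ["bcl2", "bcl2", ""],
        "length_bp": [1000, 2000, 500],
    }, index=pd.Index(["t1", "t2", "t3"], name="transcript_id"))
    return TranscriptAnnotation(df)


@pytest.fixture()
def tiny_intensities() -> IntensityMatrix:
    rng = np.random.default_rng(0)
    vals = rng.normal(8, 1, size=(50, 6))
    df = pd.DataFrame(vals, index=[f"G{i}" for i in range(50)],
                      columns=[f"s{i}" for i in range(6)])
    groups = {f"s{i}": ("nevus" if i < 3 else "melanoma") for i in range(6)}
    return IntensityMatrix(df, groups)


@pytest.fixture(scope="session")
def default_sim():
    """The study-shaped default simulation (2000 genes, planted effects)."""
    return simulate(SimConfig(seed=20120531))


@pytest.fixture(scope="session")
def null_sim():
    """No-effect NB simulation (alpha = 0.1) for calibration checks."""
    return simulate(null_config(seed=101, n_genes=2000, alpha=0.1))


@pytest.fixture()
def fixture_dir(tmp_path, tiny_counts, tiny_annotation):
    """Tiny on-disk tables for reader tests."""
    counts = tiny_counts.counts.copy()
    counts.insert(0, "transcript_id", counts.index)
    counts.to_csv(tmp_path / "counts.tsv", sep="\t", index=False)
    ann = tiny_annotation.table.copy()
    ann.insert(0, "transcript_id", ann.index)
    ann.to_csv(tmp_path / "annotation.tsv", sep="\t", index=False)
    pd.DataFrame({"sample_id": ["HP", "XE", "MM", "UM"],
                  "group": ["HP", "XE", "MM", "UM"]}
                 ).to_csv(tmp_path / "groups.tsv", sep="\t", index=False)
    return tmp_path
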