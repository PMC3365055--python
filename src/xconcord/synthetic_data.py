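"""Synthetic two-species datasets with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a fish RNA-seq design of four single-sample groups (HP, XE, MM, UM), where
  HP may be a pool of several virtual siblings (counts summed, mirroring a
  nevus-like precursor lesion pooled from 5 fish);
* negative-binomial transcript counts with mean proportional to expression
  level, transcript length (500-5000 bp) and per-sample sequencing depth,
  and variance mu + alpha*mu^2;
* multi-isoform genes with fixed isoform proportions, a configurable subset
  carrying planted isoform switches constructed so the correlation-range
  statistic is exactly 2 before count noise (one isoform an affine
  decreasing function of the other);
* planted up/down differential expression in the tumor groups, a configurable
  fraction of it conserved in a human two-group microarray design (18 nevi vs
  19 melanomas, Gaussian log2 intensities);
* an ortholog table with one-to-two fish-paralog mappings.

Everything is driven by one master seed through named substreams, so equal
seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables_io
from .tables_io import (CountMatrix, IntensityMatrix, OrthologTable,
                        TranscriptAnnotation)

FISH_GROUPS = ("HP", "XE", "MM", "UM")
TUMOR_GROUPS = ("XE", "MM", "UM")


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the design the pipeline targets: four fish groups with one
    sample each (HP pooled from 5 virtual siblings), 18 nevus vs 19 melanoma
    human arrays, NB dispersion 0.1, 8-fold planted effects with half of the
    fish signature conserved in the human arm.
    """

    seed: int = 0
    n_genes: int = 2000
    isoform_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)  # 1/2/3 isoforms
    hp_pool_size: int = 5
    n_nevus: int = 18
    n_melanoma: int = 19
    nb_alpha: float = 0.1
    baseline_log_mean: float = 5.0       # ln of mean normalized count (median ~150)
    baseline_log_sigma: float = 1.0
    n_up_fish: int = 100
    n_down_fish: int = 100
    conserved_fraction: float = 0.5
    effect_fold: float = 8.0
    n_switch_genes: int = 100
    paralog_fraction: float = 0.1
    group_effect_sigma: float = 0.0      # log2 sd of per-(gene,group) biological multipliers
    switch_profile_spread: float = 1.5   # log2 half-range of switch-gene group profiles
    array_sigma: float = 0.5
    array_base_mean: float = 8.0
    array_base_sigma: float = 1.5
    human_effect_log2: float = 3.0       # log2 fold planted in the human arm
    fish_depths: tuple[float, ...] = (1.0, 0.9, 1.2, 1.0)   # HP, XE, MM, UM
    length_range: tuple[int, int] = (500, 5000)

    def validate(self) -> None:
        if abs(sum(self.isoform_fractions) - 1.0) > 1e-9:
            raise ValueError("isoform_fractions must sum to 1")
        for frac in (*self.isoform_fractions, self.conserved_fraction,
                     self.paralog_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_up_fish + self.n_down_fish + self.n_switch_genes > self.n_genes:
            raise ValueError("planted sets exceed n_genes")
        if self.effect_fold <= 1:
            raise ValueError("effect_fold must be > 1")
        if len(self.fish_depths) != len(FISH_GROUPS):
            raise ValueError("need one depth per fish group")


@dataclass
class SimTruth:
    """Planted per-gene ground truth (one row per fish gene)."""

    df: pd.DataFrame    # index fish gene_id

    def fish_direction(self) -> pd.Series:
        return self.df["fish_direction"]

    def conserved_symbols(self, direction: str) -> set[str]:
        sel = (self.df["conserved"]) & (self.df["human_direction"] == direction)
        return set(self.df.loc[sel, "human_symbol"])

    def switch_genes(self) -> set[str]:
        return set(self.df.index[self.df["switch"]])


@dataclass
class SimResult:
    counts: CountMatrix
    annotation: TranscriptAnnotation
    intensities: IntensityMatrix
    orthologs: OrthologTable
    truth: SimTruth
    config: SimConfig

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / f"{k}.tsv" for k in
                 ("counts", "groups", "annotation", "intensities",
                  "intensity_groups", "orthologs", "truth")}
        tables_io.write_count_matrix(self.counts, paths["counts"], paths["groups"])
        tables_io.write_annotation(self.annotation, paths["annotation"])
        tables_io.write_intensity_matrix(self.intensities, paths["intensities"],
                                         paths["intensity_groups"])
        tables_io.write_ortholog_table(self.orthologs, paths["orthologs"])
        truth_out = self.truth.df.copy()
        truth_out.insert(0, "gene_id", truth_out.index)
        truth_out.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _rng_streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mean + alpha*mean^2 (Poisson when alpha == 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))


def simulate(config: SimConfig) -> SimResult:
    """Generate one dataset pair (fish counts + human intensities) with truth."""
    config.validate()
    rng = _rng_streams(config.seed,
                       ["structure", "profiles", "fish", "human"])
    n = config.n_genes
    gene_ids = [f"olag{i:05d}" for i in range(n)]
    human_symbols = [f"GENE{i:05d}" for i in range(n)]

    r_struct = rng["structure"]
    # planted roles: switch genes first, then up/down, disjoint by slicing a permutation
    perm = r_struct.permutation(n)
    switch_idx = perm[:config.n_switch_genes]
    up_idx = perm[config.n_switch_genes:config.n_switch_genes + config.n_up_fish]
    down_idx = perm[config.n_switch_genes + config.n_up_fish:
                    config.n_switch_genes + config.n_up_fish + config.n_down_fish]
    direction = np.array(["none"] * n, dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    is_switch = np.zeros(n, bool)
    is_switch[switch_idx] = True

    n_cons_up = int(round(config.conserved_fraction * len(up_idx)))
    n_cons_down = int(round(config.conserved_fraction * len(down_idx)))
    conserved = np.zeros(n, bool)
    conserved[up_idx[:n_cons_up]] = True
    conserved[down_idx[:n_cons_down]] = True
    human_direction = np.where(conserved, direction, "none")

    # isoform counts: switch genes always get exactly two isoforms
    n_iso = r_struct.choice([1, 2, 3], size=n, p=list(config.isoform_fractions))
    n_iso[is_switch] = 2

    # paralogs: pair unplanted genes from the permutation tail; the second
    # gene of each pair is re-annotated with the first gene's human symbol,
    # producing real one-human-to-two-fish mappings in the ortholog table
    n_pairs = int(round(config.paralog_fraction * n))
    head_used = config.n_switch_genes + config.n_up_fish + config.n_down_fish
    if head_used + 2 * n_pairs > n:
        raise ValueError("planted sets plus paralog pairs exceed n_genes")
    pair_idx = perm[n - 2 * n_pairs:].reshape(n_pairs, 2) if n_pairs else \
        np.empty((0, 2), dtype=int)
    human_symbol_of_gene = np.array(human_symbols, dtype=object)
    paralog_group = np.full(n, "", dtype=object)
    for ga, gb in pair_idx:
        human_symbol_of_gene[gb] = human_symbols[ga]
        paralog_group[ga] = paralog_group[gb] = human_symbols[ga]

    baseline = np.exp(r_struct.normal(config.baseline_log_mean,
                                      config.baseline_log_sigma, size=n))

    # --- per-gene per-group expression profiles (normalized-count scale) ----
    r_prof = rng["profiles"]
    n_groups = len(FISH_GROUPS)
    is_tumor = np.array([g in TUMOR_GROUPS for g in FISH_GROUPS])
    log2_fold = np.log2(config.effect_fold)
    dir_sign = np.where(direction == "up", 1.0, np.where(direction == "down", -1.0, 0.0))
    profile_log2 = np.zeros((n, n_groups))
    profile_log2 += (dir_sign[:, None] * log2_fold) * is_tumor[None, :]
    if config.group_effect_sigma > 0:
        profile_log2 += r_prof.normal(0.0, config.group_effect_sigma,
                                      size=(n, n_groups))
    gene_profile = baseline[:, None] * np.power(2.0, profile_log2)

    # --- transcripts: annotation + per-transcript group profiles ------------
    transcript_rows = []
    t_profiles = []
    for g in range(n):
        k = int(n_iso[g])
        if is_switch[g]:
            # isoform 1: non-constant group profile; isoform 2 = a*iso1 + b
            # with a in (-1, 0), which makes the two correlations to the gene
            # mean exactly +1 and -1 (RC = 2) before count noise.
            spread = config.switch_profile_spread
            w = gene_profile[g] * np.power(
                2.0, r_prof.uniform(-spread, spread, size=n_groups))
            while np.allclose(w, w[0]):
                w = gene_profile[g] * np.power(
                    2.0, r_prof.uniform(-spread, spread, size=n_groups))
            a = -r_prof.uniform(0.3, 0.7)
            b = -a * w.max() * 1.2 + 0.05 * w.mean()
            profs = np.vstack([w, a * w + b])
        else:
            fracs = r_prof.dirichlet(np.full(k, 5.0))
            profs = fracs[:, None] * gene_profile[g][None, :]
        for j in range(k):
            transcript_rows.append({
                "transcript_id": f"olat{g:05d}.{j + 1}",
                "gene_id": gene_ids[g],
                "gene_symbol": str(human_symbol_of_gene[g]).lower(),
            })
            t_profiles.append(profs[j])
    t_profiles = np.vstack(t_profiles)
    lengths = r_struct.integers(config.length_range[0], config.length_range[1] + 1,
                                size=len(transcript_rows))

    # --- fish counts ---------------------------------------------------------
    r_fish = rng["fish"]
    depths = np.asarray(config.fish_depths, dtype=float)
    length_kb = lengths / 1000.0
    count_cols = {}
    for gi, group in enumerate(FISH_GROUPS):
        mean = t_profiles[:, gi] * length_kb * depths[gi]
        if group == "HP" and config.hp_pool_size > 1:
            draws = sum(_nb_draw(r_fish, mean, config.nb_alpha)
                        for _ in range(config.hp_pool_size))
            count_cols[group] = draws
        else:
            count_cols[group] = _nb_draw(r_fish, mean, config.nb_alpha)
    counts_df = pd.DataFrame(count_cols,
                             index=[r["transcript_id"] for r in transcript_rows])
    counts_df.index.name = "transcript_id"
    counts = CountMatrix(counts_df.astype(np.int64),
                         {g: g for g in FISH_GROUPS})

    ann_df = pd.DataFrame(transcript_rows).set_index("transcript_id")
    ann_df["length_bp"] = lengths
    annotation = TranscriptAnnotation(ann_df)

    # --- ortholog table (paralog pairs share one human symbol) ---------------
    is_second_paralog = np.zeros(n, bool)
    if n_pairs:
        is_second_paralog[pair_idx[:, 1]] = True
    ortho_rows = []
    for g in range(n):
        fish_sym = str(human_symbol_of_gene[g]).lower()
        if paralog_group[g]:
            fish_sym += "b" if is_second_paralog[g] else "a"
        ortho_rows.append({"fish_gene_id": gene_ids[g],
                           "fish_symbol": fish_sym,
                           "human_symbol": human_symbol_of_gene[g]})
    orthologs = OrthologTable(pd.DataFrame(ortho_rows))

    # --- human intensities (one row per unique human symbol) ----------------
    r_human = rng["human"]
    uniq_symbols = [human_symbols[g] for g in range(n) if not is_second_paralog[g]]
    uniq_dir = [human_direction[g] for g in range(n) if not is_second_paralog[g]]
    n_u = len(uniq_symbols)
    n_h = config.n_nevus + config.n_melanoma
    samples = ([f"nevus_{i + 1:02d}" for i in range(config.n_nevus)]
               + [f"mel_{i + 1:02d}" for i in range(config.n_melanoma)])
    groups = {s: ("nevus" if s.startswith("nevus") else "melanoma") for s in samples}
    base = r_human.normal(config.array_base_mean, config.array_base_sigma, size=n_u)
    h_sign = np.where(np.asarray(uniq_dir) == "up", 1.0,
                      np.where(np.asarray(uniq_dir) == "down", -1.0, 0.0))
    is_mel = np.array([groups[s] == "melanoma" for s in samples], dtype=float)
    mean = base[:, None] + config.human_effect_log2 * h_sign[:, None] * is_mel[None, :]
    vals = mean + r_human.normal(0.0, config.array_sigma, size=(n_u, n_h))
    intens = IntensityMatrix(
        pd.DataFrame(vals, index=uniq_symbols, columns=samples),
        groups, log2_scale=True)

    truth_df = pd.DataFrame({
        "human_symbol": human_symbol_of_gene,
        "fish_direction": direction,
        "human_direction": human_direction,
        "conserved": conserved,
        "switch": is_switch,
        "paralog_group": paralog_group,
    }, index=pd.Index(gene_ids, name="gene_id"))

    return SimResult(counts=counts, annotation=annotation, intensities=intens,
                     orthologs=orthologs, truth=SimTruth(truth_df), config=config)


def null_config(seed: int = 0, n_genes: int = 2000, alpha: float = 0.1) -> SimConfig:
    """A no-effect configuration for calibration and parameter-recovery
    studies: plain NB noise with the given dispersion, no planted effects,
    no pooling, no biological group variation, equal depths, and one isoform
    per gene so the gene-level dispersion equals the per-transcript alpha
    (summing isoforms would otherwise dilute it)."""
    return SimConfig(seed=seed, n_genes=n_genes, nb_alpha=alpha,
                     n_up_fish=0, n_down_fish=0, n_switch_genes=0,
                     conserved_fraction=0.0, hp_pool_size=1,
                     group_effect_sigma=0.0, paralog_fraction=0.0,
                     isoform_fractions=(1.0, 0.0, 0.0),
                     fish_depths=(1.0, 1.0, 1.0, 1.0))


def switch_study_config(seed: int = 0, n_genes: int = 1500,
                        n_switch: int = 150) -> SimConfig:
    """Configuration for the isoform-switch benchmark: high expression and
    small dispersion so count noise is at most ~10% of the group-profile
    signal, with biological group variation giving non-switch genes a
    structured profile."""
    return SimConfig(seed=seed, n_genes=n_genes, n_switch_genes=n_switch,
                     n_up_fish=0, n_down_fish=0, conserved_fraction=0.0,
                     nb_alpha=0.005, baseline_log_mean=8.0,
                     baseline_log_sigma=0.5, group_effect_sigma=1.0,
                     isoform_fractions=(0.3, 0.5, 0.2), hp_pool_size=1,
                     fish_depths=(1.0, 1.0, 1.0, 1.0))


def score_recovery(truth: SimTruth, *,
                   fish_de=None, human_de=None,
                   conserved: tuple[set[str], set[str]] | None = None,
                   splice=None) -> pd.DataFrame:
    """Sensitivity/FDR against the planted truth for each supplied result.

    Conventions: sensitivity = TP / planted positives (0 when none planted);
    FDR = FP / called (0 when nothing called).
    """

    def _score(true_pos: set[str], called: set[str]) -> dict:
        tp = len(true_pos & called)
        fp = len(called - true_pos)
        fn = len(true_pos - called)
        return {"tp": tp, "fp": fp, "fn": fn,
                "sensitivity": tp / len(true_pos) if true_pos else 0.0,
                "fdr": fp / len(called) if called else 0.0}

    rows = []
    tdf = truth.df
    if fish_de is not None:
        for d in ("up", "down"):
            planted = set(tdf.index[tdf["fish_direction"] == d])
            rows.append({"task": f"fish_de_{d}",
                         **_score(planted, fish_de.called(d))})
    if human_de is not None:
        called_up = set(human_de.df.index[human_de.df["call"] == "up"])
        called_down = set(human_de.df.index[human_de.df["call"] == "down"])
        for d, called in (("up", called_up), ("down", called_down)):
            planted = set(tdf.loc[tdf["human_direction"] == d, "human_symbol"])
            rows.append({"task": f"human_de_{d}", **_score(planted, called)})
    if conserved is not None:
        up_set, down_set = conserved
        rows.append({"task": "conserved_up",
                     **_score(truth.conserved_symbols("up"), up_set)})
        rows.append({"task": "conserved_down",
                     **_score(truth.conserved_symbols("down"), down_set)})
    if splice is not None:
        planted = truth.switch_genes()
        called = splice.genes_in("differential")
        rows.append({"task": "switch", **_score(planted, called)})
    if not rows:
        raise ValueError("no results supplied to score")
    return pd.DataFrame(rows).set_index("task")
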