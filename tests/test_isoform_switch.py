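"""The correlation-range (RC) statistic and the four-way gene partition."""

import numpy as np
import pandas as pd
import pytest

from xconcord.isoform_switch import (CATEGORIES, classify_genes, gene_mean_profile,
                                     rc_gene, select_multi_isoform,
                                     transcript_group_profiles)
from xconcord.rnaseq_quant import ExpressionMatrix, rpkm
from xconcord.synthetic_data import simulate, switch_study_config
from xconcord.tables_io import TranscriptAnnotation


# --- independent direct-summation Pearson oracle ---------------------------

def pearson_bruteforce(x, y) -> float:
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(v * v for v in x); syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den if den > 0 else float("nan")


def rc_bruteforce(profiles: pd.DataFrame) -> float:
    mean = profiles.to_numpy().mean(axis=0)
    corrs = [pearson_bruteforce(profiles.loc[t].tolist(), mean.tolist())
             for t in profiles.index]
    defined = [c for c in corrs if np.isfinite(c)]
    return (max(defined) - min(defined)) if len(defined) >= 2 else float("nan")


def _ann(gene_of: dict) -> TranscriptAnnotation:
    df = pd.DataFrame({
        "gene_id": list(gene_of.values()),
        "gene_symbol": [g.upper() for g in gene_of.values()],
        "length_bp": 1000,
    }, index=pd.Index(list(gene_of.keys()), name="transcript_id"))
    return TranscriptAnnotation(df)


def _expr(rows: dict, groups=("HP", "XE", "MM", "UM")) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(groups))
    return ExpressionMatrix(df, {g: g for g in groups}, gate=2.0)


class TestSelection:
    def test_single_isoform_excluded_multi_included(self):
        ann = _ann({"t1": "g1", "t2": "g2", "t3": "g2", "t4": "g3",
                    "t5": "g3", "t6": "g3"})
        assert set(select_multi_isoform(ann)) == {"g2", "g3"}

    def test_selection_partitions_gene_universe(self):
        ann = _ann({f"t{i}": f"g{i % 7}" for i in range(20)})
        multi = select_multi_isoform(ann)
        n_single = sum(ann.transcripts_per_gene() == 1)
        assert len(multi) + n_single == ann.transcripts_per_gene().size


class TestGeneMeanProfile:
    def test_mean_of_two_transcripts(self):
        profiles = pd.DataFrame([[1, 2, 3, 4], [3, 2, 1, 0]],
                                index=["t1", "t2"], dtype=float)
        np.testing.assert_allclose(gene_mean_profile(profiles), [2, 2, 2, 2])

    def test_single_transcript_identity(self):
        profiles = pd.DataFrame([[5, 6, 7, 8]], index=["t1"], dtype=float)
        np.testing.assert_allclose(gene_mean_profile(profiles), [5, 6, 7, 8])

    def test_group_order_equivariance(self):
        profiles = pd.DataFrame([[1, 2, 3, 4], [4, 1, 2, 2]], dtype=float)
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(gene_mean_profile(profiles.iloc[:, perm]),
                                   gene_mean_profile(profiles)[perm])


class TestRcGene:
    def test_proportional_isoforms_rc_zero(self):
        profiles = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8]],
                                index=["t1", "t2"], dtype=float)
        rc, corrs = rc_gene(profiles)
        assert rc == pytest.approx(0.0, abs=1e-12)
        assert corrs["t1"] == pytest.approx(1.0)

    def test_anticorrelated_isoforms_rc_two(self):
        # mean = [4.5, 4, 3.5, 3]; t1 correlates +1... -1 and t2 the opposite
        profiles = pd.DataFrame([[1, 2, 3, 4], [8, 6, 4, 2]],
                                index=["t1", "t2"], dtype=float)
        rc, corrs = rc_gene(profiles)
        assert corrs["t1"] == pytest.approx(-1.0)
        assert corrs["t2"] == pytest.approx(1.0)
        assert rc == pytest.approx(2.0)

    def test_constant_profile_dropped(self):
        profiles = pd.DataFrame([[5, 5, 5, 5], [1, 2, 3, 4], [2, 4, 6, 8]],
                                index=["t1", "t2", "t3"], dtype=float)
        rc, corrs = rc_gene(profiles)
        assert np.isnan(corrs["t1"])
        assert rc == pytest.approx(0.0, abs=1e-12)  # t2, t3 both corr 1

    def test_fewer_than_two_defined_gives_nan(self):
        profiles = pd.DataFrame([[5, 5, 5, 5], [1, 2, 3, 4]],
                                index=["t1", "t2"], dtype=float)
        rc, _ = rc_gene(profiles)
        assert np.isnan(rc)

    def test_transcript_swap_invariance(self):
        profiles = pd.DataFrame([[1, 5, 2, 7], [3, 1, 9, 2]],
                                index=["t1", "t2"], dtype=float)
        rc1, _ = rc_gene(profiles)
        rc2, _ = rc_gene(profiles.iloc[::-1])
        assert rc1 == rc2

    def test_matches_bruteforce_on_random_profiles(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            k = rng.integers(2, 5)
            profiles = pd.DataFrame(rng.exponential(5, size=(k, 4)),
                                    index=[f"t{i}" for i in range(k)])
            rc, _ = rc_gene(profiles)
            rc_ref = rc_bruteforce(profiles)
            if np.isnan(rc):
                assert np.isnan(rc_ref)
            else:
                assert abs(rc - rc_ref) < 1e-12
            assert np.isnan(rc) or 0 <= rc <= 2


class TestClassifyGenes:
    def _setup(self):
        ann = _ann({"a1": "gA", "a2": "gA",      # not expressed
                    "b1": "gB", "b2": "gB",      # single expressed transcript
                    "c1": "gC", "c2": "gC",      # differential (RC = 2)
                    "d1": "gD", "d2": "gD",      # same direction
                    "e1": "gE"})                 # single-isoform: excluded
        expr = _expr({
            "a1": [0, 0, 1, 0], "a2": [1, 1, 0, 0],
            "b1": [9, 9, 9, 9], "b2": [1, 1, 1, 1],
            "c1": [10, 20, 30, 40], "c2": [80, 60, 40, 20],
            "d1": [10, 20, 30, 40], "d2": [20, 40, 60, 80],
            "e1": [50, 50, 50, 50],
        })
        return expr, ann

    def test_four_way_classification(self):
        expr, ann = self._setup()
        res = classify_genes(expr, ann)
        cats = res.df["category"]
        assert cats.loc["gA"] == "not_expressed"
        assert cats.loc["gB"] == "single_transcript"
        assert cats.loc["gC"] == "differential"
        assert cats.loc["gD"] == "same_direction"
        assert "gE" not in res.df.index

    def test_partition_sums_to_multi_isoform_count(self):
        expr, ann = self._setup()
        res = classify_genes(expr, ann)
        counts = res.category_counts()
        assert counts.sum() == len(select_multi_isoform(ann))
        assert set(res.df["category"]) <= set(CATEGORIES)

    def test_rc_threshold_boundary(self):
        # RC exactly 1 is not differential (strict >1)
        expr, ann = self._setup()
        res = classify_genes(expr, ann, rc_threshold=2.0)
        assert res.df.loc["gC", "category"] == "same_direction"

    def test_tumor_only_scope_ignores_reference_expression(self):
        ann = _ann({"f1": "gF", "f2": "gF"})
        expr = _expr({"f1": [50, 0, 0, 0], "f2": [30, 1, 1, 1]})
        res_any = classify_genes(expr, ann, expression_scope="any_group")
        res_tum = classify_genes(expr, ann, expression_scope="tumor_groups_only")
        assert res_any.df.loc["gF", "category"] == "same_direction"
        assert res_tum.df.loc["gF", "category"] == "not_expressed"


class TestPlantedSwitchRecovery:
    def test_sensitivity_and_specificity(self):
        sim = simulate(switch_study_config(seed=33, n_genes=800, n_switch=80))
        expr = rpkm(sim.counts, sim.annotation)
        res = classify_genes(expr, sim.annotation)
        planted = sim.truth.switch_genes()
        called = res.genes_in("differential")
        sens = len(called & planted) / len(planted)
        others = set(res.df.index) - planted
        spec = 1 - len(called - planted) / len(others)
        assert sens >= 0.95
        assert spec >= 0.95

    def test_pipeline_rc_equals_bruteforce_on_simulation(self):
        sim = simulate(switch_study_config(seed=34, n_genes=300, n_switch=30))
        expr = rpkm(sim.counts, sim.annotation)
        res = classify_genes(expr, sim.annotation)
        profiles = transcript_group_profiles(expr)
        gate_any = expr.expressed_mask.any(axis=1)
        by_gene = sim.annotation.table.groupby("gene_id").groups
        checked = 0
        for gene, row in res.df.iterrows():
            if row["n_isoforms_expressed"] < 2:
                continue
            expressed = [t for t in by_gene[gene] if gate_any.get(t, False)]
            ref = rc_bruteforce(profiles.loc[expressed])
            if np.isnan(row["rc_gene"]):
                assert np.isnan(ref)
            else:
                assert abs(row["rc_gene"] - ref) < 1e-12
            checked += 1
        assert checked > 50
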