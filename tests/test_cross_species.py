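"""Symbol joins, conserved signatures, motif overlaps and over-representation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from xconcord.cross_species import (CONSERVED_STATUSES, conserved_signature,
                                    join_on_symbols, motif_overlap,
                                    over_representation, zebrafish_compare)
from xconcord.diffexpr_nb import DEResult
from xconcord.microarray_de import ModeratedTResult
from xconcord.tables_io import OrthologTable, SignatureSet


def _fish(rows: dict[str, tuple]) -> DEResult:
    """rows: gene_id -> (symbol, log2fc, p, call)."""
    df = pd.DataFrame(
        [{"symbol": s, "log2fc": f, "p": p, "call": c}
         for s, f, p, c in rows.values()],
        index=pd.Index(list(rows), name="gene_id"))
    return DEResult(df=df, contrast="TUM_vs_HP", group_a="HP", group_b="TUM")


def _human(rows: dict[str, tuple]) -> ModeratedTResult:
    """rows: symbol -> (log2fc, p, call)."""
    df = pd.DataFrame([{"log2fc": f, "p": p, "call": c}
                       for f, p, c in rows.values()],
                      index=pd.Index(list(rows), name="symbol"))
    return ModeratedTResult(df=df, d0=4.0, s0_sq=1.0,
                            group_a="nevus", group_b="melanoma")


def _orth(pairs: list[tuple[str, str]]) -> OrthologTable:
    return OrthologTable(pd.DataFrame(
        [{"fish_gene_id": f, "fish_symbol": h.lower(), "human_symbol": h}
         for f, h in pairs]))


class TestJoin:
    def test_matching_up_calls_give_common_up(self):
        table = join_on_symbols(
            _fish({"f1": ("bcl2", 3.0, 0.01, "up")}),
            _human({"BCL2": (2.0, 0.01, "up")}),
            _orth([("f1", "BCL2")]))
        assert table.df.loc["BCL2", "status"] == "common_up"

    def test_paralog_any_call_policy(self):
        table = join_on_symbols(
            _fish({"f1": ("cdh2a", 3.0, 0.01, "up"),
                   "f2": ("cdh2b", 0.5, 0.9, "none")}),
            _human({"CDH2": (2.0, 0.01, "up")}),
            _orth([("f1", "CDH2"), ("f2", "CDH2")]),
            paralog_policy="any_call")
        assert table.df.loc["CDH2", "fish_call"] == "up"
        assert table.df.loc["CDH2", "status"] == "common_up"

    def test_fish_only_symbols_excluded(self):
        table = join_on_symbols(
            _fish({"f1": ("bcl2", 3.0, 0.01, "up"),
                   "f2": ("nohuman", 3.0, 0.01, "up")}),
            _human({"BCL2": (2.0, 0.01, "up")}),
            _orth([("f1", "BCL2"), ("f2", "NOHUMAN")]))
        assert list(table.df.index) == ["BCL2"]

    def test_statuses_partition_the_table(self):
        rng = np.random.default_rng(17)
        calls = ["up", "down", "none"]
        fish, human, orth = {}, {}, []
        for i in range(60):
            sym = f"G{i}"
            fish[f"f{i}"] = (sym.lower(), rng.normal(), 0.5, calls[i % 3])
            human[sym] = (rng.normal(), 0.5, calls[(i // 3) % 3])
            orth.append((f"f{i}", sym))
        table = join_on_symbols(_fish(fish), _human(human), _orth(orth))
        counts = table.status_counts()
        assert counts.sum() == len(table.df)
        assert set(table.df["status"]) <= set(CONSERVED_STATUSES)
        down_both = table.df[(table.df.fish_call == "down")
                             & (table.df.human_call == "down")]
        assert (down_both["status"] == "common_down").all()

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no symbols common"):
            join_on_symbols(_fish({"f1": ("abc", 1.0, 0.5, "none")}),
                            _human({"XYZ": (0.0, 1.0, "none")}),
                            _orth([("f1", "ABC")]))


class TestConservedSignature:
    def test_set_extraction(self):
        table = join_on_symbols(
            _fish({"f1": ("a", 3.0, 0.01, "up"),
                   "f2": ("b", -3.0, 0.01, "down"),
                   "f3": ("c", -3.0, 0.01, "down"),
                   "f4": ("d", 3.0, 0.01, "up")}),
            _human({"A": (2.0, 0.01, "up"), "B": (-2.0, 0.01, "down"),
                    "C": (-2.0, 0.01, "down"), "D": (-2.0, 0.01, "down")}),
            _orth([("f1", "A"), ("f2", "B"), ("f3", "C"), ("f4", "D")]))
        up, down = conserved_signature(table)
        assert up == {"A"} and down == {"B", "C"}
        assert not up & down

    def test_direction_swap_symmetry(self):
        flip = {"up": "down", "down": "up", "none": "none"}
        fish = {"f1": ("a", 3.0, 0.01, "up"), "f2": ("b", -3.0, 0.01, "down")}
        human = {"A": (2.0, 0.01, "up"), "B": (-2.0, 0.01, "down")}
        orth = _orth([("f1", "A"), ("f2", "B")])
        up1, down1 = conserved_signature(join_on_symbols(_fish(fish), _human(human), orth))
        fish2 = {k: (s, -f, p, flip[c]) for k, (s, f, p, c) in fish.items()}
        human2 = {k: (-f, p, flip[c]) for k, (f, p, c) in human.items()}
        up2, down2 = conserved_signature(join_on_symbols(_fish(fish2), _human(human2), orth))
        assert up1 == down2 and down1 == up2


class TestMotifOverlap:
    def _contrasts(self):
        c1 = _fish({"f1": ("a", 2.0, 0.01, "up"), "f2": ("b", 1.5, 0.01, "up"),
                    "f3": ("c", 1.0, 0.5, "none")})
        c2 = _fish({"f1": ("a", 1.5, 0.01, "up"), "f2": ("b", 0.5, 0.2, "none"),
                    "f3": ("c", 1.0, 0.5, "none")})
        return [c1, c2]

    def test_counts_with_all_quantifier(self):
        sig = SignatureSet("motif1", frozenset({"A", "B", "ZZZ"}), "up")
        rep = motif_overlap(self._contrasts(), sig, fold=2.0)
        # A: >2-fold in both contrasts; B only in the first; ZZZ absent
        assert (rep.n_signature, rep.n_shared, rep.n_meeting) == (3, 2, 1)
        assert rep.meeting_symbols == {"A"}

    def test_fold_boundary_excluded(self):
        sig = SignatureSet("m", frozenset({"A"}), "up")
        de = _fish({"f1": ("a", 1.0, 0.01, "up")})  # fold exactly 2
        rep = motif_overlap([de], sig, fold=2.0)
        assert rep.n_meeting == 0

    def test_empty_intersection(self):
        sig = SignatureSet("m", frozenset({"Q1", "Q2"}), "up")
        rep = motif_overlap(self._contrasts(), sig, fold=2.0)
        assert (rep.n_signature, rep.n_shared, rep.n_meeting) == (2, 0, 0)

    def test_monotone_in_fold_threshold(self):
        sig = SignatureSet("m", frozenset({"A", "B", "C"}), "up")
        reps = [motif_overlap(self._contrasts(), sig, fold=f).n_meeting
                for f in (1.5, 2.0, 3.0, 5.0)]
        assert all(a >= b for a, b in zip(reps, reps[1:]))

    def test_any_quantifier_and_contrast_order_invariance(self):
        sig_up = SignatureSet("zf_up", frozenset({"A", "B", "C"}), "up")
        sig_down = SignatureSet("zf_down", frozenset({"C"}), "down")
        contrasts = self._contrasts()
        up, down = zebrafish_compare(contrasts, sig_up, sig_down)
        assert up.quantifier == "any"
        assert up.n_meeting == 2          # A everywhere, B in one contrast
        assert down.n_meeting == 0
        up_rev, _ = zebrafish_compare(contrasts[::-1], sig_up, sig_down)
        assert up_rev.n_meeting == up.n_meeting


class TestOverRepresentation:
    def test_expected_count_closed_form(self):
        universe = {f"G{i}" for i in range(100)}
        pathway = {f"G{i}" for i in range(10)}
        gene_list = {f"G{i}" for i in range(50, 60)}
        out = over_representation(gene_list, {"pw": pathway}, universe)
        assert out.loc["pw", "expected"] == pytest.approx(1.0)

    def test_zero_observed_p_is_one(self):
        universe = {f"G{i}" for i in range(20)}
        out = over_representation({"G0"}, {"pw": {"G10", "G11"}}, universe)
        assert out.loc["pw", "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_case(self):
        # N=10, K=4, n=3: compare upper-tail p to direct counting
        universe = {f"G{i}" for i in range(10)}
        pathway = {"G0", "G1", "G2", "G3"}
        gene_list = {"G0", "G1", "G9"}      # k = 2
        out = over_representation(gene_list, {"pw": pathway}, universe)
        total = 0
        at_least = 0
        for combo in itertools.combinations(sorted(universe), 3):
            total += 1
            if len(set(combo) & pathway) >= 2:
                at_least += 1
        assert out.loc["pw", "p"] == pytest.approx(at_least / total, rel=1e-12)

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            over_representation({"NOPE"}, {}, {"G1"})
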