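"""Read counting, log fold enrichment, titer ranking, positional preference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qtrna import (
    LibraryClass,
    LibraryCounts,
    Phase,
    TiterRecord,
    classify_library,
    count_library_members,
    log_fold_enrichment,
    positional_preference,
    rank_selections,
    simulate_selection_reads,
    titer_log_fold_change,
)
from Bio.Seq import Seq


def make_counts(library, counts, phase=Phase.PRE, extra_discarded=0):
    full = {k: 0 for k in library.members}
    full.update(counts)
    n = sum(full.values()) + extra_discarded
    return LibraryCounts(library=library, phase=phase, counts=full,
                         n_reads_total=n, n_discarded=extra_discarded)


class TestCountLibraryMembers:
    def read_for(self, lib, key):
        return lib.flank_5 + lib.member_window(key) + lib.flank_3

    def test_exact_counting_with_discards(self, loopside_library):
        lib = loopside_library
        good = self.read_for(lib, "AAC")
        broken = ("T" + good[2:])[: len(good)]  # 5' flank broken
        counts = count_library_members([good, good, good, broken], lib,
                                       search_reverse_complement=False)
        assert counts.counts["AAC"] == 3
        assert counts.n_discarded == 1
        assert sum(counts.counts.values()) + counts.n_discarded == 4

    def test_n_in_window_discarded(self, loopside_library):
        lib = loopside_library
        read = self.read_for(lib, "AAC")
        w_start = len(lib.flank_5)  # first window base is randomized (pos 32)
        read = read[:w_start] + "N" + read[w_start + 1 :]
        counts = count_library_members([read], lib)
        assert counts.n_discarded == 1

    def test_wrong_window_length_discarded(self, loopside_library):
        lib = loopside_library
        window = lib.member_window("AAC")
        read = lib.flank_5 + window[:-1] + lib.flank_3  # one base missing
        counts = count_library_members([read], lib)
        assert counts.n_discarded == 1

    def test_reverse_complement_reads_counted(self, loopside_library):
        lib = loopside_library
        rc = str(Seq(self.read_for(lib, "GAC")).reverse_complement())
        assert count_library_members([rc], lib).counts["GAC"] == 1
        assert count_library_members(
            [rc], lib, search_reverse_complement=False).n_discarded == 1

    def test_simulated_multinomial_within_sampling_error(self, loopside_library):
        lib = loopside_library
        rng = np.random.default_rng(5)
        weights = rng.dirichlet([2.0] * 64)
        _, post = simulate_selection_reads(lib, weights, depth=10_000, seed=5)
        counts = count_library_members([str(r.seq) for r in post], lib, "POST")
        assert counts.n_discarded == 0
        p = weights / weights.sum()
        z = []
        for k, pi in zip(sorted(lib.members), p):
            sigma = math.sqrt(10_000 * pi * (1 - pi))
            z.append(abs(counts.counts[k] - 10_000 * pi) / max(sigma, 1e-9))
        # seeded draw: essentially all members within 3 sigma, none extreme
        assert np.mean(np.array(z) < 3) > 0.93
        assert max(z) < 4.5

    def test_library_without_flanks_rejected(self, loopside_library):
        from dataclasses import replace

        broken = replace(loopside_library, flank_5="")
        with pytest.raises(ValueError):
            count_library_members([], broken)


class TestLogFoldEnrichment:
    def test_identical_counts_give_zero(self, loopside_library):
        counts = {k: 10 for k in loopside_library.members}
        pre = make_counts(loopside_library, counts, Phase.PRE)
        post = make_counts(loopside_library, counts, Phase.POST)
        result = log_fold_enrichment(pre, post)
        assert all(v == 0.0 for v in result.enrichment.values())
        assert result.library_class is LibraryClass.NO_PRESSURE

    def test_hand_computed_single_winner(self, loopside_library):
        # pre uniform 100x64; post: all 6400 reads on AAA
        pre = make_counts(loopside_library, {k: 100 for k in
                                             loopside_library.members})
        post = make_counts(loopside_library, {"AAA": 6400}, Phase.POST)
        result = log_fold_enrichment(pre, post, pseudocount=1)
        expected = math.log10((6401 / 6464) / (101 / 6464))
        assert result.enrichment["AAA"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.802, abs=1e-3)
        assert all(v < 0 for k, v in result.enrichment.items() if k != "AAA")
        assert result.top_member == "AAA"
        assert result.library_class is LibraryClass.SINGLE_DOMINANT

    def test_depth_invariance_up_to_pseudocount(self, loopside_library):
        rng = np.random.default_rng(0)
        base = {k: int(c) for k, c in zip(
            sorted(loopside_library.members),
            rng.integers(50, 400, size=64))}
        pre1 = make_counts(loopside_library, base)
        post_counts = {k: 2 * c for k, c in base.items()}
        doubled_pre = make_counts(loopside_library,
                                  {k: 2 * c for k, c in base.items()})
        doubled_post = make_counts(loopside_library,
                                   {k: 4 * c for k, c in base.items()},
                                   Phase.POST)
        r1 = log_fold_enrichment(pre1, make_counts(
            loopside_library, post_counts, Phase.POST))
        r2 = log_fold_enrichment(doubled_pre, doubled_post)
        for k in loopside_library.members:
            assert abs(r1.enrichment[k] - r2.enrichment[k]) < 0.01

    def test_zero_reads_rejected(self, loopside_library):
        empty = make_counts(loopside_library, {})
        full = make_counts(loopside_library, {"AAA": 10}, Phase.POST)
        with pytest.raises(ValueError):
            log_fold_enrichment(empty, full)

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)),
                      min_size=64, max_size=64),
        psi=st.floats(0.1, 5.0),
    )
    def test_antisymmetric_under_phase_swap(self, loopside_library, data, psi):
        keys = sorted(loopside_library.members)
        pre_c = {k: a for k, (a, b) in zip(keys, data)}
        post_c = {k: b for k, (a, b) in zip(keys, data)}
        if sum(pre_c.values()) == 0 or sum(post_c.values()) == 0:
            return
        pre = make_counts(loopside_library, pre_c)
        post = make_counts(loopside_library, post_c, Phase.POST)
        fwd = log_fold_enrichment(pre, post, psi).enrichment
        rev = log_fold_enrichment(
            make_counts(loopside_library, post_c),
            make_counts(loopside_library, pre_c, Phase.POST), psi).enrichment
        for k in keys:
            assert fwd[k] == pytest.approx(-rev[k], abs=1e-12)

    def test_post_marginals_sum_to_one(self, loopside_library):
        rng = np.random.default_rng(3)
        counts = {k: int(c) for k, c in zip(sorted(loopside_library.members),
                                            rng.integers(0, 50, size=64))}
        pre = make_counts(loopside_library, {k: 5 for k in counts})
        post = make_counts(loopside_library, counts, Phase.POST)
        result = log_fold_enrichment(pre, post)
        for freqs in result.marginals_post:
            assert sum(freqs.values()) == pytest.approx(1.0)


class TestTiters:
    @pytest.mark.parametrize(
        "pre, post, expected",
        [(1e5, 1e8, 3.0), (1e5, 1e5, 0.0), (1e5, 1e4, -1.0)],
    )
    def test_log_fold_change(self, pre, post, expected):
        assert titer_log_fold_change(pre, post) == pytest.approx(expected)

    def test_nonpositive_titer_rejected(self):
        with pytest.raises(ValueError):
            titer_log_fold_change(0.0, 1e5)

    def test_rank_and_pass_flags(self):
        records = [
            TiterRecord("a", 1e5, 1.2e6),   # 12-fold: pass
            TiterRecord("b", 1e5, 1e6),     # exactly 10-fold: fail ("over")
            TiterRecord("c", 1e5, 1e8),     # pass, ranks first
        ]
        ranked = rank_selections(records)
        assert [r.selection for r, _, _ in ranked] == ["c", "a", "b"]
        assert [p for _, _, p in ranked] == [True, True, False]

    def test_empty(self):
        assert rank_selections([]) == []


class TestPositionalPreference:
    def make_result(self, counts, loopside_library):
        pre = make_counts(loopside_library, {k: 10 for k in
                                             loopside_library.members})
        post = make_counts(loopside_library, counts, Phase.POST)
        return log_fold_enrichment(pre, post)

    def test_fixed_base_at_position_37(self, loopside_library):
        counts = {k: 50 for k in loopside_library.members if k[1] == "A"}
        result = self.make_result(counts, loopside_library)
        labels = positional_preference(result)
        assert labels["37"] == "A"
        assert labels["32"] == "mixed" and labels["38"] == "mixed"

    def test_uniform_post_all_mixed(self, loopside_library):
        counts = {k: 10 for k in loopside_library.members}
        labels = positional_preference(self.make_result(counts, loopside_library))
        assert set(labels.values()) == {"mixed"}

    def test_threshold_boundary(self, loopside_library):
        # base A at 76% of position-32 reads: dominant at 0.75, not at 0.8
        counts = {}
        a_keys = [k for k in sorted(loopside_library.members) if k[0] == "A"]
        other = [k for k in sorted(loopside_library.members) if k[0] != "A"]
        for k in a_keys:
            counts[k] = 76
        for i, k in enumerate(other[:24]):
            counts[k] = 16  # 24*16 = 384; A total 16*76 = 1216 of 1600
        result = self.make_result(counts, loopside_library)
        m32 = result.marginals_post[0]
        assert m32["A"] == pytest.approx(0.76)
        assert positional_preference(result, 0.75)["32"] == "A"
        assert positional_preference(result, 0.8)["32"] == "mixed"


class TestClassification:
    def test_pure_function_of_inputs(self):
        enr = {"AAA": 1.5, "AAC": 0.2, "AAG": -0.3}
        marg = [{"A": 0.9, "C": 0.05, "G": 0.05, "T": 0.0}]
        assert classify_library(enr, marg) == classify_library(enr, marg)
        assert classify_library(enr, marg) is LibraryClass.SINGLE_DOMINANT

    def test_positional_preference_class(self):
        enr = {"AAA": 0.8, "AAC": 0.7, "AAG": -0.6}
        marg = [{"A": 0.9, "C": 0.05, "G": 0.05, "T": 0.0}]
        assert classify_library(enr, marg) is LibraryClass.POSITIONAL_PREFERENCE

    def test_no_pressure_when_quiet(self):
        enr = {"AAA": 0.3, "AAC": -0.4}
        marg = [{"A": 0.4, "C": 0.3, "G": 0.2, "T": 0.1}]
        assert classify_library(enr, marg) is LibraryClass.NO_PRESSURE
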