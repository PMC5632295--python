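import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import citescan as cs
from citescan._align import revcomp
from citescan.formats import NucRead
from citescan.preprocess import (fraction_filter, merge_pair,
                                 preprocess_sample, trim_adapters,
                                 window_trim)

from oracles import brute_fraction_keep, brute_window_trim_length


def mk(seq, q=37, rid="r"):
    return NucRead(rid, seq, [q] * len(seq))


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAdapterTrim:
    def test_5p_adapter_and_upstream_removed(self, params, rng):
        x = rand_seq(rng, 50)
        read = mk("TGTGTATAAGAGACAG" + x)
        out = trim_adapters(read, params)
        assert out.seq == x

    def test_prefix_before_adapter_also_removed(self, params, rng):
        x = rand_seq(rng, 50)
        read = mk("CCGT" + "TGTGTATAAGAGACAG" + x)
        assert trim_adapters(read, params).seq == x

    def test_3p_adapter_and_downstream_removed(self, params, rng):
        x = rand_seq(rng, 50)
        read = mk(x + "CTGTCTCTTATACACA" + rand_seq(rng, 30))
        assert trim_adapters(read, params).seq == x

    def test_no_adapter_leaves_read_unchanged(self, params):
        seq = "ACGT" * 20
        assert trim_adapters(mk(seq), params).seq == seq

    def test_short_leftover_dropped(self, params, rng):
        x = rand_seq(rng, 10)  # post-trim length 10 <= 10 -> dropped
        read = mk("TGTGTATAAGAGACAG" + x)
        assert trim_adapters(read, params) is None

    def test_one_error_in_adapter_tolerated(self, params, rng):
        x = rand_seq(rng, 50)
        adapter = "TGTGTATAAGAGACAG"
        mutated = adapter[:7] + ("A" if adapter[7] != "A" else "C") \
            + adapter[8:]
        assert trim_adapters(mk(mutated + x), params).seq == x


class TestMergePair:
    def _pair(self, rng, flen, rlen, overlap):
        """Construct fwd/rev mates sharing an exact terminal overlap."""
        insert = rand_seq(rng, flen + rlen - overlap)
        fwd = mk(insert[:flen], rid="p")
        rev = NucRead("p", revcomp(insert[-rlen:]), [37] * rlen)
        return fwd, rev, insert

    def test_exact_overlap_merges_to_expected_length(self, params, rng):
        fwd, rev, insert = self._pair(rng, 200, 200, 50)
        merged, pair = merge_pair(fwd, rev, params)
        assert pair is None
        assert len(merged) == 350
        assert merged.seq == insert

    def test_overlap_below_minimum_stays_unmerged(self, params, rng):
        fwd, rev, _ = self._pair(rng, 200, 200, 10)
        merged, pair = merge_pair(fwd, rev, params)
        # a 10-nt true overlap is below the 16-nt floor; a chance longer
        # overlap in random sequence is vanishingly unlikely
        assert merged is None and pair == (fwd, rev)

    def test_disagreement_takes_higher_quality_base(self, params, rng):
        # fwd: ...A with q30 / rev covers same position with C at q20
        core = rand_seq(rng, 40)
        fwd_seq = core + "A"
        rev_covered = core + "C"
        fwd = NucRead("p", fwd_seq, [30] * 41)
        rev = NucRead("p", revcomp(rev_covered), [20] * 41)
        merged, _ = merge_pair(fwd, rev, params)
        assert merged is not None
        assert merged.seq == core + "A"
        assert merged.quals[-1] == 10  # |30 - 20|

    def test_agreement_keeps_higher_quality(self, params, rng):
        seq = rand_seq(rng, 40)
        fwd = NucRead("p", seq, [30] * 40)
        rev = NucRead("p", revcomp(seq), [20] * 40)
        merged, _ = merge_pair(fwd, rev, params)
        assert merged.seq == seq
        assert all(q == 30 for q in merged.quals)

    def test_merge_content_symmetry(self, params, rng):
        """Swapping roles (rev side as fwd) yields the reverse-complement
        pseudo-read."""
        fwd, rev, _ = self._pair(rng, 150, 150, 60)
        m1, _ = merge_pair(fwd, rev, params)
        # exchanging the mates describes the same molecule from the
        # opposite strand
        m2, _ = merge_pair(rev, fwd, params)
        assert m1 is not None and m2 is not None
        assert m2.seq == revcomp(m1.seq)


class TestWindowTrim:
    def test_all_high_quality_unchanged(self, params):
        r = mk("A" * 60, q=30)
        assert window_trim(r, params).seq == r.seq

    def test_hand_computed_truncation(self, params):
        # 15x Q30 then 15x Q19: window means 30, 26.33, 22.67 pass; the
        # window at offset 15 has mean 19 < 20 -> truncate to 15 nt
        r = NucRead("r", "A" * 30, [30] * 15 + [19] * 15)
        assert len(window_trim(r, params)) == 15

    def test_short_read_single_window(self, params):
        r = mk("A" * 10, q=10)
        assert len(window_trim(r, params)) == 0

    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=0,
                    max_size=80))
    def test_matches_brute_force(self, quals):
        params = cs.PipelineParams()
        r = NucRead("r", "A" * len(quals), list(quals))
        expect = brute_window_trim_length(quals, params.window, params.step,
                                          params.trim_q)
        assert len(window_trim(r, params)) == expect


class TestFractionFilter:
    def test_boundary_inclusive(self, params):
        r = NucRead("r", "A" * 100, [20] * 95 + [19] * 5)
        assert fraction_filter(r, params) is True

    def test_below_boundary_dropped(self, params):
        r = NucRead("r", "A" * 100, [20] * 94 + [19] * 6)
        assert fraction_filter(r, params) is False

    def test_empty_read_dropped(self, params):
        assert fraction_filter(NucRead("r", "", []), params) is False

    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=0,
                    max_size=60))
    def test_matches_brute_force(self, quals):
        params = cs.PipelineParams()
        r = NucRead("r", "A" * len(quals), list(quals))
        assert fraction_filter(r, params) == brute_fraction_keep(
            quals, params.trim_q, params.frac_q20)


class TestPreprocessSample:
    def test_clean_sample_full_survival(self, refdb, tmp_path, params):
        from citescan.simulate import mixture_from_refdb, simulate_mixture
        spec = mixture_from_refdb(refdb, [("Bos taurus", 1.0)], 200, 5,
                                  quality_profile="clean",
                                  sub_error_rate=0.0, chimera_rate=0.0)
        paths = simulate_mixture(spec, tmp_path)
        pool = preprocess_sample(paths["r1"], paths["r2"], params)
        assert pool.counters["raw_reads"] == 400
        assert pool.counters["qc_raw_equiv"] == 400

    def test_empty_inputs(self, tmp_path, params):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("")
        r2.write_text("")
        pool = preprocess_sample(r1, r2, params)
        assert len(pool) == 0
        assert pool.counters["raw_reads"] == 0

    def test_mate_count_mismatch_raises(self, tmp_path, params):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@a\nACGTACGTACGTACGT\n+\nIIIIIIIIIIIIIIII\n")
        r2.write_text("")
        with pytest.raises(ValueError, match="mate count"):
            preprocess_sample(r1, r2, params)

    def test_oracle_equivalence_on_noisy_sample(self, refdb, tmp_path):
        """%QC equals a straight-line reference applying the four rules."""
        from citescan.simulate import mixture_from_refdb, simulate_mixture
        spec = mixture_from_refdb(refdb, [("Lactuca sativa", 1.0)], 150, 7,
                                  quality_profile="harsh",
                                  sub_error_rate=0.01, chimera_rate=0.0)
        paths = simulate_mixture(spec, tmp_path)
        params = cs.PipelineParams()
        pool = preprocess_sample(paths["r1"], paths["r2"], params)
        # reference: trim adapters + drop short, merge, window trim,
        # fraction filter -- stream by stream
        fwd = [trim_adapters(r, params) for r in cs.parse_fastq(paths["r1"])]
        rev = [trim_adapters(r, params) for r in cs.parse_fastq(paths["r2"])]
        survivors = 0
        for f, r in zip(fwd, rev):
            streams = []
            if f is not None and r is not None:
                m, pair = merge_pair(f, r, params)
                streams = [m] if m is not None else list(pair)
            elif f is not None:
                streams = [f]
            elif r is not None:
                streams = [r]
            for s in streams:
                t = window_trim(s, params)
                if fraction_filter(t, params):
                    survivors += 1
        assert len(pool) == survivors

    def test_every_survivor_satisfies_fraction_filter(self, em11_small,
                                                      params):
        _spec, paths = em11_small
        pool = preprocess_sample(paths["r1"], paths["r2"], params)
        for r in pool.reads():
            assert fraction_filter(r, params)


class TestStrictnessMonotonicity:
    def test_stricter_fraction_never_gains_reads(self, em11_small):
        _spec, paths = em11_small
        base = cs.PipelineParams()
        stricter = cs.PipelineParams(frac_q20=1.0)
        n_base = len(preprocess_sample(paths["r1"], paths["r2"], base))
        n_strict = len(preprocess_sample(paths["r1"], paths["r2"], stricter))
        assert n_strict <= n_base

    def test_stricter_quality_never_gains_reads(self, em11_small):
        _spec, paths = em11_small
        base = cs.PipelineParams()
        stricter = cs.PipelineParams(trim_q=30, frac_q20=0.99)
        n_base = len(preprocess_sample(paths["r1"], paths["r2"], base))
        n_strict = len(preprocess_sample(paths["r1"], paths["r2"], stricter))
        assert n_strict <= n_base
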