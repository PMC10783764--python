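"""Sliding-window SD scanning and organism summaries."""

import numpy as np
import pytest

from antisdscan.rrna_tail import TailRecord
from antisdscan.scan import (
    ScanConfig,
    SDCall,
    TruncatedUTR,
    scan_organism,
    scan_utr,
    summarize_organism,
)
from antisdscan.seqio import UTRRecord
from antisdscan.thermo import CANONICAL_TAIL, duplex_mfe


def utr(seq, gene_id="g", offset=-19, truncated=False):
    return UTRRecord(gene_id, seq, offset, truncated)


@pytest.fixture(scope="module")
def tail():
    return TailRecord("org", CANONICAL_TAIL)


class TestScanUTR:
    def test_planted_sd_wins_and_passes(self, tail, model, canonical_core):
        seq = "ACACA" + "AAGGAGG" + "ACACAC"  # 18 nt, SD at offsets 5..11
        call = scan_utr(utr(seq), tail, model, core=canonical_core)
        assert call.is_sd
        assert call.best_dg <= -8.4
        # the winning window covers the planted heptamer
        off = call.window_start - (-19)
        assert off <= 5 and off + 10 >= 12
        # and its pairs cover the core span -2..+4
        assert set(range(-2, 5)) <= set(call.tail_positions)

    def test_all_c_utr_vs_gc_free_tail_is_no_match(self, model):
        t = TailRecord("org", "AAUAUAUAAUAAUAA")
        call = scan_utr(utr("C" * 18), t, model)
        assert call.best_dg is None and not call.is_sd

    def test_window_tie_goes_to_5prime(self, tail, model):
        # period-8 sequence: windows at offsets 0 and 8 are the same string
        # and tie at the minimum; the 5'-most one must be reported
        seq = ("GGGACGCU" * 3)[:18]
        assert seq[0:10] == seq[8:18]
        call = scan_utr(utr(seq), tail, model)
        assert call.window_start == -19

    def test_truncated_utr_raises_skip(self, tail, model):
        with pytest.raises(TruncatedUTR):
            scan_utr(utr("ACGU" * 3, truncated=True), tail, model)

    def test_best_dg_is_window_minimum(self, tail, model):
        seq = "ACGUACGUACGUACGUAC"
        call = scan_utr(utr(seq), tail, model)
        window_dgs = []
        for off in range(9):
            m = duplex_mfe(seq[off: off + 10], tail.tail, model)
            if m is not None:
                window_dgs.append(m.dg)
        assert call.best_dg == pytest.approx(min(window_dgs))

    def test_widening_span_never_worsens(self, tail, model):
        seq18 = "ACGUACGUACGUACGUAC"
        seq22 = seq18 + "GGAG"
        c18 = scan_utr(utr(seq18), tail, model)
        c22 = scan_utr(utr(seq22, offset=-23), tail, model)
        assert c22.best_dg <= c18.best_dg


class TestScanOrganism:
    def test_batch_matches_single_calls(self, tail, model, canonical_core):
        rng = np.random.default_rng(3)
        utrs = [
            utr("".join("ACGU"[i] for i in rng.integers(0, 4, 18)), f"g{k}")
            for k in range(40)
        ]
        batch = scan_organism(utrs, tail, canonical_core, model)
        for u, call in zip(utrs, batch):
            single = scan_utr(u, tail, model, core=canonical_core)
            assert call.gene_id == single.gene_id
            if single.best_dg is None:
                assert call.best_dg is None
            else:
                assert call.best_dg == pytest.approx(single.best_dg)
                assert call.window_start == single.window_start
            if call.is_sd:
                assert call.tail_positions == single.tail_positions

    def test_truncated_and_duplicates_excluded(self, tail, model):
        utrs = [
            utr("A" * 18, "g1"),
            utr("A" * 18, "g1"),              # duplicate id
            utr("A" * 9, "g2", truncated=True),
            utr("AAGGAGGAAGGAGGAAGG", "g3"),
        ]
        calls = scan_organism(utrs, tail, None, model)
        assert [c.gene_id for c in calls] == ["g1", "g3"]

    def test_order_invariance_of_pct(self, tail, model, small_organism):
        utrs = small_organism.utrs[:60]
        fwd = scan_organism(utrs, small_organism.tail, None, model)
        rev = scan_organism(utrs[::-1], small_organism.tail, None, model)
        pct = lambda calls: summarize_organism(calls, "x").pct_sd
        assert pct(fwd) == pct(rev)


class TestSummaries:
    def make(self, flags, positions=None):
        positions = positions or [-15] * len(flags)
        return [
            SDCall(f"g{i}", -9.0 if f else -3.0, p if f else None, f)
            for i, (f, p) in enumerate(zip(flags, positions))
        ]

    def test_counts_and_percentage(self):
        s = summarize_organism(self.make([True] * 64 + [False] * 36), "o")
        assert s.n_genes_scanned == 100 and s.n_sd == 64
        assert s.pct_sd == pytest.approx(64.0)

    def test_all_negative(self):
        s = summarize_organism(self.make([False, False]), "o")
        assert s.pct_sd == 0.0 and s.mean_sd_window_position is None

    def test_single_positive(self):
        s = summarize_organism(self.make([True]), "o")
        assert s.pct_sd == 100.0

    def test_mean_window_position(self):
        s = summarize_organism(
            self.make([True, True], positions=[-19, -11]), "o"
        )
        assert s.mean_sd_window_position == pytest.approx(-15.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_organism([], "o")
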