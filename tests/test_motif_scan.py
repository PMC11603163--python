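import itertools

import pytest
from hypothesis import given, strategies as st

import exconsv as x
from exconsv.motif_scan import (
    B1_LIKE,
    CYC_YPXF,
    CYC_YP_PARTIAL,
    D1_LIKE,
    DE_LIKE,
    E1_LIKE,
    HEPTAD,
    UNCLASSIFIED,
    MotifConfig,
    PatternError,
    classify_evidence,
)

from oracles import brute_scan

CFG = MotifConfig()


def seq_with_ctd(ctd: str, total: int = 300) -> str:
    """A sequence whose C-terminal window (40%) starts exactly at `ctd`."""
    pad = total - len(ctd)
    return "L" * pad + ctd


class TestScanPattern:
    def test_literal_match(self):
        hits = x.scan_pattern("AADFDGDAA", "DFDGD")
        assert [(h.start, h.end, h.matched_text) for h in hits] == [(3, 7, "DFDGD")]

    def test_non_overlapping_dimers(self):
        assert [(h.start, h.end) for h in x.scan_pattern("GWGW", "GW")] == [
            (1, 2),
            (3, 4),
        ]

    def test_bounded_repeat_and_class(self):
        hits = x.scan_pattern("ACYACWC", "C-x(1,2)-C")
        assert [(h.start, h.end) for h in hits] == brute_scan("ACYACWC", "C-x(1,2)-C")

    def test_malformed_pattern_reports_position(self):
        with pytest.raises(PatternError) as err:
            x.scan_pattern("AAAA", "A-[A?]-C")
        assert err.value.position == 2

    @given(
        st.text(alphabet="ACGWYPSF", min_size=0, max_size=200),
        st.sampled_from(
            [
                "DFDGD",
                "G-W",
                "C-x(1,2)-C",
                "Y-P-x-F",
                "[AG]-x(0,2)-[CW]",
                "A(2,3)-C",
                "C-Y-x(0,1)-C",
            ]
        ),
    )
    def test_agrees_with_recursive_enumeration_oracle(self, seq, pattern):
        hits = x.scan_pattern(seq, pattern)
        assert [(h.start, h.end) for h in hits] == brute_scan(seq, pattern)
        for h in hits:
            assert h.matched_text == seq[h.start - 1 : h.end]


class TestDetectHeptads:
    def test_exact_tandem_repeats(self):
        seq = seq_with_ctd("YSPTSPS" * 10 + "KKK")
        hit = x.detect_heptads(seq, CFG)
        assert hit is not None and hit.motif_class == HEPTAD
        assert hit.score == 10
        assert hit.matched_text == "YSPTSPS" * 10

    def test_absent_in_plain_sequence(self):
        assert x.detect_heptads("L" * 280 + "KAVRMEWNDHQCIFKAVRME", CFG) is None

    def test_mismatch_tolerance_counts_degenerate_run(self):
        # 6 copies, each with one mismatch (P3->A), tolerance 1, min 5.
        seq = seq_with_ctd("YSATSPS" * 6)
        cfg = MotifConfig(heptad_max_mismatch=1, heptad_min_repeats=5)
        hit = x.detect_heptads(seq, cfg)
        assert hit is not None and hit.score == 6
        assert x.detect_heptads(seq, MotifConfig(heptad_max_mismatch=0)) is None

    def test_reversed_consensus_run_not_detected(self):
        seq = seq_with_ctd("".join(reversed("YSPTSPS" * 10)))
        cfg = MotifConfig(heptad_max_mismatch=0)
        assert x.detect_heptads(seq, cfg) is None

    def test_outside_ctd_window_ignored(self):
        seq = "YSPTSPS" * 10 + "L" * 300  # repeats only in the N-terminus
        assert x.detect_heptads(seq, CFG) is None


class TestCountGWWG:
    @pytest.mark.parametrize(
        "ctd,expected",
        [
            ("GWAAWGAAGW", 3),
            ("GWG", 1),  # greedy non-overlap
            ("AAAA", 0),
            ("GWGW", 2),
            ("WGGW", 2),
        ],
    )
    def test_greedy_counting(self, ctd, expected):
        assert x.count_gwwg(seq_with_ctd(ctd), CFG) == expected

    def test_matches_independent_consumer_on_random_sequences(self):
        import random

        rng = random.Random(0)

        def consume(window):
            total, pos = 0, 0
            tokens = []
            while pos < len(window):
                tokens.append(window[pos : pos + 2])
                pos += 1
            # independent formulation: walk tokens, skipping one after a hit
            count, skip = 0, False
            for i, tok in enumerate(tokens):
                if skip:
                    skip = False
                    continue
                if tok in ("GW", "WG") and len(tok) == 2:
                    count += 1
                    skip = True
            return count

        for _ in range(50):
            seq = "".join(rng.choice("GWAS") for _ in range(120))
            w0 = len(seq) - int(len(seq) * CFG.ctd_fraction)
            assert x.count_gwwg(seq, CFG) == consume(seq[w0:])


class TestDetectCycYpxf:
    def test_full_motif(self):
        seq = "A" * 100 + "CYACGGYPMF" + "A" * 100
        hit = x.detect_cyc_ypxf(seq, CFG)
        assert hit is not None and hit.motif_class == CYC_YPXF
        assert (hit.start, hit.end) == (101, 110)
        assert hit.matched_text == "CYACGGYPMF"

    def test_partial_when_ypxf_missing(self):
        seq = "A" * 100 + "CYAC" + "A" * 100
        hit = x.detect_cyc_ypxf(seq, CFG)
        assert hit is not None and hit.motif_class == CYC_YP_PARTIAL
        assert (hit.start, hit.end) == (101, 104)

    def test_absent(self):
        assert x.detect_cyc_ypxf("A" * 50, CFG) is None

    def test_spacer_bound_is_inclusive(self):
        for spacer, expect_full in [(CFG.cyc_ypxf_max_spacer, True),
                                    (CFG.cyc_ypxf_max_spacer + 1, False)]:
            seq = "CYAC" + "G" * spacer + "YPMF"
            hit = x.detect_cyc_ypxf(seq, CFG)
            is_full = hit is not None and hit.motif_class == CYC_YPXF
            assert is_full is expect_full

    def test_leftmost_full_hit_wins(self):
        seq = "CYACGGYPMF" + "A" * 30 + "CYCGGYPWF"
        hit = x.detect_cyc_ypxf(seq, CFG)
        assert hit.start == 1

    def test_three_residue_cyc_variant_matches(self):
        # C-Y-x(0,1)-C admits both CYC and CYxC readings.
        seq = "A" * 20 + "CYCGGYPMF" + "A" * 20
        hit = x.detect_cyc_ypxf(seq, CFG)
        assert hit.motif_class == CYC_YPXF


class TestClassification:
    @pytest.mark.parametrize(
        "heptads,gwwg,full,partial,bryo,label,rule",
        [
            (20, 0, False, False, False, B1_LIKE, "R1"),
            (20, 12, True, False, False, B1_LIKE, "R1"),  # heptads dominate
            (0, 0, True, False, False, D1_LIKE, "R2"),
            (0, 12, False, False, False, E1_LIKE, "R3"),
            (0, 12, False, True, False, DE_LIKE, "R4"),
            (0, 0, False, True, True, DE_LIKE, "R4"),
            (0, 0, False, True, False, UNCLASSIFIED, "R5"),
            (0, 2, False, False, False, UNCLASSIFIED, "R5"),
        ],
    )
    def test_rule_table(self, heptads, gwwg, full, partial, bryo, label, rule):
        got_label, got_rule = classify_evidence(heptads, gwwg, full, partial, bryo, CFG)
        assert (got_label, got_rule) == (label, rule)

    def test_rule_table_total_and_exclusive_on_evidence_grid(self):
        labels = {B1_LIKE, D1_LIKE, E1_LIKE, DE_LIKE, UNCLASSIFIED}
        for heptads, gwwg, full, partial, bryo in itertools.product(
            (0, 4, 5, 20), (0, 4, 5, 12), (False, True), (False, True), (False, True)
        ):
            label, rule = classify_evidence(heptads, gwwg, full, partial, bryo, CFG)
            assert label in labels
            assert rule in {"R1", "R2", "R3", "R4", "R5"}

    def test_classify_subunit_end_to_end(self):
        rec = x.ProteinRecord(
            id="b1", sequence="L" * 200 + "YSPTSPS" * 8 + "L" * 40
        )
        call = x.classify_subunit(rec)
        assert call.label == B1_LIKE and call.rule_fired == "R1"
        assert call.evidence["heptad_repeats"] == 8

    def test_determinism(self):
        rec = x.ProteinRecord(id="r", sequence="L" * 100 + "CYACGGYPMF" + "L" * 200)
        calls = [x.classify_subunit(rec) for _ in range(3)]
        assert calls[0] == calls[1] == calls[2]
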