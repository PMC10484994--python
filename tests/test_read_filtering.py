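"""Read parsing, filtering and isoform-class assignment."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrlink.gene_models import load_annotation
from utrlink.read_filtering import (
    CeStatus,
    DiscardReason,
    FilterParams,
    ReadAlignment,
    call_ce_status,
    classify_read,
    classify_sam,
    classify_utr_class,
    detect_polya_tail,
    exon_span_filter,
    is_internal_priming,
    parse_alignment,
)
from utrlink.simulate import SimConfig, SimGene, make_toy_reference, simulate_reads

PARAMS = FilterParams()


class TestParseAlignment:
    def test_spliced_with_clips(self, make_record):
        rec = make_record(cigar="10S50M200N50M20S", pos0=100,
                          seq="G" * 10 + "C" * 100 + "T" * 20)
        read = parse_alignment(rec)
        assert read.blocks == ((100, 150), (350, 400))
        assert read.clip5 == "G" * 10
        assert read.clip3 == "T" * 20

    def test_simple_match(self, make_record):
        read = parse_alignment(make_record(cigar="100M", pos0=0))
        assert read.blocks == ((0, 100),)
        assert read.clip5 == "" and read.clip3 == ""

    def test_secondary_rejected(self, make_record):
        assert parse_alignment(make_record(flag=256)) is None
        assert parse_alignment(make_record(flag=2048)) is None

    def test_missing_seq_with_clip_skipped(self, make_record):
        rec = make_record(cigar="10S90M", seq="*")
        assert parse_alignment(rec) is None

    def test_deletion_merged_insertion_skipped(self, make_record):
        rec = make_record(cigar="20M5D20M3I20M", seq="C" * 63)
        read = parse_alignment(rec)
        assert read.blocks == ((0, 65),)


class TestExonSpanFilter:
    def test_full_span_passes(self, toy_gene):
        read = ReadAlignment("r", "chr1", "+", ((100, 200), (400, 500), (600, 1000)))
        assert exon_span_filter(read, toy_gene.events[0], toy_gene, PARAMS)

    def test_missing_upstream_flank_fails(self, toy_gene):
        read = ReadAlignment("r", "chr1", "+", ((400, 500), (600, 1000)))
        assert not exon_span_filter(read, toy_gene.events[0], toy_gene, PARAMS)

    def test_partial_flank_below_threshold_fails(self, toy_gene):
        # 70 of the flank's 100 bases: 0.70 < 0.80
        read = ReadAlignment("r", "chr1", "+", ((130, 200), (400, 500), (600, 1000)))
        assert not exon_span_filter(read, toy_gene.events[0], toy_gene, PARAMS)


class TestPolyATail:
    @pytest.mark.parametrize(
        "clip, expected",
        [
            ("AAAAAAAAAA", True),
            ("", False),
            ("GATTACA", False),           # best prefix A-fraction 3/7 < 0.8
            ("AAAAG", True),              # 4/5 = 0.8 at minimum length
            ("AAAA", False),              # below tail_min_len
            ("G" + "A" * 19, True),       # one mismatch, later prefixes reach 0.9 purity
            ("AAAAA" + "G" * 40, True),   # tail adjacent to alignment end
        ],
    )
    def test_prefix_rule(self, clip, expected):
        assert detect_polya_tail(clip, PARAMS) is expected

    def test_scan_window_limits_search(self):
        # pure A beyond the 20-base window must not rescue a non-A prefix
        assert not detect_polya_tail("G" * 20 + "A" * 50, PARAMS)


class TestInternalPriming:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("A" * 20, True),
            ("AACAAGAAATAAACAAGTAA", True),   # 12 A, max run 3 -> count rule
            ("ACGTACGTACGTACGTACGT", False),  # 5 A, max run 1
            ("CCCCCAAAAAACCCCCCCCC", True),   # run of 6 triggers the run rule
            ("", False),                      # truncated window at contig end
        ],
    )
    def test_a_content_rules(self, seq, expected):
        assert is_internal_priming(seq, PARAMS) is expected


class _RefStub(dict):
    pass


@pytest.fixture(scope="module")
def flat_ref(toy_gene):
    # non-A everywhere: mispriming never fires unless a test plants A's
    ref = _RefStub()
    ref["chr1"] = "C" * 5000
    return ref


class TestClassifyUtrClass:
    def test_distal_spanning_read_is_long_without_tail(self, toy_gene, flat_ref):
        read = ReadAlignment("r", "chr1", "+", ((100, 200), (400, 500), (600, 1300)))
        label, reason = classify_utr_class(read, toy_gene, flat_ref, PARAMS)
        assert (label, reason) == ("long", None)

    def test_tailed_read_at_proximal_site_is_short(self, toy_gene, flat_ref):
        read = ReadAlignment(
            "r", "chr1", "+", ((100, 200), (400, 500), (600, 995)), clip3="A" * 15
        )
        label, reason = classify_utr_class(read, toy_gene, flat_ref, PARAMS)
        assert (label, reason) == ("short", None)

    def test_untailed_mid_utr_read_discarded(self, toy_gene, flat_ref):
        read = ReadAlignment("r", "chr1", "+", ((100, 200), (400, 500), (600, 800)))
        label, reason = classify_utr_class(read, toy_gene, flat_ref, PARAMS)
        assert label is None and reason == DiscardReason.TRUNCATED_NO_TAIL

    def test_a_rich_downstream_window_discarded_as_misprime(self, toy_gene):
        ref = _RefStub()
        ref["chr1"] = "C" * 990 + "A" * 30 + "C" * 3000
        read = ReadAlignment(
            "r", "chr1", "+", ((100, 200), (400, 500), (600, 990)), clip3="A" * 15
        )
        label, reason = classify_utr_class(read, toy_gene, ref, PARAMS)
        assert label is None and reason == DiscardReason.INTERNAL_MISPRIME

    def test_read_past_distal_plus_slack_out_of_bounds(self, toy_gene, flat_ref):
        read = ReadAlignment("r", "chr1", "+", ((100, 200), (400, 500), (600, 2600)))
        label, reason = classify_utr_class(read, toy_gene, flat_ref, PARAMS)
        assert label is None and reason == DiscardReason.OUT_OF_BOUNDS

    def test_lowering_overlap_threshold_never_demotes(self, toy_gene, flat_ref):
        # monotonicity: a smaller extension-overlap requirement can only move
        # reads toward more distal classes
        order = {None: -1, "short": 0, "long": 1}
        for end in (980, 1000, 1020, 1049, 1051, 1200, 2499):
            read = ReadAlignment(
                "r", "chr1", "+", ((100, 200), (400, 500), (600, end)), clip3="A" * 20
            )
            prev = None
            for thr in (200, 100, 50, 20, 1):
                label, _ = classify_utr_class(
                    read, toy_gene, flat_ref,
                    FilterParams(min_extension_overlap=thr),
                )
                if prev is not None:
                    assert order[label] >= order[prev]
                prev = label


class TestCeStatus:
    def test_full_ce_coverage_included(self, toy_gene):
        read = ReadAlignment("r", "chr1", "+", ((100, 200), (300, 360), (400, 500)))
        assert call_ce_status(read, toy_gene.events[0], PARAMS) is CeStatus.INCLUDED

    def test_flank_to_flank_junction_skipped(self, toy_gene):
        read = ReadAlignment("r", "chr1", "+", ((100, 200), (400, 500)))
        assert call_ce_status(read, toy_gene.events[0], PARAMS) is CeStatus.SKIPPED

    def test_partial_ce_coverage_ambiguous(self, toy_gene):
        # 40% of the CE covered: neither included nor cleanly skipped
        read = ReadAlignment("r", "chr1", "+", ((100, 200), (300, 324), (400, 500)))
        assert call_ce_status(read, toy_gene.events[0], PARAMS) is CeStatus.AMBIGUOUS


class TestPartition:
    def test_every_read_counted_once(self, default_sim):
        calls = default_sim["calls"]
        assert len({c.read_id for c in calls}) == len(calls)
        verdicts = Counter(
            c.utr_class if c.utr_class else c.discard_reason.value for c in calls
        )
        assert sum(verdicts.values()) == len(calls)
        for c in calls:
            assert (c.utr_class is None) != (c.discard_reason is None)

    def test_truth_recovery_on_clean_reads(self, default_sim):
        truth = default_sim["truth"]
        by_id = {c.read_id: c for c in default_sim["calls"]}
        clean = truth[~truth.truncated & ~truth.misprimed & ~truth.background]
        for rid, label in zip(clean.read_id, clean.true_class):
            assert by_id[rid].utr_class == label
        for rid in truth[truth.misprimed].read_id:
            assert by_id[rid].discard_reason == DiscardReason.INTERNAL_MISPRIME


def test_strand_symmetry(tmp_path):
    """Reflecting the gene to the - strand leaves all class labels unchanged."""
    outcomes = {}
    for strand in "+-":
        cfg = SimConfig(
            genes=(SimGene("g", strand=strand, reads_per_class=(120, 120)),), seed=11
        )
        ref = make_toy_reference(cfg)
        genes = load_annotation(ref.gtf_text, ref.gene_config)
        sam, truth = simulate_reads(ref, cfg, seed=3)
        path = tmp_path / f"reads_{'fwd' if strand == '+' else 'rev'}.sam"
        path.write_text(sam)
        calls, _, _ = classify_sam(str(path), genes, ref, PARAMS)
        outcomes[strand] = sorted(
            (c.read_id, c.utr_class or c.discard_reason.value) for c in calls
        )
    assert outcomes["+"] == outcomes["-"]


@settings(max_examples=200, deadline=None)
@given(st.text(alphabet="ACGT", max_size=40))
def test_tail_detection_consistent_with_bruteforce(clip):
    """Tail rule equals brute-force enumeration over all qualifying prefixes."""
    scan = clip[:PARAMS.tail_scan_window]
    expected = any(
        len(scan[:i]) >= PARAMS.tail_min_len
        and scan[:i].count("A") / i >= PARAMS.tail_min_A_frac
        for i in range(1, len(scan) + 1)
    )
    assert detect_polya_tail(clip, PARAMS) is expected
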