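"""Per-read filtering and isoform-class assignment for targeted long reads.

Converts spliced long-read alignments into per-read calls following the
parsing order used for targeted oligo-dT primed cDNA libraries:

1. span filter — the read must cover the constitutive exons flanking the
   cassette exon and the universal 3'UTR;
2. reads reaching into the most distal UTR extension are assigned the distal
   class outright (their 3' end is past every proximal cleavage site, so no
   poly(A)-tail evidence is needed);
3. remaining reads are candidate proximal-class reads and must end near a
   declared cleavage site, carry an untemplated poly(A) tail in their 3'
   soft clip, and not sit on a genomically A-rich stretch (internal
   mispriming from oligo-dT), otherwise they are discarded as truncated or
   misprimed;
4. cassette-exon status is called per event from exon coverage and the
   intron gap structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import pysam

from .gene_models import CassetteEvent, GeneModel, GenomicInterval

log = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "ReadAlignment",
    "ReadCall",
    "CeStatus",
    "DiscardReason",
    "parse_alignment",
    "exon_span_filter",
    "detect_polya_tail",
    "is_internal_priming",
    "classify_utr_class",
    "call_ce_status",
    "classify_read",
    "classify_sam",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CeStatus(str, Enum):
    INCLUDED = "INCLUDED"
    SKIPPED = "SKIPPED"
    AMBIGUOUS = "AMBIGUOUS"


class DiscardReason(str, Enum):
    FAILS_SPAN = "fails_span"
    TRUNCATED_NO_TAIL = "truncated_no_tail"
    INTERNAL_MISPRIME = "internal_misprime"
    OUT_OF_BOUNDS = "out_of_bounds"


@dataclass(frozen=True)
class FilterParams:
    """Tunable thresholds of the read filters.

    The filters themselves (tail presence, internal-priming rejection, exon
    span, extension overlap) are fixed pipeline stages; every numeric knob
    is surfaced here and in the run config.
    """

    min_exon_cov_frac: float = 0.8   # fraction of a required exon a read must cover
    min_extension_overlap: int = 50  # bases into an extension for the longer class
    tail_min_len: int = 5            # minimum untemplated-A prefix length
    tail_min_A_frac: float = 0.8     # A purity of that prefix
    tail_scan_window: int = 20       # clipped bases examined adjacent to the alignment end
    misprime_window: int = 20        # genomic bases downstream of the inferred 3' end
    misprime_max_A: int = 12         # >= this many A in the window -> misprimed
    misprime_max_run: int = 6        # or an A-run at least this long
    end_slack: int = 50              # allowed distance between read 3' end and a declared site

    def __post_init__(self) -> None:
        for name in ("min_exon_cov_frac", "tail_min_A_frac"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "min_extension_overlap", "tail_min_len", "tail_scan_window",
            "misprime_window", "misprime_max_A", "misprime_max_run", "end_slack",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ReadAlignment:
    """One primary alignment as strand-aware genomic blocks plus end clips.

    ``blocks`` are the reference-consuming segments of the CIGAR (M/=/X/D
    merged, split at N introns), sorted by genomic coordinate.  ``clip5`` and
    ``clip3`` are the soft-clipped sequences at the genomic-left and
    genomic-right ends, exactly as stored in the record (i.e. in reference
    orientation, not transcript orientation).
    """

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    clip5: str = ""
    clip3: str = ""

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcript 3' end of the alignment."""
        return self.end if self.strand == "+" else self.start

    @property
    def tail_clip(self) -> str:
        """Soft clip at the transcript 3' end, in transcript orientation."""
        if self.strand == "+":
            return self.clip3
        return revcomp(self.clip5)

    def overlap(self, start: int, end: int) -> int:
        """Aligned bases falling inside the genomic window [start, end)."""
        return sum(max(0, min(e, end) - max(s, start)) for s, e in self.blocks)

    def covered_fraction(self, iv: GenomicInterval) -> float:
        return self.overlap(iv.start, iv.end) / len(iv)


@dataclass
class ReadCall:
    """Final verdict for one read at one gene."""

    read_id: str
    gene_id: str
    utr_class: Optional[str] = None
    discard_reason: Optional[DiscardReason] = None
    ce_status: dict[str, CeStatus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.utr_class is None) == (self.discard_reason is None):
            raise ValueError("a read is either assigned a class or discarded, never both")


# ---------------------------------------------------------------------------
# alignment parsing

_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_BAM_CSOFT_CLIP = 4
_BAM_CREF_SKIP = 3


def parse_alignment(rec: pysam.AlignedSegment) -> Optional[ReadAlignment]:
    """Decode a primary SAM record into genomic blocks and end soft clips.

    Secondary and supplementary records are rejected (one vote per
    molecule); records lacking SEQ but carrying soft clips are skipped with
    a warning because the clip sequence cannot be recovered.
    """
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
        return None
    cig = rec.cigartuples
    if not cig:
        return None
    seq = rec.query_sequence
    has_clip = cig[0][0] == _BAM_CSOFT_CLIP or cig[-1][0] == _BAM_CSOFT_CLIP
    if seq is None:
        if has_clip:
            log.warning("read %s: SEQ '*' with soft clips, skipped", rec.query_name)
            return None
        seq = ""

    clip5 = seq[: cig[0][1]] if cig[0][0] == _BAM_CSOFT_CLIP else ""
    clip3 = seq[len(seq) - cig[-1][1]:] if cig[-1][0] == _BAM_CSOFT_CLIP else ""

    blocks: list[tuple[int, int]] = []
    pos = rec.reference_start
    cur: Optional[int] = None
    for op, length in cig:
        if op in _REF_CONSUMING:
            if cur is None:
                cur = pos
            pos += length
        elif op == _BAM_CREF_SKIP:
            if cur is not None:
                blocks.append((cur, pos))
                cur = None
            pos += length
        # I/S/H/P consume no reference
    if cur is not None:
        blocks.append((cur, pos))
    return ReadAlignment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        strand="-" if rec.is_reverse else "+",
        blocks=tuple(blocks),
        clip5=clip5,
        clip3=clip3,
    )


# ---------------------------------------------------------------------------
# filters


def exon_span_filter(
    read: ReadAlignment, event: CassetteEvent, gene: GeneModel, params: FilterParams
) -> bool:
    """Read covers both flanking constitutive exons and the universal 3'UTR."""
    need = (event.upstream_flank.interval, event.downstream_flank.interval, gene.universal_utr)
    return all(read.covered_fraction(iv) >= params.min_exon_cov_frac for iv in need)


def detect_polya_tail(clip_seq: str, params: FilterParams) -> bool:
    """Untemplated poly(A) tail present in the 3' soft clip.

    ``clip_seq`` must be given in transcript orientation (for - strand
    alignments: the genomic-left clip reverse-complemented).  True iff some
    prefix of the first ``tail_scan_window`` clipped bases has length >=
    ``tail_min_len`` and A-fraction >= ``tail_min_A_frac``.
    """
    scan = clip_seq[: params.tail_scan_window].upper()
    a = 0
    for i, base in enumerate(scan, start=1):
        if base == "A":
            a += 1
        if i >= params.tail_min_len and a / i >= params.tail_min_A_frac:
            return True
    return False


def _longest_a_run(seq: str) -> int:
    best = run = 0
    for base in seq:
        run = run + 1 if base == "A" else 0
        best = max(best, run)
    return best


def is_internal_priming(downstream_genomic_seq: str, params: FilterParams) -> bool:
    """Genomic A-rich stretch immediately 3' of the inferred cleavage point.

    Oligo-dT can prime internally on genomically encoded A stretches; such
    reads end at positions whose downstream genomic window is A-rich.  The
    window may be shorter than ``misprime_window`` at a contig end; it is
    evaluated as-is.
    """
    seq = downstream_genomic_seq.upper()
    return seq.count("A") >= params.misprime_max_A or _longest_a_run(seq) >= params.misprime_max_run


def _fetch_downstream(ref, gene: GeneModel, pos: int, n: int) -> str:
    """n genomic bases 3' of ``pos`` in transcript orientation, strand-aware.

    ``ref`` is any mapping-style sequence accessor (e.g. ``pyfaidx.Fasta``)
    supporting ``ref[chrom][start:end]`` with a ``.seq``-or-str result.
    """
    chrom_seq = ref[gene.chrom]
    if gene.strand == "+":
        frag = chrom_seq[pos : pos + n]
        seq = str(getattr(frag, "seq", frag))
        return seq
    frag = chrom_seq[max(0, pos - n) : pos]
    seq = str(getattr(frag, "seq", frag))
    return revcomp(seq)


def _tpos(pos: int, strand: str) -> int:
    """Map a genomic coordinate onto an axis increasing in transcription order."""
    return pos if strand == "+" else -pos


def classify_utr_class(
    read: ReadAlignment, gene: GeneModel, ref, params: FilterParams
) -> tuple[Optional[str], Optional[DiscardReason]]:
    """Assign a 3'UTR class, or a discard reason, to a span-filtered read.

    The class is that of the most distal UTR segment the read overlaps by at
    least ``min_extension_overlap`` bases.  Reads of the most distal class
    need no tail evidence — spanning the extension is proof enough.  Any
    less-distal candidate must (i) end within ``end_slack`` of that class's
    cleavage site, (ii) not be internally misprimed, and (iii) carry a
    poly(A) tail in its 3' soft clip.
    """
    labels = gene.polya.labels
    end3 = read.three_prime_end
    strand = gene.strand

    if _tpos(end3, strand) > _tpos(gene.polya.distal, strand) + params.end_slack:
        return None, DiscardReason.OUT_OF_BOUNDS

    k = 0
    for i in range(len(gene.extensions), 0, -1):
        ext = gene.extensions[i - 1]
        if read.overlap(ext.start, ext.end) >= params.min_extension_overlap:
            k = i
            break

    if k == len(labels) - 1:
        return labels[k], None

    site = gene.polya.sites[k]
    if abs(end3 - site) > params.end_slack:
        return None, DiscardReason.TRUNCATED_NO_TAIL
    if is_internal_priming(_fetch_downstream(ref, gene, end3, params.misprime_window), params):
        return None, DiscardReason.INTERNAL_MISPRIME
    if not detect_polya_tail(read.tail_clip, params):
        return None, DiscardReason.TRUNCATED_NO_TAIL
    return labels[k], None


def call_ce_status(
    read: ReadAlignment, event: CassetteEvent, params: FilterParams
) -> CeStatus:
    """INCLUDED / SKIPPED / AMBIGUOUS for one cassette exon.

    INCLUDED requires covering >= ``min_exon_cov_frac`` of the CE; SKIPPED
    requires zero CE coverage plus a single intron gap spanning the whole CE
    (the flank-to-flank junction); anything else — partial coverage, exotic
    gap structure — is AMBIGUOUS and excluded from PSI denominators.
    """
    ce = event.ce.interval
    if read.covered_fraction(ce) >= params.min_exon_cov_frac:
        return CeStatus.INCLUDED
    if read.overlap(ce.start, ce.end) == 0:
        for (s1, e1), (s2, e2) in zip(read.blocks, read.blocks[1:]):
            if e1 <= ce.start and s2 >= ce.end:
                return CeStatus.SKIPPED
    return CeStatus.AMBIGUOUS


# ---------------------------------------------------------------------------
# per-read driver


def classify_read(
    read: ReadAlignment, gene: GeneModel, ref, params: FilterParams
) -> ReadCall:
    """Full per-read verdict at one gene: span filter, class, CE status."""
    span_ok = {ev.event_id: exon_span_filter(read, ev, gene, params) for ev in gene.events}
    if gene.events and not any(span_ok.values()):
        return ReadCall(read.read_id, gene.gene_id, discard_reason=DiscardReason.FAILS_SPAN)
    if not gene.events and read.covered_fraction(gene.universal_utr) < params.min_exon_cov_frac:
        return ReadCall(read.read_id, gene.gene_id, discard_reason=DiscardReason.FAILS_SPAN)

    utr_class, reason = classify_utr_class(read, gene, ref, params)
    ce_status = {
        ev.event_id: (
            call_ce_status(read, ev, params) if span_ok[ev.event_id] else CeStatus.AMBIGUOUS
        )
        for ev in gene.events
    }
    if reason is not None:
        return ReadCall(read.read_id, gene.gene_id, discard_reason=reason, ce_status=ce_status)
    return ReadCall(read.read_id, gene.gene_id, utr_class=utr_class, ce_status=ce_status)


def classify_sam(
    sam_path: str,
    genes: Iterable[GeneModel],
    ref,
    params: Optional[FilterParams] = None,
) -> tuple[list[ReadCall], Mapping[str, ReadAlignment], int]:
    """Classify every primary alignment in a SAM/BAM file against target genes.

    A read is assigned to the single target gene whose span it overlaps on
    the matching chromosome and strand (targeted panels are designed
    non-overlapping).  Returns the calls, the parsed alignments keyed by
    read id (for coverage tracks), and the total number of primary
    alignments seen (for the on-target fraction report).
    """
    params = params or FilterParams()
    gene_list = list(genes)
    spans = [(g, g.span()) for g in gene_list]
    calls: list[ReadCall] = []
    alignments: dict[str, ReadAlignment] = {}
    n_primary = 0
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for rec in fh:
            read = parse_alignment(rec)
            if read is None:
                continue
            n_primary += 1
            for gene, span in spans:
                if (
                    read.chrom == span.chrom
                    and read.strand == gene.strand
                    and read.overlap(span.start, span.end) > 0
                ):
                    alignments[read.read_id] = read
                    calls.append(classify_read(read, gene, ref, params))
                    break
    return calls, alignments, n_primary
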