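"""Aggregation of per-read calls into PSI, dPAU, coverage and site inference.

PSI (percent spliced in) of a cassette exon is included/(included+skipped),
computed separately within each 3'UTR isoform class, over the union of
classes ("All"), and only when at least ``min_reads`` informative reads
support it — below that the value is undefined (reported as NaN/None),
never silently zero.  dPAU (distal poly(A) site usage) is the percentage of
classified reads assigned the most distal class, 0..100.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel
from .read_filtering import CeStatus, ReadAlignment, ReadCall

__all__ = [
    "MIN_READS",
    "compute_psi",
    "compute_dpau_longread",
    "count_events",
    "psi_table",
    "linkage_delta",
    "coverage_track",
    "write_bedgraph",
    "infer_polya_sites",
    "gene_body_coverage",
]

#: minimum informative reads per (class, replicate) for PSI to be defined
MIN_READS = 2

ALL_CLASS = "All"


def compute_psi(included: int, skipped: int, min_reads: int = MIN_READS) -> Optional[float]:
    """included/(included+skipped), undefined below the read-count floor."""
    if included < 0 or skipped < 0:
        raise ValueError("counts must be non-negative")
    total = included + skipped
    if total < min_reads:
        return None
    return included / total


def compute_dpau_longread(
    class_counts: Mapping[str, int], labels: Sequence[str]
) -> Optional[float]:
    """100 x (reads in the most distal class) / (all classified reads)."""
    total = sum(class_counts.get(lab, 0) for lab in labels)
    if total == 0:
        return None
    return 100.0 * class_counts.get(labels[-1], 0) / total


def count_events(
    calls: Iterable[ReadCall], gene: GeneModel, replicate: str = "rep1"
) -> pd.DataFrame:
    """Included/skipped counts per (event, UTR class) plus the 'All' union.

    Only reads assigned a UTR class contribute; AMBIGUOUS CE calls count to
    neither numerator nor denominator.
    """
    rows = []
    for ev in gene.events:
        counts = {lab: [0, 0] for lab in gene.polya.labels}
        for call in calls:
            if call.gene_id != gene.gene_id or call.utr_class is None:
                continue
            status = call.ce_status.get(ev.event_id)
            if status == CeStatus.INCLUDED:
                counts[call.utr_class][0] += 1
            elif status == CeStatus.SKIPPED:
                counts[call.utr_class][1] += 1
        for lab in gene.polya.labels:
            rows.append(
                {
                    "gene": gene.gene_id,
                    "event_id": ev.event_id,
                    "replicate": replicate,
                    "utr_class": lab,
                    "included": counts[lab][0],
                    "skipped": counts[lab][1],
                }
            )
        rows.append(
            {
                "gene": gene.gene_id,
                "event_id": ev.event_id,
                "replicate": replicate,
                "utr_class": ALL_CLASS,
                "included": sum(c[0] for c in counts.values()),
                "skipped": sum(c[1] for c in counts.values()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "event_id", "replicate", "utr_class", "included", "skipped"],
    )


def psi_table(counts: pd.DataFrame, min_reads: int = MIN_READS) -> pd.DataFrame:
    """Attach PSI to an event-count table; undefined PSIs become NaN."""
    out = counts.copy()
    out["psi"] = [
        np.nan if (v := compute_psi(i, s, min_reads)) is None else v
        for i, s in zip(out["included"], out["skipped"])
    ]
    return out


def linkage_delta(
    psi_by_class: Mapping[str, Optional[float]], labels: Sequence[str]
) -> Optional[float]:
    """|PSI_distal - PSI_proximal|; undefined unless both class PSIs are."""
    lo, hi = psi_by_class.get(labels[0]), psi_by_class.get(labels[-1])
    if lo is None or hi is None or (isinstance(lo, float) and np.isnan(lo)) or (
        isinstance(hi, float) and np.isnan(hi)
    ):
        return None
    return abs(hi - lo)


# ---------------------------------------------------------------------------
# coverage


def coverage_track(
    alignments: Iterable[ReadAlignment], span_start: int, span_end: int
) -> np.ndarray:
    """Per-base read depth over [span_start, span_end) from aligned blocks."""
    cov = np.zeros(span_end - span_start, dtype=np.int64)
    for read in alignments:
        for s, e in read.blocks:
            s, e = max(s, span_start), min(e, span_end)
            if s < e:
                cov[s - span_start : e - span_start] += 1
    return cov


def write_bedgraph(cov: np.ndarray, chrom: str, offset: int, path: str) -> None:
    """Run-length encode a coverage vector as bedGraph (zero runs skipped)."""
    with open(path, "w") as fh:
        if cov.size == 0:
            return
        change = np.flatnonzero(np.diff(cov)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [cov.size]))
        for s, e in zip(starts, ends):
            if cov[s]:
                fh.write(f"{chrom}\t{offset + s}\t{offset + e}\t{cov[s]}\n")


def infer_polya_sites(
    cov: np.ndarray,
    candidates: Sequence[int],
    offset: int = 0,
    drop_frac: float = 0.8,
    window: int = 25,
) -> tuple[list[int], Optional[int]]:
    """Cleavage sites from coverage drops, snapped to annotated candidates.

    ``cov`` is the per-base coverage of the 3'UTR region in transcription
    orientation (index 0 = stop codon side); ``candidates`` and the returned
    sites are in the same frame, shifted by ``offset``.  A drop is called at
    position p when mean coverage over the downstream ``window`` is at most
    (1 - drop_frac) of the upstream window mean; each drop is snapped to the
    nearest candidate within ``window`` bases (the hybrid
    annotation-plus-coverage rule), drops with no nearby candidate are
    ignored.  The distal end is the last covered base.

    Returns ``(sites, distal_end)``; flat-zero coverage yields ``([], None)``.
    """
    cov = np.asarray(cov, dtype=float)
    nz = np.flatnonzero(cov > 0)
    if nz.size == 0:
        return [], None
    distal_end = offset + int(nz[-1])

    found: list[int] = []
    for p in range(1, cov.size):
        up = cov[max(0, p - window) : p].mean()
        down_seg = cov[p : p + window]
        if up <= 0 or down_seg.size == 0:
            continue
        if down_seg.mean() <= (1.0 - drop_frac) * up:
            for cand in candidates:
                if abs((cand - offset) - p) <= window:
                    if cand not in found:
                        found.append(cand)
                    break
    return sorted(found), distal_end


def gene_body_coverage(
    read_transcript_pairs: Iterable[tuple[ReadAlignment, Sequence[tuple[int, int]]]],
    strand: str,
    n_bins: int = 100,
) -> np.ndarray:
    """Read presence along the scaled gene body, 5'->3', in ``n_bins`` bins.

    Each transcript (its exons as genomic ``(start, end)`` blocks) is scaled
    to ``n_bins`` relative positions and every read adds one count to each
    bin whose transcript positions it covers.  Oligo-dT primed libraries
    show the characteristic ramp toward the 3' end here.
    """
    profile = np.zeros(n_bins, dtype=np.int64)
    for read, exons in read_transcript_pairs:
        exons = sorted(exons)
        length = sum(e - s for s, e in exons)
        if length == 0:
            continue
        covered = np.zeros(length, dtype=bool)
        tpos = 0
        for s, e in exons:
            for bs, be in read.blocks:
                lo, hi = max(s, bs), min(e, be)
                if lo < hi:
                    covered[tpos + (lo - s) : tpos + (hi - s)] = True
            tpos += e - s
        if strand == "-":
            covered = covered[::-1]  # transcript 5'->3'
        idx = np.flatnonzero(covered)
        bins = np.unique(idx * n_bins // length)
        profile[bins] += 1
    return profile
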