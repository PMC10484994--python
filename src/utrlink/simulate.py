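"""Truth-labelled simulator for targeted long-read cDNA experiments.

Generates a toy reference genome, a matching GTF annotation, a per-gene
event config, and aligned reads (SAM) with per-read ground truth, emulating
the statistical structure the pipeline assumes:

* a mixture of isoforms (CE included/skipped x 3'UTR class) with
  configurable per-class inclusion probabilities and class mixture;
* untemplated poly(A) tails appearing as 3' soft clips;
* 5'-truncated reads from incomplete oligo-dT reverse transcription;
* internally misprimed reads ending at a genomically encoded A tract
  planted in the universal 3'UTR;
* off-target background genes.

Reads are emitted directly as error-free alignments with exact CIGARs, so
filter behaviour is testable bit-for-bit; no sequencing-error model or
aligner is involved.  All outputs are deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .read_filtering import CeStatus, DiscardReason, ReadCall, revcomp

__all__ = [
    "SimGene",
    "SimConfig",
    "ToyReference",
    "make_toy_reference",
    "simulate_reads",
    "write_dataset",
    "truth_compare",
]

# A-free filler written immediately downstream of every declared cleavage
# site so that clean reads ending there never trip the mispriming filter.
_CLEAN_WINDOW = "CTGCGTCGGTCTGCGTCGGT"


@dataclass(frozen=True)
class SimGene:
    """Layout and truth parameters of one simulated tandem-APA target gene.

    Defaults reproduce a near-binary exon-to-3'UTR coupling: CE inclusion
    0.95 in long-3'UTR molecules vs 0.05 in short ones, an even short/long
    mixture (true dPAU 50), 1000 reads per class, with realistic artifact
    rates (15% 5'-truncated molecules, 5% internal mispriming).
    """

    gene_id: str
    strand: str = "+"
    class_labels: tuple[str, ...] = ("short", "long")
    truth_psi: tuple[float, ...] = (0.05, 0.95)       # per class label
    reads_per_class: tuple[int, ...] = (1000, 1000)
    flank_len: int = 150
    ce_len: int = 120
    intron_len: int = 80
    coding_tail: int = 30        # coding bases of the terminal exon
    universal_len: int = 400
    extension_lens: tuple[int, ...] = (600,)
    trunc_prob: float = 0.15
    misprime_rate: float = 0.05
    misprime_tract_len: int = 15
    tail_len_range: tuple[int, int] = (15, 35)

    def __post_init__(self) -> None:
        k = len(self.class_labels)
        if not (len(self.truth_psi) == len(self.reads_per_class) == k):
            raise ValueError("per-class parameter lengths must match class count")
        if len(self.extension_lens) != k - 1:
            raise ValueError("need one extension segment per non-proximal class")
        for p in (*self.truth_psi, self.trunc_prob, self.misprime_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")

    @property
    def event_id(self) -> str:
        return f"{self.gene_id}:CE2"


@dataclass(frozen=True)
class SimConfig:
    genes: tuple[SimGene, ...] = (SimGene("geneA"),)
    n_background_genes: int = 2
    background_read_fraction: float = 0.1
    background_gene_len: int = 800
    chrom: str = "chrSim"
    spacing: int = 500
    seed: int = 0


@dataclass
class _Layout:
    gene: SimGene
    offset: int
    length: int
    # all in transcript coordinates (0 = TSS):
    flank_u: tuple[int, int] = (0, 0)
    ce: tuple[int, int] = (0, 0)
    flank_d: tuple[int, int] = (0, 0)
    term_start: int = 0
    stop_t: int = 0
    sites_t: tuple[int, ...] = ()
    tract_start_t: Optional[int] = None

    def t2g(self, v: int) -> int:
        if self.gene.strand == "+":
            return self.offset + v
        return self.offset + self.length - v

    def iv2g(self, a: int, b: int) -> tuple[int, int]:
        """Transcript-coordinate interval [a,b) to genomic half-open."""
        if self.gene.strand == "+":
            return self.offset + a, self.offset + b
        return self.offset + self.length - b, self.offset + self.length - a

    @property
    def sites_g(self) -> tuple[int, ...]:
        return tuple(self.t2g(s) for s in self.sites_t)

    @property
    def stop_g(self) -> int:
        return self.t2g(self.stop_t)


@dataclass
class ToyReference:
    chrom: str
    seq: str
    gtf_text: str
    gene_config: dict
    layouts: dict[str, _Layout]
    background: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def fasta_text(self) -> str:
        lines = [f">{self.chrom}"]
        lines += [self.seq[i : i + 80] for i in range(0, len(self.seq), 80)]
        return "\n".join(lines) + "\n"

    def __getitem__(self, chrom: str) -> str:
        # sequence-accessor protocol used by the read filters
        if chrom != self.chrom:
            raise KeyError(chrom)
        return self.seq


def _plan_layout(gene: SimGene, offset: int) -> _Layout:
    f, c, i = gene.flank_len, gene.ce_len, gene.intron_len
    flank_u = (0, f)
    ce = (f + i, f + i + c)
    flank_d = (ce[1] + i, ce[1] + i + f)
    term_start = flank_d[1] + i
    stop_t = term_start + gene.coding_tail
    sites = []
    pos = stop_t + gene.universal_len
    sites.append(pos)
    for ext in gene.extension_lens:
        pos += ext
        sites.append(pos)
    length = sites[-1]
    tract = None
    if gene.misprime_rate > 0:
        tract = sites[0] - 30 - gene.misprime_tract_len
    return _Layout(
        gene=gene, offset=offset, length=length,
        flank_u=flank_u, ce=ce, flank_d=flank_d,
        term_start=term_start, stop_t=stop_t, sites_t=tuple(sites),
        tract_start_t=tract,
    )


def _gtf_line(chrom, feature, start, end, strand, gene_id, transcript_id=None) -> str:
    attrs = f'gene_id "{gene_id}";'
    if transcript_id:
        attrs += f' transcript_id "{transcript_id}";'
    return f"{chrom}\ttoy\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"


def make_toy_reference(config: SimConfig) -> ToyReference:
    """Build the toy genome, GTF annotation and per-gene event config."""
    rng = np.random.default_rng(config.seed)
    layouts: dict[str, _Layout] = {}
    background: dict[str, tuple[int, int]] = {}
    cursor = config.spacing
    for gene in config.genes:
        lay = _plan_layout(gene, cursor)
        layouts[gene.gene_id] = lay
        cursor += lay.length + config.spacing
    for b in range(config.n_background_genes):
        background[f"bg{b + 1}"] = (cursor, cursor + config.background_gene_len)
        cursor += config.background_gene_len + config.spacing
    total = cursor + config.spacing

    seq = rng.choice(list("ACGT"), size=total)
    for lay in layouts.values():
        # A-free buffer downstream (transcript orientation) of every site
        for site_t in lay.sites_t:
            g0, g1 = lay.iv2g(site_t, site_t + len(_CLEAN_WINDOW))
            win = _CLEAN_WINDOW if lay.gene.strand == "+" else revcomp(_CLEAN_WINDOW)
            seq[g0:g1] = list(win)
        if lay.tract_start_t is not None:
            a, b = lay.tract_start_t, lay.tract_start_t + lay.gene.misprime_tract_len
            g0, g1 = lay.iv2g(a, b)
            seq[g0:g1] = list("A" * (b - a)) if lay.gene.strand == "+" else list("T" * (b - a))
    seq_str = "".join(seq)

    gtf: list[str] = []
    cfg_genes = []
    for gene in config.genes:
        lay = layouts[gene.gene_id]
        st = gene.strand
        gtf.append(_gtf_line(config.chrom, "gene", lay.t2g(0) if st == "+" else lay.iv2g(0, lay.length)[0],
                             lay.iv2g(0, lay.length)[1] if st == "-" else lay.t2g(lay.length),
                             st, gene.gene_id))
        for ci, label in enumerate(gene.class_labels):
            for inc, tag in ((True, "in"), (False, "out")):
                tid = f"{gene.gene_id}.{label}.{tag}"
                exons_t = [lay.flank_u] + ([lay.ce] if inc else []) + [
                    lay.flank_d, (lay.term_start, lay.sites_t[ci]),
                ]
                exons_g = sorted(lay.iv2g(a, b) for a, b in exons_t)
                gtf.append(_gtf_line(config.chrom, "transcript",
                                     exons_g[0][0], exons_g[-1][1], st, gene.gene_id, tid))
                for g0, g1 in exons_g:
                    gtf.append(_gtf_line(config.chrom, "exon", g0, g1, st, gene.gene_id, tid))
        cfg_genes.append(
            {
                "gene_id": gene.gene_id,
                "stop_codon": lay.stop_g,
                "polya_sites": list(lay.sites_g),
                "utr_classes": list(gene.class_labels),
                "events": [
                    {"event_id": gene.event_id, "ce": 2,
                     "upstream_flank": 1, "downstream_flank": 3}
                ],
            }
        )
    for bid, (s, e) in background.items():
        tid = f"{bid}.t1"
        gtf.append(_gtf_line(config.chrom, "gene", s, e, "+", bid))
        gtf.append(_gtf_line(config.chrom, "transcript", s, e, "+", bid, tid))
        gtf.append(_gtf_line(config.chrom, "exon", s, e, "+", bid, tid))

    return ToyReference(
        chrom=config.chrom,
        seq=seq_str,
        gtf_text="\n".join(gtf) + "\n",
        gene_config={"genes": cfg_genes},
        layouts=layouts,
        background=background,
    )


def _sam_record(
    qname: str, chrom: str, strand: str, blocks: list[tuple[int, int]],
    ref_seq: str, clip_left: str, clip_right: str,
) -> str:
    """One error-free SAM line; SEQ matches the reference over every M block."""
    cigar = []
    if clip_left:
        cigar.append(f"{len(clip_left)}S")
    seq_parts = [clip_left]
    for j, (s, e) in enumerate(blocks):
        if j:
            gap = s - blocks[j - 1][1]
            cigar.append(f"{gap}N")
        cigar.append(f"{e - s}M")
        seq_parts.append(ref_seq[s:e])
    if clip_right:
        cigar.append(f"{len(clip_right)}S")
    seq_parts.append(clip_right)
    flag = 16 if strand == "-" else 0
    return "\t".join(
        [qname, str(flag), chrom, str(blocks[0][0] + 1), "60",
         "".join(cigar), "*", "0", "0", "".join(seq_parts), "*"]
    )


def simulate_reads(
    ref: ToyReference, config: SimConfig, seed: Optional[int] = None
) -> tuple[str, pd.DataFrame]:
    """Sample reads per gene and class; returns (SAM text, truth table).

    ``seed`` overrides the read-sampling stream (default: derived from the
    config seed), letting biological replicates share one reference while
    drawing independent reads.

    Per read: CE inclusion is Bernoulli(truth PSI of its class); artifact
    draws are mutually exclusive (misprime first, then truncation) so each
    read carries exactly one truth label.  Misprimed reads end at the
    planted A tract with an untemplated-A soft clip (the oligo-dT primer);
    truncated reads lose their 5' end into the upstream flank and fail the
    span filter; clean reads end precisely at their class's cleavage site
    with an untemplated poly(A) tail.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    header = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{ref.chrom}\tLN:{len(ref.seq)}",
    ]
    records: list[tuple[int, str]] = []
    truth_rows = []
    n_target = 0
    for gene in config.genes:
        lay = ref.layouts[gene.gene_id]
        for ci, label in enumerate(gene.class_labels):
            n = gene.reads_per_class[ci]
            n_target += n
            for r in range(n):
                rid = f"{gene.gene_id}:{label}:{r:05d}"
                u = rng.random()
                misprimed = u < gene.misprime_rate
                truncated = (not misprimed) and u < gene.misprime_rate + gene.trunc_prob
                included = rng.random() < gene.truth_psi[ci]
                tail_len = int(rng.integers(*gene.tail_len_range))
                adapter_len = int(rng.integers(6, 14))
                adapter = "".join(rng.choice(list("CGT"), size=adapter_len))

                start_t = 0
                if truncated:
                    start_t = int(rng.integers(gene.flank_len // 2 + 1, lay.ce[0]))
                end_t = lay.tract_start_t if misprimed else lay.sites_t[ci]
                exons_t = [lay.flank_u] + ([lay.ce] if included else []) + [
                    lay.flank_d, (lay.term_start, end_t),
                ]
                footprint = [
                    (max(a, start_t), b) for a, b in exons_t if b > start_t
                ]
                blocks = sorted(lay.iv2g(a, b) for a, b in footprint)
                tail = "A" * tail_len
                if gene.strand == "+":
                    clip_left, clip_right = adapter, tail
                else:
                    clip_left, clip_right = revcomp(tail), revcomp(adapter)
                records.append(
                    (blocks[0][0],
                     _sam_record(rid, ref.chrom, gene.strand, blocks, ref.seq,
                                 clip_left, clip_right))
                )
                truth_rows.append(
                    {
                        "read_id": rid, "gene_id": gene.gene_id,
                        "true_class": label,
                        "true_ce": "INCLUDED" if included else "SKIPPED",
                        "truncated": truncated, "misprimed": misprimed,
                        "background": False,
                    }
                )
    frac = config.background_read_fraction
    n_bg_total = int(round(frac / (1.0 - frac) * n_target)) if frac > 0 else 0
    bg_ids = list(ref.background)
    for r in range(n_bg_total):
        bid = bg_ids[r % len(bg_ids)]
        s, e = ref.background[bid]
        rid = f"{bid}:{r:05d}"
        tail_len = int(rng.integers(15, 35))
        records.append(
            (s, _sam_record(rid, ref.chrom, "+", [(s, e)], ref.seq, "", "A" * tail_len))
        )
        truth_rows.append(
            {"read_id": rid, "gene_id": bid, "true_class": None, "true_ce": None,
             "truncated": False, "misprimed": False, "background": True}
        )
    records.sort(key=lambda t: (t[0], t[1]))
    sam_text = "\n".join(header + [rec for _, rec in records]) + "\n"
    truth = pd.DataFrame(truth_rows)
    return sam_text, truth


def write_dataset(config: SimConfig, outdir, read_seed: Optional[int] = None) -> dict:
    """Materialize FASTA, GTF, gene config YAML, SAM and truth TSV on disk."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = make_toy_reference(config)
    sam_text, truth = simulate_reads(ref, config, seed=read_seed)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "config": outdir / "genes.yaml",
        "sam": outdir / "reads.sam",
        "truth": outdir / "truth.tsv",
    }
    paths["fasta"].write_text(ref.fasta_text)
    paths["gtf"].write_text(ref.gtf_text)
    paths["config"].write_text(yaml.safe_dump(ref.gene_config, sort_keys=False))
    paths["sam"].write_text(sam_text)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def truth_compare(calls: list[ReadCall], truth: pd.DataFrame) -> dict:
    """Confusion summary of pipeline calls against simulator ground truth.

    Returns class/CE accuracy on clean full-length reads, sensitivity and
    specificity of the mispriming filter, background leakage, and the full
    truth-by-verdict confusion table.
    """
    by_id = {c.read_id: c for c in calls}
    known = set(truth["read_id"])
    stray = set(by_id) - known
    if stray:
        raise ValueError(f"calls for unknown read ids: {sorted(stray)[:5]}")

    def verdict(rid: str) -> str:
        call = by_id.get(rid)
        if call is None:
            return "unassigned"
        if call.utr_class is not None:
            return call.utr_class
        return call.discard_reason.value

    t = truth.copy()
    t["verdict"] = [verdict(r) for r in t["read_id"]]
    clean = t[~t["truncated"] & ~t["misprimed"] & ~t["background"]]
    mis = t[t["misprimed"]]
    bg = t[t["background"]]

    class_acc = float((clean["verdict"] == clean["true_class"]).mean()) if len(clean) else math.nan
    mis_sens = (
        float((mis["verdict"] == DiscardReason.INTERNAL_MISPRIME.value).mean())
        if len(mis) else math.nan
    )
    mis_spec = (
        float((clean["verdict"] != DiscardReason.INTERNAL_MISPRIME.value).mean())
        if len(clean) else math.nan
    )
    if len(bg):
        target_classes = set(t.loc[~t["background"], "true_class"].dropna())
        bg_leak = float(bg["verdict"].isin(target_classes).mean())
    else:
        bg_leak = math.nan

    ce_ok = []
    for rid, true_ce in zip(clean["read_id"], clean["true_ce"]):
        call = by_id.get(rid)
        if call is None or call.utr_class is None or not call.ce_status:
            continue
        status = next(iter(call.ce_status.values()))
        ce_ok.append(status == CeStatus(true_ce))
    ce_acc = float(np.mean(ce_ok)) if ce_ok else math.nan

    confusion = (
        t.assign(truth_label=np.where(t["background"], "background",
                 np.where(t["misprimed"], "misprimed",
                 np.where(t["truncated"], "truncated", t["true_class"]))))
        .groupby(["truth_label", "verdict"]).size().unstack(fill_value=0)
    )
    return {
        "class_accuracy": class_acc,
        "ce_accuracy": ce_acc,
        "misprime_sensitivity": mis_sens,
        "misprime_specificity": mis_spec,
        "background_leakage": bg_leak,
        "confusion": confusion,
    }
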