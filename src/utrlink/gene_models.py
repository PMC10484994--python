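"""Target-gene models: exons, cassette-exon events and tandem poly(A) sites.

A *target gene* here is a gene with tandem 3'UTR alternative polyadenylation
(two or more cleavage sites in the same terminal exon) and one or more
cassette exons (CEs) whose inclusion is to be quantified separately per
3'UTR isoform class.  The models are built from a standard GTF/GFF
annotation plus a small per-gene configuration that declares which exon is
the CE, which constitutive exons flank it, and where the tandem poly(A)
sites are.

All coordinates are 0-based, half-open; GTF input (1-based, closed) is
converted on read.  "Transcription order" means 5'->3' along the mRNA:
increasing genomic coordinate on the + strand, decreasing on the - strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import gffutils
import yaml

__all__ = [
    "GenomicInterval",
    "ExonModel",
    "CassetteEvent",
    "PolyASiteSet",
    "GeneModel",
    "AnnotationError",
    "UnknownGeneError",
    "ConstitutiveCassetteError",
    "NotTandemApaError",
    "load_annotation",
    "derive_utr_segments",
    "genes_to_config",
    "config_to_yaml",
]


class AnnotationError(ValueError):
    """Base class for annotation/config validation failures."""


class UnknownGeneError(AnnotationError):
    """A configured gene id is absent from the annotation."""


class ConstitutiveCassetteError(AnnotationError):
    """A declared cassette exon is constitutive (present in all transcripts)."""


class NotTandemApaError(AnnotationError):
    """Fewer than two tandem poly(A) sites were declared for a gene."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Number of bases shared with [start, end)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class ExonModel:
    interval: GenomicInterval
    ordinal: int  # exon number in transcription order, 1-based
    constitutive: bool


@dataclass(frozen=True)
class CassetteEvent:
    """A cassette exon between two constitutive flanking exons."""

    event_id: str
    ce: ExonModel
    upstream_flank: ExonModel
    downstream_flank: ExonModel

    def __post_init__(self) -> None:
        if not (self.upstream_flank.constitutive and self.downstream_flank.constitutive):
            raise AnnotationError(f"{self.event_id}: flanking exons must be constitutive")
        if self.ce.constitutive:
            raise ConstitutiveCassetteError(
                f"{self.event_id}: cassette exon {self.ce.ordinal} is constitutive"
            )
        if not (self.upstream_flank.ordinal < self.ce.ordinal < self.downstream_flank.ordinal):
            raise AnnotationError(
                f"{self.event_id}: CE must lie between its flanks in transcription order"
            )


@dataclass(frozen=True)
class PolyASiteSet:
    """Ordered tandem cleavage sites, proximal -> distal in transcription order.

    ``labels[i]`` names the 3'UTR class whose transcripts end at ``sites[i]``
    (e.g. ``("short", "long")`` or ``("short", "medium", "long")``).
    """

    sites: tuple[int, ...]
    labels: tuple[str, ...]
    strand: str

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise NotTandemApaError(
                f"{len(self.sites)} poly(A) site(s) declared: not a tandem-APA gene"
            )
        if len(self.labels) != len(self.sites):
            raise AnnotationError("class label count must equal site count")
        step = 1 if self.strand == "+" else -1
        diffs = [step * (b - a) for a, b in zip(self.sites, self.sites[1:])]
        if any(d <= 0 for d in diffs):
            raise AnnotationError(
                "poly(A) sites must be strictly increasing in transcription order"
            )

    @property
    def proximal(self) -> int:
        return self.sites[0]

    @property
    def distal(self) -> int:
        return self.sites[-1]


@dataclass(frozen=True)
class GeneModel:
    """A validated tandem-APA target gene with its CE events and UTR segments."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[ExonModel, ...]  # transcription order
    events: tuple[CassetteEvent, ...]
    polya: PolyASiteSet
    stop_codon: int  # genomic boundary where the 3'UTR begins
    universal_utr: GenomicInterval = field(init=False, default=None)  # type: ignore[assignment]
    extensions: tuple[GenomicInterval, ...] = field(init=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        universal, extensions = derive_utr_segments(
            self.chrom, self.strand, self.stop_codon, self.polya
        )
        object.__setattr__(self, "universal_utr", universal)
        object.__setattr__(self, "extensions", extensions)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.interval.overlap(b.interval.start, b.interval.end):
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
            step = 1 if self.strand == "+" else -1
            if step * (b.interval.start - a.interval.start) <= 0:
                raise AnnotationError(f"{self.gene_id}: exons not in transcription order")

    def exon(self, ordinal: int) -> ExonModel:
        for e in self.exons:
            if e.ordinal == ordinal:
                return e
        raise AnnotationError(f"{self.gene_id}: no exon with ordinal {ordinal}")

    @property
    def class_labels(self) -> tuple[str, ...]:
        return self.polya.labels

    def span(self) -> GenomicInterval:
        """Genomic footprint of the gene including the most distal UTR."""
        coords = [e.interval.start for e in self.exons] + [e.interval.end for e in self.exons]
        coords += [self.universal_utr.start, self.universal_utr.end]
        coords += [c for ext in self.extensions for c in (ext.start, ext.end)]
        return GenomicInterval(self.chrom, min(coords), max(coords), self.strand)

    def segment_for_class(self, index: int) -> GenomicInterval:
        """The terminal UTR segment unique to class ``index`` (0 = proximal).

        Class 0 has no unique segment; its reads end in the universal 3'UTR,
        so the universal region is returned for it.
        """
        if index == 0:
            return self.universal_utr
        return self.extensions[index - 1]


def derive_utr_segments(
    chrom: str, strand: str, stop_codon: int, polya: PolyASiteSet
) -> tuple[GenomicInterval, tuple[GenomicInterval, ...]]:
    """Split the 3'UTR into the universal segment and per-class extensions.

    The universal segment runs from the stop codon to the proximal site and
    is shared by all isoform classes; ``extensions[i]`` spans sites i -> i+1
    in transcription order and is unique to classes > i.  On the - strand
    transcription order runs against genomic coordinates but every returned
    interval still satisfies start < end.
    """
    sites = polya.sites
    if len(set(sites)) != len(sites):
        raise AnnotationError("duplicate poly(A) site positions")
    if strand == "+":
        universal = GenomicInterval(chrom, stop_codon, sites[0], strand)
        extensions = tuple(
            GenomicInterval(chrom, a, b, strand) for a, b in zip(sites, sites[1:])
        )
    else:
        universal = GenomicInterval(chrom, sites[0], stop_codon, strand)
        extensions = tuple(
            GenomicInterval(chrom, b, a, strand) for a, b in zip(sites, sites[1:])
        )
    return universal, extensions


# ---------------------------------------------------------------------------
# GTF + config loading


def _exon_key(start: int, end: int) -> tuple[int, int]:
    return (start, end)


def load_annotation(annotation_text: str, config) -> list[GeneModel]:
    """Build validated :class:`GeneModel`s from GTF text and a per-gene config.

    ``config`` is a mapping (or YAML string) with a ``genes`` list; each entry
    declares ``gene_id``, ``stop_codon``, ``polya_sites`` (genomic positions in
    transcription order, proximal first), ``utr_classes`` (one label per site),
    an ``events`` list (``event_id``, exon ordinals ``ce``, ``upstream_flank``,
    ``downstream_flank``) and an optional ``constitutive_override`` mapping of
    exon ordinal to bool.

    Constitutive status defaults to "exon present, with identical coordinates,
    in every annotated transcript of the gene"; the override exists because
    curated target panels frequently disagree with automated annotation.
    """
    if isinstance(config, str):
        config = yaml.safe_load(config)
    db = gffutils.create_db(
        data=annotation_text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # exon sets per transcript, grouped by gene, straight from the GTF
    by_gene: dict[str, dict[str, list[tuple[int, int, str, str]]]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes["gene_id"][0]
        tid = ex.attributes["transcript_id"][0]
        by_gene.setdefault(gid, {}).setdefault(tid, []).append(
            (ex.start - 1, ex.end, ex.seqid, ex.strand)  # GTF 1-based closed -> half-open
        )

    genes: list[GeneModel] = []
    for entry in config["genes"]:
        gid = entry["gene_id"]
        if gid not in by_gene:
            raise UnknownGeneError(f"gene {gid!r} not present in annotation")
        transcripts = by_gene[gid]
        chroms = {c for exons in transcripts.values() for (_, _, c, _) in exons}
        strands = {s for exons in transcripts.values() for (_, _, _, s) in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(f"{gid}: transcripts span multiple chromosomes/strands")
        chrom, strand = chroms.pop(), strands.pop()
        stop_codon = int(entry["stop_codon"])

        # Exons are modeled on the coding side of the stop codon only: the
        # 3'UTR is described by the universal/extension segments, and the
        # terminal exons of tandem-UTR transcripts differ (and overlap) only
        # past the stop.  Clipping there keeps the exon set non-overlapping
        # and makes the shared terminal-exon stub constitutive.
        def _clip(s: int, e: int) -> Optional[tuple[int, int]]:
            if strand == "+":
                e = min(e, stop_codon)
            else:
                s = max(s, stop_codon)
            return (s, e) if s < e else None

        clipped_sets = [
            {c for (s, e, _, _) in exons if (c := _clip(s, e)) is not None}
            for exons in transcripts.values()
        ]
        all_exons = sorted(set.union(*clipped_sets))
        if strand == "-":
            all_exons = all_exons[::-1]
        shared = set.intersection(*clipped_sets)
        override = {int(k): bool(v) for k, v in (entry.get("constitutive_override") or {}).items()}
        exons = tuple(
            ExonModel(
                GenomicInterval(chrom, s, e, strand),
                ordinal=i + 1,
                constitutive=override.get(i + 1, _exon_key(s, e) in shared),
            )
            for i, (s, e) in enumerate(all_exons)
        )
        exon_by_ord = {e.ordinal: e for e in exons}

        polya = PolyASiteSet(
            sites=tuple(int(p) for p in entry["polya_sites"]),
            labels=tuple(entry["utr_classes"]),
            strand=strand,
        )
        events = tuple(
            CassetteEvent(
                event_id=ev["event_id"],
                ce=exon_by_ord[int(ev["ce"])],
                upstream_flank=exon_by_ord[int(ev["upstream_flank"])],
                downstream_flank=exon_by_ord[int(ev["downstream_flank"])],
            )
            for ev in entry.get("events", [])
        )
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=exons,
                events=events,
                polya=polya,
                stop_codon=int(entry["stop_codon"]),
            )
        )
    return genes


def genes_to_config(genes: list[GeneModel]) -> dict:
    """Serialize gene models back to the config mapping (round-trips)."""
    out = []
    for g in genes:
        out.append(
            {
                "gene_id": g.gene_id,
                "stop_codon": g.stop_codon,
                "polya_sites": list(g.polya.sites),
                "utr_classes": list(g.polya.labels),
                "events": [
                    {
                        "event_id": ev.event_id,
                        "ce": ev.ce.ordinal,
                        "upstream_flank": ev.upstream_flank.ordinal,
                        "downstream_flank": ev.downstream_flank.ordinal,
                    }
                    for ev in g.events
                ],
                "constitutive_override": {e.ordinal: e.constitutive for e in g.exons},
            }
        )
    return {"genes": out}


def config_to_yaml(config: dict) -> str:
    buf = io.StringIO()
    yaml.safe_dump(config, buf, sort_keys=False)
    return buf.getvalue()
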