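import pandas as pd
import pysam
import pytest

from utrlink.gene_models import load_annotation
from utrlink.read_filtering import FilterParams, classify_sam
from utrlink.simulate import SimConfig, SimGene, make_toy_reference, write_dataset


def gtf_line(chrom, feature, start0, end, strand, gene_id, transcript_id=None):
    attrs = f'gene_id "{gene_id}";'
    if transcript_id:
        attrs += f' transcript_id "{transcript_id}";'
    return f"{chrom}\ttest\t{feature}\t{start0 + 1}\t{end}\t.\t{strand}\t.\t{attrs}"


@pytest.fixture(scope="session")
def toy_gtf():
    """Hand-written gene: 4 transcripts, CE present in 2 of 4, 2 tandem UTRs."""
    lines = []
    exons = {
        "t1": [(100, 200), (300, 360), (400, 500), (600, 1000)],  # CE in, short
        "t2": [(100, 200), (400, 500), (600, 1000)],              # CE out, short
        "t3": [(100, 200), (300, 360), (400, 500), (600, 2500)],  # CE in, long
        "t4": [(100, 200), (400, 500), (600, 2500)],              # CE out, long
    }
    for tid, exs in exons.items():
        lines.append(gtf_line("chr1", "transcript", exs[0][0], exs[-1][1], "+", "g1", tid))
        for s, e in exs:
            lines.append(gtf_line("chr1", "exon", s, e, "+", "g1", tid))
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_config():
    return {
        "genes": [
            {
                "gene_id": "g1",
                "stop_codon": 650,
                "polya_sites": [1000, 2500],
                "utr_classes": ["short", "long"],
                "events": [
                    {"event_id": "g1:CE2", "ce": 2,
                     "upstream_flank": 1, "downstream_flank": 3}
                ],
            }
        ]
    }


@pytest.fixture(scope="session")
def toy_gene(toy_gtf, toy_config):
    return load_annotation(toy_gtf, toy_config)[0]


@pytest.fixture(scope="session")
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1_000_000},
                                     {"SN": "chrSim", "LN": 10_000_000}]}
    )


@pytest.fixture(scope="session")
def make_record(sam_header):
    """Build a pysam record from (qname, flag, chrom, pos0, cigar, seq)."""

    def _make(qname="r1", flag=0, chrom="chr1", pos0=0, cigar="100M", seq=None, mapq=60):
        if seq is None:
            import re
            qlen = sum(
                int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar)
            )
            seq = "C" * qlen
        fields = [qname, str(flag), chrom, str(pos0 + 1), str(mapq), cigar,
                  "*", "0", "0", seq, "*"]
        return pysam.AlignedSegment.fromstring("\t".join(fields), sam_header)

    return _make


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One default-condition simulated dataset, classified once for reuse."""
    cfg = SimConfig(seed=5)
    outdir = tmp_path_factory.mktemp("sim")
    paths = write_dataset(cfg, outdir)
    ref = make_toy_reference(cfg)
    genes = load_annotation(ref.gtf_text, ref.gene_config)
    calls, alignments, n_primary = classify_sam(paths["sam"], genes, ref, FilterParams())
    truth = pd.read_csv(paths["truth"], sep="\t")
    return {
        "config": cfg, "paths": paths, "ref": ref, "genes": genes,
        "calls": calls, "alignments": alignments, "n_primary": n_primary,
        "truth": truth,
    }
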