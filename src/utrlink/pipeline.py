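"""End-to-end orchestration: samples -> calls -> counts -> PSI/dPAU -> stats.

The run config is a single YAML file:

.. code-block:: yaml

    reference: genome.fa
    annotation: annotation.gtf
    gene_config: genes.yaml
    output_dir: out
    seed: 0
    filter_params: {min_extension_overlap: 50}   # optional overrides
    samples:
      - {sample: ctl_rep1, condition: control, replicate: rep1, sam: ctl1.sam}
      - {sample: mut_rep1, condition: mutant,  replicate: rep1, sam: mut1.sam}

Outputs per run: a per-read call table, event counts with PSI, per-gene
dPAU, per-(gene, class) bedGraph coverage tracks, a per-gene statistical
summary across conditions, the on-target read fraction per sample, and a
machine-readable run log (parameters, seed, per-stage read attrition).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from collections import Counter
from typing import Optional

import pandas as pd
import pyfaidx
import yaml

from . import __version__
from .gene_models import GeneModel, load_annotation
from .linkage_stats import summarize_gene
from .quantify import (
    ALL_CLASS,
    compute_dpau_longread,
    count_events,
    coverage_track,
    linkage_delta,
    psi_table,
    write_bedgraph,
)
from .read_filtering import FilterParams, classify_sam

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "target_fraction_report"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (raised before any compute)."""


@dataclasses.dataclass
class RunConfig:
    reference: str
    annotation: str
    gene_config: str
    output_dir: str
    samples: list[dict]
    seed: int = 0
    filter_params: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text())
        missing = {"reference", "annotation", "gene_config", "output_dir", "samples"} - set(raw)
        if missing:
            raise ConfigError(f"run config missing keys: {sorted(missing)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("reference", "annotation", "gene_config"):
            if not pathlib.Path(getattr(self, key)).exists():
                raise ConfigError(f"{key} path does not exist: {getattr(self, key)}")
        seen = set()
        for s in self.samples:
            for k in ("sample", "condition", "replicate", "sam"):
                if k not in s:
                    raise ConfigError(f"sample entry missing {k!r}: {s}")
            if not pathlib.Path(s["sam"]).exists():
                raise ConfigError(f"SAM path does not exist: {s['sam']}")
            key = (s["condition"], s["replicate"])
            if key in seen:
                raise ConfigError(f"duplicate replicate label {key}")
            seen.add(key)

    def params(self) -> FilterParams:
        return FilterParams(**(self.filter_params or {}))


def target_fraction_report(n_on_target: int, n_aligned: int) -> float:
    """Fraction of aligned reads overlapping the target panel."""
    if n_aligned == 0:
        raise ValueError("no aligned reads")
    return n_on_target / n_aligned


def run_pipeline(config: RunConfig) -> dict:
    """Run classification, quantification and statistics for every sample.

    Returns a dict of output paths plus the in-memory summary tables.
    """
    config.validate()
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params()
    genes = load_annotation(
        pathlib.Path(config.annotation).read_text(),
        pathlib.Path(config.gene_config).read_text(),
    )
    ref = pyfaidx.Fasta(config.reference)

    call_rows, count_frames, dpau_rows, fraction_rows, attrition = [], [], [], [], []
    metrics: dict[tuple, dict[str, list]] = {}
    for s in sorted(config.samples, key=lambda d: d["sample"]):
        calls, alignments, n_primary = classify_sam(s["sam"], genes, ref, params)
        funnel = Counter(
            c.discard_reason.value if c.discard_reason else "classified" for c in calls
        )
        attrition.append(
            {"sample": s["sample"], "aligned": n_primary, "on_target": len(calls), **funnel}
        )
        fraction_rows.append(
            {
                "sample": s["sample"],
                "target_fraction": target_fraction_report(len(calls), n_primary),
            }
        )
        for c in calls:
            call_rows.append(
                {
                    "sample": s["sample"], "read_id": c.read_id, "gene": c.gene_id,
                    "utr_class": c.utr_class or "",
                    "discard_reason": c.discard_reason.value if c.discard_reason else "",
                    **{f"ce:{k}": v.value for k, v in c.ce_status.items()},
                }
            )
        for gene in genes:
            gene_calls = [c for c in calls if c.gene_id == gene.gene_id]
            counts = count_events(gene_calls, gene, replicate=s["replicate"])
            counts.insert(0, "sample", s["sample"])
            counts.insert(1, "condition", s["condition"])
            count_frames.append(counts)
            class_counts = Counter(
                c.utr_class for c in gene_calls if c.utr_class is not None
            )
            dpau = compute_dpau_longread(class_counts, gene.polya.labels)
            dpau_rows.append(
                {
                    "sample": s["sample"], "condition": s["condition"],
                    "replicate": s["replicate"], "gene": gene.gene_id,
                    "dpau": float("nan") if dpau is None else dpau,
                    **{lab: class_counts.get(lab, 0) for lab in gene.polya.labels},
                }
            )
            _write_tracks(outdir, s["sample"], gene, gene_calls, alignments)
            _collect_metrics(metrics, s, gene, gene_calls, counts, dpau)

    calls_df = pd.DataFrame(call_rows)
    counts_df = psi_table(pd.concat(count_frames, ignore_index=True))
    dpau_df = pd.DataFrame(dpau_rows)
    fraction_df = pd.DataFrame(fraction_rows)
    summary_df = _summaries(metrics, genes)

    paths = {
        "calls": outdir / "read_calls.tsv",
        "counts": outdir / "event_counts.tsv",
        "dpau": outdir / "dpau.tsv",
        "target_fraction": outdir / "target_fraction.tsv",
        "summary": outdir / "gene_summary.tsv",
        "log": outdir / "run_log.json",
    }
    calls_df.to_csv(paths["calls"], sep="\t", index=False)
    counts_df.to_csv(paths["counts"], sep="\t", index=False, float_format="%.6g")
    dpau_df.to_csv(paths["dpau"], sep="\t", index=False, float_format="%.6g")
    fraction_df.to_csv(paths["target_fraction"], sep="\t", index=False, float_format="%.6g")
    summary_df.to_csv(paths["summary"], sep="\t", index=False, float_format="%.6g")
    paths["log"].write_text(
        json.dumps(
            {
                "version": __version__,
                "seed": config.seed,
                "filter_params": dataclasses.asdict(params),
                "samples": [s["sample"] for s in config.samples],
                "attrition": attrition,
            },
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "counts": counts_df,
        "dpau": dpau_df,
        "summary": summary_df,
        "target_fraction": fraction_df,
    }


def _write_tracks(outdir, sample, gene: GeneModel, gene_calls, alignments) -> None:
    span = gene.span()
    for label in gene.polya.labels:
        reads = [
            alignments[c.read_id]
            for c in gene_calls
            if c.utr_class == label and c.read_id in alignments
        ]
        cov = coverage_track(reads, span.start, span.end)
        write_bedgraph(
            cov, gene.chrom, span.start,
            str(outdir / f"{sample}.{gene.gene_id}.{label}.bedgraph"),
        )


def _collect_metrics(metrics, s, gene, gene_calls, counts, dpau) -> None:
    for ev in gene.events:
        key = (gene.gene_id, ev.event_id, s["condition"])
        slot = metrics.setdefault(
            key, {"dPAU": [], "PSI_All": [], "PSI_Short": [], "PSI_Long": [],
                  "linkage_delta": []}
        )
        by_class = {}
        ev_counts = psi_table(counts[counts["event_id"] == ev.event_id])
        for _, row in ev_counts.iterrows():
            by_class[row["utr_class"]] = row["psi"]
        labels = gene.polya.labels
        slot["dPAU"].append(dpau)
        slot["PSI_All"].append(by_class.get(ALL_CLASS))
        slot["PSI_Short"].append(by_class.get(labels[0]))
        slot["PSI_Long"].append(by_class.get(labels[-1]))
        slot["linkage_delta"].append(linkage_delta(by_class, labels))


def _summaries(metrics, genes) -> pd.DataFrame:
    grouped: dict[tuple, dict] = {}
    for (gid, eid, cond), vals in metrics.items():
        grouped.setdefault((gid, eid), {})[cond] = vals
    rows = [
        summarize_gene(gid, eid, conds) for (gid, eid), conds in sorted(grouped.items())
    ]
    return pd.DataFrame(rows)
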