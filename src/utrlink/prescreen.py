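"""Short-read candidate screen for coupled APA and cassette-exon splicing.

Consumes poly(A)-site-usage (PAU) tables of the kind produced by 3'UTR
quantifiers and differential-splicing event tables of the kind produced by
junction-count tools, both as plain TSV with a documented column schema —
the upstream tools themselves are not run here.  The screen:

* derives per-gene dPAU (PAU of the maximum-length 3'UTR isoform) among
  expressed genes (gene-level TPM > 0);
* calls 3'UTR lengthening/shortening between two conditions from dPAU fold
  change and a BH-adjusted two-tailed t-test (lengthening: FC > 2 and
  adjusted p < 0.05; shortening: FC < 0.5 and adjusted p < 0.05);
* calls regulated cassette exons (FDR < 0.05 and |delta-PSI| > 0.2);
* tests the association between the two gene sets with a two-sided
  Fisher's exact test over the multi-isoform APA gene universe.

Expected PAU table columns: ``gene_id``, ``apa_id``, ``utr_length``,
optional ``utr_end`` (3'-most genomic coordinate, used only to break length
ties), one ``PAU_<sample>`` and one ``TPM_<sample>`` column per sample.
Expected splice table columns: ``gene_id``, ``event_type``,
``inc_level_diff``, ``fdr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage_stats import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "dpau_from_pau",
    "dpau_table",
    "call_lengthening",
    "call_regulated_ce",
    "fisher_exact_2x2",
    "candidate_genes",
    "AssociationResult",
]

LENGTHENING = "lengthening"
SHORTENING = "shortening"
UNCHANGED = "unchanged"


def _pick_distal_isoform(rows: pd.DataFrame) -> pd.Series:
    """Row of the maximum-length 3'UTR isoform; ties broken by 3'-most end."""
    max_len = rows["utr_length"].max()
    tied = rows[rows["utr_length"] == max_len]
    if len(tied) > 1:
        if "utr_end" in tied.columns and tied["utr_end"].notna().all():
            tied = tied.sort_values("utr_end")
        else:
            tied = tied.sort_values("apa_id")
        log.info(
            "gene %s: %d isoforms tie at max UTR length, keeping %s",
            rows["gene_id"].iloc[0], len(tied), tied.iloc[-1]["apa_id"],
        )
    return tied.iloc[-1]


def dpau_from_pau(rows: pd.DataFrame, sample: str) -> float:
    """dPAU for one gene in one sample: PAU of the longest 3'UTR isoform.

    Raises ``ValueError`` for single-isoform genes (no tandem APA to
    measure) and for unexpressed genes (gene-level TPM of 0).
    """
    if len(rows) < 2:
        raise ValueError("single-isoform gene: dPAU undefined")
    tpm = rows[f"TPM_{sample}"].iloc[0]
    if not tpm > 0:
        raise ValueError("gene not expressed (TPM == 0)")
    return float(_pick_distal_isoform(rows)[f"PAU_{sample}"])


def dpau_table(pau: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-gene dPAU across samples, restricted to expressed multi-isoform genes.

    A gene is kept only if it has >= 2 isoforms and gene-level TPM > 0 in
    every listed sample.
    """
    rows = []
    for gene_id, grp in pau.groupby("gene_id", sort=True):
        if len(grp) < 2:
            continue
        if any(not (grp[f"TPM_{s}"].iloc[0] > 0) for s in samples):
            continue
        distal = _pick_distal_isoform(grp)
        rows.append(
            {"gene_id": gene_id, **{s: float(distal[f"PAU_{s}"]) for s in samples}}
        )
    return pd.DataFrame(rows, columns=["gene_id", *samples])


def call_lengthening(
    dpau: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each gene as lengthening / shortening / unchanged (B vs A).

    FC is the ratio of mean dPAU in condition B over condition A; p comes
    from a two-tailed t-test per gene, adjusted across genes with BH.
    Genes with zero mean dPAU in A have undefined FC and are flagged
    (``fc`` NaN, call unchanged) rather than pseudo-counted.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    recs = []
    for _, row in dpau.iterrows():
        a = row[samples_a].to_numpy(dtype=float)
        b = row[samples_b].to_numpy(dtype=float)
        if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(b, a).pvalue)
        fc = b.mean() / a.mean() if a.mean() > 0 else np.nan
        recs.append(
            {"gene_id": row["gene_id"], "mean_a": a.mean(), "mean_b": b.mean(),
             "fc": fc, "p": p}
        )
    out = pd.DataFrame(recs)
    out["p_adj"] = bh_adjust(out["p"])
    calls = []
    for fc, padj in zip(out["fc"], out["p_adj"]):
        if np.isnan(fc):
            calls.append(UNCHANGED)
        elif fc > fc_threshold and padj < alpha:
            calls.append(LENGTHENING)
        elif fc < 1.0 / fc_threshold and padj < alpha:
            calls.append(SHORTENING)
        else:
            calls.append(UNCHANGED)
    out["call"] = calls
    return out


def call_regulated_ce(
    events: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_abs_dpsi: float = 0.2,
    event_types: tuple[str, ...] = ("CE", "SE"),
) -> pd.DataFrame:
    """High-confidence regulated cassette exons: FDR and |delta-PSI| filter.

    Keeps CE rows with ``fdr < fdr_threshold`` and ``|inc_level_diff| >
    min_abs_dpsi``; the sign of delta-PSI is retained as
    inclusion/skipping direction.
    """
    ce = events[events["event_type"].isin(event_types)].copy()
    keep = (ce["fdr"] < fdr_threshold) & (ce["inc_level_diff"].abs() > min_abs_dpsi)
    out = ce[keep].copy()
    out["direction"] = np.where(out["inc_level_diff"] > 0, "inclusion", "skipping")
    return out


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (odds_ratio, p).

    p sums hypergeometric probabilities of tables (at fixed margins) no
    more likely than the observed one.  A degenerate margin (an all-zero
    row or column) carries no information; p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        log.info("degenerate margin in %s; p = 1 by convention", t.tolist())
        odds = np.nan
        return odds, 1.0
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


@dataclass(frozen=True)
class AssociationResult:
    candidates: tuple[str, ...]
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float


def candidate_genes(
    lengthening: set[str], regulated: set[str], universe: set[str]
) -> AssociationResult:
    """Coupled AS-APA candidates plus the 2x2 association test.

    ``universe`` is the set of all expressed multi-isoform APA genes the
    calls were made on; both call sets must be subsets of it.  The 2x2
    table cross-tabulates 3'UTR-lengthening status against regulated-CE
    status over the universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    stray = (lengthening | regulated) - universe
    if stray:
        raise ValueError(f"genes outside the universe: {sorted(stray)[:5]}")
    a = len(lengthening & regulated)
    b = len(lengthening - regulated)
    c = len(regulated - lengthening)
    d = len(universe - lengthening - regulated)
    odds, p = fisher_exact_2x2([[a, b], [c, d]])
    return AssociationResult(
        candidates=tuple(sorted(lengthening & regulated)),
        table=((a, b), (c, d)),
        odds_ratio=odds,
        p=p,
    )
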