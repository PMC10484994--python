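"""Replicate-level statistics on isoform-resolved PSI and dPAU.

Within a sample, PSI_Short vs PSI_Long is a paired comparison (the pairing
is the biological replicate); genotype contrasts (control vs mutant) are
unpaired two-sample t-tests.  Raw two-sided p-values are the primary
output — multiple-testing adjustment (Benjamini-Hochberg) is available but
opt-in and clearly labelled, since per-gene raw p-values are the
convention for small targeted panels.

Sign conventions follow the questions asked of the data:

* ``paired_t_test(x, y)`` tests the increase y - x (positive t: y larger);
* ``two_sample_t_test(a, b)`` tests the difference a - b (negative t: a
  smaller);
* ``linkage_reduction`` reports effect = mean(mutant) - mean(control) on
  |PSI_Long - PSI_Short|, so a loss of exon-to-3'UTR coupling in the mutant
  appears as a negative effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "InsufficientReplicates",
    "paired_t_test",
    "two_sample_t_test",
    "linkage_reduction",
    "summarize_gene",
    "sem",
    "bh_adjust",
]


class InsufficientReplicates(ValueError):
    """Fewer replicates than the test requires."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a t-test; ``p`` is NaN for degenerate (zero-variance) data."""

    t: float
    df: float
    p: float
    effect: float  # mean difference on the test's sign convention
    kind: str      # "paired" | "two_sample"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not math.isnan(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean (ddof=1)."""
    return float(stats.sem(np.asarray(values, dtype=float)))


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed paired t-test on the per-replicate differences y - x.

    All-zero differences give t=0, p=1 (no effect, exactly); a nonzero
    constant difference has zero variance and is flagged degenerate with an
    undefined p rather than p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 2:
        raise InsufficientReplicates(f"paired t-test needs >= 2 replicate pairs, got {n}")
    d = y - x
    df = n - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TestResult(t=0.0, df=df, p=1.0, effect=0.0, kind="paired")
        return TestResult(
            t=math.inf if d.mean() > 0 else -math.inf,
            df=df, p=math.nan, effect=float(d.mean()), kind="paired", degenerate=True,
        )
    res = stats.ttest_rel(y, x)
    return TestResult(
        t=float(res.statistic), df=df, p=float(res.pvalue), effect=float(d.mean()),
        kind="paired",
    )


def two_sample_t_test(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-tailed two-sample t-test of a vs b (Student pooled by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicates("two-sample t-test needs >= 2 values per group")
    effect = float(a.mean() - b.mean())
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.isclose(effect, 0.0):
            df = a.size + b.size - 2
            return TestResult(t=0.0, df=df, p=1.0, effect=0.0, kind="two_sample")
        return TestResult(
            t=math.inf if effect > 0 else -math.inf,
            df=a.size + b.size - 2, p=math.nan, effect=effect,
            kind="two_sample", degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = float(res.df)
    else:
        df = a.size + b.size - 2
    return TestResult(
        t=float(res.statistic), df=df, p=float(res.pvalue), effect=effect,
        kind="two_sample",
    )


def _defined(values: Sequence[Optional[float]]) -> np.ndarray:
    vals = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    return np.asarray(vals, dtype=float)


def linkage_reduction(
    control_deltas: Sequence[Optional[float]],
    mutant_deltas: Sequence[Optional[float]],
    welch: bool = False,
) -> TestResult:
    """Unpaired t-test on per-replicate |PSI_Long - PSI_Short|, mutant vs control.

    Undefined deltas (a class below the PSI read-count floor in that
    replicate) are dropped; the effect is mean(mutant) - mean(control), so a
    negative effect reads as "linkage reduced in the mutant".
    """
    c = _defined(control_deltas)
    m = _defined(mutant_deltas)
    if c.size < 2 or m.size < 2:
        raise InsufficientReplicates(
            f"linkage test needs >= 2 defined deltas per condition (got {c.size}, {m.size})"
        )
    return two_sample_t_test(m, c, welch=welch)


_METRICS = ("dPAU", "PSI_All", "PSI_Short", "PSI_Long", "linkage_delta")


def summarize_gene(
    gene: str,
    event_id: str,
    replicates: Mapping[str, Mapping[str, Sequence[Optional[float]]]],
    welch: bool = False,
) -> dict:
    """Per-gene report row: mean +/- SEM per condition and genotype contrasts.

    ``replicates`` maps condition -> metric -> per-replicate values, with
    metrics among dPAU, PSI_All, PSI_Short, PSI_Long and linkage_delta.
    With two conditions each metric gets an unpaired two-sided t-test; the
    within-condition PSI_Short vs PSI_Long paired test is also reported.
    No multiple-comparison adjustment is applied here.
    """
    row: dict = {"gene": gene, "event_id": event_id}
    conditions = list(replicates)
    for cond in conditions:
        for metric in _METRICS:
            vals = _defined(replicates[cond].get(metric, ()))
            row[f"{cond}:{metric}:mean"] = float(vals.mean()) if vals.size else math.nan
            row[f"{cond}:{metric}:sem"] = sem(vals) if vals.size >= 2 else math.nan
        # within-condition coupling: paired short vs long PSI
        s = replicates[cond].get("PSI_Short", ())
        l = replicates[cond].get("PSI_Long", ())
        pairs = [
            (a, b)
            for a, b in zip(s, l)
            if _defined([a]).size and _defined([b]).size
        ]
        if len(pairs) >= 2:
            res = paired_t_test([a for a, _ in pairs], [b for _, b in pairs])
            row[f"{cond}:short_vs_long:p"] = res.p
            row[f"{cond}:short_vs_long:t"] = res.t
        else:
            row[f"{cond}:short_vs_long:p"] = math.nan
            row[f"{cond}:short_vs_long:t"] = math.nan
    if len(conditions) == 2:
        ca, cb = conditions
        for metric in _METRICS:
            a = _defined(replicates[cb].get(metric, ()))
            b = _defined(replicates[ca].get(metric, ()))
            try:
                res = two_sample_t_test(a, b, welch=welch)
                row[f"{metric}:p"] = res.p
                row[f"{metric}:effect"] = res.effect
            except InsufficientReplicates:
                row[f"{metric}:p"] = math.nan
                row[f"{metric}:effect"] = math.nan
    return row


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
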