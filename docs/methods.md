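# Methods

## The measurement model

A targeted long-read cDNA experiment produces oligo-dT primed, full-length
or 5'-truncated cDNA molecules from a curated panel of tandem-APA genes,
aligned to the genome with a splice-aware aligner. Each aligned molecule
carries joint information about (i) which tandem poly(A) site it used and
(ii) whether an upstream cassette exon (CE) was included. `utrlink`
estimates, per gene and replicate, the CE inclusion fraction conditional
on 3'UTR class — a quantity inaccessible to short reads.

The per-read generative picture the pipeline assumes:

- a molecule belongs to one 3'UTR class (its cleavage site), and its CE
  status is Bernoulli with a class-specific inclusion probability;
- oligo-dT priming leaves an untemplated poly(A) stretch that aligners
  soft-clip at the transcript 3' end;
- reverse transcription may terminate early, truncating the 5' end;
- oligo-dT can also anneal to genomically encoded A-rich stretches inside
  the transcript ("internal mispriming"), yielding reads whose 3' ends are
  artifacts: they carry an A-rich clip (templated, from the primer) and
  their downstream *genomic* window is A-rich, which is the detectable
  signature.

## Read parsing order

Parsing is deliberately asymmetric between classes. A read that extends
well into the most distal 3'UTR extension can only have come from the
distal-class molecule, so distal reads are classed first and exempt from
tail evidence. Every less-distal candidate must prove it is a genuine 3'
end: end within `end_slack` of a declared site, a poly(A) tail in the 3'
soft clip, and a non-A-rich downstream genomic window. This ordering means
the mispriming and truncation filters only ever remove putative
proximal-class reads — the direction in which internal priming biases the
class mixture. The mispriming test runs before the tail test because
misprimed reads typically *pass* the tail test (their clip is the dT
primer); reporting them as `internal_misprime` keeps the discard reasons
informative.

Reads ending between two sites but farther than `end_slack` from either
are discarded as `truncated_no_tail`; there is no evidence for which site
such a molecule used even when it carries a tail at a non-site position
(that is exactly the mispriming signature when the window is A-rich, and
an unannotated site otherwise — site refinement, below, is the tool for
the latter).

## Filter parameters

All thresholds live in `FilterParams` and the run config:

| parameter | default | meaning |
|---|---|---|
| `min_exon_cov_frac` | 0.8 | fraction of a flank/universal region a read must cover |
| `min_extension_overlap` | 50 nt | aligned bases inside an extension to claim the longer class |
| `tail_min_len` / `tail_min_A_frac` | 5 nt / 0.8 | shortest qualifying A-prefix of the 3' clip and its purity |
| `tail_scan_window` | 20 nt | clipped bases examined adjacent to the alignment end |
| `misprime_window` | 20 nt | genomic bases downstream of the inferred 3' end |
| `misprime_max_A` / `misprime_max_run` | 12 / 6 | A-count or A-run in that window that flags mispriming |
| `end_slack` | 50 nt | tolerated distance between read 3' end and a declared site |

These are conventional values for poly(A)-site curation (the 12-of-20 /
6-run internal-priming rule is the classical one used by poly(A)-site
atlases); the filters themselves, not the exact numbers, carry the method,
and all numbers are config-exposed.

## Gene models

Coordinates are 0-based half-open internally; GTF input is converted on
read. Exons are modeled on the coding side of the configured stop codon
only: terminal exons of tandem-UTR transcripts differ (and overlap) only
past the stop, so clipping there yields a clean, non-overlapping exon set
whose shared terminal stub is constitutive, while the 3'UTR itself is
carried by the universal/extension segment model. Constitutive status is
the intersection of (clipped) exon sets across annotated transcripts,
overridable per exon in the config because curated panels routinely
disagree with automated annotation. Poly(A) sites are declared in the
config (from annotation and/or coverage-drop refinement), never guessed
from transcript ends alone.

## Quantities

- **PSI** = included/(included+skipped) per (event, class, replicate),
  requiring ≥ 2 informative reads, otherwise undefined; undefined values
  propagate as missing into all statistics (no zero-imputation).
  AMBIGUOUS CE calls (partial exon coverage, exotic gap structure) are in
  neither numerator nor denominator. PSI_All is computed over the union of
  parsed classes, so it is a read-count-weighted mean of the per-class
  PSIs and always lies between them.
- **dPAU** = 100 × distal-class reads / classified reads. Discarded reads
  are not in the denominator; since truncation and mispriming removal act
  upstream of class assignment, the estimator is unbiased for the class
  mixture under the generative model above.
- **Poly(A)-site refinement**: a site is reported where the mean coverage
  of the downstream `window` (25 nt) is ≤ (1 − `drop_frac`) times the
  upstream window mean, snapped to the nearest candidate annotation site
  within the window; the distal end is the last covered base. The default
  `drop_frac` = 0.8 only reports drops of ≥ 80% (strong, unambiguous
  sites); to resolve a class mixture whose proximal fraction is f, the
  parameter must be ≤ f — the tests exercise `drop_frac` = 0.2, the
  sensitivity needed for 20% mixtures.
- **Gene-body coverage**: transcripts scaled to 100 bins, read presence
  summed per bin, 5'→3' in transcript orientation; oligo-dT libraries show
  the expected 3' ramp.

## Statistics

Within a sample, PSI_Short vs PSI_Long is paired by replicate (two-tailed
paired t, df = n−1). Between genotypes, each metric (dPAU, PSI_All,
PSI_Short, PSI_Long, linkage delta) is compared by unpaired two-tailed t
(Student pooled by default; Welch by flag — replicate pairing does not
exist across genotypes). Raw p-values are the primary output; BH
adjustment is available (`bh_adjust`) but opt-in, as is conventional for
panels of a few dozen targets. Zero-variance data yield a flagged
degenerate result with undefined p (never p = 0); identical data yield
t = 0, p = 1. t-tests are delegated to scipy and are cross-checked in the
tests against closed-form df = 1 and df = 2 t CDFs; Fisher's exact test is
cross-checked against full hypergeometric enumeration; BH against a
hand-rolled step-up implementation.

## Simulator

The simulator emulates: isoform mixtures (CE × class) with per-class
inclusion probabilities, untemplated tails (15–35 A) as soft clips,
5'-truncation (truncation point uniform between mid-upstream-flank and the
CE, guaranteeing a span-filter failure), internal mispriming at a planted
15-A tract ending 30 nt upstream of the proximal site (so the artifactual
3' end lies within `end_slack` of the site and is caught by the window
rule rather than by distance), and off-target background genes. Reads are
emitted directly as error-free alignments with exact CIGARs — no
sequencing-error model and no aligner in the loop — so recovery tests are
exact rather than statistical where the truth is deterministic.

Default conditions (the study conditions of the package): truth PSI
long/short = 0.95/0.05, 1000 reads per class (true dPAU 50), 15%
truncation, 5% mispriming, 10% background. Artifact draws are mutually
exclusive per read so each truth label maps to exactly one expected
discard reason.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: basecalling/alignment errors and clipped
junction wobble, unannotated poly(A) sites and exons, transcript-level
abundance differences between CE isoforms, mispriming at dispersed
(unplanted) A-rich positions, PCR duplicates, and capture-probe bias
between classes. On real data the filters are expected to trade some
sensitivity for the same specificity; thresholds may need loosening for
noisy basecalls.

## Problem sizes

Tests and the acceptance script run single-gene panels at 500–1000 reads
per class and 3 replicates per condition — enough for the binomial
recovery bounds (3 SE ≈ ±0.021 at n = 1000) while keeping the whole suite
in seconds. The pipeline itself streams SAM records and holds per-gene
coverage vectors only, so real panels (dozens of genes, 10⁵–10⁶ reads)
are well within a laptop's reach.

## Known limitations

- One gene per read: reads are assigned to the first overlapping target
  on the matching strand; overlapping target genes are not supported.
- The SKIPPED call requires a single clean gap spanning the CE; exotic
  multi-gap structures over the CE are AMBIGUOUS (conservative).
- dPAU from long reads inherits any class-differential capture or length
  bias of the library; the simulator does not model such bias.
- The prescreen consumes PAU/event tables by schema and does not
  re-implement the upstream quantifiers.
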