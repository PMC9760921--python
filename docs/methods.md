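# Methods

## Gene-centric coverage

The unit of analysis is the protein-coding gene, not the transcript: a
gene counts as covered when at least one of its annotated isoforms
passes the platform's detection cut-off.  The denominator of every
proportion is the gene catalog built from a GTF annotation, restricted
to biotype `protein_coding` (attribute `gene_type`, falling back to
`gene_biotype` for Ensembl-dialect files) on the 24 nuclear chromosomes;
mitochondrial and alt/random/scaffold contigs are excluded.  Gene
identity is the versionless Ensembl-style `gene_id` — symbols are not
unique and are carried only for reporting.  Transcript-level inputs
(Salmon `quant.sf`) are aggregated to genes by summing member-transcript
TPM, which leaves detection-at->0 equivalent to "any isoform detected".

Detection rules are written exactly as practitioners state them:
`FPKM > 0` and `TPM > 0` are strict (a gene at exactly the threshold is
not detected), `Ct <= 40` is inclusive.  qPCR genes past the limit are
kept in the tables with abundance 0 and their measured Ct, so the
catalog remains the denominator everywhere.

Two-platform coverage per chromosome uses inclusion–exclusion,
|A ∪ B| = |A| + |B| − |A ∩ B|, computed from explicit gene sets (the
identity is also verified against the direct union in tests).  The
k-set Venn decomposition classifies every gene of the union by its exact
membership vector; no probabilistic shortcuts.

## Formatting conventions

Reported proportions are truncated (floored) at the printed precision,
not rounded: 453/812 = 0.5578 prints as 0.55, and 224/275 = 81.45% as
81.4%.  Truncation operates on the shortest decimal representation of
the value, so ratios of integer counts format as their exact decimal
expansions would.  Integer percentages in prose are the one exception
and round half-up (63/275 = 22.9% → 23%).  Coverage tables always carry
the raw counts next to the formatted proportions, so formatting never
destroys information.

The summary row of a coverage table sums the count columns; its
proportions are the unweighted mean of the per-chromosome raw
proportions (each chromosome contributes equally, regardless of size),
then truncated.  Ratio-of-totals is deliberately not used there, as it
would be dominated by the large chromosomes.

## Similarity bands and variability

Tanimoto similarity T = |A∩B| / |A∪B| is banded as: T ≥ 0.70
"identical", 0.55 ≤ T < 0.70 "weaker", T < 0.55 "different".  The band
edges in circulation overlap at the margins; these half-open intervals
are the resolution consistent with the published verdicts (0.75 →
identical; 0.67 and 0.63 → weaker).  Two empty sets are defined as
identical (T = 1), a convention documented here because real data never
reaches it.

Inter-donor variability of a technology is
mean_d |set_d \ ∪_{d'≠d} set_{d'}| / |∪_d set_d| — donor-specific genes
over the technology-wide union.  A per-donor denominator was rejected
because the published totals it is quoted against are cross-donor
unions.

## Calibration

Relative sequencing abundances are calibrated against absolute qPCR
copies per cell by OLS on log10–log10 pairs, restricted to genes
detected by both platforms (abundance > 0, copies > 0, Ct ≤ 40).  Log
base 10 on both axes is the only transform under which one linear fit is
meaningful across the ~4-decade dynamic range.  R² = 1 − SS_res/SS_tot;
a model converts units only when R² > 0.5, otherwise conversion is
refused with the reason.  Degenerate inputs (zero variance in either
axis, fewer than 3 pairs) raise errors rather than returning
conventional values; SS_tot = 0 in particular is treated as degenerate,
not as R² = 1.

## The synthetic study generator

The generator emulates the statistical structure of a three-donor liver
profiling study so that every pipeline stage runs and is validated
without downloads.  Per gene g with true abundance C_g (copies per
cell) and transcript length L_g (kb):

- **Expression profile.** log10 C ~ N(0.7, 1.0) for the unimodal
  `liver` preset; the bimodal `hepg2` preset uses a two-component
  mixture (weights 0.4/0.6, means 0.5/2.5, σ 0.6) capturing the
  elevated, bimodal profile of actively proliferating cells.  Per-donor
  abundance is C_g times a lognormal factor with σ = 0.15 (log10).
- **Lengths.** Lognormal with median 2 kb (ln-σ 0.6); chrY genes draw
  from a short-length distribution (median 400 nt) to exercise the
  length-bias path.
- **Illumina.** reads ~ Poisson(10 · C · L); detected iff reads ≥ 1;
  FPKM = C × lognormal noise (σ = 0.1 log10) when detected, else 0.
- **ONT.** reads ~ Poisson(0.4 · C · L · e_g · s_g), where e_g is a
  per-gene capture efficiency, lognormal with σ = 2.0 (log10) and
  *shared across donors* — direct-RNA capture is strongly
  transcript-dependent, which both widens the detected/undetected split
  and keeps donor profiles correlated, as observed in multi-donor
  nanopore data — and s_g = 0.1 for transcripts shorter than 500 nt
  (short native-RNA fragments are poorly captured).  TPM is reads
  normalized to 10⁶.
- **qPCR.** Ct = 39.5 − log10(C)/log10(2) + N(0, 0.5), detected iff
  Ct ≤ 40; the reported copies-per-cell estimate is back-computed from
  Ct.  The slope is the perfect-efficiency dilution slope
  (≈3.32 cycles per decade).

Expected detection probability is non-decreasing in C on every platform
(tested on abundance tertiles).  The depth factors were fixed by desk
integration of the detection probabilities over the abundance
distribution, refined with a pilot run of the generator itself, to
reproduce the qualitative regime of the real study: pooled three-donor
coverage ordering Illumina (~0.99) > qPCR (~0.85) > ONT (~0.72),
per-donor ONT coverage in the low 0.6s, and donor variability
~0.5%/~1.9%/~3.9% (Illumina/qPCR/ONT), all below the 5% bound.  All
parameters live in `PlatformModel`/`SimulationConfig` and can be
overridden.

Randomness: one `numpy` Generator stream per purpose — truth, donor
jitter, capture efficiency, and one per (donor, platform) — all derived
from the master seed, so adding a platform or donor never perturbs the
draws of the others, and a seed fully determines the output.

**What the generator does not model:** read-level artifacts (no FASTQ,
no alignment or basecalling error), splicing and isoform switching,
GC/fragment biases, library-size variation between donors, and
correlated expression between genes.  Passing end-to-end tests
therefore demonstrates that the *analysis* behaves correctly under the
study's statistical structure — not that any particular biological
dataset will show the same numbers.

## Problem sizes in the tests

Unit tests run on hand-built fixtures of a few genes.  The end-to-end
study check uses the full 19,593-gene universe with 3 donors over 20
seeds (a few seconds of vectorized numpy); module-level simulator tests
use proportionally scaled universes (3–50% of the genome), the
package's standard knob for quick runs (`preset(..., size_factor=...)`).

## Known limitations

- The published calibration fits (R² = 0.4 and 0.29 at n = 223/171
  gene pairs) derive from raw archived sequencing data and are not
  recomputable from printed values; the calibration module is instead
  validated structurally (closed-form OLS oracle, parameter recovery,
  refusal below R² = 0.5).
- One cell of the published per-chromosome table (chrY ONT proportion,
  printed 0.03) is inconsistent with its own counts (12/40 = 0.30); the
  package reports 0.30 and makes no attempt to reproduce the printed
  cell.
- `max_transcript_length` uses the genomic span of the longest
  annotated isoform (exonic structure is out of scope); it feeds only
  the simulator's length model.
- Coverage tables support exactly two platforms in the tabular layout;
  richer combinations go through the Venn decomposition (≤ 3 sets).
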