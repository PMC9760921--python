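# genecov

Gene-centric transcriptome coverage across sequencing platforms.

## The problem

How much of the protein-coding genome does a transcriptomic experiment
actually see, and does combining platforms help?  `genecov` answers this
for the common three-platform design — short-read Illumina RNA-Seq
(abundance in FPKM), Oxford Nanopore direct RNA sequencing (TPM), and
targeted qPCR (absolute copies per cell with threshold cycle Ct) — the
design used to profile human liver tissue from multiple donors.  It is
aimed at transcriptomics groups who need to decide which platform (or
combination) achieves the most complete *gene-centric coverage*: the
fraction of a chromosome's protein-coding genes with at least one
detected transcript.

## What it computes

Given a gene catalog (from a GENCODE/Ensembl GTF) and per-(platform,
donor) quantification tables:

- **Detection sets** under explicit cut-offs — FPKM > 0, TPM > 0,
  Ct ≤ 40 (strict `>`, inclusive `≤`) — and cut-off sensitivity sweeps.
- **Per-chromosome coverage tables** with combined-platform coverage via
  inclusion–exclusion, |A ∪ B| = |A| + |B| − |A ∩ B|.  Reported
  proportions are *truncated* (floored) at the printed precision, the
  convention of the reference tables this layout mirrors.
- **Tanimoto similarity** between detection sets,
  T(a, b) = P_ab / (P_a + P_b − P_ab), with interpretation bands:
  T ≥ 0.70 effectively identical, 0.55 ≤ T < 0.70 much weaker,
  T < 0.55 considerably different; plus 2/3-set Venn decompositions.
- **Inter-donor variability**: the mean, over donors, of genes detected
  only in that donor divided by all genes the technology detects.
- **Calibration**: an ordinary-least-squares log–log fit converting
  FPKM/TPM to qPCR copies per cell, log10(copies) = a·log10(abundance) + b,
  usable for conversion only when R² > 0.5.
- **A synthetic study generator** (`genecov.simulate`) emulating the
  3-donor × 3-platform structure over the 19,593-gene human
  protein-coding universe, with unimodal (liver) or bimodal
  (proliferating cell line) expression profiles, shallow length-biased
  ONT detection, and a Ct-based qPCR detection limit.

## Worked example

```python
from genecov import (CANONICAL_RULES, detect, donor_variability,
                     format_percent, preset, simulate_study, tanimoto)

cfg = preset("liver", seed=17)          # 3 donors, 19,593 genes
catalog, truth, tables = simulate_study(cfg)
det = {(d, p): detect(tables[(d, p)], CANONICAL_RULES[p], catalog)
       for d in cfg.donors for p in ("illumina", "ont", "qpcr")}
pooled = {p: frozenset().union(*(det[(d, p)].genes for d in cfg.donors))
          for p in ("illumina", "ont", "qpcr")}
chr18 = catalog.genes_on("18")
for p in ("illumina", "qpcr", "ont"):
    n = len(pooled[p] & chr18)
    print(f"{p:9s} chr18 detected {n}/275 = {format_percent(n/275, 1)}%")
```

prints

```
illumina  chr18 detected 273/275 = 99.2%
qpcr      chr18 detected 231/275 = 84.0%
ont       chr18 detected 197/275 = 71.6%
```

— the characteristic ordering of the three technologies: near-complete
coverage from deep short-read sequencing, qPCR limited by its Ct ≤ 40
detection floor, and single-flow-cell nanopore sequencing far from
saturation.  Continuing with similarity and variability:

```
T(Illumina, qPCR) = 0.85 (identical); T(ONT, qPCR) = 0.72 (identical)
illumina  mean donor variability = 0.5%
qpcr      mean donor variability = 1.9%
ont       mean donor variability = 3.8%
```

Donor-to-donor variability stays below 5% on every platform, with the
shallow platform (ONT) the most variable — its borderline genes flip in
and out of detection between samples.

The same pipeline runs from the shell:

```bash
genecov simulate --preset liver --donors 3 --seed 17 --out study/
genecov coverage --catalog study/catalog.tsv \
    --quant illumina=study/illumina_donor1.tsv \
    --quant ont=study/ont_donor1.quant.sf --out table.tsv
genecov report --config run.yaml     # full bundle: coverage, Venn, similarity,
                                     # variability, calibration, sweep, manifest
```

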