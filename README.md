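# carnet

Analysis of chromatin-associated RNA (caRNA) interaction networks from
RNA–DNA proximity-ligation data, for researchers studying how RNA–chromatin
contacts reorganize under cellular stress — e.g. endothelial cells driven
toward dysfunction by high glucose and TNFα.

An iMARGI-style experiment yields read pairs whose read 1 comes from an RNA
and read 2 from the genomic DNA it was ligated to, delivered as BEDPE
(columns 1–3 = RNA end, 4–6 = DNA end). This package implements the
downstream computation over such pairs, together with the companion Hi-C
and single-cell RNA-seq summaries:

- **Super-enhancer (SE) annotation** — three-way SE–gene classification
  (intergenic / partial overlap / embedded) and boundary extension of
  embedded SEs to the span of their embedding genes, with collapse of
  coordinate-identical extended SEs.
- **Enrichment statistics** — for a feature class occupying genomic
  fraction *q* and a read-end proportion *p*, the odds ratio vs genome
  average, OR = (p/(1−p)) / (q/(1−q)), the fold of proportions p/q, and
  df = 1 chi-square tests (goodness-of-fit and 2×2 contingency, no
  continuity correction).
- **SE–SE interaction networks** — contacts between unordered SE pairs,
  normalized by each sample's total uniquely mapped pairs; a pair is
  *interacting* when its normalized count exceeds the 95th percentile of
  the baseline sample's nonzero normalized counts; hubs are SEs with degree
  ≥ the 95th-percentile degree; the degree distribution is summarized by a
  discrete maximum-likelihood power-law fit (Hurwitz-zeta likelihood,
  KS-minimizing x_min).
- **Hi-C structure summaries** — Measure of Concordance between TAD
  partitions, MoC(P, Q) = (Σ_{ij} |p_i ∩ q_j|² / (|p_i||q_j|) − 1) /
  (√(NM) − 1); distance-decay curves of mean contact frequency from 40 kb
  to 20 Mb; within-TAD read fractions.
- **Single-cell co-expression screen** — after cell QC (per-sample upper
  percentile on detected genes, mitochondrial cap, minimum gene count),
  the anchor-conditioned 2×2 odds ratio of partner detection between
  conditions, screened over all genes embedded in SEs that interact with
  the anchor's SE.
- **Synthetic data** — generators for every input (annotations, read
  pairs, UMI matrices, contact matrices) with controllable
  interchromosomal fraction, SE RNA-enrichment factor, designated hub
  masses, target co-expression odds ratios, and decay exponent.

## Worked example

```python
from carnet.annotations import GENOME_LENGTH_HG38
from carnet.enrichment import proportion_odds_ratio, fold_of_proportions

# 15.1% of RNA ends fall in boundary-extended SEs covering 94,493,925 bp
q = 94_493_925 / GENOME_LENGTH_HG38
r = proportion_odds_ratio(p=0.151, q=q)
print(f"genome fraction {100*q:.1f}%  OR {r.odds_ratio:.2f}  fold {r.fold:.2f}")
```

prints

```
genome fraction 3.1%  OR 5.63  fold 4.94
```

i.e. extended SEs occupy 3.1% of the genome, RNA ends are 5.6 times more
likely (in odds) to originate there than the genome average, a 4.9-fold
excess of the read proportion over the length fraction.

The numbered drivers under `analysis/` run the full story on synthetic
data — `01` simulates a three-time-point study, `02` recomputes the
published enrichment figures, `03` builds the SE networks (on the simulated
time course the interchromosomal edge count rises 9 → 41 → 127 while hub
sets grow 1 → 2 → 5 with every earlier hub persisting), `04` runs the
co-expression screen (planted odds ratios 40/8/2/1 are estimated at
42.1/7.8/2.0/0.98 and ranked in order), `05` computes the Hi-C summaries
(noiseless decay slope −1.19 on a TAD-boosted β = 1 matrix; a 200-kb
boundary jitter keeps MoC at 0.92, above the 0.75 concordance cutoff).
Each writes its tables under `results/`.

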