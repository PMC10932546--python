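# pcdhgamma

Analysis toolkit for **combinatorial γ-protocadherin (Pcdhg) isoform
expression and its effect on synaptic connectivity** in neocortical
neurons.

The mouse *Pcdhg* cluster encodes 19 "variable" isoforms (Pcdhga1–a12,
Pcdhgb1–b8 minus b3) and 3 near-ubiquitously expressed "C-type" isoforms
(C3, C4, C5). Each neuron expresses a sparse subset of the variable
isoforms — a combinatorial surface barcode — and homophilic matching of
these barcodes between neurons suppresses synapse formation: the more
similar two neurons' isoform combinations, the lower their probability of
being synaptically connected. This package implements the full
computational chain behind that result, with synthetic-data generators so
every stage is testable without the original sequencing or recording data.

## What it computes

- **`pcdhgamma.matrix`** — cell × isoform UMI count matrices from
  (barcode, UMI, isoform) read records; quality filtering (cell kept iff
  total Pcdhg UMI > 10) and binarization (isoform expressed iff its UMI
  count > 1); per-isoform expression frequencies. I/O: Matrix Market with
  barcode/isoform sidecars, dense TSV.
- **`pcdhgamma.similarity`** — the similarity level of two cells'
  variable-isoform sets, the Jaccard index
  S(A, B) = |A ∩ B| / |A ∪ B| ∈ [0, 1] (C-types excluded); plain and
  normalized Euclidean distance in the 19-dimensional UMI space (the
  normalized distance lies in [0, √2]); binned pairwise similarity
  distributions.
- **`pcdhgamma.cooccurrence`** — a test of independent isoform expression:
  the variance of the per-cell number of expressed isoform types is
  compared with the independence expectation
  σ²<sub>expected</sub> = Σᵢ pᵢ(1 − pᵢ) by a Z-test whose denominator is
  the SD of variances over 100 column-shuffled matrices.
- **`pcdhgamma.uptake`** — the plasmid co-electroporation uptake model:
  with a fraction q of the mixture tagged green and n plasmids taken up,
  R<sub>GFP-only</sub> = qⁿ, R<sub>RFP-only</sub> = (1 − q)ⁿ,
  R<sub>co</sub> = 1 − qⁿ − (1 − q)ⁿ; n is modeled as
  Normal(μ, σ²) truncated at 1, color fractions are cell-averaged, and
  (μ, σ) is fit to observed fractions by integer grid search. At the
  fitted (18, 6), 10,000 simulated cells express on average 5.6 of the 6
  electroporated isoform species.
- **`pcdhgamma.epsc`** — evoked-EPSC calling from multi-electrode
  patch-clamp sweeps (voltage clamp at −70 mV, 20 kHz): an inward
  deflection within 3 ms of the stimulus exceeding 3× the 1-s-baseline SD
  with trial-to-trial onset jitter < 0.2 ms over ≥ 10 trials counts as a
  monosynaptic connection; session-level directed adjacency matrices.
- **`pcdhgamma.connectivity`** — connection probabilities
  (connected/tested, per unordered pair or per direction, stratified by
  distance/axis/age), Pearson chi-square comparisons with
  Benjamini–Hochberg FDR across declared families, bootstrap uncertainty
  (default 100 resamples), and the linear similarity-vs-connectivity fit
  with a bootstrap 95% band.
- **`pcdhgamma.synth`** — generators for all three data modalities,
  including a shared-propensity mechanism for tunable isoform
  co-occurrence and a difference-of-exponentials EPSC kernel.

A `pcdhg` command-line tool exposes each stage
(`matrix`, `similarity`, `cooccur`, `uptake`, `epsc`, `connectivity`,
`synth`, `pipeline`); every JSON report embeds the tool version,
parameters, and seed.

## Worked example

```python
import numpy as np
from pcdhgamma import *
from pcdhgamma.synth import ExpressionGenParams, gen_expression_matrix

# a synthetic cohort with the structure of the real data:
# near-ubiquitous C-types, sparse variable isoforms, subtle co-occurrence
m = gen_expression_matrix(ExpressionGenParams(n_cells=2000, seed=7))
b = filter_binarize(m)                      # >10 total UMIs, >1 per isoform
print(f"retained {b.n_cells}/{m.n_cells} cells")

res, obs, ens = run_cooccurrence(b, seed=7)
print(f"observed variance {res.observed_variance:.3f}, "
      f"expected {res.expected_variance:.3f}, z = {res.z:.1f}, "
      f"co-occurring: {res.co_occurring}")

dist = pairwise_similarity_distribution(b)
print(f"median pairwise similarity {np.median(dist.similarities):.3f} "
      f"over {dist.n_pairs} pairs")

res2 = simulate_uptake(six_plasmid_design(), UptakeParams(18, 6, 10_000), seed=7)
print(f"mean isoform types per transfected cell: {res2.mean_types:.2f}")
```

prints

```
retained 1977/2000 cells
observed variance 6.055, expected 3.531, z = 21.6, co-occurring: True
median pairwise similarity 0.143 over 1953086 pairs
mean isoform types per transfected cell: 5.59
```

The co-occurrence Z-test flags the generator's planted coupling (observed
variance of per-cell isoform counts above the independence expectation
Σpᵢ(1 − pᵢ)); the low median Jaccard similarity reflects the sparse,
diverse variable-isoform combinations; and the uptake simulation
reproduces the ~5.6 expressed species among 6 co-electroporated plasmids.

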