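# trflpsim

Bias testing for quantitative TRFLP analysis of arbuscular mycorrhizal (AM)
fungal communities.

Terminal restriction fragment length polymorphism (TRFLP) fingerprints a
community by PCR-amplifying a marker (here the ~550 bp AM1/NS31 partial SSU
rDNA fragment) with 5′ dye-labelled primers (HEX on the AM1 end, FAM on the
NS31 end), digesting the amplicons with restriction enzymes (AluI, HinfI)
and sizing the labelled terminal fragments (TRFs) on a capillary sequencer.
Whether the resulting peak areas can be read *quantitatively* — as relative
genotype abundances — depends on the absence of bias in PCR, digestion and
electrophoresis. `trflpsim` implements the full in silico side of that
question:

- **Fragment prediction** — IUPAC recognition-site search on labelled
  amplicons, complete-digest TRF lengths, and enumeration of *pseudo-TRFs*:
  the longer fragments produced when one or more internal sites go uncut,
  which inflate apparent richness.
- **Community templates** — equal-abundance, MacArthur broken-stick
  (p_i = (1/n)·Σ_{k=i..n} 1/k) and near-equal two-genotype designs, each
  inducing a predicted TRF relative-abundance profile.
- **Peak-table processing** — the standard filtering chain for GeneMapper
  style exports: peaks >100 fluorescence units and >100 bp in the analysed
  channel (HEX/AluI, FAM/HinfI), 2-bp binning, peak *area* as abundance,
  exclusion of TRFs averaging ≤5% where present, pooling of split peaks,
  and matching of observed to predicted TRFs under electrophoretic "TRF
  drift" (labelled fragments under-read by up to ~14 bp).
- **Bias simulation** — synthetic amplicon genotypes meeting the study
  design criteria, and simulated electropherograms with calibrated linear
  drift, 2–3-way peak splitting, under-digestion pseudo-TRFs, lognormal
  area noise and a detection floor.
- **Comparison model** — `TRFLPBiasModel.fit()` runs covariance PCA of
  predicted and observed profile sets, Mantel permutation tests (Pearson r
  of distance-matrix triangles; p from joint row/column permutations) on
  Euclidean-PC and Bray-Curtis (1 − 2Σmin(a,b)/(Σa+Σb)) distances, and OLS
  regressions of observed on predicted Margalef ((S−1)/ln N) and
  Gini-Simpson (1 − Σp²) diversity.

## Worked example

Simulate the full study design — six synthetic genotypes, nine templates ×
3 replicate mixes × 3 technical fingerprints per enzyme — under the
calibrated bias regime, then compare observed against predicted profiles:

```python
from trflpsim import StudyConfig, generate_study_dataset, TRFLPBiasModel

dataset = generate_study_dataset(StudyConfig(seed=1))
results = TRFLPBiasModel.from_study(dataset).fit(n_perm=999, seed=1)
print(results.summary())
```

```
TRFLP predicted-vs-observed comparison
======================================================
samples: 81   groups (template replicates): 27
PCA variance explained (PC1+PC2): predicted 92%, observed 90%

Mantel tests (predicted vs observed distances)
------------------------------------------------------
distance                     r           p    n_perm
Euclidean (PC scores)    0.996       0.001       999
Bray-Curtis              0.997       0.001       999

Diversity recovery (observed ~ predicted, OLS)
------------------------------------------------------
index          slope      R2         F        df           p
Margalef       0.962   0.994  4.51e+03   (1, 25)   9.159e-30
Simpson        0.987   0.999  2.32e+04   (1, 25)   1.272e-38
```

Despite drift, peak splitting, under-digestion and area noise, the
between-template distance structure (Mantel r ≈ 1, p = 1/(n_perm+1)) and
both diversity indices (R² ≈ 0.99 on 27 template replicates, F tested on
1 and 25 df) are recovered almost perfectly — the signature of a protocol
that is quantitative at the community level. With all biases switched off
(`BiasConfig.zero()`) every statistic equals 1 exactly, a built-in identity
check of the processing chain.

The same stages are available as a CLI:

```bash
trflpsim simulate --out run1 --seed 1
trflpsim analyse --dataset run1 --out run1/report.json --seed 1
trflpsim report --report run1/report.json
trflpsim digest --fasta my_amplicons.fasta --out trf_table.tsv
```

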