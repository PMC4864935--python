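# histobof

Extended bag-of-features analysis of H&E histopathology images, with joint
mining of the resulting image features against gene expression, clinical
covariates and relapse-free survival.

## The problem

Whole-slide histopathology images carry prognostic information — tissue
texture, architecture, the spatial arrangement of tumour and stroma — that
genomic assays cannot see, but their size (10^10 pixels) and lack of an
obvious feature representation keep them out of standard biomarker-discovery
pipelines. `histobof` reduces each slide to a compact, data-driven feature
vector that can sit in the same table as qRT-PCR expression values and
survival times, so ordinary statistical screening (correlation tests, CCA,
Cox regression, log-rank tests) applies unchanged.

## The method

1. **Preprocessing.** RGB scans are brought to a 2.5×-equivalent working
   resolution (4 Gaussian-pyramid levels), tissue is located by adaptive
   thresholding of the green channel followed by morphological clean-up, and
   the haematoxylin channel (H-image) is separated by Ruifrok–Johnston
   colour deconvolution in optical-density space, then contrast-adjusted
   with CLAHE.

2. **Local descriptors.** Each 32×32 neighbourhood is convolved with a bank
   of 24 complex Gabor wavelets

   G(x, y; ν, θ, σ) = exp(−(x²+y²)/(2σ²)) · exp(2πνj(x cos θ + y sin θ)),

   σ ∈ {1, 2√2}, θ ∈ {0, π/4, π/2, 3π/4}, ν ∈ {3/4, 3/8, 3/16}; the mean and
   SD of each response magnitude give a 48-value descriptor.

3. **Codebook.** k-means clustering of the descriptors yields K codeblocks
   C.01…C.K. The size K is chosen to maximize

   Ψ(K) = log(n_c(n_c−1)/2) − log J(K) − log √D(K) − 0.75 log K,

   where J(K) is the total Jaccard overlap of codeblock-usage sets between
   images of different reference tissue categories (n_c of them) and D(K)
   the within-cluster total squared distance: small cross-category overlap,
   tight clusters, sparse codebooks.

4. **Recoding (6K features).** Each image becomes its codeblock histogram
   (K values) plus, per codeblock, five statistics of the 4-connected
   regions assigned to it — median area, maximum area, max/total area
   ratio, skewness of areas, mean compactness (perimeter²/area) — which
   distinguish spatial arrangements that share identical histograms.

5. **Joint mining.** Feature–gene Pearson screening (p < 0.05 and
   |ρ| ≥ 0.5, no multiplicity adjustment), CCA with Wilks' test,
   dichotomized T-stage/grade t-tests, Cox proportional-hazards models with
   hazard ratios per interquartile range, likelihood-ratio tests for
   combined image+genomic models, and Kaplan–Meier / log-rank analysis of
   median-split scores.

Because real cohort data of this kind are not public, the package ships a
first-class synthetic module: oriented-grating texture images with known
region labels, and joint feature/expression/survival tables with planted
correlations and hazard ratios.

## Worked example

```python
import numpy as np
import histobof as hb
from histobof.descriptors import describe_patches, sample_patches

bank = hb.build_bank()                      # the 24-filter Gabor bank
corpus = hb.gen_reference_corpus(n_per_class=3, n_classes=3,
                                 size=(96, 96), seed=5)
descs = [describe_patches(sample_patches(him, n=80, w=32, seed=7)[0], bank)
         for him, _ in corpus]
K, curve, books = hb.select_codebook_size(np.vstack(descs), corpus,
                                          [2, 3, 6, 12], seed=9)
print("selected K:", K)
print(curve.to_frame().round(4))

rep = hb.recode_image(corpus[0][0], books[K], w=32, bank=bank, image_id="im0")
print("representation length:", rep.values.size)

spec = hb.PlantedJointSpec(n=65, seed=11, feature_gene_corr=[(0, 0, 0.6)],
                           hazard_ratios={"freq_C.01": 1.7}, censoring=0.3)
ds = hb.gen_joint_dataset(spec)
tab = hb.correlate_features_genes(ds)
print("pairs kept by the screen:", int(tab.kept.sum()))
res = hb.cox_univariate(ds, "freq_C.01")
print(f"HR per IQR = {res.hazard_ratios.iloc[0]:.2f} "
      f"(95% CI {res.conf_int.iloc[0,0]:.2f}-{res.conf_int.iloc[0,1]:.2f}), "
      f"LRT p = {res.p_value:.4f}")
```

Output:

```
selected K: 6
    K    J          D      psi
0   2  4.5  2469.5482  -4.8312
1   3  0.0    96.6243  25.6203
2   6  0.0    10.6133  26.2048
3  12  0.0     8.9513  25.7701
representation length: 36
pairs kept by the screen: 1
HR per IQR = 1.54 (95% CI 1.06-2.22), LRT p = 0.0209
```

At K = 2 the three texture categories must share codeblocks (J = 4.5); from
K = 3 on the categories use disjoint codeblock sets (J = 0) and Ψ peaks at
K = 6, giving a 6·6 = 36-value representation per image. On the joint
tables, the screen recovers exactly the planted feature–gene pair, and the
Cox fit estimates a per-IQR hazard ratio of 1.54 for a planted 1.7 at
n = 65 (the true value lies inside the 95 % CI).

A `histobof` command-line tool exposes the same stages
(`preprocess`, `descriptors`, `codebook`, `recode`, `mine`, `simulate`);
see `histobof --help`.

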