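# cortarch

Quantitative cortical architecture analysis in Python: observer-independent
detection of cytoarchitectonic area borders, receptor-autoradiography
densitometry and fingerprints, mixed-model statistics on receptor densities,
fingerprint clustering/PCA, and seed-based functional connectivity.

The package is aimed at neuroanatomists and methods developers who work with
architectonic parcellations of primate cortex. It re-implements, as a tested
and reusable pipeline, the chain of analyses used to delineate and
characterize cortical areas of the macaque frontal lobe — and it ships a
synthetic-data module that generates every input with planted ground truth,
so the whole chain is exercisable and testable without any imaging data.

## The methods

**Border detection.** The grey level index (GLI) measures the volume fraction
of cell bodies in fixed-size square fields of a binarized histological
section. Depth profiles of the GLI are sampled along traverses running
perpendicular to the cortical surface between an outer (layer I/II) and an
inner (layer VI/white matter) contour, and each profile is reduced to a
10-feature vector: the five moments (mean, centroid, SD, skewness, kurtosis)
of the profile treated as a frequency distribution over relative depth, plus
the same five moments of its absolute first derivative. A sliding window
groups profiles into adjacent blocks of size *b* and computes the
Mahalanobis distance between block means,

    MD² = (m̄_L − m̄_R)ᵀ S⁻¹_pooled (m̄_L − m̄_R),

for every block position and every *b* from 10 to 24. Local MD maxima are
tested with Hotelling's T² (exact F transformation) under Bonferroni
correction over block positions; maxima that are significant, stable across
block sizes, and recur in at least three consecutive sections are accepted
as area borders.

**Densitometry.** Autoradiograph grey values are linearized through a
monotone calibration curve fitted to co-exposed tritium standards, and the
radioactivity concentration *R* is converted to a binding-site density
(fmol/mg protein)

    C_b = R / (E·B·W_b·S_a) · (K_D + L) / L,

with counter efficiency *E*, decay factor *B*, standard protein weight
*W_b*, specific activity *S_a*, dissociation constant *K_D* and free ligand
concentration *L*. Mean densities over all cortical layers per area, for 14
receptor types in a fixed order, form each area's *receptor fingerprint*.
The published 33-area × 14-receptor density table and the per-receptor
incubation concentrations ship as packaged fixtures.

**Statistics.** Densities in long format (area × receptor × hemisphere) are
analysed in three levels: an omnibus test of the area × receptor interaction
in the model `D = α₀ + α₁A + α₂R + α₃AR + β₁H` with hemisphere as a random
intercept; per-receptor simple-effect tests across areas with
Benjamini–Hochberg FDR over receptors; and all C(n,2) pairwise area
contrasts per receptor, FDR-corrected within receptor (528 pairs for 33
areas).

**Multivariate + connectivity.** z-scored fingerprints are compared by
Euclidean distance, clustered with Ward linkage (validated by the cophenetic
correlation coefficient and a permutation-calibrated k-means cluster-count
selection) and projected by PCA. For functional connectivity, per-vertex
BOLD time courses are demeaned per subject and concatenated; each area's
representative time course is the first principal component of its vertex
courses, and seed maps are Pearson correlations Fisher-transformed with
z = atanh(r).

## Worked example

```python
import numpy as np
from cortarch import io, quant, cluster, gli, borders, synthetic

# packaged density table: per-receptor extrema and fingerprint space
means, sds = io.load_density_fixture()            # 33 areas x 14 receptors
area, vmax, amin, vmin = quant.table_extrema(means, "GABAB")
print(f"GABA_B: max {vmax:.0f} fmol/mg in {area}, min {vmin:.0f} in {amin}")

z = quant.zscore_table(means)
print({k: round(v, 3) for k, v in cluster.linkage_comparison(z).items()})
_, _, frac = cluster.pca(z)
print(f"PC1 {frac[0]:.1%}, PC2 {frac[1]:.1%}")

# synthetic ribbon with a planted border at profile 100, then detection
base = np.full(32, 30.0)
spec = synthetic.RibbonSpec(n_profiles=200, border_positions=(100,),
                            laminar_means=(base, base + 7.5),
                            noise_sd=5.0, seed=1)
image, contours, truth = synthetic.make_ribbon(spec)
traverses = gli.build_traverses(contours, spec.n_profiles)
feats = gli.featurize_ribbon(
    [gli.sample_profile(image, t, 101, index=i) for i, t in enumerate(traverses)])
for c in borders.detect_borders(feats):
    print(f"border at profile {c.position}, "
          f"supported by {len(c.block_sizes_supporting)} block sizes, "
          f"min corrected p = {c.min_corrected_p:.2e}")
```

prints

```
GABA_B: max 2644 fmol/mg in 11l, min 1703 in 8Av
{'ward': 0.601, 'single': 0.63, 'complete': 0.653, 'average': 0.765}
PC1 45.2%, PC2 15.7%
border at profile 100, supported by 15 block sizes, min corrected p = 2.14e-27
```

The GABA_B receptor has the highest absolute density of all 462 table cells
(2644 fmol/mg protein in area 11l); the cophenetic coefficients quantify how
faithfully each linkage method's dendrogram represents the fingerprint
distances; and the border detector recovers the planted border exactly, with
support from every block size between 10 and 24.

A command-line interface mirrors the library
(`cortarch simulate|profiles|borders|quantify|stats|cluster|connectivity|report`);
`cortarch report --seed 0 --out run/` executes all seven analytic stages on
synthetic data and writes a machine-readable run manifest.

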