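# safconn

Quantifying how diffusion-MRI spatial resolution affects the reconstruction
of **short-range association fibers** (SAFs, "U-fibers") through structural
connectomics.

SAFs connect adjacent gyri within the thin superficial white-matter layer
just beneath the cortex, which makes them the first casualty of coarse
voxels: partial-volume mixing with gray matter and with radial long-range
fibers suppresses their reconstruction in tractography. `safconn`
implements the quantitative machinery needed to measure that effect — and
to test analysis code for it without any MRI acquisition, using synthetic
phantoms with analytically known ground truth.

## The metric

Given a region-by-region connectivity matrix `W` (streamline counts or
SIFT-weight sums, association fibers only: same-hemisphere pairs, `i ≠ j`)
and a binary "borders-on" adjacency matrix `A` over the cortical
parcellation, the **Short-range Connectivity Fraction** is

```
GSCF   = Σ_{i,j : A(i,j)=1} w_ij / Σ_{i,j} w_ij          (global)
RSCF_k = Σ_{j : A(k,j)=1} w_kj / Σ_j w_kj                (per region k)
```

Strength between bordering regions is attributed to SAFs; everything else
to long-range association fibers. Because both are ratios, they are
invariant to global streamline-count inflation (e.g. from up-sampling-
induced smoothing), so *within-subject* changes across imaging conditions
can be read as reconstruction bias. Paired per-subject comparisons use a
Shapiro–Wilk normality gate (two-sided paired *t* if normal, Wilcoxon
signed-rank otherwise) with Benjamini–Hochberg FDR correction per family.

## What is in the box

| module | contents |
|---|---|
| `safconn.synthetic` | ribbon parcellations with known chain adjacency, U-fiber/long-fiber tractograms with known endpoints, paired multi-resolution connectome ensembles with known attenuation, band-limited phantoms, noisy b=0 series |
| `safconn.resolution` | k-space truncation with Tukey apodization, spline re-up-sampling, temporal SNR, masked means |
| `safconn.adjacency` | borders-on matrix from labeled volumes (6-connectivity), validation |
| `safconn.connectome` | endpoint assignment, connectivity matrix construction, streamline lengths, TCK + weight-file I/O |
| `safconn.scf` | GSCF/RSCF, SAF-definition variants, relative differences, group atlas |
| `safconn.stats` | gated paired tests, BH FDR, per-region comparison families, Top-10 reduction frequency tables |
| `safconn.pipeline` / `safconn.cli` | reproducible end-to-end runs (`safconn run`), config, provenance manifest |

## Worked example

```python
import pandas as pd, numpy as np
import safconn as sc

# a parcellation with known adjacency, and a tractogram with known truth:
parc, adj = sc.make_ribbon_parcellation(n_regions_per_hemisphere=5)
tract, labels = sc.make_tractogram(
    parc, adj,
    short_pair_counts={(1, 2): 60},   # 60 U-fibers between adjacent wedges
    long_pair_counts={(1, 3): 40},    # 40 long fibers between non-adjacent wedges
    seed=11,
)
cm = sc.connectivity_from_tractogram(tract, parc)
print(cm.w.loc[1, 2], cm.w.loc[1, 3])   # 60.0 40.0
print(sc.gscf(cm, adj))                 # 0.6
```

60 of the 100 streamlines connect bordering regions, so the global
short-range connectivity fraction is exactly 0.6. A paired cohort with a
known short-range attenuation factor is one call away:

```python
spec = sc.CohortSpec(n_subjects=20, attenuation={"hi": 1.0, "lo": 0.8}, seed=3)
ensemble, truth = sc.make_connectome_ensemble(spec)
table = pd.DataFrame({r: [sc.gscf(ensemble[(s, r)], truth.true_adjacency)
                          for s in range(20)] for r in ("hi", "lo")})
comp, = sc.compare_gscf(table, ["hi", "lo"])
print(comp.test_used, round(comp.mean_relative_difference_pct, 1), comp.significant)
# paired_t -9.4 True
```

The simulated "low-resolution" condition shows a ≈ −9.4% GSCF change
against the analytic expectation of −9.7% for a 0.8 attenuation of
short-range counts on this geometry.

Or run the whole thing from a shell:

```sh
safconn run --seed 5 --out results/run5
```

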