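# pettex

Texture indices for 3D FDG-PET volumes of interest, under the two gray-level
discretizations that radiomics pipelines actually disagree about — plus the
synthetic phantom and patient-cohort experiments that show why the choice
matters.

## The problem

Texture indices (TI) summarize the spatial arrangement of uptake inside a
tumor VOI and are widely used as heterogeneity biomarkers in FDG-PET.
Before any texture matrix is built, the standardized uptake values (SUV)
inside the VOI must be discretized to a small number of gray levels, and
there are two common conventions:

* **Relative resampling (RR)** — stretch each VOI's own range to D bins:

      level(x) = round( D · (I(x) − SUVmin) / (SUVmax − SUVmin) ) + 1

* **Absolute resampling (AR)** — fixed SUV bounds shared by every VOI
  (default 0–20 SUV, D = 64, i.e. 0.3125 SUV per bin; presets AR15/AR20/AR25):

      level(x) = round( D · clip(I(x), low, high) / (high − low) ) + 1

RR is invariant under any increasing affine map of the intensities, so
RR-based TI discard the absolute SUV scale — and on texture-free data they
mostly track the VOI *volume*.  AR preserves the SUV scale, so AR-based TI
inherit the heterogeneity information already present in each tumor's SUV
range, at the price of depending on the bound choice.

From the discretized levels the package builds the co-occurrence matrix
(13 sign-free directions, distance 1, symmetric), the gray-level run-length
matrix (same 13 directions) and the gray-level zone matrix (26-connected
zones in 3D), and computes homogeneity, entropy and contrast (CM), SRE, LRE
and RLNU (GRLM), LGZE and HGZE (GZLM), plus SUVmax and metabolic volume.

## Worked example

Profile the texture indices against VOI volume in a simulated uniform
cylinder phantom (no biological texture, only spatially correlated
reconstruction noise), with spheres of 3–17 voxels diameter at 5 positions:

```python
from pettex import PhantomSpec, run_phantom_experiment

result = run_phantom_experiment(PhantomSpec())
print(result.summary[result.summary.method == "rr"]
      [["diameter", "voxel_count_mean", "entropy_mean", "rlnu_mean"]])
```

    diameter  voxel_count_mean  entropy_mean  rlnu_mean
           3               7.0         1.978      6.918
           5              33.0         4.970     31.840
           7             123.0         7.177    116.975
           9             257.0         8.312    241.792
          11             515.0         9.141    479.462
          13             925.0         9.598    845.706
          15            1419.0         9.763   1284.669
          17            2109.0         9.885   1897.814

RR entropy rises steeply and then flattens — on a *uniform* phantom it is a
function of VOI size, not of any real texture — while RLNU grows linearly
with voxel count and never flattens (`result.correlations` reports its
Spearman r = 1.0 against voxel count).  The same experiment under AR20 gives
much weaker volume correlations for most indices.

The cohort twin runs the full clinical pipeline on synthetic lung-cancer
patients (adaptive-threshold tumor segmentation, relocation of the tumor
geometry into the liver as a healthy reference, TI extraction under RR and
AR15/AR20/AR25, Wilcoxon comparisons shaped like the study tables):

```python
from pettex import CohortSpec, run_cohort_experiment

cohort = run_cohort_experiment(CohortSpec())
print(cohort.table2_like)   # tumor vs liver p-values per method
print(cohort.table4_like)   # adenocarcinoma vs squamous p-values
print(cohort.sign_table)    # which group has the higher median
```

With the default generator, every AR20 texture index separates tumor from
liver at p < 0.01 (paired Wilcoxon, n = 41), while RR entropy does not
(p ≈ 0.10): the liver's min–max-stretched noise looks just like a tumor's
min–max-stretched uptake pattern, and only the absolute scale tells them
apart.

A `pettex` command-line tool wraps the same functionality
(`pettex sim phantom`, `pettex sim cohort`, `pettex voi sphere|segment|relocate`,
`pettex extract`, `pettex study phantom|cohort`); `pettex extract` writes one
CSV row per VOI with the full index vector and its provenance.

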