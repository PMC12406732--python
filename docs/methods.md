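# Methods

## Scope and model

`immunoscape` reproduces, as a tested pipeline over single-cell tables, a
spatial analysis of NOS2/COX2-driven immune suppression in ER– breast
tumors: cells segmented from multiplex-immunofluorescence images are gated
into a phenotype lexicon, the tissue is partitioned into tumor nests (edge +
core), satellites, stroma and lymphoid aggregates, each nest's immune
context is classified into a three-type immune-desert taxonomy, and
spatial-neighborhood and cohort-survival statistics are computed.  Because
the imaging cohort itself is not public, the pipeline is driven by a
synthetic-landscape generator that plants the same structures with known
ground truth; every claim the test suite makes is therefore a claim about
recovery of planted structure, not about patient data.

## Synthetic landscapes

A landscape is a marked point pattern on a rectangular field (default
1.6 × 1.6 mm, coordinates in µm, image convention with y increasing
downward):

* **Stroma** — homogeneous Poisson process (default 1,500 cells/mm²) with a
  fixed phenotype composition (15% CD3⁺ lineages: 4% T_Eff, 2% T_Ex,
  1% CD8 T_Reg, 6% CD4 T, 2% CD4 T_Reg; 8% macrophages; remainder
  unclassified).  Densities and composition are in the range reported for
  inflamed breast-tumor stroma.
* **Tumor nests** — vertex-jittered regular polygons rescaled to an exact
  target area (default 0.15 mm²), filled uniformly at 4,000 cells/mm².
* **Lymphoid aggregates** — isotropic Gaussian clusters (σ = radius/2)
  truncated at the radius (default 80 cells, 60 µm), with a T-cell-dominated
  composition and elevated CD8 T_Regs.
* **Immune contexts per nest** — type I: NOS2⁺ edge band (50 µm deep,
  positive fraction 0.30), high-COX2 core (0.50), stroma-restricted T cells,
  proximal aggregate; type II: same minus the NOS2 edge; type III: low
  sporadic COX2 (0.05) and T-cell depletion (98%) within 500 µm of the
  nest; infiltrated: CD8 T cells planted inside the nest with density
  ∝ exp(−d/λ) of depth d, λ = 100 µm, totalling 0.25 per tumor cell.

Marker intensities follow a two-component Gaussian convention (negative
mean 1.0, positive mean 5.0, SD 0.5); intensity scales are conventions, not
estimates — the source imaging study reports no per-marker intensity
distributions.  NOS2⁺ tumor cells draw from grade-specific means
(weak 4, medium 6, strong 8) so that grade cutpoints are exercised
nontrivially.  All randomness flows from one `numpy` generator per
landscape; per-sample seeds in cohorts derive from the master seed via
`SeedSequence`, so identical configuration + seed reproduces every output
byte-for-byte.

What the generator does **not** emulate: intensity batch effects and
spillover between channels, cell-segmentation errors, necrosis, vasculature,
irregular (non-convex at large scale) nest topologies, and spatial
correlation between marker noise and position.  Passing recovery tests
therefore demonstrates correctness of the measurement machinery under the
stated point-process model, not robustness to real staining artifacts.

## Phenotype gating

Positivity is `intensity ≥ threshold` (boundary inclusive); default
thresholds sit at the midpoint of the synthetic negative/positive means
(3.0; 2.5 for NOS2 whose weakest positive component is 4.0).  Real-data use
requires user-supplied thresholds — no gates are published for the source
cohort.  Lineages are assigned by a fixed-precedence decision list
(tumor > macrophage > CD8 T_Reg > T_Ex > T_Eff > CD4 T_Reg > CD4 T > Other);
CK-SOX10⁺CD3⁺ contradictions are resolved by precedence and counted.  NOS2
grades default to per-sample tertiles of NOS2⁺ tumor intensity; "NOS2s"
denotes the strong stratum only (a switch pools medium+strong, since the
published notation does not state which stratum the summary metric pools).
At the default noise (SD 0.5) the analytic per-marker gating error is
2·Φ(−3) ≈ 0.3% (NOS2 weak vs its 2.5 threshold, the worst margin), so the
suite's ≥99% gating-accuracy bound is conservative.

## Region segmentation

Tumor cells are grouped by single linkage at 30 µm (~2 cell diameters);
each group is hulled by a concave hull computed as a morphological closing
(union of disks, eroded back) at 1.5× the link distance, dilated by half a
mean cell diameter (10 µm default) so the boundary clears the outermost
cell bodies.  The closing radius of 1.5× guarantees every single-linkage
gap is bridged with margin while limiting the area lost to convex-corner
rounding; interior holes below 0.02 mm² are filled as point-sampling
artifacts.  On planted nests this recovers areas with ≈4–7% negative bias
(boundary cells sit inside the true boundary by about half the mean
inter-cell spacing), comfortably within the 10% recovery requirement.

Area taxonomy: clusters ≤ 0.02 mm² are micro-fragments (discarded, logged);
(0.02, 0.1] mm² are satellites; > 0.1 mm² are nests, split into a 50 µm
edge band and core by polygon erosion.  Thinness (< 3 cell diameters
maximum inscribed width, via pole-of-inaccessibility) is recorded as an
attribute only — thin shape is typical of satellites but not definitional.
An edge is NOS2⁺ when ≥ 5% of its tumor cells carry any NOS2 grade; the
band width and cutoff are conventions (the source analysis states neither)
and are stamped into every region-map log.  Lymphoid aggregates are
single-linkage clusters of ≥ 20 CD3⁺ cells outside nests.  Cell→region
assignment precedence: aggregate > edge > core > satellite > stroma; cells
outside every polygon are stroma.

## Immune-desert decision table

Per nest: CD8 infiltration index (T_Eff/T_Ex fraction of core cells),
edge NOS2 status, core COX2⁺ tumor fraction, proximal stromal lymphoid
fraction (CD3⁺ fraction of stromal-compartment cells within 500 µm of the
nest boundary) and nearest-aggregate distance.  Routing: infiltration
≥ 0.05 → infiltrated; NOS2⁺ edge & COX2 ≥ 0.20 → type I; NOS2⁻ edge &
COX2 ≥ 0.20 → type II; NOS2⁻ edge, COX2 < 0.20 and proximal lymphoid
< 1% → type III; anything else takes the nearest type by criterion-mismatch
count and is flagged atypical.  The 0.20 high-COX2 cutoff operationalizes
the qualitative high / "low sporadic" contrast and is reported with every
call.  Aggregate proximity (< 0.5 mm) is recorded but not gated: the
taxonomy's association of type II with proximal aggregates is treated as a
description, not a criterion.  An undetermined edge (no edge tumor cells)
is classified by the remaining criteria and flagged.

## Neighborhood statistics

Distance bins are right-closed, (d_k, d_{k+1}], 25 µm wide by default
(first bin (0, 25]); a target at exactly 25 µm falls in the first bin, and
coincident distinct cells join the first bin.  Counts are raw (no edge
correction) and verified exactly against an all-pairs oracle.  Per-bin
enrichment divides the mean count by the CSR expectation (global target
intensity × annulus area).  Decay gradients are least-squares fits of
log(y) against bin midpoint with λ = −1/slope; y is the mean count where
the counts themselves decay (the calibration benchmarks plant exactly
that), or the enrichment inside extended structures where raw counts grow
with annulus area.  The gradient flag requires a significantly negative
slope (one-direction P ≤ 0.05 from the slope t-test).  Fits use only
nonzero bins and require at least four.

Neighborhood composition vectors (phenotype counts within 50 µm, self
excluded) are clustered by k-means (default k = 8) on standardized
features; the published clustering procedure is not specified, so k and
the radius are configuration.  The 2-D UMAP embedding is presentation-only:
cluster labels are defined in feature space and never depend on it.
Differential abundance is each cluster's share of deceased-sample cells
divided by its share of alive-sample cells (shares sum to 100% per group);
zero shares receive an additive pseudo-share of half the smallest nonzero
share, flagged per cluster.  Density heatmaps bin cells on a grid and
smooth with a truncated-Gaussian filter; the raster integrates to the cell
count up to boundary truncation.

## Cohort statistics

Mann-Whitney tests are two-sided (one-sided retained only for the
T_Eff/PDL1-macrophage ratio contrast where the source analysis used it) and
exact — by full enumeration of the U null — whenever n_A·n_B ≤ 10,000 and
the pooled values are tie-free; otherwise the normal approximation with tie
correction.  Pearson correlations use the t-distribution with n−2 df and
are computed within outcome groups.  Outlier exclusion is a ROUT-style
procedure: residuals from the median scaled by the MAD-derived robust SD
(1.4826·MAD), two-sided t-tail probabilities flagged by Benjamini-Hochberg
at rate Q (default 1%); the exact commercial implementation is proprietary,
so this robust-FDR analogue is used and every exclusion is reported.
Survival: product-limit curves; the Gehan-Breslow-Wilcoxon test is the
log-rank family weighted by the number at risk; the Mantel-Haenszel hazard
ratio is exp((O₁−E₁)/V) with CI exp((O₁−E₁)/V ± 1.96/√V) — by symmetry a
group tested against itself gives HR = 1 exactly.  Significance is
declared at P ≤ 0.05 with no multiplicity correction, matching the source
convention; every report carries the number of tests performed so readers
can apply their own correction.

Cohort survival metadata: deceased samples draw an event time from an
exponential (scale 24 months) truncated at the 60-month follow-up (they
died within the window by definition); alive samples are censored at 60
months.  Null-calibration cohorts give both groups one identical landscape
configuration; under the null the exact Mann-Whitney at n = 10 vs 10
attains a type-I rate slightly below the nominal 5% (discrete test), which
the calibration benchmark's 5% ± 2% band accommodates.

## Problem sizes

Benchmarks run at sizes chosen to give stable estimates on a single CPU:
200 planted nests (50 per type) for desert-typing recovery; 20 seeds for
decay-length calibration (each ≈200 focal cells, amplitude 20 per bin);
200 replicate null cohorts of 20 samples (~1,500 cells each, 0.81 mm²
fields) for type-I calibration; 2,000 cells for oracle-equivalence checks.
The 20-sample demonstration cohort uses full-size 2.56 mm² fields
(~4,300 cells per sample).

## Known limitations

* Region segmentation assumes nests are simply connected at the closing
  scale; true annular or highly dendritic tumor architectures would be
  smoothed.
* The desert decision table inherits its cutoffs (0.05 infiltration, 0.20
  COX2, 1% lymphoid, 5% edge NOS2) from conventions stated above; on real
  cohorts they should be treated as tunable and reported alongside calls.
* No intensity normalization or batch correction across samples is
  performed; gates are per-panel constants (or per-sample tertiles for
  NOS2 grades).
* Neighbor counts are uncorrected for field edges; profiles near the field
  boundary are biased low in the outer bins.
* The survival machinery handles right censoring only.
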