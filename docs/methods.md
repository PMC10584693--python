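# Methods

## The homeostasis model

mtDNA concentration *n* (copies per volume, arbitrary units) changes by
replication, degradation and growth dilution:

    dn/dt = kR·m/(K1 + m/n) − kD·n/(K2 + a/n) − n·ln2/T

Assumptions: most polymerase (Mip1, concentration *m*) is DNA-bound at low
*m*, so replication is polymerase-limited there and proportional to *n*
when Mip1 saturates (K1 is the Mip1–mtDNA dissociation constant); the
packaging factor Abf2 (concentration *a*) protects mtDNA stoichiometrically,
so degradation depends on the a/n ratio and falls to zero as a/n grows
(kD/K2 is the unprotected decay rate); growth is exponential with doubling
time *T*. Cell-to-cell variability and mother/bud partitioning are outside
the model's scope.

Setting dn/dt = 0 and dividing out the trivial root n = 0 gives
A·n² + B·n + C = 0 with

    A = K1·K2·ln2 + kD·K1·T
    B = a·K1·ln2 − K2·m·kR·T + K2·m·ln2 + kD·m·T
    C = a·m·ln2 − a·m·kR·T

(re-derived symbolically from the rate equation; the published polynomial
writes the rate constants as K_D/K_R, which the derivation identifies with
k_D/k_R). A > 0 always and the root product is C/A, so a strictly positive
steady state exists iff C < 0, i.e. kR·T > ln2 — replication must outrun
dilution at saturating Mip1 — and it is then unique. The solver uses the
cancellation-safe quadratic formula; when C ≥ 0 it returns n = 0 with
`exists=False`, the only non-negative fixed point. `integrate` (explicit
RK4 with a non-negativity clamp; the scalar ODE is non-stiff for any
positive parameter set) provides the independent dynamic route used in
tests: the quadratic root and the long-time trajectory agree to a relative
1e−6.

Because both saturable terms depend only on m/n and a/n, the model family
dn/dt = n·f(m/n) − n·g(a/n) − n·ln2/T is homogeneous: scaling m and a by a
common factor c scales n* by c. Hence the parameter-free predictions — a
double hemizygote (m/2, a/2) sits at exactly 50% of wild type, joint
twofold overexpression at exactly 200% — while single hemizygotes land
anywhere in [50%, 100%] depending on which of replication (large kR) or
degradation (large kD) is closer to saturation. The wild-type grid shipped
as `WILD_TYPE_GRID` (m=5, a=100, T=150, K1=5, K2=100; kR ∈ {0.01, 0.1},
kD ∈ {1, 10}) spans those regimes: the single-hemizygote sweep ranges from
52.4% to 95.1%. Units are internally consistent but arbitrary; the model
is qualitative by construction, so no unit-conversion layer exists.

## Nucleoid counting and network segmentation

Per cell, on anisotropic voxel grids ((z, y, x) voxel size in µm; the
synthetic default is (0.35, 0.1, 0.1), the z step matching typical confocal
acquisition and xy near Nyquist for the lateral resolution limit):

1. 3D Gaussian prefilter, σ = 0.75 voxel, both channels.
2. Li cross-entropy threshold of the mitochondria channel → network mask;
   network volume = in-mask voxel count × voxel volume; fragments counted
   by 26-connectivity connected components.
3. Mitochondria channel divided by its in-network median.
4. 3D local maxima (26-neighborhood) of the nucleoid channel as candidate
   foci. Plateaus (connected equal-valued maxima) contribute one
   representative, the lexicographically smallest (z, y, x) — a convention
   chosen for determinism.
5. Candidates below a Li threshold of the nucleoid channel are dropped.
6. Deduplication at the optical resolution: a spheroid with lateral radius
   0.61·λ/NA (0.222 µm at NA 1.4, λ 509 nm — the Rayleigh form, which
   matches that printed radius) and a 1 µm axial radius. Greedy by
   descending intensity, ties broken lexicographically; membership is
   boundary-inclusive; physical distances use the voxel size.
7. Iterative validation: in-network voxels are classified inside/outside
   the surviving foci's spheroids; the nucleoid channel is normalized by
   the mean over the outside voxels; each focus is kept only if a Welch
   t-test finds its normalized nucleoid intensities significantly above the
   median-normalized mitochondria intensities over the same voxels
   (discard if p > 0.025 or t ≤ 0; two-sided p by default, with a
   one-sided option since the published rule pairs a p cut-off with a sign
   condition and either reading is defensible). The pass repeats until the
   count stabilises; the count is non-increasing, so at most
   initial-count iterations run. Foci with fewer than 3 in-network spheroid
   voxels are discarded (the test needs per-group variance); spheroids are
   clipped at the grid boundary.

All thresholds and statistics are computed within the cell mask, making
cells independent — a deliberate choice where a whole-image threshold
would couple them. A cell with a constant mitochondria signal yields an
empty network and zero nucleoids rather than an error (ρ0-like cells are a
real use case).

Two honest limitations, both verified quantitatively in the test suite:

* **Network volume is relative, not absolute.** Li thresholding of a
  diffraction-blurred thin tube (PSF σ_z ≈ 0.5 µm against a ~0.15 µm tube
  radius) includes the blurred shoulder; the segmented volume exceeds the
  true tube volume by ~2–3× at realistic geometries, and the bias shrinks
  but does not vanish for implausibly fat tubes. The segmentation is
  boundary-accurate — the mask covers the true tube and stays within a
  1-voxel dilation of it on clean tubes — so volumes are comparable across
  cells imaged identically, which is how such measurements should be used.
* **The Welch validation has a per-focus false-positive rate.** Candidates
  are local maxima of smoothed (hence spatially correlated) noise, so at
  p = 0.025 a ρ0-like cell with only matrix leak-through in the nucleoid
  channel yields ~1 spurious focus, against ~20 real nucleoids in a healthy
  cell of the same size.

## qPCR quantification

Technical replicates are pooled by the mean Cq; if the replicate s.d.
exceeds 0.5 cycles, the replicate farthest from the median is excluded and
the rest re-tested (once by default — the minimal deterministic reading of
a single-exclusion rule; iterating is config-exposed). A well whose
remaining replicates still spread beyond the cut-off propagates as missing,
never as zero. Per-primer standard curves are unweighted OLS of Cq on
log10(concentration) over a 1e−4–1 pg/µL dilution series; the efficiency
10^(−1/slope) − 1 is reported but not used to re-correct concentrations
(the curve itself embodies the primer efficiency). Gene groups (nuclear:
ACT1, MIP1, MRX6; mitochondrial: COX2, COX3) are pooled by arithmetic
means, with per-gene exclusions for dosage-manipulated strains. The
budding index converts copies-per-nDNA to copies per cell —
(%buds·2 + %no-buds·1)/100 nuclear genomes per haploid cell,
(%buds·4 + %no-buds·2)/100 per diploid — and the population mean volume
gives copies per fL. Absolute copies from standards alone would need the
pg-per-copy content of the calibration product; the pipeline only ever
uses concentration ratios, where that scale cancels.

Error propagation worth knowing: with per-replicate Cq noise of s.d. 0.1
and triplicates, each pooled concentration carries ≈ ln10·(0.1/√3)/|slope|
≈ 3.9% relative error; pooling 3 nuclear and 2 mitochondrial genes leaves
≈ 3.6% on the mt/nDNA ratio, so single-plate copy numbers are accurate to
a few percent, not better.

## Scaling statistics

Binned means use equal-width bins spanning the 1st–99th volume percentile
(count configurable, default 8) with bins under 5 points suppressed and
s.e. = s.d./√n (0 for single-point bins); the published figures do not
print their edges, so these are this package's defaults. Linear fits are
OLS — by default to means of biological replicates, matching how the
figures fit, with pooled single-cell mode available. The constant-amount
expectation for a transcript is the pure dilution ratio
v_small/v_big. Copies-per-nucleoid matches qPCR populations and imaged
cells on shared volume bins (the two measurements come from different
experiments). Flow-cytometry series are background-corrected per scatter
bin against a non-fluorescent control; with two day-replicates the
estimate is the day mean and the uncertainty envelope runs from
min(day) − s.e. to max(day) + s.e., which covers the truth ~95% per bin
when day-to-day scatter matches the stated s.e. Strain comparisons use the
two-tailed two-sample t-test with Shapiro–Wilk normality reported, not
enforced.

## Synthetic data: what it emulates, and what it does not

Cells are mildly prolate voxelized ellipsoids hitting a target volume
within 5%. Networks are persistent random-walk tubes (radius 0.15 µm)
confined inside the cell, grown until the tube mask reaches a target
fraction of cell volume (default 10%) within 10%; requesting k fragments
walks k separate tubes. Nucleoids are placed on the tube centerline with a
spheroidal exclusion metric so pairs are separated by twice the optical
resolution in every direction (axial resolution being r_z/r_xy ≈ 4.5×
worse than lateral); the default density of 0.45 nucleoids/fL gives ~20 in
a 50 fL cell, consistent with ~2 mtDNA copies per nucleoid at ~0.9
copies/fL. Rendering blurs the network with an anisotropic Gaussian PSF
(default σ = (0.5, 0.09, 0.09) µm, lateral ≈ r_xy/2.35), adds nucleoid
foci as Gaussians of the PSF width at their exact physical positions, adds
a network leak-through into the nucleoid channel (factor 0.3 — the diffuse
matrix signal the Welch validation exists to reject), and applies Poisson
shot noise (200 photons per intensity unit), Gaussian read noise (s.d.
0.02) and a constant offset (0.1). Populations draw lognormal volumes
(CV 0.3, emulating an engineered >4-fold volume range) with copies = c·V
and a fixed copies-per-nucleoid. Simulated plates invert the
standard-curve chemistry from known copy numbers with Gaussian Cq noise.

Every generator is bit-deterministic given its seed, and every output
carries its ground truth. Not emulated: aberrations, bleaching, bud-neck
geometry, depth-dependent noise, plate-position effects, biological
replicate structure. Passing tests therefore demonstrate the algorithms'
correctness on data with the assumed statistical structure, not robustness
to every artefact of real microscopes and thermocyclers.

## Problem sizes

The test and acceptance runs use single-cell stacks of roughly
(16–20) × (60–70)² voxels (35–95 fL cells), 50 stacks for the end-to-end
detection check, 100 random parameter sets for the ODE-oracle check, and
100 seeded trials for the qPCR round trip — sizes at which every
statistical assertion is well-resolved and the whole suite runs in well
under a minute.
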