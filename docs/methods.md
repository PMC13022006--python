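# Methods

## Trophic positions from amino-acid δ¹⁵N

The estimator is the standard two-amino-acid formula

TP_aa = (δ¹⁵N_aa − δ¹⁵N_Phe − β_aa) / TDF_aa + 1

with the canonical seston constants β_Glu = 3.4 ‰, TDF_Glu = 7.6 ‰ and
β_Ala = 3.2 ‰, TDF_Ala = 5.7 ‰ (`TrophicCalibration`; both configurable).
The assumptions inherited from that framework: phenylalanine records the
nitrogen-source baseline unchanged, the trophic amino acid enriches by one
TDF per trophic transfer, and β/TDF measured on cultured organisms apply
to mixed field seston.  Nothing is clipped: TP < 1 (isotopically light
trophic AAs) and TP > 2 are reported as computed.

Trophoclines — slope-1 lines of constant TP in the (δ¹⁵N_Phe,
δ¹⁵N_trophic) plane — have intercept β + TDF·(TP − 1); at TP 1.0/1.5/2.0
this gives 3.4/7.2/11.0 ‰ for Glu and 3.2/6.05/8.9 ‰ for Ala (the mid Ala
intercept is often displayed rounded to 6.0).

### Mode classification

Two rules are provided, for two uses:

- `classify_trophic_mode` applies the published interpretive bands:
  TP_Glu < 1.4 autotroph side, 1.4–1.6 (closed) osmotroph band, > 1.6
  `heterotroph_dominated`; TP_Ala ≥ 1.4 flags phagotrophy ("around or
  above 1.5" operationalised as a band of half-width 0.1, mirroring the
  Glu band).  Band edges are inclusive on the mixotroph side.  Missing TPs
  give `indeterminate`; otherwise the partition of the TP plane is
  exhaustive and non-overlapping.
- `classify_nearest_archetype` assigns each axis to the closer of the
  TP 1.0 / TP 1.5 archetypes (boundary 1.25, ties toward autotrophy).
  This is the graphical trophocline judgement appropriate for noisy data
  and is the rule the recovery tests use: with ~1 ‰ per-replicate noise
  the TP_Glu standard deviation is ≈ 0.11 (triplicate means), so the
  0.2-wide printed band captures only ~65 % of true band-centre samples —
  an intrinsic property of the band geometry, not an implementation
  artefact — while nearest-archetype assignment recovers ≥ 95 %.

Uncertainty propagation is first-order Gaussian,
sd(TP) = √(sd_trophic² + sd_phe²)/TDF, treating β and TDF as exact; it is
reported but never used in classification.

End-member overlays report, per record and trophic amino acid, the nearest
trophocline on the 0.5-TP grid and the perpendicular distance
|Δδ − intercept|/√2 (vertical distance available); ties go to the lower
TP.

## Pigment unmixing (chemotaxonomy)

A sample's pigment vector (µg L⁻¹) is modelled as a non-negative
combination of class pigment:chl-a signatures; the coefficient on each
class *is* its chlorophyll-a contribution because the Chl a column of the
ratio matrix is identically 1.  Fitting is per-sample non-negative least
squares.  Pigment columns are scaled by the inverse of their RMS over
samples before fitting so abundant pigments do not dominate the objective
(configurable to none); the objective is the weighted RMS residual over
all sample × pigment cells.

The randomised procedure follows the classic protocol: each run perturbs
the nonzero non-Chl-a ratios by independent uniform ±35 % factors
(`magnitude`, the tool's conventional ratio limit), locally optimises each
of the 60 matrices, and re-seeds the next of 3 runs from the element-wise
mean of the 6 best (ranked by objective, ties by generation index).
Because the underlying software's internals are not published, local
optimisation here is an accept-if-better single-entry multiplicative
search (steps ×0.9/×1.1, entries confined to ±50 % of their initial value,
`bound`), which is derivative-free, bounded and reproducible; an accepted
step must improve the objective by more than 1e-12 so exact fits leave the
matrix untouched.  Structural zeros and the unit Chl a column are
preserved by construction through perturbation and optimisation.  The best
matrix is carried across runs, so the best objective is non-increasing.
Degenerate all-zero pigment rows yield zero composition with a warning so
whole cruises can be processed.

## Hydrographic habitat features

- **N²** = (g/ρ₀)·Δσθ/Δz on level midpoints, g = 9.81 m s⁻²,
  ρ₀ = 1025 kg m⁻³.  σθ may be supplied; otherwise it is computed from
  T/S with the one-atmosphere EOS-80 (Millero–Poisson) polynomial —
  adequate plumbing for near-surface casts where in-situ temperature
  approximates potential temperature.
- **Mixed-layer depth** is the depth of the primary (global) N² maximum,
  shallowest on ties within 1e-12; a first-local-maximum option exists.
  All-zero N² yields a missing MLD.
- **Cline depths** (nitracline 1 µM, phosphocline 0.1 µM, silicacline
  2 µM) are 0 when the surface concentration already meets the threshold,
  else the linearly interpolated first downward crossing, else missing.
- **NAI** uses the same interpolation primitive: surface NOₓ (µM) when
  ≥ 0.5 µM, else −(depth where NOₓ reaches 2 µM), else −bottom depth.
  Its mixed units (µM vs m) are kept as defined; the index is consumed
  raw by clustering and the tree.
- **Oxygen saturation** is the Garcia–Gordon combined fit (Benson–Krause
  data) evaluated in µmol kg⁻¹ and converted to mM with the local surface
  density; inputs outside the fit range warn rather than fail.
- **Plume thickness** is the interpolated depth where salinity first
  reaches 35 (the plume-extent criterion, adopted here as the thickness
  threshold); missing when the surface is already salty, the cast bottom
  when the whole cast is fresh.
- "Surface" values are the topmost valid cast level.

## Community clustering and size index

Compositions (percent of total chl a) are clustered on Manhattan
distances — robust to outlier stations — with average (UPGMA) linkage by
default (complete/single available; Ward is refused on a non-Euclidean
metric).  k defaults to 4.  Labels are renumbered in order of first
appearance so they are invariant to row order.  The PCA check is a
centered, unscaled SVD (percent units are commensurate; scaling
available); it reports variance fractions and, per cluster pair, the
PC1–PC2 centroid distance divided by the mean within-cluster RMS spread.
The mean-size index uses the standard diagnostic-pigment weights
(micro ∝ 1.41 Fuco + 1.41 Perid; nano ∝ 1.27 HexFuco + 0.35 ButFuco +
0.60 Allo; pico ∝ 1.01 Chl b + 0.86 Zea), normalised fractions and class
tags micro = 3, nano = 2, pico = 1.

## Trophic-mode tree

A C4.5-family classifier, authored here because the commercial variant's
exact heuristics (winnowing, boosting, global pruning) are not public:
binary numeric splits at midpoints of straddling values, chosen by
information gain ratio with the gain discounted by the known-value
fraction; cases with a missing tested attribute descend both children
with the training known-weight fractions; pruning is bottom-up
error-based with a Clopper–Pearson upper confidence bound at cf = 0.25;
min_cases = 2 per branch.  Ties in split selection go to the earlier
column and lower threshold, making induction deterministic and invariant
to row order.  Attribute usage counts each case's weight once per
attribute at the topmost node testing it (root = 100 %); training error
is resubstitution error under majority-path prediction.

## Synthetic generators

The generators emulate the statistical structure of the study inputs:

- **Amino-acid profiles**: per-sample Phe baselines from Uniform(2, 12) ‰
  (the spread across plume habitats); trophic AAs placed exactly on the
  archetype trophocline relative to the true baseline; every value then
  "measured" as the mean of 3 replicates with 1 ‰ per-replicate noise,
  with the replicate SD reported — mirroring the triplicate analytical
  protocol the noise figure describes.  Archetypes: photoautotroph
  (1.0, 1.0), osmo-photoautotroph (1.5, 1.0), phago-photoautotroph
  (1.0, 1.5), mixoplankton (1.5, 1.5); end-member archetypes
  protozooplankton (1.2, 2.0; strict phagotrophs keep TP_Glu low) and
  DON-grown heterotrophs (2.0, 1.5).  Mixture signatures are weighted
  arithmetic means of member δ values — exact only for equal nitrogen
  pools, a documented approximation.
- **Pigment samples**: chl a total × fraction-weighted ratio rows with
  multiplicative Gaussian noise (CV 1 %), truncated at zero; fractions
  default to a symmetric Dirichlet over the eight classes.
- **CTD/nutrient casts**: two-layer σθ and salinity with a tanh
  transition at the prescribed pycnocline (1.5 m half-width, 1 m grid,
  120 m bottom), NOₓ rising below a prescribed nitracline; by
  construction the derived MLD matches the prescription within one grid
  step and the NAI hits a chosen branch.
- **Station sets**: mixotroph-dominated stations satisfy MLD ≤ 37 m and
  surface chl a > 0.171 µg L⁻¹; autotroph stations violate the MLD rule
  (70 %) or the chlorophyll rule (30 %); all other features are drawn
  from habitat-typical ranges and are uninformative by construction.

What the generators do **not** emulate: mechanistic isotope
fractionation, spatial/temporal autocorrelation along the plume,
covariance between pigments and trophic mode, real pigment measurement
error structure (which is not multiplicative-Gaussian), or the 8-habitat
meta-classification.  Passing tests therefore demonstrate that the
estimators invert their own generative models under realistic noise — not
that the field inferences are correct.

## Problem sizes and numerics

The test suite exercises the full 60 × 3 × best-6 randomisation on 16
pigment samples, mode recovery at 500 samples per mode, and tree
induction at 100–200 stations — sizes chosen so the whole suite runs in
well under a minute apart from the randomised unmixing (~20 s).  All
randomness flows from explicit integer seeds; the pipeline fans a single
seed out to per-stage seeds by a fixed affine map so stages are
individually reproducible, and every output table carries a header with
version, seed and configuration hash.

## Known limitations

- β and TDF are culture-derived constants; mixoplankton-specific TDFs are
  unknown, so intermediate TPs are interpreted, not mechanistically
  derived.
- The unmixing optimiser is a local search; it inherits ChemTax's
  sensitivity to the initial ratio matrix, mitigated but not removed by
  the randomised multi-run protocol.
- The tree is a C4.5-family approximation, not a replica of the
  commercial C5.0; identical trees on identical data are not guaranteed.
- EOS-80 surface density (not TEOS-10) backs σθ and the oxygen unit
  conversion; differences are negligible at the surface but the choice is
  deliberate plumbing, not an oceanographic statement.
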