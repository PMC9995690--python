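# Methods

## Scientific setting

The package analyses a paired oceanographic design: at a set of stations,
(1) depth profiles of total ²³⁴Th activity and salinity are used to estimate
the downward export flux of sinking particles, and (2) 16S rRNA OTU tables
from sequentially filtered seawater (0.2–0.8 µm "free-living", 0.8–53 µm
small-particle, >53 µm large-particle fractions) describe the prokaryotic
communities down the water column. The question the linkage addresses is
whether stations with stronger particle export show tighter compositional
connectivity between surface and deep communities — i.e. whether large
sinking particles act as vectors carrying surface taxa into the mesopelagic.

## Export flux from ²³⁴Th/²³⁸U disequilibrium

²³⁸U behaves conservatively in oxygenated seawater and its activity is a
linear function of salinity, A_U = 0.0786·S − 0.315 dpm L⁻¹ (default
coefficients of the standard open-ocean regression; both configurable, with
optional coefficient uncertainties, valid for S in [30, 38]). ²³⁴Th
(half-life 24.1 d, λ = ln 2 / 24.1 ≈ 0.028761 d⁻¹) is produced by ²³⁸U decay
and scavenged by sinking particles, producing an activity deficit. Under a
1-D steady-state scavenging model with negligible advection and diffusion,

    F = λ · ∫₀^z_int (A_U(z) − A_Th(z)) dz · 1000 L m⁻³   [dpm m⁻² d⁻¹]

**Integration depth.** z_int is the shallowest *measured* depth where the
²³⁴Th/²³⁸U activity ratio is within a tolerance (default 0.05) of 1 — secular
equilibrium — subject to a persistence condition: no deeper measurement may
return to a deficit (ratio < 1 − tol). Excursions *above* 1 + tol at depth do
not restart the search; they indicate ²³⁴Th excess (remineralisation or
counting noise), not renewed scavenging, and a two-sided persistence rule
would let a single noisy deep point drag z_int down and cancel the deficit
against the excess region. If equilibrium is never reached, the deficit is
integrated to the deepest sample and the estimate is flagged `lower_bound`.

**Quadrature.** Trapezoidal rule on the measured depths, exact for
piecewise-linear deficits. The shallowest measured deficit is extended to the
surface as a constant (standard practice for the unsampled top of the
profile; a z = 0 measurement is accepted and then used directly). Net ²³⁴Th
excess integrates to a negative flux and is flagged, not clipped.

**Uncertainty.** Counting errors (1σ per activity) propagate in quadrature
through the trapezoid weights; by default only the ²³⁴Th counting error
contributes (the salinity-based A_U is treated as exact), with U-model
coefficient errors available via a flag.

## Community metrics

- **Rarefaction** subsamples each sample to 5,000 reads *without replacement*
  (multivariate hypergeometric), matching `rrarefy`-style behaviour: samples
  at or below the target are retained unchanged (or dropped on request), and
  OTUs left with zero counts everywhere are removed. One integer seed spawns
  a deterministic substream per sample, so a sample's subsample does not
  depend on which other samples are present.
- **Richness** is the count of OTUs with positive counts per (rarefied)
  sample.
- **Taxonomic aggregation** sums counts at a chosen rank (default class),
  pooling unannotated OTUs into `unclassified`; relative abundances are
  per-sample proportions, the overall share is taxon total over grand total.
  Dissimilarity statistics are computed on the rarefied table by default.
- **Bray–Curtis** dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); undefined (error) when
  both vectors are all-zero.
- **Vertical dissimilarity**: within each (station, size-fraction) stratum,
  Bray–Curtis between the shallowest sample (5 m in the study design) and
  each deeper sample.
- **ANOSIM**: R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4) on mid-ranks of all pairwise distances; R = 1 for perfect
  separation. When the number of distinct labelings n!/(∏ nᵍ!) is ≤ 10,000
  the null is enumerated exactly (p = #{R* ≥ R}/#labelings); otherwise
  Monte-Carlo with p = (1 + #{R* ≥ R})/(1 + n_perm). Groupings used by the
  pipeline: size fraction, station, and binned depth (≤100 m, 100–500 m,
  ≥500 m — sampling depths are near-unique, so ANOSIM-by-depth requires
  binning; the bins are recorded in the run report).
- **Surface-derived fraction**: for each mesopelagic sample (≥500 m), the
  percentage of its observed OTUs (and of its reads) present in any surface
  sample of the same station and fraction. "Surface" is depth ≤ 100 m
  inclusive by default; a strict `< 100 m` mode and a cross-station
  (`global`) pool are exposed as flags, since both conventions appear in the
  field literature and 100 m is itself a sampled depth.
- **Station-unique fraction**: an OTU is unique to a station if its summed
  counts over all that station's samples (all depths, and by default all
  fractions pooled) are positive and zero elsewhere; reported per community
  as % of OTUs and % of reads.

## Gradient linkage

Station-level gradients (Chl-a stock, POC stock, estimated ²³⁴Th flux) are
joined to the per-community metrics. Trends are Spearman rank correlations
of a metric against a gradient, pooling all depths within a size fraction.
The trend test is a formalisation this package adds — the field study
reported these trends graphically — and it is deliberately conservative:

**Cluster permutation.** The gradient is constant within a station while
every depth of a station shares that station's endmember composition and its
surface reference sample, so observations are dependent within stations. The
only exchangeable units under the null are stations, and the p-value
permutes the station-to-gradient assignment (exhaustively for ≤ 7 stations).
Its floor is 1/k! for k stations: a 3-station design reports the trend
*direction* through rho but can never reach α = 0.05, which is the honest
statement of what three stations support. Pooled or depth-stratified
permutation schemes were rejected: simulations with zero coupling showed
type-I rates near 30% because they ignore the within-station dependence.
With 8 exchangeable stations the cluster permutation rejects at the nominal
rate (measured ≈ 4–5% over 200 null runs).

## Synthetic data generator

The generator provides ground-truthed data with the structure the analysis
assumes; its defaults are the study-sized scenario (3 stations × 6 depths ×
3 fractions = 54 samples).

A single per-station productivity parameter φ (the fractional ²³⁴Th deficit
at the surface) drives both data types:

- **Th profiles**: A_Th(z) = A_U·(1 − φ·e^(−z/z*)) with z* = 45 m, salinity
  34, multiplicative Gaussian counting noise (CV 3%, within the stated <5%
  counting statistics); the true flux has the closed form
  λ·A_U·φ·z*·(1−e^(−Z/z*))·1000. Defaults φ = (0.15, 0.40, 0.58) put the
  estimated fluxes at roughly 300/1200/1750 dpm m⁻² d⁻¹, spanning most of
  the observed field range (~150–2000). A station with a genuine flux near
  150 is not representable under the 0.05 equilibrium tolerance — its
  activity ratio would sit inside the tolerance band and integrate to ≈ 0 —
  so the weak station is calibrated to ~300 instead.
- **Communities**: each sample's expected composition is a two-endmember
  mixture m(z)·surface + (1−m(z))·deep with
  m(z) = exp(−max(z − z₀, 0)/(L₀ + κ_f·φ)), z₀ = 100 m, L₀ = 60 m.
  Communities in the surface layer (≤ 100 m) are pure surface endmember —
  stratified water columns do not carry deep taxa upward — and the mixing
  length below grows with φ only for fractions with positive coupling κ_f
  (default: only the >53 µm fraction, κ = 400 m per unit φ). κ = 0
  everywhere is the decoupled null. Reads are multinomial at per-sample
  depths drawn uniformly from 5,000–15,000.
- **Endmembers**: Dirichlet draws over a shared 900-OTU pool partitioned
  into class blocks, scaled by per-fraction class weights (the large
  fraction enriched in Alphaproteobacteria, the small fractions in
  Gammaproteobacteria/Flavobacteriia), so a class's expected read share
  equals its weight. Per-fraction concentrations (α = 0.08 small, 0.05
  large) were calibrated once so rarefied richness spans ~180–350 OTUs,
  inside the observed 130–600 band, with the large fraction less rich.
  Surface endmembers are station-specific and include a station-private
  pool (150 OTUs at compositional share q = 0.05, α = 0.08: many rare
  private taxa, so unique OTUs are a larger share of OTUs than of reads);
  deep endmembers are station-shared so vertical structure, not station
  identity, dominates the ordination-scale signal.

**What the generator does not emulate.** Real sequence error, chimeras and
clustering artefacts; seasonal succession; advective heterogeneity;
depth-dependent salinity; correlated taxon dynamics beyond the two-endmember
mixture; and station effects in the deep endmember. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
statistical structure, not performance guarantees on field data.

## Numerical and design choices

- Fraction labels are stored as the nominal lower pore size (0.2 / 0.8 / 53).
- OTU tables are accepted in either orientation (first header cell
  `otu_id` vs `sample_id`); readers sniff tab vs comma.
- Metadata rows without table columns (collected but unsequenced samples)
  warn rather than fail.
- ANOSIM rank ties use mid-ranks; the exhaustive/Monte-Carlo switch is at
  10,000 labelings.
- All stochastic steps (generator, rarefaction, permutation tests) take
  integer seeds recorded in the run report; re-running a pipeline
  configuration is byte-reproducible.

## Known limitations

- The steady-state 1-D model ignores advection, diffusion and
  non-steady-state effects; estimates for profiles that never equilibrate
  are lower bounds.
- With three stations, gradient trends are descriptive (rho and direction),
  not inferential; the permutation p-value floor of 1/6 is reported as-is.
- The equilibrium tolerance (0.05) and surface constant-extrapolation rule
  are conventions, configurable but not estimated from data.
- Surface-derived percentages depend on detection, hence on rarefaction
  depth; they are comparable only across equally rarefied communities.
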