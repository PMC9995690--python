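# thorlink

Coupled analysis of particle export fluxes and size-fractionated prokaryotic
community connectivity in the upper ocean.

Highly productive polar waters export sinking organic particles out of the
sunlit layer. Those particles are not just carbon: they carry their attached
microbes downward, potentially seeding mesopelagic communities with surface
taxa. `thorlink` implements the two measurement chains needed to test that
link and joins them:

1. **Export flux from ²³⁴Th/²³⁸U disequilibrium.** ²³⁴Th (T₁/₂ = 24.1 d) is
   produced by conservative ²³⁸U (A_U = 0.0786·S − 0.315 dpm L⁻¹ from
   salinity) and scavenged by sinking particles. Under a steady-state 1-D
   scavenging model the export flux is

   F = λ · ∫₀^z_eq (A_U − A_Th) dz · 1000   [dpm m⁻² d⁻¹],

   integrated by trapezoid to the depth where the ²³⁴Th/²³⁸U activity ratio
   returns to secular equilibrium (ratio = 1 within a configurable
   tolerance), with 1σ counting errors propagated through the quadrature
   weights.

2. **Community connectivity from size-fractionated 16S OTU tables.**
   Rarefaction to a common read depth (5,000, hypergeometric), per-sample
   richness, class-level composition, Bray–Curtis dissimilarity between each
   station's surface (5 m) community and every deeper one, ANOSIM permutation
   tests (by size fraction, station, depth bin), and per-community fractions
   of surface-derived (mesopelagic OTUs also found ≤ 100 m) and
   station-unique OTUs.

3. **Linkage.** Station gradients (Chl-a stock, POC stock, ²³⁴Th flux) are
   joined to community metrics; Spearman trends with station-cluster
   permutation p-values quantify whether vertical dissimilarity of the
   large-particle (> 53 µm) fraction shrinks — and its surface-derived share
   grows — as export increases.

A fully ground-truthed **synthetic generator** emulates the study design
(3 stations × 6 depths × 3 size fractions, multinomial reads at
5,000–15,000 per sample) with a single per-station productivity parameter
driving both the Th deficit and the downward mixing of surface taxa in the
large fraction, so the whole chain is testable without field data.
See `docs/methods.md` for model details and limitations.

## Worked example

```python
import thorlink as tl

ds = tl.generate_dataset(tl.SyntheticConfig(seed=1))
for profile in ds.profiles:
    est = tl.steady_state_flux(profile)
    print(f"{est.station}: flux = {est.flux:7.1f} +/- {est.flux_sigma:5.1f} "
          f"dpm m-2 d-1 (z_int = {est.integration_depth:g} m)")

rt = tl.rarefy(ds.table, depth=5000, seed=1)
meta = tl.metadata_by_sample(ds.metadata)
diss = tl.vertical_dissimilarity(rt.table, meta)
surf = tl.surface_derived_fraction(rt.table, meta)
fluxes = [tl.steady_state_flux(p) for p in ds.profiles]
gradient = tl.assemble_gradient(diss, surf, ds.inventories, fluxes)
for fraction in (0.2, 0.8, 53.0):
    tr = tl.trend_dissimilarity_vs_gradient(gradient, fraction, "th234_flux", seed=1)
    print(f"{fraction:>4g} um: rho = {tr.spearman_rho:+.2f} "
          f"(p = {tr.p_value:.2f}, {tr.direction})")
```

prints

```
ST1: flux =   275.6 +/-  37.0 dpm m-2 d-1 (z_int = 40 m)
ST2: flux =  1191.2 +/-  96.9 dpm m-2 d-1 (z_int = 150 m)
ST3: flux =  1717.1 +/-  78.2 dpm m-2 d-1 (z_int = 125 m)
 0.2 um: rho = -0.13 (p = 0.67, none)
 0.8 um: rho = -0.09 (p = 0.67, none)
  53 um: rho = -0.19 (p = 0.33, none)
```

The three stations span a productivity gradient; their estimated fluxes
(~280 → ~1700 dpm m⁻² d⁻¹) recover the generator's ordering. The
surface-to-depth Bray–Curtis trend along the flux gradient is negative only
weakly for the free-living fractions but consistently for the > 53 µm
particles (the generator couples downward mixing to flux only in that
fraction). With three stations the cluster-permutation p-value can never
fall below 1/6, so directions are reported as `none` — a deliberate
statement of what a 3-station design supports; rho carries the trend.

## Command line

```bash
thorlink simulate --seed 1 --out data/            # synthetic bundle + truth
thorlink flux --profiles data/th234_profiles.tsv --out flux.csv
thorlink rarefy --otu-table data/otu_table.tsv --depth 5000 --seed 1 --out rare.tsv
thorlink metrics --otu-table rare.tsv --metadata data/sample_metadata.tsv --outdir metrics/
thorlink run --config run.yaml                    # full pipeline, 8 CSVs + report
```

`thorlink run` writes per-stage tidy CSVs (flux table, richness, class
composition, unique OTUs, ANOSIM, gradient-joined dissimilarity and
surface-derived tables, trends) plus a JSON run report recording versions,
seeds, row counts and warnings; re-running the same configuration is
byte-reproducible.

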