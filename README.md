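# sedapipe

Replicate-aware analysis of sedimentary ancient DNA (sedaDNA)
metabarcoding records: from raw per-PCR-replicate read-count tables to
quality-gated community matrices, ecological-indicator series,
stratigraphic zones, an assemblage-based temperature reconstruction, and
a multivariate analysis of the drivers of vegetation change.

It is written for palaeoecologists working with lake-sediment DNA of
plants (trnL P6 loop) and mammals (16S), where each sample is amplified
in several independent PCR replicates and sequenced together with
negative extraction/PCR controls. The replicate structure is the point:
detection patterns across replicates carry information about template
abundance, and contamination betrays itself in the controls.

## What it computes

**Retention cascade.** Barcodes are kept only with a perfect reference
match, length >= 10 bp, >= 10 total reads, and detections (>= 3 reads in
a replicate) in >= 3 replicates; homopolymer-length artifact variants are
merged into their source sequence; barcodes with higher mean counts in
negative controls than in samples are removed (with an ecological
whitelist). Mammal tables are additionally curated (off-target discards,
collapse by taxon, sporadic single-replicate detections flagged).

**Relative Abundance Index.** The central quantity is, per sample *s*
and taxon *t*,

    RAI(s, t) = prop_reads(s, t) x wtRep(s, t)

where `prop_reads` is the taxon's share of the sample's retained reads
and `wtRep` is the weighted PCR-replicate proportion: per replicate, the
taxon's reads relative to the best-represented retained taxon, averaged
over the replicates the sample ran. Both factors are in [0, 1] and
scale-free, so RAI is as well.

**Sample quality gates.** MTQ (fraction of raw reads on perfect-match
barcodes) and MAQ (fraction on fully retained barcodes) gate samples at
relaxed (MTQ >= 0.45, MAQ >= 0.175) and strict (both >= 0.9) levels, with
diagnostics of every quality metric against sample age and richness.

**Indicators.** A barcode is an indicator of an elevational vegetation
belt or of pastoral/arable land use only when *all* of its
haplotype-sharing species agree on the value (unanimity rule); belt
profiles, activity series, richness and growth-form proportions are
built from the optimal indicators.

**Zonation.** CONISS (constrained incremental sum of squares) with
broken-stick significance and exact optimal partitioning.

**Temperature.** A WA-PLS transfer function (2 components, square-root
transformed assemblages) with bootstrap RMSEP and sample-specific eSEP,
plus adjacent-sample amalgamation of low-count fossil assemblages.

**Drivers.** Fourth-root transform, RDA with AIC + permutation forward
selection and Pillai's-trace tests, a Poisson GAM for richness with
outlier screening and Durbin–Watson diagnostics, and piecewise SEM
(Fisher's C over the d-separation basis set).

Every stage is exercisable on synthetic data with recorded ground truth
(`sedapipe.synthetic_data`), so the whole pipeline is testable without
any downloads.

## Worked example

```python
from sedapipe import (
    SimulationConfig, simulate_community, simulate_drivers, run_cascade,
    compute_quality, gate_samples, rai, grade_indicators, zonate,
    transform_fourth_root, forward_select, rda,
)
from sedapipe.io_formats import align_drivers
from sedapipe.synthetic_data import barcode_species_map

cfg = SimulationConfig(seed=42, n_responsive_taxa=8, driver_effect_size=1.2)
proxies = simulate_drivers(cfg)
sample_ids = [f"S{i:03d}" for i in range(cfg.n_samples)]
ages = [(i + 1) * cfg.depth_step_cm * cfg.years_per_cm for i in range(cfg.n_samples)]
drivers = align_drivers(proxies, sample_ids, ages).drop(columns="age_calBP")

raw, traits, truth = simulate_community(cfg, driver_values=drivers)
retained, reports = run_cascade(raw)
metrics = compute_quality(raw, retained)
gates = gate_samples(metrics)
abund = rai(retained)
relaxed = sorted(gates["relaxed_set"])

assignments = grade_indicators(barcode_species_map(traits), traits)
zones = zonate(abund.value.loc[relaxed].to_numpy(),
               ages=retained.samples.loc[relaxed, "age_calBP"].to_numpy())

Y = transform_fourth_root(abund.value.loc[relaxed])
sel = forward_select(Y, drivers.loc[relaxed], n_perm=199, seed=42)
result = rda(Y, drivers.loc[relaxed][sel["selected"]])
```

Output:

```
retained 37/46 barcodes (4 artifact variants merged, 2 contaminants removed)
samples passing gates: relaxed 80, strict 58
optimal belt indicators: 36/40
significant CONISS zones: 7 (boundary ages: ['880', '2320', '4400', '6320', '8240', '11120'] cal yr BP)
selected drivers: ['LOI_percent', 'temperature_C', 'spore_influx', 'precipitation_kg_m2_month', 'charcoal_influx']
constrained variance: 83.0%
```

Reading it: of 46 raw barcodes, the cascade keeps 37 — the 4 injected
homopolymer artifacts were folded back into their source sequences and
both injected contaminants were caught by the control comparison. All 80
samples pass the relaxed quality gate but only 58 the strict one (the
generator plants an age-increasing share of imperfectly matching reads,
as degraded records show). 36 of 40 taxa are unanimous belt indicators
(4 planted conflicts are rejected). Because composition here is forced
by the simulated Holocene driver series, CONISS finds 7 significant
stratigraphic zones, forward selection keeps all five driver series, and
the constrained ordination explains 83% of the compositional variance.

A command-line surface mirrors the stages
(`sedapipe simulate | filter | quality | rai | zones | reconstruct |
drivers | run`); `sedapipe run --seed 1 --out DIR` executes everything
end to end and writes TSV/JSON artifacts plus a manifest.

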