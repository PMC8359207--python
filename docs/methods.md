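# Methods

## The inference chain

For each OTU present with positive copies in both members of a treatment
pair (one unlabelled, one ¹³C+¹⁵N-labelled incubation of the same
substrate), the analysis composes, in order:

1. **Weighted average density (WAD).** Read counts are normalized per
   fraction-sample to relative abundances and scaled by that fraction's
   qPCR total (16S copies), giving per-fraction absolute copies. The WAD
   is the copy-weighted mean of the fraction densities,
   `W = Σ ρ_k c_k / Σ c_k`. It is scale-invariant in the copies and
   always lies within the span of observed densities.
2. **GC content** from the unlabelled WAD via the linear buoyant
   density–GC relation `ρ = 1.646057 + 0.083506·G` (Schildkraut-type
   calibration as used in single-isotope qSIP). Inferred GC outside
   [0, 1] is clamped with a warning — the linear relation is only
   calibrated inside that range; whether to clamp is this package's
   choice, as the source framework leaves the case unspecified.
3. **Light molecular weight** `M_LIGHT = 0.496·G + 307.691` g/mol per
   average nucleotide.
4. **Labelled molecular weight** from the relative density shift:
   `M_LAB = (ΔW/W_light + 1)·M_LIGHT`. Buoyant density is proportional
   to molecular weight for fixed sequence, so a relative density gain
   maps one-to-one onto a relative mass gain.
5. **Maximum heavy molecular weight** under full simultaneous ¹³C + ¹⁵N
   substitution. The default ("printed") form is the combined equation
   `M_HEAVYMAX = 0.0025·G + 13.416 + M_LIGHT`.
6. **Molecular weight excess**
   `MWE = (M_LAB − M_LIGHT)/(M_HEAVYMAX − M_LIGHT)`. Negative values
   (labelled treatment banding lighter) are reported as-is, never
   clamped, and are always inactive.
7. **Active call**: `MWE ≥ threshold`, inclusive, default 0.14. The
   cutoff matches the labelled proportion of the added substrate and is
   deliberately stringent because single gradients permit no
   significance test.

Per-OTU failures (all-zero copies, degenerate weights) exclude that OTU
with a recorded reason; they never abort the run.

### The two forms of the maximum-heavy equation

The combined dual-isotope coefficients (slope 0.0025, intercept 13.416)
are **not** algebraically consistent with the sum of the carbon-only
maximum (`−0.4987282·G + 9.974564`) and the per-base nitrogen maxima
(A/G: 4.985, T: 1.994, C: 3 N → 2.991 g/mol, averaged over complementary
pairs to `3.4895 + 0.4985·G`); that sum is `−0.0002282·G + 13.464064`.
The discrepancy is ~0.4% of the increment and its provenance is unknown,
so the package implements both: `max_heavy_mode="printed"` (default,
used by the analysis verbatim) and `"per_element"` (the reconstruction,
also used by the simulator's per-element forward mode). No attempt is
made to guess which is "intended".

Setting `isotopes="C"` replaces the dual increment with the carbon-only
maximum, reproducing classic single-isotope ¹³C qSIP behaviour (the
statistic then plays the role of atom fraction excess).

### Optional extensions (off by default)

- **Natural-abundance correction**: natural ¹³C/¹⁵N content is already
  present in the unlabelled control that anchors `W_light` and GC, so no
  correction is applied by default; a flag rescales the denominator by
  the natural-abundance mass offset for methodological comparison.
- **Fraction-resampling bootstrap** (`bootstrap_mwe`): quantifies
  within-gradient sampling spread only. With one gradient per condition
  there is no biological replication to resample, which is why the
  default analysis reports point estimates only.

## Preprocessing rules

- Gradient incubations: OTUs with fewer than 13 reads summed over the
  incubation's 13 fraction-samples are removed from that incubation's
  analysis (strict `<`; exactly 13 is kept). The threshold ties to the
  fraction count: under one read per fraction on average carries no
  usable band shape. Water-column libraries instead drop singletons.
- Lineages matching a configured label set (default Cyanobacteria,
  indistinguishable from substrate-derived chloroplast DNA) are removed;
  matching is case-insensitive substring per rank, tolerating SILVA
  prefixes (`D_1__Cyanobacteria`).
- Filter order (count filter, then taxa) is logged; both orders commute
  on the OTU set and no filter ever changes a surviving OTU's counts.
- Whether count filtering preceded taxon removal in the original
  workflow is not documented; the default order here is a package
  choice, not an assertion about that workflow.
- The per-litre prokaryote abundance estimate scales the summed qPCR
  copies by (DNA extracted / DNA loaded) / volume filtered. It is
  reconstructed from a verbal description and flagged as an
  order-of-magnitude estimate; extraction yield dominates its error.
- Fraction metadata is taken as measured (refractometer densities, qPCR
  totals); no gradient-shape refitting. A fraction missing qPCR data is
  simply absent from its profile — the WAD is a per-profile statistic,
  so the matching fraction of the partner incubation is kept.

## The simulator

`simulate_pair` emulates a paired unlabelled/labelled experiment:

- **Band model**: each OTU's DNA is a Gaussian band in density, centred
  at `ρ(G)` (unlabelled) or at
  `ρ(G)·M_LAB/M_LIGHT` with `M_LAB = M_LIGHT + m·(M_HEAVYMAX − M_LIGHT)`
  for true incorporation `m` ("mwe" mode), or with per-element gains
  `afe_c`, `afe_n` ("per_element" mode). Gaussian-in-density is the
  standard isoconcentration approximation; no band model is prescribed
  by the experimental protocol. Default width σ = 0.006 g/ml spans
  roughly 3–4 of 13 fractions, resembling published per-OTU gradient
  curves.
- **Fractionation**: the density window is cut into equal-width bins;
  band mass per bin is the exact Gaussian integral (CDF differences),
  with the outermost fractions collecting the tails so copy mass is
  conserved exactly. Fraction index 1 is the heaviest fraction —
  a labelling convention only, since every statistic is
  density-weighted. (Whether the original experiment collected heavy or
  light first is unrecorded and irrelevant to results.)
- **Sequencing**: per fraction-sample, reads are multinomial over OTUs
  proportional to copy mass, at `reads_per_sample` depth. An analytic
  switch substitutes expected counts, making the pipeline an exact
  inverse of the forward model up to band discretization.
- **qPCR noise**: fraction totals are multiplied by lognormal noise with
  unit mean and CV 0.10 by default — a typical qPCR replicate spread;
  the experimental CVs were not reported, so this is a documented
  choice.
- **Determinism**: one integer seed drives all draws; emitted files
  record seed, config hash and package version.

Not simulated: PCR amplification bias, chimeras, 16S copy-number
variation between taxa, and isotope effects beyond the linear
MW→density scaling. Passing recovery tests therefore demonstrate
correctness of the inference mathematics under the stated noise model,
not robustness to those real-data artefacts.

## Numerical choices and problem sizes

- **Density window for validation grids.** The defaults place 13
  fractions across 1.660–1.780 g/ml, centred near the 1.725 g/ml loading
  density. A fully labelled high-GC band, however, sits near 1.78 g/ml —
  at the very edge of that window — and tail truncation there biases the
  WAD by far more than the discretization budget. Validation grids that
  include full labelling therefore use a 1.650–1.800 g/ml window, chosen
  a priori so every band centre lies ≥ 3σ inside the window (tail mass
  < 0.3%, WAD bias < 3e-5 g/ml). With that geometry the noise-free
  round trip recovers true MWE to < 1e-3 (dominated by assigning each
  bin's mass to its midpoint density), measured at 198 OTUs over
  GC ∈ [0.3, 0.7] × MWE ∈ {0, 0.05, 0.14, 0.3, 0.5, 1}.
- **Recovery under noise** is assessed at 13 fractions, 10⁵ reads per
  fraction-sample, qPCR CV 0.10, 200 OTUs, 3 seeds — comfortably inside
  a minute on one CPU. Observed |bias| is ~2e-3 and the 0.14 call is
  >99% accurate for truths ≥ 0.05 from the cutoff.
- Ties and degenerate inputs: all-zero copy vectors raise an
  undefined-result error (OTU excluded downstream); all-zero sample
  columns survive normalization as zeros and are flagged; the activity
  threshold comparison is inclusive.
- Results TSVs are written with 10 significant digits and round-trip
  through the reader to well below 1e-9.

## Known limitations

- The WAD-based chain assumes unimodal bands; truly bimodal label
  distributions (partial population labelling) yield intermediate MWE.
- Community summaries interpret "total sequences" as read counts of
  active OTUs (not qPCR copies), and shared-OTU percentages default to
  the union denominator; both conventions are explicit function
  arguments because the field reports such numbers without stating
  either convention.
- GC inferred from density inherits any systematic offset between the
  density calibration and the actual gradient; with one replicate per
  condition this cannot be corrected internally.
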