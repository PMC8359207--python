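# dualsip

Dual-isotope (¹³C + ¹⁵N) quantitative DNA stable-isotope probing (qSIP)
analysis: from fraction-resolved 16S rRNA OTU counts and qPCR totals to
per-OTU **molecular weight excess (MWE)** and active-taxon calls, with a
forward simulator of CsCl gradient experiments for validation.

## The problem

In DNA-SIP, a microbial community is incubated with an isotopically
labelled substrate; organisms that assimilate it build heavy isotopes
into their DNA, which then bands at a higher buoyant density in a CsCl
gradient. qSIP quantifies this per taxon: each gradient is cut into ~13
density fractions, every fraction is sequenced (16S amplicons) and
quantified (qPCR of total 16S copies), and each OTU's **weighted average
density** (WAD) is compared between an unlabelled control and a labelled
incubation.

With a single isotope the density shift converts to atom fraction excess
(AFE). When substrates carry **both** ¹³C and ¹⁵N, the shift cannot be
attributed to one element, so the statistic here is the molecular weight
excess — the observed mass gain as a fraction of the theoretical maximum
under full simultaneous ¹³C + ¹⁵N substitution:

```
W_light  = Σ ρ_k c_k / Σ c_k                    (per-OTU WAD, unlabelled)
G        = (W_light − 1.646057) / 0.083506      (GC proportion)
M_LIGHT  = 0.496 G + 307.691                    (g/mol per nucleotide)
M_LAB    = (ΔW / W_light + 1) · M_LIGHT         (ΔW = W_lab − W_light)
M_HEAVYMAX = 0.0025 G + 13.416 + M_LIGHT        (full ¹³C+¹⁵N labelling)
MWE      = (M_LAB − M_LIGHT) / (M_HEAVYMAX − M_LIGHT)
```

MWE = 0 means no incorporation, 1 means fully labelled. An OTU is called
**active** when MWE ≥ 0.14 (inclusive), a stringent cutoff matching the
labelled proportion of the added substrate. No natural-abundance
correction is applied (it is already embedded in the unlabelled control)
and no bootstrap is run by default (single gradients carry no
replication).

## Worked example

```python
import numpy as np
import dualsip as ds

cfg = ds.SimulationConfig(n_otus=60, density_range=(1.65, 1.80),
                          reads_per_sample=50_000, seed=42)
truth = ds.make_truth(cfg.n_otus, np.random.default_rng(cfg.seed),
                      mwe_values=(0.0, 0.05, 0.3, 0.5))
sim = ds.simulate_pair(cfg, truth)
results, analysis = ds.analyse_simulation(sim)

n_active = sum(r.active for r in results)
print(f"{len(results)} OTUs analysed, {n_active} called active (MWE >= 0.14)")
r = next(r for r in results if r.active)
print(f"{r.otu_id}: W_light={r.w_light:.4f}  W_lab={r.w_lab:.4f}  "
      f"GC={r.gc:.2f}  MWE={r.mwe:.3f}")
print(f"active-community density {ds.community_weighted_density(results, 'active'):.4f} g/ml; "
      f"all-OTU mean {ds.community_weighted_density(results, 'all', 'unweighted'):.4f} g/ml")
```

prints

```
60 OTUs analysed, 30 called active (MWE >= 0.14)
OTU_3: W_light=1.6728  W_lab=1.6939  GC=0.32  MWE=0.290
active-community density 1.7158 g/ml; all-OTU mean 1.7034 g/ml
```

Here 60 OTUs were simulated with incorporation levels cycling through
{0, 0.05, 0.3, 0.5}; the 30 OTUs with true MWE 0.3 or 0.5 are exactly
the ones called active. OTU_3 (true MWE 0.3, GC 0.32) banded 0.021 g/ml
heavier in the labelled gradient, recovering MWE 0.290. The active
community is denser than the community as a whole — the signature of a
labelled minority.

The same pipeline runs from the shell on real or simulated files:

```
dualsip simulate --config cfg.yaml --outdir sim/
dualsip qsip --metadata sim/fraction_metadata.csv \
             --otu-table sim/otu_table.tsv --taxonomy sim/taxonomy.tsv \
             --outdir results/
dualsip recovery --config cfg.yaml --outdir recovery/
```

Input formats: fraction metadata CSV/TSV (sample_id, incubation_id,
substrate, isotope, fraction_index, density_g_per_ml, total_16s_copies),
a classic tab-separated OTU table (OTU rows × sample columns), and a
two-column taxonomy TSV with semicolon-delimited SILVA-style lineages.

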