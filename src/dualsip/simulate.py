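"""Forward simulator of paired unlabelled/labelled SIP gradient experiments.

Each OTU's DNA is placed in the CsCl gradient as a Gaussian band in
density, centred at the buoyant density implied by its GC content
(unlabelled member) or by its GC content plus isotope incorporation
(labelled member).  The gradient is cut into equal-width density
fractions; band mass per fraction is the exact Gaussian integral over the
fraction's density bin, with the outermost fractions collecting the tails
so copy mass is conserved.  Sequencing is multinomial at finite depth per
fraction-sample, and qPCR totals carry multiplicative lognormal noise.

Every stochastic draw comes from one seeded generator, so a simulation is
fully reproducible from (config, seed).  An analytic switch replaces
multinomial counts by their expectations, turning the simulator plus the
analysis chain into an exact forward/inverse pair up to band
discretization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import __version__
from . import constants as C
from .errors import ParameterError
from .gradient_data import (
    FractionRecord,
    GradientProfile,
    OTUCountTable,
    TreatmentPair,
)
from .qsip import (
    carbon_max_increment,
    light_molecular_weight,
    max_heavy_mw_dual,
    nitrogen_max_increment,
)

# synthetic SILVA-style lineages cycled over simulated OTUs
_SYNTHETIC_LINEAGES = (
    "Bacteria;Proteobacteria;Gammaproteobacteria;Thiotrichales;Thiotrichaceae;Thiothrix",
    "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobacteraceae;Desulfobacter",
    "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae;Anaerolinea",
    "Bacteria;Planctomycetes;Phycisphaerae;Phycisphaerales;Phycisphaeraceae;Phycisphaera",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Marinilabiliaceae;Marinilabilia",
    "Archaea;Euryarchaeota;Thermoplasmata;Thermoplasmatales;Marine_Group_II;Unassigned",
    "Archaea;Crenarchaeota;Bathyarchaeia;Unassigned;Unassigned;Unassigned",
)


@dataclass
class SimulationTruth:
    """Per-OTU ground truth: GC, incorporation level and abundance.

    ``true_mwe`` drives the 'mwe' forward mode; ``afe_c``/``afe_n`` (atom
    fraction excess per element) drive the 'per_element' mode.
    """

    otu_ids: list[str]
    gc: np.ndarray
    true_mwe: np.ndarray
    rel_abundance: np.ndarray
    band_sigma: np.ndarray
    afe_c: np.ndarray | None = None
    afe_n: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.otu_ids)
        for name in ("gc", "true_mwe", "rel_abundance", "band_sigma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ParameterError(f"truth field {name} must have length {n}")
            setattr(self, name, arr)
        if ((self.gc < 0) | (self.gc > 1)).any():
            raise ParameterError("gc must lie in [0, 1]")
        if ((self.true_mwe < 0) | (self.true_mwe > 1)).any():
            raise ParameterError("true_mwe must lie in [0, 1]")
        total = self.rel_abundance.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ParameterError(f"relative abundances must sum to 1, got {total}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "otu_id": self.otu_ids,
                "gc": self.gc,
                "true_mwe": self.true_mwe,
                "afe_c": self.afe_c if self.afe_c is not None else np.nan,
                "afe_n": self.afe_n if self.afe_n is not None else np.nan,
                "rel_abundance": self.rel_abundance,
                "band_sigma": self.band_sigma,
            }
        )


@dataclass
class SimulationConfig:
    """Simulator settings.

    Defaults emulate the experimental conditions the package targets:
    13 equal gradient fractions spanning a window centred near the 1.725
    g/ml loading density, band width 0.006 g/ml (a band spans roughly 3-4
    fractions), and 10% qPCR coefficient of variation.
    """

    n_otus: int = 100
    n_fractions: int = 13
    density_range: tuple[float, float] = (1.660, 1.780)
    reads_per_sample: int = 100_000
    qpcr_total: float = 1e8  # total 16S copies loaded per gradient
    qpcr_cv: float = 0.10
    band_sigma: float = 0.006
    mode: str = "mwe"  # or "per_element"
    substrate: str = "DOM"
    analytic: bool = False  # expected counts instead of multinomial draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 3:
            raise ParameterError("n_fractions must be >= 3")
        lo, hi = self.density_range
        if not lo < hi:
            raise ParameterError("density_range must be increasing")
        if self.n_otus < 1:
            raise ParameterError("n_otus must be >= 1")
        if self.reads_per_sample < 0:
            raise ParameterError("reads_per_sample must be >= 0")
        if self.qpcr_cv < 0 or self.band_sigma <= 0 or self.qpcr_total <= 0:
            raise ParameterError("qpcr_cv >= 0, band_sigma > 0, qpcr_total > 0 required")
        if self.mode not in ("mwe", "per_element"):
            raise ParameterError(f"unknown simulation mode {self.mode!r}")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SimulatedPair:
    """A simulated experiment: treatment pair, counts, and the truth."""

    pair: TreatmentPair
    counts: OTUCountTable
    truth: SimulationTruth
    config: SimulationConfig


def density_from_gc(gc) -> float | np.ndarray:
    """Buoyant density (g/ml) of unlabelled DNA from GC proportion."""
    gc = np.asarray(gc, dtype=float)
    if ((gc < 0) | (gc > 1)).any():
        raise ParameterError("gc must lie in [0, 1]")
    out = C.DENSITY_GC_INTERCEPT + C.DENSITY_GC_SLOPE * gc
    return float(out) if out.ndim == 0 else out


def expected_labelled_density(
    gc: float,
    true_mwe: float = 0.0,
    afe_c: float = 0.0,
    afe_n: float = 0.0,
    mode: str = "mwe",
    max_heavy_mode: str = "printed",
) -> float:
    """Band-centre density of a labelled OTU under the forward model.

    mode 'mwe' places the labelled molecular weight a fraction
    ``true_mwe`` of the way from M_light to M_heavymax (combined-equation
    maximum); mode 'per_element' adds per-element gains
    afe_c * carbon maximum + afe_n * nitrogen maximum.  Density scales
    with relative molecular weight.
    """
    w_light = density_from_gc(gc)
    m_light = light_molecular_weight(gc)
    if mode == "mwe":
        m_max = max_heavy_mw_dual(gc, m_light, mode=max_heavy_mode)
        m_lab = m_light + true_mwe * (m_max - m_light)
    elif mode == "per_element":
        m_lab = (
            m_light
            + afe_c * carbon_max_increment(gc)
            + afe_n * nitrogen_max_increment(gc)
        )
    else:
        raise ParameterError(f"unknown forward mode {mode!r}")
    return w_light * m_lab / m_light


def make_truth(
    n_otus: int,
    rng: np.random.Generator,
    gc_range: tuple[float, float] = (0.3, 0.7),
    mwe_values: Sequence[float] = (0.0, 0.05, 0.14, 0.3, 0.5, 1.0),
    band_sigma: float = 0.006,
    abundance_sigma: float = 1.0,
) -> SimulationTruth:
    """Build a ground truth spreading GC evenly over ``gc_range`` and
    cycling incorporation over ``mwe_values``, with lognormal abundances.

    ``abundance_sigma`` is the log-scale spread of relative abundances
    (0 gives a perfectly even community).
    """
    gc = np.linspace(gc_range[0], gc_range[1], n_otus)
    true_mwe = np.array([mwe_values[i % len(mwe_values)] for i in range(n_otus)])
    if abundance_sigma > 0:
        rel = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_otus)
    else:
        rel = np.ones(n_otus)
    rel = rel / rel.sum()
    return SimulationTruth(
        otu_ids=[f"OTU_{i + 1}" for i in range(n_otus)],
        gc=gc,
        true_mwe=true_mwe,
        rel_abundance=rel,
        band_sigma=np.full(n_otus, band_sigma),
    )


def _band_masses(
    centres: np.ndarray, sigmas: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Gaussian band mass per density bin (OTU x bin), tails folded into
    the outermost bins so each row sums to 1 exactly."""
    z = (edges[None, :] - centres[:, None]) / sigmas[:, None]
    cdf = norm.cdf(z)
    masses = np.diff(cdf, axis=1)
    masses[:, 0] += cdf[:, 0]
    masses[:, -1] += 1.0 - cdf[:, -1]
    return masses


def simulate_pair(config: SimulationConfig, truth: SimulationTruth | None = None) -> SimulatedPair:
    """Simulate one paired unlabelled/labelled gradient experiment.

    Returns fraction metadata (as GradientProfiles with noisy qPCR
    totals), a read-count table over both members' fraction-samples, and
    the truth used.  Fraction index 1 is the heaviest fraction.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = make_truth(config.n_otus, rng, band_sigma=config.band_sigma)
    n = len(truth.otu_ids)

    lo, hi = config.density_range
    edges = np.linspace(lo, hi, config.n_fractions + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    profiles: dict[str, GradientProfile] = {}
    count_blocks: list[pd.DataFrame] = []
    for isotope in ("unlabelled", "labelled"):
        if isotope == "unlabelled":
            centres = density_from_gc(truth.gc)
        else:
            centres = np.array(
                [
                    expected_labelled_density(
                        truth.gc[i],
                        true_mwe=truth.true_mwe[i],
                        afe_c=truth.afe_c[i] if truth.afe_c is not None else 0.0,
                        afe_n=truth.afe_n[i] if truth.afe_n is not None else 0.0,
                        mode=config.mode,
                    )
                    for i in range(n)
                ]
            )
        masses = _band_masses(centres, truth.band_sigma, edges)  # OTU x bin
        copy_mass = masses * (truth.rel_abundance * config.qpcr_total)[:, None]
        fraction_totals = copy_mass.sum(axis=0)

        if config.qpcr_cv > 0:
            sig2 = np.log1p(config.qpcr_cv**2)
            noise = rng.lognormal(mean=-sig2 / 2, sigma=np.sqrt(sig2), size=len(mids))
            qpcr_totals = fraction_totals * noise
        else:
            qpcr_totals = fraction_totals.copy()

        # fraction 1 = heaviest: iterate bins in descending density
        order = np.argsort(mids)[::-1]
        inc_id = f"{config.substrate}_{isotope}"
        sample_ids = [f"{inc_id}_F{k + 1:02d}" for k in range(len(order))]
        fractions = [
            FractionRecord(
                sample_id=sample_ids[k],
                incubation_id=inc_id,
                fraction_index=k + 1,
                density=float(mids[order[k]]),
                total_copies=float(qpcr_totals[order[k]]),
            )
            for k in range(len(order))
        ]
        profiles[isotope] = GradientProfile(
            incubation_id=inc_id,
            substrate=config.substrate,
            isotope=isotope,
            fractions=fractions,
        )

        block = np.zeros((n, len(order)))
        for k, b in enumerate(order):
            col_mass = copy_mass[:, b]
            total = col_mass.sum()
            if total <= 0 or config.reads_per_sample == 0:
                continue
            p = col_mass / total
            if config.analytic:
                block[:, k] = p * config.reads_per_sample
            else:
                block[:, k] = rng.multinomial(config.reads_per_sample, p)
        count_blocks.append(
            pd.DataFrame(block, index=truth.otu_ids, columns=sample_ids)
        )

    counts_df = pd.concat(count_blocks, axis=1)
    if not config.analytic:
        counts_df = counts_df.round().astype(np.int64)
    taxonomy = {
        otu: _SYNTHETIC_LINEAGES[i % len(_SYNTHETIC_LINEAGES)]
        for i, otu in enumerate(truth.otu_ids)
    }
    counts = OTUCountTable(counts=counts_df, taxonomy=taxonomy)
    pair = TreatmentPair(unlabelled=profiles["unlabelled"], labelled=profiles["labelled"])
    return SimulatedPair(pair=pair, counts=counts, truth=truth, config=config)


def write_simulation(sim: SimulatedPair, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated experiment in the exact formats the readers accept.

    Emits fraction metadata CSV, OTU count TSV, taxonomy TSV, the truth
    table, and a manifest recording seed, config hash and version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": outdir / "fraction_metadata.csv",
        "otu_table": outdir / "otu_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.yaml",
    }

    rows = []
    for profile in (sim.pair.unlabelled, sim.pair.labelled):
        for f in profile.fractions:
            rows.append(
                {
                    "sample_id": f.sample_id,
                    "incubation_id": f.incubation_id,
                    "substrate": profile.substrate,
                    "isotope": profile.isotope,
                    "fraction_index": f.fraction_index,
                    "density_g_per_ml": f"{f.density:.6f}",
                    "total_16s_copies": f"{f.total_copies:.6e}",
                }
            )
    pd.DataFrame(rows).to_csv(paths["metadata"], index=False)

    counts = sim.counts.counts.copy()
    counts.index.name = "otu_id"
    counts.to_csv(paths["otu_table"], sep="\t")

    with open(paths["taxonomy"], "w", encoding="utf-8") as fh:
        fh.write("otu_id\tlineage\n")
        for otu in sim.counts.otu_ids:
            fh.write(f"{otu}\t{sim.counts.lineage(otu)}\n")

    sim.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")

    manifest = {
        "seed": sim.config.seed,
        "config_hash": sim.config.config_hash(),
        "version": __version__,
        "config": asdict(sim.config),
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def recovery_experiment(
    config: SimulationConfig,
    mwe_values: Sequence[float] = (0.0, 0.05, 0.3, 0.5),
    n_seeds: int = 3,
    depths: Sequence[int] | None = None,
    gc_range: tuple[float, float] = (0.3, 0.7),
    threshold: float = C.DEFAULT_MWE_THRESHOLD,
) -> pd.DataFrame:
    """Estimator-validation harness: simulate, analyse, compare to truth.

    For each sequencing depth and seed, a community cycling through
    ``mwe_values`` is simulated and pushed through the full analysis
    chain; recovered MWE is compared to truth per incorporation level.
    Returns a table with columns true_mwe, depth, n, bias, rmse, accuracy
    (accuracy = agreement of the active call at ``threshold`` with the
    true label).
    """
    from .pipeline import analyse_simulation

    if depths is None:
        depths = [config.reads_per_sample]
    records = []
    for depth in depths:
        per_otu: list[pd.DataFrame] = []
        for s in range(n_seeds):
            cfg = SimulationConfig(
                **{
                    **asdict(config),
                    "reads_per_sample": int(depth),
                    "seed": config.seed + s,
                }
            )
            rng = np.random.default_rng(cfg.seed)
            truth = make_truth(
                cfg.n_otus,
                rng,
                gc_range=gc_range,
                mwe_values=mwe_values,
                band_sigma=cfg.band_sigma,
            )
            sim = simulate_pair(cfg, truth)
            results, _ = analyse_simulation(sim, threshold=threshold)
            est = pd.DataFrame(
                {
                    "otu_id": [r.otu_id for r in results],
                    "mwe_hat": [r.mwe for r in results],
                    "active": [r.active for r in results],
                }
            )
            merged = est.merge(truth.to_frame()[["otu_id", "true_mwe"]], on="otu_id")
            per_otu.append(merged)
        allseeds = pd.concat(per_otu, ignore_index=True)
        for mwe_true, grp in allseeds.groupby("true_mwe"):
            err = grp["mwe_hat"] - mwe_true
            truly_active = mwe_true >= threshold
            records.append(
                {
                    "true_mwe": mwe_true,
                    "depth": int(depth),
                    "n": len(grp),
                    "bias": float(err.mean()),
                    "rmse": float(np.sqrt((err**2).mean())),
                    "accuracy": float((grp["active"] == truly_active).mean()),
                }
            )
    return pd.DataFrame.from_records(records)
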