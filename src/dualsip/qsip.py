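"""Dual-isotope qSIP mathematics.

The chain of inference per OTU:

1.  Weighted average density (WAD) of the OTU's 16S copies across the
    gradient, separately for the unlabelled (W_light) and labelled (W_lab)
    incubation.
2.  GC content from W_light via the linear density-GC relation.
3.  Light (unlabelled) per-nucleotide molecular weight M_light from GC.
4.  Labelled molecular weight M_lab from the relative density shift:
    M_lab = (dW/W_light + 1) * M_light.
5.  The theoretical maximum heavy molecular weight M_heavymax under full
    simultaneous 13C + 15N substitution.
6.  Molecular weight excess
    MWE = (M_lab - M_light) / (M_heavymax - M_light),
    i.e. the observed mass gain as a fraction of the theoretical maximum.
    Unlike single-isotope qSIP no atom fraction excess is computed: with
    two isotopes the mass gain cannot be attributed to one element.
7.  An OTU is called active when MWE >= threshold (default 0.14, the
    labelled proportion of the added substrate).

No natural-abundance isotope correction is applied by default: natural
heavy-isotope content is already present in the unlabelled control that
anchors W_light and GC.  No bootstrap confidence intervals are computed
by default (single gradients carry no replication); an optional
fraction-resampling bootstrap is provided as an extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import constants as C
from .errors import InvalidStateError, ParameterError, UndefinedResultError
from .gradient_data import OTUCountTable, TreatmentPair
from .preprocess import AbundanceTable

log = logging.getLogger(__name__)

# Natural abundance of the heavy isotopes (atom fraction), used only when
# the optional natural-abundance correction is enabled.
NATURAL_13C = 0.01111233
NATURAL_15N = 0.0036765


@dataclass
class QsipResult:
    """Per-OTU qSIP estimates and the active call."""

    otu_id: str
    substrate: str
    w_light: float  # g/ml
    w_lab: float  # g/ml
    delta_w: float  # g/ml
    gc: float  # proportion
    m_light: float  # g/mol per nucleotide
    m_lab: float  # g/mol
    m_heavymax: float  # g/mol
    mwe: float  # dimensionless
    active: bool
    copies_unlabelled: float
    copies_labelled: float
    lineage: str = "Unassigned"


def weighted_average_density(
    copies: Sequence[float], densities: Sequence[float]
) -> float:
    """Copy-number-weighted mean buoyant density of an OTU.

    Scale-invariant in the copy numbers and always within the span of the
    observed fraction densities.
    """
    copies = np.asarray(copies, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if copies.shape != densities.shape:
        raise ParameterError("copies and densities must have equal length")
    if (copies < 0).any():
        raise ParameterError("copy numbers must be non-negative")
    total = copies.sum()
    if total <= 0:
        raise UndefinedResultError("weighted density undefined: all copies are zero")
    return float((densities * copies).sum() / total)


def gc_from_light_density(w_light: float) -> float:
    """GC proportion from the unlabelled weighted average density.

    Inverts rho = 1.646057 + 0.083506 * G.  Values outside [0, 1] are
    clamped with a warning; the linear relation is only calibrated inside
    that range.
    """
    g = (w_light - C.DENSITY_GC_INTERCEPT) / C.DENSITY_GC_SLOPE
    if g < 0.0 or g > 1.0:
        log.warning("inferred GC %.4f outside [0, 1]; clamping", g)
        g = min(1.0, max(0.0, g))
    return float(g)


def light_molecular_weight(gc: float) -> float:
    """Mean per-nucleotide molecular weight (g/mol) of unlabelled DNA."""
    _check_gc(gc)
    return C.LIGHT_MW_SLOPE * gc + C.LIGHT_MW_INTERCEPT


def labelled_molecular_weight(w_light: float, w_lab: float, m_light: float) -> float:
    """Molecular weight in the labelled treatment from the density shift.

    Buoyant density scales linearly with molecular weight, so the relative
    density shift maps directly onto a relative mass gain.
    """
    if w_light <= 0:
        raise ParameterError("w_light must be positive")
    return ((w_lab - w_light) / w_light + 1.0) * m_light


def nitrogen_max_increment(gc: float) -> float:
    """Maximum per-nucleotide mass gain (g/mol) under full 15N labelling.

    Derived from per-base nitrogen counts (A/G: 5 N, T: 2 N, C: 3 N) by
    averaging complementary pairs: an A-T pair contributes
    (4.985 + 1.994)/2 per nucleotide and a G-C pair (4.985 + 2.991)/2.
    """
    _check_gc(gc)
    n = C.NITROGEN_MAX_PER_BASE
    at = n["A"] + n["T"]
    gc_pair = n["G"] + n["C"]
    return ((1.0 - gc) * at + gc * gc_pair) / 2.0


def carbon_max_increment(gc: float) -> float:
    """Maximum per-nucleotide mass gain (g/mol) under full 13C labelling."""
    _check_gc(gc)
    return C.CARBON_MAX_SLOPE * gc + C.CARBON_MAX_INTERCEPT


def max_heavy_mw_dual(gc: float, m_light: float, mode: str = "printed") -> float:
    """Theoretical maximum heavy MW under full 13C + 15N substitution.

    mode 'printed' uses the combined dual-isotope equation
    M_heavymax = 0.0025*G + 13.416 + M_light verbatim.  mode 'per_element'
    instead sums the carbon and nitrogen per-element maxima
    (-0.0002282*G + 13.464064 + M_light); the two are numerically close
    but not identical, and 'printed' is the analysis default.
    """
    _check_gc(gc)
    if mode == "printed":
        return C.DUAL_MAX_SLOPE * gc + C.DUAL_MAX_INTERCEPT + m_light
    if mode == "per_element":
        return m_light + carbon_max_increment(gc) + nitrogen_max_increment(gc)
    raise ParameterError(f"unknown max_heavy mode {mode!r}")


def max_heavy_mw(
    gc: float, m_light: float, isotopes: str = "CN", mode: str = "printed"
) -> float:
    """Maximum heavy MW for the configured isotope set.

    isotopes 'CN' is the dual-isotope default; 'C' reproduces the
    single-isotope (13C-only) qSIP maximum, in which case the statistic
    returned downstream is the classic atom-fraction-excess-style ratio.
    """
    if isotopes == "CN":
        return max_heavy_mw_dual(gc, m_light, mode=mode)
    if isotopes == "C":
        _check_gc(gc)
        return m_light + carbon_max_increment(gc)
    raise ParameterError(f"unknown isotope set {isotopes!r}; use 'CN' or 'C'")


def molecular_weight_excess(m_lab: float, m_light: float, m_heavymax: float) -> float:
    """MWE: observed mass gain over the theoretical maximum gain.

    May be negative when the labelled treatment banded lighter; negative
    values are reported as-is (they are never active).
    """
    if m_heavymax <= m_light:
        raise InvalidStateError(
            f"m_heavymax ({m_heavymax}) must exceed m_light ({m_light})"
        )
    return (m_lab - m_light) / (m_heavymax - m_light)


def call_active(
    results: Sequence[QsipResult], threshold: float = C.DEFAULT_MWE_THRESHOLD
) -> list[QsipResult]:
    """Set the active flag: active iff MWE >= threshold (inclusive)."""
    return [replace(r, active=bool(r.mwe >= threshold)) for r in results]


def _check_gc(gc: float) -> None:
    if not (0.0 <= gc <= 1.0):
        raise ParameterError(f"GC proportion must be in [0, 1], got {gc}")


def _natural_abundance_offset(gc: float) -> float:
    """Expected natural-abundance heavy-isotope mass already in 'light' DNA.

    Optional correction only: subtracted from both M_lab and M_heavymax's
    gain when enabled, slightly rescaling MWE.
    """
    return NATURAL_13C * carbon_max_increment(gc) + NATURAL_15N * nitrogen_max_increment(
        gc
    )


def run_qsip(
    pair: TreatmentPair,
    copies_unlabelled: AbundanceTable,
    copies_labelled: AbundanceTable,
    counts: OTUCountTable | None = None,
    threshold: float = C.DEFAULT_MWE_THRESHOLD,
    isotopes: str = "CN",
    max_heavy_mode: str = "printed",
    natural_abundance_correction: bool = False,
) -> tuple[list[QsipResult], dict[str, str]]:
    """Run the full per-OTU qSIP chain over a treatment pair.

    ``copies_unlabelled`` / ``copies_labelled`` are absolute-copy tables
    restricted to each member's fraction-samples.  OTUs must carry > 0
    copies in both members to be eligible; ineligible OTUs are excluded
    with a reason, never aborting the run.  Returns (results, exclusions).
    """
    dens_unlab = {f.sample_id: f.density for f in pair.unlabelled.fractions}
    dens_lab = {f.sample_id: f.density for f in pair.labelled.fractions}
    cols_unlab = [s for s in copies_unlabelled.sample_ids if s in dens_unlab]
    cols_lab = [s for s in copies_labelled.sample_ids if s in dens_lab]
    if not cols_unlab or not cols_lab:
        raise UndefinedResultError("no fraction-samples matched a treatment member")

    d_unlab = np.array([dens_unlab[s] for s in cols_unlab])
    d_lab = np.array([dens_lab[s] for s in cols_lab])

    otus = [o for o in copies_unlabelled.otu_ids if o in set(copies_labelled.otu_ids)]
    only_unlab = set(copies_unlabelled.otu_ids) - set(otus)
    only_lab = set(copies_labelled.otu_ids) - set(copies_unlabelled.otu_ids)

    results: list[QsipResult] = []
    exclusions: dict[str, str] = {}
    exclusions.update({o: "absent_in_labelled" for o in only_unlab})
    exclusions.update({o: "absent_in_unlabelled" for o in only_lab})

    for otu in otus:
        c_unlab = copies_unlabelled.values.loc[otu, cols_unlab].to_numpy(dtype=float)
        c_lab = copies_labelled.values.loc[otu, cols_lab].to_numpy(dtype=float)
        if c_unlab.sum() <= 0:
            exclusions[otu] = "absent_in_unlabelled"
            continue
        if c_lab.sum() <= 0:
            exclusions[otu] = "absent_in_labelled"
            continue
        try:
            w_light = weighted_average_density(c_unlab, d_unlab)
            w_lab = weighted_average_density(c_lab, d_lab)
            gc = gc_from_light_density(w_light)
            m_light = light_molecular_weight(gc)
            m_lab = labelled_molecular_weight(w_light, w_lab, m_light)
            m_heavymax = max_heavy_mw(gc, m_light, isotopes=isotopes, mode=max_heavy_mode)
            if natural_abundance_correction:
                offset = _natural_abundance_offset(gc)
                mwe = (m_lab - m_light) / (m_heavymax - m_light - offset)
            else:
                mwe = molecular_weight_excess(m_lab, m_light, m_heavymax)
        except (UndefinedResultError, InvalidStateError, ParameterError) as exc:
            exclusions[otu] = f"computation_failed: {exc}"
            log.info("OTU %s excluded: %s", otu, exc)
            continue
        lineage = counts.lineage(otu) if counts is not None else "Unassigned"
        results.append(
            QsipResult(
                otu_id=otu,
                substrate=pair.substrate,
                w_light=w_light,
                w_lab=w_lab,
                delta_w=w_lab - w_light,
                gc=gc,
                m_light=m_light,
                m_lab=m_lab,
                m_heavymax=m_heavymax,
                mwe=mwe,
                active=False,
                copies_unlabelled=float(c_unlab.sum()),
                copies_labelled=float(c_lab.sum()),
                lineage=lineage,
            )
        )
    if exclusions:
        log.info("run_qsip: excluded %d OTU(s)", len(exclusions))
    return call_active(results, threshold), exclusions


def bootstrap_mwe(
    pair: TreatmentPair,
    copies_unlabelled: AbundanceTable,
    copies_labelled: AbundanceTable,
    otu_id: str,
    n_boot: int = 999,
    seed: int | None = None,
    isotopes: str = "CN",
    max_heavy_mode: str = "printed",
) -> np.ndarray:
    """EXTENSION (off by default): fraction-resampling bootstrap of MWE.

    Resamples gradient fractions with replacement within each treatment
    and recomputes MWE.  Single gradients carry no biological replication,
    so this quantifies only within-gradient sampling spread; it is not
    part of the default analysis path.
    """
    rng = np.random.default_rng(seed)
    dens_unlab = {f.sample_id: f.density for f in pair.unlabelled.fractions}
    dens_lab = {f.sample_id: f.density for f in pair.labelled.fractions}
    cols_u = [s for s in copies_unlabelled.sample_ids if s in dens_unlab]
    cols_l = [s for s in copies_labelled.sample_ids if s in dens_lab]
    cu = copies_unlabelled.values.loc[otu_id, cols_u].to_numpy(dtype=float)
    cl = copies_labelled.values.loc[otu_id, cols_l].to_numpy(dtype=float)
    du = np.array([dens_unlab[s] for s in cols_u])
    dl = np.array([dens_lab[s] for s in cols_l])

    out = np.empty(n_boot)
    for b in range(n_boot):
        iu = rng.integers(0, len(cu), len(cu))
        il = rng.integers(0, len(cl), len(cl))
        try:
            wl = weighted_average_density(cu[iu], du[iu])
            wb = weighted_average_density(cl[il], dl[il])
            gc = gc_from_light_density(wl)
            ml = light_molecular_weight(gc)
            mlab = labelled_molecular_weight(wl, wb, ml)
            mmax = max_heavy_mw(gc, ml, isotopes=isotopes, mode=max_heavy_mode)
            out[b] = molecular_weight_excess(mlab, ml, mmax)
        except (UndefinedResultError, InvalidStateError):
            out[b] = np.nan
    return out
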