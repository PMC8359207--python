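"""End-to-end wiring: filtering -> normalization -> qSIP -> summaries.

The per-incubation steps (minimum-count filter, contaminant-taxon
removal, relative abundance, copy scaling) are applied independently to
each member of a treatment pair; OTUs that survive filtering in only one
member are excluded by the eligibility rule inside :func:`run_qsip` with
a recorded reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from . import constants as C
from .gradient_data import GradientProfile, OTUCountTable, TreatmentPair
from .preprocess import (
    DEFAULT_DROP_TAXA,
    DEFAULT_MIN_TOTAL,
    AbundanceTable,
    drop_taxa,
    filter_min_count,
    to_copies,
    to_relative,
)
from .qsip import QsipResult, run_qsip

log = logging.getLogger(__name__)


@dataclass
class PairAnalysis:
    """Everything produced for one treatment pair."""

    results: list[QsipResult]
    exclusions: dict[str, str]
    copies_unlabelled: AbundanceTable
    copies_labelled: AbundanceTable
    counts_unlabelled: OTUCountTable
    counts_labelled: OTUCountTable


def prepare_member(
    counts: OTUCountTable,
    profile: GradientProfile,
    min_total: int = DEFAULT_MIN_TOTAL,
    taxa: Iterable[str] = DEFAULT_DROP_TAXA,
) -> tuple[OTUCountTable, AbundanceTable]:
    """Filter and scale one incubation's counts to absolute copies."""
    member = counts.subset_samples(
        [s for s in profile.sample_ids if s in counts.counts.columns]
    )
    member = filter_min_count(member, member.sample_ids, min_total)
    member = drop_taxa(member, taxa)
    rel = to_relative(member)
    return member, to_copies(rel, profile)


def analyse_treatment_pair(
    pair: TreatmentPair,
    counts: OTUCountTable,
    min_total: int = DEFAULT_MIN_TOTAL,
    taxa: Iterable[str] = DEFAULT_DROP_TAXA,
    threshold: float = C.DEFAULT_MWE_THRESHOLD,
    isotopes: str = "CN",
    max_heavy_mode: str = "printed",
    natural_abundance_correction: bool = False,
) -> PairAnalysis:
    """Run the full analysis for one unlabelled/labelled pair."""
    counts_unlab, copies_unlab = prepare_member(
        counts, pair.unlabelled, min_total, taxa
    )
    counts_lab, copies_lab = prepare_member(counts, pair.labelled, min_total, taxa)
    results, exclusions = run_qsip(
        pair,
        copies_unlab,
        copies_lab,
        counts=counts,
        threshold=threshold,
        isotopes=isotopes,
        max_heavy_mode=max_heavy_mode,
        natural_abundance_correction=natural_abundance_correction,
    )
    log.info(
        "pair %s: %d OTU result(s), %d exclusion(s)",
        pair.substrate,
        len(results),
        len(exclusions),
    )
    return PairAnalysis(
        results=results,
        exclusions=exclusions,
        copies_unlabelled=copies_unlab,
        copies_labelled=copies_lab,
        counts_unlabelled=counts_unlab,
        counts_labelled=counts_lab,
    )


def analyse_simulation(sim, **kwargs) -> tuple[list[QsipResult], PairAnalysis]:
    """Convenience wrapper: analyse a SimulatedPair with default filters."""
    analysis = analyse_treatment_pair(sim.pair, sim.counts, **kwargs)
    return analysis.results, analysis


def pair_profiles(profiles: list[GradientProfile]) -> list[TreatmentPair]:
    """Group profiles into treatment pairs by substrate.

    Each substrate must contribute exactly one unlabelled and one labelled
    incubation.
    """
    from .errors import InputFormatError

    by_substrate: dict[str, dict[str, GradientProfile]] = {}
    for p in profiles:
        slot = by_substrate.setdefault(p.substrate, {})
        if p.isotope in slot:
            raise InputFormatError(
                f"substrate {p.substrate!r} has two {p.isotope!r} incubations"
            )
        slot[p.isotope] = p
    pairs = []
    for substrate, slot in sorted(by_substrate.items()):
        if set(slot) != {"unlabelled", "labelled"}:
            available = ", ".join(
                f"{p.incubation_id} ({p.isotope})" for p in profiles
            )
            raise InputFormatError(
                f"substrate {substrate!r} lacks a matched unlabelled/labelled "
                f"pair; available incubations: {available}"
            )
        pairs.append(TreatmentPair(unlabelled=slot["unlabelled"], labelled=slot["labelled"]))
    return pairs
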