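"""OTU filtering and abundance transforms ahead of the qSIP analysis.

Two mutually exclusive filtering modes mirror the two dataset types of a
SIP study: water-column amplicon libraries (singleton removal) and
gradient-fraction libraries (per-incubation minimum-count removal).
Contaminant lineages (Cyanobacteria by default, indistinguishable from
substrate-derived DNA) are dropped in either mode.  Counts are then
normalized to per-sample relative abundances and scaled to absolute 16S
copy numbers using each fraction's qPCR total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedResultError
from .gradient_data import GradientProfile, OTUCountTable

log = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 13
DEFAULT_DROP_TAXA = ("Cyanobacteria",)


@dataclass
class AbundanceTable:
    """Real-valued OTU x sample table; ``kind`` is 'relative' or 'copies'."""

    values: pd.DataFrame
    kind: str
    zero_samples: tuple[str, ...] = ()  # all-zero columns flagged at normalization

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def drop_singletons(table: OTUCountTable) -> OTUCountTable:
    """Remove OTUs whose total count across all samples is exactly 1.

    This is the water-column filtering rule; gradient incubations use
    :func:`filter_min_count` instead.
    """
    totals = table.counts.sum(axis=1)
    keep = totals[totals != 1].index
    removed = len(table.otu_ids) - len(keep)
    if removed:
        log.info("drop_singletons: removed %d singleton OTU(s)", removed)
    return table.subset_otus(keep)


def filter_min_count(
    table: OTUCountTable,
    incubation_samples: Sequence[str],
    min_total: int = DEFAULT_MIN_TOTAL,
) -> OTUCountTable:
    """Remove OTUs with fewer than ``min_total`` reads summed over one
    incubation's fraction-samples.

    The threshold of 13 matches the 13 gradient fractions per incubation:
    an OTU averaging under one read per fraction carries no usable band
    shape.  The comparison is strict (< min_total removed, == kept).
    """
    if min_total < 0:
        raise ParameterError(f"min_total must be >= 0, got {min_total}")
    cols = [s for s in incubation_samples if s in table.counts.columns]
    totals = table.counts[cols].sum(axis=1)
    keep = totals[totals >= min_total].index
    removed = len(table.otu_ids) - len(keep)
    if removed:
        log.info(
            "filter_min_count: removed %d OTU(s) with < %d reads over %d samples",
            removed,
            min_total,
            len(cols),
        )
    return table.subset_otus(keep)


def drop_taxa(
    table: OTUCountTable, labels: Iterable[str] = DEFAULT_DROP_TAXA
) -> OTUCountTable:
    """Remove OTUs whose lineage contains any label token at any rank.

    Matching is case-insensitive substring per rank, so SILVA-prefixed
    ranks like ``D_1__Cyanobacteria`` match the bare label.
    """
    labels = [str(lbl).lower() for lbl in labels]
    if not labels:
        return table

    def hit(otu: str) -> bool:
        ranks = [r.strip().lower() for r in table.lineage(otu).split(";")]
        return any(lbl in rank for lbl in labels for rank in ranks)

    keep = [o for o in table.otu_ids if not hit(o)]
    removed = len(table.otu_ids) - len(keep)
    if removed:
        log.info("drop_taxa: removed %d OTU(s) matching %s", removed, labels)
    return table.subset_otus(keep)


def to_relative(table: OTUCountTable) -> AbundanceTable:
    """Normalize each sample column to relative abundance (sums to 1).

    All-zero columns remain zero and are recorded in ``zero_samples``.
    """
    counts = table.counts.astype(float)
    sums = counts.sum(axis=0)
    zero = tuple(sums.index[sums == 0])
    if zero:
        log.warning("to_relative: %d all-zero sample column(s): %s", len(zero), zero)
    safe = sums.replace(0, 1.0)
    return AbundanceTable(values=counts / safe, kind="relative", zero_samples=zero)


def to_copies(rel: AbundanceTable, profile: GradientProfile) -> AbundanceTable:
    """Scale relative abundances to absolute 16S copies per fraction.

    Each cell becomes relative abundance x the fraction's qPCR total, so
    column sums reproduce the qPCR totals exactly.
    """
    if rel.kind != "relative":
        raise ParameterError(f"expected a relative table, got kind={rel.kind!r}")
    totals = {}
    for f in profile.fractions:
        totals[f.sample_id] = f.total_copies
    missing = [s for s in rel.sample_ids if s not in totals]
    if missing:
        raise UndefinedResultError(
            "sample(s) without a matching fraction record: " + ", ".join(missing)
        )
    scale = pd.Series({s: totals[s] for s in rel.sample_ids})
    return AbundanceTable(
        values=rel.values * scale, kind="copies", zero_samples=rel.zero_samples
    )


def prokaryote_abundance_per_litre(profile: GradientProfile) -> float:
    """Estimate total 16S copies per litre of source water for an incubation.

    The qPCR totals across fractions quantify the copies in the
    ``dna_loaded`` micrograms put on the gradient; scaling by the total DNA
    extracted and dividing by the filtered volume back-calculates a
    per-litre abundance.  This is an order-of-magnitude estimate, not an
    absolute count: the dominant error is the extraction yield itself.
    """
    if profile.dna_extracted is None or profile.volume_filtered is None:
        raise ParameterError(
            f"incubation {profile.incubation_id}: dna_extracted_ug and "
            "volume_filtered_l are required for a per-litre estimate"
        )
    if profile.dna_loaded <= 0:
        raise ParameterError("dna_loaded must be > 0")
    if profile.volume_filtered <= 0:
        raise ParameterError("volume_filtered must be > 0")
    total = float(np.sum(profile.total_copies))
    return total * (profile.dna_extracted / profile.dna_loaded) / profile.volume_filtered


def apply_filters(
    table: OTUCountTable,
    mode: str = "incubation",
    incubation_samples: Sequence[str] | None = None,
    min_total: int = DEFAULT_MIN_TOTAL,
    taxa: Iterable[str] = DEFAULT_DROP_TAXA,
) -> OTUCountTable:
    """Default filter pipeline: count filter (mode-dependent), then taxa.

    mode 'incubation' applies the per-incubation minimum-count rule over
    ``incubation_samples``; mode 'watercolumn' removes singletons.
    """
    if mode == "incubation":
        if incubation_samples is None:
            raise ParameterError("mode 'incubation' requires incubation_samples")
        table = filter_min_count(table, incubation_samples, min_total)
    elif mode == "watercolumn":
        table = drop_singletons(table)
    else:
        raise ParameterError(f"unknown filter mode {mode!r}")
    return drop_taxa(table, taxa)
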