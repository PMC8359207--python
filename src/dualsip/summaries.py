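"""Derived community-level summaries of qSIP results.

These reproduce the standard reporting shapes of a SIP study: a per-taxon
activity table (active OTU counts, read totals and percentages grouped by
phylum/class), shared-OTU fractions between incubations, copy-weighted
community densities, the partition of 16S copies into labelled vs total,
and per-OTU copy-vs-density curves for gradient plots.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedResultError
from .gradient_data import OTUCountTable
from .preprocess import AbundanceTable
from .qsip import QsipResult

ACTIVITY_COLUMNS = [
    "domain",
    "phylum",
    "class",
    "n_active_otus",
    "total_sequences",
    "percent_active",
]


def _split_lineage(lineage: str) -> tuple[str, str, str]:
    ranks = [r.strip() for r in lineage.split(";")]

    def rank(i: int) -> str:
        if i < len(ranks) and ranks[i]:
            # tolerate SILVA export prefixes like "D_1__Proteobacteria"
            token = ranks[i]
            if "__" in token:
                token = token.split("__", 1)[1] or "Unassigned"
            return token
        return "Unassigned"

    return rank(0), rank(1), rank(2)


def activity_table(
    results: Sequence[QsipResult], counts: OTUCountTable
) -> pd.DataFrame:
    """Per-(domain, phylum, class) summary of active OTUs.

    ``total_sequences`` sums the read counts of each group's active OTUs
    over the count table's samples; ``percent_active`` is the group's share
    of all active OTUs and sums to 100.  Rows are ordered Bacteria first,
    then Archaea, then other domains, alphabetically within each.
    """
    active = [r for r in results if r.active]
    if not active:
        return pd.DataFrame(columns=ACTIVITY_COLUMNS)

    read_totals = counts.counts.sum(axis=1)
    rows: dict[tuple[str, str, str], dict] = {}
    for r in active:
        key = _split_lineage(r.lineage)
        row = rows.setdefault(key, {"n_active_otus": 0, "total_sequences": 0})
        row["n_active_otus"] += 1
        row["total_sequences"] += int(read_totals.get(r.otu_id, 0))

    n_active = len(active)
    records = [
        {
            "domain": dom,
            "phylum": phy,
            "class": cls,
            "n_active_otus": v["n_active_otus"],
            "total_sequences": v["total_sequences"],
            "percent_active": 100.0 * v["n_active_otus"] / n_active,
        }
        for (dom, phy, cls), v in rows.items()
    ]
    df = pd.DataFrame(records, columns=ACTIVITY_COLUMNS)
    domain_order = {"bacteria": 0, "archaea": 1}
    df["_ord"] = df["domain"].str.lower().map(domain_order).fillna(2)
    df = (
        df.sort_values(["_ord", "phylum", "class"])
        .drop(columns="_ord")
        .reset_index(drop=True)
    )
    return df


def shared_otu_fraction(
    set_a: Iterable[str], set_b: Iterable[str], denominator: str = "union"
) -> float:
    """Percentage of OTUs shared between two sets.

    ``denominator`` selects what the intersection is divided by: the union
    (default) or one of the two sets.
    """
    a, b = set(set_a), set(set_b)
    denom = {"union": a | b, "set_a": a, "set_b": b}.get(denominator)
    if denom is None:
        raise UndefinedResultError(f"unknown denominator {denominator!r}")
    if not denom:
        raise UndefinedResultError("shared fraction undefined: empty denominator set")
    return 100.0 * len(a & b) / len(denom)


def community_weighted_density(
    results: Sequence[QsipResult],
    which: str = "active",
    weighting: str = "copies",
) -> float:
    """Mean labelled-treatment density (W_lab) over a subset of OTUs.

    ``which`` selects 'active' OTUs or 'all'; ``weighting`` is 'copies'
    (weights = labelled-incubation copy totals) or 'unweighted'.
    """
    if which == "active":
        sel = [r for r in results if r.active]
    elif which == "all":
        sel = list(results)
    else:
        raise UndefinedResultError(f"unknown selection {which!r}")
    if not sel:
        raise UndefinedResultError(f"no OTUs selected for which={which!r}")
    w_lab = np.array([r.w_lab for r in sel])
    if weighting == "copies":
        w = np.array([r.copies_labelled for r in sel])
        if w.sum() <= 0:
            raise UndefinedResultError("copy weights sum to zero")
        return float((w_lab * w).sum() / w.sum())
    if weighting == "unweighted":
        return float(w_lab.mean())
    raise UndefinedResultError(f"unknown weighting {weighting!r}")


def labelled_copy_partition(
    results: Sequence[QsipResult], copies: AbundanceTable
) -> tuple[float, float]:
    """(copies assigned to active OTUs, total copies) over a copies table."""
    active_ids = {r.otu_id for r in results if r.active}
    total = float(copies.values.to_numpy().sum())
    mask = [o in active_ids for o in copies.otu_ids]
    active_total = float(copies.values.loc[mask].to_numpy().sum())
    return active_total, total


def gradient_profile_curves(
    otu_id: str,
    copies_by_treatment: dict[str, AbundanceTable],
    densities_by_treatment: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Per-treatment copy-vs-density curves for one OTU, raw and max-normalized.

    Returns a long table (otu_id, treatment, density, copies, normalized)
    sorted by density within treatment; ``normalized`` divides by the
    treatment's maximum so curves plot on a common (0, 1] scale.
    """
    frames = []
    for treatment, table in copies_by_treatment.items():
        dens = densities_by_treatment[treatment]
        cols = [s for s in table.sample_ids if s in dens]
        series = table.values.loc[otu_id, cols].to_numpy(dtype=float)
        if series.max() <= 0:
            raise UndefinedResultError(
                f"OTU {otu_id}: all-zero copy series in treatment {treatment!r}"
            )
        df = pd.DataFrame(
            {
                "otu_id": otu_id,
                "treatment": treatment,
                "density": [dens[s] for s in cols],
                "copies": series,
                "normalized": series / series.max(),
            }
        ).sort_values("density")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
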