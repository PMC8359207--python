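"""Data model and file I/O for fraction-resolved SIP experiments.

An incubation's CsCl gradient is represented as a :class:`GradientProfile`
(an ordered list of :class:`FractionRecord`), read counts as an
:class:`OTUCountTable` (pandas DataFrame of OTUs x fraction-samples with
taxonomy attached), and a matched unlabelled/labelled incubation as a
:class:`TreatmentPair`.

File formats are deliberately plain: fraction metadata as CSV/TSV, OTU
tables as the classic tab-separated OTU-rows x sample-columns layout, and
taxonomy as two-column TSV with semicolon-delimited SILVA-style lineages.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_DNA_LOADED_UG,
    MAX_PLAUSIBLE_DENSITY,
    MIN_PLAUSIBLE_DENSITY,
)
from .errors import InputFormatError

log = logging.getLogger(__name__)

UNASSIGNED_LINEAGE = "Unassigned"

METADATA_COLUMNS = [
    "sample_id",
    "incubation_id",
    "substrate",
    "isotope",
    "fraction_index",
    "density_g_per_ml",
    "total_16s_copies",
]

#: optional per-incubation metadata columns (repeated on every row)
OPTIONAL_METADATA_COLUMNS = ["dna_loaded_ug", "dna_extracted_ug", "volume_filtered_l"]

RESULT_COLUMNS = [
    "otu_id",
    "substrate",
    "w_light",
    "w_lab",
    "delta_w",
    "gc",
    "m_light",
    "m_lab",
    "m_heavymax",
    "mwe",
    "active",
    "copies_labelled",
    "copies_unlabelled",
    "lineage",
]


@dataclass(frozen=True)
class FractionRecord:
    """One gradient fraction: its density and total 16S copy load.

    ``fraction_index`` is 1-based with 1 = the heaviest (first collected)
    fraction by convention; the analysis itself is order-invariant.
    """

    sample_id: str
    incubation_id: str
    fraction_index: int
    density: float
    total_copies: float

    def __post_init__(self) -> None:
        if not (MIN_PLAUSIBLE_DENSITY <= self.density <= MAX_PLAUSIBLE_DENSITY):
            raise InputFormatError(
                f"fraction {self.sample_id}: density {self.density:.4f} g/ml outside "
                f"plausible CsCl range [{MIN_PLAUSIBLE_DENSITY}, {MAX_PLAUSIBLE_DENSITY}]"
            )
        if self.total_copies < 0:
            raise InputFormatError(
                f"fraction {self.sample_id}: negative total_copies {self.total_copies}"
            )


@dataclass
class GradientProfile:
    """One incubation's ordered set of density fractions."""

    incubation_id: str
    substrate: str
    isotope: str  # "unlabelled" or "labelled"
    fractions: list[FractionRecord] = field(default_factory=list)
    dna_loaded: float = DEFAULT_DNA_LOADED_UG  # ug on the gradient
    dna_extracted: float | None = None  # ug from the incubation
    volume_filtered: float | None = None  # litres

    def __post_init__(self) -> None:
        idx = [f.fraction_index for f in self.fractions]
        if len(set(idx)) != len(idx):
            raise InputFormatError(
                f"incubation {self.incubation_id}: duplicate fraction_index values"
            )
        n_pos = sum(1 for f in self.fractions if f.total_copies > 0)
        if self.fractions and n_pos < 3:
            raise InputFormatError(
                f"incubation {self.incubation_id}: only {n_pos} fractions with "
                "total_copies > 0; at least 3 are needed for a weighted density"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [f.sample_id for f in self.fractions]

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.density for f in self.fractions])

    @property
    def total_copies(self) -> np.ndarray:
        return np.array([f.total_copies for f in self.fractions])

    def density_of(self, sample_id: str) -> float:
        for f in self.fractions:
            if f.sample_id == sample_id:
                return f.density
        raise KeyError(sample_id)


@dataclass
class OTUCountTable:
    """Integer read counts per OTU per fraction-sample, with taxonomy.

    ``counts`` is a DataFrame indexed by OTU id with sample-id columns.
    The simulator's analytic mode may produce real-valued expected counts;
    file readers enforce integers.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise InputFormatError(f"duplicate OTU id(s): {', '.join(map(str, dups))}")
        if (self.counts.to_numpy() < 0).any():
            raise InputFormatError("negative counts in OTU table")
        for otu in self.counts.index:
            if otu not in self.taxonomy:
                self.taxonomy[otu] = UNASSIGNED_LINEAGE

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def lineage(self, otu_id: str) -> str:
        return self.taxonomy.get(otu_id, UNASSIGNED_LINEAGE)

    def subset_otus(self, otu_ids: Iterable[str]) -> "OTUCountTable":
        keep = [o for o in self.otu_ids if o in set(otu_ids)]
        return OTUCountTable(
            counts=self.counts.loc[keep].copy(),
            taxonomy={o: self.taxonomy[o] for o in keep},
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OTUCountTable":
        return OTUCountTable(
            counts=self.counts[list(sample_ids)].copy(), taxonomy=dict(self.taxonomy)
        )


@dataclass
class TreatmentPair:
    """Matched unlabelled and labelled incubations of the same substrate."""

    unlabelled: GradientProfile
    labelled: GradientProfile

    def __post_init__(self) -> None:
        if self.unlabelled.substrate != self.labelled.substrate:
            raise InputFormatError(
                "treatment pair members must share a substrate: "
                f"{self.unlabelled.substrate!r} vs {self.labelled.substrate!r}"
            )
        if self.unlabelled.isotope == self.labelled.isotope:
            raise InputFormatError(
                "treatment pair members must differ in isotope label"
            )

    @property
    def substrate(self) -> str:
        return self.unlabelled.substrate


def _parse_float(value: str, what: str, line_no: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise InputFormatError(
            f"non-numeric {what} {value!r} on line {line_no}"
        ) from None


def read_fraction_metadata(path: str | Path) -> list[GradientProfile]:
    """Read fraction metadata (CSV or TSV) into GradientProfiles.

    Rows are grouped by ``incubation_id``; fraction order within a profile
    follows ``fraction_index``.  Optional columns ``dna_loaded_ug``,
    ``dna_extracted_ug`` and ``volume_filtered_l`` are picked up when
    present.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if sample.count("\t") >= sample.count(",") else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in METADATA_COLUMNS:
            if col not in header:
                raise InputFormatError(f"fraction metadata missing column {col!r}")
        rows = list(reader)

    groups: dict[str, dict] = {}
    for i, row in enumerate(rows):
        line_no = i + 2  # header is line 1
        inc = row["incubation_id"]
        rec = FractionRecord(
            sample_id=row["sample_id"],
            incubation_id=inc,
            fraction_index=int(
                _parse_float(row["fraction_index"], "fraction_index", line_no)
            ),
            density=_parse_float(row["density_g_per_ml"], "density", line_no),
            total_copies=_parse_float(
                row["total_16s_copies"], "total_16s_copies", line_no
            ),
        )
        g = groups.setdefault(
            inc,
            {
                "substrate": row["substrate"],
                "isotope": row["isotope"],
                "fractions": [],
                "extra": {},
            },
        )
        g["fractions"].append(rec)
        for col in OPTIONAL_METADATA_COLUMNS:
            if col in row and row[col] not in (None, ""):
                g["extra"][col] = _parse_float(row[col], col, line_no)

    profiles = []
    for inc, g in groups.items():
        extra = g["extra"]
        profiles.append(
            GradientProfile(
                incubation_id=inc,
                substrate=g["substrate"],
                isotope=g["isotope"],
                fractions=sorted(g["fractions"], key=lambda f: f.fraction_index),
                dna_loaded=extra.get("dna_loaded_ug", DEFAULT_DNA_LOADED_UG),
                dna_extracted=extra.get("dna_extracted_ug"),
                volume_filtered=extra.get("volume_filtered_l"),
            )
        )
    return profiles


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column (otu_id, lineage) TSV into a mapping."""
    taxonomy: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.lower().startswith("otu_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputFormatError(f"taxonomy line lacks a lineage: {line!r}")
            taxonomy[parts[0]] = parts[1]
    return taxonomy


def read_otu_table(path: str | Path, taxonomy_path: str | Path | None = None) -> OTUCountTable:
    """Read a classic OTU table (TSV, OTU rows x sample columns).

    The transposed layout (sample rows x OTU columns) is auto-detected from
    the top-left header token: ``otu_id`` means OTU rows, ``sample_id``
    means sample rows.  Counts must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    corner = (df.index.name or "").strip().lower()
    if corner == "sample_id":
        df = df.T
    df.index = df.index.astype(str)

    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise InputFormatError("OTU table contains non-numeric cells")
    if (values < 0).any():
        raise InputFormatError("OTU table contains negative counts")
    if not np.allclose(values, np.round(values)):
        raise InputFormatError("OTU table contains fractional counts")
    df = df.round().astype(np.int64)

    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else {}
    missing = [o for o in df.index if o not in taxonomy]
    if taxonomy and missing:
        log.warning(
            "%d OTU(s) absent from taxonomy, assigned %r: %s",
            len(missing),
            UNASSIGNED_LINEAGE,
            ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
        )
    return OTUCountTable(counts=df, taxonomy=taxonomy)


def join_samples_to_fractions(
    table: OTUCountTable, profiles: Sequence[GradientProfile]
) -> dict[str, FractionRecord]:
    """Map every sample column to exactly one FractionRecord, or fail."""
    lookup: dict[str, FractionRecord] = {}
    for p in profiles:
        for f in p.fractions:
            if f.sample_id in lookup:
                raise InputFormatError(f"sample_id {f.sample_id!r} appears in two profiles")
            lookup[f.sample_id] = f
    unmatched = [s for s in table.sample_ids if s not in lookup]
    if unmatched:
        raise InputFormatError(
            "OTU-table sample(s) with no fraction metadata: " + ", ".join(unmatched)
        )
    return {s: lookup[s] for s in table.sample_ids}


def write_results(results, path: str | Path) -> None:
    """Write per-OTU qSIP results as TSV (one row per OTU).

    Numeric values are written with 10 significant digits so the file
    round-trips through :func:`read_results` to well below 1e-9.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "otu_id": r.otu_id,
                "substrate": r.substrate,
                "w_light": r.w_light,
                "w_lab": r.w_lab,
                "delta_w": r.delta_w,
                "gc": r.gc,
                "m_light": r.m_light,
                "m_lab": r.m_lab,
                "m_heavymax": r.m_heavymax,
                "mwe": r.mwe,
                "active": r.active,
                "copies_labelled": r.copies_labelled,
                "copies_unlabelled": r.copies_unlabelled,
                "lineage": r.lineage,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"results file missing column(s): {', '.join(missing)}")
    return df
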