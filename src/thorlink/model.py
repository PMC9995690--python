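"""Shared data containers for the export-flux / community-connectivity pipeline.

The pipeline couples two observation types from the same stations:

* depth profiles of total ``234Th`` activity (with 1-sigma counting errors)
  and salinity, from which particle export fluxes are estimated, and
* a samples-by-OTUs count table of 16S amplicon reads, size-fractionated at
  0.2-0.8, 0.8-53 and >53 um (labelled by the nominal lower pore size), with
  station / depth / filtered-volume metadata per sample.

Everything downstream operates on the validated containers defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Nominal lower pore sizes (um) of the three sequential filtration classes.
FRACTIONS: tuple[float, ...] = (0.2, 0.8, 53.0)

#: Taxonomic ranks carried by a lineage, in order.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """Raised when an input file or container violates the data contract."""


class Lineage(NamedTuple):
    domain: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str

    @classmethod
    def from_parts(cls, parts: Sequence[str]) -> "Lineage":
        """Build a lineage from up to six ranked names, padding the rest."""
        cleaned = [p.strip() for p in parts if p.strip()][: len(RANKS)]
        cleaned += [UNCLASSIFIED] * (len(RANKS) - len(cleaned))
        return cls(*cleaned)

    def at_rank(self, rank: str) -> str:
        if rank == "class":
            return self.class_
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, rank)


@dataclass(frozen=True)
class SampleRecord:
    """Station / depth / size-fraction / filtered-volume annotation of a sample."""

    sample_id: str
    station: str
    depth: float  # m, positive downward
    fraction: float  # one of FRACTIONS (nominal lower pore size, um)
    volume: float  # filtered seawater, L

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: depth must be > 0 m, got {self.depth}"
            )
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: fraction {self.fraction!r} is not one "
                f"of the filtration classes {FRACTIONS}"
            )
        if self.volume <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: volume must be > 0 L, got {self.volume}"
            )


@dataclass
class OtuTable:
    """Integer count matrix of samples x OTUs.

    Invariants enforced at construction: unique sample and OTU identifiers,
    all counts non-negative integers, and every sample total > 0.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers in OTU table")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU identifiers in OTU table")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9, equal_nan=False):
                raise ValidationError("OTU counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("OTU counts must be non-negative")
        if (counts.sum(axis=1) == 0).any():
            empty = [s for s, t in zip(self.sample_ids, counts.sum(axis=1)) if t == 0]
            raise ValidationError(f"samples with zero total reads: {empty}")
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def totals(self) -> np.ndarray:
        """Per-sample read totals, in sample order."""
        return self.counts.sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[idx])

    def drop_empty_otus(self) -> "OtuTable":
        """Drop OTU columns whose counts are zero in every sample."""
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(
            list(self.sample_ids),
            [o for o, k in zip(self.otu_ids, keep) if k],
            self.counts[:, keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Samples-as-rows DataFrame view of the counts."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class TaxonomyMap:
    """OTU id -> ranked lineage, with validation flags.

    ``chloroplast_flagged`` lists OTUs whose lineage mentions chloroplasts;
    these should have been removed upstream, so their presence is reported
    (not fatal).  OTUs absent from the map are treated as unclassified.
    """

    lineages: dict[str, Lineage] = field(default_factory=dict)
    chloroplast_flagged: set[str] = field(default_factory=set)
    malformed: set[str] = field(default_factory=set)

    def lineage(self, otu_id: str) -> Lineage:
        return self.lineages.get(otu_id, Lineage.from_parts([]))

    def rank_of(self, otu_id: str, rank: str) -> str:
        return self.lineage(otu_id).at_rank(rank)

    def validation_summary(self) -> dict[str, int]:
        return {
            "n_lineages": len(self.lineages),
            "n_chloroplast_flagged": len(self.chloroplast_flagged),
            "n_malformed": len(self.malformed),
        }


@dataclass
class RadionuclideProfile:
    """Depth-ordered total 234Th activities and salinity for one station.

    Activities are in dpm per litre with 1-sigma counting uncertainties;
    salinity in g/kg is used to derive the conservative 238U activity.
    """

    station: str
    depths: np.ndarray  # m, strictly increasing
    th234: np.ndarray  # dpm L^-1
    th234_sigma: np.ndarray  # 1-sigma, dpm L^-1
    salinity: np.ndarray  # g/kg

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.th234 = np.asarray(self.th234, dtype=float)
        self.th234_sigma = np.asarray(self.th234_sigma, dtype=float)
        self.salinity = np.asarray(self.salinity, dtype=float)
        n = self.depths.size
        if n < 3:
            raise ValidationError(
                f"station {self.station!r}: a profile needs >= 3 depths, got {n}"
            )
        for name, arr in (
            ("th234", self.th234),
            ("th234_sigma", self.th234_sigma),
            ("salinity", self.salinity),
        ):
            if arr.shape != self.depths.shape:
                raise ValidationError(
                    f"station {self.station!r}: {name} length {arr.size} != "
                    f"depths length {n}"
                )
        if not np.all(np.diff(self.depths) > 0):
            raise ValidationError(
                f"station {self.station!r}: depths must be strictly increasing "
                "(duplicate or unsorted depths)"
            )
        if (self.depths < 0).any():
            raise ValidationError(f"station {self.station!r}: depths must be >= 0 m")
        if (self.th234 <= 0).any():
            raise ValidationError(f"station {self.station!r}: activities must be > 0")
        if (self.th234_sigma < 0).any():
            raise ValidationError(f"station {self.station!r}: sigmas must be >= 0")


@dataclass(frozen=True)
class SurfaceInventory:
    """Depth-integrated upper-water-column chlorophyll-a and POC stocks."""

    station: str
    chla_stock: float  # mg Chl-a m^-2
    poc_stock: float  # mg C m^-2

    def __post_init__(self) -> None:
        if self.chla_stock < 0 or self.poc_stock < 0:
            raise ValidationError(
                f"station {self.station!r}: stocks must be >= 0, got "
                f"chla={self.chla_stock}, poc={self.poc_stock}"
            )


def metadata_by_sample(records: Iterable[SampleRecord]) -> dict[str, SampleRecord]:
    """Index metadata records by sample id, rejecting duplicates."""
    out: dict[str, SampleRecord] = {}
    for rec in records:
        if rec.sample_id in out:
            raise ValidationError(f"duplicate sample id in metadata: {rec.sample_id!r}")
        out[rec.sample_id] = rec
    return out


def check_table_metadata(
    table: OtuTable, metadata: Mapping[str, SampleRecord]
) -> list[str]:
    """Cross-check an OTU table against sample metadata.

    Samples present in the table but missing from the metadata are an error;
    metadata rows without a matching table column (e.g. collected but never
    sequenced samples) produce a warning and are returned.
    """
    missing_meta = [s for s in table.sample_ids if s not in metadata]
    if missing_meta:
        raise ValidationError(f"samples without metadata: {missing_meta}")
    unsequenced = sorted(set(metadata) - set(table.sample_ids))
    if unsequenced:
        warnings.warn(
            f"{len(unsequenced)} metadata rows have no counts (not sequenced): "
            f"{unsequenced}",
            stacklevel=2,
        )
    return unsequenced
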