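"""Community-structure computations on size-fractionated OTU tables.

Implements the statistics used to quantify vertical connectivity of
prokaryotic communities: rarefaction to a common read depth, per-sample OTU
richness, taxonomic aggregation at a chosen rank, Bray-Curtis dissimilarity,
ANOSIM permutation tests, surface-to-depth dissimilarity per station and
size fraction, and the fractions of surface-derived and station-unique OTUs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.stats import rankdata

from .model import (
    OtuTable,
    SampleRecord,
    TaxonomyMap,
    UNCLASSIFIED,
    ValidationError,
)

# ---------------------------------------------------------------------------
# rarefaction


@dataclass
class RarefiedTable:
    """An OTU table subsampled without replacement to a common read depth.

    Samples whose total is at or below the target depth are retained
    unchanged (so retained totals equal ``min(depth, original total)``),
    unless ``drop_below_depth`` was requested, in which case they are listed
    in ``dropped_samples``.  OTUs left with all-zero counts are removed.
    """

    table: OtuTable
    rarefaction_depth: int
    seed: int
    dropped_samples: list[str] = field(default_factory=list)


def rarefy(
    table: OtuTable,
    depth: int = 5000,
    seed: int = 0,
    drop_below_depth: bool = False,
) -> RarefiedTable:
    """Rarefy each sample to ``depth`` reads without replacement.

    Per-sample subsampling is multivariate hypergeometric (draw ``depth``
    reads from the sample's read pool).  Each sample gets a deterministic
    substream spawned from ``seed`` and its position, so results do not
    depend on which other samples are present.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be > 0")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(table.n_samples)
    new_counts = np.zeros_like(table.counts)
    keep_samples = np.ones(table.n_samples, dtype=bool)
    dropped: list[str] = []
    for i, (row, ss) in enumerate(zip(table.counts, streams)):
        total = int(row.sum())
        if total <= depth:
            if drop_below_depth and total < depth:
                keep_samples[i] = False
                dropped.append(table.sample_ids[i])
            else:
                new_counts[i] = row
            continue
        rng = np.random.default_rng(ss)
        new_counts[i] = rng.multivariate_hypergeometric(row, depth)
    sample_ids = [s for s, k in zip(table.sample_ids, keep_samples) if k]
    sub = OtuTable(sample_ids, list(table.otu_ids), new_counts[keep_samples])
    return RarefiedTable(
        table=sub.drop_empty_otus(),
        rarefaction_depth=depth,
        seed=seed,
        dropped_samples=dropped,
    )


def richness(table: OtuTable, rarefied: bool = True) -> pd.Series:
    """Observed OTUs (count > 0) per sample.

    Richness is only comparable across samples at equal read depth; pass
    ``rarefied=False`` to acknowledge (with a warning) an unrarefied input.
    """
    if not rarefied:
        warnings.warn(
            "richness on an unrarefied table is confounded by library size",
            stacklevel=2,
        )
    return pd.Series(
        (table.counts > 0).sum(axis=1), index=table.sample_ids, name="richness"
    )


# ---------------------------------------------------------------------------
# taxonomic aggregation


@dataclass
class AggregatedTable:
    """Counts summed to a taxonomic rank, with relative abundances.

    ``counts``: taxa x samples; ``relative``: per-sample proportions summing
    to 1; ``overall``: taxon total / grand total across all samples.
    """

    rank: str
    counts: pd.DataFrame
    relative: pd.DataFrame
    overall: pd.Series


def aggregate_taxonomy(
    table: OtuTable, taxmap: TaxonomyMap, rank: str = "class"
) -> AggregatedTable:
    """Sum OTU counts to ``rank``; unclassified OTUs pool into one row."""
    labels = [taxmap.rank_of(o, rank) or UNCLASSIFIED for o in table.otu_ids]
    df = pd.DataFrame(table.counts.T, index=labels, columns=table.sample_ids)
    counts = df.groupby(level=0, sort=True).sum()
    col_tot = counts.sum(axis=0)
    relative = counts / col_tot
    overall = counts.sum(axis=1) / counts.values.sum()
    return AggregatedTable(
        rank=rank, counts=counts, relative=relative, overall=overall.rename("overall")
    )


# ---------------------------------------------------------------------------
# dissimilarity


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("vectors must have equal length")
    if (xa < 0).any() or (ya < 0).any():
        raise ValidationError("abundance vectors must be non-negative")
    if xa.sum() == 0 and ya.sum() == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(xa, ya))


def bray_curtis_matrix(table: OtuTable) -> pd.DataFrame:
    """All-pairs Bray-Curtis distance matrix of the table's samples."""
    from scipy.spatial.distance import pdist, squareform

    dm = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return pd.DataFrame(dm, index=table.sample_ids, columns=table.sample_ids)


@dataclass(frozen=True)
class DissimilarityRecord:
    """Bray-Curtis distance of a deeper community to its stratum's surface."""

    station: str
    fraction: float
    depth_deep: float  # m
    depth_surface: float  # m (the stratum's shallowest sample)
    bray_curtis: float


def vertical_dissimilarity(
    table: OtuTable, metadata: Mapping[str, SampleRecord]
) -> list[DissimilarityRecord]:
    """Surface-to-depth Bray-Curtis within each (station, fraction) stratum.

    The reference community is the stratum's shallowest sample (5 m in the
    study design); one record is produced per deeper sample.  Strata with a
    single sample yield no records and a warning.
    """
    strata: dict[tuple[str, float], list[SampleRecord]] = {}
    for sid in table.sample_ids:
        rec = metadata.get(sid)
        if rec is None:
            raise ValidationError(f"sample {sid!r} missing from metadata")
        strata.setdefault((rec.station, rec.fraction), []).append(rec)
    records: list[DissimilarityRecord] = []
    for (station, fraction), recs in sorted(strata.items()):
        recs = sorted(recs, key=lambda r: r.depth)
        if len(recs) < 2:
            warnings.warn(
                f"stratum (station={station}, fraction={fraction:g}) has a "
                "single sample; no vertical dissimilarity computed",
                stacklevel=2,
            )
            continue
        surface = table.sample_counts(recs[0].sample_id)
        for deep in recs[1:]:
            records.append(
                DissimilarityRecord(
                    station=station,
                    fraction=fraction,
                    depth_deep=deep.depth,
                    depth_surface=recs[0].depth,
                    bray_curtis=bray_curtis(surface, table.sample_counts(deep.sample_id)),
                )
            )
    return records


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM statistic R in [-1, 1] with its permutation p-value."""

    R: float
    p_value: float
    n_permutations: int
    grouping_label: str
    method: str  # "exact" (full enumeration) or "montecarlo"


def _anosim_r(condensed_ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    """R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)."""
    r_within = condensed_ranks[within_mask].mean()
    r_between = condensed_ranks[~within_mask].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def _multiset_permutations_count(group_sizes: Sequence[int]) -> int:
    total = math.factorial(sum(group_sizes))
    for g in group_sizes:
        total //= math.factorial(g)
    return total


def _multiset_permutations(pool: dict[int, int], n: int):
    """Yield all distinct orderings of a multiset given as {value: count}."""
    if n == 0:
        yield []
        return
    for v in sorted(pool):
        if pool[v] == 0:
            continue
        pool[v] -= 1
        for rest in _multiset_permutations(pool, n - 1):
            yield [v] + rest
        pool[v] += 1


def anosim(
    distance_matrix: np.ndarray | pd.DataFrame,
    groups: Sequence[object],
    n_permutations: int = 999,
    seed: int = 0,
    grouping_label: str = "",
    exhaustive_limit: int = 10_000,
) -> AnosimResult:
    """ANOSIM permutation test on a square symmetric distance matrix.

    R compares mean between-group and within-group mid-ranks of all
    off-diagonal distances, normalised by n(n-1)/4 so perfectly separated
    groups give R = 1.  When the number of distinct group labelings is at
    most ``exhaustive_limit`` the null distribution is enumerated exactly and
    ``p = #(R_perm >= R_obs) / #labelings``; otherwise ``n_permutations``
    random label shuffles give ``p = (1 + #(R_perm >= R_obs)) /
    (1 + n_permutations)``.
    """
    dm = np.asarray(
        distance_matrix.values if isinstance(distance_matrix, pd.DataFrame) else distance_matrix,
        dtype=float,
    )
    n = dm.shape[0]
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    labels = np.asarray(groups)
    if labels.size != n:
        raise ValidationError("group labels must match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or (counts < 2).any():
        raise ValidationError(
            "ANOSIM needs >= 2 groups with >= 2 members each; got sizes "
            f"{dict(zip(uniq.tolist(), counts.tolist()))}"
        )
    iu, ju = np.triu_indices(n, k=1)
    condensed = dm[iu, ju]
    ranks = rankdata(condensed)  # mid-ranks for ties

    codes = np.searchsorted(uniq, labels)

    def r_for(codes_vec: np.ndarray) -> float:
        within = codes_vec[iu] == codes_vec[ju]
        return _anosim_r(ranks, within, n)

    r_obs = r_for(codes)

    n_distinct = _multiset_permutations_count(counts.tolist())
    if n_distinct <= exhaustive_limit:
        pool = {int(c): int(k) for c, k in zip(np.unique(codes), counts)}
        hits = 0
        total = 0
        for perm in _multiset_permutations(pool, n):
            total += 1
            if r_for(np.asarray(perm)) >= r_obs - 1e-12:
                hits += 1
        return AnosimResult(
            R=float(r_obs),
            p_value=hits / total,
            n_permutations=total,
            grouping_label=grouping_label,
            method="exact",
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if r_for(rng.permutation(codes)) >= r_obs - 1e-12:
            hits += 1
    return AnosimResult(
        R=float(r_obs),
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        grouping_label=grouping_label,
        method="montecarlo",
    )


# ---------------------------------------------------------------------------
# surface-derived and station-unique OTU fractions


@dataclass(frozen=True)
class SurfaceDerivedRecord:
    """Share of a mesopelagic community already present in surface waters."""

    station: str
    fraction: float
    depth: float  # m (mesopelagic sample depth)
    pct_otus_surface_derived: float  # % of the community's observed OTUs
    pct_seqs_surface_derived: float  # % of its reads


def surface_derived_fraction(
    table: OtuTable,
    metadata: Mapping[str, SampleRecord],
    surface_max_depth: float = 100.0,
    meso_min_depth: float = 500.0,
    surface_inclusive: bool = True,
    surface_pool: str = "station",
) -> list[SurfaceDerivedRecord]:
    """Surface-derived OTU and sequence percentages per mesopelagic sample.

    A mesopelagic OTU counts as surface-derived when it is present in any
    surface sample (depth <= ``surface_max_depth``, or strictly < when
    ``surface_inclusive=False``) of the same size fraction — by default
    within the same station (``surface_pool="station"``), or in any station
    with ``surface_pool="global"``.
    """
    if surface_pool not in ("station", "global"):
        raise ValidationError("surface_pool must be 'station' or 'global'")
    recs = [metadata[s] for s in table.sample_ids]

    def is_surface(r: SampleRecord) -> bool:
        return (
            r.depth <= surface_max_depth
            if surface_inclusive
            else r.depth < surface_max_depth
        )

    out: list[SurfaceDerivedRecord] = []
    for rec in sorted(recs, key=lambda r: (r.station, r.fraction, r.depth)):
        if rec.depth < meso_min_depth:
            continue
        pool = [
            r
            for r in recs
            if is_surface(r)
            and r.fraction == rec.fraction
            and (surface_pool == "global" or r.station == rec.station)
        ]
        surface_present = np.zeros(table.n_otus, dtype=bool)
        for r in pool:
            surface_present |= table.sample_counts(r.sample_id) > 0
        meso = table.sample_counts(rec.sample_id)
        present = meso > 0
        n_otus = int(present.sum())
        if n_otus == 0:
            continue
        derived = present & surface_present
        out.append(
            SurfaceDerivedRecord(
                station=rec.station,
                fraction=rec.fraction,
                depth=rec.depth,
                pct_otus_surface_derived=100.0 * derived.sum() / n_otus,
                pct_seqs_surface_derived=100.0 * meso[derived].sum() / meso.sum(),
            )
        )
    return out


@dataclass(frozen=True)
class UniqueOtuRecord:
    """Share of a community made of OTUs found in exactly one station."""

    station: str
    fraction: float
    depth: float  # m
    pct_otus_unique: float
    pct_seqs_unique: float


def unique_otu_fraction(
    table: OtuTable,
    metadata: Mapping[str, SampleRecord],
    pool_fractions: bool = True,
) -> list[UniqueOtuRecord]:
    """Station-unique OTU and sequence percentages per community.

    An OTU is unique to a station when its summed counts over all that
    station's samples (all depths and, by default, all size fractions) are
    positive while being zero everywhere else.  With
    ``pool_fractions=False`` uniqueness is assessed within each size
    fraction separately.
    """
    recs = [metadata[s] for s in table.sample_ids]
    stations = sorted({r.station for r in recs})
    if len(stations) < 2:
        raise ValidationError("unique-OTU analysis needs >= 2 stations")

    def presence_by_station(fraction: float | None) -> dict[str, np.ndarray]:
        pres: dict[str, np.ndarray] = {
            st: np.zeros(table.n_otus, dtype=bool) for st in stations
        }
        for r in recs:
            if fraction is not None and r.fraction != fraction:
                continue
            pres[r.station] |= table.sample_counts(r.sample_id) > 0
        return pres

    cache: dict[float | None, dict[str, np.ndarray]] = {}

    out: list[UniqueOtuRecord] = []
    for rec in sorted(recs, key=lambda r: (r.station, r.fraction, r.depth)):
        key = None if pool_fractions else rec.fraction
        if key not in cache:
            cache[key] = presence_by_station(key)
        pres = cache[key]
        others = np.zeros(table.n_otus, dtype=bool)
        for st in stations:
            if st != rec.station:
                others |= pres[st]
        unique_mask = pres[rec.station] & ~others
        counts = table.sample_counts(rec.sample_id)
        present = counts > 0
        n_otus = int(present.sum())
        if n_otus == 0:
            continue
        uniq_here = present & unique_mask
        out.append(
            UniqueOtuRecord(
                station=rec.station,
                fraction=rec.fraction,
                depth=rec.depth,
                pct_otus_unique=100.0 * uniq_here.sum() / n_otus,
                pct_seqs_unique=100.0 * counts[uniq_here].sum() / counts.sum(),
            )
        )
    return out
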