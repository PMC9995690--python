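"""Synthetic station/depth/size-fraction datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: three
stations spanning a surface-productivity gradient, six depths from the mixed
layer to the mesopelagic, and three filtration size classes.  A single
per-station productivity parameter ``phi`` drives both observation types:

* the 234Th profile carries a surface deficit of fractional amplitude
  ``phi`` decaying over an e-folding depth ``z*``, so the true export flux
  has the closed form ``lambda * A_U * phi * z* * (1 - exp(-Z/z*)) * 1000``;
* each community is a two-endmember mixture, ``m(z) * surface +
  (1 - m(z)) * deep`` with ``m(z) = exp(-max(z - z0, 0) / (L0 + kappa_f *
  phi))``: pure surface endmember throughout the surface layer (z <= z0 =
  100 m), decaying below it.  The mixing length grows with productivity only
  for fractions with a positive coupling ``kappa_f`` (by default only the
  >53 um particles), encoding sinking particles as vectors of surface taxa
  to depth.  With ``kappa = 0`` the depth profile of mixing is identical at
  every station, which is the null scenario for trend type-I checks.

Surface endmembers are station-specific draws over a shared taxon pool plus
a station-private pool of compositional share ``q``; deep endmembers are
station-shared so that vertical structure, not station identity, dominates.
Reads are multinomial at per-sample depths drawn uniformly from a realistic
range, and all random draws descend from one seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .flux import DecayConstants, UraniumModel, uranium_from_salinity
from .model import (
    Lineage,
    OtuTable,
    RadionuclideProfile,
    SampleRecord,
    SurfaceInventory,
    TaxonomyMap,
)

#: class name -> (domain, phylum); the skew of class weights across size
#: fractions mirrors the field observation that large sinking particles are
#: enriched in Alphaproteobacteria while smaller fractions are dominated by
#: Gammaproteobacteria and Flavobacteriia.
CLASS_LINEAGES = {
    "Gammaproteobacteria": ("Bacteria", "Proteobacteria"),
    "Alphaproteobacteria": ("Bacteria", "Proteobacteria"),
    "Flavobacteriia": ("Bacteria", "Bacteroidetes"),
    "Marine_Group_I": ("Archaea", "Thaumarchaeota"),
    "Planctomycetacia": ("Bacteria", "Planctomycetes"),
}

_CLASS_BLOCKS = {
    "Gammaproteobacteria": 300,
    "Alphaproteobacteria": 250,
    "Flavobacteriia": 200,
    "Marine_Group_I": 50,
    "Planctomycetacia": 100,
}

_SMALL_FRACTION_WEIGHTS = {
    "Gammaproteobacteria": 0.50,
    "Alphaproteobacteria": 0.15,
    "Flavobacteriia": 0.28,
    "Marine_Group_I": 0.02,
    "Planctomycetacia": 0.05,
}
_LARGE_FRACTION_WEIGHTS = {
    "Gammaproteobacteria": 0.30,
    "Alphaproteobacteria": 0.55,
    "Flavobacteriia": 0.08,
    "Marine_Group_I": 0.01,
    "Planctomycetacia": 0.06,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the study-sized scenario."""

    stations: tuple[str, ...] = ("ST1", "ST2", "ST3")
    #: per-station productivity = fractional surface 234Th deficit, unitless
    productivity: tuple[float, ...] = (0.15, 0.40, 0.58)
    depths: tuple[float, ...] = (5.0, 25.0, 100.0, 300.0, 550.0, 700.0)
    fractions: tuple[float, ...] = (0.2, 0.8, 53.0)
    #: shared taxon pool size (split into class blocks) and per-station
    #: private pool size
    n_shared_otus: int = 900
    n_private_otus: int = 150
    #: within-class Dirichlet concentration per fraction (large particles are
    #: less even, hence lower richness)
    dirichlet_alpha: dict[float, float] = field(
        default_factory=lambda: {0.2: 0.08, 0.8: 0.08, 53.0: 0.05}
    )
    private_alpha: float = 0.08
    #: compositional share of the station-private pool in surface endmembers
    #: (many rare private taxa: a large share of a community's OTUs but a
    #: small share of its reads)
    private_taxon_share: float = 0.05
    #: per-fraction transport coupling kappa (m per unit phi); >0 only for
    #: the largest particles by default
    coupling: dict[float, float] = field(
        default_factory=lambda: {0.2: 0.0, 0.8: 0.0, 53.0: 400.0}
    )
    #: base community mixing length L0, m
    mixing_scale: float = 60.0
    #: depth of the surface layer: communities at or above this depth are
    #: pure surface endmember; the endmember mixture decays below it.  This
    #: keeps the "surface" pool (<= 100 m) free of deep-endmember taxa, as
    #: in stratified water columns, so downward transport is expressed at
    #: depth rather than polluting the surface reference.
    surface_layer_depth: float = 100.0
    #: per-sample sequencing depth drawn uniformly from this range (reads)
    read_depth_range: tuple[int, int] = (5000, 15000)
    #: 234Th deficit e-folding depth z*, m
    th_deficit_scale: float = 45.0
    #: relative 1-sigma counting error on 234Th activities
    th_noise_cv: float = 0.03
    th_depths: tuple[float, ...] = (
        5.0, 15.0, 25.0, 40.0, 60.0, 80.0, 100.0,
        125.0, 150.0, 200.0, 250.0, 300.0, 400.0,
    )
    salinity: float = 34.0
    #: surface stocks proportional to phi
    chla_per_phi: float = 480.0  # mg Chl-a m^-2 per unit phi
    poc_per_phi: float = 16.5  # mg C m^-2 per unit phi
    #: when False, all stations share one surface endmember per fraction
    #: (requires private_taxon_share = 0): the fully exchangeable null used
    #: to check trend-test calibration, since station-specific endmembers
    #: are a station-level random effect that no 3-station design can
    #: separate from a station-level gradient
    endmember_station_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.productivity) != len(self.stations):
            raise ValueError("one productivity value per station required")
        if any(p < 0 for p in self.productivity):
            raise ValueError("productivity must be >= 0")
        if not 0 <= self.private_taxon_share < 1:
            raise ValueError("private_taxon_share must be in [0, 1)")
        if any(self.coupling.get(f, 0.0) < 0 for f in self.fractions):
            raise ValueError("coupling must be >= 0")
        if not self.endmember_station_effects and self.private_taxon_share > 0:
            raise ValueError(
                "shared endmembers (endmember_station_effects=False) require "
                "private_taxon_share = 0"
            )

    def phi(self, station: str) -> float:
        return self.productivity[self.stations.index(station)]

    def alpha_for(self, fraction: float) -> float:
        return self.dirichlet_alpha.get(fraction, 0.08)

    def kappa_for(self, fraction: float) -> float:
        return self.coupling.get(fraction, 0.0)

    def class_weights(self, fraction: float) -> dict[str, float]:
        return (
            _LARGE_FRACTION_WEIGHTS if fraction >= 53.0 else _SMALL_FRACTION_WEIGHTS
        )


@dataclass
class Endmembers:
    """Surface/deep composition vectors over the full OTU space."""

    otu_ids: list[str]
    otu_class: list[str]
    surface: dict[tuple[str, float], np.ndarray]  # (station, fraction) -> comp
    deep: dict[float, np.ndarray]  # fraction -> comp (station-shared)
    private_otus: dict[str, list[str]]  # station -> private OTU ids


@dataclass
class GroundTruth:
    """What the generator knows: the targets the pipeline should recover."""

    phi: dict[str, float]
    true_flux: dict[str, float]  # dpm m^-2 d^-1
    mixing_weight: dict[str, float]  # sample_id -> m(z)
    private_otus: dict[str, list[str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "phi": self.phi,
                "true_flux": self.true_flux,
                "mixing_weight": self.mixing_weight,
                "private_otus": self.private_otus,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticDataset:
    """Full generated bundle, matching what the readers ingest."""

    table: OtuTable
    metadata: list[SampleRecord]
    taxonomy: TaxonomyMap
    profiles: list[RadionuclideProfile]
    inventories: list[SurfaceInventory]
    ground_truth: GroundTruth
    config: SyntheticConfig


def _scaled_class_blocks(n_shared: int) -> dict[str, int]:
    total = sum(_CLASS_BLOCKS.values())
    sizes = {c: max(2, round(n_shared * b / total)) for c, b in _CLASS_BLOCKS.items()}
    # adjust the largest block so sizes sum exactly to n_shared
    drift = n_shared - sum(sizes.values())
    sizes["Gammaproteobacteria"] += drift
    return sizes


def generate_endmembers(
    config: SyntheticConfig, rng: np.random.Generator
) -> Endmembers:
    """Draw surface and deep endmember compositions for every stratum.

    Shared-pool compositions are per-class Dirichlet draws scaled by the
    fraction's class weights, so a class's expected share equals its weight
    by construction.  Surface endmembers mix in the station's private pool
    at share ``q``; deep endmembers use the shared pool only and are common
    to all stations.
    """
    blocks = _scaled_class_blocks(config.n_shared_otus)
    otu_ids: list[str] = []
    otu_class: list[str] = []
    class_slices: dict[str, slice] = {}
    pos = 0
    for cls, size in blocks.items():
        class_slices[cls] = slice(pos, pos + size)
        otu_ids += [f"OTU_{cls[:4].lower()}_{i:04d}" for i in range(size)]
        otu_class += [cls] * size
        pos += size
    private_otus: dict[str, list[str]] = {}
    private_slices: dict[str, slice] = {}
    classes = list(CLASS_LINEAGES)
    for st in config.stations:
        ids = [f"OTU_priv_{st}_{i:03d}" for i in range(config.n_private_otus)]
        private_otus[st] = ids
        private_slices[st] = slice(pos, pos + config.n_private_otus)
        otu_ids += ids
        otu_class += [classes[i % len(classes)] for i in range(config.n_private_otus)]
        pos += config.n_private_otus
    n_total = pos

    def shared_draw(fraction: float) -> np.ndarray:
        comp = np.zeros(n_total)
        alpha = config.alpha_for(fraction)
        for cls, weight in config.class_weights(fraction).items():
            sl = class_slices[cls]
            size = sl.stop - sl.start
            comp[sl] = weight * rng.dirichlet(np.full(size, alpha))
        return comp / comp.sum()

    surface: dict[tuple[str, float], np.ndarray] = {}
    deep: dict[float, np.ndarray] = {}
    q = config.private_taxon_share
    for fraction in config.fractions:
        deep[fraction] = shared_draw(fraction)
        if not config.endmember_station_effects:
            common = shared_draw(fraction)
            for st in config.stations:
                surface[(st, fraction)] = common
            continue
        for st in config.stations:
            comp = (1.0 - q) * shared_draw(fraction)
            if config.n_private_otus and q > 0:
                priv = rng.dirichlet(np.full(config.n_private_otus, config.private_alpha))
                comp[private_slices[st]] = q * priv
            surface[(st, fraction)] = comp / comp.sum()
    return Endmembers(otu_ids, otu_class, surface, deep, private_otus)


def mixing_weight(
    depth: float, phi: float, kappa: float, l0: float, z0: float = 100.0
) -> float:
    """Surface-endmember weight m(z) = exp(-max(z - z0, 0) / (L0 + kappa * phi)).

    m = 1 throughout the surface layer (z <= z0); below it the surface
    contribution decays over a mixing length that grows with productivity
    for coupled fractions (kappa > 0).
    """
    return math.exp(-max(depth - z0, 0.0) / (l0 + kappa * phi))


def generate_community_profile(
    station: str,
    fraction: float,
    config: SyntheticConfig,
    endmembers: Endmembers,
) -> dict[float, np.ndarray]:
    """Expected composition at every sampling depth of one stratum."""
    phi = config.phi(station)
    kappa = config.kappa_for(fraction)
    s = endmembers.surface[(station, fraction)]
    d = endmembers.deep[fraction]
    out = {}
    for z in config.depths:
        m = mixing_weight(z, phi, kappa, config.mixing_scale, config.surface_layer_depth)
        out[z] = m * s + (1.0 - m) * d
    return out


def sample_reads(
    expected_composition: np.ndarray, read_depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read counts from an expected composition."""
    p = np.asarray(expected_composition, dtype=float)
    return rng.multinomial(int(read_depth), p / p.sum())


def true_flux(
    config: SyntheticConfig, station: str, u_model: UraniumModel = UraniumModel()
) -> float:
    """Closed-form flux implied by the generated deficit shape.

    lambda * A_U * phi * z* * (1 - exp(-Z/z*)) * 1000, with Z the deepest
    profile depth, in dpm m^-2 d^-1.
    """
    lam = DecayConstants().lambda_th234
    a_u = uranium_from_salinity(config.salinity, u_model)
    zstar = config.th_deficit_scale
    z_max = config.th_depths[-1]
    phi = config.phi(station)
    return lam * a_u * phi * zstar * (1.0 - math.exp(-z_max / zstar)) * 1000.0


def generate_th_profile(
    station: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    u_model: UraniumModel = UraniumModel(),
) -> RadionuclideProfile:
    """234Th/salinity profile with an exponential scavenging deficit.

    A_Th(z) = A_U * (1 - phi * exp(-z/z*)) with multiplicative Gaussian
    counting noise at the configured coefficient of variation; the reported
    1-sigma equals that counting error.
    """
    depths = np.asarray(config.th_depths, dtype=float)
    salinity = np.full(depths.size, config.salinity)
    a_u = np.asarray(uranium_from_salinity(salinity, u_model))
    phi = config.phi(station)
    ideal = a_u * (1.0 - phi * np.exp(-depths / config.th_deficit_scale))
    noisy = ideal * (1.0 + config.th_noise_cv * rng.standard_normal(depths.size))
    noisy = np.maximum(noisy, 1e-3)
    return RadionuclideProfile(
        station=station,
        depths=depths,
        th234=noisy,
        th234_sigma=config.th_noise_cv * noisy,
        salinity=salinity,
    )


def _taxonomy_for(endmembers: Endmembers) -> TaxonomyMap:
    taxmap = TaxonomyMap()
    for otu_id, cls in zip(endmembers.otu_ids, endmembers.otu_class):
        domain, phylum = CLASS_LINEAGES[cls]
        taxmap.lineages[otu_id] = Lineage.from_parts([domain, phylum, cls])
    return taxmap


def sample_id_for(station: str, depth: float, fraction: float) -> str:
    return f"{station}_{depth:g}m_{fraction:g}um"


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full bundle: OTU table, metadata, profiles, inventories.

    The default configuration is study-sized: 3 stations x 6 depths x 3 size
    fractions = 54 samples, with read depths of 5,000-15,000.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    endmembers = generate_endmembers(config, rng)

    sample_ids: list[str] = []
    metadata: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    mixing: dict[str, float] = {}
    lo, hi = config.read_depth_range
    for station in config.stations:
        for fraction in config.fractions:
            profile = generate_community_profile(station, fraction, config, endmembers)
            for z in config.depths:
                sid = sample_id_for(station, z, fraction)
                read_depth = int(rng.integers(lo, hi + 1))
                rows.append(sample_reads(profile[z], read_depth, rng))
                sample_ids.append(sid)
                metadata.append(
                    SampleRecord(
                        sample_id=sid,
                        station=station,
                        depth=z,
                        fraction=fraction,
                        volume=float(np.round(rng.uniform(2.5, 11.0), 1)),
                    )
                )
                mixing[sid] = mixing_weight(
                    z,
                    config.phi(station),
                    config.kappa_for(fraction),
                    config.mixing_scale,
                    config.surface_layer_depth,
                )
    table = OtuTable(sample_ids, list(endmembers.otu_ids), np.vstack(rows)).drop_empty_otus()

    profiles = [generate_th_profile(st, config, rng) for st in config.stations]
    inventories = [
        SurfaceInventory(
            station=st,
            chla_stock=config.chla_per_phi * config.phi(st),
            poc_stock=config.poc_per_phi * config.phi(st),
        )
        for st in config.stations
    ]
    truth = GroundTruth(
        phi={st: config.phi(st) for st in config.stations},
        true_flux={st: true_flux(config, st) for st in config.stations},
        mixing_weight=mixing,
        private_otus=endmembers.private_otus,
    )
    return SyntheticDataset(
        table=table,
        metadata=metadata,
        taxonomy=_taxonomy_for(endmembers),
        profiles=profiles,
        inventories=inventories,
        ground_truth=truth,
        config=config,
    )


def reduced_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A smaller, faster scenario for repeated-seed property checks."""
    base = dict(
        n_shared_otus=300,
        n_private_otus=20,
        read_depth_range=(2000, 4000),
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def null_config(seed: int = 0, n_stations: int = 8, **overrides) -> SyntheticConfig:
    """Reduced zero-coupling null for trend-test calibration checks.

    Stations are exchangeable units under kappa = 0, so the station-cluster
    permutation test is exact; with the default 3 stations its p-value floor
    is 1/3! = 1/6, hence the calibration check uses more stations (8 by
    default, floor 1/8!) to resolve rejection rates near alpha = 0.05.
    """
    base = dict(
        stations=tuple(f"N{i + 1}" for i in range(n_stations)),
        productivity=tuple(
            0.15 + (0.58 - 0.15) * i / max(n_stations - 1, 1)
            for i in range(n_stations)
        ),
        coupling={0.2: 0.0, 0.8: 0.0, 53.0: 0.0},
    )
    base.update(overrides)
    return reduced_config(seed=seed, **base)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the formats the readers ingest, plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": outdir / "otu_table.tsv",
        "metadata": outdir / "sample_metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "profiles": outdir / "th234_profiles.tsv",
        "inventories": outdir / "surface_inventories.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    tio.write_otu_table(dataset.table, paths["otu_table"])
    tio.write_sample_metadata(dataset.metadata, paths["metadata"])
    tio.write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    tio.write_radionuclide_profiles(dataset.profiles, paths["profiles"])
    tio.write_surface_inventories(dataset.inventories, paths["inventories"])
    paths["ground_truth"].write_text(dataset.ground_truth.to_json())
    return paths
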