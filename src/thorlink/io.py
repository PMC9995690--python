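"""Readers and writers for the tabular interchange formats.

All files are UTF-8 delimited text with a mandatory header row; tab is the
primary delimiter and comma is accepted (sniffed per file).  The OTU table
may be laid out either samples-as-columns (first column ``otu_id``) or
samples-as-rows (first column ``sample_id``); the header's first cell decides
and both orientations yield identical tables.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    FRACTIONS,
    Lineage,
    OtuTable,
    RadionuclideProfile,
    SampleRecord,
    SurfaceInventory,
    TaxonomyMap,
    ValidationError,
)

_OTU_HEADER_TOKENS = {"otu_id", "otu", "#otu id", "otu id", "feature_id", "feature id"}
_SAMPLE_HEADER_TOKENS = {"sample_id", "sample", "sample id"}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-separated file with a header row."""
    try:
        return pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"could not parse {path}: {exc}") from exc


def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU count table, auto-detecting its orientation.

    Raises :class:`ValidationError` on duplicate identifiers, negative or
    non-numeric counts, or samples whose total is zero.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header_line else ","
    header = [h.strip() for h in header_line.split(sep)]
    if len(set(header[1:])) != len(header[1:]):
        raise ValidationError(f"{path}: duplicate column identifiers in header")
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: OTU table needs an id column plus counts")
    first = str(df.columns[0]).strip().lower()
    samples_as_rows = first in _SAMPLE_HEADER_TOKENS
    ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    try:
        values = body.astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count value ({exc})") from exc
    if np.isnan(values).any():
        raise ValidationError(f"{path}: missing count values")
    if samples_as_rows:
        sample_ids, otu_ids = ids, [str(c) for c in body.columns]
        counts = values
    else:
        otu_ids, sample_ids = ids, [str(c) for c in body.columns]
        counts = values.T
    return OtuTable(sample_ids, otu_ids, counts)


def write_otu_table(
    table: OtuTable, path: str | Path, orientation: str = "otus_as_rows"
) -> None:
    """Write an OTU table as TSV in either orientation."""
    if orientation == "otus_as_rows":
        df = pd.DataFrame(table.counts.T, index=table.otu_ids, columns=table.sample_ids)
        df.index.name = "otu_id"
    elif orientation == "samples_as_rows":
        df = table.to_dataframe()
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t")


_FRACTION_ALIASES = {f"{f:g}": f for f in FRACTIONS}


def parse_fraction(label: object) -> float:
    """Normalize a size-fraction label to its nominal lower pore size."""
    text = str(label).strip().lower()
    for junk in (">", "um", "µm", "μm"):
        text = text.replace(junk, "")
    text = text.strip()
    if text in _FRACTION_ALIASES:
        return _FRACTION_ALIASES[text]
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(f"unrecognized size-fraction label {label!r}") from None
    for frac in FRACTIONS:
        if abs(value - frac) < 1e-9:
            return frac
    raise ValidationError(
        f"size-fraction {label!r} is not one of the filtration classes {FRACTIONS}"
    )


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read per-sample metadata (sample_id, station, depth_m, fraction_um, volume_L)."""
    df = _read_delimited(path)
    required = ["sample_id", "station", "depth_m", "fraction_um", "volume_L"]
    cols = {str(c).strip(): c for c in df.columns}
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row[cols["sample_id"]]).strip(),
                station=str(row[cols["station"]]).strip(),
                depth=float(row[cols["depth_m"]]),
                fraction=parse_fraction(row[cols["fraction_um"]]),
                volume=float(row[cols["volume_L"]]),
            )
        )
    return records


def write_sample_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "station": [r.station for r in records],
            "depth_m": [r.depth for r in records],
            "fraction_um": [f"{r.fraction:g}" for r in records],
            "volume_L": [r.volume for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column taxonomy file (otu_id, semicolon-delimited lineage).

    Malformed lineage strings produce a warning and an unclassified lineage,
    never a failure.  Lineages mentioning chloroplasts (which should have been
    removed upstream) are flagged for the validation summary.
    """
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: taxonomy needs otu_id and lineage columns")
    taxmap = TaxonomyMap()
    for _, row in df.iterrows():
        otu_id = str(row.iloc[0]).strip()
        raw = row.iloc[1]
        if not isinstance(raw, str) or not raw.strip():
            warnings.warn(f"taxonomy: empty lineage for {otu_id}", stacklevel=2)
            taxmap.malformed.add(otu_id)
            taxmap.lineages[otu_id] = Lineage.from_parts([])
            continue
        lineage = Lineage.from_parts(raw.split(";"))
        taxmap.lineages[otu_id] = lineage
        if "chloroplast" in raw.lower():
            taxmap.chloroplast_flagged.add(otu_id)
    return taxmap


def write_taxonomy(taxmap: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tlineage\n")
        for otu_id, lin in taxmap.lineages.items():
            fh.write(f"{otu_id}\t{';'.join(lin)}\n")


def read_radionuclide_profiles(path: str | Path) -> list[RadionuclideProfile]:
    """Read 234Th/salinity profiles, one depth-sorted profile per station."""
    df = _read_delimited(path)
    required = ["station", "depth_m", "th234_dpm_L", "th234_sigma", "salinity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing profile columns {missing}")
    profiles = []
    for station, grp in df.groupby("station", sort=False):
        depths = grp["depth_m"].astype(float).to_numpy()
        order = np.argsort(depths)
        if np.unique(depths).size != depths.size:
            raise ValidationError(f"station {station!r}: duplicate depths in profile")
        profiles.append(
            RadionuclideProfile(
                station=str(station),
                depths=depths[order],
                th234=grp["th234_dpm_L"].astype(float).to_numpy()[order],
                th234_sigma=grp["th234_sigma"].astype(float).to_numpy()[order],
                salinity=grp["salinity"].astype(float).to_numpy()[order],
            )
        )
    return profiles


def write_radionuclide_profiles(
    profiles: Iterable[RadionuclideProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        for z, th, sig, sal in zip(p.depths, p.th234, p.th234_sigma, p.salinity):
            rows.append((p.station, z, th, sig, sal))
    pd.DataFrame(
        rows, columns=["station", "depth_m", "th234_dpm_L", "th234_sigma", "salinity"]
    ).to_csv(path, sep="\t", index=False)


def read_surface_inventories(path: str | Path) -> list[SurfaceInventory]:
    """Read station-level Chl-a and POC stocks."""
    df = _read_delimited(path)
    required = ["station", "chla_stock_mg_m2", "poc_stock_mg_m2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing inventory columns {missing}")
    return [
        SurfaceInventory(
            station=str(row["station"]).strip(),
            chla_stock=float(row["chla_stock_mg_m2"]),
            poc_stock=float(row["poc_stock_mg_m2"]),
        )
        for _, row in df.iterrows()
    ]


def write_surface_inventories(
    inventories: Iterable[SurfaceInventory], path: str | Path
) -> None:
    inv = list(inventories)
    pd.DataFrame(
        {
            "station": [i.station for i in inv],
            "chla_stock_mg_m2": [i.chla_stock for i in inv],
            "poc_stock_mg_m2": [i.poc_stock for i in inv],
        }
    ).to_csv(path, sep="\t", index=False)


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: run config must be a mapping")
    return cfg
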