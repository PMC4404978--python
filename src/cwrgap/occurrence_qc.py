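"""Occurrence-record cleaning: dedup, land/country cross-checks, native range.

The pipeline mirrors standard practice for genebank/herbarium compilations:
collapse duplicate entries, drop records falling in the sea or in a country
other than the one stated on the label, constrain each taxon to its native
countries (gap analysis targets populations with long-term local
adaptation), enforce species-specific constraints such as a maximum distance
from the coast, and finally reduce the survivors to one modeling point per
occupied grid cell so a heavily re-collected site does not pseudo-replicate
at model resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import (
    GridSpec,
    OccurrenceRecord,
    OccurrenceSet,
    Raster,
    haversine_km,
)

DISPOSITIONS = (
    "kept",
    "duplicate_removed",
    "off_land",
    "country_mismatch",
    "outside_native",
    "missing_coords",
    "constraint_violation",
)

#: duplicate coordinates are compared after rounding to 1e-4 degrees (~11 m)
DUPLICATE_COORD_DECIMALS = 4

#: species with fewer unique modeling cells than this are unmodelable
MIN_MODEL_POINTS = 5


class QCError(ValueError):
    pass


@dataclass
class NativeRange:
    """Country-level native range, optionally with a coastal-distance limit."""

    taxon: str
    countries: list[str]
    coastal_limit_km: float | None = None

    def __post_init__(self) -> None:
        if not self.countries:
            raise QCError(f"native range for {self.taxon} has no countries")


@dataclass
class QCReport:
    """Per-record dispositions plus per-taxon record counts."""

    taxon: str
    dispositions: dict[str, str] = field(default_factory=dict)  # record_id -> code

    def flag(self, record_id: str, code: str) -> None:
        if code not in DISPOSITIONS:
            raise QCError(f"unknown disposition {code!r}")
        self.dispositions[record_id] = code

    def count(self, code: str) -> int:
        return sum(1 for c in self.dispositions.values() if c == code)

    @property
    def total(self) -> int:
        return len(self.dispositions)

    def merged_with(self, other: "QCReport") -> "QCReport":
        """Combine two stage reports; later stages override 'kept'."""
        out = QCReport(self.taxon, dict(self.dispositions))
        for rid, code in other.dispositions.items():
            if out.dispositions.get(rid, "kept") == "kept":
                out.dispositions[rid] = code
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxon,
                "record_id": list(self.dispositions),
                "disposition": list(self.dispositions.values()),
            }
        )


def _dup_key(r: OccurrenceRecord) -> tuple:
    if r.has_coords:
        return (
            r.taxon,
            r.record_type,
            round(r.longitude, DUPLICATE_COORD_DECIMALS),
            round(r.latitude, DUPLICATE_COORD_DECIMALS),
        )
    # coordinate-free records collapse only on identical provenance
    return (r.taxon, r.record_type, None, r.source, r.record_id)


def deduplicate(occ: OccurrenceSet) -> tuple[OccurrenceSet, QCReport]:
    """Collapse records identical on (taxon, type, rounded coordinates).

    Rounding to 1e-4 degrees (~11 m) merges re-entered specimens without
    merging distinct nearby populations; G and H records never collapse into
    each other.  The first occurrence wins; order is otherwise preserved.
    """
    report = QCReport(occ.taxon)
    seen: set[tuple] = set()
    kept: list[OccurrenceRecord] = []
    for r in occ.records:
        key = _dup_key(r)
        if key in seen:
            report.flag(r.record_id, "duplicate_removed")
        else:
            seen.add(key)
            kept.append(r)
            report.flag(r.record_id, "kept")
    return OccurrenceSet(occ.taxon, kept), report


def crosscheck(
    occ: OccurrenceSet,
    country_raster: Raster | None,
    native: NativeRange | None = None,
    coast_distance: Raster | None = None,
    country_codes: dict[int, str] | None = None,
) -> tuple[OccurrenceSet, QCReport]:
    """Validate coordinates against land, stated country, and native range.

    Records on sea (nodata) cells are removed as ``off_land``; records whose
    raster country disagrees with the stated country as ``country_mismatch``;
    records outside the native country list as ``outside_native``; records
    beyond the coastal limit as ``constraint_violation``.  Records without
    coordinates are retained (they still count for sampling-representativeness
    scores) but are unusable for modeling.

    ``country_codes`` maps integer raster codes to the string codes used in
    the occurrence table; identity mapping "C{code:02d}" is assumed when
    omitted.
    """
    report = QCReport(occ.taxon)
    kept: list[OccurrenceRecord] = []

    def code_of(v: int) -> str:
        if country_codes is not None:
            return country_codes.get(int(v), "")
        return f"C{int(v):02d}"

    native_set = set(native.countries) if native is not None else None
    limit = native.coastal_limit_km if native is not None else None

    for r in occ.records:
        if not r.has_coords:
            kept.append(r)
            report.flag(r.record_id, "kept")
            continue
        if country_raster is not None:
            cell = country_raster.spec.cell_of(r.longitude, r.latitude)
            on_land = cell is not None and bool(country_raster.mask[cell])
            if not on_land:
                report.flag(r.record_id, "off_land")
                continue
            raster_country = code_of(country_raster.values[cell])
            if r.country is not None and r.country != raster_country:
                report.flag(r.record_id, "country_mismatch")
                continue
            if native_set is not None and raster_country not in native_set:
                report.flag(r.record_id, "outside_native")
                continue
        elif native_set is not None and r.country is not None and r.country not in native_set:
            report.flag(r.record_id, "outside_native")
            continue
        if limit is not None and coast_distance is not None:
            d = coast_distance.sample([r.longitude], [r.latitude])[0]
            if np.isfinite(d) and d > limit:
                report.flag(r.record_id, "constraint_violation")
                continue
        kept.append(r)
        report.flag(r.record_id, "kept")
    return OccurrenceSet(occ.taxon, kept), report


def modeling_points(occ: OccurrenceSet, spec: GridSpec) -> np.ndarray:
    """Unique cell-snapped (lon, lat) coordinates for model fitting.

    One point per occupied grid cell, at the cell center; the count decides
    whether a species is modeled directly (>= 20 points), via the ensemble
    fallback (5-19), or reported unmodelable (< 5).
    """
    cells: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for r in occ.records:
        if not r.has_coords:
            continue
        cell = spec.cell_of(r.longitude, r.latitude)
        if cell is not None and cell not in seen:
            seen.add(cell)
            cells.append(cell)
    if not cells:
        raise QCError(f"species {occ.taxon} unmappable: no usable coordinates")
    return np.array([spec.cell_center(row, col) for row, col in cells])


def clean_occurrences(
    occ: OccurrenceSet,
    country_raster: Raster | None = None,
    native: NativeRange | None = None,
    coast_distance: Raster | None = None,
    country_codes: dict[int, str] | None = None,
) -> tuple[OccurrenceSet, QCReport]:
    """Full cleaning pipeline: deduplicate then cross-check."""
    deduped, rep1 = deduplicate(occ)
    cleaned, rep2 = crosscheck(
        deduped, country_raster, native, coast_distance, country_codes
    )
    return cleaned, rep1.merged_with(rep2)


def summary_counts(occ_before: OccurrenceSet, occ_after: OccurrenceSet,
                   spec: GridSpec | None = None) -> dict:
    """Per-taxon totals used in reporting: total, G, H, unique cells."""
    out = {
        "taxon": occ_before.taxon,
        "total": len(occ_before),
        "G": len(occ_before.of_type("G")),
        "H": len(occ_before.of_type("H")),
        "kept": len(occ_after),
        "kept_G": len(occ_after.of_type("G")),
        "kept_H": len(occ_after.of_type("H")),
    }
    if spec is not None:
        try:
            out["unique_cells"] = len(modeling_points(occ_after, spec))
        except QCError:
            out["unique_cells"] = 0
    return out


def read_native_ranges(path) -> dict[str, NativeRange]:
    """Read native ranges: CSV with taxon, countries (;-separated), optional
    coastal_limit_km."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        limit = row.get("coastal_limit_km")
        if limit is not None and (pd.isna(limit) or limit == ""):
            limit = None
        out[row["taxon"]] = NativeRange(
            taxon=row["taxon"],
            countries=[c.strip() for c in str(row["countries"]).split(";") if c.strip()],
            coastal_limit_km=float(limit) if limit is not None else None,
        )
    return out
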