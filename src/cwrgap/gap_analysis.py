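"""Ex situ conservation gap scores, priority categories, and collecting maps.

Three representativeness scores on a 0-10 scale summarize how completely a
species' genebank holdings cover it:

* SRS (sampling) — 10 x G / (G + H): the germplasm share of all records.
* GRS (geographic) — the share of the potential distribution covered by
  50-km circular buffers (CA50) around germplasm collection coordinates,
  measured in spherical cell areas.
* ERS (ecological) — the share of the distribution's distinct ecosystem
  classes that the CA50 touches.

The final priority score FPS is their plain mean, binned into collecting
urgency categories: HPS (FPS <= 2.5, or no germplasm at all), MPS (<= 5),
LPS (<= 7.5), NFCR otherwise.  Buffers are intersected with the predicted
range before any counting, so collections outside the modeled distribution
never inflate coverage.  Spatial outputs locate the gaps: per-taxon maps of
uncollected range, multi-species richness, hotspots of uncollected range
over high-priority taxa, and per-country zonal tabulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import Raster, buffer_mask, cell_area_raster
from .niche_model import PotentialDistribution

CA50_RADIUS_KM = 50.0

CATEGORIES = ("HPS", "MPS", "LPS", "NFCR")


class GapError(ValueError):
    pass


@dataclass
class GapScores:
    taxon: str
    G: int
    H: int
    SRS: float
    GRS: float
    ERS: float
    FPS: float
    category: str


@dataclass
class GapMaps:
    gap_by_taxon: dict[str, Raster]  # distribution minus CA50
    richness: Raster  # number of taxa predicted per cell
    hotspots: Raster  # gap count over HPS taxa only
    country_table: pd.DataFrame  # per country x taxon gap cells / km^2


def srs(G: int, H: int) -> float:
    """Sampling representativeness: 10 x germplasm share of all records."""
    if G < 0 or H < 0:
        raise GapError("record counts must be nonnegative")
    if G + H == 0:
        raise GapError("no records at all: SRS undefined")
    return 10.0 * G / (G + H)


def _ca50(
    distribution: PotentialDistribution, germplasm_points: np.ndarray,
    radius_km: float = CA50_RADIUS_KM, clip_to_distribution: bool = True,
) -> np.ndarray:
    pts = np.asarray(germplasm_points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return np.zeros(distribution.binary.spec.shape, dtype=bool)
    buf = buffer_mask([tuple(p) for p in pts], distribution.binary.spec, radius_km)
    out = buf.values == 1
    if clip_to_distribution:
        out &= distribution.support
    return out


def grs(
    distribution: PotentialDistribution,
    germplasm_points: np.ndarray,
    radius_km: float = CA50_RADIUS_KM,
    clip_to_distribution: bool = True,
) -> float:
    """Geographic representativeness: CA50 area share of the distribution.

    Areas are spherical cell-area sums; with ``clip_to_distribution`` (the
    default) buffer parts outside the predicted range do not count, keeping
    the score within [0, 10].  No georeferenced germplasm means 0.
    """
    support = distribution.support
    if not support.any():
        raise GapError(f"{distribution.taxon}: empty distribution")
    pts = np.asarray(germplasm_points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return 0.0
    areas = cell_area_raster(distribution.binary.spec)
    covered = _ca50(distribution, pts, radius_km, clip_to_distribution)
    ratio = areas[covered & support].sum() / areas[support].sum()
    return 10.0 * min(1.0, float(ratio))


def ers(
    distribution: PotentialDistribution,
    germplasm_points: np.ndarray,
    ecosystems: Raster,
    radius_km: float = CA50_RADIUS_KM,
) -> float:
    """Ecological representativeness: ecosystem classes sampled by the CA50
    as a share of classes spanned by the distribution."""
    if ecosystems.spec != distribution.binary.spec:
        raise GapError("ecosystem raster not aligned to distribution grid")
    support = distribution.support & ecosystems.mask
    range_classes = set(np.unique(ecosystems.values[support]).tolist())
    if not range_classes:
        raise GapError(
            f"{distribution.taxon}: distribution intersects no classified cells"
        )
    pts = np.asarray(germplasm_points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return 0.0
    covered = _ca50(distribution, pts, radius_km, clip_to_distribution=True)
    covered &= ecosystems.mask
    ca_classes = set(np.unique(ecosystems.values[covered]).tolist())
    return 10.0 * len(ca_classes & range_classes) / len(range_classes)


def fps_and_category(SRS: float, GRS: float, ERS: float, G: int) -> tuple[float, str]:
    """Mean of the three scores and its collecting-urgency category.

    A species with zero conserved germplasm accessions is high priority
    regardless of FPS (the override also catches the FPS = 0 corner, which
    the nominal HPS interval 0 < FPS <= 2.5 leaves open).
    """
    for name, v in (("SRS", SRS), ("GRS", GRS), ("ERS", ERS)):
        if not 0 <= v <= 10:
            raise GapError(f"{name}={v} outside [0, 10]")
    fps = (SRS + GRS + ERS) / 3.0
    if G == 0 or fps <= 2.5:
        cat = "HPS"
    elif fps <= 5:
        cat = "MPS"
    elif fps <= 7.5:
        cat = "LPS"
    else:
        cat = "NFCR"
    return fps, cat


def score_taxon(
    taxon: str,
    G: int,
    H: int,
    distribution: PotentialDistribution,
    germplasm_points: np.ndarray,
    ecosystems: Raster,
) -> GapScores:
    """All four scores for one taxon.

    ``G`` and ``H`` are record counts including non-georeferenced records
    (SRS is sample-based); ``germplasm_points`` holds only the georeferenced
    germplasm coordinates used for the CA50.
    """
    s = srs(G, H)
    g = grs(distribution, germplasm_points)
    e = ers(distribution, germplasm_points, ecosystems)
    fps, cat = fps_and_category(s, g, e, G)
    return GapScores(taxon, G, H, s, g, e, fps, cat)


def scores_frame(scores: list[GapScores]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": s.taxon,
                "G": s.G,
                "H": s.H,
                "SRS": s.SRS,
                "GRS": s.GRS,
                "ERS": s.ERS,
                "FPS": s.FPS,
                "category": s.category,
            }
            for s in scores
        ]
    )


def gap_maps(
    distributions: dict[str, PotentialDistribution],
    germplasm_points_by_taxon: dict[str, np.ndarray],
    categories: dict[str, str],
    country_raster: Raster | None = None,
    radius_km: float = CA50_RADIUS_KM,
) -> GapMaps:
    """Collecting-gap geography across taxa.

    Per-taxon gap = predicted range not covered by the CA50; richness sums
    predicted ranges over all taxa; hotspots sum gap maps over HPS taxa only;
    the country table gives zonal gap-cell counts and km^2 per country and
    taxon when a country raster is supplied.
    """
    if not distributions:
        raise GapError("no distributions supplied")
    specs = {d.binary.spec for d in distributions.values()}
    if len(specs) != 1:
        raise GapError("distribution grids are not aligned")
    spec = next(iter(specs))
    if country_raster is not None and country_raster.spec != spec:
        raise GapError("country raster grid mismatch")

    areas = cell_area_raster(spec)
    richness = np.zeros(spec.shape, dtype=np.int64)
    hotspots = np.zeros(spec.shape, dtype=np.int64)
    gaps: dict[str, Raster] = {}
    rows = []
    for taxon, dist in distributions.items():
        support = dist.support
        richness += support
        pts = germplasm_points_by_taxon.get(taxon, np.empty((0, 2)))
        covered = _ca50(dist, pts, radius_km, clip_to_distribution=True)
        gap = support & ~covered
        gaps[taxon] = Raster(spec, gap.astype(np.uint8), nodata=255)
        if categories.get(taxon) == "HPS":
            hotspots += gap
        if country_raster is not None:
            for code in np.unique(country_raster.valid_values()):
                in_country = gap & (country_raster.values == code)
                n = int(in_country.sum())
                if n:
                    rows.append(
                        {
                            "country": int(code),
                            "taxon": taxon,
                            "gap_cells": n,
                            "gap_km2": float(areas[in_country].sum()),
                        }
                    )
    table = pd.DataFrame(rows, columns=["country", "taxon", "gap_cells", "gap_km2"])
    return GapMaps(
        gap_by_taxon=gaps,
        richness=Raster(spec, richness, nodata=-1),
        hotspots=Raster(spec, hotspots, nodata=-1),
        country_table=table,
    )
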