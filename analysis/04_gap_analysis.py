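"""Score ex situ conservation gaps and map collecting priorities.

Computes SRS/GRS/ERS/FPS and the priority category per species, then the
spatial products: per-species uncollected-range maps, multi-species
richness, high-priority gap hotspots, a per-country zonal tabulation, and a
priority-map figure.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from common import FIGURES_DIR, MODELS_DIR, RESULTS, WORLD_DIR
from cwrgap.gap_analysis import gap_maps, score_taxon, scores_frame
from cwrgap.geodata import read_occurrences, read_raster, write_raster
from cwrgap.niche_model import PotentialDistribution


def main() -> None:
    ecosystems = read_raster(WORLD_DIR / "ecosystems.asc")
    countries = read_raster(WORLD_DIR / "countries.asc")
    sets, _ = read_occurrences(RESULTS / "occurrences_clean.csv")
    FIGURES_DIR.mkdir(parents=True, exist_ok=True)

    distributions, gpoints, scores = {}, {}, []
    for occ in sets:
        binary = read_raster(MODELS_DIR / f"{occ.taxon}_range.asc")
        dist = PotentialDistribution(
            taxon=occ.taxon,
            binary=binary.copy_with(binary.values.astype(np.uint8), nodata=255),
            provenance="file",
        )
        distributions[occ.taxon] = dist
        gpoints[occ.taxon] = occ.coords("G")
        G = len(occ.of_type("G"))
        H = len(occ.of_type("H"))
        s = score_taxon(occ.taxon, G, H, dist, gpoints[occ.taxon], ecosystems)
        scores.append(s)
        print(f"{occ.taxon}: G={G} H={H} SRS={s.SRS:.2f} GRS={s.GRS:.2f} "
              f"ERS={s.ERS:.2f} FPS={s.FPS:.2f} -> {s.category}")

    table = scores_frame(scores)
    table.to_csv(RESULTS / "gap_scores.csv", index=False)
    n_hps = int((table["category"] == "HPS").sum())
    print(f"mean FPS {table['FPS'].mean():.2f}; "
          f"{n_hps}/{len(table)} species are high priority for collecting")

    maps = gap_maps(distributions, gpoints,
                    {s.taxon: s.category for s in scores},
                    country_raster=countries)
    write_raster(maps.richness, RESULTS / "richness.asc")
    write_raster(maps.hotspots, RESULTS / "hotspots.asc")
    for taxon, gap in maps.gap_by_taxon.items():
        write_raster(gap, MODELS_DIR / f"{taxon}_gap.asc")
    maps.country_table.to_csv(RESULTS / "country_priorities.csv", index=False)
    top = (maps.country_table.groupby("country")["gap_km2"].sum()
           .sort_values(ascending=False))
    print("countries ranked by uncollected area (km^2):")
    print(top.round(0).to_string())

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for ax, (rast, title) in zip(
        axes,
        [(maps.richness, "species richness"),
         (maps.hotspots, "HPS collecting-gap hotspots")],
    ):
        spec = rast.spec
        im = ax.imshow(
            np.where(rast.values >= 0, rast.values, np.nan),
            extent=(spec.x_min, spec.x_max, spec.y_min, spec.y_max),
            cmap="viridis",
        )
        ax.set_title(title)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(FIGURES_DIR / "priority_maps.png", dpi=150)
    print(f"figure written to {FIGURES_DIR / 'priority_maps.png'}")


if __name__ == "__main__":
    main()
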