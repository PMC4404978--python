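"""Ecogeographic characterization: overlap, PCA, clusters, niche summaries.

Pairwise geographic (Jaccard) and niche (Schoener's D, adjusted I) overlap,
a Bartlett-validated PCA of the occurrence-level environment, hierarchical
clustering on the leading components, and per-species niche summaries
against a harvested-area-weighted crop baseline.
"""

import numpy as np
import pandas as pd

from common import MODELS_DIR, RESULTS, TRUTH_DIR, WORLD_DIR, load_stack, study_config
from cwrgap.geodata import read_occurrences, read_raster
from cwrgap.niche_compare import (
    crop_baseline,
    hcpc_clusters,
    niche_summary,
    overlap_matrices,
    pca_with_bartlett,
)
from cwrgap.occurrence_qc import modeling_points


def main() -> None:
    cfg = study_config()
    stack = load_stack()
    sets, _ = read_occurrences(RESULTS / "occurrences_clean.csv")
    taxa = [occ.taxon for occ in sets]

    ranges = {t: read_raster(MODELS_DIR / f"{t}_range.asc") for t in taxa}
    suits = {t: read_raster(TRUTH_DIR / f"{t}.asc") for t in taxa}
    overlap = overlap_matrices(ranges, suits)
    overlap.frame("geographic").to_csv(RESULTS / "overlap_geographic.csv")
    overlap.frame("D").to_csv(RESULTS / "overlap_D.csv")
    overlap.frame("I").to_csv(RESULTS / "overlap_I.csv")
    off = ~np.eye(len(taxa), dtype=bool)
    print(f"geographic overlap (Jaccard) range "
          f"{overlap.geographic[off].min():.3f}-{overlap.geographic[off].max():.3f}; "
          f"Schoener's D range {overlap.schoener[off].min():.3f}-"
          f"{overlap.schoener[off].max():.3f}")

    # occurrence-level environment matrix for PCA + clustering
    rows, labels = [], []
    for occ in sets:
        for lon, lat in modeling_points(occ, cfg.grid):
            rows.append((lon, lat))
            labels.append(occ.taxon)
    pts = np.array(rows)
    labels = np.array(labels)
    X = np.empty((len(pts), len(stack.names)))
    for j, name in enumerate(stack.names):
        X[:, j] = stack.layers[name].sample(pts[:, 0], pts[:, 1])
    keep = ~np.isnan(X).any(axis=1)
    X, labels = X[keep], labels[keep]

    pca = pca_with_bartlett(X, names=list(stack.names))
    evr = pca.explained_variance_ratio
    n_comp = max(4, int(np.searchsorted(np.cumsum(evr), 0.75) + 1))
    print(f"Bartlett chi2={pca.bartlett_chi2:.0f} (df={pca.bartlett_df}, "
          f"p={pca.bartlett_p:.2e}); "
          f"{100 * evr[:4].sum():.1f}% of variance in four components")
    pd.DataFrame(
        {"component": np.arange(1, len(evr) + 1),
         "explained_variance_ratio": evr}
    ).to_csv(RESULTS / "pca_report.csv", index=False)

    clusters = hcpc_clusters(pca.scores[:, :n_comp], X, list(stack.names),
                             labels)
    pd.DataFrame({"taxon": labels, "lon": pts[keep, 0], "lat": pts[keep, 1],
                  "cluster": clusters.assignments}).to_csv(
        RESULTS / "clusters.csv", index=False)
    desc_rows = [
        {"cluster": c, "variable": name, "direction": d}
        for c, desc in clusters.describing_variables.items()
        for name, d in desc
    ]
    pd.DataFrame(desc_rows).to_csv(RESULTS / "cluster_description.csv",
                                   index=False)
    print(f"{clusters.n_clusters} ecogeographic clusters; memberships:")
    print(clusters.species_proportions.round(2).to_string())

    harvested = read_raster(WORLD_DIR / "harvested_area.asc")
    summaries = [crop_baseline(harvested, stack, n=1000, seed=cfg.seed)]
    for occ in sets:
        summaries.append(
            niche_summary(modeling_points(occ, cfg.grid), stack, occ.taxon))
    frames = []
    for s in summaries:
        t = s.table.reset_index(names="variable")
        t.insert(0, "taxon", s.taxon)
        frames.append(t)
    pd.concat(frames).to_csv(RESULTS / "niche_summaries.csv", index=False)
    print(f"niche summaries (crop baseline + {len(sets)} species) written")


if __name__ == "__main__":
    main()
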