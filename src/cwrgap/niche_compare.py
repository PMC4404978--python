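"""Ecogeographic characterization: overlap, PCA, clustering, niche summaries.

Pairwise geography is compared by the Jaccard fraction of shared presence
cells; pairwise niches by Schoener's D (L1) and the Hellinger-based adjusted
similarity I on suitability surfaces normalized to probability mass.  A
correlation-matrix PCA over occurrence-level environmental values (validated
by Bartlett's sphericity test) feeds Ward hierarchical clustering on the
component scores (HCPC); clusters are then described by the variables whose
within-cluster mean departs >= 15% from the global mean while the
within-cluster spread shrinks by >= 20%.  Per-species niche summaries and a
harvested-area-weighted crop baseline support the boxplot-style comparison
of wild taxa against the cultivated crop's environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .geodata import Raster, VariableStack


class CompareError(ValueError):
    pass


# ---------------------------------------------------------------------------
# geographic and niche overlap
# ---------------------------------------------------------------------------


def geographic_overlap(dist_a: Raster, dist_b: Raster) -> float:
    """Jaccard share of co-occupied grid cells between two binary ranges."""
    if dist_a.spec != dist_b.spec:
        raise CompareError("ranges are not on the same grid")
    a = dist_a.values == 1
    b = dist_b.values == 1
    union = int((a | b).sum())
    if union == 0:
        raise CompareError("both ranges are empty")
    return float((a & b).sum() / union)


def _normalize_surface(p: np.ndarray, valid: np.ndarray) -> np.ndarray:
    z = np.where(valid, np.maximum(p, 0.0), 0.0)
    total = z.sum()
    if total <= 0:
        raise CompareError("suitability surface sums to zero; cannot normalize")
    return z / total


def schoener_d(p_a: Raster, p_b: Raster) -> float:
    """Schoener's D = 1 - 1/2 sum |pA - pB| on unit-mass surfaces."""
    if p_a.spec != p_b.spec:
        raise CompareError("surfaces are not on the same grid")
    valid = p_a.mask | p_b.mask
    a = _normalize_surface(np.where(p_a.mask, p_a.values, 0.0), valid)
    b = _normalize_surface(np.where(p_b.mask, p_b.values, 0.0), valid)
    return float(1.0 - 0.5 * np.abs(a - b).sum())


def warren_i(p_a: Raster, p_b: Raster) -> float:
    """Adjusted similarity I = 1 - 1/2 sum (sqrt pA - sqrt pB)^2 (Hellinger)."""
    if p_a.spec != p_b.spec:
        raise CompareError("surfaces are not on the same grid")
    valid = p_a.mask | p_b.mask
    a = _normalize_surface(np.where(p_a.mask, p_a.values, 0.0), valid)
    b = _normalize_surface(np.where(p_b.mask, p_b.values, 0.0), valid)
    return float(1.0 - 0.5 * ((np.sqrt(a) - np.sqrt(b)) ** 2).sum())


@dataclass
class OverlapMatrix:
    taxa: list[str]
    geographic: np.ndarray
    schoener: np.ndarray
    adjusted_i: np.ndarray

    def frame(self, which: str) -> pd.DataFrame:
        m = {"geographic": self.geographic, "D": self.schoener,
             "I": self.adjusted_i}[which]
        return pd.DataFrame(m, index=self.taxa, columns=self.taxa)


def overlap_matrices(
    ranges: dict[str, Raster], suitabilities: dict[str, Raster]
) -> OverlapMatrix:
    """All pairwise overlap matrices; symmetric with unit diagonal."""
    taxa = list(ranges)
    n = len(taxa)
    geo = np.eye(n)
    d = np.eye(n)
    i_m = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            geo[a, b] = geo[b, a] = geographic_overlap(ranges[taxa[a]], ranges[taxa[b]])
            d[a, b] = d[b, a] = schoener_d(
                suitabilities[taxa[a]], suitabilities[taxa[b]]
            )
            i_m[a, b] = i_m[b, a] = warren_i(
                suitabilities[taxa[a]], suitabilities[taxa[b]]
            )
    return OverlapMatrix(taxa, geo, d, i_m)


# ---------------------------------------------------------------------------
# PCA with Bartlett's sphericity test
# ---------------------------------------------------------------------------


@dataclass
class PcaReport:
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (p, p) unit eigenvectors, columns = components
    variable_correlations: np.ndarray  # (p, n_comp) variable-PC correlations
    scores: np.ndarray  # (n, p)
    columns: list[str]
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def pca_with_bartlett(X: np.ndarray, names: list[str] | None = None) -> PcaReport:
    """Correlation-matrix PCA preceded by Bartlett's test of sphericity.

    Bartlett's chi-square = -[(n-1) - (2p+5)/6] ln det(R) with p(p-1)/2
    degrees of freedom; a small p-value rejects an identity correlation
    matrix and licenses the PCA.  Requires complete rows and n > p.
    """
    X = np.asarray(X, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, p = X.shape
    if n <= p:
        raise CompareError(f"Bartlett's test needs n > p (n={n}, p={p})")
    names = names if names is not None else [f"x{j}" for j in range(p)]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant columns: {[n_ for n_, k in zip(names, keep) if not k]}"
        )
        X = X[:, keep]
        names = [n_ for n_, k in zip(names, keep) if k]
        p = X.shape[1]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular correlation matrix; determinant clipped")
        logdet = np.log(1e-300)
    chi2 = -((n - 1) - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(max(chi2, 0.0), df))

    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    ratio = eigval / eigval.sum()
    scores = Z @ eigvec
    # variable-component correlations = loading * sqrt(eigenvalue)
    corr = eigvec * np.sqrt(eigval)[None, :]
    return PcaReport(
        explained_variance_ratio=ratio,
        components=eigvec,
        variable_correlations=corr,
        scores=scores,
        columns=names,
        bartlett_chi2=float(chi2),
        bartlett_df=int(df),
        bartlett_p=pval,
    )


# ---------------------------------------------------------------------------
# HCPC-style clustering of occurrences in PC space
# ---------------------------------------------------------------------------

MEAN_DIFF_RULE = 0.15  # cluster mean departs >= 15% of |global mean|
SD_REDUCTION_RULE = 0.20  # cluster SD <= 80% of global SD
SECONDARY_MEMBERSHIP = 0.25  # second cluster label when proportion >= 0.25


@dataclass
class ClusterResult:
    assignments: np.ndarray  # cluster id (1-based) per occurrence row
    n_clusters: int
    describing_variables: dict[int, list[tuple[str, str]]]  # id -> (var, +/-)
    species_proportions: pd.DataFrame  # species x cluster membership shares
    species_labels: dict[str, tuple[int, int | None]]  # primary, secondary


def _choose_cut(Z: np.ndarray, k_range=range(2, 7)) -> int:
    """Cut maximizing the relative loss-of-inertia jump (elbow rule)."""
    heights = Z[:, 2]
    n = Z.shape[0] + 1
    # merging cost when going from k to k-1 clusters is heights[n-k]
    best_k, best_jump = 2, -np.inf
    for k in k_range:
        if k >= n:
            break
        upper = heights[n - k]  # cost of merging k -> k-1
        lower = heights[n - k - 1] if n - k - 1 >= 0 else upper
        jump = upper / lower if lower > 0 else np.inf
        if jump > best_jump:
            best_jump, best_k = jump, k
    return best_k


def hcpc_clusters(
    scores: np.ndarray,
    variables: np.ndarray,
    variable_names: list[str],
    species: np.ndarray,
    n_clusters: int | None = None,
) -> ClusterResult:
    """Ward clustering on PC scores with cluster-describing variables.

    ``scores`` are the retained PC coordinates per occurrence, ``variables``
    the raw environmental values used to describe clusters, ``species`` the
    taxon label per occurrence.  When ``n_clusters`` is not given, the cut
    between 2 and 6 clusters with the largest relative inertia jump is used.
    A variable describes a cluster when its cluster mean differs from the
    global mean by >= 15% of the global mean's magnitude (or, for variables
    centered on zero, by >= 0.15 global SD) and its cluster SD is at most 80%
    of the global SD; the sign records the direction of the departure.
    """
    scores = np.asarray(scores, dtype=float)
    variables = np.asarray(variables, dtype=float)
    species = np.asarray(species)
    n = scores.shape[0]
    if n_clusters is not None and n < n_clusters:
        raise CompareError(f"{n} rows cannot form {n_clusters} clusters")
    if n < 4:
        raise CompareError("too few occurrences to cluster")
    Z = linkage(scores, method="ward")
    k = n_clusters if n_clusters is not None else _choose_cut(Z)
    assignments = fcluster(Z, t=k, criterion="maxclust")

    describing: dict[int, list[tuple[str, str]]] = {}
    g_mean = np.nanmean(variables, axis=0)
    g_sd = np.nanstd(variables, axis=0, ddof=1)
    for c in range(1, k + 1):
        in_c = assignments == c
        rows = []
        c_mean = np.nanmean(variables[in_c], axis=0)
        c_sd = (
            np.nanstd(variables[in_c], axis=0, ddof=1)
            if in_c.sum() > 1
            else np.zeros_like(g_sd)
        )
        for j, name in enumerate(variable_names):
            if g_sd[j] == 0:
                continue
            diff = c_mean[j] - g_mean[j]
            if abs(g_mean[j]) > 1e-12:
                mean_rule = abs(diff) >= MEAN_DIFF_RULE * abs(g_mean[j])
            else:  # zero-mean variable: absolute criterion in SD units
                mean_rule = abs(diff) >= MEAN_DIFF_RULE * g_sd[j]
            sd_rule = c_sd[j] <= (1 - SD_REDUCTION_RULE) * g_sd[j]
            if mean_rule and sd_rule:
                rows.append((name, "+" if diff > 0 else "-"))
        describing[c] = rows

    taxa = pd.unique(species)
    prop = pd.DataFrame(0.0, index=taxa, columns=range(1, k + 1))
    labels: dict[str, tuple[int, int | None]] = {}
    for t in taxa:
        sel = species == t
        counts = np.bincount(assignments[sel], minlength=k + 1)[1:]
        shares = counts / counts.sum()
        prop.loc[t] = shares
        order = np.argsort(-shares)
        primary = int(order[0]) + 1
        secondary = (
            int(order[1]) + 1
            if len(order) > 1 and shares[order[1]] >= SECONDARY_MEMBERSHIP
            else None
        )
        labels[t] = (primary, secondary)
    return ClusterResult(assignments, k, describing, prop, labels)


# ---------------------------------------------------------------------------
# niche summaries and the crop baseline
# ---------------------------------------------------------------------------


@dataclass
class NicheSummary:
    """Distributional summary of environmental values at presence locations.

    The whisker bounds cover 90% of total variation (5th-95th percentiles),
    matching boxplot conventions for outlier display.
    """

    taxon: str
    table: pd.DataFrame  # index = variable; median/q25/q75/p5/p95/min/max


def _summary_table(values: np.ndarray, names: list[str]) -> pd.DataFrame:
    rows = {}
    for j, name in enumerate(names):
        col = values[:, j]
        col = col[~np.isnan(col)]
        rows[name] = {
            "median": np.median(col),
            "q25": np.percentile(col, 25),
            "q75": np.percentile(col, 75),
            "p5": np.percentile(col, 5),
            "p95": np.percentile(col, 95),
            "min": col.min(),
            "max": col.max(),
        }
    return pd.DataFrame(rows).T


def niche_summary(points: np.ndarray, stack: VariableStack, taxon: str) -> NicheSummary:
    """Per-variable summary of the stack at a species' occurrence cells."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise CompareError("no points to summarize")
    vals = np.empty((pts.shape[0], len(stack.names)))
    for j, name in enumerate(stack.names):
        vals[:, j] = stack.layers[name].sample(pts[:, 0], pts[:, 1])
    keep = ~np.isnan(vals).all(axis=1)
    return NicheSummary(taxon, _summary_table(vals[keep], list(stack.names)))


def crop_baseline(
    harvested_area: Raster,
    stack: VariableStack,
    n: int = 1000,
    seed: int = 0,
) -> NicheSummary:
    """Crop-environment baseline from harvested-area-weighted random cells.

    Draws ``n`` cells (default 1,000) with replacement, with probability
    proportional to harvested area, and summarizes the stack there — the
    cultivated counterpart to the per-species niche summaries.
    """
    if n < 1:
        raise CompareError("n must be >= 1")
    if harvested_area.spec != stack.spec:
        raise CompareError("harvested-area raster not aligned to the stack")
    w = np.where(harvested_area.mask, np.maximum(harvested_area.values, 0.0), 0.0)
    total = w.sum()
    if total <= 0:
        raise CompareError("harvested area is all zero")
    rng = np.random.default_rng(seed)
    idx = rng.choice(w.size, size=n, p=(w / total).ravel())
    rows, cols = np.unravel_index(idx, w.shape)
    vals = stack.matrix_at_cells(rows, cols)
    vals[vals == -9999.0] = np.nan
    return NicheSummary("crop", _summary_table(vals, list(stack.names)))
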