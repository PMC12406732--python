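"""Distance-binned neighborhood statistics and neighborhood clustering.

Cross-phenotype neighbor counts use right-closed distance bins
(d_k, d_{k+1}] with 25 µm default width (first bin (0, 25]); self-pairs are
excluded and no edge correction is applied (raw counts, as in the source
analyses).  Decay gradients are least-squares fits of log(mean count)
against bin midpoint; the decay length λ is −1/slope.  Neighborhood
composition vectors (phenotype counts within a radius) are clustered by
k-means in standardized feature space; a UMAP embedding is available for
presentation only and never defines the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

DEFAULT_BIN_EDGES = tuple(float(x) for x in range(0, 275, 25))
DEFAULT_NEIGHBORHOOD_RADIUS = 50.0


@dataclass
class NeighborProfile:
    """Mean per-focal-cell neighbor counts by distance bin."""

    focal: str
    target: str
    bin_edges: np.ndarray            # µm, strictly increasing, right-closed
    mean_counts: np.ndarray          # per focal cell, per bin
    enrichment: np.ndarray           # observed / CSR expectation per bin
    n_focal: int
    n_target: int

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class DecayFit:
    """Exponential decay-length fit of a neighbor profile."""

    decay_length_um: float
    slope: float
    p_value: float
    has_gradient: bool               # slope significantly negative (P ≤ 0.05)
    n_bins_used: int


def _bin_index(d: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Right-closed bin index; distance 0 (coincident cells) joins bin 0."""
    idx = np.searchsorted(edges, d, side="left") - 1
    idx[d <= edges[0]] = 0 if edges[0] == 0.0 else -1
    return idx


def binned_neighbor_counts(cells: pd.DataFrame, focal: str, target: str,
                           bin_edges=DEFAULT_BIN_EDGES,
                           field_area_um2: float | None = None,
                           ) -> NeighborProfile:
    """Mean number of target cells per focal cell in each distance bin.

    Exact (matches an all-pairs count): pairs are found with a KD-tree at
    the outermost edge, then histogrammed into right-closed bins.
    Enrichment divides each bin by the CSR expectation (target intensity ×
    annulus area), when the field area is known.
    """
    edges = np.asarray(bin_edges, float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    ph = cells["phenotype"].to_numpy()
    fidx = np.flatnonzero(ph == focal)
    tidx = np.flatnonzero(ph == target)
    if len(fidx) == 0:
        raise ValueError(f"no focal cells of phenotype {focal!r}")
    nb = len(edges) - 1
    counts = np.zeros(nb)
    if len(tidx):
        xy = cells[["x_um", "y_um"]].to_numpy()
        ft = cKDTree(xy[fidx])
        tt = cKDTree(xy[tidx])
        pairs = ft.query_ball_tree(tt, r=float(edges[-1]))
        same = focal == target
        for i, js in enumerate(pairs):
            js = np.asarray(js, dtype=int)
            if same:
                js = js[tidx[js] != fidx[i]]   # exclude self-pairs
            if len(js) == 0:
                continue
            d = np.hypot(*(xy[tidx[js]] - xy[fidx[i]]).T)
            b = _bin_index(d, edges)
            ok = (b >= 0) & (b < nb)
            np.add.at(counts, b[ok], 1)
    mean_counts = counts / len(fidx)
    enrichment = np.full(nb, np.nan)
    if field_area_um2 and len(tidx):
        intensity = len(tidx) / field_area_um2
        ann = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            enrichment = mean_counts / (intensity * ann)
    return NeighborProfile(focal=focal, target=target, bin_edges=edges,
                           mean_counts=mean_counts, enrichment=enrichment,
                           n_focal=len(fidx), n_target=len(tidx))


def decay_gradient(profile: NeighborProfile,
                   quantity: str = "counts") -> DecayFit:
    """Fit log(quantity) vs bin midpoint; λ = −1/slope.

    ``quantity`` is ``"counts"`` (mean neighbor count per bin, for profiles
    whose counts themselves decay) or ``"enrichment"`` (count normalized to
    the CSR expectation — the clustering measure whose fall-off with
    distance is the gradient of interest inside extended structures, where
    raw counts grow with annulus area).

    Requires ≥ 4 nonzero bins; all-zero (or too-sparse) profiles return the
    no-gradient sentinel (NaN λ, flag False).  The gradient flag requires a
    significantly negative slope (two-sided P ≤ 0.05 halved for direction).
    """
    if quantity not in ("counts", "enrichment"):
        raise ValueError("quantity must be 'counts' or 'enrichment'")
    y = profile.mean_counts if quantity == "counts" else profile.enrichment
    y = np.where(np.isfinite(y), y, 0.0)
    keep = y > 0
    if keep.sum() < 4:
        return DecayFit(float("nan"), float("nan"), float("nan"), False,
                        int(keep.sum()))
    x = profile.midpoints[keep]
    fit = stats.linregress(x, np.log(y[keep]))
    slope = float(fit.slope)
    lam = -1.0 / slope if slope < 0 else float("inf")
    p_neg = fit.pvalue / 2.0 if slope < 0 else 1.0 - fit.pvalue / 2.0
    return DecayFit(decay_length_um=lam, slope=slope, p_value=float(p_neg),
                    has_gradient=bool(slope < 0 and p_neg <= 0.05),
                    n_bins_used=int(keep.sum()))


def density_heatmap(cells: pd.DataFrame, mask: np.ndarray | None,
                    field_width: float, field_height: float,
                    grid_size: float = 25.0, bandwidth: float = 50.0,
                    ) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Gaussian-kernel density raster (cells per µm²) over the field.

    ``mask`` selects the cells to map (None = all).  The raster integrates
    to the mapped cell count (up to boundary truncation).  Returns
    (raster[ny, nx], extent (x0, x1, y0, y1)); row 0 is the top of the field
    (image convention).
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be > 0")
    sub = cells if mask is None else cells[np.asarray(mask, bool)]
    nx = max(int(np.ceil(field_width / grid_size)), 1)
    ny = max(int(np.ceil(field_height / grid_size)), 1)
    hist, _, _ = np.histogram2d(
        sub["y_um"].to_numpy(), sub["x_um"].to_numpy(), bins=(ny, nx),
        range=((0.0, ny * grid_size), (0.0, nx * grid_size)))
    smooth = gaussian_filter(hist, sigma=bandwidth / grid_size,
                             mode="constant")
    return smooth / grid_size**2, (0.0, nx * grid_size, ny * grid_size, 0.0)


def neighborhood_features(cells: pd.DataFrame,
                          radius: float = DEFAULT_NEIGHBORHOOD_RADIUS,
                          phenotypes: tuple[str, ...] | None = None,
                          ) -> pd.DataFrame:
    """Per-cell neighborhood composition: phenotype counts within radius.

    Self-excluded, distance ≤ radius, deterministic.  Matches the all-pairs
    brute force exactly.
    """
    ph = cells["phenotype"].to_numpy()
    if phenotypes is None:
        phenotypes = tuple(sorted(set(ph)))
    code = {p: i for i, p in enumerate(phenotypes)}
    ph_code = np.array([code.get(p, -1) for p in ph])
    xy = cells[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    feats = np.zeros((len(cells), len(phenotypes)), dtype=np.int64)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        ok = ph_code[j] >= 0
        np.add.at(feats, (i[ok], ph_code[j][ok]), 1)
        ok = ph_code[i] >= 0
        np.add.at(feats, (j[ok], ph_code[i][ok]), 1)
    return pd.DataFrame(feats, index=cells.index,
                        columns=[f"nb_{p}" for p in phenotypes])


@dataclass
class NeighborhoodClustering:
    labels: np.ndarray
    centers: np.ndarray              # in standardized feature space
    k: int
    embedding: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)


def cluster_neighborhoods(features: pd.DataFrame, k: int = 8, seed: int = 0,
                          embed: bool = False) -> NeighborhoodClustering:
    """k-means over standardized composition vectors (+ optional UMAP).

    The embedding is 2-D and for visualization only; cluster labels are
    defined in feature space and do not depend on it.
    """
    from sklearn.cluster import KMeans
    from sklearn.preprocessing import StandardScaler
    X = features.to_numpy(dtype=float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of cells {len(X)}")
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = StandardScaler().fit_transform(X[:, keep]) if keep.any() \
        else np.zeros_like(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(Xs)
    emb = None
    if embed:
        import umap
        emb = umap.UMAP(random_state=seed).fit_transform(Xs)
    return NeighborhoodClustering(labels=km.labels_, centers=km.cluster_centers_,
                                  k=k, embedding=emb,
                                  feature_names=list(features.columns))


def differential_cluster_abundance(labels: np.ndarray, groups: np.ndarray,
                                   deceased: str = "deceased",
                                   alive: str = "alive") -> pd.DataFrame:
    """Per-cluster %deceased-cell share normalized to %alive-cell share.

    Shares within each group sum to 100%.  A zero share on either side gets
    an additive pseudo-share (half the smallest nonzero share in the table)
    on both sides, flagged in the ``smoothed`` column.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    for g in (deceased, alive):
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} has zero cells")
    ks = np.unique(labels)
    share = {}
    for g in (deceased, alive):
        sel = labels[groups == g]
        share[g] = np.array([(sel == k).mean() * 100.0 for k in ks])
    nz = np.concatenate([share[deceased], share[alive]])
    nz = nz[nz > 0]
    pseudo = nz.min() / 2.0 if len(nz) else 1.0
    rows = []
    for i, k in enumerate(ks):
        d, a = share[deceased][i], share[alive][i]
        smoothed = d == 0 or a == 0
        if smoothed:
            d, a = d + pseudo, a + pseudo
        rows.append({"cluster": int(k),
                     "pct_deceased": share[deceased][i],
                     "pct_alive": share[alive][i],
                     "ratio_deceased_over_alive": d / a,
                     "smoothed": smoothed})
    return pd.DataFrame(rows)
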