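"""Weighted functional graphs and anatomy/distance-based edge structure.

A subject's connectome is the Fisher-Z-transformed Pearson correlation
matrix of the cleaned ROI series over retained frames: an undirected,
weighted, fully dense graph — no thresholding or binning. Edge classes
(short/long range, lobe sub-networks, interhemispheric, subcortical) are
fixed across gestation from the Euclidean distances at the 37-week
reference atlas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._utils import triu_pairs, upper_vec
from .atlas import RoiAtlas, scale_atlas
from .preprocess import CleanedSeries

__all__ = [
    "ConnectivityMatrix",
    "EdgeClassification",
    "build_graph",
    "edge_count",
    "classify_edges",
    "subnetwork_mean",
    "mean_distance",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric correlation (r) and Fisher-Z matrices for one subject.

    ``Z = atanh(r)`` elementwise off the diagonal; the diagonal is excluded
    from every statistic (stored as r=1, Z=0).
    """

    r: np.ndarray
    Z: np.ndarray
    n_frames_used: int
    region_names: tuple = ()

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    @property
    def z_vec(self) -> np.ndarray:
        """Strict-upper-triangle Fisher-Z edge vector."""
        return upper_vec(self.Z)


def build_graph(clean: CleanedSeries, region_names=()) -> ConnectivityMatrix:
    """Pearson/Fisher-Z connectivity from cleaned series on retained frames.

    Correlations are clipped to +/-(1 - 1e-7) before the Fisher transform so
    duplicate columns stay finite; zero-variance regions get zero edges with
    a warning.
    """
    if not clean.usable or clean.n_frames < 10:
        raise ValueError("need a usable series with at least 10 retained frames")
    data = np.asarray(clean.data, dtype=float)
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        warnings.warn(
            f"zero-variance region(s) {dead.tolist()}; their edges are set to 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    if dead.size:
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    r = np.clip(r, -R_CLIP, R_CLIP)
    np.fill_diagonal(r, 1.0)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        r=r, Z=z, n_frames_used=clean.n_frames, region_names=tuple(region_names)
    )


def edge_count(n_regions: int) -> int:
    """Number of undirected edges among ``n_regions`` nodes: n(n-1)/2."""
    n = int(n_regions)
    if n < 2:
        raise ValueError("need at least 2 regions")
    return n * (n - 1) // 2


@dataclass
class EdgeClassification:
    """Distance matrix and symmetric, diagonal-free edge-class masks."""

    distance_mm: np.ndarray
    q25_mm: float
    q75_mm: float
    short_mask: np.ndarray
    long_mask: np.ndarray
    lobe_masks: dict = field(default_factory=dict)
    interhemispheric_mask: np.ndarray | None = None
    subcortical_mask: np.ndarray | None = None

    def mask(self, name: str) -> np.ndarray:
        """Look up a mask by name: 'all', 'short', 'long', 'interhemispheric',
        'subcortical' or a lobe label."""
        if name == "all":
            out = np.ones_like(self.short_mask)
            np.fill_diagonal(out, False)
            return out
        if name == "short":
            return self.short_mask
        if name == "long":
            return self.long_mask
        if name == "interhemispheric":
            return self.interhemispheric_mask
        if name == "subcortical":
            return self.subcortical_mask
        if name in self.lobe_masks:
            return self.lobe_masks[name]
        raise KeyError(f"unknown edge class {name!r}")


def classify_edges(atlas: RoiAtlas) -> EdgeClassification:
    """Distance quartile and anatomy masks at the 37-week reference.

    Short edges: distance <= 25th percentile of the off-diagonal upper
    triangle (linear-interpolation quantiles); long edges: >= 75th
    percentile, with boundary ties excluded from 'long' if they are also
    'short' so the two classes stay disjoint. A lobe's sub-network contains
    every edge with at least one endpoint in that lobe.
    """
    coords = atlas.coord_ref
    dist = squareform(pdist(coords))
    if np.any(upper_vec(dist) == 0):
        warnings.warn("duplicate region coordinates produce zero distances", stacklevel=2)
    dvec = upper_vec(dist)
    q25, q75 = np.percentile(dvec, [25, 75])

    off_diag = ~np.eye(atlas.n_regions, dtype=bool)
    short = (dist <= q25) & off_diag
    long = (dist >= q75) & off_diag & ~short

    lobes = np.asarray(atlas.lobe)
    lobe_masks = {}
    for lobe in np.unique(lobes):
        inlobe = lobes == lobe
        lobe_masks[str(lobe)] = (inlobe[:, None] | inlobe[None, :]) & off_diag

    hemi = np.asarray(atlas.hemisphere)
    inter = (
        ((hemi[:, None] == "L") & (hemi[None, :] == "R"))
        | ((hemi[:, None] == "R") & (hemi[None, :] == "L"))
    ) & off_diag

    return EdgeClassification(
        distance_mm=dist,
        q25_mm=float(q25),
        q75_mm=float(q75),
        short_mask=short,
        long_mask=long,
        lobe_masks=lobe_masks,
        interhemispheric_mask=inter,
        subcortical_mask=lobe_masks.get(
            "subcortical", np.zeros_like(short)
        ),
    )


def subnetwork_mean(Z, mask) -> float:
    """Mean Fisher-Z over the masked strict-upper-triangle entries."""
    z = Z.Z if isinstance(Z, ConnectivityMatrix) else np.asarray(Z, dtype=float)
    m = np.asarray(mask, dtype=bool)
    i, j = triu_pairs(z.shape[0])
    sel = m[i, j]
    if not sel.any():
        raise ValueError("empty edge mask")
    return float(z[i, j][sel].mean())


def mean_distance(atlas: RoiAtlas, ga_weeks: float, edge_subset=None) -> float:
    """Mean Euclidean inter-region distance (mm) at age-scaled coordinates."""
    coords = scale_atlas(atlas, ga_weeks)
    dist = squareform(pdist(coords))
    i, j = triu_pairs(atlas.n_regions)
    vals = dist[i, j]
    if edge_subset is not None:
        sel = np.asarray(edge_subset, dtype=bool)[i, j]
        if not sel.any():
            raise ValueError("empty edge subset")
        vals = vals[sel]
    return float(vals.mean())
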