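"""Edge screening, per-edge age GLM, and network-based statistics (NBS).

Three stages of group inference on a stack of subject connectomes:

1. ``spatial_null_screen`` — compares each edge's cohort-mean Fisher-Z
   against random graphs in which connectivity is explained purely by
   spatial closeness (an exponential distance-decay curve plus Gaussian
   noise); edges not exceeding their simulated (1-alpha) quantile are
   screened out.
2. ``EdgeGLM`` — per edge, an F-test (1 numerator df) for the effect of
   gestational age in days given a per-subject motion covariate:
   F = ((SSE_reduced - SSE_full)/1) / (SSE_full/(n-3)).
3. ``NetworkBasedStatistic`` — family-wise error control over edges by
   permuting gestational age across subjects and comparing the extent
   (edge count) of observed suprathreshold connected components with the
   permutation distribution of the maximum extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse
import scipy.sparse.csgraph
from sklearn.base import BaseEstimator

from ._utils import as_rng, triu_pairs, upper_vec, vec_to_sym

__all__ = [
    "EdgeGLM",
    "NetworkBasedStatistic",
    "NbsResult",
    "spatial_null_screen",
    "edge_glm",
    "nbs",
    "node_stats",
]


def _edge_stack(z_stack: np.ndarray) -> np.ndarray:
    """Accept (subjects, n, n) or (subjects, E); return (subjects, E)."""
    z = np.asarray(z_stack, dtype=float)
    if z.ndim == 3:
        return upper_vec(z)
    if z.ndim == 2:
        return z
    raise ValueError("z_stack must be (subjects, n, n) or (subjects, n_edges)")


def _n_regions_from_edges(n_edges: int, strict: bool = True) -> int | None:
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n * (n - 1) // 2 != n_edges:
        if strict:
            raise ValueError(f"{n_edges} is not a triangular number of edges")
        return None
    return n


def spatial_null_screen(
    z_stack,
    distance_mm: np.ndarray,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed=0,
) -> np.ndarray:
    """Retain edges whose cohort-mean Z exceeds a spatial-closeness null.

    The null models the nuisance background as an exponential decay in
    distance, ``g(d) = z0 * exp(-d / lam)``. Because genuinely coupled
    edges sit above the background (and must not lift their own null), the
    curve is fitted with asymmetric trimming: after each least-squares
    pass, edges whose residual exceeds 2 robust SDs *above* the curve are
    excluded and the fit repeated. The null scale is the MAD-based robust
    SD of the kept residuals; ``n_sim`` random graphs then draw each edge
    from ``g(d) + N(0, SD)`` and an edge is retained when its observed
    mean exceeds its simulated (1-alpha) quantile. Returns a symmetric
    boolean matrix.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    z = _edge_stack(z_stack)
    n = _n_regions_from_edges(z.shape[1])
    d = upper_vec(np.asarray(distance_mm, dtype=float))
    obs = z.mean(axis=0)

    def decay(dist, z0, lam):
        return z0 * np.exp(-dist / lam)

    def robust_sd(x):
        return float(1.4826 * np.median(np.abs(x - np.median(x))))

    def fit_background(predict, fit):
        kept = np.ones(obs.size, dtype=bool)
        g = None
        for _ in range(5):
            g = predict(fit(d[kept], obs[kept]))
            resid = obs - g
            sd = max(robust_sd(resid[kept]), 1e-9)
            new_kept = resid <= 2.0 * sd
            if new_kept.sum() < max(10, obs.size // 10) or np.array_equal(new_kept, kept):
                break
            kept = new_kept
        return g, kept

    try:
        p0 = np.array([max(obs.max(), 1e-3), max(np.median(d), 1.0)])

        def fit(dd, oo):
            return scipy.optimize.least_squares(
                lambda p: decay(dd, *p) - oo, p0, max_nfev=10000
            ).x

        g, kept = fit_background(lambda p: decay(d, *p), fit)
        if not np.all(np.isfinite(g)):
            raise RuntimeError("non-finite decay fit")
    except (RuntimeError, ValueError):
        warnings.warn("exponential decay fit failed; falling back to linear decay", stacklevel=2)
        g, kept = fit_background(
            lambda coef: np.polyval(coef, d), lambda dd, oo: np.polyfit(dd, oo, 1)
        )

    resid_sd = robust_sd((obs - g)[kept])
    rng = as_rng(seed)
    if resid_sd < 1e-12:
        retained = (obs - g) > 1e-9 * (np.abs(obs) + 1.0)
    else:
        sims = rng.normal(loc=g, scale=resid_sd, size=(int(n_sim), d.size))
        cut = np.quantile(sims, 1 - alpha, axis=0)
        retained = obs > cut
    return vec_to_sym(retained.astype(float), n).astype(bool)


def _residualize(vec: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, vec, rcond=None)
    return vec - design @ beta


class EdgeGLM(BaseEstimator):
    """Per-edge GLM: Fisher-Z strength ~ intercept + motion + gestational days.

    The F statistic (and the identical squared t of the age coefficient)
    compares the full model against intercept+motion, via least squares,
    vectorized across edges.
    """

    def fit(self, z_stack, ga_days, motion):
        z = _edge_stack(z_stack)
        ga = np.asarray(ga_days, dtype=float)
        mot = np.asarray(motion, dtype=float)
        n_sub = z.shape[0]
        if n_sub < 5:
            raise ValueError("need at least 5 subjects")
        if ga.shape != (n_sub,) or mot.shape != (n_sub,):
            raise ValueError("ga_days and motion must be per-subject vectors")
        if np.ptp(ga) == 0:
            raise ValueError("gestational age is constant across subjects")

        design_red = np.column_stack([np.ones(n_sub), mot])
        y_res = _residualize(z, design_red)
        g_res = _residualize(ga, design_red)
        gg = float(g_res @ g_res)
        sse_red = (y_res**2).sum(axis=0)
        gy = g_res @ y_res
        explained = gy**2 / gg
        sse_full = np.maximum(sse_red - explained, 0.0)
        df_resid = n_sub - 3
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(sse_full > 0, explained / (sse_full / df_resid), np.inf)

        full = np.column_stack([design_red, ga])
        beta, *_ = np.linalg.lstsq(full, z, rcond=None)

        self.n_subjects_ = n_sub
        self.n_regions_ = _n_regions_from_edges(z.shape[1], strict=False)
        self.df_ = (1, df_resid)
        self.F_ = f
        self.intercept_ = beta[0]
        self.coef_motion_ = beta[1]
        self.coef_ga_ = beta[2]
        self._y_res = y_res
        self._design_red = design_red
        self._ga = ga
        return self

    @property
    def F_matrix_(self) -> np.ndarray:
        if self.n_regions_ is None:
            raise ValueError("edge count is not triangular; no square F matrix exists")
        return vec_to_sym(self.F_, self.n_regions_)

    def permuted_f(self, perm: np.ndarray) -> np.ndarray:
        """F vector with gestational ages relabelled by ``perm`` (motion fixed)."""
        g = _residualize(self._ga[perm], self._design_red)
        gg = float(g @ g)
        gy = g @ self._y_res
        explained = gy**2 / gg
        sse_red = (self._y_res**2).sum(axis=0)
        sse_full = np.maximum(sse_red - explained, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sse_full > 0, explained / (sse_full / self.df_[1]), np.inf)


def edge_glm(z_stack, ga_days, motion) -> EdgeGLM:
    """Functional wrapper: fitted :class:`EdgeGLM`."""
    return EdgeGLM().fit(z_stack, ga_days, motion)


@dataclass
class NbsResult:
    """Suprathreshold components with family-wise-error-corrected p-values."""

    components: list  # list of edge-index arrays (into the triu edge order)
    extents: np.ndarray
    p_values: np.ndarray
    null_max_extent: np.ndarray
    threshold_f: float
    n_perm: int
    component_labels: np.ndarray  # per-edge component id (-1 outside)
    significant_mask: np.ndarray  # symmetric bool (p <= alpha components)
    alpha: float


def _components(supra: np.ndarray, n: int, i_idx, j_idx):
    """Connected components (node-edge sense) of the suprathreshold graph.

    Returns (list of edge-index arrays, per-edge labels) with labels -1 for
    sub-threshold edges.
    """
    labels_edge = np.full(supra.size, -1, dtype=int)
    comps = []
    sel = np.flatnonzero(supra)
    if sel.size == 0:
        return comps, labels_edge
    adj = scipy.sparse.coo_matrix(
        (np.ones(sel.size), (i_idx[sel], j_idx[sel])), shape=(n, n)
    )
    n_comp, node_label = scipy.sparse.csgraph.connected_components(adj, directed=False)
    edge_label = node_label[i_idx[sel]]
    for lab in np.unique(edge_label):
        members = sel[edge_label == lab]
        labels_edge[members] = len(comps)
        comps.append(members)
    return comps, labels_edge


class NetworkBasedStatistic(BaseEstimator):
    """NBS with the extent (edge-count) statistic and age-relabelling permutations."""

    def __init__(self, threshold_f: float = 5.0, n_perm: int = 5000, alpha: float = 0.05, seed=0):
        self.threshold_f = threshold_f
        self.n_perm = n_perm
        self.alpha = alpha
        self.seed = seed

    def fit(self, z_stack, ga_days, motion, edge_mask=None):
        if self.threshold_f <= 0:
            raise ValueError("threshold_f must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        glm = EdgeGLM().fit(z_stack, ga_days, motion)
        n = glm.n_regions_
        i_idx, j_idx = triu_pairs(n)
        if edge_mask is not None:
            mask_vec = np.asarray(edge_mask, dtype=bool)
            if mask_vec.ndim == 2:
                mask_vec = upper_vec(mask_vec)
        else:
            mask_vec = np.ones(glm.F_.size, dtype=bool)

        supra = (glm.F_ > self.threshold_f) & mask_vec
        comps, labels = _components(supra, n, i_idx, j_idx)
        extents = np.array([len(c) for c in comps], dtype=int)

        rng = as_rng(self.seed)
        n_sub = glm.n_subjects_
        null_max = np.zeros(self.n_perm, dtype=int)
        for p in range(self.n_perm):
            perm = rng.permutation(n_sub)
            f_perm = glm.permuted_f(perm)
            supra_p = (f_perm > self.threshold_f) & mask_vec
            comps_p, _ = _components(supra_p, n, i_idx, j_idx)
            null_max[p] = max((len(c) for c in comps_p), default=0)

        p_values = np.array(
            [(1 + int((null_max >= e).sum())) / (1 + self.n_perm) for e in extents]
        )
        sig_vec = np.zeros(glm.F_.size, dtype=bool)
        for comp, p_val in zip(comps, p_values):
            if p_val <= self.alpha:
                sig_vec[comp] = True

        self.glm_ = glm
        self.result_ = NbsResult(
            components=comps,
            extents=extents,
            p_values=p_values,
            null_max_extent=null_max,
            threshold_f=float(self.threshold_f),
            n_perm=int(self.n_perm),
            component_labels=labels,
            significant_mask=vec_to_sym(sig_vec.astype(float), n).astype(bool),
            alpha=float(self.alpha),
        )
        return self


def nbs(
    z_stack,
    ga_days,
    motion,
    threshold_f: float = 5.0,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed=0,
    edge_mask=None,
) -> NbsResult:
    """Functional wrapper around :class:`NetworkBasedStatistic`."""
    est = NetworkBasedStatistic(threshold_f=threshold_f, n_perm=n_perm, alpha=alpha, seed=seed)
    est.fit(z_stack, ga_days, motion, edge_mask=edge_mask)
    return est.result_


def node_stats(f_matrix: np.ndarray) -> np.ndarray:
    """Per-region mean F over the region's incident edges."""
    f = np.asarray(f_matrix, dtype=float)
    n = f.shape[0]
    off = f.copy()
    np.fill_diagonal(off, 0.0)
    return off.sum(axis=1) / (n - 1)
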