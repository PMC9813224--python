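"""Self-modelling curve resolution (MCR-ALS) and HCA imaging.

A hyperspectral map is unmixed by factorizing the pixel x wavenumber matrix
X into non-negative concentrations C and pure spectra S,

    X = C . S^T + E,

where E is the residual. Starting from a purest-pixel estimate of S, the
factorization alternates non-negativity-constrained least squares for C given
S and for S given C until the lack of fit stops changing. The scale ambiguity
is fixed by normalizing each pure spectrum to unit maximum; component order
and per-spectrum scale remain the only indeterminacies of the factorization.

Hierarchical cluster analysis (HCA) offers an independent, more abstract
segmentation of the same pixels: agglomerative grouping of pixel spectra into
clusters of similar spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core import HyperspectralMap

__all__ = [
    "MCRResult",
    "ClusterMap",
    "initialize_pure_spectra",
    "smcr_decompose",
    "concentration_image",
    "overlay_image",
    "hca_segment",
    "reconstruct_zstack",
    "surface_profile_image",
]


@dataclass
class MCRResult:
    """Outcome of one alternating-least-squares unmixing.

    ``C`` is (n_pixels, K) non-negative concentrations; ``S`` is (K,
    n_wavenumbers) non-negative pure spectra, each row normalized to unit
    maximum; ``E = X - C S`` is the residual. ``lack_of_fit`` traces
    ||X - C S||_F / ||X||_F * 100 per iteration and is non-increasing.
    """

    C: np.ndarray
    S: np.ndarray
    E: np.ndarray
    lack_of_fit: np.ndarray
    n_iterations: int
    converged: bool

    @property
    def n_components(self) -> int:
        return self.S.shape[0]


# ---------------------------------------------------------------------------
# non-negative least squares, vectorized over many small problems


def _solve_sym(G: np.ndarray, Bt: np.ndarray) -> np.ndarray:
    """Solve G Z = Bt, falling back to least squares when G is singular."""
    try:
        return np.linalg.solve(G, Bt)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(G, Bt, rcond=None)[0]


def _nnls_gram(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min_{c >= 0} c G c^T - 2 c . b for every row b of B.

    G is the K x K Gram matrix of the fixed factor; B is (n, K). For the
    small K used in unmixing the active set is found by enumerating all
    non-empty passive subsets and keeping the feasible solution with the
    lowest objective; rows whose unconstrained solution is already
    non-negative skip the enumeration.
    """
    n, k = B.shape
    C = _solve_sym(G, B.T).T
    bad = np.flatnonzero((C < 0).any(axis=1))
    if len(bad) == 0:
        return C
    C[bad] = 0.0
    Bb = B[bad]
    best_obj = np.zeros(len(bad))  # objective of the all-zero solution
    best = np.zeros((len(bad), k))
    for r in range(1, k + 1):
        for passive in combinations(range(k), r):
            p = list(passive)
            Gp = G[np.ix_(p, p)]
            sol = _solve_sym(Gp, Bb[:, p].T).T
            feasible = (sol >= 0).all(axis=1)
            if not feasible.any():
                continue
            # objective restricted to passive set: c Gp c^T - 2 c.b
            obj = np.einsum("ij,jk,ik->i", sol, Gp, sol) - 2 * np.einsum(
                "ij,ij->i", sol, Bb[:, p]
            )
            better = feasible & (obj < best_obj - 1e-12)
            if better.any():
                best_obj[better] = obj[better]
                best[better] = 0.0
                best[np.ix_(np.flatnonzero(better), p)] = sol[better]
    C[bad] = best
    return C


def _clip_ls(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Projection variant: unconstrained solve, negatives clipped to zero."""
    return np.clip(_solve_sym(G, B.T).T, 0.0, None)


# ---------------------------------------------------------------------------


def initialize_pure_spectra(X: np.ndarray, k: int) -> np.ndarray:
    """Purest-pixel initial estimate of S by sequential maximum dissimilarity.

    The first component is the most intense pixel spectrum (largest norm;
    lowest index on ties); each subsequent component is the pixel whose
    spectrum has the largest residual after projection onto the span of the
    already-selected spectra. Deterministic.
    """
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("need at least one component")
    if k > X.shape[0]:
        raise ValueError(f"K={k} exceeds the number of pixels ({X.shape[0]})")
    norms = np.linalg.norm(X, axis=1)
    chosen = [int(np.argmax(norms))]
    R = X.copy()
    for _ in range(1, k):
        s = R[chosen[-1]]
        denom = s @ s
        if denom > 0:
            R = R - np.outer((R @ s) / denom, s)
        resid = np.linalg.norm(R, axis=1)
        resid[chosen] = -1.0
        chosen.append(int(np.argmax(resid)))
    S = X[chosen].copy()
    peak = S.max(axis=1)
    if np.any(peak <= 0):
        raise ValueError(f"cannot extract {k} non-trivial components from this map")
    return S / peak[:, None]


def smcr_decompose(
    X: np.ndarray | HyperspectralMap,
    k: int,
    tolerance: float = 1e-6,
    max_iter: int = 500,
    nonneg: str = "nnls",
    init_S: np.ndarray | None = None,
) -> MCRResult:
    """Unmix a map into K components by alternating least squares.

    Each half-step solves a non-negativity-constrained least-squares problem
    (``nonneg='nnls'``; ``'clip'`` selects the cheaper projection variant).
    Iteration stops when the relative change of the lack of fit drops below
    ``tolerance`` or after ``max_iter`` iterations (the result is then
    returned with ``converged=False``).
    """
    if isinstance(X, HyperspectralMap):
        X = X.as_matrix()
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite entries")
    if k < 1:
        raise ValueError("need at least one component")
    solve = {"nnls": _nnls_gram, "clip": _clip_ls}.get(nonneg)
    if solve is None:
        raise ValueError(f"unknown non-negativity mode {nonneg!r}")

    S = initialize_pure_spectra(X, k) if init_S is None else np.asarray(init_S, dtype=float).copy()
    norm_x = np.linalg.norm(X)
    lof_trace = []
    converged = False
    C = np.zeros((X.shape[0], k))
    for it in range(max_iter):
        C = solve(S @ S.T, X @ S.T)
        S = solve(C.T @ C, X.T @ C).T
        # fix the scale ambiguity: unit-maximum pure spectra
        peak = S.max(axis=1)
        peak[peak == 0] = 1.0
        S /= peak[:, None]
        C *= peak[None, :]
        lof = float(np.linalg.norm(X - C @ S) / norm_x * 100.0)
        lof_trace.append(lof)
        if lof < 1e-9:  # exact reconstruction up to round-off
            converged = True
            break
        if it > 0 and abs(lof_trace[-2] - lof) / max(lof_trace[-2], 1e-30) < tolerance:
            converged = True
            break
    E = X - C @ S
    return MCRResult(
        C=C, S=S, E=E,
        lack_of_fit=np.asarray(lof_trace),
        n_iterations=len(lof_trace),
        converged=converged,
    )


def concentration_image(
    result: MCRResult, component: int, shape: tuple[int, int]
) -> dict:
    """One component's concentration column reshaped to the pixel grid.

    Returns the raw (row-major) image plus a min-max scaled display copy;
    the raw intensity range is retained alongside.
    """
    if not 0 <= component < result.n_components:
        raise ValueError(f"component {component} out of range")
    raw = result.C[:, component].reshape(shape)
    lo, hi = float(raw.min()), float(raw.max())
    display = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return {"raw": raw, "display": display, "range": (lo, hi)}


def overlay_image(
    images: list[np.ndarray],
    colours: list[tuple[float, float, float]],
    min_lut_adjust: list[float] | None = None,
) -> np.ndarray:
    """Additive pseudocolour composite of concentration images.

    Each image (scaled to [0, 1]) is mapped onto its RGB colour; raising a
    channel's minimum LUT bound suppresses its low-intensity pixels to
    background before compositing, the adjustment used to merge protein and
    lipid maps cleanly.
    """
    if len(images) != len(colours):
        raise ValueError("need one colour per image")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError("images must share geometry")
    floors = min_lut_adjust or [0.0] * len(images)
    out = np.zeros(images[0].shape + (3,))
    for im, colour, floor in zip(images, colours, floors):
        if not 0.0 <= floor < 1.0:
            raise ValueError("LUT floor must lie in [0, 1)")
        v = np.clip((np.asarray(im, dtype=float) - floor) / (1.0 - floor), 0.0, 1.0)
        out += v[..., None] * np.asarray(colour, dtype=float)
    return np.clip(out, 0.0, 1.0)


@dataclass
class ClusterMap:
    """HCA segmentation: per-pixel labels plus per-cluster mean spectra.

    Labels are in [0, n_clusters) and deterministic: clusters are numbered by
    decreasing mean total intensity, so cluster 0 is the brightest tissue.
    """

    labels: np.ndarray  # (rows, cols) int
    mean_spectra: np.ndarray  # (n_clusters, n_wavenumbers)
    linkage: np.ndarray | None = None


def hca_segment(
    hsmap: HyperspectralMap | np.ndarray,
    n_clusters: int = 2,
    method: str = "ward",
    metric: str = "euclidean",
    max_pixels: int = 4096,
    shape: tuple[int, int] | None = None,
) -> ClusterMap:
    """Agglomerative clustering of pixel spectra into a segmentation map.

    Maps larger than ``max_pixels`` are clustered on a deterministic
    evenly-spaced pixel subsample; remaining pixels join the nearest cluster
    mean.
    """
    if isinstance(hsmap, HyperspectralMap):
        X = hsmap.as_matrix()
        shape = hsmap.shape
    else:
        X = np.asarray(hsmap, dtype=float)
        if shape is None:
            raise ValueError("pixel-grid shape required for a bare matrix")
    n_pixels = X.shape[0]
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    if n_clusters > n_pixels:
        raise ValueError(f"{n_clusters} clusters exceed {n_pixels} pixels")

    if n_pixels > max_pixels:
        sub_idx = np.linspace(0, n_pixels - 1, max_pixels).astype(int)
    else:
        sub_idx = np.arange(n_pixels)
    Z = linkage(X[sub_idx], method=method, metric=metric)
    sub_labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1

    means = np.vstack([X[sub_idx][sub_labels == c].mean(axis=0) for c in range(n_clusters)])
    if n_pixels > max_pixels:
        d = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        labels = d.argmin(axis=1)
        means = np.vstack([X[labels == c].mean(axis=0) for c in range(n_clusters)])
    else:
        labels = sub_labels

    # deterministic identity: order clusters by mean total intensity, descending
    order = np.argsort(-means.sum(axis=1), kind="stable")
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(n_clusters)
    labels = remap[labels]
    means = means[order]
    return ClusterMap(labels=labels.reshape(shape), mean_spectra=means, linkage=Z)


def reconstruct_zstack(
    results: list[MCRResult], shape: tuple[int, int], z_spacing: float = 5.0
) -> dict:
    """Stack per-plane unmixing results into 3-D concentration volumes.

    Components are matched across planes to plane 0 by greedy maximum cosine
    similarity of the pure spectra. Returns per-component volumes of shape
    (n_planes, rows, cols) plus the matched pure spectra and plane spacing.
    """
    if not results:
        raise ValueError("need at least one plane result")
    k = results[0].n_components
    n_pix = shape[0] * shape[1]
    for r in results:
        if r.n_components != k or r.C.shape[0] != n_pix:
            raise ValueError("planes disagree in geometry or component count")

    ref = results[0].S
    volumes = np.empty((k, len(results)) + shape)
    for z, res in enumerate(results):
        sim = _cosine_matrix(ref, res.S)
        assignment = _greedy_match(sim)
        for comp_ref, comp_z in enumerate(assignment):
            volumes[comp_ref, z] = res.C[:, comp_z].reshape(shape)
    return {
        "volumes": volumes,
        "pure_spectra": ref,
        "z_spacing": z_spacing,
        "n_planes": len(results),
    }


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / (np.linalg.norm(A, axis=1, keepdims=True) + 1e-12)
    Bn = B / (np.linalg.norm(B, axis=1, keepdims=True) + 1e-12)
    return An @ Bn.T


def _greedy_match(sim: np.ndarray) -> list[int]:
    k = sim.shape[0]
    sim = sim.copy()
    assignment = [-1] * k
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        assignment[i] = int(j)
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
    return assignment


def surface_profile_image(hsmap: HyperspectralMap) -> tuple[np.ndarray, float]:
    """The focus-tracked surface height field and its max-min span in um."""
    if hsmap.surface_height is None:
        raise ValueError("map carries no surface-height data")
    h = np.asarray(hsmap.surface_height, dtype=float)
    return h, float(h.max() - h.min())
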