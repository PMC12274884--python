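"""Topological morphology descriptor (TMD) and derived statistics.

A neurite's branching structure is summarized as a persistence barcode: one
(birth, death) interval per terminal branch, where birth is the value of a
filtration function f (radial or path distance from the root) at the
bifurcation that spawns the branch and death its value at the leaf. Components
merge under the elder rule: at each bifurcation the child component whose
originating leaf has the largest f survives and continues the parent.

The module provides the barcode extraction, the scale-invariant bar-length
entropy E(PB) = -sum (l_i/L) log(l_i/L), Gaussian-kernel persistence images,
barcode scaling transforms (uniform alpha and non-uniform alpha/beta),
population scaling optimization, Gaussian-mixture approximation of diagrams,
and binned complexity profiles.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .morphology import NeuriteTree, NeuronMorphology, DENDRITE_TYPES


@dataclass
class PersistenceBarcode:
    """Bars as an (N, 2) array of (birth, death) filtration values in μm."""

    bars: np.ndarray
    filtration: str = "radial"
    source_id: str = ""

    def __post_init__(self):
        self.bars = np.asarray(self.bars, dtype=np.float64).reshape(-1, 2)

    @property
    def n_bars(self) -> int:
        return len(self.bars)

    @property
    def lengths(self) -> np.ndarray:
        return np.abs(self.bars[:, 1] - self.bars[:, 0])

    @property
    def has_invalid_bars(self) -> bool:
        """True when some bar dies before it is born (can arise from
        non-uniform scaling)."""
        return bool(np.any(self.bars[:, 1] < self.bars[:, 0]))

    @property
    def max_death(self) -> float:
        return float(self.bars[:, 1].max())

    def sorted(self) -> "PersistenceBarcode":
        order = np.lexsort((self.bars[:, 1], self.bars[:, 0]))
        return replace(self, bars=self.bars[order])


@dataclass
class PersistenceImage:
    image: np.ndarray
    bounds: tuple  # (bmin, bmax, tmin, tmax)
    kernel_sigma: float
    resolution: int

    def same_grid(self, other: "PersistenceImage") -> bool:
        return self.resolution == other.resolution and np.allclose(
            self.bounds, other.bounds
        )


@dataclass
class DiagramMixture:
    """Gaussian mixture over persistence-diagram points (birth, death)."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    regularized: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64).reshape(-1, 2)
        self.covariances = np.asarray(self.covariances, dtype=np.float64).reshape(
            -1, 2, 2
        )
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        for c in self.covariances:
            if np.linalg.eigvalsh(c)[0] <= 0:
                raise ValueError("covariances must be positive-definite")

    @property
    def n_centers(self) -> int:
        return len(self.weights)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.n_centers, size=n, p=self.weights)
        out = np.empty((n, 2))
        for k in range(self.n_centers):
            sel = comp == k
            if sel.any():
                out[sel] = rng.multivariate_normal(
                    self.means[k], self.covariances[k], size=int(sel.sum())
                )
        return out


# ---------------------------------------------------------------------------
# Barcode extraction (elder rule)


def extract_barcode(
    tree: NeuriteTree,
    filtration: str = "radial",
    origin: np.ndarray | None = None,
    source_id: str = "",
) -> PersistenceBarcode:
    """Persistence barcode of a rooted tree under the elder rule.

    One bar per leaf. At every bifurcation the merging component whose
    originating leaf carries the largest filtration value survives (ties
    broken toward the lower node id, for determinism); each dying component
    contributes the bar (f(bifurcation), f(its leaf)). The surviving
    component yields the essential bar (f(root), f(its leaf)).
    """
    if filtration == "path":
        f = tree.path_distances()
    elif filtration == "radial":
        f = tree.radial_distances(origin)
    else:
        raise ValueError(f"unknown filtration {filtration!r}")
    n = tree.n_nodes
    kids = tree.children()
    bars = []
    # carrier[i] = (f at originating leaf, leaf id) of the surviving component
    carrier: list[tuple | None] = [None] * n
    for v in range(n - 1, -1, -1):
        ch = kids[v]
        if not ch:
            carrier[v] = (f[v], v)
            continue
        carriers = [carrier[c] for c in ch]
        best = max(range(len(ch)), key=lambda k: (carriers[k][0], -carriers[k][1]))
        for k, (val, _leaf) in enumerate(carriers):
            if k != best and len(ch) > 1:
                bars.append((f[v], val))
        carrier[v] = carriers[best]
    bars.append((f[0], carrier[0][0]))  # essential bar
    return PersistenceBarcode(np.array(bars), filtration, source_id).sorted()


def extract_morphology_barcode(
    m: NeuronMorphology,
    neurite_types=DENDRITE_TYPES,
    filtration: str = "radial",
) -> PersistenceBarcode:
    """Pooled barcode of all neurites of the given types of one neuron.

    Radial distances are measured from the soma center; path distances from
    each tree root (which sits on the soma surface after curation).
    """
    trees = m.trees(neurite_types)
    if not trees:
        raise ValueError(f"no neurites of types {neurite_types}")
    origin = m.soma_center if filtration == "radial" else None
    bars = np.vstack(
        [extract_barcode(t, filtration, origin=origin).bars for t in trees]
    )
    return PersistenceBarcode(bars, filtration, m.meta.subject_id).sorted()


# ---------------------------------------------------------------------------
# Entropy and scaling


def barcode_entropy(pb: PersistenceBarcode) -> float:
    """Shannon entropy of normalized bar lengths (natural log).

    Scale-invariant: E(a·PB) = E(PB) for any a > 0, because the normalized
    lengths l_i/L are unchanged by uniform scaling.
    """
    lengths = pb.lengths
    total = lengths.sum()
    if pb.n_bars == 0 or total <= 0:
        raise ValueError("entropy undefined for empty or zero-length barcode")
    p = lengths[lengths > 0] / total
    return float(-(p * np.log(p)).sum())


def scale_barcode(
    pb: PersistenceBarcode, alpha: float, beta: float | None = None
) -> PersistenceBarcode:
    """Uniform scaling (alpha·b, alpha·t), or non-uniform (alpha·b, beta·t)
    scaling births (bifurcations) and deaths (leaves) independently.

    Non-uniform scaling can make a bar die before its birth; the result then
    reports ``has_invalid_bars``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if beta is None:
        beta = alpha
    elif beta <= 0:
        raise ValueError("beta must be positive")
    bars = np.column_stack([alpha * pb.bars[:, 0], beta * pb.bars[:, 1]])
    return replace(pb, bars=bars)


# ---------------------------------------------------------------------------
# Persistence images


def _default_bounds(all_bars: np.ndarray, pad: float = 0.05) -> tuple:
    bmin, bmax = all_bars[:, 0].min(), all_bars[:, 0].max()
    tmin, tmax = all_bars[:, 1].min(), all_bars[:, 1].max()
    db = max(bmax - bmin, 1e-9)
    dt = max(tmax - tmin, 1e-9)
    return (bmin - pad * db, bmax + pad * db, tmin - pad * dt, tmax + pad * dt)


def _bars_image(
    bars: np.ndarray, bounds: tuple, resolution: int, sigma: float
) -> np.ndarray:
    bmin, bmax, tmin, tmax = bounds
    xs = np.linspace(bmin, bmax, resolution)
    ys = np.linspace(tmin, tmax, resolution)
    if len(bars) == 0:
        return np.zeros((resolution, resolution))
    # separable Gaussians: image = Gx^T @ Gy with per-bar row factors
    gx = np.exp(-((xs[None, :] - bars[:, 0:1]) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys[None, :] - bars[:, 1:2]) ** 2) / (2 * sigma**2))
    return gx.T @ gy


def persistence_image(
    pb: PersistenceBarcode,
    resolution: int = 100,
    kernel_sigma: float | None = None,
    bounds: tuple | None = None,
    normalize: bool = False,
) -> PersistenceImage:
    """Sum of Gaussian kernels centered on the diagram points, sampled on a
    regular grid. ``image[i, j]`` indexes (birth, death). Deterministic."""
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    if bounds is None:
        if pb.n_bars == 0:
            bounds = (0.0, 1.0, 0.0, 1.0)
        else:
            bounds = _default_bounds(pb.bars)
    if kernel_sigma is None:
        kernel_sigma = max(bounds[1] - bounds[0], bounds[3] - bounds[2]) / 20.0
    img = _bars_image(pb.bars, bounds, resolution, kernel_sigma)
    if normalize and img.sum() > 0:
        img = img / img.sum()
    return PersistenceImage(img, tuple(bounds), kernel_sigma, resolution)


def common_bounds(*populations, pad: float = 0.05) -> tuple:
    """Bounds covering every bar of every population, padded."""
    bars = np.vstack([pb.bars for pop in populations for pb in pop])
    return _default_bounds(bars, pad)


def population_image(
    pbs,
    resolution: int = 100,
    kernel_sigma: float | None = None,
    bounds: tuple | None = None,
    average: bool = False,
) -> PersistenceImage:
    """Image of a population: the sum of its members' images (or the mean,
    with ``average=True``, for size-independent comparisons)."""
    pbs = list(pbs)
    if not pbs:
        raise ValueError("empty population")
    if bounds is None:
        bounds = common_bounds(pbs)
    if kernel_sigma is None:
        kernel_sigma = max(bounds[1] - bounds[0], bounds[3] - bounds[2]) / 20.0
    bars = np.vstack([pb.bars for pb in pbs])
    img = _bars_image(bars, bounds, resolution, kernel_sigma)
    if average:
        img = img / len(pbs)
    return PersistenceImage(img, tuple(bounds), kernel_sigma, resolution)


def image_distance(a: PersistenceImage, b: PersistenceImage) -> float:
    """Sum of absolute pixel differences. Symmetric; zero iff equal."""
    if not a.same_grid(b):
        raise ValueError("images live on different grids")
    return float(np.abs(a.image - b.image).sum())


# ---------------------------------------------------------------------------
# Population scaling optimization


@dataclass
class ScalingFit:
    alpha: float
    distance: float
    beta: float | None = None
    n_iter: int = 0
    converged: bool = True

    @property
    def factors(self) -> tuple:
        return (self.alpha,) if self.beta is None else (self.alpha, self.beta)


def fit_scaling(
    pop_a,
    pop_b,
    mode: str = "uniform",
    resolution: int = 64,
    kernel_sigma: float | None = None,
    factor_max: float = 4.0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ScalingFit:
    """Optimal factor(s) scaling population ``pop_a`` onto ``pop_b``.

    Minimizes the L1 distance between per-cell-averaged population
    persistence images on a fixed common grid (covering ``pop_b`` and
    ``pop_a`` scaled up to ``factor_max``). A deterministic coarse scan
    seeds a central-difference gradient descent with backtracking line
    search, stopped when the distance improvement falls below ``tol`` or
    after ``max_iter`` iterations.
    """
    pop_a, pop_b = list(pop_a), list(pop_b)
    if not pop_a or not pop_b:
        raise ValueError("both populations must be non-empty")
    if mode not in ("uniform", "nonuniform"):
        raise ValueError(f"unknown mode {mode!r}")
    scaled_a = [scale_barcode(pb, factor_max) for pb in pop_a]
    bounds = common_bounds(pop_a, pop_b, scaled_a)
    if kernel_sigma is None:
        kernel_sigma = max(bounds[1] - bounds[0], bounds[3] - bounds[2]) / 20.0
    bars_a = np.vstack([pb.bars for pb in pop_a])
    target = _bars_image(
        np.vstack([pb.bars for pb in pop_b]), bounds, resolution, kernel_sigma
    ) / len(pop_b)

    def objective(params: np.ndarray) -> float:
        alpha = params[0]
        beta = params[-1]
        if alpha <= 0 or beta <= 0:
            return np.inf
        scaled = np.column_stack([alpha * bars_a[:, 0], beta * bars_a[:, 1]])
        img = _bars_image(scaled, bounds, resolution, kernel_sigma) / len(pop_a)
        return float(np.abs(img - target).sum())

    # deterministic coarse initialization
    grid = np.geomspace(0.25, factor_max, 21)
    if mode == "uniform":
        candidates = [np.array([a]) for a in grid]
    else:
        candidates = [np.array([a, b]) for a in grid for b in grid]
    x = min(candidates, key=objective)
    fx = objective(x)

    h = 1e-4
    step = 1e-2
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        grad = np.zeros_like(x)
        for k in range(len(x)):
            e = np.zeros_like(x)
            e[k] = h
            grad[k] = (objective(x + e) - objective(x - e)) / (2 * h)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            converged = True
            break
        improved = False
        while step > 1e-10:
            x_new = x - step * grad / gnorm
            f_new = objective(x_new)
            if f_new < fx:
                improved = True
                break
            step /= 2.0
        if not improved:
            converged = True
            break
        if fx - f_new < tol * (1.0 + fx):
            x, fx = x_new, f_new
            converged = True
            break
        x, fx = x_new, f_new
        step *= 1.5
    alpha = float(x[0])
    beta = float(x[1]) if mode == "nonuniform" else None
    return ScalingFit(alpha, fx, beta, n_iter, converged)


# ---------------------------------------------------------------------------
# Mixture approximation


def fit_diagram_mixture(pbs, n_centers: int = 3, seed: int = 0) -> DiagramMixture:
    """Maximum-likelihood Gaussian mixture over pooled diagram points."""
    from sklearn.mixture import GaussianMixture

    points = np.vstack([pb.bars for pb in pbs])
    if len(points) < n_centers:
        raise ValueError("fewer pooled points than mixture centers")
    reg = 1e-6 * max(1.0, float(points.var()))
    gm = GaussianMixture(
        n_components=n_centers,
        covariance_type="full",
        random_state=seed,
        n_init=5,
        reg_covar=reg,
        max_iter=500,
    ).fit(points)
    regularized = bool(np.any(np.linalg.eigvalsh(gm.covariances_) < 2 * reg))
    return DiagramMixture(gm.weights_, gm.means_, gm.covariances_, regularized)


# ---------------------------------------------------------------------------
# Complexity profile


def complexity_profile(pbs, bin_edges) -> "pd.DataFrame":
    """Binned complexity curve of a population of barcodes.

    Per radial/path-distance bin: the mean (over neurons) number of bars
    whose span intersects the bin, and the bar-length entropy restricted to
    bar mass (overlap length) within the bin, pooled over the population.
    """
    import pandas as pd

    edges = np.asarray(bin_edges, dtype=np.float64)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    nb = len(edges) - 1
    pbs = list(pbs)
    counts = np.zeros(nb)
    overlaps = [[] for _ in range(nb)]
    for pb in pbs:
        lo = np.minimum(pb.bars[:, 0], pb.bars[:, 1])
        hi = np.maximum(pb.bars[:, 0], pb.bars[:, 1])
        for k in range(nb):
            ov = np.minimum(hi, edges[k + 1]) - np.maximum(lo, edges[k])
            alive = ov > 0
            counts[k] += int(alive.sum())
            if alive.any():
                overlaps[k].append(ov[alive])
    n = max(len(pbs), 1)
    entropy = np.zeros(nb)
    for k in range(nb):
        if overlaps[k]:
            l = np.concatenate(overlaps[k])
            p = l / l.sum()
            entropy[k] = float(-(p * np.log(p)).sum())
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "mean_bars_alive": counts / n,
            "entropy": entropy,
        }
    )
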