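"""Niche comparisons in environmental space.

Climate observations are reduced to two principal components calibrated on
the pooled native + invaded backgrounds; occurrence and availability
densities are kernel-smoothed onto a 100 x 100 grid bounded by the background
scores.  From the gridded densities come niche expansion / stability /
unfilling (on the intersection of each range's 75th-percentile climate
region), Schoener's D with equivalency and similarity randomization tests,
and the potential niche truncation index (PNTI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

__all__ = [
    "EnvPCA",
    "NicheDensityGrid",
    "NicheMetrics",
    "RandomizationResult",
    "env_pca",
    "density_grid",
    "occupied_mask",
    "availability_mask",
    "niche_esu",
    "schoeners_d",
    "niche_randomization_test",
    "pnti",
]

MIN_OCCURRENCES = 5
#: density mass defining the occupied region of a range
OCCUPIED_MASS = 0.95
#: availability mass defining each range's analysed climate region
AVAILABLE_QUANTILE = 0.75
#: cells with availability below this fraction of the peak are treated as
#: unavailable in the occupancy correction (guards the z/z_env division)
AVAILABILITY_FLOOR_REL = 1e-3


@dataclass
class EnvPCA:
    """Centered/scaled two-axis principal decomposition of climate space."""

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_vars, 2)
    explained_variance_ratio: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.mean) / self.scale @ self.loadings


@dataclass
class NicheDensityGrid:
    z: np.ndarray  # occurrence density, sums to 1
    z_env: np.ndarray  # availability density, sums to 1
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def resolution(self) -> int:
        return self.z.shape[0]


@dataclass
class NicheMetrics:
    expansion: float
    stability: float
    unfilling: float


@dataclass
class RandomizationResult:
    d_observed: float
    p_value: float
    null_distribution: np.ndarray
    mode: str


def env_pca(background: np.ndarray) -> tuple[np.ndarray, EnvPCA]:
    """First two principal axes of the pooled background climates.

    Variables are centered and scaled to unit variance.  Sign convention:
    each axis is flipped so its largest-magnitude loading is positive.
    Returns (scores, model).
    """
    x = np.asarray(background, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 observations of >= 2 variables")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    if s.size < 2 or s[1] <= 1e-12 * s[0]:
        raise ValueError("background climate matrix has rank < 2")
    loadings = vt[:2].T.copy()
    for k in range(2):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    var = s**2 / (x.shape[0] - 1)
    evr = var / var.sum()
    model = EnvPCA(mean=mean, scale=scale, loadings=loadings, explained_variance_ratio=evr[:2])
    return xs @ loadings, model


def _kde_on_grid(points: np.ndarray, xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman plug-in bandwidth) evaluated on grid centres."""
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    support = np.vstack([xx.ravel(), yy.ravel()])
    pts = points.T
    full_rank = points.shape[0] >= 3
    if full_rank:
        cov = np.cov(pts)
        full_rank = bool(np.all(np.isfinite(cov))) and np.linalg.matrix_rank(cov) == 2
    if full_rank:
        z = gaussian_kde(pts, bw_method="silverman")(support)
    else:
        # degenerate cloud: per-axis independent kernels with a tiny floor
        sd = points.std(axis=0, ddof=1) if points.shape[0] > 1 else np.zeros(2)
        bw = np.maximum(sd * points.shape[0] ** (-1.0 / 6.0), 1e-6)
        z = np.ones(support.shape[1])
        for k in range(2):
            diff = (support[k][:, None] - points[:, k][None, :]) / bw[k]
            z *= np.exp(-0.5 * diff**2).sum(axis=1)
    z = z.reshape(xc.size, yc.size)
    total = z.sum()
    return z / total if total > 0 else z


def density_grid(
    scores_background: np.ndarray,
    scores_occurrences: np.ndarray,
    resolution: int = 100,
    bounds: tuple | None = None,
) -> NicheDensityGrid:
    """Kernel-smoothed occurrence and availability densities on an R x R grid.

    The grid is bounded by the background scores (or explicit ``bounds``);
    occurrences outside are clipped in, with a warning.  Both densities are
    normalized to sum to 1.
    """
    bg = np.asarray(scores_background, dtype=float)
    occ = np.asarray(scores_occurrences, dtype=float)
    if occ.shape[0] < MIN_OCCURRENCES:
        raise ValueError(f"at least {MIN_OCCURRENCES} occurrences required")
    if bounds is None:
        (x0, y0), (x1, y1) = bg.min(axis=0), bg.max(axis=0)
    else:
        x0, x1, y0, y1 = bounds
    if np.any(occ[:, 0] < x0) or np.any(occ[:, 0] > x1) or np.any(occ[:, 1] < y0) or np.any(occ[:, 1] > y1):
        warnings.warn("occurrence scores outside background bounds were clipped", stacklevel=2)
        occ = np.column_stack([np.clip(occ[:, 0], x0, x1), np.clip(occ[:, 1], y0, y1)])
    x_edges = np.linspace(x0, x1, resolution + 1)
    y_edges = np.linspace(y0, y1, resolution + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    z = _kde_on_grid(occ, xc, yc)
    z_env = _kde_on_grid(bg, xc, yc)
    return NicheDensityGrid(z=z, z_env=z_env, x_edges=x_edges, y_edges=y_edges)


def _top_mass_mask(density: np.ndarray, mass: float) -> np.ndarray:
    """Cells of highest density jointly holding ``mass`` of the total."""
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    total = flat.sum()
    if total <= 0:
        return np.zeros_like(density, dtype=bool)
    k = int(np.searchsorted(csum, mass * total)) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(density.shape)


def occupied_mask(grid: NicheDensityGrid, mass: float = OCCUPIED_MASS) -> np.ndarray:
    return _top_mass_mask(grid.z, mass)


def availability_mask(grid: NicheDensityGrid, quantile: float = AVAILABLE_QUANTILE) -> np.ndarray:
    return _top_mass_mask(grid.z_env, quantile)


def niche_esu(
    native: NicheDensityGrid,
    invasive: NicheDensityGrid,
    quantile: float = AVAILABLE_QUANTILE,
    occupied_mass: float = OCCUPIED_MASS,
) -> NicheMetrics:
    """Expansion / stability / unfilling on the shared analysed climate space.

    The analysis mask is the intersection of each range's ``quantile``
    availability region.  Expansion is the invasive occupied-density mass
    (within the mask) lying outside the native occupied cells, normalized by
    the invasive occupied mass within the mask; stability is its complement;
    unfilling mirrors expansion with the ranges swapped.
    """
    if native.z.shape != invasive.z.shape:
        raise ValueError("grids must share their resolution and bounds")
    mask = availability_mask(native, quantile) & availability_mask(invasive, quantile)
    if not mask.any():
        raise ValueError("empty shared-climate mask")
    occ_nat = occupied_mask(native, occupied_mass)
    occ_inv = occupied_mask(invasive, occupied_mass)
    inv_mass = invasive.z[mask & occ_inv].sum()
    nat_mass = native.z[mask & occ_nat].sum()
    expansion = invasive.z[mask & occ_inv & ~occ_nat].sum() / inv_mass if inv_mass > 0 else 0.0
    unfilling = native.z[mask & occ_nat & ~occ_inv].sum() / nat_mass if nat_mass > 0 else 0.0
    return NicheMetrics(expansion=float(expansion), stability=float(1.0 - expansion), unfilling=float(unfilling))


def _corrected_density(grid: NicheDensityGrid) -> np.ndarray:
    """Occupancy corrected for availability: normalize(z / z_env).

    Cells whose availability falls below ``AVAILABILITY_FLOOR_REL`` of the
    peak are treated as unavailable, which keeps the division from blowing up
    on the fringe of climate space.
    """
    floor = AVAILABILITY_FLOOR_REL * grid.z_env.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(grid.z_env > floor, grid.z / grid.z_env, 0.0)
    total = p.sum()
    return p / total if total > 0 else p


def schoeners_d(g1: NicheDensityGrid, g2: NicheDensityGrid) -> float:
    """Schoener's D = 1 - 0.5 sum |p1 - p2| on availability-corrected densities."""
    return float(1.0 - 0.5 * np.abs(_corrected_density(g1) - _corrected_density(g2)).sum())


def niche_randomization_test(
    native_occ: np.ndarray,
    invasive_occ: np.ndarray,
    native_bg: np.ndarray,
    invasive_bg: np.ndarray,
    mode: str = "equivalency",
    n_reps: int = 99,
    seed: int = 0,
    resolution: int = 100,
) -> RandomizationResult:
    """Schoener's D against a randomization null.

    ``equivalency`` pools the two occurrence sets and re-splits them;
    ``similarity`` relocates the invasive occurrences at random within the
    invasive background.  p-values use ``(1 + #extreme) / (1 + n_reps)``:
    for equivalency the extreme direction is null D <= observed (small p:
    niches differ), for similarity null D >= observed (small p: more similar
    than random).
    """
    if n_reps < 99:
        raise ValueError("n_reps must be >= 99")
    if mode not in ("equivalency", "similarity"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    pooled_bg = np.vstack([native_bg, invasive_bg])
    bounds = (
        pooled_bg[:, 0].min(), pooled_bg[:, 0].max(),
        pooled_bg[:, 1].min(), pooled_bg[:, 1].max(),
    )

    def build(occ, bg):
        return density_grid(bg, occ, resolution=resolution, bounds=bounds)

    g_nat = build(native_occ, native_bg)
    g_inv = build(invasive_occ, invasive_bg)
    d_obs = schoeners_d(g_nat, g_inv)

    n1 = native_occ.shape[0]
    pooled = np.vstack([native_occ, invasive_occ])
    null = np.empty(n_reps)
    for r in range(n_reps):
        if mode == "equivalency":
            idx = rng.permutation(pooled.shape[0])
            occ1, occ2 = pooled[idx[:n1]], pooled[idx[n1:]]
            null[r] = schoeners_d(build(occ1, native_bg), build(occ2, invasive_bg))
        else:
            take = rng.integers(0, invasive_bg.shape[0], size=invasive_occ.shape[0])
            null[r] = schoeners_d(g_nat, build(invasive_bg[take], invasive_bg))
    if mode == "equivalency":
        p = (1.0 + np.sum(null <= d_obs)) / (1.0 + n_reps)
    else:
        p = (1.0 + np.sum(null >= d_obs)) / (1.0 + n_reps)
    return RandomizationResult(d_observed=d_obs, p_value=float(p), null_distribution=null, mode=mode)


def pnti(
    occupied_density: np.ndarray,
    available_density: np.ndarray,
    occupied_mass: float = OCCUPIED_MASS,
    available_mass: float = 0.99,
) -> float:
    """Potential niche truncation: share of the occupied-region perimeter
    abutting or exceeding the margin of available climate space.

    Both inputs may be densities (binarized at the documented masses) or
    boolean regions.  A boundary cell of the occupied region counts as
    truncated when it lies outside the available region, touches a cell
    outside it (4-neighbourhood), or sits on the grid edge.
    """
    occ = np.asarray(occupied_density)
    avail = np.asarray(available_density)
    occ_bin = occ.astype(bool) if occ.dtype == bool else _top_mass_mask(occ, occupied_mass)
    av_bin = avail.astype(bool) if avail.dtype == bool else _top_mass_mask(avail, available_mass)
    if not occ_bin.any():
        raise ValueError("empty occupied region")
    interior = ndimage.binary_erosion(occ_bin, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    boundary = occ_bin & ~interior
    outside = ~av_bin
    # pad so the grid edge counts as "outside available space"
    outside_pad = np.pad(outside, 1, constant_values=True)
    touches = np.zeros_like(outside)
    core = outside_pad[1:-1, 1:-1]
    touches |= core
    touches |= outside_pad[:-2, 1:-1]
    touches |= outside_pad[2:, 1:-1]
    touches |= outside_pad[1:-1, :-2]
    touches |= outside_pad[1:-1, 2:]
    truncated = boundary & touches
    return float(truncated.sum() / boundary.sum())
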