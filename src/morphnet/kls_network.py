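"""Kullback–Leibler-similarity morphological connectomes.

One subject's per-region intensity distributions are estimated by Gaussian
kernel density estimation on a grid shared across all of that subject's
regions, and every region pair is scored with

    KLS(P, Q) = exp(-(KL(P || Q) + KL(Q || P)))

so that identical distributions score 1 and barely-overlapping ones tend to
0. Sharing the grid per subject keeps every pairwise divergence defined on
a common support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import rel_entr

from .io_formats import ROISampleSet

DEFAULT_GRID_POINTS = 128
DENSITY_FLOOR = 1e-10
_ZERO_VARIANCE_BANDWIDTH = 1e-3


@dataclass(frozen=True)
class DensityProfile:
    """A discretized probability density on a strictly increasing grid."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        density = np.asarray(self.density, dtype=float)
        if grid.ndim != 1 or grid.shape != density.shape:
            raise ValueError("grid and density must be 1-D arrays of equal length")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def masses(self) -> np.ndarray:
        """Per-bin probability masses (sum to 1)."""
        m = self.density * self.dx
        return m / m.sum()


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric unit-diagonal matrix of pairwise KLS values."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.abs(values - values.T).max() > 0:
            raise ValueError("similarity matrix must be exactly symmetric")
        if np.abs(np.diag(values) - 1.0).max() > 1e-9:
            raise ValueError("similarity matrix diagonal must be 1")
        object.__setattr__(self, "values", values)

    @property
    def n_regions(self) -> int:
        return len(self.labels)


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Bandwidth of a Gaussian KDE under Silverman's rule (scipy convention).

    Falls back to a tiny fixed bandwidth for zero-variance input.
    """
    samples = np.asarray(samples, dtype=float)
    sd = samples.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance samples; using fallback bandwidth", stacklevel=2)
        return _ZERO_VARIANCE_BANDWIDTH
    factor = (samples.size * 3.0 / 4.0) ** (-1.0 / 5.0)
    return float(factor * sd)


def estimate_density(
    samples: np.ndarray, grid: np.ndarray, floor: float = DENSITY_FLOOR
) -> DensityProfile:
    """Gaussian-KDE density on ``grid``, floored and renormalized.

    Requires >= 30 finite samples. The result integrates to 1 with respect
    to the (uniform) grid spacing.
    """
    samples = np.asarray(samples, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if samples.size < 30:
        raise ValueError(f"need >= 30 samples for KDE, got {samples.size}")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    if samples.std(ddof=1) == 0:
        warnings.warn("zero-variance samples; KDE with fallback bandwidth", stacklevel=2)
        density = stats.norm.pdf(grid, loc=samples[0], scale=_ZERO_VARIANCE_BANDWIDTH)
    else:
        kde = stats.gaussian_kde(samples, bw_method="silverman")
        density = kde(grid)
    density = np.maximum(density, floor)
    dx = grid[1] - grid[0]
    density = density / (density.sum() * dx)
    return DensityProfile(grid=grid, density=density)


def kl_divergence(p: DensityProfile, q: DensityProfile) -> float:
    """Discrete KL(P || Q) over bin masses; >= 0, zero iff P == Q."""
    if p.grid.shape != q.grid.shape or not np.array_equal(p.grid, q.grid):
        raise ValueError("density profiles must share the same grid")
    return float(rel_entr(p.masses(), q.masses()).sum())


def kls_similarity(p: DensityProfile, q: DensityProfile) -> float:
    """exp of the negated symmetrized KL divergence; in (0, 1]."""
    return float(np.exp(-(kl_divergence(p, q) + kl_divergence(q, p))))


def subject_grid(sample_set: ROISampleSet, grid_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Shared evaluation grid spanning the subject's pooled sample range
    padded by three (median per-region) bandwidths on each side."""
    pooled = sample_set.pooled()
    h = float(np.median([silverman_bandwidth(s) for s in sample_set.samples]))
    return np.linspace(pooled.min() - 3 * h, pooled.max() + 3 * h, grid_points)


def build_similarity_matrix(
    sample_set: ROISampleSet,
    grid_points: int = DEFAULT_GRID_POINTS,
    floor: float = DENSITY_FLOOR,
) -> SimilarityMatrix:
    """All-pairs KLS matrix for one subject (vectorized over region pairs)."""
    grid = subject_grid(sample_set, grid_points)
    n = sample_set.n_regions
    masses = np.empty((n, grid.size))
    for i, samples in enumerate(sample_set.samples):
        masses[i] = estimate_density(samples, grid, floor=floor).masses()
    log_masses = np.log(masses)
    # KL(i, j) = sum_k m_ik log(m_ik / m_jk)
    self_entropy = np.sum(masses * log_masses, axis=1)
    kl = self_entropy[:, None] - masses @ log_masses.T
    sym = kl + kl.T
    np.fill_diagonal(sym, 0.0)
    values = np.exp(-sym)
    values = (values + values.T) / 2.0  # exact symmetry against float noise
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels=list(sample_set.region_labels), values=values)
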