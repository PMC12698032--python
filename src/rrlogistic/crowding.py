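"""Crowding-index estimation and pair-correlation utilities.

The crowding index ``c`` is the competition-kernel-weighted integral of the
pair correlation function: ``c = 1`` for homogeneous (CSR) patterns, ``c > 1``
for populations overcrowded at the competition scale, ``c < 1`` for
undercrowded ones.  At demographic equilibrium the carrying capacity of the
model is the non-spatial value divided by ``c``, which makes ``c`` a
predictor of population size from purely spatial information.

Two estimators are provided:

* :func:`crowding_from_positions` -- pair sums of the (mass-renormalised)
  competition kernel over organism positions;
* :func:`crowding_from_home_ranges` -- pair sums over home-range *centres*
  of the composed kernel ``K_HR``, the competition kernel convolved with the
  stationary space-use of both organisms (per-component variance
  ``sigma_q^2 + 2 sigma_r2``).  For movement fast relative to demography the
  two agree.

Both estimators normalise by the number of ordered pairs ``N(N-1)`` and by
the kernel mass retained on the torus, so their expectation under CSR is
exactly one at any finite ``N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.spatial import cKDTree

from .geometry_kernels import (
    Domain,
    KernelSpec,
    competition_kernel_value,
    csr_expected_mass,
    kernel_retained_mass,
    periodic_kernel_value,
)

__all__ = [
    "CrowdingEstimate",
    "crowding_from_positions",
    "crowding_from_home_ranges",
    "khr_value",
    "pair_correlation",
    "ccov_from_c",
]


@dataclass(frozen=True)
class CrowdingEstimate:
    """A crowding-index estimate and the settings that produced it."""

    value: float
    estimator: str  # "positions" | "home_ranges"
    n_points: int
    sigma_q: float
    sigma_r2: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("crowding index cannot be negative")

    def __float__(self) -> float:
        return self.value


def _as_points(snapshot) -> np.ndarray:
    """Accept (N,2) arrays, snapshot DataFrames or PopulationState objects."""
    if hasattr(snapshot, "positions"):
        return np.asarray(snapshot.positions, dtype=float)
    if isinstance(snapshot, pd.DataFrame):
        return snapshot[["x", "y"]].to_numpy(dtype=float)
    return np.asarray(snapshot, dtype=float).reshape(-1, 2)


def crowding_from_positions(
    snapshot, spec: KernelSpec, domain: Domain
) -> CrowdingEstimate:
    """Crowding index from organism positions.

    ``c = A / (N (N-1)) * sum_{i != j} Kc~(x_i - x_j)`` with minimum-image
    displacements, where ``Kc~`` is the truncated kernel divided by its
    retained probability mass (so CSR patterns give exactly 1 in
    expectation).
    """
    pts = _as_points(snapshot)
    N = len(pts)
    if N < 2:
        raise ValueError(f"crowding is undefined for N={N} < 2 points")
    L = domain.L
    rcut = spec.trunc_radius
    if rcut < L / 2.0:
        wrapped = np.mod(pts, L)
        wrapped[wrapped >= L] = 0.0
        tree = cKDTree(wrapped, boxsize=L)
        pairs = tree.query_pairs(rcut, output_type="ndarray")
        if len(pairs):
            d = wrapped[pairs[:, 1]] - wrapped[pairs[:, 0]]
            d -= L * np.floor(d / L + 0.5)
            total = 2.0 * float(np.sum(competition_kernel_value(d, spec)))
        else:
            total = 0.0
        mass = kernel_retained_mass(spec)
    else:
        d = pts[None, :, :] - pts[:, None, :]
        d -= L * np.floor(d / L + 0.5)
        k = periodic_kernel_value(d, spec, domain)
        np.fill_diagonal(k, 0.0)
        total = float(np.sum(k))
        mass = csr_expected_mass(spec, domain)
    value = domain.A * total / (N * (N - 1) * mass)
    return CrowdingEstimate(value, "positions", N, spec.sigma_q)


def khr_value(u, sigma_q: float, sigma_r2: float):
    """Composed home-range competition kernel ``K_HR`` at displacement(s) u.

    The kernel felt between two range-resident organisms, as a function of
    the displacement of their home-range centres, is the competition kernel
    averaged over both organisms' stationary Gaussian space use: an
    isotropic bivariate Gaussian of per-component variance
    ``sigma_q^2 + 2 sigma_r2`` (each organism contributes ``sigma_r2`` to
    the displacement variance).  With ``sigma_r2 = 0`` it reduces to the
    untruncated competition kernel (the sessile limit).
    """
    if sigma_q < 0 or sigma_r2 < 0 or (sigma_q == 0 and sigma_r2 == 0):
        raise ValueError("need sigma_q, sigma_r2 >= 0 and not both zero")
    s2 = sigma_q**2 + 2.0 * sigma_r2
    u = np.asarray(u, dtype=float)
    r2 = np.sum(u * u, axis=-1)
    val = np.exp(-r2 / (2.0 * s2)) / (2.0 * math.pi * s2)
    return float(val) if val.ndim == 0 else val


def _khr_torus_pair_sum(centres: np.ndarray, s2: float, domain: Domain) -> float:
    """Sum of the image-summed composed kernel over ordered centre pairs,
    already divided by its mass on the torus (CSR expectation = (N)(N-1)/A)."""
    L = domain.L
    s = math.sqrt(s2)
    m = max(1, int(math.ceil(6.0 * s / L)))
    mass = special.erf((m + 0.5) * L / (s * math.sqrt(2.0))) ** 2
    dx = centres[None, :, 0] - centres[:, None, 0]
    dy = centres[None, :, 1] - centres[:, None, 1]
    dx -= L * np.floor(dx / L + 0.5)
    dy -= L * np.floor(dy / L + 0.5)
    sx = np.zeros_like(dx)
    sy = np.zeros_like(dy)
    for k in range(-m, m + 1):
        sx += np.exp(-((dx + k * L) ** 2) / (2.0 * s2))
        sy += np.exp(-((dy + k * L) ** 2) / (2.0 * s2))
    val = sx * sy / (2.0 * math.pi * s2)
    np.fill_diagonal(val, 0.0)
    return float(np.sum(val)) / mass


def crowding_from_home_ranges(
    centres, sigma_r2, spec: KernelSpec, domain: Domain
) -> CrowdingEstimate:
    """Crowding index from home-range centres and home-range size.

    ``c_HR = A / (N (N-1)) * sum_{i != j} K_HR~(mu_i - mu_j)`` where
    ``K_HR~`` is the composed kernel (competition scale plus twice the
    home-range variance), periodically image-summed and renormalised so that
    CSR centres give exactly 1 in expectation.  No simulation-style
    truncation is applied: the weighting function is defined by the
    stationary displacement distribution, and the kernel is evaluated out to
    where it is numerically negligible.

    ``sigma_r2`` may be a scalar (shared home-range size) or a length-N
    array of per-organism variances, in which case each pair uses
    ``sigma_q^2 + sigma_r2_i + sigma_r2_j``.
    """
    if hasattr(centres, "centres"):
        pts = np.asarray(centres.centres, dtype=float)
    elif isinstance(centres, pd.DataFrame):
        pts = centres[["mu_x", "mu_y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(centres, dtype=float).reshape(-1, 2)
    N = len(pts)
    if N < 2:
        raise ValueError(f"crowding is undefined for N={N} < 2 points")
    sr2 = np.asarray(sigma_r2, dtype=float)
    if np.any(sr2 < 0):
        raise ValueError("sigma_r2 must be non-negative")
    if sr2.ndim == 0:
        total = _khr_torus_pair_sum(pts, spec.sigma_q**2 + 2.0 * float(sr2), domain)
        reported_sr2 = float(sr2)
    else:
        if len(sr2) != N:
            raise ValueError("per-organism sigma_r2 must have length N")
        total = 0.0
        # pairwise composite variances differ; accumulate one i-row at a time
        L = domain.L
        for i in range(N):
            s2 = spec.sigma_q**2 + sr2[i] + np.delete(sr2, i)
            d = np.delete(pts, i, axis=0) - pts[i]
            d -= L * np.floor(d / L + 0.5)
            m = max(1, int(np.ceil(6.0 * math.sqrt(float(np.max(s2))) / L)))
            sx = np.zeros(N - 1)
            sy = np.zeros(N - 1)
            for k in range(-m, m + 1):
                sx += np.exp(-((d[:, 0] + k * L) ** 2) / (2.0 * s2))
                sy += np.exp(-((d[:, 1] + k * L) ** 2) / (2.0 * s2))
            mass = special.erf((m + 0.5) * L / np.sqrt(2.0 * s2)) ** 2
            total += float(np.sum(sx * sy / (2.0 * math.pi * s2) / mass))
        reported_sr2 = float(np.mean(sr2))
    value = domain.A * total / (N * (N - 1))
    return CrowdingEstimate(value, "home_ranges", N, spec.sigma_q, reported_sr2)


def pair_correlation(snapshot, bin_edges, domain: Domain) -> pd.DataFrame:
    """Isotropic pair correlation function on the torus.

    ``g2(r-bin) = A / (N (N-1)) * (ordered pairs in annulus) / (annulus
    area)``.  Periodic boundaries make edge correction unnecessary.  Bins
    must lie within (0, L/2], the range where torus annuli are complete.
    Returns a table with bin edges, centres, ordered-pair counts and ``g2``.
    """
    pts = _as_points(snapshot)
    N = len(pts)
    if N < 2:
        raise ValueError("pair correlation requires at least two points")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least two entries")
    if edges[0] < 0 or edges[-1] > domain.L / 2.0:
        raise ValueError("bins must lie within (0, L/2]")
    d = pts[None, :, :] - pts[:, None, :]
    d -= domain.L * np.floor(d / domain.L + 0.5)
    r = np.sqrt(np.sum(d * d, axis=-1))
    iu = np.triu_indices(N, k=1)
    counts, _ = np.histogram(r[iu], bins=edges)
    counts = 2 * counts  # ordered pairs
    area = math.pi * np.diff(edges**2)
    g2 = domain.A * counts / (N * (N - 1) * area)
    return pd.DataFrame(
        {
            "r_lo": edges[:-1],
            "r_hi": edges[1:],
            "r_mid": 0.5 * (edges[:-1] + edges[1:]),
            "pair_count": counts,
            "g2": g2,
        }
    )


def ccov_from_c(c: float, n: float) -> float:
    """Covariance-convention crowding ``c_cov = n^2 (c - 1)``.

    Relates the pair-correlation-based index to the weighted-covariance
    definition used in classical neighbourhood-competition models; zero for
    homogeneous populations at any density.
    """
    if n < 0:
        raise ValueError("density must be non-negative")
    return n * n * (c - 1.0)
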