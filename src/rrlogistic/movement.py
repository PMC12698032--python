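"""Organism movement between demographic events.

Range residency is modelled by an Ornstein-Uhlenbeck (OU) process: diffusive
motion plus linear reversion toward a home-range centre ``mu`` at rate
``1/tau``, whose stationary law is an isotropic Gaussian of per-component
variance ``sigma_r2`` centred on ``mu``.  Two limits bracket the OU regime:

* ``BM`` -- plain Brownian motion with diffusion ``D`` (tau, sigma_r2 -> inf
  with D = sigma_r2/tau fixed): uniform long-run space use over the domain.
* ``SESSILE`` -- no movement at all (D = 0): organisms sit where they settle
  at birth, recovering the classic sessile spatial logistic model.

Movement is assumed fast relative to demography, so positions are advanced
by the exact transition law of the process over each inter-event interval;
no Euler substepping is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry_kernels import Domain

__all__ = ["MovementParams", "propagate", "sample_stationary_position", "effective_diffusion"]

MODE_OU = 0
MODE_BM = 1
MODE_SESSILE = 2

_MODE_CODES = {"OU": MODE_OU, "BM": MODE_BM, "SESSILE": MODE_SESSILE}


@dataclass(frozen=True)
class MovementParams:
    """Movement mode and its parameters.

    mode : {"OU", "BM", "SESSILE"}
    tau : float
        Home-range crossing time (OU only).
    sigma_r2 : float
        Long-term positional variance per component; sets home-range size
        (OU only).
    D : float
        Diffusion coefficient.  Derived as sigma_r2/tau for OU, the free
        parameter for BM, and identically zero for SESSILE.
    """

    mode: str
    tau: float | None = None
    sigma_r2: float | None = None
    D: float | None = None

    def __post_init__(self) -> None:
        mode = self.mode.upper()
        if mode not in _MODE_CODES:
            raise ValueError(f"unknown movement mode {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        if mode == "OU":
            if not (self.tau and self.tau > 0 and self.sigma_r2 and self.sigma_r2 > 0):
                raise ValueError("OU movement requires tau > 0 and sigma_r2 > 0")
            derived = self.sigma_r2 / self.tau
            if self.D is not None and not math.isclose(self.D, derived, rel_tol=1e-9):
                raise ValueError(
                    f"inconsistent OU parameters: D={self.D} but sigma_r2/tau={derived}"
                )
            object.__setattr__(self, "D", derived)
        elif mode == "BM":
            if self.D is None or not self.D > 0:
                raise ValueError("BM movement requires D > 0")
            if self.tau is not None or self.sigma_r2 is not None:
                raise ValueError("tau/sigma_r2 are meaningless for BM (conceptually infinite)")
        else:  # SESSILE
            if self.D not in (None, 0, 0.0):
                raise ValueError("SESSILE movement has D = 0")
            object.__setattr__(self, "D", 0.0)

    @property
    def mode_code(self) -> int:
        return _MODE_CODES[self.mode]

    def home_range_area(self, quantile: float = 0.95) -> float:
        """Area of the Gaussian home range containing ``quantile`` of use.

        For an isotropic Gaussian utilisation distribution the q-quantile
        contour encloses area ``-2 pi sigma_r2 ln(1-q)``.  Returned alongside
        raw sigma_r2 in sweep outputs as the "home-range size" axis.
        """
        if self.mode != "OU":
            raise ValueError("home-range area is defined for OU movement only")
        return -2.0 * math.pi * self.sigma_r2 * math.log1p(-quantile)


def propagate(position, centre, dt: float, params: MovementParams, rng: np.random.Generator):
    """Advance position(s) by time dt using the exact transition law.

    OU:      x' = mu + (x - mu) e^{-dt/tau} + N(0, sigma_r2 (1 - e^{-2dt/tau}))
    BM:      x' = x + N(0, 2 D dt)
    SESSILE: x' = x.

    Positions are returned unwrapped (wrapping an OU path would break the
    reversion toward the centre); interactions wrap on demand.  Broadcasts
    over (..., 2) arrays of positions/centres.
    """
    if dt < 0:
        raise ValueError(f"negative time step dt={dt}")
    x = np.asarray(position, dtype=float)
    if dt == 0 or params.mode == "SESSILE":
        return x.copy()
    if params.mode == "OU":
        mu = np.asarray(centre, dtype=float)
        a = math.exp(-dt / params.tau)
        s = math.sqrt(params.sigma_r2 * -math.expm1(-2.0 * dt / params.tau))
        return mu + (x - mu) * a + s * rng.standard_normal(x.shape)
    # BM
    s = math.sqrt(2.0 * params.D * dt)
    return x + s * rng.standard_normal(x.shape)


def sample_stationary_position(
    centre, params: MovementParams, domain: Domain, rng: np.random.Generator
):
    """Draw position(s) from the asymptotic space-utilisation distribution.

    OU: Gaussian of variance sigma_r2 around the centre (returned unwrapped);
    SESSILE: the centre itself; BM: uniform over the domain (the stationary
    law of Brownian motion on the torus).
    """
    mu = np.asarray(centre, dtype=float)
    if params.mode == "SESSILE":
        return mu.copy()
    if params.mode == "OU":
        return mu + math.sqrt(params.sigma_r2) * rng.standard_normal(mu.shape)
    return domain.L * rng.random(mu.shape)


def effective_diffusion(params: MovementParams) -> float:
    """Diffusion coefficient: sigma_r2/tau (OU), D (BM), 0 (SESSILE)."""
    return float(params.D)
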