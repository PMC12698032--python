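"""Event-driven birth-dispersal-death dynamics: the range-resident logistic IBM.

Each organism carries a home-range centre ``mu`` and a position ``x``.
Births occur at constant per-capita rate ``b``; the offspring's centre is
displaced from the parent's by a dispersal-kernel draw, and its position is
sampled from the stationary space-use law of the movement process.  Deaths
occur at rate ``d0 + gamma * sum_j Kc(x_i - x_j)``, the kernel sum running
over minimum-image displacements to all other organisms.  Between
demographic events every organism moves for the exponentially distributed
waiting time.

Two interchangeable executions exist: a numba engine (:func:`run`, the
default) and a transparent NumPy reference path (:func:`gillespie_step` /
``method="reference"``) that draws the identical RNG stream, used as an
oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from . import _engine
from .config import DemographyParams, SimConfig
from .geometry_kernels import (
    Domain,
    KernelSpec,
    n_kernel_images,
    periodic_kernel_value,
)
from .movement import MovementParams

__all__ = [
    "Organism",
    "PopulationState",
    "SimResult",
    "death_rate",
    "initialize_population",
    "gillespie_step",
    "run",
]

SNAPSHOT_COLUMNS = ["id", "mu_x", "mu_y", "x", "y"]


@dataclass(frozen=True)
class Organism:
    """Read-only record of one organism: identity, home-range centre, position."""

    id: int
    centre: np.ndarray
    position: np.ndarray


@dataclass
class PopulationState:
    """Population snapshot: per-organism arrays plus the simulation clock."""

    ids: np.ndarray  # (N,) int64, unique
    centres: np.ndarray  # (N, 2), wrapped into [0, L)^2
    positions: np.ndarray  # (N, 2), unwrapped
    t: float
    domain: Domain

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.centres = np.asarray(self.centres, dtype=float).reshape(-1, 2)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if not (len(self.ids) == len(self.centres) == len(self.positions)):
            raise ValueError("ids, centres and positions must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("organism ids must be unique")

    @property
    def N(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> float:
        """Population density N / A."""
        return self.N / self.domain.A

    def __iter__(self) -> Iterator[Organism]:
        for i in range(self.N):
            yield Organism(int(self.ids[i]), self.centres[i].copy(), self.positions[i].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "mu_x": self.centres[:, 0],
                "mu_y": self.centres[:, 1],
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, domain: Domain, t: float = 0.0) -> "PopulationState":
        missing = set(SNAPSHOT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"snapshot table is missing columns {sorted(missing)}")
        return cls(
            ids=df["id"].to_numpy(),
            centres=df[["mu_x", "mu_y"]].to_numpy(),
            positions=df[["x", "y"]].to_numpy(),
            t=t,
            domain=domain,
        )

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.ids.copy(), self.centres.copy(), self.positions.copy(), self.t, self.domain
        )


@dataclass
class SimResult:
    """Outcome of a run: the abundance series, final snapshot and provenance."""

    abundance: pd.DataFrame  # columns t, N, event (+1 birth / -1 death)
    final_state: PopulationState
    seed: int | None
    config: dict
    status: str  # "completed" | "extinct"
    events_run: int

    @property
    def extinct(self) -> bool:
        return self.status == "extinct"

    def mean_abundance(self, burn_in: float = 0.5) -> float:
        """Time-weighted mean N over the post-burn-in part of the series."""
        frm = int(burn_in * len(self.abundance))
        t = self.abundance["t"].to_numpy()[frm:]
        n = self.abundance["N"].to_numpy()[frm:]
        if len(t) < 2:
            return float(n[-1]) if len(n) else 0.0
        return float(np.sum(n[:-1] * np.diff(t)) / (t[-1] - t[0]))


def death_rate(
    focal: int | Organism,
    state: PopulationState,
    params: DemographyParams,
    domain: Domain | None = None,
) -> float:
    """Per-capita death rate of one organism from brute-force pair sums.

    This is the transparent reference used to validate the engine's
    cell-list and incremental bookkeeping; it shares the kernel convention
    (truncation on the minimum-image distance, periodic-image summation for
    very long-range kernels).
    """
    domain = domain or state.domain
    if isinstance(focal, Organism):
        idx = int(np.flatnonzero(state.ids == focal.id)[0])
    else:
        idx = int(focal)
    xi = state.positions[idx]
    others = np.delete(state.positions, idx, axis=0)
    if len(others) == 0:
        return params.d0
    d = others - xi
    d -= domain.L * np.floor(d / domain.L + 0.5)
    k = periodic_kernel_value(d, params.kernel, domain)
    return params.d0 + params.gamma * float(np.sum(k))


def all_death_rates(
    state: PopulationState, params: DemographyParams, domain: Domain | None = None
) -> np.ndarray:
    """Vector of per-organism death rates (brute-force all-pairs)."""
    domain = domain or state.domain
    return np.array([death_rate(i, state, params, domain) for i in range(state.N)])


def initialize_population(config: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Uniformly random home-range centres; positions by the stationary rule.

    Centres are i.i.d. uniform on the domain (complete spatial randomness).
    Initial positions follow the same convention as newborn organisms: a
    stationary space-use draw (OU: Gaussian around the centre, BM: uniform,
    sessile: the centre itself).
    """
    n0 = config.n0
    L = config.domain.L
    centres = L * rng.random((n0, 2))
    mv = config.movement
    if mv.mode == "OU":
        positions = centres + np.sqrt(mv.sigma_r2) * rng.standard_normal((n0, 2))
    elif mv.mode == "BM":
        positions = L * rng.random((n0, 2))
    else:
        positions = centres.copy()
    return PopulationState(
        ids=np.arange(n0, dtype=np.int64),
        centres=centres,
        positions=positions,
        t=0.0,
        domain=config.domain,
    )


def gillespie_step(
    state: PopulationState,
    params: DemographyParams,
    movement: MovementParams,
    domain: Domain,
    rng: np.random.Generator,
    order: str = "move_first",
    next_id: int | None = None,
) -> tuple[PopulationState, dict]:
    """One exact Gillespie event (pure-NumPy reference path).

    Protocol: (1) death rates from current positions; (2) waiting time
    ``Exponential(bN + sum d_i)``; (3) all organisms move for that time;
    (4) birth with probability ``bN / total`` else death with per-organism
    probability ``d_i / total deaths`` -- both using the pre-move rates;
    (5) execute; (6) advance the clock.  ``order="event_first"`` executes
    the event before the movement update (the two agree to first order in
    the waiting time); the default matches the jitted engine draw for draw.
    """
    if state.N < 1:
        raise ValueError("cannot step an extinct population")
    if order not in ("move_first", "event_first"):
        raise ValueError(f"unknown step order {order!r}")
    st = state.copy()
    L = domain.L
    N = st.N
    drate = all_death_rates(st, params, domain)
    B = params.b * N
    Dtot = float(np.sum(drate))
    total = B + Dtot
    dt = rng.standard_exponential() / total

    def move(s: PopulationState) -> None:
        if movement.mode == "SESSILE" or s.N == 0:
            return
        z = rng.standard_normal((s.N, 2))
        if movement.mode == "OU":
            a = np.exp(-dt / movement.tau)
            sd = np.sqrt(movement.sigma_r2 * -np.expm1(-2.0 * dt / movement.tau))
            s.positions = s.centres + (s.positions - s.centres) * a + sd * z
        else:
            s.positions = s.positions + np.sqrt(2.0 * movement.D * dt) * z

    if order == "move_first":
        move(st)
    u = rng.random()
    if u * total < B:
        parent = int(rng.random() * N)
        if params.dispersal.family == "gaussian":
            disp = params.dispersal.sigma_d * rng.standard_normal(2)
        else:
            r = params.dispersal.gamma_scale * rng.standard_gamma(params.dispersal.shape)
            th = 2.0 * np.pi * rng.random()
            disp = np.array([r * np.cos(th), r * np.sin(th)])
        centre = st.centres[parent] + disp
        centre = centre - L * np.floor(centre / L)
        centre[centre >= L] = 0.0
        if movement.mode == "OU":
            pos = centre + np.sqrt(movement.sigma_r2) * rng.standard_normal(2)
        elif movement.mode == "BM":
            pos = L * rng.random(2)
        else:
            pos = centre.copy()
        new_id = int(st.ids.max()) + 1 if next_id is None else int(next_id)
        st.ids = np.append(st.ids, new_id)
        st.centres = np.vstack([st.centres, centre])
        st.positions = np.vstack([st.positions, pos])
        record = {"event": "birth", "id": new_id}
    else:
        v = rng.random() * Dtot
        victim = int(np.searchsorted(np.cumsum(drate), v, side="right"))
        victim = min(victim, N - 1)
        record = {"event": "death", "id": int(st.ids[victim])}
        # swap-remove, mirroring the engine's slot bookkeeping
        last = N - 1
        for arr in (st.ids, st.centres, st.positions):
            arr[victim] = arr[last]
        st.ids = st.ids[:last]
        st.centres = st.centres[:last]
        st.positions = st.positions[:last]
    if order == "event_first":
        move(st)
    st.t = state.t + dt
    record.update({"t": st.t, "N": st.N, "dt": dt})
    return st, record


def _thin(abundance: pd.DataFrame, stride: int) -> pd.DataFrame:
    """Keep every stride-th event record (the final event is always kept)."""
    if stride <= 1 or len(abundance) == 0:
        return abundance
    idx = np.arange(stride - 1, len(abundance), stride)
    if len(idx) == 0 or idx[-1] != len(abundance) - 1:
        idx = np.append(idx, len(abundance) - 1)
    return abundance.iloc[idx].reset_index(drop=True)


def _run_reference(config: SimConfig, rng: np.random.Generator, seed) -> SimResult:
    state = initialize_population(config, rng)
    t_rec, n_rec, ev_rec = [], [], []
    status = "completed"
    e = 0
    next_id = state.N  # ids are never reused, matching the engine's counter
    for e in range(config.events):
        if state.N == 0:
            status = "extinct"
            break
        state, rec = gillespie_step(
            state, config.demography, config.movement, config.domain, rng, next_id=next_id
        )
        if rec["event"] == "birth":
            next_id += 1
        t_rec.append(rec["t"])
        n_rec.append(rec["N"])
        ev_rec.append(1 if rec["event"] == "birth" else -1)
    else:
        e = config.events
    if state.N == 0:
        status = "extinct"
    abundance = pd.DataFrame(
        {"t": t_rec, "N": np.array(n_rec, dtype=np.int64), "event": np.array(ev_rec, dtype=np.int8)}
    )
    abundance = _thin(abundance, config.record_stride)
    return SimResult(abundance, state, seed, config.to_dict(), status, len(t_rec))


def run(
    config: SimConfig,
    seed: int | None = None,
    method: str = "fast",
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Run the IBM for the configured event budget (or until extinction).

    Deterministic given ``seed``: the same seed reproduces the abundance
    series bit for bit.  ``method="reference"`` uses the slow transparent
    path; both methods consume the RNG stream identically.
    """
    if method not in ("fast", "reference"):
        raise ValueError(f"unknown method {method!r}")
    if seed is None:
        seed = config.seed
    if rng is None:
        rng = np.random.default_rng(seed)
    if method == "reference":
        return _run_reference(config, rng, seed)

    demog = config.demography
    kernel = demog.kernel
    mv = config.movement
    L = config.domain.L
    n_events = config.events

    state0 = initialize_population(config, rng)
    if state0.N == 0 or n_events == 0:
        abundance = pd.DataFrame(
            {"t": np.zeros(0), "N": np.zeros(0, dtype=np.int64), "event": np.zeros(0, dtype=np.int8)}
        )
        status = "extinct" if state0.N == 0 else "completed"
        return SimResult(abundance, state0, seed, config.to_dict(), status, 0)
    if demog.gamma > 0:
        n_csr_guess = max(demog.b - demog.d0, 0.0) / demog.gamma * config.domain.A
    else:
        n_csr_guess = 0.0
    cap = int(max(4 * config.n0, 4 * n_csr_guess, 1024))
    cx = np.zeros(cap)
    cy = np.zeros(cap)
    px = np.zeros(cap)
    py = np.zeros(cap)
    ids = np.zeros(cap, dtype=np.int64)
    drate = np.zeros(cap)
    N = state0.N
    cx[:N] = state0.centres[:, 0]
    cy[:N] = state0.centres[:, 1]
    px[:N] = state0.positions[:, 0]
    py[:N] = state0.positions[:, 1]
    ids[:N] = state0.ids

    rcut = kernel.trunc_radius
    m_img = n_kernel_images(kernel, config.domain)
    ncell = min(int(L / rcut), 64) if rcut < L / 2 else 0
    s2 = kernel.sigma_q**2
    norm = 1.0 / (2.0 * np.pi * s2)
    nc2 = max(ncell * ncell, 1)
    wx = np.zeros(cap)
    wy = np.zeros(cap)
    cellix = np.zeros(cap, dtype=np.int64)
    celliy = np.zeros(cap, dtype=np.int64)
    cstart = np.zeros(nc2 + 1, dtype=np.int64)
    ccur = np.zeros(nc2, dtype=np.int64)
    corder = np.zeros(cap, dtype=np.int64)
    t_rec = np.zeros(n_events)
    n_rec = np.zeros(n_events, dtype=np.int64)
    ev_rec = np.zeros(n_events, dtype=np.int8)

    disp_family = 0 if demog.dispersal.family == "gaussian" else 1
    gshape = demog.dispersal.shape
    gscale = demog.dispersal.gamma_scale if disp_family == 1 else 0.0
    tau = mv.tau if mv.mode == "OU" else 0.0
    sigma_r2 = mv.sigma_r2 if mv.mode == "OU" else 0.0

    t = 0.0
    e = 0
    next_id = N
    rates_valid = False
    status_code = _engine.OK
    while True:
        e, N, t, next_id, status_code = _engine.run_events(
            cx, cy, px, py, ids, drate,
            N, t, next_id, rates_valid,
            L, demog.b, demog.d0, demog.gamma,
            s2, norm, rcut * rcut, m_img, ncell,
            mv.mode_code, tau, sigma_r2, float(mv.D),
            disp_family, demog.dispersal.sigma_d, gshape, gscale,
            n_events, e,
            t_rec, n_rec, ev_rec,
            wx, wy, cellix, celliy, cstart, ccur, corder,
            rng,
        )
        if status_code != _engine.CAPACITY:
            break
        # grow capacity and resume; the RNG stream is untouched by the retry
        new_cap = 2 * cap
        grow = lambda a: np.concatenate([a, np.zeros(new_cap - cap, dtype=a.dtype)])
        cx, cy, px, py, wx, wy, drate = map(grow, (cx, cy, px, py, wx, wy, drate))
        ids, cellix, celliy, corder = map(grow, (ids, cellix, celliy, corder))
        cap = new_cap
        rates_valid = True

    status = "extinct" if status_code == _engine.EXTINCT else "completed"
    abundance = _thin(
        pd.DataFrame({"t": t_rec[:e], "N": n_rec[:e], "event": ev_rec[:e]}),
        config.record_stride,
    )
    final_state = PopulationState(
        ids=ids[:N].copy(),
        centres=np.column_stack([cx[:N], cy[:N]]),
        positions=np.column_stack([px[:N], py[:N]]),
        t=t,
        domain=config.domain,
    )
    return SimResult(abundance, final_state, seed, config.to_dict(), status, e)
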