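"""Bias-exchange metadynamics engine on analytic toy landscapes.

Metadynamics deposits repulsive Gaussian hills along a collective variable;
the accumulated external potential

    V_G(s, t) = sum_{t' = tau_G, 2 tau_G, ... <= t} w exp(-(s - s(t'))^2 / (2 sigma^2))

estimates the negative of the underlying free energy once the landscape is
filled, F(s) ~= -V_G(s, t -> infinity).  In bias-exchange metadynamics
several replicas run simultaneously, each biasing a different CV (plus
unbiased "neutral" replicas), and periodically attempt configuration swaps
accepted with the Metropolis-like probability

    min(1, exp([V_a(s_a(x_a)) + V_b(s_b(x_b)) - V_a(s_a(x_b)) - V_b(s_b(x_a))] / kT)).

The dynamics here is overdamped Langevin on pluggable analytic potentials,
standing in for the all-atom MD engine; the bias bookkeeping, free-energy
readout and exchange criterion are the same as in the full method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import config
from .config import KB


# ---------------------------------------------------------------------------
# Bias bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianKernel:
    """One deposited hill: centre, width sigma (CV units), height w (kJ/mol)."""

    center: float
    width: float
    height: float
    deposit_time: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("kernel width must be positive")
        if self.height < 0:
            raise ValueError("kernel height must be non-negative")


class GaussianBias:
    """Time-ordered hill history for one biased CV.

    ``cv_id`` names the biased CV (``None`` for a neutral replica, in which
    case the bias is identically zero).
    """

    def __init__(self, cv_id: str | None = None, deposit_stride: float = config.HILL_STRIDE):
        if not deposit_stride > 0:
            raise ValueError("deposit stride must be positive")
        self.cv_id = cv_id
        self.deposit_stride = deposit_stride
        self._centers: list[float] = []
        self._widths: list[float] = []
        self._heights: list[float] = []
        self._times: list[float] = []

    # -- introspection ------------------------------------------------------

    @property
    def kernels(self) -> list[GaussianKernel]:
        return [
            GaussianKernel(c, s, w, t)
            for c, s, w, t in zip(self._centers, self._widths, self._heights, self._times)
        ]

    def __len__(self) -> int:
        return len(self._centers)

    # -- mutation -----------------------------------------------------------

    def deposit_kernel(self, center: float, width: float, height: float, t: float) -> None:
        """Append one hill at time ``t``; times must be non-decreasing."""
        if self._times and t < self._times[-1]:
            raise ValueError(
                f"out-of-order deposit: t={t} before last deposit at {self._times[-1]}"
            )
        GaussianKernel(center, width, height, t)  # validates
        self._centers.append(float(center))
        self._widths.append(float(width))
        self._heights.append(float(height))
        self._times.append(float(t))

    # -- evaluation ---------------------------------------------------------

    def _upto(self, t: float) -> int:
        return int(np.searchsorted(np.asarray(self._times), t, side="right"))

    def energy(self, s, t: float = np.inf):
        """V_G(s, t): sum of hills deposited at or before ``t``, kJ/mol."""
        k = self._upto(t)
        if k == 0:
            return np.zeros_like(np.asarray(s, dtype=float)) if np.ndim(s) else 0.0
        c = np.asarray(self._centers[:k])
        w = np.asarray(self._heights[:k])
        sig = np.asarray(self._widths[:k])
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        v = np.sum(w * np.exp(-((s_arr[:, None] - c) ** 2) / (2.0 * sig**2)), axis=1)
        return v if np.ndim(s) else float(v[0])

    def force(self, s: float, t: float = np.inf) -> float:
        """-dV_G/ds at CV value ``s``."""
        k = self._upto(t)
        if k == 0:
            return 0.0
        c = np.asarray(self._centers[:k])
        w = np.asarray(self._heights[:k])
        sig = np.asarray(self._widths[:k])
        ds = s - c
        return float(np.sum(w * ds / sig**2 * np.exp(-(ds**2) / (2.0 * sig**2))))


def bias_energy(bias: GaussianBias, s, t: float = np.inf):
    """Functional wrapper around :meth:`GaussianBias.energy`."""
    return bias.energy(s, t)


def deposit_kernel(bias: GaussianBias, current_cv: float, t: float,
                   width: float, height: float = config.HILL_HEIGHT) -> GaussianBias:
    """Deposit one hill at the current CV value; returns the updated bias."""
    bias.deposit_kernel(current_cv, width, height, t)
    return bias


class _BiasGrid:
    """Gridded mirror of a bias for O(1) force lookups during dynamics.

    Hills are splatted onto a fixed grid when deposited; the force on the CV
    is read back by linear interpolation.  Outside the grid the bias is flat
    (zero force), so the underlying landscape must confine the dynamics.
    """

    def __init__(self, lo: float, hi: float, n: int = 600):
        self.s = np.linspace(lo, hi, n)
        self.v = np.zeros(n)
        self.dvds = np.zeros(n)

    def add_hill(self, center: float, width: float, height: float) -> None:
        ds = self.s - center
        g = height * np.exp(-(ds**2) / (2.0 * width**2))
        self.v += g
        self.dvds += -ds / width**2 * g

    def force(self, s: float) -> float:
        return float(-np.interp(s, self.s, self.dvds))


# ---------------------------------------------------------------------------
# Free-energy readout
# ---------------------------------------------------------------------------


def bias_to_free_energy(bias: GaussianBias, grid: np.ndarray, t_final: float = np.inf):
    """Instantaneous estimate F(s) = -V_G(s, t_final), shifted to min 0.

    Returns a 1D :class:`~gqfold.fel.FreeEnergySurface` on bins centred at
    the grid points.
    """
    from .fel import FreeEnergySurface, edges_from_centers

    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and sorted ascending")
    f = -np.atleast_1d(bias.energy(grid, t_final))
    f = f - f.min()
    return FreeEnergySurface(
        axes=(bias.cv_id or "s",),
        edges=(edges_from_centers(grid),),
        values=f,
        mask=np.ones_like(f, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Landscapes and collective variables of the toy dynamics
# ---------------------------------------------------------------------------


@dataclass
class AnalyticLandscape:
    """Analytic potential U(x) with exact gradient, kJ/mol over nm-like x."""

    name: str
    dimension: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float] = (-2.5, 2.5)
    minima: tuple = ()


@dataclass(frozen=True)
class CoordinateCV:
    """CV that projects out one Cartesian coordinate of the toy dynamics."""

    name: str
    axis: int
    grid_range: tuple[float, float] = (-2.5, 2.5)

    def value(self, x: np.ndarray) -> float:
        return float(np.atleast_1d(x)[self.axis])

    def grad(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(np.atleast_1d(np.asarray(x, dtype=float)))
        g[self.axis] = 1.0
        return g


# ---------------------------------------------------------------------------
# Overdamped Langevin dynamics
# ---------------------------------------------------------------------------


def langevin_step(
    coordinates: np.ndarray,
    force: np.ndarray,
    dt: float,
    temperature: float,
    friction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler-Maruyama step of overdamped Langevin dynamics.

    x' = x + (dt/gamma) F + sqrt(2 kB T dt / gamma) xi, xi ~ N(0, 1) per
    dimension.  Deterministic given the generator state.
    """
    if not dt > 0 or not friction > 0:
        raise ValueError("dt and friction must be positive")
    force = np.atleast_1d(np.asarray(force, dtype=float))
    if not np.all(np.isfinite(force)):
        raise ValueError("non-finite force")
    x = np.atleast_1d(np.asarray(coordinates, dtype=float))
    noise = np.sqrt(2.0 * KB * temperature * dt / friction) * rng.standard_normal(x.shape)
    return x + (dt / friction) * force + noise


def run_langevin(
    landscape: AnalyticLandscape,
    x0,
    n_steps: int,
    dt: float,
    temperature: float = config.DEFAULT_TEMPERATURE,
    friction: float = 1.0,
    seed: int = 0,
    sample_stride: int = 1,
) -> np.ndarray:
    """Unbiased trajectory on a landscape; returns samples (n_samples, dim)."""
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    pref = dt / friction
    amp = np.sqrt(2.0 * KB * temperature * dt / friction)
    out = []
    for i in range(n_steps):
        f = -np.atleast_1d(landscape.gradient(x))
        x = x + pref * f + amp * rng.standard_normal(x.shape)
        if (i + 1) % sample_stride == 0:
            out.append(x.copy())
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Replica state and bias exchange
# ---------------------------------------------------------------------------


@dataclass
class ReplicaState:
    """One walker: coordinates, its bias (possibly empty), its CV, its rng."""

    index: int
    coordinates: np.ndarray
    bias: GaussianBias
    cv: CoordinateCV | None
    temperature: float
    rng: np.random.Generator
    exchange_log: list[tuple[float, int, bool]] = field(default_factory=list)

    def bias_at(self, x: np.ndarray, t: float = np.inf) -> float:
        """This replica's metadynamics potential evaluated on coordinates x."""
        if self.cv is None or len(self.bias) == 0:
            return 0.0
        return float(self.bias.energy(self.cv.value(x), t))


def exchange_probability(a: ReplicaState, b: ReplicaState, t: float = np.inf) -> float:
    """Metropolis-like swap acceptance probability for a pair of walkers."""
    if a.temperature != b.temperature:
        raise ValueError("replicas must share a temperature to exchange")
    delta = (
        a.bias_at(a.coordinates, t)
        + b.bias_at(b.coordinates, t)
        - a.bias_at(b.coordinates, t)
        - b.bias_at(a.coordinates, t)
    )
    return float(min(1.0, np.exp(min(delta / (KB * a.temperature), 0.0))))


def attempt_exchange(a: ReplicaState, b: ReplicaState, t: float,
                     rng: np.random.Generator) -> bool:
    """Attempt a configuration swap; on accept, coordinates swap while each
    bias stays with its replica.  Both exchange logs are appended."""
    p = exchange_probability(a, b, t)
    accepted = bool(rng.random() < p) if p < 1.0 else True
    if accepted:
        a.coordinates, b.coordinates = b.coordinates.copy(), a.coordinates.copy()
    a.exchange_log.append((t, b.index, accepted))
    b.exchange_log.append((t, a.index, accepted))
    return accepted


# ---------------------------------------------------------------------------
# Schedules and the BEMD driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Schedule:
    """Time stepping plan: all strides must be positive multiples of dt, ns."""

    dt: float
    deposit_stride: float = config.HILL_STRIDE
    exchange_stride: float = 0.005
    sample_stride: float = 0.001
    total_time: float = 1.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.total_time < 0:
            raise ValueError("total_time must be non-negative")
        for nm in ("deposit_stride", "exchange_stride", "sample_stride"):
            v = getattr(self, nm)
            if not v > 0:
                raise ValueError(f"{nm} must be positive")
            n = v / self.dt
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{nm}={v} is not a multiple of dt={self.dt}")

    def steps(self, stride: float) -> int:
        return int(round(stride / self.dt))

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))


@dataclass
class BEMDResult:
    """Output bundle: per-replica CV traces, biases and exchange logs."""

    times: np.ndarray                      # sample times, ns
    traces: list[np.ndarray]               # per replica, (n_samples, n_cvs)
    coordinates: list[np.ndarray]          # per replica, (n_samples, dim)
    replicas: list[ReplicaState]
    cv_names: tuple[str, ...]

    @property
    def exchange_logs(self) -> list[list[tuple[float, int, bool]]]:
        return [r.exchange_log for r in self.replicas]


def run_bemd(
    landscape: AnalyticLandscape,
    cv_definitions: Sequence[CoordinateCV],
    n_biased: int,
    n_neutral: int,
    schedule: Schedule,
    widths: Sequence[float],
    height: float = config.HILL_HEIGHT,
    temperature: float = config.DEFAULT_TEMPERATURE,
    friction: float = 1.0,
    seed: int = 0,
    x0=None,
) -> BEMDResult:
    """Run biased + neutral replicas with periodic random-pair exchanges.

    Replica i < n_biased biases ``cv_definitions[i]`` with hill width
    ``widths[i]``; the remaining ``n_neutral`` replicas carry no bias and
    sample the corrected ensemble.  Deterministic given the seed.
    """
    if n_biased < 1 or n_neutral < 1:
        raise ValueError("need at least one biased and one neutral replica")
    if n_biased > len(cv_definitions) or n_biased > len(widths):
        raise ValueError("not enough CV definitions/widths for the biased replicas")
    n_rep = n_biased + n_neutral
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_rep + 1)
    exch_rng = np.random.default_rng(child[-1])

    if x0 is None:
        x0 = np.zeros(landscape.dimension)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))

    replicas: list[ReplicaState] = []
    grids: list[_BiasGrid | None] = []
    for i in range(n_rep):
        biased = i < n_biased
        cv = cv_definitions[i] if biased else None
        bias = GaussianBias(cv.name if biased else None, schedule.deposit_stride)
        replicas.append(ReplicaState(
            index=i, coordinates=x0.copy(), bias=bias, cv=cv,
            temperature=temperature, rng=np.random.default_rng(child[i]),
        ))
        grids.append(_BiasGrid(*cv.grid_range) if biased else None)

    dt = schedule.dt
    pref = dt / friction
    amp = np.sqrt(2.0 * KB * temperature * dt / friction)
    dep_every = schedule.steps(schedule.deposit_stride)
    exch_every = schedule.steps(schedule.exchange_stride)
    samp_every = schedule.steps(schedule.sample_stride)

    times: list[float] = []
    traces: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    coords_out: list[list[np.ndarray]] = [[] for _ in range(n_rep)]

    for step in range(1, schedule.n_steps + 1):
        t = step * dt
        for i, rep in enumerate(replicas):
            f = -np.atleast_1d(landscape.gradient(rep.coordinates))
            if rep.cv is not None:
                fg = grids[i]
                f = f + fg.force(rep.cv.value(rep.coordinates)) * rep.cv.grad(rep.coordinates)
            if not np.all(np.isfinite(f)):
                raise FloatingPointError(f"non-finite force on replica {i} at t={t}")
            rep.coordinates = rep.coordinates + pref * f + amp * rep.rng.standard_normal(
                rep.coordinates.shape)
        if step % dep_every == 0:
            for i in range(n_biased):
                rep = replicas[i]
                s = rep.cv.value(rep.coordinates)
                rep.bias.deposit_kernel(s, widths[i], height, t)
                grids[i].add_hill(s, widths[i], height)
        if step % exch_every == 0 and n_rep >= 2:
            i, j = exch_rng.choice(n_rep, size=2, replace=False)
            attempt_exchange(replicas[int(i)], replicas[int(j)], t, exch_rng)
        if step % samp_every == 0:
            times.append(t)
            for i, rep in enumerate(replicas):
                traces[i].append(np.array([cv.value(rep.coordinates) for cv in cv_definitions]))
                coords_out[i].append(rep.coordinates.copy())

    return BEMDResult(
        times=np.asarray(times),
        traces=[np.asarray(tr).reshape(len(times), len(cv_definitions)) for tr in traces],
        coordinates=[
            np.asarray(c).reshape(len(times), landscape.dimension) for c in coords_out
        ],
        replicas=replicas,
        cv_names=tuple(cv.name for cv in cv_definitions),
    )


# ---------------------------------------------------------------------------
# Single-replica 1D metadynamics with a fill/plateau readout
# ---------------------------------------------------------------------------


@dataclass
class MetadynamicsRun:
    """1D metadynamics output with a plateau-averaged free-energy profile.

    ``profile`` is the time-average of the mean-subtracted bias shape over
    the post-fill plateau, negated and shifted to min 0 — the low-noise
    free-energy readout.  ``fill_time`` is the detected fill time (ns), or
    the midpoint fallback if no plateau was detected.
    """

    bias: GaussianBias
    grid: np.ndarray
    profile: np.ndarray
    fill_time: float
    snapshots: np.ndarray      # (n_snapshots, n_grid) bias shapes
    snapshot_times: np.ndarray


def run_metadynamics_1d(
    landscape: AnalyticLandscape,
    schedule: Schedule,
    width: float,
    height: float = config.HILL_HEIGHT,
    temperature: float = config.DEFAULT_TEMPERATURE,
    friction: float = 1.0,
    seed: int = 0,
    x0: float = 1.0,
    profile_range: tuple[float, float] = (-1.3, 1.3),
    n_grid: int = 201,
    snapshot_stride: float = 0.5,
    flat_tol_kt: float = 1.0,
) -> MetadynamicsRun:
    """Fill a 1D landscape with hills and read out the free-energy profile.

    The bias shape (grid values minus their mean) is snapshotted every
    ``snapshot_stride`` ns; the landscape counts as filled once the RMS
    change between consecutive shapes drops below ``flat_tol_kt * kB * T``
    and stays there.  The profile is averaged over all post-fill snapshots.
    """
    if landscape.dimension != 1:
        raise ValueError("run_metadynamics_1d needs a 1D landscape")
    cv = CoordinateCV("s", 0, grid_range=landscape.domain)
    rng = np.random.default_rng(seed)
    bias = GaussianBias("s", schedule.deposit_stride)
    fgrid = _BiasGrid(*landscape.domain)
    grid = np.linspace(profile_range[0], profile_range[1], n_grid)

    dt = schedule.dt
    pref = dt / friction
    amp = np.sqrt(2.0 * KB * temperature * dt / friction)
    dep_every = schedule.steps(schedule.deposit_stride)
    snap_every = max(1, int(round(snapshot_stride / dt)))

    x = np.array([float(x0)])
    shapes: list[np.ndarray] = []
    snap_times: list[float] = []
    for step in range(1, schedule.n_steps + 1):
        f = -np.atleast_1d(landscape.gradient(x)) + fgrid.force(float(x[0]))
        x = x + pref * f + amp * rng.standard_normal(1)
        if step % dep_every == 0:
            s = float(x[0])
            bias.deposit_kernel(s, width, height, step * dt)
            fgrid.add_hill(s, width, height)
        if step % snap_every == 0:
            v = np.interp(grid, fgrid.s, fgrid.v)
            shapes.append(v - v.mean())
            snap_times.append(step * dt)

    shapes_arr = np.asarray(shapes)
    snap_times_arr = np.asarray(snap_times)
    flat_tol = flat_tol_kt * KB * temperature
    fill_idx = len(shapes) // 2  # fallback: average over the last half
    rms = np.sqrt(np.mean(np.diff(shapes_arr, axis=0) ** 2, axis=1)) if len(shapes) > 1 else []
    for k, r in enumerate(rms):
        if r < flat_tol:
            fill_idx = k + 1
            break
    mean_shape = shapes_arr[fill_idx:].mean(axis=0)
    profile = -mean_shape
    profile = profile - profile.min()
    return MetadynamicsRun(
        bias=bias,
        grid=grid,
        profile=profile,
        fill_time=float(snap_times_arr[fill_idx]) if len(snap_times_arr) else 0.0,
        snapshots=shapes_arr,
        snapshot_times=snap_times_arr,
    )
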