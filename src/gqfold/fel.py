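"""Free-energy landscapes from neutral-replica samples, convergence
diagnostics, and basin identification.

The landscape is the histogram estimate F_bin = -kB*T*ln(n_bin / n_max) on a
1D or 2D grid of CV values, computed only from the unbiased (neutral)
replicas.  Basins are found by steepest descent on the binned surface and
merged when the separating saddle is shallower than a persistence threshold,
mirroring how (meta)stable states are read off such maps by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from . import config
from .config import KB


def edges_from_centers(centers: np.ndarray) -> np.ndarray:
    """Bin edges whose bins are centred on the given sorted points."""
    centers = np.asarray(centers, dtype=float)
    if centers.size == 1:
        return np.array([centers[0] - 0.5, centers[0] + 0.5])
    mid = 0.5 * (centers[1:] + centers[:-1])
    first = centers[0] - (mid[0] - centers[0])
    last = centers[-1] + (centers[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergySurface:
    """Binned free energy over one or two CV axes, kJ/mol.

    ``mask`` flags supported bins (sampled at least ``min_count`` times);
    unsupported bins hold NaN and are excluded from every comparison.  The
    minimum over supported bins is 0 by construction.
    """

    axes: tuple[str, ...]
    edges: tuple[np.ndarray, ...]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.values.ndim != len(self.axes) or len(self.edges) != len(self.axes):
            raise ValueError("axes/edges/values dimensionality mismatch")
        if self.mask.any():
            self.values = self.values - np.nanmin(self.values[self.mask])
            self.values[~self.mask] = np.nan

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def centers(self, axis: int = 0) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[1:] + e[:-1])


@dataclass
class BasinSet:
    """Partition of the supported bins into basins of attraction.

    ``labels`` assigns a basin id (0-based, ordered by ascending minimum
    free energy) to every supported bin and -1 to unsupported bins;
    ``minima`` lists (bin index tuple, free energy) per basin.
    """

    labels: np.ndarray
    minima: list[tuple[tuple[int, ...], float]]
    edges: tuple[np.ndarray, ...] = field(default_factory=tuple)

    @property
    def n_basins(self) -> int:
        return len(self.minima)


@dataclass
class ReplicaExchangeSummary:
    """Cumulative exchange statistics for one replica."""

    times: np.ndarray
    cumulative_accepted: np.ndarray
    n_attempts: int
    n_accepted: int
    mean_acceptance: float | None
    slope: float | None
    r_squared: float | None


@dataclass
class ExchangeDiagnostics:
    """Per-replica exchange summaries (linearity of accepted-count curves)."""

    replicas: list[ReplicaExchangeSummary]


# ---------------------------------------------------------------------------
# FEL estimation
# ---------------------------------------------------------------------------


def estimate_fel(
    samples: np.ndarray,
    bins: int | tuple[int, ...] = config.FEL_BINS,
    ranges=None,
    temperature: float = config.DEFAULT_TEMPERATURE,
    equilibration: float = config.FEL_EQUILIBRATION,
    axes: tuple[str, ...] | None = None,
    min_count: int = config.FEL_MIN_COUNT,
    padding: float = config.FEL_PADDING,
    connected_support: bool = True,
) -> FreeEnergySurface:
    """Histogram free-energy estimate from (neutral-replica) CV samples.

    ``samples`` is (n,) or (n, d) with d in {1, 2}.  The first
    ``equilibration`` fraction of samples is discarded.  When ``ranges`` is
    None each axis spans the observed range padded by ``padding``.  With
    ``connected_support`` (default), small isolated islands of supported
    bins are masked out: such stragglers carry no information about the
    barriers separating them from the rest of the landscape and would
    otherwise surface as spurious basins.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n, d = samples.shape
    if d not in (1, 2):
        raise ValueError("estimate_fel supports 1 or 2 CV axes")
    start = int(np.floor(equilibration * n))
    kept = samples[start:]
    if kept.shape[0] < 1:
        raise ValueError("no samples left after equilibration discard")
    if ranges is None:
        lo = kept.min(axis=0)
        hi = kept.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        ranges = [(lo[k] - padding * span[k], hi[k] + padding * span[k]) for k in range(d)]
    if isinstance(bins, int):
        bins = (bins,) * d
    counts, edges = np.histogramdd(kept, bins=bins, range=ranges)
    if counts.max() <= 0:
        raise ValueError("all histogram bins are empty")
    mask = counts >= max(1, min_count)
    if connected_support and mask.any():
        # drop small isolated support islands (sampling stragglers), keep
        # every component of substantial size
        labeled, n_comp = ndimage.label(mask)
        if n_comp > 1:
            sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
            floor = max(4.0, 0.05 * mask.sum())
            keep = {k + 1 for k, s in enumerate(sizes) if s >= floor}
            if keep:
                mask = np.isin(labeled, list(keep))
    with np.errstate(divide="ignore"):
        f = -KB * temperature * np.log(counts / counts.max())
    f[~mask] = np.nan
    if axes is None:
        axes = tuple(f"cv{k}" for k in range(d))
    return FreeEnergySurface(axes=tuple(axes), edges=tuple(np.asarray(e) for e in edges),
                             values=f, mask=mask)


def fel_rms_difference(a: FreeEnergySurface, b: FreeEnergySurface) -> float:
    """RMS free-energy difference over bins supported in both surfaces."""
    if len(a.edges) != len(b.edges) or any(
        ea.shape != eb.shape or not np.allclose(ea, eb) for ea, eb in zip(a.edges, b.edges)
    ):
        raise ValueError("mismatched bin specifications")
    both = a.mask & b.mask
    if not both.any():
        raise ValueError("no commonly supported bins")
    # each surface already has min 0 over its own support
    diff = a.values[both] - b.values[both]
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def exchange_diagnostics(exchange_logs) -> ExchangeDiagnostics:
    """Cumulative accepted-exchange counts and their linearity per replica.

    ``exchange_logs`` is a list (one per replica) of (time, partner,
    accepted) tuples.  A replica with zero attempts reports its acceptance,
    slope and R^2 as missing (None).
    """
    out = []
    for log in exchange_logs:
        if len(log) == 0:
            out.append(ReplicaExchangeSummary(
                np.array([]), np.array([]), 0, 0, None, None, None))
            continue
        t = np.array([e[0] for e in log], dtype=float)
        acc = np.array([bool(e[2]) for e in log])
        cum = np.cumsum(acc)
        n_att, n_acc = len(acc), int(cum[-1])
        slope = r2 = None
        if len(t) >= 2 and np.ptp(t) > 0:
            res = stats.linregress(t, cum)
            slope = float(res.slope)
            r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else None
        out.append(ReplicaExchangeSummary(
            times=t, cumulative_accepted=cum, n_attempts=n_att, n_accepted=n_acc,
            mean_acceptance=n_acc / n_att, slope=slope, r_squared=r2))
    return ExchangeDiagnostics(replicas=out)


def cv_coverage(trace: np.ndarray, axis_range: tuple[float, float],
                n_segments: int = 20) -> dict:
    """How thoroughly a CV trace walks its range.

    Returns the fraction of equal range segments visited and the traversal
    count: the number of alternations between the lowest and highest decile
    of the range (a full back-and-forth sweep counts as 2).
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size == 0:
        raise ValueError("empty CV trace")
    lo, hi = axis_range
    if not hi > lo:
        raise ValueError("invalid axis range")
    seg = np.clip(((trace - lo) / (hi - lo) * n_segments).astype(int), 0, n_segments - 1)
    covered = len(np.unique(seg)) / n_segments
    width = hi - lo
    extreme = np.where(trace <= lo + 0.1 * width, -1, np.where(trace >= hi - 0.1 * width, 1, 0))
    nz = extreme[extreme != 0]
    traversals = int(np.sum(np.diff(nz) != 0)) if nz.size else 0
    return {"covered_fraction": float(covered), "traversals": traversals}


# ---------------------------------------------------------------------------
# Basin identification and frame assignment
# ---------------------------------------------------------------------------


def _neighbors(idx: tuple[int, ...], shape: tuple[int, ...]):
    for axis in range(len(shape)):
        for step in (-1, 1):
            j = idx[axis] + step
            if 0 <= j < shape[axis]:
                yield idx[:axis] + (j,) + idx[axis + 1:]


def identify_basins(fel: FreeEnergySurface, min_barrier: float | None = None,
                    temperature: float = config.DEFAULT_TEMPERATURE) -> BasinSet:
    """Steepest-descent basins with persistence merging.

    Every supported bin descends to its lowest 2- (1D) or 4-neighbour (2D)
    until a local minimum; minima whose separating saddle lies less than
    ``min_barrier`` (default 1 kB*T) above the shallower minimum are merged.
    Basins are numbered by ascending minimum free energy, ties broken by
    lexicographic bin index.
    """
    if min_barrier is None:
        min_barrier = config.BASIN_MIN_BARRIER_KT * KB * temperature
    F = np.where(fel.mask, fel.values, np.inf)
    shape = F.shape
    if not fel.mask.any():
        raise ValueError("surface has no supported bins")

    supported = [tuple(idx) for idx in np.argwhere(fel.mask)]
    # steepest-descent pointer per bin (ties: lexicographically smallest bin)
    downhill: dict[tuple[int, ...], tuple[int, ...]] = {}
    for idx in supported:
        best = idx
        best_f = F[idx]
        for nb in sorted(_neighbors(idx, shape)):
            if F[nb] < best_f:
                best, best_f = nb, F[nb]
        downhill[idx] = best

    def sink(idx):
        path = []
        while downhill[idx] != idx:
            path.append(idx)
            idx = downhill[idx]
        for p in path:  # path compression
            downhill[p] = idx
        return idx

    root = {idx: sink(idx) for idx in supported}
    minima = sorted({r for r in root.values()})

    # union-find over minima with persistence merging
    parent = {m: m for m in minima}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    def saddles():
        """Lowest separating saddle per pair of current basins."""
        sad: dict[tuple, float] = {}
        for idx in supported:
            a = find(root[idx])
            for nb in _neighbors(idx, shape):
                if nb not in root:
                    continue
                b = find(root[nb])
                if a == b:
                    continue
                key = (a, b) if a < b else (b, a)
                h = max(F[idx], F[nb])
                if key not in sad or h < sad[key]:
                    sad[key] = h
        return sad

    while True:
        sad = saddles()
        merged = False
        # merge the shallowest-persistence pair first for determinism
        for (a, b), h in sorted(sad.items(), key=lambda kv: (kv[1], kv[0])):
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            shallow = max(F[ra], F[rb])
            if h - shallow < min_barrier:
                deep, other = (ra, rb) if (F[ra], ra) <= (F[rb], rb) else (rb, ra)
                parent[other] = deep
                merged = True
                break
        if not merged:
            break

    kept = sorted({find(m) for m in minima}, key=lambda m: (F[m], m))
    number = {m: k for k, m in enumerate(kept)}
    labels = np.full(shape, -1, dtype=int)
    for idx in supported:
        labels[idx] = number[find(root[idx])]
    return BasinSet(
        labels=labels,
        minima=[(m, float(F[m])) for m in kept],
        edges=fel.edges,
    )


def assign_frames(cv_values: np.ndarray, basins: BasinSet) -> np.ndarray:
    """Basin label per frame from its CV bin; -1 where unassigned.

    Frames outside the bin ranges or in unsupported bins get label -1.
    """
    cv_values = np.asarray(cv_values, dtype=float)
    if cv_values.ndim == 1:
        cv_values = cv_values[:, None]
    n, d = cv_values.shape
    if d != len(basins.edges):
        raise ValueError("CV dimensionality does not match the basin grid")
    out = np.full(n, -1, dtype=int)
    idx_per_axis = []
    inside = np.ones(n, dtype=bool)
    for k in range(d):
        e = basins.edges[k]
        ix = np.searchsorted(e, cv_values[:, k], side="right") - 1
        # right edge of the last bin is inclusive
        ix[cv_values[:, k] == e[-1]] = len(e) - 2
        ok = (ix >= 0) & (ix <= len(e) - 2)
        inside &= ok
        idx_per_axis.append(np.clip(ix, 0, len(e) - 2))
    flat = tuple(ax[inside] for ax in idx_per_axis)
    out[inside] = basins.labels[flat]
    return out


# ---------------------------------------------------------------------------
# Boltzmann sampling check (chi-square with autocorrelation correction)
# ---------------------------------------------------------------------------


@dataclass
class BoltzmannCheck:
    chi2: float
    dof: int
    pvalue: float
    n_samples: int
    n_effective: float
    iact: float


def integrated_autocorr_time(x: np.ndarray, c: float = 5.0) -> float:
    """Sokal-windowed integrated autocorrelation time, in sample strides.

    Returns tau >= 1 such that n/tau is the effective independent sample
    count; tau = 1 for white noise.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    if n < 2 or np.allclose(x, 0):
        return 1.0
    m = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, n=m)
    acf = np.fft.irfft(fx * np.conjugate(fx), n=m)[:n].real
    acf /= acf[0]
    tau = 2.0 * np.cumsum(acf) - 1.0
    window = np.arange(len(tau)) >= c * tau
    k = int(np.argmax(window)) if window.any() else n - 1
    return float(max(1.0, tau[k]))


def boltzmann_check(
    samples: np.ndarray,
    energy,
    temperature: float = config.DEFAULT_TEMPERATURE,
    support: tuple[float, float] = (-2.0, 2.0),
    n_bins: int = 10,
) -> BoltzmannCheck:
    """Chi-square comparison of 1D samples against the Boltzmann density.

    Bin edges are analytic equal-probability quantiles of exp(-U/kT) on
    ``support``.  Because Langevin samples are serially correlated, the
    chi-square statistic is scaled by n_eff/n with n_eff from the integrated
    autocorrelation time of the sample series (the well-hopping mode is the
    slowest and dominates tau).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    n = len(samples)
    if n < n_bins:
        raise ValueError("need at least n_bins samples")
    grid = np.linspace(support[0], support[1], 4001)
    u = np.array([float(energy(np.array([g]))) for g in grid])
    w = np.exp(-(u - u.min()) / (KB * temperature))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.interp(qs, cdf, grid)
    edges[0], edges[-1] = -np.inf, np.inf  # fold the negligible tails in
    obs = np.histogram(samples, bins=edges)[0]
    p = np.full(n_bins, 1.0 / n_bins)
    tau = integrated_autocorr_time(samples)
    n_eff = n / tau
    chi2 = float(n_eff * np.sum((obs / n - p) ** 2 / p))
    dof = n_bins - 1
    return BoltzmannCheck(
        chi2=chi2, dof=dof, pvalue=float(stats.chi2.sf(chi2, dof)),
        n_samples=n, n_effective=float(n_eff), iact=float(tau),
    )
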