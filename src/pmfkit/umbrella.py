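"""Umbrella sampling windows, the WHAM solver, and block errors.

Windows are a regular grid of harmonic restraints over the CV rectangle
(default force constant 5 kcal/mol/A^2, window spacing 0.25 A on the gate
axis and 0.5 A elsewhere). Each window is seeded from the string image
nearest its center, sampled with the Langevin engine, and the first
fraction of the series is discarded (default 60/560). The biased
histograms are combined by self-consistent WHAM iteration

    p(b)        = sum_i n_i(b) / sum_i N_i exp(-beta (w_i(b) - f_i))
    exp(-b f_i) = sum_b p(b) exp(-beta w_i(b))

initialized at f_i = 0 and converged on max |df_i| (default 0.001
kcal/mol). Uncertainties come from re-solving WHAM on contiguous
per-window blocks (default 3) and taking the per-bin standard deviation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .constants import DEFAULT_TEMPERATURE, kt
from .landscape import LangevinSettings, ModelPotential, _propagate_batch
from .pmf import PMFSurface, integrate_1d, make_edges
from .string_method import TransitionString

__all__ = [
    "UmbrellaWindow", "BiasedSeries", "WhamConnectivityError",
    "WhamConvergenceError", "make_window_grid", "select_seed_image",
    "sample_window", "sample_windows", "wham", "wham_2d", "block_errors",
    "integrate_1d", "DEFAULT_DISCARD_FRACTION", "write_window_table",
    "read_window_table", "write_series", "read_series",
]

#: Default burn-in fraction (mirrors keeping the last 500 of 560 samples).
DEFAULT_DISCARD_FRACTION = 60.0 / 560.0


class WhamConnectivityError(RuntimeError):
    pass


class WhamConvergenceError(RuntimeError):
    pass


@dataclass
class UmbrellaWindow:
    """One harmonic restraint window."""

    center: np.ndarray
    force_constants: np.ndarray = None   # kcal/mol/A^2, default 5 per axis
    window_sizes: np.ndarray = None      # grid spacing this window came from
    index: int = 0
    seed_image_index: Optional[int] = None
    samples_total: int = 0
    samples_discarded: int = 0
    bias_offset: float = 0.0   # additive constant; physically gauge only

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        if self.force_constants is None:
            self.force_constants = np.full_like(self.center, 5.0)
        self.force_constants = np.atleast_1d(np.asarray(self.force_constants, float))
        if self.window_sizes is not None:
            self.window_sizes = np.atleast_1d(np.asarray(self.window_sizes, float))
            if np.any(self.window_sizes <= 0):
                raise ValueError("window sizes must be positive")
        if np.any(self.force_constants <= 0):
            raise ValueError("force constants must be positive")
        if self.samples_total and self.samples_discarded >= self.samples_total:
            raise ValueError("discarded must be < total")

    @property
    def ndim(self) -> int:
        return self.center.size

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * (self.force_constants * (x - self.center) ** 2).sum(axis=-1) \
            + self.bias_offset


@dataclass
class BiasedSeries:
    """Post-discard CV samples from one window."""

    window: UmbrellaWindow
    series: np.ndarray      # (n, d)
    seed: int = 0

    def __post_init__(self):
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if self.series.size and not np.isfinite(self.series).all():
            raise ValueError(f"window {self.window.index}: non-finite samples")

    def __len__(self) -> int:
        return len(self.series)


# ---------------------------------------------------------------------------
# window placement and seeding
# ---------------------------------------------------------------------------

def make_window_grid(bounds: Sequence[Sequence[float]],
                     window_sizes: Sequence[float],
                     force_constants: Union[float, Sequence[float]] = 5.0,
                     ) -> List[UmbrellaWindow]:
    """Regular grid of window centers covering ``bounds`` inclusively.

    Per axis the centers run lo, lo+size, ... up to hi (inclusive within
    rounding); an axis narrower than one window collapses to its midpoint.
    Windows are emitted in row-major order.
    """
    bounds = [tuple(map(float, b)) for b in bounds]
    sizes = np.atleast_1d(np.asarray(window_sizes, dtype=float))
    if len(sizes) == 1 and len(bounds) > 1:
        sizes = np.repeat(sizes, len(bounds))
    if np.any(sizes <= 0):
        raise ValueError("window sizes must be positive")
    ks = np.atleast_1d(np.asarray(force_constants, dtype=float))
    if len(ks) == 1 and len(bounds) > 1:
        ks = np.repeat(ks, len(bounds))
    axes = []
    for (lo, hi), s in zip(bounds, sizes):
        if hi < lo:
            raise ValueError(f"inverted bounds ({lo}, {hi})")
        if hi - lo < s:
            axes.append(np.array([(lo + hi) / 2.0]))
        else:
            n = int(np.floor((hi - lo) / s + 1e-9))
            axes.append(lo + s * np.arange(n + 1))
    windows = []
    for i, center in enumerate(itertools.product(*axes)):
        windows.append(UmbrellaWindow(np.array(center), ks.copy(), sizes.copy(),
                                      index=i))
    return windows


def select_seed_image(window: UmbrellaWindow, string: TransitionString,
                      priority_axis: int = 0) -> int:
    """Pick the string image whose CVs best match the window center.

    If an image matches every axis within half a window size, the
    full-vector nearest image wins; otherwise the image nearest on the
    priority axis (the slow-relaxing one) wins. Ties go to the lower index.
    """
    cvs = string.cv_array()
    center = window.center
    if window.window_sizes is not None:
        half = window.window_sizes / 2.0
        within = np.all(np.abs(cvs - center) <= half, axis=1)
        if within.any():
            dist = np.linalg.norm(cvs - center, axis=1)
            dist[~within] = np.inf
            return int(np.argmin(dist))
    return int(np.argmin(np.abs(cvs[:, priority_axis] - center[priority_axis])))


# ---------------------------------------------------------------------------
# biased sampling
# ---------------------------------------------------------------------------

def sample_window(
    window: UmbrellaWindow,
    potential: ModelPotential,
    settings: LangevinSettings,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    start: Optional[np.ndarray] = None,
    record_stride: int = 1,
) -> BiasedSeries:
    """Langevin run under potential + window bias; burn-in discarded."""
    return sample_windows([window], potential, settings, discard_fraction,
                          starts=None if start is None else [start],
                          record_stride=record_stride)[0]


def sample_windows(
    windows: Sequence[UmbrellaWindow],
    potential: ModelPotential,
    settings: LangevinSettings,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    starts: Optional[Sequence[np.ndarray]] = None,
    string: Optional[TransitionString] = None,
    priority_axis: int = 0,
    record_stride: int = 1,
) -> List[BiasedSeries]:
    """Sample many windows in lockstep (identical results to one-at-a-time).

    Starting points come from, in order of preference: explicit ``starts``,
    the seed image of ``string`` selected per window, or the window center.
    Every window consumes its own RNG stream derived from (seed, index).
    ``record_stride`` keeps every stride-th step only (the engine records
    every integrator step by default, which oversamples relative to the
    correlation time; a stride near the bias relaxation time makes raw bin
    counts approximate independent counts).
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    windows = list(windows)
    n = len(windows)
    if starts is None:
        starts = []
        for w in windows:
            if string is not None:
                w.seed_image_index = select_seed_image(w, string, priority_axis)
                starts.append(string.images[w.seed_image_index].cv_values.copy())
            else:
                starts.append(w.center.copy())
    starts = np.array([np.asarray(s, dtype=float) for s in starts])
    centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constants for w in windows])
    rngs = [derive_rng(settings.seed, w.index) for w in windows]
    traj = _propagate_batch(starts, potential, settings, rngs, centers, ks,
                            record_stride=record_stride)
    total = traj.shape[0]
    n_discard = int(np.floor(discard_fraction * total))
    out = []
    for j, w in enumerate(windows):
        w.samples_total = total
        w.samples_discarded = n_discard
        out.append(BiasedSeries(w, traj[n_discard:, j, :], seed=settings.seed))
    return out


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def _bin_edges_for(series_list: Sequence[BiasedSeries], bin_size,
                   bounds=None) -> List[np.ndarray]:
    d = series_list[0].series.shape[1]
    sizes = np.atleast_1d(np.asarray(bin_size, dtype=float))
    if len(sizes) == 1 and d > 1:
        sizes = np.repeat(sizes, d)
    edges = []
    for ax in range(d):
        if bounds is not None:
            lo, hi = bounds[ax]
        else:
            data = np.concatenate([s.series[:, ax] for s in series_list])
            lo, hi = data.min(), data.max()
            # align edges to multiples of the bin size for reproducibility
            lo = np.floor(lo / sizes[ax]) * sizes[ax]
            hi = np.ceil(hi / sizes[ax]) * sizes[ax]
            if hi <= lo:
                hi = lo + sizes[ax]
        edges.append(make_edges((lo, hi), sizes[ax]))
    return edges


def _check_connectivity(counts_per_window: np.ndarray) -> None:
    """counts_per_window: (n_windows, n_bins) occupancy. Union-find over
    windows linked through shared occupied bins."""
    n = counts_per_window.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    occupied = counts_per_window > 0
    for b in range(counts_per_window.shape[1]):
        ws = np.flatnonzero(occupied[:, b])
        for w in ws[1:]:
            ra, rb = find(ws[0]), find(w)
            if ra != rb:
                parent[rb] = ra
    roots = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    if len(roots) > 1:
        comps = sorted(roots.values(), key=len, reverse=True)
        raise WhamConnectivityError(
            "window histograms form disconnected components: "
            + "; ".join("{" + ",".join(map(str, c)) + "}" for c in comps))


def wham(
    series_list: Sequence[BiasedSeries],
    bin_size: Union[float, Sequence[float]] = 0.25,
    tolerance: float = 0.001,
    max_iterations: int = 100000,
    temperature: float = DEFAULT_TEMPERATURE,
    bounds: Optional[Sequence[Sequence[float]]] = None,
    min_count: int = 1,
    axis_names: Optional[Sequence[str]] = None,
) -> PMFSurface:
    """Self-consistent WHAM in 1 or 2 dimensions.

    ``tolerance`` applies to the change of the per-window free-energy
    constants f_i between iterations (kcal/mol). Bins with fewer than
    ``min_count`` total samples are masked. The PMF is min-shifted to 0.
    """
    if not series_list:
        raise ValueError("need at least one biased series")
    d = series_list[0].series.shape[1]
    edges = _bin_edges_for(series_list, bin_size, bounds)
    shape = tuple(len(e) - 1 for e in edges)
    n_bins = int(np.prod(shape))
    n_win = len(series_list)

    counts_w = np.zeros((n_win, n_bins))
    for i, s in enumerate(series_list):
        h, _ = np.histogramdd(s.series, bins=edges)
        counts_w[i] = h.ravel()
    _check_connectivity(counts_w)
    counts = counts_w.sum(axis=0)
    N = counts_w.sum(axis=1)

    centers = np.meshgrid(*[0.5 * (e[:-1] + e[1:]) for e in edges], indexing="ij")
    pts = np.stack([c.ravel() for c in centers], axis=-1)   # (n_bins, d)
    beta = 1.0 / kt(temperature)
    bias = np.stack([w_.window.bias_energy(pts) for w_ in series_list])  # (W, B)
    # exp(-beta w) underflows harmlessly to 0 for far-away bins
    with np.errstate(under="ignore"):
        A = np.exp(-beta * bias)

    f = np.zeros(n_win)
    occupied = counts > 0
    for _ in range(max_iterations):
        expf = np.exp(beta * f)
        denom = (N * expf) @ A          # (B,)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(occupied & (denom > 0), counts / denom, 0.0)
        z = A @ p                        # (W,)
        f_new = -np.log(z) / beta
        f_new -= f_new[0]
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tolerance:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iterations} iterations; "
            f"residual {delta:.3e} kcal/mol")

    mask = counts >= max(min_count, 1)
    vals = np.full(n_bins, np.inf)
    with np.errstate(divide="ignore"):
        vals[mask] = -np.log(p[mask]) / beta
    names = tuple(axis_names) if axis_names else tuple(f"cv{i}" for i in range(d))
    surf = PMFSurface(names, tuple(edges), vals.reshape(shape),
                      mask.reshape(shape), temperature=temperature,
                      counts=counts.reshape(shape))
    return surf.min_shift()


def wham_2d(series_list, windows=None, bin_size=0.25, tolerance=0.001, **kw):
    """2D convenience wrapper around :func:`wham`."""
    if series_list and series_list[0].series.shape[1] != 2:
        raise ValueError("wham_2d expects 2D series")
    return wham(series_list, bin_size=bin_size, tolerance=tolerance, **kw)


def block_errors(
    series_list: Sequence[BiasedSeries],
    n_blocks: int = 3,
    bin_size: Union[float, Sequence[float]] = 0.25,
    tolerance: float = 0.001,
    temperature: float = DEFAULT_TEMPERATURE,
    bounds: Optional[Sequence[Sequence[float]]] = None,
    min_count: int = 1,
) -> PMFSurface:
    """Blocked-WHAM uncertainties.

    Every series is split into ``n_blocks`` contiguous equal blocks
    (preserving autocorrelation inside each block), WHAM is re-solved per
    block on a common grid, each block PMF is min-shifted, and the per-bin
    sample standard deviation across blocks is reported. Bins unsampled in
    any block are masked.
    """
    for s in series_list:
        if len(s) < n_blocks:
            raise ValueError(f"window {s.window.index}: series of length "
                             f"{len(s)} cannot form {n_blocks} blocks")
    if bounds is None:
        edges = _bin_edges_for(series_list, bin_size)
        bounds = [(e[0], e[-1]) for e in edges]
    block_pmfs = []
    for b in range(n_blocks):
        blocked = []
        for s in series_list:
            m = len(s) // n_blocks
            blocked.append(BiasedSeries(s.window, s.series[b * m:(b + 1) * m],
                                        seed=s.seed))
        block_pmfs.append(wham(blocked, bin_size=bin_size, tolerance=tolerance,
                               temperature=temperature, bounds=bounds,
                               min_count=min_count))
    mask = np.logical_and.reduce([p.sampled_mask for p in block_pmfs])
    stack = np.stack([p.values for p in block_pmfs])
    err = np.full(mask.shape, np.nan)
    err[mask] = np.std(stack[:, mask], axis=0, ddof=1)
    ref = block_pmfs[0]
    vals = np.where(mask, stack.mean(axis=0), np.inf)
    surf = PMFSurface(ref.axes, ref.edges, vals, mask,
                      block_errors=np.where(mask, err, np.nan),
                      temperature=temperature)
    return surf.min_shift()


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def write_window_table(windows: Sequence[UmbrellaWindow],
                       path: Union[str, Path]) -> None:
    rows = []
    for w in windows:
        row = {"index": w.index, "seed_image": w.seed_image_index,
               "samples_total": w.samples_total,
               "samples_discarded": w.samples_discarded}
        for ax in range(w.ndim):
            row[f"center_{ax}"] = w.center[ax]
            row[f"k_{ax}"] = w.force_constants[ax]
            if w.window_sizes is not None:
                row[f"size_{ax}"] = w.window_sizes[ax]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_window_table(path: Union[str, Path]) -> List[UmbrellaWindow]:
    df = pd.read_csv(path)
    ndim = sum(c.startswith("center_") for c in df.columns)
    windows = []
    for _, row in df.iterrows():
        sizes = None
        if f"size_0" in df.columns:
            sizes = np.array([row[f"size_{ax}"] for ax in range(ndim)])
        w = UmbrellaWindow(
            np.array([row[f"center_{ax}"] for ax in range(ndim)]),
            np.array([row[f"k_{ax}"] for ax in range(ndim)]),
            sizes, index=int(row["index"]))
        if not pd.isna(row.get("seed_image")):
            w.seed_image_index = int(row["seed_image"])
        w.samples_total = int(row.get("samples_total", 0) or 0)
        w.samples_discarded = int(row.get("samples_discarded", 0) or 0)
        windows.append(w)
    return windows


def write_series(series: BiasedSeries, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# window {series.window.index} seed {series.seed}\n")
        for i, row in enumerate(series.series):
            fh.write(str(i) + " " + " ".join(repr(float(v)) for v in row) + "\n")


def read_series(path: Union[str, Path], window: UmbrellaWindow) -> BiasedSeries:
    rows, seed = [], 0
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            toks = line.split()
            if "seed" in toks:
                seed = int(toks[toks.index("seed") + 1])
            continue
        if line.strip():
            rows.append([float(v) for v in line.split()[1:]])
    return BiasedSeries(window, np.array(rows), seed=seed)
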