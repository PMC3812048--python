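"""Binned free-energy surfaces (1D/2D) with mask and block errors.

The container is deliberately dumb: values are kcal/mol per bin,
min-shifted so that the lowest *sampled* bin reads 0; unsampled bins are
masked and never interpolated. Text round-trip is exact (repr precision).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt

__all__ = ["PMFSurface", "make_edges", "integrate_1d"]


def make_edges(bounds: Sequence[float], bin_size: float) -> np.ndarray:
    """Bin edges covering [lo, hi] with uniform bins of ``bin_size``.

    The upper edge is extended so the last bin is complete; bins are
    half-open [edge, edge+d), right-most bin closed.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError(f"invalid bounds {bounds!r}")
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    n = int(np.ceil((hi - lo) / bin_size - 1e-9))
    return lo + bin_size * np.arange(n + 1)


@dataclass
class PMFSurface:
    """A binned PMF over 1 or 2 axes.

    Attributes
    ----------
    axes : names of the axes (length 1 or 2).
    edges : bin edges per axis.
    values : free energy per bin, kcal/mol, min-shifted over sampled bins.
        Unsampled bins hold ``np.inf``.
    sampled_mask : boolean array, True where the bin is trusted.
    block_errors : optional per-bin standard deviation (kcal/mol).
    temperature : K, used for k_BT conversions downstream.
    """

    axes: tuple
    edges: tuple
    values: np.ndarray
    sampled_mask: np.ndarray
    block_errors: Optional[np.ndarray] = None
    temperature: float = DEFAULT_TEMPERATURE
    counts: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.axes = tuple(self.axes)
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        self.values = np.asarray(self.values, dtype=float)
        self.sampled_mask = np.asarray(self.sampled_mask, dtype=bool)
        if len(self.axes) != len(self.edges):
            raise ValueError("axes/edges length mismatch")
        shape = tuple(len(e) - 1 for e in self.edges)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != bins {shape}")
        if self.sampled_mask.shape != shape:
            raise ValueError("mask shape mismatch")
        if self.block_errors is not None:
            self.block_errors = np.asarray(self.block_errors, dtype=float)
            if self.block_errors.shape != shape:
                raise ValueError("block_errors shape mismatch")
            if np.any(self.block_errors[self.sampled_mask] < 0):
                raise ValueError("block errors must be non-negative")

    # -- geometry -----------------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.axes)

    def centers(self, axis: int = 0) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def bin_widths(self, axis: int = 0) -> np.ndarray:
        e = self.edges[axis]
        return np.diff(e)

    # -- values -------------------------------------------------------
    def min_shift(self) -> "PMFSurface":
        """Return a copy shifted so min over sampled bins is exactly 0."""
        vals = self.values.copy()
        if self.sampled_mask.any():
            vals[self.sampled_mask] -= vals[self.sampled_mask].min()
        vals[~self.sampled_mask] = np.inf
        return PMFSurface(self.axes, self.edges, vals, self.sampled_mask,
                          self.block_errors, self.temperature, self.counts)

    def masked_values(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=~self.sampled_mask)

    # -- text I/O -----------------------------------------------------
    def write_text(self, path: Union[str, Path]) -> None:
        path = Path(path)
        lines = [f"# pmfkit PMF ndim={self.ndim} temperature={self.temperature!r}"]
        for name, e in zip(self.axes, self.edges):
            lines.append(f"# axis {name} edges " + " ".join(repr(float(v)) for v in e))
        lines.append("# columns: bin-indices value sampled block_error")
        it = np.ndindex(*self.values.shape)
        for idx in it:
            err = "nan" if self.block_errors is None else repr(float(self.block_errors[idx]))
            lines.append(" ".join(str(i) for i in idx)
                         + f" {float(self.values[idx])!r} {int(self.sampled_mask[idx])} {err}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def read_text(cls, path: Union[str, Path]) -> "PMFSurface":
        path = Path(path)
        axes, edges = [], []
        temperature = DEFAULT_TEMPERATURE
        rows = []
        for line in path.read_text().splitlines():
            if line.startswith("# pmfkit PMF"):
                for tok in line.split():
                    if tok.startswith("temperature="):
                        temperature = float(tok.split("=", 1)[1])
            elif line.startswith("# axis "):
                parts = line.split()
                axes.append(parts[2])
                edges.append(np.array([float(v) for v in parts[4:]]))
            elif line.startswith("#") or not line.strip():
                continue
            else:
                rows.append(line.split())
        ndim = len(axes)
        shape = tuple(len(e) - 1 for e in edges)
        values = np.full(shape, np.inf)
        mask = np.zeros(shape, dtype=bool)
        errs = np.full(shape, np.nan)
        for row in rows:
            idx = tuple(int(v) for v in row[:ndim])
            values[idx] = float(row[ndim])
            mask[idx] = bool(int(row[ndim + 1]))
            errs[idx] = float(row[ndim + 2])
        block = None if np.isnan(errs).all() else errs
        return cls(tuple(axes), tuple(edges), values, mask, block, temperature)


def integrate_1d(pmf2d: PMFSurface, kept_axis: int, strip: Sequence[float]) -> PMFSurface:
    """Strip-integrate a 2D PMF into a 1D profile along ``kept_axis``.

    W1(x) = -k_BT ln sum_{y in strip} exp(-W2(x,y)/k_BT) * dy over sampled
    bins, min-shifted to 0. Columns with no sampled bin inside the strip
    are masked.
    """
    if pmf2d.ndim != 2:
        raise ValueError("integrate_1d expects a 2D PMF")
    if kept_axis not in (0, 1):
        raise ValueError("kept_axis must be 0 or 1")
    other = 1 - kept_axis
    lo, hi = float(strip[0]), float(strip[1])
    if hi <= lo:
        raise ValueError(f"empty strip {strip!r}")
    centers = pmf2d.centers(other)
    in_strip = (centers >= lo) & (centers <= hi)
    if not in_strip.any():
        raise ValueError(f"strip {strip!r} overlaps no bin on axis {pmf2d.axes[other]!r}")
    beta = 1.0 / kt(pmf2d.temperature)
    w = pmf2d.values if kept_axis == 0 else pmf2d.values.T
    m = pmf2d.sampled_mask if kept_axis == 0 else pmf2d.sampled_mask.T
    dy = pmf2d.bin_widths(other)
    w = w[:, in_strip]
    m = m[:, in_strip]
    dy = dy[in_strip]
    with np.errstate(over="ignore"):
        weight = np.where(m, np.exp(-beta * np.where(m, w, 0.0)) * dy, 0.0)
    total = weight.sum(axis=1)
    sampled = m.any(axis=1)
    if not sampled.any():
        raise ValueError("no sampled bins inside the strip")
    vals = np.full(total.shape, np.inf)
    vals[sampled] = -np.log(total[sampled]) / beta
    out = PMFSurface((pmf2d.axes[kept_axis],), (pmf2d.edges[kept_axis],),
                     vals, sampled, temperature=pmf2d.temperature)
    return out.min_shift()
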