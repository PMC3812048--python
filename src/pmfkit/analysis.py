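"""Interpretation of PMF surfaces: basins, barriers, state free energies.

State free-energy differences are Boltzmann-weighted integrals over the
state windows (not point minima), reported in k_BT. Default state windows
put the outward-facing gate near 5.5 A and the inward-facing gate near
10-10.4 A, six WHAM bins wide, and are config-overridable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .pmf import PMFSurface

__all__ = [
    "StateDefinition", "BasinReport", "DEFAULT_STATES", "find_minima",
    "state_delta_g", "barrier_height", "classify_state", "run_cycle_report",
    "LandscapeDisconnectedError",
]


class LandscapeDisconnectedError(RuntimeError):
    pass


@dataclass(frozen=True)
class StateDefinition:
    """A named rectangular region in CV space."""

    name: str
    ranges: Tuple[Tuple[float, float], ...]   # per-axis (lo, hi), Angstrom

    def __post_init__(self):
        object.__setattr__(self, "ranges",
                           tuple((float(a), float(b)) for a, b in self.ranges))
        for lo, hi in self.ranges:
            if hi <= lo:
                raise ValueError(f"state {self.name!r}: empty range ({lo}, {hi})")

    def contains(self, cv_values: Sequence[float]) -> bool:
        v = np.atleast_1d(np.asarray(cv_values, dtype=float))
        return all(lo <= x <= hi for x, (lo, hi) in zip(v, self.ranges))

    def overlaps(self, other: "StateDefinition") -> bool:
        return all(lo1 < hi2 and lo2 < hi1
                   for (lo1, hi1), (lo2, hi2) in zip(self.ranges, other.ranges))


#: Default 1D gate-axis state windows (6 WHAM bins wide).
DEFAULT_STATES = (
    StateDefinition("outward", ((4.75, 6.25),)),
    StateDefinition("inward", ((9.25, 11.25),)),
)


@dataclass
class BasinReport:
    minima: List[Tuple[Tuple[float, ...], float]]       # (location, value kcal/mol)
    barriers: Dict[str, Tuple[float, float]] = field(default_factory=dict)  # k_BT
    delta_g: Dict[str, float] = field(default_factory=dict)                 # k_BT


def find_minima(pmf: PMFSurface, min_separation: float = 0.0,
                ) -> List[Tuple[Tuple[float, ...], float]]:
    """Local minima over sampled bins (8-neighbourhood in 2D), merged
    within ``min_separation`` keeping the deeper one, sorted by depth."""
    if not pmf.sampled_mask.any():
        raise ValueError("PMF is entirely masked")
    vals = np.where(pmf.sampled_mask, pmf.values, np.inf)
    minima = []

    def neighbours(idx, shape):
        deltas = [(-1,), (1,)] if len(shape) == 1 else \
            [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
             if (di, dj) != (0, 0)]
        for d in deltas:
            nb = tuple(i + di for i, di in zip(idx, d))
            if all(0 <= i < s for i, s in zip(nb, shape)):
                if pmf.sampled_mask[nb]:
                    yield vals[nb]

    centers = [pmf.centers(ax) for ax in range(pmf.ndim)]
    for idx in np.ndindex(*vals.shape):
        if not pmf.sampled_mask[idx]:
            continue
        nb = list(neighbours(idx, vals.shape))
        # <= every existing sampled neighbour and < at least one of them
        # (plateaus and isolated bins do not qualify; flat surfaces fall
        # back to the global argmin below)
        if nb and vals[idx] <= min(nb) and vals[idx] < max(nb):
            loc = tuple(float(centers[ax][i]) for ax, i in enumerate(idx))
            minima.append((loc, float(vals[idx])))
    if not minima:  # flat or single-bin surface: take the global argmin
        idx = np.unravel_index(int(np.argmin(vals)), vals.shape)
        loc = tuple(float(centers[ax][i]) for ax, i in enumerate(idx))
        minima.append((loc, float(vals[idx])))
    minima.sort(key=lambda m: m[1])
    if min_separation > 0:
        kept: List[Tuple[Tuple[float, ...], float]] = []
        for loc, val in minima:
            if all(np.linalg.norm(np.array(loc) - np.array(kloc)) >= min_separation
                   for kloc, _ in kept):
                kept.append((loc, val))
        minima = kept
    return minima


def _state_mask_1d(pmf: PMFSurface, state: StateDefinition) -> np.ndarray:
    c = pmf.centers(0)
    lo, hi = state.ranges[0]
    m = (c >= lo) & (c <= hi) & pmf.sampled_mask
    if not m.any():
        raise ValueError(f"state {state.name!r} overlaps no sampled bin")
    return m


def state_delta_g(pmf1d: PMFSurface, state_a: StateDefinition,
                  state_b: StateDefinition,
                  temperature: float = DEFAULT_TEMPERATURE) -> float:
    """G(a) - G(b) in k_BT from Boltzmann-weighted state populations."""
    if pmf1d.ndim != 1:
        raise ValueError("state_delta_g expects a 1D PMF")
    kT = kt(temperature)
    dx = pmf1d.bin_widths(0)
    ma, mb = _state_mask_1d(pmf1d, state_a), _state_mask_1d(pmf1d, state_b)
    za = np.sum(np.exp(-pmf1d.values[ma] / kT) * dx[ma])
    zb = np.sum(np.exp(-pmf1d.values[mb] / kT) * dx[mb])
    return float(-np.log(za / zb))


def barrier_height(pmf1d: PMFSurface, state_a: StateDefinition,
                   state_b: StateDefinition,
                   temperature: float = DEFAULT_TEMPERATURE,
                   ) -> Tuple[float, float]:
    """(forward, reverse) barriers in k_BT: max PMF on the axis segment
    between the two state minima, minus each state's minimum."""
    if pmf1d.ndim != 1:
        raise ValueError("barrier_height expects a 1D PMF")
    kT = kt(temperature)
    vals = np.where(pmf1d.sampled_mask, pmf1d.values, np.inf)
    ma, mb = _state_mask_1d(pmf1d, state_a), _state_mask_1d(pmf1d, state_b)
    ia = int(np.flatnonzero(ma)[np.argmin(vals[ma])])
    ib = int(np.flatnonzero(mb)[np.argmin(vals[mb])])
    lo, hi = min(ia, ib), max(ia, ib)
    segment = vals[lo:hi + 1]
    gap = ~pmf1d.sampled_mask[lo:hi + 1]
    if gap.any():
        raise LandscapeDisconnectedError(
            f"masked bins between states {state_a.name!r} and {state_b.name!r}")
    top = segment.max()
    return (float((top - vals[ia]) / kT), float((top - vals[ib]) / kT))


def classify_state(cv_values: Sequence[float],
                   states: Sequence[StateDefinition] = DEFAULT_STATES) -> str:
    """Name of the unique containing state, else 'intermediate'."""
    states = list(states)
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"state definitions {a.name!r} and {b.name!r} overlap")
    for s in states:
        if s.contains(cv_values):
            return s.name
    return "intermediate"


# ---------------------------------------------------------------------------
# the cycle report
# ---------------------------------------------------------------------------

def run_cycle_report(config: Dict, outdir: Path) -> Dict:
    """Orchestrate per-transition analysis into a deterministic report bundle.

    ``config['transitions']`` maps transition names to dicts with a 2D
    ``pmf`` (PMFSurface or path), a ``strip`` (lo, hi) on axis 1, and
    optional ``states``. Profiles sharing an ``align_state`` are shifted so
    that state reads 0, mirroring side-by-side presentation of transitions
    that overlap at a common state. Numeric tables are CSV; plots are PNG.
    """
    if not config or "transitions" not in config or not config["transitions"]:
        raise ValueError("usage: config must name at least one transition")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    states = [StateDefinition(s["name"], tuple(map(tuple, s["ranges"])))
              for s in config.get("states", [])] or list(DEFAULT_STATES)
    align_name = config.get("align_state")
    summary: Dict = {"transitions": {}}
    profiles = {}
    for name, tcfg in config["transitions"].items():
        pmf2d = tcfg["pmf"]
        if not isinstance(pmf2d, PMFSurface):
            pmf2d = PMFSurface.read_text(pmf2d)
        from .pmf import integrate_1d
        strip = tuple(tcfg["strip"])
        prof = integrate_1d(pmf2d, kept_axis=0, strip=strip)
        profiles[name] = prof
        kT = kt(prof.temperature)
        entry = {"strip": list(strip), "minima": find_minima(prof)}
        for i, a in enumerate(states):
            for b in states[i + 1:]:
                key = f"{a.name}-{b.name}"
                try:
                    entry.setdefault("delta_g_kt", {})[key] = state_delta_g(prof, a, b)
                    fwd, rev = barrier_height(prof, a, b)
                    entry.setdefault("barriers_kt", {})[key] = [fwd, rev]
                except (ValueError, LandscapeDisconnectedError) as exc:
                    entry.setdefault("skipped", {})[key] = str(exc)
        summary["transitions"][name] = entry
        pmf2d.write_text(outdir / f"{name}_pmf2d.txt")
        prof.write_text(outdir / f"{name}_pmf1d.txt")

    # align profiles at the shared state (its Boltzmann-weighted free energy -> 0)
    if align_name:
        align = next(s for s in states if s.name == align_name)
        fig, ax = plt.subplots(figsize=(6, 4))
        rows = []
        for name, prof in profiles.items():
            kT = kt(prof.temperature)
            m = _state_mask_1d(prof, align)
            dx = prof.bin_widths(0)
            g_state = -kT * np.log(np.sum(np.exp(-prof.values[m] / kT) * dx[m]))
            shifted = prof.values - g_state
            c = prof.centers(0)
            ax.plot(c[prof.sampled_mask], shifted[prof.sampled_mask],
                    marker="o", ms=3, label=name)
            for x, v, s in zip(c, shifted, prof.sampled_mask):
                if s:
                    rows.append({"transition": name, "cv": x, "pmf_kcal": v})
        ax.set_xlabel("gate distance (A)")
        ax.set_ylabel("PMF (kcal/mol)")
        ax.legend()
        fig.savefig(outdir / "aligned_profiles.png", dpi=150)
        plt.close(fig)
        pd.DataFrame(rows).to_csv(outdir / "aligned_profiles.csv", index=False,
                                  float_format="%.10g")
        summary["aligned_at"] = align_name

    (outdir / "report.json").write_text(json.dumps(_jsonable(summary), indent=2,
                                                   sort_keys=True))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
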