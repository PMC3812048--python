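"""Deterministic generators for test inputs.

Everything here regenerates byte-identically from (parameters, seed):
toy PDB texts with analytically known COM geometry, exact draws from the
closed-form biased Gaussian distributions of a 1D harmonic potential
(the sampling oracle for WHAM tests), and string histories with known
convergence curves.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._rng import derive_rng
from .constants import DEFAULT_TEMPERATURE, kt
from .umbrella import BiasedSeries, UmbrellaWindow

__all__ = [
    "ToyResidue", "make_toy_pdb", "make_analytic_biased_series",
    "make_string_history",
]


@dataclass(frozen=True)
class ToyResidue:
    """One residue of a synthetic structure layout."""

    chain: str
    resseq: int
    resname: str
    # atoms: (name, element, (x, y, z)) or with occupancy/altloc appended
    atoms: Tuple = ()


def _fmt_atom(serial, name, altloc, resname, chain, resseq, xyz, occ, element):
    # strict PDB v3 ATOM record layout
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"ATOM  {serial:>5d} {name_field}{altloc:1s}{resname:>3s} {chain:1s}"
            f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}  ")


def make_toy_pdb(residues: Sequence[ToyResidue]) -> str:
    """Valid single-model PDB text from a residue layout.

    Atom entries are (name, element, xyz[, occupancy[, altloc]]). Duplicate
    atom serials cannot occur by construction, but duplicate
    (residue, name, altloc) combinations are rejected.
    """
    lines = []
    serial = 0
    seen = set()
    for res in residues:
        for atom in res.atoms:
            name, element, xyz = atom[0], atom[1], atom[2]
            occ = atom[3] if len(atom) > 3 else 1.0
            altloc = atom[4] if len(atom) > 4 else " "
            key = (res.chain, res.resseq, name, altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
            serial += 1
            lines.append(_fmt_atom(serial, name, altloc, res.resname,
                                   res.chain, res.resseq, xyz, occ, element))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_analytic_biased_series(
    k_true: float,
    window_centers: Sequence[float],
    bias_k: float = 5.0,
    n_per_window: int = 5000,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> List[BiasedSeries]:
    """Exact draws from the biased distributions of U(x) = 1/2 k_true x^2.

    Under bias 1/2 k_b (x - c)^2 the stationary density is Gaussian with
    mean k_b c / (k_true + k_b) and variance k_BT / (k_true + k_b); no
    dynamics involved, so these series are a closed-form sampling oracle.
    """
    if k_true <= 0:
        raise ValueError("k_true must be > 0")
    kT = kt(temperature)
    out = []
    for i, c in enumerate(window_centers):
        w = UmbrellaWindow(np.array([float(c)]), np.array([bias_k]), index=i)
        mean = bias_k * c / (k_true + bias_k)
        sd = np.sqrt(kT / (k_true + bias_k))
        rng = derive_rng(seed, i)
        x = mean + sd * rng.standard_normal(n_per_window) if n_per_window else \
            np.empty(0)
        series = BiasedSeries(w, x[:, None] if n_per_window else
                              np.empty((0, 1)), seed=seed)
        if n_per_window == 0:
            series.empty = True  # flagged degenerate fixture
        out.append(series)
    return out


def make_string_history(
    mode: str,
    n_iterations: int = 20,
    n_images: int = 10,
    ndim: int = 2,
    drift_per_iter: float = 0.1,
    freeze_after: int = 8,
    amplitude: float = 0.05,
    seed: int = 0,
) -> List[np.ndarray]:
    """String histories with analytically known convergence curves.

    modes: 'frozen' (metrics identically 0), 'drift-then-freeze' (the lag
    metric drops to 0 exactly lag iterations after the freeze), 'noisy'
    (iid jitter of the given amplitude; the lag metric plateaus near
    amplitude * sqrt(2)).
    """
    base = np.stack([np.linspace(0, 1, n_images)] * ndim, axis=1)
    history = [base.copy()]
    rng = derive_rng(seed)
    for it in range(1, n_iterations + 1):
        if mode == "frozen":
            history.append(base.copy())
        elif mode == "drift-then-freeze":
            shift = drift_per_iter * min(it, freeze_after)
            history.append(base + shift)
        elif mode == "noisy":
            history.append(base + amplitude * rng.standard_normal(base.shape))
        else:
            raise ValueError(f"unknown history mode {mode!r}")
    return history
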