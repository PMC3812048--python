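"""Analytic multi-basin model landscapes and an overdamped Langevin engine.

This module is the stand-in for the sampling engine: a designer-controlled
gate-distance x ion-displacement energy surface built from Gaussian wells
on a confined rectangle, plus Brownian (Euler-Maruyama) dynamics with
optional harmonic biases. Every downstream stage (string method, umbrella
sampling, WHAM) is validated against direct Boltzmann quadrature of these
surfaces, so the ground truth is always known.

Units: kcal/mol for energies, Angstrom for coordinates, Angstrom^2/step
for the diffusion coefficient; the integration step is dimensionless.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from ._rng import derive_rng
from .constants import DEFAULT_TEMPERATURE, kt
from .pmf import PMFSurface, integrate_1d

__all__ = [
    "GaussianWell", "ConfinementWall", "ModelPotential", "HarmonicBias",
    "LangevinSettings", "OutOfDomainError", "LangevinInstabilityError",
    "DegenerateDesignError", "build_cycle_potential", "evaluate",
    "propagate_langevin", "reference_pmf", "potential_to_config",
    "potential_from_config", "save_potential", "load_potential",
    "write_trajectory", "read_trajectory",
]


class OutOfDomainError(ValueError):
    pass


class LangevinInstabilityError(RuntimeError):
    pass


class DegenerateDesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# potential terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianWell:
    """An attractive Gaussian basin: -depth * exp(-sum (x-c)^2 / 2 w^2)."""

    center: Tuple[float, ...]
    depth: float          # kcal/mol, > 0
    widths: Tuple[float, ...]  # Gaussian sigma per axis, Angstrom

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "widths", tuple(float(w) for w in self.widths))
        if self.depth <= 0:
            raise ValueError(f"well depth must be > 0, got {self.depth}")
        if len(self.center) != len(self.widths):
            raise ValueError("center/widths dimension mismatch")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")

    def energy(self, x: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        w = np.asarray(self.widths)
        q = ((x - c) / w) ** 2
        return -self.depth * np.exp(-0.5 * q.sum(axis=-1))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        w = np.asarray(self.widths)
        e = self.energy(x)  # negative inside the well
        return (-e)[..., None] * (x - c) / w ** 2


@dataclass(frozen=True)
class ConfinementWall:
    """Steep polynomial confinement: A * sum_d ((x_d-mid_d)/half_d)^(2p).

    Guarantees the designed surfaces rise by >= amplitude at the domain
    edges so trajectories never need reflecting boundaries.
    """

    mid: Tuple[float, ...]
    half: Tuple[float, ...]
    amplitude: float = 30.0
    exponent: int = 10  # the power 2p; must be even

    def __post_init__(self):
        object.__setattr__(self, "mid", tuple(float(m) for m in self.mid))
        object.__setattr__(self, "half", tuple(float(h) for h in self.half))
        if self.exponent % 2 or self.exponent < 2:
            raise ValueError("exponent must be an even integer >= 2")
        if self.amplitude <= 0 or any(h <= 0 for h in self.half):
            raise ValueError("amplitude and half-extents must be positive")

    def energy(self, x: np.ndarray) -> np.ndarray:
        u = (x - np.asarray(self.mid)) / np.asarray(self.half)
        return self.amplitude * (u ** self.exponent).sum(axis=-1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        u = (x - np.asarray(self.mid)) / np.asarray(self.half)
        return self.amplitude * self.exponent * u ** (self.exponent - 1) / np.asarray(self.half)


@dataclass
class ModelPotential:
    """Baseline + Gaussian basins + ion-coupling wells + confinement wall.

    ``basins`` carry the ion-independent landscape (e.g. the nearly flat
    apo channel); ``couplings`` are extra wells active only near specific
    coordinate values (e.g. a deep outward well when the ion sits at its
    bound position). Both are plain Gaussian terms; the split is semantic
    and preserved through config round-trips.
    """

    domain: np.ndarray            # (2, d): [lo per axis, hi per axis]
    basins: List[GaussianWell] = field(default_factory=list)
    couplings: List[GaussianWell] = field(default_factory=list)
    baseline_offset: float = 0.0
    wall: Optional[ConfinementWall] = None
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.domain = np.asarray(self.domain, dtype=float)
        if self.domain.shape[0] != 2 or self.domain.ndim != 2:
            raise ValueError("domain must be shaped (2, ndim)")
        if np.any(self.domain[1] <= self.domain[0]):
            raise ValueError("domain upper bounds must exceed lower bounds")
        centers = [t.center for t in self.basins + self.couplings]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.allclose(centers[i], centers[j]):
                    raise DegenerateDesignError(
                        f"duplicate basin centers {centers[i]} (terms {i} and {j})")
        for t in self.basins + self.couplings:
            if np.any(np.asarray(t.center) < self.domain[0]) or \
               np.any(np.asarray(t.center) > self.domain[1]):
                raise ValueError(f"basin center {t.center} outside domain")

    @property
    def ndim(self) -> int:
        return self.domain.shape[1]

    @property
    def terms(self) -> List[GaussianWell]:
        return list(self.basins) + list(self.couplings)

    def in_domain(self, point: np.ndarray, tol: float = 1e-9) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.domain[0] - tol) and np.all(p <= self.domain[1] + tol))

    # vectorized over leading axes; no domain check (engine internals)
    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        e = np.full(x.shape[:-1], float(self.baseline_offset))
        for t in self.terms:
            e = e + t.energy(x)
        if self.wall is not None:
            e = e + self.wall.energy(x)
        return e

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for t in self.terms:
            g = g + t.gradient(x)
        if self.wall is not None:
            g = g + self.wall.gradient(x)
        return g


def evaluate(potential: ModelPotential, point: Sequence[float]) -> Tuple[float, np.ndarray]:
    """Energy (kcal/mol) and exact analytic gradient at one in-domain point."""
    p = np.asarray(point, dtype=float)
    if p.shape != (potential.ndim,):
        raise ValueError(f"point must have shape ({potential.ndim},)")
    if not potential.in_domain(p):
        raise OutOfDomainError(f"point {p.tolist()} outside domain "
                               f"{potential.domain.tolist()}")
    return float(potential.energy(p)), potential.gradient(p)


# ---------------------------------------------------------------------------
# biases and dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicBias:
    """Per-axis harmonic restraint: sum_i 1/2 k_i (x_i - c_i)^2; k_i = 0 disables."""

    center: Tuple[float, ...]
    force_constants: Tuple[float, ...]  # kcal/mol/A^2

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        ks = self.force_constants
        if np.isscalar(ks):
            ks = (float(ks),) * len(self.center)
        object.__setattr__(self, "force_constants", tuple(float(k) for k in ks))
        if len(self.center) != len(self.force_constants):
            raise ValueError("center/force_constants dimension mismatch")
        if any(k < 0 for k in self.force_constants):
            raise ValueError("force constants must be >= 0")

    def energy(self, x: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        k = np.asarray(self.force_constants)
        return 0.5 * (k * (x - c) ** 2).sum(axis=-1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        k = np.asarray(self.force_constants)
        return k * (x - c)


@dataclass(frozen=True)
class LangevinSettings:
    """Overdamped Euler-Maruyama parameters.

    x' = x - (D dt / k_BT) grad U + sqrt(2 D dt) xi
    """

    temperature: float = DEFAULT_TEMPERATURE   # K
    diffusion_coefficient: float = 0.0015      # A^2 / step
    timestep: float = 1.0                      # dimensionless step
    n_steps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    def replace(self, **kw) -> "LangevinSettings":
        from dataclasses import replace
        return replace(self, **kw)


_CHUNK = 1024  # noise is drawn per-stream in chunks of this many steps


def _propagate_batch(
    starts: np.ndarray,
    potential: ModelPotential,
    settings: LangevinSettings,
    rngs: Sequence[np.random.Generator],
    bias_centers: Optional[np.ndarray] = None,
    bias_ks: Optional[np.ndarray] = None,
    record_stride: int = 1,
) -> np.ndarray:
    """Propagate n walkers in lockstep; returns (n_recorded, n, d) where
    steps divisible by ``record_stride`` (plus step 0) are recorded.

    Each walker consumes its own RNG stream, so results are identical
    whether walkers run together or one at a time, and independent of
    the recording stride.
    """
    x = np.array(starts, dtype=float)
    n, d = x.shape
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    beta = 1.0 / kt(settings.temperature)
    D = settings.diffusion_coefficient
    dt = settings.timestep
    mob = beta * D * dt
    sigma = np.sqrt(2.0 * D * dt)
    out = np.empty((settings.n_steps // record_stride + 1, n, d))
    out[0] = x
    step = 0
    while step < settings.n_steps:
        m = min(_CHUNK, settings.n_steps - step)
        if sigma > 0:
            noise = np.stack([rng.standard_normal((m, d)) for rng in rngs], axis=1)
        else:
            noise = np.zeros((m, n, d))
        # divergence shows up as non-finite coordinates and is reported
        # below; suppress the intermediate overflow warnings
        with np.errstate(over="ignore", invalid="ignore"):
            for j in range(m):
                force = -potential.gradient(x)
                if bias_ks is not None:
                    force = force - bias_ks * (x - bias_centers)
                x = x + mob * force + sigma * noise[j]
                step += 1
                if step % record_stride == 0:
                    out[step // record_stride] = x
        if not np.isfinite(x).all():
            bad = np.argwhere(~np.isfinite(x).all(axis=1)).ravel()
            raise LangevinInstabilityError(
                f"non-finite coordinates at step {step} for walkers {bad.tolist()}; "
                f"reduce timestep or diffusion coefficient")
    return out


def propagate_langevin(
    start: Sequence[float],
    potential: ModelPotential,
    settings: LangevinSettings,
    bias: Optional[HarmonicBias] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Single overdamped trajectory of shape (n_steps+1, ndim)."""
    p = np.asarray(start, dtype=float)
    if not potential.in_domain(p):
        raise OutOfDomainError(f"start {p.tolist()} outside domain")
    if rng is None:
        rng = derive_rng(settings.seed)
    centers = ks = None
    if bias is not None:
        centers = np.asarray(bias.center)[None, :]
        ks = np.asarray(bias.force_constants)[None, :]
    traj = _propagate_batch(p[None, :], potential, settings, [rng], centers, ks)
    return traj[:, 0, :]


# ---------------------------------------------------------------------------
# reference PMF by direct Boltzmann quadrature (the recovery oracle)
# ---------------------------------------------------------------------------

def reference_pmf(
    potential: ModelPotential,
    edges: Sequence[np.ndarray],
    strip: Optional[Tuple[int, float, float]] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    n_quad: int = 6,
) -> PMFSurface:
    """PMF by midpoint quadrature of exp(-U/k_BT) inside every bin.

    Per bin b: W(b) = -k_BT ln <exp(-U/k_BT)>_b, min-shifted to 0; this is
    the same density-per-bin convention a histogram estimator targets.
    ``strip=(axis, lo, hi)`` integrates out that axis over [lo, hi] and
    returns the 1D profile on the other axis.
    """
    edges = [np.asarray(e, dtype=float) for e in edges]
    if len(edges) != potential.ndim:
        raise ValueError(f"need {potential.ndim} edge arrays, got {len(edges)}")
    if any(len(e) < 2 for e in edges):
        raise ValueError("empty grid: each axis needs at least one bin")
    beta = 1.0 / kt(temperature)
    axes_names = tuple(f"cv{i}" for i in range(potential.ndim))

    def quad_points(e):
        # midpoint rule with n_quad points per bin
        offs = (np.arange(n_quad) + 0.5) / n_quad
        return (e[:-1, None] + np.diff(e)[:, None] * offs[None, :]).ravel()

    if potential.ndim == 1:
        pts = quad_points(edges[0])[:, None]
        w = np.exp(-beta * potential.energy(pts)).reshape(-1, n_quad).mean(axis=1)
        vals = -np.log(w) / beta
        surf = PMFSurface(axes_names, tuple(edges), vals,
                          np.ones_like(vals, dtype=bool), temperature=temperature)
        return surf.min_shift()

    gx = quad_points(edges[0])
    gy = quad_points(edges[1])
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    pts = np.stack([X, Y], axis=-1)
    boltz = np.exp(-beta * potential.energy(pts))
    nb0, nb1 = len(edges[0]) - 1, len(edges[1]) - 1
    boltz = boltz.reshape(nb0, n_quad, nb1, n_quad).mean(axis=(1, 3))
    vals = -np.log(boltz) / beta
    surf = PMFSurface(axes_names, tuple(edges), vals,
                      np.ones_like(vals, dtype=bool), temperature=temperature)
    surf = surf.min_shift()
    if strip is None:
        return surf
    axis, lo, hi = strip
    return integrate_1d(surf, kept_axis=1 - axis, strip=(lo, hi))


# ---------------------------------------------------------------------------
# designed landscapes
# ---------------------------------------------------------------------------

def _cycle_domain():
    return np.array([[4.0, -6.5], [12.0, 1.5]])


def _apo_basins():
    # nearly flat released channel: two shallow basins joined by a trough,
    # barriers of a few k_BT between outward (g~5.5) and inward (g~10)
    return [
        GaussianWell((5.5, -5.0), 3.2, (0.7, 0.7)),
        GaussianWell((10.0, -5.0), 3.4, (0.7, 0.7)),
        GaussianWell((7.75, -5.0), 1.8, (1.4, 0.7)),
    ]


def _ion_couplings():
    # wells active only when the ion coordinate sits near its bound value
    # (z ~ 0): deep outward-bound, shallow inward-bound, metastable
    # intermediate site ~3 kcal/mol (~5 k_BT) above the main well; widths
    # keep the steepest slope near the umbrella force constant so windows
    # with the default 5 kcal/mol/A^2 bias stay well-behaved
    return [
        GaussianWell((5.5, 0.0), 8.0, (0.6, 0.9)),
        GaussianWell((10.0, 0.0), 1.2, (0.6, 0.9)),
        GaussianWell((5.5, -3.0), 5.0, (0.6, 0.9)),
    ]


_DESIGNS = {}


def _register(name):
    def deco(fn):
        _DESIGNS[name] = fn
        return fn
    return deco


@_register("cycle")
def _design_cycle() -> ModelPotential:
    dom = _cycle_domain()
    wall = ConfinementWall(mid=tuple(dom.mean(axis=0)),
                           half=tuple((dom[1] - dom[0]) / 2))
    return ModelPotential(dom, basins=_apo_basins(), couplings=_ion_couplings(),
                          wall=wall,
                          meta={"design": "cycle",
                                "outward_center": [5.5, 0.0],
                                "inward_center": [10.0, -5.0],
                                "intermediate_center": [5.5, -3.0],
                                "bound_z": 0.0, "released_z": -5.0})


@_register("apo-flat")
def _design_apo() -> ModelPotential:
    dom = _cycle_domain()
    wall = ConfinementWall(mid=tuple(dom.mean(axis=0)),
                           half=tuple((dom[1] - dom[0]) / 2))
    return ModelPotential(dom, basins=_apo_basins(), couplings=[], wall=wall,
                          meta={"design": "apo-flat", "released_z": -5.0})


def _isolated_well_strip_integral(well: GaussianWell, strip_g, strip_z,
                                  temperature=DEFAULT_TEMPERATURE, n=400) -> float:
    """integral of exp(-U/k_BT) of a single well over a rectangle."""
    beta = 1.0 / kt(temperature)
    g = np.linspace(strip_g[0], strip_g[1], n)
    z = np.linspace(strip_z[0], strip_z[1], n)
    G, Z = np.meshgrid(g, z, indexing="ij")
    u = well.energy(np.stack([G, Z], axis=-1))
    return float(np.trapezoid(np.trapezoid(np.exp(-beta * u), z, axis=1), g))


@_register("ion-bound")
def _design_ion_bound() -> ModelPotential:
    pot = _design_cycle()
    # designed outward-vs-inward free-energy gap at bound z: predicted from
    # the two isolated coupling wells alone, so the full-surface quadrature
    # checks that walls/neighbouring wells do not distort the design
    out_w, in_w = pot.couplings[0], pot.couplings[1]
    strips = {"outward_strip_g": (5.0, 6.0), "inward_strip_g": (9.5, 10.5),
              "bound_strip_z": (-0.5, 0.5), "released_strip_z": (-5.5, -4.5)}
    i_out = _isolated_well_strip_integral(out_w, strips["outward_strip_g"],
                                          strips["bound_strip_z"])
    i_in = _isolated_well_strip_integral(in_w, strips["inward_strip_g"],
                                         strips["bound_strip_z"])
    dg = float(-kt() * np.log(i_out / i_in))
    pot.meta.update({"design": "ion-bound",
                     "designed_delta_g_kcal": dg, **{k: list(v) for k, v in strips.items()}})
    return pot


@_register("three-well")
def _design_three_well() -> ModelPotential:
    # benchmark for the string method: two end basins joined through an
    # off-axis intermediate, so the MFEP bows away from the straight line
    dom = np.array([[-2.5, -1.5], [2.5, 2.5]])
    wall = ConfinementWall(mid=tuple(dom.mean(axis=0)),
                           half=tuple((dom[1] - dom[0]) / 2), amplitude=25.0)
    basins = [
        GaussianWell((-1.0, 0.0), 5.0, (0.45, 0.45)),
        GaussianWell((1.0, 0.0), 5.0, (0.45, 0.45)),
        GaussianWell((0.0, 1.2), 3.5, (0.5, 0.5)),
    ]
    return ModelPotential(dom, basins=basins, wall=wall,
                          meta={"design": "three-well",
                                "endpoints": [[-1.0, 0.0], [1.0, 0.0]]})


def build_cycle_potential(design: Union[str, Dict, None] = "cycle") -> ModelPotential:
    """Build a designed landscape.

    ``design`` is either a registered name ('cycle', 'apo-flat',
    'ion-bound', 'three-well') or a config dict (see
    :func:`potential_from_config`).
    """
    if design is None:
        design = "cycle"
    if isinstance(design, str):
        try:
            return _DESIGNS[design]()
        except KeyError:
            raise ValueError(f"unknown design {design!r}; "
                             f"known: {sorted(_DESIGNS)}") from None
    return potential_from_config(design)


# ---------------------------------------------------------------------------
# config / trajectory I/O
# ---------------------------------------------------------------------------

def potential_to_config(potential: ModelPotential) -> Dict:
    def well(t):
        return {"center": list(t.center), "depth": t.depth, "widths": list(t.widths)}
    cfg = {
        "domain": {"lo": potential.domain[0].tolist(),
                   "hi": potential.domain[1].tolist()},
        "baseline": potential.baseline_offset,
        "basins": [well(t) for t in potential.basins],
        "coupling": [well(t) for t in potential.couplings],
    }
    if potential.wall is not None:
        cfg["wall"] = {"mid": list(potential.wall.mid),
                       "half": list(potential.wall.half),
                       "amplitude": potential.wall.amplitude,
                       "exponent": potential.wall.exponent}
    if potential.meta:
        cfg["meta"] = dict(potential.meta)
    return cfg


def potential_from_config(cfg: Dict) -> ModelPotential:
    dom = np.array([cfg["domain"]["lo"], cfg["domain"]["hi"]], dtype=float)

    def well(d):
        return GaussianWell(tuple(d["center"]), float(d["depth"]), tuple(d["widths"]))
    wall = None
    if "wall" in cfg:
        w = cfg["wall"]
        wall = ConfinementWall(tuple(w["mid"]), tuple(w["half"]),
                               float(w.get("amplitude", 30.0)),
                               int(w.get("exponent", 10)))
    return ModelPotential(dom,
                          basins=[well(d) for d in cfg.get("basins", [])],
                          couplings=[well(d) for d in cfg.get("coupling", [])],
                          baseline_offset=float(cfg.get("baseline", 0.0)),
                          wall=wall, meta=dict(cfg.get("meta", {})))


def save_potential(potential: ModelPotential, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(potential_to_config(potential), sort_keys=False))


def load_potential(path: Union[str, Path]) -> ModelPotential:
    return potential_from_config(yaml.safe_load(Path(path).read_text()))


def write_trajectory(traj: np.ndarray, path: Union[str, Path]) -> None:
    """Plain columnar text (step, coord...) with full float precision.

    A ``.npy`` suffix selects the binary container instead; both
    round-trip losslessly.
    """
    traj = np.asarray(traj, dtype=float)
    if str(path).endswith(".npy"):
        np.save(str(path), traj)
        return
    with open(path, "w") as fh:
        fh.write("# step " + " ".join(f"coord{i+1}" for i in range(traj.shape[1])) + "\n")
        for i, row in enumerate(traj):
            fh.write(str(i) + " " + " ".join(repr(float(v)) for v in row) + "\n")


def read_trajectory(path: Union[str, Path]) -> np.ndarray:
    if str(path).endswith(".npy"):
        return np.load(str(path))
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        rows.append([float(v) for v in line.split()[1:]])
    return np.array(rows)
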