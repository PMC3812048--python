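"""Minimum free energy paths by the string method with swarms of trajectories.

An initial transition path is produced by RMSD-steered dynamics toward a
target point in CV space, subsampled into a chain of images, and then
relaxed iteratively: each iteration launches a swarm of short unbiased
trajectories from every interior image, moves the image by the mean drift,
re-relaxes it under a strong harmonic restraint, and re-parametrizes the
chain to equal arc-length spacing. Convergence is tracked by the mean RMSD
each image has moved from iteration 0 and from the same image a fixed lag
earlier.

All distances here are CV-space RMSDs: sqrt(mean over CV components of
squared differences), unweighted.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from ._rng import derive_rng
from .landscape import (HarmonicBias, LangevinSettings, ModelPotential,
                        OutOfDomainError, _propagate_batch)

__all__ = [
    "PathImage", "TransitionString", "SwarmSettings", "SteeringError",
    "SteerResult",
    "cv_rmsd", "steer_path", "subsample_to_images", "swarm_drift",
    "relax_to_cv", "reparametrize", "reparametrize_cvs", "iterate_string",
    "convergence_metrics", "ConvergenceMetrics", "zero_temperature_string",
    "distance_to_path", "tail_averaged_cvs", "write_string_checkpoint",
    "read_string_checkpoint",
]


class SteeringError(RuntimeError):
    pass


@dataclass
class SteerResult:
    trajectory: np.ndarray                 # (n+1, d) steering trajectory
    string: Optional["TransitionString"]   # None if already at the target
    schedule: np.ndarray                   # RMSD target ramp, one per frame


def cv_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class PathImage:
    index: int
    cv_values: np.ndarray
    full_state: np.ndarray = None  # engine state; equals cv for the toy engine

    def __post_init__(self):
        self.cv_values = np.asarray(self.cv_values, dtype=float)
        if not np.isfinite(self.cv_values).all():
            raise ValueError(f"image {self.index}: non-finite cv values")
        if self.full_state is None:
            self.full_state = self.cv_values.copy()
        else:
            self.full_state = np.asarray(self.full_state, dtype=float)


@dataclass
class TransitionString:
    images: List[PathImage]
    endpoints_fixed: bool = True
    iteration: int = 0
    history: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if len(self.images) < 3:
            raise ValueError(f"a string needs >= 3 images, got {len(self.images)}")
        idx = [im.index for im in self.images]
        if idx != sorted(set(idx)):
            raise ValueError("image indices must be unique and ordered")
        if not self.history:
            self.history = [self.cv_array()]

    def __len__(self) -> int:
        return len(self.images)

    def cv_array(self) -> np.ndarray:
        return np.array([im.cv_values for im in self.images])

    def with_cvs(self, cvs: np.ndarray, iteration: Optional[int] = None) -> "TransitionString":
        images = [PathImage(im.index, cv.copy(), cv.copy())
                  for im, cv in zip(self.images, cvs)]
        return TransitionString(images, self.endpoints_fixed,
                                self.iteration if iteration is None else iteration,
                                history=[h.copy() for h in self.history])


@dataclass(frozen=True)
class SwarmSettings:
    n_trajectories: int = 100
    swarm_steps: int = 50            # maps the short swarm-burst length
    relax_steps: int = 1250          # maps the constrained relaxation length
    relax_force_constant: float = 40.0  # kcal/mol/A^2

    def __post_init__(self):
        if min(self.n_trajectories, self.swarm_steps, self.relax_steps) < 1:
            raise ValueError("all counts must be >= 1")
        if self.relax_force_constant <= 0:
            raise ValueError("relax force constant must be > 0")


# ---------------------------------------------------------------------------
# steered initialization
# ---------------------------------------------------------------------------

def steer_path(
    start: Sequence[float],
    target_cv: Sequence[float],
    potential: ModelPotential,
    settings: LangevinSettings,
    speed: float = 0.00005,        # A/step decrease of the RMSD target
    stop_rmsd: float = 0.02,
    force_constant: float = 40.0,
    max_steps: Optional[int] = None,
    max_adjacent_rmsd: float = 0.2,
) -> SteerResult:
    """Drag the system toward ``target_cv`` with a moving flat-bottom RMSD restraint.

    The restraint is harmonic in (RMSD - s(t)) and one-sided (flat below the
    ramp); s(t) decreases from the initial RMSD at ``speed`` per step.
    Returns the steering trajectory, an initial string subsampled to
    ``max_adjacent_rmsd`` spacing (None if the start was already within
    ``stop_rmsd``) and the ramp schedule.
    """
    if speed <= 0 or stop_rmsd <= 0:
        raise ValueError("speed and stop_rmsd must be positive")
    x = np.asarray(start, dtype=float).copy()
    target = np.asarray(target_cv, dtype=float)
    if not potential.in_domain(x) or not potential.in_domain(target):
        raise OutOfDomainError("start/target outside domain")
    d = x.size
    rng = derive_rng(settings.seed)
    from .constants import kt
    beta = 1.0 / kt(settings.temperature)
    D, dt = settings.diffusion_coefficient, settings.timestep
    mob, sigma = beta * D * dt, np.sqrt(2.0 * D * dt)

    r0 = cv_rmsd(x, target)
    traj = [x.copy()]
    schedule = [r0]
    if r0 <= stop_rmsd:
        return SteerResult(np.array(traj), None, np.array(schedule))
    if max_steps is None:
        max_steps = int(np.ceil(r0 / speed)) + 200_000
    for step in range(1, max_steps + 1):
        s = max(r0 - speed * step, 0.0)
        r = cv_rmsd(x, target)
        force = -potential.gradient(x)
        if r > s and r > 0:
            grad_r = (x - target) / (d * r)
            force = force - force_constant * (r - s) * grad_r
        x = x + mob * force + sigma * rng.standard_normal(d)
        if not np.isfinite(x).all():
            raise SteeringError(f"non-finite coordinates at step {step}")
        traj.append(x.copy())
        schedule.append(s)
        if cv_rmsd(x, target) <= stop_rmsd:
            break
    else:
        raise SteeringError(
            f"steering did not reach stop_rmsd={stop_rmsd} in {max_steps} steps; "
            f"final RMSD {cv_rmsd(x, target):.4f}")
    traj = np.array(traj)
    string = subsample_to_images(traj, max_adjacent_rmsd)
    return SteerResult(traj, string, np.array(schedule))


def subsample_to_images(trajectory: np.ndarray,
                        max_adjacent_rmsd: float = 0.2) -> TransitionString:
    """Pick frames at (approximately) equal CV arc length including endpoints.

    Guarantees mean adjacent-image CV RMSD < ``max_adjacent_rmsd``.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or len(traj) < 2:
        raise ValueError("trajectory must hold at least 2 frames")
    d = traj.shape[1]
    seg = np.sqrt(np.mean(np.diff(traj, axis=0) ** 2, axis=1))  # rmsd metric
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        raise ValueError("trajectory has zero total arc length")
    n_img = max(int(np.floor(total / max_adjacent_rmsd)) + 2, 3)
    while True:
        targets = np.linspace(0.0, total, n_img)
        pick = np.searchsorted(arc, targets)
        pick = np.clip(pick, 0, len(traj) - 1)
        # snap to nearer neighbour in arc length
        left = np.clip(pick - 1, 0, len(traj) - 1)
        use_left = np.abs(arc[left] - targets) < np.abs(arc[pick] - targets)
        pick = np.where(use_left, left, pick)
        pick[0], pick[-1] = 0, len(traj) - 1
        pick = np.array(sorted(set(pick.tolist())))
        cvs = traj[pick]
        mean_adj = float(np.mean(np.sqrt(np.mean(np.diff(cvs, axis=0) ** 2, axis=1))))
        if mean_adj < max_adjacent_rmsd or n_img > 10 * len(traj):
            break
        n_img += 1
    images = [PathImage(i, cv) for i, cv in enumerate(cvs)]
    return TransitionString(images)


# ---------------------------------------------------------------------------
# swarm iteration building blocks
# ---------------------------------------------------------------------------

def swarm_drift(
    image: PathImage,
    potential: ModelPotential,
    swarm_settings: SwarmSettings,
    langevin_settings: LangevinSettings,
    seed: int,
    iteration: int = 0,
) -> np.ndarray:
    """Mean displacement in CV space over a swarm of short unbiased runs."""
    n = swarm_settings.n_trajectories
    starts = np.tile(image.full_state, (n, 1))
    rngs = [derive_rng(seed, iteration, image.index, k) for k in range(n)]
    settings = langevin_settings.replace(n_steps=swarm_settings.swarm_steps)
    traj = _propagate_batch(starts, potential, settings, rngs)
    return np.asarray(traj[-1] - traj[0]).mean(axis=0)


def relax_to_cv(
    state: np.ndarray,
    target_cv: np.ndarray,
    potential: ModelPotential,
    relax_steps: int,
    relax_force_constant: float,
    langevin_settings: LangevinSettings,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Evolve the state under a strong harmonic restraint to the target CVs."""
    if relax_force_constant <= 0:
        raise ValueError("relax force constant must be > 0")
    if rng is None:
        rng = derive_rng(langevin_settings.seed)
    settings = langevin_settings.replace(n_steps=relax_steps)
    centers = np.asarray(target_cv, dtype=float)[None, :]
    ks = np.full_like(centers, relax_force_constant)
    traj = _propagate_batch(np.asarray(state, dtype=float)[None, :], potential,
                            settings, [rng], centers, ks)
    return traj[-1, 0]


def reparametrize_cvs(cvs: np.ndarray, tol: float = 1e-13,
                      max_rounds: int = 200) -> np.ndarray:
    """Equal spacing along the piecewise-linear interpolant of the images.

    Points are placed on the input polyline so that adjacent-image
    Euclidean distances come out equal (fixed-point iteration on the
    arc-length positions, since equal arc length alone leaves chord
    lengths unequal across corners). Endpoints are preserved exactly;
    duplicate consecutive points are collapsed; zero total arc length is
    rejected. Idempotent to machine precision for non-degenerate paths;
    on exactly self-folding (hairpin) paths, where an equal-chord solution
    may not exist, the equal-arc-length placement is returned instead.
    """
    cvs = np.asarray(cvs, dtype=float)
    if len(cvs) < 3:
        raise ValueError("need >= 3 images to reparametrize")
    keep = np.concatenate([[True], np.linalg.norm(np.diff(cvs, axis=0), axis=1) > 0])
    path = cvs[keep]
    if len(path) < 2:
        raise ValueError("total arc length is zero")
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = len(cvs)

    def place(targets):
        out = np.empty((n, cvs.shape[1]))
        for k in range(cvs.shape[1]):
            out[:, k] = np.interp(targets, arc, path[:, k])
        out[0], out[-1] = cvs[0], cvs[-1]
        return out

    def spacing_cv(points):
        chord = np.linalg.norm(np.diff(points, axis=0), axis=1)
        return (chord.max() - chord.min()) / max(chord.mean(), 1e-300)

    # already uniform within the spacing contract: the input is its own
    # equal-chord solution, so return it unchanged (exact idempotence)
    if len(path) == len(cvs) and spacing_cv(cvs) <= 1e-9:
        return cvs.copy()

    targets = np.linspace(0.0, arc[-1], n)
    out = place(targets)

    def damped_rounds(targets, out, rounds):
        for _ in range(rounds):
            chord = np.linalg.norm(np.diff(out, axis=0), axis=1)
            if (chord.max() - chord.min()) <= tol * max(chord.mean(), 1e-300):
                return targets, out, True
            cum = np.concatenate([[0.0], np.cumsum(chord)])
            # damped re-pick of arc positions toward uniform cumulative chords
            proposal = np.interp(np.linspace(0.0, cum[-1], n), cum, targets)
            targets = np.maximum.accumulate(targets + 0.5 * (proposal - targets))
            out = place(targets)
        return targets, out, False

    targets, out, done = damped_rounds(targets, out, max_rounds)
    if done:
        return out
    # sharp-corner geometries converge slowly by iteration: try an exact
    # bisection on the common chord length first, then a long damped run
    exact = _equal_chord_walk_solve(path, n)
    if exact is not None:
        exact[0], exact[-1] = cvs[0], cvs[-1]
        return exact
    _, out, _ = damped_rounds(targets, out, 100 * max_rounds)
    return out


def _walk_equal_chords(path: np.ndarray, n_chords: int, L: float):
    """Place points a Euclidean distance L apart walking along the polyline.

    Uses the exact quadratic first-crossing within each segment; returns
    (points, final_arc_fraction_reached)."""
    pts = [path[0]]
    seg_i = 0
    pos = path[0].copy()
    seg_start = path[0]
    t0 = 0.0  # fraction already consumed of current segment
    for _ in range(n_chords):
        placed = False
        while seg_i < len(path) - 1:
            a = path[seg_i] + t0 * (path[seg_i + 1] - path[seg_i])
            d = path[seg_i + 1] - a
            # first t in (0, 1] with |a + t d - pos| = L
            w = a - pos
            A = d @ d
            B = 2.0 * (w @ d)
            C = w @ w - L * L
            if A > 0:
                disc = B * B - 4 * A * C
                if disc >= 0:
                    sq = np.sqrt(disc)
                    for root in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
                        if 1e-16 < root <= 1.0 + 1e-12:
                            t_hit = min(root, 1.0)
                            pos = a + t_hit * d
                            t0 = t0 + t_hit * (1.0 - t0)
                            if t0 >= 1.0 - 1e-15:
                                seg_i += 1
                                t0 = 0.0
                            pts.append(pos.copy())
                            placed = True
                            break
                if placed:
                    break
            seg_i += 1
            t0 = 0.0
        if not placed:   # ran out of polyline before reaching distance L
            pts.append(path[-1].copy())
    return np.array(pts)


def _equal_chord_walk_solve(path: np.ndarray, n: int,
                            iters: int = 200) -> Optional[np.ndarray]:
    """Bisection on the common chord length so the walk ends at the endpoint.

    The first-hitting arc position is monotone in L, so bisection is exact
    up to float resolution. Returns None if no bracketing works (fully
    degenerate path)."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    total = seg.sum()
    lo, hi = 0.0, total
    end = path[-1]
    for _ in range(iters):
        L = 0.5 * (lo + hi)
        pts = _walk_equal_chords(path, n - 1, L)
        # compare walked end against the true endpoint along the path:
        # overshoot if the last chord could not be completed
        if np.linalg.norm(pts[-1] - pts[-2]) < L * (1 - 1e-12):
            hi = L
        else:
            gap = np.linalg.norm(pts[-1] - end)
            if gap <= max(1e-13 * max(total, 1.0), 1e-300):
                return pts
            lo = L
        if hi - lo <= 1e-16 * max(total, 1.0):
            break
    pts = _walk_equal_chords(path, n - 1, 0.5 * (lo + hi))
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    nontrivial = chord.mean() > 1e-9 * total   # L -> 0 collapse on loops
    uniform = nontrivial and (chord.max() - chord.min()) / chord.mean() < 1e-9
    reaches_end = np.linalg.norm(pts[-1] - end) <= 1e-9 * max(total, 1.0)
    return pts if (uniform and reaches_end) else None


def reparametrize(string: TransitionString) -> TransitionString:
    return string.with_cvs(reparametrize_cvs(string.cv_array()))


def iterate_string(
    string: TransitionString,
    potential: ModelPotential,
    swarm_settings: SwarmSettings,
    langevin_settings: LangevinSettings,
    n_iterations: int,
    seed: int,
) -> TransitionString:
    """Run the 4-step swarm iteration: swarms, image drift, constrained
    relaxation, re-parametrization. Endpoint images are never touched when
    ``endpoints_fixed``. History grows by one CV snapshot per iteration.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    current = string.with_cvs(string.cv_array())
    n_img = len(current)
    interior = list(range(1, n_img - 1)) if current.endpoints_fixed \
        else list(range(n_img))
    n_traj = swarm_settings.n_trajectories
    swarm_ls = langevin_settings.replace(n_steps=swarm_settings.swarm_steps)
    relax_ls = langevin_settings.replace(n_steps=swarm_settings.relax_steps)

    cvs = current.cv_array()
    for it in range(current.iteration, current.iteration + n_iterations):
        # 1) swarms of unbiased trajectories from every interior image
        starts = np.repeat(cvs[interior], n_traj, axis=0)
        rngs = [derive_rng(seed, it, current.images[i].index, k)
                for i in interior for k in range(n_traj)]
        traj = _propagate_batch(starts, potential, swarm_ls, rngs)
        disp = (traj[-1] - traj[0]).reshape(len(interior), n_traj, -1)
        # 2) evolve images by the mean drift
        drift = disp.mean(axis=1)
        moved = cvs[interior] + drift
        # 3) constrained relaxation toward the drifted CV targets
        relax_rngs = [derive_rng(seed, it, current.images[i].index, n_traj)
                      for i in interior]
        ks = np.full_like(moved, swarm_settings.relax_force_constant)
        rtraj = _propagate_batch(cvs[interior], potential, relax_ls,
                                 relax_rngs, moved, ks)
        cvs = cvs.copy()
        cvs[interior] = rtraj[-1]
        # 4) re-parametrize to equal arc-length spacing
        cvs = reparametrize_cvs(cvs)
        current.history.append(cvs.copy())
    out = current.with_cvs(cvs, iteration=current.iteration + n_iterations)
    out.history = current.history
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceMetrics:
    rmsd_to_initial: np.ndarray          # per iteration, mean over images
    rmsd_to_lag: np.ndarray              # NaN where the lag is undefined
    lag: int
    plateau: bool
    tail_slopes: Tuple[float, float]     # (initial-series, lag-series) A/iter


def convergence_metrics(
    history: Sequence[np.ndarray],
    lag: int = 4,
    plateau_tail: int = 5,
    plateau_slope_tol: float = 1e-3,
) -> ConvergenceMetrics:
    """Per-iteration mean image RMSD to iteration 0 and to ``lag`` before.

    The plateau flag is an explicit stand-in for the visual judgment: the
    absolute slope of a linear fit over the last ``plateau_tail`` points of
    both series must fall below ``plateau_slope_tol``.
    """
    if len(history) < 1:
        raise ValueError("history must hold at least one snapshot")
    hist = [np.asarray(h, dtype=float) for h in history]
    n = len(hist)

    def mean_image_rmsd(a, b):
        return float(np.mean(np.sqrt(np.mean((a - b) ** 2, axis=1))))

    to_init = np.array([mean_image_rmsd(hist[i], hist[0]) for i in range(n)])
    to_lag = np.full(n, np.nan)
    for i in range(lag, n):
        to_lag[i] = mean_image_rmsd(hist[i], hist[i - lag])

    def tail_slope(series):
        s = series[~np.isnan(series)]
        if len(s) < plateau_tail:
            return np.nan
        y = s[-plateau_tail:]
        t = np.arange(len(y))
        return float(np.polyfit(t, y, 1)[0])

    s0, s1 = tail_slope(to_init), tail_slope(to_lag)
    plateau = (np.isfinite(s0) and np.isfinite(s1)
               and abs(s0) < plateau_slope_tol and abs(s1) < plateau_slope_tol)
    return ConvergenceMetrics(to_init, to_lag, lag, bool(plateau), (s0, s1))


def tail_averaged_cvs(history: Sequence[np.ndarray], n_tail: int) -> np.ndarray:
    """Average image CVs over the last ``n_tail`` snapshots (noise reduction)."""
    if n_tail < 1 or n_tail > len(history):
        raise ValueError("n_tail out of range")
    return np.mean([np.asarray(h) for h in history[-n_tail:]], axis=0)


# ---------------------------------------------------------------------------
# steepest-descent (zero-temperature) path — the MFEP oracle
# ---------------------------------------------------------------------------

def zero_temperature_string(
    potential: ModelPotential,
    a: Sequence[float],
    b: Sequence[float],
    n_images: int = 201,
    step: float = 2e-3,
    max_iters: int = 40000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Dense steepest-descent string between fixed endpoints.

    Independent of the swarm iteration: interior points follow the bare
    negative gradient with repeated equal-arc-length respacing until the
    largest per-iteration move falls below ``tol``.
    """
    path = np.linspace(np.asarray(a, float), np.asarray(b, float), n_images)
    for _ in range(max_iters):
        prev = path.copy()
        path[1:-1] -= step * potential.gradient(path[1:-1])
        path = reparametrize_cvs(path)
        if np.abs(path - prev).max() < tol:
            break
    return path


def distance_to_path(points: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Per-point minimum Euclidean distance to a piecewise-linear path."""
    pts = np.atleast_2d(np.asarray(points, float))
    p0 = path[:-1]
    dv = path[1:] - p0
    L2 = (dv ** 2).sum(axis=1)
    L2[L2 == 0] = 1.0
    w = pts[:, None, :] - p0[None, :, :]
    t = np.clip((w * dv[None, :, :]).sum(-1) / L2[None, :], 0.0, 1.0)
    proj = p0[None, :, :] + t[..., None] * dv[None, :, :]
    d = np.linalg.norm(pts[:, None, :] - proj, axis=-1)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def write_string_checkpoint(string: TransitionString, path: Union[str, Path]) -> None:
    """Plain-text per-iteration blocks of (image index, cv values)."""
    lines = [f"# pmfkit string checkpoint iterations={len(string.history)} "
             f"endpoints_fixed={int(string.endpoints_fixed)}"]
    for it, snap in enumerate(string.history):
        lines.append(f"# iteration {it}")
        for i, cv in enumerate(snap):
            lines.append(f"{i} " + " ".join(repr(float(v)) for v in cv))
    Path(path).write_text("\n".join(lines) + "\n")


def read_string_checkpoint(path: Union[str, Path]) -> TransitionString:
    history: List[np.ndarray] = []
    block: List[List[float]] = []
    endpoints_fixed = True
    for line in Path(path).read_text().splitlines():
        if line.startswith("# pmfkit string checkpoint"):
            for tok in line.split():
                if tok.startswith("endpoints_fixed="):
                    endpoints_fixed = bool(int(tok.split("=")[1]))
        elif line.startswith("# iteration"):
            if block:
                history.append(np.array(block))
            block = []
        elif line.strip() and not line.startswith("#"):
            block.append([float(v) for v in line.split()[1:]])
    if block:
        history.append(np.array(block))
    if not history:
        raise ValueError(f"no checkpoint blocks in {path}")
    images = [PathImage(i, cv) for i, cv in enumerate(history[-1])]
    s = TransitionString(images, endpoints_fixed=endpoints_fixed,
                         iteration=len(history) - 1)
    s.history = history
    return s
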