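"""Regime diagnostics: attractor classification, bystander-help scans,
return maps, Lyapunov estimates, basin sampling.

The click cycle of the canonical assembly supports two competing outcomes
-- a suppressive (Tr1-dominated) and a cytotoxic (Tc-dominated) response.
These tools classify which outcome a trajectory reached, scan the bystander
help level as a control parameter, and quantify sensitivity at the switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .assembly import Assembly
from .ode import OdeParams, Trajectory, build_rhs, simulate_ode, IntegrationError

__all__ = [
    "AttractorLabel",
    "BifurcationScan",
    "ReturnMap",
    "classify_attractor",
    "scan_bystander_help",
    "return_map",
    "lyapunov_estimate",
    "detect_bistability",
    "write_scan",
]

log = logging.getLogger("clicksim")

#: a population dominates when its tail mean exceeds the runner-up by this factor
DOMINANCE_MARGIN = 2.0
#: tail coefficient of variation above which a trajectory is non-stationary
CV_THRESHOLD = 0.1
#: tail mean below which a population is dynamically negligible: it is
#: excluded from the stationarity test (a cleanly decaying remnant has a
#: large relative variation but carries no regime information)
NEGLIGIBLE_ABUNDANCE = 1e-4
#: separation fraction of state norm at which twin trajectories saturate
LYAPUNOV_SATURATION = 1e-2


@dataclass(frozen=True)
class AttractorLabel:
    """Outcome of a single run: ``label`` is ``"<id>_dominant"``,
    ``"coexistence"``, ``"extinct"`` or ``"non_stationary"``."""

    label: str
    dominant_id: str | None
    final_state: np.ndarray

    def __eq__(self, other: object) -> bool:  # compare by label for convenience
        if isinstance(other, str):
            return self.label == other
        if isinstance(other, AttractorLabel):
            return self.label == other.label and self.dominant_id == other.dominant_id
        return NotImplemented


def classify_attractor(traj: Trajectory, tail_fraction: float = 0.2,
                       extinction_threshold: float = 1e-8,
                       dominance_margin: float = DOMINANCE_MARGIN,
                       cv_threshold: float = CV_THRESHOLD) -> AttractorLabel:
    """Label the attractor from the time-averaged tail of a trajectory.

    The last ``tail_fraction`` of samples is averaged.  ``extinct`` if
    every population's tail mean is below the extinction threshold;
    ``non_stationary`` if any non-negligible population's tail coefficient
    of variation exceeds ``cv_threshold`` (populations whose tail mean is
    below ``NEGLIGIBLE_ABUNDANCE`` are decaying remnants and are skipped);
    ``<id>_dominant`` if the top tail mean exceeds the runner-up by
    ``dominance_margin``; else ``coexistence``.  Depends only on tail
    statistics, so it is invariant to uniform rescaling of the time grid.
    """
    if not (0 < tail_fraction <= 1):
        raise ValueError("tail_fraction must be in (0, 1]")
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    n = traj.times.size
    start = min(n - 1, int(round(n * (1 - tail_fraction))))
    tail = traj.abundances[start:]
    mu = tail.mean(axis=0)
    final = traj.abundances[-1]
    if (mu < extinction_threshold).all():
        return AttractorLabel("extinct", None, final)
    alive = mu >= max(extinction_threshold, NEGLIGIBLE_ABUNDANCE)
    cv = np.zeros_like(mu)
    cv[alive] = tail.std(axis=0)[alive] / mu[alive]
    if (cv > cv_threshold).any():
        return AttractorLabel("non_stationary", None, final)
    order = np.argsort(mu)[::-1]
    top, second = order[0], order[1] if mu.size > 1 else order[0]
    if mu.size > 1 and mu[top] >= dominance_margin * mu[second]:
        pid = traj.ids[top]
        return AttractorLabel(f"{pid}_dominant", pid, final)
    if mu.size == 1:
        pid = traj.ids[top]
        return AttractorLabel(f"{pid}_dominant", pid, final)
    return AttractorLabel("coexistence", None, final)


@dataclass
class BifurcationScan:
    """Attractor labels and sensitivity over a grid of help levels."""

    help_values: np.ndarray
    labels: list[AttractorLabel]
    lyapunov: np.ndarray
    final_states: np.ndarray
    errors: list[str | None]
    ids: tuple[str, ...] = ()

    def label_set(self) -> set[str]:
        return {lab.label for lab in self.labels}


def scan_bystander_help(a: Assembly, h_grid: Sequence[float],
                        p: OdeParams | None = None,
                        init: Sequence[float] | None = None,
                        compute_lyapunov: bool = True) -> BifurcationScan:
    """Classify the attractor for each bystander help level in ``h_grid``.

    Every bystander input of the assembly is set to each grid value in
    turn; the run is classified and (optionally) the twin-trajectory
    Lyapunov estimate is attached.  Solver failures are recorded per grid
    point and do not abort the scan.
    """
    h_grid = np.asarray(h_grid, dtype=float)
    if h_grid.size and not (np.diff(h_grid) > 0).all():
        raise ValueError("h_grid must be strictly increasing")
    if (h_grid < 0).any():
        raise ValueError("h_grid must be non-negative")
    p = p or OdeParams()
    n = len(a.populations)
    labels: list[AttractorLabel] = []
    lams = np.full(h_grid.size, np.nan)
    finals = np.full((h_grid.size, n), np.nan)
    errors: list[str | None] = []
    for i, h in enumerate(h_grid):
        ah = a.with_help_level(float(h))
        try:
            traj = simulate_ode(ah, p, init)
        except IntegrationError as exc:
            log.warning("scan point h=%g failed: %s", h, exc)
            labels.append(AttractorLabel("failed", None, np.asarray(exc.last_state)))
            errors.append(str(exc))
            continue
        labels.append(classify_attractor(traj, extinction_threshold=p.extinction_threshold))
        finals[i] = traj.final_state
        errors.append(None)
        if compute_lyapunov:
            lams[i] = lyapunov_estimate(ah, p, init, horizon=min(p.t_end, 500.0))
    return BifurcationScan(
        help_values=h_grid, labels=labels, lyapunov=lams, final_states=finals,
        errors=errors, ids=tuple(pop.id for pop in a.populations))


@dataclass
class ReturnMap:
    """Delay-embedding of each population: points (x_t, x_{t+lag}).

    ``overlap`` is the minimum distance between non-adjacent path segments,
    normalized by the data range -- zero means the path revisits itself at
    the sampling resolution, positive means the transition paths are
    non-overlapping.
    """

    lag: int
    ids: tuple[str, ...]
    points: dict[str, np.ndarray]  # id -> (T-lag, 2) array
    overlap: float


def _min_segment_distance(pts: np.ndarray, max_segments: int = 400,
                          length_floor: float = 1e-4) -> float:
    """Minimum distance between non-adjacent moving polyline segments (2-D).

    Segments shorter than ``length_floor`` times the data range are
    effectively stationary (the path is sitting still or creeping, e.g. at
    an equilibrium or a saddle plateau); they carry no path information
    and their mutual distances sit at numerical-noise scale, so they are
    excluded.
    """
    nseg = pts.shape[0] - 1
    if nseg < 3:
        return np.inf
    stride = max(1, int(np.ceil(nseg / max_segments)))
    a0 = pts[:-1:stride]
    a1 = pts[1::stride]
    idx = np.arange(0, nseg, stride)
    span = pts.max(0) - pts.min(0)
    scale = float(np.linalg.norm(span))
    lengths = np.linalg.norm(a1 - a0, axis=1)
    moving = lengths > length_floor * max(scale, 1e-300)
    if moving.sum() < 3:
        return np.inf
    a0, a1, idx = a0[moving], a1[moving], idx[moving]
    m = a0.shape[0]
    # sample each segment at 5 points; min pairwise point distance between
    # segments more than one (original) index apart approximates segment distance
    ts = np.linspace(0.0, 1.0, 5)
    samples = a0[:, None, :] + ts[None, :, None] * (a1 - a0)[:, None, :]  # (m,5,2)
    flat = samples.reshape(m * 5, 2)
    seg_of = np.repeat(idx, 5)
    d2 = ((flat[:, None, :] - flat[None, :, :]) ** 2).sum(-1)
    sep = np.abs(seg_of[:, None] - seg_of[None, :])
    d2[sep <= stride] = np.inf
    return float(np.sqrt(d2.min()))


def return_map(traj: Trajectory, lag: int = 1) -> ReturnMap:
    """Build the time +lag vs time map for every population."""
    T = traj.times.size
    if not (1 <= lag < T):
        raise ValueError(f"lag must be in [1, {T - 1}]")
    points: dict[str, np.ndarray] = {}
    overlaps: list[float] = []
    for i, pid in enumerate(traj.ids):
        x = traj.abundances[:, i]
        pts = np.column_stack([x[:-lag], x[lag:]])
        points[pid] = pts
        rng_ = x.max() - x.min()
        if rng_ > 0:
            d = _min_segment_distance(pts)
            if np.isfinite(d):
                overlaps.append(d / rng_)
    overlap = float(min(overlaps)) if overlaps else 0.0
    return ReturnMap(lag=lag, ids=traj.ids, points=points, overlap=overlap)


def lyapunov_estimate(a: Assembly, p: OdeParams | None = None,
                      init: Sequence[float] | None = None,
                      eps: float = 1e-6, horizon: float = 500.0) -> float:
    """Largest-Lyapunov estimate from twin-trajectory divergence.

    Integrates the state and a copy displaced by ``eps`` along the
    normalized all-ones direction, then fits log separation against time
    by least squares over the pre-saturation window (separation below 1e-2
    of the mean state norm).  Integration uses tightened tolerances
    (rtol <= 1e-10, atol <= 1e-12) so solver noise stays below the
    perturbation scale.  Returns NaN when the fit window is degenerate.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    p = p or OdeParams()
    spec = build_rhs(a)
    if init is None:
        init = [pop.initial_abundance for pop in a.populations]
    x0 = np.asarray(init, dtype=float)
    direction = np.ones_like(x0) / np.sqrt(x0.size)
    y0 = x0 + eps * direction
    n = max(501, int(horizon))
    t_eval = np.linspace(0.0, horizon, n)
    rtol = min(p.relative_tolerance, 1e-10)
    atol = min(p.absolute_tolerance, 1e-12)
    kw = dict(t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
    sa = solve_ivp(spec.func, (0.0, horizon), x0, **kw)
    sb = solve_ivp(spec.func, (0.0, horizon), y0, **kw)
    if not (sa.success and sb.success):
        return float("nan")
    sep = np.linalg.norm(sa.y - sb.y, axis=0)
    norm = np.linalg.norm(sa.y, axis=0).mean()
    mask = (sep > 1e-14) & (sep < LYAPUNOV_SATURATION * max(norm, 1e-12))
    if mask.sum() < 10:
        return float("nan")
    A = np.column_stack([t_eval[mask], np.ones(int(mask.sum()))])
    slope, _ = np.linalg.lstsq(A, np.log(sep[mask]), rcond=None)[0]
    return float(slope)


def detect_bistability(a: Assembly, h: float, p: OdeParams | None = None,
                       n_inits: int = 50, seed: int = 0) -> dict[str, float]:
    """Basin fractions over random initial conditions at help level ``h``.

    Initial abundances are drawn uniformly from [0, 0.5]^N with the given
    seed; each run is classified and the fraction of runs per label
    returned (solver failures under ``"failed"``).  Fractions sum to 1.
    """
    if n_inits < 2:
        raise ValueError("n_inits must be >= 2")
    p = p or OdeParams()
    ah = a.with_help_level(float(h))
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    n = len(a.populations)
    for _ in range(n_inits):
        init = rng.uniform(0.0, 0.5, n)
        try:
            traj = simulate_ode(ah, p, init)
            lab = classify_attractor(traj, extinction_threshold=p.extinction_threshold).label
        except IntegrationError:
            lab = "failed"
        counts[lab] = counts.get(lab, 0) + 1
    return {lab: c / n_inits for lab, c in sorted(counts.items())}


def write_scan(scan: BifurcationScan, path: str | Path) -> None:
    """Write a bifurcation scan as TSV (help, label, lyapunov, finals)."""
    with open(path, "w") as fh:
        fh.write("# columns: help_level, attractor_label, lyapunov, final abundances\n")
        fh.write("help\tlabel\tlyapunov\t" + "\t".join(scan.ids) + "\n")
        for i, h in enumerate(scan.help_values):
            finals = "\t".join(f"{v:.10g}" for v in scan.final_states[i])
            fh.write(f"{h:.10g}\t{scan.labels[i].label}\t{scan.lyapunov[i]:.6g}\t{finals}\n")
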