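"""Deterministic mean-field dynamics of a click assembly.

The backend integrates a generalized Lotka-Volterra system.  For population
i with growth rate r_i, death rate d_i, help coefficient beta_i
experiencing bystander help h_i, shared carrying capacity K, kill rates
kappa_{j->i} for each killer j, and maturation rate m_i (outgoing) / m_l
(incoming from l):

    dP_i/dt = P_i [ r_i (1 + beta_i h_i) (1 - sum_j P_j / K)
                    - d_i - sum_{j kills i} kappa_{ji} P_j ]
              + sum_{l matures into i} m_l P_l  -  m_i P_i

Logistic self-limitation through the shared total keeps trajectories
bounded; mass-action killing expresses contact-dependent fratricide;
maturation moves cells within a lineage; bystander help multiplies growth
without touching the kill wiring.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .assembly import Assembly, assembly_to_dict, validate_assembly

__all__ = [
    "OdeParams",
    "Trajectory",
    "RhsSpec",
    "build_rhs",
    "simulate_ode",
    "find_equilibrium",
    "write_trajectory",
    "read_trajectory",
    "assembly_hash",
]

log = logging.getLogger("clicksim")

#: residual threshold below which the end state counts as converged
CONVERGENCE_TOL = 1e-6
#: finite-difference step for Jacobians
JACOBIAN_STEP = 1e-7


@dataclass(frozen=True)
class OdeParams:
    """Integration control for :func:`simulate_ode`."""

    absolute_tolerance: float = 1e-9
    relative_tolerance: float = 1e-7
    t_end: float = 400.0
    n_samples: int = 801
    extinction_threshold: float = 1e-8

    def __post_init__(self) -> None:
        if self.absolute_tolerance <= 0 or self.relative_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")


@dataclass
class Trajectory:
    """Time-indexed matrix of population abundances.

    ``abundances[t, i]`` is the abundance of ``ids[i]`` at ``times[t]``.
    Produced by both the ODE and the cellular-automaton backends; the
    ``metadata`` dict records provenance (assembly hash, backend tag,
    parameters, seed).
    """

    times: np.ndarray
    abundances: np.ndarray
    ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (self.times.size, len(self.ids)):
            raise ValueError("abundances must be (len(times), len(ids))")

    def column(self, pid: str) -> np.ndarray:
        return self.abundances[:, self.ids.index(pid)]

    @property
    def final_state(self) -> np.ndarray:
        return self.abundances[-1]


@dataclass(frozen=True)
class RhsSpec:
    """Vector field of an assembly: callable rhs(t, P) plus its ingredients."""

    ids: tuple[str, ...]
    func: Callable[[float, np.ndarray], np.ndarray]
    effective_growth: np.ndarray  # r_i * (1 + beta_i * h_i)
    death: np.ndarray
    kill_matrix: np.ndarray  # [victim, killer] = kappa
    maturation_out: np.ndarray  # m_i for outgoing edge, else 0
    maturation_from: np.ndarray  # [target, source] = m_source
    carrying_capacity: float

    def __call__(self, t: float, P: np.ndarray) -> np.ndarray:
        return self.func(t, P)

    def jacobian(self, P: Sequence[float], step: float = JACOBIAN_STEP) -> np.ndarray:
        """Central finite-difference Jacobian at state P."""
        P = np.asarray(P, dtype=float)
        n = P.size
        J = np.empty((n, n))
        for j in range(n):
            up, dn = P.copy(), P.copy()
            up[j] += step
            dn[j] -= step
            J[:, j] = (self.func(0.0, up) - self.func(0.0, dn)) / (2 * step)
        return J


def build_rhs(a: Assembly) -> RhsSpec:
    """Compile an assembly into its mean-field vector field.

    Raises ``ValueError`` if the assembly fails permissive validation.
    """
    report = validate_assembly(a, strict=False)
    if not report.valid:
        raise ValueError(
            "invalid assembly: " + "; ".join(v.message for v in report.violations))
    ids = tuple(p.id for p in a.populations)
    index = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    reff = np.array([
        p.growth_rate * (1.0 + p.help_coefficient * a.help_level(p.id))
        for p in a.populations])
    death = np.array([p.death_rate for p in a.populations])
    K = a.carrying_capacity
    kill = np.zeros((n, n))
    for e in a.kill_edges:
        kill[index[e.victim], index[e.killer]] += e.kill_rate
    m_out = np.zeros(n)
    m_from = np.zeros((n, n))
    for e in a.maturation_edges:
        m_out[index[e.source]] += e.rate
        m_from[index[e.target], index[e.source]] += e.rate

    def rhs(t: float, P: np.ndarray) -> np.ndarray:
        P = np.asarray(P, dtype=float)
        crowd = 1.0 - P.sum() / K
        percap = reff * crowd - death - kill @ P
        return P * percap + m_from @ P - m_out * P

    return RhsSpec(
        ids=ids, func=rhs, effective_growth=reff, death=death, kill_matrix=kill,
        maturation_out=m_out, maturation_from=m_from, carrying_capacity=K)


def assembly_hash(a: Assembly) -> str:
    """Stable short hash of the assembly definition (for provenance)."""
    blob = json.dumps(assembly_to_dict(a), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class IntegrationError(RuntimeError):
    """Raised when the integrator fails; carries the last valid state."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


def simulate_ode(a: Assembly, p: OdeParams | None = None,
                 init: Sequence[float] | None = None) -> Trajectory:
    """Integrate the assembly's mean-field dynamics on a uniform grid.

    ``init`` defaults to the populations' ``initial_abundance``.  Negative
    solver undershoot is clamped to zero after sampling (the clamp magnitude
    is logged).  The trajectory metadata records a ``converged`` flag:
    True iff max |dP/dt| < 1e-6 at ``t_end``.
    """
    p = p or OdeParams()
    spec = build_rhs(a)
    if init is None:
        init = [pop.initial_abundance for pop in a.populations]
    x0 = np.asarray(init, dtype=float)
    if x0.size != len(spec.ids):
        raise ValueError(f"init must have length {len(spec.ids)}")
    if (x0 < 0).any():
        raise ValueError("init must be non-negative")
    t_eval = np.linspace(0.0, p.t_end, p.n_samples)
    sol = solve_ivp(
        spec.func, (0.0, p.t_end), x0, t_eval=t_eval, method="LSODA",
        rtol=p.relative_tolerance, atol=p.absolute_tolerance)
    if not sol.success:
        n_ok = sol.t.size
        last_t = sol.t[-1] if n_ok else 0.0
        last_y = sol.y[:, -1] if n_ok else x0
        raise IntegrationError(f"integrator failed: {sol.message}", last_t, last_y)
    y = sol.y.T
    clamp = -np.minimum(y, 0.0).sum()
    if clamp > 0:
        log.debug("clamped negative undershoot, total magnitude %.3e", clamp)
    y = np.clip(y, 0.0, None)
    final_rhs = spec.func(p.t_end, y[-1])
    converged = bool(np.abs(final_rhs).max() < CONVERGENCE_TOL)
    meta = {
        "assembly": assembly_hash(a),
        "backend": "ode",
        "t_end": p.t_end,
        "n_samples": p.n_samples,
        "rtol": p.relative_tolerance,
        "atol": p.absolute_tolerance,
        "extinction_threshold": p.extinction_threshold,
        "converged": converged,
        "clamp_magnitude": float(clamp),
    }
    return Trajectory(times=t_eval, abundances=y, ids=spec.ids, metadata=meta)


def find_equilibrium(a: Assembly, guess: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Root of the vector field near ``guess`` plus a linear stability flag.

    Returns ``(equilibrium, stable)`` where ``stable`` is True iff the
    dominant eigenvalue of the central-finite-difference Jacobian (step
    1e-7) has negative real part.  Raises ``RuntimeError`` if no root with
    residual < 1e-10 is found from the guess.
    """
    spec = build_rhs(a)
    guess = np.asarray(guess, dtype=float)
    if (guess < 0).any():
        raise ValueError("guess must be non-negative")
    sol = root(lambda x: spec.func(0.0, x), guess, method="hybr", tol=1e-13)
    residual = np.abs(spec.func(0.0, sol.x)).max()
    if residual >= 1e-10:
        raise RuntimeError(
            f"no equilibrium found from guess (residual {residual:.2e})")
    eq = sol.x
    eigs = np.linalg.eigvals(spec.jacobian(eq))
    stable = bool(eigs.real.max() < 0)
    return eq, stable


# ---------------------------------------------------------------------------
# Trajectory TSV format: '#'-prefixed metadata lines, then a header row
# ('time' + one column per population id), tab-separated values.
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(traj.metadata):
            fh.write(f"# {key}={json.dumps(traj.metadata[key])}\n")
        fh.write("time\t" + "\t".join(traj.ids) + "\n")
        for t, row in zip(traj.times, traj.abundances):
            fh.write(f"{t:.10g}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    meta: dict = {}
    times: list[float] = []
    rows: list[list[float]] = []
    ids: tuple[str, ...] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    try:
                        meta[key.strip()] = json.loads(val)
                    except json.JSONDecodeError:
                        meta[key.strip()] = val
                continue
            parts = line.split("\t")
            if ids is None:
                if parts[0] != "time":
                    raise ValueError("trajectory file must start with a 'time' header")
                ids = tuple(parts[1:])
                continue
            times.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    if ids is None:
        raise ValueError("empty trajectory file")
    return Trajectory(
        times=np.array(times), abundances=np.array(rows), ids=ids, metadata=meta)
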