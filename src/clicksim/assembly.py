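"""Click assemblies: populations wired by directional kill interactions.

A *click* is a receptor-ligand pairing between two immune cell types that
triggers the death of exactly one of them.  An assembly collects cell
populations (each with a lineage and a maturation stage), the directed kill
edges between them, within-lineage maturation flows, and bystander-help
inputs.  Two structural rules apply: a click is exclusive to a pair of
populations (at most one kill edge per unordered pair), and killing is
directional (mutual kill edges are forbidden).  Under these rules the
sustaining core of an assembly is its smallest directed kill cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Stage",
    "Population",
    "KillEdge",
    "MaturationEdge",
    "BystanderInput",
    "Assembly",
    "Violation",
    "ValidationReport",
    "validate_assembly",
    "smallest_directed_cycle",
    "build_canonical_4click",
    "random_assembly",
    "assembly_to_dict",
    "assembly_from_dict",
    "load_assembly",
    "save_assembly",
]


class Stage(str, Enum):
    YOUNG = "young"
    MATURE = "mature"


@dataclass(frozen=True)
class Population:
    """One cell population (a node of the assembly).

    Rates are per unit time on an arbitrary time scale; ``help_coefficient``
    scales how strongly bystander help boosts the population's growth;
    ``initial_abundance`` is on the normalized response scale in [0, 1].
    """

    id: str
    lineage: str
    stage: Stage
    growth_rate: float = 1.0
    death_rate: float = 0.0
    help_coefficient: float = 0.0
    initial_abundance: float = 0.0


@dataclass(frozen=True)
class KillEdge:
    """Directional click: ``killer`` eliminates ``victim`` on contact.

    ``mechanism`` is a free-text annotation (e.g. "NK receptor",
    "Fas/FasL", "CTLA4 transendocytosis"); it does not affect dynamics.
    """

    killer: str
    victim: str
    kill_rate: float = 1.0
    mechanism: str = ""


@dataclass(frozen=True)
class MaturationEdge:
    """Within-lineage maturation flow from a young stage to a mature one."""

    source: str
    target: str
    rate: float = 0.0


@dataclass(frozen=True)
class BystanderInput:
    """Bystander help attached to one population.

    ``help_level`` is the dimensionless control parameter h; the boost a
    population receives is ``(1 + help_coefficient * h)`` on its growth
    rate.  Help changes population sizes but never the kill-cycle wiring.
    """

    target: str
    help_level: float = 0.0


@dataclass(frozen=True)
class Assembly:
    populations: tuple[Population, ...]
    kill_edges: tuple[KillEdge, ...] = ()
    maturation_edges: tuple[MaturationEdge, ...] = ()
    bystander_inputs: tuple[BystanderInput, ...] = ()
    carrying_capacity: float = 1.0

    def population_ids(self) -> list[str]:
        return [p.id for p in self.populations]

    def population(self, pid: str) -> Population:
        for p in self.populations:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def help_level(self, pid: str) -> float:
        """Help level h experienced by population ``pid`` (0 if no input)."""
        for b in self.bystander_inputs:
            if b.target == pid:
                return b.help_level
        return 0.0

    def with_help_level(self, h: float) -> "Assembly":
        """Copy of the assembly with every bystander input set to level h."""
        inputs = tuple(replace(b, help_level=float(h)) for b in self.bystander_inputs)
        return replace(self, bystander_inputs=inputs)

    def kill_graph(self) -> dict[str, list[str]]:
        """Adjacency (killer -> victims) of the kill-edge digraph."""
        adj: dict[str, list[str]] = {p.id: [] for p in self.populations}
        for e in self.kill_edges:
            adj.setdefault(e.killer, []).append(e.victim)
        return adj


@dataclass(frozen=True)
class Violation:
    rule: str
    message: str
    offenders: tuple[str, ...] = ()


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    violations: tuple[Violation, ...] = ()

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "violations": [
                {"rule": v.rule, "message": v.message, "offenders": list(v.offenders)}
                for v in self.violations
            ],
        }


def _finite_nonneg(x: float) -> bool:
    return np.isfinite(x) and x >= 0


def validate_assembly(a: Assembly, strict: bool = False) -> ValidationReport:
    """Check an assembly against the click rules.

    Permissive mode enforces referential integrity, rate positivity, the
    pair-exclusivity rule and kill directionality, and maturation-edge
    lineage/stage consistency.  ``strict`` additionally enforces the
    canonical wiring: within-lineage kill edges run young -> mature and
    cross-lineage kill edges run mature -> young (new cells regulate the
    older generation of their own lineage, not its progeny).

    All problems are reported as violations, never raised.
    """
    out: list[Violation] = []
    ids = [p.id for p in a.populations]
    seen: set[str] = set()
    for pid in ids:
        if pid in seen:
            out.append(Violation("unique-id", f"duplicate population id {pid!r}", (pid,)))
        seen.add(pid)
    pops = {p.id: p for p in a.populations}

    for p in a.populations:
        for name, val in (
            ("growth_rate", p.growth_rate),
            ("death_rate", p.death_rate),
            ("help_coefficient", p.help_coefficient),
        ):
            if not _finite_nonneg(val):
                out.append(Violation(
                    "rate-range", f"{p.id}.{name} = {val!r} must be finite and >= 0", (p.id,)))
        if not (np.isfinite(p.initial_abundance) and 0 <= p.initial_abundance <= 1):
            out.append(Violation(
                "initial-abundance",
                f"{p.id}.initial_abundance = {p.initial_abundance!r} must lie in [0, 1]",
                (p.id,)))

    if not (np.isfinite(a.carrying_capacity) and a.carrying_capacity > 0):
        out.append(Violation(
            "carrying-capacity",
            f"carrying_capacity = {a.carrying_capacity!r} must be finite and > 0", ()))

    pair_seen: set[frozenset[str]] = set()
    for e in a.kill_edges:
        edge_tag = f"{e.killer}>{e.victim}"
        for end in (e.killer, e.victim):
            if end not in pops:
                out.append(Violation(
                    "dangling-reference", f"kill edge {edge_tag} references unknown id {end!r}",
                    (edge_tag,)))
        if e.killer == e.victim:
            out.append(Violation("self-kill", f"kill edge {edge_tag} is a self-loop", (edge_tag,)))
        if not _finite_nonneg(e.kill_rate):
            out.append(Violation(
                "rate-range", f"kill edge {edge_tag} rate {e.kill_rate!r} must be >= 0",
                (edge_tag,)))
        pair = frozenset((e.killer, e.victim))
        if pair in pair_seen:
            out.append(Violation(
                "click-exclusivity",
                f"more than one kill edge between {set(pair)} "
                "(clicks are exclusive to a pair of cells; killing is directional)",
                tuple(sorted(pair))))
        pair_seen.add(pair)

    mat_out: set[str] = set()
    mat_in: set[str] = set()
    for e in a.maturation_edges:
        edge_tag = f"{e.source}->{e.target}"
        missing = [x for x in (e.source, e.target) if x not in pops]
        if missing:
            out.append(Violation(
                "dangling-reference",
                f"maturation edge {edge_tag} references unknown id(s) {missing}", (edge_tag,)))
            continue
        if not _finite_nonneg(e.rate):
            out.append(Violation(
                "rate-range", f"maturation edge {edge_tag} rate {e.rate!r} must be >= 0",
                (edge_tag,)))
        src, tgt = pops[e.source], pops[e.target]
        if src.lineage != tgt.lineage:
            out.append(Violation(
                "maturation-lineage",
                f"maturation edge {edge_tag} crosses lineages "
                f"({src.lineage!r} -> {tgt.lineage!r})", (edge_tag,)))
        if src.stage != Stage.YOUNG or tgt.stage != Stage.MATURE:
            out.append(Violation(
                "maturation-stage",
                f"maturation edge {edge_tag} must run young -> mature "
                f"(got {src.stage.value} -> {tgt.stage.value})", (edge_tag,)))
        if e.source in mat_out:
            out.append(Violation(
                "maturation-degree", f"{e.source} has more than one outgoing maturation edge",
                (e.source,)))
        if e.target in mat_in:
            out.append(Violation(
                "maturation-degree", f"{e.target} has more than one incoming maturation edge",
                (e.target,)))
        mat_out.add(e.source)
        mat_in.add(e.target)

    for b in a.bystander_inputs:
        if b.target not in pops:
            out.append(Violation(
                "dangling-reference", f"bystander input targets unknown id {b.target!r}",
                (b.target,)))
        if not _finite_nonneg(b.help_level):
            out.append(Violation(
                "rate-range", f"bystander help level {b.help_level!r} must be >= 0", (b.target,)))

    if strict:
        for e in a.kill_edges:
            if e.killer not in pops or e.victim not in pops or e.killer == e.victim:
                continue
            k, v = pops[e.killer], pops[e.victim]
            edge_tag = f"{e.killer}>{e.victim}"
            if k.lineage == v.lineage:
                if not (k.stage == Stage.YOUNG and v.stage == Stage.MATURE):
                    out.append(Violation(
                        "canonical-wiring",
                        f"within-lineage kill edge {edge_tag} must run young -> mature",
                        (edge_tag,)))
            else:
                if not (k.stage == Stage.MATURE and v.stage == Stage.YOUNG):
                    out.append(Violation(
                        "canonical-wiring",
                        f"cross-lineage kill edge {edge_tag} must run mature -> young",
                        (edge_tag,)))

    return ValidationReport(valid=not out, violations=tuple(out))


def smallest_directed_cycle(a: Assembly) -> list[str]:
    """Shortest simple directed cycle of the kill graph, or [] if acyclic.

    Ties are broken by the lexicographic order of the sorted id sequence,
    then the cycle is rotated to start at its lexicographically smallest
    member.  Uses breadth-first search from every node (shortest victim
    path back to the killer closes the shortest cycle through that node).
    """
    adj = a.kill_graph()
    best: list[str] | None = None

    def better(c1: list[str], c2: list[str] | None) -> bool:
        if c2 is None:
            return True
        if len(c1) != len(c2):
            return len(c1) < len(c2)
        return sorted(c1) < sorted(c2)

    for start in sorted(adj):
        # BFS over victims; parent links rebuild the path
        parent: dict[str, str | None] = {start: None}
        frontier = [start]
        found = None
        while frontier and found is None:
            nxt = []
            for u in frontier:
                for v in sorted(adj.get(u, ())):
                    if v == start:
                        found = u
                        break
                    if v not in parent:
                        parent[v] = u
                        nxt.append(v)
                if found is not None:
                    break
            frontier = nxt
        if found is None:
            continue
        path = [found]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])  # type: ignore[index]
        cycle = list(reversed(path))  # start .. found
        if better(cycle, best):
            best = cycle
    if best is None:
        return []
    i = best.index(min(best))
    return best[i:] + best[:i]


# ---------------------------------------------------------------------------
# Canonical 4-click (calibrated defaults live in fixtures/fig1_4click.json)
# ---------------------------------------------------------------------------

_FIXTURE_DIR = Path(__file__).parent / "fixtures"

_OVERRIDABLE = {
    "growth_rate", "death_rate", "help_coefficient", "initial_abundance",
    "kill_rate", "maturation_rate", "help_level", "carrying_capacity",
}


def build_canonical_4click(overrides: Mapping[str, object] | None = None) -> Assembly:
    """The four-population assembly of cytotoxic and type-1 helper lineages.

    Tc (young cytotoxic) matures into Tnk (cytotoxic cells expressing NK
    receptors); Th (young helper) matures into Tr1 (type-1 regulatory).
    Kill cycle: Tc kills Tnk, Tnk kills Th, Th kills Tr1, Tr1 kills Tc.
    The shipped rates are a calibrated default set (data, not code) under
    which the resting state is a stable coexistence dominated by Tr1.

    ``overrides`` maps dotted keys to values, e.g. ``{"Tc.growth_rate": 2.0,
    "Tnk>Th.kill_rate": 0.0, "Tc->Tnk.maturation_rate": 0.1,
    "Th.help_level": 2.0, "carrying_capacity": 1.0}``.  Unknown keys raise
    ``KeyError``.
    """
    a = load_assembly(_FIXTURE_DIR / "fig1_4click.json")
    if not overrides:
        return a
    pops = {p.id: p for p in a.populations}
    kills = {f"{e.killer}>{e.victim}": e for e in a.kill_edges}
    mats = {f"{e.source}->{e.target}": e for e in a.maturation_edges}
    helps = {b.target: b for b in a.bystander_inputs}
    cap = a.carrying_capacity
    for key, val in overrides.items():
        if key == "carrying_capacity":
            cap = float(val)  # type: ignore[arg-type]
            continue
        if "." not in key:
            raise KeyError(f"unknown override key {key!r}")
        target, attr = key.rsplit(".", 1)
        if attr not in _OVERRIDABLE:
            raise KeyError(f"unknown override key {key!r}")
        if attr == "kill_rate" and target in kills:
            kills[target] = replace(kills[target], kill_rate=float(val))  # type: ignore[arg-type]
        elif attr == "maturation_rate" and target in mats:
            mats[target] = replace(mats[target], rate=float(val))  # type: ignore[arg-type]
        elif attr == "help_level" and target in helps:
            helps[target] = replace(helps[target], help_level=float(val))  # type: ignore[arg-type]
        elif target in pops and attr in (
                "growth_rate", "death_rate", "help_coefficient", "initial_abundance"):
            pops[target] = replace(pops[target], **{attr: float(val)})  # type: ignore[arg-type]
        else:
            raise KeyError(f"unknown override key {key!r}")
    return Assembly(
        populations=tuple(pops[p.id] for p in a.populations),
        kill_edges=tuple(kills[f"{e.killer}>{e.victim}"] for e in a.kill_edges),
        maturation_edges=tuple(mats[f"{e.source}->{e.target}"] for e in a.maturation_edges),
        bystander_inputs=tuple(helps[b.target] for b in a.bystander_inputs),
        carrying_capacity=cap,
    )


def random_assembly(n_lineages: int, rng_seed: int) -> Assembly:
    """Random strict-valid assembly: one kill cycle over ``n_lineages`` lineages.

    Each lineage contributes a young and a mature population joined by a
    maturation edge.  The 2*n populations are wired as a single directed
    kill cycle alternating within-lineage (young -> mature) and
    cross-lineage (mature -> next lineage's young) clicks, so every edge
    satisfies the canonical wiring rule.  Rates are drawn from documented
    ranges: growth 0.5-4, death 0.02-0.3, kill 0.5-4, maturation 0.05-0.8.
    """
    if n_lineages < 2:
        raise ValueError("random_assembly needs n_lineages >= 2")
    rng = np.random.default_rng(rng_seed)
    pops: list[Population] = []
    mats: list[MaturationEdge] = []
    kills: list[KillEdge] = []
    for i in range(n_lineages):
        lin = f"L{i}"
        young, old = f"{lin}y", f"{lin}m"
        pops.append(Population(
            id=young, lineage=lin, stage=Stage.YOUNG,
            growth_rate=float(rng.uniform(0.5, 4)), death_rate=float(rng.uniform(0.02, 0.3)),
            help_coefficient=0.0, initial_abundance=float(rng.uniform(0.01, 0.2))))
        pops.append(Population(
            id=old, lineage=lin, stage=Stage.MATURE,
            growth_rate=float(rng.uniform(0.5, 4)), death_rate=float(rng.uniform(0.02, 0.3)),
            help_coefficient=0.0, initial_abundance=float(rng.uniform(0.01, 0.2))))
        mats.append(MaturationEdge(young, old, float(rng.uniform(0.05, 0.8))))
        kills.append(KillEdge(young, old, float(rng.uniform(0.5, 4)), "within-lineage"))
    for i in range(n_lineages):
        nxt = (i + 1) % n_lineages
        kills.append(KillEdge(
            f"L{i}m", f"L{nxt}y", float(rng.uniform(0.5, 4)), "cross-lineage"))
    return Assembly(
        populations=tuple(pops), kill_edges=tuple(kills),
        maturation_edges=tuple(mats), bystander_inputs=(), carrying_capacity=1.0)


# ---------------------------------------------------------------------------
# Serialization (JSON dialect; schema ships in fixtures/assembly.schema.json)
# ---------------------------------------------------------------------------

def assembly_to_dict(a: Assembly) -> dict:
    return {
        "populations": [
            {
                "id": p.id, "lineage": p.lineage, "stage": p.stage.value,
                "growth_rate": p.growth_rate, "death_rate": p.death_rate,
                "help_coefficient": p.help_coefficient,
                "initial_abundance": p.initial_abundance,
            } for p in a.populations
        ],
        "kill_edges": [
            {"killer": e.killer, "victim": e.victim, "kill_rate": e.kill_rate,
             "mechanism": e.mechanism} for e in a.kill_edges
        ],
        "maturation_edges": [
            {"source": e.source, "target": e.target, "rate": e.rate}
            for e in a.maturation_edges
        ],
        "bystander_inputs": [
            {"target": b.target, "help_level": b.help_level} for b in a.bystander_inputs
        ],
        "carrying_capacity": a.carrying_capacity,
    }


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"assembly config: {msg}")


def assembly_from_dict(d: Mapping) -> Assembly:
    """Validating reader for the assembly config dialect."""
    _require(isinstance(d, Mapping), "top level must be an object")
    _require("populations" in d, "missing key 'populations'")
    pops = []
    for i, pd in enumerate(d["populations"]):
        _require(isinstance(pd, Mapping), f"populations[{i}] must be an object")
        _require("id" in pd and isinstance(pd["id"], str), f"populations[{i}].id must be a string")
        stage = pd.get("stage", "young")
        _require(stage in ("young", "mature"),
                 f"populations[{i}].stage must be 'young' or 'mature'")
        for k in ("growth_rate", "death_rate", "help_coefficient", "initial_abundance"):
            v = pd.get(k, 0.0)
            _require(isinstance(v, (int, float)), f"populations[{i}].{k} must be a number")
        pops.append(Population(
            id=pd["id"], lineage=str(pd.get("lineage", "")), stage=Stage(stage),
            growth_rate=float(pd.get("growth_rate", 1.0)),
            death_rate=float(pd.get("death_rate", 0.0)),
            help_coefficient=float(pd.get("help_coefficient", 0.0)),
            initial_abundance=float(pd.get("initial_abundance", 0.0))))
    kills = []
    for i, ed in enumerate(d.get("kill_edges", [])):
        _require(isinstance(ed, Mapping), f"kill_edges[{i}] must be an object")
        _require("killer" in ed and "victim" in ed, f"kill_edges[{i}] needs killer and victim")
        kills.append(KillEdge(
            killer=str(ed["killer"]), victim=str(ed["victim"]),
            kill_rate=float(ed.get("kill_rate", 1.0)), mechanism=str(ed.get("mechanism", ""))))
    mats = []
    for i, ed in enumerate(d.get("maturation_edges", [])):
        _require(isinstance(ed, Mapping), f"maturation_edges[{i}] must be an object")
        _require("source" in ed and "target" in ed,
                 f"maturation_edges[{i}] needs source and target")
        mats.append(MaturationEdge(
            source=str(ed["source"]), target=str(ed["target"]),
            rate=float(ed.get("rate", 0.0))))
    helps = []
    for i, bd in enumerate(d.get("bystander_inputs", [])):
        _require(isinstance(bd, Mapping), f"bystander_inputs[{i}] must be an object")
        _require("target" in bd, f"bystander_inputs[{i}] needs target")
        helps.append(BystanderInput(
            target=str(bd["target"]), help_level=float(bd.get("help_level", 0.0))))
    cap = d.get("carrying_capacity", 1.0)
    _require(isinstance(cap, (int, float)) and cap > 0, "carrying_capacity must be > 0")
    return Assembly(
        populations=tuple(pops), kill_edges=tuple(kills), maturation_edges=tuple(mats),
        bystander_inputs=tuple(helps), carrying_capacity=float(cap))


def load_assembly(path: str | Path) -> Assembly:
    with open(path) as fh:
        return assembly_from_dict(json.load(fh))


def save_assembly(a: Assembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(assembly_to_dict(a), fh, indent=2)
        fh.write("\n")
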