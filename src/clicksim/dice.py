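"""Exact intransitive-dice tournaments.

The click cycle's logic is the logic of Efron's dice: four dice numbered so
that each beats the next in a fixed cycle with probability 2/3 and no roll
ever draws, yet no die beats all others.  Picking a die after the opponent
guarantees a win -- just as the immune response that wins depends on the
threat.  All probabilities here are exact rationals from enumeration of
the 36 ordered face pairs; floats appear only in the Monte-Carlo cross
check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Die",
    "WinRecord",
    "TournamentResult",
    "win_probability",
    "verify_intransitive_cycle",
    "tournament",
    "best_response",
    "monte_carlo_match",
    "efron_dice",
    "load_dice",
    "save_dice",
    "write_tournament",
]


@dataclass(frozen=True)
class Die:
    label: str
    faces: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.faces) != 6:
            raise ValueError(f"die {self.label!r} must have exactly 6 faces")
        if not all(isinstance(f, (int, np.integer)) for f in self.faces):
            raise ValueError(f"die {self.label!r} faces must be integers")
        object.__setattr__(self, "faces", tuple(int(f) for f in self.faces))


@dataclass(frozen=True)
class WinRecord:
    """Exact win/loss/draw probabilities for an ordered pair of dice."""

    p_win: Fraction
    p_loss: Fraction
    p_draw: Fraction

    def __post_init__(self) -> None:
        if self.p_win + self.p_loss + self.p_draw != 1:
            raise ValueError("probabilities must sum to exactly 1")


def win_probability(a: Die, b: Die) -> WinRecord:
    """Enumerate all 36 ordered face pairs of ``a`` against ``b``."""
    win = loss = draw = 0
    for fa in a.faces:
        for fb in b.faces:
            if fa > fb:
                win += 1
            elif fa < fb:
                loss += 1
            else:
                draw += 1
    return WinRecord(Fraction(win, 36), Fraction(loss, 36), Fraction(draw, 36))


def verify_intransitive_cycle(dice: Sequence[Die]) -> tuple[bool, list[WinRecord]]:
    """Does each die beat its cyclic successor with p > 1/2 and no draws?"""
    if len(dice) < 3:
        raise ValueError("an intransitive cycle needs at least 3 dice")
    records = []
    ok = True
    for i, d in enumerate(dice):
        nxt = dice[(i + 1) % len(dice)]
        rec = win_probability(d, nxt)
        records.append(rec)
        if not (rec.p_win > Fraction(1, 2) and rec.p_draw == 0):
            ok = False
    return ok, records


@dataclass(frozen=True)
class TournamentResult:
    dice: tuple[Die, ...]
    matrix: tuple[tuple[WinRecord, ...], ...]  # [i][j] = record of dice[i] vs dice[j]
    intransitive_cycle_found: bool
    cycle: tuple[str, ...]


def tournament(dice: Sequence[Die]) -> TournamentResult:
    """All pairwise match-ups plus a search for an intransitive ordering.

    The cycle search permutes the dice (n <= 8 is plenty for Efron-style
    sets) looking for an order in which every die beats its successor.
    """
    dice = tuple(dice)
    matrix = tuple(
        tuple(win_probability(a, b) for b in dice) for a in dice)
    cycle: tuple[str, ...] = ()
    found = False
    if len(dice) >= 3:
        from itertools import permutations

        # fix the first die to quotient out rotations
        for perm in permutations(range(1, len(dice))):
            order = (0,) + perm
            if all(
                matrix[order[i]][order[(i + 1) % len(order)]].p_win > Fraction(1, 2)
                and matrix[order[i]][order[(i + 1) % len(order)]].p_draw == 0
                for i in range(len(order))
            ):
                found = True
                cycle = tuple(dice[i].label for i in order)
                break
    return TournamentResult(dice=dice, matrix=matrix,
                            intransitive_cycle_found=found, cycle=cycle)


def best_response(opponent: Die, pool: Sequence[Die]) -> tuple[Die, WinRecord]:
    """The pool die with the highest win probability against ``opponent``.

    Ties break by lexicographic label order.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    ranked = sorted(pool, key=lambda d: d.label)
    best = max(ranked, key=lambda d: win_probability(d, opponent).p_win)
    return best, win_probability(best, opponent)


def monte_carlo_match(a: Die, b: Die, n_rolls: int, seed: int) -> float:
    """Empirical fraction of rolls won by ``a`` (stochastic cross-check)."""
    if n_rolls < 1:
        raise ValueError("n_rolls must be >= 1")
    rng = np.random.default_rng(seed)
    fa = np.array(a.faces)[rng.integers(0, 6, n_rolls)]
    fb = np.array(b.faces)[rng.integers(0, 6, n_rolls)]
    return float((fa > fb).sum() / n_rolls)


def efron_dice() -> list[Die]:
    """The canonical four-die Efron set (cycle A > B > C > D > A, each 2/3)."""
    return [
        Die("A", (4, 4, 4, 4, 0, 0)),
        Die("B", (3, 3, 3, 3, 3, 3)),
        Die("C", (6, 6, 2, 2, 2, 2)),
        Die("D", (5, 5, 5, 1, 1, 1)),
    ]


def load_dice(path: str | Path) -> list[Die]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError("dice config must be a list of {label, faces}")
    return [Die(str(d["label"]), tuple(d["faces"])) for d in data]


def save_dice(dice: Sequence[Die], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([{"label": d.label, "faces": list(d.faces)} for d in dice], fh, indent=2)
        fh.write("\n")


def write_tournament(result: TournamentResult, path: str | Path) -> None:
    """TSV matrix of win probabilities, rational and decimal columns."""
    with open(path, "w") as fh:
        fh.write("# pairwise p(row beats column); 'rational (decimal)'\n")
        labels = [d.label for d in result.dice]
        fh.write("die\t" + "\t".join(labels) + "\n")
        for i, row in enumerate(result.matrix):
            cells = [
                f"{int(rec.p_win * 36)}/36 ({float(rec.p_win):.4f})"
                for rec in row
            ]
            fh.write(labels[i] + "\t" + "\t".join(cells) + "\n")
        fh.write(f"# intransitive_cycle_found={result.intransitive_cycle_found} "
                 f"cycle={'>'.join(result.cycle)}\n")
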