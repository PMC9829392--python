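"""Multiplexing planner: assign targets to fluorophores and sequential
imaging/stripping cycles.

Up to four spectrally separable fluorophores can be imaged in one cycle,
and in practice five cycles of detection-oligo hybridization, imaging and
stripping are achievable without significant signal loss, giving a default
panel capacity of 4 x 5 = 20 targets per tissue section.  Fluorophore
labels are opaque strings; no spectral model is attempted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_FLUOROPHORES",
    "PanelError",
    "Assignment",
    "PanelPlan",
    "capacity",
    "plan_panel",
    "write_plan",
    "read_targets",
]

DEFAULT_FLUOROPHORES = ("AlexaFluor488", "Cy3", "TexasRed", "Cy5")
DEFAULT_MAX_CYCLES = 5


class PanelError(ValueError):
    """Raised for infeasible panel requests."""


@dataclass(frozen=True)
class Assignment:
    target_id: str
    cycle: int  # 1-based
    fluorophore: str


@dataclass(frozen=True)
class PanelPlan:
    assignments: tuple[Assignment, ...]
    n_cycles: int
    fluorophore_set: tuple[str, ...]

    def __post_init__(self) -> None:
        slots = [(a.cycle, a.fluorophore) for a in self.assignments]
        if len(set(slots)) != len(slots):
            raise PanelError("two targets share a (cycle, fluorophore) slot")
        if self.assignments and self.n_cycles != max(a.cycle for a in self.assignments):
            raise PanelError("n_cycles must equal the highest assigned cycle")


def capacity(n_fluorophores: int, n_cycles: int) -> int:
    """Panel capacity: fluorophores per cycle x imaging cycles."""
    if n_fluorophores < 1 or n_cycles < 1:
        raise PanelError(
            f"need at least one fluorophore and one cycle, got "
            f"({n_fluorophores}, {n_cycles})"
        )
    return n_fluorophores * n_cycles


def plan_panel(
    target_ids: Sequence[str],
    n_fluorophores: int = 4,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    fluorophores: Sequence[str] | None = None,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> PanelPlan:
    """Greedy cycle-major assignment of targets to (cycle, fluorophore)
    slots, in stable input order.

    ``pairs`` lists co-detected targets (a miRNA and its target mRNA) that
    must be imaged in the same cycle; pairs are placed first, each into the
    earliest cycle with two free slots, then singletons fill the remaining
    slots in order.  An unplaceable pair raises rather than being silently
    split across cycles.
    """
    if fluorophores is None:
        fluorophores = DEFAULT_FLUOROPHORES[:n_fluorophores]
        if len(fluorophores) < n_fluorophores:
            fluorophores = tuple(fluorophores) + tuple(
                f"fluor_{i + 1}" for i in range(len(fluorophores), n_fluorophores)
            )
    if len(fluorophores) != n_fluorophores:
        raise PanelError("fluorophore list length must equal n_fluorophores")
    targets = list(target_ids)
    if len(set(targets)) != len(targets):
        raise PanelError("duplicate target ids")
    cap = capacity(n_fluorophores, max_cycles)
    if len(targets) > cap:
        raise PanelError(
            f"{len(targets)} targets exceed panel capacity "
            f"{cap} = {n_fluorophores} fluorophores x {max_cycles} cycles"
        )

    pair_list = [tuple(p) for p in (pairs or [])]
    paired_ids = [t for p in pair_list for t in p]
    if len(set(paired_ids)) != len(paired_ids):
        raise PanelError("a target appears in more than one pair")
    unknown = set(paired_ids) - set(targets)
    if unknown:
        raise PanelError(f"paired targets not in target list: {sorted(unknown)}")

    free: dict[int, list[str]] = {
        c: list(fluorophores) for c in range(1, max_cycles + 1)
    }
    assignments: list[Assignment] = []

    for a, b in pair_list:
        cycle = next((c for c in free if len(free[c]) >= 2), None)
        if cycle is None:
            raise PanelError(
                f"pair ({a!r}, {b!r}) cannot share a cycle: no cycle has two "
                "free fluorophore slots; not splitting the pair"
            )
        assignments.append(Assignment(a, cycle, free[cycle].pop(0)))
        assignments.append(Assignment(b, cycle, free[cycle].pop(0)))

    singles = [t for t in targets if t not in set(paired_ids)]
    slot_iter = (
        (c, f) for c in range(1, max_cycles + 1) for f in list(free[c])
    )
    for t in singles:
        try:
            cycle, fluor = next(slot_iter)
        except StopIteration:  # pragma: no cover - guarded by capacity check
            raise PanelError("ran out of slots")
        free[cycle].remove(fluor)
        assignments.append(Assignment(t, cycle, fluor))

    assignments.sort(
        key=lambda a: (a.cycle, fluorophores.index(a.fluorophore))
    )
    n_cycles = max((a.cycle for a in assignments), default=0)
    return PanelPlan(
        assignments=tuple(assignments),
        n_cycles=n_cycles,
        fluorophore_set=tuple(fluorophores),
    )


def write_plan(plan: PanelPlan, path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.target_id, a.cycle, a.fluorophore) for a in plan.assignments],
        columns=["target_id", "cycle", "fluorophore"],
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# padlockrca panel plan; cycle is 1-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_targets(path: str | Path) -> tuple[list[str], list[tuple[str, str]]]:
    """Read a target TSV (target_id, optional pair_id column) into the
    target list and the pair list derived from shared pair_ids."""
    df = pd.read_csv(path, sep="\t", comment="#")
    targets = df["target_id"].astype(str).tolist()
    pairs: list[tuple[str, str]] = []
    if "pair_id" in df.columns:
        grouped = df.dropna(subset=["pair_id"]).groupby("pair_id")["target_id"]
        for pid, members in grouped:
            ids = members.astype(str).tolist()
            if len(ids) != 2:
                raise PanelError(
                    f"pair_id {pid!r} groups {len(ids)} targets; expected 2"
                )
            pairs.append((ids[0], ids[1]))
    return targets, pairs
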