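"""Core domain types for HTS campaign curation.

A screening campaign is a set of tested compounds (:class:`CompoundRecord`)
plus a directed-acyclic hierarchy of assays (:class:`ScreenHierarchy`):
a primary screen over the full library, confirmatory screens that
re-test primary actives, and counter screens that flag off-target
activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable


class Outcome(str, Enum):
    """Per-screen assay outcome for one compound."""

    ACTIVE = "A"
    INACTIVE = "I"
    INCONCLUSIVE = "Q"
    UNTESTED = "U"

    @classmethod
    def from_string(cls, raw: str) -> "Outcome":
        """Map a raw outcome code to the four-state vocabulary.

        Unknown strings map to INCONCLUSIVE (caller is expected to warn).
        """
        token = raw.strip().upper()
        aliases = {
            "A": cls.ACTIVE, "ACTIVE": cls.ACTIVE,
            "I": cls.INACTIVE, "INACTIVE": cls.INACTIVE,
            "Q": cls.INCONCLUSIVE, "INCONCLUSIVE": cls.INCONCLUSIVE,
            "U": cls.UNTESTED, "UNTESTED": cls.UNTESTED, "": cls.UNTESTED,
        }
        return aliases.get(token, cls.INCONCLUSIVE)


class Stage(str, Enum):
    """Role of an assay inside the screening hierarchy."""

    PRIMARY = "primary"
    CONFIRMATORY = "confirmatory"
    COUNTER = "counter"


@dataclass
class CompoundRecord:
    """One tested compound with identifiers and per-screen outcomes.

    Parameters
    ----------
    compound_id
        Non-empty identifier (PubChem-CID-like).
    smiles
        Isomeric SMILES; may be empty if ``inchi`` is present.
    inchi
        Standard InChI (prefix ``InChI=1S/``); may be empty if ``smiles``
        is present.
    outcomes
        Mapping from screen id to :class:`Outcome`.
    flags
        Audit strings accumulated during reading and curation
        (e.g. ``"non-isomeric-smiles"``). Flags never silently alter the
        record; a human (or strict mode) decides.
    label
        Final binary label assigned by hierarchical curation, or None
        before labeling.
    """

    compound_id: str
    smiles: str = ""
    inchi: str = ""
    outcomes: dict[str, Outcome] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not (self.smiles or self.inchi):
            raise ValueError(
                f"record {self.compound_id}: need at least one of smiles/inchi"
            )

    def copy(self) -> "CompoundRecord":
        """Deep-enough copy: operations never mutate caller records."""
        return replace(self, outcomes=dict(self.outcomes), flags=set(self.flags))


@dataclass(frozen=True)
class ScreenNode:
    screen_id: str
    stage: Stage
    parent_ids: tuple[str, ...] = ()
    description: str = ""


class ScreenHierarchy:
    """DAG of assays typed primary / confirmatory / counter.

    Invariants checked on construction: the graph is acyclic, every
    confirmatory or counter screen has at least one parent, and at least
    one parentless primary screen exists.
    """

    def __init__(self, nodes: Iterable[ScreenNode]):
        self.nodes: dict[str, ScreenNode] = {n.screen_id: n for n in nodes}
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            for pid in node.parent_ids:
                if pid not in self.nodes:
                    raise ValueError(
                        f"screen {node.screen_id}: unknown parent {pid!r}"
                    )
            if node.stage is not Stage.PRIMARY and not node.parent_ids:
                raise ValueError(
                    f"{node.stage.value} screen {node.screen_id} needs a parent"
                )
        roots = [n for n in self.nodes.values()
                 if n.stage is Stage.PRIMARY and not n.parent_ids]
        if not roots:
            raise ValueError("hierarchy needs at least one root primary screen")
        # cycle check by iterative DFS
        WHITE, GREY, BLACK = 0, 1, 2
        color = {sid: WHITE for sid in self.nodes}

        def children_of(sid: str) -> list[str]:
            return [n.screen_id for n in self.nodes.values()
                    if sid in n.parent_ids]

        for start in self.nodes:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(children_of(start)))]
            color[start] = GREY
            while stack:
                sid, it = stack[-1]
                for child in it:
                    if color[child] == GREY:
                        raise ValueError("hierarchy contains a cycle")
                    if color[child] == WHITE:
                        color[child] = GREY
                        stack.append((child, iter(children_of(child))))
                        break
                else:
                    color[sid] = BLACK
                    stack.pop()

    @property
    def screen_ids(self) -> set[str]:
        return set(self.nodes)

    def screens(self, stage: Stage) -> list[str]:
        return sorted(s for s, n in self.nodes.items() if n.stage is stage)

    def descendants(self, screen_id: str) -> set[str]:
        """All screens reachable downward from ``screen_id``."""
        out: set[str] = set()
        frontier = [screen_id]
        while frontier:
            sid = frontier.pop()
            for node in self.nodes.values():
                if sid in node.parent_ids and node.screen_id not in out:
                    out.add(node.screen_id)
                    frontier.append(node.screen_id)
        return out

    def linked_screens(self, primary_id: str, stage: Stage) -> list[str]:
        """Screens of ``stage`` linked (downstream) to a primary screen."""
        return sorted(s for s in self.descendants(primary_id)
                      if self.nodes[s].stage is stage)


@dataclass(frozen=True)
class StatsReport:
    """Dataset-level statistics: size, actives, hit percentage, scaffolds."""

    n_compounds: int
    n_actives: int
    n_unique_scaffolds: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_actives <= self.n_compounds:
            raise ValueError("need 0 <= n_actives <= n_compounds")

    @property
    def percent_active(self) -> float:
        if self.n_compounds == 0:
            return 0.0
        return 100.0 * self.n_actives / self.n_compounds

    @property
    def percent_active_display(self) -> str:
        """Percent active rounded to 3 decimals, e.g. ``"0.270%"``."""
        return f"{self.percent_active:.3f}%"
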