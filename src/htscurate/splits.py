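"""Benchmark split schemes: adapted cross-validation and scaffold splits.

Two standardized schemes:

- **adapted CV** — a budget-friendly alternative to nested CV: the ids
  are shuffled once into k folds; fold t is the test set of tuple t and
  its cyclic predecessor fold is the validation set, so every compound
  is tested exactly once while only k models are ever trained.
- **scaffold split** — compounds are binned by Bemis-Murcko scaffold;
  any bin holding more than a threshold fraction of the library is
  forced into training (scaffold diversity), the rest are assigned
  greedily toward a 3:1:1 train:validation:test target.  No scaffold
  ever spans two partitions, which makes the test set a scaffold-hopping
  challenge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import parse_smiles
from .types import CompoundRecord


@dataclass(frozen=True)
class SplitConfig:
    """Settings shared by both split schemes.

    ``ratio`` is the train:validation:test target for the scaffold
    split; ``big_bin_fraction`` is the library fraction above which a
    scaffold bin is forced into training (default 0.10).
    """

    k: int = 5
    ratio: tuple[int, int, int] = (3, 1, 1)
    big_bin_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if len(self.ratio) != 3 or any(r <= 0 for r in self.ratio):
            raise ValueError("ratio must be three positive numbers")
        if not 0 < self.big_bin_fraction < 1:
            raise ValueError("big_bin_fraction must be in (0, 1)")


@dataclass
class SplitPlan:
    """Index partitions for one split scheme.

    ``folds`` holds ``(train_ids, val_ids, test_ids)`` tuples (one per
    CV fold; a single tuple for scaffold splits).  ``scaffold_map`` is
    populated by the scaffold scheme.
    """

    scheme: str
    folds: list[tuple[list[str], list[str], list[str]]]
    seed: int
    scaffold_map: dict[str, str] | None = None

    def validate(self, all_ids: set[str]) -> None:
        for train, val, test in self.folds:
            parts = [set(train), set(val), set(test)]
            union = parts[0] | parts[1] | parts[2]
            if union != all_ids:
                raise AssertionError("fold does not cover all ids")
            if sum(len(p) for p in parts) != len(all_ids):
                raise AssertionError("fold partitions overlap")


def adapted_cv_folds(ids: list[str], config: SplitConfig | None = None
                     ) -> SplitPlan:
    """Adapted k-fold cross-validation plan.

    Ids are shuffled by ``config.seed`` into k near-equal folds.  For
    test fold t the validation fold is (t − 1) mod k and the remaining
    k − 2 folds train, yielding exactly k (train, val, test) tuples in
    which every id is tested exactly once.
    """
    if config is None:
        config = SplitConfig()
    ids = list(ids)
    if len(ids) < config.k:
        raise ValueError(f"need at least k={config.k} ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    rng = np.random.default_rng(config.seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    folds = [list(f) for f in np.array_split(np.array(shuffled, dtype=object),
                                             config.k)]
    tuples = []
    for t in range(config.k):
        val_idx = (t - 1) % config.k
        train = [cid for j in range(config.k) if j not in (t, val_idx)
                 for cid in folds[j]]
        tuples.append((train, list(folds[val_idx]), list(folds[t])))
    plan = SplitPlan(scheme="adapted_cv", folds=tuples, seed=config.seed)
    plan.validate(set(ids))
    return plan


def murcko_scaffold(record: CompoundRecord | str) -> str:
    """Canonical SMILES of the Bemis-Murcko framework.

    Ring systems plus their connecting linkers, side chains removed;
    acyclic molecules yield the empty scaffold ``""``.  Atom and bond
    types are retained (generic framework, not the carbon-skeleton
    abstraction).
    """
    smiles = record.smiles if isinstance(record, CompoundRecord) else record
    mol, err = parse_smiles(smiles)
    if mol is None:
        raise ValueError(f"cannot compute scaffold: {err} for {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def scaffold_split(records: list[CompoundRecord],
                   config: SplitConfig | None = None) -> SplitPlan:
    """Scaffold-disjoint train/validation/test split.

    Compounds are binned by scaffold string (the empty scaffold is one
    bin).  Bins holding more than ``big_bin_fraction`` of the library
    are forced into training; the remaining bins are assigned greedily
    — descending size, ties by scaffold string — to whichever partition
    is furthest below its ``ratio`` target.
    """
    if config is None:
        config = SplitConfig()
    bins: dict[str, list[str]] = {}
    scaffold_map: dict[str, str] = {}
    for rec in records:
        scaf = murcko_scaffold(rec)
        scaffold_map[rec.compound_id] = scaf
        bins.setdefault(scaf, []).append(rec.compound_id)
    if len(bins) < 3:
        raise ValueError("insufficient-scaffolds: need at least 3 scaffold bins")

    n_total = len(records)
    targets = np.array(config.ratio, dtype=float)
    targets = targets / targets.sum() * n_total
    partitions: list[list[str]] = [[], [], []]  # train, val, test

    forced = {scaf for scaf, members in bins.items()
              if len(members) > config.big_bin_fraction * n_total}
    for scaf in sorted(forced):
        partitions[0].extend(bins[scaf])

    remaining = sorted((s for s in bins if s not in forced),
                       key=lambda s: (-len(bins[s]), s))
    for scaf in remaining:
        deficits = targets - np.array([len(p) for p in partitions])
        # ties broken toward train, then val (argmax picks first maximum)
        partitions[np.argmax(deficits)].extend(bins[scaf])

    plan = SplitPlan(
        scheme="scaffold",
        folds=[(sorted(partitions[0]), sorted(partitions[1]),
                sorted(partitions[2]))],
        seed=config.seed,
        scaffold_map=scaffold_map,
    )
    plan.validate({r.compound_id for r in records})
    return plan
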