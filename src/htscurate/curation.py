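"""Hierarchical HTS curation: deduplication, label assignment, filters.

The pipeline mirrors how a medicinal chemist triages a raw screening
deposit before any model sees it:

1.  **dedup** — triple-keyed duplicate removal (compound id, canonical
    isomeric SMILES, standard InChI);
2.  **hierarchy** — final active/inactive labels from the
    primary/confirmatory/counter screen structure;
3.  **parse** — structures must survive a standard valence model;
4.  **inorganic** — carbon-free or exotic-element substances go;
5.  **mixture** — '.'-separated multi-component entries are collapsed,
    resolved to a single druglike component, or discarded as ambiguous;
6.  **neutralize** — isolated formal charges are zeroed atom-by-atom;
7.  **aromatize** — kekulized rings are normalized to aromatic form;
8.  **pains** — pan-assay interference substructure matches go;
9.  **druglikeness** — Lipinski Rule-of-Five screening;
10. **flags** — remaining audit flags are reported for human review
    (strict mode turns them into exclusions).

Every exclusion is attributed to the first failing stage in a
:class:`CurationReport`, and counts are conserved at every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import FilterCatalog
from rdkit.Chem.FilterCatalog import FilterCatalogParams

from .chem import (
    canonical_smiles,
    is_organic,
    mol_to_inchi,
    molecular_weight,
    parse_smiles,
    ro5_violations,
)
from .types import CompoundRecord, Outcome, ScreenHierarchy, Stage

#: Pipeline stages in execution order.
STAGE_ORDER = (
    "dedup", "hierarchy", "parse", "inorganic", "mixture",
    "neutralize", "aromatize", "pains", "druglikeness", "flags",
)

#: Mapping from interference-layer names to the published PAINS
#: catalog families shipped with RDKit.
PAINS_LAYERS = {
    "promiscuity": FilterCatalogParams.FilterCatalogs.PAINS_A,
    "optical_interference": FilterCatalogParams.FilterCatalogs.PAINS_B,
    "other_interference": FilterCatalogParams.FilterCatalogs.PAINS_C,
}


@dataclass(frozen=True)
class CurationConfig:
    """Tunable knobs of the curation pipeline.

    Parameters
    ----------
    mixture_mw_tolerance
        Mixtures whose closest component pair differs by at most this
        many daltons are discarded as ambiguous (default 5 Da).
    ro5_max_violations
        Rule-of-Five violations tolerated before a compound fails the
        druglikeness filter; 1 per Lipinski's original formulation,
        configurable to 0.
    pains_layers
        Enabled interference layers (subset of
        ``{"promiscuity", "optical_interference", "other_interference"}``).
    unconfirmed_policy
        Disposition of primary-actives never confirmed: ``"drop"``
        (default; they are ambiguous, not negatives) or ``"inactive"``.
    strict
        If True, audit flags become exclusions at the final stage.
    """

    mixture_mw_tolerance: float = 5.0
    ro5_max_violations: int = 1
    pains_layers: frozenset[str] = frozenset(PAINS_LAYERS)
    unconfirmed_policy: str = "drop"
    strict: bool = False

    def __post_init__(self) -> None:
        if self.mixture_mw_tolerance < 0:
            raise ValueError("mixture_mw_tolerance must be >= 0")
        if self.ro5_max_violations not in (0, 1):
            raise ValueError("ro5_max_violations must be 0 or 1")
        unknown = set(self.pains_layers) - set(PAINS_LAYERS)
        if unknown:
            raise ValueError(f"unknown PAINS layers: {sorted(unknown)}")
        if self.unconfirmed_policy not in ("drop", "inactive"):
            raise ValueError("unconfirmed_policy must be 'drop' or 'inactive'")


@dataclass
class CurationReport:
    """Per-stage exclusion ledger.

    ``stage_counts`` maps stage name (in pipeline order) to
    ``(n_in, n_out, n_excluded)``; ``exclusions`` lists
    ``(compound_id, stage, reason)`` triples.
    """

    stage_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)

    def record_stage(self, stage: str, n_in: int,
                     excluded: list[tuple[str, str]]) -> None:
        self.stage_counts[stage] = (n_in, n_in - len(excluded), len(excluded))
        self.exclusions.extend((cid, stage, reason) for cid, reason in excluded)

    def excluded_at(self, stage: str) -> int:
        return self.stage_counts.get(stage, (0, 0, 0))[2]

    def validate(self) -> None:
        for stage, (n_in, n_out, n_exc) in self.stage_counts.items():
            if n_in != n_out + n_exc:
                raise AssertionError(f"count leak at stage {stage}")
        ids = [cid for cid, _, _ in self.exclusions]
        if len(ids) != len(set(ids)):
            raise AssertionError("a compound was excluded more than once")


@dataclass
class CuratedDataset:
    """Final curated records (binary labels) plus the audit report."""

    records: list[CompoundRecord]
    report: CurationReport
    version: str = "1"

    @property
    def actives(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.label == "active"]

    @property
    def inactives(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.label == "inactive"]


# ---------------------------------------------------------------------------
# Stage 1: duplicate removal

def deduplicate(records: list[CompoundRecord]) -> tuple[
        list[CompoundRecord], list[tuple[str, str]]]:
    """Triple-keyed duplicate removal.

    Records are grouped as duplicates when they share a compound id, a
    canonical isomeric SMILES, or a standard InChI (union across the
    three keys).  Within a group with identical outcomes the
    lexicographically smallest compound id is kept; groups whose members
    disagree on any outcome are excluded entirely
    (``"conflicting-duplicate"``).
    """
    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    keymaps: list[dict[str, int]] = [{}, {}, {}]
    for idx, rec in enumerate(records):
        can = canonical_smiles(rec.smiles) if rec.smiles else None
        for slot, key in enumerate((rec.compound_id, can, rec.inchi or None)):
            if not key:
                continue
            if key in keymaps[slot]:
                union(idx, keymaps[slot][key])
            else:
                keymaps[slot][key] = idx

    groups: dict[int, list[int]] = {}
    for idx in range(len(records)):
        groups.setdefault(find(idx), []).append(idx)

    kept: list[CompoundRecord] = []
    excluded: list[tuple[str, str]] = []
    for members in groups.values():
        if len(members) == 1:
            kept.append(records[members[0]])
            continue
        outcome_sets = {
            tuple(sorted((k, v.value) for k, v in records[i].outcomes.items()))
            for i in members
        }
        ordered = sorted(members, key=lambda i: records[i].compound_id)
        if len(outcome_sets) > 1:
            excluded.extend((records[i].compound_id, "conflicting-duplicate")
                            for i in ordered)
        else:
            kept.append(records[ordered[0]])
            excluded.extend((records[i].compound_id, "duplicate")
                            for i in ordered[1:])
    # preserve input order among the kept records
    kept_ids = {id(r) for r in kept}
    return [r for r in records if id(r) in kept_ids], excluded


# ---------------------------------------------------------------------------
# Stage 2: hierarchical label assignment

def _disposition(rec: CompoundRecord, hierarchy: ScreenHierarchy,
                 config: CurationConfig) -> tuple[str | None, str | None]:
    """Return ``(label, exclusion_reason)`` for one record.

    Exactly one of the two is non-None.  A compound is finally active
    iff it is active in a primary screen, active in a confirmatory
    screen linked below that primary, and not active in any linked
    counter screen.
    """
    primaries = hierarchy.screens(Stage.PRIMARY)
    primary_outcomes = [rec.outcomes.get(p, Outcome.UNTESTED) for p in primaries]
    if all(o is Outcome.UNTESTED for o in primary_outcomes):
        return None, "no-primary-result"
    if not any(o is Outcome.ACTIVE for o in primary_outcomes):
        if any(o is Outcome.INACTIVE for o in primary_outcomes):
            return "inactive", None
        return None, "inconclusive-primary"

    confirmed = False
    countered = False
    for prim in primaries:
        if rec.outcomes.get(prim, Outcome.UNTESTED) is not Outcome.ACTIVE:
            continue
        confirmatories = hierarchy.linked_screens(prim, Stage.CONFIRMATORY)
        counters = hierarchy.linked_screens(prim, Stage.COUNTER)
        # a primary with no confirmatory layer confirms itself
        branch_confirmed = (not confirmatories) or any(
            rec.outcomes.get(c, Outcome.UNTESTED) is Outcome.ACTIVE
            for c in confirmatories)
        branch_countered = any(
            rec.outcomes.get(c, Outcome.UNTESTED) is Outcome.ACTIVE
            for c in counters)
        if branch_confirmed and branch_countered:
            countered = True
        elif branch_confirmed:
            confirmed = True
    if countered and not confirmed:
        return None, "counter-active"
    if confirmed:
        return "active", None
    if config.unconfirmed_policy == "inactive":
        return "inactive", None
    return None, "unconfirmed-active"


def assign_hierarchical_labels(
        records: list[CompoundRecord], hierarchy: ScreenHierarchy,
        config: CurationConfig) -> tuple[list[CompoundRecord],
                                         list[tuple[str, str]]]:
    """Assign final binary labels by walking the screen hierarchy.

    Raises ``ValueError`` when a record carries an outcome for a screen
    the hierarchy does not declare.
    """
    labeled: list[CompoundRecord] = []
    excluded: list[tuple[str, str]] = []
    declared = hierarchy.screen_ids
    for rec in records:
        unknown = set(rec.outcomes) - declared
        if unknown:
            raise ValueError(
                f"{rec.compound_id}: outcomes for undeclared screens "
                f"{sorted(unknown)}")
        label, reason = _disposition(rec, hierarchy, config)
        if label is None:
            excluded.append((rec.compound_id, reason))
        else:
            out = rec.copy()
            out.label = label
            labeled.append(out)
    return labeled, excluded


# ---------------------------------------------------------------------------
# Structural filters (stages 3-9)

def filter_parse(record: CompoundRecord) -> tuple[bool, str | None]:
    """Parse the SMILES under the standard valence model.

    When both SMILES and InChI are present and the InChI regenerated
    from the parsed structure disagrees with the deposited one, the
    record is flagged ``"representation-mismatch"`` (excluded only in
    strict mode, at the flag-review stage).
    """
    mol, err = parse_smiles(record.smiles)
    if mol is None:
        return False, err or "parse-error"
    if record.inchi and record.inchi.startswith("InChI=1S/"):
        regenerated = mol_to_inchi(mol)
        if regenerated is not None and regenerated != record.inchi:
            record.flags.add("representation-mismatch")
    return True, None


def filter_inorganic(record: CompoundRecord) -> tuple[bool, str | None]:
    """Reject carbon-free substances and exotic elements.

    A molecule passes iff it contains at least one carbon atom and only
    elements from the documented organic set
    (:data:`htscurate.chem.ORGANIC_ELEMENTS`).  For multi-component
    records the whole-record check passes when *any* component passes;
    single-component salvage belongs to the mixture stage that follows.
    """
    parts = [p for p in record.smiles.split(".") if p]
    for part in parts:
        mol, _ = parse_smiles(part)
        if mol is not None and is_organic(mol):
            return True, None
    return False, "inorganic"


def _component_druglike(mol, config: CurationConfig) -> bool:
    return len(ro5_violations(mol)) <= config.ro5_max_violations


def resolve_mixture(record: CompoundRecord, config: CurationConfig
                    ) -> tuple[CompoundRecord | None, str | None]:
    """Resolve a '.'-separated multi-component entry to one molecule.

    Rules, in order: identical components collapse to one; if the
    closest pair of distinct components differs by at most
    ``mixture_mw_tolerance`` daltons the mixture is discarded as
    ambiguous; otherwise components are filtered for organic character
    and druglikeness — exactly one survivor is kept, zero survivors
    drop the record, multiple survivors keep the heaviest with flag
    ``"mixture-multisurvivor"``.
    """
    parts = [p for p in record.smiles.split(".") if p]
    if len(parts) <= 1:
        return record, None

    unique: dict[str, object] = {}
    for part in parts:
        mol, err = parse_smiles(part)
        if mol is None:
            return None, f"mixture-component-{err}"
        unique.setdefault(Chem.MolToSmiles(mol), mol)

    def _with_smiles(smiles: str, flag: str | None = None) -> CompoundRecord:
        out = record.copy()
        out.smiles = smiles
        out.inchi = mol_to_inchi(parse_smiles(smiles)[0]) or ""
        if flag:
            out.flags.add(flag)
        return out

    if len(unique) == 1:
        return _with_smiles(next(iter(unique))), None

    weights = {smi: molecular_weight(mol) for smi, mol in unique.items()}
    ordered = sorted(weights.values())
    min_gap = min(b - a for a, b in zip(ordered, ordered[1:]))
    if min_gap <= config.mixture_mw_tolerance:
        return None, "ambiguous-mixture"

    survivors = [smi for smi, mol in unique.items()
                 if is_organic(mol) and _component_druglike(mol, config)]
    if not survivors:
        return None, "no-druglike-component"
    if len(survivors) == 1:
        return _with_smiles(survivors[0]), None
    heaviest = max(survivors, key=lambda smi: weights[smi])
    return _with_smiles(heaviest, "mixture-multisurvivor"), None


#: SMARTS for atoms carrying an isolated formal charge: charged, with a
#: hydrogen to remove (cations) or room to add one (anions), and not
#: bonded to an oppositely charged neighbor (keeps nitro, N-oxides,
#: betaines and other internally compensated groups intact).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]")


def neutralize_charges(record: CompoundRecord
                       ) -> tuple[CompoundRecord, str | None]:
    """Neutralize isolated formal charges atom-by-atom.

    Each charged atom without an oppositely charged bonded neighbor has
    its charge zeroed and its hydrogen count adjusted.  If the result
    fails revalidation the original record is kept with flag
    ``"neutralization-failed"``.
    """
    mol, err = parse_smiles(record.smiles)
    if mol is None:
        return record, err
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return record, None
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(0, h_count - charge))
        atom.SetNoImplicit(False)
        atom.UpdatePropertyCache(strict=False)
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        smiles = Chem.MolToSmiles(out)
        check, err = parse_smiles(smiles)
        if check is None:
            raise ValueError(err)
    except Exception:
        flagged = record.copy()
        flagged.flags.add("neutralization-failed")
        return flagged, None
    neutral = record.copy()
    neutral.smiles = smiles
    neutral.inchi = mol_to_inchi(out) or ""
    return neutral, None


def aromatize(record: CompoundRecord) -> tuple[CompoundRecord, str | None]:
    """Normalize kekulized ring systems to aromatic form.

    Canonicalization under RDKit's default aromaticity perception maps
    alternating single/double ring bonds onto aromatic bonds; acyclic
    and non-aromatic systems come back unchanged (up to canonical atom
    ordering).  On perception failure the record keeps its kekulized
    form with flag ``"aromatization-failed"``.
    """
    mol, err = parse_smiles(record.smiles)
    if mol is None:
        flagged = record.copy()
        flagged.flags.add("aromatization-failed")
        return flagged, None
    out = record.copy()
    out.smiles = Chem.MolToSmiles(mol)
    if not out.inchi:
        out.inchi = mol_to_inchi(mol) or ""
    return out, None


def _build_pains_catalog(layers: frozenset[str]) -> FilterCatalog.FilterCatalog:
    params = FilterCatalogParams()
    for layer in sorted(layers):
        params.AddCatalog(PAINS_LAYERS[layer])
    return FilterCatalog.FilterCatalog(params)


_CATALOG_CACHE: dict[frozenset[str], FilterCatalog.FilterCatalog] = {}


def filter_pains(record: CompoundRecord, config: CurationConfig
                 ) -> tuple[bool, list[str]]:
    """Match against the PAINS substructure catalog.

    Returns ``(passed, matched_pattern_names)``; pattern names carry
    their layer, e.g. ``"promiscuity:quinone_A(370)"``.
    """
    mol, _ = parse_smiles(record.smiles)
    if mol is None:
        return True, []
    matched: list[str] = []
    for layer in sorted(config.pains_layers):
        key = frozenset([layer])
        if key not in _CATALOG_CACHE:
            _CATALOG_CACHE[key] = _build_pains_catalog(key)
        for entry in _CATALOG_CACHE[key].GetMatches(mol):
            matched.append(f"{layer}:{entry.GetDescription()}")
    return not matched, matched


def filter_druglikeness(record: CompoundRecord, config: CurationConfig
                        ) -> tuple[bool, list[str]]:
    """Lipinski Rule-of-Five check.

    Violations counted over MW > 500 Da, logP > 5, H-bond donors > 5,
    H-bond acceptors > 10; fail iff violations exceed
    ``config.ro5_max_violations``.
    """
    mol, _ = parse_smiles(record.smiles)
    if mol is None:
        return True, []
    violations = ro5_violations(mol)
    return len(violations) <= config.ro5_max_violations, violations


# ---------------------------------------------------------------------------
# The full pipeline

def run_curation_pipeline(records: list[CompoundRecord],
                          hierarchy: ScreenHierarchy,
                          config: CurationConfig | None = None
                          ) -> CuratedDataset:
    """Run the full curation pipeline and return a labeled dataset.

    Stages run in :data:`STAGE_ORDER`; every exclusion is attributed to
    the first failing stage, and the report conserves counts at every
    stage.  Inputs are never mutated.
    """
    if config is None:
        config = CurationConfig()
    report = CurationReport()
    current = [r.copy() for r in records]

    current_after_dedup, excluded = deduplicate(current)
    report.record_stage("dedup", len(current), excluded)
    current = current_after_dedup

    labeled, excluded = assign_hierarchical_labels(current, hierarchy, config)
    report.record_stage("hierarchy", len(current), excluded)
    current = labeled

    kept, excluded = [], []
    for rec in current:
        ok, reason = filter_parse(rec)
        (kept.append(rec) if ok else excluded.append((rec.compound_id, reason)))
    report.record_stage("parse", len(current), excluded)
    current = kept

    kept, excluded = [], []
    for rec in current:
        ok, reason = filter_inorganic(rec)
        (kept.append(rec) if ok else excluded.append((rec.compound_id, reason)))
    report.record_stage("inorganic", len(current), excluded)
    current = kept

    kept, excluded = [], []
    for rec in current:
        resolved, reason = resolve_mixture(rec, config)
        if resolved is None:
            excluded.append((rec.compound_id, reason))
        else:
            kept.append(resolved)
    report.record_stage("mixture", len(current), excluded)
    current = kept

    kept, excluded = [], []
    for rec in current:
        neutral, err = neutralize_charges(rec)
        if err is not None:
            excluded.append((rec.compound_id, err))
        else:
            kept.append(neutral)
    report.record_stage("neutralize", len(current), excluded)
    current = kept

    kept, excluded = [], []
    for rec in current:
        aromatic, err = aromatize(rec)
        if err is not None:
            excluded.append((rec.compound_id, err))
        else:
            kept.append(aromatic)
    report.record_stage("aromatize", len(current), excluded)
    current = kept

    kept, excluded = [], []
    for rec in current:
        ok, patterns = filter_pains(rec, config)
        if ok:
            kept.append(rec)
        else:
            excluded.append((rec.compound_id, "pains:" + patterns[0]))
    report.record_stage("pains", len(current), excluded)
    current = kept

    kept, excluded = [], []
    for rec in current:
        ok, violations = filter_druglikeness(rec, config)
        if ok:
            kept.append(rec)
        else:
            excluded.append((rec.compound_id, "ro5:" + ",".join(violations)))
    report.record_stage("druglikeness", len(current), excluded)
    current = kept

    kept, excluded = [], []
    for rec in current:
        if config.strict and rec.flags:
            excluded.append((rec.compound_id, "flagged:" + ",".join(sorted(rec.flags))))
        else:
            kept.append(rec)
    report.record_stage("flags", len(current), excluded)
    current = kept

    report.validate()
    n_flagged = sum(1 for r in current if r.flags)
    if n_flagged:
        warnings.warn(f"{n_flagged} curated records carry audit flags "
                      "pending expert review")
    return CuratedDataset(records=current, report=report)
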