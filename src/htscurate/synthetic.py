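"""Synthetic HTS campaigns with ground truth.

Emulates a PubChem-style screening deposit — hundreds to thousands of
compounds, a sub-1% true hit rate, a loose primary threshold with a
high false-positive rate — with every data pathology the curation
pipeline exists to catch planted at exact, known counts: duplicate
CIDs, ambiguous mixtures, salt adducts, charged species, pan-assay
interference (PAINS) substructures, and Rule-of-Five violators.

The compound library is assembled from a hand-curated vocabulary of
drug-like aromatic cores and substituents, so each molecule's fate in
every structural filter is provable by construction; generative realism
is deliberately not a goal.  :func:`expected_curation_counts` replays
each record's fate analytically from its planted tag and simulated
outcomes, giving an exact per-stage oracle for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import is_organic, molecular_weight, parse_smiles, ro5_violations
from .curation import CurationConfig, filter_pains
from .types import (
    CompoundRecord,
    Outcome,
    ScreenHierarchy,
    ScreenNode,
    Stage,
)

ARTIFACT_KINDS = ("duplicates", "mixtures", "salts", "charged",
                  "pains_like", "ro5_violators")

PRIMARY_SCREEN = "primary-1"
CONFIRMATORY_SCREEN = "confirm-1"
COUNTER_SCREEN = "counter-1"


def default_hierarchy() -> ScreenHierarchy:
    """One primary, one confirmatory, one counter screen in a chain."""
    return ScreenHierarchy([
        ScreenNode(PRIMARY_SCREEN, Stage.PRIMARY,
                   description="primary single-point screen"),
        ScreenNode(CONFIRMATORY_SCREEN, Stage.CONFIRMATORY,
                   (PRIMARY_SCREEN,), "dose-response confirmation"),
        ScreenNode(COUNTER_SCREEN, Stage.COUNTER,
                   (CONFIRMATORY_SCREEN,), "off-target counter screen"),
    ])


@dataclass(frozen=True)
class CampaignSpec:
    """Parameters of a simulated screening campaign.

    Rates are probabilities in [0, 1]; ``artifact_counts`` maps artifact
    kinds (:data:`ARTIFACT_KINDS`) to exact planted counts.  Defaults
    reflect a realistic campaign: a sub-1% hit rate and a loose primary
    threshold with ~30% false positives among called actives' base rate.
    """

    n_compounds: int = 2000
    true_hit_rate: float = 0.005
    primary_fp_rate: float = 0.3
    primary_fn_rate: float = 0.01
    counter_cross_react_rate: float = 0.1
    artifact_counts: dict[str, int] = field(default_factory=lambda: {
        "duplicates": 20, "mixtures": 20, "salts": 30,
        "charged": 30, "pains_like": 15, "ro5_violators": 15,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.true_hit_rate, self.primary_fp_rate,
                     self.primary_fn_rate, self.counter_cross_react_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        unknown = set(self.artifact_counts) - set(ARTIFACT_KINDS)
        if unknown:
            raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")
        if any(c < 0 for c in self.artifact_counts.values()):
            raise ValueError("artifact counts must be non-negative")
        if sum(self.artifact_counts.values()) > self.n_compounds:
            raise ValueError("artifact counts exceed n_compounds")

    def count(self, kind: str) -> int:
        return self.artifact_counts.get(kind, 0)


@dataclass
class SyntheticCampaign:
    """A generated library plus ground truth.

    ``truth`` maps compound id to ``{"true_active": bool,
    "artifact": tag-or-None}``; ``expected`` (set once screens are
    simulated) maps pipeline stage to the exact expected exclusion
    count under the default curation configuration.
    """

    records: list[CompoundRecord]
    hierarchy: ScreenHierarchy
    truth: dict[str, dict]
    spec: CampaignSpec
    expected: dict[str, int] | None = None

    @property
    def true_active_ids(self) -> set[str]:
        return {cid for cid, t in self.truth.items() if t["true_active"]}


# ---------------------------------------------------------------------------
# Fragment vocabulary

_MONO_TEMPLATES = (
    "c1ccc({R})cc1",
    "Cc1ccc({R})cc1",
    "COc1ccc({R})cc1",
    "Fc1ccc({R})cc1",
    "Clc1ccc({R})cc1",
    "c1ccnc({R})c1",
    "c1csc({R})c1",
    "c1coc({R})c1",
    "O=C(C{R})c1ccccc1",
    "c1ccc2c(c1)cccc2{R}",
)

_DI_TEMPLATES = (
    "c1cc({R1})ccc1{R2}",
    "c1cc({R1})cc({R2})c1",
    "c1nc({R1})ccc1{R2}",
    "c1cc({R1})sc1{R2}",
    "C({R1})({R2})c1ccccc1",
)

_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CC(C)C", "CCO", "CO", "CN", "CCN",
    "C(C)=O", "C(N)=O", "C(=O)OC", "C(=O)O", "CNC", "F", "Cl", "Br",
    "C#N", "OC", "OCC", "N(C)C", "CCOC", "C(F)(F)F", "CS(C)(=O)=O",
    "CC#N", "CCF",
)

#: Catechol scaffolds substituted around the ring: every member matches
#: the PAINS optical-interference catalog by construction.
_PAINS_TEMPLATES = ("Oc1ccc({R})cc1O", "Oc1cc({R})ccc1O")

_SALT_SUFFIXES = (".[Na+].[Cl-]", ".Cl", ".[K+].[Br-]", ".Br")

_library_cache: dict[str, list] = {}


def _passes_clean_filters(smiles: str) -> bool:
    """A clean-library candidate must pass every structural filter."""
    mol, err = parse_smiles(smiles)
    if mol is None or "." in smiles:
        return False
    if not is_organic(mol):
        return False
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        return False
    if ro5_violations(mol):
        return False
    probe = CompoundRecord(compound_id="probe", smiles=smiles)
    ok, _ = filter_pains(probe, CurationConfig())
    return ok


def _clean_pool() -> list[str]:
    """Canonical SMILES of all vocabulary products passing every filter.

    Deterministic (template order then lexicographic) and cached: the
    pool depends only on the vocabulary, not on any seed.
    """
    if "clean" in _library_cache:
        return _library_cache["clean"]
    seen: dict[str, None] = {}
    candidates = [t.format(R=s) for t in _MONO_TEMPLATES for s in _SUBSTITUENTS]
    candidates += [t.format(R1=a, R2=b) for t in _DI_TEMPLATES
                   for a in _SUBSTITUENTS for b in _SUBSTITUENTS]
    for smi in candidates:
        if not _passes_clean_filters(smi):
            continue
        mol, _ = parse_smiles(smi)
        seen.setdefault(Chem.MolToSmiles(mol), None)
    pool = sorted(seen)
    _library_cache["clean"] = pool
    return pool


def _pains_pool() -> list[str]:
    """Distinct catechol-family molecules that match the PAINS catalog."""
    if "pains" in _library_cache:
        return _library_cache["pains"]
    seen: dict[str, None] = {}
    for template in _PAINS_TEMPLATES:
        for sub in _SUBSTITUENTS:
            smi = template.format(R=sub)
            mol, err = parse_smiles(smi)
            if mol is None:
                continue
            probe = CompoundRecord(compound_id="probe", smiles=smi)
            ok, _ = filter_pains(probe, CurationConfig())
            if ok:
                continue
            seen.setdefault(Chem.MolToSmiles(mol), None)
    pool = sorted(seen)
    _library_cache["pains"] = pool
    return pool


def _ro5_violator(index: int) -> str:
    """A long alkane: MW > 500 and logP > 5 gives two Ro5 violations."""
    return "C" * (36 + index)


def _charged_species(index: int) -> str:
    """Alternating alkyl carboxylates and ammonium ions."""
    k = 4 + index // 2
    if index % 2 == 0:
        return "C" * k + "C(=O)[O-]"
    return "C" * k + "C[NH3+]"


def _record(cid: str, smiles: str) -> CompoundRecord:
    mol, err = parse_smiles(smiles)
    inchi = ""
    if mol is not None:
        try:
            inchi = Chem.MolToInchi(mol) or ""
        except Exception:
            inchi = ""
    return CompoundRecord(compound_id=cid, smiles=smiles, inchi=inchi)


def generate_library(spec: CampaignSpec) -> SyntheticCampaign:
    """Build a synthetic compound library with planted artifacts.

    Every artifact kind is planted at exactly its requested count, all
    on truly inactive compounds so that structural exclusions never
    collide with the active set.  True actives are drawn from the clean
    pool at ``true_hit_rate``.  Deterministic under ``spec.seed``.
    Outcomes are left unset; see :func:`simulate_screens`.
    """
    rng = np.random.default_rng(spec.seed)
    clean_pool = list(_clean_pool())
    pains_pool = list(_pains_pool())

    n_special = sum(spec.count(k) for k in ARTIFACT_KINDS)
    n_clean = spec.n_compounds - n_special
    if spec.count("pains_like") > len(pains_pool):
        raise ValueError(
            f"at most {len(pains_pool)} distinct PAINS-like compounds available")

    # clean structures + mixture components + salt bases, all disjoint
    n_structures = (n_clean + 2 * spec.count("mixtures")
                    + spec.count("salts"))
    if n_structures > len(clean_pool):
        raise ValueError(
            f"vocabulary supports at most {len(clean_pool)} distinct "
            f"structures; requested {n_structures}")
    chosen = rng.permutation(len(clean_pool))[:n_structures]
    structures = [clean_pool[i] for i in chosen]
    clean_smiles = structures[:n_clean]
    cursor = n_clean

    records: list[CompoundRecord] = []
    truth: dict[str, dict] = {}
    counter = iter(range(10 ** 6))

    def add(smiles: str, artifact: str | None, active: bool = False) -> CompoundRecord:
        cid = f"SYN{next(counter):06d}"
        rec = _record(cid, smiles)
        records.append(rec)
        truth[cid] = {"true_active": active, "artifact": artifact}
        return rec

    n_active = int(round(spec.true_hit_rate * spec.n_compounds))
    if n_active > n_clean:
        raise ValueError("true_hit_rate leaves no room next to artifacts")
    active_slots = set(rng.choice(n_clean, size=n_active, replace=False).tolist())
    for i, smi in enumerate(clean_smiles):
        add(smi, None, active=i in active_slots)

    # duplicates: verbatim copies of clean inactive records under new CIDs
    inactive_clean = [r for i, r in enumerate(records) if i not in active_slots]
    if spec.count("duplicates") > len(inactive_clean):
        raise ValueError("not enough clean inactives to duplicate")
    dup_sources = rng.choice(len(inactive_clean),
                             size=spec.count("duplicates"), replace=False)
    for i in sorted(dup_sources.tolist()):
        src = inactive_clean[i]
        dup = add(src.smiles, "duplicate")
        dup.inchi = src.inchi
        truth[dup.compound_id]["source"] = src.compound_id

    # ambiguous mixtures: two distinct components within 5 Da of each other
    pairs = _close_mw_pairs(structures[cursor:cursor + 2 * spec.count("mixtures")],
                            spec.count("mixtures"), clean_pool, structures)
    cursor += 2 * spec.count("mixtures")
    for a, b in pairs:
        add(f"{a}.{b}", "mixture")

    # salt adducts: clean organic + inorganic counter-ions; the organic
    # component survives mixture resolution
    for i in range(spec.count("salts")):
        base = structures[cursor]
        cursor += 1
        add(base + _SALT_SUFFIXES[i % len(_SALT_SUFFIXES)], "salt")

    for i in range(spec.count("charged")):
        add(_charged_species(i), "charged")

    pains_idx = rng.permutation(len(pains_pool))[:spec.count("pains_like")]
    for i in sorted(pains_idx.tolist()):
        add(pains_pool[i], "pains")

    for i in range(spec.count("ro5_violators")):
        add(_ro5_violator(i), "ro5")

    assert len(records) == spec.n_compounds
    return SyntheticCampaign(records=records, hierarchy=default_hierarchy(),
                             truth=truth, spec=spec)


def _close_mw_pairs(reserved: list[str], n_pairs: int,
                    pool: list[str], used: list[str]) -> list[tuple[str, str]]:
    """Pair reserved structures so each pair differs by ≤ 5 Da.

    Reserved structures are re-paired by molecular weight; when a
    neighbor gap exceeds the tolerance, a partner within 5 Da is pulled
    from the unused remainder of the pool.
    """
    if n_pairs == 0:
        return []
    weights = {s: molecular_weight(parse_smiles(s)[0]) for s in reserved}
    ordered = sorted(reserved, key=lambda s: (weights[s], s))
    pairs: list[tuple[str, str]] = []
    spare: list[str] = []
    i = 0
    while i + 1 < len(ordered) and len(pairs) < n_pairs:
        a, b = ordered[i], ordered[i + 1]
        if abs(weights[a] - weights[b]) <= 5.0:
            pairs.append((a, b))
            i += 2
        else:
            spare.append(a)
            i += 1
    spare.extend(ordered[i:])
    if len(pairs) < n_pairs:
        # fall back to partners drawn from the unused pool
        unused = [s for s in pool if s not in set(used)]
        unused_w = sorted(((molecular_weight(parse_smiles(s)[0]), s)
                           for s in unused))
        for a in spare:
            if len(pairs) == n_pairs:
                break
            wa = weights[a]
            partner = next((s for w, s in unused_w if abs(w - wa) <= 5.0
                            and s != a), None)
            if partner is None:
                raise ValueError("cannot assemble enough ambiguous mixtures")
            unused_w = [(w, s) for w, s in unused_w if s != partner]
            pairs.append((a, partner))
    if len(pairs) < n_pairs:
        raise ValueError("cannot assemble enough ambiguous mixtures")
    return pairs


def simulate_screens(campaign: SyntheticCampaign,
                     spec: CampaignSpec | None = None) -> SyntheticCampaign:
    """Fill in per-screen outcomes from the ground truth.

    Primary outcomes are the true activity corrupted by the false
    positive/negative rates; the confirmatory screen runs only on
    primary actives and reports the truth; the counter screen runs on
    confirmed actives and fires on a ``counter_cross_react_rate``
    subset.  Compounds never reaching a screen stay untested.  Also
    fills ``campaign.expected`` with the exact per-stage exclusion
    oracle.  Deterministic under ``spec.seed``.
    """
    if spec is None:
        spec = campaign.spec
    rng = np.random.default_rng([spec.seed, 1])
    by_id = {r.compound_id: r for r in campaign.records}
    for rec in campaign.records:
        # planted duplicates re-report their source compound's outcomes
        if campaign.truth[rec.compound_id].get("source"):
            continue
        active = campaign.truth[rec.compound_id]["true_active"]
        if active:
            primary = (Outcome.INACTIVE if rng.random() < spec.primary_fn_rate
                       else Outcome.ACTIVE)
        else:
            primary = (Outcome.ACTIVE if rng.random() < spec.primary_fp_rate
                       else Outcome.INACTIVE)
        outcomes = {PRIMARY_SCREEN: primary,
                    CONFIRMATORY_SCREEN: Outcome.UNTESTED,
                    COUNTER_SCREEN: Outcome.UNTESTED}
        if primary is Outcome.ACTIVE:
            confirmed = Outcome.ACTIVE if active else Outcome.INACTIVE
            outcomes[CONFIRMATORY_SCREEN] = confirmed
            if confirmed is Outcome.ACTIVE:
                outcomes[COUNTER_SCREEN] = (
                    Outcome.ACTIVE
                    if rng.random() < spec.counter_cross_react_rate
                    else Outcome.INACTIVE)
        rec.outcomes = outcomes
    for rec in campaign.records:
        source = campaign.truth[rec.compound_id].get("source")
        if source:
            rec.outcomes = dict(by_id[source].outcomes)
    campaign.expected = expected_curation_counts(campaign)
    return campaign


def expected_curation_counts(campaign: SyntheticCampaign,
                             config: CurationConfig | None = None
                             ) -> dict[str, int]:
    """Exact expected per-stage exclusion counts for the pipeline.

    Walks each record through the stage order analytically, using only
    the planted artifact tag and the simulated outcomes — never the
    pipeline's own chemistry — so it serves as an independent oracle.
    Exact because every structural filter is deterministic and the
    artifact construction makes each record's fate provable.
    """
    if config is None:
        config = CurationConfig()
    expected = {s: 0 for s in ("dedup", "hierarchy", "parse", "inorganic",
                               "mixture", "neutralize", "aromatize", "pains",
                               "druglikeness", "flags")}
    for rec in campaign.records:
        tag = campaign.truth[rec.compound_id]["artifact"]
        if tag == "duplicate":
            expected["dedup"] += 1
            continue
        out = rec.outcomes
        if out:
            primary = out.get(PRIMARY_SCREEN, Outcome.UNTESTED)
            if primary is Outcome.UNTESTED:
                expected["hierarchy"] += 1
                continue
            if primary is Outcome.ACTIVE:
                confirmed = out.get(CONFIRMATORY_SCREEN) is Outcome.ACTIVE
                countered = out.get(COUNTER_SCREEN) is Outcome.ACTIVE
                if confirmed and countered:
                    expected["hierarchy"] += 1
                    continue
                if not confirmed and config.unconfirmed_policy == "drop":
                    expected["hierarchy"] += 1
                    continue
        if tag == "mixture":
            expected["mixture"] += 1
        elif tag == "pains":
            expected["pains"] += 1
        elif tag == "ro5":
            expected["druglikeness"] += 1
    return expected
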