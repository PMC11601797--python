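"""Thin RDKit helpers shared across the toolkit.

All chemistry goes through RDKit; this module centralizes parsing,
canonicalization, and the handful of molecular properties the filters
need, and keeps RDKit's logging quiet (parse failures are reported
through return values, not stderr noise).
"""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

#: Elements admitted by the organic filter (hydrogen plus the common
#: organic-chemistry set; everything else is treated as inorganic).
ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)


def parse_smiles(smiles: str):
    """Parse a SMILES string, returning ``(mol, error)``.

    ``error`` is ``None`` on success, ``"parse-error"`` for syntactically
    invalid SMILES, and ``"valence"`` when the string parses but fails
    the standard valence model.
    """
    if not smiles:
        return None, "parse-error"
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        return None, "parse-error"
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException:
        return None, "valence"
    except Exception:
        return None, "parse-error"
    return mol, None


def canonical_smiles(smiles: str) -> str | None:
    """Canonical isomeric SMILES, or None if unparsable."""
    mol, err = parse_smiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def mol_to_inchi(mol) -> str | None:
    """Standard InChI for a molecule (None on failure)."""
    try:
        inchi = Chem.MolToInchi(mol)
    except Exception:
        return None
    return inchi or None


def smiles_to_inchi(smiles: str) -> str | None:
    mol, _ = parse_smiles(smiles)
    if mol is None:
        return None
    return mol_to_inchi(mol)


def molecular_weight(mol) -> float:
    """Average molecular weight from standard atomic masses (daltons)."""
    return Descriptors.MolWt(mol)


def is_organic(mol) -> bool:
    """True iff the molecule has at least one carbon and only elements
    from :data:`ORGANIC_ELEMENTS`."""
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    return "C" in symbols and symbols <= ORGANIC_ELEMENTS


def ro5_violations(mol) -> list[str]:
    """Lipinski Rule-of-Five violations for a molecule.

    Returns the violated criteria among molecular weight > 500 Da,
    Crippen logP > 5, H-bond donors > 5, and H-bond acceptors > 10.
    """
    violations = []
    if Descriptors.MolWt(mol) > 500:
        violations.append("MW>500")
    if Crippen.MolLogP(mol) > 5:
        violations.append("logP>5")
    if Lipinski.NumHDonors(mol) > 5:
        violations.append("HBD>5")
    if Lipinski.NumHAcceptors(mol) > 10:
        violations.append("HBA>10")
    return violations


def inchi_has_stereo_layer(inchi: str) -> bool:
    """True if the InChI carries a stereo layer.

    Stereo information lives in the /t (tetrahedral) and /b (double-bond)
    sublayers; /m and /s only ever accompany them.
    """
    if not inchi:
        return False
    return any(layer and layer[0] in "tb" and len(layer) > 1
               for layer in inchi.split("/")[1:])


def smiles_has_stereo(smiles: str) -> bool:
    """True if the SMILES encodes any stereochemistry marks."""
    return any(ch in smiles for ch in ("@", "/", "\\"))
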