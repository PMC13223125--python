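"""Drug structure handling: parsing, 2D depictions, numeric descriptors.

SMILES is the preferred encoding with InChI as fallback; structures are
canonicalized (via RDKit) before graph extraction so the molecular graph
round-trips to a canonical identifier. The 2D depiction is a grayscale
raster drawn from RDKit's deterministic 2D coordinates, since the
depiction occupies one channel of the fused cell-line/drug tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

DESCRIPTOR_NAMES = (
    "heavy_atoms",
    "bonds",
    "rings",
    "aromatic_rings",
    "mol_weight",
    "tpsa",
    "rotatable_bonds",
    "target_match",
)


class StructureParseError(ValueError):
    """Raised when neither SMILES nor InChI yields a valid molecule."""


@dataclass
class MoleculeStruct:
    drug_id: str
    canonical_smiles: str
    atoms: list[tuple[str, int]]  # (element, formal charge)
    bonds: list[tuple[int, int, float, bool]]  # (begin, end, order, aromatic)
    mol: "Chem.Mol" = None
    depiction: Optional[np.ndarray] = None
    descriptors: Optional[np.ndarray] = None
    cytotoxicity_index: Optional[float] = None


def parse_structure(
    smiles: str = "", inchi: str = "", drug_id: str = ""
) -> MoleculeStruct:
    """Parse a drug structure, preferring SMILES, falling back to InChI."""
    mol = None
    if smiles:
        mol = Chem.MolFromSmiles(smiles)
    if mol is None and inchi:
        mol = Chem.MolFromInchi(inchi)
    if mol is None:
        raise StructureParseError(
            f"drug {drug_id or '<unknown>'}: neither SMILES nor InChI parsed"
        )
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)  # canonical atom ordering
    atoms = [(a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms()]
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            float(b.GetBondTypeAsDouble()),
            bool(b.GetIsAromatic()),
        )
        for b in mol.GetBonds()
    ]
    return MoleculeStruct(
        drug_id=drug_id, canonical_smiles=canonical, atoms=atoms, bonds=bonds,
        mol=mol,
    )


def render_depiction(struct: MoleculeStruct, size: int = 224) -> np.ndarray:
    """Grayscale raster of the molecule's 2D layout, values in [0, 1].

    Bonds are drawn as antialiased lines and atoms as small discs over
    RDKit's deterministic 2D coordinates, scaled to fill the canvas with
    a margin. Deterministic for a fixed canonical structure and size.
    """
    from skimage.draw import disk, line_aa

    mol = struct.mol
    AllChem.Compute2DCoords(mol)
    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y]
         for i in range(mol.GetNumAtoms())]
    )
    img = np.zeros((size, size))
    margin = max(2, size // 16)
    span = coords.max(axis=0) - coords.min(axis=0) if len(coords) else np.zeros(2)
    scale = (size - 2 * margin) / max(span.max(), 1e-9) if span.max() > 0 else 0.0
    center = (coords.min(axis=0) + coords.max(axis=0)) / 2 if len(coords) else np.zeros(2)
    px = np.full((len(coords), 2), size // 2, dtype=float)
    if scale > 0:
        px = (coords - center) * scale + size / 2
    px = np.clip(px, 0, size - 1)

    for begin, end, order, _ in struct.bonds:
        r0, c0 = int(round(px[begin, 1])), int(round(px[begin, 0]))
        r1, c1 = int(round(px[end, 1])), int(round(px[end, 0]))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        img[rr, cc] = np.maximum(img[rr, cc], val * min(order, 2.0) / 2.0)
    radius = max(1, size // 112)
    for r, c in px[:, ::-1]:
        rr, cc = disk((r, c), radius, shape=img.shape)
        img[rr, cc] = 1.0
    struct.depiction = img
    return img


def drug_descriptors(
    struct: MoleculeStruct,
    cell_line_altered_genes: Sequence[str] = (),
    drug_targets: Sequence[str] = (),
    cytotoxicity_index: Optional[float] = None,
) -> np.ndarray:
    """Fixed-length numeric descriptor vector for a parsed molecule.

    The final entry is a binary target-match indicator: 1 when any
    annotated drug target appears among the cell line's altered genes.
    The optional cytotoxicity index is a pass-through drug annotation,
    appended only when configured at the feature-assembly level.
    """
    mol = struct.mol
    match = float(bool(set(drug_targets) & set(cell_line_altered_genes)))
    vec = np.array(
        [
            float(mol.GetNumHeavyAtoms()),
            float(mol.GetNumBonds()),
            float(rdMolDescriptors.CalcNumRings(mol)),
            float(rdMolDescriptors.CalcNumAromaticRings(mol)),
            float(Descriptors.MolWt(mol)),
            float(Descriptors.TPSA(mol)),
            float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
            match,
        ]
    )
    struct.descriptors = vec
    struct.cytotoxicity_index = cytotoxicity_index
    return vec
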