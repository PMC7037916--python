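"""3D conformer preparation, per-atom field weights, and template superposition.

Every molecule gets one energy-minimized conformer, per-atom weights for the
five similarity fields (partial charge, vdW-volume steric weight, atomic logP
hydrophobicity, donor/acceptor flags) and is rigidly superposed onto a
template through the maximal common substructure of their heavy-atom graphs.

Approximations relative to the original commercial workflow, all documented:
MMFF94 replaces the Tripos force field, plain Gasteiger charges replace
Gasteiger-Hueckel, and the atomic hydrophobicity weights come from the
Wildman-Crippen logP contribution scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS, rdMolDescriptors

from .errors import AlignmentError, PreparationError

logger = logging.getLogger(__name__)

FIELD_NAMES = ("S", "E", "H", "D", "A")

# donor: any N/O/S bearing at least one hydrogen; acceptor: any oxygen, or a
# nitrogen that is neither quaternary/charged nor an amide-type nitrogen.
DONOR_SMARTS = "[#7,#8,#16;!H0]"
ACCEPTOR_SMARTS = "[$([#8]),$([#7;v3;!$([#7]-[#6]=[#8,#16]);!$([#7+])])]"


@dataclass(frozen=True)
class PrepConfig:
    """Conformer generation / minimization settings."""

    energy_tolerance: float = 0.005  # kcal/mol, recorded with outputs
    max_iterations: int = 10000
    template_id: str = "MOX"
    n_conformers: int = 10
    seed: int = 20200203
    donor_convention: str = "heavy"  # "heavy" or "hydrogen"
    min_scaffold_atoms: int = 6

    def __post_init__(self) -> None:
        if self.energy_tolerance <= 0 or self.max_iterations <= 0:
            raise ValueError("energy_tolerance and max_iterations must be positive")
        if self.donor_convention not in ("heavy", "hydrogen"):
            raise ValueError("donor_convention must be 'heavy' or 'hydrogen'")


@dataclass
class AlignedMolecule:
    """Point-atom view of a prepared molecule in the common reference frame.

    ``weights`` maps each of the five field names to a per-atom weight vector:
    ``S`` vdW radius cubed, ``E`` partial charge, ``H`` atomic logP
    contribution, ``D``/``A`` donor/acceptor indicator.
    """

    compound_id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    weights: dict[str, np.ndarray]
    scaffold_map: list[tuple[int, int]] = field(default_factory=list)  # (own, template) pairs
    rmsd_to_template: float | None = None
    mol: Chem.Mol | None = None  # underlying RDKit molecule, if any
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for name in FIELD_NAMES:
            w = np.asarray(self.weights[name], dtype=float)
            if w.shape != (len(self.elements),):
                raise ValueError(f"weight vector {name} has wrong length")
            self.weights[name] = w

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def translated(self, shift: np.ndarray) -> "AlignedMolecule":
        out = self.copy()
        out.coords = self.coords + np.asarray(shift, dtype=float)
        return out

    def copy(self) -> "AlignedMolecule":
        return AlignedMolecule(
            compound_id=self.compound_id,
            elements=list(self.elements),
            coords=self.coords.copy(),
            weights={k: v.copy() for k, v in self.weights.items()},
            scaffold_map=list(self.scaffold_map),
            rmsd_to_template=self.rmsd_to_template,
            mol=self.mol,
            provenance=dict(self.provenance),
        )


def _embed_and_minimize(mol: Chem.Mol, config: PrepConfig) -> tuple[Chem.Mol, int, float]:
    """Return (mol with single chosen conformer, conformer id, energy)."""
    molH = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
    params = AllChem.ETKDGv3()
    params.randomSeed = config.seed
    conf_ids = list(
        AllChem.EmbedMultipleConfs(molH, numConfs=config.n_conformers, params=params)
    )
    if not conf_ids:
        raise PreparationError(
            f"embedding failed for {mol.GetProp('_Name') if mol.HasProp('_Name') else Chem.MolToSmiles(mol)}"
        )
    results = AllChem.MMFFOptimizeMoleculeConfs(
        molH, maxIters=config.max_iterations, nonBondedThresh=100.0
    )
    energies = [e if ok == 0 else np.inf for ok, e in results]
    if not np.isfinite(energies).any():
        # fall back to unconverged energies rather than failing outright
        energies = [e for _, e in results]
    best = int(np.argmin(energies))
    best_id = conf_ids[best]
    keep = Chem.Mol(molH)
    keep.RemoveAllConformers()
    keep.AddConformer(molH.GetConformer(best_id), assignId=True)
    return keep, best, float(energies[best])


def atom_field_weights(molH: Chem.Mol, donor_convention: str = "heavy") -> dict[str, np.ndarray]:
    """Per-atom weights for the five similarity fields on an explicit-H molecule."""
    pt = Chem.GetPeriodicTable()
    n = molH.GetNumAtoms()

    AllChem.ComputeGasteigerCharges(molH)
    charges = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in molH.GetAtoms()], dtype=float
    )
    bad = ~np.isfinite(charges)
    if bad.any():
        logger.warning("replacing %d non-finite Gasteiger charges by 0", int(bad.sum()))
        charges[bad] = 0.0

    steric = np.array([pt.GetRvdw(a.GetAtomicNum()) ** 3 for a in molH.GetAtoms()], dtype=float)
    crippen = rdMolDescriptors._CalcCrippenContribs(molH)
    hydrophobic = np.array([c[0] for c in crippen], dtype=float)

    donors = np.zeros(n)
    acceptors = np.zeros(n)
    donor_heavy = {i for (i,) in molH.GetSubstructMatches(Chem.MolFromSmarts(DONOR_SMARTS))}
    for (i,) in molH.GetSubstructMatches(Chem.MolFromSmarts(ACCEPTOR_SMARTS)):
        acceptors[i] = 1.0
    if donor_convention == "heavy":
        for i in donor_heavy:
            donors[i] = 1.0
    else:  # weight lives on the polar hydrogens themselves
        for i in donor_heavy:
            for nb in molH.GetAtomWithIdx(i).GetNeighbors():
                if nb.GetAtomicNum() == 1:
                    donors[nb.GetIdx()] = 1.0

    return {"S": steric, "E": charges, "H": hydrophobic, "D": donors, "A": acceptors}


def prepare_3d(mol: Chem.Mol, config: PrepConfig | None = None, compound_id: str | None = None) -> AlignedMolecule:
    """Build one minimized conformer and populate the per-atom field weights."""
    config = config or PrepConfig()
    if compound_id is None:
        compound_id = mol.GetProp("_Name") if mol.HasProp("_Name") else Chem.MolToSmiles(mol)
    try:
        molH, conf_index, energy = _embed_and_minimize(mol, config)
    except PreparationError:
        raise
    except Exception as exc:  # RDKit raises bare Exceptions in places
        raise PreparationError(f"preparation failed for {compound_id}: {exc}") from exc

    weights = atom_field_weights(molH, config.donor_convention)
    net_formal = float(Chem.GetFormalCharge(molH))
    if abs(float(weights["E"].sum()) - net_formal) > 0.01:
        raise PreparationError(
            f"{compound_id}: charge sum {weights['E'].sum():.4f} != formal charge {net_formal}"
        )
    coords = molH.GetConformer().GetPositions()
    elements = [a.GetSymbol() for a in molH.GetAtoms()]
    return AlignedMolecule(
        compound_id=compound_id,
        elements=elements,
        coords=np.asarray(coords, dtype=float),
        weights=weights,
        mol=molH,
        provenance={
            "seed": config.seed,
            "conformer_index": conf_index,
            "mmff_energy": energy,
            "energy_tolerance": config.energy_tolerance,
            "max_iterations": config.max_iterations,
        },
    )


def prepare_from_smiles(smiles: str, compound_id: str, config: PrepConfig | None = None) -> AlignedMolecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise PreparationError(f"unparsable SMILES for {compound_id}: {smiles}")
    mol.SetProp("_Name", compound_id)
    return prepare_3d(mol, config, compound_id=compound_id)


def _mcs_atom_pairs(mol_a: Chem.Mol, mol_b: Chem.Mol) -> list[tuple[int, int]]:
    """Heavy-atom index pairs (a, b) of the maximum common substructure."""
    a_noH = Chem.RemoveHs(mol_a)
    b_noH = Chem.RemoveHs(mol_b)
    params = rdFMCS.MCSParameters()
    params.Timeout = 30
    params.BondCompareParameters.RingMatchesRingOnly = True
    res = rdFMCS.FindMCS([a_noH, b_noH], params)
    if res.canceled and res.numAtoms == 0:
        return []
    query = Chem.MolFromSmarts(res.smartsString)
    if query is None:
        return []
    # ties between symmetry-equivalent matches broken by lowest index order,
    # which is deterministic for a fixed input ordering
    match_a = a_noH.GetSubstructMatch(query)
    match_b = b_noH.GetSubstructMatch(query)
    if not match_a or not match_b:
        return []
    # RemoveHs preserves heavy-atom indices for AddHs-built molecules
    return sorted(zip(match_a, match_b))


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns (rotation 3x3, translation 3, rmsd); x_new = x @ R.T + t.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - cm @ R.T
    moved = moving @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return R, t, rmsd


def align_to_template(
    mol: AlignedMolecule, template: AlignedMolecule, config: PrepConfig | None = None
) -> AlignedMolecule:
    """Rigidly superpose ``mol`` onto ``template`` via their common scaffold.

    The template is left untouched.  The scaffold map and the scaffold RMSD
    after superposition are recorded on the returned copy.
    """
    config = config or PrepConfig()
    if mol.mol is None or template.mol is None:
        raise AlignmentError("both molecules need an underlying RDKit structure for MCS alignment")
    pairs = _mcs_atom_pairs(mol.mol, template.mol)
    if len(pairs) < config.min_scaffold_atoms:
        raise AlignmentError(
            f"common scaffold of {mol.compound_id} and {template.compound_id} has "
            f"{len(pairs)} atoms (< {config.min_scaffold_atoms})"
        )
    own_idx = [p[0] for p in pairs]
    tpl_idx = [p[1] for p in pairs]
    R, t, rmsd = kabsch(mol.coords[own_idx], template.coords[tpl_idx])
    out = mol.copy()
    out.coords = mol.coords @ R.T + t
    out.scaffold_map = pairs
    out.rmsd_to_template = rmsd
    out.provenance = dict(mol.provenance, template=template.compound_id, scaffold_size=len(pairs))
    return out


def scaffold_rmsd(mol: AlignedMolecule, template: AlignedMolecule) -> float:
    """RMSD over the stored scaffold map, without re-fitting."""
    if not mol.scaffold_map:
        raise AlignmentError(f"{mol.compound_id} has no scaffold map")
    own_idx = [p[0] for p in mol.scaffold_map]
    tpl_idx = [p[1] for p in mol.scaffold_map]
    d = mol.coords[own_idx] - template.coords[tpl_idx]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def write_aligned_sdf(molecules: Sequence[AlignedMolecule], path) -> None:
    """Write aligned structures with per-atom weights as SD tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for am in molecules:
            if am.mol is None:
                continue
            mol = Chem.Mol(am.mol)
            conf = mol.GetConformer()
            for i in range(mol.GetNumAtoms()):
                conf.SetAtomPosition(i, am.coords[i].tolist())
            mol.SetProp("_Name", am.compound_id)
            for name in FIELD_NAMES:
                mol.SetProp(
                    f"duotox_weights_{name}",
                    " ".join(f"{w:.6f}" for w in am.weights[name]),
                )
            if am.rmsd_to_template is not None:
                mol.SetProp("duotox_scaffold_rmsd", f"{am.rmsd_to_template:.6f}")
            writer.write(mol)
    finally:
        writer.close()
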