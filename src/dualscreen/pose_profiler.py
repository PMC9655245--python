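"""Docking-pose interaction profiling against pre-determined residues.

Given a receptor structure (PDB) and docked ligand poses (multi-record SDF,
up to 10 poses per molecule per structure), count hydrogen bonds and
Van-der-Waals contacts to a configured residue list and classify each pose
as "positively docked" by a target-specific rule:

* BACE-1: at least 4 hydrogen bonds (pair-level counting), of which at
  least 2 to the catalytic aspartate dyad (Asp32/Asp228), and contacts to
  at least 8 listed residues.
* AChE (peripheral site): VdW contacts with *all nine* listed aromatic-
  gorge residues (Tyr72, Trp86, Gly121, Tyr124, Glu202, Trp286, Tyr337,
  Tyr341, His447); hydrogen bonds are not part of the AChE rule.

Detection is heavy-atom and distance-based only (H-bond: donor/acceptor-
capable N/O/S pairs within 3.5 A; contact: any heavy-atom pair within
5.0 A); poses and receptors routinely lack hydrogens, and no angle term is
applied.  Waters, ions and het ligands are stripped from the receptor on
load.  Structures whose author numbering differs from the canonical one
(e.g. the Asp93/Asp289 convention for the BACE-1 dyad) are handled through
an explicit residue-numbering map, never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
from rdkit import Chem

log = logging.getLogger(__name__)

__all__ = [
    "ResidueSpec",
    "InteractionCriteria",
    "BACE1_CRITERIA",
    "ACHE_CRITERIA",
    "PoseInteractionProfile",
    "DockingOutcome",
    "Receptor",
    "load_receptor",
    "load_poses",
    "count_hbonds",
    "count_vdw_contacts",
    "profile_pose",
    "classify_pose",
    "profile_molecule",
]

HBOND_ELEMENTS = {"N", "O", "S"}  # S as acceptor; element-based typing
MAX_POSES_PER_STRUCTURE = 10


# ---------------------------------------------------------------------------
# residue specs and criteria

@dataclass(frozen=True)
class ResidueSpec:
    """One receptor residue of interest (canonical numbering)."""

    name: str  # 3-letter residue name
    number: int
    chain: str = "A"
    role: str = "vdw"  # hbond | vdw | catalytic

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError("residue number must be >= 1")
        if self.role not in ("hbond", "vdw", "catalytic"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}"

    @property
    def hbond_capable(self) -> bool:
        return self.role in ("hbond", "catalytic")


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance cutoffs, residue lists and the positively-docked rule."""

    target: str  # "bace1" or "ache"
    residues: tuple[ResidueSpec, ...]
    hbond_max_dist: float = 3.5
    vdw_max_dist: float = 5.0
    min_hbonds: int = 0
    min_catalytic_hbonds: int = 0
    min_contacts: int = 0
    require_all_contacts: bool = False
    any_residue_contacts: bool = False  # count contacts to any protein residue

    def __post_init__(self) -> None:
        if self.hbond_max_dist <= 0 or self.vdw_max_dist <= 0:
            raise ValueError("distance cutoffs must be positive")
        for spec in self.residues:
            if spec.role == "catalytic" and not spec.hbond_capable:
                raise ValueError("catalytic residues must be H-bond capable")

    @property
    def hbond_residues(self) -> tuple[ResidueSpec, ...]:
        return tuple(r for r in self.residues if r.hbond_capable)

    @property
    def catalytic_residues(self) -> tuple[ResidueSpec, ...]:
        return tuple(r for r in self.residues if r.role == "catalytic")


#: BACE-1: H-bonding residues around the catalytic dyad plus the residues
#: that make VdW contact in most ligand-bound crystal structures.
BACE1_CRITERIA = InteractionCriteria(
    target="bace1",
    residues=(
        ResidueSpec("ASP", 32, role="catalytic"),
        ResidueSpec("GLY", 34, role="hbond"),
        ResidueSpec("THR", 72, role="hbond"),
        ResidueSpec("GLN", 73, role="hbond"),
        ResidueSpec("ASP", 228, role="catalytic"),
        ResidueSpec("GLY", 230, role="hbond"),
        ResidueSpec("THR", 232, role="hbond"),
        ResidueSpec("GLY", 11, role="vdw"),
        ResidueSpec("LEU", 30, role="vdw"),
        ResidueSpec("SER", 35, role="vdw"),
        ResidueSpec("TYR", 71, role="vdw"),
        ResidueSpec("PHE", 108, role="vdw"),
        ResidueSpec("THR", 231, role="vdw"),
    ),
    min_hbonds=4,
    min_catalytic_hbonds=2,
    min_contacts=8,
)

#: AChE peripheral-site rule: every one of the nine gorge residues must be
#: contacted; H-bonds are profiled but not required.
ACHE_CRITERIA = InteractionCriteria(
    target="ache",
    residues=(
        ResidueSpec("TYR", 72),
        ResidueSpec("TRP", 86),
        ResidueSpec("GLY", 121),
        ResidueSpec("TYR", 124),
        ResidueSpec("GLU", 202),
        ResidueSpec("TRP", 286),
        ResidueSpec("TYR", 337),
        ResidueSpec("TYR", 341),
        ResidueSpec("HIS", 447),
    ),
    require_all_contacts=True,
)


# ---------------------------------------------------------------------------
# structures and poses

@dataclass
class Receptor:
    """Receptor heavy atoms: (chain, residue name, residue number, atom
    name, element, xyz), waters/ions/het groups stripped."""

    atoms: list[tuple[str, str, int, str, str, np.ndarray]]
    name: str = ""

    def residue_atoms(self, spec: ResidueSpec, numbering: Optional[Mapping[int, int]] = None):
        number = numbering.get(spec.number, spec.number) if numbering else spec.number
        found = [a for a in self.atoms if a[2] == number and (a[0] == spec.chain or not spec.chain)]
        if not found:
            raise KeyError(f"residue {spec.label} (file number {number}) absent from structure {self.name!r}")
        wrong = {a[1] for a in found} - {spec.name}
        if wrong:
            raise KeyError(
                f"residue number {number} in {self.name!r} is {sorted(wrong)}, expected {spec.name}"
            )
        return found


_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def load_receptor(path, name: str = "") -> Receptor:
    """Read a PDB file, keeping amino-acid heavy atoms only (waters, ions
    and het ligands are stripped)."""
    st = gemmi.read_structure(str(path))
    atoms = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name not in _AMINO_ACIDS:
                continue
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                atoms.append(
                    (
                        chain.name,
                        res.name,
                        res.seqid.num,
                        atom.name,
                        atom.element.name,
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
    return Receptor(atoms=atoms, name=name or str(path))


@dataclass
class Pose:
    """One docked ligand pose: heavy-atom elements and coordinates."""

    mol_id: str
    pose_id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3)


def load_poses(path, group_by: str = "title") -> dict[str, list[Pose]]:
    """Read a multi-record SDF of docked poses, grouped per molecule.

    ``group_by`` is either ``"title"`` (the molecule name line) or the name
    of an SD property field carrying the molecule id; successive records
    with the same id are successive poses.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=False)
    grouped: dict[str, list[Pose]] = {}
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("skipping unreadable SDF record %d", i)
            continue
        if group_by == "title":
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        else:
            mol_id = mol.GetProp(group_by) if mol.HasProp(group_by) else f"mol{i}"
        conf = mol.GetConformer()
        keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        coords = np.array([list(conf.GetAtomPosition(j)) for j in keep]).reshape(-1, 3)
        elements = [mol.GetAtomWithIdx(j).GetSymbol() for j in keep]
        poses = grouped.setdefault(mol_id, [])
        poses.append(Pose(mol_id, f"{mol_id}/pose{len(poses) + 1}", elements, coords))
    return grouped


# ---------------------------------------------------------------------------
# interaction counting

@dataclass
class PoseInteractionProfile:
    """H-bond records and contacted residues for one pose."""

    pose_id: str
    target: str
    hbonds: list[tuple[str, str, int, float]] = field(default_factory=list)
    # (residue label, receptor atom, ligand atom index, distance)
    contacted_residues: set[str] = field(default_factory=set)

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)

    @property
    def n_contacts(self) -> int:
        return len(self.contacted_residues)

    def hbonds_to(self, labels: Iterable[str]) -> int:
        labels = set(labels)
        return sum(1 for rec in self.hbonds if rec[0] in labels)


def count_hbonds(
    pose: Pose,
    receptor: Receptor,
    criteria: InteractionCriteria,
    numbering: Optional[Mapping[int, int]] = None,
) -> list[tuple[str, str, int, float]]:
    """Hydrogen-bond records to the criteria's H-bond residues.

    One record per (receptor polar atom, ligand polar atom) pair within the
    cutoff; several pairs to the same residue count separately.  Polar
    means element N, O or S.
    """
    records = []
    ligand_polar = [
        (j, pose.coords[j]) for j, el in enumerate(pose.elements) if el in HBOND_ELEMENTS
    ]
    for spec in criteria.hbond_residues:
        for chain, rname, rnum, aname, element, xyz in receptor.residue_atoms(spec, numbering):
            if element not in HBOND_ELEMENTS:
                continue
            for j, lig_xyz in ligand_polar:
                d = float(np.linalg.norm(xyz - lig_xyz))
                if d <= criteria.hbond_max_dist:
                    records.append((spec.label, aname, j, d))
    return records


def count_vdw_contacts(
    pose: Pose,
    receptor: Receptor,
    criteria: InteractionCriteria,
    numbering: Optional[Mapping[int, int]] = None,
) -> set[str]:
    """Labels of listed residues with any heavy atom within the VdW cutoff
    of any ligand heavy atom."""
    contacted = set()
    for spec in criteria.residues:
        res_xyz = np.array([a[5] for a in receptor.residue_atoms(spec, numbering)])
        d = np.linalg.norm(res_xyz[:, None, :] - pose.coords[None, :, :], axis=-1)
        if (d <= criteria.vdw_max_dist).any():
            contacted.add(spec.label)
    return contacted


def profile_pose(
    pose: Pose,
    receptor: Receptor,
    criteria: InteractionCriteria,
    numbering: Optional[Mapping[int, int]] = None,
) -> PoseInteractionProfile:
    return PoseInteractionProfile(
        pose_id=pose.pose_id,
        target=criteria.target,
        hbonds=count_hbonds(pose, receptor, criteria, numbering),
        contacted_residues=count_vdw_contacts(pose, receptor, criteria, numbering),
    )


def classify_pose(profile: PoseInteractionProfile, criteria: InteractionCriteria) -> bool:
    """Apply the target's positively-docked rule to a computed profile."""
    if profile.target != criteria.target:
        raise ValueError(
            f"profile computed for target {profile.target!r}, rule is for {criteria.target!r}"
        )
    if criteria.require_all_contacts:
        wanted = {r.label for r in criteria.residues}
        return profile.contacted_residues >= wanted
    catalytic = {r.label for r in criteria.catalytic_residues}
    if profile.n_hbonds < criteria.min_hbonds:
        return False
    if profile.hbonds_to(catalytic) < criteria.min_catalytic_hbonds:
        return False
    return profile.n_contacts >= criteria.min_contacts


# ---------------------------------------------------------------------------
# per-molecule aggregation

@dataclass
class DockingOutcome:
    """Docked status of one molecule across one or more receptor structures.

    ``pose_counts[name]`` is the number of positively-docked poses in that
    structure (at most 10); a molecule is docked overall if it is docked in
    at least one structure, and the reported total is the sum over
    structures (so at most 30 across the three BACE-1 protonation states).
    """

    mol_id: str
    pose_counts: dict[str, int]

    @property
    def docked_per_structure(self) -> dict[str, bool]:
        return {k: v > 0 for k, v in self.pose_counts.items()}

    @property
    def docked(self) -> bool:
        return any(v > 0 for v in self.pose_counts.values())

    @property
    def total_poses(self) -> int:
        return sum(self.pose_counts.values())

    @property
    def n_structures_docked(self) -> int:
        return sum(1 for v in self.pose_counts.values() if v > 0)

    def to_dict(self) -> dict:
        return {
            "mol_id": self.mol_id,
            "pose_counts": self.pose_counts,
            "docked": self.docked,
            "total_poses": self.total_poses,
            "n_structures_docked": self.n_structures_docked,
        }


def profile_molecule(
    mol_id: str,
    poses_per_structure: Mapping[str, Sequence[Pose]],
    receptors: Mapping[str, Receptor],
    criteria: InteractionCriteria,
    numbering_maps: Optional[Mapping[str, Mapping[int, int]]] = None,
) -> DockingOutcome:
    """Classify every pose in every structure and aggregate per molecule."""
    counts: dict[str, int] = {}
    for sname, poses in poses_per_structure.items():
        if len(poses) > MAX_POSES_PER_STRUCTURE:
            raise ValueError(
                f"{mol_id}: {len(poses)} poses for structure {sname}, "
                f"maximum is {MAX_POSES_PER_STRUCTURE}"
            )
        numbering = (numbering_maps or {}).get(sname)
        receptor = receptors[sname]
        counts[sname] = sum(
            classify_pose(profile_pose(p, receptor, criteria, numbering), criteria)
            for p in poses
        )
    return DockingOutcome(mol_id=mol_id, pose_counts=counts)
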