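"""Synthetic fixtures with known ground truth.

Three generators make the rest of the package testable without any
external download:

* :func:`make_classification_dataset` — two-class descriptor tables with a
  controllable number of informative descriptors and class-mean separation
  (in sd units), for exercising filter-ensemble training.
* :func:`make_pose_fixture` — a miniature receptor (PDB) plus one ligand
  pose (SDF) whose hydrogen bonds and VdW contacts to named residues are
  planted *exactly*: H-bond partners at ~3.0-3.1 A, contact atoms at
  4.5 A, decoy atoms far beyond every cutoff.  Residues sit on a wide
  circle (15 A spacing) so no interaction leaks across residues, and the
  whole complex is given a random rigid rotation+translation under the
  seed.  Bond-chemistry realism is deliberately not attempted: the
  profiler is distance- and element-based, so elements and coordinates
  are all that matter.
* :func:`make_screening_library` — SMILES sampled from a small fragment
  grammar (linear assembly of ring and chain units), canonical and
  RDKit-parseable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .pose_profiler import InteractionCriteria, ResidueSpec

__all__ = [
    "ClassificationSpec",
    "make_classification_dataset",
    "PoseFixtureSpec",
    "ExpectedProfile",
    "make_pose_fixture",
    "make_screening_library",
]


# ---------------------------------------------------------------------------
# classification tables

@dataclass(frozen=True)
class ClassificationSpec:
    """Two-class descriptor-table generator settings.

    ``effect`` is the class-mean separation of informative descriptors in
    units of the within-class standard deviation; noise descriptors share
    one distribution across classes.
    """

    n_actives: int = 200
    n_inactives: int = 200
    n_descriptors: int = 20
    n_informative: int = 3
    effect: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative cannot exceed n_descriptors")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if min(self.n_actives, self.n_inactives, self.n_descriptors) < 1:
            raise ValueError("sizes must be positive")


def make_classification_dataset(
    spec: ClassificationSpec,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Descriptor table + 0/1 labels + names of the informative descriptors.

    Informative descriptors: actives ~ N(effect, 1), inactives ~ N(0, 1);
    noise descriptors ~ N(0, 1) in both classes.  Deterministic under seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"d{i:03d}" for i in range(spec.n_descriptors)]
    informative = sorted(rng.choice(spec.n_descriptors, size=spec.n_informative, replace=False))
    n = spec.n_actives + spec.n_inactives
    X = rng.standard_normal((n, spec.n_descriptors))
    y = np.concatenate([np.ones(spec.n_actives, dtype=int), np.zeros(spec.n_inactives, dtype=int)])
    for col in informative:
        X[y == 1, col] += spec.effect
    table = pd.DataFrame(X, columns=names)
    table.index = [f"syn{i:05d}" for i in range(n)]
    table.index.name = "mol_id"
    return table, y, [names[i] for i in informative]


# ---------------------------------------------------------------------------
# receptor/pose geometry fixtures

#: plausible polar (H-bond target) side-chain / backbone atom per residue type
_POLAR_TARGET_ATOM = {
    "ASP": ("OD1", "O"),
    "GLU": ("OE1", "O"),
    "GLN": ("OE1", "O"),
    "ASN": ("OD1", "O"),
    "THR": ("OG1", "O"),
    "SER": ("OG", "O"),
    "TYR": ("OH", "O"),
    "TRP": ("NE1", "N"),
    "HIS": ("ND1", "N"),
    "GLY": ("O", "O"),
}

_MAX_HBONDS_PER_RESIDUE = 5


@dataclass(frozen=True)
class PoseFixtureSpec:
    """What to plant: H-bond counts and contacts per residue label.

    ``hbond_counts`` maps residue labels (e.g. ``"ASP32"``) of H-bond
    capable residues in the criteria list to the number of ligand polar
    atoms placed within H-bond range; ``contact_residues`` are additional
    labels that get a carbon planted in VdW range.  Residues H-bonded to
    are contacted by construction (a polar atom 3 A from a side chain is
    within 5 A of the residue), so they need not be listed again.
    """

    criteria: InteractionCriteria
    hbond_counts: Mapping[str, int] = field(default_factory=dict)
    contact_residues: frozenset = frozenset()
    n_decoys: int = 4
    seed: int = 0
    mol_id: str = "fixture"

    def __post_init__(self) -> None:
        by_label = {r.label: r for r in self.criteria.residues}
        for label, count in self.hbond_counts.items():
            if label not in by_label:
                raise ValueError(f"{label} is not in the criteria residue list")
            spec = by_label[label]
            if not spec.hbond_capable:
                raise ValueError(f"{label} has role {spec.role!r}; cannot plant H-bonds")
            if spec.name not in _POLAR_TARGET_ATOM:
                raise ValueError(f"no polar target atom known for residue type {spec.name}")
            if not 0 <= count <= _MAX_HBONDS_PER_RESIDUE:
                raise ValueError(
                    f"{label}: planted H-bond count {count} outside [0, {_MAX_HBONDS_PER_RESIDUE}] "
                    "(geometric packing limit)"
                )
        for label in self.contact_residues:
            if label not in by_label:
                raise ValueError(f"{label} is not in the criteria residue list")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")


@dataclass
class ExpectedProfile:
    """Ground truth planted by :func:`make_pose_fixture`."""

    hbond_counts: dict[str, int]
    contacted_residues: set[str]

    @property
    def n_hbonds(self) -> int:
        return sum(self.hbond_counts.values())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    return q * np.sign(np.diag(r))


def make_pose_fixture(
    spec: PoseFixtureSpec, out_dir
) -> tuple[Path, Path, ExpectedProfile]:
    """Write ``receptor.pdb`` and ``pose.sdf`` under ``out_dir``.

    Returns the two paths and the planted ground truth.  Geometry: the
    criteria's residues sit on a circle with >= 15 A spacing; each residue
    is a minimal amino acid (N, CA, C, O, CB, and one polar target atom
    pointing outward); planted ligand atoms sit 3.0-3.1 A (H-bond, element
    N) or 4.5 A (contact, element C) outward of the residue; decoy carbons
    lie > 20 A from every residue.  The whole complex is rigidly rotated
    and translated at random under the seed, which changes nothing about
    the planted interaction counts.
    """
    rng = np.random.default_rng(spec.seed)
    residues = spec.criteria.residues
    n_res = len(residues)
    R = max(15.0 / (2.0 * math.sin(math.pi / max(n_res, 2))), 12.0)

    receptor_atoms: list[tuple[ResidueSpec, str, str, np.ndarray]] = []
    ligand_atoms: list[tuple[str, np.ndarray]] = []
    expected = ExpectedProfile(hbond_counts={}, contacted_residues=set())

    z = np.array([0.0, 0.0, 1.0])
    for i, res in enumerate(residues):
        theta = 2.0 * math.pi * i / n_res
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        v = np.cross(z, u)
        c = R * u

        target_name = _POLAR_TARGET_ATOM.get(res.name, (None, None))[0]
        target_el = _POLAR_TARGET_ATOM.get(res.name, (None, None))[1]
        # minimal residue: backbone away from the ligand side, one outward
        # polar atom when the residue type has one
        receptor_atoms.append((res, "CA", "C", c))
        receptor_atoms.append((res, "N", "N", c - 2.0 * u))
        receptor_atoms.append((res, "C", "C", c - 1.2 * u + 0.8 * v))
        if res.name != "GLY":
            receptor_atoms.append((res, "O", "O", c - 2.8 * u))
            receptor_atoms.append((res, "CB", "C", c + 1.2 * v))
        if target_name is not None and not (res.name != "GLY" and target_name == "O"):
            receptor_atoms.append((res, target_name, target_el, c + 1.2 * u))

        n_hb = spec.hbond_counts.get(res.label, 0)
        if n_hb:
            cone = [u]
            for p in (v, -v, z, -z):
                w = u + 0.35 * p
                cone.append(w / np.linalg.norm(w))
            for k in range(n_hb):
                ligand_atoms.append(("N", c + 4.2 * cone[k]))
            expected.hbond_counts[res.label] = n_hb
            expected.contacted_residues.add(res.label)
        if res.label in spec.contact_residues and n_hb == 0:
            ligand_atoms.append(("C", c + 4.5 * u))
            expected.contacted_residues.add(res.label)

    # decoy ligand atoms far outside every cutoff
    for k in range(spec.n_decoys):
        theta = 2.0 * math.pi * k / max(spec.n_decoys, 1)
        pos = (R + 30.0) * np.array([math.cos(theta), math.sin(theta), 0.0]) + 5.0 * z
        ligand_atoms.append(("C", pos))

    # one common rigid transform for receptor and pose
    rot = _random_rotation(rng)
    shift = rng.uniform(-20.0, 20.0, size=3)
    transform = lambda x: rot @ x + shift

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / "receptor.pdb"
    sdf_path = out_dir / "pose.sdf"

    _write_receptor_pdb(pdb_path, receptor_atoms, transform)
    _write_pose_sdf(sdf_path, spec.mol_id, ligand_atoms, transform)
    return pdb_path, sdf_path, expected


def _write_receptor_pdb(path: Path, atoms, transform) -> None:
    st = gemmi.Structure()
    st.name = "synthetic receptor"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple, gemmi.Residue] = {}
    order: list[tuple] = []
    for res_spec, aname, element, xyz in atoms:
        key = (res_spec.chain, res_spec.number, res_spec.name)
        if key not in res_map:
            residue = gemmi.Residue()
            residue.name = res_spec.name
            residue.seqid = gemmi.SeqId(res_spec.number, " ")
            res_map[key] = residue
            order.append(key)
        atom = gemmi.Atom()
        atom.name = aname
        atom.element = gemmi.Element(element)
        pos = transform(xyz)
        atom.pos = gemmi.Position(*pos)
        res_map[key].add_atom(atom)
    for key in order:
        chain_name = key[0] or "A"
        if chain_name not in chain_map:
            chain_map[chain_name] = gemmi.Chain(chain_name)
        chain_map[chain_name].add_residue(res_map[key])
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def _write_pose_sdf(path: Path, mol_id: str, atoms, transform) -> None:
    mol = Chem.RWMol()
    conf = Chem.Conformer(len(atoms))
    for i, (element, xyz) in enumerate(atoms):
        mol.AddAtom(Chem.Atom(element))
        pos = transform(xyz)
        conf.SetAtomPosition(i, Point3D(*(float(x) for x in pos)))
    mol.AddConformer(conf)
    out = mol.GetMol()
    out.SetProp("_Name", mol_id)
    out.UpdatePropertyCache(strict=False)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    writer.write(out)
    writer.close()


# ---------------------------------------------------------------------------
# screening libraries

_FRAGMENTS = [
    "C", "CC", "CCC", "CO", "CN", "C(=O)", "C(=O)N", "C(=O)O", "CS",
    "c1ccccc1", "c1ccncc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccc(O)cc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "c1ccc2ccccc2c1", "c1cnc2ccccc2c1",
]


def make_screening_library(n: int, seed: int = 0) -> list[str]:
    """Sample ``n`` valid canonical SMILES from a linear fragment grammar.

    Each molecule is a concatenation of 2-6 fragment units; assemblies that
    fail RDKit parsing are resampled.  Deterministic under seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        k = int(rng.integers(2, 7))
        smiles = "".join(_FRAGMENTS[int(i)] for i in rng.integers(0, len(_FRAGMENTS), size=k))
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        out.append(Chem.MolToSmiles(mol))
    return out


def write_smiles_file(smiles: Sequence[str], path, prefix: str = "lib") -> None:
    with open(path, "w") as fh:
        for i, smi in enumerate(smiles):
            fh.write(f"{smi}\t{prefix}{i:05d}\n")
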