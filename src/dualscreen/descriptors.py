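"""2D physico-chemical descriptor computation.

The descriptor set is an open 2D set: a handful of named atom/charge counts
(``a_hyd``, ``a_nN``, ``a_nI``, ``weight``, ``logP``, ``FCharge``,
``chiral``) plus the standard subdivided-surface-area (SlogP_VSA, SMR_VSA,
PEOE_VSA) families and a few connectivity/shape descriptors — roughly the
2D slice a practitioner would compute for filter-based classification.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

log = logging.getLogger(__name__)

_HALOGENS = {9, 17, 35, 53}

#: version tag recorded alongside trained models; Tanimoto and descriptor
#: values are only comparable within one version.
DESCRIPTOR_SET_VERSION = "dualscreen-2d-v1"


def _a_hyd(mol: Chem.Mol) -> int:
    """Number of non-polar heavy atoms (carbon and halogen)."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6 or a.GetAtomicNum() in _HALOGENS)


def _count_element(mol: Chem.Mol, z: int) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == z)


def _chiral(mol: Chem.Mol) -> int:
    return len(Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False))


_NAMED = {
    "a_hyd": _a_hyd,
    "a_nN": lambda m: _count_element(m, 7),
    "a_nO": lambda m: _count_element(m, 8),
    "a_nS": lambda m: _count_element(m, 16),
    "a_nI": lambda m: _count_element(m, 53),
    "a_heavy": lambda m: m.GetNumHeavyAtoms(),
    "weight": Descriptors.MolWt,
    "logP": Crippen.MolLogP,
    "FCharge": Chem.GetFormalCharge,
    "chiral": _chiral,
    "a_don": rdMolDescriptors.CalcNumHBD,
    "a_acc": rdMolDescriptors.CalcNumHBA,
    "b_rotN": rdMolDescriptors.CalcNumRotatableBonds,
    "rings": rdMolDescriptors.CalcNumRings,
    "arom_rings": rdMolDescriptors.CalcNumAromaticRings,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "FractionCSP3": rdMolDescriptors.CalcFractionCSP3,
}

_FAMILY_PREFIXES = ("SlogP_VSA", "SMR_VSA", "PEOE_VSA", "EState_VSA", "Chi", "Kappa", "BalabanJ", "BertzCT")


def descriptor_names() -> list[str]:
    """Names of all descriptors, named counts first then the VSA/shape families."""
    family = [n for n, _ in Descriptors._descList if n.startswith(_FAMILY_PREFIXES)]
    return list(_NAMED) + sorted(family)


def compute_descriptors(mol: Chem.Mol) -> dict[str, float]:
    """Compute the full descriptor dictionary for one molecule."""
    out = {name: float(fn(mol)) for name, fn in _NAMED.items()}
    family = dict(Descriptors.CalcMolDescriptors(mol, missingVal=0.0))
    for name, _ in Descriptors._descList:
        if name.startswith(_FAMILY_PREFIXES):
            out[name] = float(family[name])
    return out


def compute_descriptor_table(
    records: Iterable, smiles_of=lambda r: r.smiles, id_of=lambda r: r.mol_id
) -> pd.DataFrame:
    """Descriptor table (rows: mol_id, columns: descriptors) for records.

    Unparseable SMILES are dropped with a warning rather than raising, so a
    large screening pool with a few bad entries still descriptorizes.
    """
    rows = {}
    for rec in records:
        mol = Chem.MolFromSmiles(smiles_of(rec))
        if mol is None:
            log.warning("skipping unparseable SMILES for %s", id_of(rec))
            continue
        rows[id_of(rec)] = compute_descriptors(mol)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=descriptor_names())
    table.index.name = "mol_id"
    return table.astype(float)


def reject_descriptors(
    table: pd.DataFrame, var_threshold: float = 1e-8, corr_threshold: float = 0.95
) -> pd.DataFrame:
    """Drop low-variance and highly correlated descriptor columns.

    Constant (variance < ``var_threshold``) columns go first.  Then, for
    every pair with |Pearson r| > ``corr_threshold``, the lower-variance
    column is dropped (ties keep the lexicographically first name).  The
    result is idempotent: applying the rejection twice changes nothing.
    """
    if table.shape[1] == 0:
        raise ValueError("empty descriptor table")
    variances = table.var(axis=0, ddof=1)
    keep = variances[variances >= var_threshold].index.tolist()
    if not keep:
        raise ValueError("all descriptor columns rejected by the variance threshold")

    # visit in priority order (high variance first, name as tie-break) and
    # greedily keep columns uncorrelated with everything kept so far
    order = sorted(keep, key=lambda c: (-variances[c], c))
    corr = table[order].corr().abs().to_numpy()
    pos = {c: i for i, c in enumerate(order)}
    kept: list[str] = []
    for col in order:
        i = pos[col]
        if all(corr[i, pos[k]] <= corr_threshold for k in kept):
            kept.append(col)
    if not kept:
        raise ValueError("all descriptor columns rejected")
    kept_in_input_order = [c for c in table.columns if c in set(kept)]
    return table[kept_in_input_order]
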