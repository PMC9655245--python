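"""Dataset curation: loading, deduplication, diversity pruning, labelling,
decoy dilution and fold assignment.

The curation path mirrors the usual preparation of a ligand-based training
set from an activity-database export: canonicalize and deduplicate SMILES,
optionally drop implausibly potent entries and unwanted chemotypes
(covalent-warhead patterns), restrict structural redundancy with a pairwise
Tanimoto cutoff, assign binary labels under an AvI or HvL scheme, dilute
actives with property-matched decoys from a large untagged pool, and split
the result into stratified folds for cross-validated model building.
"""

from __future__ import annotations

import csv
import logging
from statistics import geometric_mean
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .records import ActivityScheme, DiversityFilterSpec, MoleculeRecord

log = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "ActivityScheme",
    "DiversityFilterSpec",
    "load_activity_csv",
    "load_smiles_file",
    "canonicalize",
    "deduplicate",
    "exclude_patterns",
    "fingerprint",
    "tanimoto_matrix",
    "diversity_prune",
    "assign_classes",
    "sample_decoys",
    "make_folds",
]

# ---------------------------------------------------------------------------
# loading / canonicalization

def canonicalize(smiles: str) -> Optional[str]:
    """Canonical SMILES, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def load_activity_csv(path) -> list[MoleculeRecord]:
    """Read an activity table (mol_id, smiles, activity_nM, target).

    SMILES are canonicalized on load; rows that fail to parse are dropped
    with a warning.  ``activity_nM`` may be empty for pool molecules.
    """
    records: list[MoleculeRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            can = canonicalize(row["smiles"])
            if can is None:
                log.warning("dropping %s: unparseable SMILES %r", row.get("mol_id"), row["smiles"])
                continue
            raw = (row.get("activity_nM") or "").strip()
            records.append(
                MoleculeRecord(
                    mol_id=row["mol_id"],
                    smiles=can,
                    activity_nM=float(raw) if raw else None,
                    target=row.get("target", "") or "",
                )
            )
    return records


def load_smiles_file(path, prefix: str = "pool") -> list[MoleculeRecord]:
    """Read a plain SMILES file (one molecule per line, optional id column)."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            can = canonicalize(parts[0])
            if can is None:
                log.warning("dropping line %d: unparseable SMILES %r", i + 1, parts[0])
                continue
            mol_id = parts[1] if len(parts) > 1 else f"{prefix}{i:06d}"
            records.append(MoleculeRecord(mol_id=mol_id, smiles=can))
    return records


# ---------------------------------------------------------------------------
# deduplication and chemotype exclusion

_ACTIVITY_RULES = {
    "geometric_mean": lambda vals: geometric_mean(vals),
    "min": min,
    "median": lambda vals: float(np.median(vals)),
}


def deduplicate(
    records: Sequence[MoleculeRecord],
    activity_rule: str = "geometric_mean",
    min_activity_nM: float = 0.1,
) -> list[MoleculeRecord]:
    """Collapse records sharing a canonical SMILES into one.

    When duplicates report different IC50s the retained value follows
    ``activity_rule`` (geometric mean by default — IC50s are log-scale
    quantities).  Records with reported IC50 below ``min_activity_nM``
    (default 0.1 nM) are treated as probable unit errors and dropped;
    pass ``min_activity_nM=0`` to keep everything.
    """
    rule = _ACTIVITY_RULES[activity_rule]
    by_smiles: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.activity_nM is not None and rec.activity_nM < min_activity_nM:
            log.warning("dropping %s: IC50 %.3g nM below plausibility bound", rec.mol_id, rec.activity_nM)
            continue
        if rec.smiles not in by_smiles:
            order.append(rec.smiles)
        by_smiles.setdefault(rec.smiles, []).append(rec)

    out = []
    for smi in order:
        group = by_smiles[smi]
        first = group[0]
        activities = [r.activity_nM for r in group if r.activity_nM is not None]
        merged = rule(activities) if activities else None
        out.append(
            MoleculeRecord(
                mol_id=first.mol_id, smiles=smi, activity_nM=merged, target=first.target
            )
        )
    return out


def exclude_patterns(
    records: Sequence[MoleculeRecord], smarts_patterns: Sequence[str]
) -> list[MoleculeRecord]:
    """Drop molecules matching any SMARTS exclusion pattern.

    Used to remove covalent-inhibitor chemotypes (phosphorus compounds,
    carbamates, selected esters) before training a non-covalent binder
    model; the pattern list is user configuration, nothing is hard-coded.
    """
    mols = [Chem.MolFromSmarts(p) for p in smarts_patterns]
    bad = [p for p, m in zip(smarts_patterns, mols) if m is None]
    if bad:
        raise ValueError(f"invalid SMARTS pattern(s): {bad}")
    out = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if any(mol.HasSubstructMatch(q) for q in mols):
            log.info("excluding %s by SMARTS pattern", rec.mol_id)
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# fingerprints / Tanimoto / diversity

def fingerprint(smiles: str, spec: DiversityFilterSpec = DiversityFilterSpec()):
    """Linear path-based fingerprint (paths up to 7 bonds, 1024 bits).

    This is the FP2-style dialect: hashed linear fragments, no branched
    subgraphs.  Returns an RDKit ExplicitBitVect.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.RDKFingerprint(mol, minPath=1, maxPath=7, fpSize=1024, branchedPaths=False)


def tanimoto_matrix(
    records: Sequence[MoleculeRecord], spec: DiversityFilterSpec = DiversityFilterSpec()
) -> np.ndarray:
    """Symmetric pairwise Tanimoto matrix, TI = |A∩B| / |A∪B| over bit sets.

    A molecule with an empty fingerprint gets TI 0 against everything
    (logged) but 1.0 on its own diagonal entry.
    """
    if not records:
        raise ValueError("need at least one record")
    fps = [fingerprint(r.smiles, spec) for r in records]
    n = len(fps)
    mat = np.eye(n)
    for i in range(n):
        if fps[i].GetNumOnBits() == 0:
            log.warning("%s has an empty fingerprint; TI forced to 0", records[i].mol_id)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = set(fps[i].GetOnBits()), set(fps[j].GetOnBits())
            union = len(a | b)
            mat[i, j] = mat[j, i] = (len(a & b) / union) if union else 0.0
    return mat


def diversity_prune(
    records: Sequence[MoleculeRecord], spec: DiversityFilterSpec
) -> list[MoleculeRecord]:
    """Greedy diversity restriction: keep a molecule only if its TI to every
    already-kept molecule is <= the cutoff.

    Records are visited sorted by mol_id so the result is deterministic.
    At cutoff 1.0 only fingerprint-identical molecules are removed.  The
    kept set is maximal for the visit order: re-adding any dropped molecule
    would violate the cutoff against some survivor.
    """
    ordered = sorted(records, key=lambda r: r.mol_id)
    mat = tanimoto_matrix(ordered, spec)
    kept_idx: list[int] = []
    for i in range(len(ordered)):
        # fingerprint-identical pairs (TI == 1) are redundant at any cutoff
        if all(mat[i, j] <= spec.tanimoto_cutoff and mat[i, j] < 1.0 for j in kept_idx):
            kept_idx.append(i)
    return [ordered[i] for i in kept_idx]


# ---------------------------------------------------------------------------
# labelling

def assign_classes(
    records: Sequence[MoleculeRecord], scheme: ActivityScheme
) -> list[MoleculeRecord]:
    """Apply an activity scheme, returning labelled copies.

    AvI: any record with IC50 below the active cutoff is labelled 1;
    records without a reported activity (pool molecules) are labelled 0;
    measured records at/above the cutoff are excluded.

    HvL: IC50 < active cutoff -> 1, IC50 > low cutoff -> 0, anything in
    between (or unmeasured) is excluded from the output.
    """
    out: list[MoleculeRecord] = []
    if scheme.model_type == "AvI":
        for rec in records:
            if rec.activity_nM is None:
                out.append(rec.with_label(0))
            elif rec.activity_nM < scheme.active_cutoff_nM:
                out.append(rec.with_label(1))
    else:
        for rec in records:
            if rec.activity_nM is None:
                continue
            if rec.activity_nM < scheme.active_cutoff_nM:
                out.append(rec.with_label(1))
            elif rec.activity_nM > scheme.low_cutoff_nM:
                out.append(rec.with_label(0))
        labels = {r.class_label for r in out}
        if labels != {0, 1}:
            raise ValueError(
                "HvL scheme produced a single class; the model is untrainable "
                f"(labels present: {sorted(labels)})"
            )
    return out


# ---------------------------------------------------------------------------
# decoy dilution

_DECOY_PROPS = {
    "HBD": rdMolDescriptors.CalcNumHBD,
    "HBA": rdMolDescriptors.CalcNumHBA,
    "MW": Descriptors.MolWt,
    "logP": Crippen.MolLogP,
}


def _decoy_property_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    rows = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        rows[rec.mol_id] = {name: fn(mol) for name, fn in _DECOY_PROPS.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def sample_decoys(
    actives: Sequence[MoleculeRecord],
    pool: Sequence[MoleculeRecord],
    ratio: float = 100.0,
    tolerance: float = 1.5,
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Sample property-matched decoys from an untagged pool.

    Eligible pool molecules have H-bond donor count, acceptor count,
    molecular weight and logP each within mean +/- ``tolerance`` * sd of the
    actives' distribution (the applicability-domain restriction).  Exactly
    ``ratio * len(actives)`` of them are drawn uniformly at random under
    ``seed`` and returned labelled 0.
    """
    if not actives:
        raise ValueError("no actives supplied")
    n_wanted = int(round(ratio * len(actives)))
    act = _decoy_property_frame(actives)
    mean, sd = act.mean(), act.std(ddof=1).fillna(0.0)
    lo, hi = mean - tolerance * sd, mean + tolerance * sd

    pool_props = _decoy_property_frame(pool)
    ok = ((pool_props >= lo) & (pool_props <= hi)).all(axis=1)
    eligible_ids = set(pool_props.index[ok])
    eligible = [r for r in pool if r.mol_id in eligible_ids]
    if len(eligible) < n_wanted:
        per_prop = {
            name: int(((pool_props[name] < lo[name]) | (pool_props[name] > hi[name])).sum())
            for name in pool_props
        }
        raise ValueError(
            f"decoy pool too small: need {n_wanted}, only {len(eligible)} eligible; "
            f"pool molecules rejected per property: {per_prop}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_wanted, replace=False)
    return [eligible[i].with_label(0) for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# folds

def make_folds(
    records: Sequence[MoleculeRecord], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Stratified random k-fold assignment, mol_id -> fold in {1..k}.

    Each class is shuffled and dealt round-robin, so every fold carries the
    global active:inactive proportion to within one molecule per class.
    """
    by_class: dict[int, list[MoleculeRecord]] = {0: [], 1: []}
    for rec in records:
        if rec.class_label is None:
            raise ValueError(f"{rec.mol_id} has no class label; run assign_classes first")
        by_class[rec.class_label].append(rec)
    if not by_class[0] or not by_class[1]:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for label, members in by_class.items():
        if len(members) < k:
            raise ValueError(f"class {label} has {len(members)} molecules, fewer than k={k}")
        ids = sorted(r.mol_id for r in members)
        rng.shuffle(ids)
        for i, mol_id in enumerate(ids):
            assignment[mol_id] = (i % k) + 1
    return assignment
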