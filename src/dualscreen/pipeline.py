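"""End-to-end demonstration pipeline on synthetic inputs.

:func:`dry_run` exercises the full screening workflow without any external
data: a fragment-grammar library is descriptorized, two filter-ensemble
models are trained on hidden property rules standing in for the two
targets, the library is screened through the model cascade, synthetic
docking poses are generated and profiled for the survivors, and the
weighted ligand+structure score selects final candidates.  Everything is
deterministic under one seed.
"""

from __future__ import annotations

import tempfile
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import combine_rank, descriptors, ise, pose_profiler, synth
from .records import MoleculeRecord

__all__ = ["dry_run"]

#: reference-set sizes for weight calibration (known duals vs. randoms)
N_KNOWN_DUALS = 46
N_RANDOMS = 150


def _hidden_labels(
    table: pd.DataFrame, cols: tuple[str, str], band: tuple[float, float] = (0.35, 0.85)
) -> np.ndarray:
    """Binary labels from a hidden two-descriptor band rule: a molecule is
    "active" iff both descriptors fall inside the given quantile band — a
    stand-in structure-activity relationship that, like real potency
    cliffs, rewards a property window rather than an extreme."""
    ok = np.ones(len(table), dtype=bool)
    for c in cols:
        lo, hi = table[c].quantile(band[0]), table[c].quantile(band[1])
        ok &= (table[c] >= lo).to_numpy() & (table[c] <= hi).to_numpy()
    return ok.astype(int)


def _reference_components(rng: np.random.Generator, schema) -> tuple[list, list]:
    """Synthetic calibration sets: strong known duals, weak randoms."""

    def draw(strong: bool) -> dict:
        comp = {}
        for name, (lo, hi) in schema.bounds.items():
            if name.endswith("_docked"):
                comp[name] = float(rng.random() < (0.9 if strong else 0.2))
            elif name.endswith("_poses"):
                frac = rng.uniform(0.4, 1.0) if strong else rng.uniform(0.0, 0.2)
                comp[name] = float(round(frac * hi))
            else:  # model index in [-1, 1]
                comp[name] = float(rng.uniform(0.3, 0.9) if strong else rng.uniform(-0.9, 0.3))
        return comp

    knowns = [draw(True) for _ in range(N_KNOWN_DUALS)]
    randoms = [draw(False) for _ in range(N_RANDOMS)]
    return knowns, randoms


def dry_run(
    n_library: int = 1000,
    seed: int = 0,
    max_docking_candidates: int = 30,
    work_dir: Optional[str] = None,
) -> dict:
    """Run the whole pipeline on synthetic data; returns summary counts.

    Every selected candidate is guaranteed (and audited by the caller) to
    have a weighted score > 0.5 and calculated logP < 4.
    """
    rng = np.random.default_rng(seed)

    # 1. library generation + curation
    smiles = synth.make_screening_library(n_library, seed=seed)
    records = [MoleculeRecord(f"lib{i:05d}", s) for i, s in enumerate(smiles)]
    seen: set[str] = set()
    unique = [r for r in records if not (r.smiles in seen or seen.add(r.smiles))]
    full_table = descriptors.compute_descriptor_table(unique)
    table = descriptors.reject_descriptors(full_table)

    # 2. two ligand-based models trained on hidden property rules
    config = ise.ISEConfig(
        seed=int(rng.integers(2**31 - 1)), mcc_min=0.2,
        n_iterations=20, filters_per_iteration=200,
    )
    y_a = _hidden_labels(full_table, ("arom_rings", "a_acc"))
    model_a = ise.train_model(table, y_a, config, scheme="ache-like")
    config_b = ise.ISEConfig(
        seed=int(rng.integers(2**31 - 1)), mcc_min=0.2,
        n_iterations=20, filters_per_iteration=200,
    )
    y_b = _hidden_labels(full_table, ("a_nN", "b_rotN"))
    model_b = ise.train_model(table, y_b, config_b, scheme="bace1-like")

    # 3. cascade screening (first model gates)
    screened = ise.screen_cascade([model_a, model_b], table)
    survivors = screened.index[screened["passed"]].tolist()
    docking_set = survivors[:max_docking_candidates]

    # 4. synthetic docking: one AChE structure, three BACE-1 structures
    schema = combine_rank.default_schema(
        ache_models=("ache_m1",), bace1_models=("bace1_m2",),
        ache_pose_max=10, bace1_pose_max=30,
    )
    base = Path(work_dir) if work_dir else Path(tempfile.mkdtemp(prefix="dualscreen_"))
    components: dict[str, dict] = {}
    ache_docked = bace1_docked = 0
    ache_labels = [r.label for r in pose_profiler.ACHE_CRITERIA.residues]
    bace1_hb = [r.label for r in pose_profiler.BACE1_CRITERIA.hbond_residues]
    bace1_all = [r.label for r in pose_profiler.BACE1_CRITERIA.residues]
    for mol_id in docking_set:
        mol_rng = np.random.default_rng([seed, zlib.crc32(mol_id.encode())])
        # AChE: contact all nine residues with probability ~0.5
        good = mol_rng.random() < 0.5
        n_contact = 9 if good else int(mol_rng.integers(0, 9))
        spec = synth.PoseFixtureSpec(
            criteria=pose_profiler.ACHE_CRITERIA,
            contact_residues=frozenset(ache_labels[:n_contact]),
            n_decoys=int(mol_rng.integers(0, 5)),
            seed=int(mol_rng.integers(2**31 - 1)), mol_id=mol_id,
        )
        pdb, sdf, _ = synth.make_pose_fixture(spec, base / mol_id / "ache")
        rec = pose_profiler.load_receptor(pdb)
        pose = pose_profiler.load_poses(sdf)[mol_id]
        ache_out = pose_profiler.profile_molecule(
            mol_id, {"4M0F": pose}, {"4M0F": rec}, pose_profiler.ACHE_CRITERIA
        )
        # BACE-1: three structures, each with its own planted pattern
        bace_poses, bace_recs = {}, {}
        for s_i, sname in enumerate(("prot1", "prot2", "deprot")):
            strong = mol_rng.random() < 0.4
            hb = {"ASP32": 2, "ASP228": 1, "GLY34": 1} if strong else {"ASP32": int(mol_rng.integers(0, 2))}
            n_extra = 5 if strong else int(mol_rng.integers(0, 4))
            contacts = frozenset(l for l in bace1_all if l not in bace1_hb)
            spec_b = synth.PoseFixtureSpec(
                criteria=pose_profiler.BACE1_CRITERIA,
                hbond_counts=hb,
                contact_residues=frozenset(list(contacts)[:n_extra]),
                n_decoys=int(mol_rng.integers(0, 5)),
                seed=int(mol_rng.integers(2**31 - 1)), mol_id=mol_id,
            )
            pdb_b, sdf_b, _ = synth.make_pose_fixture(spec_b, base / mol_id / f"bace1_{sname}")
            bace_recs[sname] = pose_profiler.load_receptor(pdb_b)
            bace_poses[sname] = pose_profiler.load_poses(sdf_b)[mol_id]
        bace1_out = pose_profiler.profile_molecule(
            mol_id, bace_poses, bace_recs, pose_profiler.BACE1_CRITERIA
        )
        ache_docked += ache_out.docked
        bace1_docked += bace1_out.docked
        components[mol_id] = {
            "ache_m1": float(np.clip(screened.loc[mol_id, "index_1"], -1, 1)),
            "bace1_m2": float(np.clip(screened.loc[mol_id, "index_2"], -1, 1)),
            "ache_docked": float(ache_out.docked),
            "ache_poses": float(ache_out.total_poses),
            "bace1_docked": float(bace1_out.docked),
            "bace1_poses": float(bace1_out.total_poses),
        }

    # 5. weight calibration and final selection
    knowns, randoms = _reference_components(
        np.random.default_rng([seed, 77]), schema
    )
    weights, calib_report = combine_rank.calibrate_weights(
        knowns, randoms, schema, seed=seed
    )
    logp = full_table["logP"].to_dict()
    scored = combine_rank.score_candidates(components, weights, schema, logp)
    selected = combine_rank.select_candidates(scored, threshold=0.5, logp_max=4.0)

    return {
        "n_library": n_library,
        "n_unique": len(unique),
        "model_a_top_mcc": float(model_a.filters[0][1].mcc),
        "model_b_top_mcc": float(model_b.filters[0][1].mcc),
        "n_pass_stage1": int((screened["failed_stage"] != 1).sum()),
        "n_pass_all": len(survivors),
        "n_docked_ache": int(ache_docked),
        "n_docked_bace1": int(bace1_docked),
        "calibration_objective": float(calib_report["objective"]),
        "n_selected": len(selected),
        "selected": [
            {"mol_id": c.mol_id, "score": float(c.score), "logP": float(c.logP)}
            for c in selected
        ],
        "scored": [
            {"mol_id": c.mol_id, "score": float(c.score),
             "sub_scores": {k: float(v) for k, v in c.sub_scores.items()},
             "logP": float(c.logP), "selected": bool(c.selected)}
            for c in scored
        ],
    }
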