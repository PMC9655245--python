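"""Weighted combination of ligand-based indexes and docking outcomes.

Each candidate molecule carries a named component vector: model indexes in
[-1, 1] for every screening model, a per-target docked flag (0/1) and a
per-target positively-docked pose count (0-10 for a single structure, 0-30
when pooled over three structures).  Components are normalized to [0, 1]
(indexes via (x+1)/2, pose counts divided by their maxima), weighted on the
probability simplex, and reduced to a global score plus one sub-score per
target.  Selection demands every score strictly above the threshold
(default 0.5) and calculated logP strictly below the cap (default 4).

Weights are calibrated on a reference set of known dual-target inhibitors
against random molecules: a seeded random search on the simplex maximizes
(fraction of knowns above threshold) - (fraction of randoms above
threshold).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ComponentSchema",
    "WeightVector",
    "CandidateScore",
    "normalize_components",
    "calibrate_weights",
    "weighted_score",
    "score_candidates",
    "select_candidates",
]


@dataclass(frozen=True)
class ComponentSchema:
    """Declares component names, their raw bounds and target grouping.

    ``bounds[name]`` is (lo, hi) of the raw component; indexes use (-1, 1),
    flags (0, 1), pose counts (0, max).  ``groups[name]`` assigns each
    component to a per-target sub-score ("ache" / "bace1").
    """

    bounds: Mapping[str, tuple[float, float]]
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.bounds) != set(self.groups):
            raise ValueError("bounds and groups must cover the same components")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"{name}: invalid bounds ({lo}, {hi})")

    @property
    def names(self) -> list[str]:
        return sorted(self.bounds)


def default_schema(
    ache_models: Sequence[str] = ("ache_m1", "ache_m4", "ache_m5"),
    bace1_models: Sequence[str] = ("bace1_m2", "bace1_m8"),
    ache_pose_max: int = 10,
    bace1_pose_max: int = 30,
) -> ComponentSchema:
    """The usual component layout: three AChE and two BACE-1 model indexes,
    one docked flag and one pose count per target."""
    bounds: dict[str, tuple[float, float]] = {}
    groups: dict[str, str] = {}
    for name in ache_models:
        bounds[name], groups[name] = (-1.0, 1.0), "ache"
    for name in bace1_models:
        bounds[name], groups[name] = (-1.0, 1.0), "bace1"
    bounds["ache_docked"], groups["ache_docked"] = (0.0, 1.0), "ache"
    bounds["ache_poses"], groups["ache_poses"] = (0.0, float(ache_pose_max)), "ache"
    bounds["bace1_docked"], groups["bace1_docked"] = (0.0, 1.0), "bace1"
    bounds["bace1_poses"], groups["bace1_poses"] = (0.0, float(bace1_pose_max)), "bace1"
    return ComponentSchema(bounds=bounds, groups=groups)


@dataclass(frozen=True)
class WeightVector:
    """Non-negative component weights summing to one."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()))
        if (vals < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.isclose(vals.sum(), 1.0):
            raise ValueError(f"weights must sum to 1, got {vals.sum()}")

    @classmethod
    def uniform(cls, names: Sequence[str]) -> "WeightVector":
        w = 1.0 / len(names)
        return cls({n: w for n in names})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dict(self.weights), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "WeightVector":
        with open(path) as fh:
            return cls(json.load(fh))


@dataclass
class CandidateScore:
    mol_id: str
    score: float
    sub_scores: dict[str, float]
    logP: float
    selected: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------

def normalize_components(raw: Mapping[str, float], schema: ComponentSchema) -> dict[str, float]:
    """Map raw components onto [0, 1] (affine per component, bijective on
    its declared range)."""
    out = {}
    for name in schema.names:
        if name not in raw:
            raise KeyError(f"component {name!r} missing")
        lo, hi = schema.bounds[name]
        x = float(raw[name])
        if not lo <= x <= hi:
            raise ValueError(f"component {name!r}={x} outside bounds [{lo}, {hi}]")
        out[name] = (x - lo) / (hi - lo)
    return out


def weighted_score(components: Mapping[str, float], weights: WeightVector) -> float:
    """Dot product of normalized components with the weight vector."""
    if set(components) != set(weights.weights):
        raise KeyError(
            f"component/weight name mismatch: {sorted(set(components) ^ set(weights.weights))}"
        )
    return float(sum(components[n] * weights.weights[n] for n in components))


def _group_score(
    components: Mapping[str, float], weights: WeightVector, schema: ComponentSchema, group: str
) -> float:
    names = [n for n in schema.names if schema.groups[n] == group]
    total_w = sum(weights.weights[n] for n in names)
    if total_w == 0:
        return 0.0
    return sum(components[n] * weights.weights[n] for n in names) / total_w


def calibrate_weights(
    known_duals: Sequence[Mapping[str, float]],
    randoms: Sequence[Mapping[str, float]],
    schema: ComponentSchema,
    threshold: float = 0.5,
    n_samples: int = 2000,
    seed: int = 0,
) -> tuple[WeightVector, dict[str, float]]:
    """Search the weight simplex for the best known/random separation.

    Components are normalized internally.  Candidate weight vectors are the
    uniform vector plus ``n_samples`` Dirichlet draws; the objective is
    (fraction of knowns scoring > threshold) - (fraction of randoms scoring
    > threshold).  Returns the best vector and a report with both fractions
    and the objective.  If the two reference sets have identical component
    distributions a warning is issued and uniform weights are returned.
    """
    if not known_duals or not randoms:
        raise ValueError("both reference sets must be non-empty")
    names = schema.names
    K = np.array([[normalize_components(c, schema)[n] for n in names] for c in known_duals])
    R = np.array([[normalize_components(c, schema)[n] for n in names] for c in randoms])

    def objective(w: np.ndarray) -> tuple[float, float, float]:
        f_known = float((K @ w > threshold).mean())
        f_random = float((R @ w > threshold).mean())
        return f_known - f_random, f_known, f_random

    rng = np.random.default_rng(seed)
    uniform = np.full(len(names), 1.0 / len(names))
    candidates = [uniform] + list(rng.dirichlet(np.ones(len(names)), size=n_samples))
    best_w, best = uniform, objective(uniform)
    for w in candidates[1:]:
        obj = objective(w)
        if obj[0] > best[0]:
            best_w, best = w, obj

    identical = K.shape == R.shape and np.allclose(np.sort(K, axis=0), np.sort(R, axis=0))
    if identical:
        warnings.warn("reference sets are indistinguishable; returning uniform weights")
        best_w, best = uniform, objective(uniform)

    report = {"objective": best[0], "frac_knowns": best[1], "frac_randoms": best[2]}
    return WeightVector(dict(zip(names, (float(v) for v in best_w)))), report


def score_candidates(
    components_by_mol: Mapping[str, Mapping[str, float]],
    weights: WeightVector,
    schema: ComponentSchema,
    logp_by_mol: Mapping[str, float],
) -> list[CandidateScore]:
    """Global and per-target weighted scores for every molecule."""
    out = []
    for mol_id, raw in components_by_mol.items():
        comp = normalize_components(raw, schema)
        sub = {g: _group_score(comp, weights, schema, g) for g in sorted(set(schema.groups.values()))}
        out.append(
            CandidateScore(
                mol_id=mol_id,
                score=weighted_score(comp, weights),
                sub_scores=sub,
                logP=float(logp_by_mol[mol_id]),
            )
        )
    return out


def select_candidates(
    scored: Sequence[CandidateScore], threshold: float = 0.5, logp_max: float = 4.0
) -> list[CandidateScore]:
    """Apply the selection rule and return selected candidates, best first.

    A molecule is selected iff the global score *and* every per-target
    sub-score are strictly above ``threshold`` and its logP is strictly
    below ``logp_max``.  Rejected molecules keep an elimination reason on
    their record.
    """
    selected = []
    for cand in scored:
        low = [g for g, s in cand.sub_scores.items() if not s > threshold]
        if not cand.score > threshold:
            cand.selected, cand.reason = False, f"score {cand.score:.3f} <= {threshold}"
        elif low:
            cand.selected, cand.reason = False, f"sub-score(s) below threshold: {','.join(low)}"
        elif not cand.logP < logp_max:
            cand.selected, cand.reason = False, f"logP {cand.logP:.2f} >= {logp_max}"
        else:
            cand.selected, cand.reason = True, ""
            selected.append(cand)
    return sorted(selected, key=lambda c: (-c.score, c.mol_id))
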