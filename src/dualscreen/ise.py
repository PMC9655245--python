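"""Filter-ensemble classification models (iterative stochastic elimination).

A *filter* is a conjunction of five closed value ranges over five distinct
2D descriptors; a molecule "passes" a filter iff all five ranges hold.
Filters are scored by the Matthews correlation coefficient of their
pass/fail decision against the binary activity labels, written in the
rate convention

    MCC = (P*N - Pf*Nf) / sqrt((N+Nf)(N+Pf)(P+Nf)(P+Pf))

where P and N are the percentages of actives passing and inactives failing
(true positive / true negative rates) and Pf, Nf their false counterparts,
so P + Nf = 100 and N + Pf = 100.

A *model* is an ordered ensemble of filters, each carrying its held-out
performance.  Screening a molecule through a model yields a per-molecule
index in [-1, 1]:

    Index = (1/n) * sum_i [ d_i * min(P_i/Pf_i, cap) - df_i * min(Nf_i/N_i, cap) ]

with d_i = 1 (df_i = 0) if the molecule passes filter i and the reverse if
it fails; zero denominators are smoothed by eps = 0.5 percentage points and
each per-filter contribution is capped (default cap 1.0, so the index stays
within [-1, 1]).  Positive indexes mark predicted actives.

Model construction searches the space of filters by iterative stochastic
elimination: candidate (descriptor, range) building blocks are sampled into
random five-descriptor filters, the blocks are scored by the average MCC of
the filters that used them, and after each generation the worst blocks are
stochastically eliminated so later generations concentrate on discriminating
descriptor ranges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PropertyRange",
    "Filter",
    "FilterPerformance",
    "Model",
    "ISEConfig",
    "mcc",
    "evaluate_filter",
    "train_model",
    "molecule_index",
    "screen_table",
    "model_auc",
    "screen_cascade",
    "cross_validate",
    "merge_models",
]

EPSILON_PCT = 0.5  # percentage-point smoothing for zero denominators in Eq-2 ratios
FILTER_SIZE = 5  # descriptor ranges per filter


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class PropertyRange:
    """Closed interval constraint on one descriptor."""

    descriptor: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ValueError(f"{self.descriptor}: lo {self.lo} > hi {self.hi}")

    def holds(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class Filter:
    """Conjunction of five ranges over five distinct descriptors."""

    ranges: tuple[PropertyRange, ...]

    def __post_init__(self) -> None:
        if len(self.ranges) != FILTER_SIZE:
            raise ValueError(f"a filter has exactly {FILTER_SIZE} ranges, got {len(self.ranges)}")
        names = [r.descriptor for r in self.ranges]
        if len(set(names)) != FILTER_SIZE:
            raise ValueError(f"filter descriptors must be distinct, got {names}")

    @property
    def descriptors(self) -> tuple[str, ...]:
        return tuple(r.descriptor for r in self.ranges)

    def passes(self, row) -> bool:
        return all(r.holds(float(row[r.descriptor])) for r in self.ranges)


@dataclass(frozen=True)
class FilterPerformance:
    """Confusion rates (percent, per class) and MCC of one filter.

    P: true-positive rate (% of actives passing); N: true-negative rate
    (% of inactives failing); Pf = 100 - N (false positives), Nf = 100 - P
    (false negatives).
    """

    P: float
    N: float
    Pf: float
    Nf: float
    mcc: float

    def __post_init__(self) -> None:
        for name in ("P", "N", "Pf", "Nf"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not math.isclose(self.P + self.Nf, 100.0, abs_tol=1e-6):
            raise ValueError("P + Nf must equal 100")
        if not math.isclose(self.N + self.Pf, 100.0, abs_tol=1e-6):
            raise ValueError("N + Pf must equal 100")


@dataclass
class Model:
    """Ordered filter ensemble with per-filter held-out performance."""

    filters: list[tuple[Filter, FilterPerformance]]
    scheme: str = ""
    seed: Optional[int] = None
    fold: Optional[int] = None
    index_cap: float = 1.0
    descriptor_set_version: str = ""

    def __post_init__(self) -> None:
        if not self.filters:
            raise ValueError("a model needs at least one filter")

    @property
    def n(self) -> int:
        return len(self.filters)

    @property
    def descriptors(self) -> set[str]:
        return {d for f, _ in self.filters for d in f.descriptors}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "fold": self.fold,
            "index_cap": self.index_cap,
            "descriptor_set_version": self.descriptor_set_version,
            "filters": [
                {
                    "ranges": [asdict(r) for r in f.ranges],
                    "performance": asdict(p),
                }
                for f, p in self.filters
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Model":
        filters = [
            (
                Filter(tuple(PropertyRange(**r) for r in item["ranges"])),
                FilterPerformance(**item["performance"]),
            )
            for item in d["filters"]
        ]
        return cls(
            filters=filters,
            scheme=d.get("scheme", ""),
            seed=d.get("seed"),
            fold=d.get("fold"),
            index_cap=d.get("index_cap", 1.0),
            descriptor_set_version=d.get("descriptor_set_version", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Model":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ISEConfig:
    """Search settings for iterative stochastic elimination.

    n_filters: maximum filters kept in the model; mcc_min: minimum held-out
    MCC a filter must reach; n_iterations: elimination generations;
    filters_per_iteration: random filters sampled per generation;
    elimination_fraction: share of the candidate (descriptor, range) pool
    exposed to elimination each generation; holdout_fraction: share of the
    training rows reserved for held-out filter scoring; n_quantiles:
    active-class quantile grid defining candidate range endpoints.
    """

    n_filters: int = 10
    mcc_min: float = 0.3
    n_iterations: int = 30
    filters_per_iteration: int = 300
    elimination_fraction: float = 0.3
    holdout_fraction: float = 0.25
    n_quantiles: int = 10
    index_cap: float = 1.0
    seed: int = 0


# ---------------------------------------------------------------------------
# MCC / filter evaluation

def mcc(P: float, N: float, Pf: float, Nf: float) -> float:
    """Matthews correlation coefficient from class-wise rates.

    Accepts percentages (P + Nf = 100) or fractions (P + Nf = 1).  Returns
    0.0 when any factor of the denominator vanishes (the degenerate
    pass-everything / fail-everything filters).
    """
    if min(P, N, Pf, Nf) < 0:
        raise ValueError("rates must be non-negative")
    denom = (N + Nf) * (N + Pf) * (P + Nf) * (P + Pf)
    if denom == 0:
        return 0.0
    return (P * N - Pf * Nf) / math.sqrt(denom)


def _pass_vector(filt: Filter, table: pd.DataFrame) -> np.ndarray:
    ok = np.ones(len(table), dtype=bool)
    for r in filt.ranges:
        col = table[r.descriptor].to_numpy()
        ok &= (col >= r.lo) & (col <= r.hi)
    return ok


def evaluate_filter(filt: Filter, table: pd.DataFrame, labels: Sequence[int]) -> FilterPerformance:
    """Score one filter against labelled descriptor rows.

    P is the percentage of label-1 molecules passing the conjunction, N the
    percentage of label-0 molecules failing it.
    """
    missing = [d for d in filt.descriptors if d not in table.columns]
    if missing:
        raise KeyError(f"descriptors missing from table: {missing}")
    y = np.asarray(labels, dtype=int)
    if len(y) != len(table):
        raise ValueError("labels and table length mismatch")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")
    passed = _pass_vector(filt, table)
    P = 100.0 * passed[y == 1].sum() / n_pos
    N = 100.0 * (~passed[y == 0]).sum() / n_neg
    Pf, Nf = 100.0 - N, 100.0 - P
    return FilterPerformance(P=P, N=N, Pf=Pf, Nf=Nf, mcc=mcc(P, N, Pf, Nf))


# ---------------------------------------------------------------------------
# molecule index (Eq-2 style scoring)

def _ratios(perf: FilterPerformance, cap: float) -> tuple[float, float]:
    r_pass = min(perf.P / max(perf.Pf, EPSILON_PCT), cap)
    r_fail = min(perf.Nf / max(perf.N, EPSILON_PCT), cap)
    return r_pass, r_fail


def molecule_index(model: Model, row) -> float:
    """Per-molecule model index: mean of capped pass/fail ratio contributions.

    Passing filter i contributes +min(P_i/Pf_i, cap); failing contributes
    -min(Nf_i/N_i, cap); the index is the mean contribution over the model's
    filters and lies in [-cap, +cap].
    """
    for f, _ in model.filters:
        for d in f.descriptors:
            if d not in row:
                raise KeyError(f"descriptor {d!r} missing from molecule row")
    total = 0.0
    for f, perf in model.filters:
        r_pass, r_fail = _ratios(perf, model.index_cap)
        total += r_pass if f.passes(row) else -r_fail
    return total / model.n


def screen_table(model: Model, table: pd.DataFrame) -> pd.Series:
    """Vectorized molecule_index over a descriptor table."""
    missing = [d for d in model.descriptors if d not in table.columns]
    if missing:
        raise KeyError(f"descriptors missing from table: {missing}")
    acc = np.zeros(len(table))
    for f, perf in model.filters:
        r_pass, r_fail = _ratios(perf, model.index_cap)
        passed = _pass_vector(f, table)
        acc += np.where(passed, r_pass, -r_fail)
    return pd.Series(acc / model.n, index=table.index, name="index")


def model_auc(model: Model, table: pd.DataFrame, labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC of model indexes vs labels, ties averaged."""
    from scipy.stats import rankdata

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes")
    scores = screen_table(model, table).to_numpy()
    ranks = rankdata(scores)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# training: iterative stochastic elimination

@dataclass
class _Candidate:
    descriptor: str
    lo: float
    hi: float
    passes: np.ndarray  # bool per training row
    score_sum: float = 0.0
    uses: int = 0

    @property
    def mean_score(self) -> float:
        return self.score_sum / self.uses if self.uses else 0.0


def _candidate_pool(table: pd.DataFrame, labels: np.ndarray, n_quantiles: int) -> list[_Candidate]:
    """All contiguous quantile-to-quantile ranges of each descriptor.

    Endpoints are quantiles of the *active* class, so candidate ranges
    concentrate where actives live.
    """
    qs = np.linspace(0, 1, n_quantiles + 1)
    pool: list[_Candidate] = []
    active = table.loc[labels == 1]
    for name in table.columns:
        col = table[name].to_numpy()
        edges = np.unique(np.quantile(active[name].to_numpy(), qs))
        for i in range(len(edges)):
            for j in range(i + 1, len(edges)):
                lo, hi = float(edges[i]), float(edges[j])
                pool.append(_Candidate(name, lo, hi, (col >= lo) & (col <= hi)))
    return pool


def _rates(passed: np.ndarray, y: np.ndarray, n_pos: int, n_neg: int):
    P = 100.0 * passed[y == 1].sum() / n_pos
    N = 100.0 * (~passed[y == 0]).sum() / n_neg
    return P, N, 100.0 - N, 100.0 - P


def train_model(
    table: pd.DataFrame,
    labels: Sequence[int],
    config: ISEConfig = ISEConfig(),
    scheme: str = "",
    fold: Optional[int] = None,
    descriptor_set_version: str = "",
) -> Model:
    """Construct a filter-ensemble model by iterative stochastic elimination.

    The labelled rows are split (stratified, seeded) into a search part and
    a held-out part.  Each generation samples random five-descriptor filters
    from the surviving candidate (descriptor, range) blocks and scores them
    by MCC on the search part; blocks accumulate the scores of the filters
    that used them, and after every generation the weakest blocks are
    eliminated with probability proportional to their badness rank.  The
    best distinct filters are then re-scored on the held-out part and kept
    if their held-out MCC reaches ``config.mcc_min``.
    """
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    if table.shape[1] < FILTER_SIZE:
        raise ValueError(f"need at least {FILTER_SIZE} descriptors, got {table.shape[1]}")

    rng = np.random.default_rng(config.seed)

    # stratified search/held-out split
    holdout = np.zeros(len(y), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_hold = max(1, int(round(config.holdout_fraction * len(idx))))
        holdout[idx[:n_hold]] = True
    tr_y, ho_y = y[~holdout], y[holdout]
    if len(np.unique(tr_y)) < 2 or len(np.unique(ho_y)) < 2:
        raise ValueError("classes too small for a stratified held-out split")

    pool = _candidate_pool(table, y, config.n_quantiles)
    for cand in pool:
        cand.tr = cand.passes[~holdout]
    n_pos, n_neg = int((tr_y == 1).sum()), int((tr_y == 0).sum())

    best: dict[tuple, tuple[float, tuple[int, ...]]] = {}
    pool_idx = list(range(len(pool)))

    for _ in range(config.n_iterations):
        by_desc: dict[str, list[int]] = {}
        for i in pool_idx:
            by_desc.setdefault(pool[i].descriptor, []).append(i)
        desc_names = sorted(by_desc)
        if len(desc_names) < FILTER_SIZE:
            break
        for _ in range(config.filters_per_iteration):
            chosen_desc = rng.choice(len(desc_names), size=FILTER_SIZE, replace=False)
            members = tuple(
                int(rng.choice(by_desc[desc_names[k]])) for k in sorted(chosen_desc)
            )
            passed = pool[members[0]].tr.copy()
            for m in members[1:]:
                passed &= pool[m].tr
            P, N, Pf, Nf = _rates(passed, tr_y, n_pos, n_neg)
            score = mcc(P, N, Pf, Nf)
            for m in members:
                pool[m].score_sum += score
                pool[m].uses += 1
            key = tuple(sorted(members))
            if key not in best or best[key][0] < score:
                best[key] = (score, members)

        # stochastic elimination: rank used candidates by mean score, remove
        # from the bottom `elimination_fraction` with rank-proportional odds
        used = [i for i in pool_idx if pool[i].uses > 0]
        used.sort(key=lambda i: pool[i].mean_score)
        n_elim_zone = int(len(used) * config.elimination_fraction)
        doomed = set()
        for rank, i in enumerate(used[:n_elim_zone]):
            p_elim = (n_elim_zone - rank) / max(n_elim_zone, 1)
            if rng.random() < p_elim:
                doomed.add(i)
        survivors = [i for i in pool_idx if i not in doomed]
        # never let a descriptor or the pool collapse below a usable size
        if len({pool[i].descriptor for i in survivors}) >= FILTER_SIZE:
            pool_idx = survivors

    if not best:
        raise ValueError("search produced no candidate filters")

    # re-score the best search-phase filters on the held-out rows; only the
    # top search-ranked filters are evaluated there, so the reported held-out
    # MCCs are not inflated by a wide winner-takes-all selection
    ho_table = table.iloc[np.flatnonzero(holdout)]
    candidates = sorted(best.values(), key=lambda t: -t[0])[: config.n_filters]
    scored: list[tuple[Filter, FilterPerformance]] = []
    seen: set[tuple] = set()
    for _, members in candidates:
        ranges = tuple(
            PropertyRange(pool[m].descriptor, pool[m].lo, pool[m].hi)
            for m in sorted(members, key=lambda m: pool[m].descriptor)
        )
        if ranges in seen:
            continue
        seen.add(ranges)
        filt = Filter(ranges)
        perf = evaluate_filter(filt, ho_table, ho_y)
        scored.append((filt, perf))
    scored.sort(key=lambda fp: -fp[1].mcc)
    kept = [(f, p) for f, p in scored if p.mcc >= config.mcc_min][: config.n_filters]
    if not kept:
        best_mcc = scored[0][1].mcc if scored else float("nan")
        raise ValueError(
            f"no filter reached held-out MCC {config.mcc_min}; best found {best_mcc:.3f}"
        )
    return Model(
        filters=kept,
        scheme=scheme,
        seed=config.seed,
        fold=fold,
        index_cap=config.index_cap,
        descriptor_set_version=descriptor_set_version,
    )


# ---------------------------------------------------------------------------
# cross-validation harness and fold merging

def cross_validate(
    table: pd.DataFrame,
    labels: Sequence[int],
    folds: Sequence[int],
    config: ISEConfig = ISEConfig(),
    scheme: str = "",
) -> pd.DataFrame:
    """Train on each (k-1)-fold union, evaluate on the held-out fold.

    Returns one row per fold with the top-filter held-out MCC and the model
    AUC on that fold — the spread across folds is the usual bias check.
    Models are stored in the result's ``model`` column.
    """
    y = np.asarray(labels, dtype=int)
    folds = np.asarray(folds, dtype=int)
    rows = []
    for k in sorted(np.unique(folds)):
        train_mask = folds != k
        model = train_model(
            table.loc[train_mask], y[train_mask], config, scheme=scheme, fold=int(k)
        )
        test_table, test_y = table.loc[~train_mask], y[~train_mask]
        top = max(
            (evaluate_filter(f, test_table, test_y) for f, _ in model.filters),
            key=lambda p: p.mcc,
        )
        rows.append(
            {
                "fold": int(k),
                "top_filter_mcc": top.mcc,
                "auc": model_auc(model, test_table, test_y),
                "model": model,
            }
        )
    return pd.DataFrame(rows).set_index("fold")


def merge_models(models: Sequence[Model]) -> Model:
    """Union of the filters of several (fold) models into one screening model."""
    if not models:
        raise ValueError("nothing to merge")
    filters = [fp for m in models for fp in m.filters]
    filters.sort(key=lambda fp: -fp[1].mcc)
    first = models[0]
    return Model(
        filters=filters,
        scheme=first.scheme,
        seed=first.seed,
        fold=None,
        index_cap=first.index_cap,
        descriptor_set_version=first.descriptor_set_version,
    )


# ---------------------------------------------------------------------------
# cascade screening

def screen_cascade(
    models: Sequence[Model],
    table: pd.DataFrame,
    stage_threshold: float = 0.0,
) -> pd.DataFrame:
    """Screen a library through an ordered model cascade.

    Stage 1 is the gate: molecules whose first-model index is <= the stage
    threshold are marked failed at stage 1 and receive no further indexes.
    Survivors are scored by all remaining models in parallel.  The result
    has one ``index_<i>`` column per model, a ``passed`` flag (positive
    index in every model) and ``failed_stage`` (0 = never failed).
    """
    if not models:
        raise ValueError("need at least one model")
    out = pd.DataFrame(index=table.index)
    idx1 = screen_table(models[0], table)
    out["index_1"] = idx1
    alive = idx1 > stage_threshold
    for i, model in enumerate(models[1:], start=2):
        col = pd.Series(np.nan, index=table.index)
        if alive.any():
            col[alive] = screen_table(model, table.loc[alive])
        out[f"index_{i}"] = col
    index_cols = [c for c in out.columns if c.startswith("index_")]
    failed_stage = np.zeros(len(out), dtype=int)
    failed_stage[~alive] = 1
    for i, c in enumerate(index_cols[1:], start=2):
        newly = alive & (out[c] <= stage_threshold) & (failed_stage == 0)
        failed_stage[newly.to_numpy()] = i
    out["failed_stage"] = failed_stage
    out["passed"] = failed_stage == 0
    return out
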