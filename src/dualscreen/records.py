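"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


@dataclass
class MoleculeRecord:
    """A single molecule in an activity dataset or a screening pool.

    ``activity_nM`` is the reported IC50 in nanomolar; it is absent for
    molecules drawn from an untagged pool (e.g. vendor catalogs standing in
    for ZINC).  ``class_label`` is set only after a labelling scheme has been
    applied: 1 = active (or highly active), 0 = inactive / low activity.
    """

    mol_id: str
    smiles: str
    activity_nM: Optional[float] = None
    target: str = ""
    class_label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.activity_nM is not None and not self.activity_nM > 0:
            raise ValueError(
                f"{self.mol_id}: activity must be positive, got {self.activity_nM}"
            )
        if self.class_label not in (None, 0, 1):
            raise ValueError(f"{self.mol_id}: class_label must be 0/1/None")

    def with_label(self, label: int) -> "MoleculeRecord":
        return replace(self, class_label=label)


@dataclass(frozen=True)
class ActivityScheme:
    """How IC50 values are turned into binary class labels.

    Two schemes are supported:

    * ``"AvI"`` (actives vs. inactives): every molecule with IC50 below
      ``active_cutoff_nM`` (default 10,000 nM) is an active; the negative
      class is supplied separately by diluting with pool molecules at
      ``dilution_ratio`` decoys per active (typically 100:1).
    * ``"HvL"`` (high vs. low activity): IC50 < ``active_cutoff_nM``
      (default 100 nM) is the high class, IC50 > ``low_cutoff_nM``
      (default 1000 nM; a 3000 nM variant is also used) is the low class,
      and molecules between the cutoffs are excluded.
    """

    model_type: str = "AvI"
    active_cutoff_nM: float = 10_000.0
    low_cutoff_nM: float = 1_000.0
    dilution_ratio: float = 100.0

    def __post_init__(self) -> None:
        if self.model_type not in ("AvI", "HvL"):
            raise ValueError(f"unknown model_type {self.model_type!r}")
        if self.model_type == "HvL" and not self.active_cutoff_nM < self.low_cutoff_nM:
            raise ValueError("HvL requires active_cutoff_nM < low_cutoff_nM")
        if self.dilution_ratio <= 0:
            raise ValueError("dilution_ratio must be positive")


@dataclass(frozen=True)
class DiversityFilterSpec:
    """Tanimoto-similarity pruning parameters.

    ``tanimoto_cutoff`` is the maximum pairwise Tanimoto index allowed among
    surviving molecules (the useful range for diversity restriction is
    0.7-1.0, where 1.0 removes only fingerprint-identical duplicates).
    ``fingerprint_dialect`` records how fingerprints were computed, since
    Tanimoto values are only comparable within one dialect.
    """

    tanimoto_cutoff: float = 1.0
    fingerprint_dialect: str = "linear-7bond-1024bit"

    def __post_init__(self) -> None:
        if not 0.7 <= self.tanimoto_cutoff <= 1.0:
            raise ValueError("tanimoto_cutoff must lie in [0.7, 1.0]")
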