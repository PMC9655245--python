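# dualscreen

Virtual-screening toolkit for discovering **dual inhibitors of
acetylcholinesterase (AChE, peripheral anionic site) and β-secretase
(BACE-1)** — the two enzymes whose simultaneous inhibition is a candidate
strategy against amyloid-β formation and aggregation in Alzheimer's
disease.  It is aimed at computational chemists who want to combine
ligand-based classification with structure-based post-processing of
docking results in one reproducible pipeline:

1. **Dataset curation** (`dualscreen.mol_data`) — canonicalization and
   deduplication of activity tables, Tanimoto-index diversity pruning,
   actives-vs-inactives (AvI) and high-vs-low (HvL) labelling schemes,
   property-matched decoy dilution, stratified five-fold splits.
2. **Filter-ensemble models** (`dualscreen.ise`) — classification models
   built by iterative stochastic elimination.  Each *filter* is a
   conjunction of five descriptor ranges; its quality is the Matthews
   correlation coefficient of its pass/fail decision,

   MCC = (P·N − P_f·N_f) / √((N+N_f)(N+P_f)(P+N_f)(P+P_f)),

   with P, N the true-positive/true-negative percentages and P_f, N_f
   their false counterparts.  Screening a molecule through an n-filter
   model yields an index in [−1, 1],

   Index = (1/n) Σᵢ [ δᵢ·min(Pᵢ/P_fᵢ, cap) − δ_fᵢ·min(N_fᵢ/Nᵢ, cap) ],

   where δᵢ = 1 if the molecule passes filter i.  Libraries are screened
   through a model cascade gated by the first model's positive index.
3. **Pose profiling** (`dualscreen.pose_profiler`) — counts hydrogen bonds
   (donor/acceptor N/O/S heavy-atom pairs ≤ 3.5 Å) and Van-der-Waals
   contacts (any heavy-atom pair ≤ 5 Å) between docked poses (SDF) and
   pre-determined receptor residues (PDB), then applies the
   positively-docked rules: BACE-1 needs ≥ 4 H-bonds including ≥ 2 to the
   catalytic Asp32/Asp228 dyad plus ≥ 8 contacted residues; AChE needs
   contacts with all nine gorge residues (Tyr72, Trp86, Gly121, Tyr124,
   Glu202, Trp286, Tyr337, Tyr341, His447).
4. **Structure selection** (`dualscreen.target_selection`) — TP/FP
   enrichment ratios and specificity for choosing which crystal structure
   to dock against.
5. **Candidate ranking** (`dualscreen.combine_rank`) — normalized, weighted
   combination of model indexes and docking outcomes, with weight
   calibration against known dual inhibitors and the final selection rule
   (all scores > 0.5, calculated logP < 4).
6. **Synthetic fixtures** (`dualscreen.synth`) — descriptor tables with
   known informative descriptors and receptor/pose geometries with exactly
   planted interactions, so the whole pipeline is testable offline.

Pose *generation* (conformer enumeration, docking engines, receptor
protonation) is out of scope: the package analyzes poses produced
elsewhere.

## Worked example

Train a model on a synthetic two-class table (200 actives + 200 inactives,
20 descriptors of which `d010`, `d012`, `d015` carry a 3-sd class
separation) and score a structure choice:

```python
from dualscreen import ise, synth
from dualscreen.target_selection import DockingTestSet, enrichment_ratio

table, labels, informative = synth.make_classification_dataset(
    synth.ClassificationSpec(seed=0))          # informative: d010, d012, d015
model = ise.train_model(table, labels, ise.ISEConfig(seed=0))
top_filter, perf = model.filters[0]
print(top_filter.descriptors)   # ('d007', 'd010', 'd012', 'd017', 'd019')
print(perf.P, perf.N, perf.mcc) # 88.0 98.0 0.864
print(ise.model_auc(model, table, labels))  # 0.998

res = enrichment_ratio(DockingTestSet(48, 17, 125, 21))
print(res.tp_rate, res.fp_rate, res.rounded_ratio())  # 0.354 0.168 2.1
```

The top filter's five ranges include two of the three planted informative
descriptors; its held-out MCC of 0.864 means the filter alone classifies
the held-out fold far above chance, and the model index orders actives
above inactives with AUC 0.998.  The enrichment example reproduces the
structure-choice arithmetic: a structure that docks 17/48 actives but only
21/125 low-activity molecules enriches true positives ~2.1-fold.

A command-line interface mirrors the library:

```bash
dualscreen curate --activities acts.csv --scheme hvl --tanimoto 0.7
dualscreen train --curated curated.csv --descriptors curated_descriptors.csv
dualscreen screen --models m1.json m2.json --library zinc.smi --cascade
dualscreen poses --receptor 4djw.pdb --poses poses.sdf --target bace1
dualscreen select-structure --counts counts.csv --criterion specificity
dualscreen combine --components comp.csv --weights w.json --logp-max 4
```

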