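# Methods

## Problem setting

The package implements a two-stage virtual-screening strategy for dual
AChE/BACE-1 inhibitor discovery: ligand-based filter-ensemble models score
millions of molecules cheaply, and only the top-indexed molecules proceed
to structure-based post-processing, where docked poses are judged by
whether they reproduce the interaction pattern seen in ligand-bound
crystal structures.  A final weighted score merges both evidence sources.

## Dataset curation

Activity tables (mol_id, SMILES, IC50 in nM, target) are canonicalized on
load; duplicates by canonical SMILES are merged, with conflicting IC50s
resolved by geometric mean (IC50 is a log-scale quantity; `min` and
`median` are available).  Records reporting IC50 < 0.1 nM are dropped as
probable unit errors; the bound is configurable.  Covalent-warhead
chemotypes (organophosphates, carbamates, selected esters) are removed via
a user-supplied SMARTS exclusion list — the exact ester subset and the
literature-based identification of peripheral-site binders require human
judgement, so they are configuration, not code.

**Diversity pruning.** Pairwise Tanimoto indexes are computed over linear
path-based fingerprints (paths of 1–7 bonds hashed to 1024 bits, the
FP2-style dialect; the dialect string is recorded in outputs because TI
values are not comparable across dialects).  Pruning is greedy in mol_id
order: a molecule is kept iff its TI to every kept molecule is ≤ the
cutoff.  Fingerprint-identical pairs (TI = 1.0) are redundant at any
cutoff and are always collapsed; consequently the cutoff-1.0 setting
removes exactly the fingerprint duplicates.  The kept set is maximal for
the visit order.

**Labelling.** AvI: IC50 < 10,000 nM → active (1); pool molecules → 0.
HvL: IC50 < 100 nM → 1, IC50 > 1000 nM → 0 (3000 nM variant available),
the 100–1000 nM window is excluded.  HvL with an empty class raises — the
scheme is untrainable.

**Decoys.** AvI actives are diluted (default 100:1) with pool molecules
whose H-bond donor count, acceptor count, molecular weight and logP each
lie within mean ± 1.5 sd of the actives — an applicability-domain
restriction.  The 1.5-sd tolerance quantifies "close to the average"; it
keeps ~87% of a matched population per property while excluding gross
outliers.  Sampling is uniform among eligible molecules under the seed.

**Folds.** Stratified 5-fold assignment by round-robin dealing of each
shuffled class, so per-fold class proportions match the global proportion
to within one molecule per class.

**Descriptors.** An open 2D set: named atom/charge counts (`a_hyd` =
non-polar atom count, `a_nN`, `a_nI`, `weight`, `logP`, `FCharge`,
`chiral`, …) plus the subdivided-surface-area (SlogP_VSA/SMR_VSA/PEOE_VSA/
EState_VSA) and connectivity families from RDKit, ~80 columns.  Columns
with variance below threshold are dropped, then correlated pairs
(|r| > 0.95) keep the higher-variance member (lexicographic tie-break);
the operation is idempotent.

## Filter-ensemble models (iterative stochastic elimination)

A filter is a conjunction of five closed ranges over five distinct
descriptors.  Filter quality is the MCC of its pass/fail decision written
in class-rate form (P + N_f = 100, N + P_f = 100); any zero factor in the
denominator yields MCC = 0, which correctly scores the degenerate
pass-everything/pass-nothing filters as uninformative.

The search is a seeded, fully specified variant of iterative stochastic
elimination:

1. Candidate building blocks are (descriptor, range) pairs whose endpoints
   are active-class quantiles (11-point grid → 55 contiguous ranges per
   descriptor), so ranges concentrate where actives live.
2. The labelled rows are split stratified into a search part (75%) and a
   held-out part (25%).
3. Each generation samples 300 random filters (5 distinct descriptors, one
   surviving range each) and scores them on the search part; every block
   accumulates the MCC of the filters that used it.
4. After each generation the blocks in the bottom 30% by mean accumulated
   MCC are eliminated stochastically, with probability decreasing linearly
   in rank (the worst block is almost surely removed).  Elimination never
   reduces the pool below five distinct descriptors.
5. After 30 generations the best filters *by search score* are re-scored
   on the held-out part; filters reaching `mcc_min` are kept (default up
   to 10), sorted by held-out MCC.

Only the top `n_filters` search-ranked candidates are ever evaluated on
the held-out rows.  Evaluating a wide pool there and keeping the maximum
would inflate the reported held-out MCC by winner's-curse selection; with
the narrow candidate list the label-shuffle control stays near zero (the
test suite requires |mean MCC| < 0.15 over 20 shuffles).

**Index.** Passing filter i contributes +min(Pᵢ/P_fᵢ, cap), failing
contributes −min(N_fᵢ/Nᵢ, cap); the index is the mean over filters.  The
raw rate ratios can exceed 1 by orders of magnitude, yet published model
indexes live in [−1, 1]; capping each contribution at 1.0 (configurable)
resolves that ambiguity and is recorded in the model metadata.  Zero
denominators are smoothed with ε = 0.5 percentage points, which keeps the
ordering of near-perfect filters without infinite contributions.

**Cascade.** Screening applies an ordered model list: molecules with a
non-positive first-model index are eliminated at stage 1 and receive no
further indexes; survivors are scored by all remaining models in
parallel, and each molecule's record reports the stage that eliminated it.

**Cross-validation.** `cross_validate` trains on each 4-fold union and
reports the held-out top-filter MCC and model AUC per fold; fold models
can be merged (filter union, re-sorted by MCC) into one screening model —
how the original fold models were merged for screening is not specified
anywhere, so the union is this package's choice and is explicit in the
model file.

## Pose profiling

Interaction detection is heavy-atom and distance-only: H-bonds are
donor/acceptor-capable element pairs (N, O any role; S acceptor) within
3.5 Å, restricted to the listed H-bond residues, with pair-level counting
(two polar atoms near one carboxylate count twice — deliberate, since the
published rule counts hydrogen *bonds*, not partners); VdW contact means
any heavy atom of a listed residue within 5 Å of any ligand heavy atom.
No angle term is applied because docked poses and prepared receptors
frequently lack hydrogens and the source rules state only distances.
Waters, ions and het ligands are stripped on load, so bridging-water
H-bonds are out of scope.  Residue lookup uses canonical numbering
(Asp32/Asp228) with an explicit per-structure numbering map (e.g. +61 for
the Asp93/Asp289 convention); maps are configuration and never inferred.

Rules: BACE-1 — ≥ 4 H-bonds, of which ≥ 2 to the catalytic dyad (both
aspartates pooled), and ≥ 8 contacted residues from the 13-residue list
(7 H-bonding + 6 VdW); an `any_residue_contacts` switch widens the contact
count to the whole protein for users who read "eight contacts with the
protein" literally.  AChE — contacts with all nine gorge residues; H-bonds
are profiled but not part of the rule.  A molecule is docked per structure
if any of its ≤ 10 poses passes, docked overall if docked in ≥ 1
structure, and its reported pose total is summed over structures (max 30
for the three BACE-1 protonation states).

## Structure selection and candidate ranking

Enrichment ratio = (docked actives / actives) / (docked inactives /
inactives), flagged infinite when no inactive docks; specificity =
fraction of inactives rejected.  Ratios are reported unrounded plus
rounded to two significant figures.  Ranking is best-first by the chosen
criterion with the other criterion, then the structure id, as tie-breaks.

Components (model indexes, docked flags, pose counts) are normalized to
[0, 1] (indexes via (x+1)/2, pose counts by their maxima) and combined
linearly with weights on the probability simplex.  The exact historical
weighting formula is not published; the linear normalized form with a
seeded Dirichlet random search (2000 draws + the uniform vector,
objective = fraction of known duals above threshold minus fraction of
randoms above it) is this package's fully specified stand-in, and the
weight vector is always serialized next to the results.  "Score > 0.5 in
all scores" is read as: the global score *and* each per-target sub-score
(weighted mean of that target's components) must exceed the threshold
strictly; calculated logP must be strictly below 4.  Rejected molecules
carry an elimination reason.

## Synthetic fixtures

*Classification tables*: informative descriptors are class-conditional
normals separated by the effect size in sd units; noise descriptors share
one distribution.  The canonical test conditions are 200+200 molecules,
20 descriptors, 3 informative at 3 sd — separation strong enough that a
five-range filter can reach MCC ≥ 0.8 on a 100-row held-out split, yet
weak enough that a poor search cannot.

*Receptor/pose geometries*: the criteria's residues sit on a circle with
≥ 15 Å spacing; each residue is a minimal amino acid (N, CA, C, O, CB and
one outward polar atom).  H-bond plants are ligand nitrogens 3.0–3.1 Å
from the residue's polar atom inside a narrow cone (≤ 5 per residue by
packing); contact plants are carbons 4.5 Å from CA; decoys lie > 20 Å
away; no two atoms come closer than 1 Å.  The spacing guarantees no
interaction leaks across residues, so the planted profile is *exactly*
what the profiler must report — the generator/analyzer pair is tested for
equality, not tolerance.  The whole complex receives a seeded random rigid
rotation and translation, which doubles as a rigid-motion-invariance
exercise.  Bond-chemistry realism is not attempted: the profiler is
element- and distance-based, so elements and coordinates suffice, and the
files are labelled synthetic.

*Libraries*: SMILES assembled from a small fragment grammar (2–6 ring and
chain units), RDKit-validated and canonical; ~95% unique at n = 1000.

What passing tests show — and do not.  The fixtures establish that the
statistics, rules and search behave exactly as specified on data whose
ground truth is known.  They do not show that real activity data is
separable by five-range filters, that real poses are as clean as planted
geometries (no competing residues at 5–15 Å, no alternative conformers),
or that the descriptor set matches any historical proprietary set; model
quality on real data must be established with the cross-validation
harness on that data.

## Problem sizes and numerical choices

The end-to-end dry run uses a 1,000-molecule library, 30 docking
candidates and 1 pose per structure — sizes chosen so the full suite and
the acceptance script each complete in well under a minute per run while
still exercising every stage.  Hidden "activity" rules in the dry run are
two-descriptor quantile-band rules (a property window, like a real potency
cliff) rather than top-quantile rules, which would confound activity with
molecular size and push every candidate over the logP cut.  All
randomness flows from numpy `default_rng` seeded by the caller; every
entry point is deterministic under its seed.

## Known limitations

- Historical MCC/AUC tables from screening campaigns on curated ChEMBL
  snapshots with proprietary descriptors are not reproducible here by
  design; the harness reproduces the experimental design, not those
  numbers.
- H-bond detection without hydrogens or angles over-counts relative to
  geometric H-bond definitions; this matches the distance-only rule the
  profiler implements but is not a general-purpose interaction
  fingerprint.
- The weight-calibration search optimizes a step-function objective; with
  few reference molecules many weight vectors tie and the seeded search
  picks one reproducibly, but the tie structure means weights should be
  read as *a* solution, not *the* solution.
- `sample_decoys` matches marginal property windows, not the joint
  distribution; strongly correlated actives can admit decoys outside the
  joint envelope.
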