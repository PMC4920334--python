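# Methods

This note documents the models and procedures implemented in `paleoroute`,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical and design decisions a maintainer
would want written down.

## Orthologue screening

The screening engine formalizes a curation workflow for growing a
phylogenomic gene-family collection one species at a time. For one family:

* **Prefilter.** Candidate sequences enter only if some similarity hit has
  E-value strictly below the threshold (default 10⁻²⁰). The hit-table reader
  supports the minimal 3-column and the standard 12-column tabular layouts;
  the E-value column is explicit configuration, never autodetected beyond
  the column count, because a silently misparsed column is worse than a
  required flag.
* **Placement.** A candidate is inserted into the existing alignment by
  global pairwise alignment (BLOSUM62, gap open −11 / extend −1) against the
  best-scoring existing row; candidate insertions become all-gap columns, so
  existing rows are never edited. Realignment retries use the second-best
  reference row.
* **Distance statistics.** All decisions consume only patristic distances
  on a gene tree. The built-in backend is neighbor-joining on
  gamma-corrected 20-state distances (shape 1.0); any externally computed
  tree (e.g. a maximum-likelihood tree) can be supplied instead, and the
  decision rules are invariant to that choice up to the distances it
  implies. The reference statistic is the mean and *sample* (n−1) standard
  deviation of all pairwise distances among previously accepted
  orthologues; the acceptance ceiling is mean + 3·SD. The sample SD is the
  conservative choice for the small reference sets where the statistic is
  noisiest. At least 4 accepted orthologues (6 pairs) are required for a
  usable SD; smaller families route every candidate to `indeterminate`
  rather than pretending to a threshold.
* **Decision table.** Single candidates: within threshold → rule 1
  (accept); beyond threshold the candidate is checked for misalignment —
  operationalized as fewer than 50% of its non-gap residues falling in
  columns occupied by at least 50% of the other rows — with one realignment
  retry. A candidate still misaligned after the retry is rejected under
  rule 2a; one whose realignment brings it under the threshold is accepted
  under rule 1 with a note. Otherwise plausibility decides: implausible
  placement → rule 2b (reject as probable paralogue), plausible → rule 2c
  (accept but flag for possible later exclusion). Multiple candidates: a
  monophyletic candidate clade with acceptable average distance keeps only
  the member with the shortest terminal branch, ties broken by smallest id
  (rule 3a); a non-clade with exactly one member within threshold keeps that
  member if plausibly placed (rule 3b); all members beyond threshold are all
  rejected (rule 3c). Mixed configurations outside the table — including a
  single within-threshold candidate that is implausibly placed — are
  labelled `indeterminate` for manual review rather than guessed.
* **Plausibility** automates visual inspection as nearest-accepted-
  neighbour taxonomy agreement at a configurable rank: at a coarse rank a
  myriapod sequence clustering with a chelicerate passes, while at any rank
  an arthropod sequence clustering with a vertebrate fails.

Decision records are total (every candidate gets exactly one) and a record
is accepting only under rules 1, 2c, 3a, 3b. Co-candidates passed over in a
3a/3b family share the scenario's rule code with `accepted = False` and an
explanatory note, since the scenario — not the individual — carries the rule
identity.

"Minimal branch length" in rule 3a is read as minimal *terminal* (pendant)
branch length: the natural per-sequence quantity. Rule 3b is read literally
as exactly-one-below-threshold.

## Block trimming and concatenation

The trimmer implements a documented simplification of conserved-block
trimming driven by four settings: a column whose gap fraction exceeds
`max_gap_fraction` (default 0.5) is excluded outright; otherwise the modal
residue frequency over **all** rows (gaps count against conservation)
classifies it as highly conserved (≥ `flank_fraction`, default 0.75),
conserved (≥ `conserved_fraction`, default 0.5) or nonconserved. Kept
blocks are the maximal runs of conserved-or-better columns, shrunk to their
outermost highly conserved columns (flanks must be highly conserved), that
are at least `min_block` (default 5) columns long. The full iterative
flank-trimming algorithm of the classic implementations is deliberately not
reproduced — the simplified rule is fully specified by the printed settings
and is testable against a brute-force column scan. Trimming is idempotent.

Column coordinates are 1-based inclusive in every report; internal indices
are 0-based half-open. Concatenation orders genes lexicographically (a
deterministic choice), pads absent taxa with gaps, and emits a partition
table that provably tiles the matrix plus per-taxon occupancy.

## Timescaling

`assign_node_ages` implements deterministic minimum-age scaling: a
post-order pass sets each internal node's age to the oldest child age plus a
minimum branch duration (default 1 Myr), lifted to any calibration minimum
resolving to that node; a pre-order pass re-checks monotonicity. Fossil
tips sit at their occurrence age (ranges must be resolved to a point age by
the user). Calibration maxima are hard constraints: a conflict aborts with
the offending node named, because silently compressing ages would corrupt
every downstream rate. Stochastic timescaling (cal3-style) and relaxed-clock
dating are out of scope. The 1 Myr minimum branch duration is a documented
default, not an estimate; it only breaks exact zero-length branches.

## Mk ancestral-state reconstruction

* **Parameterization.** q is the rate of change to each alternative state
  (the off-diagonal entry of the generator), so the total leaving rate is
  (k−1)q. This matters when comparing rates across software, since Mk
  parameterizations vary.
* **Root prior** is uniform — the stationary distribution of the symmetric
  chain and the standard equal-rates maximum-likelihood convention.
* **Likelihood** by pruning with per-node rescaling (stable to hundreds of
  tips). At q = 0 the likelihood is 1/k when all tips share a state and 0
  otherwise.
* **Optimization**: bounded scalar search on log₁₀ q over [−8, 2] with
  tolerance 1e-8. The 1-D likelihood is unimodal in practice; no restarts.
  An all-identical tip configuration returns q̂ = 0 with a warning, not an
  error.
* **Marginals** by the outside–inside (re-rooting) recursion; because the
  Mk transition matrix is symmetric the outside partials propagate with the
  same matrices as the inside ones. Per-node vectors are normalized to sum
  to one. At the root these equal the prior-weighted conditional
  likelihoods; away from the root they are true re-rooted marginals.
* **Fossil tips** need no special treatment: the chronogram's branch
  durations already terminate them at their occurrence ages, which is
  exactly how deep fossils inform ancestral states. Ambiguous tips
  (state `?`) carry a partial-likelihood vector of ones.

## Rate diagnostics

Branches of the chronogram and the substitutions-per-site tree are matched
by the tip set below them; rate = substitution length / duration, and each
branch carries the midpoint of its parent and child ages. The at-median
fraction needs a tolerance for "identical to the median": relative 1e-6 by
default, exposed as configuration because any such count is
tolerance-dependent. Internal branches only by default; a flag includes
pendant branches. Root-ward clustering is operationalized as a one-sided
permutation test on branch midpoint ages (statistic: mean age of at-median
branches minus mean age of the rest; smoothed p = (1 + #{perm ≥ obs}) /
(n_perm + 1), seeded). The test design is this package's contribution; its
null calibration is checked empirically in the acceptance suite.

## Synthetic data: what it emulates, what it does not

* **Species trees** are seeded Yule trees (exponential waiting times, a
  final stem draw so every pendant branch is strictly positive).
* **Sequences** evolve under a 20-state symmetric substitution process with
  expected substitutions per site equal to branch length; the probability
  two sites separated by path length d match is 1/20 + (19/20)e^(−20d/19).
  No rate heterogeneity across sites, no indels, no empirical
  exchangeabilities — enough to drive distances and the screening rules,
  and fully analyzable in closed form.
* **E-values** come from a fixed monotone surrogate map,
  E = 10^(2 − L·max(0, identity − 0.06)) clamped to [1e-180, 100]: identical
  sequences hit the floor, random amino-acid background sits at 100. It
  does not claim to reproduce real search statistics.
* **Gene families**: Poisson duplications fall on edges proportionally to
  length; pendant-edge duplications yield in-paralogs, internal-edge
  duplications yield elongated out-paralog subtrees. The validation
  scenario (`plant_out_paralog`) uses the canonical out-paralog history — a
  duplication preceding the family's root speciation, with the copy's
  branches (stem included) multiplied by 3 — because that construction
  guarantees the planted paralog's mean distance (> 4 tree depths) exceeds
  any attainable mean + 3·SD threshold (< ~3 depths), whereas shallower
  within-tree duplications straddle the threshold on a nontrivial fraction
  of Yule trees. Default family size is 20 taxa; real curated families are
  typically larger still.
* **Habitat states** evolve forward under the same Mk transition
  probabilities the inference uses, with a uniform (or pinned) root state.
* **The fossil-bearing demonstration case** grafts one deep Cambrian-age
  marine fossil tip (sister to the whole extant radiation), two Devonian
  and one Triassic–Jurassic freshwater fossils onto a 21-tip extant tree
  with mostly freshwater tips — the qualitative structure of a total-group
  crustacean habitat matrix. It is a synthetic stand-in: reproducing any
  published root probabilities exactly would require the source topology,
  calibrations and habitat matrix.
* **Rate fixtures** plant round(0.645 · n) internal branches exactly at the
  base rate (which is then the median, since the fraction exceeds one half)
  with the remainder lognormal around it; 202 tips give 200 internal
  branches so the planted fraction is exactly 0.645. `rootward=True` makes
  the at-median branches the oldest by midpoint; `rootward=False` is the
  null configuration for calibrating the permutation test.

Passing tests on these generators demonstrate correctness of the
implemented statistics and decision rules under the stated models; they do
not demonstrate robustness to alignment error, rate heterogeneity,
incomplete lineage sorting, or fossil misplacement, none of which the
generators produce.

## Problem sizes and determinism

The test and acceptance workloads use 100 enumeration cross-checks on ≤5-tip
chronograms, 20 rate-recovery replicates on one 500-tip chronogram, 50
screening families of 20 taxa, and 200 null simulations × 199 permutations
for the clustering-test calibration — sizes at which the enumeration oracles
are exact and the whole suite runs in seconds. Every stochastic component
takes an explicit seed; reruns are byte-identical, and `scripts/acceptance.py`
derives all of its seeds from `--seed`.

## Known limitations

* The alignment placement is pairwise-against-one-reference, not a profile
  aligner; heavily gapped references can produce suboptimal placements
  (they are then caught by the misalignment rule rather than fixed).
* Neighbor-joining with gamma-corrected distances is a deliberately simple
  tree backend; for publication-grade screening supply an external ML tree.
* Minimum-age timescaling produces the youngest chronogram consistent with
  the constraints; node ages are lower bounds, not estimates.
* The Mk model assumes a single symmetric rate; directional habitat
  transitions (e.g. marine → freshwater easier than the reverse) require an
  asymmetric model, which is out of scope.
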