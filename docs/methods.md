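# Methods

## Problem setting

Fungal hybrid megasynthetases (PKS-NRPS and NRPS-PKS genes) show a patchy,
section-crossing distribution in genera like *Aspergillus*. Two processes
can produce that pattern: vertical inheritance followed by differential
loss, and horizontal gene transfer (HGT). They leave different traces in a
gene tree. Under vertical inheritance with loss, surviving homologs still
sort by taxonomic section and accumulate divergence, so each gene's nearest
tree neighbor is a same-section gene. HGT instead places a gene at a short
patristic distance from genes of a foreign section. `hybridtrace` measures
exactly that quantity and validates the measurement against simulations
with known ground truth.

## Domain merging and architecture calls

Domain scanners report megasynthetase domains as multiple short fragments
often enough that merging is required before any architecture call. Two
same-type annotations merge when **both** fragments are shorter than 350 aa
and the gap between them (`next.start − prev.end − 1`, 1-based inclusive
coordinates) is under 100 aa. The length condition is read as applying to
the candidate fragments, not to the merged span: the rule exists to glue
split fragments, and a full-length (≥ 350 aa) domain is not a fragment.
Merging proceeds leftmost-first, the growing interval absorbing successors
until ineligible; because absorption only grows interval lengths and never
reopens a rejected pair, one sweep reaches the fixed point (the
implementation still re-sweeps defensively, and idempotence is tested).
Overlapping same-type intervals are scanner artifacts and merge
unconditionally, carrying a warning flag. Different types never merge.

Architecture calling is deliberately simple and rule-based: PKS module =
KS ∧ AT; NRPS module = C ∧ A; both modules → hybrid, oriented P-type
(PKS-NRPS) if the first KS starts before the first A, else N-type; single
modules give PKS / NRPS; KS without AT → PKS-like; A without C → NRPS-like;
anything else → other. This is a documented stand-in for pipeline-specific
annotation systems (e.g. SMURF) whose exact rules are not public; it is not
expected to reproduce any particular published gene census. The
signature-to-token vocabulary is a shipped, editable two-column table;
unmapped signatures are ignored by the classifier. Duplicate (type, start)
rows are rejected at parse time, which also guarantees the orientation rule
never ties.

## Distances and the nearest-neighbor screen

The cophenetic matrix is computed in one postorder sweep (each node carries
its subtree's tip-depth list; pairs meeting at a node get the sum of their
depths), O(n²) total and independent of root placement. Tests hold it
against an independent per-pair lowest-common-ancestor path walk on 1000
random trees, and check the four-point condition of additive tree metrics.

For each focal tip the nearest non-self tip is found by exhaustive row
scan; exact ties break to the lexicographically smaller tip id, making the
result deterministic and order-invariant. Same-species paralogs are
eligible neighbors — the screen reports `same_species` so users can filter,
rather than silently excluding them. A tip becomes a **candidate HGT** when
its nearest neighbor is cross-section *and* the distance falls within a
quantile (default 0.25) of all nearest-neighbor distances; the quantile is
a screening knob, not an estimate, but the short-distance condition is part
of the signal — distant cross-section neighbors arise whenever a section
retains a single homolog, with no transfer involved.

Monophyly uses unrooted edge semantics: a labeled set is monophyletic iff
some edge's removal bipartitions the tips into exactly that set versus the
rest. The implementation compares cached per-node tip sets (and their
complements) under the written rooting, which enumerates all edges of the
unrooted tree; tests verify agreement with an independently coded per-edge
graph traversal on 1000 random (tree, subset) instances and invariance
under rerooting. Singleton sets are trivially monophyletic. Maximal
attribute-pure clades (both sides of every bipartition, filtered to
single-valued tip sets, then reduced to maximal elements) always partition
the tips and quantify how section-sorted a tree is.

## Hit filtering

Per query: drop hits below 80% query coverage, then keep the top 15 by
descending bitscore, ties broken by ascending e-value then subject id.
Coverage-first order follows the natural reading of "best N hits satisfying
a coverage cutoff"; "best" means bitscore because bitscores are
database-size independent. When the tabular input lacks a coverage column
it is computed as `100 × alignment_length / query_length` from the
companion FASTA. Compound labeling joins each tip's single best retained
hit against a reference subject→compound map; unlabeled subjects warn and
leave the tip unannotated.

## The simulator

`synthetic_data` provides the controlled conditions for validating the
screen.

**Species tree.** Ultrametric, with sections monophyletic by construction.
Within-section coalescences at ages uniform in (0.2, 1.0) ×
`within_section_divergence`; section stems join at ages uniform in
(0.75, 1.0) × `species_tree_height`, root pinned at the height. This is the
"deep stems, shallow tips" regime in which the screen's baseline is clean:
with no transfer, every nearest neighbor is same-section.

**Gene process.** Each gene lineage duplicates at rate λd, dies at rate λl
and transfers a copy at rate λt (exponential waiting times, one seeded
generator for everything). A transfer recipient is a contemporaneous
species-tree branch, drawn from the branches whose section sets are
disjoint from the donor's with probability `transfer_cross_section_prob`
(otherwise from the remainder; if the preferred pool is empty the other is
used, and with no recipient at all the event is a no-op). Transfers are
additive — donor and recipient both carry the gene afterwards. Every event
is logged; every extant tip records whether any transfer lies on its
root-to-tip path. Branch lengths are elapsed time × i.i.d. lognormal noise
with mean 1 and CV `branch_length_noise_cv`, a cheap surrogate for rate
heterogeneity.

**Defaults** (chosen once as the study conditions): 4 sections × 4 species,
height 1.0, within-section divergence 0.1, λd = 0.3 and λl = 0.2 (gene
turnover is frequent in these families), λt = 0.1 — calibrated a priori so
that the probability of no transfer on a height-1 root-to-tip path,
e^(−0.1) ≈ 0.90, leaves roughly 10% of tips with transferred ancestry
(measured: ~9%) — cross-section probability 1.0, noise CV 0.3.

**Bookkeeping.** Extant copies = root copies + duplications + transfers +
lineage splits at speciation nodes − losses; the speciation-split count is
carried on the result so the identity is checkable from the event log.

## What the simulations show — and what they do not

The validation experiment (100 replicates at the defaults) yields:

* the λt = 0 control produces **zero** candidate-HGT flags;
* with all rates zero the gene tree is topologically identical to the
  species tree (RF = 0) in 100/100 seeds;
* transferred tips sit far closer to foreign sections than vertical tips
  (nearest-cross-section distance, one-sided Mann–Whitney p ≈ 1e-70;
  medians ≈ 0.75 vs 1.56);
* mean recall of the cross-section nearest-neighbor call is ≈ 0.16–0.24
  and mean precision ≈ 0.5.

The low recall is a structural property of the process, not an
implementation artifact, and it delineates the screen's real sensitivity:
with deep stems, most of a lineage's lifetime is spent on section stems, so
most transfers land there and the transferred copy subsequently co-speciates
with the recipient section. All its descendants are truth-positive, but
their nearest neighbors are *each other* — same section — so the screen
cannot see them. The screen detects **recent, single-lineage** transfers
(the lone foreign tip inside a host clade), which is precisely the
short-distance signature it was designed around; it is blind to ancient
transfers that have since speciated into whole section-pure families, and
it produces occasional false positives when loss strands a section with a
single surviving homolog (mitigated by the short-distance condition in the
candidate flag). Users interpreting per-species origin summaries on real
data should read them the same way.

Other aspects of real data the simulator does not emulate: sequence-level
evolution (branch noise is lognormal, not a relaxed clock with site
heterogeneity), gene conversion or recombination between hybrids after
transfer, incomplete lineage sorting, and alignment/tree-inference error.
Passing tests therefore demonstrate correctness of the computations and the
qualitative behavior of the screen under a clean DTL process, not
performance on any particular empirical dataset.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere; gap = next.start − prev.end − 1.
* Missing branch lengths parse to 0 with a warning; trees with < 2 tips are
  rejected by the distance code; single-tip trees still round-trip.
* Newick serialization uses 10 significant digits; round-trip isomorphism
  and branch-length sums are property-tested.
* Nearest-neighbor and hit-filter ties have total deterministic orderings
  (lexicographic ids; bitscore → e-value → subject id).
* An all-extinct gene family returns `gene_tree=None`, flagged `extinct`,
  with recall/precision reported as undefined rather than 0.
* Simulation problem sizes in tests and the acceptance script (100
  replicates, 16-species trees, tens of gene copies) were chosen as the
  smallest sizes at which the Monte-Carlo checks are stable.
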