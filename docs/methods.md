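# Methods

This note documents the models and procedures implemented in `paleokaryo`,
the parameters that matter, what the simulator does and does not emulate,
and the numerical choices made where the design was open.

## Synonymous divergence (Nei–Gojobori)

`ksdist.ng_ks` implements the NG86 counting estimator for aligned, in-frame
coding sequences.

* **Sites.** At each codon position the synonymous fraction is
  (number of synonymous single-nucleotide changes) / (number of possible
  changes), with changes that create stop codons excluded from the possible
  set; the nonsynonymous fraction is its complement, so S + N = 3 per
  compared codon. Sites are averaged over the two sequences.
* **Differences.** Codons differing at k positions are scored by averaging
  synonymous/nonsynonymous step counts over the k! orderings of single
  steps, excluding orderings that pass through a stop codon; if every
  ordering does, all orderings are used with stop-adjacent steps counted as
  nonsynonymous.
* **Correction.** Jukes–Cantor, d = −¾ ln(1 − 4p/3), matching the original
  method. p ≥ 3/4 is reported as a saturation flag on the estimate, not an
  exception. Gap- or N-containing codons are skipped pairwise.

An independent implementation (Biopython's experimental NG86 routine) is
used in the test suite as a cross-check; its stop-codon convention differs
slightly (stop-creating changes count as nonsynonymous sites), so agreement
is asserted to ±0.02 on random stop-free sequences and exactly on
hand-enumerated codons.

## Ks peak fitting

Per-block median Ks values (median of the defined pair estimates; even
counts take the central mean) represent blocks. Peaks are located by
fitting 1..k_max-component Gaussian mixtures by EM
(scikit-learn's `GaussianMixture` behind the module surface) and choosing
the component count with the lowest BIC.

Parameters: trimming window (0.005, 3.0] before fitting — the floor removes
allele-level noise, the ceiling saturated pairs; 10 k-means++-seeded
restarts; EM tolerance 1e-6; 500 max iterations; reported standard
deviations floored at 1e-4 (a degenerate all-identical sample fits a
single near-delta component rather than erroring). At least 50 values are
required. Fitting is deterministic given the seed. When a dataset yields
fewer than 50 block medians (small simulated genomes), the pipeline falls
back to per-pair Ks values and records which stream it used.

## Anchors and collinear blocks

Homolog pairs become dot-plot anchors if they pass a c-score filter: pair
(a,b) is kept iff score(a,b) ≥ c × max(best score of a, best score of b),
i.e. the pair is within the threshold of both genes' best hits. Defaults:
c = 0.99 for block, Ks and painting work. Self-comparisons drop identity
pairs and near-diagonal pairs within 10 ranks (tandem/proximal duplicates
are not collinearity evidence); tandem arrays (rank-adjacent same-family
runs) are collapsed to their highest-scoring carrier so they cannot inflate
depth.

Blocks are chained per chromosome pair by O(m²) dynamic programming with
chain score = anchor count, strict monotonicity on both rank axes
(separately for parallel and antiparallel orientation), and consecutive
rank gaps ≤ max_gap on both axes. Chains are extracted greedily
best-first, each anchor used at most once, ties broken deterministically
(smaller chromosome id, then lower rank). Defaults min_block_size = 5,
max_gap = 25, consistent with common collinearity-tool practice; gene rank,
not base pairs, is the coordinate throughout, with base pairs kept only for
reporting.

## Syntenic depth and ploidy inference

For a query/reference comparison, the depth of a reference gene is the
number of blocks whose reference-axis rank span contains it; the modal
depth over covered genes (depth ≥ 1) is the query's retained copy number.
Covered-only modes are used because fractionation-induced zeros would
otherwise dominate. A minimum covered fraction (default 0.3 per side)
guards the mode's meaning.

**Depth uses a permissive homolog set (c = 0.5).** Co-ortholog copies
created by the same polyploidy event diverge from the reference at the same
time, so their similarity scores are statistically tied; a strict c-score
keeps only the noise-best copy per gene, thins each copy's anchor density
by the copy number, fragments the blocks, and biases the modal depth
downward (a 2×2×2 history then reads 7:1 rather than 8:1). Block, Ks and
painting stages keep the strict threshold, where one-best matching is the
point.

Ratios are decomposed into ordered factor sequences over {2, 3} whose
length equals the number of post-reference Ks peaks, by exhaustive
enumeration. A unique factorization is an unambiguous call (factors mapped
oldest-peak-first); multiple factorizations set an ambiguity flag listing
all candidates — cross-species comparisons are the sanctioned resolver —
and zero factorizations raise an inconsistency. Ratios whose query side is
not divisible by the reference side are routed to the shared-event test.

**Shared vs independent events.** Events of equal multiplicity on two
lineages whose paralog-peak ages agree within a tolerance (default 0.15 Ks,
configurable) are paired as shared, oldest first; unpaired events are
lineage-specific. The observed cross-lineage ratio is then checked against
the pairing under two conventions — orthologous depth (shared events cancel)
and paralog-inclusive depth (they do not) — because published ratios mix
both conventions; a ratio matching neither is reported as inconsistent with
no call, and the rule used is recorded in the output.

## Karyotype painting and event classification

Painting partitions each extant chromosome into maximal anchor runs
assigned to the proto-chromosome contributing the anchors. Runs with fewer
than `min_paint` (3) anchors or spanning fewer than `min_segment_genes`
(10) ranks are merged into the flanking segment with more anchors (ties
toward the preceding segment); segment bounds are then stretched to cover
every rank, so the painting is a partition.

Classification reduces each chromosome's segment signature iteratively:

* **NCF** — a complete donor segment (reaching both its proto's termini
  within a `telomere_window` of 5 ranks) flanked on both sides by the same
  host proto; the flanks merge and reduction continues, so stacked fusions
  resolve.
* **EEJ** — a junction where both segments reach their own proto's
  terminus; fused composites track their outer ends, so chains of
  successive end-joins (the A6+C6+B6 pattern) reduce correctly. An NCF
  whose insertion point lies within `min_segment_genes` of a host end loses
  its short flank in painting and degrades to an EEJ read — the same
  one-sided ambiguity that arises when such signatures are read from real
  dot plots.
* **RTA** — two chromosomes left unreduced that carry the same two protos
  as reciprocal partial arms count as one paired, count-neutral event.
* Remaining split protos are **FISSION**; anything else is reported
  **UNRESOLVED** with its signature attached, and the chromosome-count
  arithmetic n_extant = n_proto − #EEJ − #NCF + #FISSION is emitted with a
  balanced flag.

Painting is done against a ploidy-matched ancestor proxy — for simulated
lineages, the snapshot taken immediately after the lineage's most recent
polyploidy — so each proto copy is a distinct painting target and the
arithmetic is well-defined.

## Ancestral-karyotype reconstruction

For a conserved genome claimed to hold m complete ancestor copies:
(1) the claim is verified against the intra-genomic modal block depth;
(2) block-side intervals are merged into regions per chromosome (strict
overlap only — touching intervals are kept apart because a fusion junction
is a touch), adjacent regions are merged when they share a partner
chromosome (continuity on an intact copy spans its partner's fusion
junction, while the junction itself joins regions with different partners),
and the connected components of the block graph, gated to blocks whose
median Ks lies within ±0.2 of the WGD age, are the proto-chromosomes;
(3) each proto is validated by its component-local modal copy count and,
when an outgroup is supplied, by requiring ≥ 0.6 of its families to be
outgroup-collinear. Orientation of reconstructed protos is arbitrary and
reported as such. Known limitation: if both copies of the same proto pair
are fused to each other reciprocally (copy 1 of P nested into copy 1 of Q
and copy 2 of Q into copy 2 of P), the block graph is genuinely cyclic and
the two protos cannot be separated by connectivity alone; such karyotypes
fail validation rather than silently merging elsewhere.

## Subgenome assignment, CSO logic, duplication modes

Genes take the subgenome of the doubled-ancestor copy whose painted segment
covers them; LF/MF polarity comes from total assigned counts with a
two-sided binomial test (p < 0.05) separating real dominance from noise,
and exact ties labelled with a warning. The CSO filter admits orthogroups
present in ≥ min_units (8) subgenome units and in all required outgroup
units; cells are categorised Absent / Single Copy / Two Copies / Multiple
as a pure function of the count, and CSOs cluster 1/2/3 by the first
outgroup's copy number (1, 2, ≥3; absent outgroup copies fall to cluster 1).
"Retained in over 50% of a subgenome class" is read as a strict inequality,
so with eight units retained means ≥ 5. Asymmetry across species pairs is
tested per cluster and category with a two-sided Wilcoxon signed-rank test
(the significance threshold the source analyses quote without naming a
test), skipped with a notice below 5 pairs.

Duplication modes follow the DupGen-style precedence WGD > TD > PD > TRD >
DSD: collinear-block anchor membership (with anchors whose Ks deviates more
than 0.3 from their block's median excluded — a young tandem pair that
chains into an old homeologous block is not a WGD duplicate); rank-adjacent
homolog; homolog within proximal_window = 10 ranks; not outgroup-syntenic
while the closest (best-scoring) partner is; everything else dispersed.
Genes with no within-genome homolog are UD. The outgroup ancestral-locus
test uses anchor membership of permissively chained outgroup blocks
(c = 0.5), because under strict filtering a young duplicate out-competes
its parent's ortholog pair and erases the parent's ancestral-locus
evidence.

## The simulator and what passing tests show

`evosim` evolves ordered gene layouts through dated events applied oldest
first. Ks for a pair is drawn from Normal(age, 0.1·age) truncated at zero —
an explicit per-event peak model rather than a substitution clock — and
homolog scores are synthesised as 100·(1 − ks/3), so c-score filtering can
be exercised without alignment. Families are single-copy at the root, which
makes depth ratios analytically predictable. Fractionation keeps at least
one copy per family (conditioning that raises effective retention from p to
p/(1−q), q the all-copies-lost probability — the tests assert this
conditional expectation). Small-scale duplications are planted at distinct
ages spread over an interval and at loci not already involved in an earlier
event, so each duplicate's closest homolog is its own partner; dispersed
duplications relocate both copies, since the transposed mode is defined by
the parent keeping the ancestral locus. Random fusions prefer previously
untouched chromosomes, nested insertions land ≥ 25 genes inside the host,
translocation breaks stay ≥ 15 genes from termini, and inversions nest
within a single ancestral segment — event placements that keep signatures
separable, as the trajectories reported for real genomes typically are.

Problem sizes used throughout the tests and the acceptance script — 11
proto-chromosomes × 200 genes for depth and trajectory work, × 300–450 for
the duplication-mode battery, 1,500 points per mixture component — are desk
scale and chosen so each check isolates one inference.

What the simulator does not emulate: nucleotide-level evolution beyond
synonymous edits (no transition/transversion bias, no rate variation across
sites or lineages), gene-family birth at the root, annotation error,
missing orthology, transposable elements, or base-pair genome size. Passing
tests therefore demonstrate that the inference machinery is correct under
its stated model — unimodal per-event Ks peaks, rank-collinear blocks,
majority-vote painting — not that it is robust to assembly or annotation
artefacts in real genomes.
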