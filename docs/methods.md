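# Methods

This note documents the models and procedures implemented in cslkit, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.  Every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Catalog and motif model

A catalog row is a gene-family member with a TIGR-style locus identifier
`LOC_Os<chr>g<number>`; the chromosome (1–12) is parsed from the locus and
cross-checked against the family table.  The **ordinal index** — the rank of
the gene model along its chromosome — would normally come from a full genome
annotation; the catalog parser derives it as `locus_number // 10`, exploiting
the convention that gene models are numbered in steps of ten.  This is a
heuristic: it is exact whenever the annotation kept the original numbering,
and it is the basis of the intervening-gene count in the tandem rule.

The catalytic signature of processive glycosyl transferases is scanned as an
ordered leftmost search: the first `D-x-D`; then the next isolated aspartate
(no adjacent D) at least `g_min` residues downstream; then the first
`?-x-x-R-W` pentapeptide downstream of that, whose first residue names the
variant (Q, R, L are the observed classes; anything else is reported
literally and flagged nonstandard).  `g_min` defaults to 5 residues.  The
biology fixes the motif composition but not the spacing, so `g_min` is a
design choice, exposed as a parameter; per-gene calls on proteins whose true
spacing is unusual are therefore not guaranteed.

Percent similarity is a global end-to-end Needleman–Wunsch alignment with an
identity matrix (match +1, mismatch 0, gap −1, no affine gaps) returning
`100 · matches / alignment_length`.  Among score-optimal alignments the one
with the most matches, then the shortest, is chosen, which makes the value
well-defined and symmetric.  The integral scoring keeps the dynamic program
exactly checkable against exhaustive alignment enumeration (done in the
tests for lengths ≤ 6).

## Duplication calling

**Tandem.**  Two same-family members on one chromosome link when at most
`max_intervening` gene models (default 5) lie between them, measured on the
ordinal index; the transitive closure forms clusters.  Only same-family
links are allowed — a tandem duplicate is by definition a family paralog.

**Segmental.**  Pre-scored collinear anchors are chained by dynamic
programming: chain score = Σ anchor scores − Σ gap penalties, with penalty
`score_unit · mean(gap_a, gap_b) / max_gap` per link and links forbidden
when either axis gap exceeds `max_gap` (default 100 kb).  Both orientations
of the second axis are tried; blocks are extracted best-first and chains
with fewer than `min_anchors` (default 5) are discarded.  The classic
synteny-tool parameterization (minimum five aligned pairs, 100 kb distance)
maps onto `min_anchors` and `max_gap`; E-value filtering of anchors is out
of scope because anchors arrive pre-scored.  A same-family pair whose two
members fall inside the two regions of one block is called segmental;
pairs already joined in a tandem cluster are excluded.

**Fate classification.**  A tissue counts as expressed when the signal
exceeds a threshold θ (pipeline default: the 60th percentile of the whole
matrix).  With Jaccard overlap j between the two expressed-tissue sets
(cut 0.5) and the Pearson correlation's two-sided t test (α = 0.05):

| condition | fate |
|---|---|
| one set empty, other ≥ 3 tissues | nonfunctionalization |
| overlap ≥ 0.5 and correlation significant | conserved |
| overlap < 0.5, both sets have exclusive tissues | subfunctionalization |
| overlap < 0.5, one set nested in the other | neofunctionalization candidate |
| anything else (incl. both silent) | ambiguous |

The underlying biology is qualitative ("lost expression", "strong
expression"), so θ, the overlap cut and the ≥ 3-tissue strength rule are
explicit configuration, not claims of a canonical decision boundary.  When
a gene has several probes the per-sample maximum across probes is used;
this is a pragmatic default for conflicting probe sets, not a validated
resolution.

## Co-expression clustering

Signals are transformed `x → log2(x+1)` (base and offset are a design
choice; the offset keeps zero signals at zero) and clustered by
agglomerative **complete linkage** on Euclidean distances.  The
implementation is the explicit O(n³) agglomeration with the max-of-max
Lance–Williams update and a deterministic tie-break (lexicographically
smallest combined member-name tuple), so merge histories are reproducible
bit-for-bit; complete linkage guarantees nondecreasing merge heights.  The
tests verify it against (a) a brute-force oracle that re-scans all
leaf-pair maxima at every step and (b) SciPy's complete-linkage heights.

The dendrogram is cut twice (k = 3 major groups, k = 10 subgroups, labelled
`IA…`), mirroring the three-major/ten-subgroup reading of a family panel.
The exact cut criterion used in classic heatmap figures is rarely stated,
so specific published memberships are not claimed to be bit-reproducible;
what the package guarantees is the partition property and planted-group
recovery (below).  Marker links are computed on raw signals by default
(`use_log` switches), reporting each marker's best non-marker partner and
flagging links with r ≥ 0.9.  Cross-study group matching uses cosine
similarity of signatures restricted to a tissue-concept map.  Tissue
specificity is `tau = Σ(1 − x_i/x_max)/(n−1)` on the log scale.

## Artificial-mutant screen

"Clustered together" is operationalized via the **minimal subtree**: the
lowest merge node whose subtree contains all focal leaves.  A candidate c
is *absorbed* when the minimal subtree spanning (remaining complex members
+ c) contains at most `slack` leaves that are neither complex members nor
candidates (default slack 1).  Spanning focal-plus-candidate, rather than
asking whether the candidate invades the focal pair's own subtree, matches
how a reader calls "X and Y clustered together with Z" on a dendrogram even
when X and Y merge first.

The screen is three steps: (1) gating — in every suspected tissue the
target must fall below the q = 0.25 quantile of its own cross-tissue
profile and at least one candidate must exceed its own median ("low" and
"high" are relative to the gene's own distribution because absolute
microarray levels are probe-dependent); (2) delete the target, re-cluster,
test absorption; (3) also remove the suspected tissues (all samples sharing
the tissue label, across varieties) and re-test.  Absorption present in (2)
and lost in (3) yields the `tissue_dependent` verdict; persisting,
`supported`; never present, `not_supported`.  Clustering defaults to the
genes supplied by the caller (the pipeline restricts to the families of the
complex genes, the analogue of clustering a CESA-only submatrix); double
deletions are composed by deleting further genes before screening.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design: 45 family genes in seven families
on 12 chromosomes; a six-member tandem array (max spacing 5) plus two
tandem pairs; six collinear blocks of eight anchors with sub-100 kb gaps,
each carrying one same-family pair; a 33-sample panel (17 tissues, two
varieties); ten co-expression groups in three super-groups; five marker
genes; one redundancy triple.  Signals follow

    signal = base · group_factor(tissue) · gene_amplitude · exp(N(0, σ²))

with base 100, high/low tissue factors 8.0 / 0.5, gene amplitudes
log-uniform on (0.8, 1.25), noise σ = 0.3 by default, and a silent level of
≈ 1.  Markers are group-mean copies plus additive noise scaled by
`τ = sqrt(1/r² − 1)` so the expected correlation equals the target r
(0.95); the measured median over 20 seeds is 0.95.  Proteins are built from
an alphabet excluding D, R and W so the planted motif components are
provably the only ones present.

The redundancy triple is planted structurally: the target sits in the
"complex" group but is silenced in two designated tissues; the candidate
group shares the complex's young-tissue signature plus those two tissues; a
*neighbour* group agrees with the complex everywhere except the two tissues.
With all tissues, the candidates are the complex remnant's nearest cluster
(absorbed); with the two tissues excluded, the neighbour group becomes
nearer and the absorption collapses — exactly the tissue-dependent pattern
the screen is designed to detect.  Measured recovery: 19–20 of 20 seeds at
σ = 0.2.

Because the silenced target is, by construction, an eleventh expression
pattern, the ten-group recovery benchmark runs the generator with the
redundancy triple disabled (a config field); at σ = 0.3 the median adjusted
Rand index over 20 seeds is 1.0.  With the triple present the target splits
off as a singleton at k = 10 and forces two genuine groups to merge
(median ARI 0.85) — a property of the planted design, not of the
clustering.

What the generator does **not** emulate: probe-level microarray artifacts
(MAS5 normalization, cross-hybridization), correlated noise across tissues,
variety effects, unbalanced group sizes, or genes whose group membership is
ambiguous.  Passing the recovery benchmarks therefore shows the procedures
are correct and well-calibrated on clean planted structure; it does not
bound their error on real arrays, where group boundaries are softer and
probe handling matters.

## Numerical choices

- All tie-breaks (cluster merges, argmax tissues, best partners, chain
  extraction) are lexicographic or index-based, making every output
  deterministic given inputs and seed.
- Pearson matrices are symmetrized and clipped to [−1, 1]; constant genes
  are excluded from correlation with a warning.
- |r| = 1 is treated as significant for any n ≥ 3 (the t statistic
  diverges).
- Expression files round-trip through text at six significant digits;
  reports contain no timestamps, so reruns are checksum-identical.
- Degenerate inputs fail loudly: empty sequences, all-zero profiles,
  negative signals, unknown ids and ragged rows raise typed errors naming
  the offender.

## Problem sizes

The test suite and acceptance script run the oracle comparisons at ≤ 12
leaves/anchors (where exhaustive enumeration is exact), the recovery
benchmarks at the study scale (45–50 genes × 33 samples, 20 seeds), and the
end-to-end determinism check on the full simulated pipeline; the whole
suite completes in a few seconds on one CPU.

## Known limitations

- The ordinal-index heuristic miscounts intervening genes wherever an
  annotation renumbered loci; a positional GFF3 can be supplied instead.
- Anchor generation (genome self-alignment, E-value filtering) and
  duplication dating (Ks/Ka) are out of scope.
- The fate decision table collapses a continuum into five labels; the
  `ambiguous` class is a feature, not a failure mode.
- Published per-gene motif calls for proteins with unusual component
  spacing may differ from the scanner's defaults (`g_min`).
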