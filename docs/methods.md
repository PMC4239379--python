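# Methods

This note documents the rules the package implements, the parameters that
matter, the synthetic-data models behind the tests, and the numerical and
design choices made where the underlying workflow left them open.

## The classification model

A xylogen-like protein (XYLP) is modeled as a conjunction of three
structural features on a secreted backbone:

1. **PAST-rich regions.** A window of length `window` (default 50
   residues) slides over the sequence with step 1; a window qualifies when
   its Pro/Ala/Ser/Thr fraction *strictly* exceeds `threshold` (default
   0.35 — the ">35%" rule is read literally, so exactly 35% fails).
   Every residue covered by at least one qualifying window is PAST-covered
   and maximal covered runs become regions, each scored by its own PAST
   fraction. Sequences shorter than the window are scanned with a single
   whole-sequence window. The window length is not dictated by the rule
   itself; 50 residues is comparable to the spans such regions occupy in
   family members of 140–240 aa and is configurable.

2. **AG glycomodules.** The arabinogalactan O-glycosylation signal is
   approximated by the canonical dipeptide set `{AP, PA, SP, TP, GP, VP}`
   (configurable). Scanning is left-to-right and non-overlapping: the
   leftmost eligible dipeptide always wins and an overlapping later start
   is skipped (so `PAP` with set `{PA, AP}` yields one hit, `PA`). By
   default hits count only when the whole dipeptide lies inside a
   PAST-rich region; switching that restriction off can only add hits
   (a tested monotonicity property).

3. **The eight-cysteine nsLTP motif.** The template
   `C g1 C g2 CC g3 C h C g4 C g5 C` constrains five inter-cysteine gap
   lengths and the single hydrophobic residue `h ∈ {L, I, V}` between the
   fifth and sixth cysteine. Printed spacings such as `X12/14` are read as
   the two-element set {12, 14}, not the range (a `widen_gap_sets` helper
   converts sets to ranges for sensitivity analysis). Gap segments are
   cysteine-free by default so that exactly eight cysteines form the
   motif ("eight strictly conserved cysteines"); `allow_internal_cys`
   relaxes this. The scanner tries start positions left to right and gap
   lengths in ascending order, making the reported match deterministic
   (leftmost). Clade A and clade C have printed spacings and get dedicated
   templates; clades B and D do not, so motif-based clade hypotheses are
   only ever A or C — B/D membership comes from the phylogeny module.

The verdict: `is_xylp` iff the externally supplied signal-peptide flag is
true AND some template matches AND at least one glycomodule is found. GPI
anchoring is recorded but never required (one family member lacks it).
Signal-peptide/GPI/N-glycosylation predictions are consumed as input
flags; the package never re-predicts them.

## Phylogeny

Distances: p-distance with pairwise gap deletion (positions where either
sequence is gapped are dropped per pair), optionally Kimura's protein
correction `d = -ln(1 - p - 0.2 p²)`. The distance model used by the
original Clustal X workflow is not recoverable, so exact reproduction of a
particular published topology is not a goal; p-distance is the simplest
defensible default.

Neighbor joining is the standard Saitou–Nei agglomeration with two
determinism guarantees: ties in the Q criterion break by the smallest
(row, column) index pair, and negative branch-length estimates are clamped
to zero with the original value logged. Bootstrap resamples alignment
columns with replacement (default 1000 replicates, configurable; tests use
20–100 for speed) and reports, for each internal edge of the full-data
tree, the fraction of replicate trees containing the same bipartition.

Note that NJ agrees with an exhaustive least-squares topology search only
on matrices that are (approximately) tree metrics; on arbitrary symmetric
matrices the two criteria genuinely diverge. The NJ validation therefore
draws its matrices from random trees with additive distances, clean (for
consistency checks) or with small Gaussian noise (for the least-squares
comparison) — the input class a distance method is defined over.

Clade extraction takes one user-supplied anchor leaf per clade. The edges
on anchor-to-anchor paths form the separating set; each leaf joins the
clade of the anchor reachable across the fewest separating edges, and a
leaf tied between anchors stays unassigned. This recovers planted groups
exactly when each clade is a subtree, the intended use.

## Duplication rules

Tandem: for every pair of family genes on one chromosome, the number of
intervening genes is the rank difference minus one, computed over the
*full* gene annotation (family or not); a pair is tandem iff that count is
≤ `max_intervening` (default 5, boundary inclusive — "no more than five").
Strand is ignored; the rule is purely count-based. Pairs chain into arrays
by transitive closure. Any two family members qualify as candidate
homologs by default; an identity gate can be applied upstream by filtering
the family list.

Segmental: a homolog pair is segmental iff its two genes match the two
regions of one duplicated block within `max_pair_distance_kb` (default
500). A gene matches a region when its midpoint lies inside it (distance
0) or within the cap of the nearest region boundary; midpoints avoid
ambiguity for genes straddling block edges. When collinear anchor
coordinates are supplied per block, the distance to the nearest anchor
replaces the boundary proxy (both modes exist because published block
definitions often omit anchor pairs). If several blocks qualify, the one
with the smallest worst-side distance is reported.

The summary counts genes in tandem calls, genes in segmental calls, their
union, and the union as a percentage of the family size (2 decimals).

## Expression rules

- **EST specificity**: a gene is tissue-specific iff one tissue's count
  strictly exceeds half the gene's total (at most one tissue can); zero
  totals are non-specific. Counts must be integers.
- **MPSS bins**: the gene-level statistic is the maximum tpm across
  libraries (configurable to the mean; which statistic the original
  analysis used is not stated). Bins: <50 low, 50–500 moderate (both
  boundaries inside), >500 strong.
- **Microarray normalization**: `global-mean` divides every cell by the
  arithmetic grand mean of the matrix, then takes logs (base 2 by
  convention; the base is configurable). `gene-mean` divides each cell by
  its gene's *geometric* row mean — exactly mean-centering the log values,
  which is what per-gene centering in Cluster-style workflows does (and
  the only reading under which a (2, 8) row maps to (−1, +1) in log2).
  Global-mean is the default.
- **Clustering**: average linkage on 1 − Pearson correlation across
  samples (the linkage/metric of the original Cluster/TreeView workflow
  are not stated; these are the conventional defaults). A zero-variance
  profile has no correlation distance and raises unless a
  fall-back-to-Euclidean flag is set. Dendrograms serialize to Newick.
- **Fold-change screen**: flagged iff treated/control ≥ 2 or ≤ 0.5,
  boundary inclusive ("≥ 2-fold"); zero controls are rejected, direction
  recorded.
- **qPCR**: replicate Cts are averaged per dilution level, then mean Ct is
  regressed on log10(quantity) (≥3 levels required; the canonical series
  is 1, 3, 9, 27). Efficiency is `10^(-1/slope) − 1`; a perfect doubling
  gives slope −3.322 and efficiency 1.00. A non-negative slope marks the
  curve invalid (flagged, not silently accepted). Relative expression
  converts each Ct to a quantity on its own gene's curve and divides the
  target quantity by the housekeeping-gene quantity.

## Synthetic data

The generators emit the exact file formats the pipeline reads plus a
truth table, and are byte-deterministic under a fixed seed.

*Families.* Each true member is signal stub + PAST region with planted
glycomodules + a motif drawn uniformly from its clade's gap sets +
optional trailing PAST region + C-terminal stub. Alphabets are chosen so
the planted structure is identifiable: proline occurs only inside planted
PAST regions (every default glycomodule contains P, so no accidental hits
elsewhere) and cysteine only inside the motif. Decoys violate exactly one
conjunct each — seven cysteines, one gap outside the clade set, a
proline-free PAST region (zero glycomodules), or a false signal flag — so
classifier errors are attributable to a specific rule. Truth labels are
defined with respect to the clade-specific templates (A and C): a
wrong-gap decoy deliberately violates only clade spacing and would still
match the fully generic eight-cysteine template, so decoy guarantees are
stated against the clade templates.

*Genome layouts.* Tandem arrays are planted as explicit intervening-gene
counts (including the boundary value 5) on one chromosome, separated by
enough background genes that cross-array pairs can never be tandem;
segmental pairs get one block each on dedicated chromosome pairs, with
per-gene offsets from the block region (0 = inside) so both sides of the
500 kb cap are exercised.

*Expression.* EST counts are multinomial with planted majority tissues
(specific genes put 65–85% of their total in one tissue; non-specific
genes are capped at half the total). MPSS values are log-normal around
planted class medians (10 / 150 / 2000 tpm) with z-scores truncated at
±2.5 so the planted class always survives the noise. Stress tables carry
planted true folds; the noise parameter is the standard deviation of the
log measurement error of the *fold* (applied to the treated matrix, with
the control as the clean reference baseline), since the screen operates on
the ratio and its error budget is what matters.

*qPCR.* Ct = intercept + slope·log10(quantity) + Gaussian noise with
slope = −1/log10(1 + efficiency), standards at 1/3/9/27 in triplicate,
efficiencies restricted to (0.5, 1.1].

What passing on synthetic data does **not** show: the generators plant
unambiguous, noise-controlled structure; real protein families have
degenerate motifs, PAST regions near the threshold, incomplete
annotations, and expression tables with missing or non-integer entries.
Synthetic recovery validates the rules' implementation, not their
biological sensitivity or specificity.

## Problem sizes and tolerances

The validation suite uses 10,000 sequences for the motif/regex agreement
check, 100 random additive trees (5–8 taxa) for NJ consistency, 50
noisy tree metrics (4–5 taxa) for the least-squares comparison, 200
random layouts for the tandem oracle, 200 planted proteins for classifier
recovery, and 100 seeds for qPCR efficiency recovery (median absolute
error < 0.05 at Ct noise sd 0.1). Bootstrap validation uses 20–100
replicates; 1000 remains the library default. Hand-computed normalization
examples are checked to 3 decimals; closed-form qPCR values (slope
−3.322, quantity 6.75 at Ct 22.0 on the perfect curve) to the printed
precision.

## Known limitations

- Clade hypotheses from motif spacing cover clades A and C only; B/D
  assignment requires the tree.
- The EST/MPSS/microarray rules are the printed screening heuristics;
  no statistical testing or multiple-testing correction is performed,
  by design.
- Exact reproduction of the published tree topology and heat-map figures
  is out of scope (alignment-program internals and image rendering are
  not part of the rule set).
- The two acceptance checks that consume the deposited archive and the
  supplementary EST table require the user to download those files; the
  package cannot fetch them.
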