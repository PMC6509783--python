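# Methods

## Sequence model and alignment primitives

Proteins are records over the 20 canonical amino acids; `-` is the only
gap character (`.` is normalised on read). Global alignment is Gotoh's
three-state dynamic program under BLOSUM62 with affine gaps: a gap run of
length L costs `gap_open + L * gap_extend`, with `gap_open = 10`,
`gap_extend = 1` in matrix half-bit units — conventional protein defaults.
Traceback ties are resolved in the fixed order substitution > gap in the
second sequence > gap in the first, so reported alignments (not just
scores) are bit-reproducible. The kernel is numba-jitted; correctness is
pinned by an exhaustive-enumeration oracle on short pairs and a score
cross-check against Biopython's affine-gap aligner.

Pairwise identity divides identical aligned pairs by the ungapped length
of the **shorter** sequence (the CD-HIT convention). This matters at the
margins: a perfect fragment counts as 100% identical to its full-length
parent and is therefore absorbed during redundancy removal. The identity
definition used by the original CD-HIT runs of the kind of study this
package supports is rarely stated; with a different denominator
(alignment length, longer sequence), cluster counts near the threshold can
shift by a few percent.

Column trimming retains exactly the columns whose gap fraction is ≤ the
threshold (default 0.5): a column with *more than* 50% gaps is removed,
matching the usual trimal `-gt 0.5` behaviour. p-distance uses pairwise
deletion (sites gapped in either row are excluded) and raises rather than
returning 0 when no comparable sites remain.

## Redundancy clustering

Greedy incremental clustering: sequences sorted by length descending
(input order breaking ties); each joins the first existing cluster — in
creation order — whose representative it matches at ≥ the threshold,
else founds a new cluster. Representatives are founders, hence the
longest members. No k-mer prefilter is used: inputs are curated gene
families (hundreds of sequences), and full alignments keep the step
exact. The contract (every id in exactly one cluster; members ≥ threshold
to their representative; representatives mutually < threshold in creation
order) is verified against independently computed all-pairs identity
matrices in the test suite.

## Residue diagnosis

The scheme file carries the reference sequence, five named 1-based
positions with their expected reference residues (validated at load), an
ordered rule list, a default, and warning rules. Position mapping walks
the reference's gap structure to find each position's alignment column
and reads the query letter there ('-' if gapped). In pairwise mode the
alignment is computed on the fly; in MSA mode the reference row of the
supplied alignment is used — the right choice whenever queries and
reference are already co-aligned, and the only reliable choice for
distant homologs.

Rule order encodes the biochemical priorities: catalytic-dyad integrity
dominates (loss of either carboxylate ⇒ inactive, high confidence);
substrate-shift rules (D→E at the catalytic acid, then at the stabilizer
⇒ xyloglucanase) come before the low-confidence inactivation rules
(stabilizer lost; Ala→Gly); the default is glucanase. Glutamate at the
catalytic base is treated as carboxylate-preserving — unobserved in the
assayed panel, but consistent with the carboxyl-unit rationale behind the
dyad rule. Any gap among the five positions short-circuits to
`indeterminate`. Tyr8 substitutions never change the label (Y→F is known
to be tolerated); they are recorded as evidence. Glucomannanase
side-activity has no residue correlate at these five positions and is
deliberately not a label. Two documented blind spots are preserved, not
patched: xyloglucanases lacking either D→E substitution present a fully
conserved profile and are predicted glucanase.

## Gene structure

Intron phase is `(upstream CDS nucleotides) mod 3` (phase 1 = after the
first nucleotide of a codon) and the anchor residue is
`floor(upstream / 3)`; phase-0 introns anchor to the codon following the
boundary so a single anchor definition serves all phases. Minus-strand
genes are processed in translation order, so genomic coordinates never
enter the formulas. GFF3 input is 1-based inclusive; residue indices are
0-based internally and in reports. Conservation grouping is single
linkage over projected introns (same phase, column difference ≤
tolerance, default 0); the tolerance is exposed because position
conservation in real data is assessed qualitatively. Group membership is
invariant to input order, and the group count is non-increasing in the
tolerance.

## Tree scanning

Monophyly in unrooted mode asks whether some branch bipartitions the
leaves exactly into group vs complement (so a group and its complement
are equivalent); rooted mode requires an actual node. The defining
branch's numeric label is returned as support; posterior probabilities
(≤ 1) and bootstrap percentages (≤ 100) are auto-distinguished per tree.
Origin counting requires an explicit outgroup — no midpoint-rooting
default, to avoid silently wrong roots — and counts maximal subtrees
whose leaves all belong to the group; a polytomy whose descendants are
all in-group counts once. Sister composition histograms a chosen lineage
level over the sibling subtree of a monophyletic group.

Neighbor joining follows the standard Q-criterion and branch-length
formulas; Q ties break on the smallest index pair in the current
agglomeration ordering, making output deterministic even on degenerate
(all-equal) matrices. Because floating-point summation order can make Q
microscopically asymmetric, argmin hits are normalised to ordered pairs
before tie-breaking. Negative branch lengths on non-additive input are
reported as computed. The builder exists so synthetic scenarios need no
external inference tool; it recovers the generating topology on additive
matrices (verified against scikit-bio's NJ as an independent oracle).

## Synthetic families

The generator evolves a root protein along a guide tree: root drawn
uniformly over the 20 residues (with the five diagnostic positions fixed
at their canonical states), and per branch of length t each site
substitutes with probability `1 − exp(−rate·t)`, uniformly over the other
19 residues. This is a single-rate, at-most-one-hit-per-branch model —
adequate at the moderate divergences simulated (expected root-to-leaf
path ≈ 0.3 substitutions/site), but it underestimates multiple hits on
long branches and has no site-rate heterogeneity, no indels and no
compositional bias; passing tests therefore demonstrate correctness of
the analysis logic, not robustness to alignment error or saturation.
Because no indels are simulated, the true alignment is the leaf sequences
themselves; the written alignment artifact appends the diagnostic
scheme's reference as a gap-padded row so residue diagnosis can run in
MSA mode (family coordinates 1–180 are collinear with the reference by
construction).

HGT is simulated by re-sourcing the recipient subtree's ancestral
sequence from the donor node's sequence and re-evolving the subtree.
Function labels are implanted by overwriting the five diagnostic
positions *after* substitution, so labels are never corrupted by chance —
the classifier, not the mutation process, is under test; leaves without
an explicit label receive the ancestral glucanase state. The ancestral
intron (default: anchor codon 5, phase 1, inside a 16-residue
signal-peptide annotation) is inherited by a designated clade; extra
introns arise on branches as a Poisson process and are inherited by the
branch's descendants. Extras are drawn outside the signal-peptide region
and at globally unique (anchor, phase) sites, mirroring the empirical
situation in which the conserved signal-peptide intron is the only one
there — and keeping the implanted group exactly recoverable. CDS records
are reverse-translated with seeded uniform synonymous-codon choice plus a
TAA stop; gene models place introns of random length (60–199 nt) on a
per-gene scaffold with random strand. A single seeded RNG stream with a
fixed draw order makes all artifacts byte-reproducible.

Two ready-made scenarios define the standard test conditions. The HGT
scenario: 60 leaves — two bacteria (outgroup), four fungal clades, mites
and springtails as separate arthropod clades, and a 12-leaf beetle clade
re-sourced from a fungal donor clade — protein length 200 (a typical
GH45 catalytic domain), branch lengths scaled to a mean root-to-leaf
depth of 0.3. The intron scenario: 14 species, one gene each, 10 of them
in the clade carrying the ancestral intron, extra-intron rate 2.0 per
unit branch length (a handful of lineage-specific introns per family).

## Pipeline

`run_all` composes cluster → trim → diagnose → introns → treescan over
shared inputs, skipping stages whose inputs are not configured. Every
threshold is echoed in the report; counts are re-derivable from the stage
TSVs; stage failures carry the stage name and offending record. The
report body contains no timestamps, so identical inputs give
byte-identical reports.

## Validation harness

`scripts/acceptance.py` recomputes: classifier concordance on the
documented assay worked examples (10 residue-state cases, including both
textual readings of the one inconsistently described dyad mutant) and the
two blind spots; HGT recovery (recipient monophyly + fungal-dominated
sister + three arthropod origins on the NJ tree) over 20 seeded
60-leaf scenarios; exact ancestral-intron-group recovery over 20 seeded
14-species scenarios; and oracle agreement for alignment (200
length-≤ 6 pairs vs exhaustive enumeration), clustering (50 random
12-sequence sets vs an independent identity matrix) and NJ (100 random
5–8-leaf additive matrices). Scenario seeds are derived from the
command-line seed; panel sizes keep the full run under a few seconds on
one CPU.

## Known limitations

* Redundancy clustering is quadratic; it targets curated families
  (≲ 10³ sequences), not proteome-scale screens.
* Pairwise-mode residue mapping degrades with reference–query divergence;
  use MSA mode beyond ~50% identity.
* The rule table predicts only the three assayed substrate classes;
  activities without a residue correlate (glucomannanase side-activity,
  the blind-spot xyloglucanases) are invisible by design.
* Tree inference itself (ML/Bayesian) is out of scope: trees are inputs,
  and the bundled NJ is a tool for synthetic validation, not a substitute
  for model-based inference on real data.
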