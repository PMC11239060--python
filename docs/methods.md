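# Methods

## The model: base sets, not characters

All operations treat an aligned ITS matrix as samples × columns of *base
sets*. A plain base expands to a singleton set; a multi-base IUPAC code
(`R Y S W K M B D H V`) expands to its standard set and is interpreted as a
heteromorphic (heteroallelic) site — the two ITS alleles of a
heterokaryotic fruit body read simultaneously — rather than as sequencing
ambiguity. Two further states exist:

* **gap** (`-`): an internal deletion is a real character state; gap vs
  base is a difference, gap vs gap identity. *Terminal* gap runs, by
  contrast, encode unsequenced ends and are treated as missing (the rule
  is configurable per matrix, `terminal_gaps_missing`).
* **missing** (`N`, or a terminal gap): never heteromorphic, never counted
  in differences or diagnostics. This is the conservative reading; the
  source tables never print an N.

Two states are *disjoint* when they share no allele (gaps being their own
allele class). Disjointness is the single primitive behind diagnosability
and difference scoring.

## Coordinates

Both systems are 1-based and inclusive. *Alignment* coordinates are raw
column numbers. *Local* coordinates count ungapped residues of a chosen
reference sample from the first window compatible (by base-set
intersection, so `y` matches C or T) with the conserved ITS start motif
`tygaatt`; first occurrence wins. Which sample anchors the local mode is
the caller's choice — species descriptions number markers against the
taxon being characterised, clade-level markers against a reference
alignment, and the library exposes both.

## Diagnostic markers

A column is diagnostic for a target group when every target/non-target
pair of state sets is disjoint. Missing cells are ignored; a column where
either side is entirely missing is skipped. This "pure" single-column
diagnosability is deliberate: combination keys over multiple partially
diagnostic columns are a different method and out of scope. A documented
consequence of ignoring missing cells is that adding a non-target sample
can un-skip a previously skipped column, so monotonicity of the diagnostic
set holds only over columns that were actually compared.

Formatting: window width W = 13 by default; for k diagnostic characters
the left flank takes ⌊(W−k)/2⌋ characters and the right flank the
remainder, giving the conventional 6+1+6 and 5+2+6 layouts. Flanks are
lowercase (from the reference's anchored ungapped sequence in local mode,
its raw row in alignment mode), diagnostic characters uppercase — a
heteromorphic diagnostic state prints as its uppercase code. Runs of
consecutive diagnostic columns merge into one marker (`@p-q`). Run ends
are joined by an ASCII hyphen by default; pass `dash="–"` for typographic
output. Windows truncated by sequence ends are flagged. Deletion markers
(reference gapped at the diagnostic run) have no printed exemplar in the
genre, so the dialect here is `flank[---]flank` with the position of the
first affected column, alignment coordinates only.

## Difference counts

For a pairwise comparison, a column is excluded when either side is
missing, or — with the default `exclude_heteromorphic=True` — when either
side carries a multi-base code; exclusion is per comparison, not
matrix-wide. Among counted columns a difference is scored iff the sets are
disjoint. Species-level *unique sites* additionally require each group to
be internally invariant at the column; columns variable within a group are
excluded (`excluded_polymorphic`), not averaged — the fixed-difference
reading, which is what makes the sister-species count come out at five.
Species-vs-sample counts collapse the group to its invariant consensus
under the same rule.

Indels are scored per column by default (a 3-column deletion = 3
differences); `indel_mode="event"` counts a contiguous gap run as one
difference, recorded at its first column, because published totals rarely
state their convention. Both modes are exposed everywhere.

## Morphometry

Spore summaries follow the standard description grammar: extremes in
parentheses, 5th–95th percentile range, mean ± SD for length and width,
Qm, and `n = i × j` (measurements per collection × collections).
Percentiles use linear interpolation between closest ranks (numpy's
default, the "type 7" convention — the sources do not state one); SD uses
the n−1 denominator; Qm is the mean of per-spore length/width ratios,
never the ratio of means, with a logged warning when the two disagree by
more than 5%. Default rounding: ranges to 0.1 μm with trailing `.0`
trimmed, means to 0.1, SD to 0.01, Qm to 0.01 — the precision of printed
descriptions. The renderer always prints the extreme parentheses, even
when an extreme coincides with its percentile.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes —
nothing more. All samples share one uniform-composition background
sequence beginning with a concrete anchor (`TTGAATT`); each species
receives `n_fixed_diffs / 2` private substitution columns (star design),
so every species pair differs at exactly `n_fixed_diffs` substitution
columns (an odd count splits ceil/floor between exactly two species and is
otherwise rejected). Deletion blocks are interior gap runs carried by one
species. Heteromorphic cells are planted per sample per column at
`heteromorphism_rate` by replacing the base with the two-base code joining
it to a random alternative; planted positions and the anchor are exempt,
which is what guarantees that heteromorphism never perturbs fixed-difference
counts when exclusion is on. One `numpy` RNG stream per call, seeded
explicitly; a truth table records every planted feature.

Defaults are the study regime the package targets: a 718-column alignment,
two focal species of 5 and 11 specimens, four substitution differences
plus a one-column deletion (five unique sites), heteromorphism rate 0.01
per cell; spore defaults are 20 measurements × 10 collections from
normals (6.2 ± 0.67 × 4.6 ± 0.45 μm) truncated at zero.

What the generator does **not** emulate: phylogenetic substitution models,
rate heterogeneity across sites, alignment error, within-species
substitution polymorphism beyond heteromorphic cells, or length variation
at terminal ends. Passing the planted-truth tests therefore shows the
pipeline's bookkeeping is exact under its own assumptions, not that real
communities are this clean.

## Bundled data

`itsdiag.datasets` carries two curated polymorphic-position matrices
observed among *Agaricus* specimens (16 samples × 21 positions for the
sister pair *A. glabriusculus* / *A. badiosquamulosus*; 9 × 8 for
*A. dunensis*) embedded at their original column numbers into a fixed,
shared background so full-length stages can run. Because the background is
identical across samples, the embedded matrices vary at exactly the listed
positions. Printed interior deletions are encoded as internal gaps. The
marker demonstration community is synthetic, constructed so the target
species carries exactly the two published-style markers.

## Problem sizes and numerical choices

The test suite runs random-instance oracle equivalence at up to 12 samples
× 60 columns over 200 seeds per property, pairwise oracle recounts at 200
columns, and morphometry recovery at n = 2000 — sizes chosen so the whole
suite completes in seconds while exercising every code path. Ties and
degenerate inputs: duplicate sample ids, unequal row lengths, characters
outside the IUPAC set, groups overlapping or spanning the whole matrix,
sub-2-record measurement sets and non-positive dimensions are all rejected
with named errors; an all-gap row is treated as entirely missing.

## Known limitations

* Single-column diagnosability only; no minimal multi-column key search.
* The accession-scale difference counts (12/18/19/3/≥15 in the source
  Notes) need the full GenBank sequences, which are not redistributable
  here; the corresponding check runs only when the user supplies the
  aligned accessions under `data/`.
* Whether published difference counts used type specimens or consensus,
  and per-column or per-event indel scoring, is unstated; both indel modes
  are provided and the fixed-difference reading is the default.
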