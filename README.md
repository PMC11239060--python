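# itsdiag

Diagnostic-character analysis of fungal ITS barcode alignments, built for
the kind of species delimitation practised in *Agaricus* sect. *Minores*
taxonomy: closely related species separated by a handful of fixed
nucleotide differences, sequenced from heterokaryotic (n+n) fruit bodies
whose two ITS alleles surface as multi-base IUPAC codes.

## What it does

The central semantic choice runs through every stage: in a direct read of a
heterokaryon, a code such as `Y` is not an ambiguous call (C *or* T) but a
**heteromorphic site** — both a C allele and a T allele are present. Every
character is therefore expanded into a *base set*, and all comparisons are
set comparisons:

* **Diagnostic markers** — an alignment column is diagnostic for a taxon
  when every target sample's base set is disjoint from every other
  sample's (so a target `Y` against an outside `T` is *not* diagnostic).
  Markers print in the field's notation — flanking sequence in lowercase,
  diagnostic characters capitalised, `@position` suffix — in raw alignment
  columns or in 1-based ungapped positions anchored at the conserved ITS
  start motif `tygaatt`.
* **Polymorphic-position tables** — the samples × variable-positions
  matrices of taxonomic papers, with `-` for deletions and `*` marking
  heteromorphic cells.
* **Difference counts** — pairwise and species-level nucleotide
  differences "excluding heteromorphic sites", and *unique (fixed) sites*
  between two species: columns where each species is internally invariant
  and the two are mutually disjoint.
* **Spore morphometry** — the `(a) b–c (d) × (e) f–g (h) μm,
  [avX ± SD, Qm, n = i × j]` summary from raw length×width measurements
  (5th/95th percentile ranges, Qm = mean length/width ratio).
* **Synthetic communities** — a seeded generator that plants fixed
  differences, heteromorphic cells and deletion blocks with a recoverable
  truth table, so the whole pipeline is testable without downloads.

## Worked example

```python
from itsdiag.datasets import load_glabriusculus_badiosquamulosus, load_marker_demo
from itsdiag.diffs import group_unique_sites
from itsdiag.markers import discover_and_format

m = load_glabriusculus_badiosquamulosus()   # 16 specimens, 730 columns
rep = group_unique_sites(m, "A_glabriusculus", "A_badiosquamulosus")
print(rep.differences, rep.difference_positions)

for marker in discover_and_format(load_marker_demo(), "A_badiosquamulosus"):
    print(marker.notation())
```

prints

```
5 [298, 306, 535, 571, 669]
aatcttCttcccg@200
attccTTggagca@420-421
```

— five fixed sites separate *A. glabriusculus* from *A. badiosquamulosus*
once heteromorphic columns are excluded (the last one, 669, is a
one-column deletion), and the demonstration community yields the two
species-specific markers: a diagnostic `C` at local position 200 and a
double `TT` at 420–421, each shown inside its 13-character window.

The same stages are available from the shell:

```
itsdiag simulate --seed 3 --out sim/
itsdiag markers  --alignment sim/community.fasta --groups sim/groups.tsv --group species_A
itsdiag diffs    --alignment sim/community.fasta --groups sim/groups.tsv --a species_A --b species_B
itsdiag spores   --input measurements.tsv
itsdiag report   --config run.yaml
```

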