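# Methods

This note records the models, conventions and numerical choices behind
`mitocomp`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates, topology and region extraction

All coordinates are 0-based half-open internally and 1-based inclusive on
file I/O (the GenBank convention). A feature may wrap the replication
origin only on a circular genome; internally a wrapping feature keeps
`start < L <= end` so its length is always `end − start`, and it is
written out as a `join(start..L,1..k)` compound location.

Animal mitogenomes are circular molecules, but assemblies are sometimes
deposited (and described) as linear. Rather than guess which a given
record means, topology is an explicit per-genome flag: `circular`
(default) enables origin wraps and the wrap adjacency in gene-order
comparisons; `linear` disables both. Composition never double-counts the
origin either way.

Gene-name normalization is table-driven (a packaged synonym table plus a
tRNA grammar that understands anticodon triplets and codon-class
qualifiers such as `(UUR)`), never heuristic: a name that is not in the
table, or a Leu/Ser tRNA without anticodon evidence, maps to an explicit
`unknown` sentinel. Unknown-named genes still count toward composition
but are excluded from gene-order analysis.

## Composition and skews

AT-skew `(A−T)/(A+T)` and GC-skew `(G−C)/(G+C)` are computed over
reading-orientation counts; both are scale-invariant, so printed
percentages are equally valid inputs. A zero denominator yields NaN plus
a warning — never 0, never an exception — because "no A or T at all" is
an absence of evidence, not symmetry.

Codon positions are assigned per gene: the counter restarts at each
CDS's first base and advances cyclically 1→2→3 through the annotated
span *including* an incomplete terminal codon. This makes the three
position lengths tile the PCG region exactly (11,114 bp ⇒
3705/3705/3704), which a truncate-to-full-codons rule could not do.

Where features of the same category overlap, each genomic position is
counted once, for the first feature covering it (the codon-position
counter still advances over skipped positions, so later genes stay in
frame). This "first coverage" rule keeps the per-category rows a true
union while preserving the site-length tiling identity for any input.

Ambiguity codes stay in the sequence but are excluded from base counts
and the percentage denominator; the reported length remains the raw span.
Report rounding follows the printed-table convention: percentages to 2
decimals, skews to 3, half away from zero.

## Codon usage

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: 62 sense codons, stops TAA/TAG, AGA/AGG = Ser), taken from
Biopython's code tables and configurable by table id.

Codon counts pool all PCGs of a genome, reading each CDS in frame from
its annotated first base and dropping a trailing 1–2-mer. RSCU divides a
codon's count by its family mean; leucine and serine are normalized as
single families (the definition speaks of *all* codons encoding the
amino acid) but displayed split into Leu1 (CUN) / Leu2 (UUR) and
Ser1 (AGN) / Ser2 (UCN), matching the conventional figures. Because
published RSCU values are produced by various external tools whose
Leu/Ser handling is rarely stated, split-family normalization is
available behind a flag; the test suite pins the joint mode. Families
with zero total count report NaN (not 0, which would be a valid "never
used despite an observed family" statement).

Stop classification in the census is purely length-based: a CDS whose
length is not a codon multiple ends in an incomplete T or TA stop
(completed to TAA by polyadenylation in vivo — biology the package notes
but does not model); a complete terminal codon outside the stop set is
classified `other` with a misannotation warning. Codon ranking breaks
ties alphabetically, so outputs are deterministic.

## Gene-order comparison

Orders are signed permutations over the 37 genes plus CR, with the
packaged ancestral insect arrangement (*D. yakuba*) as the default
reference. Circular orders are rotated so the gene after the CR comes
first; the CR thus anchors rotation and participates in adjacency
counting but never appears inside an event cluster.

The diff aligns the two orders over their shared genes (missing genes
are excluded pairwise, loudly), then scans for maximal runs of
disagreeing positions, extending each run until both sides contain the
same gene set. Each balanced run is one event; token uniqueness
guarantees termination and rotation invariance is tested property-style.
Events are spelled with their conserved left-flank gene
(`COX2-trnK-trnD → COX2-trnD-trnK`) for readability.

Classification is strictly order/sign-based, tried in a fixed sequence:
inversion (block reversed, every sign flipped), shuffle (two adjacent
genes exchanged, signs kept), transposition (some single contiguous
block moved, signs kept — established by exhaustive search over block
moves), inverse transposition (a moved and sign-flipped block), else
`complex` with the raw clusters preserved. One consequence worth noting:
descriptions in the literature sometimes call a positional swap of
neighboring tRNAs an "inversion" even when no strand change is shown.
Absent sign evidence this package reports such a swap as a shuffle; the
fixture orders of the four study taxa therefore keep every token's
ancestral strand, and their trnA/trnR and trnT/trnP changes classify as
shuffles. Strand-aware reclassification happens automatically if
annotations with flipped strands are supplied.

Breakpoint distance counts signed reference adjacencies absent from the
derived order. An adjacency `(a, b)` read on the opposite strand is
`(−b, −a)`; both spellings denote the same junction and are stored under
one canonical representative. Circular orders include the wrap
adjacency. The implementation is verified against a brute-force oracle
on every signed permutation of up to five genes and random seven-gene
cases.

Pattern catalogs collapse identical derived clusters across taxa. The
canonical pattern string is the event's derived core (flanks stripped,
CR excluded) with minus-strand tokens suffixed `(-)`, normalized under
orientation so a cluster and its reverse-complement reading collide.

## Supermatrices

Alignment (MAFFT-class tools) and trimming (TrimAl-class tools) are out
of scope; the builder consumes already-aligned per-gene FASTA. Genes
concatenate in the ancestral genomic order (PCGs, then rrnL, rrnS), each
contributing one partition with 1-based inclusive coordinates, emitted
in RAxML and NEXUS `sets` formats.

Translation maps each codon column triple to one amino-acid column; a
codon containing any gap becomes a gap, an internal stop becomes `X`
with a warning, a terminal stop `*`. Third-position stripping removes
every third column and stamps the result's column provenance so it
cannot be stripped twice. The builder asserts the width identities
`w(cds12) = 2/3·w(cds)` and `w(cds_faa) = w(cds)/3` on every bundle: a
nucleotide matrix and its third-position-stripped counterpart can never
legitimately have equal site counts, so any published pair of equal
counts for the two is flagged as inconsistent rather than reproduced.
Missing taxa are fatal by default; an explicit `gaps` policy pads with
gap rows and warns.

## The synthetic-genome generator

The generator is the package's ground-truth instrument: every pipeline
stage is tested against what the generator *recorded drawing* rather
than against itself.

Model: i.i.d. bases per site within each region class. PCG internal
codons are drawn from the product of three per-codon-position base
distributions (optionally reweighted per codon), with stop codons
excluded by renormalization; starts are drawn from {ATA, ATT, ATG, ATC,
TTG} (weights 0.34/0.34/0.20/0.10/0.02 — ATN dominant, TTG rare, as
observed in bees); a CDS whose planned length is ≡ 0 mod 3 ends TAA
(p = 0.9) or TAG, otherwise in a literal TA or T. Minority-strand genes
of the ancestral plan are emitted in reading orientation and inserted
reverse-complemented. Intergenic spacers of 0–20 bp are uniform.

Defaults emulate an AT-rich bee mitogenome: 13 PCGs totalling 11,114 bp
with exactly one incomplete-stop gene (ND5, 1718 bp ≡ 2 mod 3), giving
codon-position lengths 3705/3705/3704; 22 tRNAs of 59–72 bp (within the
observed 50–77 bp range); rRNAs of 1325/785 bp; a 2755 bp control
region; per-position base profiles with the characteristic ordering
site3 > site1 > site2 in AT and a strongly T-skewed second position.

AT calibration: the expected AT contribution of the PCGs — including
start/stop conventions and the stop-exclusion renormalization — is
computed analytically, and the AT levels of the non-coding region
classes are then solved so the *expected* whole-genome AT content equals
`at_target` exactly, while preserving fixed offsets between classes (CR
highest, echoing real control regions). Deviations from the target are
therefore pure binomial sampling noise, which is what the 3-standard-
error acceptance check assumes.

Planted rearrangements are applied to the gene plan before emission.
Edits must name contiguous, pairwise non-overlapping clusters (overlap
is fatal — it would make event recovery ill-posed) and never involve the
CR. The manifest records each edit's ancestral window and derived
segment directly from the edit bookkeeping, independently of the diff
machinery that is later tested against it.

What the generator does **not** model — and what passing tests therefore
do not show about real data: codon autocorrelation and amino-acid-level
selection, gene-specific composition differences, tRNA/rRNA secondary
structure, overlapping genes, annotation error, duplicated control
regions, and heteroplasmy. It validates counting, skew, RSCU,
gene-order and matrix arithmetic, not biological realism.

## Problem sizes

The default test battery uses one ~17.8 kb synthetic genome shared
across modules, 20 seeds for the AT-calibration check, 100 random edit
manifests (≤ 4 edits each), exhaustive signed permutations up to n = 5
plus 200 random n = 7 cases for the breakpoint oracle, and 50 + 100
random RSCU count vectors. The full suite completes in a few seconds on
one CPU.

## Known limitations

* Published composition tables print 2-decimal percentages; recomputing
  3-decimal skews from them carries an irreducible ±0.001 quantization,
  and a handful of published cells disagree with their own printed
  inputs by more (documented where tested).
* Event classification is local and single-operation: overlapping or
  compound histories within one cluster report as `complex` rather than
  being decomposed (no TDRL or rearrangement-distance machinery).
* The unknown-name sentinel keeps unidentifiable genes out of gene-order
  analysis; a genome annotated with many unknowns will silently yield a
  sparse order (each exclusion is warned about at parse time).
* Supermatrix assembly assumes codon-aware (in-frame, gap-multiple-of-3
  per codon) PCG alignments; frameshifted alignments surface as
  width-divisibility errors, not as repaired output.
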