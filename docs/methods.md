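# Methods

## The assay being modeled

Transposon display (SSAP) reads out, for one targeted LTR
retrotransposon family, the set of distances between each genomic
insertion and its nearest flanking restriction site. `tdsim` models the
molecular steps deterministically:

1. **Digestion.** Complete digestion of linear contigs by a type-II
   enzyme defined by an IUPAC recognition motif and top/bottom cut
   offsets (EcoRI: `GAATTC`, cut after base 1 top / base 5 bottom,
   leaving 5′-AATT overhangs). Fragments are indexed by top-strand cut
   positions and tile each contig exactly; the 4-nt overhang is
   attributed to the downstream fragment. Partial digestion is not
   modeled: the protocol this emulates digests to completion, and a
   partial-digest model would need kinetic parameters the assay does not
   constrain.
2. **Ligation.** An adaptor duplex (strands `CTCGTAGACTGCGTACC` /
   `AATTGGTACGCAGTCTAC`, 5′-AATT overhang) is ligated onto every cut
   end; chromosome ends receive nothing. The reconstructed junction
   (`…G + AATTGGTACGCAGTCTAC` on the top strand at a right-hand end)
   contains `GAATTG`, not `GAATTC`, so ligation destroys the recognition
   site — an invariant the test suite asserts literally on random
   genomes.
3. **Selective PCR** (digestion-aware). Every binding site of the core
   TE primer that points toward an adaptor-ligated fragment end yields
   exactly one TE→adaptor product ending at that cut — complete
   digestion means no product can reach past the nearest cut. Fragments
   ligated at both ends also amplify adaptor↔adaptor, matching the
   unlabeled background products of the real first PCR.
4. **Labeled PCR.** Only products carrying a TE-primer end (and hence
   the tail) re-amplify with the fluorescent primer; the adaptor↔adaptor
   background drops out. The operation is a pure subset and idempotent.
5. **Gel.** Product lengths are merged into bands by single-linkage
   clustering under a size-dependent tolerance; band intensity counts
   co-migrating products. Lanes can be rendered as a text gel with
   100-bp ladder lanes using a log10(size) migration model (display
   convention only; no quantitative claims attach to it).
6. **Comparison.** Bands from all samples are clustered once globally
   into consensus bins (the analogue of reading lanes against shared
   ladders), giving a band × sample presence/absence matrix; a band
   present in some but not all samples is called polymorphic, and
   pairwise band differences are Hamming distances on the matrix
   columns. Jaccard and Dice band-sharing distances summarize pairs;
   a lane with zero bands (negative control) makes its distances
   undefined (NaN) rather than zero or one.

## Two PCR modes

* **Naive mode** (`naive_insilico_pcr`) reproduces the primer-screening
  computation: every primer site is paired with *every* restriction-site
  occurrence downstream of its 3′ end within the size cap, ignoring
  digestion, with the genomic span measured from the primer 5′ end
  through the far edge of the motif. Counts are reported separately for
  + and − strand primer sites (the fw/rv columns of a primer report).
  This mode feeds candidate selection.
* **Digestion-aware mode** (`selective_pcr`) is the assay model: only
  the nearest cut exists on a fragment. Its spans are what appear on the
  virtual gel.

Every digestion-aware product equals the naive product with the nearest
downstream site; naive mode's extra products correspond to sites beyond
the first cut.

## Size arithmetic

A TE→adaptor product's length is

```
product = tail_len + genomic_span + adaptor_extension
```

where `genomic_span` runs from the core primer's 5′ end to the cut of
the strand the primer copies — the bottom-strand cut for a + site (so
the span includes the 4-nt regenerated overhang) and the top-strand cut
for a − site — and `adaptor_extension` is the ligated adaptor's length
beyond the overhang (14 nt for the default adaptor). Measuring to the
template-strand cut makes spans strand-symmetric: reverse-complementing
a genome leaves the product-length multiset unchanged whenever no primer
footprint overlaps a recognition motif. (When a footprint does overlap a
motif the asymmetry is real: the two strands are severed at different
offsets inside the motif, so one orientation's template survives and the
other's does not.) Both junction orientations use the same extension
constant; the adaptor's 3-nt unpaired 5′ tip on the short strand, which
would make left-end products one to three bases different in a fully
atomistic account, is deliberately ignored — gel resolution is far
coarser.

Binding-site search requires the primer's 3′-terminal `anchor_len`
(default 3) bases to match exactly and allows `max_mismatches` (default
0) elsewhere; N never matches anything. Amplicons are deduplicated by
(contig, primer 5′ position, cut, strand) so overlapping annotations
cannot double-count products.

## Primer design

Candidates are all `primer_len`-mers (default 20) of the window formed
by the terminal `window_bp` (default 100) bases of the element's 3′ LTR,
read in element orientation (reverse-complemented for − strand
elements; for a − element the leftmost LTR is the 3′ one). k-mers
overlapping N are skipped — hybridization across an ambiguous base is
unpredictable. Filters apply to the core (untailed) primer: GC between
`gc_min`/`gc_max` (default 40–60%, inclusive) and Tm between
`tm_min`/`tm_max` (default 55–60 °C). The default Tm model is the
SantaLucia nearest-neighbor duplex model (via Biopython's
`MeltingTemp.Tm_NN`) at 50 mM monovalent salt and 250 nM primer; the
Wallace rule 2(A+T)+4(G+C) is retained as a deterministic option and
test oracle. Published TD primer sets include cores outside their own
stated GC band, so `strict=False` demotes filter violations to warnings
for reproduction work.

The universal 20-nt tail `TGTATACTGGAGCTGAGCTT` — the landing site of
the fluorescent primer — is prepended after filtering; only the tailed
Tm is recorded (tailing raises Tm but does not affect specificity).
`check_tail_absent` verifies the tail and its reverse complement are
absent from a target genome, the property that makes the fluorescent
primer specific to first-PCR products.

Selection keeps candidates whose joint (fw+rv) naive amplicon count lies
in `[amp_count_min, amp_count_max]` (default 19–60, inclusive — per-
strand counts of published primers fall below the lower bound, so the
band is read jointly) and whose amplicons respect `amp_size_max`
(default 5000 bp). Survivors are ranked by distance of the count from
the band midpoint, then core-Tm distance from the Tm-band midpoint, then
lexicographically — the acceptance band itself does not order
candidates, so the ranking is a deterministic tie-break of this
package's own choosing.

## Synthetic data generator

`fixtures` emulates a multi-population TD study: a shared random
background genome (default 200 kb, 50% GC — loci are what matter, not
chromosome-scale realism), one element family (default 300 bp identical
LTRs flanking a 2 kb internal region, echoing typical LTR/Ty3
structure), copies planted at dispersed loci, and a loci × samples
presence matrix describing which insertions segregate. Two choices make
the expected band set exactly computable:

* backgrounds (and element sequences) can be generated **site-free** —
  chance `GAATTC` occurrences are removed by point substitution — so the
  only cut sites are the planted ones (one `GAATTC` a configurable
  offset downstream of each insertion);
* the internal region carries **one recognition site** at a fixed offset
  (default 400 bp), so the 5′-LTR copy of the outward primer (the LTRs
  are identical, so it binds both) yields one constant-length internal
  product per full-length copy — a single intense, monomorphic band, the
  in-silico analogue of a within-element amplicon — instead of a
  locus-dependent long product that would entangle the truth table.

Ground truth (per-sample product lengths, the polymorphic subset) is
computed by direct arithmetic on the construction parameters, never by
running the pipeline, which makes it a genuine end-to-end oracle. What
passing against this generator does *not* show: behavior on nested or
decayed elements, target-site duplications, related families with
near-identical LTRs, heterozygous samples, or incomplete digestion —
real gels carry those complications, and co-migrating bands from
different loci (treated as identical here, as on a real gel) can mask
true polymorphisms.

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open everywhere; GFF3 input/
  output converts to/from 1-based inclusive, and reports print 1-based.
* IUPAC ambiguity codes other than N in genomes collapse to N with a
  warning; non-IUPAC characters are rejected.
* Gel tolerance `max(abs_bp, rel_frac·size)` defaults to max(5 bp,
  2%·size), emulating the resolution of a 2% agarose gel; both knobs are
  configurable since no instrument-grade resolution model is claimed.
  Band representative size is the median member length (robust to
  asymmetric merges). Adjacent-pair merging evaluates the tolerance at
  the pair midpoint.
* Single-linkage clustering is deterministic for fixed input; alignment
  of fingerprints across samples applies the tolerance once globally so
  pair difference counts are consistent with the consensus rows.
* A fragment shorter than the primer simply yields no binding sites; an
  element whose 3′ LTR is shorter than the design window truncates the
  window with a warning; an annotation with a single LTR is an error
  unless explicitly allowed.
* Reverse priming is modeled positionally at ligated junctions (any
  ligated end can be extended) rather than by matching a literal
  reverse-primer sequence against the junction; the junction chemistry
  is unambiguous whereas printed reverse-primer sequences in published
  tables are not always exact continuations of the printed adaptor
  strands.

## Problem sizes

The test suite and `scripts/acceptance.py` exercise the chemistry
invariants on hundreds to a thousand random 10 kb genomes, the PCR
oracle on 200–500 random 0.5–10 kb sequences, and truth recovery on a
200 kb, 5-locus, 4-sample population — sizes at which every check runs
in seconds while still covering thousands of fragments, junctions and
products per run.

## Known limitations

PCR efficiency, touchdown-cycle thermodynamics, primer dimers and
hairpins, star activity, methylation sensitivity, ligase efficiency and
chimera formation are out of scope; fluorophore properties are carried
as metadata only. Polymorphism calls are presence/absence of co-binned
band sizes — the method cannot distinguish two different loci whose
products co-migrate, and makes no population-genetic inference from the
distance matrices it reports.
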