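# Methods

## The circularization model

A permuted group I intron precursor is modeled as a linear RNA of four
parts, 5'→3': a 45-nt **antisense region**, the **ribozyme** (catalytic
core with a 13-nt internal guide sequence, IGS, at its 5' portion), the
**target insert** to be circularized, and a **backbone tail** from the
expression vector. The antisense region is the reverse complement of the
first 45 nt of the backbone tail, so the two flanks can pair and juxtapose
the splice sites. The 5' splice site is the ribozyme/target boundary and
the 3' splice site the target/backbone boundary.

Splicing is simulated purely at sequence level: an exogenous guanosine
attacks the 5' splice site, the backbone tail is released, and the freed
target 3'-hydroxyl attacks the 3' splice site, joining the target's ends.
The circular product carries the target insert and nothing else; kinetics,
folding, misfolded or abortive intermediates, and circularization
*efficiency* are deliberately out of scope (efficiency is an assay-side
measurement, `circRNA / total RNA`, not a sequence prediction).

### Guanosine bookkeeping

Mechanistic descriptions of where the attacking G ends up are inconsistent
in the literature for permuted topologies (it is sometimes drawn on the
circular product, which contradicts the observed absence of added
nucleotides). The simulator therefore treats G attachment as explicit
bookkeeping with three settings — `downstream_fragment` (default: the G
joins the fragment released at the attacked site, standard group-I
accounting), `upstream_fragment`, or `none` — and guarantees in all cases
that the circle itself never carries the G. Mass balance,
`len(circ) + len(upstream) + len(downstream) = len(precursor) + 1` when a
G is added, is a tested invariant.

## IGS design

The IGS is exactly 13 nt. Its 3'-most 9 nt (the **P1 segment**) must pair
the target's 3'-terminal 9-mer at all 9 positions, antiparallel, with the
position opposite the target's 3'-terminal U forced to G — the G·U wobble
that marks the cleavage site. Its 5'-most 6 nt (the **P10 segment**) pair
the target's 5'-terminal 6-mer; incomplete pairing is tolerated, with an
admissibility threshold `p10_min_pairs` (default 4 of 6, wobble counted).
The threshold is a *tolerance*, not a requirement for mismatches: a
perfectly complementary P10 is accepted.

Since 9 + 6 > 13, the two segments share two IGS positions. P1's hard
constraints take precedence on the overlap (the shared positions are fixed
by P1 and still *scored* in P10), leaving 4 freely optimizable IGS bases.
Each free base has a Watson–Crick partner available, so optimization
reduces to choosing, per position, the alphabetically smallest base that
pairs — which makes the designed IGS simultaneously a pairing maximizer
and the lexicographically smallest such maximizer. This is verified
against brute-force enumeration of all rotations × all 4⁴ free-base
choices on small targets.

## Junction selection

* `exact` — search all rotations of the circular target that end on an
  existing U; keep the one whose IGS achieves the highest P10 score, ties
  broken toward the smallest rotation offset. The spliced product is then
  the target circle exactly (artificial splice site, native sequence).
* `insert_u` — keep the caller's linearization and append a U; the product
  is one nucleotide longer. Never appropriate for coding circles (it
  shifts the frame) and flagged as such by the coding validator.
* `native` — `exact` at the native offset if that linearization already
  ends in U, otherwise `insert_u` there.

All tie-breaks are deterministic, so identical inputs yield byte-identical
designs with no seeds involved. A junction score depends only on the
linearization's terminal 6-mer and 9-mer, so rotation scoring uses a 15-nt
proxy — an exact optimization, not an approximation.

Targets must be ≥ 20 nt by default (`min_target_len`); 15 nt is the hard
floor below which the P1 and P10 footprints would overlap on the target.

## Coding circles

`build_coding_insert` validates the ORF (AUG start, terminal stop, length
divisible by 3), requires the split position to be a strictly interior
codon boundary, and emits `C_half + IRES + N_half`; circularizing this
linearization reconstitutes the ORF downstream of the IRES. Because the
circular product is rotation-invariant, in exact mode the junction position
cannot change the product sequence; translation risks arise only from U
insertion or user-edited flanks. The validator therefore checks the
*product*: (a) the ORF reads contiguously around the circle from its AUG;
(b) no in-frame codon spanning the stored junction is a premature stop
(frame anchored at the ORF start, falling back to its leading codons when
the junction itself was mutated); (c) the product has the intended
ORF+IRES length (a +1-nt U insertion fails this even though it matches the
insert-U design's own intent).

## Packaged resources

* **Ribozyme scaffold** — the model uses the catalytic core at
  *T. thermophila* LSU intron coordinates 28–414 (387 nt, 1-based
  inclusive), with its first 13 nt treated as the replaceable IGS slot so
  installing a designed IGS preserves length and coordinate bookkeeping.
  The packaged copy
  (`data/tetrahymena_core_28_414.synthetic.fasta`) is a **synthetic
  stand-in** for that core: no design rule reads scaffold internals (only
  its length and slot matter in a sequence-level model), but users
  preparing real constructs should supply an experimentally validated
  scaffold via `--scaffold`.
* **Backbone tail** — a 60-nt synthetic placeholder; real designs should
  pass their vector's downstream sequence (`--backbone`). Only its first
  `antisense_len` nucleotides are consequential (they define the antisense
  region).
* **Promoters** — `--promoter T7` prepends the canonical 18-nt T7 promoter
  for in-vitro transcription templates; for cellular promoters (e.g. CMV)
  pass the promoter sequence explicitly, since no canonical short constant
  exists to package.
* **IRES** — no IRES ships with the package; `fixtures.synthetic_ires`
  generates labeled synthetic placeholders that exercise the topology only.

## Assay computations

* **Primers** — exhaustive search over windows of 18–25 nt, Tm window
  50–68 °C, ranked by |Tm − 60 °C|, then GC within 40–60 %, then a G/C 3'
  end, then position (fully deterministic). Divergent pairs place the
  reverse primer in the 5' half and the forward primer in the 3' half of
  the circle's linearization, so the predicted amplicon
  `template[fwd_start:] + template[:rev_end]` necessarily spans the
  back-splice junction; convergent amplicons lie inside the target;
  linear-mode amplicons span the 3' splice site into the backbone and
  therefore occur on no circular product.
* **Melting temperature** — Wallace rule 2(A+T) + 4(G+C) below 14 nt,
  nearest-neighbor thermodynamics otherwise (both via Biopython); the
  method used is recorded per primer.
* **2^-ΔΔCt** — ΔCt pairs target and reference Ct per (sample, replicate)
  before any averaging (standard Livak bookkeeping); ΔΔCt is the group
  mean ΔCt minus the control-group mean; the SEM is taken over
  per-replicate fold values and is undefined (NaN) for n = 1. The result
  is invariant under any constant shift of all Ct values.
* **Splicing efficiency** — `circ / total`, with `circ > total` rejected
  as a consistency error rather than clamped.

## Synthetic data

The fixture generator emulates only what the design rules consume: circular
RNAs of specified length and GC content with a guaranteed minimum U count
(exact mode needs a U to splice at), and clean ORFs (AUG, single terminal
stop, no internal in-frame stop) assembled codon-wise. It reproduces no
compositional statistics, repeats, or secondary structure of real
transcripts, so passing sweeps demonstrate correctness of the sequence
algebra and design logic, not wet-lab performance (circularization
efficiency, expression levels, RNase R resistance are not modeled).

Problem sizes in the test-suite sweeps — 1000 targets of 20–500 nt for the
round-trip and simulator-oracle properties, 150 targets of ≤ 30 nt for the
exhaustive designer oracle, 200 ORFs of 30–150 nt for coding round trips —
were chosen so each property is exercised across the full supported length
range while the whole suite stays interactive (~10 s).

## Known limitations

* No RNA secondary-structure or free-energy computation anywhere: P1/P10
  are scored by base-pair counting, and emitted sequences are intended as
  input to external folding tools.
* The simulator's product identities are exact, but it cannot detect a
  ribozyme whose real fold is disrupted by a particular insert.
* Primer design knows nothing about cross-hybridization, secondary
  structure, or amplification efficiency; 2^-ΔΔCt assumes 100 % doubling
  per cycle.
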