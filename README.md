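# ribocirc

Design automation for circular RNA expression constructs based on the
self-splicing group I intron ribozyme of *Tetrahymena thermophila*.

Circular RNAs (circRNAs) lack free 5'/3' ends, which makes them resistant
to exonucleases and attractive both for functional studies of endogenous
circRNAs and as stable, low-immunogenicity mRNA substitutes. A permuted
group I ribozyme can produce them cleanly: the target sequence is placed
*downstream* of the ribozyme, a 45-nt antisense region complementary to the
vector backbone is placed upstream, and two guanosine-initiated
transesterifications excise the flanks and join the target's ends into a
covalently closed circle with **no extra nucleotides** in the product.

The ribozyme recognizes its substrate through an adjustable 13-nt internal
guide sequence (IGS) at its 5' portion:

* **helix P1** — the 3'-most 9 nt of the IGS pair the target's 3'-terminal
  9-mer; the IGS base opposite the target's 3'-terminal U is G, so the 5'
  splice site sits on a G·U wobble pair;
* **helix P10** — the 5'-most 6 nt of the IGS pair the target's 5'-terminal
  6-mer, tolerating mismatches ("incomplete" pairing).

Because a circle can be opened anywhere, a target whose natural junction
does not end in U can either receive an inserted U (product one nucleotide
longer) or be opened at an *artificial* splice site on an existing U, which
reproduces the natural circle exactly. For coding circRNAs the ORF is split
at a codon boundary and inserted in reverse order around an IRES
(`C-half + IRES + N-half`), so circularization reconstitutes the ORF
downstream of the IRES; the toolkit checks that the end-joining sequence
never becomes a premature stop codon and that no frameshift is introduced.

`ribocirc` implements this design space end to end, entirely in silico:

| module      | what it does |
|-------------|--------------|
| `seqcore`   | validated RNA/DNA sequences, circular rotation/equivalence, Watson–Crick + wobble pairing, FASTA I/O |
| `designer`  | junction selection and 13-nt IGS design (P1/P10 scoring, deterministic tie-breaks) |
| `constructs`| precursor assembly (antisense + ribozyme + target + backbone), split-ORF/IRES inserts, GenBank/FASTA I/O |
| `splicesim` | deterministic sequence-level splicing simulation with guanosine-addition bookkeeping |
| `assay`     | divergent/convergent/linear detection primers, melting temperatures, 2^-ΔΔCt quantification, splicing efficiency |
| `fixtures`  | seeded synthetic targets/ORFs so everything runs offline |

## Worked example

```bash
ribocirc fixture --length 120 --seed 7 --out target.fasta
ribocirc design  --target target.fasta --mode exact --out-prefix circX
ribocirc splice  --construct circX.gb --verify-against circX.intended.fasta \
                 --out-prefix circX
ribocirc primers --construct circX.gb --mode all --out primers.tsv
```

`circX.json` reports the design (abridged):

```
junction = {insert_u: False, mode: exact, rotation_offset: 39, terminal_residue: U}
igs  = CACAGUGUCUUUG        p1_segment = GUGUCUUUG   p10_segment = CACAGU
p1_pairs = 9                p10_pairs  = 6
wobble_positions = [[P1, 0]]
```

The designer opened the 120-nt circular target at position 39 — an existing
U, so no nucleotide is inserted — and derived an IGS whose P1 pairs all 9
positions (the single wobble, `[P1, 0]`, is the obligatory G·U at the splice
site) and whose P10 pairs 6/6. `circX.gb` is the annotated precursor
(45-nt antisense region, 387-nt ribozyme carrying the IGS, target, 60-nt
backbone tail). `circX.products.json` then shows the simulated splicing:

```
circ_length = 120   upstream_fragment_length = 432   downstream_fragment_length = 61
junction = [U, A]   g_added_to = downstream_fragment
```

The 120-nt circle is exactly the input target (verified up to rotation);
the attacking guanosine is book-kept on the released backbone fragment
(61 = 60 + 1). `primers.tsv` holds the three detection sets:

```
mode        fwd                        rev                        tm_fwd  tm_rev  amplicon_len  spans_junction
divergent   CCCCGGTTGTAAGAAGCTGGCAAAG  CAGCTATGTGTCCCCAGATGGTCGA  60.23   59.83   64            True
convergent  TCGACCATCTGGGGACACATAGCTG  CTTTGCCAGCTTCTTACAACCGGGG  59.83   60.23   106           False
linear      AATCGCTACAATGCGTCGGCGTT    ACCTGCAGATTCCGGATCGACAGTT  60.12   60.00   122           False
```

Divergent primers amplify only across the back-splice junction (circRNA),
convergent primers amplify within the target (total RNA), and the
linear-mode amplicon overlaps backbone sequence that no circular product
contains. Ct tables from such assays feed `ribocirc quant`, e.g. a target
Ct of 20 vs 24 with a constant reference gives ΔΔCt = −4, fold change 16.

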