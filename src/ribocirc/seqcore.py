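"""Nucleotide-sequence algebra.

Provides the validated sequence container (:class:`NucleicSeq`), the
Watson-Crick + G.U wobble base-pairing model (:class:`PairRule`), circular
rotation/equivalence, reverse complement, and FASTA I/O with a topology
header token.

All pairing rules downstream (IGS/P1/P10 design, splice-site cross-checks)
are stated on RNA, so RNA is the canonical internal alphabet; DNA input is
converted on ingestion and converted back only for DNA artifacts (GenBank,
synthesis-ready FASTA). Coordinates are 0-based, half-open everywhere in
the API.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, TopologyError

DNA = "DNA"
RNA = "RNA"
LINEAR = "linear"
CIRCULAR = "circular"

_STRICT = {DNA: set("ACGT"), RNA: set("ACGU")}
# IUPAC ambiguity codes, accepted only under the permissive flag
_AMBIGUOUS = set("RYSWKMBDHVN")

_COMPLEMENT = {
    DNA: str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"),
    RNA: str.maketrans("ACGURYSWKMBDHVN", "UGCAYRSWMKVHDBN"),
}

_WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class NucleicSeq:
    """A validated nucleotide sequence with alphabet and topology tags.

    Parameters
    ----------
    residues
        Nucleotide string over ``{A,C,G,T}`` (DNA) or ``{A,C,G,U}`` (RNA).
        Input is case-insensitive; canonical storage is uppercase.
    alphabet
        ``"DNA"`` or ``"RNA"``.
    topology
        ``"linear"`` or ``"circular"``. A circular sequence is stored as one
        particular linearization; rotations of it denote the same molecule.
    name
        Free-text identifier, carried through FASTA/GenBank round trips.
    permissive
        Accept IUPAC ambiguity codes. They are never accepted inside pairing
        segments regardless of this flag.
    """

    residues: str
    alphabet: str = RNA
    topology: str = LINEAR
    name: str = ""
    permissive: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.alphabet not in (DNA, RNA):
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        if self.topology not in (LINEAR, CIRCULAR):
            raise TopologyError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise AlphabetError("empty sequence")
        allowed = _STRICT[self.alphabet] | (_AMBIGUOUS if self.permissive else set())
        for i, sym in enumerate(self.residues):
            if sym not in allowed:
                raise AlphabetError(
                    f"invalid {self.alphabet} symbol {sym!r} at position {i}"
                    + ("" if self.permissive else " (IUPAC codes need permissive=True)")
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def has_ambiguity(self) -> bool:
        return any(sym in _AMBIGUOUS for sym in self.residues)

    def to_rna(self) -> "NucleicSeq":
        """Return the RNA form (T->U); identity on RNA input."""
        if self.alphabet == RNA:
            return self
        return replace(self, residues=self.residues.replace("T", "U"), alphabet=RNA)

    def to_dna(self) -> "NucleicSeq":
        """Return the DNA form (U->T); identity on DNA input. Involution with to_rna."""
        if self.alphabet == DNA:
            return self
        return replace(self, residues=self.residues.replace("U", "T"), alphabet=DNA)


@dataclass(frozen=True)
class PairRule:
    """Base-pairing relation: Watson-Crick, optionally extended by G.U wobble."""

    allow_wobble: bool = True

    def pair_set(self) -> set:
        return _WATSON_CRICK | (_WOBBLE if self.allow_wobble else set())

    def pairs(self, x: str, y: str) -> bool:
        return pairs(x, y, self)

    def is_wobble(self, x: str, y: str) -> bool:
        return (x, y) in _WOBBLE


WOBBLE_RULE = PairRule(allow_wobble=True)
STRICT_RULE = PairRule(allow_wobble=False)


def pairs(x: str, y: str, rule: PairRule = WOBBLE_RULE) -> bool:
    """True iff RNA nucleotides ``x`` and ``y`` pair under ``rule`` (symmetric)."""
    x, y = x.upper(), y.upper()
    for sym in (x, y):
        if sym not in _STRICT[RNA]:
            raise AlphabetError(
                f"{sym!r} is not an unambiguous RNA symbol (pairing context)"
            )
    return (x, y) in rule.pair_set()


def reverse_complement(s: NucleicSeq) -> NucleicSeq:
    """Antiparallel complement in the same alphabet; an involution."""
    rc = s.residues.translate(_COMPLEMENT[s.alphabet])[::-1]
    return replace(s, residues=rc)


def rotate(s: NucleicSeq, offset: int) -> NucleicSeq:
    """Linearization of circular ``s`` starting at ``offset``.

    Rotating by the full length is the identity. Rotating a linear sequence
    is a :class:`TopologyError` because it would silently change the molecule.
    """
    if not s.is_circular:
        raise TopologyError("rotate() requires a circular sequence")
    k = offset % len(s)
    return replace(s, residues=s.residues[k:] + s.residues[:k])


def circular_equivalent(a: NucleicSeq, b: NucleicSeq) -> bool:
    """True iff some rotation of ``a`` equals ``b`` (as circular molecules).

    Alphabet differences are bridged by the T<->U bijection; different
    lengths compare unequal rather than raising.
    """
    ra, rb = a.to_rna().residues, b.to_rna().residues
    if len(ra) != len(rb):
        return False
    return rb in (ra + ra)


def canonical_rotation(s: NucleicSeq) -> NucleicSeq:
    """Lexicographically smallest rotation — a canonical form for circles."""
    if not s.is_circular:
        raise TopologyError("canonical_rotation() requires a circular sequence")
    doubled = s.residues + s.residues
    n = len(s)
    best = min(range(n), key=lambda i: doubled[i : i + n])
    return rotate(s, best)


# ---------------------------------------------------------------------------
# FASTA I/O. Topology is declared in the description via "topology=circular".

_TOPOLOGY_TOKEN = "topology="


def _detect_alphabet(residues: str) -> str:
    return DNA if "T" in residues.upper() and "U" not in residues.upper() else RNA


def read_fasta(
    path, alphabet: str | None = None, permissive: bool = False
) -> List[NucleicSeq]:
    """Read a (multi-record) FASTA file into :class:`NucleicSeq` objects.

    Topology is taken from a ``topology=circular`` token in the header;
    the alphabet is auto-detected (presence of T vs U) unless forced.
    """
    out: List[NucleicSeq] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        topo = CIRCULAR if _TOPOLOGY_TOKEN + CIRCULAR in rec.description else LINEAR
        out.append(
            NucleicSeq(
                residues,
                alphabet=alphabet or _detect_alphabet(residues),
                topology=topo,
                name=rec.id,
                permissive=permissive,
            )
        )
    if not out:
        raise AlphabetError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Sequence[NucleicSeq] | NucleicSeq, path, width: int = 60) -> None:
    """Write sequences as FASTA, 60-column wrapped, with topology tokens."""
    if isinstance(seqs, NucleicSeq):
        seqs = [seqs]
    records = []
    for i, s in enumerate(seqs):
        rid = s.name or f"seq{i + 1}"
        records.append(
            SeqRecord(Seq(s.residues), id=rid, description=f"{_TOPOLOGY_TOKEN}{s.topology}")
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
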