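"""Precursor assembly and coding-circRNA topology.

A precursor transcript reads, 5' to 3':

    antisense region | ribozyme (with IGS installed) | target insert | backbone tail

The 45-nt antisense region is the reverse complement of the first 45 nt of
the backbone tail; pairing of these two flanks juxtaposes the splice sites
and assists ribozyme folding. The 5' splice site is the ribozyme/target
boundary, the 3' splice site the target/backbone boundary.

For coding circRNAs the target insert carries a split ORF around an IRES in
reversed order — ``C_half + IRES + N_half`` — so that circularization
restores the contiguous ORF downstream of the IRES.

The packaged ribozyme scaffold models the catalytic core of the Tetrahymena
thermophila LSU group I intron at intron coordinates 28-414 (387 nt); the
designed 13-nt IGS is installed by substitution into the scaffold's 5'
IGS slot so coordinate bookkeeping stays fixed. The packaged copy is a
synthetic stand-in for the core (sequence-level design rules never read
scaffold internals, only its length and slot); supply your own scaffold
FASTA to use an experimentally validated ribozyme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .designer import IGS_LEN, IGSDesign
from .errors import AnnotationError, FrameError, ValidationError
from .seqcore import (
    CIRCULAR,
    LINEAR,
    RNA,
    NucleicSeq,
    read_fasta,
    reverse_complement,
)

DEFAULT_ANTISENSE_LEN = 45
#: 1-based coordinates of the active core within the T. thermophila intron
DEFAULT_INTRON_COORDS = (28, 414)

STOP_CODONS = {"UAA", "UAG", "UGA"}

#: T7 RNA polymerase promoter (DNA, sense strand), for in vitro transcription
T7_PROMOTER = "TAATACGACTCACTATAG"


@dataclass(frozen=True)
class RibozymeScaffold:
    """The catalytic RNA core with a replaceable 13-nt IGS slot at its 5' end.

    ``intron_coords`` records which part of the full intron the scaffold
    spans (1-based, inclusive); the packaged default spans 28-414, so its
    length is end - start + 1 = 387.
    """

    sequence: str
    intron_coords: Tuple[int, int] = DEFAULT_INTRON_COORDS
    igs_slot: Tuple[int, int] = (0, IGS_LEN)

    def __post_init__(self) -> None:
        s, e = self.igs_slot
        if e - s != IGS_LEN:
            raise ValidationError(f"igs_slot must span {IGS_LEN} nt")
        if not (0 <= s < e <= len(self.sequence)):
            raise ValidationError("igs_slot outside scaffold")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_igs(self, igs: str) -> str:
        """Scaffold sequence with the designed IGS installed in the slot."""
        if len(igs) != IGS_LEN:
            raise ValidationError(f"IGS must be {IGS_LEN} nt, got {len(igs)}")
        s, e = self.igs_slot
        return self.sequence[:s] + igs + self.sequence[e:]


def default_scaffold() -> RibozymeScaffold:
    """The packaged 387-nt scaffold (intron coordinates 28-414, synthetic core)."""
    ref = resources.files("ribocirc.data").joinpath("tetrahymena_core_28_414.synthetic.fasta")
    with resources.as_file(ref) as path:
        seq = read_fasta(path, alphabet=RNA)[0]
    start, end = DEFAULT_INTRON_COORDS
    assert len(seq) == end - start + 1
    return RibozymeScaffold(seq.residues)


def default_backbone_tail() -> NucleicSeq:
    """A 60-nt synthetic vector-backbone tail used when none is supplied.

    The real construct sits in a pCDH backbone; any tail of >= antisense_len
    nucleotides works because the antisense region is derived from the tail
    itself. This packaged tail is a synthetic placeholder.
    """
    # deterministic, mixed-composition placeholder (not a natural sequence)
    residues = "GCUAAGUCCGAUCAGGCAUAGUCCAGGAACUGUCGAUCCGGAAUCUGCAGGUACAGGCUA"
    return NucleicSeq(residues, RNA, LINEAR, name="backbone_tail_synthetic")


@dataclass(frozen=True)
class Feature:
    """Annotated interval on a construct (0-based, half-open)."""

    label: str
    start: int
    end: int
    strand: int = 1

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrecursorConstruct:
    """Annotated precursor transcript ready for splicing simulation."""

    sequence: NucleicSeq
    features: Tuple[Feature, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def feature(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise AnnotationError(f"construct has no feature {label!r}")

    def has_feature(self, label: str) -> bool:
        return any(f.label == label for f in self.features)

    def subseq(self, label: str) -> str:
        f = self.feature(label)
        return self.sequence.residues[f.start : f.end]


def build_precursor(
    linearized_target: NucleicSeq,
    igs: IGSDesign,
    scaffold: Optional[RibozymeScaffold] = None,
    backbone_tail: Optional[NucleicSeq] = None,
    antisense_len: int = DEFAULT_ANTISENSE_LEN,
    name: str = "precursor",
    provenance: Optional[dict] = None,
) -> PrecursorConstruct:
    """Assemble antisense + ribozyme(IGS) + target + backbone tail.

    The antisense region is the reverse complement of the first
    ``antisense_len`` nucleotides of the backbone tail, so the two excised
    flanks can pair and juxtapose the splice sites.
    """
    scaffold = scaffold or default_scaffold()
    backbone_tail = (backbone_tail or default_backbone_tail()).to_rna()
    target = linearized_target.to_rna()
    if target.is_circular:
        raise ValidationError("pass the linearized target (see designer.linearize)")
    if not target.residues.endswith("U"):
        raise ValidationError("linearized target must end in U (post junction selection)")
    if len(backbone_tail) < antisense_len:
        raise ValueError(
            f"backbone_tail ({len(backbone_tail)} nt) shorter than antisense_len={antisense_len}"
        )

    ribo = scaffold.with_igs(igs.igs)
    antisense = reverse_complement(
        NucleicSeq(backbone_tail.residues[:antisense_len], RNA)
    ).residues
    seq = antisense + ribo + target.residues + backbone_tail.residues

    a = antisense_len
    ss5 = a + len(ribo)  # ribozyme/target boundary
    ss3 = ss5 + len(target)  # target/backbone boundary
    slot_s, slot_e = scaffold.igs_slot
    features = (
        Feature("antisense_region", 0, a),
        Feature("ribozyme", a, ss5),
        Feature("IGS", a + slot_s, a + slot_e),
        Feature("target", ss5, ss3),
        Feature("P10_target_site", ss5, ss5 + 6),
        Feature("P1_target_site", ss3 - 9, ss3),
        Feature("backbone_tail", ss3, len(seq)),
        Feature("splice_site_5p", ss5 - 1, ss5 + 1),
        Feature("splice_site_3p", ss3 - 1, ss3 + 1),
    )
    return PrecursorConstruct(
        sequence=NucleicSeq(seq, RNA, LINEAR, name=name),
        features=features,
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# Coding (split-ORF / IRES) topology


def _validate_orf(orf: NucleicSeq) -> str:
    r = orf.to_rna().residues
    if len(r) % 3 != 0:
        raise ValidationError(f"ORF length {len(r)} not divisible by 3")
    if not r.startswith("AUG"):
        raise ValidationError("ORF must start with AUG")
    if r[-3:] not in STOP_CODONS:
        raise ValidationError("ORF must end with a stop codon")
    return r


def build_coding_insert(
    orf: NucleicSeq, ires: NucleicSeq, split_pos: int
) -> NucleicSeq:
    """Split the ORF at a codon boundary and emit ``C_half + IRES + N_half``.

    The halves are placed in reverse order so the circular form restores
    the contiguous ORF immediately downstream of the IRES.
    """
    r = _validate_orf(orf)
    if not (0 < split_pos < len(r)):
        raise ValidationError(f"split_pos {split_pos} must be strictly inside the ORF")
    if split_pos % 3 != 0:
        raise FrameError(f"split_pos {split_pos} is not on a codon boundary")
    n_half, c_half = r[:split_pos], r[split_pos:]
    insert = c_half + ires.to_rna().residues + n_half
    return NucleicSeq(insert, RNA, LINEAR, name=(orf.name or "orf") + "_split_insert")


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of coding-product checks; ``ok`` iff translation is preserved."""

    orf_recovered: bool
    junction_stop: bool
    frame_intact: bool
    detail: str = ""

    @property
    def ok(self) -> bool:
        return self.orf_recovered and not self.junction_stop and self.frame_intact


def validate_coding_junction(
    circ: NucleicSeq, orf: NucleicSeq, intended: Optional[NucleicSeq] = None
) -> ValidationReport:
    """Check that a circular product still encodes the intended protein.

    * ``orf_recovered`` — the full ORF reads contiguously around the circle
      from its AUG (i.e. appears in the doubled linearization).
    * ``junction_stop`` — an in-frame codon spanning the stored junction
      (between the linearization's last and first residue) is a premature
      stop. The reading-frame anchor is the ORF start (falling back to its
      first codons if the junction itself was mutated).
    * ``frame_intact`` — the product has the intended length when
      ``intended`` is given (a +1-nt U insertion shifts the frame), else
      inferred from ORF recovery.
    """
    s = circ.to_rna().residues
    r = _validate_orf(orf)
    L = len(s)
    doubled = s + s

    pos = doubled.find(r)
    orf_recovered = 0 <= pos < L
    if pos < 0:  # anchor the frame on the ORF's leading codons instead
        for k in (9, 6, 3):
            pos = doubled.find(r[:k])
            if 0 <= pos < L:
                break
    junction_stop = False
    if 0 <= pos < L:
        n_codons = len(r) // 3
        for k in range(n_codons - 1):  # premature = before the intended stop
            i0 = (pos + 3 * k) % L
            if i0 > L - 3:  # codon wraps across the junction
                if doubled[i0 : i0 + 3] in STOP_CODONS:
                    junction_stop = True

    if intended is not None:
        frame_intact = len(s) == len(intended)
    else:
        frame_intact = orf_recovered
    detail = ""
    if not orf_recovered:
        detail = "ORF does not read contiguously around the circle"
    elif junction_stop:
        detail = "premature stop codon spans the junction"
    elif not frame_intact:
        detail = f"product length {len(s)} differs from intended {len(intended)}"
    return ValidationReport(orf_recovered, junction_stop, frame_intact, detail)


# ---------------------------------------------------------------------------
# GenBank I/O (DNA artifact; internal RNA is back-transcribed on write)


def to_genbank(construct: PrecursorConstruct, path, promoter: Optional[str] = None) -> None:
    """Write the construct as an annotated GenBank file (DNA sense strand).

    ``promoter`` may be ``"T7"`` or an explicit DNA sequence to prepend for
    transcription context; feature coordinates are shifted accordingly.
    """
    offset = 0
    prom_seq = ""
    if promoter:
        prom_seq = T7_PROMOTER if promoter.upper() == "T7" else promoter.upper()
        offset = len(prom_seq)
    dna = prom_seq + construct.sequence.to_dna().residues
    rec = SeqRecord(
        Seq(dna),
        id=(construct.sequence.name or "construct")[:16] or "construct",
        name=(construct.sequence.name or "construct")[:16] or "construct",
        description="ribozyme circRNA precursor construct",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "linear"
    if construct.provenance:
        rec.annotations["comment"] = json.dumps(construct.provenance, sort_keys=True)
    if prom_seq:
        rec.features.append(
            SeqFeature(SimpleLocation(0, offset, 1), type="misc_feature",
                       qualifiers={"label": ["promoter"]})
        )
    for f in construct.features:
        rec.features.append(
            SeqFeature(
                SimpleLocation(f.start + offset, f.end + offset, f.strand),
                type="misc_feature",
                qualifiers={"label": [f.label]},
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def from_genbank(path) -> PrecursorConstruct:
    """Read a construct written by :func:`to_genbank` (round-trip exact)."""
    rec = SeqIO.read(str(path), "genbank")
    offset = 0
    feats: List[Feature] = []
    for sf in rec.features:
        label = sf.qualifiers.get("label", ["?"])[0]
        if label == "promoter":
            offset = int(sf.location.end)
    for sf in rec.features:
        label = sf.qualifiers.get("label", ["?"])[0]
        if label == "promoter":
            continue
        feats.append(
            Feature(label, int(sf.location.start) - offset, int(sf.location.end) - offset,
                    sf.location.strand or 1)
        )
    dna = str(rec.seq)[offset:]
    provenance = {}
    if "comment" in rec.annotations:
        try:
            provenance = json.loads(rec.annotations["comment"])
        except (TypeError, ValueError):
            provenance = {"comment": rec.annotations["comment"]}
    seq = NucleicSeq(dna, "DNA", LINEAR, name=rec.name).to_rna()
    return PrecursorConstruct(sequence=seq, features=tuple(feats), provenance=provenance)
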