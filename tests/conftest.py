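"""Shared fixtures: a hand-checkable toy construct and small helpers."""

import pytest

from ribocirc.constructs import RibozymeScaffold, build_precursor
from ribocirc.designer import IGSDesign
from ribocirc.seqcore import NucleicSeq, reverse_complement

TOY_TARGET = "GGAUACGU"  # 8 nt, ends in U
TOY_BACKBONE = "CCCCCGGGGGAAAAAUUUUUCCCCCGGGGGAAAAAUUUUUCCCCC"  # 45 nt
TOY_SCAFFOLD = "A" * 13 + "CCCCCCA"  # 20 nt, first 13 = IGS slot


def toy_igs() -> IGSDesign:
    """An IGS whose P1 pairs the toy construct's annotated 3' splice region.

    The P1 cross-check spans the 9-mer ending at the 3' splice site, which
    for the 8-nt toy target includes the scaffold's final base (A), so
    P1 = G + revcomp("AGGAUACGU")[1:].
    """
    ninemer = TOY_SCAFFOLD[-1] + TOY_TARGET  # "AGGAUACGU"
    p1 = "G" + reverse_complement(NucleicSeq(ninemer)).residues[1:]
    igs = "AAAA" + p1
    return IGSDesign(
        igs=igs,
        p1_segment=igs[4:],
        p10_segment=igs[:6],
        p1_pairs=9,
        p10_pairs=4,
        wobble_positions=(("P1", 0),),
    )


@pytest.fixture
def toy_construct():
    """The 118-nt toy precursor: 45 antisense + 20 scaffold + 8 target + 45 tail."""
    return build_precursor(
        NucleicSeq(TOY_TARGET, name="toy"),
        toy_igs(),
        scaffold=RibozymeScaffold(TOY_SCAFFOLD, intron_coords=(1, 20)),
        backbone_tail=NucleicSeq(TOY_BACKBONE, name="toy_tail"),
    )
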