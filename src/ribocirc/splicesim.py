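"""Deterministic sequence-level model of ribozyme self-splicing.

An exogenous guanosine attacks the 5' splice site; after removal of the 3'
backbone the freed target 3'-hydroxyl attacks the 3' splice site, joining
the target's ends into a covalently closed circle and releasing the
antisense+ribozyme upstream fragment and the backbone tail. The model is
purely string-level: no kinetics, no misfolded intermediates, and the
circular product never carries extra nucleotides.

Bookkeeping of the attacking G is configurable. Group-I chemistry leaves
the exogenous G on the fragment released at the attacked (5') site, which
in this permuted topology is the downstream intermediate; the default
therefore prepends one G to the downstream fragment, and the mass-balance
invariant

    len(circ) + len(upstream) + len(downstream) == len(precursor) + 1

holds whenever a G is added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .designer import P1_START, score_helix
from .errors import AnnotationError, DesignInconsistency
from .seqcore import CIRCULAR, LINEAR, RNA, NucleicSeq, circular_equivalent

G_CHOICES = ("downstream_fragment", "upstream_fragment", "none")


@dataclass(frozen=True)
class SpliceProducts:
    """Predicted products of one self-splicing event.

    ``circ`` is stored linearized at the junction (its last residue is the
    target's 3' terminus, its first the target's 5' residue), tagged
    circular. ``junction`` records those two joined residues.
    """

    circ: NucleicSeq
    upstream_fragment: NucleicSeq
    downstream_fragment: NucleicSeq
    g_added_to: str
    junction: Tuple[str, str]
    precursor: NucleicSeq


def find_splice_sites(precursor) -> Tuple[int, int]:
    """Locate the 5' and 3' splice sites from construct annotations.

    ``ss5`` is the ribozyme/target boundary and ``ss3`` the target/backbone
    boundary (0-based cut positions). The annotation is cross-checked
    against P1 geometry: the 9-mer immediately 5' of the 3' splice site
    must fully pair the IGS P1 segment, otherwise the annotation and the
    design disagree and :class:`DesignInconsistency` is raised.
    """
    for label in ("ribozyme", "target", "backbone_tail", "IGS"):
        if not precursor.has_feature(label):
            raise AnnotationError(f"precursor lacks required feature {label!r}")
    ribo = precursor.feature("ribozyme")
    target = precursor.feature("target")
    backbone = precursor.feature("backbone_tail")
    if ribo.end != target.start or target.end != backbone.start:
        raise AnnotationError("features are not contiguous at the splice boundaries")
    ss5, ss3 = target.start, target.end

    igs = precursor.subseq("IGS")
    p1_segment = igs[P1_START:]
    target_3p = precursor.sequence.residues[ss3 - 9 : ss3]
    n_paired, _ = score_helix(p1_segment, target_3p)
    if n_paired != 9:
        raise DesignInconsistency(
            f"P1 segment pairs only {n_paired}/9 positions of the annotated "
            "target 3' terminus; splice sites and IGS are off-register"
        )
    return ss5, ss3


def simulate_splicing(precursor, g_attachment: str = "downstream_fragment") -> SpliceProducts:
    """Cut at both splice sites, circularize the target, return all products."""
    if g_attachment not in G_CHOICES:
        raise ValueError(f"g_attachment must be one of {G_CHOICES}")
    ss5, ss3 = find_splice_sites(precursor)
    s = precursor.sequence.residues
    name = precursor.sequence.name or "precursor"

    circ = NucleicSeq(s[ss5:ss3], RNA, CIRCULAR, name=name + "_circ")
    up = s[:ss5]
    down = s[ss3:]
    if g_attachment == "downstream_fragment":
        down = "G" + down
    elif g_attachment == "upstream_fragment":
        up = up + "G"
    return SpliceProducts(
        circ=circ,
        upstream_fragment=NucleicSeq(up, RNA, LINEAR, name=name + "_upstream"),
        downstream_fragment=NucleicSeq(down, RNA, LINEAR, name=name + "_downstream"),
        g_added_to=g_attachment if g_attachment != "none" else "none",
        junction=(s[ss3 - 1], s[ss5]),
        precursor=precursor.sequence,
    )


def verify_product(products: SpliceProducts, intended: NucleicSeq) -> bool:
    """True iff the predicted circle is the intended circle (up to rotation)."""
    return circular_equivalent(products.circ, intended)


def junction_context(products: SpliceProducts, flank: int = 10) -> str:
    """Sequence around the back-splice junction (3' side | 5' side), for primers."""
    s = products.circ.residues
    k = min(flank, len(s))
    return s[-k:] + s[:k]


def product_report(products: SpliceProducts, flank: int = 10) -> dict:
    """JSON-serializable product summary."""
    return {
        "circ_length": len(products.circ),
        "circ": products.circ.residues,
        "upstream_fragment_length": len(products.upstream_fragment),
        "downstream_fragment_length": len(products.downstream_fragment),
        "g_added_to": products.g_added_to,
        "junction": list(products.junction),
        "junction_context": junction_context(products, flank),
    }
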