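"""High-level design workflows tying the modules together.

These are the functions the CLI wraps: one call takes a circular target
(or an ORF + IRES pair) to an annotated precursor construct plus the
predicted products, with the design report carried as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from . import designer, splicesim
from .config import DEFAULTS, load_config
from .constructs import (
    PrecursorConstruct,
    RibozymeScaffold,
    ValidationReport,
    build_coding_insert,
    build_precursor,
    validate_coding_junction,
)
from .designer import IGSDesign, JunctionChoice, design_report
from .errors import ValidationError
from .seqcore import CIRCULAR, NucleicSeq, PairRule


@dataclass(frozen=True)
class DesignResult:
    """Everything produced by one design run."""

    choice: JunctionChoice
    igs: IGSDesign
    construct: PrecursorConstruct
    intended: NucleicSeq  # the circular product the design promises
    report: dict
    #: for coding designs, the ORF+IRES insert as a circle (without any
    #: inserted U) — the reference for frame-intactness checks
    coding_insert: Optional[NucleicSeq] = None


def design_circ(
    target: NucleicSeq,
    mode: str = "exact",
    native_offset: Optional[int] = None,
    scaffold: Optional[RibozymeScaffold] = None,
    backbone_tail: Optional[NucleicSeq] = None,
    config: Optional[dict] = None,
) -> DesignResult:
    """Design a precursor construct for a (noncoding) circular target."""
    cfg = config or dict(DEFAULTS)
    rule = PairRule(allow_wobble=bool(cfg["allow_wobble"]))
    choice = designer.select_junction(
        target, mode=mode, native_offset=native_offset, rule=rule,
        min_target_len=int(cfg["min_target_len"]),
    )
    lin = designer.linearize(target, choice)
    igs = designer.design_igs(
        lin, rule=rule, p10_min_pairs=int(cfg["p10_min_pairs"]),
        strict=bool(cfg["strict"]),
    )
    report = design_report(choice, igs)
    report["config"] = dict(cfg)
    construct = build_precursor(
        lin, igs, scaffold=scaffold, backbone_tail=backbone_tail,
        antisense_len=int(cfg["antisense_len"]),
        name=(target.name or "target") + "_precursor",
        provenance=report,
    )
    return DesignResult(choice, igs, construct, designer.intended_circle(target, choice), report)


def design_coding(
    orf: NucleicSeq,
    ires: NucleicSeq,
    split_pos: Optional[int] = None,
    mode: str = "exact",
    scaffold: Optional[RibozymeScaffold] = None,
    backbone_tail: Optional[NucleicSeq] = None,
    config: Optional[dict] = None,
) -> DesignResult:
    """Design a coding-circRNA construct (split ORF around an IRES).

    ``split_pos`` defaults to the codon boundary nearest the ORF midpoint.
    Exact mode is strongly preferred: a U insertion shifts the reading
    frame and is flagged by :func:`validate_coding_product`.
    """
    r = orf.to_rna()
    if split_pos is None:
        split_pos = (len(r) // 2 // 3) * 3
        if split_pos == 0:
            raise ValidationError("ORF too short to split")
    insert = build_coding_insert(r, ires, split_pos)
    circ_target = NucleicSeq(
        insert.residues, topology=CIRCULAR, name=(orf.name or "orf") + "_coding"
    )
    result = design_circ(
        circ_target, mode=mode, native_offset=0, scaffold=scaffold,
        backbone_tail=backbone_tail, config=config,
    )
    result.report["coding"] = {"split_pos": split_pos, "orf_len": len(r), "ires_len": len(ires)}
    return replace(result, coding_insert=circ_target)


def splice_and_verify(result: DesignResult, g_attachment: str = "downstream_fragment"):
    """Simulate splicing of a design and verify the product against the intent."""
    products = splicesim.simulate_splicing(result.construct, g_attachment=g_attachment)
    ok = splicesim.verify_product(products, result.intended)
    return products, ok


def validate_coding_product(
    result: DesignResult, orf: NucleicSeq, g_attachment: str = "downstream_fragment"
) -> ValidationReport:
    """Splice a coding design and run the translation-preservation checks.

    The frame reference is the unmodified ORF+IRES circle, so a +1-nt U
    insertion is reported as a frameshift even though it matches the
    design's own (insert_u) intent.
    """
    products, _ = splice_and_verify(result, g_attachment=g_attachment)
    reference = result.coding_insert or result.intended
    return validate_coding_junction(products.circ, orf, intended=reference)
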