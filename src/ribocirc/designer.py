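"""Junction selection and internal guide sequence (IGS) design.

The ribozyme recognizes its substrate through a 13-nt IGS at its 5'
portion. Two helices position the splice sites:

* **P1** — the 3'-most 9 nt of the IGS paired antiparallel with the
  target's 3'-terminal 9-mer. P1 must pair at all 9 positions, and the IGS
  base opposite the target's 3'-terminal U is forced to G so the splice
  site sits on a G.U wobble.
* **P10** — the 5'-most 6 nt of the IGS paired with the target's
  5'-terminal 6-mer. Incomplete pairing is tolerated (default: at least
  4 of 6 positions, wobble counted).

On a 13-nt IGS the 9-nt and 6-nt windows overlap by two positions; P1
constraints win on the overlap, leaving 4 freely optimizable IGS bases.

Because a circular target can be opened anywhere, the designer first
selects a junction: either the native junction (appending a U when the
native 3' residue is not U, at the cost of a +1-nt product) or an
*artificial* site at an existing U, which reproduces the native circle
exactly. Exact mode searches all U-terminal rotations and keeps the one
whose IGS pairs P10 best (ties: smallest rotation offset; lexicographically
smallest IGS), so designs are reproducible without seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

from .errors import (
    AlphabetError,
    DesignError,
    DesignWarning,
    NoSpliceSiteFound,
    TopologyError,
)
from .seqcore import (
    CIRCULAR,
    RNA,
    NucleicSeq,
    PairRule,
    WOBBLE_RULE,
    pairs,
    reverse_complement,
    rotate,
)

IGS_LEN = 13
P1_LEN = 9
P10_LEN = 6
#: index within the IGS where the P1 segment starts (last 9 of 13)
P1_START = IGS_LEN - P1_LEN

# smallest base (alphabetically) that pairs each target base; used for the
# free IGS positions so the lexicographically smallest maximizer is chosen
_BEST_PARTNER = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class JunctionChoice:
    """Where the circular target is opened for splicing.

    ``rotation_offset`` is the 0-based start of the chosen linearization on
    the circular target; ``terminal_residue`` is the 3'-terminal residue of
    that linearization (always U after any insertion); ``insert_u`` marks
    the +1-nt uridine appended in ``insert_u`` mode.
    """

    rotation_offset: int
    terminal_residue: str
    insert_u: bool
    mode: str  # "exact" | "insert_u"

    def __post_init__(self) -> None:
        if self.mode == "exact" and (self.insert_u or self.terminal_residue != "U"):
            raise DesignError("exact mode requires a terminal U and no insertion")
        if self.mode == "insert_u" and not self.insert_u:
            raise DesignError("insert_u mode implies insert_u=True")


@dataclass(frozen=True)
class IGSDesign:
    """A 13-nt IGS with its P1/P10 segments and pairing bookkeeping.

    ``wobble_positions`` lists ``("P1", i)`` / ``("P10", i)`` tuples for
    segment positions paired by G.U.
    """

    igs: str
    p1_segment: str
    p10_segment: str
    p1_pairs: int
    p10_pairs: int
    wobble_positions: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.igs) != IGS_LEN:
            raise DesignError(f"IGS must be {IGS_LEN} nt, got {len(self.igs)}")
        if self.igs[P1_START:] != self.p1_segment or self.igs[:P10_LEN] != self.p10_segment:
            raise DesignError("P1/P10 segments must sit at fixed IGS coordinates")


def score_helix(
    igs_segment: NucleicSeq | str,
    target_segment: NucleicSeq | str,
    rule: PairRule = WOBBLE_RULE,
) -> Tuple[int, List[int]]:
    """Count antiparallel paired positions between two equal-length segments.

    Position ``i`` of ``igs_segment`` is scored against position ``L-1-i``
    of ``target_segment``; the returned wobble list holds segment positions
    (on the IGS side) paired by G.U.
    """
    a = str(igs_segment).upper()
    b = str(target_segment).upper()
    if len(a) != len(b):
        raise ValueError(f"segment length mismatch: {len(a)} vs {len(b)}")
    n, wobbles = 0, []
    for i, x in enumerate(a):
        y = b[len(b) - 1 - i]
        if pairs(x, y, rule):
            n += 1
            if rule.is_wobble(x, y):
                wobbles.append(i)
    return n, wobbles


def _check_pairing_segment(seg: str, what: str) -> None:
    for i, sym in enumerate(seg):
        if sym not in "ACGU":
            raise AlphabetError(f"ambiguity code {sym!r} in {what} pairing segment (position {i})")


def design_igs(
    linearized_target: NucleicSeq,
    rule: PairRule = WOBBLE_RULE,
    p10_min_pairs: int = 4,
    strict: bool = False,
) -> IGSDesign:
    """Derive the 13-nt IGS for a U-terminal linearized target.

    P1 is the reverse complement of the target's 3'-terminal 9-mer with the
    position opposite the terminal U forced to G (the splice-site wobble).
    The four IGS positions outside P1 are chosen to maximize P10 pairing
    against the target's 5'-terminal 6-mer; each such position has a
    Watson-Crick partner available, and ties are broken toward the
    lexicographically smallest IGS, so the result is deterministic.

    A P10 score below ``p10_min_pairs`` emits :class:`DesignWarning`
    (raised as :class:`DesignError` under ``strict``).
    """
    t = linearized_target.to_rna()
    if len(t) < 15:
        raise DesignError(
            f"target must be >= 15 nt so P1 and P10 windows do not overlap (got {len(t)})"
        )
    if not rule.allow_wobble:
        raise DesignError("IGS design requires wobble pairing (splice-site G.U)")
    t3 = t.residues[-P1_LEN:]
    t5 = t.residues[:P10_LEN]
    _check_pairing_segment(t3, "P1")
    _check_pairing_segment(t5, "P10")
    if t3[-1] != "U":
        raise DesignError("linearized target must end in U (run select_junction first)")

    p1 = reverse_complement(NucleicSeq(t3, RNA)).residues
    p1 = "G" + p1[1:]  # wobble opposite the 3'-terminal U marks the cleavage site

    # IGS positions 0..3 are free; 4..12 are the P1 segment (4,5 shared with P10)
    free = "".join(_BEST_PARTNER[t5[P10_LEN - 1 - i]] for i in range(P1_START))
    igs = free + p1

    p1_pairs, p1_wob = score_helix(igs[P1_START:], t3, rule)
    p10_pairs, p10_wob = score_helix(igs[:P10_LEN], t5, rule)
    if p1_pairs != P1_LEN:
        raise DesignError("internal error: P1 failed to pair fully")  # pragma: no cover
    if p10_pairs < p10_min_pairs:
        msg = f"P10 pairs {p10_pairs}/{P10_LEN} below required {p10_min_pairs}"
        if strict:
            raise DesignError(msg)
        warnings.warn(msg, DesignWarning, stacklevel=2)

    wobbles = tuple([("P1", i) for i in p1_wob] + [("P10", i) for i in p10_wob])
    return IGSDesign(
        igs=igs,
        p1_segment=igs[P1_START:],
        p10_segment=igs[:P10_LEN],
        p1_pairs=p1_pairs,
        p10_pairs=p10_pairs,
        wobble_positions=wobbles,
    )


def _u_rotation_offsets(t: NucleicSeq) -> List[int]:
    """Rotation offsets whose linearization ends on a U, ascending."""
    n = len(t)
    return sorted((i + 1) % n for i, sym in enumerate(t.residues) if sym == "U")


def enumerate_exact_junctions(
    target: NucleicSeq, rule: PairRule = WOBBLE_RULE
) -> List[Tuple[int, int]]:
    """All U-terminal rotations with their best achievable P10 score.

    Returns ``(rotation_offset, p10_pairs)`` sorted by offset. Useful for
    inspecting the admissible-junction set at a given P10 threshold.
    """
    t = target.to_rna()
    r = t.residues
    if len(r) < 15:
        raise DesignError("junction scoring needs targets of >= 15 nt")
    out = []
    for off in _u_rotation_offsets(t):
        lin = r[off:] + r[:off]
        # the IGS depends only on the terminal 6-mer and 9-mer, so score a
        # 15-nt proxy; identical result, independent of target length
        proxy = NucleicSeq(lin[:P10_LEN] + lin[-P1_LEN:], RNA)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DesignWarning)
            d = design_igs(proxy, rule=rule, p10_min_pairs=0)
        out.append((off, d.p10_pairs))
    return out


def select_junction(
    target: NucleicSeq,
    mode: str = "exact",
    native_offset: Optional[int] = None,
    rule: PairRule = WOBBLE_RULE,
    min_target_len: int = 20,
) -> JunctionChoice:
    """Choose where the circle is opened.

    Modes
    -----
    ``exact``
        Pick, among all rotations ending on an existing U, the one whose
        IGS achieves the best P10 pairing (ties: smallest offset). The
        spliced product then reproduces the target circle exactly.
    ``insert_u``
        Keep the ``native_offset`` linearization and append a U; the
        product is one nucleotide longer than the target.
    ``native``
        ``exact`` at ``native_offset`` if that linearization already ends
        in U, otherwise ``insert_u`` there. ``native_offset`` defaults to 0
        (the stored linearization of the circular input).
    """
    if not target.is_circular:
        raise TopologyError("select_junction requires a circular target")
    t = target.to_rna()
    if len(t) < min_target_len:
        raise DesignError(f"target shorter than min_target_len={min_target_len}")

    if mode == "exact":
        candidates = enumerate_exact_junctions(t, rule)
        if not candidates:
            raise NoSpliceSiteFound(
                "exact mode needs at least one U in the target; use insert_u mode"
            )
        best_off, _ = max(candidates, key=lambda c: (c[1], -c[0]))
        return JunctionChoice(best_off, "U", False, "exact")

    if mode == "insert_u":
        if native_offset is None:
            raise ValueError("insert_u mode requires native_offset")
        return JunctionChoice(native_offset % len(t), "U", True, "insert_u")

    if mode == "native":
        off = 0 if native_offset is None else native_offset % len(t)
        lin = rotate(t, off)
        if lin.residues.endswith("U"):
            return JunctionChoice(off, "U", False, "exact")
        return JunctionChoice(off, "U", True, "insert_u")

    raise ValueError(f"unknown junction mode {mode!r}")


def linearize(target: NucleicSeq, choice: JunctionChoice) -> NucleicSeq:
    """The linear target insert implied by a junction choice (U appended in insert_u mode)."""
    t = target.to_rna()
    lin = rotate(t, choice.rotation_offset)
    residues = lin.residues + ("U" if choice.insert_u else "")
    return NucleicSeq(residues, RNA, "linear", name=target.name or "target")


def intended_circle(target: NucleicSeq, choice: JunctionChoice) -> NucleicSeq:
    """The circular product the design promises (includes the extra U if any)."""
    lin = linearize(target, choice)
    return replace(lin, topology=CIRCULAR)


def design_report(choice: JunctionChoice, igs: IGSDesign) -> dict:
    """JSON-serializable summary of a junction + IGS design."""
    return {
        "junction": {
            "rotation_offset": choice.rotation_offset,
            "mode": choice.mode,
            "insert_u": choice.insert_u,
            "terminal_residue": choice.terminal_residue,
        },
        "igs": igs.igs,
        "p1_segment": igs.p1_segment,
        "p10_segment": igs.p10_segment,
        "p1_pairs": igs.p1_pairs,
        "p10_pairs": igs.p10_pairs,
        "wobble_positions": [list(w) for w in igs.wobble_positions],
    }
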