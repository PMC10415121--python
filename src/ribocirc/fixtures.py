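"""Seeded synthetic targets so the whole pipeline is testable offline.

`random_target` emulates the kind of substrate the circularization system
is pointed at: a circular RNA of a chosen length and GC content with at
least one U (exact-mode designs need a U to splice at), or — with
``coding=True`` — a clean ORF (AUG start, single terminal stop, no internal
in-frame stop) to be split around an IRES. It makes no attempt to mimic
the composition statistics or secondary structure of any real transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constructs import STOP_CODONS
from .errors import SpecError
from .seqcore import CIRCULAR, LINEAR, RNA, NucleicSeq

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic target."""

    length: int
    gc_fraction: float = 0.5
    min_u_count: int = 1
    seed: int = 0
    coding: bool = False

    def __post_init__(self) -> None:
        if self.length < 20:
            raise SpecError("fixture targets must be >= 20 nt")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise SpecError("gc_fraction must lie in [0, 1]")
        if self.min_u_count < 1:
            raise SpecError("min_u_count must be >= 1 (exact mode needs a U)")
        if self.min_u_count > self.length:
            raise SpecError("min_u_count exceeds length")
        if self.coding and self.length % 3 != 0:
            raise SpecError("coding fixtures need a length divisible by 3")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """AUG + non-stop codons + one stop, sampled base-wise at the given GC."""
    probs = _base_probs(gc)
    n_internal = length // 3 - 2
    codons = []
    while len(codons) < n_internal:
        codon = "".join(rng.choice(_BASES, size=3, p=probs))
        if codon not in STOP_CODONS:
            codons.append(codon)
    stop = str(rng.choice(np.array(sorted(STOP_CODONS))))
    return "AUG" + "".join(codons) + stop


def random_target(spec: FixtureSpec) -> NucleicSeq:
    """Deterministic circular RNA target satisfying the fixture spec."""
    rng = np.random.default_rng(spec.seed)
    for _ in range(200):
        if spec.coding:
            residues = _random_orf(rng, spec.length, spec.gc_fraction)
        else:
            residues = "".join(
                rng.choice(_BASES, size=spec.length, p=_base_probs(spec.gc_fraction))
            )
            u_count = residues.count("U")
            if u_count < spec.min_u_count:
                # convert randomly chosen non-U positions (A first, to keep GC)
                chars = list(residues)
                order = [i for i, c in enumerate(chars) if c == "A"] + [
                    i for i, c in enumerate(chars) if c in "CG"
                ]
                picks = rng.permutation(order)[: spec.min_u_count - u_count]
                for i in picks:
                    chars[i] = "U"
                residues = "".join(chars)
        if residues.count("U") >= spec.min_u_count:
            name = f"fixture_L{spec.length}_s{spec.seed}" + ("_orf" if spec.coding else "")
            return NucleicSeq(residues, RNA, CIRCULAR, name=name)
    raise SpecError(f"could not satisfy fixture spec {spec} after 200 attempts")


def random_orf(length: int, seed: int = 0, gc_fraction: float = 0.5) -> NucleicSeq:
    """A linear ORF fixture (AUG ... stop, no internal in-frame stop)."""
    circ = random_target(FixtureSpec(length, gc_fraction, seed=seed, coding=True))
    return NucleicSeq(circ.residues, RNA, LINEAR, name=circ.name)


def synthetic_ires(length: int = 60, seed: int = 0) -> NucleicSeq:
    """A synthetic IRES placeholder for coding-design fixtures.

    Real designs should supply an experimentally validated IRES (e.g. CVB3);
    this stand-in only exercises the split-ORF topology.
    """
    rng = np.random.default_rng(seed + 10_007)
    residues = "".join(rng.choice(_BASES, size=length, p=_base_probs(0.5)))
    return NucleicSeq(residues, RNA, LINEAR, name=f"ires_synthetic_s{seed}")
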