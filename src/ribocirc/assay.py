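"""Validation-side computations: detection primers and qPCR math.

Three primer sets distinguish the RNA species produced by a circularizing
construct:

* **divergent** — primers face away from each other on the linear map of
  the circle, so they amplify only across the back-splice junction and
  detect the circRNA specifically;
* **convergent** — both primers sit inside the target, amplifying total
  RNA (precursor plus circle);
* **linear** — one primer in the target and one in precursor-only sequence
  (backbone tail), detecting the non-circularized form.

Quantification follows the Livak 2^-ddCt scheme: per-sample pairing of
target and reference Ct, group means of dCt, fold change relative to the
control group, and the SEM of per-replicate fold values. Splicing
efficiency is the circular fraction circRNA / total RNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt
from Bio.SeqUtils import gc_fraction

from .errors import AlphabetError, ConsistencyError, DataError, DesignError
from .seqcore import DNA, NucleicSeq, reverse_complement
from .splicesim import SpliceProducts

WALLACE_MAX_LEN = 13  # Wallace rule below 14 nt, nearest-neighbor from 14 up


@dataclass(frozen=True)
class PrimerParams:
    """Primer-search constraints (lengths in nt, temperatures in deg C)."""

    min_len: int = 18
    max_len: int = 25
    tm_min: float = 50.0
    tm_max: float = 68.0
    tm_target: float = 60.0


@dataclass(frozen=True)
class PrimerSet:
    """A designed primer pair with its predicted amplicon."""

    mode: str  # divergent | convergent | linear
    fwd: str  # DNA, 5'->3'
    rev: str  # DNA, 5'->3'
    template: str  # circ | precursor
    amplicon: str
    amplicon_len: int
    spans_junction: bool
    tm_fwd: float
    tm_rev: float
    tm_method_fwd: str
    tm_method_rev: str
    fwd_start: int
    rev_end: int


def melting_temp(primer: NucleicSeq) -> float:
    """Primer melting temperature in deg C.

    Wallace rule 2(A+T)+4(G+C) for primers shorter than 14 nt,
    nearest-neighbor thermodynamics otherwise.
    """
    if primer.alphabet != DNA:
        raise AlphabetError("melting_temp expects a DNA primer")
    if len(primer) < 8:
        raise DesignError(f"primer too short for a meaningful Tm ({len(primer)} nt)")
    if len(primer) <= WALLACE_MAX_LEN:
        return float(_mt.Tm_Wallace(primer.residues))
    return float(_mt.Tm_NN(primer.residues))


def tm_method(length: int) -> str:
    return "wallace" if length <= WALLACE_MAX_LEN else "nearest_neighbor"


def divergent_amplicon(template: str, fwd_start: int, rev_end: int) -> str:
    """Amplicon of a divergent pair on a circular template.

    Runs from ``fwd_start`` through the junction to ``rev_end`` (exclusive):
    ``template[fwd_start:] + template[:rev_end]``.
    """
    return template[fwd_start:] + template[:rev_end]


def _candidate_primers(template: str, lo: int, hi: int, params: PrimerParams):
    """All windows of template[lo:hi] passing the Tm window, with rank keys."""
    out = []
    for plen in range(params.min_len, params.max_len + 1):
        for start in range(lo, hi - plen + 1):
            site = template[start : start + plen]
            tm = melting_temp(NucleicSeq(site, DNA))
            if not (params.tm_min <= tm <= params.tm_max):
                continue
            gc = 100.0 * gc_fraction(site)
            key = (
                abs(tm - params.tm_target),
                0 if 40.0 <= gc <= 60.0 else 1,
                0 if site[-1] in "GC" else 1,
                start,
                plen,
            )
            out.append((key, start, start + plen, site, tm))
    return sorted(out)


def _pick(template: str, lo: int, hi: int, params: PrimerParams, what: str):
    cands = _candidate_primers(template, lo, hi, params)
    if not cands:
        raise DesignError(
            f"no {what} primer in window [{lo},{hi}) satisfies length "
            f"{params.min_len}-{params.max_len} and Tm "
            f"{params.tm_min}-{params.tm_max} degC"
        )
    return cands[0]


def design_primers(
    products: SpliceProducts, mode: str, params: Optional[PrimerParams] = None
) -> PrimerSet:
    """Design one deterministic primer pair for the requested detection mode.

    Ranking is exhaustive over candidate windows: Tm closest to the target
    Tm, then GC within 40-60%, then a G/C 3' end, with position as the
    final deterministic tie-break.
    """
    params = params or PrimerParams()
    circ = products.circ.to_dna().residues
    L = len(circ)

    if mode == "divergent":
        if L < 2 * params.min_len + 1:
            raise DesignError(
                f"circular template of {L} nt too short for divergent primers"
            )
        half = L // 2
        # rev binds the 5' half, fwd the 3' half: they face away on the
        # linear map and can only meet across the junction
        _, fs, fe, fsite, ftm = _pick(circ, half, L, params, "forward")
        _, rs, re_, rsite, rtm = _pick(circ, 0, half, params, "reverse")
        amp = divergent_amplicon(circ, fs, re_)
        rev = reverse_complement(NucleicSeq(rsite, DNA)).residues
        return PrimerSet(
            "divergent", fsite, rev, "circ", amp, len(amp), True,
            ftm, rtm, tm_method(len(fsite)), tm_method(len(rev)), fs, re_,
        )

    if mode == "convergent":
        if L < 2 * params.min_len + 1:
            raise DesignError(f"target of {L} nt too short for convergent primers")
        half = L // 2
        _, fs, fe, fsite, ftm = _pick(circ, 0, half, params, "forward")
        _, rs, re_, rsite, rtm = _pick(circ, half, L, params, "reverse")
        amp = circ[fs:re_]
        rev = reverse_complement(NucleicSeq(rsite, DNA)).residues
        return PrimerSet(
            "convergent", fsite, rev, "circ", amp, len(amp), False,
            ftm, rtm, tm_method(len(fsite)), tm_method(len(rev)), fs, re_,
        )

    if mode == "linear":
        pre = products.precursor.to_dna().residues
        # target region sits between the upstream fragment and backbone tail
        t_start = len(products.upstream_fragment)
        t_end = t_start + L
        if t_end - t_start < params.min_len or len(pre) - t_end < params.min_len:
            raise DesignError("precursor windows too short for linear-mode primers")
        _, fs, fe, fsite, ftm = _pick(pre, t_start, t_end, params, "forward")
        _, rs, re_, rsite, rtm = _pick(pre, t_end, len(pre), params, "reverse")
        amp = pre[fs:re_]
        rev = reverse_complement(NucleicSeq(rsite, DNA)).residues
        return PrimerSet(
            "linear", fsite, rev, "precursor", amp, len(amp), False,
            ftm, rtm, tm_method(len(fsite)), tm_method(len(rev)), fs, re_,
        )

    raise ValueError(f"unknown primer mode {mode!r}")


def primer_table(sets: List[PrimerSet]) -> pd.DataFrame:
    """Primer sets as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "mode": p.mode,
                "fwd": p.fwd,
                "rev": p.rev,
                "tm_fwd": round(p.tm_fwd, 2),
                "tm_rev": round(p.tm_rev, 2),
                "amplicon_len": p.amplicon_len,
                "spans_junction": p.spans_junction,
                "template": p.template,
            }
            for p in sets
        ]
    )


# ---------------------------------------------------------------------------
# qPCR quantification


@dataclass
class CtTable:
    """Ct measurements with a reference (housekeeping) gene and control group.

    ``data`` columns: sample, group, replicate, gene, ct. Every
    (sample, replicate) that measures any gene must also measure the
    reference gene; Ct values must be finite and positive.
    """

    data: pd.DataFrame
    reference_gene: str
    control_group: str

    REQUIRED = ("sample", "group", "replicate", "gene", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DataError(f"Ct table missing columns: {missing}")
        ct = pd.to_numeric(self.data["ct"], errors="coerce")
        if ct.isna().any() or not np.isfinite(ct).all() or (ct <= 0).any():
            bad = self.data.loc[~np.isfinite(ct) | (ct <= 0), "sample"].tolist()
            raise DataError(f"non-finite or non-positive Ct values for samples {bad}")
        self.data = self.data.assign(ct=ct)
        if self.control_group not in set(self.data["group"]):
            raise DataError(f"control group {self.control_group!r} absent from table")
        units = self.data.groupby(["sample", "replicate"])["gene"].apply(set)
        for (sample, rep), genes in units.items():
            if self.reference_gene not in genes:
                raise DataError(
                    f"sample {sample!r} replicate {rep!r} lacks reference gene "
                    f"{self.reference_gene!r}"
                )

    @classmethod
    def from_tsv(cls, path, reference_gene: str, control_group: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene, control_group)


def ddct_fold_change(table: CtTable, target_gene: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method, per group.

    dCt = Ct(target) - Ct(reference) per (sample, replicate);
    ddCt = mean dCt(group) - mean dCt(control); fold = 2^-ddCt.
    The SEM column is the standard error over per-replicate fold values
    (each replicate folded against the control-group mean dCt); it is NaN
    for single-replicate groups.
    """
    df = table.data
    if target_gene not in set(df["gene"]):
        raise DataError(f"target gene {target_gene!r} absent from table")
    wide = (
        df[df["gene"].isin([target_gene, table.reference_gene])]
        .pivot_table(index=["sample", "group", "replicate"], columns="gene",
                     values="ct", aggfunc="mean")
        .reset_index()
    )
    if target_gene not in wide.columns:
        raise DataError(f"no paired measurements for {target_gene!r}")
    sub = wide.dropna(subset=[target_gene])
    if sub[table.reference_gene].isna().any():
        bad = sub.loc[sub[table.reference_gene].isna(), "sample"].tolist()
        raise DataError(f"missing reference Ct for samples {bad}")
    sub = sub.assign(dct=sub[target_gene] - sub[table.reference_gene])
    if table.control_group not in set(sub["group"]):
        raise DataError(
            f"target gene {target_gene!r} not measured in control group "
            f"{table.control_group!r}"
        )
    ctrl_mean = sub.loc[sub["group"] == table.control_group, "dct"].mean()

    rows = []
    for group, g in sub.groupby("group", sort=True):
        ddct = g["dct"].mean() - ctrl_mean
        folds = np.power(2.0, -(g["dct"] - ctrl_mean))
        n = len(g)
        sem = float(folds.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
        rows.append(
            {
                "group": group,
                "n": n,
                "delta_delta_ct": float(ddct),
                "fold_change": float(2.0 ** -ddct),
                "sem": sem,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def splicing_efficiency(circ_quantity: float, total_quantity: float) -> float:
    """Fraction of product circularized: circRNA / total RNA, in (0, 1].

    The circular species is a subset of total RNA, so a circular quantity
    exceeding the total is a consistency error, not a clamp.
    """
    if circ_quantity <= 0 or total_quantity <= 0:
        raise ConsistencyError("quantities must be positive")
    if circ_quantity > total_quantity:
        raise ConsistencyError(
            f"circRNA quantity {circ_quantity} exceeds total {total_quantity}"
        )
    return circ_quantity / total_quantity
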