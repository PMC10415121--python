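"""Detection primers, melting temperatures, and qPCR quantification math."""

import math

import numpy as np
import pandas as pd
import pytest

from ribocirc.assay import (
    CtTable,
    PrimerParams,
    ddct_fold_change,
    design_primers,
    divergent_amplicon,
    melting_temp,
    primer_table,
    splicing_efficiency,
)
from ribocirc.errors import AlphabetError, ConsistencyError, DataError, DesignError
from ribocirc.fixtures import FixtureSpec, random_target
from ribocirc.pipeline import design_circ
from ribocirc.seqcore import DNA, NucleicSeq
from ribocirc.splicesim import simulate_splicing


def products_for(length, seed):
    return simulate_splicing(design_circ(random_target(FixtureSpec(length, seed=seed))).construct)


class TestMeltingTemp:
    def test_wallace_rule_on_12mer(self):
        assert melting_temp(NucleicSeq("ACGTACGTACGT", DNA)) == pytest.approx(36.0)

    def test_wallace_all_at(self):
        assert melting_temp(NucleicSeq("AAAAAAAAAAAA", DNA)) == pytest.approx(24.0)

    def test_nearest_neighbor_above_13nt(self):
        tm = melting_temp(NucleicSeq("ACGTACGTACGTACGTAC", DNA))
        assert 30.0 < tm < 80.0  # physically plausible NN value

    def test_deterministic(self):
        p = NucleicSeq("GCGCATATGCGCATAT", DNA)
        assert melting_temp(p) == melting_temp(p)

    def test_rna_rejected(self):
        with pytest.raises(AlphabetError):
            melting_temp(NucleicSeq("ACGUACGUACGU"))

    def test_too_short_rejected(self):
        with pytest.raises(DesignError):
            melting_temp(NucleicSeq("ACGTACG", DNA))


class TestPrimerDesign:
    def test_divergent_amplicon_walks_around_the_circle(self):
        template = "A" * 60
        amp = divergent_amplicon(template, 35, 24)
        assert len(amp) == (60 - 35) + 24 == 49

    def test_divergent_set_spans_junction(self):
        products = products_for(120, 3)
        p = design_primers(products, "divergent")
        assert p.spans_junction and p.template == "circ"
        circ = products.circ.to_dna().residues
        # the amplicon wraps the junction: suffix + prefix of the linearization
        assert p.amplicon == circ[p.fwd_start :] + circ[: p.rev_end]
        assert p.fwd in p.amplicon

    def test_convergent_amplicon_stays_inside_target(self):
        products = products_for(120, 3)
        p = design_primers(products, "convergent")
        assert not p.spans_junction
        # target-only: a contiguous block of the circle's linearization, hence
        # also present in the precursor (detects total RNA, circ + precursor)
        assert p.amplicon in products.circ.to_dna().residues
        assert p.amplicon in products.precursor.to_dna().residues

    def test_linear_amplicon_absent_from_circle(self):
        products = products_for(120, 3)
        p = design_primers(products, "linear")
        circ = products.circ.to_dna().residues
        assert p.amplicon not in circ + circ  # not even across the junction
        assert p.template == "precursor"

    @pytest.mark.parametrize("seed", range(6))
    def test_mode_invariants_on_random_fixtures(self, seed):
        products = products_for(90 + seed * 25, seed)
        circ = products.circ.to_dna().residues
        div = design_primers(products, "divergent")
        conv = design_primers(products, "convergent")
        lin = design_primers(products, "linear")
        assert div.amplicon == circ[div.fwd_start :] + circ[: div.rev_end]
        assert conv.amplicon in circ
        assert lin.amplicon not in circ + circ

    def test_deterministic_given_params(self):
        a = design_primers(products_for(150, 4), "divergent")
        b = design_primers(products_for(150, 4), "divergent")
        assert a == b

    def test_too_short_template_raises(self):
        products = products_for(20, 5)
        with pytest.raises(DesignError):
            design_primers(products, "divergent")

    def test_unmeetable_tm_window_raises_with_constraint(self):
        products = products_for(120, 3)
        params = PrimerParams(tm_min=95.0, tm_max=99.0)
        with pytest.raises(DesignError, match="Tm"):
            design_primers(products, "divergent", params)

    def test_primer_table_columns(self):
        products = products_for(120, 3)
        table = primer_table([design_primers(products, m)
                              for m in ("divergent", "convergent", "linear")])
        assert list(table["mode"]) == ["divergent", "convergent", "linear"]
        assert set(table.columns) >= {"fwd", "rev", "tm_fwd", "tm_rev",
                                      "amplicon_len", "spans_junction"}


def ct_table(rows, reference="GAPDH", control="NC"):
    return CtTable(
        pd.DataFrame(rows, columns=["sample", "group", "replicate", "gene", "ct"]),
        reference_gene=reference,
        control_group=control,
    )


WORKED_EXAMPLE = [
    ("s1", "treated", 1, "circX", 20.0),
    ("s1", "treated", 1, "GAPDH", 18.0),
    ("s2", "NC", 1, "circX", 24.0),
    ("s2", "NC", 1, "GAPDH", 18.0),
]


class TestDdct:
    def test_worked_example_fold_16(self):
        out = ddct_fold_change(ct_table(WORKED_EXAMPLE), "circX")
        assert out.loc["treated", "delta_delta_ct"] == pytest.approx(-4.0)
        assert out.loc["treated", "fold_change"] == pytest.approx(16.0)

    def test_group_vs_itself_fold_1(self):
        out = ddct_fold_change(ct_table(WORKED_EXAMPLE), "circX")
        assert out.loc["NC", "fold_change"] == pytest.approx(1.0)

    def test_plus_one_ct_halves_fold(self):
        shifted = [
            (s, g, r, gene, ct + (1.0 if gene == "circX" and g == "treated" else 0.0))
            for s, g, r, gene, ct in WORKED_EXAMPLE
        ]
        out = ddct_fold_change(ct_table(shifted), "circX")
        assert out.loc["treated", "fold_change"] == pytest.approx(8.0)

    def test_invariant_under_global_ct_shift(self):
        shifted = [(s, g, r, gene, ct + 3.7) for s, g, r, gene, ct in WORKED_EXAMPLE]
        a = ddct_fold_change(ct_table(WORKED_EXAMPLE), "circX")
        b = ddct_fold_change(ct_table(shifted), "circX")
        pd.testing.assert_frame_equal(a, b)

    def test_sem_over_three_experiments(self):
        rows = []
        for i, (ct_t, ct_r) in enumerate([(20.0, 18.0), (20.5, 18.2), (19.8, 17.9)]):
            rows += [(f"t{i}", "treated", i, "circX", ct_t),
                     (f"t{i}", "treated", i, "GAPDH", ct_r)]
        for i, (ct_t, ct_r) in enumerate([(24.0, 18.0), (23.8, 18.1), (24.1, 17.8)]):
            rows += [(f"c{i}", "NC", i, "circX", ct_t),
                     (f"c{i}", "NC", i, "GAPDH", ct_r)]
        out = ddct_fold_change(ct_table(rows), "circX")
        assert out.loc["treated", "n"] == 3
        assert np.isfinite(out.loc["treated", "sem"])
        # SEM of per-replicate folds, independently recomputed
        dct = np.array([2.0, 2.3, 1.9])
        ctrl = np.array([6.0, 5.7, 6.3]).mean()
        folds = 2.0 ** -(dct - ctrl)
        assert out.loc["treated", "sem"] == pytest.approx(
            folds.std(ddof=1) / math.sqrt(3)
        )

    def test_missing_reference_names_sample(self):
        rows = [r for r in WORKED_EXAMPLE if not (r[0] == "s2" and r[3] == "GAPDH")]
        with pytest.raises(DataError, match="s2"):
            ct_table(rows)

    def test_nonpositive_ct_rejected(self):
        rows = WORKED_EXAMPLE + [("s3", "NC", 1, "circX", -1.0),
                                 ("s3", "NC", 1, "GAPDH", 18.0)]
        with pytest.raises(DataError):
            ct_table(rows)

    def test_absent_target_gene_rejected(self):
        with pytest.raises(DataError):
            ddct_fold_change(ct_table(WORKED_EXAMPLE), "nosuchgene")


class TestSplicingEfficiency:
    @pytest.mark.parametrize("circ, total, expected", [(4.0, 5.0, 0.8), (3.0, 3.0, 1.0)])
    def test_examples(self, circ, total, expected):
        assert splicing_efficiency(circ, total) == pytest.approx(expected)

    def test_circ_exceeding_total_is_inconsistent(self):
        with pytest.raises(ConsistencyError):
            splicing_efficiency(5.0, 4.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ConsistencyError):
            splicing_efficiency(0.0, 4.0)

    @pytest.mark.parametrize("scale", [0.1, 1.0, 37.5])
    def test_scale_invariance(self, scale):
        assert splicing_efficiency(2.0 * scale, 7.0 * scale) == pytest.approx(2.0 / 7.0)
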