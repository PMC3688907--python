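from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_call, make_expression
from complexdyn.complex_map import ComplexRecord, MappingTable, resolve_complexes
from complexdyn.detection import DetectionCall
from complexdyn.errors import ConfigError
from complexdyn.isoform import (
    MajorIsoformAssignment,
    assign_major_isoforms,
    eligible_components,
    major_involvement,
    switch_matrix,
)
from complexdyn.pfpc import call_pfpc
from oracle_utils import brute_major, brute_switch_fraction


class TestAssignment:
    def test_argmax_of_detected_transcripts(self):
        expr = make_expression(
            {"T1": {"s": (5.0, 0.1)}, "T2": {"s": (3.0, 0.1)}}, ["s"]
        )
        call = make_call({"T1": {"s"}, "T2": {"s"}}, ["s"])
        out = assign_major_isoforms(expr, call, {"T1": "G", "T2": "G"})
        assert out.by_sample["s"] == {"G": "T1"}

    def test_tie_breaks_to_smallest_transcript_id(self):
        expr = make_expression(
            {"T2": {"s": (4.0, 0.1)}, "T1": {"s": (4.0, 0.1)}}, ["s"]
        )
        call = make_call({"T2": {"s"}, "T1": {"s"}}, ["s"])
        out = assign_major_isoforms(expr, call, {"T1": "G", "T2": "G"})
        assert out.by_sample["s"] == {"G": "T1"}

    def test_undetected_dominant_is_skipped(self):
        expr = make_expression(
            {"T1": {"s": (9.0, 2.5)}, "T2": {"s": (3.0, 0.1)}}, ["s"]
        )
        call = make_call({"T1": set(), "T2": {"s"}}, ["s"])
        out = assign_major_isoforms(expr, call, {"T1": "G", "T2": "G"})
        assert out.by_sample["s"] == {"G": "T2"}

    def test_gene_with_no_detection_out_of_domain(self):
        expr = make_expression({"T1": {"s": (1.0, 2.0)}}, ["s"])
        call = make_call({"T1": set()}, ["s"])
        out = assign_major_isoforms(expr, call, {"T1": "G"})
        assert out.by_sample["s"] == {}

    def test_random_matrix_matches_argmax_oracle(self):
        rng = np.random.default_rng(13)
        transcripts = [f"T{i:03d}" for i in range(500)]
        tx_gene = {t: f"G{rng.integers(0, 200):03d}" for t in transcripts}
        samples = ["a", "b", "c"]
        est = pd.DataFrame(
            rng.normal(size=(500, 3)), index=transcripts, columns=samples
        )
        detected = pd.DataFrame(
            rng.random((500, 3)) < 0.7, index=transcripts, columns=samples
        )
        expr = make_expression({}, samples)
        expr.estimate, expr.sd = est, est.abs()
        call = DetectionCall("transcript", detected)
        out = assign_major_isoforms(expr, call, tx_gene)
        estimates = {
            (t, s): est.loc[t, s] for t in transcripts for s in samples
        }
        det_sets = {s: set(detected.index[detected[s]]) for s in samples}
        expected = brute_major(estimates, det_sets, tx_gene)
        assert out.by_sample == expected

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_invariant_under_monotone_rescaling_of_one_sample(self, scale, shift):
        rng = np.random.default_rng(3)
        transcripts = [f"T{i}" for i in range(30)]
        tx_gene = {t: f"G{i % 10}" for i, t in enumerate(transcripts)}
        est = pd.DataFrame(
            rng.normal(size=(30, 2)), index=transcripts, columns=["a", "b"]
        )
        expr = make_expression({}, ["a", "b"])
        expr.estimate, expr.sd = est, est.abs()
        call = DetectionCall(
            "transcript",
            pd.DataFrame(True, index=transcripts, columns=["a", "b"]),
        )
        base = assign_major_isoforms(expr, call, tx_gene)
        est2 = est.copy()
        est2["a"] = est2["a"] * scale + shift
        expr2 = make_expression({}, ["a", "b"])
        expr2.estimate, expr2.sd = est2, est2.abs()
        assert assign_major_isoforms(expr2, call, tx_gene).by_sample == base.by_sample


class TestEligibility:
    def test_two_transcripts_of_one_gene_required(self, small_mapping):
        eligible = eligible_components(
            ["P1", "P2", "P3", "P4"], small_mapping
        )
        # P1: 1 tx; P2: 2 tx of G2; P3: 3 tx of G3; P4: 2 tx but on 2 genes
        assert eligible == {"P2": "G2", "P3": "G3"}

    def test_multi_gene_protein_eligible_when_one_gene_contributes_two(self):
        mapping = MappingTable.from_associations(
            [("P", "T1", "Ga"), ("P", "T2", "Ga"), ("P", "T3", "Gb")]
        )
        assert eligible_components(["P"], mapping) == {"P": "Ga"}

    def test_min_transcripts_must_be_at_least_two(self, small_mapping):
        with pytest.raises(ConfigError):
            eligible_components(["P1"], small_mapping, min_transcripts=1)


class TestSwitchMatrix:
    def make_assignment(self, majors: dict) -> MajorIsoformAssignment:
        return MajorIsoformAssignment(samples=list(majors), by_sample=majors)

    def test_identical_samples_give_zero_matrix(self):
        majors = {"a": {"G1": "T1", "G2": "T3"}, "b": {"G1": "T1", "G2": "T3"}}
        out = switch_matrix(
            self.make_assignment(majors), {"P1": "G1", "P2": "G2"}
        )
        assert (out.fractions.to_numpy() == 0).all()
        assert out.overall_switch_fraction == 0.0

    def test_planted_twelve_percent_on_hundred_components(self):
        """12 of 100 eligible constituents flip dominant isoform: entry 0.12."""
        genes = [f"G{i:03d}" for i in range(100)]
        a = {g: f"{g}.T1" for g in genes}
        b = dict(a)
        for g in genes[:12]:
            b[g] = f"{g}.T2"
        out = switch_matrix(
            self.make_assignment({"a": a, "b": b}),
            {f"P{g}": g for g in genes},
        )
        assert out.fractions.loc["a", "b"] == pytest.approx(0.12)
        assert out.denominators.loc["a", "b"] == 100
        assert out.overall_switch_fraction == pytest.approx(0.12)

    def test_symmetry_zero_diagonal_and_range(self):
        rng = np.random.default_rng(17)
        samples = [f"s{i}" for i in range(5)]
        genes = [f"G{i}" for i in range(40)]
        majors = {
            s: {g: f"{g}.T{rng.integers(0, 3)}" for g in genes if rng.random() < 0.8}
            for s in samples
        }
        out = switch_matrix(
            self.make_assignment(majors), {f"P{g}": g for g in genes}
        )
        values = out.fractions.to_numpy()
        assert np.allclose(values, values.T, equal_nan=True)
        assert np.all(np.diag(values) == 0)
        finite = values[~np.isnan(values)]
        assert ((finite >= 0) & (finite <= 1)).all()
        # cross-check every pair against the loop oracle
        for i, si in enumerate(samples):
            for sj in samples[i + 1 :]:
                expected, denom = brute_switch_fraction(
                    majors[si], majors[sj], {f"P{g}": g for g in genes}
                )
                got = out.fractions.loc[si, sj]
                assert out.denominators.loc[si, sj] == denom
                if expected is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)

    def test_empty_denominator_reported_missing_not_zero(self):
        majors = {"a": {"G1": "T1"}, "b": {}}
        out = switch_matrix(self.make_assignment(majors), {"P1": "G1"})
        assert np.isnan(out.fractions.loc["a", "b"])
        assert out.denominators.loc["a", "b"] == 0


class TestInvolvement:
    def run_involvement(self, mapping, complexes, expr_values, detected):
        samples = ["s"]
        expr = make_expression(expr_values, samples)
        call = make_call(detected, samples)
        kept, _ = resolve_complexes(complexes, mapping)
        pfpc_res = call_pfpc(kept, call, mapping)
        assignment = assign_major_isoforms(expr, call, mapping.transcript_to_gene)
        return major_involvement(assignment, pfpc_res, kept, mapping)

    def test_sole_isoform_is_trivially_major(self):
        mapping = MappingTable.from_associations([("P1", "T1", "G1")])
        out = self.run_involvement(
            mapping,
            [ComplexRecord("C1", "c", ("P1",))],
            {"T1": {"s": (1.0, 0.1)}},
            {"T1": {"s"}},
        )
        assert out.loc["s", "pfpc_major_fraction"] == 1.0
        assert out.loc["s", "subunit_major_fraction"] == 1.0

    def test_major_outside_subunit_transcripts_excluded(self):
        # G1 produces T1 (subunit-coding) and T2 (not mapped to P1);
        # T2 dominates, so P1 carries no major isoform
        mapping = MappingTable.from_associations(
            [("P1", "T1", "G1"), ("Q1", "T2", "G1")]
        )
        out = self.run_involvement(
            mapping,
            [ComplexRecord("C1", "c", ("P1",))],
            {"T1": {"s": (1.0, 0.1)}, "T2": {"s": (5.0, 0.1)}},
            {"T1": {"s"}, "T2": {"s"}},
        )
        assert out.loc["s", "pfpc_major_fraction"] == 0.0
        assert out.loc["s", "subunit_major_fraction"] == 0.0

    def test_planted_involvement_rate_recovered(self, make_study):
        cfg, universe, panel, truth = make_study(
            31, n_complexes=60, involvement_rate=0.8, absent_rate=0.0,
            coexpression=1.0, noise_sd=0.05,
        )
        kept, _ = resolve_complexes(universe.complexes, universe.mapping)
        call = DetectionCall("transcript", panel.detected)
        expr = make_expression({}, panel.samples)
        expr.estimate, expr.sd = panel.estimate, panel.sd
        pfpc_res = call_pfpc(kept, call, universe.mapping)
        assignment = assign_major_isoforms(
            expr, call, universe.mapping.transcript_to_gene
        )
        out = major_involvement(assignment, pfpc_res, kept, universe.mapping)
        for s in panel.samples:
            assert out.loc[s, "subunit_major_fraction"] == pytest.approx(
                truth.involvement[s]["subunit_major_fraction"]
            )
            assert out.loc[s, "pfpc_major_fraction"] == pytest.approx(
                truth.involvement[s]["pfpc_major_fraction"]
            )
        # with no absences, the realized subunit fraction is the planted rate
        n_proteins = len(universe.complex_proteins)
        expected = 1.0 - len(universe.noninvolved) / n_proteins
        for s in panel.samples:
            assert out.loc[s, "subunit_major_fraction"] == pytest.approx(expected)
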