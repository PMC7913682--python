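"""Read classification, PSI estimation and detection-bias measurement."""

import numpy as np
import pandas as pd
import pytest

from splicedex.panel import SpliceEvent
from splicedex.quantify import (
    AMBIGUOUS,
    AlignmentRecord,
    EXCLUSION,
    INCLUSION,
    UNINFORMATIVE,
    align_reads_exact,
    build_isoform_refs,
    classify_reads,
    clopper_pearson,
    count_and_psi,
    detection_bias,
)
from splicedex import simulate


def tiny_ref(up="AAAA", cassette="CC", down="GGGG"):
    event = SpliceEvent(event_id="e", gene="E", cassette_len=len(cassette))
    return build_isoform_refs(event, up, cassette, down)


class TestBuildIsoformRefs:
    def test_construction_and_junction_offsets(self):
        ref = tiny_ref()
        assert ref.inclusion_seq == "AAAACCGGGG"
        assert ref.exclusion_seq == "AAAAGGGG"
        assert ref.inclusion_junctions == (4, 6)
        assert ref.exclusion_junction == 4

    def test_length_identity(self, panel36):
        for eid, ref in panel36.refs.items():
            assert len(ref.inclusion_seq) - len(ref.exclusion_seq) == ref.event.cassette_len

    def test_empty_cassette_rejected(self):
        event = SpliceEvent(event_id="e", gene="E", cassette_len=2)
        with pytest.raises(ValueError):
            build_isoform_refs(event, "AAAA", "", "GGGG")

    def test_cassette_length_must_match_declaration(self):
        event = SpliceEvent(event_id="e", gene="E", cassette_len=5)
        with pytest.raises(ValueError):
            build_isoform_refs(event, "AAAA", "CC", "GGGG")


def rec(target, score, start, end, read_id="r", primary=True):
    return AlignmentRecord(read_id=read_id, target=target, score=score,
                           primary=primary, ref_start=start, ref_end=end)


class TestClassifyReads:
    def setup_method(self):
        # junctions: inclusion at 40 and 60, exclusion at 40
        event = SpliceEvent(event_id="e", gene="E", cassette_len=20)
        self.ref = build_isoform_refs(event, "A" * 40, "C" * 20, "G" * 40)

    def test_single_target_junction_read_is_informative(self):
        out = classify_reads([rec(EXCLUSION, 40.0, 20, 60)], self.ref)
        assert out[0].best_target == EXCLUSION
        assert out[0].spans_junction

    def test_shared_flank_read_is_uninformative(self):
        # equal score on both isoforms, spans no junction of either
        out = classify_reads(
            [rec(INCLUSION, 30.0, 0, 30), rec(EXCLUSION, 30.0, 0, 30)], self.ref
        )
        assert out[0].best_target == UNINFORMATIVE

    def test_equal_score_junction_reads_are_ambiguous(self):
        out = classify_reads(
            [rec(INCLUSION, 40.0, 20, 60), rec(EXCLUSION, 40.0, 20, 60)], self.ref
        )
        assert out[0].best_target == AMBIGUOUS
        assert out[0].score_margin == 0.0

    def test_overhang_requirement(self):
        # covers the junction at 40 with only 5 nt on the right
        out = classify_reads([rec(EXCLUSION, 25.0, 20, 45)], self.ref, min_overhang=8)
        assert out[0].best_target == UNINFORMATIVE
        out = classify_reads([rec(EXCLUSION, 25.0, 20, 45)], self.ref, min_overhang=5)
        assert out[0].best_target == EXCLUSION

    def test_non_primary_alignments_not_counted(self):
        out = classify_reads([rec(EXCLUSION, 40.0, 20, 60, primary=False)], self.ref)
        assert out[0].best_target == UNINFORMATIVE
        assert not out[0].primary

    def test_unknown_reference_name_rejected(self):
        with pytest.raises(ValueError, match="unknown reference"):
            classify_reads([rec("intron", 40.0, 20, 60)], self.ref)

    def test_agrees_with_brute_force_on_simulated_reads(self, panel36, rng):
        """Exhaustive substring scoring against both isoforms reproduces the
        classifier's calls on 150-nt error-free reads."""
        ref = panel36.refs["Clcn1"]
        reads, _ = simulate.simulate_reads(ref, 0.4, 300, rng)
        pairs = [(r.read_id, r.sequence) for r in reads]
        out = {c.read_id: c.best_target
               for c in classify_reads(align_reads_exact(pairs, ref), ref)}
        for read_id, seq in pairs:
            # brute force: score = read length where the read occurs exactly
            scores = {}
            spans = {}
            for target in (INCLUSION, EXCLUSION):
                pos = ref.sequence(target).find(seq)
                if pos < 0:
                    continue
                scores[target] = len(seq)
                spans[target] = any(
                    pos + 8 <= j <= pos + len(seq) - 8 for j in ref.junctions(target)
                )
            if len(scores) == 1:
                (target,) = scores
                expect = target if spans[target] else UNINFORMATIVE
            else:
                expect = AMBIGUOUS if any(spans.values()) else UNINFORMATIVE
            assert out[read_id] == expect


class TestCountAndPsi:
    def _classified(self, n_inc, n_exc, n_amb=0, n_uninf=0):
        from splicedex.quantify import ClassifiedRead

        out = []
        labels = ([INCLUSION] * n_inc + [EXCLUSION] * n_exc
                  + [AMBIGUOUS] * n_amb + [UNINFORMATIVE] * n_uninf)
        for i, lab in enumerate(labels):
            out.append(ClassifiedRead(f"r{i}", lab, True, lab in (INCLUSION, EXCLUSION), 1.0))
        return out

    def test_symmetric_counts_give_half(self):
        counts, psi = count_and_psi(self._classified(100, 100))
        assert psi.psi == pytest.approx(0.5)
        assert counts.n_informative == 200

    def test_zero_inclusion_boundary(self):
        _, psi = count_and_psi(self._classified(0, 50))
        assert psi.psi == 0.0
        assert psi.ci_low == 0.0

    def test_count_conservation(self):
        counts, _ = count_and_psi(self._classified(10, 20, 3, 7))
        assert counts.total == 40

    def test_low_coverage_flagged_undefined(self):
        counts, psi = count_and_psi(self._classified(5, 5), min_reads=20)
        assert not psi.defined and psi.psi is None
        assert counts.n_informative == 10

    def test_psi_invariant_to_read_order_and_duplication(self):
        cls = self._classified(30, 70, 5, 5)
        _, a = count_and_psi(cls)
        _, b = count_and_psi(cls[::-1])
        _, c = count_and_psi(cls + cls)
        assert a.psi == b.psi == c.psi

    def test_clopper_pearson_interval_contains_estimate(self):
        low, high = clopper_pearson(30, 100)
        assert low < 0.30 < high
        # the exact interval at n=100 is a few points wide
        assert high - low < 0.25

    def test_binomial_coverage_at_assay_depth(self, rng):
        """The 95% interval covers the binomial truth at the assay's
        typical informative depth (~4100 reads/event)."""
        n, p, reps = 4100, 0.30, 300
        k = rng.binomial(n, p, size=reps)
        from scipy import stats as st

        low = np.where(k == 0, 0.0, st.beta.ppf(0.025, k, n - k + 1))
        high = np.where(k == n, 1.0, st.beta.ppf(0.975, k + 1, n - k))
        coverage = np.mean((low <= p) & (p <= high))
        assert coverage >= 0.95


class TestDetectionBias:
    def _matrix(self, values, events=("a", "b"), samples=("s1", "s2")):
        return pd.DataFrame(values, index=list(events), columns=list(samples))

    def test_identity_gives_zero_bias(self):
        m = self._matrix([[0.5, 0.6], [0.2, 0.3]])
        per_event, overall = detection_bias(m, m.copy())
        assert overall == pytest.approx(0.0)
        assert (per_event["mean_delta_psi_pct"] == 0).all()

    def test_constant_shift_measured_in_percentage_points(self):
        ref = self._matrix([[0.5, 0.6], [0.2, 0.3]])
        tgt = ref.copy()
        tgt.loc["a"] -= 0.05
        per_event, _ = detection_bias(tgt, ref)
        assert per_event.loc["a", "mean_delta_psi_pct"] == pytest.approx(-5.0)
        assert per_event.loc["b", "mean_delta_psi_pct"] == pytest.approx(0.0)

    def test_disjoint_matrices_rejected(self):
        a = self._matrix([[0.5, 0.6]], events=("a",))
        b = self._matrix([[0.5, 0.6]], events=("b",))
        with pytest.raises(ValueError):
            detection_bias(a, b)

    def test_length_bias_underdetects_inclusion_more_for_longer_cassettes(self, rng):
        """PCR length bias produces negative PSI bias whose magnitude grows
        with cassette size, matching the closed-form expectation."""
        lam, cycles, true_psi, exc_len = 0.002, 15, 0.5, 450
        biases = {}
        for c_len in (45, 150, 300):
            event = SpliceEvent(event_id=f"c{c_len}", gene="G", cassette_len=c_len)
            ref = build_isoform_refs(
                event, "".join(rng.choice(list("ACGT"), 200)),
                "".join(rng.choice(list("ACGT"), c_len)),
                "".join(rng.choice(list("ACGT"), exc_len - 200)),
            )
            reads, truth = simulate.simulate_reads(
                ref, true_psi, 20000, rng, lam=lam, cycles=cycles
            )
            recs = align_reads_exact([(r.read_id, r.sequence) for r in reads], ref)
            _, psi = count_and_psi(classify_reads(recs, ref))
            biases[c_len] = (psi.psi - true_psi) * 100
            expect = (truth["observed_p_inclusion"] - true_psi) * 100
            assert biases[c_len] == pytest.approx(expect, abs=1.5)
        assert biases[45] < 0
        assert biases[45] > biases[150] > biases[300]

    def test_unbiased_simulation_recovers_truth(self, panel36, rng):
        """Without length bias the overall mean bias is < 0.5 PSI points."""
        deltas = []
        for eid in ("Bin1", "Clcn1", "Ttn"):
            ref = panel36.refs[eid]
            reads, _ = simulate.simulate_reads(ref, 0.4, 10000, rng, lam=0.0)
            recs = align_reads_exact([(r.read_id, r.sequence) for r in reads], ref)
            _, psi = count_and_psi(classify_reads(recs, ref))
            deltas.append((psi.psi - 0.4) * 100)
        assert abs(np.mean(deltas)) < 0.5
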