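"""Simulator contracts: determinism, truth tables and closed-form checks."""

import numpy as np
import pandas as pd
import pytest

from splicedex import simulate
from splicedex.dose_response import fit_events, four_pl
from splicedex.quantify import align_reads_exact, classify_reads, count_and_psi
from splicedex.splice_index import mdsi_table, normalize, reference_stats


class TestSimulateReads:
    def test_deterministic_under_seed(self, panel36):
        ref = panel36.refs["Atp2a1"]
        a, _ = simulate.simulate_reads(ref, 0.3, 200, np.random.default_rng(7))
        b, _ = simulate.simulate_reads(ref, 0.3, 200, np.random.default_rng(7))
        assert a == b

    def test_unbiased_inclusion_fraction(self, panel36, rng):
        ref = panel36.refs["Clcn1"]
        reads, truth = simulate.simulate_reads(ref, 0.5, 10000, rng, lam=0.0)
        frac = np.mean([r.true_isoform == "inclusion" for r in reads])
        sd = np.sqrt(0.25 / 10000)
        assert abs(frac - 0.5) < 3 * sd
        assert truth["observed_p_inclusion"] == pytest.approx(0.5)

    def test_pure_inclusion_boundary(self, panel36, rng):
        reads, _ = simulate.simulate_reads(panel36.refs["Nfix"], 1.0, 500, rng)
        assert all(r.true_isoform == "inclusion" for r in reads)

    def test_read_longer_than_amplicon_rejected(self, panel36, rng):
        with pytest.raises(ValueError):
            simulate.simulate_reads(panel36.refs["Nfix"], 0.5, 10, rng, read_len=10000)

    def test_length_bias_expectation_closed_form(self, panel36, rng):
        """Measured inclusion fraction under amplification bias matches
        psi*w_inc/(psi*w_inc + (1-psi)*w_exc) within Monte Carlo error."""
        ref = panel36.refs["Ttn"]  # 303 nt cassette: largest length contrast
        lam = 0.003
        expect = simulate.observed_inclusion_probability(
            0.5, len(ref.inclusion_seq), len(ref.exclusion_seq), lam=lam
        )
        assert expect < 0.5  # longer inclusion amplicon is under-amplified
        reads, _ = simulate.simulate_reads(ref, 0.5, 20000, rng, lam=lam)
        recs = align_reads_exact([(r.read_id, r.sequence) for r in reads], ref)
        _, psi = count_and_psi(classify_reads(recs, ref))
        assert psi.psi == pytest.approx(expect, abs=3 * np.sqrt(0.25 / 20000) + 0.005)

    def test_fastq_roundtrip(self, panel36, rng, tmp_path):
        from Bio import SeqIO

        reads, _ = simulate.simulate_reads(panel36.refs["Nfix"], 0.5, 20, rng)
        path = tmp_path / "reads.fastq"
        simulate.write_fastq(reads, path)
        back = list(SeqIO.parse(str(path), "fastq"))
        assert [str(r.seq) for r in back] == [r.sequence for r in reads]


class TestSimulateCohort:
    def test_zero_noise_limit_reproduces_curve_exactly(self, panel36, rng):
        curves = simulate.default_event_curves(panel36.events, rng)
        sim = simulate.simulate_cohort(
            panel36.events, curves, [("g", 3, 0.5)], rng, noise_sd=0.0, n_reads=10**8
        )
        for eid in ("Atp2a1", "Clcn1"):
            init, final, ec50, hill = curves[eid]
            want = four_pl(0.5, init, final, ec50, hill)
            assert sim.psi.loc[eid].iloc[0] == pytest.approx(want, abs=1e-3)

    def test_truth_table_roundtrips(self, panel36, rng):
        curves = simulate.default_event_curves(panel36.events, rng)
        sim = simulate.simulate_cohort(panel36.events, curves,
                                       [("a", 4, 0.0), ("b", 4, 1.0)], rng)
        # every sample x event pair is recorded with its generating curve
        assert len(sim.truth) == 8 * len(panel36.events)
        merged = sim.truth.merge(
            sim.counts, on=["sample_id", "event"], validate="one_to_one"
        )
        np.testing.assert_allclose(
            merged["n_inclusion"] / (merged["n_inclusion"] + merged["n_exclusion"]),
            sim.psi.T.stack().reorder_levels([0, 1]).loc[
                list(zip(merged["sample_id"], merged["event"]))
            ].to_numpy(),
        )

    def test_endpoint_anchor_recovery(self, panel36, rng):
        """Anchors fitted downstream recover the generating curve
        endpoints: WT median near PSI(0), severe 95th percentile near
        PSI(1)."""
        curves = simulate.default_event_curves(panel36.events, rng)
        sim = simulate.simulate_cohort(
            panel36.events, curves, [("WT", 12, 0.0), ("dm", 40, 1.0)],
            rng, noise_sd=0.01, n_reads=4000,
        )
        wt = [s for s in sim.psi.columns if s.startswith("WT")]
        dm = [s for s in sim.psi.columns if s.startswith("dm")]
        stats = reference_stats(sim.psi, wt, dm)
        for eid in ("Atp2a1", "Clcn1", "Ttn"):
            init, final, ec50, hill = curves[eid]
            assert stats.loc[eid, "psi_wt"] == pytest.approx(init, abs=0.02)
            assert stats.loc[eid, "psi_dm95"] == pytest.approx(
                four_pl(1.0, init, final, ec50, hill), abs=0.05
            )

    def test_end_to_end_curve_recovery(self, panel36, rng):
        """Cohort -> anchors -> mDSI -> per-event 4PL refit recovers each
        event's generating response curve.

        The index axis is a monotone (but nonlinear) image of the latent
        activity, so the raw (EC50, Hill) tuple is only identified up to
        that reparameterization; the axis-invariant quantities are (i) the
        half-shift point -- where the fitted curve crosses the generating
        curve's midpoint PSI, compared with the generating EC50 mapped
        through the empirical activity-to-index calibration -- and (ii)
        the fitted curve's per-sample PSI predictions."""
        from scipy.optimize import brentq

        curves = simulate.default_event_curves(panel36.events, rng)
        groups = [(f"g{i}", 20, x) for i, x in
                  enumerate((0.0, 0.2, 0.4, 0.6, 0.8, 1.0))]
        sim = simulate.simulate_cohort(panel36.events, curves, groups, rng,
                                       noise_sd=0.03, n_reads=4000)
        wt = [s for s in sim.psi.columns if s.startswith("g0_")]
        dm = [s for s in sim.psi.columns if s.startswith("g5_")]
        stats = reference_stats(sim.psi, wt, dm)
        table = mdsi_table(normalize(sim.psi, stats), panel36.roles)
        calib = table.join(sim.samples.set_index("sample_id")).groupby(
            "latent_activity")["mdsi"].mean()
        fits = fit_events(sim.psi, table["mdsi"])
        latent = sim.samples.set_index("sample_id")["latent_activity"]
        half_shift_errors, prediction_errors = [], []
        for e in panel36.events:
            if e.role != "test":
                continue
            init, final, ec50, hill = curves[e.event_id]
            f = fits.loc[e.event_id]
            mid = (init + final) / 2
            cross = brentq(
                lambda x: four_pl(x, f.psi_init, f.psi_final, f.ec50, f.hill) - mid,
                1e-6, 2.0,
            )
            ec50_on_index = float(np.interp(ec50, calib.index, calib.to_numpy()))
            half_shift_errors.append(abs(cross - ec50_on_index))
            truth_psi = four_pl(latent.to_numpy(), init, final, ec50, hill)
            pred = four_pl(table["mdsi"].clip(lower=0).loc[latent.index].to_numpy(),
                           f.psi_init, f.psi_final, f.ec50, f.hill)
            prediction_errors.append(np.median(np.abs(pred - truth_psi)))
        assert np.median(half_shift_errors) < 0.1
        assert np.median(prediction_errors) < 0.05


class TestSimulateFlanks:
    def test_deterministic_under_seed(self):
        planted = [simulate.PlantedMotif("GCTGC", "downstream_intron", (20, 150), 0.5)]
        a = simulate.simulate_flanks(5, 5, np.random.default_rng(3), planted=planted)
        b = simulate.simulate_flanks(5, 5, np.random.default_rng(3), planted=planted)
        assert [r.sequences for r in a[0]] == [r.sequences for r in b[0]]
        for ra, rb in zip(a[0], b[0]):
            assert ra.delta_psi == rb.delta_psi

    def test_truth_table_records_planted_positions(self, rng):
        planted = [simulate.PlantedMotif("GCTGC", "downstream_intron", (20, 30), 1.0)]
        fg, _, truth = simulate.simulate_flanks(10, 0, rng, planted=planted)
        assert len(truth) == 10
        for row in truth.itertuples():
            rec = next(r for r in fg if r.exon_id == row.exon_id)
            assert rec.sequences[row.region][row.offset : row.offset + 5] == "GCTGC"
            assert rec.conservation[row.region][row.offset : row.offset + 5].mean() >= 0.5

    def test_window_outside_region_rejected(self):
        with pytest.raises(ValueError):
            simulate.PlantedMotif("GCTGC", "upstream_exon_edge", (40, 60), 0.5)

    def test_null_simulation_false_call_rate(self, rng):
        """Without planting, BH-significant windows are rare (<= 5% of the
        family, and in practice essentially absent)."""
        from splicedex.motif import window_enrichment

        fg, bg, _ = simulate.simulate_flanks(40, 40, rng)
        result = window_enrichment(fg, bg)
        rate = float((result["q"] < 0.05).mean())
        assert rate <= 0.05
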