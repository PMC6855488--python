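"""Trace parameter extraction: CT, A5, MCF, LI60, ML, breakdown time."""

import numpy as np
import pytest

from fibrolyse.simulate import (
    TraceModelParams,
    analytic_ct,
    model_amplitude,
    params_for_li60,
    simulate_trace,
)
from fibrolyse.traces import (
    InsufficientRuntimeError,
    NoClotError,
    TraceParameters,
    ViscoelasticTrace,
    compute_a5,
    compute_breakdown_time,
    compute_ct,
    compute_li60,
    compute_mcf,
    compute_ml,
    extract_parameters,
    read_trace_csv,
    write_extraction_report,
)


def linear_trace(points, runtime=7200.0):
    t, a = zip(*points)
    return ViscoelasticTrace(np.array(t, float), np.array(a, float), runtime=runtime)


class TestTraceValidation:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            linear_trace([(0, 0), (10, 1), (5, 2)])

    def test_rejects_negative_amplitude(self):
        with pytest.raises(ValueError, match="non-negative"):
            linear_trace([(0, 0), (10, -1)])

    def test_rejects_samples_beyond_runtime(self):
        with pytest.raises(ValueError, match="runtime"):
            linear_trace([(0, 0), (8000, 5)], runtime=7200)


class TestCT:
    def test_interpolates_between_samples(self):
        # 0 mm at 60 s, 4 mm at 120 s: the 2 mm threshold is hit midway
        tr = linear_trace([(0, 0), (60, 0), (120, 4), (7200, 4)])
        assert compute_ct(tr) == pytest.approx(90.0)

    def test_first_sample_already_at_threshold(self):
        tr = linear_trace([(30, 2.0), (7200, 50.0)])
        assert compute_ct(tr) == pytest.approx(30.0)

    def test_flat_line_raises_no_clot(self):
        tr = linear_trace([(0, 0.5), (7200, 0.5)])
        with pytest.raises(NoClotError):
            compute_ct(tr)

    def test_matches_analytic_solution_of_generator(self, base_params):
        tr = simulate_trace(base_params)
        ct = compute_ct(tr)
        assert abs(ct - analytic_ct(base_params)) <= base_params.sample_interval


class TestMCFAndA5:
    def test_mcf_is_sample_maximum(self):
        tr = linear_trace([(0, 0), (100, 10), (200, 55), (7200, 40)])
        assert compute_mcf(tr) == 55.0

    def test_mcf_of_monotone_trace_is_final_amplitude(self):
        tr = linear_trace([(0, 0), (3600, 30), (7200, 48)])
        assert compute_mcf(tr) == 48.0

    def test_mcf_recovers_model_plateau(self, base_params):
        pars = extract_parameters(simulate_trace(base_params))
        assert pars.mcf == pytest.approx(60.0, abs=0.05)

    def test_a5_reads_amplitude_five_minutes_after_ct(self):
        tr = linear_trace([(0, 0), (100, 2), (400, 32), (7200, 32)])
        assert compute_a5(tr, ct=100.0) == pytest.approx(32.0)

    def test_a5_on_constant_trace(self):
        tr = linear_trace([(0, 40), (7200, 40)])
        assert compute_a5(tr, ct=0.0) == pytest.approx(40.0)

    def test_a5_matches_model_amplitude(self, base_params):
        tr = simulate_trace(base_params)
        ct = compute_ct(tr)
        expected = model_amplitude(base_params, np.array([ct + 300.0]))[0]
        assert compute_a5(tr, ct) == pytest.approx(expected, abs=0.05)

    def test_a5_short_run_raises(self):
        tr = linear_trace([(0, 0), (100, 5), (200, 10)], runtime=200)
        with pytest.raises(InsufficientRuntimeError):
            compute_a5(tr, ct=60.0)


class TestLI60:
    def test_no_lysis_gives_100(self):
        tr = linear_trace([(0, 0), (100, 50), (7200, 50)])
        assert compute_li60(tr, ct=50.0, mcf=50.0) == pytest.approx(100.0)

    def test_half_amplitude_gives_50(self):
        tr = linear_trace([(0, 0), (100, 60), (3700, 30), (7200, 30)])
        assert compute_li60(tr, ct=100.0, mcf=60.0) == pytest.approx(50.0)

    def test_zero_mcf_raises(self):
        tr = linear_trace([(0, 0), (7200, 0)])
        with pytest.raises(ValueError, match="mcf"):
            compute_li60(tr, ct=0.0, mcf=0.0)

    def test_recovers_61_percent_lysis_regime(self, base_params):
        # the lower-quartile regime of the effusion arm: LI60 = 61 %
        q = params_for_li60(61.0, 47.0, base_params)
        pars = extract_parameters(simulate_trace(q))
        assert pars.li60 == pytest.approx(61.0, abs=0.5)


class TestML:
    def test_monotone_trace_has_zero_ml(self):
        tr = linear_trace([(0, 0), (3600, 30), (7200, 48)])
        assert compute_ml(tr, mcf=48.0) == 0.0

    def test_total_breakdown_gives_100(self):
        tr = linear_trace([(0, 0), (600, 60), (5000, 0), (7200, 0)])
        assert compute_ml(tr, mcf=60.0) == pytest.approx(100.0)

    def test_definition_arithmetic(self):
        # MCF 50 mm falling to a 41 mm minimum is 18 % maximum lysis
        tr = linear_trace([(0, 0), (600, 50), (7200, 41)])
        assert compute_ml(tr, mcf=50.0) == pytest.approx(18.0)


class TestBreakdownTime:
    def test_absent_when_clot_persists(self):
        tr = linear_trace([(0, 0), (600, 50), (7200, 40)])
        assert compute_breakdown_time(tr, ct=60.0) is None

    def test_crossing_at_25_minutes_after_ct(self):
        ct = 100.0
        t_cross = ct + 25 * 60.0
        tr = linear_trace([(0, 0), (ct, 2), (600, 50), (t_cross - 300, 4),
                           (t_cross + 300, 0), (7200, 0)])
        bt = compute_breakdown_time(tr, ct=ct)
        assert bt == pytest.approx(25.0, abs=0.1)

    def test_clock_from_test_start_option(self):
        ct = 100.0
        tr = linear_trace([(0, 0), (ct, 2), (600, 50), (1500, 0), (7200, 0)])
        from_ct = compute_breakdown_time(tr, ct=ct, clock="ct")
        from_start = compute_breakdown_time(tr, ct=ct, clock="start")
        assert from_start == pytest.approx(from_ct + ct / 60.0)

    def test_matches_analytic_crossing_of_fulminant_model(self, base_params):
        # exponential lysis tuned so the 2 mm down-crossing sits at CT + 28 min
        ct = analytic_ct(base_params)
        onset = 700.0
        t_target = ct + 28 * 60.0
        lam = np.log(base_params.mcf_true / 2.0) / (t_target - base_params.t0 - onset)
        p = TraceModelParams(
            t0=base_params.t0, k=base_params.k, mcf_true=base_params.mcf_true,
            lysis_onset=onset, lysis_rate=lam,
        )
        tr = simulate_trace(p)
        bt = compute_breakdown_time(tr, ct=compute_ct(tr))
        assert bt == pytest.approx(28.0, abs=p.sample_interval / 60.0 + 0.05)


class TestExtractParameters:
    def test_no_lysis_trace(self, base_params):
        pars = extract_parameters(simulate_trace(base_params))
        assert pars.ml == pytest.approx(0.0, abs=0.1)
        assert pars.li60 == pytest.approx(100.0, abs=0.1)
        assert pars.breakdown_time is None

    def test_fulminant_trace(self, base_params):
        p = TraceModelParams(
            t0=45, k=0.01, mcf_true=60, lysis_onset=700.0, lysis_rate=4e-3
        )
        pars = extract_parameters(simulate_trace(p))
        assert pars.ml == pytest.approx(100.0, abs=0.1)
        assert pars.breakdown_time is not None

    def test_parameter_invariants_over_random_cohort(self, rng):
        # ML >= 100 - LI60, A5 <= MCF, everything bounded, on 50 random traces
        for _ in range(50):
            p = TraceModelParams(
                t0=float(rng.uniform(20, 120)),
                k=float(rng.uniform(0.004, 0.05)),
                mcf_true=float(rng.uniform(20, 75)),
                lysis_onset=float(rng.uniform(800, 4000)),
                lysis_rate=float(rng.uniform(0, 8e-4)),
                noise_sd=0.0,
                sample_interval=2.0,
            )
            pars = extract_parameters(simulate_trace(p))
            assert 0 <= pars.li60 <= 100
            assert 0 <= pars.ml <= 100
            assert pars.a5 <= pars.mcf + 1e-9
            assert pars.ml >= 100 - pars.li60 - 0.5

    def test_sampling_density_invariance(self, base_params):
        # halving the sample interval moves LI60 by < 0.5 points
        q = params_for_li60(61.0, 47.0, base_params)
        coarse = extract_parameters(simulate_trace(q))
        fine = extract_parameters(
            simulate_trace(
                TraceModelParams(
                    **{**q.__dict__, "sample_interval": q.sample_interval / 2}
                )
            )
        )
        assert abs(coarse.li60 - fine.li60) < 0.5


class TestTraceParametersType:
    def test_rejects_a5_above_mcf(self):
        with pytest.raises(ValueError):
            TraceParameters(ct=60, mcf=40, ml=0, a5=45)

    def test_rejects_nonpositive_breakdown(self):
        with pytest.raises(ValueError):
            TraceParameters(ct=60, mcf=40, ml=10, breakdown_time=0.0)


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path, base_params):
        import pandas as pd

        tr = simulate_trace(base_params)
        path = tmp_path / "trace.csv"
        pd.DataFrame({"time_s": tr.times, "amplitude_mm": tr.amplitudes}).to_csv(
            path, index=False
        )
        back = read_trace_csv(path)
        assert np.allclose(back.amplitudes, tr.amplitudes)

    def test_extraction_report_columns(self, tmp_path, base_params):
        pars = extract_parameters(simulate_trace(base_params))
        df = write_extraction_report([("t1", pars)], tmp_path / "report.csv")
        assert list(df.columns) == [
            "trace_id", "ct_s", "a5_mm", "mcf_mm", "li60_pct", "ml_pct", "breakdown_min",
        ]
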