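"""Reader PETHs, Monte-Carlo bands, and pair classification."""

import numpy as np
import pytest

import assemblyreaders as ar
from assemblyreaders.readers import (
    _null_peth_sums,
    classify_reader_pair,
    compute_peth,
    shuffle_bands,
)

from conftest import poisson_train


class TestComputePeth:
    def test_deterministic_reader_fills_one_bin(self):
        peaks = np.arange(10.0, 310.0, 3.0)  # windows never overlap
        reader = peaks + 0.020
        peth = compute_peth(reader, peaks)
        # +20 ms falls in the [20, 30) ms bin; count equals the trial count
        j = np.flatnonzero(peth.bin_starts_ms == 20.0)[0]
        assert peth.m[j] == peaks.size
        assert peth.m.sum() == peaks.size

    def test_thirty_spike_minimum(self):
        peaks = np.arange(10.0, 97.0, 3.0)  # 29 trials, one spike each
        reader = peaks + 0.02
        assert compute_peth(reader, peaks).excluded
        peaks = np.arange(10.0, 100.0, 3.0)  # 30 trials
        assert not compute_peth(peaks + 0.02, peaks).excluded

    def test_poisson_reader_flat(self):
        reader = poisson_train(20.0, 400.0, 3)
        peaks = np.sort(np.random.default_rng(4).uniform(2, 398, 300))
        peth = compute_peth(reader, peaks)
        expect = peth.m.mean()
        assert np.all(np.abs(peth.m - expect) < 5 * np.sqrt(expect))

    def test_zero_peaks_error(self):
        with pytest.raises(ValueError):
            compute_peth(np.array([1.0]), np.empty(0))


class TestShuffleBands:
    def test_null_preserves_trial_totals(self):
        rng = np.random.default_rng(0)
        M = rng.poisson(0.3, (40, 200)).astype(np.int64)
        tr, bi = np.nonzero(M)
        nnz = np.bincount(tr, minlength=40).astype(np.int64)
        null = _null_peth_sums(nnz, M[tr, bi].astype(np.int64), 200, 50, 7)
        assert np.all(null.sum(axis=1) == M.sum())

    def test_null_matches_numpy_permutation_distribution(self):
        # the partial Fisher-Yates kernel and full row permutation agree in
        # distribution: compare per-bin null means/sds on one matrix
        rng = np.random.default_rng(1)
        M = rng.poisson(0.5, (30, 50)).astype(np.int64)
        tr, bi = np.nonzero(M)
        nnz = np.bincount(tr, minlength=30).astype(np.int64)
        null = _null_peth_sums(nnz, M[tr, bi].astype(np.int64), 50, 2000, 9)
        ref = np.stack([
            np.take_along_axis(M, rng.permuted(
                np.tile(np.arange(50), (30, 1)), axis=1), axis=1).sum(axis=0)
            for _ in range(2000)
        ])
        assert np.allclose(null.mean(axis=0).mean(), ref.mean(axis=0).mean(),
                           rtol=0.02)
        assert np.allclose(null.std(axis=0).mean(), ref.std(axis=0).mean(),
                           rtol=0.1)

    def test_excluded_peth_rejected(self):
        peth = compute_peth(np.array([10.002]), np.array([10.0]))
        with pytest.raises(ValueError):
            shuffle_bands(peth)

    def test_deterministic_given_seed(self):
        reader = poisson_train(10.0, 200.0, 5)
        peaks = np.sort(np.random.default_rng(6).uniform(2, 198, 100))
        a = shuffle_bands(compute_peth(reader, peaks), seed=3)
        b = shuffle_bands(compute_peth(reader, peaks), seed=3)
        assert np.array_equal(a.pointwise_band, b.pointwise_band)
        assert a.global_band == b.global_band


class TestClassifyReaderPair:
    def test_planted_collective_reader_significant(self, planted_session,
                                                   first_assembly):
        reader = first_assembly["readers"]["collective"]
        rt = planted_session["spikes"].trains[reader]
        _, verdict = ar.test_pair(rt, first_assembly["events"].peaks, seed=2)
        assert verdict["significant"]
        assert 10.0 <= verdict["first_sig_delay_ms"] <= 30.0

    def test_reader_preceding_assembly_not_significant(self):
        peaks = np.arange(10.0, 400.0, 1.0)
        rng = np.random.default_rng(8)
        reader = np.sort(np.concatenate([
            peaks - 0.020,  # fires BEFORE the assembly
            rng.uniform(0, 400, 200),
        ]))
        _, verdict = ar.test_pair(reader, peaks, seed=1)
        assert not verdict["significant"]
        assert not verdict["crit_mode"]

    def test_invariant_to_spikes_outside_window(self, planted_session,
                                                first_assembly):
        reader = first_assembly["readers"]["collective"]
        rt = planted_session["spikes"].trains[reader]
        peaks = first_assembly["events"].peaks
        far = np.sort(np.concatenate([rt, peaks.max() + 100.0 + np.arange(50.0)]))
        _, v1 = ar.test_pair(rt, peaks, seed=2)
        _, v2 = ar.test_pair(far, peaks, seed=2)
        assert v1["significant"] == v2["significant"]
        assert v1["first_sig_delay_ms"] == v2["first_sig_delay_ms"]


class TestDelayProfile:
    def test_planted_delays_peak_in_response_window(self, planted_session,
                                                    detected):
        spikes = planted_session["spikes"]
        truth = planted_session["truth"]
        verdicts = []
        for pi, model in detected["by_planted"].items():
            ev = ar.activation_events(spikes, model, planted_session["epochs"])
            for r in truth.readers:
                if r["assembly"] == pi and r["mode"] == "collective":
                    _, v = ar.test_pair(spikes.trains[r["unit"]], ev.peaks,
                                        seed=pi)
                    verdicts.append(v)
        prof = ar.delay_profile(verdicts)
        assert prof["percent"].sum() <= 100.0 + 1e-9
        peak_delay = prof["delay_ms"][np.argmax(prof["percent"])]
        assert 10.0 <= peak_delay <= 30.0

    def test_no_testable_pairs_error(self):
        with pytest.raises(ValueError):
            ar.delay_profile([{"testable": False}])


class TestMemberCountResponseCurve:
    def test_collective_reader_response_increases_with_members(
        self, planted_session, first_assembly
    ):
        reader = first_assembly["readers"]["collective"]
        rt = planted_session["spikes"].trains[reader]
        curve = ar.member_count_response_curve(rt, first_assembly["events"])
        assert curve["testable"]
        assert curve["spearman_rho"] > 0
        means = curve["mean_response_hz"]
        assert means[-1] > means[0]

    def test_single_stratum_flagged(self):
        from assemblyreaders.activation import ActivationSeries

        ev = ActivationSeries(
            times=np.empty(0), strength=np.empty(0), window_ms=15.0,
            step_ms=1.0, peaks=np.arange(30.0) + 5.0,
            starts=np.arange(30.0) + 5.0, stops=np.arange(30.0) + 5.0,
            n_active=np.full(30, 3), recruited=[np.array([0, 1, 2])] * 30,
        )
        curve = ar.member_count_response_curve(poisson_train(5, 40, 1), ev)
        assert not curve["testable"]


class TestLeaveKOut:
    def test_collective_reader_survives_leave_one_out(
        self, planted_session, first_assembly
    ):
        reader = first_assembly["readers"]["collective"]
        spikes = planted_session["spikes"]
        res = ar.leave_k_out_response(
            spikes.trains[reader], spikes, first_assembly["model"].members,
            first_assembly["events"], k=1,
            duration_s=planted_session["epochs"].total_duration,
            min_events=10,  # short fixture: most events recruit everyone
        )
        assert res["testable"]
        assert res["response_hz"] > res["baseline_hz"]

    def test_single_driver_collapses_to_baseline(self):
        # reader driven solely by member 0's spikes; events without member 0
        # carry no excess response
        rng = np.random.default_rng(3)
        duration = 600.0
        m0 = poisson_train(2.0, duration, 10)
        trains = {0: m0, 1: poisson_train(2.0, duration, 11),
                  2: poisson_train(2.0, duration, 12)}
        reader_times = np.sort(np.concatenate([
            m0 + 0.02, rng.uniform(0, duration, 600)
        ]))
        spikes = ar.SpikeData(trains=trains, structure={u: "A" for u in trains})
        from assemblyreaders.activation import ActivationSeries

        with_m0 = np.sort(rng.choice(m0, 100, replace=False))
        without_m0 = np.sort(rng.uniform(1, duration - 1, 100))
        peaks = np.concatenate([with_m0, without_m0])
        order = np.argsort(peaks)
        recruited = [np.array([0])] * 100 + [np.array([1, 2])] * 100
        ev = ActivationSeries(
            times=np.empty(0), strength=np.empty(0), window_ms=15.0,
            step_ms=1.0, peaks=peaks[order], starts=peaks[order] - 0.005,
            stops=peaks[order] + 0.005,
            n_active=np.array([recruited[i].size for i in order]),
            recruited=[recruited[i] for i in order],
        )
        res = ar.leave_k_out_response(
            reader_times, spikes, np.array([0, 1, 2]), ev, k=1,
            duration_s=duration,
        )
        assert res["testable"]
        assert res["top_members"] == [0]
        assert res["response_hz"] < 2 * res["baseline_hz"]

    def test_k_exceeding_members_error(self, planted_session, first_assembly):
        with pytest.raises(ValueError):
            ar.leave_k_out_response(
                np.array([1.0]), planted_session["spikes"],
                first_assembly["model"].members, first_assembly["events"],
                k=len(first_assembly["model"].members),
            )


class TestSplitHalfResponseScore:
    def test_planted_coupling_scores_correlate(self, planted_session,
                                               first_assembly):
        reader = first_assembly["readers"]["collective"]
        rt = planted_session["spikes"].trains[reader]
        res = ar.split_half_response_score(rt, first_assembly["events"].peaks,
                                           seed=4)
        assert res["testable"]
        assert res["correlation"] > 0.5

    def test_null_pair_scores_uncorrelated(self):
        rng = np.random.default_rng(9)
        rs = []
        for i in range(10):
            reader = poisson_train(10.0, 500.0, 60 + i)
            peaks = np.sort(rng.uniform(2, 498, 300))
            res = ar.split_half_response_score(reader, peaks, seed=i)
            rs.append(res["correlation"])
        assert abs(np.median(rs)) < 0.3

    def test_deterministic(self, planted_session, first_assembly):
        reader = first_assembly["readers"]["collective"]
        rt = planted_session["spikes"].trains[reader]
        a = ar.split_half_response_score(rt, first_assembly["events"].peaks, seed=4)
        b = ar.split_half_response_score(rt, first_assembly["events"].peaks, seed=4)
        assert a["correlation"] == b["correlation"]
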