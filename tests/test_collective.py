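"""Linear readout, supralinearity, simulated readers and AB/AA events."""

import numpy as np
import pytest

import assemblyreaders as ar
from assemblyreaders.activation import ActivationSeries
from assemblyreaders.collective import supralinearity_zdiff

from conftest import poisson_train


def make_events(peaks, recruited, window_ms=15.0):
    peaks = np.asarray(peaks, float)
    return ActivationSeries(
        times=np.empty(0), strength=np.empty(0), window_ms=window_ms,
        step_ms=1.0, peaks=peaks, starts=peaks - 0.005, stops=peaks + 0.005,
        n_active=np.array([len(r) for r in recruited], int),
        recruited=[np.asarray(r, int) for r in recruited],
    )


@pytest.fixture(scope="module")
def readout_setup(planted_session, first_assembly):
    spikes = planted_session["spikes"]
    model = first_assembly["model"]
    events = first_assembly["events"]
    t_in, t_out = ar.split_member_triggers(spikes, model.members, events)
    return spikes, model, events, t_in, t_out


class TestFitLinearReadout:
    def test_uncoupled_reader_weights_near_zero(self, readout_setup):
        spikes, model, events, t_in, t_out = readout_setup
        reader = poisson_train(5.0, 600.0, 77)
        ro = ar.fit_linear_readout(reader, spikes, model.members, t_in, t_out,
                                   seed=0)
        j = np.argmin(np.abs(ro.delays_ms - 20.0))
        member_w = ro.W[j][1:]
        # intercept carries the baseline; member weights stay near zero
        assert np.all(np.abs(member_w) < 0.05)
        assert ro.W[j][0] > 0

    def test_copy_reader_puts_weight_on_its_member(self, readout_setup):
        spikes, model, events, t_in, t_out = readout_setup
        j_member = int(model.members[0])
        reader = spikes.trains[j_member] + 0.020
        ro = ar.fit_linear_readout(reader, spikes, model.members, t_in, t_out,
                                   seed=0)
        j = np.argmin(np.abs(ro.delays_ms - 20.0))
        w = ro.W[j][1:]
        assert np.argmax(np.abs(w)) == 0  # member order follows model.members
        assert w[0] > 5 * np.max(np.abs(w[1:]))

    def test_minimum_out_triggers_enforced(self, readout_setup):
        spikes, model, events, t_in, t_out = readout_setup
        with pytest.raises(ValueError, match="out-of-assembly"):
            ar.fit_linear_readout(np.array([1.0]), spikes, model.members,
                                  t_in, t_out[:50], seed=0)

    def test_eta_matches_normal_equations_oracle(self, readout_setup):
        spikes, model, events, t_in, t_out = readout_setup
        reader = poisson_train(8.0, 600.0, 78)
        rng = np.random.default_rng(0)
        t_out_small = np.sort(rng.choice(t_out, 300, replace=False))
        t_in_small = t_in[:100]
        ro = ar.fit_linear_readout(reader, spikes, model.members,
                                   t_in_small, t_out_small,
                                   delay_step_ms=250.0, seed=0)
        from assemblyreaders.collective import _design
        from assemblyreaders.readers import window_counts

        X = _design(spikes, model.members, t_out_small, 15.0)
        for j, d in enumerate(ro.delays_ms):
            y = window_counts(reader, t_out_small, d - 7.5, d + 7.5).astype(float)
            beta = np.linalg.pinv(X.T @ X) @ X.T @ y
            Xin = _design(spikes, model.members, t_in_small, 15.0)
            assert (Xin @ beta).mean() == pytest.approx(ro.eta[j], abs=1e-8)


class TestSupralinearityIndex:
    def test_zero_when_observed_equals_linear(self, readout_setup):
        spikes, model, events, t_in, t_out = readout_setup
        reader = poisson_train(5.0, 600.0, 79)
        ro = ar.fit_linear_readout(reader, spikes, model.members, t_in, t_out,
                                   seed=0)
        ro.r_in = ro.eta.copy()
        S = ar.supralinearity_index(ro)
        assert np.allclose(S, 0.0)

    def test_perfect_reader_supralinear_at_20ms(self, readout_setup):
        spikes, model, events, t_in, t_out = readout_setup
        reader = ar.simulate_perfect_reader(events, len(model.members))
        ro = ar.fit_linear_readout(reader, spikes, model.members, t_in, t_out,
                                   seed=0)
        S = ar.supralinearity_index(ro)
        assert ro.at(S, 20.0) > 0
        assert ro.at(S, 20.0) > ro.at(S, -500.0)
        assert supralinearity_zdiff(ro) > 0

    def test_independent_reader_near_zero(self, readout_setup):
        spikes, model, events, t_in, t_out = readout_setup
        reader = ar.simulate_independent_reader(spikes, model.members)
        ro = ar.fit_linear_readout(reader, spikes, model.members, t_in, t_out,
                                   seed=0)
        S = ar.supralinearity_index(ro)
        assert abs(ro.at(S, 20.0)) < 0.05

    def test_not_testable_when_eta20_nonpositive(self, readout_setup):
        spikes, model, events, t_in, t_out = readout_setup
        reader = poisson_train(5.0, 600.0, 80)
        ro = ar.fit_linear_readout(reader, spikes, model.members, t_in, t_out,
                                   seed=0)
        ro.eta = -np.abs(ro.eta)
        with pytest.raises(ValueError, match="not testable"):
            ar.supralinearity_index(ro)


class TestSimulatedReaders:
    def test_half_rule(self):
        ev = make_events(
            [10.0, 20.0, 30.0],
            [[0, 1], [0], [0, 1, 2, 3]],
        )
        out = ar.simulate_perfect_reader(ev, n_members=4)
        # recruiting 2 of 4 fires; 1 of 4 does not; 4 of 4 fires
        assert np.allclose(out, [10.02, 30.02])

    def test_large_assembly_uses_largest_observed_subset(self):
        # 10 members but at most 4 ever coactive: threshold is 2
        ev = make_events(
            [10.0, 20.0, 30.0],
            [[0, 1], [0], [0, 1, 2, 3]],
        )
        out = ar.simulate_perfect_reader(ev, n_members=10)
        assert np.allclose(out, [10.02, 30.02])

    def test_independent_reader_is_shifted_copy(self, planted_session,
                                                first_assembly):
        spikes = planted_session["spikes"]
        members = first_assembly["model"].members
        out = ar.simulate_independent_reader(spikes, members)
        pooled = spikes.pooled(members)
        assert out.size == pooled.size
        assert np.allclose(out - pooled, 0.020)


class TestFindAbAaEvents:
    def test_aa_event_midpoint(self):
        ev = ar.find_ab_aa_events(np.array([0.0, 0.010]), np.empty(0))
        assert ev["aa_mid"].tolist() == [0.005]
        assert ev["ab_mid"].size == 0

    def test_ab_event_midpoint(self):
        ev = ar.find_ab_aa_events(np.array([0.0]), np.array([0.012]),
                                  timescale_ms=15.0)
        assert ev["ab_mid"].tolist() == [0.006]
        assert ev["ab_delay_ms"].tolist() == [12.0]

    def test_intervening_spike_rejects_pair(self):
        # A at 0 and 8 ms, B at 12 ms: the A(8)-B(12) pair survives (nothing
        # between them) but A(0)-B(12) is not a pair (A(8) intervenes)
        ev = ar.find_ab_aa_events(np.array([0.0, 0.008]), np.array([0.012]))
        assert ev["ab_delay_ms"].tolist() == [4.0]
        assert ev["aa_delay_ms"].tolist() == [8.0]

    def test_other_member_exclusion(self):
        ev = ar.find_ab_aa_events(
            np.array([0.0]), np.array([0.012]),
            other_times=np.array([0.014]),
        )
        assert ev["ab_mid"].size == 0


class TestAbAaResponse:
    def test_identical_event_sets_zero_difference(self):
        reader = poisson_train(10.0, 200.0, 81)
        mids = np.sort(np.random.default_rng(5).uniform(2, 198, 40))
        res = ar.ab_aa_response(reader, mids, mids)
        assert np.allclose(res.difference, 0.0)

    def test_minimum_event_counts(self):
        reader = poisson_train(10.0, 100.0, 82)
        with pytest.raises(ValueError, match="at least"):
            ar.ab_aa_response(reader, np.arange(10.0), np.arange(25.0))

    def test_coincidence_vs_rate_reader_dissociation(self, planted_session,
                                                     first_assembly):
        spikes = planted_session["spikes"]
        truth = planted_session["truth"]
        members = truth.members[0]
        # pool isolated AB/AA pairs over member-pair permutations
        ab, aa = [], []
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                others = spikes.pooled(
                    [m for k, m in enumerate(members) if k not in (i, j)]
                )
                ev = ar.find_ab_aa_events(
                    spikes.trains[members[i]], spikes.trains[members[j]],
                    other_times=others,
                )
                ab.append(ev["ab_mid"])
                aa.append(ev["aa_mid"])
        ab = np.sort(np.concatenate(ab))
        aa = np.sort(np.concatenate(aa))
        assert ab.size >= 20 and aa.size >= 20
        co = first_assembly["readers"]["coincidence"]
        rate = first_assembly["readers"]["independent"]
        d_co = ar.ab_aa_response(spikes.trains[co], ab, aa)
        d_rate = ar.ab_aa_response(spikes.trains[rate], ab, aa)
        assert d_co.difference_at(20.0) > 1.0
        assert abs(d_rate.difference_at(20.0)) < 1.0


class TestTimescaleScan:
    def test_collective_structure_specific_to_planted_scale(
        self, planted_session, first_assembly
    ):
        spikes = planted_session["spikes"]
        epochs = planted_session["epochs"]
        reader = ar.simulate_perfect_reader(
            first_assembly["events"], len(first_assembly["model"].members)
        )
        scan = ar.timescale_scan(spikes, epochs, reader,
                                 scales_ms=(15.0, 50.0), seed=3)
        assert scan[15.0]["testable"]
        z15 = scan[15.0]["zdiff_20ms"]
        assert z15 > 0
        if scan[50.0]["testable"]:
            assert scan[50.0]["zdiff_20ms"] < 0.5 * z15
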