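"""Assembly detection: eigenvalue bound, Otsu membership, ICA recovery,
controls and cross-validation."""

import copy

import numpy as np
import pytest

import assemblyreaders as ar
from assemblyreaders.detect import detect_assemblies, otsu_members

from conftest import poisson_train


class TestMarcenkoPasturBound:
    @pytest.mark.parametrize(
        "n_units,n_bins,expected",
        [(100, 10000, 1.21), (1, 10000, 1.0201)],
    )
    def test_closed_form(self, n_units, n_bins, expected):
        assert ar.marcenko_pastur_bound(n_units, n_bins) == pytest.approx(expected)

    def test_invalid_regime(self):
        with pytest.raises(ValueError):
            ar.marcenko_pastur_bound(100, 100)

    def test_white_noise_rarely_exceeds_bound(self):
        # eigenvalues of pure-noise correlation matrices stay below the bound
        rng = np.random.default_rng(0)
        n_units, n_bins = 30, 3000
        bound = ar.marcenko_pastur_bound(n_units, n_bins)
        n_exceed = 0
        for _ in range(200):
            X = rng.standard_normal((n_units, n_bins))
            ev = np.linalg.eigvalsh(np.corrcoef(X))
            n_exceed += int(np.any(ev > bound))
        assert n_exceed / 200 <= 0.05


class TestOtsuMembers:
    def test_bimodal_example_selects_top_group(self):
        thr, members, eff = otsu_members(np.array([0.9, 0.8, 0.05, 0.04, 0.03]))
        assert sorted(members.tolist()) == [0, 1]
        assert 0.05 < thr < 0.8

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            w = np.abs(rng.standard_normal(rng.integers(4, 20)))
            if np.ptp(w) == 0:
                continue
            thr, members, eff = otsu_members(w)
            # oracle: try every split of the sorted values
            ws = np.sort(w)
            best_inter, best_k = -1.0, None
            for k in range(1, ws.size):
                if ws[k] == ws[k - 1]:
                    continue
                lo, hi = ws[:k], ws[k:]
                p = k / ws.size
                inter = p * (1 - p) * (lo.mean() - hi.mean()) ** 2
                if inter > best_inter:
                    best_inter, best_k = inter, k
            assert members.size == ws.size - best_k
            assert eff == pytest.approx(best_inter / np.var(w))
            assert 0.0 <= eff <= 1.0

    def test_perfectly_bimodal_effectiveness_near_one(self):
        w = np.array([0.7] * 4 + [0.01] * 8)
        _, members, eff = otsu_members(w)
        assert members.size == 4
        assert eff > 0.99

    def test_no_separation_error(self):
        with pytest.raises(ValueError, match="no separation"):
            otsu_members(np.full(5, 0.3))


class TestDetectAssemblies:
    def test_recovers_planted_member_sets(self, planted_session, detected):
        truth = planted_session["truth"]
        assert len(detected["by_planted"]) == len(truth.members)

    def test_weight_invariants(self, detected):
        for m in detected["models"]:
            assert np.linalg.norm(m.weights) == pytest.approx(1.0, abs=1e-8)
            assert m.weights[np.argmax(np.abs(m.weights))] > 0
            # members reproduce exactly from (weights, otsu_threshold)
            rebuilt = m.unit_index[np.abs(m.weights) > m.otsu_threshold]
            assert set(rebuilt.tolist()) == set(m.members.tolist())

    def test_independent_poisson_yields_no_assemblies(self):
        n_hits = 0
        for seed in range(10):
            spikes = ar.SpikeData(
                trains={u: poisson_train(2.0, 300.0, 100 * seed + u)
                        for u in range(20)},
                structure={u: "A" for u in range(20)},
            )
            models = ar.detect(spikes, ar.IntervalSet([[0.0, 300.0]]), seed=seed)
            n_hits += bool(models)
        assert n_hits <= 1  # >=95% of null runs come up empty

    def test_two_disjoint_assemblies_match_planted_vectors(self, planted_session, detected):
        truth = planted_session["truth"]
        for pi, model in detected["by_planted"].items():
            v = np.zeros(model.unit_index.size)
            v[np.isin(model.unit_index, truth.members[pi])] = 1.0
            v /= np.linalg.norm(v)
            assert abs(v @ model.weights) > 0.8

    def test_requires_zscored_matrix(self, planted_session):
        spikes = planted_session["spikes"]
        Z = ar.bin_and_zscore(spikes.subset(spikes.units_in("A")),
                              planted_session["epochs"], zscore=False)
        with pytest.raises(ValueError, match="z-scored"):
            detect_assemblies(Z)


class TestFilterMixedSign:
    def test_sign_partition(self, detected):
        m = copy.deepcopy(detected["models"][0])
        kept, discarded = ar.filter_mixed_sign([m])
        assert kept and not discarded
        bad = copy.deepcopy(m)
        bad.sign_valid = False
        kept, discarded = ar.filter_mixed_sign([m, bad])
        assert len(kept) == 1 and len(discarded) == 1


class TestShuffleSpikeIdentities:
    def test_per_unit_counts_and_pooled_times_preserved(self, planted_session):
        spikes = planted_session["spikes"]
        A = spikes.subset(spikes.units_in("A"))
        sh = ar.shuffle_spike_identities(A, seed=3)
        for u in A.trains:
            assert sh.trains[u].size == A.trains[u].size
        assert np.allclose(sh.pooled(), A.pooled())

    def test_shuffling_reduces_detection_count(self, planted_session, detected):
        spikes = planted_session["spikes"]
        A = spikes.subset(spikes.units_in("A"))
        epochs = planted_session["epochs"]
        truth = planted_session["truth"]
        planted_sets = [set(m) for m in truth.members]
        counts = []
        for seed in range(5):
            models_sh = ar.detect(
                ar.shuffle_spike_identities(A, seed=seed), epochs, seed=401
            )
            counts.append(len(models_sh))
            for m in models_sh:
                assert set(int(u) for u in m.members) not in planted_sets
        assert max(counts) <= len(detected["models"])


class TestSplitHalfCrossvalidate:
    def test_planted_assemblies_match_across_halves(self, planted_session):
        spikes = planted_session["spikes"]
        A = spikes.subset(spikes.units_in("A"))
        rep = ar.split_half_crossvalidate(A, planted_session["epochs"], seed=8)
        assert rep["frac_matched"] >= 0.9
        assert all(p["significant"] for p in rep["pairs"])

    def test_null_data_yields_no_matches(self):
        spikes = ar.SpikeData(
            trains={u: poisson_train(2.0, 600.0, 300 + u) for u in range(15)},
            structure={u: "A" for u in range(15)},
        )
        rep = ar.split_half_crossvalidate(
            spikes, ar.IntervalSet([[0.0, 600.0]]), seed=1
        )
        assert rep["n_matched"] <= 1

    def test_matching_is_symmetric(self, detected):
        a, b = detected["models"][:2], detected["models"][:3]
        fw = {(i, j) for i, j, _ in ar.match_assemblies(a, b)}
        bw = {(j, i) for i, j, _ in ar.match_assemblies(b, a)}
        assert fw == bw


@pytest.fixture(scope="module")
def dense_session():
    # denser regime: the median-error gain statistic needs busy units
    cfg = ar.default_config(
        seed=5, duration_s=900.0, n_assemblies=1, members_per_assembly=10,
        n_units_a=20, n_units_b=4, reader_modes=(),
        rate_log_mean=float(np.log(6.0)), rate_log_sd=0.1,
    )
    cfg.assemblies[0].incidence_hz = 3.0
    spikes, epochs, truth = ar.generate_session(cfg)
    A = spikes.subset(spikes.units_in("A"))
    Z = ar.bin_and_zscore(A, epochs)
    models = ar.detect(A, epochs, seed=5)
    model = next(
        m for m in models
        if set(int(u) for u in m.members) == set(truth.members[0])
    )
    return Z, model


class TestPeerPrediction:
    def test_planted_members_have_positive_median_gain(self, dense_session):
        Z, model = dense_session
        g = ar.peer_prediction_gain(Z, model, seed=1)
        assert np.median(g) > 0

    def test_pseudo_member_gain_near_zero(self, dense_session):
        Z, model = dense_session
        fake = copy.deepcopy(model)
        fake.members = np.array(list(model.members[:-1]) + [19])
        g = ar.peer_prediction_gain(Z, fake, seed=1)
        assert abs(g[-1]) < 0.01

    def test_too_few_members_error(self, dense_session):
        Z, model = dense_session
        lone = copy.deepcopy(model)
        lone.members = model.members[:1]
        with pytest.raises(ValueError):
            ar.peer_prediction_gain(Z, lone)


class TestMemberSynchronyCCG:
    def test_identical_trains_peak_at_zero_lag(self):
        t = poisson_train(5.0, 120.0, 9)
        spikes = ar.SpikeData(trains={0: t, 1: t.copy()},
                              structure={0: "A", 1: "A"})
        model = ar.AssemblyModel(
            weights=np.array([0.7, 0.7]) / np.hypot(0.7, 0.7),
            unit_index=np.array([0, 1]), members=np.array([0, 1]),
            otsu_threshold=0.1, effectiveness=1.0, timescale_ms=15.0,
            sign_valid=True,
        )
        out = ar.member_synchrony_ccg(spikes, model)
        assert out["members"][(0, 1)]["mode_ms"] == pytest.approx(0.0, abs=2.6)

    def test_independent_pair_flat(self):
        spikes = ar.SpikeData(
            trains={0: poisson_train(5.0, 300.0, 1),
                    1: poisson_train(5.0, 300.0, 2)},
            structure={0: "A", 1: "A"},
        )
        model = ar.AssemblyModel(
            weights=np.array([0.7, 0.7]) / np.hypot(0.7, 0.7),
            unit_index=np.array([0, 1]), members=np.array([0, 1]),
            otsu_threshold=0.1, effectiveness=1.0, timescale_ms=15.0,
            sign_valid=True,
        )
        out = ar.member_synchrony_ccg(spikes, model)
        z = out["members"][(0, 1)]["z"]
        assert np.mean(np.abs(z) < 3) > 0.95

    def test_planted_members_peak_within_timescale(self, planted_session,
                                                   first_assembly):
        spikes = planted_session["spikes"]
        model = first_assembly["model"]
        nonmembers = [u for u in spikes.units_in("A")
                      if u not in set(model.members)][:3]
        controls = [(int(model.members[0]), int(u)) for u in nonmembers]
        out = ar.member_synchrony_ccg(spikes, model, control_pairs=controls)
        modes = np.array([abs(v["mode_ms"]) for v in out["members"].values()])
        assert np.median(modes) <= model.timescale_ms

    def test_serialization_roundtrip(self, detected, tmp_path):
        ar.detect.__module__  # namespace guard
        from assemblyreaders.detect import load_assemblies, save_assemblies
        save_assemblies(detected["models"], tmp_path / "a.json")
        back = load_assemblies(tmp_path / "a.json")
        for a, b in zip(detected["models"], back):
            assert np.allclose(a.weights, b.weights)
            assert set(a.members.tolist()) == set(b.members.tolist())
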