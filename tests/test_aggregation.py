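"""DNT admission, weighted/hierarchical averaging, federated rounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedlung.aggregation import (
    RoundState,
    ThresholdPolicy,
    ValidationMatrix,
    ValidationScore,
    client_validation_score,
    dnt_admit,
    hierarchical_aggregate,
    round_client_seed,
    run_federation,
    run_round,
    train_centralized,
    weighted_average,
)
from fedlung.model import (
    Architecture,
    ModelParameters,
    TrainingConfig,
    init_params,
    train_local,
)
from fedlung.topology import build_topology

ARCH = Architecture()


def _score_map(values):
    return {i: ValidationScore(v_pa=v, v_pd=v) for i, v in enumerate(values)}


class TestValidationScore:
    def test_combined_is_mean(self):
        s = ValidationScore(v_pa=0.8, v_pd=0.4)
        assert s.v == pytest.approx(0.6)

    def test_majority_model_scores_one_third(self, setup5):
        calib_x, calib_y = setup5.calibration_set
        # zero parameters predict the first class everywhere (tie-break)
        params = ModelParameters(flat=np.zeros(ARCH.n_params), arch=ARCH)
        frac0 = np.mean(calib_y == 0)
        s = client_validation_score(params, calib_x, calib_y)
        assert s.v_pa == pytest.approx(frac0)
        assert s.v_pd == pytest.approx(frac0)
        assert s.v == pytest.approx(frac0)

    def test_combined_mean_for_random_models(self, setup5):
        calib_x, calib_y = setup5.calibration_set
        rng = np.random.default_rng(4)
        for _ in range(500):
            params = ModelParameters(flat=rng.normal(size=ARCH.n_params), arch=ARCH)
            s = client_validation_score(params, calib_x, calib_y)
            assert s.v == (s.v_pa + s.v_pd) / 2

    def test_empty_calibration_rejected(self):
        params = init_params(ARCH, 0)
        with pytest.raises(ValueError):
            client_validation_score(params, np.zeros((0, 8)), np.zeros(0, int))


class TestValidationMatrix:
    def test_append_rows(self):
        m = ValidationMatrix()
        m.append(0, _score_map([0.5, 0.6]))
        m.append(1, _score_map([0.7]))
        assert len(m) == 2

    def test_duplicate_round_rejected(self):
        m = ValidationMatrix()
        m.append(0, _score_map([0.5]))
        with pytest.raises(ValueError):
            m.append(0, _score_map([0.5]))

    def test_missing_client_is_absent_not_zero(self):
        m = ValidationMatrix()
        m.append(0, {0: ValidationScore(0.5, 0.5)})
        m.append(1, {1: ValidationScore(0.7, 0.7)})
        df = m.to_frame()
        assert np.isnan(df.loc[1, "client_0"])
        assert df.loc[0, "client_0"] == 0.5


class TestDntAdmit:
    def test_absolute_cutoff(self):
        admitted, fb = dnt_admit(_score_map([0.9, 0.8, 0.2]),
                                 ThresholdPolicy("absolute", tau=0.5))
        assert admitted == {0, 1} and not fb

    def test_off_admits_all(self):
        admitted, fb = dnt_admit(_score_map([0.1, 0.2, 0.3]), ThresholdPolicy("off"))
        assert admitted == {0, 1, 2} and not fb

    def test_equal_scores_robust_admits_all(self):
        admitted, fb = dnt_admit(_score_map([0.4] * 5),
                                 ThresholdPolicy("robust", z=3.0))
        assert admitted == set(range(5)) and not fb

    def test_empty_admission_falls_back_to_best(self):
        admitted, fb = dnt_admit(_score_map([0.1, 0.3, 0.2]),
                                 ThresholdPolicy("absolute", tau=0.9))
        assert admitted == {1} and fb

    @given(
        vals=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        tau1=st.floats(0.0, 1.0),
        tau2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_absolute_monotone_in_tau(self, vals, tau1, tau2):
        lo, hi = sorted((tau1, tau2))
        scores = _score_map(vals)
        a_lo, _ = dnt_admit(scores, ThresholdPolicy("absolute", tau=lo))
        a_hi, _ = dnt_admit(scores, ThresholdPolicy("absolute", tau=hi))
        assert a_hi <= a_lo


class TestWeightedAverage:
    def test_single_model_identity(self):
        p = init_params(ARCH, 0)
        out = weighted_average([p], [3.7])
        assert np.array_equal(out.flat, p.flat)

    def test_midpoint(self):
        z = ModelParameters(flat=np.zeros(ARCH.n_params), arch=ARCH)
        o = ModelParameters(flat=np.ones(ARCH.n_params), arch=ARCH)
        out = weighted_average([z, o], [1.0, 1.0])
        assert np.allclose(out.flat, 0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        models = [ModelParameters(flat=rng.normal(size=ARCH.n_params), arch=ARCH)
                  for _ in range(7)]
        w = rng.uniform(0.1, 2.0, size=7)
        out = weighted_average(models, w)
        # independently coded sum(w*x)/sum(w)
        expect = np.zeros(ARCH.n_params)
        for m, wi in zip(models, w):
            expect += wi * m.flat
        expect /= w.sum()
        assert np.allclose(out.flat, expect, atol=1e-12)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(8)
        models = [ModelParameters(flat=rng.normal(size=ARCH.n_params), arch=ARCH)
                  for _ in range(4)]
        w = rng.uniform(0.1, 1.0, size=4)
        scaled = [ModelParameters(flat=2.5 * m.flat, arch=ARCH) for m in models]
        assert np.allclose(
            weighted_average(scaled, w).flat,
            2.5 * weighted_average(models, w).flat,
            atol=1e-12,
        )

    def test_zero_weights_rejected(self):
        p = init_params(ARCH, 0)
        with pytest.raises(ValueError):
            weighted_average([p, p], [0.0, 0.0])

    def test_architecture_mismatch_rejected(self):
        a = init_params(ARCH, 0)
        b = init_params(Architecture(hidden_layers=(8,)), 0)
        with pytest.raises(ValueError):
            weighted_average([a, b], [1.0, 1.0])


class TestHierarchicalAggregate:
    def _random_instance(self, rng):
        n = int(rng.integers(2, 12))
        k = int(rng.integers(1, n + 1))
        topo = build_topology(n, k)
        params = {i: ModelParameters(flat=rng.normal(size=ARCH.n_params), arch=ARCH)
                  for i in range(n)}
        weights = {i: float(rng.integers(1, 20)) for i in range(n)}
        return topo, params, weights

    def test_single_router_equals_flat(self):
        rng = np.random.default_rng(9)
        topo, params, weights = build_topology(4, 1), {}, {}
        params = {i: ModelParameters(flat=rng.normal(size=ARCH.n_params), arch=ARCH)
                  for i in range(4)}
        weights = {i: float(i + 1) for i in range(4)}
        h = hierarchical_aggregate(topo, params, weights, range(4))
        f = weighted_average([params[i] for i in range(4)],
                             [weights[i] for i in range(4)])
        assert np.allclose(h.flat, f.flat, atol=1e-12)

    def test_full_admission_equals_flat_mean_random_topologies(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            topo, params, weights = self._random_instance(rng)
            n = topo.n_clients
            h = hierarchical_aggregate(topo, params, weights, range(n))
            f = weighted_average([params[i] for i in range(n)],
                                 [weights[i] for i in range(n)])
            assert np.allclose(h.flat, f.flat, atol=1e-10)

    def test_router_without_admitted_clients_is_skipped(self):
        rng = np.random.default_rng(11)
        topo = build_topology(4, 2)  # routers {0,2} and {1,3}
        params = {i: ModelParameters(flat=rng.normal(size=ARCH.n_params), arch=ARCH)
                  for i in range(4)}
        weights = {i: 1.0 for i in range(4)}
        h = hierarchical_aggregate(topo, params, weights, {1, 3})
        f = weighted_average([params[1], params[3]], [1.0, 1.0])
        assert np.allclose(h.flat, f.flat, atol=1e-12)

    def test_nothing_admitted_rejected(self):
        topo = build_topology(2, 1)
        params = {i: init_params(ARCH, i) for i in range(2)}
        with pytest.raises(ValueError):
            hierarchical_aggregate(topo, params, {0: 1.0, 1: 1.0}, set())


class TestRounds:
    def test_single_client_round_is_plain_local_training(self, setup5):
        x, y = setup5.shards[0]
        topo = build_topology(1, 1)
        cfg = TrainingConfig(epochs=5, learning_rate=0.1, batch_size=16, seed=3)
        state = RoundState(0, init_params(ARCH, 0))
        out = run_round(state, topo, {0: (x, y)}, cfg, ThresholdPolicy("off"),
                        setup5.calibration_set)
        local_cfg = TrainingConfig(epochs=5, learning_rate=0.1, batch_size=16,
                                   seed=round_client_seed(3, 0, 0))
        expect = train_local(init_params(ARCH, 0), x, y, local_cfg)
        assert np.array_equal(out.global_params.flat, expect.flat)

    def test_identical_shards_aggregate_to_single_client(self, setup5):
        x, y = setup5.shards[0]
        topo = build_topology(4, 2)
        shards = {i: (x, y) for i in range(4)}
        # full-batch: the shuffle order cannot differentiate the clients
        cfg = TrainingConfig(epochs=10, learning_rate=0.05, batch_size=10_000, seed=5)
        state = RoundState(0, init_params(ARCH, 1))
        out = run_round(state, topo, shards, cfg, ThresholdPolicy("off"),
                        setup5.calibration_set)
        local_cfg = TrainingConfig(epochs=10, learning_rate=0.05,
                                   batch_size=10_000, seed=round_client_seed(5, 0, 0))
        single = train_local(init_params(ARCH, 1), x, y, local_cfg)
        assert np.allclose(out.global_params.flat, single.flat, atol=1e-10)

    def test_federation_deterministic(self, setup5):
        cfg = TrainingConfig(epochs=3, learning_rate=0.1, batch_size=16, seed=2)
        args = (setup5.topology, setup5.shards, setup5.calibration_set,
                setup5.test_set, 3, cfg, ThresholdPolicy("off"), 0, setup5.scaler)
        a = run_federation(*args)
        b = run_federation(*args)
        assert np.array_equal(a.final_params.flat, b.final_params.flat)
        assert a.round_log == b.round_log

    def test_one_round_one_client_equals_centralized(self, setup5):
        x, y = setup5.pooled_train
        topo = build_topology(1, 1)
        cfg = TrainingConfig(epochs=5, learning_rate=0.1, batch_size=16, seed=4)
        fed = run_federation(topo, {0: (x, y)}, setup5.calibration_set,
                             setup5.test_set, 1, cfg, ThresholdPolicy("off"),
                             init_seed=6, scaler=setup5.scaler)
        central = train_centralized(x, y, 1, cfg, init_seed=6)
        assert np.array_equal(fed.final_params.flat, central.flat)

    def test_off_policy_admits_everyone_each_round(self, setup5):
        cfg = TrainingConfig(epochs=2, learning_rate=0.1, batch_size=16, seed=1)
        fed = run_federation(setup5.topology, setup5.shards, setup5.calibration_set,
                             setup5.test_set, 2, cfg, ThresholdPolicy("off"), 0,
                             setup5.scaler)
        for entry in fed.round_log:
            assert entry["admitted"] == sorted(setup5.shards)
            assert not entry["fallback"]
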