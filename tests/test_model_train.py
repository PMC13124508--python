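"""End-to-end model wiring, training protocol, robustness harness."""

import numpy as np
import pytest

from imtscast.core import (IMTSEpisode, IrregularSeries, Observation, Query,
                           apply_standardizer, fit_standardizer,
                           split_episodes)
from imtscast.model import Forecaster, ModelConfig, collate, prepare_episode
from imtscast.synthetic import default_config, generate_cohort
from imtscast.train import (TrainingConfig, evaluate_model, fit_forecaster,
                            run_robustness)

TOY = ModelConfig.small(scales=(1.0, 2.0, 4.0), window_end=4.0, horizon=4.0,
                        d_time=4, d_freq=8, d_fused=8, d_model=8, d_ff=16,
                        d_hidden=4, d_time_embed=4, d_fourier=4, d_graph=3,
                        seed=0)


def toy_cohort(n=12, seed=0, n_variables=3):
    cfg = default_config(
        seed=seed, n_variables=n_variables, n_episodes=n, window_end=4.0,
        horizon=4.0, sampling_rates=(3.0,) * n_variables,
        coupling=((0, 2, 1.0),), frequencies=((0.25,),) * n_variables,
        amplitudes=((1.0,),) * n_variables, n_queries_per_variable=3)
    return generate_cohort(cfg)


def _wake(model):
    """Give the zero-initialized output projection generic weights so an
    untrained model's predictions respond to its inputs."""
    r = np.random.default_rng(1234)
    model.head.W_out.data = r.normal(0, 0.3, model.head.W_out.shape)
    return model


@pytest.fixture(scope="module")
def toy():
    eps, gt = toy_cohort()
    model = _wake(Forecaster(TOY, np.linspace(0.1, 1.0, 4)))
    return eps, gt, model


def test_eval_forward_deterministic(toy):
    eps, _, model = toy
    a = model.forward_episode(eps[0]).predictions.data
    b = model.forward_episode(eps[0]).predictions.data
    np.testing.assert_array_equal(a, b)


def test_batched_equals_single_episode(toy):
    eps, _, model = toy
    batch = collate(model.prepare(eps[:3]))
    merged = model.forward_batch(batch).predictions.data
    singles = np.concatenate([model.forward_episode(e).predictions.data
                              for e in eps[:3]])
    np.testing.assert_allclose(merged, singles, atol=1e-9)


def test_padding_invariance(toy):
    """Collating with episodes of different density never changes outputs."""
    eps, _, model = toy
    dense, _ = toy_cohort(n=1, seed=99)
    ref = model.forward_episode(eps[0]).predictions.data
    mixed = collate(model.prepare([eps[0], dense[0]]))
    out = model.forward_batch(mixed)
    np.testing.assert_allclose(out.predictions.data[:len(ref)], ref,
                               atol=1e-9)


def test_no_graph_restores_variable_independence():
    """Editing one variable's data leaves other variables' forecasts
    untouched when the graph stage is ablated."""
    eps, _ = toy_cohort(n=2, seed=5)
    cfg = ModelConfig.from_dict({**TOY.to_dict(), "no_graph": True})
    model = _wake(Forecaster(cfg, np.linspace(0.1, 1.0, 4)))
    ep = eps[0]
    ref = model.forward_episode(ep)
    # perturb variable 1's observations drastically
    new_series = list(ep.series)
    s = new_series[0]
    new_series[0] = IrregularSeries(
        s.variable_id,
        tuple(Observation(o.time, o.value + 50.0) for o in s.observations))
    ep2 = IMTSEpisode(ep.episode_id, tuple(new_series), ep.window_end,
                      ep.horizon, ep.queries)
    out = model.forward_episode(ep2)
    other = ref.variable_index != 0
    np.testing.assert_allclose(out.predictions.data[other],
                               ref.predictions.data[other], atol=1e-9)
    assert not np.allclose(out.predictions.data[~other],
                           ref.predictions.data[~other])


def test_complete_model_couples_variables(toy):
    eps, _, model = toy
    ep = eps[0]
    ref = model.forward_episode(ep)
    new_series = list(ep.series)
    s = new_series[0]
    new_series[0] = IrregularSeries(
        s.variable_id,
        tuple(Observation(o.time, o.value + 50.0) for o in s.observations))
    ep2 = IMTSEpisode(ep.episode_id, tuple(new_series), ep.window_end,
                      ep.horizon, ep.queries)
    out = model.forward_episode(ep2)
    other = ref.variable_index != 0
    assert not np.allclose(out.predictions.data[other],
                           ref.predictions.data[other])


def test_full_forward_matches_hand_trace():
    """Step-by-step recomputation of the pipeline on a 2-variable toy."""
    from scipy.stats import norm
    from imtscast.patching import PatchSpec, build_patch_grid
    from imtscast.graph import lomb_scargle_power

    def gelu_np(x):
        return x * norm.cdf(x)

    cfg = ModelConfig.small(
        scales=(2.0,), window_end=4.0, horizon=2.0, d_time=3, d_freq=8,
        d_fused=5, d_model=6, d_ff=8, d_hidden=3, d_time_embed=3,
        d_fourier=2, d_graph=2, n_ifan_layers=1, seed=7)
    probe = np.array([0.2, 0.4])
    model = _wake(Forecaster(cfg, probe))
    series = (IrregularSeries(1, (Observation(0.5, 1.0),
                                  Observation(3.0, -1.0),
                                  Observation(3.5, 0.5))),
              IrregularSeries(2, (Observation(1.0, 2.0),)))
    ep = IMTSEpisode("t", series, 4.0, 2.0,
                     (Query(1, 5.0, 0.3), Query(2, 6.0, -0.2)))
    got = model.forward_episode(ep).predictions.data

    # ---- independent trace with plain numpy ----
    enc = model.encoder
    omega, alpha = enc.time_embedding.omega.data, enc.time_embedding.alpha.data

    def phi(t):
        ang = t * omega + alpha
        return np.concatenate([[ang[0]], np.sin(ang[1:])])

    def ttcn(ts, vs):
        z = np.stack([np.concatenate([phi(t), [v]])
                      for t, v in zip(ts, vs)])
        out = np.zeros(cfg.d_time)
        for k in range(cfg.d_time):
            W1 = enc.ttcn.W1.data[k]
            b1 = enc.ttcn.b1.data[k, 0, 0]
            W2 = enc.ttcn.W2.data[k]
            b2 = enc.ttcn.b2.data[k, 0, 0]
            s = np.stack([W2.T @ gelu_np(W1.T @ zz + b1) + b2 for zz in z])
            e = np.exp(s - s.max(axis=0, keepdims=True))
            f = e / e.sum(axis=0, keepdims=True)
            out[k] = np.sum(f * z)
        return out

    def ifan(ts, vs):
        lay = enc.ifan.layers[0]
        feats = []
        for t, v in zip(ts, vs):
            u = lay["Wp"].data[0] * v + lay["Up"].data * t
            g = gelu_np(lay["Bpbar"].data + lay["Wpbar"].data[0] * v
                        + lay["Vpbar"].data * t)
            feats.append(np.concatenate([np.cos(u), np.sin(u), g]))
        return np.mean(feats, axis=0)

    spec = PatchSpec(scales=(2.0,), window_end=4.0)
    grid = build_patch_grid(ep, spec)
    h = np.zeros((2, 2, cfg.d_fused))
    for i in range(2):
        for p in (1, 2):
            patch = grid.patch(i, 0, p)
            if len(patch) == 0:
                h[i, p - 1] = enc.empty_tokens.data[0]
            else:
                ht = ttcn(patch.rescaled_times, patch.values)
                hf = ifan(patch.rescaled_times, patch.values)
                h[i, p - 1] = np.concatenate([ht, hf]) \
                    @ enc.fusion.W.data + enc.fusion.b.data
    # scale fusion (S = 1)
    m = gelu_np(h @ model.scale_fusion.W.data + model.scale_fusion.b.data)
    # transformer (pre-norm, 1 layer, 1 head)
    from imtscast.fusion import sinusoidal_positions
    lay = model.transformer.layers[0]
    x = m + sinusoidal_positions(2, cfg.d_model)

    def layernorm(v, g, b):
        mu, var = v.mean(-1, keepdims=True), v.var(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + 1e-5) * g + b

    for i in range(2):
        hn = layernorm(x[i], lay["ln1_g"].data, lay["ln1_b"].data)
        q, k, v = hn @ lay["Wq"].data, hn @ lay["Wk"].data, hn @ lay["Wv"].data
        sc = q @ k.T / np.sqrt(cfg.d_model)
        at = np.exp(sc - sc.max(-1, keepdims=True))
        at /= at.sum(-1, keepdims=True)
        x[i] = x[i] + (at @ v) @ lay["Wo"].data
        hn = layernorm(x[i], lay["ln2_g"].data, lay["ln2_b"].data)
        x[i] = x[i] + gelu_np(hn @ lay["W_ff1"].data + lay["b_ff1"].data) \
            @ lay["W_ff2"].data + lay["b_ff2"].data
    # spectral features over the coarsest (only) scale patch covering k
    f = np.zeros((2, 2, 2))
    for i in range(2):
        for kk in (1, 2):
            patch = grid.patch(i, 0, kk)
            if len(patch) >= 3:
                f[i, kk - 1] = lomb_scargle_power(patch.times, patch.values,
                                                  probe)
    # dynamic graph + GCN per interval
    mbar = np.zeros_like(x)
    for kk in range(2):
        C = np.hstack([x[:, kk], f[:, kk]])
        Es = C @ model.graph.W_source.data
        Et = C @ model.graph.W_target.data
        sc = np.maximum(Es @ Et.T, 0)
        e = np.exp(sc - sc.max(-1, keepdims=True))
        A = e / e.sum(-1, keepdims=True)
        Ah = A + np.eye(2)
        d = Ah.sum(1)
        An = Ah / np.sqrt(np.outer(d, d))
        mbar[:, kk] = gelu_np(An @ x[:, kk] @ model.graph.W_gnn.data)
    # prediction head from the last interval
    expected = []
    for (i, tau) in ((0, 5.0), (1, 6.0)):
        c = mbar[i, -1]
        tf = (tau - 4.0) / 2.0
        u = c @ model.head.Wp.data + model.head.Up.data * tf
        g = gelu_np(model.head.Bpbar.data + c @ model.head.Wpbar.data
                    + model.head.Vpbar.data * tf)
        z = np.concatenate([np.cos(u), np.sin(u), g])
        expected.append(z @ model.head.W_out.data[:, 0]
                        + model.head.b_out.data[0])
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_ablation_flags_change_parameter_sets():
    base = Forecaster(TOY, np.linspace(0.1, 1, 4))
    nof = Forecaster(ModelConfig.from_dict(
        {**TOY.to_dict(), "no_frequency": True}))
    assert nof.n_parameters() < base.n_parameters()
    nog = Forecaster(ModelConfig.from_dict(
        {**TOY.to_dict(), "no_graph": True}), np.linspace(0.1, 1, 4))
    assert not any(k.startswith("graph.") for k in nog.params())


def test_prealigned_representation_single_tokens(toy):
    eps, _, _ = toy
    cfg = ModelConfig.from_dict({**TOY.to_dict(), "no_patching": True})
    model = Forecaster(cfg, np.linspace(0.1, 1.0, 4))
    prep = prepare_episode(eps[0], cfg, model.probe_frequencies)
    union = sorted({o.time for s in eps[0].series for o in s.observations})
    assert prep.n_canonical == len(union)
    out = model.forward_episode(eps[0])
    assert len(out) == len(eps[0].queries)


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def split_cohort():
    eps, _ = toy_cohort(n=24, seed=1)
    tr, va, te = split_episodes(eps, (0.5, 0.25, 0.25), seed=0)
    std = fit_standardizer(tr)
    return ([apply_standardizer(e, std) for e in tr],
            [apply_standardizer(e, std) for e in va],
            [apply_standardizer(e, std) for e in te])


def test_training_reduces_loss(split_cohort):
    tr, va, te = split_cohort
    model = Forecaster(TOY, np.linspace(0.1, 1, 4))
    log = fit_forecaster(model, tr, va,
                         TrainingConfig(learning_rate=5e-3, batch_size=6,
                                        max_epochs=6, patience=6, seed=2))
    assert log.train_loss[-1] < log.train_loss[0]
    assert len(log.valid_loss) == 6


def test_patience_zero_stops_after_first_non_improvement(split_cohort):
    tr, va, _ = split_cohort
    model = Forecaster(TOY, np.linspace(0.1, 1, 4))
    log = fit_forecaster(model, tr, va,
                         TrainingConfig(learning_rate=5e-3, batch_size=6,
                                        max_epochs=50, patience=0, seed=2))
    # stopped at the first epoch whose validation loss did not improve
    worse = [i for i in range(1, len(log.valid_loss))
             if log.valid_loss[i] >= log.valid_loss[i - 1]]
    assert len(log.valid_loss) == (worse[0] + 1 if worse else 50)


def test_same_seed_identical_training(split_cohort):
    tr, va, _ = split_cohort
    logs = []
    for _ in range(2):
        model = Forecaster(TOY, np.linspace(0.1, 1, 4))
        logs.append(fit_forecaster(
            model, tr, va, TrainingConfig(learning_rate=5e-3, batch_size=6,
                                          max_epochs=3, patience=5, seed=9)))
    np.testing.assert_allclose(logs[0].train_loss, logs[1].train_loss,
                               atol=1e-12)


def test_checkpoint_round_trip(tmp_path, split_cohort):
    tr, va, te = split_cohort
    model = Forecaster(TOY, np.linspace(0.1, 1, 4))
    fit_forecaster(model, tr, va,
                   TrainingConfig(learning_rate=5e-3, batch_size=6,
                                  max_epochs=2, patience=5, seed=3))
    before = evaluate_model(model, te)
    path = tmp_path / "ckpt.npz"
    model.save(path)
    loaded = Forecaster.load(path)
    after = evaluate_model(loaded, te)
    assert before == after


def test_seed_isolation():
    """Model-init seed and data-side seed are independent streams."""
    a = Forecaster(ModelConfig.from_dict({**TOY.to_dict(), "seed": 1}),
                   np.linspace(0.1, 1, 4))
    b = Forecaster(ModelConfig.from_dict({**TOY.to_dict(), "seed": 1}),
                   np.linspace(0.1, 1, 4))
    c = Forecaster(ModelConfig.from_dict({**TOY.to_dict(), "seed": 2}),
                   np.linspace(0.1, 1, 4))
    pa, pb, pc = a.params(), b.params(), c.params()
    assert all(np.array_equal(pa[k].data, pb[k].data) for k in pa)
    assert any(not np.array_equal(pa[k].data, pc[k].data) for k in pa)


def test_divergence_aborts(split_cohort):
    tr, va, _ = split_cohort
    model = Forecaster(TOY, np.linspace(0.1, 1, 4))
    model.scale_fusion.W.data[:] = np.nan    # poisoned state -> NaN loss
    with pytest.raises(RuntimeError, match="non-finite"):
        fit_forecaster(model, tr, va,
                       TrainingConfig(learning_rate=1e-3, batch_size=6,
                                      max_epochs=5, patience=5, seed=0))


# ---------------------------------------------------------------------------
# robustness harness
# ---------------------------------------------------------------------------

def test_robustness_rho_zero_rows_identical(split_cohort):
    tr, va, te = split_cohort
    model = Forecaster(TOY, np.linspace(0.1, 1, 4))
    fit_forecaster(model, tr, va,
                   TrainingConfig(learning_rate=5e-3, batch_size=6,
                                  max_epochs=2, patience=5, seed=4))
    table = run_robustness(model, te, rhos=(0.0, 0.3),
                           n_seeds=2, base_seed=7)
    base = evaluate_model(model, te)
    for pattern in ("pointwise", "blockwise"):
        row = table[(0.0, pattern)]
        for k, v in base.items():
            assert row[f"{k}_mean"] == v
            assert row[f"{k}_std"] == 0.0
    # perturbed rows report spread over seeds
    assert table[(0.3, "pointwise")]["MSE_std"] >= 0.0
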