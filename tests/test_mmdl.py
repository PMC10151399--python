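import numpy as np
import pytest

from gpfusion.mmdl import (
    MMDLConfig,
    PlainLayer,
    ResidualBlock,
    build_mmdl,
    layer_widths,
    predict_mmdl,
    train_mmdl,
)


@pytest.mark.parametrize(
    "N1,nHL,expected",
    [
        (16, 4, [16, 8, 4, 2]),
        (16, 1, [16]),
        (5, 3, [5, 2, 1]),
        (1, 3, [1, 1, 1]),  # floor-halving clamps at 1
    ],
)
def test_layer_width_halving(N1, nHL, expected):
    assert layer_widths(N1, nHL) == expected


def expected_param_count(input_dims, config):
    """Independent closed-form parameter count oracle."""
    total = 0
    fusion_in = 0
    for q, d in input_dims.items():
        widths = [max(1, config.N1[q] // 2**l) for l in range(config.nHL[q])]
        i = 0
        while i + 1 < len(widths):
            w1, w2 = widths[i], widths[i + 1]
            total += d * w1 + w1 + 2 * w1          # dense1 + bn1
            total += w1 * w2 + w2 + 2 * w2         # dense2 + bn2
            if d != w2:
                total += d * w2                    # bias-free projection
            d = w2
            i += 2
        if i < len(widths):
            w = widths[i]
            total += d * w + w + 2 * w
            d = w
        fusion_in += d
    return total + fusion_in + 1


def test_parameter_count_formula_over_random_configs(rng):
    for _ in range(20):
        dims = {}
        nHL, N1 = {}, {}
        for q, wmax in (("year", 16), ("genomic", 128), ("ndvi", 64)):
            if rng.random() < 0.8:
                dims[q] = int(rng.integers(1, 40))
                nHL[q] = int(rng.integers(1, 6))
                N1[q] = int(rng.integers(1, wmax))
        if not dims:
            dims = {"genomic": 10}
            nHL["genomic"], N1["genomic"] = 2, 8
        cfg = MMDLConfig(nHL=nHL, N1=N1, seed=0)
        model = build_mmdl(dims, cfg)
        assert model.count_params() == expected_param_count(dims, cfg)


def test_hand_forward_pass_single_unit_tower():
    # dense w=2,b=0 -> BN (inference, mean 0, var 1) -> relu -> output w=1,b=0
    cfg = MMDLConfig(nHL={"genomic": 1}, N1={"genomic": 1}, l2=0.0, dropout=0.0, seed=0)
    model = build_mmdl({"genomic": 1}, cfg)
    layer = model.towers["genomic"].blocks[0]
    layer.d.W[:] = 2.0
    layer.d.b[:] = 0.0
    layer.bn.run_mean[:] = 0.0
    layer.bn.run_var[:] = 1.0 - layer.bn.eps
    model.fusion.W[:] = 1.0
    model.fusion.b[:] = 0.0
    out = predict_mmdl(model, {"genomic": np.array([[3.0]])})
    np.testing.assert_allclose(out, [6.0], atol=1e-9)
    # negative input is clipped by the relu
    out = predict_mmdl(model, {"genomic": np.array([[-3.0]])})
    np.testing.assert_allclose(out, [0.0], atol=1e-12)


def test_zero_network_outputs_bias(rng):
    cfg = MMDLConfig(nHL={"genomic": 2, "ndvi": 1}, N1={"genomic": 8, "ndvi": 4}, seed=0)
    model = build_mmdl({"genomic": 5, "ndvi": 3}, cfg)
    for p, _ in model.params():
        p[:] = 0.0
    out = predict_mmdl(
        model, {"genomic": rng.standard_normal((4, 5)), "ndvi": rng.standard_normal((4, 3))}
    )
    np.testing.assert_array_equal(out, np.zeros(4))


def test_fusion_width_is_sum_of_tower_outputs():
    cfg = MMDLConfig(
        nHL={"year": 1, "genomic": 2, "ndvi": 1},
        N1={"year": 4, "genomic": 16, "ndvi": 2},
        seed=0,
    )
    model = build_mmdl({"year": 2, "genomic": 30, "ndvi": 6}, cfg)
    # tower final widths: 4, 8 (16 -> 8), 2
    assert model.fusion_in_dim == 4 + 8 + 2


def test_residual_blocks_pair_layers_and_project_skips():
    cfg = MMDLConfig(nHL={"genomic": 5}, N1={"genomic": 16}, seed=0)
    model = build_mmdl({"genomic": 10}, cfg)
    blocks = model.towers["genomic"].blocks
    # widths [16, 8, 4, 2, 1] -> two residual pairs + one plain trailing layer
    assert [type(b).__name__ for b in blocks] == [
        "ResidualBlock", "ResidualBlock", "PlainLayer"
    ]
    assert blocks[0].proj is not None         # 10 -> 8 needs projection
    assert blocks[0].proj.b is None           # bias-free skip


def test_dropping_year_tower_only_changes_fusion_width():
    cfg = MMDLConfig(
        nHL={"year": 1, "genomic": 2, "ndvi": 1},
        N1={"year": 4, "genomic": 16, "ndvi": 8},
        seed=0,
    )
    full = build_mmdl({"year": 2, "genomic": 20, "ndvi": 6}, cfg)
    loo = build_mmdl({"genomic": 20, "ndvi": 6}, cfg)
    assert set(loo.towers) == {"genomic", "ndvi"}
    year_width = full.towers["year"].out_dim
    assert full.fusion_in_dim - loo.fusion_in_dim == year_width
    assert loo.towers["genomic"].out_dim == full.towers["genomic"].out_dim


def test_training_is_bit_reproducible(rng):
    X = {"genomic": rng.standard_normal((60, 8))}
    y = rng.standard_normal(60)
    cfg = MMDLConfig(nHL={"genomic": 2}, N1={"genomic": 8}, l2=0.0, dropout=0.0,
                     wd=0.0, lr=0.01, patience=4, max_epochs=20, seed=42)
    m1 = build_mmdl({"genomic": 8}, cfg)
    m2 = build_mmdl({"genomic": 8}, cfg)
    _, h1 = train_mmdl(m1, X, y, cfg)
    _, h2 = train_mmdl(m2, X, y, cfg)
    assert h1 == h2
    np.testing.assert_array_equal(
        predict_mmdl(m1, X), predict_mmdl(m2, X)
    )


def test_early_stopping_respects_epoch_cap(rng):
    X = {"genomic": rng.standard_normal((50, 4))}
    y = rng.standard_normal(50)
    cfg = MMDLConfig(nHL={"genomic": 1}, N1={"genomic": 4}, patience=1000,
                     max_epochs=128, seed=0)
    _, history = train_mmdl(build_mmdl({"genomic": 4}, cfg), X, y, cfg)
    assert len(history) <= 128
    # tiny patience halts early on a flat loss surface
    cfg2 = MMDLConfig(nHL={"genomic": 1}, N1={"genomic": 4}, patience=1,
                      lr=1e-9, seed=0)
    _, history2 = train_mmdl(build_mmdl({"genomic": 4}, cfg2), X, y, cfg2)
    assert len(history2) < 128


def test_learning_rate_decays_exponentially(rng):
    X = {"genomic": rng.standard_normal((40, 4))}
    y = rng.standard_normal(40)
    cfg = MMDLConfig(nHL={"genomic": 1}, N1={"genomic": 4}, lr=0.01, wd=0.5,
                     patience=1000, max_epochs=5, seed=0)
    _, history = train_mmdl(build_mmdl({"genomic": 4}, cfg), X, y, cfg)
    lrs = np.array([h["lr"] for h in history])
    np.testing.assert_allclose(lrs, 0.01 * np.exp(-0.5 * np.arange(len(lrs))))


def test_constant_target_is_learned(rng):
    X = {"genomic": rng.standard_normal((100, 5))}
    c = 7.0
    y = np.full(100, c)
    cfg = MMDLConfig(nHL={"genomic": 1}, N1={"genomic": 4}, l2=1e-4, dropout=0.0,
                     wd=0.0, lr=0.05, patience=64, seed=3)
    model = build_mmdl({"genomic": 5}, cfg)
    train_mmdl(model, X, y, cfg)
    pred = predict_mmdl(model, X)
    assert np.abs(pred - c).max() < 0.05 * abs(c) + 0.05


def test_prediction_determinism_and_dim_mismatch(rng):
    cfg = MMDLConfig(nHL={"genomic": 2}, N1={"genomic": 8}, dropout=0.3, seed=0)
    model = build_mmdl({"genomic": 6}, cfg)
    X = {"genomic": rng.standard_normal((10, 6))}
    np.testing.assert_array_equal(predict_mmdl(model, X), predict_mmdl(model, X))
    with pytest.raises(ValueError, match="columns"):
        predict_mmdl(model, {"genomic": rng.standard_normal((10, 7))})
    with pytest.raises(ValueError, match="modalities"):
        predict_mmdl(model, {"ndvi": rng.standard_normal((10, 6))})


def test_signal_beats_permutation_null():
    """On high-heritability synthetic data the network must predict held-out
    lines better than the 97.5th percentile of a label-permutation null."""
    from gpfusion.synthdata import SimulationConfig, simulate_dataset
    from gpfusion.trial_data import PredictorSpec, assemble_predictors

    cfg = SimulationConfig(J=200, p=400, h2=0.9, var_year=0.0, var_gxe=0.02,
                           years=("y1", "y2"), seed=17)
    _, _, feats, trial = simulate_dataset(cfg)
    blocks = assemble_predictors(trial.records, feats, PredictorSpec())
    test_lines = np.arange(160, 200)
    te = np.isin(blocks.line_index, test_lines)
    net_cfg = MMDLConfig(nHL={"year": 1, "genomic": 2}, N1={"year": 4, "genomic": 64},
                         l2=1e-5, dropout=0.05, lr=5e-3, wd=0.01, patience=16, seed=5)
    tr_data = {"year": blocks.X_year[~te], "genomic": blocks.ZLstar[~te]}
    y = blocks.y
    m, s = y[~te].mean(), y[~te].std()
    model = build_mmdl({"year": 2, "genomic": 200}, net_cfg)
    train_mmdl(model, tr_data, (y[~te] - m) / s, net_cfg)
    pred = predict_mmdl(model, {"year": blocks.X_year[te], "genomic": blocks.ZLstar[te]})
    obs = y[te]
    cor = np.corrcoef(obs, pred)[0, 1]
    null_rng = np.random.default_rng(0)
    null = [
        np.corrcoef(null_rng.permutation(obs), pred)[0, 1] for _ in range(1000)
    ]
    assert cor > 0.3
    assert cor > np.quantile(null, 0.975)
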