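import subprocess

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from miratlas.combat import ConfoundedDesignError, adjust, fit_batch_model


def two_batch_sim(seed, n_feat=200, n_samp=60, shift=2.0, scale=1.5, noise=0.5):
    """Batch 2 shifted by +2.0 on average, with per-feature shifts drawn
    around that mean (the location/scale model's own generative assumption)
    and a 1.5× noise scale."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 12, size=n_feat)
    shifts = shift + rng.normal(0, 1.0, size=n_feat)
    batch = ["b1"] * (n_samp // 2) + ["b2"] * (n_samp - n_samp // 2)
    Y = base[None, :] + rng.normal(0, noise, size=(n_samp, n_feat))
    sel = np.array([b == "b2" for b in batch])
    Y[sel] = base[None, :] + shifts[None, :] + scale * rng.normal(
        0, noise, size=(sel.sum(), n_feat)
    )
    return make_matrix(Y, batch=batch), batch


def recovered_shift(model):
    """Per-feature batch-2 minus batch-1 location, back on the data scale."""
    return (model.gamma_hat[1] - model.gamma_hat[0]) * np.sqrt(model.sigma2)


def test_single_batch_fit_is_identity():
    rng = np.random.default_rng(10)
    m = make_matrix(rng.normal(8, 2, size=(12, 30)))
    model = fit_batch_model(m)
    assert np.abs(model.gamma_star).max() < 1e-8
    assert np.abs(model.delta2_star - 1).max() < 1e-8
    out = adjust(m, model)
    np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-8)


def test_recovers_injected_location_shift():
    m, _ = two_batch_sim(seed=11)
    model = fit_batch_model(m)
    assert model.converged
    assert abs(recovered_shift(model).mean() - 2.0) < 0.15


def test_identical_batches_give_near_identity_adjustment():
    rng = np.random.default_rng(12)
    Y = rng.normal(8, 1, size=(40, 50))
    m = make_matrix(Y, batch=["b1"] * 20 + ["b2"] * 20)
    model = fit_batch_model(m)
    # per-feature batch means differ only by sampling noise; no systematic shift
    assert abs((model.gamma_hat[1] - model.gamma_hat[0]).mean()) < 0.1
    out = adjust(m, model)
    assert np.abs(out.values.to_numpy() - Y).mean() < 0.2


def test_adjustment_removes_batch_mean_difference():
    m, batch = two_batch_sim(seed=13)
    sel = np.array([b == "b2" for b in batch])
    Y = m.values.to_numpy()
    before = np.abs(Y[sel].mean(axis=0) - Y[~sel].mean(axis=0)).mean()
    out = adjust(m, fit_batch_model(m)).values.to_numpy()
    after = np.abs(out[sel].mean(axis=0) - out[~sel].mean(axis=0)).mean()
    assert after <= 0.05 * before


def test_refit_on_adjusted_data_finds_no_batch_effect():
    m, _ = two_batch_sim(seed=14)
    adjusted = adjust(m, fit_batch_model(m))
    refit = fit_batch_model(adjusted)
    assert np.abs(refit.gamma_hat).mean() < 0.05


def test_shift_recovery_over_20_replicates():
    errors = []
    for seed in range(20):
        m, _ = two_batch_sim(seed=100 + seed)
        model = fit_batch_model(m)
        errors.append(abs(np.median(recovered_shift(model)) - 2.0))
    assert np.median(errors) < 0.2  # < 10% of the injected +2.0


def test_order_invariance():
    m, batch = two_batch_sim(seed=15, n_feat=40, n_samp=20)
    out = adjust(m, fit_batch_model(m))
    rng = np.random.default_rng(0)
    perm = rng.permutation(m.n_samples)
    m2_vals = m.values.iloc[perm]
    m2 = type(m)(m2_vals, m.sample_meta.iloc[perm])
    out2 = adjust(m2, fit_batch_model(m2))
    np.testing.assert_allclose(
        out2.values.to_numpy(),
        out.values.iloc[perm].to_numpy(),
        rtol=1e-8, atol=1e-8,
    )


def test_covariate_structure_survives_adjustment():
    rng = np.random.default_rng(16)
    n_feat = 120
    base = rng.uniform(6, 11, size=n_feat)
    effect = 2.5  # cellB sits 2.5 log2 units above cellA on half the features
    hot = rng.random(n_feat) < 0.5
    rows, labels, batches = [], [], []
    for i in range(48):
        cell = "cellA" if (i // 4) % 2 == 0 else "cellB"  # not chip-aligned
        batchname = f"chip{i % 4}"
        mu = base + (effect * hot if cell == "cellB" else 0)
        shift = {"chip0": 0.0, "chip1": 1.0, "chip2": -0.8, "chip3": 0.5}[batchname]
        rows.append(mu + shift + rng.normal(0, 0.3, size=n_feat))
        labels.append(cell)
        batches.append(batchname)
    m = make_matrix(np.array(rows), batch=batches, label=labels)
    model = fit_batch_model(m, covariate_labels=labels)
    out = adjust(m, model).values.to_numpy()
    sel = np.array([l == "cellB" for l in labels])
    observed = (out[sel].mean(axis=0) - out[~sel].mean(axis=0))[hot].mean()
    assert abs(observed - effect) < 0.1 * effect


def test_missing_values_stay_missing():
    m, _ = two_batch_sim(seed=17, n_feat=30, n_samp=20)
    vals = m.values.to_numpy()
    vals[2, 5] = np.nan
    m2 = make_matrix(vals, batch=list(m.sample_meta["batch_id"]))
    out = adjust(m2, fit_batch_model(m2))
    assert np.isnan(out.values.iloc[2, 5])
    assert out.values.isna().sum().sum() == 1


def test_singleton_batch_rejected():
    m = make_matrix(np.random.default_rng(18).normal(size=(5, 10)),
                    batch=["b1", "b1", "b1", "b1", "b2"])
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_batch_model(m)


def test_confounded_covariate_rejected():
    rng = np.random.default_rng(19)
    batch = ["b1"] * 5 + ["b2"] * 5
    m = make_matrix(rng.normal(size=(10, 8)), batch=batch)
    with pytest.raises(ConfoundedDesignError):
        fit_batch_model(m, covariate_labels=batch)  # covariate == batch


def test_model_tsv_bundle_round_trip(tmp_path):
    m, _ = two_batch_sim(seed=20, n_feat=10, n_samp=10)
    model = fit_batch_model(m)
    model.to_tsv(tmp_path)
    hyper = pd.read_csv(tmp_path / "hyperparameters.tsv", sep="\t")
    est = pd.read_csv(tmp_path / "batch_estimates.tsv", sep="\t")
    assert list(hyper["batch"]) == model.batches
    assert len(est) == len(model.batches) * len(model.features)
    np.testing.assert_allclose(
        est.loc[est["batch"] == "b1", "gamma_star"].to_numpy(),
        model.gamma_star[0],
    )


def test_matches_bioconductor_sva_combat(tmp_path):
    """Independent oracle: the reference Bioconductor implementation on a
    small complete-data two-batch fixture (agreement to ~1%; denominators
    differ at O(1/N))."""
    rng = np.random.default_rng(42)
    G, n = 40, 20
    base = rng.normal(8, 1.5, size=(G, 1))
    Y = base + rng.normal(0, 0.6, size=(G, n))
    batch = np.array([1] * 10 + [2] * 10)
    Y[:, batch == 2] += 1.2 + rng.normal(0, 0.4, size=(G, 10))
    np.savetxt(tmp_path / "y.tsv", Y, delimiter="\t")
    np.savetxt(tmp_path / "batch.tsv", batch, fmt="%d")
    script = tmp_path / "combat.R"
    script.write_text(
        'suppressMessages(library(sva))\n'
        'Y <- as.matrix(read.table("y.tsv", sep="\\t"))\n'
        'batch <- scan("batch.tsv")\n'
        'out <- ComBat(dat=Y, batch=batch, par.prior=TRUE)\n'
        'write.table(out, "out.tsv", sep="\\t", row.names=FALSE, col.names=FALSE)\n'
    )
    subprocess.run(
        ["Rscript", "combat.R"], cwd=tmp_path, check=True,
        capture_output=True, timeout=300,
    )
    ref = np.loadtxt(tmp_path / "out.tsv")
    m = make_matrix(Y.T, batch=[f"b{b}" for b in batch])
    ours = adjust(m, fit_batch_model(m)).values.to_numpy().T
    assert np.abs(ours - ref).max() < 0.15
    assert np.abs(ours - ref).mean() < 0.03
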