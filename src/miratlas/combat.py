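"""Empirical Bayes location/scale batch-effect adjustment (ComBat).

Chips hybridized on different days or in different labs show systematic
per-feature shifts (location) and spreads (scale) unrelated to biology.
The model, per feature g, sample j of batch i:

    Y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg

with optional biological covariates X (here typically cell type), a normal
prior gamma_ig ~ N(gamma_bar_i, tau2_bar_i) and an inverse-gamma prior
delta2_ig ~ InvGamma(lambda_i, theta_i), both with hyperparameters fit by
method of moments across features.  Per-batch location/scale estimates are
shrunk toward the batch-level priors by the standard fixed-point iteration
(empirical Bayes), stabilizing features with few samples, and the data are
adjusted to the batch-free model.

Variance denominators are N−1 throughout, so a single-batch fit is exactly
the identity adjustment (gamma* = 0, delta*^2 = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import SampleMatrix

__all__ = ["BatchModel", "fit_batch_model", "adjust"]

logger = logging.getLogger(__name__)


class ConfoundedDesignError(ValueError):
    """Covariates are collinear with batch; effects are not separable."""


@dataclass
class BatchModel:
    """Fitted batch model: per-feature/per-batch estimates and priors."""

    features: list[str]
    batches: list[str]
    sample_ids: list[str]
    batch_of_sample: pd.Series            # sample_id -> batch label
    covariate_levels: list[str]           # dropped-first one-hot column names
    covariate_of_sample: pd.Series | None
    alpha: np.ndarray                     # (G,) grand mean
    sigma2: np.ndarray                    # (G,) pooled residual variance
    beta_cov: np.ndarray                  # (G, C) covariate coefficients
    gamma_hat: np.ndarray                 # (I, G) raw batch locations
    delta2_hat: np.ndarray                # (I, G) raw batch scales
    gamma_star: np.ndarray                # (I, G) shrunken locations
    delta2_star: np.ndarray               # (I, G) shrunken scales
    gamma_bar: np.ndarray                 # (I,) location prior mean
    tau2_bar: np.ndarray                  # (I,) location prior variance
    lambda_: np.ndarray                   # (I,) scale prior shape
    theta: np.ndarray                     # (I,) scale prior rate
    converged: bool
    n_iter: int
    low_confidence: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, directory: str | Path) -> None:
        """Write a TSV bundle: hyperparameters + per-batch estimates."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "batch": self.batches,
                "gamma_bar": self.gamma_bar,
                "tau2_bar": self.tau2_bar,
                "lambda": self.lambda_,
                "theta": self.theta,
            }
        ).to_csv(directory / "hyperparameters.tsv", sep="\t", index=False)
        rows = []
        for i, b in enumerate(self.batches):
            for g, f in enumerate(self.features):
                rows.append(
                    (b, f, self.gamma_hat[i, g], self.delta2_hat[i, g],
                     self.gamma_star[i, g], self.delta2_star[i, g])
                )
        pd.DataFrame(
            rows,
            columns=["batch", "feature", "gamma_hat", "delta2_hat",
                     "gamma_star", "delta2_star"],
        ).to_csv(directory / "batch_estimates.tsv", sep="\t", index=False)


def _design(
    batch: pd.Series, covariates: pd.Series | None
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Batch one-hot (all levels) and covariate one-hot (first level dropped)."""
    batches = sorted(batch.unique())
    B = np.column_stack([(batch == b).to_numpy(float) for b in batches])
    if covariates is None:
        return B, batches, np.zeros((len(batch), 0)), []
    levels = sorted(pd.Series(covariates).unique())[1:]
    C = np.column_stack([(covariates == l).to_numpy(float) for l in levels]) \
        if levels else np.zeros((len(batch), 0))
    return B, batches, C, [str(l) for l in levels]


def fit_batch_model(
    m: SampleMatrix,
    batch_labels: Sequence | pd.Series | None = None,
    covariate_labels: Sequence | pd.Series | None = None,
    *,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> BatchModel:
    """Fit the empirical Bayes batch model.

    ``batch_labels`` defaults to the matrix's ``batch_id`` metadata column;
    ``covariate_labels`` is an optional per-sample categorical (e.g. cell
    type) whose structure is protected from removal.  Requires at least two
    samples per batch and a full-rank design.  Per-feature statistics use
    non-missing entries only; a feature entirely missing within a batch gets
    a shrinkage-only estimate from the batch prior and is logged as
    low-confidence.
    """
    Y = m.values.to_numpy(dtype=float)
    n, G = Y.shape
    sample_ids = list(m.values.index)
    if batch_labels is None:
        batch = m.sample_meta["batch_id"].astype(str)
    else:
        batch = pd.Series([str(b) for b in batch_labels], index=sample_ids)
    cov = None
    if covariate_labels is not None:
        cov = pd.Series(list(covariate_labels), index=sample_ids).astype(str)

    counts = batch.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(
            f"batches with fewer than 2 samples: {sorted(singletons.index)}"
        )

    B, batches, C, cov_cols = _design(batch, cov)
    D = np.hstack([B, C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ConfoundedDesignError(
            "design is rank-deficient: covariate columns "
            f"{cov_cols or '(none)'} are collinear with batches {batches}"
        )
    I = len(batches)

    missing = np.isnan(Y)
    feat_batch_n = np.zeros((I, G))
    for i, b in enumerate(batches):
        feat_batch_n[i] = (~missing[(batch == b).to_numpy()]).sum(axis=0)
    if ((feat_batch_n > 0).sum(axis=0) < min(2, I)).any():
        bad = [m.values.columns[g] for g in
               np.where((feat_batch_n > 0).sum(axis=0) < min(2, I))[0]]
        raise ValueError(f"features observed in fewer than 2 batches: {bad[:5]}")

    # Per-feature least squares on non-missing entries.
    coef = np.empty((D.shape[1], G))
    resid = np.full_like(Y, np.nan)
    full = ~missing.any(axis=0)
    if full.any():
        sol, *_ = np.linalg.lstsq(D, Y[:, full], rcond=None)
        coef[:, full] = sol
        resid[:, full] = Y[:, full] - D @ sol
    for g in np.where(~full)[0]:
        ok = ~missing[:, g]
        sol, *_ = np.linalg.lstsq(D[ok], Y[ok, g], rcond=None)
        coef[:, g] = sol
        resid[ok, g] = Y[ok, g] - D[ok] @ sol

    gamma_raw = coef[:I]                      # (I, G) per-batch means
    beta_cov = coef[I:].T                     # (G, C)
    # Grand mean weighted by per-feature observation counts per batch, so
    # features unmeasured on some chips are not dragged toward zero.
    n_ok = (~missing).sum(axis=0).astype(float)
    alpha = (feat_batch_n * gamma_raw).sum(axis=0) / n_ok
    sigma2 = np.nansum(resid**2, axis=0) / (n_ok - 1)
    if (sigma2 <= 0).any():
        bad = [m.values.columns[g] for g in np.where(sigma2 <= 0)[0]]
        raise ValueError(f"zero residual variance for features: {bad[:5]}")

    Z = (Y - alpha[None, :] - C @ beta_cov.T) / np.sqrt(sigma2)[None, :]

    gamma_hat = np.zeros((I, G))
    delta2_hat = np.ones((I, G))
    estimable = np.zeros((I, G), dtype=bool)
    for i, b in enumerate(batches):
        rows = (batch == b).to_numpy()
        Zi = Z[rows]
        obs = ~np.isnan(Zi)
        cnt = obs.sum(axis=0)
        safe = np.where(obs, Zi, 0.0)
        mu = safe.sum(axis=0) / np.maximum(cnt, 1)
        v = (np.where(obs, (Zi - mu[None, :]) ** 2, 0.0)).sum(axis=0) / np.maximum(
            cnt - 1, 1
        )
        ok = (cnt >= 2) & (v > 0)
        gamma_hat[i, ok] = mu[ok]
        delta2_hat[i, ok] = v[ok]
        estimable[i] = ok

    gamma_bar = np.empty(I)
    tau2_bar = np.empty(I)
    lambda_ = np.empty(I)
    theta = np.empty(I)
    degenerate_scale = np.zeros(I, dtype=bool)
    for i in range(I):
        gh = gamma_hat[i, estimable[i]]
        dh = delta2_hat[i, estimable[i]]
        gamma_bar[i] = gh.mean()
        tau2_bar[i] = gh.var(ddof=1) if gh.size > 1 else 0.0
        mbar = dh.mean()
        s2 = dh.var(ddof=1) if dh.size > 1 else 0.0
        if s2 <= 1e-12:
            degenerate_scale[i] = True
            lambda_[i] = np.inf
            theta[i] = np.inf
        else:
            lambda_[i] = (2 * s2 + mbar**2) / s2
            theta[i] = (mbar * s2 + mbar**3) / s2

    # Empirical Bayes fixed point, vectorized over features within a batch.
    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter = 0
    converged = True
    for i, b in enumerate(batches):
        rows = (batch == b).to_numpy()
        Zi = Z[rows]
        cnt = (~np.isnan(Zi)).sum(axis=0).astype(float)
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        it = 0
        while True:
            it += 1
            g_new = (cnt * tau2_bar[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                cnt * tau2_bar[i] + d_old
            )
            if degenerate_scale[i]:
                d_new = delta2_hat[i].copy()
            else:
                ss = np.nansum((Zi - g_new[None, :]) ** 2, axis=0)
                d_new = (theta[i] + 0.5 * ss) / (cnt / 2 + lambda_[i] - 1)
            change = max(
                np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
                np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
            if it >= max_iter:
                converged = False
                break
        n_iter = max(n_iter, it)
        gamma_star[i] = g_old
        delta2_star[i] = d_old
        # Features unobserved (or single-valued) in this batch: prior means.
        holes = ~estimable[i]
        if holes.any():
            gamma_star[i, holes] = gamma_bar[i]
            prior_mean = (
                theta[i] / (lambda_[i] - 1) if np.isfinite(theta[i]) else 1.0
            )
            delta2_star[i, holes] = prior_mean
            for g in np.where(holes)[0]:
                logger.info(
                    "fit_batch_model: feature %s unobserved in batch %s; "
                    "shrinkage-only estimate (low confidence)",
                    m.values.columns[g], b,
                )

    if not converged:
        raise RuntimeError(
            f"empirical Bayes iteration did not converge in {max_iter} steps "
            f"(last max relative change recorded); inspect the returned data"
        )
    low_conf = [
        (batches[i], str(m.values.columns[g]))
        for i in range(I)
        for g in np.where(~estimable[i])[0]
    ]
    return BatchModel(
        features=[str(c) for c in m.values.columns],
        batches=batches,
        sample_ids=[str(s) for s in sample_ids],
        batch_of_sample=batch,
        covariate_levels=cov_cols,
        covariate_of_sample=cov,
        alpha=alpha,
        sigma2=sigma2,
        beta_cov=beta_cov,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2_bar=tau2_bar,
        lambda_=lambda_,
        theta=theta,
        converged=converged,
        n_iter=n_iter,
        low_confidence=low_conf,
    )


def adjust(m: SampleMatrix, model: BatchModel) -> SampleMatrix:
    """Remove fitted batch effects: Y* = sigma_g (Z − gamma*)/delta* + alpha_g + X beta_g.

    Missing entries stay missing; dimensions and ordering are preserved.
    Features or batches unseen at fit time are an error.
    """
    feats = [str(c) for c in m.values.columns]
    if feats != model.features:
        raise ValueError("feature set/order differs from the fitted model")
    batch = m.sample_meta["batch_id"].astype(str)
    unseen = sorted(set(batch) - set(model.batches))
    if unseen:
        raise ValueError(f"samples from batches unseen at fit time: {unseen}")

    Y = m.values.to_numpy(dtype=float)
    if model.covariate_of_sample is not None:
        C = np.column_stack(
            [
                (model.covariate_of_sample.reindex(m.values.index) == l).to_numpy(float)
                for l in model.covariate_levels
            ]
        ) if model.covariate_levels else np.zeros((len(m.values), 0))
    else:
        C = np.zeros((len(m.values), 0))
    cov_part = C @ model.beta_cov.T
    sd = np.sqrt(model.sigma2)[None, :]
    Z = (Y - model.alpha[None, :] - cov_part) / sd
    out = np.full_like(Y, np.nan)
    for i, b in enumerate(model.batches):
        rows = (batch == b).to_numpy()
        if not rows.any():
            continue
        Zi = (Z[rows] - model.gamma_star[i][None, :]) / np.sqrt(
            model.delta2_star[i]
        )[None, :]
        out[rows] = Zi * sd + model.alpha[None, :] + cov_part[rows]
    return SampleMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.sample_meta.copy(),
    )
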