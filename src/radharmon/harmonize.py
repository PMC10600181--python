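"""Batch-effect correction methods for multi-scanner radiomic features.

Three corrections are implemented, mirroring the standard toolbox for
cross-scanner PET feature harmonization:

``phantom_correct``
    Physical cross-calibration: the per-feature ratio of two scanners'
    measurements of the same uniform cylinder phantom is multiplied onto
    the non-reference batch.

``combat``
    Empirical-Bayes location-scale adjustment.  Each feature is
    standardized, per-batch location (gamma) and scale (delta^2)
    parameters are estimated, shrunk toward parametric priors (normal for
    locations, inverse-gamma for scales, both fit by method of moments),
    and the data are back-transformed.  ``mode="global"`` aligns every
    batch to the pooled mean/variance; ``mode="reference"`` aligns all
    other batches to a designated reference batch, which passes through
    unchanged.

``linear_batch_remove``
    Least-squares removal of additive batch effects: per feature, an
    intercept plus sum-to-zero batch effects are fit and the fitted batch
    term subtracted.  With two batches both corrected batch means equal
    the unweighted average of the observed batch means, exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix, PhantomMeasurement

__all__ = ["HarmonizationResult", "ComBatModel", "phantom_correct", "combat",
           "linear_batch_remove", "HarmonizationError", "DegeneratePhantomError"]


class HarmonizationError(ValueError):
    """Input unusable for the requested correction."""


class DegeneratePhantomError(HarmonizationError):
    """A phantom measurement is (near-)zero, so its ratio is undefined."""


@dataclass
class ComBatModel:
    """Fitted ComBat parameters (per feature g, per batch i)."""

    mode: str                          # "global" or "reference"
    reference_batch: int | None
    batches: list[int]
    grand_mean: np.ndarray             # alpha_g
    pooled_sd: np.ndarray              # sigma_g of the standardization
    gamma_hat: np.ndarray              # (B, G) batch locations, standardized scale
    delta2_hat: np.ndarray             # (B, G) batch variances, standardized scale
    gamma_star: np.ndarray             # (B, G) EB-shrunk locations
    delta2_star: np.ndarray            # (B, G) EB-shrunk variances
    gamma_bar: np.ndarray              # (B,) normal prior means
    tau2: np.ndarray                   # (B,) normal prior variances
    lam: np.ndarray                    # (B,) inverse-gamma shapes
    theta: np.ndarray                  # (B,) inverse-gamma scales
    n_iter: int = 0
    converged: bool = True


@dataclass
class HarmonizationResult:
    """A corrected feature matrix plus the fitted correction parameters."""

    corrected: FeatureMatrix
    method: str
    params: object = field(default=None, repr=False)


def phantom_correct(data: FeatureMatrix,
                    phantom_ref: PhantomMeasurement,
                    phantom_other: PhantomMeasurement,
                    reference_batch: int = 2,
                    eps: float = 1e-12,
                    skip_degenerate: bool = False) -> HarmonizationResult:
    """Multiply the non-reference batch by per-feature phantom ratios.

    For each feature g the ratio ``r_g = phantom_ref_g / phantom_other_g``
    is computed and every subject *not* in ``reference_batch`` has feature
    g multiplied by ``r_g``; reference-batch subjects are unchanged.  A
    phantom value with ``|phantom_other_g| < eps`` is a degenerate
    measurement: by default an error naming the feature, or — with
    ``skip_degenerate`` — the feature passes through unchanged with a
    warning (a uniform cylinder genuinely yields ill-defined values for
    some heterogeneity features).
    """
    names = data.feature_names
    for ph in (phantom_ref, phantom_other):
        missing = set(names) - set(ph.feature_names)
        if missing:
            raise HarmonizationError(
                f"phantom '{ph.scanner_id}' missing features: {sorted(missing)}")
    ref = phantom_ref.values.reindex(names).to_numpy()
    other = phantom_other.values.reindex(names).to_numpy()

    ratios = np.ones(len(names))
    degenerate = np.abs(other) < eps
    if degenerate.any():
        bad = [names[i] for i in np.where(degenerate)[0]]
        if not skip_degenerate:
            raise DegeneratePhantomError(
                f"phantom value below eps={eps} for features {bad}")
        warnings.warn(f"degenerate phantom features passed through unchanged: {bad}")
    ratios[~degenerate] = ref[~degenerate] / other[~degenerate]

    X = data.values.to_numpy().copy()
    nonref = ~data.batch_mask(reference_batch)
    X[nonref] = X[nonref] * ratios
    return HarmonizationResult(corrected=data.with_values(X), method="phantom",
                               params={"ratios": dict(zip(names, ratios)),
                                       "reference_batch": reference_batch})


def _batch_groups(data: FeatureMatrix, min_per_batch: int = 2
                  ) -> tuple[list[int], list[np.ndarray]]:
    labels = data.batches
    if len(labels) < 2:
        raise HarmonizationError("correction requires >= 2 batches")
    masks = [data.batch_mask(b) for b in labels]
    for b, m in zip(labels, masks):
        if m.sum() < min_per_batch:
            raise HarmonizationError(
                f"batch {b} has < {min_per_batch} subjects")
    return labels, masks


def combat(data: FeatureMatrix,
           mode: str = "global",
           reference_batch: int | None = None,
           tol: float = 1e-4,
           max_iter: int = 100) -> HarmonizationResult:
    """Empirical-Bayes location-scale batch adjustment.

    Corrected values are ``Y* = (sigma_g / delta*_ig) * (Z - gamma*_ig)
    + alpha_g`` where Z is the standardized data.  The EB fixed point for
    ``(gamma*, delta*^2)`` iterates until the maximum absolute parameter
    change drops below ``tol`` or ``max_iter`` is hit (warning, not
    error).  In reference mode standardization uses the reference batch's
    own mean/variance and the reference rows are returned unchanged.
    """
    if mode not in ("global", "reference"):
        raise ValueError(f"unknown ComBat mode: {mode!r}")
    labels, masks = _batch_groups(data)
    if mode == "reference":
        if reference_batch is None or reference_batch not in labels:
            raise HarmonizationError(
                f"reference batch {reference_batch!r} not among batches {labels}")
    X = data.values.to_numpy()
    n, G = X.shape
    n_i = np.array([m.sum() for m in masks])
    B = len(labels)

    batch_means = np.stack([X[m].mean(axis=0) for m in masks])        # (B, G)
    within_var = np.stack([X[m].var(axis=0, ddof=1) for m in masks])  # (B, G)
    zero_var = np.where(within_var.min(axis=0) <= 0)[0]
    if zero_var.size:
        bad = [data.feature_names[g] for g in zero_var]
        raise HarmonizationError(f"zero within-batch variance for features {bad}")

    if mode == "global":
        alpha = (n_i / n) @ batch_means
        resid = np.vstack([X[m] - batch_means[i] for i, m in enumerate(masks)])
        sigma2 = (resid ** 2).sum(axis=0) / n
    else:
        ref_idx = labels.index(reference_batch)
        alpha = batch_means[ref_idx]
        ref_rows = X[masks[ref_idx]]
        sigma2 = ((ref_rows - alpha) ** 2).sum(axis=0) / n_i[ref_idx]
    sigma = np.sqrt(sigma2)

    Z = (X - alpha) / sigma
    gamma_hat = np.stack([Z[m].mean(axis=0) for m in masks])
    delta2_hat = np.stack([Z[m].var(axis=0, ddof=1) for m in masks])

    # method-of-moments parametric priors
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m_d = delta2_hat.mean(axis=1)
    s2_d = delta2_hat.var(axis=1, ddof=1)
    lam = (2 * s2_d + m_d ** 2) / s2_d
    theta = (m_d * s2_d + m_d ** 3) / s2_d

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        g_old, d_old = gamma_star.copy(), delta2_star.copy()
        for i, m in enumerate(masks):
            gamma_star[i] = ((n_i[i] * tau2[i] * gamma_hat[i]
                              + delta2_star[i] * gamma_bar[i])
                             / (n_i[i] * tau2[i] + delta2_star[i]))
            ss = ((Z[m] - gamma_star[i]) ** 2).sum(axis=0)
            delta2_star[i] = ((theta[i] + 0.5 * ss)
                              / (n_i[i] / 2 + lam[i] - 1))
        change = max(np.abs(gamma_star - g_old).max(),
                     np.abs(delta2_star - d_old).max())
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"ComBat EB fixed point did not converge in {max_iter} "
                      "iterations; using last iterate")

    if mode == "reference":
        ref_idx = labels.index(reference_batch)
        gamma_star[ref_idx] = 0.0
        delta2_star[ref_idx] = 1.0

    Y = np.empty_like(X)
    for i, m in enumerate(masks):
        Y[m] = (Z[m] - gamma_star[i]) / np.sqrt(delta2_star[i]) * sigma + alpha
    if mode == "reference":
        Y[masks[ref_idx]] = X[masks[ref_idx]]

    model = ComBatModel(mode=mode, reference_batch=reference_batch,
                        batches=labels, grand_mean=alpha, pooled_sd=sigma,
                        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
                        gamma_star=gamma_star, delta2_star=delta2_star,
                        gamma_bar=gamma_bar, tau2=tau2, lam=lam, theta=theta,
                        n_iter=n_iter, converged=converged)
    tag = "combat_global" if mode == "global" else f"combat_ref{reference_batch}"
    return HarmonizationResult(corrected=data.with_values(Y), method=tag,
                               params=model)


def linear_batch_remove(data: FeatureMatrix) -> HarmonizationResult:
    """Subtract least-squares additive batch effects (sum-to-zero coding).

    Per feature the fitted effect of batch b is its batch mean minus the
    unweighted average of all batch means; subtracting it equalizes every
    corrected batch mean to that unweighted average.  Idempotent.
    """
    labels, masks = _batch_groups(data, min_per_batch=1)
    X = data.values.to_numpy().copy()
    batch_means = np.stack([X[m].mean(axis=0) for m in masks])
    grand = batch_means.mean(axis=0)     # unweighted over batches
    effects = batch_means - grand
    for i, m in enumerate(masks):
        X[m] -= effects[i]
    return HarmonizationResult(
        corrected=data.with_values(X), method="linear",
        params={"batch_effects": {b: dict(zip(data.feature_names, effects[i]))
                                  for i, b in enumerate(labels)}})
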