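"""Synthetic two-scanner radiogenomic cohorts with known ground truth.

Real multi-scanner PET radiomic datasets are rarely deposited, so every
downstream stage (harmonization, batch diagnostics, association scanning)
is exercised on simulated cohorts that emulate the relevant structure:

* two batches of configurable sizes (two PET/CT scanners);
* a per-feature location-scale batch effect — batch-1 values are mapped
  ``x -> delta_g * x + gamma_g * sd_g`` with ``gamma`` expressed in
  within-batch standard-deviation units and ``delta > 0`` a scale factor,
  the model class ComBat assumes;
* heavy-tailed feature-scale heterogeneity: base magnitudes drawn
  log-uniformly over several decades, as radiomic texture features span
  many orders of magnitude;
* binary gene-mutation indicators with configurable cohort frequencies,
  kept at minor frequency >= 0.05 by resampling;
* a configurable set of true feature -> mutation couplings (mutation
  carriers get a mean shift in the causal feature, expressed per SD).

All randomness flows from a single seed through per-stage child seeds, so
the same config always yields byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, MutationMatrix, PhantomMeasurement

__all__ = ["SimulationConfig", "SimulationTruth", "generate_cohort",
           "generate_phantom_pair", "DEFAULT_CAUSAL_PAIRS"]

#: default true feature->mutation couplings (feature idx, gene idx, shift per SD)
DEFAULT_CAUSAL_PAIRS = [(0, 0, 1.5), (7, 0, 1.0), (21, 3, -1.2)]


@dataclass
class SimulationConfig:
    """Parameters of a simulated two-batch radiogenomic cohort.

    Defaults are the study conditions the package's acceptance checks run
    under: 208 subjects split evenly over two scanners, 86 texture
    features, 50 genes, a location-dominated batch effect (2-SD shift with
    per-feature scale factors spread ~20% around 1) and three causal
    feature->gene couplings.
    """

    n_subjects: int = 208
    batch_proportion: float = 0.5       # fraction of subjects in batch 1
    n_features: int = 86
    n_genes: int = 50
    gamma: float | np.ndarray = 2.0     # additive shift, within-batch SD units
    delta: float | np.ndarray = 1.0     # multiplicative scale factor, > 0
    # scanners affect different texture features to different degrees; when
    # gamma/delta are scalars, per-feature effects are drawn around them
    # (normal for gamma, log-normal for delta) — the location-scale population
    # the empirical-Bayes correction models.  Vector gamma/delta are used
    # verbatim and ignore these spreads.
    gamma_sd: float = 0.5
    delta_log_sd: float = 0.2
    scale_decades: tuple[float, float] = (-3.0, 3.0)  # log10 range of base magnitudes
    feature_scales: np.ndarray | None = None          # overrides scale_decades
    # None -> DEFAULT_CAUSAL_PAIRS restricted to the configured dimensions;
    # [] -> no feature-mutation coupling
    causal_pairs: list[tuple[int, int, float]] | None = None
    base_mutation_freq: np.ndarray | None = None      # per gene, in [0.05, 0.95]
    mutation_freq_range: tuple[float, float] = (0.08, 0.40)
    n_rare_genes: int = 0               # extra genes deliberately below the MAF floor
    rare_gene_freq: float = 0.02
    base_mean: float = 10.0             # pre-scale feature mean
    noise_sd: float = 1.0               # pre-scale residual SD
    phantom_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        n1 = int(round(self.n_subjects * self.batch_proportion))
        n2 = self.n_subjects - n1
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"each batch needs >= 2 subjects (got {n1} and {n2})")
        if np.any(np.asarray(self.delta, dtype=float) <= 0):
            raise ValueError("delta must be positive elementwise")
        if self.base_mutation_freq is not None:
            f = np.asarray(self.base_mutation_freq, dtype=float)
            if f.shape != (self.n_genes,):
                raise ValueError("base_mutation_freq length must equal n_genes")
            if np.any((f < 0.05) | (f > 0.95)):
                raise ValueError("base_mutation_freq must lie in [0.05, 0.95]")
        for g, j, _ in self.resolved_causal_pairs():
            if not (0 <= g < self.n_features and 0 <= j < self.n_genes):
                raise ValueError(f"causal pair ({g}, {j}) out of range")

    def resolved_causal_pairs(self) -> list[tuple[int, int, float]]:
        if self.causal_pairs is None:
            return [(g, j, s) for g, j, s in DEFAULT_CAUSAL_PAIRS
                    if g < self.n_features and j < self.n_genes]
        return list(self.causal_pairs)

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """A no-batch-effect, no-association scenario (gamma 0, delta 1)."""
        kw = dict(gamma=0.0, gamma_sd=0.0, delta=1.0, delta_log_sd=0.0,
                  causal_pairs=[], seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SimulationTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    gamma: np.ndarray                   # per-feature shift actually applied (SD units)
    delta: np.ndarray                   # per-feature scale factor
    feature_scales: np.ndarray          # per-feature base magnitudes
    causal_pairs: list[tuple[int, int, float]]
    mutation_freq: np.ndarray
    phantom_scale: dict[str, np.ndarray]  # per-scanner multiplicative factors
    feature_names: list[str] = field(default_factory=list)


def _broadcast(x, n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"expected scalar or length-{n} vector, got shape {arr.shape}")
    return arr.copy()


def generate_cohort(config: SimulationConfig
                    ) -> tuple[FeatureMatrix, MutationMatrix, SimulationTruth]:
    """Simulate a two-batch feature matrix, mutation matrix and ground truth.

    Feature values are ``scale_g * (mu + shift_from_mutations + eps)`` with
    Gaussian residuals; batch-1 subjects are then transformed by
    ``x -> delta_g * x + gamma_g * sd_g`` where ``sd_g`` is the empirical
    within-batch SD of the untransformed feature.  Gene columns whose
    observed minor frequency falls below 0.05 are redrawn (the rare genes
    requested via ``n_rare_genes`` are exempt — they exist to exercise the
    frequency filter).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_feat, rng_mut = [np.random.default_rng(s) for s in ss.spawn(2)]

    n = config.n_subjects
    n1 = int(round(n * config.batch_proportion))
    G = config.n_features
    if np.ndim(config.gamma) == 0 and config.gamma_sd > 0:
        gamma = rng_feat.normal(float(config.gamma), config.gamma_sd, size=G)
    else:
        gamma = _broadcast(config.gamma, G)
    if np.ndim(config.delta) == 0 and config.delta_log_sd > 0:
        delta = np.exp(rng_feat.normal(np.log(float(config.delta)),
                                       config.delta_log_sd, size=G))
    else:
        delta = _broadcast(config.delta, G)

    if config.feature_scales is not None:
        scales = _broadcast(config.feature_scales, G)
    else:
        lo, hi = config.scale_decades
        scales = 10.0 ** rng_feat.uniform(lo, hi, size=G)

    # mutations
    n_total_genes = config.n_genes + config.n_rare_genes
    if config.base_mutation_freq is not None:
        freqs = np.asarray(config.base_mutation_freq, dtype=float)
    else:
        freqs = rng_mut.uniform(*config.mutation_freq_range, size=config.n_genes)
    freqs = np.concatenate([freqs, np.full(config.n_rare_genes,
                                           config.rare_gene_freq)])
    mut = (rng_mut.random((n, n_total_genes)) < freqs).astype(int)
    for j in range(config.n_genes):  # enforce the minor-frequency floor
        for _ in range(1000):
            f = mut[:, j].mean()
            if 0.05 <= f <= 0.95:
                break
            mut[:, j] = (rng_mut.random(n) < freqs[j]).astype(int)
        else:  # pragma: no cover - unreachable for freqs in [0.08, 0.4]
            raise RuntimeError(f"could not satisfy frequency floor for gene {j}")

    # features on the pre-scale (SD ~ noise_sd) level
    base = config.base_mean + rng_feat.normal(0.0, config.noise_sd, size=(n, G))
    for g, j, slope in config.resolved_causal_pairs():
        base[:, g] += slope * config.noise_sd * mut[:, j]
    X = base * scales                   # heavy-tailed magnitude layer

    # location-scale batch effect on batch 1, gamma in within-batch SD units
    sd = X.std(axis=0, ddof=1)
    X[:n1] = delta * X[:n1] + gamma * sd

    subj = [f"S{i+1:04d}" for i in range(n)]
    fnames = [f"feature_{g+1:03d}" for g in range(G)]
    gnames = [f"gene_{j+1:03d}" for j in range(config.n_genes)]
    gnames += [f"rare_gene_{j+1:03d}" for j in range(config.n_rare_genes)]
    batch = pd.Series(np.r_[np.ones(n1, int), np.full(n - n1, 2)],
                      index=subj, name="batch")

    fm = FeatureMatrix(values=pd.DataFrame(X, index=subj, columns=fnames),
                       batch=batch)
    mm = MutationMatrix(values=pd.DataFrame(mut, index=subj, columns=gnames))
    truth = SimulationTruth(
        gamma=gamma, delta=delta, feature_scales=scales,
        causal_pairs=config.resolved_causal_pairs(),
        mutation_freq=freqs,
        phantom_scale={"scanner1": delta.copy(), "scanner2": np.ones(G)},
        feature_names=fnames,
    )
    return fm, mm, truth


def generate_phantom_pair(truth: SimulationTruth,
                          noise_sd: float = 0.0,
                          base_level: float = 10.0,
                          seed: int | None = None
                          ) -> tuple[PhantomMeasurement, PhantomMeasurement]:
    """Simulate one uniform-cylinder phantom measurement per scanner.

    The phantom vector for scanner ``s`` is the base phantom profile
    (``base_level`` x the per-feature magnitude layer) times that scanner's
    multiplicative factor, optionally perturbed by Gaussian measurement
    noise scaled to the profile.
    """
    profile = base_level * truth.feature_scales
    rng = np.random.default_rng(seed)
    out = []
    for scanner, factor in truth.phantom_scale.items():
        v = profile * factor
        if noise_sd > 0:
            v = v * (1.0 + rng.normal(0.0, noise_sd, size=v.shape))
        names = truth.feature_names or [f"feature_{g+1:03d}"
                                        for g in range(len(v))]
        out.append(PhantomMeasurement(scanner_id=scanner,
                                      values=pd.Series(v, index=names)))
    return out[0], out[1]
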