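"""Synthetic cohorts with known gene-pair structure.

The generator emulates the statistical skeleton the discovery pipeline
assumes: two latent patient clusters, a block of informative immune genes
shifted between the clusters, planted discriminative gene pairs (each
informative gene against a designated stable partner), survival hazard tied to
the planted pair score, a logistic treatment-response label, and per-sample
monotone platform distortions for cross-platform experiments.

Layout of the planted signal
----------------------------
Log-scale expression of gene g in sample s is
``mu_g + shift_g * 1[s in cluster A] + N(0, sigma^2)`` where ``shift_g`` is
``delta`` for the informative genes, ``weak_effect_frac * delta`` for a block
of weakly shifted genes, and 0 otherwise.

Informative gene baselines are evenly spaced (spacing ``0.275 * delta``) so
that neighbouring informative genes do not share discriminative partners; each
planted partner sits exactly midway between its informative gene's two cluster
means (margin ``delta / 2`` on either side); all remaining genes live in
baseline bands *outside* the discriminative window of every informative gene.
This makes the planted pairs the identifiable ground truth: a pair built from
a background gene is (near-)constant across the cohort and cannot separate the
clusters.

The weakly shifted block mimics the broad transcriptional difference between
real patient clusters: it is what the k-means stage clusters on and it
populates the DEG/IRDEG stages, but a shift of ``0.4 * delta`` is too small
for any pair built on such a gene to pass the diversity filter at the default
alpha = 0.8 (the best possible partner leaves a margin of only ``0.2 * delta``
per side), so the planted pairs remain the unique final-stage truth. Real
cohorts offer no such guarantee — see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ClinicalTable, ExpressionMatrix, GenePair, ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "apply_platform_distortion",
]

# Expression floor (log2-like scale): keeps values strictly positive so that
# power-law monotone distortions remain well defined.
_EXPR_FLOOR = 0.05


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are the study conditions used throughout the test-suite: a
    200-patient cohort on a 600-gene panel, 60 immune genes of which 10 are
    informative (shifted by ``effect`` log2 units between clusters),
    log-expression noise 0.5, exponential survival with a baseline hazard of
    0.02 per month scaled by ``exp(hazard_beta * planted_score)``, independent
    exponential censoring, and a logistic response model on the planted score.
    """

    n_samples: int = 200
    n_genes: int = 600
    n_immune: int = 60
    n_informative: int = 10
    n_weak: int = 120
    weak_effect_frac: float = 0.4
    cluster_frac: float = 0.5
    effect: float = 2.0
    noise_sd: float = 0.5
    base_hazard: float = 0.02
    hazard_beta: float = 2.0
    censor_rate: float = 0.015
    response_gamma: tuple[float, float] = (-1.5, 3.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.n_informative <= self.n_immune <= self.n_genes):
            raise ValidationError("need 0 < n_informative <= n_immune <= n_genes")
        if not (0 < self.cluster_frac < 1):
            raise ValidationError("cluster_frac must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.base_hazard <= 0 or self.censor_rate <= 0:
            raise ValidationError("hazard and censoring rates must be positive")
        if self.effect < 0:
            raise ValidationError("effect must be non-negative")
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples")
        if self.n_genes - self.n_immune < self.n_informative:
            raise ValidationError("need enough non-immune genes to host planted partners")
        n_background = self.n_genes - 2 * self.n_informative
        if not (0 <= self.n_weak <= n_background):
            raise ValidationError("n_weak must fit among the background genes")
        if not (0 <= self.weak_effect_frac < 1):
            raise ValidationError("weak_effect_frac must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted: cluster labels, planted pairs, per-sample planted score."""

    cluster_label: pd.Series
    planted_pairs: tuple[GenePair, ...]
    planted_score: pd.Series
    immune_genes: tuple[str, ...]

    def to_json(self, path) -> None:
        obj = {
            "cluster_label": self.cluster_label.to_dict(),
            "planted_pairs": [[p.gene_a, p.gene_b] for p in self.planted_pairs],
            "planted_score": {k: float(v) for k, v in self.planted_score.items()},
            "immune_genes": list(self.immune_genes),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            cluster_label=pd.Series(obj["cluster_label"], name="cluster"),
            planted_pairs=tuple(GenePair(a, b) for a, b in obj["planted_pairs"]),
            planted_score=pd.Series(obj["planted_score"], name="planted_score"),
            immune_genes=tuple(obj["immune_genes"]),
        )


def _gene_ids(cfg: SimulationConfig) -> list[str]:
    immune = [f"IMM{i + 1:04d}" for i in range(cfg.n_immune)]
    other = [f"GEN{i + 1:04d}" for i in range(cfg.n_genes - cfg.n_immune)]
    return immune + other


def _baselines(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene baseline means and cluster-A shifts; see the module docstring."""
    mu = np.empty(cfg.n_genes)
    k = cfg.n_informative
    spacing = 0.275 * cfg.effect
    start = 6.0
    mu_inf = start + spacing * np.arange(k)
    top = mu_inf[-1] + cfg.effect  # highest cluster-A mean of an informative gene
    gap = 0.3 + 0.15 * cfg.effect

    # informative immune genes
    mu[:k] = mu_inf
    # stable partners: first k non-immune genes, midway between the cluster means
    mu[cfg.n_immune : cfg.n_immune + k] = mu_inf + cfg.effect / 2.0
    # background genes (immune and non-immune): bands outside every
    # discriminative window
    bg = np.concatenate(
        [np.arange(k, cfg.n_immune), np.arange(cfg.n_immune + k, cfg.n_genes)]
    )
    low_hi = start - gap
    high_lo, high_hi = top + gap, top + gap + 1.5
    pick_low = rng.random(bg.size) < 0.6
    mu[bg] = np.where(
        pick_low,
        rng.uniform(2.0, max(low_hi, 2.2), size=bg.size),
        rng.uniform(high_lo, high_hi, size=bg.size),
    )

    shift = np.zeros(cfg.n_genes)
    shift[:k] = cfg.effect
    if cfg.n_weak:
        # weak block drawn preferentially from the immune list, so the
        # immune-high cluster (label 'A') is unambiguous in rank space
        imm_bg = np.arange(k, cfg.n_immune)
        non_bg = np.arange(cfg.n_immune + k, cfg.n_genes)
        n_imm_weak = max(cfg.n_weak - non_bg.size, min(imm_bg.size, cfg.n_weak // 2))
        weak = np.concatenate(
            [
                rng.choice(imm_bg, size=n_imm_weak, replace=False),
                rng.choice(non_bg, size=cfg.n_weak - n_imm_weak, replace=False),
            ]
        )
        shift[weak] = cfg.weak_effect_frac * cfg.effect
    return mu, shift


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Draw one cohort; fully reproducible from ``cfg.seed``.

    Returns the expression matrix (log2-like scale), the clinical table
    (time in months, event, response, covariates age/sex/stage/node) and the
    planted ground truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]

    mu, shift = _baselines(cfg, rng)
    n_a = int(round(cfg.cluster_frac * cfg.n_samples))
    n_a = min(max(n_a, 2), cfg.n_samples - 2)
    in_a = np.zeros(cfg.n_samples, dtype=bool)
    in_a[rng.permutation(cfg.n_samples)[:n_a]] = True

    x = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    x += shift[:, None] * in_a[None, :]
    np.maximum(x, _EXPR_FLOOR, out=x)

    expr = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), copy=False)

    k = cfg.n_informative
    planted = tuple(
        GenePair(genes[i], genes[cfg.n_immune + i]) for i in range(k)
    )
    score = (
        (x[:k, :] > x[cfg.n_immune : cfg.n_immune + k, :]).sum(axis=0).astype(float) / k
    )

    # survival: exponential with hazard scaled by the planted score
    rate = cfg.base_hazard * np.exp(cfg.hazard_beta * score)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / cfg.censor_rate, size=cfg.n_samples)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    g0, g1 = cfg.response_gamma
    responder = rng.random(cfg.n_samples) < expit(g0 + g1 * score)

    clin = pd.DataFrame(
        {
            "sample_id": samples,
            "time": np.maximum(time, 1e-3),
            "event": event,
            "response": np.where(responder, "responder", "non_responder"),
            "age": np.clip(np.round(rng.normal(62, 10, cfg.n_samples)), 30, 88).astype(int),
            "sex": rng.integers(0, 2, cfg.n_samples),
            "stage": rng.integers(1, 5, cfg.n_samples),
            "node": rng.integers(0, 2, cfg.n_samples),
        }
    )
    clinical = ClinicalTable(clin)

    truth = GroundTruth(
        cluster_label=pd.Series(
            np.where(in_a, "A", "B"), index=samples, name="cluster"
        ),
        planted_pairs=planted,
        planted_score=pd.Series(score, index=samples, name="planted_score"),
        immune_genes=tuple(genes[: cfg.n_immune]),
    )
    return expr, clinical, truth


def apply_platform_distortion(
    expr: ExpressionMatrix,
    mode: Literal["monotone", "noisy"] = "monotone",
    seed: int = 0,
    *,
    noise_sd: float = 0.3,
    params: tuple[float, float, float] | None = None,
) -> ExpressionMatrix:
    """Re-measure a cohort on a distorted "platform".

    ``monotone`` applies an independent strictly increasing map per sample,
    ``a + b * x**p`` with ``b, p > 0`` drawn per sample (``params=(a, b, p)``
    pins the same map for every sample; ``(0, 1, 1)`` is the identity). Within
    each sample, the relative ordering of genes — and hence every gene-pair
    score — is exactly preserved.

    ``noisy`` first adds i.i.d. Gaussian noise (sd ``noise_sd``) on the input
    scale, then applies the monotone map, so that a controlled fraction of
    pairwise orderings flips: a pair with within-sample gap g flips with
    probability ``Phi(-|g| / (noise_sd * sqrt(2)))``.
    """
    if mode not in ("monotone", "noisy"):
        raise ValidationError(f"unknown distortion mode {mode!r}")
    rng = np.random.default_rng(seed)
    x = expr.values.copy()
    if np.any(x <= 0):
        raise ValidationError("platform distortion requires strictly positive values")
    if mode == "noisy":
        if noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
        x = np.maximum(x, _EXPR_FLOOR)
    n_samples = x.shape[1]
    if params is not None:
        a = np.full(n_samples, float(params[0]))
        b = np.full(n_samples, float(params[1]))
        p = np.full(n_samples, float(params[2]))
    else:
        a = rng.uniform(-1.0, 1.0, n_samples)
        b = rng.uniform(0.5, 2.0, n_samples)
        p = rng.uniform(0.8, 1.25, n_samples)
    if np.any(b <= 0) or np.any(p <= 0):
        raise ValidationError("monotone map needs b > 0 and p > 0")
    y = a[None, :] + b[None, :] * np.power(x, p[None, :])
    return ExpressionMatrix(
        pd.DataFrame(y, index=expr.gene_ids, columns=expr.sample_ids), copy=False
    )
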