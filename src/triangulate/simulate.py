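"""Synthetic data generation for validating the latent-class estimator.

Two generators:

* :func:`simulate_binary` draws binary call matrices directly from the
  model: latent association labels A_i ~ Bernoulli(ρ) first, then the K
  calls conditionally independently with P(Y=1|A=1)=φ_k and
  P(Y=1|A=0)=ψ_k.  This is distribution-identical to drawing the pattern
  counts from a multinomial over the 2^K theoretical pattern
  probabilities (the pattern distribution marginalizes A), but it also
  yields ground-truth labels for FDR-calibration checks.

* :func:`simulate_pvalue_matrix` emulates the per-method p-value matrices
  a multi-method study produces: null p-values are Uniform(0,1), true-
  association p-values are Beta(a_k, 1) with 0 < a_k ≤ 1, independent
  across methods given the label.  Thresholding at t then gives a method
  false-positive rate of exactly t and sensitivity t^{a_k}, so a whole
  ROC curve has a known closed form.

All randomness flows from a single root seed through
``numpy.random.SeedSequence`` spawning, in documented order (labels
stream first, then one stream per method column), so reruns are
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    BinaryOutcomeMatrix,
    OperatingCharacteristics,
    fit_mle,
    tabulate_patterns,
)

__all__ = [
    "SimulatedDataset",
    "SyntheticPValueSpec",
    "StudyResult",
    "simulate_binary",
    "simulate_study",
    "simulate_pvalue_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulatedDataset:
    matrix: BinaryOutcomeMatrix
    latent: np.ndarray  # A_i in {0,1}
    truth: OperatingCharacteristics
    seed: int


@dataclass(frozen=True)
class SyntheticPValueSpec:
    """Beta(a_k, 1)-alternative p-value generator settings.

    At threshold t, method k has implied sensitivity t^{a_k} and implied
    false-positive rate t; a_k = 1 makes the method powerless.
    """

    rho: float
    shapes: tuple  # a_k per method, each in (0, 1]
    n: int
    seed: int = 0
    method_labels: tuple = ()

    def __post_init__(self):
        shapes = tuple(float(a) for a in self.shapes)
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly in (0, 1)")
        if any(not 0.0 < a <= 1.0 for a in shapes):
            raise ValueError("beta shapes a_k must lie in (0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "shapes", shapes)
        ml = tuple(self.method_labels) or tuple(
            f"method{k + 1}" for k in range(len(shapes))
        )
        if len(ml) != len(shapes):
            raise ValueError("method_labels length must match shapes")
        object.__setattr__(self, "method_labels", ml)


def _streams(seed: int, n_children: int):
    return np.random.SeedSequence(seed).spawn(n_children)


def simulate_binary(
    truth: OperatingCharacteristics, n: int, seed: int = 0
) -> SimulatedDataset:
    """Draw an n × K binary call matrix with its latent labels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss_label, ss_calls = _streams(seed, 2)
    A = (np.random.default_rng(ss_label).random(n) < truth.rho).astype(np.int8)
    rng = np.random.default_rng(ss_calls)
    u = rng.random((n, truth.K))
    rates = np.where(A[:, None] == 1, truth.phi[None, :], truth.psi[None, :])
    Y = (u < rates).astype(np.int8)
    matrix = BinaryOutcomeMatrix(Y)
    return SimulatedDataset(matrix=matrix, latent=A, truth=truth, seed=seed)


@dataclass(frozen=True)
class StudyResult:
    """Per-repeat MLEs plus their mean and SD, one column per parameter."""

    estimates: pd.DataFrame  # repeats × (2K+1)
    truth: OperatingCharacteristics
    n: int
    n_failed: int = 0

    @property
    def mean(self) -> pd.Series:
        return self.estimates.mean()

    @property
    def sd(self) -> pd.Series:
        return self.estimates.std(ddof=1)


def simulate_study(
    truth: OperatingCharacteristics,
    n: int,
    repeats: int = 100,
    seed: int = 0,
    n_starts: int = 5,
) -> StudyResult:
    """Repeat simulate → tabulate → fit and collect the estimates.

    Each repeat r uses a child seed spawned from (seed, r) for both the
    dataset and the fit's random starts.  Failed fits are excluded from
    the summary with a warning.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    K = truth.K
    cols = ["rho"] + [f"phi_{k + 1}" for k in range(K)] + [f"psi_{k + 1}" for k in range(K)]
    rows = []
    n_failed = 0
    for r in range(repeats):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        try:
            ds = simulate_binary(truth, n, seed=rep_seed)
            fit = fit_mle(tabulate_patterns(ds.matrix), n_starts=n_starts, seed=rep_seed)
            rows.append(fit.estimates.to_vector())
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            logger.warning("simulation repeat %d failed: %s", r, exc)
    if n_failed:
        logger.warning("%d of %d repeats failed", n_failed, repeats)
    df = pd.DataFrame(rows, columns=cols)
    return StudyResult(estimates=df, truth=truth, n=n, n_failed=n_failed)


def simulate_pvalue_matrix(spec: SyntheticPValueSpec):
    """Generate an n × K p-value matrix with latent labels.

    Returns ``(PValueMatrix, A)`` where A is the 0/1 latent label vector.
    """
    from .sweep import PValueMatrix  # local import avoids a cycle

    K = len(spec.shapes)
    children = _streams(spec.seed, 1 + K)
    A = (np.random.default_rng(children[0]).random(spec.n) < spec.rho).astype(np.int8)
    p = np.empty((spec.n, K))
    for k in range(1, K + 1):
        rng = np.random.default_rng(children[k])
        null_p = rng.random(spec.n)
        # Beta(a, 1) via inverse CDF u^{1/a} of a fresh uniform draw
        alt_p = rng.random(spec.n) ** (1.0 / spec.shapes[k - 1])
        p[:, k - 1] = np.where(A == 1, alt_p, null_p)
    pm = PValueMatrix(values=p, method_labels=spec.method_labels)
    return pm, A
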