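"""Specificity-weighted association scores and false discovery rates.

Given estimated operating characteristics, each pair's K binary calls are
combined into

* an association score  S_i = Σ_k Y_ik ψ′_k / Σ_k ψ′_k  — the specificity-
  weighted fraction of methods calling the pair positive, in [0, 1];
* a pair-level FDR — the Bayes posterior probability of no association
  given the call pattern, FDR_i = P(A=0 | Y_i1..Y_iK);
* per-method FDR  ψ_k(1−ρ) / (ψ_k(1−ρ) + φ_k ρ);
* an overall FDR — a weighted mean of FDR_i over the n₊ pairs with S_i > 0,
  with rank-based inverse-normal weights ω_i = Φ⁻¹((r_i − ½)/n₊) + 1 so
  that higher-scoring (lower-FDR) pairs are up-weighted.  For untied
  scores Σω_i = n₊, the number of combined discoveries.  Weights are
  clipped at 0 so the overall FDR stays a convex combination of the
  pair-level values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .model import BinaryOutcomeMatrix, OperatingCharacteristics

__all__ = [
    "ScoredPair",
    "association_score",
    "method_fdr",
    "pair_fdr",
    "rank_based_weights",
    "overall_fdr",
    "score_pairs",
    "fdr_at_discovery_count",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredPair:
    pair_label: object
    pattern: tuple
    S: float
    FDR: float
    omega: float | None = None  # defined only when S > 0


def association_score(pattern, specificity) -> float:
    """S = Σ_k Y_k ψ′_k / Σ_k ψ′_k for one call pattern."""
    y = np.asarray(pattern, dtype=float)
    spec = np.asarray(specificity, dtype=float)
    if y.shape != spec.shape:
        raise ValueError("pattern and specificity lengths differ")
    if ((spec < 0) | (spec > 1)).any():
        raise ValueError("specificities must lie in [0, 1]")
    total = spec.sum()
    if total <= 0:
        raise ValueError("all-zero specificity vector: score undefined")
    return float((y * spec).sum() / total)


def method_fdr(phi_k: float, psi_k: float, rho: float) -> float:
    """Model-based FDR of a single method: ψ(1−ρ) / (ψ(1−ρ) + φρ)."""
    num = psi_k * (1.0 - rho)
    den = num + phi_k * rho
    if den <= 0:
        raise ZeroDivisionError("method never calls positive: FDR undefined")
    return float(num / den)


def pair_fdr(pattern, oc: OperatingCharacteristics) -> float:
    """Posterior probability of no association given the call pattern."""
    y = np.asarray(pattern)
    if y.shape != (oc.K,):
        raise ValueError(f"pattern length does not match K={oc.K}")
    null = (1.0 - oc.rho) * np.prod(np.where(y == 1, oc.psi, 1.0 - oc.psi))
    alt = oc.rho * np.prod(np.where(y == 1, oc.phi, 1.0 - oc.phi))
    if null + alt <= 0:
        raise ZeroDivisionError("pattern has probability 0 under both classes")
    return float(null / (null + alt))


def rank_based_weights(scores) -> np.ndarray:
    """Inverse-normal rank weights over the pairs with S > 0.

    Returns a full-length vector with NaN where S_i = 0.  Positive pairs
    get ω_i = Φ⁻¹((r_i − 0.5)/n₊) + 1 with average ranks for ties.  By
    symmetry of the normal quantile function, untied weights sum to n₊
    exactly (the number of combined discoveries); ties can move the sum
    slightly.  The lowest-ranked weights turn negative once n₊ > 3; they
    are clipped at zero inside :func:`overall_fdr`, not here.
    """
    s = np.asarray(scores, dtype=float)
    pos = s > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive scores: weights undefined")
    ranks = rankdata(s[pos], method="average")
    w = norm.ppf((ranks - 0.5) / n_pos) + 1.0
    out = np.full(s.shape, np.nan)
    out[pos] = w
    return out


def overall_fdr(scores, fdrs) -> float:
    """Rank-weighted mean of pair FDRs over pairs with S > 0.

    Negative weights are clipped at 0 so the result stays a convex
    combination of the included pair-level FDRs.
    """
    s = np.asarray(scores, dtype=float)
    f = np.asarray(fdrs, dtype=float)
    w = rank_based_weights(s)
    pos = s > 0
    wc = w[pos]
    n_neg = int((wc < 0).sum())
    if n_neg:
        logger.info("clipping %d negative rank weights at 0", n_neg)
        wc = np.clip(wc, 0.0, None)
    return float(np.sum(wc * f[pos]) / np.sum(wc))


def score_pairs(matrix: BinaryOutcomeMatrix, oc: OperatingCharacteristics) -> pd.DataFrame:
    """Score every pair; returns the atlas table.

    Columns: pair label, per-method calls, score S, posterior FDR, rank
    weight omega (NaN when S = 0), and a significance flag FDR < 0.05.
    """
    if matrix.K != oc.K:
        raise ValueError("matrix and operating characteristics disagree on K")
    spec = oc.specificity
    y = matrix.values
    total = spec.sum()
    if total <= 0:
        raise ValueError("all-zero specificity vector: scores undefined")
    S = (y * spec).sum(axis=1) / total

    null = (1.0 - oc.rho) * np.prod(np.where(y == 1, oc.psi, 1.0 - oc.psi), axis=1)
    alt = oc.rho * np.prod(np.where(y == 1, oc.phi, 1.0 - oc.phi), axis=1)
    fdr = null / (null + alt)

    df = pd.DataFrame({"pair": list(matrix.pair_labels)})
    for k, name in enumerate(matrix.method_labels):
        df[name] = y[:, k]
    df["S"] = S
    df["FDR"] = fdr
    df["omega"] = rank_based_weights(S) if (S > 0).any() else np.nan
    df["significant"] = df["FDR"] < 0.05
    return df


def fdr_at_discovery_count(scores, fdrs, m: int) -> float:
    """Overall FDR of the top-m pairs ranked by score.

    Pairs are ordered by descending S with ties broken by ascending
    pair-level FDR; the rank-based weighting is then applied within the
    selected set.  Used to compare the combined call set against a single
    method at a matched number of discoveries.
    """
    s = np.asarray(scores, dtype=float)
    f = np.asarray(fdrs, dtype=float)
    if not 1 <= m <= len(s):
        raise ValueError("m must be between 1 and the number of pairs")
    order = np.lexsort((f, -s))[:m]
    sel_s, sel_f = s[order], f[order]
    if not (sel_s > 0).any():
        raise ValueError("no positive scores among the top-m pairs")
    keep = sel_s > 0
    return overall_fdr(sel_s[keep], sel_f[keep])
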