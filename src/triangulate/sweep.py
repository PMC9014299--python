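"""Threshold sweeps: binarize p-values, fit per threshold, build ROC tables.

Each method's p-values are turned into binary calls at a significance
threshold t (positive iff p ≤ t).  Sweeping t over a grid and re-fitting
the latent-class model at every point traces out an estimated ROC curve
per method — (ψ̂_k(t), φ̂_k(t)) with bootstrap whiskers — alongside the
per-method FDR and the combined score's discovery count and overall FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_operating_characteristics
from .model import BinaryOutcomeMatrix, fit_mle, tabulate_patterns
from .scoring import method_fdr, overall_fdr, score_pairs

__all__ = ["PValueMatrix", "DEFAULT_GRID", "drop_incomplete", "binarize", "sweep"]

logger = logging.getLogger(__name__)

#: the standard 18-point grid: 0.01–0.09 by 0.01, then 0.1–0.9 by 0.1
DEFAULT_GRID = tuple(np.round(np.arange(1, 10) * 0.01, 2)) + tuple(
    np.round(np.arange(1, 10) * 0.1, 1)
)


@dataclass(frozen=True)
class PValueMatrix:
    """n × K p-values, possibly with missing entries (NaN)."""

    values: np.ndarray
    pair_labels: tuple = ()
    method_labels: tuple = ()

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be 2-D (n, K)")
        finite = vals[~np.isnan(vals)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)
        n, K = vals.shape
        pl = tuple(self.pair_labels) or tuple(f"pair{i}" for i in range(n))
        ml = tuple(self.method_labels) or tuple(f"method{k + 1}" for k in range(K))
        if len(pl) != n or len(ml) != K:
            raise ValueError("label lengths must match the matrix shape")
        object.__setattr__(self, "pair_labels", pl)
        object.__setattr__(self, "method_labels", ml)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


def drop_incomplete(pmatrix: PValueMatrix) -> PValueMatrix:
    """Keep only rows with all K p-values present (complete-case filter)."""
    keep = ~np.isnan(pmatrix.values).any(axis=1)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no complete rows remain after dropping missing values")
    if n_dropped:
        logger.info("dropped %d of %d rows with missing p-values", n_dropped, pmatrix.n)
    return PValueMatrix(
        values=pmatrix.values[keep],
        pair_labels=tuple(l for l, k in zip(pmatrix.pair_labels, keep) if k),
        method_labels=pmatrix.method_labels,
    )


def binarize(pmatrix: PValueMatrix, t: float) -> BinaryOutcomeMatrix:
    """Binary calls Y_ik = 1 iff p_ik ≤ t (inclusive threshold)."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    if np.isnan(pmatrix.values).any():
        raise ValueError("matrix has missing entries; run drop_incomplete first")
    return BinaryOutcomeMatrix(
        values=(pmatrix.values <= t).astype(np.int8),
        pair_labels=pmatrix.pair_labels,
        method_labels=pmatrix.method_labels,
    )


def sweep(
    pmatrix: PValueMatrix,
    grid=DEFAULT_GRID,
    B: int = 99,
    seed: int = 0,
    n_starts: int = 20,
) -> pd.DataFrame:
    """Fit the model at every threshold and assemble the ROC table.

    Per (threshold, method) row: sensitivity and false-positive-rate
    estimates with bootstrap SEs, ρ̂, the method FDR, and the raw
    positive-call count.  One extra "combined" row per threshold carries
    the discovery count n₊ and overall FDR of the specificity-weighted
    score.  Thresholds where the fit sits on a boundary (ρ̂ outside
    [0.01, 0.99] or any φ̂_k < ψ̂_k) are flagged unstable, not dropped.
    """
    grid = sorted(float(t) for t in grid)
    if not grid or grid[0] <= 0 or grid[-1] >= 1:
        raise ValueError("threshold grid must be nonempty within (0, 1)")
    pmatrix = drop_incomplete(pmatrix)

    rows = []
    for j, t in enumerate(grid):
        t_seed = int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31))
        binary = binarize(pmatrix, t)
        calls = binary.values.sum(axis=0)
        table = tabulate_patterns(binary)
        fit = fit_mle(table, n_starts=n_starts, seed=t_seed)
        oc = fit.estimates
        unstable = bool(
            oc.rho < 0.01 or oc.rho > 0.99 or (oc.phi < oc.psi).any() or not fit.converged
        )
        boot = bootstrap_operating_characteristics(
            binary, B=B, seed=t_seed, point=oc
        )
        K = binary.K
        phi_se = boot.se[1 : K + 1]
        psi_se = boot.se[K + 1 :]
        for k, name in enumerate(binary.method_labels):
            try:
                m_fdr = method_fdr(oc.phi[k], oc.psi[k], oc.rho)
            except ZeroDivisionError:
                m_fdr = np.nan
            rows.append(
                dict(
                    threshold=t, method=name, tpr=oc.phi[k], tpr_se=phi_se[k],
                    fpr=oc.psi[k], fpr_se=psi_se[k], rho=oc.rho, fdr=m_fdr,
                    n_calls=int(calls[k]), n_pos=np.nan, unstable=unstable,
                )
            )
        scored = score_pairs(binary, oc)
        pos = scored["S"] > 0
        comb_fdr = (
            overall_fdr(scored["S"].to_numpy(), scored["FDR"].to_numpy())
            if pos.any()
            else np.nan
        )
        rows.append(
            dict(
                threshold=t, method="combined", tpr=np.nan, tpr_se=np.nan,
                fpr=np.nan, fpr_se=np.nan, rho=oc.rho, fdr=comb_fdr,
                n_calls=np.nan, n_pos=int(pos.sum()), unstable=unstable,
            )
        )
    return pd.DataFrame(rows)
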