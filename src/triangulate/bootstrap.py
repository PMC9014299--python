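"""Nonparametric bootstrap standard errors for the operating characteristics.

Hypothesis pairs (rows) are resampled with replacement; methods (columns)
never are.  Because the likelihood depends on the data only through the
pattern counts, resampling n rows with replacement is carried out as a
single multinomial draw over the empirical pattern distribution, which is
exactly equivalent and O(2^K) per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    BinaryOutcomeMatrix,
    OperatingCharacteristics,
    PatternTable,
    fit_mle,
    tabulate_patterns,
)

__all__ = ["BootstrapSummary", "bootstrap_operating_characteristics"]

logger = logging.getLogger(__name__)

#: parameter order of the replicate-estimate columns
def _param_names(K: int) -> list[str]:
    return ["rho"] + [f"phi_{k + 1}" for k in range(K)] + [f"psi_{k + 1}" for k in range(K)]


@dataclass(frozen=True)
class BootstrapSummary:
    """Point estimates plus replicate table and per-parameter mean/SE."""

    B: int
    point: OperatingCharacteristics
    replicate_estimates: np.ndarray  # B_effective × (2K+1)
    mean: np.ndarray
    se: np.ndarray
    n_failed: int = 0

    @property
    def effective_B(self) -> int:
        return self.replicate_estimates.shape[0]

    @property
    def param_names(self) -> list[str]:
        return _param_names(self.point.K)

    def to_flat_dict(self) -> dict:
        out = {"B": self.B, "effective_B": self.effective_B, "n_failed": self.n_failed}
        for name, m, s in zip(self.param_names, self.mean, self.se):
            out[f"{name}_boot_mean"] = float(m)
            out[f"{name}_boot_se"] = float(s)
        return out


def bootstrap_operating_characteristics(
    matrix: BinaryOutcomeMatrix,
    B: int = 99,
    seed: int = 0,
    n_starts: int = 5,
    point: OperatingCharacteristics | None = None,
) -> BootstrapSummary:
    """Bootstrap SEs of (ρ, φ, ψ) over B row-resampled replicates.

    Each replicate r draws its pattern counts from Multinomial(n, empirical
    pattern frequencies), refits by :func:`fit_mle` with a reduced start
    budget (moment start + ``n_starts − 1`` random), and applies the
    label-switching convention.  Replicate r is seeded deterministically
    from (seed, r), so individual replicates are reproducible and the
    summary is bit-identical across reruns.  Failed replicates are dropped
    from the SE with a warning rather than aborting.
    """
    if B < 1:
        raise ValueError("need B >= 1 bootstrap replicates")
    table = tabulate_patterns(matrix)
    if point is None:
        point = fit_mle(table, seed=seed).estimates

    n = table.n
    freq = table.counts / n
    estimates = []
    n_failed = 0
    for r in range(B):
        rep_seed = np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31)
        rng = np.random.default_rng(rep_seed)
        counts = rng.multinomial(n, freq)
        try:
            # fit seed is shared across replicates so identical resamples
            # yield identical fits (only the resampling stream varies with r)
            fit = fit_mle(PatternTable(counts, table.K), n_starts=n_starts, seed=seed)
            estimates.append(fit.estimates.to_vector())
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", r, exc)

    if n_failed:
        logger.warning("%d of %d bootstrap replicates failed; effective B=%d",
                       n_failed, B, B - n_failed)
    rep = np.asarray(estimates)
    return BootstrapSummary(
        B=B,
        point=point,
        replicate_estimates=rep,
        mean=rep.mean(axis=0),
        se=rep.std(axis=0, ddof=1) if rep.shape[0] > 1 else np.zeros(rep.shape[1]),
        n_failed=n_failed,
    )
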