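"""Two-class latent class model for K conditionally independent binary tests.

The model: each hypothesis pair i has an unobserved association status
A_i ∈ {0, 1} with prevalence ρ = P(A=1).  Method k calls the pair positive
(Y_ik = 1) with sensitivity φ_k = P(Y=1|A=1) and false-positive rate
ψ_k = P(Y=1|A=0).  Conditional on A, the K calls are independent, so the
probability of an outcome pattern y = (y_1, ..., y_K) is

    P(y) = ρ ∏_k φ_k^{y_k} (1−φ_k)^{1−y_k} + (1−ρ) ∏_k ψ_k^{y_k} (1−ψ_k)^{1−y_k}

With K ≥ 3 the 2^K − 1 pattern degrees of freedom exceed the 2K + 1
parameters and the model is identifiable without any gold standard.  The
likelihood depends on the data only through the pattern counts, so all
fitting operates on a :class:`PatternTable` and costs O(2^K) per
evaluation regardless of n.

The likelihood is invariant under swapping the latent classes,
(ρ, φ, ψ) → (1−ρ, ψ, φ); estimates are reported under the convention
Σ_k (φ_k − ψ_k) ≥ 0 (nonnegative average Youden index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "BinaryOutcomeMatrix",
    "PatternTable",
    "OperatingCharacteristics",
    "FitResult",
    "IdentifiabilityError",
    "DegenerateDataWarning",
    "tabulate_patterns",
    "pattern_probability",
    "log_likelihood",
    "fit_mle",
    "fit_em",
    "resolve_label_switching",
]

#: parameters and pattern probabilities are clipped to [EPS, 1 − EPS]
#: inside the likelihood so degenerate data cannot produce log(0)
EPS = 1e-10


class IdentifiabilityError(ValueError):
    """Raised when the model is not identifiable (K < 3)."""


class DegenerateDataWarning(UserWarning):
    """Emitted when the data cannot pin down interior parameter values."""


@dataclass(frozen=True)
class BinaryOutcomeMatrix:
    """n × K matrix of binary calls Y_ik, one row per hypothesis pair.

    Parameters
    ----------
    values
        Array of shape (n, K) with entries in {0, 1}; no missingness.
    pair_labels
        Length-n identifiers for the hypothesis pairs, e.g. ``(trait,
        tissue)`` tuples or opaque strings.
    method_labels
        Length-K method names.
    """

    values: np.ndarray
    pair_labels: tuple = ()
    method_labels: tuple = ()

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D array of shape (n, K)")
        if vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("need n >= 1 rows and K >= 1 methods")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("entries must be exactly 0 or 1, no missing values")
        object.__setattr__(self, "values", vals.astype(np.int8))
        n, K = vals.shape
        pl = tuple(self.pair_labels) or tuple(f"pair{i}" for i in range(n))
        ml = tuple(self.method_labels) or tuple(f"method{k + 1}" for k in range(K))
        if len(pl) != n:
            raise ValueError(f"pair_labels has length {len(pl)}, expected {n}")
        if len(ml) != K:
            raise ValueError(f"method_labels has length {len(ml)}, expected {K}")
        object.__setattr__(self, "pair_labels", pl)
        object.__setattr__(self, "method_labels", ml)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


def _all_patterns(K: int) -> np.ndarray:
    """All 2^K bit patterns, shape (2^K, K); row index is the big-endian int."""
    idx = np.arange(2**K)
    return (idx[:, None] >> np.arange(K - 1, -1, -1)[None, :]) & 1


def _pattern_index(bits: np.ndarray) -> np.ndarray:
    K = bits.shape[-1]
    weights = 1 << np.arange(K - 1, -1, -1)
    return bits @ weights


@dataclass(frozen=True)
class PatternTable:
    """Counts of the 2^K outcome patterns; sufficient statistic for the fit.

    ``counts[j]`` is the number of rows whose pattern, read as a big-endian
    binary integer, equals j.
    """

    counts: np.ndarray
    K: int

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (2**self.K,):
            raise ValueError(f"counts must have length 2^K = {2 ** self.K}")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict:
        """Map each K-bit tuple to its count (all 2^K keys present)."""
        pats = _all_patterns(self.K)
        return {tuple(int(b) for b in row): int(c) for row, c in zip(pats, self.counts)}


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Prevalence ρ plus per-method sensitivity φ_k and false-positive rate ψ_k."""

    rho: float
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        if phi.shape != psi.shape or phi.ndim != 1:
            raise ValueError("phi and psi must be 1-D vectors of equal length")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        for name, v in (("phi", phi), ("psi", psi)):
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "psi", psi)

    @property
    def K(self) -> int:
        return self.phi.shape[0]

    @property
    def specificity(self) -> np.ndarray:
        """ψ′_k = 1 − ψ_k."""
        return 1.0 - self.psi

    @property
    def false_negative_rate(self) -> np.ndarray:
        """φ′_k = 1 − φ_k."""
        return 1.0 - self.phi

    def swapped(self) -> "OperatingCharacteristics":
        """The label-swapped parameterization (1−ρ, ψ, φ); same likelihood."""
        return OperatingCharacteristics(1.0 - self.rho, self.psi.copy(), self.phi.copy())

    def to_vector(self) -> np.ndarray:
        """Flatten to (ρ, φ_1..φ_K, ψ_1..ψ_K)."""
        return np.concatenate([[self.rho], self.phi, self.psi])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "OperatingCharacteristics":
        v = np.asarray(v, dtype=float)
        K = (len(v) - 1) // 2
        return cls(float(v[0]), v[1 : K + 1], v[K + 1 :])


@dataclass(frozen=True)
class FitResult:
    estimates: OperatingCharacteristics
    log_likelihood: float
    converged: bool
    n_starts: int
    start_seed: int
    label_swapped: bool = False

    def to_flat_dict(self) -> dict:
        oc = self.estimates
        out = {"rho": oc.rho}
        for k in range(oc.K):
            out[f"phi_{k + 1}"] = float(oc.phi[k])
            out[f"psi_{k + 1}"] = float(oc.psi[k])
            out[f"specificity_{k + 1}"] = float(1.0 - oc.psi[k])
        out.update(
            log_likelihood=self.log_likelihood,
            converged=self.converged,
            n_starts=self.n_starts,
            start_seed=self.start_seed,
            label_swapped=self.label_swapped,
        )
        return out


def tabulate_patterns(matrix: BinaryOutcomeMatrix) -> PatternTable:
    """Count the occurrences of each of the 2^K outcome patterns."""
    idx = _pattern_index(matrix.values.astype(np.int64))
    counts = np.bincount(idx, minlength=2**matrix.K)
    return PatternTable(counts, matrix.K)


def pattern_probability(oc: OperatingCharacteristics, pattern) -> float:
    """Probability of one K-bit outcome pattern under the mixture model."""
    y = np.asarray(pattern)
    if y.shape != (oc.K,):
        raise ValueError(f"pattern length {y.shape} does not match K={oc.K}")
    a = np.prod(np.where(y == 1, oc.phi, 1.0 - oc.phi))
    b = np.prod(np.where(y == 1, oc.psi, 1.0 - oc.psi))
    return float(oc.rho * a + (1.0 - oc.rho) * b)


def _pattern_probs(rho: float, phi: np.ndarray, psi: np.ndarray, pats: np.ndarray):
    """Vector of all 2^K pattern probabilities plus the two class components."""
    a = np.prod(np.where(pats == 1, phi, 1.0 - phi), axis=1)
    b = np.prod(np.where(pats == 1, psi, 1.0 - psi), axis=1)
    return rho * a + (1.0 - rho) * b, a, b


def log_likelihood(oc: OperatingCharacteristics, table: PatternTable) -> float:
    """Multinomial log-likelihood Σ_patterns count · log P(pattern)."""
    if oc.K != table.K:
        raise ValueError(f"oc has K={oc.K} but table has K={table.K}")
    pats = _all_patterns(table.K)
    p, _, _ = _pattern_probs(oc.rho, oc.phi, oc.psi, pats)
    return float(table.counts @ np.log(np.clip(p, EPS, 1.0)))


def resolve_label_switching(result: FitResult) -> FitResult:
    """Apply the convention Σ_k(φ_k − ψ_k) ≥ 0, swapping classes if needed."""
    oc = result.estimates
    if float(np.sum(oc.phi - oc.psi)) < 0.0:
        return replace(result, estimates=oc.swapped(), label_swapped=True)
    return result


def _check_fittable(table: PatternTable) -> None:
    if table.K < 3:
        raise IdentifiabilityError(
            f"K={table.K} methods give 2^K-1={2 ** table.K - 1} degrees of freedom, "
            f"fewer than the 2K+1={2 * table.K + 1} parameters; need K >= 3"
        )
    if table.n < 2 * table.K + 1:
        warnings.warn(
            f"n={table.n} is below the parameter count {2 * table.K + 1}; "
            "estimates will be unstable",
            DegenerateDataWarning,
            stacklevel=3,
        )
    if (table.counts > 0).sum() <= 1:
        warnings.warn(
            "all rows share a single outcome pattern; estimates lie on the "
            "parameter-space boundary",
            DegenerateDataWarning,
            stacklevel=3,
        )


def _nll_and_grad(z: np.ndarray, counts: np.ndarray, pats: np.ndarray):
    """Negative log-likelihood and gradient on the logit scale.

    z = logit(ρ, φ_1..K, ψ_1..K).  The chain rule through the logistic map
    multiplies each probability-scale gradient entry by p(1−p).
    """
    K = pats.shape[1]
    theta = np.clip(expit(z), EPS, 1.0 - EPS)
    rho, phi, psi = theta[0], theta[1 : K + 1], theta[K + 1 :]
    p, a, b = _pattern_probs(rho, phi, psi, pats)
    p = np.clip(p, EPS, 1.0)
    w = counts / p  # c_j / P_j
    nll = -float(counts @ np.log(p))

    g = np.empty_like(theta)
    g[0] = -float(w @ (a - b))
    # d a_j / d phi_k = a_j * (y_jk/phi_k − (1−y_jk)/(1−phi_k))
    da = np.where(pats == 1, 1.0 / phi, -1.0 / (1.0 - phi))
    db = np.where(pats == 1, 1.0 / psi, -1.0 / (1.0 - psi))
    g[1 : K + 1] = -rho * ((w * a) @ da)
    g[K + 1 :] = -(1.0 - rho) * ((w * b) @ db)
    return nll, g * theta * (1.0 - theta)


def _moment_start(table: PatternTable) -> np.ndarray:
    """Heuristic start: ρ=0.5, φ_k/ψ_k bracketing each observed positive rate."""
    pats = _all_patterns(table.K)
    rate = (table.counts @ pats) / max(table.n, 1)
    phi0 = np.clip(rate + 0.15, 0.01, 0.99)
    psi0 = np.clip(rate - 0.15, 0.01, 0.99)
    return np.concatenate([[0.5], phi0, psi0])


def fit_mle(
    table: PatternTable,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood fit by quasi-Newton (L-BFGS-B) on the logit scale.

    One moment-based start plus ``n_starts − 1`` uniform-random starts;
    the best local optimum is kept and the label-switching convention
    Σ_k(φ_k − ψ_k) ≥ 0 is applied.

    Parameters
    ----------
    table
        Pattern counts from :func:`tabulate_patterns`.
    n_starts
        Total number of optimizer starts (>= 1).
    seed
        Seeds the random starts; the fit is deterministic given (table, seed).
    tol
        Gradient tolerance passed to the optimizer.
    """
    _check_fittable(table)
    pats = _all_patterns(table.K)
    counts = table.counts.astype(float)
    rng = np.random.default_rng(seed)

    starts = [_moment_start(table)]
    for _ in range(max(n_starts, 1) - 1):
        starts.append(rng.uniform(0.05, 0.95, size=2 * table.K + 1))

    best = None
    any_converged = False
    for s in starts:
        res = minimize(
            _nll_and_grad,
            logit(np.clip(s, 0.01, 0.99)),
            args=(counts, pats),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": tol, "ftol": 1e-13, "maxiter": 500},
        )
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res

    theta = np.clip(expit(best.x), EPS, 1.0 - EPS)
    oc = OperatingCharacteristics.from_vector(theta)
    result = FitResult(
        estimates=oc,
        log_likelihood=-float(best.fun),
        converged=bool(any_converged),
        n_starts=len(starts),
        start_seed=seed,
    )
    return resolve_label_switching(result)


def _em_from(
    theta0: np.ndarray, counts: np.ndarray, pats: np.ndarray, tol: float, max_iter: int
):
    """Run EM from one start; returns (theta, loglik, converged)."""
    K = pats.shape[1]
    theta = np.clip(theta0, EPS, 1.0 - EPS)
    n = counts.sum()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        rho, phi, psi = theta[0], theta[1 : K + 1], theta[K + 1 :]
        p, a, b = _pattern_probs(rho, phi, psi, pats)
        p = np.clip(p, EPS, 1.0)
        ll = float(counts @ np.log(p))
        # E-step: responsibility of the associated class per pattern
        r = rho * a / p
        # M-step: weighted positive-call fractions in each latent class
        w1 = counts * r
        w0 = counts * (1.0 - r)
        s1, s0 = w1.sum(), w0.sum()
        rho_new = s1 / n
        phi_new = (w1 @ pats) / s1 if s1 > 0 else phi
        psi_new = (w0 @ pats) / s0 if s0 > 0 else psi
        theta = np.clip(np.concatenate([[rho_new], phi_new, psi_new]), EPS, 1.0 - EPS)
        if ll - ll_old < tol and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
    rho, phi, psi = theta[0], theta[1 : K + 1], theta[K + 1 :]
    p, _, _ = _pattern_probs(rho, phi, psi, pats)
    ll = float(counts @ np.log(np.clip(p, EPS, 1.0)))
    return theta, ll, converged


def fit_em(
    table: PatternTable,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """EM fit of the same likelihood; independent cross-check of fit_mle.

    The E-step computes each pattern's posterior responsibility for the
    associated class; the M-step replaces (ρ, φ, ψ) with responsibility-
    weighted frequencies.  The log-likelihood is non-decreasing across
    iterations; iteration stops when the per-step gain drops below ``tol``.
    Multi-start mirrors :func:`fit_mle` so both can find the global optimum.
    """
    _check_fittable(table)
    pats = _all_patterns(table.K)
    counts = table.counts.astype(float)
    rng = np.random.default_rng(seed)

    starts = [_moment_start(table)]
    for _ in range(max(n_starts, 1) - 1):
        starts.append(rng.uniform(0.05, 0.95, size=2 * table.K + 1))

    best_theta, best_ll, best_conv = None, -np.inf, False
    for s in starts:
        theta, ll, conv = _em_from(s, counts, pats, tol, max_iter)
        if ll > best_ll:
            best_theta, best_ll, best_conv = theta, ll, conv

    oc = OperatingCharacteristics.from_vector(best_theta)
    result = FitResult(
        estimates=oc,
        log_likelihood=best_ll,
        converged=best_conv,
        n_starts=len(starts),
        start_seed=seed,
    )
    return resolve_label_switching(result)
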