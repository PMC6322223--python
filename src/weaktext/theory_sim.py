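"""Weak-supervision loss-bound theory and its empirical verification.

Model.  A binary task (labels in {+1, −1}, uniform marginals) is labeled by
an m-rule labeling function whose i-th rule is correct with probability
φ_i.  Under independence the joint of the rule output Λ and the truth Y is

    p_φ(Λ, Y) = (1/2) Π_i [ φ_i · 1{Λ=Y} + (1 − φ_i) · 1{Λ≠Y} ],

so the agreement probability collapses to a single number

    q = P(Λ = Y) = Π φ_i / (Π φ_i + Π (1 − φ_i)).

Losses.  For a weight vector w, features f(d) and ridge coefficient ρ, the
true-label empirical loss is the regularized logistic loss

    L(w) = (1/|D|) Σ_d log(1 + exp(−wᵀf(d) · Y_d)) + ρ‖w‖²,

and the weak-label loss replaces the per-document term with its conditional
expectation given the observed weak label Λ_d:

    L_φ(w) = (1/|D|) Σ_d [ q·log(1+exp(−wᵀf(d)Λ_d))
                           + (1−q)·log(1+exp(+wᵀf(d)Λ_d)) ] + ρ‖w‖².

Bound.  With |D| = ε⁻² training documents the difference obeys
|L(w) − L_φ(w)| ≤ c‖w‖ε/2 for a constant c, and the ridge optimum satisfies
‖w‖ ≤ 1/(2ρ).  ``verify_bound`` checks this empirically: it simulates data
from the model above, fits w by minimizing the weak loss with deterministic
gradient descent, and reports the observed gap, the implied constant
ĉ = 2|L − L_φ|/(‖w‖ε), and the norm condition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RuleAccuracyProfile",
    "LossSpec",
    "BoundReport",
    "agreement_probability",
    "sample_weak_labels",
    "weak_loss",
    "true_loss",
    "fit_weak_logistic",
    "verify_bound",
]


@dataclass(frozen=True)
class RuleAccuracyProfile:
    """Per-rule correctness probabilities φ = (φ_1..φ_m)."""

    phi: Tuple[float, ...]

    def __post_init__(self) -> None:
        phi = tuple(float(p) for p in self.phi)
        object.__setattr__(self, "phi", phi)
        if len(phi) < 1:
            raise ValueError("at least one rule accuracy required")
        if any(not (0.0 < p < 1.0) for p in phi):
            raise ValueError("each rule accuracy must lie in (0, 1)")

    @property
    def m(self) -> int:
        return len(self.phi)


def _as_profile(phi) -> RuleAccuracyProfile:
    if isinstance(phi, RuleAccuracyProfile):
        return phi
    if isinstance(phi, (int, float)):
        return RuleAccuracyProfile((float(phi),))
    return RuleAccuracyProfile(tuple(phi))


def agreement_probability(phi) -> float:
    """P(Λ = Y): the normalized product Πφ / (Πφ + Π(1−φ)).

    Symmetric in the φ_i and strictly increasing in each φ_i above 0.5.
    Computed in log space for numerical robustness at extreme accuracies.
    """
    profile = _as_profile(phi)
    log_agree = sum(math.log(p) for p in profile.phi)
    log_disagree = sum(math.log1p(-p) for p in profile.phi)
    # q = e^a / (e^a + e^b) = sigmoid(a - b)
    delta = log_agree - log_disagree
    if delta >= 0:
        return 1.0 / (1.0 + math.exp(-delta))
    return math.exp(delta) / (1.0 + math.exp(delta))


def sample_weak_labels(true_labels: Sequence[int], phi, seed: int) -> np.ndarray:
    """Flip each ±1 label independently with probability 1 − q.

    Implements the weak-label channel: Λ = Y with probability
    q = agreement_probability(φ), else Λ = −Y.  Reproducible by seed.
    """
    y = np.asarray(true_labels)
    if y.size and not np.isin(y, (-1, 1)).all():
        raise ValueError("true labels must be +1/-1 for the binary weak-label model")
    q = agreement_probability(phi)
    rng = np.random.default_rng(seed)
    flips = rng.random(y.size) >= q
    out = y.copy()
    out[flips] = -out[flips]
    return out


@dataclass
class LossSpec:
    """Weight vector, ridge coefficient and the feature map dimension."""

    w: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.rho <= 0:
            raise ValueError("the ridge coefficient rho must be positive")


def _log1pexp(u: np.ndarray) -> np.ndarray:
    """log(1 + exp(u)) computed stably."""
    return np.logaddexp(0.0, u)


def true_loss(features: np.ndarray, true_labels: Sequence[int], spec: LossSpec) -> float:
    """Regularized logistic loss under the true labels."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(true_labels, dtype=float)
    s = X @ spec.w
    return float(np.mean(_log1pexp(-s * y)) + spec.rho * spec.w @ spec.w)


def weak_loss(
    features: np.ndarray,
    weak_labels: Sequence[int],
    phi,
    spec: LossSpec,
) -> float:
    """Weak-label loss: per-document conditional expectation given Λ.

    q·log(1+exp(−wᵀx·Λ)) + (1−q)·log(1+exp(+wᵀx·Λ)), averaged, plus ρ‖w‖².
    Collapses to the true-label loss when q = 1 and Λ = Y.
    """
    X = np.asarray(features, dtype=float)
    lam = np.asarray(weak_labels, dtype=float)
    q = agreement_probability(phi)
    s = X @ spec.w
    per_doc = q * _log1pexp(-s * lam) + (1.0 - q) * _log1pexp(s * lam)
    return float(np.mean(per_doc) + spec.rho * spec.w @ spec.w)


# ---------------------------------------------------------------------------
# Fitting and bound verification
# ---------------------------------------------------------------------------

def _weak_loss_grad(
    X: np.ndarray, lam: np.ndarray, q: float, w: np.ndarray, rho: float
) -> np.ndarray:
    s = X @ w
    sig = 1.0 / (1.0 + np.exp(-np.clip(s * lam, -500, 500)))
    # d/ds [q·l(-sΛ) + (1-q)·l(sΛ)] = Λ·(sig - q)
    coeff = lam * (sig - q)
    return X.T @ coeff / X.shape[0] + 2.0 * rho * w


def fit_weak_logistic(
    features: np.ndarray,
    weak_labels: Sequence[int],
    phi,
    rho: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> Tuple[np.ndarray, bool]:
    """Minimize the (convex) weak loss by gradient descent with backtracking.

    Deterministic: no randomness, fixed zero initialization.  Returns the
    fitted weight vector and a convergence flag (gradient norm below tol).
    """
    X = np.asarray(features, dtype=float)
    lam = np.asarray(weak_labels, dtype=float)
    q = agreement_probability(phi)
    w = np.zeros(X.shape[1])
    spec = LossSpec(w=w, rho=rho)
    loss = weak_loss(X, lam, phi, spec)
    step = 1.0
    converged = False
    for _ in range(max_iter):
        g = _weak_loss_grad(X, lam, q, w, rho)
        gnorm = float(np.linalg.norm(g))
        if gnorm < tol:
            converged = True
            break
        # backtracking line search on the Armijo condition
        step = min(step * 2.0, 1e3)
        while step > 1e-16:
            w_new = w - step * g
            new_loss = weak_loss(X, lam, phi, LossSpec(w=w_new, rho=rho))
            if new_loss <= loss - 0.5 * step * gnorm**2:
                break
            step *= 0.5
        else:
            break
        w, loss = w_new, new_loss
    return w, converged


@dataclass
class BoundReport:
    """One grid cell's empirical check of |L − L_φ| ≤ c‖w‖ε/2."""

    n_docs: int
    phi: Tuple[float, ...]
    rho: float
    epsilon: float
    observed_gap: float
    w_norm: float
    c_hat: float
    norm_bound: float
    norm_ok: bool
    converged: bool
    rep: int
    seed: int

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_docs": self.n_docs,
            "phi": list(self.phi),
            "rho": self.rho,
            "epsilon": self.epsilon,
            "observed_gap": self.observed_gap,
            "w_norm": self.w_norm,
            "c_hat": self.c_hat,
            "norm_bound": self.norm_bound,
            "norm_ok": self.norm_ok,
            "converged": self.converged,
            "rep": self.rep,
            "seed": self.seed,
        }


def _simulate_dataset(
    n: int, phi, dim: int, seed: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (features, weak labels, true labels) from the weak-label model.

    Features are standard Gaussian; the rule output Λ is a logistic function
    of a fixed direction through the features (so the weak-loss fit has
    something to learn); the true label Y is then drawn from Λ through the
    accuracy channel P(Y = Λ) = q — exactly the joint p_φ with uniform
    marginals that the bound assumes.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, dim))
    beta = np.zeros(dim)
    beta[: min(3, dim)] = 1.0
    logits = X @ beta
    lam = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-logits)), 1, -1)
    q = agreement_probability(phi)
    flips = rng.random(n) >= q
    y = np.where(flips, -lam, lam)
    return X, lam, y


def verify_bound(
    n_docs_grid: Sequence[int] = (400, 1600, 6400),
    phi=(0.9,),
    rho: float = 0.1,
    n_rep: int = 20,
    dim: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> List[BoundReport]:
    """Empirically verify the weak/true loss gap bound on a grid of |D|.

    For each grid cell and repetition: simulate data from the weak-label
    model, fit w by minimizing the weak loss, evaluate both losses at the
    fitted w, and report the gap, the implied constant ĉ = 2·gap/(‖w‖·ε)
    with ε = |D|^(−1/2), and the ‖w‖ ≤ 1/(2ρ) check.  Non-convergent fits
    are flagged in the report, never silently dropped.
    """
    if not n_docs_grid:
        raise ValueError("the |D| grid must be non-empty")
    profile = _as_profile(phi)
    reports: List[BoundReport] = []
    base = np.random.default_rng(seed)
    for n in n_docs_grid:
        eps = 1.0 / math.sqrt(n)
        for rep in range(n_rep):
            cell_seed = int(base.integers(0, 2**31 - 1))
            X, lam, y = _simulate_dataset(n, profile, dim, cell_seed)
            w, converged = fit_weak_logistic(
                X, lam, profile, rho, tol=tol, max_iter=max_iter
            )
            spec = LossSpec(w=w, rho=rho)
            gap = abs(true_loss(X, y, spec) - weak_loss(X, lam, profile, spec))
            wn = float(np.linalg.norm(w))
            c_hat = 2.0 * gap / (wn * eps) if wn > 0 else 0.0
            reports.append(
                BoundReport(
                    n_docs=n,
                    phi=profile.phi,
                    rho=rho,
                    epsilon=eps,
                    observed_gap=gap,
                    w_norm=wn,
                    c_hat=c_hat,
                    norm_bound=1.0 / (2.0 * rho),
                    norm_ok=wn <= 1.0 / (2.0 * rho) + 1e-6,
                    converged=converged,
                    rep=rep,
                    seed=cell_seed,
                )
            )
    return reports


def bound_summary(reports: Sequence[BoundReport]) -> Dict[int, Dict[str, float]]:
    """Median gap and ĉ per |D| grid value."""
    out: Dict[int, Dict[str, float]] = {}
    for n in sorted({r.n_docs for r in reports}):
        cell = [r for r in reports if r.n_docs == n]
        out[n] = {
            "median_gap": float(np.median([r.observed_gap for r in cell])),
            "median_c_hat": float(np.median([r.c_hat for r in cell])),
            "max_w_norm": float(max(r.w_norm for r in cell)),
            "all_norm_ok": all(r.norm_ok for r in cell),
            "all_converged": all(r.converged for r in cell),
        }
    return out


def save_bound_reports(reports: Sequence[BoundReport], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
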