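"""Beta-uniform mixture (BUM) modelling of p-values and node scoring.

The BUM density is ``f(p) = lam + (1 - lam) * alpha * p**(alpha - 1)``
with shape ``alpha`` in (0, 1) and mixture weight ``lam`` in [0, 1):
the uniform part captures null genes, the beta part Beta(alpha, 1)
signal. Its value at p = 1, ``pi = lam + (1 - lam) * alpha``, is the
density minimum and serves as the conservative null-density bound in the
FDR <-> p-value-threshold transform:

    tau(FDR) = [ (pi - lam * FDR) / (FDR * (1 - lam)) ] ** (1 / (alpha - 1))

Nodes are scored ``s(p) = (alpha - 1) * (log p - log tau)`` — positive
below the threshold tau, zero at it, negative above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

_P_FLOOR = 1e-300
_LOGIT_EPS = 1e-8

#: fixed multi-start grid for the (alpha, lam) likelihood, which has a
#: near-exchangeable ridge for flat inputs
_STARTS = ((0.2, 0.1), (0.5, 0.5), (0.8, 0.9), (0.3, 0.7), (0.6, 0.3))


@dataclass(frozen=True)
class BumFit:
    """Fitted mixture parameters; ``pi`` is the density at p = 1."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.lam < 1.0:
            raise ValueError("lam must be in [0, 1)")

    @property
    def pi(self) -> float:
        return self.lam + (1.0 - self.lam) * self.alpha

    def density(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.lam + (1.0 - self.lam) * self.alpha * p ** (self.alpha - 1.0)


@dataclass(frozen=True)
class ScoringConfig:
    """A p-value threshold tau with its equivalent FDR (and optional top-K)."""

    fdr: float
    tau: float
    k_positive: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")


def _prepare(pvalues) -> np.ndarray:
    p = np.asarray(list(pvalues.values()) if isinstance(pvalues, dict) else pvalues, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.maximum(p, _P_FLOOR)


def log_likelihood(p: np.ndarray, alpha: float, lam: float) -> float:
    dens = lam + (1.0 - lam) * alpha * np.power(p, alpha - 1.0)
    return float(np.sum(np.log(dens)))


def fit_bum(pvalues) -> BumFit:
    """Maximum-likelihood BUM fit.

    Maximises sum(log(lam + (1-lam) * alpha * p**(alpha-1))) over
    (alpha, lam) in (0,1) x [0,1) by bounded quasi-Newton from a fixed
    grid of five starts on the logit scale. Requires at least 10
    p-values; exact zeros are floored before logs.
    """
    p = _prepare(pvalues)
    if p.size < 10:
        raise ValueError(f"need >= 10 p-values to fit the mixture, got {p.size}")
    logp = np.log(p)

    def neg_ll(theta: np.ndarray) -> float:
        alpha = float(expit(theta[0]))
        lam = float(expit(theta[1]))
        dens = lam + (1.0 - lam) * alpha * np.exp((alpha - 1.0) * logp)
        return -float(np.sum(np.log(np.maximum(dens, 1e-300))))

    bounds = [(-18.0, 18.0), (-18.0, 18.0)]
    best = None
    for a0, l0 in _STARTS:
        theta0 = np.array([math.log(a0 / (1 - a0)), math.log(l0 / (1 - l0))])
        res = minimize(
            neg_ll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    alpha = float(expit(best.x[0]))
    lam = float(expit(best.x[1]))
    alpha = min(max(alpha, _LOGIT_EPS), 1.0 - _LOGIT_EPS)
    lam = min(max(lam, 0.0), 1.0 - _LOGIT_EPS)
    return BumFit(alpha=alpha, lam=lam)


def override_lambda(fit: BumFit, lam_new: float) -> BumFit:
    """Replace the mixture weight, keeping alpha; pi follows."""
    if not 0.0 <= lam_new < 1.0:
        raise ValueError("lam_new must be in [0, 1)")
    return replace(fit, lam=lam_new)


def fdr_to_tau(fit: BumFit, fdr: float) -> float:
    """P-value threshold tau equivalent to an FDR cut under the fitted BUM."""
    pi = fit.pi
    if not 0.0 < fdr <= pi:
        raise ValueError(
            f"fdr must lie in (0, pi={pi:.6g}]; larger cuts exceed the uniform density bound"
        )
    ratio = (pi - fit.lam * fdr) / (fdr * (1.0 - fit.lam))
    return float(ratio ** (1.0 / (fit.alpha - 1.0)))


def tau_to_fdr(fit: BumFit, tau: float) -> float:
    """Exact inverse of :func:`fdr_to_tau`."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    return float(fit.pi / (fit.lam + (1.0 - fit.lam) * tau ** (fit.alpha - 1.0)))


def select_top_k(fit: BumFit, pvalues: dict, k: int) -> ScoringConfig:
    """Choose tau so that exactly k genes receive positive weight.

    tau is the geometric mean of the k-th and (k+1)-th smallest p-values
    (scale-appropriate for values spanning decades); the equivalent FDR is
    derived through :func:`tau_to_fdr`. A tie p_(k) == p_(k+1) is refused,
    naming the tied genes.
    """
    items = sorted(pvalues.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}]")
    pk, pk1 = items[k - 1][1], items[k][1]
    if pk == pk1:
        tied = [g for g, p in items if p == pk]
        raise ValueError(
            f"cannot split exactly {k} genes: tied p-value {pk:.3g} shared by {tied}"
        )
    tau = math.sqrt(max(pk, _P_FLOOR) * max(pk1, _P_FLOOR))
    return ScoringConfig(fdr=tau_to_fdr(fit, tau), tau=tau, k_positive=k)


def score_nodes(pvalues: dict, fit: BumFit, config: ScoringConfig) -> dict[str, float]:
    """Per-node weights s(p) = (alpha - 1) * (log p - log tau).

    Positive for p < tau, zero at p = tau, negative for p > tau; exact
    zeros are floored at 1e-300 before the log.
    """
    log_tau = math.log(config.tau)
    out = {}
    for gene, p in pvalues.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of range for {gene}: {p}")
        out[gene] = (fit.alpha - 1.0) * (math.log(max(p, _P_FLOOR)) - log_tau)
    return out


def write_weights(weights: dict, pvalues: dict, path) -> None:
    table = pd.DataFrame(
        {
            "pvalue": pd.Series(pvalues),
            "weight": pd.Series(weights),
        }
    ).sort_index()
    table["is_positive"] = table["weight"] > 0
    table.to_csv(path, sep="\t", index_label="gene", float_format="%.8g")
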