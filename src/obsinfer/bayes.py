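"""Dirichlet-multinomial machinery shared by observers and inference.

A Bayesian n-gram observer places a symmetric Dirichlet(alpha) prior on
the emission probabilities of every context of an order-R Markov model,
and an exponential complexity prior over the order itself,

    P(M_R) ∝ exp(-gamma * (|A| - 1) * |A|**R),

penalizing model topologies with more free transition parameters.  The
observer's memory limitation enters through the data-use weight beta,
which discounts every context count: n -> beta * n.  This module
implements the (log) prior over orders, the beta-discounted
Dirichlet-multinomial evidence, the normalized posterior over orders with
its MAP order R*, and the two predictive distributions the observer
strategies use:

* ``predictive_argmax`` — the joint MAP estimate (MAP order, then MAP
  emission parameters), the "n-gram argmax" strategy's predictive;
* ``predictive_average`` — the prior-weighted mixture over orders of the
  posterior-mean (Laplace-smoothed) per-order predictives, the "n-gram
  average" strategy's predictive.

All arithmetic is in log space (``gammaln``, ``logsumexp``); argmax ties
are broken toward the smaller (simpler) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .stimuli import ContextCounts, SequentialCounter, SymbolSequence, EntropyCurve, context_code

__all__ = [
    "STRATEGIES",
    "ObserverSpec",
    "OrderPosterior",
    "log_prior_order",
    "log_evidence_order",
    "order_posterior",
    "predictive_argmax",
    "predictive_average",
    "prior_weights",
    "asymptotic_map_order",
]

#: Recognized observer strategy labels.
STRATEGIES = ("ngram_argmax", "ngram_average", "glm")

_DENOM_TOL = 1e-12


@dataclass(frozen=True)
class ObserverSpec:
    """A strategy label plus the parameters that define the observer.

    Parameters
    ----------
    strategy:
        One of ``ngram_argmax``, ``ngram_average``, ``glm``.
    alpha:
        Dirichlet concentration of the prior over emission probabilities
        (n-gram strategies).  Must be > 0; the argmax strategy further
        requires alpha >= 1 so its joint MAP is well defined.
    beta:
        Data-use weight in [0, 1]; every count the observer holds is
        scaled to beta * n before entering its formulas.
    gamma:
        Complexity penalty >= 0 in the prior over Markov orders.
    window:
        History length k >= 1 of the logistic (GLM) observer.
    ridge:
        L2 penalty of the GLM fit (kept tiny; it only tames separable
        histories).
    """

    strategy: str
    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    window: Optional[int] = None
    ridge: float = 1e-4

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "glm":
            if self.window is None or self.window < 1:
                raise ValueError("glm requires window >= 1")
            if any(v is not None for v in (self.alpha, self.beta, self.gamma)):
                raise ValueError("glm takes only a window parameter")
        else:
            if self.alpha is None or self.beta is None or self.gamma is None:
                raise ValueError(f"{self.strategy} requires alpha, beta and gamma")
            if self.alpha <= 0:
                raise ValueError("alpha must be > 0")
            if self.strategy == "ngram_argmax" and self.alpha < 1:
                raise ValueError("ngram_argmax requires alpha >= 1 (MAP undefined below)")
            if not 0 <= self.beta <= 1:
                raise ValueError("beta must lie in [0, 1]")
            if self.gamma < 0:
                raise ValueError("gamma must be >= 0")
            if self.window is not None:
                raise ValueError("window applies to the glm strategy only")

    @property
    def is_bayesian(self) -> bool:
        return self.strategy in ("ngram_argmax", "ngram_average")

    def label(self) -> str:
        if self.strategy == "glm":
            return f"glm(k={self.window})"
        return (
            f"{self.strategy}(alpha={self.alpha:g}, beta={self.beta:g}, "
            f"gamma={self.gamma:g})"
        )


def log_prior_order(R: int, gamma: float, alphabet_size: int) -> float:
    """Unnormalized log prior over Markov orders: -gamma (|A|-1) |A|**R."""
    if R < 0:
        raise ValueError("R must be >= 0")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return -gamma * (alphabet_size - 1) * alphabet_size ** R


def log_evidence_order(
    counts: ContextCounts | SequentialCounter,
    R: int,
    alpha: float,
    beta: float = 1.0,
) -> float:
    """Log marginal likelihood of the data under order R, counts discounted by beta.

    Sum over contexts c of

        logG(|A|a) - |A| logG(a) + sum_s logG(b n(cs) + a) - logG(b n(c) + |A|a)

    which is the standard Dirichlet-multinomial evidence when beta = 1 and
    exactly 0 for an empty sequence (or beta = 0).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    if R > counts.max_order:
        raise ValueError(f"R={R} exceeds max_order={counts.max_order}")
    A = counts.alphabet.size
    ncs = counts.n_context_symbol[R]
    nc = counts.n_context[R]
    occupied = nc > 0  # empty contexts contribute exactly 0
    if not np.any(occupied):
        return 0.0
    ncs = ncs[occupied]
    nc = nc[occupied]
    per_ctx = (
        gammaln(A * alpha)
        - A * gammaln(alpha)
        + gammaln(beta * ncs + alpha).sum(axis=1)
        - gammaln(beta * nc + A * alpha)
    )
    return float(per_ctx.sum())


@dataclass
class OrderPosterior:
    """Posterior over Markov orders R = 0..r_max for one observer."""

    r_max: int
    gamma: float
    log_prior: np.ndarray
    log_evidence: np.ndarray
    log_posterior: np.ndarray
    map_order: int
    z_prior: float

    def to_dict(self) -> dict:
        return {
            "r_max": self.r_max,
            "gamma": self.gamma,
            "log_prior": list(map(float, self.log_prior)),
            "log_evidence": list(map(float, self.log_evidence)),
            "log_posterior": list(map(float, self.log_posterior)),
            "map_order": int(self.map_order),
            "z_prior": float(self.z_prior),
        }


def order_posterior(
    counts: ContextCounts | SequentialCounter,
    spec: ObserverSpec,
    r_max: int,
) -> OrderPosterior:
    """Combine prior and evidence into a normalized posterior over orders.

    The MAP order R* maximizes log prior + log evidence; exact ties go to
    the smaller order.
    """
    if r_max > counts.max_order:
        raise ValueError("r_max exceeds the available count orders")
    A = counts.alphabet.size
    lp = np.array([log_prior_order(R, spec.gamma, A) for R in range(r_max + 1)])
    le = np.array(
        [log_evidence_order(counts, R, spec.alpha, spec.beta) for R in range(r_max + 1)]
    )
    score = lp + le
    log_post = score - logsumexp(score)
    return OrderPosterior(
        r_max=r_max,
        gamma=spec.gamma,
        log_prior=lp,
        log_evidence=le,
        log_posterior=log_post,
        map_order=int(np.argmax(score)),  # first max == smallest R on ties
        z_prior=float(np.exp(lp).sum()),
    )


def predictive_argmax(
    counts: ContextCounts | SequentialCounter,
    spec: ObserverSpec,
    map_order: int,
    context: Sequence[int] | int,
    symbol: int,
) -> float:
    """MAP-parameter predictive at the MAP order (the n-gram argmax rule).

        p(s | c) = (alpha + beta n(cs) - 1) / (|A| (alpha - 1) + beta n(c))

    The alpha = 1, no-data case is 0/0 and returns the uniform 1/|A|.
    """
    if spec.alpha is None or spec.alpha < 1:
        raise ValueError("predictive_argmax requires alpha >= 1")
    A = counts.alphabet.size
    code = context if isinstance(context, (int, np.integer)) else context_code(context, A)
    ncs = counts.n_context_symbol[map_order][code, symbol]
    nc = counts.n_context[map_order][code]
    denom = A * (spec.alpha - 1) + spec.beta * nc
    if denom <= _DENOM_TOL:
        return 1.0 / A
    return float((spec.alpha + spec.beta * ncs - 1) / denom)


def prior_weights(gamma: float, alphabet_size: int, r_max: int) -> np.ndarray:
    """Normalized prior weights over orders 0..r_max (the truncated Z)."""
    lp = np.array([log_prior_order(R, gamma, alphabet_size) for R in range(r_max + 1)])
    w = np.exp(lp - lp.max())
    return w / w.sum()


def predictive_average(
    counts: ContextCounts | SequentialCounter,
    spec: ObserverSpec,
    r_max: int,
    history: SymbolSequence | Sequence[int],
    symbol: int,
) -> float:
    """Prior-weighted mixture of per-order posterior-mean predictives.

        p(s | h) = (1/Z) sum_R e^{-gamma(|A|-1)|A|^R}
                   (alpha + beta n(c_R s)) / (|A| alpha + beta n(c_R))

    with c_R the length-R suffix of the history and Z the prior
    normalizer truncated (and renormalized) at r_max.  The prior weights
    decay doubly exponentially in R, so truncation at the default r_max
    is numerically irrelevant.
    """
    if r_max > counts.max_order:
        raise ValueError("r_max exceeds the available count orders")
    hist = history.symbols if isinstance(history, SymbolSequence) else np.asarray(history)
    if r_max > len(hist):
        raise ValueError("r_max exceeds the available history length")
    A = counts.alphabet.size
    w = prior_weights(spec.gamma, A, r_max)
    total = 0.0
    for R in range(r_max + 1):
        code = context_code(hist[len(hist) - R:], A)
        ncs = counts.n_context_symbol[R][code, symbol]
        nc = counts.n_context[R][code]
        total += w[R] * (spec.alpha + spec.beta * ncs) / (A * spec.alpha + spec.beta * nc)
    return float(total)


def asymptotic_map_order(
    alpha: float,
    gamma: float,
    t: int,
    entropy_curve: EntropyCurve,
    r_max: int,
    alphabet_size: int = 2,
) -> int:
    """Large-t approximation to the MAP order R*.

    Maximizes, over R <= r_max,

        -(|A|-1) |A|^R gamma + |A|^R log[G(|A|a)/G(a)^|A|] - t h_mu(R)

    The entropy term carries a minus sign: higher orders win once the
    predictive gain t (h_mu(R) - h_mu(R')) outweighs the complexity cost,
    so for stimuli with ever-decreasing h_mu the selected order grows
    with t.  Ties go to the smaller order.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    A = alphabet_size
    scores = np.array(
        [
            -(A - 1) * A ** R * gamma
            + A ** R * (gammaln(A * alpha) - A * gammaln(alpha))
            - t * entropy_curve[R]
            for R in range(r_max + 1)
        ]
    )
    return int(np.argmax(scores))
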