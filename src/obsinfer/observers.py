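"""Trial-by-trial simulation of probability-matching observers.

Three observer families are simulated:

* ``ngram_argmax`` — at each trial picks the MAP Markov order from the
  posterior over orders and predicts with the MAP emission parameters of
  that order;
* ``ngram_average`` — mixes the per-order posterior-mean predictives
  with the complexity-prior weights;
* ``glm`` — refits a ridge-penalized logistic regression of the next
  symbol on the last k symbols at every trial and predicts with the
  fitted sigmoid.

Every observer probability-matches: it guesses symbol s with exactly the
probability its internal model assigns to s.  The per-trial probability
vectors (the emission probabilities ``p_obs``) are a deterministic
function of the stimulus and the observer parameters; only the guesses
are stochastic.  An ensemble of identical clones therefore shares one
emission stream, and the clones' guess frequencies estimate it.

The prediction for trial t is made before s_t is revealed, from the
counts of s_1..s_{t-1} only; trial 1 is uniform for every strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, gammaln, log_expit

from .bayes import ObserverSpec, prior_weights
from .stimuli import SequentialCounter, SymbolSequence

__all__ = [
    "PredictionTrace",
    "EnsembleTrace",
    "emission_stream",
    "ngram_emission_streams",
    "glm_emission_stream",
    "probability_match",
    "fit_glm_step",
    "simulate_observer",
    "run_ensemble",
]

DEFAULT_R_MAX = 8


@dataclass
class PredictionTrace:
    """Aligned per-trial predictions and/or analytic emission probabilities.

    ``emission_probs[t - 1]`` is the probability vector the trial-t guess
    was (or would be) drawn from; ``predictions`` is None for purely
    analytic (infinite-clone) traces.
    """

    emission_probs: np.ndarray
    predictions: Optional[np.ndarray] = None
    stimulus: Optional[SymbolSequence] = None

    def __post_init__(self):
        self.emission_probs = np.asarray(self.emission_probs, dtype=float)
        if self.predictions is not None:
            self.predictions = np.asarray(self.predictions, dtype=np.int64)
            if len(self.predictions) != len(self.emission_probs):
                raise ValueError("predictions and emission_probs must align")

    def __len__(self) -> int:
        return len(self.emission_probs)


@dataclass
class EnsembleTrace:
    """Guesses of n identical clones plus their per-trial frequencies."""

    prediction_matrix: np.ndarray  # (n_clones, n_trials)
    empirical_freqs: np.ndarray  # (n_trials, |A|)
    emission_probs: Optional[np.ndarray] = None

    @property
    def n_clones(self) -> int:
        return self.prediction_matrix.shape[0]

    @property
    def n_trials(self) -> int:
        return self.prediction_matrix.shape[1]


# ---------------------------------------------------------------------------
# logistic (GLM) observer
# ---------------------------------------------------------------------------


def _ridge_logistic(X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """MAP weights of intercept + linear logistic model with L2 penalty.

    Maximizes sum_i log sigma((2 y_i - 1) (w0 + w.x_i)) - ridge/2 ||w||^2
    by damped Newton iterations.  The penalty covers the intercept too,
    which keeps the optimum finite on single-class and separable
    histories — the only reason the ridge exists.
    """
    n, k = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    d = k + 1
    w = np.zeros(d)

    def objective(wv: np.ndarray) -> float:
        z = Xd @ wv
        return float(log_expit((2 * y - 1) * z).sum() - 0.5 * ridge * wv @ wv)

    obj = objective(w)
    for _ in range(100):
        p = expit(Xd @ w)
        grad = Xd.T @ (y - p) - ridge * w
        if np.abs(grad).max() < 1e-10:
            break
        wdiag = np.maximum(p * (1 - p), 1e-12)
        H = (Xd * wdiag[:, None]).T @ Xd + ridge * np.eye(d)
        step = np.linalg.solve(H, grad)
        # backtracking: the objective is concave but tiny ridges allow
        # overshooting on separable data
        scale, new_obj = 1.0, objective(w + step)
        while new_obj < obj and scale > 1e-8:
            scale *= 0.5
            new_obj = objective(w + scale * step)
        if new_obj <= obj + 1e-14:
            break
        w = w + scale * step
        obj = new_obj
    return w


def fit_glm_step(
    history: SymbolSequence | Sequence[int],
    window: int,
    ridge: float = 1e-4,
) -> np.ndarray:
    """Predictive probability vector of the GLM observer for the next trial.

    Builds every (length-k window, next symbol) pair available in the
    history, fits the penalized logistic model, and evaluates it on the
    current last-k window.  Until at least k + 2 training pairs exist the
    observer has nothing to fit and predicts uniformly.  Binary alphabets
    only.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    hist = history.symbols if isinstance(history, SymbolSequence) else np.asarray(history)
    n_pairs = len(hist) - window
    if n_pairs < window + 2:
        return np.array([0.5, 0.5])
    X = np.lib.stride_tricks.sliding_window_view(hist, window)[:-1].astype(float)
    y = hist[window:].astype(float)
    w = _ridge_logistic(X, y, ridge)
    current = hist[len(hist) - window:].astype(float)
    p1 = float(expit(w[0] + current @ w[1:]))
    return np.array([1.0 - p1, p1])


def glm_emission_stream(
    stimulus: SymbolSequence,
    window: int,
    ridge: float = 1e-4,
) -> np.ndarray:
    """Per-trial GLM predictive vectors, refit from scratch each trial."""
    T = len(stimulus)
    probs = np.empty((T, 2))
    for t in range(T):
        probs[t] = fit_glm_step(stimulus.symbols[:t], window, ridge)
    return probs


# ---------------------------------------------------------------------------
# Bayesian n-gram observers: batched trial-by-trial streams
# ---------------------------------------------------------------------------


class _EvidenceTracker:
    """Incrementally maintained log evidence per order for one (alpha, beta).

    Observing one symbol changes a single (context, symbol) count at each
    order, so the Dirichlet-multinomial evidence update is four log-gamma
    terms per order — O(r_max) per trial instead of O(|A|^R)."""

    def __init__(self, alpha: float, beta: float, r_max: int, alphabet_size: int):
        self.alpha = alpha
        self.beta = beta
        self.A = alphabet_size
        self.log_evidence = np.zeros(r_max + 1)

    def update(self, orders: np.ndarray, n_cs: np.ndarray, n_c: np.ndarray) -> None:
        a, b, A = self.alpha, self.beta, self.A
        delta = (
            gammaln(b * (n_cs + 1) + a)
            - gammaln(b * n_cs + a)
            - gammaln(b * (n_c + 1) + A * a)
            + gammaln(b * n_c + A * a)
        )
        self.log_evidence[orders] += delta


def ngram_emission_streams(
    stimulus: SymbolSequence,
    specs: Sequence[ObserverSpec],
    r_max: int = DEFAULT_R_MAX,
) -> List[np.ndarray]:
    """Emission-probability streams of several n-gram observers in one sweep.

    All specs share the causal count sweep over the stimulus; argmax
    specs additionally share incremental evidence trackers per distinct
    (alpha, beta).  Orders considered at trial t are capped at the
    available history length, so early trials fall back to low orders.
    """
    A = stimulus.alphabet.size
    if A != 2:
        raise NotImplementedError("n-gram streams are implemented for binary alphabets")
    T = len(stimulus)
    for spec in specs:
        if not spec.is_bayesian:
            raise ValueError("ngram_emission_streams takes n-gram specs only")

    counter = SequentialCounter(stimulus.alphabet, r_max)
    trackers: Dict[Tuple[float, float], _EvidenceTracker] = {}
    log_priors: Dict[float, np.ndarray] = {}
    weights: Dict[Tuple[float, int], np.ndarray] = {}
    for spec in specs:
        if spec.strategy == "ngram_argmax":
            key = (spec.alpha, spec.beta)
            if key not in trackers:
                trackers[key] = _EvidenceTracker(spec.alpha, spec.beta, r_max, A)
        if spec.gamma not in log_priors:
            log_priors[spec.gamma] = np.array(
                [-spec.gamma * (A - 1) * A ** R for R in range(r_max + 1)]
            )

    out = [np.empty((T, A)) for _ in specs]
    orders_full = np.arange(r_max + 1)
    for t in range(T):
        eff = min(r_max, counter.t)
        orders = orders_full[: eff + 1]
        # counts at the current context of each order, for every symbol
        n_c = np.array([counter.n_context[R][counter.context(R)] for R in orders])
        n_cs = np.array(
            [counter.n_context_symbol[R][counter.context(R)] for R in orders]
        )  # (eff+1, A)
        for j, spec in enumerate(specs):
            a, b = spec.alpha, spec.beta
            if spec.strategy == "ngram_average":
                wkey = (spec.gamma, eff)
                if wkey not in weights:
                    weights[wkey] = prior_weights(spec.gamma, A, eff)
                w = weights[wkey]
                p = w @ ((a + b * n_cs) / (A * a + b * n_c)[:, None])
            else:  # ngram_argmax
                scores = log_priors[spec.gamma][: eff + 1] + trackers[
                    (a, b)
                ].log_evidence[: eff + 1]
                R_star = int(np.argmax(scores))
                denom = A * (a - 1) + b * n_c[R_star]
                if denom <= 1e-12:
                    p = np.full(A, 1.0 / A)
                else:
                    p = (a + b * n_cs[R_star] - 1) / denom
            out[j][t] = p
        s = int(stimulus.symbols[t])
        for tracker in trackers.values():
            tracker.update(orders, n_cs[:, s], n_c)
        counter.observe(s)
    return out


def emission_stream(
    spec: ObserverSpec,
    stimulus: SymbolSequence,
    r_max: int = DEFAULT_R_MAX,
) -> PredictionTrace:
    """Per-trial analytic emission probabilities p_obs of one observer.

    This is the observer's fingerprint: the exact probability with which
    an infinite ensemble of identical clones would guess each symbol at
    each trial.
    """
    if spec.strategy == "glm":
        probs = glm_emission_stream(stimulus, spec.window, spec.ridge)
    else:
        probs = ngram_emission_streams(stimulus, [spec], r_max)[0]
    return PredictionTrace(emission_probs=probs, stimulus=stimulus)


# ---------------------------------------------------------------------------
# probability matching and simulation
# ---------------------------------------------------------------------------


def probability_match(
    emission: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Draw one guess from an emission-probability vector."""
    emission = np.asarray(emission, dtype=float)
    if abs(emission.sum() - 1.0) > 1e-8 or np.any(emission < 0):
        raise ValueError("emission vector must be a probability distribution")
    u = rng.random()
    return int(np.searchsorted(np.cumsum(emission), u, side="right").clip(0, len(emission) - 1))


def _match_stream(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized probability matching over a (T, |A|) stream."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))
    return (u[:, None] >= cum).sum(axis=1).clip(0, probs.shape[1] - 1).astype(np.int64)


def _stochastic_dropout_stream(
    spec: ObserverSpec,
    stimulus: SymbolSequence,
    r_max: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Emission stream when observations are randomly dropped from memory.

    Each revealed symbol is retained in the observer's memory with
    probability beta (dropped with probability 1 - beta); the retained
    subsequence is treated as the observer's whole history and the
    n-gram formulas are applied to it with beta = 1.  This stream is
    stochastic (it depends on the dropout draws) and does not coincide
    with the deterministic count-discount stream except at beta = 1.
    """
    inner = ObserverSpec(
        strategy=spec.strategy, alpha=spec.alpha, beta=1.0, gamma=spec.gamma
    )
    keep = rng.random(len(stimulus)) < spec.beta
    A = stimulus.alphabet.size
    T = len(stimulus)
    probs = np.empty((T, A))
    retained: List[int] = []
    for t in range(T):
        sub = SymbolSequence(np.array(retained, dtype=np.int64), stimulus.alphabet)
        probs[t] = _single_step_probs(inner, sub, r_max)
        if keep[t]:
            retained.append(int(stimulus.symbols[t]))
    return probs


def _single_step_probs(
    spec: ObserverSpec, history: SymbolSequence, r_max: int
) -> np.ndarray:
    """Predictive vector after an arbitrary history (one-step helper)."""
    ext = SymbolSequence(
        np.append(history.symbols, 0).astype(np.int64), history.alphabet
    )
    return ngram_emission_streams(ext, [spec], r_max)[0][-1]


def simulate_observer(
    spec: ObserverSpec,
    stimulus: SymbolSequence,
    seed: int | np.random.Generator = 0,
    dropout_mode: str = "discount",
    r_max: int = DEFAULT_R_MAX,
) -> PredictionTrace:
    """Simulate one probability-matching observer over the whole stimulus.

    ``dropout_mode='discount'`` (default) applies the memory limitation
    as the deterministic count discount n -> beta n, exactly matching the
    likelihood formulas used for inference.  ``'stochastic'`` instead
    drops each observation from memory with probability 1 - beta, a
    more literal reading of random forgetting whose emission stream is
    itself random.
    """
    rng = np.random.default_rng(seed)
    if dropout_mode == "discount" or spec.strategy == "glm":
        probs = emission_stream(spec, stimulus, r_max).emission_probs
    elif dropout_mode == "stochastic":
        probs = _stochastic_dropout_stream(spec, stimulus, r_max, rng)
    else:
        raise ValueError("dropout_mode must be 'discount' or 'stochastic'")
    preds = _match_stream(probs, rng)
    return PredictionTrace(emission_probs=probs, predictions=preds, stimulus=stimulus)


def run_ensemble(
    spec: ObserverSpec,
    stimulus: SymbolSequence,
    n_clones: int,
    seed: int = 0,
    dropout_mode: str = "discount",
    r_max: int = DEFAULT_R_MAX,
) -> EnsembleTrace:
    """Independent identical clones sharing one stimulus.

    In discount mode all clones share the analytic emission stream, so
    only the guesses are redrawn per clone; clone seeds are spawned from
    the root seed so adding clones never perturbs earlier ones.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    A = stimulus.alphabet.size
    child_seeds = np.random.SeedSequence(seed).spawn(n_clones)
    if dropout_mode == "discount" or spec.strategy == "glm":
        probs = emission_stream(spec, stimulus, r_max).emission_probs
        matrix = np.stack(
            [
                _match_stream(probs, np.random.default_rng(cs))
                for cs in child_seeds
            ]
        )
        shared_probs = probs
    else:
        traces = [
            simulate_observer(spec, stimulus, np.random.default_rng(cs),
                              dropout_mode=dropout_mode, r_max=r_max)
            for cs in child_seeds
        ]
        matrix = np.stack([tr.predictions for tr in traces])
        shared_probs = None
    freqs = np.stack(
        [(matrix == s).mean(axis=0) for s in range(A)], axis=1
    )
    return EnsembleTrace(
        prediction_matrix=matrix, empirical_freqs=freqs, emission_probs=shared_probs
    )
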