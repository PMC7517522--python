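"""Order-R Markov stimulus models, sequence generation and count statistics.

The stimulus in a sequence-learning experiment is a symbol stream drawn
from an order-R Markov model over a small finite alphabet (binary in all
the experiments shipped with this package).  Everything downstream — the
Bayesian predictive formulas, the simulated observers and the likelihood
machinery — consumes either the raw :class:`SymbolSequence` or the context
count statistics n(c), n(cs) computed here.

Contexts are written most-recent-last: the length-R context at trial t is
``s_{t-R} ... s_{t-1}``.  Internally a context is encoded as a base-|A|
integer with the *oldest* symbol in the most significant digit, so that
appending a symbol ``s`` maps code ``c`` to ``(c * |A| + s) mod |A|**R``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Alphabet",
    "BINARY",
    "SymbolSequence",
    "MarkovModel",
    "ContextCounts",
    "SequentialCounter",
    "EntropyCurve",
    "sample_markov_model",
    "generate_stimulus",
    "count_contexts",
    "conditional_entropy",
    "entropy_curve",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class Alphabet:
    """An ordered finite symbol set; symbols are single-character tokens."""

    symbols: tuple

    def __post_init__(self):
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        object.__setattr__(self, "symbols", tuple(str(s) for s in self.symbols))

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, token: str) -> int:
        return self.symbols.index(token)


#: The binary alphabet {0, 1} used throughout the shipped experiments.
BINARY = Alphabet(("0", "1"))


class SymbolSequence:
    """A trial-indexed stimulus (or prediction) stream of alphabet indices.

    Trials are 1-based in the scientific description; storage is a plain
    0-based integer array.  ``seq.suffix(k)`` returns the last ``k``
    symbols (most-recent-last), i.e. the length-k context for the *next*
    trial.
    """

    __slots__ = ("symbols", "alphabet")

    def __init__(self, symbols: Iterable[int], alphabet: Alphabet = BINARY):
        arr = np.asarray(list(symbols) if not isinstance(symbols, np.ndarray) else symbols,
                         dtype=np.int64)
        if arr.ndim != 1:
            raise ValueError("sequence must be one-dimensional")
        if arr.size and (arr.min() < 0 or arr.max() >= alphabet.size):
            raise ValueError("symbol index out of alphabet range")
        self.symbols = arr
        self.alphabet = alphabet

    @classmethod
    def from_string(cls, text: str, alphabet: Alphabet = BINARY) -> "SymbolSequence":
        text = text.strip()
        lookup = {tok: i for i, tok in enumerate(alphabet.symbols)}
        try:
            idx = [lookup[ch] for ch in text]
        except KeyError as exc:
            pos = next(i for i, ch in enumerate(text) if ch not in lookup)
            raise ValueError(
                f"invalid symbol {exc.args[0]!r} at position {pos + 1}"
            ) from None
        return cls(idx, alphabet)

    def to_string(self) -> str:
        return "".join(self.alphabet.symbols[i] for i in self.symbols)

    def suffix(self, k: int) -> np.ndarray:
        if k < 0 or k > len(self):
            raise ValueError(f"suffix length {k} not in [0, {len(self)}]")
        return self.symbols[len(self) - k:]

    def __len__(self) -> int:
        return int(self.symbols.size)

    def __getitem__(self, i):
        return self.symbols[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SymbolSequence)
            and self.alphabet == other.alphabet
            and np.array_equal(self.symbols, other.symbols)
        )

    def __repr__(self) -> str:
        s = self.to_string()
        shown = s if len(s) <= 40 else s[:37] + "..."
        return f"SymbolSequence({shown!r}, t={len(self)})"


def _context_strings(alphabet: Alphabet, order: int) -> List[str]:
    """All |A|^R context strings in code order (oldest symbol first)."""
    if order == 0:
        return [""]
    out = []
    for code in range(alphabet.size ** order):
        digits = []
        c = code
        for _ in range(order):
            digits.append(alphabet.symbols[c % alphabet.size])
            c //= alphabet.size
        out.append("".join(reversed(digits)))
    return out


def context_code(context: Sequence[int], alphabet_size: int) -> int:
    """Encode a most-recent-last context (indices) as a base-|A| integer."""
    code = 0
    for s in context:
        code = code * alphabet_size + int(s)
    return code


@dataclass
class MarkovModel:
    """A fully specified order-R Markov model.

    ``emission[c, s]`` is the probability of emitting symbol index ``s``
    from the length-R context with code ``c``.
    """

    order: int
    alphabet: Alphabet
    emission: np.ndarray

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        self.emission = np.asarray(self.emission, dtype=float)
        n_ctx = self.alphabet.size ** self.order
        if self.emission.shape != (n_ctx, self.alphabet.size):
            raise ValueError(
                f"emission must have shape ({n_ctx}, {self.alphabet.size})"
            )
        if np.any(self.emission < 0):
            raise ValueError("emission probabilities must be nonnegative")
        rows = self.emission.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("each emission row must sum to 1")

    @property
    def n_contexts(self) -> int:
        return self.alphabet.size ** self.order

    # -- context-chain structure -------------------------------------------

    def context_transition_matrix(self) -> np.ndarray:
        """Transition matrix of the induced chain over length-R contexts."""
        A, n = self.alphabet.size, self.n_contexts
        T = np.zeros((n, n))
        for c in range(n):
            for s in range(A):
                T[c, (c * A + s) % n] += self.emission[c, s]
        return T

    def is_irreducible(self) -> bool:
        if self.order == 0:
            return True
        T = self.context_transition_matrix()
        n_comp, _ = connected_components(csr_matrix(T > 0), connection="strong")
        return n_comp == 1

    def stationary_contexts(self) -> np.ndarray:
        """Stationary distribution over length-R contexts.

        Falls back to the uniform distribution when the context chain is
        not irreducible (then no unique stationary law exists).
        """
        n = self.n_contexts
        if self.order == 0:
            return np.ones(1)
        if not self.is_irreducible():
            return np.full(n, 1.0 / n)
        T = self.context_transition_matrix()
        vals, vecs = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        table = {
            ctx: [float(p) for p in row]
            for ctx, row in zip(_context_strings(self.alphabet, self.order),
                                self.emission)
        }
        return json.dumps(
            {
                "order": self.order,
                "alphabet": list(self.alphabet.symbols),
                "emission": table,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MarkovModel":
        obj = json.loads(text)
        alphabet = Alphabet(tuple(obj["alphabet"]))
        order = int(obj["order"])
        strings = _context_strings(alphabet, order)
        emission = np.array([obj["emission"][c] for c in strings], dtype=float)
        return cls(order=order, alphabet=alphabet, emission=emission)


def sample_markov_model(
    order: int,
    alphabet: Alphabet = BINARY,
    concentration: float = 1.0,
    seed: int | np.random.Generator = 0,
    min_order_gap: float | None = None,
) -> MarkovModel:
    """Draw an order-R model with Dirichlet(concentration) emission rows.

    Each of the |A|^R context rows is drawn independently from a symmetric
    Dirichlet.  ``concentration`` near 1 gives diffuse, often strongly
    structured rows; large values give near-uniform (low-information)
    stimuli.

    A random draw can land arbitrarily close to a lower-order model (all
    rows nearly equal), in which case the nominal order is not the true
    Markov order and the stimulus carries no structure for an observer to
    exploit.  ``min_order_gap`` (nats) rejects such draws: the model is
    resampled until it is irreducible and every conditional-entropy step
    h_mu(r-1) - h_mu(r), r = 1..R, is at least the given value, so each
    additional symbol of memory buys real predictability.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    n_ctx = alphabet.size ** order
    for _ in range(1000):
        emission = rng.dirichlet([concentration] * alphabet.size, size=n_ctx)
        model = MarkovModel(order=order, alphabet=alphabet, emission=emission)
        if min_order_gap is None or order == 0:
            return model
        if not model.is_irreducible():
            continue
        h = [conditional_entropy(model, r) for r in range(order + 1)]
        if all(h[r - 1] - h[r] >= min_order_gap for r in range(1, order + 1)):
            return model
    raise RuntimeError(
        f"could not sample an order-{order} model with entropy gap >= {min_order_gap}"
    )


def generate_stimulus(
    model: MarkovModel,
    length: int,
    seed: int | np.random.Generator = 0,
    burn_in: int = 0,
) -> SymbolSequence:
    """Sample a length-t stimulus from the model.

    The initial length-R context is drawn from the stationary context
    distribution (uniform over contexts when the chain is reducible) and
    optionally advanced ``burn_in`` extra steps before recording, so the
    recorded counts carry no transient bias.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = np.random.default_rng(seed)
    A = model.alphabet.size
    R = model.order
    n_ctx = model.n_contexts
    ctx = int(rng.choice(n_ctx, p=model.stationary_contexts()))
    for _ in range(burn_in):
        s = int(rng.choice(A, p=model.emission[ctx]))
        ctx = (ctx * A + s) % n_ctx

    out = np.empty(length, dtype=np.int64)
    # emit the initial context symbols first (they are part of the stimulus)
    initial = []
    c = ctx
    for _ in range(R):
        initial.append(c % A)
        c //= A
    initial = list(reversed(initial))[: length]
    out[: len(initial)] = initial
    u = rng.random(max(length - len(initial), 0))
    cum = np.cumsum(model.emission, axis=1)
    for t in range(len(initial), length):
        s = int(np.searchsorted(cum[ctx], u[t - len(initial)], side="right"))
        s = min(s, A - 1)
        out[t] = s
        ctx = (ctx * A + s) % n_ctx
    return SymbolSequence(out, model.alphabet)


@dataclass
class ContextCounts:
    """Sliding-window context counts n(c) and n(cs) for all orders <= R_max.

    ``n_context[R][c]`` is the number of windows whose length-R prefix is
    the context coded ``c``; ``n_context_symbol[R][c, s]`` additionally
    fixes the following symbol.  Windows that would start before trial 1
    are skipped, so at order R there are max(t - R, 0) windows in total.
    """

    max_order: int
    alphabet: Alphabet
    n_context: List[np.ndarray] = field(default_factory=list)
    n_context_symbol: List[np.ndarray] = field(default_factory=list)

    def n(self, R: int, context_code_: int) -> int:
        return int(self.n_context[R][context_code_])

    def n_sym(self, R: int, context_code_: int, symbol: int) -> int:
        return int(self.n_context_symbol[R][context_code_, symbol])


def count_contexts(seq: SymbolSequence, max_order: int) -> ContextCounts:
    """Overlapping sliding-window counts for every order 0..max_order."""
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    A = seq.alphabet.size
    t = len(seq)
    sym = seq.symbols
    n_context, n_context_symbol = [], []
    for R in range(max_order + 1):
        n_ctx = A ** R
        ncs = np.zeros((n_ctx, A), dtype=np.int64)
        if t > R:
            if R == 0:
                codes = np.zeros(t, dtype=np.int64)
                nxt = sym
            else:
                # context code of window ending just before position i
                weights = A ** np.arange(R - 1, -1, -1)
                windows = np.lib.stride_tricks.sliding_window_view(sym, R)[:-1]
                codes = windows @ weights
                nxt = sym[R:]
            np.add.at(ncs, (codes, nxt), 1)
        n_context_symbol.append(ncs)
        n_context.append(ncs.sum(axis=1))
    return ContextCounts(
        max_order=max_order,
        alphabet=seq.alphabet,
        n_context=n_context,
        n_context_symbol=n_context_symbol,
    )


class SequentialCounter:
    """Causal, incrementally updated context counts.

    At any point the counter holds exactly the counts of the symbols fed
    so far, plus the current length-R suffix code for each order — what an
    observer knows just before the next trial.  ``observe`` costs
    O(max_order) per symbol, which keeps trial-by-trial likelihood sweeps
    linear in t.
    """

    def __init__(self, alphabet: Alphabet, max_order: int):
        self.alphabet = alphabet
        self.max_order = max_order
        A = alphabet.size
        self.t = 0
        self.n_context = [np.zeros(A ** R, dtype=np.int64) for R in range(max_order + 1)]
        self.n_context_symbol = [
            np.zeros((A ** R, A), dtype=np.int64) for R in range(max_order + 1)
        ]
        self._ctx = [0] * (max_order + 1)  # running suffix code per order

    def context(self, R: int) -> int | None:
        """Code of the last-R-symbols context, or None if t < R."""
        if self.t < R:
            return None
        return self._ctx[R]

    def observe(self, symbol: int) -> None:
        A = self.alphabet.size
        for R in range(self.max_order + 1):
            if self.t >= R:
                c = self._ctx[R]
                self.n_context[R][c] += 1
                self.n_context_symbol[R][c, symbol] += 1
            self._ctx[R] = (self._ctx[R] * A + symbol) % (A ** R) if R else 0
        self.t += 1

    def snapshot(self) -> ContextCounts:
        return ContextCounts(
            max_order=self.max_order,
            alphabet=self.alphabet,
            n_context=[a.copy() for a in self.n_context],
            n_context_symbol=[a.copy() for a in self.n_context_symbol],
        )


@dataclass
class EntropyCurve:
    """Conditional entropies h_mu(R) (nats) of a stimulus model, by order."""

    values: Dict[int, float]

    def __getitem__(self, R: int) -> float:
        return self.values[R]

    @property
    def r_max(self) -> int:
        return max(self.values)


def _extended_stationary(model: MarkovModel, m: int) -> np.ndarray:
    """Stationary distribution over length-m contexts, m >= model.order."""
    A = model.alphabet.size
    R = model.order
    pi_R = model.stationary_contexts()
    if m == R:
        return pi_R
    # extend one symbol at a time: P(c, s) = P(c) * emission(last-R of c, s)
    pi = pi_R
    mask_R = A ** R
    for cur in range(R, m):
        new = np.zeros(A ** (cur + 1))
        c_arr = np.arange(A ** cur)
        sub = c_arr % mask_R  # last R symbols of the length-cur context
        for s in range(A):
            new[c_arr * A + s] += pi * model.emission[sub, s]
        pi = new
    return pi


def conditional_entropy(model: MarkovModel, order: int) -> float:
    """Exact h_mu(order): H[S_{R'+1} | last R' symbols] in nats.

    For R' >= model order this is the entropy rate; for smaller R' it is
    the (larger) entropy of the marginalized predictive distribution under
    the stationary law.  Raises for reducible chains, whose stationary law
    is not unique.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if model.order > 0 and not model.is_irreducible():
        T = model.context_transition_matrix()
        n_comp, labels = connected_components(csr_matrix(T > 0), connection="strong")
        strings = _context_strings(model.alphabet, model.order)
        unreachable = [strings[i] for i in range(len(strings)) if labels[i] != labels[0]]
        raise ValueError(
            "model context chain is not irreducible; unreachable context set "
            f"includes {unreachable[:8]}"
        )
    A = model.alphabet.size
    R = model.order
    m = max(R, order)
    pi_m = _extended_stationary(model, m)
    # predictive per length-m context is the emission of its last-R suffix
    c_arr = np.arange(A ** m)
    emis_m = model.emission[c_arr % (A ** R)]
    if order >= R and m == order:
        cond_ctx_p = pi_m
        predictive = emis_m
    else:
        # marginalize down to the last-`order` symbols
        suffix = c_arr % (A ** order)
        n_small = A ** order
        cond_ctx_p = np.zeros(n_small)
        predictive = np.zeros((n_small, A))
        np.add.at(cond_ctx_p, suffix, pi_m)
        np.add.at(predictive, suffix, pi_m[:, None] * emis_m)
        nz = cond_ctx_p > 0
        predictive[nz] /= cond_ctx_p[nz, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(predictive > 0, predictive * np.log(predictive), 0.0)
    h = -np.sum(cond_ctx_p * plogp.sum(axis=1))
    return float(max(h, 0.0))


def entropy_curve(model: MarkovModel, r_max: int) -> EntropyCurve:
    """h_mu(R) for R = 0..r_max."""
    return EntropyCurve({R: conditional_entropy(model, R) for R in range(r_max + 1)})
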