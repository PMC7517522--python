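# Methods

## Stimulus model

Stimuli are realizations of order-R Markov models over the binary
alphabet {0, 1}: the distribution of the next symbol depends only on the
last R symbols (the *context*). A model is the table of |A|^R emission
vectors θ. `sample_markov_model` draws each row independently from a
symmetric Dirichlet with concentration 1 by default — diffuse over the
simplex, so draws range from nearly deterministic to nearly uniform
rows.

Two conventions fixed here because they matter downstream:

* **Initialization.** The first R symbols are drawn from the stationary
  distribution of the induced context chain (computed by an eigenvector
  of the context transition matrix; uniform over contexts if the chain
  is not irreducible), so context counts carry no transient bias.
* **Counting.** Counts n(c), n(cs) are overlapping sliding windows with
  1-based trials, contexts written most-recent-last, and no padding:
  windows that would start before trial 1 are skipped, so at order R a
  length-t sequence yields max(t − R, 0) windows.

`conditional_entropy` gives the exact h_μ(R) = H[S_{R+1} | last R
symbols] in nats from the stationary law, marginalizing down for R below
the model order. All entropies and likelihoods are in natural logs.

### When a sampled model is *not* order R

A Dirichlet draw can land arbitrarily close to a lower-order model (all
rows nearly equal). Such a draw's nominal order is not its Markov order,
and the resulting stimulus carries no structure for any observer to
exploit. `sample_markov_model(min_order_gap=g)` therefore optionally
rejection-samples until every conditional-entropy step h_μ(r−1) − h_μ(r),
r = 1..R, is at least g nats. The experiments use:

* classification (confusion) experiments: g = 0.1 — every extra symbol
  of memory must buy ≈ 0.14 bits of predictability. On unstructured
  stimuli all observer strategies emit near-constant streams and the
  classes are indistinguishable *in principle*; requiring structure is a
  precondition of the classification claim (sufficiently complex stimuli
  are what guarantee that a finite-window GLM cannot mimic the n-gram
  strategies), not a tuning knob.
* parameter-recovery experiments: g = 0.01, since the infinite-clone
  evidence is noise-free and only degenerate draws need excluding; deep
  models (R ≥ 4) cannot carry 0.1-nat steps at every level inside the
  ln 2 total entropy budget.

## Observers

All observers probability match: they guess s with exactly the
probability their internal model assigns to s. The per-trial probability
vectors (the *emission stream* p_obs) are a deterministic function of
(observer, stimulus); only the guesses are stochastic. Trial 1 is
uniform for every strategy (no history — the convention for the
undefined first prediction).

**Bayesian n-gram observers.** The prior over Markov orders is
P(M_R) ∝ exp(−γ(|A|−1)|A|^R) (the exponent counts the model's free
transition parameters). The marginal likelihood of the data under order
R with β-discounted counts is the Dirichlet-multinomial evidence

    Σ_c [ log Γ(|A|α) − |A| log Γ(α) + Σ_s log Γ(β n(cs) + α) − log Γ(β n(c) + |A|α) ],

exactly 0 on an empty history (and for β = 0). The argmax strategy picks
R* = argmax_R [log prior + log evidence] each trial and predicts with the
MAP parameters; its 0/0 corner (α = 1, no data) returns the uniform
1/|A|, and α < 1 is rejected because the joint MAP does not exist there.
The average strategy mixes the per-order posterior-mean predictives with
the *prior* weights, the mixture truncated and renormalized at a
configurable r_max (default 8): the weights decay doubly exponentially
in R, so the truncation error is below e^{−γ·2^{r_max}}.

**β as count discount vs random forgetting.** The likelihood formulas
scale every count deterministically (n → β n), and the default simulator
does exactly that, so simulated observers match the inference-side
formulas bit for bit. A `stochastic` dropout mode instead drops each
observation from the observer's memory independently with probability
1 − β and applies the formulas with β = 1 to the retained subsequence —
a more literal reading of random forgetting whose emission stream is
itself random and does *not* coincide with the discounted one except at
β = 1. β is documented as a "data-use weight"; whether a user maps it to
a drop probability is left to them.

**GLM observer.** A logistic model (intercept + one weight per lag, raw
0/1 features) of the next symbol on the last k symbols, refit from
scratch on all available (window, next-symbol) pairs at every trial —
the cleanest "ideal GLM observer"; until k + 2 pairs exist it predicts
uniformly. The fit maximizes the L2-penalized log likelihood (ridge
1e-4, damped Newton); the penalty covers the intercept so the optimum
stays finite on single-class and perfectly separable histories, which
occur routinely in early trials. The tiny solver is hand-written because
the per-trial refit schedule makes solver overhead the dominant cost and
because off-the-shelf logistic fits exclude the intercept from the
penalty and reject single-class targets.

**Ensembles.** n identical clones share the stimulus; in discount mode
they share one analytic emission stream and only the guesses are
redrawn, so clone frequencies estimate p_obs directly. Clone seeds are
spawned from the root seed (numpy `SeedSequence`), so enlarging an
ensemble never perturbs earlier clones.

## Inference

The log likelihood of a candidate observer given a prediction stream is
Σ_t log p_model(ŝ_t | history_t), computed by regenerating the
candidate's emission stream on the same stimulus. For the GLM candidate
the per-trial probability enters through its logarithm (its printed
definition without the log would not be a likelihood and could not be
compared across strategies). With infinite clones the per-trial average
log likelihood is the cross-entropy Σ_s p_obs(s) log p_model(s), which
by Gibbs' inequality is uniquely maximized when the candidate's stream
reproduces p_obs — the consistency property the recovery experiments
verify.

A naive implementation rebuilds counts and the order posterior from
scratch every trial (O(ν N² 2^R) over a ν-point grid); it is kept as
`reference_loglik` and used as an oracle. The production path keeps
running counts and per-(α, β) evidence accumulators, updating four
log-Gamma terms per order per trial, and evaluates all grid points in
one sweep; the two paths agree to 1e-9 (exactly, up to float accumulation
order) and the fast path is linear in N.

**Grid search and identifiability.** The n-gram likelihood surfaces are
ridged and non-convex, so maximization is exhaustive over parameter
grids. The maximum is routinely non-unique: (α, β) → (Lα, Lβ) leaves
the average-strategy likelihood exactly unchanged, so every grid point
on a rescaled ray ties. All points within 1e-9 of the maximum form the
argmax set, and φ = β/α (average) or β/(α−1) (argmax) and γ are
reported as intervals over that set — the lower/upper-bound protocol.

For the argmax strategy the corresponding ray scales (α−1, β) by L with
a compensating shift γ → γ + [f(α′) − f(α)]/(|A|−1), f(a) =
log Γ(|A|a)/Γ(a)^{|A|}. That shift equalizes the *asymptotic*
order-selection scores exactly (for every R and t), but the exact
finite-data evidence is a sum over occupied contexts with
parameterization-dependent small-count terms, so the two
parameterizations can select different MAP orders on a few
prior-dominated early trials or near evidence crossings; on every trial
where the selected orders agree the predictives are identical. The test
suite checks the invariance in exactly that form: per-trial equality
conditional on matching MAP order, exact invariance of the compensated
asymptotic score, and end-to-end likelihood equality on configurations
whose MAP-order trajectories coincide throughout (enforced with a
dominant complexity prior).

**Classification.** A single observer's stream is scored under all
three candidate families; the coarse label merges the two n-gram
strategies into "Bayesian". Exact likelihood ties go to Bayesian — on
structured stimuli the n-gram families strictly contain the predictive
information a finite-window GLM can express, so a tie is evidence for
the richer class; exact ties are measure-zero anyway.

## Experiments

**Confusion (model recovery).** Defaults: order-2 stimuli of 500 trials
(the scale a long behavioral session could plausibly reach; the
desk-scale tests use 300), one fresh model and stimulus per observer,
Bayesian population = n-gram average observers with α = 1,
β ∈ {0.5, 1}, γ ∈ {0.5, 2}, GLM population k ∈ {1, 2, 3}, candidate
grids α ∈ {1, 2, 3}, β ∈ {0.5, 1}, γ ∈ {0.5, 2}, k ∈ {1, 2, 3}.
Classification of single observers at this scale is nearly — not
exactly — perfect: a residual ~1–3% of GLM observers (chiefly small k on
the less-structured stimulus draws) is misclassified as Bayesian, which
is finite-data class overlap under probability-matching noise, visible
in the acceptance run as t2 of 1–3 out of 100.

**Recovery (parameter identification).** For each (R, N, true spec,
replicate), the true observer's analytic emission stream is the
evidence; the same-strategy grid search records |φ_bound − φ_true| for
the smallest and largest maximizing φ (γ likewise for the average
strategy), aggregated as means with normal-approximation 95% confidence
intervals. With the truth's φ on the grid, the average-strategy errors
are exactly 0 at every tested (R, N).

## Numerical choices

* All likelihood arithmetic in log space (`gammaln`, `logsumexp`);
  argmax ties always break toward the smaller order / simpler model.
* Probabilities serialize with 17 significant digits (bit-exact CSV
  round-trips); sequences serialize as one line of characters.
* Zero-probability predictions yield −inf log likelihoods, which
  propagate; a grid whose every point is −inf raises.
* r_max defaults to 8 for binary alphabets (256 contexts at the top
  order); order-selection at trial t is capped at the available history
  length.

## Limitations

* Binary alphabets only in the n-gram sweep and GLM observers; the
  stimulus layer is written for general finite alphabets.
* The synthetic stimuli are exactly order-R Markov with stationary
  initialization; real experimental stimuli may be non-stationary or
  hidden-state, and human observers are heterogeneous — passing
  model-recovery tests here says the *method* is sound at these scales,
  not that real observers fit any of the three families.
* Parameter (as opposed to class) recovery from a single observer's
  finite prediction string is unreliable by design of the problem; only
  φ up to grid resolution, and only with ensemble/analytic evidence, is
  exact.
* The stochastic-dropout simulator has no matching closed-form
  likelihood; inference on such traces uses the discounted formulas as
  an approximation.
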