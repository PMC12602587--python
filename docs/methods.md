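# Methods

## Model and conventions

The Ising model here is the 0/1-coded pairwise Markov random field over
$m$ binary variables: thresholds $\tau \in \mathbb{R}^m$, symmetric
interaction matrix $\omega$ with an exactly zero diagonal, each unordered
pair contributing one term $\omega_{ij} y_i y_j$.  The 0/1 coding (symptom
absent/present) is essential: the forced-response rule below — a case whose
other variables sum to $k-1$ must have the remaining variable present — is
only valid when "present" is coded 1.  No $\pm 1$ parameterisation or
converter is provided.

All partition sums are computed by exact enumeration in log space
(log-sum-exp), so weights of magnitude ~5 at $m = 9$ cannot overflow.
Enumeration is refused above a hard cap of $m = 20$ (~10^6 states) unless
the caller raises the cap explicitly; no approximate inference is offered,
because every use case targeted here involves networks small enough to
enumerate.  Pattern order is lexicographic with node 1 as the most
significant bit, so supports, serialisations and samplers are reproducible
bit for bit.

## Selection and the corrected likelihoods

Data selected at sum score $s \ge k$ follow the conditional distribution
with normaliser $Z^{(k)}$, the potential sum restricted to admissible
patterns.  Two corrected estimators follow:

**Multivariate ML.**  The truncated family is a regular exponential family
with sufficient statistics $(y_i)$ and $(y_i y_j)_{i<j}$; the gradient of
the mean negative log-likelihood is (model expectation − observed mean) of
those statistics under the $k$-truncated distribution, and the Hessian is
their truncated-model covariance — both exact via enumeration.  The
optimizer is L-BFGS on $(\tau, \text{vec-upper}(\omega))$ initialised at
marginal logits with zero interactions, followed by damped Newton polishing
with the exact Hessian; the information matrix near a high cutoff is
ill-conditioned (condition numbers ~10^6 on 9-node data selected at
$k = 5$), where quasi-Newton alone stalls around gradient norms of 10^-4.
A fit is declared converged when every gradient component (observed minus
expected sufficient statistic) is below 1e-5.  Standard errors come from
the inverse observed information; pruning is a single Wald
remove-then-refit pass (iterating to a fixed point is not done — one pass
matches the remove-and-re-estimate convention of the pruning literature and
is what the significance level calibrates).  An optional ridge penalty
(1e-4 per observation) exists for near-degenerate truncated data and is off
by default, since the multivariate estimator is meant to be unpenalised.
The uncorrected baseline is the identical machinery with the full-state
normaliser $Z$ applied to the selected data — "estimation as usual".

**Nodewise pseudo-likelihood.**  Each node is regressed on the remaining
nodes.  Conditioning on the selection event changes the node-conditional
only in one case: predictors summing to $k-1$ force the response to 1.
Those cases contribute likelihood 1 and are dropped; dropping and
assigning unit likelihood are algebraically identical, and a test asserts
this to machine precision.  Rows with predictor sums below $k-1$ cannot
occur in validly selected data.  Directed slope pairs are symmetrised by
averaging, the convention of the nodewise Ising literature.  Edge
inclusion uses the AND rule: two-sided Wald significance (default
$\alpha = 0.01$) in both directed regressions, or nonzero lasso status in
both for the eLasso flavour.  An OR-rule variant exists behind a flag but
is not a headline mode.

**eLasso.**  Per node, an L1 logistic path of 100 penalties, log-spaced
from the smallest penalty that zeroes all slopes ($\lambda_{\max} =
\max_j |x_j^\top (y - \bar y)| / n$) down to 0.001 of it, with the exactly
empty model always included as the strongest-penalty candidate (at the
$\lambda_{\max}$ boundary itself the solver can return borderline-nonzero
coefficients, which would otherwise deprive the EBIC of its null
candidate).  Model selection minimises
EBIC $= -2\ell + d\log n' + 2\gamma d\log(m-1)$ with $\gamma = 0.25$ by
default and $d$ the number of nonzero slopes.  $n'$ is the
post-correction row count — the likelihood being penalised is over
exactly those rows, so they are what the BIC term should count; this is a
package choice, as the interaction between the correction and the EBIC
sample size is not otherwise prescribed.  Because predictors are binary,
each design has at most $2^{m-1}$ distinct rows; fits use weighted unique
rows, making path cost essentially independent of $n$.

**Separation.**  With little variance after a high cutoff, a directed
logistic regression can separate.  Detection is via solver
non-convergence or absolute slopes above 15; the affected directed edge is
then treated as not significant (conservative), the fit flagged, and a
structured warning emitted.  A node whose response is single-valued after
correction raises a degenerate-node error naming the node.

## Sampling

Both samplers enumerate the relevant support, compute exact pattern
probabilities, and draw categorically with a per-call seeded generator —
no global RNG state, no MCMC, no rejection.  Sampling the conditional
distribution directly makes the post-selection sample size the controlled
quantity (selection-based designs report n after selection) and costs the
same however small $P(s \ge k)$ is.

## The data-generating fixture

The 9-node "true" network is a synthetic stand-in constrained to summary
statistics typical of dense empirical symptom networks: 29 of 36 edges
present (density $29/36 \approx .81$), all present edges positive, their
mean weight exactly 0.61 (weights drawn as $|N(0,1)| + 0.1$ and rescaled),
thresholds drawn uniformly from $[-3, -1]$.  Edge placement and weight
spread come from a seeded generator rather than being hand-picked, so the
fixture implies no particular empirical topology.  Thresholds are redrawn
(deterministically, continuing the stream, bounded retries) until
$P(S \ge 5) \ge 0.01$ so that selection at $k = 5$ keeps a non-negligible
subpopulation; under the default seed $P(S \ge 5) \approx 0.65$ and
$P(S < 2) \approx 0.07$, so both cutoffs genuinely split the population.

What the generator emulates: a dense, uniformly positive conditional
dependence structure with rare-ish individual symptoms and strong
co-activation.  What it does not emulate: measurement error, skip
structures in interviews (which induce deterministic negative associations
the correction cannot and should not absorb), item-level missingness, and
population heterogeneity.  Passing tests therefore show the estimators
recover an Ising generating process after sum-score selection; they do not
show robustness to model misspecification.

## Simulation harness

The factorial design crosses post-selection sample sizes
{500, 1000, 2500, 5000} with cutoffs {0, 2, 5}; each replicate fits three
estimators (eLasso, nodewise thresholding at $\alpha = 0.01$, multivariate
with pruning at $\alpha = 0.01$) in corrected and uncorrected variants —
six networks per run, three at $k = 0$ where the variants coincide; the
full design at 100 replicates is 1,200 runs.  Per-replicate seeds derive
deterministically from (base seed, n, k, replicate), so results are
identical regardless of scheduling and replicates can run on several
workers.  Condition summaries are means over replicates (medians
available).  Estimator failures inside a replicate are recorded with a
reason, never raised.

The spurious-negative proportion divides by all unordered pairs;
a true-present-pairs denominator is available as an option, since the
denominator is a reporting convention rather than part of the estimand.

The test suite runs the harness at reduced size — 20 replicates,
$n \le 2500$ — and the consistency check uses n in {500, 5000, 50000}
averaged over 10 seeds; these sizes keep the full suite comfortably
re-runnable on one CPU while leaving the qualitative contrasts (corrected
error below uncorrected in every selected cell, corrected specificity near
$1 - \alpha$, spurious negatives concentrated in uncorrected fits at
$k = 5$) far outside Monte Carlo noise.

## Numerical choices and edge cases

* Partition sums: log-sum-exp always; conditional probabilities of
  excluded patterns are exactly 0, not underflow.
* Optimizer tolerances: L-BFGS gradient tolerance 1e-8, Newton polish to
  1e-6, convergence declared at 1e-5 on the sufficient-statistic scale
  (so "converged" means observed and fitted moments agree to 1e-5).
* Ties and ordering: supports and serialised patterns are lexicographic;
  pruning removes all non-significant edges in one batch, not
  sequentially, so the result does not depend on edge order.
* Degenerate inputs: constant nodes, rows violating the declared cutoff,
  empty supports ($k > m$), and singular information matrices all raise
  structured errors naming the offending node/row rather than producing
  silent numbers.
* Thresholds at high cutoffs are weakly identified (patterns with low sum
  scores are never observed); the implementation reports the information
  matrix condition number in fit diagnostics instead of attempting a
  remedy.

## Known limitations

* Exact enumeration caps the method at ~20 nodes.
* The correction assumes the selection mechanism is exactly "sum score of
  the modelled variables $\ge k$"; other selection rules (key-symptom
  requirements, skip structures) are outside its scope.
* No latent-variable, moderated, or ordinal/Gaussian graphical model
  extensions; the truncation trick does not transfer directly to
  continuous normalisers.
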