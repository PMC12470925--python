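# Methods

## Model and estimand

Each race × birthweight × gestation stratum is an independent binomial:
deaths `r` out of births `n` with unknown rate `PO`, the stratum's potential
outcome. Under a beta(a, b) prior the posterior is beta(a + r, b + n − r)
exactly, so the model that is usually fitted by MCMC is here sampled
directly: independent Monte-Carlo draws from the closed-form conjugate
posterior are draws from the exact stationary distribution the MCMC would
target, with no burn-in or convergence diagnostics needed. This equivalence
is a property of full conjugacy plus cellwise independence; it is documented
here rather than tested against an MCMC run.

The causal reading treats the mortality probability itself as the potential
outcome shared by all infants with the same covariate vector (a direct
Bayesian outcome model, not a factual/counterfactual pairing), and the two
mediators as a single 25-level interaction node, so no natural
direct/indirect decomposition is attempted. Identification rests on the
usual stratification assumptions: no interference between infants (family
clustering is ignored), positivity in observed strata, and no unmeasured
confounders of the race–outcome relation beyond the modelled strata.

A control strategy replaces targeted strata's mortality rate with a
reference rate and propagates the change drawwise:

1. controlled stratum deaths `s.r = n_cell · PO_ref` (kept real-valued —
   rounding would bias small strata);
2. counterfactual population deaths `p.r = r_race − Σ_targeted (r_cell −
   s.r)`;
3. counterfactual race rate `new.PO = p.r / n_race`;
4. `CDE = new.PO[Black] − new.PO[non-Black]`,
   `PA = 100 · (TE − CDE) / TE`.

All quantities in one run share a single random stream so that differences,
ratios and percentages are coherent draw by draw; the identity
`PA = 100(TE − CDE)/TE` holds exactly per draw.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| prior (a, b) | (1, 10) | weakly informative beta prior favouring low rates; uniform(0,1) = beta(1,1) for sensitivity |
| n_draws | 10,000 | Monte-Carlo sample size per quantity |
| summaries | median, 2.5/97.5 percentiles | linear interpolation between order statistics; any standard percentile definition differs by O(1/n_draws), below reporting precision |
| incidence prior | beta(0.5, 0.5) | Jeffreys prior on stratum membership for the incidence relative risk |
| reference stratum | NBW/TD | normal birthweight, term delivery |

Category boundaries follow the WHO/clinical convention; the upper edges
(4.0 kg exactly, 41 completed weeks) are counted as normal. These edge
assignments are design choices where the verbal definitions ("2.5 kg to
4.0 kg", "37 to 41 weeks") are ambiguous.

### Single-mediator controls (binary model)

The propagation equations are written for the joint control. For controlling
only one mediator two reference rules are plausible and both are exposed:
`match_other_mediator` (an abnormal-birthweight stratum takes the rate of
the normal-birthweight stratum with the *same* gestation level — the minimal
intervention consistent with "set birthweight to normal") and `joint_normal`
(all targeted strata take the NBW/TD rate). `match_other_mediator` is the
default for single-mediator controls; the joint control always uses
`joint_normal`, under which the binary both-mediator control and the 5 × 5
all-strata control are algebraically identical (verified drawwise in the
tests).

### Incidence relative risk

Credibility intervals are reported for the per-stratum incidence ratio, but
no likelihood for stratum membership is prescribed by the propagation
equations; we adopt independent conjugate binomial posteriors with a
Jeffreys prior per race. Plug-in medians match the posterior medians at
reporting precision. The published value for the extreme stratum appears
both as 2.75 and 2.76 in different places; the plug-in arithmetic from the
printed counts gives 2.754, and the package reports its computed value.

## What the uncertainty does and does not include

`p.r` is built from the *observed* race death totals, which enter as data,
not as posterior quantities. CDE and PA posteriors therefore quantify
uncertainty in the reference rate and the marginal rates, conditional on the
realized counts. In repeated sampling from a fixed population this makes the
CDE interval narrower than a fully generative interval; the recovery
experiment shows near-nominal coverage for stratum POs, the total effect and
the dominant-stratum PA, with mild undercoverage for the pooled binary
control, whose residual depends most strongly on the realized counts. Pooled
coverage in the shipped experiment (20 replicates of 10^6 births, 4,000
draws per quantity) is ~93%.

## Synthetic cohorts

The generator emulates the magnitudes of recent U.S. national
singleton-birth data: ~10% of births in the Black group; stratum mortality
from ~0.002 (NBW/TD) to ~0.42 (ELBW/EPTD), differing modestly between races
within stratum; non-reference incidence specified for the non-Black group
with Black incidence given by per-stratum incidence ratios (2.75 for
ELBW/EPTD); the reference stratum absorbing the remainder (≥ 0.75 per race);
and structural zeros at MAC/EPTD and MAC/VPTD. The implied marginal
mortality ratio between races is ≈ 1.9, matching the observed ~2-fold
disparity. Implied truths (marginal rates, TE, RR, and PA under any control)
are computed by closed-form mixture arithmetic, independent of the inference
code.

Individual records are realised by sampling grams and weeks uniformly within
each stratum's window, so classification and aggregation reproduce the
generated counts exactly; the within-stratum distribution is irrelevant to
inference because categorisation is its only consumer. Optional missingness
blanks one mediator per affected record (half and half). What the generator
does **not** emulate: family clustering of births (the independence
assumption is taken at face value), covariates such as maternal age or
plurality, secular trends, and any real-data coding noise — so passing tests
demonstrate correctness of the calculus under the model's own assumptions,
not robustness to violations of them.

## Numerical and design notes

* Draw counts: tests use 500–100,000 draws depending on the tolerance
  needed; the recovery experiment uses 20 replicates of 10^6 births with
  4,000 draws per quantity — large enough for stable 95% intervals while
  keeping the full suite to seconds.
* Degenerate inputs: zero births in a stratum make the posterior the prior;
  a control targeting an empty stratum is a logged no-op; a race group with
  zero births is an error for marginal effects; draws where TE = 0 are
  excluded from PA with a logged count (impossible at realistic scales).
* Zero-event strata keep full posteriors (e.g. 0 deaths in 14 births has
  median 0.028 under beta(1,10) and 0.045 under uniform); the sensitivity
  module flags strata whose PO median moves more than 0.0005 between priors.
  PA is robust to the prior because it depends on the heavily populated
  reference and marginal strata, not on the sparse stratum's own rate.
* Unobserved strata are reported as not observed rather than given
  prior-only estimates.
* Records missing both mediators are counted once, under birthweight, in the
  drop log (deterministic reporting).
* The binary analysis of fully population-scale data is not reproducible
  from printed inputs alone (the collapsed stratum counts are not public);
  it is validated by the drawwise equivalence with the 5 × 5 joint control
  and the no-disparity null instead.

## Known limitations

Mortality-rate CrIs inherit the beta(1,10) prior's downward pull in sparse
strata (by design); the CDE/PA uncertainty is conditional on realized
population counts as described above; and the race-group collapse to a
binary factor is taken as given in the input data — subgroup structure
within either group is out of scope.
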