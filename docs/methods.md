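# Methods

## Model

The unit of data is a genotype-stratified contingency table for one
adverse-event outcome in one trial: within each stratum (APOE ε4/ε4 vs
not) and each arm (active vs placebo), a count of patients with and
without the event. Stratum × arm event rates are

```
r_hA = A_h/(A_h+B_h)   r_hP = C_h/(C_h+D_h)
r_nA = A_n/(A_n+B_n)   r_nP = C_n/(C_n+D_n)
```

and the homozygote prevalence is π = (A_h+B_h+C_h+D_h)/N_total. The
policy model assumes testing changes exposure only in the ε4/ε4 stratum:
an identified homozygote is withheld from therapy with probability p and
then experiences the placebo-arm rate r_hP. Everything else follows
algebraically — ARR = p·π·RD_h, NNT = 1/ARR, Reduction = ARR/risk_base —
so the model's content is (i) the Binomial sampling assumption within
each cell and (ii) the assumption that withheld patients revert to
placebo-arm risk. No clinical-benefit, cost, or differential-efficacy
modelling is attempted; the output is a risk-side quantity only.

## Posterior and Monte Carlo

Each cell proportion gets an independent conjugate posterior under the
Jeffreys prior Beta(0.5, 0.5): Beta(events+0.5, non_events+0.5). The
Jeffreys prior matters in practice because the symptomatic ARIA-E
placebo arms contain zero events; the half-count keeps the placebo rate
strictly positive without dominating the data. π is treated the same way
on the genotype split, Beta(n_h+0.5, n_n+0.5) (`pi_mode="sampled"`); a
`fixed` mode holds π at its point estimate. The two modes differ
negligibly at trial sample sizes (n ≈ 1700–1800) but are both exposed
because the prevalence is the one input a site may want to recalibrate —
`pi_hat(override=...)` accepts a local prevalence directly.

The five rates are sampled mutually independently: the aggregate tables
carry no joint structure to exploit. Draws are generated **once per
sweep** and transformed across the whole p-grid, which (a) is cheaper
and (b) makes the scaling NNT(p) = NNT(1)/p hold draw-by-draw, so it is
asserted exactly in tests rather than approximately.

## Summaries and the sign convention for NNT

Point summaries are medians with equal-tailed 95% credible intervals
(2.5/97.5 percentiles, linear interpolation between order statistics —
stated because percentile conventions differ across toolchains).

NNT intervals are obtained by computing quantiles on the ARR scale and
inverting through x ↦ 1/x, which is monotone on the positive half-line.
When an ARR quantile is ≤ 0 the corresponding NNT bound is +∞: a policy
that averts nothing (or harms) has no finite number-needed-to-test, and
we deliberately do not report a signed "number needed to harm". For the
five packaged tables the posterior mass of RD_h is decisively positive
and the transform coincides with direct per-draw quantiles (this
equivalence is tested); the ARR-scale route only matters for noisy
synthetic tables.

## Tunable parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| p | probability therapy is withheld from an identified ε4/ε4 patient | grid 0…1 step 0.01 | an operational, site-specific quantity, not a recommendation |
| n_draws | Monte-Carlo draws per sweep | 100,000 | medians stable to <1% across seeds at this size |
| seed | RNG seed | explicit everywhere | recorded in every output artifact |
| k | average extra MRI scans per ARIA event | 1 | an assumption by nature; 1–2 plausible for any ARIA, ~4 for symptomatic events needing urgent imaging |
| pi_mode | sampled vs fixed prevalence | sampled | see above |

## Synthetic data generator

`SyntheticSpec` fixes the arm denominators (conditioning on observed
sample sizes, exactly as the posterior model does) and draws event
counts Binomially at known true rates. `membership="random"` instead
draws each arm's genotype split Binomially at the true π, which is the
mode used to exercise π recovery. Table generation and posterior
refitting use two independent seed streams so a recovery failure can be
attributed to one of them.

Because generator and model agree by construction, nominal ~95% CrI
coverage of the true NNT is expected and observed (0.96 over 200
replicates at Clarity-AD-scale arm sizes with 4,000 posterior draws per
replicate — draw count chosen so quantile Monte-Carlo error is
negligible relative to the posterior width). What this does **not**
show: robustness to anything real tables might violate — correlated
outcomes across ARIA subtypes, time-varying hazards, imaging-schedule
differences between arms, or patient-level confounding. The generator
emulates the published aggregate structure only.

## Numerical choices and degenerate inputs

- ARR = 0 (e.g. p = 0) returns NNT = +∞, never an exception; text
  outputs render it as the literal token `inf`.
- A reduction fraction with risk_base = 0 is undefined and raises.
- Tables must have strictly positive denominators in all four
  stratum × arm cells; counts are integers (the model never needs
  fractional counts).
- Recovery with an infinite true NNT (p = 0 or RD_h ≤ 0) returns a
  report with an explicit status rather than a coverage number.

## Known limitations

- Aggregate counts only; no patient-level model.
- RD_n is computed and exposed for completeness but no policy metric
  consumes it — withholding does not touch the non-homozygote stratum.
- Symptomatic ARIA is only available for lecanemab among the packaged
  tables; the asymmetry is in the published data, not imputed away.
- k enters only as a division and inherits all the uncertainty of being
  an assumption; NNT_MRI figures are illustrative.
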