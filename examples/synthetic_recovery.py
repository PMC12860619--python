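"""Parameter recovery on synthetic trials.

Generates trials at a known truth (lecanemab-like rates and arm sizes),
refits the posterior pipeline on each, and checks how often the 95%
credible interval covers the true NNT.
"""

from apoennt import SyntheticSpec, recovery_experiment

spec = SyntheticSpec.from_arm_sizes(
    true_r_hA=46 / 141, true_r_hP=5 / 133,
    true_r_nA=67 / 757, true_r_nP=10 / 764,
    n_hA=141, n_hP=133, n_nA=757, n_nP=764,
)
rep = recovery_experiment(spec, n_replicates=200, n_draws=4000, p=1.0, seed=0)
print(f"true NNT(p=1) = {rep.true_nnt:.1f}")
print(f"95% CrI coverage over {rep.n_replicates} replicates: {rep.coverage:.3f}")
print(f"median bias of the posterior-median NNT: {rep.median_bias:+.2f}")

print("\nCoverage near 0.95 means the credible intervals are honest when "
      "the Binomial sampling model holds; the small positive bias "
      "reflects the convexity of 1/ARR at trial-scale counts.")
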