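import math

import numpy as np
import pytest

from apoennt import SyntheticSpec, generate_trial, load_synthetic_spec, recovery_experiment
from apoennt.rates import point_rate


def trial_scale_spec(seed=0, scale=1):
    """Clarity-AD-like truth: lecanemab any-ARIA-E point rates and arm sizes."""
    return SyntheticSpec.from_arm_sizes(
        true_r_hA=46 / 141, true_r_hP=5 / 133, true_r_nA=67 / 757, true_r_nP=10 / 764,
        n_hA=141 * scale, n_hP=133 * scale, n_nA=757 * scale, n_nP=764 * scale,
        seed=seed,
    )


def test_degenerate_rates():
    zero = SyntheticSpec(0, 0, 0, 0, 0.3, 100, 100, seed=1)
    t = generate_trial(zero)
    assert (t.A_h, t.C_h, t.A_n, t.C_n) == (0, 0, 0, 0)
    one = SyntheticSpec(1, 1, 1, 1, 0.3, 100, 100, seed=1)
    t = generate_trial(one)
    assert (t.B_h, t.D_h, t.B_n, t.D_n) == (0, 0, 0, 0)


def test_generated_rates_near_truth():
    """Generated point rates fall within 3 Binomial SEs of the true rates."""
    spec = trial_scale_spec(seed=123)
    t = generate_trial(spec)
    for ev, n, true in ((t.A_h, t.A_h + t.B_h, spec.true_r_hA),
                        (t.C_h, t.C_h + t.D_h, spec.true_r_hP),
                        (t.A_n, t.A_n + t.B_n, spec.true_r_nA),
                        (t.C_n, t.C_n + t.D_n, spec.true_r_nP)):
        se = math.sqrt(true * (1 - true) / n)
        assert abs(point_rate(ev, n) - true) < 3 * se


def test_explicit_arm_sizes_fix_pi():
    spec = trial_scale_spec()
    assert spec.true_pi == pytest.approx(274 / 1795)
    t = generate_trial(spec)
    assert t.pi_hat() == pytest.approx(spec.true_pi)


def test_random_membership_recovers_pi():
    spec = SyntheticSpec(0.3, 0.05, 0.1, 0.01, true_pi=0.2,
                         n_active=2000, n_placebo=2000,
                         membership="random", seed=5)
    pis = [generate_trial(spec, rng=rng).pi_hat()
           for rng in [np.random.default_rng(s) for s in range(30)]]
    se = math.sqrt(0.2 * 0.8 / 4000)
    assert abs(np.mean(pis) - 0.2) < 3 * se / math.sqrt(30)


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(1.2, 0, 0, 0, 0.3, 100, 100)
    with pytest.raises(ValueError):
        SyntheticSpec(0.3, 0.1, 0.1, 0.1, 0.0, 100, 100)
    with pytest.raises(ValueError):
        SyntheticSpec(0.3, 0.1, 0.1, 0.1, 0.3, 1, 100)


def test_recovery_p_zero_has_explicit_status():
    rep = recovery_experiment(trial_scale_spec(), n_replicates=2,
                              n_draws=200, p=0.0, seed=0)
    assert rep.coverage is None
    assert math.isinf(rep.true_nnt)
    assert "undefined" in rep.status


def test_recovery_single_replicate():
    rep = recovery_experiment(trial_scale_spec(), n_replicates=1,
                              n_draws=1000, p=1.0, seed=3)
    assert rep.coverage in (0.0, 1.0)
    assert rep.status == "ok"


def test_recovery_converges_with_large_samples():
    """With arm sizes x100 the posterior concentrates: the median posterior
    NNT lands within 2% of the true NNT."""
    spec = trial_scale_spec(seed=7, scale=100)
    rep = recovery_experiment(spec, n_replicates=5, n_draws=4000, p=1.0, seed=7)
    assert np.median(rep.median_nnt_estimates) == pytest.approx(
        spec.true_nnt(1.0), rel=0.02)


def test_point_nnt_distribution_brackets_fixture_value():
    """Across generated replicates at the fixture truth, the point NNTs
    bracket the fixture's own point NNT (sanity anchor)."""
    spec = trial_scale_spec(seed=11)
    rng = np.random.default_rng(11)
    nnts = []
    for _ in range(40):
        t = generate_trial(spec, rng=rng)
        rd = point_rate(t.A_h, t.A_h + t.B_h) - point_rate(t.C_h, t.C_h + t.D_h)
        nnts.append(1.0 / (t.pi_hat() * rd))
    fixture_nnt = 1.0 / (spec.true_pi * spec.true_RD_h)
    assert min(nnts) < fixture_nnt < max(nnts)


def test_load_spec_names_missing_field(tmp_path):
    path = tmp_path / "spec.yaml"
    path.write_text("true_r_hA: 0.3\ntrue_r_hP: 0.05\ntrue_r_nA: 0.1\n"
                    "true_pi: 0.15\nn_active: 100\nn_placebo: 100\n")
    with pytest.raises(ValueError, match="true_r_nP"):
        load_synthetic_spec(path)
    path.write_text(path.read_text() + "true_r_nP: 0.01\nseed: 4\n")
    spec = load_synthetic_spec(path)
    assert spec.true_r_nP == 0.01 and spec.seed == 4
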