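import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apoennt import arr, evaluate_policy, nnt, nnt_mri, reduction, risk_base, risk_policy

# lecanemab any-ARIA-E point estimates
R_HA, R_HP, R_NA = 46 / 141, 5 / 133, 67 / 757
PI = 274 / 1795

unit = st.floats(0.0, 1.0, allow_nan=False)


def test_risk_base_point_estimate():
    assert risk_base(R_HA, R_NA, PI) == pytest.approx(0.12480, abs=1e-5)
    assert risk_base(0.3, 0.1, 0.0) == 0.1
    assert risk_base(0.3, 0.1, 1.0) == 0.3


def test_risk_policy_limits():
    assert risk_policy(R_HA, R_HP, R_NA, PI, 0.0) == risk_base(R_HA, R_NA, PI)
    assert risk_policy(R_HA, R_HP, R_NA, PI, 1.0) == pytest.approx(0.08074, abs=1e-4)
    # no drug-attributable risk in the homozygote stratum -> policy changes nothing
    assert risk_policy(0.2, 0.2, 0.1, 0.3, 0.7) == pytest.approx(risk_base(0.2, 0.1, 0.3))


def test_arr_values():
    assert arr(R_HA - R_HP, PI, 1.0) == pytest.approx(0.044061, abs=1e-5)
    assert arr(0.9, 0.9, 0.0) == 0.0
    assert arr(0.5, 0.5, 0.5) == pytest.approx(0.125)


def test_nnt_point_estimates():
    # any-ARIA-H point NNTs at p=1: ~36.5 (lecanemab), ~20.0 (donanemab)
    assert nnt(55 / 141 - 28 / 133, 274 / 1795, 1.0) == pytest.approx(36.49, abs=0.05)
    assert nnt(72 / 143 - 30 / 146, 289 / 1720, 1.0) == pytest.approx(19.97, abs=0.05)
    assert nnt(R_HA - R_HP, PI, 0.0) == math.inf
    assert nnt(-0.1, 0.5, 1.0) == math.inf


def test_reduction_fractions():
    assert reduction(R_HA - R_HP, R_HA, R_NA, PI, 1.0) == pytest.approx(0.353, abs=0.001)
    sympt = reduction(13 / 141 - 0.0, 13 / 141, 12 / 757, PI, 1.0)
    assert sympt == pytest.approx(0.512, abs=0.002)
    assert reduction(R_HA - R_HP, R_HA, R_NA, PI, 0.0) == 0.0
    with pytest.raises(ValueError):
        reduction(0.1, 0.0, 0.0, 0.5, 1.0)


def test_nnt_mri():
    assert nnt_mri(80.0, 4.0) == 20.0
    assert nnt_mri(37.2, 1.0) == 37.2
    assert nnt_mri(math.inf, 2.0) == math.inf
    with pytest.raises(ValueError):
        nnt_mri(10.0, 0.0)


def test_out_of_range_inputs_rejected():
    with pytest.raises(ValueError):
        risk_base(1.2, 0.1, 0.5)
    with pytest.raises(ValueError):
        arr(1.5, 0.5, 0.5)


@settings(max_examples=200, derandomize=True)
@given(r_hA=unit, r_hP=unit, r_nA=unit, pi=unit, p=unit)
def test_risk_conservation_identity(r_hA, r_hP, r_nA, pi, p):
    """risk_base - risk_policy equals p*pi*RD_h to machine precision for
    any admissible rates: the closed forms are one algebraic identity."""
    lhs = risk_base(r_hA, r_nA, pi) - risk_policy(r_hA, r_hP, r_nA, pi, p)
    assert lhs == pytest.approx(arr(r_hA - r_hP, pi, p), abs=1e-15)


@settings(max_examples=100, derandomize=True)
@given(p=st.floats(0.01, 1.0), pi=st.floats(0.05, 0.95), rd=st.floats(0.01, 0.9))
def test_nnt_scaling_and_monotonicity(p, pi, rd):
    """NNT(p) = NNT(1)/p exactly, hence strictly decreasing in p when RD_h>0;
    reduction is exactly linear in p."""
    assert nnt(rd, pi, p) == pytest.approx(nnt(rd, pi, 1.0) / p, rel=1e-12)
    assert reduction(rd, 0.5, 0.1, pi, p) == pytest.approx(
        p * reduction(rd, 0.5, 0.1, pi, 1.0), rel=1e-12)
    if p < 1.0:
        assert nnt(rd, pi, 1.0) < nnt(rd, pi, p)


def test_agent_level_oracle():
    """Brute-force patient simulation (genotype ~ Bernoulli(pi), withhold ~
    Bernoulli(p) for homozygotes, event at the stratum/arm rate) reproduces
    the closed-form risk_base, risk_policy and ARR within 3 MC SEs."""
    r_hA, r_hP, r_nA, pi, p = 0.33, 0.04, 0.09, 0.15, 0.6
    n = 400_000
    rng = np.random.default_rng(2024)

    homo = rng.random(n) < pi
    withheld = homo & (rng.random(n) < p)
    rate_policy = np.where(homo, np.where(withheld, r_hP, r_hA), r_nA)
    ev_policy = rng.random(n) < rate_policy
    rate_base = np.where(homo, r_hA, r_nA)
    ev_base = rng.random(n) < rate_base

    for sim, closed in ((ev_base.mean(), risk_base(r_hA, r_nA, pi)),
                        (ev_policy.mean(), risk_policy(r_hA, r_hP, r_nA, pi, p))):
        se = math.sqrt(closed * (1 - closed) / n)
        assert abs(sim - closed) < 3 * se

    arr_se = math.sqrt((risk_base(r_hA, r_nA, pi) + risk_policy(r_hA, r_hP, r_nA, pi, p)) / n)
    assert abs((ev_base.mean() - ev_policy.mean()) - arr(r_hA - r_hP, pi, p)) < 3 * arr_se


def test_evaluate_policy_bundles_consistently():
    m = evaluate_policy(R_HA, R_HP, R_NA, PI, p=1.0, k=2.0)
    assert m.risk_base - m.risk_policy == pytest.approx(m.arr, abs=1e-15)
    assert m.nnt == pytest.approx(1 / m.arr)
    assert m.nnt_mri == pytest.approx(m.nnt / 2)
    assert m.reduction == pytest.approx(m.arr / m.risk_base)
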