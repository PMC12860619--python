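"""Closed-form policy metrics at a withholding probability p.

Under a policy that withholds anti-amyloid therapy from an identified
ε4-homozygote with probability p, the population ARIA risk drops from

    risk_base   = π·r_hA + (1−π)·r_nA

to

    risk_policy = π·[(1−p)·r_hA + p·r_hP] + (1−π)·r_nA,

so the absolute risk reduction per tested patient is ARR = p·π·RD_h with
RD_h = r_hA − r_hP, and NNT = 1/ARR.  The fractional reduction in total
events is ARR/risk_base, and NNT_MRI = NNT/k converts to testing effort
per MRI scan averted given k extra scans per event.

All functions accept scalars or numpy arrays (vectorized over posterior
draws).  A non-positive ARR maps NNT to +infinity — withholding that
averts nothing (or "harms") has no finite number-needed-to-test — rather
than to a signed number-needed-to-harm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolicyMetrics",
    "risk_base",
    "risk_policy",
    "arr",
    "nnt",
    "reduction",
    "nnt_mri",
    "evaluate_policy",
]

ArrayLike = float | np.ndarray


def _check_unit(name: str, x: ArrayLike) -> None:
    if np.any((np.asarray(x) < 0) | (np.asarray(x) > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class PolicyMetrics:
    """All policy metrics evaluated at one withholding probability p."""

    p: float
    risk_base: float
    risk_policy: float
    arr: float
    nnt: float
    reduction: float
    k: float
    nnt_mri: float


def risk_base(r_hA: ArrayLike, r_nA: ArrayLike, pi: ArrayLike) -> ArrayLike:
    """Baseline risk π·r_hA + (1−π)·r_nA (treat everyone, no testing)."""
    _check_unit("r_hA", r_hA)
    _check_unit("r_nA", r_nA)
    _check_unit("pi", pi)
    return pi * r_hA + (1.0 - pi) * r_nA


def risk_policy(r_hA: ArrayLike, r_hP: ArrayLike, r_nA: ArrayLike,
                pi: ArrayLike, p: ArrayLike) -> ArrayLike:
    """Population risk when ε4/ε4 patients are withheld with probability p.

    Withheld homozygotes are exposed to the placebo-arm rate r_hP; the
    non-homozygote stratum is untouched.  Equals ``risk_base`` at p = 0.
    """
    for name, x in (("r_hA", r_hA), ("r_hP", r_hP), ("r_nA", r_nA), ("pi", pi), ("p", p)):
        _check_unit(name, x)
    return pi * ((1.0 - p) * r_hA + p * r_hP) + (1.0 - pi) * r_nA


def arr(RD_h: ArrayLike, pi: ArrayLike, p: ArrayLike) -> ArrayLike:
    """Absolute risk reduction p·π·RD_h; linear in p."""
    _check_unit("pi", pi)
    _check_unit("p", p)
    if np.any(np.abs(np.asarray(RD_h)) > 1):
        raise ValueError("RD_h must lie in [-1, 1]")
    return p * pi * RD_h


def nnt(RD_h: ArrayLike, pi: ArrayLike, p: ArrayLike) -> ArrayLike:
    """Number needed to test 1/(p·π·RD_h); +inf when ARR ≤ 0."""
    a = np.asarray(arr(RD_h, pi, p), dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(a > 0, np.divide(1.0, a, where=a > 0,
                                        out=np.full_like(a, np.inf)), np.inf)
    return float(out) if out.ndim == 0 else out


def reduction(RD_h: ArrayLike, r_hA: ArrayLike, r_nA: ArrayLike,
              pi: ArrayLike, p: ArrayLike) -> ArrayLike:
    """Fractional reduction in total events, ARR / risk_base; ∝ p."""
    base = np.asarray(risk_base(r_hA, r_nA, pi), dtype=float)
    if np.any(base <= 0):
        raise ValueError("risk_base must be positive for a reduction fraction")
    out = np.asarray(arr(RD_h, pi, p), dtype=float) / base
    return float(out) if out.ndim == 0 else out


def nnt_mri(nnt_value: ArrayLike, k: float) -> ArrayLike:
    """NNT per MRI averted, NNT/k; +inf propagates.

    k is the assumed average number of additional MRI scans triggered by
    one ARIA event (a pure user parameter, typically 1–4).
    """
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    out = np.asarray(nnt_value, dtype=float) / k
    return float(out) if out.ndim == 0 else out


def evaluate_policy(r_hA: float, r_hP: float, r_nA: float, pi: float,
                    p: float, k: float = 1.0) -> PolicyMetrics:
    """Evaluate every metric at one p from scalar rates (point-estimate mode)."""
    base = float(risk_base(r_hA, r_nA, pi))
    pol = float(risk_policy(r_hA, r_hP, r_nA, pi, p))
    rd_h = r_hA - r_hP
    a = float(arr(rd_h, pi, p))
    n = float(nnt(rd_h, pi, p))
    red = float(reduction(rd_h, r_hA, r_nA, pi, p))
    return PolicyMetrics(p=p, risk_base=base, risk_policy=pol, arr=a,
                         nnt=n, reduction=red, k=k, nnt_mri=float(nnt_mri(n, k)))
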