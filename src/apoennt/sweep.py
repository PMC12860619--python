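"""Monte-Carlo sweep of policy metrics over a grid of withholding
probabilities, with median and 95% equal-tailed credible intervals.

One joint set of posterior rate draws is generated per sweep and reused
across the whole p-grid, so the curves in p are coherent transformations
of the same posterior sample and the exact scaling NNT(p) = NNT(1)/p
holds draw-by-draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .rates import RateDraws, risk_differences, sample_joint
from .tables import StratifiedTrialTable

__all__ = ["SweepResult", "run_sweep", "summarize", "nnt_summary_from_arr", "plot_sweep"]

METRICS = ("arr", "nnt", "reduction", "nnt_mri")


def summarize(draws: np.ndarray) -> tuple[float, float, float]:
    """Median and equal-tailed 95% interval (2.5/97.5 percentiles).

    Percentiles use linear interpolation between order statistics (the
    numpy default); the convention matters at small draw counts.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize an empty array")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return float(med), float(lo), float(hi)


def nnt_summary_from_arr(arr_draws: np.ndarray, p: float | None = None
                         ) -> tuple[float, float, float]:
    """NNT (median, lower, upper) via quantile transformation of ARR.

    Quantiles are taken on the ARR scale and inverted through the
    decreasing map x ↦ 1/x, so the 97.5% ARR quantile gives the NNT lower
    bound.  An ARR quantile ≤ 0 maps to an infinite NNT bound, which keeps
    the summary defined when posterior ARR mass touches zero.  When all
    draws are positive the result coincides with direct per-draw 1/ARR
    quantiles (monotone-transform equivariance).
    """
    arr_draws = np.asarray(arr_draws, dtype=float)
    if p is not None:
        arr_draws = p * arr_draws
    a_med, a_lo, a_hi = summarize(arr_draws)

    def inv(a: float) -> float:
        return 1.0 / a if a > 0 else np.inf

    return inv(a_med), inv(a_hi), inv(a_lo)


@dataclass(frozen=True)
class SweepResult:
    """Per-p summaries of arr, nnt, reduction and nnt_mri.

    ``summaries`` is a tidy frame with columns
    ``p, metric, median, lower, upper`` — one row per grid point per
    metric.  Configuration (seed, draws, k, π mode) is carried along so
    any serialization can be regenerated exactly.
    """

    drug_label: str
    outcome_label: str
    p_grid: np.ndarray
    summaries: pd.DataFrame
    n_draws: int
    seed: int
    k: float
    pi_mode: str

    def metric_at(self, metric: str, p: float) -> tuple[float, float, float]:
        """(median, lower, upper) for one metric at one grid value of p."""
        sel = self.summaries[(self.summaries["metric"] == metric)
                             & np.isclose(self.summaries["p"], p)]
        if sel.empty:
            raise KeyError(f"no summary for metric={metric!r} at p={p}")
        row = sel.iloc[0]
        return float(row["median"]), float(row["lower"]), float(row["upper"])

    def to_csv(self, path: str | Path) -> None:
        """Write the summary table with a config header (inf as 'inf')."""
        with open(Path(path), "w") as fh:
            fh.write(f"# drug: {self.drug_label}\n")
            fh.write(f"# outcome: {self.outcome_label}\n")
            fh.write(f"# n_draws: {self.n_draws}\n")
            fh.write(f"# seed: {self.seed}\n")
            fh.write(f"# k: {self.k}\n")
            fh.write(f"# pi_mode: {self.pi_mode}\n")
            self.summaries.to_csv(fh, index=False, float_format="%.10g")


def default_p_grid() -> np.ndarray:
    """p from 0 to 1 in steps of 0.01."""
    return np.round(np.linspace(0.0, 1.0, 101), 2)


def run_sweep(
    table: StratifiedTrialTable,
    p_grid: np.ndarray | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
    k: float = 1.0,
    pi_mode: str = "sampled",
    draws: RateDraws | None = None,
) -> SweepResult:
    """Sweep all policy metrics over ``p_grid``.

    Draws are generated once (or supplied via ``draws`` for reuse across
    sweeps) and transformed per p.  NNT and NNT_MRI intervals come from
    :func:`nnt_summary_from_arr`; ARR and reduction are summarized
    directly per draw.
    """
    p_grid = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    if p_grid.size == 0:
        raise ValueError("p_grid is empty")
    if np.any((p_grid < 0) | (p_grid > 1)):
        raise ValueError("p_grid values must lie in [0, 1]")
    if draws is None:
        draws = sample_joint(table, n_draws=n_draws, seed=seed, pi_mode=pi_mode)
    rd = risk_differences(draws)
    base = metrics.risk_base(draws.r_hA, draws.r_nA, draws.pi)
    arr_unit = draws.pi * rd.RD_h          # ARR at p = 1, per draw

    rows = []
    for p in p_grid:
        arr_p = p * arr_unit
        for name, summ in (
            ("arr", summarize(arr_p)),
            ("nnt", nnt_summary_from_arr(arr_p)),
            ("reduction", summarize(arr_p / base)),
        ):
            rows.append((p, name, *summ))
        n_med, n_lo, n_hi = rows[-2][2:]   # nnt summary of this p
        rows.append((p, "nnt_mri", n_med / k, n_lo / k, n_hi / k))

    summaries = pd.DataFrame(rows, columns=["p", "metric", "median", "lower", "upper"])
    return SweepResult(
        drug_label=table.drug_label, outcome_label=table.outcome_label,
        p_grid=p_grid, summaries=summaries, n_draws=draws.n_draws,
        seed=draws.seed, k=k, pi_mode=pi_mode,
    )


def plot_sweep(results: list[SweepResult], metric: str = "nnt",
               path: str | Path | None = None, ymax: float | None = None):
    """Median curve with shaded 95% CrI versus p, one line per result.

    Optional; returns the matplotlib figure.  NNT axes are truncated at
    ``ymax`` because the curve diverges as p → 0.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for res in results:
        sub = res.summaries[res.summaries["metric"] == metric]
        label = f"{res.drug_label} {res.outcome_label}"
        ax.plot(sub["p"], sub["median"], label=label)
        ax.fill_between(sub["p"], sub["lower"],
                        np.minimum(sub["upper"], ymax or np.inf), alpha=0.25)
    ax.set_xlabel("withholding probability p")
    ax.set_ylabel(metric)
    if ymax is not None:
        ax.set_ylim(0, ymax)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
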