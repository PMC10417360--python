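"""Posterior summaries: medians, shortest 95% HPD intervals, sign
probabilities and decision flags.

The point estimate of every (co)variance component and derived
parameter is the posterior median.  Interval estimates are empirical
highest-posterior-density intervals: the shortest contiguous window of
sorted retained samples holding the requested mass.  For a genetic
correlation, P0 is the posterior probability of the estimate's sign
(samples > 0 for a positive median, < 0 for a negative one) and P01 the
probability of exceeding 0.1 in that direction; a correlation is
flagged different from zero when P0 > 0.80 and relevant when
P01 > 0.70.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import SampleStore

P0_THRESHOLD = 0.80
P01_THRESHOLD = 0.70


def derived_parameters(G: np.ndarray, R: np.ndarray):
    """Heritabilities and genetic correlation of one (G, R) draw.

    h2_t = G_tt / (G_tt + R_tt) and r_g = G12 / sqrt(G11 G22).
    """
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    denom1 = G[0, 0] + R[0, 0]
    denom2 = G[1, 1] + R[1, 1]
    assert denom1 > 0 and denom2 > 0, "non-positive variance draw"
    h2 = (G[0, 0] / denom1, G[1, 1] / denom2)
    rg = G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])
    return h2, float(rg)


def posterior_median(samples) -> float:
    """Lower-middle order statistic (deterministic for even n)."""
    x = np.sort(np.asarray(samples, dtype=float))
    return float(x[(len(x) - 1) // 2])


def hpd_interval(samples, mass: float = 0.95):
    """Shortest contiguous interval holding ``mass`` of the samples.

    Scans all sorted-sample windows whose endpoints lie
    m = ceil(mass * n) order statistics apart and returns the narrowest
    (leftmost on ties), the usual empirical post-Gibbs construction.
    Requires at least 100 samples for a meaningful interval.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 samples for an HPD interval, got {n}")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = min(int(np.ceil(mass * n)), n - 1)
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))  # argmin returns the leftmost minimum
    return float(x[i]), float(x[i + m])


def sign_probabilities(samples):
    """(P0, P01) with the direction taken from the posterior median.

    Positive median: fractions of samples strictly > 0 and > 0.1;
    negative median: strictly < 0 and < -0.1.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    med = posterior_median(x)
    if med >= 0:
        p0 = float(np.mean(x > 0.0))
        p01 = float(np.mean(x > 0.1))
    else:
        p0 = float(np.mean(x < 0.0))
        p01 = float(np.mean(x < -0.1))
    return p0, p01


def decision_flags(p0: float, p01: float):
    """(different-from-zero, relevant) under the P0 > 0.80 / P01 > 0.70 rule."""
    return p0 > P0_THRESHOLD, p01 > P01_THRESHOLD


@dataclass
class PosteriorSummary:
    parameter: str
    median: float
    hpd_low: float
    hpd_high: float
    p0: float
    p01: float
    nonzero: bool
    relevant: bool
    multimodal_flag: bool = False  # median outside the HPD window


def summarize_samples(samples, parameter: str,
                      mass: float = 0.95) -> PosteriorSummary:
    med = posterior_median(samples)
    lo, hi = hpd_interval(samples, mass)
    p0, p01 = sign_probabilities(samples)
    nz, rel = decision_flags(p0, p01)
    return PosteriorSummary(parameter, med, lo, hi, p0, p01, nz, rel,
                            multimodal_flag=not (lo <= med <= hi))


def summarize(store: SampleStore, mass: float = 0.95) -> pd.DataFrame:
    """One summary row per stored parameter of a completed run.

    Columns mirror the report layout: parameter, median, hpd_low,
    hpd_high, p0, p01, nonzero, relevant.
    """
    if len(store) == 0:
        raise ValueError("empty sample store")
    rows = []
    for par in ("G11", "G12", "G22", "R11", "R12", "R22",
                "h2_t1", "h2_t2", "rg"):
        x = store[par]
        if par == "R12" and np.all(x == 0.0):
            # structurally constrained covariance: report as-is
            rows.append(PosteriorSummary(par, 0.0, 0.0, 0.0, 0.0, 0.0,
                                         False, False))
            continue
        rows.append(summarize_samples(x, par, mass))
    df = pd.DataFrame([vars(s) for s in rows])
    return df.drop(columns=["multimodal_flag"])


def write_summary(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.4f")


def trace_plot(store: SampleStore, path, parameters=("G11", "G22", "rg")):
    """Basic trace plots of retained draws (one panel per parameter)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(parameters), 1, figsize=(8, 2.2 * len(parameters)),
                             sharex=True)
    axes = np.atleast_1d(axes)
    for ax, par in zip(axes, parameters):
        ax.plot(store["iter"], store[par], lw=0.4)
        ax.set_ylabel(par)
    axes[-1].set_xlabel("iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
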