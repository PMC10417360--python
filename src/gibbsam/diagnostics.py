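"""Raftery-Lewis run-length and convergence diagnostic.

The chain is dichotomized at its q-quantile; the smallest thinning k
for which the binary chain behaves as a first-order (rather than
second-order) Markov chain is selected by a BIC comparison on the
triple-transition table.  Burn-in and required run length then follow
from the fitted 2-state transition matrix, and the dependence factor
I = required-n / n-min measures how much autocorrelation inflates the
run beyond the i.i.d. requirement
n-min = ceil(q (1-q) (z_{(1+s)/2} / r)^2).

Defaults (q=0.025, r=0.005, s=0.95) are the classic choice: estimating
a 2.5% posterior quantile to within +-0.005 with 95% confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class RafteryLewisResult:
    q: float
    r: float
    s: float
    thinning_k: int
    burn_in_m: int
    required_n: int
    n_min: int

    @property
    def dependence_factor(self) -> float:
        """I = required-n / n-min; ~1 for an i.i.d. chain, >> 1 for a
        strongly autocorrelated one.  I < 1 can occur by sampling noise
        and is flagged by callers, not failed."""
        return self.required_n / self.n_min


def n_min(q: float = 0.025, r: float = 0.005, s: float = 0.95) -> int:
    """I.i.d.-chain run length for the requested quantile precision;
    independent of the chain itself."""
    z = norm.ppf(0.5 * (1.0 + s))
    return int(np.ceil(q * (1.0 - q) * (z / r) ** 2))


def _g2_bic(t: np.ndarray, n: int) -> float:
    """BIC comparing second- vs first-order Markov on the 2x2x2 triple
    counts; >= 0 means the thinned chain is not yet first-order."""
    fitted = np.zeros_like(t, dtype=float)
    for j in range(2):
        colsum = t[:, j, :].sum()
        if colsum > 0:
            fitted[:, j, :] = np.outer(t[:, j, :].sum(axis=1),
                                       t[:, j, :].sum(axis=0)) / colsum
    mask = t > 0
    g2 = 2.0 * np.sum(t[mask] * np.log(t[mask] / fitted[mask]))
    return g2 - np.log(n) * 2.0


def raftery_lewis(chain, q: float = 0.025, r: float = 0.005,
                  s: float = 0.95, eps: float = 0.001) -> RafteryLewisResult:
    """Run-length diagnostic for one monitored parameter."""
    x = np.asarray(chain, dtype=float)
    nmin = n_min(q, r, s)
    if len(x) < nmin:
        raise ValueError(
            f"chain of length {len(x)} is shorter than the minimum "
            f"{nmin} required for q={q}, r={r}, s={s}; run longer")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) chain")
    z = norm.ppf(0.5 * (1.0 + s))
    dichot = (x <= np.quantile(x, q)).astype(np.int64)

    kthin = 1
    while True:
        u = dichot[::kthin]
        if len(u) < 3:
            raise ValueError("chain too short after thinning; run longer")
        triples = u[:-2] * 4 + u[1:-1] * 2 + u[2:]
        t = np.bincount(triples, minlength=8).reshape(2, 2, 2).astype(float)
        if _g2_bic(t, len(u) - 2) < 0:
            break
        kthin += 1

    pairs = u[:-1] * 2 + u[1:]
    c = np.bincount(pairs, minlength=4).reshape(2, 2).astype(float)
    if c[0].sum() == 0 or c[1].sum() == 0:
        raise ValueError("dichotomized chain never crosses the quantile; "
                         "run longer")
    alpha = c[0, 1] / c[0].sum()  # P(cross into tail)
    beta = c[1, 0] / c[1].sum()   # P(cross out of tail)
    if alpha == 0 or beta == 0:
        raise ValueError("no transitions observed in the 2-state chain; "
                         "run longer")
    lam = abs(1.0 - alpha - beta)
    if lam > 0:
        tempburn = (np.log(eps * (alpha + beta) / max(alpha, beta))
                    / np.log(lam))
        nburn = int(np.ceil(max(tempburn, 0.0))) * kthin
    else:
        nburn = kthin
    tempprec = ((2.0 - alpha - beta) * alpha * beta * z ** 2
                / ((alpha + beta) ** 3 * r ** 2))
    nkeep = int(np.ceil(tempprec)) * kthin
    return RafteryLewisResult(q=q, r=r, s=s, thinning_k=kthin,
                              burn_in_m=nburn, required_n=nburn + nkeep,
                              n_min=nmin)


def diagnose_store(store, parameters=("G11", "G12", "G22", "R11", "R22",
                                      "h2_t1", "h2_t2", "rg"),
                   warn_factor: float = 5.0, log=None):
    """Raftery-Lewis report for every monitored (co)variance component.

    Advisory: parameters whose dependence factor exceeds ``warn_factor``
    are flagged in the returned table (and the log), never failed.
    """
    import pandas as pd

    rows = []
    for par in parameters:
        x = store[par]
        if np.ptp(x) == 0:  # structurally constrained (e.g. R12 = 0)
            continue
        res = raftery_lewis(x)
        rows.append({"parameter": par, "thinning_k": res.thinning_k,
                     "burn_in": res.burn_in_m, "required_n": res.required_n,
                     "n_min": res.n_min,
                     "dependence_factor": res.dependence_factor,
                     "high_autocorrelation":
                         res.dependence_factor > warn_factor})
    df = pd.DataFrame(rows)
    if log is not None:
        log.write("Raftery-Lewis diagnostic (q=0.025, r=0.005, s=0.95)\n")
        log.write(df.to_string(index=False) + "\n")
    return df
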