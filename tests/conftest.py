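import numpy as np
import pandas as pd
import pytest

from gibbsam.pedigree import Pedigree
from gibbsam.simulate import simulate_breeding_values


def make_random_pedigree(rng, n, n_founders=None, p_unknown=0.2) -> Pedigree:
    """Random valid pedigree: founders first, then animals drawing each
    parent (possibly unknown) from the earlier animals."""
    n_founders = n_founders or max(2, n // 5)
    recs = []
    for a in range(1, n + 1):
        if a <= n_founders:
            recs.append((a, 0, 0))
            continue
        s = int(rng.integers(1, a)) if rng.random() > p_unknown else 0
        d = int(rng.integers(1, a)) if rng.random() > p_unknown else 0
        if d == s:
            d = 0
        recs.append((a, s, d))
    rng.shuffle(recs)
    return Pedigree.from_records(recs)


def make_halfsib_data(rng, n_sires, n_prog, G, R, mu=(0.0, 0.0)):
    """Balanced paternal half-sib families with both traits recorded on
    every offspring (dams unknown and unrelated)."""
    recs = [(s, 0, 0) for s in range(1, n_sires + 1)]
    aid = n_sires
    for s in range(1, n_sires + 1):
        for _ in range(n_prog):
            aid += 1
            recs.append((aid, s, 0))
    ped = Pedigree.from_records(recs)
    bv = simulate_breeding_values(ped, np.asarray(G, float), rng)
    off = ped.index_of(np.arange(n_sires + 1, aid + 1))
    L = np.linalg.cholesky(np.asarray(R, float))
    e = rng.standard_normal((len(off), 2)) @ L.T
    y = np.asarray(mu) + bv[off] + e
    pheno = pd.DataFrame({
        "animal": np.asarray(ped.ids)[off],
        "t1": y[:, 0],
        "t2": y[:, 1],
    })
    return ped, pheno


def anova_halfsib_h2(y, sire_of_record, n_prog):
    """Sire-model ANOVA heritability: h2 = 4 sigma_s^2 / sigma_p^2 from
    the between/within mean squares of a balanced design."""
    sires = np.unique(sire_of_record)
    means = np.array([y[sire_of_record == s].mean() for s in sires])
    grand = y.mean()
    msb = n_prog * np.sum((means - grand) ** 2) / (len(sires) - 1)
    ssw = sum(np.sum((y[sire_of_record == s] - m) ** 2)
              for s, m in zip(sires, means))
    msw = ssw / (len(y) - len(sires))
    sigma_s = (msb - msw) / n_prog
    return 4.0 * sigma_s / (sigma_s + msw)


@pytest.fixture
def rng():
    return np.random.default_rng(20230728)
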