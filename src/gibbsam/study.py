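"""Study orchestration: run every bivariate trait pair and assemble
report tables.

A study pairs each purebred boar-taint trait with each crossbred
production/ham-quality trait (plus, optionally, the purebred pairs
among the boar-taint compounds themselves), runs one bivariate chain
per pair, and merges the posterior summaries into a heritability table
and a genetic-correlation table with HPD bounds, P0, P01 and the
0.80/0.70 decision flags.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gibbs import ChainConfig, run_chain
from .phenotypes import BivariateModelSpec, TraitModel, build_design
from .summary import summarize

PB_EFFECTS = ("date_of_analysis",)
CB_EFFECTS = ("sex", "slaughter_group")


@dataclass
class StudyPlan:
    """Ordered list of trait pairs with shared chain settings.

    ``effects`` maps trait name -> tuple of fixed-effect columns;
    per-run seeds are derived deterministically from the chain seed and
    the pair index.
    """

    pairs: list
    effects: dict
    chain: ChainConfig = field(default_factory=ChainConfig)
    reference_pairs: dict = field(default_factory=dict)  # trait -> pair index

    def __post_init__(self):
        seen = set()
        for pair in self.pairs:
            key = frozenset(pair)
            if key in seen:
                raise ValueError(f"duplicate trait pair {pair}")
            seen.add(key)

    def run_seed(self, pair_index: int) -> int:
        ss = np.random.SeedSequence(self.chain.seed, spawn_key=(pair_index,))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def plan_study(pb_traits, cb_traits, include_pb_pairs: bool = True,
               chain: ChainConfig | None = None,
               effects: dict | None = None) -> StudyPlan:
    """All PB x CB combinations, plus unordered PB x PB pairs if asked."""
    pb_traits = list(pb_traits)
    cb_traits = list(cb_traits)
    allnames = pb_traits + cb_traits
    if len(set(allnames)) != len(allnames):
        raise ValueError("duplicate trait names in the study")
    pairs = []
    if include_pb_pairs:
        pairs += list(itertools.combinations(pb_traits, 2))
    pairs += list(itertools.product(pb_traits, cb_traits))
    eff = {t: PB_EFFECTS for t in pb_traits}
    eff.update({t: CB_EFFECTS for t in cb_traits})
    if effects:
        eff.update(effects)
    return StudyPlan(pairs=pairs, effects=eff,
                     chain=chain or ChainConfig())


@dataclass
class StudyResult:
    heritability: pd.DataFrame
    correlations: pd.DataFrame
    failures: list

    @property
    def ok(self) -> bool:
        return not self.failures


def run_study(plan: StudyPlan, ped, pheno, out_dir=None, log=None) -> StudyResult:
    """Execute every planned pair sequentially.

    A failed run is recorded and the study continues; callers should
    treat a non-empty failure list as a non-zero exit.  The
    heritability of each trait is reported from its designated
    reference pair (by default the first pair in which it appears).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    h2_rows, rg_rows, failures = [], [], []
    h2_seen = {}
    for k, (ta, tb) in enumerate(plan.pairs):
        seed = plan.run_seed(k)
        cfg = replace(plan.chain, seed=seed)
        spec = BivariateModelSpec(
            TraitModel(ta, plan.effects.get(ta, ())),
            TraitModel(tb, plan.effects.get(tb, ())))
        tag = f"{ta}_x_{tb}"
        try:
            design = build_design(ped, pheno, spec)
            store = run_chain(
                design, cfg,
                samples_path=(out / f"samples_{tag}.csv") if out else None,
                log=log)
            summ = summarize(store).set_index("parameter")
        except Exception as exc:  # noqa: BLE001 - study must continue
            failures.append((tag, repr(exc)))
            if log is not None:
                log.write(f"FAILED {tag}: {exc!r}\n")
            continue
        rg = summ.loc["rg"]
        rg_rows.append({
            "trait1": ta, "trait2": tb, "rg": rg["median"],
            "hpd_low": rg["hpd_low"], "hpd_high": rg["hpd_high"],
            "p0": rg["p0"], "p01": rg["p01"],
            "nonzero": bool(rg["nonzero"]), "relevant": bool(rg["relevant"]),
            "residual_free": design.residual_free, "seed": seed,
        })
        for trait, par in ((ta, "h2_t1"), (tb, "h2_t2")):
            ref = plan.reference_pairs.get(trait, h2_seen.get(trait, k))
            if trait not in h2_seen:
                h2_seen[trait] = k
            if ref != k:
                continue
            h2 = summ.loc[par]
            h2_rows.append({
                "trait": trait, "h2": h2["median"],
                "hpd_low": h2["hpd_low"], "hpd_high": h2["hpd_high"],
                "from_pair": tag, "seed": seed,
            })
    h2_df = pd.DataFrame(h2_rows)
    rg_df = pd.DataFrame(rg_rows)
    if out is not None:
        h2_df.to_csv(out / "heritability.csv", index=False,
                     float_format="%.4f")
        rg_df.to_csv(out / "correlations.csv", index=False,
                     float_format="%.4f")
    return StudyResult(h2_df, rg_df, failures)
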