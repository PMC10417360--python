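"""Synthetic two-tier breeding data with the structure the analysis assumes.

The generator emulates a purebred nucleus plus crossbred sib-testing
design: nucleus boars mated to nucleus sows produce purebred (PB)
offspring carrying boar-taint phenotypes, while semen from (a subset of)
the same boars inseminates unrelated crossbred (CB) dams to produce CB
offspring carrying carcass/ham phenotypes.  The two trait groups are
therefore recorded on disjoint animal sets and connected only through
the shared sires -- exactly the situation in which the residual
covariance of a PB x CB trait pair is structurally zero and the genetic
correlation is identified through the pedigree alone.

Trait calibrations (mean, phenotypic SD, heritability) and the default
genetic correlations are published posterior-median estimates for a
commercial Italian heavy-pig sire line (C21 Goland), so
parameter-recovery runs double as a reproduction of that parameter
set.

Breeding values follow the pedigree recursion a_i = 0.5(a_s + a_d) + m_i
with Mendelian-sampling covariance 0.5 (1 - (f_s + f_d)/2) G, giving
(a_1, a_2) ~ N(0, G (x) A) exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree


@dataclass(frozen=True)
class TraitSpec:
    """Calibration of one simulated trait.

    ``mean`` and ``sd`` are on the analysis scale (log ng/g for the
    boar-taint compounds); ``h2`` is the additive fraction of the
    model variance (phenotypic variance net of batch effects).
    """

    name: str
    mean: float
    sd: float
    h2: float
    group: str = "pb"  # 'pb': purebred-recorded, 'cb': crossbred-recorded


#: Purebred boar-taint traits (log ng/g) and crossbred carcass/ham traits,
#: calibrated to the descriptive statistics and posterior median
#: heritabilities of the source population.
DEFAULT_TRAITS = {
    "androstenone": TraitSpec("androstenone", 6.76, 0.76, 0.41, "pb"),
    "skatole": TraitSpec("skatole", 3.28, 1.07, 0.49, "pb"),
    "indole": TraitSpec("indole", 2.62, 0.92, 0.37, "pb"),
    "bw270": TraitSpec("bw270", 170.22, 15.71, 0.50, "cb"),
    "killing_out": TraitSpec("killing_out", 82.85, 1.62, 0.29, "cb"),
    "backfat": TraitSpec("backfat", 27.31, 5.38, 0.41, "cb"),
    "lean_meat": TraitSpec("lean_meat", 50.65, 3.67, 0.45, "cb"),
    "marbling": TraitSpec("marbling", 1.40, 0.86, 0.42, "cb"),
    "subcut_fat_score": TraitSpec("subcut_fat_score", 0.05, 1.56, 0.39, "cb"),
    "fat_biceps": TraitSpec("fat_biceps", 22.61, 7.55, 0.39, "cb"),
    "fat_semimem": TraitSpec("fat_semimem", 0.59, 0.10, 0.35, "cb"),
    "iodine": TraitSpec("iodine", 69.01, 3.68, 0.43, "cb"),
    "pufa": TraitSpec("pufa", 15.08, 2.10, 0.44, "cb"),
    "c18_2n6": TraitSpec("c18_2n6", 13.00, 1.87, 0.44, "cb"),
    "c18_0": TraitSpec("c18_0", 11.59, 1.69, 0.43, "cb"),
    "mufa_pufa": TraitSpec("mufa_pufa", 3.31, 0.49, 0.41, "cb"),
    "round_shape": TraitSpec("round_shape", 1.72, 0.87, 0.37, "cb"),
    "color": TraitSpec("color", -0.04, 1.37, 0.32, "cb"),
    "veining": TraitSpec("veining", 1.15, 0.88, 0.23, "cb"),
    "weight_loss": TraitSpec("weight_loss", 26.70, 1.85, 0.36, "cb"),
}

#: Posterior-median genetic correlations used as default simulation
#: truths (unordered trait pairs).
DEFAULT_GENETIC_CORRELATIONS = {
    ("androstenone", "skatole"): 0.40,
    ("androstenone", "indole"): 0.57,
    ("skatole", "indole"): 0.85,
    ("androstenone", "bw270"): -0.11,
    ("skatole", "bw270"): -0.07,
    ("indole", "bw270"): -0.19,
    ("androstenone", "killing_out"): 0.00,
    ("skatole", "killing_out"): -0.40,
    ("indole", "killing_out"): 0.21,
    ("androstenone", "backfat"): -0.26,
    ("skatole", "backfat"): -0.55,
    ("indole", "backfat"): -0.44,
    ("androstenone", "lean_meat"): 0.06,
    ("skatole", "lean_meat"): -0.20,
    ("indole", "lean_meat"): -0.35,
    ("androstenone", "marbling"): -0.26,
    ("skatole", "marbling"): 0.11,
    ("indole", "marbling"): 0.04,
    ("androstenone", "subcut_fat_score"): -0.14,
    ("skatole", "subcut_fat_score"): 0.11,
    ("indole", "subcut_fat_score"): -0.17,
    ("androstenone", "fat_biceps"): -0.15,
    ("skatole", "fat_biceps"): 0.54,
    ("indole", "fat_biceps"): -0.07,
    ("androstenone", "fat_semimem"): 0.16,
    ("skatole", "fat_semimem"): 0.43,
    ("indole", "fat_semimem"): 0.05,
    ("androstenone", "iodine"): -0.07,
    ("skatole", "iodine"): -0.64,
    ("indole", "iodine"): -0.54,
    ("androstenone", "pufa"): -0.20,
    ("skatole", "pufa"): -0.33,
    ("indole", "pufa"): -0.13,
    ("androstenone", "c18_2n6"): -0.21,
    ("skatole", "c18_2n6"): -0.32,
    ("indole", "c18_2n6"): -0.12,
    ("androstenone", "c18_0"): 0.02,
    ("skatole", "c18_0"): 0.25,
    ("indole", "c18_0"): 0.21,
    ("androstenone", "mufa_pufa"): 0.41,
    ("skatole", "mufa_pufa"): 0.50,
    ("indole", "mufa_pufa"): 0.25,
    ("androstenone", "round_shape"): 0.01,
    ("skatole", "round_shape"): 0.05,
    ("indole", "round_shape"): 0.24,
    ("androstenone", "color"): 0.16,
    ("skatole", "color"): -0.13,
    ("indole", "color"): -0.16,
    ("androstenone", "veining"): -0.08,
    ("skatole", "veining"): -0.01,
    ("indole", "veining"): 0.25,
    ("androstenone", "weight_loss"): 0.01,
    ("skatole", "weight_loss"): -0.13,
    ("indole", "weight_loss"): -0.02,
}


def default_correlation(trait_a: str, trait_b: str) -> float:
    try:
        return DEFAULT_GENETIC_CORRELATIONS[(trait_a, trait_b)]
    except KeyError:
        return DEFAULT_GENETIC_CORRELATIONS[(trait_b, trait_a)]


@dataclass
class SimConfig:
    """Population design and trait truths for one simulated dataset.

    The default counts reproduce the source population: 27 nucleus
    boars x 226 nucleus sows -> 1115 PB offspring with boar-taint
    records, and 731 CB sires x 1885 unrelated CB dams -> 26,577 CB
    offspring with carcass/ham records, with all 27 nucleus boars also
    siring CB progeny (~35 CB piglets per nucleus boar).

    Batch structure scales with the data: assay batches
    ("date of analysis") of ~12 PB pigs and slaughter groups of ~70 CB
    pigs, which at full scale yields the recorded 94 batch and
    100-400 group levels.  Batch and group effects are centred normal
    with SDs of 0.3 and 0.2 phenotypic SD; sex enters as a fixed
    contrast of 0.25 phenotypic SD.
    """

    trait1: TraitSpec = DEFAULT_TRAITS["skatole"]
    trait2: TraitSpec = DEFAULT_TRAITS["backfat"]
    genetic_correlation: float | None = None  # default: study estimate
    residual_correlation: float = 0.0  # only for same-tier pairs
    n_nucleus_boars: int = 27
    n_nucleus_sows: int = 226
    n_pb: int = 1115
    n_cb_sires: int = 731
    n_cb_dams: int = 1885
    n_cb: int = 26_577
    shared_sires: int = 27
    pb_batch_size: int = 12
    cb_group_size: int = 70
    batch_sd_frac: float = 0.3
    group_sd_frac: float = 0.2
    sex_contrast_frac: float = 0.25
    seed: int = 1

    def __post_init__(self):
        if self.genetic_correlation is None:
            self.genetic_correlation = default_correlation(
                self.trait1.name, self.trait2.name)
        if self.shared_sires > self.n_nucleus_boars:
            raise ValueError("shared_sires cannot exceed the nucleus boars")
        if self.n_cb > 0 and self.n_cb_sires < max(self.shared_sires, 1):
            raise ValueError("need at least shared_sires CB sires")
        if self.two_tier and self.n_cb > 0 and self.shared_sires == 0 \
                and abs(self.genetic_correlation) > 0:
            pass  # legal but the correlation is unidentifiable downstream

    @property
    def two_tier(self) -> bool:
        return self.trait2.group == "cb"

    @property
    def n_batches(self) -> int:
        return max(2, round(self.n_pb / self.pb_batch_size))

    @property
    def n_groups(self) -> int:
        return max(2, round(self.n_cb / self.cb_group_size)) if self.n_cb else 0

    # ---- variance calibration ---------------------------------------

    def _model_variance(self, trait: TraitSpec) -> float:
        """Phenotypic variance net of batch/sex effects so that the
        total simulated variance matches the trait's descriptive SD."""
        vp = trait.sd ** 2
        if trait.group == "pb":
            return vp * (1.0 - self.batch_sd_frac ** 2)
        vfix = self.group_sd_frac ** 2 + self.sex_contrast_frac ** 2 / 4.0
        return vp * (1.0 - vfix)

    @property
    def G(self) -> np.ndarray:
        v1 = self.trait1.h2 * self._model_variance(self.trait1)
        v2 = self.trait2.h2 * self._model_variance(self.trait2)
        g12 = self.genetic_correlation * np.sqrt(v1 * v2)
        G = np.array([[v1, g12], [g12, v2]])
        if np.linalg.eigvalsh(G)[0] <= 0:
            raise ValueError("true G is not positive definite")
        return G

    @property
    def R(self) -> np.ndarray:
        v1 = (1.0 - self.trait1.h2) * self._model_variance(self.trait1)
        v2 = (1.0 - self.trait2.h2) * self._model_variance(self.trait2)
        r12 = 0.0 if self.two_tier else self.residual_correlation * np.sqrt(v1 * v2)
        return np.array([[v1, r12], [r12, v2]])

    def truth(self) -> dict:
        """True parameter values on the scales the analysis reports."""
        G, R = self.G, self.R
        return {
            "trait1": self.trait1.name, "trait2": self.trait2.name,
            "G": G.tolist(), "R": R.tolist(),
            "h2_t1": float(G[0, 0] / (G[0, 0] + R[0, 0])),
            "h2_t2": float(G[1, 1] / (G[1, 1] + R[1, 1])),
            "rg": float(self.genetic_correlation),
        }

    @classmethod
    def desk(cls, trait1="skatole", trait2="backfat", seed=1, **kw) -> "SimConfig":
        """Reduced-scale two-tier preset: ~1000 PB from the full nucleus,
        ~3000 CB from ~30 shared + proportional extra sires."""
        t1 = DEFAULT_TRAITS[trait1] if isinstance(trait1, str) else trait1
        t2 = DEFAULT_TRAITS[trait2] if isinstance(trait2, str) else trait2
        if t2.group == "pb":
            kw.setdefault("n_cb", 0)
            kw.setdefault("n_cb_sires", 27)
            kw.setdefault("n_cb_dams", 0)
        else:
            kw.setdefault("n_cb", 3000)
            # ~36 CB progeny per sire and ~14 per dam, as at full scale
            kw.setdefault("n_cb_sires",
                          max(kw.get("shared_sires", 27), round(kw["n_cb"] / 36)))
            kw.setdefault("n_cb_dams", max(1, round(kw["n_cb"] / 14)))
        kw.setdefault("n_pb", 1000)
        return cls(trait1=t1, trait2=t2, seed=seed, **kw)


@dataclass
class SimulatedData:
    """Pedigree, role indices, phenotypes and simulation truth."""

    ped: Pedigree
    roles: dict          # role name -> array of original ids
    phenotypes: pd.DataFrame
    breeding_values: np.ndarray  # (q, 2), pedigree order
    config: SimConfig

    def write(self, outdir) -> None:
        from pathlib import Path
        from .pedigree import write_pedigree
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_pedigree(self.ped, out / "pedigree.csv")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False,
                               na_rep="NA", float_format="%.8g")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.config.truth(), fh, indent=1)


def _balanced(pool: np.ndarray, n: int, rng) -> np.ndarray:
    """Random assignment of ``pool`` members to n slots, as equal as
    possible (each member gets floor(n/len) or ceil(n/len) slots)."""
    reps = np.resize(pool, n)
    return rng.permutation(reps)


def simulate_pedigree(cfg: SimConfig, rng=None):
    """Two-tier pedigree: nucleus founders, PB offspring from balanced
    boar x sow matings, CB offspring from the sire pool (shared nucleus
    boars plus extra CB sires) on unrelated CB dams.

    Returns (Pedigree, roles) with roles mapping
    'nucleus_boars'/'nucleus_sows'/'extra_sires'/'cb_dams'/'pb'/'cb'
    to original id arrays.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_extra = (cfg.n_cb_sires - cfg.shared_sires) if cfg.n_cb else 0
    counts = [cfg.n_nucleus_boars, cfg.n_nucleus_sows, n_extra,
              cfg.n_cb_dams if cfg.n_cb else 0, cfg.n_pb, cfg.n_cb]
    if cfg.n_pb > 0 and (cfg.n_nucleus_boars == 0 or cfg.n_nucleus_sows == 0):
        raise ValueError("PB offspring need nucleus boars and sows")
    if cfg.n_cb > 0 and (cfg.n_cb_sires == 0 or cfg.n_cb_dams == 0):
        raise ValueError("CB offspring need sires and dams")
    starts = np.concatenate([[1], 1 + np.cumsum(counts)])
    boars = np.arange(starts[0], starts[1])
    sows = np.arange(starts[1], starts[2])
    extras = np.arange(starts[2], starts[3])
    cbdams = np.arange(starts[3], starts[4])
    pb = np.arange(starts[4], starts[5])
    cb = np.arange(starts[5], starts[6])

    records = [(a, 0, 0) for a in np.concatenate([boars, sows, extras, cbdams])]
    pb_sires = _balanced(boars, cfg.n_pb, rng)
    pb_dams = _balanced(sows, cfg.n_pb, rng)
    records += [(a, s, d) for a, s, d in zip(pb, pb_sires, pb_dams)]
    if cfg.n_cb:
        sire_pool = np.concatenate([boars[: cfg.shared_sires], extras])
        cb_sires = _balanced(sire_pool, cfg.n_cb, rng)
        cb_dams_a = _balanced(cbdams, cfg.n_cb, rng)
        records += [(a, s, d) for a, s, d in zip(cb, cb_sires, cb_dams_a)]
    ped = Pedigree.from_records(records)
    roles = {"nucleus_boars": boars, "nucleus_sows": sows,
             "extra_sires": extras, "cb_dams": cbdams, "pb": pb, "cb": cb}
    return ped, roles


def simulate_breeding_values(ped: Pedigree, G: np.ndarray, rng) -> np.ndarray:
    """Bivariate breeding values with covariance G (x) A.

    Founders are N(0, G); a non-founder is the parent average plus a
    Mendelian-sampling deviation with covariance w G, where
    w = 0.5 (1 - (f_s + f_d)/2) for two known parents, 0.75 - 0.25 f_s
    for one, and 1 for none.  Processed level-by-level so each batch is
    vectorized.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    q = ped.n
    w = ped.mendelian_d()  # same weights as the A = T D T' decomposition
    G = np.asarray(G, dtype=float)
    Lg = (np.linalg.cholesky(G) if np.linalg.eigvalsh(G)[0] > 0
          else _chol_psd(G))
    a = np.zeros((q, 2))
    level = np.zeros(q, dtype=int)
    for par in (ped.sire, ped.dam):
        known = par >= 0
        level[known] = np.maximum(level[known], level[par[known]] + 1)
    # levels are consistent because the pedigree is topologically ordered
    for lv in range(level.max() + 1):
        idx = np.nonzero(level == lv)[0]
        m = (rng.standard_normal((len(idx), 2)) * np.sqrt(w[idx])[:, None]) @ Lg.T
        mean = np.zeros((len(idx), 2))
        for par in (ped.sire[idx], ped.dam[idx]):
            known = par >= 0
            mean[known] += 0.5 * a[par[known]]
        a[idx] = mean + m
    return a


def _chol_psd(G):
    """Factor of a merely positive *semi*definite G (e.g. zero variance)."""
    vals, vecs = np.linalg.eigh(G)
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))


def simulate_phenotypes(ped: Pedigree, roles: dict, bv: np.ndarray,
                        cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Phenotype table: trait 1 on PB offspring (mean + assay batch +
    a1 + e1), trait 2 on CB offspring for two-tier designs (mean + sex +
    slaughter group + a2 + e2, residuals independent of trait 1) or on
    the same PB animals for purebred pairs (shared batch levels,
    trait-specific batch effects, residual correlation as configured)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    R = cfg.R
    t1, t2 = cfg.trait1, cfg.trait2
    pb_idx = ped.index_of(roles["pb"])
    nb = cfg.n_batches
    batch = rng.integers(0, nb, cfg.n_pb)
    batch_eff1 = rng.normal(0.0, cfg.batch_sd_frac * t1.sd, nb)

    cols = {"animal": [], t1.name: [], t2.name: [],
            "date_of_analysis": [], "sex": [], "slaughter_group": []}

    if cfg.two_tier:
        e1 = rng.normal(0.0, np.sqrt(R[0, 0]), cfg.n_pb)
        y1 = t1.mean + batch_eff1[batch] + bv[pb_idx, 0] + e1
        cols["animal"].append(roles["pb"])
        cols[t1.name].append(y1)
        cols[t2.name].append(np.full(cfg.n_pb, np.nan))
        cols["date_of_analysis"].append(batch + 1)
        cols["sex"].append(np.full(cfg.n_pb, -1))
        cols["slaughter_group"].append(np.full(cfg.n_pb, -1))

        cb_idx = ped.index_of(roles["cb"])
        ng = cfg.n_groups
        grp = rng.integers(0, ng, cfg.n_cb)
        grp_eff = rng.normal(0.0, cfg.group_sd_frac * t2.sd, ng)
        sex = rng.integers(0, 2, cfg.n_cb)
        delta = cfg.sex_contrast_frac * t2.sd
        e2 = rng.normal(0.0, np.sqrt(R[1, 1]), cfg.n_cb)
        y2 = (t2.mean + grp_eff[grp] + (sex - 0.5) * delta
              + bv[cb_idx, 1] + e2)
        cols["animal"].append(roles["cb"])
        cols[t1.name].append(np.full(cfg.n_cb, np.nan))
        cols[t2.name].append(y2)
        cols["date_of_analysis"].append(np.full(cfg.n_cb, -1))
        cols["sex"].append(sex)
        cols["slaughter_group"].append(grp + 1)
    else:
        batch_eff2 = rng.normal(0.0, cfg.batch_sd_frac * t2.sd, nb)
        Lr = _chol_psd(R) if np.linalg.det(R) <= 0 else np.linalg.cholesky(R)
        e = rng.standard_normal((cfg.n_pb, 2)) @ Lr.T
        y1 = t1.mean + batch_eff1[batch] + bv[pb_idx, 0] + e[:, 0]
        y2 = t2.mean + batch_eff2[batch] + bv[pb_idx, 1] + e[:, 1]
        cols["animal"].append(roles["pb"])
        cols[t1.name].append(y1)
        cols[t2.name].append(y2)
        cols["date_of_analysis"].append(batch + 1)
        cols["sex"].append(np.full(cfg.n_pb, -1))
        cols["slaughter_group"].append(np.full(cfg.n_pb, -1))

    df = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    for c in ("date_of_analysis", "sex", "slaughter_group"):
        df[c] = df[c].astype(float)
        df.loc[df[c] < 0, c] = np.nan
    return df


def simulate(cfg: SimConfig) -> SimulatedData:
    """Full dataset: pedigree, breeding values, phenotypes, truth."""
    rng = np.random.default_rng(cfg.seed)
    ped, roles = simulate_pedigree(cfg, rng)
    bv = simulate_breeding_values(ped, cfg.G, rng)
    pheno = simulate_phenotypes(ped, roles, bv, cfg, rng)
    return SimulatedData(ped, roles, pheno, bv, cfg)
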