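"""Phenotype tables, pre-analysis transforms and bivariate design assembly.

Phenotypes live in a wide table: one row per animal, one column per
trait, plus columns holding the levels of the systematic environmental
effects (assay batch, sex, slaughter group, ...).  Missing entries are
``NA``.  :func:`build_design` turns a pedigree, a phenotype table and a
:class:`BivariateModelSpec` into the incidence structures the Gibbs
sampler consumes.

Boar-taint compound concentrations are natural-log transformed before
analysis; crossbred body weight is adjusted to a 270-day endpoint by a
per-animal linear regression of weight on age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree


def log_transform(values, ids=None) -> np.ndarray:
    """Natural logarithm of strictly positive concentrations (ng/g).

    Non-positive values cannot be log-transformed; the corresponding
    records are rejected (returned as NaN) with a warning naming the
    offending animals.
    """
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    ok = v > 0
    out[ok] = np.log(v[ok])
    if not np.all(ok | np.isnan(v)):
        bad = np.nonzero(~ok & ~np.isnan(v))[0]
        labels = [ids[i] for i in bad] if ids is not None else list(bad)
        warnings.warn(
            f"rejected {len(bad)} non-positive concentration(s) "
            f"(records {labels[:10]}{'...' if len(labels) > 10 else ''})",
            stacklevel=2,
        )
    return out


def adjust_bw_to_270(ages, weights, target: float = 270.0) -> float:
    """Body weight at the target age from a per-animal OLS regression.

    Fits weight = a + b * age by ordinary least squares over the
    animal's repeated measures and evaluates the line at ``target``
    days.  With fewer than two distinct ages the endpoint is undefined
    and NaN is returned with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(ages) < 2 or np.ptp(ages) == 0:
        warnings.warn("need >= 2 distinct ages for weight adjustment; "
                      "returning missing", stacklevel=2)
        return float("nan")
    slope, intercept = np.polyfit(ages, weights, 1)
    return float(intercept + slope * target)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a delimited phenotype table; first column is the animal id,
    ``NA`` marks missing values."""
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
    df = df.rename(columns={df.columns[0]: "animal"})
    return df


@dataclass(frozen=True)
class TraitModel:
    """One trait and the systematic (fixed) effects of its model."""

    name: str
    effects: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple(self.effects))


@dataclass
class BivariateModelSpec:
    """Trait pair for one bivariate run.

    ``residual_covariance_free`` may be left ``None`` to be inferred
    from the data: the residual covariance is estimable only when some
    animal carries records for both traits; for disjointly recorded
    pairs (purebred vs crossbred) it is structurally constrained to 0.
    """

    trait1: TraitModel
    trait2: TraitModel
    residual_covariance_free: bool | None = None


@dataclass
class TraitDesign:
    """Assembled incidence structure for one trait of a bivariate run."""

    name: str
    y: np.ndarray
    X: sp.csr_matrix
    animal_rows: np.ndarray  # pedigree internal index per record
    columns: list = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.y)


@dataclass
class DesignBundle:
    ped: Pedigree
    t1: TraitDesign
    t2: TraitDesign
    residual_free: bool
    spec: BivariateModelSpec

    @property
    def joint_animals(self) -> np.ndarray:
        return np.intersect1d(self.t1.animal_rows, self.t2.animal_rows)


def _trait_design(ped: Pedigree, df: pd.DataFrame, trait: TraitModel) -> TraitDesign:
    if trait.name not in df.columns:
        raise KeyError(f"trait column '{trait.name}' not in phenotype table")
    rows = df[df[trait.name].notna()].copy()
    for eff in trait.effects:
        if eff not in df.columns:
            raise KeyError(f"effect column '{eff}' not in phenotype table")
        missing = rows[eff].isna()
        if missing.any():
            warnings.warn(
                f"{trait.name}: dropped {int(missing.sum())} record(s) with "
                f"missing '{eff}' label", stacklevel=3,
            )
            rows = rows[~missing]
    if rows.empty:
        raise ValueError(f"no usable records for trait '{trait.name}'")
    if rows["animal"].duplicated().any():
        dup = rows.loc[rows["animal"].duplicated(), "animal"].iloc[0]
        raise ValueError(
            f"{trait.name}: more than one record for animal {dup}")
    animal_rows = ped.index_of(rows["animal"].to_numpy())
    n = len(rows)
    y = rows[trait.name].to_numpy(dtype=float)

    blocks, columns = [], []
    if not trait.effects:
        blocks.append(sp.csr_matrix(np.ones((n, 1))))
        columns.append("(mean)")
    for k, eff in enumerate(trait.effects):
        codes, levels = pd.factorize(rows[eff], sort=True)
        # first effect keeps all levels (carries the general mean);
        # later effects absorb their first level for identifiability
        drop_first = k > 0
        if drop_first and len(levels) == 1:
            continue
        keep = codes >= 1 if drop_first else codes >= 0
        col = codes - 1 if drop_first else codes
        ncol = len(levels) - (1 if drop_first else 0)
        blocks.append(
            sp.csr_matrix(
                (np.ones(int(keep.sum())), (np.nonzero(keep)[0], col[keep])),
                shape=(n, ncol),
            )
        )
        columns.extend(f"{eff}:{lv}" for lv in levels[1 if drop_first else 0:])
    X = sp.hstack(blocks, format="csr")
    return TraitDesign(trait.name, y, X, animal_rows, columns)


def build_design(ped: Pedigree, pheno: pd.DataFrame,
                 spec: BivariateModelSpec) -> DesignBundle:
    """Assemble the design bundle for a bivariate animal-model run.

    Every phenotyped animal must be in the pedigree.  The residual
    covariance is flagged free only when the two traits share at least
    one recorded animal; otherwise it is structurally zero.
    """
    t1 = _trait_design(ped, pheno, spec.trait1)
    t2 = _trait_design(ped, pheno, spec.trait2)
    shared = np.intersect1d(t1.animal_rows, t2.animal_rows).size > 0
    free = spec.residual_covariance_free
    if free is None:
        free = shared
    elif free and not shared:
        raise ValueError(
            "residual covariance cannot be free: the traits share no "
            "recorded animal"
        )
    return DesignBundle(ped, t1, t2, bool(free), spec)
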