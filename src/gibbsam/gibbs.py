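"""Bivariate Bayesian animal-model Gibbs sampler.

Model, per trait t in {1, 2}:

    y_t = X_t b_t + Z_t a_t + e_t

with flat priors on the fixed effects b_t and on the (co)variance
components, additive genetic effects (a_1, a_2) ~ N(0, G (x) A) over all
pedigree animals, and residuals ~ N(0, R) per animal over the recorded
cells.  When the two traits are recorded on disjoint animal sets the
residual covariance R12 is not estimable and is held at exactly 0.

One Gibbs cycle draws

1. all location parameters jointly from their multivariate-normal full
   conditional (mixed-model equations with R^-1 data weights and
   G^-1 (x) A^-1 on the animal block),
2. G from an inverse-Wishart with scale S_a, S_a[i,j] = a_i' A^-1 a_j,
3. R from per-trait scaled inverse-chi-squares (disjoint recording) or
   a 2x2 inverse-Wishart over the jointly recorded animals.

The location draw uses sampling-by-perturbation: with C the coefficient
matrix and eta = W'R^-1(y + e*) + F z, where e* ~ N(0, R) per record
pattern and F F' = G^-1 (x) A^-1, the solution of C theta = eta is an
exact draw from N(C^-1 W'R^-1 y, C^-1).  The pedigree factor
A^-1 = L_A L_A' with L_A = (I-P)' D^-1/2 makes F z an O(q) operation.
C is refactorized each iteration with a sparse Cholesky whose symbolic
analysis is computed once; equations are ordered youngest animal first
(traits interleaved) with fixed effects last, which keeps fill low on
pedigree problems.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import invwishart

from .phenotypes import DesignBundle
from .sparse_chol import (NotPositiveDefiniteError, SparseCholesky,
                          embed_positions, structural_union)

SAMPLE_COLUMNS = ["iter", "G11", "G12", "G22", "R11", "R12", "R22",
                  "h2_t1", "h2_t2", "rg"]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings.

    ``df_convention`` fixes the degrees of freedom of the conditional
    inverse-Wishart / scaled inverse-chi-square draws.  "flat" is the
    conditional implied by a constant prior on the (co)variances:
    df = q - 3 (genetic, 2 traits), n - 3 (joint residual) and a
    chi-square with n - 2 df for a single residual variance.  "q" uses
    df = q resp. n_t, a convention found in some Gibbs implementations;
    it corresponds to an extra |G|^-3/2 prior factor that diverges at
    singular G and measurably attracts weakly informed chains to the
    |r_g| = 1 boundary, so "flat" is the default.
    """

    iterations: int = 20_000
    burn_in: int = 4_000
    lag: int = 4
    seed: int = 1
    df_convention: str = "flat"

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn-in must be smaller than total iterations")
        if self.lag < 1:
            raise ValueError("thinning lag must be >= 1")
        if self.df_convention not in ("flat", "q"):
            raise ValueError("df_convention must be 'flat' or 'q'")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.lag

    @classmethod
    def desk(cls, seed: int = 1, **kw) -> "ChainConfig":
        """Desk-scale preset: 20,000 iterations, 4,000 burn-in, lag 4."""
        return cls(iterations=20_000, burn_in=4_000, lag=4, seed=seed, **kw)

    @classmethod
    def full(cls, seed: int = 1, **kw) -> "ChainConfig":
        """Publication-scale preset: 1,000,000 iterations, 100,000
        burn-in, lag 20 -- the settings used for the original full-data
        analyses; desk() is the reduced-scale default."""
        return cls(iterations=1_000_000, burn_in=100_000, lag=20, seed=seed, **kw)


@dataclass
class SampleStore:
    """Retained thinned draws of the (co)variance components and the
    derived heritabilities and genetic correlation."""

    samples: pd.DataFrame
    trait_names: tuple = ("t1", "t2")
    config: ChainConfig | None = None
    n_rejected: int = 0
    runtime_s: float = 0.0

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, key):
        return self.samples[key].to_numpy()

    def save(self, path) -> None:
        self.samples.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def load(cls, path, trait_names=("t1", "t2")) -> "SampleStore":
        return cls(pd.read_csv(path), trait_names=tuple(trait_names))


def _ensure_pd_scale(S: np.ndarray) -> np.ndarray:
    """Ridge a (numerically) singular cross-product scale matrix.

    Degenerate scales arise from an all-zero start or from perfectly
    correlated effects at the parameter-space boundary.
    """
    try:
        np.linalg.cholesky(S)
        return S
    except np.linalg.LinAlgError:
        return S + max(1e-10 * np.trace(S), 1e-12) * np.eye(2)


def sample_genetic_covariance(a1: np.ndarray, a2: np.ndarray, a_inv,
                              rng: np.random.Generator,
                              df_convention: str = "flat") -> np.ndarray:
    """Draw G from its inverse-Wishart full conditional.

    Scale S_a[i,j] = a_i' A^-1 a_j over all q pedigree animals; degrees
    of freedom q - 3 under the flat-prior conditional (q under the "q"
    convention), so the conditional mean is S_a/(df - 3).
    Non-positive-definite draws are redrawn (at most 100 attempts).
    """
    ainv = a_inv.csr if hasattr(a_inv, "csr") else a_inv
    q = ainv.shape[0]
    u1 = ainv @ a1
    u2 = ainv @ a2
    S = np.array([[a1 @ u1, a1 @ u2], [a1 @ u2, a2 @ u2]])
    S = _ensure_pd_scale(S)
    df = q - 3 if df_convention == "flat" else q
    for _ in range(100):
        G = invwishart.rvs(df=df, scale=S, random_state=rng)
        try:
            np.linalg.cholesky(G)
            return G
        except np.linalg.LinAlgError:
            continue
    raise RuntimeError("could not draw a positive definite G in 100 attempts")


def sample_residual(e1: np.ndarray, e2: np.ndarray,
                    joint: tuple | None,
                    free: bool, rng: np.random.Generator,
                    df_convention: str = "flat") -> np.ndarray:
    """Draw R from its full conditional.

    Disjoint recording (``free=False``): each residual variance comes
    from a scaled inverse-chi-square with scale e_t'e_t (df n_t - 2
    under the flat-prior conditional, n_t under the "q" convention),
    and the covariance is exactly 0.  Free case: a 2x2 inverse-Wishart
    from the residual cross-products over the jointly recorded animals,
    ``joint = (idx1, idx2)`` giving each trait's record positions of
    those animals.
    """
    n1, n2 = len(e1), len(e2)
    assert n1 > 0 and n2 > 0, "trait without records must be excluded upstream"
    off = 2 if df_convention == "flat" else 0
    if not free:
        # draw = scale / chi2_df
        r11 = (e1 @ e1) / rng.chisquare(n1 - off)
        r22 = (e2 @ e2) / rng.chisquare(n2 - off)
        return np.array([[r11, 0.0], [0.0, r22]])
    i1, i2 = joint
    E = np.column_stack([e1[i1], e2[i2]])
    S = _ensure_pd_scale(E.T @ E)
    nj = len(i1)
    df = nj - 3 if df_convention == "flat" else nj
    for _ in range(100):
        R = invwishart.rvs(df=df, scale=S, random_state=rng)
        try:
            np.linalg.cholesky(R)
            return R
        except np.linalg.LinAlgError:
            continue
    raise RuntimeError("could not draw a positive definite R in 100 attempts")


class GibbsSampler:
    """Assembled bivariate animal-model sampler for one design bundle.

    Construction performs all structure-dependent work (equation
    ordering, component matrices, symbolic Cholesky); :meth:`run`
    executes the chain.
    """

    def __init__(self, design: DesignBundle, config: ChainConfig):
        self.design = design
        self.config = config
        ped = design.ped
        q = ped.n
        self.q = q
        t1, t2 = design.t1, design.t2
        n1, n2 = t1.n_records, t2.n_records
        p1, p2 = t1.X.shape[1], t2.X.shape[1]
        self.p = p1 + p2
        self.dim = self.p + 2 * q

        for td in (t1, t2):
            if np.var(td.y) <= 0:
                raise ValueError(
                    f"trait '{td.name}' has zero phenotypic variance")

        # ---- equation ordering: animals youngest-first, traits
        # interleaved per animal, fixed effects last ----------------------
        self._colA1 = 2 * (q - 1 - np.arange(q))          # trait-1 BV column
        self._colA2 = self._colA1 + 1
        fix0 = 2 * q

        rows1 = np.arange(n1)
        rows2 = n1 + np.arange(n2)
        X1 = t1.X.tocoo()
        X2 = t2.X.tocoo()
        wr = np.concatenate([
            X1.row, rows2[X2.row],
            rows1, rows2,
        ])
        wc = np.concatenate([
            fix0 + X1.col, fix0 + p1 + X2.col,
            self._colA1[t1.animal_rows], self._colA2[t2.animal_rows],
        ])
        wv = np.concatenate([X1.data, X2.data, np.ones(n1), np.ones(n2)])
        self._W = sp.coo_matrix((wv, (wr, wc)),
                                shape=(n1 + n2, self.dim)).tocsr()
        self._WT = self._W.T.tocsr()
        self._y = np.concatenate([t1.y, t2.y])
        self._rows1, self._rows2 = rows1, rows2

        # record patterns
        common, i1, i2 = np.intersect1d(t1.animal_rows, t2.animal_rows,
                                        return_indices=True)
        self._joint1 = rows1[i1]
        self._joint2 = rows2[i2]
        self._joint_idx = (i1, i2)
        self._single1 = np.setdiff1d(rows1, self._joint1)
        self._single2 = np.setdiff1d(rows2, self._joint2)
        self.free = design.residual_free and len(common) > 0

        # ---- constant sparse components of the coefficient matrix -------
        ainv = ped.a_inverse()
        self._ainv = ainv
        acoo = ainv.csr.tocoo()
        r1c, c1c = self._colA1[acoo.row], self._colA1[acoo.col]
        r2c, c2c = self._colA2[acoo.row], self._colA2[acoo.col]
        K11 = sp.coo_matrix((acoo.data, (r1c, c1c)), shape=(self.dim, self.dim))
        K22 = sp.coo_matrix((acoo.data, (r2c, c2c)), shape=(self.dim, self.dim))
        K12 = sp.coo_matrix(
            (np.concatenate([acoo.data, acoo.data]),
             (np.concatenate([r1c, r2c]), np.concatenate([c2c, c1c]))),
            shape=(self.dim, self.dim))

        def crossprod(rows):
            Wg = self._W[rows]
            return (Wg.T @ Wg).tocsc()

        def crossmix(rows_a, rows_b):
            Wa, Wb = self._W[rows_a], self._W[rows_b]
            M = (Wa.T @ Wb).tocsc()
            return (M + M.T).tocsc()

        if self.free:
            comps = [crossprod(self._joint1), crossprod(self._joint2),
                     crossmix(self._joint1, self._joint2)]
            if len(self._single1):
                comps.append(crossprod(self._single1))
            if len(self._single2):
                comps.append(crossprod(self._single2))
            self._n_single = (len(self._single1) > 0, len(self._single2) > 0)
        else:
            comps = [crossprod(rows1), crossprod(rows2)]
        comps += [K11.tocsc(), K12.tocsc(), K22.tocsc()]

        self._union = structural_union(comps)
        self._compdata = np.zeros((len(comps), self._union.nnz))
        for k, m in enumerate(comps):
            m = m.tocsc()
            m.sort_indices()
            self._compdata[k, embed_positions(self._union, m)] = m.data
        du = self._union.diagonal()
        cols = np.repeat(np.arange(self.dim), np.diff(self._union.indptr))
        self._diag_pos = np.nonzero(self._union.indices == cols)[0]

        self._chol = SparseCholesky(self._union)
        self._d = ped.mendelian_d()
        self.n_rejected = 0

    # ------------------------------------------------------------------

    def _coef_data(self, G, R):
        """Per-iteration numeric data of the coefficient matrix."""
        Ginv = np.linalg.inv(G)
        if self.free:
            Rinv = np.linalg.inv(R)
            coefs = [Rinv[0, 0], Rinv[1, 1], Rinv[0, 1]]
            if self._n_single[0]:
                coefs.append(1.0 / R[0, 0])
            if self._n_single[1]:
                coefs.append(1.0 / R[1, 1])
        else:
            coefs = [1.0 / R[0, 0], 1.0 / R[1, 1]]
        coefs += [Ginv[0, 0], Ginv[0, 1], Ginv[1, 1]]
        return np.asarray(coefs) @ self._compdata, Ginv

    def _rinv_apply(self, v, R):
        """Apply the block-diagonal R^-1 over record patterns."""
        u = np.empty_like(v)
        if self.free:
            Rinv = np.linalg.inv(R)
            u[self._single1] = v[self._single1] / R[0, 0]
            u[self._single2] = v[self._single2] / R[1, 1]
            v1, v2 = v[self._joint1], v[self._joint2]
            u[self._joint1] = Rinv[0, 0] * v1 + Rinv[0, 1] * v2
            u[self._joint2] = Rinv[0, 1] * v1 + Rinv[1, 1] * v2
        else:
            u[self._rows1] = v[self._rows1] / R[0, 0]
            u[self._rows2] = v[self._rows2] / R[1, 1]
        return u

    def _perturbed_rhs(self, G, Ginv, R, rng):
        estar = np.empty(len(self._y))
        if self.free:
            L = np.linalg.cholesky(R)
            z = rng.standard_normal((len(self._joint1), 2))
            estar[self._joint1] = L[0, 0] * z[:, 0]
            estar[self._joint2] = L[1, 0] * z[:, 0] + L[1, 1] * z[:, 1]
            estar[self._single1] = np.sqrt(R[0, 0]) * rng.standard_normal(
                len(self._single1))
            estar[self._single2] = np.sqrt(R[1, 1]) * rng.standard_normal(
                len(self._single2))
        else:
            estar[self._rows1] = np.sqrt(R[0, 0]) * rng.standard_normal(
                len(self._rows1))
            estar[self._rows2] = np.sqrt(R[1, 1]) * rng.standard_normal(
                len(self._rows2))
        rhs = self._WT @ self._rinv_apply(self._y + estar, R)
        # pedigree-structured noise with covariance G^-1 (x) A^-1
        Lg = np.linalg.cholesky(Ginv)
        ped = self.design.ped
        z1 = ped.chol_apply(rng.standard_normal(self.q), self._d)
        z2 = ped.chol_apply(rng.standard_normal(self.q), self._d)
        rhs[self._colA1] += Lg[0, 0] * z1
        rhs[self._colA2] += Lg[1, 0] * z1 + Lg[1, 1] * z2
        return rhs

    def sample_location(self, G, R, rng):
        """One exact joint draw of (b1, b2, a1, a2) from the full
        conditional given G and R.

        Returns (b1, b2, a1, a2) with breeding values in pedigree order.
        On a factorization failure the diagonal is jittered by
        1e-8 tr(C)/dim once before giving up on the iteration.
        """
        data, Ginv = self._coef_data(G, R)
        rhs = self._perturbed_rhs(G, Ginv, R, rng)
        try:
            self._chol.factor(data)
        except NotPositiveDefiniteError:
            jit = 1e-8 * data[self._diag_pos].sum() / self.dim
            data = data.copy()
            data[self._diag_pos] += jit
            self._chol.factor(data)  # second failure aborts the iteration
        theta = self._chol.solve(rhs)
        t1, t2 = self.design.t1, self.design.t2
        p1 = t1.X.shape[1]
        b = theta[2 * self.q:]
        return (b[:p1], b[p1:], theta[self._colA1], theta[self._colA2])

    def residuals(self, b1, b2, a1, a2):
        t1, t2 = self.design.t1, self.design.t2
        e1 = t1.y - t1.X @ b1 - a1[t1.animal_rows]
        e2 = t2.y - t2.X @ b2 - a2[t2.animal_rows]
        return e1, e2

    def initial_components(self):
        """Starting (G, R): half the phenotypic variance per trait on
        each diagonal, zero covariances."""
        v1 = np.var(self.design.t1.y)
        v2 = np.var(self.design.t2.y)
        G = np.diag([0.5 * v1, 0.5 * v2])
        return G, G.copy()

    def run(self, samples_path=None, log=None) -> SampleStore:
        """Execute the chain and return the thinned post-burn-in draws."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        G, R = self.initial_components()
        rows = np.empty((cfg.n_retained, len(SAMPLE_COLUMNS)))
        kept = 0
        self.n_rejected = 0
        t_start = time.perf_counter()
        for it in range(1, cfg.iterations + 1):
            try:
                b1, b2, a1, a2 = self.sample_location(G, R, rng)
            except NotPositiveDefiniteError as exc:
                self.n_rejected += 1
                if self.n_rejected > 0.01 * cfg.iterations:
                    raise RuntimeError(
                        f"more than 1% of iterations aborted "
                        f"(last failure: {exc})") from exc
                continue
            e1, e2 = self.residuals(b1, b2, a1, a2)
            G = sample_genetic_covariance(a1, a2, self._ainv, rng,
                                          cfg.df_convention)
            R = sample_residual(e1, e2, self._joint_idx, self.free, rng,
                                cfg.df_convention)
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.lag == 0 \
                    and kept < cfg.n_retained:
                h2_1 = G[0, 0] / (G[0, 0] + R[0, 0])
                h2_2 = G[1, 1] / (G[1, 1] + R[1, 1])
                rg = G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])
                rows[kept] = (it, G[0, 0], G[0, 1], G[1, 1],
                              R[0, 0], R[0, 1], R[1, 1], h2_1, h2_2, rg)
                kept += 1
        runtime = time.perf_counter() - t_start
        store = SampleStore(
            pd.DataFrame(rows[:kept], columns=SAMPLE_COLUMNS),
            trait_names=(self.design.t1.name, self.design.t2.name),
            config=cfg, n_rejected=self.n_rejected, runtime_s=runtime,
        )
        if samples_path is not None:
            store.save(samples_path)
        if log is not None:
            log.write(
                f"traits: {store.trait_names[0]} x {store.trait_names[1]}\n"
                f"config: iterations={cfg.iterations} burn_in={cfg.burn_in} "
                f"lag={cfg.lag} seed={cfg.seed} df={cfg.df_convention}\n"
                f"records: n1={self.design.t1.n_records} "
                f"n2={self.design.t2.n_records} q={self.q} "
                f"residual_free={self.free}\n"
                f"retained: {kept}  rejected_iterations: {self.n_rejected}\n"
                f"runtime_s: {runtime:.1f}\n")
        return store


def init_chain(design: DesignBundle, config: ChainConfig) -> GibbsSampler:
    """Validate the design and prepare a seeded sampler."""
    return GibbsSampler(design, config)


def run_chain(design: DesignBundle, config: ChainConfig,
              samples_path=None, log=None) -> SampleStore:
    """Assemble and run one bivariate chain (convenience wrapper)."""
    return GibbsSampler(design, config).run(samples_path=samples_path, log=log)
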