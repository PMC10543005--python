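"""Heteroskedastic twin repeated-measures linear mixed model, fit by REML.

The model behind every group-level test in this pipeline:

    y = X beta + Z_f b_f + Z_mz b_mz + Z_dz b_dz + eps

* Fixed effects use centred codes: stimulus level -0.5 / 0 / +0.5 (low,
  medium, high) and condition -0.5 control / +0.5 placebo; the optional
  interaction is the product of the coded columns.
* ``b_f`` is a family-level random vector over the random terms (default:
  intercept, level, placebo), shared by both twins of a pair, with an
  unstructured covariance.
* Individual-level random vectors are split by zygosity: each participant
  loads on either the MZ-suffixed or the DZ-suffixed copy of the random
  columns (the other copy is identically zero), and the covariance matrix is
  block diagonal by zygosity — so DZ twins may be more variable within
  family than MZ twins without biasing the fixed effects toward either
  group.  Singleton participants load on the family block only: with one
  member per family the individual effect is not identifiable and is fixed
  at zero.
* The residual is iid by default; an optional residual-variance *group*
  column allows separate residual variances (used e.g. to express classic
  heteroskedastic two-group problems).

Estimation maximizes the REML criterion profiled over the residual scale,
with all covariance blocks in a log-Cholesky parameterization (positive
semidefinite by construction) and a quasi-Newton optimizer with random
restarts.  Wald t tests use Satterthwaite degrees of freedom obtained by the
delta method on the inverse observed REML information (central differences
on the unconstrained scale).

Implementation note: because families are independent, every REML quantity
is assembled from per-family cross-products (U'U, U'X, U'y, ...) computed
once per dataset; each objective evaluation then costs only small dense
algebra batched over families, independent of the number of trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import CONDITION_CODES, LEVEL_CODES

__all__ = [
    "ModelSpec",
    "EncodedDesign",
    "FixedEffectEstimate",
    "FitResult",
    "EffectSizeD",
    "encode_design",
    "fit_reml",
    "satterthwaite_df",
    "test_fixed_effect",
    "interaction_protocol",
    "cohens_d",
    "one_sample_t_power",
]

_INTERACTION = "stimulus_level:placebo_condition"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description (the only model shapes supported).

    ``fixed`` names the non-intercept fixed terms; ``stimulus_level`` and
    ``placebo_condition`` are recoded from the factor columns, anything else
    is taken as a numeric column.  ``random`` defaults to intercept plus all
    fixed terms, entering the family block and both zygosity-split
    individual blocks.  ``covariates`` are appended to the fixed part only
    (robustness checks).
    """

    outcome: str
    fixed: tuple[str, ...] = ("stimulus_level", "placebo_condition")
    include_interaction: bool = False
    covariates: tuple[str, ...] = ()
    random: tuple[str, ...] | None = None
    include_family_block: bool = True
    include_individual_blocks: bool = True
    family_col: str = "family_id"
    participant_col: str = "participant_id"
    zygosity_col: str = "zygosity"
    residual_group_col: str | None = None

    def random_terms(self) -> tuple[str, ...]:
        if self.random is not None:
            return self.random
        return ("intercept",) + self.fixed


@dataclass(frozen=True)
class FixedEffectEstimate:
    term: str
    beta: float
    se: float
    t: float
    df: float
    p: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class EffectSizeD:
    d: float
    n: int


def _term_column(table: pd.DataFrame, term: str) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(table))
    if term == "stimulus_level":
        levels = table["stimulus_level"]
        bad = set(levels.unique()) - set(LEVEL_CODES)
        if bad:
            raise ValueError(f"unknown stimulus levels {sorted(bad)}")
        return levels.map(LEVEL_CODES).to_numpy(float)
    if term == "placebo_condition":
        col = "condition" if "condition" in table.columns else "placebo_condition"
        conds = table[col]
        bad = set(conds.unique()) - set(CONDITION_CODES)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        return conds.map(CONDITION_CODES).to_numpy(float)
    return table[term].to_numpy(float)


class EncodedDesign:
    """Fixed matrix, random covariates and grouping indices for one model."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.n = len(table)
        if self.n == 0:
            raise ValueError("empty table")

        zyg = table[spec.zygosity_col].astype(str)
        bad = set(zyg.unique()) - {"MZ", "DZ", "singleton"}
        if bad:
            raise ValueError(f"unknown zygosity values {sorted(bad)}")

        names = ["intercept"] + list(spec.fixed)
        cols = [_term_column(table, t) for t in names]
        if spec.include_interaction:
            if len(spec.fixed) < 2:
                raise ValueError("interaction requires two fixed terms")
            cols.append(cols[1] * cols[2])
            names.append(_INTERACTION)
        for cov in spec.covariates:
            cols.append(table[cov].to_numpy(float))
            names.append(cov)
        self.X = np.column_stack(cols)
        self.fixed_names = names
        self.y = table[spec.outcome].to_numpy(float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("outcome contains non-finite values")

        self.random_names = list(spec.random_terms())
        self.R = np.column_stack([_term_column(table, t) for t in self.random_names])
        self.d = self.R.shape[1]

        self.family = table[spec.family_col].to_numpy()
        self.participant = table[spec.participant_col].to_numpy()
        self.zygosity = zyg.to_numpy()
        if spec.residual_group_col is not None:
            codes, _ = pd.factorize(table[spec.residual_group_col], sort=True)
            self.resid_group = codes.astype(int)
        else:
            self.resid_group = np.zeros(self.n, dtype=int)
        self.n_resid_groups = int(self.resid_group.max()) + 1

        self.n_families = len(pd.unique(self.family))
        self.n_participants = len(pd.unique(self.participant))

    def dense_random_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Explicit Z with zygosity-suffixed individual columns (tests)."""
        blocks: list[np.ndarray] = []
        names: list[str] = []
        if self.spec.include_family_block:
            for fid in pd.unique(self.family):
                sel = (self.family == fid)[:, None]
                blocks.append(self.R * sel)
                names += [f"{t}|family:{fid}" for t in self.random_names]
        if self.spec.include_individual_blocks:
            for pid in pd.unique(self.participant):
                rows = self.participant == pid
                z = self.zygosity[rows][0]
                if z == "singleton":
                    continue
                blocks.append(self.R * (rows & (z == "MZ"))[:, None])
                names += [f"{t}_monozygotic|{pid}" for t in self.random_names]
                blocks.append(self.R * (rows & (z == "DZ"))[:, None])
                names += [f"{t}_dizygotic|{pid}" for t in self.random_names]
        Z = np.hstack(blocks) if blocks else np.empty((self.n, 0))
        return Z, names


def encode_design(
    table: pd.DataFrame, spec: ModelSpec | None = None, include_interaction: bool = False, outcome: str | None = None
) -> EncodedDesign:
    """Encode a trial/contrast table for the twin LMM."""
    if spec is None:
        if outcome is None:
            raise ValueError("give either a ModelSpec or an outcome name")
        spec = ModelSpec(outcome=outcome, include_interaction=include_interaction)
    return EncodedDesign(table, spec)


# ---------------------------------------------------------------------------
# REML machinery


def _chol_param_count(d: int) -> int:
    return d * (d + 1) // 2


class _StructureGroup:
    """Families sharing one random-block signature, with stacked products."""

    def __init__(self, blocks: tuple[str, ...], d: int):
        self.blocks = blocks          # e.g. ('family', 'MZ', 'MZ')
        self.d = d
        self.q = d * len(blocks)
        self.A_uu: list[np.ndarray] = []
        self.A_ux: list[np.ndarray] = []
        self.A_uy: list[np.ndarray] = []

    def stack(self) -> None:
        self.A_uu = np.stack(self.A_uu)   # (m, K, q, q)
        self.A_ux = np.stack(self.A_ux)   # (m, K, q, p)
        self.A_uy = np.stack(self.A_uy)   # (m, K, q)
        # fixed and outcome cross-products joined for a single solve
        self.A_uxy = np.concatenate([self.A_ux, self.A_uy[..., None]], axis=-1)


class _REMLProblem:
    """Cross-product representation of one encoded dataset."""

    def __init__(self, enc: EncodedDesign):
        self.enc = enc
        X, y, R = enc.X, enc.y, enc.R
        n, p = X.shape
        d = enc.d
        K = enc.n_resid_groups
        self.n, self.p, self.d, self.K = n, p, d, K

        # global fixed-part cross-products per residual group
        self.A_xx = np.zeros((K, p, p))
        self.A_xy = np.zeros((K, p))
        self.A_yy = np.zeros(K)
        self.n_k = np.zeros(K)
        for k in range(K):
            rows = enc.resid_group == k
            Xk, yk = X[rows], y[rows]
            self.A_xx[k] = Xk.T @ Xk
            self.A_xy[k] = Xk.T @ yk
            self.A_yy[k] = yk @ yk
            self.n_k[k] = rows.sum()

        # per-family random-block cross-products, grouped by signature
        self.groups: dict[tuple[str, ...], _StructureGroup] = {}
        fam_codes, fam_index = pd.factorize(enc.family)
        for f in range(len(fam_index)):
            rows = np.flatnonzero(fam_codes == f)
            blocks: list[str] = []
            member_rows: list[np.ndarray] = []
            if enc.spec.include_family_block:
                blocks.append("family")
                member_rows.append(rows)
            if enc.spec.include_individual_blocks:
                pids = pd.unique(enc.participant[rows])
                for pid in pids:
                    prows = rows[enc.participant[rows] == pid]
                    z = enc.zygosity[prows[0]]
                    if z == "singleton":
                        continue
                    blocks.append(z)
                    member_rows.append(prows)
            if not blocks:
                continue
            sig = tuple(blocks)
            grp = self.groups.get(sig)
            if grp is None:
                grp = self.groups[sig] = _StructureGroup(sig, d)
            q = grp.q
            U = np.zeros((len(rows), q))
            row_pos = {r: i for i, r in enumerate(rows)}
            for b, mrows in enumerate(member_rows):
                idx = [row_pos[r] for r in mrows]
                U[idx, b * d : (b + 1) * d] = R[mrows]
            A_uu = np.zeros((K, q, q))
            A_ux = np.zeros((K, q, p))
            A_uy = np.zeros((K, q))
            gk = enc.resid_group[rows]
            for k in np.unique(gk):
                sel = gk == k
                Uk = U[sel]
                A_uu[k] = Uk.T @ Uk
                A_ux[k] = Uk.T @ X[rows][sel]
                A_uy[k] = Uk.T @ y[rows][sel]
            grp.A_uu.append(A_uu)
            grp.A_ux.append(A_ux)
            grp.A_uy.append(A_uy)
        for grp in self.groups.values():
            grp.stack()

        self.block_kinds = sorted(
            {kind for grp in self.groups.values() for kind in grp.blocks},
            key=["family", "MZ", "DZ"].index,
        )
        self.n_theta = len(self.block_kinds) * _chol_param_count(d) + (K - 1)

    # -- parameter handling -------------------------------------------------

    def unpack(self, theta: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        lambdas_b, w_b = self.unpack_batch(np.asarray(theta)[None])
        return {k: v[0] for k, v in lambdas_b.items()}, w_b[0]

    def unpack_batch(
        self, thetas: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Vectorized unpack: thetas (B, n_theta) -> per-kind (B, d, d) + (B, K)."""
        thetas = np.atleast_2d(thetas)
        B = thetas.shape[0]
        d = self.d
        npar = _chol_param_count(d)
        tril = np.tril_indices(d)
        diag_pos = np.flatnonzero(tril[0] == tril[1])
        lambdas: dict[str, np.ndarray] = {}
        k = 0
        for kind in self.block_kinds:
            part = thetas[:, k : k + npar].copy()
            part[:, diag_pos] = np.exp(np.clip(part[:, diag_pos], -40.0, 40.0))
            L = np.zeros((B, d, d))
            L[:, tril[0], tril[1]] = part
            lambdas[kind] = L
            k += npar
        w = np.ones((B, self.K))
        if self.K > 1:
            w[:, 1:] = np.exp(np.clip(thetas[:, k : k + self.K - 1], -40.0, 40.0))
        return lambdas, w

    def start(self, scale: float = 0.3) -> np.ndarray:
        theta = np.zeros(self.n_theta)
        npar = _chol_param_count(self.d)
        k = 0
        for _ in self.block_kinds:
            pos = k
            for i in range(self.d):
                for j in range(i + 1):
                    if i == j:
                        theta[pos] = np.log(scale)
                    pos += 1
            k += npar
        return theta

    # -- criterion -----------------------------------------------------------

    def _assemble_batch(self, lambdas: dict[str, np.ndarray], w: np.ndarray):
        """(S_xx, S_xy, S_yy, logdet Vtilde, ok) for a batch of parameters.

        All quantities are for unit residual scale; ``ok`` flags batch
        elements whose covariance assembly is numerically sound.
        """
        B = w.shape[0]
        invw = 1.0 / w                                        # (B, K)
        S_xx = np.einsum("bk,kpq->bpq", invw, self.A_xx)
        S_xy = np.einsum("bk,kp->bp", invw, self.A_xy)
        S_yy = invw @ self.A_yy
        logdet = np.log(w) @ self.n_k
        ok = np.ones(B, dtype=bool)

        K = self.K
        for grp in self.groups.values():
            d, q = grp.d, grp.q
            T = np.zeros((B, q, q))
            for b_i, kind in enumerate(grp.blocks):
                sl = slice(b_i * d, (b_i + 1) * d)
                T[:, sl, sl] = lambdas[kind]
            Tt = T.transpose(0, 2, 1)[:, None]            # (B, 1, q, q)
            if K == 1:
                iw = invw[:, 0][:, None, None, None]
                Au = grp.A_uu[None, :, 0] * iw            # (B, m, q, q)
                Axy = grp.A_uxy[None, :, 0] * iw          # (B, m, q, p+1)
            else:
                Au = np.einsum("bk,mkij->bmij", invw, grp.A_uu, optimize=True)
                Axy = np.einsum("bk,mkip->bmip", invw, grp.A_uxy, optimize=True)
            M = Tt @ Au @ T[:, None] + np.eye(q)
            bad = ~np.all(np.isfinite(M.reshape(B, -1)), axis=1)
            if bad.any():
                ok &= ~bad
                M[bad] = np.eye(q)
            try:
                L = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                # isolate the offending batch elements
                for b in range(B):
                    try:
                        np.linalg.cholesky(M[b])
                    except np.linalg.LinAlgError:
                        ok[b] = False
                        M[b] = np.broadcast_to(np.eye(q), M[b].shape).copy()
                L = np.linalg.cholesky(M)
            logdet = logdet + 2.0 * np.log(
                np.einsum("bmii->bmi", L)
            ).sum(axis=(1, 2))
            C = Tt @ Axy                                  # (B, m, q, p+1)
            MinvC = np.linalg.solve(M, C)
            corr = (C.transpose(0, 1, 3, 2) @ MinvC).sum(axis=1)  # (B, p+1, p+1)
            S_xx -= corr[:, : self.p, : self.p]
            S_xy -= corr[:, : self.p, self.p]
            S_yy -= corr[:, self.p, self.p]
        return S_xx, S_xy, S_yy, logdet, ok

    def neg2_profiled_batch(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        lambdas, w = self.unpack_batch(thetas)
        S_xx, S_xy, S_yy, logdet, ok = self._assemble_batch(lambdas, w)
        n, p = self.n, self.p
        sign, logdet_sxx = np.linalg.slogdet(np.where(ok[:, None, None], S_xx, np.eye(p)))
        ok &= sign > 0
        beta = np.linalg.solve(np.where(ok[:, None, None], S_xx, np.eye(p)), S_xy[..., None])[..., 0]
        qres = S_yy - np.einsum("bp,bp->b", S_xy, beta)
        # a (near-)perfect fit leaves qres ~ 0; clamp to keep the criterion
        # finite so the GLS solution is still recoverable
        floor = 1e-12 * (np.abs(S_yy) + 1.0)
        ok &= qres > -floor
        qres = np.maximum(qres, floor)
        sigma2 = np.where(ok, qres, 1.0) / (n - p)
        out = (
            (n - p) * (np.log(sigma2) + 1.0 + np.log(2.0 * np.pi))
            + logdet
            + logdet_sxx
        )
        out[~ok] = np.inf
        return out

    def neg2_profiled(self, theta: np.ndarray) -> float:
        return float(self.neg2_profiled_batch(np.asarray(theta)[None])[0])

    def neg2_full_batch(self, thetas_full: np.ndarray) -> np.ndarray:
        """Unprofiled criterion; last column of thetas_full is log sigma^2."""
        thetas_full = np.atleast_2d(thetas_full)
        thetas, logs2 = thetas_full[:, :-1], thetas_full[:, -1]
        sigma2 = np.exp(logs2)
        lambdas, w = self.unpack_batch(thetas)
        S_xx, S_xy, S_yy, logdet, ok = self._assemble_batch(lambdas, w)
        n, p = self.n, self.p
        sign, logdet_sxx = np.linalg.slogdet(np.where(ok[:, None, None], S_xx, np.eye(p)))
        ok &= sign > 0
        beta = np.linalg.solve(np.where(ok[:, None, None], S_xx, np.eye(p)), S_xy[..., None])[..., 0]
        qres = S_yy - np.einsum("bp,bp->b", S_xy, beta)
        out = (
            (n - p) * (np.log(sigma2) + np.log(2.0 * np.pi))
            + logdet
            + logdet_sxx
            + qres / sigma2
        )
        out[~ok] = np.inf
        return out

    def neg2_full(self, theta_full: np.ndarray) -> float:
        return float(self.neg2_full_batch(np.asarray(theta_full)[None])[0])

    def gls(self, theta: np.ndarray):
        """beta-hat, cov(beta-hat), sigma2-hat at given variance parameters."""
        lambdas, w = self.unpack_batch(np.asarray(theta)[None])
        S_xx, S_xy, S_yy, _, ok = self._assemble_batch(lambdas, w)
        if not ok[0]:
            raise np.linalg.LinAlgError("covariance assembly failed")
        S_xx, S_xy, S_yy = S_xx[0], S_xy[0], float(S_yy[0])
        beta = np.linalg.solve(S_xx, S_xy)
        qres = S_yy - float(S_xy @ beta)
        qres = max(qres, 1e-12 * (abs(S_yy) + 1.0))
        sigma2 = qres / (self.n - self.p)
        cov_beta = sigma2 * np.linalg.inv(S_xx)
        return beta, cov_beta, sigma2

    def contrast_variance_batch(self, thetas_full: np.ndarray, c: np.ndarray) -> np.ndarray:
        """f(theta) = c' (X'V^-1 X)^-1 c, the Wald variance of c'beta."""
        thetas_full = np.atleast_2d(thetas_full)
        thetas, logs2 = thetas_full[:, :-1], thetas_full[:, -1]
        lambdas, w = self.unpack_batch(thetas)
        S_xx, _, _, _, ok = self._assemble_batch(lambdas, w)
        p = self.p
        cc = np.broadcast_to(c, (thetas_full.shape[0], p))
        sol = np.linalg.solve(np.where(ok[:, None, None], S_xx, np.eye(p)), cc[..., None])[..., 0]
        out = np.exp(logs2) * np.einsum("bp,bp->b", cc, sol)
        out[~ok] = np.nan
        return out

    def contrast_variance(self, theta_full: np.ndarray, c: np.ndarray) -> float:
        return float(self.contrast_variance_batch(np.asarray(theta_full)[None], c)[0])


@dataclass
class FitResult:
    spec: ModelSpec
    fixed_names: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    residual_weights: np.ndarray
    variance_components: dict[str, np.ndarray]
    reml_loglik: float
    theta: np.ndarray
    converged: bool
    boundary: bool
    n_restarts_used: int
    n_obs: int
    n_participants: int
    n_families: int
    random_names: list[str] = field(default_factory=list)
    _problem: _REMLProblem | None = field(default=None, repr=False)

    @property
    def theta_full(self) -> np.ndarray:
        return np.append(self.theta, np.log(self.sigma2))

    def coef(self, term: str) -> float:
        return float(self.beta[self.fixed_names.index(term)])


def fit_reml(
    encoded: EncodedDesign,
    max_restarts: int = 3,
    start_scale: float = 0.3,
    seed: int = 0,
    gtol: float = 1e-6,
) -> FitResult:
    """Maximize the profiled REML criterion and return the fit.

    Quasi-Newton (L-BFGS-B) with up to ``max_restarts`` perturbed restarts;
    non-convergence of every attempt raises.  Fits with a random-effect SD
    estimated at (numerically) zero are flagged ``boundary``, not errored.
    """
    if encoded.n_families < 2:
        raise ValueError("need at least 2 families")
    prob = _REMLProblem(encoded)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))

    if prob.n_theta == 0:
        # no free variance parameters: the GLS solution is closed-form
        theta = np.empty(0)
        beta, cov_beta, sigma2 = prob.gls(theta)
        return FitResult(
            spec=encoded.spec,
            fixed_names=list(encoded.fixed_names),
            beta=beta,
            cov_beta=cov_beta,
            sigma2=sigma2,
            residual_weights=np.ones(1),
            variance_components={"residual_var": np.array([sigma2])},
            reml_loglik=-0.5 * prob.neg2_profiled(theta),
            theta=theta,
            converged=True,
            boundary=False,
            n_restarts_used=0,
            n_obs=encoded.n,
            n_participants=encoded.n_participants,
            n_families=encoded.n_families,
            random_names=list(encoded.random_names),
            _problem=prob,
        )

    m = prob.n_theta
    h = 1e-5
    eye_h = h * np.eye(m)

    def fun_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        # one batched evaluation supplies the value and the central-
        # difference gradient (2m+1 criterion evaluations per call)
        pts = np.vstack([theta[None], theta + eye_h, theta - eye_h])
        vals = prob.neg2_profiled_batch(pts)
        with np.errstate(invalid="ignore"):
            grad = (vals[1 : m + 1] - vals[m + 1 :]) / (2.0 * h)
        grad[~np.isfinite(grad)] = 0.0
        return float(vals[0]), grad

    best = None
    n_used = 0
    for attempt in range(max_restarts):
        n_used = attempt + 1
        x0 = prob.start(start_scale)
        if attempt > 0:
            x0 = x0 + 0.5 * rng.standard_normal(x0.size)
        res = optimize.minimize(
            fun_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best.success and np.isfinite(best.fun):
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"REML did not converge after {max_restarts} restarts: "
            f"{getattr(best, 'message', 'no finite criterion value')}"
        )

    theta = best.x
    beta, cov_beta, sigma2 = prob.gls(theta)
    lambdas, w = prob.unpack(theta)

    vcs: dict[str, np.ndarray] = {}
    boundary = False
    for kind, L in lambdas.items():
        cov = sigma2 * (L @ L.T)
        key = {"family": "family_cov", "MZ": "mz_cov", "DZ": "dz_cov"}[kind]
        vcs[key] = cov
        if np.any(np.diag(L) < 1e-5):
            boundary = True
    vcs["residual_var"] = sigma2 * w

    return FitResult(
        spec=encoded.spec,
        fixed_names=list(encoded.fixed_names),
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        residual_weights=w,
        variance_components=vcs,
        reml_loglik=-0.5 * float(best.fun),
        theta=theta,
        converged=bool(best.success),
        boundary=boundary,
        n_restarts_used=n_used,
        n_obs=encoded.n,
        n_participants=encoded.n_participants,
        n_families=encoded.n_families,
        random_names=list(encoded.random_names),
        _problem=prob,
    )


def satterthwaite_df(fit: FitResult, contrast: np.ndarray, step: float = 1e-5) -> float:
    """Satterthwaite degrees of freedom for the Wald t of ``contrast``'beta.

    df = 2 f^2 / Var(f) with f = c'(X'V^-1 X)^-1 c; Var(f) by the delta
    method: gradient of f in the variance parameters (central differences,
    unconstrained scale) against the inverse observed REML information.
    Singular information yields df = inf with a warning.
    """
    prob = fit._problem
    if prob is None:
        raise ValueError("fit carries no problem handle")
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.fixed_names),):
        raise ValueError("contrast length must match the fixed effects")
    th = fit.theta_full
    m = th.size

    pts = np.vstack([th[None], th + step * np.eye(m), th - step * np.eye(m)])
    fv = prob.contrast_variance_batch(pts, c)
    f0 = float(fv[0])
    grad = (fv[1 : m + 1] - fv[m + 1 :]) / (2.0 * step)

    # second differences use a larger step than the gradient: the criterion
    # is O(n), so a 1e-5 step would leave O(1e-6) roundoff noise in the
    # Hessian; 2e-4 balances roundoff against truncation
    hs = 2e-4
    iu, ju = np.triu_indices(m)
    E = np.eye(m) * hs
    pp = np.vstack(
        [th + E[i] + E[j] for i, j in zip(iu, ju)]
        + [th + E[i] - E[j] for i, j in zip(iu, ju)]
        + [th - E[i] + E[j] for i, j in zip(iu, ju)]
        + [th - E[i] - E[j] for i, j in zip(iu, ju)]
    )
    vals = prob.neg2_full_batch(pp).reshape(4, -1)
    # Hessian of the *negative log-likelihood* = neg2/2
    hvals = (vals[0] - vals[1] - vals[2] + vals[3]) / (8.0 * hs * hs)
    H = np.zeros((m, m))
    H[iu, ju] = hvals
    H[ju, iu] = hvals

    try:
        hinv_g = np.linalg.solve(H, grad)
    except np.linalg.LinAlgError:
        warnings.warn("singular REML information; df reported as inf", stacklevel=2)
        return np.inf
    var_f = float(grad @ hinv_g)
    if var_f <= 0 or not np.isfinite(var_f):
        warnings.warn("non-positive delta-method variance; df reported as inf", stacklevel=2)
        return np.inf
    return 2.0 * f0 * f0 / var_f


def test_fixed_effect(fit: FitResult, term: str) -> FixedEffectEstimate:
    """Wald t test with Satterthwaite df, two-sided p and 95% CI."""
    if term not in fit.fixed_names:
        raise KeyError(f"term {term!r} not in model ({fit.fixed_names})")
    i = fit.fixed_names.index(term)
    c = np.zeros(len(fit.fixed_names))
    c[i] = 1.0
    beta = float(fit.beta[i])
    se = float(np.sqrt(fit.cov_beta[i, i]))
    df = satterthwaite_df(fit, c)
    tval = beta / se if se > 0 else np.inf * np.sign(beta)
    if np.isfinite(df):
        p = 2.0 * stats.t.sf(abs(tval), df)
        tcrit = stats.t.ppf(0.975, df)
    else:
        p = 2.0 * stats.norm.sf(abs(tval))
        tcrit = stats.norm.ppf(0.975)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return FixedEffectEstimate(
        term=term, beta=beta, se=se, t=tval, df=df, p=p,
        ci95=(beta - tcrit * se, beta + tcrit * se),
    )


@dataclass
class ProtocolReport:
    """Interaction-then-mains protocol output."""

    full: FitResult
    reduced: FitResult | None
    interaction: FixedEffectEstimate
    estimates: dict[str, FixedEffectEstimate]
    source: dict[str, str]  # term -> "full" | "reduced"

    @property
    def reported(self) -> FitResult:
        return self.reduced if self.reduced is not None else self.full


def interaction_protocol(
    table: pd.DataFrame,
    outcome: str,
    alpha: float = 0.05,
    seed: int = 0,
    **spec_kwargs,
) -> ProtocolReport:
    """Fit with the interaction; refit without it if non-significant.

    Main effects are reported from the reduced model when the interaction p
    is >= alpha (for interpretability), from the full model otherwise; both
    fits are retained and each reported row is flagged with its source.
    """
    spec_full = ModelSpec(outcome=outcome, include_interaction=True, **spec_kwargs)
    full = fit_reml(encode_design(table, spec_full), seed=seed)
    inter = test_fixed_effect(full, _INTERACTION)

    estimates: dict[str, FixedEffectEstimate] = {}
    source: dict[str, str] = {}
    if inter.p >= alpha:
        reduced = fit_reml(
            encode_design(table, replace(spec_full, include_interaction=False)),
            seed=seed,
        )
        for term in reduced.fixed_names:
            estimates[term] = test_fixed_effect(reduced, term)
            source[term] = "reduced"
        estimates[_INTERACTION] = inter
        source[_INTERACTION] = "full"
    else:
        reduced = None
        for term in full.fixed_names:
            estimates[term] = test_fixed_effect(full, term)
            source[term] = "full"
    return ProtocolReport(
        full=full, reduced=reduced, interaction=inter, estimates=estimates, source=source
    )


def cohens_d(values: np.ndarray) -> EffectSizeD:
    """d = mean / sample SD across participants (no familial structure)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; Cohen's d undefined")
    return EffectSizeD(d=float(values.mean() / sd), n=int(values.size))


def one_sample_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Exact two-sided one-sample t-test power at effect size ``d``."""
    df = n - 1
    ncp = d * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
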