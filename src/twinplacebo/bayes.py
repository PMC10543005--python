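"""Nested-model Bayes factors for fixed effects in the twin model (JZS style).

The alternative ("full") model contains the fixed main effects (optionally
plus the level x condition interaction) and random *intercepts* for family
and for participant split by zygosity — no random slopes.  The null model is
the full model minus the fixed effect of interest.  The Bayes factor is
bf10 = p(y | full) / p(y | null).

Priors follow the Jeffreys–Zellner–Siow construction on the standardized
outcome:

* the intercept gets a flat prior and sigma^2 the Jeffreys prior 1/sigma^2
  (common to both models, so they cancel);
* each non-intercept fixed effect beta_c gets beta_c | g_c ~ N(0, g_c sigma^2)
  with g_c ~ r_c^2 / chi^2_1, i.e. a Cauchy(0, r_c sigma) prior: the effect
  of interest uses ``rscale`` (default 1, a wide prior), other fixed
  covariates use the nuisance scale 1;
* each random-intercept group (family, MZ participants, DZ participants)
  gets a common variance ratio g with the same scaled-inverse-chi-squared
  prior at the nuisance scale.

Conditional on g the model is Gaussian and the marginal over (intercept,
sigma^2) is closed-form; the remaining integral over g is Monte Carlo with
draws from the prior, reported with its relative standard error (the
"proportional error") and an effective-sample-size guard.  The one-sample
reduction of this construction (single g-prior column, no random effects)
is exactly the classic JZS t-test Bayes factor, which anchors the module's
correctness in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .twinlmm import EncodedDesign, ModelSpec, _REMLProblem

__all__ = [
    "BFResult",
    "GMixtureModel",
    "marginal_likelihood_mc",
    "bf_fixed_effect",
    "bf_robustness",
    "interpret_bf",
    "RSCALE_GRID",
]

#: default prior-width robustness grid (medium, wide, ultrawide)
RSCALE_GRID = (np.sqrt(2.0) / 2.0, 1.0, np.sqrt(2.0))

_NUISANCE_SCALE = 1.0
_INTERACTION = "stimulus_level:placebo_condition"


@dataclass(frozen=True)
class BFResult:
    bf10: float
    proportional_error: float
    rscale: float
    n_mc: int
    seed: int
    effect: str | None = None
    include_interaction: bool = False
    log_ml_full: float = 0.0
    log_ml_null: float = 0.0


class GMixtureModel:
    """One model side: cross-products plus the g-prior map over columns.

    ``X`` columns are partitioned into flat-prior columns (``flat_idx``,
    normally just the intercept) and g-prior columns (``g_scales``, column
    index -> Cauchy scale).  Random-intercept structure, if any, enters via
    per-family cross-products grouped by zygosity signature.
    """

    def __init__(
        self,
        n: int,
        names: list[str],
        A_xx: np.ndarray,
        A_xy: np.ndarray,
        A_yy: float,
        groups: list[tuple[tuple[str, ...], np.ndarray, np.ndarray, np.ndarray]],
        flat_idx: list[int],
        g_scales: dict[int, float],
    ):
        self.n = n
        self.names = list(names)
        self.p = len(names)
        self.A_xx, self.A_xy, self.A_yy = A_xx, A_xy, A_yy
        self.groups = groups  # (blocks, A_uu (m,q,q), A_ux (m,q,p), A_uy (m,q))
        self.block_kinds = sorted({k for blocks, *_ in groups for k in blocks})
        self.flat_idx = list(flat_idx)
        self.g_idx = sorted(g_scales)
        self.g_scales = [g_scales[i] for i in self.g_idx]

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        outcome: str,
        fixed: tuple[str, ...],
        include_interaction: bool,
        effect: str | None,
        rscale: float,
        standardize: bool = True,
    ) -> "GMixtureModel":
        spec = ModelSpec(
            outcome=outcome,
            fixed=fixed,
            include_interaction=include_interaction,
            random=("intercept",),
        )
        enc = EncodedDesign(table, spec)
        if standardize:
            enc.y = (enc.y - enc.y.mean()) / enc.y.std(ddof=1)
        prob = _REMLProblem(enc)
        groups = [
            (grp.blocks, grp.A_uu[:, 0], grp.A_ux[:, 0], grp.A_uy[:, 0])
            for grp in prob.groups.values()
        ]
        flat_idx = [enc.fixed_names.index("intercept")]
        g_scales = {
            i: (rscale if name == effect else _NUISANCE_SCALE)
            for i, name in enumerate(enc.fixed_names)
            if name != "intercept"
        }
        return cls(
            enc.n, enc.fixed_names, prob.A_xx[0], prob.A_xy[0], float(prob.A_yy[0]),
            groups, flat_idx, g_scales,
        )

    @classmethod
    def from_arrays(
        cls,
        y: np.ndarray,
        X: np.ndarray,
        flat_idx: list[int],
        g_scales: dict[int, float],
        names: list[str] | None = None,
    ) -> "GMixtureModel":
        """No-random-effects model from raw arrays (e.g. one-sample design)."""
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        names = names or [f"x{i}" for i in range(X.shape[1])]
        return cls(
            len(y), names, X.T @ X, X.T @ y, float(y @ y), [], flat_idx, g_scales
        )

    def without_column(self, name: str) -> "GMixtureModel":
        """The nested model with one g-prior column removed."""
        i = self.names.index(name)
        if i in self.flat_idx:
            raise ValueError("cannot drop a flat-prior column")
        keep = [j for j in range(self.p) if j != i]
        remap = {j: k for k, j in enumerate(keep)}
        groups = [
            (blocks, A_uu, A_ux[:, :, keep], A_uy)
            for blocks, A_uu, A_ux, A_uy in self.groups
        ]
        return GMixtureModel(
            self.n,
            [self.names[j] for j in keep],
            self.A_xx[np.ix_(keep, keep)],
            self.A_xy[keep],
            self.A_yy,
            groups,
            [remap[j] for j in self.flat_idx],
            {remap[j]: s for j, s in zip(self.g_idx, self.g_scales) if j != i},
        )

    # -- conditional marginal ------------------------------------------------

    @property
    def g_dim(self) -> int:
        """Dimension of the g vector (random groups + g-prior columns)."""
        return len(self.block_kinds) + len(self.g_idx)

    def prior_scales(self) -> np.ndarray:
        """Cauchy/half-scale r per g component (groups first, then columns)."""
        return np.array(
            [_NUISANCE_SCALE] * len(self.block_kinds) + list(self.g_scales)
        )

    def log_conditional(self, phi: np.ndarray) -> np.ndarray:
        """log p(y | g = exp(phi)) for a (D, g_dim) array of log-g draws."""
        phi = np.atleast_2d(phi)
        D = phi.shape[0]
        nk = len(self.block_kinds)
        g_rand = {kind: np.exp(phi[:, i]) for i, kind in enumerate(self.block_kinds)}
        gam = np.exp(phi[:, nk:]) if self.g_idx else np.empty((D, 0))

        S_xx = np.broadcast_to(self.A_xx, (D, self.p, self.p)).copy()
        S_xy = np.broadcast_to(self.A_xy, (D, self.p)).copy()
        S_yy = np.full(D, self.A_yy)
        logdetV = np.zeros(D)

        p = self.p
        for blocks, A_uu, A_ux, A_uy in self.groups:
            q = A_uu.shape[-1]
            A_uxy = np.concatenate([A_ux, A_uy[..., None]], axis=-1)
            t = np.empty((D, q))
            for b, kind in enumerate(blocks):
                t[:, b] = np.sqrt(g_rand[kind])
            M = t[:, None, :, None] * A_uu[None] * t[:, None, None, :] + np.eye(q)
            L = np.linalg.cholesky(M)              # (D, m, q, q)
            logdetV += 2.0 * np.log(np.einsum("dmii->dmi", L)).sum(axis=(1, 2))
            C = t[:, None, :, None] * A_uxy[None]  # (D, m, q, p+1)
            MinvC = np.linalg.solve(M, C)
            corr = (C.transpose(0, 1, 3, 2) @ MinvC).sum(axis=1)
            S_xx -= corr[:, :p, :p]
            S_xy -= corr[:, :p, p]
            S_yy -= corr[:, p, p]

        kc = len(self.g_idx)
        if kc:
            C = self.g_idx
            S_cc = S_xx[:, C][:, :, C]
            S_xc = S_xx[:, :, C]
            S_cy = S_xy[:, C]
            core = S_cc.copy()
            idx = np.arange(kc)
            core[:, idx, idx] += 1.0 / gam
            sign, logdet_core = np.linalg.slogdet(core)
            core_inv = np.linalg.inv(core)
            logdetV += np.log(gam).sum(axis=1) + logdet_core
            W = S_xc @ core_inv                       # (D, p, kc)
            S_xx = S_xx - W @ S_xc.transpose(0, 2, 1)
            S_xy = S_xy - (W @ S_cy[..., None])[..., 0]
            S_yy = S_yy - (S_cy[:, None, :] @ core_inv @ S_cy[..., None])[:, 0, 0]

        F = self.flat_idx
        p0 = len(F)
        if p0:
            S_00 = S_xx[:, F][:, :, F]
            S_0y = S_xy[:, F]
            _, logdet_00 = np.linalg.slogdet(S_00)
            alpha = np.linalg.solve(S_00, S_0y[..., None])[..., 0]
            qres = S_yy - np.einsum("dp,dp->d", S_0y, alpha)
        else:
            logdet_00 = np.zeros(D)
            qres = S_yy

        m0 = self.n - p0
        qres = np.maximum(qres, np.finfo(float).tiny)
        return (
            gammaln(m0 / 2.0)
            - (m0 / 2.0) * np.log(np.pi * qres)
            - 0.5 * logdetV
            - 0.5 * logdet_00
        )

    def log_prior(self, phi: np.ndarray) -> np.ndarray:
        """Log prior density of phi = log g, Jacobian included.

        Each g has the scaled-inverse-chi-squared prior with 1 df and scale
        r (equivalently g = r^2/chi^2_1), i.e. a Cauchy(0, r sigma) prior on
        the corresponding standardized coefficient.
        """
        phi = np.atleast_2d(phi)
        r = self.prior_scales()
        b = r * r / 2.0
        return np.sum(
            0.5 * np.log(b) - gammaln(0.5) - 0.5 * phi - b * np.exp(-phi), axis=1
        )

    def log_joint(self, phi: np.ndarray) -> np.ndarray:
        return self.log_conditional(phi) + self.log_prior(phi)


def _laplace_proposal(model: GMixtureModel) -> tuple[np.ndarray, np.ndarray]:
    """Mode and Cholesky covariance factor of the log-g posterior kernel."""
    from scipy import optimize

    dim = model.g_dim
    neg = lambda phi: -float(model.log_joint(phi[None])[0])
    best = None
    for start in (np.log(model.prior_scales() ** 2), np.zeros(dim)):
        res = optimize.minimize(neg, start, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    mode = best.x

    h = 1e-3
    H = np.zeros((dim, dim))
    for i in range(dim):
        ei = np.zeros(dim); ei[i] = h
        for j in range(i + 1):
            ej = np.zeros(dim); ej[j] = h
            H[i, j] = H[j, i] = (
                neg(mode + ei + ej) - neg(mode + ei - ej)
                - neg(mode - ei + ej) + neg(mode - ei - ej)
            ) / (4 * h * h)
    # robust covariance: clip curvature eigenvalues (a boundary-flat or
    # slightly indefinite Hessian must not collapse the proposal), then
    # inflate mildly so the proposal over- rather than under-covers
    evals, evecs = np.linalg.eigh((H + H.T) / 2.0)
    evals = np.clip(evals, 1e-2, 1e6)
    cov = (evecs / evals) @ evecs.T
    L = 1.2 * np.linalg.cholesky((cov + cov.T) / 2.0 + 1e-12 * np.eye(dim))
    return mode, L


def marginal_likelihood_mc(
    model: GMixtureModel, n_mc: int = 2000, seed: int = 0, df_proposal: float = 7.0
) -> tuple[float, float]:
    """log marginal likelihood and its MC standard error (log scale).

    The g integral is importance-weighted Monte Carlo: the proposal is a
    multivariate t (default 7 df) centred on the mode of the log-g posterior
    kernel with Laplace covariance; the weights are posterior kernel over
    proposal density.  SE(log ML) = sd(w)/(sqrt(n_mc) mean(w)) by the delta
    method on the weight variance.  Raises when the weight effective sample
    size falls below 5% of ``n_mc``.  A model with no g components at all
    has a closed-form marginal likelihood, returned with zero error.
    """
    dim = model.g_dim
    if dim == 0:
        return float(model.log_conditional(np.empty((1, 0)))[0]), 0.0

    mode, L = _laplace_proposal(model)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(111,)))

    def draw_and_weigh(center: np.ndarray, L_prop: np.ndarray):
        z = rng.standard_normal((n_mc, dim))
        u = rng.chisquare(df_proposal, n_mc)
        phi = center + (z @ L_prop.T) * np.sqrt(df_proposal / u)[:, None]
        delta = phi - center
        sol = np.linalg.solve(L_prop, delta.T).T
        maha = np.sum(sol * sol, axis=1)
        logdet_L = float(np.log(np.diag(L_prop)).sum())
        log_q = (
            gammaln((df_proposal + dim) / 2.0)
            - gammaln(df_proposal / 2.0)
            - 0.5 * dim * np.log(df_proposal * np.pi)
            - logdet_L
            - 0.5 * (df_proposal + dim) * np.log1p(maha / df_proposal)
        )
        return phi, model.log_joint(phi) - log_q

    # up to three adaptation rounds: if the weights degenerate, re-centre on
    # the weighted draws and widen (standard adaptive importance sampling)
    for round_ in range(3):
        phi, logw = draw_and_weigh(mode, L)
        ref = logw.max()
        w = np.exp(logw - ref)
        ess = w.sum() ** 2 / (w**2).sum()
        if ess >= 0.05 * n_mc:
            break
        wn = w / w.sum()
        mode = wn @ phi
        centred = phi - mode
        cov = (centred * wn[:, None]).T @ centred
        cov = cov + np.diag(np.full(dim, 1e-4)) + 0.25 * np.diag(np.diag(cov))
        L = 1.3 * np.linalg.cholesky((cov + cov.T) / 2.0)
    else:
        raise RuntimeError(
            f"importance-weight ESS {ess:.1f} < 5% of n_mc={n_mc} after "
            "adaptation; increase n_mc"
        )

    mean_w = w.mean()
    log_ml = ref + np.log(mean_w)
    se = w.std(ddof=1) / (np.sqrt(n_mc) * mean_w)
    return float(log_ml), float(se)


def bf_fixed_effect(
    table: pd.DataFrame,
    outcome: str,
    effect: str | None,
    rscale: float = 1.0,
    n_mc: int = 2000,
    seed: int = 0,
    include_interaction: bool = False,
    fixed: tuple[str, ...] = ("stimulus_level", "placebo_condition"),
) -> BFResult:
    """Bayes factor (alternative over null) for one fixed effect.

    The outcome is standardized first.  ``effect=None`` is the degenerate
    request where full and null coincide: bf10 = 1 exactly.  When the
    interaction is included and a main effect is tested, the interaction
    term stays in both models (the null is the full model minus only the
    effect of interest).
    """
    if effect is None:
        return BFResult(
            bf10=1.0, proportional_error=0.0, rscale=rscale, n_mc=0, seed=seed,
            effect=None, include_interaction=include_interaction,
        )
    if effect == _INTERACTION:
        include_interaction = True
    elif effect not in fixed:
        raise KeyError(f"effect {effect!r} is not among the fixed terms {fixed}")

    full = GMixtureModel.from_table(
        table, outcome, fixed, include_interaction, effect, rscale
    )
    null = full.without_column(effect)

    log_full, se_full = marginal_likelihood_mc(full, n_mc=n_mc, seed=seed)
    log_null, se_null = marginal_likelihood_mc(null, n_mc=n_mc, seed=seed + 1)
    bf10 = float(np.exp(log_full - log_null))
    prop = float(np.sqrt(se_full**2 + se_null**2))
    return BFResult(
        bf10=bf10, proportional_error=prop, rscale=rscale, n_mc=n_mc, seed=seed,
        effect=effect, include_interaction=include_interaction,
        log_ml_full=log_full, log_ml_null=log_null,
    )


def bf_robustness(
    table: pd.DataFrame,
    outcome: str,
    effect: str,
    rscales: tuple[float, ...] = RSCALE_GRID,
    n_mc: int = 2000,
    seed: int = 0,
) -> tuple[list[BFResult], bool]:
    """BF grid over prior widths x interaction inclusion, plus a flag.

    The flag is True when every cell of the grid falls on the same side of
    the 1/3 and 3 evidence thresholds (a qualitatively robust conclusion).
    """
    results: list[BFResult] = []
    for k, rscale in enumerate(rscales):
        for j, inter in enumerate((False, True)):
            results.append(
                bf_fixed_effect(
                    table, outcome, effect, rscale=rscale, n_mc=n_mc,
                    seed=seed + 101 * k + 17 * j, include_interaction=inter,
                )
            )
    bfs = np.array([r.bf10 for r in results])
    robust = bool(
        np.all(bfs < 1 / 3) or np.all(bfs > 3) or np.all((bfs >= 1 / 3) & (bfs <= 3))
    )
    return results, robust


_BANDS = [
    (1 / 100, "extreme evidence for null"),
    (1 / 30, "very strong evidence for null"),
    (1 / 10, "strong evidence for null"),
    (1 / 3, "moderate evidence for null"),
    (1.0, "anecdotal evidence for null"),
    (3.0, "anecdotal evidence for alternative"),
    (10.0, "moderate evidence for alternative"),
    (30.0, "strong evidence for alternative"),
    (100.0, "very strong evidence for alternative"),
]


def interpret_bf(bf10: float) -> tuple[str, str]:
    """Jeffreys-style evidence label and odds string for a Bayes factor.

    Examples: 0.044 -> ("strong evidence for null", "23:1 odds in favor of
    the null"); 1.0 -> ("no evidence", "1:1").
    """
    if not (bf10 > 0):
        raise ValueError("bf10 must be positive")
    if bf10 == 1.0:
        return "no evidence", "1:1"
    label = "extreme evidence for alternative"
    for upper, name in _BANDS:
        if bf10 < upper:
            label = name
            break
    if bf10 < 1:
        odds = f"{round(1.0 / bf10)}:1 odds in favor of the null"
    else:
        odds = f"{round(bf10)}:1 odds in favor of the alternative"
    return label, odds
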