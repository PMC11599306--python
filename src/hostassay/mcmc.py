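"""From-scratch MCMC for multi-term variance-component models.

Two samplers are provided:

* :func:`fit_gaussian_lmm` — a pure Gibbs sampler for a Gaussian linear
  mixed model with an intercept and any number of scalar random
  intercept terms.  Every full conditional is conjugate: the whole
  location vector (intercept plus all group effects) is drawn jointly
  from its multivariate-normal full conditional, each variance
  component from its scaled inverse-chi-square (scalar inverse-Wishart,
  parameterised by ``(V, nu)``) full conditional, and the residual
  variance from its inverse-gamma full conditional.

* :func:`fit_binary_glmm` — the binary-response analogue with a logit
  link and a *fixed* residual variance.  Each individual carries a
  latent value ``eta`` whose likelihood is Bernoulli(inverse-logit(eta))
  and whose prior is Normal(linear predictor, fixed residual variance).
  Latents are updated by vectorised random-walk Metropolis (proposal
  scale adapted towards ~44% acceptance during burn-in only, then
  frozen), augmented by a joint translation move that shifts the
  intercept and all latents together to decouple mixing of the
  intercept from the latent field.  All remaining updates are the same
  conjugate ones as in the Gaussian sampler.

Group effects are not sum-to-zero constrained; hierarchical shrinkage
through their variance priors identifies them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "MCMCSettings",
    "PosteriorDraws",
    "fit_gaussian_lmm",
    "fit_binary_glmm",
]

#: response name -> data column
RESPONSE_COLUMNS = {
    "survival": "survived",
    "surv": "survived",
    "mass": "pupal_mass_mg",
    "devtime": "dev_time_days",
}

_FAMILIES = ("gaussian", "binary-logit")


@dataclass(frozen=True)
class ModelSpec:
    """Which response is modelled and with which random intercept terms.

    Sex can only enter the mass model: pupae can be sexed but larvae
    cannot, so sex is unobserved for the individuals that contribute to
    survival, and unknown for non-survivors generally.
    """

    response: str
    family: str
    random_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_COLUMNS:
            raise ValueError(f"unknown response {self.response!r}")
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if "sex" in self.random_terms and self.response != "mass":
            raise ValueError("sex is only observable (and fittable) for mass")
        if len(set(self.random_terms)) != len(self.random_terms):
            raise ValueError("duplicate random terms")

    @classmethod
    def survival(cls) -> "ModelSpec":
        return cls("survival", "binary-logit",
                   ("host", "population", "population:host", "culture"))

    @classmethod
    def mass(cls) -> "ModelSpec":
        return cls("mass", "gaussian",
                   ("host", "population", "population:host", "sex", "culture"))

    @classmethod
    def devtime(cls) -> "ModelSpec":
        return cls("devtime", "gaussian",
                   ("host", "population", "population:host", "culture"))

    @classmethod
    def for_response(cls, response: str) -> "ModelSpec":
        return {"survival": cls.survival, "surv": cls.survival,
                "mass": cls.mass, "devtime": cls.devtime}[response]()


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    Fixed effect: Normal(fixed_mean, fixed_variance) with a large default
    variance.  Each random-term variance: scalar inverse-Wishart with
    scale ``V`` and degrees of freedom ``nu`` (equivalently inverse-gamma
    with shape nu/2 and scale nu*V/2); ``per_term`` overrides the global
    (V, nu) pair for named terms.  Residual: same family for Gaussian
    responses; for the binary model the residual variance is *fixed* at
    ``fixed_residual`` in every draw.
    """

    fixed_mean: float = 0.0
    fixed_variance: float = 1e8
    V: float = 1.0
    nu: float = 0.002
    residual_V: float = 1.0
    residual_nu: float = 0.002
    fixed_residual: float = 1.0
    per_term: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fixed_variance <= 0:
            raise ValueError("fixed_variance must be > 0")
        for v, nu in [(self.V, self.nu), (self.residual_V, self.residual_nu)]:
            if v <= 0 or nu <= 0:
                raise ValueError("V and nu must be > 0")
        if self.fixed_residual <= 0:
            raise ValueError("fixed_residual must be > 0")

    def term_hyper(self, term: str) -> tuple[float, float]:
        if term in self.per_term:
            v, nu = self.per_term[term]
            return float(v), float(nu)
        return self.V, self.nu


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length bookkeeping: stored draws = (iterations - burnin) / thin."""

    iterations: int
    burnin: int
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burnin + self.thin - 1) // self.thin

    @classmethod
    def published_protocol(cls, seed: int = 0) -> "MCMCSettings":
        """The full-length protocol used for the real data analysis."""
        return cls(iterations=1_500_000, burnin=500_000, thin=100, seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0) -> "MCMCSettings":
        """Desk-scale settings for simulation studies and tests."""
        return cls(iterations=13_000, burnin=3_000, thin=10, seed=seed)


@dataclass
class PosteriorDraws:
    """Stored MCMC output for one fitted model.

    ``params`` holds one row per stored draw.  Columns: ``intercept``,
    ``var_<term>`` for each random term, ``var_residual`` (a constant
    column when the residual is fixed), and ``u_<term>[<level>]`` for
    every group effect.
    """

    params: pd.DataFrame
    spec: ModelSpec
    priors: PriorSpec
    settings: MCMCSettings
    levels: dict[str, tuple[str, ...]]

    @property
    def n_draws(self) -> int:
        return len(self.params)

    def intercept(self) -> np.ndarray:
        return self.params["intercept"].to_numpy()

    def variance_columns(self) -> list[str]:
        return [c for c in self.params.columns if c.startswith("var_")]

    def variance_components(self) -> pd.DataFrame:
        return self.params[self.variance_columns()]

    def group_effect_matrix(self, term: str) -> np.ndarray:
        """(n_draws, n_levels) matrix of effects for one term."""
        if term not in self.levels:
            raise KeyError(f"term {term!r} not in draws "
                           f"(have {sorted(self.levels)})")
        cols = [f"u_{term}[{lv}]" for lv in self.levels[term]]
        return self.params[cols].to_numpy()

    # -- serialisation -------------------------------------------------

    def save(self, prefix) -> None:
        """Write ``<prefix>_draws.csv`` plus a JSON sidecar of metadata."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.params.to_csv(f"{prefix}_draws.csv", index=False)
        meta = {
            "spec": asdict(self.spec),
            "priors": asdict(self.priors),
            "settings": asdict(self.settings),
            "levels": {k: list(v) for k, v in self.levels.items()},
        }
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "PosteriorDraws":
        params = pd.read_csv(f"{prefix}_draws.csv")
        with open(f"{prefix}_meta.json") as fh:
            meta = json.load(fh)
        spec = ModelSpec(
            response=meta["spec"]["response"],
            family=meta["spec"]["family"],
            random_terms=tuple(meta["spec"]["random_terms"]),
        )
        pr = dict(meta["priors"])
        priors = PriorSpec(**pr)
        settings = MCMCSettings(**meta["settings"])
        levels = {k: tuple(v) for k, v in meta["levels"].items()}
        return cls(params=params, spec=spec, priors=priors,
                   settings=settings, levels=levels)


# ---------------------------------------------------------------------------
# model frame construction
# ---------------------------------------------------------------------------


def _term_values(df: pd.DataFrame, term: str) -> pd.Series:
    if ":" in term:
        a, b = term.split(":", 1)
        for c in (a, b):
            if c not in df.columns:
                raise KeyError(f"interaction {term!r} needs column {c!r}")
        return df[a].astype(str) + ":" + df[b].astype(str)
    if term not in df.columns:
        raise KeyError(f"random term {term!r} names no data column")
    return df[term]


def _model_frame(table: pd.DataFrame, spec: ModelSpec):
    """Drop rows with missing response or term columns; build codes."""
    ycol = RESPONSE_COLUMNS[spec.response]
    if ycol not in table.columns:
        raise KeyError(f"response column {ycol!r} missing from table")
    keep = table[ycol].notna()
    for term in spec.random_terms:
        base = term.split(":") if ":" in term else [term]
        for c in base:
            keep &= table[c].notna()
    df = table.loc[keep]
    y = df[ycol].to_numpy(float)
    codes, levels, counts = {}, {}, {}
    for term in spec.random_terms:
        cat = pd.Categorical(_term_values(df, term))
        if len(cat.categories) < 2:
            raise ValueError(
                f"random term {term!r} has a single level; it cannot "
                "contribute a variance component"
            )
        codes[term] = np.asarray(cat.codes)
        levels[term] = tuple(str(c) for c in cat.categories)
        counts[term] = np.bincount(codes[term], minlength=len(cat.categories))
    return y, codes, levels, counts


def _draw_invgamma(rng, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _run_sampler(table, spec, priors, settings, fixed_variances, binary):
    from scipy.linalg import cho_factor, cho_solve, solve_triangular

    fixed_variances = dict(fixed_variances or {})
    y, codes, levels, counts = _model_frame(table, spec)
    n = len(y)
    if n == 0:
        raise ValueError("no analysable rows after dropping missing data")
    terms = list(spec.random_terms)
    K = len(terms)
    rng = np.random.default_rng(settings.seed)

    if binary:
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError(f"binary response must lie in {{0,1}}, saw {uniq}")
        if len(uniq) < 2:
            raise ValueError(
                "response is constant (all 0 or all 1); the intercept is "
                "unidentifiable without an informative prior"
            )
        ve = float(priors.fixed_residual)
        pbar = y.mean()
        beta0 = float(np.log(pbar / (1.0 - pbar)))
        eta = np.where(y > 0, beta0 + 1.0, beta0 - 1.0)
        step = 1.0
        tstep = 0.2
        lstep = [0.5] * K  # per-term level-shift proposal scales
    else:
        if np.var(y) == 0.0:
            raise ValueError("response column has zero variance")
        beta0 = float(y.mean())
        ve = fixed_variances.get("residual", float(np.var(y)))
        eta = None

    # location design bookkeeping: column 0 is the intercept, then one
    # block per random term; the whole location vector is sampled
    # jointly from its multivariate-normal full conditional
    qs = [len(levels[t]) for t in terms]
    offs = np.concatenate([[1], 1 + np.cumsum(qs)])[:K]
    q_tot = 1 + int(sum(qs))
    col_idx = [np.zeros(n, dtype=int)] + [
        offs[k] + codes[t] for k, t in enumerate(terms)
    ]
    CtC = np.zeros((q_tot, q_tot))
    for a in range(K + 1):
        for b in range(K + 1):
            np.add.at(CtC, (col_idx[a], col_idx[b]), 1.0)
    diag_idx = np.diag_indices(q_tot)

    u = [np.zeros(qk) for qk in qs]
    total = np.zeros(n)  # sum of all group-effect contributions
    sig2 = np.array([fixed_variances.get(t, 1.0) for t in terms])

    S = settings.n_stored
    st_intercept = np.empty(S)
    st_sig2 = np.empty((S, K))
    st_ve = np.empty(S)
    st_u = [np.empty((S, qk)) for qk in qs]

    pm, pv = priors.fixed_mean, priors.fixed_variance
    acc = 0
    tacc = 0
    lacc = [0] * K
    window = 25
    s = 0
    for it in range(settings.iterations):
        if binary:
            # --- vectorised random-walk Metropolis on the latent field
            mu = beta0 + total
            prop = eta + step * rng.standard_normal(n)
            logr = (
                y * (prop - eta)
                - (np.logaddexp(0.0, prop) - np.logaddexp(0.0, eta))
                - ((prop - mu) ** 2 - (eta - mu) ** 2) / (2.0 * ve)
            )
            accept = np.log(rng.random(n)) < logr
            eta = np.where(accept, prop, eta)
            acc += int(accept.sum())
            # --- joint translation of intercept and every latent;
            # (eta - mu) is invariant, so only the Bernoulli likelihood
            # and the intercept prior enter the ratio
            delta = tstep * rng.standard_normal()
            dlog = (
                y.sum() * delta
                - float(np.sum(np.logaddexp(0.0, eta + delta)
                               - np.logaddexp(0.0, eta)))
                - ((beta0 + delta - pm) ** 2 - (beta0 - pm) ** 2) / (2.0 * pv)
            )
            if np.log(rng.random()) < dlog:
                eta = eta + delta
                beta0 += delta
                tacc += 1
            # --- per-term level shifts: move one level's effect and the
            # latents of its members together (levels are disjoint, so
            # acceptance factorises across levels)
            for k, t in enumerate(terms):
                g = codes[t]
                qk = qs[k]
                d = lstep[k] * rng.standard_normal(qk)
                di = d[g]
                dlik = y * di - (np.logaddexp(0.0, eta + di)
                                 - np.logaddexp(0.0, eta))
                lev = np.bincount(g, weights=dlik, minlength=qk)
                lev -= ((u[k] + d) ** 2 - u[k] ** 2) / (2.0 * sig2[k])
                ok = np.log(rng.random(qk)) < lev
                if ok.any():
                    u[k] = np.where(ok, u[k] + d, u[k])
                    bump = np.where(ok[g], di, 0.0)
                    eta = eta + bump
                    total += bump
                lacc[k] += int(ok.sum())
            # adapt proposal scales during burn-in only, then freeze
            if it < settings.burnin and (it + 1) % window == 0:
                rate = acc / (window * n)
                step = float(np.clip(step * np.exp(rate - 0.44), 1e-3, 50.0))
                trate = tacc / window
                tstep = float(np.clip(tstep * np.exp(trate - 0.44), 1e-4, 50.0))
                for k in range(K):
                    lrate = lacc[k] / (window * qs[k])
                    lstep[k] = float(np.clip(
                        lstep[k] * np.exp(lrate - 0.44), 1e-4, 50.0))
                acc = tacc = 0
                lacc = [0] * K
            ywork = eta
        else:
            ywork = y

        # --- joint draw of (intercept, all group effects)
        dprior = np.empty(q_tot)
        dprior[0] = 1.0 / pv
        for k in range(K):
            dprior[offs[k]:offs[k] + qs[k]] = 1.0 / sig2[k]
        P = CtC / ve
        P[diag_idx] += dprior
        rhs = np.empty(q_tot)
        rhs[0] = ywork.sum() / ve + pm / pv
        for k, t in enumerate(terms):
            rhs[offs[k]:offs[k] + qs[k]] = (
                np.bincount(codes[t], weights=ywork, minlength=qs[k]) / ve
            )
        cf = cho_factor(P, lower=True, check_finite=False)
        mean = cho_solve(cf, rhs, check_finite=False)
        z = rng.standard_normal(q_tot)
        b = mean + solve_triangular(cf[0], z, lower=True, trans="T",
                                    check_finite=False)
        beta0 = float(b[0])
        total[:] = 0.0
        for k, t in enumerate(terms):
            u[k] = b[offs[k]:offs[k] + qs[k]]
            total += u[k][codes[t]]

        # --- variance components (scalar inverse-Wishart conditionals)
        for k, t in enumerate(terms):
            if t not in fixed_variances:
                V, nu = priors.term_hyper(t)
                sig2[k] = _draw_invgamma(
                    rng, (nu + qs[k]) / 2.0, (nu * V + u[k] @ u[k]) / 2.0
                )

        # --- joint scale move on (u_k, sig2_k): multiplies the block by a
        # and its variance by a^2.  Conditional Gibbs alone mixes slowly
        # when a variance sits near zero (the "funnel"); this move walks
        # along the funnel axis.  The u-prior normalisation cancels the
        # u-Jacobian, leaving 2*ln(a) plus the variance-prior ratio.
        res = (eta if binary else y) - beta0 - total
        for k, t in enumerate(terms):
            if t in fixed_variances:
                continue
            a = float(np.exp(0.7 * rng.standard_normal()))
            dc = (a - 1.0) * u[k][codes[t]]
            dlik = -float(((res - dc) ** 2 - res ** 2).sum()) / (2.0 * ve)
            V, nu = priors.term_hyper(t)
            sh, sc = nu / 2.0 + 1.0, nu * V / 2.0
            s_old, s_new = sig2[k], a * a * sig2[k]
            dpr = (-sh * np.log(s_new) - sc / s_new) - (
                -sh * np.log(s_old) - sc / s_old)
            if np.log(rng.random()) < dlik + dpr + 2.0 * np.log(a):
                u[k] = a * u[k]
                sig2[k] = s_new
                total += dc
                res = res - dc

        # --- residual variance (Gaussian responses only; fixed for binary)
        if not binary and "residual" not in fixed_variances:
            resid = ywork - beta0 - total
            ve = _draw_invgamma(
                rng,
                (priors.residual_nu + n) / 2.0,
                (priors.residual_nu * priors.residual_V + resid @ resid) / 2.0,
            )

        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            st_intercept[s] = beta0
            st_sig2[s] = sig2
            st_ve[s] = ve
            for k in range(K):
                st_u[k][s] = u[k]
            s += 1

    cols = {"intercept": st_intercept}
    for k, t in enumerate(terms):
        cols[f"var_{t}"] = st_sig2[:, k]
    cols["var_residual"] = st_ve
    for k, t in enumerate(terms):
        for j, lv in enumerate(levels[t]):
            cols[f"u_{t}[{lv}]"] = st_u[k][:, j]
    params = pd.DataFrame(cols)
    return PosteriorDraws(params=params, spec=spec, priors=priors,
                          settings=settings, levels=levels)


def fit_gaussian_lmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    fixed_variances: dict | None = None,
) -> PosteriorDraws:
    """Fit a Gaussian mixed model by Gibbs sampling.

    ``fixed_variances`` maps term names (or ``"residual"``) to values
    that are held constant instead of sampled — useful for conditioning
    the sampler when validating it against closed-form posteriors.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_gaussian_lmm requires a gaussian-family spec")
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings.reduced()
    return _run_sampler(table, spec, priors, settings, fixed_variances,
                        binary=False)


def fit_binary_glmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    fixed_variances: dict | None = None,
) -> PosteriorDraws:
    """Fit the binary-logit mixed model with fixed residual variance."""
    if spec.family != "binary-logit":
        raise ValueError("fit_binary_glmm requires a binary-logit spec")
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings.reduced()
    return _run_sampler(table, spec, priors, settings, fixed_variances,
                        binary=True)
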