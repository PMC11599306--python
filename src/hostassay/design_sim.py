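"""Design-evaluation simulation for the mixed-brood (pseudoreplicated) assay.

Group rearing makes brood membership unobservable, so the fitted models
omit a brood term that truly exists in the data-generating process.
This module quantifies the consequences: data are simulated *with*
brood effects, the brood column is dropped, the focal model is fitted
*without* a brood term at reduced chain settings, and bias, precision,
credible-interval coverage, false-positive rate (null focal effect) and
power (non-null focal effect) are aggregated over replicates.

Because variance posteriors cannot contain zero, "significance" of a
component needs an explicit rule.  The rule used here calls a component
positive when the lower bound of the HPD interval of its *variance
share* exceeds a small threshold ``epsilon_share``.  The threshold is
not asserted to be anyone's published rule: it should be calibrated on
null cells (:func:`calibrate_epsilon`) so that the null positive-call
rate sits at a chosen nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import AssayDesign, make_design
from .diagnostics import hpd_interval
from .mcmc import MCMCSettings, ModelSpec, PriorSpec, PosteriorDraws, \
    fit_binary_glmm, fit_gaussian_lmm
from .partition import variance_shares
from .simulate import GenerativeParams, simulate_assay

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "positive_call",
    "calibrate_epsilon",
    "run_scenario",
    "run_cell",
    "summarize_grid",
]

_FOCAL = "host"


def positive_call(
    draws: PosteriorDraws,
    component: str,
    epsilon_share: float = 0.01,
    prob: float = 0.95,
) -> bool:
    """True iff the HPD lower bound of the component's variance share > epsilon."""
    shares = variance_shares(draws, prob=prob)
    if component not in shares.share_draws.columns:
        raise KeyError(f"component {component!r} not among "
                       f"{list(shares.share_draws.columns)}")
    lo, _ = hpd_interval(shares.share_draws[component].to_numpy(), prob)
    return bool(lo > epsilon_share)


def calibrate_epsilon(null_lower_bounds, alpha: float = 0.05) -> float:
    """Share-threshold giving a null positive-call rate of ~``alpha``.

    ``null_lower_bounds`` are HPD lower bounds of the focal component's
    share collected from replicates simulated under a null focal effect;
    the calibrated epsilon is their upper ``alpha`` quantile.
    """
    lbs = np.asarray(null_lower_bounds, dtype=float)
    if lbs.size == 0:
        raise ValueError("no null replicates to calibrate on")
    return float(np.quantile(lbs, 1.0 - alpha))


@dataclass(frozen=True)
class ScenarioSpec:
    """Grid of simulation cells: brood-variance levels x focal settings.

    ``host_variances`` supplies the focal (host) variance per setting:
    0 encodes the null, a positive value the alternative.  ``replicates``
    datasets are simulated per cell and each is fitted at the reduced
    ``settings``.  One master ``seed`` spawns independent per-replicate
    streams.
    """

    design: AssayDesign = field(default_factory=lambda: make_design(
        2, 4, 2, 10, broods_per_pop=(8, 8)))
    base_params: GenerativeParams = field(default_factory=GenerativeParams)
    brood_variances: tuple[float, ...] = (0.0, 0.5, 1.0)
    host_variances: tuple[float, ...] = (0.0, 2.09)
    replicates: int = 50
    settings: MCMCSettings = field(default_factory=lambda: MCMCSettings(
        iterations=3000, burnin=1000, thin=2))
    response: str = "survival"
    epsilon_share: float = 0.01
    prob: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(v < 0 for v in self.brood_variances):
            raise ValueError("brood variances must be >= 0")
        if any(v < 0 for v in self.host_variances):
            raise ValueError("host variances must be >= 0")


@dataclass
class ScenarioResult:
    """Aggregated estimates for one (brood variance, focal variance) cell.

    ``component_stats`` indexes the modelled variance components with
    their generative truth, mean bias, RMSE, 95%-CI coverage and
    Monte-Carlo SEs (NaN when only one usable replicate).  ``calls`` and
    ``share_lower_bounds`` keep per-replicate focal-call material so
    thresholds can be recalibrated without refitting.
    """

    brood_variance: float
    focal_variance: float
    replicates: int
    n_failed: int
    component_stats: pd.DataFrame
    positive_rate: float
    positive_rate_se: float
    calls: np.ndarray
    share_lower_bounds: np.ndarray


def _with_variances(params: GenerativeParams, response: str,
                    brood_var: float, host_var: float) -> GenerativeParams:
    rp = getattr(params, response)
    rp = replace(rp, var_brood=brood_var, var_host=host_var)
    return replace(params, **{response: rp})


def _fit(table, spec, priors, settings):
    if spec.family == "binary-logit":
        return fit_binary_glmm(table, spec, priors, settings)
    return fit_gaussian_lmm(table, spec, priors, settings)


def run_cell(
    spec: ScenarioSpec,
    brood_var: float,
    host_var: float,
    seed_seq: np.random.SeedSequence,
    priors: PriorSpec | None = None,
) -> ScenarioResult:
    """Simulate, drop brood, fit and aggregate one scenario cell."""
    params = _with_variances(spec.base_params, spec.response,
                             brood_var, host_var)
    model = ModelSpec.for_response(spec.response)
    priors = priors or PriorSpec()
    rp = getattr(params, spec.response)
    truths = {
        "population": rp.var_population,
        "host": rp.var_host,
        "population:host": rp.var_pop_host,
        "culture": rp.var_culture,
    }
    comps = [t for t in model.random_terms if t in truths]
    if model.family == "gaussian":
        # sampled (not fixed) residual: its generative truth is the
        # response's residual variance
        truths["residual"] = rp.var_residual
        comps.append("residual")

    est = {c: [] for c in comps}
    cover = {c: [] for c in comps}
    calls, lbs = [], []
    n_failed = 0
    for child in seed_seq.spawn(spec.replicates):
        s_sim, s_fit = (int(g) % 2**31 for g in child.generate_state(2))
        table = simulate_assay(spec.design, params, seed=s_sim,
                               drop_brood=True)
        try:
            draws = _fit(table, model, priors,
                         replace(spec.settings, seed=s_fit))
        except ValueError:
            # e.g. all-dead replicate under a harsh survival setting:
            # flagged and excluded, never fatal
            n_failed += 1
            continue
        shares = variance_shares(draws, prob=spec.prob)
        for c in comps:
            x = draws.params[f"var_{c}"].to_numpy()
            est[c].append(x.mean())
            lo, hi = hpd_interval(x, spec.prob)
            cover[c].append(lo <= truths[c] <= hi)
        lo, _ = hpd_interval(shares.share_draws[_FOCAL].to_numpy(), spec.prob)
        lbs.append(lo)
        calls.append(lo > spec.epsilon_share)

    used = spec.replicates - n_failed
    rows = []
    for c in comps:
        e = np.asarray(est[c], dtype=float)
        cv = np.asarray(cover[c], dtype=float)
        if used == 0:
            rows.append({"component": c, "truth": truths[c], "bias": np.nan,
                         "rmse": np.nan, "coverage": np.nan,
                         "bias_se": np.nan, "coverage_se": np.nan})
            continue
        bias = float(np.mean(e - truths[c]))
        rmse = float(np.sqrt(np.mean((e - truths[c]) ** 2)))
        coverage = float(cv.mean())
        if used > 1:
            bias_se = float(np.std(e, ddof=1) / np.sqrt(used))
            coverage_se = float(np.sqrt(coverage * (1 - coverage) / used))
        else:
            bias_se = coverage_se = np.nan
        rows.append({"component": c, "truth": truths[c], "bias": bias,
                     "rmse": rmse, "coverage": coverage,
                     "bias_se": bias_se, "coverage_se": coverage_se})
    calls_arr = np.asarray(calls, dtype=bool)
    rate = float(calls_arr.mean()) if used else np.nan
    rate_se = (float(np.sqrt(rate * (1 - rate) / used))
               if used > 1 else np.nan)
    return ScenarioResult(
        brood_variance=brood_var,
        focal_variance=host_var,
        replicates=spec.replicates,
        n_failed=n_failed,
        component_stats=pd.DataFrame(rows).set_index("component"),
        positive_rate=rate,
        positive_rate_se=rate_se,
        calls=calls_arr,
        share_lower_bounds=np.asarray(lbs, dtype=float),
    )


def run_scenario(spec: ScenarioSpec) -> list[ScenarioResult]:
    """Run the full brood-variance x focal-setting grid."""
    root = np.random.SeedSequence(spec.seed)
    cells = [(b, h) for b in spec.brood_variances for h in spec.host_variances]
    results = []
    for (b, h), child in zip(cells, root.spawn(len(cells))):
        results.append(run_cell(spec, b, h, child))
    return results


def summarize_grid(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tidy long-format table over scenario cells and components."""
    if not results:
        raise ValueError("no scenario results to summarize")
    rows = []
    for res in results:
        for comp, r in res.component_stats.iterrows():
            rows.append(
                {
                    "brood_variance": res.brood_variance,
                    "focal_variance": res.focal_variance,
                    "component": comp,
                    "truth": r["truth"],
                    "bias": r["bias"],
                    "rmse": r["rmse"],
                    "coverage": r["coverage"],
                    "bias_se": r["bias_se"],
                    "coverage_se": r["coverage_se"],
                    "positive_rate": res.positive_rate,
                    "positive_rate_se": res.positive_rate_se,
                    "replicates": res.replicates,
                    "n_failed": res.n_failed,
                }
            )
    return pd.DataFrame(rows)
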