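"""Posterior variance partitioning and treatment-level predictions.

Variance shares are computed draw-wise on the link scale: within each
stored draw, a component's share is its variance divided by the sum of
all sampled components *plus the residual* (fixed or sampled).  Because
the ratio is formed inside each draw, the posterior mean share need not
equal the ratio of posterior-mean variances.  No logistic
distribution-specific variance (pi^2/3) is added to the denominator:
the residual enters at its modelled (fixed) value, keeping the
partition on the same link scale as the fitted model.  The convention
is switchable via ``extra_residual``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .diagnostics import effective_sample_size, hpd_interval
from .mcmc import PosteriorDraws

__all__ = [
    "VarianceShareSummary",
    "PredictionDraws",
    "variance_shares",
    "treatment_predictions",
    "summarize_model",
]


@dataclass
class VarianceShareSummary:
    """Per-component share and raw-scale posterior summaries.

    ``table`` has one row per component (index) with columns
    ``share_mean, share_lower, share_upper, var_mean, var_lower,
    var_upper``; ``share_draws`` keeps the draw-wise shares (they sum to
    one within every draw by construction).
    """

    table: pd.DataFrame
    share_draws: pd.DataFrame


def variance_shares(
    draws: PosteriorDraws,
    prob: float = 0.95,
    extra_residual: float = 0.0,
) -> VarianceShareSummary:
    """Partition link-scale variance across components, draw by draw.

    ``extra_residual`` adds a constant to the denominator in every draw
    (e.g. pi^2/3 for a latent-logistic convention); the default of zero
    matches partitioning on the link scale with the modelled residual.
    """
    cols = draws.variance_columns()
    if len(cols) < 2:
        raise ValueError("need at least one variance component plus residual")
    V = draws.params[cols].to_numpy()
    total = V.sum(axis=1) + extra_residual
    if np.any(total <= 0.0):
        raise ValueError("zero total variance in at least one draw")
    shares = V / total[:, None]
    names = [c[len("var_"):] for c in cols]
    rows = []
    for j, name in enumerate(names):
        s_lo, s_hi = hpd_interval(shares[:, j], prob)
        v_lo, v_hi = hpd_interval(V[:, j], prob)
        rows.append(
            {
                "component": name,
                "share_mean": shares[:, j].mean(),
                "share_lower": s_lo,
                "share_upper": s_hi,
                "var_mean": V[:, j].mean(),
                "var_lower": v_lo,
                "var_upper": v_hi,
            }
        )
    table = pd.DataFrame(rows).set_index("component")
    share_draws = pd.DataFrame(shares, columns=names)
    return VarianceShareSummary(table=table, share_draws=share_draws)


@dataclass
class PredictionDraws:
    """Response-scale posterior predictions for a set of treatment groups.

    ``draws`` is (n_draws, n_groups), column-aligned with ``labels``.
    For ``level="cell"`` each label is a ``(population, host)`` tuple.
    """

    metric: str
    level: str
    labels: list
    draws: np.ndarray
    link: str

    def label_strings(self) -> list[str]:
        return [":".join(l) if isinstance(l, tuple) else str(l)
                for l in self.labels]

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []
        for j, lab in enumerate(self.label_strings()):
            lo, hi = hpd_interval(self.draws[:, j], prob)
            rows.append({"group": lab, "mean": self.draws[:, j].mean(),
                         "lower": lo, "upper": hi})
        return pd.DataFrame(rows)

    def grand(self, prob: float = 0.95) -> dict:
        """Draw-wise arithmetic mean across groups, then summarised."""
        g = self.draws.mean(axis=1)
        lo, hi = hpd_interval(g, prob)
        return {"mean": float(g.mean()), "lower": lo, "upper": hi}


def _invlink(family: str):
    if family == "binary-logit":
        return expit, "logit"
    return (lambda x: x), "identity"


def treatment_predictions(
    draws: PosteriorDraws,
    level: str = "host",
    population_mode: str = "zero",
) -> PredictionDraws:
    """Posterior predictions per host or per host-by-population cell.

    Per draw the group prediction is ``invlink(intercept + u_host)`` at
    host level, adding ``u_population + u_population:host`` at cell
    level.  Random terms outside the requested level are set to zero
    (the conditional-mode convention); at host level,
    ``population_mode="average"`` instead averages the response-scale
    cell predictions over populations.
    """
    if level not in ("host", "cell"):
        raise ValueError(f"unknown level {level!r}; use 'host' or 'cell'")
    inv, link = _invlink(draws.spec.family)
    b0 = draws.intercept()[:, None]
    uh = draws.group_effect_matrix("host")
    hosts = list(draws.levels["host"])

    def cell_matrix():
        up = draws.group_effect_matrix("population")
        pops = list(draws.levels["population"])
        uph = draws.group_effect_matrix("population:host")
        ph_levels = list(draws.levels["population:host"])
        ph_index = {lv: j for j, lv in enumerate(ph_levels)}
        S = uh.shape[0]
        mats, labels = [], []
        for i, p in enumerate(pops):
            for j, h in enumerate(hosts):
                key = f"{p}:{h}"
                eta = b0[:, 0] + up[:, i] + uh[:, j]
                if key in ph_index:
                    eta = eta + uph[:, ph_index[key]]
                mats.append(inv(eta))
                labels.append((p, h))
        return np.column_stack(mats), labels, pops

    if level == "cell":
        mat, labels, _ = cell_matrix()
        return PredictionDraws(draws.spec.response, "cell", labels, mat, link)

    if population_mode == "zero":
        pred = inv(b0 + uh)
    elif population_mode == "average":
        mat, labels, pops = cell_matrix()
        npop = len(pops)
        pred = mat.reshape(mat.shape[0], npop, len(hosts)).mean(axis=1)
    else:
        raise ValueError("population_mode must be 'zero' or 'average'")
    return PredictionDraws(draws.spec.response, "host", hosts, pred, link)


def summarize_model(draws: PosteriorDraws, prob: float = 0.95) -> pd.DataFrame:
    """Summary table: one row per fixed term and variance component.

    Columns: posterior mean, HPD credible interval, effective sample
    size (reported as n, with a warning suppressed, for constant
    columns such as a fixed residual).
    """
    rows = []
    for col in ["intercept"] + draws.variance_columns():
        x = draws.params[col].to_numpy()
        lo, hi = hpd_interval(x, prob)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = effective_sample_size(x)
        rows.append({"term": col, "mean": x.mean(), "lower": lo,
                     "upper": hi, "ess": ess})
    return pd.DataFrame(rows)
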