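"""Local-adaptation criteria over host x population posterior predictions.

Two classical criteria are evaluated against a map of the locally
abundant hosts at each population's collection site:

* **local vs foreign** — per host (the "environment"), the posterior
  probability that each population's prediction is the best of all
  populations; the flora-designated local population "wins" when it has
  the highest such probability.
* **home vs away** — per population, the posterior probability that its
  performance on its home host(s) exceeds its performance on away
  hosts.  This criterion is misleading when environments differ in
  average quality, so the report carries a caveat flag and it should
  not be read as a definitive test.

Both are computed draw-wise, so criterion-1 probabilities are invariant
to monotone transformations of the metric; for criterion 2 a rank-based
comparison (``method="rank"``) provides the same invariance, while the
default compares home and away means on the metric's own scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .partition import PredictionDraws

__all__ = [
    "DEFAULT_FLORA",
    "AdaptationReport",
    "local_vs_foreign",
    "home_vs_away",
    "evaluate_local_adaptation",
]

#: Locally abundant assay hosts at each collection site, encoded from
#: prose habitat descriptions of the sites; an interpretation, shipped
#: as a replaceable default rather than a ground truth.
DEFAULT_FLORA: dict[str, frozenset] = {
    "Devon": frozenset({"oak"}),
    "Edinburgh": frozenset({"oak", "sycamore"}),
    "Buckinghamshire": frozenset({"apple", "cherry", "hawthorn"}),
    "Suffolk": frozenset({"oak", "birch", "sycamore"}),
}


def _cell_array(pred):
    # accepts PredictionDraws or DerivedPosterior with (population, host) labels
    if getattr(pred, "level", "cell") != "cell" or not all(
        isinstance(l, tuple) for l in pred.labels
    ):
        raise ValueError("need cell-level (population x host) predictions")
    pops = sorted({p for p, _ in pred.labels})
    hosts = sorted({h for _, h in pred.labels})
    index = {lab: j for j, lab in enumerate(pred.labels)}
    S = pred.draws.shape[0]
    arr = np.empty((S, len(pops), len(hosts)))
    for i, p in enumerate(pops):
        for j, h in enumerate(hosts):
            if (p, h) not in index:
                raise ValueError(f"missing cell prediction for {(p, h)}")
            arr[:, i, j] = pred.draws[:, index[(p, h)]]
    return arr, pops, hosts


def _validate_flora(flora, pops, hosts):
    missing = [p for p in pops if p not in flora]
    if missing:
        raise KeyError(f"flora map lacks populations {missing}")
    unknown = {h for p in pops for h in flora[p]} - set(hosts)
    return unknown  # reported, not fatal


def local_vs_foreign(
    pred: PredictionDraws,
    flora: dict | None = None,
    higher_is_better: bool = True,
) -> pd.DataFrame:
    """Criterion 1: is the local population the best on its local host?

    Returns one row per host with each population's probability of being
    the best performer on that host (draw-wise argmax frequencies), the
    set of populations for which the host is local, and whether a local
    population holds the highest probability.
    """
    flora = DEFAULT_FLORA if flora is None else flora
    arr, pops, hosts = _cell_array(pred)
    _validate_flora(flora, pops, hosts)
    vals = arr if higher_is_better else -arr
    best = vals.argmax(axis=1)  # (S, H)
    rows = []
    for j, h in enumerate(hosts):
        freqs = np.bincount(best[:, j], minlength=len(pops)) / arr.shape[0]
        locals_ = [p for p in pops if h in flora[p]]
        top = pops[int(np.argmax(freqs))]
        rows.append(
            {
                "host": h,
                **{f"p_best[{p}]": freqs[i] for i, p in enumerate(pops)},
                "local_populations": ";".join(locals_),
                "top_population": top,
                "local_wins": top in locals_ if locals_ else np.nan,
            }
        )
    return pd.DataFrame(rows)


def home_vs_away(
    pred: PredictionDraws,
    flora: dict | None = None,
    higher_is_better: bool = True,
    method: str = "mean",
) -> pd.DataFrame:
    """Criterion 2: does each population do better at home than away?

    Per draw, the population's predictions on its home hosts are
    averaged and compared with the average over away hosts
    (``method="mean"``), or the within-population host ranks are averaged
    instead (``method="rank"``, invariant to monotone transformations).
    """
    if method not in ("mean", "rank"):
        raise ValueError("method must be 'mean' or 'rank'")
    flora = DEFAULT_FLORA if flora is None else flora
    arr, pops, hosts = _cell_array(pred)
    _validate_flora(flora, pops, hosts)
    rows = []
    for i, p in enumerate(pops):
        home = [j for j, h in enumerate(hosts) if h in flora[p]]
        away = [j for j, h in enumerate(hosts) if h not in flora[p]]
        if not home:
            raise ValueError(f"population {p!r} has no home host in the map")
        if not away:
            raise ValueError(f"population {p!r} has no away host in the map")
        vals = arr[:, i, :] if higher_is_better else -arr[:, i, :]
        if method == "rank":
            vals = vals.argsort(axis=1).argsort(axis=1).astype(float)
        diff = vals[:, home].mean(axis=1) - vals[:, away].mean(axis=1)
        rows.append(
            {
                "population": p,
                "home_hosts": ";".join(hosts[j] for j in home),
                "p_home_better": float(np.mean(diff > 0)
                                       + 0.5 * np.mean(diff == 0)),
                "caveat": "not a definitive test when environments differ "
                          "in average quality",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AdaptationReport:
    """Both criteria for one performance metric."""

    metric: str
    local_vs_foreign: pd.DataFrame
    home_vs_away: pd.DataFrame


def evaluate_local_adaptation(
    pred: PredictionDraws,
    flora: dict | None = None,
    higher_is_better: bool = True,
    method: str = "mean",
) -> AdaptationReport:
    return AdaptationReport(
        metric=pred.metric,
        local_vs_foreign=local_vs_foreign(pred, flora, higher_is_better),
        home_vs_away=home_vs_away(pred, flora, higher_is_better, method),
    )
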