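"""Experimental layout of a group-reared, multi-population host-plant assay.

The assay fully crosses source populations with host-plant treatments.
Within each population x host cell, larvae are reared in fixed-size
cultures (containers).  Every larva descends from one of a finite pool
of wild-caught broods belonging to its source population, and cultures
are mixed-brood by construction: brood identity is real in the
data-generating process but is not recorded per individual in the
analysable table (individuals cannot be tracked inside a culture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default source-population labels (four British collection sites).
POPULATIONS = ("Buckinghamshire", "Devon", "Edinburgh", "Suffolk")

#: Default host-plant treatments (nine common, widespread species).
HOSTS = (
    "alder",
    "apple",
    "birch",
    "cherry",
    "hawthorn",
    "oak",
    "sallow",
    "sycamore",
    "willow",
)

#: Number of wild-caught females (broods) obtained per population.
BROOD_COUNTS = {
    "Buckinghamshire": 15,
    "Devon": 14,
    "Edinburgh": 126,
    "Suffolk": 19,
}


@dataclass(frozen=True)
class AssayDesign:
    """A fully crossed population x host rearing design.

    Parameters
    ----------
    n_pops, n_hosts
        Numbers of source populations and host-plant treatments.
    n_cultures_per_cell
        Rearing containers per population x host cell.
    n_per_culture
        Larvae per rearing container.
    broods_per_pop
        Size of each population's brood pool, ordered as ``pop_labels``.
    pop_labels, host_labels
        Treatment labels; free strings, matched case-sensitively.
    """

    n_pops: int
    n_hosts: int
    n_cultures_per_cell: int
    n_per_culture: int
    broods_per_pop: tuple[int, ...]
    pop_labels: tuple[str, ...]
    host_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_hosts", "n_cultures_per_cell", "n_per_culture"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if len(self.broods_per_pop) != self.n_pops:
            raise ValueError(
                f"broods_per_pop has length {len(self.broods_per_pop)}, "
                f"expected n_pops={self.n_pops}"
            )
        if any(b < 1 for b in self.broods_per_pop):
            raise ValueError("every brood pool must hold at least one brood")
        if len(self.pop_labels) != self.n_pops:
            raise ValueError("pop_labels length must equal n_pops")
        if len(self.host_labels) != self.n_hosts:
            raise ValueError("host_labels length must equal n_hosts")
        if len(set(self.pop_labels)) != self.n_pops:
            raise ValueError("population labels must be unique")
        if len(set(self.host_labels)) != self.n_hosts:
            raise ValueError("host labels must be unique")

    @property
    def n_cells(self) -> int:
        return self.n_pops * self.n_hosts

    @property
    def n_cultures(self) -> int:
        return self.n_cells * self.n_cultures_per_cell

    @property
    def n_individuals(self) -> int:
        return self.n_cultures * self.n_per_culture

    def frame(self) -> pd.DataFrame:
        """Expand the design into one row per individual.

        Rows are ordered population-major, then host, culture, individual;
        this ordering is the canonical one used by :func:`assign_broods`
        and the simulator.  Culture ids embed their cell so that each
        culture maps to exactly one (population, host) pair.
        """
        rows = self.n_individuals
        per_pop = self.n_hosts * self.n_cultures_per_cell * self.n_per_culture
        per_host = self.n_cultures_per_cell * self.n_per_culture
        idx = np.arange(rows)
        pop_idx = idx // per_pop
        host_idx = (idx % per_pop) // per_host
        cult_idx = (idx % per_host) // self.n_per_culture
        pops = np.asarray(self.pop_labels, dtype=object)[pop_idx]
        hosts = np.asarray(self.host_labels, dtype=object)[host_idx]
        cultures = np.array(
            [f"{p}-{h}-c{c + 1}" for p, h, c in zip(pops, hosts, cult_idx)],
            dtype=object,
        )
        ids = np.array([f"i{k + 1:05d}" for k in idx], dtype=object)
        return pd.DataFrame(
            {
                "id": ids,
                "population": pops,
                "host": hosts,
                "culture": cultures,
                "_pop_idx": pop_idx,
                "_host_idx": host_idx,
            }
        )


def make_design(
    n_pops: int = 4,
    n_hosts: int = 9,
    n_cultures_per_cell: int = 5,
    n_per_culture: int = 20,
    broods_per_pop=None,
    pop_labels=None,
    host_labels=None,
) -> AssayDesign:
    """Build a validated :class:`AssayDesign`.

    The default configuration reproduces the full assay layout: 4
    populations x 9 hosts x 5 cultures x 20 larvae = 3600 individuals.
    """
    if pop_labels is None:
        pop_labels = (
            POPULATIONS
            if n_pops == len(POPULATIONS)
            else tuple(f"pop{i + 1}" for i in range(n_pops))
        )
    if host_labels is None:
        host_labels = (
            HOSTS
            if n_hosts == len(HOSTS)
            else tuple(f"host{i + 1}" for i in range(n_hosts))
        )
    if broods_per_pop is None:
        if all(p in BROOD_COUNTS for p in pop_labels):
            broods_per_pop = tuple(BROOD_COUNTS[p] for p in pop_labels)
        else:
            broods_per_pop = tuple(10 for _ in range(n_pops))
    return AssayDesign(
        n_pops=int(n_pops),
        n_hosts=int(n_hosts),
        n_cultures_per_cell=int(n_cultures_per_cell),
        n_per_culture=int(n_per_culture),
        broods_per_pop=tuple(int(b) for b in broods_per_pop),
        pop_labels=tuple(pop_labels),
        host_labels=tuple(host_labels),
    )


def paper_design() -> AssayDesign:
    """The published assay layout: 4 x 9 x 5 x 20 with the real brood pools."""
    return make_design()


def assign_broods(design: AssayDesign, seed) -> np.ndarray:
    """Assign every individual a brood drawn uniformly from its population's pool.

    Cultures are mixed-brood: no constraint ties a culture to a single
    brood.  Deterministic given ``seed`` (an int, or a ready-made
    :class:`numpy.random.Generator`).

    Returns an object array of brood labels (``"<pop>-b<k>"``) aligned
    with ``design.frame()`` row order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = design.frame()
    pop_idx = frame["_pop_idx"].to_numpy()
    pools = np.asarray(design.broods_per_pop)
    # inverse-CDF draw: uniform over each row's own pool size
    draw = np.floor(rng.random(len(frame)) * pools[pop_idx]).astype(int)
    pops = frame["population"].to_numpy()
    return np.array(
        [f"{p}-b{k + 1:03d}" for p, k in zip(pops, draw)], dtype=object
    )
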