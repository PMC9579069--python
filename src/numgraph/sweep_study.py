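"""Connectivity-distance sweeps and maximum-standard-deviation selection.

For a fixed numerosity, every index is evaluated on G_d over a grid of
connectivity distances (reference grid: delta, delta+5, ..., 2R).  Because
an index's value is constant (or nearly so) at both extremes of d, the most
informative distance for comparing patterns is where the across-pattern
standard deviation sigma_m(n, d) peaks; ``max_sd_selection`` locates that
distance d_m per index and extracts the per-pattern values there, which are
the substrate of the max-SD correlation and PCA analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from . import indices as gi
from .geomgraph import build_graph
from .occupancy import occupancy_analytic
from .stimgen import PointConfiguration

__all__ = [
    "ALL_INDICES",
    "SweepSettings",
    "IndexTable",
    "MaxSDEntry",
    "sweep",
    "max_sd_distance",
    "max_sd_selection",
    "connectivity_threshold",
    "index_floor_distance",
    "default_d_grid",
]

#: The eleven indices of the study: occupancy plus the ten graph indices.
ALL_INDICES = ("OC",) + gi.INDEX_NAMES


def default_d_grid(R: float = 160.0, delta: float = 10.0, step: float = 5.0) -> np.ndarray:
    """The reference grid {delta, delta+step, ..., 2R}."""
    return np.arange(delta, 2 * R + step / 2, step)


@dataclass(frozen=True)
class SweepSettings:
    """Shared settings for stochastic indices within a sweep."""

    walks: int = 1000
    max_iters: int = 1000
    tol: float = 1e-6
    seed: int = 0


@dataclass
class IndexTable:
    """Index values on a (pattern x d x index) grid, in tidy form.

    ``data`` columns: pattern_id, n, d, index, value, mc_error, ok.
    Failed cells carry ok=False and NaN, never silent absence.
    """

    data: pd.DataFrame
    d_grid: np.ndarray
    n: int
    provenance: dict = field(default_factory=dict)

    def pivot(self, index_name: str) -> pd.DataFrame:
        """Patterns (rows, sorted by id) x grid distances (columns)."""
        sub = self.data[self.data["index"] == index_name]
        if sub.empty:
            raise KeyError(f"index {index_name!r} not in table")
        return sub.pivot(index="pattern_id", columns="d", values="value").sort_index()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def save_provenance(self, path: str | Path) -> None:
        import json

        prov = dict(self.provenance)
        prov["d_grid"] = list(map(float, self.d_grid))
        prov["n"] = int(self.n)
        Path(path).write_text(json.dumps(prov, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndexTable":
        df = pd.read_csv(path)
        return cls(
            data=df,
            d_grid=np.sort(df["d"].unique()),
            n=int(df["n"].iloc[0]),
        )


@dataclass(frozen=True)
class MaxSDEntry:
    """Per-index result of the max-SD selection (one row of the d_m table)."""

    index: str
    d_m: float
    sigma_max: float
    values_at_dm: np.ndarray  # aligned with pattern_ids
    pattern_ids: tuple[str, ...]


class DegenerateVarianceError(ValueError):
    """Index constant across patterns at every grid distance."""


def sweep(
    configs: Sequence[PointConfiguration],
    d_grid: Sequence[float],
    indices: Sequence[str] = ALL_INDICES,
    settings: SweepSettings | None = None,
) -> IndexTable:
    """Evaluate the requested indices for every (pattern, d) cell.

    All configurations must share one numerosity.  Stochastic indices draw
    from per-(pattern, d) child generators spawned from the master seed, so
    the whole table is a pure function of (configs, grid, settings).
    """
    if len(d_grid) == 0:
        raise ValueError("d_grid must be nonempty")
    d_grid = np.asarray(sorted(d_grid), dtype=float)
    ns = {c.n for c in configs}
    if len(ns) != 1:
        raise ValueError(f"all configurations must share one numerosity, got {sorted(ns)}")
    n = ns.pop()
    settings = settings or SweepSettings()
    graph_indices = [m for m in indices if m != "OC"]
    want_oc = "OC" in indices
    rows = []
    for ci, cfg in enumerate(configs):
        dist = cfg.distance_matrix()
        for d in d_grid:
            if want_oc:
                try:
                    oc = occupancy_analytic(cfg, d).value
                    rows.append((cfg.pattern_id, n, d, "OC", oc, np.nan, True))
                except Exception:
                    rows.append((cfg.pattern_id, n, d, "OC", np.nan, np.nan, False))
            if graph_indices:
                g = build_graph(cfg, d, _dist=dist)
                rng = np.random.default_rng(
                    np.random.SeedSequence(settings.seed, spawn_key=(ci, int(round(d * 1000))))
                )
                for iv in gi.compute_all(
                    g,
                    indices=tuple(graph_indices),
                    walks=settings.walks,
                    max_iters=settings.max_iters,
                    tol=settings.tol,
                    seed=rng,
                ):
                    rows.append(
                        (cfg.pattern_id, n, d, iv.index_name, iv.value,
                         np.nan if iv.mc_error is None else iv.mc_error,
                         not np.isnan(iv.value))
                    )
    df = pd.DataFrame(rows, columns=["pattern_id", "n", "d", "index", "value", "mc_error", "ok"])
    prov = {
        "seed": settings.seed,
        "walks": settings.walks,
        "max_iters": settings.max_iters,
        "tol": settings.tol,
        "indices": list(indices),
    }
    return IndexTable(data=df, d_grid=d_grid, n=n, provenance=prov)


def max_sd_distance(table: IndexTable, index_name: str) -> MaxSDEntry:
    """Smallest grid d attaining the maximal across-pattern sample SD."""
    wide = table.pivot(index_name)
    if wide.shape[0] < 2:
        raise ValueError("max-SD selection needs at least 2 patterns")
    sds = wide.std(axis=0, ddof=1).to_numpy()
    if np.all(sds == 0):
        raise DegenerateVarianceError(f"{index_name} is constant at every grid distance")
    k = int(np.argmax(sds))  # first occurrence = smallest d on ties
    d_m = float(wide.columns[k])
    return MaxSDEntry(
        index=index_name,
        d_m=d_m,
        sigma_max=float(sds[k]),
        values_at_dm=wide.iloc[:, k].to_numpy(),
        pattern_ids=tuple(wide.index),
    )


def max_sd_selection(table: IndexTable, indices: Sequence[str] | None = None) -> dict[str, MaxSDEntry]:
    """Max-SD entry for every index in the table (Table-2-style object)."""
    names = indices if indices is not None else [m for m in ALL_INDICES if m in set(table.data["index"])]
    return {m: max_sd_distance(table, m) for m in names}


def max_sd_frame(selection: dict[str, MaxSDEntry], R: float = 160.0) -> pd.DataFrame:
    """Summary frame: index, d_m, d_m/R, sigma_max."""
    return pd.DataFrame(
        [
            {"index": e.index, "d_m": e.d_m, "d_m_over_R": e.d_m / R, "sigma_max": e.sigma_max}
            for e in selection.values()
        ]
    )


def critical_connection_distance(config: PointConfiguration) -> float:
    """Smallest d at which G_d is connected = longest edge of the Euclidean MST."""
    if config.n == 1:
        return 0.0
    mst = minimum_spanning_tree(csr_matrix(config.distance_matrix()))
    return float(mst.max())


def connectivity_threshold(
    configs: Sequence[PointConfiguration], d_grid: Sequence[float]
) -> float | None:
    """Smallest grid d at which every configuration's G_d is connected.

    Computed from the per-pattern critical distance (longest MST edge);
    returns None if no grid distance connects all patterns.
    """
    if len(configs) == 0 or len(d_grid) == 0:
        raise ValueError("configs and d_grid must be nonempty")
    crit = max(critical_connection_distance(c) for c in configs)
    grid = np.asarray(sorted(d_grid), dtype=float)
    ok = grid[grid >= crit]
    return float(ok[0]) if ok.size else None


def index_floor_distance(table: IndexTable, index_name: str, tol: float = 1e-12) -> float | None:
    """Smallest grid d at and beyond which the index's across-pattern variance is zero.

    Detects threshold/saturation distances (e.g. DN reaching its floor);
    None if the index never saturates on the grid.
    """
    wide = table.pivot(index_name)
    sds = wide.std(axis=0, ddof=1).to_numpy()
    zero = sds <= tol
    # longest all-zero suffix
    if not zero[-1]:
        return None
    k = len(zero)
    while k > 0 and zero[k - 1]:
        k -= 1
    return float(wide.columns[k])
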