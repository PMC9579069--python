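"""Random dot-pattern generation for numerosity stimuli.

Patterns are sets of points confined to a circular aperture of radius ``R``
(pixels), with a minimum pairwise spacing ``delta`` that prevents element
overlap.  Points are drawn by rejection sampling: candidates are uniform on
the bounding square ``[-R, R]^2``, kept if they fall inside the aperture and
are at least ``delta`` away from every point already placed.  The resulting
point process is uniform on the disk conditional on the spacing constraint.

Coordinates are in pixels, origin at the aperture center, y increasing
upward.  All randomness flows from a single master seed through
:class:`numpy.random.SeedSequence` spawn keys, so any individual pattern of a
study set can be regenerated without regenerating the whole set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "PointConfiguration",
    "PackingError",
    "generate_pattern",
    "generate_study_set",
    "pair_proximity_probability",
    "pair_proximity_exact",
    "save_patterns_csv",
    "load_patterns_csv",
    "save_patterns_json",
    "load_patterns_json",
]

#: Default numerosities of the reference study.
STUDY_NUMEROSITIES = (22, 28, 34, 40)
#: Default aperture radius in pixels (5 deg of visual angle at 57 cm, 32 px/deg).
STUDY_RADIUS = 160.0
#: Default minimum spacing, R/16.
STUDY_DELTA = 10.0


class PackingError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget.

    Signals an infeasible (or near-infeasible) combination of numerosity,
    spacing and aperture radius.
    """


@dataclass(frozen=True)
class PointConfiguration:
    """A labeled set of 2D points inside a circular aperture.

    Parameters
    ----------
    points : ndarray of shape (n, 2)
        Point coordinates in pixels, aperture centered at the origin.
    R : float
        Aperture radius in pixels.
    delta : float
        Minimum pairwise spacing the pattern was generated under (0 for
        externally loaded patterns without spacing metadata).
    seed : int or None
        Seed the pattern was generated from; ``None`` for loaded patterns.
    pattern_id : str
        Label, e.g. ``"n22_p0007"``.
    """

    points: np.ndarray
    R: float
    delta: float = 0.0
    seed: int | None = None
    pattern_id: str = "pattern"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be an (n, 2) array with n >= 1")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances, shape (n, n)."""
        diff = self.points[:, None, :] - self.points[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def min_spacing(self) -> float:
        """Smallest pairwise distance (inf for a single point)."""
        if self.n < 2:
            return float("inf")
        dm = self.distance_matrix()
        return float(dm[np.triu_indices(self.n, k=1)].min())


def _pattern_rng(master_seed: int, n: int, replicate: int) -> np.random.Generator:
    # Fixed spawn rule: child = SeedSequence(master, spawn_key=(n, replicate)).
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(n, replicate)))


def generate_pattern(
    n: int,
    R: float = STUDY_RADIUS,
    delta: float = STUDY_DELTA,
    seed: int = 0,
    max_attempts: int = 100_000,
    pattern_id: str | None = None,
    _rng: np.random.Generator | None = None,
) -> PointConfiguration:
    """Generate one random pattern by rejection sampling.

    Candidates are drawn uniformly in ``[-R, R]^2`` and accepted if they lie
    inside the aperture disk and at distance >= ``delta`` from every accepted
    point (a distance of exactly ``delta`` is accepted).

    Raises
    ------
    PackingError
        If ``max_attempts`` candidate draws are used up before ``n`` points
        are placed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if max_attempts < n:
        raise ValueError("max_attempts must be at least n")
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    pts = np.empty((n, 2))
    placed = 0
    for _ in range(max_attempts):
        cand = rng.uniform(-R, R, size=2)
        if cand[0] ** 2 + cand[1] ** 2 > R**2:
            continue
        if placed and delta > 0:
            d2 = ((pts[:placed] - cand) ** 2).sum(axis=1)
            if d2.min() < delta**2:
                continue
        pts[placed] = cand
        placed += 1
        if placed == n:
            return PointConfiguration(
                points=pts,
                R=R,
                delta=delta,
                seed=seed,
                pattern_id=pattern_id or f"n{n}_s{seed}",
            )
    raise PackingError(
        f"failed to place {n} points (placed {placed}) with delta={delta}, "
        f"R={R} within {max_attempts} attempts"
    )


def generate_study_set(
    numerosities: Sequence[int] = STUDY_NUMEROSITIES,
    patterns_per_n: int = 1000,
    R: float = STUDY_RADIUS,
    delta: float = STUDY_DELTA,
    seed: int = 0,
    max_attempts: int = 100_000,
) -> list[PointConfiguration]:
    """Generate ``patterns_per_n`` patterns for each numerosity.

    Each pattern draws from its own child generator spawned from the master
    seed by ``(n, replicate)``, so the set is reproducible as a whole and
    pattern-by-pattern.
    """
    if not numerosities:
        raise ValueError("numerosities must be nonempty")
    if patterns_per_n < 1:
        raise ValueError("patterns_per_n must be >= 1")
    out: list[PointConfiguration] = []
    for n in numerosities:
        for rep in range(patterns_per_n):
            rng = _pattern_rng(seed, n, rep)
            out.append(
                generate_pattern(
                    n, R=R, delta=delta, seed=seed, max_attempts=max_attempts,
                    pattern_id=f"n{n:02d}_p{rep:04d}", _rng=rng,
                )
            )
    return out


def pair_proximity_probability(
    R: float = STUDY_RADIUS,
    delta: float = STUDY_DELTA,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of P(|U - V| <= delta) for U, V uniform on the disk.

    Returns ``(estimate, standard_error)``.  With delta = R/16 the probability
    is about 0.0038, which is why plain rejection sampling wastes very few
    draws at study numerosities.
    """
    if not 0 < delta <= 2 * R:
        raise ValueError("delta must satisfy 0 < delta <= 2R")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 250_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        # uniform points on the disk via sqrt-radius polar sampling
        u = np.sqrt(rng.random((2, m))) * R
        th = rng.uniform(0, 2 * np.pi, (2, m))
        x = u * np.cos(th)
        y = u * np.sin(th)
        d2 = (x[0] - x[1]) ** 2 + (y[0] - y[1]) ** 2
        hits += int((d2 <= delta**2).sum())
        remaining -= m
    p = hits / n_samples
    se = float(np.sqrt(max(p * (1 - p), 1e-300) / n_samples))
    return p, se


def pair_proximity_exact(R: float, delta: float) -> float:
    """P(|U - V| <= delta) by numerical integration of the disk line-picking density.

    For two independent uniform points in a disk of radius R, the distance
    density is ``f(s) = (2s/R^2) * (2/pi) * (acos(t/2) - (t/2) sqrt(1 - t^2/4))``
    with ``t = s/R``.  Used as an independent oracle for the Monte-Carlo
    estimator.
    """
    def pdf(s: float) -> float:
        t = s / R
        return (2 * s / R**2) * (2 / np.pi) * (np.arccos(t / 2) - (t / 2) * np.sqrt(1 - t * t / 4))

    val, _ = integrate.quad(pdf, 0.0, delta)
    return float(val)


# ---------------------------------------------------------------------------
# Serialization: CSV (one row per point) and JSON (one record per pattern).

def save_patterns_csv(configs: Iterable[PointConfiguration], path: str | Path) -> None:
    rows = []
    for c in configs:
        for x, y in c.points:
            rows.append({"pattern_id": c.pattern_id, "n": c.n, "x": x, "y": y})
    pd.DataFrame(rows, columns=["pattern_id", "n", "x", "y"]).to_csv(path, index=False)


def load_patterns_csv(path: str | Path, R: float = STUDY_RADIUS, delta: float = 0.0) -> list[PointConfiguration]:
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("pattern_id", sort=False):
        out.append(PointConfiguration(points=grp[["x", "y"]].to_numpy(), R=R, delta=delta, pattern_id=str(pid)))
    return out


def save_patterns_json(configs: Iterable[PointConfiguration], path: str | Path) -> None:
    recs = [
        {
            "pattern_id": c.pattern_id,
            "n": c.n,
            "R": c.R,
            "delta": c.delta,
            "seed": c.seed,
            "points": c.points.tolist(),
        }
        for c in configs
    ]
    Path(path).write_text(json.dumps(recs))


def load_patterns_json(path: str | Path) -> list[PointConfiguration]:
    recs = json.loads(Path(path).read_text())
    return [
        PointConfiguration(
            points=np.asarray(r["points"], dtype=float),
            R=r["R"],
            delta=r.get("delta", 0.0),
            seed=r.get("seed"),
            pattern_id=r["pattern_id"],
        )
        for r in recs
    ]
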