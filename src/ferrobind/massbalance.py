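"""Mass-balance decomposition of titration equivalence points.

A point (X, R) of the diagram that lies inside the triangle spanned by three
mineral vertices is a unique iron-molar mixture of those minerals: the
fractions f solve

    sum f_i = 1,   sum f_i X_i = X,   sum f_i R_i = R,

i.e. barycentric coordinates in the (X, R) plane (the lever rule).  The first
equivalence point is instead checked against the schwertmannite line
R = 2.75 X; the second is decomposed into ferrous hydroxide, green rust and
magnetite fractions, the basis of per-mineral percentage tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equivalence import EquivalencePoints
from .minerals import (
    DEFAULT_CANDIDATES,
    DiagramPoint,
    MineralSpecies,
    default_registry,
    mineral_vertex,
)

__all__ = [
    "MineralFractions",
    "OutOfRegionError",
    "DegenerateGeometryError",
    "schwertmannite_residual",
    "decompose_E2",
    "equal_pair_solve",
    "fraction_table",
]


class OutOfRegionError(ValueError):
    """Diagram point outside the candidate triangle (a fraction < 0)."""


class DegenerateGeometryError(ValueError):
    """Candidate vertices are affinely dependent in the (X, R) plane."""


@dataclass(frozen=True)
class MineralFractions:
    """Iron-molar fractions per mineral, summing to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        for name, f in self.fractions.items():
            if not -1e-9 <= f <= 1.0 + 1e-9:
                raise ValueError(f"fraction {name} = {f} out of [0, 1]")

    def __getitem__(self, name: str) -> float:
        return self.fractions[name]

    def reconstruct(self, registry: dict[str, MineralSpecies] | None = None) -> DiagramPoint:
        """The diagram point implied by the fractions (conservation check)."""
        registry = default_registry() if registry is None else registry
        x = sum(f * mineral_vertex(n, registry).X for n, f in self.fractions.items())
        r = sum(f * mineral_vertex(n, registry).R for n, f in self.fractions.items())
        return DiagramPoint(X=x, R=r)


def schwertmannite_residual(e1_r: float, x: float,
                            registry: dict[str, MineralSpecies] | None = None) -> float:
    """Signed deviation of a first equivalence point from the line R = 2.75 X."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("X must lie in [0, 1]")
    registry = default_registry() if registry is None else registry
    return e1_r - mineral_vertex("schwertmannite", registry).R * x


def decompose_E2(
    point: DiagramPoint,
    candidates: tuple[str, str, str] = DEFAULT_CANDIDATES,
    registry: dict[str, MineralSpecies] | None = None,
    tol: float = 1e-6,
) -> MineralFractions:
    """Barycentric mineral fractions of a second equivalence point.

    Solves the 3x3 linear system of total-iron, ferric-iron and hydroxide
    conservation.  Fractions with |f| < tol are clamped to zero and the rest
    renormalized; any fraction below -tol marks the point as outside the
    candidate region and raises :class:`OutOfRegionError` naming the violated
    constraint.
    """
    registry = default_registry() if registry is None else registry
    vertices = [mineral_vertex(name, registry) for name in candidates]
    a = np.array(
        [[1.0, 1.0, 1.0],
         [v.X for v in vertices],
         [v.R for v in vertices]]
    )
    if abs(np.linalg.det(a)) < 1e-12:
        raise DegenerateGeometryError(
            f"vertices of {candidates} are affinely dependent in the (X, R) plane"
        )
    f = np.linalg.solve(a, np.array([1.0, point.X, point.R]))
    for name, value in zip(candidates, f):
        if value < -tol:
            raise OutOfRegionError(
                f"point (X={point.X:g}, R={point.R:g}) lies outside the "
                f"{'/'.join(candidates)} region: fraction {name} = {value:.6f} < 0"
            )
    f = np.where(np.abs(f) < tol, 0.0, f)
    f = f / f.sum()
    return MineralFractions(dict(zip(candidates, map(float, f))))


def equal_pair_solve(
    x: float,
    pair: tuple[str, str] = ("green_rust", "magnetite"),
    third: str = "ferrous_hydroxide",
    registry: dict[str, MineralSpecies] | None = None,
) -> MineralFractions:
    """Mineral fractions with the two paired species constrained equal.

    With f_pair1 = f_pair2 = g and f_third = 1 - 2g, ferric conservation
    g (X_p1 + X_p2) + (1 - 2g) X_third = X fixes g.  For the green-rust /
    magnetite pair over ferrous hydroxide this gives g = X: e.g. at X = 0.2
    the mixture is 60 % ferrous hydroxide, 20 % green rust, 20 % magnetite.
    """
    if not 0.0 <= x <= 2.0 / 3.0:
        raise ValueError("X must lie in [0, 2/3] for this constraint")
    registry = default_registry() if registry is None else registry
    xp1 = mineral_vertex(pair[0], registry).X
    xp2 = mineral_vertex(pair[1], registry).X
    xt = mineral_vertex(third, registry).X
    if xp1 + xp2 == 0:
        raise ValueError("paired species must carry ferric iron")
    denom = xp1 + xp2 - 2.0 * xt
    if denom == 0:
        raise ValueError("constraint degenerate: pair and third have equal mean X")
    g = (x - xt) / denom
    if not -1e-12 <= g <= 0.5 + 1e-12:
        raise ValueError(
            f"no feasible equal-pair solution at X = {x}: g = {g:.6f} out of [0, 0.5]"
        )
    g = min(max(g, 0.0), 0.5)
    return MineralFractions({third: 1.0 - 2.0 * g, pair[0]: g, pair[1]: g})


def fraction_table(
    runs: list[tuple[float, EquivalencePoints, str]],
    candidates: tuple[str, str, str] = DEFAULT_CANDIDATES,
    registry: dict[str, MineralSpecies] | None = None,
) -> pd.DataFrame:
    """Long-format per-mineral percentage table over (X, label) runs.

    Columns: X, label, species, percent, note.  Percentages are iron-molar
    and sum to 100 per run.  Decomposition failures yield rows with NaN
    percent and the error message in ``note`` instead of aborting.
    """
    registry = default_registry() if registry is None else registry
    records = []
    for x, points, label in runs:
        try:
            fractions = decompose_E2(
                DiagramPoint(X=x, R=points.e2_r), candidates, registry
            )
            for name in candidates:
                records.append(
                    {"X": x, "label": label, "species": name,
                     "percent": 100.0 * fractions[name], "note": ""}
                )
        except (OutOfRegionError, DegenerateGeometryError, ValueError) as exc:
            for name in candidates:
                records.append(
                    {"X": x, "label": label, "species": name,
                     "percent": float("nan"), "note": str(exc)}
                )
    return pd.DataFrame.from_records(
        records, columns=["X", "label", "species", "percent", "note"]
    )
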