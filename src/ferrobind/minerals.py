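"""Stoichiometric registry for the iron minerals of alkaline co-precipitation.

Five minerals span the redox range of the mixed ferric/ferrous system that
forms when NaOH is titrated into an iron sulfate solution: ferrous hydroxide
Fe(OH)2, sulfate green rust Fe(II)4Fe(III)2(OH)12·SO4, magnetite
Fe(II)Fe(III)2O4, goethite FeOOH, and the sulfated ferric oxyhydroxide
schwertmannite FeO(OH)(1-2z)(SO4)z (balanced here per mole of Fe).

Each mineral maps to a vertex of the mass-balance diagram whose axes are

* ``X`` — ferric molar fraction, Fe3+/(Fe2+ + Fe3+), and
* ``R`` — mol of OH- consumed per mol of total iron.

Both coordinates are exact rationals of the stoichiometric coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import yaml

__all__ = [
    "MineralSpecies",
    "DiagramPoint",
    "schwertmannite",
    "default_registry",
    "mineral_vertex",
    "x_ratio",
    "base_rate",
    "registry_to_yaml",
    "registry_from_yaml",
]


@dataclass(frozen=True)
class MineralSpecies:
    """One mineral phase with its per-formula iron and hydroxide counts.

    ``z_sulfate`` is only meaningful for schwertmannite, where the hydroxide
    count per Fe is tied to the sulfate substitution: OH/Fe = 3 - 2*z.
    """

    name: str
    fe2_per_formula: Fraction
    fe3_per_formula: Fraction
    oh_per_formula: Fraction
    z_sulfate: Fraction | None = None

    def __post_init__(self) -> None:
        for attr in ("fe2_per_formula", "fe3_per_formula", "oh_per_formula"):
            value = Fraction(getattr(self, attr))
            object.__setattr__(self, attr, value)
            if value < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0, got {value}")
        if self.fe2_per_formula + self.fe3_per_formula == 0:
            raise ValueError(f"{self.name}: species must contain iron")
        if self.z_sulfate is not None:
            z = Fraction(self.z_sulfate)
            object.__setattr__(self, "z_sulfate", z)
            expected_oh = (3 - 2 * z) * (self.fe2_per_formula + self.fe3_per_formula)
            if self.oh_per_formula != expected_oh:
                raise ValueError(
                    f"{self.name}: OH per formula must equal (3 - 2 z) per Fe for a "
                    f"sulfated ferric oxyhydroxide; expected {expected_oh}, "
                    f"got {self.oh_per_formula}"
                )

    @property
    def fe_total(self) -> Fraction:
        return self.fe2_per_formula + self.fe3_per_formula


@dataclass(frozen=True)
class DiagramPoint:
    """A point of the mass-balance diagram: ferric fraction X, base ratio R."""

    X: float
    R: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.X <= 1.0:
            raise ValueError(f"X must lie in [0, 1], got {self.X}")
        if self.R < 0.0:
            raise ValueError(f"R must be >= 0, got {self.R}")


def schwertmannite(z: Fraction | float = Fraction(1, 8)) -> MineralSpecies:
    """Schwertmannite balanced per mole of Fe: Fe3+ + (3-2z) OH- + z SO4^2-.

    The default sulfate substitution z = 1/8 gives OH/Fe = 2.75, the slope of
    the first-equivalence-point line R1 = 2.75 X.
    """
    z = Fraction(z).limit_denominator(10**6)
    return MineralSpecies(
        name="schwertmannite",
        fe2_per_formula=Fraction(0),
        fe3_per_formula=Fraction(1),
        oh_per_formula=3 - 2 * z,
        z_sulfate=z,
    )


def default_registry(z_sulfate: Fraction | float = Fraction(1, 8)) -> dict[str, MineralSpecies]:
    """The five-mineral registry keyed by species name.

    Goethite is present for diagram completeness; the default second
    equivalence-point decomposition uses only ferrous hydroxide, green rust
    and magnetite (the 0 <= X <= 2/3 regime).
    """
    species = [
        MineralSpecies("ferrous_hydroxide", Fraction(1), Fraction(0), Fraction(2)),
        MineralSpecies("green_rust", Fraction(4), Fraction(2), Fraction(12)),
        MineralSpecies("magnetite", Fraction(1), Fraction(2), Fraction(8)),
        MineralSpecies("goethite", Fraction(0), Fraction(1), Fraction(3)),
        schwertmannite(z_sulfate),
    ]
    return {s.name: s for s in species}


DEFAULT_CANDIDATES = ("ferrous_hydroxide", "green_rust", "magnetite")


def mineral_vertex(species: MineralSpecies | str,
                   registry: dict[str, MineralSpecies] | None = None) -> DiagramPoint:
    """Diagram vertex of a mineral: X = fe3/(fe2+fe3), R = OH per mole Fe."""
    if isinstance(species, str):
        registry = default_registry() if registry is None else registry
        try:
            species = registry[species]
        except KeyError:
            raise ValueError(
                f"unknown species {species!r}; known: {sorted(registry)}"
            ) from None
    x = species.fe3_per_formula / species.fe_total
    r = species.oh_per_formula / species.fe_total
    return DiagramPoint(X=float(x), R=float(r))


def x_ratio(fe3_conc: float, fe2_conc: float) -> float:
    """Ferric molar fraction X = [Fe3+]/([Fe3+] + [Fe2+]).

    Concentrations may be in any common unit (the ratio is scale invariant).
    """
    if fe3_conc < 0 or fe2_conc < 0:
        raise ValueError("concentrations must be >= 0")
    total = fe3_conc + fe2_conc
    if total == 0:
        raise ValueError("at least one iron concentration must be positive")
    return fe3_conc / total


def base_rate(flow_ul_per_min: float, base_conc_M: float,
              solution_volume_mL: float, fe_total_conc_mM: float) -> float:
    """Effective titration rate in R units per minute.

    rate = (flow * [NaOH]) / (V_solution * [Fe]_total); e.g. 50 uL/min of
    1 M NaOH into 20 mL at 50 mM total iron gives 0.05 R/min.
    """
    args = (flow_ul_per_min, base_conc_M, solution_volume_mL, fe_total_conc_mM)
    if any(a <= 0 for a in args):
        raise ValueError("all inputs must be positive")
    mol_base_per_min = flow_ul_per_min * 1e-6 * base_conc_M
    mol_fe = solution_volume_mL * 1e-3 * fe_total_conc_mM * 1e-3
    return mol_base_per_min / mol_fe


# --- registry serialization ------------------------------------------------

def _species_to_dict(s: MineralSpecies) -> dict:
    d = {
        "fe2_per_formula": str(s.fe2_per_formula),
        "fe3_per_formula": str(s.fe3_per_formula),
        "oh_per_formula": str(s.oh_per_formula),
    }
    if s.z_sulfate is not None:
        d["z_sulfate"] = str(s.z_sulfate)
    return d


def _species_from_dict(name: str, d: dict) -> MineralSpecies:
    return MineralSpecies(
        name=name,
        fe2_per_formula=Fraction(str(d["fe2_per_formula"])),
        fe3_per_formula=Fraction(str(d["fe3_per_formula"])),
        oh_per_formula=Fraction(str(d["oh_per_formula"])),
        z_sulfate=Fraction(str(d["z_sulfate"])) if "z_sulfate" in d else None,
    )


def registry_to_yaml(registry: dict[str, MineralSpecies], path: str | Path) -> None:
    payload = {name: _species_to_dict(s) for name, s in registry.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def registry_from_yaml(path: str | Path) -> dict[str, MineralSpecies]:
    payload = yaml.safe_load(Path(path).read_text())
    return {name: _species_from_dict(name, d) for name, d in payload.items()}
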