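"""Synthetic pH-titration curves for alkaline iron co-precipitation.

A slow constant feed of NaOH into a mixed Fe2+/Fe3+ sulfate solution produces
a staircase pH record: a low plateau while ferric oxyhydroxide precipitates,
a step at the first equivalence point E1, a middle plateau while the mixed
ferrous/ferric minerals form, a second step at E2 and a final high plateau of
excess base.  The generator models this morphology as a sum of two logistic
steps between three plateau levels, with the steps centred on the
stoichiometric equivalence points:

* E1 = (OH/Fe of schwertmannite) * X, the ferric precipitation line, and
* E2 = sum_i f_i R_i over the end-point mineral mixture f.

A "protein" additive mode reproduces the empirical signature of a
ferrous-sequestering additive: for ferrous-rich runs (X below a threshold)
the middle plateau forms earlier (E2 shifted to lower R) and at lower pH.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from .minerals import (
    DEFAULT_CANDIDATES,
    MineralSpecies,
    default_registry,
    mineral_vertex,
)

__all__ = [
    "TitrationCurve",
    "ProteinDeltas",
    "SynthParams",
    "CurveParseError",
    "default_end_fractions",
    "theoretical_breakpoints",
    "simulate_titration",
    "write_curve",
    "read_curve",
]


class CurveParseError(ValueError):
    """Malformed titration-curve file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


@dataclass
class TitrationCurve:
    """Sampled (time, R, pH) titration record with run metadata.

    ``meta`` carries at least X, fe_total_mM, rate_per_min, additive_label and
    seed; the generator also records its ground-truth breakpoints.  ``eh_mv``
    is an optional redox channel preserved through file round trips.
    """

    time_s: np.ndarray
    r: np.ndarray
    ph: np.ndarray
    meta: dict
    eh_mv: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if not (len(self.time_s) == len(self.r) == len(self.ph)):
            raise ValueError("time, R and pH must have equal length")
        if np.any(np.diff(self.r) < 0):
            raise ValueError("R must be nondecreasing")
        if np.any((self.ph < 0) | (self.ph > 14)):
            raise ValueError("pH out of [0, 14]")
        if self.eh_mv is not None:
            self.eh_mv = np.asarray(self.eh_mv, dtype=float)
            if len(self.eh_mv) != len(self.r):
                raise ValueError("Eh channel length mismatch")

    def __len__(self) -> int:
        return len(self.r)


@dataclass(frozen=True)
class ProteinDeltas:
    """Additive effect: middle-plateau pH drop and E2 advance (R units)."""

    dph_plateau2: float = 0.4
    dr_e2: float = 0.15


@dataclass
class SynthParams:
    """Generator knobs for the three-plateau curve.

    plateau_ph     -- the three plateau pH levels (must increase)
    step_sharpness -- logistic rate in 1/R units; larger = sharper steps
    noise_sd       -- Gaussian pH-meter noise, pH units
    end_fractions  -- iron-molar mineral fractions at E2 (None = X-dependent
                      default mixture)
    protein_deltas -- additive effect sizes, applied when X <= protein_x_max
    cadence_s      -- logger sampling interval
    rate_per_min   -- base feed rate in R/min
    r_max          -- end of titration (None = E2 + 1)
    """

    plateau_ph: tuple[float, float, float] = (2.5, 7.0, 12.5)
    step_sharpness: float = 20.0
    noise_sd: float = 0.02
    end_fractions: dict[str, float] | None = None
    protein_deltas: ProteinDeltas = field(default_factory=ProteinDeltas)
    protein_x_max: float = 0.4
    cadence_s: float = 3.0
    rate_per_min: float = 0.05
    r_max: float | None = None
    fe_total_mM: float = 50.0

    def __post_init__(self) -> None:
        p1, p2, p3 = self.plateau_ph
        if not p1 < p2 < p3:
            raise ValueError("plateau pH levels must strictly increase")
        if self.step_sharpness <= 0:
            raise ValueError("step_sharpness must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cadence_s <= 0 or self.rate_per_min <= 0:
            raise ValueError("cadence and rate must be positive")


def default_end_fractions(x: float) -> dict[str, float]:
    """Feasible default mineral mixture at the second equivalence point.

    For X <= 0.5 the ferric iron is split equally between green rust and
    magnetite (each takes fraction X of the iron) with ferrous hydroxide
    carrying the excess ferrous iron; for 0.5 < X <= 2/3 ferrous hydroxide is
    exhausted and the green-rust/magnetite balance follows from ferric
    conservation.
    """
    if not 0.0 <= x <= 2.0 / 3.0:
        raise ValueError("default mixture covers 0 <= X <= 2/3 only")
    if x <= 0.5:
        return {
            "ferrous_hydroxide": 1.0 - 2.0 * x,
            "green_rust": x,
            "magnetite": x,
        }
    f_m = 3.0 * x - 1.0
    return {"ferrous_hydroxide": 0.0, "green_rust": 1.0 - f_m, "magnetite": f_m}


def theoretical_breakpoints(
    x: float,
    end_fractions: dict[str, float] | None = None,
    registry: dict[str, MineralSpecies] | None = None,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Stoichiometric equivalence points (E1_R, E2_R) for ferric fraction X.

    E1 is base consumed precipitating the ferric iron as schwertmannite;
    E2 is the fraction-weighted sum of the end-mixture vertices.  The mixture
    must conserve ferric iron: sum f_i X_i == X (checked to ``tol``).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("X must lie in [0, 1]")
    registry = default_registry() if registry is None else registry
    fractions = default_end_fractions(x) if end_fractions is None else end_fractions
    total = sum(fractions.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"fractions must sum to 1, got {total}")
    implied_x = 0.0
    e2 = 0.0
    for name, f in fractions.items():
        vertex = mineral_vertex(name, registry)
        implied_x += f * vertex.X
        e2 += f * vertex.R
    if abs(implied_x - x) > max(tol, 1e-9):
        raise ValueError(
            f"end fractions imply X = {implied_x:.6f}, inconsistent with X = {x}"
        )
    e1 = mineral_vertex("schwertmannite", registry).R * x
    return e1, e2


def simulate_titration(
    x: float,
    params: SynthParams | None = None,
    seed: int = 0,
    protein: bool = False,
) -> TitrationCurve:
    """Generate one noisy three-plateau titration curve.

    Deterministic for a fixed seed.  With ``protein=True`` and
    X <= params.protein_x_max, the middle plateau is lowered by
    ``dph_plateau2`` and E2 advanced by ``dr_e2``.
    """
    params = SynthParams() if params is None else params
    fractions = params.end_fractions or default_end_fractions(x)
    e1, e2 = theoretical_breakpoints(x, fractions)

    p1, p2, p3 = params.plateau_ph
    affected = protein and x <= params.protein_x_max
    if affected:
        p2 = p2 - params.protein_deltas.dph_plateau2
        e2 = e2 - params.protein_deltas.dr_e2

    dr = params.rate_per_min * params.cadence_s / 60.0
    r_max = params.r_max if params.r_max is not None else e2 + 1.0
    n = int(round(r_max / dr)) + 1
    r = np.arange(n) * dr
    time_s = np.arange(n) * params.cadence_s

    s = params.step_sharpness
    ph = p1 + (p2 - p1) * expit(s * (r - e1)) + (p3 - p2) * expit(s * (r - e2))
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        ph = ph + rng.normal(0.0, params.noise_sd, size=n)
    ph = np.clip(ph, 0.0, 14.0)

    meta = {
        "X": x,
        "fe_total_mM": params.fe_total_mM,
        "rate_per_min": params.rate_per_min,
        "cadence_s": params.cadence_s,
        "additive_label": "protein" if protein else "none",
        "protein_effect_applied": bool(affected),
        "seed": int(seed),
        "noise_sd": params.noise_sd,
        "end_fractions": dict(fractions),
        "e1_r_true": e1,
        "e2_r_true": e2,
    }
    return TitrationCurve(time_s=time_s, r=r, ph=ph, meta=meta)


# --- delimited-text I/O ----------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_curve(curve: TitrationCurve, path: str | Path) -> None:
    """Write a curve as CSV with the metadata as a JSON header comment."""
    path = Path(path)
    cols = ["time_s", "R", "pH"] + (["Eh_mV"] if curve.eh_mv is not None else [])
    with path.open("w") as fh:
        fh.write("# meta: " + json.dumps(curve.meta, sort_keys=True) + "\n")
        fh.write(",".join(cols) + "\n")
        columns = [curve.time_s, curve.r, curve.ph]
        if curve.eh_mv is not None:
            columns.append(curve.eh_mv)
        for row in zip(*columns):
            fh.write(",".join(_FLOAT_FMT % v for v in row) + "\n")


def read_curve(path: str | Path) -> TitrationCurve:
    """Read a curve written by :func:`write_curve` (or hand-made CSV).

    Requires columns time_s, R, pH; an Eh_mV column is preserved.  Reports
    the 1-based line number of any malformed row.
    """
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("meta:"):
                    try:
                        meta = json.loads(body[len("meta:"):])
                    except json.JSONDecodeError:
                        raise CurveParseError("unreadable metadata JSON", lineno)
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                for required in ("time_s", "R", "pH"):
                    if required not in header:
                        raise CurveParseError(f"missing column {required!r}", lineno)
                continue
            parts = line.split(",")
            if len(parts) != len(header):
                raise CurveParseError(
                    f"expected {len(header)} fields, got {len(parts)}", lineno
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise CurveParseError("non-numeric field", lineno)
    if header is None or not rows:
        raise CurveParseError("no data rows found")
    data = np.asarray(rows)
    idx = {name: i for i, name in enumerate(header)}
    r = data[:, idx["R"]]
    if np.any(np.diff(r) < 0):
        first_bad = int(np.argmax(np.diff(r) < 0)) + 1
        raise CurveParseError("non-monotone R", first_bad + 2)
    eh = data[:, idx["Eh_mV"]] if "Eh_mV" in idx else None
    return TitrationCurve(
        time_s=data[:, idx["time_s"]], r=r, ph=data[:, idx["pH"]],
        meta=meta, eh_mv=eh,
    )
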