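"""Chemical-shift-perturbation (CSP) analysis for the C20Mms6 peptide.

The 20-residue acidic C-terminal peptide of Mms6
(Ac-KSRDIESAQSDEEVELRDAL-Am) binds divalent metals through its carboxylate
side chains.  Adding metal to the apo peptide perturbs proton chemical
shifts; per residue we track the amide-proton shift change and the mean
side-chain shift change, rank residues by perturbation magnitude to map the
binding hotspot (the DEEVE cluster, residues 11-15), and measure deviation
of Halpha shifts from random-coil reference values as a disorder check.

Because paramagnetic iron broadens nearby signals (PRE), atoms can vanish
from the metal-bound table; means are taken only over atoms observed in both
conditions and the number of lost atoms is reported.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PEPTIDE_SEQUENCE",
    "ShiftSet",
    "load_random_coil",
    "reference_shiftset",
    "delta_shifts",
    "random_coil_deviation",
    "rank_hotspots",
    "synth_shift_tables",
    "write_shifts",
    "read_shifts",
]

#: the C20Mms6 peptide, N-acetylated / C-amidated (caps not indexed)
PEPTIDE_SEQUENCE = "KSRDIESAQSDEEVELRDAL"

#: default binding hotspot: the acidic DEEVE-cluster carboxylate residues
DEEVE_HOTSPOT = (11, 12, 13, 15)

_SIDECHAIN_EXCLUDED = {"HN", "HA"}


@dataclass
class ShiftSet:
    """Assigned 1H shifts for one sample condition.

    ``entries`` columns: residue (1-based), code (one-letter), atom
    (HN/HA/HB/HG), ppm.  ``condition`` records metal, equivalents and pH.
    """

    entries: pd.DataFrame
    condition: dict = field(default_factory=dict)
    sequence: str = PEPTIDE_SEQUENCE

    def __post_init__(self) -> None:
        required = {"residue", "code", "atom", "ppm"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"entries missing columns {sorted(missing)}")
        e = self.entries
        bad = e[(e.residue < 1) | (e.residue > len(self.sequence))]
        if len(bad):
            raise ValueError(f"residue index out of 1..{len(self.sequence)}")
        for _, row in e.iterrows():
            if self.sequence[int(row.residue) - 1] != row.code:
                raise ValueError(
                    f"residue {int(row.residue)} code {row.code!r} does not match "
                    f"sequence {self.sequence[int(row.residue) - 1]!r}"
                )
        if e.duplicated(["residue", "atom"]).any():
            raise ValueError("duplicate (residue, atom) assignment")


def load_random_coil() -> pd.DataFrame:
    """Packaged random-coil 1H reference shifts (standard literature values).

    Columns code, atom, ppm; users may substitute any table with the same
    schema in :func:`random_coil_deviation` and :func:`reference_shiftset`.
    """
    with importlib.resources.files("ferrobind.data").joinpath(
            "random_coil_1h.csv").open() as fh:
        return pd.read_csv(fh)


def reference_shiftset(reference: pd.DataFrame | None = None,
                       condition: dict | None = None,
                       sequence: str = PEPTIDE_SEQUENCE) -> ShiftSet:
    """Random-coil ShiftSet for the peptide (idealized unstructured apo)."""
    reference = load_random_coil() if reference is None else reference
    lookup = {(row.code, row.atom): row.ppm for row in reference.itertuples()}
    rows = []
    for i, code in enumerate(sequence, start=1):
        for atom in ("HN", "HA", "HB", "HG"):
            if (code, atom) in lookup:
                rows.append({"residue": i, "code": code, "atom": atom,
                             "ppm": lookup[(code, atom)]})
    cond = condition or {"metal": "none", "equivalents": 0.0, "ph": 5.66}
    return ShiftSet(entries=pd.DataFrame(rows), condition=cond, sequence=sequence)


def delta_shifts(apo: ShiftSet, holo: ShiftSet,
                 ph_tol: float = 0.05) -> pd.DataFrame:
    """Per-residue perturbation table, holo minus apo.

    Columns: residue, code, amide_delta (HN; NaN if unobserved in either
    condition), mean_sidechain_delta (mean over HB/HG protons present in both
    sets; NaN if none), n_sidechain_atoms (atoms averaged), n_missing (atoms
    observed in only one condition and hence excluded, e.g. lost to PRE
    broadening).

    The two conditions must share the peptide sequence and be at the same pH
    within ``ph_tol`` — metal addition acidifies the sample, and uncontrolled
    pH drift masquerades as binding shifts.
    """
    if apo.sequence != holo.sequence:
        raise ValueError("sequence mismatch between conditions")
    ph_a = apo.condition.get("ph")
    ph_h = holo.condition.get("ph")
    if ph_a is not None and ph_h is not None and abs(ph_a - ph_h) > ph_tol:
        raise ValueError(
            f"pH mismatch ({ph_a} vs {ph_h} > tol {ph_tol}): shift changes are "
            "only attributable to metal binding at matched pH"
        )
    merged = apo.entries.merge(
        holo.entries, on=["residue", "code", "atom"], how="outer",
        suffixes=("_apo", "_holo"),
    )
    merged["delta"] = merged.ppm_holo - merged.ppm_apo
    rows = []
    for i, code in enumerate(apo.sequence, start=1):
        sub = merged[merged.residue == i]
        amide = sub[sub.atom == "HN"]["delta"]
        amide_delta = float(amide.iloc[0]) if len(amide) else float("nan")
        side = sub[~sub.atom.isin(_SIDECHAIN_EXCLUDED)]
        shared = side.delta.dropna()
        rows.append({
            "residue": i,
            "code": code,
            "amide_delta": amide_delta,
            "mean_sidechain_delta": float(shared.mean()) if len(shared) else float("nan"),
            "n_sidechain_atoms": int(len(shared)),
            "n_missing": int(sub.delta.isna().sum()),
        })
    return pd.DataFrame(rows)


def random_coil_deviation(
    shifts: ShiftSet,
    reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Halpha deviation from random-coil values, per residue plus summary.

    Returns (table with residue/code/deviation, summary with max_abs,
    mean_abs and sd of the absolute deviations).  A residue whose type is
    missing from the reference raises, naming the residue.
    """
    reference = load_random_coil() if reference is None else reference
    lookup = {(row.code, row.atom): row.ppm for row in reference.itertuples()}
    ha = shifts.entries[shifts.entries.atom == "HA"]
    rows = []
    for row in ha.itertuples():
        key = (row.code, "HA")
        if key not in lookup:
            raise ValueError(
                f"no random-coil HA reference for residue {int(row.residue)} "
                f"({row.code})"
            )
        rows.append({"residue": int(row.residue), "code": row.code,
                     "deviation": row.ppm - lookup[key]})
    table = pd.DataFrame(rows)
    devs = np.abs(table.deviation.to_numpy())
    summary = {
        "max_abs": float(devs.max()) if len(devs) else float("nan"),
        "mean_abs": float(devs.mean()) if len(devs) else float("nan"),
        "sd": float(devs.std(ddof=1)) if len(devs) > 1 else float("nan"),
    }
    return table, summary


def rank_hotspots(table: pd.DataFrame, k: int = 4) -> tuple[list[int], list[tuple[int, int]]]:
    """Residues ranked by perturbation; contiguous clusters among the top k.

    Primary key |mean_sidechain_delta| (NaN treated as 0), ties broken by
    |amide_delta| then residue index.  Clusters are maximal runs of adjacent
    residue indices within the top-k set; an all-zero table yields stable
    index order and no clusters.
    """
    if table.empty:
        raise ValueError("empty perturbation table")
    t = table.copy()
    t["side_mag"] = t.mean_sidechain_delta.abs().fillna(0.0)
    t["amide_mag"] = t.amide_delta.abs().fillna(0.0)
    t = t.sort_values(["side_mag", "amide_mag", "residue"],
                      ascending=[False, False, True], kind="mergesort")
    ranked = [int(r) for r in t.residue]
    top = sorted(ranked[:k]) if np.any(t.side_mag.to_numpy() > 0) or \
        np.any(t.amide_mag.to_numpy() > 0) else []
    clusters: list[tuple[int, int]] = []
    for res in top:
        if clusters and res == clusters[-1][1] + 1:
            clusters[-1] = (clusters[-1][0], res)
        else:
            clusters.append((res, res))
    return ranked, clusters


def synth_shift_tables(
    hotspot_residues: tuple[int, ...] = DEEVE_HOTSPOT,
    effect_size: float | dict[int, float] = 0.05,
    noise_sd: float = 0.005,
    seed: int = 0,
    secondary_residues: dict[int, float] | None = None,
    amide_factor: float = 0.5,
    metal: str = "Fe2",
    dropout: float = 0.0,
) -> tuple[ShiftSet, ShiftSet]:
    """Synthetic apo/holo shift-table pair with a known perturbation hotspot.

    The apo table is the random-coil reference plus Gaussian jitter of sd
    ``noise_sd``; the holo table adds ``effect_size`` ppm to the side-chain
    protons of each hotspot residue (``amide_factor`` of it to the HN) plus
    fresh noise.  ``secondary_residues`` maps extra residues to a relative
    effect (e.g. {6: 0.4} for a weak secondary site).  ``dropout`` removes
    that fraction of holo atoms at random, emulating PRE signal loss.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n_res = len(PEPTIDE_SEQUENCE)
    for res in hotspot_residues:
        if not 1 <= res <= n_res:
            raise ValueError(f"hotspot residue {res} out of 1..{n_res}")
    if not np.isfinite(np.atleast_1d(
            list(effect_size.values()) if isinstance(effect_size, dict)
            else [effect_size])).all():
        raise ValueError("effect sizes must be finite")

    effects: dict[int, float] = {}
    if isinstance(effect_size, dict):
        effects.update(effect_size)
    else:
        effects.update({res: effect_size for res in hotspot_residues})
    base_effect = max(abs(v) for v in effects.values()) if effects else 0.0
    for res, rel in (secondary_residues or {}).items():
        if not 1 <= res <= n_res:
            raise ValueError(f"secondary residue {res} out of 1..{n_res}")
        effects.setdefault(res, rel * base_effect)

    apo = reference_shiftset(
        condition={"metal": "none", "equivalents": 0.0, "ph": 5.66})
    apo_entries = apo.entries.copy()
    apo_entries["ppm"] = apo_entries.ppm + rng.normal(0.0, noise_sd,
                                                      len(apo_entries))
    holo_entries = apo_entries.copy()
    for res, eff in effects.items():
        mask_side = (holo_entries.residue == res) & \
            (~holo_entries.atom.isin(_SIDECHAIN_EXCLUDED))
        holo_entries.loc[mask_side, "ppm"] += eff
        mask_hn = (holo_entries.residue == res) & (holo_entries.atom == "HN")
        holo_entries.loc[mask_hn, "ppm"] += amide_factor * eff
    holo_entries["ppm"] = holo_entries.ppm + rng.normal(0.0, noise_sd,
                                                        len(holo_entries))
    if dropout > 0:
        keep = rng.random(len(holo_entries)) >= dropout
        holo_entries = holo_entries[keep].reset_index(drop=True)

    apo_set = ShiftSet(entries=apo_entries,
                       condition={"metal": "none", "equivalents": 0.0, "ph": 5.66})
    holo_set = ShiftSet(entries=holo_entries,
                        condition={"metal": metal, "equivalents": 3.0, "ph": 5.66})
    return apo_set, holo_set


# --- delimited-text I/O ----------------------------------------------------

def write_shifts(shifts: ShiftSet, path: str | Path) -> None:
    """TSV with header residue,code,atom,ppm; condition as a JSON sidecar."""
    path = Path(path)
    shifts.entries.to_csv(path, sep="\t", index=False,
                          columns=["residue", "code", "atom", "ppm"],
                          float_format="%.6g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(shifts.condition, sort_keys=True) + "\n")


def read_shifts(path: str | Path) -> ShiftSet:
    path = Path(path)
    entries = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    condition = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ShiftSet(entries=entries, condition=condition)
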