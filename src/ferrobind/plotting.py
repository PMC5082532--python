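"""Quick-look plots for titration curves, free-energy profiles and CSP maps."""

from __future__ import annotations

import numpy as np

from .equivalence import EquivalencePoints
from .titration import TitrationCurve
from .trajanalysis import FreeEnergyProfile


def plot_titration(curve: TitrationCurve, points: EquivalencePoints | None = None,
                   ax=None):
    """pH vs R, optionally with detected equivalence points marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.r, curve.ph, lw=0.8,
            label=curve.meta.get("additive_label", "run"))
    if points is not None:
        ax.axvline(points.e1_r, color="tab:orange", ls="--", label="E1")
        ax.axvline(points.e2_r, color="tab:red", ls="--", label="E2")
        ax.plot([points.estar_r], [points.ph_at_estar], "k*", ms=10, label="E*")
    ax.set_xlabel("R (mol NaOH / mol Fe)")
    ax.set_ylabel("pH")
    ax.legend()
    return ax


def plot_pmf(profile: FreeEnergyProfile, ax=None):
    """Free-energy profile A(r); the line breaks where g(r) = 0."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.r, profile.a, lw=1.0)
    if profile.well is not None:
        ax.plot(*profile.well, "rv", label=f"well {profile.well[1]:.1f} kJ/mol")
        ax.legend()
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("r (Å)")
    ax.set_ylabel("A(r) (kJ/mol)")
    return ax


def plot_csp(table, ax=None):
    """Per-residue amide and mean side-chain shift changes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    width = 0.4
    res = table.residue.to_numpy()
    ax.bar(res - width / 2, np.nan_to_num(table.amide_delta), width,
           label="amide HN")
    ax.bar(res + width / 2, np.nan_to_num(table.mean_sidechain_delta), width,
           label="mean side chain")
    ax.set_xlabel("residue")
    ax.set_ylabel("Δδ (ppm)")
    ax.legend()
    return ax
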