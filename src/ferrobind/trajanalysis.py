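"""Ion-trajectory statistics: binding classification, RDF and free energy.

A frame is classified *bound* when the ion lies within a cutoff (3 A by
default, closed interval) of at least one oxygen site, the standard
geometric criterion for inner-sphere metal-oxygen contact.  From the pooled
ion-oxygen distances the radial distribution function g(r) is built with
spherical-shell volume normalization and scaled so its long-range tail
averages to 1; Boltzmann inversion

    A(r) = -R T ln g(r)

then gives the free-energy profile, whose deepest minimum is the binding
well and whose subsequent maximum sets the desorption barrier
|depth| + barrier height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import GAS_R_KJ
from .mcsim import IonTrajectory

__all__ = [
    "BindingRecords",
    "RadialDistribution",
    "FreeEnergyProfile",
    "binding_series",
    "site_occupancy",
    "co_binding",
    "rdf",
    "free_energy",
    "well_and_barrier",
    "per_site_profiles",
]


def _site_distances(traj: IonTrajectory, periodic: bool = True) -> np.ndarray:
    """(n_frames, n_sites) ion-site distances, minimum image if periodic."""
    delta = traj.frames[:, None, :] - traj.site_positions[None, :, :]
    if periodic:
        box = traj.box_edge
        delta -= box * np.round(delta / box)
    return np.sqrt((delta ** 2).sum(axis=2))


@dataclass
class BindingRecords:
    """Per-frame binding classification against every site."""

    site_ids: tuple[str, ...]
    min_dist: np.ndarray          # (n_frames, n_sites)
    cutoff: float

    def __post_init__(self) -> None:
        if self.min_dist.ndim != 2:
            raise ValueError("min_dist must be (n_frames, n_sites)")

    @property
    def site_bound(self) -> np.ndarray:
        """(n_frames, n_sites) boolean: site within cutoff (closed interval)."""
        return self.min_dist <= self.cutoff

    @property
    def bound_any(self) -> np.ndarray:
        return self.site_bound.any(axis=1)

    @property
    def bound_fraction(self) -> float:
        return float(self.bound_any.mean())

    def bound_sites(self, frame: int) -> set[str]:
        mask = self.site_bound[frame]
        return {sid for sid, m in zip(self.site_ids, mask) if m}


def binding_series(traj: IonTrajectory, cutoff: float = 3.0,
                   periodic: bool = True) -> BindingRecords:
    """Classify every frame of a trajectory at the given contact cutoff."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return BindingRecords(
        site_ids=traj.site_ids,
        min_dist=_site_distances(traj, periodic=periodic),
        cutoff=cutoff,
    )


def site_occupancy(
    records: BindingRecords,
    thresholds: tuple[float, float] = (0.4, 0.15),
) -> dict[str, tuple[float, str]]:
    """Per-site occupancy among bound frames, with a high/medium/low label.

    occupancy(site) = P(site within cutoff | some site within cutoff).  With
    no bound frames at all, every occupancy is 0 ('none').
    """
    hi, med = thresholds
    bound = records.bound_any
    n_bound = int(bound.sum())
    out: dict[str, tuple[float, str]] = {}
    for j, sid in enumerate(records.site_ids):
        if n_bound == 0:
            out[sid] = (0.0, "none")
            continue
        occ = float((records.site_bound[bound, j]).mean())
        label = "high" if occ >= hi else ("medium" if occ >= med else "low")
        out[sid] = (occ, label)
    return out


def co_binding(records: BindingRecords, site_a: str, site_b: str) -> float | None:
    """Conditional co-binding probability P(site_b bound | site_a bound).

    Returns None (undefined, not zero) when site_a is never bound.
    """
    for sid in (site_a, site_b):
        if sid not in records.site_ids:
            raise ValueError(f"unknown site id {sid!r}")
    ia = records.site_ids.index(site_a)
    ib = records.site_ids.index(site_b)
    a = records.site_bound[:, ia]
    n_a = int(a.sum())
    if n_a == 0:
        return None
    joint = int((a & records.site_bound[:, ib]).sum())
    return joint / n_a


@dataclass
class RadialDistribution:
    """Tail-normalized radial distribution of pooled ion-site distances."""

    r: np.ndarray               # bin centres, A
    g: np.ndarray
    counts: np.ndarray          # raw per-bin pair counts
    bin_width: float
    r_max: float
    tail_window: float
    n_frames: int
    n_sites: int


def _histogram_rdf(distances: np.ndarray, bin_width: float, r_max: float,
                   tail_window: float) -> RadialDistribution:
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g_raw = counts / shell
    tail = centres >= r_max - tail_window
    tail_mean = g_raw[tail].mean() if np.any(counts[tail]) else 0.0
    if tail_mean == 0.0:
        raise ValueError("no counts in the tail window; cannot normalize")
    return RadialDistribution(
        r=centres, g=g_raw / tail_mean, counts=counts,
        bin_width=bin_width, r_max=r_max, tail_window=tail_window,
        n_frames=0, n_sites=0,
    )


def rdf(traj: IonTrajectory, bin_width: float = 0.05,
        r_max: float | None = None, tail_window: float = 3.0,
        periodic: bool = True) -> RadialDistribution:
    """RDF of the ion against all sites, pooled over frames.

    Each bin count is divided by its spherical-shell volume, then the whole
    profile is scaled so that the mean over the tail window
    [r_max - tail_window, r_max] is 1 (g converges to unity at large
    separations).  ``r_max`` defaults to half the box edge and may not
    exceed it (minimum-image distances are only complete up to there).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    half_box = traj.box_edge / 2.0
    r_max = half_box if r_max is None else r_max
    if r_max > half_box + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half box edge {half_box}")
    d = _site_distances(traj, periodic=periodic)
    out = _histogram_rdf(d.ravel(), bin_width, r_max, tail_window)
    out.n_frames = len(traj)
    out.n_sites = d.shape[1]
    return out


@dataclass
class FreeEnergyProfile:
    """A(r) = -RT ln g(r); NaN marks bins where g = 0 (A undefined there)."""

    r: np.ndarray
    g: np.ndarray
    a: np.ndarray               # kJ/mol, NaN where g == 0
    temperature: float
    gas_r: float = GAS_R_KJ
    counts: np.ndarray | None = None               # per-bin pair counts, if known
    well: tuple[float, float] | None = None        # (r_min, depth)
    barrier: tuple[float, float] | None = None     # (r_barrier, height)
    desorption_barrier: float | None = None
    has_binding_well: bool | None = None


def free_energy(dist: RadialDistribution | tuple[np.ndarray, np.ndarray],
                temperature: float = 300.0) -> FreeEnergyProfile:
    """Boltzmann inversion of a tail-normalized g(r)."""
    counts = None
    if isinstance(dist, RadialDistribution):
        r, g = dist.r, dist.g
        counts = dist.counts
    else:
        r, g = dist
        r = np.asarray(r, dtype=float)
        g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("g(r) must be nonnegative")
    a = np.full_like(g, np.nan, dtype=float)
    mask = g > 0
    a[mask] = -GAS_R_KJ * temperature * np.log(g[mask])
    return FreeEnergyProfile(r=r, g=g, a=a, temperature=temperature,
                             counts=counts)


def well_and_barrier(profile: FreeEnergyProfile,
                     min_counts: int = 5) -> FreeEnergyProfile:
    """Annotate the deepest binding well and the desorption barrier.

    The well is the global minimum of A (required < 0 for a binding well);
    the barrier is the highest finite maximum between the well and the first
    return of A to the tail level (A >= 0); the total desorption barrier is
    |depth| + max(barrier height, 0).  Without a negative minimum the profile
    is flagged ``has_binding_well=False`` rather than raising.

    For histogram-derived profiles, bins holding fewer than ``min_counts``
    pair counts are ineligible as the well: a near-empty small-radius shell
    has Poisson relative error on g(r) of order 1 and would otherwise yield
    spurious deep minima.
    """
    a = profile.a
    if profile.counts is not None:
        a = np.where(profile.counts >= min_counts, a, np.nan)
    finite = np.isfinite(a)
    if not np.any(finite):
        return replace(profile, has_binding_well=False)
    idx_min = int(np.nanargmin(a))
    depth = float(a[idx_min])
    if depth >= 0:
        return replace(profile, has_binding_well=False)
    r_min = float(profile.r[idx_min])

    # first crossing back to tail level (A >= 0) beyond the well
    idx_cross = len(a)
    for j in range(idx_min + 1, len(a)):
        if np.isfinite(a[j]) and a[j] >= 0:
            idx_cross = j
            break
    segment = a[idx_min + 1: idx_cross + 1]
    seg_r = profile.r[idx_min + 1: idx_cross + 1]
    height = 0.0
    r_barrier = float("nan")
    if segment.size and np.any(np.isfinite(segment)):
        k = int(np.nanargmax(segment))
        if np.isfinite(segment[k]) and segment[k] > 0:
            height = float(segment[k])
            r_barrier = float(seg_r[k])
    desorption = abs(depth) + max(height, 0.0)
    return replace(
        profile,
        well=(r_min, depth),
        barrier=(r_barrier, height) if height > 0 else None,
        desorption_barrier=desorption,
        has_binding_well=True,
    )


def per_site_profiles(
    traj: IonTrajectory,
    bin_width: float = 0.05,
    r_max: float | None = None,
    tail_window: float = 3.0,
    temperature: float = 300.0,
    periodic: bool = True,
) -> dict[str, FreeEnergyProfile | None]:
    """Annotated free-energy profile per individual site.

    A site whose distance record never enters [0, r_max] (no counts even in
    the tail) maps to None (flagged empty) rather than a bogus profile.
    """
    half_box = traj.box_edge / 2.0
    r_max = half_box if r_max is None else r_max
    if r_max > half_box + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half box edge {half_box}")
    d = _site_distances(traj, periodic=periodic)
    out: dict[str, FreeEnergyProfile | None] = {}
    for j, sid in enumerate(traj.site_ids):
        try:
            dist = _histogram_rdf(d[:, j], bin_width, r_max, tail_window)
        except ValueError:
            out[sid] = None
            continue
        dist.n_frames = len(traj)
        dist.n_sites = 1
        out[sid] = well_and_barrier(free_energy(dist, temperature))
    return out
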