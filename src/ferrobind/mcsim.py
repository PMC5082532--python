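"""Desk-scale Metropolis Monte Carlo of a single ion among fixed oxygen sites.

One Fe2+/Fe3+ ion moves in a periodic cubic box containing a rigid cluster of
oxygen "binding sites" that stand in for the carbonyl and carboxylate oxygens
of an acidic peptide.  Each site carries an attractive well

    u_k(d) = depth_k * exp(-(d - r0_k)^2 / (2 w_k^2)),   depth_k <= 0,

a Gaussian in the ion-oxygen distance centred on the bond distance r0 (2.85 A
by default, the optimum Fe-O separation), so that the generating potential
has closed-form Boltzmann statistics against which trajectory analysis can be
validated.  Sampling is plain Metropolis at fixed temperature with uniform
cube proposals and minimum-image periodic distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from numba import njit

from .constants import GAS_R_KJ

__all__ = [
    "BindingSite",
    "SiteModel",
    "IonTrajectory",
    "XYZParseError",
    "default_deev_model",
    "single_site_model",
    "simulate_ion",
    "batch_ensemble",
    "write_xyz",
    "read_xyz",
    "model_to_yaml",
    "model_from_yaml",
]


class XYZParseError(ValueError):
    def __init__(self, message: str, frame: int | None = None):
        self.frame = frame
        suffix = f" (frame {frame})" if frame is not None else ""
        super().__init__(message + suffix)


@dataclass(frozen=True)
class BindingSite:
    """One oxygen site: position (A), well depth (kJ/mol, <= 0), width and
    bond-distance offset of the Gaussian well (A)."""

    id: str
    position: tuple[float, float, float]
    well_depth: float
    well_width: float = 0.35
    bond_distance: float = 2.85

    def __post_init__(self) -> None:
        if self.well_depth > 0:
            raise ValueError(f"site {self.id}: well depth must be <= 0 kJ/mol")
        if self.well_width <= 0:
            raise ValueError(f"site {self.id}: well width must be positive")
        if self.bond_distance < 0:
            raise ValueError(f"site {self.id}: bond distance must be >= 0")


@dataclass(frozen=True)
class SiteModel:
    sites: tuple[BindingSite, ...]
    box_edge: float = 40.0
    charge_label: str = "Fe2"

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")
        if self.charge_label not in ("Fe2", "Fe3"):
            raise ValueError("charge_label must be 'Fe2' or 'Fe3'")
        object.__setattr__(self, "sites", tuple(self.sites))
        seen = set()
        for s in self.sites:
            if s.id in seen:
                raise ValueError(f"duplicate site id {s.id!r}")
            seen.add(s.id)
            if any(not 0.0 <= c < self.box_edge for c in s.position):
                raise ValueError(f"site {s.id} outside box [0, {self.box_edge})")

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sites)

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=float)

    def scaled(self, depth_scale: float) -> "SiteModel":
        """Uniformly scale all well depths (e.g. extra ferric charge)."""
        sites = tuple(replace(s, well_depth=s.well_depth * depth_scale)
                      for s in self.sites)
        return replace(self, sites=sites)


@dataclass
class IonTrajectory:
    """Sampled ion coordinates plus the fixed site geometry they were run in.

    ``frames`` has one row per retained sample (every ``sample_every`` MC
    sweeps); coordinates are wrapped into [0, box_edge).
    """

    frames: np.ndarray
    site_ids: tuple[str, ...]
    site_positions: np.ndarray
    box_edge: float
    seed: int
    sample_every: int = 1
    acceptance_rate: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.site_positions = np.asarray(self.site_positions, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 3:
            raise ValueError("frames must be (n, 3)")
        if np.any((self.frames < 0) | (self.frames >= self.box_edge)):
            raise ValueError("frames must be wrapped into the box")

    def __len__(self) -> int:
        return len(self.frames)


def default_deev_model(charge_label: str = "Fe2") -> SiteModel:
    """Synthetic 12-oxygen site cluster emulating a DEEV-like tetrapeptide.

    This geometry is a documented fixture, not the real peptide: 12 oxygen
    sites on a compact shell around the box centre.  Three sites are strong
    (-9 to -11 kJ/mol; the E13-carboxylate / bridging-carbonyl class) and the
    rest weak (-4 kJ/mol; the D11/E12 class), mirroring the two site classes
    seen in peptide-ion simulations.
    """
    c = 20.0
    golden = np.pi * (3.0 - np.sqrt(5.0))
    radius = 4.5
    strong = {0: -11.0, 1: -10.0, 2: -9.0}
    sites = []
    for k in range(12):
        zf = 1.0 - 2.0 * (k + 0.5) / 12.0
        rho = np.sqrt(1.0 - zf * zf)
        theta = golden * k
        pos = (
            float(c + radius * rho * np.cos(theta)),
            float(c + radius * rho * np.sin(theta)),
            float(c + radius * zf),
        )
        depth = strong.get(k, -4.0)
        sites.append(BindingSite(id=f"o{k + 1:02d}", position=pos, well_depth=depth))
    return SiteModel(sites=tuple(sites), box_edge=40.0, charge_label=charge_label)


def single_site_model(depth: float, width: float = 0.35,
                      bond_distance: float = 2.85, box_edge: float = 40.0,
                      charge_label: str = "Fe2") -> SiteModel:
    """One site at the box centre — the parameter-recovery workhorse."""
    c = box_edge / 2.0
    site = BindingSite(id="o01", position=(c, c, c), well_depth=depth,
                       well_width=width, bond_distance=bond_distance)
    return SiteModel(sites=(site,), box_edge=box_edge, charge_label=charge_label)


@njit(cache=True)
def _energy(pos, site_pos, depths, widths, r0s, box):
    u = 0.0
    for k in range(site_pos.shape[0]):
        d2 = 0.0
        for a in range(3):
            dx = pos[a] - site_pos[k, a]
            dx -= box * np.round(dx / box)
            d2 += dx * dx
        d = np.sqrt(d2)
        dd = d - r0s[k]
        u += depths[k] * np.exp(-dd * dd / (2.0 * widths[k] * widths[k]))
    return u


@njit(cache=True)
def _mc_kernel(site_pos, depths, widths, r0s, box, beta, step,
               n_burn, n_sweeps, sample_every, x0, seed):
    np.random.seed(seed)
    pos = x0.copy()
    e = _energy(pos, site_pos, depths, widths, r0s, box)
    prop = np.empty(3)
    n_acc = 0
    n_samples = n_sweeps // sample_every
    frames = np.empty((n_samples, 3))
    k = 0
    for sweep in range(n_burn + n_sweeps):
        for a in range(3):
            prop[a] = pos[a] + (np.random.random() - 0.5) * step
            prop[a] = prop[a] % box
        e_new = _energy(prop, site_pos, depths, widths, r0s, box)
        de = e_new - e
        if de <= 0.0 or np.random.random() < np.exp(-beta * de):
            for a in range(3):
                pos[a] = prop[a]
            e = e_new
            n_acc += 1
        if sweep >= n_burn and (sweep - n_burn + 1) % sample_every == 0:
            for a in range(3):
                frames[k, a] = pos[a]
            k += 1
    return frames, n_acc


def simulate_ion(
    model: SiteModel,
    temperature: float = 300.0,
    n_sweeps: int = 100_000,
    sample_every: int = 10,
    start_site: str = "random",
    seed: int = 0,
    step_size: float = 5.0,
    n_burn: int = 1000,
) -> IonTrajectory:
    """Metropolis trajectory of one ion in the site model's box.

    Proposals are uniform in a cube of edge ``step_size``; coordinates are
    periodically wrapped.  ``start_site`` places the ion one bond distance
    from the named site (or uniformly at random for ``"random"``).  The
    returned trajectory holds ``n_sweeps // sample_every`` frames taken after
    ``n_burn`` equilibration sweeps, and logs the overall acceptance rate.
    Deterministic for a fixed seed.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    if start_site == "random":
        x0 = rng.uniform(0.0, model.box_edge, size=3)
    else:
        ids = model.site_ids
        if start_site not in ids:
            raise ValueError(f"start site {start_site!r} not in model {ids}")
        site = model.sites[ids.index(start_site)]
        x0 = (np.asarray(site.position) +
              np.array([site.bond_distance, 0.0, 0.0])) % model.box_edge

    site_pos = model.positions()
    depths = np.array([s.well_depth for s in model.sites])
    widths = np.array([s.well_width for s in model.sites])
    r0s = np.array([s.bond_distance for s in model.sites])
    beta = 1.0 / (GAS_R_KJ * temperature)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    frames, n_acc = _mc_kernel(
        site_pos, depths, widths, r0s, model.box_edge, beta, step_size,
        int(n_burn), int(n_sweeps), int(sample_every),
        np.asarray(x0, dtype=float), kernel_seed,
    )
    return IonTrajectory(
        frames=frames,
        site_ids=model.site_ids,
        site_positions=site_pos,
        box_edge=model.box_edge,
        seed=int(seed),
        sample_every=int(sample_every),
        acceptance_rate=n_acc / (n_burn + n_sweeps),
        meta={
            "temperature_K": temperature,
            "n_sweeps": int(n_sweeps),
            "n_burn": int(n_burn),
            "step_size_A": step_size,
            "start_site": start_site,
            "charge_label": model.charge_label,
            "well_depths_kJmol": [s.well_depth for s in model.sites],
        },
    )


def batch_ensemble(
    model: SiteModel,
    n_starts: int = 12,
    depth_scale: float = 1.0,
    seeds: list[int] | None = None,
    **sim_kwargs,
) -> list[IonTrajectory]:
    """One trajectory per starting site, emulating a multi-start production set.

    For an Fe3 model the well depths are multiplied by ``depth_scale``
    (> 1 makes binding uniformly more favourable, the extra-charge effect).
    Starts cycle through the site ids; if ``n_starts`` exceeds the number of
    sites the remainder start at random positions.
    """
    if seeds is None:
        seeds = list(range(n_starts))
    if len(seeds) < n_starts:
        raise ValueError(f"need {n_starts} seeds, got {len(seeds)}")
    run_model = model.scaled(depth_scale) if model.charge_label == "Fe3" else model
    ids = run_model.site_ids
    out = []
    for i in range(n_starts):
        start = ids[i] if i < len(ids) else "random"
        out.append(simulate_ion(run_model, start_site=start, seed=seeds[i],
                                **sim_kwargs))
    return out


# --- XYZ I/O ---------------------------------------------------------------

def write_xyz(traj: IonTrajectory, path: str | Path) -> None:
    """Multi-frame XYZ: fixed 'O' site block then the 'FE' ion, per frame.

    The comment line carries the box edge; the first frame's comment also
    lists the site ids so a round trip is lossless (coordinates to 1e-6 A).
    """
    path = Path(path)
    n_atoms = len(traj.site_ids) + 1
    with path.open("w") as fh:
        for i, frame in enumerate(traj.frames):
            fh.write(f"{n_atoms}\n")
            comment = f"box={traj.box_edge:.6f} frame={i}"
            if i == 0:
                comment += " sites=" + ",".join(traj.site_ids)
            fh.write(comment + "\n")
            for pos in traj.site_positions:
                fh.write("O %.6f %.6f %.6f\n" % tuple(pos))
            fh.write("FE %.6f %.6f %.6f\n" % tuple(frame))


def read_xyz(path: str | Path) -> IonTrajectory:
    """Read a trajectory in the :func:`write_xyz` convention.

    Site depths are not stored in XYZ; the returned trajectory carries
    geometry only, which is all the trajectory statistics need.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos = 0
    frames = []
    site_positions: np.ndarray | None = None
    site_ids: tuple[str, ...] | None = None
    box = None
    n_atoms = None
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError:
            raise XYZParseError("bad atom-count line", frame_idx)
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise XYZParseError(
                f"inconsistent atom count {count} != {n_atoms}", frame_idx)
        if pos + 1 + count >= len(lines) + 1 and len(lines) - pos - 2 < count:
            raise XYZParseError("truncated frame", frame_idx)
        comment = lines[pos + 1]
        for token in comment.split():
            if token.startswith("box="):
                box = float(token[4:])
            elif token.startswith("sites="):
                site_ids = tuple(token[6:].split(","))
        block = lines[pos + 2: pos + 2 + count]
        if len(block) < count:
            raise XYZParseError("truncated frame", frame_idx)
        atoms = []
        for ln in block:
            parts = ln.split()
            if len(parts) != 4:
                raise XYZParseError("bad atom line", frame_idx)
            atoms.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
        elements = [a[0] for a in atoms]
        if elements[-1] != "FE" or any(e != "O" for e in elements[:-1]):
            raise XYZParseError("expected site 'O' block then ion 'FE'", frame_idx)
        coords = np.array([a[1:] for a in atoms])
        if site_positions is None:
            site_positions = coords[:-1]
        frames.append(coords[-1])
        pos += 2 + count
        frame_idx += 1
    if not frames or site_positions is None or box is None:
        raise XYZParseError("no frames found")
    if site_ids is None:
        site_ids = tuple(f"o{k + 1:02d}" for k in range(len(site_positions)))
    return IonTrajectory(
        frames=np.array(frames), site_ids=site_ids,
        site_positions=site_positions, box_edge=box, seed=-1,
        meta={"source": str(path)},
    )


# --- model config I/O ------------------------------------------------------

def model_to_yaml(model: SiteModel, path: str | Path) -> None:
    payload = {
        "box_edge": model.box_edge,
        "charge_label": model.charge_label,
        "sites": [
            {"id": s.id, "position": [float(c) for c in s.position],
             "well_depth": float(s.well_depth),
             "well_width": float(s.well_width),
             "bond_distance": float(s.bond_distance)}
            for s in model.sites
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def model_from_yaml(path: str | Path) -> SiteModel:
    payload = yaml.safe_load(Path(path).read_text())
    sites = tuple(
        BindingSite(
            id=d["id"], position=tuple(d["position"]),
            well_depth=d["well_depth"],
            well_width=d.get("well_width", 0.35),
            bond_distance=d.get("bond_distance", 2.85),
        )
        for d in payload["sites"]
    )
    return SiteModel(sites=sites, box_edge=payload["box_edge"],
                     charge_label=payload.get("charge_label", "Fe2"))
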