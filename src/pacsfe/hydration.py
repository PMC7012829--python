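"""Hydration, hydrogen-bond and fluctuation analyses on structures.

Counting conventions (stated once, used everywhere):

* Water is identified by residue name (HOH/WAT/SOL...), counted at its
  oxygen.
* First hydration shell: minimum distance to any solute atom in [0, 3] Å
  (closed right boundary); second shell: (3, 6] Å.  The two are disjoint
  and their union is everything within 6 Å.
* Distances use the minimum-image convention for orthorhombic boxes.
* Shell volumes are hit-or-miss Monte-Carlo estimates under a fixed seed;
  shell densities are counts over those volumes, and the r-ratios are shell
  density over bulk density.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import KB_J_PER_K
from .structure import SelectionError, Structure, Trajectory, last_half_window


class DataError(ValueError):
    pass


class PBCError(ValueError):
    pass


class ModeError(ValueError):
    """Angle-based hydrogen-bond criterion requested without hydrogens."""


FIRST_SHELL = 3.0
SECOND_SHELL = 6.0


# ---------------------------------------------------------------------------
# Distance helpers
# ---------------------------------------------------------------------------


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(coords, box)


def min_distances(
    points: np.ndarray, targets: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Minimum distance from each point to the target set (min-image under
    an orthorhombic box)."""
    points = np.atleast_2d(points)
    if box is not None:
        tree = cKDTree(_wrap(targets, box), boxsize=box)
        d, _ = tree.query(_wrap(points, box))
    else:
        tree = cKDTree(targets)
        d, _ = tree.query(points)
    return np.asarray(d, dtype=float)


def pair_distance_matrix(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """All-pairs distances (used by the brute-force oracles and small sets)."""
    delta = a[:, None, :] - b[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.sqrt(np.sum(delta * delta, axis=2))


# ---------------------------------------------------------------------------
# Hydration shells
# ---------------------------------------------------------------------------


@dataclass
class ShellCounts:
    """Water counts, Monte-Carlo shell volumes, densities, and densities
    relative to bulk for the first (0-3 Å) and second (3-6 Å) shells."""

    n_first: int
    n_second: int
    shell_volumes: tuple[float, float]
    densities: tuple[float, float]
    bulk_density: float | None
    ratios: tuple[float, float] | None
    radii: tuple[float, float] = (FIRST_SHELL, SECOND_SHELL)

    # Field-notation aliases
    @property
    def N_1SW(self) -> int:
        return self.n_first

    @property
    def N_2SW(self) -> int:
        return self.n_second

    @property
    def r_1SW(self) -> float | None:
        return None if self.ratios is None else self.ratios[0]

    @property
    def r_2SW(self) -> float | None:
        return None if self.ratios is None else self.ratios[1]


def _mc_domain(structure: Structure, solute_idx: np.ndarray, outer: float):
    if structure.box is not None:
        return None, structure.box, float(np.prod(structure.box))
    lo = structure.coords[solute_idx].min(axis=0) - outer
    hi = structure.coords[solute_idx].max(axis=0) + outer
    return lo, hi - lo, float(np.prod(hi - lo))


def shell_volumes_mc(
    structure: Structure,
    solute_idx: np.ndarray,
    radii: tuple[float, float] = (FIRST_SHELL, SECOND_SHELL),
    n_samples: int = 200_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Hit-or-miss Monte-Carlo volumes (Å³) of the two shells and the bulk.

    With a box, points are drawn in the box (bulk = beyond the outer shell);
    without one, in the solute bounding box padded by the outer radius and
    the "bulk" volume is undefined (returned as nan).
    """
    rng = np.random.default_rng(seed)
    lo, extent, volume = _mc_domain(structure, solute_idx, radii[1])
    pts = rng.random((n_samples, 3)) * extent
    if lo is not None:
        pts = pts + lo
    d = min_distances(pts, structure.coords[solute_idx], structure.box)
    v1 = volume * float(np.mean(d <= radii[0]))
    v2 = volume * float(np.mean((d > radii[0]) & (d <= radii[1])))
    v_bulk = volume * float(np.mean(d > radii[1])) if structure.box is not None else float("nan")
    return v1, v2, v_bulk


def shell_water_counts(
    structure: Structure,
    solute: np.ndarray | None = None,
    radii: tuple[float, float] = (FIRST_SHELL, SECOND_SHELL),
    mc_samples: int = 200_000,
    mc_seed: int = 0,
) -> ShellCounts:
    """Count surface waters in the first and second hydration shells.

    A water (counted at its oxygen) is first-shell iff its minimum distance
    to any solute atom is <= radii[0], second-shell iff in (radii[0],
    radii[1]].  ``solute`` defaults to every non-water atom.
    """
    if solute is None:
        solute = np.flatnonzero(structure.mask(water=False))
    solute = np.asarray(solute)
    if solute.size == 0:
        raise SelectionError("solute selection is empty")
    waters = structure.water_oxygen_indices()
    if waters.size == 0:
        warnings.warn("no waters in structure; returning zero counts", RuntimeWarning)
        d = np.empty(0)
    else:
        if structure.box is not None:
            span = structure.coords.max(axis=0) - structure.coords.min(axis=0)
            if np.any(span > structure.box * (1.0 + 1e-9) + 1e-6):
                raise PBCError(
                    "coordinates span more than the stated box; wrap or fix the box"
                )
        d = min_distances(
            structure.coords[waters], structure.coords[solute], structure.box
        )
    n1 = int(np.count_nonzero(d <= radii[0]))
    n2 = int(np.count_nonzero((d > radii[0]) & (d <= radii[1])))
    v1, v2, v_bulk = shell_volumes_mc(structure, solute, radii, mc_samples, mc_seed)
    rho1 = n1 / v1 if v1 > 0 else float("nan")
    rho2 = n2 / v2 if v2 > 0 else float("nan")
    if structure.box is not None and np.isfinite(v_bulk) and v_bulk > 0:
        n_bulk = int(np.count_nonzero(d > radii[1]))
        bulk = n_bulk / v_bulk
        ratios = (rho1 / bulk, rho2 / bulk) if bulk > 0 else None
    else:
        bulk, ratios = None, None
    return ShellCounts(
        n_first=n1, n_second=n2, shell_volumes=(v1, v2),
        densities=(rho1, rho2), bulk_density=bulk, ratios=ratios, radii=radii,
    )


def shell_water_counts_brute(
    structure: Structure,
    solute: np.ndarray,
    radii: tuple[float, float] = (FIRST_SHELL, SECOND_SHELL),
) -> tuple[int, int]:
    """All-pairs O(N·M) reference for the shell counts (oracle)."""
    waters = structure.water_oxygen_indices()
    if waters.size == 0:
        return 0, 0
    d = pair_distance_matrix(
        structure.coords[waters], structure.coords[np.asarray(solute)], structure.box
    ).min(axis=1)
    return int(np.count_nonzero(d <= radii[0])), int(
        np.count_nonzero((d > radii[0]) & (d <= radii[1]))
    )


# ---------------------------------------------------------------------------
# Interface residues and interface waters
# ---------------------------------------------------------------------------


@dataclass
class InterfaceSet:
    """Residues in persistent inter-chain contact over the analysis window."""

    residues: set[tuple[str, int]]
    occupancy: dict[tuple[str, int], float]
    window: np.ndarray
    threshold: float
    cutoff: float


def interface_residues(
    trajectory: Trajectory,
    chain_a: str = "A",
    chain_b: str = "B",
    cutoff: float = 4.5,
    threshold: float = 0.8,
    window: np.ndarray | None = None,
) -> InterfaceSet:
    """Residues (of either chain) with any heavy atom within ``cutoff`` of
    the partner chain in at least ``threshold`` of the window frames.

    The window defaults to the last half of the trajectory (the equilibrated
    tail).
    """
    top = trajectory.topology
    idx_a = np.flatnonzero(top.mask(chain=chain_a, heavy=True))
    idx_b = np.flatnonzero(top.mask(chain=chain_b, heavy=True))
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError(f"chains {chain_a!r}/{chain_b!r} absent or empty")
    if window is None:
        window = last_half_window(trajectory.n_frames)
    window = np.asarray(window)
    if window.size < 2:
        raise DataError("need at least 2 frames in the analysis window")

    keys = [(str(top.chains[i]), int(top.resids[i])) for i in range(top.n_atoms)]
    hits: dict[tuple[str, int], int] = {}
    for f in window:
        frame = trajectory.coords[f]
        box = None
        if trajectory.boxes is not None:
            box = trajectory.boxes[f]
        elif top.box is not None:
            box = top.box
        d_ab = min_distances(frame[idx_a], frame[idx_b], box)
        d_ba = min_distances(frame[idx_b], frame[idx_a], box)
        frame_res = {keys[i] for i, dist in zip(idx_a, d_ab) if dist <= cutoff}
        frame_res |= {keys[i] for i, dist in zip(idx_b, d_ba) if dist <= cutoff}
        for key in frame_res:
            hits[key] = hits.get(key, 0) + 1
    occupancy = {key: n / len(window) for key, n in hits.items()}
    residues = {key for key, occ in occupancy.items() if occ >= threshold}
    return InterfaceSet(
        residues=residues, occupancy=occupancy, window=window,
        threshold=threshold, cutoff=cutoff,
    )


def interface_water_counts(
    structure: Structure,
    interface: InterfaceSet | Sequence[tuple[str, int]],
    radii: tuple[float, float] = (FIRST_SHELL, SECOND_SHELL),
    mc_samples: int = 200_000,
    mc_seed: int = 0,
) -> ShellCounts:
    """Shell water counts around the interface residues only (N_1IW/N_2IW)."""
    residues = interface.residues if isinstance(interface, InterfaceSet) else set(interface)
    if not residues:
        raise SelectionError("interface residue set is empty")
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for ch, rid in residues:
        mask |= structure.mask(chain=ch, resid=rid)
    mask &= structure.mask(water=False)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError("interface residues matched no solute atoms")
    return shell_water_counts(structure, idx, radii, mc_samples, mc_seed)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass
class HBondCounts:
    """Hydrogen-bond tallies: protein-protein (intra + inter), protein-water,
    and protein-water-protein bridges (waters H-bonded to two distinct
    protein chains, counted once per water)."""

    H_PP: int
    H_PW: int
    H_PWP: int
    pairs_pp: list[tuple[int, int]] = field(default_factory=list)
    pairs_pw: list[tuple[int, int]] = field(default_factory=list)
    bridging_waters: list[int] = field(default_factory=list)


_POLAR_ELEMENTS = ("N", "O")
_COVALENT_H_CUTOFF = 1.25


def _polar_atoms(structure: Structure) -> np.ndarray:
    return np.flatnonzero(np.isin(structure.elements, _POLAR_ELEMENTS))


def _attached_hydrogens(structure: Structure, heavy_idx: np.ndarray) -> dict[int, list[int]]:
    h_idx = np.flatnonzero(structure.elements == "H")
    attached: dict[int, list[int]] = {i: [] for i in heavy_idx}
    if h_idx.size == 0:
        return attached
    d = pair_distance_matrix(
        structure.coords[h_idx], structure.coords[heavy_idx], structure.box
    )
    nearest = d.argmin(axis=1)
    for row, hi in enumerate(h_idx):
        col = nearest[row]
        if d[row, col] <= _COVALENT_H_CUTOFF:
            attached[int(heavy_idx[col])].append(int(hi))
    return attached


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, box) -> float:
    v1 = a - b
    v2 = c - b
    if box is not None:
        v1 -= box * np.round(v1 / box)
        v2 -= box * np.round(v2 / box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_counts(
    structure: Structure,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 150.0,
    mode: str = "auto",
    bridge_by: str = "chain",
) -> HBondCounts:
    """Count hydrogen bonds with a geometric criterion.

    ``mode="angle"``: donor-acceptor distance <= 3.5 Å and D-H···A angle
    >= 150° for some hydrogen covalently attached (<= 1.25 Å) to the donor.
    ``mode="distance"``: N/O pairs within the cutoff (for hydrogen-free
    models).  ``mode="auto"`` picks angle when hydrogens exist.  A
    donor/acceptor pair counts once.  Same-residue pairs are excluded.
    ``bridge_by``: "chain" counts a water as bridging when it binds two
    distinct protein chains; "residue" when it binds two distinct residues.
    """
    has_h = bool(np.any(structure.elements == "H"))
    if mode == "auto":
        mode = "angle" if has_h else "distance"
    if mode == "angle" and not has_h:
        raise ModeError("angle criterion requested but the structure has no hydrogens")
    if mode not in ("angle", "distance"):
        raise ValueError(f"unknown mode {mode!r}")

    polar = _polar_atoms(structure)
    if polar.size == 0:
        return HBondCounts(0, 0, 0)
    water_mask = structure.mask(water=True)
    box = structure.box
    coords = structure.coords
    if box is not None:
        tree = cKDTree(_wrap(coords[polar], box), boxsize=box)
    else:
        tree = cKDTree(coords[polar])
    candidate_pairs = tree.query_pairs(distance_cutoff, output_type="ndarray")

    attached = _attached_hydrogens(structure, polar) if mode == "angle" else {}

    def same_residue(i: int, j: int) -> bool:
        return (
            structure.chains[i] == structure.chains[j]
            and structure.resids[i] == structure.resids[j]
        )

    def is_bond(i: int, j: int) -> bool:
        if mode == "distance":
            return True
        for donor, acceptor in ((i, j), (j, i)):
            for h in attached.get(donor, []):
                if _angle_deg(coords[donor], coords[h], coords[acceptor], box) >= angle_cutoff:
                    return True
        return False

    pp, pw = [], []
    water_partners: dict[int, set] = {}
    for a, b in candidate_pairs:
        i, j = int(polar[a]), int(polar[b])
        if same_residue(i, j):
            continue
        wi, wj = bool(water_mask[i]), bool(water_mask[j])
        if wi and wj:
            continue  # water-water bonds are out of scope
        if not is_bond(i, j):
            continue
        if not wi and not wj:
            pp.append((i, j))
        else:
            prot, wat = (j, i) if wi else (i, j)
            pw.append((prot, wat))
            tag = (
                str(structure.chains[prot])
                if bridge_by == "chain"
                else (str(structure.chains[prot]), int(structure.resids[prot]))
            )
            water_partners.setdefault(wat, set()).add(tag)
    # group waters by residue (multi-atom waters share one bridge count)
    bridging = [w for w, tags in water_partners.items() if len(tags) >= 2]
    return HBondCounts(
        H_PP=len(pp), H_PW=len(pw), H_PWP=len(bridging),
        pairs_pp=pp, pairs_pw=pw, bridging_waters=bridging,
    )


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

#: Charged-group side-chain atoms per residue type.
CHARGED_GROUP_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


def salt_bridge_occupancy(
    trajectory: Trajectory,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
    cutoff: float = 4.0,
) -> float:
    """Fraction of frames in which the two residues' charged-group heavy
    atoms come within ``cutoff`` Å."""
    top = trajectory.topology

    def group(chain, rid):
        mask = top.mask(chain=chain, resid=rid)
        if not mask.any():
            raise SelectionError(f"residue {chain}:{rid} not found")
        resname = str(top.resnames[np.flatnonzero(mask)[0]])
        names = CHARGED_GROUP_ATOMS.get(resname)
        if names is not None:
            sel = np.flatnonzero(mask & np.isin(top.names, names))
        else:  # unknown residue type: side-chain-agnostic polar fallback
            sel = np.flatnonzero(mask & np.isin(top.elements, _POLAR_ELEMENTS))
        if sel.size == 0:
            raise SelectionError(
                f"residue {chain}:{rid} ({resname}) has no charged-group atoms"
            )
        return sel

    sel_a = group(*residue_a)
    sel_b = group(*residue_b)
    n_hit = 0
    for f in range(trajectory.n_frames):
        box = trajectory.boxes[f] if trajectory.boxes is not None else top.box
        d = pair_distance_matrix(
            trajectory.coords[f][sel_a], trajectory.coords[f][sel_b], box
        )
        if d.min() <= cutoff:
            n_hit += 1
    return n_hit / trajectory.n_frames


# ---------------------------------------------------------------------------
# Compressibility, bulk density, SASA
# ---------------------------------------------------------------------------


@dataclass
class CompressibilityResult:
    kappa_T: float
    mean_volume: float
    variance_volume: float
    temperature: float | None
    window: np.ndarray
    unit: str  # "1/MPa" or "reduced" (kT = 1, volume units^-1... per kT)


def isothermal_compressibility(
    volumes: np.ndarray,
    temperature: float | None = None,
    window: np.ndarray | None = None,
    reduced: bool = False,
) -> CompressibilityResult:
    """Volume-fluctuation compressibility κ_T = (⟨V²⟩-⟨V⟩²)/(k_B T ⟨V⟩).

    The average runs over ``window`` (default: the last half of the series;
    population variance).  ``reduced=True`` treats k_B T = 1 with volumes in
    Å³ (toy systems); otherwise volumes are Å³, ``temperature`` is in K and
    κ_T is returned in 1/MPa.
    """
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes <= 0):
        raise DataError("volumes must be positive")
    if window is None:
        window = last_half_window(len(volumes))
    window = np.asarray(window)
    if window.size < 2:
        raise DataError("need at least 2 frames in the window")
    v = volumes[window]
    mean = float(v.mean())
    var = float(v.var())  # population variance
    if reduced:
        kappa = var / mean
        return CompressibilityResult(kappa, mean, var, None, window, "reduced")
    if temperature is None:
        raise DataError("temperature (K) required unless reduced=True")
    # V in Å³ = 1e-30 m³; κ[1/Pa] = var·1e-30/(kB·T·mean); 1/MPa = 1e6/Pa
    kappa = var * 1e-30 / (KB_J_PER_K * temperature * mean) * 1e6
    return CompressibilityResult(kappa, mean, var, temperature, window, "1/MPa")


def bulk_density(
    boxes: np.ndarray,
    n_waters: int | np.ndarray,
    window: np.ndarray | None = None,
) -> float:
    """Mean water number density (Å⁻³) over the window: count / box volume.

    ``boxes`` is (n_frames, 3) box lengths (or a single (3,) box); the
    window defaults to the last half of the series.
    """
    boxes = np.asarray(boxes, dtype=float)
    if boxes.size == 0:
        raise DataError("box required for bulk density")
    boxes = boxes.reshape(-1, 3)
    counts = np.broadcast_to(np.asarray(n_waters, dtype=float), (len(boxes),))
    if window is None:
        window = last_half_window(len(boxes))
    window = np.asarray(window)
    dens = counts[window] / np.prod(boxes[window], axis=1)
    return float(dens.mean())


#: Van der Waals radii (Å) for SASA.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 1.56,
}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    selection: np.ndarray | None = None,
    radii_overrides: dict[str, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is sampled with ``n_points`` sphere points at radius
    r_vdw + probe; a point is accessible if no other atom's probe-expanded
    sphere covers it.  Returns (total over the selection, per-atom areas for
    the whole structure) in Å².
    """
    table = dict(VDW_RADII)
    if radii_overrides:
        table.update({k.upper(): v for k, v in radii_overrides.items()})
    elements = [str(e).upper() for e in structure.elements]
    unknown = sorted({e for e in elements if e not in table})
    if unknown:
        raise KeyError(
            f"no van der Waals radius for element(s) {unknown}; pass radii_overrides"
        )
    radii = np.array([table[e] for e in elements]) + probe_radius
    coords = structure.coords
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(structure.n_atoms)
    max_reach = 2.0 * radii.max()
    for i in range(structure.n_atoms):
        neighbors = [
            j for j in tree.query_ball_point(coords[i], max_reach)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]
        ]
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            # points exactly on a shared surface belong to the lower index
            if j < i:
                accessible &= d > radii[j] + 1e-9
            else:
                accessible &= d >= radii[j] - 1e-9
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    if selection is None:
        total = float(areas.sum())
    else:
        total = float(areas[np.asarray(selection)].sum())
    return total, areas
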