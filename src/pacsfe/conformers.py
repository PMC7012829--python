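"""Dihedral-based conformer classification and structural comparison.

The response regulator's activation state is read off the first side-chain
torsion (χ1, quadruple N-CA-CB-CG) of the switch tyrosine: χ1 in
[-45°, 135°) is the inactive rotamer (the ~+60° basin), everything else is
active (the ~-150° basin).  The conformer free-energy difference follows
from the two populations, ΔG_M = -kT ln(P_inactive / P_active).

Also here: Kabsch superposition RMSD, medoid representative structures from
k-means on superposed α-carbon coordinates, and a dwell-filtered dihedral
transition counter.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import kt_kcal_per_mol
from .hydration import DataError
from .structure import SelectionError, Structure, Trajectory, last_half_window

INACTIVE = "inactive"
ACTIVE = "active"

#: χ1 interval classified as the inactive rotamer: left-closed, right-open.
INACTIVE_RANGE = (-45.0, 135.0)

#: Default χ1 atom quadruple.
CHI1_QUADRUPLE = ("N", "CA", "CB", "CG")


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle (degrees, in (-180, 180]) of four points,
    IUPAC convention (cis = 0, trans = 180)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass
class DihedralSeries:
    """Per-frame torsion angles (degrees, (-180, 180]) of one residue."""

    residue: tuple[str, int]
    quadruple: tuple[str, str, str, str]
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any((self.angles <= -180.0) | (self.angles > 180.0)):
            raise ValueError("angles must lie in (-180, 180]")


def dihedral_series(
    trajectory: Trajectory,
    residue: tuple[str, int],
    quadruple: tuple[str, str, str, str] = CHI1_QUADRUPLE,
) -> DihedralSeries:
    """Torsion time series for one residue across all frames."""
    top = trajectory.topology
    chain, rid = residue
    idx = []
    for name in quadruple:
        found = np.flatnonzero(top.mask(chain=chain, resid=rid, name=name))
        if found.size == 0:
            raise SelectionError(
                f"atom {name!r} missing in residue {chain}:{rid}"
            )
        idx.append(int(found[0]))
    angles = np.array(
        [
            dihedral_angle(*(trajectory.coords[f][i] for i in idx))
            for f in range(trajectory.n_frames)
        ]
    )
    return DihedralSeries(residue=residue, quadruple=tuple(quadruple), angles=angles)


# ---------------------------------------------------------------------------
# Conformer classification and population free energy
# ---------------------------------------------------------------------------


@dataclass
class FormClassification:
    labels: np.ndarray  # "active"/"inactive" per frame
    boundaries: tuple[float, float] = INACTIVE_RANGE

    @property
    def p_active(self) -> float:
        return float(np.mean(self.labels == ACTIVE))

    @property
    def p_inactive(self) -> float:
        return float(np.mean(self.labels == INACTIVE))


def classify_form(series: DihedralSeries | np.ndarray) -> FormClassification:
    """Label frames active/inactive from χ1 (inactive iff -45° <= χ1 < 135°)."""
    angles = series.angles if isinstance(series, DihedralSeries) else np.asarray(series)
    lo, hi = INACTIVE_RANGE
    inactive = (angles >= lo) & (angles < hi)
    labels = np.where(inactive, INACTIVE, ACTIVE)
    return FormClassification(labels=labels)


@dataclass
class MonomerFreeEnergy:
    P_active: float
    P_inactive: float
    delta_G_M: float  # kcal/mol (or kT when reduced)
    temperature: float | None
    unit: str


def monomer_form_free_energy(
    classification: FormClassification,
    temperature: float | None = 300.0,
) -> MonomerFreeEnergy:
    """ΔG_M = ΔG_inactive − ΔG_active = −kT ln(P_inactive / P_active).

    Positive when the inactive form is rarer.  ``temperature=None`` gives
    the reduced-unit (kT) value.  A vanishing population yields a signed
    infinity with a warning.
    """
    if classification.labels.size == 0:
        raise DataError("empty classification")
    p_a = classification.p_active
    p_i = classification.p_inactive
    kt = kt_kcal_per_mol(temperature) if temperature is not None else 1.0
    unit = "kcal/mol" if temperature is not None else "kT"
    if p_a == 0.0 or p_i == 0.0:
        warnings.warn(
            "one conformer population is zero; free energy is infinite",
            RuntimeWarning,
        )
        dg = float("-inf") if p_i > 0 else float("inf")
    else:
        dg = -kt * float(np.log(p_i / p_a))
    return MonomerFreeEnergy(
        P_active=p_a, P_inactive=p_i, delta_G_M=dg, temperature=temperature, unit=unit
    )


# ---------------------------------------------------------------------------
# Superposition RMSD and representatives
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids aligning mobile onto
    reference (least squares)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, mc, rc


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly superpose coordinates onto a reference (proper rotation only)."""
    rot, mc, rc = _kabsch(mobile, reference)
    return (mobile - mc) @ rot.T + rc


def rmsd_after_superposition(
    reference: Structure | np.ndarray,
    frame: Structure | np.ndarray,
    selection: np.ndarray | None = None,
) -> float:
    """RMSD (Å) after optimal rigid superposition.

    ``selection`` (indices into both structures, default: α-carbons if
    present, else all atoms) must address equally sized, consistently
    ordered atom sets.  Improper rotations (reflections) are never used.
    """
    ref = reference.coords if isinstance(reference, Structure) else np.asarray(reference)
    mob = frame.coords if isinstance(frame, Structure) else np.asarray(frame)
    if selection is None and isinstance(reference, Structure):
        ca = np.flatnonzero(reference.mask(name="CA"))
        selection = ca if ca.size else None
    if selection is not None:
        selection = np.asarray(selection)
        ref = ref[selection]
        mob = mob[selection]
    if ref.shape != mob.shape:
        raise ValueError(f"selection size mismatch: {ref.shape} vs {mob.shape}")
    fitted = superpose(mob, ref)
    return float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))


def representative_structures(
    trajectory: Trajectory,
    k: int = 5,
    window: np.ndarray | None = None,
    seed: int = 0,
    selection: np.ndarray | None = None,
) -> tuple[list[int], np.ndarray]:
    """Representative frames by k-means on superposed coordinates.

    Frames in the window (default: last half) are superposed onto the first
    window frame on ``selection`` (default α-carbons, else all atoms), then
    clustered; each cluster's representative is the medoid frame (the frame
    nearest its center — a mean of coordinates is not a physical structure).
    Returns (absolute frame indices of the k representatives, per-window
    cluster labels).
    """
    from sklearn.cluster import KMeans

    top = trajectory.topology
    if window is None:
        window = last_half_window(trajectory.n_frames)
    window = np.asarray(window)
    if window.size < k:
        raise DataError(f"window has {window.size} frames, need at least k={k}")
    if selection is None:
        ca = np.flatnonzero(top.mask(name="CA"))
        selection = ca if ca.size else np.arange(top.n_atoms)
    ref = trajectory.coords[window[0]][selection]
    fitted = np.stack(
        [superpose(trajectory.coords[f][selection], ref) for f in window]
    )
    flat = fitted.reshape(len(window), -1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(flat)
    reps = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(flat[members] - km.cluster_centers_[c], axis=1)
        reps.append(int(window[members[int(np.argmin(d))]]))
    return reps, labels


# ---------------------------------------------------------------------------
# Dihedral transition counting
# ---------------------------------------------------------------------------


def dihedral_transition_count(
    labels: np.ndarray | FormClassification,
    dwell: int = 10,
) -> list[int]:
    """Frame indices of label switches that persist for >= ``dwell`` frames.

    A switch that reverts before ``dwell`` frames is chatter, not an event.
    (A deliberately simple dwell-filtered crossing counter; not a full
    dihedral transition analysis.)
    """
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    if isinstance(labels, FormClassification):
        labels = labels.labels
    labels = np.asarray(labels)
    events: list[int] = []
    if labels.size == 0:
        return events
    current = labels[0]
    i = 1
    n = len(labels)
    while i < n:
        if labels[i] != current:
            run_end = i
            while run_end < n and labels[run_end] == labels[i]:
                run_end += 1
            if run_end - i >= dwell:
                events.append(i)
                current = labels[i]
            i = run_end
        else:
            i += 1
    return events
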