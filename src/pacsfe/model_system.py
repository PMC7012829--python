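"""Toy stand-in for the MD engine.

The all-atom engine is replaced by overdamped Langevin (Euler–Maruyama)
dynamics in reduced units (kT = 1) on a pressure-parameterized binding
potential.  The dissociation coordinate d is the distance of a walker (the
ligand center of mass) from the origin (the receptor center of mass).

Pressure enters as a linear shallowing of the binding well,

    depth_eff = well_depth_0 - pressure_coefficient * (pressure - 0.1 MPa),

which emulates the observed weakening of protein-protein binding with
pressure through enhanced hydration, with a controllable ground truth.  The
radial funnel is a flat-bottomed well joined to zero by a C¹ smoothstep wall
of width w = sqrt(6 * depth / stiffness) (so that max |U''| = stiffness): the
bound state is then genuinely square-well-like, which is the regime in which
the standard-state volume correction (bound state = flat well of depth ΔW
over volume V_b) is accurate.  A reflective outer wall at ``wall_radius``
emulates the finite simulation box and makes the unbound state normalizable.

An analytic oracle (:func:`analytic_reference`) integrates the Boltzmann
weight over the same potential, including the 4πr² Jacobian for the radial
funnel, giving the exact profile and standard binding free energy that the
sampled pipeline is expected to recover.

Time is labeled "ps" in the reduced dynamics so that cycle accounting
(0.1 ns of MD per replica per cycle) maps one-to-one onto the pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

from .constants import REFERENCE_PRESSURE_MPA, STANDARD_STATE_VOLUME_A3
from .structure import Structure, concatenate

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


RADIAL_FUNNEL = "radial_funnel_3d"
DOUBLE_WELL = "double_well_1d"


class ConfigurationError(ValueError):
    """Invalid potential/engine configuration."""


class PropagationError(RuntimeError):
    """Numerical failure (NaN energy/force) during propagation."""


class ResolutionError(ValueError):
    """Analysis grid too coarse for the potential."""


class PlacementError(RuntimeError):
    """Solvated-structure generator could not place the requested waters."""


# ---------------------------------------------------------------------------
# Potential
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PotentialSpec:
    """Pressure-parameterized binding potential.

    Parameters
    ----------
    kind:
        ``"radial_funnel_3d"`` (flat-bottomed attractive well around the
        origin, flat beyond the wall region) or ``"double_well_1d"``
        (two symmetric Gaussian wells at ±bound_radius).
    well_depth_0:
        Well depth in kT at the reference pressure (0.1 MPa).
    pressure:
        Hydrostatic pressure in MPa.
    pressure_coefficient:
        Linear well-shallowing coefficient, kT per MPa.
    bound_radius:
        Å; the well region (funnel: U(bound_radius) = -depth/2; double well:
        positions of the two minima).
    wall_radius:
        Å; reflective outer boundary.
    stiffness:
        kT/Å²; maximum curvature of the well wall.
    """

    kind: str = RADIAL_FUNNEL
    well_depth_0: float = 7.0
    pressure: float = REFERENCE_PRESSURE_MPA
    pressure_coefficient: float = 0.025
    bound_radius: float = 6.0
    wall_radius: float = 30.0
    stiffness: float = 30.0

    @property
    def effective_well_depth(self) -> float:
        return self.well_depth_0 - self.pressure_coefficient * (
            self.pressure - REFERENCE_PRESSURE_MPA
        )

    @property
    def dimension(self) -> int:
        return 3 if self.kind == RADIAL_FUNNEL else 1

    def validate(self) -> None:
        if self.kind not in (RADIAL_FUNNEL, DOUBLE_WELL):
            raise ConfigurationError(f"unknown potential kind {self.kind!r}")
        if self.effective_well_depth <= 0:
            raise ConfigurationError(
                f"effective well depth {self.effective_well_depth:.3f} kT is not "
                f"positive at pressure {self.pressure} MPa"
            )
        if not (self.wall_radius > self.bound_radius > 0):
            raise ConfigurationError(
                "need wall_radius > bound_radius > 0, got "
                f"wall_radius={self.wall_radius}, bound_radius={self.bound_radius}"
            )
        if self.stiffness <= 0:
            raise ConfigurationError("stiffness must be positive")
        if self.kind == RADIAL_FUNNEL and self.wall_half_width >= self.bound_radius:
            raise ConfigurationError(
                "stiffness too low: well wall (half-width "
                f"{self.wall_half_width:.2f} Å) does not fit inside bound_radius"
            )

    @property
    def wall_width(self) -> float:
        """Width w of the smoothstep wall, sqrt(6*depth/stiffness)."""
        return math.sqrt(6.0 * max(self.effective_well_depth, 1e-12) / self.stiffness)

    @property
    def wall_half_width(self) -> float:
        return 0.5 * self.wall_width

    @property
    def flat_radius(self) -> float:
        """Radius beyond which the funnel potential is exactly zero."""
        if self.kind == RADIAL_FUNNEL:
            return self.bound_radius + self.wall_half_width
        return self.bound_radius + 4.0 * math.sqrt(
            2.0 * self.effective_well_depth / self.stiffness
        )


class Potential:
    """Callable energy/force field built from a :class:`PotentialSpec`."""

    def __init__(self, spec: PotentialSpec):
        spec.validate()
        self.spec = spec
        self.dimension = spec.dimension
        self._eps = spec.effective_well_depth
        if spec.kind == RADIAL_FUNNEL:
            self._w = spec.wall_width
            self._r0 = spec.bound_radius - spec.wall_half_width
        else:
            self._a = spec.bound_radius
            self._alpha = spec.stiffness / (2.0 * self._eps)

    # radial profile (funnel) / 1-D profile (double well)
    def radial_energy(self, r):
        r = np.asarray(r, dtype=float)
        if self.spec.kind == RADIAL_FUNNEL:
            t = np.clip((r - self._r0) / self._w, 0.0, 1.0)
            return -self._eps * (1.0 - 3.0 * t**2 + 2.0 * t**3)
        x = r
        return -self._eps * (
            np.exp(-self._alpha * (x - self._a) ** 2)
            + np.exp(-self._alpha * (x + self._a) ** 2)
        )

    def radial_force(self, r):
        """-dU/dr (scalar radial force; negative = attractive/inward)."""
        r = np.asarray(r, dtype=float)
        if self.spec.kind == RADIAL_FUNNEL:
            t = (r - self._r0) / self._w
            inside = (t > 0.0) & (t < 1.0)
            t = np.clip(t, 0.0, 1.0)
            return np.where(inside, -(6.0 * self._eps / self._w) * t * (1.0 - t), 0.0)
        x = r
        g1 = np.exp(-self._alpha * (x - self._a) ** 2)
        g2 = np.exp(-self._alpha * (x + self._a) ** 2)
        return -2.0 * self._alpha * self._eps * ((x - self._a) * g1 + (x + self._a) * g2)

    def energy(self, position) -> float:
        x = np.atleast_1d(np.asarray(position, dtype=float))
        if self.spec.kind == RADIAL_FUNNEL:
            return float(self.radial_energy(np.linalg.norm(x)))
        return float(self.radial_energy(x[0]))

    def force(self, position) -> np.ndarray:
        x = np.atleast_1d(np.asarray(position, dtype=float))
        if self.spec.kind == RADIAL_FUNNEL:
            r = np.linalg.norm(x)
            if r == 0.0:
                return np.zeros(3)
            return float(self.radial_force(r)) * x / r
        return np.array([float(self.radial_force(x[0]))])

    def __call__(self, position):
        return self.energy(position), self.force(position)


def make_potential(spec: PotentialSpec) -> Potential:
    """Build the callable potential; raises ConfigurationError on bad specs."""
    return Potential(spec)


# ---------------------------------------------------------------------------
# Overdamped Langevin propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LangevinParams:
    """Euler–Maruyama parameters, reduced units (kT = 1 by default).

    ``record_stride_fine`` is the archive recording stride (the analogue of
    the engine's fine trajectory output); ``record_stride_rank`` is the
    snapshot stride used for ranking in the adaptive-sampling loop (the
    analogue of snapshots sampled every 1 ps).  Both are in steps.
    """

    temperature_kT: float = 1.0
    diffusion: float = 0.3  # Å²/ps
    timestep: float = 0.001  # ps
    n_steps: int = 100_000
    record_stride_fine: int = 100  # -> 0.1 ps at default timestep
    record_stride_rank: int = 1000  # -> 1 ps at default timestep

    def validate(self) -> None:
        if self.temperature_kT <= 0 or self.diffusion <= 0 or self.timestep <= 0:
            raise ConfigurationError("temperature_kT, diffusion, timestep must be > 0")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be >= 0")
        if self.record_stride_fine < 1 or self.record_stride_rank < 1:
            raise ConfigurationError("record strides must be >= 1")
        if self.n_steps and self.n_steps % self.record_stride_fine:
            raise ConfigurationError(
                "n_steps must be a multiple of record_stride_fine"
            )

    def validate_against(self, spec: PotentialSpec) -> None:
        """Step-size sanity: one free-diffusion step must move well under the
        bound radius on average."""
        rms_step = math.sqrt(2.0 * self.diffusion * self.timestep)
        if rms_step >= 0.1 * spec.bound_radius:
            raise ConfigurationError(
                f"timestep too large: rms free step {rms_step:.3f} Å is not "
                f"< 0.1 x bound_radius ({0.1 * spec.bound_radius:.3f} Å)"
            )

    @property
    def fine_interval_ps(self) -> float:
        return self.timestep * self.record_stride_fine

    @property
    def rank_interval_ps(self) -> float:
        return self.timestep * self.record_stride_rank


@dataclass(frozen=True)
class EngineState:
    """A walker configuration: position (Å), time (ps), provenance stamp."""

    position: np.ndarray
    time: float = 0.0
    rng_stamp: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.atleast_1d(np.asarray(self.position, dtype=float))
        )


@dataclass
class Segment:
    """A recorded trajectory segment: times (ps), positions, and the
    dissociation coordinate (distance from the origin) per recorded frame."""

    times: np.ndarray
    positions: np.ndarray
    cv: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_position(self) -> np.ndarray:
        return self.positions[-1]


@njit(cache=True)
def _step_radial_funnel(x, n_steps, dt, mob, sig, eps, r0, w, wall, stride, noise, out):
    rec = 1
    for s in range(n_steps):
        r = math.sqrt(x[0] * x[0] + x[1] * x[1] + x[2] * x[2])
        fmag = 0.0
        if r0 < r < r0 + w:
            t = (r - r0) / w
            fmag = -(6.0 * eps / w) * t * (1.0 - t)
        for k in range(3):
            drift = 0.0
            if r > 0.0:
                drift = mob * fmag * x[k] / r
            x[k] += drift * dt + sig * noise[s, k]
        r = math.sqrt(x[0] * x[0] + x[1] * x[1] + x[2] * x[2])
        if r > wall:
            f = (2.0 * wall - r) / r
            for k in range(3):
                x[k] *= f
        if (s + 1) % stride == 0:
            for k in range(3):
                out[rec, k] = x[k]
            rec += 1


@njit(cache=True)
def _step_double_well(x, n_steps, dt, mob, sig, eps, a, alpha, wall, stride, noise, out):
    rec = 1
    for s in range(n_steps):
        d1 = x[0] - a
        d2 = x[0] + a
        f = -2.0 * alpha * eps * (
            d1 * math.exp(-alpha * d1 * d1) + d2 * math.exp(-alpha * d2 * d2)
        )
        x[0] += mob * f * dt + sig * noise[s, 0]
        if x[0] > wall:
            x[0] = 2.0 * wall - x[0]
        elif x[0] < -wall:
            x[0] = -2.0 * wall - x[0]
        if (s + 1) % stride == 0:
            out[rec, 0] = x[0]
            rec += 1


def propagate(
    potential,
    state: EngineState,
    params: LangevinParams,
    rng_seed: int | Sequence[int],
) -> Segment:
    """Run Euler–Maruyama overdamped Langevin dynamics from ``state``.

    Returns a segment of ``n_steps / record_stride_fine + 1`` frames
    including the initial state.  The same ``rng_seed`` yields a
    bit-identical segment.  Positions are reflected at the outer wall.
    """
    params.validate()
    spec = getattr(potential, "spec", None)
    if spec is not None:
        params.validate_against(spec)
    dim = getattr(potential, "dimension", None) or len(state.position)
    x0 = np.asarray(state.position, dtype=float).copy()
    if len(x0) != dim:
        raise ConfigurationError(
            f"state position has dimension {len(x0)}, potential expects {dim}"
        )
    n_rec = (params.n_steps // params.record_stride_fine) if params.n_steps else 0
    out = np.empty((n_rec + 1, dim), dtype=float)
    out[0] = x0
    mob = params.diffusion / params.temperature_kT
    sig = math.sqrt(2.0 * params.diffusion * params.timestep)

    if params.n_steps:
        rng = np.random.default_rng(rng_seed)
        noise = rng.standard_normal((params.n_steps, dim))
        if spec is not None and spec.kind == RADIAL_FUNNEL:
            pot: Potential = potential
            _step_radial_funnel(
                x0, params.n_steps, params.timestep, mob, sig,
                pot._eps, pot._r0, pot._w, spec.wall_radius,
                params.record_stride_fine, noise, out,
            )
        elif spec is not None and spec.kind == DOUBLE_WELL:
            pot = potential
            _step_double_well(
                x0, params.n_steps, params.timestep, mob, sig,
                pot._eps, pot._a, pot._alpha, spec.wall_radius,
                params.record_stride_fine, noise, out,
            )
        else:
            _propagate_generic(potential, x0, params, mob, sig, noise, out)

    bad = ~np.all(np.isfinite(out), axis=1)
    if np.any(bad):
        step = int(np.argmax(bad)) * params.record_stride_fine
        raise PropagationError(f"non-finite position near step {step}")
    times = state.time + params.fine_interval_ps * np.arange(n_rec + 1)
    cv = np.linalg.norm(out, axis=1) if dim > 1 else np.abs(out[:, 0])
    return Segment(times=times, positions=out, cv=cv)


def _propagate_generic(potential, x, params, mob, sig, noise, out) -> None:
    """Pure-Python fallback for user-supplied potentials (tests, custom wells)."""
    wall = getattr(getattr(potential, "spec", None), "wall_radius", None)
    rec = 1
    for s in range(params.n_steps):
        f = np.asarray(potential.force(x), dtype=float)
        if not np.all(np.isfinite(f)):
            raise PropagationError(f"non-finite force at step {s}")
        x += mob * f * params.timestep + sig * noise[s]
        if wall is not None:
            r = np.linalg.norm(x)
            if r > wall:
                x *= (2.0 * wall - r) / r
        if (s + 1) % params.record_stride_fine == 0:
            out[rec] = x
            rec += 1


# ---------------------------------------------------------------------------
# Analytic reference (quadrature oracle)
# ---------------------------------------------------------------------------


@dataclass
class ReferenceResult:
    """Quadrature reference for the MSM stage (all energies in kT).

    ``pmf`` is the per-bin free energy -kT ln p_bin (min shifted to zero) on
    bins of width ``grid_step`` covering [0, wall_radius]; for the radial
    funnel p_bin includes the 4πr² Jacobian, so it is directly comparable to
    the stationary distribution of microstates along d.

    ``delta_G_bind_standard`` is the reference for the bound-volume-corrected
    estimator: -ΔW - kT ln(V_bound/V°) with ΔW the exact flat-tail offset of
    the potential of mean force above its minimum and V_bound the analytically
    known volume of the bound region (the sphere of radius ``boundary``).
    ``delta_G_bind_standard_exact`` is the direct Boltzmann-integral form
    -kT ln(Z_bound/V°); the two coincide in the square-well limit.
    """

    centers: np.ndarray
    edges: np.ndarray
    bin_prob: np.ndarray
    pmf: np.ndarray
    boundary: float
    p_bound: float
    delta_W: float
    bound_volume: float
    delta_G_bind: float
    delta_G_bind_standard: float
    delta_G_bind_standard_exact: float
    temperature_kT: float


def radial_binding_quadrature(
    u_of_r: Callable[[float], float],
    boundary: float,
    wall_radius: float,
    temperature_kT: float = 1.0,
    points: Sequence[float] | None = None,
) -> tuple[float, float, float, float]:
    """Boltzmann quadrature for a radial potential (u in kT-compatible units).

    Returns (Z_bound, Z_unbound, delta_G_bind, delta_G_bind_standard) where
    Z = ∫ 4πr² exp(-u(r)/kT) dr over [0, boundary] / [boundary, wall] and

        delta_G_bind          = -kT ln(Z_b / Z_u)
        delta_G_bind_standard = -kT ln(Z_b / V°)   (V° = 1661 Å³)

    The standard form assumes u -> 0 in the unbound region (the convention
    the flat-tail profile offset realizes in the sampled pipeline).
    """
    beta = 1.0 / temperature_kT

    def integrand(r: float) -> float:
        return 4.0 * math.pi * r * r * math.exp(-beta * u_of_r(r))

    def _quad(lo: float, hi: float) -> float:
        pts = [p for p in (points or []) if lo < p < hi]
        val, _ = integrate.quad(integrand, lo, hi, points=pts or None, limit=200)
        return val

    z_b = _quad(0.0, boundary)
    z_u = _quad(boundary, wall_radius)
    dg_bind = -temperature_kT * math.log(z_b / z_u)
    dg_std = -temperature_kT * math.log(z_b / STANDARD_STATE_VOLUME_A3)
    return z_b, z_u, dg_bind, dg_std


def analytic_reference(
    spec: PotentialSpec,
    temperature_kT: float = 1.0,
    grid_step: float = 0.5,
    boundary: float | None = None,
) -> ReferenceResult:
    """Numerical-quadrature oracle: reference profile and binding free energy.

    ``boundary`` defaults to the radius at which the potential becomes flat
    (the exact analogue of "the region before the free energy curve becomes
    flat").
    """
    pot = make_potential(spec)
    if grid_step >= spec.bound_radius:
        raise ResolutionError(
            f"grid_step {grid_step} Å must be finer than bound_radius "
            f"{spec.bound_radius} Å"
        )
    if boundary is None:
        boundary = min(spec.flat_radius, spec.wall_radius)
    beta = 1.0 / temperature_kT
    edges = np.arange(0.0, spec.wall_radius + 0.5 * grid_step, grid_step)
    if edges[-1] < spec.wall_radius:
        edges = np.append(edges, spec.wall_radius)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if spec.kind == RADIAL_FUNNEL:
        def integrand(r):
            return 4.0 * math.pi * r * r * np.exp(-beta * pot.radial_energy(r))
    else:
        # 1-D |x| coordinate: both half-lines contribute equally, no Jacobian
        def integrand(r):
            return 2.0 * np.exp(-beta * pot.radial_energy(r))

    fine = np.linspace(0.0, spec.wall_radius, 20001)
    dens = integrand(fine)
    cum = integrate.cumulative_trapezoid(dens, fine, initial=0.0)
    total = cum[-1]
    bin_mass = np.interp(edges[1:], fine, cum) - np.interp(edges[:-1], fine, cum)
    bin_prob = bin_mass / total
    with np.errstate(divide="ignore"):
        pmf = -temperature_kT * np.log(bin_prob)
    pmf -= pmf.min()

    z_b = float(np.interp(boundary, fine, cum))
    # integrate the tail directly: total - z_b cancels catastrophically
    # when the well is deep
    tail_mask = fine >= boundary
    z_u = float(np.trapezoid(dens[tail_mask], fine[tail_mask]))
    p_bound = z_b / (z_b + z_u)
    delta_G_bind = -temperature_kT * math.log(z_b / z_u)
    dg_std_exact = -temperature_kT * math.log(z_b / STANDARD_STATE_VOLUME_A3)
    # Flat-tail offset of the PMF above its minimum (the tail potential is
    # exactly zero by construction) and the analytic bound-region volume.
    delta_w = float(-np.min(pot.radial_energy(fine)))
    if spec.kind == RADIAL_FUNNEL:
        bound_volume = (4.0 / 3.0) * math.pi * boundary**3
    else:
        bound_volume = 2.0 * boundary
    dg_std = -delta_w - temperature_kT * math.log(
        bound_volume / STANDARD_STATE_VOLUME_A3
    )
    return ReferenceResult(
        centers=centers,
        edges=edges,
        bin_prob=bin_prob,
        pmf=pmf,
        boundary=float(boundary),
        p_bound=p_bound,
        delta_W=delta_w,
        bound_volume=bound_volume,
        delta_G_bind=delta_G_bind,
        delta_G_bind_standard=dg_std,
        delta_G_bind_standard_exact=dg_std_exact,
        temperature_kT=temperature_kT,
    )


# ---------------------------------------------------------------------------
# Synthetic solvated structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeadSet:
    """A labeled cluster of solute beads (centers in Å, radii in Å)."""

    label: str
    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "centers", np.asarray(self.centers, dtype=float).reshape(-1, 3)
        )
        radii = np.broadcast_to(
            np.asarray(self.radii, dtype=float), (len(self.centers),)
        ).copy()
        object.__setattr__(self, "radii", radii)


@dataclass(frozen=True)
class SolvatedSystemSpec:
    """Synthetic solvated system: two solute bead clusters plus point waters
    whose density in the 0–3 Å and 3–6 Å shells (distances measured to the
    nearest bead center) is a controllable multiple of the bulk density.

    A shell multiplier > 1 emulates the pressure-induced increase of water
    density around protein surfaces relative to bulk.
    """

    solute_bead_sets: tuple[BeadSet, BeadSet]
    box: np.ndarray
    water_count: int
    shell_density_multipliers: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    first_shell: float = 3.0
    second_shell: float = 6.0
    mc_samples: int = 200_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "box", np.asarray(self.box, dtype=float).reshape(3))

    def validate(self) -> None:
        if self.water_count < 0:
            raise ConfigurationError("water_count must be >= 0")
        if any(m < 0 for m in self.shell_density_multipliers):
            raise ConfigurationError("shell density multipliers must be >= 0")
        for bs in self.solute_bead_sets:
            if np.any(bs.centers < 0) or np.any(bs.centers > self.box):
                raise ConfigurationError(f"bead set {bs.label!r} has beads outside the box")
            if np.any(bs.radii < 0):
                raise ConfigurationError("bead radii must be >= 0")


def _classify_regions(points: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                      r1: float, r2: float, chunk: int = 50_000) -> np.ndarray:
    """Region codes: -1 inside a bead, 0 first shell, 1 second shell, 2 bulk.

    Distances are measured to bead centers; chunked so the pairwise matrix
    stays small for large point sets.
    """
    region = np.full(len(points), 2, dtype=np.int8)
    for start in range(0, len(points), chunk):
        pts = points[start : start + chunk]
        diff = pts[:, None, :] - centers[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=2))
        inside = np.any(dist < radii[None, :], axis=1)
        mind = dist.min(axis=1)
        reg = np.full(len(pts), 2, dtype=np.int8)
        reg[mind <= r2] = 1
        reg[mind <= r1] = 0
        reg[inside] = -1
        region[start : start + chunk] = reg
    return region


def generate_solvated_structure(spec: SolvatedSystemSpec) -> Structure:
    """Generate a solvated toy structure.

    Solute beads become two chains of carbon pseudo-atoms; waters are
    oxygen-only HOH residues on chain W.  Water counts per shell are drawn
    from Poisson distributions with mean multiplier × bulk_density × shell
    volume (shell volumes estimated by hit-or-miss Monte Carlo under the
    same seed), realized by inverse-CDF so that raising a multiplier with
    the seed fixed can only increase the corresponding shell count.
    """
    from scipy import stats

    spec.validate()
    rng = np.random.default_rng([spec.seed, 0x501F])
    centers = np.concatenate([bs.centers for bs in spec.solute_bead_sets])
    radii = np.concatenate([bs.radii for bs in spec.solute_bead_sets])
    box_volume = float(np.prod(spec.box))

    # Monte-Carlo region volumes (fixed sub-seed for reproducibility)
    mc_rng = np.random.default_rng([spec.seed, 0xA3])
    mc_points = mc_rng.random((spec.mc_samples, 3)) * spec.box
    mc_region = _classify_regions(mc_points, centers, radii, spec.first_shell, spec.second_shell)
    frac = np.array([np.mean(mc_region == code) for code in (0, 1, 2)])
    v_shell1, v_shell2, v_bulk = frac * box_volume
    if spec.water_count and v_bulk <= 0:
        raise PlacementError("box leaves no bulk volume for waters")

    rho_nominal = spec.water_count / box_volume
    m1, m2 = spec.shell_density_multipliers
    lam = np.array([m1 * rho_nominal * v_shell1, m2 * rho_nominal * v_shell2])
    # Inverse-CDF Poisson: monotone coupling in the multipliers under a seed.
    u = rng.random(2)
    n_shell = np.array(
        [int(stats.poisson.ppf(u[i], lam[i])) if lam[i] > 0 else 0 for i in range(2)]
    )
    n_bulk = spec.water_count - int(n_shell.sum())
    if n_bulk < 0:
        raise PlacementError(
            "shell multipliers demand more waters than water_count provides"
        )

    waters = []
    for code, count in ((0, n_shell[0]), (1, n_shell[1]), (2, n_bulk)):
        placed = 0
        attempts = 0
        pts: list[np.ndarray] = []
        while placed < count:
            batch = max(4 * (count - placed), 1024)
            cand = rng.random((batch, 3)) * spec.box
            keep = cand[_classify_regions(cand, centers, radii,
                                          spec.first_shell, spec.second_shell) == code]
            take = keep[: count - placed]
            pts.append(take)
            placed += len(take)
            attempts += batch
            if attempts > 200 * max(count, 1) + 1_000_000:
                raise PlacementError(
                    f"could not place {count} waters in region {code}; "
                    "box too small or region empty"
                )
        if count:
            waters.append(np.concatenate(pts))
    water_coords = np.concatenate(waters) if waters else np.empty((0, 3))

    parts = []
    for bs in spec.solute_bead_sets:
        n = len(bs.centers)
        parts.append(
            Structure(
                names=np.full(n, "C"),
                elements=np.full(n, "C"),
                resnames=np.full(n, "BEA"),
                resids=np.arange(1, n + 1),
                chains=np.full(n, bs.label),
                coords=bs.centers,
            )
        )
    nw = len(water_coords)
    if nw:
        parts.append(
            Structure(
                names=np.full(nw, "O"),
                elements=np.full(nw, "O"),
                resnames=np.full(nw, "HOH"),
                resids=np.arange(1, nw + 1),
                chains=np.full(nw, "W"),
                coords=water_coords,
            )
        )
    return concatenate(parts, box=spec.box.copy())
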