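"""End-to-end toy pipeline: adaptive sampling → MSM → binding free energy.

This is the glue the demo CLI and the reproduction script drive: build the
pressure-parameterized toy complex, dissociate it by cascade selection,
estimate per-trial Markov state models on the dissociation coordinate, and
reduce them to a profile and a standard binding free energy, next to the
quadrature reference for the same potential.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_system import (
    LangevinParams,
    PotentialSpec,
    analytic_reference,
    make_potential,
)
from .msm import (
    BindingFreeEnergy,
    FreeEnergyProfile,
    Microstates,
    binding_free_energy,
    build_transition_model,
    cluster_microstates,
    detect_flat_boundary,
    free_energy_profile,
    implied_timescales,
    stationary_distribution,
    stratified_subsample,
)
from .pacs import CycleConfig, PacsArchive, ToyEngine, run_trials


@dataclass
class MsmSettings:
    """MSM stage knobs: state count, lag (ps), estimator, hull stride."""

    k: int = 30
    lag_ps: float = 1.0
    estimator: str = "reversible"
    hull_stride_ps: float = 2.0
    boundary: float | str = "auto"
    timescale_lags_ps: tuple[float, ...] = (0.5, 1.0, 2.0)
    grid_step: float = 1.0
    cluster_band_cap: int = 3000
    boundary_slope_tol: float | None = 0.25
    seed: int = 0


@dataclass
class PipelineResult:
    pressure: float
    archive: PacsArchive
    profile: FreeEnergyProfile
    binding: BindingFreeEnergy
    reference_delta_G_standard: float
    timescales_converged: bool
    n_cycles: dict[int, int] = field(default_factory=dict)


def msm_binding_free_energy(
    archive: PacsArchive,
    settings: MsmSettings,
    temperature_kT: float = 1.0,
) -> tuple[FreeEnergyProfile, BindingFreeEnergy, bool]:
    """Per-trial MSMs on the archive, cross-trial profile, Eq. 2/3 outputs.

    Clustering and MSM construction are done independently per trial (each
    dissociation simulation yields its own microstates), then profiles are
    averaged on a common grid and the bound-volume hulls are averaged
    before the standard-state correction.
    """
    stride = archive.fine_interval_ps
    trials_models: list[tuple[Microstates, np.ndarray, np.ndarray]] = []
    converged = True
    for trial in archive.trials:
        cvs = archive.cv_segments(trial)
        pooled = stratified_subsample(
            np.concatenate(cvs), per_band=settings.cluster_band_cap,
            seed=settings.seed + trial,
        )
        ms = cluster_microstates(pooled, k=settings.k, seed=settings.seed + trial)
        assigns = [ms.assign(c) for c in cvs]
        model = build_transition_model(
            assigns, settings.lag_ps, stride=stride, n_states=ms.k,
            estimator=settings.estimator,
        )
        pi = stationary_distribution(model)
        trials_models.append((ms, pi, model.active_set))
        its = implied_timescales(
            assigns, settings.timescale_lags_ps, stride=stride, n_states=ms.k,
            estimator=settings.estimator,
        )
        converged = converged and bool(its["converged"].iloc[0])

    profile = free_energy_profile(
        trials_models, temperature_kT=temperature_kT, geometry="radial_3d",
        grid_step=settings.grid_step,
    )
    boundary = settings.boundary
    boundary_val = (
        detect_flat_boundary(profile, slope_tol=settings.boundary_slope_tol)
        if boundary == "auto"
        else float(boundary)
    )
    bound_points = []
    for trial in archive.trials:
        pts = archive.positions(trial, settings.hull_stride_ps)
        r = np.linalg.norm(pts, axis=1)
        bound_points.append(pts[r <= boundary_val])
    binding = binding_free_energy(
        profile, trials_models, bound_points, boundary=boundary_val,
        temperature_kT=temperature_kT,
    )
    return profile, binding, converged


def run_toy_pipeline(
    pressures: Sequence[float] = (0.1, 50.0, 100.0),
    seed: int = 1,
    potential_spec: PotentialSpec | None = None,
    langevin: LangevinParams | None = None,
    config: CycleConfig | None = None,
    msm_settings: MsmSettings | None = None,
) -> list[PipelineResult]:
    """Dissociate the toy complex at each pressure and estimate ΔG°_bind.

    All randomness descends from ``seed``; the same seed reproduces the
    results bit-for-bit.  Energies are in kT (reduced units).
    """
    base_spec = potential_spec or PotentialSpec()
    langevin = langevin or LangevinParams()
    config = config or CycleConfig()
    msm_settings = msm_settings or MsmSettings(seed=seed)
    results = []
    for pressure in pressures:
        spec = PotentialSpec(
            kind=base_spec.kind,
            well_depth_0=base_spec.well_depth_0,
            pressure=pressure,
            pressure_coefficient=base_spec.pressure_coefficient,
            bound_radius=base_spec.bound_radius,
            wall_radius=base_spec.wall_radius,
            stiffness=base_spec.stiffness,
        )
        potential = make_potential(spec)
        # identical base seed at every pressure: replica noise streams are
        # paired across pressures, so each trial is a paired replication
        engine = ToyEngine(potential, langevin, base_seed=seed)
        archive = run_trials(engine, np.zeros(3), config)
        profile, binding, converged = msm_binding_free_energy(
            archive, msm_settings, temperature_kT=langevin.temperature_kT
        )
        ref = analytic_reference(spec, temperature_kT=langevin.temperature_kT)
        results.append(
            PipelineResult(
                pressure=pressure,
                archive=archive,
                profile=profile,
                binding=binding,
                reference_delta_G_standard=ref.delta_G_bind_standard,
                timescales_converged=converged,
                n_cycles={t: archive.n_cycles(t) for t in archive.trials},
            )
        )
    return results
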