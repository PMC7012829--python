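"""Markov-state-model estimation of the free-energy profile and binding
free energy along the dissociation coordinate.

Pipeline: k-means microstates on the pooled coordinate samples, lagged
transition counts that never cross segment boundaries, a reversible
transition-matrix estimator, implied-timescale validation, the profile
-kT ln π, and the bound/unbound free-energy difference

    ΔG_bind = -kT ln(P_b / P_u)

plus the standard-state form with the bound-volume correction

    ΔG°_bind = -ΔW - kT ln(V_b / V°),   V° = 1661 Å³,

where V_b is the convex-hull volume of the ligand-COM positions sampled in
the bound state (receptor COM at the origin) and ΔW is the offset of the
flat unbound tail of the profile above the bound minimum.

Estimators
----------
``reversible`` (default): maximum-likelihood reversible transition matrix
(self-consistent fixed-point iteration).  Its stationary distribution is
consistent even when the trajectory pool is adaptively biased, as
cascade-selection archives always are.  ``symmetrized``: row-normalized
(C+Cᵀ)/2 — detailed balance by construction, but its stationary vector is
the empirical visitation frequency, appropriate only for equilibrium
trajectory pools.  ``nonreversible``: row-normalized raw counts.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError

from .constants import STANDARD_STATE_VOLUME_A3


class ClusteringError(ValueError):
    pass


class EstimationError(RuntimeError):
    pass


class ConnectivityError(RuntimeError):
    pass


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Microstates
# ---------------------------------------------------------------------------


@dataclass
class Microstates:
    """1-D microstates: sorted k-means centers with nearest-center assignment."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).ravel()
        if len(self.centers) < 2:
            raise ClusteringError("need at least 2 microstates")
        if np.any(np.diff(self.centers) <= 0):
            raise ClusteringError("centers must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.centers)

    @property
    def edges(self) -> np.ndarray:
        """Voronoi cell edges on the coordinate axis, clipped at zero."""
        mids = 0.5 * (self.centers[:-1] + self.centers[1:])
        lo = max(0.0, self.centers[0] - (mids[0] - self.centers[0]))
        hi = self.centers[-1] + (self.centers[-1] - mids[-1])
        return np.concatenate([[lo], mids, [hi]])

    def assign(self, samples: np.ndarray) -> np.ndarray:
        """Nearest-center indices for coordinate samples."""
        samples = np.asarray(samples, dtype=float)
        mids = 0.5 * (self.centers[:-1] + self.centers[1:])
        return np.searchsorted(mids, samples)

    def shell_volumes(self, geometry: str = "radial_3d") -> np.ndarray:
        """Configurational volume of each Voronoi cell (Å³ for radial_3d,
        Å for linear); used to convert state probabilities to densities."""
        e = self.edges
        if geometry == "radial_3d":
            return (4.0 / 3.0) * np.pi * (e[1:] ** 3 - e[:-1] ** 3)
        if geometry == "linear":
            return np.diff(e)
        raise ValueError(f"unknown geometry {geometry!r}")


def cluster_microstates(
    cv_samples: np.ndarray, k: int = 30, seed: int = 0
) -> Microstates:
    """k-means microstates (k-means++ init under ``seed``) on the pooled
    dissociation-coordinate samples."""
    from sklearn.cluster import KMeans

    cv_samples = np.asarray(cv_samples, dtype=float).ravel()
    distinct = np.unique(cv_samples)
    if len(distinct) < k:
        raise ClusteringError(
            f"need at least {k} distinct samples, got {len(distinct)}"
        )
    if len(distinct) == k:
        return Microstates(centers=np.sort(distinct))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(cv_samples.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    if np.any(np.diff(centers) <= 0):  # merge pathological duplicates
        centers = np.unique(centers)
        if len(centers) < k:
            raise ClusteringError("k-means produced duplicate centers")
    return Microstates(centers=centers)


def stratified_subsample(
    cv_samples: np.ndarray,
    per_band: int = 3000,
    band_width: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Cap the sample count per coordinate band.

    Adaptive-sampling archives can be overwhelmingly dominated by the region
    where the walkers stall; capping each ``band_width`` Å band at
    ``per_band`` samples gives the clustering a pool that resolves the whole
    dissociation path instead of spending nearly all microstates on the
    most-visited basin.  Only clustering uses the balanced pool; transition
    counting always uses the full archive.
    """
    cv_samples = np.asarray(cv_samples, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    bands = np.floor(cv_samples / band_width).astype(np.int64)
    keep = []
    for b in np.unique(bands):
        idx = np.flatnonzero(bands == b)
        if len(idx) > per_band:
            idx = rng.choice(idx, per_band, replace=False)
        keep.append(idx)
    return cv_samples[np.sort(np.concatenate(keep))]


def kmeans_objective(samples: np.ndarray, centers: np.ndarray) -> float:
    """Within-cluster sum of squared distances (1-D)."""
    samples = np.asarray(samples, dtype=float).ravel()
    d = np.abs(samples[:, None] - np.asarray(centers).ravel()[None, :])
    return float((d.min(axis=1) ** 2).sum())


# ---------------------------------------------------------------------------
# Transition model
# ---------------------------------------------------------------------------


@dataclass
class TransitionModel:
    lag: float  # in the time unit of `stride`
    stride: float
    count_matrix: np.ndarray  # raw counts, full k x k
    transition_matrix: np.ndarray  # on the active set
    active_set: np.ndarray
    estimator: str
    pi_active: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.count_matrix.shape[0]


def _count_transitions(
    assignments: Sequence[np.ndarray], lag_steps: int, n_states: int
) -> np.ndarray:
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    for seg in assignments:
        seg = np.asarray(seg, dtype=np.int64)
        if len(seg) <= lag_steps:
            continue
        np.add.at(counts, (seg[:-lag_steps], seg[lag_steps:]), 1)
    return counts


def _reversible_mle(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000):
    """Self-consistent reversible maximum-likelihood estimator.

    Iterates x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j) to convergence;
    T_ij = x_ij / x_i and π_i = x_i / Σx.
    """
    c = counts.astype(float)
    c_row = c.sum(axis=1)
    x = c + c.T
    for _ in range(max_iter):
        x_row = x.sum(axis=1)
        denom = (c_row / x_row)[:, None] + (c_row / x_row)[None, :]
        x_new = np.where(denom > 0, (c + c.T) / np.where(denom > 0, denom, 1.0), 0.0)
        delta = np.max(np.abs(x_new - x)) / max(x_new.max(), 1e-300)
        x = x_new
        if delta < tol:
            break
    x_row = x.sum(axis=1)
    t = x / x_row[:, None]
    pi = x_row / x_row.sum()
    return t, pi


def build_transition_model(
    assignments: Sequence[np.ndarray],
    lag: float,
    stride: float = 1.0,
    n_states: int | None = None,
    estimator: str = "reversible",
) -> TransitionModel:
    """Lagged transition model from time-ordered state indices.

    ``assignments`` is a list of per-segment index arrays sampled every
    ``stride`` time units; counting uses a sliding window and never crosses
    segment boundaries.  The model is restricted to the largest connected
    component of the symmetrized count graph.
    """
    if estimator not in ("reversible", "symmetrized", "nonreversible"):
        raise ValueError(f"unknown estimator {estimator!r}")
    ratio = lag / stride
    lag_steps = int(round(ratio))
    if lag_steps < 1 or abs(ratio - lag_steps) > 1e-9:
        raise ValueError(f"lag {lag} must be a positive multiple of the stride {stride}")
    assignments = [np.asarray(a, dtype=np.int64) for a in assignments]
    if n_states is None:
        n_states = int(max((a.max() for a in assignments if len(a)), default=-1)) + 1
    counts = _count_transitions(assignments, lag_steps, n_states)
    if counts.sum() == 0:
        raise EstimationError(f"no transitions observed at lag {lag}")

    sym = counts + counts.T
    n_comp, labels = connected_components(sym > 0, directed=False)
    occupied = sym.sum(axis=1) > 0
    sizes = np.bincount(labels[occupied], minlength=n_comp) if occupied.any() else []
    largest = int(np.argmax(sizes))
    active = np.flatnonzero((labels == largest) & occupied)
    sub = counts[np.ix_(active, active)]

    pi = None
    if estimator == "reversible":
        t, pi = _reversible_mle(sub)
    elif estimator == "symmetrized":
        s = (sub + sub.T) / 2.0
        rows = s.sum(axis=1)
        t = s / rows[:, None]
        pi = rows / rows.sum()
    else:
        rows = sub.sum(axis=1).astype(float)
        t = sub / np.where(rows > 0, rows, 1.0)[:, None]

    return TransitionModel(
        lag=lag, stride=stride, count_matrix=counts, transition_matrix=t,
        active_set=active, estimator=estimator, pi_active=pi,
    )


def stationary_distribution(model: TransitionModel) -> np.ndarray:
    """Stationary distribution over the active set (left eigenvector for
    eigenvalue 1, or the closed form carried by reversible estimators)."""
    if model.pi_active is not None:
        return model.pi_active
    t = model.transition_matrix
    n_comp, _ = connected_components(t > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ConnectivityError(
            f"transition matrix is reducible ({n_comp} strong components)"
        )
    vals, vecs = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def implied_timescales(
    assignments: Sequence[np.ndarray],
    lags: Sequence[float],
    n_timescales: int = 3,
    stride: float = 1.0,
    n_states: int | None = None,
    estimator: str = "reversible",
    flatness_tol: float = 0.10,
) -> pd.DataFrame:
    """Implied timescales t_i(τ) = -τ / ln λ_i(τ) for a list of lag times.

    Returns a tidy table (lag, index, timescale, converged): ``converged``
    is True on every row when the slowest timescale varies by less than
    ``flatness_tol`` between the last two lags.
    """
    if len(lags) < 2:
        raise ValueError("need at least 2 lag times")
    rows = []
    top_by_lag = []
    for lag in lags:
        model = build_transition_model(
            assignments, lag, stride=stride, n_states=n_states, estimator=estimator
        )
        vals = np.linalg.eigvals(model.transition_matrix)
        if np.any(np.abs(np.imag(vals)) > 1e-8):
            warnings.warn(
                "complex transition-matrix eigenvalues; using magnitudes",
                RuntimeWarning,
            )
        mags = np.abs(vals)
        mags = np.sort(mags)[::-1]
        below = mags[(mags < 1.0 - 1e-12) & (mags > 0.0)]
        ts = -lag / np.log(below[:n_timescales])
        top_by_lag.append(ts[0] if len(ts) else np.nan)
        for i, t in enumerate(ts):
            rows.append(dict(lag=lag, index=i + 1, timescale=float(t)))
    t_last, t_prev = top_by_lag[-1], top_by_lag[-2]
    converged = bool(
        np.isfinite(t_last) and np.isfinite(t_prev)
        and abs(t_last - t_prev) / max(abs(t_prev), 1e-300) < flatness_tol
    )
    df = pd.DataFrame(rows)
    df["converged"] = converged
    return df


# ---------------------------------------------------------------------------
# Free-energy profile
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyProfile:
    """Profile along the dissociation coordinate.

    ``pmf`` is -kT ln π per microstate interpolated to the common grid;
    ``pmf_density`` divides π by each state's configurational (shell)
    volume first, removing the 4πd² geometric growth so that the unbound
    tail is flat — that is the curve used for flat-tail detection and ΔW.
    Both are shifted to min = 0.  Mean and SD are across trials.
    """

    grid: np.ndarray
    pmf_mean: np.ndarray
    pmf_sd: np.ndarray
    pmf_density_mean: np.ndarray
    pmf_density_sd: np.ndarray
    per_trial_pmf: np.ndarray
    per_trial_pmf_density: np.ndarray
    temperature_kT: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_angstrom": self.grid,
                "pmf": self.pmf_mean,
                "sd": self.pmf_sd,
                "pmf_density": self.pmf_density_mean,
                "sd_density": self.pmf_density_sd,
            }
        )


def _single_profile(
    microstates: Microstates,
    pi: np.ndarray,
    active_set: np.ndarray,
    temperature_kT: float,
    geometry: str,
):
    centers = microstates.centers[active_set]
    volumes = microstates.shell_volumes(geometry)[active_set]
    good = pi > 0
    if not np.all(good):
        warnings.warn(
            f"{np.count_nonzero(~good)} zero-probability microstates excluded",
            RuntimeWarning,
        )
    centers, pi, volumes = centers[good], pi[good], volumes[good]
    pmf = -temperature_kT * np.log(pi)
    pmf_density = -temperature_kT * np.log(pi / volumes)
    return centers, pmf - pmf.min(), pmf_density - pmf_density.min()


def free_energy_profile(
    trials: Sequence[tuple[Microstates, np.ndarray, np.ndarray]],
    temperature_kT: float = 1.0,
    geometry: str = "radial_3d",
    grid_step: float = 1.0,
) -> FreeEnergyProfile:
    """Cross-trial profile: per-trial (microstates, π, active_set) profiles
    are linearly interpolated onto a common ``grid_step`` grid, then
    averaged; the SD across trials is reported alongside."""
    if not trials:
        raise ValueError("need at least one trial")
    per = [
        _single_profile(ms, pi, act, temperature_kT, geometry)
        for ms, pi, act in trials
    ]
    lo = max(c[0] for c, _, _ in per)
    hi = min(c[-1] for c, _, _ in per)
    if hi <= lo:
        raise EstimationError("trial profiles do not overlap on the coordinate")
    grid = np.arange(math.ceil(lo / grid_step) * grid_step, hi + 1e-9, grid_step)
    pmfs = np.stack([np.interp(grid, c, p) for c, p, _ in per])
    dens = np.stack([np.interp(grid, c, p) for c, _, p in per])
    pmfs -= pmfs.min(axis=1, keepdims=True)
    dens -= dens.min(axis=1, keepdims=True)
    return FreeEnergyProfile(
        grid=grid,
        pmf_mean=pmfs.mean(axis=0),
        pmf_sd=pmfs.std(axis=0),
        pmf_density_mean=dens.mean(axis=0),
        pmf_density_sd=dens.std(axis=0),
        per_trial_pmf=pmfs,
        per_trial_pmf_density=dens,
        temperature_kT=temperature_kT,
    )


def detect_flat_boundary(
    profile: FreeEnergyProfile,
    slope_tol: float | None = None,
    run_length: float = 5.0,
) -> float:
    """Smallest coordinate beyond which the density profile's slope stays
    below ``slope_tol`` (default 0.05 kT/Å) for ``run_length`` Å."""
    kT = profile.temperature_kT
    tol = slope_tol if slope_tol is not None else 0.05 * kT
    g = profile.grid
    y = profile.pmf_density_mean
    slopes = np.abs(np.diff(y) / np.diff(g))
    need = max(int(round(run_length / np.median(np.diff(g)))), 1)
    flat = slopes < tol
    for i in range(len(flat) - need + 1):
        if flat[i : i + need].all():
            return float(g[i])
    raise EstimationError(
        "no flat region found; the profile never levels off within the "
        "sampled range"
    )


# ---------------------------------------------------------------------------
# Binding free energy (Eq. 2 / Eq. 3 outputs)
# ---------------------------------------------------------------------------


@dataclass
class BindingFreeEnergy:
    boundary: float
    P_b: float
    P_u: float
    delta_G_bind: float
    delta_W: float
    V_b: float
    V_std: float
    delta_G_bind_standard: float
    temperature_kT: float
    per_trial_delta_G_bind: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_trial_V_b: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_trial_delta_G_bind_standard: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def delta_G_bind_standard_sd(self) -> float:
        if self.per_trial_delta_G_bind_standard.size < 2:
            return float("nan")
        return float(self.per_trial_delta_G_bind_standard.std(ddof=1))


def hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume (Å³) of 3-D points; degenerate input is an error."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
        raise GeometryError("need >= 4 three-dimensional points for a hull")
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:
        raise GeometryError(f"degenerate convex hull: {exc}") from exc


def binding_free_energy(
    profile: FreeEnergyProfile,
    trials: Sequence[tuple[Microstates, np.ndarray, np.ndarray]],
    bound_com_coordinates: Sequence[np.ndarray],
    boundary: float | str = "auto",
    temperature_kT: float = 1.0,
    delta_w_mode: str = "arithmetic",
) -> BindingFreeEnergy:
    """Bound/unbound partition and the standard binding free energy.

    P_b and P_u sum the stationary probabilities on each side of
    ``boundary`` (auto: flat-tail detection on the density profile).  ΔW is
    the mean of the flat-region density profile above its bound minimum
    (``delta_w_mode="weighted"`` uses the probability-weighted mean
    instead).  V_b is the convex-hull volume of the per-trial bound-state
    COM clouds, averaged across trials before the volume correction.
    """
    if isinstance(boundary, str):
        if boundary != "auto":
            raise ValueError(f"boundary must be a float or 'auto', got {boundary!r}")
        boundary_val = detect_flat_boundary(profile)
    else:
        boundary_val = float(boundary)
    if not (profile.grid[0] <= boundary_val <= profile.grid[-1]):
        raise ValueError(
            f"boundary {boundary_val} Å outside sampled range "
            f"[{profile.grid[0]}, {profile.grid[-1]}] Å"
        )
    kT = temperature_kT

    dgs, pbs = [], []
    for ms, pi, act in trials:
        centers = ms.centers[act]
        p_b = float(pi[centers <= boundary_val].sum())
        p_u = float(pi[centers > boundary_val].sum())
        if p_b <= 0 or p_u <= 0:
            raise EstimationError("boundary leaves an empty bound or unbound state")
        pbs.append(p_b / (p_b + p_u))
        dgs.append(-kT * math.log(p_b / p_u))
    p_b_mean = float(np.mean(pbs))
    delta_g_bind = float(np.mean(dgs))

    tail = profile.grid >= boundary_val
    if delta_w_mode == "arithmetic":
        delta_w = float(profile.pmf_density_mean[tail].mean())
    elif delta_w_mode == "weighted":
        w = np.exp(-profile.pmf_mean[tail] / kT)
        delta_w = float(np.average(profile.pmf_density_mean[tail], weights=w))
    else:
        raise ValueError(f"unknown delta_w_mode {delta_w_mode!r}")

    vbs = np.array([hull_volume(np.asarray(pts)) for pts in bound_com_coordinates])
    v_b = float(vbs.mean())
    v_std = STANDARD_STATE_VOLUME_A3
    dg_std = -delta_w - kT * math.log(v_b / v_std)
    # trial-to-trial spread: per-trial flat-tail offsets with per-trial hulls
    per_trial_dw = profile.per_trial_pmf_density[:, tail].mean(axis=1)
    if len(per_trial_dw) == len(vbs):
        per_trial_std = -per_trial_dw - kT * np.log(vbs / v_std)
    else:
        per_trial_std = -delta_w - kT * np.log(vbs / v_std)
    return BindingFreeEnergy(
        boundary=boundary_val,
        P_b=p_b_mean,
        P_u=1.0 - p_b_mean,
        delta_G_bind=delta_g_bind,
        delta_W=delta_w,
        V_b=v_b,
        V_std=v_std,
        delta_G_bind_standard=dg_std,
        temperature_kT=kT,
        per_trial_delta_G_bind=np.asarray(dgs),
        per_trial_V_b=vbs,
        per_trial_delta_G_bind_standard=per_trial_std,
    )
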