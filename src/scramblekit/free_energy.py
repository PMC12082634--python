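"""Free-energy profiles from headgroup densities, and their thermodynamics.

The transverse free-energy profile of a lipid headgroup is obtained by
Boltzmann inversion of its equilibrium number density, dG(z) = -RT
ln(rho(z)/rho0), with rho0 chosen so the global minimum is zero.  Densities
are histogrammed in a protein-fixed frame (z relative to the reference-group
centroid) because the membrane shape fluctuates.  Profiles measured at
several temperatures decompose into enthalpic and entropic parts by finite
differences, assuming the entropy is constant across each temperature pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import R_KJ
from .io import LipidSet, Profile1D, Trajectory

logger = logging.getLogger("scramblekit")

__all__ = [
    "FreeEnergyProfile",
    "ThermoDecomposition",
    "ThicknessBarrierFit",
    "density_profile",
    "boltzmann_invert",
    "barrier_height",
    "decompose_thermo",
    "fit_thickness_barrier",
    "predict_barrier_reduction",
]


@dataclass
class FreeEnergyProfile:
    """dG(z) in kJ/mol on a uniform z grid (nm, membrane frame).

    Unsampled bins carry +inf.  The finite minimum is zero by construction.
    ``unsampled_core`` flags interior unsampled bins, which make any barrier
    a lower bound.
    """

    z: np.ndarray
    dG: np.ndarray
    temperature: float
    error: np.ndarray | None = None
    unsampled_core: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        if self.z.shape != self.dG.shape:
            raise ValueError("grid and dG must have equal length")
        finite = np.isfinite(self.dG)
        if not finite.any():
            raise ValueError("profile has no finite values")
        if abs(self.dG[finite].min()) > 1e-9:
            raise ValueError("profile minimum must be zero (normalize first)")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if np.any(self.error[np.isfinite(self.error)] < 0):
                raise ValueError("errors must be non-negative")

    @classmethod
    def from_profile1d(cls, profile: Profile1D, temperature: float) -> "FreeEnergyProfile":
        """Treat a two-column profile (e.g. an imported PMF) as dG(z),
        shifting so its minimum is zero."""
        v = np.asarray(profile.values, dtype=float)
        finite = np.isfinite(v)
        return cls(
            z=profile.z,
            dG=v - v[finite].min(),
            temperature=temperature,
            error=profile.error,
        )


def density_profile(
    traj: Trajectory,
    selection: np.ndarray,
    reference: np.ndarray,
    n_slices: int = 300,
) -> Profile1D:
    """Time-averaged number density (1/nm^3) of the selected particles along
    z, measured relative to the per-frame centroid of the reference group.

    The grid spans the (mean) box height in ``n_slices`` uniform slices;
    relative z is wrapped into [-Lz/2, Lz/2).
    """
    selection = np.asarray(selection, dtype=np.intp)
    reference = np.asarray(reference, dtype=np.intp)
    if len(selection) == 0:
        raise ValueError("empty selection")
    if len(reference) == 0:
        raise ValueError("empty reference group")
    if n_slices < 10:
        raise ValueError("need at least 10 slices")
    lz = float(traj.box[:, 2].mean())
    lx = float(traj.box[:, 0].mean())
    ly = float(traj.box[:, 1].mean())
    edges = np.linspace(-lz / 2, lz / 2, n_slices + 1)
    z = traj.positions[:, selection, 2].astype(float)
    zref = traj.positions[:, reference, 2].astype(float).mean(axis=1)
    rel = (z - zref[:, None] + lz / 2) % lz - lz / 2
    counts, _ = np.histogram(rel.ravel(), bins=edges)
    dz = lz / n_slices
    density = counts / (traj.n_frames * lx * ly * dz)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(z=centers, values=density, unit="1/nm^3")


def boltzmann_invert(density: Profile1D, temperature: float) -> FreeEnergyProfile:
    """dG(z) = -RT ln(rho(z)/rho0), rho0 = max density so min dG = 0.

    Zero-density bins become +inf; interior unsampled bins (between the
    outermost sampled ones) set ``unsampled_core`` — the resulting barrier
    is then only a lower bound.
    """
    rho = np.asarray(density.values, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    if not np.any(rho > 0):
        raise ValueError("density is zero everywhere")
    rho0 = rho.max()
    with np.errstate(divide="ignore"):
        dg = -R_KJ * temperature * np.log(rho / rho0)
    sampled = np.flatnonzero(rho > 0)
    core = np.any(rho[sampled[0] : sampled[-1] + 1] == 0)
    if core:
        logger.warning("unsampled interior bins: barrier is a lower bound")
    return FreeEnergyProfile(
        z=density.z, dG=dg, temperature=temperature, unsampled_core=bool(core)
    )


def _mirror_value(profile: FreeEnergyProfile, z: float) -> float:
    finite = np.isfinite(profile.dG)
    return float(np.interp(-z, profile.z[finite], profile.dG[finite]))


def barrier_height(
    profile: FreeEnergyProfile,
    error_mode: str = "mirror",
    replica_profiles: list[FreeEnergyProfile] | None = None,
) -> tuple[float, float]:
    """Barrier G‡: the maximum dG between the two leaflet minima.

    The minima are the finite minima on either side of the grid midpoint
    (the membrane centre in the protein frame).  Errors: ``mirror`` uses the
    leaflet asymmetry |dG(z*) - dG(-z*)| at the barrier; ``replicas`` uses
    the standard deviation of replica profiles at the barrier position.
    """
    g = profile.dG
    z = profile.z
    finite = np.isfinite(g)
    mid = 0.5 * (z[0] + z[-1])
    left = finite & (z < mid)
    right = finite & (z >= mid)
    if not left.any() or not right.any():
        raise ValueError("profile is not sampled on both sides of the midpoint")
    i_left = np.flatnonzero(left)[np.argmin(g[left])]
    i_right = np.flatnonzero(right)[np.argmin(g[right])]
    between = slice(i_left, i_right + 1)
    seg = g[between]
    seg_finite = seg[np.isfinite(seg)]
    g_barrier = float(seg_finite.max())
    if g_barrier <= max(g[i_left], g[i_right]) + 1e-12:
        raise ValueError("profile is monotone between minima; no barrier")
    i_barrier = i_left + int(np.nanargmax(np.where(np.isfinite(seg), seg, -np.inf)))
    z_barrier = float(z[i_barrier])
    if error_mode == "mirror":
        err = abs(g_barrier - _mirror_value(profile, z_barrier))
    elif error_mode == "replicas":
        if not replica_profiles:
            raise ValueError("error_mode='replicas' needs replica profiles")
        vals = [
            float(np.interp(z_barrier, p.z[np.isfinite(p.dG)], p.dG[np.isfinite(p.dG)]))
            for p in replica_profiles
        ]
        err = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    else:
        raise ValueError(f"unknown error mode {error_mode!r}")
    return g_barrier, err


@dataclass
class ThermoDecomposition:
    """dG = dH - T dS at the midpoint temperature, from temperature pairs.

    ``minus_TdS`` stores -T_mid * dS so that dG = dH + minus_TdS pointwise.
    ``error`` is the absolute difference between the two pair estimates.
    """

    z: np.ndarray
    dG: np.ndarray
    dH: np.ndarray
    minus_TdS: np.ndarray
    temperature: float
    error_dH: np.ndarray | None = None
    error_mTdS: np.ndarray | None = None

    def __post_init__(self) -> None:
        resid = self.dG - (self.dH + self.minus_TdS)
        finite = np.isfinite(resid)
        if finite.any() and np.max(np.abs(resid[finite])) > 1e-6:
            raise ValueError("dG = dH - T dS identity violated")


def _resample(profile: FreeEnergyProfile, z: np.ndarray) -> np.ndarray:
    if profile.z.shape == z.shape and np.allclose(profile.z, z, atol=1e-6):
        return profile.dG
    if z[0] < profile.z[0] - 1e-6 or z[-1] > profile.z[-1] + 1e-6:
        raise ValueError("profiles do not overlap on a common grid")
    finite = np.isfinite(profile.dG)
    return np.interp(z, profile.z[finite], profile.dG[finite])


def decompose_thermo(
    profiles: dict[float, FreeEnergyProfile],
    pairs: tuple[tuple[float, float], ...] = ((300.0, 320.0), (290.0, 330.0)),
    t_mid: float = 310.0,
) -> ThermoDecomposition:
    """Entropy/enthalpy decomposition by finite differences over temperature
    pairs, assuming constant entropy within each pair window:

        dS(z)  = -[dG(z, T2) - dG(z, T1)] / (T2 - T1)
        dH(z)  =  dG(z, T_mid) + T_mid dS(z)

    Reported values are the means over the pairs; the error is the absolute
    difference between the two pair estimates (requires exactly two pairs;
    with one pair the error is undefined).
    """
    if t_mid not in profiles:
        raise ValueError(f"need a profile at the midpoint temperature {t_mid} K")
    for t1, t2 in pairs:
        if t1 >= t2:
            raise ValueError("each pair must be ordered T1 < T2")
        if t1 not in profiles or t2 not in profiles:
            raise ValueError(f"missing profiles for pair ({t1}, {t2})")
    zgrid = profiles[t_mid].z
    g_mid = profiles[t_mid].dG
    ds_list, dh_list = [], []
    for t1, t2 in pairs:
        g1 = _resample(profiles[t1], zgrid)
        g2 = _resample(profiles[t2], zgrid)
        ds = -(g2 - g1) / (t2 - t1)
        ds_list.append(ds)
        dh_list.append(g_mid + t_mid * ds)
    ds_mean = np.mean(ds_list, axis=0)
    dh_mean = np.mean(dh_list, axis=0)
    if len(pairs) == 2:
        err_dh = np.abs(dh_list[0] - dh_list[1])
        err_mtds = t_mid * np.abs(ds_list[0] - ds_list[1])
    else:
        err_dh = err_mtds = None
    return ThermoDecomposition(
        z=zgrid,
        dG=g_mid,
        dH=dh_mean,
        minus_TdS=-t_mid * ds_mean,
        temperature=t_mid,
        error_dH=err_dh,
        error_mTdS=err_mtds,
    )


@dataclass
class ThicknessBarrierFit:
    """Least-squares line of flip-flop barrier against membrane thickness."""

    slope: float  # kJ/mol per nm
    intercept: float  # kJ/mol
    se_slope: float
    se_intercept: float
    thickness: np.ndarray
    barrier: np.ndarray

    def predict(self, thickness: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(thickness, dtype=float)


def fit_thickness_barrier(
    thickness: np.ndarray, barrier: np.ndarray
) -> ThicknessBarrierFit:
    t = np.asarray(thickness, dtype=float)
    b = np.asarray(barrier, dtype=float)
    if len(t) < 2 or len(np.unique(t)) < 2:
        raise ValueError("need at least two distinct thickness values")
    res = stats.linregress(t, b)
    return ThicknessBarrierFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr or 0.0),
        se_intercept=float(res.intercept_stderr or 0.0),
        thickness=t,
        barrier=b,
    )


def predict_barrier_reduction(
    fit: ThicknessBarrierFit, thickness_local: float, thickness_bulk: float
) -> float:
    """Barrier lowering ddG implied by local thinning: the y-axis separation
    of the fitted line at the bulk vs local thickness."""
    return float(fit.predict(thickness_bulk) - fit.predict(thickness_local))
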