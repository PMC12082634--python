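"""Local membrane thickness, lipid environment classes, and 3D density maps.

Thickness is the local interleaflet distance of the headgroup (phosphate)
beads: on an xy grid, mean head z of the upper leaflet minus mean head z of
the lower leaflet, accumulated over frames.  Lipid environments are
classified by the minimum 3D distance from the headgroup to any protein
bead: within the near cutoff of a site -> that site; beyond the bulk
exclusion from all -> bulk; otherwise intermediate.  Volumetric densities
are voxel counts in the protein-fixed frame, normalised to number density
and averaged over replicas; a scrambling pathway is 'continuous' when one
26-connected component of supra-threshold voxels bridges both leaflet
planes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import LipidSet, ProteinSites, Trajectory
from .kinetics import LeafletStateSeries

logger = logging.getLogger("scramblekit")

__all__ = [
    "ThicknessMap2D",
    "DensityMap3D",
    "thickness_map",
    "classify_lipid_environment",
    "EnvironmentLabels",
    "volumetric_density",
    "pathway_continuity",
    "ContinuityReport",
]


@dataclass
class ThicknessMap2D:
    """Mean interleaflet headgroup distance per xy cell (nm); NaN where a
    cell never sampled both leaflets."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    thickness: np.ndarray  # (nx, ny), NaN = undefined
    count: np.ndarray  # total head observations per cell

    def defined(self) -> np.ndarray:
        return np.isfinite(self.thickness)


def thickness_map(
    traj: Trajectory,
    lipids: LipidSet,
    states: LeafletStateSeries,
    grid_spacing: float = 0.2,
) -> ThicknessMap2D:
    """Per-cell thickness = mean upper-leaflet head z - mean lower-leaflet
    head z, over all frames, with xy wrapped into the (mean) box."""
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    lx = float(traj.box[:, 0].mean())
    ly = float(traj.box[:, 1].mean())
    nx = max(int(round(lx / grid_spacing)), 1)
    ny = max(int(round(ly / grid_spacing)), 1)
    heads = traj.positions[:, lipids.head_indices, :].astype(float)
    ix = np.clip((heads[..., 0] % lx) / lx * nx, 0, nx - 1e-9).astype(int)
    iy = np.clip((heads[..., 1] % ly) / ly * ny, 0, ny - 1e-9).astype(int)
    z = heads[..., 2]
    up = states.assigned == 1

    sums = np.zeros((2, nx, ny))
    counts = np.zeros((2, nx, ny))
    leaf = np.where(up, 0, 1)
    np.add.at(sums, (leaf.ravel(), ix.ravel(), iy.ravel()), z.ravel())
    np.add.at(counts, (leaf.ravel(), ix.ravel(), iy.ravel()), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_up = sums[0] / counts[0]
        mean_lo = sums[1] / counts[1]
        thick = mean_up - mean_lo
    thick[(counts[0] == 0) | (counts[1] == 0)] = np.nan
    x_centers = (np.arange(nx) + 0.5) * lx / nx
    y_centers = (np.arange(ny) + 0.5) * ly / ny
    return ThicknessMap2D(
        x_centers=x_centers,
        y_centers=y_centers,
        thickness=thick,
        count=counts.sum(axis=0),
    )


@dataclass
class EnvironmentLabels:
    """Per-lipid, per-frame environment labels.

    ``labels`` holds integer codes into ``categories``; categories are
    ``near-<site>`` per site, then "intermediate", then "bulk".
    """

    labels: np.ndarray  # (n_frames, n_lipids) int16
    categories: list[str]
    lipid_ids: np.ndarray

    def fractions(self) -> dict[str, float]:
        total = self.labels.size
        return {
            cat: float((self.labels == i).sum()) / total
            for i, cat in enumerate(self.categories)
        }

    def label_names(self) -> np.ndarray:
        return np.asarray(self.categories, dtype=object)[self.labels]


def classify_lipid_environment(
    traj: Trajectory,
    lipids: LipidSet,
    sites: ProteinSites,
    near_cutoff: float = 2.0,
    bulk_exclusion: float = 3.0,
) -> EnvironmentLabels:
    """Classify every lipid at every frame by its head-to-protein distance.

    The classes partition each frame exhaustively: nearest site when the
    minimum distance is <= near_cutoff, bulk when >= bulk_exclusion from all
    protein beads, intermediate otherwise.
    """
    if near_cutoff >= bulk_exclusion:
        raise ValueError("near cutoff must be smaller than the bulk exclusion")
    site_names = sorted(sites.sites)
    categories = [f"near-{s}" for s in site_names] + ["intermediate", "bulk"]
    i_intermediate = len(site_names)
    i_bulk = i_intermediate + 1
    all_idx = (
        np.concatenate([sites.sites[s] for s in site_names])
        if site_names
        else np.array([], dtype=np.intp)
    )
    nf = traj.n_frames
    nl = len(lipids)
    labels = np.full((nf, nl), i_bulk, dtype=np.int16)
    if len(all_idx) == 0:
        return EnvironmentLabels(labels, categories, lipids.lipid_ids)
    site_slices = []
    start = 0
    for s in site_names:
        k = len(sites.sites[s])
        site_slices.append(slice(start, start + k))
        start += k
    for f in range(nf):
        box = traj.box[f]
        heads = traj.positions[f, lipids.head_indices].astype(float)
        beads = traj.positions[f, all_idx].astype(float)
        delta = heads[:, None, :] - beads[None, :, :]
        delta -= box * np.round(delta / box)
        d = np.sqrt((delta**2).sum(axis=2))  # (n_lipids, n_beads)
        d_site = np.stack([d[:, sl].min(axis=1) for sl in site_slices], axis=1)
        dmin = d_site.min(axis=1)
        nearest = d_site.argmin(axis=1)
        lab = np.full(nl, i_bulk, dtype=np.int16)
        lab[dmin < bulk_exclusion] = i_intermediate
        near = dmin <= near_cutoff
        lab[near] = nearest[near]
        labels[f] = lab
    return EnvironmentLabels(labels, categories, lipids.lipid_ids)


@dataclass
class DensityMap3D:
    """Time-averaged number density (1/nm^3) on a voxel grid in the
    reference frame (origin at the reference-group centroid)."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    density: np.ndarray  # (nx, ny, nz)
    n_frames: int
    n_observations: int
    n_replicas: int = 1
    label: str = ""

    @property
    def voxel_volume(self) -> float:
        return float(
            (self.edges[0][1] - self.edges[0][0])
            * (self.edges[1][1] - self.edges[1][0])
            * (self.edges[2][1] - self.edges[2][0])
        )

    def z_centers(self) -> np.ndarray:
        e = self.edges[2]
        return 0.5 * (e[:-1] + e[1:])


def volumetric_density(
    trajectories: Sequence[Trajectory],
    selection: np.ndarray,
    reference: np.ndarray,
    voxel: float = 0.2,
    label: str = "",
) -> DensityMap3D:
    """Voxelised density of the selected beads, averaged over replicas.

    Coordinates are expressed relative to the reference-group centroid
    (protein frame) and wrapped into the box, so every observation lands in
    a voxel: sum(density) * voxel volume * frames = observation count.
    """
    if voxel < 0.01:
        raise ValueError("voxel smaller than 0.01 nm is degenerate")
    selection = np.asarray(selection, dtype=np.intp)
    reference = np.asarray(reference, dtype=np.intp)
    if len(selection) == 0 or len(reference) == 0:
        raise ValueError("selection and reference must be non-empty")
    box = np.asarray([t.box.mean(axis=0) for t in trajectories]).mean(axis=0)
    nbins = np.maximum((box / voxel).round().astype(int), 1)
    edges = tuple(
        np.linspace(-box[d] / 2, box[d] / 2, nbins[d] + 1) for d in range(3)
    )
    total = np.zeros(tuple(nbins))
    n_frames = 0
    n_obs = 0
    for traj in trajectories:
        pos = traj.positions[:, selection, :].astype(float)
        ref = traj.positions[:, reference, :].astype(float).mean(axis=1)
        rel = pos - ref[:, None, :]
        rel = (rel + box / 2) % box - box / 2
        h, _ = np.histogramdd(rel.reshape(-1, 3), bins=edges)
        total += h
        n_frames += traj.n_frames
        n_obs += rel.shape[0] * rel.shape[1]
    vol = float(np.prod(box / nbins))
    return DensityMap3D(
        edges=edges,
        density=total / (n_frames * vol),
        n_frames=n_frames,
        n_observations=n_obs,
        n_replicas=len(trajectories),
        label=label,
    )


@dataclass
class ContinuityReport:
    continuous: bool
    threshold: float
    n_components: int
    spanning_component: int | None
    component_sizes: list[int]


def pathway_continuity(
    density_map: DensityMap3D,
    z_lower: float,
    z_upper: float,
    threshold: float,
) -> ContinuityReport:
    """Is there a 26-connected component of voxels with density >= threshold
    that touches both leaflet planes (z_lower and z_upper, nm in the map
    frame)?  Lost continuity at the midplane means no scrambling pathway."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    zc = density_map.z_centers()
    if not (zc[0] <= z_lower <= zc[-1]) or not (zc[0] <= z_upper <= zc[-1]):
        raise ValueError("leaflet planes must lie inside the map z-extent")
    k_lo = int(np.argmin(np.abs(zc - z_lower)))
    k_up = int(np.argmin(np.abs(zc - z_upper)))
    mask = density_map.density >= threshold
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    sizes = [int((labels == i).sum()) for i in range(1, n + 1)]
    spanning = None
    lo_labels = set(np.unique(labels[:, :, k_lo])) - {0}
    up_labels = set(np.unique(labels[:, :, k_up])) - {0}
    common = lo_labels & up_labels
    if common:
        spanning = int(min(common))
    return ContinuityReport(
        continuous=spanning is not None,
        threshold=threshold,
        n_components=n,
        spanning_component=spanning,
        component_sizes=sizes,
    )
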