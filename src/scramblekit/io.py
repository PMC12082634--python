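"""Domain types and file I/O for the scrambling-analysis pipeline.

Units are fixed package-wide: lengths in nm, times in ns, temperatures in K,
energies in kJ/mol, scrambling rates in 1/us.  Structure and coordinate files
(GRO, PDB, XTC, TRR) are read and written through MDAnalysis; PDB Angstrom
coordinates are converted to nm on ingest.  Only orthorhombic boxes are
supported — the membrane patches this package targets are rectangular.

All downstream modules consume the types defined here; none of them read
files directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("scramblekit")

__all__ = [
    "BeadSelectionMap",
    "Trajectory",
    "LipidSet",
    "ProteinSites",
    "ReplicaSet",
    "Profile1D",
    "RateTable",
    "FormatError",
    "SelectionError",
    "UnsupportedFeatureError",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "read_tabular_profile",
    "write_tabular_profile",
    "read_assay_csv",
    "write_assay_csv",
    "load_config",
    "configure_logging",
]


class FormatError(ValueError):
    """A file could not be parsed in the expected format."""


class SelectionError(ValueError):
    """A selection did not resolve to the expected particles."""


class UnsupportedFeatureError(ValueError):
    """Input uses a feature outside this package's scope (e.g. triclinic box)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class BeadSelectionMap:
    """Names of the beads that define lipids, protein sites and the frame.

    ``lipid_beads`` maps a lipid residue name to its (head, tail) bead names,
    e.g. ``{"POPC": ("PO4", "C4B")}``.  ``protein_groups`` maps a site label
    to residue-id ranges ``(segid_or_None, first_resid, last_resid)`` whose
    particles define the scrambling pathway.  ``reference_group`` selects the
    membrane-frame reference particles the same way.
    """

    lipid_beads: Mapping[str, tuple[str, str]]
    protein_groups: Mapping[str, Sequence[tuple[str | None, int, int]]] = field(
        default_factory=dict
    )
    reference_group: Sequence[tuple[str | None, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lt, pair in self.lipid_beads.items():
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValueError(
                    f"lipid type {lt!r} must map to distinct (head, tail) bead names"
                )
        for site, ranges in self.protein_groups.items():
            if len(ranges) == 0:
                raise ValueError(f"site {site!r} has no residue ranges")
            for _, lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"site {site!r}: residue range {lo} > {hi}")


@dataclass
class Trajectory:
    """In-memory trajectory: wrapped coordinates plus particle metadata.

    positions : (n_frames, n_particles, 3) float array, nm
    times     : (n_frames,) float array, ns, strictly increasing
    box       : (n_frames, 3) float array, orthorhombic box lengths, nm
    """

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    segids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_particles, 3)")
        if len(self.times) != self.positions.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.box.shape != (len(self.times), 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("all box lengths must be positive")
        n = self.positions.shape[1]
        for arr_name in ("names", "resnames", "resids"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length does not match particle count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]


@dataclass
class LipidSet:
    """Lipid bookkeeping: id -> (type, head particle index, tail particle index)."""

    lipid_ids: np.ndarray
    lipid_types: np.ndarray
    head_indices: np.ndarray
    tail_indices: np.ndarray

    def __post_init__(self) -> None:
        self.lipid_ids = np.asarray(self.lipid_ids)
        self.lipid_types = np.asarray(self.lipid_types)
        self.head_indices = np.asarray(self.head_indices, dtype=np.intp)
        self.tail_indices = np.asarray(self.tail_indices, dtype=np.intp)
        if not (
            len(self.lipid_ids)
            == len(self.lipid_types)
            == len(self.head_indices)
            == len(self.tail_indices)
        ):
            raise ValueError("LipidSet field lengths disagree")
        if np.any(self.head_indices == self.tail_indices):
            raise ValueError("head and tail indices must differ for every lipid")

    def __len__(self) -> int:
        return len(self.lipid_ids)


@dataclass
class ProteinSites:
    """Named pathway sites (label -> particle indices) plus the frame reference."""

    sites: dict[str, np.ndarray]
    reference_indices: np.ndarray

    def __post_init__(self) -> None:
        self.sites = {k: np.asarray(v, dtype=np.intp) for k, v in self.sites.items()}
        self.reference_indices = np.asarray(self.reference_indices, dtype=np.intp)
        if len(self.reference_indices) == 0:
            raise ValueError("membrane-frame reference group must be non-empty")
        for name, idx in self.sites.items():
            if len(idx) == 0:
                raise SelectionError(f"site {name!r} resolved to zero particles")


@dataclass
class Replica:
    trajectory: Trajectory
    temperature: float
    composition: str = ""
    replica_index: int = 0
    duration_us: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.duration_us is None:
            t = self.trajectory.times
            self.duration_us = float(t[-1] - t[0]) / 1000.0


@dataclass
class ReplicaSet:
    """A set of replica simulations sharing one topology."""

    replicas: list[Replica]

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("ReplicaSet must contain at least one replica")
        n0 = self.replicas[0].trajectory.n_particles
        for r in self.replicas:
            if r.trajectory.n_particles != n0:
                raise ValueError("replicas must share one topology")

    def __iter__(self):
        return iter(self.replicas)

    def __len__(self) -> int:
        return len(self.replicas)


@dataclass
class Profile1D:
    """A profile on a uniform z grid (nm): density, free energy, thickness..."""

    z: np.ndarray
    values: np.ndarray
    unit: str = ""
    error: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z.shape != self.values.shape:
            raise ValueError("grid and values must have equal length")
        if len(self.z) > 1:
            dz = np.diff(self.z)
            if np.any(np.abs(dz - dz[0]) > 1e-9):
                raise ValueError("z grid must be uniform within 1e-9 nm")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if self.error.shape != self.values.shape:
                raise ValueError("error length must match values")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else 0.0


@dataclass
class RateTable:
    """Per-site, per-lipid-type scrambling rates with replica standard errors.

    ``table`` columns: site, lipid_type, rate_per_us, se_per_us, n_replicas,
    total_events.  Totals over lipid types appear as lipid_type == "total".
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "site",
            "lipid_type",
            "rate_per_us",
            "se_per_us",
            "n_replicas",
            "total_events",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"RateTable missing columns: {sorted(missing)}")
        if (self.table["rate_per_us"] < 0).any() or (self.table["se_per_us"] < 0).any():
            raise ValueError("rates and standard errors must be non-negative")
        if (self.table["n_replicas"] < 1).any():
            raise ValueError("n_replicas must be >= 1")

    def formatted(self) -> pd.DataFrame:
        """Rates as '7.7 ± 0.7' strings, one decimal, per-site rows."""
        out = self.table.copy()
        out["rate"] = [
            f"{r:.1f} ± {s:.1f}"
            for r, s in zip(out["rate_per_us"], out["se_per_us"])
        ]
        return out[["site", "lipid_type", "rate", "n_replicas", "total_events"]]

    def lookup(self, site: str, lipid_type: str) -> tuple[float, float]:
        sel = self.table[
            (self.table["site"] == site) & (self.table["lipid_type"] == lipid_type)
        ]
        if sel.empty:
            raise KeyError(f"no row for site={site!r}, lipid_type={lipid_type!r}")
        row = sel.iloc[0]
        return float(row["rate_per_us"]), float(row["se_per_us"])


# --------------------------------------------------------------------------
# MDAnalysis-backed readers / writers
# --------------------------------------------------------------------------

_A_PER_NM = 10.0
_PS_PER_NS = 1000.0


def _check_orthorhombic(dimensions: np.ndarray) -> None:
    if dimensions is None or np.any(np.asarray(dimensions[:3]) <= 0):
        raise FormatError("file does not define a positive simulation box")
    angles = np.asarray(dimensions[3:6])
    if np.any(np.abs(angles - 90.0) > 1e-3):
        raise UnsupportedFeatureError(
            f"triclinic box (angles {angles}) is not supported; "
            "only orthorhombic membrane patches are handled"
        )


def _universe_to_trajectory(u) -> Trajectory:
    n_frames = len(u.trajectory)
    n_atoms = len(u.atoms)
    positions = np.empty((n_frames, n_atoms, 3), dtype=np.float32)
    times = np.empty(n_frames)
    box = np.empty((n_frames, 3))
    for i, ts in enumerate(u.trajectory):
        _check_orthorhombic(ts.dimensions)
        positions[i] = ts.positions / _A_PER_NM
        times[i] = ts.time / _PS_PER_NS
        box[i] = ts.dimensions[:3] / _A_PER_NM
    if n_frames > 1 and np.all(times == times[0]):
        # formats without time stamps: fall back to frame index in ns
        times = np.arange(n_frames, dtype=float)
    try:
        segids = u.atoms.segids.astype(str)
    except Exception:  # pragma: no cover - topology without segments
        segids = np.array([""] * n_atoms)
    return Trajectory(
        times=times,
        positions=positions,
        box=box,
        names=u.atoms.names.astype(str),
        resnames=u.atoms.resnames.astype(str),
        resids=u.atoms.resids.astype(int),
        segids=segids,
    )


def read_trajectory(
    path: str | Path,
    topology: str | Path | None = None,
    n_particles: int | None = None,
) -> Trajectory:
    """Read a GRO/PDB/XTC/TRR file into a :class:`Trajectory` (nm, ns).

    Binary coordinate formats (XTC/TRR) need ``topology`` (a GRO or PDB file)
    for particle metadata.  ``n_particles``, when given, is cross-checked
    against the file.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if topology is not None:
            u = mda.Universe(str(topology), str(path))
        else:
            u = mda.Universe(str(path))
    except UnsupportedFeatureError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    if n_particles is not None and len(u.atoms) != n_particles:
        raise FormatError(
            f"{path.name} has {len(u.atoms)} particles, expected {n_particles}"
        )
    traj = _universe_to_trajectory(u)
    logger.info("read %d frames, %d particles from %s", traj.n_frames,
                traj.n_particles, path.name)
    return traj


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as GRO (multi-frame) or XTC, chosen by extension."""
    import MDAnalysis as mda

    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    n = traj.n_particles
    resids = np.asarray(traj.resids)
    # MDAnalysis wants per-residue arrays
    _, res_first = np.unique(resids, return_index=True)
    res_first.sort()
    per_res_resids = resids[res_first]
    per_res_names = np.asarray(traj.resnames)[res_first]
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(res_first),
        atom_resindex=np.searchsorted(per_res_resids, resids),
        trajectory=True,
    )
    u.add_TopologyAttr("names", np.asarray(traj.names))
    u.add_TopologyAttr("resnames", per_res_names)
    u.add_TopologyAttr("resids", per_res_resids)
    with mda.Writer(str(path), n_atoms=n) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = np.asarray(traj.positions[i], dtype=np.float64) * _A_PER_NM
            u.dimensions = [*(traj.box[i] * _A_PER_NM), 90.0, 90.0, 90.0]
            u.trajectory.ts.time = traj.times[i] * _PS_PER_NS
            u.trajectory.ts.frame = i
            w.write(u.atoms)
    logger.info("wrote %d frames to %s", traj.n_frames, path.name)


def _resolve_ranges(u, ranges: Sequence[tuple[str | None, int, int]]) -> np.ndarray:
    idx: list[np.ndarray] = []
    for segid, lo, hi in ranges:
        sel = f"resid {lo}:{hi}"
        if segid:
            sel += f" and segid {segid}"
        idx.append(u.select_atoms(sel).indices)
    if idx:
        return np.unique(np.concatenate(idx))
    return np.array([], dtype=np.intp)


def read_topology(
    path: str | Path, selmap: BeadSelectionMap
) -> tuple[LipidSet, ProteinSites]:
    """Resolve the bead-selection map against a structure file.

    Every residue whose name appears in ``selmap.lipid_beads`` must contain
    exactly the named head and tail bead; a missing bead raises
    :class:`SelectionError` naming the residue.
    """
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {Path(path).name}: {exc}") from exc

    ids, types, heads, tails = [], [], [], []
    for res in u.residues:
        pair = selmap.lipid_beads.get(res.resname)
        if pair is None:
            continue
        head_name, tail_name = pair
        names = res.atoms.names
        h = np.flatnonzero(names == head_name)
        t = np.flatnonzero(names == tail_name)
        if len(h) != 1 or len(t) != 1:
            raise SelectionError(
                f"residue {res.resname} {res.resid}: expected one {head_name} "
                f"and one {tail_name} bead (found {len(h)}/{len(t)})"
            )
        ids.append(int(res.resid))
        types.append(res.resname)
        heads.append(int(res.atoms.indices[h[0]]))
        tails.append(int(res.atoms.indices[t[0]]))
    lipids = LipidSet(
        lipid_ids=np.array(ids),
        lipid_types=np.array(types),
        head_indices=np.array(heads, dtype=np.intp),
        tail_indices=np.array(tails, dtype=np.intp),
    )

    site_idx: dict[str, np.ndarray] = {}
    for name, ranges in selmap.protein_groups.items():
        resolved = _resolve_ranges(u, ranges)
        if len(resolved) == 0:
            raise SelectionError(f"protein site {name!r} resolved to zero particles")
        site_idx[name] = resolved
    ref = _resolve_ranges(u, selmap.reference_group)
    if len(ref) == 0:
        # fall back: site beads, else the lipid heads, keep the frame defined
        if site_idx:
            ref = np.unique(np.concatenate(list(site_idx.values())))
        elif len(heads):
            ref = np.asarray(heads, dtype=np.intp)
        else:
            raise SelectionError("reference group resolved to zero particles")
    sites = ProteinSites(sites=site_idx, reference_indices=ref)
    logger.info("resolved %d lipids, %d sites from %s", len(lipids),
                len(site_idx), Path(path).name)
    return lipids, sites


# --------------------------------------------------------------------------
# tabular profiles and assay curves
# --------------------------------------------------------------------------


def read_tabular_profile(path: str | Path) -> Profile1D:
    """Read a two-column whitespace table (XVG dialect: '#'/'@' lines skipped)."""
    z, v = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            try:
                z.append(float(parts[0]))
                v.append(float(parts[1]))
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{Path(path).name}:{lineno}: not a two-column numeric line: {s!r}"
                ) from exc
    if len(z) < 2:
        raise FormatError(f"{Path(path).name}: fewer than two data lines")
    zarr = np.array(z)
    if np.any(np.diff(zarr) <= 0):
        raise FormatError(f"{Path(path).name}: grid is not strictly increasing")
    return Profile1D(z=zarr, values=np.array(v))


def write_tabular_profile(profile: Profile1D, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for zi, vi in zip(profile.z, profile.values):
            fh.write(f"{float(zi)!r} {float(vi)!r}\n")


def read_assay_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an assay curve CSV with header ``time_s,intensity``."""
    df = pd.read_csv(path)
    if not {"time_s", "intensity"} <= set(df.columns):
        raise FormatError(f"{Path(path).name}: expected columns time_s,intensity")
    return df["time_s"].to_numpy(float), df["intensity"].to_numpy(float)


def write_assay_csv(times: np.ndarray, intensity: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_s": times, "intensity": intensity}).to_csv(path, index=False)


# --------------------------------------------------------------------------
# configuration and logging
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "leaflet_threshold_nm": 2.1,
    "site_cutoff_nm": 2.0,
    "bulk_exclusion_nm": 3.0,
    "leaflet_sign": 1,
    "n_slices": 300,
    "temperature_K": 310.0,
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON run configuration merged over the package defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".json"}:
        user = json.loads(text)
    else:
        import yaml

        user = yaml.safe_load(text)
    if not isinstance(user, dict):
        raise FormatError(f"{path.name}: config must be a mapping")
    cfg.update(user)
    logger.info("resolved config: %s", cfg)
    return cfg


def configure_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = "%(asctime)s %(name)s %(levelname)s %(message)s"
    for h in handlers:
        h.setFormatter(logging.Formatter(fmt))
        logger.addHandler(h)
    logger.setLevel(level)
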