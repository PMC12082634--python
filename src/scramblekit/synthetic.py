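"""Synthetic membrane trajectories and assay curves with known ground truth.

The generator emulates the geometry of a coarse-grained translocon/membrane
system: lipids are head+tail bead pairs whose transverse (z) positions
fluctuate around leaflet planes, flip-flop events arrive as a Poisson
process per (lipid type, protein site), and a flipping lipid first moves
laterally to its assigned site and then traverses the membrane linearly in
z over a fixed transit time.  Protein sites are static bead columns (the
backbone of the real complex is restrained, so static sites are the honest
analogue).  Every event is recorded in an :class:`EventLog`, giving each
analysis stage a known truth to be measured against.

Defaults mimic the study conditions the analyses target: a 15 x 15 x 12 nm
box with 600 POPC lipids (300 per leaflet), leaflet separation 4 nm,
transverse fluctuation 0.3 nm, 20 us duration at 1 ns frame spacing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_KJ
from .io import LipidSet, ProteinSites, Replica, ReplicaSet, Trajectory

logger = logging.getLogger("scramblekit")

__all__ = [
    "SyntheticSpec",
    "EventLog",
    "generate_trajectory",
    "generate_replicas",
    "generate_arrhenius_series",
    "arrhenius_true_rate",
    "ArrheniusSeries",
    "sample_from_pmf",
    "generate_assay_curve",
]


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of a synthetic membrane trajectory.

    ``flip_rates`` maps lipid type -> site label -> true event rate for the
    whole system in 1/us (the convention scrambling rates are reported in).
    """

    n_per_leaflet: dict[str, int] = field(default_factory=lambda: {"POPC": 300})
    box: tuple[float, float, float] = (15.0, 15.0, 12.0)
    leaflet_separation: float = 4.0  # nm between head planes
    tail_offset: float = 1.0  # nm, tail plane on the opposite side of midplane
    sigma_z: float = 0.3  # nm transverse fluctuation of each bead
    sigma_xy: float = 0.1  # nm lateral random-walk step per frame
    flip_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"POPC": {"Sec61": 0.0, "TRAP": 0.0}}
    )
    transit_time_ns: float = 50.0
    site_centers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Sec61": (4.5, 7.5), "TRAP": (10.5, 7.5)}
    )
    n_frames: int = 20001
    dt_ns: float = 1.0
    temperature: float = 310.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lt, per_site in self.flip_rates.items():
            for site, r in per_site.items():
                if r < 0:
                    raise ValueError(f"negative flip rate for ({lt}, {site})")
                if r > 0 and site not in self.site_centers:
                    raise ValueError(f"rate given for unknown site {site!r}")
        if self.transit_time_ns >= self.duration_ns:
            raise ValueError("flip transit time must be shorter than the trajectory")
        if self.sigma_z >= self.leaflet_separation / 2:
            raise ValueError("sigma_z must be below half the leaflet separation")

    @property
    def duration_ns(self) -> float:
        return (self.n_frames - 1) * self.dt_ns

    @property
    def duration_us(self) -> float:
        return self.duration_ns / 1000.0

    @property
    def n_lipids(self) -> int:
        return 2 * sum(self.n_per_leaflet.values())


@dataclass
class EventLog:
    """Ground-truth flip events: (lipid id, type, start time ns, direction, site)."""

    lipid_ids: list[int] = field(default_factory=list)
    lipid_types: list[str] = field(default_factory=list)
    t_start_ns: list[float] = field(default_factory=list)
    directions: list[str] = field(default_factory=list)
    sites: list[str] = field(default_factory=list)

    def append(self, lid: int, ltype: str, t: float, direction: str, site: str) -> None:
        self.lipid_ids.append(lid)
        self.lipid_types.append(ltype)
        self.t_start_ns.append(t)
        self.directions.append(direction)
        self.sites.append(site)

    def __len__(self) -> int:
        return len(self.lipid_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lipid_id": self.lipid_ids,
                "lipid_type": self.lipid_types,
                "t_start_ns": self.t_start_ns,
                "direction": self.directions,
                "site": self.sites,
            }
        )


_SITE_BEADS_Z = np.linspace(-2.0, 2.0, 5)  # bead column spanning the membrane


def _per_lipid_rng(seed: int, lipid_index: int) -> np.random.Generator:
    # counter-based stream: adding lipids never perturbs existing streams
    return np.random.default_rng([seed, 1, lipid_index])


def generate_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, LipidSet, ProteinSites, EventLog]:
    """Generate one synthetic trajectory with its ground-truth event log.

    Identical specs (including the seed) produce identical output.
    """
    nf = spec.n_frames
    times = np.arange(nf) * spec.dt_ns
    lx, ly, lz = spec.box
    zc = lz / 2.0
    head_off = spec.leaflet_separation / 2.0

    # --- lipid layout: per type, upper leaflet block then lower ----------
    lipid_types: list[str] = []
    init_sign: list[int] = []
    for lt, n in spec.n_per_leaflet.items():
        lipid_types += [lt] * (2 * n)
        init_sign += [1] * n + [-1] * n
    n_lip = len(lipid_types)
    lipid_types_arr = np.array(lipid_types)
    init_sign_arr = np.array(init_sign, dtype=np.int8)

    # --- draw flip events as Poisson processes per (type, site) ---------
    raw_events: list[tuple[float, str, str]] = []  # (t, type, site)
    for ti, (lt, per_site) in enumerate(sorted(spec.flip_rates.items())):
        for si, (site, rate) in enumerate(sorted(per_site.items())):
            if rate <= 0:
                continue
            rng_e = np.random.default_rng([spec.seed, 2, ti, si])
            rate_per_ns = rate / 1000.0
            window = spec.duration_ns - spec.transit_time_ns
            t = 0.0
            while True:
                t += rng_e.exponential(1.0 / rate_per_ns)
                if t > window:
                    break
                raw_events.append((t, lt, site))
    raw_events.sort(key=lambda e: e[0])

    rng_assign = np.random.default_rng([spec.seed, 3])
    type_members = {lt: np.flatnonzero(lipid_types_arr == lt) for lt in spec.n_per_leaflet}

    busy_until = np.full(n_lip, -np.inf)
    cur_sign = init_sign_arr.copy()
    log = EventLog()
    scheduled: list[tuple[int, float, str]] = []  # (lipid index, start, site)
    n_queued = 0
    for t, lt, site in raw_events:
        i = int(rng_assign.choice(type_members[lt]))
        start = t
        if start < busy_until[i]:
            start = busy_until[i]
            n_queued += 1
        if start > spec.duration_ns - spec.transit_time_ns:
            logger.warning("event for lipid %d queued past trajectory end; dropped", i)
            continue
        direction = "upper->lower" if cur_sign[i] > 0 else "lower->upper"
        log.append(i + 1, lt, float(start), direction, site)
        scheduled.append((i, start, site))
        busy_until[i] = start + spec.transit_time_ns
        cur_sign[i] = -cur_sign[i]
    if n_queued:
        logger.info("%d overlapping flip events queued after current transit", n_queued)

    # --- baseline coordinates -------------------------------------------
    # sign of each lipid per frame: flips at the end of each transit window
    sign = np.repeat(init_sign_arr[None, :], nf, axis=0).astype(np.int8)
    for i, start, _site in scheduled:
        f1 = int(np.searchsorted(times, start + spec.transit_time_ns))
        sign[f1:, i] *= -1

    head = np.empty((nf, n_lip, 3), dtype=np.float32)
    tail = np.empty((nf, n_lip, 3), dtype=np.float32)
    for i in range(n_lip):
        rng_i = _per_lipid_rng(spec.seed, i)
        xy0 = rng_i.uniform([0.0, 0.0], [lx, ly])
        steps = rng_i.normal(0.0, spec.sigma_xy, size=(nf, 2))
        steps[0] = 0.0
        walk = xy0 + np.cumsum(steps, axis=0)
        head[:, i, :2] = walk
        tail[:, i, :2] = walk  # tail tracks the head laterally
        head[:, i, 2] = zc + sign[:, i] * head_off + rng_i.normal(0, spec.sigma_z, nf)
        tail[:, i, 2] = zc - sign[:, i] * spec.tail_offset + rng_i.normal(
            0, spec.sigma_z, nf
        )

    # --- overlay flip transits ------------------------------------------
    rng_site = np.random.default_rng([spec.seed, 4])
    for (i, start, site), direction in zip(scheduled, log.directions):
        f0 = int(np.searchsorted(times, start))
        f1 = int(np.searchsorted(times, start + spec.transit_time_ns))
        f1 = min(f1, nf - 1)
        s_from = 1 if direction == "upper->lower" else -1
        # lateral: jump to within 1 nm of the site center, hold through transit
        cx, cy = spec.site_centers[site]
        r = math.sqrt(rng_site.uniform(0.0, 1.0))
        phi = rng_site.uniform(0.0, 2 * math.pi)
        px, py = cx + r * math.cos(phi), cy + r * math.sin(phi)
        for arr in (head, tail):
            dx = np.array([px, py], dtype=np.float32) - arr[f1, i, :2]
            arr[f0 : f1 + 1, i, :2] = [px, py]
            arr[f1 + 1 :, i, :2] += dx  # keep the post-transit walk continuous
        # transverse: linear traversal of head and tail planes
        frac = (times[f0 : f1 + 1] - start) / spec.transit_time_ns
        frac = np.clip(frac, 0.0, 1.0)
        head[f0 : f1 + 1, i, 2] = zc + s_from * head_off * (1 - 2 * frac)
        tail[f0 : f1 + 1, i, 2] = zc - s_from * spec.tail_offset * (1 - 2 * frac)

    # --- protein site beads and frame reference -------------------------
    site_names = sorted(spec.site_centers)
    n_site_beads = len(_SITE_BEADS_Z)
    prot_xyz = []
    for name in site_names:
        cx, cy = spec.site_centers[name]
        for dz in _SITE_BEADS_Z:
            prot_xyz.append([cx, cy, zc + dz])
    prot_xyz.append([lx / 2, ly / 2, zc])  # REF bead at the membrane center
    prot_xyz = np.array(prot_xyz, dtype=np.float32)
    n_prot = len(prot_xyz)

    n_particles = 2 * n_lip + n_prot
    positions = np.empty((nf, n_particles, 3), dtype=np.float32)
    positions[:, 0 : 2 * n_lip : 2] = head
    positions[:, 1 : 2 * n_lip : 2] = tail
    positions[:, 2 * n_lip :] = prot_xyz[None, :, :]
    # store wrapped coordinates
    positions %= np.array(spec.box, dtype=np.float32)

    names = np.empty(n_particles, dtype=object)
    resnames = np.empty(n_particles, dtype=object)
    resids = np.empty(n_particles, dtype=int)
    names[0 : 2 * n_lip : 2] = "PO4"
    names[1 : 2 * n_lip : 2] = "C4B"
    resnames[0 : 2 * n_lip : 2] = lipid_types_arr
    resnames[1 : 2 * n_lip : 2] = lipid_types_arr
    resids[0 : 2 * n_lip : 2] = np.arange(1, n_lip + 1)
    resids[1 : 2 * n_lip : 2] = np.arange(1, n_lip + 1)
    site_indices: dict[str, np.ndarray] = {}
    p = 2 * n_lip
    rid = n_lip + 1
    for name in site_names:
        idx = np.arange(p, p + n_site_beads)
        site_indices[name] = idx
        names[idx] = [f"BB{j+1}" for j in range(n_site_beads)]
        resnames[idx] = name[:5]
        resids[idx] = rid
        rid += 1
        p += n_site_beads
    names[p] = "REF"
    resnames[p] = "REF"
    resids[p] = rid

    traj = Trajectory(
        times=times,
        positions=positions,
        box=np.tile(np.array(spec.box), (nf, 1)),
        names=names.astype(str),
        resnames=resnames.astype(str),
        resids=resids,
        segids=np.array([""] * n_particles),
    )
    lipids = LipidSet(
        lipid_ids=np.arange(1, n_lip + 1),
        lipid_types=lipid_types_arr,
        head_indices=np.arange(0, 2 * n_lip, 2),
        tail_indices=np.arange(1, 2 * n_lip, 2),
    )
    ref = (
        np.concatenate(list(site_indices.values()))
        if site_indices
        else np.array([n_particles - 1])
    )
    sites = ProteinSites(sites=site_indices, reference_indices=ref)
    logger.info(
        "synthetic trajectory: %d lipids, %d frames, %d true events",
        n_lip, nf, len(log),
    )
    return traj, lipids, sites, log


def generate_replicas(
    spec: SyntheticSpec, n_replicas: int = 5
) -> tuple[ReplicaSet, list[EventLog], LipidSet, ProteinSites]:
    """Independent replicas differing only in their derived seeds."""
    replicas, logs = [], []
    lipids = sites = None
    for r in range(n_replicas):
        s = SyntheticSpec(**{**spec.__dict__, "seed": (spec.seed * 1009 + r) % 2**31})
        traj, lipids, sites, log = generate_trajectory(s)
        replicas.append(
            Replica(
                trajectory=traj,
                temperature=spec.temperature,
                composition="+".join(sorted(spec.n_per_leaflet)),
                replica_index=r,
            )
        )
        logs.append(log)
    return ReplicaSet(replicas), logs, lipids, sites


def arrhenius_true_rate(e_a: float, ln_a: float, temperature: float) -> float:
    """k(T) = exp(lnA - E_A / (R T)), in the units of exp(lnA) (here 1/us)."""
    return math.exp(ln_a - e_a / (R_KJ * temperature))


@dataclass
class ArrheniusSeries:
    temperatures: list[float]
    replica_sets: dict[float, ReplicaSet]
    event_logs: dict[float, list[EventLog]]
    true_rates: dict[float, float]
    lipids: LipidSet
    sites: ProteinSites


def generate_arrhenius_series(
    e_a: float,
    ln_a: float,
    temperatures: list[float],
    spec: SyntheticSpec,
    n_replicas: int = 1,
) -> ArrheniusSeries:
    """Replica sets at several temperatures with Arrhenius-distributed true rates.

    The template spec's flip rates set the relative weight of each
    (type, site) channel; at each temperature they are rescaled so the total
    system rate equals exp(lnA - E_A/(R T)) 1/us.
    """
    if len(set(temperatures)) < 2:
        raise ValueError("need at least two distinct temperatures")
    if any(t <= 0 for t in temperatures):
        raise ValueError("temperatures must be positive")
    total = sum(r for per in spec.flip_rates.values() for r in per.values())
    if total <= 0:
        raise ValueError("template spec must have a positive total flip rate")
    sets, logs, rates = {}, {}, {}
    lipids = sites = None
    for j, temp in enumerate(temperatures):
        k_true = arrhenius_true_rate(e_a, ln_a, temp)
        scaled = {
            lt: {site: r * k_true / total for site, r in per.items()}
            for lt, per in spec.flip_rates.items()
        }
        s = SyntheticSpec(
            **{
                **spec.__dict__,
                "flip_rates": scaled,
                "temperature": temp,
                "seed": (spec.seed * 7919 + 31 * j) % 2**31,
            }
        )
        rs, rl, lipids, sites = generate_replicas(s, n_replicas)
        sets[temp], logs[temp], rates[temp] = rs, rl, k_true
    return ArrheniusSeries(
        temperatures=list(temperatures),
        replica_sets=sets,
        event_logs=logs,
        true_rates=rates,
        lipids=lipids,
        sites=sites,
    )


def sample_from_pmf(
    profile, temperature: float, n: int, seed: int | None = None
) -> np.ndarray:
    """Draw z samples with probability proportional to exp(-dG(z)/RT).

    ``profile`` is any object with uniform ``z`` (nm) and free-energy values
    in kJ/mol (``values`` or ``dG``).  Sampling is inverse-CDF on the grid
    with uniform jitter inside each bin.
    """
    z = np.asarray(profile.z, dtype=float)
    g = np.asarray(getattr(profile, "dG", getattr(profile, "values", None)), dtype=float)
    rt = R_KJ * temperature
    w = np.where(np.isfinite(g), np.exp(-(g - np.nanmin(g[np.isfinite(g)])) / rt), 0.0)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("profile has no finite bins to sample from")
    rng = np.random.default_rng(seed)
    bins = rng.choice(len(z), size=n, p=w / total)
    dz = z[1] - z[0] if len(z) > 1 else 0.0
    return z[bins] + rng.uniform(-dz / 2, dz / 2, size=n)


def generate_assay_curve(model, times, noise_sigma: float = 0.0, seed: int | None = None):
    """Forward-simulated assay curve plus i.i.d. Gaussian noise."""
    from .assay import simulate_assay

    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    curve = simulate_assay(model, times)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        curve.fluorescence = curve.fluorescence + rng.normal(
            0.0, noise_sigma, size=len(curve.times)
        )
    return curve
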