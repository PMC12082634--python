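"""Flip-flop detection, rate statistics, and Arrhenius/Eyring kinetics.

A lipid's orientation is read from the transverse separation of its head and
tail beads, dz = z_head - z_tail: beyond a threshold (default 2.1 nm) the
lipid is in a leaflet, in between it is undetermined.  The *assigned*
leaflet carries hysteresis — it changes only when the lipid fully crosses to
the opposite threshold — so midplane dwellers are never double counted.
Each assignment change is one flip-flop event; events are attributed to a
protein site when they initiate within a cutoff (default 2 nm) of its
pathway beads, and rates are mean events per microsecond over replicas with
the replica-to-replica standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import K_B, PLANCK_H, R_KJ
from .io import LipidSet, ProteinSites, RateTable, ReplicaSet, Trajectory

logger = logging.getLogger("scramblekit")

__all__ = [
    "LeafletStateSeries",
    "FlipFlopEvent",
    "ArrheniusFit",
    "assign_leaflets",
    "detect_events",
    "assign_events_to_sites",
    "compute_rates",
    "threshold_scan",
    "plateau_window",
    "fit_arrhenius",
    "eyring_rate",
    "eyring_speedup",
    "scaled_half_life",
    "compare_rates",
    "events_to_dataframe",
]

UPPER, UNDETERMINED, LOWER = 1, 0, -1


@dataclass
class LeafletStateSeries:
    """Instantaneous and hysteresis-carried leaflet state per lipid, per frame.

    ``instantaneous``: +1 upper / 0 undetermined / -1 lower.
    ``assigned``: +1 / -1, changes only on full crossings.
    """

    times: np.ndarray
    lipid_ids: np.ndarray
    instantaneous: np.ndarray  # (n_frames, n_lipids) int8
    assigned: np.ndarray  # (n_frames, n_lipids) int8
    threshold: float

    def __post_init__(self) -> None:
        # assignment may change only where the instantaneous state equals
        # the new leaflet (full crossing)
        ch = self.assigned[1:] != self.assigned[:-1]
        if np.any(ch & (self.instantaneous[1:] != self.assigned[1:])):
            raise ValueError("assigned leaflet changed without a threshold crossing")


@dataclass
class FlipFlopEvent:
    """One interleaflet transition of one lipid."""

    lipid_id: int
    lipid_type: str
    time_ns: float
    direction: str  # "upper->lower" or "lower->upper"
    head_position: np.ndarray
    site: str = "bulk"


def events_to_dataframe(events: Sequence[FlipFlopEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lipid_id": [e.lipid_id for e in events],
            "lipid_type": [e.lipid_type for e in events],
            "time_ns": [e.time_ns for e in events],
            "direction": [e.direction for e in events],
            "site": [e.site for e in events],
        }
    )


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def assign_leaflets(
    traj: Trajectory,
    lipids: LipidSet,
    threshold: float = 2.1,
    leaflet_sign: int = 1,
) -> LeafletStateSeries:
    """Classify every lipid at every frame and carry assignments with hysteresis.

    ``leaflet_sign=+1`` is the physically natural convention (head above tail
    means upper leaflet); ``-1`` inverts it.  Event *counting* is invariant
    to this choice.  Initial assignments come from the head's side of the
    membrane midplane (mean head z) at frame 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bz = traj.box[:, 2]
    if np.any(threshold >= bz / 2):
        logger.warning(
            "threshold %.2f nm >= half box height; no lipid can qualify", threshold
        )
    zh = traj.positions[:, lipids.head_indices, 2].astype(float)
    zt = traj.positions[:, lipids.tail_indices, 2].astype(float)
    dz = _min_image(zh - zt, bz[:, None])
    inst = np.zeros(dz.shape, dtype=np.int8)
    inst[dz >= threshold] = UPPER
    inst[dz <= -threshold] = LOWER
    inst *= np.int8(np.sign(leaflet_sign))

    # initial assignment: side of the membrane midplane at frame 0
    mid0 = zh[0].mean()
    init = np.where(zh[0] >= mid0, UPPER, LOWER).astype(np.int8)
    init *= np.int8(np.sign(leaflet_sign))

    # forward-fill the determined states over time (hysteresis)
    nf, nl = inst.shape
    det = inst != UNDETERMINED
    idx = np.where(det, np.arange(nf)[:, None], -1)
    last = np.maximum.accumulate(idx, axis=0)
    cols = np.broadcast_to(np.arange(nl), (nf, nl))
    assigned = np.where(last >= 0, inst[np.clip(last, 0, None), cols], init[None, :])
    return LeafletStateSeries(
        times=traj.times,
        lipid_ids=lipids.lipid_ids,
        instantaneous=inst,
        assigned=assigned.astype(np.int8),
        threshold=threshold,
    )


def detect_events(
    states: LeafletStateSeries, traj: Trajectory, lipids: LipidSet
) -> list[FlipFlopEvent]:
    """One event per assigned-leaflet change, at the first frame of the new
    assignment; a lipid's directions alternate by construction."""
    changes = states.assigned[1:] != states.assigned[:-1]
    frames, cols = np.nonzero(changes)
    frames = frames + 1
    events: list[FlipFlopEvent] = []
    for f, c in zip(frames, cols):
        new = states.assigned[f, c]
        direction = "upper->lower" if new == LOWER else "lower->upper"
        events.append(
            FlipFlopEvent(
                lipid_id=int(lipids.lipid_ids[c]),
                lipid_type=str(lipids.lipid_types[c]),
                time_ns=float(traj.times[f]),
                direction=direction,
                head_position=traj.positions[f, lipids.head_indices[c]].astype(float),
            )
        )
    events.sort(key=lambda e: e.time_ns)
    logger.info("detected %d flip-flop events", len(events))
    return events


def assign_events_to_sites(
    events: Sequence[FlipFlopEvent],
    sites: ProteinSites,
    traj: Trajectory,
    cutoff: float = 2.0,
) -> list[FlipFlopEvent]:
    """Label each event with the site whose pathway beads are nearest (3D
    minimum-image distance <= cutoff) to the head at the event frame, else
    'bulk'.  Ties break by distance, then site-name order."""
    if not sites.sites:
        return [
            FlipFlopEvent(e.lipid_id, e.lipid_type, e.time_ns, e.direction,
                          e.head_position, "bulk")
            for e in events
        ]
    for name, idx in sites.sites.items():
        if len(idx) == 0:
            raise ValueError(f"site {name!r} has an empty bead set")
    site_names = sorted(sites.sites)
    out: list[FlipFlopEvent] = []
    for e in events:
        f = int(np.searchsorted(traj.times, e.time_ns))
        f = min(f, traj.n_frames - 1)
        box = traj.box[f]
        best_site, best_d = "bulk", np.inf
        for name in site_names:
            beads = traj.positions[f, sites.sites[name]].astype(float)
            delta = _min_image(beads - e.head_position, box)
            d = float(np.sqrt((delta**2).sum(axis=1)).min())
            if d <= cutoff and d < best_d:
                best_site, best_d = name, d
        out.append(
            FlipFlopEvent(e.lipid_id, e.lipid_type, e.time_ns, e.direction,
                          e.head_position, best_site)
        )
    return out


def compute_rates(
    replica_events: Sequence[Sequence[FlipFlopEvent]],
    durations_us: Sequence[float],
) -> RateTable:
    """Per-(site, lipid type) rates: mean over replicas of events/duration,
    with SE = replica sample SD / sqrt(n).  A 'total' lipid_type row per site
    sums the per-type rates, its SE computed from per-replica totals."""
    n_rep = len(replica_events)
    if n_rep == 0:
        raise ValueError("need at least one replica")
    durations = np.asarray(durations_us, dtype=float)
    if len(durations) != n_rep or np.any(durations <= 0):
        raise ValueError("each replica needs a positive duration in us")

    keys: set[tuple[str, str]] = set()
    per_rep: list[dict[tuple[str, str], int]] = []
    for evs in replica_events:
        counts: dict[tuple[str, str], int] = {}
        for e in evs:
            k = (e.site, e.lipid_type)
            counts[k] = counts.get(k, 0) + 1
        per_rep.append(counts)
        keys |= set(counts)
    if not keys:
        keys = {("bulk", "all")}

    rows = []
    sites_seen = sorted({s for s, _ in keys})
    for site in sites_seen:
        types = sorted({t for s, t in keys if s == site})
        totals = np.zeros(n_rep)
        for t in types:
            k_rep = np.array(
                [per_rep[r].get((site, t), 0) / durations[r] for r in range(n_rep)]
            )
            totals += k_rep
            se = k_rep.std(ddof=1) / np.sqrt(n_rep) if n_rep > 1 else 0.0
            rows.append(
                dict(
                    site=site,
                    lipid_type=t,
                    rate_per_us=k_rep.mean(),
                    se_per_us=se,
                    n_replicas=n_rep,
                    total_events=int(sum(per_rep[r].get((site, t), 0) for r in range(n_rep))),
                )
            )
        se_tot = totals.std(ddof=1) / np.sqrt(n_rep) if n_rep > 1 else 0.0
        rows.append(
            dict(
                site=site,
                lipid_type="total",
                rate_per_us=totals.mean(),
                se_per_us=se_tot,
                n_replicas=n_rep,
                total_events=int(
                    sum(
                        per_rep[r].get((site, t), 0)
                        for r in range(n_rep)
                        for t in types
                    )
                ),
            )
        )
    return RateTable(pd.DataFrame(rows))


def threshold_scan(
    traj: Trajectory,
    lipids: LipidSet,
    thresholds: Sequence[float],
    duration_us: float | None = None,
) -> pd.DataFrame:
    """Run assign -> detect at each threshold; returns threshold, n_events, rate."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    if duration_us is None:
        duration_us = float(traj.times[-1] - traj.times[0]) / 1000.0
    rows = []
    for d in thresholds:
        states = assign_leaflets(traj, lipids, threshold=d)
        n = len(detect_events(states, traj, lipids))
        rows.append(dict(threshold_nm=d, n_events=n, rate_per_us=n / duration_us))
    return pd.DataFrame(rows)


def plateau_window(scan: pd.DataFrame, tol: float = 0.10) -> tuple[float, float]:
    """Widest contiguous threshold window where the rate varies < tol
    (relative to the window mean)."""
    thr = scan["threshold_nm"].to_numpy()
    rate = scan["rate_per_us"].to_numpy(float)
    best = (thr[0], thr[0])
    best_width = -1.0
    n = len(thr)
    for i in range(n):
        for j in range(i, n):
            w = rate[i : j + 1]
            m = w.mean()
            spread = (w.max() - w.min()) if m == 0 else (w.max() - w.min()) / m
            if spread < tol and thr[j] - thr[i] > best_width:
                best_width = thr[j] - thr[i]
                best = (float(thr[i]), float(thr[j]))
    return best


@dataclass
class ArrheniusFit:
    """ln k = lnA - E_A / (R T), fitted by least squares."""

    e_a: float  # kJ/mol
    ln_a: float  # ln(1/us)
    se_e_a: float
    se_ln_a: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    weighted: bool = False

    def predict(self, temperature: np.ndarray) -> np.ndarray:
        """Rates (1/us) predicted at the given temperatures."""
        t = np.asarray(temperature, dtype=float)
        return np.exp(self.ln_a - self.e_a / (R_KJ * t))


def fit_arrhenius(
    temperatures: Sequence[float],
    rates: Sequence[float],
    errors: Sequence[float] | None = None,
    weighted: bool = False,
) -> ArrheniusFit:
    """Fit ln k against 1/T.  Default: ordinary least squares.  With
    ``weighted=True``, inverse-variance weights from the relative errors
    SE/k (the error of ln k)."""
    t = np.asarray(temperatures, dtype=float)
    k = np.asarray(rates, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least three distinct temperatures")
    if np.any(k <= 0):
        raise ValueError("all rates must be positive; exclude zero-rate points")
    x = 1.0 / t
    y = np.log(k)
    if weighted:
        if errors is None:
            raise ValueError("weighted fit needs standard errors")
        se = np.asarray(errors, dtype=float)
        w = (k / se) ** 2
        X = np.vstack([np.ones_like(x), x]).T
        W = np.diag(w)
        cov = np.linalg.inv(X.T @ W @ X)
        beta = cov @ (X.T @ W @ y)
        yhat = X @ beta
        dof = max(len(x) - 2, 1)
        s2 = float((w * (y - yhat) ** 2).sum()) / dof
        se_b = np.sqrt(np.diag(cov) * s2)
        intercept, slope = beta
        se_int, se_slope = se_b
        resid = y - yhat
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        se_slope, se_int = res.stderr, res.intercept_stderr
        resid = y - (intercept + slope * x)
    return ArrheniusFit(
        e_a=-slope * R_KJ,
        ln_a=float(intercept),
        se_e_a=float((se_slope or 0.0) * R_KJ),
        se_ln_a=float(se_int or 0.0),
        residuals=resid,
        weighted=weighted,
    )


def eyring_rate(g_barrier: float, temperature: float, kappa: float = 1.0) -> float:
    """Transition-state rate k = kappa (k_B T / h) exp(-G‡ / R T), in 1/s."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return kappa * (K_B * temperature / PLANCK_H) * np.exp(
        -g_barrier / (R_KJ * temperature)
    )


def eyring_speedup(g_ref: float, g_new: float, temperature: float) -> float:
    """Fold acceleration when the barrier drops from g_ref to g_new (kJ/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp((g_ref - g_new) / (R_KJ * temperature)))


def scaled_half_life(t_ref: float, fold: float) -> float:
    """Half-life after a fold-change acceleration, in the units of t_ref."""
    return t_ref / fold


def compare_rates(rates_a: Sequence[float], rates_b: Sequence[float]) -> float:
    """Two-sided Welch t-test on per-replica rates."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicas per group")
    if np.array_equal(np.sort(a), np.sort(b)) and a.std() == 0 and b.std() == 0:
        return 1.0
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)
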