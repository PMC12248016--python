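"""Trajectory observables: hydrogen-bond graphs, water-wire detection and
classification, nearest-chloride distance series with smoothing and
leaving-event calls, inner-gate state classification, and wire-occupancy
summaries.

A hydrogen bond is a donor-acceptor pair within the distance cutoff
(default 3.5 Å) whose donor-H-acceptor angle meets the angle cutoff
(default 150 deg). A water wire is a path in the per-frame hydrogen-bond
graph from a protein source site to a solution-compartment pseudo-node.
An ion has "left" the anion pathway when its smoothed distance from the
Y445 Cα stays above 12 Å for the dwell time (or to the trajectory end).
Coordinates must be pre-imaged; no periodic wrapping is applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from clcpipe.core_io import (
    AnalysisConfig,
    CompartmentSpec,
    TrajectoryFrameSet,
    WireClassDef,
    default_compartments,
)

logger = logging.getLogger("clcpipe")


# ---------------------------------------------------------------------------
# Hydrogen-bond graph
# ---------------------------------------------------------------------------

@dataclass
class HBondGraph:
    """Undirected hydrogen-bond connectivity for one frame.

    Nodes are water-oxygen atom ids, protein donor/acceptor (N/O) atom
    ids, and compartment names; edges are geometric hydrogen bonds, plus
    membership edges from each compartment to the waters inside it.
    """

    graph: nx.Graph
    frame_index: int


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees (b is the vertex, i.e. the hydrogen)."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def build_hbond_graph(traj: TrajectoryFrameSet, frame_index: int,
                      config: AnalysisConfig,
                      compartments: Optional[Sequence[CompartmentSpec]] = None,
                      ) -> HBondGraph:
    """Build the hydrogen-bond graph for one frame.

    Water-water and water-protein pairs within the distance cutoff are
    kept if any hydrogen of a donor water makes the required
    donor-H-acceptor angle. Protein N/O atoms participate as acceptors
    (the scaffold carries no protein hydrogens); a water without
    hydrogens falls back to distance-only when
    ``config.hbond_distance_only_fallback`` is set (logged), else it
    cannot donate.
    """
    if compartments is None:
        compartments = default_compartments(config.compartment_z_half)
    top = traj.topology
    xyz = traj.coords[frame_index]

    o_idx = traj.indices_by_role("water_O")
    prot_mask = (top.role == "protein") & top.element.isin(["N", "O"])
    prot_idx = np.flatnonzero(prot_mask.to_numpy())
    h_by_o = traj.water_hydrogens()

    node_idx = np.concatenate([o_idx, prot_idx]).astype(int)
    is_water = np.concatenate([np.ones(len(o_idx), bool),
                               np.zeros(len(prot_idx), bool)])
    atom_ids = top.atom_id.to_numpy()

    g = nx.Graph()
    for i, w in zip(node_idx, is_water):
        g.add_node(int(atom_ids[i]), kind="water" if w else "protein",
                   index=int(i))
    for comp in compartments:
        g.add_node(comp.name, kind="compartment")

    if len(node_idx) > 0:
        tree = cKDTree(xyz[node_idx])
        pairs = tree.query_pairs(config.hbond_distance_cutoff)
    else:
        pairs = set()

    angle_min = config.hbond_angle_cutoff_deg
    for a, b in pairs:
        ia, ib = int(node_idx[a]), int(node_idx[b])
        if not (is_water[a] or is_water[b]):
            continue  # protein-protein contacts are not wire edges
        # same-residue pair (e.g. O of a water vs its own H) cannot occur
        # among O/N nodes, but two protein atoms of one residue can; the
        # water check above already excludes that case.
        bonded = False
        for donor, acceptor, donor_is_water in ((ia, ib, is_water[a]),
                                                (ib, ia, is_water[b])):
            if not donor_is_water:
                continue  # only waters donate here
            hs = h_by_o.get(donor, [])
            if not hs:
                if config.hbond_distance_only_fallback:
                    logger.warning(
                        "water O atom %d has no hydrogens; using "
                        "distance-only hydrogen-bond fallback",
                        atom_ids[donor])
                    bonded = True
                    break
                continue
            for h in hs:
                ang = _angle_deg(xyz[donor], xyz[h], xyz[acceptor])
                if ang >= angle_min:
                    bonded = True
                    break
            if bonded:
                break
        if bonded:
            g.add_edge(int(atom_ids[ia]), int(atom_ids[ib]))

    # compartment membership edges
    if len(o_idx) > 0:
        o_xyz = xyz[o_idx]
        assigned = np.zeros(len(o_idx), dtype=bool)
        for comp in compartments:
            mask = comp.contains(o_xyz, atom_ids[o_idx]) & ~assigned
            assigned |= mask
            for i in np.flatnonzero(mask):
                g.add_edge(comp.name, int(atom_ids[o_idx[i]]))
    return HBondGraph(graph=g, frame_index=frame_index)


# ---------------------------------------------------------------------------
# Water-wire detection
# ---------------------------------------------------------------------------

@dataclass
class WaterWireRecord:
    """One detected wire: frame, subunit, class, and the node path from
    the source site to the sink compartment."""

    frame_index: int
    subunit: str
    wire_class: int
    path: list
    path_length: int = 0

    def __post_init__(self) -> None:
        self.path_length = len(self.path)


def _source_nodes(traj: TrajectoryFrameSet, chain: str,
                  wc: WireClassDef) -> list[int]:
    nodes = []
    for resnum, aname in wc.source:
        try:
            idx = traj.atom_index(chain, resnum, aname)
        except KeyError as exc:
            raise KeyError(
                f"wire class {wc.wire_class} source atom missing from "
                f"topology: {exc}") from exc
        nodes.append(int(traj.topology.atom_id.iloc[idx]))
    return nodes


def _waypoint_waters(traj: TrajectoryFrameSet, frame_index: int, chain: str,
                     wc: WireClassDef, radius: float) -> set[int]:
    """Atom ids of water oxygens within ``radius`` of the waypoint atom."""
    resnum, aname = wc.waypoint
    wp_idx = traj.atom_index(chain, resnum, aname)
    xyz = traj.coords[frame_index]
    o_idx = traj.indices_by_role("water_O")
    if len(o_idx) == 0:
        return set()
    d = np.linalg.norm(xyz[o_idx] - xyz[wp_idx], axis=1)
    ids = traj.topology.atom_id.to_numpy()[o_idx[d <= radius]]
    return {int(i) for i in ids}


def detect_water_wires(traj: TrajectoryFrameSet, hb: HBondGraph,
                       config: AnalysisConfig,
                       sink: str = "intracellular",
                       chains: Optional[Sequence[str]] = None,
                       ) -> list[WaterWireRecord]:
    """Detect wires of every configured class in one frame's graph.

    For waypoint_mode 'require' a wire exists when some water near the
    waypoint is reachable from the source and reaches the sink (the
    reported path is the concatenated shortest route through the best
    such water); for 'exclude' connectivity is evaluated with the
    waypoint-adjacent waters removed.
    """
    g = hb.graph
    records: list[WaterWireRecord] = []
    if chains is None:
        chains = traj.chains
    if sink not in g:
        return records
    for chain in chains:
        for wc in config.wire_classes:
            sources = [s for s in _source_nodes(traj, chain, wc) if s in g]
            if not sources:
                continue
            path = _class_path(traj, hb, chain, wc, sources, sink, config)
            if path is not None:
                records.append(WaterWireRecord(
                    frame_index=hb.frame_index, subunit=chain,
                    wire_class=wc.wire_class, path=path))
    return records


def _class_path(traj, hb, chain, wc, sources, sink, config):
    g = hb.graph
    if wc.waypoint_mode == "exclude":
        near = _waypoint_waters(traj, hb.frame_index, chain, wc,
                                config.waypoint_radius)
        sub = g.subgraph(n for n in g.nodes if n not in near)
        return _shortest_from_any(sub, sources, sink)
    if wc.waypoint_mode == "require":
        near = _waypoint_waters(traj, hb.frame_index, chain, wc,
                                config.waypoint_radius)
        best = None
        for w in sorted(near):
            if w not in g:
                continue
            try:
                p_src = min(
                    (nx.shortest_path(g, s, w) for s in sources
                     if nx.has_path(g, s, w)),
                    key=len, default=None)
                if p_src is None or not nx.has_path(g, w, sink):
                    continue
                p_sink = nx.shortest_path(g, w, sink)
                path = p_src + p_sink[1:]
                if best is None or len(path) < len(best):
                    best = path
            except nx.NetworkXNoPath:
                continue
        return best
    return _shortest_from_any(g, sources, sink)


def _shortest_from_any(g, sources, sink):
    best = None
    for s in sources:
        if s not in g or sink not in g:
            continue
        if nx.has_path(g, s, sink):
            p = nx.shortest_path(g, s, sink)
            if best is None or len(p) < len(best):
                best = p
    return best


def detect_wires_trajectory(traj: TrajectoryFrameSet, config: AnalysisConfig,
                            compartments: Optional[Sequence[CompartmentSpec]]
                            = None, sink: str = "intracellular",
                            ) -> list[WaterWireRecord]:
    """Per-frame wire detection over a whole trajectory."""
    records: list[WaterWireRecord] = []
    for f in range(traj.n_frames):
        hb = build_hbond_graph(traj, f, config, compartments)
        records.extend(detect_water_wires(traj, hb, config, sink=sink))
    logger.info("detected %d wire records over %d frames",
                len(records), traj.n_frames)
    return records


# ---------------------------------------------------------------------------
# Nearest-ion distance series and leaving events
# ---------------------------------------------------------------------------

@dataclass
class LeavingEvent:
    onset_time_ns: float
    exit_side: Optional[str]


@dataclass
class IonDistanceSeries:
    """Per-subunit distance from the reference atom (default Y445 Cα) to
    the nearest Cl- ion, raw and smoothed, with called leaving events."""

    subunit: str
    times_ns: np.ndarray
    raw: np.ndarray
    nearest_z: np.ndarray          # z of the nearest ion (exit-side call)
    smoothed: Optional[np.ndarray] = None
    events: list[LeavingEvent] = field(default_factory=list)
    verdict: str = "stayed"        # left | stayed | indeterminate
    flagged_empty: bool = False    # frames with no ions present


def nearest_ion_distance(traj: TrajectoryFrameSet,
                         reference: Optional[tuple[int, str]] = None,
                         ion_role: str = "chloride",
                         ) -> list[IonDistanceSeries]:
    """d(t) = min over ions of the Euclidean distance to the reference
    atom, per subunit; ties break to the lowest atom_id. Frames with no
    ions record +inf and flag the series."""
    if reference is None:
        reference = (445, "CA")
    out = []
    ion_idx = traj.indices_by_role(ion_role)
    for chain in traj.chains:
        ref_idx = traj.atom_index(chain, reference[0], reference[1])
        if len(ion_idx) == 0:
            raw = np.full(traj.n_frames, np.inf)
            zs = np.full(traj.n_frames, np.nan)
            out.append(IonDistanceSeries(chain, traj.times_ns.copy(), raw,
                                         zs, flagged_empty=True))
            logger.warning("no %s ions in trajectory; distances set to "
                           "+inf for chain %s", ion_role, chain)
            continue
        ref = traj.coords[:, ref_idx, :]            # (F, 3)
        ions = traj.coords[:, ion_idx, :]           # (F, I, 3)
        d = np.linalg.norm(ions - ref[:, None, :], axis=2)
        # argmin returns the first minimum; ion_idx is sorted by atom_id
        j = np.argmin(d, axis=1)
        raw = d[np.arange(traj.n_frames), j]
        zs = ions[np.arange(traj.n_frames), j, 2]
        out.append(IonDistanceSeries(chain, traj.times_ns.copy(), raw, zs))
    return out


def moving_average(values: np.ndarray, times_ns: np.ndarray,
                   window_ns: float) -> np.ndarray:
    """Centered moving average with windows truncated (shrunk) at the
    edges; output is aligned to the input times."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return values.copy()
    dt = float(np.median(np.diff(times_ns)))
    half = max(0, int(round(window_ns / dt)) // 2)
    if half == 0:
        return values.copy()
    out = np.empty_like(values)
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def detect_leaving_events(series: IonDistanceSeries, config: AnalysisConfig,
                          ) -> IonDistanceSeries:
    """Call leaving events on the smoothed series.

    An event is the first time the smoothed distance exceeds the leave
    threshold and stays above it for at least ``min_dwell_ns`` or to the
    trajectory end. Trajectories shorter than the dwell window yield the
    verdict 'indeterminate'. The exit side is the sign of z (membrane
    midplane at z = 0) of the nearest ion at onset.
    """
    if series.smoothed is None:
        series.smoothed = moving_average(series.raw, series.times_ns,
                                         config.smoothing_window_ns)
    t = series.times_ns
    span = t[-1] - t[0] if len(t) > 1 else 0.0
    series.events = []
    if span < config.min_dwell_ns:
        series.verdict = "indeterminate"
        return series
    above = series.smoothed > config.leave_threshold
    n = len(above)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        dwell = t[j - 1] - t[i]
        if dwell >= config.min_dwell_ns or j == n:
            # exit side from the first *raw* threshold crossing (the
            # smoothed onset can precede actual departure)
            raw_cross = np.flatnonzero(series.raw > config.leave_threshold)
            side = None
            if len(raw_cross):
                z = series.nearest_z[raw_cross[0]]
                if np.isfinite(z):
                    side = "extracellular" if z > 0 else "intracellular"
            series.events.append(LeavingEvent(onset_time_ns=float(t[i]),
                                              exit_side=side))
        i = j
    series.verdict = "left" if series.events else "stayed"
    return series


def aggregate_leaving(series_list: Sequence[IonDistanceSeries]) -> dict:
    """k-of-n replicate report over per-trajectory verdicts."""
    verdicts = [s.verdict for s in series_list]
    n_left = sum(v == "left" for v in verdicts)
    n_det = sum(v in ("left", "stayed") for v in verdicts)
    sides = [e.exit_side for s in series_list for e in s.events
             if e.exit_side is not None]
    return {
        "n": len(verdicts),
        "n_determinate": n_det,
        "n_left": n_left,
        "n_stayed": n_det - n_left,
        "n_indeterminate": len(verdicts) - n_det,
        "exit_sides": sides,
        "verdicts": verdicts,
    }


# ---------------------------------------------------------------------------
# Inner-gate state
# ---------------------------------------------------------------------------

@dataclass
class GateStateSeries:
    subunit: str
    times_ns: np.ndarray
    distance: np.ndarray      # S107 OG - Y445 OH, Å
    state: np.ndarray         # "open" / "closed"


def classify_gate_state(traj: TrajectoryFrameSet, config: AnalysisConfig,
                        ) -> list[GateStateSeries]:
    """Open when the S107 OG - Y445 OH separation exceeds the gate-open
    cutoff (default 6 Å), else closed."""
    out = []
    for chain in traj.chains:
        i_og = traj.atom_index(chain, 107, "OG")
        i_oh = traj.atom_index(chain, 445, "OH")
        d = np.linalg.norm(traj.coords[:, i_og, :] - traj.coords[:, i_oh, :],
                           axis=1)
        state = np.where(d > config.gate_open_cutoff, "open", "closed")
        out.append(GateStateSeries(chain, traj.times_ns.copy(), d, state))
    return out


# ---------------------------------------------------------------------------
# Wire-occupancy summary
# ---------------------------------------------------------------------------

@dataclass
class WireOccupancySummary:
    """Per-simulation fraction of frames with any wire, plus box-plot
    statistics across simulations (median, Q1-Q3, 1.5x IQR whiskers;
    quartiles by linear interpolation)."""

    fractions: np.ndarray
    per_class_fractions: dict
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


def wire_fraction(records: Sequence[WaterWireRecord], n_frames: int,
                  wire_class: Optional[int] = None) -> float:
    """Fraction of frames containing a wire (of one class, or any)."""
    frames = {r.frame_index for r in records
              if wire_class is None or r.wire_class == wire_class}
    return len(frames) / n_frames if n_frames else 0.0


def summarize_wire_occupancy(records_per_sim: Sequence[Sequence[WaterWireRecord]],
                             n_frames: int) -> WireOccupancySummary:
    fractions = np.array([wire_fraction(r, n_frames)
                          for r in records_per_sim])
    classes = sorted({rec.wire_class for recs in records_per_sim
                      for rec in recs})
    per_class = {c: [wire_fraction(r, n_frames, c) for r in records_per_sim]
                 for c in classes}
    q1, med, q3 = np.percentile(fractions, [25, 50, 75]) if len(fractions) \
        else (np.nan, np.nan, np.nan)
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = fractions[(fractions >= lo_lim) & (fractions <= hi_lim)]
    wlo = float(inside.min()) if len(inside) else float("nan")
    whi = float(inside.max()) if len(inside) else float("nan")
    return WireOccupancySummary(fractions=fractions,
                                per_class_fractions=per_class,
                                median=float(med), q1=float(q1), q3=float(q3),
                                whisker_low=wlo, whisker_high=whi)
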