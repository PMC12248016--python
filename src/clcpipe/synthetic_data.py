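"""Seeded generators with planted ground truth for every pipeline stage.

The trajectory generator builds a minimal two-subunit scaffold (reference
atoms for S107, E113, K131, E148, E203, F357 and Y445 on chains A and B)
rather than a full transporter model; every downstream detector depends
only on these declared reference atoms, so the stand-in is faithful at
desk scale. Planted observables:

* water wires -- chains of waters with 2.8 Å O-O spacing and near-linear
  (>=160 deg) donor-H-acceptor geometry, comfortably inside the default
  3.5 Å / 150 deg detection cutoffs so generator and detector thresholds
  stay decoupled;
* Cl- leaving events -- ions displaced monotonically past 12 Å from the
  Y445 Cα toward a planted exit side;
* inner-gate opening -- S107 OG / Y445 OH separation stepped above the
  gate-open cutoff.

Uptake curves follow intrinsic-rate x protection-factor kinetics with a
back-exchange retention factor; flux traces have a valinomycin onset and
known unitary turnover; titration heats follow the one-site Wiseman
isotherm. Same seed + spec gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from clcpipe import core_io
from clcpipe.core_io import TrajectoryFrameSet

AMINO1 = "ACDEFGHIKLMNQRSTVWY"  # no proline; prolines are placed explicitly


class SpecError(ValueError):
    """Raised when a generator spec is internally inconsistent."""


# ---------------------------------------------------------------------------
# Trajectory generator
# ---------------------------------------------------------------------------

# Reference-atom scaffold, one copy per subunit (chain offsets applied in x).
# Positions in Å; membrane midplane at z = 0, intracellular side at z < 0.
_SCAFFOLD = [
    # (residue_number, residue_name, atom_name, element, xyz)
    (107, "SER", "CA", "C", (-2.0, 0.0, -6.0)),
    (107, "SER", "OG", "O", (-1.5, 0.0, -7.5)),
    (113, "GLU", "CA", "C", (6.0, 0.0, -2.0)),
    (131, "LYS", "CA", "C", (-4.0, 0.0, 0.0)),
    (131, "LYS", "NZ", "N", (-3.0, 0.0, -1.0)),
    (148, "GLU", "CA", "C", (0.0, 0.0, 6.0)),
    (148, "GLU", "OE1", "O", (0.0, 0.0, 4.5)),
    (148, "GLU", "OE2", "O", (0.0, 1.2, 4.8)),
    (203, "GLU", "CA", "C", (3.5, 0.0, -4.0)),
    (203, "GLU", "OE1", "O", (2.5, 0.0, -2.5)),
    (357, "PHE", "CA", "C", (5.0, 0.0, 5.0)),
    (445, "TYR", "CA", "C", (2.0, 0.0, -7.0)),
    (445, "TYR", "OH", "O", (1.0, 0.0, -6.0)),
]

_CHAIN_X_OFFSET = 60.0   # separation between the two subunits
_Z_INTRA = -12.0         # intracellular compartment boundary (slab half-width)
_OO_SPACING = 2.8        # planted O-O hydrogen-bond length
_OH_LENGTH = 0.96
_GATE_OPEN_OH = (6.8, 0.0, -6.0)   # Y445 OH position in the open gate
_BOUND_CL = ((0.0, 0.0, 2.0), (0.0, 0.0, -1.0))        # S_ext / S_cen analogs
_BOUND_CL_INNER = ((0.5, 0.0, -7.5), (0.0, 0.0, -8.5))  # at the inner gate

# Water-wire waypoints per class: polylines from the source protein atom
# toward the intracellular slab (class 2 passes near E203 OE1, class 3
# avoids it, class 1 runs from the inner-gate hydroxyls).
_WIRE_PATHS = {
    1: {"source": (107, "OG"), "via": [(-1.5, 0.0, -13.5)]},
    2: {"source": (148, "OE1"), "via": [(2.5, 0.0, -2.5), (5.5, 0.0, -5.0),
                                        (5.5, 0.0, -13.5)]},
    3: {"source": (148, "OE2"), "via": [(-3.0, 4.0, -2.0), (-3.0, 4.0, -13.5)]},
}


@dataclass
class WireEpisode:
    chain: str
    wire_class: int
    start_frame: int
    end_frame: int      # inclusive


@dataclass
class LeavingEpisode:
    chain: str
    depart_frame: int
    exit_side: str = "extracellular"   # or "intracellular"
    transit_frames: int = 15


@dataclass
class GateEpisode:
    chain: str
    start_frame: int
    end_frame: int      # inclusive


@dataclass
class TrajectorySpec:
    """Ground-truth plan for one synthetic trajectory."""

    n_frames: int = 100
    frame_dt_ns: float = 0.2     # 200 ps save interval
    chains: tuple[str, ...] = ("A", "B")
    wire_episodes: list[WireEpisode] = field(default_factory=list)
    leaving_episodes: list[LeavingEpisode] = field(default_factory=list)
    gate_episodes: list[GateEpisode] = field(default_factory=list)
    n_bulk_waters: int = 8
    noise_sigma: float = 0.0     # Å, isotropic Gaussian on all atoms
    seed: int = 0
    condition: str = "Egate_deprotonated"
    replicate: int = 0

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise SpecError("noise sigma must be >= 0")
        seen: dict[tuple, list[tuple[int, int]]] = {}
        for ep in self.wire_episodes:
            if not (0 <= ep.start_frame <= ep.end_frame < self.n_frames):
                raise SpecError(f"wire episode outside frame range: {ep}")
            if ep.wire_class not in _WIRE_PATHS:
                raise SpecError(f"unknown wire class {ep.wire_class}")
            if ep.chain not in self.chains:
                raise SpecError(f"unknown chain {ep.chain!r}")
            key = (ep.chain, ep.wire_class)
            for s, e in seen.get(key, []):
                if ep.start_frame <= e and s <= ep.end_frame:
                    raise SpecError(
                        f"overlapping wire episodes for chain {ep.chain} "
                        f"class {ep.wire_class} are geometrically "
                        "unrealizable (coincident water chains)")
            seen.setdefault(key, []).append((ep.start_frame, ep.end_frame))
        for ep in self.gate_episodes:
            if not (0 <= ep.start_frame <= ep.end_frame < self.n_frames):
                raise SpecError(f"gate episode outside frame range: {ep}")
        sides = {"extracellular", "intracellular"}
        by_chain: dict[str, list[LeavingEpisode]] = {}
        for ep in self.leaving_episodes:
            if not (0 <= ep.depart_frame < self.n_frames):
                raise SpecError(f"leaving episode outside frame range: {ep}")
            if ep.exit_side not in sides:
                raise SpecError(f"bad exit side {ep.exit_side!r}")
            by_chain.setdefault(ep.chain, []).append(ep)
        for chain, eps in by_chain.items():
            if len(eps) > 1:
                raise SpecError(
                    f"multiple leaving episodes for chain {chain} are "
                    "geometrically unrealizable (ions leave once)")


def _wire_water_positions(wire_class: int, x_off: float) -> np.ndarray:
    """Water oxygen positions realizing one planted wire."""
    path = _WIRE_PATHS[wire_class]
    src = next(np.array(xyz) for r, n, a, e, xyz in _SCAFFOLD
               if (r, a) == path["source"])
    points = [src] + [np.asarray(p, dtype=float) for p in path["via"]]
    oxygens: list[np.ndarray] = []
    pos = points[0]
    remaining = points[1:]
    carry = _OO_SPACING
    while remaining:
        seg_end = remaining[0]
        seg = seg_end - pos
        seg_len = float(np.linalg.norm(seg))
        if carry > seg_len:
            carry -= seg_len
            pos = seg_end
            remaining.pop(0)
            continue
        pos = pos + seg * (carry / seg_len)
        oxygens.append(pos.copy())
        carry = _OO_SPACING
    if not oxygens or oxygens[-1][2] > _Z_INTRA - 0.5:
        # extend straight down until comfortably inside the slab
        last = oxygens[-1] if oxygens else src
        while last[2] > _Z_INTRA - 0.5:
            last = last + np.array([0.0, 0.0, -_OO_SPACING])
            oxygens.append(last.copy())
    out = np.array(oxygens)
    out[:, 0] += x_off
    return out


def _water_atoms(o_pos: np.ndarray, donate_to: np.ndarray) -> np.ndarray:
    """O + 2 H coordinates with one H aimed at the acceptor ``donate_to``."""
    d = donate_to - o_pos
    d = d / np.linalg.norm(d)
    # arbitrary perpendicular for the second hydrogen
    perp = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(d, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    h1 = o_pos + _OH_LENGTH * d
    h2 = o_pos + _OH_LENGTH * (0.326 * d + 0.945 * perp)  # ~109.5 deg
    return np.array([o_pos, h1, h2])


def gen_trajectory(spec: TrajectorySpec) -> TrajectoryFrameSet:
    """Generate a trajectory with the planted episodes geometrically
    realized. Deterministic given the spec seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    atoms: list[dict] = []   # topology rows
    base: list[np.ndarray] = []  # base coordinates (closed / bound / parked)

    def add_atom(name, resname, resnum, chain, element, xyz):
        atoms.append(dict(atom_name=name, residue_name=resname,
                          residue_number=resnum, chain_id=chain,
                          element=element))
        base.append(np.asarray(xyz, dtype=float))

    chain_off = {c: i * _CHAIN_X_OFFSET for i, c in enumerate(spec.chains)}

    # protein scaffold
    scaffold_idx: dict[tuple, int] = {}
    for chain in spec.chains:
        for resnum, resname, aname, elem, xyz in _SCAFFOLD:
            scaffold_idx[(chain, resnum, aname)] = len(atoms)
            p = np.asarray(xyz, dtype=float) + [chain_off[chain], 0.0, 0.0]
            add_atom(aname, resname, resnum, chain, elem, p)

    # wire waters: topology is fixed, so each planted wire owns a set of
    # waters that are parked far from everything outside its episodes
    wire_atoms: dict[int, dict] = {}   # episode index -> dict
    water_resnum = 1000
    park_counter = 0
    for ei, ep in enumerate(spec.wire_episodes):
        x_off = chain_off[ep.chain]
        o_pos = _wire_water_positions(ep.wire_class, x_off)
        src = next(np.array(xyz) for r, n, a, e, xyz in _SCAFFOLD
                   if (r, a) == _WIRE_PATHS[ep.wire_class]["source"])
        src = src + [x_off, 0.0, 0.0]
        acceptors = [src] + [o_pos[i] for i in range(len(o_pos) - 1)]
        formed = []
        parked = []
        indices = []
        for wi, (o, acc) in enumerate(zip(o_pos, acceptors)):
            triple = _water_atoms(o, acc)
            park = triple + np.array([0.0, 30.0 + 6.0 * park_counter, -o[2]])
            park_counter += 1
            idx0 = len(atoms)
            for name, elem, xyz in zip(("O", "H1", "H2"), ("O", "H", "H"),
                                       park):
                add_atom(name, "HOH", water_resnum, ep.chain, elem, xyz)
            water_resnum += 1
            formed.append(triple)
            parked.append(park)
            indices.append(idx0)
        wire_atoms[ei] = dict(formed=np.concatenate(formed),
                              parked=np.concatenate(parked),
                              idx0=indices[0], n=3 * len(o_pos))

    # bulk waters, placed in a lateral band that cannot touch scaffold,
    # wires, or compartment-connected regions
    for b in range(spec.n_bulk_waters):
        chain = spec.chains[b % len(spec.chains)]
        o = np.array([chain_off[chain] + rng.uniform(-15, 15),
                      rng.uniform(10.0, 24.0),
                      rng.uniform(-8.0, 8.0)])
        triple = _water_atoms(o, o + np.array([1.0, 0.0, 0.0]))
        for name, elem, xyz in zip(("O", "H1", "H2"), ("O", "H", "H"), triple):
            add_atom(name, "HOH", water_resnum, chain, elem, xyz)
        water_resnum += 1

    # chloride ions: two per subunit
    leaving_by_chain = {ep.chain: ep for ep in spec.leaving_episodes}
    cl_info: list[dict] = []
    for chain in spec.chains:
        ep = leaving_by_chain.get(chain)
        bound = (_BOUND_CL_INNER
                 if ep is not None and ep.exit_side == "intracellular"
                 else _BOUND_CL)
        for k, pos in enumerate(bound):
            p = np.asarray(pos, dtype=float) + [chain_off[chain], 0.0, 0.0]
            cl_info.append(dict(idx=len(atoms), chain=chain, bound=p, k=k))
            add_atom("CL", "CLA", 2000 + k, chain, "CL", p)

    base_arr = np.array(base)
    n_atoms = len(atoms)
    coords = np.tile(base_arr, (spec.n_frames, 1, 1))

    # realize wire episodes
    for ei, ep in enumerate(spec.wire_episodes):
        info = wire_atoms[ei]
        sl = slice(info["idx0"], info["idx0"] + info["n"])
        coords[ep.start_frame:ep.end_frame + 1, sl, :] = info["formed"]

    # realize leaving episodes (both ions of the subunit leave)
    for ep in spec.leaving_episodes:
        sign = 1.0 if ep.exit_side == "extracellular" else -1.0
        for info in cl_info:
            if info["chain"] != ep.chain:
                continue
            exit_pos = info["bound"] + np.array([0.0, 0.0, sign * 30.0])
            for f in range(ep.depart_frame, spec.n_frames):
                t = min(1.0, (f - ep.depart_frame) / max(1, ep.transit_frames))
                coords[f, info["idx"], :] = (1 - t) * info["bound"] + t * exit_pos

    # realize gate-open episodes (Y445 OH steps away from S107 OG)
    for ep in spec.gate_episodes:
        gi = scaffold_idx[(ep.chain, 445, "OH")]
        open_pos = np.asarray(_GATE_OPEN_OH) + [chain_off[ep.chain], 0.0, 0.0]
        coords[ep.start_frame:ep.end_frame + 1, gi, :] = open_pos

    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)

    topology = pd.DataFrame(atoms)
    topology.insert(0, "atom_id", np.arange(1, n_atoms + 1))
    topology["role"] = core_io.assign_roles(
        topology.residue_name.to_numpy(), topology.element.to_numpy())
    times = spec.frame_dt_ns * np.arange(spec.n_frames)
    meta = dict(condition=spec.condition, replicate=spec.replicate,
                seed=spec.seed)
    return TrajectoryFrameSet(topology=topology, coords=coords,
                              times_ns=times, box=None, metadata=meta)


def trajectory_ground_truth(spec: TrajectorySpec) -> dict:
    """JSON-serializable record of what was planted."""
    return {
        "n_frames": spec.n_frames,
        "frame_dt_ns": spec.frame_dt_ns,
        "wire_episodes": [vars(e) for e in spec.wire_episodes],
        "leaving_episodes": [vars(e) for e in spec.leaving_episodes],
        "gate_episodes": [vars(e) for e in spec.gate_episodes],
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "condition": spec.condition,
    }


# ---------------------------------------------------------------------------
# HDX uptake generator
# ---------------------------------------------------------------------------

# labeling time grid (s) used in the emulated experiments; the starred
# points (20, 633, 20000) are triplicated
DEFAULT_TIME_GRID = (20.0, 63.0, 200.0, 633.0, 2000.0, 6325.0, 20000.0, 63000.0)
TRIPLICATED_TIMES = (20.0, 633.0, 20000.0)


def exchangeable_positions(sequence: str, start: int = 1) -> list[int]:
    """1-based residue positions contributing exchangeable amides: the
    first two residues and prolines beyond position 2 are excluded."""
    return [start + i for i in range(2, len(sequence))
            if sequence[i] != "P"]


@dataclass
class UptakeSpec:
    """Ground truth for a synthetic peptide-uptake dataset.

    Per-residue uptake follows beta * (1 - exp(-k_int(pH) * t / P_r))
    with k_int(pH) = k_ref * 10**(pH - ref_pH) (base-catalyzed regime);
    a peptide's uptake sums its exchangeable residues. The fully
    deuterated control equals beta * N_ex plus noise.
    """

    sequence: str = ""
    peptides: Optional[pd.DataFrame] = None   # peptide_map schema
    protection: Optional[np.ndarray] = None   # per residue, >= 1
    k_ref: float = 1.0      # s^-1 at ref_pH
    ref_pH: float = 3.0
    ph_list: tuple[float, ...] = (3.0, 3.5, 4.0, 4.5, 6.5)
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    beta: float = 0.7       # back-exchange retention factor, in (0, 1]
    noise_sigma: float = 0.0   # Da
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            rng = np.random.default_rng(12345)
            self.sequence = "".join(rng.choice(list(AMINO1), size=120))
        if self.peptides is None:
            self.peptides = gen_peptide_map(self.sequence, n_peptides=24,
                                            length_range=(8, 16), seed=777)
        if self.protection is None:
            self.protection = np.ones(len(self.sequence))
        self.protection = np.asarray(self.protection, dtype=float)
        if len(self.protection) != len(self.sequence):
            raise SpecError("protection must have one factor per residue")
        if np.any(self.protection < 1):
            raise SpecError("protection factors must be >= 1")
        if not (0 < self.beta <= 1):
            raise SpecError("beta must be in (0, 1]")


def peptide_uptake_truth(spec: UptakeSpec, start: int, end: int,
                         pH: float, t: float) -> float:
    """Noise-free uptake (Da) of one peptide under the generator law."""
    seq = spec.sequence[start - 1:end]
    k_int = spec.k_ref * 10.0 ** (pH - spec.ref_pH)
    tot = 0.0
    for pos in exchangeable_positions(seq, start=start):
        P = spec.protection[pos - 1]
        tot += spec.beta * (1.0 - np.exp(-k_int * t / P))
    return tot


def gen_uptake_dataset(spec: UptakeSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Return (hdx_uptake table, fd_control table, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for pep in spec.peptides.itertuples():
        for pH in spec.ph_list:
            for t in spec.time_grid:
                n_rep = 3 if t in TRIPLICATED_TIMES else 1
                clean = peptide_uptake_truth(spec, pep.start, pep.end, pH, t)
                for rep in range(1, n_rep + 1):
                    d = clean + rng.normal(0.0, spec.noise_sigma)
                    rows.append(dict(peptide_id=pep.peptide_id,
                                     start=pep.start, end=pep.end,
                                     sequence=pep.sequence, pH=pH,
                                     time_s=t, uptake_Da=max(d, 0.0),
                                     replicate=rep))
    uptake = pd.DataFrame(rows)
    fd_rows = []
    for pep in spec.peptides.itertuples():
        n_ex = len(exchangeable_positions(pep.sequence, start=pep.start))
        d = spec.beta * n_ex + rng.normal(0.0, spec.noise_sigma)
        fd_rows.append(dict(peptide_id=pep.peptide_id, uptake_Da=max(d, 0.0)))
    fd = pd.DataFrame(fd_rows)
    truth = dict(k_ref=spec.k_ref, ref_pH=spec.ref_pH, beta=spec.beta,
                 protection=spec.protection.tolist(),
                 noise_sigma=spec.noise_sigma, seed=spec.seed)
    return uptake, fd, truth


def gen_peptide_map(sequence: str, n_peptides: int,
                    length_range: tuple[int, int] = (6, 18),
                    seed: int = 0) -> pd.DataFrame:
    """Random peptide map over ``sequence`` (peptide_map schema,
    1-based inclusive start/end). Deterministic given seed."""
    rng = np.random.default_rng(seed)
    L = len(sequence)
    rows = []
    for i in range(n_peptides):
        plen = int(rng.integers(length_range[0],
                                min(length_range[1], L) + 1))
        start = int(rng.integers(1, L - plen + 2))
        end = start + plen - 1
        rows.append(dict(peptide_id=f"pep{i + 1:03d}", start=start, end=end,
                         sequence=sequence[start - 1:end]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flux-trace generator
# ---------------------------------------------------------------------------

@dataclass
class FluxSpec:
    """Ground truth for one pair of flux-assay electrode traces.

    The Cl- trace is in mM (electrode already calibrated); the H+ trace
    is recorded as pH so the analysis stage must invert pH -> mol H+
    through the stated buffer capacity. Traces are flat (up to leak and
    noise) before the valinomycin time and ramp at the planted unitary
    rates afterwards.
    """

    rate_cl: float = 2300.0      # Cl- ions/s per transporter
    rate_h: float = 1100.0       # H+ ions/s per transporter
    protein_ug: float = 0.47     # reconstituted protein in the cuvette
    transporter_kda: float = 100.0   # molar mass of the (dimeric) transporter
    volume_L: float = 6.6e-4
    buffer_capacity: float = 1e-3    # mol H+ per pH unit per L
    t_val: float = 30.0          # s
    duration: float = 120.0
    dt: float = 0.5
    cl0_mM: float = 0.05
    ph0: float = 4.5
    cl_leak_mM_s: float = 0.0    # pre-valinomycin drift
    ph_leak_s: float = 0.0
    cl_noise_mM: float = 0.0
    ph_noise: float = 0.0
    seed: int = 0

    @property
    def transporter_mol(self) -> float:
        return self.protein_ug * 1e-6 / (self.transporter_kda * 1e3)


def gen_flux_traces(spec: FluxSpec) -> tuple[pd.DataFrame, dict]:
    """Return (flux_trace table, ground truth).

    Post-valinomycin, [Cl-] rises at rate_cl x transporters (release
    from vesicles) and extravesicular pH rises as H+ is pumped into the
    vesicles (uptake removes H+ from the measured solution).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    n_mol = spec.transporter_mol
    cl_rate_mM_s = spec.rate_cl * n_mol / spec.volume_L * 1e3   # mM/s
    ph_rate_s = spec.rate_h * n_mol / (spec.buffer_capacity * spec.volume_L)

    post = np.clip(t - spec.t_val, 0.0, None)
    cl = spec.cl0_mM + spec.cl_leak_mM_s * t + cl_rate_mM_s * post
    ph = spec.ph0 + spec.ph_leak_s * t + ph_rate_s * post
    if spec.cl_noise_mM > 0:
        cl = cl + rng.normal(0.0, spec.cl_noise_mM, len(t))
    if spec.ph_noise > 0:
        ph = ph + rng.normal(0.0, spec.ph_noise, len(t))
    trace = pd.DataFrame(dict(time_s=t, chloride_mM=cl, pH=ph))
    truth = dict(rate_cl=spec.rate_cl, rate_h=spec.rate_h,
                 stoichiometry=(spec.rate_cl / spec.rate_h
                                if spec.rate_h > 0 else None),
                 transporter_mol=n_mol, volume_L=spec.volume_L,
                 buffer_capacity=spec.buffer_capacity, t_val=spec.t_val,
                 seed=spec.seed)
    return trace, truth


# ---------------------------------------------------------------------------
# ITC titration generator
# ---------------------------------------------------------------------------

@dataclass
class ITCSpec:
    """One-site Wiseman titration (n fixed at 1): 30 mM titrant injected
    10 µL at a time into a ~15 µM cell, as in the emulated experiments."""

    kd_mM: float = 1.0
    dh_kcal: float = -2.0
    cell_uM: float = 15.0
    syringe_mM: float = 30.0
    cell_volume_mL: float = 1.4
    n_injections: int = 25
    inj_volume_uL: float = 10.0
    noise_ucal: float = 0.0
    seed: int = 0


def gen_itc_titration(spec: ITCSpec) -> tuple[pd.DataFrame, dict]:
    """Return (itc_injections table, ground truth)."""
    from clcpipe.functional_assays import wiseman_heats

    rng = np.random.default_rng(spec.seed)
    vols = np.full(spec.n_injections, spec.inj_volume_uL * 1e-6)  # L
    heats = wiseman_heats(kd_M=spec.kd_mM * 1e-3,
                          dh_cal_mol=spec.dh_kcal * 1e3,
                          n_sites=1.0,
                          cell_M=spec.cell_uM * 1e-6,
                          syringe_M=spec.syringe_mM * 1e-3,
                          cell_volume_L=spec.cell_volume_mL * 1e-3,
                          inj_volumes_L=vols)
    if spec.noise_ucal > 0:
        heats = heats + rng.normal(0.0, spec.noise_ucal, len(heats))
    table = pd.DataFrame(dict(
        injection_index=np.arange(1, spec.n_injections + 1),
        volume_uL=np.full(spec.n_injections, spec.inj_volume_uL),
        heat_ucal=heats,
    ))
    truth = dict(kd_mM=spec.kd_mM, dh_kcal=spec.dh_kcal,
                 cell_uM=spec.cell_uM, syringe_mM=spec.syringe_mM,
                 noise_ucal=spec.noise_ucal, seed=spec.seed)
    return table, truth


# ---------------------------------------------------------------------------
# Bundle writer (used by the CLI simulate-data stage)
# ---------------------------------------------------------------------------

def write_bundle(outdir: str | Path, seed: int = 0) -> dict:
    """Write one synthetic dataset of every input kind plus ground-truth
    sidecars; returns the mapping of what was written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    tspec = TrajectorySpec(
        n_frames=60, seed=seed,
        wire_episodes=[WireEpisode("A", 2, 10, 40)],
        leaving_episodes=[LeavingEpisode("A", 20, "extracellular")],
        gate_episodes=[GateEpisode("A", 20, 59)],
    )
    traj = gen_trajectory(tspec)
    core_io.write_trajectory(traj, outdir / "trajectory.pdb")
    (outdir / "trajectory.truth.json").write_text(
        json.dumps(trajectory_ground_truth(tspec), indent=2))
    written["trajectory"] = "trajectory.pdb"

    uspec = UptakeSpec(seed=seed, noise_sigma=0.05)
    uptake, fd, utruth = gen_uptake_dataset(uspec)
    core_io.write_table(uptake, outdir / "hdx_uptake.csv", "hdx_uptake")
    core_io.write_table(fd, outdir / "fd_control.csv", "fd_control")
    core_io.write_table(uspec.peptides, outdir / "peptide_map.csv",
                        "peptide_map")
    (outdir / "hdx.truth.json").write_text(json.dumps(utruth, indent=2))
    written["hdx"] = "hdx_uptake.csv"

    fspec = FluxSpec(seed=seed, cl_noise_mM=0.01, ph_noise=0.002)
    trace, ftruth = gen_flux_traces(fspec)
    core_io.write_table(trace, outdir / "flux_trace.csv", "flux_trace")
    (outdir / "flux.truth.json").write_text(json.dumps(ftruth, indent=2))
    written["flux"] = "flux_trace.csv"

    ispec = ITCSpec(seed=seed, noise_ucal=0.07)
    inj, itruth = gen_itc_titration(ispec)
    core_io.write_table(inj, outdir / "itc_injections.csv", "itc_injections")
    (outdir / "itc.truth.json").write_text(json.dumps(itruth, indent=2))
    written["itc"] = "itc_injections.csv"
    return written
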