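"""Readers/writers, configuration and shared domain containers.

Trajectories are interchanged as multi-MODEL text PDB files (MODEL/ENDMDL
delimit frames). Tabular assay data (HDX uptake, flux traces, ITC
injections, peptide maps) are CSV with fixed, documented schemas. All
coordinates are in Å, trajectory times in ns, assay times in s.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("clcpipe")

# Residue names recognised as water / chloride in input files
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP3P", "SOL", "SPC"}
CHLORIDE_RESNAMES = {"CLA", "CL", "CL-", " CL"}

AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed or violates its schema."""


class IntegrityError(ValueError):
    """Raised when parsed data violate a container invariant."""


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

TOPOLOGY_COLUMNS = [
    "atom_id", "atom_name", "residue_name", "residue_number",
    "chain_id", "element", "role",
]


def assign_roles(residue_names: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Tag each atom as protein / water_O / water_H / chloride / other.

    Roles are derived from residue and element names: HOH/WAT/TIP3/SOL are
    waters (split by element), CLA/CL are chloride ions, standard amino
    acids are protein.
    """
    roles = np.full(len(residue_names), "other", dtype=object)
    rn = np.char.upper(np.asarray(residue_names, dtype=str))
    el = np.char.upper(np.asarray(elements, dtype=str))
    is_water = np.isin(rn, list(WATER_RESNAMES))
    roles[is_water & (el == "O")] = "water_O"
    roles[is_water & (el == "H")] = "water_H"
    roles[np.isin(rn, list(CHLORIDE_RESNAMES))] = "chloride"
    roles[np.isin(rn, list(AMINO3))] = "protein"
    return roles


@dataclass
class TrajectoryFrameSet:
    """Ordered frames of labeled 3-D points: the substrate for all
    geometric trajectory analyses.

    topology: one row per atom (atom_id, atom_name, residue_name,
        residue_number [1-based CLC-ec1 numbering: E148, E203, E113, S107,
        Y445, K131, F357 are addressable], chain_id, element, role).
    coords:  (n_frames, n_atoms, 3) array in Å.
    times_ns: strictly increasing frame time stamps.
    """

    topology: pd.DataFrame
    coords: np.ndarray
    times_ns: np.ndarray
    box: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.topology.columns]
        if missing:
            raise IntegrityError(f"topology missing columns: {missing}")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise IntegrityError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise IntegrityError(
                f"every frame must have one coordinate triple per atom "
                f"({self.coords.shape[1]} != {len(self.topology)})"
            )
        if len(self.times_ns) != self.coords.shape[0]:
            raise IntegrityError("times_ns length must equal frame count")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise IntegrityError("times_ns must be strictly increasing")
        self._check_water_linkage()

    def _check_water_linkage(self) -> None:
        # every water_H must share (chain, residue) with a water_O
        top = self.topology
        h = top[top.role == "water_H"]
        if len(h) == 0:
            return
        o_keys = set(zip(top.loc[top.role == "water_O", "chain_id"],
                         top.loc[top.role == "water_O", "residue_number"]))
        for _, row in h.iterrows():
            if (row.chain_id, row.residue_number) not in o_keys:
                raise IntegrityError(
                    f"water hydrogen {row.atom_id} has no parent oxygen "
                    f"(chain {row.chain_id}, residue {row.residue_number})"
                )

    # -- selection helpers ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chains(self) -> list[str]:
        return sorted(self.topology.chain_id.unique())

    def atom_index(self, chain_id: str, residue_number: int,
                   atom_name: str) -> int:
        top = self.topology
        sel = top[(top.chain_id == chain_id)
                  & (top.residue_number == residue_number)
                  & (top.atom_name == atom_name)]
        if len(sel) == 0:
            raise KeyError(
                f"no atom {atom_name} in residue {residue_number} "
                f"chain {chain_id}"
            )
        return int(sel.index[0])

    def indices_by_role(self, role: str,
                        chain_id: Optional[str] = None) -> np.ndarray:
        top = self.topology
        mask = top.role == role
        if chain_id is not None:
            mask &= top.chain_id == chain_id
        return np.flatnonzero(mask.to_numpy())

    def water_hydrogens(self) -> dict[int, list[int]]:
        """Map each water oxygen index to its hydrogen indices."""
        top = self.topology
        out: dict[int, list[int]] = {}
        groups: dict[tuple, list[tuple[int, str]]] = {}
        for i, row in enumerate(top.itertuples()):
            if row.role in ("water_O", "water_H"):
                groups.setdefault((row.chain_id, row.residue_number), []).append(
                    (i, row.role))
        for members in groups.values():
            o = [i for i, r in members if r == "water_O"]
            hs = [i for i, r in members if r == "water_H"]
            if o:
                out[o[0]] = hs
        return out


@dataclass
class CompartmentSpec:
    """Geometric rule assigning waters to a solution compartment.

    A compartment is a z-slab in Å relative to the membrane midplane
    (z = 0), or an explicit atom-id set. Compartments must be disjoint.
    """

    name: str
    z_min: Optional[float] = None
    z_max: Optional[float] = None
    atom_ids: Optional[set[int]] = None

    def contains(self, coords: np.ndarray,
                 atom_ids: Optional[np.ndarray] = None) -> np.ndarray:
        if self.atom_ids is not None:
            if atom_ids is None:
                raise ValueError("atom_ids required for membership compartment")
            return np.isin(atom_ids, list(self.atom_ids))
        z = coords[:, 2]
        mask = np.ones(len(z), dtype=bool)
        if self.z_min is not None:
            mask &= z >= self.z_min
        if self.z_max is not None:
            mask &= z <= self.z_max
        return mask


def default_compartments(z_half: float = 12.0) -> list[CompartmentSpec]:
    """Intracellular below, extracellular above a membrane slab of
    half-thickness ``z_half`` Å centred on z = 0."""
    return [
        CompartmentSpec("intracellular", z_max=-z_half),
        CompartmentSpec("extracellular", z_min=z_half),
    ]


@dataclass
class WireClassDef:
    """Declarative definition of one water-wire class.

    A wire of this class is a hydrogen-bonded water path from any of the
    ``source`` protein atoms to the sink compartment. ``waypoint_mode``
    'require' ('exclude') demands the path pass through (avoid) waters
    within ``AnalysisConfig.waypoint_radius`` of the waypoint atom.
    """

    wire_class: int
    source: tuple[tuple[int, str], ...]          # (residue_number, atom_name)
    waypoint: Optional[tuple[int, str]] = None
    waypoint_mode: str = "none"                  # none | require | exclude

    def __post_init__(self) -> None:
        if self.waypoint_mode not in ("none", "require", "exclude"):
            raise ValueError(f"bad waypoint_mode {self.waypoint_mode!r}")


def default_wire_classes() -> list[WireClassDef]:
    """Wire classes used throughout: class 1 reaches the anion permeation
    pathway (inner-gate S107/Y445 hydroxyls near S_cen/S_int); classes 2
    and 3 terminate at the gating glutamate E148 carboxylate and are split
    by whether the path crosses the E203 (Glu_in) H+-pathway segment."""
    return [
        WireClassDef(1, ((107, "OG"), (445, "OH"))),
        WireClassDef(2, ((148, "OE1"), (148, "OE2")),
                     waypoint=(203, "OE1"), waypoint_mode="require"),
        WireClassDef(3, ((148, "OE1"), (148, "OE2")),
                     waypoint=(203, "OE1"), waypoint_mode="exclude"),
    ]


@dataclass
class AnalysisConfig:
    """Tunable thresholds for the trajectory observables.

    Defaults: hydrogen bond = donor-acceptor <= 3.5 Å and
    donor-H-acceptor angle >= 150 deg; an ion has left the pathway when
    its smoothed distance from the Y445 Cα exceeds 12 Å; distance series
    are smoothed with a 20 ns moving average.
    """

    hbond_distance_cutoff: float = 3.5      # Å, donor-acceptor
    hbond_angle_cutoff_deg: float = 150.0   # donor-H-acceptor
    hbond_distance_only_fallback: bool = False
    leave_threshold: float = 12.0           # Å
    smoothing_window_ns: float = 20.0
    min_dwell_ns: float = 50.0
    gate_open_cutoff: float = 6.0           # Å, S107 OG - Y445 OH
    waypoint_radius: float = 4.0            # Å
    compartment_z_half: float = 12.0        # Å
    ion_reference: tuple[int, str] = (445, "CA")
    wire_classes: list[WireClassDef] = field(default_factory=default_wire_classes)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hbond_distance_cutoff", "hbond_angle_cutoff_deg",
                     "leave_threshold", "smoothing_window_ns", "min_dwell_ns",
                     "gate_open_cutoff", "waypoint_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "wire_classes" in data:
            data["wire_classes"] = [
                WireClassDef(
                    wire_class=w["wire_class"],
                    source=tuple((int(r), a) for r, a in w["source"]),
                    waypoint=tuple(w["waypoint"]) if w.get("waypoint") else None,
                    waypoint_mode=w.get("waypoint_mode", "none"),
                )
                for w in data["wire_classes"]
            ]
        if "ion_reference" in data:
            data["ion_reference"] = tuple(data["ion_reference"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ion_reference"] = list(self.ion_reference)
        d["wire_classes"] = [
            {"wire_class": w.wire_class,
             "source": [list(s) for s in w.source],
             "waypoint": list(w.waypoint) if w.waypoint else None,
             "waypoint_mode": w.waypoint_mode}
            for w in self.wire_classes
        ]
        return d


# ---------------------------------------------------------------------------
# Trajectory PDB I/O (multi-MODEL text PDB; MODEL/ENDMDL delimit frames)
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, frame_dt_ns: float = 0.2,
                    t0_ns: float = 0.0,
                    metadata: Optional[dict] = None) -> TrajectoryFrameSet:
    """Read a multi-MODEL PDB file into a :class:`TrajectoryFrameSet`.

    A PDB without MODEL records yields a single-frame trajectory. Frame
    times are ``t0_ns + i * frame_dt_ns`` (the PDB format carries no time
    stamps; 0.2 ns matches a 200 ps save interval).
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdbf = PDBFile.read(str(path))
        stack = pdbf.get_structure(model=None)
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    roles = assign_roles(stack.res_name, stack.element)
    topology = pd.DataFrame({
        "atom_id": np.arange(1, n_atoms + 1),
        "atom_name": np.asarray(stack.atom_name, dtype=str),
        "residue_name": np.asarray(stack.res_name, dtype=str),
        "residue_number": np.asarray(stack.res_id, dtype=int),
        "chain_id": np.asarray(stack.chain_id, dtype=str),
        "element": np.asarray(stack.element, dtype=str),
        "role": roles,
    })
    box = None
    if stack.box is not None:
        box = np.asarray(np.diagonal(stack.box[0]), dtype=float)
    times = t0_ns + frame_dt_ns * np.arange(coords.shape[0])
    traj = TrajectoryFrameSet(topology=topology, coords=coords,
                              times_ns=times, box=box,
                              metadata=dict(metadata or {}))
    _warn_on_wraparound(traj)
    logger.info("read %d frames x %d atoms from %s",
                traj.n_frames, traj.n_atoms, path)
    return traj


def _warn_on_wraparound(traj: TrajectoryFrameSet) -> None:
    """Detectors assume pre-imaged coordinates; warn if frame-to-frame
    jumps approach half the box (suggesting periodic wrap-around)."""
    if traj.box is None or traj.n_frames < 2:
        return
    jumps = np.abs(np.diff(traj.coords, axis=0)).max()
    if jumps > 0.5 * float(np.min(traj.box)):
        logger.warning(
            "frame-to-frame displacement %.1f Å exceeds half the box; "
            "trajectory may not be re-imaged", jumps)


def write_trajectory(traj: TrajectoryFrameSet, path: str | Path) -> None:
    """Write a trajectory as a multi-MODEL PDB (coordinates at PDB
    precision, 1e-3 Å)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_atoms
    arr = struc.AtomArray(n)
    top = traj.topology
    arr.chain_id = top.chain_id.to_numpy(dtype="U4")
    arr.res_id = top.residue_number.to_numpy(dtype=int)
    arr.res_name = top.residue_name.to_numpy(dtype="U5")
    arr.atom_name = top.atom_name.to_numpy(dtype="U6")
    arr.element = top.element.to_numpy(dtype="U2")
    arr.hetero = ~np.isin(np.char.upper(top.residue_name.to_numpy(dtype=str)),
                          list(AMINO3))
    frames = []
    for i in range(traj.n_frames):
        a = arr.copy()
        a.coord = traj.coords[i].astype(np.float32)
        frames.append(a)
    stack = struc.stack(frames)
    if traj.box is not None:
        stack.box = np.tile(np.diag(traj.box), (traj.n_frames, 1, 1))
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# CSV table schemas
# ---------------------------------------------------------------------------

TABLE_SCHEMAS: dict[str, dict] = {
    "hdx_uptake": {
        "required": ["peptide_id", "start", "end", "sequence", "pH",
                     "time_s", "uptake_Da", "replicate"],
        "monotone_time": None,
    },
    "fd_control": {
        "required": ["peptide_id", "uptake_Da"],
        "monotone_time": None,
    },
    "flux_trace": {
        "required": ["time_s", "chloride_mM", "pH"],
        "monotone_time": "time_s",
    },
    "itc_injections": {
        "required": ["injection_index", "volume_uL", "heat_ucal"],
        "monotone_time": None,
    },
    "peptide_map": {
        "required": ["peptide_id", "start", "end", "sequence"],
        "monotone_time": None,
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's CSV table formats.

    Raises :class:`FormatError` on a missing required column or a
    non-monotone time column. An empty file yields an empty (but
    correctly typed) table with a logged warning.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}; "
                         f"one of {sorted(TABLE_SCHEMAS)}")
    spec = TABLE_SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("empty table %s (%s)", path, schema)
        return pd.DataFrame(columns=spec["required"])
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} "
                          f"for schema {schema!r}")
    if len(df) == 0:
        logger.warning("table %s (%s) has no rows", path, schema)
    tcol = spec["monotone_time"]
    if tcol is not None and len(df) > 1:
        if not np.all(np.diff(df[tcol].to_numpy(dtype=float)) > 0):
            raise FormatError(f"{path}: column {tcol!r} must be strictly "
                              "increasing")
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    spec = TABLE_SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise FormatError(f"cannot write schema {schema!r}: missing {missing}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, stage: str, inputs: Sequence[str],
                   config: dict, seed: Optional[int]) -> None:
    """Write a JSON run manifest (inputs, config hash, seed, versions)
    sufficient to reproduce any stochastic stage bit-for-bit."""
    from clcpipe import __version__

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "inputs": list(inputs),
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "clcpipe": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_cli(argv: Optional[Sequence[str]] = None) -> int:
    """Entry point chaining the pipeline stages (thin wrapper over
    :mod:`clcpipe.cli`)."""
    from clcpipe.cli import main

    return main(argv)
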