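"""Shared fixtures: hand-built micro-frames and default analysis config."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clcpipe.core_io import AnalysisConfig, TrajectoryFrameSet


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def make_water_frame(o_positions, h_directions=None, extra_atoms=(),
                     n_frames=1):
    """Build a tiny TrajectoryFrameSet of waters (plus optional labeled
    protein atoms) for direct geometry tests.

    o_positions: list of water-oxygen xyz. h_directions: per water, unit
    direction its first hydrogen points along (second H is arbitrary);
    defaults to +x. extra_atoms: (atom_name, residue_name,
    residue_number, element, xyz) tuples appended as chain-A atoms.
    """
    rows, coords = [], []
    aid = 1
    for i, o in enumerate(o_positions):
        o = np.asarray(o, dtype=float)
        d = np.asarray(h_directions[i] if h_directions is not None
                       else [1.0, 0, 0], dtype=float)
        d = d / np.linalg.norm(d)
        perp = np.cross(d, [0, 0, 1.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(d, [0, 1.0, 0])
        perp /= np.linalg.norm(perp)
        for name, el, xyz in (("O", "O", o),
                              ("H1", "H", o + 0.96 * d),
                              ("H2", "H", o + 0.96 * (0.326 * d + 0.945 * perp))):
            rows.append(dict(atom_id=aid, atom_name=name, residue_name="HOH",
                             residue_number=100 + i, chain_id="A",
                             element=el,
                             role="water_O" if el == "O" else "water_H"))
            coords.append(xyz)
            aid += 1
    for name, resname, resnum, el, xyz in extra_atoms:
        role = "protein" if resname not in ("CLA",) else "chloride"
        rows.append(dict(atom_id=aid, atom_name=name, residue_name=resname,
                         residue_number=resnum, chain_id="A", element=el,
                         role=role))
        coords.append(np.asarray(xyz, dtype=float))
        aid += 1
    coords = np.array(coords)[None].repeat(n_frames, axis=0)
    return TrajectoryFrameSet(
        topology=pd.DataFrame(rows), coords=coords,
        times_ns=0.2 * np.arange(n_frames))


@pytest.fixture
def water_frame_factory():
    return make_water_frame
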