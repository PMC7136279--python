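"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from hdxens.features import FeatureTable
from hdxens.io import Topology
from hdxens.synthetic import TwoStateSpec, two_state_problem


def make_backbone(n_res: int, with_h: bool = True, proline_at: tuple = ()):
    """Synthetic extended-chain topology + one frame of coordinates.

    Each residue carries N, (H), CA, C, O in a planar zig-zag; geometry is
    regular but not physical — it exists to exercise atom bookkeeping.
    """
    names, elements, resids, xyz = [], [], [], []
    for i in range(1, n_res + 1):
        is_pro = i in proline_at
        base = np.array([3.5 * i, 0.0, 0.0])
        atoms = [
            ("N", "N", base),
            ("CA", "C", base + (0.8, 1.2, 0.0)),
            ("C", "C", base + (2.0, 0.6, 0.0)),
            ("O", "O", base + (2.0, -0.6, 0.0)),
        ]
        if with_h and i > 1 and not is_pro:
            atoms.insert(1, ("H", "H", base + (-0.4, -0.9, 0.0)))
        for nm, el, pos in atoms:
            names.append(nm)
            elements.append(el)
            resids.append(i)
            xyz.append(pos)
    topo = Topology(
        atom_resids=np.array(resids),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.arange(1, n_res + 1),
        resnames=np.array(
            ["PRO" if i in proline_at else "ALA" for i in range(1, n_res + 1)],
            dtype=object,
        ),
    )
    return topo, np.array(xyz)


def tiny_feature_table() -> FeatureTable:
    """3 frames x 4 residues (residue 1 non-exchanging)."""
    residues = np.array([1, 2, 3, 4])
    nc = np.array(
        [[0, 4.0, 10.0, 6.0], [0, 8.0, 2.0, 5.0], [0, 6.0, 5.0, 7.0]]
    )
    nh = np.array([[0, 1.0, 1.0, 0.0], [0, 0.0, 1.0, 1.0], [0, 1.0, 0.0, 0.0]])
    return FeatureTable(residues, nc, nh, np.array([False, True, True, True]))


@pytest.fixture(scope="session")
def small_problem():
    """Well-separated two-state benchmark, 300 frames x 15 residues."""
    return two_state_problem(TwoStateSpec(n_frames=300, n_residues=15, seed=11))


@pytest.fixture(scope="session")
def default_problem():
    """Full-size benchmark at the standard fixture scale (1000 x 30)."""
    return two_state_problem(TwoStateSpec(seed=1))
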