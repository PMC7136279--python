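"""Structural ensemble input/output.

Reads multi-model PDB files and binary trajectories (DCD/XTC/... anything
MDAnalysis understands) into a light-weight :class:`Topology` +
:class:`EnsembleCoordinates` pair, identifies backbone amide N/H atoms, and
optionally reconstructs missing amide hydrogens from ideal peptide geometry.

Residue numbering is 1-based author numbering taken from the input file; a
single chain is analyzed per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyEnsembleError, ReconstructionError, TopologyError

__all__ = [
    "Topology",
    "EnsembleCoordinates",
    "load_ensemble",
    "reconstruct_amide_hydrogens",
    "reconstruct_ensemble",
    "place_amide_hydrogen",
    "write_multimodel_pdb",
]

#: N-H bond length used when rebuilding amide hydrogens (Angstrom).
NH_BOND_LENGTH = 1.01


def element_from_name(name: str) -> str:
    """Best-effort element from a PDB atom name (handles '1HB2' dialects)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise TopologyError(f"cannot infer element for atom name {name!r}")
    first = stripped[0].upper()
    # two-letter biologically relevant elements occurring in protein files
    if stripped[:2].upper() in {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE"} and len(name.strip()) > 1:
        return stripped[:2].capitalize()
    return first


@dataclass
class Topology:
    """Atom/residue bookkeeping for one protein chain.

    Arrays are parallel over atoms; residue arrays are parallel over residues
    in strictly increasing author numbering.
    """

    atom_resids: np.ndarray     # (n_atoms,) 1-based residue index per atom
    atom_names: np.ndarray      # (n_atoms,) str
    elements: np.ndarray        # (n_atoms,) str, e.g. "C", "N", "O", "H", "S"
    resids: np.ndarray          # (n_res,) unique residue indices, increasing
    resnames: np.ndarray        # (n_res,) 3-letter codes
    chain: str = "A"

    def __post_init__(self) -> None:
        self.atom_resids = np.asarray(self.atom_resids, dtype=int)
        self.atom_names = np.asarray(
            [n.strip() for n in self.atom_names], dtype=object
        )
        self.elements = np.asarray([e.strip() for e in self.elements], dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        if not (len(self.atom_resids) == len(self.atom_names) == len(self.elements)):
            raise TopologyError("atom arrays must be parallel")
        if len(self.resids) != len(self.resnames):
            raise TopologyError("residue arrays must be parallel")
        if np.any(np.diff(self.resids) <= 0):
            raise TopologyError("residue indices must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_resids)

    @property
    def is_proline(self) -> np.ndarray:
        return np.asarray([rn.upper() == "PRO" for rn in self.resnames])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e.upper() != "H" for e in self.elements])

    @property
    def on_mask(self) -> np.ndarray:
        """Potential H-bond acceptors: all O and N atoms."""
        return np.asarray([e.upper() in ("O", "N") for e in self.elements])

    def _find_atom(self, resid: int, names: tuple[str, ...]) -> int | None:
        sel = np.nonzero(self.atom_resids == resid)[0]
        for want in names:
            for i in sel:
                if self.atom_names[i].upper() == want:
                    return int(i)
        return None

    def amide_n_index(self, resid: int) -> int | None:
        return self._find_atom(resid, ("N",))

    def amide_h_index(self, resid: int) -> int | None:
        return self._find_atom(resid, ("H", "HN", "H1"))

    def backbone_index(self, resid: int, name: str) -> int | None:
        return self._find_atom(resid, (name,))

    def residue_name(self, resid: int) -> str:
        idx = np.nonzero(self.resids == resid)[0]
        if idx.size == 0:
            raise TopologyError(f"residue {resid} not in topology")
        return str(self.resnames[idx[0]])

    def exchangeable_residues(self) -> np.ndarray:
        """Residues with an observable amide: non-proline, non-N-terminal."""
        first = self.resids[0]
        keep = (~self.is_proline) & (self.resids != first)
        return self.resids[keep]


@dataclass
class EnsembleCoordinates:
    """Ordered frames of per-atom coordinates, in Angstrom."""

    coords: np.ndarray                      # (n_frames, n_atoms, 3)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise EmptyEnsembleError("ensemble has zero frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, k: int) -> np.ndarray:
        return self.coords[k]


def _dedupe_altloc(atoms):
    """Keep the highest-occupancy conformer per (resid, atom name)."""
    try:
        altlocs = atoms.altLocs
    except Exception:
        return atoms
    if all(a.strip() == "" for a in altlocs):
        return atoms
    try:
        occ = atoms.occupancies
    except Exception:
        occ = np.ones(len(atoms))
    best: dict[tuple[int, str], tuple[float, int]] = {}
    for i, at in enumerate(atoms):
        key = (int(at.resid), at.name)
        if key not in best or occ[i] > best[key][0]:
            best[key] = (occ[i], i)
    keep = sorted(i for _, i in best.values())
    return atoms[keep]


def load_ensemble(
    structure_file,
    trajectory_files=None,
    stride: int = 1,
    chain: str | None = None,
) -> tuple[Topology, EnsembleCoordinates]:
    """Load a structural ensemble from a PDB (+ optional trajectories).

    Parameters
    ----------
    structure_file : path
        PDB (possibly multi-model) or PSF-style topology file.
    trajectory_files : path or list of paths, optional
        Binary trajectory/ies (DCD, XTC, ...) congruent with the topology.
    stride : int
        Keep every ``stride``-th frame.
    chain : str, optional
        Chain/segment identifier to analyze; required when the file holds
        several chains.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise TopologyError("stride must be a positive integer")
    traj = trajectory_files
    if traj is not None and not isinstance(traj, (list, tuple)):
        traj = [traj]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(structure_file), *[str(t) for t in (traj or [])])
        except Exception as exc:  # atom-count mismatch surfaces here
            raise TopologyError(f"failed to load ensemble: {exc}") from exc

    atoms = u.atoms
    segids = sorted({s.strip() for s in getattr(atoms, "segids", [])} |
                    {c.strip() for c in getattr(atoms, "chainIDs", [""])
                     if hasattr(atoms, "chainIDs")})
    segids = [s for s in segids if s]
    if chain is not None:
        sel = atoms.select_atoms(f"segid {chain}")
        if len(sel) == 0 and hasattr(atoms, "chainIDs"):
            sel = atoms.select_atoms(f"chainID {chain}")
        if len(sel) == 0:
            raise TopologyError(f"chain {chain!r} not found (have {segids})")
        atoms = sel
    elif len(segids) > 1:
        raise TopologyError(
            f"multiple chains present ({segids}); select one with chain=..."
        )
    atoms = _dedupe_altloc(atoms)

    try:
        elements = [str(e) for e in atoms.elements]
        if any(not e.strip() for e in elements):
            raise AttributeError
    except Exception:
        elements = [element_from_name(n) for n in atoms.names]

    resids = []
    resnames = []
    for res in atoms.residues:
        resids.append(int(res.resid))
        resnames.append(str(res.resname))
    topology = Topology(
        atom_resids=atoms.resids,
        atom_names=atoms.names,
        elements=elements,
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        chain=chain or (segids[0] if segids else "A"),
    )

    frames = []
    for _ in u.trajectory[::stride]:
        frames.append(atoms.positions.astype(float).copy())
    if not frames:
        raise EmptyEnsembleError("no frames loaded")
    coords = EnsembleCoordinates(
        np.array(frames),
        provenance={
            "structure": str(structure_file),
            "trajectories": [str(t) for t in (traj or [])],
            "stride": stride,
        },
    )
    return topology, coords


def place_amide_hydrogen(
    n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray
) -> np.ndarray:
    """Ideal amide H position: 1.01 A from N, in the C(i-1)-N-CA plane,
    along the external bisector of the C(i-1)-N-CA angle."""
    v1 = ca - n
    v2 = c_prev - n
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ReconstructionError("degenerate backbone geometry")
    d = -(v1 / n1 + v2 / n2)
    nd = np.linalg.norm(d)
    if nd < 1e-10:
        raise ReconstructionError("collinear backbone geometry; bisector undefined")
    return n + NH_BOND_LENGTH * d / nd


def reconstruct_amide_hydrogens(
    topology: Topology, frame: np.ndarray
) -> tuple[Topology, np.ndarray]:
    """Add missing backbone amide hydrogens to one frame.

    For every non-proline residue after the first that lacks an amide H, an H
    atom is appended (named "H") at the ideal planar position.  Existing
    hydrogens are untouched; the operation is idempotent.  Returns the
    (possibly augmented) topology and coordinates.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise TopologyError("frame shape inconsistent with topology")
    new_resids, new_names, new_elements, new_xyz = [], [], [], []
    resids = topology.resids
    for pos, resid in enumerate(resids):
        if pos == 0 or topology.is_proline[pos]:
            continue
        if topology.amide_h_index(int(resid)) is not None:
            continue
        i_n = topology.amide_n_index(int(resid))
        i_ca = topology.backbone_index(int(resid), "CA")
        prev = int(resids[pos - 1])
        i_c = topology.backbone_index(prev, "C")
        if i_n is None or i_ca is None or i_c is None:
            raise ReconstructionError(
                f"residue {resid}: missing backbone atoms for H reconstruction"
            )
        new_resids.append(int(resid))
        new_names.append("H")
        new_elements.append("H")
        new_xyz.append(place_amide_hydrogen(frame[i_n], frame[i_ca], frame[i_c]))
    if not new_resids:
        return topology, frame
    aug = Topology(
        atom_resids=np.concatenate([topology.atom_resids, new_resids]),
        atom_names=np.concatenate([topology.atom_names, new_names]),
        elements=np.concatenate([topology.elements, new_elements]),
        resids=topology.resids,
        resnames=topology.resnames,
        chain=topology.chain,
    )
    return aug, np.vstack([frame, np.array(new_xyz)])


def reconstruct_ensemble(
    topology: Topology, ensemble: EnsembleCoordinates
) -> tuple[Topology, EnsembleCoordinates]:
    """Apply :func:`reconstruct_amide_hydrogens` to every frame consistently."""
    new_topo = None
    frames = []
    for k in range(ensemble.n_frames):
        t, f = reconstruct_amide_hydrogens(topology, ensemble[k])
        if new_topo is None:
            new_topo = t
        frames.append(f)
    return new_topo, EnsembleCoordinates(np.array(frames), ensemble.provenance)


def write_multimodel_pdb(topology: Topology, frames, path) -> None:
    """Write frames as a multi-model PDB (used for cluster representatives)."""
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for m, xyz in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            serial = 0
            for i in range(topology.n_atoms):
                serial += 1
                name = topology.atom_names[i]
                pname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
                resid = int(topology.atom_resids[i])
                resname = topology.residue_name(resid)
                x, y, z = xyz[i]
                fh.write(
                    f"ATOM  {serial:5d} {pname}{'':1s}{resname:<3s} "
                    f"{topology.chain[:1] or 'A'}{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{topology.elements[i]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
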