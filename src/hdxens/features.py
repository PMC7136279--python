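"""Per-frame structural observables of the forward model.

For each exchange-competent residue the forward model needs two counts per
frame: ``N_C`` (heavy atoms within 6.5 A of the amide N, excluding residues
i-2..i+2) and ``N_H`` (O/N atoms within 2.4 A of the amide H).  Both cutoffs
are strict (< cutoff).  Counts are stored in a :class:`FeatureTable`, which
also round-trips to a plain TSV so that the reweighting machinery never needs
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import FeatureError, InputError
from .forward import ForwardModelParams, Segment
from .io import EnsembleCoordinates, Topology

__all__ = [
    "CONTACT_CUTOFF",
    "HBOND_CUTOFF",
    "NEIGHBOR_EXCLUSION",
    "FeatureTable",
    "compute_contacts",
    "compute_hbonds",
    "build_feature_table",
    "peptide_burial_score",
]

#: Heavy-atom contact cutoff around the amide N (Angstrom, strict).
CONTACT_CUTOFF = 6.5
#: H-bond acceptor cutoff around the amide H (Angstrom, strict).
HBOND_CUTOFF = 2.4
#: Residues i-2..i+2 are excluded from the contact count (clamped at termini).
NEIGHBOR_EXCLUSION = 2


@dataclass
class FeatureTable:
    """Frame x residue matrices of amide contact and H-bond counts."""

    residues: np.ndarray        # (R,) 1-based author numbering
    n_contacts: np.ndarray      # (F, R) nonnegative integers
    n_hbonds: np.ndarray        # (F, R) nonnegative integers
    exchangeable: np.ndarray    # (R,) False for prolines / N-terminal residue

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.n_contacts = np.atleast_2d(np.asarray(self.n_contacts, dtype=float))
        self.n_hbonds = np.atleast_2d(np.asarray(self.n_hbonds, dtype=float))
        self.exchangeable = np.asarray(self.exchangeable, dtype=bool)
        r = self.residues.size
        if self.exchangeable.shape != (r,):
            raise InputError("exchangeable mask must match residues")
        if self.n_contacts.shape != self.n_hbonds.shape or self.n_contacts.shape[1] != r:
            raise InputError("feature matrices inconsistent with residue list")
        if np.any(self.n_contacts < 0) or np.any(self.n_hbonds < 0):
            raise InputError("counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.n_contacts.shape[0]

    @property
    def n_residues(self) -> int:
        return self.residues.size

    def observable(self, params: ForwardModelParams) -> np.ndarray:
        """Per-frame linear observable ``b_ik = beta_C N_C + beta_H N_H`` over
        exchange-competent residues only, shape (F, R_exchangeable)."""
        m = self.exchangeable
        bc, bh = params.coefficients(self.residues[m])
        return bc * self.n_contacts[:, m] + bh * self.n_hbonds[:, m]

    def subset_frames(self, index) -> "FeatureTable":
        index = np.asarray(index)
        return FeatureTable(
            self.residues,
            self.n_contacts[index],
            self.n_hbonds[index],
            self.exchangeable,
        )

    def to_file(self, path) -> None:
        f_idx, r_idx = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_residues), indexing="ij"
        )
        pd.DataFrame(
            {
                "frame": f_idx.ravel(),
                "residue": self.residues[r_idx.ravel()],
                "n_contacts": self.n_contacts.ravel(),
                "n_hbonds": self.n_hbonds.ravel(),
                "exchangeable": self.exchangeable[r_idx.ravel()].astype(int),
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_file(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        need = {"frame", "residue", "n_contacts", "n_hbonds"}
        if not need.issubset(df.columns):
            raise InputError(f"{path}: need columns {sorted(need)}")
        residues = np.sort(df["residue"].unique())
        frames = np.sort(df["frame"].unique())
        pivot_c = df.pivot(index="frame", columns="residue", values="n_contacts")
        pivot_h = df.pivot(index="frame", columns="residue", values="n_hbonds")
        pivot_c = pivot_c.reindex(index=frames, columns=residues)
        pivot_h = pivot_h.reindex(index=frames, columns=residues)
        if pivot_c.isna().any().any() or pivot_h.isna().any().any():
            raise InputError(f"{path}: missing (frame, residue) entries")
        if "exchangeable" in df.columns:
            ex = (
                df.drop_duplicates("residue")
                .set_index("residue")["exchangeable"]
                .reindex(residues)
                .to_numpy(bool)
            )
        else:
            ex = np.ones(residues.size, dtype=bool)
        return cls(residues, pivot_c.to_numpy(float), pivot_h.to_numpy(float), ex)


def _neighbor_window(resid: int, resids: np.ndarray) -> np.ndarray:
    lo = resid - NEIGHBOR_EXCLUSION
    hi = resid + NEIGHBOR_EXCLUSION
    return (resids >= lo) & (resids <= hi)


def compute_contacts(
    frame: np.ndarray,
    topology: Topology,
    cutoff: float = CONTACT_CUTOFF,
    residues=None,
) -> np.ndarray:
    """Heavy-atom contact count ``N_C`` per residue for one frame.

    Counts non-hydrogen atoms strictly within ``cutoff`` of each residue's
    amide N, excluding every atom of residues i-2..i+2 (self included).
    """
    frame = np.asarray(frame, dtype=float)
    residues = topology.exchangeable_residues() if residues is None else residues
    heavy = np.nonzero(topology.heavy_mask)[0]
    tree = cKDTree(frame[heavy])
    heavy_resids = topology.atom_resids[heavy]
    out = np.zeros(len(residues))
    for j, resid in enumerate(residues):
        i_n = topology.amide_n_index(int(resid))
        if i_n is None:
            raise FeatureError(f"residue {resid}: no amide N atom")
        near = tree.query_ball_point(frame[i_n], cutoff)
        near = np.asarray(near, dtype=int)
        if near.size:
            d = np.linalg.norm(frame[heavy[near]] - frame[i_n], axis=1)
            near = near[d < cutoff]
        keep = ~_neighbor_window(int(resid), heavy_resids[near])
        out[j] = int(np.count_nonzero(keep))
    return out


def compute_hbonds(
    frame: np.ndarray,
    topology: Topology,
    cutoff: float = HBOND_CUTOFF,
    residues=None,
    exclude_neighbor_window: bool = False,
) -> np.ndarray:
    """H-bond count ``N_H`` per residue for one frame.

    Counts O/N atoms strictly within ``cutoff`` of the residue's amide H.
    The amide's own backbone N is always excluded; optionally the whole
    i-2..i+2 window can be excluded as for contacts.
    """
    frame = np.asarray(frame, dtype=float)
    residues = topology.exchangeable_residues() if residues is None else residues
    acceptors = np.nonzero(topology.on_mask)[0]
    tree = cKDTree(frame[acceptors])
    acc_resids = topology.atom_resids[acceptors]
    out = np.zeros(len(residues))
    for j, resid in enumerate(residues):
        i_h = topology.amide_h_index(int(resid))
        if i_h is None:
            raise FeatureError(
                f"residue {resid}: no amide H atom "
                "(reconstruct hydrogens or provide them in the input)"
            )
        i_n = topology.amide_n_index(int(resid))
        near = np.asarray(tree.query_ball_point(frame[i_h], cutoff), dtype=int)
        if near.size:
            d = np.linalg.norm(frame[acceptors[near]] - frame[i_h], axis=1)
            near = near[d < cutoff]
        keep = acceptors[near] != i_n
        if exclude_neighbor_window:
            keep &= ~_neighbor_window(int(resid), acc_resids[near])
        out[j] = int(np.count_nonzero(keep))
    return out


def build_feature_table(
    ensemble: EnsembleCoordinates,
    topology: Topology,
    exclude_neighbor_window_hbonds: bool = False,
) -> FeatureTable:
    """Contact and H-bond counts for every frame and residue.

    Non-exchanging residues (prolines, the N-terminal residue) are carried
    with zero counts and flagged ``exchangeable=False``.
    """
    residues = topology.resids
    exchangeable = np.isin(residues, topology.exchangeable_residues())
    comp = residues[exchangeable]
    nc = np.zeros((ensemble.n_frames, residues.size))
    nh = np.zeros_like(nc)
    col = {int(r): j for j, r in enumerate(residues)}
    for k in range(ensemble.n_frames):
        try:
            c = compute_contacts(ensemble[k], topology, residues=comp)
            h = compute_hbonds(
                ensemble[k],
                topology,
                residues=comp,
                exclude_neighbor_window=exclude_neighbor_window_hbonds,
            )
        except FeatureError as exc:
            raise FeatureError(f"frame {k}: {exc}") from exc
        for j, r in enumerate(comp):
            nc[k, col[int(r)]] = c[j]
            nh[k, col[int(r)]] = h[j]
    return FeatureTable(residues, nc, nh, exchangeable)


def peptide_burial_score(features: FeatureTable, segment: Segment) -> float:
    """Burial proxy of a peptide: mean contact count of its exchange-competent
    residues over all frames (higher = more buried, less likely observed)."""
    sel = np.isin(features.residues, list(segment.residues())) & features.exchangeable
    if not np.any(sel):
        raise InputError(
            f"segment ({segment.start}, {segment.end}) has no exchange-competent "
            "residues in the feature table"
        )
    return float(features.n_contacts[:, sel].mean())
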