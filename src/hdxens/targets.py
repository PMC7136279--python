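"""Artificial target HDX data construction.

Benchmark targets are built from an ensemble with known composition: frames
are assigned to reference states by Calpha RMSD, per-state protection factors
are mixed in a chosen ratio, deuterated fractions are computed on a peptide
segmentation of the sequence, and the information content can be degraded in
controlled ways (longer segments, reduced coverage, Gaussian noise, regional
forward-model perturbations, removal of a state from the input ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyEnsembleError, InputError
from .forward import (
    DeuterationSeries,
    ForwardModelParams,
    IntrinsicRates,
    ProtectionFactors,
    Segment,
    ensemble_lnP,
    segment_deuteration,
)

__all__ = [
    "STATE_A",
    "STATE_B",
    "UNASSIGNED",
    "StateAssignment",
    "assign_states",
    "mix_lnP",
    "make_segments",
    "residue_segments",
    "reduce_coverage",
    "add_noise",
    "build_target",
    "remove_state_frames",
]

STATE_A = "A"
STATE_B = "B"
UNASSIGNED = "unassigned"


def _ca_trace(topology, frame: np.ndarray) -> np.ndarray:
    idx = [
        i
        for i in range(topology.n_atoms)
        if topology.atom_names[i].upper() == "CA"
    ]
    if len(idx) < 3:
        raise InputError("need at least 3 Calpha atoms for RMSD assignment")
    return np.asarray(frame, dtype=float)[idx]


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal (Kabsch)
    superposition."""
    from .analysis import pairwise_rmsd

    return pairwise_rmsd(a, b, superpose=True)


@dataclass
class StateAssignment:
    """Per-frame state labels from RMSD proximity to two references."""

    labels: np.ndarray          # (F,) values in {STATE_A, STATE_B, UNASSIGNED}
    rmsd_a: np.ndarray          # (F,) Calpha RMSD to reference A, Angstrom
    rmsd_b: np.ndarray
    rmsd_cutoff: float

    @property
    def fractions(self) -> dict:
        n = self.labels.size
        return {
            lab: float(np.count_nonzero(self.labels == lab)) / n
            for lab in (STATE_A, STATE_B, UNASSIGNED)
        }

    def frames_of(self, label: str) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


def assign_states(
    ensemble,
    topology,
    ref_a: np.ndarray,
    ref_b: np.ndarray,
    cutoff: float = 1.0,
) -> StateAssignment:
    """Label each frame by Calpha RMSD (after Kabsch superposition) to two
    reference conformations; frames within ``cutoff`` of a reference take its
    label (the nearer one when both qualify; an exact tie stays unassigned)."""
    ra = _ca_trace(topology, ref_a)
    rb = _ca_trace(topology, ref_b)
    n = ensemble.n_frames
    rmsd_a = np.empty(n)
    rmsd_b = np.empty(n)
    labels = np.full(n, UNASSIGNED, dtype=object)
    for k in range(n):
        ca = _ca_trace(topology, ensemble[k])
        rmsd_a[k] = superposed_rmsd(ca, ra)
        rmsd_b[k] = superposed_rmsd(ca, rb)
        in_a = rmsd_a[k] < cutoff
        in_b = rmsd_b[k] < cutoff
        if in_a and (not in_b or rmsd_a[k] < rmsd_b[k]):
            labels[k] = STATE_A
        elif in_b and (not in_a or rmsd_b[k] < rmsd_a[k]):
            labels[k] = STATE_B
    return StateAssignment(labels, rmsd_a, rmsd_b, float(cutoff))


def mix_lnP(
    lnp_a: ProtectionFactors, lnp_b: ProtectionFactors, fraction_a: float
) -> ProtectionFactors:
    """Linear mixture ``f * lnP_A + (1 - f) * lnP_B`` per residue."""
    if not (0.0 <= fraction_a <= 1.0):
        raise InputError("fraction_a must be in [0, 1]")
    if not np.array_equal(lnp_a.residues, lnp_b.residues):
        raise InputError("protection-factor residue sets differ")
    return ProtectionFactors(
        lnp_a.residues, fraction_a * lnp_a.lnp + (1.0 - fraction_a) * lnp_b.lnp
    )


def make_segments(n_residues: int, segment_length: int) -> list[Segment]:
    """Consecutive peptide segments with a one-residue overlap (1-L, L-2L-1,
    ...); the last segment that fully fits is extended to the C-terminus."""
    if not (2 <= segment_length <= n_residues):
        raise InputError("need 2 <= segment_length <= n_residues")
    step = segment_length - 1
    segments = []
    start = 1
    while start + step <= n_residues:
        segments.append(Segment(start, start + step))
        start += step
    last = segments[-1]
    if last.end != n_residues:
        segments[-1] = Segment(last.start, n_residues)
    return segments


def residue_segments(residues) -> list[Segment]:
    """Residue-resolution targets as two-residue segments (i-1, i): the
    segment-start exclusion leaves exactly residue i in the average."""
    return [Segment(int(r) - 1, int(r)) for r in residues]


def reduce_coverage(
    segments: list[Segment],
    burial_scores,
    keep_fraction: float,
    n_residues: int | None = None,
) -> list[Segment]:
    """Drop the most buried peptides (highest score first; ties by lower start
    index) until the retained residue coverage first falls to
    ``<= keep_fraction`` of the sequence."""
    scores = np.asarray(burial_scores, dtype=float)
    if scores.shape != (len(segments),):
        raise InputError("one burial score per segment required")
    if not (0.0 < keep_fraction <= 1.0):
        raise InputError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return list(segments)
    n_residues = n_residues or max(s.end for s in segments)

    def coverage(kept: list[Segment]) -> float:
        covered: set[int] = set()
        for s in kept:
            covered.update(s.span())
        return len(covered) / n_residues

    kept = list(segments)
    order = sorted(
        range(len(segments)), key=lambda i: (-scores[i], segments[i].start)
    )
    for i in order:
        if coverage(kept) <= keep_fraction:
            break
        kept = [s for s in kept if s != segments[i]]
    if not kept:
        raise InputError("coverage reduction removed every segment")
    return kept


def add_noise(
    series: DeuterationSeries, sigma: float, seed: int | None = None
) -> DeuterationSeries:
    """Independent Gaussian noise per data point (values deliberately not
    clamped to [0, 1]; inspect ``out_of_range()`` on the result)."""
    if sigma < 0:
        raise InputError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    noisy = series.values + rng.normal(0.0, sigma, size=series.values.shape)
    return DeuterationSeries(series.segments, series.times, noisy)


def build_target(
    lnp: ProtectionFactors,
    rates: IntrinsicRates,
    segments: list[Segment],
    times,
    *,
    regional_params: ForwardModelParams | None = None,
    features=None,
    weights=None,
    literal_denominator: bool = False,
) -> DeuterationSeries:
    """Deterministic target series from protection factors.

    With ``regional_params`` (a parameter set carrying per-residue overrides)
    and the generating ``features``/``weights``, protection factors are
    recomputed so that the override betas apply in the affected region.
    """
    if regional_params is not None:
        if features is None:
            raise InputError("regional_params requires the generating features")
        from .reweight import EnsembleWeights

        w = weights if weights is not None else EnsembleWeights.uniform(
            features.n_frames
        )
        lnp = ensemble_lnP(features, w, regional_params)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    values = np.vstack(
        [
            segment_deuteration(lnp, rates, seg, times, literal_denominator)
            for seg in segments
        ]
    )
    return DeuterationSeries(list(segments), times, values)


def remove_state_frames(
    features,
    assignment: StateAssignment,
    rmsd_cutoff: float,
    reference: str = STATE_A,
):
    """Drop every frame whose Calpha RMSD to the named reference is below the
    cutoff (emulates missing-state / insufficient-sampling scenarios);
    returns (filtered features, kept frame indices)."""
    rmsd = assignment.rmsd_a if reference == STATE_A else assignment.rmsd_b
    keep = np.nonzero(rmsd >= rmsd_cutoff)[0]
    if keep.size == 0:
        raise EmptyEnsembleError("all frames removed by the RMSD cutoff")
    return features.subset_frames(keep), keep
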