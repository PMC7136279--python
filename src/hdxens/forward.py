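"""Forward model: protection factors and EX2 deuterated fractions.

Backbone-amide protection is modelled as a linear function of two structural
observables of each amide, the number of heavy-atom contacts ``N_C`` and the
number of hydrogen bonds ``N_H``:

    ln P_i = < beta_C * N_C,i + beta_H * N_H,i >

where ``< >`` is an ensemble average (optionally reweighted).  Under EX2
kinetics the deuterated fraction of residue ``i`` after labeling time ``t``
(minutes) is ``1 - exp(-k_int,i * t / P_i)``, and a peptide-level value is the
mean over the segment's exchange-competent residues (the segment's first
residue and prolines carry no observable amide deuterium and are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "BETA_C_RANGE",
    "BETA_H_RANGE",
    "ForwardModelParams",
    "IntrinsicRates",
    "ProtectionFactors",
    "Segment",
    "DeuterationSeries",
    "ensemble_lnP",
    "residue_deuteration",
    "segment_deuteration",
    "dD_dlnP",
    "normalize_experimental",
]

#: Explored range of the contact scaling factor (dimensionless).
BETA_C_RANGE = (0.0, 1.5)
#: Explored range of the H-bond scaling factor (dimensionless).
BETA_H_RANGE = (0.0, 16.0)


@dataclass(frozen=True)
class ForwardModelParams:
    """Scaling factors of the empirical protection-factor model.

    Parameters
    ----------
    beta_c : float
        Weight of the heavy-atom contact count, default 0.35.
    beta_h : float
        Weight of the amide H-bond count, default 2.0.
    overrides : dict, optional
        Per-residue ``{resid: (beta_c, beta_h)}`` replacements.  Used only
        when *generating* perturbed target data for regional model-error
        studies; the reweighting optimizer never touches overrides.
    """

    beta_c: float = 0.35
    beta_h: float = 2.0
    overrides: dict | None = field(default=None)

    def __post_init__(self) -> None:
        if not (BETA_C_RANGE[0] <= self.beta_c <= BETA_C_RANGE[1]):
            raise InputError(f"beta_c={self.beta_c} outside {BETA_C_RANGE}")
        if not (BETA_H_RANGE[0] <= self.beta_h <= BETA_H_RANGE[1]):
            raise InputError(f"beta_h={self.beta_h} outside {BETA_H_RANGE}")

    def replace(self, beta_c: float | None = None, beta_h: float | None = None) -> "ForwardModelParams":
        return ForwardModelParams(
            beta_c=self.beta_c if beta_c is None else beta_c,
            beta_h=self.beta_h if beta_h is None else beta_h,
            overrides=self.overrides,
        )

    def coefficients(self, residues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-residue (beta_c, beta_h) vectors, honouring overrides."""
        residues = np.asarray(residues)
        bc = np.full(residues.shape, self.beta_c, dtype=float)
        bh = np.full(residues.shape, self.beta_h, dtype=float)
        if self.overrides:
            for r, (c, h) in self.overrides.items():
                sel = residues == r
                bc[sel] = c
                bh[sel] = h
        return bc, bh


@dataclass
class IntrinsicRates:
    """Per-residue intrinsic exchange rate constants, in 1/min.

    Values are consumed from a user-supplied table (sequence- and
    condition-dependent reference values); prolines carry no entry.
    """

    residues: np.ndarray
    k_int: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.k_int = np.asarray(self.k_int, dtype=float)
        if self.residues.shape != self.k_int.shape:
            raise InputError("residues and k_int must have equal length")
        if self.residues.size == 0:
            raise InputError("empty intrinsic-rate table")
        if np.any(self.k_int <= 0):
            raise InputError("intrinsic rates must be positive")

    def get(self, resid: int) -> float:
        idx = np.nonzero(self.residues == resid)[0]
        if idx.size == 0:
            raise InputError(f"no intrinsic rate for residue {resid}")
        return float(self.k_int[idx[0]])

    def __contains__(self, resid: int) -> bool:
        return bool(np.any(self.residues == resid))

    def to_file(self, path) -> None:
        pd.DataFrame({"residue": self.residues, "k_int": self.k_int}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_file(cls, path) -> "IntrinsicRates":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        if df.shape[1] < 2:
            raise InputError(f"{path}: expected two columns (residue, k_int)")
        return cls(df.iloc[:, 0].to_numpy(int), df.iloc[:, 1].to_numpy(float))


@dataclass
class ProtectionFactors:
    """Natural-log protection factors ``ln P_i`` for a set of residues."""

    residues: np.ndarray
    lnp: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.lnp = np.asarray(self.lnp, dtype=float)
        if self.residues.shape != self.lnp.shape:
            raise InputError("residues and lnp must have equal length")

    def get(self, resid: int) -> float:
        idx = np.nonzero(self.residues == resid)[0]
        if idx.size == 0:
            raise InputError(f"no protection factor for residue {resid}")
        return float(self.lnp[idx[0]])

    def __contains__(self, resid: int) -> bool:
        return bool(np.any(self.residues == resid))

    def as_series(self) -> pd.Series:
        return pd.Series(self.lnp, index=self.residues, name="lnP")


@dataclass(frozen=True, order=True)
class Segment:
    """Peptide segment [start, end], inclusive, 1-based author numbering."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"segment ({self.start}, {self.end}): need start < end")

    def residues(self) -> range:
        """Residues contributing deuterium: start+1 .. end (prolines removed later)."""
        return range(self.start + 1, self.end + 1)

    def span(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class DeuterationSeries:
    """Segment x labeling-time matrix of deuterated fractions ``D_j,t``."""

    segments: list[Segment]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.segments), self.times.size):
            raise InputError(
                f"values shape {self.values.shape} != "
                f"({len(self.segments)}, {self.times.size})"
            )

    @property
    def n_data(self) -> int:
        return int(self.values.size)

    def out_of_range(self) -> np.ndarray:
        """Boolean mask of entries outside [0, 1] (noise may push them out)."""
        return (self.values < 0.0) | (self.values > 1.0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"{t:g}" for t in self.times]
        )
        df.insert(0, "segment_start", [s.start for s in self.segments])
        df.insert(1, "segment_end", [s.end for s in self.segments])
        return df

    def to_file(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_file(cls, path) -> "DeuterationSeries":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        cols = list(df.columns)
        if cols[:2] != ["segment_start", "segment_end"]:
            raise InputError(
                f"{path}: first columns must be segment_start, segment_end"
            )
        segments = [
            Segment(int(a), int(b))
            for a, b in zip(df["segment_start"], df["segment_end"])
        ]
        times = np.array([float(c) for c in cols[2:]])
        return cls(segments, times, df[cols[2:]].to_numpy(float))


def ensemble_lnP(features, weights, params: ForwardModelParams) -> ProtectionFactors:
    """Weighted ensemble-average protection factors.

    ``ln P_i = sum_k Omega_k (beta_C N_C,ik + beta_H N_H,ik)`` over the
    exchange-competent residues of the feature table.
    """
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    if w.ndim != 1 or w.shape[0] != features.n_frames:
        raise InputError("weights length must equal the frame count")
    if abs(w.sum() - 1.0) > 1e-8 or np.any(w < -1e-12):
        raise InputError("weights must be nonnegative and normalized")
    mask = features.exchangeable
    residues = features.residues[mask]
    bc, bh = params.coefficients(residues)
    b = bc * features.n_contacts[:, mask] + bh * features.n_hbonds[:, mask]
    return ProtectionFactors(residues, w @ b)


def residue_deuteration(lnp: float, k_int: float, t: float) -> float:
    """Deuterated fraction of one residue: ``1 - exp(-k_int t e^{-lnP})``."""
    if t < 0:
        raise InputError("labeling time must be nonnegative")
    if k_int <= 0:
        raise InputError("intrinsic rate must be positive")
    return float(-np.expm1(-k_int * t * np.exp(-lnp)))


def _included_residues(
    lnp: ProtectionFactors, rates: IntrinsicRates, segment: Segment
) -> list[int]:
    """Exchange-competent residues of a segment (drops start residue and any
    residue lacking a protection factor or intrinsic rate, i.e. prolines)."""
    return [r for r in segment.residues() if r in lnp and r in rates]


def segment_deuteration(
    lnp: ProtectionFactors,
    rates: IntrinsicRates,
    segment: Segment,
    times,
    literal_denominator: bool = False,
) -> np.ndarray:
    """Peptide deuterated fraction at each labeling time (minutes).

    The average runs over residues ``start+1 .. end`` excluding prolines.  By
    default the denominator is the number of residues actually averaged, so
    ``D -> 1`` as ``t -> inf``; ``literal_denominator=True`` divides by
    ``end - start`` regardless of exclusions.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    incl = _included_residues(lnp, rates, segment)
    if not incl:
        raise InputError(f"segment ({segment.start}, {segment.end}) has no "
                         "exchange-competent residues")
    denom = (segment.end - segment.start) if literal_denominator else len(incl)
    k = np.array([rates.get(r) for r in incl])
    lp = np.array([lnp.get(r) for r in incl])
    u = k[None, :] * times[:, None] * np.exp(-lp)[None, :]
    return (-np.expm1(-u)).sum(axis=1) / denom


def dD_dlnP(
    lnp: ProtectionFactors,
    rates: IntrinsicRates,
    segment: Segment,
    t: float,
    literal_denominator: bool = False,
) -> np.ndarray:
    """Partials ``dD_j,t / dlnP_i`` over ``lnp.residues``; zero outside the segment.

    With ``u = k_i t e^{-lnP_i}``, each included residue contributes
    ``-u e^{-u} / denom``.
    """
    if t < 0:
        raise InputError("labeling time must be nonnegative")
    incl = _included_residues(lnp, rates, segment)
    if not incl:
        raise InputError(f"segment ({segment.start}, {segment.end}) has no "
                         "exchange-competent residues")
    denom = (segment.end - segment.start) if literal_denominator else len(incl)
    out = np.zeros_like(lnp.lnp)
    for r in incl:
        i = int(np.nonzero(lnp.residues == r)[0][0])
        u = rates.get(r) * t * np.exp(-lnp.lnp[i])
        out[i] = -u * np.exp(-u) / denom
    return out


def normalize_experimental(
    raw: DeuterationSeries,
    max_deuteration_control: DeuterationSeries,
    d2o_fraction: float = 1.0,
) -> DeuterationSeries:
    """Back-exchange / D2O-fraction normalization against a maximally
    deuterated control: ``raw / (control * d2o_fraction)`` element-wise."""
    ctrl = max_deuteration_control
    if [s for s in raw.segments] != [s for s in ctrl.segments] or not np.array_equal(
        raw.times, ctrl.times
    ):
        raise InputError("raw and control series must share segments and times")
    if np.any(ctrl.values <= 0):
        raise InputError("control deuteration values must be positive")
    if d2o_fraction <= 0:
        raise InputError("d2o_fraction must be positive")
    return DeuterationSeries(
        raw.segments, raw.times, raw.values / (ctrl.values * d2o_fraction)
    )
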