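"""Download-free synthetic fixtures.

Two generators cover the package's needs at desk scale: a feature-level
two-state ensemble (frames drawn from per-residue Poisson contact counts and
Bernoulli H-bond indicators, with optional interpolated "decoy" frames) for
the reweighting machinery, and a coordinate-level toy trace ensemble for the
geometry, RMSD and clustering code.  Both are deterministic per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .features import FeatureTable
from .forward import ForwardModelParams, IntrinsicRates, ensemble_lnP
from .io import EnsembleCoordinates
from .reweight import EnsembleWeights
from .targets import build_target, mix_lnP, residue_segments

__all__ = [
    "DEFAULT_TIMES",
    "TwoStateSpec",
    "generate_two_state_features",
    "generate_toy_trace_ensemble",
    "uniform_rates",
    "two_state_problem",
]

#: Standard labeling time points, minutes.
DEFAULT_TIMES = (0.167, 1.0, 10.0, 60.0, 120.0)


@dataclass(frozen=True)
class TwoStateSpec:
    """Generative description of a two-state feature ensemble.

    State A emulates a compact (protected) conformation, state B an open
    (exposed) one; the default per-residue parameter ranges keep the states
    well separated in (N_C, N_H) space.  ``decoy_fraction`` frames are drawn
    from per-residue means interpolated at a random coordinate within
    ``decoy_range`` between the two states.
    """

    n_frames: int = 1000
    n_residues: int = 30
    fraction_a: float = 0.5
    decoy_fraction: float = 0.0
    decoy_range: tuple[float, float] = (0.2, 0.8)
    contact_mean_a: tuple[float, float] = (8.0, 16.0)
    contact_mean_b: tuple[float, float] = (2.0, 6.0)
    hbond_p_a: tuple[float, float] = (0.6, 1.0)
    hbond_p_b: tuple[float, float] = (0.0, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_residues < 2:
            raise InputError("need n_frames >= 1 and n_residues >= 2")
        if not (0.0 <= self.fraction_a <= 1.0):
            raise InputError("fraction_a must be in [0, 1]")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise InputError("decoy_fraction must be in [0, 1]")
        for rng_ in (self.contact_mean_a, self.contact_mean_b):
            if rng_[0] < 0 or rng_[1] < rng_[0]:
                raise InputError("contact mean ranges must be ordered, >= 0")
        for rng_ in (self.hbond_p_a, self.hbond_p_b):
            if not (0 <= rng_[0] <= rng_[1] <= 1):
                raise InputError("H-bond probability ranges must lie in [0, 1]")


def generate_two_state_features(
    spec: TwoStateSpec,
) -> tuple[FeatureTable, np.ndarray]:
    """Draw a feature ensemble; returns (table, true per-frame labels).

    Labels are "A", "B" or "decoy".  Residue 1 is flagged non-exchanging
    (protein N-terminus); the synthetic protein contains no prolines.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.n_residues
    mean_a = rng.uniform(*spec.contact_mean_a, size=R)
    mean_b = rng.uniform(*spec.contact_mean_b, size=R)
    p_a = rng.uniform(*spec.hbond_p_a, size=R)
    p_b = rng.uniform(*spec.hbond_p_b, size=R)
    if np.allclose(mean_a, mean_b) and np.allclose(p_a, p_b):
        warnings.warn("two-state spec is degenerate: states are identical")

    n_decoy = int(round(spec.n_frames * spec.decoy_fraction))
    n_a = int(round((spec.n_frames - n_decoy) * spec.fraction_a))
    n_b = spec.n_frames - n_decoy - n_a
    labels = np.array(["A"] * n_a + ["B"] * n_b + ["decoy"] * n_decoy, dtype=object)
    rng.shuffle(labels)

    nc = np.zeros((spec.n_frames, R))
    nh = np.zeros((spec.n_frames, R))
    for k, lab in enumerate(labels):
        if lab == "A":
            mu, p = mean_a, p_a
        elif lab == "B":
            mu, p = mean_b, p_b
        else:
            alpha = rng.uniform(*spec.decoy_range)
            mu = alpha * mean_a + (1 - alpha) * mean_b
            p = alpha * p_a + (1 - alpha) * p_b
        nc[k] = rng.poisson(mu)
        nh[k] = rng.binomial(1, p)

    residues = np.arange(1, R + 1)
    exchangeable = residues != 1
    return FeatureTable(residues, nc, nh, exchangeable), labels


def generate_toy_trace_ensemble(
    n_frames: int,
    n_atoms: int,
    cluster_centers,
    spread: float,
    weights_hint=None,
    seed: int | None = None,
) -> tuple[EnsembleCoordinates, np.ndarray]:
    """Coordinate frames scattered isotropically around given center traces;
    returns (ensemble, per-frame generating-center labels)."""
    centers = [np.asarray(c, dtype=float) for c in cluster_centers]
    for c in centers:
        if c.shape != (n_atoms, 3):
            raise InputError("all centers must have shape (n_atoms, 3)")
    rng = np.random.default_rng(seed)
    hint = (
        np.full(len(centers), 1.0 / len(centers))
        if weights_hint is None
        else np.asarray(weights_hint, dtype=float)
    )
    hint = hint / hint.sum()
    counts = np.floor(hint * n_frames).astype(int)
    while counts.sum() < n_frames:
        counts[int(np.argmax(hint * n_frames - counts))] += 1
    labels = np.repeat(np.arange(len(centers)), counts)
    frames = np.empty((n_frames, n_atoms, 3))
    for k, lab in enumerate(labels):
        frames[k] = centers[lab] + rng.normal(0.0, spread, size=(n_atoms, 3))
    return EnsembleCoordinates(frames, {"generator": "toy_trace"}), labels


def uniform_rates(n_residues: int, k: float = 1.0) -> IntrinsicRates:
    """Constant intrinsic-rate table (1/min) over residues 1..n."""
    if n_residues < 1:
        raise InputError("n_residues must be >= 1")
    if k <= 0:
        raise InputError("rate must be positive")
    residues = np.arange(1, n_residues + 1)
    return IntrinsicRates(residues, np.full(n_residues, float(k)))


@dataclass
class TwoStateProblem:
    """A ready-to-fit recovery benchmark with known ground truth."""

    features: FeatureTable
    labels: np.ndarray
    rates: IntrinsicRates
    target: "object"
    lnp_a: "object"
    lnp_b: "object"
    lnp_mix: "object"
    fraction_a_target: float
    spec: TwoStateSpec
    params: ForwardModelParams = field(default_factory=ForwardModelParams)

    def state_weight(self, weights, label: str = "A") -> float:
        w = np.asarray(getattr(weights, "values", weights), dtype=float)
        return float(w[self.labels == label].sum())


def two_state_problem(
    spec: TwoStateSpec | None = None,
    fraction_a_target: float = 0.6,
    times=DEFAULT_TIMES,
    k_int: float = 1.0,
    params: ForwardModelParams | None = None,
    segments=None,
) -> TwoStateProblem:
    """Generate a feature ensemble and a residue-level target whose
    deuteration corresponds to a known A:B protection-factor mixture."""
    spec = spec or TwoStateSpec()
    params = params or ForwardModelParams()
    features, labels = generate_two_state_features(spec)
    rates = uniform_rates(spec.n_residues, k_int)

    def _subensemble_lnp(label: str):
        idx = np.nonzero(labels == label)[0]
        if idx.size == 0:
            raise InputError(f"no frames with label {label!r}")
        sub = features.subset_frames(idx)
        return ensemble_lnP(sub, EnsembleWeights.uniform(idx.size), params)

    lnp_a = _subensemble_lnp("A")
    lnp_b = _subensemble_lnp("B")
    lnp_mix = mix_lnP(lnp_a, lnp_b, fraction_a_target)
    if segments is None:
        segments = residue_segments(features.residues[features.exchangeable])
    target = build_target(lnp_mix, rates, segments, times)
    return TwoStateProblem(
        features=features,
        labels=labels,
        rates=rates,
        target=target,
        lnp_a=lnp_a,
        lnp_b=lnp_b,
        lnp_mix=lnp_mix,
        fraction_a_target=fraction_a_target,
        spec=spec,
        params=params,
    )
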