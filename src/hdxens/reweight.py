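"""Maximum-entropy reweighting of structural ensembles against HDX-MS data.

The model: frame weights are exponentially tilted in the per-frame amide
observables,

    Omega_k  propto  exp{ sum_i lambda_i [beta_C N_C,ik + beta_H N_H,ik] },

which is the minimal (maximum-entropy) bias able to shift the
ensemble-averaged protection factors ln P_i.  The lambda_i are chosen to
minimize the likelihood

    L = W_app / k_B T - ln rho_err(D_sim),

where ``rho_err`` is a Gaussian error model of tunable precision ``gamma``
(uncertainty scale ``eta``, fixed to 1 by convention) over all target
deuterated fractions, and the apparent work

    W_app = k_B T ln < exp{-sum_i lambda_i (b_i(X) - ln P_i)} >_corrected

equals ``k_B T`` times the Kullback-Leibler divergence between the initial
and reweighted ensembles.  Minimization iterates the damped fixed-point
update  ``lambda <- lambda (1 - eps) + eps * d ln rho_err / d lnP``,
optionally interleaved with a greedy Monte Carlo optimization of the
forward-model scaling factors beta_C, beta_H.

Usage follows the statsmodels pattern: build a :class:`MaxEntReweighting`
model from a feature table, a target deuteration series and intrinsic rates,
call :meth:`~MaxEntReweighting.fit`, and inspect the returned
:class:`ReweightingResults` (``summary()``, weights, W_app, MSD, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InputError
from .forward import (
    BETA_C_RANGE,
    BETA_H_RANGE,
    DeuterationSeries,
    ForwardModelParams,
    IntrinsicRates,
    ProtectionFactors,
)

__all__ = [
    "KB_KJ_MOL",
    "EnsembleWeights",
    "MaxEntReweighting",
    "ReweightingResults",
    "DecisionCurve",
    "omega_weights",
    "apparent_work",
    "apparent_work_kl",
    "log_error_density",
    "mean_squared_deviation",
    "lambda_step",
    "mc_optimize_betas",
    "run_reweighting",
    "gamma_scan",
    "kish_ess",
]

#: Boltzmann constant in kJ mol^-1 K^-1.
KB_KJ_MOL = 0.0083144621

#: Maximum Monte Carlo step sizes for the beta parameters (10% of the
#: explored ranges).
DELTA_BETA_C_MAX = 0.15
DELTA_BETA_H_MAX = 1.6


class EnsembleWeights:
    """Normalized statistical weights Omega_k over ensemble frames."""

    def __init__(self, values) -> None:
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise InputError("weights must be a nonempty 1-D array")
        if np.any(v < -1e-12):
            raise InputError("weights must be nonnegative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise InputError(f"weights must sum to 1 (got {v.sum()!r})")
        self.values = np.clip(v, 0.0, None)
        self.values = self.values / self.values.sum()

    @classmethod
    def uniform(cls, n: int) -> "EnsembleWeights":
        return cls(np.full(n, 1.0 / n))

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.values)

    def kish_ess(self) -> float:
        return kish_ess(self)

    def to_file(self, path) -> None:
        pd.DataFrame(
            {"frame": np.arange(self.n), "weight": self.values}
        ).to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_file(cls, path) -> "EnsembleWeights":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        return cls(df["weight"].to_numpy(float))


def _as_weight_array(weights) -> np.ndarray:
    return np.asarray(getattr(weights, "values", weights), dtype=float)


def kish_ess(weights) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2`` of normalized
    weights; ranges from 1 (all mass on one frame) to N (uniform)."""
    w = _as_weight_array(weights)
    return float(w.sum() ** 2 / np.sum(w ** 2))


def omega_weights(
    lambdas, features, params: ForwardModelParams
) -> EnsembleWeights:
    """Frame weights from the bias coefficients lambda (log-sum-exp safe)."""
    lam = np.asarray(lambdas, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise InputError("non-finite lambda")
    b = features.observable(params)
    if lam.shape != (b.shape[1],):
        raise InputError(
            f"lambda length {lam.shape} != exchange-competent residues {b.shape[1]}"
        )
    logw = b @ lam
    logw -= logw.max()
    w = np.exp(logw)
    return EnsembleWeights(w / w.sum())


def apparent_work(
    lambdas,
    features,
    params: ForwardModelParams,
    temperature: float = 300.0,
) -> float:
    """Apparent work (kJ/mol) of the applied bias,

        W_app = k_B T ln < exp{-sum_i lambda_i (b_i - lnP_i)} >_Omega

    with lnP_i the reweighted ensemble averages.  Identical to
    ``k_B T * d_KL(reweighted || initial)``; see :func:`apparent_work_kl`.
    """
    lam = np.asarray(lambdas, dtype=float)
    b = features.observable(params)
    logw = b @ lam
    shift = logw.max()
    w = np.exp(logw - shift)
    Z = w.sum()
    omega = w / Z
    lnp = omega @ b
    # <exp{-lam.(b - lnP)}>_Omega = exp{lam.lnP} * N / sum_k exp{lam.b_k}
    log_mean = float(lam @ lnp + np.log(b.shape[0]) - (shift + np.log(Z)))
    if not np.isfinite(log_mean):
        raise InputError("non-finite apparent work")
    return KB_KJ_MOL * temperature * log_mean


def apparent_work_kl(weights, temperature: float = 300.0) -> float:
    """``k_B T (sum_k Omega_k ln Omega_k + ln N)`` in kJ/mol."""
    w = _as_weight_array(weights)
    nz = w > 0
    return KB_KJ_MOL * temperature * float(np.sum(w[nz] * np.log(w[nz])) + np.log(w.size))


def _check_matching(sim: DeuterationSeries, target: DeuterationSeries) -> None:
    if sim.values.shape != target.values.shape:
        raise InputError("sim/target shape mismatch")
    if list(sim.segments) != list(target.segments) or not np.allclose(
        sim.times, target.times
    ):
        raise InputError("sim/target segments or times differ")


def log_error_density(
    sim: DeuterationSeries,
    target: DeuterationSeries,
    gamma: float,
    eta: float = 1.0,
) -> float:
    """Log of the Gaussian error model (normalization dropped):
    ``- sum_{j,t} gamma (D_sim - D_exp)^2 / (2 eta^2)``."""
    _check_matching(sim, target)
    dd = sim.values - target.values
    return float(-gamma * np.sum(dd ** 2) / (2.0 * eta ** 2))


def mean_squared_deviation(
    sim: DeuterationSeries, target: DeuterationSeries, eta: float = 1.0
) -> float:
    """``MSD = chi^2 / N_D`` with ``chi^2 = sum ((D_sim - D_exp)/eta)^2``."""
    _check_matching(sim, target)
    if sim.n_data == 0:
        raise InputError("no data points")
    dd = (sim.values - target.values) / eta
    return float(np.sum(dd ** 2) / sim.n_data)


def msd_to_rmse_da(msd: float, mass_per_site: float = 1.0) -> float:
    """Convert a deuterated-fraction MSD to the per-residue root-mean-square
    mass error in Daltons (one exchangeable deuterium per residue)."""
    return float(np.sqrt(msd) * mass_per_site)


# --------------------------------------------------------------------------
# vectorized engine shared by the model, the standalone steps and the scans


class _Engine:
    """Precomputed arrays for fast iteration of one reweighting problem."""

    def __init__(self, features, target, rates, eta, literal_denominator):
        mask = features.exchangeable
        self.residues = features.residues[mask]
        self.NC = np.ascontiguousarray(features.n_contacts[:, mask])
        self.NH = np.ascontiguousarray(features.n_hbonds[:, mask])
        self.n_frames = self.NC.shape[0]
        self.n_res = self.residues.size
        self.times = np.asarray(target.times, dtype=float)
        self.D_exp = target.values
        self.target = target
        self.eta = float(eta)
        idx_of = {int(r): j for j, r in enumerate(self.residues)}
        S = len(target.segments)
        self.M = np.zeros((S, self.n_res))
        self.k = np.ones(self.n_res)
        has_rate = np.zeros(self.n_res, dtype=bool)
        for j, r in enumerate(self.residues):
            if int(r) in rates:
                self.k[j] = rates.get(int(r))
                has_rate[j] = True
        for sj, seg in enumerate(target.segments):
            incl = [
                idx_of[r]
                for r in seg.residues()
                if r in idx_of and has_rate[idx_of[r]]
            ]
            missing = [
                r for r in seg.residues() if r in idx_of and not has_rate[idx_of[r]]
            ]
            if missing:
                raise InputError(
                    f"segment ({seg.start}, {seg.end}): residues {missing} "
                    "lack intrinsic rates"
                )
            if not incl:
                raise InputError(
                    f"segment ({seg.start}, {seg.end}) covers no residue of "
                    "the feature table"
                )
            denom = (seg.end - seg.start) if literal_denominator else len(incl)
            self.M[sj, incl] = 1.0 / denom
        self.covered = self.M.any(axis=0)

    def b_matrix(self, params: ForwardModelParams) -> np.ndarray:
        bc, bh = params.coefficients(self.residues)
        return bc * self.NC + bh * self.NH

    def state(self, lam: np.ndarray, b: np.ndarray, gamma: float) -> dict:
        logw = b @ lam
        shift = logw.max()
        w = np.exp(logw - shift)
        Z = w.sum()
        omega = w / Z
        lnp = omega @ b
        u = self.k[None, :] * self.times[:, None] * np.exp(-lnp)[None, :]
        d_res = -np.expm1(-u)                       # (T, R)
        d_sim = self.M @ d_res.T                    # (S, T)
        dd = d_sim - self.D_exp
        eta2 = self.eta ** 2
        msd = float(np.sum(dd ** 2) / dd.size) / eta2
        ln_rho = -gamma * float(np.sum(dd ** 2)) / (2.0 * eta2)
        A = self.M.T @ dd                           # (R, T)
        grad = (gamma / eta2) * np.sum(A * (u * np.exp(-u)).T, axis=1)
        wapp_kt = float(lam @ lnp) + np.log(self.n_frames) - (shift + np.log(Z))
        return {
            "omega": omega,
            "lnp": lnp,
            "d_sim": d_sim,
            "msd": msd,
            "ln_rho": ln_rho,
            "grad": grad,
            "wapp_kt": wapp_kt,
            "likelihood": wapp_kt - ln_rho,
        }

    def msd_at(self, lam: np.ndarray, params: ForwardModelParams) -> float:
        b = self.b_matrix(params)
        logw = b @ lam
        w = np.exp(logw - logw.max())
        omega = w / w.sum()
        lnp = omega @ b
        u = self.k[None, :] * self.times[:, None] * np.exp(-lnp)[None, :]
        d_sim = self.M @ (-np.expm1(-u)).T
        dd = (d_sim - self.D_exp) / self.eta
        return float(np.sum(dd ** 2) / dd.size)


def _mc_betas(
    engine: _Engine,
    lam: np.ndarray,
    params: ForwardModelParams,
    rng: np.random.Generator,
    n_trials: int,
    joint: bool,
) -> tuple[ForwardModelParams, float]:
    """Greedy random-walk optimization of (beta_C, beta_H): a proposal is
    accepted only if the (gamma-free) MSD strictly decreases."""
    best = params
    best_msd = engine.msd_at(lam, params)
    for _ in range(n_trials):
        dc = rng.uniform(-DELTA_BETA_C_MAX, DELTA_BETA_C_MAX)
        dh = rng.uniform(-DELTA_BETA_H_MAX, DELTA_BETA_H_MAX)
        if not joint:
            if rng.uniform() < 0.5:
                dh = 0.0
            else:
                dc = 0.0
        cand = best.replace(
            beta_c=float(np.clip(best.beta_c + dc, *BETA_C_RANGE)),
            beta_h=float(np.clip(best.beta_h + dh, *BETA_H_RANGE)),
        )
        msd = engine.msd_at(lam, cand)
        if msd < best_msd:
            best, best_msd = cand, msd
    return best, best_msd


@dataclass
class ReweightingResults:
    """Outcome of one maximum-entropy reweighting optimization."""

    residues: np.ndarray
    lambdas: np.ndarray
    params: ForwardModelParams
    gamma: float
    eta: float
    temperature: float
    weights: EnsembleWeights
    lnp: ProtectionFactors
    d_sim: DeuterationSeries
    w_app: float
    w_app_kl: float
    msd: float
    likelihood: float
    n_iter: int
    converged: bool
    update_rate: float
    history: pd.DataFrame = field(repr=False, default=None)

    @property
    def kish_ess(self) -> float:
        return kish_ess(self.weights)

    def lambda_of(self, resid: int) -> float:
        idx = np.nonzero(self.residues == resid)[0]
        if idx.size == 0:
            raise InputError(f"residue {resid} not in model")
        return float(self.lambdas[idx[0]])

    def summary(self) -> str:
        kbt = KB_KJ_MOL * self.temperature
        lines = [
            "Maximum-entropy HDX ensemble reweighting",
            "=" * 56,
            f"frames                    {self.weights.n:>12d}",
            f"residues (exchangeable)   {self.residues.size:>12d}",
            f"target data points        {self.d_sim.n_data:>12d}",
            f"gamma                     {self.gamma:>12.4g}",
            f"eta                       {self.eta:>12.4g}",
            f"temperature (K)           {self.temperature:>12.1f}",
            "-" * 56,
            f"converged                 {str(self.converged):>12s}",
            f"iterations                {self.n_iter:>12d}",
            f"final update rate eps     {self.update_rate:>12.4g}",
            f"beta_C                    {self.params.beta_c:>12.4f}",
            f"beta_H                    {self.params.beta_h:>12.4f}",
            f"MSD                       {self.msd:>12.4e}",
            f"W_app (kJ/mol)            {self.w_app:>12.4f}",
            f"W_app / k_B T             {self.w_app / kbt:>12.4f}",
            f"likelihood L              {self.likelihood:>12.6g}",
            f"Kish ESS                  {self.kish_ess:>12.1f}",
            "=" * 56,
        ]
        return "\n".join(lines)


@dataclass
class DecisionCurve:
    """W_app vs MSD across a gamma scan (the L-curve / decision plot)."""

    gammas: np.ndarray
    w_app: np.ndarray
    msd: np.ndarray
    converged: np.ndarray
    params: list
    results: list = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gamma": self.gammas,
                "w_app": self.w_app,
                "msd": self.msd,
                "converged": self.converged.astype(int),
                "beta_c": [p.beta_c for p in self.params],
                "beta_h": [p.beta_h for p in self.params],
            }
        )

    def to_file(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    def plot(self, ax=None):
        """Decision plot: W_app against MSD, annotated with gamma."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.msd, self.w_app, "o-")
        for g, m, w in zip(self.gammas, self.msd, self.w_app):
            ax.annotate(f"{g:g}", (m, w), fontsize=7)
        ax.set_xscale("log")
        ax.set_xlabel("MSD")
        ax.set_ylabel(r"$W_{app}$ (kJ/mol)")
        return ax


class MaxEntReweighting:
    """Maximum-entropy reweighting model for one ensemble + target dataset.

    Parameters
    ----------
    features : FeatureTable
        Per-frame amide contact / H-bond counts.
    target : DeuterationSeries
        Target (experimental or artificial) deuterated fractions.
    rates : IntrinsicRates
        Intrinsic exchange rate constants (1/min).
    eta : float
        Uncertainty scale of the error model (default 1; by convention gamma
        alone sets the effective precision).
    temperature : float
        Temperature in K used to express W_app in kJ/mol (default 300).
    params : ForwardModelParams, optional
        Initial forward-model scaling factors (default beta_C=0.35,
        beta_H=2.0).
    literal_denominator : bool
        Divide segment averages by ``end - start`` instead of the number of
        residues actually averaged.
    """

    def __init__(
        self,
        features,
        target: DeuterationSeries,
        rates: IntrinsicRates,
        *,
        eta: float = 1.0,
        temperature: float = 300.0,
        params: ForwardModelParams | None = None,
        literal_denominator: bool = False,
    ) -> None:
        if eta <= 0:
            raise InputError("eta must be positive")
        self.features = features
        self.target = target
        self.rates = rates
        self.eta = float(eta)
        self.temperature = float(temperature)
        self.params0 = params or ForwardModelParams()
        self._engine = _Engine(features, target, rates, eta, literal_denominator)

    @classmethod
    def from_files(
        cls, features_file, target_file, rates_file, **kwargs
    ) -> "MaxEntReweighting":
        from .features import FeatureTable

        return cls(
            FeatureTable.from_file(features_file),
            DeuterationSeries.from_file(target_file),
            IntrinsicRates.from_file(rates_file),
            **kwargs,
        )

    @property
    def residues(self) -> np.ndarray:
        return self._engine.residues

    def predict(
        self, weights=None, params: ForwardModelParams | None = None
    ) -> DeuterationSeries:
        """Forward-model deuteration of the (optionally reweighted) ensemble."""
        params = params or self.params0
        eng = self._engine
        if weights is None:
            w = np.full(eng.n_frames, 1.0 / eng.n_frames)
        else:
            w = _as_weight_array(weights)
        b = eng.b_matrix(params)
        lnp = w @ b
        u = eng.k[None, :] * eng.times[:, None] * np.exp(-lnp)[None, :]
        return DeuterationSeries(
            self.target.segments, eng.times, eng.M @ (-np.expm1(-u)).T
        )

    def fit(
        self,
        gamma: float,
        *,
        update_rate: float = 0.01,
        max_iter: int = 50_000,
        tol: float = 1e-8,
        optimize_betas: bool = False,
        beta_update_interval: int = 1,
        n_beta_trials: int = 100,
        joint_beta_proposals: bool = True,
        seed: int | None = None,
        grow_interval: int = 20,
        min_update_rate: float = 1e-9,
        lambdas0=None,
        params0: ForwardModelParams | None = None,
        keep_history: bool = True,
    ) -> ReweightingResults:
        """Minimize L = W_app/k_BT - ln rho_err by damped fixed-point
        iteration of lambda, optionally interleaving Monte Carlo beta moves.

        The update rate adapts by backtracking: a step that would increase L
        is rejected and eps halved (ConvergenceError below
        ``min_update_rate``); after ``grow_interval`` consecutive accepted
        steps eps doubles (capped at 1), so L is non-increasing over accepted
        iterations and the damping recovers once the iteration stabilizes.
        """
        if gamma <= 0:
            raise InputError("gamma must be positive")
        if not (0 < update_rate <= 1):
            raise InputError("update rate must be in (0, 1]")
        eng = self._engine
        params = params0 or self.params0
        lam = (
            np.zeros(eng.n_res)
            if lambdas0 is None
            else np.array(lambdas0, dtype=float)
        )
        if lam.shape != (eng.n_res,):
            raise InputError("lambdas0 has wrong length")
        rng = np.random.default_rng(seed)
        eps = float(update_rate)
        b = eng.b_matrix(params)
        hist: list[tuple] = []
        converged = False
        it = 0
        streak = 0
        st = eng.state(lam, b, gamma)
        for it in range(1, max_iter + 1):
            if optimize_betas and (it - 1) % beta_update_interval == 0:
                params, _ = _mc_betas(
                    eng, lam, params, rng, n_beta_trials, joint_beta_proposals
                )
                b = eng.b_matrix(params)
                st = eng.state(lam, b, gamma)
            if not np.all(np.isfinite(st["grad"])):
                bad_res = eng.residues[~np.isfinite(st["grad"])]
                raise ConvergenceError(f"non-finite gradient at residues {bad_res}")
            lam_new = lam * (1.0 - eps) + eps * st["grad"]
            st_new = eng.state(lam_new, b, gamma)
            accept = st_new["likelihood"] <= st["likelihood"] * (1 + 1e-12) + 1e-12
            # fixed-point residual scaled by the nominal rate, so the
            # stopping rule is independent of the adaptive eps
            delta = update_rate * float(np.max(np.abs(st["grad"] - lam)))
            if keep_history:
                hist.append(
                    (it, st_new["likelihood"], st_new["wapp_kt"], st_new["msd"],
                     params.beta_c, params.beta_h, delta, int(accept), eps)
                )
            if accept:
                lam = lam_new
                st = st_new
                streak += 1
                if streak >= grow_interval:
                    eps = min(eps * 2.0, 1.0)
                    streak = 0
                if delta < tol:
                    converged = True
                    break
            else:
                eps *= 0.5
                streak = 0
                if eps < min_update_rate:
                    raise ConvergenceError(
                        "likelihood cannot be decreased; update rate floor reached"
                    )

        st = eng.state(lam, b, gamma)
        kbt = KB_KJ_MOL * self.temperature
        weights = EnsembleWeights(st["omega"])
        history = (
            pd.DataFrame(
                hist,
                columns=[
                    "iteration", "likelihood", "wapp_kt", "msd",
                    "beta_c", "beta_h", "max_dlambda", "accepted", "eps",
                ],
            )
            if keep_history
            else None
        )
        return ReweightingResults(
            residues=eng.residues.copy(),
            lambdas=lam,
            params=params,
            gamma=float(gamma),
            eta=self.eta,
            temperature=self.temperature,
            weights=weights,
            lnp=ProtectionFactors(eng.residues.copy(), st["lnp"].copy()),
            d_sim=DeuterationSeries(
                self.target.segments, eng.times, st["d_sim"].copy()
            ),
            w_app=kbt * st["wapp_kt"],
            w_app_kl=apparent_work_kl(weights, self.temperature),
            msd=st["msd"],
            likelihood=st["likelihood"],
            n_iter=it,
            converged=converged,
            update_rate=eps,
            history=history,
        )

    def gamma_scan(self, gammas, **fit_kwargs) -> DecisionCurve:
        """Fit at each gamma (strictly increasing), warm-starting lambda and
        beta from the previous point; unconverged points are flagged, not
        fatal."""
        gammas = np.asarray(gammas, dtype=float)
        if gammas.size < 2:
            raise InputError("need at least 2 gamma values")
        if np.any(np.diff(gammas) <= 0):
            raise InputError("gamma values must be strictly increasing")
        fit_kwargs.setdefault("keep_history", False)
        lam = None
        params = None
        w_app, msd, conv, plist, rlist = [], [], [], [], []
        for g in gammas:
            try:
                res = self.fit(g, lambdas0=lam, params0=params, **fit_kwargs)
                lam = res.lambdas
                params = res.params
                w_app.append(res.w_app)
                msd.append(res.msd)
                conv.append(res.converged)
                plist.append(res.params)
                rlist.append(res)
            except ConvergenceError:
                w_app.append(np.nan)
                msd.append(np.nan)
                conv.append(False)
                plist.append(params or self.params0)
                rlist.append(None)
        return DecisionCurve(
            gammas=gammas,
            w_app=np.array(w_app),
            msd=np.array(msd),
            converged=np.array(conv, dtype=bool),
            params=plist,
            results=rlist,
        )


# --------------------------------------------------------------------------
# functional wrappers


def lambda_step(
    lambdas,
    features,
    target: DeuterationSeries,
    rates: IntrinsicRates,
    params: ForwardModelParams,
    gamma: float,
    eta: float = 1.0,
    update_rate: float = 0.01,
    literal_denominator: bool = False,
) -> np.ndarray:
    """One damped fixed-point update of the lambda vector."""
    eng = _Engine(features, target, rates, eta, literal_denominator)
    lam = np.asarray(lambdas, dtype=float)
    st = eng.state(lam, eng.b_matrix(params), gamma)
    if not np.all(np.isfinite(st["grad"])):
        bad = eng.residues[~np.isfinite(st["grad"])]
        raise ConvergenceError(f"non-finite gradient at residues {bad}")
    return lam * (1.0 - update_rate) + update_rate * st["grad"]


def mc_optimize_betas(
    lambdas,
    features,
    target: DeuterationSeries,
    rates: IntrinsicRates,
    params: ForwardModelParams,
    n_trials: int = 100,
    seed: int | None = None,
    eta: float = 1.0,
    joint_proposals: bool = True,
    literal_denominator: bool = False,
) -> ForwardModelParams:
    """Greedy Monte Carlo refinement of (beta_C, beta_H) at fixed lambda."""
    eng = _Engine(features, target, rates, eta, literal_denominator)
    best, _ = _mc_betas(
        eng,
        np.asarray(lambdas, dtype=float),
        params,
        np.random.default_rng(seed),
        n_trials,
        joint_proposals,
    )
    return best


def run_reweighting(
    features, target, rates, gamma, **options
) -> ReweightingResults:
    """Build a :class:`MaxEntReweighting` model and fit it at one gamma."""
    model_kw = {
        k: options.pop(k)
        for k in ("eta", "temperature", "params", "literal_denominator")
        if k in options
    }
    return MaxEntReweighting(features, target, rates, **model_kw).fit(
        gamma, **options
    )


def gamma_scan(features, target, rates, gammas, **options) -> DecisionCurve:
    """Decision-curve scan over gamma values (module-level convenience)."""
    model_kw = {
        k: options.pop(k)
        for k in ("eta", "temperature", "params", "literal_denominator")
        if k in options
    }
    return MaxEntReweighting(features, target, rates, **model_kw).gamma_scan(
        gammas, **options
    )
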