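"""Alchemical solvation free energies: softcore decoupling, MBAR, bootstrap.

The decoupling pathway scales only solute-solvent Lennard-Jones interactions
(solute charges are switched off in the toy workflow, a documented
limitation appropriate for the neutral toy solutes). A coupling variable
``lambda`` runs from 0 (solute decoupled, gas-like) to 1 (fully coupled),
so ``dG_solv = G(coupled) - G(decoupled)`` is negative for favourable
solvation.

Softcore form ("1-1-48", finite at r = 0 for lambda < 1)::

    u(r; lam) = lam * 4 eps * (A^(12/n) - A^(6/n)),
    A = sigma^n / (alpha * sigma^n * (1 - lam) + r^n),   n = 48

with lambda-power 1, (1-lambda)-power 1 and distance-power n = 48; default
alpha = 0.003. At lam = 1 this is exactly the plain LJ potential; at lam = 0
it vanishes identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import R_GAS
from .forcefield import ParameterSet, SystemSpec
from .toysim import (
    MCEngine,
    SimSettings,
    TrajectoryStats,
    _minimum_image,
    build_particle_system,
    effective_r_cut,
)

__all__ = [
    "LambdaSchedule",
    "SoftcoreSpec",
    "ReducedPotentialMatrix",
    "FreeEnergyResult",
    "softcore_lj",
    "sample_alchemical",
    "mbar_estimate",
    "bootstrap_dG",
    "redistribute_lambdas",
    "solvation_free_energy",
]

#: consecutive-state overlap below this triggers a warning
MIN_OVERLAP = 0.03


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class LambdaSchedule:
    """Strictly increasing coupling values from exactly 0 to exactly 1."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.values
        if len(v) < 2:
            raise ValueError("schedule needs at least 2 lambda states")
        if v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("schedule endpoints must be exactly 0 and 1")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def uniform(cls, k: int) -> "LambdaSchedule":
        return cls(tuple(np.linspace(0.0, 1.0, k)))


@dataclass(frozen=True)
class SoftcoreSpec:
    """Softcore shape parameters (defaults: the 1-1-48 form, alpha = 0.003)."""

    alpha: float = 0.003
    lambda_power: int = 1
    one_minus_lambda_power: int = 1
    distance_power: int = 48

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        for p in (self.lambda_power, self.one_minus_lambda_power, self.distance_power):
            if not (isinstance(p, int) and p > 0):
                raise ValueError("softcore powers must be positive integers")


@dataclass
class ReducedPotentialMatrix:
    """Samples from K states evaluated at all K states (dimensionless beta*U)."""

    u_kn: np.ndarray  # (K, N_total)
    n_k: np.ndarray  # (K,)
    temperature: float = 298.15
    schedule: LambdaSchedule | None = None

    def __post_init__(self) -> None:
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u_kn.shape[1] != int(self.n_k.sum()):
            raise ValueError("sum of n_k must equal the number of columns")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("u_kn must be finite")

    def save(self, data_path, meta_path) -> None:
        """Delimited-text matrix plus a JSON sidecar (n_k, schedule, T)."""
        import json

        np.savetxt(data_path, self.u_kn, fmt="%.10g", delimiter="\t")
        meta = {
            "n_k": self.n_k.tolist(),
            "temperature": self.temperature,
            "schedule": list(self.schedule.values) if self.schedule else None,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, data_path, meta_path) -> "ReducedPotentialMatrix":
        import json

        with open(meta_path) as fh:
            meta = json.load(fh)
        u_kn = np.atleast_2d(np.loadtxt(data_path, delimiter="\t"))
        sched = (
            LambdaSchedule(tuple(meta["schedule"])) if meta.get("schedule") else None
        )
        return cls(u_kn, np.asarray(meta["n_k"]), meta["temperature"], sched)


@dataclass
class FreeEnergyResult:
    """End-to-end dG with per-interval breakdown and overlap diagnostics."""

    dG: float
    uncertainty: float
    per_interval: list[tuple[float, float]]
    overlap: np.ndarray
    low_overlap: bool = False
    free_energies: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# softcore potential
# ---------------------------------------------------------------------------


def softcore_lj(epsilon, sigma, r, lam: float, spec: SoftcoreSpec = SoftcoreSpec()):
    """Softcore-decoupled LJ energy (kJ/mol); scalar or array arguments.

    ``lam = 1`` reproduces :func:`ljfit.forcefield.lj_energy` exactly;
    ``lam = 0`` returns 0; for ``lam < 1`` the energy is finite at ``r = 0``
    (provided ``alpha > 0``).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    eps = np.asarray(epsilon, dtype=float)
    sig = np.asarray(sigma, dtype=float)
    r_arr = np.asarray(r, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigma must be > 0")
    if np.any(r_arr < 0):
        raise ValueError("r must be >= 0")
    if lam == 1.0:  # exact endpoint identity with the plain LJ potential
        sr6 = (sig / r_arr) ** 6
        out = 4.0 * eps * (sr6 * sr6 - sr6)
        return float(out) if out.ndim == 0 else out
    n = spec.distance_power
    # A = 1 / (alpha (1-lam)^b + (r/sigma)^n); computed via the scaled distance
    t = (r_arr / sig) ** n
    denom = spec.alpha * (1.0 - lam) ** spec.one_minus_lambda_power + t
    with np.errstate(divide="ignore"):
        a = np.where(denom > 0, 1.0 / np.maximum(denom, 1e-300), np.inf)
    u = (
        lam**spec.lambda_power
        * 4.0
        * eps
        * (a ** (12.0 / n) - a ** (6.0 / n))
    )
    out = np.where(lam == 0.0, 0.0, u)
    return float(out) if out.ndim == 0 else out


def _softcore_r2_fn(lam: float, spec: SoftcoreSpec):
    """Vectorized (eps, sig, r2) -> energy callback for the MC engine."""
    if lam == 0.0:
        return lambda eps, sig, r2: np.zeros_like(np.asarray(eps, dtype=float))
    if lam == 1.0:

        def plain(eps, sig, r2):
            sr6 = (np.asarray(sig, dtype=float) ** 2 / np.asarray(r2, dtype=float)) ** 3
            return 4.0 * np.asarray(eps, dtype=float) * (sr6 * sr6 - sr6)

        return plain

    def fn(eps, sig, r2):
        n = spec.distance_power
        t = (np.asarray(r2, dtype=float) / np.asarray(sig) ** 2) ** (n / 2.0)
        denom = spec.alpha * (1.0 - lam) ** spec.one_minus_lambda_power + t
        a = 1.0 / np.maximum(denom, 1e-300)
        return (
            lam**spec.lambda_power
            * 4.0
            * np.asarray(eps, dtype=float)
            * (a ** (12.0 / n) - a ** (6.0 / n))
        )

    return fn


# ---------------------------------------------------------------------------
# alchemical sampling
# ---------------------------------------------------------------------------


def solute_coupling_energy(
    positions: np.ndarray,
    box_edge: float,
    psys,
    lam: float,
    spec: SoftcoreSpec,
    r_cut: float,
) -> float:
    """Solute-solvent softcore energy of one configuration (kJ/mol)."""
    if psys.solute_mol is None:
        raise ValueError("system has no solute")
    sl = psys.mol_slices[psys.solute_mol]
    solv_mask = psys.site_mol != psys.solute_mol
    pos_solv = positions[solv_mask]
    types_solv = psys.site_type[solv_mask]
    rc = effective_r_cut(r_cut, box_edge)
    fn = _softcore_r2_fn(lam, spec)
    total = 0.0
    for k in range(sl.start, sl.stop):
        delta = _minimum_image(pos_solv - positions[k], box_edge)
        r2 = np.einsum("ij,ij->i", delta, delta)
        mask = r2 < rc * rc
        if not np.any(mask):
            continue
        eps = psys.eps_table[psys.site_type[k], types_solv[mask]]
        sig = psys.sig_table[psys.site_type[k], types_solv[mask]]
        total += float(np.sum(fn(eps, sig, r2[mask])))
    return total


def sample_alchemical(
    system: SystemSpec,
    params: ParameterSet,
    schedule: LambdaSchedule,
    settings: SimSettings,
    softcore: SoftcoreSpec = SoftcoreSpec(),
) -> ReducedPotentialMatrix:
    """Run one MC simulation per lambda state and cross-evaluate all samples.

    Only the solute-solvent LJ interaction is scaled (softcore); solute
    charges are off. Each state uses a seed derived from ``settings.seed``,
    so a fixed seed yields a bit-identical matrix.
    """
    if len(schedule) < 2:
        raise ValueError("schedule must contain at least 2 states")
    if system.solute is None:
        raise ValueError("alchemical sampling requires a solute")
    if system.box_edge is None:
        raise ValueError("solvation systems must specify box_edge")
    temperature = (
        settings.temperature if settings.temperature is not None else system.temperature
    )
    beta = 1.0 / (R_GAS * temperature)
    k_states = len(schedule)
    all_configs: list[tuple[np.ndarray, float]] = []
    n_k = []
    psys_template = build_particle_system(system, params)
    for k, lam in enumerate(schedule.values):
        rng = np.random.default_rng(np.random.SeedSequence((settings.seed, k)))
        engine = MCEngine(
            build_particle_system(system, params),
            system.box_edge,
            settings,
            rng,
            npt=False,
            solute_pair_fn=_softcore_r2_fn(lam, softcore),
            solute_charge_scale=0.0,
        )
        stats = engine.run()
        for cfg in stats.configurations:
            all_configs.append((cfg.positions, cfg.box_edge))
        n_k.append(len(stats.configurations))

    u_kn = np.empty((k_states, sum(n_k)))
    for j, lam in enumerate(schedule.values):
        for n, (pos, box) in enumerate(all_configs):
            u_kn[j, n] = beta * solute_coupling_energy(
                pos, box, psys_template, lam, softcore, settings.r_cut
            )
    return ReducedPotentialMatrix(u_kn, np.asarray(n_k), temperature, schedule)


def statistical_inefficiency(series) -> float:
    """Integrated-autocorrelation statistical inefficiency g >= 1.

    Standard estimator: g = 1 + 2 sum_t C(t) (1 - t/n), truncated at the
    first non-positive autocorrelation.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        return 1.0
    dx = x - x.mean()
    var = float(np.dot(dx, dx)) / n
    if var <= 0.0:
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = float(np.dot(dx[: n - t], dx[t:])) / ((n - t) * var)
        if c <= 0.0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(1.0, g)


def subsample_matrix(mat: ReducedPotentialMatrix) -> ReducedPotentialMatrix:
    """Decorrelate each state's samples by its statistical inefficiency.

    The inefficiency for state k is measured on the coupling-energy series of
    a neighbouring state's reduced potential evaluated on state k's samples
    (the state's own diagonal row can be constant, e.g. at lambda = 0).
    """
    k_states = mat.u_kn.shape[0]
    starts = np.concatenate([[0], np.cumsum(mat.n_k)])
    keep_cols = []
    new_n_k = []
    for k in range(k_states):
        cols = np.arange(starts[k], starts[k + 1])
        probe = k + 1 if k + 1 < k_states else k - 1
        g = statistical_inefficiency(mat.u_kn[probe, cols])
        stride = max(1, int(math.ceil(g)))
        sel = cols[::stride]
        keep_cols.append(sel)
        new_n_k.append(len(sel))
    keep = np.concatenate(keep_cols)
    return ReducedPotentialMatrix(
        mat.u_kn[:, keep], np.asarray(new_n_k), mat.temperature, mat.schedule
    )


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------


def _mbar_weights(u_kn: np.ndarray, n_k: np.ndarray, f_k: np.ndarray) -> np.ndarray:
    """Log-weights matrix; W_nk = exp(f_k - u_kn) / sum_l N_l exp(f_l - u_ln)."""
    log_denom = logsumexp(
        (f_k - u_kn.T), b=n_k[np.newaxis, :].astype(float), axis=1
    )  # (N,)
    return np.exp(f_k[np.newaxis, :] - u_kn.T - log_denom[:, np.newaxis])


def mbar_estimate(
    u_kn: np.ndarray | ReducedPotentialMatrix,
    n_k: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 50000,
    temperature: float = 298.15,
) -> FreeEnergyResult:
    """Solve the MBAR self-consistency equations for K states.

    Dimensionless free energies are anchored at state 0; the result converts
    to kJ/mol via RT. Uses self-consistent iteration with a Newton switch on
    the convex log-likelihood. Raises :class:`ConvergenceError` if the
    increment does not fall below ``tol`` within ``max_iter`` iterations.
    """
    if isinstance(u_kn, ReducedPotentialMatrix):
        mat = u_kn
        u_kn, n_k, temperature = mat.u_kn, mat.n_k, mat.temperature
    u_kn = np.asarray(u_kn, dtype=float)
    n_k = np.asarray(n_k, dtype=float)
    k_states, n_total = u_kn.shape
    if k_states < 2:
        raise ValueError("need at least 2 states")
    if int(n_k.sum()) != n_total:
        raise ValueError("sum of n_k must equal number of samples")

    f_k = np.zeros(k_states)
    residual = np.inf
    for it in range(max_iter):
        # self-consistent update: f_k = -ln sum_n exp(-u_kn) / denom_n
        log_denom = logsumexp((f_k - u_kn.T), b=n_k[None, :], axis=1)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f_k)))
        f_k = f_new
        if residual < tol:
            break
        if it > 20 and residual < 1e-2:
            # Newton refinement on f[1:] (state 0 anchored)
            for _ in range(50):
                w = _mbar_weights(u_kn, n_k, f_k)  # (N, K)
                g = n_k * (w.sum(axis=0) - 1.0)  # gradient * N
                wn = w * n_k[None, :]
                h = np.diag(n_k * w.sum(axis=0)) - wn.T @ wn
                try:
                    step = np.linalg.solve(h[1:, 1:], g[1:])
                except np.linalg.LinAlgError:
                    break
                f_try = f_k.copy()
                f_try[1:] -= step
                f_try -= f_try[0]
                residual = float(np.max(np.abs(f_try - f_k)))
                f_k = f_try
                if residual < tol:
                    break
            if residual < tol:
                break
    if residual >= tol:
        raise ConvergenceError("MBAR did not converge", residual)

    w = _mbar_weights(u_kn, n_k, f_k)  # (N, K)
    theta = _asymptotic_covariance(w, n_k)
    rt = R_GAS * temperature
    dg = (f_k[-1] - f_k[0]) * rt
    var_end = theta[-1, -1] + theta[0, 0] - 2.0 * theta[-1, 0]
    per_interval = []
    for k in range(k_states - 1):
        ddg = (f_k[k + 1] - f_k[k]) * rt
        var = theta[k + 1, k + 1] + theta[k, k] - 2.0 * theta[k + 1, k]
        per_interval.append((ddg, rt * math.sqrt(max(var, 0.0))))
    overlap = w.T @ (w * n_k[None, :])
    low = bool(
        np.min([overlap[k, k + 1] for k in range(k_states - 1)]) < MIN_OVERLAP
    )
    if low:
        warnings.warn(
            "consecutive-state configurational overlap below "
            f"{MIN_OVERLAP}; free energy estimate may be unreliable",
            stacklevel=2,
        )
    return FreeEnergyResult(
        dG=dg,
        uncertainty=rt * math.sqrt(max(var_end, 0.0)),
        per_interval=per_interval,
        overlap=overlap,
        low_overlap=low,
        free_energies=f_k.copy(),
        extras={"iterations": it + 1, "residual": residual},
    )


def _asymptotic_covariance(w: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the dimensionless free energies.

    Theta = V S (I - S V^T N V S)^+ S V^T with W = U S V^T (economy SVD)
    and N = diag(n_k); covariance differences give the dG uncertainties.
    """
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    v = vt.T
    inner = np.eye(len(s)) - (s[:, None] * vt) @ (n_k[:, None] * v) * s[None, :]
    theta = v @ (s[:, None] * np.linalg.pinv(inner, rcond=1e-12) * s[None, :]) @ vt
    return theta


def bootstrap_dG(
    u_kn: np.ndarray | ReducedPotentialMatrix,
    n_k: np.ndarray | None = None,
    n_boot: int = 50,
    seed: int = 0,
    temperature: float = 298.15,
) -> float:
    """Bootstrap standard deviation of the end-to-end dG (kJ/mol).

    Configurations are resampled with replacement within each state; the
    MBAR estimate is recomputed per replicate.
    """
    if isinstance(u_kn, ReducedPotentialMatrix):
        mat = u_kn
        u_kn, n_k, temperature = mat.u_kn, mat.n_k, mat.temperature
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    u_kn = np.asarray(u_kn, dtype=float)
    n_k = np.asarray(n_k, dtype=int)
    starts = np.concatenate([[0], np.cumsum(n_k)])
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        cols = np.concatenate(
            [
                starts[k] + rng.integers(0, n_k[k], size=n_k[k])
                for k in range(len(n_k))
            ]
        )
        res = mbar_estimate(
            u_kn[:, cols], n_k, tol=1e-8, temperature=temperature
        )
        estimates[b] = res.dG
    return float(np.std(estimates, ddof=1))


# ---------------------------------------------------------------------------
# lambda redistribution
# ---------------------------------------------------------------------------


def redistribute_lambdas(
    schedule: LambdaSchedule, per_interval_uncertainties
) -> LambdaSchedule:
    """Move interior lambda values toward equal per-interval uncertainties.

    The cumulative uncertainty profile over the current schedule is treated
    as piecewise linear in lambda and inverted at equally spaced quantiles.
    Endpoints stay exactly 0 and 1; equal uncertainties are a fixed point.
    """
    delta = np.asarray(per_interval_uncertainties, dtype=float)
    if len(delta) != len(schedule) - 1:
        raise ValueError("need one uncertainty per interval")
    if np.any(delta <= 0):
        raise ValueError("uncertainties must be positive")
    cum = np.concatenate([[0.0], np.cumsum(delta)])
    targets = np.linspace(0.0, cum[-1], len(schedule))
    new = np.interp(targets, cum, schedule.values)
    new[0], new[-1] = 0.0, 1.0
    # guard against numerically coincident interior points
    for i in range(1, len(new)):
        if new[i] <= new[i - 1]:
            new[i] = new[i - 1] + 1e-9
    new[-1] = 1.0
    return LambdaSchedule(tuple(new))


def solvation_free_energy(
    system: SystemSpec,
    params: ParameterSet,
    schedule: LambdaSchedule,
    settings: SimSettings,
    n_trial_rounds: int = 3,
    softcore: SoftcoreSpec = SoftcoreSpec(),
    trial_fraction: float = 0.25,
    bootstrap: int = 0,
    decorrelate: bool = True,
) -> FreeEnergyResult:
    """Full alchemical workflow: trial rounds, redistribution, production, MBAR.

    Sign convention: ``dG_solv = G(coupled) - G(decoupled)``, negative for
    favourable solvation. With ``decorrelate`` (default) the production
    samples are subsampled by their statistical inefficiency before
    estimation, so the reported uncertainty accounts for MC correlation.
    With ``bootstrap > 0``, a bootstrap standard deviation is stored in
    ``extras["bootstrap_sd"]``.
    """
    from dataclasses import replace as dc_replace

    trial_steps = max(
        int(settings.n_steps * trial_fraction), settings.equil_steps + 10
    )
    trial_settings = dc_replace(
        settings,
        n_steps=trial_steps,
        sample_interval=max(1, settings.sample_interval // 2),
    )
    current = schedule
    for round_idx in range(n_trial_rounds):
        mat = sample_alchemical(
            system, params, current,
            dc_replace(trial_settings, seed=trial_settings.seed + 1000 * (round_idx + 1)),
            softcore,
        )
        res = mbar_estimate(mat)
        current = redistribute_lambdas(
            current, [max(d, 1e-6) for _, d in res.per_interval]
        )
    mat = sample_alchemical(system, params, current, settings, softcore)
    if decorrelate:
        mat = subsample_matrix(mat)
    result = mbar_estimate(mat)
    result.extras["schedule"] = list(current.values)
    result.extras["n_k_used"] = mat.n_k.tolist()
    if bootstrap:
        result.extras["bootstrap_sd"] = bootstrap_dG(
            mat, n_boot=bootstrap, seed=settings.seed
        )
    return result
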