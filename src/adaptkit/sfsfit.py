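"""Simulation-based composite-likelihood fitting of two-deme demographies.

The observed folded joint SFS is compared with a Monte-Carlo expectation
computed from the package's own coalescent simulator (branch-area estimator,
recombination off: the expected SFS is recombination-invariant).  The
composite log-likelihood is multinomial over SFS cells with low-support
entries masked; optimization is multi-start Nelder-Mead on log-transformed
sizes/rates (linear times) with common random numbers across each
maximization cycle, the simulation count escalating over cycles.  Models are
compared by AIC and Akaike weights; uncertainties come from a parametric
bootstrap.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _kernels
from .coalescent import child_seed_sequence, flatten_demography
from .models import DemographicModel, Epoch, MigrationWindow
from .stats import JointSFS

__all__ = [
    "FitResult",
    "ModelComparison",
    "expected_sfs",
    "composite_log_likelihood",
    "sample_sfs",
    "set_param",
    "get_param",
    "fit_model",
    "compare_models",
    "bootstrap_ci",
    "years_from_generations",
]

_P_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Expected SFS
# ---------------------------------------------------------------------------

def expected_sfs(
    model: DemographicModel,
    sample_sizes,
    n_sims: int,
    seed: int,
    fold: bool = True,
) -> JointSFS:
    """Monte-Carlo expected joint SFS (normalized over segregating classes).

    Accumulates branch area per descendant-count cell over ``n_sims``
    genealogies; mutations are Poisson on branch area, so the normalized
    accumulation is the expected proportion of SNPs per cell.  Deterministic
    for a given seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    sizes = tuple(int(x) for x in np.atleast_1d(sample_sizes))
    if model.n_demes == 1 and len(sizes) == 2 and sizes[1] == 0:
        sizes = sizes[:1]  # 1-deme spectra are stored with a trivial second axis
    if len(sizes) != model.n_demes:
        raise ValueError("one sample size per deme is required")
    n0 = sizes[0]
    n1 = sizes[1] if model.n_demes == 2 else 0
    bk, N0, N1, m01, m10, merged = flatten_demography(model)
    raw = _kernels.sim_sfs_batch(int(n_sims), n0, n1, bk, N0, N1, m01, m10, merged,
                                 int(seed) % (2**31 - 1))
    sfs = JointSFS(raw, (n0, n1), folded=False,
                   mean_tree_length=float(raw.sum()) / n_sims)
    if fold:
        sfs = sfs.fold()
    return sfs.normalized()


def sample_sfs(expected: JointSFS, n_snps: int, seed: int) -> JointSFS:
    """Multinomial draw of an observed SFS from expected cell proportions."""
    rng = np.random.default_rng(seed)
    p = expected.counts.ravel()
    p = p / p.sum()
    counts = rng.multinomial(int(n_snps), p).reshape(expected.counts.shape)
    return JointSFS(counts.astype(float), expected.sample_sizes, folded=expected.folded)


# ---------------------------------------------------------------------------
# Composite likelihood
# ---------------------------------------------------------------------------

def composite_log_likelihood(
    obs: JointSFS,
    exp: JointSFS,
    min_support: int = 10,
    expected_total: float | None = None,
) -> float:
    """Multinomial composite log-likelihood over retained SFS cells.

    Cells with observed support below ``min_support`` SNPs (and the fixed
    corners) are masked; the expected proportions are renormalized over the
    retained cells and floored at a small positive constant.

    With ``expected_total`` (the model's expected SNP count for the data's
    sequence length) a Poisson term on the retained SNP count is added,
    which is what makes an overall population-size scaling identifiable from
    an otherwise scale-free spectrum shape.
    """
    if obs.counts.shape != exp.counts.shape or obs.folded != exp.folded:
        raise ValueError("observed and expected spectra must match in shape and folding")
    keep = (~obs.mask) & (~exp.mask) & (obs.counts >= min_support)
    if not np.any(keep):
        raise ValueError("all SFS cells are masked")
    p = np.maximum(exp.counts[keep], 0.0)
    tot_all = np.maximum(exp.counts[~exp.mask], 0.0).sum()
    tot = p.sum()
    frac_retained = tot / tot_all if tot_all > 0 else 0.0
    p = p / tot if tot > 0 else p
    p = np.maximum(p, _P_FLOOR)
    ll = float(np.sum(obs.counts[keep] * np.log(p)))
    if expected_total is not None:
        lam = max(expected_total * frac_retained, _P_FLOOR)
        s_obs = float(obs.counts[keep].sum())
        ll += s_obs * math.log(lam) - lam
    return ll


# ---------------------------------------------------------------------------
# Free-parameter addressing
# ---------------------------------------------------------------------------
# Parameters are addressed by name:
#   "divergence_time", "ancestral_size",
#   "size:<epoch>:<deme>", "epoch_time:<epoch>",
#   "mig:<window>:m01" / "mig:<window>:m10"

_LOG_SCALE_PREFIXES = ("ancestral_size", "size:", "mig:")


def _is_log_scale(name: str) -> bool:
    return name.startswith(_LOG_SCALE_PREFIXES)


def get_param(model: DemographicModel, name: str) -> float:
    if name == "divergence_time":
        return float(model.divergence_time)
    if name == "ancestral_size":
        return float(model.ancestral_size)
    parts = name.split(":")
    if parts[0] == "size":
        return float(model.epochs[int(parts[1])].deme_sizes[int(parts[2])])
    if parts[0] == "epoch_time":
        return float(model.epochs[int(parts[1])].start_time)
    if parts[0] == "mig":
        w = model.migration_windows[int(parts[1])]
        return float(w.m_01 if parts[2] == "m01" else w.m_10)
    raise KeyError(name)


def set_param(model: DemographicModel, name: str, value: float) -> DemographicModel:
    if name == "divergence_time":
        # migration windows are defined only up to the divergence event:
        # truncate (or drop) windows the new time no longer spans
        t = float(value)
        wins = []
        for w in model.migration_windows:
            if w.t_start >= t:
                continue
            wins.append(MigrationWindow(w.t_start, min(w.t_end, t), w.m_01, w.m_10))
        return model.with_params(divergence_time=t, migration_windows=tuple(wins))
    if name == "ancestral_size":
        return model.with_params(ancestral_size=float(value))
    parts = name.split(":")
    if parts[0] in ("size", "epoch_time"):
        i = int(parts[1])
        epochs = list(model.epochs)
        ep = epochs[i]
        if parts[0] == "size":
            sizes = list(ep.deme_sizes)
            sizes[int(parts[2])] = float(value)
            epochs[i] = Epoch(ep.start_time, tuple(sizes))
        else:
            epochs[i] = Epoch(float(value), ep.deme_sizes)
        return model.with_params(epochs=tuple(epochs))
    if parts[0] == "mig":
        i = int(parts[1])
        wins = list(model.migration_windows)
        w = wins[i]
        if parts[2] == "m01":
            wins[i] = MigrationWindow(w.t_start, w.t_end, float(value), w.m_10)
        else:
            wins[i] = MigrationWindow(w.t_start, w.t_end, w.m_01, float(value))
        return model.with_params(migration_windows=tuple(wins))
    raise KeyError(name)


def apply_params(model: DemographicModel, params: dict[str, float]) -> DemographicModel:
    for k, v in params.items():
        model = set_param(model, k, v)
    return model


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Best-of-runs composite-likelihood fit for one model."""

    model_name: str
    params: dict[str, float]
    loglik: float
    k: int
    fitted_model: DemographicModel
    run_trace: list[float] = field(default_factory=list)
    converged: bool = True
    generation_years: float = 1.0

    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik


def _to_internal(name: str, x: float) -> float:
    return math.log10(x) if _is_log_scale(name) else x


def _from_internal(name: str, z: float) -> float:
    return 10.0 ** z if _is_log_scale(name) else z


def fit_model(
    obs: JointSFS,
    template: DemographicModel,
    bounds: dict[str, tuple[float, float]],
    n_runs: int = 50,
    sims_schedule: tuple[int, int] = (100_000, 1_000_000),
    max_cycles: int = 40,
    seed: int = 0,
    min_support: int = 10,
    nm_iter_per_cycle: int = 3,
    sequence_length: float | None = None,
    final_sims: int | None = None,
) -> FitResult:
    """Multi-start simulated composite-likelihood maximization.

    Each run starts uniformly (in internal scale) within ``bounds`` and walks
    through ``max_cycles`` cycles of Nelder-Mead; within a cycle the
    Monte-Carlo seed is held fixed (common random numbers) and the simulation
    count per likelihood evaluation escalates geometrically from
    ``sims_schedule[0]`` to ``sims_schedule[1]`` across cycles.  Returns the
    best run; fully reproducible per seed.

    ``sequence_length`` switches on the Poisson total-SNP-count term of
    :func:`composite_log_likelihood` (needed when a pure size scaling is
    free, whose signature the normalized spectrum shape cannot see).

    ``final_sims`` rescores every run's end point on a dedicated seed with
    that many simulations before picking the best run.  Model comparison
    across separate fits needs this: the returned log-likelihoods are then
    evaluated on a common, low-noise Monte-Carlo sample instead of the last
    optimization cycle's, which an optimizer partially overfits.
    """
    if not bounds:
        raise ValueError("bounds must name at least one free parameter")
    names = list(bounds)
    lo = np.array([_to_internal(n, bounds[n][0]) for n in names])
    hi = np.array([_to_internal(n, bounds[n][1]) for n in names])
    if np.any(hi < lo):
        raise ValueError("invalid bounds")
    sizes = obs.sample_sizes
    n_min, n_max = sims_schedule
    if max_cycles > 1:
        ratio = (n_max / n_min) ** (1.0 / (max_cycles - 1))
        cycle_sims = [int(round(n_min * ratio**c)) for c in range(max_cycles)]
    else:
        cycle_sims = [int(n_max)]
    rng = np.random.default_rng(seed)
    cycle_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=max_cycles)]
    final_seed = int(rng.integers(0, 2**31 - 1))

    def objective(z, n_sims, sim_seed):
        zc = np.clip(z, lo, hi)
        params = {n: _from_internal(n, v) for n, v in zip(names, zc)}
        try:
            model = apply_params(template, params)
        except ValueError:
            return 1e18  # invalid geometry (e.g. window beyond divergence)
        exp = expected_sfs(model, sizes, n_sims, sim_seed, fold=obs.folded)
        expected_total = None
        if sequence_length is not None:
            expected_total = model.mutation_rate * sequence_length * exp.mean_tree_length
        penalty = 1e6 * float(np.sum((z - zc) ** 2))
        return -composite_log_likelihood(obs, exp, min_support, expected_total) + penalty

    best = None
    trace: list[float] = []
    improved_any = False
    for _ in range(n_runs):
        z = rng.uniform(lo, hi)
        f_first = None
        f_last = None
        for c in range(max_cycles):
            if np.all(hi == lo):
                z = lo.copy()
                f_last = objective(z, cycle_sims[c], cycle_seeds[c])
                break
            res = optimize.minimize(
                objective,
                z,
                args=(cycle_sims[c], cycle_seeds[c]),
                method="Nelder-Mead",
                options={"maxiter": nm_iter_per_cycle * len(names), "xatol": 1e-4,
                         "fatol": 1e-3, "adaptive": len(names) > 2},
            )
            z = np.clip(res.x, lo, hi)
            f_last = res.fun
            if f_first is None:
                f_first = f_last
        # score the run end point on a common sample (fresh seed if rescoring)
        if final_sims is not None:
            f_final = objective(z, final_sims, final_seed)
        else:
            f_final = objective(z, cycle_sims[-1], cycle_seeds[-1])
        trace.append(-f_final)
        if f_first is None or f_final < f_first:
            improved_any = True
        if best is None or f_final < best[0]:
            best = (f_final, z)

    z = best[1]
    params = {n: _from_internal(n, v) for n, v in zip(names, z)}
    return FitResult(
        model_name=template.name,
        params=params,
        loglik=-best[0],
        k=len(names),
        fitted_model=apply_params(template, params),
        run_trace=trace,
        converged=improved_any or bool(np.all(hi == lo)),
        generation_years=template.generation_years,
    )


@dataclass
class ModelComparison:
    """AIC table across fitted models."""

    model_names: list[str]
    aic: np.ndarray
    delta_aic: np.ndarray
    weights: np.ndarray

    def best(self) -> str:
        return self.model_names[int(np.argmin(self.aic))]


def compare_models(fits: list[FitResult]) -> ModelComparison:
    """AIC = 2k - 2*logL; Akaike weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2)."""
    if not fits:
        raise ValueError("need at least one fit")
    aic = np.array([f.aic() for f in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()
    return ModelComparison([f.model_name for f in fits], aic, delta, w)


def bootstrap_ci(
    best: FitResult,
    template: DemographicModel,
    bounds: dict[str, tuple[float, float]],
    sample_sizes,
    n_snps: int,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    n_runs: int = 2,
    sims_schedule: tuple[int, int] = (2_000, 10_000),
    max_cycles: int = 5,
    exp_sims: int = 50_000,
) -> dict:
    """Parametric-bootstrap percentile intervals for the free parameters.

    Simulates ``n_boot`` observed spectra (multinomial with ``n_snps`` SNPs)
    at the point estimate and refits each with a reduced run/cycle budget.
    Refit failures are counted and excluded from the interval.
    """
    point = apply_params(template, best.params)
    seeds = child_seed_sequence(seed, 2 * n_boot + 1)
    exp = expected_sfs(point, sample_sizes, exp_sims, seeds[-1])
    estimates = {k: [] for k in best.params}
    failures = 0
    for b in range(n_boot):
        obs_b = sample_sfs(exp, n_snps, seeds[b])
        try:
            fit_b = fit_model(obs_b, template, bounds, n_runs=n_runs,
                              sims_schedule=sims_schedule, max_cycles=max_cycles,
                              seed=seeds[n_boot + b])
        except ValueError:
            failures += 1
            continue
        for k, v in fit_b.params.items():
            estimates[k].append(v)
    alpha = (1 - level) / 2
    intervals = {}
    for k, vals in estimates.items():
        arr = np.asarray(vals)
        intervals[k] = (float(np.quantile(arr, alpha)), float(np.quantile(arr, 1 - alpha)))
    return {"intervals": intervals, "failures": failures, "estimates": estimates}


def years_from_generations(fit: FitResult, g: float | None = None) -> dict[str, float]:
    """Calibrate time parameters to years (times scale by g; sizes/rates unchanged)."""
    g = fit.generation_years if g is None else g
    if g <= 0:
        raise ValueError("generation time must be positive")
    out = {}
    for name, value in fit.params.items():
        if name == "divergence_time" or name.startswith("epoch_time"):
            out[name] = value * g
        else:
            out[name] = value
    return out
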