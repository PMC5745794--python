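"""Reference desk-scale experiments: simulate-and-recover study designs.

These routines bundle the package's end-to-end validation experiments so
they can be run reproducibly from tests or scripts:

* simulate a folded joint SFS under the best-fit two-wave demographic model
  and re-estimate one parameter at a time by composite likelihood;
* simulate the F2 flowering-time design and recover the two QTLs' variance
  explained and the genome-wide permutation LOD threshold;
* AIC model identification and sweep-scan false-positive-rate checks at
  reduced scale.

All randomness derives from a single seed per experiment.
"""

from __future__ import annotations

import numpy as np

from .coalescent import child_seed_sequence, simulate_panel
from .models import DemographicModel, reference_models
from .qtl import (QtlModel, arabidopsis_style_map, interval_mapping,
                  permutation_threshold, simulate_f2, variance_explained)
from .sfsfit import compare_models, expected_sfs, fit_model, sample_sfs
from .sweep import calibrate_cutoff, clr_scan, folded_background
from .stats import JointSFS

__all__ = [
    "M4_TRUTH",
    "demographic_recovery",
    "qtl_pve_recovery",
    "lod_threshold_experiment",
    "aic_model_identification",
    "sweep_fpr_experiment",
    "study_qtl_truth",
]

#: published best-fit parameter vector of the two-wave model, by the
#: package's free-parameter names
M4_TRUTH = {
    "divergence_time": 61_409.0,
    "ancestral_size": 179_724.0,
    "size:2:0": 78_454.0,   # popY size after divergence
    "size:0:0": 45_089.0,   # popY size in the most recent epoch
}

_BOUNDS = {
    "divergence_time": (10_000.0, 200_000.0),
    "ancestral_size": (20_000.0, 1_000_000.0),
    "size:2:0": (5_000.0, 500_000.0),
    "size:0:0": (5_000.0, 500_000.0),
}


def demographic_recovery(
    free_params=("divergence_time", "ancestral_size", "size:2:0", "size:0:0"),
    n_seeds: int = 5,
    seed: int = 1,
    n_snps: int = 200_000,
    sample_sizes: tuple[int, int] = (86, 25),
    truth_sims: int = 60_000,
    n_runs: int = 3,
    sims_schedule: tuple[int, int] = (3_000, 15_000),
    max_cycles: int = 6,
) -> dict:
    """Simulate-and-refit experiment under the best-fit two-wave model.

    For each seed a folded joint SFS of ``n_snps`` SNPs is drawn from the
    model's expected spectrum at the published parameter vector; each free
    parameter is then re-estimated on that spectrum with the others held at
    truth.  Returns per-parameter estimates and medians.
    """
    m4 = reference_models()[3]
    seeds = child_seed_sequence(seed, 3 * n_seeds)
    estimates: dict[str, list[float]] = {p: [] for p in free_params}
    for i in range(n_seeds):
        exp_truth = expected_sfs(m4, sample_sizes, truth_sims, seed=seeds[3 * i])
        obs = sample_sfs(exp_truth, n_snps, seed=seeds[3 * i + 1])
        for param in free_params:
            fit = fit_model(
                obs, m4, {param: _BOUNDS[param]},
                n_runs=n_runs, sims_schedule=sims_schedule, max_cycles=max_cycles,
                seed=seeds[3 * i + 2],
            )
            estimates[param].append(float(fit.params[param]))
    return {
        "truth": {p: M4_TRUTH[p] for p in free_params},
        "estimates": estimates,
        "medians": {p: float(np.median(v)) for p, v in estimates.items()},
    }


def study_qtl_truth() -> tuple:
    """Study-design truth: map, QTL model, and the true drop-one PVEs.

    Two additive QTLs (chromosomes 2 and 5, at genotyped markers) with
    effects set so (i) the two homozygous parents flower at 50.33 and 24.87
    days and (ii) the drop-one variance fractions are 60.9% and 21.6% of the
    phenotypic variance, leaving 17.5% residual.
    """
    gmap = arabidopsis_style_map()
    # a2^2/2 : a5^2/2 : sd^2 = 0.609 : 0.216 : 0.175 and 2*(a2+a5) = 50.33-24.87
    a2, a5, sd = 7.978, 4.752, 3.024
    q2 = float(gmap.positions["chr2"][2])
    q5 = float(gmap.positions["chr5"][3])
    truth = QtlModel(qtls=(("chr2", q2, a2, 0.0), ("chr5", q5, a5, 0.0)),
                     residual_sd=sd, grand_mean=(50.33 + 24.87) / 2.0)
    v = a2**2 / 2 + a5**2 / 2 + sd**2
    true_pve = (100 * a2**2 / 2 / v, 100 * a5**2 / 2 / v)
    return gmap, truth, true_pve


def qtl_pve_recovery(n_seeds: int = 25, n: int = 86, seed: int = 1) -> dict:
    """Recover per-QTL variance explained on the study-scale F2 design.

    Each replicate simulates 86 F2 plants, locates the per-chromosome LOD
    peaks, and partitions variance by drop-one fits at the estimated peaks.
    """
    gmap, truth, true_pve = study_qtl_truth()
    seeds = child_seed_sequence(seed, n_seeds)
    pve2, pve5 = [], []
    for s in seeds:
        cross = simulate_f2(n, gmap, truth, seed=s)
        curve = interval_mapping(cross)
        peaks = curve.loc[curve.groupby("chrom")["lod"].idxmax()].set_index("chrom")
        est = variance_explained(
            cross, [("chr2", float(peaks.loc["chr2", "cM"])),
                    ("chr5", float(peaks.loc["chr5", "cM"]))])
        pve2.append(est["per_qtl_pve"][0])
        pve5.append(est["per_qtl_pve"][1])
    return {
        "true_pve": true_pve,
        "median_pve": (float(np.median(pve2)), float(np.median(pve5))),
        "estimates": (pve2, pve5),
    }


def lod_threshold_experiment(seed: int = 1, n: int = 86, n_perm: int = 1000,
                             alpha: float = 0.05) -> float:
    """Genome-wide 5% permutation LOD threshold on the study F2 design."""
    gmap, truth, _ = study_qtl_truth()
    s1, s2 = child_seed_sequence(seed, 2)
    cross = simulate_f2(n, gmap, truth, seed=s1)
    return permutation_threshold(cross, n_perm=n_perm, alpha=alpha, seed=s2)


def aic_model_identification(
    n_reps: int = 20,
    seed: int = 1,
    sample_sizes: tuple[int, int] = (10, 6),
    n_snps: int = 30_000,
) -> dict:
    """Reduced-scale AIC model choice between isolation and gene flow.

    Data are simulated under a divergence model with strong continuous gene
    flow; both an isolation model (divergence time free, k=1) and the
    gene-flow model (divergence time and symmetric rate free, k=2) are
    fitted, and AIC/Akaike weights pick a winner.  Reports how often the
    generating (gene-flow) model is identified.
    """
    from .models import Epoch, MigrationWindow

    t_div = 20_000.0
    common = dict(n_demes=2, epochs=(Epoch(0.0, (20_000.0, 20_000.0)),),
                  divergence_time=t_div, ancestral_size=20_000.0)
    m_iso = DemographicModel(name="isolation", **common)
    m_mig_truth = DemographicModel(
        name="migration",
        migration_windows=(MigrationWindow(0.0, t_div, 2e-4, 2e-4),),
        **common,
    )
    # candidate gene-flow template starts away from the generating rate
    m_mig_fit = m_mig_truth.with_params(
        migration_windows=(MigrationWindow(0.0, t_div, 1e-5, 1e-5),))
    seeds = child_seed_sequence(seed, 3 * n_reps)
    correct = 0
    weight_sums = []
    for i in range(n_reps):
        exp = expected_sfs(m_mig_truth, sample_sizes, 4_000, seed=seeds[3 * i])
        obs = sample_sfs(exp, n_snps, seed=seeds[3 * i + 1])
        fit_kwargs = dict(n_runs=1, sims_schedule=(1_000, 3_000), max_cycles=3,
                          seed=seeds[3 * i + 2], final_sims=40_000)
        fits = [
            fit_model(obs, m_iso, {"divergence_time": (2_000.0, 100_000.0)}, **fit_kwargs),
            fit_model(obs, m_mig_fit,
                      {"divergence_time": (2_000.0, 100_000.0),
                       "mig:0:m01": (1e-6, 1e-3),
                       "mig:0:m10": (1e-6, 1e-3)}, **fit_kwargs),
        ]
        cmp_ = compare_models(fits)
        weight_sums.append(float(cmp_.weights.sum()))
        if cmp_.best() == "migration":
            correct += 1
    return {"fraction_correct": correct / n_reps, "weight_sums": weight_sums}


def sweep_fpr_experiment(
    seed: int = 1,
    n_calibration: int = 40,
    n_evaluation: int = 40,
    fpr: float = 0.05,
    n_hap: int = 40,
    length: int = 50_000,
    grid: int = 10,
) -> dict:
    """Realized vs nominal CLR false-positive rate on neutral panels.

    The cutoff is calibrated on one set of neutral panels and evaluated on an
    independent set simulated under the same model with the same scan
    parameters.
    """
    from .models import Epoch

    model = DemographicModel(n_demes=1, epochs=(Epoch(0.0, (20_000.0,)),))
    seeds = child_seed_sequence(seed, n_calibration + n_evaluation + 1)
    panels = [simulate_panel(model, (n_hap,), length, s)
              for s in seeds[: n_calibration + n_evaluation]]
    pooled = np.concatenate([p.matrix.sum(axis=0) for p in panels])
    folded = np.bincount(np.minimum(pooled, n_hap - pooled), minlength=n_hap // 2 + 1)
    background = folded.astype(float)
    background[1:][background[1:] == 0] = 0.5
    scans = [clr_scan(p, background, n_grid=grid) for p in panels]
    cutoff = calibrate_cutoff(scans[:n_calibration], fpr)
    eval_values = np.concatenate([s.values for s in scans[n_calibration:]])
    realized = float(np.mean(eval_values > cutoff))
    return {"nominal": fpr, "realized": realized, "cutoff": cutoff,
            "n_eval_points": int(eval_values.size)}
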