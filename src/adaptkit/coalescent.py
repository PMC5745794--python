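"""Structured-coalescent simulation of two-population SNP haplotype panels.

The simulator is the engine behind both the simulation-based composite
likelihood (demographic fitting) and the neutral null datasets used to
calibrate sweep-scan cutoffs.  Without recombination a single genealogy is
drawn per panel (numba kernel); with recombination a Hudson-style ancestral
recombination graph is built so linkage disequilibrium decays with physical
distance.

Samples are haplotypes: highly selfing strains are treated as single haploid
genomes, so a deme of diploid effective size N coalesces pairs at rate
1/(2N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .arg import simulate_arg_mutations
from .models import DemographicModel

__all__ = ["HaplotypePanel", "flatten_demography", "simulate_panel", "simulate_null_set"]


@dataclass
class HaplotypePanel:
    """Phased binary haplotype-by-site matrix with physical positions.

    ``matrix`` is haplotypes x segregating sites with allele codes {0, 1};
    ``positions`` are 1-based bp, strictly increasing; ``pop_labels`` gives
    one population label per haplotype row.
    """

    matrix: np.ndarray
    positions: np.ndarray
    sequence_length: int
    pop_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[1] != self.positions.size:
            raise ValueError("one position per site is required")
        if self.matrix.shape[0] != len(self.pop_labels):
            raise ValueError("one population label per haplotype is required")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 1 or self.positions[-1] > self.sequence_length:
                raise ValueError("positions must lie in [1, sequence_length]")
            csum = self.matrix.sum(axis=0)
            if np.any(csum == 0) or np.any(csum == self.matrix.shape[0]):
                raise ValueError("every column must be polymorphic")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def deme_rows(self, label: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.pop_labels) if l == label])

    def subset(self, rows: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to haplotype ``rows``; monomorphic columns dropped."""
        sub = self.matrix[rows]
        csum = sub.sum(axis=0)
        keep = (csum > 0) & (csum < len(rows))
        return HaplotypePanel(
            sub[:, keep],
            self.positions[keep],
            self.sequence_length,
            [self.pop_labels[i] for i in rows],
        )


def flatten_demography(model: DemographicModel):
    """Piecewise-constant representation consumed by the numba kernels.

    Returns ``(bk, N0, N1, m01, m10, merged)`` where interval ``i`` covers
    ``[bk[i], bk[i+1])``.  The last breakpoint is effectively infinite.
    """
    cuts = {0.0}
    cuts.update(ep.start_time for ep in model.epochs)
    for w in model.migration_windows:
        cuts.add(w.t_start)
        cuts.add(w.t_end)
    if model.n_demes == 2:
        cuts.add(float(model.divergence_time))
    bk = np.array(sorted(cuts) + [1e300], dtype=np.float64)
    n_iv = len(bk) - 1
    N0 = np.empty(n_iv)
    N1 = np.ones(n_iv)
    m01 = np.zeros(n_iv)
    m10 = np.zeros(n_iv)
    merged = np.zeros(n_iv, dtype=np.int64)
    for i in range(n_iv):
        t = bk[i]
        if model.n_demes == 1:
            merged[i] = 1
            N0[i] = model.size_at(0, t)
            continue
        if t >= model.divergence_time:
            merged[i] = 1
            N0[i] = model.ancestral_size
            continue
        N0[i] = model.size_at(0, t)
        N1[i] = model.size_at(1, t)
        for w in model.migration_windows:
            if w.t_start <= t < w.t_end:
                m01[i] += w.m_01
                m10[i] += w.m_10
    return bk, N0, N1, m01, m10, merged


def _check_sample(model: DemographicModel, n_per_deme) -> tuple[int, int]:
    n_per_deme = tuple(int(x) for x in np.atleast_1d(n_per_deme))
    if len(n_per_deme) != model.n_demes:
        raise ValueError(
            f"model has {model.n_demes} deme(s) but {len(n_per_deme)} sample sizes given"
        )
    if any(x < 1 for x in n_per_deme):
        raise ValueError("need at least one haplotype per deme")
    return n_per_deme if model.n_demes == 2 else (n_per_deme[0], 0)


def _default_labels(n_demes: int) -> list[str]:
    return ["popY", "popN"][:n_demes]


def simulate_panel(
    model: DemographicModel,
    n_per_deme,
    length: int,
    seed: int,
    with_recombination: bool = False,
    pop_labels: list[str] | None = None,
) -> HaplotypePanel:
    """Draw one SNP haplotype panel under ``model``.

    Mutations are Poisson with rate ``mu * branch_length * length`` placed
    uniformly on an infinite-sites approximation (integer positions,
    collisions re-drawn).  With ``with_recombination`` a Hudson ancestral
    recombination graph is simulated at per-bp rate ``model.recombination_rate``.
    Identical seeds give identical panels.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    n0, n1 = _check_sample(model, n_per_deme)
    labels = pop_labels or _default_labels(model.n_demes)
    row_labels = [labels[0]] * n0 + ([labels[1]] * n1 if model.n_demes == 2 else [])
    rng = np.random.default_rng(seed)

    if with_recombination and model.recombination_rate > 0:
        muts = simulate_arg_mutations(model, n0, n1, length, rng)
        return _panel_from_mutations(muts, n0 + n1, length, row_labels)

    _kernels.seed_rng(int(rng.integers(0, 2**31 - 1)))
    bk, N0, N1, m01, m10, merged = flatten_demography(model)
    parent, node_time, jcnt, kcnt = _kernels.sim_tree(n0, n1, bk, N0, N1, m01, m10, merged)
    return _panel_from_tree(parent, node_time, n0 + n1, model.mutation_rate, length, rng, row_labels)


def _panel_from_tree(parent, node_time, n, mu, length, rng, row_labels) -> HaplotypePanel:
    n_nodes = 2 * n - 1
    blen = np.zeros(n_nodes)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    total = blen.sum()
    n_mut = rng.poisson(mu * total * length)
    n_mut = min(n_mut, length)  # infinite-sites cap at desk scale
    if n_mut == 0:
        return HaplotypePanel(np.zeros((n, 0), np.int8), np.array([], np.int64), length, row_labels)
    # descendant-leaf membership per node (children precede parents)
    desc = np.zeros((n_nodes, n), dtype=bool)
    desc[np.arange(n), np.arange(n)] = True
    for u in range(n_nodes - 1):
        desc[parent[u]] |= desc[u]
    branch = rng.choice(n_nodes, size=n_mut, p=blen / total)
    positions = rng.choice(length, size=n_mut, replace=False) + 1
    order = np.argsort(positions)
    positions = positions[order]
    branch = branch[order]
    matrix = desc[branch].T.astype(np.int8)
    return HaplotypePanel(matrix, positions, length, row_labels)


def _panel_from_mutations(muts, n, length, row_labels) -> HaplotypePanel:
    """Assemble a panel from (position, carrier-bitmask) pairs from the ARG."""
    if not muts:
        return HaplotypePanel(np.zeros((n, 0), np.int8), np.array([], np.int64), length, row_labels)
    muts.sort(key=lambda m: m[0])
    positions = np.array([m[0] for m in muts], dtype=np.int64)
    matrix = np.zeros((n, len(muts)), dtype=np.int8)
    for col, (_, mask) in enumerate(muts):
        for i in range(n):
            if mask >> i & 1:
                matrix[i, col] = 1
    return HaplotypePanel(matrix, positions, length, row_labels)


def simulate_null_set(
    model: DemographicModel,
    n_datasets: int,
    length: int,
    n_per_deme,
    seed: int,
    with_recombination: bool = False,
) -> list[HaplotypePanel]:
    """Independent neutral panels for sweep-cutoff calibration.

    Per-dataset seeds are derived deterministically from the master seed, so
    any replicate can be regenerated in isolation.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    child_seeds = child_seed_sequence(seed, n_datasets)
    return [
        simulate_panel(model, n_per_deme, length, s, with_recombination=with_recombination)
        for s in child_seeds
    ]


def child_seed_sequence(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate child seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]
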