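"""Windowed diversity statistics and site-frequency spectra.

Implements the sliding-window summaries used genome-wide (nucleotide
diversity pi, Watterson's theta, Hudson's FST in 200-kb windows stepped by
10 kb) and the joint folded site-frequency spectrum that feeds demographic
fitting and the sweep scan.  All statistics operate on
:class:`~adaptkit.coalescent.HaplotypePanel` objects; per-site allele counts
are complete-case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescent import HaplotypePanel

__all__ = [
    "WindowConfig",
    "JointSFS",
    "nucleotide_diversity",
    "watterson_theta",
    "hudson_fst",
    "joint_folded_sfs",
    "private_snp_counts",
    "snp_saturation",
    "harmonic_number",
]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry in bp (defaults mirror the study: 200 kb / 10 kb)."""

    window_size: int = 200_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.step < 1:
            raise ValueError("window_size and step must be >= 1")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")

    def windows(self, sequence_length: int) -> np.ndarray:
        """(start, end) pairs, 1-based inclusive, clipped to the sequence."""
        starts = np.arange(1, sequence_length + 1, self.step)
        ends = np.minimum(starts + self.window_size - 1, sequence_length)
        keep = starts <= sequence_length
        return np.column_stack([starts[keep], ends[keep]])


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1..k} 1/i, the Watterson denominator."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def _per_site_pi(matrix: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2p(1-p) * n/(n-1)."""
    n = matrix.shape[0]
    p = matrix.mean(axis=0)
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def _window_sum(values: np.ndarray, positions: np.ndarray, wins: np.ndarray) -> np.ndarray:
    out = np.empty(len(wins))
    for i, (s, e) in enumerate(wins):
        lo = np.searchsorted(positions, s, side="left")
        hi = np.searchsorted(positions, e, side="right")
        out[i] = values[lo:hi].sum()
    return out


def nucleotide_diversity(panel: HaplotypePanel, cfg: WindowConfig | None = None):
    """Per-site pi values and, if ``cfg`` is given, per-window pi per bp.

    Returns ``(per_site, windows_table)``; ``windows_table`` is an array of
    (start, end, pi) rows with pi divided by the full window length, or None
    when no window configuration is supplied.
    """
    if panel.n_haplotypes < 2:
        raise ValueError("pi requires at least 2 haplotypes")
    per_site = _per_site_pi(panel.matrix)
    if cfg is None:
        return per_site, None
    wins = cfg.windows(panel.sequence_length)
    sums = _window_sum(per_site, panel.positions, wins)
    lengths = wins[:, 1] - wins[:, 0] + 1
    return per_site, np.column_stack([wins, sums / lengths])


def watterson_theta(panel: HaplotypePanel, cfg: WindowConfig | None = None):
    """Watterson's theta per bp: S / (a_{n-1} * L), per window if ``cfg``."""
    n = panel.n_haplotypes
    if n < 2:
        raise ValueError("theta_W requires at least 2 haplotypes")
    a = harmonic_number(n - 1)
    if cfg is None:
        return panel.n_sites / (a * panel.sequence_length)
    wins = cfg.windows(panel.sequence_length)
    s = _window_sum(np.ones(panel.n_sites), panel.positions, wins)
    lengths = wins[:, 1] - wins[:, 0] + 1
    return np.column_stack([wins, s / (a * lengths)])


def hudson_fst(
    panel: HaplotypePanel,
    deme_labels: tuple[str, str] | None = None,
    cfg: WindowConfig | None = None,
):
    """Hudson's FST = 1 - mean(pi_within) / pi_between (ratio of averages).

    Within-deme diversity is the mean pairwise difference (unbiased, with
    the n/(n-1) correction), so the estimator is centred at 0 for unstructured
    data; at equal sample frequencies it returns -1/(n-1), vanishing with
    deme size.  With ``cfg`` returns (start, end, fst) rows; windows with
    zero between-deme diversity are flagged as NaN.  Without ``cfg`` returns
    the genome-wide value.
    """
    labels = sorted(set(panel.pop_labels)) if deme_labels is None else list(deme_labels)
    if len(set(labels)) != 2:
        raise ValueError("Hudson FST requires exactly two demes")
    ra = panel.deme_rows(labels[0])
    rb = panel.deme_rows(labels[1])
    if len(ra) < 2 or len(rb) < 2:
        raise ValueError("need >= 2 haplotypes per deme")
    pa = panel.matrix[ra].mean(axis=0)
    pb = panel.matrix[rb].mean(axis=0)
    na, nb = len(ra), len(rb)
    within = 0.5 * (2 * pa * (1 - pa) * na / (na - 1) + 2 * pb * (1 - pb) * nb / (nb - 1))
    between = pa * (1 - pb) + pb * (1 - pa)
    if cfg is None:
        tot_b = between.sum()
        return 1.0 - within.sum() / tot_b if tot_b > 0 else np.nan
    wins = cfg.windows(panel.sequence_length)
    w_sum = _window_sum(within, panel.positions, wins)
    b_sum = _window_sum(between, panel.positions, wins)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(b_sum > 0, 1.0 - w_sum / b_sum, np.nan)
    return np.column_stack([wins, fst])


@dataclass
class JointSFS:
    """Two-dimensional site-frequency spectrum over per-deme allele counts.

    ``counts[j, k]`` is the number (or expected proportion) of SNPs whose
    focal allele is carried by j deme-0 and k deme-1 haplotypes.  Folded
    spectra accumulate each configuration onto its minor orientation; the
    fixed corners (0,0) and (n0,n1) are structurally empty.  ``mask`` marks
    entries excluded from likelihood computation.
    """

    counts: np.ndarray
    sample_sizes: tuple[int, int]
    folded: bool = False
    mask: np.ndarray | None = None
    #: expected total tree length per genealogy (set by the simulator's
    #: expectation; lets a likelihood include the expected SNP count
    #: lambda = mu * L * mean_tree_length)
    mean_tree_length: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n0, n1 = self.sample_sizes
        if self.counts.shape != (n0 + 1, n1 + 1):
            raise ValueError("counts must have shape (n0+1, n1+1)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.mask is None:
            self.mask = np.zeros_like(self.counts, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        # fixed classes never carry information about segregating sites
        self.mask[0, 0] = True
        self.mask[n0, n1] = True

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def fold(self) -> "JointSFS":
        """Accumulate (j,k) and (n0-j, n1-k) onto the minor orientation."""
        if self.folded:
            return self
        n0, n1 = self.sample_sizes
        out = np.zeros_like(self.counts)
        for j in range(n0 + 1):
            for k in range(n1 + 1):
                jj, kk = _canonical_fold(j, k, n0, n1)
                out[jj, kk] += self.counts[j, k]
        return JointSFS(out, self.sample_sizes, folded=True,
                        mean_tree_length=self.mean_tree_length)

    def normalized(self) -> "JointSFS":
        tot = self.total
        if tot <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return JointSFS(self.counts / tot, self.sample_sizes, folded=self.folded,
                        mask=self.mask.copy(), mean_tree_length=self.mean_tree_length)

    def marginal(self, deme: int) -> np.ndarray:
        """Folded marginal minor-allele spectrum for one deme.

        Entry i (1 <= i <= n/2) counts SNPs with minor-allele count i in the
        deme's subsample, pooling over the other deme.
        """
        axis = 1 - deme
        marg = self.counts.sum(axis=axis)
        n = self.sample_sizes[deme]
        folded = np.zeros(n // 2 + 1)
        for j in range(n + 1):
            folded[min(j, n - j)] += marg[j]
        return folded

    # -- text round trip -------------------------------------------------

    def to_text(self, path) -> None:
        header = f"# n0={self.sample_sizes[0]} n1={self.sample_sizes[1]} folded={int(self.folded)}"
        np.savetxt(path, self.counts, header=header, comments="")

    @classmethod
    def from_text(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("#").split()
        kv = dict(item.split("=") for item in header)
        counts = np.loadtxt(path, skiprows=1)
        return cls(np.atleast_2d(counts), (int(kv["n0"]), int(kv["n1"])),
                   folded=bool(int(kv["folded"])))


def _canonical_fold(j: int, k: int, n0: int, n1: int) -> tuple[int, int]:
    t, tc = j + k, (n0 - j) + (n1 - k)
    if (t, j) <= (tc, n0 - j):
        return j, k
    return n0 - j, n1 - k


def joint_folded_sfs(
    panel: HaplotypePanel,
    deme_labels: tuple[str, str] | None = None,
    fold: bool = True,
) -> JointSFS:
    """Joint SFS of a two-deme panel (complete genotypes required)."""
    labels = sorted(set(panel.pop_labels)) if deme_labels is None else list(deme_labels)
    if len(labels) != 2:
        raise ValueError("joint SFS requires exactly two demes")
    ra = panel.deme_rows(labels[0])
    rb = panel.deme_rows(labels[1])
    n0, n1 = len(ra), len(rb)
    j = panel.matrix[ra].sum(axis=0)
    k = panel.matrix[rb].sum(axis=0)
    counts = np.zeros((n0 + 1, n1 + 1))
    np.add.at(counts, (j, k), 1)
    sfs = JointSFS(counts, (n0, n1), folded=False)
    return sfs.fold() if fold else sfs


def private_snp_counts(panel: HaplotypePanel, deme_labels: tuple[str, str] | None = None) -> dict:
    """Count SNPs whose (panel-wide) minor allele occurs in only one deme."""
    labels = sorted(set(panel.pop_labels)) if deme_labels is None else list(deme_labels)
    out = {l: 0 for l in labels}
    rows = {l: panel.deme_rows(l) for l in labels}
    n = panel.n_haplotypes
    tot = panel.matrix.sum(axis=0)
    minor_is_one = tot * 2 <= n  # ties counted as allele 1
    for s in range(panel.n_sites):
        allele = 1 if minor_is_one[s] else 0
        carriers = [l for l in labels if np.any(panel.matrix[rows[l], s] == allele)]
        if len(carriers) == 1:
            out[carriers[0]] += 1
    return out


def snp_saturation(
    panel: HaplotypePanel,
    subsample_sizes,
    replicates: int = 30,
    seed: int = 0,
):
    """SNP recovery curve under random subsampling of haplotypes.

    For each subsample size, draws ``replicates`` random haplotype subsets
    and counts the segregating sites they retain.  Returns an array of
    (size, mean, sd) rows.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_haplotypes
    rows = []
    for size in subsample_sizes:
        if size > n:
            raise ValueError("subsample size exceeds panel size")
        counts = []
        for _ in range(replicates):
            sub = rng.choice(n, size=size, replace=False)
            m = panel.matrix[sub]
            csum = m.sum(axis=0)
            counts.append(int(np.sum((csum > 0) & (csum < size))))
        rows.append((size, float(np.mean(counts)), float(np.std(counts, ddof=0))))
    return np.array(rows)
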