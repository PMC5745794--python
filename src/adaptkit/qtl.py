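"""F2 cross simulation and interval mapping of a quantitative trait.

An F2 population from two inbred parents segregates AA : AB : BB = 1 : 2 : 1
at every locus.  Gametes are simulated along a genetic map with the Haldane
map function (no interference); phenotypes are Gaussian around the sum of
per-QTL additive and dominance effects.  Mapping uses Haley-Knott
regression on conditional expected genotype scores at pseudo-markers, with
genome-wide significance from phenotype permutations, percent variance
explained (PVE) from the fitted model, a two-group haplotype association
test, and a nonsynonymous candidate-variant filter for fine-mapped
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GeneticMap",
    "F2Cross",
    "QtlModel",
    "arabidopsis_style_map",
    "simulate_f2",
    "interval_mapping",
    "permutation_threshold",
    "variance_explained",
    "haplotype_association",
    "candidate_filter",
    "haldane_c",
]

MISSING = -1


def haldane_c(d_cm: float) -> float:
    """Haldane map function: recombination fraction for ``d_cm`` centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


@dataclass
class GeneticMap:
    """Marker positions (cM) per chromosome, optionally with bp positions."""

    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    marker_names: dict[str, list[str]] = field(default_factory=dict)
    physical_positions: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            p = np.asarray(self.positions[chrom], dtype=float)
            if p.size < 1:
                raise ValueError("every chromosome needs at least one marker")
            if np.any(np.diff(p) < 0):
                raise ValueError("marker positions must be nondecreasing")
            self.positions[chrom] = p
            if chrom not in self.marker_names:
                self.marker_names[chrom] = [f"{chrom}_m{i}" for i in range(p.size)]

    @property
    def n_markers(self) -> int:
        return sum(len(self.positions[c]) for c in self.chromosomes)

    def marker_index(self) -> list[tuple[str, int]]:
        """Flat (chromosome, local index) per genotype-matrix column."""
        return [(c, i) for c in self.chromosomes for i in range(len(self.positions[c]))]


def arabidopsis_style_map(n_markers_per_chrom=(8, 5, 6, 5, 8),
                          chrom_lengths_cm=(136.0, 90.0, 105.0, 85.0, 122.0)) -> GeneticMap:
    """Five-chromosome map with 32 evenly spaced markers (study-like design)."""
    chroms = [f"chr{i+1}" for i in range(len(n_markers_per_chrom))]
    positions = {
        c: np.linspace(0.0, L, k)
        for c, k, L in zip(chroms, n_markers_per_chrom, chrom_lengths_cm)
    }
    return GeneticMap(chroms, positions)


@dataclass(frozen=True)
class QtlModel:
    """Truth object for the simulator: QTL effects on a genetic map.

    ``qtls`` holds (chromosome, position_cM, additive, dominance); the
    additive effect is half the homozygote difference, positive values mean
    the 'A'-parent allele delays the trait.
    """

    qtls: tuple[tuple[str, float, float, float], ...]
    residual_sd: float
    grand_mean: float

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual sd must be positive")


@dataclass
class F2Cross:
    """Genotype matrix (0=AA, 1=AB, 2=BB, -1 missing) plus phenotypes and map."""

    genotypes: np.ndarray
    phenotypes: np.ndarray
    map: GeneticMap

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.genotypes.shape[1] != self.map.n_markers:
            raise ValueError("genotype columns must match map markers")
        if self.genotypes.shape[0] != self.phenotypes.size:
            raise ValueError("one phenotype per individual is required")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def to_csv(self, geno_path, pheno_path, map_path) -> None:
        idx = self.map.marker_index()
        cols = [self.map.marker_names[c][i] for c, i in idx]
        pd.DataFrame(self.genotypes, columns=cols).to_csv(geno_path, index=False)
        pd.DataFrame({"phenotype": self.phenotypes}).to_csv(pheno_path, index=False)
        rows = [(c, self.map.marker_names[c][i], self.map.positions[c][i]) for c, i in idx]
        pd.DataFrame(rows, columns=["chrom", "marker", "cM"]).to_csv(map_path, index=False)


def _simulate_gamete(map_positions: np.ndarray, rng) -> np.ndarray:
    """0/1 parental-origin vector along one chromosome (Haldane, no interference)."""
    k = map_positions.size
    g = np.empty(k, dtype=np.int8)
    g[0] = rng.integers(2)
    for i in range(1, k):
        c = haldane_c(map_positions[i] - map_positions[i - 1])
        g[i] = g[i - 1] ^ (rng.random() < c)
    return g


def simulate_f2(
    n: int,
    gmap: GeneticMap,
    truth: QtlModel,
    seed: int = 0,
    missing_rate: float = 0.0,
    parental_means: tuple[float, float] | None = None,
) -> F2Cross:
    """Simulate an F2 cross segregating the QTLs in ``truth``.

    QTL loci are inserted into the gamete chain at their map positions and
    dropped from the returned genotype matrix.  ``parental_means`` may be
    given instead of a grand mean: the additive effects are then centred so
    the two homozygous parents hit those means in expectation.
    """
    rng = np.random.default_rng(seed)
    aug_positions: dict[str, np.ndarray] = {}
    qtl_slots: list[tuple[str, int, float, float]] = []
    for chrom in gmap.chromosomes:
        pos = list(gmap.positions[chrom])
        for (qc, qpos, add, dom) in truth.qtls:
            if qc == chrom:
                if not (pos[0] <= qpos <= pos[-1]):
                    raise ValueError("QTL positions must lie within the map span")
                pos.append(qpos)
        aug = np.array(sorted(pos))
        aug_positions[chrom] = aug
    for (qc, qpos, add, dom) in truth.qtls:
        local = int(np.searchsorted(aug_positions[qc], qpos))
        qtl_slots.append((qc, local, add, dom))

    mean = truth.grand_mean
    if parental_means is not None:
        mean = 0.5 * (parental_means[0] + parental_means[1])

    geno_cols = []
    qtl_geno = {i: np.empty(n, dtype=np.int8) for i in range(len(qtl_slots))}
    per_chrom_geno: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        aug = aug_positions[chrom]
        G = np.empty((n, aug.size), dtype=np.int8)
        for ind in range(n):
            G[ind] = _simulate_gamete(aug, rng) + _simulate_gamete(aug, rng)
        per_chrom_geno[chrom] = G
    phen = np.full(n, mean, dtype=float)
    for qi, (qc, local, add, dom) in enumerate(qtl_slots):
        g = per_chrom_geno[qc][:, local]
        qtl_geno[qi] = g
        score = g.astype(float) - 1.0  # -1, 0, +1 for AA, AB, BB
        phen += -add * score + dom * (g == 1)
    phen += rng.normal(0.0, truth.residual_sd, size=n)

    for chrom in gmap.chromosomes:
        aug = aug_positions[chrom]
        keep = np.isin(np.arange(aug.size), [
            int(np.searchsorted(aug, p)) for p in gmap.positions[chrom]
        ])
        # marker columns are those at original map positions
        marker_cols = [int(np.searchsorted(aug, p)) for p in gmap.positions[chrom]]
        geno_cols.append(per_chrom_geno[chrom][:, marker_cols])
    genotypes = np.concatenate(geno_cols, axis=1)
    if missing_rate > 0:
        mask = rng.random(genotypes.shape) < missing_rate
        genotypes = np.where(mask, MISSING, genotypes).astype(np.int8)
    return F2Cross(genotypes, phen, gmap)


# ---------------------------------------------------------------------------
# Haley-Knott interval mapping
# ---------------------------------------------------------------------------

def _transition(c: float) -> np.ndarray:
    """Gamete-allele transition matrix over recombination fraction ``c``."""
    return np.array([[1 - c, c], [c, 1 - c]])


def _genotype_probs_chrom(geno: np.ndarray, marker_cm: np.ndarray, eval_cm: np.ndarray):
    """P(AA/AB/BB) at ``eval_cm`` for each individual, given flanking markers.

    Works per gamete: each F2 genotype constrains its two (exchangeable)
    gametes; AB splits evenly over the two phases.  Conditioning on the
    nearest informative marker on each side is exact under the Haldane
    (Markov) model.
    """
    n = geno.shape[0]
    out = np.empty((n, eval_cm.size, 3))
    cache: dict = {}
    # per-individual informative markers; probabilities depend only on the
    # flanking marker indices and genotypes, so memoize per pattern
    for ind in range(n):
        inf = np.where(geno[ind] != MISSING)[0]
        for pi, p in enumerate(eval_cm):
            left = inf[marker_cm[inf] <= p]
            right = inf[marker_cm[inf] > p]
            li = int(left[-1]) if left.size else None
            ri = int(right[0]) if right.size else None
            key = (pi, li, ri,
                   int(geno[ind, li]) if li is not None else -9,
                   int(geno[ind, ri]) if ri is not None else -9)
            probs = cache.get(key)
            if probs is None:
                probs = _locus_probs(geno[ind], marker_cm, p, li, ri)
                cache[key] = probs
            out[ind, pi] = probs
    return out


def _gamete_prob(allele_probs_left, d1, allele_probs_right, d2):
    """P(pseudo-locus allele) for one gamete given flanking allele distributions."""
    joint = np.zeros(2)
    if d1 is None and d2 is None:
        return np.array([0.5, 0.5])
    if d2 is None:
        T = _transition(haldane_c(d1))
        return allele_probs_left @ T
    if d1 is None:
        T = _transition(haldane_c(d2))
        return T @ allele_probs_right  # symmetric chain
    T1 = _transition(haldane_c(d1))
    T2 = _transition(haldane_c(d2))
    for a in range(2):
        joint[a] = (allele_probs_left @ T1[:, a]) * (T2[a] @ allele_probs_right)
    s = joint.sum()
    return joint / s if s > 0 else np.array([0.5, 0.5])


def _locus_probs(geno_row, marker_cm, p, li, ri):
    """Genotype probabilities at position ``p`` given flanking marker genotypes."""
    # enumerate phase assignments of the flanking genotypes to the two gametes
    def phases(g):
        if g == 0:
            return [((1, 0), (1, 0))], [1.0]
        if g == 2:
            return [((0, 1), (0, 1))], [1.0]
        return [((1, 0), (0, 1)), ((0, 1), (1, 0))], [0.5, 0.5]

    lphases, lw = phases(int(geno_row[li])) if li is not None else ([None], [1.0])
    rphases, rw = phases(int(geno_row[ri])) if ri is not None else ([None], [1.0])
    d1 = p - marker_cm[li] if li is not None else None
    d2 = marker_cm[ri] - p if ri is not None else None
    probs = np.zeros(3)
    for lp, wl in zip(lphases, lw):
        for rp, wr in zip(rphases, rw):
            g1 = _gamete_prob(np.array(lp[0]) if lp else None, d1,
                              np.array(rp[0]) if rp else None, d2)
            g2 = _gamete_prob(np.array(lp[1]) if lp else None, d1,
                              np.array(rp[1]) if rp else None, d2)
            w = wl * wr
            probs[0] += w * g1[0] * g2[0]
            probs[1] += w * (g1[0] * g2[1] + g1[1] * g2[0])
            probs[2] += w * g1[1] * g2[1]
    return probs


def _eval_grid(marker_cm: np.ndarray, step: float) -> np.ndarray:
    lo, hi = marker_cm[0], marker_cm[-1]
    grid = np.arange(lo, hi + 1e-9, step) if hi > lo else np.array([lo])
    return np.unique(np.concatenate([grid, marker_cm]))


def genotype_probabilities(cross: F2Cross, step: float = 2.0):
    """Conditional genotype probabilities at pseudo-markers every ``step`` cM.

    Returns ``(table, probs)``: a DataFrame of (chrom, cM) evaluation
    positions and an (individuals, positions, 3) array.
    """
    tables, blocks = [], []
    col0 = 0
    for chrom in cross.map.chromosomes:
        cm = cross.map.positions[chrom]
        k = cm.size
        geno = cross.genotypes[:, col0:col0 + k]
        col0 += k
        grid = _eval_grid(cm, step)
        blocks.append(_genotype_probs_chrom(geno, cm, grid))
        tables.append(pd.DataFrame({"chrom": chrom, "cM": grid}))
    return pd.concat(tables, ignore_index=True), np.concatenate(blocks, axis=1)


def _lod_curve_from_probs(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Haley-Knott LOD at each evaluation position."""
    n = y.size
    xa = probs[:, :, 2] - probs[:, :, 0]
    xd = probs[:, :, 1]
    y0 = y - y.mean()
    rss0 = float(y0 @ y0)
    n_pos = probs.shape[1]
    lod = np.empty(n_pos)
    for p in range(n_pos):
        X = np.column_stack([np.ones(n), xa[:, p], xd[:, p]])
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        rss1 = float(np.sum((y - fitted) ** 2))
        lod[p] = (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300))
    return lod


def interval_mapping(cross: F2Cross, step: float = 2.0):
    """Haley-Knott interval mapping.

    Returns a DataFrame with columns (chrom, cM, lod).  Raises on fewer than
    10 phenotyped individuals or a constant phenotype.
    """
    if cross.n_individuals < 10:
        raise ValueError("interval mapping needs >= 10 phenotyped individuals")
    if np.ptp(cross.phenotypes) == 0:
        raise ValueError("phenotype is constant")
    if np.any(np.all(cross.genotypes == MISSING, axis=0)):
        raise ValueError("a marker column is entirely missing")
    table, probs = genotype_probabilities(cross, step)
    table = table.copy()
    table["lod"] = _lod_curve_from_probs(probs, cross.phenotypes)
    return table


def permutation_threshold(
    cross: F2Cross,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step: float = 2.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The genotype-probability design matrices are fixed; the phenotype vector
    is permuted ``n_perm`` times and the (1 - alpha) quantile of the maximal
    LOD is returned.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    _, probs = genotype_probabilities(cross, step)
    n = cross.n_individuals
    n_pos = probs.shape[1]
    # orthonormal bases per position: LOD depends on ||Q'y||^2
    Qs = np.empty((n_pos, n, 3))
    ranks = np.empty(n_pos, dtype=int)
    for p in range(n_pos):
        X = np.column_stack([np.ones(n), probs[:, p, 2] - probs[:, p, 0], probs[:, p, 1]])
        Q, R = np.linalg.qr(X)
        keep = np.abs(np.diag(R)) > 1e-10
        Qs[p] = 0.0
        Qs[p][:, : keep.sum()] = Q[:, keep]
        ranks[p] = keep.sum()
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    ones = np.ones(n) / np.sqrt(n)
    for b in range(n_perm):
        y = rng.permutation(cross.phenotypes)
        tss = float(np.sum((y - y.mean()) ** 2))
        proj = np.einsum("pnk,n->pk", Qs, y)
        rss1 = np.sum(y**2) - np.sum(proj**2, axis=1)
        lod = (n / 2.0) * np.log10(tss / np.maximum(rss1, 1e-300))
        maxima[b] = lod.max()
    return float(np.quantile(maxima, 1.0 - alpha))


def variance_explained(cross: F2Cross, qtl_positions: list[tuple[str, float]]) -> dict:
    """Percent variance explained at the given QTL peak positions.

    Single QTL: PVE = 100 * (1 - 10^(-2 LOD / n)).  Multiple QTLs: drop-one
    partition from the joint Haley-Knott fit, PVE_q = 100 * (RSS_without_q -
    RSS_full) / TSS, plus the joint model PVE.
    """
    y = cross.phenotypes
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))
    cols = [np.ones(n)]
    per_qtl_cols = []
    for chrom, cm in qtl_positions:
        if chrom not in cross.map.chromosomes:
            raise ValueError(f"unknown chromosome {chrom}")
        sub = _qtl_design(cross, chrom, cm)
        per_qtl_cols.append(sub)
        cols.extend(sub)
    X_full = np.column_stack(cols)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    rss_full = rss(X_full)
    out = {"joint_pve": 100.0 * (tss - rss_full) / tss, "per_qtl_pve": []}
    if len(qtl_positions) == 1:
        lod = (n / 2.0) * np.log10(tss / max(rss_full, 1e-300))
        out["per_qtl_pve"] = [100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))]
        out["lod"] = [lod]
        return out
    lods = []
    for q in range(len(qtl_positions)):
        cols_red = [np.ones(n)]
        for qq, sub in enumerate(per_qtl_cols):
            if qq != q:
                cols_red.extend(sub)
        rss_red = rss(np.column_stack(cols_red))
        out["per_qtl_pve"].append(100.0 * (rss_red - rss_full) / tss)
        lods.append((n / 2.0) * np.log10(rss_red / max(rss_full, 1e-300)))
    out["lod"] = lods
    return out


def _qtl_design(cross: F2Cross, chrom: str, cm: float):
    """Additive/dominance expected-score columns at one map position."""
    col0 = 0
    for c in cross.map.chromosomes:
        k = cross.map.positions[c].size
        if c == chrom:
            geno = cross.genotypes[:, col0:col0 + k]
            probs = _genotype_probs_chrom(geno, cross.map.positions[c], np.array([cm]))
            return [probs[:, 0, 2] - probs[:, 0, 0], probs[:, 0, 1]]
        col0 += k
    raise ValueError(chrom)


def haplotype_association(phenotypes, haplotype_labels, test: str = "ranksum") -> dict:
    """Two-group phenotype comparison between haplotype classes.

    Default is the two-sided Wilcoxon rank-sum (exact for small samples);
    Welch's t is available via ``test='welch'``.  Reports group means and
    medians alongside the statistic and p-value.
    """
    y = np.asarray(phenotypes, dtype=float)
    labels = np.asarray(haplotype_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two haplotype groups are required")
    g1 = y[labels == groups[0]]
    g2 = y[labels == groups[1]]
    if g1.size < 2 or g2.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if test == "ranksum":
        res = sps.mannwhitneyu(g1, g2, alternative="two-sided",
                               method="exact" if min(g1.size, g2.size) < 20 else "auto")
    elif test == "welch":
        res = sps.ttest_ind(g1, g2, equal_var=False)
    else:
        raise ValueError("test must be 'ranksum' or 'welch'")
    return {
        "groups": list(map(str, groups)),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "means": (float(g1.mean()), float(g2.mean())),
        "medians": (float(np.median(g1)), float(np.median(g2))),
        "test": test,
    }


NONSYN_LABELS = {"missense", "nonsynonymous", "stop_gained", "stop_lost", "start_lost"}


def candidate_filter(variants, interval: tuple[int, int] | None = None) -> dict:
    """Nonsynonymous candidate variants in a fine-mapped interval, by gene.

    ``variants`` is an iterable of mappings with keys ``pos``, ``gene`` and
    ``effect``; amino-acid-changing effect labels are retained.  Returns
    ``{gene: [variants]}`` sorted by gene.
    """
    out: dict[str, list] = {}
    for v in variants:
        if interval is not None and not (interval[0] <= v["pos"] <= interval[1]):
            continue
        if str(v["effect"]).lower() not in NONSYN_LABELS:
            continue
        out.setdefault(str(v["gene"]), []).append(v)
    return dict(sorted(out.items()))
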