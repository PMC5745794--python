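"""Selective-sweep scans: SFS-based CLR and LD-based omega statistic.

``clr_scan`` implements the composite-likelihood-ratio test of a hard-sweep
spectrum against the genome-wide background spectrum.  At a focal position
the sweep model lets each sampled lineage escape the sweep with probability
``p_e = 1 - exp(-alpha * d)`` (``d`` = distance from the focal site); the
non-escaping lineages collapse onto the star-like swept ancestor, which
distorts the background frequency spectrum toward extreme classes.  The
likelihood ratio is maximized over a grid of sweep intensities ``alpha``
that includes the neutral limit (everyone escapes), so CLR >= 0 everywhere.

``omega_scan`` contrasts linkage disequilibrium within the two flanks of a
grid point against LD across the flanks: a completed sweep elevates r^2
within each flank but not across the swept site.

Cutoffs are calibrated on neutral null simulations at a chosen
false-positive rate; regions above cutoff are merged and the two methods'
regions intersected into consensus candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .coalescent import HaplotypePanel

__all__ = [
    "SweepScan",
    "OmegaConfig",
    "clr_scan",
    "omega_scan",
    "calibrate_cutoff",
    "merge_regions",
    "intersect_methods",
    "genes_in_regions",
    "sweep_spectrum",
    "folded_background",
]


@dataclass
class SweepScan:
    """Grid of sweep-statistic values, with calibration state."""

    grid_positions: np.ndarray
    values: np.ndarray
    method: str
    cutoff: float | None = None
    fpr: float | None = None
    significant_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid_positions = np.asarray(self.grid_positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid_positions.shape != self.values.shape:
            raise ValueError("one value per grid position is required")


@dataclass(frozen=True)
class OmegaConfig:
    """Omega-scan geometry (defaults: 10-kb grid, minwin 10 kb, maxwin 100 kb)."""

    grid_interval: int = 10_000
    minwin: int = 10_000
    maxwin: int = 100_000

    def __post_init__(self) -> None:
        if self.grid_interval < 1:
            raise ValueError("grid_interval must be >= 1")
        if self.minwin > self.maxwin:
            raise ValueError("minwin must not exceed maxwin")


# ---------------------------------------------------------------------------
# CLR scan
# ---------------------------------------------------------------------------

def _lbinom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def sweep_spectrum(p_bg_unfolded: np.ndarray, pe: float, n: int) -> np.ndarray:
    """Post-sweep unfolded spectrum given escape probability ``pe``.

    ``p_bg_unfolded[j]`` (length n+1; entries 1..n-1 used) is the background
    probability of derived count j.  Backwards in time K ~ Binomial(n, pe)
    lineages escape; the rest coalesce instantly onto one swept ancestor, so
    the post-sweep sample corresponds to a pre-sweep draw of K+1 lineages
    (hypergeometric within the background configuration), with the ancestor's
    allele copied to the n-K non-escapees.  Returned spectrum is conditioned
    on polymorphism (classes 1..n-1 renormalized).
    """
    p = np.asarray(p_bg_unfolded, dtype=float)
    q = np.zeros(n + 1)
    j = np.arange(1, n)  # background derived counts
    logw_K = _lbinom(n, np.arange(n + 1)) + np.arange(n + 1) * np.log(max(pe, 1e-300)) \
        + (n - np.arange(n + 1)) * np.log(max(1 - pe, 1e-300))
    if pe <= 0:
        w_K = np.zeros(n + 1)
        w_K[0] = 1.0
    elif pe >= 1:
        w_K = np.zeros(n + 1)
        w_K[n] = 1.0
    else:
        w_K = np.exp(logw_K)
    for K in range(n + 1):
        if w_K[K] < 1e-14:
            continue
        if K == n:  # everyone escapes: the background spectrum is untouched
            q[1:n] += w_K[K] * p[1:n]
            continue
        m = K + 1  # escapees plus the swept ancestor
        h = np.arange(0, m + 1)
        # P(h derived among m drawn | j of n): hypergeometric
        with np.errstate(invalid="ignore"):
            logH = (_lbinom(j[:, None], h[None, :])
                    + _lbinom(n - j[:, None], m - h[None, :])
                    - _lbinom(n, m))
        H = np.where(np.isfinite(logH), np.exp(logH), 0.0)
        pj = p[1:n]
        anc_derived = H * (h[None, :] / m)        # swept ancestor carries derived
        anc_ancestral = H * (1 - h[None, :] / m)
        A = pj @ anc_ancestral  # post-sweep count b = h
        B = pj @ anc_derived    # post-sweep count b = (h-1) + (n-K)
        q[h] += w_K[K] * A
        idx = h - 1 + (n - K)
        ok = (h >= 1) & (idx <= n)
        np.add.at(q, idx[ok], w_K[K] * B[ok])
    q = q[: n + 1]
    poly = q[1:n].sum()
    out = np.zeros(n + 1)
    if poly > 0:
        out[1:n] = q[1:n] / poly
    return out


def _fold_1d(q: np.ndarray, n: int) -> np.ndarray:
    folded = np.zeros(n // 2 + 1)
    for b in range(1, n):
        folded[min(b, n - b)] += q[b]
    return folded


def _unfold_background(folded_counts: np.ndarray, n: int) -> np.ndarray:
    """Spread folded minor-allele classes symmetrically to an unfolded spectrum."""
    p = np.zeros(n + 1)
    for c in range(1, n // 2 + 1):
        if c == n - c:
            p[c] = folded_counts[c]
        else:
            p[c] = folded_counts[c] / 2.0
            p[n - c] = folded_counts[c] / 2.0
    tot = p.sum()
    if tot <= 0:
        raise ValueError("background spectrum has no mass")
    return p / tot


def folded_background(panel: HaplotypePanel, pseudocount: float = 0.5) -> np.ndarray:
    """Genome-wide folded minor-allele spectrum of a panel.

    Empty frequency classes receive ``pseudocount`` so the spectrum can serve
    as a CLR background even at desk-scale SNP counts (a zero-mass class
    would otherwise make the background likelihood degenerate).
    """
    n = panel.n_haplotypes
    counts = panel.matrix.sum(axis=0)
    folded = np.bincount(np.minimum(counts, n - counts), minlength=n // 2 + 1).astype(float)
    folded[1:][folded[1:] == 0] = pseudocount
    return folded


DEFAULT_ALPHA_GRID = np.logspace(-7, -1, 64)
_G_GRID = np.logspace(-4, np.log10(25.0), 48)  # alpha*d grid for p_e lookup


def clr_scan(
    panel: HaplotypePanel,
    background: np.ndarray,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
) -> SweepScan:
    """Composite-likelihood-ratio sweep scan on the folded frequency spectrum.

    ``background`` is the genome-wide folded minor-allele spectrum (length
    ``n//2 + 1``, entry 0 ignored) for the same sample size as ``panel``.
    ``CLR(x) = 2 [max_alpha log CL_sweep - log CL_background]`` with the
    neutral limit included, so values are nonnegative.
    """
    n = panel.n_haplotypes
    background = np.asarray(background, dtype=float)
    if background.shape[0] != n // 2 + 1:
        raise ValueError("background spectrum must match the panel sample size")
    if np.any(background[1:] <= 0):
        raise ValueError("background spectrum has zero-mass classes")
    if grid is None:
        grid = np.linspace(1, panel.sequence_length, n_grid).round().astype(np.int64)
    grid = np.asarray(grid, dtype=np.int64)
    if grid.size == 0:
        raise ValueError("empty scan grid")

    p_unf = _unfold_background(background, n)
    log_pb_fold = np.log(np.maximum(_fold_1d(p_unf, n), 1e-300))  # class 0 is never used
    # precompute folded log sweep spectra on the alpha*d grid
    logQ = np.empty((len(_G_GRID), n // 2 + 1))
    for i, g in enumerate(_G_GRID):
        q = sweep_spectrum(p_unf, 1.0 - np.exp(-g), n)
        logQ[i] = np.log(np.maximum(_fold_1d(q, n), 1e-12))

    counts = panel.matrix.sum(axis=0)
    c_sites = np.minimum(counts, n - counts)  # folded minor counts, >= 1
    pos = panel.positions.astype(float)
    bg_site = log_pb_fold[c_sites]

    values = np.zeros(len(grid))
    log_g_edges = np.log10(_G_GRID)
    for gi, x in enumerate(grid):
        d = np.abs(pos - x)
        best = 0.0
        for alpha in alpha_grid:
            g = alpha * d
            near = g < 25.0  # beyond this the sweep spectrum is the background
            if not np.any(near):
                continue
            gg = np.clip(g[near], _G_GRID[0], _G_GRID[-1])
            idx = np.clip(np.searchsorted(log_g_edges, np.log10(gg)), 0, len(_G_GRID) - 1)
            ll = np.sum(logQ[idx, c_sites[near]] - bg_site[near])
            if ll > best:
                best = ll
        values[gi] = 2.0 * best
    return SweepScan(grid, values, method="CLR")


# ---------------------------------------------------------------------------
# Omega scan
# ---------------------------------------------------------------------------

def _r_squared(matrix: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between sites (columns) from phased haplotypes."""
    X = matrix.astype(float)
    X = X - X.mean(axis=0)
    cov = X.T @ X
    var = np.diag(cov).copy()
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return r**2


def omega_scan(panel: HaplotypePanel, cfg: OmegaConfig | None = None) -> SweepScan:
    """LD-contrast omega statistic on a regular grid.

    At each grid point the sites within ``maxwin`` on each side are split
    into a left and a right set; omega is the ratio of mean within-side r^2
    to mean cross-side r^2, maximized over admissible window extents (each
    flank spanning between ``minwin`` and ``maxwin``).  Grid points without
    at least two SNPs on both flanks get NaN.
    """
    cfg = cfg or OmegaConfig()
    grid = np.arange(cfg.grid_interval, panel.sequence_length + 1, cfg.grid_interval,
                     dtype=np.int64)
    pos = panel.positions
    values = np.full(len(grid), np.nan)
    for gi, x in enumerate(grid):
        lo = np.searchsorted(pos, x - cfg.maxwin, side="left")
        hi = np.searchsorted(pos, x + cfg.maxwin, side="right")
        mid = np.searchsorted(pos, x, side="right")
        left_idx = np.arange(lo, mid)[::-1]   # nearest-to-x first
        right_idx = np.arange(mid, hi)
        if len(left_idx) < 2 or len(right_idx) < 2:
            continue
        local = np.concatenate([left_idx[::-1], right_idx])
        r2 = _r_squared(panel.matrix[:, local])
        nL = len(left_idx)
        # index maps into the local r2 block (left reversed back to genomic order)
        Lmap = np.arange(nL)[::-1]
        Rmap = np.arange(nL, nL + len(right_idx))
        values[gi] = _max_omega(
            r2, Lmap, Rmap,
            np.abs(pos[left_idx] - x), np.abs(pos[right_idx] - x),
            cfg.minwin,
        )
    return SweepScan(grid, values, method="omega")


def _max_omega(r2, Lmap, Rmap, dL, dR, minwin) -> float:
    """Maximize omega over prefix extents of each flank (leftmost split on ties)."""
    nL, nR = len(Lmap), len(Rmap)
    # cumulative within-flank pair sums as the flank grows outwards
    SL = np.zeros(nL + 1)
    for a in range(1, nL + 1):
        SL[a] = SL[a - 1] + r2[Lmap[a - 1], Lmap[:a - 1]].sum()
    SR = np.zeros(nR + 1)
    for b in range(1, nR + 1):
        SR[b] = SR[b - 1] + r2[Rmap[b - 1], Rmap[:b - 1]].sum()
    # cross-sum matrix: SX[a, b] = sum r2 over first a left x first b right
    cross = r2[np.ix_(Lmap, Rmap)]
    SX = np.zeros((nL + 1, nR + 1))
    SX[1:, 1:] = np.cumsum(np.cumsum(cross, axis=0), axis=1)
    # admissible extents: at least 2 SNPs and all SNPs within minwin included
    a_min = max(2, int(np.searchsorted(np.sort(dL), minwin, side="left")))
    b_min = max(2, int(np.searchsorted(np.sort(dR), minwin, side="left")))
    a_min = min(a_min, nL)
    b_min = min(b_min, nR)
    best = np.nan
    for a in range(a_min, nL + 1):
        for b in range(b_min, nR + 1):
            pairs_within = a * (a - 1) / 2 + b * (b - 1) / 2
            num = (SL[a] + SR[b]) / pairs_within
            den = SX[a, b] / (a * b)
            w = np.inf if den == 0 else num / den
            if np.isnan(best) or w > best:
                best = w
    return best


# ---------------------------------------------------------------------------
# Calibration and region algebra
# ---------------------------------------------------------------------------

def calibrate_cutoff(null_scans: list[SweepScan], fpr: float = 1e-4) -> float:
    """(1 - fpr) quantile of the pooled null statistic distribution."""
    if not null_scans:
        raise ValueError("no null scans supplied")
    values = np.concatenate([s.values for s in null_scans])
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("null scans contain no finite statistic values")
    if values.size < 1.0 / fpr:
        warnings.warn(
            f"only {values.size} null values for a {fpr:g} false-positive rate; "
            "cutoff uses the widest available quantile",
            stacklevel=2,
        )
    return float(np.quantile(values, 1.0 - fpr))


def merge_regions(scan: SweepScan, max_gap: int | None = None) -> list[tuple[int, int]]:
    """Merge grid points above the cutoff into regions (1-based inclusive).

    Neighbouring significant grid points within ``max_gap`` bp (default: the
    grid spacing) fall into one region spanning them.  Idempotent; stores the
    result on the scan.
    """
    if scan.cutoff is None:
        raise ValueError("scan has no calibrated cutoff")
    if max_gap is None:
        diffs = np.diff(scan.grid_positions)
        max_gap = int(diffs.min()) if diffs.size else 1
    with np.errstate(invalid="ignore"):
        sig = scan.grid_positions[np.nan_to_num(scan.values, nan=-np.inf) > scan.cutoff]
    regions: list[tuple[int, int]] = []
    for p in sig:
        if regions and p - regions[-1][1] <= max_gap:
            regions[-1] = (regions[-1][0], int(p))
        else:
            regions.append((int(p), int(p)))
    scan.significant_regions = regions
    return regions


def intersect_methods(regions_a, regions_b) -> list[tuple[int, int]]:
    """Interval intersection of two sorted, non-overlapping region lists."""
    out = []
    i = j = 0
    a = sorted(regions_a)
    b = sorted(regions_b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def genes_in_regions(regions, gff_path, chrom: str | None = None):
    """IDs of GFF genes overlapping any region by >= 1 bp (closed intervals).

    Malformed GFF rows are skipped; the skip count is reported in the second
    return value.
    """
    import gffutils

    good_lines = []
    skipped = 0
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                good_lines.append(line)
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                if len(parts) < 9:
                    raise ValueError
                int(parts[3]), int(parts[4])
            except ValueError:
                skipped += 1
                continue
            good_lines.append(line)
    db = gffutils.create_db("".join(good_lines), dbfn=":memory:", from_string=True,
                            force=True, keep_order=True,
                            merge_strategy="create_unique")
    hits = set()
    for gene in db.features_of_type("gene"):
        if chrom is not None and gene.seqid != chrom:
            continue
        for s, e in regions:
            if gene.start <= e and s <= gene.end:
                hits.add(gene.id)
                break
    return sorted(hits), skipped
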