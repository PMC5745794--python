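"""Post-calling hard filters for SNP/indel site records.

The rules mirror a standard GATK-style VariantFiltration pass: site quality
Q >= 30, mapping quality MQ >= 20, quality-by-depth QD >= 10,
ReadPosRankSum >= -8.0, depth DP >= 3, strand-bias FS <= 10 for SNPs
(<= 200 for indels), no more than three SNPs in any 10-bp span, and a
biallelic call-rate requirement.  Annotations absent at a site (e.g.
ReadPosRankSum at homozygous-only sites) pass that rule and are tallied
separately.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteRecord",
    "FilterConfig",
    "apply_hard_filters",
    "density_filter",
    "biallelic_callrate_filter",
    "subset_noncoding",
]

MISSING = -1


@dataclass
class SiteRecord:
    """One variant site: alleles, per-sample calls, and filter annotations.

    ``genotypes`` is an (n_samples, ploidy) integer array of allele indices
    with -1 for missing calls.  ``annotations`` may omit any of
    Q/MQ/QD/ReadPosRankSum/DP/FS.
    """

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    genotypes: np.ndarray
    annotations: dict = field(default_factory=dict)
    variant_class: str = "SNP"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        self.genotypes = np.atleast_2d(np.asarray(self.genotypes, dtype=np.int16))
        if isinstance(self.alt, str):
            self.alt = (self.alt,)
        self.alt = tuple(self.alt)
        if self.variant_class not in ("SNP", "indel"):
            raise ValueError("variant_class must be 'SNP' or 'indel'")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1

    @property
    def n_called(self) -> int:
        return int(np.sum(np.all(self.genotypes != MISSING, axis=1)))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the hard-filter pass (defaults are the study's)."""

    min_q: float = 30.0
    min_mq: float = 20.0
    min_qd: float = 10.0
    min_read_pos_rank_sum: float = -8.0
    min_dp: float = 3.0
    max_fs_snp: float = 10.0
    max_fs_indel: float = 200.0
    density_max_snps: int = 3
    density_window: int = 10
    min_called_samples: int = 219

    def __post_init__(self) -> None:
        for v in (self.min_q, self.min_mq, self.min_qd, self.min_read_pos_rank_sum,
                  self.min_dp, self.max_fs_snp, self.max_fs_indel):
            if not math.isfinite(v):
                raise ValueError("thresholds must be finite")
        if self.density_window < 1:
            raise ValueError("density_window must be >= 1")


def _rules(cfg: FilterConfig):
    return [
        ("Q", lambda r, v: v >= cfg.min_q),
        ("MQ", lambda r, v: v >= cfg.min_mq),
        ("QD", lambda r, v: v >= cfg.min_qd),
        ("ReadPosRankSum", lambda r, v: v >= cfg.min_read_pos_rank_sum),
        ("DP", lambda r, v: v >= cfg.min_dp),
        ("FS", lambda r, v: v <= (cfg.max_fs_indel if r.variant_class == "indel" else cfg.max_fs_snp)),
    ]


def apply_hard_filters(records: list[SiteRecord], cfg: FilterConfig | None = None):
    """Site-wise hard filtering.

    Returns ``(passed, tally)``; the tally attributes each rejected record to
    its first failing rule (so the rule counts sum to the rejected count) and
    additionally counts missing annotations under ``missing_<field>``.
    Filtering is idempotent and requires (chrom, pos)-sorted input.
    """
    cfg = cfg or FilterConfig()
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")
    passed: list[SiteRecord] = []
    tally: Counter = Counter()
    for rec in records:
        failed = None
        for name, ok in _rules(cfg):
            val = rec.annotations.get(name)
            if val is None:
                tally[f"missing_{name}"] += 1  # absent annotation passes the rule
                continue
            if not ok(rec, float(val)):
                failed = name
                break
        if failed is None:
            passed.append(rec)
        else:
            tally[failed] += 1
    return passed, dict(tally)


def density_filter(
    positions,
    max_snps: int = 3,
    window: int = 10,
    thin: bool = False,
):
    """Drop SNP clusters denser than ``max_snps`` per ``window`` bp.

    Any span of ``window`` consecutive bp (endpoints inclusive) holding more
    than ``max_snps`` SNPs disqualifies, by default, every SNP in that span
    (``thin=True`` instead keeps the first ``max_snps`` of each offending
    run).  Idempotent; ``positions`` must be strictly increasing.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    if pos.size <= max_snps:
        return pos.copy()
    bad = np.zeros(pos.size, dtype=bool)
    for i in range(pos.size - max_snps):
        if pos[i + max_snps] - pos[i] < window:  # max_snps+1 SNPs inside `window` bp
            if thin:
                bad[i + max_snps] = True
            else:
                bad[i : i + max_snps + 1] = True
    return pos[~bad]


def biallelic_callrate_filter(records: list[SiteRecord], min_called: int) -> list[SiteRecord]:
    """Keep biallelic SNPs called in at least ``min_called`` samples."""
    return [
        r for r in records
        if r.is_biallelic and r.variant_class == "SNP" and r.n_called >= min_called
    ]


def subset_noncoding(records: list[SiteRecord], coding_intervals) -> list[SiteRecord]:
    """Records whose position overlaps no coding interval.

    ``coding_intervals`` are merged, sorted (start, end) pairs in BED-style
    0-based coordinates; a 1-based position ``p`` is treated as covered when
    ``start <= p <= end``, the conservative boundary reading (a SNP touching
    either edge of a coding interval is excluded).
    """
    ivs = sorted((int(s), int(e)) for s, e in coding_intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"malformed interval ({s}, {e})")
    if not ivs:
        return list(records)
    starts = np.array([s for s, _ in ivs])
    ends = np.array([e for _, e in ivs])
    out = []
    for r in records:
        i = np.searchsorted(starts, r.pos, side="right") - 1
        covered = i >= 0 and r.pos <= ends[i]
        # adjacent intervals may not be merged on the start bound
        if not covered and i + 1 < len(starts) and starts[i + 1] == r.pos:
            covered = True
        if not covered:
            out.append(r)
    return out
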