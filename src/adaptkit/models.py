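"""Two-deme demographic models for *Arabidopsis thaliana* range-expansion history.

A :class:`DemographicModel` describes, backwards in time, a one- or two-deme
piecewise-constant population history: per-deme size epochs, an optional
divergence event at which the two demes merge into a single ancestral deme,
and zero or more time windows of (possibly asymmetric) migration.

The four templates returned by :func:`reference_models` encode the competing
gene-flow scenarios for the Yangtze-basin (popY) versus north-western China
(popN) populations: no gene flow, a single migration window, continuous
migration since divergence, and two asymmetric migration windows.  The
two-window model carries the published best-fit parameter vector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "Epoch",
    "MigrationWindow",
    "DemographicModel",
    "reference_models",
    "MU_PER_BP_PER_GEN",
    "REC_PER_BP_PER_GEN",
]

#: Spontaneous mutation rate, per bp per generation.
MU_PER_BP_PER_GEN = 7e-9
#: Crossover rate, per bp per generation (3.6 cM/Mb).
REC_PER_BP_PER_GEN = 3.6e-8


@dataclass(frozen=True)
class Epoch:
    """Piecewise-constant size epoch starting at ``start_time`` generations ago.

    ``deme_sizes`` are diploid effective sizes, one per deme.  The epoch
    extends backwards until the start of the next epoch (or the divergence
    time for two-deme models).
    """

    start_time: float
    deme_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError("epoch start_time must be >= 0")
        if any(n <= 0 for n in self.deme_sizes):
            raise ValueError("deme sizes must be positive")


@dataclass(frozen=True)
class MigrationWindow:
    """Migration active on ``[t_start, t_end)`` generations ago.

    ``m_01`` is the per-generation fraction of deme-0 lineages that (viewed
    backwards in time) move to deme 1; ``m_10`` the reverse.  Asymmetric gene
    flow means ``m_01 != m_10``.
    """

    t_start: float
    t_end: float
    m_01: float
    m_10: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_end):
            raise ValueError("need 0 <= t_start < t_end")
        for m in (self.m_01, self.m_10):
            if not (0 <= m < 1):
                raise ValueError("migration fractions must lie in [0, 1)")


@dataclass(frozen=True)
class DemographicModel:
    """A one- or two-deme piecewise-constant demographic history.

    Times are in generations before present; sizes are diploid effective
    sizes.  For two-deme models the demes merge (backwards in time) into a
    single ancestral deme of size ``ancestral_size`` at ``divergence_time``.
    """

    n_demes: int
    epochs: tuple[Epoch, ...]
    divergence_time: float | None = None
    ancestral_size: float | None = None
    migration_windows: tuple[MigrationWindow, ...] = ()
    mutation_rate: float = MU_PER_BP_PER_GEN
    recombination_rate: float = REC_PER_BP_PER_GEN
    generation_years: float = 1.0
    name: str = "model"

    def __post_init__(self) -> None:
        if self.n_demes not in (1, 2):
            raise ValueError("only 1- or 2-deme models are supported")
        if not self.epochs:
            raise ValueError("at least one epoch is required")
        for ep in self.epochs:
            if len(ep.deme_sizes) != self.n_demes:
                raise ValueError("every epoch must give one size per deme")
        starts = [ep.start_time for ep in self.epochs]
        if starts != sorted(starts) or starts[0] != 0:
            raise ValueError("epochs must start at 0 and be time-sorted")
        if self.n_demes == 2:
            if self.divergence_time is None or self.ancestral_size is None:
                raise ValueError("two-deme models need divergence_time and ancestral_size")
            if self.divergence_time <= 0 or self.ancestral_size <= 0:
                raise ValueError("divergence_time and ancestral_size must be positive")
            for w in self.migration_windows:
                if w.t_end > self.divergence_time:
                    raise ValueError("migration windows must end by the divergence time")
        elif self.migration_windows:
            raise ValueError("one-deme models cannot have migration windows")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.generation_years <= 0:
            raise ValueError("generation_years must be positive")

    # -- convenience -----------------------------------------------------

    def size_at(self, deme: int, t: float) -> float:
        """Diploid size of ``deme`` at time ``t`` generations ago."""
        if self.n_demes == 2 and self.divergence_time is not None and t >= self.divergence_time:
            return float(self.ancestral_size)
        n = self.epochs[0].deme_sizes[deme]
        for ep in self.epochs:
            if ep.start_time <= t:
                n = ep.deme_sizes[deme]
            else:
                break
        return float(n)

    def with_params(self, **updates) -> "DemographicModel":
        """Return a copy with top-level fields replaced."""
        return dataclasses.replace(self, **updates)

    # -- (de)serialization -----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_demes": self.n_demes,
            "epochs": [[ep.start_time, list(ep.deme_sizes)] for ep in self.epochs],
            "divergence_time": self.divergence_time,
            "ancestral_size": self.ancestral_size,
            "migration_windows": [
                [w.t_start, w.t_end, w.m_01, w.m_10] for w in self.migration_windows
            ],
            "mutation_rate": self.mutation_rate,
            "recombination_rate": self.recombination_rate,
            "generation_years": self.generation_years,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            n_demes=int(d["n_demes"]),
            epochs=tuple(Epoch(float(t), tuple(float(x) for x in sizes)) for t, sizes in d["epochs"]),
            divergence_time=d.get("divergence_time"),
            ancestral_size=d.get("ancestral_size"),
            migration_windows=tuple(
                MigrationWindow(*map(float, w)) for w in d.get("migration_windows", [])
            ),
            mutation_rate=float(d.get("mutation_rate", MU_PER_BP_PER_GEN)),
            recombination_rate=float(d.get("recombination_rate", REC_PER_BP_PER_GEN)),
            generation_years=float(d.get("generation_years", 1.0)),
            name=str(d.get("name", "model")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Published parameter skeleton.  Deme 0 = popY (Yangtze basin), deme 1 = popN
# (north-western China).  Times in generations (g = 1 year).
# ---------------------------------------------------------------------------

T_DIV = 61_409.0
N_ANC = 179_724.0
N_Y_POST_DIV = 78_454.0
N_N_POST_DIV = 26_959.0
N_Y_RECENT = 45_089.0
N_N_RECENT = 45_617.0
T_Y_CHANGE = 7_543.0
T_N_CHANGE = 7_169.0
MIG_WINDOW_1 = (14_307.0, 18_652.0)  # older wave
MIG_WINDOW_2 = (7_660.0, 8_440.0)    # younger wave
#: Default per-generation migration fraction for gene-flow templates; the
#: published fit reports both waves as weak but does not print magnitudes.
DEFAULT_MIG_RATE = 1e-5


def _size_skeleton() -> tuple[Epoch, ...]:
    # Recent epoch first; size changes at 7,543 (popY) and 7,169 (popN)
    # generations ago produce three distinct epochs between 0 and T_div.
    return (
        Epoch(0.0, (N_Y_RECENT, N_N_RECENT)),
        Epoch(T_N_CHANGE, (N_Y_RECENT, N_N_POST_DIV)),
        Epoch(T_Y_CHANGE, (N_Y_POST_DIV, N_N_POST_DIV)),
    )


def reference_models(mig_rate: float = DEFAULT_MIG_RATE) -> list[DemographicModel]:
    """The four competing two-deme gene-flow scenarios.

    M1: isolation (no gene flow).  M2: one migration window (the younger
    wave).  M3: continuous migration since divergence.  M4: two asymmetric
    migration windows — the best-fit model, pre-filled with the published
    parameter vector.

    ``mig_rate`` seeds the migration fraction of the free templates; the
    published fit reports the gene flow only as "weak".
    """
    common = dict(
        n_demes=2,
        epochs=_size_skeleton(),
        divergence_time=T_DIV,
        ancestral_size=N_ANC,
        mutation_rate=MU_PER_BP_PER_GEN,
        recombination_rate=REC_PER_BP_PER_GEN,
        generation_years=1.0,
    )
    m1 = DemographicModel(name="M1_no_gene_flow", migration_windows=(), **common)
    m2 = DemographicModel(
        name="M2_one_window",
        migration_windows=(MigrationWindow(*MIG_WINDOW_2, mig_rate, mig_rate),),
        **common,
    )
    m3 = DemographicModel(
        name="M3_continuous",
        migration_windows=(MigrationWindow(0.0, T_DIV, mig_rate, mig_rate),),
        **common,
    )
    m4 = DemographicModel(
        name="M4_two_windows",
        migration_windows=(
            MigrationWindow(*MIG_WINDOW_2, mig_rate, mig_rate),
            MigrationWindow(*MIG_WINDOW_1, mig_rate, mig_rate),
        ),
        **common,
    )
    return [m1, m2, m3, m4]
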