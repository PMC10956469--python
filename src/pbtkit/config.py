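"""Configuration objects for the simulator, the parentage engine and the pipeline.

Defaults encode the study conditions of a four-program, two-lineage hatchery
steelhead system: three programs of Central Valley ("cv") lineage and one of
coastal lineage, 92 autosomal SNP loci plus a Y-linked sex marker and an
inversion-indicator locus, a per-gene-copy genotyping error rate of 0.005,
and pedigree acceptance at FDR <= 0.01.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

AGES = (2, 3, 4, 5, 6)

SEX_MARKER = "SexY"
OMY05_MARKER = "Omy05R"


@dataclasses.dataclass
class ProgramSpec:
    """One hatchery program: id, genetic lineage, scale and mating practice.

    ``mating_rule`` is ``one_male`` (each female mated with a single male;
    the practice at large programs) or ``two_males`` (each female's eggs
    divided between two males; the practice at small programs to mitigate
    loss of effective population size).
    """

    program_id: str
    lineage_id: str
    spawners_per_year: int = 200
    mating_rule: str = "one_male"

    def __post_init__(self) -> None:
        if self.mating_rule not in ("one_male", "two_males"):
            raise ValueError(f"unknown mating_rule {self.mating_rule!r}")


def _default_programs() -> list[ProgramSpec]:
    return [
        ProgramSpec("CH", "cv", 200, "one_male"),
        ProgramSpec("FRH", "cv", 200, "one_male"),
        ProgramSpec("MRH", "cv", 200, "two_males"),
        ProgramSpec("NH", "coastal", 200, "two_males"),
    ]


def _default_age_dist() -> dict:
    # (lineage, sex) -> probability over ages 2..6.  cv-lineage programs are
    # dominated by age-2 spawners (males more so); the coastal lineage by
    # age-3 spawners, matching the qualitative age structure of the system.
    return {
        ("cv", "F"): (0.75, 0.22, 0.026, 0.004, 0.0),
        ("cv", "M"): (0.88, 0.11, 0.008, 0.002, 0.0),
        ("coastal", "F"): (0.11, 0.85, 0.034, 0.004, 0.002),
        ("coastal", "M"): (0.20, 0.767, 0.030, 0.002, 0.001),
    }


def _default_iteroparity() -> dict:
    # iteroparity is female-biased in the cv lineage and near-absent coastal
    return {
        ("cv", "F"): 0.12,
        ("cv", "M"): 0.02,
        ("coastal", "F"): 0.002,
        ("coastal", "M"): 0.002,
    }


def _default_repeat() -> dict:
    # within-season repeat spawning is strongly male-biased
    return {
        ("cv", "F"): 0.02,
        ("cv", "M"): 0.18,
        ("coastal", "F"): 0.01,
        ("coastal", "M"): 0.18,
    }


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the forward hatchery-broodstock simulator.

    Parameters
    ----------
    n_loci : int
        Number of autosomal analysis loci (the sex marker and the inversion
        indicator are added on top).
    founder_freq_range : (float, float)
        Ancestral allele frequencies are drawn uniformly on this interval.
    lineage_fst : float
        Balding-Nichols divergence between the two lineages.
    programs : list of ProgramSpec
    years : sequence of int
        Consecutive spawn-season labels.
    age_at_return_dist : {(lineage, sex): tuple of 5 floats}
        Probability over ages 2..6 at first return.
    iteroparity_prob, repeat_spawn_prob : {(lineage, sex): float}
    stray_matrix : row-stochastic array over programs (natal -> return).
    omy05_freq_R : {lineage: float}
        Frequency of the rearranged (R) inversion haplotype.
    omy05_age_effect : {lineage: float}
        Odds multiplier on returning at age 2 per copy of R.
    offspring_per_pair_mean, offspring_per_pair_dispersion : float
        Negative-binomial family sizes for returning offspring per pair.
    epsilon_sim : float
        Per-gene-copy genotyping error rate.
    missing_rate : float
        Per-locus-call missing probability.
    meta_error_sex_rate, meta_error_date_rate : float
        Rates of recording errors in phenotypic sex / spawn date.
    """

    n_loci: int = 92
    founder_freq_range: tuple[float, float] = (0.2, 0.8)
    lineage_fst: float = 0.1
    programs: list[ProgramSpec] = dataclasses.field(default_factory=_default_programs)
    years: Sequence[int] = tuple(range(2011, 2020))
    age_at_return_dist: dict = dataclasses.field(default_factory=_default_age_dist)
    iteroparity_prob: dict = dataclasses.field(default_factory=_default_iteroparity)
    repeat_spawn_prob: dict = dataclasses.field(default_factory=_default_repeat)
    stray_matrix: np.ndarray | None = None
    omy05_freq_R: dict = dataclasses.field(
        default_factory=lambda: {"cv": 0.08, "coastal": 0.20}
    )
    omy05_age_effect: dict = dataclasses.field(
        default_factory=lambda: {"cv": 1.0, "coastal": 2.0}
    )
    offspring_per_pair_mean: float = 1.0
    offspring_per_pair_dispersion: float = 0.5
    epsilon_sim: float = 0.005
    missing_rate: float = 0.02
    meta_error_sex_rate: float = 0.002
    meta_error_date_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.founder_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("founder_freq_range must be inside (0, 1)")
        if not (0.0 <= self.lineage_fst < 1.0):
            raise ValueError("lineage_fst must be in [0, 1)")
        if not (0.0 <= self.epsilon_sim < 0.5):
            raise ValueError("epsilon_sim must be in [0, 0.5)")
        if self.stray_matrix is None:
            self.stray_matrix = default_stray_matrix(len(self.programs))
        self.stray_matrix = np.asarray(self.stray_matrix, dtype=float)
        k = len(self.programs)
        if self.stray_matrix.shape != (k, k):
            raise ValueError("stray_matrix must be programs x programs")
        if not np.allclose(self.stray_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("stray_matrix rows must sum to 1")
        for key, vec in self.age_at_return_dist.items():
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"age_at_return_dist[{key}] must sum to 1")

    @property
    def lineages(self) -> list[str]:
        seen: list[str] = []
        for p in self.programs:
            if p.lineage_id not in seen:
                seen.append(p.lineage_id)
        return seen


def default_stray_matrix(n_programs: int, stay: float = 0.97) -> np.ndarray:
    """Near-identity row-stochastic matrix: most fish return to their natal
    program, the remainder spread evenly over the others."""
    if n_programs == 1:
        return np.ones((1, 1))
    off = (1.0 - stay) / (n_programs - 1)
    m = np.full((n_programs, n_programs), off)
    np.fill_diagonal(m, stay)
    return m


@dataclasses.dataclass
class ParentageConfig:
    """Parameters of the trio-likelihood parentage engine.

    ``epsilon`` is the assumed per-gene-copy genotyping error rate
    (0.005, i.e. effectively 1% per locus); assignments are accepted when
    the maximum a posteriori relationship is a parent-offspring trio and
    the Benjamini-Hochberg q-value is at most ``fdr_threshold``.
    """

    epsilon: float = 0.005
    fdr_threshold: float = 0.01
    allowed_age_gap: tuple[int, int] = (2, 6)
    null_sim_size: int = 100_000
    allele_freq_source: str = "pooled"
    min_loci_for_trio: int = 50
    top_k_candidates: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must be in (0, 0.5)")
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.allele_freq_source not in ("pooled", "per_program"):
            raise ValueError("allele_freq_source must be pooled|per_program")


@dataclasses.dataclass
class QCConfig:
    max_missing_frac: float = 0.10
    min_analysis_loci: int = 50
    season_boundary_month: int = 7


@dataclasses.dataclass
class IdentityConfig:
    match_threshold: float = 0.95
    min_shared_loci: int = 60
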