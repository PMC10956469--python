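"""Forward simulator for multi-hatchery broodstock datasets with known truth.

Simulates a set of hatchery programs drawing broodstock from two diverged
genetic lineages over consecutive spawn seasons.  Each season, returning
offspring of earlier seasons (at ages 2-6), iteroparous returns and
founder fill-ins are spawned in female x male pairings per the program's
mating rule; family sizes of *returning* offspring are negative-binomial;
offspring inherit one allele per parent per locus; strays return to a
non-natal program per a row-stochastic matrix.  A Y-linked marker carries
sex and an inversion-indicator locus can bias age at return (odds
multiplier on age-2 per copy of the rearranged haplotype).

``observe`` turns the truth into the raw data the analysis sees: one row
per spawn event under a fresh sample id, with per-gene-copy genotyping
error, missing calls, and rare metadata errors (wrong phenotypic sex or
spawn date).
"""

from __future__ import annotations

import dataclasses
import json
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import AGES, OMY05_MARKER, SEX_MARKER, SimulationConfig
from .data import MISSING, GenotypeTable, write_sample_table

__all__ = [
    "TruthBundle",
    "draw_founder_frequencies",
    "simulate_population",
    "observe",
    "season_start",
    "SEASON_DAYS",
]

#: spawning season runs December 1 (of season_year - 1) for 90 days
SEASON_DAYS = 90


def season_start(season_year: int) -> date:
    return date(season_year - 1, 12, 1)


@dataclasses.dataclass
class TruthBundle:
    """Ground truth emitted by the simulator.

    Attributes
    ----------
    fish : DataFrame with fish_id, sex, natal_program, lineage,
        cohort_year, is_founder.
    true_genotypes : GenotypeTable over fish (error-free).
    true_pedigree : DataFrame offspring/mother/father fish ids
        (founders have no parents and do not appear as offspring).
    spawn_events : DataFrame fish_id, program, spawn_year, spawn_date.
    identity_map : sample_id -> fish_id; filled by :func:`observe`.
    """

    config: SimulationConfig
    loci: list[str]
    lineage_freqs: dict[str, np.ndarray]
    fish: pd.DataFrame
    true_genotypes: GenotypeTable
    true_pedigree: pd.DataFrame
    spawn_events: pd.DataFrame
    identity_map: dict[str, str] = dataclasses.field(default_factory=dict)

    def pedigree_set(self) -> set[tuple[str, str, str]]:
        return set(
            zip(
                self.true_pedigree["offspring"],
                self.true_pedigree["mother"],
                self.true_pedigree["father"],
            )
        )

    def save(self, outdir) -> None:
        """Write the trio list as CSV and a JSON parameter echo."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.true_pedigree.to_csv(outdir / "true_pedigree.csv", index=False)
        pd.DataFrame(
            {"sample_id": list(self.identity_map), "fish_id": list(self.identity_map.values())}
        ).to_csv(outdir / "true_identity_map.csv", index=False)
        cfg = dataclasses.asdict(self.config)
        cfg["stray_matrix"] = np.asarray(cfg["stray_matrix"]).tolist()
        cfg["age_at_return_dist"] = {f"{k[0]}|{k[1]}": list(v) for k, v in cfg["age_at_return_dist"].items()}
        cfg["iteroparity_prob"] = {f"{k[0]}|{k[1]}": v for k, v in cfg["iteroparity_prob"].items()}
        cfg["repeat_spawn_prob"] = {f"{k[0]}|{k[1]}": v for k, v in cfg["repeat_spawn_prob"].items()}
        cfg["years"] = list(cfg["years"])
        with open(outdir / "simulation_params.json", "w", encoding="utf-8") as fh:
            json.dump(cfg, fh, indent=2, default=str)


def locus_names(cfg: SimulationConfig) -> list[str]:
    return [f"Omy_{i + 1:03d}" for i in range(cfg.n_loci)] + [SEX_MARKER, OMY05_MARKER]


def draw_founder_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Per-lineage allele-frequency vectors via the Balding-Nichols model.

    A shared ancestral frequency p is drawn uniformly on
    ``founder_freq_range`` per locus; each lineage then draws from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``lineage_fst``, giving lineage
    vectors correlated around the ancestral draw with tunable divergence.
    At F = 0 every lineage receives the ancestral vector unchanged.

    The returned vectors cover the autosomal loci plus the inversion
    indicator (at ``omy05_freq_R``); the sex-marker slot is NaN since that
    locus is determined by sex, not by a population frequency.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.founder_freq_range
    anc = rng.uniform(lo, hi, size=cfg.n_loci)
    f = cfg.lineage_fst
    out: dict[str, np.ndarray] = {}
    for lineage in cfg.lineages:
        if f == 0.0:
            p = anc.copy()
        else:
            scale = (1.0 - f) / f
            p = rng.beta(anc * scale, (1.0 - anc) * scale)
            p = np.clip(p, 1e-6, 1.0 - 1e-6)
        vec = np.concatenate([p, [np.nan, cfg.omy05_freq_R[lineage]]])
        out[lineage] = vec
    return out


# ---------------------------------------------------------------------------
# internal simulation state


class _Registry:
    """Grows the fish table and genotype matrix during the forward pass."""

    def __init__(self, n_loci_total: int):
        self.sex: list[str] = []
        self.natal: list[int] = []
        self.lineage: list[str] = []
        self.cohort: list[int] = []
        self.founder: list[bool] = []
        self.codes: list[np.ndarray] = []
        self.n_loci_total = n_loci_total

    def add(self, sex, natal, lineage, cohort, founder, codes) -> int:
        self.sex.append(sex)
        self.natal.append(natal)
        self.lineage.append(lineage)
        self.cohort.append(cohort)
        self.founder.append(founder)
        self.codes.append(codes)
        return len(self.sex) - 1

    def fish_id(self, idx: int) -> str:
        return f"FISH{idx:06d}"


def _hwe_draw(rng, freqs: np.ndarray, sex: str, omy_freq: float) -> np.ndarray:
    """Draw one founder genotype; freqs covers autosomal + [nan, omy05]."""
    n_aut = freqs.size - 2
    p = freqs[:n_aut]
    g = rng.binomial(1, p) + rng.binomial(1, p)
    omy = rng.binomial(1, omy_freq) + rng.binomial(1, omy_freq)
    sex_code = 0 if sex == "F" else 1  # XX vs XY
    return np.concatenate([g, [sex_code, omy]]).astype(np.int8)


def _mendel_children(rng, gm: np.ndarray, gf: np.ndarray, k: int) -> np.ndarray:
    """k offspring genotypes from mother/father codes (vectorized).

    The sex-marker locus rides along: mothers are 0 (XX) and fathers 1
    (XY), so a child is 1 (male) iff it receives the father's Y copy.
    """
    L = gm.size
    def gamete(g):
        # allele contributed per child x locus: 0 or 1 copies of B
        probs = np.where(g == 0, 0.0, np.where(g == 2, 1.0, 0.5))
        return rng.random((k, L)) < probs

    return (gamete(gm).astype(np.int8) + gamete(gf).astype(np.int8))


def _age_probs(base: np.ndarray, n_r_alleles: int, effect: float) -> np.ndarray:
    """Reweight the age-at-return distribution by the inversion effect:
    odds of age-2 multiplied by effect per R allele."""
    if effect == 1.0 or n_r_alleles == 0 or base[0] in (0.0, 1.0):
        return base
    p2 = base[0]
    odds = p2 / (1 - p2) * effect**n_r_alleles
    p2_new = odds / (1 + odds)
    out = base.copy()
    out[0] = p2_new
    out[1:] *= (1 - p2_new) / (1 - p2)
    return out


def simulate_population(cfg: SimulationConfig) -> TruthBundle:
    """Run the forward simulation and return the ground truth."""
    import logging

    log = logging.getLogger(__name__)
    rng = np.random.default_rng(cfg.seed)
    loci = locus_names(cfg)
    freqs = draw_founder_frequencies(cfg, rng)
    n_total = len(loci)
    reg = _Registry(n_total)
    programs = cfg.programs
    years = list(cfg.years)
    year_set = set(years)
    age_probs_base = {k: np.asarray(v, float) for k, v in cfg.age_at_return_dist.items()}

    # (year, program_idx) -> list of fish indices scheduled to return/spawn
    pending: dict[tuple[int, int], list[int]] = {}

    events: list[tuple[int, int, int, date]] = []  # fish_idx, prog, year, date
    pedigree: list[tuple[int, int, int]] = []

    def schedule(year: int, prog: int, fish_idx: int) -> None:
        pending.setdefault((year, prog), []).append(fish_idx)

    def new_founder(prog_idx: int, sex: str, year: int) -> int:
        spec = programs[prog_idx]
        lineage = spec.lineage_id
        g = _hwe_draw(rng, freqs[lineage], sex, cfg.omy05_freq_R[lineage])
        pseudo_age = int(rng.choice(AGES, p=age_probs_base[(lineage, sex)]))
        return reg.add(sex, prog_idx, lineage, year - pseudo_age, True, g)

    # spawning happens on discrete operating days so that a female and the
    # male(s) fertilizing her eggs share a recorded spawn date
    n_op_days = SEASON_DAYS // 5
    def op_dates(year: int) -> list[date]:
        start = season_start(year)
        return [start + timedelta(days=5 * j) for j in range(n_op_days)]

    for year in years:
        for pi, spec in enumerate(programs):
            lineage = spec.lineage_id
            returners = pending.pop((year, pi), [])
            target = spec.spawners_per_year
            # top up with founders to the program's annual target,
            # balancing sexes so pairing is possible
            n_f = sum(1 for i in returners if reg.sex[i] == "F")
            n_m = len(returners) - n_f
            spawners = list(returners)
            while n_f + n_m < target or n_f == 0 or n_m == 0:
                if n_f + n_m >= target and n_f > 0 and n_m > 0:
                    break
                sex = "F" if (n_f <= n_m) else "M"
                spawners.append(new_founder(pi, sex, year))
                if sex == "F":
                    n_f += 1
                else:
                    n_m += 1
                if target == 0 and n_f > 0 and n_m > 0:
                    break
            if not spawners or n_f == 0 or n_m == 0:
                log.warning("no usable spawner pool at %s in %d; year skipped",
                            spec.program_id, year)
                continue

            # spawn events on operating days: one event per fish, plus an
            # optional within-season repeat on a different day
            days = op_dates(year)
            def event_days(i: int, allowed: list[int]) -> list[int]:
                k = 1
                if rng.random() < cfg.repeat_spawn_prob[(reg.lineage[i], reg.sex[i])]:
                    k = 2
                replace = len(allowed) < k
                return sorted(rng.choice(allowed, size=k, replace=replace).tolist())

            males = [i for i in spawners if reg.sex[i] == "M"]
            females = [i for i in spawners if reg.sex[i] == "F"]
            male_days: dict[int, list[int]] = {}
            for i in males:
                for dj in event_days(i, list(range(len(days)))):
                    male_days.setdefault(dj, []).append(i)
            days_with_males = sorted(male_days)
            female_events: list[tuple[int, int]] = []
            for i in females:
                for dj in event_days(i, days_with_males):
                    female_events.append((i, dj))

            for dj, ms in sorted(male_days.items()):
                for i in ms:
                    events.append((i, pi, year, days[dj]))
            for i, dj in female_events:
                events.append((i, pi, year, days[dj]))

            # matings: each female event fertilized by 1 or 2 males
            # spawning on the same operating day
            n_mates = 1 if spec.mating_rule == "one_male" else 2
            for mother, dj in female_events:
                avail = male_days[dj]
                if n_mates == 1 or len(set(avail)) == 1:
                    mates = [avail[int(rng.integers(len(avail)))]]
                else:
                    mates = []
                    while len(mates) < 2:
                        m = avail[int(rng.integers(len(avail)))]
                        if m not in mates:
                            mates.append(m)
                for father in mates:
                    k = int(
                        rng.negative_binomial(
                            cfg.offspring_per_pair_dispersion,
                            cfg.offspring_per_pair_dispersion
                            / (cfg.offspring_per_pair_dispersion + cfg.offspring_per_pair_mean),
                        )
                    )
                    if k == 0:
                        continue
                    kids = _mendel_children(rng, reg.codes[mother], reg.codes[father], k)
                    for kid_codes in kids:
                        sex = "M" if kid_codes[n_total - 2] == 1 else "F"
                        base = age_probs_base[(lineage, sex)]
                        probs = _age_probs(
                            base, int(kid_codes[n_total - 1]), cfg.omy05_age_effect[lineage]
                        )
                        age = int(rng.choice(AGES, p=probs))
                        ret_year = year + age
                        if ret_year not in year_set:
                            continue  # returns outside the study window
                        ci = reg.add(sex, pi, lineage, year, False, kid_codes)
                        pedigree.append((ci, mother, father))
                        ret_prog = int(rng.choice(len(programs), p=cfg.stray_matrix[pi]))
                        schedule(ret_year, ret_prog, ci)

            # iteroparity: re-entry in the following season at the same program
            for i in set(spawners):
                if rng.random() < cfg.iteroparity_prob[(reg.lineage[i], reg.sex[i])]:
                    nxt = year + 1
                    if nxt in year_set:
                        schedule(nxt, pi, i)

    fish_ids = [reg.fish_id(i) for i in range(len(reg.sex))]
    fish = pd.DataFrame(
        {
            "fish_id": fish_ids,
            "sex": reg.sex,
            "natal_program": [programs[p].program_id for p in reg.natal],
            "lineage": reg.lineage,
            "cohort_year": reg.cohort,
            "is_founder": reg.founder,
        }
    )
    gt = GenotypeTable(fish_ids, loci, np.vstack(reg.codes) if reg.codes else
                       np.empty((0, n_total), dtype=np.int8))
    ped = pd.DataFrame(
        [(fish_ids[o], fish_ids[m], fish_ids[f]) for o, m, f in pedigree],
        columns=["offspring", "mother", "father"],
    )
    ev = pd.DataFrame(
        [(fish_ids[i], programs[p].program_id, y, d) for i, p, y, d in events],
        columns=["fish_id", "program", "spawn_year", "spawn_date"],
    )
    return TruthBundle(cfg, loci, freqs, fish, gt, ped, ev)


# ---------------------------------------------------------------------------
# observation model


def _apply_genotyping_error(rng, codes: np.ndarray, eps: float) -> np.ndarray:
    """Flip each gene copy independently with probability eps."""
    if eps == 0.0:
        return codes.copy()
    # emission cdf rows indexed by true code
    e = eps
    table = np.array(
        [
            [(1 - e) ** 2, 2 * e * (1 - e), e**2],
            [e * (1 - e), (1 - e) ** 2 + e**2, e * (1 - e)],
            [e**2, 2 * e * (1 - e), (1 - e) ** 2],
        ]
    )
    cdf = table.cumsum(axis=1)
    u = rng.random(codes.shape)
    out = (u[..., None] > cdf[codes]).sum(axis=-1).astype(np.int8)
    return out


def observe(
    truth: TruthBundle, cfg: SimulationConfig | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Emit the observed dataset: one sample row per spawn event.

    Genotypes carry per-gene-copy error and missing calls; phenotypic sex
    and spawn date carry rare recording errors.  The genetic-sex column is
    read off the *observed* sex-marker call (it reflects the true sex up
    to genotyping error, never metadata error).  Fills
    ``truth.identity_map``.
    """
    if cfg is None:
        cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    ev = truth.spawn_events.reset_index(drop=True)
    n = len(ev)
    fish_idx = truth.true_genotypes.index_of(ev["fish_id"])
    true_codes = truth.true_genotypes.codes[fish_idx]
    obs = _apply_genotyping_error(rng, true_codes, cfg.epsilon_sim)
    if cfg.missing_rate > 0:
        miss = rng.random(obs.shape) < cfg.missing_rate
        obs[miss] = MISSING

    sample_ids = [f"S{i:06d}" for i in range(n)]
    truth.identity_map = dict(zip(sample_ids, ev["fish_id"]))

    sex_col = truth.loci.index(SEX_MARKER)
    sex_call = obs[:, sex_col]
    genetic_sex = np.where(
        sex_call == MISSING, "unknown", np.where(sex_call == 0, "F", "M")
    )

    true_sex = truth.fish.set_index("fish_id")["sex"].reindex(ev["fish_id"]).to_numpy()
    flip = rng.random(n) < cfg.meta_error_sex_rate
    pheno_sex = np.where(flip, np.where(true_sex == "F", "M", "F"), true_sex)

    dates = list(ev["spawn_date"])
    perturb = rng.random(n) < cfg.meta_error_date_rate
    for i in np.flatnonzero(perturb):
        start = season_start(int(ev.loc[i, "spawn_year"]))
        dates[i] = start + timedelta(days=int(rng.integers(0, SEASON_DAYS)))

    cohort = truth.fish.set_index("fish_id")["cohort_year"].reindex(ev["fish_id"]).to_numpy()
    age = ev["spawn_year"].to_numpy() - cohort
    length = rng.normal(550.0 + 80.0 * (age - 2), 40.0).round(0)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "program": ev["program"],
            "spawn_date": dates,
            "spawn_year": ev["spawn_year"],
            "phenotypic_sex": pheno_sex,
            "genetic_sex": genetic_sex,
            "length_mm": length,
            "adipose_present": False,
        }
    )
    gt = GenotypeTable(sample_ids, list(truth.loci), obs)
    return gt, samples


def write_dataset(gt: GenotypeTable, samples: pd.DataFrame, outdir, seed: int) -> None:
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt.to_csv(outdir / "genotypes.csv", seed=seed)
    write_sample_table(samples, outdir / "samples.csv", seed=seed)
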