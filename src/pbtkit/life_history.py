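"""Pedigree- and cluster-derived life-history summaries.

Spawning-use classification (once / repeat within a season / iteroparous
across seasons), age at spawning from parent-offspring trios, spawn-date
binning, straying matrices, observed reproductive success, inversion-
karyotype summaries with exact HWE and 1:2:1 segregation tests, and the
rank/contingency tests used on these tables.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from .identity import IndividualCluster
from .parentage import Pedigree
from .popgen import HWEResult, hwe_exact

log = logging.getLogger(__name__)

USE_ONCE = "once"
USE_REPEAT = "repeat"
USE_ITERO = "iteroparous"
USE_BOTH = "repeat_and_iteroparous"


@dataclasses.dataclass
class SpawnUseRecord:
    fish_id: str
    programs: list[str]
    use: str
    n_events: int
    sex: str
    years: list[int]


def classify_spawn_use(
    clusters: list[IndividualCluster],
) -> tuple[list[SpawnUseRecord], pd.DataFrame]:
    """Classify each fish's spawning use and tabulate counts by program.

    A fish with one event spawned ``once``; events in two or more seasons
    make it ``iteroparous``; two or more events within one season make it
    a ``repeat`` spawner; both patterns earn the combined label.  The
    count table is use-exclusive: the combined label is counted as
    iteroparous there (logged), so each fish contributes once per program
    it spawned at (cross-program fish are flagged).
    """
    records = []
    rows = []
    n_both = 0
    for c in clusters:
        per_year = Counter(e.spawn_year for e in c.spawn_events)
        years = sorted(per_year)
        itero = len(years) >= 2
        repeat = any(v >= 2 for v in per_year.values())
        if itero and repeat:
            use = USE_BOTH
            n_both += 1
        elif itero:
            use = USE_ITERO
        elif repeat:
            use = USE_REPEAT
        else:
            use = USE_ONCE
        programs = c.programs
        records.append(
            SpawnUseRecord(c.fish_id, programs, use, c.n_events, c.resolved_sex, years)
        )
        table_use = USE_ITERO if use == USE_BOTH else use
        for prog in programs:
            rows.append(
                {"program": prog, "sex": c.resolved_sex, "use": table_use,
                 "fish_id": c.fish_id, "cross_program": len(programs) > 1}
            )
    if n_both:
        log.info("%d fish both repeat and iteroparous; counted as iteroparous "
                 "in the use table", n_both)
    long = pd.DataFrame(rows)
    counts = (
        long.groupby(["program", "sex", "use"]).size().rename("count").reset_index()
        if len(long)
        else pd.DataFrame(columns=["program", "sex", "use", "count"])
    )
    return records, counts


def use_percentages(counts: pd.DataFrame, by_sex: bool = False) -> pd.DataFrame:
    """Percentages of each use per program (or per sex within program),
    with the program (or sex-within-program) totals as denominators."""
    keys = ["program", "sex"] if by_sex else ["program"]
    g = counts.groupby(keys + ["use"])["count"].sum().reset_index()
    totals = g.groupby(keys)["count"].transform("sum")
    g["percent"] = 100.0 * g["count"] / totals
    return g


# ---------------------------------------------------------------------------
# ages


def tabulate_ages(
    pedigree: Pedigree,
    cluster_info: pd.DataFrame,
    sampling_years: tuple[int, int] | None = None,
    min_age: int = 2,
) -> pd.DataFrame:
    """Age records per assigned offspring.

    Age = offspring spawn year - parent spawn year (the parents' spawn
    year is the offspring's cohort year; both parents share it by
    construction).  ``cluster_info`` maps fish_id to program and sex.
    When the sampling window is given, a censoring note is logged for
    return years within ``min_age`` of its edges (offspring returning at
    other ages cannot have both a sampled parent and a sampled return
    there).
    """
    t = pedigree.trios
    info = cluster_info.set_index("fish_id")
    ages = pd.DataFrame(
        {
            "offspring_fish": t["offspring"],
            "age": t["spawn_year"] - t["parent_year"],
            "cohort_year": t["parent_year"],
            "return_year": t["spawn_year"],
            "program": info["program"].reindex(t["offspring"]).to_numpy(),
            "sex": info["resolved_sex"].reindex(t["offspring"]).to_numpy(),
        }
    )
    if (ages["age"] < 1).any():
        raise AssertionError("age < 1 in pedigree; improbable-trio removal missed it")
    if sampling_years is not None:
        first, last = sampling_years
        edge = ages["return_year"].isin(
            list(range(first, first + min_age)) + [last]
        )
        if edge.any():
            log.info(
                "%d age records fall in return years censored by the sampling "
                "window [%d, %d]; age mixtures there are truncated",
                int(edge.sum()), first, last,
            )
    return ages


def age_distribution(ages: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Counts and row percentages of age by the given grouping columns."""
    g = ages.groupby(by + ["age"]).size().rename("count").reset_index()
    totals = g.groupby(by)["count"].transform("sum")
    g["percent"] = 100.0 * g["count"] / totals
    return g


def size_at_age(ages: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Counts of each age across recorded lengths (mm) by program."""
    df = ages.copy()
    df["length_mm"] = lengths.reindex(df["offspring_fish"]).to_numpy()
    return (
        df.dropna(subset=["length_mm"])
        .groupby(["program", "age"])["length_mm"]
        .agg(["count", "mean", "std"])
        .reset_index()
    )


# ---------------------------------------------------------------------------
# spawn-date bins


def bin_spawn_dates(events: pd.DataFrame, bin_days: int = 5) -> pd.DataFrame:
    """Bin spawn dates into half-open ``bin_days`` units.

    Bins are [start, start + bin_days) anchored at each program's earliest
    event date within each season; the bin label is the bin start date.
    """
    if bin_days <= 0:
        raise ValueError("bin_days must be positive")
    df = events.copy()
    df["spawn_date"] = pd.to_datetime(df["spawn_date"])
    anchor = df.groupby(["program", "spawn_year"])["spawn_date"].transform("min")
    offset = (df["spawn_date"] - anchor).dt.days
    df["bin_index"] = offset // bin_days
    df["bin_start"] = (anchor + pd.to_timedelta(df["bin_index"] * bin_days, unit="D")).dt.date
    keys = [k for k in ("program", "spawn_year", "sex", "age") if k in df.columns]
    return (
        df.groupby(keys + ["bin_start"]).size().rename("count").reset_index()
    )


# ---------------------------------------------------------------------------
# straying


def straying_matrix(
    pedigree: Pedigree, origin: pd.Series, return_program: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Origin-program x return-program counts and column percentages.

    Origin is the program where the parents were sampled; a stray returned
    to a different program.  Percentages are per origin-program total
    (column percentages in the origin-by-return layout).
    """
    t = pedigree.trios
    df = pd.DataFrame(
        {
            "origin": origin.reindex(t["mother"]).to_numpy(),
            "return": return_program.reindex(t["offspring"]).to_numpy(),
        }
    )
    counts = (
        df.groupby(["return", "origin"]).size().unstack("origin", fill_value=0)
    )
    rates = 100.0 * counts / counts.sum(axis=0)
    return counts, rates


# ---------------------------------------------------------------------------
# reproductive success


def reproductive_success(
    pedigree: Pedigree, records: list[SpawnUseRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean observed offspring counts by sex and spawning-use type.

    Per-event means divide each fish's assigned offspring by its event
    count; fish with no assigned offspring contribute zeros.  Multi-event
    fish recorded as different sexes across events were already removed
    by identity validation.
    """
    t = pedigree.trios
    n_off = pd.concat([t["mother"], t["father"]]).value_counts()
    rows = []
    for r in records:
        k = int(n_off.get(r.fish_id, 0))
        rows.append(
            {
                "fish_id": r.fish_id,
                "sex": r.sex,
                "use": r.use,
                "n_events": r.n_events,
                "n_offspring": k,
                "per_event": k / r.n_events,
            }
        )
    per_fish = pd.DataFrame(rows)
    summary = (
        per_fish.groupby(["sex", "use"])
        .agg(
            n_fish=("fish_id", "size"),
            mean_total=("n_offspring", "mean"),
            mean_per_event=("per_event", "mean"),
        )
        .reset_index()
    )
    return per_fish, summary


# ---------------------------------------------------------------------------
# inversion karyotype


@dataclasses.dataclass
class SegregationTest:
    n_AA: int
    n_AR: int
    n_RR: int
    statistic: float
    df: int
    p_value: float
    method: str


def omy05_frequency_table(karyo: pd.DataFrame) -> pd.DataFrame:
    """Karyotype counts and percentages by program (and sex when present).

    ``karyo`` needs fish_id, karyotype in {AA, AR, RR}, program, and
    optionally sex.
    """
    keys = [k for k in ("program", "sex") if k in karyo.columns]
    g = karyo.groupby(keys + ["karyotype"]).size().rename("count").reset_index()
    totals = g.groupby(keys)["count"].transform("sum")
    g["percent"] = 100.0 * g["count"] / totals
    return g


def omy05_hwe_by_program(karyo: pd.DataFrame) -> dict[str, HWEResult]:
    out = {}
    for prog, sub in karyo.groupby("program"):
        c = sub["karyotype"].value_counts()
        out[prog] = hwe_exact(int(c.get("AA", 0)), int(c.get("AR", 0)), int(c.get("RR", 0)))
    return out


def segregation_test(n_AA: int, n_AR: int, n_RR: int) -> SegregationTest:
    """Goodness of fit of offspring karyotypes from AR x AR matings to the
    Mendelian 1:2:1 expectation.

    Chi-square with 2 df; when any expected cell count falls below 5 an
    exact multinomial test is substituted (noted in ``method``).
    """
    obs = np.array([n_AA, n_AR, n_RR], dtype=float)
    n = obs.sum()
    if n == 0:
        raise ValueError("no offspring")
    expected = n * np.array([0.25, 0.5, 0.25])
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    if (expected < 5).any():
        p = _exact_multinomial_p(obs.astype(int), np.array([0.25, 0.5, 0.25]))
        return SegregationTest(n_AA, n_AR, n_RR, chi2, 2, p, "exact_multinomial")
    p = float(stats.chi2.sf(chi2, df=2))
    return SegregationTest(n_AA, n_AR, n_RR, chi2, 2, p, "chi_square")


def _exact_multinomial_p(obs: np.ndarray, probs: np.ndarray) -> float:
    """Two-sided exact multinomial p: total probability of outcomes no more
    likely than the observed one (small n only)."""
    n = int(obs.sum())
    p_obs = stats.multinomial.pmf(obs, n, probs)
    total = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            p = stats.multinomial.pmf([a, b, c], n, probs)
            if p <= p_obs * (1 + 1e-12):
                total += p
    return min(float(total), 1.0)


def ar_cross_offspring(pedigree: Pedigree, karyotype: pd.Series) -> pd.DataFrame:
    """Offspring of AR x AR parent pairs, with their own karyotypes."""
    t = pedigree.trios
    km = karyotype.reindex(t["mother"]).to_numpy()
    kf = karyotype.reindex(t["father"]).to_numpy()
    ko = karyotype.reindex(t["offspring"]).to_numpy()
    sel = (km == "AR") & (kf == "AR") & pd.notna(ko)
    return pd.DataFrame({"offspring": t.loc[sel, "offspring"], "karyotype": ko[sel]})


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(*groups) -> tuple[float, int, float]:
    """Kruskal-Wallis rank-sum H with tie correction; chi-square p-value.

    Returns (H, df, p).  All-identical values give H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, len(groups) - 1, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)
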