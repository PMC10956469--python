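"""Life-history summaries: spawning use, ages, date bins, straying,
reproductive success, inversion-karyotype tests, rank tests."""

import datetime

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pbtkit.identity import IndividualCluster, SpawnEvent
from pbtkit.life_history import (
    age_distribution,
    ar_cross_offspring,
    bin_spawn_dates,
    classify_spawn_use,
    kruskal_wallis,
    reproductive_success,
    segregation_test,
    straying_matrix,
    tabulate_ages,
    use_percentages,
)
from pbtkit.parentage import Pedigree


def _cluster(fish_id, events, sex="F"):
    evs = [SpawnEvent(f"{fish_id}e{i}", p, d, y) for i, (p, d, y) in enumerate(events)]
    return IndividualCluster(fish_id, [e.sample_id for e in evs], evs[0].sample_id, sex, evs)


D = datetime.date


def test_classify_spawn_use_definitions():
    clusters = [
        _cluster("once", [("CH", D(2013, 1, 5), 2013)]),
        _cluster("rep", [("CH", D(2013, 1, 5), 2013), ("CH", D(2013, 2, 10), 2013)]),
        _cluster("itero", [("CH", D(2013, 1, 5), 2013), ("CH", D(2015, 1, 9), 2015)]),
        _cluster(
            "both",
            [
                ("CH", D(2013, 1, 5), 2013),
                ("CH", D(2013, 2, 1), 2013),
                ("CH", D(2014, 1, 7), 2014),
            ],
        ),
    ]
    records, counts = classify_spawn_use(clusters)
    uses = {r.fish_id: r.use for r in records}
    assert uses == {
        "once": "once",
        "rep": "repeat",
        "itero": "iteroparous",
        "both": "repeat_and_iteroparous",
    }
    # the use table is use-exclusive: combined counts as iteroparous
    table = counts.groupby("use")["count"].sum().to_dict()
    assert table == {"once": 1, "repeat": 1, "iteroparous": 2}


def _make_use_counts(program, itero, once, repeat):
    return pd.DataFrame(
        {
            "program": [program] * 3,
            "sex": ["F"] * 3,
            "use": ["iteroparous", "once", "repeat"],
            "count": [itero, once, repeat],
        }
    )


def test_use_percentages_published_iteroparity_rate():
    """Iteroparous 364 of (364 + 1829 + 304) spawners: 14.58%, the highest
    program-level iteroparity in the system."""
    pct = use_percentages(_make_use_counts("MRH", 364, 1829, 304))
    val = pct.set_index("use").loc["iteroparous", "percent"]
    assert val == pytest.approx(14.58, abs=0.01)


def test_tabulate_ages_and_distribution():
    trios = pd.DataFrame(
        {
            "offspring": ["K1", "K2"],
            "mother": ["M", "M"],
            "father": ["F", "F"],
            "parent_year": [2015, 2011],
            "spawn_year": [2018, 2013],
            "provenance": ["both_runs"] * 2,
        }
    )
    info = pd.DataFrame(
        {"fish_id": ["K1", "K2"], "program": ["CH", "CH"], "resolved_sex": ["F", "M"]}
    )
    ped = Pedigree(trios, pd.DataFrame(columns=["offspring", "reason"]))
    ages = tabulate_ages(ped, info)
    assert dict(zip(ages["offspring_fish"], ages["age"])) == {"K1": 3, "K2": 2}
    dist = age_distribution(ages, ["program"])
    assert dist["percent"].sum() == pytest.approx(100.0)


def test_all_parents_one_year_gives_single_age_class():
    trios = pd.DataFrame(
        {
            "offspring": [f"K{i}" for i in range(10)],
            "mother": ["M"] * 10,
            "father": ["F"] * 10,
            "parent_year": [2012] * 10,
            "spawn_year": [2014] * 10,
            "provenance": ["both_runs"] * 10,
        }
    )
    info = pd.DataFrame(
        {
            "fish_id": [f"K{i}" for i in range(10)],
            "program": ["CH"] * 10,
            "resolved_sex": ["F"] * 10,
        }
    )
    ages = tabulate_ages(Pedigree(trios, pd.DataFrame()), info)
    dist = age_distribution(ages, ["program"])
    assert len(dist) == 1 and dist.iloc[0]["age"] == 2 and dist.iloc[0]["percent"] == 100.0


def test_bin_spawn_dates_half_open_convention():
    ev = pd.DataFrame(
        {
            "program": ["CH"] * 3,
            "spawn_year": [2013] * 3,
            "spawn_date": [D(2012, 12, 1), D(2012, 12, 5), D(2012, 12, 6)],
        }
    )
    out = bin_spawn_dates(ev, bin_days=5)
    bins = dict(zip(out["bin_start"], out["count"]))
    assert bins == {D(2012, 12, 1): 2, D(2012, 12, 6): 1}


def test_bin_10_days_halves_bin_count():
    days = [D(2012, 12, 1) + datetime.timedelta(days=i) for i in range(60)]
    ev = pd.DataFrame(
        {"program": ["CH"] * 60, "spawn_year": [2013] * 60, "spawn_date": days}
    )
    b5 = bin_spawn_dates(ev, 5)
    b10 = bin_spawn_dates(ev, 10)
    assert len(b5) == 12 and len(b10) == 6


def test_uniform_dates_give_uniform_bins(rng):
    days = [D(2012, 12, 1) + datetime.timedelta(days=int(d))
            for d in rng.integers(0, 60, size=1200)]
    ev = pd.DataFrame(
        {"program": ["CH"] * 1200, "spawn_year": [2013] * 1200, "spawn_date": days}
    )
    out = bin_spawn_dates(ev, 10)
    p = stats.chisquare(out["count"]).pvalue
    assert p > 0.001


def _toy_pedigree_counts(counts_by_origin_return):
    rows = []
    fish_prog = {}
    k = 0
    for (orig, ret), n in counts_by_origin_return.items():
        for _ in range(n):
            o, m, f = f"K{k}", f"M{k}", f"F{k}"
            fish_prog[o] = ret
            fish_prog[m] = orig
            fish_prog[f] = orig
            rows.append(
                {
                    "offspring": o,
                    "mother": m,
                    "father": f,
                    "parent_year": 2012,
                    "spawn_year": 2014,
                    "provenance": "both_runs",
                }
            )
            k += 1
    ped = Pedigree(pd.DataFrame(rows), pd.DataFrame())
    prog = pd.Series(fish_prog)
    return ped, prog


def test_straying_matrix_published_stray_rate():
    """A program whose offspring return (2, 37, 1704, 182) to the four
    hatcheries sends 9.5% of its returns to the fourth one."""
    ped, prog = _toy_pedigree_counts(
        {
            ("MRH", "CH"): 2,
            ("MRH", "FRH"): 37,
            ("MRH", "MRH"): 1704,
            ("MRH", "NH"): 182,
        }
    )
    counts, rates = straying_matrix(ped, prog, prog)
    assert counts.loc["NH", "MRH"] == 182
    assert rates.loc["NH", "MRH"] == pytest.approx(9.45, abs=0.06)
    assert rates["MRH"].sum() == pytest.approx(100.0)


def test_straying_matrix_toy_percentages():
    ped, prog = _toy_pedigree_counts({("A", "A"): 9, ("A", "B"): 1})
    counts, rates = straying_matrix(ped, prog, prog)
    assert rates.loc["A", "A"] == pytest.approx(90.0)
    assert rates.loc["B", "A"] == pytest.approx(10.0)


def test_reproductive_success_per_event_and_total():
    trios = pd.DataFrame(
        {
            "offspring": ["K1", "K2", "K3", "K4"],
            "mother": ["MOM"] * 4,
            "father": ["F1", "F1", "F2", "F2"],
            "parent_year": [2012] * 4,
            "spawn_year": [2014] * 4,
            "provenance": ["both_runs"] * 4,
        }
    )
    from pbtkit.life_history import SpawnUseRecord

    records = [
        SpawnUseRecord("MOM", ["CH"], "iteroparous", 2, "F", [2012, 2013]),
        SpawnUseRecord("ZERO", ["CH"], "once", 1, "F", [2012]),
    ]
    per_fish, summary = reproductive_success(
        Pedigree(trios, pd.DataFrame()), records
    )
    row = per_fish.set_index("fish_id").loc["MOM"]
    assert row["n_offspring"] == 4 and row["per_event"] == 2.0
    zero = per_fish.set_index("fish_id").loc["ZERO"]
    assert zero["n_offspring"] == 0  # contributes zero, not excluded


def test_segregation_balanced_and_near_balanced():
    t = segregation_test(100, 200, 100)
    assert t.statistic == 0.0 and t.p_value == pytest.approx(1.0)
    t2 = segregation_test(116, 233, 116)
    assert t2.statistic == pytest.approx(0.0021505, abs=1e-4)
    assert t2.df == 2


def test_segregation_small_counts_use_exact_test():
    t = segregation_test(3, 6, 2)
    assert t.method == "exact_multinomial"
    assert 0 < t.p_value <= 1


def test_segregation_detects_rr_deficit():
    """A strong deficit of one homozygote class rejects 1:2:1."""
    t = segregation_test(140, 240, 60)
    assert t.p_value < 0.001


def test_ar_cross_offspring_selects_heterozygous_matings():
    trios = pd.DataFrame(
        {
            "offspring": ["K1", "K2"],
            "mother": ["M1", "M2"],
            "father": ["F1", "F2"],
            "parent_year": [2012] * 2,
            "spawn_year": [2014] * 2,
            "provenance": ["both_runs"] * 2,
        }
    )
    karyo = pd.Series(
        {"M1": "AR", "F1": "AR", "K1": "RR", "M2": "AA", "F2": "AR", "K2": "AR"}
    )
    out = ar_cross_offspring(Pedigree(trios, pd.DataFrame()), karyo)
    assert list(out["offspring"]) == ["K1"]


def test_kruskal_wallis_hand_values():
    h, df, p = kruskal_wallis([1, 2, 3], [1, 2, 3])
    assert h == pytest.approx(0.0, abs=1e-12)
    h2, df2, p2 = kruskal_wallis([1, 2, 3], [4, 5, 6])
    assert h2 == pytest.approx(3.857142857, abs=1e-6)
    assert df2 == 1


def test_kruskal_wallis_identical_values():
    h, df, p = kruskal_wallis([2, 2], [2, 2, 2])
    assert h == 0.0 and p == 1.0


def test_kruskal_wallis_null_p_uniform(rng):
    ps = []
    for _ in range(400):
        a, b = rng.normal(size=8), rng.normal(size=8)
        ps.append(kruskal_wallis(a, b)[2])
    ps = np.array(ps)
    assert 0.4 < ps.mean() < 0.6
    assert 0.01 <= (ps < 0.05).mean() <= 0.12
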