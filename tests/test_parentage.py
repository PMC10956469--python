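"""Trio-likelihood engine: error kernel, LOD oracle, MAP categories,
candidate pools, FDR machinery, reconciliation and improbable-trio removal."""

import datetime
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from pbtkit.config import ParentageConfig
from pbtkit.data import MISSING, GenotypeTable
from pbtkit.parentage import (
    ParentageModel,
    ParentageResults,
    Pedigree,
    build_tables,
    estimate_allele_freqs,
    genotype_error_kernel,
    reconcile_runs,
    remove_improbable_trios,
    trio_lod,
)

# ---------------------------------------------------------------------------
# exhaustive enumeration oracle


def trio_lod_oracle(oo, om, of, freqs, eps):
    """Trio LOD by explicit enumeration over all 27 true-genotype
    configurations per locus (loop transcription, no shared code path)."""

    def hwe(q):
        return [(1 - q) ** 2, 2 * q * (1 - q), q**2]

    def transmit(g):
        return [0.0, 0.5, 1.0][g]

    def mendel(gm, gf, go):
        tm, tf = transmit(gm), transmit(gf)
        return [
            (1 - tm) * (1 - tf),
            tm * (1 - tf) + tf * (1 - tm),
            tm * tf,
        ][go]

    E = genotype_error_kernel(eps)
    total = 0.0
    for l, q in enumerate(freqs):
        if MISSING in (oo[l], om[l], of[l]):
            continue
        pr = hwe(q)
        lp = lu = 0.0
        for gm in range(3):
            for gf in range(3):
                for go in range(3):
                    base = pr[gm] * pr[gf] * E[gm, om[l]] * E[gf, of[l]] * E[go, oo[l]]
                    lp += base * mendel(gm, gf, go)
                    lu += base * pr[go]
        total += np.log10(lp / lu)
    return total


@pytest.mark.parametrize("eps", [0.005, 0.05])
def test_trio_lod_matches_exhaustive_enumeration(eps, rng):
    freqs = np.array([0.3, 0.5, 0.8])
    for _ in range(40):
        om = rng.integers(0, 4, size=3)
        of = rng.integers(0, 4, size=3)
        oo = rng.integers(0, 4, size=3)
        lod, _, _ = trio_lod(oo, om, of, freqs, eps)
        assert lod == pytest.approx(trio_lod_oracle(oo, om, of, freqs, eps), abs=1e-10)


def test_trio_lod_one_locus_hand_value():
    """Parents AA x AA with offspring AA at p = 0.5: as the error rate
    vanishes the per-locus LOD approaches log10(1 / 0.25)."""
    z = np.array([0])
    lod, flags, n = trio_lod(z, z, z, np.array([0.5]), 1e-9)
    assert lod == pytest.approx(np.log10(4.0), abs=1e-6)
    assert not flags.any() and n == 1


def test_trio_lod_mendelian_impossibility():
    """Parents AA x AA with offspring BB: the LOD collapses (finite only
    through the error terms) and the incompatibility flag is set."""
    aa = np.array([0])
    bb = np.array([2])
    lod, flags, _ = trio_lod(bb, aa, aa, np.array([0.5]), 0.005)
    assert lod < -3
    assert flags[0]


def test_trio_lod_missing_locus_contributes_zero():
    freqs = np.array([0.4, 0.4])
    full, _, _ = trio_lod(np.array([0, 0]), np.array([0, 0]), np.array([0, 0]), freqs, 0.01)
    part, _, n = trio_lod(
        np.array([0, MISSING]), np.array([0, 0]), np.array([0, 0]), freqs, 0.01
    )
    single, _, _ = trio_lod(np.array([0]), np.array([0]), np.array([0]), freqs[:1], 0.01)
    assert n == 1
    assert part == pytest.approx(single)
    assert part != pytest.approx(full)


# ---------------------------------------------------------------------------
# error kernel and frequency estimation


def test_error_kernel_values_and_normalization():
    e = 0.01
    K = genotype_error_kernel(e)
    assert K[0, 0] == pytest.approx((1 - e) ** 2)
    assert K[0, 1] == pytest.approx(2 * e * (1 - e))
    assert K[0, 2] == pytest.approx(e**2)
    assert np.allclose(K.sum(axis=1), 1.0, atol=1e-14)


def test_estimate_allele_freqs_counts_and_monomorphic_flag():
    codes = np.array([[0, 0], [1, 0]], dtype=np.int8)  # {AA, AB} and {AA, AA}
    freqs, poly = estimate_allele_freqs(codes)
    assert freqs[0] == pytest.approx(0.25)  # p_B; p_A = 0.75
    assert poly[0]
    assert not poly[1]  # monomorphic


def test_estimate_allele_freqs_recovers_truth_within_binomial_se(rng):
    p = rng.uniform(0.2, 0.8, size=92)
    n = 1000
    codes = ((rng.random((n, 92)) < p).astype(np.int8) + (rng.random((n, 92)) < p)).astype(np.int8)
    freqs, _ = estimate_allele_freqs(codes)
    se = np.sqrt(p * (1 - p) / (2 * n))
    assert np.mean(np.abs(freqs - p) <= 4 * se) >= 0.95


# ---------------------------------------------------------------------------
# micro-dataset model behaviour


def _micro_model(mode="constrained", **cfg_kw):
    """Two adults (one pair) in 2011 and one Mendelian-perfect offspring
    in 2013, on a 60-locus panel at p = 0.5."""
    rng = np.random.default_rng(99)
    L = 60
    gm = rng.integers(0, 3, size=L).astype(np.int8)
    gf = rng.integers(0, 3, size=L).astype(np.int8)

    def gamete(g):
        return np.where(g == 0, 0, np.where(g == 2, 1, rng.integers(0, 2, size=L)))

    go = (gamete(gm) + gamete(gf)).astype(np.int8)
    # background adults so allele frequencies are estimable
    extra = rng.integers(0, 3, size=(20, L)).astype(np.int8)
    ids = ["MOM", "DAD", "KID"] + [f"X{i}" for i in range(20)]
    codes = np.vstack([gm, gf, go, extra])
    gt = GenotypeTable(ids, [f"L{i}" for i in range(L)], codes)
    d = datetime.date(2010, 12, 15)
    fish = pd.DataFrame(
        {
            "fish_id": ids,
            "resolved_sex": ["F", "M", "F"] + ["F", "M"] * 10,
            "first_spawn_year": [2011, 2011, 2013] + [2011] * 20,
        }
    )
    events = pd.DataFrame(
        {
            "fish_id": [f for f in ids],
            "spawn_year": [2011, 2011, 2013] + [2011] * 20,
            "spawn_date": [d, d, datetime.date(2012, 12, 20)] + [d] * 20,
        }
    )
    cfg = ParentageConfig(null_sim_size=4000, min_loci_for_trio=30, **cfg_kw)
    return ParentageModel(gt, fish, events, cfg, mode)


def test_perfect_trio_assigned_parent_pair():
    res = _micro_model().fit(seed=3)
    row = res.assignments.set_index("offspring").loc["KID"]
    assert row["map_category"] == "parent_pair"
    assert {row["mother"], row["father"]} == {"MOM", "DAD"}
    assert row["mother"] == "MOM"  # ordered by resolved sex
    assert row["parent_year"] == 2011
    assert row["q"] <= 0.01


def test_allowed_age_gap_defines_parent_years():
    """Offspring spawning in 2013 with gap [2, 6] can only draw parents
    from 2007-2011; with gap [3, 6] the 2011 adults are out of range."""
    res = _micro_model(allowed_age_gap=(3, 6)).fit(seed=3)
    row = res.assignments.set_index("offspring").loc["KID"]
    assert row["map_category"] == "unassignable"


def test_constrained_mode_requires_opposite_sex_same_date():
    m = _micro_model()
    fish = m.fish.copy()
    fish.loc[fish["fish_id"] == "DAD", "resolved_sex"] = "F"  # now two females
    m2 = ParentageModel(m.genotypes, fish, m.events, m.config, "constrained")
    row = m2.fit(seed=3).assignments.set_index("offspring").loc["KID"]
    assert not (
        row["map_category"] == "parent_pair"
        and {row.get("mother"), row.get("father")} == {"MOM", "DAD"}
    )


def test_unconstrained_mode_ignores_sex_for_pairing():
    m = _micro_model("unconstrained")
    fish = m.fish.copy()
    fish.loc[fish["fish_id"] == "DAD", "resolved_sex"] = "F"
    m2 = ParentageModel(m.genotypes, fish, m.events, m.config, "unconstrained")
    row = m2.fit(seed=3).assignments.set_index("offspring").loc["KID"]
    assert row["map_category"] == "parent_pair"
    assert {row["mother"], row["father"]} == {"MOM", "DAD"}


def test_iteroparous_adult_in_both_year_pools():
    """An adult spawning in 2011 and 2013 is a candidate parent for
    offspring born in either year."""
    m = _micro_model()
    events = pd.concat(
        [
            m.events,
            pd.DataFrame(
                {
                    "fish_id": ["MOM", "DAD"],
                    "spawn_year": [2013, 2013],
                    "spawn_date": [datetime.date(2012, 12, 20)] * 2,
                }
            ),
        ],
        ignore_index=True,
    )
    fish = pd.concat(
        [
            m.fish,
            pd.DataFrame(
                {"fish_id": ["KID2"], "resolved_sex": ["M"], "first_spawn_year": [2015]}
            ),
        ],
        ignore_index=True,
    )
    # KID2 shares KID's genotype pattern: make it a child of the same pair
    rng = np.random.default_rng(7)
    gm = m.genotypes.codes[m._fish_index["MOM"]]
    gf = m.genotypes.codes[m._fish_index["DAD"]]
    L = len(m.genotypes.loci)

    def gamete(g):
        return np.where(g == 0, 0, np.where(g == 2, 1, rng.integers(0, 2, size=L)))

    kid2 = (gamete(gm) + gamete(gf)).astype(np.int8)
    gt = GenotypeTable(
        m.genotypes.sample_ids + ["KID2"],
        m.genotypes.loci,
        np.vstack([m.genotypes.codes, kid2]),
    )
    events2 = pd.concat(
        [
            events,
            pd.DataFrame(
                {
                    "fish_id": ["KID2"],
                    "spawn_year": [2015],
                    "spawn_date": [datetime.date(2014, 12, 20)],
                }
            ),
        ],
        ignore_index=True,
    )
    res = ParentageModel(gt, fish, events2, m.config, "constrained").fit(seed=3)
    rows = res.assignments.set_index("offspring")
    assert {rows.loc["KID", "mother"], rows.loc["KID", "father"]} == {"MOM", "DAD"}
    assert {rows.loc["KID2", "mother"], rows.loc["KID2", "father"]} == {"MOM", "DAD"}
    # the pair spawned in 2011 and 2013; both pools carry it, so the
    # assigned cohort is one of the two
    assert rows.loc["KID2", "parent_year"] in (2011, 2013)


def test_q_monotone_nonincreasing_in_lod_within_pool(small_run):
    """Within a fixed pool size, the BH q-value never increases with LOD."""
    a = small_run.unconstrained.assignments.dropna(subset=["lod", "q"])
    for _, grp in a.groupby("pool_size"):
        if len(grp) < 2:
            continue
        g = grp.sort_values("lod")
        assert (np.diff(g["q"].to_numpy()) <= 1e-12).all()


# ---------------------------------------------------------------------------
# reconciliation


def _fake_results(rows, mode):
    df = pd.DataFrame(
        rows,
        columns=["offspring", "mother", "father", "parent_year", "spawn_year",
                 "lod", "q", "map_category", "pool_size"],
    )
    model = SimpleNamespace(config=ParentageConfig(), mode=mode)
    return ParentageResults(model, df)


def _row(off, mom, dad, q, py=2011, sy=2013):
    return (off, mom, dad, py, sy, 25.0, q, "parent_pair", 100)


def test_reconcile_provenance_rules():
    cons = _fake_results(
        [_row("K1", "M1", "F1", 0.002), _row("K3", "M3", "F3", 0.002)], "constrained"
    )
    unc = _fake_results(
        [
            _row("K1", "M1", "F1", 0.003),
            _row("K2", "M2", "F2", 0.001),
            _row("K3", "M9", "F9", 0.0001),
        ],
        "unconstrained",
    )
    ped = reconcile_runs(cons, unc)
    t = ped.trios.set_index("offspring")
    assert t.loc["K1", "provenance"] == "both_runs"
    assert t.loc["K2", "provenance"] == "unconstrained_only"
    # conflicting pairs: the lower-q (unconstrained) trio wins
    assert t.loc["K3", "provenance"] == "constrained_preferred"
    assert t.loc["K3", "mother"] == "M9"
    ped.check_accounting()


def test_reconcile_conflict_tie_goes_to_constrained():
    cons = _fake_results([_row("K", "Mc", "Fc", 0.004)], "constrained")
    unc = _fake_results([_row("K", "Mu", "Fu", 0.004)], "unconstrained")
    ped = reconcile_runs(cons, unc)
    assert ped.trios.iloc[0]["mother"] == "Mc"


def test_reconcile_swapped_parent_order_is_same_trio():
    cons = _fake_results([_row("K", "A", "B", 0.004)], "constrained")
    unc = _fake_results([_row("K", "B", "A", 0.002)], "unconstrained")
    ped = reconcile_runs(cons, unc)
    assert ped.trios.iloc[0]["provenance"] == "both_runs"


def test_remove_improbable_trios_reasons():
    trios = pd.DataFrame(
        {
            "offspring": ["K1", "K2", "K3", "K4"],
            "mother": ["A", "B", "C", "K4"],
            "father": ["A2", "B2", "C2", "D2"],
            "parent_year": [2011, 2013, 2011, 2011],
            "spawn_year": [2013, 2013, 2013, 2013],
            "lod": [20.0] * 4,
            "q": [0.001] * 4,
            "provenance": ["both_runs"] * 4,
        }
    )
    fish = pd.DataFrame(
        {
            "fish_id": ["A", "A2", "B", "B2", "C", "C2", "K4", "D2"],
            "resolved_sex": ["M", "M", "F", "M", "F", "M", "F", "M"],
        }
    )
    ped = remove_improbable_trios(
        Pedigree(trios, pd.DataFrame(columns=["offspring", "reason"])), fish
    )
    reasons = dict(zip(ped.removals["offspring"], ped.removals["reason"]))
    assert reasons == {"K1": "sex_conflict", "K2": "date_conflict", "K4": "self_parent"}
    assert list(ped.trios["offspring"]) == ["K3"]


def test_null_simulation_importance_weights_calibrated(fast_parentage_config):
    """The mixture importance-sampling estimator of P(null LOD >= t)
    integrates to ~1 at t = -inf and is monotone in t."""
    m = _micro_model()
    lods, logw = m.simulate_null_lods(20000, seed=5)
    w = np.exp(logw)
    assert w.mean() == pytest.approx(1.0, abs=0.05)  # normalization
    ts = np.quantile(lods, [0.1, 0.5, 0.9])
    ps = [(w * (lods >= t)).mean() for t in ts]
    assert ps[0] >= ps[1] >= ps[2]
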