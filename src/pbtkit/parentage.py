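"""Likelihood-based parent-pair assignment with an error model and FDR control.

Each candidate offspring is assigned to its most likely parent pair by a
trio likelihood ratio.  At each biallelic locus the parental hypothesis
puts Hardy-Weinberg priors (at allele frequencies estimated from the adult
pool) on the true parental genotypes, Mendelian transmission on the true
offspring genotype, and an allele-wise genotyping-error kernel (each gene
copy observed correctly with probability 1-epsilon) on all three observed
genotypes; the unrelated hypothesis draws the offspring's true genotype
from Hardy-Weinberg independently of the parents.  The trio LOD is the
log10 ratio summed over loci called in all three members.

Assignments are categorised by the maximum a posteriori relationship
(parent pair / mother only / father only / unrelated, equal priors), and a
per-offspring p-value for the best LOD against a simulated unrelated null
is pool-size adjusted and converted to a q-value by Benjamini-Hochberg.
Accepted trios have MAP category parent-pair and q at or below the FDR
threshold (default 0.01).

Two run modes mirror hatchery practice: the *constrained* run pairs only
adults with identical recorded spawn dates and opposite resolved sexes;
the *unconstrained* run pairs any two adults sharing a spawn year, which
recovers offspring whose parents' metadata (sex or date) was recorded
wrongly.  ``reconcile_runs`` merges the two into a final pedigree and
``remove_improbable_trios`` drops residual sex- or date-conflicted trios.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import ParentageConfig
from .data import MISSING, GenotypeTable

log = logging.getLogger(__name__)

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# likelihood building blocks


def genotype_error_kernel(epsilon: float) -> np.ndarray:
    """Unordered-genotype emission matrix E[true, observed].

    Each gene copy is observed correctly with probability 1-epsilon and
    flipped with epsilon, independently; rows sum to 1.
    """
    e = epsilon
    return np.array(
        [
            [(1 - e) ** 2, 2 * e * (1 - e), e**2],
            [e * (1 - e), (1 - e) ** 2 + e**2, e * (1 - e)],
            [e**2, 2 * e * (1 - e), (1 - e) ** 2],
        ]
    )


def _mendel_tensor() -> np.ndarray:
    """M[gm, gf, go]: offspring genotype distribution given parents."""
    t = np.array([0.0, 0.5, 1.0])  # P(transmit B | genotype)
    m = np.zeros((3, 3, 3))
    for gm in range(3):
        for gf in range(3):
            tm, tf = t[gm], t[gf]
            m[gm, gf, 0] = (1 - tm) * (1 - tf)
            m[gm, gf, 1] = tm * (1 - tf) + tf * (1 - tm)
            m[gm, gf, 2] = tm * tf
    return m


_MENDEL = _mendel_tensor()


def _incompatibility_table() -> np.ndarray:
    """inc[om, of, oo] = 1 when the observed trio has no Mendelian-consistent
    phase ignoring genotyping error; observed index 3 (missing) is compatible."""
    inc = np.zeros((4, 4, 4), dtype=bool)
    for om in range(3):
        for of in range(3):
            for oo in range(3):
                inc[om, of, oo] = _MENDEL[om, of, oo] == 0.0
    return inc


INCOMPATIBILITY = _incompatibility_table()


def hwe_priors(freqs: np.ndarray) -> np.ndarray:
    """(L, 3) Hardy-Weinberg genotype priors from B-allele frequencies."""
    q = np.asarray(freqs, dtype=float)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)


@dataclasses.dataclass
class LikelihoodTables:
    """Per-locus log10 likelihood-ratio lookup tables.

    Observed-genotype index 3 denotes a missing call and contributes zero
    to every LOD (per-locus complete-case).
    """

    loci: list[str]
    freqs: np.ndarray
    epsilon: float
    trio: np.ndarray  # (L, 4, 4, 4) log10 LR, [obs_m, obs_f, obs_o]
    pair: np.ndarray  # (L, 4, 4) log10 LR, [obs_o, obs_p]
    prior: np.ndarray  # (L, 3)
    marginal: np.ndarray  # (L, 3) P(observed genotype)
    kernel: np.ndarray  # (3, 3)


def build_tables(loci: list[str], freqs: np.ndarray, epsilon: float) -> LikelihoodTables:
    freqs = np.asarray(freqs, dtype=float)
    pr = hwe_priors(freqs)  # (L,3)
    E = genotype_error_kernel(epsilon)
    E4 = np.concatenate([E, np.ones((3, 1))], axis=1)  # obs index 3 = missing
    marg = pr @ E  # (L,3)
    marg4 = np.concatenate([marg, np.ones((len(freqs), 1))], axis=1)

    # trio numerator: sum over true gm, gf, go
    num = np.einsum(
        "lm,lf,mfo,ma,fb,oc->labc", pr, pr, _MENDEL, E4, E4, E4, optimize=True
    )
    den = np.einsum("la,lb,lc->labc", marg4, marg4, marg4)
    trio = np.log10(num) - np.log10(den)
    # per-locus complete-case: a locus missing in any member contributes 0
    trio[:, 3, :, :] = 0.0
    trio[:, :, 3, :] = 0.0
    trio[:, :, :, 3] = 0.0

    # single-parent: true offspring = one allele from parent, one from HWE
    t = np.array([0.0, 0.5, 1.0])
    q = freqs[:, None]  # (L,1)
    po_given_gp = np.stack(
        [
            (1 - t)[None, :] * (1 - q),
            t[None, :] * (1 - q) + (1 - t)[None, :] * q,
            t[None, :] * q,
        ],
        axis=-1,
    )  # (L, gp, go)
    num2 = np.einsum("lp,lpo,pa,ob->lba", pr, po_given_gp, E4, E4, optimize=True)
    den2 = np.einsum("lb,la->lba", marg4, marg4)  # [obs_o, obs_p]
    pair = np.log10(num2) - np.log10(den2)
    pair[:, 3, :] = 0.0
    pair[:, :, 3] = 0.0
    return LikelihoodTables(list(loci), freqs, epsilon, trio, pair, pr, marg, E)


def estimate_allele_freqs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Allele-count frequencies per locus and a polymorphism mask.

    Monomorphic or uncalled loci are flagged (mask False) and must be
    excluded from LOD computation.
    """
    codes = np.asarray(codes)
    n1 = (codes == 1).sum(axis=0)
    n2 = (codes == 2).sum(axis=0)
    n = (codes != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, (n1 + 2 * n2) / (2.0 * n), np.nan)
    poly = (n > 0) & (freq > 0.0) & (freq < 1.0)
    return freq, poly


def trio_lod(
    offspring_g: np.ndarray,
    mother_g: np.ndarray,
    father_g: np.ndarray,
    freqs: np.ndarray,
    epsilon: float,
    min_loci: int = 0,
) -> tuple[float, np.ndarray, int]:
    """Trio LOD and per-locus incompatibility flags for one candidate trio.

    Returns (lod, incompatibility flags over loci, n co-called loci); the
    lod is NaN when fewer than ``min_loci`` loci are called in all three
    members.
    """
    tables = build_tables([f"L{i}" for i in range(len(freqs))], freqs, epsilon)
    return _trio_lod_from_tables(offspring_g, mother_g, father_g, tables, min_loci)


def _trio_lod_from_tables(oo, om, of, tables: LikelihoodTables, min_loci=0):
    L = len(tables.loci)
    idx = np.arange(L)
    contrib = tables.trio[idx, om, of, oo]
    called = (oo != MISSING) & (om != MISSING) & (of != MISSING)
    flags = INCOMPATIBILITY[om, of, oo]
    n_called = int(called.sum())
    if n_called < min_loci:
        return float("nan"), flags, n_called
    return float(contrib.sum()), flags, n_called


# ---------------------------------------------------------------------------
# model / results


@dataclasses.dataclass
class AdultPool:
    """Adults eligible as parents, with their spawn events.

    ``events`` needs columns fish_id, spawn_year, spawn_date; ``fish``
    needs fish_id, resolved_sex.  Iteroparous fish appear in the pool of
    every year in which they spawned.
    """

    fish: pd.DataFrame
    events: pd.DataFrame


class ParentageModel:
    """Trio-likelihood parentage over a set of candidate offspring.

    Parameters
    ----------
    genotypes : GenotypeTable
        Canonical genotype per fish on the analysis locus panel (adults
        and offspring share the table; every spawner is both a candidate
        offspring and, in later years, a candidate parent).
    fish : DataFrame with fish_id, resolved_sex, first_spawn_year.
    events : DataFrame with fish_id, spawn_year, spawn_date.
    config : ParentageConfig
    mode : "constrained" or "unconstrained"
    """

    def __init__(
        self,
        genotypes: GenotypeTable,
        fish: pd.DataFrame,
        events: pd.DataFrame,
        config: ParentageConfig | None = None,
        mode: str = "constrained",
    ):
        if mode not in ("constrained", "unconstrained"):
            raise ValueError("mode must be constrained|unconstrained")
        self.config = config or ParentageConfig()
        self.mode = mode
        self.fish = fish.reset_index(drop=True)
        self.events = events.reset_index(drop=True)
        freqs, poly = estimate_allele_freqs(genotypes.codes)
        if not poly.all():
            dropped = [l for l, ok in zip(genotypes.loci, poly) if not ok]
            log.info("excluding %d monomorphic/uncalled loci from LOD: %s",
                     len(dropped), ", ".join(dropped))
        keep = [l for l, ok in zip(genotypes.loci, poly) if ok]
        self.genotypes = genotypes.subset_loci(keep)
        self.freqs = freqs[poly]
        self.tables = build_tables(keep, self.freqs, self.config.epsilon)
        self._fish_index = {f: i for i, f in enumerate(self.genotypes.sample_ids)}

    # ------------------------------------------------------------- utilities

    def _codes_for(self, fish_ids) -> np.ndarray:
        idx = np.array([self._fish_index[f] for f in fish_ids], dtype=np.intp)
        return self.genotypes.codes[idx]

    def _screen_scores(self, off_codes: np.ndarray, par_codes: np.ndarray) -> np.ndarray:
        """Single-parent LODs, offspring x adults, via one-hot matrix product."""
        L = off_codes.shape[1]
        S = self.tables.pair  # (L, 4, 4) [obs_o, obs_p]
        O4 = np.eye(4, dtype=np.float32)[off_codes]  # (n_off, L, 4)
        A = np.einsum("ila,lab->ilb", O4, S.astype(np.float32)).reshape(len(off_codes), 4 * L)
        P4 = np.eye(4, dtype=np.float32)[par_codes].reshape(len(par_codes), 4 * L)
        return A @ P4.T

    # ------------------------------------------------------------------ fit

    def fit(self, seed: int = 0) -> "ParentageResults":
        cfg = self.config
        lo, hi = cfg.allowed_age_gap
        events = self.events
        fish = dict(zip(self.fish["fish_id"], self.fish["resolved_sex"]))
        years = sorted(events["spawn_year"].unique())

        # adults per year (fish with >=1 spawn event that year)
        adults_by_year = {
            y: sorted(events.loc[events["spawn_year"] == y, "fish_id"].unique())
            for y in years
        }
        # fish-level event dates per year for the constrained mode
        dates_by: dict[tuple[str, int], set] = {}
        for fid, yr, d in zip(events["fish_id"], events["spawn_year"], events["spawn_date"]):
            dates_by.setdefault((fid, int(yr)), set()).add(d)

        # offspring = every fish, at its first spawn year
        off_year = self.fish.set_index("fish_id")["first_spawn_year"]
        rows: list[dict] = []
        for y in years:
            off_ids = sorted(off_year.index[off_year == y])
            if not off_ids:
                continue
            parent_years = [py for py in range(y - hi, y - lo + 1) if py in adults_by_year]
            parent_years = [py for py in parent_years if adults_by_year[py]]
            if not parent_years:
                for o in off_ids:
                    rows.append({"offspring": o, "spawn_year": y,
                                 "map_category": "unassignable", "pool_size": 0})
                continue
            off_codes = self._codes_for(off_ids)
            # shortlist per parent year by single-parent LOD
            shortlist: dict[int, list[list[str]]] = {}
            for py in parent_years:
                ads = adults_by_year[py]
                scores = self._screen_scores(off_codes, self._codes_for(ads))
                k = min(cfg.top_k_candidates, len(ads))
                top = np.argsort(-scores, axis=1, kind="stable")[:, :k]
                shortlist[py] = [[ads[j] for j in row] for row in top]

            pool_sizes = self._pool_sizes(off_ids, parent_years, adults_by_year, dates_by, fish)
            for i, o in enumerate(off_ids):
                rows.append(
                    self._assign_one(
                        o, y, i, shortlist, parent_years, fish, dates_by, pool_sizes[o]
                    )
                )

        res = pd.DataFrame(rows)
        res["run_mode"] = self.mode
        res = self._attach_fdr(res, seed)
        return ParentageResults(self, res)

    def _pool_sizes(self, off_ids, parent_years, adults_by_year, dates_by, fish) -> dict:
        """Number of candidate pairs per offspring (full pool, not shortlist)."""
        if self.mode == "unconstrained":
            total = sum(
                n * (n - 1) // 2 for n in (len(adults_by_year[py]) for py in parent_years)
            )
            return {o: total for o in off_ids}
        # constrained: opposite-sex fish sharing a recorded date
        total = 0
        for py in parent_years:
            ads = adults_by_year[py]
            date_count: dict[object, list[int]] = {}
            for a in ads:
                sex = fish[a]
                for d in dates_by.get((a, py), ()):
                    cnt = date_count.setdefault(d, [0, 0])
                    cnt[0 if sex == "F" else 1] += 1
            total += sum(nf * nm for nf, nm in date_count.values())
        return {o: total for o in off_ids}

    def _candidate_pairs(self, shortlist, parent_years, fish, dates_by):
        """(parent_a, parent_b, parent_year) tuples from shortlisted adults."""
        pairs = []
        for py in parent_years:
            cands = shortlist[py]
            if self.mode == "unconstrained":
                for a, b in combinations(cands, 2):
                    pairs.append((a, b, py))
            else:
                for a, b in combinations(cands, 2):
                    sa, sb = fish[a], fish[b]
                    if sa == sb:
                        continue
                    if dates_by.get((a, py), set()) & dates_by.get((b, py), set()):
                        pairs.append((a, b, py))
        return pairs

    def _assign_one(self, o, y, i, shortlist, parent_years, fish, dates_by, pool_size):
        cfg = self.config
        sl = {py: shortlist[py][i] for py in parent_years}
        pairs = self._candidate_pairs(sl, parent_years, fish, dates_by)
        pairs = [(a, b, py) for a, b, py in pairs if a != o and b != o]
        base = {"offspring": o, "spawn_year": y, "pool_size": pool_size}
        if not pairs:
            return {**base, "map_category": "unassignable"}
        codes = self.genotypes.codes
        fidx = self._fish_index
        oo = codes[fidx[o]]
        L = codes.shape[1]
        lidx = np.arange(L)
        ia = np.array([fidx[a] for a, _b, _py in pairs], dtype=np.intp)
        ib = np.array([fidx[b] for _a, b, _py in pairs], dtype=np.intp)
        ga_all, gb_all = codes[ia], codes[ib]
        trio_oo = self.tables.trio[lidx, :, :, oo]  # (L, 4, 4) at this offspring
        lods = trio_oo[lidx[None, :], ga_all, gb_all].sum(axis=1)
        n_called_all = (
            (ga_all != MISSING) & (gb_all != MISSING) & (oo != MISSING)[None, :]
        ).sum(axis=1)
        ok = n_called_all >= cfg.min_loci_for_trio
        if not ok.any():
            return {**base, "map_category": "unassignable"}
        best_i = int(np.argmax(np.where(ok, lods, -np.inf)))
        lod = float(lods[best_i])
        a, b, py = pairs[best_i]
        n_called = int(n_called_all[best_i])
        flags = INCOMPATIBILITY[ga_all[best_i], gb_all[best_i], oo]
        # order the pair mother-first by resolved sex when determinable
        sa, sb = fish[a], fish[b]
        if (sa, sb) == ("M", "F") or (sb == "F" and sa != "F"):
            a, b = b, a
        ga, gb = codes[fidx[a]], codes[fidx[b]]
        lod_m = self._single_lod(oo, ga)
        lod_f = self._single_lod(oo, gb)
        cats = {"unrelated": 0.0, "mother_only": lod_m, "father_only": lod_f,
                "parent_pair": lod}
        top = max(cats.values())
        # ties break toward the less specific relationship (conservative):
        # the first category in unrelated < single-parent < pair order wins
        category = next(k for k, v in cats.items() if v == top)
        n_inc = int((flags & (oo != MISSING) & (ga != MISSING) & (gb != MISSING)).sum())
        return {
            **base,
            "mother": a,
            "father": b,
            "parent_year": py,
            "lod": lod,
            "lod_mother": lod_m,
            "lod_father": lod_f,
            "map_category": category,
            "n_compatible_loci": n_called - n_inc,
            "n_incompatible_loci": n_inc,
        }

    def _single_lod(self, oo: np.ndarray, op: np.ndarray) -> float:
        L = len(self.tables.loci)
        return float(self.tables.pair[np.arange(L), oo, op].sum())

    # ------------------------------------------------------------------ FDR

    def simulate_null_lods(self, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
        """Simulate trio LODs under a mixture of the unrelated and parental
        models and return (lods, log-weights for the unrelated target).

        Half the trios are drawn with the offspring unrelated to the pair,
        half with a true parental trio; importance weights
        w = f_null / f_mix = 1 / (0.5 + 0.5 * 10^LOD) let the far upper
        tail of the *unrelated* LOD distribution be estimated without the
        1/n resolution floor of a plain Monte-Carlo null.  Genotyping
        error and the empirical per-locus missingness pattern are applied
        to all three simulated members.
        """
        rng = np.random.default_rng(seed)
        L = len(self.tables.loci)
        pr = self.tables.prior  # (L,3)
        cum = pr.cumsum(axis=1)
        miss = (self.genotypes.codes == MISSING).mean(axis=0)

        def draw_hwe(size):
            u = rng.random((size, L))
            return (u[..., None] > cum[None]).sum(axis=-1).astype(np.int8)

        gm, gf = draw_hwe(n), draw_hwe(n)
        go = draw_hwe(n)
        # second half: offspring Mendelian from the pair
        half = n // 2
        t = np.array([0.0, 0.5, 1.0])
        tm, tf = t[gm[half:]], t[gf[half:]]
        go[half:] = (
            (rng.random((n - half, L)) < tm).astype(np.int8)
            + (rng.random((n - half, L)) < tf).astype(np.int8)
        )

        def observe(g):
            cdf = self.tables.kernel.cumsum(axis=1)
            obs = (rng.random(g.shape)[..., None] > cdf[g]).sum(axis=-1).astype(np.int8)
            obs[rng.random(g.shape) < miss[None, :]] = MISSING
            return obs

        om, of, oo = observe(gm), observe(gf), observe(go)
        lidx = np.arange(L)
        lods = self.tables.trio[lidx[None, :], om, of, oo].sum(axis=1)
        logw = -np.logaddexp(np.log(0.5), np.log(0.5) + lods * _LN10)
        return lods, logw

    def _attach_fdr(self, res: pd.DataFrame, seed: int) -> pd.DataFrame:
        cfg = self.config
        has = res["map_category"].ne("unassignable") & res.get("lod", pd.Series(dtype=float)).notna()
        res["p_single"] = np.nan
        res["p_adj"] = np.nan
        res["q"] = np.nan
        if not has.any():
            return res
        lods, logw = self.simulate_null_lods(cfg.null_sim_size, seed)
        order = np.argsort(lods)
        lods_sorted = lods[order]
        w_sorted = np.exp(logw[order])
        # tail weight sums: P(null LOD >= t)
        tail = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]]) / len(lods)
        obs = res.loc[has, "lod"].to_numpy()
        pos = np.searchsorted(lods_sorted, obs, side="left")
        p_single = np.maximum(tail[pos], 1e-300)
        resolution = w_sorted.min() / len(lods)
        if resolution > 1e-12:
            log.warning("null simulation resolution limited to %.2e", resolution)
        pool = res.loc[has, "pool_size"].to_numpy().astype(float)
        with np.errstate(divide="ignore"):
            p_adj = -np.expm1(pool * np.log1p(-np.minimum(p_single, 1 - 1e-16)))
        p_adj = np.clip(p_adj, 0.0, 1.0)
        res.loc[has, "p_single"] = p_single
        res.loc[has, "p_adj"] = p_adj
        _, q, _, _ = multipletests(p_adj, method="fdr_bh")
        res.loc[has, "q"] = q
        return res


class ParentageResults:
    """Fitted parentage assignments for one run mode."""

    def __init__(self, model: ParentageModel, assignments: pd.DataFrame):
        self.model = model
        self.assignments = assignments

    @property
    def accepted(self) -> pd.DataFrame:
        a = self.assignments
        ok = (a["map_category"] == "parent_pair") & (a["q"] <= self.model.config.fdr_threshold)
        return a.loc[ok].reset_index(drop=True)

    def summary(self) -> pd.DataFrame:
        a = self.assignments
        return pd.DataFrame(
            {
                "run_mode": [self.model.mode],
                "n_offspring": [len(a)],
                "n_assignable": [int((a["map_category"] != "unassignable").sum())],
                "n_parent_pair": [int((a["map_category"] == "parent_pair").sum())],
                "n_accepted": [len(self.accepted)],
                "fdr_threshold": [self.model.config.fdr_threshold],
                "epsilon": [self.model.config.epsilon],
            }
        )

    def plot_lod_distribution(self, ax=None, bins: int = 60):
        """Histogram of best-pair LODs, accepted trios highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a = self.assignments.dropna(subset=["lod"])
        acc = self.accepted
        ax.hist(a["lod"], bins=bins, color="0.7", label="all best pairs")
        if len(acc):
            ax.hist(acc["lod"], bins=bins, color="tab:blue",
                    label=f"accepted (q <= {self.model.config.fdr_threshold})")
        ax.set_xlabel("trio LOD (log10 LR)")
        ax.set_ylabel("offspring")
        ax.legend(frameon=False)
        return ax


# ---------------------------------------------------------------------------
# reconciliation


@dataclasses.dataclass
class Pedigree:
    """Final reconciled pedigree with provenance and removal log."""

    trios: pd.DataFrame  # offspring, mother, father, parent_year, lod, q, provenance
    removals: pd.DataFrame  # offspring, reason

    def counts(self) -> dict[str, int]:
        c = self.trios["provenance"].value_counts().to_dict()
        c["total"] = len(self.trios)
        c["removed_improbable"] = len(self.removals)
        return c

    def check_accounting(self, n_removed_improbable: int | None = None) -> None:
        c = self.trios["provenance"].value_counts()
        total = int(
            c.get("both_runs", 0)
            + c.get("unconstrained_only", 0)
            + c.get("constrained_preferred", 0)
            + c.get("constrained_only", 0)
        )
        if total != len(self.trios):
            raise AssertionError("pedigree accounting identity violated")

    def to_csv(self, path) -> None:
        self.trios.to_csv(path, index=False)

    def to_kid_pa_ma(self, path) -> None:
        """3-column kid/pa/ma flat file for common pedigree tools."""
        out = self.trios[["offspring", "father", "mother"]].copy()
        out.columns = ["kid", "pa", "ma"]
        out.to_csv(path, sep="\t", index=False)


def _pair_key(row) -> frozenset:
    return frozenset((row["mother"], row["father"]))


def reconcile_runs(
    constrained: ParentageResults, unconstrained: ParentageResults
) -> Pedigree:
    """Merge accepted trios of the two run modes into one pedigree.

    The same accepted trio in both runs -> ``both_runs``.  Accepted only
    in the unconstrained run -> ``unconstrained_only`` (tagged a presumed
    metadata error).  Both accepted but with different parent pairs ->
    the lower-q trio wins (tie to constrained), ``constrained_preferred``.
    Accepted only in the constrained run -> ``constrained_only``.
    """
    cols = ["mother", "father", "parent_year", "spawn_year", "lod", "q"]
    cons = constrained.accepted.set_index("offspring")
    unc = unconstrained.accepted.set_index("offspring")
    rows = []
    for o in sorted(set(cons.index) | set(unc.index)):
        in_c, in_u = o in cons.index, o in unc.index
        if in_c and in_u:
            rc, ru = cons.loc[o], unc.loc[o]
            if _pair_key(rc) == _pair_key(ru):
                rows.append({**rc[cols].to_dict(), "offspring": o,
                             "provenance": "both_runs"})
            else:
                winner = rc if rc["q"] <= ru["q"] else ru
                log.info("conflicting accepted trios for %s: q %.3g (constrained) vs "
                         "%.3g (unconstrained)", o, rc["q"], ru["q"])
                rows.append({**winner[cols].to_dict(), "offspring": o,
                             "provenance": "constrained_preferred"})
        elif in_u:
            ru = unc.loc[o]
            rows.append({**ru[cols].to_dict(), "offspring": o,
                         "provenance": "unconstrained_only",
                         "presumed_metadata_error": True})
        else:
            rc = cons.loc[o]
            rows.append({**rc[cols].to_dict(), "offspring": o,
                         "provenance": "constrained_only"})
    trios = pd.DataFrame(rows)
    if trios.empty:
        trios = pd.DataFrame(columns=["offspring", *cols, "provenance"])
    ped = Pedigree(trios, pd.DataFrame(columns=["offspring", "reason"]))
    ped.check_accounting()
    return ped


def remove_improbable_trios(
    pedigree: Pedigree, fish: pd.DataFrame, config: ParentageConfig | None = None
) -> Pedigree:
    """Drop trios with residual sex or spawning-date conflicts.

    Removes trios where both assigned parents share a resolved genetic
    sex, where a parent's spawn year is not earlier than the offspring's
    by at least the minimum age gap, or where a parent is the offspring
    itself.  Removals are logged with a reason.
    """
    config = config or ParentageConfig()
    min_gap = config.allowed_age_gap[0]
    sex = fish.set_index("fish_id")["resolved_sex"]
    keep_rows, removed = [], []
    for _, row in pedigree.trios.iterrows():
        o, m, f = row["offspring"], row["mother"], row["father"]
        if m == o or f == o:
            removed.append({"offspring": o, "reason": "self_parent"})
        elif sex.get(m) == sex.get(f):
            removed.append({"offspring": o, "reason": "sex_conflict"})
        elif row["spawn_year"] - row["parent_year"] < min_gap:
            removed.append({"offspring": o, "reason": "date_conflict"})
        else:
            keep_rows.append(row)
    trios = pd.DataFrame(keep_rows).reset_index(drop=True)
    if trios.empty:
        trios = pedigree.trios.iloc[0:0]
    removals = pd.concat(
        [pedigree.removals, pd.DataFrame(removed, columns=["offspring", "reason"])],
        ignore_index=True,
    )
    return Pedigree(trios, removals)
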