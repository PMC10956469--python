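"""End-to-end orchestration: simulate/load -> QC -> identity -> parentage
(two passes around marker diagnostics) -> popgen + life-history reports.

The parentage stage follows a two-pass design: a preliminary constrained
run feeds per-marker Mendelian-incompatibility diagnostics; markers with
incompatibility rates above 2% are excluded; the final constrained and
unconstrained runs use the reduced panel and are reconciled into the
pedigree.  Every stage's accounting identity (input = retained + removed;
cluster members sum to retained samples; pedigree provenance counts sum
to the total) is asserted and recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import identity as identity_mod
from . import life_history as lh
from . import marker_diag, popgen, qc, synth
from .config import (
    OMY05_MARKER,
    SEX_MARKER,
    IdentityConfig,
    ParentageConfig,
    QCConfig,
    SimulationConfig,
)
from .data import GenotypeTable, read_sample_table
from .parentage import (
    ParentageModel,
    Pedigree,
    estimate_allele_freqs,
    reconcile_runs,
    remove_improbable_trios,
)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Either a simulation block or input paths, plus stage settings."""

    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    samples_path: str | None = None
    qc: QCConfig = dataclasses.field(default_factory=QCConfig)
    identity: IdentityConfig = dataclasses.field(default_factory=IdentityConfig)
    parentage: ParentageConfig = dataclasses.field(default_factory=ParentageConfig)
    fst_subset_size: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.genotypes_path is not None or self.samples_path is not None
        if self.simulation is not None and has_paths:
            raise ValueError("exactly one of simulation block / input paths allowed")
        if self.simulation is None and not (self.genotypes_path and self.samples_path):
            raise ValueError(
                "configuration needs a simulation block or both genotypes_path "
                "and samples_path"
            )


@dataclasses.dataclass
class PipelineResult:
    """In-memory results of a full pipeline run."""

    genotypes: GenotypeTable
    samples: pd.DataFrame
    clusters: list
    cluster_removals: pd.DataFrame
    panel: qc.LocusPanel
    final_panel: qc.LocusPanel
    diagnostics: pd.DataFrame
    constrained: object
    unconstrained: object
    pedigree: Pedigree
    truth: synth.TruthBundle | None
    manifest: dict


def clusters_to_model_inputs(clusters, genotypes: GenotypeTable, loci: list[str]):
    """Fish-level inputs for the parentage model from identity clusters.

    Canonical-sample genotypes on the given panel; per-fish sex, primary
    program and first spawn year; the flat event list (iteroparous fish
    thereby enter the parent pool of every year they spawned)."""
    fish_rows, event_rows = [], []
    for c in clusters:
        first = min(c.spawn_events, key=lambda e: (e.spawn_year, str(e.spawn_date)))
        fish_rows.append(
            (c.fish_id, c.resolved_sex, int(first.spawn_year), first.program)
        )
        for e in c.spawn_events:
            event_rows.append((c.fish_id, int(e.spawn_year), e.spawn_date, e.program))
    fish = pd.DataFrame(
        fish_rows, columns=["fish_id", "resolved_sex", "first_spawn_year", "program"]
    )
    events = pd.DataFrame(
        event_rows, columns=["fish_id", "spawn_year", "spawn_date", "program"]
    )
    gt = genotypes.subset_samples([c.canonical_sample for c in clusters])
    gt = GenotypeTable(list(fish["fish_id"]), gt.loci, gt.codes).subset_loci(loci)
    return gt, fish, events


def run(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Run the full pipeline; deterministic given config and seed."""
    manifest: dict = {"seed": config.seed, "outputs": {}, "identities": {}}
    truth = None
    if config.simulation is not None:
        truth = synth.simulate_population(config.simulation)
        gt_raw, samples_raw = synth.observe(truth)
    else:
        gt_raw = GenotypeTable.from_csv(config.genotypes_path)
        samples_raw = read_sample_table(config.samples_path)
    manifest["outputs"]["raw_samples"] = len(samples_raw)

    # locus panel: all loci typed in all years here; special markers tagged
    coverage = pd.DataFrame(
        {"locus": gt_raw.loci, "typed_all_years": True}
    )
    panel = qc.select_loci(coverage, SEX_MARKER, OMY05_MARKER,
                           min_analysis_loci=config.qc.min_analysis_loci)

    gt_clean, samples_clean, qc_report = qc.run_qc(gt_raw, samples_raw, panel, config.qc)
    manifest["outputs"]["qc_retained"] = gt_clean.n_samples
    manifest["identities"]["qc_accounting"] = True  # run_qc asserts it

    clusters, cluster_removals = identity_mod.resolve_identity(
        gt_clean, samples_clean, config.identity
    )
    n_members = sum(len(c.members) for c in clusters) + int(
        cluster_removals["n_members"].sum() if len(cluster_removals) else 0
    )
    manifest["outputs"]["clusters_valid"] = len(clusters)
    manifest["outputs"]["clusters_removed"] = len(cluster_removals)
    manifest["identities"]["cluster_membership"] = None  # filled below

    # preliminary parentage on the full analysis panel
    analysis_loci = panel.analysis_loci
    gt_fish, fish, events = clusters_to_model_inputs(clusters, gt_clean, analysis_loci)
    prelim = ParentageModel(gt_fish, fish, events, config.parentage, "constrained").fit(
        seed=config.seed + 11
    )
    prelim_trios = prelim.accepted
    if len(prelim_trios) > 0:
        freqs, _ = estimate_allele_freqs(gt_fish.codes)
        diags = marker_diag.diagnose_markers(
            prelim_trios.rename(columns={"offspring": "offspring"}), gt_fish, freqs
        )
        diag_df = marker_diag.diagnostics_frame(diags)
        bad = diag_df.loc[diag_df["excluded"].fillna(False), "locus"].tolist()
    else:
        log.warning("preliminary run accepted no trios; skipping marker exclusion")
        diag_df = pd.DataFrame()
        bad = []
    if bad:
        log.info("excluding %d high-incompatibility markers: %s", len(bad), bad)
    final_panel = qc.select_loci(
        coverage, SEX_MARKER, OMY05_MARKER, exclusion_list=bad,
        min_analysis_loci=config.qc.min_analysis_loci,
    )

    gt_fish2, fish2, events2 = clusters_to_model_inputs(
        clusters, gt_clean, final_panel.analysis_loci
    )
    constrained = ParentageModel(
        gt_fish2, fish2, events2, config.parentage, "constrained"
    ).fit(seed=config.seed + 13)
    unconstrained = ParentageModel(
        gt_fish2, fish2, events2, config.parentage, "unconstrained"
    ).fit(seed=config.seed + 17)
    pedigree = reconcile_runs(constrained, unconstrained)
    pedigree = remove_improbable_trios(pedigree, fish2, config.parentage)
    manifest["outputs"]["pedigree_trios"] = len(pedigree.trios)
    manifest["outputs"]["pedigree_removed_improbable"] = len(pedigree.removals)
    counts = pedigree.trios["provenance"].value_counts().to_dict() if len(pedigree.trios) else {}
    manifest["identities"]["pedigree_accounting"] = (
        sum(counts.values()) == len(pedigree.trios)
    )
    manifest["outputs"]["provenance"] = counts

    # reports
    reports = _build_reports(config, gt_clean, samples_clean, clusters, fish2, pedigree)
    manifest["outputs"].update({k: len(v) for k, v in reports.items()})
    manifest["identities"]["cluster_membership"] = (
        n_members == gt_clean.n_samples
    )
    for name, ok in manifest["identities"].items():
        if ok is False:
            raise AssertionError(f"accounting identity failed: {name}")

    result = PipelineResult(
        gt_clean, samples_clean, clusters, cluster_removals, panel, final_panel,
        diag_df, constrained, unconstrained, pedigree, truth, manifest,
    )
    if outdir is not None:
        _write_outputs(result, reports, outdir, config)
    return result


def _karyotype_frame(gt: GenotypeTable, fish: pd.DataFrame) -> pd.DataFrame:
    """Inversion karyotypes (AA/AR/RR) per fish from the indicator locus."""
    if OMY05_MARKER not in gt.loci:
        return pd.DataFrame(columns=["fish_id", "karyotype", "program", "sex"])
    col = gt.loci.index(OMY05_MARKER)
    codes = gt.codes[gt.index_of(fish["fish_id"]), col]
    name = {0: "AA", 1: "AR", 2: "RR", 3: None}
    return pd.DataFrame(
        {
            "fish_id": fish["fish_id"],
            "karyotype": [name[int(c)] for c in codes],
            "program": fish["program"].to_numpy(),
            "sex": fish["resolved_sex"].to_numpy(),
        }
    ).dropna(subset=["karyotype"])


def _build_reports(config, gt_clean, samples, clusters, fish, pedigree) -> dict:
    reports: dict[str, pd.DataFrame] = {}
    records, use_counts = lh.classify_spawn_use(clusters)
    reports["spawn_use_counts"] = use_counts
    reports["spawn_use_percent"] = lh.use_percentages(use_counts)
    stat_tests: list[dict] = []

    # multiple-spawning (event count) comparisons across programs and sexes
    n_events = pd.DataFrame(
        {"fish_id": [c.fish_id for c in clusters],
         "n_events": [c.n_events for c in clusters]}
    ).merge(fish[["fish_id", "program", "resolved_sex"]], on="fish_id")
    for key in ("program", "resolved_sex"):
        groups = [g["n_events"].to_numpy() for _, g in n_events.groupby(key)]
        if len(groups) >= 2 and all(len(g) for g in groups):
            h, dof, p = lh.kruskal_wallis(*groups)
            stat_tests.append(
                {"test": "kruskal_wallis", "grouping": f"n_spawn_events~{key}",
                 "statistic": h, "df": dof, "p": p}
            )

    info = fish.rename(columns={"resolved_sex": "resolved_sex"})
    if len(pedigree.trios):
        ages = lh.tabulate_ages(pedigree, info)
        reports["ages"] = ages
        reports["age_by_program_sex"] = lh.age_distribution(ages, ["program", "sex"])
        origin = fish.set_index("fish_id")["program"]
        counts, rates = lh.straying_matrix(pedigree, origin, origin)
        reports["straying_counts"] = counts.reset_index()
        reports["straying_rates"] = rates.reset_index()
        per_fish, rs = lh.reproductive_success(pedigree, records)
        reports["reproductive_success"] = rs
    # karyotype summaries: the cleaned table still carries the indicator locus
    canon = gt_clean.subset_samples([c.canonical_sample for c in clusters])
    gt_fish_all = GenotypeTable(list(fish["fish_id"]), canon.loci, canon.codes)
    karyo = _karyotype_frame(gt_fish_all, fish)
    if len(karyo):
        reports["omy05_frequencies"] = lh.omy05_frequency_table(karyo)
        hwe = lh.omy05_hwe_by_program(karyo)
        reports["omy05_hwe"] = pd.DataFrame(
            {
                "program": list(hwe),
                "D": [r.D for r in hwe.values()],
                "p_value": [r.p_value for r in hwe.values()],
            }
        )
        if len(pedigree.trios):
            kser = karyo.set_index("fish_id")["karyotype"]
            ar = lh.ar_cross_offspring(pedigree, kser)
            if len(ar):
                c = ar["karyotype"].value_counts()
                seg = lh.segregation_test(
                    int(c.get("AA", 0)), int(c.get("AR", 0)), int(c.get("RR", 0))
                )
                reports["omy05_segregation"] = pd.DataFrame([dataclasses.asdict(seg)])
                stat_tests.append(
                    {"test": f"segregation_1_2_1[{seg.method}]",
                     "grouping": "offspring_of_AR_x_AR",
                     "statistic": seg.statistic, "df": seg.df, "p": seg.p_value}
                )

    # popgen per program on analysis loci
    analysis = [l for l in gt_clean.loci if l not in (SEX_MARKER, OMY05_MARKER)]
    sub = gt_clean.subset_loci(analysis)
    rows = []
    for prog, s in samples.groupby("program"):
        codes = sub.codes[sub.index_of(list(s["sample_id"]))]
        try:
            ho, he = popgen.heterozygosity(codes)
            rows.append({"program": prog, "Ho": ho, "He": he, "n": len(s)})
        except ValueError:
            pass
    reports["heterozygosity"] = pd.DataFrame(rows)
    progs = sorted(samples["program"].unique())
    if len(progs) >= 2:
        rng = np.random.default_rng(config.seed + 23)
        frames = []
        for pa_i in range(len(progs)):
            for pb_i in range(pa_i + 1, len(progs)):
                ca = _program_subset(sub, samples, progs[pa_i], config.fst_subset_size, rng)
                cb = _program_subset(sub, samples, progs[pb_i], config.fst_subset_size, rng)
                try:
                    theta = popgen.pairwise_fst([ca, cb]).theta
                except ValueError:
                    theta = float("nan")
                frames.append({"pop_a": progs[pa_i], "pop_b": progs[pb_i], "theta": theta})
        reports["fst_matrix"] = pd.DataFrame(frames)
    reports["stat_tests"] = pd.DataFrame(
        stat_tests, columns=["test", "grouping", "statistic", "df", "p"]
    )
    return reports


def _program_subset(gt: GenotypeTable, samples, program, size, rng):
    ids = list(samples.loc[samples["program"] == program, "sample_id"])
    if len(ids) > size:
        ids = [ids[i] for i in sorted(rng.choice(len(ids), size=size, replace=False))]
    return gt.codes[gt.index_of(ids)]


def _write_outputs(result: PipelineResult, reports: dict, outdir, config) -> None:
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.pedigree.to_csv(out / "pedigree.csv")
    result.pedigree.to_kid_pa_ma(out / "pedigree_kid_pa_ma.tsv")
    identity_mod.clusters_to_frame(result.clusters).to_csv(
        out / "clusters.csv", index=False
    )
    if len(result.diagnostics):
        result.diagnostics.to_csv(out / "marker_diagnostics.csv", index=False)
    for name, df in reports.items():
        df.to_csv(out / f"{name}.csv", index=False)
    if result.truth is not None:
        result.truth.save(out / "truth")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
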