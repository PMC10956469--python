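"""Cleaning of raw genotype + metadata tables.

Marker selection (loci typed in all years; special markers tagged),
regenotype resolution (keep the most complete genotype per sample id),
missing-data filtering (drop samples missing more than 10% of loci) and
sex resolution (genetic sex takes precedence over phenotypic; samples
missing both are removed).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .config import OMY05_MARKER, SEX_MARKER, QCConfig
from .data import GenotypeTable

log = logging.getLogger(__name__)

ROLE_ANALYSIS = "autosomal_analysis"
ROLE_SEX = "sex_marker"
ROLE_OMY05 = "omy05_marker"
ROLE_EXCLUDED = "excluded"


@dataclasses.dataclass
class LocusPanel:
    """Locus ids with role tags and a typed-in-all-years flag."""

    roles: dict[str, str]
    typed_all_years: dict[str, bool]

    def loci_with_role(self, role: str) -> list[str]:
        return [l for l, r in self.roles.items() if r == role]

    @property
    def analysis_loci(self) -> list[str]:
        return self.loci_with_role(ROLE_ANALYSIS)

    @property
    def special_loci(self) -> list[str]:
        return [l for l, r in self.roles.items() if r in (ROLE_SEX, ROLE_OMY05)]

    @property
    def panel_loci(self) -> list[str]:
        """Analysis plus special loci (the denominator for missingness)."""
        return [l for l, r in self.roles.items() if r != ROLE_EXCLUDED]


def select_loci(
    year_coverage: pd.DataFrame,
    sex_marker: str = SEX_MARKER,
    omy05_marker: str = OMY05_MARKER,
    exclusion_list: list[str] | None = None,
    min_analysis_loci: int = 50,
) -> LocusPanel:
    """Build the analysis locus panel.

    Parameters
    ----------
    year_coverage : DataFrame indexed or keyed by locus with a boolean
        column per year (or a single boolean column ``typed_all_years``):
        whether the locus was genotyped in that year.
    exclusion_list : loci to re-tag as excluded (e.g. the
        high-incompatibility markers flagged by marker diagnostics).

    Loci not typed across all years are excluded from downstream analyses;
    the sex marker and the inversion indicator are tagged with their roles
    and never enter the autosomal analysis set.
    """
    df = year_coverage.copy()
    if "locus" in df.columns:
        df = df.set_index("locus")
    if "typed_all_years" in df.columns:
        typed = df["typed_all_years"].astype(bool)
    else:
        typed = df.astype(bool).all(axis=1)
    exclusion = set(exclusion_list or [])
    roles: dict[str, str] = {}
    for locus, ok in typed.items():
        if locus in exclusion or not ok:
            roles[locus] = ROLE_EXCLUDED
        elif locus == sex_marker:
            roles[locus] = ROLE_SEX
        elif locus == omy05_marker:
            roles[locus] = ROLE_OMY05
        else:
            roles[locus] = ROLE_ANALYSIS
    panel = LocusPanel(roles, typed.to_dict())
    n = len(panel.analysis_loci)
    if n < min_analysis_loci:
        raise ValueError(
            f"only {n} analysis loci remain (< {min_analysis_loci}); panel unusable"
        )
    return panel


def resolve_regenotypes(
    gt: GenotypeTable, sample_ids: list[str] | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Keep one genotype row per sample id: the one with fewest missing loci.

    Ties are broken toward the latest-loaded row and logged.  Returns the
    deduplicated table plus a report of dropped rows.
    """
    ids = sample_ids if sample_ids is not None else gt.sample_ids
    n_called = gt.n_called()
    best: dict[str, int] = {}
    ties: list[str] = []
    for i, sid in enumerate(ids):
        if sid not in best:
            best[sid] = i
        else:
            j = best[sid]
            if n_called[i] > n_called[j]:
                best[sid] = i
            elif n_called[i] == n_called[j]:
                best[sid] = i  # latest load order wins
                ties.append(sid)
    if ties:
        log.info("regenotype ties broken toward latest load for %d sample(s): %s",
                 len(ties), ", ".join(sorted(set(ties))[:10]))
    keep = sorted(best.values())
    dropped = [i for i in range(len(ids)) if i not in set(keep)]
    report = pd.DataFrame(
        {"sample_id": [ids[i] for i in dropped], "n_called": n_called[dropped]}
    )
    out = GenotypeTable([ids[i] for i in keep], list(gt.loci), gt.codes[keep])
    return out, report


def filter_missing(
    gt: GenotypeTable, panel: LocusPanel, max_missing_frac: float = 0.10
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop samples missing more than ``max_missing_frac`` of panel loci.

    A sample is removed when its missing calls over the analysis+special
    panel exceed ``max_missing_frac`` of the panel in whole loci: the
    required call count is ``L - ceil(max_missing_frac * L)`` (82 of 92
    held, 81 removed, at the 10% threshold).
    """
    sub = gt.subset_loci(panel.panel_loci)
    n_called = sub.n_called()
    required = sub.n_loci - math.ceil(max_missing_frac * sub.n_loci - 1e-9)
    keep = n_called >= required
    removed = pd.DataFrame(
        {
            "sample_id": [s for s, k in zip(gt.sample_ids, keep) if not k],
            "n_called": n_called[~keep],
            "required": required,
            "reason": "missing_data",
        }
    )
    out = GenotypeTable(
        [s for s, k in zip(gt.sample_ids, keep) if k], list(gt.loci), gt.codes[keep]
    )
    return out, removed


def resolve_sex(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve each sample's sex from genetic and phenotypic records.

    Genetic sex is used when present; otherwise phenotypic.  Samples with
    neither are removed.  Genetic/phenotypic conflicts resolve in favour
    of the genetic marker and are logged (they feed the metadata-error
    pathway of the unconstrained parentage run).
    """
    df = samples.copy()
    gen = df["genetic_sex"].fillna("unknown")
    phe = df["phenotypic_sex"].fillna("unknown")
    resolved = np.where(gen != "unknown", gen, phe)
    removed_mask = (gen == "unknown") & (phe == "unknown")
    conflict = (gen != "unknown") & (phe != "unknown") & (gen != phe)
    if conflict.any():
        log.info("sex conflicts resolved toward genetic sex for %d sample(s)",
                 int(conflict.sum()))
    df["resolved_sex"] = resolved
    df["sex_conflict"] = conflict.to_numpy()
    removed = df.loc[removed_mask, ["sample_id"]].copy()
    removed["reason"] = "sex_unknown"
    return df.loc[~removed_mask].reset_index(drop=True), removed


@dataclasses.dataclass
class QCReport:
    n_input: int
    n_retained: int
    removals: pd.DataFrame  # sample_id, reason

    def check(self) -> None:
        if self.n_input != self.n_retained + len(self.removals):
            raise AssertionError(
                f"QC accounting identity violated: {self.n_input} input != "
                f"{self.n_retained} retained + {len(self.removals)} removed"
            )


def run_qc(
    gt: GenotypeTable,
    samples: pd.DataFrame,
    panel: LocusPanel,
    cfg: QCConfig | None = None,
) -> tuple[GenotypeTable, pd.DataFrame, QCReport]:
    """Full QC pass: regenotype resolution, missingness filter, sex resolution."""
    cfg = cfg or QCConfig()
    n_input = gt.n_samples
    gt, regeno_report = resolve_regenotypes(gt)
    gt, miss_removed = filter_missing(gt, panel, cfg.max_missing_frac)
    samples = samples[samples["sample_id"].isin(gt.sample_ids)].reset_index(drop=True)
    samples, sex_removed = resolve_sex(samples)
    gt = gt.subset_samples(list(samples["sample_id"]))
    removals = pd.concat(
        [
            regeno_report.assign(reason="regenotype_duplicate")[["sample_id", "reason"]],
            miss_removed[["sample_id", "reason"]],
            sex_removed[["sample_id", "reason"]],
        ],
        ignore_index=True,
    )
    report = QCReport(n_input, gt.n_samples, removals)
    report.check()
    return gt, samples, report
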