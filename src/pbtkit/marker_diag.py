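"""Per-marker Mendelian-incompatibility accounting over assigned trios.

For each locus, counts the fraction of accepted trios (all three members
called) whose observed genotypes admit no Mendelian-consistent phase, and
inverts the expected incompatibility curve Q(epsilon) to estimate the
minimum per-gene-copy genotyping error rate needed to produce that
fraction.  Loci with incompatibility rates above 2% are flagged for
exclusion from the final parentage pass.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import MISSING, GenotypeTable
from .parentage import INCOMPATIBILITY, _MENDEL, genotype_error_kernel, hwe_priors

log = logging.getLogger(__name__)

EXCLUSION_RATE = 0.02


@dataclasses.dataclass
class MarkerDiagnostics:
    locus_id: str
    n_trios_called: int
    n_incompatible: int
    epsilon_hat: float | None
    excluded: bool

    @property
    def incompatibility_rate(self) -> float | None:
        if self.n_trios_called == 0:
            return None
        return self.n_incompatible / self.n_trios_called


def per_marker_incompatibility(
    trios: pd.DataFrame, genotypes: GenotypeTable
) -> pd.DataFrame:
    """Per-locus incompatibility counts over trios.

    ``trios`` needs offspring/mother/father fish-id columns resolvable in
    ``genotypes``.  Returns a frame with locus, n_trios_called,
    n_incompatible, rate and the >2% exclusion flag; loci never called in
    any complete trio get an undefined (NaN) rate and are flagged.
    """
    if len(trios) == 0:
        raise ValueError("no trios supplied")
    go = genotypes.codes[genotypes.index_of(trios["offspring"])]
    gm = genotypes.codes[genotypes.index_of(trios["mother"])]
    gf = genotypes.codes[genotypes.index_of(trios["father"])]
    called = (go != MISSING) & (gm != MISSING) & (gf != MISSING)
    inc = INCOMPATIBILITY[gm, gf, go] & called
    n_called = called.sum(axis=0)
    n_inc = inc.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_called > 0, n_inc / np.maximum(n_called, 1), np.nan)
    return pd.DataFrame(
        {
            "locus": genotypes.loci,
            "n_trios_called": n_called,
            "n_incompatible": n_inc,
            "incompatibility_rate": rate,
            "excluded": (rate > EXCLUSION_RATE) | (n_called == 0),
        }
    )


def expected_incompatibility_rate(epsilon: float, freq: float) -> float:
    """Q(epsilon): probability that a true parental trio at a biallelic
    locus with B-allele frequency ``freq`` presents an observed Mendelian
    incompatibility when each of the 6 gene copies errs independently.

    Computed by exhaustive enumeration over the 27 true and 27 observed
    genotype configurations: parents from Hardy-Weinberg priors, offspring
    by Mendelian transmission, observations through the error kernel.
    Q(0) = 0 and Q increases continuously from 0.
    """
    pr = hwe_priors(np.array([freq]))[0]
    E = genotype_error_kernel(epsilon)
    true_trio = np.einsum("m,f,mfo->mfo", pr, pr, _MENDEL)
    obs_trio = np.einsum("mfo,ma,fb,oc->abc", true_trio, E, E, E)
    return float(obs_trio[INCOMPATIBILITY[:3, :3, :3]].sum())


def estimate_min_error_rate(observed_rate: float, freq: float) -> float:
    """Solve Q(epsilon_hat) = observed incompatibility rate.

    Q is continuous and increasing on [0, 0.5) for polymorphic loci, so
    the root is found by bracketed bisection.  An observed rate of 0 maps
    to epsilon_hat = 0; a rate beyond the attainable maximum is capped at
    the upper bracket with a warning.
    """
    if observed_rate <= 0.0:
        return 0.0
    hi = 0.5 - 1e-9
    q_max = expected_incompatibility_rate(hi, freq)
    if observed_rate >= q_max:
        log.warning(
            "observed incompatibility rate %.4f exceeds attainable Q(max)=%.4f "
            "at freq %.3f; epsilon_hat capped", observed_rate, q_max, freq
        )
        return hi
    return float(
        brentq(lambda e: expected_incompatibility_rate(e, freq) - observed_rate, 0.0, hi)
    )


def diagnose_markers(
    trios: pd.DataFrame, genotypes: GenotypeTable, freqs: np.ndarray
) -> list[MarkerDiagnostics]:
    """Full per-marker diagnostics with error-rate estimates."""
    table = per_marker_incompatibility(trios, genotypes)
    out = []
    for row, freq in zip(table.itertuples(index=False), freqs):
        rate = row.incompatibility_rate
        eps_hat = None
        if row.n_trios_called > 0 and 0.0 < freq < 1.0:
            eps_hat = estimate_min_error_rate(float(rate), float(freq))
        elif row.n_trios_called > 0:
            eps_hat = 0.0 if rate == 0.0 else None
        out.append(
            MarkerDiagnostics(
                row.locus, int(row.n_trios_called), int(row.n_incompatible),
                eps_hat, bool(row.excluded),
            )
        )
    return out


def diagnostics_frame(diags: list[MarkerDiagnostics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [d.locus_id for d in diags],
            "n_trios_called": [d.n_trios_called for d in diags],
            "n_incompatible": [d.n_incompatible for d in diags],
            "incompatibility_rate": [d.incompatibility_rate for d in diags],
            "epsilon_hat": [d.epsilon_hat for d in diags],
            "excluded": [d.excluded for d in diags],
        }
    )
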