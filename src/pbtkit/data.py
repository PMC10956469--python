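"""Genotype and sample-metadata containers and their CSV dialect.

Genotypes are diploid calls at biallelic SNP loci, encoded per locus as
``0`` (A/A), ``1`` (A/B), ``2`` (B/B) and ``3`` (missing).  On disk a
genotype table has two allele columns per locus, named ``<locus>`` and
``<locus>_1``; a missing call is ``"0"`` in both columns.  This mirrors the
two-column SNP table layout commonly exported by genotyping platforms.
"""

from __future__ import annotations

import dataclasses
import io
from datetime import date

import numpy as np
import pandas as pd

MISSING = 3

#: allele letters used in the CSV dialect; "0" encodes a missing call
_ALLELES = ("A", "B")

#: decode (allele_a, allele_b) -> genotype code
_PAIR_TO_CODE = {
    ("A", "A"): 0,
    ("A", "B"): 1,
    ("B", "A"): 1,
    ("B", "B"): 2,
    ("0", "0"): MISSING,
}
_CODE_TO_PAIR = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}

SAMPLE_COLUMNS = [
    "sample_id",
    "program",
    "spawn_date",
    "phenotypic_sex",
    "genetic_sex",
    "length_mm",
    "adipose_present",
]


def spawn_season(d: date, boundary_month: int = 7) -> int:
    """Season label for a spawn date.

    A spawning season runs across the calendar-year boundary (December
    through February/March); dates from ``boundary_month`` 1 of year *y* to
    the day before ``boundary_month`` 1 of year *y+1* are labelled *y+1*,
    so a December spawner and a February spawner of one season share a
    label, and the label equals the calendar year of the season's January.
    """
    return d.year + 1 if d.month >= boundary_month else d.year


@dataclasses.dataclass
class GenotypeTable:
    """Diploid genotype calls for a set of samples on a shared locus panel.

    Attributes
    ----------
    sample_ids : list of str
    loci : list of str
    codes : int8 array, shape (n_samples, n_loci)
        Genotype codes 0/1/2, or 3 for a missing call.
    """

    sample_ids: list[str]
    loci: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, shape (n_samples, n_loci)."""
        return self.codes != MISSING

    def n_called(self) -> np.ndarray:
        """Number of called loci per sample."""
        return self.called().sum(axis=1)

    def index_of(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=np.intp)

    def subset_samples(self, sample_ids) -> "GenotypeTable":
        idx = self.index_of(sample_ids)
        return GenotypeTable(list(sample_ids), list(self.loci), self.codes[idx])

    def subset_loci(self, loci) -> "GenotypeTable":
        pos = {l: j for j, l in enumerate(self.loci)}
        idx = np.array([pos[l] for l in loci], dtype=np.intp)
        return GenotypeTable(list(self.sample_ids), list(loci), self.codes[:, idx])

    # ---------------------------------------------------------------- CSV I/O

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, list[str]] = {"sample_id": list(self.sample_ids)}
        for j, locus in enumerate(self.loci):
            a = [_CODE_TO_PAIR[c][0] for c in self.codes[:, j]]
            b = [_CODE_TO_PAIR[c][1] for c in self.codes[:, j]]
            cols[locus] = a
            cols[f"{locus}_1"] = b
        return pd.DataFrame(cols)

    def to_csv(self, path, seed: int | None = None) -> None:
        buf = io.StringIO()
        if seed is not None:
            buf.write(f"# seed={seed}\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        sample_ids = df["sample_id"].astype(str).tolist()
        loci = [c for c in df.columns if c != "sample_id" and not c.endswith("_1")]
        codes = np.empty((len(sample_ids), len(loci)), dtype=np.int8)
        for j, locus in enumerate(loci):
            a = df[locus].astype(str).to_numpy()
            b = df[f"{locus}_1"].astype(str).to_numpy()
            codes[:, j] = [_PAIR_TO_CODE[(x, y)] for x, y in zip(a, b)]
        return cls(sample_ids, loci, codes)

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, comment="#", dtype=str)
        return cls.from_frame(df)


def write_sample_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    buf = io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", parse_dates=["spawn_date"])
    df["spawn_date"] = df["spawn_date"].dt.date
    if "spawn_year" not in df.columns:
        df["spawn_year"] = [spawn_season(d) for d in df["spawn_date"]]
    return df
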