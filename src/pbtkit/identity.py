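"""Collapse sample ids from the same physical fish into individual clusters.

Repeat spawners and iteroparous fish are sampled once per spawning event,
so one fish can carry several sample ids.  Pairs of samples sharing at
least 95% of unordered genotypes over co-called loci are joined by an
edge; the connected components of that graph are the individuals.
Clusters whose members disagree on resolved sex, or contain a pair called
as opposite homozygotes at any locus, are removed as irreconcilable.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .config import IdentityConfig
from .data import MISSING, GenotypeTable


class SpawnEvent(NamedTuple):
    sample_id: str
    program: str
    spawn_date: object
    spawn_year: int


@dataclasses.dataclass
class MatchEdge:
    sample_a: str
    sample_b: str
    shared_loci: int
    matching_loci: int

    @property
    def match_fraction(self) -> float:
        return self.matching_loci / self.shared_loci


@dataclasses.dataclass
class IndividualCluster:
    """One physical fish: its sample ids and per-fish attributes."""

    fish_id: str
    members: list[str]
    canonical_sample: str
    resolved_sex: str | None
    spawn_events: list[SpawnEvent]  # sorted by (spawn_date, sample_id)
    status: str = "valid"

    @property
    def n_events(self) -> int:
        return len(self.spawn_events)

    @property
    def spawn_years(self) -> list[int]:
        return sorted({e.spawn_year for e in self.spawn_events})

    @property
    def programs(self) -> list[str]:
        return sorted({e.program for e in self.spawn_events})


def match_fraction(
    g1: np.ndarray, g2: np.ndarray, min_shared_loci: int = 60
) -> MatchEdge | None:
    """Unordered-genotype agreement over loci called in both samples.

    Returns None when fewer than ``min_shared_loci`` loci are co-called
    (too little information for a reliable identity comparison).
    """
    both = (g1 != MISSING) & (g2 != MISSING)
    shared = int(both.sum())
    if shared < min_shared_loci:
        return None
    matching = int((g1[both] == g2[both]).sum())
    return MatchEdge("a", "b", shared, matching)


def _pair_matrices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (matching, shared) locus counts via one-hot matrix products."""
    called = (codes != MISSING).astype(np.float32)
    n, L = codes.shape
    flat = np.zeros((n, 3 * L), dtype=np.float32)
    for g in range(3):
        flat[:, g * L : (g + 1) * L] = codes == g
    matches = flat @ flat.T
    shared = called @ called.T
    return np.rint(matches).astype(np.int32), np.rint(shared).astype(np.int32)


def compute_edges(
    gt: GenotypeTable, cfg: IdentityConfig | None = None
) -> list[MatchEdge]:
    """All sample pairs whose match fraction reaches the identity threshold."""
    cfg = cfg or IdentityConfig()
    matches, shared = _pair_matrices(gt.codes)
    ok = (shared >= cfg.min_shared_loci) & (
        matches >= cfg.match_threshold * shared
    )
    ok = np.triu(ok, k=1)
    edges = []
    for i, j in np.argwhere(ok):
        edges.append(
            MatchEdge(
                gt.sample_ids[i], gt.sample_ids[j],
                int(shared[i, j]), int(matches[i, j]),
            )
        )
    return edges


def build_clusters(
    gt: GenotypeTable,
    samples: pd.DataFrame,
    edges: list[MatchEdge],
) -> list[IndividualCluster]:
    """Connected components of the match graph, one cluster per fish.

    Singleton samples become singleton clusters.  The canonical sample is
    the member with fewest missing loci (ties broken toward the
    lexicographically smallest sample id), which also names the fish.
    Output order is deterministic: clusters sorted by fish id.
    """
    graph = nx.Graph()
    graph.add_nodes_from(gt.sample_ids)
    graph.add_edges_from((e.sample_a, e.sample_b) for e in edges)
    n_called = dict(zip(gt.sample_ids, gt.n_called()))
    has_sex = "resolved_sex" in samples.columns
    meta = {
        row.sample_id: (
            SpawnEvent(row.sample_id, row.program, row.spawn_date, int(row.spawn_year)),
            row.resolved_sex if has_sex else None,
        )
        for row in samples.itertuples(index=False)
    }
    clusters: list[IndividualCluster] = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        canonical = min(members, key=lambda s: (-n_called[s], s))
        events = sorted(
            (meta[s][0] for s in members), key=lambda e: (str(e.spawn_date), e.sample_id)
        )
        sexes = {meta[s][1] for s in members}
        resolved = sexes.pop() if len(sexes) == 1 else None
        clusters.append(IndividualCluster(canonical, members, canonical, resolved, events))
    clusters.sort(key=lambda c: c.fish_id)
    return clusters


def validate_clusters(
    clusters: list[IndividualCluster], gt: GenotypeTable
) -> tuple[list[IndividualCluster], pd.DataFrame]:
    """Remove clusters with inconsistent sex or opposite-homozygote members.

    A multi-sample fish whose samples were recorded with different
    resolved sexes cannot be placed in parent pools; a pair of member
    genotypes called as different homozygotes at any locus indicates a
    sample mix-up rather than genotyping noise.  Both are removed and
    reported.
    """
    valid: list[IndividualCluster] = []
    removed: list[tuple[str, str, int]] = []
    idx = {s: i for i, s in enumerate(gt.sample_ids)}
    for cl in clusters:
        if cl.resolved_sex is None:
            cl.status = "removed_sex_conflict"
            removed.append((cl.fish_id, "sex_conflict", len(cl.members)))
            continue
        bad = False
        mem = [gt.codes[idx[s]] for s in cl.members]
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                a, b = mem[i], mem[j]
                if (((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).any():
                    bad = True
                    break
            if bad:
                break
        if bad:
            cl.status = "removed_homozygote_conflict"
            removed.append((cl.fish_id, "homozygote_conflict", len(cl.members)))
        else:
            valid.append(cl)
    report = pd.DataFrame(removed, columns=["fish_id", "reason", "n_members"])
    return valid, report


def resolve_identity(
    gt: GenotypeTable, samples: pd.DataFrame, cfg: IdentityConfig | None = None
) -> tuple[list[IndividualCluster], pd.DataFrame]:
    """Full identity pass: edges, components, validation."""
    cfg = cfg or IdentityConfig()
    edges = compute_edges(gt, cfg)
    clusters = build_clusters(gt, samples, edges)
    assert sum(len(c.members) for c in clusters) == gt.n_samples
    return validate_clusters(clusters, gt)


def clusters_to_frame(clusters: list[IndividualCluster]) -> pd.DataFrame:
    """Cluster table: fish id, members, sex, spawn events."""
    rows = []
    for c in clusters:
        programs = c.programs
        rows.append(
            {
                "fish_id": c.fish_id,
                "members": ";".join(c.members),
                "canonical_sample": c.canonical_sample,
                "resolved_sex": c.resolved_sex,
                "n_spawn_events": c.n_events,
                "programs": ";".join(programs),
                "cross_program": len(programs) > 1,
                "spawn_dates": ";".join(str(e.spawn_date) for e in c.spawn_events),
                "status": c.status,
            }
        )
    return pd.DataFrame(rows)
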