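"""Molecular-group construction and trueness-to-type categorization.

Accessions whose harmonized SSR fingerprints agree at more than a tolerance
threshold (default 90% of alleles at mutually typed loci, matching the
error margin of routine fragment analysis) are treated as clones of one
cultivar and collected into a *molecular group*.  Combining the genetic
groups with the pomologists' determinations yields per-tree authenticity
categories:

1. true-to-type (determination consistent with the group consensus name);
3. own molecular group but no pomological reference available;
4. no pomological determination possible;
5. determination approved with reservation.

Category 2 is reserved for sour cherries and never emitted here.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .core import AccessionRecord, PomologyKind, SSRGenotype

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.90
DEFAULT_MIN_SHARED = 8


@dataclass(frozen=True)
class SimilarityResult:
    """Pairwise simple-matching similarity between two fingerprints."""

    id1: str
    id2: str
    shared_loci: int
    matching_alleles: int
    similarity: float
    comparable: bool

    def __post_init__(self) -> None:
        if self.comparable and not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity out of [0, 1]")


@dataclass(frozen=True)
class MolecularGroup:
    group_id: str
    member_ids: tuple[str, ...]
    representative: SSRGenotype
    representative_support: int

    @property
    def size(self) -> int:
        return len(self.member_ids)


class Category(enum.IntEnum):
    TRUE_TO_TYPE = 1
    OWN_GROUP_NO_REFERENCE = 3
    NO_POMOLOGICAL_DETERMINATION = 4
    APPROVED_WITH_RESERVATION = 5


@dataclass(frozen=True)
class TruenessAssessment:
    accession_id: str
    category: Optional[Category]
    resolved_name: str = ""
    relabel: bool = False
    unresolved: bool = False

    def __post_init__(self) -> None:
        if self.category in (Category.TRUE_TO_TYPE, Category.APPROVED_WITH_RESERVATION):
            if not self.resolved_name:
                raise ValueError(f"category {self.category} requires a resolved name")


def _pair_match_count(p1: tuple[int, int], p2: tuple[int, int]) -> int:
    """Multiset-intersection size of two allele pairs (0, 1 or 2)."""
    m1 = (p1[0] == p2[0]) + (p1[1] == p2[1])
    m2 = (p1[0] == p2[1]) + (p1[1] == p2[0])
    return max(m1, m2)


def similarity(
    g1: SSRGenotype,
    g2: SSRGenotype,
    min_shared: int = DEFAULT_MIN_SHARED,
    id1: str = "g1",
    id2: str = "g2",
    mode: str = "allele",
) -> SimilarityResult:
    """Simple-matching similarity over loci typed in both genotypes.

    ``mode='allele'`` (default) counts matched alleles by greedy multiset
    matching of the two pairs per locus: similarity = matched alleles /
    (2 x shared loci).  ``mode='locus'`` scores a locus 1 only when the two
    pairs are identical as multisets.  Pairs sharing fewer than
    ``min_shared`` typed loci are flagged not comparable.
    """
    shared = 0
    matched = 0
    loci_matched = 0
    for locus, p1 in g1.alleles.items():
        p2 = g2.alleles.get(locus)
        if p1 is None or p2 is None:
            continue
        shared += 1
        m = _pair_match_count(p1, p2)
        matched += m
        loci_matched += m == 2
    comparable = shared >= min_shared
    if not comparable:
        sim = float("nan")
    elif mode == "allele":
        sim = matched / (2 * shared)
    elif mode == "locus":
        sim = loci_matched / shared
    else:
        raise ValueError(f"unknown similarity mode {mode!r}")
    return SimilarityResult(id1, id2, shared, matched, sim, comparable)


def _genotype_arrays(
    genotypes: Sequence[SSRGenotype], loci: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(n, L) arrays of the sorted allele pairs; -1 marks missing."""
    n, L = len(genotypes), len(loci)
    a1 = np.full((n, L), -1, dtype=np.int64)
    a2 = np.full((n, L), -1, dtype=np.int64)
    for i, g in enumerate(genotypes):
        for j, locus in enumerate(loci):
            pair = g.alleles.get(locus)
            if pair is not None:
                a1[i, j], a2[i, j] = pair
    return a1, a2


def similarity_matrix(
    genotypes: Sequence[SSRGenotype],
    min_shared: int = DEFAULT_MIN_SHARED,
    mode: str = "allele",
) -> tuple[np.ndarray, np.ndarray]:
    """Dense pairwise similarity: (sim, shared_loci) matrices.

    ``sim[i, j]`` is NaN for pairs sharing fewer than ``min_shared`` typed
    loci; the diagonal is 1 (when enough loci are typed).  Vectorized per
    row, suitable for collections of a few thousand fingerprints.
    """
    if mode not in ("allele", "locus"):
        raise ValueError(f"unknown similarity mode {mode!r}")
    loci = list(genotypes[0].alleles)
    a1, a2 = _genotype_arrays(genotypes, loci)
    n = len(genotypes)
    typed = a1 >= 0
    sim = np.full((n, n), np.nan)
    shared_out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = typed[i] & typed  # (n, L)
        shared = both.sum(axis=1)
        m1 = (a1[i] == a1).astype(np.int8) + (a2[i] == a2).astype(np.int8)
        m2 = (a1[i] == a2).astype(np.int8) + (a2[i] == a1).astype(np.int8)
        m = np.maximum(m1, m2)
        m = np.where(both, m, 0)
        if mode == "allele":
            with np.errstate(invalid="ignore", divide="ignore"):
                s = m.sum(axis=1) / (2 * shared)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                s = (m == 2).sum(axis=1) / shared
        s = np.where(shared >= min_shared, s, np.nan)
        sim[i] = s
        shared_out[i] = shared
    return sim, shared_out


def build_groups(
    records: Sequence[AccessionRecord],
    threshold: float = DEFAULT_THRESHOLD,
    min_shared: int = DEFAULT_MIN_SHARED,
    mode: str = "allele",
) -> list[MolecularGroup]:
    """Partition accessions into molecular groups by single linkage.

    An edge joins two accessions when their similarity strictly exceeds
    ``threshold``; groups are the connected components, so near-identical
    fingerprints chain into one group (transitive merges are logged for
    curator review).  The representative genotype is the most frequent
    exact genotype in the group; ties go to the more complete genotype,
    then the lexicographically smallest accession id.  Groups are returned
    sorted by size (descending), then by smallest member id.
    """
    ids = [r.accession_id for r in records]
    genotypes = [r.genotype for r in records]
    sim, _ = similarity_matrix(genotypes, min_shared=min_shared, mode=mode)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(records)))
    ii, jj = np.where(np.triu(sim > threshold, k=1))
    graph.add_edges_from(zip(ii.tolist(), jj.tolist()))

    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), min(ids[i] for i in c)))

    groups: list[MolecularGroup] = []
    for gix, comp in enumerate(components, start=1):
        # transitive-merge audit: any member pair at or below threshold?
        if len(comp) > 2:
            sub = sim[np.ix_(comp, comp)]
            low = np.nanmin(sub[np.triu_indices(len(comp), k=1)])
            if low <= threshold:
                log.info(
                    "group %d: transitive merge (min within-group similarity %.3f)",
                    gix,
                    low,
                )
        counts: dict[tuple, list[int]] = {}
        for i in comp:
            counts.setdefault(genotypes[i].key(), []).append(i)
        # prefer frequency, then genotype completeness, then smallest id
        candidates = sorted(
            counts.items(),
            key=lambda kv: (
                -len(kv[1]),
                -genotypes[kv[1][0]].n_typed,
                min(ids[i] for i in kv[1]),
            ),
        )
        best_key, best_members = candidates[0]
        groups.append(
            MolecularGroup(
                group_id=f"MG{gix:04d}",
                member_ids=tuple(ids[i] for i in comp),
                representative=genotypes[best_members[0]],
                representative_support=len(best_members),
            )
        )
    return groups


def _group_consensus(
    group: MolecularGroup, by_id: dict[str, AccessionRecord]
) -> tuple[str, bool]:
    """Majority pomologically determined name in a group.

    Returns (name, tie); name is empty when no member is determined.
    """
    votes: dict[str, int] = {}
    for acc in group.member_ids:
        st = by_id[acc].pomological_status
        if st.kind is PomologyKind.DETERMINED:
            votes[st.name] = votes.get(st.name, 0) + 1
    if not votes:
        return "", False
    best = max(votes.values())
    winners = sorted(n for n, v in votes.items() if v == best)
    return winners[0], len(winners) > 1


def assign_categories(
    groups: Sequence[MolecularGroup],
    records: Sequence[AccessionRecord],
    reference_names: Optional[set[str]] = None,
) -> list[TruenessAssessment]:
    """Assign the trueness-to-type category to every accession.

    Per accession: a pomological determination consistent with its group's
    consensus name gives category 1 under that name; a determination that
    conflicts with the consensus is reported as category 1 under the
    consensus name with a relabel flag.  Accessions without a pomological
    reference in a group lacking any determined member are category 3;
    undetermined trees are category 4 and reservations category 5.  A group
    whose determined names tie is reported UNRESOLVED (no category) for its
    determined members.
    """
    by_id = {r.accession_id: r for r in records}
    reference_names = reference_names or set()
    out: list[TruenessAssessment] = []
    for group in groups:
        consensus, tie = _group_consensus(group, by_id)
        for acc in group.member_ids:
            st = by_id[acc].pomological_status
            if st.kind is PomologyKind.NOT_DETERMINED:
                out.append(
                    TruenessAssessment(acc, Category.NO_POMOLOGICAL_DETERMINATION)
                )
            elif st.kind is PomologyKind.WITH_RESERVATION:
                out.append(
                    TruenessAssessment(
                        acc, Category.APPROVED_WITH_RESERVATION, resolved_name=st.name
                    )
                )
            elif st.kind is PomologyKind.DETERMINED:
                if tie:
                    out.append(TruenessAssessment(acc, None, unresolved=True))
                elif st.name == consensus:
                    out.append(
                        TruenessAssessment(
                            acc, Category.TRUE_TO_TYPE, resolved_name=st.name
                        )
                    )
                else:
                    log.info(
                        "%s determined %r but group consensus is %r: relabel",
                        acc,
                        st.name,
                        consensus,
                    )
                    out.append(
                        TruenessAssessment(
                            acc,
                            Category.TRUE_TO_TYPE,
                            resolved_name=consensus,
                            relabel=True,
                        )
                    )
            else:  # NO_REFERENCE
                if consensus and not tie:
                    # the group is resolved by other members' determinations
                    out.append(
                        TruenessAssessment(
                            acc,
                            Category.TRUE_TO_TYPE,
                            resolved_name=consensus,
                            relabel=True,
                        )
                    )
                else:
                    out.append(
                        TruenessAssessment(acc, Category.OWN_GROUP_NO_REFERENCE)
                    )
    order = {r.accession_id: i for i, r in enumerate(records)}
    out.sort(key=lambda a: order[a.accession_id])
    return out


def category_summary(assessments: Sequence[TruenessAssessment]) -> dict:
    """Counts and percentages per category (layout of the published
    authenticity summary table)."""
    total = len(assessments)
    counts: dict[str, int] = {}
    for a in assessments:
        key = "UNRESOLVED" if a.category is None else a.category.name
        counts[key] = counts.get(key, 0) + 1
    return {
        "total": total,
        "counts": counts,
        "percent": {k: round(100.0 * v / total, 2) for k, v in counts.items()},
    }
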