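"""Per-locus diversity parameters, identity probabilities, rarefied allelic
richness, minimal discriminating marker sets, and pairwise Fst.

All statistics operate on the deduplicated unique genotypes (one per
molecular group), matching genebank reporting practice.  Per-locus
quantities (allele count Na, effective alleles Ne = 1/Sum(p_i^2), observed
and expected heterozygosity, rarefied allelic richness Ar(g)) follow the
GenAlEx / ADZE definitions; the probability of identity uses

    PI     = 2 (Sum p_i^2)^2 - Sum p_i^4
    PI_sib = 0.25 + 0.5 Sum p_i^2 + 0.5 (Sum p_i^2)^2 - 0.25 Sum p_i^4

the chance that two random unrelated (resp. full-sib) diploids under
Hardy-Weinberg equilibrium share a genotype at the locus; the product over
loci gives the multilocus identity probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MarkerPanel, SSRGenotype


@dataclass(frozen=True)
class LocusFrequencies:
    """Allele counts and relative frequencies at one locus."""

    locus: str
    counts: dict[int, int]  # allele size -> gene copies
    n_individuals: int  # individuals typed at the locus
    n_heterozygotes: int

    @property
    def n_copies(self) -> int:
        return 2 * self.n_individuals

    @property
    def freqs(self) -> dict[int, float]:
        total = self.n_copies
        return {a: c / total for a, c in self.counts.items()}

    @property
    def freq_array(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=float) / self.n_copies


@dataclass(frozen=True)
class AlleleFrequencyTable:
    loci: tuple[str, ...]
    by_locus: dict[str, LocusFrequencies]

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.by_locus[locus]


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    N: int
    Na: int
    Ne: float
    Ho: float
    He: float
    Ar: Optional[float]
    PI: float
    PIsib: float


def allele_frequencies(
    genotypes: Sequence[SSRGenotype], panel: Optional[MarkerPanel] = None
) -> AlleleFrequencyTable:
    """Tabulate per-locus allele counts and relative frequencies.

    Each genotype contributes two gene copies per non-missing locus; loci
    typed in no individual are excluded with a warning.
    """
    loci = list(panel) if panel is not None else list(genotypes[0].alleles)
    by_locus: dict[str, LocusFrequencies] = {}
    kept: list[str] = []
    for locus in loci:
        counts: dict[int, int] = {}
        n_ind = 0
        n_het = 0
        for g in genotypes:
            pair = g.alleles.get(locus)
            if pair is None:
                continue
            n_ind += 1
            n_het += pair[0] != pair[1]
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
        if n_ind == 0:
            warnings.warn(f"locus {locus} typed in 0 individuals; excluded", stacklevel=2)
            continue
        kept.append(locus)
        by_locus[locus] = LocusFrequencies(
            locus, dict(sorted(counts.items())), n_ind, n_het
        )
    return AlleleFrequencyTable(tuple(kept), by_locus)


def _sum_powers(p: np.ndarray) -> tuple[float, float]:
    return float(np.sum(p**2)), float(np.sum(p**4))


def pi_single_locus(p: np.ndarray) -> tuple[float, float]:
    """(PI, PIsib) for one locus from its allele-frequency vector."""
    s2, s4 = _sum_powers(p)
    pi = 2.0 * s2**2 - s4
    pisib = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    return pi, pisib


def allelic_richness(
    freqs: AlleleFrequencyTable, g: Optional[int] = None
) -> tuple[dict[str, float], int]:
    """Rarefied allelic richness Ar(g) per locus at g gene copies.

    Ar(g) = Sum_i [1 - C(N - n_i, g) / C(N, g)] — the expected number of
    distinct alleles in a random subsample of g of the locus's N gene
    copies (exact rational arithmetic).  Default g = 2 x the smallest
    per-locus sample size, the largest size every locus supports.
    """
    if g is None:
        g = 2 * min(freqs[l].n_individuals for l in freqs.loci)
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2 gene copies")
    out: dict[str, float] = {}
    for locus in freqs.loci:
        lf = freqs[locus]
        N = lf.n_copies
        if g > N:
            raise ValueError(
                f"g={g} exceeds gene copies N={N} at locus {locus}"
            )
        denom = math.comb(N, g)
        ar = 0.0
        for n_i in lf.counts.values():
            absent = math.comb(N - n_i, g) if N - n_i >= g else 0
            ar += float(1 - Fraction(absent, denom))
        out[locus] = ar
    return out, g


@dataclass(frozen=True)
class PIResult:
    """Per-locus identity probabilities and their cumulative products."""

    loci: tuple[str, ...]
    pi: dict[str, float]
    pisib: dict[str, float]
    order_pi: tuple[str, ...]  # loci sorted by ascending PI
    order_pisib: tuple[str, ...]
    cumulative_pi: tuple[float, ...]  # running product along order_pi
    cumulative_pisib: tuple[float, ...]

    @property
    def mean_pi(self) -> float:
        return float(np.mean(list(self.pi.values())))

    @property
    def mean_pisib(self) -> float:
        return float(np.mean(list(self.pisib.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Locus": l,
                "PI": self.pi[l],
                "PIsib": self.pisib[l],
            }
            for l in self.loci
        ]
        return pd.DataFrame(rows)


def pi(freqs: AlleleFrequencyTable) -> PIResult:
    """PI and PIsib per locus plus cumulative multilocus products.

    The cumulative products follow loci sorted by ascending single-locus
    value (most discriminating first), the ordering used when choosing a
    minimal marker set.
    """
    pis = {}
    pisibs = {}
    for locus in freqs.loci:
        p = freqs[locus].freq_array
        pis[locus], pisibs[locus] = pi_single_locus(p)
    order_pi = tuple(sorted(freqs.loci, key=lambda l: (pis[l], l)))
    order_pisib = tuple(sorted(freqs.loci, key=lambda l: (pisibs[l], l)))
    cum_pi = tuple(np.cumprod([pis[l] for l in order_pi]).tolist())
    cum_pisib = tuple(np.cumprod([pisibs[l] for l in order_pisib]).tolist())
    return PIResult(
        freqs.loci, pis, pisibs, order_pi, order_pisib, cum_pi, cum_pisib
    )


def locus_diversity(
    genotypes: Sequence[SSRGenotype],
    panel: Optional[MarkerPanel] = None,
    rarefaction_g: Optional[int] = None,
) -> pd.DataFrame:
    """The per-locus diversity table (Locus, N, Na, Ne, Ho, He, Ar, PI,
    PIsib) with an unweighted arithmetic Mean row."""
    freqs = allele_frequencies(genotypes, panel)
    ar, g = allelic_richness(freqs, rarefaction_g)
    pres = pi(freqs)
    rows = []
    for locus in freqs.loci:
        lf = freqs[locus]
        p = lf.freq_array
        s2 = float(np.sum(p**2))
        he = 1.0 - s2
        ne = 1.0 / s2
        rows.append(
            LocusDiversity(
                locus=locus,
                N=lf.n_individuals,
                Na=len(lf.counts),
                Ne=ne,
                Ho=lf.n_heterozygotes / lf.n_individuals,
                He=he,
                Ar=ar[locus],
                PI=pres.pi[locus],
                PIsib=pres.pisib[locus],
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    mean = df[["Na", "Ne", "Ho", "He", "Ar", "PI", "PIsib"]].mean()
    mean_row = {"locus": "Mean", "N": pd.NA, **mean.to_dict()}
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    df.attrs["rarefaction_g"] = g
    return df


@dataclass(frozen=True)
class MinimalMarkerSet:
    mode: str
    loci: tuple[str, ...]  # loci included, in the order added
    size: int
    unresolved_pairs: tuple[tuple[int, int], ...] = ()
    cumulative: tuple[float, ...] = ()


def _pairs_identical_at(
    genotypes: Sequence[SSRGenotype], loci: Sequence[str]
) -> list[tuple[int, int]]:
    """Index pairs of genotypes not discriminated by any of the loci.

    A locus discriminates a pair only when both genotypes are typed there
    and the allele multisets differ.
    """
    n = len(genotypes)
    undetermined = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for locus in loci:
        still = []
        for i, j in undetermined:
            p1 = genotypes[i].alleles.get(locus)
            p2 = genotypes[j].alleles.get(locus)
            if p1 is not None and p2 is not None and p1 != p2:
                continue
            still.append((i, j))
        undetermined = still
        if not undetermined:
            break
    return undetermined


def minimal_marker_set(
    genotypes: Sequence[SSRGenotype],
    freqs: AlleleFrequencyTable,
    mode: str = "empirical",
    sib_threshold: Optional[float] = None,
) -> MinimalMarkerSet:
    """Smallest prefix of the PI-ranked panel that discriminates the set.

    ``empirical`` adds loci in ascending-PI order until every genotype pair
    differs at >=1 included locus (pairs identical across the whole panel
    are returned unresolved).  ``sib`` orders by ascending PIsib and stops
    when the cumulative PIsib drops below a chance-identity threshold,
    default 1 / C(n, 2) — the expected number of coincidentally matching
    sib-level pairs falling below one.
    """
    pres = pi(freqs)
    n = len(genotypes)
    if mode == "empirical":
        chosen: list[str] = []
        for locus in pres.order_pi:
            chosen.append(locus)
            if not _pairs_identical_at(genotypes, chosen):
                return MinimalMarkerSet("empirical", tuple(chosen), len(chosen))
        unresolved = _pairs_identical_at(genotypes, list(pres.order_pi))
        return MinimalMarkerSet(
            "empirical", pres.order_pi, len(pres.order_pi), tuple(unresolved)
        )
    if mode == "sib":
        if sib_threshold is None:
            sib_threshold = 1.0 / math.comb(n, 2)
        chosen = []
        cum: list[float] = []
        running = 1.0
        for locus in pres.order_pisib:
            chosen.append(locus)
            running *= pres.pisib[locus]
            cum.append(running)
            if running < sib_threshold:
                return MinimalMarkerSet(
                    "sib", tuple(chosen), len(chosen), cumulative=tuple(cum)
                )
        return MinimalMarkerSet(
            "sib",
            tuple(chosen),
            len(chosen),
            unresolved_pairs=tuple(_pairs_identical_at(genotypes, chosen)),
            cumulative=tuple(cum),
        )
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class FstResult:
    label1: str
    label2: str
    fst: float
    per_locus: dict[str, float]


def _cluster_freqs(
    genotypes: Sequence[SSRGenotype],
    labels: Sequence[str],
    panel: Optional[MarkerPanel],
) -> dict[str, AlleleFrequencyTable]:
    groups: dict[str, list[SSRGenotype]] = {}
    for g, lab in zip(genotypes, labels):
        groups.setdefault(lab, []).append(g)
    out = {}
    for lab, gs in sorted(groups.items()):
        if len(gs) < 2:
            warnings.warn(f"cluster {lab!r} has <2 genotypes; excluded", stacklevel=3)
            continue
        out[lab] = allele_frequencies(gs, panel)
    return out


def fst(
    genotypes: Sequence[SSRGenotype],
    labels: Sequence[str],
    panel: Optional[MarkerPanel] = None,
) -> list[FstResult]:
    """Pairwise Wright's Fst between supplied cluster labels.

    Per locus, Fst = (Ht - Hs) / Ht with Hs the unweighted mean expected
    heterozygosity of the two clusters and Ht the expected heterozygosity
    of their unweighted mean allele frequencies; the reported value is the
    mean over loci with Ht > 0.
    """
    if len(genotypes) != len(labels):
        raise ValueError("genotypes and labels differ in length")
    tables = _cluster_freqs(genotypes, labels, panel)
    if len(tables) < 2:
        raise ValueError("need at least two clusters of size >= 2")
    names = sorted(tables)
    results = []
    for i, l1 in enumerate(names):
        for l2 in names[i + 1 :]:
            t1, t2 = tables[l1], tables[l2]
            per_locus = {}
            for locus in t1.loci:
                if locus not in t2.by_locus:
                    continue
                f1, f2 = t1[locus].freqs, t2[locus].freqs
                alleles = set(f1) | set(f2)
                p1 = np.array([f1.get(a, 0.0) for a in alleles])
                p2 = np.array([f2.get(a, 0.0) for a in alleles])
                hs = 0.5 * ((1 - np.sum(p1**2)) + (1 - np.sum(p2**2)))
                pbar = 0.5 * (p1 + p2)
                ht = 1 - float(np.sum(pbar**2))
                if ht > 0:
                    per_locus[locus] = (ht - hs) / ht
            value = float(np.mean(list(per_locus.values()))) if per_locus else 0.0
            results.append(FstResult(l1, l2, value, per_locus))
    return results
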