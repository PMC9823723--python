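"""Core domain types for SSR genebank curation.

The objects here model what a genebank curator actually handles: a marker
panel of microsatellite (SSR) loci, per-tree diploid fragment-length
profiles, accession passport data with a pomological determination, and
pedigree hypotheses to be verified genetically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

#: The 16 ECPGR-recommended sweet cherry SSR loci, in panel order.
ECPGR_CHERRY_LOCI: tuple[str, ...] = (
    "BPPCT037",
    "CPPCT006",
    "CPPCT022",
    "EMPA002",
    "EMPA003",
    "EMPA017",
    "EMPA026",
    "EMPaS01",
    "EMPaS02",
    "EMPaS06",
    "EMPaS10",
    "EMPaS12",
    "EMPaS14",
    "PceGA34",
    "PS05C03",
    "UDP98-412",
)

AllelePair = tuple[int, int]


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered set of SSR loci with optional motif lengths and size ranges.

    Parameters
    ----------
    loci
        Ordered locus names; must be unique and non-empty.
    motif_bp
        Optional repeat-motif length per locus (bp); dinucleotide SSRs use 2.
    size_range
        Optional (min, max) expected fragment size per locus (bp).
    """

    loci: tuple[str, ...]
    motif_bp: Mapping[str, int] = field(default_factory=dict)
    size_range: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("marker panel must contain at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[str]:
        return iter(self.loci)

    @classmethod
    def cherry_default(cls) -> "MarkerPanel":
        """The standard 16-locus ECPGR sweet cherry panel (2 bp motifs)."""
        return cls(loci=ECPGR_CHERRY_LOCI, motif_bp={n: 2 for n in ECPGR_CHERRY_LOCI})


@dataclass(frozen=True)
class SSRGenotype:
    """A diploid multi-locus fragment-length profile.

    Each locus carries an unordered pair of allele sizes in bp, stored sorted
    ascending (homozygotes as a duplicated size), or ``None`` for missing.
    """

    alleles: Mapping[str, Optional[AllelePair]]

    def __post_init__(self) -> None:
        canon: dict[str, Optional[AllelePair]] = {}
        any_typed = False
        for locus, pair in self.alleles.items():
            if pair is None:
                canon[locus] = None
                continue
            a, b = int(pair[0]), int(pair[1])
            if a <= 0 or b <= 0:
                raise ValueError(f"allele sizes must be positive at {locus}: {pair}")
            canon[locus] = (a, b) if a <= b else (b, a)
            any_typed = True
        if not any_typed:
            raise ValueError("genotype must have at least one non-missing locus")
        object.__setattr__(self, "alleles", canon)

    def __getitem__(self, locus: str) -> Optional[AllelePair]:
        return self.alleles[locus]

    def is_missing(self, locus: str) -> bool:
        return self.alleles.get(locus) is None

    @property
    def typed_loci(self) -> tuple[str, ...]:
        return tuple(l for l, p in self.alleles.items() if p is not None)

    @property
    def n_typed(self) -> int:
        return len(self.typed_loci)

    def key(self, loci: Optional[tuple[str, ...]] = None) -> tuple:
        """Hashable canonical form (used for exact-genotype counting)."""
        loci = loci if loci is not None else tuple(self.alleles)
        return tuple((l, self.alleles.get(l)) for l in loci)


class PomologyKind(enum.Enum):
    """Outcome classes of the pomological (phenotypic) determination."""

    DETERMINED = "determined"
    NO_REFERENCE = "no_reference"
    NOT_DETERMINED = "not_determined"
    WITH_RESERVATION = "with_reservation"


@dataclass(frozen=True)
class PomologicalStatus:
    kind: PomologyKind
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind in (PomologyKind.DETERMINED, PomologyKind.WITH_RESERVATION):
            if not self.name:
                raise ValueError(f"{self.kind.value} requires a cultivar name")

    @classmethod
    def determined(cls, name: str) -> "PomologicalStatus":
        return cls(PomologyKind.DETERMINED, name)

    @classmethod
    def no_reference(cls) -> "PomologicalStatus":
        return cls(PomologyKind.NO_REFERENCE)

    @classmethod
    def not_determined(cls) -> "PomologicalStatus":
        return cls(PomologyKind.NOT_DETERMINED)

    @classmethod
    def with_reservation(cls, name: str) -> "PomologicalStatus":
        return cls(PomologyKind.WITH_RESERVATION, name)


@dataclass(frozen=True)
class AccessionRecord:
    """One curated tree: passport fields plus its SSR genotype."""

    accession_id: str
    collection: str
    assumed_name: str
    genotype: SSRGenotype
    pomological_status: PomologicalStatus = field(
        default_factory=PomologicalStatus.not_determined
    )
    lab_batch: str = ""


@dataclass(frozen=True)
class PedigreeHypothesis:
    """A literature-derived parentage claim: child and its assumed parents.

    ``UNKNOWN`` (or empty) marks a parent with no genotyped candidate, e.g.
    open-pollinated fathers; at least one parent must be named.
    """

    child: str
    assumed_mother: str = ""
    assumed_father: str = ""

    UNKNOWN = ""

    def __post_init__(self) -> None:
        mother = "" if self.assumed_mother.upper() == "UNKNOWN" else self.assumed_mother
        father = "" if self.assumed_father.upper() == "UNKNOWN" else self.assumed_father
        object.__setattr__(self, "assumed_mother", mother)
        object.__setattr__(self, "assumed_father", father)
        if not mother and not father:
            raise ValueError("at least one parent must be named")
        if self.child in (mother, father):
            raise ValueError("child cannot be its own parent")
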