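"""Synthetic genebank collections with known ground truth.

The generator emulates the statistical structure of a clonal fruit
collection genotyped with dinucleotide SSRs: multi-allelic loci on a
strictly 2 bp allele ladder with Dirichlet-distributed frequencies,
cultivars as Hardy-Weinberg founder draws or designed crosses (trios and
full-sib families), and per-tree clones degraded by per-reaction
mistyping (~10%, the routine PCR-artifact rate), +/-1 bp sizing jitter,
missing loci, and constant per-locus inter-laboratory size offsets.

Every corruption is logged per accession, so tests can replay them onto
the pristine genotypes and verify the bookkeeping exactly, and the
generator certifies the similarity margins (worst within-cultivar clone
similarity vs. best between-cultivar similarity) on which duplicate
detection relies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    AccessionRecord,
    MarkerPanel,
    PedigreeHypothesis,
    PomologicalStatus,
    SSRGenotype,
)
from .identity_dedup import similarity

CorruptionOp = tuple  # ("mistype", locus, slot, new) | ("jitter", locus, slot, d) | ("missing", locus)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic collection.

    Defaults model a mid-size curated collection: ~15 alleles per locus on
    a 2 bp ladder (Dirichlet-skewed frequencies tuned to an expected
    heterozygosity near 0.7), 1-6 clonal trees per cultivar, 10%
    per-reaction mistyping, occasional missing loci and +/-1 bp sizing
    jitter.
    """

    seed: int
    n_cultivars: int = 50
    clones_per_cultivar: tuple[int, int] = (2, 6)
    n_loci: int = 16
    alleles_per_locus: tuple[int, int] = (8, 22)
    motif_bp: int = 2
    dirichlet_alpha: float = 0.25
    clone_error_rate: float = 0.10
    max_mistypes_per_clone: Optional[int] = None  # cap planted mistypes
    missing_rate: float = 0.03
    sizing_jitter_rate: float = 0.05
    n_trios: int = 0
    n_sib_families: int = 0
    sib_family_size: int = 3
    lab_offsets: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    n_reference_genotypes: int = 0
    reference_prob: float = 0.90  # cultivar has a pomological reference
    not_determined_rate: float = 0.044  # per tree
    reservation_rate: float = 0.016  # per tree
    mislabel_rate: float = 0.0  # determined trees given a wrong name
    n_collections: int = 6

    def __post_init__(self) -> None:
        for name in (
            "clone_error_rate",
            "missing_rate",
            "sizing_jitter_rate",
            "reference_prob",
            "not_determined_rate",
            "reservation_rate",
            "mislabel_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_loci < 2:
            raise ValueError("need at least 2 loci")
        if (self.n_trios or self.n_sib_families) and self.alleles_per_locus[0] < 2:
            raise ValueError("crosses need at least 2 alleles per locus")

    @property
    def reference_batch(self) -> str:
        return "LAB1"

    @property
    def batches(self) -> tuple[str, ...]:
        return (self.reference_batch, *sorted(self.lab_offsets))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    panel: MarkerPanel
    ladders: dict[str, tuple[int, ...]]
    frequencies: dict[str, dict[int, float]]
    true_genotypes: dict[str, SSRGenotype]  # cultivar -> pristine genotype
    cultivar_of: dict[str, str]  # accession -> cultivar
    parents: dict[str, tuple[str, str]]  # cultivar -> (mother, father)
    corruptions: dict[str, tuple[CorruptionOp, ...]]
    has_reference: dict[str, bool]
    reference_ids: tuple[str, ...]  # assumed names of harmonization refs
    min_within_similarity: float
    max_between_similarity: float

    def clones(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for acc, cv in self.cultivar_of.items():
            out.setdefault(cv, []).append(acc)
        return out

    def to_json(self, path) -> None:
        payload = {
            "cultivar_of": self.cultivar_of,
            "parents": {c: list(p) for c, p in self.parents.items()},
            "corruptions": {a: [list(op) for op in ops] for a, ops in self.corruptions.items()},
            "has_reference": self.has_reference,
            "reference_ids": list(self.reference_ids),
            "min_within_similarity": self.min_within_similarity,
            "max_between_similarity": self.max_between_similarity,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _hwe_draw(rng, ladders, freqs, loci) -> SSRGenotype:
    alleles = {}
    for locus in loci:
        ladder = ladders[locus]
        p = freqs[locus]
        pair = rng.choice(ladder, size=2, p=p)
        alleles[locus] = (int(pair[0]), int(pair[1]))
    return SSRGenotype(alleles)


def _cross(rng, loci, gm: SSRGenotype, gf: SSRGenotype) -> SSRGenotype:
    alleles = {}
    for locus in loci:
        m = gm.alleles[locus]
        f = gf.alleles[locus]
        alleles[locus] = (m[rng.integers(2)], f[rng.integers(2)])
    return SSRGenotype(alleles)


def replay_corruptions(
    truth: GroundTruth,
    accession_id: str,
    config: GeneratorConfig,
    batch: str,
) -> SSRGenotype:
    """Re-apply the logged corruptions (and the batch offset) to the
    pristine cultivar genotype; must reproduce the emitted record."""
    cv = truth.cultivar_of[accession_id]
    working = {l: list(p) for l, p in truth.true_genotypes[cv].alleles.items()}
    for op in truth.corruptions[accession_id]:
        kind = op[0]
        if kind == "mistype":
            _, locus, slot, new = op
            working[locus][slot] = new
        elif kind == "jitter":
            _, locus, slot, delta = op
            working[locus][slot] += delta
        elif kind == "missing":
            working[op[1]] = None  # type: ignore[assignment]
    offsets = config.lab_offsets.get(batch, {})
    alleles = {}
    for locus, pair in working.items():
        if pair is None:
            alleles[locus] = None
        else:
            off = offsets.get(locus, 0)
            alleles[locus] = (pair[0] + off, pair[1] + off)
    return SSRGenotype(alleles)


def generate(config: GeneratorConfig) -> tuple[list[AccessionRecord], GroundTruth]:
    """Generate a collection with clones, crosses and corruptions.

    Deterministic under ``config.seed``.  Returns the accession records
    (pomological statuses included) and the full ground truth.
    """
    rng = np.random.default_rng(config.seed)
    loci = tuple(f"SSR{i + 1:02d}" for i in range(config.n_loci))
    panel = MarkerPanel(loci=loci, motif_bp={l: config.motif_bp for l in loci})

    ladders: dict[str, tuple[int, ...]] = {}
    freqs: dict[str, np.ndarray] = {}
    lo, hi = config.alleles_per_locus
    for locus in loci:
        k = int(rng.integers(lo, hi + 1))
        base = int(rng.integers(80, 240))
        ladders[locus] = tuple(base + config.motif_bp * i for i in range(k))
        freqs[locus] = rng.dirichlet(np.full(k, config.dirichlet_alpha))

    # cultivars: founders, then trio children, then full-sib families
    true_genotypes: dict[str, SSRGenotype] = {}
    parents: dict[str, tuple[str, str]] = {}
    founders = [f"CV{i + 1:03d}" for i in range(config.n_cultivars)]
    for cv in founders:
        true_genotypes[cv] = _hwe_draw(rng, ladders, freqs, loci)
    next_ix = config.n_cultivars
    for t in range(config.n_trios):
        m, f = rng.choice(config.n_cultivars, size=2, replace=False)
        cv = f"CV{next_ix + 1:03d}"
        next_ix += 1
        parents[cv] = (founders[m], founders[f])
        true_genotypes[cv] = _cross(rng, loci, true_genotypes[founders[m]], true_genotypes[founders[f]])
    for s in range(config.n_sib_families):
        m, f = rng.choice(config.n_cultivars, size=2, replace=False)
        for _ in range(config.sib_family_size):
            cv = f"CV{next_ix + 1:03d}"
            next_ix += 1
            parents[cv] = (founders[m], founders[f])
            true_genotypes[cv] = _cross(
                rng, loci, true_genotypes[founders[m]], true_genotypes[founders[f]]
            )

    cultivars = list(true_genotypes)
    has_reference = {cv: bool(rng.random() < config.reference_prob) for cv in cultivars}
    batches = config.batches
    collections = [f"P{i + 1}" for i in range(config.n_collections)]

    records: list[AccessionRecord] = []
    cultivar_of: dict[str, str] = {}
    corruptions: dict[str, tuple[CorruptionOp, ...]] = {}
    acc_ix = 0

    # pristine harmonization references, one per batch
    reference_ids: list[str] = []
    if config.n_reference_genotypes and len(batches) > 1:
        for cv in cultivars[: config.n_reference_genotypes]:
            ref_name = f"REF_{cv}"
            reference_ids.append(ref_name)
            for batch in batches:
                acc_ix += 1
                acc = f"R{acc_ix:04d}"
                cultivar_of[acc] = cv
                corruptions[acc] = ()
                offsets = config.lab_offsets.get(batch, {})
                alleles = {
                    l: (p[0] + offsets.get(l, 0), p[1] + offsets.get(l, 0))
                    for l, p in true_genotypes[cv].alleles.items()
                }
                records.append(
                    AccessionRecord(
                        accession_id=acc,
                        collection=collections[0],
                        assumed_name=ref_name,
                        genotype=SSRGenotype(alleles),
                        pomological_status=PomologicalStatus.not_determined(),
                        lab_batch=batch,
                    )
                )

    clone_lo, clone_hi = config.clones_per_cultivar
    for cv in cultivars:
        n_clones = int(rng.integers(clone_lo, clone_hi + 1))
        for _ in range(n_clones):
            acc_ix += 1
            acc = f"T{acc_ix:04d}"
            cultivar_of[acc] = cv
            batch = batches[int(rng.integers(len(batches)))]
            working = {l: list(p) for l, p in true_genotypes[cv].alleles.items()}
            ops: list[CorruptionOp] = []
            mistype_loci = [l for l in loci if rng.random() < config.clone_error_rate]
            if config.max_mistypes_per_clone is not None:
                mistype_loci = mistype_loci[: config.max_mistypes_per_clone]
            for locus in mistype_loci:
                slot = int(rng.integers(2))
                new = int(rng.choice(ladders[locus], p=freqs[locus]))
                working[locus][slot] = new
                ops.append(("mistype", locus, slot, new))
            for locus in loci:
                for slot in range(2):
                    if rng.random() < config.sizing_jitter_rate:
                        delta = int(rng.choice([-1, 1]))
                        working[locus][slot] += delta
                        ops.append(("jitter", locus, slot, delta))
            missing: list[str] = []
            for locus in loci:
                if rng.random() < config.missing_rate:
                    missing.append(locus)
            if len(missing) == len(loci):
                missing = missing[:-1]  # keep one typed locus
            for locus in missing:
                working[locus] = None  # type: ignore[assignment]
                ops.append(("missing", locus))
            offsets = config.lab_offsets.get(batch, {})
            alleles = {
                l: None
                if pair is None
                else (pair[0] + offsets.get(l, 0), pair[1] + offsets.get(l, 0))
                for l, pair in working.items()
            }

            # pomological label for the tree
            if rng.random() < config.not_determined_rate:
                status = PomologicalStatus.not_determined()
            elif rng.random() < config.reservation_rate:
                status = PomologicalStatus.with_reservation(cv)
            elif has_reference[cv]:
                name = cv
                if config.mislabel_rate and rng.random() < config.mislabel_rate:
                    others = [c for c in cultivars if c != cv]
                    name = others[int(rng.integers(len(others)))]
                status = PomologicalStatus.determined(name)
            else:
                status = PomologicalStatus.no_reference()

            records.append(
                AccessionRecord(
                    accession_id=acc,
                    collection=collections[int(rng.integers(len(collections)))],
                    assumed_name=cv,
                    genotype=SSRGenotype(alleles),
                    pomological_status=status,
                    lab_batch=batch,
                )
            )
            corruptions[acc] = tuple(ops)

    # similarity margins: what harmonization can at best recover
    # (mistype + missing survive harmonization; jitter and offsets do not)
    ideal: dict[str, SSRGenotype] = {}
    for rec in records:
        if rec.accession_id.startswith("R"):
            continue
        cv = cultivar_of[rec.accession_id]
        working = {l: list(p) for l, p in true_genotypes[cv].alleles.items()}
        for op in corruptions[rec.accession_id]:
            if op[0] == "mistype":
                working[op[1]][op[2]] = op[3]
            elif op[0] == "missing":
                working[op[1]] = None  # type: ignore[assignment]
        ideal[rec.accession_id] = SSRGenotype(
            {l: None if p is None else (p[0], p[1]) for l, p in working.items()}
        )
    min_within = 1.0
    for acc, g in ideal.items():
        cv = cultivar_of[acc]
        s = similarity(g, true_genotypes[cv], min_shared=1)
        min_within = min(min_within, s.similarity)
    max_between = 0.0
    cvs = list(true_genotypes)
    for i in range(len(cvs)):
        for j in range(i + 1, len(cvs)):
            s = similarity(
                true_genotypes[cvs[i]], true_genotypes[cvs[j]], min_shared=1
            )
            max_between = max(max_between, s.similarity)

    truth = GroundTruth(
        panel=panel,
        ladders=ladders,
        frequencies={
            l: {int(a): float(p) for a, p in zip(ladders[l], freqs[l])} for l in loci
        },
        true_genotypes=true_genotypes,
        cultivar_of=cultivar_of,
        parents=parents,
        corruptions=corruptions,
        has_reference=has_reference,
        reference_ids=tuple(reference_ids),
        min_within_similarity=min_within,
        max_between_similarity=max_between,
    )
    return records, truth


def pedigree_hypotheses(truth: GroundTruth) -> list[PedigreeHypothesis]:
    """True pedigree hypotheses for every designed cross."""
    return [
        PedigreeHypothesis(child=cv, assumed_mother=m, assumed_father=f)
        for cv, (m, f) in truth.parents.items()
    ]


def target_profile(config: GeneratorConfig) -> dict:
    """Analytic expectations of the panel profile under the Dirichlet model.

    For a symmetric Dirichlet(alpha) over k alleles,
    E[Sum p_i^2] = (alpha + 1) / (k alpha + 1), so the expected
    heterozygosity of a random panel locus is the average of
    1 - (alpha + 1)/(k alpha + 1) over the allele-count range.
    """
    lo, hi = config.alleles_per_locus
    a = config.dirichlet_alpha
    he = [1.0 - (a + 1.0) / (k * a + 1.0) for k in range(lo, hi + 1)]
    return {
        "expected_mean_He": float(np.mean(he)),
        "expected_mean_Na_ladder": (lo + hi) / 2.0,
        "expected_He_by_k": {k: v for k, v in zip(range(lo, hi + 1), he)},
    }
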