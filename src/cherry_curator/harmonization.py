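"""Cross-batch harmonization of SSR fragment lengths.

Fragment sizes from different capillary platforms differ by small, locus-
specific constant offsets; within a platform, sizing is only reliable to
about +/-1 bp.  This module makes sizes comparable in two explicit steps:

1. ``estimate_offsets`` — per (lab batch, locus) integer offsets estimated
   from reference genotypes run in more than one batch;
2. ``build_bins`` / ``apply`` — dataset-dependent allele binning that merges
   sizes closer than 2 bp, so a +/-1 bp sizing difference never separates
   two alleles.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .core import AccessionRecord, MarkerPanel, SSRGenotype

log = logging.getLogger(__name__)


def _round_half_toward_zero(x: float) -> int:
    import math

    return int(math.copysign(math.floor(abs(x) + 0.5 - 1e-12), x)) if x else 0


@dataclass(frozen=True)
class OffsetTable:
    """Additive integer size corrections per (lab batch, locus).

    The designated reference batch has offset 0 everywhere; applying the
    table shifts every other batch onto the reference batch's size scale.
    """

    reference_batch: str
    offsets: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def get(self, batch: str, locus: str) -> int:
        if batch == self.reference_batch:
            return 0
        return self.offsets.get((batch, locus), 0)

    def to_json(self, path) -> None:
        payload = {
            "reference_batch": self.reference_batch,
            "offsets": [
                {"batch": b, "locus": l, "offset": o}
                for (b, l), o in sorted(self.offsets.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "OffsetTable":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            reference_batch=payload["reference_batch"],
            offsets={
                (e["batch"], e["locus"]): int(e["offset"]) for e in payload["offsets"]
            },
        )


@dataclass(frozen=True)
class BinningMap:
    """Per-locus allele bins: raw size -> bin center.

    Bin centers within a locus are at least 2 bp apart, so +/-1 bp
    neighbours always share a bin.
    """

    centers: Mapping[str, tuple[int, ...]]
    mapping: Mapping[str, Mapping[int, int]]
    chained_merges: tuple[tuple[str, tuple[int, ...]], ...] = ()

    def bin(self, locus: str, size: int) -> int:
        m = self.mapping.get(locus, {})
        if size in m:
            return m[size]
        # tolerate an unseen size if it is within 1 bp of an existing center
        best = None
        for center in self.centers.get(locus, ()):
            d = abs(center - size)
            if d <= 1 and (best is None or d < abs(best - size)):
                best = center
        if best is None:
            raise ValueError(f"allele {size} at {locus} not covered by any bin")
        return best

    def to_json(self, path) -> None:
        payload = {
            "centers": {l: list(c) for l, c in self.centers.items()},
            "mapping": {
                l: {str(k): v for k, v in m.items()} for l, m in self.mapping.items()
            },
            "chained_merges": [
                {"locus": l, "run": list(run)} for l, run in self.chained_merges
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def estimate_offsets(
    records: Sequence[AccessionRecord],
    reference_ids: Sequence[str],
    reference_batch: str,
    panel: Optional[MarkerPanel] = None,
) -> OffsetTable:
    """Estimate per-(batch, locus) offsets from shared reference genotypes.

    For each non-reference batch and locus, the offset is the rounded median
    (half toward zero) of ``reference-batch size - batch size`` over the
    sorted allele pairs of reference genotypes present in both batches.
    Loci with no shared reference data get offset 0 with a warning.
    """
    by_name_batch: dict[tuple[str, str], SSRGenotype] = {}
    batches: set[str] = set()
    for rec in records:
        batches.add(rec.lab_batch)
        if rec.assumed_name in reference_ids or rec.accession_id in reference_ids:
            key = (
                rec.assumed_name if rec.assumed_name in reference_ids else rec.accession_id,
                rec.lab_batch,
            )
            by_name_batch[key] = rec.genotype

    ref_names = [
        n for n in reference_ids if (n, reference_batch) in by_name_batch
    ]
    if not ref_names:
        raise ValueError(
            f"no reference genotype present in reference batch {reference_batch!r}"
        )

    loci = list(panel) if panel is not None else list(records[0].genotype.alleles)
    offsets: dict[tuple[str, str], int] = {}
    for batch in sorted(batches - {reference_batch}):
        for locus in loci:
            diffs: list[int] = []
            for name in ref_names:
                other = by_name_batch.get((name, batch))
                ref = by_name_batch[(name, reference_batch)]
                if other is None:
                    continue
                pr, po = ref.alleles.get(locus), other.alleles.get(locus)
                if pr is None or po is None:
                    continue
                diffs += [pr[0] - po[0], pr[1] - po[1]]
            if not diffs:
                warnings.warn(
                    f"no shared reference data for batch {batch!r}, locus {locus!r}; "
                    "offset set to 0",
                    stacklevel=2,
                )
                offsets[(batch, locus)] = 0
                continue
            diffs.sort()
            n = len(diffs)
            med = (
                diffs[n // 2]
                if n % 2
                else (diffs[n // 2 - 1] + diffs[n // 2]) / 2.0
            )
            offsets[(batch, locus)] = _round_half_toward_zero(float(med))
    return OffsetTable(reference_batch=reference_batch, offsets=offsets)


def apply_offsets(
    records: Sequence[AccessionRecord], offsets: OffsetTable
) -> list[AccessionRecord]:
    """Shift every allele by its batch/locus offset; batches collapse onto
    the reference batch label so the correction is idempotent."""
    out = []
    for rec in records:
        alleles = {}
        for locus, pair in rec.genotype.alleles.items():
            if pair is None:
                alleles[locus] = None
            else:
                off = offsets.get(rec.lab_batch, locus)
                alleles[locus] = (pair[0] + off, pair[1] + off)
        out.append(
            replace(
                rec,
                genotype=SSRGenotype(alleles),
                lab_batch=offsets.reference_batch,
            )
        )
    return out


def build_bins(
    records: Sequence[AccessionRecord], panel: Optional[MarkerPanel] = None
) -> BinningMap:
    """Build per-locus allele bins by greedy run-merging of observed sizes.

    Distinct observed sizes at a locus are sorted; maximal runs whose
    consecutive gaps are <=1 bp are merged into one bin whose center is the
    modal observed size of the run (ties broken toward the smaller size).
    Runs spanning 3+ sizes (chained merges) are recorded for curator review,
    since the pairwise +/-1 bp rule is ambiguous for them.
    """
    loci = list(panel) if panel is not None else list(records[0].genotype.alleles)
    counts: dict[str, dict[int, int]] = {l: {} for l in loci}
    for rec in records:
        for locus in loci:
            pair = rec.genotype.alleles.get(locus)
            if pair is None:
                continue
            for a in pair:
                counts[locus][a] = counts[locus].get(a, 0) + 1

    centers: dict[str, tuple[int, ...]] = {}
    mapping: dict[str, dict[int, int]] = {}
    chained: list[tuple[str, tuple[int, ...]]] = []
    for locus in loci:
        sizes = sorted(counts[locus])
        runs: list[list[int]] = []
        for s in sizes:
            if runs and s - runs[-1][-1] <= 1:
                runs[-1].append(s)
            else:
                runs.append([s])
        locus_centers: list[int] = []
        locus_map: dict[int, int] = {}
        for run in runs:
            center = max(run, key=lambda s: (counts[locus][s], -s))
            locus_centers.append(center)
            for s in run:
                locus_map[s] = center
            if len(run) >= 3:
                chained.append((locus, tuple(run)))
                log.info("chained bin merge at %s: %s -> %d", locus, run, center)
        centers[locus] = tuple(locus_centers)
        mapping[locus] = locus_map
    return BinningMap(centers=centers, mapping=mapping, chained_merges=tuple(chained))


def apply(
    records: Sequence[AccessionRecord],
    offsets: Optional[OffsetTable] = None,
    bins: Optional[BinningMap] = None,
) -> list[AccessionRecord]:
    """Offset-correct and bin every allele; missing data is preserved.

    Idempotent on its own output: corrected records carry the reference
    batch label (offset 0) and bin centers map to themselves.
    """
    out = list(records)
    if offsets is not None:
        out = apply_offsets(out, offsets)
    if bins is not None:
        binned = []
        for rec in out:
            alleles = {}
            for locus, pair in rec.genotype.alleles.items():
                if pair is None:
                    alleles[locus] = None
                else:
                    alleles[locus] = (bins.bin(locus, pair[0]), bins.bin(locus, pair[1]))
            binned.append(replace(rec, genotype=SSRGenotype(alleles)))
        out = binned
    return out


def harmonize(
    records: Sequence[AccessionRecord],
    reference_ids: Sequence[str] = (),
    reference_batch: str = "",
    panel: Optional[MarkerPanel] = None,
) -> tuple[list[AccessionRecord], Optional[OffsetTable], BinningMap]:
    """Full harmonization: estimate offsets (if references given), apply
    them, build bins on the corrected data, and bin all alleles."""
    offsets = None
    out = list(records)
    if reference_ids and reference_batch:
        offsets = estimate_offsets(records, reference_ids, reference_batch, panel)
        out = apply_offsets(out, offsets)
    bins = build_bins(out, panel)
    out = apply(out, None, bins)
    return out, offsets, bins
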