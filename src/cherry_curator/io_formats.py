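"""Readers and writers for the tabular and tree artifacts of the pipeline.

Genotype tables use the GenAlEx-style codominant layout: one row per tree,
two integer columns per locus named ``<locus>.1`` / ``<locus>.2``, missing
data encoded as 0 (or empty on input).  Everything round-trips bit-stable;
files are UTF-8 because cultivar names carry umlauts.
"""

from __future__ import annotations

import csv
import io
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy

from .core import (
    AccessionRecord,
    MarkerPanel,
    PedigreeHypothesis,
    PomologicalStatus,
    PomologyKind,
    SSRGenotype,
)

PathLike = Union[str, Path]

_PASSPORT_COLUMNS = ("accession_id", "collection", "assumed_name")
_OPTIONAL_COLUMNS = ("pomological_status", "pomological_name", "lab_batch")


class GenotypeTableError(ValueError):
    """Raised for structurally invalid genotype tables."""


def _parse_allele(raw: str, row: int, column: str) -> Optional[int]:
    raw = raw.strip()
    if raw == "" or raw == "0":
        return None
    try:
        return int(raw)
    except ValueError:
        raise GenotypeTableError(
            f"non-integer allele {raw!r} at row {row}, column {column!r}"
        ) from None


def _status_from_fields(kind_raw: str, name: str) -> PomologicalStatus:
    kind_raw = kind_raw.strip().lower()
    if not kind_raw:
        return PomologicalStatus.not_determined()
    kind = PomologyKind(kind_raw)
    return PomologicalStatus(kind, name.strip())


def infer_panel(path: PathLike) -> MarkerPanel:
    """Build a panel from a table's ``<locus>.1``/``<locus>.2`` columns."""
    text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.reader(io.StringIO(text)))
    header = None
    for row in rows[:3]:
        if "accession_id" in [c.strip() for c in row]:
            header = [c.strip() for c in row]
            break
    if header is None:
        raise GenotypeTableError(f"{path}: no 'accession_id' header row found")
    cols = set(header)
    loci = [
        c[:-2]
        for c in header
        if c.endswith(".1") and f"{c[:-2]}.2" in cols
    ]
    if not loci:
        raise GenotypeTableError(f"{path}: no locus column pairs found")
    return MarkerPanel(loci=tuple(loci))


def read_genotype_table(
    path: PathLike,
    panel: MarkerPanel,
    locus_columns: Optional[dict[str, tuple[str, str]]] = None,
) -> list[AccessionRecord]:
    """Read a GenAlEx-style CSV of diploid SSR genotypes.

    Parameters
    ----------
    path
        CSV file with passport columns (``accession_id``, ``collection``,
        ``assumed_name``, optionally ``pomological_status``,
        ``pomological_name`` and ``lab_batch``) followed by two columns per
        locus.  A two-line numeric GenAlEx header before the column-name row
        is tolerated and skipped.
    panel
        The marker panel; every panel locus must have two columns.
    locus_columns
        Optional explicit mapping ``locus -> (col1, col2)`` for dialects that
        do not follow the ``<locus>.1``/``<locus>.2`` naming.

    Returns
    -------
    Records in input order.  A single given allele at a locus is expanded to
    a homozygous pair; ``0``/empty pairs become missing.  Alleles outside a
    declared panel size range produce a warning but the record is kept.
    """
    text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.reader(io.StringIO(text)))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise GenotypeTableError(f"{path}: empty genotype table")

    # Skip a GenAlEx two-line numeric preamble if present.
    header_idx = 0
    while header_idx < len(rows) and "accession_id" not in rows[header_idx]:
        header_idx += 1
        if header_idx > 2:
            raise GenotypeTableError(f"{path}: no 'accession_id' header row found")
    header = [h.strip() for h in rows[header_idx]]
    col_idx = {name: i for i, name in enumerate(header)}
    for col in _PASSPORT_COLUMNS:
        if col not in col_idx:
            raise GenotypeTableError(f"{path}: missing passport column {col!r}")

    if locus_columns is None:
        locus_columns = {l: (f"{l}.1", f"{l}.2") for l in panel}
    for locus, (c1, c2) in locus_columns.items():
        if c1 not in col_idx or c2 not in col_idx:
            raise GenotypeTableError(f"{path}: missing allele columns for locus {locus!r}")

    records: list[AccessionRecord] = []
    seen_ids: set[str] = set()
    for rix, row in enumerate(rows[header_idx + 1 :], start=header_idx + 2):
        get = lambda col: row[col_idx[col]].strip() if col_idx[col] < len(row) else ""
        acc_id = get("accession_id")
        if not acc_id:
            raise GenotypeTableError(f"{path}: empty accession_id at row {rix}")
        if acc_id in seen_ids:
            raise GenotypeTableError(f"{path}: duplicate accession_id {acc_id!r}")
        seen_ids.add(acc_id)

        alleles: dict[str, Optional[tuple[int, int]]] = {}
        for locus in panel:
            c1, c2 = locus_columns[locus]
            a1 = _parse_allele(get(c1), rix, c1)
            a2 = _parse_allele(get(c2), rix, c2)
            if a1 is None and a2 is None:
                alleles[locus] = None
                continue
            if a1 is None:
                a1 = a2
            if a2 is None:
                a2 = a1
            rng = panel.size_range.get(locus)
            if rng is not None:
                for a in (a1, a2):
                    if not rng[0] <= a <= rng[1]:
                        warnings.warn(
                            f"{acc_id}: allele {a} at {locus} outside declared "
                            f"range {rng}; record kept",
                            stacklevel=2,
                        )
            alleles[locus] = (a1, a2)  # type: ignore[assignment]

        status = _status_from_fields(
            get("pomological_status") if "pomological_status" in col_idx else "",
            get("pomological_name") if "pomological_name" in col_idx else "",
        )
        records.append(
            AccessionRecord(
                accession_id=acc_id,
                collection=get("collection"),
                assumed_name=get("assumed_name"),
                genotype=SSRGenotype(alleles),
                pomological_status=status,
                lab_batch=get("lab_batch") if "lab_batch" in col_idx else "",
            )
        )
    return records


def write_genalex(records: Sequence[AccessionRecord], path: PathLike) -> None:
    """Write records as a GenAlEx-compatible codominant CSV.

    The two-line header declares (n_loci is implicit in the layout):
    line 1 — number of samples, number of loci, number of populations,
    then per-population sample counts; line 2 — dataset title and
    population names.  Missing alleles are written as 0.  The output
    round-trips through :func:`read_genotype_table`.
    """
    if not records:
        raise ValueError("cannot write an empty record list")
    loci = list(records[0].genotype.alleles)
    pops: dict[str, int] = {}
    for rec in records:
        pops[rec.collection] = pops.get(rec.collection, 0) + 1

    out = Path(path)
    with out.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([len(records), len(loci), len(pops), *pops.values()])
        w.writerow(["cherry_curator export", "", "", *pops.keys()])
        header = list(_PASSPORT_COLUMNS) + list(_OPTIONAL_COLUMNS)
        for locus in loci:
            header += [f"{locus}.1", f"{locus}.2"]
        w.writerow(header)
        for rec in records:
            row = [
                rec.accession_id,
                rec.collection,
                rec.assumed_name,
                rec.pomological_status.kind.value,
                rec.pomological_status.name,
                rec.lab_batch,
            ]
            for locus in loci:
                pair = rec.genotype.alleles.get(locus)
                row += [0, 0] if pair is None else [pair[0], pair[1]]
            w.writerow(row)


def read_pedigree_csv(path: PathLike) -> list[PedigreeHypothesis]:
    """Read pedigree hypotheses from a ``child,mother,father`` CSV.

    Empty or ``UNKNOWN`` parent cells mean the parent is not genotyped
    (e.g. open pollination).
    """
    text = Path(path).read_text(encoding="utf-8")
    rows = [r for r in csv.reader(io.StringIO(text)) if any(c.strip() for c in r)]
    if not rows:
        return []
    start = 1 if rows[0][0].strip().lower() in ("child", "cultivar", "cultivar_name") else 0
    out = []
    for row in rows[start:]:
        child = row[0].strip()
        mother = row[1].strip() if len(row) > 1 else ""
        father = row[2].strip() if len(row) > 2 else ""
        out.append(PedigreeHypothesis(child, mother, father))
    return out


def write_pedigree_csv(hypotheses: Sequence[PedigreeHypothesis], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["child", "mother", "father"])
        for h in hypotheses:
            w.writerow([h.child, h.assumed_mother, h.assumed_father])


def write_newick(tree, path: PathLike) -> None:
    """Write a tree (phylogeny module tree or dendropy Tree) as newick.

    Internal support values become internal node labels; leaf labels
    containing spaces or quotes are quoted.  Unlabeled leaves are an error.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = tree.to_dendropy()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree contains an unlabeled leaf")
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=False,
    )


def read_newick(path: PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=False)
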