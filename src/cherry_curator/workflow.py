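"""End-to-end orchestration: harmonize -> dedup -> categorize ->
diversity/PI -> tree -> parentage, from one config, with a reproducible
run manifest.

Outputs are plain CSV/newick/JSON files in the run directory, laid out
like the published summary tables so curator-facing diffs stay readable.
Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import AccessionRecord, MarkerPanel, PedigreeHypothesis
from . import diversity_stats, harmonization, identity_dedup, io_formats, phylogeny_nj
from .parentage import ParentageConfig, verify_pedigrees
from .synthetic_collection import GeneratorConfig, generate, pedigree_hypotheses

log = logging.getLogger(__name__)

ALL_STAGES = ("harmonize", "dedup", "categories", "diversity", "tree", "parentage")


@dataclass(frozen=True)
class RunConfig:
    outdir: str
    seed: int = 1
    genotype_csv: Optional[str] = None
    pedigree_csv: Optional[str] = None
    synthetic: Optional[GeneratorConfig] = None
    reference_ids: tuple[str, ...] = ()
    reference_batch: str = ""
    threshold: float = identity_dedup.DEFAULT_THRESHOLD
    min_shared: int = identity_dedup.DEFAULT_MIN_SHARED
    bootstrap_replicates: int = 1000
    tree_max_taxa: int = 120
    parentage: ParentageConfig = field(default_factory=ParentageConfig)
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.genotype_csv is None and self.synthetic is None:
            raise ValueError("either genotype_csv or a synthetic config is required")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (nested synthetic/parentage sections)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if "synthetic" in raw and raw["synthetic"] is not None:
        raw["synthetic"] = GeneratorConfig(**raw["synthetic"])
    if "parentage" in raw and raw["parentage"] is not None:
        raw["parentage"] = ParentageConfig(**raw["parentage"])
    for key in ("reference_ids", "stages"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _config_payload(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if hasattr(obj, "value"):
            return obj.value
        return obj

    return encode(config)


def run(config: RunConfig, panel: Optional[MarkerPanel] = None) -> dict:
    """Execute the configured stages; returns a report bundle dict.

    Any stage failure aborts with the stage name; outputs of completed
    stages are retained in the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outdir": str(outdir)}
    stage = "setup"
    try:
        # ---- inputs
        truth = None
        if config.genotype_csv is not None:
            panel = panel or MarkerPanel.cherry_default()
            records = io_formats.read_genotype_table(config.genotype_csv, panel)
        else:
            records, truth = generate(config.synthetic)
            panel = truth.panel
        report["n_records"] = len(records)

        hypotheses: list[PedigreeHypothesis] = []
        if config.pedigree_csv is not None:
            hypotheses = io_formats.read_pedigree_csv(config.pedigree_csv)
        elif truth is not None:
            hypotheses = pedigree_hypotheses(truth)

        # ---- harmonization
        stage = "harmonize"
        if "harmonize" in config.stages:
            reference_ids = config.reference_ids or (
                truth.reference_ids if truth is not None else ()
            )
            reference_batch = config.reference_batch
            if not reference_batch and config.synthetic is not None:
                reference_batch = config.synthetic.reference_batch
            records, offsets, bins = harmonization.harmonize(
                records,
                reference_ids=reference_ids,
                reference_batch=reference_batch if reference_ids else "",
                panel=panel,
            )
            if offsets is not None:
                offsets.to_json(outdir / "offsets.json")
            bins.to_json(outdir / "bins.json")

        # ---- duplicate detection + categories
        stage = "dedup"
        groups = identity_dedup.build_groups(
            records, threshold=config.threshold, min_shared=config.min_shared
        )
        rep_of = {g.group_id: g for g in groups}
        member_rows = []
        for g in groups:
            for acc in g.member_ids:
                member_rows.append(
                    {
                        "accession_id": acc,
                        "group_id": g.group_id,
                        "representative": int(
                            rep_of[g.group_id].representative.key()
                            == next(
                                r.genotype.key()
                                for r in records
                                if r.accession_id == acc
                            )
                        ),
                    }
                )
        pd.DataFrame(member_rows).to_csv(outdir / "groups.csv", index=False)
        report["n_groups"] = len(groups)

        stage = "categories"
        if "categories" in config.stages:
            assessments = identity_dedup.assign_categories(groups, records)
            pd.DataFrame(
                [
                    {
                        "accession_id": a.accession_id,
                        "category": "" if a.category is None else int(a.category),
                        "resolved_name": a.resolved_name,
                        "relabel": int(a.relabel),
                        "unresolved": int(a.unresolved),
                    }
                    for a in assessments
                ]
            ).to_csv(outdir / "categories.csv", index=False)
            summary = identity_dedup.category_summary(assessments)
            (outdir / "category_summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
            )
            report["category_summary"] = summary

        # unique genotypes: one representative per molecular group
        uniques = [g.representative for g in groups]
        unique_labels = [g.group_id for g in groups]

        # ---- diversity statistics on the unique genotypes
        stage = "diversity"
        if "diversity" in config.stages:
            table = diversity_stats.locus_diversity(uniques, panel)
            table.round(4).to_csv(outdir / "diversity.csv", index=False)
            freqs = diversity_stats.allele_frequencies(uniques, panel)
            pres = diversity_stats.pi(freqs)
            pres.to_frame().round(6).to_csv(outdir / "pi.csv", index=False)
            mms = diversity_stats.minimal_marker_set(uniques, freqs, mode="empirical")
            mms_sib = diversity_stats.minimal_marker_set(uniques, freqs, mode="sib")
            report["diversity"] = {
                "mean_He": float(table.iloc[-1]["He"]),
                "mean_Na": float(table.iloc[-1]["Na"]),
                "mean_Ne": float(table.iloc[-1]["Ne"]),
                "mean_Ho": float(table.iloc[-1]["Ho"]),
                "mean_PI": pres.mean_pi,
                "mean_PIsib": pres.mean_pisib,
                "minimal_marker_set_empirical": mms.size,
                "minimal_marker_set_sib": mms_sib.size,
            }

        # ---- phylogenetic tree on the unique genotypes
        stage = "tree"
        if "tree" in config.stages and len(uniques) >= 4:
            take = min(len(uniques), config.tree_max_taxa)
            tree = phylogeny_nj.bootstrap_support(
                uniques[:take],
                labels=unique_labels[:take],
                B=config.bootstrap_replicates,
                seed=config.seed,
            )
            io_formats.write_newick(tree, outdir / "tree.nwk")
            report["tree_taxa"] = take

        # ---- parentage verification
        stage = "parentage"
        if "parentage" in config.stages and hypotheses:
            name_to_genotype = {}
            for rec in records:
                cv = rec.assumed_name or rec.accession_id
                name_to_genotype.setdefault(cv, rec.genotype)
            freqs = diversity_stats.allele_frequencies(uniques, panel)
            results = verify_pedigrees(
                hypotheses,
                name_to_genotype,
                freqs,
                config.parentage,
                seed=config.seed,
            )
            pd.DataFrame(
                [
                    {
                        "cultivar": r.hypothesis.child,
                        "assumed_mother": r.hypothesis.assumed_mother,
                        "assumed_father": r.hypothesis.assumed_father,
                        "mode": "" if r.mode is None else r.mode.value,
                        "LOD": round(r.lod, 4) if r.lod == r.lod else "",
                        "confidence": r.verdict.value,
                        "loci_compared": r.loci_compared,
                        "mismatching_loci": r.mismatching_loci,
                    }
                    for r in results
                ]
            ).to_csv(outdir / "parentage.csv", index=False)
            report["parentage"] = {
                "n_hypotheses": len(results),
                "verdicts": {
                    v: sum(1 for r in results if r.verdict.value == v)
                    for v in ("*", "+", "-", "unevaluated")
                },
            }

        # ---- manifest
        stage = "manifest"
        manifest = {
            "package": "cherry-curator",
            "version": __version__,
            "config": _config_payload(config),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
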