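"""Pipeline orchestration: one config in, a deterministic report bundle out.

Order of stages follows the mining campaign itself: screen the accession
panel (funnel), align the allele sequences, build the consensus, call
consensus-relative variants, segment and match polymorphic blocks, and
compute the domain-partitioned diversity table.  Every numeric cell in the
bundle is produced by the corresponding library operation; this module only
wires them together and writes files.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .blocks import (
    chimera_report,
    match_block,
    ploidy_block_profile,
    segment_blocks,
    write_blocks_tsv,
    write_chimera_json,
    write_matches_tsv,
)
from .diversity import summarize_table3, write_diversity_tsv
from .funnel import (
    read_accession_tsv,
    stage_filters,
    summarize_funnel,
    write_funnel_tsv,
)
from .gene_model import default_domain_map, default_gene_model, load_gene_config
from .io_alignment import (
    AlleleAlignment,
    add_reference_row,
    align_near_identical,
    build_consensus,
    read_fasta,
    read_prealigned_fasta,
    write_alignment_fasta,
)
from .variants import (
    VariantTable,
    annotate_table,
    call_variants,
    flag_pseudogene,
    write_variants_tsv,
    write_variants_vcf,
)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and options steering one pipeline run."""

    sequences_fasta: str | None = None
    metadata_tsv: str | None = None
    prealigned_fasta: str | None = None
    accessions_tsv: str | None = None
    gene_config: str | None = None
    isolates: Sequence[str] = ()
    output_dir: str = "results/pipeline"
    seed: int = 0
    block_min_sites: int = 3
    block_max_gap: int = 250
    rounding: str = "floor"
    group_by_ploidy: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**cfg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest of outputs and key numbers.

    Any stage failure aborts with a stage-named message and removes partial
    outputs.  Re-running with identical config and inputs yields byte-identical
    files.
    """
    out = Path(config.output_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": {
            "block_min_sites": config.block_min_sites,
            "block_max_gap": config.block_max_gap,
            "rounding": config.rounding,
        },
        "outputs": [],
    }

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    try:
        # --- funnel ------------------------------------------------------
        if config.accessions_tsv:
            isolates = list(config.isolates)
            if not isolates:
                raise PipelineError("funnel: isolate panel not configured")
            records = read_accession_tsv(config.accessions_tsv, isolates)
            records = stage_filters(records, isolates)
            report = summarize_funnel(records)
            write_funnel_tsv(report, emit("funnel.tsv"))
            manifest["funnel_totals"] = list(report.totals)

        # --- sequences and alignment --------------------------------------
        if not config.sequences_fasta and not config.prealigned_fasta:
            _write_manifest(out, manifest)
            return manifest
        if config.prealigned_fasta:
            alignment = read_prealigned_fasta(config.prealigned_fasta)
            sequences = read_fasta(
                config.prealigned_fasta, config.metadata_tsv, allow_gaps=True
            )
        else:
            sequences = read_fasta(config.sequences_fasta, config.metadata_tsv)
            alignment = align_near_identical(sequences)
        roles = {s.id: s.role for s in sequences}
        ploidy = {s.id: s.ploidy_group for s in sequences}

        profile = build_consensus(
            alignment, roles=roles, include_roles=("allele", "reference")
        )
        alignment = add_reference_row(alignment, profile.consensus, "consensus")
        write_alignment_fasta(alignment, emit("alignment.fasta"))
        consensus = profile.consensus_ungapped

        # --- gene model -----------------------------------------------------
        if config.gene_config:
            path = Path(config.gene_config)
            if not path.exists():
                raise PipelineError(f"gene_model: config not found: {path}")
            model, domains = load_gene_config(path)
        else:
            model, domains = default_gene_model(), default_domain_map()
        if model.span[1] > len(consensus):
            raise PipelineError(
                f"gene_model: model span {model.span} exceeds consensus "
                f"length {len(consensus)}"
            )

        # --- variants -------------------------------------------------------
        allele_ids = [s.id for s in sequences if roles[s.id] == "allele"]
        table = VariantTable([])
        pseudo: dict[str, str] = {}
        for aid in allele_ids:
            t = annotate_table(
                call_variants(alignment, aid, "consensus"), model, consensus, domains
            )
            is_pseudo, reason = flag_pseudogene(t, model)
            if is_pseudo:
                pseudo[aid] = reason
            table = table.extend(t)
        write_variants_tsv(table, emit("variants.tsv"))
        write_variants_vcf(table, consensus, emit("variants.vcf"))
        manifest["pseudogenes"] = pseudo

        # --- blocks ---------------------------------------------------------
        all_blocks, all_matches, reports = [], [], []
        blocks_by_allele = {}
        donor_ids = [i for i in alignment.ids if i not in ("consensus",)]
        for aid in allele_ids:
            blocks, isolated = segment_blocks(
                table, aid, config.block_min_sites, config.block_max_gap
            )
            blocks_by_allele[aid] = blocks
            matches_per_block = [
                match_block(b, alignment, [d for d in donor_ids if d != aid], "consensus")
                for b in blocks
            ]
            all_blocks.extend(blocks)
            for ms in matches_per_block:
                all_matches.extend(ms)
            reports.append(
                chimera_report(aid, blocks, matches_per_block, roles, isolated)
            )
        write_blocks_tsv(all_blocks, emit("blocks.tsv"))
        write_matches_tsv(all_matches, emit("block_matches.tsv"))
        write_chimera_json(reports, emit("chimera_reports.json"))
        profile_rows = ploidy_block_profile(blocks_by_allele, ploidy)
        (out / "block_profile.json").write_text(
            json.dumps(profile_rows, indent=2) + "\n"
        )
        manifest["outputs"].append("block_profile.json")

        # --- diversity ------------------------------------------------------
        non_pseudo = [a for a in allele_ids if a not in pseudo]
        if config.group_by_ploidy:
            groups = {}
            for g in ("hexaploid", "tetraploid"):
                members = [a for a in non_pseudo if ploidy.get(a) == g]
                if len(members) >= 2:
                    groups[g] = members
            if not groups:
                groups = {"all": non_pseudo}
        else:
            groups = {"all": non_pseudo}
        if any(len(g) >= 2 for g in groups.values()):
            rows = summarize_table3(
                alignment, model, domains, groups, "consensus", mode=config.rounding
            )
            write_diversity_tsv(rows, emit("diversity.tsv"))

        _write_manifest(out, manifest)
        return manifest
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline failed: {exc}") from exc


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    manifest["outputs"].append("manifest.json")


def render_reports(bundle_dir: str | Path, fmt: str = "tsv") -> list[Path]:
    """Render the bundle's tabular reports in the requested format.

    TSV files are the native output; ``fmt='json'`` re-renders every TSV as a
    records-oriented JSON file carrying the same numbers.  Other formats are
    unsupported.
    """
    import pandas as pd

    bundle_dir = Path(bundle_dir)
    tsvs = sorted(bundle_dir.glob("*.tsv"))
    if fmt == "tsv":
        return tsvs
    if fmt != "json":
        raise ValueError(f"unsupported format: {fmt!r}")
    out_paths = []
    for tsv in tsvs:
        df = pd.read_csv(tsv, sep="\t", dtype=str).fillna("")
        target = tsv.with_suffix(".json")
        target.write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
        out_paths.append(target)
    return out_paths
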