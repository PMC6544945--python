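"""End-to-end orchestration: search -> extract -> validate -> consensus ->
classify -> quantify -> gene association -> phylogeny.

Stages communicate through files in standard formats inside the output
directory, so any stage can be re-run independently; a manifest records the
config hash, seed and package version for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import ClassificationParams, classification_table, classify_consensus_set
from .consensus import consensus_from_copies
from .core_io import read_fasta, read_gff3, write_fasta, write_report
from .element_structure import validate_copy
from .gene_association import classify_insertion, summarize_contexts, write_context_table
from .homology_search import coverage_of, extract_copy, index_genome, search, write_hits_tsv
from .phylo import bootstrap, distance_matrix, nj_tree
from .quantify import average_divergence, count_copies, genome_fraction, make_report
from .consensus import align_copies


class ConfigError(ValueError):
    """Missing or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    genome_fasta: str
    seed_fasta: str
    out_dir: str
    gff3: str | None = None
    species: str | None = None
    seed: int = 0
    min_identity: float = 0.8
    min_len: int = 100
    flank: int = 200
    word_size: int = 11
    run_phylo: bool = False
    bootstrap_replicates: int = 100
    max_phylo_copies: int = 30

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class PipelineResult:
    out_dir: Path
    consensus_set: list = field(default_factory=list)
    reports: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(vars(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    result = PipelineResult(out_dir=out, manifest=manifest)
    try:
        genomes = read_fasta(config.genome_fasta)
        seeds = read_fasta(config.seed_fasta)
    except (OSError, ValueError) as exc:
        raise ConfigError(f"cannot read inputs: {exc}") from exc
    if not genomes or not seeds:
        raise ConfigError("empty genome or seed FASTA")
    genome_bp = sum(g.length for g in genomes)
    gene_models = read_gff3(config.gff3) if config.gff3 else None

    index = index_genome(genomes, config.word_size)
    stage = "search"
    try:
        consensus_set = []
        per_element = {}
        for seedrec in seeds:
            hits = search(
                seedrec.sequence, index,
                min_identity=config.min_identity, min_len=config.min_len,
            )
            write_hits_tsv(hits, out / f"hits_{seedrec.contig_id}.tsv")

            stage = "extract"
            copies = [
                extract_copy(h, genomes, config.flank, query_len=seedrec.length)
                for h in hits
            ]
            stage = "validate"
            for c in copies:
                validate_copy(c)

            stage = "consensus"
            if len(copies) >= 2:
                cons = consensus_from_copies(copies, name=seedrec.contig_id)
            else:
                continue
            consensus_set.append(cons)
            per_element[cons.name] = (hits, copies, cons)
        if not consensus_set:
            raise ValueError("no element produced enough copies for a consensus")
        write_fasta(consensus_set, out / "consensus.fasta")

        stage = "classify"
        classify_consensus_set(consensus_set, species=config.species)
        rows = classification_table(consensus_set)
        with open(out / "classification.tsv", "w") as fh:
            cols = list(rows[0].keys())
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")

        stage = "quantify"
        reports = []
        for cons in consensus_set:
            hits = search(
                cons.sequence, index,
                min_identity=config.min_identity, min_len=config.min_len,
            )
            counted = count_copies(hits, config.min_identity, config.min_len)
            copy_seqs = [
                extract_copy(h, genomes, 0, query_len=cons.length).sequence
                for h in counted
            ]
            reports.append(make_report(cons.name, cons, counted, copy_seqs, genome_bp))
        write_report(reports, out / "report.tsv")
        result.reports = reports

        if gene_models is not None:
            stage = "gene_association"
            orig_name = {c.name: key for key, c in
                         ((k, v[2]) for k, v in per_element.items())}
            all_ctx, all_loci = [], []
            for cons in consensus_set:
                hits, copies, _ = per_element[orig_name.get(cons.name, cons.name)]
                for c in copies:
                    all_ctx.append(classify_insertion(c, gene_models))
                    all_loci.append(c.locus)
            if all_ctx:
                write_context_table(all_ctx, all_loci, out / "gene_context.tsv")
                summary = summarize_contexts(all_ctx)
                (out / "gene_context_summary.json").write_text(
                    json.dumps(summary, indent=2)
                )
        elif config.gff3 is None:
            manifest["stages"]["gene_association"] = "skipped (no GFF3)"

        if config.run_phylo:
            stage = "phylo"
            rng = np.random.default_rng(config.seed)
            biggest = max(per_element.values(), key=lambda t: len(t[1]))
            copies = biggest[1][: config.max_phylo_copies]
            if len(copies) >= 3:
                labels = [c.locus.to_1based() for c in copies]
                rows_aln = align_copies([c.sequence for c in copies])
                mat = distance_matrix(rows_aln, labels)
                newick = nj_tree(mat, labels)
                (out / "copies.nwk").write_text(newick + "\n")
                supports = bootstrap(
                    rows_aln, labels, config.bootstrap_replicates, rng
                )
                (out / "bootstrap.tsv").write_text(
                    "bipartition\tsupport\n"
                    + "".join(
                        f"{','.join(sorted(bp))}\t{s:.3f}\n" for bp, s in supports.items()
                    )
                )
        manifest["stages"].update({s: "ok" for s in (
            "search", "extract", "validate", "consensus", "classify", "quantify"
        )})
        result.consensus_set = consensus_set
    except ConfigError:
        raise
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
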