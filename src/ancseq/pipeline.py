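"""End-to-end orchestration: config, node resolution, staged pipeline runs.

A run loads and validates the inputs, roots the tree by the configured
outgroup, optionally fits the gamma shape, reconstructs marginal ancestors
at each target node, and emits the design products (identity matrix,
substitution maps in reference numbering, conservation calls, codon
optimized genes) plus a machine-readable JSON report.  Every stage logs the
input checksums and the RNG seed so a resurrection design is exactly
replayable.

Coordinates in all outputs are 1-based: alignment columns over the full
alignment, reference numbering over non-gap reference positions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .alignment import ProteinAlignment
from .asr import AncestralReconstructionModel
from .resurrection import (
    CodonUsageTable,
    codon_optimize,
    conservation_grades,
    identity_matrix,
    map_substitutions,
)
from .substitution import get_model
from .tree import PhyloTree, root_by_outgroup

__all__ = ["PipelineConfig", "PipelineReport", "resolve_node", "run_pipeline"]

log = logging.getLogger("ancseq")


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    alignment: str
    tree: str
    outdir: str
    outgroup: list[str] = Field(default_factory=list)
    targets: list[int | list[str]] = Field(default_factory=list)
    reference_id: str | None = None
    reference_cds: str | None = None  # FASTA path
    usage_table: str | None = None  # TSV path
    model: str = "LG"
    alpha: float | str = "fit"  # numeric value, or "fit"
    n_categories: int = 4
    seed: int | None = None
    empirical_frequencies: bool = True
    pseudocount: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate_paths(self) -> None:
        for attr in ("alignment", "tree", "reference_cds", "usage_table"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: no such file {p!r}")
        if self.reference_cds is not None and self.seed is None:
            raise ValueError("seed is mandatory when codon design is requested")
        if isinstance(self.alpha, str) and self.alpha != "fit":
            raise ValueError(f"alpha must be a number or 'fit', got {self.alpha!r}")


class NodeReport(BaseModel):
    node: int
    descendants: list[str]
    mean_pp: float
    n_tied_sites: int
    n_gap_sites: int
    n_substitutions: int | None = None
    gene_fasta: str | None = None
    gene_seed: int | None = None


class PipelineReport(BaseModel):
    """Machine-readable run summary (the shipped JSON-schema's model)."""

    version: str
    config_hash: str
    input_checksums: dict[str, str]
    seed: int | None
    model: str
    alpha: float | None
    log_likelihood: float
    n_leaves: int
    n_sites: int
    nodes: list[NodeReport]
    outputs: list[str]


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def resolve_node(tree: PhyloTree, selector: int | Iterable[str]) -> int:
    """Resolve a target-node selector to a post-order node id.

    An integer is validated against the tree's numbering; a leaf-label set
    resolves to its most recent common ancestor.  Selecting a single leaf
    (or the whole leaf set, i.e. the root) is allowed but logged, since it
    is rarely what an ancestor query intends.
    """
    if isinstance(selector, (int, np.integer)):
        nid = int(selector)
        if not 0 <= nid < tree.n_nodes:
            raise KeyError(f"node id {nid} outside 0..{tree.n_nodes - 1}")
        if tree.is_leaf(nid):
            log.warning("selector %d is a leaf; leaves are not ancestors", nid)
        return nid
    labels = list(selector)
    if not labels:
        raise ValueError("empty node selector")
    nid = tree.mrca(labels)
    if tree.is_leaf(nid):
        log.warning("selector %r resolves to a leaf", labels)
    elif nid == tree.root:
        log.warning("selector resolves to the root; check the leaf set")
    return nid


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all configured stages; abort on first failure with the stage
    name and a replayable sub-command hint."""
    stage = "validate"
    try:
        config.validate_paths()
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        checksums = {
            k: _sha256(getattr(config, k))
            for k in ("alignment", "tree", "reference_cds", "usage_table")
            if getattr(config, k) is not None
        }
        cfg_hash = hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]
        log.info("config %s; checksums %s; seed %s", cfg_hash, checksums, config.seed)

        stage = "load"
        alignment = ProteinAlignment.from_fasta(config.alignment)
        tree = PhyloTree.from_newick(config.tree)

        stage = "root"
        if config.outgroup:
            tree = root_by_outgroup(tree, config.outgroup)
            tree.to_newick(outdir / "rooted.nwk")

        stage = "model"
        base = get_model(
            config.model,
            gamma_shape=1.0 if config.alpha == "fit" else float(config.alpha),
            n_categories=config.n_categories,
        )
        asr_model = AncestralReconstructionModel(
            alignment,
            tree,
            base,
            use_empirical_frequencies=config.empirical_frequencies,
            pseudocount=config.pseudocount,
        )
        stage = "fit"
        results = asr_model.fit(fit_alpha=config.alpha == "fit")
        log.info("logL %.3f alpha %s", results.log_likelihood, results.alpha)

        stage = "identity"
        idm = identity_matrix(alignment)
        idm.to_csv(outdir / "identity_matrix.csv", float_format="%.2f")

        stage = "conservation"
        profile = conservation_grades(tree, results.substitution_model, alignment)
        profile.to_frame().to_csv(outdir / "conservation.tsv", sep="\t", index=False)

        usage = CodonUsageTable.from_tsv(config.usage_table) if config.usage_table else None
        ref_cds = None
        if config.reference_cds:
            from Bio import SeqIO

            rec = next(SeqIO.parse(config.reference_cds, "fasta"))
            ref_cds = str(rec.seq)

        node_ids = [resolve_node(tree, sel) for sel in config.targets] or [tree.root]
        node_reports: list[NodeReport] = []
        outputs = ["identity_matrix.csv", "conservation.tsv"]
        anc_fasta = []
        for nid in node_ids:
            stage = f"asr(node {nid})"
            rec = results.reconstruct(nid)
            rec.to_tsv(outdir / f"node{nid}_posteriors.tsv")
            outputs.append(f"node{nid}_posteriors.tsv")
            anc_fasta.append((f"node{nid}", rec.map_sequence, rec.ungapped_sequence))
            nrep = NodeReport(
                node=nid,
                descendants=sorted(tree.leaf_set(nid)),
                mean_pp=rec.mean_pp,
                n_tied_sites=rec.n_tied_sites,
                n_gap_sites=int(rec.gap_mask.sum()),
            )
            if config.reference_id:
                stage = f"substitutions(node {nid})"
                smap = map_substitutions(
                    rec, config.reference_id, alignment, grades=profile.grades
                )
                smap.to_tsv(outdir / f"node{nid}_substitutions.tsv")
                outputs.append(f"node{nid}_substitutions.tsv")
                nrep.n_substitutions = len(smap.entries)
            if ref_cds is not None and usage is not None and config.reference_id:
                stage = f"design(node {nid})"
                gene_seed = int(config.seed) + nid
                gene = codon_optimize(
                    rec.map_sequence,
                    alignment.row(config.reference_id),
                    ref_cds,
                    usage,
                    seed=gene_seed,
                )
                gpath = outdir / f"node{nid}_gene.fasta"
                gpath.write_text(f">node{nid}_gene seed={gene_seed}\n{gene.full_sequence}\n")
                gene.provenance_frame().to_csv(
                    outdir / f"node{nid}_gene_provenance.tsv", sep="\t", index=False
                )
                outputs += [f"node{nid}_gene.fasta", f"node{nid}_gene_provenance.tsv"]
                nrep.gene_fasta = gpath.name
                nrep.gene_seed = gene_seed
                log.info("designed node %d gene with seed %d", nid, gene_seed)
            node_reports.append(nrep)

        stage = "write"
        with open(outdir / "ancestors.fasta", "w") as fh:
            for name, gapped, _ in anc_fasta:
                fh.write(f">{name}\n{gapped}\n")
        with open(outdir / "ancestors_ungapped.fasta", "w") as fh:
            for name, _, ungapped in anc_fasta:
                fh.write(f">{name}\n{ungapped}\n")
        outputs += ["ancestors.fasta", "ancestors_ungapped.fasta"]

        report = PipelineReport(
            version=__version__,
            config_hash=cfg_hash,
            input_checksums=checksums,
            seed=config.seed,
            model=config.model,
            alpha=results.alpha,
            log_likelihood=results.log_likelihood,
            n_leaves=tree.n_leaves,
            n_sites=alignment.length,
            nodes=node_reports,
            outputs=sorted(set(outputs)) + ["report.json"],
        )
        (outdir / "report.json").write_text(report.model_dump_json(indent=2))
        return report
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc


class PipelineStageError(RuntimeError):
    """Failure in a named pipeline stage, with a replay hint."""

    def __init__(self, stage: str, cause: Exception) -> None:
        self.stage = stage
        self.cause = cause
        super().__init__(
            f"pipeline stage {stage!r} failed: {cause} "
            f"(replay with: ancseq run --config <config> after fixing the input)"
        )
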