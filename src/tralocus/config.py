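"""Run configuration, manifests and the end-to-end pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__

log = logging.getLogger("tralocus")


class ConfigError(ValueError):
    """Invalid or unknown configuration (exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3)."""


@dataclass
class RunConfig:
    """Flat configuration for the end-to-end pipeline.

    Unknown keys are rejected.  Stage selection controls which of
    simulate / annotate / classify / phylo / repertoire / report run; the
    simulate stage generates the inputs the later stages consume when no
    external FASTA/FASTQ paths are given.
    """

    stages: tuple[str, ...] = ("simulate", "annotate", "classify", "phylo",
                               "repertoire", "report")
    out_dir: str = "tralocus_run"
    seed: int = 0
    # external inputs (optional; the simulate stage provides them otherwise)
    genome_fasta: str | None = None
    c_queries_fasta: str | None = None
    germline_fasta: str | None = None
    r1: str | None = None
    r2: str | None = None
    sample: str = "sample1"
    # key thresholds
    subgroup_threshold: float = 75.0
    ortholog_threshold: float = 90.0
    bootstrap_reps: int = 500
    strict_conserved: bool = False
    # synthetic locus and repertoire knobs
    locus_n_subgroups: int = 8
    locus_genes_per_subgroup: tuple[int, int] = (3, 7)
    locus_within_identity: float = 0.86
    locus_between_identity: float = 0.55
    locus_pseudogene_fraction: float = 0.2
    locus_orf_fraction: float = 0.1
    locus_n_traj: int = 10
    locus_n_trdd: int = 3
    rep_n_reads: int = 2000
    rep_productive_fraction: float = 0.8
    rep_error_rate: float = 0.0

    _ALL_STAGES = ("simulate", "annotate", "classify", "phylo", "repertoire", "report")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        bad = [s for s in cfg.stages if s not in cls._ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must be a flat mapping")
        return cls.from_mapping(data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages and write a run manifest.

    Every artifact is recorded in ``manifest.json`` with the tool version,
    config hash and input checksums; a stage failure raises
    :class:`StageError` with stage-scoped context.
    """
    from Bio import SeqIO

    from .annotate import AnnotationConfig, annotate_locus, write_annotation
    from .numbering import imgt_number_v
    from .phylo import DistanceMatrix, bootstrap_support
    from .repertoire import (
        GermlineDB,
        assignments_to_airr,
        merge_pairs,
        normalize_counts,
        run_pipeline_reads,
        usage_tables,
    )
    from .reports import distance_heatmap, locus_ideogram, usage_heatmap
    from .simulate import (
        LocusSpec,
        RepertoireSpec,
        simulate_locus,
        simulate_repertoire_reads,
        write_fastq,
    )
    from .subgroups import classify_locus
    from ._seq import translate

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tralocus",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "inputs": {},
        "outputs": [],
        "skipped_stages": [s for s in RunConfig._ALL_STAGES if s not in config.stages],
    }

    def emit(path: Path):
        manifest["outputs"].append(str(path.relative_to(out)))

    state: dict = {}
    try:
        if "simulate" in config.stages:
            log.info("stage simulate: seed=%d", config.seed)
            spec = LocusSpec(
                n_subgroups=config.locus_n_subgroups,
                genes_per_subgroup=tuple(config.locus_genes_per_subgroup),
                within_subgroup_identity=config.locus_within_identity,
                between_subgroup_identity=config.locus_between_identity,
                pseudogene_fraction=config.locus_pseudogene_fraction,
                orf_fraction=config.locus_orf_fraction,
                n_traj=config.locus_n_traj,
                n_trdd=config.locus_n_trdd,
                rng_seed=config.seed,
            )
            sim = simulate_locus(spec)
            state["sim"] = sim
            sim.write_fasta(out / "locus.fasta")
            sim.write_truth_gff3(out / "truth.gff3")
            emit(out / "locus.fasta")
            emit(out / "truth.gff3")
            rep_spec = RepertoireSpec(
                n_reads=config.rep_n_reads,
                productive_fraction=config.rep_productive_fraction,
                substitution_error_rate=config.rep_error_rate,
                rng_seed=config.seed,
            )
            pairs, truth = simulate_repertoire_reads(sim.germline_set(), rep_spec,
                                                     sample=config.sample)
            write_fastq(pairs, out / "reads_R1.fastq", out / "reads_R2.fastq")
            emit(out / "reads_R1.fastq")
            emit(out / "reads_R2.fastq")
            import pandas as pd

            pd.DataFrame(truth).drop(columns=["amplicon"]).to_csv(
                out / "reads_truth.tsv", sep="\t", index=False
            )
            emit(out / "reads_truth.tsv")
            state["reads"] = ([(r, a) for r, a, _ in pairs], [(r, b) for r, _, b in pairs])
            state["germline"] = sim.germline_set()

        if "annotate" in config.stages:
            log.info("stage annotate")
            if config.genome_fasta:
                rec = next(SeqIO.parse(config.genome_fasta, "fasta"))
                genome, contig = str(rec.seq).upper(), rec.id
                manifest["inputs"]["genome_fasta"] = _sha256(Path(config.genome_fasta))
                queries = {
                    r.id: str(r.seq).upper()
                    for r in SeqIO.parse(config.c_queries_fasta, "fasta")
                }
                manifest["inputs"]["c_queries_fasta"] = _sha256(Path(config.c_queries_fasta))
            elif "sim" in state:
                genome, contig = state["sim"].genome, state["sim"].contig
                queries = state["sim"].c_queries()
            else:
                raise ConfigError("annotate stage needs genome_fasta or the simulate stage")
            acfg = AnnotationConfig(strict_conserved=config.strict_conserved)
            ann = annotate_locus(genome, queries, acfg, contig=contig)
            state["annotation"] = ann

        if "classify" in config.stages:
            log.info("stage classify")
            if "annotation" not in state:
                raise ConfigError("classify stage needs the annotate stage")
            classify_locus(state["annotation"], config.subgroup_threshold)
            paths = write_annotation(state["annotation"], out)
            for p in paths.values():
                emit(p)

        if "phylo" in config.stages:
            log.info("stage phylo: %d bootstrap replicates", config.bootstrap_reps)
            if "annotation" not in state:
                raise ConfigError("phylo stage needs the annotate stage")
            ann = state["annotation"]
            from .numbering import align_v_domains

            seqs = {}
            for g in ann.of_type("V"):
                if g.functionality == "F" and g.name:
                    seqs[g.name] = translate(g.part_seq(ann.genome, "V-REGION"))
            if len(seqs) >= 3:
                aligned = align_v_domains(seqs)
                dm = DistanceMatrix.from_alignment(aligned)
                dm.write_phylip(out / "v_distances.phy")
                emit(out / "v_distances.phy")
                state["dm"] = dm
                tree = bootstrap_support(aligned, config.bootstrap_reps, config.seed)
                (out / "v_tree.nwk").write_text(tree.newick(with_support=True) + "\n")
                emit(out / "v_tree.nwk")
            else:
                log.warning("phylo: fewer than three functional V genes; skipped")

        if "repertoire" in config.stages:
            log.info("stage repertoire")
            if config.r1 and config.r2:
                r1, r2 = config.r1, config.r2
                manifest["inputs"]["r1"] = _sha256(Path(r1))
                manifest["inputs"]["r2"] = _sha256(Path(r2))
            elif "reads" in state:
                r1, r2 = state["reads"]
            else:
                raise ConfigError("repertoire stage needs r1/r2 or the simulate stage")
            if config.germline_fasta:
                db = GermlineDB.from_fasta(config.germline_fasta)
                manifest["inputs"]["germline_fasta"] = _sha256(Path(config.germline_fasta))
            elif "germline" in state:
                db = GermlineDB.from_germline_set(state["germline"].genes)
            else:
                raise ConfigError("repertoire stage needs a germline reference")
            merged, drop_merge = merge_pairs(r1, r2, sample=config.sample)
            log.info("merge: %d merged, %d dropped", len(merged), len(drop_merge))
            assignments, drop_assign = run_pipeline_reads(merged, db)
            log.info("assigned %d reads (%d dropped at filters)",
                     len(assignments), len(drop_assign))
            airr = assignments_to_airr(assignments)
            airr.to_csv(out / "rearrangements.tsv", sep="\t", index=False)
            emit(out / "rearrangements.tsv")
            usage = usage_tables(assignments)
            state["usage"] = usage
            for sample, tables in usage.items():
                for label, um in tables.items():
                    p = out / f"usage_{sample}_{label}.tsv"
                    um.vj_counts.to_csv(p, sep="\t")
                    emit(p)

        if "report" in config.stages:
            log.info("stage report")
            if "annotation" in state:
                locus_ideogram(state["annotation"].genes,
                               len(state["annotation"].genome), out / "locus_map.png")
                emit(out / "locus_map.png")
                emit(out / "locus_map.tsv")
            if "dm" in state:
                distance_heatmap(state["dm"], out / "v_distance_heatmap.png")
                emit(out / "v_distance_heatmap.png")
                emit(out / "v_distance_heatmap.tsv")
            if "usage" in state:
                import pandas as pd

                for sample, tables in state["usage"].items():
                    counts = tables["productive"].vj_counts
                    flat = counts.stack().rename("count").reset_index()
                    flat.columns = ["v_call", "j_call", "count"]
                    if counts.values.sum() > 0:
                        norm = normalize_counts(
                            counts.stack().to_frame(sample).clip(lower=0)
                        )
                        mat = norm[sample].unstack()
                    else:
                        mat = counts.astype(float)
                    usage_heatmap(mat, out / f"usage_heatmap_{sample}.png",
                                  title=f"{sample} productive V x J (log2)")
                    emit(out / f"usage_heatmap_{sample}.png")
                    emit(out / f"usage_heatmap_{sample}.tsv")
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # pragma: no cover - stage-scoped diagnostics
        raise StageError(f"pipeline stage failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    return out
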