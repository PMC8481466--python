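"""Run configuration and end-to-end pipeline orchestration.

All analysis thresholds live here with their standard defaults (minimum
contig length 1000 bp, 90%/90% redundancy merging, 20 bp terminal repeat,
3-read presence minimum, plasmid score 15, adjusted-p significance 1e-5);
any override is echoed in the run log.  ``run_pipeline`` executes the
stages curation -> annotation -> clustering -> abundance -> diversity ->
differential abundance -> concordance, writing plain-text artifacts that
carry the configuration hash, and is byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import abundance, annotation, clustering, curation, diffabund, diversity, synthetic

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for a pipeline run."""

    output_dir: str = "viropipe_out"
    contigs: str | None = None
    annotations: str | None = None
    evidence_flags: str | None = None
    reads_dir: str | None = None
    metadata: str | None = None
    demo: bool = False

    min_len: int = 1000
    identity_min: float = 0.90
    coverage_min: float = 0.90
    k_min: int = 20
    min_reads: int = 3
    plasmid_score_min: float = 15.0
    alpha: float = 1e-5
    min_shared_genes: int = 2
    n_permutations: int = 999
    read_length: int = 150
    seed: int = 0

    stages: tuple[str, ...] = (
        "curation", "annotation", "clustering", "abundance",
        "diversity", "diffabund", "concordance",
    )
    demo_n_viral: int = 50
    demo_n_contaminant: int = 10
    demo_animals_per_treatment: int = 3
    demo_reads_per_sample: int = 20_000
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        extra = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra = extra
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not change the analysis and is excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _load_reads_dir(reads_dir: Path) -> dict[str, list[tuple[str, str]]]:
    reads: dict[str, list[tuple[str, str]]] = {}
    for path in sorted(reads_dir.iterdir()):
        if path.suffix not in {".fastq", ".fq", ".fasta", ".fa"}:
            continue
        fmt = "fastq" if path.suffix in {".fastq", ".fq"} else "fasta"
        reads[path.stem] = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), fmt)]
    return reads


def run_pipeline(config: RunConfig) -> Path:
    """Execute the pipeline and return the output directory.

    In ``demo`` mode a synthetic community is generated first and its
    inputs written under ``<output>/inputs``; otherwise all configured
    input paths must exist (validated before any stage runs, so a missing
    sample sheet aborts before the abundance stage is reached).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_path = out / "run_log.jsonl"
    defaults = RunConfig()
    overrides = {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(RunConfig)
        if f.name not in {"extra", "output_dir"}
        and getattr(config, f.name) != getattr(defaults, f.name)
    }
    events: list[dict] = [{"event": "start", "config_hash": chash,
                           "overrides": {k: str(v) for k, v in overrides.items()}}]

    def _log(**kw):
        events.append(kw)
        with open(log_path, "w") as fh:
            for e in events:
                fh.write(json.dumps(e, sort_keys=True) + "\n")

    _log(event="configured")

    truth_counts = None
    community = None
    if config.demo:
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        community = synthetic.generate_genomes(
            n_viral=config.demo_n_viral,
            n_contaminant=config.demo_n_contaminant,
            seed=config.seed,
        )
        viral_ids = community.viral_ids
        # baseline abundances are expected per-sample counts; spread the
        # sample depth evenly across genomes
        depth = config.demo_reads_per_sample / len(community.sequences)
        rng_abund = {gid: depth for gid in community.sequences}
        # spike singleton genomes (the tail of the viral id list) so the
        # effects stay visible after cluster aggregation
        s1, s2, s3 = viral_ids[-1], viral_ids[-2], viral_ids[-3]
        effects = [
            (s1, "PFF+LPS", "T1", 3.0),
            (s1, "PFF+LPS", "T5", 3.0),
            (s2, "monomer+LPS", "T5", -3.0),
            (s3, "PFF", "T5", 2.5),
        ]
        design = synthetic.CommunityDesign(
            baseline_abundances=rng_abund,
            effect_table=effects,
            n_animals_per_treatment=config.demo_animals_per_treatment,
            reads_per_sample=config.demo_reads_per_sample,
            read_length=config.read_length,
            seed=config.seed,
        )
        reads, truth_counts, metadata = synthetic.simulate_reads(community, design)
        synthetic.write_fasta(community.sequences, inputs / "contigs.fasta")
        _write(community.annotations, inputs / "annotations.tsv")
        _write(community.evidence_flags, inputs / "evidence_flags.tsv")
        _write(metadata, inputs / "metadata.tsv")
        _write(truth_counts, inputs / "truth_counts.tsv", index=True)
        contigs = [
            curation.Contig(t.genome_id, community.sequences[t.genome_id])
            for t in community.truths
        ]
        annotations = community.annotations
        flags = community.evidence_flags
        _log(event="demo_inputs", n_genomes=len(contigs))
    else:
        required = {"contigs": config.contigs, "annotations": config.annotations,
                    "metadata": config.metadata}
        if "abundance" in config.stages:
            required["reads_dir"] = config.reads_dir
        for name, path in required.items():
            if path is None or not Path(path).exists():
                raise PipelineError(f"missing input '{name}'; aborting before any stage")
        contigs = [
            curation.Contig(r.id, str(r.seq).upper())
            for r in SeqIO.parse(config.contigs, "fasta")
        ]
        annotations = pd.read_csv(config.annotations, sep="\t")
        flags = (
            pd.read_csv(config.evidence_flags, sep="\t")
            if config.evidence_flags else None
        )
        metadata = pd.read_csv(config.metadata, sep="\t")
        reads = _load_reads_dir(Path(config.reads_dir)) if config.reads_dir else {}

    stage = "curation"
    try:
        evidence = curation.evidence_from_annotations(contigs, annotations, flags)
        result = curation.curate(
            contigs, evidence,
            min_len=config.min_len, k_min=config.k_min,
            identity_min=config.identity_min, coverage_min=config.coverage_min,
            plasmid_score_min=config.plasmid_score_min,
        )
        viral = result.viral
        _write(result.report, out / "curation_report.tsv")
        synthetic.write_fasta({c.contig_id: c.sequence for c in viral},
                              out / "viral_database.fasta")
        _log(event="stage_done", stage=stage, n_viral=len(viral), config_hash=chash)

        if "annotation" not in config.stages:
            _log(event="stopped", completed=stage)
            return out
        stage = "annotation"
        ann_table = annotation.annotate_contigs([c.contig_id for c in viral], annotations)
        _write(ann_table, out / "lifestyle_family.tsv")
        _log(event="stage_done", stage=stage, config_hash=chash)

        if "clustering" not in config.stages:
            _log(event="stopped", completed=stage)
            return out
        stage = "clustering"
        cluster_map = clustering.cluster_contigs(
            annotations, [c.contig_id for c in viral], min_shared=config.min_shared_genes
        )
        _write(cluster_map, out / "cluster_map.tsv")
        _log(event="stage_done", stage=stage,
             n_clustered=int(cluster_map["status"].str.startswith("cluster:").sum()),
             config_hash=chash)

        if "abundance" not in config.stages:
            _log(event="stopped", completed=stage)
            return out
        stage = "abundance"
        profiles, unmapped = abundance.map_reads(
            reads, viral, read_length=config.read_length
        )
        _write(profiles, out / "coverage_profiles.tsv")
        contig_counts = abundance.count_table(
            profiles, min_reads=config.min_reads,
            sample_order=list(metadata["sample_id"]),
        )
        _write(contig_counts, out / "counts_contigs.tsv", index=True)
        group_counts = abundance.aggregate_clusters(contig_counts, cluster_map)
        _write(group_counts, out / "counts_groups.tsv", index=True)
        _log(event="stage_done", stage=stage,
             unmapped={k: int(v) for k, v in sorted(unmapped.items())},
             config_hash=chash)

        if "diversity" not in config.stages:
            _log(event="stopped", completed=stage)
            return out
        stage = "diversity"
        alpha_div = pd.DataFrame(
            {
                "sample_id": group_counts.columns,
                "shannon": [
                    diversity.shannon(group_counts[s]) if group_counts[s].sum() > 0 else 0.0
                    for s in group_counts.columns
                ],
            }
        )
        _write(alpha_div, out / "alpha_diversity.tsv")
        beta = diversity.beta_diversity_matrix(group_counts)
        _write(beta, out / "beta_matrix.tsv", index=True)
        ord_res = diversity.pcoa(beta, n_axes=2)
        coords = ord_res.coordinates.copy()
        coords.insert(0, "sample_id", coords.index)
        _write(coords, out / "pcoa_coordinates.tsv")
        meta_idx = metadata.set_index("sample_id").loc[beta.index]
        perm = diversity.permanova(
            beta, meta_idx["timepoint"].values,
            n_perm=config.n_permutations, seed=config.seed,
        )
        _write(pd.DataFrame([perm]), out / "permanova_time.tsv")
        per_animal, by_treatment, by_cage = diversity.longitudinal_dissimilarity(
            group_counts, metadata
        )
        _write(per_animal, out / "longitudinal_dissimilarity.tsv")
        _write(by_treatment.reset_index(), out / "longitudinal_by_treatment.tsv")
        _log(event="stage_done", stage=stage,
             permanova_time_r2=perm["r2"], config_hash=chash)

        if "diffabund" not in config.stages:
            _log(event="stopped", completed=stage)
            return out
        stage = "diffabund"
        de = diffabund.nb_wald_test(group_counts, metadata, alpha=config.alpha)
        _write(de, out / "differential_abundance.tsv")
        _write(diffabund.volcano_table(de), out / "volcano.tsv")
        _log(event="stage_done", stage=stage,
             n_significant=int(de["significant"].sum()), config_hash=chash)

        if "concordance" not in config.stages:
            _log(event="stopped", completed=stage)
            return out
        stage = "concordance"
        records, summary = diffabund.concordance(de)
        _write(
            records.assign(
                treatments_altered=records["treatments_altered"].map(",".join),
                timepoints_altered=records["timepoints_altered"].map(",".join),
                direction=records["direction"].map(
                    lambda d: ";".join(f"{t}:{c}={v}" for (t, c), v in sorted(d.items()))
                ),
            )
            if len(records) else records,
            out / "concordance.tsv",
        )
        with open(out / "concordance_summary.json", "w") as fh:
            json.dump({"config_hash": chash, **summary}, fh, indent=2, sort_keys=True)
        _log(event="stage_done", stage=stage, config_hash=chash, **{
            k: v for k, v in summary.items() if not isinstance(v, dict)
        })
    except PipelineError:
        raise
    except Exception as exc:  # partial outputs are retained on disk
        _log(event="stage_failed", stage=stage, error=str(exc))
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    _log(event="finished", config_hash=chash)
    return out
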