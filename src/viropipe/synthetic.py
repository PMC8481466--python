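"""Synthetic faecal-virome community generator.

Emits phage-like genomes, protein annotations, per-sample reads and sample
metadata with full ground truth, emulating the structure of a longitudinal
six-arm rodent study: treatments {Sham, LPS, monomer, monomer+LPS, PFF,
PFF+LPS}, timepoints {Base, T1, T5}, animals housed two cages per arm.
Every downstream stage (curation, clustering, presence filtering, diversity
and differential abundance) can be tested against the returned truth labels
and truth count tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import pvog_tier_threshold

TREATMENTS = ("Sham", "LPS", "monomer", "monomer+LPS", "PFF", "PFF+LPS")
TIMEPOINTS = ("Base", "T1", "T5")

#: terminal direct-repeat length used to linearize circular genomes; shared
#: constant with the circularity detector
TERMINAL_REPEAT = 20

_FAMILIES = ("Siphoviridae", "Myoviridae", "Podoviridae", "Microviridae")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeTruth:
    """Ground-truth record for one synthetic genome."""

    genome_id: str
    length_bp: int
    topology: str  # circular | linear
    lifestyle: str  # lysogenic | unknown
    role: str  # virus | bacterial_contaminant | plasmid_contaminant
    family_label: str
    cluster_label: str


@dataclass
class CommunityDesign:
    """Experimental design for read simulation.

    ``baseline_abundances`` are strictly positive expected relative weights
    per genome; ``effect_table`` rows are (genome_id, treatment, timepoint,
    log2 fold change) perturbations applied multiplicatively; ``dispersion``
    is the negative-binomial overdispersion shared across genomes
    (var = mu + dispersion * mu^2).
    """

    baseline_abundances: dict[str, float]
    effect_table: list[tuple[str, str, str, float]] = field(default_factory=list)
    treatments: tuple[str, ...] = TREATMENTS
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_animals_per_treatment: int = 6
    dispersion: float = 0.1
    reads_per_sample: int = 20_000
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.baseline_abundances.values()):
            raise ValueError("baseline abundances must be strictly positive")
        known = set(self.baseline_abundances)
        for gid, trt, tp, _ in self.effect_table:
            if gid not in known:
                raise ValueError(f"effect_table references unknown genome {gid}")
            if trt not in self.treatments or tp not in self.timepoints:
                raise ValueError(f"effect_table references unknown cell ({trt}, {tp})")


@dataclass
class SyntheticCommunity:
    truths: list[GenomeTruth]
    sequences: dict[str, str]
    annotations: pd.DataFrame
    evidence_flags: pd.DataFrame

    @property
    def viral_ids(self) -> list[str]:
        return [t.genome_id for t in self.truths if t.role == "virus"]

    @property
    def contaminant_ids(self) -> list[str]:
        return [t.genome_id for t in self.truths if t.role != "virus"]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_genomes(
    n_viral: int,
    n_contaminant: int = 0,
    length_range: tuple[int, int] = (1_500, 50_000),
    circular_fraction: float = 0.2,
    lysogenic_fraction: float = 0.1,
    seed: int = 0,
    terminal_repeat: int = TERMINAL_REPEAT,
    cluster_size: int = 3,
    clustered_fraction: float = 0.7,
    plasmid_fraction: float = 0.5,
) -> SyntheticCommunity:
    """Generate a synthetic community with known truth labels.

    Viral genomes get length-tiered phage-orthologous-group annotations
    (always enough to pass the curation threshold), a family label, and —
    for the lysogenic fraction — an integrase or recombinase gene.  Genomes
    sharing a cluster label draw their orthologous groups from a common
    pool, so the gene-sharing graph can recover the clustering.  Bacterial
    contaminants carry ribosomal proteins; plasmid contaminants carry a
    replication protein scoring >= 15.  Circular genomes are emitted
    linearized with their first ``terminal_repeat`` bases duplicated at the
    3' terminus.
    """
    if n_viral < 0 or n_contaminant < 0:
        raise ValueError("genome counts must be non-negative")
    if n_viral + n_contaminant == 0:
        raise ValueError("at least one genome must be requested")
    if not (0 <= circular_fraction <= 1 and 0 <= lysogenic_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if length_range[0] < 1000:
        raise ValueError("minimum genome length is 1000 bp")

    rng = np.random.default_rng(seed)
    truths: list[GenomeTruth] = []
    sequences: dict[str, str] = {}
    ann_rows: list[tuple[str, int, str, str, float]] = []
    flag_rows: list[tuple[str, bool, bool, bool]] = []

    # cluster memberships: leading clustered_fraction of viral genomes in
    # groups of cluster_size, remainder singletons
    n_clustered = int(round(n_viral * clustered_fraction))
    cluster_of: list[str] = []
    for i in range(n_viral):
        if i < n_clustered:
            cluster_of.append(f"truthVC{i // cluster_size:03d}")
        else:
            cluster_of.append(f"singleton{i:03d}")
    # per-cluster orthologous-group pools, disjoint across clusters
    pools: dict[str, list[str]] = {}
    counter = 0
    for lab in cluster_of:
        if lab not in pools:
            pools[lab] = [f"VOG{counter + j:05d}" for j in range(12)]
            counter += 12

    lysogenic_draws = rng.random(n_viral) < lysogenic_fraction
    circular_draws = rng.random(n_viral) < circular_fraction

    log_lo, log_hi = np.log(length_range[0]), np.log(length_range[1])

    for i in range(n_viral):
        gid = f"virus{i:04d}"
        length = int(np.exp(rng.uniform(log_lo, log_hi)))
        core = _random_sequence(rng, length)
        circular = bool(circular_draws[i])
        seq = core + core[:terminal_repeat] if circular else core
        family = _FAMILIES[int(rng.integers(len(_FAMILIES)))]
        lifestyle = "lysogenic" if lysogenic_draws[i] else "unknown"
        truths.append(
            GenomeTruth(gid, len(seq), "circular" if circular else "linear",
                        lifestyle, "virus", family, cluster_of[i])
        )
        sequences[gid] = seq
        pidx = 0
        n_pvog = pvog_tier_threshold(len(seq)) + 2
        # every cluster member carries the pool's first four families, so any
        # pair of members shares enough genes to be joined by the graph
        pool = pools[cluster_of[i]]
        extra = rng.choice(pool[4:], size=n_pvog - 4, replace=False)
        labels = list(pool[:4]) + list(extra)
        for lab in labels:
            ann_rows.append((gid, pidx, "pVOG", str(lab), float(rng.uniform(30, 150))))
            pidx += 1
        for _ in range(3):
            ann_rows.append((gid, pidx, f"family:{family}", "", float(rng.uniform(30, 150))))
            pidx += 1
        if lifestyle == "lysogenic":
            cat = "integrase" if rng.random() < 0.5 else "recombinase"
            ann_rows.append((gid, pidx, cat, "", float(rng.uniform(30, 150))))
            pidx += 1
        flag_rows.append((gid, bool(rng.random() < 0.4), bool(rng.random() < 0.3),
                          bool(rng.random() < 0.2)))

    n_plasmid = int(round(n_contaminant * plasmid_fraction))
    junk_counter = 0
    for i in range(n_contaminant):
        is_plasmid = i < n_plasmid
        gid = f"plasmid{i:04d}" if is_plasmid else f"bacteria{i:04d}"
        length = int(np.exp(rng.uniform(log_lo, log_hi)))
        core = _random_sequence(rng, length)
        circular = bool(is_plasmid and rng.random() < 0.5)
        seq = core + core[:terminal_repeat] if circular else core
        role = "plasmid_contaminant" if is_plasmid else "bacterial_contaminant"
        truths.append(
            GenomeTruth(gid, len(seq), "circular" if circular else "linear",
                        "unknown", role, "none", "none")
        )
        sequences[gid] = seq
        pidx = 0
        if is_plasmid:
            ann_rows.append((gid, pidx, "plasmid_rep", "", float(rng.uniform(20, 80))))
            pidx += 1
        else:
            for _ in range(2):
                ann_rows.append((gid, pidx, "ribosomal", "", float(rng.uniform(30, 150))))
                pidx += 1
        # sub-threshold orthologous-group noise, private labels
        for _ in range(int(rng.integers(0, 3))):
            ann_rows.append((gid, pidx, "pVOG", f"JUNK{junk_counter:05d}",
                             float(rng.uniform(20, 60))))
            junk_counter += 1
            pidx += 1
        flag_rows.append((gid, False, False, False))

    annotations = pd.DataFrame(
        ann_rows, columns=["contig_id", "protein_index", "category", "label", "score"]
    )
    evidence_flags = pd.DataFrame(
        flag_rows,
        columns=["contig_id", "refseq_viral_hit", "external_classifier_viral", "dark_matter"],
    )
    return SyntheticCommunity(truths, sequences, annotations, evidence_flags)


def build_metadata(design: CommunityDesign) -> pd.DataFrame:
    """Sample sheet: one row per animal x timepoint, two cages per arm.

    Cage codes follow the C<cage>-R<rat> convention (cage number, rat number
    within cage); sample_id is ``<animal_id>-<timepoint>``.
    """
    rows = []
    per_cage = -(-design.n_animals_per_treatment // 2)  # ceil
    cage_no = 0
    for trt in design.treatments:
        for a in range(design.n_animals_per_treatment):
            cage = cage_no + 1 + a // per_cage
            rat = a % per_cage + 1
            animal_id = f"C{cage:02d}-R{rat}"
            for tp in design.timepoints:
                rows.append((f"{animal_id}-{tp}", animal_id, f"C{cage:02d}", trt, tp))
        cage_no += 2
    return pd.DataFrame(
        rows, columns=["sample_id", "animal_id", "cage_id", "treatment", "timepoint"]
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu).astype(float)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p).astype(float)


def simulate_reads(
    community: SyntheticCommunity,
    design: CommunityDesign,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample read sets with a ground-truth count table.

    Per sample, expected genome weights are the baseline abundances scaled
    by 2**log2FC for any (treatment, timepoint) effect, realized as
    negative-binomial draws; exactly ``reads_per_sample`` reads are then
    emitted by a multinomial over those weights, so per-sample read counts
    are conserved exactly.  Reads are error-free forward-strand substrings
    with uniform start positions; starts on circular genomes may wrap the
    origin.  Returns (reads per sample, truth count table genomes x
    samples, metadata).
    """
    genome_ids = [t.genome_id for t in community.truths if t.genome_id in design.baseline_abundances]
    missing = set(design.baseline_abundances) - set(community.sequences)
    if missing:
        raise ValueError(f"design references unknown genomes: {sorted(missing)}")
    metadata = build_metadata(design)
    rng = np.random.default_rng(design.seed)
    effects: dict[tuple[str, str], dict[str, float]] = {}
    for gid, trt, tp, lfc in design.effect_table:
        effects.setdefault((trt, tp), {})[gid] = lfc

    topo = {t.genome_id: t for t in community.truths}
    rl = design.read_length
    base = np.array([design.baseline_abundances[g] for g in genome_ids])

    reads: dict[str, list[tuple[str, str]]] = {}
    counts = np.zeros((len(genome_ids), len(metadata)), dtype=int)
    for s_idx, row in enumerate(metadata.itertuples()):
        if design.reads_per_sample == 0:
            warnings.warn(f"sample {row.sample_id}: zero reads requested")
            reads[row.sample_id] = []
            continue
        mu = base.copy()
        cell = effects.get((row.treatment, row.timepoint), {})
        for g_idx, gid in enumerate(genome_ids):
            if gid in cell:
                mu[g_idx] *= 2.0 ** cell[gid]
        weights = _nb_draw(rng, mu, design.dispersion)
        if weights.sum() == 0:
            weights = mu
        sample_counts = rng.multinomial(design.reads_per_sample, weights / weights.sum())
        counts[:, s_idx] = sample_counts
        sample_reads: list[tuple[str, str]] = []
        r = 0
        for g_idx, gid in enumerate(genome_ids):
            c = int(sample_counts[g_idx])
            if c == 0:
                continue
            seq = community.sequences[gid]
            t = topo[gid]
            if t.topology == "circular":
                core_len = len(seq) - TERMINAL_REPEAT
                ext = seq[:core_len] + seq[: rl - 1]
                starts = rng.integers(0, core_len, size=c)
            else:
                ext = seq
                starts = rng.integers(0, max(len(seq) - rl, 0) + 1, size=c)
            for s in starts:
                sample_reads.append((f"{row.sample_id}_r{r}", ext[s : s + rl]))
                r += 1
        reads[row.sample_id] = sample_reads
    truth = pd.DataFrame(counts, index=genome_ids, columns=list(metadata["sample_id"]))
    return reads, truth, metadata


# ---------------------------------------------------------------------------
# plain-text writers


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_reads_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def extract_marker(community: SyntheticCommunity, marker_len: int = 1_650) -> dict[str, str]:
    """Cut a housekeeping-marker-like segment (cpn60-sized, ~1.65 kb) from
    each bacterial contaminant, for marker-based contamination estimates."""
    out = {}
    for t in community.truths:
        if t.role == "bacterial_contaminant":
            seq = community.sequences[t.genome_id]
            out[f"{t.genome_id}_cpn60"] = seq[: min(marker_len, len(seq))]
    return out
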