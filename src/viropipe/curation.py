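"""Viral contig curation.

Turns an assembled contig set plus per-contig evidence into a nonredundant,
decontaminated viral database.  The pipeline pools several lines of viral
evidence (reference-database hits, circular topology in virus-enriched
assemblies, an external classifier flag, "dark matter" rescue, and tiered
phage-orthologous-group enrichment), then strips contigs carrying ribosomal
proteins or plasmid replication proteins, and finally collapses redundant
sequences keeping the larger of any homologous pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import edlib
import pandas as pd

logger = logging.getLogger(__name__)

#: minimum contig length retained by the pipeline (bp)
MIN_CONTIG_LEN = 1000
#: minimum terminal direct repeat taken as evidence of a circular genome (bp)
CIRCULAR_K_MIN = 20
#: HMM bit-score at and above which a plasmid replication-protein hit
#: disqualifies a contig
PLASMID_SCORE_MIN = 15.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """A nucleotide contig with curation-relevant attributes.

    ``topology`` is ``"linear"`` until :func:`detect_circularity` assigns it.
    ``source`` records which sequencing fraction the assembly came from:
    ``"viral_enriched"`` (virus-like-particle enrichment) or ``"wgs"``
    (whole-genome shotgun of the total microbiome).
    """

    contig_id: str
    sequence: str
    source: str = "viral_enriched"
    topology: str = "linear"
    terminal_repeat: int = 0

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def core_length(self) -> int:
        """Length of the underlying genome: circular contigs are emitted
        linearized with their terminal repeat duplicated at the 3' end."""
        return len(self.sequence) - self.terminal_repeat


@dataclass
class EvidenceRecord:
    """Pooled per-contig evidence used for the viral / contaminant calls.

    Boolean fields abstract the external searches (RefSeq BLAST at E<=1e-5,
    classifier categories 1-2, absence from the NT database); counts and
    scores carry the orthologous-group and contaminant-protein hits.
    """

    contig_id: str
    refseq_viral_hit: bool = False
    external_classifier_viral: bool = False
    dark_matter: bool = False
    pvog_hit_count: int = 0
    ribosomal_hit: bool = False
    plasmid_rep_hit_score: float | None = None
    integrase_or_recombinase: bool = False


def length_filter(contigs: list[Contig], min_len: int = MIN_CONTIG_LEN) -> list[Contig]:
    """Discard contigs shorter than ``min_len`` bp (strictly less than)."""
    if not contigs:
        warnings.warn("length_filter received no contigs")
        return []
    return [c for c in contigs if c.length_bp >= min_len]


def detect_circularity(contig: Contig, k_min: int = CIRCULAR_K_MIN) -> str:
    """Label a contig circular if its termini carry an exact direct repeat.

    A contig is circular iff a prefix of length >= ``k_min`` exactly equals
    a suffix.  The detected repeat length is stored on the contig so that
    downstream coordinate arithmetic can fold positions onto the circular
    core.  Contigs shorter than ``2 * k_min`` cannot be assessed and are
    called linear with a warning.
    """
    seq = contig.sequence
    if len(seq) < 2 * k_min:
        warnings.warn(f"{contig.contig_id}: too short for circularity detection")
        contig.topology = "linear"
        contig.terminal_repeat = 0
        return "linear"
    if seq[:k_min] != seq[-k_min:]:
        contig.topology = "linear"
        contig.terminal_repeat = 0
        return "linear"
    k = k_min
    while k < len(seq) // 2 and seq[: k + 1] == seq[-(k + 1):]:
        k += 1
    contig.topology = "circular"
    contig.terminal_repeat = k
    return "circular"


# tiers: (lower bound inclusive in bp, required hits); upper bounds are the
# next tier's lower bound, half-open
_PVOG_TIERS = ((60_000, 8), (40_000, 7), (20_000, 6), (10_000, 5), (5_000, 4), (0, 3))


def pvog_tier_threshold(length_bp: int) -> int:
    """Required phage-orthologous-group hit count for a contig to be called
    protein-content viral, tiered by length: <5 kb needs 3 hits, then 4, 5,
    6, 7 for each tier up to 8 hits at >=60 kb.
    """
    if length_bp < MIN_CONTIG_LEN:
        raise ValueError(f"length {length_bp} below global minimum {MIN_CONTIG_LEN}")
    for lower, hits in _PVOG_TIERS:
        if length_bp >= lower:
            return hits
    raise AssertionError("unreachable")


def classify_viral(contig: Contig, ev: EvidenceRecord) -> bool:
    """Pool the independent viral-evidence routes (set union).

    A contig is viral if any holds: a viral RefSeq hit; circular topology in
    the virus-enriched fraction; the external classifier called it viral;
    it is dark matter from the virus-enriched fraction; or its
    orthologous-group hit count reaches the length-tiered threshold.
    """
    enriched = contig.source == "viral_enriched"
    return (
        ev.refseq_viral_hit
        or (contig.topology == "circular" and enriched)
        or ev.external_classifier_viral
        or (ev.dark_matter and enriched)
        or ev.pvog_hit_count >= pvog_tier_threshold(contig.length_bp)
    )


def remove_contaminants(
    contigs: list[Contig],
    evidence: dict[str, EvidenceRecord],
    plasmid_score_min: float = PLASMID_SCORE_MIN,
) -> tuple[list[Contig], dict[str, str]]:
    """Drop putative-viral contigs with contaminant signatures.

    Contigs encoding ribosomal proteins are removed outright; contigs with a
    plasmid replication-protein hit scoring at or above ``plasmid_score_min``
    are removed.  Returns the survivors and a {contig_id: reason} log.
    """
    removed: dict[str, str] = {}
    kept: list[Contig] = []
    for c in contigs:
        ev = evidence[c.contig_id]
        if ev.ribosomal_hit:
            removed[c.contig_id] = "ribosomal_protein"
        elif ev.plasmid_rep_hit_score is not None and ev.plasmid_rep_hit_score >= plasmid_score_min:
            removed[c.contig_id] = "plasmid_replication_protein"
        else:
            kept.append(c)
    for cid, reason in removed.items():
        logger.info("removed %s: %s", cid, reason)
    return kept, removed


def _kmer_set(seq: str, k: int) -> set[str]:
    # canonical k-mers so reverse-complement homologs still share seeds
    out = set()
    rc = reverse_complement(seq)
    n = len(seq)
    for i in range(0, n - k + 1):
        fwd = seq[i : i + k]
        rev = rc[n - k - i : n - i]
        out.add(min(fwd, rev))
    return out


def _homologous(short: str, long: str, identity_min: float) -> bool:
    """Containment homology: the whole shorter sequence aligns within the
    longer (either strand) with identity >= identity_min."""
    max_dist = int(len(short) * (1.0 - identity_min))
    for query in (short, reverse_complement(short)):
        res = edlib.align(query, long, mode="HW", task="distance", k=max_dist)
        if res["editDistance"] != -1:
            return True
    return False


def merge_redundant(
    contigs: list[Contig],
    identity_min: float = 0.90,
    coverage_min: float = 0.90,
    seed_k: int = 15,
) -> list[Contig]:
    """Collapse redundant sequences, retaining the larger of any homologous
    pair (>= ``identity_min`` identity over >= ``coverage_min`` of the
    shorter sequence; the verification aligns the entire shorter sequence
    within the longer, so coverage of the shorter is complete).

    Greedy by descending length (ties broken by lexicographic contig_id), so
    the surviving set does not depend on input order.  Candidate pairs are
    prefiltered by shared canonical ``seed_k``-mers before alignment.
    """
    del coverage_min  # containment verification covers the shorter fully
    order = sorted(contigs, key=lambda c: (-c.length_bp, c.contig_id))
    survivors: list[Contig] = []
    kmers: list[set[str]] = []
    for c in order:
        ck = _kmer_set(c.sequence, seed_k)
        absorbed = False
        for s, sk in zip(survivors, kmers):
            if ck & sk and _homologous(c.sequence, s.sequence, identity_min):
                absorbed = True
                logger.info("merged %s into %s", c.contig_id, s.contig_id)
                break
        if not absorbed:
            survivors.append(c)
            kmers.append(ck)
    surviving_ids = {c.contig_id for c in survivors}
    return [c for c in contigs if c.contig_id in surviving_ids]


def evidence_from_annotations(
    contigs: list[Contig],
    annotations: pd.DataFrame,
    flags: pd.DataFrame | None = None,
) -> dict[str, EvidenceRecord]:
    """Build evidence records from a protein annotation table.

    ``annotations`` columns: contig_id, protein_index, category, label,
    score.  Categories: ``pVOG``, ``ribosomal``, ``plasmid_rep``,
    ``integrase``, ``recombinase``, ``family:<name>``.  ``flags``, if given,
    contributes the database-abstraction booleans (refseq_viral_hit,
    external_classifier_viral, dark_matter) per contig_id.
    """
    by_contig = dict(tuple(annotations.groupby("contig_id", sort=False)))
    flag_rows = {}
    if flags is not None:
        flag_rows = {r.contig_id: r for r in flags.itertuples()}
    evidence = {}
    for c in contigs:
        rows = by_contig.get(c.contig_id)
        ev = EvidenceRecord(contig_id=c.contig_id)
        if rows is not None:
            cats = rows["category"]
            ev.pvog_hit_count = int((cats == "pVOG").sum())
            ev.ribosomal_hit = bool((cats == "ribosomal").any())
            plasmid = rows.loc[cats == "plasmid_rep", "score"]
            if len(plasmid):
                ev.plasmid_rep_hit_score = float(plasmid.max())
            ev.integrase_or_recombinase = bool(cats.isin(["integrase", "recombinase"]).any())
        fr = flag_rows.get(c.contig_id)
        if fr is not None:
            ev.refseq_viral_hit = bool(fr.refseq_viral_hit)
            ev.external_classifier_viral = bool(fr.external_classifier_viral)
            ev.dark_matter = bool(fr.dark_matter)
        evidence[c.contig_id] = ev
    return evidence


@dataclass
class CurationResult:
    viral: list[Contig]
    report: pd.DataFrame = field(repr=False)


def curate(
    contigs: list[Contig],
    evidence: dict[str, EvidenceRecord],
    min_len: int = MIN_CONTIG_LEN,
    k_min: int = CIRCULAR_K_MIN,
    identity_min: float = 0.90,
    coverage_min: float = 0.90,
    plasmid_score_min: float = PLASMID_SCORE_MIN,
) -> CurationResult:
    """Run the full curation cascade and return survivors plus a per-contig
    decision report (decision in {too_short, not_viral, contaminant:<why>,
    redundant, retained})."""
    decisions: dict[str, str] = {}
    survivors = length_filter(contigs, min_len=min_len)
    for c in contigs:
        if c.length_bp < min_len:
            decisions[c.contig_id] = "too_short"
    for c in survivors:
        detect_circularity(c, k_min=k_min)
    viral = []
    for c in survivors:
        ev = evidence.get(c.contig_id)
        if ev is None:
            logger.warning("no evidence for %s; skipped", c.contig_id)
            decisions[c.contig_id] = "no_evidence"
            continue
        if classify_viral(c, ev):
            viral.append(c)
        else:
            decisions[c.contig_id] = "not_viral"
    clean, removed = remove_contaminants(viral, evidence, plasmid_score_min=plasmid_score_min)
    for cid, reason in removed.items():
        decisions[cid] = f"contaminant:{reason}"
    merged = merge_redundant(clean, identity_min=identity_min, coverage_min=coverage_min)
    merged_ids = {c.contig_id for c in merged}
    for c in clean:
        decisions[c.contig_id] = "retained" if c.contig_id in merged_ids else "redundant"
    report = pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in contigs],
            "length_bp": [c.length_bp for c in contigs],
            "topology": [c.topology for c in contigs],
            "decision": [decisions[c.contig_id] for c in contigs],
        }
    )
    return CurationResult(viral=merged, report=report)
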