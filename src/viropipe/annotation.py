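"""ORF calling, replication-lifestyle and family assignment for viral contigs.

The ORF caller is a deliberately simple deterministic gene finder (ATG-only
starts, standard stop codons, both strands, minimum peptide length).
Lifestyle is lysogenic iff the contig encodes a phage integrase and/or
recombinase; family is a majority vote over per-protein family annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .curation import reverse_complement

_STOPS = {"TAA", "TAG", "TGA"}
_MAX_N_RUN = "N" * 11


@dataclass
class OrfCall:
    contig_id: str
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str  # "+" | "-"
    protein_sequence: str


def _scan_strand(seq: str, min_nt: int):
    """Maximal ATG->stop frames on one strand: per frame, the first ATG after
    the previous stop opens the ORF closed by the next in-frame stop."""
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if start is not None and (i + 3 - start) >= min_nt:
                    yield start, i + 3
                start = None
            elif start is None and codon == "ATG":
                start = i


def find_orfs(contig_id: str, sequence: str, min_aa: int = 30) -> list[OrfCall]:
    """All maximal ATG->stop open reading frames of >= ``min_aa`` residues on
    both strands, in ascending start order.  Frames spanning an ambiguity
    run longer than 10 bases are suppressed.  Coordinates are 1-based
    inclusive on the forward strand; the stop codon is included in the span
    but not the peptide.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A, C, G, T, N")
    min_nt = (min_aa + 1) * 3  # peptide plus stop codon
    n = len(seq)
    calls: list[OrfCall] = []
    for i, j in _scan_strand(seq, min_nt):
        sub = seq[i:j]
        if _MAX_N_RUN in sub:
            continue
        protein = str(Seq(sub[:-3]).translate())
        calls.append(OrfCall(contig_id, i + 1, j, "+", protein))
    rc = reverse_complement(seq)
    for i, j in _scan_strand(rc, min_nt):
        sub = rc[i:j]
        if _MAX_N_RUN in sub:
            continue
        protein = str(Seq(sub[:-3]).translate())
        calls.append(OrfCall(contig_id, n - j + 1, n - i, "-", protein))
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


@dataclass
class Lifestyle:
    contig_id: str
    label: str  # lysogenic | unknown


def assign_lifestyle(contig_id: str, annotations: pd.DataFrame) -> Lifestyle:
    """Lysogenic iff the contig has any integrase or recombinase annotation;
    phages without detectable lysogeny genes replicate by an unknown
    strategy."""
    rows = annotations[annotations["contig_id"] == contig_id]
    if rows.empty:
        warnings.warn(f"{contig_id}: absent from annotation table")
        return Lifestyle(contig_id, "unknown")
    lyso = rows["category"].isin(["integrase", "recombinase"]).any()
    return Lifestyle(contig_id, "lysogenic" if lyso else "unknown")


def assign_family(contig_id: str, annotations: pd.DataFrame) -> str:
    """Majority vote over the contig's per-protein family annotations
    (``family:<name>`` category rows); ties and missing votes yield
    ``unclassified``."""
    rows = annotations[annotations["contig_id"] == contig_id]
    fams = rows.loc[rows["category"].str.startswith("family:"), "category"]
    if fams.empty:
        return "unclassified"
    counts = fams.str.removeprefix("family:").value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        return "unclassified"
    return str(counts.index[0])


def annotate_contigs(contig_ids: list[str], annotations: pd.DataFrame) -> pd.DataFrame:
    """Lifestyle + family table for a set of contigs."""
    rows = []
    for cid in contig_ids:
        rows.append((cid, assign_lifestyle(cid, annotations).label,
                     assign_family(cid, annotations)))
    return pd.DataFrame(rows, columns=["contig_id", "lifestyle", "family"])


def orfs_to_gff3(calls: list[OrfCall]) -> str:
    """Serialize ORF calls as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for k, c in enumerate(calls):
        lines.append(
            "\t".join(
                [c.contig_id, "viropipe", "CDS", str(c.start), str(c.end), ".",
                 c.strand, "0", f"ID=orf{k:05d}"]
            )
        )
    return "\n".join(lines) + "\n"
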