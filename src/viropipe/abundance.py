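"""Read mapping, breadth-of-coverage presence filtering and count tables.

Reads are assigned to viral contigs by an exact-substring mapper (a desk-
scale stand-in for an end-to-end short-read aligner; SAM ingestion is
supported for alignments produced externally).  A contig counts as present
in a sample only if at least ``min_reads`` reads map to it AND the fraction
of its positions covered by reads reaches a length-tiered breadth
threshold; cells failing the filter record zero reads.  Contig counts are
then aggregated into viral-cluster (VC) rows, with ambiguous and
unclustered contigs kept as singletons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .curation import Contig, reverse_complement

#: minimum mapped reads for presence, applied jointly with the breadth tier
MIN_READS = 3

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit hashes of every k-mer plus a validity mask (windows
    containing non-ACGT bases are invalid)."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    h = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        h = (h << np.uint64(2)) | codes[j : m + j].astype(np.uint64)
    bad = np.concatenate(([0], np.cumsum(codes > 3)))
    valid = (bad[k:] - bad[:-k]) == 0
    return h, valid


@dataclass
class CoverageProfile:
    contig_id: str
    sample_id: str
    read_count: int
    covered_bases: int
    length_bp: int

    @property
    def breadth(self) -> float:
        return self.covered_bases / self.length_bp


class ReferenceIndex:
    """Seed-and-verify exact-substring index over a contig database.

    Every ``seed_k``-mer position of every reference is hashed; a read is
    placed by looking up the hash of its leading ``seed_k``-mer (forward,
    then reverse-complement) and verifying the full read as an exact
    substring.  Circular contigs are indexed on their core rotated past the
    origin by one read length, so wrap-around reads map; coverage positions
    are folded back onto the core.  A read matching several contigs is
    assigned once, to the lexicographically smallest contig_id.
    """

    def __init__(self, contigs: list[Contig], read_length: int = 150, seed_k: int = 31):
        self.seed_k = seed_k
        self.contigs = sorted(contigs, key=lambda c: c.contig_id)
        self.core_len: dict[str, int] = {}
        self._ext: list[str] = []
        hash_blocks, idx_blocks, pos_blocks = [], [], []
        for ci, c in enumerate(self.contigs):
            core = c.core_length
            self.core_len[c.contig_id] = core
            if c.topology == "circular":
                ext = c.sequence[:core] + c.sequence[: read_length - 1]
            else:
                ext = c.sequence
            self._ext.append(ext)
            h, valid = _kmer_hashes(_encode(ext), seed_k)
            keep = np.nonzero(valid)[0]
            hash_blocks.append(h[keep])
            idx_blocks.append(np.full(keep.size, ci, dtype=np.int32))
            pos_blocks.append(keep.astype(np.int32))
        allh = np.concatenate(hash_blocks) if hash_blocks else np.empty(0, dtype=np.uint64)
        order = np.argsort(allh, kind="stable")
        self._hashes = allh[order]
        self._cidx = np.concatenate(idx_blocks)[order] if idx_blocks else np.empty(0, np.int32)
        self._pos = np.concatenate(pos_blocks)[order] if pos_blocks else np.empty(0, np.int32)

    def _verify(self, read: str, lo: int, hi: int) -> tuple[int, int] | None:
        best: tuple[str, int, int] | None = None
        for j in range(lo, hi):
            ci = int(self._cidx[j])
            pos = int(self._pos[j])
            ext = self._ext[ci]
            if ext[pos : pos + len(read)] == read:
                cid = self.contigs[ci].contig_id
                if best is None or cid < best[0]:
                    best = (cid, ci, pos)
        if best is None:
            return None
        return best[1], best[2]

    @staticmethod
    def _seed_hashes(chunks: list[str], k: int, revcomp: bool) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized 2-bit hashes of one k-length chunk per read.  With
        ``revcomp`` the chunks are reverse-complemented before hashing."""
        codes = _CODE[
            np.frombuffer("".join(chunks).encode(), dtype=np.uint8)
        ].reshape(len(chunks), k)
        if revcomp:
            codes = np.where(codes <= 3, 3 - codes, codes)[:, ::-1]
        ok = (codes <= 3).all(axis=1)
        h = np.zeros(len(chunks), dtype=np.uint64)
        for j in range(k):
            h = (h << np.uint64(2)) | codes[:, j].astype(np.uint64)
        return h, ok

    def map_batch(self, reads: list[str]) -> list[tuple[int, int, int] | None]:
        """Map reads; each result is (contig_index, start, span_length) in
        extended-reference coordinates, or None if unmapped."""
        k = self.seed_k
        out: list[tuple[int, int, int] | None] = [None] * len(reads)
        if not reads or self._hashes.size == 0:
            return out
        usable = [i for i, r in enumerate(reads) if len(r) >= k]
        if not usable:
            return out
        for strand in ("fwd", "rev"):
            pending = [i for i in usable if out[i] is None]
            if not pending:
                break
            if strand == "fwd":
                chunks = [reads[i][:k] for i in pending]
            else:
                # seed of the reverse-complemented read = revcomp of the
                # read's last k bases
                chunks = [reads[i][-k:] for i in pending]
            seeds, ok = self._seed_hashes(chunks, k, revcomp=(strand == "rev"))
            lo = np.searchsorted(self._hashes, seeds, side="left")
            hi = np.searchsorted(self._hashes, seeds, side="right")
            for n_, i in enumerate(pending):
                if not ok[n_] or lo[n_] == hi[n_]:
                    continue
                query = reads[i] if strand == "fwd" else reverse_complement(reads[i])
                hit = self._verify(query, int(lo[n_]), int(hi[n_]))
                if hit is not None:
                    out[i] = (hit[0], hit[1], len(reads[i]))
        return out

    def fold_intervals(self, ci: int, placements: list[tuple[int, int]]) -> int:
        """Union of read intervals folded onto the circular core; returns
        covered base count."""
        core = self.contigs[ci].core_length
        ivals: list[tuple[int, int]] = []
        for s, span in placements:
            e = s + span
            if e <= core:
                ivals.append((s, e))
            else:
                ivals.append((s, core))
                ivals.append((0, min(e - core, core)))
        ivals.sort()
        covered = 0
        cur_s, cur_e = None, None
        for s, e in ivals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        return covered


def map_reads(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    contigs: list[Contig],
    read_length: int = 150,
    seed_k: int = 31,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map per-sample read sets onto a contig database.

    Returns a coverage-profile table (one row per contig x sample:
    read_count, covered_bases, length_bp, breadth) and per-sample unmapped
    read counts.  ``length_bp`` is the contig's circular core length where
    applicable, so breadth is a true fraction of genome positions.
    """
    index = ReferenceIndex(contigs, read_length=read_length, seed_k=seed_k)
    rows = []
    unmapped: dict[str, int] = {}
    for sample_id in reads_by_sample:
        pairs = reads_by_sample[sample_id]
        seqs = [seq for _, seq in pairs]
        hits = index.map_batch(seqs)
        unmapped[sample_id] = sum(1 for h in hits if h is None)
        placements: dict[int, list[tuple[int, int]]] = {}
        for h in hits:
            if h is None:
                continue
            ci, pos, span = h
            placements.setdefault(ci, []).append((pos, span))
        for ci, c in enumerate(index.contigs):
            pl = placements.get(ci, [])
            covered = index.fold_intervals(ci, pl) if pl else 0
            rows.append((c.contig_id, sample_id, len(pl), covered, c.core_length))
    profiles = pd.DataFrame(
        rows, columns=["contig_id", "sample_id", "read_count", "covered_bases", "length_bp"]
    )
    profiles["breadth"] = profiles["covered_bases"] / profiles["length_bp"]
    return profiles, unmapped


def coverage_from_sam(path, sample_id: str) -> pd.DataFrame:
    """Build the coverage-profile table from a SAM file (1-based POS; the
    reference span of each alignment is taken from its CIGAR blocks)."""
    rows: dict[str, list[tuple[int, int]]] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for aln in sam:
            if aln.is_unmapped:
                continue
            rows.setdefault(aln.reference_name, []).extend(aln.get_blocks())
    out = []
    for ref, length in lengths.items():
        ivals = sorted(rows.get(ref, []))
        covered, cur_s, cur_e = 0, None, None
        n_reads = 0
        for s, e in ivals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        # read count = number of alignments for this reference
        n_reads = len(rows.get(ref, []))
        out.append((ref, sample_id, n_reads, covered, length))
    profiles = pd.DataFrame(
        out, columns=["contig_id", "sample_id", "read_count", "covered_bases", "length_bp"]
    )
    profiles["breadth"] = profiles["covered_bases"] / profiles["length_bp"]
    return profiles


def breadth_threshold(length_bp: int) -> float:
    """Length-tiered minimum breadth of coverage for presence: 50% for
    contigs <5 kb, 30% for >=5 and <20 kb, 10% for >=20 kb."""
    if length_bp >= 20_000:
        return 0.10
    if length_bp >= 5_000:
        return 0.30
    return 0.50


def presence_filter(
    read_count: int, breadth: float, length_bp: int, min_reads: int = MIN_READS
) -> tuple[bool, int]:
    """Presence rule for one contig-sample pair: at least ``min_reads``
    mapped reads and breadth at or above the length tier; failing pairs
    record zero reads."""
    present = read_count >= min_reads and breadth >= breadth_threshold(length_bp)
    return present, read_count if present else 0


def count_table(
    profiles: pd.DataFrame,
    min_reads: int = MIN_READS,
    sample_order: list[str] | None = None,
) -> pd.DataFrame:
    """Apply the presence filter to a coverage-profile table and pivot to a
    contigs x samples count table (failing cells exactly 0)."""
    prof = profiles.copy()
    thr = prof["length_bp"].map(breadth_threshold)
    present = (prof["read_count"] >= min_reads) & (prof["breadth"] >= thr)
    prof["count"] = np.where(present, prof["read_count"], 0)
    table = prof.pivot_table(
        index="contig_id", columns="sample_id", values="count", fill_value=0, aggfunc="sum"
    ).astype(int)
    table.index.name = None
    table.columns.name = None
    if sample_order is not None:
        table = table.reindex(columns=sample_order, fill_value=0)
    return table.sort_index()


def aggregate_clusters(table: pd.DataFrame, cluster_map: pd.DataFrame) -> pd.DataFrame:
    """Sum contig counts within viral clusters; ambiguous and unclustered
    contigs become singleton rows keyed by their own contig_id.  Per-sample
    totals are conserved."""
    status = dict(zip(cluster_map["contig_id"], cluster_map["status"]))
    groups = []
    for cid in table.index:
        st = status.get(cid)
        if st is None:
            warnings.warn(f"{cid}: missing from cluster map; treated as unclustered")
            groups.append(cid)
        elif st.startswith("cluster:"):
            groups.append(st)
        else:  # ambiguous or unclustered -> singleton
            groups.append(cid)
    out = table.groupby(pd.Index(groups, name=None)).sum().sort_index()
    out.index.name = None
    return out


def marker_contamination_fraction(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    marker_sequences: dict[str, str],
    seed_k: int = 31,
) -> pd.Series:
    """Fraction of each sample's reads aligning to a marker-gene database
    (e.g. the bacterial housekeeping gene cpn60), an estimate of bacterial
    contamination in virome sequencing."""
    if not marker_sequences:
        raise ValueError("marker database is empty")
    marker_contigs = [Contig(k, s) for k, s in marker_sequences.items()]
    read_len = max(
        (len(seq) for pairs in reads_by_sample.values() for _, seq in pairs), default=150
    )
    index = ReferenceIndex(marker_contigs, read_length=read_len, seed_k=seed_k)
    out = {}
    for sample_id, pairs in reads_by_sample.items():
        if not pairs:
            warnings.warn(f"sample {sample_id}: no reads")
            out[sample_id] = 0.0
            continue
        hits = index.map_batch([seq for _, seq in pairs])
        out[sample_id] = sum(1 for h in hits if h is not None) / len(pairs)
    return pd.Series(out, name="marker_fraction")
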