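"""Best-stratum all-hit read placement with soft-clip rescue.

Mirrors the behaviour of a -v-mode short-read aligner reporting all
placements in the minimal-mismatch stratum (up to 2 mismatches, suppressed
above 50 placements), followed by the length-dependent mismatch filters used
for small-RNA data: reads under 20 nt tolerate no mismatch, reads of
20-40 nt at most one, and a mismatch at the final (3'-most) sequenced base is
disregarded, accommodating tRNA 3' CCA maturation and miRNA 3' tailing.
Reads that fail are retried after clipping 1-3 nt from the 3' end (then the
5' end) at a 1-mismatch budget; clipped placements only need a mapping
length of at least 17 nt.  Clipped bases are retained on the record — they
are the substrate for non-templated-addition calling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .simulate import revcomp

MAX_MISMATCH_FULL = 2
MAX_MISMATCH_CLIPPED = 1
MAX_HITS = 50
MAX_CLIP = 3
MIN_MAPPING_LENGTH = 17
SHORT_READ = 20       # reads below this tolerate no (effective) mismatch
MEDIUM_READ = 40      # reads up to this tolerate one

STATUS_MAPPED = "mapped"
STATUS_UNMAPPED = "unmapped"
STATUS_SUPPRESSED = "suppressed"


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    chrom: str
    start: int           # 0-based leftmost genome coordinate of aligned part
    strand: str
    mismatches: int      # last-base mismatches excluded
    clip5: int = 0
    clip3: int = 0
    clip5_seq: str = ""
    clip3_seq: str = ""
    length: int = 0      # mapping length (aligned bases)
    n_hits: int = 1      # placements in the best stratum

    @property
    def end(self) -> int:
        return self.start + self.length


class GenomeIndex:
    """Exact and <=2-mismatch lookup on both strands of a toy genome."""

    def __init__(self, genome: dict[str, str]):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._arrays = {
            c: np.frombuffer(s.encode(), dtype=np.uint8)
            for c, s in self.genome.items()}

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.genome[chrom][start:end]

    def _exact(self, query: str):
        """All exact placements of the oriented query; list of
        (chrom, start, strand, 0)."""
        hits = []
        rc = revcomp(query)
        for chrom, seq in self.genome.items():
            for pat, strand in ((query, "+"), (rc, "-")):
                i = seq.find(pat)
                while i != -1:
                    hits.append((chrom, i, strand, 0))
                    i = seq.find(pat, i + 1)
        return hits

    def _scan(self, query: str, max_mm: int):
        """All placements with <= max_mm substitutions (vectorised)."""
        hits = []
        q_fwd = np.frombuffer(query.encode(), dtype=np.uint8)
        q_rev = np.frombuffer(revcomp(query).encode(), dtype=np.uint8)
        L = len(query)
        for chrom, arr in self._arrays.items():
            if arr.size < L:
                continue
            windows = sliding_window_view(arr, L)
            for q, strand in ((q_fwd, "+"), (q_rev, "-")):
                mm = (windows != q).sum(axis=1)
                for i in np.nonzero(mm <= max_mm)[0]:
                    hits.append((chrom, int(i), strand, int(mm[i])))
        return hits

    def best_stratum(self, query: str, max_mm: int):
        """All placements in the minimal-mismatch stratum, or []."""
        hits = self._exact(query)
        if not hits:
            hits = self._scan(query, max_mm)
            if not hits:
                return []
            best = min(h[3] for h in hits)
            hits = [h for h in hits if h[3] == best]
        return sorted(hits, key=lambda h: (h[0], h[1], h[2]))


def _mismatch_profile(index: GenomeIndex, query: str, chrom: str, start: int,
                      strand: str):
    """(effective mismatches, raw mismatches) for one placement; a mismatch
    at the final sequenced base of the read does not count."""
    L = len(query)
    gslice = index.slice(chrom, start, start + L)
    oriented = query if strand == "+" else revcomp(query)
    raw = 0
    last_mismatch = False
    for j, (a, b) in enumerate(zip(oriented, gslice)):
        if a != b:
            raw += 1
            read_pos = j if strand == "+" else L - 1 - j
            if read_pos == L - 1:
                last_mismatch = True
    return raw - (1 if last_mismatch else 0), raw


def map_full(read_id: str, query: str, index: GenomeIndex):
    """Full-length placement.  Returns (status, records)."""
    hits = index.best_stratum(query, MAX_MISMATCH_FULL)
    if not hits:
        return STATUS_UNMAPPED, []
    if len(hits) > MAX_HITS:
        return STATUS_SUPPRESSED, []
    L = len(query)
    records = []
    for chrom, start, strand, _raw in hits:
        eff, raw = _mismatch_profile(index, query, chrom, start, strand)
        if L < SHORT_READ and eff >= 1:
            continue
        if SHORT_READ <= L <= MEDIUM_READ and eff >= 2:
            continue
        records.append(AlignmentRecord(read_id, chrom, start, strand, eff,
                                       length=L))
    if not records:
        return STATUS_UNMAPPED, []
    records = [replace(r, n_hits=len(records)) for r in records]
    return STATUS_MAPPED, records


def rescue_clip(read_id: str, query: str, index: GenomeIndex):
    """Recursive 1 nt soft clipping from the 3' end, then the 5' end, at a
    one-mismatch budget; stops at the first success.  Placements shorter
    than 17 aligned nt are discarded.  Returns (status, records)."""
    for end in ("3", "5"):
        for k in range(1, MAX_CLIP + 1):
            if end == "3":
                sub, clip5, clip3 = query[:-k], 0, k
                c5s, c3s = "", query[-k:]
            else:
                sub, clip5, clip3 = query[k:], k, 0
                c5s, c3s = query[:k], ""
            if len(sub) < MIN_MAPPING_LENGTH:
                break
            hits = index.best_stratum(sub, MAX_MISMATCH_CLIPPED)
            if not hits:
                continue
            if len(hits) > MAX_HITS:
                return STATUS_SUPPRESSED, []
            records = []
            for chrom, start, strand, _raw in hits:
                eff, raw = _mismatch_profile(index, sub, chrom, start, strand)
                records.append(AlignmentRecord(
                    read_id, chrom, start, strand, eff,
                    clip5=clip5, clip3=clip3, clip5_seq=c5s, clip3_seq=c3s,
                    length=len(sub), n_hits=len(hits)))
            return STATUS_MAPPED, records
    return STATUS_UNMAPPED, []


def map_read(read_id: str, query: str, index: GenomeIndex):
    """map_full with soft-clip rescue for reads it cannot place."""
    status, records = map_full(read_id, query, index)
    if status == STATUS_MAPPED or status == STATUS_SUPPRESSED:
        return status, records
    return rescue_clip(read_id, query, index)


@dataclass
class AlignedRead:
    """One read with its best-stratum placements (post filters)."""
    read_id: str
    cell: str
    umi: str
    insert: str
    records: list = field(default_factory=list)

    @property
    def primary(self) -> AlignmentRecord:
        return self.records[0]


def align_batch(fastq_path: str, cell: str, index: GenomeIndex):
    """Align one preprocessed per-cell FASTQ.

    Returns (aligned reads, tally) with tally conservation:
    mapped + unmapped + suppressed == input reads.
    """
    from .preprocess import iter_fastq, umi_from_read_id

    tally = {STATUS_MAPPED: 0, STATUS_UNMAPPED: 0, STATUS_SUPPRESSED: 0}
    out = []
    for rid, seq in iter_fastq(fastq_path):
        status, records = map_read(rid, seq, index)
        tally[status] += 1
        if status == STATUS_MAPPED:
            out.append(AlignedRead(rid, cell, umi_from_read_id(rid), seq,
                                   records))
    return out, tally


# ----------------------------------------------------------------- SAM I/O

def sam_header(index: GenomeIndex) -> dict:
    return {"HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(s)}
                   for c, s in sorted(index.genome.items())]}


def write_sam(aligned: list[AlignedRead], index: GenomeIndex,
              path: str) -> None:
    """One SAM record per retained placement; UMI in RX, effective mismatch
    count in NM, soft clips in the CIGAR."""
    import pysam

    refs = sorted(index.genome)
    ref_id = {c: i for i, c in enumerate(refs)}
    with pysam.AlignmentFile(path, "w", header=sam_header(index)) as fh:
        for ar in aligned:
            for i, rec in enumerate(ar.records):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = ar.read_id
                seq = ar.insert if rec.strand == "+" else revcomp(ar.insert)
                a.query_sequence = seq
                a.flag = (16 if rec.strand == "-" else 0) | \
                         (256 if i > 0 else 0)
                a.reference_id = ref_id[rec.chrom]
                a.reference_start = rec.start
                a.mapping_quality = 255
                # clips are given in read orientation; swap for minus strand
                c5, c3 = rec.clip5, rec.clip3
                left, right = (c5, c3) if rec.strand == "+" else (c3, c5)
                cigar = []
                if left:
                    cigar.append((4, left))
                cigar.append((0, rec.length))
                if right:
                    cigar.append((4, right))
                a.cigar = cigar
                a.set_tag("RX", ar.umi)
                a.set_tag("NM", rec.mismatches)
                a.set_tag("NH", rec.n_hits)
                a.set_tag("CB", ar.cell)
                fh.write(a)


def read_sam(path: str) -> list[AlignedRead]:
    """Inverse of :func:`write_sam` (groups placements per read id)."""
    import pysam

    from .preprocess import umi_from_read_id

    by_read: dict[str, AlignedRead] = {}
    with pysam.AlignmentFile(path, "r") as fh:
        for a in fh:
            strand = "-" if a.is_reverse else "+"
            seq = a.query_sequence
            insert = seq if strand == "+" else revcomp(seq)
            cig = a.cigartuples or []
            left = cig[0][1] if cig and cig[0][0] == 4 else 0
            right = cig[-1][1] if cig and cig[-1][0] == 4 else 0
            c5, c3 = (left, right) if strand == "+" else (right, left)
            L = sum(n for op, n in cig if op == 0)
            clip5_seq = insert[:c5] if c5 else ""
            clip3_seq = insert[-c3:] if c3 else ""
            rec = AlignmentRecord(
                a.query_name, a.reference_name, a.reference_start, strand,
                a.get_tag("NM"), clip5=c5, clip3=c3, clip5_seq=clip5_seq,
                clip3_seq=clip3_seq, length=L, n_hits=a.get_tag("NH"))
            ar = by_read.get(a.query_name)
            if ar is None:
                ar = AlignedRead(a.query_name, a.get_tag("CB"),
                                 umi_from_read_id(a.query_name), insert)
                by_read[a.query_name] = ar
            ar.records.append(rec)
    return list(by_read.values())
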