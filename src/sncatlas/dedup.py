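"""Directional UMI deduplication and molecule remapping.

Reads are grouped per cell by (chromosome, strand, template 5' position);
within a group, UMIs are clustered with the directional rule: a directed
edge runs from UMI a to UMI b when their Hamming distance is 1 and
count(a) >= 2 * count(b) - 1.  Each component reachable from a local count
maximum is one molecule; the highest-count UMI supplies the representative
read.  Representatives are then remapped through the same aligner to restore
multi-mapping information that deduplication collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignedRead, map_read, STATUS_MAPPED
from .config import UMI_LENGTH


@dataclass
class Molecule:
    cell: str
    read_id: str                 # representative read
    umi: str                     # representative (highest-count) UMI
    cluster: dict                # UMI -> read count over the cluster
    insert: str
    placements: list = field(default_factory=list)
    clip5_seq: str = ""
    clip3_seq: str = ""

    @property
    def cluster_size(self) -> int:
        return sum(self.cluster.values())


def _hamming1(a: str, b: str) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > 1:
                return False
    return mm == 1


def cluster_umis_directional(counts: dict[str, int]) -> list[dict[str, int]]:
    """Cluster a UMI multiset with the directional rule.

    Returns one dict per molecule (UMI -> count), highest-count seed first
    in each cluster's iteration order.  Seeds are processed by decreasing
    count (ties lexicographic), so a low-count UMI reachable from two maxima
    is captured by the higher-count one.
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    assigned: set[str] = set()
    clusters = []
    for seed in order:
        if seed in assigned:
            continue
        cluster = {seed: counts[seed]}
        assigned.add(seed)
        frontier = [seed]
        while frontier:
            nxt = []
            for a in frontier:
                for b in order:
                    if b in assigned:
                        continue
                    if _hamming1(a, b) and counts[a] >= 2 * counts[b] - 1:
                        cluster[b] = counts[b]
                        assigned.add(b)
                        nxt.append(b)
            frontier = sorted(nxt, key=lambda u: (-counts[u], u))
        clusters.append(cluster)
    return clusters


def _template_position(record) -> tuple[str, str, int]:
    """Grouping key: genomic 5' end of the template, compensating soft
    clips, as positional UMI grouping does."""
    if record.strand == "+":
        pos = record.start - record.clip5
    else:
        pos = record.end + record.clip5
    return record.chrom, record.strand, pos


def dedup_directional(aligned: list[AlignedRead],
                      cell: str) -> list[Molecule]:
    """Collapse one cell's aligned reads to molecules."""
    groups: dict[tuple, dict[str, list[AlignedRead]]] = {}
    for ar in aligned:
        if len(ar.umi) != UMI_LENGTH:
            raise ValueError(
                f"UMI length {len(ar.umi)} != {UMI_LENGTH} for {ar.read_id}")
        # multi-mapped reads group by their lexicographically first placement
        key = _template_position(ar.records[0])
        groups.setdefault(key, {}).setdefault(ar.umi, []).append(ar)
    molecules = []
    for key in sorted(groups):
        by_umi = groups[key]
        counts = {u: len(reads) for u, reads in by_umi.items()}
        for cluster in cluster_umis_directional(counts):
            seed = next(iter(cluster))
            rep = by_umi[seed][0]
            molecules.append(Molecule(
                cell=cell, read_id=rep.read_id, umi=seed, cluster=cluster,
                insert=rep.insert, placements=list(rep.records),
                clip5_seq=rep.primary.clip5_seq,
                clip3_seq=rep.primary.clip3_seq))
    return molecules


def remap_molecules(molecules: list[Molecule], index):
    """Re-run each representative insert through the aligner, replacing its
    placement set; molecules that no longer map are dropped with a tally."""
    kept = []
    dropped = 0
    for mol in molecules:
        status, records = map_read(mol.read_id, mol.insert, index)
        if status != STATUS_MAPPED:
            dropped += 1
            continue
        mol.placements = records
        mol.clip5_seq = records[0].clip5_seq
        mol.clip3_seq = records[0].clip3_seq
        kept.append(mol)
    return kept, dropped
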