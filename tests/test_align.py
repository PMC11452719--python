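"""Best-stratum alignment, mismatch filters and soft-clip rescue."""

import numpy as np
import pytest

from sncatlas.align import (GenomeIndex, STATUS_MAPPED, STATUS_SUPPRESSED,
                            STATUS_UNMAPPED, align_batch, map_full, map_read,
                            read_sam, rescue_clip, write_sam)
from sncatlas.simulate import revcomp

from oracles import oracle_map


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    return {"chrT": seq}, GenomeIndex({"chrT": seq})


def _mutate(seq, pos, base=None):
    old = seq[pos]
    new = base or {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
    return seq[:pos] + new + seq[pos + 1:]


def test_exact_hit_both_strands(toy):
    genome, index = toy
    q = genome["chrT"][100:122]
    status, recs = map_full("r", q, index)
    assert status == STATUS_MAPPED
    assert (recs[0].chrom, recs[0].start, recs[0].strand) == ("chrT", 100, "+")
    status, recs = map_full("r", revcomp(q), index)
    assert recs[0].strand == "-" and recs[0].start == 100


def test_absent_query_unmapped(toy):
    _, index = toy
    status, recs = map_full("r", "A" * 25, index)
    assert status == STATUS_UNMAPPED and recs == []


def test_short_read_one_mismatch_rejected(toy):
    """Reads under 20 nt tolerate no internal mismatch."""
    genome, index = toy
    q = _mutate(genome["chrT"][200:219], 8)
    status, _ = map_full("r", q, index)
    assert status == STATUS_UNMAPPED


def test_last_base_mismatch_forgiven(toy):
    """A 25 nt read with two mismatches, one at the final base, is kept
    with a recorded mismatch count of 1."""
    genome, index = toy
    q = _mutate(_mutate(genome["chrT"][300:325], 10), 24)
    status, recs = map_full("r", q, index)
    assert status == STATUS_MAPPED
    assert recs[0].mismatches == 1


def test_medium_read_two_internal_mismatches_rejected(toy):
    genome, index = toy
    q = _mutate(_mutate(genome["chrT"][300:325], 10), 15)
    status, _ = map_full("r", q, index)
    assert status == STATUS_UNMAPPED


def test_suppression_over_50_loci():
    unit = "ACGTTGCAACGTGGCTAGCTT"  # 21 nt, planted 51 times
    spacer = "C" * 5
    genome = {"chrR": spacer + (unit + spacer) * 51}
    index = GenomeIndex(genome)
    status, _ = map_full("r", unit, index)
    assert status == STATUS_SUPPRESSED


def test_clip_rescue_stops_at_first_success(toy):
    """Two non-genomic 3' bases: one clip plus the forgiven last-base
    mismatch already satisfies the 1-mismatch budget."""
    genome, index = toy
    junk = "".join("T" if genome["chrT"][422 + i] != "T" else "G"
                   for i in range(2))
    q = genome["chrT"][400:422] + junk
    status, recs = rescue_clip("r", q, index)
    assert status == STATUS_MAPPED
    assert recs[0].clip3 == 1 and recs[0].clip3_seq == q[-1:]
    assert recs[0].length == 23 and recs[0].mismatches == 0


def test_clip_rescue_three_junk_bases(toy):
    """Three non-genomic 3' bases need two clips (third forgiven)."""
    genome, index = toy
    junk = "".join("T" if genome["chrT"][422 + i] != "T" else "G"
                   for i in range(3))
    q = genome["chrT"][400:422] + junk
    status, recs = rescue_clip("r", q, index)
    assert status == STATUS_MAPPED
    assert recs[0].clip3 == 2 and recs[0].clip3_seq == q[-2:]


def test_clip_rescue_five_prime(toy):
    genome, index = toy
    base = genome["chrT"][500:522]
    # three 5' bases each mismatching the genome directly upstream
    junk = "".join("T" if genome["chrT"][497 + i] != "T" else "G"
                   for i in range(3))
    q = junk + base
    status, recs = map_read("r", q, index)
    assert status == STATUS_MAPPED
    assert recs[0].clip5 == 2 and recs[0].clip5_seq == q[:2]
    assert recs[0].start == 499


def test_clip_beyond_budget_unmapped(toy):
    """Clipping is capped at 3 nt per end; with the extra 1-mismatch
    budget, five non-genomic 3' bases can no longer be rescued."""
    genome, index = toy
    tail = "".join("T" if genome["chrT"][622 + i] != "T" else "G"
                   for i in range(5))
    q = genome["chrT"][600:622] + tail
    status, _ = map_read("r", q, index)
    assert status == STATUS_UNMAPPED


def test_clip_to_short_mapping_discarded(toy):
    """18 nt read whose rescue would need a mapping of 16 nt (< 17)."""
    genome, index = toy
    tail = "".join("T" if genome["chrT"][715 + i] != "T" else "G"
                   for i in range(3))
    q = genome["chrT"][700:715] + tail
    assert len(q) == 18
    status, _ = map_read("r", q, index)
    assert status == STATUS_UNMAPPED


def test_oracle_equivalence_quick(toy):
    """Implementation vs brute-force enumerator on random/mutated reads."""
    genome, index = toy
    rng = np.random.default_rng(0)
    seq = genome["chrT"]
    reads = []
    for _ in range(60):
        L = int(rng.integers(18, 40))
        pos = int(rng.integers(0, len(seq) - L))
        r = seq[pos:pos + L]
        for npos in rng.integers(0, L, size=int(rng.integers(0, 3))):
            r = _mutate(r, int(npos))
        if rng.random() < 0.3:
            r = r + "".join(rng.choice(list("ACGT"),
                                       size=int(rng.integers(1, 5))))
        if rng.random() < 0.5:
            r = revcomp(r)
        reads.append(r)
    reads += ["".join(rng.choice(list("ACGT"), size=25)) for _ in range(20)]
    for r in reads:
        status, recs = map_read("x", r, index)
        o_status, o_hits = oracle_map(r, genome)
        assert status == o_status, r
        got = sorted((p.chrom, p.start, p.strand, p.mismatches, p.clip5,
                      p.clip3) for p in recs)
        assert got == o_hits, r


def test_strand_symmetry(toy):
    """Reverse-complementing genome and read mirrors the coordinates."""
    genome, index = toy
    seq = genome["chrT"]
    flipped = GenomeIndex({"chrT": revcomp(seq)})
    q = _mutate(seq[800:828], 12)
    _, recs = map_full("r", q, index)
    _, recs_f = map_full("r", revcomp(q), flipped)
    assert len(recs) == len(recs_f)
    for a, b in zip(recs, recs_f):
        assert b.start == len(seq) - a.end
        assert a.mismatches == b.mismatches


def test_align_batch_tally_and_sam_roundtrip(tmp_path, toy):
    genome, index = toy
    seq = genome["chrT"]
    fq = tmp_path / "cell.fastq"
    reads = {
        "good_AAAACCCC": seq[900:925],
        "minus_GGGGTTTT": revcomp(seq[950:975]),
        "bad_CCCCAAAA": "ACGT" * 7,
    }
    with open(fq, "w") as fh:
        for rid, s in reads.items():
            fh.write(f"@{rid}\n{s}\n+\n{'I' * len(s)}\n")
    aligned, tally = align_batch(str(fq), "cellX", index)
    assert sum(tally.values()) == 3
    assert tally[STATUS_MAPPED] == 2

    sam = tmp_path / "cell.sam"
    write_sam(aligned, index, str(sam))
    back = read_sam(str(sam))
    assert {a.read_id for a in back} == {a.read_id for a in aligned}
    orig = {a.read_id: a for a in aligned}
    for a in back:
        o = orig[a.read_id]
        assert a.umi == o.umi and a.insert == o.insert
        assert [(r.chrom, r.start, r.strand, r.clip5, r.clip3)
                for r in a.records] == \
               [(r.chrom, r.start, r.strand, r.clip5, r.clip3)
                for r in o.records]


def test_empty_fastq_valid_sam(tmp_path, toy):
    _, index = toy
    fq = tmp_path / "empty.fastq"
    fq.write_text("")
    aligned, tally = align_batch(str(fq), "c", index)
    assert aligned == [] and sum(tally.values()) == 0
    sam = tmp_path / "empty.sam"
    write_sam(aligned, index, str(sam))
    text = sam.read_text()
    assert text.startswith("@HD")


def test_planted_reads_map_to_their_locus(pipeline_result, truth):
    """Error-free collision-free simulation: every molecule's placement
    starts within the planted templated span."""
    planted = truth.set_index("molecule_id")
    for mol in pipeline_result.molecules:
        row = planted.loc[mol.read_id.rsplit("_", 1)[0].rsplit(".", 1)[0]]
        hits = [(p.chrom, p.start, p.strand) for p in mol.placements]
        assert (row["chrom"], row["start"], row["strand"]) in hits or \
               any(p.chrom == row["chrom"] and
                   abs(p.start - row["start"]) <= 3 for p in mol.placements)
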