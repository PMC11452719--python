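"""Synthetic Small-seq data with planted molecular ground truth.

The simulator builds a toy genome with planted small-RNA features, draws
per-cell molecules from a day-dependent biotype mixture with lineage-specific
marker miRNAs, decorates miRNA molecules with end shifts and non-templated 3'
additions (NTAs) and tRNA molecules with fragment classes, and renders
Small-seq-structured FASTQ (8 nt UMI + 2 filler bases + insert + adapter +
poly(A) padding, PCR duplicates sharing the UMI).  Every planted molecule is
recorded in a truth table so each downstream pipeline stage can be checked
exactly.

Planted NTA bases are guaranteed to mismatch the genome at their implied
positions (adenosine where possible, the dominant addition in vivo), so an
error-free run is fully recoverable by sequence comparison.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .annotate import AnnotationRecord, AnnotationSet
from .config import (AMINO_ACIDS, ANTICODONS, CATCHALL_TRACKS, FILLER,
                     ConfigurationError, SimulationConfig, SizingError)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oriented_slice(genome: dict[str, str], chrom: str, start: int, end: int,
                   strand: str) -> str:
    s = genome[chrom][start:end]
    return s if strand == "+" else revcomp(s)


# ------------------------------------------------------------------ reference

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _dangerous_adapter_patterns(adapter: str) -> list[tuple[str, int]]:
    """(pattern, mismatch budget) pairs a random genome must avoid.

    A transcript 3' end that looks like the adapter — or like an adapter
    prefix whose continuation into the real, ligated adapter still matches
    the adapter within the 10% trimming budget — would be trimmed into the
    insert.  The dangerous prefixes follow from the adapter's self-overlap
    distances; prefixes completed by planted poly-A additions are included.
    """
    L = len(adapter)
    budget = int(0.1 * L)
    pats = [(adapter, budget)]
    for g in range(3, L):
        d = sum(a != b for a, b in zip(adapter[g:], adapter[:L - g]))
        if d <= budget:
            pats.append((adapter[:g], budget - d))
            for j in (1, 2, 3):
                if g - j >= 3 and adapter[g - j:g] == "A" * j:
                    pats.append((adapter[:g - j], budget - d))
    return pats


def _scrub_adapter(seq: str, adapter: str) -> str:
    """Rewrite genome windows that could forge an adapter match during
    trimming (either orientation), so inserts never mimic the adapter."""
    adapter = adapter.upper()
    pats = []
    for pat, mm_budget in _dangerous_adapter_patterns(adapter):
        pats.append((pat, mm_budget))
        pats.append((revcomp(pat), mm_budget))
    out = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    changed = True
    while changed:
        changed = False
        for pat, mm_budget in pats:
            L = len(pat)
            if out.size < L:
                continue
            win = sliding_window_view(out, L)
            p = np.frombuffer(pat.encode(), dtype=np.uint8)
            mm = (win != p).sum(axis=1)
            for i in np.nonzero(mm <= mm_budget)[0]:
                for off in range(0, L, max(L // (mm_budget + 2), 1)):
                    want = chr(p[off])
                    out[i + off] = ord("C" if want != "C" else "G")
                changed = True
    return out.tobytes().decode()


def build_reference(config: SimulationConfig):
    """Random genome with planted, non-overlapping features per biotype.

    Returns ``(genome, annotations)`` where genome maps chromosome name to
    sequence.  Mature miRNAs are nested inside hairpin records; tRNAs carry
    an amino-acid/anticodon label.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    plan: list[tuple[str, int, str | None]] = []  # (biotype, length, label)
    hp_len = config.mirna_mature_length + 48
    for i in range(config.n_mirna):
        plan.append(("miRNA_primary", hp_len, None))
    for i in range(config.n_rrna):
        plan.append(("rRNA", 150, None))
    for i in range(config.n_snorna):
        plan.append(("snoRNA", 90, None))
    for i in range(config.n_snrna):
        plan.append(("snRNA", 110, None))
    for i in range(config.n_trna):
        aa = AMINO_ACIDS[i % len(AMINO_ACIDS)]
        ac = ANTICODONS[i % len(ANTICODONS)]
        plan.append(("tRNA", config.trna_length, f"{aa}:{ac}"))
    lo, hi = config.pirna_length_range
    for i in range(config.n_pirna):
        L = int(np.clip(round(rng.normal(config.pirna_length_mode, 1.5)), lo, hi))
        plan.append(("piRNA", L, None))
    for i in range(config.n_protein_coding):
        plan.append(("protein_coding", 300, None))
    for i in range(config.n_lncrna):
        plan.append(("lncRNA", 250, None))
    for i in range(config.n_repeat):
        plan.append(("repeat", 120, None))
    for i in range(config.n_pseudogene):
        plan.append(("pseudogene", 200, None))

    total = sum(L for _, L, _ in plan)
    min_gap = 12
    need = total + min_gap * (len(plan) + 1)
    if need > config.genome_length:
        raise SizingError(
            f"genome_length={config.genome_length} too short for planted "
            f"features (need >= {need})")

    chrom = "chr1"
    seq = list(_scrub_adapter(_random_seq(rng, config.genome_length),
                              config.adapter_sequence))
    ann = AnnotationSet()
    slack = config.genome_length - total - min_gap * (len(plan) + 1)
    gaps = rng.multinomial(slack, np.ones(len(plan) + 1) / (len(plan) + 1))
    pos = min_gap + int(gaps[0])
    counters: dict[str, int] = {}
    repeat_seq: str | None = None
    for i, (biotype, L, label) in enumerate(plan):
        strand = "+" if rng.random() < 0.5 else "-"
        idx = counters.get(biotype, 0)
        counters[biotype] = idx + 1
        start, end = pos, pos + L
        if biotype == "repeat" and config.duplicate_repeat:
            # identical copies so repeat-derived reads multi-map
            if repeat_seq is None:
                repeat_seq = "".join(seq[start:end])
            else:
                seq[start:end] = list(repeat_seq)
            strand = "+"
        if biotype == "miRNA_primary":
            name = f"hairpin-{idx:02d}"
            ann.add(AnnotationRecord("miRNA_primary", chrom, start, end,
                                     strand, name))
            # mature product 10 nt inside the hairpin 5' end
            off = 10
            if strand == "+":
                ms, me = start + off, start + off + config.mirna_mature_length
            else:
                me = end - off
                ms = me - config.mirna_mature_length
            ann.add(AnnotationRecord("miRNA", chrom, ms, me, strand,
                                     f"mir-{idx:02d}", parent=name))
        else:
            prefix = {"rRNA": "rrna", "snoRNA": "snord", "snRNA": "snrna",
                      "tRNA": "trna", "piRNA": "pirna",
                      "protein_coding": "gene", "lncRNA": "lnc",
                      "repeat": "rep", "pseudogene": "pseudo"}[biotype]
            ann.add(AnnotationRecord(biotype, chrom, start, end, strand,
                                     f"{prefix}-{idx:02d}", label=label))
        pos = end + min_gap + int(gaps[i + 1])

    genome = {chrom: "".join(seq)}
    if config.n_mt_trna > 0:
        mt = _scrub_adapter(_random_seq(rng, config.chrm_length),
                            config.adapter_sequence)
        genome["chrM"] = mt
        span = config.chrm_length // (config.n_mt_trna + 1)
        for i in range(config.n_mt_trna):
            start = span * i + 50
            end = start + config.trna_length
            if end > config.chrm_length:
                raise SizingError("chrm_length too short for mt-tRNAs")
            aa = AMINO_ACIDS[i % len(AMINO_ACIDS)]
            ac = ANTICODONS[i % len(ANTICODONS)]
            ann.add(AnnotationRecord("tRNA", "chrM", start, end, "+",
                                     f"mt-trna-{i:02d}", label=f"{aa}:{ac}"))
    return genome, ann


def marker_assignments(config: SimulationConfig,
                       annotations: AnnotationSet) -> dict[str, list[str]]:
    """Lineage -> designated marker miRNA names (disjoint blocks)."""
    mirnas = sorted(r.name for r in annotations.by_biotype("miRNA"))
    out: dict[str, list[str]] = {}
    k = config.n_markers_per_lineage
    targets = [ln for ln in config.lineages if ln != "pre-lineage"]
    for j, lineage in enumerate(targets):
        out[lineage] = mirnas[j * k:(j + 1) * k]
    return out


# ------------------------------------------------------------------ cells

def assign_cells(config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell metadata: day, lineage, batch, simulated sequencing depth."""
    rows = []
    # the first two days of a multi-day design precede lineage segregation
    pre_days = set(config.days[:2]) if len(config.days) > 2 else set()
    post_lineages = [ln for ln in config.lineages if ln != "pre-lineage"]
    for i in range(config.n_cells):
        day = config.days[i % len(config.days)]
        if day in pre_days or not post_lineages:
            lineage = "pre-lineage"
        else:
            lineage = post_lineages[(i // len(config.days)) % len(post_lineages)]
        depth = max(1, int(rng.normal(config.mean_sequenced_reads,
                                      0.1 * config.mean_sequenced_reads)))
        rows.append({"cell": f"cell{i:03d}", "day": day, "lineage": lineage,
                     "batch": f"batch{i % config.n_batches}",
                     "sequenced_reads": depth})
    return pd.DataFrame(rows, columns=["cell", "day", "lineage", "batch",
                                       "sequenced_reads"])


# ------------------------------------------------------------------ UMIs

def _code_umi(index: int) -> str:
    """Single-substitution-detecting UMI: 7 base-4 digits plus a checksum
    digit, so any two codewords differ at >= 2 positions."""
    digits = [(index >> (2 * k)) & 3 for k in range(7)]
    digits.append(sum(digits) % 4)
    return "".join(BASES[d] for d in digits)


# ------------------------------------------------------------------ molecules

def _draw_from(rng, probs: dict) -> object:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _nta_bases(genome, chrom, strand, templated_end_coord, length) -> str:
    """NTA string of ``length`` bases, each guaranteed to mismatch the genome
    base it would occupy if templated; adenosine preferred."""
    out = []
    for j in range(length):
        if strand == "+":
            g = genome[chrom][templated_end_coord + j]
        else:
            g = revcomp(genome[chrom][templated_end_coord - 1 - j])
        out.append("A" if g != "A" else "C")
    return "".join(out)


def simulate_molecules(config: SimulationConfig, genome: dict[str, str],
                       annotations: AnnotationSet) -> pd.DataFrame:
    """Draw the per-cell molecular ground truth table.

    One row per planted molecule, carrying its feature, templated genomic
    span, insert sequence, isomiR shifts / NTA string / tRF class where
    applicable, UMI, and PCR copy number.
    """
    rng = np.random.default_rng(config.seed + 1)
    cells = assign_cells(config, rng)
    markers = marker_assignments(config, annotations)

    by_bt = {bt: sorted(annotations.by_biotype(bt), key=lambda r: r.name)
             for bt in ["miRNA", "rRNA", "snoRNA", "snRNA", "piRNA"]}
    trnas = sorted([r for r in annotations.by_biotype("tRNA")
                    if r.chrom != "chrM"], key=lambda r: r.name)
    mt_trnas = sorted([r for r in annotations.by_biotype("tRNA")
                       if r.chrom == "chrM"], key=lambda r: r.name)
    catchall = {t: sorted(annotations.by_biotype(t), key=lambda r: r.name)
                for t in CATCHALL_TRACKS}
    for bt, recs in {**by_bt, "tRNA": trnas}.items():
        if not recs:
            raise ConfigurationError(
                f"no planted features for requested biotype {bt}")

    rows = []
    for _, cell_row in cells.iterrows():
        cell, day, lineage = cell_row["cell"], cell_row["day"], cell_row["lineage"]
        mix = config.day_mixture(day)
        if not mt_trnas:
            mix = {k: v for k, v in mix.items() if k != "mito"}
            tot = sum(mix.values())
            mix = {k: v / tot for k, v in mix.items()}
        mirna_recs = by_bt["miRNA"]
        w = np.ones(len(mirna_recs))
        boost = 2.0 ** config.marker_log2fc
        for i, rec in enumerate(mirna_recs):
            for ln, names in markers.items():
                if rec.name in names and lineage == ln:
                    w[i] = boost
        w = w / w.sum()

        umi_counter = 0
        for mi in range(config.n_molecules_per_cell):
            biotype = _draw_from(rng, mix)
            mito = biotype == "mito"
            row = {"cell": cell, "molecule_id": f"{cell}:m{mi:05d}",
                   "shift5": 0, "shift3": 0, "nta": "", "trf_class": "",
                   "mito": mito}
            if biotype == "miRNA":
                rec = mirna_recs[rng.choice(len(mirna_recs), p=w)]
                row.update(_mirna_molecule(config, rng, genome, rec))
            elif biotype in ("tRNA", "mito"):
                recs = mt_trnas if mito else trnas
                rec = _pick_trna(config, rng, recs, day)
                row.update(_trna_molecule(config, rng, genome, rec))
            elif biotype == "piRNA":
                rec = by_bt["piRNA"][rng.integers(len(by_bt["piRNA"]))]
                row.update({
                    "biotype": "piRNA", "feature": rec.name,
                    "chrom": rec.chrom, "strand": rec.strand,
                    "start": rec.start, "end": rec.end,
                    "insert": oriented_slice(genome, rec.chrom, rec.start,
                                             rec.end, rec.strand)})
            elif biotype == "other":
                track = CATCHALL_TRACKS[rng.integers(len(CATCHALL_TRACKS))]
                recs = catchall[track]
                if not recs:
                    raise ConfigurationError(f"no features for track {track}")
                rec = recs[rng.integers(len(recs))]
                row.update(_fragment(rng, genome, rec, (18, 30)))
            else:
                rec = by_bt[biotype][rng.integers(len(by_bt[biotype]))]
                row.update(_fragment(rng, genome, rec,
                                     config.fragment_length_range))
            if config.collision_free_umis:
                row["umi"] = _code_umi(umi_counter)
                umi_counter += 1
            else:
                row["umi"] = _random_seq(rng, config.umi_length)
            row["pcr_copies"] = 1 + int(rng.poisson(config.pcr_duplication_rate))
            rows.append(row)

    truth = pd.DataFrame(rows)
    if truth.empty:
        truth = pd.DataFrame(columns=[
            "cell", "molecule_id", "biotype", "feature", "chrom", "strand",
            "start", "end", "insert", "shift5", "shift3", "nta", "trf_class",
            "mito", "umi", "pcr_copies"])
    truth.attrs["cells"] = cells
    return truth


def _mirna_molecule(config, rng, genome, rec) -> dict:
    min_len = 18
    while True:
        s5 = _draw_from(rng, config.shift5_probs)
        s3 = _draw_from(rng, config.shift3_probs)
        if rec.length + s5 + s3 >= min_len:
            break
    if rec.strand == "+":
        start, end = rec.start - s5, rec.end + s3
    else:
        start, end = rec.start - s3, rec.end + s5
    insert = oriented_slice(genome, rec.chrom, start, end, rec.strand)
    nta = ""
    if rng.random() < config.nta_rate:
        k = _draw_from(rng, config.nta_length_probs)
        t3 = end if rec.strand == "+" else start
        nta = _nta_bases(genome, rec.chrom, rec.strand, t3, k)
        insert += nta
    return {"biotype": "miRNA", "feature": rec.name, "chrom": rec.chrom,
            "strand": rec.strand, "start": start, "end": end,
            "insert": insert, "shift5": s5, "shift3": s3, "nta": nta}


def _pick_trna(config, rng, recs, day):
    if config.trna_aa_day_weights is None:
        return recs[rng.integers(len(recs))]
    weights = config.trna_aa_day_weights.get(day, {})
    w = np.array([weights.get((r.label or "").split(":")[0], 1.0)
                  for r in recs], dtype=float)
    return recs[rng.choice(len(recs), p=w / w.sum())]


def _trna_molecule(config, rng, genome, rec) -> dict:
    klass = _draw_from(rng, config.trf_class_mix)
    gene_len = rec.length
    if klass == "five_prime_half":
        a = int(rng.integers(0, 4))           # read starts a nt inside
        L = int(rng.integers(28, 45))
        start_in, end_in = a, a + L
    elif klass == "three_prime_half":
        b = int(rng.integers(0, 4))           # read ends b nt inside
        L = int(rng.integers(28, 45))
        end_in = gene_len - b
        start_in = end_in - L
    else:
        a = int(rng.integers(0, 4))
        b = int(rng.integers(0, 4))
        start_in, end_in = a, gene_len - b
    s5, s3 = -start_in, end_in - gene_len
    if rec.strand == "+":
        start, end = rec.start + start_in, rec.start + end_in
    else:
        start, end = rec.end - end_in, rec.end - start_in
    insert = oriented_slice(genome, rec.chrom, start, end, rec.strand)
    nta = ""
    if config.add_cca and end_in == gene_len:
        t3 = end if rec.strand == "+" else start
        cca = _nta_bases(genome, rec.chrom, rec.strand, t3, 3)
        nta = cca
        insert += cca
    return {"biotype": "tRNA", "feature": rec.name, "chrom": rec.chrom,
            "strand": rec.strand, "start": start, "end": end,
            "insert": insert, "shift5": s5, "shift3": s3,
            "trf_class": klass, "nta": nta}


def _fragment(rng, genome, rec, length_range) -> dict:
    lo, hi = length_range
    L = int(rng.integers(lo, hi + 1))
    L = min(L, rec.length)
    off = int(rng.integers(0, rec.length - L + 1))
    if rec.strand == "+":
        start, end = rec.start + off, rec.start + off + L
    else:
        start, end = rec.end - off - L, rec.end - off
    return {"biotype": rec.biotype, "feature": rec.name, "chrom": rec.chrom,
            "strand": rec.strand, "start": start, "end": end,
            "insert": oriented_slice(genome, rec.chrom, start, end,
                                     rec.strand)}


# ------------------------------------------------------------------ reads

def _with_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def render_reads(truth: pd.DataFrame, genome: dict[str, str],
                 config: SimulationConfig, outdir: str) -> pd.DataFrame:
    """Write per-cell FASTQ and return the truth table with a ``truncated``
    column marking molecules whose insert or minimum tail did not fit the
    read-length budget.

    Each read is UMI + 2 filler bases + insert (with per-copy substitution
    errors) + adapter + poly(A) padding; PCR copies share UMI and insert.
    """
    rng = np.random.default_rng(config.seed + 2)
    os.makedirs(os.path.join(outdir, "reads"), exist_ok=True)
    truth = truth.copy()
    head = config.umi_length + len(FILLER)
    truncated = []
    cells = truth.attrs.get("cells")
    cell_ids = list(cells["cell"]) if cells is not None else \
        sorted(truth["cell"].unique())
    handles = {}
    try:
        for cell in cell_ids:
            handles[cell] = open(
                os.path.join(outdir, "reads", f"{cell}.fastq"), "w")
        for _, row in truth.iterrows():
            insert = row["insert"]
            full = head + len(insert)
            trunc = full + 10 > config.read_length
            truncated.append(trunc)
            fh = handles[row["cell"]]
            for c in range(int(row["pcr_copies"])):
                ins = _with_errors(rng, insert, config.seq_error_rate)
                read = row["umi"] + FILLER + ins + config.adapter_sequence
                if len(read) < config.read_length:
                    read += "A" * (config.read_length - len(read))
                read = read[:config.read_length]
                rid = f"{row['molecule_id']}.c{c}"
                fh.write(f"@{rid}\n{read}\n+\n{'I' * len(read)}\n")
    finally:
        for fh in handles.values():
            fh.close()
    truth["truncated"] = truncated if len(truth) else \
        pd.Series([], dtype=bool)
    return truth


# ------------------------------------------------------------------ dataset

def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fasta(genome: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")}


def emit_dataset(config: SimulationConfig, outdir: str) -> dict:
    """Write the complete synthetic dataset and a checksum manifest."""
    os.makedirs(outdir, exist_ok=True)
    genome, ann = build_reference(config)
    truth = simulate_molecules(config, genome, ann)
    cells = truth.attrs["cells"]
    truth = render_reads(truth, genome, config, outdir)

    write_fasta(genome, os.path.join(outdir, "genome.fa"))
    ann.to_gff3(os.path.join(outdir, "annotations.gff3"))
    ann.to_bed(os.path.join(outdir, "annotations.bed"))
    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    cells.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)

    mirnas = sorted(r.name for r in ann.by_biotype("miRNA"))
    pairs = pd.DataFrame([
        {"mirna": m, "gene": f"GENE{j:03d}-{m}"}
        for m in mirnas for j in range(3)])
    pairs.to_csv(os.path.join(outdir, "target_pairs.tsv"), sep="\t",
                 index=False)
    novel_candidate_grid().to_csv(
        os.path.join(outdir, "novel_candidates.tsv"), sep="\t", index=False)

    files = ["genome.fa", "annotations.gff3", "annotations.bed", "truth.tsv",
             "cells.tsv", "target_pairs.tsv", "novel_candidates.tsv"]
    files += [os.path.join("reads", f"{c}.fastq") for c in cells["cell"]]
    manifest = {
        "seed": config.seed,
        "n_cells": config.n_cells,
        "files": {f: _sha256(os.path.join(outdir, f)) for f in files},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ----------------------------------------------------- statistical fixtures

def simulate_null_counts(seed: int, n_cells: int = 100, n_features: int = 2000,
                         nb_mean: float = 5.0, nb_size: float = 10.0):
    """Two same-law negative-binomial groups (no signal)."""
    rng = np.random.default_rng(seed)
    p = nb_size / (nb_size + nb_mean)
    counts = rng.negative_binomial(nb_size, p, size=(n_cells, n_features))
    cells = [f"c{i:03d}" for i in range(n_cells)]
    feats = [f"f{j:04d}" for j in range(n_features)]
    groups = pd.Series(["A"] * (n_cells // 2) + ["B"] * (n_cells - n_cells // 2),
                       index=cells)
    return pd.DataFrame(counts, index=cells, columns=feats), groups


def simulate_de_counts(seed: int, n_cells: int = 100, n_features: int = 2000,
                       n_de: int = 100, log2fc: float = 1.0,
                       nb_mean: float = 5.0, nb_size: float = 10.0):
    """Negative-binomial counts with the first ``n_de`` features shifted by
    ``log2fc`` in group B."""
    counts, groups = simulate_null_counts(seed, n_cells, n_features,
                                          nb_mean, nb_size)
    rng = np.random.default_rng(seed + 1)
    b_cells = groups[groups == "B"].index
    mean_alt = nb_mean * 2.0 ** log2fc
    p_alt = nb_size / (nb_size + mean_alt)
    alt = rng.negative_binomial(nb_size, p_alt,
                                size=(len(b_cells), n_de))
    counts.loc[b_cells, counts.columns[:n_de]] = alt
    return counts, groups, list(counts.columns[:n_de])


def simulate_pseudobulk_pairs(seed: int, n_pairs: int = 1000,
                              n_planted: int = 50, n_groups: int = 10,
                              rho: float = -0.95):
    """Pseudobulk miRNA/gene profiles for candidate pairs; the first
    ``n_planted`` pairs share a latent profile at correlation ``rho``."""
    rng = np.random.default_rng(seed)
    groups = [f"g{i}" for i in range(n_groups)]
    mirna = {}
    gene = {}
    planted = []
    rows = []
    for i in range(n_pairs):
        m, g = f"mir{i:04d}", f"gene{i:04d}"
        x = rng.normal(size=n_groups)
        if i < n_planted:
            s = abs(rho)
            noise = rng.normal(size=n_groups)
            y = np.sign(rho) * (s * x + np.sqrt(1 - s * s) * noise)
            planted.append((m, g))
        else:
            y = rng.normal(size=n_groups)
        mirna[m] = x
        gene[g] = y
        rows.append({"mirna": m, "gene": g})
    return (pd.DataFrame(mirna, index=groups),
            pd.DataFrame(gene, index=groups),
            pd.DataFrame(rows), planted)


def simulate_trajectory_data(seed: int, n_cells: int = 200, n_mirnas: int = 50,
                             n_assoc: int = 10, slope: float = 1.0,
                             noise_sd: float = 0.5, n_batches: int = 2):
    """Log-scale expression with the first ``n_assoc`` miRNAs linear in
    pseudotime plus an additive batch offset."""
    rng = np.random.default_rng(seed)
    cells = [f"c{i:03d}" for i in range(n_cells)]
    pseudotime = pd.Series(rng.uniform(0, 10, n_cells), index=cells)
    batch = pd.Series([f"b{i % n_batches}" for i in range(n_cells)],
                      index=cells)
    offs = {f"b{k}": rng.normal(0, 0.3) for k in range(n_batches)}
    data = {}
    names = [f"mir{j:03d}" for j in range(n_mirnas)]
    for j, name in enumerate(names):
        base = rng.normal(2, 0.5)
        mu = base + (slope * pseudotime.values if j < n_assoc else 0.0)
        mu = mu + batch.map(offs).values
        data[name] = mu + rng.normal(0, noise_sd, n_cells)
    return pd.DataFrame(data, index=cells), pseudotime, batch, names[:n_assoc]


def make_pattern_profiles(seed: int, n_per_class: int = 5, n_bins: int = 20):
    """Binned expression profiles with known transient / rising / falling
    shapes, keyed C1 (low-high-low), C2 (low-high), C3 (high-low)."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, n_bins)
    rows, labels = {}, {}
    for i in range(n_per_class):
        noise = lambda: rng.normal(0, 0.05, n_bins)
        rows[f"peak{i}"] = np.exp(-((x - 0.5) ** 2) / 0.02) + noise()
        labels[f"peak{i}"] = "C1"
        rows[f"up{i}"] = x + noise()
        labels[f"up{i}"] = "C2"
        rows[f"down{i}"] = 1 - x + noise()
        labels[f"down{i}"] = "C3"
    return pd.DataFrame(rows).T, labels


def novel_candidate_grid() -> pd.DataFrame:
    """16-row candidate table covering every pass/fail combination of the
    four novel-miRNA selection criteria."""
    rows = []
    for bits in range(16):
        randfold = bool(bits & 1)
        score_ok = bool(bits & 2)
        batches_ok = bool(bits & 4)
        support_ok = bool(bits & 8)
        n_cells = 35 if support_ok else 12
        if support_ok:
            # 40 reads, 36 in 20-25 nt (90%)
            lens = [22] * 36 + [48] * 4
        else:
            lens = [22] * 10 + [48] * 30
        per_cell = []
        for ci in range(n_cells):
            chunk = lens[ci::n_cells]
            if chunk:
                per_cell.append(
                    f"cell{ci:02d}:" + ",".join(str(v) for v in chunk))
        rows.append({
            "candidate_id": f"cand{bits:02d}",
            "significant_randfold": "yes" if randfold else "no",
            "mirdeep_score": 3.5 if score_ok else -0.5,
            "expressed_in": "batch0;batch1" if batches_ok else "batch0",
            "read_lengths_by_cell": ";".join(per_cell),
        })
    return pd.DataFrame(rows)
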