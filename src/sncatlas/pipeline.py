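"""End-to-end driver: FASTQ -> molecules -> annotated count matrices.

Chains UMI extraction and trimming, best-stratum alignment with soft-clip
rescue, directional UMI deduplication with remapping, and hierarchical
biotype assignment, per cell, over a dataset directory produced by
:func:`sncatlas.simulate.emit_dataset` (or any directory with the same
layout).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignedRead, GenomeIndex, STATUS_MAPPED, map_read
from .annotate import AnnotationSet, assign_all, build_count_matrices, load_gff3
from .config import SimulationConfig
from .dedup import dedup_directional, remap_molecules
from .preprocess import TrimReport, iter_fastq, preprocess_read
from .simulate import read_fasta


@dataclass
class PipelineResult:
    molecules: list
    assigned: list
    matrices: dict
    proportions: pd.DataFrame
    length_hists: dict
    cell_stats: pd.DataFrame
    trim_reports: dict = field(default_factory=dict)
    align_tallies: dict = field(default_factory=dict)
    dedup_dropped: dict = field(default_factory=dict)


def process_cell(fastq_path: str, cell: str, adapter: str,
                 index: GenomeIndex):
    """Preprocess + align + dedup + remap one cell's raw FASTQ."""
    report = TrimReport()
    aligned = []
    tally = {"mapped": 0, "unmapped": 0, "suppressed": 0}
    for rid, seq in iter_fastq(fastq_path):
        trimmed, reason = preprocess_read(rid, seq, adapter)
        if trimmed is None:
            report.discarded[reason] += 1
            continue
        report.kept += 1
        status, records = map_read(trimmed.read_id, trimmed.insert, index)
        tally[status] += 1
        if status == STATUS_MAPPED:
            aligned.append(AlignedRead(trimmed.read_id, cell, trimmed.umi,
                                       trimmed.insert, records))
    molecules = dedup_directional(aligned, cell)
    molecules, dropped = remap_molecules(molecules, index)
    return molecules, report, tally, dropped


def run_pipeline(dataset_dir: str,
                 adapter: str | None = None) -> PipelineResult:
    """Run the full quantification over a dataset directory."""
    if adapter is None:
        adapter = SimulationConfig().adapter_sequence
    genome = read_fasta(os.path.join(dataset_dir, "genome.fa"))
    ann = AnnotationSet(load_gff3(os.path.join(dataset_dir,
                                               "annotations.gff3")))
    index = GenomeIndex(genome)
    cells = pd.read_csv(os.path.join(dataset_dir, "cells.tsv"), sep="\t")

    molecules = []
    trim_reports, tallies, dropped_tally = {}, {}, {}
    for cell in cells["cell"]:
        fq = os.path.join(dataset_dir, "reads", f"{cell}.fastq")
        mols, report, tally, dropped = process_cell(fq, cell, adapter, index)
        molecules.extend(mols)
        trim_reports[cell] = report
        tallies[cell] = tally
        dropped_tally[cell] = dropped

    assigned = assign_all(molecules, ann)
    matrices, props, hists, stats = build_count_matrices(assigned, cells)
    stats = stats.join(cells.set_index("cell")["sequenced_reads"])
    return PipelineResult(molecules, assigned, matrices, props, hists, stats,
                          trim_reports, tallies, dropped_tally)


def truth_expected_counts(truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-category cells x features integer matrices implied by a truth
    table (the planted molecule counts the pipeline should recover)."""
    t = truth.copy()
    catchall = {"protein_coding": "protein_coding_sense",
                "lncRNA": "lncRNA_sense", "repeat": "repeat_sense",
                "pseudogene": "pseudogene"}
    t["category"] = t["biotype"].map(lambda b: catchall.get(b, b))
    out = {}
    for cat, sub in t.groupby("category"):
        mat = (sub.groupby(["cell", "feature"]).size()
               .unstack(fill_value=0).astype(int))
        mat = mat[sorted(mat.columns)]
        mat.index.name = "cell"
        out[cat] = mat
    return out


def compare_to_truth(result: PipelineResult, truth: pd.DataFrame):
    """Exact per-(cell, feature) comparison of recovered vs planted counts.

    Returns (n_entries_compared, n_mismatched) over the union of planted
    and recovered matrix entries for every category.
    """
    expected = truth_expected_counts(truth)
    compared = mismatched = 0
    cats = set(expected) | set(result.matrices)
    for cat in cats:
        exp = expected.get(cat)
        got = result.matrices.get(cat)
        if exp is None:
            exp = got * 0
        if got is None:
            got = exp * 0
        cells = sorted(set(exp.index) | set(got.index))
        feats = sorted(set(exp.columns) | set(got.columns))
        e = exp.reindex(index=cells, columns=feats, fill_value=0)
        g = got.reindex(index=cells, columns=feats, fill_value=0)
        compared += e.size
        mismatched += int((e.to_numpy() != g.to_numpy()).sum())
    return compared, mismatched
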