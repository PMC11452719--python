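"""Cell QC, feature filtering, normalisation and rank-based differential
expression for small-RNA count matrices.

Cells must reach 0.5 million sequenced reads, keep mitochondrial molecules
below 25% and express more than 100 miRNA molecules.  Features are kept when
counted in at least two cells.  Size factors are library sizes median-centred
within each sequencing batch so that factors are comparable across batches
(a documented stand-in for pooled deconvolution with cross-batch rescaling);
expression is log2(count / size_factor + 1).  Group contrasts use the
two-sided Wilcoxon rank-sum test (exact enumeration for small tie-free
groups, tie-corrected normal approximation otherwise), Benjamini-Hochberg
adjustment across features, and the thresholds FDR < 0.05, log2 fold change
above a contrast-specific cut (0.1 for miRNA stage contrasts, 0.25 for
ICM-vs-TE gene contrasts) with expression in more than a third of the cells
of the favoured group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_READS = 5e5
MAX_MITO_FRACTION = 0.25
MIN_MIRNA_MOLECULES = 100
MIN_CELLS_PER_FEATURE = 2
DEFAULT_LOG2FC = 0.1
GENE_LOG2FC = 0.25
FDR_CUT = 0.05
MIN_EXPRESSING_FRACTION = 1.0 / 3.0
MARKER_PADJ = 0.001


@dataclass
class CellQCRecord:
    cell: str
    sequenced_reads: float
    mito_fraction: float
    mirna_molecules: int
    passed: bool
    reasons: list = field(default_factory=list)


def qc_cells(matrices: dict[str, pd.DataFrame], cell_stats: pd.DataFrame,
             mirna_metric: str = "molecules"):
    """Apply the three per-cell quality filters.

    ``cell_stats`` is indexed by cell with columns ``sequenced_reads`` and
    ``mito_fraction``; miRNA expression comes from the miRNA matrix, either
    as total molecules (default) or as distinct expressed species
    (``mirna_metric="species"``).  Returns (records, filtered matrices).
    """
    if mirna_metric not in ("molecules", "species"):
        raise ValueError("mirna_metric must be 'molecules' or 'species'")
    mirna = matrices.get("miRNA")
    cells = list(cell_stats.index)
    records = []
    for cell in cells:
        row = cell_stats.loc[cell]
        if mirna is None or cell not in mirna.index:
            n_mirna = 0
        elif mirna_metric == "molecules":
            n_mirna = int(mirna.loc[cell].sum())
        else:
            n_mirna = int((mirna.loc[cell] > 0).sum())
        reasons = []
        if row["sequenced_reads"] < MIN_READS:
            reasons.append("reads")
        if row["mito_fraction"] >= MAX_MITO_FRACTION:
            reasons.append("mito")
        if n_mirna <= MIN_MIRNA_MOLECULES:
            reasons.append("mirna_molecules")
        records.append(CellQCRecord(cell, float(row["sequenced_reads"]),
                                    float(row["mito_fraction"]), n_mirna,
                                    not reasons, reasons))
    passed = [r.cell for r in records if r.passed]
    filtered = {bt: m.loc[m.index.intersection(passed)]
                for bt, m in matrices.items()}
    return records, filtered


def filter_features(matrix: pd.DataFrame,
                    min_cells: int = MIN_CELLS_PER_FEATURE) -> pd.DataFrame:
    """Keep features with at least one count in >= ``min_cells`` cells."""
    keep = (matrix > 0).sum(axis=0) >= min_cells
    return matrix.loc[:, keep]


def normalize(matrix: pd.DataFrame,
              batches: pd.Series | None = None):
    """Batch-comparable log-normalisation.

    Size factor = library size / within-batch median library size, so
    factors are strictly positive with median 1 inside every batch and are
    comparable across batches of different depth.  Returns
    (log2-normalised matrix, size factors).
    """
    lib = matrix.sum(axis=1).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"cell {bad!r} has zero total count; "
                         "it should have failed QC")
    if batches is None:
        batches = pd.Series("batch0", index=matrix.index)
    sf = pd.Series(index=matrix.index, dtype=float)
    for _, cells in lib.groupby(batches.reindex(lib.index)):
        sf.loc[cells.index] = cells / cells.median()
    norm = np.log2(matrix.div(sf, axis=0) + 1.0)
    return norm, sf


@dataclass
class DEResult:
    feature: str
    group1: str
    group2: str
    log2fc: float          # group2 - group1, Seurat-style mean convention
    p_value: float
    fdr: float
    frac1: float
    frac2: float
    significant: bool


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact enumeration for tie-free groups of <= 10,
    tie-corrected normal approximation otherwise."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    pooled = np.concatenate([x, y])
    method = "auto"
    if len(x) <= 10 and len(y) <= 10 and \
            len(np.unique(pooled)) == len(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def _log2fc(x: np.ndarray, y: np.ndarray) -> float:
    """log2 fold change of group means on the de-logged scale with a
    pseudocount of 1 (the convention of the cited single-cell toolkit)."""
    mx = np.mean(2.0 ** x - 1.0)
    my = np.mean(2.0 ** y - 1.0)
    return float(np.log2(my + 1.0) - np.log2(mx + 1.0))


def wilcoxon_de(norm: pd.DataFrame, groups: pd.Series, group1: str,
                group2: str, log2fc_threshold: float = DEFAULT_LOG2FC,
                fdr_cut: float = FDR_CUT) -> pd.DataFrame:
    """Per-feature two-group comparison on log-normalised values.

    Returns a DataFrame (one row per feature) with log2fc (group2 vs
    group1), raw p, BH-adjusted FDR, per-group expressing fractions and the
    significance flag: FDR < 0.05, |log2fc| above threshold in favour of the
    higher group, and > 1/3 expressing cells in the favoured group.
    """
    groups = groups.reindex(norm.index)
    idx1 = groups[groups == group1].index
    idx2 = groups[groups == group2].index
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("both groups need at least 2 cells")
    X1 = norm.loc[idx1]
    X2 = norm.loc[idx2]
    x1 = X1.to_numpy(dtype=float)
    x2 = X2.to_numpy(dtype=float)

    # vectorised asymptotic pass; exact/degenerate features recomputed below
    with np.errstate(all="ignore"):
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided",
                                 method="asymptotic", axis=0)
    pvals = np.asarray(res.pvalue, dtype=float)
    small = x1.shape[0] <= 10 and x2.shape[0] <= 10
    for j, feat in enumerate(norm.columns):
        a, b = x1[:, j], x2[:, j]
        constant = np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]
        if constant:
            pvals[j] = 1.0
        elif small:
            pvals[j] = _rank_sum_p(a, b)
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    rows = []
    for j, feat in enumerate(norm.columns):
        a, b = x1[:, j], x2[:, j]
        lfc = _log2fc(a, b)
        f1 = float((a > 0).mean())
        f2 = float((b > 0).mean())
        favored_frac = f2 if lfc > 0 else f1
        sig = (fdr[j] < fdr_cut and abs(lfc) > log2fc_threshold and
               favored_frac > MIN_EXPRESSING_FRACTION)
        rows.append({"feature": feat, "group1": group1, "group2": group2,
                     "log2fc": lfc, "p_value": float(pvals[j]),
                     "fdr": float(fdr[j]), "frac1": f1, "frac2": f2,
                     "significant": bool(sig)})
    return pd.DataFrame(rows).set_index("feature")


def find_markers(norm: pd.DataFrame, labels: pd.Series,
                 padj_cut: float = MARKER_PADJ) -> dict[str, pd.DataFrame]:
    """One-vs-rest markers per cluster: adjusted p < padj_cut with positive
    fold change, ranked by fold change.  Singleton clusters are skipped."""
    import warnings

    labels = labels.reindex(norm.index)
    out = {}
    for cluster in sorted(labels.dropna().unique()):
        in_cluster = labels == cluster
        if in_cluster.sum() < 2 or (~in_cluster).sum() < 2:
            warnings.warn(f"cluster {cluster!r} too small; skipped")
            continue
        contrast = labels.map(lambda v: cluster if v == cluster else "rest")
        de = wilcoxon_de(norm, contrast, "rest", cluster)
        markers = de[(de["fdr"] < padj_cut) & (de["log2fc"] > 0)]
        out[cluster] = markers.sort_values("log2fc", ascending=False)
    return out


def aggregate_locus(matrix: pd.DataFrame, annotations, chrom: str,
                    start: int, end: int, biotype: str | None = None):
    """Per-cell summed expression of all features inside a genomic region."""
    import warnings

    members = [r.name for r in annotations.overlapping(chrom, start, end)
               if (biotype is None or r.biotype == biotype)
               and r.name in matrix.columns]
    if not members:
        warnings.warn(f"region {chrom}:{start}-{end} contains no features")
        return pd.Series(0, index=matrix.index, name="aggregate"), members
    return matrix[members].sum(axis=1).rename("aggregate"), members


def marker_origin_proportions(markers: list[str],
                              families: dict[str, str]) -> pd.Series:
    """Fraction of markers per named family/region (e.g. the chromosome 19
    and 14 miRNA clusters)."""
    if not markers:
        return pd.Series(dtype=float)
    fam = pd.Series({m: families.get(m, "other") for m in markers})
    return fam.value_counts() / len(markers)
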