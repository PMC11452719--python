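"""Pseudotime branch alignment, trajectory-associated miRNA selection,
expression-pattern clustering, miRNA-target correlation and novel-miRNA
filtering.

Pseudotime is inferred separately for the inner-cell-mass (ICM) and
trophectoderm (TE) branches, so the ICM axis is rescaled onto the TE axis
with the closed form

    scale_factor = (Psd_TE_max - Psd_pre_max) / (Psd_ICM_max - Psd_pre_max)
    Psd_ICM_mod  = (Psd_ICM - Psd_pre_max) * scale_factor + Psd_pre_max

applied to ICM cells past the latest pre-lineage pseudotime; the rescaled
ICM maximum then coincides with the TE maximum, and the transform is the
identity when the branch maxima agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

PRE = "pre-lineage"
ICM = "ICM"
TE = "TE"


@dataclass
class PseudotimeAlignment:
    pre_max: float
    te_max: float
    icm_max: float
    scale_factor: float


def rescale_pseudotime(table: pd.DataFrame,
                       lineage_col: str = "lineage",
                       pseudotime_col: str = "pseudotime"):
    """Align the ICM pseudotime axis onto the TE axis.

    ``table`` needs one row per cell with lineage in {pre-lineage, ICM, TE}.
    Returns (PseudotimeAlignment, table with a ``pseudotime_rescaled``
    column).  TE and pre-lineage cells, and ICM cells not beyond the latest
    pre-lineage cell, are left unchanged.
    """
    for lin in (PRE, ICM, TE):
        if not (table[lineage_col] == lin).any():
            raise ValueError(f"no cells with lineage {lin!r}")
    psd = table[pseudotime_col].astype(float)
    pre_max = float(psd[table[lineage_col] == PRE].max())
    te_max = float(psd[table[lineage_col] == TE].max())
    icm_max = float(psd[table[lineage_col] == ICM].max())
    denom = icm_max - pre_max
    if denom <= 0:
        raise ValueError(
            "latest ICM pseudotime must exceed the latest pre-lineage "
            f"pseudotime (got {icm_max} <= {pre_max})")
    scale = (te_max - pre_max) / denom
    out = table.copy()
    rescaled = psd.copy()
    mask = (table[lineage_col] == ICM) & (psd > pre_max)
    rescaled[mask] = (psd[mask] - pre_max) * scale + pre_max
    out["pseudotime_rescaled"] = rescaled
    return PseudotimeAlignment(pre_max, te_max, icm_max, scale), out


def select_trajectory_mirnas(norm: pd.DataFrame, pseudotime: pd.Series,
                             batch: pd.Series | None,
                             de_features: set[str] | None = None,
                             fdr_cut: float = 0.05) -> pd.DataFrame:
    """Trajectory-associated miRNAs on one branch.

    Each miRNA is regressed on pseudotime with the sequencing batch as an
    additive covariate; the pseudotime slope is tested, p-values are BH
    adjusted across miRNAs, and associations at FDR < 0.05 are intersected
    with the supplied stage-wise differential-expression set (adjacent
    stages or later-vs-E3 contrasts).
    """
    cells = norm.index
    if len(cells) < 10:
        raise ValueError("need at least 10 cells on the branch")
    pt = pseudotime.reindex(cells).astype(float)
    X = pd.DataFrame({"pseudotime": pt}, index=cells)
    if batch is not None:
        b = batch.reindex(cells)
        if b.nunique() > 1:
            X = pd.concat([X, pd.get_dummies(b, prefix="batch",
                                             drop_first=True, dtype=float)],
                          axis=1)
        else:
            warnings.warn("single batch; covariate dropped")
    X = sm.add_constant(X)
    rows = []
    for feat in norm.columns:
        fit = sm.OLS(norm[feat].astype(float), X).fit()
        rows.append({"mirna": feat, "slope": fit.params["pseudotime"],
                     "p_value": fit.pvalues["pseudotime"]})
    res = pd.DataFrame(rows).set_index("mirna")
    res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    res["associated"] = res["fdr"] < fdr_cut
    if de_features is not None:
        res["stage_de"] = res.index.isin(de_features)
        res["selected"] = res["associated"] & res["stage_de"]
    else:
        res["selected"] = res["associated"]
    return res


def binned_profiles(norm: pd.DataFrame, pseudotime: pd.Series,
                    features: list[str], n_bins: int = 20) -> pd.DataFrame:
    """Mean expression per equal-width pseudotime bin (features x bins);
    empty bins are interpolated from their neighbours."""
    pt = pseudotime.reindex(norm.index).astype(float)
    edges = np.linspace(pt.min(), pt.max(), n_bins + 1)
    which = np.clip(np.digitize(pt, edges[1:-1]), 0, n_bins - 1)
    prof = pd.DataFrame(index=features, columns=range(n_bins), dtype=float)
    for b in range(n_bins):
        cells = norm.index[which == b]
        if len(cells):
            prof[b] = norm.loc[cells, features].mean(axis=0)
    return prof.interpolate(axis=1, limit_direction="both")


def cluster_patterns(profiles: pd.DataFrame, seed: int = 0,
                     n_restarts: int = 25) -> pd.Series:
    """k-means (k=3) over z-scored binned profiles, with centroids labelled
    by shape: C2 rises (largest last-minus-first thirds contrast), C3 falls
    (most negative contrast), C1 is transient (middle third above both
    ends)."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for k=3 clustering")
    X = profiles.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(Z)
    cent = km.cluster_centers_
    third = max(cent.shape[1] // 3, 1)
    first = cent[:, :third].mean(axis=1)
    last = cent[:, -third:].mean(axis=1)
    delta = last - first
    names = {}
    names[int(np.argmax(delta))] = "C2"
    names[int(np.argmin(delta))] = "C3"
    for k in range(3):
        if k not in names:
            names[k] = "C1"
    return pd.Series([names[int(k)] for k in labels], index=profiles.index,
                     name="pattern")


def pseudobulk(norm: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Mean log-normalised expression per group (groups x features); empty
    groups are dropped with a warning."""
    grouping = grouping.reindex(norm.index)
    missing = grouping.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} cells without a group dropped")
    out = norm[~missing].groupby(grouping[~missing]).mean()
    out.index.name = "group"
    return out


@dataclass
class CorrelationResult:
    mirna: str
    gene: str
    n: int
    r: float
    t: float
    p_negative: float
    p_positive: float


def correlate_targets(mirna_pb: pd.DataFrame, gene_pb: pd.DataFrame,
                      pairs: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation with one-sided t-tests per candidate pair.

    Pseudobulk tables are aligned on their common groups (n >= 3 required);
    t = r * sqrt(n - 2) / sqrt(1 - r^2); zero-variance profiles are skipped
    with a reason.  Returns a DataFrame with significance calls in both
    directions at p < 0.05.
    """
    common = mirna_pb.index.intersection(gene_pb.index)
    n = len(common)
    if n < 3:
        raise ValueError(f"need >= 3 shared pseudobulk groups, got {n}")
    M = mirna_pb.loc[common]
    G = gene_pb.loc[common]
    rows = []
    for mirna, gene in pairs[["mirna", "gene"]].itertuples(index=False):
        if mirna not in M.columns or gene not in G.columns:
            rows.append({"mirna": mirna, "gene": gene, "n": n, "r": np.nan,
                         "t": np.nan, "p_negative": np.nan,
                         "p_positive": np.nan, "skipped": "missing_feature"})
            continue
        x = M[mirna].to_numpy(dtype=float)
        y = G[gene].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"mirna": mirna, "gene": gene, "n": n, "r": np.nan,
                         "t": np.nan, "p_negative": np.nan,
                         "p_positive": np.nan, "skipped": "zero_variance"})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = max(min(r, 1.0), -1.0)
        df = n - 2
        if abs(r) >= 1.0:
            t = np.inf * np.sign(r)
            p_neg = 0.0 if r < 0 else 1.0
        else:
            t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
            p_neg = float(stats.t.cdf(t, df))
        rows.append({"mirna": mirna, "gene": gene, "n": n, "r": r,
                     "t": float(t), "p_negative": p_neg,
                     "p_positive": 1.0 - p_neg, "skipped": ""})
    res = pd.DataFrame(rows)
    res["significant_negative"] = res["p_negative"] < 0.05
    res["significant_positive"] = res["p_positive"] < 0.05
    return res


# --------------------------------------------------------------- novel miRNA

NOVEL_MIN_CELLS = 30
NOVEL_LENGTH_RANGE = (20, 25)
NOVEL_LENGTH_FRACTION = 0.75


def _parse_lengths(field: str) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    if not isinstance(field, str) or not field.strip():
        return out
    for chunk in field.split(";"):
        if ":" not in chunk:
            raise ValueError(f"malformed read-length field: {chunk!r}")
        cell, lens = chunk.split(":", 1)
        out[cell] = [int(v) for v in lens.split(",") if v]
    return out


def novel_criteria(row: pd.Series) -> dict[str, bool]:
    """The four selection predicates for one candidate."""
    randfold = str(row["significant_randfold"]).strip().lower() in \
        ("yes", "true", "significant", "1")
    score = float(row["mirdeep_score"]) > 0
    contexts = [c for c in str(row["expressed_in"]).split(";") if c.strip()]
    breadth = len(set(contexts)) >= 2
    lengths = _parse_lengths(row["read_lengths_by_cell"])
    n_cells = len(lengths)
    all_lens = [v for lens in lengths.values() for v in lens]
    lo, hi = NOVEL_LENGTH_RANGE
    frac = (sum(lo <= v <= hi for v in all_lens) / len(all_lens)
            if all_lens else 0.0)
    support = n_cells >= NOVEL_MIN_CELLS and frac >= NOVEL_LENGTH_FRACTION
    return {"randfold": randfold, "score": score, "breadth": breadth,
            "support": support}


def filter_novel(candidates: pd.DataFrame) -> pd.DataFrame:
    """Accept candidates passing all four criteria: significant hairpin
    folding, positive discovery score, expression in >= 2 batches or
    timepoints, and read support from >= 30 cells with >= 75% of
    overlapping reads in 20-25 nt."""
    required = ["candidate_id", "significant_randfold", "mirdeep_score",
                "expressed_in", "read_lengths_by_cell"]
    rows = []
    for _, row in candidates.iterrows():
        missing = [c for c in required if c not in row or pd.isna(row[c])]
        if missing:
            rows.append({"candidate_id": row.get("candidate_id", "?"),
                         "accepted": False,
                         "reason": f"missing:{','.join(missing)}"})
            continue
        crit = novel_criteria(row)
        failed = [k for k, ok in crit.items() if not ok]
        rows.append({"candidate_id": row["candidate_id"],
                     **{f"pass_{k}": v for k, v in crit.items()},
                     "accepted": not failed,
                     "reason": ";".join(failed)})
    return pd.DataFrame(rows)
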