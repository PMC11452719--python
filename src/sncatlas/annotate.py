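"""Hierarchical, strand-aware annotation of deduplicated molecules.

Each molecule is assigned to exactly one category.  Small-RNA biotypes are
resolved first, in a fixed priority order (miRNA, rRNA, snoRNA, snRNA, tRNA,
piRNA); molecules overlapping none of those same-strand are routed to
catch-all genomic categories (protein-coding, lncRNA, repeats, pseudogenes,
with sense/antisense suffixes) or left unannotated.  Reads assigned to mature
miRNA or piRNA must additionally be shorter than 40 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

#: category priority for the small-RNA biotypes, highest first
PRIORITY = ["miRNA", "rRNA", "snoRNA", "snRNA", "tRNA", "piRNA"]

#: catch-all labels in priority order for molecules missing every small-RNA
#: track; strand suffix reflects placement strand vs feature strand
CATCHALL_ORDER = [
    ("protein_coding", "sense"), ("protein_coding", "antisense"),
    ("lncRNA", "sense"), ("lncRNA", "antisense"),
    ("repeat", "sense"), ("repeat", "antisense"),
    ("pseudogene", None),
]

#: biotypes whose assigned reads must be < 40 nt
SHORT_ONLY = {"miRNA", "piRNA"}
MAX_SHORT_LENGTH = 40

#: non-priority biotype labels the loader accepts
EXTRA_BIOTYPES = {"miRNA_primary"} | {t for t, _ in CATCHALL_ORDER if t}
ACCEPTED_BIOTYPES = set(PRIORITY) | EXTRA_BIOTYPES | {"pseudogene"}

MITO_CHROMS = {"chrM", "MT"}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    """One genomic feature: 0-based half-open interval with strand."""

    biotype: str
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    parent: str | None = None
    #: free-form label, e.g. "Arg:ACG" for tRNAs or a family name for miRNAs
    label: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotationSet:
    """Priority-ordered annotation records with interval lookup."""

    def __init__(self, records: list[AnnotationRecord] | None = None):
        self.records: list[AnnotationRecord] = []
        self._trees: dict[str, IntervalTree] = {}
        self._by_name: dict[tuple[str, str], AnnotationRecord] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: AnnotationRecord) -> None:
        if rec.start >= rec.end:
            raise AnnotationError(
                f"invalid interval for {rec.name}: [{rec.start},{rec.end})")
        self.records.append(rec)
        self._trees.setdefault(rec.chrom, IntervalTree())
        self._trees[rec.chrom].addi(rec.start, rec.end, rec)
        self._by_name[(rec.biotype, rec.name)] = rec

    def __len__(self) -> int:
        return len(self.records)

    def by_biotype(self, biotype: str) -> list[AnnotationRecord]:
        return [r for r in self.records if r.biotype == biotype]

    def get(self, biotype: str, name: str) -> AnnotationRecord:
        return self._by_name[(biotype, name)]

    def overlapping(self, chrom: str, start: int, end: int,
                    strand: str | None = None) -> list[AnnotationRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [r for r in hits if r.strand == strand]
        return sorted(hits, key=lambda r: (r.start, r.end, r.name))

    # ------------------------------------------------------------------ I/O

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in sorted(self.records,
                            key=lambda r: (r.chrom, r.start, r.name)):
                attrs = [f"ID={r.name}", f"biotype={r.biotype}"]
                if r.parent:
                    attrs.append(f"Parent={r.parent}")
                if r.label:
                    attrs.append(f"label={r.label}")
                fh.write("\t".join([
                    r.chrom, "sncatlas", r.biotype, str(r.start + 1),
                    str(r.end), ".", r.strand, ".", ";".join(attrs)]) + "\n")

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for r in sorted(self.records,
                            key=lambda r: (r.chrom, r.start, r.name)):
                fh.write("\t".join([
                    r.chrom, str(r.start), str(r.end),
                    f"{r.biotype}:{r.name}", "0", r.strand]) + "\n")


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for item in attr_field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_gff3(path: str, biotype: str | None = None) -> list[AnnotationRecord]:
    """Parse GFF3 (1-based closed) into 0-based half-open records.

    ``biotype`` overrides the per-line type/attribute; otherwise the feature
    type column (or a ``biotype=`` attribute) is used and must be a known
    label.
    """
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}:{line_no}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs_s = parts
            attrs = _parse_attributes(attrs_s)
            bt = biotype or attrs.get("biotype", ftype)
            _check_biotype(bt, path, line_no)
            start_i, end_i = int(start) - 1, int(end)
            if start_i < 0 or start_i >= end_i:
                raise AnnotationError(
                    f"{path}:{line_no}: bad GFF3 coordinates {start}..{end}")
            records.append(AnnotationRecord(
                biotype=bt, chrom=chrom, start=start_i, end=end_i,
                strand=strand, name=attrs.get("ID", f"feat{line_no}"),
                parent=attrs.get("Parent"), label=attrs.get("label")))
    return records


def load_bed(path: str, biotype: str | None = None) -> list[AnnotationRecord]:
    """Parse BED6 (0-based half-open).  Names of the form ``biotype:name``
    carry their own biotype unless ``biotype`` is forced."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise AnnotationError(f"{path}:{line_no}: expected BED6")
            chrom, start, end, name, _, strand = parts[:6]
            bt, feat_name = biotype, name
            if bt is None and ":" in name:
                bt, feat_name = name.split(":", 1)
            if bt is None:
                raise AnnotationError(
                    f"{path}:{line_no}: no biotype for BED record {name}")
            _check_biotype(bt, path, line_no)
            start_i, end_i = int(start), int(end)
            if start_i < 0 or start_i >= end_i:
                raise AnnotationError(
                    f"{path}:{line_no}: bad BED coordinates {start}..{end}")
            records.append(AnnotationRecord(
                biotype=bt, chrom=chrom, start=start_i, end=end_i,
                strand=strand, name=feat_name))
    return records


def _check_biotype(bt: str, path: str, line_no: int) -> None:
    if bt not in ACCEPTED_BIOTYPES:
        raise AnnotationError(
            f"{path}:{line_no}: unknown biotype {bt!r}; accepted: "
            f"{sorted(ACCEPTED_BIOTYPES)}")


def load_annotations(paths: dict[str, str] | list[str]) -> AnnotationSet:
    """Load GFF3/BED files into one AnnotationSet.

    ``paths`` is either a mapping biotype -> file (the biotype is forced for
    every record of that file, mirroring per-database annotation roles) or a
    list of files whose records carry their own biotype labels.
    """
    recs: list[AnnotationRecord] = []
    if isinstance(paths, dict):
        items = [(bt, p) for bt, p in paths.items()]
    else:
        items = [(None, p) for p in paths]
    for bt, path in items:
        if str(path).endswith((".bed", ".bed6")):
            recs.extend(load_bed(path, biotype=bt))
        else:
            recs.extend(load_gff3(path, biotype=bt))
    return AnnotationSet(recs)


# --------------------------------------------------------------- assignment

@dataclass
class AssignedMolecule:
    molecule: object
    category: str
    feature: str | None
    overlap: int
    record: AnnotationRecord | None = None


def _best_overlap(placements, annotations: AnnotationSet, biotypes,
                  insert_length: int, sense: bool = True):
    """Best (priority, overlap) feature over all placements.

    Returns (biotype, record, overlap) or None.  ``sense=False`` matches
    features on the opposite strand of the placement.
    """
    best = None
    rank = {bt: i for i, bt in enumerate(biotypes)}
    for pl in placements:
        want = None if sense is None else None
        for rec in annotations.overlapping(pl.chrom, pl.start, pl.end):
            if rec.biotype not in rank:
                continue
            same = rec.strand == pl.strand
            if sense is True and not same:
                continue
            if sense is False and same:
                continue
            if rec.biotype in SHORT_ONLY and insert_length >= MAX_SHORT_LENGTH:
                continue
            ov = min(rec.end, pl.end) - max(rec.start, pl.start)
            if ov <= 0:
                continue
            key = (rank[rec.biotype], -ov, rec.name)
            if best is None or key < best[0]:
                best = (key, rec, ov)
    if best is None:
        return None
    return best[1].biotype, best[1], best[2]


def assign_category(molecule, annotations: AnnotationSet):
    """Assign a molecule to its highest-priority same-strand small-RNA
    category, or return None if no track matches (caller then falls through
    to :func:`assign_other`)."""
    hit = _best_overlap(molecule.placements, annotations, PRIORITY,
                        len(molecule.insert), sense=True)
    if hit is None:
        return None
    biotype, rec, ov = hit
    return AssignedMolecule(molecule, biotype, rec.name, ov, rec)


def assign_other(molecule, annotations: AnnotationSet) -> AssignedMolecule:
    """Catch-all labelling for molecules missed by every small-RNA track."""
    for track, orient in CATCHALL_ORDER:
        sense = True if orient == "sense" else False if orient == "antisense" else None
        for pl in molecule.placements:
            for rec in annotations.overlapping(pl.chrom, pl.start, pl.end):
                if rec.biotype != track:
                    continue
                same = rec.strand == pl.strand
                if sense is True and not same:
                    continue
                if sense is False and same:
                    continue
                ov = min(rec.end, pl.end) - max(rec.start, pl.start)
                label = track if orient is None else f"{track}_{orient}"
                return AssignedMolecule(molecule, label, rec.name, ov, rec)
    return AssignedMolecule(molecule, "unannotated", None, 0, None)


def assign_all(molecules, annotations: AnnotationSet) -> list[AssignedMolecule]:
    out = []
    for mol in molecules:
        assigned = assign_category(mol, annotations)
        if assigned is None:
            assigned = assign_other(mol, annotations)
        out.append(assigned)
    return out


# ------------------------------------------------------------ count matrices

def build_count_matrices(assigned: list[AssignedMolecule],
                         metadata: pd.DataFrame,
                         mito_chroms: set[str] = MITO_CHROMS):
    """Integer cells x features count matrix per biotype, plus per-cell
    biotype proportions, per-biotype insert-length histograms, and per-cell
    stats (total molecules, mitochondrial molecules).

    ``metadata`` must carry one row per cell (index or 'cell' column).
    """
    cells = list(metadata["cell"]) if "cell" in metadata.columns \
        else list(metadata.index)
    known = set(cells)
    counts: dict[str, dict[tuple[str, str], int]] = {}
    lengths: dict[str, dict[int, int]] = {}
    cat_counts: dict[tuple[str, str], int] = {}
    mito: dict[str, int] = {c: 0 for c in cells}
    for am in assigned:
        cell = am.molecule.cell
        if cell not in known:
            raise KeyError(f"cell {cell!r} missing from metadata")
        feature = am.feature if am.feature is not None else am.category
        counts.setdefault(am.category, {})
        counts[am.category][(cell, feature)] = \
            counts[am.category].get((cell, feature), 0) + 1
        lengths.setdefault(am.category, {})
        L = len(am.molecule.insert)
        lengths[am.category][L] = lengths[am.category].get(L, 0) + 1
        cat_counts[(cell, am.category)] = cat_counts.get((cell, am.category), 0) + 1
        if am.molecule.placements and \
                am.molecule.placements[0].chrom in mito_chroms:
            mito[cell] += 1

    matrices = {}
    for cat, d in counts.items():
        ser = pd.Series(d)
        mat = ser.unstack(fill_value=0)
        mat = mat.reindex(index=cells, fill_value=0)
        mat = mat[sorted(mat.columns)].astype(int)
        mat.index.name = "cell"
        matrices[cat] = mat

    cat_ser = pd.Series(cat_counts, dtype=float)
    props = cat_ser.unstack(fill_value=0.0).reindex(index=cells, fill_value=0.0)
    totals = props.sum(axis=1)
    props = props.div(totals.replace(0, 1.0), axis=0)
    props.index.name = "cell"

    length_hists = {
        cat: pd.Series(d).sort_index().rename("count")
        for cat, d in lengths.items()
    }
    stats = pd.DataFrame({
        "cell": cells,
        "total_molecules": totals.reindex(cells).fillna(0).astype(int).values,
        "mito_molecules": [mito[c] for c in cells],
    }).set_index("cell")
    stats["mito_fraction"] = (
        stats["mito_molecules"] / stats["total_molecules"].replace(0, 1))
    return matrices, props, length_hists, stats
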