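"""isomiR and tRNA-fragment classification.

A molecule's insert is compared base-by-base against the genome at its
placement.  The maximal 3'-terminal run of bases that mismatch their implied
genome positions is the non-templated addition (NTA); the templated ends
that remain are compared with the annotated feature ends, in feature-strand
orientation, to give the 5' and 3' shifts (positive = elongation beyond the
annotated end, negative = trimming/into the gene).  This sequence-level
definition subsumes both soft-clipped bases and terminal aligned mismatches
(the aligner forgives a mismatch at the read's final base), so planted
modifications are recovered exactly on error-free data.

isomiRs are miRNA molecules shifted by -3..+3 at either end and/or carrying
1-3 non-templated 3' bases.  tRNA molecules are classed as 5' halves
(length < 50 nt, 3' shift <= -10 but 5' shift > -10), 3' halves (the mirror
pattern), full length (> 50 nt, neither end shifted beyond -10), or
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import AnnotationRecord, AssignedMolecule
from .simulate import revcomp

MAX_ISOMIR_SHIFT = 3
MAX_NTA = 3

TRF_LENGTH_CUT = 50
TRF_SHIFT_CUT = -10

FIVE_HALF = "five_prime_half"
THREE_HALF = "three_prime_half"
FULL_LENGTH = "full_length"
UNCLASSIFIED = "unclassified"


@dataclass
class IsomiRRecord:
    cell: str
    mirna: str
    shift5: int
    shift3: int
    nta: str
    length_class: str    # canonical / 5'-trim / 5'-elong / 3'-trim / 3'-elong / mixed
    excluded: bool = False

    @property
    def is_canonical(self) -> bool:
        return self.shift5 == 0 and self.shift3 == 0 and not self.nta

    @property
    def category(self) -> str:
        return f"{self.length_class}|{'NTA' if self.nta else 'no-NTA'}"


@dataclass
class TRFRecord:
    cell: str
    trna: str
    amino_acid: str
    anticodon: str
    length: int
    shift5: int
    shift3: int
    klass: str


def _implied_base(index, placement, insert_len: int, i: int) -> str:
    """Genome base (oriented to the read) implied for insert position i."""
    g = index.genome[placement.chrom]
    if placement.strand == "+":
        pos = placement.start - placement.clip5 + i
        if 0 <= pos < len(g):
            return g[pos]
    else:
        pos = placement.start + placement.length - 1 + placement.clip5 - i
        if 0 <= pos < len(g):
            return revcomp(g[pos])
    return "N"


def end_profile(molecule, placement, index):
    """(shift-ready genome coords, NTA run) for one placement.

    Returns (g5, g3, nta) where g5/g3 are the genome coordinates of the
    templated 5'/3' terminal bases and nta is the non-templated 3' string.
    """
    insert = molecule.insert
    L = len(insert)
    run = 0
    while run < L:
        i = L - 1 - run
        if insert[i] != _implied_base(index, placement, L, i):
            run += 1
        else:
            break
    nta = insert[L - run:] if run else ""
    t3_index = L - 1 - run
    t5_index = placement.clip5
    if placement.strand == "+":
        base = placement.start - placement.clip5
        g5 = base + t5_index
        g3 = base + t3_index
    else:
        base = placement.start + placement.length - 1 + placement.clip5
        g5 = base - t5_index
        g3 = base - t3_index
    return g5, g3, nta


def end_shifts(g5: int, g3: int, ref: AnnotationRecord) -> tuple[int, int]:
    """Shifts of templated ends vs annotated ends, feature-strand oriented;
    positive = beyond the annotated end."""
    if ref.strand == "+":
        shift5 = ref.start - g5
        shift3 = g3 - (ref.end - 1)
    else:
        shift5 = g5 - (ref.end - 1)
        shift3 = ref.start - g3
    return shift5, shift3


def _matching_placement(molecule, ref: AnnotationRecord):
    for pl in molecule.placements:
        if pl.chrom == ref.chrom and pl.strand == ref.strand and \
                pl.start < ref.end and pl.end > ref.start:
            return pl
    return None


def classify_isomir(assigned: AssignedMolecule, index) -> IsomiRRecord:
    """Classify one mature-miRNA molecule relative to its annotated form."""
    if assigned.category != "miRNA":
        raise ValueError("molecule not assigned to miRNA")
    ref = assigned.record
    mol = assigned.molecule
    pl = _matching_placement(mol, ref)
    if pl is None:
        raise ValueError(
            f"no placement of {mol.read_id} overlaps mature {ref.name}")
    g5, g3, nta = end_profile(mol, pl, index)
    shift5, shift3 = end_shifts(g5, g3, ref)
    excluded = (abs(shift5) > MAX_ISOMIR_SHIFT or
                abs(shift3) > MAX_ISOMIR_SHIFT or len(nta) > MAX_NTA)
    if shift5 == 0 and shift3 == 0:
        length_class = "canonical"
    elif shift3 == 0:
        length_class = "5'-trim" if shift5 < 0 else "5'-elong"
    elif shift5 == 0:
        length_class = "3'-trim" if shift3 < 0 else "3'-elong"
    else:
        length_class = "mixed"
    return IsomiRRecord(mol.cell, ref.name, shift5, shift3, nta,
                        length_class, excluded)


def trf_class(length: int, shift5: int, shift3: int) -> str:
    """Deterministic tRF class from read length and end shifts.

    'Shorter than 50' is read as length <= 49 and 'exceeding 50' as
    length >= 51; exactly 50 nt is unclassified, as are fragments shifted
    beyond -10 at both ends or long reads with one shifted end.
    """
    if length < TRF_LENGTH_CUT:
        if shift3 <= TRF_SHIFT_CUT and shift5 > TRF_SHIFT_CUT:
            return FIVE_HALF
        if shift5 <= TRF_SHIFT_CUT and shift3 > TRF_SHIFT_CUT:
            return THREE_HALF
        return UNCLASSIFIED
    if length > TRF_LENGTH_CUT:
        if shift5 > TRF_SHIFT_CUT and shift3 > TRF_SHIFT_CUT:
            return FULL_LENGTH
    return UNCLASSIFIED


def classify_trf(assigned: AssignedMolecule, index) -> TRFRecord:
    """Classify one tRNA molecule into 5'-half / 3'-half / full length."""
    if assigned.category != "tRNA":
        raise ValueError("molecule not assigned to tRNA")
    ref = assigned.record
    mol = assigned.molecule
    pl = _matching_placement(mol, ref)
    if pl is None:
        raise ValueError(
            f"no placement of {mol.read_id} overlaps tRNA {ref.name}")
    g5, g3, nta = end_profile(mol, pl, index)
    shift5, shift3 = end_shifts(g5, g3, ref)
    templated_length = len(mol.insert) - len(nta) - pl.clip5
    aa, _, ac = (ref.label or "::").partition(":")
    return TRFRecord(mol.cell, ref.name, aa, ac, templated_length,
                     shift5, shift3,
                     trf_class(templated_length, shift5, shift3))


# ------------------------------------------------------------------ summaries

LENGTH_CLASSES = ["canonical", "5'-trim", "5'-elong", "3'-trim", "3'-elong",
                  "mixed"]


def isomir_frame(records: list[IsomiRRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell": r.cell, "mirna": r.mirna, "shift5": r.shift5,
        "shift3": r.shift3, "nta": r.nta, "length_class": r.length_class,
        "canonical": r.is_canonical, "excluded": r.excluded}
        for r in records])


def summarize_isomir(records: list[IsomiRRecord], metadata: pd.DataFrame):
    """Per-day isomiR composition.

    Returns (per-day class proportions incl. NTA stats, per-(day, miRNA)
    class proportions).  Molecules with out-of-range shifts are excluded
    and tallied in the 'excluded_n' column.
    """
    df = isomir_frame(records)
    if df.empty:
        raise ValueError("no isomiR records to summarise")
    day_of = metadata.set_index("cell")["day"]
    df["day"] = df["cell"].map(day_of)
    excluded = df.groupby("day")["excluded"].sum().rename("excluded_n")
    ok = df[~df["excluded"]]
    rows = []
    for day, sub in ok.groupby("day"):
        n = len(sub)
        row = {"day": day, "n": n}
        for cls in LENGTH_CLASSES:
            row[cls] = (sub["length_class"] == cls).sum() / n
        row["nta_fraction"] = (sub["nta"] != "").sum() / n
        for k in (1, 2, 3):
            row[f"nta_A{k}"] = (sub["nta"] == "A" * k).sum() / n
        row["nta_other"] = ((sub["nta"] != "") &
                            ~sub["nta"].isin(["A", "AA", "AAA"])).sum() / n
        rows.append(row)
    per_day = pd.DataFrame(rows).set_index("day")
    per_day = per_day.join(excluded)
    per_mirna = (ok.groupby(["day", "mirna"])["length_class"]
                 .value_counts(normalize=True).unstack(fill_value=0.0))
    return per_day, per_mirna


def trf_frame(records: list[TRFRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell": r.cell, "trna": r.trna, "amino_acid": r.amino_acid,
        "anticodon": r.anticodon, "length": r.length, "shift5": r.shift5,
        "shift3": r.shift3, "klass": r.klass} for r in records])


def codon_usage(records: list[TRFRecord], metadata: pd.DataFrame):
    """Per-day amino-acid proportions, one table per tRF class; each row
    sums to 1."""
    df = trf_frame(records)
    if df.empty:
        raise ValueError("no tRF records to summarise")
    day_of = metadata.set_index("cell")["day"]
    df["day"] = df["cell"].map(day_of)
    tables = {}
    for klass, sub in df.groupby("klass"):
        tab = (sub.groupby("day")["amino_acid"]
               .value_counts(normalize=True).unstack(fill_value=0.0))
        tables[klass] = tab
    return tables
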