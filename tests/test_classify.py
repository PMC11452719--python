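"""isomiR and tRNA-fragment classification."""

import numpy as np
import pandas as pd
import pytest

from sncatlas.align import GenomeIndex
from sncatlas.annotate import AnnotationRecord, AssignedMolecule
from sncatlas.classify import (classify_isomir, classify_trf, codon_usage,
                               summarize_isomir, trf_class)
from sncatlas.config import SimulationConfig
from sncatlas.simulate import build_reference, simulate_molecules

from oracles import oracle_trf_class


@pytest.fixture(scope="module")
def mir_setup():
    rng = np.random.default_rng(17)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    # force a non-A base right after the mature end so an 'A' NTA mismatches
    seq = seq[:122] + "G" + seq[123:]
    genome = {"chr1": seq}
    mature = AnnotationRecord("miRNA", "chr1", 100, 122, "+", "mir-t")
    return genome, GenomeIndex(genome), mature


def _assigned(genome, mature, insert, start, clip3=0, clip5=0):
    from sncatlas.align import AlignmentRecord
    from sncatlas.dedup import Molecule

    L = len(insert) - clip3 - clip5
    rec = AlignmentRecord("r", mature.chrom, start, mature.strand, 0,
                          clip5=clip5, clip3=clip3,
                          clip5_seq=insert[:clip5] if clip5 else "",
                          clip3_seq=insert[-clip3:] if clip3 else "",
                          length=L)
    mol = Molecule(cell="c0", read_id="r", umi="A" * 8,
                   cluster={"A" * 8: 1}, insert=insert, placements=[rec])
    return AssignedMolecule(mol, "miRNA", mature.name, L, mature)


def test_canonical(mir_setup):
    genome, index, mature = mir_setup
    insert = genome["chr1"][100:122]
    rec = classify_isomir(_assigned(genome, mature, insert, 100), index)
    assert rec.is_canonical
    assert rec.length_class == "canonical" and rec.nta == ""


def test_templated_three_prime_elongation(mir_setup):
    genome, index, mature = mir_setup
    insert = genome["chr1"][100:123]   # one extra genome-templated base
    rec = classify_isomir(_assigned(genome, mature, insert, 100), index)
    assert rec.shift3 == 1 and rec.shift5 == 0
    assert rec.length_class == "3'-elong" and rec.nta == ""


def test_nta_detected_from_clipped_bases(mir_setup):
    genome, index, mature = mir_setup
    # genome reads 'G' after the mature end: appended "AA" is non-templated
    insert = genome["chr1"][100:122] + "AA"
    rec = classify_isomir(_assigned(genome, mature, insert, 100, clip3=2),
                          index)
    assert rec.nta == "AA"
    assert rec.shift3 == 0 and rec.length_class == "canonical"
    assert not rec.is_canonical
    assert rec.category.endswith("|NTA")


def test_five_prime_trim(mir_setup):
    genome, index, mature = mir_setup
    insert = genome["chr1"][102:122]
    rec = classify_isomir(_assigned(genome, mature, insert, 102), index)
    assert rec.shift5 == -2 and rec.length_class == "5'-trim"


def test_placement_must_overlap_mature(mir_setup):
    genome, index, mature = mir_setup
    insert = genome["chr1"][300:322]
    with pytest.raises(ValueError, match="overlaps mature"):
        classify_isomir(_assigned(genome, mature, insert, 300), index)


@pytest.mark.parametrize("length,s5,s3,expected", [
    (32, 0, -40, "five_prime_half"),
    (32, -40, 0, "three_prime_half"),
    (72, 0, 0, "full_length"),
    (74, -2, -2, "full_length"),
    (30, -20, -20, "unclassified"),
    (50, 0, 0, "unclassified"),       # boundary length exactly 50
    (49, 0, -10, "five_prime_half"),  # shift exactly -10 counts
    (60, -15, 0, "unclassified"),     # long read with one shifted end
])
def test_trf_rule_examples(length, s5, s3, expected):
    assert trf_class(length, s5, s3) == expected


def test_trf_grid_spot_check_against_oracle():
    rng = np.random.default_rng(3)
    for _ in range(2000):
        L = int(rng.integers(17, 91))
        s5 = int(rng.integers(-40, 6))
        s3 = int(rng.integers(-40, 6))
        assert trf_class(L, s5, s3) == oracle_trf_class(L, s5, s3)


def _sim_records(cfg):
    """Classify all planted miRNA/tRNA molecules straight from truth-table
    geometry via the full pipeline fixtures elsewhere; here we reuse the
    simulator + pipeline on a tiny dataset."""
    import tempfile

    from sncatlas.pipeline import run_pipeline
    from sncatlas.simulate import emit_dataset, read_fasta

    with tempfile.TemporaryDirectory() as d:
        emit_dataset(cfg, d)
        truth = pd.read_csv(f"{d}/truth.tsv", sep="\t").fillna(
            {"nta": "", "trf_class": ""})
        res = run_pipeline(d)
        index = GenomeIndex(read_fasta(f"{d}/genome.fa"))
        cells = pd.read_csv(f"{d}/cells.tsv", sep="\t")
    iso, trf = [], []
    for am in res.assigned:
        if am.category == "miRNA":
            iso.append((am, classify_isomir(am, index)))
        elif am.category == "tRNA":
            trf.append((am, classify_trf(am, index)))
    return truth, iso, trf, cells


def test_planted_modifications_recovered_exactly():
    cfg = SimulationConfig(seed=21, n_cells=4, n_molecules_per_cell=150,
                           collision_free_umis=True, seq_error_rate=0.0,
                           nta_rate=0.35)
    truth, iso, trf, _ = _sim_records(cfg)
    planted = truth.set_index("molecule_id")
    assert iso and trf
    for am, rec in iso:
        row = planted.loc[am.molecule.read_id.rsplit("_", 1)[0]
                          .rsplit(".", 1)[0]]
        assert (rec.shift5, rec.shift3, rec.nta) == \
            (row["shift5"], row["shift3"], row["nta"])
    for am, rec in trf:
        row = planted.loc[am.molecule.read_id.rsplit("_", 1)[0]
                          .rsplit(".", 1)[0]]
        if row["trf_class"]:
            assert rec.klass == row["trf_class"]


def test_summaries_are_proportions():
    cfg = SimulationConfig(seed=22, n_cells=4, n_molecules_per_cell=150,
                           collision_free_umis=True, seq_error_rate=0.0)
    truth, iso, trf, cells = _sim_records(cfg)
    per_day, per_mirna = summarize_isomir([r for _, r in iso], cells)
    classes = ["canonical", "5'-trim", "5'-elong", "3'-trim", "3'-elong",
               "mixed"]
    assert np.allclose(per_day[classes].sum(axis=1), 1.0)
    assert ((per_day["nta_fraction"] >= 0) &
            (per_day["nta_fraction"] <= 1)).all()
    tables = codon_usage([r for _, r in trf], cells)
    for tab in tables.values():
        assert np.allclose(tab.sum(axis=1), 1.0)


def test_all_canonical_summary():
    cfg = SimulationConfig(seed=23, n_cells=3, n_molecules_per_cell=100,
                           collision_free_umis=True, seq_error_rate=0.0,
                           shift5_probs={0: 1.0}, shift3_probs={0: 1.0},
                           nta_rate=0.0)
    truth, iso, _, cells = _sim_records(cfg)
    per_day, _ = summarize_isomir([r for _, r in iso], cells)
    assert (per_day["canonical"] == 1.0).all()
    assert (per_day["nta_fraction"] == 0.0).all()


def test_nta_rate_recovery_binomial():
    """Planted 30% NTA rate recovered within 3 binomial SE at n >= 10^4."""
    cfg = SimulationConfig(seed=24, n_cells=20, n_molecules_per_cell=1500,
                           nta_rate=0.30)
    genome, ann = build_reference(cfg)
    truth = simulate_molecules(cfg, genome, ann)
    mir = truth[truth["biotype"] == "miRNA"]
    assert len(mir) >= 5000
    p = 0.30
    se = np.sqrt(p * (1 - p) / len(mir))
    assert abs((mir["nta"] != "").mean() - p) < 3 * se


def test_planted_codon_trend_recovered():
    """Arg fraction falling 0.4 -> 0.1 across days in tRNA gene choice."""
    weights = {}
    days = ["E3", "E4", "E5", "E6", "E7"]
    for i, day in enumerate(days):
        frac = 0.4 - (0.3 * i / 4)
        # one Arg gene among 8: weight w/(w+7) = frac
        w = 7 * frac / (1 - frac)
        weights[day] = {"Arg": w}
    cfg = SimulationConfig(seed=25, n_cells=25, n_molecules_per_cell=800,
                           trna_aa_day_weights=weights)
    genome, ann = build_reference(cfg)
    truth = simulate_molecules(cfg, genome, ann)
    cells = truth.attrs["cells"].set_index("cell")
    trna = truth[(truth["biotype"] == "tRNA") & ~truth["mito"]].copy()
    trna["day"] = trna["cell"].map(cells["day"])
    trna["aa"] = trna["feature"].str.startswith("trna-0") & \
        trna["feature"].isin(["trna-00"])
    for day, target in [("E3", 0.4), ("E7", 0.1)]:
        sub = trna[trna["day"] == day]
        got = (sub["feature"] == "trna-00").mean()  # trna-00 carries Arg
        se = np.sqrt(target * (1 - target) / len(sub))
        assert abs(got - target) < 3 * se
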