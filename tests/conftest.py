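import pandas as pd
import pytest

from sncatlas import SimulationConfig, emit_dataset
from sncatlas.align import GenomeIndex
from sncatlas.annotate import AnnotationSet, load_gff3
from sncatlas.pipeline import run_pipeline
from sncatlas.simulate import read_fasta


def small_config(**overrides) -> SimulationConfig:
    """Error-free, collision-free conditions for exact-recovery checks."""
    base = dict(seed=3, n_cells=5, n_molecules_per_cell=200,
                collision_free_umis=True, seq_error_rate=0.0, nta_rate=0.3)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    emit_dataset(small_config(), str(out))
    return str(out)


@pytest.fixture(scope="session")
def truth(dataset_dir):
    df = pd.read_csv(f"{dataset_dir}/truth.tsv", sep="\t")
    return df.fillna({"nta": "", "trf_class": ""})


@pytest.fixture(scope="session")
def genome(dataset_dir):
    return read_fasta(f"{dataset_dir}/genome.fa")


@pytest.fixture(scope="session")
def annotations(dataset_dir):
    return AnnotationSet(load_gff3(f"{dataset_dir}/annotations.gff3"))


@pytest.fixture(scope="session")
def index(genome):
    return GenomeIndex(genome)


@pytest.fixture(scope="session")
def pipeline_result(dataset_dir):
    return run_pipeline(dataset_dir)
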