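"""Simulation configuration.

The simulator emulates the read structure of single-cell Small-seq libraries:
each read carries an 8 nt unique molecular identifier (UMI), two fixed filler
bases, the small-RNA insert, and a 3' ligation adapter followed by poly(A)
padding up to the read-length budget.  Per-biotype insert-length modes follow
the canonical small-RNA classes (mature miRNA ~22 nt, piRNA ~30 nt, full
tRNA ~74 nt).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

UMI_LENGTH = 8
#: fixed bases inserted between the UMI and the RNA insert; the preprocessing
#: step discards two bases after UMI extraction, so a constant makes trimming
#: verifiable against planted truth.
FILLER = "CA"

BIOTYPES = ["miRNA", "rRNA", "snoRNA", "snRNA", "tRNA", "piRNA"]
CATCHALL_TRACKS = ["protein_coding", "lncRNA", "repeat", "pseudogene"]

DEFAULT_DAYS = ["E3", "E4", "E5", "E6", "E7"]
DEFAULT_LINEAGES = ["pre-lineage", "ICM", "TE"]

# Qualitative per-day biotype mixture: piRNA and tRNA fractions fall across
# development while miRNA and snoRNA rise; endpoints are free parameters of
# the simulation, interpolated linearly over the configured days.
MIX_START = {
    "miRNA": 0.12, "rRNA": 0.14, "snoRNA": 0.13, "snRNA": 0.05,
    "tRNA": 0.28, "piRNA": 0.20, "other": 0.06, "mito": 0.02,
}
MIX_END = {
    "miRNA": 0.28, "rRNA": 0.18, "snoRNA": 0.22, "snRNA": 0.05,
    "tRNA": 0.12, "piRNA": 0.07, "other": 0.06, "mito": 0.02,
}

AMINO_ACIDS = ["Arg", "Asn", "Glu", "Gly", "Lys", "Leu", "Ser", "Val"]
ANTICODONS = ["ACG", "GTT", "TTC", "GCC", "CTT", "AAG", "AGA", "AAC"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class SizingError(ConfigurationError):
    """Raised when the genome is too short to host the requested features."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_cells: int = 50
    days: list[str] = field(default_factory=lambda: list(DEFAULT_DAYS))
    lineages: list[str] = field(default_factory=lambda: list(DEFAULT_LINEAGES))
    n_batches: int = 2

    genome_length: int = 30_000
    chrm_length: int = 2_000

    # per-biotype planted feature counts
    n_mirna: int = 12
    n_rrna: int = 2
    n_snorna: int = 6
    n_snrna: int = 4
    n_trna: int = 8
    n_pirna: int = 10
    n_protein_coding: int = 3
    n_lncrna: int = 2
    n_repeat: int = 2
    n_pseudogene: int = 2
    n_mt_trna: int = 2
    #: when true, the two repeat records share an identical sequence so that
    #: repeat-derived molecules multi-map (used to exercise remapping).
    duplicate_repeat: bool = False

    # insert geometry (nt)
    mirna_mature_length: int = 22
    pirna_length_range: tuple[int, int] = (26, 32)
    pirna_length_mode: int = 30
    trna_length: int = 74
    fragment_length_range: tuple[int, int] = (18, 40)
    read_length: int = 100

    # molecular ground truth
    n_molecules_per_cell: int = 600
    mean_sequenced_reads: float = 2.0e6

    # isomiR model: probabilities over 5'/3' end shifts in -3..+3 and the
    # non-templated 3' addition (NTA) rate with 1-3 added bases
    shift5_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.84, -1: 0.06, 1: 0.04, -2: 0.03,
                                 2: 0.01, -3: 0.01, 3: 0.01})
    shift3_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.60, 1: 0.12, -1: 0.12, 2: 0.06,
                                 -2: 0.06, 3: 0.02, -3: 0.02})
    nta_rate: float = 0.14
    nta_length_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})

    trf_class_mix: dict[str, float] = field(
        default_factory=lambda: {"five_prime_half": 0.3,
                                 "three_prime_half": 0.3,
                                 "full_length": 0.4})
    #: optional per-day amino-acid weights for tRNA gene choice, e.g.
    #: {"E3": {"Arg": 4.0}, ...}; None means uniform over planted genes.
    trna_aa_day_weights: dict[str, dict[str, float]] | None = None
    add_cca: bool = False

    pcr_duplication_rate: float = 1.0
    seq_error_rate: float = 1e-3
    adapter_sequence: str = "AGATCGGAAGAGC"
    umi_length: int = UMI_LENGTH
    #: collision-free mode assigns per-cell UMIs from a single-substitution
    #: detecting code (pairwise Hamming distance >= 2) so directional
    #: deduplication can never merge distinct molecules.
    collision_free_umis: bool = False

    # lineage structure: designated marker miRNAs get a lineage-dependent
    # expected-count multiplier of 2**marker_log2fc.
    n_markers_per_lineage: int = 2
    marker_log2fc: float = 2.0

    mix_start: dict[str, float] = field(default_factory=lambda: dict(MIX_START))
    mix_end: dict[str, float] = field(default_factory=lambda: dict(MIX_END))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.umi_length != UMI_LENGTH:
            raise ConfigurationError(
                f"umi_length must be {UMI_LENGTH}, got {self.umi_length}")
        for name, probs in [("shift5_probs", self.shift5_probs),
                            ("shift3_probs", self.shift3_probs),
                            ("nta_length_probs", self.nta_length_probs),
                            ("trf_class_mix", self.trf_class_mix)]:
            total = sum(probs.values())
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ConfigurationError(f"{name} probabilities outside [0,1]")
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {total})")
        for name, p in [("nta_rate", self.nta_rate),
                        ("seq_error_rate", self.seq_error_rate)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")
        if any(abs(s) > 3 for s in self.shift5_probs) or \
           any(abs(s) > 3 for s in self.shift3_probs):
            raise ConfigurationError("isomiR shifts limited to -3..+3")
        if self.pcr_duplication_rate < 0:
            raise ConfigurationError("pcr_duplication_rate must be >= 0")
        if not self.adapter_sequence:
            raise ConfigurationError("adapter_sequence must be non-empty")

    def day_mixture(self, day: str) -> dict[str, float]:
        """Linearly interpolated biotype mixture for ``day``."""
        i = self.days.index(day)
        t = i / max(len(self.days) - 1, 1)
        mix = {k: (1 - t) * self.mix_start[k] + t * self.mix_end[k]
               for k in self.mix_start}
        total = sum(mix.values())
        return {k: v / total for k, v in mix.items()}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("shift5_probs", "shift3_probs", "nta_length_probs"):
            if key in data:
                data[key] = {int(k): float(v) for k, v in data[key].items()}
        for key in ("pirna_length_range", "fragment_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
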