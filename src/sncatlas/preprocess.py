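"""UMI extraction and 3' adapter / poly(A) trimming.

The first 8 nt of every read are the UMI, moved into the read identifier
behind an underscore; the following two bases are library filler and are
discarded.  The 3' adapter is then located with a semi-global match allowing
a 10% mismatch rate at minimum overlap 3 and removed together with
everything downstream of it (the poly(A) padding); a read with no adapter
match may instead lose a terminal poly(A) run.  Reads are retained only if
the final insert is 18-81 nt AND at least 10 bases of adapter/poly(A) tail
were removed, which guards against inserts that merely ran off the end of
the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import UMI_LENGTH

UMI_SEPARATOR = "_"
DISCARD_AFTER_UMI = 2
MIN_INSERT = 18
MAX_INSERT = 81
MIN_TAIL = 10
ADAPTER_ERROR_RATE = 0.1
MIN_OVERLAP = 3


@dataclass
class TrimmedRead:
    read_id: str          # original id + "_" + UMI
    umi: str
    insert: str
    trimmed_tail_length: int


@dataclass
class TrimReport:
    """Per-cell accounting; kept + sum(discarded) == input reads."""
    kept: int = 0
    discarded: dict = field(default_factory=lambda: {
        "too_short_read": 0, "insert_too_short": 0, "insert_too_long": 0,
        "tail_too_short": 0})

    @property
    def total(self) -> int:
        return self.kept + sum(self.discarded.values())

    def to_dict(self) -> dict:
        return {"kept": self.kept, "discarded": dict(self.discarded),
                "total": self.total}


def extract_umi(read_id: str, seq: str):
    """Split off the 8 nt UMI (appended to the read id) and drop the two
    filler bases.  Returns ``(new_id, umi, remainder)`` or None for reads of
    10 nt or less."""
    if len(seq) <= UMI_LENGTH + DISCARD_AFTER_UMI:
        return None
    umi = seq[:UMI_LENGTH]
    remainder = seq[UMI_LENGTH + DISCARD_AFTER_UMI:]
    return f"{read_id}{UMI_SEPARATOR}{umi}", umi, remainder


def _find_adapter(seq: str, adapter: str) -> int | None:
    """Leftmost start of a semi-global 3' adapter match.

    The adapter prefix is aligned at every position; a match needs overlap
    >= 3 with at most floor(0.1 * overlap) mismatches and must run to the
    read end or cover the whole adapter (no indels).
    """
    n, m = len(seq), len(adapter)
    for i in range(0, n - MIN_OVERLAP + 1):
        overlap = min(n - i, m)
        budget = int(ADAPTER_ERROR_RATE * overlap)
        mm = 0
        ok = True
        for j in range(overlap):
            if seq[i + j] != adapter[j]:
                mm += 1
                if mm > budget:
                    ok = False
                    break
        if ok:
            return i
    return None


def trim_read(remainder: str, adapter: str):
    """Trim the 3' adapter (and everything after it) or a terminal poly(A)
    run.  Returns ``(insert, tail_length, reason)`` where reason is None for
    a kept read."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    i = _find_adapter(remainder, adapter)
    if i is None:
        # poly(A)-only tail (adapter truncated off the read)
        j = len(remainder)
        while j > 0 and remainder[j - 1] == "A":
            j -= 1
        cut = j if len(remainder) - j >= MIN_OVERLAP else len(remainder)
    else:
        cut = i
    insert = remainder[:cut]
    tail = len(remainder) - cut
    if tail < MIN_TAIL:
        return insert, tail, "tail_too_short"
    if len(insert) < MIN_INSERT:
        return insert, tail, "insert_too_short"
    if len(insert) > MAX_INSERT:
        return insert, tail, "insert_too_long"
    return insert, tail, None


def preprocess_read(read_id: str, seq: str, adapter: str):
    """Full per-read preprocessing.  Returns (TrimmedRead, reason)."""
    ext = extract_umi(read_id, seq)
    if ext is None:
        return None, "too_short_read"
    new_id, umi, remainder = ext
    insert, tail, reason = trim_read(remainder, adapter)
    if reason is not None:
        return None, reason
    return TrimmedRead(new_id, umi, insert, tail), None


def iter_fastq(path: str):
    """Yield (id, sequence) from a FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            yield header[1:].split()[0], seq


def preprocess_fastq(in_path: str, out_path: str, adapter: str) -> TrimReport:
    report = TrimReport()
    with open(out_path, "w") as out:
        for rid, seq in iter_fastq(in_path):
            trimmed, reason = preprocess_read(rid, seq, adapter)
            if trimmed is None:
                report.discarded[reason] += 1
                continue
            report.kept += 1
            out.write(f"@{trimmed.read_id}\n{trimmed.insert}\n+\n"
                      f"{'I' * len(trimmed.insert)}\n")
    return report


def umi_from_read_id(read_id: str) -> str:
    return read_id.rsplit(UMI_SEPARATOR, 1)[1]
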