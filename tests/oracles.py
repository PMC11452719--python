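"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each rule with naive enumeration (per-position
scanning, fixed-point closures, plain-Python sums) rather than reusing any
code path from the package.
"""

from __future__ import annotations

import math

from scipy.special import stdtr

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


# ----------------------------------------------------------------- aligner

def _all_placements(read: str, genome: dict, max_mm: int):
    """Every placement with <= max_mm substitutions, by scanning each
    position on each strand with early exit."""
    out = []
    L = len(read)
    read_rc = rc(read)
    for chrom, seq in genome.items():
        n = len(seq)
        for oriented, strand in ((read, "+"), (read_rc, "-")):
            for pos in range(n - L + 1):
                mm = 0
                for j in range(L):
                    if seq[pos + j] != oriented[j]:
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    out.append((chrom, pos, strand, mm))
    return out


def _effective_mm(read: str, genome: dict, chrom: str, pos: int,
                  strand: str) -> int:
    """Mismatch count with the final sequenced base forgiven."""
    L = len(read)
    seg = genome[chrom][pos:pos + L]
    oriented = read if strand == "+" else rc(read)
    eff = 0
    for j in range(L):
        if oriented[j] != seg[j]:
            read_pos = j if strand == "+" else L - 1 - j
            if read_pos != L - 1:
                eff += 1
    return eff


def oracle_map(read: str, genome: dict):
    """Reference implementation of full-length mapping + clip rescue.

    Returns (status, placements) where each placement is
    (chrom, pos, strand, effective_mm, clip5, clip3).
    """
    status, hits = _oracle_full(read, genome)
    if status != "unmapped":
        return status, hits
    return _oracle_rescue(read, genome)


def _oracle_full(read: str, genome: dict):
    hits = _all_placements(read, genome, 2)
    if not hits:
        return "unmapped", []
    best = min(h[3] for h in hits)
    stratum = [h for h in hits if h[3] == best]
    if len(stratum) > 50:
        return "suppressed", []
    L = len(read)
    kept = []
    for chrom, pos, strand, _ in stratum:
        eff = _effective_mm(read, genome, chrom, pos, strand)
        if L < 20 and eff >= 1:
            continue
        if 20 <= L <= 40 and eff >= 2:
            continue
        kept.append((chrom, pos, strand, eff, 0, 0))
    if not kept:
        return "unmapped", []
    return "mapped", sorted(kept)


def _oracle_rescue(read: str, genome: dict):
    for end in ("3", "5"):
        for k in (1, 2, 3):
            sub = read[:-k] if end == "3" else read[k:]
            if len(sub) < 17:
                break
            hits = _all_placements(sub, genome, 1)
            if not hits:
                continue
            best = min(h[3] for h in hits)
            stratum = [h for h in hits if h[3] == best]
            if len(stratum) > 50:
                return "suppressed", []
            clip5, clip3 = (0, k) if end == "3" else (k, 0)
            out = []
            for chrom, pos, strand, _ in stratum:
                eff = _effective_mm(sub, genome, chrom, pos, strand)
                out.append((chrom, pos, strand, eff, clip5, clip3))
            return "mapped", sorted(out)
    return "unmapped", []


# ------------------------------------------------------------- directional

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def oracle_directional_count(counts: dict[str, int]) -> int:
    """Number of molecules under the directional rule, computed as a
    fixed-point closure from each remaining count maximum."""
    nodes = sorted(counts, key=lambda u: (-counts[u], u))
    unassigned = set(nodes)
    n_clusters = 0
    for seed in nodes:
        if seed not in unassigned:
            continue
        unassigned.discard(seed)
        comp = {seed}
        changed = True
        while changed:
            changed = False
            for a in sorted(comp):
                for b in sorted(unassigned):
                    if _hamming(a, b) == 1 and \
                            counts[a] >= 2 * counts[b] - 1:
                        comp.add(b)
                        unassigned.discard(b)
                        changed = True
        n_clusters += 1
    return n_clusters


# -------------------------------------------------------------------- tRF

def oracle_trf_class(length: int, shift5: int, shift3: int) -> str:
    """Literal restatement of the published fragment rules."""
    is_short = length < 50
    is_long = length > 50
    shifted5 = shift5 <= -10
    shifted3 = shift3 <= -10
    if is_short and shifted3 and not shifted5:
        return "five_prime_half"
    if is_short and shifted5 and not shifted3:
        return "three_prime_half"
    if is_long and not shifted5 and not shifted3:
        return "full_length"
    return "unclassified"


# ----------------------------------------------------------------- Pearson

def oracle_pearson_onesided(x, y):
    """Plain-Python Pearson r and one-sided negative/positive p-values via
    the regularised incomplete beta (scipy.special.stdtr)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    df = n - 2
    if abs(r) >= 1.0:
        return r, (0.0 if r < 0 else 1.0), (0.0 if r > 0 else 1.0)
    t = r * math.sqrt(df) / math.sqrt(1 - r * r)
    p_neg = float(stdtr(df, t))
    return r, p_neg, 1.0 - p_neg
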