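"""Mapped-read handling: coverage tracks, duplicate capping and MNase
cut-site tetramer statistics.

A read certifies the fragment's 5' cleavage point: for a + read the cut
sits immediately 5' of ``start``, for a - read immediately 3' of
``end - 1`` (i.e. at coordinate ``end``).  The tetramer spanning a cut at
inter-base coordinate i is ``genome[i-2:i+2]``, read on the fragment's
strand, and is collapsed with its reverse complement into one of 136
canonical pairs.  Enrichment over the genomic 4-mer background follows
the construction of published MNase cut-preference tables: ratio =
(observed/sites) / background probability with a two-sided binomial
p-value, floored at 1e-18.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DimensionError
from .sequences import (
    N_PAIRS,
    PAIR_INDEX_OF_CODE,
    PAIR_LABELS,
    REVCOMP_CODE,
    encode_sequence,
    tetramer_codes,
)

logger = logging.getLogger(__name__)

P_VALUE_FLOOR = 1e-18


class ReadAlignment(NamedTuple):
    """A mapped read interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class CoverageTrack:
    """Per-bp non-negative coverage per chromosome."""

    data: dict[str, np.ndarray]
    normalized: bool = False
    total_reads: int = 0


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def _reference_length(cigar: str) -> int:
    length = 0
    for num, op in _CIGAR_RE.findall(cigar):
        if op in _REF_CONSUMING:
            length += int(num)
    return length


def read_alignments(path, fmt: str | None = None,
                    genome_lengths: dict[str, int] | None = None,
                    strict: bool = False) -> list[ReadAlignment]:
    """Parse mapped reads from BED6 or SAM text into ReadAlignments.

    ``fmt`` is inferred from the extension when omitted.  Malformed lines
    and out-of-range/unknown-chromosome records are counted and logged;
    with ``strict=True`` they raise instead.
    """
    path = str(path)
    if fmt is None:
        fmt = "SAM" if path.endswith(".sam") else "BED"
    fmt = fmt.upper()
    if fmt not in ("BED", "SAM"):
        raise ConfigError(f"unknown alignment format {fmt!r}")
    reads: list[ReadAlignment] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser", "@")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = fields[5] if len(fields) >= 6 else "+"
                else:  # SAM text
                    flag = int(fields[1])
                    if flag & 4:  # unmapped
                        continue
                    chrom = fields[2]
                    start = int(fields[3]) - 1  # SAM is 1-based
                    end = start + _reference_length(fields[5])
                    strand = "-" if flag & 16 else "+"
                if strand not in "+-" or start < 0 or end <= start:
                    raise ValueError("bad interval")
                if genome_lengths is not None:
                    if chrom not in genome_lengths:
                        raise ValueError(f"unknown chromosome {chrom!r}")
                    if end > genome_lengths[chrom]:
                        raise ValueError("read beyond chromosome end")
            except (ValueError, IndexError) as exc:
                n_bad += 1
                if strict:
                    raise ConfigError(f"{path}:{lineno}: {exc}") from exc
                continue
            reads.append(ReadAlignment(chrom, start, end, strand))
    if n_bad:
        logger.warning("%s: skipped %d malformed/out-of-range lines", path, n_bad)
    if not reads:
        logger.warning("%s: no alignments parsed", path)
    return reads


def cap_duplicates(reads: Iterable[ReadAlignment], k: float = 5.0,
                   absolute_cap: int | None = None) -> list[ReadAlignment]:
    """Cap the multiplicity of identical-coordinate reads.

    Reads sharing (chrom, start, strand) above the cap are dropped,
    keeping the first occurrences in input order (deterministic).  The cap
    is ``ceil(mean + k * SD)`` of the multiplicity distribution (default
    k = 5), or ``absolute_cap`` when given.  This removes largely
    over-represented reads — PCR amplification artifacts.
    """
    reads = list(reads)
    if not reads:
        return reads
    counts = Counter((r.chrom, r.start, r.strand) for r in reads)
    if absolute_cap is not None:
        cap = int(absolute_cap)
    else:
        mult = np.array(list(counts.values()), dtype=float)
        cap = int(np.ceil(mult.mean() + k * mult.std()))
    cap = max(cap, 1)
    seen: Counter = Counter()
    out = []
    for r in reads:
        key = (r.chrom, r.start, r.strand)
        seen[key] += 1
        if seen[key] <= cap:
            out.append(r)
    if len(out) < len(reads):
        logger.info("cap_duplicates: dropped %d reads above cap %d",
                    len(reads) - len(out), cap)
    return out


def extend_reads(reads: Iterable[ReadAlignment], length: int = 147,
                 genome_lengths: dict[str, int] | None = None) -> list[ReadAlignment]:
    """Extend single-end reads to the expected fragment length.

    A short sequencing read certifies only the fragment's 5' end; for
    fragment-level coverage (nucleosome footprints) each read is extended
    to ``length`` bp in its 3' direction, clipped at chromosome ends when
    lengths are provided.  Reads already at least ``length`` long are
    returned unchanged.
    """
    if length <= 0:
        raise ConfigError("extension length must be positive")
    out = []
    for r in reads:
        if r.end - r.start >= length:
            out.append(r)
            continue
        if r.strand == "+":
            start, end = r.start, r.start + length
        else:
            start, end = r.end - length, r.end
        if genome_lengths is not None:
            L = genome_lengths.get(r.chrom)
            if L is not None:
                start, end = max(start, 0), min(end, L)
        if end > start:
            out.append(ReadAlignment(r.chrom, start, end, r.strand))
    return out


def build_coverage(reads: Iterable[ReadAlignment],
                   genome_lengths: dict[str, int],
                   on_out_of_bounds: str = "error") -> CoverageTrack:
    """Raw per-bp coverage: value at p = number of reads containing p."""
    if on_out_of_bounds not in ("error", "skip"):
        raise ConfigError("on_out_of_bounds must be 'error' or 'skip'")
    diffs = {chrom: np.zeros(length + 1) for chrom, length in genome_lengths.items()}
    n_used = 0
    for r in reads:
        arr = diffs.get(r.chrom)
        if arr is None or r.start < 0 or r.end > len(arr) - 1:
            if on_out_of_bounds == "error":
                raise DimensionError(f"read {r} outside genome")
            continue
        arr[r.start] += 1
        arr[r.end] -= 1
        n_used += 1
    data = {chrom: np.cumsum(d[:-1]) for chrom, d in diffs.items()}
    return CoverageTrack(data=data, normalized=False, total_reads=n_used)


def rpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale coverage to reads per million: value * 1e6 / total_reads."""
    if track.normalized:
        raise ConfigError("track is already r.p.m.-normalized")
    if track.total_reads <= 0:
        raise ConfigError("cannot normalize a track with zero reads")
    factor = 1e6 / track.total_reads
    data = {chrom: v * factor for chrom, v in track.data.items()}
    return CoverageTrack(data=data, normalized=True, total_reads=track.total_reads)


def _cut_positions(reads: Iterable[ReadAlignment], end: str):
    """Yield (chrom, cut coordinate, is_minus) for the requested read end(s)."""
    if end not in ("5p", "3p", "both"):
        raise ConfigError("end must be one of '5p', '3p', 'both'")
    for r in reads:
        five = r.start if r.strand == "+" else r.end
        three = r.end if r.strand == "+" else r.start
        if end in ("5p", "both"):
            yield r.chrom, five, r.strand == "-"
        if end in ("3p", "both"):
            # the 3' end is reported on the opposite strand orientation
            yield r.chrom, three, r.strand == "+"


def extract_cut_tetramers(reads: Iterable[ReadAlignment], genome: dict[str, str],
                          end: str = "5p"):
    """Count cut-site tetramers (canonical pairs) at read ends.

    For a + read starting at s the tetramer is ``genome[s-2:s+2]``; for a
    - read with 5' fragment end at e it is the reverse complement of
    ``genome[e-2:e+2]``.  Sites within 2 bp of a chromosome edge or whose
    window contains N are skipped and tallied.

    Returns ``(counts, n_sites, n_skipped)`` where ``counts`` maps pair
    label -> observed count and ``n_sites`` is the number of counted sites.
    """
    codes = {chrom: encode_sequence(seq) for chrom, seq in genome.items()}
    tet = {chrom: tetramer_codes(c) if len(c) >= 4 else np.empty(0, dtype=np.int64)
           for chrom, c in codes.items()}
    counts = np.zeros(N_PAIRS, dtype=np.int64)
    n_sites = n_skipped = 0
    by_chrom: dict[str, list] = {}
    for chrom, pos, is_minus in _cut_positions(reads, end):
        by_chrom.setdefault(chrom, []).append((pos, is_minus))
    for chrom, items in by_chrom.items():
        if chrom not in tet:
            raise DimensionError(f"chromosome {chrom!r} missing from genome")
        t = tet[chrom]
        L = len(codes[chrom])
        pos = np.array([p for p, _ in items], dtype=np.int64)
        minus = np.array([m for _, m in items], dtype=bool)
        ok = (pos >= 2) & (pos <= L - 2)
        n_skipped += int((~ok).sum())
        pos, minus = pos[ok], minus[ok]
        tc = t[pos - 2]  # tetramer spanning the cut: genome[pos-2:pos+2]
        valid = tc >= 0
        n_skipped += int((~valid).sum())
        tc, minus = tc[valid], minus[valid]
        tc = np.where(minus, REVCOMP_CODE[tc], tc)
        counts += np.bincount(PAIR_INDEX_OF_CODE[tc], minlength=N_PAIRS)
        n_sites += len(tc)
    return (
        {PAIR_LABELS[i]: int(c) for i, c in enumerate(counts) if c > 0},
        n_sites,
        n_skipped,
    )


def genome_background(genome: dict[str, str]) -> dict[str, float]:
    """Genomic 4-mer background probability per canonical pair.

    All overlapping forward-strand 4-mers are counted, reverse-complement
    counts added by symmetry, collapsed to the 136 pairs and normalized to
    sum to 1.
    """
    counts = np.zeros(N_PAIRS, dtype=np.int64)
    for seq in genome.values():
        codes = encode_sequence(seq)
        if len(codes) < 4:
            continue
        tc = tetramer_codes(codes)
        tc = tc[tc >= 0]
        counts += np.bincount(PAIR_INDEX_OF_CODE[tc], minlength=N_PAIRS)
        counts += np.bincount(PAIR_INDEX_OF_CODE[REVCOMP_CODE[tc]], minlength=N_PAIRS)
    total = counts.sum()
    if total == 0:
        raise DimensionError("genome contains no unambiguous 4-mers")
    return {PAIR_LABELS[i]: counts[i] / total for i in range(N_PAIRS)}


_EXACT_TEST_MAX_N = 100_000


def _binom_p_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided binomial test; exact for moderate n, normal approximation
    with continuity correction for large n."""
    if n <= _EXACT_TEST_MAX_N:
        return stats.binomtest(k, n, p0).pvalue
    mean = n * p0
    sd = np.sqrt(n * p0 * (1.0 - p0))
    z = (abs(k - mean) - 0.5) / sd
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def tetramer_enrichment(counts: dict[str, int], n_sites: int,
                        background: dict[str, float]) -> pd.DataFrame:
    """Cut-site tetramer enrichment statistics, sorted by ratio (desc).

    ratio = (observed / n_sites) / background probability; p_value is a
    two-sided binomial test of the observed count against the background,
    floored at 1e-18 (mirroring "< 10^-18" reporting).  Pairs with zero
    background are flagged with NaN ratio.
    """
    if n_sites <= 0:
        raise ConfigError("n_sites must be positive")
    rows = []
    for label in PAIR_LABELS:
        p0 = background.get(label, 0.0)
        k = int(counts.get(label, 0))
        if p0 <= 0.0:
            ratio = float("nan")
            pval = float("nan")
            if k:
                logger.warning("pair %s observed %d times but absent from background",
                               label, k)
        else:
            ratio = (k / n_sites) / p0
            pval = max(_binom_p_two_sided(k, n_sites, p0), P_VALUE_FLOOR)
        rows.append((label, k, n_sites, p0, ratio, pval))
    df = pd.DataFrame(rows, columns=["pair_label", "observed", "n_sites",
                                     "background_prob", "ratio", "p_value"])
    return df.sort_values("ratio", ascending=False, ignore_index=True)
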