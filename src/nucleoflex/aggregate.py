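"""Metagene aggregation of per-bp tracks around genomic anchors.

Averages a signal in gene orientation around TSS/TTS anchors (or,
strandless, around region midpoints): offset +x always means x bp
downstream of the anchor in the direction of transcription.  Positions
falling outside the chromosome are ignored and per-offset counts
reported, so profiles near chromosome ends remain unbiased averages.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple

import numpy as np

from .errors import ConfigError
from .regions import Region

logger = logging.getLogger(__name__)


class Anchor(NamedTuple):
    chrom: str
    position: int
    strand: str


def tss_tts_anchors(genes, which: str = "tss") -> list[Anchor]:
    """TSS or TTS anchors from gene records (0-based half-open, stranded).

    The TSS is the 5' end of the gene in strand orientation (start for +,
    end - 1 for -), the TTS the 3' end.
    """
    if which not in ("tss", "tts"):
        raise ConfigError("which must be 'tss' or 'tts'")
    anchors = []
    for g in genes:
        chrom, start, end, strand = g.chrom, g.start, g.end, g.strand
        five, three = (start, end - 1) if strand == "+" else (end - 1, start)
        pos = five if which == "tss" else three
        anchors.append(Anchor(chrom, int(pos), strand))
    return anchors


def _as_dict(track):
    if hasattr(track, "data"):
        return track.data
    if isinstance(track, np.ndarray):
        return {"seq": track}
    return track


def anchor_profile(track, anchors: Iterable[Anchor], flank: int = 1000):
    """Mean signal per offset in [-flank, +flank] around stranded anchors.

    Minus-strand windows are reversed so positive offsets point
    downstream in gene orientation.  Returns ``(mean, counts)`` arrays of
    length ``2 * flank + 1``; offsets with no in-bounds data are NaN in
    ``mean``.  Anchors whose whole window misses the chromosome are
    skipped and tallied.
    """
    if flank <= 0:
        raise ConfigError("flank must be positive")
    data = _as_dict(track)
    width = 2 * flank + 1
    total = np.zeros(width)
    counts = np.zeros(width, dtype=np.int64)
    n_skipped = 0
    for a in anchors:
        values = data.get(a.chrom)
        if values is None:
            n_skipped += 1
            continue
        n = len(values)
        lo, hi = a.position - flank, a.position + flank + 1
        clo, chi = max(lo, 0), min(hi, n)
        if chi <= clo:
            n_skipped += 1
            continue
        window = np.full(width, np.nan)
        window[clo - lo:chi - lo] = values[clo:chi]
        if a.strand == "-":
            window = window[::-1]
        good = np.isfinite(window)
        total[good] += window[good]
        counts += good
    if n_skipped:
        logger.warning("anchor_profile: skipped %d anchors with empty windows", n_skipped)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return mean, counts


def region_midpoint_profile(track, regions: Iterable[Region], flank: int = 1000):
    """As :func:`anchor_profile` with strandless anchors at region midpoints
    (``floor((start + end) / 2)``)."""
    anchors = [Anchor(r.chrom, (r.start + r.end) // 2, "+") for r in regions]
    return anchor_profile(track, anchors, flank=flank)


def minmax_scale(vector: np.ndarray) -> np.ndarray:
    """Scale a vector to [0, 1]: ``(v - min) / (max - min)``.

    NaNs are preserved; a vector without two distinct finite values has no
    defined scaling and raises.
    """
    v = np.asarray(vector, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2 or np.isclose(finite.min(), finite.max()):
        raise ConfigError("min-max scaling undefined for (near-)constant vectors")
    return (v - finite.min()) / (finite.max() - finite.min())
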