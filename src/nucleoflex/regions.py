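"""Coverage-derived regions and nucleosome calls.

Low-coverage regions (LRs) are genomic segments whose MNase coverage is
non-zero but anomalously low — the mark of extensive nuclease degradation.
Common low regions (CLRs) are low in both the naked-DNA and nucleosomal
samples.  Nucleosomes are called as 147 bp footprints centred on peaks of
the (FFT-smoothed, optionally bias-corrected) nucleosomal coverage and
classified as well-positioned or fuzzy from peak height and footprint
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DimensionError

logger = logging.getLogger(__name__)

FOOTPRINT = 147
HALF_UP = 73    # footprint = [dyad - 73, dyad + 74), dyad at offset 73


@dataclass(frozen=True)
class Region:
    """A scored genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mean_signal: float = float("nan")
    kind: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise DimensionError(f"empty region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NucleosomeCall:
    """A called nucleosome: dyad plus a fixed 147 bp footprint."""

    chrom: str
    dyad: int
    height_score: float
    cls: str = ""

    @property
    def start(self) -> int:
        return self.dyad - HALF_UP

    @property
    def end(self) -> int:
        return self.dyad + (FOOTPRINT - HALF_UP)


def _as_dict(track):
    """Accept a CoverageTrack, a {chrom: array} dict, or a bare array."""
    if hasattr(track, "data"):
        return track.data
    if isinstance(track, np.ndarray):
        return {"seq": track}
    return track


def _runs(mask: np.ndarray):
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    return list(zip(np.flatnonzero(padded == 1), np.flatnonzero(padded == -1)))


def detect_lr(track, q: float = 0.05, min_len: int = 50, merge_gap: int = 20,
              kind: str = "LR") -> list[Region]:
    """Low-coverage regions: non-zero coverage at or below the per-chromosome
    ``q``-quantile of non-zero values.

    Zero-coverage positions never qualify (they carry no evidence of
    degradation, only of absent data), but runs separated by a gap shorter
    than ``merge_gap`` are merged, so short zero stretches inside a
    degraded segment do not split it.  Runs shorter than ``min_len`` after
    merging are dropped.

    Edge case (pinned by test): an all-equal positive chromosome has its
    q-quantile equal to the constant, so the whole chromosome qualifies as
    one LR.
    """
    if not 0.0 < q < 1.0:
        raise ConfigError("quantile must lie in (0, 1)")
    out = []
    for chrom, values in _as_dict(track).items():
        values = np.asarray(values, dtype=float)
        nz = values[values > 0]
        if nz.size == 0:
            logger.warning("chromosome %s has all-zero coverage; no LRs", chrom)
            continue
        thr = np.quantile(nz, q)
        mask = (values > 0) & (values <= thr)
        runs = _runs(mask)
        merged = []
        for start, end in runs:
            # bridge only short zero-coverage gaps: a gap between candidate
            # runs holds either zeros or above-threshold positions, and
            # merging across high coverage would join unrelated segments
            if (merged and start - merged[-1][1] < merge_gap
                    and values[merged[-1][1]:start].max() <= thr):
                merged[-1][1] = end
            else:
                merged.append([start, end])
        for start, end in merged:
            if end - start >= min_len:
                seg = values[start:end]
                out.append(Region(chrom=chrom, start=int(start), end=int(end),
                                  mean_signal=float(seg.mean()), kind=kind))
    return out


def common_lr(lr_a: list[Region], lr_b: list[Region], min_len: int = 50) -> list[Region]:
    """Base-pair intersection of two region sets (CLRs).

    Inputs must each be non-overlapping; fragments >= ``min_len`` are kept.
    Commutative, and the result is contained in both inputs.
    """
    by_chrom_a, by_chrom_b = {}, {}
    for r in lr_a:
        by_chrom_a.setdefault(r.chrom, []).append(r)
    for r in lr_b:
        by_chrom_b.setdefault(r.chrom, []).append(r)
    out = []
    for chrom in sorted(set(by_chrom_a) & set(by_chrom_b)):
        a = sorted(by_chrom_a[chrom], key=lambda r: r.start)
        b = sorted(by_chrom_b[chrom], key=lambda r: r.start)
        i = j = 0
        while i < len(a) and j < len(b):
            start = max(a[i].start, b[j].start)
            end = min(a[i].end, b[j].end)
            if end - start >= min_len:
                parts = [x.mean_signal for x in (a[i], b[j]) if np.isfinite(x.mean_signal)]
                mean = float(np.mean(parts)) if parts else float("nan")
                out.append(Region(chrom=chrom, start=start, end=end,
                                  mean_signal=mean, kind="CLR"))
            if a[i].end <= b[j].end:
                i += 1
            else:
                j += 1
    return out


def correct_bias(nuc_track, naked_track, alpha: float = 0.5, mode: str = "log2"):
    """Correct nucleosomal coverage for intrinsic MNase sequence bias using
    the naked-DNA degradation profile as background.

    Both tracks must be r.p.m.-normalized over the same genome.  Default is
    the symmetric log-ratio ``log2((nuc + alpha) / (naked + alpha))`` with
    pseudocount ``alpha`` (r.p.m.); ``mode="ratio"`` returns the plain
    ratio.  Positions where both signals are zero come out as 0 (log mode)
    or 1 (ratio mode) by construction.  Returns ``{chrom: ndarray}``.
    """
    nuc, naked = _as_dict(nuc_track), _as_dict(naked_track)
    for t, name in ((nuc_track, "nucleosomal"), (naked_track, "naked")):
        if hasattr(t, "normalized") and not t.normalized:
            raise ConfigError(f"{name} track must be r.p.m.-normalized before correction")
    if set(nuc) != set(naked):
        raise DimensionError("tracks cover different chromosomes")
    if mode not in ("log2", "ratio"):
        raise ConfigError(f"unknown correction mode {mode!r}")
    out = {}
    for chrom in nuc:
        a, b = np.asarray(nuc[chrom], float), np.asarray(naked[chrom], float)
        if a.shape != b.shape:
            raise DimensionError(f"chromosome {chrom} length mismatch")
        ratio = (a + alpha) / (b + alpha)
        out[chrom] = np.log2(ratio) if mode == "log2" else ratio
    return out


def fft_smooth(track, keep_fraction: float = 0.02):
    """Low-pass smooth a per-bp track by discarding high Fourier components.

    Per chromosome of length n, the lowest ``floor(keep_fraction * n / 2)``
    positive frequencies (plus the DC term, hence also their conjugates)
    are retained and everything else zeroed before inverting.  The output
    is real and the track mean is preserved exactly.  ``keep_fraction = 1``
    is the identity; chromosomes shorter than 3 positions are returned
    unchanged.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ConfigError("keep_fraction must lie in (0, 1]")
    out = {}
    chroms = _as_dict(track)
    for chrom, values in chroms.items():
        v = np.asarray(values, dtype=float)
        n = len(v)
        if n < 3:
            out[chrom] = v.copy()
            continue
        spectrum = np.fft.rfft(v)
        kmax = max(1, int(np.floor(keep_fraction * (n // 2))))
        spectrum[kmax + 1:] = 0.0
        out[chrom] = np.fft.irfft(spectrum, n=n)
    if isinstance(track, np.ndarray):
        return out["seq"]
    return out


def call_nucleosomes(smoothed, height_threshold_quantile: float = 0.25,
                     raw=None) -> list[NucleosomeCall]:
    """Call nucleosome dyads at strict local maxima of the smoothed track.

    A peak is kept if its smoothed value exceeds the
    ``height_threshold_quantile`` of all chromosome values.  The call's
    ``height_score`` is the empirical quantile rank of the peak value
    within its chromosome (in [0, 1]).  Footprints that would be clipped
    at a chromosome edge are dropped.  ``raw`` is accepted for signature
    compatibility and ignored (scores are defined on the smoothed track).
    """
    if not 0.0 <= height_threshold_quantile < 1.0:
        raise ConfigError("height_threshold_quantile must lie in [0, 1)")
    calls = []
    for chrom, values in _as_dict(smoothed).items():
        v = np.asarray(values, dtype=float)
        n = len(v)
        if n < 3:
            continue
        thr = np.nanquantile(v, height_threshold_quantile)
        interior = v[1:-1]
        peaks = np.flatnonzero((interior > v[:-2]) & (interior > v[2:])) + 1
        peaks = peaks[v[peaks] > thr]
        sorted_vals = np.sort(v[np.isfinite(v)])
        for dyad in peaks:
            if dyad - HALF_UP < 0 or dyad + (FOOTPRINT - HALF_UP) > n:
                continue
            rank = np.searchsorted(sorted_vals, v[dyad], side="left")
            calls.append(NucleosomeCall(chrom=chrom, dyad=int(dyad),
                                        height_score=rank / len(sorted_vals)))
    return calls


def peak_contrast(smoothed: np.ndarray, dyad: int, scale: float) -> float:
    """Sharpness of a called peak: its height above the mean signal at the
    two footprint edges, normalized by the chromosome's dynamic range
    (10th-90th percentile).  A well-defined nucleosome peak drops towards
    the flanking linkers within +-74 bp; a delocalized (fuzzy) cluster
    forms a broad plateau whose edges are still high, giving low contrast.
    """
    if scale <= 0:
        return 0.0
    n = len(smoothed)
    left = smoothed[max(dyad - 74, 0)]
    right = smoothed[min(dyad + 74, n - 1)]
    return float((smoothed[dyad] - 0.5 * (left + right)) / scale)


def classify_calls(calls: list[NucleosomeCall], smoothed=None,
                   overlap_max: int = 50, h_min: float = 0.4,
                   contrast_min: float = 0.2) -> list[NucleosomeCall]:
    """Label calls well-positioned or fuzzy.

    A call is fuzzy when any of the delocalization signatures fires:
    its footprint overlaps a neighbouring call's by more than
    ``overlap_max`` bp (both members are fuzzy), its height score falls
    below ``h_min``, or — when the ``smoothed`` track is provided — its
    peak contrast (see :func:`peak_contrast`) falls below
    ``contrast_min``.  Remaining calls are well-positioned.
    """
    tracks = _as_dict(smoothed) if smoothed is not None else None
    by_chrom: dict[str, list[NucleosomeCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    out = []
    for chrom in by_chrom:
        group = sorted(by_chrom[chrom], key=lambda c: c.dyad)
        fuzzy = [False] * len(group)
        for i in range(len(group) - 1):
            overlap = group[i].end - group[i + 1].start
            if overlap > overlap_max:
                fuzzy[i] = fuzzy[i + 1] = True
        if tracks is not None and chrom in tracks:
            v = np.asarray(tracks[chrom], dtype=float)
            finite = v[np.isfinite(v)]
            scale = float(np.quantile(finite, 0.9) - np.quantile(finite, 0.1))
            for i, c in enumerate(group):
                if peak_contrast(v, c.dyad, scale) < contrast_min:
                    fuzzy[i] = True
        for c, is_fuzzy in zip(group, fuzzy):
            if is_fuzzy or c.height_score < h_min:
                out.append(replace(c, cls="fuzzy"))
            else:
                out.append(replace(c, cls="well-positioned"))
    return out
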