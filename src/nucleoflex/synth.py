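"""Ground-truth generator: synthetic genomes and sequence-biased MNase
digestion, replacing deposited sequencing data for desk-scale testing.

The generator emulates the statistical structure of a paired MNase-seq
experiment on yeast-like chromatin:

* a synthetic genome with non-overlapping genes, each flanked by a
  nucleosome-depleted-region (NDR) cassette of poly(dA:dT)-like sequence
  upstream of the TSS and downstream of the TTS;
* planted nucleosome dyads — phased ("sharp") arrays over gene bodies,
  delocalized low-occupancy ("jittered") dyads in intergenic background;
* a digestion simulator: cuts fall as a Poisson process over inter-base
  positions with intensity proportional to a tetramer cut-weight map
  (endo- and exonucleolytic preferences collapsed into one map),
  attenuated by ``protection`` inside nucleosome footprints.  Fragments
  are the intervals between consecutive cuts of one digestion pass,
  size-selected to ``fragment_range`` (~150 bp mononucleosome band), ends
  trimmed inward by a geometric number of bases re-weighted by the same
  map (exonuclease nibbling), and sequenced as 54 bp single-end reads
  from the fragment 5' end on a uniformly chosen strand.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from ``SimConfig.seed``; outputs are fully deterministic given the seed.

What this does NOT model: sequencing errors, PCR duplicates, mappability,
chromatin remodellers, or any coupling between nucleosome placement and
the underlying sequence other than the planted NDRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError
from .mnase import ReadAlignment
from .regions import FOOTPRINT, HALF_UP, NucleosomeCall, Region
from .sequences import (
    N_PAIRS,
    PAIR_INDEX_OF_CODE,
    PAIR_LABELS,
    REVCOMP_CODE,
    encode_sequence,
    tetramer_codes,
)

logger = logging.getLogger(__name__)

READ_LENGTH = 54


class GeneModel(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str
    name: str


class Dyad(NamedTuple):
    chrom: str
    pos: int
    cls: str  # "sharp" | "jittered"


def default_cut_weights() -> dict[str, float]:
    """Default per-pair cut weights: A/T-centred tetramers are preferred.

    The qualitative ordering follows published MNase preference tables —
    tetramers with a central TA step strongest, then AT, then AA/TT —
    with everything else at baseline.  Endo- and exonucleolytic
    preferences are collapsed into this single map, so A/T-rich tracts
    are both preferred primary cut sites and preferentially degraded.
    """
    central_weight = {"TA": 8.0, "AT": 6.0, "AA": 3.0, "TT": 3.0}
    weights = {}
    for label in PAIR_LABELS:
        tet = label[:4]
        weights[label] = central_weight.get(tet[1:3], 1.0)
    return weights


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    genome_length: int = 60_000
    gc: float = 0.39                    # yeast-like genomic GC
    gc_amplitude: float = 0.0           # sinusoidal regional GC variation
    gc_period: int = 500                # period of the GC wave (bp)
    n_genes: int = 30
    gene_length: int = 1_000            # compressed gene-dense toy genome
    ndr_length: int = 200               # promoter/terminator-scale NDR tract
    ndr_motif: str = "A"                # tiled to ndr_length: homopolymeric poly(dA:dT) tract
    nucleosome_spacing: int = 165       # 147 bp core + ~18 bp linker
    jitter: int = 40                    # +- delocalization of fuzzy dyads
    fuzzy_occupancy: float = 0.4        # fraction of cells occupying a fuzzy dyad
    cut_weights: dict[str, float] = field(default_factory=default_cut_weights)
    protection: float = 0.05            # cut-rate multiplier inside footprints
    fragment_range: tuple[int, int] = (120, 180)
    exo_trim_mean: float = 2.0          # mean exonucleolytic end trim (bp)
    digestion_rate_naked: float = 1.0 / 150.0     # mean cuts per bp, naked DNA
    digestion_rate_chromatin: float = 1.0 / 25.0  # linkers digested to completion
    n_fragments: int = 200_000
    seed: int = 0
    chrom_name: str = "chrS"

    def __post_init__(self):
        if not 0.0 < self.gc < 1.0:
            raise ConfigError("gc must lie in (0, 1)")
        if not 0.0 <= self.protection <= 1.0:
            raise ConfigError("protection must lie in [0, 1]")
        fmin, fmax = self.fragment_range
        if not 0 < fmin < fmax:
            raise ConfigError("fragment_range must satisfy 0 < min < max")
        if fmin < READ_LENGTH:
            raise ConfigError(f"fragments must be at least {READ_LENGTH} bp")
        if any(w <= 0 for w in self.cut_weights.values()):
            raise ConfigError("cut weights must be positive")
        if self.nucleosome_spacing < FOOTPRINT:
            raise ConfigError("nucleosome_spacing must be >= 147")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside synthetic reads."""

    genes: list[GeneModel] = field(default_factory=list)
    ndrs: list[Region] = field(default_factory=list)
    dyads: list[Dyad] = field(default_factory=list)
    cut_weights: dict[str, float] = field(default_factory=dict)
    end_pair_counts: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome generation and nucleosome placement
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig):
    """Synthetic genome + gene annotation + planted NDR cassettes.

    Background sequence is i.i.d. at the configured GC; genes are placed
    non-overlapping and evenly spaced, each wrapped by an NDR cassette on
    both sides (upstream of the TSS, downstream of the TTS, whichever the
    strand).  Returns ``(genome, truth)``.
    """
    rng = config.rng(0)
    L = config.genome_length
    unit = config.gene_length + 2 * config.ndr_length
    total = config.n_genes * unit
    if config.n_genes > 0 and total + config.n_genes + 1 > L:
        raise ConfigError(
            f"{config.n_genes} genes of {unit} bp do not fit in {L} bp")
    gc_local = config.gc + config.gc_amplitude * np.sin(
        2.0 * np.pi * np.arange(L) / config.gc_period)
    gc_local = np.clip(gc_local, 0.02, 0.98)
    # base order A, C, G, T with per-position probs (1-g)/2, g/2, g/2, (1-g)/2
    u = rng.random(L)
    idx = ((u > (1 - gc_local) / 2).astype(np.int8) + (u > 0.5)
           + (u > (1 + gc_local) / 2))
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[idx]
    truth = SimTruth(cut_weights=dict(config.cut_weights))
    chrom = config.chrom_name
    if config.n_genes > 0:
        gap = (L - total) / (config.n_genes + 1)
        cassette = (config.ndr_motif * (config.ndr_length // len(config.ndr_motif) + 1)
                    )[:config.ndr_length]
        cassette_codes = np.frombuffer(cassette.encode(), dtype=np.uint8)
        for i in range(config.n_genes):
            ndr1 = int(round((i + 1) * gap + i * unit))
            gene_start = ndr1 + config.ndr_length
            gene_end = gene_start + config.gene_length
            ndr2 = gene_end
            strand = "+" if rng.random() < 0.5 else "-"
            seq[ndr1:ndr1 + config.ndr_length] = cassette_codes
            seq[ndr2:ndr2 + config.ndr_length] = cassette_codes
            truth.genes.append(GeneModel(chrom, gene_start, gene_end, strand,
                                         f"gene{i + 1:04d}"))
            truth.ndrs.append(Region(chrom, ndr1, ndr1 + config.ndr_length, kind="NDR"))
            truth.ndrs.append(Region(chrom, ndr2, ndr2 + config.ndr_length, kind="NDR"))
    genome = {chrom: seq.tobytes().decode("ascii")}
    return genome, truth


def place_nucleosomes(genome: dict[str, str], truth: SimTruth,
                      config: SimConfig) -> SimTruth:
    """Plant nucleosome dyads: phased sharp arrays over gene bodies,
    jittered dyads in the intergenic non-NDR background.

    The first genic dyad sits ``linker + 74`` bp downstream of the TSS
    (linker = spacing - 147) and successive dyads follow at the configured
    spacing while their footprint stays inside the gene.  Intergenic
    dyads sit on the same grid but are jittered uniformly by +-``jitter``
    bp; any dyad whose footprint would intersect an NDR or leave its
    interval is dropped.
    """
    rng = config.rng(1)
    linker = config.nucleosome_spacing - FOOTPRINT
    chrom = config.chrom_name
    L = len(genome[chrom])
    dyads: list[Dyad] = []
    for gene in truth.genes:
        if gene.strand == "+":
            d = gene.start + linker + 74
            while d + (FOOTPRINT - HALF_UP) <= gene.end:
                dyads.append(Dyad(chrom, d, "sharp"))
                d += config.nucleosome_spacing
        else:
            d = gene.end - 1 - linker - 74
            while d - HALF_UP >= gene.start:
                dyads.append(Dyad(chrom, d, "sharp"))
                d -= config.nucleosome_spacing
    # intergenic intervals = complement of genes and NDRs
    blocked = sorted([(g.start, g.end) for g in truth.genes]
                     + [(r.start, r.end) for r in truth.ndrs])
    cursor = 0
    intervals = []
    for start, end in blocked:
        if start > cursor:
            intervals.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < L:
        intervals.append((cursor, L))
    for a, b in intervals:
        d = a + linker + 74
        while d + (FOOTPRINT - HALF_UP) <= b:
            j = int(rng.integers(-config.jitter, config.jitter + 1))
            dj = d + j
            if dj - HALF_UP >= a and dj + (FOOTPRINT - HALF_UP) <= b:
                dyads.append(Dyad(chrom, dj, "jittered"))
            d += config.nucleosome_spacing
    truth.dyads = sorted(dyads, key=lambda x: (x.chrom, x.pos))
    return truth


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def _cut_intensity(seq: str, config: SimConfig, dyads, rate: float):
    """Per-inter-base cut intensity (length L+1), tetramer-weighted,
    normalized to a genomic mean of ``rate`` before protection.

    Sharp dyads protect their footprint deterministically (every cell has
    the nucleosome at the same place); jittered dyads model population
    heterogeneity — the footprint sits at a uniformly jittered offset in
    each cell — so their protection is the jitter-smeared expectation,
    partial over a widened envelope.
    """
    codes = encode_sequence(seq)
    L = len(codes)
    weights_by_pair = np.array([config.cut_weights[l] for l in PAIR_LABELS])
    w = np.zeros(L + 1)
    tc = tetramer_codes(codes)
    valid = tc >= 0
    w[2:L - 1][valid] = weights_by_pair[PAIR_INDEX_OF_CODE[np.where(valid, tc, 0)]][valid]
    mean_w = w[w > 0].mean() if (w > 0).any() else 1.0
    p = w / mean_w * rate
    if dyads:
        # expected fraction of cells protecting each bond
        cover = np.zeros(L + 2)
        J = config.jitter
        for d in dyads:
            # cuts severing two wrapped bases are protected; the bonds at
            # the footprint boundaries stay accessible
            lo, hi = d.pos - HALF_UP + 1, d.pos + (FOOTPRINT - HALF_UP)
            if d.cls == "sharp" or J == 0:
                cover[max(0, lo):hi] += 1.0
            else:
                frac = config.fuzzy_occupancy / (2 * J + 1)
                for off in range(-J, J + 1):
                    cover[max(0, lo + off):hi + off] += frac
        cover = np.minimum(cover[:L + 1], 1.0)
        p = p * (1.0 - (1.0 - config.protection) * cover)
    return np.minimum(p, 0.5)


def simulate_digestion(genome: dict[str, str], config: SimConfig,
                       dyads: list[Dyad] | None = None, stage: int = 2):
    """Digest the genome and emit single-end reads with ground truth.

    ``dyads=None`` selects naked-DNA mode (no protection, gentle
    digestion); a dyad list selects chromatin mode (aggressive linker
    digestion attenuated by ``protection`` inside footprints).  Returns
    ``(reads, end_pair_counts)`` where ``end_pair_counts`` counts the true
    tetramer pair at each emitted 5' cut.
    """
    rng = config.rng(stage)
    rate = config.digestion_rate_naked if dyads is None else config.digestion_rate_chromatin
    fmin, fmax = config.fragment_range
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    shares = np.round(config.n_fragments * lengths / lengths.sum()).astype(int)
    shares[-1] = config.n_fragments - shares[:-1].sum()
    reads: list[ReadAlignment] = []
    end_pair_counts = np.zeros(N_PAIRS, dtype=np.int64)
    for chrom, want in zip(chroms, shares):
        if want <= 0:
            continue
        seq = genome[chrom]
        chrom_dyads = None if dyads is None else [d for d in dyads if d.chrom == chrom]
        p = _cut_intensity(seq, config, chrom_dyads, rate)
        C = np.concatenate(([0.0], np.cumsum(p)))  # prefix sums; weight of i = C[i+1]-C[i]
        total = C[-1]
        if total <= 0:
            raise ConfigError(f"chromosome {chrom} has zero cut intensity")
        starts_acc, ends_acc = [], []
        collected = 0
        attempts = 0
        while collected < want:
            k = rng.poisson(total)
            if k < 2:
                attempts += 1
                if attempts > 1_000_000:
                    raise ConfigError("no eligible cut pair after 1e6 digestion passes")
                continue
            cuts = np.unique(np.searchsorted(C, rng.uniform(0.0, total, k), side="right") - 1)
            lens = np.diff(cuts)
            ok = (lens >= fmin) & (lens <= fmax)
            attempts += len(lens)
            if not ok.any():
                if attempts > 1_000_000 and collected == 0:
                    raise ConfigError(
                        "no eligible cut pair after 1e6 attempts; "
                        f"rate={rate:.4g}, fragment_range={config.fragment_range}")
                continue
            starts_acc.append(cuts[:-1][ok])
            ends_acc.append(cuts[1:][ok])
            collected += int(ok.sum())
        starts = np.concatenate(starts_acc)[:want]
        ends = np.concatenate(ends_acc)[:want]
        minus = rng.random(want) < 0.5
        # exonucleolytic end trimming: geometric depth, landing point
        # re-weighted by the same tetramer map
        if config.exo_trim_mean > 0:
            pr = 1.0 / (1.0 + config.exo_trim_mean)
            t = rng.geometric(pr, size=want) - 1
        else:
            t = np.zeros(want, dtype=np.int64)
        t = np.minimum(t, ends - starts - READ_LENGTH)
        u = rng.random(want)
        # + fragments: trim 5' end [s, s+t] forward; - fragments: [e-t, e] backward
        lo = np.where(minus, ends - t, starts)
        hi = np.where(minus, ends, starts + t)
        span = C[hi + 1] - C[lo]
        pick = np.searchsorted(C, C[lo] + u * span, side="right") - 1
        pick = np.clip(pick, lo, hi)
        pick = np.where(span > 0, pick, np.where(minus, ends, starts))
        new_starts = np.where(minus, starts, pick)
        new_ends = np.where(minus, pick, ends)
        # true tetramer pair at the emitted 5' cut
        tc = tetramer_codes(encode_sequence(seq))
        cut5 = np.where(minus, new_ends, new_starts)
        in_range = (cut5 >= 2) & (cut5 <= len(seq) - 2)
        raw5 = tc[np.clip(cut5 - 2, 0, len(tc) - 1)]
        good = in_range & (raw5 >= 0)
        oriented = np.where(minus, REVCOMP_CODE[np.clip(raw5, 0, 255)], raw5)
        end_pair_counts += np.bincount(PAIR_INDEX_OF_CODE[oriented[good]], minlength=N_PAIRS)
        read_starts = np.where(minus, new_ends - READ_LENGTH, new_starts)
        read_ends = read_starts + READ_LENGTH
        for s, e, m in zip(read_starts.tolist(), read_ends.tolist(), minus.tolist()):
            reads.append(ReadAlignment(chrom, s, e, "-" if m else "+"))
    return reads, end_pair_counts


def occupancy_track(truth: SimTruth, genome_lengths: dict[str, int],
                    jitter: int = 40, window: int = FOOTPRINT,
                    fuzzy_occupancy: float = 0.4) -> dict[str, np.ndarray]:
    """Expected planted nucleosome occupancy per position.

    Sharp dyads contribute their 147 bp footprint at weight 1; jittered
    dyads spread the footprint uniformly over their +-``jitter``
    delocalization envelope (the population-expected coverage of a fuzzy
    nucleosome).  ``window`` > 1 additionally averages over a candidate
    footprint, giving the occupancy a nucleosome placed at each dyad
    position would overlap — the natural counterpart of a per-dyad
    deformation-energy track.
    """
    out = {}
    for chrom, L in genome_lengths.items():
        diff = np.zeros(L + 1)
        for d in truth.dyads:
            if d.chrom != chrom:
                continue
            if d.cls == "sharp" or jitter == 0:
                diff[max(0, d.pos - HALF_UP)] += 1.0
                diff[min(L, d.pos + (FOOTPRINT - HALF_UP))] -= 1.0
            else:
                w = fuzzy_occupancy / (2 * jitter + 1)
                for off in range(-jitter, jitter + 1):
                    diff[max(0, d.pos + off - HALF_UP)] += w
                    diff[min(L, d.pos + off + (FOOTPRINT - HALF_UP))] -= w
        occ = np.maximum(np.cumsum(diff[:-1]), 0.0)  # clear cumsum round-off
        if window > 1:
            occ = np.convolve(occ, np.full(window, 1.0 / window), mode="same")
        out[chrom] = occ
    return out


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def _dyad_recovery(true_pos: np.ndarray, called_pos: np.ndarray, tol: int) -> float:
    if len(true_pos) == 0:
        return float("nan")
    if len(called_pos) == 0:
        return 0.0
    called = np.sort(called_pos)
    idx = np.searchsorted(called, true_pos)
    best = np.full(len(true_pos), np.iinfo(np.int64).max)
    for shift in (-1, 0):
        j = np.clip(idx + shift, 0, len(called) - 1)
        best = np.minimum(best, np.abs(called[j] - true_pos))
    return float((best <= tol).mean())


def _best_jaccard(region: Region, candidates: list[Region]) -> float:
    best = 0.0
    for c in candidates:
        if c.chrom != region.chrom:
            continue
        inter = min(region.end, c.end) - max(region.start, c.start)
        if inter <= 0:
            continue
        union = max(region.end, c.end) - min(region.start, c.start)
        best = max(best, inter / union)
    return best


def truth_report(truth: SimTruth, calls: list[NucleosomeCall] | None = None,
                 lrs: list[Region] | None = None,
                 enrichment: pd.DataFrame | None = None,
                 tol: int = 20, class_tol: int = 74) -> pd.DataFrame:
    """Recovery metrics of an analysis against the planted ground truth.

    * dyad recovery rate (per class and overall) at ``tol`` bp;
    * class recovery: fraction of sharp dyads whose nearest call within
      ``class_tol`` bp is labelled well-positioned, and of jittered dyads
      whose nearest call is fuzzy;
    * mean best-Jaccard of planted NDRs against detected LRs;
    * Spearman correlation of planted cut weights vs recovered ratios.
    Deterministic; metrics whose inputs are absent come out NaN.
    """
    rows = []
    if calls is not None:
        by_cls = {"sharp": [], "jittered": []}
        for d in truth.dyads:
            by_cls[d.cls].append(d.pos)
        called = np.array(sorted(c.dyad for c in calls), dtype=np.int64)
        for cls, positions in by_cls.items():
            rows.append((f"dyad_recovery_{cls}",
                         _dyad_recovery(np.array(positions, dtype=np.int64), called, tol)))
        rows.append(("dyad_recovery_all",
                     _dyad_recovery(np.array([d.pos for d in truth.dyads], dtype=np.int64),
                                    called, tol)))
        classified = [c for c in calls if c.cls]
        if classified:
            cd = np.array([c.dyad for c in classified], dtype=np.int64)
            order = np.argsort(cd)
            cd = cd[order]
            labels = np.array([classified[i].cls for i in order])
            # sharp dyads are scored individually: nearest call within
            # class_tol must be well-positioned
            hits = 0
            for pos in by_cls["sharp"]:
                i = np.searchsorted(cd, pos)
                best, best_d = None, class_tol + 1
                for j in (i - 1, i):
                    if 0 <= j < len(cd) and abs(int(cd[j]) - pos) < best_d:
                        best, best_d = labels[j], abs(int(cd[j]) - pos)
                if best == "well-positioned":
                    hits += 1
            rows.append(("class_recovery_sharp",
                         hits / len(by_cls["sharp"]) if by_cls["sharp"] else float("nan")))
            # jittered dyads form delocalized clusters whose peaks merge,
            # so they are scored per cluster: a cluster is recovered as
            # fuzzy when the calls falling in its span are mostly fuzzy
            clusters = []
            for pos in sorted(by_cls["jittered"]):
                if clusters and pos - clusters[-1][-1] < 300:
                    clusters[-1].append(pos)
                else:
                    clusters.append([pos])
            hits = 0
            for cluster in clusters:
                lo, hi = cluster[0] - class_tol, cluster[-1] + class_tol
                inside = (cd >= lo) & (cd <= hi)
                if inside.any() and (labels[inside] == "fuzzy").mean() >= 0.5:
                    hits += 1
            rows.append(("class_recovery_jittered",
                         hits / len(clusters) if clusters else float("nan")))
    if lrs is not None:
        jac = [_best_jaccard(ndr, lrs) for ndr in truth.ndrs]
        rows.append(("ndr_lr_mean_jaccard", float(np.mean(jac)) if jac else float("nan")))
    if enrichment is not None:
        merged = enrichment[np.isfinite(enrichment["ratio"])]
        weights = np.array([truth.cut_weights[l] for l in merged["pair_label"]])
        rho = sps.spearmanr(weights, merged["ratio"]).statistic
        rows.append(("weight_ratio_spearman", float(rho)))
    return pd.DataFrame(rows, columns=["metric", "value"])
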