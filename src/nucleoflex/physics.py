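"""Sequence-dependent physical descriptors of DNA.

A base-pair step is described by six rigid-body helical parameters, in the
fixed order ``(shift, slide, rise, tilt, roll, twist)`` — translations in
Angstrom, rotations in degrees.  Around its sequence-dependent equilibrium
geometry each step behaves harmonically, with a 6x6 stiffness (force
constant) matrix Theta obtained as kT times the inverse of the covariance
matrix of the helical parameters over a conformational ensemble.

Two scalar summaries are derived from the per-step model:

* ``k_total`` — the product of the six diagonal ("pure") stiffness
  constants, a rough, unitless-by-convention global estimate of step
  flexibility (larger = stiffer);
* the nucleosome deformation energy — the harmonic cost
  ``E = 0.5 X^T Theta X`` of deforming a 147 bp window from its
  equilibrium into a target nucleosome-wrapped conformation, summed over
  the 146 steps of the window.

Because the elastic model is per-step, the 876x876 stiffness super-matrix
of a 147 bp window is block-diagonal and the energy decomposes into a sum
of per-step quadratic forms; the vectorized profile code exploits this.

Strand symmetry: reading a step on the opposite strand reverses the
context and flips the signs of shift and tilt.  Tables store only the
canonical (lexicographically smaller) context of each reverse-complement
pair; lookups for the other orientation apply the sign flips.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigError, DimensionError, IllConditionedError, InvalidSequenceError
from .regions import Region
from .sequences import (
    canonical_context,
    dinucleotide_codes,
    encode_sequence,
    reverse_complement,
    tetramer_codes,
    _decode_kmer,
    PAIR_CANONICAL_CODES,
)

logger = logging.getLogger(__name__)

PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")

#: sign flips applied to (shift, slide, rise, tilt, roll, twist) when a
#: step context is read on the opposite strand
STRAND_FLIP_SIGNS = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, 1.0])

#: kT at 298 K in kcal/mol
KT_298 = 0.593

_CANONICAL_DINUCS = ("AA", "AC", "AG", "AT", "CA", "CC", "CG", "GA", "GC", "TA")
_CANONICAL_TETRAMERS = tuple(_decode_kmer(c, 4) for c in PAIR_CANONICAL_CODES)

NUCLEOSOME_BP = 147
NUCLEOSOME_STEPS = 146
DYAD_OFFSET = 73  # dyad = window start + 73 (0-based)


def stiffness_from_covariance(C: np.ndarray, kT: float = KT_298) -> np.ndarray:
    """Stiffness matrix ``kT * C^-1`` from a helical-parameter covariance.

    ``C`` must be symmetric positive definite (it is a covariance matrix
    estimated from a conformational ensemble).  The result is symmetrized
    to remove round-off asymmetry.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise IllConditionedError(f"covariance must be square, got shape {C.shape}")
    if not np.allclose(C, C.T, rtol=0.0, atol=1e-8 * max(1.0, float(np.abs(C).max()))):
        raise IllConditionedError("covariance matrix is not symmetric")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise IllConditionedError("covariance matrix is not positive definite") from exc
    theta = kT * np.linalg.inv(C)
    return 0.5 * (theta + theta.T)


@dataclass
class StepStiffness:
    """Equilibrium geometry and harmonic stiffness of one base-pair step.

    ``context`` is the canonical dinucleotide (len 2) or tetramer (len 4);
    ``equilibrium`` the six mean helical parameters; ``theta`` the 6x6
    stiffness matrix in kcal/mol per (A or deg)^2.
    """

    context: str
    equilibrium: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.equilibrium = np.asarray(self.equilibrium, dtype=float).reshape(6)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (6, 6):
            raise DimensionError("theta must be 6x6")
        if not np.allclose(self.theta, self.theta.T, rtol=0.0, atol=1e-9):
            raise IllConditionedError(f"theta for {self.context} is not symmetric")
        if np.any(np.diag(self.theta) <= 0):
            raise IllConditionedError(f"non-positive diagonal stiffness for {self.context}")

    @property
    def k_diag(self) -> np.ndarray:
        """The six pure stiffness constants (diagonal of theta)."""
        return np.diag(self.theta)

    @property
    def k_total(self) -> float:
        """Product of the six pure stiffness constants."""
        return float(np.prod(np.diag(self.theta)))


def k_total(step: StepStiffness) -> float:
    """Scalar flexibility summary of a step: product of the six pure constants."""
    return step.k_total


# TSV column layout: context, six equilibrium values, then the 21
# upper-triangle entries of theta row-major.
_TRIU = np.triu_indices(6)
_EQ_COLS = [f"{p}0" for p in PARAM_NAMES]
_THETA_COLS = [f"t{i + 1}{j + 1}" for i, j in zip(*_TRIU)]


@dataclass
class StiffnessTable:
    """Complete reverse-complement-collapsed table of step stiffness entries.

    10 canonical entries at dinucleotide level, 136 at tetramer level.
    Lookup of any valid raw context succeeds; non-canonical contexts are
    served through strand symmetry (shift/tilt sign flips).
    """

    level: str
    entries: dict[str, StepStiffness]
    temperature_kT: float = KT_298

    def __post_init__(self):
        if self.level not in ("dinucleotide", "tetramer"):
            raise ConfigError(f"unknown stiffness level {self.level!r}")
        expected = _CANONICAL_DINUCS if self.level == "dinucleotide" else _CANONICAL_TETRAMERS
        missing = sorted(set(expected) - set(self.entries))
        extra = sorted(set(self.entries) - set(expected))
        if missing or extra:
            raise ConfigError(
                f"{self.level} table incomplete: missing {missing[:5]}, unexpected {extra[:5]}"
            )

    @property
    def context_length(self) -> int:
        return 2 if self.level == "dinucleotide" else 4

    def lookup(self, context: str):
        """``(mu, theta)`` for a raw (possibly non-canonical) context.

        Strand-adjusted: when the reverse complement is the stored form,
        shift and tilt signs are flipped in ``mu`` and the corresponding
        rows/columns of ``theta`` sign-adjusted.
        """
        canon, reversed_flag = canonical_context(context)
        if len(canon) != self.context_length:
            raise InvalidSequenceError(
                f"context {context!r} has wrong length for a {self.level} table"
            )
        entry = self.entries[canon]
        mu, theta = entry.equilibrium, entry.theta
        if reversed_flag:
            mu = mu * STRAND_FLIP_SIGNS
            theta = theta * np.outer(STRAND_FLIP_SIGNS, STRAND_FLIP_SIGNS)
        return mu, theta

    @classmethod
    def from_entries(cls, entries, level: str, temperature_kT: float = KT_298):
        return cls(level=level, entries={e.context: e for e in entries},
                   temperature_kT=temperature_kT)

    @classmethod
    def from_tsv(cls, path, temperature_kT: float = KT_298) -> "StiffnessTable":
        """Read a stiffness table from its documented TSV format.

        Columns: ``context``, ``shift0 .. twist0``, then the 21
        upper-triangle theta entries ``t11 .. t66`` row-major.  A header
        line is required; '#' comment lines are ignored.
        """
        df = pd.read_csv(path, sep="\t", comment="#")
        required = ["context"] + _EQ_COLS + _THETA_COLS
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigError(f"stiffness TSV missing columns {missing}")
        entries = {}
        ctx_len = None
        for _, row in df.iterrows():
            ctx = str(row["context"]).upper()
            ctx_len = len(ctx) if ctx_len is None else ctx_len
            theta = np.zeros((6, 6))
            theta[_TRIU] = row[_THETA_COLS].to_numpy(dtype=float)
            theta = theta + np.triu(theta, 1).T
            entries[ctx] = StepStiffness(
                context=ctx,
                equilibrium=row[_EQ_COLS].to_numpy(dtype=float),
                theta=theta,
            )
        level = "dinucleotide" if ctx_len == 2 else "tetramer"
        return cls(level=level, entries=entries, temperature_kT=temperature_kT)

    def to_tsv(self, path) -> None:
        rows = []
        for ctx in sorted(self.entries):
            e = self.entries[ctx]
            rows.append([ctx, *e.equilibrium, *e.theta[_TRIU]])
        df = pd.DataFrame(rows, columns=["context"] + _EQ_COLS + _THETA_COLS)
        df.to_csv(path, sep="\t", index=False)


def load_dinucleotide_table(temperature_kT: float = KT_298) -> StiffnessTable:
    """The packaged synthetic dinucleotide stiffness/equilibrium table.

    Values are literature-flavoured but synthetic (constructed for this
    package, not fitted to any simulation ensemble): A-tract steps (AA,
    AT) are stiff, pyrimidine-purine steps (TA, CA, CG) flexible, with
    magnitudes typical of published helical-parameter force constants.
    """
    with resources.as_file(
        resources.files("nucleoflex.data") / "dinucleotide_stiffness_synthetic.tsv"
    ) as p:
        return StiffnessTable.from_tsv(p, temperature_kT=temperature_kT)


def tetramer_table_from_dinucleotide(table: StiffnessTable) -> StiffnessTable:
    """Expand a dinucleotide table to the 136 canonical tetramer contexts.

    Each tetramer inherits the parameters of its central dinucleotide step
    (no flanking-dependence is invented); useful for exercising the
    tetramer-level machinery when no fitted tetramer table is available.
    """
    if table.level != "dinucleotide":
        raise ConfigError("input table must be dinucleotide level")
    entries = []
    for tet in _CANONICAL_TETRAMERS:
        mu, theta = table.lookup(tet[1:3])
        entries.append(StepStiffness(context=tet, equilibrium=mu, theta=theta))
    return StiffnessTable.from_entries(entries, level="tetramer",
                                       temperature_kT=table.temperature_kT)


# ---------------------------------------------------------------------------
# nucleosome target shape
# ---------------------------------------------------------------------------

@dataclass
class NucleosomeShape:
    """Target DNA conformation on the histone core: 146 steps x 6 params."""

    steps: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=float)
        if self.steps.shape != (NUCLEOSOME_STEPS, 6):
            raise DimensionError(
                f"nucleosome shape must be {NUCLEOSOME_STEPS}x6, got {self.steps.shape}"
            )

    @classmethod
    def ideal(cls, amp_roll: float = 6.0, amp_tilt: float = 3.0,
              twist: float = 34.3, rise: float = 3.32,
              period: float = 10.25) -> "NucleosomeShape":
        """Synthetic idealized wrapped conformation.

        Roll and tilt oscillate sinusoidally with the helical period
        (default 10.25 bp) in phase quadrature, which makes the bending
        direction rotate with the helix as the DNA follows the
        superhelical path; twist and rise are constant.  The phase is
        centred on the dyad so that roll is even and tilt odd about the
        centre — the symmetry a palindromic wrapped conformation must
        have, and what makes energy profiles strand-symmetric.
        """
        u = np.arange(NUCLEOSOME_STEPS) - (NUCLEOSOME_STEPS - 1) / 2.0
        phase = 2.0 * np.pi * u / period
        steps = np.zeros((NUCLEOSOME_STEPS, 6))
        steps[:, 3] = amp_tilt * np.sin(phase)
        steps[:, 4] = amp_roll * np.cos(phase)
        steps[:, 5] = twist
        steps[:, 2] = rise
        return cls(steps)

    @classmethod
    def from_tsv(cls, path) -> "NucleosomeShape":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in PARAM_NAMES if c not in df.columns]
        if missing:
            raise ConfigError(f"shape TSV missing columns {missing}")
        return cls(df[list(PARAM_NAMES)].to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.steps, columns=list(PARAM_NAMES)).to_csv(
            path, sep="\t", index=False
        )


def _as_shape_array(shape) -> np.ndarray:
    if isinstance(shape, NucleosomeShape):
        return shape.steps
    arr = np.asarray(shape, dtype=float)
    if arr.shape != (NUCLEOSOME_STEPS, 6):
        raise DimensionError(f"shape must be {NUCLEOSOME_STEPS}x6, got {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _check_alphabet(seq: str) -> None:
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise InvalidSequenceError(f"non-ACGT(N) characters in sequence: {sorted(bad)}")


def _step_code_array(seq: str, level: str) -> np.ndarray:
    """Per-step context codes; -1 where the context window does not fit
    or touches an ambiguous base.  Length is ``len(seq) - 1``."""
    codes = encode_sequence(seq)
    if level == "dinucleotide":
        return dinucleotide_codes(codes)
    out = np.full(len(codes) - 1, -1, dtype=np.int64)
    if len(codes) >= 4:
        out[1:-1] = tetramer_codes(codes)  # step i context seq[i-1:i+3]
    return out


def _ktotal_lut(table: StiffnessTable) -> np.ndarray:
    """k_total per raw context code (k_total is strand-invariant)."""
    n = 16 if table.level == "dinucleotide" else 256
    k = table.context_length
    lut = np.empty(n)
    for code in range(n):
        _, theta = table.lookup(_decode_kmer(code, k))
        lut[code] = np.prod(np.diag(theta))
    return lut


def ktotal_profile(seq: str, table: StiffnessTable, smooth_window: int = 1) -> np.ndarray:
    """Per-step k_total track for a sequence.

    Position i covers step ``seq[i:i+1+1]``; the returned array has length
    ``len(seq) - 1`` with NaN where the context window does not fit (track
    edges at tetramer level) or touches an N.  ``smooth_window`` applies a
    centred moving average (odd width; 1 = none).
    """
    _check_alphabet(seq)
    if len(seq) < table.context_length:
        raise InvalidSequenceError("sequence shorter than the context window")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ConfigError("smooth_window must be a positive odd integer")
    scodes = _step_code_array(seq, table.level)
    lut = np.append(_ktotal_lut(table), np.nan)
    values = lut[np.where(scodes < 0, len(lut) - 1, scodes)]
    if smooth_window > 1:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        core = np.convolve(values, kernel, mode="valid")
        out = np.full_like(values, np.nan)
        half = smooth_window // 2
        out[half:half + len(core)] = core
        return out
    return values


def deformation_energy(window: str, table: StiffnessTable, shape) -> float:
    """Harmonic energy (kcal/mol) of deforming a 147 bp window onto the
    nucleosome shape: ``sum_s 0.5 (x_s - mu_s)^T Theta_s (x_s - mu_s)``.

    Returns NaN if the window contains N (or, at tetramer level, because
    the terminal steps lack context the window is evaluated over the 144
    steps with defined context — callers comparing levels should use the
    profile functions, which handle edges uniformly).
    """
    if len(window) != NUCLEOSOME_BP:
        raise DimensionError(f"window must be {NUCLEOSOME_BP} bp, got {len(window)}")
    _check_alphabet(window)
    x = _as_shape_array(shape)
    if "N" in window.upper():
        return float("nan")
    total = 0.0
    k = table.context_length
    for s in range(NUCLEOSOME_STEPS):
        if k == 2:
            ctx = window[s:s + 2]
        else:
            if s == 0 or s == NUCLEOSOME_STEPS - 1:
                continue  # terminal steps have no tetramer context
            ctx = window[s - 1:s + 3]
        mu, theta = table.lookup(ctx)
        d = x[s] - mu
        total += 0.5 * float(d @ theta @ d)
    return total


def _estep_lut(table: StiffnessTable, shape_arr: np.ndarray) -> np.ndarray:
    """Per-(context code, window step j) energy contributions, shape
    (ncodes+1, 146); the last row is NaN for invalid codes."""
    n = 16 if table.level == "dinucleotide" else 256
    k = table.context_length
    lut = np.empty((n + 1, NUCLEOSOME_STEPS))
    for code in range(n):
        mu, theta = table.lookup(_decode_kmer(code, k))
        d = shape_arr - mu[None, :]
        lut[code] = 0.5 * np.einsum("jk,kl,jl->j", d, theta, d)
    lut[n] = np.nan
    return lut


def energy_profile(genome, table: StiffnessTable, shape, stride: int = 1):
    """Nucleosome deformation energy of every 147 bp window, per dyad.

    ``genome`` is a ``{name: sequence}`` mapping (a bare string is treated
    as one chromosome).  The energy of the window starting at p is
    assigned to its dyad p + 73; positions without a complete window (or
    off-stride) are NaN.  Chromosomes shorter than 147 bp are skipped with
    a warning.  Returns ``{name: ndarray}`` (or a bare array for a bare
    string input).
    """
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    bare = isinstance(genome, str)
    chroms = {"seq": genome} if bare else genome
    shape_arr = _as_shape_array(shape)
    lut = _estep_lut(table, shape_arr)
    nan_row = lut.shape[0] - 1
    out = {}
    for name, seq in chroms.items():
        _check_alphabet(seq)
        L = len(seq)
        track = np.full(L, np.nan)
        if L < NUCLEOSOME_BP:
            warnings.warn(f"chromosome {name!r} shorter than {NUCLEOSOME_BP} bp; skipped")
            out[name] = track
            continue
        scodes = _step_code_array(seq, table.level)
        idx = np.where(scodes < 0, nan_row, scodes)
        starts = np.arange(0, L - NUCLEOSOME_BP + 1, stride)
        energies = np.zeros(len(starts))
        # windows are self-contained: at tetramer level the two terminal
        # steps of each window lack in-window context and are skipped,
        # matching deformation_energy()
        steps = (range(NUCLEOSOME_STEPS) if table.level == "dinucleotide"
                 else range(1, NUCLEOSOME_STEPS - 1))
        for j in steps:
            energies += lut[idx[starts + j], j]
        track[starts + DYAD_OFFSET] = energies
        out[name] = track
    return out["seq"] if bare else out


def predict_regions(energy_track, depleted_quantile: float = 0.9,
                    enriched_quantile: float = 0.1, min_len: int = 50):
    """Energy-based nucleosome-depleted / enriched region prediction.

    High deformation energy disfavours nucleosome formation, so depleted
    regions are maximal runs (>= ``min_len`` bp of dyad positions) with
    energy strictly above the ``depleted_quantile`` of the chromosome-wide
    finite-energy distribution, and enriched regions runs strictly below
    the ``enriched_quantile``.  Returns ``(depleted, enriched)`` lists of
    :class:`~nucleoflex.regions.Region`.
    """
    if not (0.0 < enriched_quantile < 1.0 and 0.0 < depleted_quantile < 1.0):
        raise ConfigError("quantiles must lie in (0, 1)")
    if enriched_quantile >= depleted_quantile:
        raise ConfigError("enriched_quantile must be below depleted_quantile")
    bare = isinstance(energy_track, np.ndarray)
    chroms = {"seq": energy_track} if bare else energy_track
    depleted, enriched = [], []
    for name, values in chroms.items():
        finite = np.isfinite(values)
        if not finite.any():
            logger.warning("chromosome %s has no finite energies", name)
            continue
        vals = values[finite]
        hi = np.quantile(vals, depleted_quantile)
        lo = np.quantile(vals, enriched_quantile)
        for mask, thr, sink, kind in (
            (np.greater, hi, depleted, "predicted_depleted"),
            (np.less, lo, enriched, "predicted_enriched"),
        ):
            hits = finite & mask(np.nan_to_num(values, nan=thr), thr)
            for start, end in _runs(hits):
                if end - start >= min_len:
                    sink.append(Region(chrom=name, start=int(start), end=int(end),
                                       mean_signal=float(np.nanmean(values[start:end])),
                                       kind=kind))
    return depleted, enriched


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, end) half-open pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts, ends))
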