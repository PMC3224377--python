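import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import block_diag

from nucleoflex import (
    ConfigError,
    DimensionError,
    IllConditionedError,
    InvalidSequenceError,
    NucleosomeShape,
    StepStiffness,
    StiffnessTable,
    deformation_energy,
    energy_profile,
    k_total,
    ktotal_profile,
    predict_regions,
    reverse_complement,
    stiffness_from_covariance,
    tetramer_table_from_dinucleotide,
)
from nucleoflex.physics import KT_298, STRAND_FLIP_SIGNS

from conftest import random_sequence


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def gauss_jordan_inverse(M):
    """Textbook Gauss-Jordan inversion with partial pivoting (oracle)."""
    n = len(M)
    a = np.hstack([np.array(M, dtype=float), np.eye(n)])
    for col in range(n):
        pivot = col + int(np.argmax(np.abs(a[col:, col])))
        a[[col, pivot]] = a[[pivot, col]]
        a[col] /= a[col, col]
        for row in range(n):
            if row != col:
                a[row] -= a[row, col] * a[col]
    return a[:, n:]


def window_energy_blockdiag(window, table, shape):
    """876x876 block-diagonal quadratic-form oracle for one 147 bp window."""
    arr = shape.steps if isinstance(shape, NucleosomeShape) else shape
    thetas, devs = [], []
    for s in range(146):
        if table.context_length == 2:
            ctx = window[s:s + 2]
        else:
            if s in (0, 145):
                continue
            ctx = window[s - 1:s + 3]
        mu, theta = table.lookup(ctx)
        thetas.append(theta)
        devs.append(arr[s] - mu)
    big = block_diag(*thetas)
    x = np.concatenate(devs)
    return 0.5 * float(x @ big @ x)


def random_spd(rng, n=6):
    A = rng.normal(size=(n, n))
    return A @ A.T + n * np.eye(n)


# ---------------------------------------------------------------------------
# stiffness algebra
# ---------------------------------------------------------------------------

def test_stiffness_from_covariance_trivials():
    np.testing.assert_allclose(stiffness_from_covariance(np.eye(6), kT=0.593),
                               0.593 * np.eye(6))
    v = np.array([1.0, 2.0, 4.0, 0.5, 0.25, 8.0])
    np.testing.assert_allclose(stiffness_from_covariance(np.diag(v), kT=2.0),
                               np.diag(2.0 / v))


def test_stiffness_from_covariance_matches_gauss_jordan(rng):
    for _ in range(20):
        C = random_spd(rng)
        theta = stiffness_from_covariance(C, kT=KT_298)
        np.testing.assert_allclose(theta, KT_298 * gauss_jordan_inverse(C),
                                   rtol=1e-8, atol=1e-10)
        assert np.allclose(theta, theta.T, atol=1e-9)


def test_stiffness_inversion_round_trips(rng):
    C = random_spd(rng)
    theta = stiffness_from_covariance(C, kT=1.0)
    np.testing.assert_allclose(stiffness_from_covariance(theta, kT=1.0), C,
                               rtol=1e-8, atol=1e-10)


def test_stiffness_from_covariance_rejects_bad_matrices(rng):
    with pytest.raises(IllConditionedError):
        stiffness_from_covariance(np.zeros((6, 6)))
    asym = np.eye(6)
    asym[0, 1] = 0.5
    with pytest.raises(IllConditionedError):
        stiffness_from_covariance(asym)
    with pytest.raises(IllConditionedError):
        stiffness_from_covariance(np.eye(5)[:, :4])


def test_k_total_is_diagonal_product(dinuc_table):
    step = StepStiffness("AA", np.zeros(6), np.diag([2.0] * 6))
    assert k_total(step) == 64.0
    assert k_total(StepStiffness("TA", np.zeros(6), np.eye(6))) == 1.0
    for entry in dinuc_table.entries.values():
        assert entry.k_total == pytest.approx(float(np.prod(np.diag(entry.theta))),
                                              rel=1e-12)


# ---------------------------------------------------------------------------
# table semantics
# ---------------------------------------------------------------------------

def test_table_lookup_applies_strand_flips(dinuc_table):
    mu_aa, th_aa = dinuc_table.lookup("AA")
    mu_tt, th_tt = dinuc_table.lookup("TT")
    np.testing.assert_allclose(mu_tt, mu_aa * STRAND_FLIP_SIGNS)
    np.testing.assert_allclose(
        th_tt, th_aa * np.outer(STRAND_FLIP_SIGNS, STRAND_FLIP_SIGNS))
    # diagonal (pure constants) and hence k_total are strand-invariant
    np.testing.assert_allclose(np.diag(th_tt), np.diag(th_aa))


def test_table_roundtrip_through_tsv(dinuc_table, tmp_path):
    path = tmp_path / "table.tsv"
    dinuc_table.to_tsv(path)
    again = StiffnessTable.from_tsv(path)
    assert again.level == "dinucleotide"
    for ctx, entry in dinuc_table.entries.items():
        np.testing.assert_allclose(again.entries[ctx].theta, entry.theta)
        np.testing.assert_allclose(again.entries[ctx].equilibrium, entry.equilibrium)


def test_incomplete_table_rejected(dinuc_table):
    entries = dict(dinuc_table.entries)
    entries.pop("TA")
    with pytest.raises(ConfigError):
        StiffnessTable(level="dinucleotide", entries=entries)


def test_tetramer_expansion_has_136_consistent_entries(dinuc_table):
    tet = tetramer_table_from_dinucleotide(dinuc_table)
    assert tet.level == "tetramer"
    assert len(tet.entries) == 136
    # central-step inheritance: AATT's central step is AT
    mu, theta = tet.lookup("AATT")
    mu2, theta2 = dinuc_table.lookup("AT")
    np.testing.assert_allclose(mu, mu2)
    np.testing.assert_allclose(theta, theta2)


# ---------------------------------------------------------------------------
# k_total profile
# ---------------------------------------------------------------------------

def test_ktotal_profile_homopolymer(dinuc_table):
    prof = ktotal_profile("AAAA", dinuc_table)
    expected = dinuc_table.entries["AA"].k_total
    np.testing.assert_allclose(prof, [expected] * 3)


def test_ktotal_profile_matches_naive_loop(dinuc_table, rng):
    seq = random_sequence(rng, 1000)
    prof = ktotal_profile(seq, dinuc_table)
    for i in rng.choice(len(seq) - 1, size=40, replace=False):
        _, theta = dinuc_table.lookup(seq[i:i + 2])
        assert prof[i] == pytest.approx(float(np.prod(np.diag(theta))), rel=1e-12)


@given(seq=st.text(alphabet="ACGT", min_size=2, max_size=60))
@settings(max_examples=50, deadline=None)
def test_ktotal_profile_strand_symmetry(dinuc_table, seq):
    prof = ktotal_profile(seq, dinuc_table)
    rev = ktotal_profile(reverse_complement(seq), dinuc_table)
    np.testing.assert_allclose(rev[::-1], prof, rtol=1e-12)


def test_ktotal_profile_handles_n_and_rejects_garbage(dinuc_table):
    prof = ktotal_profile("AANCC", dinuc_table)
    assert np.isnan(prof[1]) and np.isnan(prof[2])
    assert np.isfinite(prof[0]) and np.isfinite(prof[3])
    with pytest.raises(InvalidSequenceError):
        ktotal_profile("AAXA", dinuc_table)


def test_ktotal_profile_smoothing_is_centered_average(dinuc_table, rng):
    seq = random_sequence(rng, 200)
    raw = ktotal_profile(seq, dinuc_table)
    sm = ktotal_profile(seq, dinuc_table, smooth_window=5)
    i = 60
    assert sm[i] == pytest.approx(raw[i - 2:i + 3].mean())
    assert np.isnan(sm[0]) and np.isnan(sm[-1])
    with pytest.raises(ConfigError):
        ktotal_profile(seq, dinuc_table, smooth_window=4)


# ---------------------------------------------------------------------------
# deformation energy
# ---------------------------------------------------------------------------

def test_energy_zero_at_equilibrium(dinuc_table, rng):
    window = random_sequence(rng, 147)
    steps = np.array([dinuc_table.lookup(window[s:s + 2])[0] for s in range(146)])
    assert deformation_energy(window, dinuc_table, steps) == pytest.approx(0.0, abs=1e-12)


def test_energy_single_roll_deviation(uniform_table):
    shape = np.zeros((146, 6))
    shape[70, 4] = 1.0  # roll +1 deg at one step, k_roll = 0.02
    E = deformation_energy("A" * 147, uniform_table, shape)
    assert E == pytest.approx(0.5 * 0.02 * 1.0**2)


def test_energy_matches_blockdiag_oracle(dinuc_table, ideal_shape, rng):
    for _ in range(10):
        window = random_sequence(rng, 147)
        shape = NucleosomeShape(ideal_shape.steps + rng.normal(0, 0.5, (146, 6)))
        E = deformation_energy(window, dinuc_table, shape)
        assert E == pytest.approx(window_energy_blockdiag(window, dinuc_table, shape),
                                  rel=1e-10)


def test_energy_canonical_vs_raw_context_invariance(dinuc_table, ideal_shape):
    # a window and its content looked up via non-canonical contexts must agree:
    # TT lookups go through AA with sign flips
    E1 = deformation_energy("T" * 147, dinuc_table, ideal_shape)
    E2 = window_energy_blockdiag("T" * 147, dinuc_table, ideal_shape)
    assert E1 == pytest.approx(E2, rel=1e-10)


def test_energy_scales_linearly_with_theta(dinuc_table, ideal_shape, rng):
    window = random_sequence(rng, 147)
    scaled = StiffnessTable.from_entries(
        [StepStiffness(e.context, e.equilibrium, 3.0 * e.theta)
         for e in dinuc_table.entries.values()],
        level="dinucleotide")
    assert deformation_energy(window, scaled, ideal_shape) == pytest.approx(
        3.0 * deformation_energy(window, dinuc_table, ideal_shape), rel=1e-10)


def test_energy_input_validation(dinuc_table, ideal_shape):
    with pytest.raises(DimensionError):
        deformation_energy("A" * 146, dinuc_table, ideal_shape)
    with pytest.raises(DimensionError):
        deformation_energy("A" * 147, dinuc_table, np.zeros((145, 6)))
    assert np.isnan(deformation_energy("A" * 100 + "N" + "A" * 46,
                                       dinuc_table, ideal_shape))


def test_energy_nonnegative_for_spd_tables(dinuc_table, ideal_shape, rng):
    for _ in range(5):
        window = random_sequence(rng, 147)
        assert deformation_energy(window, dinuc_table, ideal_shape) >= 0.0


# ---------------------------------------------------------------------------
# energy profile
# ---------------------------------------------------------------------------

def test_energy_profile_constant_on_homopolymer(dinuc_table, ideal_shape):
    prof = energy_profile("A" * 400, dinuc_table, ideal_shape)
    vals = prof[np.isfinite(prof)]
    assert len(vals) == 400 - 147 + 1
    np.testing.assert_allclose(vals, vals[0], rtol=1e-9)
    # dyad indexing: first window's energy sits at position 73
    assert np.isfinite(prof[73]) and not np.isfinite(prof[72])


def test_energy_profile_stride_is_exact_subsample(dinuc_table, ideal_shape, rng):
    seq = random_sequence(rng, 1200)
    full = energy_profile(seq, dinuc_table, ideal_shape)
    strided = energy_profile(seq, dinuc_table, ideal_shape, stride=7)
    idx = np.flatnonzero(np.isfinite(strided))
    assert np.array_equal(idx, np.arange(0, 1200 - 147 + 1, 7) + 73)
    np.testing.assert_allclose(strided[idx], full[idx], rtol=0, atol=0)


def test_energy_profile_matches_window_calls(dinuc_table, ideal_shape, rng):
    seq = random_sequence(rng, 800)
    prof = energy_profile(seq, dinuc_table, ideal_shape)
    for start in rng.choice(800 - 147, size=15, replace=False):
        window = seq[start:start + 147]
        assert prof[start + 73] == pytest.approx(
            deformation_energy(window, dinuc_table, ideal_shape), rel=1e-9)


def test_energy_profile_tetramer_level_matches_window_calls(dinuc_table, ideal_shape, rng):
    table = tetramer_table_from_dinucleotide(dinuc_table)
    seq = random_sequence(rng, 500)
    prof = energy_profile(seq, table, ideal_shape)
    for start in (0, 100, 353):
        assert prof[start + 73] == pytest.approx(
            deformation_energy(seq[start:start + 147], table, ideal_shape), rel=1e-9)


def test_energy_profile_short_chromosome_warns(dinuc_table, ideal_shape):
    with pytest.warns(UserWarning):
        prof = energy_profile({"tiny": "ACGT" * 10}, dinuc_table, ideal_shape)
    assert not np.isfinite(prof["tiny"]).any()


def test_energy_profile_strand_symmetry(dinuc_table, ideal_shape, rng):
    seq = random_sequence(rng, 2000)
    fwd = energy_profile(seq, dinuc_table, ideal_shape)
    rev = energy_profile(reverse_complement(seq), dinuc_table, ideal_shape)
    fin = np.isfinite(fwd)
    np.testing.assert_allclose(rev[::-1][fin], fwd[fin], rtol=1e-9)


# ---------------------------------------------------------------------------
# region prediction
# ---------------------------------------------------------------------------

def test_predict_regions_constant_track_is_empty():
    dep, enr = predict_regions(np.full(500, 3.0), 0.9, 0.1, min_len=10)
    assert dep == [] and enr == []


def test_predict_regions_finds_rectangular_plateau():
    track = np.full(10_000, 1.0)
    track[4000:4200] = 5.0
    dep, enr = predict_regions(track, depleted_quantile=0.9,
                               enriched_quantile=0.01, min_len=50)
    assert len(dep) == 1
    assert (dep[0].start, dep[0].end) == (4000, 4200)


def test_predict_regions_sets_are_disjoint(rng):
    track = rng.normal(size=20_000)
    dep, enr = predict_regions(track, 0.8, 0.2, min_len=5)
    covered = np.zeros(20_000, dtype=int)
    for r in dep + enr:
        covered[r.start:r.end] += 1
    assert covered.max() <= 1
    for r in dep:
        assert r.kind == "predicted_depleted"


def test_predict_regions_validates_quantiles(rng):
    track = rng.normal(size=100)
    with pytest.raises(ConfigError):
        predict_regions(track, 1.2, 0.1)
    with pytest.raises(ConfigError):
        predict_regions(track, 0.4, 0.6)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def test_ideal_shape_is_dyad_symmetric(ideal_shape):
    s = ideal_shape.steps
    # roll/twist/rise even about the dyad, tilt/shift odd
    np.testing.assert_allclose(s[::-1, 4], s[:, 4], atol=1e-9)
    np.testing.assert_allclose(s[::-1, 3], -s[:, 3], atol=1e-9)
    np.testing.assert_allclose(s[:, 0], 0.0)


def test_shape_tsv_roundtrip(ideal_shape, tmp_path):
    path = tmp_path / "shape.tsv"
    ideal_shape.to_tsv(path)
    again = NucleosomeShape.from_tsv(path)
    np.testing.assert_allclose(again.steps, ideal_shape.steps)
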