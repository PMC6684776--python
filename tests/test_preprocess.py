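"""COW alignment (with an exhaustive-enumeration oracle) and row/column
preprocessing post-conditions."""

import itertools

import numpy as np
import pytest

from crpkit.io import FingerprintMatrix, Spectrum
from crpkit.preprocess import (CowParams, PreprocessRecipe, apply_mean_center,
                               choose_reference, cow_align_matrix,
                               cow_align_pair, mean_center, normalize_sum,
                               optimize_cow, snv, snv_rows, subtract_blank)


# ---------------------------------------------------------------------------
# COW
# ---------------------------------------------------------------------------

def brute_force_cow_benefit(q, r, segment_length, slack):
    """Enumerate every interior-boundary placement; the DP must match this."""
    n = len(q)
    n_seg = (n - 1) // segment_length
    bounds = [i * segment_length for i in range(n_seg)] + [n - 1]
    best = -np.inf
    for combo in itertools.product(range(-slack, slack + 1), repeat=n_seg - 1):
        sh = [0, *combo, 0]
        total = 0.0
        for j in range(n_seg):
            ref = r[bounds[j]: bounds[j + 1] + 1]
            L = len(ref)
            pos = np.linspace(bounds[j] + sh[j], bounds[j + 1] + sh[j + 1], L)
            i0 = np.clip(np.floor(pos).astype(int), 0, n - 2)
            fr = pos - i0
            v = q[i0] * (1 - fr) + q[i0 + 1] * fr
            vc, rc = v - v.mean(), ref - ref.mean()
            d = np.sqrt((vc @ vc) * (rc @ rc))
            total += (vc @ rc) / d if d > 0 else 0.0
        best = max(best, total)
    return best


def test_cow_params_invariants_and_defaults():
    assert (CowParams().segment_length, CowParams().slack) == (150, 5)
    with pytest.raises(ValueError):
        CowParams(segment_length=5, slack=3)
    with pytest.raises(ValueError):
        CowParams(slack=0)


def test_cow_identity_warp():
    rng = np.random.default_rng(0)
    sig = rng.normal(0, 1, 200).cumsum()
    res = cow_align_pair(sig, sig, segment_length=50, slack=5)
    n_seg = (len(sig) - 1) // 50
    assert res.benefit == pytest.approx(n_seg, abs=1e-9)
    assert np.allclose(res.warped, sig)
    assert res.boundary_positions[0] == 0
    assert res.boundary_positions[-1] == len(sig) - 1


def test_cow_recovers_shifted_peak():
    x = np.arange(300, dtype=float)
    ref = np.exp(-0.5 * ((x - 150) / 5) ** 2)
    query = np.exp(-0.5 * ((x - 153) / 5) ** 2)
    res = cow_align_pair(query, ref, segment_length=50, slack=5)
    before = np.corrcoef(query, ref)[0, 1]
    after = np.corrcoef(res.warped, ref)[0, 1]
    assert after > before


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("segment_length,slack", [(13, 1), (13, 2), (10, 2), (17, 1)])
def test_cow_dp_matches_exhaustive_enumeration(seed, segment_length, slack):
    """On every instance with <= 3 interior boundaries and slack <= 2 the DP
    benefit equals brute-force enumeration over all boundary placements."""
    rng = np.random.default_rng(seed)
    n = 40 if segment_length == 13 else 50
    q = rng.normal(0, 1, n).cumsum()
    r = rng.normal(0, 1, n).cumsum()
    n_seg = (n - 1) // segment_length
    assert n_seg - 1 <= 3
    res = cow_align_pair(q, r, segment_length, slack)
    assert res.benefit == pytest.approx(brute_force_cow_benefit(q, r, segment_length, slack),
                                        abs=1e-9)
    assert res.warped.size == n
    assert res.boundary_positions[0] == 0 and res.boundary_positions[-1] == n - 1
    assert np.all(np.diff(res.boundary_positions) > 0)


def test_cow_rejects_short_signals():
    with pytest.raises(ValueError, match="shorter"):
        cow_align_pair(np.arange(20.0), np.arange(20.0), segment_length=15, slack=2)


def test_choose_reference_cases():
    identical = FingerprintMatrix(np.tile(np.sin(np.arange(50)), (3, 1)),
                                  np.arange(50), ["a", "b", "c"])
    assert choose_reference(identical) == 0
    rng = np.random.default_rng(1)
    r0 = rng.normal(0, 1, 200).cumsum()
    r2 = rng.normal(0, 1, 200).cumsum()
    r1 = (r0 + r2) / 2 + rng.normal(0, 0.01, 200)
    m = FingerprintMatrix(np.vstack([r0, r1, r2]), np.arange(200), ["a", "b", "c"])
    assert choose_reference(m) == 1
    two = FingerprintMatrix(np.vstack([r0, r2]), np.arange(200), ["a", "b"])
    assert choose_reference(two) == 0
    with pytest.raises(ValueError, match="constant"):
        choose_reference(FingerprintMatrix(np.ones((3, 10)), np.arange(10),
                                           ["a", "b", "c"]))


def test_optimize_cow_tie_break_and_shift_recovery():
    # identical rows: every parameter pair scores equally -> smallest wins
    identical = FingerprintMatrix(np.tile(np.sin(np.arange(200) / 7), (3, 1)),
                                  np.arange(200), ["a", "b", "c"])
    params = optimize_cow(identical, [30, 50], [1, 5])
    assert (params.segment_length, params.slack) == (30, 1)
    with pytest.raises(ValueError):
        optimize_cow(identical, [], [1])

    # rows shifted by up to +-4 points: alignment must raise mean pairwise corr
    x = np.arange(600, dtype=float)
    template = (np.exp(-0.5 * ((x - 200) / 6) ** 2)
                + 0.7 * np.exp(-0.5 * ((x - 420) / 7) ** 2))
    rng = np.random.default_rng(3)
    rows = [np.interp(x, x + s, template) for s in rng.integers(-4, 5, size=6)]
    m = FingerprintMatrix(np.vstack(rows), x, [f"s{i}" for i in range(6)])
    params = optimize_cow(m, [30, 50], [1, 5])
    aligned = cow_align_matrix(m, params)

    def mean_pairwise_corr(X):
        C = np.corrcoef(X)
        return C[np.triu_indices_from(C, 1)].mean()

    assert mean_pairwise_corr(aligned.X) > mean_pairwise_corr(m.X)


# ---------------------------------------------------------------------------
# Row / column preprocessing
# ---------------------------------------------------------------------------

def test_snv_examples_and_idempotence():
    assert np.allclose(snv([1, 2, 3]), [-1, 0, 1])
    rng = np.random.default_rng(0)
    row = rng.normal(3, 5, 100)
    out = snv(row)
    assert abs(out.mean()) < 1e-12
    assert abs(out.std(ddof=1) - 1) < 1e-12
    assert np.allclose(snv(out), out)
    with pytest.raises(ValueError, match="constant"):
        snv(np.ones(5))
    with pytest.raises(ValueError, match="row"):
        snv_rows(np.vstack([row, np.ones(100)]))


def test_mean_center_stored_means():
    X = np.array([[1.0, 10.0], [3.0, 20.0]])
    Xc, means = mean_center(X)
    assert np.allclose(Xc[:, 0], [-1, 1])
    assert np.allclose(means, [2, 15])
    # a validation row equal to the calibration means centers to zero
    assert np.allclose(apply_mean_center(means[None, :], means), 0)
    # centering twice with stored means subtracts zeros the second time
    assert np.allclose(apply_mean_center(Xc, mean_center(Xc)[1]), Xc)


def test_normalize_sum():
    assert np.allclose(normalize_sum([2, -2, 4]), [0.25, -0.25, 0.5])
    rng = np.random.default_rng(1)
    row = rng.normal(size=40)
    assert abs(np.abs(normalize_sum(row)).sum() - 1) < 1e-12
    assert np.allclose(normalize_sum(3.7 * row), normalize_sum(row))
    with pytest.raises(ValueError):
        normalize_sum(np.zeros(4))


def test_subtract_blank():
    ax = np.arange(5.0)
    chrom = Spectrum(ax, np.array([0.0, 1.0, 3.0, 1.0, 0.0]), sample_id="s")
    lifted = Spectrum(ax, chrom.intensity + 5.0, sample_id="s")
    blank = Spectrum(ax, np.full(5, 5.0), sample_id="blank")
    rec = subtract_blank(lifted, blank)
    assert np.allclose(rec.intensity, chrom.intensity)
    zero = subtract_blank(chrom, chrom)
    assert np.allclose(zero.intensity, 0)
    ident = subtract_blank(chrom, Spectrum(ax, np.zeros(5), sample_id="b"))
    assert np.allclose(ident.intensity, chrom.intensity)
    with pytest.raises(ValueError, match="ax"):
        subtract_blank(chrom, Spectrum(ax + 1, np.zeros(5), sample_id="b"))


def test_recipe_uses_calibration_means_only():
    rng = np.random.default_rng(2)
    cal = FingerprintMatrix(rng.normal(size=(6, 30)), np.arange(30),
                            [f"c{i}" for i in range(6)])
    val = FingerprintMatrix(rng.normal(size=(3, 30)), np.arange(30),
                            [f"v{i}" for i in range(3)])
    recipe = PreprocessRecipe(["snv", "mean_center"])
    cal_t = recipe.fit_transform(cal)
    val_t = recipe.transform(val)
    assert np.allclose(cal_t.X.mean(axis=0), 0, atol=1e-12)
    # validation columns are NOT zero-mean: they were centered with the
    # calibration means, not their own
    assert not np.allclose(val_t.X.mean(axis=0), 0, atol=1e-6)
    manual = apply_mean_center(snv_rows(val.X), snv_rows(cal.X).mean(axis=0))
    assert np.array_equal(val_t.X, manual)
    # bit-identical on re-run
    assert np.array_equal(recipe.transform(val).X, val_t.X)


def test_recipe_validation():
    with pytest.raises(ValueError, match="unknown"):
        PreprocessRecipe(["snv", "despike"])
    with pytest.raises(ValueError, match="last"):
        PreprocessRecipe(["mean_center", "snv"])
    with pytest.raises(ValueError, match="once"):
        PreprocessRecipe(["mean_center", "mean_center"])
    with pytest.raises(ValueError, match="blank"):
        PreprocessRecipe(["blank_subtract"])
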