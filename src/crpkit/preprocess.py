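"""Signal alignment and row/column preprocessing.

Correlation optimized warping (COW) aligns a query signal to a reference by
piecewise-linear stretching/compression: both signals are cut into segments
of nominal length ``segment_length`` (grid points); each interior segment
boundary of the query may move by up to ``slack`` points; the warp chosen is
the one maximising the sum over segments of the Pearson correlation between
the reference segment and the query segment linearly interpolated to the
reference segment's length.  Endpoints stay fixed, so the warped signal has
the input length.  The optimum is found exactly by dynamic programming over
boundary shifts.

Also here: the row/column preprocessing used before multivariate modelling —
standard normal variate (SNV, per-row standardisation), column mean
centering (fitted on calibration rows only and re-applied to validation
rows), sum-normalisation, and blank subtraction — composable in order via
:class:`PreprocessRecipe`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import FingerprintMatrix, Spectrum

__all__ = [
    "CowParams",
    "WarpResult",
    "cow_align_pair",
    "cow_align_matrix",
    "choose_reference",
    "optimize_cow",
    "snv",
    "snv_rows",
    "mean_center",
    "apply_mean_center",
    "normalize_sum",
    "normalize_sum_rows",
    "subtract_blank",
    "PreprocessRecipe",
]

# Defaults matching the mass-spectral matrices this toolkit targets.
DEFAULT_SEGMENT = 150
DEFAULT_SLACK = 5


@dataclass(frozen=True)
class CowParams:
    """COW settings; ``segment_length >= slack + 3`` keeps boundaries ordered."""

    segment_length: int = DEFAULT_SEGMENT
    slack: int = DEFAULT_SLACK
    reference_index: int = 0

    def __post_init__(self) -> None:
        if self.slack < 1:
            raise ValueError("slack must be >= 1")
        if self.segment_length < self.slack + 3:
            raise ValueError("segment_length must be >= slack + 3")
        if self.reference_index < 0:
            raise ValueError("reference_index must be >= 0")


@dataclass
class WarpResult:
    """Outcome of one pairwise alignment.

    ``boundary_positions`` are the chosen query-side segment endpoints on the
    common grid (0-based); the first is 0 and the last n-1.  ``benefit`` is
    the summed per-segment correlation achieved (upper bound: the number of
    segments).
    """

    warped: np.ndarray
    boundary_positions: np.ndarray
    benefit: float


def _segment_bounds(n: int, segment_length: int) -> np.ndarray:
    n_seg = (n - 1) // segment_length
    if n_seg < 2:
        raise ValueError(
            f"signal of {n} points is shorter than 2 segments of {segment_length}"
        )
    bounds = [i * segment_length for i in range(n_seg)]
    bounds.append(n - 1)  # last segment absorbs the remainder
    return np.asarray(bounds, dtype=int)


def _interp_at(q: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of q (indexed 0..n-1) at fractional positions."""
    i0 = np.floor(pos).astype(int)
    np.clip(i0, 0, q.size - 2, out=i0)
    frac = pos - i0
    return q[i0] * (1.0 - frac) + q[i0 + 1] * frac


def _segment_corr_table(q: np.ndarray, ref_seg: np.ndarray,
                        starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Pearson correlation of each (start, end) query stretch vs ref_seg.

    Returns shape (len(starts), len(ends)); zero-variance segments (either
    side) contribute correlation 0 so flat baseline regions keep the dynamic
    program finite.
    """
    L = ref_seg.size
    t = np.linspace(0.0, 1.0, L)
    pos = starts[:, None, None] + (ends[None, :, None] - starts[:, None, None]) * t
    vals = _interp_at(q, pos)  # (a, b, L)
    vc = vals - vals.mean(axis=-1, keepdims=True)
    rc = ref_seg - ref_seg.mean()
    denom = np.sqrt(np.einsum("abl,abl->ab", vc, vc) * float(rc @ rc))
    num = vc @ rc
    corr = np.zeros(denom.shape)
    ok = denom > 0
    corr[ok] = num[ok] / denom[ok]
    return corr


def cow_align_pair(query: np.ndarray, reference: np.ndarray,
                   segment_length: int = DEFAULT_SEGMENT,
                   slack: int = DEFAULT_SLACK) -> WarpResult:
    """Align ``query`` to ``reference`` by COW; exact DP over boundary shifts.

    Ties between warp paths resolve toward smaller absolute boundary shifts
    (so an already-aligned query comes back unchanged with benefit equal to
    the segment count).
    """
    query = np.asarray(query, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if query.shape != reference.shape:
        raise ValueError("query and reference must have equal length")
    CowParams(segment_length=segment_length, slack=slack)  # validate the pair
    n = query.size
    bounds = _segment_bounds(n, segment_length)
    n_seg = bounds.size - 1
    # Shift candidates ordered by |shift| so argmax-first tie-breaks prefer
    # the least deformation.
    shifts = np.array(sorted(range(-slack, slack + 1), key=lambda s: (abs(s), s)))

    prev_states = np.array([0])
    prev_score = np.zeros(1)
    backs: list[tuple[np.ndarray, np.ndarray]] = []
    for j in range(n_seg):
        cur_states = np.array([0]) if j + 1 == n_seg else shifts
        ref_seg = reference[bounds[j]: bounds[j + 1] + 1]
        starts = (bounds[j] + prev_states).astype(float)
        ends = (bounds[j + 1] + cur_states).astype(float)
        corr = _segment_corr_table(query, ref_seg, starts, ends)
        total = prev_score[:, None] + corr
        back = np.argmax(total, axis=0)  # first max -> smallest |prev shift|
        prev_score = total[back, np.arange(cur_states.size)]
        backs.append((prev_states, back))
        prev_states = cur_states

    benefit = float(prev_score[0])
    chosen = np.zeros(n_seg + 1, dtype=int)
    cur = 0
    for j in range(n_seg - 1, -1, -1):
        states, back = backs[j]
        cur = int(back[cur])
        chosen[j] = states[cur]
    qpos = bounds + chosen

    warped = np.empty(n)
    for j in range(n_seg):
        L = bounds[j + 1] - bounds[j] + 1
        pos = np.linspace(qpos[j], qpos[j + 1], L)
        warped[bounds[j]: bounds[j + 1] + 1] = _interp_at(query, pos)
    return WarpResult(warped=warped, boundary_positions=qpos, benefit=benefit)


def choose_reference(m: FingerprintMatrix) -> int:
    """Row whose summed Pearson correlation to all other rows is largest.

    Constant rows are excluded from candidacy (their correlation is
    undefined); ties resolve to the lowest index.
    """
    X = m.X
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to choose a reference")
    sd = X.std(axis=1)
    candidates = np.where(sd > 0)[0]
    if candidates.size == 0:
        raise ValueError("all rows are constant; no reference can be chosen")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(X)
    C = np.nan_to_num(C, nan=0.0)
    C = (C + C.T) / 2.0  # corrcoef is only symmetric to the ulp
    np.fill_diagonal(C, 0.0)
    sums = C.sum(axis=1)
    sums[sd == 0] = -np.inf
    return int(np.argmax(sums))


def cow_align_matrix(m: FingerprintMatrix, params: CowParams) -> FingerprintMatrix:
    """Align every row to the reference row; the reference is unchanged."""
    if not 0 <= params.reference_index < m.n_samples:
        raise ValueError("reference_index out of range")
    ref = m.X[params.reference_index]
    X = np.empty_like(m.X)
    for i in range(m.n_samples):
        if i == params.reference_index:
            X[i] = ref
        else:
            X[i] = cow_align_pair(m.X[i], ref, params.segment_length, params.slack).warped
    return FingerprintMatrix(X, m.axis.copy(), list(m.sample_ids),
                             None if m.class_labels is None else list(m.class_labels),
                             class_set=m.class_set)


def _alignment_score(raw: FingerprintMatrix, aligned: FingerprintMatrix) -> float:
    """Simplicity + peak factor, the warping-quality score used for tuning.

    Simplicity rewards a low effective rank of the aligned, row-normalised
    matrix (sum sigma^4 / (sum sigma^2)^2 over singular values); the peak
    factor penalises area distortion introduced by the warp.
    """
    Xa = aligned.X
    norms = np.linalg.norm(Xa, axis=1)
    norms[norms == 0] = 1.0
    sv = np.linalg.svd(Xa / norms[:, None], compute_uv=False)
    s2 = sv ** 2
    simplicity = float((s2 ** 2).sum() / (s2.sum() ** 2)) if s2.sum() > 0 else 0.0
    area_raw = np.abs(raw.X).sum(axis=1)
    area_warp = np.abs(Xa).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(area_raw > 0, np.abs(area_warp - area_raw) / area_raw, 0.0)
    peak_factor = 1.0 - float(np.minimum(1.0, rel).mean())
    return simplicity + peak_factor


def optimize_cow(m: FingerprintMatrix, segment_grid, slack_grid,
                 reference_index: int | None = None) -> CowParams:
    """Grid-search (segment, slack) maximising simplicity + peak factor.

    Ties resolve to the smaller segment, then the smaller slack.
    """
    segment_grid = sorted(int(s) for s in segment_grid)
    slack_grid = sorted(int(s) for s in slack_grid)
    if not segment_grid or not slack_grid:
        raise ValueError("segment_grid and slack_grid must be non-empty")
    ref = choose_reference(m) if reference_index is None else reference_index
    best: tuple[float, CowParams] | None = None
    for seg in segment_grid:
        for sl in slack_grid:
            params = CowParams(segment_length=seg, slack=sl, reference_index=ref)
            aligned = cow_align_matrix(m, params)
            score = _alignment_score(m, aligned)
            if best is None or score > best[0] + 1e-12:
                best = (score, params)
    assert best is not None
    return best[1]


def snv(row: np.ndarray) -> np.ndarray:
    """Standard normal variate: (x - mean) / sd with the sample (n-1) sd."""
    row = np.asarray(row, dtype=float)
    if row.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = row.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant row")
    return (row - row.mean()) / sd


def snv_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"SNV undefined for constant row(s) {bad.tolist()}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def mean_center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each column; returns (centered, column means) so the means can
    be re-applied to validation rows without refitting."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    return X - means, means


def apply_mean_center(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) - np.asarray(means, dtype=float)


def normalize_sum(row: np.ndarray) -> np.ndarray:
    """Divide by the sum of absolute values; output satisfies sum|y| = 1."""
    row = np.asarray(row, dtype=float)
    total = np.abs(row).sum()
    if total == 0:
        raise ValueError("cannot sum-normalize an all-zero row")
    return row / total


def normalize_sum_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    totals = np.abs(X).sum(axis=1)
    bad = np.where(totals == 0)[0]
    if bad.size:
        raise ValueError(f"all-zero row(s) {bad.tolist()} cannot be normalized")
    return X / totals[:, None]


def subtract_blank(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Point-wise sample - blank (baseline removal); may go negative."""
    if not np.array_equal(sample.axis, blank.axis):
        raise ValueError("sample and blank axes differ")
    return Spectrum(sample.axis, sample.intensity - blank.intensity,
                    sample_id=sample.sample_id, replicate_id=sample.replicate_id,
                    class_label=sample.class_label)


_RECIPE_STEPS = ("cow", "blank_subtract", "snv", "normalize_sum", "mean_center")


class PreprocessRecipe:
    """Ordered preprocessing steps with calibration-only fitted statistics.

    Steps are drawn from {cow, blank_subtract, snv, normalize_sum,
    mean_center}; ``mean_center`` may appear at most once and must be last.
    ``fit`` learns the column means (and, for cow, stores the calibration
    reference row); ``transform`` applies the same fitted steps to any
    matrix, so validation rows are centered with calibration means, never
    refit.
    """

    def __init__(self, steps, cow_params: CowParams | None = None,
                 blank: Spectrum | None = None):
        steps = tuple(steps)
        unknown = [s for s in steps if s not in _RECIPE_STEPS]
        if unknown:
            raise ValueError(f"unknown preprocessing step(s): {unknown}")
        if steps.count("mean_center") > 1:
            raise ValueError("mean_center may appear at most once")
        if "mean_center" in steps and steps[-1] != "mean_center":
            raise ValueError("mean_center must be the last step")
        if "cow" in steps and cow_params is None:
            cow_params = CowParams()
        if "blank_subtract" in steps and blank is None:
            raise ValueError("blank_subtract requires a blank spectrum")
        self.steps = steps
        self.cow_params = cow_params
        self.blank = blank
        self.column_means_: np.ndarray | None = None
        self.reference_row_: np.ndarray | None = None

    def _apply_unfitted(self, m: FingerprintMatrix) -> np.ndarray:
        X = m.X.copy()
        for step in self.steps:
            if step == "cow":
                assert self.reference_row_ is not None
                p = self.cow_params
                for i in range(X.shape[0]):
                    if np.array_equal(X[i], self.reference_row_):
                        continue
                    X[i] = cow_align_pair(X[i], self.reference_row_,
                                          p.segment_length, p.slack).warped
            elif step == "blank_subtract":
                assert self.blank is not None
                if not np.array_equal(m.axis, self.blank.axis):
                    raise ValueError("blank axis does not match matrix axis")
                X = X - self.blank.intensity
            elif step == "snv":
                X = snv_rows(X)
            elif step == "normalize_sum":
                X = normalize_sum_rows(X)
            elif step == "mean_center":
                pass  # handled with fitted means
        return X

    def fit(self, calibration: FingerprintMatrix) -> "PreprocessRecipe":
        if "cow" in self.steps:
            self.reference_row_ = calibration.X[self.cow_params.reference_index].copy()
        X = self._apply_unfitted(calibration)
        if "mean_center" in self.steps:
            self.column_means_ = X.mean(axis=0)
        return self

    def transform(self, m: FingerprintMatrix) -> FingerprintMatrix:
        if "mean_center" in self.steps and self.column_means_ is None:
            raise ValueError("recipe with mean_center must be fitted first")
        if "cow" in self.steps and self.reference_row_ is None:
            raise ValueError("recipe with cow must be fitted first")
        X = self._apply_unfitted(m)
        if "mean_center" in self.steps:
            X = apply_mean_center(X, self.column_means_)
        return FingerprintMatrix(X, m.axis.copy(), list(m.sample_ids),
                                 None if m.class_labels is None else list(m.class_labels),
                                 class_set=m.class_set)

    def fit_transform(self, calibration: FingerprintMatrix) -> FingerprintMatrix:
        return self.fit(calibration).transform(calibration)
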