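"""Synthetic two-class CRP fingerprint generator.

Emulates MALDI-TOF fingerprints of two herb classes in the 2-6 kDa window:
each class is a template of Gaussian marker peaks (cysteine-rich peptides
appear as near-Gaussian singly-charged peaks in reflector mode at this
resolution), acquired in triplicate with

* multiplicative amplitude noise per marker (shot-to-shot ionisation
  variability),
* additive white noise and a constant baseline offset,
* a per-replicate global m/z shift and a smooth local warp (calibration
  drift), which is what correlation optimized warping later corrects.

The default templates carry the four marker masses of the two root herbs the
toolkit was built around — 3811.8 / 4724.4 Da ("RA") and 3944.3 / 4780.1 Da
("RH") — on a 30935-point grid, and the default benchmark draws 38 RH + 49 RA
samples in triplicate, mirroring the study-scale matrix shape.

Randomness: one integer seed; per-(class, sample, replicate) substreams are
derived by counters through ``numpy.random.SeedSequence``, so generating a
dataset is independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FingerprintMatrix, Spectrum, assemble_matrix, average_replicates

__all__ = [
    "ClassTemplate",
    "SimulationParams",
    "simulate_spectrum",
    "simulate_dataset",
    "default_templates",
    "default_benchmark",
]


@dataclass(frozen=True)
class ClassTemplate:
    """Noiseless class fingerprint: Gaussian markers on a fixed grid.

    ``markers`` is a tuple of (center Da, amplitude, width Da) triples; width
    is the Gaussian sigma.  Centers must lie inside ``axis_range``.
    """

    class_label: str
    markers: tuple[tuple[float, float, float], ...]
    axis_range: tuple[float, float] = (2000.0, 6000.0)
    n_points: int = 30935

    def __post_init__(self) -> None:
        lo, hi = self.axis_range
        if not lo < hi:
            raise ValueError("axis_range must be (lo, hi) with lo < hi")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        for c, a, w in self.markers:
            if not lo <= c <= hi:
                raise ValueError(f"marker center {c} outside axis_range {self.axis_range}")
            if a <= 0 or w <= 0:
                raise ValueError("marker amplitudes and widths must be > 0")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.axis_range[0], self.axis_range[1], self.n_points)

    def clean_signal(self, grid: np.ndarray | None = None) -> np.ndarray:
        """Sum of the template Gaussians, no baseline and no noise."""
        x = self.grid if grid is None else np.asarray(grid, dtype=float)
        y = np.zeros_like(x)
        for c, a, w in self.markers:
            y += a * np.exp(-0.5 * ((x - c) / w) ** 2)
        return y


@dataclass(frozen=True)
class SimulationParams:
    """Noise / distortion model; all magnitudes nonnegative.

    intensity_noise_cv: per-marker multiplicative amplitude CV (fraction).
    additive_noise_sd:  white noise sd in intensity units.
    baseline_level:     constant offset added to every replicate.
    global_shift_sd:    sd (Da) of the per-replicate rigid m/z shift.
    local_warp_sd:      sd (Da) of a smooth (5-knot) warp field.
    n_replicates:       acquisitions per sample (averaged downstream).
    """

    intensity_noise_cv: float = 0.1
    additive_noise_sd: float = 0.02
    baseline_level: float = 0.05
    global_shift_sd: float = 1.0
    local_warp_sd: float = 0.5
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intensity_noise_cv", "additive_noise_sd", "baseline_level",
                     "global_shift_sd", "local_warp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


_N_WARP_KNOTS = 5


def _replicate_rng(p: SimulationParams, class_index: int, sample_index: int,
                   replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(p.seed),
                                spawn_key=(class_index, sample_index, replicate))
    return np.random.default_rng(ss)


def simulate_spectrum(t: ClassTemplate, p: SimulationParams, sample_id: str,
                      class_index: int = 0, sample_index: int = 0) -> list[Spectrum]:
    """Simulate the replicate acquisitions of one sample.

    Deterministic given (seed, class_index, sample_index): the same sample
    regenerates bit-identically regardless of how many other samples were
    drawn before it.
    """
    x = t.grid
    out: list[Spectrum] = []
    for rep in range(p.n_replicates):
        rng = _replicate_rng(p, class_index, sample_index, rep)
        shift = rng.normal(0.0, p.global_shift_sd) if p.global_shift_sd > 0 else 0.0
        if p.local_warp_sd > 0:
            knots_x = np.linspace(x[0], x[-1], _N_WARP_KNOTS)
            knots_y = rng.normal(0.0, p.local_warp_sd, _N_WARP_KNOTS)
            warp = np.interp(x, knots_x, knots_y)
        else:
            warp = 0.0
        y = np.full_like(x, float(p.baseline_level))
        for c, a, w in t.markers:
            eps = rng.normal(0.0, p.intensity_noise_cv) if p.intensity_noise_cv > 0 else 0.0
            y += a * (1.0 + eps) * np.exp(-0.5 * ((x - c - shift - warp) / w) ** 2)
        if p.additive_noise_sd > 0:
            y += rng.normal(0.0, p.additive_noise_sd, x.size)
        out.append(Spectrum(x, y, sample_id=sample_id, replicate_id=rep,
                            class_label=t.class_label))
    return out


def simulate_dataset(tA: ClassTemplate, tB: ClassTemplate,
                     n_per_class: int | tuple[int, int],
                     p: SimulationParams) -> FingerprintMatrix:
    """Replicate-averaged two-class dataset; rows = class A samples then class B."""
    if (tA.axis_range, tA.n_points) != (tB.axis_range, tB.n_points):
        raise ValueError("class templates must share axis_range and n_points")
    if isinstance(n_per_class, int):
        nA = nB = n_per_class
    else:
        nA, nB = n_per_class
    if nA < 1 or nB < 1:
        raise ValueError("n_per_class must be >= 1 for both classes")
    rows: list[Spectrum] = []
    for ci, (t, n) in enumerate(((tA, nA), (tB, nB))):
        for i in range(n):
            sid = f"{t.class_label}{i + 1:02d}"
            reps = simulate_spectrum(t, p, sid, class_index=ci, sample_index=i)
            rows.append(average_replicates(reps))
    return assemble_matrix(rows, class_set=(tA.class_label, tB.class_label))


def default_templates(n_points: int = 30935) -> tuple[ClassTemplate, ClassTemplate]:
    """RH / RA marker templates (hedytide and astratide masses, 2-6 kDa grid)."""
    rh = ClassTemplate("RH", ((3944.3, 1.0, 2.0), (4780.1, 0.8, 2.2)), n_points=n_points)
    ra = ClassTemplate("RA", ((3811.8, 1.0, 2.0), (4724.4, 0.8, 2.2)), n_points=n_points)
    return rh, ra


def default_benchmark(seed: int = 7, n_points: int = 30935,
                      n_per_class: tuple[int, int] = (38, 49),
                      **param_overrides) -> FingerprintMatrix:
    """The toolkit's standard synthetic benchmark: 38 RH + 49 RA, triplicates."""
    rh, ra = default_templates(n_points=n_points)
    params = SimulationParams(seed=seed, **param_overrides)
    return simulate_dataset(rh, ra, n_per_class, params)
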