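"""Synthetic forearm phantoms and simulated longitudinal cohorts.

Every downstream stage is exercised against known ground truth, so no
patient data are needed.  The phantom emulates the acquisition geometry of
the study protocol: 2D gradient echoes at TE = 3.45/4.60/5.75 ms, nine
6 mm axial slices with a 12 mm gap, 320x320 matrix, 0.56x0.56 mm pixels.
Geometry is deliberately schematic -- concentric discs with the muscle
compartment split into ten angular sectors -- because only the label and
statistics structure matters, not anatomical realism.

The cohort generator mirrors the study design: 15 non-ambulant subjects at
baseline with monotone attrition to 9/7/7 at 3/6/12 months, a
time-non-ambulant covariate, a subject random intercept and i.i.d.
residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .dixon import DEFAULT_ECHO_TIMES, DEFAULT_PIXEL_SIZE, EchoSeries
from .labels import ALL_LABELS
from .roi import LabelMask

__all__ = [
    "PhantomSpec",
    "FieldSpec",
    "CohortSpec",
    "build_forearm_phantom",
    "simulate_echoes",
    "simulate_cohort",
    "noise_sd_for_snr",
    "scale_ff_to_target",
]

#: default per-muscle true fat fractions (percent), a disease-like profile
#: with the radial extensor group (label 6) most affected
DEFAULT_MUSCLE_FF = {
    1: 12.0, 2: 10.0, 3: 13.0, 4: 9.0, 5: 8.0,
    6: 31.2, 7: 15.0, 8: 14.0, 9: 13.0, 10: 12.0,
}


@dataclass
class PhantomSpec:
    """Geometry and ground-truth composition of the forearm phantom."""

    grid_shape: tuple[int, int] = (320, 320)
    pixel_size: tuple[float, float] = DEFAULT_PIXEL_SIZE
    n_slices: int = 9
    slice_thickness: float = 6.0  # mm
    slice_gap: float = 12.0  # mm
    muscle_ff_true: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MUSCLE_FF)
    )
    compartment_radius: float = 30.0  # mm
    bone_radius: float = 7.0  # mm
    subcutaneous_ring: float = 6.0  # mm
    total_signal: float = 1.0  # arbitrary units per tissue pixel

    def __post_init__(self) -> None:
        if min(self.pixel_size) <= 0:
            raise ValueError("pixel_size must be positive")
        if set(self.muscle_ff_true) != set(ALL_LABELS):
            raise ValueError(
                "muscle_ff_true must define labels 1..10 exactly; got "
                f"{sorted(self.muscle_ff_true)}"
            )
        for lab, ff in self.muscle_ff_true.items():
            if not 0.0 <= ff <= 100.0:
                raise ValueError(f"fat fraction for label {lab} outside [0, 100]")
        if not 0 < self.bone_radius < self.compartment_radius:
            raise ValueError("need 0 < bone_radius < compartment_radius")
        if self.subcutaneous_ring < 0:
            raise ValueError("subcutaneous_ring must be nonnegative")
        if self.total_signal <= 0:
            raise ValueError("total_signal must be positive")
        half_fov = min(
            self.grid_shape[0] * self.pixel_size[0],
            self.grid_shape[1] * self.pixel_size[1],
        ) / 2.0
        if self.compartment_radius + self.subcutaneous_ring >= half_fov:
            raise ValueError("phantom does not fit inside the field of view")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def slice_spacing(self) -> float:
        return self.slice_thickness + self.slice_gap


@dataclass
class FieldSpec:
    """Smooth field-induced phase maps as low-order 2D polynomials.

    Coefficient matrices are in the ``numpy.polynomial.polynomial.polyval2d``
    convention, evaluated on normalised coordinates x, y in [-1, 1] over the
    grid.  ``phase0_coeffs`` gives the receiver phase phi0; the
    ``phase_per_echo_coeffs`` give phi, the field phase accrued per echo
    spacing.  By default the generated 2*phi map is checked to step less
    than ``max_gradient`` between neighbouring pixels so unwrapping is
    well-posed; set ``allow_wrap_violation`` to generate failure cases.
    """

    phase0_coeffs: np.ndarray = field(
        default_factory=lambda: np.array([[0.4, 0.9], [1.3, 0.0]])
    )
    phase_per_echo_coeffs: np.ndarray = field(
        default_factory=lambda: np.array([[0.3, 2.2], [2.9, 1.1]])
    )
    max_gradient: float = np.pi  # radians/pixel bound on the 2*phi map
    allow_wrap_violation: bool = False

    def evaluate(self, grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(phi0, phi) maps for one slice of the given in-plane shape."""
        ny, nx = grid_shape
        y = np.linspace(-1.0, 1.0, ny)
        x = np.linspace(-1.0, 1.0, nx)
        yy, xx = np.meshgrid(y, x, indexing="ij")
        phi0 = npoly.polyval2d(xx, yy, np.atleast_2d(self.phase0_coeffs))
        phi = npoly.polyval2d(xx, yy, np.atleast_2d(self.phase_per_echo_coeffs))
        if not self.allow_wrap_violation:
            two_phi = 2.0 * phi
            step = max(
                float(np.abs(np.diff(two_phi, axis=0)).max(initial=0.0)),
                float(np.abs(np.diff(two_phi, axis=1)).max(initial=0.0)),
            )
            if step >= self.max_gradient:
                raise ValueError(
                    f"2*phi steps {step:.3f} rad/pixel, beyond the capture "
                    f"bound {self.max_gradient:.3f}; reduce the coefficients "
                    "or set allow_wrap_violation"
                )
        return phi0, phi


@dataclass
class CohortSpec:
    """Design of a simulated longitudinal cohort.

    Defaults reproduce the study conditions: 15 subjects at baseline,
    monotone dropout to 9/7/7 at 3/6/12 months, baseline mean total
    compartment fat fraction 14.1%, true mean changes (1.4, 3.9, 5.0)
    percentage points, time non-ambulant uniform on 4.7--41.6 months.
    """

    n_subjects: int = 15
    visit_months: tuple[int, ...] = (0, 3, 6, 12)
    n_per_visit: tuple[int, ...] = (15, 9, 7, 7)
    baseline_mean: float = 14.1  # percent
    true_mean_change: dict[int, float] = field(
        default_factory=lambda: {3: 1.4, 6: 3.9, 12: 5.0}
    )
    between_subject_sd: float = 5.0  # percent
    residual_sd: float = 2.0  # percent
    covariate_range_months: tuple[float, float] = (4.7, 41.6)
    covariate_effect: float = 0.2  # percent per month non-ambulant
    outcome_name: str = "total_ff_central"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_visit) != len(self.visit_months):
            raise ValueError("n_per_visit must match visit_months")
        if self.visit_months[0] != 0:
            raise ValueError("first visit must be baseline (0 months)")
        if self.n_per_visit[0] != self.n_subjects:
            raise ValueError("all subjects must attend baseline")
        if any(
            a < b for a, b in zip(self.n_per_visit, self.n_per_visit[1:])
        ):
            raise ValueError("n_per_visit must be non-increasing (monotone dropout)")
        if self.between_subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        missing = set(self.visit_months[1:]) - set(self.true_mean_change)
        if missing:
            raise ValueError(f"true_mean_change missing visits {sorted(missing)}")
        lo, hi = self.covariate_range_months
        if not lo <= hi:
            raise ValueError("covariate range must be ordered")


def build_forearm_phantom(
    spec: PhantomSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, LabelMask]:
    """Ground-truth water and fat maps plus the muscle label mask.

    Concentric geometry: signal-free bone disc, muscle annulus split into
    ten equal angular sectors (labels 1..10, dorsal 1-6 in the upper half),
    and a pure-fat subcutaneous ring.  Within sector r every pixel holds
    fat = total_signal * ff_true[r]/100 and water = total_signal - fat, so
    per-ROI fat fractions equal the specified truth exactly.  The
    compartment tapers mildly (5%) from the proximal to the distal end of
    the stack so slice levels are distinguishable.  Construction is
    deterministic; ``seed`` is accepted for interface symmetry.

    Returns arrays of shape (n_slices, ny, nx).
    """
    del seed  # geometry is deterministic
    ny, nx = spec.grid_shape
    py, px = spec.pixel_size
    yy = (np.arange(ny) - (ny - 1) / 2.0) * py
    xx = (np.arange(nx) - (nx - 1) / 2.0) * px
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    r = np.hypot(X, Y)
    theta = np.mod(np.arctan2(Y, X), 2.0 * np.pi)
    sector = (theta / (2.0 * np.pi) * len(ALL_LABELS)).astype(int) + 1
    sector = np.clip(sector, 1, len(ALL_LABELS))

    water = np.zeros((spec.n_slices, ny, nx))
    fat = np.zeros_like(water)
    labels = np.zeros(water.shape, dtype=np.int16)

    mid = (spec.n_slices - 1) / 2.0
    for k in range(spec.n_slices):
        taper = 1.0 + (0.05 * (k - mid) / mid if mid > 0 else 0.0)
        comp_r = spec.compartment_radius * taper
        muscle = (r > spec.bone_radius) & (r <= comp_r)
        ring = (r > comp_r) & (r <= comp_r + spec.subcutaneous_ring)
        labels[k][muscle] = sector[muscle]
        for lab, ff in spec.muscle_ff_true.items():
            sel = muscle & (sector == lab)
            fat[k][sel] = spec.total_signal * ff / 100.0
            water[k][sel] = spec.total_signal * (1.0 - ff / 100.0)
        fat[k][ring] = spec.total_signal
    return water, fat, LabelMask(labels=labels, pixel_area=px * py)


def noise_sd_for_snr(total_signal: float, snr: float = 50.0) -> float:
    """Per-component complex noise sd giving the target in-phase magnitude SNR."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return total_signal / snr


def simulate_echoes(
    water: np.ndarray,
    fat: np.ndarray,
    fieldmap: FieldSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    echo_times: tuple[float, float, float] = DEFAULT_ECHO_TIMES,
    pixel_size: tuple[float, float] = DEFAULT_PIXEL_SIZE,
) -> EchoSeries:
    """Forward-simulate the three-point Dixon acquisition.

    S_k = (W + F*exp(i*(k-1)*pi)) * exp(i*(phi0 + (k-1)*phi)) + eps_k with
    eps_k complex Gaussian, sd ``noise_sd`` per component.  Deterministic
    given ``seed``.  The same smooth field maps are applied to every slice.
    """
    water = np.asarray(water, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if water.shape != fat.shape:
        raise ValueError("water and fat must share one grid")
    if water.min() < 0 or fat.min() < 0:
        raise ValueError("water and fat must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    fieldmap = fieldmap if fieldmap is not None else FieldSpec()
    phi0, phi = fieldmap.evaluate(water.shape[-2:])

    rng = np.random.default_rng(seed)
    echoes = []
    for k in range(3):
        chem = 1.0 if k % 2 == 0 else -1.0  # exp(i*k*pi) for the fat peak
        s = (water + chem * fat) * np.exp(1j * (phi0 + k * phi))
        if noise_sd > 0:
            s = s + noise_sd * (
                rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
            )
        echoes.append(s)
    return EchoSeries(
        S1=echoes[0], S2=echoes[1], S3=echoes[2],
        echo_times=echo_times, pixel_size=pixel_size,
    )


def scale_ff_to_target(
    spec: PhantomSpec, target_total_ff: float, slice_index: int | None = None
) -> PhantomSpec:
    """Rescale per-muscle truths so the CSA-weighted compartment mean hits a target.

    Keeps the relative profile across muscles, weights by the actual pixel
    counts of the generated mask (central slice unless ``slice_index`` is
    given), and returns a new spec whose true weighted-mean fat fraction
    equals ``target_total_ff`` exactly.
    """
    if not 0.0 <= target_total_ff <= 100.0:
        raise ValueError("target_total_ff must lie in [0, 100]")
    _, _, mask = build_forearm_phantom(spec)
    k = spec.n_slices // 2 if slice_index is None else slice_index
    lab = mask.labels[k]
    counts = {l: int((lab == l).sum()) for l in ALL_LABELS}
    total = sum(counts.values())
    current = sum(
        spec.muscle_ff_true[l] * counts[l] for l in ALL_LABELS
    ) / total
    if current == 0:
        raise ValueError("cannot scale an all-zero fat-fraction profile")
    factor = target_total_ff / current
    scaled = {l: spec.muscle_ff_true[l] * factor for l in ALL_LABELS}
    if max(scaled.values()) > 100.0:
        raise ValueError("scaling pushes a muscle fat fraction above 100%")
    out = PhantomSpec(**{**spec.__dict__, "muscle_ff_true": scaled})
    return out


def simulate_cohort(cohort: CohortSpec) -> pd.DataFrame:
    """Simulate a longitudinal outcome table with monotone dropout.

    Generating model (z centred at the covariate-range midpoint so the
    baseline mean is interpretable directly):

        y_ij = baseline_mean + change[visit_j] + gamma*(z_i - z_mid)
               + b_i + e_ij

    with b_i ~ N(0, between_subject_sd^2) and e_ij ~ N(0, residual_sd^2).
    Which subjects drop out (and the single subject off steroids) are drawn
    from the seeded generator; dropout is monotone, so the table has
    sum(n_per_visit) rows.

    Columns: subject_id, visit_months, outcome_name, value,
    time_non_ambulant, steroid.
    """
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n_subjects
    lo, hi = cohort.covariate_range_months
    z = rng.uniform(lo, hi, size=n)
    z_mid = (lo + hi) / 2.0
    b = rng.normal(0.0, cohort.between_subject_sd, size=n)

    # last attended visit per subject, matching n_per_visit exactly
    order = rng.permutation(n)
    last_visit = np.full(n, cohort.visit_months[-1])
    pos = 0
    for v_prev, n_prev, n_next in zip(
        cohort.visit_months, cohort.n_per_visit, cohort.n_per_visit[1:]
    ):
        n_drop = n_prev - n_next
        last_visit[order[pos : pos + n_drop]] = v_prev
        pos += n_drop

    no_steroid = rng.integers(0, n)

    rows = []
    for i in range(n):
        for v in cohort.visit_months:
            if v > last_visit[i]:
                break
            delta = 0.0 if v == 0 else cohort.true_mean_change[v]
            e = rng.normal(0.0, cohort.residual_sd) if cohort.residual_sd > 0 else 0.0
            rows.append(
                {
                    "subject_id": f"S{i + 1:02d}",
                    "visit_months": int(v),
                    "outcome_name": cohort.outcome_name,
                    "value": cohort.baseline_mean
                    + delta
                    + cohort.covariate_effect * (z[i] - z_mid)
                    + b[i]
                    + e,
                    "time_non_ambulant": z[i],
                    "steroid": i != no_steroid,
                }
            )
    return pd.DataFrame(rows)
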