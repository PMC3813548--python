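"""Synthetic SEEG cohorts with prescribed connectivity statistics.

No interictal SEEG with outcome labels is publicly available, so every
downstream stage is exercised on simulated recordings whose population
correlation structure is controlled exactly:

* :func:`sample_target_correlation` draws a valid correlation matrix whose
  off-diagonal mean and SD hit requested targets, via truncated-normal draws
  projected to the nearest correlation matrix (Higham alternating
  projections) with a recentering refinement;
* :func:`simulate_recording` colours independent white Gaussian channels with
  a matrix square root of the target, band-limits the result to 5–50 Hz (so
  the analysis filter leaves the correlations untouched), then adds 60 Hz
  line noise, sub-0.5 Hz drift and biexponential spike transients;
* :func:`simulate_cohort` assembles two patient groups — weak/homogeneous
  vs. strong/heterogeneous connectivity — with per-patient region coverage,
  enough pre-seizure data for the segment-selection rules, and a terminal
  annotated seizure 30 minutes after the last eligible window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .preprocessing import (
    REGIONS,
    ChannelInfo,
    FilterSpec,
    Recording,
    bandpass_filter,
)

__all__ = [
    "CorrelationTarget",
    "ArtifactSpec",
    "CohortSpec",
    "InfeasibleTargetError",
    "ProjectionConvergenceError",
    "nearest_correlation",
    "sample_target_correlation",
    "simulate_recording",
    "simulate_cohort",
    "iter_cohort",
]


class InfeasibleTargetError(ValueError):
    """Requested off-diagonal statistics admit no correlation matrix nearby."""


class ProjectionConvergenceError(RuntimeError):
    """Alternating projections failed to reach a correlation matrix."""


@dataclass
class CorrelationTarget:
    """A population correlation matrix with known off-diagonal statistics."""

    n_channels: int
    target_mean: float
    target_sd: float
    matrix: np.ndarray

    def realized_stats(self) -> tuple[float, float]:
        """Off-diagonal mean and sample SD actually achieved by ``matrix``."""
        upper = self.matrix[np.triu_indices(self.n_channels, k=1)]
        sd = 0.0 if upper.size == 1 else float(upper.std(ddof=1))
        return float(upper.mean()), sd


@dataclass(frozen=True)
class ArtifactSpec:
    """Amplitudes (in multiples of per-channel clean-signal SD) and rates of
    the injected artifacts: 60 Hz mains interference, slow (< 0.5 Hz) drift,
    and Poisson-timed biexponential spike transients."""

    line_noise_amplitude: float = 2.0
    drift_amplitude: float = 1.0
    spike_rate: float = 0.05
    spike_amplitude: float = 8.0
    spike_duration: float = 0.07

    def __post_init__(self):
        for name in (
            "line_noise_amplitude",
            "drift_amplitude",
            "spike_rate",
            "spike_amplitude",
            "spike_duration",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic two-group cohort.

    Positive-outcome (seizure-free) patients draw their target off-diagonal
    (mean, SD) uniformly from low ranges, negative-outcome patients from
    higher, more dispersed ranges; each patient samples 4–8 of the 9 temporal
    regions.  Defaults give 12 + 11 patients with three ~90 s interictal
    segments at 200 Hz and a seizure annotated 30 minutes after the eligible
    span.
    """

    n_positive: int = 12
    n_negative: int = 11
    pos_mean_range: tuple[float, float] = (0.05, 0.25)
    pos_sd_range: tuple[float, float] = (0.02, 0.10)
    neg_mean_range: tuple[float, float] = (0.25, 0.55)
    neg_sd_range: tuple[float, float] = (0.10, 0.25)
    regions_per_patient: tuple[int, int] = (4, 8)
    sampling_rate: float = 200.0
    n_segments: int = 3
    segment_duration: float = 90.0
    preictal_exclusion_s: float = 1800.0
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_positive < 2 or self.n_negative < 2:
            raise ValueError("each group needs at least 2 patients")
        if self.sampling_rate <= 120.0:
            raise ValueError(
                "sampling_rate must exceed 120 Hz so the 60 Hz stop is representable"
            )
        lo, hi = self.regions_per_patient
        if not (2 <= lo <= hi <= len(REGIONS)):
            raise ValueError("regions_per_patient must be a range within [2, 9]")
        for name in ("pos_mean_range", "neg_mean_range"):
            a, b = getattr(self, name)
            if not (-1.0 < a <= b < 1.0):
                raise ValueError(f"{name} must be a valid interval inside (-1, 1)")
        for name in ("pos_sd_range", "neg_sd_range"):
            a, b = getattr(self, name)
            if not (0.0 <= a <= b):
                raise ValueError(f"{name} must be a valid non-negative interval")
        if self.n_segments < 1 or self.segment_duration <= 0:
            raise ValueError("need n_segments ≥ 1 and a positive segment_duration")

    def to_dict(self) -> dict:
        return asdict(self)


def nearest_correlation(
    matrix: np.ndarray, tolerance: float = 1e-8, max_iterations: int = 200
) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix onto the correlation matrices.

    Alternating projections between the positive-semidefinite cone and the
    unit-diagonal affine set, with Dykstra's correction so the limit is the
    nearest correlation matrix in the Frobenius norm.  An input that is
    already a valid correlation matrix is returned unchanged.

    Raises
    ------
    ProjectionConvergenceError
        Naming the eigenvalue residual if ``max_iterations`` is exhausted.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(a, a.T, atol=1e-8, rtol=0.0):
        raise ValueError("input must be symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=1e-8, rtol=0.0):
        raise ValueError("input must have a unit diagonal")

    y = a.copy()
    ds = np.zeros_like(a)
    residual = np.inf
    for _ in range(max(max_iterations, 1)):
        r = y - ds
        w, v = np.linalg.eigh(r)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        x = (x + x.T) / 2.0
        ds = x - r
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        residual = -float(np.linalg.eigvalsh(y).min())
        if residual <= tolerance:
            break
    else:
        raise ProjectionConvergenceError(
            f"no correlation matrix within {max_iterations} iterations; "
            f"eigenvalue residual {residual:.3e} exceeds tolerance {tolerance:.1e}"
        )
    y = np.clip((y + y.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(y, 1.0)
    return y


def _build_symmetric(offdiag: np.ndarray, n: int) -> np.ndarray:
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = offdiag
    m[(iu[1], iu[0])] = offdiag
    return m


def sample_target_correlation(
    n_channels: int,
    target_mean: float,
    target_sd: float,
    rng: np.random.Generator,
    max_retries: int = 50,
    mean_tol: float = 0.02,
    sd_tol: float = 0.03,
) -> CorrelationTarget:
    """Draw a correlation matrix with prescribed off-diagonal mean and SD.

    Off-diagonals are drawn from a normal truncated to (−0.99, 0.99),
    symmetrised, and projected to the nearest correlation matrix.  Because the
    projection can bias the realised statistics, up to five recentering rounds
    shift and rescale the off-diagonals toward the targets and re-project; the
    draw is accepted once the realised mean is within ``mean_tol`` and the
    realised SD within ``sd_tol`` of their targets, and redrawn otherwise.

    Raises
    ------
    InfeasibleTargetError
        After ``max_retries`` failed draws (e.g. a strongly negative mean
        that no positive-semidefinite matrix of this size can achieve).
    """
    if n_channels < 2:
        raise ValueError("n_channels must be ≥ 2")
    if abs(target_mean) > 1.0 or target_sd < 0.0:
        raise ValueError("need |target_mean| ≤ 1 and target_sd ≥ 0")
    if abs(target_mean) == 1.0 and target_sd > 0.0:
        raise InfeasibleTargetError("|mean| = 1 requires target_sd = 0")

    n_off = n_channels * (n_channels - 1) // 2

    def accept(m: np.ndarray) -> CorrelationTarget | None:
        t = CorrelationTarget(n_channels, target_mean, target_sd, m)
        rm, rs = t.realized_stats()
        if abs(rm - target_mean) <= mean_tol and abs(rs - target_sd) <= sd_tol:
            return t
        return None

    # Degenerate SD: a constant off-diagonal matrix, PSD iff c ≥ −1/(n−1).
    if target_sd == 0.0:
        const = _build_symmetric(np.full(n_off, target_mean), n_channels)
        try:
            proj = nearest_correlation(const)
        except ProjectionConvergenceError as exc:  # pragma: no cover
            raise InfeasibleTargetError(str(exc)) from exc
        got = accept(proj)
        if got is not None:
            return got
        raise InfeasibleTargetError(
            f"constant off-diagonal {target_mean} admits no correlation matrix "
            f"of size {n_channels} within tolerance"
        )

    lo, hi = -0.99, 0.99
    a = (lo - target_mean) / target_sd
    b = (hi - target_mean) / target_sd
    for _ in range(max_retries):
        off = stats.truncnorm.rvs(
            a, b, loc=target_mean, scale=target_sd, size=n_off, random_state=rng
        )
        m = nearest_correlation(_build_symmetric(off, n_channels))
        got = accept(m)
        for _refine in range(5):
            if got is not None:
                return got
            iu = np.triu_indices(n_channels, k=1)
            cur = m[iu]
            cm = cur.mean()
            cs = cur.std(ddof=1) if cur.size > 1 else 0.0
            scale = 1.0 if cs == 0.0 else target_sd / cs
            cur = np.clip((cur - cm) * scale + target_mean, lo, hi)
            m = nearest_correlation(_build_symmetric(cur, n_channels))
            got = accept(m)
        if got is not None:
            return got
    raise InfeasibleTargetError(
        f"could not realise off-diagonal mean {target_mean} ± {mean_tol} and "
        f"SD {target_sd} ± {sd_tol} on a {n_channels}×{n_channels} correlation "
        f"matrix after {max_retries} draws"
    )


def _matrix_sqrt_psd(matrix: np.ndarray) -> np.ndarray:
    """Symmetric square root with eigenvalues floored at 0 (projection can
    leave tiny negative eigenvalues)."""
    w, v = np.linalg.eigh(matrix)
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _spike_kernel(sampling_rate: float, duration: float) -> np.ndarray:
    """Biexponential transient with unit peak amplitude."""
    tau_r = duration / 7.0
    tau_d = duration / 2.5
    t = np.arange(0, int(round(3 * duration * sampling_rate))) / sampling_rate
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = np.abs(k).max()
    return k / peak if peak > 0 else k


def simulate_recording(
    target: CorrelationTarget,
    sampling_rate: float,
    duration: float,
    artifacts: ArtifactSpec,
    region_labels: Sequence[str] | Sequence[ChannelInfo],
    rng: np.random.Generator,
    seizure_onsets: Sequence[int] = (),
    patient_id: str | None = None,
    outcome: bool | None = None,
) -> Recording:
    """Simulate a band-limited multichannel recording with target correlations.

    Independent white Gaussian channels are coloured with the symmetric matrix
    square root of ``target.matrix`` and band-limited to 5–50 Hz; because the
    same linear filter acts on every channel, the pairwise correlations of the
    clean part equal the target (up to estimation error).  Artifacts — common
    60 Hz line noise, per-channel slow drift, and Poisson spike transients on
    random channel subsets — are added afterwards, scaled by each channel's
    clean-signal SD.

    Raises
    ------
    ValueError
        If ``sampling_rate`` ≤ 120 Hz (the 60 Hz stop frequency would not be
        representable) or ``duration`` < 2 s.
    """
    if sampling_rate <= 120.0:
        raise ValueError("sampling_rate must exceed 120 Hz (60 Hz stop frequency)")
    if duration < 2.0:
        raise ValueError("duration must be at least 2 s to resolve the 5 Hz edge")
    channels = [
        c if isinstance(c, ChannelInfo) else ChannelInfo(f"c{i:02d}-{c}", c)
        for i, c in enumerate(region_labels)
    ]
    if len(channels) != target.n_channels:
        raise ValueError("one region label per target channel required")

    n = int(round(sampling_rate * duration))
    root = _matrix_sqrt_psd(target.matrix)
    clean = root @ rng.standard_normal((target.n_channels, n))
    clean = bandpass_filter(clean, sampling_rate, FilterSpec())
    sd = clean.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0

    x = clean.copy()
    t = np.arange(n) / sampling_rate
    if artifacts.line_noise_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        line = np.sin(2 * np.pi * 60.0 * t + phase)
        x += artifacts.line_noise_amplitude * sd * line[None, :]
    if artifacts.drift_amplitude > 0:
        # drift content is < 0.5 Hz, so synthesise it on a coarse 8 Hz grid
        # and linearly interpolate to the full sampling rate
        tc = np.arange(0.0, duration + 0.25, 0.125)
        drift_c = np.zeros((len(channels), tc.size))
        for _ in range(3):
            f = rng.uniform(0.01, 0.4, size=len(channels))
            ph = rng.uniform(0, 2 * np.pi, size=len(channels))
            drift_c += np.sin(2 * np.pi * f[:, None] * tc[None, :] + ph[:, None])
        drift = np.empty((len(channels), n))
        for i in range(len(channels)):
            drift[i] = np.interp(t, tc, drift_c[i])
        drift /= np.maximum(drift.std(axis=1, keepdims=True), 1e-12)
        x += artifacts.drift_amplitude * sd * drift
    if artifacts.spike_rate > 0 and artifacts.spike_amplitude > 0:
        kernel = _spike_kernel(sampling_rate, artifacts.spike_duration)
        n_events = rng.poisson(artifacts.spike_rate * duration)
        for _ in range(n_events):
            start = int(rng.integers(0, max(n - kernel.size, 1)))
            hit = rng.random(len(channels)) < 0.5
            if not hit.any():
                hit[int(rng.integers(len(channels)))] = True
            sign = rng.choice([-1.0, 1.0])
            stop = min(start + kernel.size, n)
            seg = kernel[: stop - start]
            x[hit, start:stop] += (
                sign * artifacts.spike_amplitude * sd[hit] * seg[None, :]
            )

    return Recording(
        samples=x,
        sampling_rate=sampling_rate,
        channels=channels,
        seizure_onsets=list(seizure_onsets),
        patient_id=patient_id,
        outcome=outcome,
    )


def iter_cohort(
    spec: CohortSpec,
) -> Iterator[tuple[Recording, bool, tuple[float, float]]]:
    """Yield ``(recording, outcome, realized_target_stats)`` per patient.

    Patients are generated lazily (one recording held in memory at a time);
    :func:`simulate_cohort` materialises the list.  Reproducible: an identical
    spec (including seed) yields a bit-identical cohort.
    """
    n_total = spec.n_positive + spec.n_negative
    children = np.random.SeedSequence(spec.seed).spawn(n_total)
    # eligible span leaves 20% slack so segment selection can spread windows
    eligible = spec.n_segments * spec.segment_duration * 1.2
    total_duration = eligible + spec.preictal_exclusion_s + 1.0
    onset = int(round((eligible + spec.preictal_exclusion_s) * spec.sampling_rate))

    for k in range(n_total):
        positive = k < spec.n_positive
        pid = f"P{k + 1:02d}" if positive else f"N{k - spec.n_positive + 1:02d}"
        rng = np.random.default_rng(children[k])
        mean_rng = spec.pos_mean_range if positive else spec.neg_mean_range
        sd_rng = spec.pos_sd_range if positive else spec.neg_sd_range
        t_mean = rng.uniform(*mean_rng)
        t_sd = rng.uniform(*sd_rng)
        n_regions = int(rng.integers(spec.regions_per_patient[0], spec.regions_per_patient[1] + 1))
        regions = [REGIONS[i] for i in sorted(rng.choice(len(REGIONS), n_regions, replace=False))]
        channels = [ChannelInfo(f"{pid}-{r}1", r) for r in regions]
        target = sample_target_correlation(n_regions, t_mean, t_sd, rng)
        rec = simulate_recording(
            target,
            spec.sampling_rate,
            total_duration,
            spec.artifacts,
            channels,
            rng,
            seizure_onsets=[onset],
            patient_id=pid,
            outcome=positive,
        )
        yield rec, positive, target.realized_stats()


def simulate_cohort(
    spec: CohortSpec,
) -> list[tuple[Recording, bool, tuple[float, float]]]:
    """Generate the full cohort as a list (see :func:`iter_cohort`)."""
    return list(iter_cohort(spec))
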