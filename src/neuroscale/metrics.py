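"""Summary statistics: CTF, sensor correlation distance, resolvable scale.

The contrast transfer function of a sensor is the RMS of its response over
the Monte Carlo ensemble divided by the RMS of the cortical activation;
with row-normalized gains and z-scored patterns it is 1 when the forward
model does not attenuate cortical contrast.  The correlation distance of a
sensor is the maximum 3D distance to another sensor whose pseudo-timecourse
correlates above a threshold (default r > 0.5), falling back to the
montage's minimum separation when none qualifies.  The resolvable spatial
pattern scale is read off a smoothing-spline fit of mean correlation
distance versus log10 scale area: the smallest scale where the fitted
curve exceeds its minimum by one sensor-wise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .forward import ForwardModel
from .montage import SensorMontage
from .patterns import ActivationEnsemble

__all__ = [
    "SensorStats",
    "ScaleCurve",
    "propagate",
    "compute_ctf",
    "correlation_distance",
    "smoothing_spline",
    "resolvable_scale",
]


@dataclass
class SensorStats:
    """Per-sensor and sensor-mean statistics at one spatial scale."""

    modality: str
    scale_area: float  # cm^2
    ctf_per_sensor: np.ndarray
    ctf_mean: float
    corr_distance_per_sensor: np.ndarray  # cm
    corr_distance_mean: float
    corr_distance_sd: float
    rms_x: float
    n_instances: int
    correlation_matrix: np.ndarray | None = None
    degenerate_channels: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))


@dataclass
class ScaleCurve:
    """Correlation distance across scales with spline fit and resolvable scale."""

    modality: str
    scale_areas: np.ndarray  # cm^2, ascending
    mean_distances: np.ndarray  # cm
    sd_distances: np.ndarray  # cm
    fitted_distances: np.ndarray  # spline at the input scales
    resolvable_scale: float  # cm^2, nan when undefined
    defined: bool
    threshold: float  # cm, fitted minimum + SD
    spline: object | None = None


def propagate(model: ForwardModel, ensemble: ActivationEnsemble | np.ndarray) -> np.ndarray:
    """Sensor pseudo-timecourses y = A x, per Monte Carlo instance (noise-free)."""
    x = ensemble.values if isinstance(ensemble, ActivationEnsemble) else ensemble
    if not model.normalized:
        raise ValueError("forward model must be row-normalized before propagation")
    if model.n_sources != x.shape[0]:
        raise ValueError(
            f"dimension mismatch: gains {model.gains.shape} vs patterns {x.shape}"
        )
    y = model.gains @ x
    return np.asarray(y)


def compute_ctf(
    pseudo_timecourse: np.ndarray, ensemble: ActivationEnsemble, cortical_mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sensor CTF = RMS_y / RMS_x and its sensor mean."""
    if pseudo_timecourse.shape[1] < 2:
        raise ValueError("need at least 2 Monte Carlo instances")
    rms_y = np.sqrt(np.mean(pseudo_timecourse**2, axis=1))
    rms_x = ensemble.rms(cortical_mask)
    ctf = rms_y / rms_x
    return ctf, float(ctf.mean())


def correlation_distance(
    pseudo_timecourse: np.ndarray,
    montage: SensorMontage,
    r_threshold: float = 0.5,
    r_mode: str = "absolute",
    return_matrix: bool = False,
    block: int = 2048,
) -> dict:
    """Maximum distance to a correlated sensor, per seed sensor.

    Pearson correlation of every sensor pair across instances; a sensor's
    correlation distance is the largest 3D distance to any *other* sensor
    whose correlation exceeds ``r_threshold``, or the montage minimum
    separation when none qualifies.  ``r_mode`` picks the connectivity
    convention: ``"absolute"`` thresholds |r| (anticorrelated sensors --
    e.g. the two lobes of a dipolar EEG topography -- count as connected,
    the usual sensor-space functional-connectivity reading), ``"signed"``
    thresholds r itself.  Constant (zero-variance) channels are treated as
    uncorrelated with everything and reported.
    """
    Y = pseudo_timecourse
    N, K = Y.shape
    if K < 3:
        raise ValueError("need at least 3 instances for correlations")
    pos = montage.positions
    if pos.shape[0] != N:
        raise ValueError("montage size does not match timecourse rows")
    Z = Y - Y.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1)
    degenerate = np.nonzero(sd == 0)[0]
    safe = np.where(sd == 0, 1.0, sd)
    Z = Z / (safe[:, None] * np.sqrt(K))
    Z[degenerate] = 0.0

    min_sep = montage.min_separation
    dist_out = np.full(N, min_sep)
    corr_full = np.empty((N, N)) if return_matrix else None
    for start in range(0, N, block):
        sl = slice(start, min(start + block, N))
        r = Z[sl] @ Z.T  # (b, N)
        if return_matrix:
            corr_full[sl] = r
        if r_mode == "absolute":
            hit = np.abs(r) > r_threshold
        elif r_mode == "signed":
            hit = r > r_threshold
        else:
            raise ValueError(f"unknown r_mode {r_mode!r}")
        hit[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] = False
        d = np.linalg.norm(pos[sl][:, None, :] - pos[None, :, :], axis=-1)
        d[~hit] = -1.0
        dmax = d.max(axis=1)
        dist_out[sl] = np.where(dmax > 0, dmax, min_sep)
    if return_matrix:
        np.fill_diagonal(corr_full, 1.0)
    return {
        "per_sensor": dist_out,
        "mean": float(dist_out.mean()),
        "sd": float(dist_out.std()),
        "degenerate_channels": degenerate,
        "correlation_matrix": corr_full,
        "min_separation": min_sep,
    }


def smoothing_spline(x: np.ndarray, y: np.ndarray, p: float = 0.95) -> CubicSpline:
    """Cubic smoothing spline minimizing p*sum (y-f)^2 + (1-p)*int f''^2.

    The MATLAB ``csaps`` convention for the smoothing parameter p in (0, 1].
    Solved by the Reinsch/Green-Silverman linear system at the knots; the
    result is the natural cubic spline through the smoothed knot values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite inputs to smoothing_spline")
    if p >= 1.0:
        return CubicSpline(x, y, bc_type="natural")
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = h[j] / 6.0
            R[j, j - 1] = h[j] / 6.0
    alpha = (1.0 - p) / p
    K = Q @ np.linalg.solve(R, Q.T)
    f = np.linalg.solve(np.eye(n) + alpha * K, y)
    return CubicSpline(x, f, bc_type="natural")


def resolvable_scale(
    scale_areas: np.ndarray,
    mean_distances: np.ndarray,
    sd_distances: np.ndarray,
    modality: str = "",
    p: float = 0.95,
    sd_rule: str = "at_minimum",
    grid: int = 4001,
) -> ScaleCurve:
    """Smallest scale where the fitted correlation-distance curve exceeds
    its minimum by one sensor-wise standard deviation.

    The spline is fitted against log10(scale area).  ``sd_rule`` picks the
    standard deviation entering the threshold: ``at_minimum`` (SD at the
    input scale nearest the fitted minimum) or ``pooled`` (mean SD over
    scales).
    """
    areas = np.asarray(scale_areas, dtype=float)
    means = np.asarray(mean_distances, dtype=float)
    sds = np.asarray(sd_distances, dtype=float)
    if len(areas) < 5:
        raise ValueError("need at least 5 scales")
    if not (np.all(np.isfinite(areas)) and np.all(np.isfinite(means)) and np.all(np.isfinite(sds))):
        raise ValueError("non-finite inputs")
    order = np.argsort(areas)
    areas, means, sds = areas[order], means[order], sds[order]
    lx = np.log10(areas)
    spline = smoothing_spline(lx, means, p=p)
    xs = np.linspace(lx[0], lx[-1], grid)
    fs = spline(xs)
    imin = int(np.argmin(fs))
    xmin, fmin = xs[imin], fs[imin]
    if sd_rule == "at_minimum":
        sd_thr = sds[int(np.argmin(np.abs(lx - xmin)))]
    elif sd_rule == "pooled":
        sd_thr = float(sds.mean())
    else:
        raise ValueError(f"unknown sd_rule {sd_rule!r}")
    threshold = fmin + sd_thr
    g = lambda t: spline(t) - threshold  # noqa: E731
    crossing = np.nan
    above = fs[imin:] > threshold
    if above.any():
        j = imin + int(np.argmax(above))
        if j == imin or g(xs[j - 1]) >= 0:
            crossing = xs[j - 1] if j > imin else xmin
        else:
            crossing = brentq(g, xs[j - 1], xs[j], xtol=1e-10)
    defined = np.isfinite(crossing)
    return ScaleCurve(
        modality=modality,
        scale_areas=areas,
        mean_distances=means,
        sd_distances=sds,
        fitted_distances=spline(lx),
        resolvable_scale=float(10**crossing) if defined else float("nan"),
        defined=bool(defined),
        threshold=float(threshold),
        spline=spline,
    )
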