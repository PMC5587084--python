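"""FRAP and FLIP analysis: curve extraction, normalization and fitting.

FRAP (fluorescence recovery after photobleaching) quantifies protein
mobility: a region of the ER is bleached and the return of fluorescence
is recorded.  The full-scale-normalized recovery ``F(t)`` is fitted with
a double exponential sharing one plateau,

    F(t) = M · (1 − a·e^(−k1·t) − (1 − a)·e^(−k2·t)),   k1 ≥ k2,

whose plateau ``M`` is the mobile fraction, whose half-recovery time
``t½`` solves ``F(t) = M/2``, and which maps to an apparent diffusion
coefficient ``D = (r_n² + r_e²)/(8·t½)`` for the bleach ROI's nominal
and effective (equal-area-circle) radii.

FLIP (fluorescence loss in photobleaching) repeatedly bleaches one spot
and reports the loss of fluorescence in a surrounding "donut" ring and
in a distant region: simultaneous loss demonstrates luminal continuity,
a stable distant region reveals a disconnected compartment.

The fitting interface follows the model/results convention: build a
:class:`FrapModel` from a :class:`RecoveryCurve` (or directly from a
movie), call :meth:`~FrapModel.fit`, and read estimates, uncertainties
and the summary table off the returned :class:`FrapResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize

from .core import FitFailure, Movie, Roi

__all__ = [
    "RoiGeometry",
    "RecoveryCurve",
    "FrapModel",
    "FrapResults",
    "FlipResult",
    "extract_timeseries",
    "normalize_full_scale",
    "fit_double_exponential",
    "apparent_diffusion",
    "neighbor_correct",
    "flip_metrics",
]


@dataclass(frozen=True)
class RoiGeometry:
    """Bleach-ROI geometry used for the t½ → D conversion.

    ``effective_radius_um`` is the radius of the circle of equal area,
    ``r_e = sqrt(area/π)``; ``nominal_radius_um`` defaults to ``r_e``
    (rectangular ROIs are mapped to their equal-area circle).
    """

    shape: str
    dims_um: tuple[float, ...]
    nominal_radius_um: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "circle"):
            raise ValueError("shape must be rectangle|circle")
        if any(d <= 0 for d in self.dims_um):
            raise ValueError("dimensions must be > 0")

    @property
    def area_um2(self) -> float:
        if self.shape == "circle":
            return float(np.pi * self.dims_um[0] ** 2)
        return float(self.dims_um[0] * self.dims_um[1])

    @property
    def effective_radius_um(self) -> float:
        return float(np.sqrt(self.area_um2 / np.pi))

    @property
    def radius_nominal_um(self) -> float:
        return (self.nominal_radius_um if self.nominal_radius_um is not None
                else self.effective_radius_um)

    @classmethod
    def rectangle(cls, width_um: float, height_um: float) -> "RoiGeometry":
        return cls("rectangle", (width_um, height_um))

    @classmethod
    def circle(cls, radius_um: float) -> "RoiGeometry":
        return cls("circle", (radius_um,), nominal_radius_um=radius_um)

    @classmethod
    def from_roi(cls, roi: Roi) -> "RoiGeometry":
        if roi.shape == "circle":
            return cls.circle(roi.dims_um[0])
        return cls.rectangle(*roi.dims_um)


@dataclass
class RecoveryCurve:
    """Full-scale-normalized FRAP curve.

    Pre-bleach frames have mean 1, the first post-bleach frame is 0.
    ``times_s`` are the acquisition times (strictly increasing).
    """

    times_s: np.ndarray
    values: np.ndarray
    pre_bleach_count: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (1 <= self.pre_bleach_count < len(self.times_s)):
            raise ValueError("pre_bleach_count must leave post-bleach frames")

    @property
    def post_times_s(self) -> np.ndarray:
        """Times since bleach end (first post-bleach frame at t = 0)."""
        t0 = self.times_s[self.pre_bleach_count]
        return self.times_s[self.pre_bleach_count:] - t0

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.pre_bleach_count:]


# ---------------------------------------------------------------------------
# extraction and normalization
# ---------------------------------------------------------------------------

def extract_timeseries(movie: Movie, rois: Mapping[str, Roi],
                       channel: str | None = None) -> dict[str, np.ndarray]:
    """Per-frame mean intensity for each named ROI."""
    if movie.n_frames == 0:
        raise ValueError("movie has no frames")
    stack = movie.channel(channel) if channel else movie.data[:, 0]
    H, W = stack.shape[1:]
    w_um, h_um = W * movie.pixel_size_um, H * movie.pixel_size_um
    out = {}
    for name, roi in rois.items():
        x0, y0, x1, y1 = roi.bounds_um()
        if x0 < 0 or y0 < 0 or x1 > w_um or y1 > h_um:
            raise ValueError(f"ROI '{name}' lies outside the frame")
        mask = roi.mask(H, W, movie.pixel_size_um)
        if not mask.any():
            raise ValueError(f"ROI '{name}' covers no pixels")
        out[name] = stack[:, mask].mean(axis=1)
    return out


def normalize_full_scale(raw_target: np.ndarray, raw_reference: np.ndarray,
                         raw_background: np.ndarray, pre_bleach_count: int,
                         times_s: np.ndarray | None = None) -> RecoveryCurve:
    """Background/acquisition-corrected, full-scale-normalized recovery.

    Corrected ``C(t) = (target − background)/(reference − background)``;
    full scale ``F(t) = (C(t) − C(t₀⁺))/(mean pre-bleach C − C(t₀⁺))``
    with ``t₀⁺`` the first post-bleach frame, so pre-bleach maps to 1 and
    the first post-bleach frame to 0.
    """
    raw_target = np.asarray(raw_target, dtype=float)
    raw_reference = np.asarray(raw_reference, dtype=float)
    raw_background = np.asarray(raw_background, dtype=float)
    if pre_bleach_count < 1:
        raise ValueError("need at least one pre-bleach frame")
    denom = raw_reference - raw_background
    if np.any(denom <= 0):
        raise ValueError("reference must stay strictly above background")
    corrected = (raw_target - raw_background) / denom
    c_post0 = corrected[pre_bleach_count]
    c_pre = corrected[:pre_bleach_count].mean()
    gap = c_pre - c_post0
    if gap == 0:
        raise ValueError("no pre/post-bleach gap: nothing was bleached")
    values = (corrected - c_post0) / gap
    if times_s is None:
        times_s = np.arange(len(values), dtype=float)
    return RecoveryCurve(times_s, values, pre_bleach_count)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

def _model(t, M, a, k1, k2):
    return M * (1.0 - a * np.exp(-k1 * t) - (1.0 - a) * np.exp(-k2 * t))


class FrapModel:
    """Double-exponential recovery model for one full-scale FRAP curve.

    The shared-plateau convex-weight parameterization (``M``, ``a``,
    ``k1``, ``k2``) keeps the fitted plateau inside [0, 1.05] and avoids
    the degenerate two-amplitude regime; the fit runs over the
    post-bleach samples only, from a multi-start grid.
    """

    MIN_POST_SAMPLES = 8

    def __init__(self, curve: RecoveryCurve):
        self.curve = curve
        if len(curve.post_values) < self.MIN_POST_SAMPLES:
            raise ValueError(
                f"need at least {self.MIN_POST_SAMPLES} post-bleach samples")

    @classmethod
    def from_movie(cls, movie: Movie, target: Roi, reference: Roi,
                   background: Roi | None = None,
                   pre_bleach_count: int = 3) -> "FrapModel":
        rois = {"target": target, "reference": reference}
        if background is not None:
            rois["background"] = background
        curves = extract_timeseries(movie, rois)
        bg = curves.get("background", np.zeros(movie.n_frames))
        curve = normalize_full_scale(curves["target"], curves["reference"],
                                     bg, pre_bleach_count,
                                     times_s=movie.times_s)
        return cls(curve)

    def fit(self) -> "FrapResults":
        t = self.curve.post_times_s
        y = self.curve.post_values
        if np.max(np.abs(y)) < 1e-3:
            # fully immobile: nothing recovered
            return FrapResults(self, np.array([0.0, 1.0, 1.0, 0.01]),
                               np.full(4, np.nan), rss=float(np.sum(y ** 2)))

        plateau0 = float(np.clip(np.mean(y[int(0.8 * len(y)):]), 0.05, 1.05))
        half_idx = np.nonzero(y >= plateau0 / 2.0)[0]
        t_half0 = t[half_idx[0]] if half_idx.size and t[half_idx[0]] > 0 \
            else max(t[-1] / 10.0, 1e-3)
        kg = np.log(2.0) / t_half0
        lower = [0.0, 0.0, 1e-6, 1e-6]
        upper = [1.05, 1.0, 1e3, 1e3]
        starts = []
        for a0 in (1.0, 0.7, 0.4):
            for spread in (1.0, 5.0, 25.0):
                starts.append([plateau0, a0, kg * np.sqrt(spread),
                               kg / np.sqrt(spread)])
        best = None
        for x0 in starts:
            x0 = np.clip(x0, lower, upper)
            try:
                res = optimize.least_squares(
                    lambda p: _model(t, *p) - y, x0,
                    bounds=(lower, upper), method="trf", max_nfev=2000)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitFailure("double-exponential fit failed from every start")
        M, a, k1, k2 = best.x
        if k1 < k2:  # relabel so k1 is the fast rate
            k1, k2 = k2, k1
            a = 1.0 - a
        params = np.array([M, a, k1, k2])
        bse = _bse_from_lsq(best, len(y))
        return FrapResults(self, params, bse, rss=float(2 * best.cost))


def _bse_from_lsq(res, n_obs: int) -> np.ndarray:
    """Standard errors from the least-squares Jacobian (Gauss-Newton)."""
    try:
        J = res.jac
        dof = max(n_obs - J.shape[1], 1)
        s2 = 2 * res.cost / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        return np.full(4, np.nan)


@dataclass
class FrapResults:
    """Fitted FRAP parameters with uncertainties and derived quantities."""

    model: FrapModel
    params: np.ndarray  # (M, a, k1, k2)
    bse: np.ndarray
    rss: float
    param_names: tuple[str, ...] = ("mobile_fraction", "amplitude_a",
                                    "rate_k1", "rate_k2")

    @property
    def mobile_fraction(self) -> float:
        return float(self.params[0])

    @property
    def amplitude_a(self) -> float:
        return float(self.params[1])

    @property
    def rate_k1(self) -> float:
        return float(self.params[2])

    @property
    def rate_k2(self) -> float:
        return float(self.params[3])

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _model(np.asarray(t, dtype=float), *self.params)

    @property
    def t_half_s(self) -> float | None:
        """Time at which the fitted curve reaches half its plateau
        (numeric root of ``F(t) = M/2``; None for an immobile curve)."""
        M = self.mobile_fraction
        if M <= 1e-3:
            return None
        hi = self.model.curve.post_times_s[-1] if \
            self.model.curve.post_times_s[-1] > 0 else 1.0
        f = lambda t: self.predict(t) - M / 2.0
        while f(hi) < 0:
            hi *= 2.0
            if hi > 1e12:
                return None
        return float(optimize.brentq(f, 0.0, hi))

    def diffusion(self, roi: RoiGeometry) -> float:
        t_half = self.t_half_s
        if t_half is None:
            return 0.0
        return apparent_diffusion(t_half, roi)

    def summary(self) -> str:
        lines = ["FRAP double-exponential fit",
                 "=" * 46,
                 f"{'parameter':<18}{'estimate':>12}{'std err':>12}"]
        for name, p, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<18}{p:>12.4f}{se:>12.4f}")
        t_half = self.t_half_s
        lines.append("-" * 46)
        lines.append(f"{'t_half_s':<18}"
                     f"{t_half if t_half is not None else float('nan'):>12.4f}")
        lines.append(f"{'rss':<18}{self.rss:>12.6f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.times_s, c.values, "o", ms=3, label="normalized data")
        t0 = c.times_s[c.pre_bleach_count]
        tt = np.linspace(0, c.post_times_s[-1], 200)
        ax.plot(tt + t0, self.predict(tt), "-", label="double-exp fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("full-scale normalized intensity")
        ax.legend()
        return ax


def fit_double_exponential(curve: RecoveryCurve) -> FrapResults:
    """Fit the double-exponential recovery model to one curve."""
    return FrapModel(curve).fit()


def apparent_diffusion(t_half_s: float, roi: RoiGeometry) -> float:
    """Apparent diffusion coefficient from the half-recovery time.

    Simplified confocal large-ROI relation ``D = (r_n² + r_e²)/(8·t½)``
    with the nominal and effective (equal-area circle) ROI radii.
    """
    if t_half_s <= 0:
        raise ValueError("t_half must be > 0")
    rn = roi.radius_nominal_um
    re = roi.effective_radius_um
    return (rn ** 2 + re ** 2) / (8.0 * t_half_s)


# ---------------------------------------------------------------------------
# FLIP
# ---------------------------------------------------------------------------

@dataclass
class FlipResult:
    """Fluorescence-loss metrics for the donut and distant regions."""

    t50_donut_s: float | None
    t50_distant_s: float | None
    final_loss_donut: float
    final_loss_distant: float
    stable_distant: bool


def neighbor_correct(curve: np.ndarray, neighbor: np.ndarray,
                     pre_bleach_count: int) -> np.ndarray:
    """Divide by an unbleached neighbor-cell curve (acquisition-bleaching
    correction) and renormalize the pre-bleach mean to 1."""
    curve = np.asarray(curve, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if np.any(neighbor <= 0):
        raise ValueError("neighbor curve must be strictly positive")
    corrected = curve / neighbor
    pre = corrected[:pre_bleach_count].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach mean")
    return corrected / pre


def _t50(times: np.ndarray, loss: np.ndarray) -> float | None:
    """First crossing of loss = 0.5, by linear interpolation."""
    above = np.nonzero(loss >= 0.5)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    l0, l1 = loss[i - 1], loss[i]
    return float(t0 + (0.5 - l0) / (l1 - l0) * (t1 - t0))


def flip_metrics(curves: Mapping[str, np.ndarray], times_s: np.ndarray,
                 pre_bleach_count: int = 2,
                 stable_threshold: float = 0.1) -> FlipResult:
    """Loss metrics from normalized FLIP curves.

    ``curves`` must contain ``donut`` and ``distant`` series (a ``spot``
    series may be present), each background/neighbor corrected and
    normalized so the pre-bleach mean is 1 (checked to 5%).  The loss is
    ``1 − F(t)``; ``t50`` is the first crossing of 0.5; the distant
    region is flagged stable when its final loss stays below
    ``stable_threshold``.
    """
    times_s = np.asarray(times_s, dtype=float)
    for name in ("donut", "distant"):
        if name not in curves:
            raise ValueError(f"missing '{name}' curve")
        pre = np.mean(np.asarray(curves[name][:pre_bleach_count], dtype=float))
        if abs(pre - 1.0) > 0.05:
            raise ValueError(
                f"'{name}' curve is not normalized (pre-bleach mean {pre:.3f})")
    post = slice(pre_bleach_count, None)
    loss_donut = 1.0 - np.asarray(curves["donut"], dtype=float)
    loss_distant = 1.0 - np.asarray(curves["distant"], dtype=float)
    t_post = times_s[post]
    result = FlipResult(
        t50_donut_s=_t50(t_post, loss_donut[post]),
        t50_distant_s=_t50(t_post, loss_distant[post]),
        final_loss_donut=float(loss_donut[-1]),
        final_loss_distant=float(loss_distant[-1]),
        stable_distant=bool(loss_distant[-1] < stable_threshold),
    )
    return result
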