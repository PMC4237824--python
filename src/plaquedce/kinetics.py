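"""Pixel-wise kinetic analysis of dynamic contrast-enhanced vessel-wall series.

The processing chain mirrors the standard vasa-vasorum (V-V) imaging
pipeline for bright-blood carotid DCE:

1. rigid, translation-only registration of the dynamic frames against a
   Kalman-tracked running reference (normalized cross-correlation);
2. per-pixel temporal smoothing with a fixed-interval Kalman smoother under
   a random-walk signal model;
3. inversion of the spoiled-gradient-echo signal equation to contrast
   concentration, using the pre-injection frames as the T10 baseline;
4. arterial input function (AIF) extraction from the brightest lumen pixels;
5. per-pixel Patlak estimation
       C_t(t) = Ktrans * int_0^t Cp dtau + vp * Cp(t)
   by ordinary least squares, giving the transfer constant Ktrans (min^-1)
   and fractional plasma volume vp;
6. plaque-mean measurement over the vessel wall with pixels within 1 mm of
   the lumen contour excluded (bright-lumen contamination guard).

Raw least-squares estimates are kept unclamped for averaging and statistics;
clamping to display ranges happens only when rendering V-V images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from .core import AcquisitionProtocol, AIFCurve, ScanRecord

__all__ = [
    "DCESeries",
    "ConcentrationSeries",
    "KineticMap",
    "PlaqueMeasurement",
    "ComplianceReport",
    "spgr_signal",
    "register_series",
    "kalman_smooth",
    "estimate_noise_variance",
    "smooth_series_auto",
    "signal_to_concentration",
    "extract_aif",
    "patlak_fit",
    "render_vv_image",
    "polygon_mask",
    "wall_mask_with_exclusion",
    "max_wall_thickness",
    "measure_plaque",
    "check_protocol",
    "subject_protocol_compliance",
    "apply_inclusion",
]


# --------------------------------------------------------------------------
# containers

@dataclass
class DCESeries:
    """4D dynamic signal array (slices x rows x cols x frames) with metadata."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (slices, rows, cols, frames)")
        if self.frame_times is None:
            self.frame_times = self.protocol.frame_times
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.shape[-1] != self.protocol.n_frames:
            raise ValueError("frame count does not match protocol")
        if self.frame_times.size != self.data.shape[-1]:
            raise ValueError("frame_times length does not match data")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ConcentrationSeries:
    """Per-pixel contrast concentration (mmol/L), same layout as the signal series."""

    conc: np.ndarray
    baseline_frames: np.ndarray
    frame_times: np.ndarray
    protocol: AcquisitionProtocol
    valid_mask: np.ndarray | None = None  # (slices, rows, cols); True = invertible

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.conc.shape[:-1], dtype=bool)


@dataclass
class KineticMap:
    """Per-pixel Patlak estimates: Ktrans in min^-1, vp unitless (raw, unclamped)."""

    ktrans: np.ndarray
    vp: np.ndarray
    fit_residual: np.ndarray
    valid_mask: np.ndarray


@dataclass
class PlaqueMeasurement:
    """Plaque-mean kinetic measurement of one scan.

    ``missing`` is set when the analysis mask was empty; the means are then
    NaN rather than zero so that downstream statistics treat the scan as
    absent, not as a zero-enhancement plaque.
    """

    subject_id: str | None
    scan_index: int | None
    mean_ktrans: float
    mean_vp: float
    analyzed_area: float
    max_wall_thickness: float = float("nan")
    missing: bool = False


# --------------------------------------------------------------------------
# SPGR physics

def spgr_signal(conc: np.ndarray, t10_ms, m0, r1: float,
                tr_ms: float, flip_deg: float) -> np.ndarray:
    """Steady-state spoiled gradient echo signal for a given contrast concentration.

    S = M0 * sin(a) * (1 - E) / (1 - cos(a) * E),  E = exp(-TR * R1(t)),
    R1(t) = 1/T10 + r1 * C(t)  with rates in s^-1 and r1 in L mmol^-1 s^-1.

    ``t10_ms`` and ``m0`` may be scalars or arrays broadcastable against
    ``conc`` (concentration carries the trailing time axis).
    """
    conc = np.asarray(conc, dtype=float)
    t10 = np.asarray(t10_ms, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if t10.ndim and t10.ndim == conc.ndim - 1:
        t10 = t10[..., None]
    if m0.ndim and m0.ndim == conc.ndim - 1:
        m0 = m0[..., None]
    r10 = 1000.0 / t10  # s^-1
    r1t = r10 + r1 * conc
    e = np.exp(-(tr_ms / 1000.0) * r1t)
    a = math.radians(flip_deg)
    return m0 * math.sin(a) * (1.0 - e) / (1.0 - math.cos(a) * e)


# --------------------------------------------------------------------------
# registration

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    if denom == 0.0:
        return 0.0
    return float((a * b).sum()) / denom


def _register_frame(frame: np.ndarray, ref: np.ndarray, max_shift: int,
                    subpixel: bool) -> tuple[np.ndarray, float, float]:
    """Find the translation of ``frame`` that best matches ``ref`` by NCC."""
    best = (-2.0, 0, 0)
    scores = np.full((2 * max_shift + 1, 2 * max_shift + 1), -2.0)
    for iy, dy in enumerate(range(-max_shift, max_shift + 1)):
        for ix, dx in enumerate(range(-max_shift, max_shift + 1)):
            s = _ncc(np.roll(frame, (dy, dx), axis=(0, 1)), ref)
            scores[iy, ix] = s
            if s > best[0]:
                best = (s, dy, dx)
    _, dy, dx = best
    fy, fx = float(dy), float(dx)
    if subpixel:
        iy, ix = dy + max_shift, dx + max_shift
        if 0 < iy < 2 * max_shift and 0 < ix < 2 * max_shift:
            fy += _parabolic_peak(scores[iy - 1, ix], scores[iy, ix], scores[iy + 1, ix])
            fx += _parabolic_peak(scores[iy, ix - 1], scores[iy, ix], scores[iy, ix + 1])
    if subpixel and (fy != dy or fx != dx):
        out = ndimage.shift(frame, (fy, fx), order=1, mode="nearest")
    else:
        out = np.roll(frame, (dy, dx), axis=(0, 1))
        fy, fx = float(dy), float(dx)
    return out, fy, fx


def _parabolic_peak(lo: float, mid: float, hi: float) -> float:
    denom = lo - 2.0 * mid + hi
    if denom >= 0:
        return 0.0
    return 0.5 * (lo - hi) / denom


def register_series(series: DCESeries, reference_frame: int = 0,
                    max_shift_px: int = 3, subpixel: bool = False,
                    gain_ratio: float = 1.0):
    """Rigidly align every frame to a Kalman-tracked running reference.

    Each slice is registered independently (translation only). The reference
    starts as ``reference_frame`` and is updated after each frame with a
    scalar Kalman gain for a random-walk reference model, so slow contrast
    enhancement is tracked while frame noise is averaged down. All-zero
    frames are skipped and flagged.

    Returns
    -------
    (registered, shifts_mm, skipped)
        ``shifts_mm`` has shape (n_slices, n_frames, 2) in (row, col) mm;
        ``skipped`` lists (slice, frame) pairs left untouched.
    """
    if series.n_frames < 2:
        raise ValueError("need at least two frames to register")
    data = series.data.copy()
    n_slices, _, _, n_frames = data.shape
    px = series.protocol.pixel_size
    shifts = np.zeros((n_slices, n_frames, 2))
    skipped: list[tuple[int, int]] = []
    for s in range(n_slices):
        ref = data[s, :, :, reference_frame].copy()
        # scalar Kalman variance recursion for the running reference
        p, q, r = 1.0, gain_ratio, 1.0
        for t in range(n_frames):
            frame = data[s, :, :, t]
            if not np.any(frame):
                skipped.append((s, t))
                continue
            if t == reference_frame:
                reg, dy, dx = frame, 0.0, 0.0
            else:
                reg, dy, dx = _register_frame(frame, ref, max_shift_px, subpixel)
            data[s, :, :, t] = reg
            shifts[s, t] = (dy * px, dx * px)
            pp = p + q
            k = pp / (pp + r)
            ref = ref + k * (reg - ref)
            p = (1.0 - k) * pp
    out = DCESeries(data=data, protocol=series.protocol, frame_times=series.frame_times)
    return out, shifts, skipped


# --------------------------------------------------------------------------
# temporal smoothing

def _rts_smooth(y: np.ndarray, q, r: float) -> np.ndarray:
    """Fixed-interval RTS smoother for random-walk curves on the last axis.

    ``q`` may be a scalar or an array matching ``y.shape[:-1]`` (per-pixel
    process variance); the variance recursion then runs element-wise.
    """
    n = y.shape[-1]
    q = np.asarray(q, dtype=float)
    shape = y.shape[:-1] if q.ndim else ()
    xf = np.empty_like(y)
    pf = np.empty(shape + (n,)) if q.ndim else np.empty(n)
    pp = np.empty_like(pf)
    xf[..., 0] = y[..., 0]
    pf[..., 0] = r
    pp[..., 0] = r
    for t in range(1, n):
        pp[..., t] = pf[..., t - 1] + q
        k = pp[..., t] / (pp[..., t] + r)
        xf[..., t] = xf[..., t - 1] + k * (y[..., t] - xf[..., t - 1])
        pf[..., t] = (1.0 - k) * pp[..., t]
    xs = np.empty_like(y)
    xs[..., n - 1] = xf[..., n - 1]
    for t in range(n - 2, -1, -1):
        a = pf[..., t] / pp[..., t + 1]
        xs[..., t] = xf[..., t] + a * (xs[..., t + 1] - xf[..., t])
    return xs


def kalman_smooth(series: DCESeries, process_var: float, obs_var: float) -> DCESeries:
    """Fixed-interval Kalman (RTS) smoothing of every pixel time curve.

    State model: random walk x_t = x_{t-1} + w_t, w_t ~ N(0, process_var);
    observation y_t = x_t + v_t, v_t ~ N(0, obs_var). Because the variance
    recursion is pixel-independent, the gains are scalars per time step and
    the smoother is applied to the whole volume at once.
    """
    if process_var <= 0 or obs_var <= 0:
        raise ValueError("process_var and obs_var must be positive")
    xs = _rts_smooth(series.data, float(process_var), float(obs_var))
    return DCESeries(data=xs, protocol=series.protocol, frame_times=series.frame_times)


def estimate_noise_variance(series: DCESeries) -> float:
    """Estimate the observation (noise) variance from the pre-contrast frames.

    Uses half the mean squared difference between consecutive baseline
    frames, which is unbiased for white observation noise on a constant
    pre-contrast signal. Returns 0 for a noise-free series.
    """
    base = series.protocol.baseline_frames
    if base.size < 2:
        return 0.0
    d = np.diff(series.data[..., base], axis=-1)
    return float(np.mean(d * d) / 2.0)


def smooth_series_auto(series: DCESeries, min_obs_var: float = 1e-12) -> DCESeries:
    """Kalman-smooth with variances estimated from the data itself.

    The observation variance comes from the baseline frames
    (:func:`estimate_noise_variance`); the process variance is estimated
    per pixel as the mean squared frame-to-frame increment of that pixel's
    own curve with the noise contribution removed. Pixels with strong true
    dynamics (the lumen bolus) therefore keep their transients, while
    flat curves are smoothed hard. A (near-)noise-free series is returned
    unchanged: with obs_var ~ 0 the smoother is the identity and smoothing
    would only add numerical error.
    """
    r = estimate_noise_variance(series)
    if r <= min_obs_var:
        return series
    d = np.diff(series.data, axis=-1)
    q = np.maximum(np.mean(d * d, axis=-1) - 2.0 * r, 0.25 * r)
    xs = _rts_smooth(series.data, q, r)
    return DCESeries(data=xs, protocol=series.protocol, frame_times=series.frame_times)


# --------------------------------------------------------------------------
# signal -> concentration

def signal_to_concentration(series: DCESeries, t10, r1: float,
                            baseline_frames=None) -> ConcentrationSeries:
    """Invert the SPGR signal equation to contrast concentration per pixel.

    The equilibrium amplitude A = M0*sin(flip) is estimated per pixel from
    the mean of the baseline (pre-injection) frames together with the
    assumed T10; T1(t) then follows in closed form from
    E = (A - S) / (A - cos(flip) * S) and C = (1/T1 - 1/T10) / r1.

    Pixels whose signal leaves the invertible branch of the SPGR curve
    (E outside (0, 1), e.g. S >= A) are flagged invalid instead of being
    extrapolated.
    """
    proto = series.protocol
    if baseline_frames is None:
        baseline_frames = proto.baseline_frames
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise ValueError("need at least one baseline frame")
    t10 = np.asarray(t10, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("t10 must be positive")
    t10 = np.broadcast_to(t10, np.broadcast_shapes(t10.shape,
                                                   series.data.shape[:-1]))

    a = math.radians(proto.flip_angle)
    c = math.cos(a)
    tr_s = proto.tr / 1000.0
    r10 = 1000.0 / t10  # s^-1
    e0 = np.exp(-tr_s * r10)

    s = series.data
    s_base = s[..., baseline_frames].mean(axis=-1)
    # A = M0*sin(flip), inferred from the baseline signal level and T10
    amp = s_base * (1.0 - c * e0) / (1.0 - e0)
    amp_b = amp[..., None] if amp.ndim == s.ndim - 1 else amp

    num = amp_b - s
    den = amp_b - c * s
    with np.errstate(divide="ignore", invalid="ignore"):
        e = num / den
        valid_t = (e > 0.0) & (e < 1.0) & np.isfinite(e)
        r1t = np.where(valid_t, -np.log(np.where(valid_t, e, 0.5)) / tr_s, np.nan)
        r10_b = r10[..., None] if (r10.ndim and r10.ndim == s.ndim - 1) else r10
        conc = (r1t - r10_b) / r1
    valid = np.all(valid_t, axis=-1) & np.all(np.isfinite(conc), axis=-1)
    conc = np.where(valid[..., None], conc, 0.0)
    return ConcentrationSeries(conc=conc, baseline_frames=baseline_frames,
                               frame_times=series.frame_times, protocol=proto,
                               valid_mask=valid)


# --------------------------------------------------------------------------
# AIF extraction

def extract_aif(conc: ConcentrationSeries, lumen_contour: np.ndarray,
                hematocrit: float = 0.42, slice_index: int = 0,
                pixel_size: float | None = None) -> AIFCurve:
    """Extract the arterial input function from the lumen of one slice.

    Blood concentration per frame is the mean over the top quartile of lumen
    pixels ranked by total post-injection enhancement (the brightest,
    least partial-volumed blood); plasma concentration is
    C_p = C_blood / (1 - hematocrit). The curve is clipped at zero, so it is
    exactly zero on baseline frames of a noise-free series.

    The quartile is re-selected per frame with that frame left out of the
    ranking sum: a pixel's own noise at frame t then never influences
    whether it is averaged at frame t, which removes the upward selection
    bias that ranking and averaging the same noisy values would create.
    """
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError("hematocrit must be in [0, 1)")
    px = pixel_size if pixel_size is not None else conc.protocol.pixel_size
    shape = conc.conc.shape[1:3]
    mask = polygon_mask(lumen_contour, shape, px)
    mask &= conc.valid_mask[slice_index]
    n_pix = int(mask.sum())
    if n_pix == 0:
        raise ValueError("empty lumen ROI: unusable AIF")
    if n_pix < 10:
        raise ValueError(f"lumen ROI has only {n_pix} pixels (need >= 10)")
    curves = conc.conc[slice_index][mask]  # (n_pix, n_frames)
    n_frames = curves.shape[1]
    post = np.setdiff1d(np.arange(n_frames), conc.baseline_frames)
    total = curves[:, post].sum(axis=1)
    k = max(1, int(math.ceil(n_pix / 4)))
    cb = np.empty(n_frames)
    for t in range(n_frames):
        score = total - curves[:, t] if t in post else total
        top = np.argsort(score)[-k:]
        cb[t] = curves[top, t].mean()
    cp = np.clip(cb, 0.0, None) / (1.0 - hematocrit)
    return AIFCurve(times=conc.frame_times, cp=cp)


# --------------------------------------------------------------------------
# Patlak fit

def patlak_fit(conc: ConcentrationSeries, aif: AIFCurve,
               fit_frames=None) -> KineticMap:
    """Per-pixel ordinary least squares fit of the Patlak model.

    Solves C_t(t_k) = Ktrans * int_0^{t_k} Cp dtau + vp * Cp(t_k) for every
    pixel over the fit frames, with the running AIF integral evaluated by
    the trapezoidal rule on the frame times in minutes (so Ktrans is in
    min^-1). Baseline frames (C_p = 0) are included by default: the model
    has no intercept, so they cost nothing and stabilize the fit. Raw,
    unclamped estimates are stored.
    """
    if aif.n_frames != conc.conc.shape[-1]:
        raise ValueError("AIF length does not match concentration series")
    if fit_frames is None:
        fit_frames = np.arange(conc.conc.shape[-1])
    fit_frames = np.asarray(fit_frames, dtype=int)
    n_post = np.sum(~np.isin(fit_frames, conc.baseline_frames))
    if n_post < 3:
        raise ValueError("need at least 3 post-injection fit frames")

    integral = aif.integral_minutes()
    x = np.column_stack([integral[fit_frames], aif.cp[fit_frames]])
    if np.linalg.matrix_rank(x) < 2:
        shape = conc.conc.shape[:-1]
        nan = np.full(shape, np.nan)
        return KineticMap(ktrans=nan, vp=nan.copy(),
                          fit_residual=np.zeros(shape),
                          valid_mask=np.zeros(shape, dtype=bool))

    y = conc.conc[..., fit_frames]
    pinv = np.linalg.pinv(x)  # (2, n_fit)
    beta = np.einsum("pk,...k->...p", pinv, y)
    ktrans, vp = beta[..., 0], beta[..., 1]
    resid = y - np.einsum("kp,...p->...k", x, beta)
    rms = np.sqrt(np.mean(resid * resid, axis=-1))
    valid = conc.valid_mask & np.isfinite(ktrans) & np.isfinite(vp)
    return KineticMap(ktrans=ktrans, vp=vp, fit_residual=rms, valid_mask=valid)


# --------------------------------------------------------------------------
# rendering

def render_vv_image(kmap: KineticMap, slice_index: int = 0,
                    ktrans_max: float = 0.2, vp_max: float = 1.0,
                    channel: str = "both") -> np.ndarray:
    """Render a vasa-vasorum (V-V) image: Ktrans in green, vp in red.

    Channels are clamped to their display ranges (Ktrans: 0-0.2 min^-1,
    vp: 0-1); blue stays zero. ``channel`` selects "both", "ktrans" or "vp"
    for single-channel display. Returns (rows, cols, 3) floats in [0, 1].
    """
    kt = kmap.ktrans[slice_index] if kmap.ktrans.ndim == 3 else kmap.ktrans
    vp = kmap.vp[slice_index] if kmap.vp.ndim == 3 else kmap.vp
    green = np.clip(kt / ktrans_max, 0.0, 1.0)
    red = np.clip(vp / vp_max, 0.0, 1.0)
    img = np.zeros(kt.shape + (3,))
    if channel in ("both", "ktrans"):
        img[..., 1] = green
    if channel in ("both", "vp"):
        img[..., 0] = red
    if channel not in ("both", "ktrans", "vp"):
        raise ValueError("channel must be 'both', 'ktrans' or 'vp'")
    return img


# --------------------------------------------------------------------------
# masks and measurement

def _pixel_centers(shape: tuple[int, int], pixel_size: float):
    rows, cols = shape
    y = (np.arange(rows) + 0.5) * pixel_size
    x = (np.arange(cols) + 0.5) * pixel_size
    xx, yy = np.meshgrid(x, y)
    return np.column_stack([xx.ravel(), yy.ravel()])


def polygon_mask(contour: np.ndarray, shape: tuple[int, int],
                 pixel_size: float) -> np.ndarray:
    """Pixels whose centers fall inside a polygon given in mm coordinates."""
    contour = np.asarray(contour, dtype=float)
    path = MplPath(contour)
    pts = _pixel_centers(shape, pixel_size)
    return path.contains_points(pts).reshape(shape)


def wall_mask_with_exclusion(lumen_contour: np.ndarray, outer_contour: np.ndarray,
                             pixel_size: float, shape: tuple[int, int],
                             exclusion_mm: float = 1.0) -> np.ndarray:
    """Vessel-wall analysis mask with the near-lumen exclusion ring.

    Selects pixels whose centers lie inside the outer-wall contour, outside
    the lumen contour and strictly more than ``exclusion_mm`` from the lumen
    polygon (Euclidean distance to the polygon itself, in mm). The 1 mm
    default guards plaque means against bright-lumen partial-volume and
    motion contamination.
    """
    import shapely

    lumen_poly = shapely.Polygon(np.asarray(lumen_contour, dtype=float))
    outer_poly = shapely.Polygon(np.asarray(outer_contour, dtype=float))
    if not lumen_poly.within(outer_poly):
        raise ValueError("lumen contour must lie strictly inside the outer contour")

    inside_outer = polygon_mask(outer_contour, shape, pixel_size)
    inside_lumen = polygon_mask(lumen_contour, shape, pixel_size)
    mask = inside_outer & ~inside_lumen
    if exclusion_mm > 0:
        pts = _pixel_centers(shape, pixel_size)
        ring = shapely.LinearRing(np.asarray(lumen_contour, dtype=float))
        dist = shapely.distance(shapely.points(pts), ring).reshape(shape)
        mask &= dist > exclusion_mm
    return mask


def max_wall_thickness(lumen_contour: np.ndarray, outer_contour: np.ndarray,
                       n_samples: int = 720) -> float:
    """Maximum wall thickness in mm: largest distance from the outer-wall
    boundary to the lumen contour, sampled densely along the outer boundary."""
    import shapely

    lumen = shapely.LinearRing(np.asarray(lumen_contour, dtype=float))
    outer = shapely.LinearRing(np.asarray(outer_contour, dtype=float))
    ts = np.linspace(0.0, outer.length, n_samples, endpoint=False)
    pts = [outer.interpolate(t) for t in ts]
    return float(max(p.distance(lumen) for p in pts))


def measure_plaque(kmap: KineticMap, mask: np.ndarray, pixel_size: float,
                   slice_index: int = 0, subject_id: str | None = None,
                   scan_index: int | None = None,
                   wall_thickness: float = float("nan")) -> PlaqueMeasurement:
    """Plaque-mean Ktrans and vp over the valid masked pixels of one slice.

    The analyzed area is the count of valid masked pixels times the pixel
    area. An empty mask yields a measurement marked missing (NaN means),
    never zeros.
    """
    kt = kmap.ktrans[slice_index] if kmap.ktrans.ndim == 3 else kmap.ktrans
    vp = kmap.vp[slice_index] if kmap.vp.ndim == 3 else kmap.vp
    vmask = kmap.valid_mask[slice_index] if kmap.valid_mask.ndim == 3 else kmap.valid_mask
    sel = np.asarray(mask, dtype=bool) & vmask
    n = int(sel.sum())
    if n == 0:
        return PlaqueMeasurement(subject_id=subject_id, scan_index=scan_index,
                                 mean_ktrans=float("nan"), mean_vp=float("nan"),
                                 analyzed_area=0.0, max_wall_thickness=wall_thickness,
                                 missing=True)
    return PlaqueMeasurement(
        subject_id=subject_id, scan_index=scan_index,
        mean_ktrans=float(kt[sel].mean()), mean_vp=float(vp[sel].mean()),
        analyzed_area=n * pixel_size ** 2,
        max_wall_thickness=wall_thickness, missing=False)


# --------------------------------------------------------------------------
# protocol compliance and inclusion filters

@dataclass
class ComplianceReport:
    """Per-scan protocol-compliance flags (True = violation present)."""

    subject_id: str
    scan_index: int
    incorrect_time_interval: bool
    too_few_time_frames: bool
    contrast_not_injected: bool
    improper_alignment: bool

    @property
    def compliant(self) -> bool:
        return not (self.incorrect_time_interval or self.too_few_time_frames
                    or self.contrast_not_injected or self.improper_alignment)

    @property
    def violations(self) -> list[str]:
        out = []
        if self.incorrect_time_interval:
            out.append("incorrect time interval")
        if self.too_few_time_frames:
            out.append("too few time frames")
        if self.contrast_not_injected:
            out.append("failure to inject contrast agent")
        if self.improper_alignment:
            out.append("improper alignment of images")
        return out


def check_protocol(record: ScanRecord, protocol: AcquisitionProtocol,
                   interval_tol_s: float = 1.0) -> ComplianceReport:
    """Flag the four protocol-violation types on a single scan record:
    wrong frame interval (beyond ``interval_tol_s``), too few frames,
    missing contrast injection, and a slab not centered on the bifurcation."""
    return ComplianceReport(
        subject_id=record.subject_id,
        scan_index=record.scan_index,
        incorrect_time_interval=abs(record.frame_interval_actual
                                    - protocol.frame_interval) > interval_tol_s,
        too_few_time_frames=record.n_frames_actual < protocol.n_frames,
        contrast_not_injected=not record.contrast_injected,
        improper_alignment=not record.slab_centered_on_bifurcation,
    )


def subject_protocol_compliance(roster, protocol: AcquisitionProtocol,
                                interval_tol_s: float = 1.0) -> dict[str, bool]:
    """Subject-level compliance: a subject passes only if both scans pass all
    four checks."""
    out: dict[str, bool] = {}
    for rec in roster:
        ok = check_protocol(rec, protocol, interval_tol_s).compliant
        out[rec.subject_id] = out.get(rec.subject_id, True) and ok
    return out


def apply_inclusion(measurements, threshold_mm: float = 1.0):
    """Keep measurements whose plaque has maximum wall thickness strictly
    greater than ``threshold_mm`` (distinct-plaque inclusion rule)."""
    return [m for m in measurements if m.max_wall_thickness > threshold_mm]
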