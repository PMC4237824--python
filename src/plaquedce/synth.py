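"""Synthetic study inputs: vessel phantoms, bolus AIFs, dynamic series,
scan-rescan measurement cohorts and a study roster with exclusion flags.

The generators reproduce the statistical structure the downstream analysis
assumes: Patlak tissue kinetics at carotid-plaque magnitudes
(Ktrans ~ 0.06 min^-1, vp ~ 0.07), SPGR signal generation under the
acquisition protocol (18 frames, 18 s apart, injection at frame 3), a
balanced two-scan-per-subject measurement model
y_ij = mu + b_i + e_ij, and a 51-subject roster carrying the
protocol-violation and image-quality flags of a multi-center study
(10 protocol-excluded, 6 quality-excluded, 35 analyzed). Every generator is
a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import AcquisitionProtocol, AIFCurve, ScanRecord, protocol_for_vendor
from .kinetics import DCESeries, spgr_signal

__all__ = [
    "TissueProperties",
    "VesselPhantom",
    "CohortSpec",
    "generate_aif",
    "build_phantom",
    "simulate_series",
    "generate_measurement_cohort",
    "generate_roster_fixture",
    "ROSTER_SITE_SIZES",
]


# --------------------------------------------------------------------------
# arterial input function

def generate_aif(protocol: AcquisitionProtocol, peak: float = 2.0,
                 washout_rate: float = 0.2) -> AIFCurve:
    """Population bolus AIF sampled at the protocol's frame times.

    A gamma-variate first pass (peaking one frame interval after injection)
    plus a slowly rising, mono-exponentially decaying washout tail whose
    decay constant is ``washout_rate`` (1/min). The curve is zero before the
    injection frame and scaled so that its maximum over the sampled frames
    equals ``peak`` (mmol/L); a peak near 2 mmol/L is typical plasma
    concentration for a 0.05 mmol/kg dose.
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    if washout_rate <= 0:
        raise ValueError("washout_rate must be positive")
    times = protocol.frame_times
    t_inj = times[protocol.injection_frame - 1]
    tau = times - t_inj
    tp = protocol.frame_interval  # bolus peaks ~1 frame after injection
    a = 3.0
    with np.errstate(invalid="ignore"):
        bolus = np.where(tau > 0, (tau / tp) ** a * np.exp(a * (1.0 - tau / tp)), 0.0)
    k_s = washout_rate / 60.0  # 1/min -> 1/s
    tail = np.where(tau > 0, 0.4 * (1.0 - np.exp(-tau / tp)) * np.exp(-k_s * tau), 0.0)
    cp = bolus + tail
    cp *= peak / cp.max()
    return AIFCurve(times=times, cp=cp)


# --------------------------------------------------------------------------
# vessel phantom

@dataclass(frozen=True)
class TissueProperties:
    """Baseline relaxation / signal-scale constants used by the simulator.

    T10 values in ms; r1 is the contrast relaxivity in L mmol^-1 s^-1
    (literature-typical gadolinium value at 3T). ``m0`` values are
    arbitrary-unit equilibrium signal scales.
    """

    t10_wall: float = 1000.0
    t10_blood: float = 1650.0
    t10_background: float = 1200.0
    m0_wall: float = 1.0
    m0_blood: float = 1.0
    m0_background: float = 0.3
    r1: float = 4.5


@dataclass
class VesselPhantom:
    """2D carotid cross-section phantom with ground-truth kinetic maps.

    Masks and per-pixel maps live on a square lattice with the protocol's
    pixel size; contours are polygons in mm (pixel centers at
    (i + 0.5) * pixel_size). Inside the lumen vp = 1 and Ktrans = 0 (pure
    plasma); the wall carries the requested Ktrans/vp.
    """

    grid_shape: tuple[int, int]
    pixel_size: float
    lumen_mask: np.ndarray
    wall_mask: np.ndarray
    lumen_contour: np.ndarray
    outer_contour: np.ndarray
    ktrans_true: np.ndarray
    vp_true: np.ndarray
    t10: np.ndarray
    m0: np.ndarray
    r1: float

    def max_wall_thickness(self) -> float:
        from .kinetics import max_wall_thickness as _mwt

        return _mwt(self.lumen_contour, self.outer_contour)


def _circle(center: tuple[float, float], radius, n: int = 256) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    r = np.broadcast_to(np.asarray(radius, dtype=float), theta.shape)
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def build_phantom(protocol: AcquisitionProtocol, lumen_radius: float = 3.0,
                  wall_thickness: float = 1.5, plaque_bulge: float = 2.0,
                  ktrans_wall: float = 0.062, vp_wall: float = 0.067,
                  seed: int = 0, grid_shape: tuple[int, int] = (64, 64),
                  tissue: TissueProperties = TissueProperties(),
                  spatial_variation: float = 0.0,
                  plaque_angle: float = 0.0) -> VesselPhantom:
    """Build an annular vessel-wall phantom with an eccentric plaque bulge.

    The outer boundary is the lumen circle offset by ``wall_thickness`` plus
    a smooth angular bump of height ``plaque_bulge`` centered on
    ``plaque_angle`` (radians), emulating a distinct plaque. With
    ``spatial_variation`` > 0 the wall's true Ktrans/vp get a smooth
    multiplicative perturbation of that relative amplitude.
    """
    if lumen_radius <= 0 or wall_thickness <= 0:
        raise ValueError("lumen_radius and wall_thickness must be positive")
    if plaque_bulge < 0:
        raise ValueError("plaque_bulge must be non-negative")
    px = protocol.pixel_size
    half_y = grid_shape[0] * px / 2.0
    half_x = grid_shape[1] * px / 2.0
    r_out_max = lumen_radius + wall_thickness + plaque_bulge
    if r_out_max >= min(half_x, half_y):
        raise ValueError("vessel geometry exceeds the simulated field of view")

    center = (half_x, half_y)
    n_theta = 256
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    ang = np.angle(np.exp(1j * (theta - plaque_angle)))
    bump = np.exp(-0.5 * (ang / 0.7) ** 2)
    r_outer = lumen_radius + wall_thickness + plaque_bulge * bump

    lumen_contour = _circle(center, lumen_radius, n_theta)
    outer_contour = np.column_stack([center[0] + r_outer * np.cos(theta),
                                     center[1] + r_outer * np.sin(theta)])

    y = (np.arange(grid_shape[0]) + 0.5) * px
    x = (np.arange(grid_shape[1]) + 0.5) * px
    xx, yy = np.meshgrid(x, y)
    rr = np.hypot(xx - center[0], yy - center[1])
    pix_theta = np.arctan2(yy - center[1], xx - center[0])
    pang = np.angle(np.exp(1j * (pix_theta - plaque_angle)))
    pix_r_outer = (lumen_radius + wall_thickness
                   + plaque_bulge * np.exp(-0.5 * (pang / 0.7) ** 2))
    lumen_mask = rr < lumen_radius
    wall_mask = (rr >= lumen_radius) & (rr < pix_r_outer)

    ktrans = np.zeros(grid_shape)
    vp = np.zeros(grid_shape)
    ktrans[wall_mask] = ktrans_wall
    vp[wall_mask] = vp_wall
    vp[lumen_mask] = 1.0
    if spatial_variation > 0:
        rng = np.random.default_rng(seed)
        field_ = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=4.0)
        field_ /= max(np.abs(field_).max(), 1e-12)
        mod = 1.0 + spatial_variation * field_
        ktrans[wall_mask] *= mod[wall_mask]
        vp[wall_mask] = np.clip(vp[wall_mask] * mod[wall_mask], 0.0, 1.0)

    t10 = np.full(grid_shape, tissue.t10_background)
    t10[wall_mask] = tissue.t10_wall
    t10[lumen_mask] = tissue.t10_blood
    m0 = np.full(grid_shape, tissue.m0_background)
    m0[wall_mask] = tissue.m0_wall
    m0[lumen_mask] = tissue.m0_blood

    return VesselPhantom(grid_shape=grid_shape, pixel_size=px,
                         lumen_mask=lumen_mask, wall_mask=wall_mask,
                         lumen_contour=lumen_contour, outer_contour=outer_contour,
                         ktrans_true=ktrans, vp_true=vp, t10=t10, m0=m0,
                         r1=tissue.r1)


# --------------------------------------------------------------------------
# dynamic series simulation

def tissue_concentration(ktrans: np.ndarray, vp: np.ndarray,
                         aif: AIFCurve) -> np.ndarray:
    """Patlak forward model: C_t(t) = Ktrans * int_0^t Cp dtau + vp * Cp(t).

    Ktrans in min^-1; the running integral uses the trapezoidal rule on the
    frame times in minutes. Exactly linear in (Ktrans, vp).
    """
    integral = aif.integral_minutes()
    return (np.asarray(ktrans)[..., None] * integral
            + np.asarray(vp)[..., None] * aif.cp)


def simulate_series(phantom: VesselPhantom, aif: AIFCurve,
                    protocol: AcquisitionProtocol, noise_sd: float = 0.0,
                    motion_amplitude: float = 0.0, seed: int = 0,
                    n_slices: int = 1) -> DCESeries:
    """Forward-simulate a dynamic SPGR series from a phantom and an AIF.

    Per pixel, tissue concentration follows the Patlak model; concentration
    maps to signal through the steady-state SPGR equation with the phantom's
    T10/M0/r1. Zero-mean Gaussian noise of ``noise_sd`` (signal units) is
    added, and each frame may be rigidly translated by an independent
    uniform(-a, a) mm shift per axis with a = ``motion_amplitude``
    (scan-to-scan positioning / patient-motion surrogate). Identical
    arguments including ``seed`` give byte-identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if aif.n_frames != protocol.n_frames:
        raise ValueError("AIF frame count does not match protocol")
    rng = np.random.default_rng(seed)
    conc = tissue_concentration(phantom.ktrans_true, phantom.vp_true, aif)
    signal = spgr_signal(conc, phantom.t10, phantom.m0, phantom.r1,
                         protocol.tr, protocol.flip_angle)
    data = np.broadcast_to(signal, (n_slices,) + signal.shape).copy()
    if motion_amplitude > 0:
        shifts_mm = rng.uniform(-motion_amplitude, motion_amplitude,
                                size=(n_slices, protocol.n_frames, 2))
        for s in range(n_slices):
            for t in range(protocol.n_frames):
                data[s, :, :, t] = ndimage.shift(
                    data[s, :, :, t], shifts_mm[s, t] / phantom.pixel_size,
                    order=1, mode="nearest")
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return DCESeries(data=data, protocol=protocol, frame_times=aif.times)


# --------------------------------------------------------------------------
# measurement cohort

@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a balanced scan-rescan measurement cohort.

    The measurement model is y_ij = mu + b_i + e_ij for subject i and scan
    j in {1, 2}, with b_i ~ N(0, sigma_b^2) (between-subject) and
    e_ij ~ N(0, sigma_w^2) (between-scan). Plaque areas are lognormal and
    shared between scans up to a small lognormal jitter. Defaults match the
    reproducibility cohort of the transfer constant: n = 35 (20 GE / 15
    Philips), mu = 0.062 min^-1, between-scan CV 25%, ICC 0.65.
    """

    n_subjects: int = 35
    n_ge: int = 20
    grand_mean: float = 0.062
    between_subject_sd: float = 0.062 * 0.25 * math.sqrt(0.65 / 0.35)
    between_scan_sd: float = 0.062 * 0.25
    area_log_mean: float = math.log(28.0)
    area_log_sd: float = 0.55
    area_scan_jitter: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not 0 <= self.n_ge <= self.n_subjects:
            raise ValueError("n_ge must be between 0 and n_subjects")
        if self.between_subject_sd < 0 or self.between_scan_sd < 0:
            raise ValueError("variance components must be non-negative")

    @classmethod
    def from_cv_icc(cls, n_subjects: int = 35, grand_mean: float = 0.062,
                    cv: float = 0.25, icc: float = 0.65, n_ge: int | None = None,
                    seed: int = 0, **kwargs) -> "CohortSpec":
        """Construct from the reported summary scale: between-scan CV and ICC.

        sigma_w = cv * mu and sigma_b = sigma_w * sqrt(icc / (1 - icc)).
        """
        if not 0 <= icc < 1:
            raise ValueError("icc must be in [0, 1)")
        sw = cv * grand_mean
        sb = sw * math.sqrt(icc / (1.0 - icc)) if icc > 0 else 0.0
        if n_ge is None:
            n_ge = round(n_subjects * 20 / 35)
        return cls(n_subjects=n_subjects, n_ge=n_ge, grand_mean=grand_mean,
                   between_subject_sd=sb, between_scan_sd=sw, seed=seed, **kwargs)

    @property
    def implied_icc(self) -> float:
        tot = self.between_subject_sd ** 2 + self.between_scan_sd ** 2
        return self.between_subject_sd ** 2 / tot if tot > 0 else 0.0

    @property
    def implied_cv(self) -> float:
        return self.between_scan_sd / self.grand_mean


def generate_measurement_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one paired scan-rescan cohort table from a :class:`CohortSpec`.

    Returns a DataFrame with columns subject_id, vendor, y1, y2, area1,
    area2 — one row per subject, both scans present.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    b = rng.normal(0.0, spec.between_subject_sd, size=n)
    e = rng.normal(0.0, spec.between_scan_sd, size=(n, 2))
    y = spec.grand_mean + b[:, None] + e
    area = np.exp(rng.normal(spec.area_log_mean, spec.area_log_sd, size=n))
    jit = np.exp(rng.normal(0.0, spec.area_scan_jitter, size=(n, 2)))
    areas = area[:, None] * jit
    vendor = np.array(["GE"] * spec.n_ge + ["Philips"] * (n - spec.n_ge))
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "vendor": vendor,
        "y1": y[:, 0], "y2": y[:, 1],
        "area1": areas[:, 0], "area2": areas[:, 1],
    })


# --------------------------------------------------------------------------
# study roster fixture

# Site sizes sum to 51 over 15 sites (max 6 subjects per site).
ROSTER_SITE_SIZES = (6, 5, 5, 4, 4, 4, 4, 3, 3, 3, 3, 2, 2, 2, 1)

# Sites using GE scanners; chosen so the analyzed set splits 20 GE / 15 Philips.
_GE_SITES = {1, 2, 4, 5, 8, 9, 12, 15}


def generate_roster_fixture(seed: int = 0) -> list[ScanRecord]:
    """Build the 51-subject, 102-scan study roster with exclusion flags.

    Exactly 10 subjects carry one protocol violation each — incorrect frame
    interval (3), too few frames (2), missed contrast injection (2),
    misaligned slab (3); categories are disjoint. The violators are spread
    over 9 sites (one per site at sites 1-8 plus both subjects of the
    two-subject site 14). Of the remaining 41 subjects, exactly 6 have an
    uninterpretable scan (quality score 1), spread over 6 sites (9-13 plus
    one in site 1). No site accumulates more than 2 exclusions, leaving 35
    analyzable subjects from 14 sites. The seed randomizes which scan of a
    flagged subject carries the flag, the benign quality scores, and the
    actual violating values; the counts are structural.
    """
    rng = np.random.default_rng(seed)
    subjects: list[tuple[str, str, str]] = []  # (subject_id, site_id, vendor)
    sid = 0
    for s, size in enumerate(ROSTER_SITE_SIZES, start=1):
        vendor = "GE" if s in _GE_SITES else "Philips"
        for _ in range(size):
            sid += 1
            subjects.append((f"P{sid:03d}", f"site{s:02d}", vendor))

    by_site: dict[str, list[int]] = {}
    for idx, (_, site, _) in enumerate(subjects):
        by_site.setdefault(site, []).append(idx)

    # protocol violators: first subject of sites 1..8, both subjects of site 14
    violator_idx = [by_site[f"site{s:02d}"][0] for s in range(1, 9)]
    violator_idx += by_site["site14"]
    categories = (["interval"] * 3 + ["frames"] * 2 + ["contrast"] * 2
                  + ["alignment"] * 3)
    categories = list(rng.permutation(categories))
    violation = dict(zip(violator_idx, categories))

    # quality exclusions: one subject in each of sites 9..13 + one in site 1
    quality_idx = [by_site[f"site{s:02d}"][0] for s in range(9, 14)]
    quality_idx.append(by_site["site01"][1])
    assert not set(quality_idx) & set(violation)

    roster: list[ScanRecord] = []
    for idx, (subj, site, vendor) in enumerate(subjects):
        bad_scan = int(rng.integers(1, 3))
        cat = violation.get(idx)
        q1_scan = bad_scan if idx in quality_idx else 0
        for scan in (1, 2):
            rec = ScanRecord(subject_id=subj, scan_index=scan, vendor=vendor,
                             site_id=site,
                             quality_score=1 if scan == q1_scan
                             else int(rng.integers(2, 5)))
            if cat is not None and scan == bad_scan:
                if cat == "interval":
                    rec.frame_interval_actual = float(rng.choice([13.0, 21.0, 24.0]))
                elif cat == "frames":
                    rec.n_frames_actual = int(rng.integers(8, 16))
                elif cat == "contrast":
                    rec.contrast_injected = False
                elif cat == "alignment":
                    rec.slab_centered_on_bifurcation = False
            roster.append(rec)
    return roster
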