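"""Synthetic spheroid studies: images, ATP labels, dose-response panels, biomarkers.

Every downstream stage (segmentation, shape features, normalization, the deep
regressor, dose-response/DILI analysis) is testable against this generator
without any real-data download.  The generative model is deliberately simple
but maps the three morphological axes a pathologist grades — contour
indentation, core darkening, fragmentation — each to one knob that is a
monotone function of ground-truth viability, plus a granular interior texture
cue.  Per-spheroid multiplicative jitter on each cue emulates biological
heterogeneity: no single cue determines viability exactly, so estimators that
integrate all cues can outperform ones restricted to a fixed feature list.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "MorphologyParams",
    "SyntheticStudySpec",
    "DoseResponseSpec",
    "StudyData",
    "viability_to_morphology",
    "render_spheroid",
    "generate_study",
    "generate_dose_response",
    "generate_biomarkers",
    "MANIFEST_COLUMNS",
    "ATP_UNIT_NM",
    "VIABILITY_MAX",
]

# Viability is control-normalized ATP; values modestly above 1 occur when a
# spheroid outperforms the control median.  1.3 is the supported ceiling.
VIABILITY_MAX = 1.3

# Absolute ATP scale of a fully viable spheroid, in nM.  Only normalized
# values matter downstream; this sets a realistic order of magnitude.
ATP_UNIT_NM = 800.0

# Morphology map ceilings (fraction of radius / intensity fractions) and
# per-spheroid heterogeneity: each cue carries independent multiplicative
# log-normal jitter, so no single cue pins viability down exactly.  The
# granular-texture cue is the most reliable one and is visible only in the
# raw pixels, not in contour/brightness summaries.
MAX_IRREGULARITY = 0.35
MAX_CORE_DARKNESS = 0.60
MAX_TEXTURE = 0.22
AMP_JITTER_SD = 0.85
DARKNESS_JITTER_SD = 0.70
TEXTURE_JITTER_SD = 0.12
TEXTURE_GRAIN_SIGMA = 3.0  # px; granularity at the scale of cell clusters
MAX_ROUGHNESS = 0.05  # viability-independent fine boundary roughness

MANIFEST_COLUMNS = [
    "Domain", "Location", "Study", "Day", "Treatment", "Compound",
    "Concentration_uM", "Plate", "Well", "Microscope", "Location_in_bucket",
    "Value", "w", "h", "xmin", "ymin", "xmax", "ymax",
    "Cytoplasmic_score", "Nuclear_score", "Contour_score",
]


@dataclass(frozen=True)
class MorphologyParams:
    """Rendering parameters for one synthetic spheroid.

    ``irregularity_harmonics`` is a list of ``(order, phase, weight)`` tuples;
    the boundary radius is ``radius * (1 + A * sum(w * cos(k*theta + phi)))``
    with ``A = irregularity_amplitude``.  ``roughness_harmonics`` add fine,
    viability-independent boundary roughness (individual cells at the rim)
    scaled by ``roughness_amplitude`` in the same functional form.
    """

    radius: float
    irregularity_amplitude: float
    irregularity_harmonics: tuple
    core_darkness: float
    fragment_count: int
    background_level: float = 0.80
    noise_sd: float = 0.02
    texture_strength: float = 0.0
    baseline_attenuation: float = 0.25  # healthy spheroids are visibly darker
    # optical nuisances: linear illumination gradient across the frame,
    # per-image exposure scale, and slight defocus blur (sigma in px)
    illumination_gradient: float = 0.0
    illumination_angle: float = 0.0
    exposure: float = 1.0
    defocus_sigma: float = 0.0
    roughness_amplitude: float = 0.0
    roughness_harmonics: tuple = ()

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.irregularity_amplitude <= 0.5):
            raise ValueError("irregularity_amplitude must lie in [0, 0.5]")
        if not (0.0 <= self.core_darkness <= 1.0):
            raise ValueError("core_darkness must lie in [0, 1]")
        if self.fragment_count < 0:
            raise ValueError("fragment_count must be >= 0")


def viability_to_morphology(v, seed, radius=None):
    """Map a ground-truth viability fraction to rendering parameters.

    The map is deterministic given ``(v, seed)``.  Contour irregularity and
    core darkness increase as viability falls (both are exactly zero for
    ``v >= 1``); fragments appear only below v = 0.25.  The seed controls the
    harmonic make-up of the contour perturbation, the per-spheroid cue
    jitter, and the spheroid radius.
    """
    v = float(v)
    if not (0.0 <= v <= VIABILITY_MAX):
        raise ValueError(f"viability {v!r} outside [0, {VIABILITY_MAX}]")
    rng = np.random.default_rng(seed)

    # draws below are in fixed order so that the map is monotone in v for a
    # fixed seed: none of the random factors depends on v
    if radius is None:
        radius = rng.uniform(14.0, 22.0)
    orders = rng.choice(np.arange(3, 9), size=3, replace=False)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    weights = rng.dirichlet(np.ones(3))
    r_orders = rng.choice(np.arange(10, 17), size=4, replace=False)
    r_phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
    r_weights = rng.dirichlet(np.ones(4))
    roughness = rng.uniform(0.0, MAX_ROUGHNESS)
    jit_amp = np.exp(rng.normal(0.0, AMP_JITTER_SD))
    jit_dark = np.exp(rng.normal(0.0, DARKNESS_JITTER_SD))
    jit_tex = np.exp(rng.normal(0.0, TEXTURE_JITTER_SD))

    deficit = 1.0 - min(max(v, 0.0), 1.0)
    amp = min(MAX_IRREGULARITY * jit_amp, 0.5) * deficit**1.5
    darkness = min(MAX_CORE_DARKNESS * jit_dark, 1.0) * deficit
    texture = min(MAX_TEXTURE * jit_tex, 0.5) * deficit
    frags = int(1 + rng.poisson(2.0 * (0.25 - v) / 0.25)) if v < 0.25 else 0

    harmonics = tuple(
        (int(k), float(p), float(w)) for k, p, w in zip(orders, phases, weights)
    )
    return MorphologyParams(
        radius=float(radius),
        irregularity_amplitude=float(amp),
        irregularity_harmonics=harmonics,
        core_darkness=float(darkness),
        fragment_count=frags,
        texture_strength=float(texture),
        illumination_gradient=float(rng.uniform(0.0, 0.08)),
        illumination_angle=float(rng.uniform(0.0, 2.0 * np.pi)),
        exposure=float(rng.uniform(0.92, 1.08)),
        defocus_sigma=float(rng.uniform(0.3, 0.6)),
        roughness_amplitude=float(roughness),
        roughness_harmonics=tuple(
            (int(k), float(p), float(w))
            for k, p, w in zip(r_orders, r_phases, r_weights)
        ),
    )


def _boundary_radius(params, theta):
    r = np.ones_like(theta)
    a = params.irregularity_amplitude
    if a > 0:
        for order, phase, weight in params.irregularity_harmonics:
            r = r + a * weight * np.cos(order * theta + phase)
    ra = params.roughness_amplitude
    if ra > 0:
        for order, phase, weight in params.roughness_harmonics:
            r = r + ra * weight * np.cos(order * theta + phase)
    return params.radius * r


def render_spheroid(params, image_size, seed):
    """Render one spheroid; returns ``(image, mask)``.

    ``image`` is float32 in [0, 1]; ``mask`` marks interior pixels of the
    main body exactly (fragments are rendered but excluded from the mask).
    Rendering is bit-identical for identical ``(params, image_size, seed)``.
    """
    image_size = int(image_size)
    if image_size < 4 * params.radius:
        raise ValueError(
            f"image_size {image_size} too small for radius {params.radius:.1f} "
            "(need >= 4 * radius)"
        )
    rng = np.random.default_rng(seed)
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(np.float64)
    dx, dy = xx - c, yy - c
    rr = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    rb = _boundary_radius(params, theta)
    mask = rr <= rb
    rho = np.where(mask, rr / np.maximum(rb, 1e-9), 1.0)

    # attenuation: flat body + darker rim + viability-dependent dark core
    attn = (
        params.baseline_attenuation
        + 0.15 * np.exp(-(((1.0 - rho) * params.radius / 2.5) ** 2))
        + params.core_darkness * np.exp(-((rho / 0.55) ** 2))
    )
    img = np.full((image_size, image_size), params.background_level)
    img[mask] = params.background_level * np.clip(1.0 - attn[mask], 0.02, None)

    if params.texture_strength > 0:
        # additive granularity: scattered-light variation at the cell-cluster
        # scale, independent of how dark the necrotic core is
        speck = gaussian_filter(rng.standard_normal(img.shape),
                                sigma=TEXTURE_GRAIN_SIGMA)
        sd = speck.std()
        if sd > 0:
            img[mask] += 0.5 * params.texture_strength * speck[mask] / sd

    for _ in range(params.fragment_count):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        dist = rng.uniform(1.15, 1.6) * params.radius
        fr = rng.uniform(0.10, 0.25) * params.radius
        fx = np.clip(c + dist * np.cos(ang), fr, image_size - 1 - fr)
        fy = np.clip(c + dist * np.sin(ang), fr, image_size - 1 - fr)
        fd = np.hypot(xx - fx, yy - fy)
        img *= 1.0 - 0.35 * np.exp(-((fd / fr) ** 2))

    # optical nuisances: defocus, illumination gradient, exposure
    if params.defocus_sigma > 0:
        img = gaussian_filter(img, params.defocus_sigma)
    if params.illumination_gradient > 0:
        u = (dx * np.cos(params.illumination_angle)
             + dy * np.sin(params.illumination_angle)) / image_size
        img = img * (1.0 + params.illumination_gradient * u)
    img = img * params.exposure

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), mask


def _default_control_sampler(rng):
    return float(np.clip(rng.normal(1.0, 0.05), 0.8, VIABILITY_MAX))


def _default_treated_sampler(rng):
    return float(rng.uniform(0.0, 1.2))


@dataclass
class SyntheticStudySpec:
    """Configuration for one synthetic labeled study.

    ``batch_scale`` multiplies every raw ATP value of the study; ``None``
    draws it log-normally (sigma 0.4) to emulate the between-study batch
    effect.  ``control_fraction`` is the fraction of wells per plate left
    untreated; studies are expected to carry at least 12 control wells per
    plate.
    """

    study_id: str = "S1"
    domain: str = "A"
    location: str = "LabA"
    microscope: str = "synthetic_scope"
    n_plates: int = 1
    wells_per_plate: int = 48
    control_fraction: float = 0.25
    batch_scale: float | None = None
    viability_sampler: object = None  # callable rng -> v, for treated wells
    atp_noise_cv: float = 0.10
    seed: int = 0
    image_size: int = 96
    day: int | None = None

    def __post_init__(self):
        if self.n_plates < 1 or self.wells_per_plate < 1:
            raise ValueError("n_plates and wells_per_plate must be >= 1")
        if not (0.0 <= self.control_fraction <= 1.0):
            raise ValueError("control_fraction must lie in [0, 1]")
        if self.atp_noise_cv < 0:
            raise ValueError("atp_noise_cv must be >= 0")
        n_ctrl = int(round(self.control_fraction * self.wells_per_plate))
        if n_ctrl < 12:
            warnings.warn(
                f"study {self.study_id}: {n_ctrl} control wells per plate "
                "(fewer than the recommended 12)",
                stacklevel=2,
            )


@dataclass
class StudyData:
    """A generated study: manifest rows plus aligned in-memory images."""

    manifest: pd.DataFrame
    images: list
    masks: list
    truth: pd.DataFrame

    def write(self, out_dir, write_masks=False):
        """Write images as 8-bit PNGs plus manifest.csv and truth.csv."""
        import imageio.v3 as iio

        os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
        for path, img in zip(self.manifest["Location_in_bucket"], self.images):
            iio.imwrite(
                os.path.join(out_dir, path),
                np.round(np.asarray(img) * 255).astype(np.uint8),
            )
        if write_masks:
            os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)
            for path, m in zip(self.manifest["Location_in_bucket"], self.masks):
                name = os.path.basename(path)
                iio.imwrite(
                    os.path.join(out_dir, "masks", name),
                    (np.asarray(m) * 255).astype(np.uint8),
                )
        self.manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        self.truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)


def _well_name(i):
    return f"{chr(ord('A') + i // 12)}{i % 12 + 1}"


def generate_study(spec: SyntheticStudySpec) -> StudyData:
    """Generate one study: per-well viability, image, raw ATP, manifest row.

    Raw ATP is ``batch_scale * ATP_UNIT_NM * v * (1 + eps)`` with
    ``eps ~ N(0, atp_noise_cv)``; control wells draw viability near 1.  The
    manifest follows the standard column schema; ``truth`` carries the
    ground-truth viability, per-well seeds and the batch scale.
    """
    rng = np.random.default_rng(spec.seed)
    batch_scale = (
        float(np.exp(rng.normal(0.0, 0.4))) if spec.batch_scale is None
        else float(spec.batch_scale)
    )
    if batch_scale <= 0:
        raise ValueError("batch_scale must be positive")
    treated_sampler = spec.viability_sampler or _default_treated_sampler
    day = int(spec.day) if spec.day is not None else int(rng.integers(3, 8))
    n_ctrl = int(round(spec.control_fraction * spec.wells_per_plate))

    rows, images, masks, truth_rows = [], [], [], []
    for p in range(spec.n_plates):
        plate = f"P{p + 1}"
        order = rng.permutation(spec.wells_per_plate)
        for i in range(spec.wells_per_plate):
            well = _well_name(i)
            is_control = order[i] < n_ctrl
            v = (
                _default_control_sampler(rng) if is_control
                else treated_sampler(rng)
            )
            wseed = int(rng.integers(0, 2**31 - 1))
            morph = viability_to_morphology(v, wseed)
            img, mask = render_spheroid(morph, spec.image_size, wseed + 1)
            atp = batch_scale * ATP_UNIT_NM * v * (
                1.0 + rng.normal(0.0, spec.atp_noise_cv)
            )
            atp = max(atp, 0.0)

            ys, xs = np.nonzero(mask)
            h = w = spec.image_size
            xmin, xmax = xs.min() / w, (xs.max() + 1) / w
            ymin, ymax = ys.min() / h, (ys.max() + 1) / h

            healthy = min(max(v, 0.0), 1.0)
            scores = np.clip(
                np.round(4.0 * healthy + rng.normal(0.0, 0.5, size=3)), 0, 4
            ).astype(int)
            conc = 0.0 if is_control else float(
                np.round(10 ** rng.uniform(-1, 2), 3)
            )
            rows.append({
                "Domain": spec.domain,
                "Location": spec.location,
                "Study": spec.study_id,
                "Day": day,
                "Treatment": "control" if is_control else "drug",
                "Compound": "DMSO" if is_control else f"cmpd-{order[i]:03d}",
                "Concentration_uM": conc,
                "Plate": plate,
                "Well": well,
                "Microscope": spec.microscope,
                "Location_in_bucket":
                    f"images/{spec.study_id}_{plate}_{well}.png",
                "Value": atp,
                "w": w,
                "h": h,
                "xmin": round(xmin, 6),
                "ymin": round(ymin, 6),
                "xmax": round(xmax, 6),
                "ymax": round(ymax, 6),
                "Cytoplasmic_score": int(scores[0]),
                "Nuclear_score": int(scores[1]),
                "Contour_score": int(scores[2]),
            })
            images.append(img)
            masks.append(mask)
            truth_rows.append({
                "Study": spec.study_id, "Plate": plate, "Well": well,
                "true_viability": v, "well_seed": wseed,
                "batch_scale": batch_scale,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return StudyData(manifest, images, masks, pd.DataFrame(truth_rows))


@dataclass
class DoseResponseSpec:
    """One synthetic drug for the dose-response/DILI pipeline.

    Mean viability at concentration ``c`` on the final day follows the Hill
    curve ``v(c) = 1 / (1 + (c / true_ic50)**hill_slope)``; on earlier days
    the apparent IC50 is shifted up by ``onset_rate`` per remaining day, so
    drug effect sets in monotonically over the time course.
    """

    drug: str
    true_ic50: float
    hill_slope: float
    concentrations: tuple
    cmax: float
    dili_label: int
    replicates_per_conc: int = 5
    days: tuple = (7,)
    noise_cv: float = 0.10
    onset_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be sorted strictly ascending")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")
        if self.true_ic50 <= 0 or self.cmax <= 0:
            raise ValueError("true_ic50 and cmax must be positive")


def hill_viability(conc, ic50, hill_slope):
    """Descending Hill curve with top 1 and bottom 0."""
    conc = np.asarray(conc, dtype=float)
    return 1.0 / (1.0 + (conc / ic50) ** hill_slope)


def generate_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """Per-replicate viabilities over the day x concentration grid.

    Columns: drug, concentration_uM, day, replicate, viability, cmax_uM,
    dili_label.  With ``noise_cv=0`` the final-day means are exact Hill
    values, so a round-trip fit recovers ``true_ic50``.
    """
    rng = np.random.default_rng(spec.seed)
    last_day = max(spec.days)
    rows = []
    for day in spec.days:
        ic50_day = spec.true_ic50 * (1.0 + spec.onset_rate * (last_day - day))
        for c in spec.concentrations:
            mu = float(hill_viability(c, ic50_day, spec.hill_slope))
            for rep in range(spec.replicates_per_conc):
                v = mu * (1.0 + rng.normal(0.0, spec.noise_cv)) \
                    if spec.noise_cv > 0 else mu
                rows.append({
                    "drug": spec.drug,
                    "concentration_uM": float(c),
                    "day": int(day),
                    "replicate": rep,
                    "viability": max(float(v), 0.0),
                    "cmax_uM": spec.cmax,
                    "dili_label": int(spec.dili_label),
                })
    return pd.DataFrame(rows)


BIOMARKER_CHANNELS = ("yellow_488_617", "red_488_685", "green_561_617")


def generate_biomarkers(v, seed, target_corr=(0.8, 0.7, 0.75),
                        slopes=(1.0, 0.8, 1.2), intercepts=(0.5, 0.6, 0.4)):
    """Per-channel fluorescence biomarker scores as noisy affine maps of viability.

    Noise is calibrated so each channel's population correlation with the
    supplied viability sample equals ``target_corr`` (requires the standard
    0.6-0.9 regime).  Raises if viability has zero variance, where the
    correlation is undefined.
    """
    v = np.asarray(v, dtype=float)
    if np.any((v < 0) | (v > VIABILITY_MAX)):
        raise ValueError(f"viability values outside [0, {VIABILITY_MAX}]")
    sd = v.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(v).max())):
        raise ValueError("viability has zero variance: correlation undefined")
    rng = np.random.default_rng(seed)
    out = {}
    for ch, rho, a, b in zip(BIOMARKER_CHANNELS, target_corr, slopes, intercepts):
        if not (0.0 < rho <= 1.0):
            raise ValueError("target correlation must lie in (0, 1]")
        noise_sd = abs(a) * sd * np.sqrt(1.0 / rho**2 - 1.0)
        out[ch] = np.clip(a * v + b + rng.normal(0.0, noise_sd, v.shape), 0.0, None)
    return pd.DataFrame(out)
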