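"""Synthetic PET tumor phantoms and whole pre/post-therapy cohorts.

Every downstream stage (delineation, features, cohort statistics) is
exercised on these phantoms, so the generator is first-class, deterministic
code with known ground truth.

Single tumor model
------------------
An ellipsoid of peak uptake ``suv_peak`` sits in a uniform background.
Intra-tumor heterogeneity is a log-normal multiplicative Gaussian random
field: white noise smoothed with a Gaussian kernel of width
``texture_corr_len`` (mm), standardized, and exponentiated so the
multiplicative field has mean 1 and standard deviation ``heterogeneity_sd``
while staying positive.  The volume is then blurred with a Gaussian PSF of
``blur_fwhm`` (mm) emulating scanner resolution, additive Gaussian noise of
SD ``noise_sd`` is applied, and values are clipped at zero.  This is an
SUV-space emulation; no scanner physics (sinograms, reconstruction) is
simulated.

Cohort model
------------
A cohort draws per-patient clinical covariates (age, FIGO stage, response,
recurrence, cycles, regimen) with category proportions mirroring an
83-patient cervical-cancer chemotherapy cohort, paired pre/post tumors
with post-therapy shrinkage and SUV decline (strong in responders, mild in
non-responders), and optional *planted effects*: requested Spearman
correlations between a named pipeline feature (e.g. ``pre_cov``,
``post_glcm_energy``) and a covariate.  Effects are realized through five
latent physical channels per patient — texture heterogeneity, texture
smoothness, relative noise level, focal-uptake strength (a hot spot), and a
shared tumor-size multiplier.  A least-squares solver distributes covariate
loadings over the channels using a Monte-Carlo-measured sensitivity matrix
(``_SENSITIVITY``), corrected for the physical response baselines
(``_BASELINE``) and the measured efficiency of the linearized model
(``_EFFICIENCY``); all three tables were calibrated once under the default
cohort conditions and frozen.

All randomness flows from one seeded generator per call with a documented
draw order, so identical (spec, seed) yields bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .errors import ConfigError, GeometryError
from .io import SUVVolume, write_volume
from .segmentation import VOIMask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "PlantedEffect",
    "GroundTruth",
    "PatientRecord",
    "CohortBundle",
    "generate_phantom",
    "generate_cohort",
    "planted_truth",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of a single synthetic tumor.

    Defaults emulate the acquisition geometry of a clinical whole-body PET
    reconstruction (4 x 4 mm in-plane voxels, 5 mm slice thickness) with a
    ~7 mm PSF, and a mid-range cervical primary tumor.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 26)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 5.0)
    tumor_center: tuple[float, float, float] | None = None  # mm; default mid-grid
    tumor_radii: tuple[float, float, float] = (16.0, 14.0, 15.0)  # ellipsoid semi-axes
    suv_peak: float = 12.0
    background_suv: float = 1.0
    heterogeneity_sd: float = 0.5  # SD of the multiplicative texture field
    texture_corr_len: float = 10.0  # mm
    blur_fwhm: float = 6.0  # mm
    noise_sd: float = 0.5  # additive SUV noise
    hotspot_factor: float = 1.0  # focal-uptake multiplier (1 = no hot spot)
    hotspot_radius_frac: float = 0.35  # hot-spot radius as fraction of tumor radii

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 2 for n in self.grid_shape):
            raise ConfigError(f"grid_shape must be 3 sizes >= 2, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigError("voxel spacing must be positive on every axis")
        if any(r <= 0 for r in self.tumor_radii):
            raise ConfigError("tumor radii must be positive")
        if not self.suv_peak > self.background_suv >= 0:
            raise ConfigError("require suv_peak > background_suv >= 0")
        if self.heterogeneity_sd < 0 or self.noise_sd < 0:
            raise ConfigError("heterogeneity_sd and noise_sd must be >= 0")
        if self.texture_corr_len <= 0 or self.blur_fwhm < 0:
            raise ConfigError("texture_corr_len must be > 0 and blur_fwhm >= 0")
        if self.hotspot_factor < 1 or not 0 < self.hotspot_radius_frac < 1:
            raise ConfigError(
                "hotspot_factor must be >= 1 and hotspot_radius_frac in (0, 1)"
            )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing))

    def center_mm(self) -> tuple[float, float, float]:
        if self.tumor_center is not None:
            return tuple(float(c) for c in self.tumor_center)
        return tuple(e / 2.0 for e in self.extent_mm)


class PlantedEffect(NamedTuple):
    """A target Spearman association between a pipeline feature and a covariate."""

    feature: str  # e.g. "pre_cov", "post_glcm_energy"
    covariate: str  # "age" | "response" | "recurrence"
    rho: float

    @property
    def sign(self) -> str:
        return "+" if self.rho > 0 else ("-" if self.rho < 0 else "0")


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic paired pre/post cohort.

    Default category proportions (FIGO 2/52/29, recurrence 45/13/25,
    regimen 77/3/2/1, age median ~55 range 24-76) mirror an 83-patient
    cervical-cancer chemotherapy cohort.  ``post_shrinkage`` and
    ``post_suv_decline`` are uniform ranges of the fractional MTV reduction
    and SUV decline applied to responders; non-responders get mild
    fluctuations around no change.
    """

    n_patients: int = 83
    seed: int = 0
    response_rate: float = 0.6
    recurrence_rates: tuple[float, float, float] = (45 / 83, 13 / 83, 25 / 83)
    age_range: tuple[int, int] = (24, 76)
    planted_effects: tuple = ()
    post_shrinkage: tuple[float, float] = (0.35, 0.65)
    post_suv_decline: tuple[float, float] = (0.25, 0.50)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError(f"cohort needs n_patients >= 2, got {self.n_patients}")
        if not 0 <= self.response_rate <= 1:
            raise ConfigError("response_rate must lie in [0, 1]")
        if any(not 0 <= r <= 1 for r in self.recurrence_rates) or not math.isclose(
            sum(self.recurrence_rates), 1.0, abs_tol=1e-9
        ):
            raise ConfigError("recurrence_rates must be fractions summing to 1")
        effects = tuple(PlantedEffect(*e) for e in self.planted_effects)
        object.__setattr__(self, "planted_effects", effects)
        seen = set()
        for e in effects:
            if abs(e.rho) >= 1:
                raise ConfigError(f"|target rho| must be < 1, got {e.rho}")
            key = (e.feature, e.covariate)
            if key in seen:
                raise ConfigError(f"duplicate planted effect for {key}")
            seen.add(key)
            _parse_effect_feature(e.feature)  # raises for undrivable features
            if e.covariate not in _COVARIATE_KIND:
                raise ConfigError(
                    f"cannot plant on covariate {e.covariate!r}; "
                    f"supported: {sorted(_COVARIATE_KIND)}"
                )


@dataclass
class GroundTruth:
    """What the generator actually put into a phantom volume."""

    true_mask: VOIMask
    true_mtv_cm3: float
    drivers: dict = field(default_factory=dict)


@dataclass
class PatientRecord:
    patient_id: str
    pre: SUVVolume
    post: SUVVolume
    pre_truth: GroundTruth
    post_truth: GroundTruth


@dataclass
class CohortBundle:
    """A generated cohort: volumes, clinical table, and planted ground truth."""

    spec: CohortSpec
    patients: list[PatientRecord]
    clinical: pd.DataFrame
    planted: pd.DataFrame
    drivers: pd.DataFrame


def _gaussian_field(white: np.ndarray, corr_len_mm: float, spacing) -> np.ndarray:
    """Standardized Gaussian random field with the given correlation length."""
    sigma_vox = [corr_len_mm / s for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[SUVVolume, GroundTruth]:
    """Generate one synthetic SUV tumor volume with ground truth.

    Draw order from the seeded generator: (1) texture white-noise field,
    (2) additive-noise field.  Both are always drawn so that changing
    amplitude parameters leaves the underlying noise realizations fixed.
    """
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape
    spacing = spec.voxel_spacing
    center = spec.center_mm()
    for c, r, e in zip(center, spec.tumor_radii, spec.extent_mm):
        if c - r < 0 or c + r > e:
            raise GeometryError(
                f"tumor (center {center} mm, radii {spec.tumor_radii} mm) "
                f"extends outside the {e:.0f} mm grid extent"
            )

    white = rng.standard_normal(shape)
    noise = rng.standard_normal(shape)

    axes = [
        ((np.arange(n) + 0.5) * s - c) / r
        for n, s, c, r in zip(shape, spacing, center, spec.tumor_radii)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    inside = zz**2 + yy**2 + xx**2 <= 1.0
    if not inside.any():
        raise GeometryError("tumor covers no voxel center at this resolution")

    vol = np.full(shape, float(spec.background_suv))
    if spec.heterogeneity_sd > 0:
        g = _gaussian_field(white, spec.texture_corr_len, spacing)
        s_log = math.sqrt(math.log1p(spec.heterogeneity_sd**2))
        mult = np.exp(s_log * g - 0.5 * s_log**2)
        vol[inside] = spec.suv_peak * mult[inside]
    else:
        vol[inside] = spec.suv_peak

    if spec.hotspot_factor > 1:
        # focal high-uptake subregion: a small ellipsoid offset from the
        # tumor center along a fixed diagonal, uptake multiplied by the
        # hotspot factor (before PSF blur)
        h_center = tuple(
            c + 0.45 * r / math.sqrt(3.0) for c, r in zip(center, spec.tumor_radii)
        )
        h_radii = tuple(spec.hotspot_radius_frac * r for r in spec.tumor_radii)
        h_axes = [
            ((np.arange(n) + 0.5) * s - c) / r
            for n, s, c, r in zip(shape, spacing, h_center, h_radii)
        ]
        hz, hy, hx = np.meshgrid(*h_axes, indexing="ij")
        hot = (hz**2 + hy**2 + hx**2 <= 1.0) & inside
        vol[hot] *= spec.hotspot_factor

    if spec.blur_fwhm > 0:
        sigma_vox = [spec.blur_fwhm * _FWHM_TO_SIGMA / s for s in spacing]
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        vol = vol + spec.noise_sd * noise
    vol = np.clip(vol, 0.0, None)

    mask = VOIMask(inside, spacing)
    truth = GroundTruth(
        true_mask=mask,
        true_mtv_cm3=mask.volume_mm3 / 1000.0,
        drivers=dict(
            heterogeneity_sd=spec.heterogeneity_sd,
            texture_corr_len=spec.texture_corr_len,
            noise_sd=spec.noise_sd,
            suv_peak=spec.suv_peak,
        ),
    )
    return SUVVolume(vol, spacing, provenance="raw-suv"), truth


# --- planted-effect machinery -------------------------------------------------

#: Per-timepoint latent channels (drawn pre then post) plus one shared
#: per-patient "size" channel that scales both timepoints' radii equally
#: (so planted size effects never invert the pre -> post shrinkage).
_CHANNELS = ("heterogeneity", "smoothness", "noise", "focality")
_SHARED_CHANNELS = ("size",)

_COVARIATE_KIND = {"age": "continuous", "response": "binary", "recurrence": "binary"}

#: Monte-Carlo-measured Spearman sensitivity of each extracted feature to a
#: unit latent shift in each channel, through the full pipeline (default
#: phantom geometry, default extraction settings, mixed pre/post sizes).
#: Frozen at package-build time; the planting solver inverts this matrix.
_SENSITIVITY: dict[str, dict[str, float]] = {
    "cov": {
        "heterogeneity": 0.52, "smoothness": -0.18, "noise": 0.10,
        "focality": 0.34, "size": -0.05,
    },
    "entropy_bits": {
        "heterogeneity": -0.10, "smoothness": 0.12, "noise": -0.05,
        "focality": -0.56, "size": 0.17,
    },
    "glcm_contrast": {
        "heterogeneity": 0.33, "smoothness": -0.13, "noise": 0.24,
        "focality": 0.23, "size": -0.47,
    },
    "glcm_correlation": {
        "heterogeneity": -0.13, "smoothness": 0.09, "noise": -0.29,
        "focality": -0.29, "size": 0.48,
    },
    "glcm_energy": {
        "heterogeneity": -0.25, "smoothness": 0.02, "noise": -0.15,
        "focality": 0.43, "size": 0.29,
    },
    "glcm_homogeneity": {
        "heterogeneity": -0.35, "smoothness": 0.11, "noise": -0.26,
        "focality": 0.17, "size": 0.44,
    },
}

#: Per-feature efficiency of the linearized planting model: the realized
#: Spearman rho is systematically below the sensitivity-matrix prediction
#: (channel cross-talk, rank nonlinearity); measured end-to-end by Monte
#: Carlo and frozen.  The solver divides its target by this factor.
_EFFICIENCY: dict[str, float] = {
    "cov": 0.80,
    "entropy_bits": 0.80,
    "glcm_contrast": 1.00,
    "glcm_correlation": 0.80,
    "glcm_energy": 0.75,
    "glcm_homogeneity": 0.64,
}

#: (full feature name, covariate) -> realized rho with no planting, from the
#: physical responder effects (shrinkage, SUV decline) alone.  Measured by
#: Monte Carlo on unplanted default cohorts; zero where not listed.
_BASELINE: dict[tuple[str, str], float] = {
    ("post_glcm_contrast", "response"): 0.09,
    ("post_glcm_correlation", "response"): -0.11,
    ("post_glcm_energy", "response"): -0.10,
    ("post_glcm_homogeneity", "response"): -0.10,
}

# channel -> (base value, log-scale gain per latent SD).  The noise base is
# relative to the tumor's peak SUV (PET noise grows with activity), so a
# post-therapy SUV decline does not masquerade as a texture change.  The
# focality channel sets the hot-spot uptake multiplier, and the shared size
# channel a radii multiplier (its latent is clipped so tumors stay on-grid).
_CHANNEL_BASE = {
    "heterogeneity": (0.5, 0.60),
    "smoothness": (10.0, 0.30),
    "noise": (0.05, 0.60),
}
_FOCALITY_BASE = (0.7, 0.80)  # hotspot_factor = 1 + base * exp(gain * d)
_SIZE_GAIN = 0.22  # radii multiplier = exp(gain * clip(d, -2.5, 2.5))


def _parse_effect_feature(name: str) -> tuple[str, str]:
    """Split a planted feature name into (timepoint, base feature)."""
    for tp in ("pre", "post"):
        prefix = tp + "_"
        if name.startswith(prefix):
            base = name[len(prefix):]
            if base == "entropy":
                base = "entropy_bits"
            if base not in _SENSITIVITY:
                raise ConfigError(
                    f"the generator cannot drive feature {name!r}; drivable: "
                    f"{sorted(_SENSITIVITY)}"
                )
            return tp, base
    raise ConfigError(
        f"planted feature {name!r} must be prefixed with 'pre_' or 'post_'"
    )


def planted_truth(cspec: CohortSpec) -> pd.DataFrame:
    """One row per planted effect with its expected sign and target rho."""
    rows = [
        dict(feature=e.feature, covariate=e.covariate, target_rho=e.rho, sign=e.sign)
        for e in cspec.planted_effects
    ]
    return pd.DataFrame(rows, columns=["feature", "covariate", "target_rho", "sign"])


def _covariate_rank_factor(covariate: str, cspec: CohortSpec) -> float:
    """Spearman attenuation from observing the covariate instead of its latent.

    A binary covariate cut from a normal latent at success probability p has
    rank correlation sqrt(3 p (1-p)) with the latent; a continuous covariate
    that is a monotone transform of the latent keeps essentially full rank
    correlation (0.99 allows for rounding ties).
    """
    kind = _COVARIATE_KIND[covariate]
    if kind == "continuous":
        return 0.99
    p = cspec.response_rate if covariate == "response" else 1.0 - cspec.recurrence_rates[0]
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.sqrt(3.0 * p * (1.0 - p))


def _effect_loadings(cspec: CohortSpec) -> dict:
    """Per-(timepoint, channel) list of (covariate, signed latent loading).

    For each covariate the targets of its planted effects (baseline-corrected
    and rank-factor-rescaled) are matched in the least-squares sense by
    loadings over the involved channels, using the frozen sensitivity matrix
    ``realized_f ~ rank_factor * sum_c S[f][c] * L[c]``.  Shared channels are
    keyed under timepoint ``"shared"``.
    """
    by_cov: dict[str, list[tuple[str, str, float]]] = {}
    for e in cspec.planted_effects:
        tp, base = _parse_effect_feature(e.feature)
        baseline = _BASELINE.get((e.feature, e.covariate), 0.0)
        target = (e.rho - baseline) / (
            _covariate_rank_factor(e.covariate, cspec) * _EFFICIENCY[base]
        )
        by_cov.setdefault(e.covariate, []).append((tp, base, target))

    loadings: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for covariate, effects in by_cov.items():
        cols: list[tuple[str, str]] = []
        for tp, base, _ in effects:
            for ch, s in _SENSITIVITY[base].items():
                key = ("shared", ch) if ch in _SHARED_CHANNELS else (tp, ch)
                if abs(s) >= 0.05 and key not in cols:
                    cols.append(key)
        A = np.zeros((len(effects), len(cols)))
        t = np.zeros(len(effects))
        for r, (tp, base, target) in enumerate(effects):
            t[r] = target
            for c, (ctp, ch) in enumerate(cols):
                if ctp == "shared" or ctp == tp:
                    A[r, c] = _SENSITIVITY[base].get(ch, 0.0)
        # ridge-regularized solve keeps loadings modest under collinearity
        lam = np.linalg.solve(A.T @ A + 0.02 * np.eye(len(cols)), A.T @ t)
        lam = np.clip(lam, -0.97, 0.97)
        for c, key in enumerate(cols):
            if abs(lam[c]) > 1e-9:
                loadings.setdefault(key, []).append((covariate, float(lam[c])))
    return loadings


def generate_cohort(
    cspec: CohortSpec,
    out_dir: str | Path | None = None,
    phantom_template: PhantomSpec | None = None,
) -> CohortBundle:
    """Generate a paired pre/post phantom cohort with clinical covariates.

    Draw order from the single seeded generator: (1) age latents,
    (2) response latents, (3) recurrence latents, (4) cycles, (5) regimen,
    (6) channel residuals (pre then post, channels in fixed order),
    (7) tumor geometry (size, anisotropy, center jitter, peak SUV),
    (8) shrinkage/decline uniforms, (9) per-volume child seeds.

    When ``out_dir`` is given, volumes are written as
    ``{patient_id}_pre.nii.gz`` / ``{patient_id}_post.nii.gz``, ground-truth
    masks as ``{patient_id}_{tp}_truthmask.nii.gz``, the clinical table as
    ``clinical.csv`` and the planted-truth table as ``planted_truth.csv``.
    """
    template = phantom_template or PhantomSpec()
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_patients

    # (1-3) covariate latents
    z_age = rng.standard_normal(n)
    z_resp = rng.standard_normal(n)
    z_rec = rng.standard_normal(n)
    lo_age, hi_age = cspec.age_range
    age = np.clip(np.round(54.0 + 12.0 * z_age), lo_age, hi_age).astype(int)
    responder = z_resp > norm.ppf(1.0 - cspec.response_rate)
    p_none, p_local, _ = cspec.recurrence_rates
    c1 = norm.ppf(p_none) if p_none > 0 else -np.inf
    c2 = norm.ppf(p_none + p_local) if p_none + p_local < 1 else np.inf
    recurrence = np.where(z_rec <= c1, "none", np.where(z_rec <= c2, "local", "distant"))
    figo = rng.choice(["IIIC1", "IIIC2", "IVB"], size=n, p=[2 / 83, 52 / 83, 29 / 83])
    cycles = rng.choice([6, 5, 4, 3, 7], size=n, p=[69 / 83, 7 / 83, 5 / 83, 1 / 83, 1 / 83])
    regimen = rng.choice(
        [
            "paclitaxel+cisplatin",
            "paclitaxel+carboplatin",
            "paclitaxel+carboplatin+bevacizumab",
            "etoposide+cisplatin",
        ],
        size=n,
        p=[77 / 83, 3 / 83, 2 / 83, 1 / 83],
    )

    cov_latent = {"age": z_age, "response": z_resp, "recurrence": z_rec}
    loadings = _effect_loadings(cspec)

    # (6) channel latents: pre channels, post channels, then shared channels
    channel_d: dict[tuple[str, str], np.ndarray] = {}
    for tp in ("pre", "post", "shared"):
        chans = _SHARED_CHANNELS if tp == "shared" else _CHANNELS
        for ch in chans:
            eps = rng.standard_normal(n)
            loads = loadings.get((tp, ch), [])
            total = sum(l**2 for _, l in loads)
            if total > 1.0:  # keep unit variance; rescale proportionally
                scale = 1.0 / math.sqrt(total)
                loads = [(c, l * scale) for c, l in loads]
                total = 1.0
            d = math.sqrt(max(0.0, 1.0 - total)) * eps
            for cov_name, lam in loads:
                d = d + lam * cov_latent[cov_name]
            channel_d[(tp, ch)] = d

    # (7) tumor geometry; the shared size channel multiplies the radii
    r0 = rng.uniform(17.0, 22.0, size=n)
    aniso = rng.uniform(0.85, 1.15, size=(n, 3))
    jitter = rng.uniform(-2.0, 2.0, size=(n, 3))
    suv_peak_pre = rng.uniform(8.0, 18.0, size=n)
    size_mult = np.exp(_SIZE_GAIN * np.clip(channel_d[("shared", "size")], -2.5, 2.5))
    r0 = r0 * size_mult  # pre MTV roughly 10-70 cm^3

    # (8) response to therapy; non-responders also change mildly
    u_shrink = rng.uniform(size=n)
    u_decline = rng.uniform(size=n)
    s_lo, s_hi = cspec.post_shrinkage
    q_lo, q_hi = cspec.post_suv_decline
    shrink = np.where(
        responder, s_lo + u_shrink * (s_hi - s_lo), 0.10 + u_shrink * 0.30
    )
    decline = np.where(
        responder, q_lo + u_decline * (q_hi - q_lo), 0.05 + u_decline * 0.20
    )
    shrink = np.clip(shrink, -0.30, 0.90)

    # (9) per-volume child seeds
    child_seeds = rng.integers(0, 2**31 - 1, size=(n, 2))

    def channel_value(tp: str, ch: str, i: int, peak: float = 1.0) -> float:
        base, gain = _CHANNEL_BASE[ch]
        scale = peak if ch == "noise" else 1.0
        return float(scale * base * math.exp(gain * channel_d[(tp, ch)][i]))

    center0 = template.center_mm()
    patients: list[PatientRecord] = []
    driver_rows = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        radii_pre = tuple(r0[i] * aniso[i])
        center = tuple(c + j for c, j in zip(center0, jitter[i]))
        scale_post = float((1.0 - shrink[i]) ** (1.0 / 3.0))
        suv_post = max(3.0, float(suv_peak_pre[i] * (1.0 - decline[i])))
        vols = {}
        truths = {}
        for k, tp in enumerate(("pre", "post")):
            radii = radii_pre if tp == "pre" else tuple(r * scale_post for r in radii_pre)
            fb, fg = _FOCALITY_BASE
            spec_i = replace(
                template,
                tumor_center=center,
                tumor_radii=radii,
                suv_peak=float(suv_peak_pre[i]) if tp == "pre" else suv_post,
                heterogeneity_sd=channel_value(tp, "heterogeneity", i),
                texture_corr_len=channel_value(tp, "smoothness", i),
                noise_sd=channel_value(
                    tp, "noise", i,
                    peak=float(suv_peak_pre[i]) if tp == "pre" else suv_post,
                ),
                hotspot_factor=1.0
                + fb * math.exp(fg * float(channel_d[(tp, "focality")][i])),
            )
            vols[tp], truths[tp] = generate_phantom(spec_i, int(child_seeds[i, k]))
            driver_rows.append(
                dict(
                    patient_id=pid,
                    timepoint=tp,
                    heterogeneity_sd=spec_i.heterogeneity_sd,
                    texture_corr_len=spec_i.texture_corr_len,
                    noise_sd=spec_i.noise_sd,
                    hotspot_factor=spec_i.hotspot_factor,
                    size_mult=float(size_mult[i]),
                    suv_peak=spec_i.suv_peak,
                    true_mtv_cm3=truths[tp].true_mtv_cm3,
                )
            )
        patients.append(
            PatientRecord(pid, vols["pre"], vols["post"], truths["pre"], truths["post"])
        )

    clinical = pd.DataFrame(
        dict(
            patient_id=[p.patient_id for p in patients],
            age=age,
            figo=figo,
            response=np.where(responder, "responder", "non-responder"),
            recurrence=recurrence,
            cycles=cycles,
            regimen=regimen,
        )
    )
    bundle = CohortBundle(
        spec=cspec,
        patients=patients,
        clinical=clinical,
        planted=planted_truth(cspec),
        drivers=pd.DataFrame(driver_rows),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p in patients:
            write_volume(p.pre, out / f"{p.patient_id}_pre.nii.gz")
            write_volume(p.post, out / f"{p.patient_id}_post.nii.gz")
            for tp, truth in (("pre", p.pre_truth), ("post", p.post_truth)):
                mvol = SUVVolume(
                    truth.true_mask.mask.astype(np.float32),
                    truth.true_mask.voxel_spacing,
                )
                write_volume(mvol, out / f"{p.patient_id}_{tp}_truthmask.nii.gz")
        clinical.to_csv(out / "clinical.csv", index=False)
        bundle.planted.to_csv(out / "planted_truth.csv", index=False)
        bundle.drivers.to_csv(out / "truth_drivers.csv", index=False)
    return bundle
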