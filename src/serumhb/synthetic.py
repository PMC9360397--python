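"""Synthetic serum-colour data generator.

Emulates the graded-haemolysis study design: each animal's serum is split
into subsamples spiked to known haemolysed fractions, and each specimen is
characterised by a reference haemoglobin concentration (g/L), an absorbance
at 540 nm, and mean R/G/B channel values extracted from a photograph of the
cuvette.  Forward models are simple calibration lines plus Gaussian noise;
the noise level is solved in closed form so that a simulated calibration
set reproduces a requested Pearson correlation in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

__all__ = [
    "STUDY_FRACTIONS",
    "SAMPLE_TABLE_COLUMNS",
    "ForwardModelParams",
    "StudyDesign",
    "SerumSample",
    "generate_design",
    "serum_hb",
    "absorbance_forward",
    "noise_sd_for_target_r",
    "rgb_forward",
    "render_patch",
    "generate_samples",
    "generate_replicates",
    "write_samples",
    "read_samples",
]

#: Haemolysed fractions used in the original study design (0% ... 10%).
STUDY_FRACTIONS: tuple[float, ...] = (0.0, 0.002, 0.005, 0.010, 0.025, 0.050, 0.100)

#: Column order of the sample table (the 70 x 7 data-matrix analogue plus ids).
SAMPLE_TABLE_COLUMNS = [
    "sample_id",
    "animal_id",
    "fraction",
    "hb_ref",
    "absorbance540",
    "r_mean",
    "g_mean",
    "b_mean",
    "intensity",
]

# Rec.601 luma weights; shared with image_rgb.weighted_intensity.
_INTENSITY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class ForwardModelParams:
    """Constants of the signal forward models.

    The absorbance and Redbance lines default to the published calibration
    coefficients; G and B channels follow weak invented trends so that they
    are only loosely correlated with haemoglobin.
    """

    abs_intercept: float = 0.1051          # absorbance units
    abs_slope: float = 0.0873              # absorbance per g/L
    red_intercept: float = 0.0929          # Redbance units
    red_slope: float = 0.0187              # Redbance per g/L
    target_r_abs: float = 0.991
    target_r_red: float = 0.983
    g_intercept: float = 185.0             # channel units
    g_slope: float = -0.5                  # channel per g/L
    g_noise_sd: float = 7.0                # total G noise budget, channel units
    b_intercept: float = 125.0
    b_slope: float = -0.2
    b_noise_sd: float = 4.0                # total B noise budget, channel units
    # Fraction of the Redbance-scale noise VARIANCE that is a common
    # illumination/exposure factor multiplying all three channels; it is
    # what lets multivariate calibration outperform the univariate R-channel
    # route, as observed in practice.  The remainder is R-specific.
    illumination_share: float = 0.9
    baseline_free_hb_sd: float = 0.02      # g/L, blank free-Hb variability
    # Repeatability noise used for replicate/blank specimens (much smaller
    # than the between-sample calibration scatter implied by target_r_*).
    replicate_abs_noise_sd: float = 0.005  # absorbance units
    replicate_red_noise_sd: float = 0.003  # Redbance units
    # G/B noise budgets shrink by this factor for replicate specimens
    replicate_channel_noise_scale: float = 0.25

    def __post_init__(self) -> None:
        if self.abs_slope <= 0 or self.red_slope <= 0:
            raise ValueError("calibration slopes must be positive")
        for r in (self.target_r_abs, self.target_r_red):
            if not (0.0 < r < 1.0):
                raise ValueError(f"target correlation {r} not in (0, 1)")
        if not (0.0 <= self.illumination_share <= 1.0):
            raise ValueError("illumination_share must lie in [0, 1]")


@dataclass(frozen=True)
class StudyDesign:
    """A crossed design: every animal contributes one specimen per fraction."""

    animal_ids: tuple[str, ...]
    blood_hb_per_animal: tuple[float, ...]  # g/L whole-blood Hb
    haemolysis_fractions: tuple[float, ...]
    seed: int
    blood_hb_bounds: tuple[float, float] = (80.0, 140.0)

    def __post_init__(self) -> None:
        if len(self.animal_ids) != len(self.blood_hb_per_animal):
            raise ValueError("one blood Hb value per animal is required")
        lo, hi = self.blood_hb_bounds
        for hb in self.blood_hb_per_animal:
            if not (lo <= hb <= hi):
                raise ValueError(f"blood Hb {hb} outside bounds [{lo}, {hi}]")
        fr = self.haemolysis_fractions
        if list(fr) != sorted(fr):
            raise ValueError("fractions must be sorted ascending")
        if any(f < 0.0 or f > 0.1 for f in fr):
            raise ValueError("fractions must lie in [0, 0.1]")

    @property
    def n_samples(self) -> int:
        return len(self.animal_ids) * len(self.haemolysis_fractions)


@dataclass(frozen=True)
class SerumSample:
    """One graded-haemolysis specimen with every measured signal."""

    sample_id: str
    animal_id: str
    fraction: float
    hb_ref: float
    absorbance540: float
    r_mean: float
    g_mean: float
    b_mean: float
    intensity: float

    def __post_init__(self) -> None:
        if self.hb_ref < 0:
            raise ValueError("hb_ref must be non-negative")
        if self.absorbance540 < 0:
            raise ValueError("absorbance must be non-negative")
        for name in ("r_mean", "g_mean", "b_mean", "intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name}={v} outside [0, 255]")


def generate_design(
    n_animals: int,
    fractions=STUDY_FRACTIONS,
    seed: int = 42,
    blood_hb_mean: float = 110.0,
    blood_hb_sd: float = 15.0,
    blood_hb_bounds: tuple[float, float] = (80.0, 140.0),
) -> StudyDesign:
    """Draw per-animal whole-blood Hb and build the crossed design.

    Blood Hb is sampled from a truncated normal so every value stays within
    physiological bounds; the draw is deterministic for a given seed.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be at least 1")
    fractions = tuple(sorted(float(f) for f in fractions))
    if not fractions:
        raise ValueError("at least one haemolysis fraction is required")
    for f in fractions:
        if f < 0.0 or f > 0.1:
            raise ValueError(f"haemolysis fraction {f} outside [0, 0.1]")
    rng = np.random.default_rng(seed)
    lo, hi = blood_hb_bounds
    a = (lo - blood_hb_mean) / blood_hb_sd
    b = (hi - blood_hb_mean) / blood_hb_sd
    blood_hb = stats.truncnorm.rvs(
        a, b, loc=blood_hb_mean, scale=blood_hb_sd, size=n_animals, random_state=rng
    )
    animal_ids = tuple(f"cow{i + 1:02d}" for i in range(n_animals))
    return StudyDesign(
        animal_ids=animal_ids,
        blood_hb_per_animal=tuple(float(h) for h in blood_hb),
        haemolysis_fractions=fractions,
        seed=seed,
        blood_hb_bounds=blood_hb_bounds,
    )


def serum_hb(blood_hb: float, fraction: float, rng=None, baseline_sd: float = 0.0) -> float:
    """Serum Hb of a spiked specimen: fraction x whole-blood Hb plus a small
    non-negative baseline free-Hb term (clipped at zero)."""
    if blood_hb <= 0:
        raise ValueError("blood_hb must be positive")
    if not (0.0 <= fraction <= 0.1):
        raise ValueError("fraction must lie in [0, 0.1]")
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be non-negative")
    baseline = 0.0
    if baseline_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        baseline = max(0.0, float(rng.normal(0.0, baseline_sd)))
    return fraction * blood_hb + baseline


def absorbance_forward(hb, params: ForwardModelParams, noise_sd: float = 0.0, rng=None):
    """Absorbance at 540 nm from the calibration line plus Gaussian noise,
    clipped at zero.  Accepts scalars or arrays."""
    hb = np.asarray(hb, dtype=float)
    if np.any(hb < 0):
        raise ValueError("hb must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    signal = params.abs_intercept + params.abs_slope * hb
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    out = np.clip(signal, 0.0, None)
    return float(out) if out.ndim == 0 else out


def noise_sd_for_target_r(slope: float, hb_values, target_r: float) -> float:
    """Gaussian noise level that makes the simulated signal correlate with
    Hb at ``target_r`` in expectation: sigma = |slope| * SD(hb) * sqrt(1/r^2 - 1)."""
    if not (0.0 < target_r < 1.0):
        raise ValueError("target_r must lie in (0, 1)")
    hb = np.asarray(hb_values, dtype=float)
    sd = float(np.std(hb))
    if sd == 0.0:
        raise ValueError("hb_values must have nonzero variance")
    return abs(slope) * sd * np.sqrt(1.0 / target_r**2 - 1.0)


def rgb_forward(hb, params: ForwardModelParams, red_noise_sd: float = 0.0, rng=None):
    """Channel means for a serum specimen.

    The R channel is derived by inverting the Redbance line; noise of total
    SD ``red_noise_sd`` is injected on the Redbance scale so the published
    line is the recoverable truth.  A share of that noise variance
    (``params.illumination_share``) is a common exposure factor that
    multiplies all three channels; G and B additionally follow weak linear
    trends with their own noise so that neither correlates with Hb beyond
    ~0.5.  All channels are clamped to [1, 255].
    """
    hb = np.asarray(hb, dtype=float)
    if np.any(hb < 0):
        raise ValueError("hb must be non-negative")
    if red_noise_sd < 0:
        raise ValueError("red_noise_sd must be non-negative")
    noisy = red_noise_sd > 0 or rng is not None
    if rng is None and noisy:
        rng = np.random.default_rng()
    n = hb.shape if hb.ndim else ()
    common = np.zeros(n)
    sd_common = np.sqrt(params.illumination_share) * red_noise_sd
    sd_specific = np.sqrt(max(red_noise_sd**2 - sd_common**2, 0.0))
    redbance = params.red_intercept + params.red_slope * hb
    if red_noise_sd > 0:
        common = rng.normal(0.0, sd_common, size=n)
        redbance = redbance + common + rng.normal(0.0, sd_specific, size=n)
    r = np.clip(256.0 * 10.0 ** (-redbance), 1.0, 255.0)
    # G/B noise budgets are totals: the common factor's contribution is
    # subtracted (in variance) from the channel-specific part.
    g_trend = params.g_intercept + params.g_slope * hb
    b_trend = params.b_intercept + params.b_slope * hb
    ln10 = np.log(10.0)
    g = g_trend * 10.0 ** (-common)
    b = b_trend * 10.0 ** (-common)
    if noisy:
        g_common_sd = params.g_intercept * ln10 * sd_common
        b_common_sd = params.b_intercept * ln10 * sd_common
        g_specific = np.sqrt(max(params.g_noise_sd**2 - g_common_sd**2, 0.0))
        b_specific = np.sqrt(max(params.b_noise_sd**2 - b_common_sd**2, 0.0))
        g = g + rng.normal(0.0, g_specific, size=np.shape(g))
        b = b + rng.normal(0.0, b_specific, size=np.shape(b))
    g = np.clip(g, 1.0, 255.0)
    b = np.clip(b, 1.0, 255.0)
    if r.ndim == 0:
        return float(r), float(g), float(b)
    return r, g, b


def render_patch(rgb, size: int, pixel_noise_sd: float = 0.0, seed: int = 0, path=None):
    """Write a lossless PNG patch of a uniform colour with per-pixel noise.

    The extracted ROI mean of the written image stays within the standard
    error of the requested channel means.  Returns the path written.
    """
    r, g, b = rgb
    for v in (r, g, b):
        if not (0.0 <= v <= 255.0):
            raise ValueError(f"channel mean {v} outside [0, 255]")
    if size < 1:
        raise ValueError("size must be at least 1 pixel")
    if path is None:
        raise ValueError("an output path is required")
    rng = np.random.default_rng(seed)
    pixels = np.empty((size, size, 3), dtype=float)
    pixels[..., 0], pixels[..., 1], pixels[..., 2] = r, g, b
    if pixel_noise_sd > 0:
        pixels += rng.normal(0.0, pixel_noise_sd, size=pixels.shape)
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    path = Path(path)
    Image.fromarray(pixels, mode="RGB").save(path, format="PNG")
    return path


def _weighted_intensity(r, g, b):
    wr, wg, wb = _INTENSITY_WEIGHTS
    return wr * np.asarray(r) + wg * np.asarray(g) + wb * np.asarray(b)


def generate_samples(
    design: StudyDesign, params: ForwardModelParams | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Simulate all signals for a design and return the sample table.

    Noise levels for absorbance and Redbance are solved from the target
    correlations against the realised serum Hb values of the design, so a
    fitted calibration on this table recovers the published lines.
    """
    params = params or ForwardModelParams()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    hb_values = []
    for animal, blood in zip(design.animal_ids, design.blood_hb_per_animal):
        for frac in design.haemolysis_fractions:
            hb = serum_hb(blood, frac, rng=rng, baseline_sd=params.baseline_free_hb_sd)
            rows.append((f"{animal}-h{int(round(frac * 1000)):03d}", animal, frac, hb))
            hb_values.append(hb)
    hb = np.asarray(hb_values)
    sd_abs = noise_sd_for_target_r(params.abs_slope, hb, params.target_r_abs)
    sd_red = noise_sd_for_target_r(params.red_slope, hb, params.target_r_red)
    absorbance = absorbance_forward(hb, params, noise_sd=sd_abs, rng=rng)
    r, g, b = rgb_forward(hb, params, red_noise_sd=sd_red, rng=rng)
    frame = pd.DataFrame(rows, columns=["sample_id", "animal_id", "fraction", "hb_ref"])
    frame["absorbance540"] = absorbance
    frame["r_mean"] = r
    frame["g_mean"] = g
    frame["b_mean"] = b
    frame["intensity"] = _weighted_intensity(r, g, b)
    return frame[SAMPLE_TABLE_COLUMNS]


def generate_replicates(
    hb_level: float,
    n: int,
    params: ForwardModelParams | None = None,
    seed: int = 42,
) -> pd.DataFrame:
    """Simulate ``n`` replicate specimens at a fixed Hb level.

    Signals carry only the repeatability noise (replicate_*_noise_sd), the
    appropriate scale for precision and blank determinations; hb_ref keeps
    the baseline free-Hb variability so blanks have a nonzero spread.
    """
    if hb_level < 0:
        raise ValueError("hb_level must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    params = params or ForwardModelParams()
    rng = np.random.default_rng(seed)
    baseline = np.clip(rng.normal(0.0, params.baseline_free_hb_sd, size=n), 0.0, None)
    hb = hb_level + baseline
    absorbance = absorbance_forward(hb, params, noise_sd=params.replicate_abs_noise_sd, rng=rng)
    scale = params.replicate_channel_noise_scale
    rep_params = dataclasses.replace(
        params,
        g_noise_sd=scale * params.g_noise_sd,
        b_noise_sd=scale * params.b_noise_sd,
    )
    r, g, b = rgb_forward(hb, rep_params, red_noise_sd=params.replicate_red_noise_sd, rng=rng)
    frame = pd.DataFrame(
        {
            "sample_id": [f"rep-{hb_level:g}-{i + 1:02d}" for i in range(n)],
            "animal_id": "replicate",
            "fraction": np.nan,
            "hb_ref": hb,
            "absorbance540": absorbance,
            "r_mean": r,
            "g_mean": g,
            "b_mean": b,
            "intensity": _weighted_intensity(r, g, b),
        }
    )
    return frame[SAMPLE_TABLE_COLUMNS]


def write_samples(frame: pd.DataFrame, path) -> None:
    """Write the sample table as UTF-8 CSV with the canonical header."""
    frame[SAMPLE_TABLE_COLUMNS].to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    return frame[SAMPLE_TABLE_COLUMNS]
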