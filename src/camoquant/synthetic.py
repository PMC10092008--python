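"""Synthetic study inputs: textures, scenes, spectra, receptor sets and
predation event tables.

Everything the analysis chain consumes can be generated here with fixed
seeds, emulating the study conditions of a lichen-moth field experiment:

* **lichen / moth textures** — high-contrast two-tone blotch fields
  (thresholded low-pass-filtered Gaussian random fields) with a
  controllable characteristic pattern scale; the moth's wing pattern is
  lichen-like by default.
* **bark textures** — the same construction vertically stretched
  (striated) and at low contrast.
* **scenes** — an elliptical moth patch (22 mm span at 10 px/mm by
  default) composited onto a background texture, expanded into
  receptor catch channels through per-channel affine maps, with a
  0/1/2 label mask.
* **predation data** — exponential attack hazards per treatment,
  observed only at 24/48/72 h checks and right-censored at 72 h, with
  100 replicates per treatment by default.
* **receptor sets** — Gaussian-shaped sensitivities; the default is a
  blue-tit-like approximation (λmax 372/449/502/563 nm plus a broad
  double cone).  These are stand-ins: real sensitivity curves, cone
  abundances and Weber fractions are species measurements the
  generator does not reproduce.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import DomainError, UsageError
from .rnl import DEFAULT_REFERENCE_WEBER, weber_fractions
from .spectra import (
    LABEL_ANIMAL,
    LABEL_BACKGROUND,
    CatchImage,
    ReceptorSet,
    Spectrum,
)

TEXTURE_CLASSES = ("lichen", "bark", "moth")


@dataclass(frozen=True)
class TextureConfig:
    """Parameters of a two-tone random texture.

    ``scale_px`` is the characteristic blotch/striation period in
    pixels, ``contrast`` the separation of the two tones around 0.5
    (0–1), ``anisotropy`` a vertical stretch factor (bark striations),
    and ``speckle`` the residual noise amplitude relative to contrast.
    """

    kind: str
    scale_px: float = 32.0
    contrast: float = 0.8
    anisotropy: float = 1.0
    speckle: float = 0.03
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_CLASSES:
            raise UsageError(f"texture class must be one of {TEXTURE_CLASSES}")
        if self.scale_px < 2:
            raise DomainError("characteristic scale must be at least 2 px")
        if not 0.0 <= self.contrast <= 1.0:
            raise DomainError("contrast must lie in [0, 1]")
        if self.anisotropy < 1.0:
            raise DomainError("anisotropy must be >= 1")


def texture_defaults(kind: str, seed: int | None = None) -> TextureConfig:
    """Study-condition texture presets.

    Lichen is a coarse, high-contrast blotch field; the moth wing is the
    same class at slightly higher contrast (high-contrast black and
    white pattern); bark is finer, low contrast and vertically striated.
    """
    if kind == "lichen":
        return TextureConfig("lichen", scale_px=32.0, contrast=0.8, seed=seed)
    if kind == "moth":
        return TextureConfig("moth", scale_px=32.0, contrast=0.9, seed=seed)
    if kind == "bark":
        return TextureConfig("bark", scale_px=12.0, contrast=0.3, anisotropy=4.0, seed=seed)
    raise UsageError(f"texture class must be one of {TEXTURE_CLASSES}")


def gen_texture(cfg: TextureConfig, size, seed: int | None = None) -> np.ndarray:
    """Generate a single-channel texture in [0, 1].

    A Gaussian random field is low-pass filtered at the characteristic
    scale (σ = scale/2π so the octave pattern-energy spectrum of the
    thresholded field peaks near ``scale_px``), thresholded at its
    median into two tones 0.5 ± contrast/2, and dusted with residual
    speckle proportional to the contrast (so zero contrast yields an
    exactly constant field).  Bark fields are smoothed anisotropically
    (σ_vertical = anisotropy · σ) to produce vertical striations.
    """
    if np.ndim(size) == 0:
        size = (int(size), int(size))
    size = tuple(int(s) for s in size)
    if min(size) < 4 * cfg.scale_px:
        raise UsageError(
            f"image size {size} must be at least 4× the characteristic scale {cfg.scale_px}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    field = rng.standard_normal(size)
    sigma = cfg.scale_px / (2.0 * np.pi)
    sigmas = (sigma * cfg.anisotropy, sigma)
    smooth = gaussian_filter(field, sigmas, mode="wrap")
    two_tone = np.where(
        smooth > np.median(smooth), 0.5 + cfg.contrast / 2.0, 0.5 - cfg.contrast / 2.0
    )
    noise_amp = cfg.speckle * cfg.contrast
    tex = two_tone + noise_amp * rng.standard_normal(size)
    return np.clip(tex, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Receptor sets and spectra
# ---------------------------------------------------------------------------

#: blue-tit-like single-cone peaks (uv, sw, mw, lw) in nm — an
#: approximation; no real sensitivity data are reproduced here
DEFAULT_LAMBDA_MAX = (372.0, 449.0, 502.0, 563.0)
DEFAULT_WIDTHS = (28.0, 32.0, 36.0, 40.0)
#: relative cone abundances for the chromatic channels
DEFAULT_ABUNDANCES = (1.0, 1.92, 2.68, 2.7)
DEFAULT_NAMES = ("uv", "sw", "mw", "lw")


def gen_receptor_set(
    lambda_max=DEFAULT_LAMBDA_MAX,
    widths=DEFAULT_WIDTHS,
    abundances=DEFAULT_ABUNDANCES,
    names=DEFAULT_NAMES,
    reference_weber: float = DEFAULT_REFERENCE_WEBER,
    luminance_peak_nm: float = 560.0,
    luminance_width_nm: float = 90.0,
    luminance_name: str = "dbl",
    luminance_weber: float | None = None,
    lo: float = 300.0,
    hi: float = 700.0,
) -> ReceptorSet:
    """Gaussian-sensitivity receptor set plus a broad luminance channel.

    Weber fractions for the chromatic channels follow the abundance
    scaling ω_i = ν·sqrt(η_max/η_i); the luminance (double-cone)
    channel gets ``luminance_weber`` (default: the reference ν).
    """
    names = tuple(names)
    if len(set(names + (luminance_name,))) != len(names) + 1:
        raise UsageError("receptor names (incl. luminance channel) must be unique")
    if not (len(lambda_max) == len(widths) == len(abundances) == len(names)):
        raise UsageError("lambda_max, widths, abundances and names must align")
    for lm in lambda_max:
        if not lo < lm < hi:
            raise DomainError(f"λmax {lm} outside spectrum support [{lo}, {hi}]")
    webers = weber_fractions(abundances, reference_weber)
    sens = {
        n: Spectrum.gaussian(lm, w, lo=lo, hi=hi)
        for n, lm, w in zip(names, lambda_max, widths)
    }
    sens[luminance_name] = Spectrum.gaussian(luminance_peak_nm, luminance_width_nm, lo=lo, hi=hi)
    return ReceptorSet(
        names=names + (luminance_name,),
        sensitivities=sens,
        abundances={**dict(zip(names, map(float, abundances)))},
        weber={
            **dict(zip(names, map(float, webers))),
            luminance_name: float(
                reference_weber if luminance_weber is None else luminance_weber
            ),
        },
        luminance_channel=luminance_name,
    )


def flat_illuminant(lo: float = 300.0, hi: float = 700.0) -> Spectrum:
    return Spectrum.flat(1.0, lo, hi, kind="irradiance")


def daylight_illuminant(lo: float = 300.0, hi: float = 700.0) -> Spectrum:
    """A smooth daylight-like irradiance curve (broad, slightly blue-
    depleted in the UV) — synthetic, not a CIE standard."""
    wl = np.arange(lo, hi + 0.5, 1.0)
    vals = 0.6 + 0.5 * np.exp(-0.5 * ((wl - 560.0) / 180.0) ** 2) - 0.25 * np.exp(
        -0.5 * ((wl - 320.0) / 60.0) ** 2
    )
    return Spectrum(wl, np.clip(vals, 1e-3, None), kind="irradiance")


def smooth_reflectance(
    rng: np.random.Generator,
    n_bumps: int = 3,
    lo: float = 300.0,
    hi: float = 700.0,
) -> Spectrum:
    """Random smooth reflectance: a baseline plus Gaussian bumps,
    rescaled into (0.05, 0.95)."""
    wl = np.arange(lo, hi + 0.5, 1.0)
    vals = np.full_like(wl, rng.uniform(0.2, 0.5))
    for _ in range(n_bumps):
        centre = rng.uniform(lo + 30, hi - 30)
        width = rng.uniform(25, 90)
        vals += rng.uniform(-0.3, 0.5) * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    span = vals.max() - vals.min()
    if span > 0:
        vals = 0.05 + 0.9 * (vals - vals.min()) / span
    return Spectrum(wl, vals, kind="reflectance")


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

#: per-channel affine expansion of the grey texture into catch channels;
#: slopes differ so the channels are not degenerate copies
_CHANNEL_GAIN = {"uv": 0.55, "sw": 0.70, "mw": 0.85, "lw": 0.95, "dbl": 0.90}
#: sign pattern of the chromatic offset applied to the moth region
_OFFSET_SIGN = {"uv": 1.0, "sw": -1.0, "mw": 1.0, "lw": -1.0, "dbl": 0.0}


def gen_scene(
    moth_cfg: TextureConfig | None = None,
    bg_cfg: TextureConfig | None = None,
    size=(384, 384),
    moth_span_mm: float = 22.0,
    moth_aspect: float = 0.55,
    scale_px_per_mm: float = 10.0,
    receptors: ReceptorSet | None = None,
    chromatic_offset: float = 0.0,
    luminance_offset: float = 0.0,
    seed: int | None = None,
) -> tuple[CatchImage, np.ndarray]:
    """Composite a moth-shaped texture patch onto a background.

    The moth is an ellipse whose major axis equals the resting wingspan
    (22 mm by default, i.e. 220 px at 10 px/mm).  The grey textures are
    expanded into one channel per receptor by per-channel affine maps;
    ``chromatic_offset`` multiplies the moth region by (1 ± offset) with
    alternating sign across chromatic channels (luminance untouched) and
    ``luminance_offset`` scales the moth's luminance channel, so colour
    and brightness mismatch are controllable independently of pattern;
    with both zero the moth differs from its background in pattern only.
    When the moth and background texture configs are identical the moth
    patch reuses the background realization, giving a perfectly matched
    (invisible) target.
    Returns the catch image and a label mask (1 = moth, 2 = background).
    """
    if np.ndim(size) == 0:
        size = (int(size), int(size))
    h, w = (int(s) for s in size)
    recs = receptors if receptors is not None else gen_receptor_set()
    ss = np.random.SeedSequence(seed)
    seed_moth, seed_bg = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    moth_cfg = moth_cfg if moth_cfg is not None else texture_defaults("moth")
    bg_cfg = bg_cfg if bg_cfg is not None else texture_defaults("lichen")

    major_px = moth_span_mm * scale_px_per_mm
    minor_px = moth_aspect * major_px
    if major_px > w or minor_px > h:
        raise UsageError(
            f"moth ({major_px:.0f}×{minor_px:.0f} px) does not fit in scene {size}"
        )
    bg_tex = gen_texture(bg_cfg, (h, w), seed=seed_bg)
    if replace(moth_cfg, seed=None) == replace(bg_cfg, seed=None):
        # identical texture specs: the moth patch is a continuation of the
        # background field (perfect pattern match by construction)
        moth_tex = bg_tex
    else:
        moth_tex = gen_texture(moth_cfg, (h, w), seed=seed_moth)
    yy, xx = np.mgrid[0:h, 0:w]
    inside = (
        ((xx - (w - 1) / 2.0) / (major_px / 2.0)) ** 2
        + ((yy - (h - 1) / 2.0) / (minor_px / 2.0)) ** 2
    ) <= 1.0
    grey = np.where(inside, moth_tex, bg_tex)
    mask = np.where(inside, LABEL_ANIMAL, LABEL_BACKGROUND).astype(int)

    channels: dict[str, np.ndarray] = {}
    for name in recs.names:
        gain = _CHANNEL_GAIN.get(name, 0.8)
        # multiplicative per-channel map: with zero offsets every channel is
        # the same function of grey up to scale, so log contrasts agree
        # across channels and the chromatic signal is exactly zero
        ch = gain * (0.06 + grey)
        sign = _OFFSET_SIGN.get(name, 1.0)
        if name != recs.luminance_channel and chromatic_offset != 0.0:
            ch = np.where(inside, ch * (1.0 + sign * chromatic_offset), ch)
        if name == recs.luminance_channel and luminance_offset != 0.0:
            ch = np.where(inside, ch * (1.0 + luminance_offset), ch)
        channels[name] = np.clip(ch, 1e-4, None)
    return CatchImage(channels, scale_px_per_mm, recs), mask


# ---------------------------------------------------------------------------
# Predation data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredationSimConfig:
    """Exponential-hazard predation experiment observed at fixed checks.

    ``hazards`` maps treatment → attack rate in events per hour.
    Defaults mirror a field design of 100 replicates per treatment
    checked at 24/48/72 h with right-censoring at 72 h.
    """

    hazards: dict[str, float]
    n_per_treatment: int = 100
    check_times: tuple[float, ...] = (24.0, 48.0, 72.0)
    end_time: float = 72.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.hazards:
            raise UsageError("at least one treatment hazard is required")
        for trt, h in self.hazards.items():
            if h < 0:
                raise DomainError(f"hazard for {trt!r} must be nonnegative")
        checks = tuple(float(t) for t in self.check_times)
        if any(b <= a for a, b in zip(checks, checks[1:])) or checks[0] <= 0:
            raise DomainError("check times must be positive and increasing")
        object.__setattr__(self, "check_times", checks)
        if self.n_per_treatment < 1:
            raise DomainError("n_per_treatment must be positive")


def hazard_for_event_fraction(fraction: float, end_time: float = 72.0) -> float:
    """Exponential rate giving the requested event probability by
    ``end_time`` (the inverse of 1 − exp(−λT))."""
    if not 0.0 <= fraction < 1.0:
        raise DomainError("event fraction must lie in [0, 1)")
    return -np.log(1.0 - fraction) / end_time


def gen_predation_dataset(cfg: PredationSimConfig) -> pd.DataFrame:
    """Simulate an interval-checked predation event table.

    True attack times are exponential; an attack is recorded at the
    first check time ≥ the true time (status 1), otherwise the
    replicate is censored at the end of the study (status 0).
    """
    rng = np.random.default_rng(cfg.seed)
    checks = np.asarray(cfg.check_times)
    rows = []
    for trt in sorted(cfg.hazards):
        lam = cfg.hazards[trt]
        if lam > 0:
            true_t = rng.exponential(1.0 / lam, size=cfg.n_per_treatment)
        else:
            true_t = np.full(cfg.n_per_treatment, np.inf)
        for i, t in enumerate(true_t):
            hit = checks[checks >= t]
            if t <= cfg.end_time and len(hit):
                rows.append((f"{trt}_{i:03d}", trt, float(hit[0]), 1))
            else:
                rows.append((f"{trt}_{i:03d}", trt, float(cfg.end_time), 0))
    return pd.DataFrame(rows, columns=["replicate_id", "treatment", "time_h", "status"])
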