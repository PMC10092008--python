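"""Spectra, receptor sets and quantum-catch computation.

The vision-model inputs are wavelength-indexed functions: stimulus
reflectance R(λ), illuminant irradiance I(λ) and receptor spectral
sensitivities S_i(λ).  The photon signal of receptor *i* viewing a
stimulus (its *quantum catch*) is

    Q_i = ∫ R(λ) I(λ) S_i(λ) dλ

computed here by the trapezoid rule on a common 1-nm grid.  With
von Kries adaptation each Q_i is divided by the catch of a perfect
white reflector (R ≡ 1) under the same illuminant, which makes catches
invariant to any rescaling of the illuminant — the normalisation that
lets field images taken under different skies be compared.

Catch *images* carry one 2-D array per receptor plus a physical pixel
scale, and regions of interest are integer label images using the
convention 0 = ignore, 1 = animal, 2 = background sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateCatchError,
    DimensionError,
    DomainError,
    RangeError,
    UsageError,
)

SPECTRUM_KINDS = ("reflectance", "irradiance", "sensitivity")

#: ROI label conventions
LABEL_IGNORE = 0
LABEL_ANIMAL = 1
LABEL_BACKGROUND = 2


@dataclass(frozen=True)
class Spectrum:
    """A nonnegative function of wavelength sampled at increasing points.

    Parameters
    ----------
    wavelengths_nm :
        Strictly increasing sample wavelengths in nanometres.
    values :
        Nonnegative values, one per wavelength.
    kind :
        One of ``reflectance``, ``irradiance`` or ``sensitivity``.
    allow_above_unity :
        Reflectance normally lies in [0, 1]; measurements scaled against
        a white standard may exceed 1 and must say so explicitly.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    allow_above_unity: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise DimensionError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise UsageError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise DomainError("wavelengths must be strictly increasing")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise DomainError("spectrum values must be finite and nonnegative")
        if self.kind not in SPECTRUM_KINDS:
            raise UsageError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        if self.kind == "reflectance" and not self.allow_above_unity and np.any(vals > 1 + 1e-9):
            raise DomainError(
                "reflectance above 1 requires allow_above_unity=True (white-standard scaling)"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of values onto ``grid`` (no range check)."""
        return np.interp(np.asarray(grid, float), self.wavelengths_nm, self.values)

    # -- constructors ---------------------------------------------------
    @classmethod
    def flat(
        cls,
        value: float,
        lo: float = 300.0,
        hi: float = 700.0,
        step: float = 1.0,
        kind: str = "reflectance",
        **kw,
    ) -> "Spectrum":
        wl = np.arange(lo, hi + step / 2, step)
        return cls(wl, np.full_like(wl, float(value)), kind=kind, **kw)

    @classmethod
    def gaussian(
        cls,
        peak_nm: float,
        sigma_nm: float,
        lo: float = 300.0,
        hi: float = 700.0,
        step: float = 1.0,
        kind: str = "sensitivity",
        amplitude: float = 1.0,
    ) -> "Spectrum":
        wl = np.arange(lo, hi + step / 2, step)
        vals = amplitude * np.exp(-0.5 * ((wl - peak_nm) / sigma_nm) ** 2)
        return cls(wl, vals, kind=kind)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, kind: str = "reflectance", **kw) -> "Spectrum":
        df = pd.read_csv(path)
        if not {"wavelength_nm", "value"} <= set(df.columns):
            raise UsageError(f"{path}: expected columns wavelength_nm,value")
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), kind=kind, **kw)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "value": self.values}
        ).to_csv(path, index=False)


def resample_spectrum(s: Spectrum, grid: np.ndarray, extrapolate: bool = False) -> Spectrum:
    """Linearly interpolate ``s`` onto ``grid``, preserving its kind.

    Extrapolation beyond the measured support is forbidden by default and
    raises :class:`RangeError`.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise UsageError("grid must be a non-empty 1-D array")
    lo, hi = s.support
    if not extrapolate and (grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9):
        raise RangeError(
            f"grid [{grid.min()}, {grid.max()}] outside spectrum support [{lo}, {hi}]"
        )
    # A 1-point grid is valid for interpolation queries but not a Spectrum;
    # callers wanting point values should use Spectrum.interp.
    if grid.size < 2:
        raise UsageError("resampling grid needs at least two points")
    return Spectrum(grid, s.interp(grid), kind=s.kind,
                    allow_above_unity=s.allow_above_unity)


@dataclass(frozen=True)
class ReceptorSet:
    """Ordered receptor sensitivities with noise parameters.

    ``names`` orders the receptors; ``luminance_channel`` designates the
    achromatic (double-cone) channel, and the remaining names form the
    chromatic subset.  ``abundances`` are relative receptor densities
    η_i used to scale channel noise; ``weber`` are the per-channel Weber
    fractions ω_i.
    """

    names: tuple[str, ...]
    sensitivities: dict[str, Spectrum]
    abundances: dict[str, float]
    weber: dict[str, float]
    luminance_channel: str

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise UsageError("receptor names must be unique")
        if self.luminance_channel not in names:
            raise UsageError(
                f"luminance channel {self.luminance_channel!r} not among {names}"
            )
        if len(self.chromatic_names) < 2:
            raise UsageError("need at least two chromatic receptor channels")
        for n in names:
            if n not in self.sensitivities:
                raise UsageError(f"missing sensitivity spectrum for {n!r}")
            if self.weber.get(n, 0.0) <= 0:
                raise DomainError(f"Weber fraction for {n!r} must be positive")
        for n in self.chromatic_names:
            if self.abundances.get(n, 0.0) <= 0:
                raise DomainError(f"abundance for {n!r} must be positive")

    @property
    def chromatic_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n != self.luminance_channel)

    def chromatic_weber(self) -> np.ndarray:
        return np.array([self.weber[n] for n in self.chromatic_names])

    # -- I/O: directory of per-receptor CSVs plus one YAML config -------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for n in self.names:
            self.sensitivities[n].to_csv(path / f"{n}.csv")
        cfg = {
            "names": list(self.names),
            "abundances": {k: float(v) for k, v in self.abundances.items()},
            "weber": {k: float(v) for k, v in self.weber.items()},
            "luminance_channel": self.luminance_channel,
        }
        (path / "receptors.yaml").write_text(yaml.safe_dump(cfg))

    @classmethod
    def from_dir(cls, path) -> "ReceptorSet":
        path = Path(path)
        cfg = yaml.safe_load((path / "receptors.yaml").read_text())
        sens = {
            n: Spectrum.from_csv(path / f"{n}.csv", kind="sensitivity")
            for n in cfg["names"]
        }
        return cls(
            names=tuple(cfg["names"]),
            sensitivities=sens,
            abundances=dict(cfg["abundances"]),
            weber=dict(cfg["weber"]),
            luminance_channel=cfg["luminance_channel"],
        )


@dataclass(frozen=True)
class CatchVector:
    """Per-receptor quantum catches.  Zero catch is an error state."""

    q: dict[str, float]
    adapted: bool = False

    def __post_init__(self) -> None:
        for name, val in self.q.items():
            if not np.isfinite(val) or val <= 0:
                raise DegenerateCatchError(f"non-positive catch for receptor {name!r}")

    def __getitem__(self, name: str) -> float:
        return self.q[name]

    def array(self, names) -> np.ndarray:
        return np.array([self.q[n] for n in names], dtype=float)


def quantum_catch(
    reflectance: Spectrum,
    illuminant: Spectrum,
    receptors: ReceptorSet,
    von_kries: bool = True,
    grid_step: float = 1.0,
) -> CatchVector:
    """Trapezoidal quantum catches Q_i = ∫ R·I·S_i dλ on a common grid.

    All operands are resampled to a shared ``grid_step``-nm grid covering
    the intersection of their supports.  With ``von_kries`` each catch is
    divided by the catch of a perfect reflector under the same
    illuminant, yielding dimensionless adapted catches.
    """
    q: dict[str, float] = {}
    for name in receptors.names:
        sens = receptors.sensitivities[name]
        lo = max(reflectance.support[0], illuminant.support[0], sens.support[0])
        hi = min(reflectance.support[1], illuminant.support[1], sens.support[1])
        if hi - lo < grid_step:
            raise RangeError(f"no overlapping wavelength support for receptor {name!r}")
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        r = reflectance.interp(grid)
        i = illuminant.interp(grid)
        s = sens.interp(grid)
        val = float(np.trapezoid(r * i * s, grid))
        if von_kries:
            white = float(np.trapezoid(i * s, grid))
            if white <= 0:
                raise DegenerateCatchError(f"zero white-point catch for {name!r}")
            val /= white
        if val <= 0:
            raise DegenerateCatchError(f"zero integral catch for receptor {name!r}")
        q[name] = val
    return CatchVector(q, adapted=von_kries)


@dataclass
class CatchImage:
    """Per-pixel quantum catches: one 2-D channel per receptor.

    All channels share one shape; ``scale_px_per_mm`` records the
    physical pixel scale used by acuity control and size conventions.
    """

    channels: dict[str, np.ndarray]
    scale_px_per_mm: float
    receptor_set: ReceptorSet | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise UsageError("a catch image needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise DimensionError(f"channels differ in shape: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.scale_px_per_mm <= 0:
            raise DomainError("scale_px_per_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def luminance_name(self) -> str:
        if self.receptor_set is not None:
            return self.receptor_set.luminance_channel
        if "dbl" in self.channels:
            return "dbl"
        return next(reversed(self.channels))

    def luminance(self) -> np.ndarray:
        return self.channels[self.luminance_name]

    def map(self, fn) -> "CatchImage":
        return CatchImage(
            {k: fn(v) for k, v in self.channels.items()},
            self.scale_px_per_mm,
            self.receptor_set,
        )


def validate_mask(
    mask: np.ndarray,
    shape: tuple[int, int] | None = None,
    require: tuple[int, ...] = (LABEL_ANIMAL, LABEL_BACKGROUND),
) -> np.ndarray:
    """Check an ROI label image: integer labels in {0, 1, 2}."""
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        if not np.allclose(mask, np.round(mask)):
            raise UsageError("mask must contain integer labels")
        mask = np.round(mask).astype(int)
    if shape is not None and mask.shape != tuple(shape):
        raise DimensionError(f"mask shape {mask.shape} != image shape {shape}")
    bad = set(np.unique(mask)) - {LABEL_IGNORE, LABEL_ANIMAL, LABEL_BACKGROUND}
    if bad:
        raise UsageError(f"unexpected mask labels {sorted(bad)}; allowed are 0/1/2")
    for lab in require:
        if not np.any(mask == lab):
            raise UsageError(f"required ROI label {lab} is empty")
    return mask


def image_to_catch(
    image: np.ndarray,
    mapping: np.ndarray,
    receptor_names: tuple[str, ...] | list[str],
    scale_px_per_mm: float,
    receptor_set: ReceptorSet | None = None,
    clamp_fraction: float = 1e-6,
) -> CatchImage:
    """Map a linearised multi-channel image to receptor catch channels.

    ``image`` has shape (H, W, C_camera) and must already be linear and
    white-standard normalised; ``mapping`` is an (n_receptors, C_camera)
    matrix.  Negative results are clamped to ``clamp_fraction`` of the
    channel maximum with a warning (log-form contrasts need positivity).
    """
    image = np.asarray(image, dtype=float)
    mapping = np.asarray(mapping, dtype=float)
    if image.ndim != 3:
        raise DimensionError("image must have shape (H, W, n_camera_channels)")
    if mapping.ndim != 2 or mapping.shape[1] != image.shape[2]:
        raise DimensionError(
            f"mapping shape {mapping.shape} incompatible with image channels {image.shape[2]}"
        )
    if mapping.shape[0] != len(receptor_names):
        raise DimensionError("one mapping row per receptor name is required")
    out = np.einsum("hwc,rc->hwr", image, mapping)
    channels: dict[str, np.ndarray] = {}
    n_clamped_total = 0
    for k, name in enumerate(receptor_names):
        ch = out[:, :, k]
        peak = ch.max()
        if peak <= 0:
            raise DegenerateCatchError(
                f"mapping produced a non-positive channel for receptor {name!r}"
            )
        n_neg = int(np.count_nonzero(ch < 0))
        if n_neg:
            ch = np.maximum(ch, clamp_fraction * peak)
            n_clamped_total += n_neg
        channels[name] = ch
    if n_clamped_total:
        warnings.warn(
            f"clamped {n_clamped_total} negative pixel catches to "
            f"{clamp_fraction} of channel max",
            stacklevel=2,
        )
    return CatchImage(channels, scale_px_per_mm, receptor_set)
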