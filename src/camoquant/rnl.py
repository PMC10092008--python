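"""Receptor-noise-limited (RNL) colour and luminance discrimination.

Perceptual distance between two stimuli *a* and *b* is computed in the
log form of the receptor-noise-limited model.  Per-receptor contrasts
are Δf_i = ln(Qa_i / Qb_i); chromatic distance is the noise-weighted
spread of the chromatic contrasts,

    ΔS² = min_c Σ_i (Δf_i − c)² / ω_i²
        = Σ_i w_i Δf_i² − (Σ_i w_i Δf_i)² / Σ_i w_i,   w_i = 1/ω_i²

which reduces to the published closed forms for di-, tri- and
tetrachromats (e.g. dichromat ΔS = |Δf₁ − Δf₂| / sqrt(ω₁² + ω₂²)).
Achromatic distance uses the designated luminance (double-cone)
channel alone, ΔL = |ln(Qa_D / Qb_D)| / ω_D.

Both are in just-noticeable-difference (JND) units: values below ~1
imply the receiver cannot tell the stimuli apart, and larger values an
increasing probability of discrimination.  The achromatic variant lacks
strong behavioural validation and its results should be read with
caution; :class:`JNDResult` carries that flag.

Weber fractions scale with receptor abundance as ω_i = ν·sqrt(η_max/η_i)
so the most abundant receptor carries the reference noise ν.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCatchError, DomainError, UsageError
from .spectra import (
    LABEL_ANIMAL,
    LABEL_BACKGROUND,
    CatchImage,
    CatchVector,
    ReceptorSet,
    Spectrum,
    quantum_catch,
    validate_mask,
)

#: default reference Weber fraction for the most abundant cone
DEFAULT_REFERENCE_WEBER = 0.05

ACHROMATIC_CAVEAT = (
    "achromatic (luminance) JNDs from the RNL model lack strong "
    "behavioural validation; interpret with caution"
)


def weber_fractions(abundances, reference_weber: float = DEFAULT_REFERENCE_WEBER) -> np.ndarray:
    """Per-receptor Weber fractions ω_i = ν·sqrt(η_max / η_i)."""
    eta = np.asarray(abundances, dtype=float)
    if eta.size == 0 or np.any(eta <= 0) or not np.all(np.isfinite(eta)):
        raise DomainError("abundances must be positive and finite")
    if reference_weber <= 0:
        raise DomainError("reference Weber fraction must be positive")
    return reference_weber * np.sqrt(eta.max() / eta)


@dataclass(frozen=True)
class JNDResult:
    """Chromatic and achromatic distances in JND units (symmetric, ≥ 0)."""

    chromatic_jnd: float
    achromatic_jnd: float
    achromatic_caveat: str = ACHROMATIC_CAVEAT

    @property
    def combined(self) -> float:
        return float(np.hypot(self.chromatic_jnd, self.achromatic_jnd))


def _log_contrasts(a: CatchVector, b: CatchVector, names) -> np.ndarray:
    qa = a.array(names)
    qb = b.array(names)
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise DegenerateCatchError("log contrasts need strictly positive catches")
    return np.log(qa / qb)


def rnl_distance(delta_f: np.ndarray, weber: np.ndarray) -> float:
    """Noise-weighted spread of contrasts: the n-channel RNL chromatic
    distance in its variationally-equivalent closed form."""
    delta_f = np.asarray(delta_f, dtype=float)
    weber = np.asarray(weber, dtype=float)
    if delta_f.shape != weber.shape or delta_f.ndim != 1:
        raise DomainError("delta_f and weber must be 1-D and equal length")
    if delta_f.size < 2:
        raise UsageError("chromatic distance needs at least two channels")
    if np.any(weber <= 0):
        raise DomainError("Weber fractions must be positive")
    w = 1.0 / weber**2
    c = np.sum(w * delta_f) / np.sum(w)
    return float(np.sqrt(max(np.sum(w * (delta_f - c) ** 2), 0.0)))


def chromatic_jnd(a: CatchVector, b: CatchVector, receptors: ReceptorSet) -> float:
    """Chromatic ΔS between two catch vectors over the chromatic channels."""
    names = receptors.chromatic_names
    df = _log_contrasts(a, b, names)
    return rnl_distance(df, receptors.chromatic_weber())


def achromatic_jnd(a: CatchVector, b: CatchVector, receptors: ReceptorSet) -> float:
    """Achromatic ΔL = |ln(Qa_D/Qb_D)| / ω_D on the luminance channel."""
    name = receptors.luminance_channel
    df = _log_contrasts(a, b, (name,))
    return float(abs(df[0]) / receptors.weber[name])


def jnd(a: CatchVector, b: CatchVector, receptors: ReceptorSet) -> JNDResult:
    return JNDResult(chromatic_jnd(a, b, receptors), achromatic_jnd(a, b, receptors))


# ---------------------------------------------------------------------------
# ROI-level comparison on catch images
# ---------------------------------------------------------------------------

def roi_mean_catch(img: CatchImage, mask: np.ndarray, label: int) -> CatchVector:
    """Mean catch per channel over the pixels carrying ``label``."""
    mask = validate_mask(mask, img.shape, require=(label,))
    sel = mask == label
    return CatchVector(
        {name: float(ch[sel].mean()) for name, ch in img.channels.items()}
    )


def roi_jnd(
    img: CatchImage,
    mask: np.ndarray,
    receptors: ReceptorSet | None = None,
    labels: tuple[int, int] = (LABEL_ANIMAL, LABEL_BACKGROUND),
) -> JNDResult:
    """One JND pair per image: ROI-mean catches of animal vs background.

    The means are taken on the (acuity-controlled) catch image, giving a
    single chromatic and achromatic distance for the region pair.
    """
    recs = receptors if receptors is not None else img.receptor_set
    if recs is None:
        raise UsageError("a ReceptorSet is required (argument or img.receptor_set)")
    a = roi_mean_catch(img, mask, labels[0])
    b = roi_mean_catch(img, mask, labels[1])
    return jnd(a, b, recs)


# ---------------------------------------------------------------------------
# Spectral nearest-match ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    index: int
    delta_s: float
    delta_l: float
    distance: float


def rank_spectral_match(
    target: Spectrum,
    candidates: list[Spectrum],
    illuminant: Spectrum,
    receptors: ReceptorSet,
    metric: str = "combined",
    von_kries: bool = True,
) -> list[MatchResult]:
    """Rank candidate spectra by perceptual distance to a target.

    Used e.g. to pick the printing material whose colour is closest to a
    measured wing patch.  ``metric`` is ``combined`` (sqrt(ΔS² + ΔL²),
    default) or ``chromatic``; ties keep input order.
    """
    if not candidates:
        raise UsageError("need at least one candidate spectrum")
    if metric not in ("combined", "chromatic"):
        raise UsageError(f"unknown metric {metric!r}")
    qt = quantum_catch(target, illuminant, receptors, von_kries=von_kries)
    results = []
    for i, cand in enumerate(candidates):
        qc = quantum_catch(cand, illuminant, receptors, von_kries=von_kries)
        ds = chromatic_jnd(qt, qc, receptors)
        dl = achromatic_jnd(qt, qc, receptors)
        dist = float(np.hypot(ds, dl)) if metric == "combined" else ds
        results.append(MatchResult(i, ds, dl, dist))
    order = np.argsort([r.distance for r in results], kind="stable")
    return [results[i] for i in order]
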