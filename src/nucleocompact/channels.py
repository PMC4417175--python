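"""DNA extension in nanochannels: measurement, population statistics,
fragment filtering, coil/condensed classification and condensation thresholds.

The extension of a channel-confined molecule is the span of the
above-threshold fluorescence signal projected on the channel axis, with the
threshold set at background + 2x background-noise SD.  Populations of ~30
molecules per condition are summarized by a Gaussian fit of the extension
histogram; fragments are rejected below mean - 2 SD; condensed molecules are
recognized as compact (span within twice the point-spread-function FWHM)
bright (peak-to-background at least twice the coil median) spots; the
condensation threshold of a concentration series is the lowest concentration
at which the majority of molecules are condensed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

__all__ = [
    "ChannelImage",
    "ExtensionRecord",
    "PopulationStats",
    "measure_extension",
    "gaussian_population_fit",
    "fragment_filter",
    "classify_condensed",
    "relative_extension",
    "critical_concentration",
]

#: Contour length of YOYO-stained T4 DNA (um), the default normalization.
T4_CONTOUR_UM = 57.0


@dataclass(frozen=True)
class ChannelImage:
    """Fluorescence image of a single channel-confined molecule."""

    intensity: np.ndarray
    pixel_size_um: float
    channel_axis: tuple[float, float] = (1.0, 0.0)  # unit vector, x = columns

    def __post_init__(self):
        img = np.asarray(self.intensity, dtype=float)
        if img.ndim != 2:
            raise ValueError("intensity must be a 2D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        ax = np.asarray(self.channel_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("channel axis must be a nonzero vector")
        object.__setattr__(self, "intensity", img)
        object.__setattr__(self, "channel_axis", tuple(ax / n))


@dataclass(frozen=True)
class ExtensionRecord:
    extension_um: float
    peak_to_background: float
    condensed: Optional[bool] = None
    concentration_uM: Optional[float] = None
    channel_nm: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.extension_um < 0:
            raise ValueError("extension must be non-negative")
        if self.concentration_uM is not None and self.concentration_uM < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class PopulationStats:
    mean_um: float
    sd_um: float
    gaussian_fit: Optional[tuple[float, float, float]]  # (mean, sigma, amplitude)
    fit_ok: Optional[bool]
    fragment_cutoff_um: float
    n_kept: int
    n_rejected: int
    notice: Optional[str] = None


class EmptyDetectionError(ValueError):
    """No pixel rises above the detection threshold."""


def _background_stats(img: np.ndarray) -> tuple[float, float]:
    """Robust background mean and noise SD (median / scaled MAD).

    The molecule occupies a small fraction of the frame, so the image median
    tracks the background level and the image MAD tracks the background
    noise.
    """
    bg = float(np.median(img))
    mad = float(np.median(np.abs(img - bg)))
    return bg, 1.4826 * mad


def measure_extension(
    img: ChannelImage,
    threshold_factor: float = 2.0,
    *,
    background: Optional[float] = None,
    noise_sd: Optional[float] = None,
) -> ExtensionRecord:
    """Extension of the molecule along the channel axis.

    The detection threshold is background + ``threshold_factor`` x
    background-noise SD.  A 3-pixel median filter along the channel axis is
    applied before thresholding: it deletes isolated shot-noise pixels
    exactly while acting as the identity on the monotone edges of the
    (PSF-blurred) molecule signal.  Above-threshold pixels are grouped into
    connected components, the brightest component is taken as the molecule,
    and its span projected on the channel axis is the extension.
    """
    data = img.intensity
    ax = img.channel_axis
    size = (1, 3) if abs(ax[0]) >= abs(ax[1]) else (3, 1)
    work = ndimage.median_filter(data, size=size, mode="nearest")
    if background is None or noise_sd is None:
        bg_est, sd_est = _background_stats(data)
        bg = bg_est if background is None else background
        sd = sd_est if noise_sd is None else noise_sd
    else:
        bg, sd = background, noise_sd
    thr = bg + threshold_factor * sd
    mask = work > thr
    if not mask.any():
        raise EmptyDetectionError("no pixels above the detection threshold")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sums = ndimage.sum_labels(work - bg, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sums)) + 1
        mask = labels == keep
    rows, cols = np.nonzero(mask)
    ax = img.channel_axis
    proj = cols * ax[0] + rows * ax[1]
    # span between the outermost above-threshold pixel centers
    extension = (proj.max() - proj.min()) * img.pixel_size_um
    peak = float(data[mask].max())
    p2b = (peak - bg) / bg if bg > 0 else np.inf
    return ExtensionRecord(extension_um=float(extension), peak_to_background=float(p2b))


def _gauss(x, mu, sigma, amp):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def gaussian_population_fit(
    records: Sequence[ExtensionRecord | float],
    n_bins: Optional[int] = None,
    r2_threshold: float = 0.8,
) -> PopulationStats:
    """Gaussian fit of the extension histogram plus sample statistics.

    A histogram with ~sqrt(n) bins is fitted by least squares; the fit is
    flagged poor (``fit_ok=False``) when its coefficient of determination
    falls below ``r2_threshold``, as happens for bimodal populations.
    """
    ext = np.asarray(
        [r.extension_um if isinstance(r, ExtensionRecord) else float(r) for r in records]
    )
    if len(ext) < 10:
        raise ValueError("need at least 10 records for a population fit")
    mean = float(ext.mean())
    sd = float(ext.std(ddof=1))
    cutoff = mean - 2.0 * sd
    if sd == 0:
        return PopulationStats(
            mean_um=mean,
            sd_um=0.0,
            gaussian_fit=None,
            fit_ok=None,
            fragment_cutoff_um=cutoff,
            n_kept=len(ext),
            n_rejected=0,
            notice="degenerate population (all extensions equal); Gaussian fit skipped",
        )
    if n_bins is None:
        n_bins = max(6, int(round(np.sqrt(len(ext)))))
    counts, edges = np.histogram(ext, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _gauss, centers, counts, p0=[mean, sd, counts.max()], maxfev=10000
        )
        fit = (float(popt[0]), float(abs(popt[1])), float(popt[2]))
        resid = counts - _gauss(centers, *popt)
        ss_tot = ((counts - counts.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
        ok = bool(r2 >= r2_threshold)
        notice = None if ok else f"Gaussian fit poor (R^2 = {r2:.2f}); population may be multimodal"
    except RuntimeError:
        fit, ok, notice = None, False, "Gaussian fit did not converge"
    n_frag = int((ext < cutoff).sum())
    return PopulationStats(
        mean_um=mean,
        sd_um=sd,
        gaussian_fit=fit,
        fit_ok=ok,
        fragment_cutoff_um=cutoff,
        n_kept=len(ext) - n_frag,
        n_rejected=n_frag,
        notice=notice,
    )


def fragment_filter(
    records: Sequence[ExtensionRecord | float],
) -> tuple[list, list]:
    """One-pass rejection of fragments below mean - 2 SD of the intact peak.

    The mean and SD describe the intact population, whose extensions cluster
    in a near-Gaussian peak, so they are estimated robustly (median and
    1.4826 x MAD): moment estimates would be inflated by the very fragments
    the cutoff is meant to remove.  Records with extension strictly below
    the cutoff are rejected; the pass is not iterated.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    ext = np.asarray(
        [r.extension_um if isinstance(r, ExtensionRecord) else float(r) for r in records]
    )
    med = np.median(ext)
    sd_robust = 1.4826 * np.median(np.abs(ext - med))
    cutoff = med - 2.0 * sd_robust
    kept = [r for r, e in zip(records, ext) if e >= cutoff]
    rejected = [r for r, e in zip(records, ext) if e < cutoff]
    return kept, rejected


def classify_condensed(
    rec: ExtensionRecord,
    psf_fwhm_um: float,
    coil_reference: Optional[Sequence[ExtensionRecord]] = None,
    compactness_factor: float = 2.0,
    brightness_factor: float = 2.0,
) -> bool:
    """Condensed iff the molecule is compact and bright.

    Compact: extension <= ``compactness_factor`` x PSF FWHM (boundary
    included).  Bright: peak-to-background at least ``brightness_factor``
    times the median of a coil reference population.  Without a reference the
    brightness criterion is skipped with a warning.

    Both factors are operational conventions, not physics: the above-
    threshold span of a diffraction-limited spot is itself ~2-2.5 x the PSF
    FWHM once the peak stands well above the detection threshold, so a
    larger compactness factor is appropriate for bright spots.
    """
    if psf_fwhm_um <= 0:
        raise ValueError("PSF FWHM must be positive")
    compact = rec.extension_um <= compactness_factor * psf_fwhm_um
    if coil_reference is None or len(coil_reference) == 0:
        warnings.warn(
            "no coil reference population; condensed call uses the extension criterion only",
            stacklevel=2,
        )
        return compact
    ref = float(np.median([r.peak_to_background for r in coil_reference]))
    return compact and rec.peak_to_background >= brightness_factor * ref


def relative_extension(rec: ExtensionRecord | float, contour_um: float = T4_CONTOUR_UM) -> float:
    """Extension divided by the molecule's contour length."""
    if contour_um <= 0:
        raise ValueError("contour length must be positive")
    ext = rec.extension_um if isinstance(rec, ExtensionRecord) else float(rec)
    return ext / contour_um


@dataclass(frozen=True)
class CondensationThreshold:
    critical_uM: Optional[float]
    interval_uM: tuple[Optional[float], Optional[float]]
    condensed_fraction: dict
    notice: Optional[str] = None


def critical_concentration(
    series: Sequence[tuple[float, Sequence[ExtensionRecord]]],
) -> CondensationThreshold:
    """Condensation threshold of a concentration series.

    The threshold is the lowest tested concentration with condensed fraction
    above one half; the bracketing interval runs from the highest
    sub-threshold concentration tested to the threshold itself.  If no tested
    concentration crosses one half, an open interval is returned with a
    notice.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 concentrations")
    fractions = {}
    for conc, recs in sorted(series, key=lambda cr: cr[0]):
        if len(recs) < 10:
            raise ValueError(f"need at least 10 records per concentration (got {len(recs)})")
        flags = [r.condensed for r in recs]
        if any(f is None for f in flags):
            raise ValueError("records must carry condensed labels; run classify_condensed first")
        fractions[conc] = float(np.mean(flags))
    concs = sorted(fractions)
    over = [c for c in concs if fractions[c] > 0.5]
    if not over:
        return CondensationThreshold(
            critical_uM=None,
            interval_uM=(concs[-1], None),
            condensed_fraction=fractions,
            notice="no tested concentration reaches a condensed majority",
        )
    crit = over[0]
    below = [c for c in concs if c < crit]
    return CondensationThreshold(
        critical_uM=crit,
        interval_uM=(below[-1] if below else None, crit),
        condensed_fraction=fractions,
    )
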