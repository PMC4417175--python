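"""Ground-truth synthetic data for every analysis stage.

Generators emulate the experimental inputs of the study conditions: 2D
surface-equilibrated WLC contours (1000 bp scale: contour ~340-350 nm,
persistence 49-60 nm), diffraction-blurred fluorescence images of channel-
confined molecules (extended coils of ~3-17 um or compact condensed spots)
and of free molecules in the bulk phase, and 4-composition contrast-variation
SANS curves built from the cylindrical shell/Gaussian coat model.  Every
generator is deterministic given its seed and returns the ground truth it
encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .channels import ChannelImage
from .gyration import Frame
from .sans import (
    DNA_MATCH_D2O,
    PROTEIN_MATCH_D2O,
    RadialProfile,
    ScatteringCurve,
    StructureFactorModel,
    contrast_coefficients,
    structure_factor,
)
from .wlc import ContourTrace

__all__ = [
    "SynthSpec",
    "gen_wlc_traces",
    "gen_channel_image",
    "gen_bulk_stack",
    "gen_sans_dataset",
    "PSF_SIGMA_UM",
]

#: Gaussian PSF width of the fluorescence imaging model (um); the
#: diffraction-limited scale of a high-NA 100x objective.
PSF_SIGMA_UM = 0.12


@dataclass(frozen=True)
class SynthSpec:
    """Recorded generator provenance attached to synthetic datasets."""

    kind: str
    params: dict
    seed: int


# --- 2D worm-like-chain traces ----------------------------------------------


def gen_wlc_traces(
    n: int,
    contour_nm: float,
    P_nm: float,
    step_nm: float,
    seed: int,
) -> list[ContourTrace]:
    """Ensemble of 2D-equilibrated WLC contours.

    Successive turning angles are independent Gaussians with variance
    step/P, which makes the ensemble tangent correlation decay exactly as
    exp(-L/(2P)) at separations that are multiples of the step.  The
    generated polyline length equals the requested contour exactly.
    """
    if step_nm >= P_nm / 2.0:
        raise ValueError("step must be much smaller than P (step < P/2)")
    if n < 1 or contour_nm <= step_nm:
        raise ValueError("need n >= 1 and contour > step")
    rng = np.random.default_rng(seed)
    n_seg = max(2, int(round(contour_nm / step_nm)))
    b = contour_nm / n_seg
    traces = []
    for i in range(n):
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        dphi = rng.normal(0.0, np.sqrt(b / P_nm), size=n_seg - 1)
        phi = phi0 + np.concatenate([[0.0], np.cumsum(dphi)])
        steps = b * np.column_stack([np.cos(phi), np.sin(phi)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        traces.append(ContourTrace(f"mol{i:04d}", pts))
    return traces


# --- channel-confined molecule images ----------------------------------------


def gen_channel_image(
    extension_um: float = 10.0,
    *,
    condensed: bool = False,
    pixel_um: float = 0.16,
    snr: Optional[float] = 10.0,
    seed: int = 0,
    image_length_um: float = 20.0,
    n_rows: int = 15,
    background: float = 20.0,
    psf_sigma_um: float = PSF_SIGMA_UM,
    spot_sigma_um: float = 0.05,
    spot_brightness: float = 3.0,
) -> tuple[ChannelImage, dict]:
    """Fluorescence image of one channel-confined molecule, plus ground truth.

    A coil is an axial top-hat of length ``extension_um`` one channel-row
    wide, blurred with a Gaussian PSF.  A condensed molecule is a compact
    globule (physical size ``spot_sigma_um``) that images as a Gaussian spot
    of width sqrt(spot^2 + psf^2); its peak brightness in the image is
    ``spot_brightness`` times the coil amplitude -- the same molecule's
    photons concentrated into a diffraction-limited blob.  If ``snr`` is
    finite the image carries Poisson noise; the signal amplitude is snr x the
    background shot-noise SD.
    """
    if extension_um < 0:
        raise ValueError("extension must be non-negative")
    rng = np.random.default_rng(seed)
    nx = int(round(image_length_um / pixel_um))
    img = np.zeros((n_rows, nx))
    row = n_rows // 2
    bg_sd = np.sqrt(background)
    amp = (snr if snr is not None else 10.0) * bg_sd

    x = (np.arange(nx) + 0.5) * pixel_um
    x0 = image_length_um / 2.0
    if condensed:
        # already the PSF-convolved image of a sub-resolution globule
        sig_eff = np.sqrt(spot_sigma_um**2 + psf_sigma_um**2)
        y = (np.arange(n_rows) - row) * pixel_um
        img = spot_brightness * amp * np.exp(
            -0.5 * ((x[None, :] - x0) ** 2 + y[:, None] ** 2) / max(sig_eff, 1e-6) ** 2
        )
    else:
        half = extension_um / 2.0
        img[row] = np.where(np.abs(x - x0) <= half, amp, 0.0)
        if psf_sigma_um > 0:
            img = ndimage.gaussian_filter(img, sigma=psf_sigma_um / pixel_um)
    img = img + background
    if snr is not None and np.isfinite(snr):
        img = rng.poisson(img).astype(float)
    truth = {
        "extension_um": float(extension_um),
        "condensed": bool(condensed),
        "pixel_um": pixel_um,
        "snr": snr,
        "seed": seed,
    }
    return ChannelImage(img, pixel_size_um=pixel_um), truth


# --- bulk-phase frames --------------------------------------------------------


def gen_bulk_stack(
    long_axis_um: float,
    *,
    kind: str = "gaussian",
    anisotropy: float = 3.0,
    n_frames: int = 50,
    pixel_um: float = 0.16,
    field_um: float = 20.0,
    seed: int = 0,
    background: float = 20.0,
    snr: Optional[float] = 20.0,
    rotate: bool = True,
) -> tuple[list[Frame], dict]:
    """Stack of frames of one unconstrained molecule, plus ground truth.

    ``kind='gaussian'``: anisotropic Gaussian blob whose second moment along
    the long axis is long_axis^2/12 (sigma_a = long_axis/sqrt(12)), with
    transverse sigma smaller by ``anisotropy``.  ``kind='rod'``: a uniform
    rod of length ``long_axis_um``.  Frame orientation is random per frame
    when ``rotate`` is set; shot noise is Poisson at amplitude snr x
    background SD.
    """
    if long_axis_um <= 0:
        raise ValueError("long axis must be positive")
    rng = np.random.default_rng(seed)
    npx = int(round(field_um / pixel_um))
    coords = (np.arange(npx) + 0.5) * pixel_um - field_um / 2.0
    X, Y = np.meshgrid(coords, coords)
    bg_sd = np.sqrt(background)
    amp = (snr if snr is not None else 20.0) * bg_sd

    sigma_a = long_axis_um / np.sqrt(12.0)
    sigma_b = sigma_a / anisotropy
    frames = []
    for _ in range(n_frames):
        theta = rng.uniform(0.0, np.pi) if rotate else 0.0
        ca, sa = np.cos(theta), np.sin(theta)
        u = ca * X + sa * Y  # along the molecule's long axis
        v = -sa * X + ca * Y
        if kind == "gaussian":
            sig = amp * np.exp(-0.5 * (u / sigma_a) ** 2 - 0.5 * (v / sigma_b) ** 2)
        elif kind == "rod":
            w = max(pixel_um, sigma_b / 2.0)
            sig = amp * ((np.abs(u) <= long_axis_um / 2.0) & (np.abs(v) <= w / 2.0))
        else:
            raise ValueError(f"unknown kind {kind!r}")
        img = sig + background
        if snr is not None and np.isfinite(snr):
            img = rng.poisson(img).astype(float)
            frames.append(Frame(img, pixel_size_um=pixel_um))
        else:
            frames.append(Frame(img, pixel_size_um=pixel_um, background=background, noise_sd=0.0))
    truth = {
        "long_axis_um": float(long_axis_um),
        "kind": kind,
        "anisotropy": anisotropy,
        "seed": seed,
    }
    return frames, truth


# --- SANS contrast-variation datasets ----------------------------------------


def gen_sans_dataset(
    profile: RadialProfile,
    interspersion_nm: float = 10.0,
    rod_length_nm: float = 51.0,
    *,
    d2o_fractions: Sequence[float] = (0.0, PROTEIN_MATCH_D2O, DNA_MATCH_D2O, 1.0),
    noise_pct: float = 0.0,
    seed: int = 0,
    q: Optional[np.ndarray] = None,
    dna_amplitude: float = 0.3,
    dna_radius_nm: float = 1.0,
    background_level: float = 0.0,
    finite_length: bool = False,
) -> tuple[list[ScatteringCurve], dict]:
    """Multi-contrast scattering curves from the cylinder coat model.

    The forward model per composition f is

        I(q; f) = c_p(f)^2 S_protein(q) + c_d(f)^2 S_dna(q) + background,

    with S_protein the cylinder-coat structure factor of ``profile`` and
    S_dna a uniform-rod term of radius ``dna_radius_nm`` scaled by
    ``dna_amplitude``.  The protein term vanishes identically at the protein
    match composition (40% D2O by default) and the DNA term at 64%.
    Noise is multiplicative Gaussian with relative SD ``noise_pct``/100.
    """
    if q is None:
        q = np.linspace(0.07, 3.0, 120)
    q = np.asarray(q, dtype=float)
    rng = np.random.default_rng(seed)
    model_p = StructureFactorModel(profile, interspersion_nm, rod_length_nm, finite_length)
    S_p = np.asarray(structure_factor(model_p, q, warn_validity=False))
    dna_profile = RadialProfile("shell", (0.0, dna_radius_nm))
    model_d = StructureFactorModel(dna_profile, 0.34, rod_length_nm, finite_length)
    S_d = dna_amplitude * np.asarray(structure_factor(model_d, q, warn_validity=False))

    curves = []
    for f in d2o_fractions:
        cp, cd = contrast_coefficients(f)
        I0 = cp**2 * S_p + cd**2 * S_d + background_level
        if noise_pct > 0:
            I = I0 * (1.0 + rng.normal(0.0, noise_pct / 100.0, size=I0.shape))
            sigma = np.abs(I0) * noise_pct / 100.0
        else:
            I = I0
            sigma = np.maximum(np.abs(I0), 1e-12) * 1e-6  # nominal uncertainty
        curves.append(ScatteringCurve(q, I, sigma, d2o_fraction=f))
    truth = {
        "profile_kind": profile.kind,
        "profile_params": profile.params,
        "interspersion_nm": interspersion_nm,
        "rod_length_nm": rod_length_nm,
        "S_protein": S_p,
        "S_dna": S_d,
        "noise_pct": noise_pct,
        "seed": seed,
    }
    return curves, truth
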