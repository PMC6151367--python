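"""Image-domain surrogate for PET acquisition and reconstruction.

Tomographic reconstruction from sinograms is out of scope; its observable
effects on the image are emulated instead:

1. the nominal concentration field is blurred with a Gaussian system PSF
   (``psf_fwhm``, mm);
2. the field is sampled onto the reconstruction grid (in-plane pixel size
   = FOV / matrix_size, slice thickness separate);
3. seeded multiplicative Gaussian noise of relative amplitude
   ``noise_scale`` is added (a Poisson-like surrogate whose strength stands
   in for count statistics: fewer iterations x subsets or no TOF -> more
   noise);
4. a Gaussian post-reconstruction filter (``fwhm_filter``, mm) smooths the
   noisy image, exactly as the clinical reconstruction protocol does.

Identical seed and settings reproduce the volume bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import ndimage

from .phantom import Phantom
from .volume import ActivityVolume, resample_to_spacing

_ALLOWED_MATRIX = (128, 192, 256)
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AcquisitionSettings:
    """One reconstruction-surrogate setting.

    ``noise_scale`` is the relative standard deviation of the multiplicative
    noise injected before the post-filter; it is the image-domain stand-in
    for the iterations x subsets product and TOF usage.
    """

    matrix_size: int = 256
    fwhm_filter: float = 5.0  # mm, post-reconstruction Gaussian
    psf_fwhm: float = 6.4  # mm, system resolution (smaller with PSF modelling)
    noise_scale: float = 0.2
    slice_thickness: float = 3.27  # mm
    seed: int = 0
    fov_mm: float = 700.0
    label: str = ""

    def __post_init__(self):
        if self.matrix_size not in _ALLOWED_MATRIX:
            raise ValueError(f"matrix_size must be one of {_ALLOWED_MATRIX}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.fwhm_filter < 0 or self.psf_fwhm < 0:
            raise ValueError("FWHM values must be >= 0")

    @property
    def pixel_size(self) -> float:
        """In-plane reconstructed pixel size, mm."""
        return self.fov_mm / self.matrix_size

    @property
    def grid_spacing(self) -> tuple[float, float, float]:
        return (self.pixel_size, self.pixel_size, self.slice_thickness)


def _gaussian_mm(values: np.ndarray, fwhm: float, spacing) -> np.ndarray:
    if fwhm <= 0:
        return values
    sigma = [fwhm * _FWHM_TO_SIGMA / s for s in spacing]
    return ndimage.gaussian_filter(values, sigma=sigma, mode="nearest")


def simulate_acquisition(
    phantom: Phantom,
    settings: AcquisitionSettings,
    margin_mm: float = 20.0,
) -> ActivityVolume:
    """Simulate one reconstructed PET volume of the phantom.

    The lesion is embedded in ``margin_mm`` of uniform background before
    blurring, so spill-out and background statistics are represented.  The
    output grid covers the same physical extent as the padded GS grid;
    total activity is conserved by the linear resampling.
    """
    lesion_extent = 2.0 * phantom.shell.spec.base_radius * (
        1.0 + phantom.shell.spec.deformation_amplitude
    )
    if lesion_extent < 2.0 * settings.psf_fwhm:
        warnings.warn(
            f"lesion extent {lesion_extent:.1f} mm is below twice the PSF "
            f"FWHM ({settings.psf_fwhm:.1f} mm): partial-volume dominated",
            stacklevel=2,
        )

    nominal = phantom.nominal_concentrations().astype(np.float64)
    pad = tuple(
        int(np.ceil(margin_mm / s)) for s in phantom.spacing
    )
    nominal = np.pad(
        nominal, [(p, p) for p in pad], mode="constant",
        constant_values=phantom.background,
    )
    blurred = _gaussian_mm(nominal, settings.psf_fwhm, phantom.spacing)
    gs_vol = ActivityVolume(blurred, phantom.spacing)
    recon = resample_to_spacing(gs_vol, settings.grid_spacing, order=1)

    values = recon.values
    if settings.noise_scale > 0:
        rng = np.random.default_rng(settings.seed)
        values = values * (1.0 + settings.noise_scale * rng.standard_normal(values.shape))
    values = _gaussian_mm(values, settings.fwhm_filter, recon.spacing)
    values = np.clip(values, 0.0, None)
    meta = dict(recon.meta)
    meta.update(settings=settings, seed=settings.seed)
    return ActivityVolume(values, recon.spacing, recon.origin, meta)


def make_test_retest(
    phantom: Phantom, settings: AcquisitionSettings
) -> tuple[ActivityVolume, ActivityVolume]:
    """Two acquisitions identical in signal, independent in noise.

    Child seeds are derived from ``settings.seed`` with a counter scheme and
    recorded in each volume's metadata, so a rerun reproduces both members.
    """
    children = np.random.SeedSequence(settings.seed).spawn(2)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    pair = tuple(
        simulate_acquisition(phantom, dc_replace(settings, seed=s)) for s in seeds
    )
    for vol, s in zip(pair, seeds):
        vol.meta["retest_member_seed"] = s
    return pair


def uniform_region_cov(vol: ActivityVolume, mask: np.ndarray | None = None) -> float:
    """Noise estimate: percent COV of voxel values in a uniform region.

    With no mask, the central third of the volume is used (mirrors drawing a
    large ROI inside the liver).
    """
    if mask is None:
        sl = tuple(slice(n // 3, 2 * n // 3) for n in vol.shape)
        roi = vol.values[sl]
    else:
        roi = vol.values[mask]
    m = float(roi.mean())
    if m <= 0:
        raise ValueError("ROI mean is non-positive")
    return 100.0 * float(roi.std()) / m


def reconstruction_grid(base_seed: int = 0) -> dict[str, list[AcquisitionSettings]]:
    """The reconstruction-surrogate settings families under study.

    Mirrors a clinical evaluation grid: reconstruction algorithm variants
    (PSF modelling sharpens the effective resolution, TOF lowers noise),
    iteration and subset counts (noise scales with 1/sqrt(updates)),
    reconstructed matrix size, and post-filter FWHM.  The standard protocol
    is 3 it x 18 sub, 5 mm filter, matrix 256, PSF+TOF.
    """
    def s(label, *, psf=True, tof=True, it=3, sub=18, fwhm=5.0, matrix=256):
        noise = 0.2 * np.sqrt((3 * 18) / (it * sub)) * (1.0 if tof else 1.3)
        return AcquisitionSettings(
            matrix_size=matrix,
            fwhm_filter=fwhm,
            psf_fwhm=4.8 if psf else 6.4,
            noise_scale=float(noise),
            seed=base_seed,
            label=label,
        )

    return {
        "algorithm": [
            s("osem", psf=False, tof=False),
            s("osem+psf", psf=True, tof=False),
            s("osem+tof", psf=False, tof=True),
            s("osem+psf+tof", psf=True, tof=True),
        ],
        "iterations": [s(f"it{i}", it=i) for i in (2, 3, 4)],
        "subsets": [s(f"sub{n}", sub=n) for n in (18, 24)],
        "matrix": [s(f"m{m}", matrix=m) for m in (128, 192, 256)],
        "fwhm": [s(f"fwhm{f}", fwhm=float(f), matrix=192) for f in (5, 7)],
    }


def default_settings(seed: int = 0) -> AcquisitionSettings:
    """The standard clinical protocol surrogate."""
    return AcquisitionSettings(seed=seed, label="standard")
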