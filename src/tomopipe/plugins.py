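"""Default plugin registry: every correction, transform and reconstruction
op wrapped as a registered pipeline plugin with a JSON-expressible schema.

Plugins needing side data (flat/dark stacks, monitor readings) read it from
the block's metadata, where the NXtomo loader and the simulator place it.
The recommended standard absorption chain is::

    remove_outliers -> flat_dark -> monitor_norm? -> paganin? -> neg_log
        -> to_sinograms -> com_align? -> remove_rings -> fbp

Only space compatibility is machine-validated; this ordering is the
documented convention.
"""

from __future__ import annotations

import numpy as np

from . import preprocess, recon, sinogram
from .framework import DataBlock, PluginRegistry, PluginSpec, ProcessList, Space

__all__ = ["default_registry", "standard_absorption_list"]


def _p_remove_outliers(block: DataBlock, outlier_k: float, window: int) -> DataBlock:
    opts = preprocess.CorrectionOptions(outlier_k=outlier_k, window=window)
    repaired, mask = preprocess.remove_outlier_pixels(block, opts)
    repaired.meta = dict(repaired.meta)
    repaired.meta["n_outliers_repaired"] = int(np.count_nonzero(mask))
    return repaired


def _p_flat_dark(block: DataBlock, eps: float, flat_reduce: str) -> DataBlock:
    opts = preprocess.CorrectionOptions(eps=eps, flat_reduce=flat_reduce)
    return preprocess.flat_dark_correct(block, options=opts)


def _p_monitor_norm(block: DataBlock) -> DataBlock:
    return preprocess.monitor_normalize(block)


def _p_paganin(
    block: DataBlock,
    delta_beta: float,
    distance_z: float,
    wavelength: float,
    pixel_size: float | None,
) -> DataBlock:
    params = preprocess.PaganinParams(
        delta_beta=delta_beta,
        distance_z=distance_z,
        wavelength=wavelength,
        pixel_size=pixel_size if pixel_size is not None else block.pixel_size,
    )
    return preprocess.paganin_filter(block, params)


def _p_neg_log(block: DataBlock) -> DataBlock:
    return preprocess.neg_log(block)


def _p_to_sinograms(block: DataBlock) -> DataBlock:
    return sinogram.to_sinograms(block)


def _p_com_align(block: DataBlock) -> DataBlock:
    # Slice-wise over the vertical axis; fit parameters land in metadata.
    out = np.empty_like(np.asarray(block.values, dtype=float))
    fits = []
    for k in range(block.values.shape[0]):
        corrected, fit, shifts = sinogram.com_align(
            block.values[k], block.angles_deg
        )
        out[k] = corrected
        fits.append(
            {
                "amplitude": fit.amplitude,
                "phase": fit.phase,
                "offset": fit.offset,
                "shifts_px": shifts.tolist(),
            }
        )
    result = block.replace(values=out)
    result.meta = dict(result.meta)
    result.meta["com_align"] = fits
    return result


def _p_remove_rings(block: DataBlock, smooth_window: int) -> DataBlock:
    return sinogram.remove_rings(block, smooth_window=smooth_window)


def _p_fbp(
    block: DataBlock,
    filter_window: str,
    cor_offset_px: float,
    pad_factor: int,
) -> DataBlock:
    cfg = recon.ReconConfig(
        filter_window=filter_window,
        cor_offset_px=cor_offset_px,
        pad_factor=pad_factor,
        det_spacing=block.pixel_size,
    )
    return recon.reconstruct_volume(block, cfg)


def default_registry() -> PluginRegistry:
    """Registry with the standard plugin set registered in chain order."""
    reg = PluginRegistry()
    reg.register(
        PluginSpec(
            "remove_outliers",
            Space.DETECTOR,
            Space.DETECTOR,
            {"outlier_k": {"default": 3.0}, "window": {"default": 3}},
            citation="median/MAD zinger and dead-pixel repair",
            granularity="frame",
        ),
        _p_remove_outliers,
    )
    reg.register(
        PluginSpec(
            "flat_dark",
            Space.DETECTOR,
            Space.PROJECTION,
            {"eps": {"default": 1e-6}, "flat_reduce": {"default": "mean"}},
            citation="flat-/dark-field transmission normalisation",
            granularity="frame",
        ),
        _p_flat_dark,
    )
    reg.register(
        PluginSpec(
            "monitor_norm",
            Space.PROJECTION,
            Space.PROJECTION,
            {},
            citation="incident-flux normalisation from monitor readings",
            granularity="frame",
        ),
        _p_monitor_norm,
    )
    reg.register(
        PluginSpec(
            "paganin",
            Space.PROJECTION,
            Space.PROJECTION,
            {
                "delta_beta": {"default": 250.0},
                "distance_z": {"required": True},
                "wavelength": {"required": True},
                "pixel_size": {"default": None},
            },
            citation="Paganin et al., J. Microsc. 206 (2002) 33-40",
            granularity="frame",
        ),
        _p_paganin,
    )
    reg.register(
        PluginSpec(
            "neg_log",
            Space.PROJECTION,
            Space.PROJECTION,
            {},
            citation="Beer-Lambert attenuation line integrals",
            granularity="frame",
        ),
        _p_neg_log,
    )
    reg.register(
        PluginSpec(
            "to_sinograms",
            Space.PROJECTION,
            Space.SINOGRAM,
            {},
            citation="projection-to-sinogram axis permutation",
            granularity="global",
        ),
        _p_to_sinograms,
    )
    reg.register(
        PluginSpec(
            "com_align",
            Space.SINOGRAM,
            Space.SINOGRAM,
            {},
            citation="centre-of-mass sine-fit hysteresis alignment",
            granularity="slice",
        ),
        _p_com_align,
    )
    reg.register(
        PluginSpec(
            "remove_rings",
            Space.SINOGRAM,
            Space.SINOGRAM,
            {"smooth_window": {"default": 21}},
            citation="mean-profile residual stripe suppression",
            granularity="slice",
        ),
        _p_remove_rings,
    )
    reg.register(
        PluginSpec(
            "fbp",
            Space.SINOGRAM,
            Space.IMAGE,
            {
                "filter_window": {"default": "ramp"},
                "cor_offset_px": {"default": 0.0},
                "pad_factor": {"default": 4},
            },
            citation="parallel-beam filtered back projection",
            granularity="slice",
        ),
        _p_fbp,
    )
    return reg


def standard_absorption_list(
    cor_offset_px: float = 0.0,
    smooth_window: int = 21,
    com_align: bool = False,
    description: str = "standard absorption tomography chain",
) -> ProcessList:
    """The recommended detector -> image chain for plain absorption scans."""
    plist = ProcessList(description=description)
    plist.add("remove_outliers")
    plist.add("flat_dark")
    plist.add("neg_log")
    plist.add("to_sinograms")
    if com_align:
        plist.add("com_align")
    plist.add("remove_rings", smooth_window=smooth_window)
    plist.add("fbp", cor_offset_px=cor_offset_px)
    return plist
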