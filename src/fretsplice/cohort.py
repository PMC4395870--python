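"""End-to-end synthetic embryo cohorts for power and calibration studies.

A cohort is a set of embryos imaged under identical conditions; each
embryo is rendered as an independent Poisson realization of the same
scene, pushed through the full index pipeline, and reduced to its pooled
SDR / non-SDR means.  The paired SDR-vs-non-SDR difference across the
cohort then feeds the paired t-test, which is how operating
characteristics (power at a given efficiency contrast, size under the
null, null p-value uniformity for the force-insensitive construct) are
measured.
"""

from __future__ import annotations

import numpy as np

from .fret import CalibrationParams, ChannelStack, compute_fret_map
from .roistats import RoiSpec, extract_roi_values, paired_test, pool_embryo
from .synthetic import (
    ForwardModelParams,
    TensionScene,
    _noiseless_channels,
    make_embryo_scene,
)

__all__ = ["default_calibration", "simulate_cohort", "cohort_pvalues"]


def default_calibration(params: ForwardModelParams, bin_factor: int = 1) -> CalibrationParams:
    """Calibration matching the forward model's optics exactly."""
    return CalibrationParams(
        alpha=params.alpha,
        delta=params.delta,
        QD=params.QD,
        phi_ratio=params.phi_ratio,
        noise_gain=1.0,
        threshold_k=2.0,
        bin_factor=bin_factor,
    )


def simulate_cohort(
    scene: TensionScene,
    params: ForwardModelParams,
    calib: CalibrationParams,
    n_embryos: int = 10,
    n_frames: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled SDR and non-SDR means for ``n_embryos`` independent embryos.

    The noiseless channel expectations are computed once per scene and each
    embryo/frame draws its own Poisson realization, so a cohort costs
    little more than its noise draws.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scene.seed))
    ID0, IA0, IF0 = _noiseless_channels(scene, params)
    bg = float(params.background)
    roi = RoiSpec(sdr_box=scene.sdr_box, embryo_mask=scene.embryo_mask)
    roi_b = roi.binned(calib.bin_factor)
    sdr = np.empty(n_embryos)
    nonsdr = np.empty(n_embryos)
    for e in range(n_embryos):
        if params.noise == "poisson":
            draws = rng.poisson(np.broadcast_to(
                np.stack([ID0, IA0, IF0]), (n_frames, 3, *ID0.shape)
            )).astype(np.float64)
            stack = ChannelStack(
                ID=draws[:, 0], IA=draws[:, 1], IF=draws[:, 2],
                background={"ID": bg, "IA": bg, "IF": bg},
            )
        else:
            stack = ChannelStack(
                ID=np.broadcast_to(ID0, (n_frames, *ID0.shape)).copy(),
                IA=np.broadcast_to(IA0, (n_frames, *IA0.shape)).copy(),
                IF=np.broadcast_to(IF0, (n_frames, *IF0.shape)).copy(),
                background={"ID": bg, "IA": bg, "IF": bg},
            )
        fmap = compute_fret_map(stack, calib)
        frames = extract_roi_values(fmap, roi_b)
        m = pool_embryo(frames, embryo_id=f"e{e}", construct=scene.construct)
        sdr[e] = m.sdr_mean
        nonsdr[e] = m.nonsdr_mean
    return sdr, nonsdr


def cohort_pvalues(
    scene: TensionScene,
    params: ForwardModelParams,
    calib: CalibrationParams,
    n_cohorts: int,
    n_embryos: int = 10,
    n_frames: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Paired-test p-values across independent replicate cohorts."""
    pvals = np.empty(n_cohorts)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_cohorts)):
        rng = np.random.default_rng(child)
        sdr, nonsdr = simulate_cohort(scene, params, calib, n_embryos, n_frames, rng)
        pvals[i] = paired_test(sdr, nonsdr).pvalue
    return pvals


def scene_with_contrast(
    delta_e: float,
    params: ForwardModelParams,
    e_out: float = 0.30,
    shape: tuple[int, int] = (48, 72),
    construct: str = "TSMod",
    seed: int = 0,
) -> TensionScene:
    """Scene whose SDR sits ``delta_e`` efficiency units below the rest.

    Forces are chosen by inverting the spring/Förster relation so that the
    non-SDR cortex reads ``e_out`` and the SDR ``e_out - delta_e`` — the
    natural way to pose "a contrast of X efficiency units" for power
    studies.  A force-insensitive construct ignores the contrast entirely.
    """
    from .synthetic import fret_to_force

    if delta_e < 0 or e_out - delta_e <= 0:
        raise ValueError("need 0 <= delta_e < e_out")
    f_out = fret_to_force(e_out, params)
    f_sdr = fret_to_force(e_out - delta_e, params) if delta_e > 0 else f_out
    return make_embryo_scene(
        shape=shape,
        force_base=f_out,
        force_sdr=f_sdr,
        sdr_size=(12, 8),
        construct=construct,
        seed=seed,
    )
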