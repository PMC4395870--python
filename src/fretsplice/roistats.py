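"""ROI extraction, per-embryo pooling and the statistical test battery.

Every embryo contributes two regions of interest: a small box over the
sensory depression region (SDR, the putative pharynx attachment site) and
the remainder of the embryo (non-SDR).  Comparing the two *within* one
image makes the contrast independent of sensor expression level, bleaching
and acquisition settings, since every pixel shares the same history.
FRET-index values from the 3–5 z-frames spanning the buccal cavity are
pooled per embryo, and the pooled mean is the experimental unit entering
the tests: a paired two-tailed t-test within embryos, a two-sample t-test
between groups, with normality (Jarque–Bera), equal variance (Levene) and
a distribution-free cross-check (Mann–Whitney U).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fret import ChannelStack, FretMap

__all__ = [
    "RoiSpec",
    "EmbryoMeasurement",
    "TestResult",
    "extract_roi_values",
    "pool_embryo",
    "paired_test",
    "unpaired_test",
    "assumption_checks",
    "mann_whitney",
    "expression_independence",
]

log = logging.getLogger(__name__)


class RoiError(ValueError):
    """Raised when an ROI selection is empty or inconsistent."""


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    note: str = ""


@dataclass
class RoiSpec:
    """SDR box plus embryo footprint; non-SDR is the footprint minus the box.

    ``sdr_box`` is (row0, row1, col0, col1), half-open, 0-based, in the
    coordinates of the FRET map it will be applied to (i.e. post-binning
    coordinates if the map was binned).
    """

    sdr_box: tuple[int, int, int, int]
    embryo_mask: np.ndarray

    def __post_init__(self) -> None:
        self.embryo_mask = np.asarray(self.embryo_mask, dtype=bool)
        r0, r1, c0, c1 = self.sdr_box
        h, w = self.embryo_mask.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise RoiError(f"sdr_box {self.sdr_box} out of bounds for mask {h}x{w}")
        if not self.sdr_mask.any():
            raise RoiError("SDR ROI contains no embryo pixels")
        if not self.nonsdr_mask.any():
            raise RoiError("non-SDR ROI is empty")

    @property
    def sdr_mask(self) -> np.ndarray:
        r0, r1, c0, c1 = self.sdr_box
        box = np.zeros_like(self.embryo_mask)
        box[r0:r1, c0:c1] = True
        return box & self.embryo_mask

    @property
    def nonsdr_mask(self) -> np.ndarray:
        r0, r1, c0, c1 = self.sdr_box
        box = np.zeros_like(self.embryo_mask)
        box[r0:r1, c0:c1] = True
        return self.embryo_mask & ~box

    def binned(self, factor: int) -> "RoiSpec":
        """ROI in the coordinates of a map binned by ``factor``.

        A binned embryo pixel is kept if any contributing pixel was embryo.
        """
        if factor == 1:
            return self
        h, w = self.embryo_mask.shape
        hb, wb = h // factor, w // factor
        m = self.embryo_mask[: hb * factor, : wb * factor]
        mask = m.reshape(hb, factor, wb, factor).any(axis=(1, 3))
        r0, r1, c0, c1 = self.sdr_box
        box = (r0 // factor, max(r1 // factor, r0 // factor + 1),
               c0 // factor, max(c1 // factor, c0 // factor + 1))
        return RoiSpec(sdr_box=box, embryo_mask=mask)


@dataclass
class EmbryoMeasurement:
    """Pooled per-embryo FRET means; the experimental unit of the study."""

    embryo_id: str
    stage: str
    construct: str
    sdr_mean: float
    nonsdr_mean: float
    n_frames: int
    n_valid_sdr: int
    n_valid_nonsdr: int


def extract_roi_values(fret_map: FretMap, roi: RoiSpec) -> pd.DataFrame:
    """Per-frame valid-pixel mean FRET in the SDR and non-SDR.

    Frames in which either ROI retains no valid pixel are dropped with a
    logged warning; if no frame survives, an error is raised.
    """
    sdr, nonsdr = roi.sdr_mask, roi.nonsdr_mask
    if sdr.shape != fret_map.F.shape[1:]:
        raise RoiError(
            f"ROI mask {sdr.shape} does not match map frames {fret_map.F.shape[1:]}"
        )
    rows = []
    for t in range(fret_map.n_frames):
        v = fret_map.valid_mask[t]
        vs, vn = v & sdr, v & nonsdr
        ns, nn = int(vs.sum()), int(vn.sum())
        if ns == 0 or nn == 0:
            log.warning("frame %d dropped: empty valid ROI (sdr=%d, nonsdr=%d)", t, ns, nn)
            continue
        rows.append(
            {
                "frame": t,
                "sdr_mean": float(fret_map.F[t][vs].mean()),
                "nonsdr_mean": float(fret_map.F[t][vn].mean()),
                "n_valid_sdr": ns,
                "n_valid_nonsdr": nn,
            }
        )
    if not rows:
        raise RoiError("all frames dropped: no valid pixels in one or both ROIs")
    return pd.DataFrame(rows)


def pool_embryo(
    frame_values: pd.DataFrame,
    embryo_id: str = "embryo",
    stage: str = "1.5-fold",
    construct: str = "TSMod",
) -> EmbryoMeasurement:
    """Unweighted mean across retained frames for each ROI."""
    if len(frame_values) < 1:
        raise RoiError("no frames to pool")
    return EmbryoMeasurement(
        embryo_id=embryo_id,
        stage=stage,
        construct=construct,
        sdr_mean=float(frame_values["sdr_mean"].mean()),
        nonsdr_mean=float(frame_values["nonsdr_mean"].mean()),
        n_frames=int(len(frame_values)),
        n_valid_sdr=int(frame_values["n_valid_sdr"].sum()),
        n_valid_nonsdr=int(frame_values["n_valid_nonsdr"].sum()),
    )


def _degenerate_diff_result(diffs: np.ndarray) -> TestResult | None:
    if np.ptp(diffs) == 0:
        if diffs[0] == 0:
            return TestResult(0.0, 1.0, note="all differences zero")
        warnings.warn(
            "zero variance of paired differences; p-value is the exact limit 0",
            stacklevel=3,
        )
        return TestResult(np.inf if diffs[0] > 0 else -np.inf, 0.0,
                          note="zero-variance differences")
    return None


def paired_test(sdr_means, nonsdr_means) -> TestResult:
    """Two-tailed paired t-test on per-embryo SDR minus non-SDR differences."""
    a = np.asarray(sdr_means, dtype=np.float64)
    b = np.asarray(nonsdr_means, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("paired test requires n >= 2 embryos")
    deg = _degenerate_diff_result(a - b)
    if deg is not None:
        return deg
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), float(p))


def unpaired_test(group_a, group_b, equal_var: bool = True) -> TestResult:
    """Two-tailed two-sample t-test (classical pooled-variance by default).

    Welch's correction is available with ``equal_var=False`` for groups
    failing the equal-variance check.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample test requires n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TestResult(0.0, 1.0, note="all values equal")
        warnings.warn("zero within-group variance; p-value is the exact limit 0",
                      stacklevel=2)
        return TestResult(np.inf if a[0] > b[0] else -np.inf, 0.0,
                          note="zero-variance groups")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(float(t), float(p))


def assumption_checks(*groups) -> dict:
    """Normality (Jarque–Bera, per group) and equal variance (Levene).

    The Jarque–Bera statistic is ``n/6 * (S**2 + K**2/4)`` with sample
    skewness S and excess kurtosis K, referred to chi-square(2).  Levene's
    test uses absolute deviations from the group *means* (the original
    formulation, not the median-centred Brown–Forsythe variant).
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if not arrays:
        raise ValueError("at least one group required")
    jb = []
    for g in arrays:
        if g.size < 3:
            raise ValueError("Jarque-Bera requires n >= 3")
        stat, p = stats.jarque_bera(g)
        jb.append(TestResult(float(stat), float(p)))
    out = {"jarque_bera": jb if len(jb) > 1 else jb[0]}
    if len(arrays) >= 2:
        stat, p = stats.levene(*arrays, center="mean")
        out["levene"] = TestResult(float(stat), float(p))
    return out


def mann_whitney(group_a, group_b, exact_cutoff: int = 20) -> TestResult:
    """Two-tailed Mann–Whitney U with mid-rank tie handling.

    Exact enumeration of the U null distribution for small tie-free
    samples (both n <= ``exact_cutoff``); otherwise the tie-corrected
    normal approximation.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size <= exact_cutoff and b.size <= exact_cutoff and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), note=method)


def expression_independence(fret_map: FretMap, stack: ChannelStack) -> TestResult:
    """Pearson r between valid-pixel FRET index and raw acceptor counts.

    For an intramolecular sensor the index must not track expression level;
    a strong correlation indicates intermolecular transfer.  Returns NaN
    with a note if either input is constant across valid pixels.
    """
    v = fret_map.valid_mask
    if stack.IA.shape != v.shape:
        raise RoiError("stack and FRET map shapes differ")
    if int(v.sum()) < 10:
        raise RoiError("need at least 10 valid pixels for the independence check")
    f = fret_map.F[v]
    ia = stack.IA[v]
    if np.ptp(f) == 0 or np.ptp(ia) == 0:
        return TestResult(np.nan, np.nan, note="degenerate (constant) input")
    r, p = stats.pearsonr(f, ia)
    return TestResult(float(r), float(p))


def measurements_frame(measurements: list[EmbryoMeasurement]) -> pd.DataFrame:
    """Embryo-level results table (one row per embryo)."""
    return pd.DataFrame(
        [
            {
                "embryo_id": m.embryo_id,
                "stage": m.stage,
                "construct": m.construct,
                "sdr_mean": m.sdr_mean,
                "nonsdr_mean": m.nonsdr_mean,
                "n_frames": m.n_frames,
            }
            for m in measurements
        ]
    )
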