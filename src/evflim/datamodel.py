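"""Core containers for TCSPC fluorescence-lifetime image data.

A FLIM acquisition produces, for every pixel of a field of view, a histogram
of photon arrival delays relative to the excitation pulse.  The containers
here hold that 3-D (row, col, time-bin) photon-count array together with the
time base and acquisition metadata, plus the instrument response function
(IRF) and integer label masks used downstream.

Unit conventions
----------------
* time-base metadata (bin width, period, origin) in **picoseconds**;
* fluorescence lifetimes in **nanoseconds**;
* pixel size in micrometres per pixel;
* coordinates are 0-based ``(row, col)`` with pixel centres on the integer
  lattice; times refer to bin centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "TimeAxis",
    "DecayStack",
    "InstrumentResponse",
    "LabelMask",
    "default_collection_axis",
    "default_analysis_axis",
    "rebin_time",
    "integrate_intensity",
    "PROTOCOL_FOV_UM",
    "PROTOCOL_FOV_PX",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: Field-of-view extent and pixel grid of the acquisition protocol being
#: emulated (180 x 180 um^2 imaged onto 512 x 512 pixels).
PROTOCOL_FOV_UM = 180.0
PROTOCOL_FOV_PX = 512
DEFAULT_PIXEL_SIZE_UM = PROTOCOL_FOV_UM / PROTOCOL_FOV_PX


@dataclass(frozen=True)
class TimeAxis:
    """Uniform TCSPC time base within one laser repetition period.

    Parameters
    ----------
    bin_width_ps : float
        Width of one histogram bin in picoseconds.
    n_bins : int
        Number of bins in the collection window.
    period_ps : float
        Laser repetition period.  The angular repetition frequency
        ``omega = 2*pi/period`` enters every phasor computation.
    origin_ps : float
        Left edge of the first bin (usually 0).
    """

    bin_width_ps: float
    n_bins: int
    period_ps: float
    origin_ps: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width_ps <= 0:
            raise ValueError(f"bin_width_ps must be > 0, got {self.bin_width_ps}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.period_ps <= 0:
            raise ValueError(f"period_ps must be > 0, got {self.period_ps}")
        window = self.n_bins * self.bin_width_ps
        if window > self.period_ps * (1.0 + 1e-9):
            raise ValueError(
                f"collection window {window} ps exceeds repetition period "
                f"{self.period_ps} ps"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def window_ps(self) -> float:
        """Total collection window in ps."""
        return self.n_bins * self.bin_width_ps

    @property
    def centers_ps(self) -> np.ndarray:
        """Bin centres t_k = origin + (k + 1/2) * bin_width, in ps."""
        return self.origin_ps + (np.arange(self.n_bins) + 0.5) * self.bin_width_ps

    @property
    def centers_ns(self) -> np.ndarray:
        return self.centers_ps / 1000.0

    @property
    def edges_ns(self) -> np.ndarray:
        """n_bins + 1 bin edges in ns."""
        return (self.origin_ps + np.arange(self.n_bins + 1) * self.bin_width_ps) / 1000.0

    @property
    def bin_width_ns(self) -> float:
        return self.bin_width_ps / 1000.0

    @property
    def period_ns(self) -> float:
        return self.period_ps / 1000.0

    def omega_ns(self, harmonic: int = 1) -> float:
        """Angular frequency of the given harmonic, in rad/ns."""
        if harmonic < 1:
            raise ValueError("harmonic must be >= 1")
        return harmonic * 2.0 * math.pi / self.period_ns

    def rebinned(self, factor: int, allow_partial: bool = False) -> "TimeAxis":
        """Axis obtained by summing groups of `factor` adjacent bins."""
        if factor < 1 or int(factor) != factor:
            raise ValueError(f"rebin factor must be a positive integer, got {factor}")
        factor = int(factor)
        n_out = self.n_bins // factor
        if n_out * factor != self.n_bins and not allow_partial:
            raise ValueError(
                f"{self.n_bins} bins do not divide into groups of {factor}; "
                "pass allow_partial=True to drop trailing bins"
            )
        if n_out < 2:
            raise ValueError("rebinning would leave fewer than 2 bins")
        return TimeAxis(
            bin_width_ps=self.bin_width_ps * factor,
            n_bins=n_out,
            period_ps=self.period_ps,
            origin_ps=self.origin_ps,
        )


def default_collection_axis() -> TimeAxis:
    """8 ps collection bins, 1536 bins, window tiling the repetition period.

    The emulated protocol collects at 8 ps and analyses at 128 ps.  The
    repetition period defaults to the collection window (12.288 ns,
    ~81.4 MHz): when the binned window tiles the period exactly, the discrete
    phasor of a periodic decay matches the continuous-time transform to
    numerical precision (see the phasor module).
    """
    return TimeAxis(bin_width_ps=8.0, n_bins=1536, period_ps=12288.0)


def default_analysis_axis() -> TimeAxis:
    """128 ps analysis bins: the collection axis rebinned by 16."""
    return default_collection_axis().rebinned(16)


@dataclass(frozen=True)
class DecayStack:
    """Per-pixel photon-count decay histograms for one field of view."""

    counts: np.ndarray  # (rows, cols, n_bins), non-negative integers
    axis: TimeAxis
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frames_accumulated: int = 20
    fov_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError(f"counts must be 3-D (row, col, time), got shape {c.shape}")
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError(f"counts must have an integer dtype, got {c.dtype}")
        if c.shape[2] != self.axis.n_bins:
            raise ValueError(
                f"counts has {c.shape[2]} time bins but axis declares {self.axis.n_bins}"
            )
        if c.size and int(c.min()) < 0:
            raise ValueError("counts must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "counts", c)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    def total_photons(self) -> int:
        return int(self.counts.sum(dtype=np.int64))


@dataclass(frozen=True)
class InstrumentResponse:
    """Instrument response function, measured or parametric Gaussian.

    ``kind="measured"`` carries a histogram on a :class:`TimeAxis`;
    ``kind="gaussian"`` is parameterised by its FWHM and peak position t0.
    A Gaussian with ``fwhm_ps == 0`` degenerates to an ideal (delta)
    response at t0, which is convenient in tests.
    """

    kind: str
    histogram: np.ndarray | None = None
    axis: TimeAxis | None = None
    fwhm_ps: float | None = None
    t0_ps: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "measured":
            if self.histogram is None or self.axis is None:
                raise ValueError("measured IRF requires histogram and axis")
            h = np.asarray(self.histogram, dtype=float)
            if h.ndim != 1 or h.shape[0] != self.axis.n_bins:
                raise ValueError("IRF histogram length must match its axis")
            if h.min() < 0:
                raise ValueError("IRF histogram must be non-negative")
            if h.sum() <= 0:
                raise ValueError("measured IRF histogram total must be > 0")
            object.__setattr__(self, "histogram", h)
        elif self.kind == "gaussian":
            if self.fwhm_ps is None or self.fwhm_ps < 0:
                raise ValueError("gaussian IRF requires fwhm_ps >= 0")
        else:
            raise ValueError(f"unknown IRF kind {self.kind!r}")

    @property
    def sigma_ns(self) -> float:
        if self.kind != "gaussian":
            raise ValueError("sigma_ns is defined for gaussian IRFs only")
        return self.fwhm_ps / (2.0 * math.sqrt(2.0 * math.log(2.0))) / 1000.0

    @property
    def t0_ns(self) -> float:
        return self.t0_ps / 1000.0


def default_irf() -> InstrumentResponse:
    """Gaussian IRF, FWHM 250 ps, peak at 0.6 ns: a typical hybrid-detector
    TCSPC response."""
    return InstrumentResponse(kind="gaussian", fwhm_ps=250.0, t0_ps=600.0)


@dataclass(frozen=True)
class LabelMask:
    """Integer label image; 0 is background, each nonzero label is named."""

    labels: np.ndarray
    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must have an integer dtype")
        if lab.size and int(lab.min()) < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(lab).tolist()) - {0}
        missing = present - set(int(k) for k in self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "legend", dict(self.legend))

    @property
    def labels_present(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})


# -- operations --------------------------------------------------------------


def rebin_time(stack: DecayStack, factor: int, allow_partial: bool = False) -> DecayStack:
    """Sum groups of `factor` adjacent time bins.

    Photons are conserved exactly over the retained range; trailing bins that
    do not fill a group are dropped only when ``allow_partial`` is set.
    """
    new_axis = stack.axis.rebinned(factor, allow_partial=allow_partial)
    factor = int(factor)
    n_keep = new_axis.n_bins * factor
    c = stack.counts[:, :, :n_keep]
    rebinned = c.reshape(c.shape[0], c.shape[1], new_axis.n_bins, factor).sum(
        axis=3, dtype=np.int64
    )
    # keep a compact dtype when the totals allow it
    if rebinned.size and rebinned.max() <= np.iinfo(np.uint32).max:
        rebinned = rebinned.astype(np.uint32)
    return replace(stack, counts=rebinned, axis=new_axis)


def integrate_intensity(stack: DecayStack) -> np.ndarray:
    """Total photon count per pixel (the intensity image)."""
    return stack.counts.sum(axis=2, dtype=np.int64)
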