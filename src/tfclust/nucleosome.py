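"""Nucleosome positioning strength (FFT power at the repeat length) and
central depletion around region sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genomic_io import GenomicInterval, SignalTrack

__all__ = [
    "OccupancyProfile",
    "PositioningSpectrum",
    "DepletionStat",
    "anchored_occupancy",
    "positioning_power",
    "dominant_period",
    "nucleosome_depletion",
]


@dataclass
class OccupancyProfile:
    """Mean per-offset occupancy anchored on region centres."""

    offsets: np.ndarray      # -flank .. +flank at 1 bp
    values: np.ndarray
    n_regions: int

    @property
    def flank(self) -> int:
        return int(self.offsets[-1])


def anchored_occupancy(
    regions: list[GenomicInterval], track: SignalTrack, flank: int = 2000
) -> OccupancyProfile:
    """Average the track over +-flank around each region centre (1 bp grid)."""
    if not regions:
        raise ValueError("no regions")
    acc = np.zeros(2 * flank + 1)
    n = 0
    for iv in regions:
        c = iv.midpoint
        if c - flank < 0:
            warnings.warn(f"region at {iv.chrom}:{c} too close to chromosome edge; skipped")
            continue
        acc += track.values(iv.chrom, c - flank, c + flank + 1)
        n += 1
    if n == 0:
        raise ValueError("no usable regions")
    return OccupancyProfile(np.arange(-flank, flank + 1), acc / n, n)


@dataclass
class PositioningSpectrum:
    """Magnitude spectrum of the mean-subtracted occupancy profile."""

    frequencies: np.ndarray   # cycles per bp
    power: np.ndarray         # raw DFT magnitudes
    repeat_length: int
    power_at_repeat: float


def positioning_power(
    profile: OccupancyProfile, repeat_length: int = 200
) -> PositioningSpectrum:
    """Raw DFT magnitude of the mean-subtracted profile; the positioning
    strength is the magnitude at the frequency bin nearest 1/repeat_length.

    No taper or normalisation is applied, so magnitudes are comparable only
    between profiles of equal length.
    """
    if repeat_length <= 0:
        raise ValueError("repeat_length must be > 0")
    x = profile.values - profile.values.mean()
    if len(x) < 4 * repeat_length:
        raise ValueError("profile too short for the requested repeat length")
    power = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0)
    idx = int(np.argmin(np.abs(freqs - 1.0 / repeat_length)))
    return PositioningSpectrum(freqs, power, repeat_length, float(power[idx]))


def dominant_period(
    spectrum: PositioningSpectrum, band: tuple[float, float] = (150.0, 250.0)
) -> float:
    """Period (bp) of the strongest component within a period band."""
    lo, hi = band
    mask = (spectrum.frequencies > 0) & \
        (1.0 / np.maximum(spectrum.frequencies, 1e-12) >= lo) & \
        (1.0 / np.maximum(spectrum.frequencies, 1e-12) <= hi)
    if not mask.any():
        raise ValueError("no frequency bins in the requested band")
    idx = np.nonzero(mask)[0][np.argmax(spectrum.power[mask])]
    return float(1.0 / spectrum.frequencies[idx])


@dataclass
class DepletionStat:
    """Background-minus-centre occupancy difference D."""

    depletion: float
    centre_halfwidth: int
    bg_offset: int
    bg_halfwidth: int


def nucleosome_depletion(
    profile: OccupancyProfile,
    centre_halfwidth: int = 50,
    bg_offset: int = 2000,
    bg_halfwidth: int = 100,
) -> DepletionStat:
    """D = mean occupancy in the two background windows minus the centre mean.

    Background windows sit just inside +-bg_offset: offsets o with
    bg_offset - 2*bg_halfwidth <= |o| <= bg_offset. Positive D means the
    centre is depleted.
    """
    offs = profile.offsets
    if bg_offset > profile.flank:
        raise ValueError("background window outside the profile")
    if bg_offset - 2 * bg_halfwidth <= centre_halfwidth:
        raise ValueError("background window overlaps the centre window")
    centre = profile.values[np.abs(offs) <= centre_halfwidth]
    bg_mask = (np.abs(offs) >= bg_offset - 2 * bg_halfwidth) & (np.abs(offs) <= bg_offset)
    bg = profile.values[bg_mask]
    return DepletionStat(
        float(bg.mean() - centre.mean()), centre_halfwidth, bg_offset, bg_halfwidth
    )
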