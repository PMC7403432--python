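"""Synthetic MALDI-TOF spectra, peak picking, annotation and normalization.

The measurement model is deliberately simple: each panel species contributes
a Gaussian peak at its theoretical permethylated [M+Na]+ m/z with area
proportional to its relative abundance, on a uniform m/z grid spanning the
1,500-5,000 Da acquisition window, plus a flat baseline and white Gaussian
noise.  Isotope envelopes, matrix clusters and multiply charged ions are not
modeled; the monoisotopic centroid stands for the species.

Peak intensities are quantified as apex height of the centroided maximum
(log-parabolic apex interpolation, which is exact for noise-free Gaussian
peaks), and relative abundance is the per-species height divided by the
summed height of all panel species, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .glycan_core import ACQUISITION_WINDOW, GlycanPanel

__all__ = [
    "Spectrum",
    "PeakList",
    "GlycomeProfile",
    "SynthesisParams",
    "synthesize_spectrum",
    "pick_peaks",
    "annotate",
    "normalize",
    "read_spectrum",
    "write_spectrum",
    "read_mzml",
    "profiles_to_frame",
    "frame_to_profiles",
]


@dataclass
class Spectrum:
    """One acquisition: strictly increasing m/z grid and intensities >= 0."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class PeakList:
    """Centroided peaks: (centroid m/z, apex height), sorted by m/z."""

    centroids: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.centroids.shape != self.heights.shape:
            raise ValueError("centroids and heights must have equal length")
        if self.centroids.size and np.any(np.diff(self.centroids) < 0):
            raise ValueError("centroids must be sorted")
        if np.any(self.heights <= 0):
            raise ValueError("peak heights must be positive")

    def __len__(self):
        return self.centroids.size


@dataclass
class GlycomeProfile:
    """Relative abundances (percent of total panel signal) for one sample."""

    sample_id: str
    abundance: dict  # short_name -> percent

    def __post_init__(self):
        vals = np.array(list(self.abundance.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("abundances must be non-negative")
        if abs(vals.sum() - 100.0) > 1e-6:
            raise ValueError(f"abundances must sum to 100, got {vals.sum():.8f}")

    def vector(self, panel: GlycanPanel) -> np.ndarray:
        return np.array([self.abundance[n] for n in panel.short_names])


@dataclass(frozen=True)
class SynthesisParams:
    """Instrument-emulation knobs for :func:`synthesize_spectrum`.

    peak_sigma:  Gaussian peak width (SD), Da.
    baseline:    flat baseline level, intensity units.
    noise_sd:    white-noise SD, intensity units.
    grid_step:   m/z grid spacing, Da.
    total_signal: summed peak area of the full panel, intensity units*Da.
    """

    peak_sigma: float = 0.3
    baseline: float = 0.0
    noise_sd: float = 0.0
    grid_step: float = 0.2
    total_signal: float = 1.0e5


def synthesize_spectrum(
    profile: GlycomeProfile,
    panel: GlycanPanel,
    params: SynthesisParams = SynthesisParams(),
    seed: int | np.random.Generator = 0,
) -> Spectrum:
    """Render a profile as a synthetic spectrum; deterministic given seed."""
    unknown = set(profile.abundance) - set(panel.short_names)
    if unknown:
        raise ValueError(f"profile contains species absent from panel: {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = ACQUISITION_WINDOW
    grid = np.arange(lo, hi + params.grid_step / 2, params.grid_step)
    intensity = np.full(grid.shape, float(params.baseline))
    sigma = params.peak_sigma
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    for sp in panel:
        frac = profile.abundance.get(sp.short_name, 0.0) / 100.0
        if frac <= 0:
            continue
        area = params.total_signal * frac
        center = sp.theoretical_mz
        w = np.abs(grid - center) < 6 * sigma
        intensity[w] += area * norm * np.exp(-0.5 * ((grid[w] - center) / sigma) ** 2)
    if params.noise_sd > 0:
        intensity += rng.normal(0.0, params.noise_sd, size=grid.shape)
        np.clip(intensity, 0.0, None, out=intensity)
    return Spectrum(mz=grid, intensity=intensity, sample_id=profile.sample_id)


def _apex_height(y0: float, y1: float, y2: float, baseline: float) -> float:
    """Apex of a Gaussian peak from three samples around the maximum.

    Fits a parabola through the log of the baseline-subtracted triplet;
    exact for pure Gaussian samples.  Falls back to the raw maximum when a
    flank is at/below baseline or the curvature is non-concave.
    """
    a, b, c = y0 - baseline, y1 - baseline, y2 - baseline
    if a <= 0 or c <= 0 or b <= a or b <= c:
        return max(y1 - baseline, 0.0)
    la, lb, lc = np.log(a), np.log(b), np.log(c)
    denom = la - 2 * lb + lc
    if denom >= 0:
        return b
    delta = 0.5 * (la - lc) / denom
    return float(np.exp(lb - 0.25 * delta * (la - lc)))


def pick_peaks(
    spectrum: Spectrum,
    min_snr: float = 3.0,
    window_da: float = 1.5,
) -> PeakList:
    """Detect local maxima above baseline + ``min_snr`` x noise and centroid them.

    Baseline is estimated as the global median (peaks are sparse over the
    3,500 Da window) and noise as the upper-side quantile spread
    (84.1th percentile minus median, one sigma for Gaussian noise), which
    stays calibrated when the noise floor is clipped at zero.  The centroid
    is the intensity-weighted mean over ± ``window_da``; the height is the
    log-parabolic apex of the three samples around the maximum.
    """
    y = spectrum.intensity
    if y.size == 0:
        raise ValueError("empty spectrum")
    x = spectrum.mz
    baseline = float(np.median(y))
    noise = float(np.quantile(y, 0.8413)) - baseline
    threshold = baseline + min_snr * noise
    above = (y > threshold) & (y > baseline)
    # strict local maxima (ties broken to the left-most sample of a plateau)
    idx = np.flatnonzero(above[1:-1] & (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    if idx.size == 0:
        return PeakList(np.empty(0), np.empty(0))
    step = float(np.median(np.diff(x)))
    half = max(int(round(window_da / step)), 1)
    centroids, heights = [], []
    for k, i in enumerate(idx):
        lo, hi = max(i - half, 0), min(i + half + 1, y.size)
        # truncate at the midpoint to adjacent peaks so a close neighbor's
        # flank cannot drag the centroid
        if k > 0:
            lo = max(lo, (idx[k - 1] + i) // 2 + 1)
        if k + 1 < idx.size:
            hi = min(hi, (i + idx[k + 1]) // 2 + 1)
        w = np.clip(y[lo:hi] - baseline, 0.0, None)
        if w.sum() <= 0:
            continue
        centroids.append(float(np.dot(x[lo:hi], w) / w.sum()))
        heights.append(_apex_height(y[i - 1], y[i], y[i + 1], baseline))
    order = np.argsort(centroids)
    c = np.array(centroids)[order]
    h = np.array(heights)[order]
    keep = h > 0
    return PeakList(c[keep], h[keep])


def annotate(
    peaks: PeakList,
    panel: GlycanPanel,
    tolerance: float = GlycanPanel.DEFAULT_TOLERANCE,
):
    """Assign peaks to the nearest panel species within ``tolerance`` Da.

    Each peak goes to at most one species (ties to the lower-m/z species);
    heights of multiple peaks matching one species are summed; species
    without a matching peak get height 0.  Returns ``(heights, unassigned)``
    where ``unassigned`` is the list of unmatched centroids for QC.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    mzs = panel.mz_values
    names = panel.short_names
    order = np.argsort(mzs, kind="stable")
    heights = {n: 0.0 for n in names}
    unassigned = []
    for c, h in zip(peaks.centroids, peaks.heights):
        d = np.abs(mzs - c)
        best = np.min(d)
        if best <= tolerance:
            # ties resolved toward the lower-m/z species
            cand = np.flatnonzero(np.isclose(d, best))
            j = cand[np.argmin(mzs[cand])]
            heights[names[j]] += float(h)
        else:
            unassigned.append(float(c))
    return heights, unassigned


def normalize(heights: Mapping[str, float], sample_id: str = "") -> GlycomeProfile:
    """Convert raw per-species heights to percent of total panel signal."""
    total = float(sum(heights.values()))
    if total <= 0:
        raise ValueError(
            "all species heights are zero: spectrum carries no interpretable panel signal"
        )
    abundance = {k: 100.0 * v / total for k, v in heights.items()}
    # absorb float round-off into the most abundant species so the sum is
    # exactly 100 and no near-zero species can dip negative
    s = sum(abundance.values())
    if s != 100.0:
        top = max(abundance, key=abundance.get)
        abundance[top] += 100.0 - s
    return GlycomeProfile(sample_id=sample_id, abundance=abundance)


# ---------------------------------------------------------------------------
# I/O

def read_spectrum(path, sample_id: str = "") -> Spectrum:
    """Read a two-column (m/z, intensity) whitespace- or comma-delimited file."""
    arr = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return Spectrum(mz=arr[:, 0], intensity=arr[:, 1], sample_id=sample_id)


def write_spectrum(spectrum: Spectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.mz, spectrum.intensity]),
        fmt="%.6f\t%.6f".split("\t"),
        delimiter="\t",
        header="mz\tintensity",
    )


def read_mzml(path, sample_id: str = "") -> Spectrum:
    """Read the first MS1 spectrum of an mzML file (requires pyteomics)."""
    try:
        from pyteomics import mzml as _mzml
    except ImportError as exc:  # pragma: no cover
        raise ImportError("mzML reading requires the 'pyteomics' extra") from exc
    with _mzml.read(str(path)) as reader:
        for entry in reader:
            mz = np.asarray(entry["m/z array"], dtype=float)
            it = np.asarray(entry["intensity array"], dtype=float)
            order = np.argsort(mz)
            return Spectrum(mz=mz[order], intensity=it[order], sample_id=sample_id)
    raise ValueError(f"no spectra found in {path}")


def profiles_to_frame(profiles: Iterable[GlycomeProfile]) -> pd.DataFrame:
    """Tidy long-format table: sample_id, short_name, percent."""
    rows = [
        {"sample_id": p.sample_id, "short_name": k, "percent": v}
        for p in profiles
        for k, v in p.abundance.items()
    ]
    return pd.DataFrame(rows)


def frame_to_profiles(frame: pd.DataFrame) -> list:
    out = []
    for sid, grp in frame.groupby("sample_id", sort=False):
        out.append(
            GlycomeProfile(
                sample_id=str(sid),
                abundance=dict(zip(grp["short_name"], grp["percent"].astype(float))),
            )
        )
    return out
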