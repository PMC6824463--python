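"""S/G1 replication profiling: copy number, smoothing, peak and origin calls.

The copy-number profile is the per-bin ratio of an S-phase coverage track to
a G1 (unreplicated) track; in a two-state cell population its expected value
is 1 + f, with f the fraction of cells in which the bin is replicated.  The
profile is low-pass filtered by a Fourier transform (all components with
wavelength below a cutoff removed) and peaks are defined as local maxima
whose derivative keeps its sign for more than a persistence distance on both
sides.  An origin's fired fraction is copy number - 1, and origins fired in
at least 20% of cells are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import GenomicTrack, Origin, ValidationError

__all__ = [
    "ReplicationProfile",
    "Peak",
    "FiredOriginCall",
    "compute_copy_number",
    "fourier_smooth",
    "call_peaks",
    "call_fired_origins",
    "interorigin_distances",
    "peak_widths",
]


@dataclass
class ReplicationProfile:
    """Raw and smoothed copy-number tracks sharing one binning."""

    raw_ratio: GenomicTrack
    smoothed: GenomicTrack
    cutoff_wavelength: float

    def __post_init__(self) -> None:
        self.raw_ratio.require_same_binning(self.smoothed)


@dataclass
class Peak:
    """Local maximum of the smoothed profile passing the persistence rule."""

    chrom: str
    apex_pos: int          # 1-based bp, bin midpoint
    apex_value: float
    left_extent: int       # bp of sustained non-negative derivative before apex
    right_extent: int      # bp of sustained non-positive derivative after apex
    apex_bin: int
    fwhm: Optional[float] = None
    truncated: bool = False


@dataclass
class FiredOriginCall:
    origin: Origin
    copy_number: float
    fired_fraction: float
    fired: bool
    matched_peak: Optional[Peak] = None


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------


def compute_copy_number(
    s_track: GenomicTrack,
    g1_track: GenomicTrack,
    min_g1: float = 1.0,
    anchor: str = "modal",
    g1_reference: str = "binwise",
    g1_smooth_wavelength: float = 100_000.0,
) -> GenomicTrack:
    """Per-bin S/G1 ratio with optional normalization anchoring.

    ``anchor``:

    * ``"none"`` — plain per-bin ratio (appropriate when both libraries are
      known to be depth-matched, e.g. simulated reads).
    * ``"total"`` — S scaled so genome-wide totals match G1 first.
    * ``"modal"`` (default) — total scaling followed by division by the mode
      of the ratio distribution, so that the unreplicated background sits at
      copy number 1 even when a substantial part of the genome replicated.

    ``g1_reference`` controls how the G1 denominator is formed:

    * ``"binwise"`` (default) — the raw per-bin G1 count, which divides out
      per-bin coverage bias (mappability, GC) at the cost of doubling the
      counting noise in the ratio.
    * ``"smoothed"`` — G1 low-pass filtered at ``g1_smooth_wavelength``
      before division; corrects slowly varying bias only.
    * ``"flat"`` — each chromosome's mean G1 coverage; the minimum-variance
      choice when G1 coverage is believed uniform, as in depth-matched
      simulated libraries.

    Bins with raw G1 coverage below ``min_g1`` are flagged missing.
    """
    s_track.require_same_binning(g1_track)
    if min_g1 < 1:
        raise ValidationError("min_g1 must be >= 1")
    if anchor not in ("none", "total", "modal"):
        raise ValidationError(f"unknown anchor mode {anchor!r}")
    if g1_reference not in ("binwise", "smoothed", "flat"):
        raise ValidationError(f"unknown g1_reference mode {g1_reference!r}")
    g_total = g1_track.total()
    s_total = s_track.total()
    if g_total <= 0:
        raise ValidationError("G1 track has zero total coverage")
    if s_total <= 0:
        raise ValidationError("S track has zero total coverage")
    scale = g_total / s_total if anchor in ("total", "modal") else 1.0

    if g1_reference == "smoothed":
        denom_track = fourier_smooth(g1_track, g1_smooth_wavelength)
    else:
        denom_track = g1_track

    ratio: dict[str, np.ndarray] = {}
    for chrom, g in g1_track:
        s = s_track.data[chrom]
        if g1_reference == "flat":
            denom = np.full_like(g, np.nanmean(g))
        else:
            denom = denom_track.data[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (s * scale) / denom
        r[~np.isfinite(r)] = np.nan
        r[g < min_g1] = np.nan
        ratio[chrom] = r
    out = GenomicTrack(g1_track.bin_size, ratio, label="copy number")

    if anchor == "modal":
        mode = _ratio_mode(out)
        for chrom in out.data:
            out.data[chrom] = out.data[chrom] / mode
    return out


def _ratio_mode(track: GenomicTrack, smooth_bins: int = 11, n_hist: int = 100) -> float:
    """Mode of the ratio distribution, estimated on a lightly averaged copy.

    A moving average suppresses per-bin Poisson noise before the histogram;
    the mode is the midpoint of the fullest histogram bin between the 1st and
    99th percentiles.
    """
    vals = []
    kernel = np.ones(smooth_bins) / smooth_bins
    for _, arr in track:
        a = arr.copy()
        mask = np.isnan(a)
        if mask.all():
            continue
        if mask.any():
            idx = np.arange(len(a))
            a[mask] = np.interp(idx[mask], idx[~mask], a[~mask])
        if len(a) >= smooth_bins:
            a = np.convolve(a, kernel, mode="valid")
        vals.append(a)
    flat = np.concatenate(vals)
    lo, hi = np.percentile(flat, [1, 99])
    if hi <= lo:
        return float(np.median(flat))
    hist, edges = np.histogram(flat, bins=n_hist, range=(lo, hi))
    k = int(np.argmax(hist))
    return float((edges[k] + edges[k + 1]) / 2.0)


# ---------------------------------------------------------------------------
# Fourier smoothing
# ---------------------------------------------------------------------------


def fourier_smooth(ratio: GenomicTrack, cutoff_wavelength: float) -> GenomicTrack:
    """Low-pass filter each chromosome, removing wavelengths below the cutoff.

    Missing bins are linearly interpolated before the transform and re-flagged
    after.  Each chromosome is mirror-padded on both sides before the real
    FFT, which suppresses wrap-around artifacts; the DC component is kept, so
    the chromosome mean is preserved.
    """
    if cutoff_wavelength < 2 * ratio.bin_size:
        raise ValidationError(
            f"cutoff_wavelength must be >= 2 * bin_size "
            f"({2 * ratio.bin_size}), got {cutoff_wavelength}"
        )
    out: dict[str, np.ndarray] = {}
    for chrom, arr in ratio:
        n = len(arr)
        if n < 2:
            warnings.warn(f"chromosome {chrom} shorter than 2 bins; smoothing skipped")
            out[chrom] = arr.copy()
            continue
        mask = np.isnan(arr)
        a = arr.copy()
        if mask.all():
            out[chrom] = a
            continue
        if mask.any():
            idx = np.arange(n)
            a[mask] = np.interp(idx[mask], idx[~mask], a[~mask])
        padded = np.concatenate([a[::-1], a, a[::-1]])
        spec = np.fft.rfft(padded)
        freqs = np.fft.rfftfreq(len(padded), d=ratio.bin_size)
        # wavelength < cutoff  <=>  frequency > 1/cutoff (equality retained)
        spec[freqs > 1.0 / cutoff_wavelength + 1e-15] = 0.0
        sm = np.fft.irfft(spec, n=len(padded))[n : 2 * n]
        sm[mask] = np.nan
        out[chrom] = sm
    return GenomicTrack(ratio.bin_size, out, label="smoothed " + (ratio.label or "ratio"))


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------


def call_peaks(smoothed: GenomicTrack, persistence_bp: int = 3000) -> list[Peak]:
    """Local maxima of the smoothed profile with sign persistence.

    A peak is a point where the per-bin derivative changes from plus to
    minus and keeps a non-negative sign for more than ``persistence_bp``
    before the change point and a non-positive sign for more than
    ``persistence_bp`` after it (with at least one strictly positive step
    before and one strictly negative step after, so flat stretches are not
    peaks).  A zero-derivative plateau satisfying the rule yields one peak at
    the plateau midpoint.  Chromosome-terminal windows shorter than the
    persistence distance cannot host a peak.
    """
    if persistence_bp <= 0:
        raise ValidationError("persistence_bp must be > 0")
    m = int(persistence_bp // smoothed.bin_size) + 1  # steps covering > persistence_bp
    peaks: list[Peak] = []
    for chrom, y in smoothed:
        n = len(y)
        if n < 2 * m + 1:
            continue
        d = np.diff(y)
        nonneg = d >= 0
        nonpos = d <= 0
        pos = d > 0
        neg = d < 0
        cn = np.concatenate([[0], np.cumsum(nonneg)])
        cp = np.concatenate([[0], np.cumsum(nonpos)])
        ap = np.concatenate([[0], np.cumsum(pos)])
        an = np.concatenate([[0], np.cumsum(neg)])
        qual = np.zeros(n, dtype=bool)
        i = np.arange(m, n - m)
        # windows of derivative steps [i-m, i-1] and [i, i+m-1]
        pre_all = (cn[i] - cn[i - m]) == m
        post_all = (cp[i + m] - cp[i]) == m
        pre_any = (ap[i] - ap[i - m]) > 0
        post_any = (an[i + m] - an[i]) > 0
        qual[i] = pre_all & post_all & pre_any & post_any
        # group consecutive qualifying bins; apex = run midpoint
        idx = np.flatnonzero(qual)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s_i, e_i in zip(starts, ends):
            run = idx[s_i : e_i + 1]
            apex = int(run[(len(run)) // 2]) if len(run) % 2 else int(run[len(run) // 2 - 1])
            left = 0
            k = apex - 1
            while k >= 0 and nonneg[k]:
                left += 1
                k -= 1
            right = 0
            k = apex
            while k <= n - 2 and nonpos[k]:
                right += 1
                k += 1
            peaks.append(
                Peak(
                    chrom=chrom,
                    apex_pos=apex * smoothed.bin_size + smoothed.bin_size // 2 + 1,
                    apex_value=float(y[apex]),
                    left_extent=left * smoothed.bin_size,
                    right_extent=right * smoothed.bin_size,
                    apex_bin=apex,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# fired-origin calling
# ---------------------------------------------------------------------------


def call_fired_origins(
    profile: ReplicationProfile,
    origins: Sequence[Origin],
    fired_threshold: float = 0.20,
    match_tol: int = 5000,
    peaks: Optional[list[Peak]] = None,
    window_bp: int = 9000,
    source: str = "raw",
) -> list[FiredOriginCall]:
    """Per-origin copy number, fired fraction and the >=20%-fired flag.

    Copy number is the mean of the copy-number profile over ±``window_bp``
    around the origin bin (``window_bp=0`` uses the single origin bin).
    Averaging over a window just inside the expected replicated-tract
    half-width (fork travel, 10 kb by default under HU) makes the estimate
    far less sensitive to counting noise and filter ringing than a single
    smoothed bin; ``source`` selects the raw ratio (default, unbiased) or
    the smoothed profile.  fired_fraction = clamp(copy_number - 1, 0, 1).
    """
    if not 0 < fired_threshold <= 1:
        raise ValidationError("fired_threshold must be in (0, 1]")
    if source not in ("raw", "smoothed"):
        raise ValidationError(f"unknown source {source!r}")
    if peaks is None:
        peaks = call_peaks(profile.smoothed)
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)

    sm = profile.raw_ratio if source == "raw" else profile.smoothed
    wbins = int(window_bp // sm.bin_size)
    calls: list[FiredOriginCall] = []
    for ori in origins:
        if ori.chrom not in sm.data:
            raise ValidationError(f"origin {ori.id}: chromosome {ori.chrom!r} not in profile")
        b = sm.bin_index(ori.chrom, ori.pos)
        y = sm.data[ori.chrom]
        lo, hi = max(b - wbins, 0), min(b + wbins, len(y) - 1)
        window = y[lo : hi + 1]
        cn = float(np.nanmean(window)) if np.any(np.isfinite(window)) else np.nan
        frac = float(np.clip(cn - 1.0, 0.0, 1.0)) if np.isfinite(cn) else np.nan
        fired = bool(np.isfinite(frac) and frac >= fired_threshold)
        nearest = None
        best = match_tol + 1
        for p in peaks_by_chrom.get(ori.chrom, []):
            dist = abs(p.apex_pos - ori.pos)
            if dist <= match_tol and dist < best:
                nearest, best = p, dist
        calls.append(FiredOriginCall(ori, cn, frac, fired, nearest))
    return calls


def interorigin_distances(
    calls: Sequence[FiredOriginCall],
) -> list[tuple[Origin, float]]:
    """Distance from each fired origin to its nearest fired neighbor.

    Fired origins alone on their chromosome get a missing (NaN) distance.
    """
    fired = [c.origin for c in calls if c.fired]
    by_chrom: dict[str, list[Origin]] = {}
    for o in fired:
        by_chrom.setdefault(o.chrom, []).append(o)
    result: list[tuple[Origin, float]] = []
    for chrom, oris in by_chrom.items():
        oris = sorted(oris, key=lambda o: o.pos)
        if len(oris) == 1:
            result.append((oris[0], float("nan")))
            continue
        pos = np.array([o.pos for o in oris], dtype=float)
        gaps = np.diff(pos)
        for i, o in enumerate(oris):
            if i == 0:
                d = gaps[0]
            elif i == len(oris) - 1:
                d = gaps[-1]
            else:
                d = min(gaps[i - 1], gaps[i])
            result.append((o, float(d)))
    return result


# ---------------------------------------------------------------------------
# peak widths
# ---------------------------------------------------------------------------


def peak_widths(profile: ReplicationProfile, peaks: Sequence[Peak]) -> list[Peak]:
    """Full width at half maximum above copy-number baseline 1.0.

    The half-height is (apex + 1)/2; crossings are linearly interpolated
    between bins.  If a flank never descends to the half-height before its
    adjacent valley (or chromosome end), the width falls back to the
    valley-to-valley distance and the peak is flagged truncated.  Peaks whose
    apex does not rise above baseline get a missing width.
    """
    out: list[Peak] = []
    for p in peaks:
        y = profile.smoothed.data[p.chrom]
        bs = profile.smoothed.bin_size
        apex = p.apex_bin
        if not np.isfinite(y[apex]) or y[apex] <= 1.0:
            out.append(
                Peak(p.chrom, p.apex_pos, p.apex_value, p.left_extent, p.right_extent,
                     apex, fwhm=None, truncated=False)
            )
            continue
        half = (y[apex] + 1.0) / 2.0

        def flank(direction: int) -> tuple[float, bool]:
            """Distance (bins) from apex to half-height crossing or valley."""
            i = apex
            while True:
                j = i + direction
                if j < 0 or j >= len(y) or not np.isfinite(y[j]) or y[j] > y[i]:
                    return abs(i - apex), True  # valley / end reached first
                if y[j] <= half:
                    t = (y[i] - half) / (y[i] - y[j])
                    return abs(i - apex) + t, False
                i = j

        ld, ltrunc = flank(-1)
        rd, rtrunc = flank(+1)
        out.append(
            Peak(p.chrom, p.apex_pos, p.apex_value, p.left_extent, p.right_extent,
                 apex, fwhm=(ld + rd) * bs, truncated=ltrunc or rtrunc)
        )
    return out
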