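"""Replication-normalized DNA-damage (γH2A-type ChIP) analysis.

A phospho-histone IP track is first normalized to the unmodified-histone
control, then to the amount of replication at each locus (copy number - 1),
so that loci damaged *per unit of replication* stand out.  Origins are
classified by the orientation of their flanking gene pair — an origin
between convergently transcribed genes sends both forks head-on into
transcription — and per-origin enrichment is binned by replication timing
(T_rep) within each orientation class.

Missing data policy: every normalization emits NaN rather than clamped
values; aggregations ignore NaN and report the contributing n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomicTrack, Origin, ValidationError
from .profiling import ReplicationProfile

__all__ = [
    "OriginContext",
    "normalize_chip",
    "normalize_by_replication",
    "meta_origin_profile",
    "classify_origin_gene_context",
    "binned_damage_by_trep",
    "fit_enrichment_trend",
    "estimate_damage_parameters",
    "annotation_overlap_report",
]


@dataclass
class OriginContext:
    """Origin plus the orientation class of its flanking gene pair.

    ``pair_class`` is "convergent", "nonconvergent" or "unclassified";
    ``subclass`` refines nonconvergent into "codirectional"/"divergent".
    """

    origin: Origin
    left_gene: Optional[GeneAnnotation]
    right_gene: Optional[GeneAnnotation]
    pair_class: str
    subclass: str = ""


def normalize_chip(
    ip: GenomicTrack,
    control: GenomicTrack,
    pseudocount: float = 1.0,
    min_control: float = 1.0,
) -> GenomicTrack:
    """IP/control ratio after scaling both tracks to equal totals.

    Bins whose scaled control falls below ``min_control`` are flagged
    missing rather than divided.
    """
    ip.require_same_binning(control)
    ip_total, c_total = ip.total(), control.total()
    if ip_total <= 0 or c_total <= 0:
        raise ValidationError("IP and control tracks must have positive totals")
    target = (ip_total + c_total) / 2.0
    out: dict[str, np.ndarray] = {}
    for chrom, c in control:
        i = ip.data[chrom] * (target / ip_total)
        c = c * (target / c_total)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (i + pseudocount) / (c + pseudocount)
        r[~np.isfinite(r)] = np.nan
        r[c < min_control] = np.nan
        out[chrom] = r
    return GenomicTrack(ip.bin_size, out, label="chip ratio")


def normalize_by_replication(
    chip_ratio: GenomicTrack,
    profile: ReplicationProfile,
    min_replication: float = 0.05,
) -> GenomicTrack:
    """Divide ChIP enrichment by the local amount of replication.

    Amount of replication = smoothed copy number - 1.  Bins replicating in
    fewer than ``min_replication`` of cells are flagged missing, never
    divided — an unreplicated locus has no defined per-replication damage.
    """
    if min_replication <= 0:
        raise ValidationError("min_replication must be > 0")
    chip_ratio.require_same_binning(profile.smoothed)
    out: dict[str, np.ndarray] = {}
    for chrom, r in chip_ratio:
        amount = profile.smoothed.data[chrom] - 1.0
        res = np.full_like(r, np.nan)
        ok = np.isfinite(amount) & (amount >= min_replication) & np.isfinite(r)
        res[ok] = r[ok] / amount[ok]
        out[chrom] = res
    return GenomicTrack(chip_ratio.bin_size, out, label="damage per replication")


def meta_origin_profile(
    track: GenomicTrack,
    origins: Sequence[Origin],
    half_window: int = 10_000,
    trep_cutoff: float = 27.5,
) -> dict[str, dict]:
    """Origin-centered average profiles for all / early / late origins.

    Early means t_rep <= ``trep_cutoff`` (an origin exactly at the cutoff is
    counted early; the interval convention has to close somewhere).  Windows
    running past a chromosome end contribute only where defined.  Returns,
    per subset, the position offsets (bp), the position-wise mean, and the
    number of origins contributing at the center.
    """
    if half_window % track.bin_size != 0:
        raise ValidationError("half_window must be a multiple of bin_size")
    w = half_window // track.bin_size
    subsets = {
        "all": list(origins),
        "early": [o for o in origins if o.t_rep <= trep_cutoff],
        "late": [o for o in origins if o.t_rep > trep_cutoff],
    }
    offsets = np.arange(-w, w + 1) * track.bin_size
    result: dict[str, dict] = {}
    for name, oris in subsets.items():
        if not oris:
            result[name] = {"offsets": offsets, "mean": np.full(2 * w + 1, np.nan), "n": 0}
            continue
        stack = np.full((len(oris), 2 * w + 1), np.nan)
        for k, ori in enumerate(oris):
            y = track.data[ori.chrom]
            b = track.bin_index(ori.chrom, ori.pos)
            lo, hi = b - w, b + w
            src_lo, src_hi = max(lo, 0), min(hi, len(y) - 1)
            stack[k, src_lo - lo : src_hi - lo + 1] = y[src_lo : src_hi + 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mean = np.nanmean(stack, axis=0)
        result[name] = {"offsets": offsets, "mean": mean, "n": len(oris)}
    return result


def classify_origin_gene_context(
    origins: Sequence[Origin],
    genes: Sequence[GeneAnnotation],
    max_scan: int = 20_000,
) -> list[OriginContext]:
    """Orientation class of the gene pair flanking each origin.

    The flanking genes are the nearest genes wholly left and wholly right of
    the origin.  Replication proceeds outward from the origin, so the
    leftward fork meets the left gene head-on iff that gene is transcribed
    rightward (+), and the rightward fork meets the right gene head-on iff
    it is transcribed leftward (-).  The pair is convergent iff both genes
    are head-on (transcribed toward each other across the origin).  Origins
    inside a gene body, or missing a flanking gene within ``max_scan`` bp,
    are unclassified.
    """
    genes_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in genes_by_chrom:
        genes_by_chrom[chrom].sort(key=lambda g: (g.start, g.end))

    contexts: list[OriginContext] = []
    for ori in origins:
        gs = genes_by_chrom.get(ori.chrom, [])
        inside = any(g.start <= ori.pos <= g.end for g in gs)
        left = max(
            (g for g in gs if g.end < ori.pos and ori.pos - g.end <= max_scan),
            key=lambda g: g.end,
            default=None,
        )
        right = min(
            (g for g in gs if g.start > ori.pos and g.start - ori.pos <= max_scan),
            key=lambda g: g.start,
            default=None,
        )
        if inside or left is None or right is None:
            contexts.append(OriginContext(ori, left, right, "unclassified"))
            continue
        left_head_on = left.strand == "+"
        right_head_on = right.strand == "-"
        if left_head_on and right_head_on:
            pair_class, subclass = "convergent", "convergent"
        elif not left_head_on and not right_head_on:
            pair_class, subclass = "nonconvergent", "divergent"
        else:
            pair_class, subclass = "nonconvergent", "codirectional"
        contexts.append(OriginContext(ori, left, right, pair_class, subclass))
    return contexts


def binned_damage_by_trep(
    normalized: GenomicTrack,
    contexts: Sequence[OriginContext],
    bin_edges: Sequence[float],
    window_bp: int = 2000,
) -> pd.DataFrame:
    """Mean per-origin damage enrichment by T_rep bin and orientation class.

    Per origin, enrichment is the mean of the normalized damage track over
    ±``window_bp``; rows are (trep_lo, trep_hi, pair_class, n_origins,
    mean_enrichment, sem).  Unclassified origins are excluded; empty bins
    are dropped with a warning.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be increasing with >= 2 entries")
    w = max(int(window_bp // normalized.bin_size), 0)

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        for klass in ("convergent", "nonconvergent"):
            vals = []
            for ctx in contexts:
                if ctx.pair_class != klass:
                    continue
                t = ctx.origin.t_rep
                if not (lo <= t < hi):
                    continue
                y = normalized.data[ctx.origin.chrom]
                b = normalized.bin_index(ctx.origin.chrom, ctx.origin.pos)
                win = y[max(b - w, 0) : min(b + w, len(y) - 1) + 1]
                if np.any(np.isfinite(win)):
                    vals.append(float(np.nanmean(win)))
            if not vals:
                warnings.warn(
                    f"no {klass} origins with data in T_rep bin [{lo}, {hi})"
                )
                continue
            vals_arr = np.array(vals)
            rows.append(
                {
                    "trep_lo": lo,
                    "trep_hi": hi,
                    "pair_class": klass,
                    "n_origins": len(vals_arr),
                    "mean_enrichment": float(vals_arr.mean()),
                    "sem": float(vals_arr.std(ddof=1) / np.sqrt(len(vals_arr)))
                    if len(vals_arr) > 1
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def fit_enrichment_trend(table: pd.DataFrame, pair_class: str) -> float:
    """Weighted linear trend of mean enrichment across T_rep bin centers.

    Slope in enrichment units per minute for one orientation class; NaN when
    fewer than two bins are populated.
    """
    sub = table[table["pair_class"] == pair_class]
    if len(sub) < 2:
        return float("nan")
    x = (sub["trep_lo"].to_numpy() + sub["trep_hi"].to_numpy()) / 2.0
    y = sub["mean_enrichment"].to_numpy()
    n = sub["n_origins"].to_numpy().astype(float)
    wsum = n.sum()
    xm, ym = (x * n).sum() / wsum, (y * n).sum() / wsum
    denom = (n * (x - xm) ** 2).sum()
    if denom == 0:
        return float("nan")
    return float((n * (x - xm) * (y - ym)).sum() / denom)


def estimate_damage_parameters(table: pd.DataFrame, t_min: float) -> tuple[float, float]:
    """Recover (beta, trep_slope) of the convergent-enrichment model.

    Under the generative model the convergent/nonconvergent enrichment ratio
    is 1 + beta * (1 + slope * (t_rep - t_min)); regressing that excess on
    T_rep bin centers gives beta as the intercept at ``t_min`` and
    beta * slope as the slope, which normalizes away any global scaling of
    the damage track.
    """
    conv = table[table["pair_class"] == "convergent"].set_index(["trep_lo", "trep_hi"])
    nonc = table[table["pair_class"] == "nonconvergent"].set_index(["trep_lo", "trep_hi"])
    shared = conv.index.intersection(nonc.index)
    if len(shared) < 2:
        return float("nan"), float("nan")
    centers = np.array([(lo + hi) / 2.0 - t_min for lo, hi in shared])
    excess = (
        conv.loc[shared, "mean_enrichment"].to_numpy()
        / nonc.loc[shared, "mean_enrichment"].to_numpy()
        - 1.0
    )
    n = conv.loc[shared, "n_origins"].to_numpy().astype(float)
    wsum = n.sum()
    xm, ym = (centers * n).sum() / wsum, (excess * n).sum() / wsum
    denom = (n * (centers - xm) ** 2).sum()
    slope_abs = (n * (centers - xm) * (excess - ym)).sum() / denom if denom > 0 else np.nan
    beta = ym - slope_abs * xm  # excess extrapolated to t_min
    slope = slope_abs / beta if beta else float("nan")
    return float(beta), float(slope)


def annotation_overlap_report(
    track: GenomicTrack,
    features: dict[str, Sequence[tuple[str, int, int]]],
) -> pd.DataFrame:
    """Mean track signal inside vs outside each feature class.

    Generic check for co-localization of a damage signal with an annotation
    set (tRNA genes, LTRs, centromeres ...): ``features`` maps a class name
    to (chrom, start, end) intervals, 1-based closed.  Reports the mean
    signal over feature bins, over the remaining bins, and their ratio.
    """
    rows = []
    for name, intervals in features.items():
        inside_mask = {c: np.zeros(track.n_bins(c), dtype=bool) for c in track.data}
        for chrom, start, end in intervals:
            if chrom not in inside_mask:
                continue
            b0 = (start - 1) // track.bin_size
            b1 = (end - 1) // track.bin_size
            inside_mask[chrom][max(b0, 0) : min(b1, track.n_bins(chrom) - 1) + 1] = True
        ins, outs = [], []
        for chrom, arr in track:
            ins.append(arr[inside_mask[chrom]])
            outs.append(arr[~inside_mask[chrom]])
        inside_vals = np.concatenate(ins)
        outside_vals = np.concatenate(outs)
        mean_in = float(np.nanmean(inside_vals)) if inside_vals.size else float("nan")
        mean_out = float(np.nanmean(outside_vals)) if outside_vals.size else float("nan")
        rows.append(
            {
                "feature": name,
                "n_bins": int(inside_vals.size),
                "mean_inside": mean_in,
                "mean_outside": mean_out,
                "ratio": mean_in / mean_out if mean_out else float("nan"),
            }
        )
    return pd.DataFrame(rows)
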