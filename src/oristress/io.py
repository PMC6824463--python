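"""File formats: bedGraph tracks, origin/gene annotations, result tables.

bedGraph is the exchange format for binned signal (0-based half-open
intervals); origins travel as TSV (id, chrom, pos, t_rep, status); genes as
GFF3 or BED6.  Readers validate strictly and fail with the offending line
number; every writer emits files its paired reader accepts.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomicTrack, Origin, ValidationError

__all__ = [
    "read_track",
    "write_track",
    "read_origins",
    "write_origins",
    "read_genes",
    "write_genes",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def read_track(
    path: PathLike,
    bin_size: int,
    format: str = "bedgraph",
    chrom_sizes: Optional[dict[str, int]] = None,
    label: str = "",
) -> GenomicTrack:
    """Read a bedGraph (or header-equipped TSV) into a binned track.

    Intervals are 0-based half-open and may be finer or coarser than
    ``bin_size``; each output bin is the coverage-weighted mean of the
    intervals overlapping it, NaN where nothing overlaps.  Overlapping
    intervals are an error, as is a coordinate past a declared chromosome
    end.  Without ``chrom_sizes`` each chromosome's length is the largest
    end seen.
    """
    if format not in ("bedgraph", "tsv"):
        raise ValidationError(f"unknown track format {format!r}")
    path = Path(path)
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if format == "tsv" and lineno == 1 and line.lower().startswith("chrom"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed line ({exc})") from None
            if start < 0 or end <= start:
                raise ValidationError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if chrom_sizes is not None:
                size = chrom_sizes.get(chrom)
                if size is None:
                    raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > size:
                    raise ValidationError(
                        f"{path}:{lineno}: interval end {end} past chromosome "
                        f"{chrom} length {size}"
                    )
            intervals.setdefault(chrom, []).append((start, end, value))

    data: dict[str, np.ndarray] = {}
    chroms = list(chrom_sizes) if chrom_sizes is not None else sorted(intervals)
    for chrom in chroms:
        ivs = sorted(intervals.get(chrom, []))
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{path}: overlapping intervals on {chrom} at {s2} (< end {e1})"
                )
        length = chrom_sizes[chrom] if chrom_sizes is not None else (ivs[-1][1] if ivs else 0)
        n = -(-length // bin_size) if length else 0
        weight = np.zeros(n)
        accum = np.zeros(n)
        for s, e, v in ivs:
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, min(b1, n - 1) + 1):
                ov = min(e, (b + 1) * bin_size) - max(s, b * bin_size)
                weight[b] += ov
                accum[b] += v * ov
        with np.errstate(invalid="ignore"):
            vals = accum / weight
        vals[weight == 0] = np.nan
        data[chrom] = vals
    return GenomicTrack(bin_size, data, label=label or path.stem)


def write_track(track: GenomicTrack, path: PathLike, format: str = "bedgraph") -> None:
    """Write one line per non-missing bin as bedGraph (0-based half-open)."""
    if format not in ("bedgraph", "tsv"):
        raise ValidationError(f"unknown track format {format!r}")
    path = Path(path)
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("chrom\tstart\tend\tvalue\n")
        for chrom, arr in track:
            for b, v in enumerate(arr):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{b * track.bin_size}\t{(b + 1) * track.bin_size}\t{v:.8g}\n")


# ---------------------------------------------------------------------------
# origins
# ---------------------------------------------------------------------------

_ORIGIN_COLS = ["id", "chrom", "pos", "t_rep", "status"]


def read_origins(path: PathLike) -> list[Origin]:
    """Origins from TSV with columns id, chrom, pos, t_rep, status."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_ORIGIN_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: origin table missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                Origin(str(row["id"]), str(row["chrom"]), int(row["pos"]),
                       float(row["t_rep"]), str(row["status"]))
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from None
    return out


def write_origins(origins: Sequence[Origin], path: PathLike) -> None:
    pd.DataFrame(
        [(o.id, o.chrom, o.pos, o.t_rep, o.status) for o in origins],
        columns=_ORIGIN_COLS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------


def read_genes(path: PathLike, format: Optional[str] = None) -> list[GeneAnnotation]:
    """Genes from GFF3 (``gene`` features only) or BED6.

    GFF3 coordinates are 1-based closed and kept as such; BED intervals
    (0-based half-open) are converted.  A missing strand is an error.  A
    GFF3 with no ``gene`` features yields an empty list with a warning.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bed" if suffix == ".bed" else "gff3"
    if format not in ("gff3", "bed"):
        raise ValidationError(f"unknown gene format {format!r}")
    genes: list[GeneAnnotation] = []
    saw_feature = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if format == "gff3":
                if len(parts) < 9:
                    raise ValidationError(f"{path}:{lineno}: expected 9 GFF3 columns")
                saw_feature = True
                if parts[2] != "gene":
                    continue
                chrom, start, end, strand = parts[0], parts[3], parts[4], parts[6]
                gid = _gff3_id(parts[8]) or f"gene_{lineno}"
            else:
                if len(parts) < 6:
                    raise ValidationError(f"{path}:{lineno}: BED6 requires 6 columns")
                saw_feature = True
                chrom, bstart, bend, gid, _, strand = parts[:6]
                start, end = str(int(bstart) + 1), bend
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            try:
                genes.append(GeneAnnotation(gid, chrom, int(start), int(end), strand))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    if not genes and saw_feature:
        warnings.warn(f"{path}: no 'gene' features found")
    return genes


def _gff3_id(attributes: str) -> Optional[str]:
    for field in attributes.split(";"):
        field = field.strip()
        if field.startswith("ID="):
            return field[3:]
    return None


def write_genes(genes: Sequence[GeneAnnotation], path: PathLike, format: str = "gff3") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
                )
        elif format == "bed":
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.id}\t0\t{g.strand}\n")
        else:
            raise ValidationError(f"unknown gene format {format!r}")
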