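"""Readers and writers for the package's plain-text formats.

All genomic coordinates are 0-based half-open on disk and in memory.
Formats are deliberately simple and diff-friendly:

* annotation: 6-column BED plus ``family`` and ``integration_id`` columns;
* per-locus counts: TSV with a header and ``#library_totals`` comment lines
  carrying each dataset's ChIP and input library sizes;
* coverage: 4-column bedGraph;
* titrations, peak lists and FRAP series: small TSVs with ``#key value``
  comment headers for scalar metadata.

Writers use a fixed float format so identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import COLUMNS, AnnotationError, RepeatAnnotation
from .biophys import PEAK_COLUMNS, FrapCurve, TitrationSeries
from .enrich import FamilyEnrichmentMatrix, LocusCountTable

__all__ = [
    "read_bed_annotation",
    "write_bed_annotation",
    "read_count_table",
    "write_count_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_titration",
    "write_titration",
    "read_peak_list",
    "write_peak_list",
    "read_frap",
    "write_frap",
    "write_enrichment_matrix",
]

FLOAT_FORMAT = "%.10g"


def _read_comments(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            if parts:
                meta[parts[0]] = "\t".join(parts[1:])
    return meta


# ----------------------------------------------------------------------
# annotation BED+2
# ----------------------------------------------------------------------

def read_bed_annotation(path, genome_lengths: dict[str, int] | None = None) -> RepeatAnnotation:
    """Read a 6+2-column BED annotation; malformed lines are reported by number."""
    rows = []
    errors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                errors.append(f"line {lineno}: expected 8 columns, got {len(parts)}")
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if start >= end:
                errors.append(f"line {lineno}: start >= end ({start} >= {end})")
                continue
            if parts[5] not in ("+", "-"):
                errors.append(f"line {lineno}: bad strand {parts[5]!r}")
                continue
            rows.append((parts[0], start, end, parts[3], parts[4], parts[5], parts[6], parts[7]))
    if errors:
        raise AnnotationError("malformed BED annotation:\n" + "\n".join(errors))
    df = pd.DataFrame(rows, columns=COLUMNS)
    return RepeatAnnotation(df, genome_lengths=genome_lengths or {})


def write_bed_annotation(annotation: RepeatAnnotation, path) -> None:
    annotation.df.to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# per-locus counts
# ----------------------------------------------------------------------

def write_count_table(table: LocusCountTable, path) -> None:
    with open(path, "w") as fh:
        for ds in sorted(table.library_totals):
            chip_t, input_t = table.library_totals[ds]
            fh.write(f"#library_totals\t{ds}\t{chip_t}\t{input_t}\n")
        table.df.to_csv(fh, sep="\t", index=False)


def read_count_table(path) -> LocusCountTable:
    totals: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            if parts[0] == "library_totals":
                totals[parts[1]] = (int(parts[2]), int(parts[3]))
    df = pd.read_csv(path, sep="\t", comment="#")
    return LocusCountTable(df, totals)


# ----------------------------------------------------------------------
# bedGraph coverage
# ----------------------------------------------------------------------

def read_bedgraph(path, chrom_lengths: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Read 4-column bedGraph into per-base arrays (one per chromosome)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "start", "end", "value"]
    )
    lengths = dict(chrom_lengths or {})
    for chrom, sub in df.groupby("chrom"):
        lengths.setdefault(chrom, int(sub.end.max()))
    tracks = {chrom: np.zeros(length) for chrom, length in lengths.items()}
    for row in df.itertuples(index=False):
        tracks[row.chrom][row.start : row.end] = row.value
    return tracks


def write_bedgraph(coverage: dict[str, np.ndarray], path) -> None:
    """Write per-base arrays as run-length-collapsed bedGraph (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            track = np.asarray(coverage[chrom], dtype=float)
            if track.size == 0:
                continue
            change = np.flatnonzero(np.diff(track)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [track.size]])
            for s, e in zip(starts, ends):
                v = track[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{FLOAT_FORMAT % v}\n")


# ----------------------------------------------------------------------
# biophysics tables
# ----------------------------------------------------------------------

def write_titration(series: TitrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#p_total\t{FLOAT_FORMAT % series.p_total}\n")
        series.to_frame().to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_titration(path) -> TitrationSeries:
    meta = _read_comments(path)
    if "p_total" not in meta:
        raise ValueError(f"{path}: missing '#p_total' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    return TitrationSeries(
        ligand=df["ligand"].to_numpy(), delta_i=df["delta_i"].to_numpy(),
        p_total=float(meta["p_total"]),
    )


def write_peak_list(peaks: pd.DataFrame, path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_peak_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: peak list missing columns {missing}")
    return df


def write_frap(curve: FrapCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_prebleach\t{curve.n_prebleach}\n")
        curve.to_frame().to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_frap(path) -> FrapCurve:
    meta = _read_comments(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return FrapCurve(
        time=df["time"].to_numpy(),
        intensity_bleached=df["intensity_bleached"].to_numpy(),
        intensity_unbleached=df["intensity_unbleached"].to_numpy(),
        n_prebleach=int(meta.get("n_prebleach", 1)),
    )


# ----------------------------------------------------------------------
# result matrices
# ----------------------------------------------------------------------

def write_enrichment_matrix(matrix: FamilyEnrichmentMatrix, prefix) -> list[str]:
    """Write raw_median/zscore/n_loci_used TSVs; returns the paths written."""
    paths = []
    for name, frame in (
        ("raw_median", matrix.raw_median),
        ("zscore", matrix.zscore),
        ("n_loci_used", matrix.n_loci_used),
    ):
        path = f"{prefix}.{name}.tsv"
        frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="family")
        paths.append(path)
    return paths
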