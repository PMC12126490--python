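"""Repeat-family ChIP enrichment statistics.

For each annotated locus of each repetitive-element family, the ChIP signal
is depth-normalized (CPM), divided by the depth-normalized input signal, and
summarized per family as the median fold enrichment over surviving loci.
Loci with less than 1 input read are removed first — both a coverage filter
and the guard against division by zero.  Per dataset, family medians are
z-score transformed (each dataset normalized to itself) so enrichment is
comparable across ChIPs of different efficiency, and the resulting
families x datasets matrix is hierarchically clustered with a Spearman-rank
distance (1 - rho, average linkage) — the standard repeat-enrichment
heatmap object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import leaves_list, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

__all__ = [
    "LocusCountTable",
    "FamilyEnrichmentMatrix",
    "compute_cpm",
    "filter_low_coverage",
    "locus_fold_enrichment",
    "family_median",
    "zscore_transform",
    "cluster_matrix",
    "run_enrichment_pipeline",
]

COUNT_COLUMNS = ["locus_id", "dataset", "chip_count", "input_count"]


@dataclass
class LocusCountTable:
    """Per-locus ChIP and input fragment counts for one or more datasets.

    ``library_totals`` maps each dataset to its ``(chip_total, input_total)``
    library sizes; CPM for ChIP and input each use their own total.
    """

    df: pd.DataFrame
    library_totals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        counts = self.df[["chip_count", "input_count"]]
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for ds in self.df.dataset.unique():
            if ds not in self.library_totals:
                raise ValueError(f"no library totals for dataset {ds!r}")
            chip_t, input_t = self.library_totals[ds]
            sub = self.df[self.df.dataset == ds]
            if chip_t < sub.chip_count.sum() or input_t < sub.input_count.sum():
                raise ValueError(f"library totals for {ds!r} smaller than column sums")

    @property
    def datasets(self) -> list[str]:
        return sorted(self.df.dataset.unique())

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class FamilyEnrichmentMatrix:
    """Families x datasets enrichment summary (the clustered-heatmap object)."""

    raw_median: pd.DataFrame
    zscore: pd.DataFrame
    n_loci_used: pd.DataFrame
    dropped_families: dict[str, list[str]] = field(default_factory=dict)

    @property
    def families(self) -> list[str]:
        return list(self.raw_median.index)

    @property
    def datasets(self) -> list[str]:
        return list(self.raw_median.columns)


def compute_cpm(count, library_total):
    """Counts per million: count / library_total * 1e6."""
    library_total = np.asarray(library_total, dtype=float)
    if np.any(library_total <= 0):
        raise ValueError("library_total must be positive")
    out = np.asarray(count, dtype=float) / library_total * 1e6
    return float(out) if out.ndim == 0 else out


def filter_low_coverage(table: LocusCountTable, family_of: Mapping[str, str] | None = None) -> LocusCountTable:
    """Drop low-coverage loci: rows with less than 1 input read.

    Exactly the rows with ``input_count >= 1`` are retained.  If a
    locus -> family map is given, removal counts are logged per family.
    """
    keep = table.df.input_count >= 1
    removed = table.df[~keep]
    if len(removed):
        if family_of is not None:
            fams = removed.locus_id.map(lambda l: family_of.get(l, "?"))
            for fam, n in fams.value_counts().items():
                logger.info("low-coverage filter removed %d loci of family %s", n, fam)
        else:
            logger.info("low-coverage filter removed %d loci", len(removed))
    out = table.df[keep]
    if out.empty:
        warnings.warn("all loci removed by the <1-input-read filter", stacklevel=2)
    return LocusCountTable(out, dict(table.library_totals))


def locus_fold_enrichment(chip_cpm, input_cpm):
    """Depth-normalized ChIP over depth-normalized input at one locus."""
    input_cpm = np.asarray(input_cpm, dtype=float)
    if np.any(input_cpm <= 0):
        raise ValueError("input CPM must be positive (low-coverage filter not applied?)")
    out = np.asarray(chip_cpm, dtype=float) / input_cpm
    return float(out) if out.ndim == 0 else out


def family_median(fe_values: Sequence[float], family: str = "") -> float:
    """Median fold enrichment of a family (mean of central pair for even n)."""
    arr = np.asarray(fe_values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"family {family!r} has no loci after filtering")
    return float(np.median(arr))


def zscore_transform(medians: Sequence[float], dataset: str = "") -> np.ndarray:
    """Standardize per-family medians of one dataset to mean 0, sample sd 1."""
    arr = np.asarray(medians, dtype=float)
    if arr.size < 2:
        raise ValueError(f"dataset {dataset!r}: need at least 2 families to z-score")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError(f"dataset {dataset!r}: zero variance across family medians")
    return (arr - arr.mean()) / sd


def _spearman_distance_matrix(values: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    for i, lab in enumerate(labels):
        if np.all(values[i] == values[i][0]):
            raise ValueError(f"row {lab!r} is constant; Spearman distance undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(values, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d


@dataclass
class ClusterResult:
    """Deterministic ordering and linkage from Spearman-distance clustering."""

    labels: list[str]
    order: list[int]
    linkage: np.ndarray

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.order]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def cluster_matrix(matrix: FamilyEnrichmentMatrix, axis: str = "families") -> ClusterResult:
    """Agglomerative clustering with d = 1 - Spearman rho, average linkage.

    Rows are pre-sorted lexicographically by label so ties break
    deterministically.
    """
    if axis == "families":
        frame = matrix.zscore
    elif axis == "datasets":
        frame = matrix.zscore.T
    else:
        raise ValueError(f"axis must be 'families' or 'datasets', got {axis!r}")
    if frame.isna().any().any():
        raise ValueError("matrix has missing values; cannot cluster")
    frame = frame.sort_index(kind="mergesort")
    labels = list(frame.index)
    d = _spearman_distance_matrix(frame.to_numpy(dtype=float), labels)
    Z = _average_linkage(squareform(d, checks=False))
    order = [int(i) for i in leaves_list(Z)]
    return ClusterResult(labels=labels, order=order, linkage=Z)


def run_enrichment_pipeline(
    annotation,
    counts: LocusCountTable,
    cluster: bool = True,
) -> FamilyEnrichmentMatrix:
    """CPM -> low-coverage filter -> fold enrichment -> family median -> z-score.

    ``annotation`` supplies the locus -> family assignment (a
    :class:`~ervscape.annotation.RepeatAnnotation` or any object with a
    ``df`` holding ``locus_id`` and ``family`` columns).  Families with no
    surviving locus in a dataset are dropped from the matrix (all datasets)
    with a warning, keeping every z-score column well-defined.
    """
    fam_map = dict(zip(annotation.df.locus_id, annotation.df.family))
    missing = set(counts.df.locus_id) - set(fam_map)
    if missing:
        raise ValueError(f"counts reference loci absent from annotation: {sorted(missing)[:5]}")

    try:
        filtered = filter_low_coverage(counts, fam_map)
    except Exception as exc:
        raise RuntimeError(f"stage filter_low_coverage failed: {exc}") from exc

    df = filtered.df.copy()
    df["family"] = df.locus_id.map(fam_map)
    chip_totals = df.dataset.map(lambda d: filtered.library_totals[d][0]).to_numpy(float)
    input_totals = df.dataset.map(lambda d: filtered.library_totals[d][1]).to_numpy(float)
    df["fe"] = locus_fold_enrichment(
        compute_cpm(df.chip_count.to_numpy(), chip_totals),
        compute_cpm(df.input_count.to_numpy(), input_totals),
    )

    datasets = sorted(counts.df.dataset.unique())
    all_families = sorted(set(fam_map[l] for l in counts.df.locus_id))
    med = pd.DataFrame(index=all_families, columns=datasets, dtype=float)
    nloc = pd.DataFrame(0, index=all_families, columns=datasets, dtype=int)
    for (fam, ds), grp in df.groupby(["family", "dataset"], sort=False):
        med.loc[fam, ds] = family_median(grp.fe.to_numpy(), fam)
        nloc.loc[fam, ds] = len(grp)

    dropped: dict[str, list[str]] = {}
    incomplete = med.index[med.isna().any(axis=1)]
    for fam in incomplete:
        dropped[fam] = list(med.columns[med.loc[fam].isna()])
        warnings.warn(f"family {fam!r} empty after filtering in {dropped[fam]}; dropped", stacklevel=2)
    med = med.drop(index=incomplete)
    nloc = nloc.drop(index=incomplete)

    z = pd.DataFrame(index=med.index, columns=med.columns, dtype=float)
    for ds in datasets:
        try:
            z[ds] = zscore_transform(med[ds].to_numpy(), ds)
        except Exception as exc:
            raise RuntimeError(f"stage zscore_transform failed: {exc}") from exc

    result = FamilyEnrichmentMatrix(raw_median=med, zscore=z, n_loci_used=nloc, dropped_families=dropped)
    if cluster and len(result.families) >= 2:
        try:
            order = cluster_matrix(result, axis="families")
        except Exception as exc:
            raise RuntimeError(f"stage cluster_matrix failed: {exc}") from exc
        result.raw_median = result.raw_median.loc[order.ordered_labels]
        result.zscore = result.zscore.loc[order.ordered_labels]
        result.n_loci_used = result.n_loci_used.loc[order.ordered_labels]
    return result
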