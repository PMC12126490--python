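"""LTR-anchored coverage profiles and differential accessibility.

A full-length ERV integration carries two near-identical LTRs; plotting both
double-counts the element, so per integration only the 5' LTR is kept (solo
"orphan" LTRs are kept as-is).  Each surviving LTR contributes one anchor at
its strand-aware 5' boundary, and coverage is laid out over an asymmetric
window (default 1.5 kb upstream to 8 kb downstream, the span of a typical
full-length element) in fixed-width bins, reflected for minus-strand
anchors so "upstream" is biological upstream.

Differential accessibility between two conditions is tested per family on
per-anchor counts with a two-sided Wilcoxon rank-sum test (exact null for
small tie-free samples, normal approximation with continuity and tie
correction otherwise) and Benjamini-Hochberg adjustment across the families
tested in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .annotation import (
    ROLE_LTR3,
    ROLE_LTR5,
    ROLE_ORPHAN_LTR,
    AnnotationError,
    RepeatAnnotation,
)

__all__ = [
    "AnchorSet",
    "ProfileMatrix",
    "dedup_ltrs",
    "build_profile_matrix",
    "average_profile",
    "count_in_anchor_intervals",
    "ltr_differential_test",
    "wilcoxon_rank_sum",
]

DEFAULT_WINDOW_UP = 1500
DEFAULT_WINDOW_DOWN = 8000
DEFAULT_BIN_SIZE = 50

#: combined sample size up to which the exact Wilcoxon null is enumerated
EXACT_WILCOXON_MAX_N = 25


@dataclass
class AnchorSet:
    """Deduplicated LTR anchors plus the profile window geometry.

    One row per kept LTR: ``chrom, position, strand, family, integration_id,
    start, end`` where ``position`` is the strand-aware 5' boundary (interval
    start on +, interval end on -) and ``[start, end)`` is the LTR interval
    itself (used when counting reads within LTRs).
    """

    anchors: pd.DataFrame
    window_up: int = DEFAULT_WINDOW_UP
    window_down: int = DEFAULT_WINDOW_DOWN
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if min(self.window_up, self.window_down, self.bin_size) <= 0:
            raise ValueError("window_up, window_down and bin_size must be positive")
        if (self.window_up + self.window_down) % self.bin_size != 0:
            raise ValueError("window span must be divisible by bin_size")
        if self.anchors.integration_id.duplicated().any():
            raise ValueError("more than one anchor per integration after dedup")

    @property
    def n_bins(self) -> int:
        return (self.window_up + self.window_down) // self.bin_size

    def __len__(self) -> int:
        return len(self.anchors)


def dedup_ltrs(
    annotation: RepeatAnnotation,
    family_ltr_map: Mapping[str, Sequence[str]],
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> AnchorSet:
    """One anchor per integration: the 5' LTR where both LTRs are present.

    Orphan LTRs and single-LTR integrations are kept as-is.  An integration
    with two 5'-LTR records is malformed and raises
    :class:`~ervscape.annotation.AnnotationError`.
    """
    roled = annotation.assign_roles(family_ltr_map)
    ltr_roles = (ROLE_LTR5, ROLE_LTR3, ROLE_ORPHAN_LTR)
    ltrs = roled[roled.role.isin(ltr_roles)]
    fam_of_subfam = {
        name: fam for fam, names in family_ltr_map.items() for name in names
    }

    rows = []
    for intg, grp in ltrs.groupby("integration_id", sort=False):
        if (grp.role == ROLE_LTR5).sum() > 1:
            raise AnnotationError(f"integration {intg!r} has two 5'-LTR records")
        if (grp.role == ROLE_LTR5).any():
            keep = grp[grp.role == ROLE_LTR5].iloc[0]
        else:
            keep = grp.iloc[0]  # orphan or lone 3' LTR
        position = int(keep.start) if keep.strand == "+" else int(keep.end)
        rows.append(
            {
                "chrom": keep.chrom,
                "position": position,
                "strand": keep.strand,
                "family": fam_of_subfam.get(keep.family, keep.family),
                "integration_id": intg,
                "start": int(keep.start),
                "end": int(keep.end),
            }
        )
    anchors = pd.DataFrame(
        rows, columns=["chrom", "position", "strand", "family", "integration_id", "start", "end"]
    )
    anchors = anchors.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)
    return AnchorSet(anchors, window_up=window_up, window_down=window_down, bin_size=bin_size)


@dataclass
class ProfileMatrix:
    """Anchors x bins matrix of mean per-base coverage, with an out-of-genome mask."""

    values: np.ndarray  # (n_anchors, n_bins)
    mask: np.ndarray  # True where the bin falls outside the genome
    anchor_ids: list[str]
    bin_starts: np.ndarray  # biological offset of each bin's left edge
    bin_size: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{int(s)}" for s in self.bin_starts]
        df = pd.DataFrame(self.values, index=self.anchor_ids, columns=cols)
        return df.mask(self.mask)


def build_profile_matrix(
    coverage: Mapping[str, np.ndarray],
    anchors: AnchorSet,
    sort_rows: bool = True,
) -> ProfileMatrix:
    """Per-anchor binned coverage over [-window_up, +window_down).

    ``coverage`` maps chromosome to a per-base signal array.  Minus-strand
    windows are reflected.  Bins extending past chromosome ends are masked
    (excluded from column means), not clipped to zero.  Rows are ordered by
    descending row mean by default.
    """
    up, down, width = anchors.window_up, anchors.window_down, anchors.bin_size
    n_bins = anchors.n_bins
    offsets = np.arange(-up, down)  # biological offsets, one per base

    values = np.zeros((len(anchors), n_bins))
    mask = np.zeros((len(anchors), n_bins), dtype=bool)
    ids = []
    for i, a in enumerate(anchors.anchors.itertuples(index=False)):
        if a.chrom not in coverage:
            raise KeyError(f"anchor chromosome {a.chrom!r} absent from coverage")
        track = np.asarray(coverage[a.chrom], dtype=float)
        if a.strand == "+":
            pos = a.position + offsets
        else:
            pos = a.position - 1 - offsets
        in_genome = (pos >= 0) & (pos < track.size)
        base_vals = np.where(in_genome, track[np.clip(pos, 0, track.size - 1)], np.nan)
        per_bin = base_vals.reshape(n_bins, width)
        valid = in_genome.reshape(n_bins, width)
        n_valid = valid.sum(axis=1)
        full = n_valid == width
        with np.errstate(invalid="ignore"):
            values[i] = np.where(full, np.nansum(per_bin, axis=1) / np.maximum(n_valid, 1), np.nan)
        # partially covered bins: mean over in-genome bases; fully outside: masked
        partial = (n_valid > 0) & ~full
        values[i, partial] = np.nansum(per_bin[partial], axis=1) / n_valid[partial]
        mask[i] = n_valid == 0
        values[i, mask[i]] = np.nan
        ids.append(a.integration_id)

    order = np.arange(len(ids))
    if sort_rows and len(ids):
        row_means = np.array([np.nanmean(v) if not np.all(m) else -np.inf for v, m in zip(values, mask)])
        order = np.argsort(-row_means, kind="mergesort")
    return ProfileMatrix(
        values=values[order],
        mask=mask[order],
        anchor_ids=[ids[i] for i in order],
        bin_starts=np.arange(-up, down, width),
        bin_size=width,
    )


def average_profile(matrix: ProfileMatrix) -> pd.DataFrame:
    """Per-bin mean over unmasked rows, with SEM; fully masked bins are NaN."""
    vals = np.where(matrix.mask, 0.0, matrix.values)
    n = np.sum(~matrix.mask, axis=0)
    sums = vals.sum(axis=0)
    mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    dev2 = np.where(matrix.mask, 0.0, (matrix.values - mean) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(dev2.sum(axis=0) / np.maximum(n - 1, 1))
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame(
        {"bin_start": matrix.bin_starts, "mean": mean, "sem": sem, "n": n}
    )


def count_in_anchor_intervals(coverage: Mapping[str, np.ndarray], anchors: AnchorSet) -> pd.DataFrame:
    """Total signal within each kept LTR interval (read counting surrogate)."""
    rows = []
    for a in anchors.anchors.itertuples(index=False):
        track = np.asarray(coverage[a.chrom], dtype=float)
        rows.append(
            {
                "integration_id": a.integration_id,
                "family": a.family,
                "count": float(track[a.start : a.end].sum()),
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p-value.

    The exact null distribution is used when the combined sample size is at
    most 25 and there are no ties; otherwise the normal approximation with
    continuity and tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_WILCOXON_MAX_N and tie_free) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def ltr_differential_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    grouping: str = "family",
) -> pd.DataFrame:
    """Per-family Wilcoxon rank-sum between two conditions, BH-adjusted.

    Each input holds one row per anchor with at least ``grouping`` and
    ``count`` columns.  Adjustment spans exactly the families tested in this
    invocation.  A family with zero anchors in either condition raises.
    """
    fams = sorted(set(counts_a[grouping]) | set(counts_b[grouping]))
    rows = []
    for fam in fams:
        xa = counts_a.loc[counts_a[grouping] == fam, "count"].to_numpy(float)
        xb = counts_b.loc[counts_b[grouping] == fam, "count"].to_numpy(float)
        if xa.size == 0 or xb.size == 0:
            raise ValueError(f"family {fam!r} has zero anchors in one condition")
        w, p = wilcoxon_rank_sum(xa, xb)
        rows.append({"family": fam, "n_a": xa.size, "n_b": xb.size, "W": w, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out.p.to_numpy(), method="fdr_bh")[1]
    return out
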