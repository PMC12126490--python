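"""Family-labelled repeat annotations.

A repeat annotation is a table of genomic intervals (0-based, half-open),
each carrying a subfamily label (e.g. ``IAPLTR1_Mm`` or ``IAPEz-int``) and an
integration identifier grouping the pieces of one genomic insertion: a
full-length ERV integration is 5'-LTR + internal segment(s) + 3'-LTR on one
strand, while a solitary ("orphan") LTR forms an integration of its own.

Whether a subfamily is an LTR or an internal segment is not a column of the
interval file; it is knowledge about the repeat library.  Callers supply a
``family -> LTR subfamily names`` map (e.g. ``{"IAPEz": ["IAPLTR1_Mm",
"IAPLTR2_Mm"]}``) and roles (5' LTR, 3' LTR, internal, orphan LTR) are
derived strand-awarely from positions within each integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RepeatLocus",
    "RepeatAnnotation",
    "AnnotationError",
    "ROLE_LTR5",
    "ROLE_LTR3",
    "ROLE_INTERNAL",
    "ROLE_ORPHAN_LTR",
    "infer_integrations",
]

ROLE_LTR5 = "LTR5"
ROLE_LTR3 = "LTR3"
ROLE_INTERNAL = "internal"
ROLE_ORPHAN_LTR = "orphanLTR"

#: column order of the in-memory table and of the BED+2 dialect
COLUMNS = ["chrom", "start", "end", "locus_id", "score", "strand", "family", "integration_id"]


class AnnotationError(ValueError):
    """Raised for structurally invalid annotations (overlaps, bad intervals...)."""


@dataclass(frozen=True)
class RepeatLocus:
    """One annotated repeat interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    locus_id: str
    strand: str
    family: str
    integration_id: str
    role: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"locus {self.locus_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"locus {self.locus_id}: strand must be + or -, got {self.strand!r}")


@dataclass
class RepeatAnnotation:
    """A validated, sorted collection of repeat loci.

    Wraps a :class:`pandas.DataFrame` with columns
    ``chrom, start, end, locus_id, score, strand, family, integration_id``.
    """

    df: pd.DataFrame
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise AnnotationError(f"annotation missing columns: {missing}")
        self.df = (
            self.df[COLUMNS]
            .astype({"start": np.int64, "end": np.int64})
            .sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check intervals are well-formed, sorted, non-overlapping, in bounds."""
        df = self.df
        bad = df[df.start >= df.end]
        if len(bad):
            raise AnnotationError(
                "start >= end at loci: " + ", ".join(bad.locus_id.astype(str).head(10))
            )
        if (df.start < 0).any():
            raise AnnotationError("negative start coordinate")
        if not df.strand.isin(["+", "-"]).all():
            raise AnnotationError("strand column must be '+' or '-'")
        if df.locus_id.duplicated().any():
            dupes = df.locus_id[df.locus_id.duplicated()].unique()[:5]
            raise AnnotationError(f"duplicate locus_ids: {list(dupes)}")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub.start.to_numpy()
            ends = sub.end.to_numpy()
            overlap = starts[1:] < ends[:-1]
            if overlap.any():
                i = int(np.argmax(overlap))
                raise AnnotationError(
                    f"overlapping loci on {chrom}: "
                    f"{sub.locus_id.iloc[i]} and {sub.locus_id.iloc[i + 1]}"
                )
            if chrom in self.genome_lengths and ends[-1] > self.genome_lengths[chrom]:
                raise AnnotationError(f"locus beyond end of {chrom}")

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def families(self) -> list[str]:
        return sorted(self.df.family.unique())

    def loci(self) -> Iterable[RepeatLocus]:
        for row in self.df.itertuples(index=False):
            yield RepeatLocus(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                locus_id=row.locus_id,
                strand=row.strand,
                family=row.family,
                integration_id=row.integration_id,
            )

    # ------------------------------------------------------------------
    def assign_roles(self, family_ltr_map: Mapping[str, Sequence[str]]) -> pd.DataFrame:
        """Return a copy of the table with a ``role`` column.

        ``family_ltr_map`` maps a named family (e.g. ``IAPEz``) to the
        subfamily names of its LTRs; subfamilies of a mapped family that are
        not LTRs are internal segments.  Within an integration the LTR at the
        strand-aware 5' side is LTR5 and the one at the 3' side is LTR3; an
        integration consisting only of LTR loci yields orphan LTRs.
        Subfamilies of unmapped families get role ``None``.
        """
        ltr_to_family: dict[str, str] = {}
        mapped_subfams: set[str] = set()
        for fam, ltr_names in family_ltr_map.items():
            for name in ltr_names:
                ltr_to_family[name] = fam
                mapped_subfams.add(name)

        df = self.df.copy()
        df["role"] = None
        is_ltr = df.family.isin(ltr_to_family)
        for _, idx in df.groupby("integration_id", sort=False).groups.items():
            sub = df.loc[idx]
            ltr_idx = sub.index[is_ltr.loc[sub.index]]
            if len(ltr_idx) == 0:
                continue
            other_idx = sub.index.difference(ltr_idx)
            if len(other_idx) == 0:
                df.loc[ltr_idx, "role"] = ROLE_ORPHAN_LTR
                continue
            df.loc[other_idx, "role"] = ROLE_INTERNAL
            if len(ltr_idx) > 2:
                raise AnnotationError(
                    f"integration {sub.integration_id.iloc[0]} has {len(ltr_idx)} LTR loci "
                    "(at most a 5' and a 3' LTR expected)"
                )
            strands = sub.strand.unique()
            if len(strands) > 1:
                raise AnnotationError(
                    f"integration {sub.integration_id.iloc[0]} mixes strands"
                )
            strand = strands[0]
            ltrs = df.loc[ltr_idx].sort_values("start")
            if len(ltr_idx) == 1:
                # single LTR flanking an internal segment: 5' if upstream of it
                ltr = df.loc[ltr_idx[0]]
                internal_start = df.loc[other_idx, "start"].min()
                upstream = ltr.start < internal_start
                if strand == "-":
                    upstream = not upstream
                df.loc[ltr_idx[0], "role"] = ROLE_LTR5 if upstream else ROLE_LTR3
            else:
                first, last = ltrs.index[0], ltrs.index[-1]
                if strand == "+":
                    df.loc[first, "role"] = ROLE_LTR5
                    df.loc[last, "role"] = ROLE_LTR3
                else:
                    df.loc[first, "role"] = ROLE_LTR3
                    df.loc[last, "role"] = ROLE_LTR5
        return df


def infer_integrations(
    annotation: RepeatAnnotation,
    family_ltr_map: Mapping[str, Sequence[str]],
    max_gap: int = 1000,
) -> RepeatAnnotation:
    """Group loci into integrations for flat BED input lacking integration ids.

    Runs of same-family (LTR or internal subfamily of one named family),
    same-strand loci on one chromosome separated by gaps of at most
    ``max_gap`` bp are assigned a shared integration id; everything else
    keeps a singleton id.
    """
    subfam_to_family: dict[str, str] = {}
    for fam, ltr_names in family_ltr_map.items():
        for name in ltr_names:
            subfam_to_family[name] = fam

    def named_family(subfam: str) -> str:
        if subfam in subfam_to_family:
            return subfam_to_family[subfam]
        # internal segments conventionally carry an "-int"/"_int" suffix
        for suffix in ("-int", "_int", "-I"):
            if subfam.endswith(suffix):
                return subfam[: -len(suffix)]
        return subfam

    df = annotation.df.copy()
    new_ids = []
    counter = 0
    prev = None
    current_id = None
    for row in df.itertuples(index=False):
        fam = named_family(row.family)
        if (
            prev is not None
            and row.chrom == prev.chrom
            and row.strand == prev.strand
            and fam == prev_fam
            and row.start - prev.end <= max_gap
        ):
            new_ids.append(current_id)
        else:
            counter += 1
            current_id = f"inf{counter:06d}"
            new_ids.append(current_id)
        prev = row
        prev_fam = fam
    df["integration_id"] = new_ids
    return RepeatAnnotation(df, genome_lengths=dict(annotation.genome_lengths))
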