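"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its arguments including the seed, so
pipelines built on these inputs are reproducible byte-for-byte.  Each
generator draws from its own RNG stream derived from ``(seed, operation
name)``, so reusing one config across generators cannot cross-contaminate
streams.

What is emulated:

* multi-family repeat annotations with full-length integrations
  (5'-LTR + internal + 3'-LTR, contiguous, one strand) and solo "orphan"
  LTRs, placed without overlap on a synthetic chromosome;
* overdispersed (negative binomial) ChIP and input fragment counts with
  planted per-family enrichment factors and dataset-specific library sizes;
* two-condition ATAC-style counts with planted accessibility loss at
  chosen families;
* fluorescence titrations from the quadratic (ligand-depletion) binding
  isotherm, exact when noiseless;
* apo/bound HSQC peak lists with planted shifts and disappeared residues;
* half-bleach FRAP recovery curves with a planted transient dip.

Raw reads, alignment artifacts, PCR duplicates and spike-ins are not
simulated: generators produce the per-locus count and per-base coverage
level objects the downstream statistics actually consume.
"""

from __future__ import annotations

import hashlib
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import RepeatAnnotation
from .biophys import FrapCurve, TitrationSeries, predict_delta_i
from .enrich import LocusCountTable

__all__ = [
    "SimulationConfig",
    "generate_repeat_annotation",
    "simulate_count_table",
    "simulate_coverage",
    "simulate_atac_counts",
    "simulate_titration",
    "simulate_peak_lists",
    "simulate_frap_curve",
]

#: dispersion above which negative-binomial sampling switches to its Poisson limit
POISSON_DISPERSION_THRESHOLD = 1e6

SYNTH_CHROM = "chrS"


def _rng(seed: int, operation: str) -> np.random.Generator:
    """Independent stream per (seed, operation name)."""
    tag = int.from_bytes(hashlib.sha256(operation.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial by (mean, dispersion); Poisson limit at huge dispersion."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if np.any(mean <= 0):
        raise ValueError("negative binomial mean must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if not np.isfinite(dispersion) or dispersion >= POISSON_DISPERSION_THRESHOLD:
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


@dataclass
class SimulationConfig:
    """Study conditions for the genomics generators.

    ``enrichment_factors`` maps dataset -> family -> multiplicative ChIP
    enrichment over input (1 = no enrichment).  ``library_sizes`` maps
    dataset -> total mapped fragments, either one integer used for both
    ChIP and input or a ``(chip_total, input_total)`` pair.
    """

    seed: int = 0
    n_families: int = 5
    loci_per_family: int = 50
    genome_length: int = 5_000_000
    enrichment_factors: dict = field(default_factory=dict)
    nb_dispersion: float = 10.0
    library_sizes: dict = field(default_factory=lambda: {"chip1": 10_000_000})
    input_mean: float = 20.0
    ltr_length: int = 350
    internal_length: int = 5000
    orphan_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.loci_per_family < 1:
            raise ValueError("n_families and loci_per_family must be >= 1")
        if not 0.0 <= self.orphan_fraction <= 1.0:
            raise ValueError("orphan_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.input_mean <= 0:
            raise ValueError("nb_dispersion and input_mean must be positive")
        if min(self.ltr_length, self.internal_length) <= 0:
            raise ValueError("ltr_length and internal_length must be positive")
        for ds, fam_map in self.enrichment_factors.items():
            for fam, f in fam_map.items():
                if f <= 0:
                    raise ValueError(f"enrichment factor for {ds}/{fam} must be > 0, got {f}")

    @property
    def family_names(self) -> list[str]:
        return [f"fam{i + 1:02d}" for i in range(self.n_families)]

    @property
    def datasets(self) -> list[str]:
        return sorted(self.library_sizes)

    def totals(self, dataset: str) -> tuple[int, int]:
        v = self.library_sizes[dataset]
        if isinstance(v, (tuple, list)):
            chip_t, input_t = int(v[0]), int(v[1])
        else:
            chip_t = input_t = int(v)
        if chip_t <= 0 or input_t <= 0:
            raise ValueError(f"library sizes for {dataset!r} must be positive")
        return chip_t, input_t


class PlacementError(RuntimeError):
    """Could not place all loci without overlap within the genome."""


def generate_repeat_annotation(config: SimulationConfig) -> RepeatAnnotation:
    """Non-overlapping repeat annotation with full-length and orphan LTRs.

    Per family, ``loci_per_family`` integrations are placed on one synthetic
    chromosome; a fraction ``orphan_fraction`` (rounded) are solo LTRs, the
    rest are contiguous LTR-internal-LTR elements sharing an integration id.
    Subfamilies are named ``<family>_LTR`` and ``<family>_int``.  Raises
    :class:`PlacementError` when random placement cannot fit the loci.
    """
    rng = _rng(config.seed, "generate_repeat_annotation")
    full_width = 2 * config.ltr_length + config.internal_length
    rows = []
    starts_sorted: list[int] = []
    ends_by_start: dict[int, int] = {}

    def try_place(width: int) -> int:
        limit = config.genome_length - width
        if limit <= 0:
            raise PlacementError(
                f"genome_length {config.genome_length} cannot hold an element of width {width}"
            )
        for _ in range(1000):
            s = int(rng.integers(0, limit))
            i = bisect_left(starts_sorted, s)
            ok = True
            if i > 0 and ends_by_start[starts_sorted[i - 1]] > s:
                ok = False
            if ok and i < len(starts_sorted) and starts_sorted[i] < s + width:
                ok = False
            if ok:
                insort(starts_sorted, s)
                ends_by_start[s] = s + width
                return s
        raise PlacementError(
            "could not place a locus without overlap after 1000 attempts; "
            "increase genome_length or reduce loci"
        )

    for family in config.family_names:
        n_orphan = int(round(config.orphan_fraction * config.loci_per_family))
        for k in range(config.loci_per_family):
            orphan = k < n_orphan
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            intg = f"{family}.i{k + 1:04d}"
            if orphan:
                s = try_place(config.ltr_length)
                rows.append(
                    (SYNTH_CHROM, s, s + config.ltr_length, f"{intg}.ltr", 0, strand,
                     f"{family}_LTR", intg)
                )
            else:
                s = try_place(full_width)
                L = config.ltr_length
                rows.append((SYNTH_CHROM, s, s + L, f"{intg}.ltrA", 0, strand, f"{family}_LTR", intg))
                rows.append(
                    (SYNTH_CHROM, s + L, s + L + config.internal_length, f"{intg}.int", 0, strand,
                     f"{family}_int", intg)
                )
                rows.append(
                    (SYNTH_CHROM, s + L + config.internal_length, s + full_width, f"{intg}.ltrB",
                     0, strand, f"{family}_LTR", intg)
                )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "locus_id", "score", "strand", "family", "integration_id"],
    )
    return RepeatAnnotation(df, genome_lengths={SYNTH_CHROM: config.genome_length})


def default_family_ltr_map(config: SimulationConfig) -> dict[str, list[str]]:
    """family -> LTR subfamily names for annotations from this generator."""
    return {fam: [f"{fam}_LTR"] for fam in config.family_names}


def _factor_for(config: SimulationConfig, dataset: str, subfamily: str) -> float:
    fam_map = config.enrichment_factors.get(dataset, {})
    if subfamily in fam_map:
        return float(fam_map[subfamily])
    for suffix in ("_LTR", "_int"):
        if subfamily.endswith(suffix) and subfamily[: -len(suffix)] in fam_map:
            return float(fam_map[subfamily[: -len(suffix)]])
    raise ValueError(f"no enrichment factor for family {subfamily!r} in dataset {dataset!r}")


def simulate_count_table(annotation: RepeatAnnotation, config: SimulationConfig) -> LocusCountTable:
    """Overdispersed ChIP/input counts with planted per-family enrichment.

    Input counts are NB(mean = ``input_mean``, dispersion); ChIP counts are
    NB(mean = factor x input_mean x chip/input library-size ratio,
    dispersion), so CPM normalization recovers the planted factor in
    expectation.
    """
    rng = _rng(config.seed, "simulate_count_table")
    rows = []
    totals: dict[str, tuple[int, int]] = {}
    loci = annotation.df
    for ds in config.datasets:
        chip_t, input_t = config.totals(ds)
        totals[ds] = (chip_t, input_t)
        scale = chip_t / input_t
        factors = np.array([_factor_for(config, ds, f) for f in loci.family])
        input_counts = _nb_draw(rng, config.input_mean, config.nb_dispersion, len(loci))
        chip_means = factors * config.input_mean * scale
        chip_counts = _nb_draw(rng, chip_means, config.nb_dispersion, len(loci))
        for lid, c, i in zip(loci.locus_id, chip_counts, input_counts):
            rows.append((lid, ds, int(c), int(i)))
    df = pd.DataFrame(rows, columns=["locus_id", "dataset", "chip_count", "input_count"])
    return LocusCountTable(df, totals)


def simulate_coverage(
    annotation: RepeatAnnotation,
    config: SimulationConfig,
    dataset: str,
    background: float = 0.05,
) -> dict[str, np.ndarray]:
    """Per-base coverage: flat background plus per-locus enrichment blocks."""
    rng = _rng(config.seed, f"simulate_coverage:{dataset}")
    tracks: dict[str, np.ndarray] = {}
    for chrom, length in annotation.genome_lengths.items():
        tracks[chrom] = np.full(length, background)
    for row in annotation.df.itertuples(index=False):
        factor = _factor_for(config, dataset, row.family)
        level = background * factor * float(rng.uniform(0.8, 1.2))
        tracks[row.chrom][row.start : row.end] += level
    return tracks


def simulate_atac_counts(
    anchors: pd.DataFrame,
    mean: float,
    dispersion: float,
    loss_factors: Mapping[str, float],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition per-anchor counts with planted accessibility loss.

    ``anchors`` needs ``integration_id`` and ``family`` columns (an
    :class:`~ervscape.ltr.AnchorSet`'s table works).  Condition A draws from
    NB(mean, dispersion); condition B multiplies the mean of each family by
    its ``loss_factors`` entry (default 1 = no change; 0.25 = 4x loss).
    """
    rng = _rng(seed, "simulate_atac_counts")
    fams = anchors["family"].to_numpy()
    n = len(anchors)
    a = _nb_draw(rng, mean, dispersion, n)
    means_b = np.array([mean * float(loss_factors.get(f, 1.0)) for f in fams])
    b = _nb_draw(rng, means_b, dispersion, n)
    base = anchors[["integration_id", "family"]].reset_index(drop=True)
    df_a = base.assign(count=a.astype(float))
    df_b = base.assign(count=b.astype(float))
    return df_a, df_b


def simulate_titration(
    kd: float,
    delta_i_max: float,
    p_total: float,
    ligand_series: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Titration from the quadratic isotherm; exact when ``noise_sd`` is 0."""
    ligand = np.asarray(ligand_series, dtype=float)
    if ligand.size == 0:
        raise ValueError("ligand_series is empty")
    clean = predict_delta_i(ligand, p_total, kd, delta_i_max)
    noise = _rng(seed, "simulate_titration").normal(0.0, noise_sd, ligand.size) if noise_sd > 0 else 0.0
    return TitrationSeries(ligand=ligand, delta_i=np.asarray(clean) + noise, p_total=p_total)


def simulate_peak_lists(
    n_residues: int,
    shifted_set: Sequence[int] = (),
    disappeared_set: Sequence[int] = (),
    shift_magnitudes=(0.1, 0.5),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apo and bound HSQC peak lists with planted shifts and disappearances.

    Apo peaks sit on a jittered grid (well separated relative to typical
    matching tolerances).  ``shift_magnitudes`` is either one ``(dH, dN)``
    pair applied to every shifted residue or a mapping residue -> pair.
    Returns ``(apo, bound)`` tables with columns
    ``residue_id, delta_h, delta_n, intensity``.
    """
    shifted = set(int(r) for r in shifted_set)
    disappeared = set(int(r) for r in disappeared_set)
    if shifted & disappeared:
        raise ValueError(f"residues in both shifted and disappeared sets: {sorted(shifted & disappeared)}")
    valid = set(range(1, n_residues + 1))
    bad = (shifted | disappeared) - valid
    if bad:
        raise ValueError(f"residue ids outside 1..{n_residues}: {sorted(bad)}")

    rng = _rng(seed, "simulate_peak_lists")
    n_cols = int(np.ceil(np.sqrt(n_residues)))
    ids = np.arange(1, n_residues + 1)
    gh = 6.5 + 0.3 * (ids % n_cols).astype(float)
    gn = 105.0 + 2.5 * (ids // n_cols).astype(float)
    apo = pd.DataFrame(
        {
            "residue_id": ids,
            "delta_h": gh + rng.uniform(-0.02, 0.02, n_residues),
            "delta_n": gn + rng.uniform(-0.2, 0.2, n_residues),
            "intensity": rng.uniform(0.8, 1.2, n_residues),
        }
    )

    def magnitudes(res: int) -> tuple[float, float]:
        if isinstance(shift_magnitudes, Mapping):
            return shift_magnitudes[res]
        return tuple(shift_magnitudes)  # type: ignore[return-value]

    bound = apo.copy()
    for res in sorted(shifted):
        dh, dn = magnitudes(res)
        i = bound.index[bound.residue_id == res][0]
        bound.loc[i, "delta_h"] += dh
        bound.loc[i, "delta_n"] += dn
    bound = bound[~bound.residue_id.isin(disappeared)].reset_index(drop=True)
    return apo, bound


def simulate_frap_curve(
    dip_depth: float,
    dip_time: float,
    n_frames: int = 300,
    frame_dt: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_prebleach: int = 5,
    dip_width: float = 2.0,
    bleach_depth: float = 0.5,
    recovery_tau: float = 10.0,
) -> FrapCurve:
    """Half-bleach FRAP curve with a planted Gaussian dip in the unbleached half.

    Bleach occurs at t = 0 after ``n_prebleach`` baseline frames.  The
    noiseless unbleached trace is ``1 - dip_depth * exp(-(t - dip_time)^2 /
    (2 * dip_width^2))``, whose analytic minimum is ``1 - dip_depth``; the
    bleached half follows a simple exponential recovery (plumbing only).
    """
    if not 0.0 <= dip_depth < 1.0:
        raise ValueError("dip_depth must be in [0, 1)")
    t = (np.arange(n_frames) - n_prebleach) * frame_dt
    if not t[0] <= dip_time <= t[-1]:
        raise ValueError(f"dip_time {dip_time} outside series span [{t[0]}, {t[-1]}]")
    unbleached = 1.0 - dip_depth * np.exp(-((t - dip_time) ** 2) / (2.0 * dip_width**2))
    bleached = np.where(t < 0, 1.0, 1.0 - bleach_depth * np.exp(-np.maximum(t, 0.0) / recovery_tau))
    if noise_sd > 0:
        rng = _rng(seed, "simulate_frap_curve")
        unbleached = unbleached + rng.normal(0.0, noise_sd, n_frames)
        bleached = bleached + rng.normal(0.0, noise_sd, n_frames)
    return FrapCurve(
        time=t,
        intensity_bleached=bleached,
        intensity_unbleached=unbleached,
        n_prebleach=n_prebleach,
    )
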