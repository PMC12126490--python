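"""Binding isotherms, chemical-shift perturbations, and FRAP dip depths.

Three small quantitative models used to characterize a protein-peptide
interaction:

* a ligand-depletion (quadratic) binding isotherm for fluorescence
  titrations, fitted by nonlinear least squares to estimate the dissociation
  constant ``Kd`` and the saturating signal change ``dI_max``;
* two standard per-residue chemical-shift-perturbation (CSP) metrics for
  1H,15N HSQC titrations — the Euclidean form ``sqrt(dH^2 + (dN/5)^2)`` and
  the weighted absolute-sum form ``|dH| + alpha*|dN|`` (alpha = 0.105, the
  ratio of the backbone 1H to 15N shift ranges) — together with apo/bound
  peak matching and disappeared-peak calling;
* the transient intensity dip of the non-bleached half in half-bleach FRAP,
  read from a Savitzky-Golay-smoothed recovery curve; a deep dip indicates
  liquid-like internal mixing of the compartment.

Concentration and intensity units are caller-supplied and opaque; only
internal consistency is assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linear_sum_assignment
from scipy.signal import savgol_filter

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "CSPRecord",
    "FrapCurve",
    "predict_delta_i",
    "fit_binding_isotherm",
    "summarize_replicates",
    "csp_euclidean",
    "csp_weighted_abs",
    "match_and_classify_peaks",
    "frap_dip_depth",
    "DEFAULT_ALPHA",
    "PEAK_COLUMNS",
]

DEFAULT_ALPHA = 0.105

#: expected columns of a peak-list table
PEAK_COLUMNS = ["residue_id", "delta_h", "delta_n", "intensity"]

STATUS_MATCHED = "matched"
STATUS_DISAPPEARED = "disappeared"
STATUS_UNASSIGNED = "unassigned"


# ----------------------------------------------------------------------
# quadratic binding isotherm
# ----------------------------------------------------------------------

def predict_delta_i(L, P: float, kd: float, delta_i_max: float):
    """Signal change at ligand concentration(s) ``L`` under ligand depletion.

    dI = dI_max * ((L + P + Kd) - sqrt((L + P + Kd)^2 - 4*P*L)) / (2*P)

    The square-root argument is clamped at zero: at exact stoichiometric
    saturation with ``Kd = 0`` it vanishes analytically and may go slightly
    negative in floating point.
    """
    if P <= 0:
        raise ValueError(f"protein concentration must be positive, got {P}")
    if kd < 0:
        raise ValueError(f"Kd must be non-negative, got {kd}")
    L = np.asarray(L, dtype=float)
    if (L < 0).any():
        raise ValueError("ligand concentrations must be non-negative")
    s = L + P + kd
    disc = s * s - 4.0 * P * L
    frac = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * P)
    out = delta_i_max * frac
    return float(out) if out.ndim == 0 else out


@dataclass
class TitrationSeries:
    """One titration: ligand concentrations, observed signal changes, [P]."""

    ligand: np.ndarray
    delta_i: np.ndarray
    p_total: float

    def __post_init__(self) -> None:
        self.ligand = np.asarray(self.ligand, dtype=float)
        self.delta_i = np.asarray(self.delta_i, dtype=float)
        if self.ligand.size == 0:
            raise ValueError("titration series is empty")
        if self.ligand.shape != self.delta_i.shape:
            raise ValueError("ligand and delta_i must have equal length")
        if (self.ligand < 0).any():
            raise ValueError("ligand concentrations must be non-negative")
        if self.p_total <= 0:
            raise ValueError("p_total must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ligand": self.ligand, "delta_i": self.delta_i})


@dataclass
class TitrationFit:
    """Least-squares estimates for one titration."""

    kd: float
    delta_i_max: float
    kd_stderr: float
    delta_i_max_stderr: float
    residual_norm: float
    n_points: int


def fit_binding_isotherm(series: TitrationSeries) -> TitrationFit:
    """Fit (Kd, dI_max) of the quadratic isotherm to a titration.

    Initialization: dI_max at the largest observed response, Kd at the
    ligand concentration of half-maximal response; Kd is bounded below by 0.
    Raises ``RuntimeError`` on non-convergence and ``ValueError`` on a flat
    (degenerate) series.
    """
    L, y, P = series.ligand, series.delta_i, series.p_total
    if L.size < 4:
        raise ValueError(f"need at least 4 titration points, got {L.size}")
    span = float(np.ptp(y))
    if span == 0.0:
        raise ValueError("degenerate titration: all responses identical")
    dmax0 = float(y[np.argmax(np.abs(y))])
    half = dmax0 / 2.0
    order = np.argsort(L)
    kd0 = float(np.interp(half, y[order], L[order])) if dmax0 > 0 else float(np.median(L))
    kd0 = max(kd0, 1e-12)

    def model(l, kd, dmax):
        return predict_delta_i(l, P, kd, dmax)

    try:
        popt, pcov = curve_fit(
            model,
            L,
            y,
            p0=[kd0, dmax0],
            bounds=([0.0, -np.inf], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"isotherm fit did not converge: {exc}") from exc
    resid = y - model(L, *popt)
    if not np.all(np.isfinite(resid)):
        raise RuntimeError("isotherm fit produced non-finite residuals")
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
    return TitrationFit(
        kd=float(popt[0]),
        delta_i_max=float(popt[1]),
        kd_stderr=float(stderr[0]),
        delta_i_max_stderr=float(stderr[1]),
        residual_norm=float(np.linalg.norm(resid)),
        n_points=int(L.size),
    )


def summarize_replicates(fits: Sequence[TitrationFit]) -> dict:
    """Mean Kd across replicate fits with sample-SD error (n-1 denominator)."""
    if len(fits) == 0:
        raise ValueError("no replicate fits supplied")
    kds = np.array([f.kd for f in fits], dtype=float)
    return {
        "kd_mean": float(kds.mean()),
        "kd_sd": float(kds.std(ddof=1)) if kds.size > 1 else float("nan"),
        "n": int(kds.size),
    }


# ----------------------------------------------------------------------
# chemical shift perturbations
# ----------------------------------------------------------------------

def csp_euclidean(d_h, d_n):
    """Combined CSP, Euclidean form: sqrt(dH^2 + (dN/5)^2), in ppm."""
    d_h = np.asarray(d_h, dtype=float)
    d_n = np.asarray(d_n, dtype=float)
    out = np.sqrt(d_h**2 + (d_n / 5.0) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_weighted_abs(d_h, d_n, alpha: float = DEFAULT_ALPHA):
    """Combined CSP, weighted absolute-sum form: |dH| + alpha*|dN|, in ppm."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    d_h = np.asarray(d_h, dtype=float)
    d_n = np.asarray(d_n, dtype=float)
    out = np.abs(d_h) + alpha * np.abs(d_n)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CSPRecord:
    """Per-residue perturbation between apo and bound HSQC spectra."""

    residue_id: int
    d_h: float
    d_n: float
    csp_euclidean: float
    csp_weighted: float
    alpha: float
    status: str


def _check_peaklist(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} peak list missing columns {missing}")
    if df.residue_id.duplicated().any():
        dupes = df.residue_id[df.residue_id.duplicated()].tolist()
        raise ValueError(f"{name} peak list has duplicate residue_ids: {dupes[:5]}")
    return df.reset_index(drop=True)


def match_and_classify_peaks(
    apo: pd.DataFrame,
    bound: pd.DataFrame,
    tol_h: float = 0.05,
    tol_n: float = 0.5,
    intensity_floor: float = 0.2,
) -> list[CSPRecord]:
    """Match apo peaks to bound peaks and call disappeared residues.

    Assignment is global: the total Euclidean-CSP distance over all matched
    pairs is minimized (Hungarian algorithm), with a pair admissible only
    inside the ``(tol_h, tol_n)`` tolerance ellipse.  An unmatched apo peak
    with no admissible bound peak of intensity at least ``intensity_floor``
    times its own is called *disappeared* (exchange-broadened beyond
    detection); otherwise it is left *unassigned*.
    """
    if tol_h <= 0 or tol_n <= 0:
        raise ValueError("tolerances must be positive")
    apo = _check_peaklist(apo, "apo")
    bound = _check_peaklist(bound, "bound")

    n_a, n_b = len(apo), len(bound)
    dh = apo.delta_h.to_numpy()[:, None] - bound.delta_h.to_numpy()[None, :]
    dn = apo.delta_n.to_numpy()[:, None] - bound.delta_n.to_numpy()[None, :]
    feasible = (dh / tol_h) ** 2 + (dn / tol_n) ** 2 <= 1.0
    dist = np.sqrt(dh**2 + (dn / 5.0) ** 2)
    BIG = dist[feasible].sum() + dist.max() + 1.0 if feasible.any() else 1.0
    cost = np.where(feasible, dist, BIG)

    rows, cols = linear_sum_assignment(cost) if n_a and n_b else (np.array([], int),) * 2
    matched_col = {int(r): int(c) for r, c in zip(rows, cols) if feasible[r, c]}

    records: list[CSPRecord] = []
    for i, peak in enumerate(apo.itertuples(index=False)):
        if i in matched_col:
            j = matched_col[i]
            d_h = float(bound.delta_h.iloc[j] - peak.delta_h)
            d_n = float(bound.delta_n.iloc[j] - peak.delta_n)
            records.append(
                CSPRecord(
                    residue_id=int(peak.residue_id),
                    d_h=d_h,
                    d_n=d_n,
                    csp_euclidean=csp_euclidean(d_h, d_n),
                    csp_weighted=csp_weighted_abs(d_h, d_n),
                    alpha=DEFAULT_ALPHA,
                    status=STATUS_MATCHED,
                )
            )
        else:
            nearby = feasible[i] & (bound.intensity.to_numpy() >= intensity_floor * peak.intensity)
            status = STATUS_UNASSIGNED if nearby.any() else STATUS_DISAPPEARED
            records.append(
                CSPRecord(
                    residue_id=int(peak.residue_id),
                    d_h=float("nan"),
                    d_n=float("nan"),
                    csp_euclidean=float("nan"),
                    csp_weighted=float("nan"),
                    alpha=DEFAULT_ALPHA,
                    status=status,
                )
            )
    return records


def csp_records_to_frame(records: Sequence[CSPRecord]) -> pd.DataFrame:
    """Tabulate CSP records (the per-residue bar-plot table)."""
    return pd.DataFrame(
        {
            "residue_id": [r.residue_id for r in records],
            "d_h": [r.d_h for r in records],
            "d_n": [r.d_n for r in records],
            "csp_euclidean": [r.csp_euclidean for r in records],
            "csp_weighted": [r.csp_weighted for r in records],
            "alpha": [r.alpha for r in records],
            "status": [r.status for r in records],
        }
    )


# ----------------------------------------------------------------------
# FRAP dip depth
# ----------------------------------------------------------------------

@dataclass
class FrapCurve:
    """Half-bleach FRAP time series, normalized to a pre-bleach baseline of 1."""

    time: np.ndarray
    intensity_bleached: np.ndarray
    intensity_unbleached: np.ndarray
    n_prebleach: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity_bleached = np.asarray(self.intensity_bleached, dtype=float)
        self.intensity_unbleached = np.asarray(self.intensity_unbleached, dtype=float)
        if not (self.time.shape == self.intensity_bleached.shape == self.intensity_unbleached.shape):
            raise ValueError("time and intensity arrays must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.n_prebleach < 1 or self.n_prebleach > self.time.size:
            raise ValueError("pre-bleach baseline segment must be non-empty")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "intensity_bleached": self.intensity_bleached,
                "intensity_unbleached": self.intensity_unbleached,
            }
        )


def frap_dip_depth(
    curve: FrapCurve,
    sg_window: int = 11,
    sg_order: int = 3,
    probe_times: Sequence[float] = (),
    probe_halfwidth: float = 5.0,
) -> dict[float, float]:
    """Dip depths of the non-bleached half at the given probe times.

    The unbleached trace is smoothed with a Savitzky-Golay filter
    (``sg_window`` frames, polynomial order ``sg_order``); the dip at probe
    time ``t`` is ``1 - min(smoothed)`` over a symmetric window of
    ``probe_halfwidth`` seconds around ``t``, clipped to [0, 1].
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    if sg_window >= curve.time.size:
        raise ValueError(
            f"sg_window ({sg_window}) must be smaller than the series length ({curve.time.size})"
        )
    smoothed = savgol_filter(curve.intensity_unbleached, sg_window, sg_order)
    depths: dict[float, float] = {}
    for t in probe_times:
        if t < curve.time[0] or t > curve.time[-1]:
            raise ValueError(f"probe time {t} outside series span")
        mask = np.abs(curve.time - t) <= probe_halfwidth
        depth = 1.0 - float(smoothed[mask].min())
        depths[float(t)] = float(min(max(depth, 0.0), 1.0))
    return depths
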