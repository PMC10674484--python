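"""Pyrene-assay estimation of the critical aggregation concentration.

Pyrene's first (372 nm) and third (387 nm) emission vibronic bands change
relative intensity with the polarity of the probe's surroundings: the I1/I3
ratio sits near 1.8 in water and drops when pyrene partitions into an
apolar aggregate core.  Plotting I1/I3 against log10(concentration) of an
amphiphile therefore shows two linear regimes — a near-flat polar branch
below the critical aggregation concentration (cac) and a steeply
descending branch above it — and the cac is read off at the intersection
of the two lines.

The breakpoint search is a deterministic scan over all splits of the
sorted points into a left and a right segment (each at least three
points): each side gets an ordinary least-squares line in
(log10 c, ratio) space, the split is admissible when the intersection
falls between the two bracketing concentrations, and the admissible split
with the smallest total squared residual wins.  A bootstrap over points
gives a confidence interval.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "CacFit",
    "vibronic_ratio",
    "fit_cac_segmented",
    "read_ratio_table",
    "read_spectra_dir",
    "write_cac_report",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """An emission spectrum labelled by the titrant concentration (uM)."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    label_uM: Optional[float] = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or inten.shape != wl.shape:
            raise ValueError("wavelengths and intensities must match in length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class TitrationSeries:
    """(concentration uM, I1/I3 ratio) points, sorted by concentration."""

    concentrations_uM: np.ndarray
    ratios: np.ndarray
    provenance: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_uM, dtype=float)
        r = np.asarray(self.ratios, dtype=float)
        if c.ndim != 1 or r.shape != c.shape:
            raise ValueError("concentrations and ratios must match in length")
        if len(c) < 6:
            raise ValueError(f"need at least 6 titration points, got {len(c)}")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        order = np.argsort(c)
        c, r = c[order], r[order]
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be distinct")
        object.__setattr__(self, "concentrations_uM", c)
        object.__setattr__(self, "ratios", r)
        if self.provenance is not None:
            prov = tuple(np.asarray(self.provenance, dtype=object)[order])
            object.__setattr__(self, "provenance", prov)

    def __len__(self) -> int:
        return len(self.concentrations_uM)


@dataclass(frozen=True)
class CacFit:
    """Two-segment fit of I1/I3 vs log10(concentration).

    ``flag`` is ``"ok"`` or ``"no_breakpoint"`` (single linear regime, or
    no admissible intersection).  Slopes are in ratio units per decade of
    concentration.
    """

    cac_uM: Optional[float]
    log10_cac: Optional[float]
    slope_below: Optional[float]
    intercept_below: Optional[float]
    slope_above: Optional[float]
    intercept_above: Optional[float]
    sse: Optional[float]
    bootstrap_ci_uM: Optional[Tuple[float, float]]
    flag: str
    split_index: Optional[int] = None


def vibronic_ratio(
    spectrum: EmissionSpectrum,
    lambda1_nm: float = 372.0,
    lambda3_nm: float = 387.0,
    window_nm: float = 2.0,
) -> float:
    """I1/I3: peak intensity near 372 nm over peak intensity near 387 nm.

    Each band intensity is the maximum within ``window_nm`` of the nominal
    wavelength, which tolerates small calibration shifts.
    """
    wl = spectrum.wavelengths_nm
    for lam in (lambda1_nm, lambda3_nm):
        if lam - window_nm < wl[0] or lam + window_nm > wl[-1]:
            raise ValueError(
                f"band at {lam} nm (±{window_nm}) outside the spectral grid "
                f"[{wl[0]}, {wl[-1]}] nm"
            )

    def band_max(lam: float) -> float:
        mask = np.abs(wl - lam) <= window_nm
        return float(spectrum.intensities[mask].max())

    i1, i3 = band_max(lambda1_nm), band_max(lambda3_nm)
    if i3 == 0:
        raise ValueError("third vibronic band has zero intensity; ratio undefined")
    return i1 / i3


def _linefit(x: np.ndarray, y: np.ndarray):
    """OLS line through (x, y): slope, intercept, sse, sum (x - xbar)^2.

    Returns None for a degenerate segment (all x identical).
    """
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    if sxx == 0:
        return None
    slope = float(dx @ (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    sse = float(resid @ resid)
    return slope, intercept, sse, sxx


def _grid_breakpoint(x: np.ndarray, y: np.ndarray, min_seg: int = 3):
    """Best admissible split; returns (k, lines, xstar, sse) or None.

    Slope standard errors use the residual variance pooled over both
    segments (n - 4 degrees of freedom), which keeps the equality test
    stable when one segment has only three points.
    """
    n = len(x)
    best = None
    for k in range(min_seg, n - min_seg + 1):
        left = _linefit(x[:k], y[:k])
        right = _linefit(x[k:], y[k:])
        if left is None or right is None:
            continue
        m1, b1, sse1, sxx1 = left
        m2, b2, sse2, sxx2 = right
        dm = m1 - m2
        if dm == 0:
            continue
        xstar = (b2 - b1) / dm
        # the intersection must fall inside the measured concentration
        # range; noise may push it slightly past the split's own bracket
        if not x[0] <= xstar <= x[-1]:
            continue
        sse = sse1 + sse2
        s2_pooled = sse / max(n - 4, 1)
        se1 = float(np.sqrt(s2_pooled / sxx1))
        se2 = float(np.sqrt(s2_pooled / sxx2))
        if best is None or sse < best[-1]:
            best = (k, (m1, b1, se1), (m2, b2, se2), xstar, sse)
    return best


def fit_cac_segmented(
    series: TitrationSeries,
    method: str = "grid_breakpoint",
    n_bootstrap: int = 500,
    seed: int = 0,
    regions: Optional[Tuple[Sequence[int], Sequence[int]]] = None,
) -> CacFit:
    """Estimate the cac as the intersection of two lines in semi-log space.

    Parameters
    ----------
    series : TitrationSeries
        Sorted (concentration, I1/I3) points; at least 3 per segment.
    method : {"grid_breakpoint", "manual_regions"}
        ``grid_breakpoint`` scans every admissible split of the sorted
        points; ``manual_regions`` fits the two index ranges given in
        ``regions``.
    n_bootstrap : int
        Number of resamples for the percentile confidence interval
        (0 disables the bootstrap).
    seed : int
        Seed for the bootstrap resampling.

    Returns
    -------
    CacFit
        With ``flag="no_breakpoint"`` when the two slopes are
        indistinguishable within their joint standard error or no split
        admits an in-range intersection.
    """
    x = np.log10(series.concentrations_uM)
    y = series.ratios

    if method == "manual_regions":
        if regions is None:
            raise ValueError("manual_regions requires the two index ranges")
        left, right = (np.asarray(r, dtype=int) for r in regions)
        if len(left) < 3 or len(right) < 3:
            raise ValueError("each region needs at least 3 points")
        fit1 = _linefit(x[left], y[left])
        fit2 = _linefit(x[right], y[right])
        if fit1 is None or fit2 is None:
            raise ValueError("a region has no spread in concentration")
        m1, b1, sse1, sxx1 = fit1
        m2, b2, sse2, sxx2 = fit2
        s2_pooled = (sse1 + sse2) / max(len(left) + len(right) - 4, 1)
        se1 = float(np.sqrt(s2_pooled / sxx1))
        se2 = float(np.sqrt(s2_pooled / sxx2))
        if _slopes_equal(m1, se1, m2, se2):
            return _no_breakpoint()
        xstar = (b2 - b1) / (m1 - m2)
        return CacFit(
            cac_uM=float(10**xstar), log10_cac=float(xstar),
            slope_below=m1, intercept_below=b1,
            slope_above=m2, intercept_above=b2,
            sse=sse1 + sse2, bootstrap_ci_uM=None, flag="ok",
        )
    if method != "grid_breakpoint":
        raise ValueError(f"unknown method {method!r}")

    best = _grid_breakpoint(x, y)
    if best is None:
        return _no_breakpoint()
    k, (m1, b1, se1), (m2, b2, se2), xstar, sse = best
    if _slopes_equal(m1, se1, m2, se2):
        return _no_breakpoint()

    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(x)
        boot = []
        for _ in range(n_bootstrap):
            idx = np.sort(rng.integers(0, n, size=n))
            xb, yb = x[idx], y[idx]
            if len(np.unique(xb)) < 4:
                continue
            res = _grid_breakpoint(xb, yb)
            if res is not None:
                boot.append(res[3])
        if len(boot) >= 10:
            lo, hi = np.percentile(boot, [2.5, 97.5])
            ci = (float(10**lo), float(10**hi))

    return CacFit(
        cac_uM=float(10**xstar), log10_cac=float(xstar),
        slope_below=m1, intercept_below=b1,
        slope_above=m2, intercept_above=b2,
        sse=sse, bootstrap_ci_uM=ci, flag="ok", split_index=k,
    )


def _slopes_equal(m1: float, se1: float, m2: float, se2: float) -> bool:
    joint_se = float(np.hypot(se1 if np.isfinite(se1) else 0.0,
                              se2 if np.isfinite(se2) else 0.0))
    atol = 1e-9 * (1.0 + abs(m1) + abs(m2))
    return abs(m1 - m2) <= max(joint_se, atol)


def _no_breakpoint() -> CacFit:
    return CacFit(cac_uM=None, log10_cac=None, slope_below=None,
                  intercept_below=None, slope_above=None, intercept_above=None,
                  sse=None, bootstrap_ci_uM=None, flag="no_breakpoint")


# ---------------------------------------------------------------------------
# text I/O

_CONC_RE = re.compile(r"(\d+(?:\.\d+)?)\s*uM", re.IGNORECASE)


def read_ratio_table(path) -> TitrationSeries:
    """Read a delimited (concentration_uM, ratio) or
    (concentration_uM, I1, I3) table; '#' lines are comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns")
    if data.shape[1] == 3:
        ratios = data[:, 1] / data[:, 2]
    else:
        ratios = data[:, 1]
    return TitrationSeries(concentrations_uM=data[:, 0], ratios=ratios)


def read_spectra_dir(directory, **ratio_kwargs) -> TitrationSeries:
    """Build a titration series from a directory of 2-column spectra.

    Each file holds (wavelength_nm, intensity); the concentration is taken
    from a ``# concentration_uM = <x>`` header line, or failing that from a
    ``<x>uM`` token in the filename.
    """
    directory = Path(directory)
    concs, ratios, names = [], [], []
    for path in sorted(directory.iterdir()):
        if path.suffix not in {".tsv", ".txt", ".csv", ".dat"}:
            continue
        conc = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "concentration_uM" in line:
                    conc = float(line.split("=")[1])
        if conc is None:
            m = _CONC_RE.search(path.name)
            if m:
                conc = float(m.group(1))
        if conc is None:
            raise ValueError(f"{path}: no concentration in header or filename")
        data = np.loadtxt(path, comments="#")
        spec = EmissionSpectrum(data[:, 0], data[:, 1], label_uM=conc)
        concs.append(conc)
        ratios.append(vibronic_ratio(spec, **ratio_kwargs))
        names.append(path.name)
    return TitrationSeries(np.array(concs), np.array(ratios),
                           provenance=tuple(names))


def write_cac_report(fit: CacFit, series: TitrationSeries,
                     json_path, segments_path=None) -> None:
    """Write the fit as JSON and a plot-ready table of both segments."""
    report = {
        "cac_uM": fit.cac_uM,
        "log10_cac": fit.log10_cac,
        "slope_below_per_decade": fit.slope_below,
        "intercept_below": fit.intercept_below,
        "slope_above_per_decade": fit.slope_above,
        "intercept_above": fit.intercept_above,
        "sse": fit.sse,
        "bootstrap_ci_uM": fit.bootstrap_ci_uM,
        "flag": fit.flag,
    }
    Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    if segments_path is not None and fit.flag == "ok":
        x = np.log10(series.concentrations_uM)
        below = fit.slope_below * x + fit.intercept_below
        above = fit.slope_above * x + fit.intercept_above
        np.savetxt(
            segments_path,
            np.column_stack([series.concentrations_uM, series.ratios, below, above]),
            header="concentration_uM\tratio\tsegment_below\tsegment_above",
            fmt="%.6g", delimiter="\t",
        )
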