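"""Multi-exponential analysis of TCSPC fluorescence decays.

A time-correlated single-photon-counting histogram records photon arrival
times whose expectation is a sum of exponentials, optionally convolved with
the instrument response function (IRF), on top of a constant background::

    m(t) = B + sum_i A_i exp(-(t - t0) / tau_i)          (tail fit)
    m(t) = B + (IRF (x) sum_i A_i exp(-t / tau_i))(t)    (reconvolution)

Counts are Poisson distributed, so the fit minimises chi-square with
variance ``max(counts, 1)`` per channel.  Fractional amplitudes
``alpha_i = A_i / sum_j A_j`` and the amplitude-weighted mean lifetime
``<tau> = sum_i alpha_i tau_i`` summarise the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import lmfit
import numpy as np

__all__ = [
    "DecayTrace",
    "DecayFit",
    "DecayFitError",
    "fit_multiexponential",
    "average_lifetime",
    "read_decay_table",
    "write_decay_table",
    "write_fit_report",
]


class DecayFitError(RuntimeError):
    """Raised when the decay fit cannot produce trustworthy parameters."""


@dataclass(frozen=True)
class DecayTrace:
    """A TCSPC histogram: photon counts on a uniform time grid (ns).

    ``counts`` are non-negative; floats are accepted so that noiseless
    model curves can round-trip through the fitter.  ``irf`` is an optional
    instrument-response histogram on the same grid.
    """

    times_ns: np.ndarray
    counts: np.ndarray
    irf: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ns, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times_ns", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and counts must be 1-D arrays of equal length")
        dt = np.diff(t)
        if len(t) < 2 or np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        # rounded text representations keep ~1e-4 relative channel spacing
        if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.irf is not None:
            irf = np.asarray(self.irf, dtype=float)
            object.__setattr__(self, "irf", irf)
            if irf.shape != t.shape:
                raise ValueError("irf must share the time grid of the counts")

    @property
    def dt_ns(self) -> float:
        return float(self.times_ns[1] - self.times_ns[0])


@dataclass(frozen=True)
class DecayFit:
    """Result of a multi-exponential decay fit.

    ``components`` are (alpha, tau_ns) pairs sorted by ascending lifetime
    with the alphas normalised to sum to one.  ``flag`` is ``"ok"`` or
    ``"ill-conditioned"`` (two lifetimes within 5% of each other).
    """

    components: Tuple[Tuple[float, float], ...]
    background: float
    chi2_reduced: float
    fitted_curve: np.ndarray
    fit_times_ns: np.ndarray
    average_lifetime_ns: float
    covariance: Optional[np.ndarray]
    stderr: Tuple[Tuple[Optional[float], Optional[float]], ...]
    flag: str = "ok"

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def taus_ns(self) -> np.ndarray:
        return np.array([t for _, t in self.components])


def average_lifetime(fit, mode: str = "amplitude") -> float:
    """Mean lifetime of a fit (or of an (alpha, tau) sequence), in ns.

    ``amplitude`` mode returns sum(a_i tau_i)/sum(a_i): the mean arrival
    time weighted by how many molecules decay through each channel.
    ``intensity`` mode weights by emitted photons instead,
    sum(a_i tau_i^2)/sum(a_i tau_i), and is never smaller.
    """
    comps = fit.components if isinstance(fit, DecayFit) else tuple(fit)
    if len(comps) == 0:
        raise ValueError("fit has no components")
    a = np.array([c[0] for c in comps], dtype=float)
    tau = np.array([c[1] for c in comps], dtype=float)
    if mode == "amplitude":
        return float(np.sum(a * tau) / np.sum(a))
    if mode == "intensity":
        return float(np.sum(a * tau**2) / np.sum(a * tau))
    raise ValueError(f"unknown mode {mode!r}; use 'amplitude' or 'intensity'")


def _multiexp(t_rel: np.ndarray, amps: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.sum(amps[:, None] * np.exp(-t_rel[None, :] / taus[:, None]), axis=0)


def _model_curve(params: lmfit.Parameters, t_rel: np.ndarray, n: int,
                 irf: Optional[np.ndarray]) -> np.ndarray:
    amps = np.array([params[f"amp{i}"].value for i in range(n)])
    taus = np.array([params[f"tau{i}"].value for i in range(n)])
    decay = _multiexp(t_rel, amps, taus)
    if irf is not None:
        decay = np.convolve(irf, decay)[: len(t_rel)]
    return params["background"].value + decay


def _tail_slope_tau(t: np.ndarray, c: np.ndarray) -> float:
    """Crude longest-lifetime estimate from the log-linear tail."""
    n = len(t)
    tail = slice(max(0, int(0.5 * n)), n)
    tt, cc = t[tail], c[tail]
    pos = cc > 0
    if pos.sum() >= 3:
        slope = np.polyfit(tt[pos], np.log(cc[pos]), 1)[0]
        if slope < 0:
            return float(np.clip(-1.0 / slope, t[1] - t[0], t[-1] - t[0]))
    return float(0.2 * (t[-1] - t[0]))


def fit_multiexponential(
    trace: DecayTrace,
    n_components: int,
    fit_start: Optional[float] = None,
    reconvolve: bool = False,
) -> DecayFit:
    """Weighted least-squares fit of ``n_components`` exponentials.

    Parameters
    ----------
    trace : DecayTrace
        Histogram to fit; the grid must be uniform.
    n_components : int
        Number of exponential terms (1-4).
    fit_start : float, optional
        Start of the fit window in ns.  Unset: the channel of maximum
        counts (tail fitting), or the first channel when reconvolving.
    reconvolve : bool
        Convolve the model with ``trace.irf`` (required present) instead of
        tail fitting.

    Notes
    -----
    The optimisation is deterministic: initial lifetimes come from the
    tail slope and a fixed geometric ladder, and a small fixed set of
    perturbed restarts guards against local minima.

    Raises
    ------
    DecayFitError
        If no start converges.  A fit whose lifetimes collapse onto each
        other (within 5%) is returned with ``flag="ill-conditioned"``.
    """
    if not 1 <= n_components <= 4:
        raise ValueError(f"n_components must be in 1..4, got {n_components}")
    t, c = trace.times_ns, trace.counts
    irf_norm = None
    if reconvolve:
        if trace.irf is None:
            raise ValueError("reconvolve=True requires trace.irf")
        if trace.irf.sum() <= 0:
            raise ValueError("irf has no counts")
        irf_norm = trace.irf / trace.irf.sum()
        start_idx = 0
    else:
        start_idx = int(np.argmax(c))
    if fit_start is not None:
        start_idx = int(np.searchsorted(t, fit_start))
    if len(t) - start_idx < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} channels past fit_start, "
            f"have {len(t) - start_idx}"
        )
    tfit = t[start_idx:]
    cfit = c[start_idx:]
    t_rel = tfit - tfit[0] if irf_norm is None else t - t[0]
    weights = 1.0 / np.sqrt(np.maximum(cfit, 1.0))

    def residual(params):
        curve = _model_curve(params, t_rel, n_components, irf_norm)
        if irf_norm is not None:
            curve = curve[start_idx:]
        return (curve - cfit) * weights

    tau_long = _tail_slope_tau(tfit, cfit)
    peak = float(cfit.max())
    bg0 = max(float(np.median(cfit[-max(8, len(cfit) // 20):])), 0.0)

    rng = np.random.default_rng(20201122)  # fixed: restarts, not data noise
    best = None
    for attempt in range(4):
        params = lmfit.Parameters()
        params.add("background", value=bg0, min=0.0)
        for i in range(n_components):
            ratio = 0.3 ** (n_components - 1 - i)
            tau0 = tau_long * ratio
            if attempt > 0:
                tau0 *= float(np.exp(rng.normal(0.0, 0.35)))
            params.add(f"tau{i}", value=tau0, min=1e-6 * tau_long)
            params.add(f"amp{i}", value=max(peak - bg0, 1.0) / n_components,
                       min=0.0)
        try:
            result = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if not result.success:
            continue
        if best is None or result.redchi < best.redchi:
            best = result
        # a weighted fit at the Poisson-expected chi2 has converged;
        # further restarts cannot improve it meaningfully
        if best.redchi < 1.15:
            break
    if best is None:
        raise DecayFitError("decay fit did not converge for any start")

    amps = np.array([best.params[f"amp{i}"].value for i in range(n_components)])
    taus = np.array([best.params[f"tau{i}"].value for i in range(n_components)])
    amp_err = [best.params[f"amp{i}"].stderr for i in range(n_components)]
    tau_err = [best.params[f"tau{i}"].stderr for i in range(n_components)]
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    errs = tuple((amp_err[i], tau_err[i]) for i in order)
    total = amps.sum()
    alphas = amps / total if total > 0 else np.full(n_components, np.nan)

    flag = "ok"
    for i in range(n_components - 1):
        if taus[i + 1] <= 0 or abs(taus[i + 1] - taus[i]) / taus[i + 1] < 0.05:
            flag = "ill-conditioned"

    curve = _model_curve(best.params, t_rel, n_components, irf_norm)
    if irf_norm is not None:
        fit_times, fitted = t, curve
    else:
        fit_times, fitted = tfit, curve
    components = tuple((float(a), float(tau)) for a, tau in zip(alphas, taus))
    return DecayFit(
        components=components,
        background=float(best.params["background"].value),
        chi2_reduced=float(best.redchi),
        fitted_curve=fitted,
        fit_times_ns=fit_times,
        average_lifetime_ns=average_lifetime(components, "amplitude"),
        covariance=getattr(best, "covar", None),
        stderr=errs,
        flag=flag,
    )


# ---------------------------------------------------------------------------
# text I/O

def read_decay_table(path) -> DecayTrace:
    """Read a 2-column (time_ns, counts) delimited text file.

    An optional third column is taken as IRF counts on the same grid.
    Lines starting with '#' are comments; the delimiter is any whitespace
    or a comma.
    """
    data = np.loadtxt(path, comments="#", delimiter=None if _is_ws(path) else ",")
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns")
    irf = data[:, 2] if data.shape[1] == 3 else None
    return DecayTrace(times_ns=data[:, 0], counts=data[:, 1], irf=irf)


def _is_ws(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "," not in line
    return True


def write_decay_table(trace: DecayTrace, path) -> None:
    """Write a trace as delimited text (time_ns, counts[, irf])."""
    cols = [trace.times_ns, trace.counts]
    header = "time_ns\tcounts"
    if trace.irf is not None:
        cols.append(trace.irf)
        header += "\tirf_counts"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.9g",
               delimiter="\t")


def write_fit_report(fit: DecayFit, json_path, curve_path=None) -> None:
    """Write fit parameters as JSON and, optionally, the fitted curve table."""
    report = {
        "components": [
            {"alpha": a, "tau_ns": tau,
             "alpha_stderr": fit.stderr[i][0], "tau_stderr_ns": fit.stderr[i][1]}
            for i, (a, tau) in enumerate(fit.components)
        ],
        "background_counts": fit.background,
        "chi2_reduced": fit.chi2_reduced,
        "average_lifetime_ns": fit.average_lifetime_ns,
        "flag": fit.flag,
    }
    Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    if curve_path is not None:
        np.savetxt(curve_path,
                   np.column_stack([fit.fit_times_ns, fit.fitted_curve]),
                   header="time_ns\tfitted_counts", fmt="%.6g", delimiter="\t")
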