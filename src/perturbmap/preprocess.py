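"""Fluorescence preprocessing: neuropil correction, ΔF/F, event traces.

ΔF/F uses a slow rolling-percentile baseline: per frame, the baseline is
the ``pct``-th percentile (linear interpolation between order statistics)
of the neuron's fluorescence over a window of ``half_window`` frames
before and after, truncated at the trace edges.  Events come from a
direct AR1 inversion of ΔF/F with a fixed indicator time constant and a
small-event floor; analyses default to ΔF/F, with the event path available
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivityBundle",
    "neuropil_correct",
    "delta_f_over_f",
    "delta_f_over_f_matrix",
    "deconvolve_ar1",
    "preprocess_session",
    "DegenerateBaselineError",
]


class DegenerateBaselineError(ValueError):
    """Baseline fluorescence was <= 0 somewhere, ΔF/F undefined."""


@dataclass
class ActivityBundle:
    """Processed activity: ΔF/F and nonnegative deconvolved events."""

    dff: np.ndarray
    events: np.ndarray | None
    frame_rate: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff must be finite")
        if self.events is not None:
            if self.events.shape != self.dff.shape:
                raise ValueError("events and dff shapes differ")
            if np.any(self.events < 0):
                raise ValueError("events must be nonnegative")


def neuropil_correct(f_raw: np.ndarray, f_neu: np.ndarray, r: float = 0.7) -> np.ndarray:
    """Subtract the scaled neuropil trace: f_raw − r · f_neu (r = 0.7)."""
    f_raw = np.asarray(f_raw)
    f_neu = np.asarray(f_neu)
    if f_raw.shape != f_neu.shape:
        raise ValueError(f"shape mismatch: {f_raw.shape} vs {f_neu.shape}")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    return f_raw - r * f_neu


def _interior_percentile_numpy(f: np.ndarray, w: int, pct: float) -> np.ndarray:
    win = 2 * w + 1
    from numpy.lib.stride_tricks import sliding_window_view
    view = sliding_window_view(f, win, axis=1)  # (n, t-2w, win)
    out = np.empty((f.shape[0], view.shape[1]))
    chunk = max(1, int(2e7 // (win * f.shape[0])))
    for s in range(0, view.shape[1], chunk):
        sl = view[:, s:s + chunk]
        out[:, s:s + sl.shape[1]] = np.percentile(sl, pct, axis=2)
    return out


_numba_interior = None


def _get_numba_interior():
    """JIT-compiled sliding-window percentile (sorted-buffer updates);
    falls back to chunked numpy when numba is unavailable."""
    global _numba_interior
    if _numba_interior is not None:
        return _numba_interior
    try:
        from numba import njit
    except ImportError:  # pragma: no cover
        _numba_interior = False
        return False

    @njit(cache=False)
    def interior(f, w, kf):
        n, t = f.shape
        m = 2 * w + 1
        k = int(kf)
        frac = kf - k
        out = np.empty((n, t - 2 * w))
        for i in range(n):
            buf = np.sort(f[i, :m].copy())
            out[i, 0] = buf[k] + frac * (buf[k + 1] - buf[k]) \
                if k + 1 < m else buf[k]
            for s in range(1, t - 2 * w):
                old = f[i, s - 1]
                new = f[i, s + m - 1]
                j = np.searchsorted(buf, old)
                if new >= old:
                    while j + 1 < m and buf[j + 1] < new:
                        buf[j] = buf[j + 1]
                        j += 1
                else:
                    while j > 0 and buf[j - 1] > new:
                        buf[j] = buf[j - 1]
                        j -= 1
                buf[j] = new
                out[i, s] = buf[k] + frac * (buf[k + 1] - buf[k]) \
                    if k + 1 < m else buf[k]
        return out

    _numba_interior = interior
    return interior


def _rolling_percentile(f: np.ndarray, half_window: int, pct: float) -> np.ndarray:
    """Per-frame percentile of f over [t-half_window, t+half_window],
    truncated at the edges.  f is (neurons, frames)."""
    n, t = f.shape
    w = half_window
    base = np.empty((n, t), dtype=np.float64)
    interior_lo = min(w, t)
    interior_hi = max(t - w, interior_lo)
    # edges: growing/shrinking windows
    for i in range(interior_lo):
        base[:, i] = np.percentile(f[:, : i + w + 1], pct, axis=1)
    for i in range(interior_hi, t):
        base[:, i] = np.percentile(f[:, i - w:], pct, axis=1)
    # interior: full-size windows
    if interior_hi > interior_lo:
        jit = _get_numba_interior()
        kf = (pct / 100.0) * (2 * w)  # linear-interpolation position
        if jit:
            base[:, interior_lo:interior_hi] = jit(
                np.ascontiguousarray(f, dtype=np.float64), w, kf)
        else:
            base[:, interior_lo:interior_hi] = \
                _interior_percentile_numpy(f, w, pct)
    return base


def delta_f_over_f(f: np.ndarray, half_window: int = 450, pct: float = 8.0) -> np.ndarray:
    """ΔF/F with a rolling ``pct``-th percentile baseline.

    Accepts a single trace or a (neurons, frames) matrix.  Raises
    :class:`DegenerateBaselineError` if any baseline value is <= 0.
    """
    f = np.asarray(f, dtype=np.float64)
    single = f.ndim == 1
    mat = f[None, :] if single else f
    if mat.shape[1] < 1:
        raise ValueError("empty trace")
    base = _rolling_percentile(mat, int(half_window), float(pct))
    if np.any(base <= 0):
        bad = np.unique(np.nonzero(base <= 0)[0])
        raise DegenerateBaselineError(
            f"non-positive baseline for neuron(s) {bad.tolist()[:10]}")
    dff = (mat - base) / base
    return dff[0] if single else dff


def delta_f_over_f_matrix(f: np.ndarray, half_window: int = 450,
                          pct: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Matrix ΔF/F that flags (rather than raises on) degenerate neurons.

    Returns (dff, bad_mask); rows with a non-positive baseline anywhere are
    zeroed and flagged so downstream stages can exclude them.
    """
    f = np.asarray(f, dtype=np.float64)
    base = _rolling_percentile(f, int(half_window), float(pct))
    bad = np.any(base <= 0, axis=1)
    base[bad] = 1.0
    dff = (f - base) / base
    dff[bad] = 0.0
    return dff, bad


def deconvolve_ar1(dff: np.ndarray, frame_rate: float, tau: float,
                   event_floor: float = 0.05) -> np.ndarray:
    """Invert the AR1 calcium kernel to recover event magnitudes.

    The indicator model is c[t] = g c[t-1] + s[t] with g = exp(-1/(fr·tau));
    the inversion s[t] = c[t] - g c[t-1] is exact on noiseless transients.
    Events below ``event_floor`` (and negative residuals) are set to zero.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    dff = np.asarray(dff, dtype=np.float64)
    if not np.all(np.isfinite(dff)):
        raise ValueError("non-finite values in dff")
    g = np.exp(-1.0 / (frame_rate * tau))
    s = dff.copy()
    if dff.ndim == 1:
        s[1:] -= g * dff[:-1]
    else:
        s[:, 1:] -= g * dff[:, :-1]
    s[s < event_floor] = 0.0
    return s


def preprocess_session(session, *, r: float = 0.7, half_window: int = 450,
                       pct: float = 8.0, tau: float | None = None,
                       event_floor: float = 0.05,
                       compute_events: bool = False) -> ActivityBundle:
    """Run the full preprocessing chain on a :class:`~perturbmap.syndata.Session`.

    Stores the result under ``session.processed['bundle']`` and returns it.
    ``tau`` defaults to the generator's calcium_tau when available, else 0.35 s.
    """
    f = neuropil_correct(session.f_raw, session.f_neu, r=r)
    dff, bad = delta_f_over_f_matrix(f, half_window=half_window, pct=pct)
    events = None
    if compute_events:
        if tau is None:
            tau = session.params.calcium_tau if session.params is not None else 0.35
        events = deconvolve_ar1(dff, session.frame_rate, tau, event_floor)
    bundle = ActivityBundle(dff=dff, events=events, frame_rate=session.frame_rate)
    session.processed["bundle"] = bundle
    session.processed["degenerate_neurons"] = np.flatnonzero(bad)
    return bundle
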