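"""Derived metrics: APD, transient metrics, I-V / gain curves, integrated
flux fractions, fractional release, recirculation, exponential fits.

All metrics are pure functions of simulation output plus configuration; they
can be recomputed from any stored :class:`~gpmyo.cell.SimulationResult`.
Quadrature is trapezoidal on the 1-ms output grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

APD_NO_CAPTURE = float("nan")


def apd(t, v, fraction: float = 0.9, reference: str = "upstroke") -> float:
    """Action-potential duration at the given repolarization fraction.

    Measured from the time of maximum upstroke velocity (default) or from
    the start of the trace (``reference='onset'``) to the time V first falls
    below ``peak - fraction * (peak - rest)``, where rest is the
    pre-upstroke potential.  Returns NaN if no AP is detected (no capture).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) < 3:
        return APD_NO_CAPTURE
    kv = int(np.argmax(v))
    if v[kv] < -20.0 or kv == 0:
        return APD_NO_CAPTURE
    dv = np.gradient(v, t)
    kup = int(np.argmax(dv[: kv + 1]))
    v_rest = v[: max(kup, 1)].min() if kup > 0 else v[0]
    v_thr = v[kv] - fraction * (v[kv] - v_rest)
    below = np.where((t > t[kv]) & (v <= v_thr))[0]
    if len(below) == 0:
        return APD_NO_CAPTURE
    k = below[0]
    # sub-sample crossing by linear interpolation
    t_cross = np.interp(v_thr, [v[k], v[k - 1]], [t[k], t[k - 1]])
    t_ref = t[kup] if reference == "upstroke" else t[0]
    return float(t_cross - t_ref)


@dataclass
class TransientMetrics:
    peak: float
    time_to_peak: float          # from trace start (stimulus), ms
    delay_from_v_peak: float     # ms
    decay_half_time: float       # time from peak to half-amplitude, ms
    diastolic: float


def transient_metrics(t, x, v=None) -> TransientMetrics:
    """Peak/timing/decay metrics of a transient (Ca2+, force, ...)."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    kc = int(np.argmax(x))
    dia = float(x[0])
    half = dia + 0.5 * (x[kc] - dia)
    below = np.where((t > t[kc]) & (x <= half))[0]
    decay = float(t[below[0]] - t[kc]) if len(below) else float("nan")
    delay = float("nan")
    if v is not None:
        delay = float(t[kc] - t[int(np.argmax(np.asarray(v)))])
    return TransientMetrics(peak=float(x[kc]), time_to_peak=float(t[kc] - t[0]),
                            delay_from_v_peak=delay, decay_half_time=decay,
                            diastolic=dia)


@dataclass
class GainCurve:
    v_test: np.ndarray
    peak_lcc: np.ndarray
    peak_ryr: np.ndarray
    gain: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            self.gain = np.where(self.peak_lcc > 0,
                                 self.peak_ryr / self.peak_lcc, np.nan)


def ecc_gain_curve(v_test, peak_lcc, peak_ryr) -> GainCurve:
    """ECC gain (peak RyR flux / peak LCC flux) vs test potential."""
    return GainCurve(np.asarray(v_test, dtype=float),
                     np.asarray(peak_lcc, dtype=float),
                     np.asarray(peak_ryr, dtype=float))


@dataclass
class FluxFractions:
    serca: float
    ncx: float
    sl_pump: float
    mito_bolus: float           # mito return during relaxation / total removal


def integrated_flux_fractions(result, window: tuple[int, int] | None = None
                              ) -> FluxFractions:
    """Removal-pathway shares from the Ca2+ transient peak to end-diastole.

    Fluxes are integrated at the output resolution (1 ms by default) with
    trapezoidal quadrature; fractions are shares of the summed removal by
    SERCa, NCX, and the sarcolemmal Ca2+ pump (they sum to 1).  The net
    mitochondrial return bolus is reported separately as a fraction of the
    same total.  ``window`` overrides the (peak, end) sample indices.
    """
    d = result.derived()
    t = result.t
    if window is None:
        kc = int(np.argmax(result.ca_i))
        window = (kc, len(t))
    sl = slice(*window)
    i_up = np.trapezoid(np.clip(d["j_up"][sl], 0.0, None), t[sl])
    i_ncx = np.trapezoid(np.clip(-d["j_ncx_cyto"][sl], 0.0, None), t[sl])
    i_pca = np.trapezoid(np.clip(-d["j_pca_cyto"][sl], 0.0, None), t[sl])
    tot = i_up + i_ncx + i_pca
    j_mito_ret = d["j_mncx_cyto"][sl] - d["j_uni_cyto"][sl]
    bolus = np.trapezoid(np.clip(j_mito_ret, 0.0, None), t[sl])
    return FluxFractions(serca=float(i_up / tot), ncx=float(i_ncx / tot),
                         sl_pump=float(i_pca / tot),
                         mito_bolus=float(bolus / tot))


def total_sr_ca(result) -> np.ndarray:
    """Total SR Ca2+ (free + buffered), SR-volume-referenced (mM)."""
    return result.state("ca_nsr") + result.state("csqn")


def fractional_release(result) -> float:
    """1 - (systolic total SR Ca2+) / (diastolic total SR Ca2+)."""
    sr = total_sr_ca(result)
    return float(1.0 - sr.min() / sr[0])


def recirculation_fraction(result) -> float:
    """SR-derived share of the Ca2+ cycled through the cytosol per beat.

    Computed as the ratio of integrated SERCa resequestration to total
    integrated cytosolic removal (SERCa + NCX + sarcolemmal pump) over the
    full cycle; the complement is the transsarcolemmal share.
    """
    d = result.derived()
    t = result.t
    i_up = np.trapezoid(np.clip(d["j_up"], 0.0, None), t)
    i_ncx = np.trapezoid(np.clip(-d["j_ncx_cyto"], 0.0, None), t)
    i_pca = np.trapezoid(np.clip(-d["j_pca_cyto"], 0.0, None), t)
    return float(i_up / (i_up + i_ncx + i_pca))


def subspace_oo_max(result, plateau_v: float = -20.0) -> float:
    """Max open-open subspace Ca2+ (mM) during the AP plateau.

    The algebraic open-open concentration is evaluated at every sample; the
    maximum is taken over the plateau (V above ``plateau_v``), the window in
    which release events actually occur.
    """
    d = result.derived()
    mask = result.v >= plateau_v
    if not mask.any():
        return float(d["ca_ss_oo"].max())
    return float(d["ca_ss_oo"][mask].max())


@dataclass
class ExponentialFit:
    amplitude: float
    tau: float
    offset: float
    residuals: np.ndarray
    converged: bool


def fit_single_exponential(x, y) -> ExponentialFit:
    """Least-squares fit of ``y = offset - amplitude * exp(-x / tau)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    c0 = y.max()
    a0 = max(c0 - y.min(), 1e-6)
    tau0 = max((x.max() - x.min()) / 3.0, 1.0)

    def model(xx, a, tau, c):
        return c - a * np.exp(-xx / tau)

    try:
        popt, _ = curve_fit(model, x, y, p0=(a0, tau0, c0), maxfev=20000)
    except RuntimeError:
        return ExponentialFit(np.nan, np.nan, np.nan, y - y, False)
    resid = y - model(x, *popt)
    return ExponentialFit(amplitude=float(popt[0]), tau=float(popt[1]),
                          offset=float(popt[2]), residuals=resid,
                          converged=True)
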