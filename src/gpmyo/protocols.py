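"""Declarative experiment protocols and their runners.

Every experiment is described by a :class:`ProtocolSpec` (serializable to a
plain dict / YAML round trip without loss) and executed by
:func:`run_protocol`, which dispatches on the variant.  The uniporter-block
experiment is a parameter overlay (``vmuni_scale``) applicable to any
protocol rather than a separate variant.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import analysis, cell
from .params import Parameters

VARIANTS = ("pacing", "voltage_step_family", "ap_clamp", "s1s2_restitution",
            "frequency_staircase", "workload_transition")

STAIRCASE_BCLS = (3000.0, 2000.0, 1500.0, 1000.0, 700.0, 500.0, 300.0)


@dataclass
class ProtocolSpec:
    variant: str
    bcl: float | None = None
    n_beats: int | None = None
    holding: float | None = None
    test_potentials: tuple[float, ...] | None = None
    step_duration: float | None = None
    pre_duration: float | None = None
    s1_bcl: float | None = None
    di_list: tuple[float, ...] | None = None
    bcls: tuple[float, ...] | None = None
    seconds_per_step: float | None = None
    high_freq: float | None = None
    phase_seconds: tuple[float, float, float] | None = None
    base_freq: float | None = None
    clamp_t: tuple[float, ...] | None = None
    clamp_v: tuple[float, ...] | None = None
    interpolation: str = "linear"
    vmuni_scale: float | None = None   # overlay; None = parameter file value
    iks_variant: str | None = None     # overlay

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown protocol variant {self.variant!r}")
        for name in ("bcl", "step_duration", "s1_bcl", "seconds_per_step"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.test_potentials is not None:
            if len(self.test_potentials) == 0:
                raise ValueError("empty test-potential list")
            for v in self.test_potentials:
                if not (-100.0 <= v <= 80.0):
                    raise ValueError(f"test potential {v} outside [-100, 80]")
        if self.di_list is not None:
            dis = list(self.di_list)
            if any(d <= 0 for d in dis) or dis != sorted(dis):
                raise ValueError("DI list must be positive and increasing")

    # -- lossless serialization -------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            if v is None:
                continue
            out[k] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ProtocolSpec":
        kw = dict(data)
        for name in ("test_potentials", "di_list", "bcls", "phase_seconds",
                     "clamp_t", "clamp_v"):
            if name in kw and kw[name] is not None:
                kw[name] = tuple(float(x) for x in kw[name])
        return cls(**kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ProtocolSpec":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def pacing(bcl: float, n_beats: int) -> ProtocolSpec:
    return ProtocolSpec(variant="pacing", bcl=bcl, n_beats=n_beats)


def voltage_step_family(holding: float = -40.0,
                        tests: Sequence[float] | None = None,
                        duration: float = 400.0,
                        pre_duration: float = 2000.0) -> ProtocolSpec:
    """Family of test steps from a holding pre-clamp (I-V / gain curves)."""
    if tests is None:
        tests = np.arange(-40.0, 61.0, 5.0)
    return ProtocolSpec(variant="voltage_step_family", holding=holding,
                        test_potentials=tuple(float(v) for v in tests),
                        step_duration=duration, pre_duration=pre_duration)


def s1s2_restitution(s1_bcl: float = 2000.0,
                     di_list: Sequence[float] | None = None) -> ProtocolSpec:
    """S1-S2 restitution from steady pacing at ``s1_bcl`` (0.5 Hz default)."""
    if di_list is None:
        di_list = (25., 50., 75., 100., 150., 200., 300., 400., 600., 900.,
                   1300., 1800., 2500., 3500., 5000.)
    return ProtocolSpec(variant="s1s2_restitution", s1_bcl=s1_bcl,
                        di_list=tuple(float(d) for d in di_list))


def frequency_staircase(bcls: Sequence[float] = STAIRCASE_BCLS,
                        seconds_per_step: float = 180.0) -> ProtocolSpec:
    """Stepwise BCL decrease, three simulated minutes per step."""
    return ProtocolSpec(variant="frequency_staircase",
                        bcls=tuple(float(b) for b in bcls),
                        seconds_per_step=seconds_per_step)


def workload_transition(high_freq: float,
                        phase_seconds=(100.0, 200.0, 200.0),
                        base_freq: float = 0.25) -> ProtocolSpec:
    """Low-high-low pacing-frequency transition (NADH/force kinetics)."""
    if high_freq <= 0:
        raise ValueError("high_freq must be positive")
    return ProtocolSpec(variant="workload_transition", high_freq=high_freq,
                        phase_seconds=tuple(float(x) for x in phase_seconds),
                        base_freq=base_freq)


def ap_clamp_from_file(path, interpolation: str = "linear") -> ProtocolSpec:
    """AP-clamp protocol from a two-column CSV ``time_ms,voltage_mV``."""
    with open(path) as fh:
        return ap_clamp_from_text(fh.read(), interpolation)


def ap_clamp_from_text(text: str, interpolation: str = "linear"
                       ) -> ProtocolSpec:
    if interpolation not in ("linear",):
        raise ValueError(f"unsupported interpolation {interpolation!r}")
    fh = io.StringIO(text)
    header = fh.readline().strip()
    if header.replace(" ", "") != "time_ms,voltage_mV":
        raise ValueError("line 1: expected header 'time_ms,voltage_mV'")
    ts, vs = [], []
    for ln, line in enumerate(fh, start=2):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"line {ln}: expected two comma-separated columns")
        try:
            tv, vv = float(parts[0]), float(parts[1])
        except ValueError as e:
            raise ValueError(f"line {ln}: {e}") from None
        if ts and tv <= ts[-1]:
            raise ValueError(f"line {ln}: time not strictly increasing")
        ts.append(tv)
        vs.append(vv)
    if len(ts) < 2:
        raise ValueError("waveform needs at least two samples")
    return ProtocolSpec(variant="ap_clamp", clamp_t=tuple(ts),
                        clamp_v=tuple(vs), interpolation=interpolation)


def synthetic_ap_waveform(kind: str = "guinea-pig", apd: float = 200.0,
                          dt: float = 1.0, total: float = 1000.0,
                          v_rest: float = -85.0):
    """Synthetic AP-clamp waveforms for tests and demonstrations.

    ``guinea-pig``: fast upstroke to ~+50 mV, slow monotone plateau decay
    (no phase-1 notch).  ``canine``: spike-notch-dome morphology with early
    repolarization.  Returns (t, v) arrays.
    """
    t = np.arange(0.0, total + 0.5 * dt, dt)
    v = np.full_like(t, v_rest)
    if kind == "guinea-pig":
        v_peak, v_plateau = 50.0, 20.0
        for i, tt in enumerate(t):
            if tt < 2.0:
                v[i] = v_rest + (v_peak - v_rest) * tt / 2.0
            elif tt < apd:
                x = (tt - 2.0) / (apd - 2.0)
                v[i] = (v_peak - (v_peak - v_plateau) * x ** 0.5
                        - (v_plateau - v_rest) * x ** 6)
        k = np.argmin(np.abs(t - apd))
        v[k:] = v_rest + (v[k] - v_rest) * np.exp(-(t[k:] - t[k]) / 15.0)
    elif kind == "canine":
        v_peak, v_notch, v_dome = 45.0, 5.0, 20.0
        for i, tt in enumerate(t):
            if tt < 2.0:
                v[i] = v_rest + (v_peak - v_rest) * tt / 2.0
            elif tt < 12.0:
                v[i] = v_peak - (v_peak - v_notch) * (tt - 2.0) / 10.0
            elif tt < 60.0:
                v[i] = v_notch + (v_dome - v_notch) * (tt - 12.0) / 48.0
            elif tt < apd:
                x = (tt - 60.0) / (apd - 60.0)
                v[i] = v_dome - (v_dome - v_rest) * x ** 3
        k = np.argmin(np.abs(t - apd))
        v[k:] = v_rest + (v[k] - v_rest) * np.exp(-(t[k:] - t[k]) / 15.0)
    else:
        raise ValueError(f"unknown waveform kind {kind!r}")
    return t, v


def waveform_to_csv(t, v) -> str:
    lines = ["time_ms,voltage_mV"]
    lines += [f"{tt:.6g},{vv:.6g}" for tt, vv in zip(t, v)]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------

def _apply_overlays(p: Parameters, spec: ProtocolSpec) -> Parameters:
    over = {}
    if spec.vmuni_scale is not None:
        if not (0.0 <= spec.vmuni_scale <= 1.0):
            raise ValueError("vmuni_scale must be in [0, 1]")
        over["vmuni_scale"] = spec.vmuni_scale
    if spec.iks_variant is not None:
        over["iks_variant"] = {"viswanathan99": 0.0,
                               "zeng95": 1.0}[spec.iks_variant]
    return p.with_values(**over) if over else p


@dataclass
class StepResponse:
    v_test: float
    t: np.ndarray
    i_cal: np.ndarray
    j_lcc: np.ndarray
    j_ryr: np.ndarray


@dataclass
class VClampFamilyResult:
    holding: float
    steps: list[StepResponse]

    def peak_table(self):
        v = np.array([s.v_test for s in self.steps])
        pk_i = np.array([s.i_cal.min() for s in self.steps])
        pk_l = np.array([s.j_lcc.max() for s in self.steps])
        pk_r = np.array([s.j_ryr.max() for s in self.steps])
        return v, pk_i, pk_l, pk_r

    def gain_curve(self) -> analysis.GainCurve:
        v, _, pk_l, pk_r = self.peak_table()
        return analysis.ecc_gain_curve(v, pk_l, pk_r)


@dataclass
class RestitutionPoint:
    di: float
    apd90: float
    ca_peak: float


@dataclass
class RestitutionResult:
    s1_bcl: float
    s1_apd90: float
    points: list[RestitutionPoint]

    def arrays(self):
        cap = [p for p in self.points if np.isfinite(p.apd90)]
        return (np.array([p.di for p in cap]),
                np.array([p.apd90 for p in cap]))

    def fit(self) -> analysis.ExponentialFit:
        di, a = self.arrays()
        return analysis.fit_single_exponential(di, a)


@dataclass
class StaircaseStep:
    bcl: float
    apd90: float
    ca_peak: float
    ca_dia: float
    peak_force: float            # mN/mm^2, last-beat peak stress
    accumulated_force: float     # mN/mm^2, time-averaged stress over a cycle
    na_i: float


@dataclass
class StaircaseResult:
    steps: list[StaircaseStep]


@dataclass
class WorkloadResult:
    t: np.ndarray                # ms, coarse grid
    nadh: np.ndarray
    ca_m: np.ndarray
    stress_avg: np.ndarray       # 4000-ms moving average of stress
    high_freq: float


def run_protocol(spec: ProtocolSpec, p: Parameters, y0=None, *,
                 rtol: float = 1e-7, atol: float = 1e-9, dt_out: float = 1.0,
                 max_beats: int = 300):
    """Execute a protocol; the return type depends on the variant."""
    p = _apply_overlays(p, spec)
    if y0 is None:
        y0 = cell.load_initial_state()
    y0 = np.asarray(y0, dtype=float)
    kw = dict(rtol=rtol, atol=atol)

    if spec.variant == "pacing":
        y, info = cell.pace_to_steady_state(spec.bcl, p, y0,
                                            max_beats=max_beats, **kw)
        res = cell.simulate_pacing(p, y, spec.bcl, spec.n_beats or 1,
                                   dt_out=dt_out, **kw)
        res.meta.update(info)
        return res

    if spec.variant == "voltage_step_family":
        segs = [cell.Segment(duration=spec.pre_duration or 2000.0,
                             mode=cell.MODE_VC, v_start=spec.holding)]
        yh = cell.integrate_segments(y0, segs, p, dt_out=10.0, **kw).y[-1]
        steps = []
        for vt in spec.test_potentials:
            segs = [cell.Segment(duration=spec.step_duration or 400.0,
                                 mode=cell.MODE_VC, v_start=float(vt))]
            r = cell.integrate_segments(yh, segs, p, dt_out=min(dt_out, 0.5),
                                        **kw)
            d = r.derived()
            steps.append(StepResponse(v_test=float(vt), t=r.t,
                                      i_cal=d["i_cal"], j_lcc=d["j_lcc_ss"],
                                      j_ryr=d["j_ryr_ss"]))
        return VClampFamilyResult(holding=float(spec.holding), steps=steps)

    if spec.variant == "s1s2_restitution":
        y, _ = cell.pace_to_steady_state(spec.s1_bcl, p, y0,
                                         max_beats=max_beats, **kw)
        # one S1 beat; save the state at the end of the AP (APD90 crossing)
        res = cell.simulate_pacing(p, y, spec.s1_bcl, 1, dt_out=dt_out, **kw)
        s1_apd = analysis.apd(res.t, res.v, 0.9, reference="onset")
        k_end = int(np.searchsorted(res.t, s1_apd))
        y_end = res.y[min(k_end, len(res.t) - 1)].copy()
        points = []
        for di in spec.di_list:
            segs = [cell.Segment(duration=float(di), mode=cell.MODE_CC)]
            segs += cell.beat_segments(1000.0, p, 1)
            r = cell.integrate_segments(y_end, segs, p, dt_out=dt_out, **kw)
            mask = r.t >= di
            a = analysis.apd(r.t[mask], r.v[mask], 0.9)
            points.append(RestitutionPoint(
                di=float(di), apd90=a, ca_peak=float(r.ca_i[mask].max())))
        return RestitutionResult(s1_bcl=float(spec.s1_bcl),
                                 s1_apd90=float(s1_apd), points=points)

    if spec.variant == "frequency_staircase":
        y = y0.copy()
        out = []
        for bcl in spec.bcls:
            n = max(int(round((spec.seconds_per_step or 180.0) * 1000.0
                              / bcl)), 1)
            for _ in range(n - 1):
                r = cell.integrate_segments(y, cell.beat_segments(bcl, p, 1),
                                            p, dt_out=bcl / 4, **kw)
                y = r.y[-1]
            res = cell.simulate_pacing(p, y, bcl, 1, dt_out=dt_out, **kw)
            y = res.y[-1]
            d = res.derived()
            out.append(StaircaseStep(
                bcl=float(bcl),
                apd90=analysis.apd(res.t, res.v, 0.9),
                ca_peak=float(res.ca_i.max()),
                ca_dia=float(res.ca_i[0]),
                peak_force=float(d["stress"].max()),
                accumulated_force=float(np.trapezoid(d["stress"], res.t)
                                        / (res.t[-1] - res.t[0])),
                na_i=float(res.state("na_i").mean()),
            ))
        return StaircaseResult(steps=out)

    if spec.variant == "workload_transition":
        base_bcl = 1000.0 / (spec.base_freq or 0.25)
        high_bcl = 1000.0 / spec.high_freq
        phases = [(base_bcl, spec.phase_seconds[0]),
                  (high_bcl, spec.phase_seconds[1]),
                  (base_bcl, spec.phase_seconds[2])]
        y = y0.copy()
        ts, nadhs, cams, stresses = [], [], [], []
        t_off = 0.0
        for bcl, seconds in phases:
            n = max(int(round(seconds * 1000.0 / bcl)), 1)
            for _ in range(n):
                res = cell.simulate_pacing(p, y, bcl, 1, dt_out=20.0, **kw)
                y = res.y[-1]
                d = res.derived()
                ts.append(t_off + res.t[1:])
                nadhs.append(res.state("nadh")[1:])
                cams.append(res.state("ca_m")[1:])
                stresses.append(d["stress"][1:])
                t_off += res.t[-1]
        t = np.concatenate(ts)
        stress = np.concatenate(stresses)
        # 4000-ms moving average on the coarse grid
        dt = t[1] - t[0]
        w = max(int(round(4000.0 / dt)), 1)
        kern = np.ones(w) / w
        stress_avg = np.convolve(stress, kern, mode="same")
        return WorkloadResult(t=t, nadh=np.concatenate(nadhs),
                              ca_m=np.concatenate(cams),
                              stress_avg=stress_avg,
                              high_freq=float(spec.high_freq))

    if spec.variant == "ap_clamp":
        ct = np.asarray(spec.clamp_t, dtype=float)
        cv = np.asarray(spec.clamp_v, dtype=float)
        segs = []
        for k in range(len(ct) - 1):
            dur = ct[k + 1] - ct[k]
            slope = (cv[k + 1] - cv[k]) / dur
            segs.append(cell.Segment(duration=dur, mode=cell.MODE_VC,
                                     v_start=float(cv[k]) if k == 0 else None,
                                     v_slope=float(slope)))
        y0c = y0.copy()
        y0c[cell.IV] = cv[0]
        res = cell.integrate_segments(y0c, segs, p, dt_out=dt_out, **kw)
        res.meta["ap_clamp"] = True
        return res

    raise AssertionError("unreachable")
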