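"""Biolayer-interferometry (BLI) sensorgram preprocessing and 1:1 kinetic fits.

A BLI experiment follows one biosensor through five phases: primary baseline,
DNA loading, secondary baseline, association (protein at concentration C binds
the immobilised DNA) and dissociation (sensor returned to buffer).  Under a
1:1 Langmuir model with pseudo-first-order association the response obeys

    association:   Y(t) = Y0 + A * (1 - exp(-k_obs * t)),  k_obs = k_a*C + k_d
    dissociation:  Y(t) = Y0 + A * exp(-k_d * t)

with the equilibrium constant K_d = k_d / k_a.  This module implements the
standard preprocessing chain (Savitzky-Golay smoothing, secondary-baseline
referencing, interstep alignment), per-segment exponential fits, the two-stage
rate-constant route (k_obs vs C regression), a global 1:1 fit sharing
(k_a, k_d) across a concentration series with per-sensor R_max, and the
qualitative no/weak/strong binding call.

Concentrations are molar throughout this module; the file formats in
:mod:`coperon.io` use nM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from enum import Enum

import lmfit
import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

logger = logging.getLogger(__name__)

__all__ = [
    "PHASES",
    "KineticParams",
    "Sensorgram",
    "SensorgramSet",
    "SegmentFit",
    "FitResult",
    "TwoStageResult",
    "BindingCall",
    "InvalidInputError",
    "NoBindingSignalError",
    "subtract_reference_baseline",
    "smooth_savgol",
    "interstep_align",
    "preprocess",
    "fit_dissociation",
    "fit_association",
    "derive_ka",
    "derive_equilibrium_kd",
    "two_stage_fit",
    "global_fit_1to1",
    "classify_binding",
]

#: Canonical phase order of the Octet protocol.
PHASES = (
    "primary_baseline",
    "loading",
    "secondary_baseline",
    "association",
    "dissociation",
)


class InvalidInputError(ValueError):
    pass


class NoBindingSignalError(RuntimeError):
    """Raised when the data carry no usable association signal."""


@dataclass(frozen=True)
class KineticParams:
    """True or assumed 1:1 rate constants.

    k_a in M^-1 s^-1, k_d in s^-1, R_max in response units; the equilibrium
    dissociation constant K_d = k_d / k_a is derived, never stored.
    """

    k_a: float
    k_d: float
    R_max: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_a) and self.k_a > 0):
            raise InvalidInputError("k_a must be finite and > 0")
        if not (np.isfinite(self.k_d) and self.k_d >= 0):
            raise InvalidInputError("k_d must be finite and >= 0")
        if not (np.isfinite(self.R_max) and self.R_max >= 0):
            raise InvalidInputError("R_max must be finite and >= 0")

    @property
    def K_d(self) -> float:
        return self.k_d / self.k_a


@dataclass
class Sensorgram:
    """One biosensor's annotated response-vs-time trace.

    ``time`` is the global clock in seconds (strictly increasing), ``phase``
    labels each sample with one of :data:`PHASES` (contiguous, in order), and
    ``analyte_conc`` is the protein concentration in M (0 for a reference
    sensor).
    """

    time: np.ndarray
    response: np.ndarray
    phase: np.ndarray
    analyte_conc: float
    sensor_id: str
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.phase = np.asarray(self.phase)
        if not (self.time.size == self.response.size == self.phase.size):
            raise InvalidInputError("time/response/phase lengths differ")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        seen = [p for i, p in enumerate(self.phase) if i == 0 or p != self.phase[i - 1]]
        order = [p for p in PHASES if p in seen]
        if seen != order:
            raise InvalidInputError(f"phases not contiguous/in schedule order: {seen}")

    def phases_present(self) -> list[str]:
        return [p for p in PHASES if np.any(self.phase == p)]

    def segment(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        """(time, response) of one phase; time on the global clock."""
        m = self.phase == phase
        if not np.any(m):
            raise InvalidInputError(
                f"sensor {self.sensor_id!r} has no {phase!r} segment"
            )
        return self.time[m], self.response[m]

    def with_response(self, response: np.ndarray) -> "Sensorgram":
        return replace(self, response=np.asarray(response, dtype=float))


@dataclass
class SensorgramSet:
    """A concentration series of sensorgrams sharing one phase schedule.

    May include zero-concentration reference sensors; ``truth`` carries the
    generating parameters when the set is synthetic.
    """

    sensorgrams: list[Sensorgram]
    truth: KineticParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        concs = [s.analyte_conc for s in self.sensorgrams if not s.is_reference]
        if any(c <= 0 for c in concs):
            raise InvalidInputError("non-reference sensors need conc > 0")

    def __iter__(self):
        return iter(self.sensorgrams)

    def __len__(self) -> int:
        return len(self.sensorgrams)

    @property
    def measurement_sensors(self) -> list[Sensorgram]:
        return [s for s in self.sensorgrams if not s.is_reference and s.analyte_conc > 0]

    @property
    def concentrations(self) -> list[float]:
        return sorted({s.analyte_conc for s in self.measurement_sensors})

    def map_responses(self, fn) -> "SensorgramSet":
        return replace(self, sensorgrams=[fn(s) for s in self.sensorgrams])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def subtract_reference_baseline(sset: SensorgramSet) -> SensorgramSet:
    """Reference every sensor against the across-sensor secondary baseline.

    The mean secondary-baseline trace over all sensors is summarised by an
    ordinary least-squares line in absolute time, and that line is subtracted
    pointwise from every sensor's full trace.  For a flat common baseline this
    reduces to subtracting its mean; a common-mode linear drift is removed
    over the whole run.
    """
    if not sset.sensorgrams:
        raise InvalidInputError("empty sensorgram set")
    segs = []
    for s in sset:
        if "secondary_baseline" not in s.phases_present():
            raise InvalidInputError(
                f"sensor {s.sensor_id!r} lacks a secondary_baseline phase"
            )
        segs.append(s.segment("secondary_baseline"))
    n = min(t.size for t, _ in segs)
    t_ref = segs[0][0][:n]
    mean_trace = np.mean([y[:n] for _, y in segs], axis=0)
    if n >= 2:
        slope, intercept = np.polyfit(t_ref, mean_trace, 1)
    else:
        slope, intercept = 0.0, float(mean_trace[0])

    def _sub(s: Sensorgram) -> Sensorgram:
        return s.with_response(s.response - (intercept + slope * s.time))

    return sset.map_responses(_sub)


def smooth_savgol(trace: Sensorgram, window: int = 11, polyorder: int = 3) -> Sensorgram:
    """Savitzky-Golay smoothing applied per phase (no leakage across steps).

    Segments shorter than ``window`` use the largest valid odd window (with
    ``polyorder`` reduced below it when necessary); a warning is logged.
    """
    if window % 2 == 0:
        raise InvalidInputError("window must be odd")
    if window <= polyorder:
        raise InvalidInputError("window must exceed polyorder")
    y = trace.response.copy()
    for phase in trace.phases_present():
        m = trace.phase == phase
        n = int(m.sum())
        w, p = window, polyorder
        if n < w:
            w = n if n % 2 == 1 else n - 1
            p = min(p, w - 1)
            logger.warning(
                "segment %s of sensor %s shorter than window; shrunk to %d",
                phase, trace.sensor_id, w,
            )
            if w < 2:
                continue
        y[m] = savgol_filter(trace.response[m], w, p)
    return trace.with_response(y)


def interstep_align(trace: Sensorgram) -> Sensorgram:
    """Remove step offsets by enforcing offset-continuity at phase boundaries.

    Each phase is shifted so its first sample equals the last sample of the
    preceding phase; afterwards the dissociation start equals the association
    end exactly.
    """
    y = trace.response.copy()
    present = trace.phases_present()
    for prev, cur in zip(present, present[1:]):
        prev_m = trace.phase == prev
        cur_m = trace.phase == cur
        if not prev_m.any() or not cur_m.any():
            raise InvalidInputError("empty phase during alignment")
        offset = y[cur_m][0] - y[prev_m][-1]
        y[np.nonzero(cur_m)[0][0]:] -= offset
    return trace.with_response(y)


def preprocess(
    sset: SensorgramSet,
    window: int = 11,
    polyorder: int = 3,
    smooth: bool = True,
    subtract_baseline: bool = True,
    align: bool = True,
) -> SensorgramSet:
    """Standard chain: smoothing, baseline referencing, interstep alignment."""
    out = sset
    if smooth:
        out = out.map_responses(lambda s: smooth_savgol(s, window, polyorder))
    if subtract_baseline:
        out = subtract_reference_baseline(out)
    if align:
        out = out.map_responses(interstep_align)
    return out


# ---------------------------------------------------------------------------
# per-segment exponential fits
# ---------------------------------------------------------------------------


@dataclass
class SegmentFit:
    """Result of a single-exponential fit to one phase segment."""

    Y0: float
    A: float
    rate: float
    residual_sd: float
    converged: bool
    rate_se: float | None = None

    def __post_init__(self) -> None:
        if self.converged and self.rate < 0:
            raise InvalidInputError("converged fit must have rate >= 0")


def _fit_exponential(t: np.ndarray, y: np.ndarray, rising: bool) -> SegmentFit:
    t = t - t[0]
    span = float(np.ptp(y))
    if span < 1e-12 or t.size < 4:
        return SegmentFit(Y0=float(np.mean(y)), A=0.0, rate=0.0,
                          residual_sd=float(np.std(y)), converged=True, rate_se=0.0)

    if rising:
        def model(t, y0, a, k):
            return y0 + a * (1.0 - np.exp(-k * t))
        a0, y00 = y[-1] - y[0], y[0]
    else:
        def model(t, y0, a, k):
            return y0 + a * np.exp(-k * t)
        a0, y00 = y[0] - y[-1], y[-1]

    # crude rate init from the half-amplitude crossing time
    target = y[0] + 0.5 * (y[-1] - y[0])
    cross = np.nonzero((y - target) * (y[0] - target) <= 0)[0]
    t_half = t[cross[0]] if cross.size and t[cross[0]] > 0 else t[-1] / 3.0
    k0 = math.log(2.0) / max(t_half, t[1] if t.size > 1 else 1e-3)

    m = lmfit.Model(model)
    params = m.make_params(y0=y00, a=a0, k=max(k0, 1e-6))
    params["k"].set(min=0.0)
    try:
        res = m.fit(y, params, t=t)
    except Exception:
        return SegmentFit(Y0=float(y00), A=float(a0), rate=float("nan"),
                          residual_sd=float("nan"), converged=False)
    ok = bool(res.success) and np.isfinite(res.params["k"].value)
    if not ok:
        return SegmentFit(Y0=float(y00), A=float(a0), rate=float("nan"),
                          residual_sd=float("nan"), converged=False)
    return SegmentFit(
        Y0=float(res.params["y0"].value),
        A=float(res.params["a"].value),
        rate=float(res.params["k"].value),
        residual_sd=float(np.std(res.residual)),
        converged=True,
        rate_se=(float(res.params["k"].stderr) if res.params["k"].stderr else None),
    )


def fit_association(trace: Sensorgram) -> SegmentFit:
    """Fit Y = Y0 + A(1 - e^(-k_obs t)) to the association segment."""
    t, y = trace.segment("association")
    return _fit_exponential(t, y, rising=True)


def fit_dissociation(trace: Sensorgram) -> SegmentFit:
    """Fit Y = Y0 + A e^(-k_d t) to the dissociation segment."""
    t, y = trace.segment("dissociation")
    return _fit_exponential(t, y, rising=False)


# ---------------------------------------------------------------------------
# rate-constant algebra
# ---------------------------------------------------------------------------


def derive_ka(k_obs: float, k_d: float, conc: float) -> float:
    """k_a = (k_obs - k_d) / C, the pseudo-first-order identity."""
    if conc <= 0 or not np.isfinite(conc):
        raise InvalidInputError("concentration must be > 0")
    if k_obs < k_d:
        raise NoBindingSignalError(
            f"k_obs ({k_obs:g}) below k_d ({k_d:g}): no association signal"
        )
    return (k_obs - k_d) / conc


def derive_equilibrium_kd(k_a: float, k_d: float) -> float:
    """K_d = k_d / k_a."""
    if k_a <= 0 or not np.isfinite(k_a):
        raise InvalidInputError("k_a must be > 0")
    return k_d / k_a


@dataclass
class TwoStageResult:
    """Two-stage route: per-trace k_obs, then the k_obs-vs-C line."""

    k_obs: dict[float, float]
    k_a: float
    k_d: float
    K_d: float
    intercept: float


def two_stage_fit(sset: SensorgramSet) -> TwoStageResult:
    """Per-trace k_obs regression route to (k_a, k_d, K_d).

    k_obs is fitted per measurement sensor, k_d from the highest-concentration
    dissociation, k_a from the slope of the k_obs-vs-C line.
    """
    sensors = sset.measurement_sensors
    if len({s.analyte_conc for s in sensors}) < 2:
        raise InvalidInputError("need >= 2 distinct positive concentrations")
    kobs: dict[float, list[float]] = {}
    for s in sensors:
        f = fit_association(s)
        if f.converged and f.rate > 0:
            kobs.setdefault(s.analyte_conc, []).append(f.rate)
    if len(kobs) < 2:
        raise NoBindingSignalError("fewer than 2 concentrations with usable k_obs")
    concs = sorted(kobs)
    mean_kobs = {c: float(np.mean(kobs[c])) for c in concs}
    reg = linregress(concs, [mean_kobs[c] for c in concs])
    if reg.slope <= 0:
        raise NoBindingSignalError("k_obs does not increase with concentration")
    top = max(sensors, key=lambda s: s.analyte_conc)
    kd = fit_dissociation(top).rate
    ka = float(reg.slope)
    return TwoStageResult(
        k_obs=mean_kobs,
        k_a=ka,
        k_d=float(kd),
        K_d=derive_equilibrium_kd(ka, kd),
        intercept=float(reg.intercept),
    )


# ---------------------------------------------------------------------------
# global 1:1 fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Global 1:1 fit across a concentration series.

    Rates are shared across sensors, R_max is per sensor; K_d = k_d/k_a holds
    exactly.  ``r_squared`` pools every fitted association and dissociation
    point.
    """

    k_a: float
    k_d: float
    K_d: float
    k_a_se: float | None
    k_d_se: float | None
    K_d_se: float | None
    r_max: dict[str, float]
    k_obs: dict[float, float]
    r_squared: float
    n_sensors: int
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not math.isclose(
            self.K_d, self.k_d / self.k_a, rel_tol=1e-12, abs_tol=0.0
        ):
            raise InvalidInputError("K_d must equal k_d/k_a")


def _analytic_1to1(t_a, t_d, conc, ka, kd, rmax, y0, t_assoc_end):
    """Association + dissociation closed form for constant analyte conc."""
    kobs = ka * conc + kd
    req = rmax * conc / (conc + kd / ka)
    ya = y0 + req * (1.0 - np.exp(-kobs * t_a))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc_end))
    yd = y0 + r_end * np.exp(-kd * t_d)
    return ya, yd


def global_fit_1to1(sset: SensorgramSet) -> FitResult:
    """Globally fit shared (k_a, k_d) with per-sensor R_max and offset.

    Association and dissociation segments of every measurement sensor are fit
    jointly to the analytic 1:1 model; initial values are seeded from the
    two-stage route.  Raises on fewer than 2 distinct concentrations; a
    non-converged optimisation returns ``converged=False`` with diagnostics.
    """
    sensors = sset.measurement_sensors
    concs = sorted({s.analyte_conc for s in sensors})
    if len(concs) < 2:
        raise InvalidInputError(
            "global fit needs >= 2 distinct positive concentrations"
        )

    data = []
    for s in sensors:
        ta, ya = s.segment("association")
        td, yd = s.segment("dissociation")
        t_assoc_end = td[0] - ta[0]
        data.append((s, ta - ta[0], ya, td - td[0], yd, t_assoc_end))

    try:
        init = two_stage_fit(sset)
        ka0, kd0 = init.k_a, max(init.k_d, 1e-6)
    except (InvalidInputError, NoBindingSignalError):
        ka0, kd0 = 1e5, 1e-2
    kd0 = min(max(kd0, 1e-7), 1.0)

    params = lmfit.Parameters()
    params.add("ka", value=ka0, min=1.0)
    params.add("kd", value=kd0, min=0.0)
    for i, (s, _, ya, _, _, _) in enumerate(data):
        amp = max(float(ya[-1] - ya[0]), 1e-6)
        kd_over_ka = kd0 / ka0
        rmax0 = amp * (s.analyte_conc + kd_over_ka) / s.analyte_conc
        params.add(f"rmax_{i}", value=rmax0, min=0.0)
        params.add(f"y0_{i}", value=float(ya[0]))

    def residual(p):
        ka, kd = p["ka"].value, p["kd"].value
        out = []
        for i, (s, ta, ya, td, yd, t_end) in enumerate(data):
            ym_a, ym_d = _analytic_1to1(
                ta, td, s.analyte_conc, ka, kd,
                p[f"rmax_{i}"].value, p[f"y0_{i}"].value, t_end,
            )
            out.append(ya - ym_a)
            out.append(yd - ym_d)
        return np.concatenate(out)

    res = lmfit.minimize(residual, params, method="leastsq",
                         xtol=1e-12, ftol=1e-12, max_nfev=20000)

    ka = float(res.params["ka"].value)
    kd = float(res.params["kd"].value)
    ka_se = float(res.params["ka"].stderr) if res.params["ka"].stderr else None
    kd_se = float(res.params["kd"].stderr) if res.params["kd"].stderr else None
    K_d = kd / ka
    K_d_se = None
    if ka_se is not None and kd_se is not None and kd > 0:
        K_d_se = K_d * math.hypot(kd_se / kd, ka_se / ka)

    resid = residual(res.params)
    pooled = np.concatenate([np.r_[ya, yd] for _, _, ya, _, yd, _ in data])
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((pooled - pooled.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    return FitResult(
        k_a=ka,
        k_d=kd,
        K_d=K_d,
        k_a_se=ka_se,
        k_d_se=kd_se,
        K_d_se=K_d_se,
        r_max={s.sensor_id: float(res.params[f"rmax_{i}"].value)
               for i, (s, *_rest) in enumerate(data)},
        k_obs={c: ka * c + kd for c in concs},
        r_squared=float(max(min(r2, 1.0), 0.0) if np.isfinite(r2) else 0.0),
        n_sensors=len(data),
        converged=bool(res.success),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# binding call
# ---------------------------------------------------------------------------


class BindingCall(Enum):
    """Qualitative affinity category with its table rendering."""

    NONE = "-"
    WEAK = "+"
    STRONG = "++"

    @property
    def symbol(self) -> str:
        return self.value


#: Affinity below this is called strong binding (250 nM).
STRONG_KD_THRESHOLD = 250e-9
#: Default top assay concentration (3 uM); K_d beyond it is no binding.
DEFAULT_MAX_ASSAY_CONC = 3e-6


def classify_binding(
    fit: FitResult, max_assay_conc: float = DEFAULT_MAX_ASSAY_CONC
) -> BindingCall:
    """Map a fit to the no/weak/strong (-, +, ++) binding call.

    Strong: converged with K_d < 250 nM.  Weak: converged with K_d up to the
    top assay concentration.  Anything else (unconverged, or K_d beyond the
    assay range) is no binding.
    """
    if not fit.converged or not np.isfinite(fit.K_d):
        return BindingCall.NONE
    if fit.K_d < STRONG_KD_THRESHOLD:
        return BindingCall.STRONG
    if fit.K_d <= max_assay_conc:
        return BindingCall.WEAK
    return BindingCall.NONE
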