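"""Synthetic observation-study generator and rate estimation.

The underlying field study timed ~220 patients through an outpatient
pharmacy over two 4-hour shifts, recording arrivals in standard 30-minute
windows and per-stage service times on observation forms.  No such log is
deposited anywhere, so this module generates statistically equivalent
logs (Poisson arrivals at the shift rates, exponential services) by
running the discrete-event engine, and provides the estimators and
goodness-of-fit tests the analysis pipeline needs:

* :func:`estimate_rates` — per-window arrival rate lambda and service
  rate mu (patients per window per server's worth of service time);
* :func:`fit_tests` — chi-square test of window counts against a Poisson
  law and a Kolmogorov-Smirnov test of service times against an
  exponential law, both with the unknown mean estimated from the data.
  Default p-values come from a parametric bootstrap: with 8-16 windows
  the asymptotic chi-square has almost no cells left after pooling, and
  the classical KS p-value is badly conservative once the mean is
  estimated, so neither attains the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .analytics import ShiftParameters
from .des import NetworkConfig, ServiceDistribution, StationConfig, simulate
from .errors import ConfigError, InsufficientDataError, InvalidParameterError
from .pharmacy import (
    BASELINE_STAFFING,
    EVENING_SHIFT,
    MORNING_SHIFT,
    calibrate_baseline,
)

__all__ = [
    "ShiftPlan",
    "ObservationDesign",
    "PatientLog",
    "RateEstimate",
    "GofResult",
    "ShiftFitReport",
    "generate_log",
    "estimate_rates",
    "fit_tests",
    "poisson_chi_square",
    "exponential_ks",
    "pharmacy_study_design",
    "consolidated_study_design",
]

#: Observation-form column stems for the pharmacy stations.
_SHORT = {"receiving": "receive", "filling": "fill", "delivery": "deliver"}


@dataclass(frozen=True)
class ShiftPlan:
    """One shift of the observation design.

    ``staffing`` and ``service_means`` share keys and define the stations
    (in insertion order) of the simulated service network; a single
    consolidated station is perfectly valid and is what the shift-level
    rate estimates assume.
    """

    label: str
    start_minutes: float
    end_minutes: float
    lam_per_window: float
    staffing: dict[str, int]
    service_means: dict[str, float]

    def __post_init__(self) -> None:
        if self.end_minutes <= self.start_minutes:
            raise ConfigError("shift must have positive length")
        if self.lam_per_window < 0:
            raise ConfigError("arrival rate must be >= 0")
        if set(self.staffing) != set(self.service_means) or not self.staffing:
            raise ConfigError("staffing and service_means must share >= 1 station")

    @property
    def minutes(self) -> float:
        return self.end_minutes - self.start_minutes


@dataclass(frozen=True)
class ObservationDesign:
    shifts: tuple[ShiftPlan, ...]
    window_minutes: float = 30.0
    target_n: int = 220
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shifts", tuple(self.shifts))
        if not self.shifts:
            raise ConfigError("need at least one shift")
        if self.target_n < 1:
            raise ConfigError("target_n must be > 0")
        for plan in self.shifts:
            if abs(plan.minutes / self.window_minutes % 1.0) > 1e-9:
                raise ConfigError(
                    f"window must divide shift length (shift {plan.label!r})"
                )


@dataclass
class PatientLog:
    """Per-patient timestamp records, in minutes from each shift's start.

    ``shift_minutes`` maps shift label to shift length so that empty
    trailing windows still count in rate estimation.
    """

    frame: pd.DataFrame
    shift_minutes: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def service_columns(self) -> list[tuple[str, str]]:
        """(start, end) column pairs of the service phases, in order."""
        pairs = []
        for col in self.frame.columns:
            if col.endswith("_start"):
                end = col[: -len("_start")] + "_end"
                if end in self.frame.columns:
                    pairs.append((col, end))
        return pairs

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.3f")

    @classmethod
    def from_csv(cls, path, shift_minutes: dict[str, float] | None = None) -> "PatientLog":
        frame = pd.read_csv(path)
        if shift_minutes is None:
            shift_minutes = {lbl: 240.0 for lbl in frame["shift"].unique()}
        return cls(frame=frame, shift_minutes=shift_minutes)


def pharmacy_study_design(seed: int = 0, target_n: int = 220) -> ObservationDesign:
    """The full three-station pharmacy emulation: morning (8:00-12:00) and
    evening (14:00-18:00) shifts at the study's arrival rates, station
    service means calibrated from the observed per-station waits."""
    plans = []
    for shift, (start, end) in ((MORNING_SHIFT, (0.0, 240.0)), (EVENING_SHIFT, (240.0, 480.0))):
        cfg = calibrate_baseline(shift)
        plans.append(
            ShiftPlan(
                label=shift.label,
                start_minutes=start,
                end_minutes=end,
                lam_per_window=shift.lam,
                staffing=dict(BASELINE_STAFFING[shift.label]),
                service_means={st.name: st.service.mean_minutes for st in cfg.stations},
            )
        )
    return ObservationDesign(shifts=tuple(plans), target_n=target_n, seed=seed)


def consolidated_study_design(
    shifts: tuple[ShiftParameters, ...] = (MORNING_SHIFT, EVENING_SHIFT),
    seed: int = 0,
    target_n: int = 220,
    windows_per_shift: int | None = None,
) -> ObservationDesign:
    """Single consolidated service stage per shift at the shift-level
    rates (service mean 30/mu, s servers).  This is the design under
    which the shift-level estimators are exactly specified — per-patient
    total service time is exponential with rate mu — and is therefore the
    design used for estimator-recovery and test-calibration studies."""
    plans = []
    t0 = 0.0
    for sp in shifts:
        minutes = sp.shift_minutes if windows_per_shift is None else 30.0 * windows_per_shift
        plans.append(
            ShiftPlan(
                label=sp.label,
                start_minutes=t0,
                end_minutes=t0 + minutes,
                lam_per_window=sp.lam,
                staffing={"service": sp.s},
                service_means={"service": 30.0 / sp.mu},
            )
        )
        t0 += minutes
    return ObservationDesign(shifts=tuple(plans), target_n=target_n, seed=seed)


def _shift_seed(design: ObservationDesign, idx: int) -> int:
    ss = np.random.SeedSequence(design.seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_log(design: ObservationDesign) -> PatientLog:
    """Simulate the service network per shift and emit the observation-form
    patient log.  Deterministic given ``design.seed``.  Patients still in
    the pharmacy at shift close keep NaN timestamps for unreached stages.
    A ``sampled`` column marks every k-th patient, emulating the study's
    systematic random sample of ~``target_n`` patients."""
    frames: list[pd.DataFrame] = []
    shift_minutes: dict[str, float] = {}
    for idx, plan in enumerate(design.shifts):
        shift_minutes[plan.label] = plan.minutes
        if plan.lam_per_window == 0:
            continue
        stations = tuple(
            StationConfig(
                name=st,
                servers=int(plan.staffing[st]),
                service=ServiceDistribution("exponential", plan.service_means[st]),
            )
            for st in plan.staffing
        )
        cfg = NetworkConfig(
            stations=stations,
            arrival_rate_per_min=plan.lam_per_window / design.window_minutes,
            horizon_minutes=plan.minutes,
            seed=_shift_seed(design, idx),
        )
        res = simulate(cfg)
        rec = res.records
        out = pd.DataFrame({"shift": plan.label, "arrival": rec["arrival"]})
        for st in plan.staffing:
            stem = _SHORT.get(st, st)
            out[f"{stem}_start"] = rec[f"{st}_start"]
            out[f"{stem}_end"] = rec[f"{st}_end"]
        if "fill_end" in out.columns:
            # moment of referring to the cashier (folded into filling)
            out.insert(out.columns.get_loc("fill_end") + 1, "cashier", out["fill_end"])
        frames.append(out)

    if not frames:
        frame = pd.DataFrame(columns=["id", "shift", "sampled", "arrival"])
        return PatientLog(frame=frame, shift_minutes=shift_minutes)

    frame = pd.concat(frames, ignore_index=True)
    frame.insert(0, "id", np.arange(len(frame)))
    k = max(1, len(frame) // design.target_n)
    frame.insert(2, "sampled", frame["id"] % k == 0)
    return PatientLog(frame=frame, shift_minutes=shift_minutes)


@dataclass(frozen=True)
class RateEstimate:
    """Per-shift arrival and service rate estimates (per window).

    ``n_service`` counts patients whose service completed (events); the
    service-rate estimate also uses the partial service exposure of
    patients still in the pharmacy at shift close.
    """

    lam_hat: float
    lam_se: float
    mu_hat: float
    mu_se: float
    n_windows: int
    n_service: int


def _window_counts(
    arrivals: np.ndarray, minutes: float, window: float, origin: float
) -> np.ndarray:
    n_windows = int(round(minutes / window))
    if n_windows < 2:
        raise InsufficientDataError("need >= 2 windows")
    idx = np.floor((arrivals - origin) / window).astype(int)
    if len(idx) and (idx.min() < 0 or idx.max() >= n_windows):
        raise InvalidParameterError("arrival outside the shift's windows")
    return np.bincount(idx, minlength=n_windows)


def _service_exposure(
    sub: pd.DataFrame,
    pairs: list[tuple[str, str]],
    shift_minutes: float,
) -> tuple[float, int, np.ndarray]:
    """Total observed service exposure, completion count, and the
    completed patients' total service times.

    A patient still mid-service when the shift closes contributes the
    elapsed part of the interrupted phase plus any finished phases, as a
    censored observation.  Ignoring such patients would drop exactly the
    longest service times and bias the rate upward.
    """
    exposure = 0.0
    completed: list[float] = []
    starts = sub[[p[0] for p in pairs]].to_numpy(dtype=float)
    ends = sub[[p[1] for p in pairs]].to_numpy(dtype=float)
    durations = ends - starts
    for row_s, row_d in zip(starts, durations):
        if np.all(np.isfinite(row_d)):
            total = float(np.sum(row_d))
            exposure += total
            completed.append(total)
        else:
            fin = np.isfinite(row_d)
            exposure += float(np.sum(row_d[fin]))
            open_phase = np.isfinite(row_s) & ~fin
            if np.any(open_phase):
                exposure += float(shift_minutes - row_s[open_phase][0])
    return exposure, len(completed), np.asarray(completed)


def estimate_rates(
    log: PatientLog, window_minutes: float = 30.0, *, origin: float = 0.0
) -> dict[str, RateEstimate]:
    """Estimate lambda (mean arrivals per window, all arrivals) and mu
    (patients served per window per server's worth of service time,
    queue waits excluded) for each shift in the log.

    mu is the censored-exponential maximum-likelihood rate
    (completions over total service exposure, converted to per-window
    units) with the standard (e-1)/e small-sample correction when at
    least two completions are available; with a single completion it
    reduces to window over that patient's total service time.
    """
    if len(log) == 0:
        raise InsufficientDataError("empty patient log")
    out: dict[str, RateEstimate] = {}
    pairs = log.service_columns()
    for label, sub in log.frame.groupby("shift", sort=False):
        counts = _window_counts(
            sub["arrival"].to_numpy(), log.shift_minutes[label], window_minutes, origin
        )
        lam_hat = float(counts.mean())
        lam_se = float(np.sqrt(lam_hat / len(counts)))

        svc = sub[sub["sampled"]] if "sampled" in sub.columns else sub
        exposure, events, _ = _service_exposure(svc, pairs, log.shift_minutes[label])
        if events < 1 or exposure <= 0:
            raise InsufficientDataError(
                f"shift {label!r}: need >= 1 completed service record"
            )
        numer = events - 1 if events >= 2 else events
        mu_hat = window_minutes * numer / exposure
        # exponential-rate MLE has SE ~= mu/sqrt(events)
        mu_se = mu_hat / np.sqrt(events) if events >= 2 else float("nan")
        out[label] = RateEstimate(
            lam_hat=lam_hat,
            lam_se=lam_se,
            mu_hat=mu_hat,
            mu_se=float(mu_se),
            n_windows=len(counts),
            n_service=events,
        )
    return out


@dataclass(frozen=True)
class GofResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n: int = 0


@dataclass(frozen=True)
class ShiftFitReport:
    arrival: GofResult
    service: GofResult


def _pool_bins(lam_hat: float, n: int, counts: np.ndarray) -> np.ndarray:
    """Inclusive upper bounds of pooled count-value cells; each cell's
    expected count under Poisson(lam_hat) is >= 5 where achievable, with
    the open tail merged so the cells partition {0, 1, 2, ...}."""
    hi = int(max(counts.max(initial=0), stats.poisson.ppf(1 - 1e-9, lam_hat))) + 1
    pmf = stats.poisson.pmf(np.arange(hi + 1), lam_hat)
    uppers: list[int] = []
    acc = 0.0
    for k in range(hi + 1):
        acc += pmf[k]
        if n * acc >= 5.0:
            uppers.append(k)
            acc = 0.0
    if not uppers:
        uppers = [int(np.floor(lam_hat))]
    # tail probability beyond the last closed cell
    tail = 1.0 - stats.poisson.cdf(uppers[-1], lam_hat)
    if n * tail < 5.0 and len(uppers) > 1:
        uppers.pop()
    return np.asarray(uppers, dtype=int)


def _cell_probs(uppers: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Cell probabilities under Poisson(lam); lam may be a vector.  Cells
    are (-inf, u0], (u0, u1], ..., (u_last, inf)."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    cdf = stats.poisson.cdf(uppers[None, :], lam[:, None])
    probs = np.concatenate(
        [cdf[:, :1], np.diff(cdf, axis=1), 1.0 - cdf[:, -1:]], axis=1
    )
    return probs


def _cell_counts(uppers: np.ndarray, counts: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(uppers, counts, side="left")
    k = len(uppers) + 1
    if counts.ndim == 1:
        return np.bincount(idx, minlength=k)
    obs = np.zeros((counts.shape[0], k))
    for j in range(k):
        obs[:, j] = np.sum(idx == j, axis=1)
    return obs


def poisson_chi_square(
    counts: np.ndarray,
    *,
    method: str = "bootstrap",
    n_boot: int = 300,
    rng: np.random.Generator | None = None,
) -> GofResult:
    """Chi-square goodness of fit of window counts against Poisson with
    the rate estimated from the same counts.

    ``method="asymptotic"`` uses the chi-square reference with
    df = cells - 2 (one parameter estimated); it requires >= 3 cells
    after pooling.  ``method="bootstrap"`` (default) simulates the null
    distribution of the statistic, re-estimating the rate for every
    bootstrap sample, and is calibrated at any window count.
    """
    counts = np.asarray(counts, dtype=int)
    n = len(counts)
    if n < 5:
        raise InsufficientDataError("arrival test needs >= 5 windows")
    lam_hat = float(counts.mean())
    if lam_hat <= 0:
        raise InsufficientDataError("arrival test needs a positive mean count")
    uppers = _pool_bins(lam_hat, n, counts)
    obs = _cell_counts(uppers, counts)
    exp = n * _cell_probs(uppers, lam_hat)[0]
    T = float(np.sum((obs - exp) ** 2 / exp))
    k = len(uppers) + 1
    if method == "asymptotic":
        df = k - 2
        if df < 1:
            raise InsufficientDataError(
                "too few cells for the asymptotic chi-square; use bootstrap"
            )
        return GofResult(T, float(stats.chi2.sf(T, df)), "asymptotic", df=df, n=n)
    if method != "bootstrap":
        raise InvalidParameterError(f"unknown method {method!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    sim = rng.poisson(lam_hat, size=(int(n_boot), n))
    lam_b = sim.mean(axis=1)
    ok = lam_b > 0
    probs = np.empty((int(n_boot), k))
    probs[ok] = _cell_probs(uppers, lam_b[ok])
    probs[~ok] = np.nan
    obs_b = _cell_counts(uppers, sim)
    with np.errstate(invalid="ignore", divide="ignore"):
        T_b = np.nansum((obs_b - n * probs) ** 2 / (n * probs), axis=1)
    T_b = T_b[ok]
    p = (1.0 + np.sum(T_b >= T - 1e-12)) / (len(T_b) + 1.0)
    return GofResult(T, float(p), "bootstrap", df=k - 2, n=n)


def _ks_exponential_stat(x: np.ndarray) -> np.ndarray:
    """Row-wise KS distance of samples (axis -1) to Expon(mean of the row)."""
    x = np.sort(np.atleast_2d(x), axis=1)
    n = x.shape[1]
    f = 1.0 - np.exp(-x / x.mean(axis=1, keepdims=True))
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - f, axis=1)
    d_minus = np.max(f - (i - 1) / n, axis=1)
    return np.maximum(d_plus, d_minus)


def exponential_ks(
    times: np.ndarray,
    *,
    method: str = "bootstrap",
    n_boot: int = 300,
    rng: np.random.Generator | None = None,
) -> GofResult:
    """KS test of service times against an exponential law with the mean
    estimated from the sample.  The default parametric bootstrap
    re-estimates the mean per bootstrap sample; the asymptotic option
    uses the classical KS p-value, which is conservative here."""
    times = np.asarray(times, dtype=float)
    times = times[np.isfinite(times)]
    n = len(times)
    if n < 5 or np.any(times < 0) or times.mean() <= 0:
        raise InsufficientDataError("service test needs >= 5 non-negative times")
    D = float(_ks_exponential_stat(times)[0])
    if method == "asymptotic":
        p = float(stats.kstest(times, "expon", args=(0, times.mean())).pvalue)
        return GofResult(D, p, "asymptotic", n=n)
    if method != "bootstrap":
        raise InvalidParameterError(f"unknown method {method!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    sim = rng.exponential(times.mean(), size=(int(n_boot), n))
    D_b = _ks_exponential_stat(sim)
    p = (1.0 + np.sum(D_b >= D - 1e-12)) / (len(D_b) + 1.0)
    return GofResult(D, float(p), "bootstrap", n=n)


def fit_tests(
    log: PatientLog,
    window_minutes: float = 30.0,
    *,
    origin: float = 0.0,
    method: str = "bootstrap",
    n_boot: int = 300,
    seed: int = 0,
) -> dict[str, ShiftFitReport]:
    """Per-shift goodness-of-fit report: Poisson window counts and
    exponential per-patient total service times."""
    if len(log) == 0:
        raise InsufficientDataError("empty patient log")
    rng = np.random.default_rng(seed)
    pairs = log.service_columns()
    out: dict[str, ShiftFitReport] = {}
    for label, sub in log.frame.groupby("shift", sort=False):
        counts = _window_counts(
            sub["arrival"].to_numpy(), log.shift_minutes[label], window_minutes, origin
        )
        arrival = poisson_chi_square(counts, method=method, n_boot=n_boot, rng=rng)
        svc = sub[sub["sampled"]] if "sampled" in sub.columns else sub
        total = np.zeros(len(svc))
        for start, end in pairs:
            total = total + (svc[end] - svc[start]).to_numpy()
        service = exponential_ks(total, method=method, n_boot=n_boot, rng=rng)
        out[label] = ShiftFitReport(arrival=arrival, service=service)
    return out
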