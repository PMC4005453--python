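"""Closed-form M/M/s queueing indicators for a pharmacy work shift.

Two analytic routes are provided:

* :func:`indicators_from_observed_L` — the field-study route.  The mean
  number of patients in the pharmacy, L, is an *observed* quantity; the
  remaining indicators are derived from it with Little's-law arithmetic
  (Lq = L - r, Wq = 30*Lq/lambda, W = Wq + 30/mu) and reduced to printed
  numbers with a :class:`~pharmqueue.reporting.ReportingPolicy`.
* :func:`erlang_c_indicators` — textbook M/M/s steady state (Erlang-C),
  used as the independent oracle for the discrete-event simulator.

Rates are expressed per 30-minute interval (the study's standard
observation window); waiting and sojourn times are returned in minutes.
The factor 30 that converts interval-units to minutes is always explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import (
    InconsistentObservationError,
    InstabilityError,
    InvalidParameterError,
)
from .reporting import STUDY_POLICY, ReportingPolicy

__all__ = [
    "ShiftParameters",
    "QueueIndicators",
    "SampleSizeSpec",
    "mean_in_service",
    "indicators_from_observed_L",
    "erlang_c_wait_probability",
    "erlang_c_wq",
    "erlang_c_indicators",
    "sample_size",
    "mm1_service_rate_from_wait",
]


@dataclass(frozen=True)
class ShiftParameters:
    """Arrival/service rates and staffing for one work shift.

    lam
        Arrival rate, patients per 30-minute interval.
    mu
        Service rate, patients per 30-minute interval *per server*.
    s
        Number of servers (total personnel for system-level formulas,
        station staff for per-station use).
    shift_minutes
        Shift duration in minutes (the studied pharmacy ran 4-hour shifts).
    """

    label: str
    lam: float
    mu: float
    s: int
    shift_minutes: float = 240.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise InvalidParameterError("arrival rate lam must be > 0")
        if self.mu <= 0:
            raise InvalidParameterError("service rate mu must be > 0")
        if int(self.s) < 1 or self.s != int(self.s):
            raise InvalidParameterError("server count s must be a positive integer")
        if self.shift_minutes <= 0:
            raise InvalidParameterError("shift_minutes must be > 0")

    @property
    def offered_load(self) -> float:
        """a = lam/mu, the mean number of busy servers (dimensionless)."""
        return self.lam / self.mu

    @property
    def utilization(self) -> float:
        """rho = lam/(s*mu)."""
        return self.lam / (self.s * self.mu)

    @property
    def is_stable(self) -> bool:
        return self.lam < self.s * self.mu


@dataclass(frozen=True)
class QueueIndicators:
    """The seven shift-level performance indicators.

    r    mean number of patients in service (persons)
    L    mean number of patients in the pharmacy (persons)
    Lq   mean queue length (persons)
    Wq   mean waiting time in queues (minutes)
    W    mean total time in the pharmacy (minutes)
    Wa   mean time of not receiving immediate service, 30/(s*mu - lam),
         reported in the study's dimensionless printed form
    rho  system utilization, lam/(s*mu)
    p_wait  Erlang-C probability that an arrival must queue (only set by
         the steady-state route)
    """

    r: float
    L: float
    Lq: float
    Wq: float
    W: float
    Wa: float
    rho: float
    p_wait: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "r": self.r,
            "L": self.L,
            "Lq": self.Lq,
            "Wq": self.Wq,
            "W": self.W,
            "Wa": self.Wa,
            "rho": self.rho,
        }
        if self.p_wait is not None:
            d["p_wait"] = self.p_wait
        return d


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the normal-approximation sample-size formula n=((z*delta)/d)^2.

    z      normal quantile (1.96 for a two-sided 5% level)
    delta  standard deviation of the waiting time, minutes
    d      acceptable margin of error, minutes
    """

    z: float = 1.96
    delta: float = 5.12
    d: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise InvalidParameterError("delta must be > 0")
        if self.d <= 0:
            raise InvalidParameterError("margin d must be > 0")


def mean_in_service(
    params: ShiftParameters, policy: ReportingPolicy | None = STUDY_POLICY
) -> float:
    """Mean number of patients receiving service, r = lam/mu."""
    r = params.lam / params.mu
    return r if policy is None else policy.apply(r)


def indicators_from_observed_L(
    params: ShiftParameters,
    L_observed: float,
    policy: ReportingPolicy | None = STUDY_POLICY,
    *,
    wq_decimals: int | None = None,
) -> QueueIndicators:
    """Derive the shift indicators from the *observed* mean number in system.

    With ``policy=None`` the exact (unformatted) chain is returned, which
    satisfies L = Lq + r and W = Wq + 30/mu identically.  With a policy,
    the study's printed computation chain is followed: r is formatted
    first, Lq = L - r uses the formatted r, Wq is formatted at
    ``wq_decimals`` (the tables print the two shifts at different
    precisions), and W adds 30/mu to the *formatted* Wq before its own
    formatting.

    Raises
    ------
    InstabilityError
        if lam >= s*mu (Wa and rho undefined).
    InconsistentObservationError
        if ``L_observed`` is below the mean number in service.
    """
    lam, mu, s = params.lam, params.mu, params.s
    if lam >= s * mu:
        raise InstabilityError(
            f"lam={lam} >= s*mu={s * mu}: Wa and rho are undefined"
        )
    r_exact = lam / mu
    if policy is None:
        if L_observed < r_exact:
            raise InconsistentObservationError(
                f"observed L={L_observed} below mean in service r={r_exact:.4f}"
            )
        Lq = L_observed - r_exact
        Wq = 30.0 * Lq / lam
        return QueueIndicators(
            r=r_exact,
            L=L_observed,
            Lq=Lq,
            Wq=Wq,
            W=Wq + 30.0 / mu,
            Wa=30.0 / (s * mu - lam),
            rho=lam / (s * mu),
        )

    r = policy.apply(r_exact)
    if L_observed < r:
        raise InconsistentObservationError(
            f"observed L={L_observed} below mean in service r={r}"
        )
    Lq = L_observed - r
    Wq = policy.apply(30.0 * Lq / lam, wq_decimals)
    W = policy.apply(Wq + 30.0 / mu)
    return QueueIndicators(
        r=r,
        L=policy.apply(L_observed),
        Lq=policy.apply(Lq),
        Wq=Wq,
        W=W,
        Wa=policy.apply(30.0 / (s * mu - lam)),
        rho=policy.apply(lam / (s * mu)),
    )


def erlang_c_wait_probability(offered_load: float, s: int) -> float:
    """Erlang-C probability of delay, C(s, a) with a = lam/mu.

    Uses the numerically stable Erlang-B recurrence
    B(0)=1, B(k) = a*B(k-1)/(k + a*B(k-1)), then
    C = B(s) / (1 - rho*(1 - B(s))).
    """
    a = float(offered_load)
    s = int(s)
    if a <= 0:
        raise InvalidParameterError("offered load must be > 0")
    if s < 1:
        raise InvalidParameterError("s must be >= 1")
    if a >= s:
        raise InstabilityError(f"offered load a={a} >= s={s}")
    b = 1.0
    for k in range(1, s + 1):
        b = a * b / (k + a * b)
    rho = a / s
    return b / (1.0 - rho * (1.0 - b))


def erlang_c_wq(lam: float, mu: float, s: int) -> float:
    """Steady-state M/M/s mean queueing delay, in the time unit of the rates.

    ``lam`` and ``mu`` may be per minute or per interval, as long as they
    agree; the returned Wq is in the corresponding time unit.
    """
    if lam <= 0 or mu <= 0:
        raise InvalidParameterError("rates must be > 0")
    c = erlang_c_wait_probability(lam / mu, s)
    return c / (s * mu - lam)


def erlang_c_indicators(
    params: ShiftParameters, policy: ReportingPolicy | None = None
) -> QueueIndicators:
    """Textbook M/M/s steady-state indicators (rates per 30 min, times in
    minutes).  This is the oracle route: it assumes L itself follows the
    steady-state model rather than being observed."""
    lam, mu, s = params.lam, params.mu, params.s
    if not params.is_stable:
        raise InstabilityError(f"lam={lam} >= s*mu={s * mu}")
    a = params.offered_load
    rho = params.utilization
    c = erlang_c_wait_probability(a, s)
    Lq = c * rho / (1.0 - rho)
    Wq = 30.0 * Lq / lam
    ind = QueueIndicators(
        r=a,
        L=Lq + a,
        Lq=Lq,
        Wq=Wq,
        W=Wq + 30.0 / mu,
        Wa=30.0 / (s * mu - lam),
        rho=rho,
        p_wait=c,
    )
    if policy is None:
        return ind
    return QueueIndicators(
        **{k: policy.apply(v) for k, v in ind.as_dict().items() if k != "p_wait"},
        p_wait=policy.apply(c, 4),
    )


def sample_size(spec: SampleSizeSpec) -> float:
    """n = ((z * delta) / d)^2, unrounded."""
    return ((spec.z * spec.delta) / spec.d) ** 2


def mm1_service_rate_from_wait(lam_per_min: float, wq_minutes: float) -> float:
    """Invert the M/M/1 delay formula Wq = lam / (mu*(mu - lam)) for mu.

    Returns the positive root of mu^2 - lam*mu - lam/Wq = 0, which always
    exceeds ``lam_per_min`` (the recovered station is automatically
    stable).  Used to calibrate a single-server station's unobserved
    service rate from its observed mean wait.
    """
    lam = float(lam_per_min)
    wq = float(wq_minutes)
    if lam <= 0 or wq <= 0:
        raise InvalidParameterError("lam and Wq must be > 0")
    return 0.5 * (lam + math.sqrt(lam * lam + 4.0 * lam / wq))
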