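"""Discrete-event simulator for tandem multi-server FIFO queueing networks.

Patients arrive in a Poisson stream, traverse the configured stations in
order, hold one server per station for a sampled service time, and leave.
The engine is a classic event-list simulation (heap-ordered), with two
determinism guarantees:

* identical seed and configuration give a bit-identical patient record
  stream;
* random draws are consumed from one substream per station plus one for
  arrivals, all spawned from the base seed, so changing one station's
  staffing does not perturb the other stations' draws (common random
  numbers for scenario comparisons).

Event ties are broken deterministically: at equal timestamps departures
are processed before arrivals, and among equals the lower patient id goes
first.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InvalidParameterError

__all__ = [
    "ServiceDistribution",
    "StationConfig",
    "NetworkConfig",
    "StationStats",
    "SimulationResult",
    "ReplicationResult",
    "simulate",
    "replicate",
    "queue_length_distribution",
    "DEFAULT_QUEUE_BINS",
]

_DEPART, _ARRIVE = 0, 1

#: Queue-length report bins used by the field study, read as
#: [0,5), [5,10), [10,15), [15,20), [20,24] (the published bins overlap
#: at their endpoints; the half-open reading removes the ambiguity).
DEFAULT_QUEUE_BINS: tuple[float, ...] = (0, 5, 10, 15, 20, 24)


@dataclass(frozen=True)
class ServiceDistribution:
    """Service-time distribution of one station (mean in minutes)."""

    family: str = "exponential"
    mean_minutes: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "deterministic"):
            raise ConfigError(f"unknown service family {self.family!r}")
        if self.mean_minutes <= 0:
            raise ConfigError("mean service time must be > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "exponential":
            return float(rng.exponential(self.mean_minutes))
        return self.mean_minutes


@dataclass(frozen=True)
class StationConfig:
    name: str
    servers: int
    service: ServiceDistribution

    def __post_init__(self) -> None:
        if int(self.servers) < 1:
            raise ConfigError(f"station {self.name!r} needs >= 1 server")


@dataclass(frozen=True)
class NetworkConfig:
    """A tandem network plus run parameters.

    Stations are visited first to last.  Statistics are collected on
    [warmup_minutes, horizon_minutes]; the default warm-up of 0 with an
    empty start mimics a shift that opens with no patients present.
    """

    stations: tuple[StationConfig, ...]
    arrival_rate_per_min: float
    horizon_minutes: float
    warmup_minutes: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stations", tuple(self.stations))
        if len(self.stations) < 1:
            raise ConfigError("need at least one station")
        names = [st.name for st in self.stations]
        if len(set(names)) != len(names):
            raise ConfigError("station names must be unique")
        if self.arrival_rate_per_min <= 0:
            raise ConfigError("arrival rate must be > 0")
        if not (self.horizon_minutes > self.warmup_minutes >= 0):
            raise ConfigError("require horizon > warmup >= 0")

    def station_names(self) -> list[str]:
        return [st.name for st in self.stations]

    def with_servers(self, staffing: dict[str, int]) -> "NetworkConfig":
        """Copy of the config with some stations' server counts replaced."""
        unknown = set(staffing) - set(self.station_names())
        if unknown:
            raise ConfigError(f"unknown stations {sorted(unknown)}")
        new = tuple(
            replace(st, servers=int(staffing.get(st.name, st.servers)))
            for st in self.stations
        )
        return replace(self, stations=new)

    def utilization(self, station: str) -> float:
        """Offered load per server, lam * E[S] / c, at one station."""
        for st in self.stations:
            if st.name == station:
                return (
                    self.arrival_rate_per_min
                    * st.service.mean_minutes
                    / st.servers
                )
        raise ConfigError(f"unknown station {station!r}")


@dataclass
class StationStats:
    """Post-warm-up statistics of a single station in a single run."""

    name: str
    n_arrivals: int
    mean_wait: float
    time_avg_queue_len: float
    prob_no_queue: float
    queue_found: np.ndarray = field(repr=False)

    def queue_len_histogram(
        self, bin_edges: tuple[float, ...] = DEFAULT_QUEUE_BINS
    ) -> np.ndarray:
        return _histogram(self.queue_found, bin_edges)


@dataclass
class SimulationResult:
    """One replication's output."""

    config: NetworkConfig
    stations: dict[str, StationStats]
    n_arrivals: int
    n_completed: int
    n_in_system_at_horizon: int
    mean_time_in_system: float
    records: pd.DataFrame | None = None


def _histogram(found: np.ndarray, bin_edges) -> np.ndarray:
    """Occupancy fractions over bins [e0,e1), ..., [e_{k-1}, e_k] with
    values above the last edge clipped into the last bin so the fractions
    always partition the arrivals."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise InvalidParameterError("bin edges must be strictly increasing")
    if len(found) == 0:
        return np.zeros(len(edges) - 1)
    x = np.minimum(np.asarray(found, dtype=float), edges[-1])
    counts, _ = np.histogram(x, bins=edges)
    return counts / len(found)


def simulate(
    config: NetworkConfig, *, rep: int = 0, collect_records: bool = True
) -> SimulationResult:
    """Run one replication of the tandem network.

    ``rep`` selects the replication substream; :func:`replicate` passes
    0..n-1 so that its first replication is identical to a plain
    ``simulate`` call with the same config.
    """
    m = len(config.stations)
    horizon = float(config.horizon_minutes)
    wstart = float(config.warmup_minutes)

    ss = np.random.SeedSequence(config.seed, spawn_key=(rep,))
    streams = ss.spawn(1 + m)
    arrival_rng = np.random.default_rng(streams[0])
    station_rngs = [np.random.default_rng(s) for s in streams[1:]]

    # Pre-draw the Poisson arrival process on [0, horizon).
    rate = config.arrival_rate_per_min
    gaps = arrival_rng.exponential(1.0 / rate, size=max(16, int(rate * horizon * 1.25)))
    times = np.cumsum(gaps)
    while times.size == 0 or times[-1] < horizon:
        more = arrival_rng.exponential(1.0 / rate, size=max(16, int(rate * horizon * 0.25)))
        times = np.concatenate([times, times[-1] + np.cumsum(more)]) if times.size else np.cumsum(more)
    arrivals = times[times < horizon]
    n = len(arrivals)

    # Per-station state.
    free = [st.servers for st in config.stations]
    waiting: list[deque[int]] = [deque() for _ in range(m)]
    dists = [st.service for st in config.stations]

    # Statistics accumulators.
    area = [0.0] * m          # integral of waiting-count over [wstart, horizon]
    last_t = [wstart] * m
    qlen = [0] * m
    wait_sum = [0.0] * m
    wait_n = [0] * m
    found: list[list[int]] = [[] for _ in range(m)]
    tis_sum = 0.0
    tis_n = 0
    n_completed = 0

    # Per-patient timestamps (station-major): queue entry, start, end.
    q_t = np.full((m, n), np.nan)
    s_t = np.full((m, n), np.nan)
    e_t = np.full((m, n), np.nan)

    def advance_area(i: int, t: float) -> None:
        if t > wstart:
            area[i] += qlen[i] * (t - max(last_t[i], wstart))
        last_t[i] = t

    def start_service(i: int, pid: int, t: float) -> None:
        s_t[i, pid] = t
        w = t - q_t[i, pid]
        if q_t[i, pid] >= wstart:
            wait_sum[i] += w
            wait_n[i] += 1
        svc = dists[i].sample(station_rngs[i])
        heapq.heappush(heap, (t + svc, _DEPART, pid, i))

    heap: list[tuple[float, int, int, int]] = [
        (float(arrivals[pid]), _ARRIVE, pid, 0) for pid in range(n)
    ]
    heapq.heapify(heap)

    while heap:
        t, kind, pid, i = heapq.heappop(heap)
        if t > horizon:
            break
        if kind == _ARRIVE:
            q_t[i, pid] = t
            if t >= wstart:
                found[i].append(len(waiting[i]))
            if free[i] > 0 and not waiting[i]:
                free[i] -= 1
                start_service(i, pid, t)
            else:
                advance_area(i, t)
                waiting[i].append(pid)
                qlen[i] += 1
        else:  # departure from station i
            e_t[i, pid] = t
            free[i] += 1
            if waiting[i]:
                advance_area(i, t)
                nxt = waiting[i].popleft()
                qlen[i] -= 1
                free[i] -= 1
                start_service(i, nxt, t)
            if i + 1 < m:
                heapq.heappush(heap, (t, _ARRIVE, pid, i + 1))
            else:
                n_completed += 1
                if arrivals[pid] >= wstart:
                    tis_sum += t - arrivals[pid]
                    tis_n += 1

    for i in range(m):
        advance_area(i, horizon)

    span = horizon - wstart
    station_stats: dict[str, StationStats] = {}
    for i, st in enumerate(config.stations):
        fnd = np.asarray(found[i], dtype=np.int64)
        station_stats[st.name] = StationStats(
            name=st.name,
            n_arrivals=len(fnd),
            mean_wait=wait_sum[i] / wait_n[i] if wait_n[i] else float("nan"),
            time_avg_queue_len=area[i] / span,
            prob_no_queue=float(np.mean(fnd == 0)) if len(fnd) else float("nan"),
            queue_found=fnd,
        )

    records = None
    if collect_records:
        cols: dict[str, np.ndarray] = {"id": np.arange(n), "arrival": arrivals}
        for i, st in enumerate(config.stations):
            cols[f"{st.name}_queue_entry"] = q_t[i]
            cols[f"{st.name}_start"] = s_t[i]
            cols[f"{st.name}_end"] = e_t[i]
        records = pd.DataFrame(cols)

    return SimulationResult(
        config=config,
        stations=station_stats,
        n_arrivals=n,
        n_completed=n_completed,
        n_in_system_at_horizon=n - n_completed,
        mean_time_in_system=tis_sum / tis_n if tis_n else float("nan"),
        records=records,
    )


@dataclass
class ReplicationResult:
    """Across-replication means with normal-approximation confidence
    half-widths, plus the per-replication values they summarize."""

    config: NetworkConfig
    n_reps: int
    confidence: float
    #: station -> statistic -> per-replication values
    per_rep: dict[str, dict[str, np.ndarray]]
    #: system-level statistic -> per-replication values
    system_per_rep: dict[str, np.ndarray]
    #: pooled queue-lengths-found-at-arrival per station
    queue_found: dict[str, np.ndarray]

    def _z(self) -> float:
        return float(stats.norm.ppf(0.5 * (1.0 + self.confidence)))

    def station_mean(self, station: str, stat: str) -> float:
        return float(np.nanmean(self.per_rep[station][stat]))

    def station_halfwidth(self, station: str, stat: str) -> float:
        x = self.per_rep[station][stat]
        x = x[~np.isnan(x)]
        if len(x) < 2:
            return float("nan")
        return self._z() * float(np.std(x, ddof=1)) / np.sqrt(len(x))

    def system_mean(self, stat: str) -> float:
        return float(np.nanmean(self.system_per_rep[stat]))

    def system_halfwidth(self, stat: str) -> float:
        x = self.system_per_rep[stat]
        x = x[~np.isnan(x)]
        if len(x) < 2:
            return float("nan")
        return self._z() * float(np.std(x, ddof=1)) / np.sqrt(len(x))

    def summary(self) -> dict:
        out: dict = {"n_reps": self.n_reps, "confidence": self.confidence, "stations": {}}
        for name, d in self.per_rep.items():
            out["stations"][name] = {
                stat: {
                    "mean": self.station_mean(name, stat),
                    "halfwidth": self.station_halfwidth(name, stat),
                }
                for stat in d
            }
        out["system"] = {
            stat: {
                "mean": self.system_mean(stat),
                "halfwidth": self.system_halfwidth(stat),
            }
            for stat in self.system_per_rep
        }
        return out


_STATION_STATS = ("mean_wait", "time_avg_queue_len", "prob_no_queue")
_SYSTEM_STATS = ("mean_time_in_system", "n_completed", "n_arrivals")


def replicate(
    config: NetworkConfig,
    n_reps: int,
    *,
    confidence: float = 0.95,
) -> ReplicationResult:
    """Run ``n_reps`` independent replications (substreams 0..n_reps-1 of
    the base seed) and summarize each statistic across them."""
    if int(n_reps) < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    if not (0 < confidence < 1):
        raise InvalidParameterError("confidence must be in (0, 1)")
    names = config.station_names()
    per_rep = {nm: {st: np.empty(n_reps) for st in _STATION_STATS} for nm in names}
    system = {st: np.empty(n_reps) for st in _SYSTEM_STATS}
    found = {nm: [] for nm in names}
    for r in range(int(n_reps)):
        res = simulate(config, rep=r, collect_records=False)
        for nm in names:
            stn = res.stations[nm]
            per_rep[nm]["mean_wait"][r] = stn.mean_wait
            per_rep[nm]["time_avg_queue_len"][r] = stn.time_avg_queue_len
            per_rep[nm]["prob_no_queue"][r] = stn.prob_no_queue
            found[nm].append(stn.queue_found)
        system["mean_time_in_system"][r] = res.mean_time_in_system
        system["n_completed"][r] = res.n_completed
        system["n_arrivals"][r] = res.n_arrivals
    return ReplicationResult(
        config=config,
        n_reps=int(n_reps),
        confidence=confidence,
        per_rep=per_rep,
        system_per_rep=system,
        queue_found={nm: np.concatenate(found[nm]) for nm in names},
    )


def queue_length_distribution(
    result: SimulationResult | ReplicationResult,
    station: str,
    bin_edges=DEFAULT_QUEUE_BINS,
) -> np.ndarray:
    """Fraction of arriving patients who found the station's queue length
    within each bin ([lo, hi) except the last bin, which is closed; values
    beyond the last edge count in the last bin)."""
    if isinstance(result, ReplicationResult):
        if station not in result.queue_found:
            raise InvalidParameterError(f"unknown station {station!r}")
        found = result.queue_found[station]
    else:
        if station not in result.stations:
            raise InvalidParameterError(f"unknown station {station!r}")
        found = result.stations[station].queue_found
    return _histogram(found, bin_edges)
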