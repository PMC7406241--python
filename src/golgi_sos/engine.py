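"""Exact event-driven simulation of the self-organising compartment system.

Two implementations of the same stochastic law live here:

* :class:`Simulation` / :func:`run` — the production engine, a thin driver
  around the jit-compiled kernel in :mod:`golgi_sos._core`.  It keeps class
  propensities incrementally and is fast enough for phase-diagram sweeps.
* :func:`total_propensity` / :func:`step` — a direct O(M^2) reference that
  enumerates every addressable event from the rate laws in
  :mod:`golgi_sos.model_core`.  It is deliberately simple and serves as the
  independent oracle for the production engine: on any frozen state the two
  must sample events from the same distribution.

Cargo molecules are passive labels injected from the ER (as a finite pulse
or tagging a fraction of incoming vesicles); they ride budding vesicles
with probability 1/n and never alter any propensity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from ._core import EVENT_KIND_NAMES
from .meanfield import calibrate_influx
from .model_core import (
    Compartment,
    Identity,
    Parameters,
    boundary_fusion_rate,
    budding_rates,
    conversion_rates,
    fusion_rate,
    purity_from_fractions,
)

__all__ = [
    "Simulation",
    "Trajectory",
    "SystemState",
    "EventRecord",
    "run",
    "total_propensity",
    "step",
    "resolve_influx",
]

EVENT_COLUMNS = [
    "time", "kind", "donor_id", "acceptor_id", "identity",
    "donor_n", "donor_ncis", "donor_nmedial", "donor_ntrans",
    "acceptor_ncis", "acceptor_nmedial", "acceptor_ntrans", "cargo_moved",
]

TRANSPORT_COLUMNS = [
    "time", "identity",
    "donor_phi_cis", "donor_phi_medial", "donor_phi_trans",
    "acceptor_phi_cis", "acceptor_phi_medial", "acceptor_phi_trans",
    "cargo", "back_fusion", "is_exit", "donor_id", "acceptor_id",
]

SNAPSHOT_COLUMNS = [
    "time", "compartment_id", "n_cis", "n_medial", "n_trans", "n_cargo",
]

SERIES_COLUMNS = [
    "time", "n_total", "n_cis", "n_medial", "n_trans",
    "n_compartments", "n_nonvesicle", "purity",
    "cargo_in_system", "cargo_exited_er", "cargo_exited_tgn",
]


def resolve_influx(params: Parameters) -> float:
    """Injection rate used for a run: explicit j, or the well-sorted
    calibration from the target mean system size."""
    if params.j is not None:
        return float(params.j)
    return calibrate_influx(
        params.n_target, params.km, params.alpha_er, params.alpha_tgn
    )


# ---------------------------------------------------------------------------
# Production engine
# ---------------------------------------------------------------------------

class Simulation:
    """Mutable simulation state driven in chunks by the jitted kernel.

    Most users want :func:`run`; this class is for custom drivers
    (frozen-state sampling, mid-run cargo injection, checkpointing).
    """

    def __init__(
        self,
        params: Parameters,
        *,
        capacity: int = 2048,
        record_events: bool = False,
        validate: bool = False,
        seed: int | None = None,
        event_buffer: int = 200_000,
        transport_buffer: int = 100_000,
    ) -> None:
        self.params = params
        self.j = resolve_influx(params)
        self._record_events = bool(record_events)
        self._validate = bool(validate)

        self._alloc(capacity)
        self.fstate = np.zeros(_core.FSTATE_LEN, dtype=np.float64)
        self.istate = np.zeros(_core.ISTATE_LEN, dtype=np.int64)
        self.rstate = _core.seed_state(params.seed if seed is None else seed)

        self.pf = np.zeros(_core.PF_LEN, dtype=np.float64)
        self.pf[_core.P_J] = self.j
        self.pf[_core.P_KB] = params.kb
        self.pf[_core.P_KM] = params.km
        self.pf[_core.P_AER] = params.alpha_er
        self.pf[_core.P_ATGN] = params.alpha_tgn
        self.pf[_core.P_FUSION_ON] = 1.0 if params.inter_compartment_fusion else 0.0
        self.pf[_core.P_LINEAR] = 1.0 if params.budding_mode == "linear" else 0.0
        self.pf[_core.P_CARGO_CONT] = 0.0

        self._ev = np.empty((event_buffer, _core.EV_COLS), dtype=np.float64)
        self._ev_n = np.zeros(1, dtype=np.int64)
        self._tr = np.empty((transport_buffer, _core.TR_COLS), dtype=np.float64)
        self._tr_n = np.zeros(1, dtype=np.int64)
        self._ev_chunks: list[np.ndarray] = []
        self._tr_chunks: list[np.ndarray] = []

    def _alloc(self, capacity: int) -> None:
        self.cnt = np.zeros((capacity, 3), dtype=np.int64)
        self.cargo = np.zeros(capacity, dtype=np.int64)
        self.uid = np.zeros(capacity, dtype=np.int64)
        self.bud_flag = np.zeros(capacity, dtype=np.uint8)
        self.bud_ident = np.zeros(capacity, dtype=np.int8)
        self.bud_donor_uid = np.full(capacity, -3, dtype=np.int64)
        self.bud_phi = np.zeros((capacity, 3), dtype=np.float64)
        self.bud_time = np.zeros(capacity, dtype=np.float64)
        self.order = np.arange(capacity, dtype=np.int64)
        self.pos = np.arange(capacity, dtype=np.int64)

    def _grow(self) -> None:
        old = self.order.shape[0]
        new = old * 2
        for name in ("cnt", "bud_phi"):
            arr = getattr(self, name)
            grown = np.zeros((new, 3), dtype=arr.dtype)
            grown[:old] = arr
            setattr(self, name, grown)
        for name, fill in (
            ("cargo", 0), ("uid", 0), ("bud_flag", 0), ("bud_ident", 0),
            ("bud_donor_uid", -3), ("bud_time", 0.0),
        ):
            arr = getattr(self, name)
            grown = np.full(new, fill, dtype=arr.dtype)
            grown[:old] = arr
            setattr(self, name, grown)
        order = np.empty(new, dtype=np.int64)
        order[:old] = self.order
        order[old:] = np.arange(old, new, dtype=np.int64)
        pos = np.empty(new, dtype=np.int64)
        pos[:old] = self.pos
        pos[old:] = np.arange(old, new, dtype=np.int64)
        self.order = order
        self.pos = pos

    # -- state construction ------------------------------------------------

    @classmethod
    def from_compartments(
        cls,
        compartments: list[Compartment],
        params: Parameters,
        **kwargs,
    ) -> "Simulation":
        sim = cls(params, **kwargs)
        for comp in compartments:
            sim.add_compartment(comp.counts, cargo=comp.cargo)
        return sim

    def add_compartment(self, counts, cargo: int = 0) -> int:
        """Insert a compartment; returns its unique id.

        Bookkeeping counters are updated as if its patches and cargo had
        been injected, so conservation invariants keep holding.
        """
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (3,) or counts.sum() < 1 or np.any(counts < 0):
            raise ValueError("counts must be 3 non-negative integers summing to >= 1")
        m = int(self.istate[_core.I_M])
        while m + 1 >= self.order.shape[0]:
            self._grow()
        s = self.order[m]
        self.cnt[s] = counts
        self.cargo[s] = cargo
        new_uid = int(self.istate[_core.I_NEXT_UID])
        self.uid[s] = new_uid
        self.istate[_core.I_NEXT_UID] += 1
        self.bud_flag[s] = 0
        self.pos[s] = m
        self.istate[_core.I_M] = m + 1
        self.istate[_core.I_INJECTED] += int(counts.sum())
        self.istate[_core.I_CARGO_INJ] += int(cargo)
        return new_uid

    # -- cargo -------------------------------------------------------------

    def inject_cargo_pulse(self, count: int) -> None:
        """Tag the next ``count`` injected vesicles with one cargo each."""
        if count < 0:
            raise ValueError("pulse count must be non-negative")
        self.istate[_core.I_PULSE] += count

    def set_continuous_cargo(self, fraction: float) -> None:
        """Tag each injected vesicle with one cargo with this probability."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        self.pf[_core.P_CARGO_CONT] = fraction

    # -- advancing ---------------------------------------------------------

    def advance(self, t_end: float, max_events: int | None = None) -> int:
        """Advance to ``t_end`` (or by ``max_events``); returns events run."""
        start_events = int(self.istate[_core.I_NEVENTS])
        budget = np.int64(2**62) if max_events is None else np.int64(max_events)
        while True:
            done = int(self.istate[_core.I_NEVENTS]) - start_events
            status = _core._advance(
                self.cnt, self.cargo, self.uid, self.bud_flag, self.bud_ident,
                self.bud_donor_uid, self.bud_phi, self.bud_time,
                self.order, self.pos, self.fstate, self.istate, self.rstate,
                self.pf, float(t_end), budget - done,
                self._ev, self._ev_n, self._tr, self._tr_n,
                self._record_events, self._validate,
            )
            if status == _core.OK:
                break
            if status == _core.MAX_EVENTS:
                break
            if status == _core.SLOTS_FULL:
                self._grow()
            elif status == _core.EVLOG_FULL:
                self._flush_events()
            elif status == _core.TRLOG_FULL:
                self._flush_transport()
            elif status == _core.INVALID:
                raise RuntimeError(
                    "state invariant violated during simulation "
                    f"(t={self.time:.6g}); this indicates an engine bug"
                )
            else:  # pragma: no cover
                raise RuntimeError(f"unknown kernel status {status}")
        return int(self.istate[_core.I_NEVENTS]) - start_events

    def _flush_events(self) -> None:
        n = int(self._ev_n[0])
        if n:
            self._ev_chunks.append(self._ev[:n].copy())
            self._ev_n[0] = 0

    def _flush_transport(self) -> None:
        n = int(self._tr_n[0])
        if n:
            self._tr_chunks.append(self._tr[:n].copy())
            self._tr_n[0] = 0

    # -- inspection --------------------------------------------------------

    @property
    def time(self) -> float:
        return float(self.fstate[_core.F_TIME])

    @property
    def n_compartments(self) -> int:
        return int(self.istate[_core.I_M])

    @property
    def n_events(self) -> int:
        return int(self.istate[_core.I_NEVENTS])

    def active_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(counts (m,3), cargo (m,), uid (m,)) copies of the live state."""
        sel = self.order[: self.n_compartments]
        return self.cnt[sel].copy(), self.cargo[sel].copy(), self.uid[sel].copy()

    def compartments(self) -> list[Compartment]:
        counts, cargo, uids = self.active_counts()
        return [
            Compartment(counts=c, cargo=int(g), id=int(u))
            for c, g, u in zip(counts, cargo, uids)
        ]

    @property
    def counters(self) -> dict[str, int]:
        ist = self.istate
        return {
            "injected_patches": int(ist[_core.I_INJECTED]),
            "exited_er_patches": int(ist[_core.I_EXIT_ER]),
            "exited_tgn_patches": int(ist[_core.I_EXIT_TGN]),
            "cargo_injected": int(ist[_core.I_CARGO_INJ]),
            "cargo_exited_er": int(ist[_core.I_CARGO_ER]),
            "cargo_exited_tgn": int(ist[_core.I_CARGO_TGN]),
            "n_events": int(ist[_core.I_NEVENTS]),
        }

    def series_row(self) -> dict[str, float]:
        counts, cargo, _ = self.active_counts()
        n = counts.sum(axis=1)
        row = {
            "time": self.time,
            "n_total": float(n.sum()),
            "n_cis": float(counts[:, 0].sum()),
            "n_medial": float(counts[:, 1].sum()),
            "n_trans": float(counts[:, 2].sum()),
            "n_compartments": float(len(n)),
            "n_nonvesicle": float(np.count_nonzero(n >= 2)),
            "cargo_in_system": float(cargo.sum()),
            "cargo_exited_er": float(self.istate[_core.I_CARGO_ER]),
            "cargo_exited_tgn": float(self.istate[_core.I_CARGO_TGN]),
        }
        big = n >= 2
        if np.any(big):
            phi = counts[big] / n[big, None]
            p = purity_from_fractions(phi)
            row["purity"] = float(np.sum(n[big] * p) / n[big].sum())
        else:
            row["purity"] = float("nan")
        return row

    # -- checkpointing (used by frozen-state resampling tests) -------------

    def checkpoint(self) -> dict[str, np.ndarray]:
        """Snapshot of everything except the RNG stream."""
        names = (
            "cnt", "cargo", "uid", "bud_flag", "bud_ident", "bud_donor_uid",
            "bud_phi", "bud_time", "order", "pos", "fstate", "istate",
        )
        return {name: getattr(self, name).copy() for name in names}

    def restore(self, chk: dict[str, np.ndarray]) -> None:
        for name, arr in chk.items():
            np.copyto(getattr(self, name), arr)
        self._ev_n[0] = 0
        self._tr_n[0] = 0
        self._ev_chunks.clear()
        self._tr_chunks.clear()

    # -- log extraction ----------------------------------------------------

    def drain_events(self) -> pd.DataFrame:
        self._flush_events()
        if self._ev_chunks:
            raw = np.concatenate(self._ev_chunks)
        else:
            raw = np.empty((0, _core.EV_COLS))
        self._ev_chunks.clear()
        df = pd.DataFrame(raw, columns=EVENT_COLUMNS)
        df["kind"] = df["kind"].astype(int).map(EVENT_KIND_NAMES)
        for col in EVENT_COLUMNS[2:]:
            df[col] = df[col].astype(np.int64)
        return df

    def drain_transport(self) -> pd.DataFrame:
        self._flush_transport()
        if self._tr_chunks:
            raw = np.concatenate(self._tr_chunks)
        else:
            raw = np.empty((0, _core.TR_COLS))
        self._tr_chunks.clear()
        df = pd.DataFrame(raw, columns=TRANSPORT_COLUMNS)
        df["identity"] = df["identity"].astype(np.int64)
        df["cargo"] = df["cargo"].astype(np.int64)
        df["back_fusion"] = df["back_fusion"] > 0.5
        df["is_exit"] = df["is_exit"] > 0.5
        df["donor_id"] = df["donor_id"].astype(np.int64)
        df["acceptor_id"] = df["acceptor_id"].astype(np.int64)
        return df


@dataclass
class Trajectory:
    """Output of one simulation run.

    Attributes
    ----------
    series : sampled scalar time series (sizes, counts, purity, cargo).
    snapshots : full compartment tables at snapshot times.
    transport : one row per cargo-carrying budding->fusion episode.
    events : full event log (only if ``record_events`` was requested).
    counters : final cumulative bookkeeping counters.
    """

    params: Parameters
    j: float
    series: pd.DataFrame
    snapshots: pd.DataFrame
    transport: pd.DataFrame
    events: pd.DataFrame | None
    counters: dict[str, int]


def _schedule(t_max: float, interval: float) -> np.ndarray:
    n = int(round(t_max / interval))
    grid = np.arange(1, n + 1) * interval
    if grid[-1] < t_max - 1e-12:
        grid = np.append(grid, t_max)
    grid[-1] = min(grid[-1], t_max)
    return grid


def run(
    params: Parameters,
    *,
    sample_interval: float = 0.1,
    snapshot_interval: float = 1.0,
    record_events: bool = False,
    record_snapshots: bool = True,
    validate: bool = False,
    pulse: tuple[float, int] | None = None,
    continuous_cargo: float = 0.0,
    seed: int | None = None,
    capacity: int = 2048,
) -> Trajectory:
    """Simulate from an empty system up to ``params.t_max``.

    Observers sample the scalar series every ``sample_interval`` and the
    full compartment table every ``snapshot_interval`` (time units 1/Kf).
    ``pulse=(t0, count)`` releases a cargo pulse at time t0 (each of the
    next ``count`` injected vesicles carries one cargo);
    ``continuous_cargo=p`` tags each injected vesicle with probability p.
    Identical params + seed + observer schedule give identical trajectories.
    """
    sim = Simulation(
        params,
        capacity=capacity,
        record_events=record_events,
        validate=validate,
        seed=seed,
    )
    if continuous_cargo:
        sim.set_continuous_cargo(continuous_cargo)

    samples = _schedule(params.t_max, sample_interval)
    snap_every = max(1, int(round(snapshot_interval / sample_interval)))

    rows = [sim.series_row()]
    snap_parts: list[pd.DataFrame] = []

    def take_snapshot() -> None:
        counts, cargo, uids = sim.active_counts()
        snap_parts.append(
            pd.DataFrame(
                {
                    "time": sim.time,
                    "compartment_id": uids,
                    "n_cis": counts[:, 0],
                    "n_medial": counts[:, 1],
                    "n_trans": counts[:, 2],
                    "n_cargo": cargo,
                }
            )
        )

    if record_snapshots:
        take_snapshot()

    pulse_time = math.inf
    pulse_count = 0
    if pulse is not None:
        pulse_time, pulse_count = float(pulse[0]), int(pulse[1])
        if pulse_time > params.t_max:
            raise ValueError("pulse time must lie within the simulation horizon")
    pulse_armed = pulse is not None

    for k, t in enumerate(samples):
        if pulse_armed and pulse_time <= t:
            sim.advance(pulse_time)
            sim.inject_cargo_pulse(pulse_count)
            pulse_armed = False
        sim.advance(t)
        rows.append(sim.series_row())
        if record_snapshots and (k + 1) % snap_every == 0:
            take_snapshot()

    series = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    snapshots = (
        pd.concat(snap_parts, ignore_index=True)
        if snap_parts
        else pd.DataFrame(columns=SNAPSHOT_COLUMNS)
    )
    events = sim.drain_events() if record_events else None
    transport = sim.drain_transport()
    return Trajectory(
        params=params,
        j=sim.j,
        series=series,
        snapshots=snapshots,
        transport=transport,
        events=events,
        counters=sim.counters,
    )


# ---------------------------------------------------------------------------
# Reference implementation (independent oracle)
# ---------------------------------------------------------------------------

@dataclass
class EventRecord:
    """One executed event: its time, class, and participants."""

    time: float
    kind: str
    details: dict = field(default_factory=dict)


@dataclass
class SystemState:
    """Plain-Python system state for the reference implementation."""

    compartments: list[Compartment] = field(default_factory=list)
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    injected_patches: int = 0
    exited_er_patches: int = 0
    exited_tgn_patches: int = 0
    cargo_injected: int = 0
    cargo_exited_er: int = 0
    cargo_exited_tgn: int = 0
    pulse_remaining: int = 0
    continuous_cargo: float = 0.0

    def __post_init__(self) -> None:
        # compartments present at construction count as injected material so
        # the conservation ledger balances from the start
        self.injected_patches += sum(c.n for c in self.compartments)
        self.cargo_injected += sum(c.cargo for c in self.compartments)

    @property
    def total_patches(self) -> int:
        return int(sum(c.n for c in self.compartments))

    def find(self, comp_id: int) -> Compartment:
        for c in self.compartments:
            if c.id == comp_id:
                return c
        raise KeyError(comp_id)


def inject_cargo(state: SystemState, *, pulse: int | None = None,
                 continuous: float | None = None) -> SystemState:
    """Arm cargo injection on the reference state.

    ``pulse=k`` tags the next k injected vesicles with one cargo each;
    ``continuous=p`` tags each injected vesicle with probability p.
    """
    if pulse is not None:
        if pulse < 0:
            raise ValueError("pulse count must be non-negative")
        state.pulse_remaining += int(pulse)
    if continuous is not None:
        if not 0.0 <= continuous <= 1.0:
            raise ValueError("continuous fraction must lie in [0, 1]")
        state.continuous_cargo = float(continuous)
    return state


def total_propensity(
    state: SystemState, params: Parameters
) -> tuple[float, list[tuple[float, str, dict]]]:
    """Full enumeration of every addressable event and its rate.

    Returns ``(R_total, events)`` where each event is
    ``(rate, kind, payload)``.  Quadratic in the number of compartments;
    intended for small systems and as the sampling-law oracle for the
    production engine.
    """
    j = resolve_influx(params)
    events: list[tuple[float, str, dict]] = [(j, "injection", {})]
    comps = state.compartments
    er, tgn = params.boundaries
    for idx_a in range(len(comps)):
        a = comps[idx_a]
        for idx_b in range(idx_a + 1, len(comps)):
            b = comps[idx_b]
            rate = fusion_rate(a, b, params)
            if rate > 0:
                events.append((rate, "fusion", {"a": a.id, "b": b.id}))
        for boundary in (er, tgn):
            rate = boundary_fusion_rate(a, boundary)
            if rate > 0:
                events.append(
                    (rate, "boundary_fusion", {"a": a.id, "boundary": boundary.role})
                )
        for ident, rate in budding_rates(a, params).items():
            if rate > 0:
                events.append((rate, "budding", {"a": a.id, "identity": ident}))
        for src, rate in conversion_rates(a, params).items():
            if rate > 0:
                events.append((rate, "conversion", {"a": a.id, "source": src}))
    r_total = float(sum(rate for rate, _, _ in events))
    return r_total, events


def step(state: SystemState, params: Parameters) -> EventRecord:
    """Execute one exact Gillespie step on the reference state, in place.

    Draws the waiting time from Exp(R_total), picks one event with
    probability rate/R_total, and applies it.
    """
    r_total, events = total_propensity(state, params)
    if r_total <= 0:
        raise RuntimeError("cannot step a system with zero total propensity")
    rng = state.rng
    state.time += rng.exponential(1.0 / r_total)
    u = rng.uniform(0.0, r_total)
    acc = 0.0
    chosen = events[-1]
    for ev in events:
        acc += ev[0]
        if acc >= u:
            chosen = ev
            break
    _, kind, info = chosen
    details = dict(info)

    if kind == "injection":
        cargo = 0
        if state.pulse_remaining > 0:
            cargo = 1
            state.pulse_remaining -= 1
        elif state.continuous_cargo > 0 and rng.random() < state.continuous_cargo:
            cargo = 1
        vesicle = Compartment.pure(Identity.CIS, cargo=cargo)
        state.compartments.append(vesicle)
        state.injected_patches += 1
        state.cargo_injected += cargo
        details["vesicle"] = vesicle.id
    elif kind == "fusion":
        a = state.find(info["a"])
        b = state.find(info["b"])
        a.counts = a.counts + b.counts
        a.cargo += b.cargo
        state.compartments.remove(b)
    elif kind == "boundary_fusion":
        a = state.find(info["a"])
        if info["boundary"] == "ER":
            state.exited_er_patches += a.n
            state.cargo_exited_er += a.cargo
        else:
            state.exited_tgn_patches += a.n
            state.cargo_exited_tgn += a.cargo
        state.compartments.remove(a)
    elif kind == "budding":
        a = state.find(info["a"])
        ident = int(info["identity"])
        if a.counts[ident] < 1:
            raise RuntimeError("budding an absent identity (propensity bug)")
        n = a.n
        moved = int(rng.binomial(a.cargo, 1.0 / n)) if a.cargo else 0
        a.counts[ident] -= 1
        a.cargo -= moved
        vesicle = Compartment.pure(Identity(ident), cargo=moved)
        state.compartments.append(vesicle)
        details["vesicle"] = vesicle.id
        details["cargo_moved"] = moved
    elif kind == "conversion":
        a = state.find(info["a"])
        src = int(info["source"])
        a.counts[src] -= 1
        a.counts[src + 1] += 1
    else:  # pragma: no cover
        raise RuntimeError(f"unknown event kind {kind}")

    if state.total_patches != (
        state.injected_patches - state.exited_er_patches - state.exited_tgn_patches
    ):  # pragma: no cover - conservation is structural
        warnings.warn("patch conservation violated", RuntimeWarning)
    return EventRecord(time=state.time, kind=kind, details=details)
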