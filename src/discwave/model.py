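"""Intercellular calcium dynamics on a cell lattice.

Each cell carries four state variables: cytosolic free calcium ``c`` (μM),
ER luminal calcium ``s`` (μM), IP3 ``p`` (μM) and the slow IP3R
inactivation gate ``h`` (dimensionless, in [0, 1]).  The single-cell
dynamics combine

* ligand-driven IP3 production (``v_plc × dose``) and first-order IP3
  degradation,
* IP3R release from the ER with a two-gate open probability
  ``((p/(p+d1)) (c/(c+d5)) h)³`` — activation by IP3 and calcium, slow
  calcium-dependent inactivation of ``h`` (the refractory mechanism),
* a passive ER leak and SERCA re-uptake (Hill coefficient 2),
* store-operated entry (SOCE) that grows as the ER store empties, and
  plasma-membrane extrusion,
* optional stochastic spike events: brief IP3R-independent calcium
  injections at a per-cell Poisson rate.

Cells exchange both calcium and IP3 through gap junctions; the junctional
flux into cell *i* is ``D · Σ_j w_ij (x_j − x_i) / area_i`` with ``w_ij``
the edge weight from :func:`discwave.lattice.coupling_graph`.  Per-edge
fluxes are antisymmetric, so junctional exchange conserves total calcium.

Pharmacological conditions act as parameter switches: 2-APB zeroes IP3R and
SOCE fluxes (stochastic spikes are insensitive to it), Thapsigargin
irreversibly zeroes SERCA, BAPTA removes external calcium (SOCE and spike
influx draw nothing), Carbenoxolone zeroes every junctional weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import scipy.sparse as sp

from . import _core
from .lattice import TissueLattice, coupling_graph

__all__ = [
    "CellState",
    "ModelParams",
    "PharmacologySchedule",
    "Trajectory",
    "SimulationError",
    "derivatives",
    "apply_condition",
    "simulate",
    "onset_experiment",
    "resting_state",
]


class SimulationError(RuntimeError):
    """Raised when integration becomes unstable or a state turns invalid."""


@dataclass
class CellState:
    """Per-cell state arrays (or scalars for a single cell)."""

    c: np.ndarray  # cytosolic free calcium, μM
    s: np.ndarray  # ER luminal calcium, μM
    p: np.ndarray  # IP3, μM
    h: np.ndarray  # IP3R inactivation gate, in [0, 1]

    def copy(self) -> "CellState":
        return CellState(
            np.array(self.c, dtype=float, copy=True),
            np.array(self.s, dtype=float, copy=True),
            np.array(self.p, dtype=float, copy=True),
            np.array(self.h, dtype=float, copy=True),
        )

    def validate(self) -> None:
        for name in ("c", "s", "p", "h"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"state variable {name!r} contains non-finite values")
            if np.any(v < 0):
                raise ValueError(f"state variable {name!r} contains negative values")
        if np.any(np.asarray(self.h) > 1 + 1e-9):
            raise ValueError("gate h exceeds 1")


@dataclass
class ModelParams:
    """Rate constants of the calcium model.  Units: μM, s, μm.

    The defaults are the ``pouch-18C`` calibration: with ``dose = 1``
    (5% fly extract equivalent) the median cell is an oscillator close to
    its excitability threshold, and the small log-normal cell-to-cell
    heterogeneity on ``v_plc`` and ``tau_h`` places a few strongly driven
    pacemaker cells in the tissue whose rhythm the coupled sheet adopts.
    """

    # IP3R / ER
    v_ip3r: float = 6.0        # max IP3R channel flux rate, s⁻¹
    v_leak: float = 0.002      # ER leak rate, s⁻¹
    v_serca: float = 1.5       # max SERCA rate, μM·s⁻¹
    k_serca: float = 0.15      # SERCA half-activation, μM
    d1: float = 0.1            # IP3 activation constant, μM
    d5: float = 0.3            # Ca activation constant, μM
    d2: float = 0.8            # Ca inactivation constant of h, μM
    tau_h: float = 150.0       # h relaxation time, s
    # IP3 turnover
    v_plc: float = 0.026       # ligand-driven IP3 production per unit dose, μM·s⁻¹
    k_deg: float = 1.0 / 30.0  # IP3 degradation, s⁻¹
    # plasma membrane
    v_soce: float = 0.02       # max store-operated entry, μM·s⁻¹
    k_soce: float = 4.0        # store half-depletion constant, μM
    v_pm_out: float = 0.03     # plasma-membrane extrusion, s⁻¹
    # stochastic spikes
    j_spike: float = 0.5       # spike-event calcium injection, μM·s⁻¹
    lambda_spike: float = 0.0  # spike rate, cell⁻¹·s⁻¹
    spike_duration: float = 2.0  # s
    # junctional transfer
    d_c: float = 3.0           # junctional coefficient for c, μm·s⁻¹ per unit weight
    d_p: float = 0.5           # junctional coefficient for p
    # geometry / volumes
    beta: float = 0.185        # ER-to-cytosol volume ratio
    # heterogeneity and environment
    hetero_cv: float = 0.08    # per-cell CV on v_plc and tau_h
    ca_ext: float = 1.0        # external calcium availability, 0 or 1
    dose: float = 0.0          # ambient ligand dose (1.0 ≙ 5% fly extract)
    gj_block: bool = False     # Carbenoxolone: zero all junctional weights
    #: region name -> {param name -> multiplier}; applied on top of the
    #: per-cell heterogeneity (supported: 'v_plc', 'tau_h', 'v_soce').
    region_modifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("region_modifiers", "gj_block"):
                continue
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"parameter {f.name!r} must be ≥ 0, got {v}")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


_CONDITION_KEYS = {"extract_dose", "two_apb", "thapsigargin", "bapta", "carbenoxolone"}


class PharmacologySchedule:
    """Time-stamped condition switches.

    Entries are ``(time_s, condition)`` with ``condition`` a dict using the
    keys ``extract_dose`` (float), ``two_apb``, ``thapsigargin``, ``bapta``,
    ``carbenoxolone`` (bools).  Times must be non-decreasing.  Thapsigargin
    is irreversible: once applied, a later ``thapsigargin: False`` entry is
    ignored.
    """

    def __init__(self, entries):
        entries = [(float(t), dict(c)) for t, c in entries]
        times = [t for t, _ in entries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be non-decreasing")
        for _, cond in entries:
            unknown = set(cond) - _CONDITION_KEYS
            if unknown:
                raise ValueError(f"unknown condition keys: {sorted(unknown)}")
        self.entries = entries

    @classmethod
    def constant(cls, dose: float) -> "PharmacologySchedule":
        return cls([(0.0, {"extract_dose": float(dose)})])

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def apply_condition(params: ModelParams, condition: dict) -> ModelParams:
    """Return a copy of ``params`` with one condition switch applied.

    This applies switches forward only; :func:`simulate` additionally
    re-derives the effective parameters from the pre-treatment baseline at
    every schedule entry, so that reversible drugs (2-APB, BAPTA,
    Carbenoxolone) wash out while Thapsigargin latches.
    """
    unknown = set(condition) - _CONDITION_KEYS
    if unknown:
        raise ValueError(f"unknown condition keys: {sorted(unknown)}")
    out = params
    if "extract_dose" in condition:
        out = out.replace(dose=float(condition["extract_dose"]))
    if condition.get("two_apb"):
        out = out.replace(v_ip3r=0.0, v_soce=0.0)
    if condition.get("thapsigargin"):
        out = out.replace(v_serca=0.0)
    if "bapta" in condition:
        out = out.replace(ca_ext=0.0 if condition["bapta"] else 1.0)
    if "carbenoxolone" in condition:
        out = out.replace(gj_block=bool(condition["carbenoxolone"]))
    return out


# ---------------------------------------------------------------------- #
# Right-hand side
# ---------------------------------------------------------------------- #


def _rhs(
    c, s, p, h, pr: ModelParams, W, wsum, inv_area, g_plc, tau_h, spike_in,
    g_soce=1.0,
):
    """Time derivatives of (c, s, p, h).  All array arguments are (N,)."""
    gate = (p / (p + pr.d1)) * (c / (c + pr.d5)) * h
    open_p = gate * gate * gate
    release = (pr.v_ip3r * open_p + pr.v_leak) * (s - c)
    serca = pr.v_serca * c * c / (pr.k_serca * pr.k_serca + c * c)
    soce = g_soce * pr.v_soce * pr.k_soce**2 / (pr.k_soce**2 + s * s) * pr.ca_ext
    if W is not None:
        jc = pr.d_c * (W @ c - wsum * c) * inv_area
        jp = pr.d_p * (W @ p - wsum * p) * inv_area
    else:
        jc = jp = 0.0
    dc = release - serca + soce - pr.v_pm_out * c + spike_in + jc
    ds = -(release - serca) / pr.beta
    dp = g_plc * pr.v_plc * pr.dose - pr.k_deg * p + jp
    dh = (pr.d2 / (pr.d2 + c) - h) / tau_h
    return dc, ds, dp, dh


def _per_cell_arrays(params: ModelParams, lattice: TissueLattice, rng):
    """Per-cell multipliers for v_plc, tau_h and v_soce.

    Log-normal heterogeneity (median 1, CV ``hetero_cv``) on v_plc and
    tau_h drawn from ``rng``, times the per-region modifiers from
    ``params.region_modifiers`` (supported keys: v_plc, tau_h, v_soce).
    """
    n = lattice.n_cells
    cv = params.hetero_cv
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        g_plc = np.exp(rng.normal(0.0, sigma, n))
        g_tau = np.exp(rng.normal(0.0, sigma, n))
    else:
        g_plc = np.ones(n)
        g_tau = np.ones(n)
    g_soce = np.ones(n)
    for region, mods in params.region_modifiers.items():
        idx = lattice.cells_in_region(region)
        g_plc[idx] *= mods.get("v_plc", 1.0)
        g_tau[idx] *= mods.get("tau_h", 1.0)
        g_soce[idx] *= mods.get("v_soce", 1.0)
    return g_plc, params.tau_h * g_tau, g_soce


def derivatives(
    state: CellState,
    params: ModelParams,
    lattice: TissueLattice,
    dose: float | None = None,
    *,
    W: sp.spmatrix | None = None,
    g_plc: np.ndarray | None = None,
    tau_h: np.ndarray | None = None,
    spike_input: np.ndarray | float = 0.0,
) -> CellState:
    """Per-cell state rates for a given tissue state.

    ``dose`` overrides ``params.dose`` when given.  Junctional weights
    default to ``coupling_graph(lattice, 1.0, fold_block=True)``; they are
    zeroed under ``params.gj_block`` (Carbenoxolone).
    """
    state.validate()
    pr = params if dose is None else params.replace(dose=float(dose))
    n = lattice.n_cells
    if W is None:
        W = coupling_graph(lattice, 1.0, fold_block=True)
    if pr.gj_block:
        W = None
        wsum = None
    else:
        wsum = np.asarray(W.sum(axis=1)).ravel()
    inv_area = 1.0 / lattice.areas
    if g_plc is None:
        g_plc = np.ones(n)
    if tau_h is None:
        tau_h = np.full(n, pr.tau_h)
    c = np.asarray(state.c, dtype=float)
    s = np.asarray(state.s, dtype=float)
    p = np.asarray(state.p, dtype=float)
    h = np.asarray(state.h, dtype=float)
    spike_in = np.asarray(spike_input, dtype=float) * pr.ca_ext
    dc, ds, dp, dh = _rhs(c, s, p, h, pr, W, wsum, inv_area, g_plc, tau_h, spike_in)
    rates = CellState(dc, ds, dp, dh)
    for name in ("c", "s", "p", "h"):
        if not np.all(np.isfinite(getattr(rates, name))):
            raise SimulationError(f"non-finite rate in {name!r}")
    return rates


# ---------------------------------------------------------------------- #
# Steady state
# ---------------------------------------------------------------------- #


def resting_state(params: ModelParams, dose: float = 0.0) -> CellState:
    """Single-cell fixed point at a given dose (scalar state).

    Found by relaxation integration followed by a Newton polish; at doses
    where the cell is oscillatory the relaxed state is returned as-is (the
    fixed point is unstable there and not a resting state).
    """
    from scipy.optimize import root

    pr = params.replace(dose=float(dose), lambda_spike=0.0)
    one = np.ones(1)
    y = np.array([0.05, 5.0, pr.v_plc * pr.dose / pr.k_deg, 0.9])

    def f(y):
        c, s, p, h = (np.array([max(v, 0.0)]) for v in y)
        dc, ds, dp, dh = _rhs(
            c, s, p, h, pr, None, None, one, one, one * pr.tau_h, 0.0
        )
        return np.array([dc[0], ds[0], dp[0], dh[0]])

    dt = 0.05
    for _ in range(int(4000 / dt)):
        y = np.maximum(y + dt * f(y), 1e-12)
    sol = root(f, y, method="hybr")
    if sol.success and np.all(sol.x >= -1e-9) and sol.x[3] <= 1 + 1e-9:
        y = np.maximum(sol.x, 0.0)
    return CellState(*(np.array([v]) for v in y))


# ---------------------------------------------------------------------- #
# Trajectory container
# ---------------------------------------------------------------------- #


@dataclass
class Trajectory:
    """Recorded per-cell state time series plus the spike-event log."""

    times: np.ndarray          # (T,) record times, s
    c: np.ndarray              # (T, N) float32
    s: np.ndarray
    p: np.ndarray
    h: np.ndarray
    events: list               # list of (cell_id, time_s) stochastic spikes
    seed: int

    def __post_init__(self):
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("record times must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return self.c.shape[1]

    def save(self, path) -> None:
        """Binary container (npz) holding all state arrays and the event log."""
        ev = np.array(
            [(int(c), float(t)) for c, t in self.events], dtype=float
        ).reshape(-1, 2)
        np.savez_compressed(
            path, times=self.times, c=self.c, s=self.s, p=self.p, h=self.h,
            events=ev, seed=np.array([self.seed]),
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        d = np.load(path)
        events = [(int(a), float(b)) for a, b in d["events"]]
        return cls(
            times=d["times"], c=d["c"], s=d["s"], p=d["p"], h=d["h"],
            events=events, seed=int(d["seed"][0]),
        )

    def events_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.events, columns=["cell_id", "time_s"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------- #
# Integration
# ---------------------------------------------------------------------- #


def _effective_params(base: ModelParams, flags: dict, dose: float) -> ModelParams:
    """Parameters under the currently active condition flags."""
    pr = base.replace(dose=dose)
    if flags.get("two_apb"):
        pr = pr.replace(v_ip3r=0.0, v_soce=0.0)
    if flags.get("thapsigargin"):
        pr = pr.replace(v_serca=0.0)
    if flags.get("bapta"):
        pr = pr.replace(ca_ext=0.0)
    if flags.get("carbenoxolone"):
        pr = pr.replace(gj_block=True)
    return pr


def simulate(
    lattice: TissueLattice,
    params: ModelParams,
    schedule: PharmacologySchedule,
    duration: float,
    dt: float = 0.02,
    record_interval: float = 1.0,
    seed: int = 0,
) -> Trajectory:
    """Integrate the tissue model with a fixed-step Heun (RK2) scheme.

    One global seed governs both the per-cell heterogeneity and the
    stochastic spike process, so identical inputs give identical output.
    States are kept non-negative by step rejection (an offending step is
    re-taken with 8 substeps); divergence aborts with a diagnostic naming
    the step size.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt <= 0 or record_interval <= 0:
        raise ValueError("dt and record_interval must be > 0")
    if not isinstance(schedule, PharmacologySchedule):
        schedule = PharmacologySchedule(schedule)

    n = lattice.n_cells
    ss = np.random.SeedSequence(seed)
    hetero_rng, spike_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    g_plc, tau_h_cell, g_soce = _per_cell_arrays(params, lattice, hetero_rng)

    W_full = coupling_graph(lattice, 1.0, fold_block=True)
    wsum_full = np.asarray(W_full.sum(axis=1)).ravel()
    inv_area = 1.0 / lattice.areas

    # initial state: the dose-0 resting fixed point of the median cell
    rest = resting_state(params, dose=0.0)
    c = np.full(n, float(rest.c[0]))
    s = np.full(n, float(rest.s[0]))
    p = np.full(n, float(rest.p[0]))
    h = np.full(n, float(rest.h[0]))

    # schedule bookkeeping
    flags: dict = {}
    dose = 0.0
    entries = list(schedule)
    next_entry = 0

    def switch_to(cond: dict):
        nonlocal dose
        if "extract_dose" in cond:
            dose = float(cond["extract_dose"])
        for key in ("two_apb", "bapta", "carbenoxolone"):
            if key in cond:
                flags[key] = bool(cond[key])
        if cond.get("thapsigargin"):
            flags["thapsigargin"] = True  # irreversible

    # apply all entries at t <= 0
    while next_entry < len(entries) and entries[next_entry][0] <= 0.0:
        switch_to(entries[next_entry][1])
        next_entry += 1
    pr = _effective_params(params, flags, dose)

    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(record_interval / dt)))
    rec_idx = range(0, n_steps + 1, rec_every)
    n_rec = len(rec_idx)
    times = np.array([k * dt for k in rec_idx])
    C = np.empty((n_rec, n), dtype=np.float32)
    S = np.empty_like(C)
    P = np.empty_like(C)
    H = np.empty_like(C)

    # stochastic spikes: homogeneous per-cell Poisson process drawn up front
    lam = params.lambda_spike
    if lam > 0:
        counts = spike_rng.poisson(lam * duration, n)
        ev_cells = np.repeat(np.arange(n), counts)
        ev_times = spike_rng.uniform(0.0, duration, counts.sum())
        order = np.argsort(ev_times, kind="stable")
        ev_times = ev_times[order]
        ev_cells = ev_cells[order].astype(np.int64)
    else:
        ev_times = np.empty(0)
        ev_cells = np.empty(0, dtype=np.int64)
    events = [(int(i), float(t)) for i, t in zip(ev_cells, ev_times)]
    spike_until = np.full(n, -1.0)

    # breakpoints: record steps plus schedule-switch steps
    switch_steps = sorted(
        {
            min(max(int(round(t_sw / dt)), 0), n_steps)
            for t_sw, _ in entries[next_entry:]
        }
    )
    breaks = sorted(set(range(0, n_steps + 1, rec_every)) | set(switch_steps))
    if breaks[-1] != n_steps:
        breaks.append(n_steps)

    indptr = W_full.indptr.astype(np.int64)
    indices = W_full.indices.astype(np.int64)
    w_data = W_full.data.astype(np.float64)
    zero_data = np.zeros_like(w_data)

    def seg_args(pr):
        data = zero_data if pr.gj_block else w_data
        plc_in = g_plc * pr.v_plc * pr.dose
        return data, plc_in

    data, plc_in = seg_args(pr)
    rec_ptr = 0
    ev_ptr = 0
    switch_iter = iter(switch_steps)
    pending_switch = next(switch_iter, None)

    for bi in range(len(breaks)):
        k = breaks[bi]
        t = k * dt
        # apply switches scheduled at this step
        if pending_switch is not None and k == pending_switch:
            while next_entry < len(entries) and (
                int(round(entries[next_entry][0] / dt)) <= k
            ):
                switch_to(entries[next_entry][1])
                next_entry += 1
            pr = _effective_params(params, flags, dose)
            data, plc_in = seg_args(pr)
            pending_switch = next(switch_iter, None)
        if k % rec_every == 0:
            C[rec_ptr] = c
            S[rec_ptr] = s
            P[rec_ptr] = p
            H[rec_ptr] = h
            rec_ptr += 1
        if bi == len(breaks) - 1:
            break
        seg_steps = breaks[bi + 1] - k
        status, ev_ptr = _core.run_segment(
            c, s, p, h, seg_steps, t, dt,
            indptr, indices, data, wsum_full, inv_area,
            pr.v_ip3r, pr.v_leak, pr.v_serca, pr.k_serca, pr.d1, pr.d5,
            pr.d2, plc_in, pr.k_deg, g_soce * pr.v_soce, pr.k_soce, pr.v_pm_out,
            pr.ca_ext, pr.d_c, pr.d_p, pr.beta, tau_h_cell,
            pr.j_spike, pr.spike_duration, spike_until,
            ev_times, ev_cells, ev_ptr,
        )
        if status == 1:
            raise SimulationError(
                f"state became negative near t={t:.3f} s even after step "
                f"rejection; dt={dt} exceeds the stability bound"
            )
        if status == 2:
            raise SimulationError(
                f"state divergence near t={t:.3f} s; dt={dt} is unstable"
            )

    return Trajectory(times=times, c=C, s=S, p=P, h=H, events=events, seed=seed)


def onset_experiment(
    lattice: TissueLattice,
    params: ModelParams,
    seed: int = 0,
    pbs_duration: float = 300.0,
    dose: float = 1.0,
    duration: float = 4800.0,
    dt: float = 0.02,
    record_interval: float = 2.0,
) -> Trajectory:
    """Oscillation-onset protocol: PBS (dose 0), then a step to 5% extract.

    Reproduces the three observed phases: an immediate uniform calcium rise
    in every cell, the appearance of interspersed fluctuating domains of
    high and low activity, and the eventual coarsening into few coordinated
    waves (quantified by a decreasing domain count).
    """
    schedule = PharmacologySchedule(
        [(0.0, {"extract_dose": 0.0}), (pbs_duration, {"extract_dose": dose})]
    )
    return simulate(
        lattice, params, schedule, duration=duration, dt=dt,
        record_interval=record_interval, seed=seed,
    )
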