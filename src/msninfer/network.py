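"""Random inhibitory MSN networks and their deterministic dynamics.

A network of N identical MSN cells is wired by directed inhibitory
collaterals: every ordered pair (i != j) is connected independently with
probability p (0.2 by convention, giving a binomial in-degree of mean
~N*p).  Two dimensionless levels parameterize a simulation: feedforward
excitation g_E sets the per-cell constant excitatory conductance,
G_ex ~ U[0.04381, 0.04381 + 0.002 g_E] (the base is approximately the
firing-threshold conductance, so every cell is driven above threshold),
and recurrent inhibition g_I sets the per-edge maximal synaptic
conductance, G_syn ~ U[0.001 g_I, 0.001 g_I + 0.001].  Synaptic gating
follows ds/dt = a H(V_pre)(1 - s) - B s with a = 2 and per-presynaptic
B ~ U[0.08, 0.09]; inhibitory current is G_syn s (V - V_Cl) with
V_Cl = -80 mV and excitation G_ex (V - V_cat) with V_cat = 0 mV.

Simulations are entirely deterministic given the realization and step: all
fluctuations are generated intrinsically by the recurrent inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import cell as _cell
from ._kernel import run_network
from .cell import DEFAULT_PARAMS, MSNCellParams

__all__ = [
    "NetworkConfig",
    "NetworkRealization",
    "SimulationResult",
    "IntegrationError",
    "ProbeError",
    "build_network",
    "scaled_screen_realization",
    "simulate",
    "gating_step",
    "inhibitory_current",
    "excitatory_current",
    "ipsp_probe",
    "rheobase_conductance",
]

GEX_BASE = 0.04381      # lower edge of the G_ex draw (~threshold conductance)
GEX_SCALE = 0.002       # G_ex range per unit g_E
GSYN_SCALE = 0.001      # G_syn lower edge per unit g_I; range width is 0.001
B_LO, B_HI = 0.08, 0.09
GATING_A = 2.0


class IntegrationError(RuntimeError):
    pass


class ProbeError(RuntimeError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Simulation settings.  Durations in seconds, dt in milliseconds."""

    n_cells: int = 2500
    p_connect: float = 0.2
    g_e: float = 50.0
    g_i: float = 33.0
    duration: float = 200.0
    dt: float = 0.05
    seed: int = 0
    transient: float = 2.0          # discarded settling time, s
    syn_update_ms: float = 0.5      # refresh interval of the synaptic gather
    lockout_ms: float = 2.0         # spike-detection refractory lockout
    cell_params: MSNCellParams = DEFAULT_PARAMS

    def __post_init__(self):
        if not (0.0 <= self.p_connect < 1.0):
            raise ValueError("p_connect must lie in [0, 1)")
        if self.g_e < 0 or self.g_i < 0:
            raise ValueError("g_e and g_i must be non-negative")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


@dataclass
class NetworkRealization:
    """One wiring + conductance draw.  CSR rows are postsynaptic cells."""

    indptr: np.ndarray          # (n_cells + 1,)
    indices: np.ndarray         # presynaptic cell of each edge
    g_syn: np.ndarray           # per-edge maximal synaptic conductance
    b_decay: np.ndarray         # per-presynaptic-cell gating decay rate
    g_ex: np.ndarray            # per-cell excitatory conductance
    seed: int
    g_e: float
    g_i: float

    @property
    def n_cells(self) -> int:
        return self.g_ex.size

    @property
    def n_edges(self) -> int:
        return self.indices.size

    def in_degrees(self) -> np.ndarray:
        return np.diff(self.indptr)


@dataclass
class SimulationResult:
    """Per-cell spike times (seconds, within [0, duration]) plus provenance."""

    spike_times: list[np.ndarray]
    config: NetworkConfig
    realization_seed: int
    voltage: np.ndarray | None = None
    voltage_stride_ms: float | None = None
    voltage_cells: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.config.duration

    def rates(self) -> np.ndarray:
        return np.array([t.size for t in self.spike_times]) / self.duration


def build_network(config: NetworkConfig) -> NetworkRealization:
    """Draw wiring and all random conductances for one (g_E, g_I, seed).

    The draw order is fixed so that two configs sharing a seed share the
    adjacency, the per-edge and per-cell uniform variates, and hence differ
    only through the g_E / g_I scaling of G_ex / G_syn; simulations at one
    g_I level but different g_E are identical except for excitation.
    """
    n = config.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(config.seed)
    indptr = np.zeros(n + 1, dtype=np.int64)
    rows = []
    for i in range(n):
        mask = rng.random(n) < config.p_connect
        mask[i] = False
        pre = np.nonzero(mask)[0]
        rows.append(pre)
        indptr[i + 1] = indptr[i] + pre.size
    indices = np.concatenate(rows) if rows else np.empty(0, np.int64)
    b_decay = rng.uniform(B_LO, B_HI, size=n)
    edge_u = rng.random(indices.size)
    cell_u = rng.random(n)
    g_syn = GSYN_SCALE * config.g_i + GSYN_SCALE * edge_u
    g_ex = GEX_BASE + GEX_SCALE * config.g_e * cell_u
    return NetworkRealization(
        indptr=indptr, indices=indices.astype(np.int64), g_syn=g_syn,
        b_decay=b_decay, g_ex=g_ex, seed=config.seed,
        g_e=config.g_e, g_i=config.g_i,
    )


def scaled_screen_realization(
    config: NetworkConfig, reference_in_degree: float = 500.0
) -> NetworkRealization:
    """Build a realization for the scaled-down screening protocol.

    Screening runs use far fewer cells than the reference network (2500
    cells, in-degree ~500).  Shrinking the in-degree K weakens the
    recurrent inhibitory input fluctuations, whose variance ~ K * G_syn^2
    controls the frozen-to-active transition; to keep the screen in the
    same dynamical regime as the reference, every synaptic conductance is
    multiplied by sqrt(reference_in_degree / K).  At full scale the factor
    is 1 and this reduces to :func:`build_network`.
    """
    rl = build_network(config)
    k_actual = config.p_connect * (config.n_cells - 1)
    if k_actual <= 0:
        raise ValueError("scaled screen needs a connected network")
    rl.g_syn = rl.g_syn * np.sqrt(reference_in_degree / k_actual)
    return rl


# cached initial state per (params, dt): all cells start at the isolated
# undriven resting state with closed synapses
_REST_CACHE: dict[tuple, tuple] = {}


def _initial_state(params: MSNCellParams, dt: float):
    key = (params, round(dt, 9))
    if key not in _REST_CACHE:
        _REST_CACHE[key] = _cell.resting_state(params, 0.0, dt=dt)
    return _REST_CACHE[key]


def _run(
    config: NetworkConfig,
    indptr, indices, g_syn, b_decay, g_ex,
    record_cells: np.ndarray | None = None,
    record_stride: int = 1,
    max_rate_hz: float = 250.0,
):
    params = config.cell_params
    dt = config.dt
    tab = _cell.gating_tables(params, dt)
    P = _cell.params_vector(params)
    n = g_ex.size
    total_ms = (config.transient + config.duration) * 1000.0
    n_steps = int(round(total_ms / dt))
    record_start = int(round(config.transient * 1000.0 / dt))
    s_dec0 = np.exp(-b_decay * dt)
    s_dec1 = np.exp(-(GATING_A + b_decay) * dt)
    s_inf = GATING_A / (GATING_A + b_decay)
    v0, h0, n0, b0, a0 = _initial_state(params, dt)
    max_spikes = int(n * config.duration * max_rate_hz) + 1024
    vrec_idx = (np.empty(0, np.int64) if record_cells is None
                else np.asarray(record_cells, np.int64))
    out = run_network(
        indptr, indices, g_syn, g_ex, s_dec0, s_dec1, s_inf,
        tab, _cell.V_GRID_MIN, 1.0 / _cell.V_GRID_STEP, P,
        dt, n_steps, max(int(round(config.syn_update_ms / dt)), 1),
        max(int(round(config.lockout_ms / dt)), 1), record_start,
        np.full(n, v0), np.full(n, h0), np.full(n, n0), np.full(n, b0),
        np.full(n, a0), np.zeros(n),
        max_spikes, vrec_idx, record_stride if vrec_idx.size else n_steps + 1,
    )
    status, nsp, sp_cell, sp_time, V, H, N, B, A, vrec = out
    if status > 0:
        raise IntegrationError(
            f"|V| exceeded 200 mV at step {status} (t = {status * dt:.3f} ms); "
            "reduce dt or check parameters"
        )
    if status == -2:
        raise IntegrationError("spike buffer overflow; raise max_rate_hz")
    sp_cell = sp_cell[:nsp]
    sp_time = sp_time[:nsp] / 1000.0 - config.transient
    spikes = [sp_time[sp_cell == i] for i in range(n)]
    return spikes, vrec


def simulate(realization: NetworkRealization, config: NetworkConfig,
             record_cells=None, record_stride: int = 1) -> SimulationResult:
    """Integrate the network; deterministic given (realization, dt).

    Spike times are upward 0-mV crossings after the settling transient,
    reported in seconds from the end of the transient.
    """
    if realization.n_cells != config.n_cells:
        raise ValueError("realization and config disagree on n_cells")
    spikes, vrec = _run(
        config, realization.indptr, realization.indices, realization.g_syn,
        realization.b_decay, realization.g_ex,
        record_cells=record_cells, record_stride=record_stride,
    )
    return SimulationResult(
        spike_times=spikes, config=config, realization_seed=realization.seed,
        voltage=vrec if record_cells is not None else None,
        voltage_stride_ms=config.dt * record_stride if record_cells is not None else None,
        voltage_cells=np.asarray(record_cells) if record_cells is not None else None,
    )


def gating_step(s: float, v_pre: float, b: float, dt: float, a: float = GATING_A) -> float:
    """One exact step of ds/dt = a H(V_pre)(1 - s) - B s; s stays in [0, 1].

    H(V_pre) is 1 while the presynaptic membrane overshoots 0 mV (a spike)
    and 0 otherwise.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("gating variable outside [0, 1]")
    if v_pre > 0.0:
        s_inf = a / (a + b)
        return s_inf + (s - s_inf) * np.exp(-(a + b) * dt)
    return s * np.exp(-b * dt)


def inhibitory_current(v_post: float, s: float, g_syn: float,
                       v_cl: float = DEFAULT_PARAMS.v_cl) -> float:
    """I_syn = G_syn s (V - V_Cl); positive (hyperpolarizing) above -80 mV."""
    return g_syn * s * (v_post - v_cl)


def excitatory_current(v_post: float, g_ex: float,
                       v_cat: float = DEFAULT_PARAMS.v_cat) -> float:
    """I_ex = G_ex (V - V_cat); negative (depolarizing) below 0 mV."""
    return g_ex * (v_post - v_cat)


_RHEO_CACHE: dict[tuple, float] = {}


def rheobase_conductance(
    params: MSNCellParams = DEFAULT_PARAMS,
    dt: float = 0.05,
    tol: float = 1e-5,
    t_probe: float = 10.0,
) -> float:
    """Threshold excitatory conductance of an isolated cell, by bisection.

    A level counts as suprathreshold when the cell still fires in the
    second half of a ``t_probe``-second window (sustained firing, not an
    onset transient while the slow gates settle).  Converges to ``tol`` in
    conductance.
    """
    key = (params, round(dt, 9), tol, t_probe)
    if key in _RHEO_CACHE:
        return _RHEO_CACHE[key]

    def fires(g: float) -> bool:
        cfg = NetworkConfig(
            n_cells=2, p_connect=0.0, g_e=0.0, g_i=0.0,
            duration=t_probe, dt=dt, transient=0.0, cell_params=params,
        )
        spikes, _ = _run(
            cfg, np.zeros(3, np.int64), np.empty(0, np.int64), np.empty(0),
            np.full(2, 0.085), np.array([g, 0.0]),
        )
        return bool(np.any(spikes[0] > 0.5 * t_probe))

    lo, hi = 0.02, 0.08
    for _ in range(6):
        if not fires(lo):
            break
        lo *= 0.5
    for _ in range(6):
        if fires(hi):
            break
        hi *= 1.6
    if fires(lo) or not fires(hi):
        raise RuntimeError("could not bracket the firing threshold")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    theta = 0.5 * (lo + hi)
    _RHEO_CACHE[key] = theta
    return theta


def ipsp_probe(
    g_i: float,
    params: MSNCellParams = DEFAULT_PARAMS,
    dt: float = 0.05,
    margin: float = 0.75,
    pre_factor: float = 1.005,
    settle: float = 6.0,
    max_wait: float = 30.0,
    window_ms: float = 400.0,
) -> tuple[float, float, float]:
    """Single-IPSP two-cell protocol: (amplitude mV, half-decay ms, area uV*s).

    The presynaptic cell is driven just above threshold (slow tonic firing,
    so successive IPSPs are well separated); the postsynaptic cell is held
    just below threshold at ``margin`` times the rheobase conductance.  The
    synapse carries the nominal conductance 0.001 g_I and the central
    gating decay B = 0.085.  From the postsynaptic trace around the first
    well-isolated presynaptic spike after settling: amplitude is the peak
    hyperpolarization below the pre-spike baseline, half-decay the time
    from the peak back to half the peak deflection, and area the time
    integral of the deflection (1 mV*ms = 1 uV*s).
    """
    if g_i < 0:
        raise ValueError("g_i must be non-negative")
    theta = rheobase_conductance(params, dt=dt)
    if g_i == 0.0:
        return 0.0, 0.0, 0.0       # nominal conductance 0.001*g_I vanishes
    g_ex = np.array([pre_factor * theta, margin * theta])
    indptr = np.array([0, 0, 1], np.int64)      # one edge, cell 0 -> cell 1
    indices = np.array([0], np.int64)
    g_syn = np.array([GSYN_SCALE * g_i])
    b = np.full(2, 0.085)
    cfg = NetworkConfig(n_cells=2, p_connect=0.0, g_e=0.0, g_i=g_i,
                        duration=max_wait, dt=dt, transient=0.0,
                        cell_params=params)
    spikes, vrec = _run(cfg, indptr, indices, g_syn, b, g_ex,
                        record_cells=np.array([1]), record_stride=1)
    if np.any(spikes[1] > settle):
        raise ProbeError("postsynaptic cell fired during the probe; lower margin")
    pre = spikes[0]
    if pre.size < 2 or pre[pre > settle].size == 0:
        raise ProbeError("presynaptic cell fired too rarely; raise pre_factor")
    # first post-settle spike preceded by a gap long enough for the previous
    # IPSP to have mostly decayed and followed by a clean measurement window
    gaps_ok = np.nonzero(
        (pre[1:] > settle)
        & (np.diff(pre) > 0.05)
        & (np.append(np.diff(pre)[1:], np.inf) > 0.04)
    )[0]
    if gaps_ok.size == 0:
        raise ProbeError("no isolated IPSP found; lower pre_factor")
    t0 = pre[gaps_ok[0] + 1]
    i0 = int(round(t0 * 1000.0 / dt))
    i1 = min(i0 + int(window_ms / dt), vrec.shape[1])
    nxt = pre[pre > t0]
    if nxt.size:
        i1 = min(i1, int(round(nxt[0] * 1000.0 / dt)))
    v = vrec[0, i0:i1]
    baseline = float(vrec[0, i0 - 1])
    defl = baseline - v
    amplitude = float(defl.max())
    if amplitude <= 0.0:
        return 0.0, 0.0, 0.0
    ipk = int(defl.argmax())
    after = defl[ipk:]
    below = np.nonzero(after <= amplitude / 2.0)[0]
    half_decay = float(below[0] * dt) if below.size else float(after.size * dt)
    area = float(np.trapezoid(np.clip(defl, 0.0, None), dx=dt))
    return amplitude, half_decay, area
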