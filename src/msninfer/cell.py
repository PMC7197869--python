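"""Reference single-compartment MSN cell model.

The network contract only requires a pluggable excitable cell with the
signature properties of a medium spiny neuron: a hyperpolarized resting
potential near the −90 mV leak reversal, quiescence below a threshold level
of constant excitatory conductance and tonic firing above it, a long first
spike latency near rheobase, and spikes that overshoot 0 mV (the synaptic
gating variable of a presynaptic cell opens while its membrane potential is
above 0).  This module provides the package's reference implementation: a
conductance-based model with fast Na+/K+ spike currents (Wang-Buzsaki
kinetics), an inward-rectifier K+ current that stabilizes the
hyperpolarized "down" state, and a slowly inactivating A-type K+ current
whose slow inactivation produces the characteristic delayed ramp to the
first spike.  All conductances are expressed per unit capacitance
(numerically mS/cm^2 with C = 1 uF/cm^2, i.e. units of 1/ms), voltages in
mV and time in ms.

Channel steady states and relaxation factors are tabulated on a voltage
grid once per (parameters, dt) and linearly interpolated inside the
integration kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MSNCellParams", "DEFAULT_PARAMS", "gating_tables", "params_vector",
           "resting_state", "V_GRID_MIN", "V_GRID_MAX", "V_GRID_STEP"]

V_GRID_MIN = -130.0
V_GRID_MAX = 60.0
V_GRID_STEP = 0.05


@dataclass(frozen=True)
class MSNCellParams:
    """Conductances (1/ms), reversals (mV) and kinetics of the cell model."""

    g_na: float = 35.0
    e_na: float = 55.0
    g_k: float = 9.0
    e_k: float = -90.0
    #: inward rectifier: active below ~-90 mV, deactivates on depolarization
    g_kir: float = 0.25
    kir_half: float = -102.0
    kir_slope: float = 13.0
    #: slowly inactivating A-type K+: subthreshold activation, slow inactivation
    g_kas: float = 0.1968
    kas_act_half: float = -58.0
    kas_act_slope: float = 4.0
    tau_a: float = 180.0
    kas_inact_half: float = -55.0
    kas_inact_slope: float = 8.0
    tau_b: float = 1000.0
    #: leak with the hyperpolarized (modified) reversal
    g_l: float = 0.035
    e_l: float = -90.0
    #: temperature factor of the spike-current kinetics
    phi: float = 3.5
    #: synaptic reversals: chloride (inhibition) and cation (excitation)
    v_cl: float = -80.0
    v_cat: float = 0.0


DEFAULT_PARAMS = MSNCellParams()


def _sigmoid(v, half, slope):
    return 1.0 / (1.0 + np.exp((v - half) / slope))


def _spike_current_rates(v: np.ndarray):
    # Wang-Buzsaki Na/K kinetics (instantaneous m; first-order h, n)
    vm = v + 35.0
    am = np.where(np.abs(vm) < 1e-7, 1.0, 0.1 * vm / (1.0 - np.exp(-vm / 10.0)))
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-0.1 * (v + 28.0)))
    vn = v + 34.0
    an = np.where(np.abs(vn) < 1e-7, 0.1, 0.01 * vn / (1.0 - np.exp(-vn / 10.0)))
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


def gating_tables(params: MSNCellParams, dt: float) -> np.ndarray:
    """Voltage-grid tables for the integration kernel.

    Rows: m_inf, kir_inf, h_inf, h_decay, n_inf, n_decay, b_inf, b_decay,
    a_inf, a_decay, where *_decay = exp(-dt / tau) is the per-step
    exponential-Euler relaxation factor of the gate at that voltage.  The
    Kir gate and the Na activation m are instantaneous; the A-current
    activation a and inactivation b are first-order with fixed time
    constants (a is slow enough that it tracks the mean depolarization but
    not individual synaptic transients).
    """
    v = np.arange(V_GRID_MIN, V_GRID_MAX + V_GRID_STEP / 2, V_GRID_STEP)
    am, bm, ah, bh, an, bn = _spike_current_rates(v)
    tab = np.empty((10, v.size))
    tab[0] = am / (am + bm)
    tab[1] = _sigmoid(v, params.kir_half, params.kir_slope)
    tab[2] = ah / (ah + bh)
    tab[3] = np.exp(-dt * params.phi * (ah + bh))
    tab[4] = an / (an + bn)
    tab[5] = np.exp(-dt * params.phi * (an + bn))
    tab[6] = _sigmoid(v, params.kas_inact_half, params.kas_inact_slope)
    tab[7] = np.full(v.size, np.exp(-dt / params.tau_b))
    tab[8] = 1.0 - _sigmoid(v, params.kas_act_half, params.kas_act_slope)
    tab[9] = np.full(v.size, np.exp(-dt / params.tau_a))
    return np.ascontiguousarray(tab)


def params_vector(params: MSNCellParams) -> np.ndarray:
    """Scalar parameter vector consumed by the kernel."""
    return np.array([
        params.g_na, params.e_na, params.g_k, params.e_k,
        params.g_kir, params.g_kas, params.g_l, params.e_l,
        params.v_cl, params.v_cat,
    ])


def resting_state(
    params: MSNCellParams = DEFAULT_PARAMS,
    g_ex: float = 0.0,
    dt: float = 0.05,
    settle_ms: float = 2000.0,
) -> tuple[float, float, float, float, float]:
    """Relaxed (V, h, n, b, a) of an isolated cell under constant excitation.

    Used both for the quiescence contract and as the common initial
    condition of network simulations (every cell starts at the undriven
    resting state with closed synapses).
    """
    from ._kernel import run_network

    tab = gating_tables(params, dt)
    P = params_vector(params)
    n_steps = int(round(settle_ms / dt))
    indptr = np.zeros(2, np.int64)
    out = run_network(
        indptr, np.empty(0, np.int64), np.empty(0),
        np.array([g_ex]),
        np.array([1.0]), np.array([1.0]), np.array([0.0]),
        tab, V_GRID_MIN, 1.0 / V_GRID_STEP, P,
        dt, n_steps, 1_000_000_000, int(round(2.0 / dt)), n_steps + 1,
        np.array([params.e_l]), np.array([1.0]), np.array([0.0]), np.array([1.0]),
        np.array([0.0]), np.array([0.0]),
        16, np.empty(0, np.int64), 1_000_000_000,
    )
    status, _, _, _, V, H, N, B, A, _ = out
    if status != 0:
        raise RuntimeError("resting-state relaxation diverged")
    return float(V[0]), float(H[0]), float(N[0]), float(B[0]), float(A[0])
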