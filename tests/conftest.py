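"""Shared fixtures: the scaled network screening runs.

Network-level checks use a scaled-down screening protocol instead of the
reference 2500-cell, 200-s simulations (which take hours of CPU): 300
cells with the in-degree held at ~100 by raising the connection
probability, synaptic conductances compensated by sqrt(500/100) to
preserve the variance of the recurrent input (see
``msninfer.network.scaled_screen_realization``), 60-80 s of simulated
time at dt = 0.1 ms.  The screening grid spans the frozen regime, the
transition and the active regime at three excitation levels.  All runs
are deterministic given their fixed seeds; they are session-scoped
because each costs tens of seconds of CPU.
"""

import numpy as np
import pandas as pd
import pytest

from msninfer.features import (
    FEATURE_NAMES,
    ISIFeatureExtractor,
    isi_moments,
    ks_distances,
    ml_lognormal,
    DegenerateTrainError,
)
from msninfer.network import NetworkConfig, scaled_screen_realization, simulate
from msninfer.population import active_cell_counts, rate_correlation_entropy
from msninfer.segments import SpikeTrain, library_split_halves

SCREEN_N = 300
SCREEN_K = 100
SCREEN_DT = 0.1
GRID_GE = (25.0, 50.0, 75.0)
GRID_GI = (3.0, 9.0, 15.0, 21.0, 29.0)
GRID_T = 60.0


def screen_run(g_e, g_i, seed, duration):
    cfg = NetworkConfig(
        n_cells=SCREEN_N, p_connect=SCREEN_K / (SCREEN_N - 1),
        g_e=g_e, g_i=g_i, duration=duration, dt=SCREEN_DT, seed=seed,
    )
    return simulate(scaled_screen_realization(cfg), cfg)


def single_unit_stats(result, with_ks=False):
    """Population means of the per-cell single-unit statistics."""
    rates, cvs, slns = [], [], []
    ks = {"ks_e": [], "ks_gamma": [], "ks_ln": [], "ks_ig": []}
    for t in result.spike_times:
        if t.size < 11:
            continue
        isis = np.diff(t)
        try:
            _, cv, _, _ = isi_moments(isis, t_seg=result.duration)
        except DegenerateTrainError:
            cv = 0.0
        rates.append(t.size / result.duration)
        cvs.append(cv)
        slns.append(ml_lognormal(isis)[1])
        if with_ks:
            try:
                for k, v in ks_distances(isis, t_seg=result.duration).items():
                    ks[k].append(v)
            except DegenerateTrainError:
                pass
    n_any, n_stats = active_cell_counts(result.spike_times)
    out = {
        "act": n_any, "n11": n_stats,
        "rate": float(np.mean(rates)), "cv": float(np.mean(cvs)),
        "sigma_ln": float(np.mean(slns)),
    }
    if with_ks:
        out.update({k: float(np.mean(v)) for k, v in ks.items() if v})
    return out


@pytest.fixture(scope="session")
def screen_grid():
    """Simulations of the screening grid, keyed by (g_E, g_I)."""
    out = {}
    for gi_idx, g_i in enumerate(GRID_GI):
        seed = 8000 + 1000 * gi_idx      # one master seed per g_I level
        for g_e in GRID_GE:
            out[(g_e, g_i)] = screen_run(g_e, g_i, seed, GRID_T)
    return out


@pytest.fixture(scope="session")
def grid_stats(screen_grid):
    """Per-grid-point population statistics plus rate-correlation entropy."""
    rows = []
    for (g_e, g_i), res in screen_grid.items():
        row = {"g_e": g_e, "g_i": g_i}
        row.update(single_unit_stats(res))
        row["entropy"] = rate_correlation_entropy(
            res.spike_times, res.duration).entropy
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["g_e", "g_i"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def half_split_features(screen_grid):
    """First/second-half feature matrices of every grid simulation."""
    halves = {}
    for key, res in screen_grid.items():
        trains = [SpikeTrain(t, res.duration, i)
                  for i, t in enumerate(res.spike_times)]
        first, second = library_split_halves(trains)
        ext = ISIFeatureExtractor(t_seg=res.duration / 2)
        fa = ext.fit(first).transform([s for s in first if s.n_spikes >= 11])
        fb = ext.transform([s for s in second if s.n_spikes >= 11])
        halves[key] = (fa[list(FEATURE_NAMES)].to_numpy(),
                       fb[list(FEATURE_NAMES)].to_numpy())
    return halves


@pytest.fixture(scope="session")
def wt_hd_screen():
    """Best-fit-parameter screening runs: WT (50, 33) vs HD (40, 41).

    Two seeds per point, 80 s each; returns the seed-averaged statistics.
    """
    out = {}
    for tag, g_e, g_i in (("wt", 50.0, 33.0), ("hd", 40.0, 41.0)):
        stats = [single_unit_stats(screen_run(g_e, g_i, seed * 101, 80.0),
                                   with_ks=True)
                 for seed in (21, 22)]
        out[tag] = {k: float(np.mean([s[k] for s in stats]))
                    for k in stats[0]}
    return out
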