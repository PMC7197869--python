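"""End-to-end workflow: parameter sweep -> feature library -> KL fit.

A sweep materializes one directory per (g_E, g_I) grid point containing the
spike TSV, the per-cell feature CSV and a manifest (config hash, counts).
One master seed is assigned per g_I level and shared across all g_E at that
level, so simulations at a given inhibition level differ only in their
excitation draws.  Fits read the feature CSVs back as a
:class:`~msninfer.klfit.ModelLibrary`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .features import FEATURE_NAMES, ISIFeatureExtractor
from .klfit import KLParameterEstimator, ModelLibrary, fit_dataset
from .network import NetworkConfig, SimulationResult, build_network, simulate
from .segments import SpikeTrainSegment

__all__ = [
    "RunConfig", "result_features", "run_sweep", "load_library", "run_fit",
]

#: default g_I lattice (step 4 covering the quoted working range)
DEFAULT_GI = tuple(range(5, 66, 4))
#: default g_E levels (unequally spaced, denser at low excitation)
DEFAULT_GE = (15.0, 25.0, 32.0, 40.0, 50.0, 62.0, 75.0, 90.0, 110.0)


@dataclass
class RunConfig:
    """Settings of a sweep + fit workflow.  All seeds are explicit."""

    g_e_list: tuple = DEFAULT_GE
    g_i_list: tuple = DEFAULT_GI
    n_cells: int = 2500
    p_connect: float = 0.2
    duration: float = 200.0
    dt: float = 0.05
    network_seed: int = 0
    subset_seed: int = 0
    n_feat: int = 7
    n_subsets: int = 30
    beta: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d = {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d))

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def result_features(result: SimulationResult) -> pd.DataFrame:
    """Per-active-cell feature table of one simulation (model mode).

    Every cell's full-duration train with more than 10 spikes becomes one
    observation; sparser cells are dropped.
    """
    segs = [
        SpikeTrainSegment(spike_times=t, t_seg=result.duration,
                          group="model", source=f"c{i}")
        for i, t in enumerate(result.spike_times) if t.size >= 11
    ]
    return ISIFeatureExtractor(t_seg=result.duration).fit(segs).transform(segs)


def _point_dir(root: Path, g_e: float, g_i: float) -> Path:
    return root / f"gE{g_e:g}_gI{g_i:g}"


def run_sweep(config: RunConfig, out_dir, progress: bool = False) -> dict:
    """Simulate every grid point and write the model library to disk.

    Resumable: a grid point whose manifest matches the config hash is
    skipped.  Returns the sweep manifest.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    entries = []
    for gi_idx, g_i in enumerate(config.g_i_list):
        seed = config.network_seed + 1000 * gi_idx   # one master seed per g_I
        for g_e in config.g_e_list:
            pdir = _point_dir(root, g_e, g_i)
            man = pdir / "manifest.json"
            if man.exists() and json.loads(man.read_text()).get("config_hash") == chash:
                entries.append(json.loads(man.read_text()))
                continue
            cfg = NetworkConfig(
                n_cells=config.n_cells, p_connect=config.p_connect,
                g_e=g_e, g_i=g_i, duration=config.duration,
                dt=config.dt, seed=seed,
            )
            rl = build_network(cfg)
            res = simulate(rl, cfg)
            feats = result_features(res)
            pdir.mkdir(parents=True, exist_ok=True)
            _io.write_result(pdir / "spikes.tsv", res, rl)
            feats.to_csv(pdir / "features.csv", index=False)
            entry = {
                "g_e": g_e, "g_i": g_i, "seed": seed,
                "n_observations": int(len(feats)),
                "realization_hash": _io.realization_hash(rl),
                "config_hash": chash,
            }
            man.write_text(json.dumps(entry, indent=1))
            entries.append(entry)
            if progress:
                print(f"gE={g_e} gI={g_i}: {len(feats)} observations")
    manifest = {"config_hash": chash, "n_points": len(entries), "entries": entries}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_library(library_dir) -> ModelLibrary:
    """Assemble a :class:`ModelLibrary` from a sweep directory."""
    root = Path(library_dir)
    points = {}
    for man in sorted(root.glob("*/manifest.json")):
        entry = json.loads(man.read_text())
        feats = pd.read_csv(man.parent / "features.csv")
        points[(entry["g_e"], entry["g_i"])] = feats[list(FEATURE_NAMES)].to_numpy()
    if not points:
        raise FileNotFoundError(f"no library entries under {root}")
    return ModelLibrary.from_dict(points)


def run_fit(features: pd.DataFrame, library_dir, out_dir,
            n_feat: int = 7, n_subsets: int = 30, beta: float = 3.0,
            seed: int = 0) -> dict:
    """Fit a feature dataset against a library on disk; write estimate,
    heat map and a short human-readable report."""
    library = load_library(library_dir)
    est, grid = fit_dataset(features, library, n_feat=n_feat,
                            n_subsets=n_subsets, beta=beta, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = {
        "g_e": est.g_e, "g_i": est.g_i,
        "g_e_se": est.g_e_se, "g_i_se": est.g_i_se,
        "n_observations": int(len(features)),
        "n_feat": n_feat, "n_subsets": n_subsets, "beta": beta, "seed": seed,
    }
    (out / "estimate.json").write_text(json.dumps(result, indent=1))
    grid.to_csv(out / "kl_grid.csv", index=False)
    (out / "report.txt").write_text(
        f"dataset: {len(features)} segments\n"
        f"library: {len(library.features)} grid points "
        f"(g_E {library.g_e_levels.tolist()}, g_I {library.g_i_levels.tolist()})\n"
        f"estimate: gE* = {est.g_e:.2f} +- {est.g_e_se:.2f}, "
        f"gI* = {est.g_i:.2f} +- {est.g_i_se:.2f}\n"
    )
    return result
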