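"""End-to-end pipeline driver: generate -> simulate -> observe -> compare
-> metrics, with a manifest tying every output file to the configuration
and seeds that produced it."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io import (file_digest, write_profile_csv, write_summary_csv,
                 write_tracks_csv, write_traces_csv)
from .params import (LayerSpec, SamplingScheme, SimConfig, VelocityModelParams,
                     asdict_flat)
from .paths import summarize_path
from .rng import stage_rng, stage_seed_sequence
from .sampling import observe, one_way_anova, rmse, scale_rmse
from .dispersal import layer_encounter, sd_growth_slope, sd_over_time
from .sim import run
from .synth import generate_library

log = logging.getLogger("planktonwalk")

STAGES = ("generate", "simulate", "observe", "compare", "metrics")


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    seed: int
    version: str
    config: dict
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)     # filename -> sha256
    stages: list = field(default_factory=list)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record(self, stage: str, files: dict) -> None:
        if stage not in self.stages:
            self.stages.append(stage)
        self.outputs.update({str(k): file_digest(v) for k, v in files.items()})

    def write(self, path) -> None:
        self.finished = time.time()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Execute all five stages, writing CSV artifacts and a manifest.

    ``config`` is the mapping returned by :func:`planktonwalk.io.load_config`;
    re-running with the same config and seed reproduces identical digests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen: VelocityModelParams = config.get("generator", VelocityModelParams())
    simc: SimConfig = config["simulation"]
    scheme: SamplingScheme = config.get("sampling", SamplingScheme())
    layer: LayerSpec | None = config.get("layer")
    seed = int(seed if seed is not None else config.get("seed", 0))
    n_paths = int(config.get("n_paths", 1032))
    taus = [float(t) for t in config.get("taus", [simc.tau])]

    manifest = RunManifest(seed=seed, version=__version__,
                           config={k: asdict_flat(v) if dataclasses.is_dataclass(v) else v
                                   for k, v in config.items()})
    manifest.stage_seeds = {
        "library": str(stage_seed_sequence(seed, "library")),
        "sim": str(stage_seed_sequence(seed, "sim")),
        "sampling": str(stage_seed_sequence(seed, "sampling")),
    }

    stage = "generate"
    try:
        log.info("stage generate: %d paths, seed %d", n_paths, seed)
        library = generate_library(gen, n_paths, stage_rng(seed, "library"))
        tracks = out / "tracks.csv"
        write_tracks_csv(library, tracks)
        summary = out / "path_summary.csv"
        write_summary_csv([summarize_path(p) for p in library.paths], summary)
        manifest.record(stage, {"tracks.csv": tracks, "path_summary.csv": summary})

        stage = "simulate"
        traces_by_tau = {}
        for tau in taus:
            cfg = dataclasses.replace(simc, tau=tau, seed=seed)
            log.info("stage simulate: tau=%g s, %d agents x %d replicates",
                     tau, cfg.n_agents, cfg.n_replicates)
            traces = run(cfg, library)
            traces_by_tau[tau] = traces
            f = out / f"trace_tau{tau:g}.csv"
            write_traces_csv(traces, f)
            manifest.record(stage, {f.name: f})

        stage = "observe"
        profiles = {}
        for tau, traces in traces_by_tau.items():
            profs = [observe(tr, scheme,
                             rng=stage_rng(seed, "sampling", tr.replicate_id))
                     for tr in traces]
            profiles[tau] = profs
            f = out / f"profile_tau{tau:g}.csv"
            write_profile_csv(profs[0], f)
            manifest.record(stage, {f.name: f})

        stage = "compare"
        observed_tau = max(taus)
        observed = profiles[observed_tau][0]
        raw = {tau: [rmse(p, observed) for p in profs]
               for tau, profs in profiles.items()}
        scaled = scale_rmse(raw)
        import pandas as pd
        cmp_df = pd.DataFrame({
            "tau_s": list(raw),
            "rmse_mean": [float(np.mean(v)) for v in raw.values()],
            "rmse_sd": [float(np.std(v, ddof=0)) for v in raw.values()],
            "scaled_rmse_mean": [float(np.mean(scaled[t])) for t in raw],
        })
        f = out / "rmse_by_tau.csv"
        cmp_df.to_csv(f, index=False, float_format="%.12g")
        files = {f.name: f}
        if len(taus) >= 2 and all(len(v) >= 2 for v in raw.values()):
            res = one_way_anova({f"tau={t:g}": v for t, v in raw.items()})
            fa = out / "rmse_anova.json"
            fa.write_text(json.dumps({
                "F": res.f_statistic, "p": res.p_value,
                "bonferroni_alpha": res.bonferroni_alpha,
                "significant_pairs": {f"{a} vs {b}": sig for (a, b), sig
                                      in res.significant_pairs.items()},
            }, indent=2) + "\n")
            files[fa.name] = fa
        manifest.record(stage, files)

        stage = "metrics"
        metrics = {}
        for tau, traces in traces_by_tau.items():
            series = sd_over_time(traces)
            entry = {
                "sd_final_cm": float(series.mean_sd[-1]),
                "sd_slope_mm_min": sd_growth_slope(series, window="growth"),
            }
            if layer is not None and simc.column_height_cm is not None \
                    and layer.top_m * 100 <= simc.column_height_cm:
                enc = layer_encounter(traces, layer)
                entry["layer_arrival_h"] = enc.arrival_time_s / 3600.0
                entry["layer_residence_h"] = enc.residence_s / 3600.0
            metrics[f"tau={tau:g}"] = entry
        f = out / "dispersal_metrics.json"
        f.write_text(json.dumps(metrics, indent=2) + "\n")
        manifest.record(stage, {f.name: f})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
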