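"""End-to-end synthetic-recording analysis pipeline.

Chains simulation -> detection -> highest-activity windowing -> ECDF/density
summaries -> bootstrap-subsampled KS decisions (amplitude and interevent
interval) -> peak-aligned averaging and biexponential decay fits -> summary
statistics, for a two-group (control vs treated) comparison, and writes
every artifact with a manifest carrying the package version, the
configuration hash and the per-stage seeds.  A single global seed
deterministically spawns independent per-stage substreams (keyed by stage
name), so any stage can be rerun in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .events import DetectionConfig, average_events, detect_events, \
    select_highest_activity_window
from .io import write_event_table
from .kinetics import fit_biexponential
from .resample import BootstrapKSConfig, bootstrap_ks, ecdf, kde_density
from .summary_stats import GroupSummary, ttest_from_summary
from .trace_sim import SimConfig, simulate_spsc_trace

__all__ = ["PipelineConfig", "run_ephys_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for the two-group synthetic analysis."""

    control: SimConfig = field(default_factory=SimConfig)
    treated: SimConfig = field(default_factory=SimConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    bootstrap: BootstrapKSConfig = field(default_factory=BootstrapKSConfig)
    window_s: float = 60.0
    avg_pre_ms: float = 5.0
    avg_post_ms: float = 80.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kw: dict[str, Any] = {}
        for key, sub_cls in (("control", SimConfig), ("treated", SimConfig),
                             ("detection", DetectionConfig),
                             ("bootstrap", BootstrapKSConfig)):
            if key in d:
                kw[key] = sub_cls(**d[key])
        for key in ("window_s", "avg_pre_ms", "avg_post_ms", "seed"):
            if key in d:
                kw[key] = d[key]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def _stamp(config: PipelineConfig, seed: int) -> dict:
    return {"version": __version__, "config_hash": config.digest(), "seed": seed}


def run_ephys_pipeline(
    config: PipelineConfig, outdir: str | Path, write_traces: bool = False
) -> dict[str, Any]:
    """Run the full two-group analysis; returns the in-memory results.

    Artifacts written to ``outdir``: per-group event tables (full record and
    highest-activity window), ECDF and density tables for amplitude and
    interevent interval, bootstrap-KS result JSONs, decay-fit JSONs, a
    summary-statistics JSON (per-group amplitude/IEI summaries plus the
    two-group t-tests), and ``manifest.json`` listing every artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    results: dict[str, Any] = {}

    pooled: dict[str, dict[str, np.ndarray]] = {}
    for group in ("control", "treated"):
        sim_cfg: SimConfig = getattr(config, group)
        sim_cfg = dataclasses.replace(
            sim_cfg, seed=stage_seed(config.seed, f"sim:{group}")
        )
        trace, truth = simulate_spsc_trace(sim_cfg)
        if write_traces:
            from .io import write_trace

            write_trace(outdir / f"trace_{group}.csv", trace)
            artifacts.append(f"trace_{group}.csv")

        events = detect_events(trace, config.detection)
        write_event_table(outdir / f"events_{group}.tsv", events)
        artifacts.append(f"events_{group}.tsv")

        win_events, win_start = select_highest_activity_window(
            events, trace.duration_s, min(config.window_s, trace.duration_s)
        )
        write_event_table(outdir / f"window_events_{group}.tsv", win_events)
        artifacts.append(f"window_events_{group}.tsv")

        amps = win_events.amplitude_pa
        ieis = win_events.iei_s
        pooled[group] = {"amplitude": amps, "iei": ieis}

        for name, vals in (("amplitude", amps), ("iei", ieis)):
            if vals.size:
                e = ecdf(vals)
                np.savetxt(
                    outdir / f"ecdf_{name}_{group}.tsv",
                    np.column_stack([e.support, e.probs]),
                    delimiter="\t", header=f"{name}\tcum_prob", comments="",
                )
                artifacts.append(f"ecdf_{name}_{group}.tsv")
            if vals.size >= 2 and np.ptp(vals) > 0:
                d = kde_density(vals, log_transform=(name == "iei"))
                np.savetxt(
                    outdir / f"density_{name}_{group}.tsv",
                    np.column_stack([d.grid, d.density]),
                    delimiter="\t", header=f"{name}\tdensity", comments="",
                )
                artifacts.append(f"density_{name}_{group}.tsv")

        avg = average_events(trace, win_events, config.avg_pre_ms,
                             config.avg_post_ms)
        fit = fit_biexponential(avg.waveform - np.median(trace.samples),
                                trace.fs_hz)
        fit_d = dataclasses.asdict(fit)
        _write_json(outdir / f"decay_{group}.json",
                    {**fit_d, **_stamp(config, sim_cfg.seed)})
        artifacts.append(f"decay_{group}.json")

        results[group] = {
            "n_events": len(events),
            "window_start_s": win_start,
            "n_window_events": len(win_events),
            "decay_fit": fit,
            "ground_truth_n": len(truth),
        }

    for name in ("amplitude", "iei"):
        ks_cfg = dataclasses.replace(
            config.bootstrap, seed=stage_seed(config.seed, f"ks:{name}")
        )
        res = bootstrap_ks(pooled["control"][name], pooled["treated"][name],
                           ks_cfg)
        _write_json(
            outdir / f"ks_{name}.json",
            {
                "fraction_significant": res.fraction_significant,
                "percent_significant": res.percent_significant,
                "decision": bool(res.decision),
                "config": dataclasses.asdict(ks_cfg),
                **_stamp(config, ks_cfg.seed),
            },
        )
        np.savetxt(outdir / f"ks_{name}_pvalues.tsv", res.pvalues,
                   header="pvalue", comments="")
        artifacts += [f"ks_{name}.json", f"ks_{name}_pvalues.tsv"]
        results[f"ks_{name}"] = res

    summaries = {}
    for name in ("amplitude", "iei"):
        groups = {}
        for group in ("control", "treated"):
            v = pooled[group][name]
            groups[group] = GroupSummary(
                mean=float(v.mean()), sem=float(v.std(ddof=1) / np.sqrt(v.size)),
                n=int(v.size), label=f"{group}:{name}",
            )
        t, df, p = ttest_from_summary(groups["control"], groups["treated"],
                                      variant="welch")
        summaries[name] = {
            "control": dataclasses.asdict(groups["control"]),
            "treated": dataclasses.asdict(groups["treated"]),
            "welch_t": t, "df": df, "p": p,
        }
        results[f"summary_{name}"] = summaries[name]
    _write_json(outdir / "summary_stats.json",
                {**summaries, **_stamp(config, config.seed)})
    artifacts.append("summary_stats.json")

    manifest = {
        **_stamp(config, config.seed),
        "artifacts": sorted(artifacts),
        "config": config.to_dict(),
    }
    _write_json(outdir / "manifest.json", manifest)
    results["manifest"] = manifest
    return results
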