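"""End-to-end orchestration: simulate -> features -> decode -> stats/pod/erp.

``run_pipeline`` executes the selected analyses for a synthetic multi-
participant dataset and writes CSV/JSON results plus a manifest recording
every seed and parameter in effect, so that identical configs yield
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import DecodingTimecourse
from .decoding import DecoderConfig, decode_timecourse, shuffled_decode
from .design import generate_design, make_pseudo_pings
from .erp import ping_contrast
from .features import WindowSpec, baseline_correct, gaussian_moving_average, \
    zscore_across_channels
from .pod import SOA_ORDER, pod_test
from .simulate import SimulationConfig, simulate_epochs
from .stats import ANALYSIS_WINDOWS_MS, StatConfig, two_level_permutation, \
    wilcoxon_contrast

__all__ = ["RunConfig", "run_pipeline", "participant_seeds", "simulate_participant"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    seed: int = 0
    out_dir: str = "results"
    lock: str = "cue"
    analyses: tuple[str, ...] = ("decode", "stats", "pod", "erp")
    n_blocks: int = 8
    n_pairs_per_block: int = 10
    n_reps: int = 4
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    stat: StatConfig = field(default_factory=StatConfig)
    pod_n_second_level: int = 1_000_000
    pod_detector: str = "cumsum_derivative"
    label_col: str = "label_top"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["analyses"] = list(self.analyses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        if "window" in d and isinstance(d["window"], dict):
            d["window"] = WindowSpec(**d["window"])
        if "decoder" in d and isinstance(d["decoder"], dict):
            d["decoder"] = DecoderConfig(**d["decoder"])
        if "stat" in d and isinstance(d["stat"], dict):
            s = dict(d["stat"])
            if s.get("analysis_window_ms") is not None:
                s["analysis_window_ms"] = tuple(s["analysis_window_ms"])
            d["stat"] = StatConfig(**s)
        if "analyses" in d:
            d["analyses"] = tuple(d["analyses"])
        return cls(**d)


def participant_seeds(master_seed: int, n: int) -> list[int]:
    """Derive independent per-participant seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % 2 ** 31) for child in ss.spawn(n)]


def simulate_participant(cfg: RunConfig, seed: int, lock: str | None = None):
    """Design + pseudo-pings + simulated epochs for one participant."""
    lock = lock or cfg.lock
    design = generate_design(cfg.n_blocks, cfg.n_pairs_per_block, cfg.n_reps,
                             seed=seed)
    design = make_pseudo_pings(design, seed=seed + 1)
    sim = dataclasses.replace(cfg.sim, seed=seed)
    return design, simulate_epochs(design, sim, lock=lock)


def _features(cfg: RunConfig, epochs):
    fs = gaussian_moving_average(baseline_correct(epochs), cfg.window)
    return zscore_across_channels(fs)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured analyses; return the result bundle.

    Writes per-analysis CSV/JSON files under ``cfg.out_dir`` plus
    ``manifest.json``. Raises with the failing stage named.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = participant_seeds(cfg.seed, cfg.sim.n_participants)
    bundle: dict = {"seeds": seeds}
    stage = "simulate"
    try:
        participants = []
        for s in seeds:
            design, epochs = simulate_participant(cfg, s)
            participants.append((design, epochs))

        stage = "features"
        feats = [(_features(cfg, ep), ep.metadata) for _, ep in participants]

        if "decode" in cfg.analyses or "stats" in cfg.analyses or "pod" in cfg.analyses:
            stage = "decode"
            emp_ping, shuf_ping, emp_noping = [], [], []
            pod_emp, pod_shuf = [], []
            window_times = None
            for (fs, meta), s in zip(feats, seeds):
                dcfg = dataclasses.replace(cfg.decoder, seed=s)
                is_ping = (meta["condition"] != "none").to_numpy()
                fs_ping = _subset(fs, meta, is_ping)
                fs_noping = _subset(fs, meta, ~is_ping)
                labels = meta[cfg.label_col].to_numpy()
                tc_ping = decode_timecourse(fs_ping, labels[is_ping], dcfg)
                sh_ping = shuffled_decode(fs_ping, labels[is_ping], dcfg)
                tc_noping = decode_timecourse(fs_noping, labels[~is_ping], dcfg)
                emp_ping.append(tc_ping.empirical)
                shuf_ping.append(sh_ping)
                emp_noping.append(tc_noping.empirical)
                window_times = tc_ping.window_times
                if "pod" in cfg.analyses:
                    emp_d, shuf_d = {}, {}
                    for cond in SOA_ORDER:
                        m = (meta["condition"] == cond).to_numpy()
                        fs_c = _subset(fs, meta, m)
                        emp_d[cond] = decode_timecourse(fs_c, labels[m], dcfg).empirical
                        shuf_d[cond] = shuffled_decode(fs_c, labels[m], dcfg)
                    pod_emp.append(emp_d)
                    pod_shuf.append(shuf_d)
            group = DecodingTimecourse(window_times, np.vstack(emp_ping),
                                       np.stack(shuf_ping), cfg.decoder.metric,
                                       0.5, 2)
            pd.DataFrame({"window_time_ms": window_times,
                          "auc_ping_mean": group.empirical.mean(axis=0),
                          "auc_noping_mean": np.vstack(emp_noping).mean(axis=0)}
                         ).to_csv(out / "decoding_summary.csv", index=False)
            bundle["decoding"] = group

        if "stats" in cfg.analyses:
            stage = "stats"
            scfg = dataclasses.replace(
                cfg.stat, seed=cfg.seed,
                analysis_window_ms=cfg.stat.analysis_window_ms
                or ANALYSIS_WINDOWS_MS.get(cfg.lock))
            res = two_level_permutation(group.empirical, group.shuffled, scfg,
                                        window_times=window_times)
            res.to_frame().to_csv(out / "twolevel_ping.csv", index=False)
            contrast = wilcoxon_contrast(np.vstack(emp_ping), np.vstack(emp_noping),
                                         scfg, window_times=window_times)
            contrast.to_frame().to_csv(out / "wilcoxon_ping_vs_noping.csv", index=False)
            bundle["twolevel"] = res
            bundle["wilcoxon"] = contrast

        if "pod" in cfg.analyses:
            stage = "pod"
            pod_res = pod_test(pod_emp, pod_shuf, window_times=window_times,
                               n_second_level=cfg.pod_n_second_level,
                               detector=cfg.pod_detector, seed=cfg.seed)
            pod_res.to_frame().to_csv(out / "pod_participants.csv", index=False)
            (out / "pod_summary.json").write_text(json.dumps({
                "group_pod_norm": pod_res.group_pod,
                "p_value": pod_res.p_value,
                "null_mean": pod_res.null_mean,
                "n_second_level": pod_res.n_second_level,
                "detector": pod_res.detector,
            }, indent=2))
            bundle["pod"] = pod_res

        if "erp" in cfg.analyses:
            stage = "erp"
            ping_locked, pseudo_locked = [], []
            for (design, _), s in zip(participants, seeds):
                sim = dataclasses.replace(cfg.sim, seed=s)
                recall = design[design["phase"] == "recall"]
                ep = simulate_epochs(design, sim, lock="ping")
                is_ping = (ep.metadata["condition"] != "none").to_numpy()
                ping_locked.append(ep.select_trials(np.flatnonzero(is_ping)))
                pseudo_locked.append(ep.select_trials(np.flatnonzero(~is_ping)))
                del recall
            erp_res = ping_contrast(ping_locked, pseudo_locked,
                                    n_randomizations=min(cfg.pod_n_second_level, 10_000),
                                    seed=cfg.seed)
            erp_res.contrast.to_csv(out / "erp_ping_contrast.csv", index=False)
            bundle["erp"] = erp_res
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": cfg.to_dict(),
        "participant_seeds": seeds,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def _subset(fs, meta, mask):
    from .containers import FeatureSeries

    idx = np.flatnonzero(mask)
    return FeatureSeries(fs.values[idx], fs.window_times, fs.feature_names,
                         fs.provenance,
                         meta.iloc[idx].reset_index(drop=True))
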