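"""Config-driven orchestration: simulate -> preprocess -> decode -> stats -> report.

One flat declarative configuration drives the full synthetic-cohort
analysis; every stochastic step is seeded from a master seed through a
documented splitting scheme (participant p gets ``master*1000 + p``, each
decoding stage derives its own stream), so a config re-run reproduces
identical outputs.  Each stage writes tidy tables under the output
directory and the run manifest records the config hash, seed registry and
produced files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardiac, decoding, eeg, fusion, pupil, stats, synth
from .containers import CLASS_ORDER
from .montage import LAYOUTS, layout_channels

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report"]

log = logging.getLogger("errpfusion")

VALID_FUSION_MODES = ("eeg_only", "pupil_only", "sf", "bf")


@dataclass
class PipelineConfig:
    """Flat declarative configuration of a full synthetic-cohort analysis."""

    seed: int = 1
    n_participants: int = 19
    n_runs: int = 9
    layouts: tuple = ("one_channel", "three_channel", "full")
    windows: tuple = (1, 4, 8, 16)
    fusion_modes: tuple = ("eeg_only", "sf", "bf")
    cv_repetitions: int = 10
    cv_folds: int = 5
    out_dir: str = "results/pipeline"
    stages: tuple = ("simulate", "preprocess", "decode", "stats", "report")
    calibration_duration_s: float = 120.0

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_runs < 1:
            raise ValueError("participant and run counts must be positive")
        for l in self.layouts:
            if l not in LAYOUTS:
                raise ValueError(f"unknown layout {l!r}")
        for w in self.windows:
            if w not in decoding.WINDOW_LENGTHS:
                raise ValueError(f"unsupported window length {w}")
        for m in self.fusion_modes:
            if m not in VALID_FUSION_MODES:
                raise ValueError(f"unknown fusion mode {m!r}")
        unknown = set(self.stages) - {"simulate", "preprocess", "decode",
                                      "stats", "report"}
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed_registry: dict
    outputs: list = field(default_factory=list)
    log_path: str = ""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _participant_seed(master: int, p: int) -> int:
    return int((master * 1000 + p) % (2**31))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in fixed order and write tidy outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.hash(),
                           {"master": config.seed,
                            "participants": [_participant_seed(config.seed, p)
                                             for p in range(config.n_participants)]},
                           log_path=str(out / "pipeline.log"))

    def emit(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False)
        manifest.outputs.append(str(path))

    # ---- simulate + preprocess (per participant, kept in memory) ----
    eeg_sets, pupil_sets, hr_sets = [], [], []
    ga_eeg = ga_pupil = ga_hr = None
    if "simulate" in config.stages or "preprocess" in config.stages:
        cfgs = synth.cohort_configs(config.n_participants, config.seed,
                                    n_runs=config.n_runs)
        from .io import write_events_tsv
        for p, gcfg in enumerate(cfgs):
            part = synth.simulate_participant(gcfg, config.calibration_duration_s)
            if p == 0:
                write_events_tsv(part.flight.events, out / "events_p0.tsv")
                manifest.outputs.append(str(out / "events_p0.tsv"))
            if "preprocess" not in config.stages:
                continue
            try:
                eeg_sets.append(eeg.preprocess_eeg(part))
                pupil_sets.append(pupil.preprocess_pupil(part))
                t, hr = cardiac.rr_to_hr(part.flight.rr)
                hr_sets.append(cardiac.epoch_hr(t, hr, part.flight.events))
            except Exception as exc:
                raise RuntimeError(f"preprocess failed for participant {p}: {exc}") from exc
            log.info("preprocessed participant %d", p)

    if eeg_sets:
        ga_eeg = eeg.grand_average_erp(eeg_sets)
        ga_pupil = pupil.grand_average_pupil(pupil_sets)
        ga_hr = cardiac.grand_average_hr(hr_sets)
        rows = []
        for cond in ga_eeg.mean:
            ch = ga_eeg.channel_names.index("FCz")
            for t, v in zip(ga_eeg.t_axis, ga_eeg.mean[cond][ch]):
                rows.append({"condition": cond, "time_s": float(t),
                             "fcz_uV": float(v)})
        emit("grand_average_fcz.csv", pd.DataFrame(rows))

    # ---- decode ----
    acc_rows, trace_store = [], {}
    if "decode" in config.stages:
        if not eeg_sets:
            raise RuntimeError("decode stage requires preprocess outputs")
        for p, (es, ps) in enumerate(zip(eeg_sets, pupil_sets)):
            seed_p = _participant_seed(config.seed, p)
            e_al, p_al = fusion.align_trials(es, ps.as_epochset())
            e_bal = decoding.balance_classes(e_al, seed=seed_p + 17)
            keep_ids = e_bal.event_ids
            p_bal = p_al.select_trials(
                np.nonzero(np.isin(p_al.event_ids, keep_ids))[0])
            e32 = decoding.resample_epochs(e_bal)
            p32 = decoding.resample_epochs(p_bal)
            plan = decoding.make_folds(e_bal.labels, seed_p + 29,
                                       config.cv_repetitions, config.cv_folds)
            for layout in config.layouts:
                chans = layout_channels(layout)
                for w in config.windows:
                    for mode in config.fusion_modes:
                        if mode == "eeg_only":
                            res = decoding.decode_sliding(e32, chans, w, plan)
                        elif mode == "pupil_only":
                            res = decoding.decode_sliding(
                                p32, [p32.channel_names[0]], w, plan)
                        elif mode == "sf":
                            fused = fusion.simple_fusion_features(e_bal, p_bal)
                            res = decoding.decode_sliding(
                                fused, list(chans) + [p32.channel_names[0]],
                                w, plan)
                        else:
                            res = fusion.bayes_fusion_decode(
                                e_bal, p_bal, chans, w, plan)
                        peak, peak_t, mcp = decoding.peak_metrics(res)
                        acc_rows.append({
                            "participant": p, "layout": layout, "window": w,
                            "mode": mode, "peak_accuracy": peak,
                            "peak_time_s": peak_t, "mean_correct_post": mcp,
                            "n_trials": int(len(e_bal.labels))})
                        trace_store.setdefault((layout, w, mode), []).append(
                            (res.times_s, res.accuracy))
            log.info("decoded participant %d", p)
        emit("decoding_metrics.csv", pd.DataFrame(acc_rows))
        trace_rows = []
        for (layout, w, mode), traces in trace_store.items():
            for p, (t, a) in enumerate(traces):
                for ti, ai in zip(t, a):
                    trace_rows.append({"participant": p, "layout": layout,
                                       "window": w, "mode": mode,
                                       "time_s": float(ti),
                                       "accuracy": float(ai)})
        emit("accuracy_traces.csv", pd.DataFrame(trace_rows))

    # ---- stats ----
    if "stats" in config.stages:
        stat_frames = []
        if pupil_sets and hr_sets:
            phys = stats.peak_response_tests(pupil_sets, hr_sets)
            phys.insert(0, "analysis", "peak_response")
            stat_frames.append(phys)
        if acc_rows:
            df = pd.DataFrame(acc_rows)
            thr = stats.average_threshold(
                df.groupby("participant")["n_trials"].first())
            stat_frames.append(pd.DataFrame([{
                "analysis": "significance_threshold", "modality": "",
                "contrast": "binomial", "statistic": thr, "p_raw": np.nan,
                "p_fdr": np.nan, "significant": np.nan}]))
            rows = []
            for (layout, w), sub in df.groupby(["layout", "window"]):
                wide = sub.pivot(index="participant", columns="mode",
                                 values="peak_accuracy")
                if wide.shape[1] >= 2:
                    fr = stats.friedman_nemenyi(
                        {m: wide[m].to_numpy() for m in wide.columns})
                    rows.append({"analysis": "friedman_peak",
                                 "modality": layout,
                                 "contrast": f"window_{w}",
                                 "statistic": fr["statistic"],
                                 "p_raw": fr["p"], "p_fdr": np.nan,
                                 "significant": fr["p"] < 0.05})
            if rows:
                fr_df = pd.DataFrame(rows)
                fr_df["p_fdr"] = stats.fdr_adjust(fr_df["p_raw"].to_numpy())
                fr_df["significant"] = fr_df["p_fdr"] < 0.05
                stat_frames.append(fr_df)
        if stat_frames:
            emit("statistics.csv", pd.concat(stat_frames, ignore_index=True))

    # ---- report ----
    if "report" in config.stages:
        report_path = report(manifest, out, ga_eeg, ga_pupil, ga_hr,
                             pd.DataFrame(acc_rows) if acc_rows else None,
                             trace_store)
        manifest.outputs.append(str(report_path))

    manifest.save(out / "manifest.json")
    return manifest


def report(manifest: RunManifest, out_dir, ga_eeg=None, ga_pupil=None,
           ga_hr=None, metrics: pd.DataFrame | None = None,
           trace_store: dict | None = None) -> Path:
    """Render grand-average traces and accuracy panels into a summary.

    Figures show the theoretical chance level (0.25 for four balanced
    classes) and the binomial significance threshold for the run's trial
    counts; missing stage outputs cause their section to be skipped with a
    notice.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    lines = ["# Pipeline report", "", f"config hash: {manifest.config_hash}", ""]
    colors = {"target": "#d4a017", "passive": "#c0392b", "active": "#2e6da4",
              "correct": "#222222"}

    if ga_eeg is not None:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ch = ga_eeg.channel_names.index("FCz")
        for cond, m in ga_eeg.mean.items():
            ax.plot(ga_eeg.t_axis, m[ch], label=cond,
                    color=colors.get(cond, None))
            ax.fill_between(ga_eeg.t_axis, m[ch] - ga_eeg.sem[cond][ch],
                            m[ch] + ga_eeg.sem[cond][ch], alpha=0.2,
                            color=colors.get(cond, None))
        ax.axvline(0, color="k", lw=0.5)
        ax.set(xlabel="time (s)", ylabel="FCz (µV)", title="grand-average ERP")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / "report_erp.png", dpi=110)
        plt.close(fig)
        lines.append("![ERP](report_erp.png)")
    else:
        lines.append("_EEG grand averages unavailable; section skipped._")

    for name, ga, unit in (("pupil", ga_pupil, "mm"), ("hr", ga_hr, "bpm")):
        if ga is None:
            lines.append(f"_{name} grand averages unavailable; section skipped._")
            continue
        fig, ax = plt.subplots(figsize=(6, 3))
        for cond, m in ga["mean"].items():
            ax.plot(ga["t_axis"], m, label=cond, color=colors.get(cond, None))
        ax.axvline(0, color="k", lw=0.5)
        ax.set(xlabel="time (s)", ylabel=f"Δ {unit}",
               title=f"grand-average {name} response")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"report_{name}.png", dpi=110)
        plt.close(fig)
        lines.append(f"![{name}](report_{name}.png)")

    if metrics is not None and trace_store:
        thr = stats.average_threshold(
            metrics.groupby("participant")["n_trials"].first())
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for (layout, w, mode), traces in sorted(trace_store.items()):
            t = traces[0][0]
            mean = np.mean([a for _, a in traces], axis=0)
            ax.plot(t, mean, label=f"{layout}/{w}/{mode}", lw=1)
        ax.axhline(0.25, ls="--", color="k", lw=0.8, label="chance (0.25)")
        ax.axhline(thr, ls=":", color="k", lw=0.8,
                   label=f"binomial threshold ({thr:.3f})")
        ax.set(xlabel="time (s)", ylabel="accuracy",
               title="grand-average decoding accuracy")
        ax.legend(fontsize=5, ncol=2)
        fig.tight_layout()
        fig.savefig(out_dir / "report_accuracy.png", dpi=110)
        plt.close(fig)
        lines += ["![accuracy](report_accuracy.png)", "",
                  f"chance level: 0.25; binomial significance threshold: {thr:.3f}", ""]
        lines.append(metrics.groupby(["layout", "window", "mode"])
                     [["peak_accuracy", "mean_correct_post"]]
                     .mean().round(3).to_markdown())
    else:
        lines.append("_decoding outputs unavailable; section skipped._")

    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
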