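"""End-to-end workflow: stimulus simulation → synthetic EEG →
preprocessing → ROI window means → ANOVA, plus simulation studies used to
validate the chain by parameter recovery.

A single master seed drives everything: per-subject generators are spawned
as ``SeedSequence(master, spawn_key=(mode_index, subject))`` so any stage
can be re-run in isolation, and identical configurations with the same
seed reproduce byte-identical event tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tripletmmn import erp_stats, formats, infotheory, paradigm, preprocess, synth_eeg

__all__ = [
    "RunConfig",
    "subject_waveforms",
    "cohort_waveforms",
    "run_pipeline",
    "recovery_study",
    "interaction_detection_study",
]


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a simulated experiment run."""

    stream: paradigm.StreamConfig = field(default_factory=paradigm.StreamConfig)
    transitions: paradigm.TransitionTable = field(default_factory=paradigm.TransitionTable)
    truth: synth_eeg.ErpGroundTruth = field(default_factory=synth_eeg.ErpGroundTruth)
    noise: synth_eeg.NoiseSpec = field(default_factory=synth_eeg.NoiseSpec)
    n_subjects: int = 21
    modes: tuple[str, ...] = ("isochronous", "random")
    windows: tuple[str, ...] = ("smmn_main", "smmn_early", "locmmn")
    master_seed: int = 0
    write_raw: bool = False

    def stream_for(self, mode: str) -> paradigm.StreamConfig:
        if mode == "isochronous" and self.stream.soa_mode != "isochronous":
            return paradigm.StreamConfig.isochronous(
                n_triplets_per_block=self.stream.n_triplets_per_block,
                n_blocks=self.stream.n_blocks,
                min_separation=self.stream.min_separation,
                standard_side_first_block=self.stream.standard_side_first_block,
                target_rate_per_min=self.stream.target_rate_per_min,
                inter_block_gap_ms=self.stream.inter_block_gap_ms,
            )
        if mode == "random" and self.stream.soa_mode != "random":
            return paradigm.StreamConfig.random_soa(
                n_triplets_per_block=self.stream.n_triplets_per_block,
                n_blocks=self.stream.n_blocks,
                min_separation=self.stream.min_separation,
                standard_side_first_block=self.stream.standard_side_first_block,
                target_rate_per_min=self.stream.target_rate_per_min,
                inter_block_gap_ms=self.stream.inter_block_gap_ms,
            )
        return self.stream

    # -- flat, lossless (de)serialization ---------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            d = dataclasses.asdict(obj)
            return {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()
            }

        return dict(
            stream=enc(self.stream),
            transitions=enc(self.transitions),
            truth=enc(self.truth),
            noise=enc(self.noise),
            n_subjects=self.n_subjects,
            modes=list(self.modes),
            windows=list(self.windows),
            master_seed=self.master_seed,
            write_raw=self.write_raw,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        stream = d.get("stream", {}).copy()
        if "pause_range_ms" in stream:
            stream["pause_range_ms"] = tuple(stream["pause_range_ms"])
        return cls(
            stream=paradigm.StreamConfig(**stream),
            transitions=paradigm.TransitionTable(**d.get("transitions", {})),
            truth=synth_eeg.ErpGroundTruth(**d.get("truth", {})),
            noise=synth_eeg.NoiseSpec(**d.get("noise", {})),
            n_subjects=int(d.get("n_subjects", 21)),
            modes=tuple(d.get("modes", ("isochronous", "random"))),
            windows=tuple(d.get("windows", ("smmn_main", "smmn_early", "locmmn"))),
            master_seed=int(d.get("master_seed", 0)),
            write_raw=bool(d.get("write_raw", False)),
        )

    def to_yaml(self, path) -> None:
        formats.dump_yaml(self.to_dict(), path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(formats.load_yaml(path))


def subject_waveforms(
    sub: synth_eeg.SubjectData,
) -> tuple[pd.DataFrame, dict, preprocess.EpochSet]:
    """Preprocess one simulated subject: re-reference, filter, reject,
    epoch, ROI-average.  Returns (waveforms, exclusion tallies, epochs)."""
    rec = preprocess.rereference_mastoid_mean(sub.recording)
    rec = preprocess.lowpass_fir(rec)
    mask = preprocess.gliding_window_reject(rec)
    ep = preprocess.extract_epochs(rec, mask, subject=sub.subject)
    wf = preprocess.roi_waveforms(ep)
    return wf, ep.exclusions, ep


def cohort_waveforms(
    cfg: RunConfig,
    mode: str,
    montage: synth_eeg.MontageSpec | None = None,
    outdir: Path | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate and preprocess a full cohort.

    Returns ROI waveforms with a ``subject`` index level, and the
    per-subject exclusion tallies.  Optionally writes per-subject event
    TSVs, epoch arrays (+ JSON sidecars), and raw BrainVision files.
    """
    montage = montage or synth_eeg.default_montage()
    frames, logs = [], []
    for sub in synth_eeg.iter_cohort(
        cfg.n_subjects,
        mode,
        cfg.stream_for(mode),
        cfg.transitions,
        cfg.truth,
        cfg.noise,
        montage,
        cfg.master_seed,
    ):
        wf, tallies, ep = subject_waveforms(sub)
        if outdir is not None:
            sdir = Path(outdir) / mode
            sdir.mkdir(parents=True, exist_ok=True)
            formats.write_events_tsv(sub.events, sdir / f"sub-{sub.subject:02d}_events.tsv")
            np.save(sdir / f"sub-{sub.subject:02d}_epochs.npy", ep.data)
            sidecar = dict(
                subject=sub.subject,
                mode=mode,
                conditions=ep.info["category"].value_counts().to_dict(),
                exclusions=tallies,
                tmin_ms=ep.tmin_ms,
                tmax_ms=ep.tmax_ms,
            )
            (sdir / f"sub-{sub.subject:02d}_epochs.json").write_text(
                json.dumps(sidecar, indent=1)
            )
            if cfg.write_raw:
                formats.write_brainvision(sub.recording, sdir / f"sub-{sub.subject:02d}")
        frames.append(pd.concat({sub.subject: wf}, names=["subject"]))
        logs.append(dict(subject=sub.subject, mode=mode, **tallies))
    return pd.concat(frames), logs


_CONTRASTS = {
    "smmn_main": ("standard", "stat_deviant"),
    "smmn_early": ("standard", "stat_deviant"),
    "locmmn": ("standard", "phys_deviant"),
    "early_neg": ("standard", "stat_deviant"),
    "positivity": ("standard", "stat_deviant"),
}


def _cells(waveforms: pd.DataFrame, window_name: str) -> pd.DataFrame:
    win = erp_stats.WINDOWS[window_name]
    wm = erp_stats.window_means(waveforms, win)
    std, dev = _CONTRASTS[window_name]
    return erp_stats.contrast_cells(wm, standard=std, deviant=dev)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run the full workflow and write the report bundle.

    Produces per-subject event TSVs and epoch stores, cohort ROI waveform
    TSVs, ANOVA tables per window (within-cohort and, when both modes are
    simulated, the mixed isochronicity contrasts), the predictability
    table, and a JSON run log with exclusion tallies.  Identical seeds
    yield identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    table = infotheory.predictability_table(cfg.transitions, cfg.stream_for("random"))
    (outdir / "predictability.tsv").write_text(table.to_tsv(), encoding="utf-8")

    waveforms: dict[str, pd.DataFrame] = {}
    logs: list[dict] = []
    for mode in cfg.modes:
        try:
            wf, log = cohort_waveforms(cfg, mode, outdir=outdir)
        except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
            raise RuntimeError(f"stage cohort[{mode}] failed: {exc}") from exc
        waveforms[mode] = wf
        logs.extend(log)
        wf.to_csv(outdir / f"roi_waveforms_{mode}.tsv", sep="\t")

    report_lines = []
    anovas: dict[str, pd.DataFrame] = {}
    for mode in cfg.modes:
        for wname in cfg.windows:
            cells = _cells(waveforms[mode], wname)
            tab = erp_stats.rm_anova(
                cells, within=["deviance", "area", "lateralisation", "block_group"]
            )
            key = f"{mode}_{wname}"
            anovas[key] = tab
            tab.to_csv(outdir / f"anova_{key}.tsv", sep="\t")
            report_lines.append(f"[{key}] " + erp_stats.format_effect(tab, "deviance"))

    if set(cfg.modes) >= {"isochronous", "random"}:
        for wname in cfg.windows:
            mixed, simple = erp_stats.interaction_contrast(
                _cells(waveforms["isochronous"], wname),
                _cells(waveforms["random"], wname),
            )
            key = f"interaction_{wname}"
            anovas[key] = mixed
            mixed.to_csv(outdir / f"anova_{key}.tsv", sep="\t")
            report_lines.append(
                f"[{key}] " + erp_stats.format_effect(mixed, "deviance × isochronicity")
            )
            for grp, s in simple.items():
                report_lines.append(
                    f"[{key}] simple effect ({grp}): {s['estimate']:+.2f} µV, "
                    f"F = {s['F']:.2f}, p = {s['p']:.4f}"
                )

    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n", encoding="utf-8")
    (outdir / "run_log.json").write_text(json.dumps(logs, indent=1), encoding="utf-8")
    return dict(anovas=anovas, exclusions=logs, report="\n".join(report_lines))


# ---------------------------------------------------------------------------
# simulation studies (parameter recovery / interaction detection)
# ---------------------------------------------------------------------------

def _study_config(
    n_subjects: int,
    seed: int,
    truth: synth_eeg.ErpGroundTruth,
    n_blocks: int = 2,
    noise: synth_eeg.NoiseSpec | None = None,
) -> RunConfig:
    """Reduced-scale study conditions: blocks of 50 triplets keep the
    exact category quotas while making many simulated cohorts feasible."""
    return RunConfig(
        stream=paradigm.StreamConfig(n_triplets_per_block=50, n_blocks=n_blocks),
        truth=truth,
        noise=noise or synth_eeg.NoiseSpec(),
        n_subjects=n_subjects,
        master_seed=seed,
    )


def recovery_study(
    n_sims: int = 100,
    n_subjects: int = 21,
    seed: int = 0,
    mode: str = "random",
    window: str = "locmmn",
) -> dict:
    """Recover the injected location-MMN amplitude end-to-end.

    For each simulated cohort the deviance simple effect (deviant −
    standard window-mean amplitude, averaged over ROIs) is compared to the
    ground-truth prediction from the injected kernel and gain map.
    Returns the mean estimate, the predicted value, and the relative
    error of the across-simulation mean.
    """
    montage = synth_eeg.default_montage()
    win = erp_stats.WINDOWS[window]
    estimates = []
    for s in range(n_sims):
        cfg = _study_config(
            n_subjects, seed * 100_003 + s, synth_eeg.ErpGroundTruth(), n_blocks=1
        )
        wf, _ = cohort_waveforms(cfg, mode, montage=montage)
        cells = _cells(wf, window)
        means = cells.groupby("deviance", observed=True)["amplitude"].mean()
        estimates.append(float(means["deviant"] - means["standard"]))
    comp = synth_eeg.ErpGroundTruth().locmmn_component(mode)
    predicted = float(
        np.mean(
            list(
                synth_eeg.ErpGroundTruth()
                .predicted_roi_window_effect(comp, (win.lo_ms, win.hi_ms), montage)
                .values()
            )
        )
    )
    mean_est = float(np.mean(estimates))
    return dict(
        estimates=estimates,
        mean_estimate=mean_est,
        predicted=predicted,
        relative_error=abs(mean_est - predicted) / abs(predicted),
    )


def interaction_detection_study(
    n_sims: int = 40,
    n_subjects: int = 21,
    seed: int = 0,
    alpha: float = 0.001,
    window: str = "smmn_main",
) -> dict:
    """Power of the deviance × isochronicity interaction when the sMMN is
    injected only in the isochronous group.

    Each simulation draws independent isochronous and non-isochronous
    cohorts, runs the mixed ANOVA on the statistical-deviance contrast,
    and tests the interaction at ``alpha``.  Returns the detection rate.

    The study runs at a reduced trial count (two 50-triplet blocks per
    subject versus six of 400 in the full design), so the background
    noise SD is scaled to preserve the full design's per-subject contrast
    precision: the deviance-contrast SE scales as
    ``sd * sqrt(1/n_deviant + 1/n_standard)``, and matching the full
    design's value (8 µV at roughly 115 deviant / 1040 standard surviving
    epochs) at the reduced counts (~5 / 43) gives sd ≈ 1.7 µV.
    """
    truth = synth_eeg.ErpGroundTruth(
        smmn_scale={"isochronous": 1.0, "random": 0.0}
    )
    noise = synth_eeg.NoiseSpec(background_sd=1.7)
    montage = synth_eeg.default_montage()
    hits = 0
    pvals = []
    for s in range(n_sims):
        base = seed * 100_003 + s
        cfg_iso = _study_config(n_subjects, 2 * base, truth, noise=noise)
        cfg_rnd = _study_config(n_subjects, 2 * base + 1, truth, noise=noise)
        wf_iso, _ = cohort_waveforms(cfg_iso, "isochronous", montage=montage)
        wf_rnd, _ = cohort_waveforms(cfg_rnd, "random", montage=montage)
        mixed, _ = erp_stats.interaction_contrast(
            _cells(wf_iso, window),
            _cells(wf_rnd, window),
            within=("deviance", "area", "lateralisation"),
        )
        p = float(mixed.loc["deviance × isochronicity", "p"])
        pvals.append(p)
        hits += p < alpha
    return dict(detection_rate=hits / n_sims, pvals=pvals, alpha=alpha)
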