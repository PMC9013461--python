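"""End-to-end orchestration: simulate -> preprocess -> qc -> metrics -> stats.

A single :class:`RunConfig` drives all stages. The master seed
deterministically derives a per-stage seed (hash of seed and stage name)
so stages can be rerun independently yet reproducibly; rerunning the whole
pipeline with the same config yields byte-identical output files. Every
generated antenna ends up either analyzed or excluded-with-reason -- no
data are silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import metrics as metrics_mod
from . import preprocess as pre
from . import qc as qc_mod
from . import stats as stats_mod
from . import synthetic
from .signal_io import Recording, read_recording, write_recording

__all__ = [
    "RunConfig",
    "PipelineError",
    "stage_seed",
    "run",
    "build_metrics_table",
    "make_report",
]

log = logging.getLogger("eagkit")


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and offending record."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**32)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "eagkit_run"
    master_seed: int = 0
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    input_dir: str | None = None  # use existing data instead of simulating
    filter_window_ms: float = 11.0
    qc_k: float = 6.0
    qc_window_s: float = 0.5
    k_tapers: int = 5
    n_sim: int = 10_000
    onset_crossing: str = "last"
    population: str = "pop1"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def generator_config(self) -> synthetic.GeneratorConfig:
        overrides = dict(self.generator)
        overrides.setdefault("rng_seed", stage_seed(self.master_seed, "simulate"))
        # coerce nested YAML mappings into their dataclasses
        if isinstance(overrides.get("antenna_kinetics"), dict):
            overrides["antenna_kinetics"] = synthetic.AntennaKinetics(
                **overrides["antenna_kinetics"]
            )
        if isinstance(overrides.get("ecotype_effects"), dict):
            overrides["ecotype_effects"] = synthetic.EcotypeEffects(
                **overrides["ecotype_effects"]
            )
        if "odorant_kinetics" in overrides:
            overrides["odorant_kinetics"] = {
                name: kin if isinstance(kin, synthetic.OdorantKinetics)
                else synthetic.OdorantKinetics(**kin)
                for name, kin in overrides["odorant_kinetics"].items()
            }
        if "odorants" in overrides:
            overrides["odorants"] = tuple(overrides["odorants"])
        return synthetic.GeneratorConfig(**overrides)


def _write_trace_csv(trace: pre.Trace, path: Path) -> None:
    pd.DataFrame(
        {"time_s": trace.times(), "voltage_mV": trace.voltage}
    ).to_csv(path, index=False)


def _trace_stem(trace: pre.Trace) -> str:
    return (
        f"{trace.antenna_id}_{trace.odorant}_{trace.pulse_duration_ms:g}ms_"
        f"{trace.block}"
    )


def build_metrics_table(
    median_traces: list[pre.Trace],
    recordings: dict[str, Recording],
    crossing: str = "last",
) -> pd.DataFrame:
    """Response metrics of all main-block median traces, one row per
    antenna x odorant x pulse duration."""
    rows = []
    for tr in median_traces:
        if tr.block != "main":
            continue
        rec = recordings[tr.antenna_id]
        m = metrics_mod.compute_metrics(tr, crossing=crossing)
        rows.append(
            {
                "antenna_id": tr.antenna_id,
                "ecotype": rec.ecotype,
                "population": rec.population,
                "odorant": tr.odorant,
                "pulse_duration_ms": tr.pulse_duration_ms,
                "strength_mV": m.strength_mV,
                "onset_s": m.onset_s,
                "offset_s": m.offset_s,
                "peak_time_s": m.peak_time_s,
                "onset_valid": m.onset_valid,
                "offset_valid": m.offset_valid,
            }
        )
    return pd.DataFrame(rows)


def _simulate_stage(config: RunConfig, out: Path) -> tuple[list[Recording], pd.DataFrame]:
    gen_config = config.generator_config()
    recordings, truth = synthetic.generate_cohort(
        gen_config, population=config.population
    )
    rec_dir = out / "recordings"
    for rec in recordings:
        write_recording(rec, rec_dir)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return recordings, truth


def _load_stage(config: RunConfig) -> list[Recording]:
    directory = Path(config.input_dir)
    ids = sorted(p.name[: -len(".meta.json")] for p in directory.glob("*.meta.json"))
    if not ids:
        raise PipelineError(f"stage load: no recordings found in {directory}")
    return [read_recording(directory, antenna_id) for antenna_id in ids]


def run(config: RunConfig) -> dict:
    """Execute all stages; returns a bundle of output paths and tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_lines = [f"master_seed: {config.master_seed}", f"n_sim: {config.n_sim}"]

    # --- simulate (or load) ------------------------------------------------
    truth = None
    try:
        if config.input_dir is None:
            recordings, truth = _simulate_stage(config, out)
        else:
            recordings = _load_stage(config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage simulate/load failed: {exc}") from exc
    rec_by_id = {r.antenna_id: r for r in recordings}
    log.info("simulate: %d recordings", len(recordings))

    # --- preprocess --------------------------------------------------------
    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    median_traces: dict[str, list[pre.Trace]] = {}
    for rec in recordings:
        try:
            med = pre.preprocess_recording(rec, window_ms=config.filter_window_ms)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"stage preprocess failed on antenna {rec.antenna_id}: {exc}"
            ) from exc
        median_traces[rec.antenna_id] = med
        for tr in med:
            _write_trace_csv(tr, traces_dir / f"{_trace_stem(tr)}.csv")

    # --- qc ----------------------------------------------------------------
    qc_rows = []
    included: list[str] = []
    for rec in recordings:
        controls = [t for t in median_traces[rec.antenna_id] if t.block == "control"]
        if not controls:
            raise PipelineError(
                f"stage qc: antenna {rec.antenna_id} has no final control block"
            )
        shift = qc_mod.detect_baseline_shift(
            rec, k=config.qc_k, window_s=config.qc_window_s
        )
        result = qc_mod.qc_antenna(controls[0], baseline_shift_detected=shift)
        qc_rows.append(dataclasses.asdict(result))
        if result.decision == "include":
            included.append(rec.antenna_id)
    qc_report = pd.DataFrame(qc_rows)
    qc_report.to_csv(out / "qc_report.csv", index=False)
    log.info("qc: %d/%d antennae included", len(included), len(recordings))

    # --- metrics -----------------------------------------------------------
    kept = [t for a in included for t in median_traces[a]]
    metrics_table = build_metrics_table(kept, rec_by_id, crossing=config.onset_crossing)
    metrics_table.to_csv(out / "metrics.csv", index=False)

    tracking_rows = []
    for tr in kept:
        if tr.block != "train":
            continue
        window = metrics_mod.psd_train_window(tr)
        psd = metrics_mod.multitaper_psd(
            window, tr.sampling_rate, k_tapers=config.k_tapers
        )
        tracking_rows.append(
            {
                "antenna_id": tr.antenna_id,
                "ecotype": rec_by_id[tr.antenna_id].ecotype,
                "odorant": tr.odorant,
                "tracking_score": metrics_mod.tracking_score(psd),
                "n_tapers": psd.n_tapers,
            }
        )
    tracking = pd.DataFrame(tracking_rows)
    tracking.to_csv(out / "tracking.csv", index=False)

    # --- stats -------------------------------------------------------------
    contrast_frames = []
    recovery_rows = []
    seed = stage_seed(config.master_seed, "stats")
    if len(metrics_table):
        for i, odorant in enumerate(sorted(metrics_table["odorant"].unique())):
            try:
                fit = stats_mod.fit_strength_model(metrics_table, odorant=odorant)
            except stats_mod.ModelError as exc:
                log_lines.append(f"strength model skipped for {odorant}: {exc}")
                continue
            draws = stats_mod.simulate_posterior(fit, n_sim=config.n_sim, seed=seed + i)
            table = stats_mod.summarize_strength_contrasts(
                fit, draws, label_prefix=f"{odorant} strength "
            )
            table.insert(0, "odorant", odorant)
            table.insert(1, "model", "strength")
            contrast_frames.append(table)
            if truth is not None:
                eco = fit.params[f"ecotype[{stats_mod.ECOTYPE_ALT}]"]
                recovery_rows.append(
                    {
                        "odorant": odorant,
                        "quantity": "log2_amplitude_ratio",
                        "true_value": float(truth["true_log2_ratio"].iloc[0]),
                        "estimate": float(eco),
                    }
                )
            for j, which in enumerate(("onset", "offset")):
                try:
                    tfit = stats_mod.fit_timing_model(
                        metrics_table, which=which, odorant=odorant
                    )
                except stats_mod.ModelError as exc:
                    log_lines.append(f"{which} model skipped for {odorant}: {exc}")
                    continue
                tdraws = stats_mod.simulate_posterior(
                    tfit, n_sim=config.n_sim, seed=seed + 1000 + 2 * i + j
                )
                s = stats_mod.summarize_comparison(
                    tdraws,
                    stats_mod.ecotype_contrast(tfit),
                    label=f"{odorant} {which} 300 ms",
                )
                contrast_frames.append(
                    pd.DataFrame(
                        [
                            {
                                "odorant": odorant,
                                "model": which,
                                "contrast": s.label,
                                "mean_log2": s.mean,
                                "lo95_log2": s.lo95,
                                "hi95_log2": s.hi95,
                                "ratio": s.ratio,
                                "p_fw_greater": s.p_fw_greater,
                                "certainty": s.certainty,
                                "direction": s.direction,
                                "stars": s.stars,
                            }
                        ]
                    )
                )
    contrasts = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame(
            columns=[
                "odorant", "model", "contrast", "mean_log2", "lo95_log2",
                "hi95_log2", "ratio", "p_fw_greater", "certainty",
                "direction", "stars",
            ]
        )
    )
    contrasts.to_csv(out / "contrasts.csv", index=False)
    recovery = pd.DataFrame(
        recovery_rows, columns=["odorant", "quantity", "true_value", "estimate"]
    )
    if truth is not None:
        recovery.to_csv(out / "recovery.csv", index=False)

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "out_dir": out,
        "qc_report": qc_report,
        "metrics": metrics_table,
        "tracking": tracking,
        "contrasts": contrasts,
        "recovery": recovery if truth is not None else None,
        "included": included,
    }


def make_report(bundle: dict) -> str:
    """Render a plain-text summary page of a completed run.

    One section per population x odorant with per-antenna metric dots,
    posterior contrasts (with asterisks matching the contrast table
    exactly), tracking scores, and the exclusion list with reason codes.
    The report is also written to ``report.md`` in the run directory.
    """
    lines = ["# eagkit run report", ""]
    qc_report: pd.DataFrame = bundle["qc_report"]
    excluded = qc_report[qc_report["decision"] == "exclude"]
    lines.append(
        f"Antennae analyzed: {len(bundle['included'])} / {len(qc_report)}"
    )
    if len(excluded):
        lines.append("Excluded:")
        for _, row in excluded.iterrows():
            lines.append(f"  - {row['antenna_id']}: {row['reason']}")
    lines.append("")

    metrics_table: pd.DataFrame = bundle["metrics"]
    contrasts: pd.DataFrame = bundle["contrasts"]
    if len(metrics_table) == 0:
        lines.append("No analyzable metrics.")
    else:
        for (population, odorant), grp in metrics_table.groupby(
            ["population", "odorant"]
        ):
            lines.append(f"## {population} / {odorant}")
            abbrev = {"full-winged": "fw", "wing-reduced": "wr", "reference": "ref"}
            for dur, sub in grp.groupby("pulse_duration_ms"):
                per_ant = ", ".join(
                    f"{r.antenna_id}({abbrev.get(r.ecotype, '?')})={r.strength_mV:.3f}"
                    for r in sub.itertuples()
                )
                lines.append(f"  {dur:g} ms strength (mV): {per_ant}")
            lines.append("")
    if len(contrasts) == 0:
        lines.append("No testable contrasts.")
    else:
        lines.append("## Ecotype contrasts (full-winged vs wing-reduced)")
        for _, row in contrasts.iterrows():
            lines.append(
                f"  {row['contrast']}: log2 diff {row['mean_log2']:+.3f} "
                f"[{row['lo95_log2']:+.3f}, {row['hi95_log2']:+.3f}], "
                f"certainty {row['certainty']:.3f} {row['stars']}"
                f" ({row['direction']})"
            )
    tracking: pd.DataFrame = bundle["tracking"]
    if len(tracking):
        lines.append("")
        lines.append("## 10-Hz pulse tracking")
        for _, row in tracking.iterrows():
            lines.append(
                f"  {row['antenna_id']} ({row['ecotype']}, {row['odorant']}): "
                f"score {row['tracking_score']:.2f}"
            )
    text = "\n".join(lines) + "\n"
    (Path(bundle["out_dir"]) / "report.md").write_text(text)
    return text
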