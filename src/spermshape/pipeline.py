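"""End-to-end orchestration: simulate → segment → measure → FHA → classify.

A :class:`PipelineConfig` carries every tunable constant plus the single
RNG seed; rerunning with the same config reproduces identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discriminant, fha, io, morpho, segment, synth

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "measure_cohort_images"]


@dataclass
class PipelineConfig:
    """Serializable configuration for a full pipeline run."""

    # imaging / calibration
    pixel_size_um: float = 0.11
    bit_depth: int = 8
    # synthetic cohort
    n_af_rams: int = synth.REFERENCE_COHORT["AF"]
    n_lf_rams: int = synth.REFERENCE_COHORT["LF"]
    sperm_per_ram: int = synth.SPERM_PER_RAM
    # segmentation
    log_sigma_um: float = segment.DEFAULT_SIGMA_UM
    threshold_policy: str = "otsu"
    min_area_um2: float = segment.DEFAULT_MIN_AREA_UM2
    max_area_um2: float = segment.DEFAULT_MAX_AREA_UM2
    solidity_cutoff: float = segment.DEFAULT_SOLIDITY_CUTOFF
    # fha
    n_polar_samples: int = fha.DEFAULT_N_SAMPLES
    max_harmonic: int = fha.DEFAULT_MAX_HARMONIC
    half_pixel_correction: bool = True
    # discriminant
    priors: str = "equal"
    entry_p: float = discriminant.DEFAULT_ENTRY_P
    stay_p: float = discriminant.DEFAULT_STAY_P
    tie_policy: str = "majority"
    labels_from: str = "threshold"   # "threshold" (re-derive from rates) or "truth"
    feature_list: list[str] | None = None
    # plumbing
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.log_sigma_um <= 0:
            raise ValueError("pixel size and LoG sigma must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        if self.n_polar_samples < 2 * self.max_harmonic + 1:
            raise ValueError("n_polar_samples must exceed 2*max_harmonic")
        if self.labels_from not in {"threshold", "truth"}:
            raise ValueError("labels_from must be 'threshold' or 'truth'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: pd.DataFrame          # per-ram feature matrix (measured)
    labels: pd.Series
    cutoff: float | None
    model: discriminant.StepwiseLDA
    cv: discriminant.CrossValidationReport
    report: dict
    recovery: pd.DataFrame | None = None   # per-nucleus true vs measured amplitudes


def measure_cohort_images(
    cohort: synth.Cohort, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and measure every rendered nucleus patch in a cohort.

    Returns (per-ram feature matrix, per-nucleus recovery table pairing
    true and measured amplitudes).  Nuclei whose patch segmentation does
    not yield exactly one accepted object are dropped and logged.
    """
    if cohort.detail != "images":
        raise ValueError("cohort was generated without rendered images")
    offset = config.pixel_size_um / 2 if config.half_pixel_correction else 0.0
    rows, recov = [], []
    for ram in cohort.rams:
        hsets, morphos = [], []
        for j, (patch, _true_mask) in enumerate(ram.patches):
            objs, traces = segment.segment_image(
                patch,
                pixel_size_um=config.pixel_size_um,
                sigma_um=config.log_sigma_um,
                threshold_policy=config.threshold_policy,
                ram_id=ram.ram_id,
                min_area_um2=config.min_area_um2,
                max_area_um2=config.max_area_um2,
                solidity_cutoff=config.solidity_cutoff,
            )
            acc = {o.label: o for o in objs if o.accepted}
            accepted = [(acc[t.label], t) for t in traces if t.label in acc]
            if len(accepted) != 1:
                warnings.warn(
                    f"{ram.ram_id} nucleus {j}: {len(accepted)} accepted objects, skipped"
                )
                continue
            obj, trace = accepted[0]
            try:
                h = fha.harmonics_from_trace(
                    trace,
                    n_samples=config.n_polar_samples,
                    max_harmonic=config.max_harmonic,
                    radial_offset_um=offset,
                )
                rec = morpho.measure(
                    obj, patch, config.pixel_size_um, trace=trace, ram_id=ram.ram_id
                )
            except (ValueError, segment.SegmentationError) as e:
                warnings.warn(f"{ram.ram_id} nucleus {j}: {e}")
                continue
            hsets.append(h)
            morphos.append(rec)
            true_amp = ram.harmonic_sets[j].amplitudes
            meas_amp = h.amplitudes
            recov.append(
                {
                    "ram_id": ram.ram_id,
                    "nucleus": j,
                    **{f"true_ha{k}": true_amp[k] for k in range(len(true_amp))},
                    **{f"meas_ha{k}": meas_amp[k] for k in range(len(meas_amp))},
                }
            )
        if len(hsets) < 2:
            raise RuntimeError(f"{ram.ram_id}: fewer than 2 measurable nuclei")
        mm = morpho.summarize_morpho(morphos)["mean"].to_dict()
        s = fha.summarize_ram(hsets, morpho_means=mm, ram_id=ram.ram_id, group=ram.group)
        rows.append(s.to_row())
    features = pd.DataFrame(rows).set_index("ram_id")
    return features, pd.DataFrame(recov)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic pipeline under one config.

    Simulates the cohort, derives the feature matrix (from rendered images
    when the cohort is image-detailed, otherwise from the generator's true
    contours), labels rams by thresholding conception rates (or from the
    generator's truth), performs stepwise discriminant selection, and
    evaluates the model by leave-one-out cross-validation.  Writes
    artifacts plus a manifest when ``config.outdir`` is set.
    """
    config.validate()
    render = synth.RenderParams(bit_depth=config.bit_depth)
    detail = "images" if config.sperm_per_ram * (config.n_af_rams + config.n_lf_rams) <= 20000 else "summary"
    cohort = synth.generate_cohort(
        config.n_af_rams,
        config.n_lf_rams,
        config.sperm_per_ram,
        rng_seed=config.seed,
        detail=detail,
        pixel_size_um=config.pixel_size_um,
        render_params=render,
    )
    recovery = None
    if detail == "images":
        features, recovery = measure_cohort_images(cohort, config)
    else:
        features = cohort.feature_matrix()
    feature_cols = features.drop(columns=["group", "n_sperm"])

    cutoff = None
    if config.labels_from == "threshold":
        records, cutoff = discriminant.threshold_groups(cohort.fertility)
        labels = pd.Series(
            {r.ram_id: r.group for r in records}, name="group"
        ).loc[features.index]
    else:
        labels = cohort.labels().loc[features.index]

    model = discriminant.StepwiseLDA(
        entry_p=config.entry_p,
        stay_p=config.stay_p,
        priors=config.priors,
        tie_policy=config.tie_policy,
        feature_list=config.feature_list,
    ).fit(feature_cols, labels)
    cv = discriminant.loo_crossvalidate(
        feature_cols,
        labels,
        priors=config.priors,
        tie_policy=config.tie_policy,
        features=model.selected_features_ or None,
    )
    summaries = features.drop(columns=["n_sperm"])
    report = discriminant.build_report(model, cv, summaries=summaries, cutoff=cutoff)
    report["config_hash"] = config.config_hash()
    report["seed"] = config.seed

    result = PipelineResult(
        config=config,
        features=features,
        labels=labels,
        cutoff=cutoff,
        model=model,
        cv=cv,
        report=report,
        recovery=recovery,
    )
    if config.outdir:
        _write_artifacts(result, cohort)
    return result


def _write_artifacts(result: PipelineResult, cohort: synth.Cohort) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_features(result.features, out / "features.csv")
    io.write_fertility(cohort.fertility, out / "fertility.csv")
    io.write_json(result.report, out / "results.json")
    (out / "report.md").write_text(discriminant.report_markdown(result.report))
    if result.recovery is not None:
        result.recovery.to_csv(out / "recovery.csv", index=False)
    manifest = {
        "config": json.loads(result.config.to_json()),
        "config_hash": result.config.config_hash(),
        "n_rams": int(len(result.features)),
    }
    io.write_json(manifest, out / "manifest.json")
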