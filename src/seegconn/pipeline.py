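"""End-to-end orchestration: recordings → features → classified report.

``run_pipeline`` drives the whole analysis for a cohort — segment selection,
preprocessing, per-segment Pearson matrices, segment averaging, contact→region
reduction, (mean, SD) feature extraction, group rank-sum comparisons, the
linear classifier with leave-one-out evaluation and the label-permutation
significance test — and writes every intermediate artifact plus a structured
JSON report that carries enough provenance (config echo, config hash, derived
seeds) to reproduce itself exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassifierReport,
    PermutationResult,
    fit_lda,
    fit_linear_svc,
    loo_evaluate,
    permutation_test,
    rank_sum_test,
)
from .cohort import ArtifactSpec, CohortSpec, iter_cohort
from .connectivity import (
    ConnectivityMatrix,
    PatientFeatures,
    average_matrices,
    contacts_to_regions,
    group_region_pair_means,
    offdiagonal_features,
    pearson_matrix,
)
from .io import read_recording_bundle
from .preprocessing import FilterSpec, Recording, preprocess_segment, select_segments

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "patient_features"]

log = logging.getLogger("seegconn")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end analysis needs, with study defaults.

    Input is either a synthetic ``cohort`` spec or a directory of recording
    bundles (``input_dir``, which takes precedence when set).  In synthetic
    mode the cohort seed and the permutation seed are both derived from
    ``seed`` so a single integer reproduces the whole report.
    """

    output_dir: str = "seegconn_output"
    input_dir: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    n_segments: int = 3
    segment_duration: float = 90.0
    preictal_exclusion_s: float = 1800.0
    clip_threshold: float = 5.0
    classifier: str = "svc"
    svc_C: float = 1000.0
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.classifier not in ("svc", "lda"):
            raise ValueError("classifier must be 'svc' or 'lda'")
        if self.svc_C <= 0 or self.n_permutations < 1:
            raise ValueError("svc_C must be > 0 and n_permutations ≥ 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_dict(self) -> dict:
        """Config without ``output_dir``: the parameters that determine the
        analysis result, used for the report echo and the config hash."""
        d = self.to_dict()
        d.pop("output_dir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "artifacts" in c and isinstance(c["artifacts"], dict):
                c["artifacts"] = ArtifactSpec(**c["artifacts"])
            for key in ("pos_mean_range", "pos_sd_range", "neg_mean_range",
                        "neg_sd_range", "regions_per_patient"):
                if key in c:
                    c[key] = tuple(c[key])
            d["cohort"] = CohortSpec(**c)
        if "filter_spec" in d and isinstance(d["filter_spec"], dict):
            d["filter_spec"] = FilterSpec(**d["filter_spec"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    """Container for the pipeline's in-memory outputs."""

    features: list[PatientFeatures]
    report: ClassifierReport
    permutation: PermutationResult
    line_weights: np.ndarray
    line_offset: float
    rank_sum: dict[str, tuple[float, float]]
    output_dir: Path


def patient_features(
    recording: Recording,
    n_segments: int = 3,
    segment_duration: float = 90.0,
    preictal_exclusion_s: float = 1800.0,
    filter_spec: FilterSpec | None = None,
    clip_threshold: float = 5.0,
) -> tuple[PatientFeatures, ConnectivityMatrix, list[ConnectivityMatrix]]:
    """One patient end-to-end: segments → matrices → region-level features.

    Returns the (mean, SD) features, the averaged region-level matrix, and
    the per-segment contact-level matrices.
    """
    windows = select_segments(
        recording,
        n_segments=n_segments,
        segment_duration=segment_duration,
        preictal_exclusion_s=preictal_exclusion_s,
        threshold_k=clip_threshold,
    )
    ids = recording.contact_ids
    seg_mats = []
    for w in windows:
        clean = preprocess_segment(recording, w, filter_spec, clip_threshold)
        seg_mats.append(pearson_matrix(clean, ids))
    avg = average_matrices(seg_mats)
    region_avg = contacts_to_regions(avg, recording.channels)
    mean, sd = offdiagonal_features(region_avg)
    pf = PatientFeatures(
        patient_id=recording.patient_id or "unknown",
        mean_connectivity=mean,
        sd_connectivity=sd,
        outcome=bool(recording.outcome),
    )
    return pf, region_avg, seg_mats


def _iter_input(config: PipelineConfig) -> Iterator[tuple[Recording, bool, tuple | None]]:
    if config.input_dir is not None:
        metas = sorted(Path(config.input_dir).glob("*.meta.json"))
        if not metas:
            raise FileNotFoundError(f"no *.meta.json bundles in {config.input_dir}")
        for meta in metas:
            rec = read_recording_bundle(meta)
            if rec.outcome is None:
                raise ValueError(f"bundle {meta.name} lacks an outcome label")
            yield rec, bool(rec.outcome), None
    else:
        ss = np.random.SeedSequence(config.seed).generate_state(2) & 0x7FFFFFFF
        spec = dataclasses.replace(
            config.cohort,
            n_segments=config.n_segments,
            segment_duration=config.segment_duration,
            preictal_exclusion_s=config.preictal_exclusion_s,
            seed=int(ss[0]),
        )
        yield from iter_cohort(spec)


def _write_matrix(m: ConnectivityMatrix, path: Path) -> None:
    m.to_frame().to_csv(path, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write artifacts under ``config.output_dir``.

    Writes per-patient segment matrices, averaged region matrices, the
    features table, group region-pair matrices (NaN marks pairs absent from a
    group), and ``report.json``.  Identical config (and seed) reproduces a
    byte-identical report.
    """
    out = Path(config.output_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: hash=%s seed=%d", config.config_hash(), config.seed)

    features: list[PatientFeatures] = []
    region_mats: list[ConnectivityMatrix] = []
    manifest_rows = []
    for rec, outcome, target_stats in _iter_input(config):
        try:
            pf, region_avg, seg_mats = patient_features(
                rec,
                n_segments=config.n_segments,
                segment_duration=config.segment_duration,
                preictal_exclusion_s=config.preictal_exclusion_s,
                filter_spec=config.filter_spec,
                clip_threshold=config.clip_threshold,
            )
        except Exception as exc:
            raise RuntimeError(
                f"segment/connectivity stage failed for patient "
                f"{rec.patient_id!r}: {exc}"
            ) from exc
        log.info(
            "patient %s: %d channels, mean=%.4f sd=%.4f outcome=%s",
            pf.patient_id, rec.n_channels, pf.mean_connectivity,
            pf.sd_connectivity, outcome,
        )
        for k, m in enumerate(seg_mats, start=1):
            _write_matrix(m, out / "matrices" / f"{pf.patient_id}_seg{k}.csv")
        _write_matrix(region_avg, out / "matrices" / f"{pf.patient_id}_avg_regions.csv")
        features.append(pf)
        region_mats.append(region_avg)
        row = {"patient_id": pf.patient_id, "outcome": outcome}
        if target_stats is not None:
            row["target_mean"], row["target_sd"] = target_stats
        manifest_rows.append(row)

    labels = [f.outcome for f in features]
    if len(features) < 3 or len(set(labels)) < 2:
        raise ValueError("need ≥ 3 patients with both outcome labels present")

    feat_df = pd.DataFrame(
        {
            "patient_id": [f.patient_id for f in features],
            "mean_connectivity": [f.mean_connectivity for f in features],
            "sd_connectivity": [f.sd_connectivity for f in features],
            "outcome": labels,
        }
    )
    feat_df.to_csv(out / "features.csv", index=False, float_format="%.10g")
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False,
                                       float_format="%.10g")

    pos_df, neg_df, mask = group_region_pair_means(region_mats, labels)
    pos_df.to_csv(out / "group_regions_positive.csv", float_format="%.10g")
    neg_df.to_csv(out / "group_regions_negative.csv", float_format="%.10g")
    mask.to_csv(out / "region_presence.csv")

    points = feat_df[["mean_connectivity", "sd_connectivity"]].to_numpy()
    means_pos = points[np.asarray(labels), 0]
    means_neg = points[~np.asarray(labels), 0]
    sds_pos = points[np.asarray(labels), 1]
    sds_neg = points[~np.asarray(labels), 1]
    rank_sum = {
        "mean_connectivity": rank_sum_test(means_pos, means_neg),
        "sd_connectivity": rank_sum_test(sds_pos, sds_neg),
    }

    if config.classifier == "svc":
        fitter = lambda x, y: fit_linear_svc(x, y, C=config.svc_C)  # noqa: E731
    else:
        fitter = fit_lda
    line = fitter(points, labels)
    ids = [f.patient_id for f in features]
    report = loo_evaluate(points, labels, fitter, patient_ids=ids)
    perm_seed = int((np.random.SeedSequence(config.seed).generate_state(2) & 0x7FFFFFFF)[1])
    perm = permutation_test(
        points, labels, n_permutations=config.n_permutations,
        seed=perm_seed, fitter=fitter,
    )
    log.info(
        "classification: acc=%.3f sens=%.3f spec=%.3f p_acc=%.4g",
        report.accuracy, report.sensitivity, report.specificity, perm.p_accuracy,
    )

    doc = {
        "software": {"package": "seegconn", "version": __version__},
        "config": config.analysis_dict(),
        "config_hash": config.config_hash(),
        "seeds": {"config": config.seed, "permutation": perm_seed},
        "separating_line": {
            "weights": [float(w) for w in line.weights],
            "offset": float(line.offset),
        },
        "loo_predictions": {
            pid: bool(p) for pid, p in zip(ids, report.predictions)
        },
        "counts": {"tp": report.tp, "fp": report.fp, "tn": report.tn, "fn": report.fn},
        "metrics": report.metrics(),
        "permutation": {
            "n_permutations": perm.n_permutations,
            "p_sensitivity": perm.p_sensitivity,
            "p_specificity": perm.p_specificity,
            "p_accuracy": perm.p_accuracy,
        },
        "rank_sum": {
            k: {"statistic": v[0], "p_two_sided": v[1]} for k, v in rank_sum.items()
        },
    }
    (out / "report.json").write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        features=features,
        report=report,
        permutation=perm,
        line_weights=line.weights,
        line_offset=line.offset,
        rank_sum=rank_sum,
        output_dir=out,
    )
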