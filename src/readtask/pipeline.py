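"""End-to-end orchestration: extract → assemble → cross-validate.

`extract_cohort` turns a synthetic (or loaded) cohort into the shared
per-segment feature table plus the two fluency images per segment;
`run_pipeline` evaluates the speech-only, video-only and fused feature
selections with both classifiers under the repeated-CV protocol, retraining
the RRF heads inside each training fold.
"""
from __future__ import annotations

import logging
import time

import pandas as pd

from . import audio as audio_mod
from . import head as head_mod
from . import mouth as mouth_mod
from .config import PipelineConfig
from .datatypes import AudioSignal, FrameParams, LandmarkSequence, ReadingMeta
from .evaluate import FEATURE_SELECTIONS, CVConfig, EvalReport, cross_validate
from .rrf import RRFFoldExtractor
from .synthetic import SyntheticCohort

__all__ = ["extract_segment", "extract_cohort", "run_pipeline"]

log = logging.getLogger(__name__)


def extract_segment(
    signal: AudioSignal,
    lm: LandmarkSequence,
    meta: ReadingMeta,
    config: PipelineConfig | None = None,
):
    """All per-segment features plus the two fluency images.

    Returns (features: dict, map_image, spectrogram_image).
    """
    config = config or PipelineConfig()
    params = FrameParams.from_seconds(signal.rate, config.frame_s, config.hop_s)
    feats = audio_mod.acoustic_features(
        signal, params, intensity_convention=config.intensity_convention
    )
    feats.update(
        head_mod.head_features(
            lm, meta, dead_band=config.dead_band_px, min_run=config.min_run_frames
        )
    )
    mar = mouth_mod.mar_sequence(lm)
    map_img = mouth_mod.time_domain_map(mar, out_size=config.image_side)
    spec_img = mouth_mod.spectrogram_3d(
        mar,
        out_size=config.image_side,
        segment_s=config.stft_segment_s,
        hop_s=config.stft_hop_s,
    )
    return feats, map_img, spec_img


def extract_cohort(
    cohort: SyntheticCohort,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, list, list]:
    """Per-segment feature table and fluency images for a whole cohort.

    The table has one row per (subject, segment) with the acoustic and
    head-movement columns plus the group label; the two image lists align
    with the table rows.
    """
    config = config or PipelineConfig()
    rows, map_images, spec_images = [], [], []
    t0 = time.time()
    for subject in cohort.subjects:
        for j in range(cohort.spec.segments_per_subject):
            seg = subject.segment(j)
            feats, map_img, spec_img = extract_segment(
                seg.audio, seg.landmarks, seg.meta, config
            )
            rows.append(
                {"subject": subject.subject_id, "segment": j, "label": subject.label, **feats}
            )
            map_images.append(map_img)
            spec_images.append(spec_img)
    log.info(
        "extracted %d segments from %d subjects in %.1f s",
        len(rows), len(cohort.subjects), time.time() - t0,
    )
    return pd.DataFrame(rows), map_images, spec_images


def run_pipeline(
    cohort: SyntheticCohort,
    config: PipelineConfig | None = None,
    selections: tuple[str, ...] = ("speech", "video", "fused"),
    classifiers: tuple[str, ...] = ("svm", "rf"),
) -> tuple[dict[str, dict[str, EvalReport]], pd.DataFrame]:
    """Extract features and evaluate every (selection, classifier) pair.

    Returns ({selection: {classifier: EvalReport}}, feature_table).  RRF
    heads are retrained on each CV training fold, so no test segment ever
    influences the embedding that represents it.
    """
    config = config or PipelineConfig()
    table, map_images, spec_images = extract_cohort(cohort, config)
    labels = table["label"].to_numpy()
    extractor = None
    needs_rrf = any(
        any(c.startswith("rrf") for c in FEATURE_SELECTIONS[s]) for s in selections
    )
    if needs_rrf:
        extractor = RRFFoldExtractor(
            map_images, spec_images, labels, spec=config.backbone, cfg=config.train
        )
    cv = CVConfig(
        folds=config.cv.folds,
        repeats=config.cv.repeats,
        stratified=config.cv.stratified,
        seed=config.seed if config.cv.seed == 0 else config.cv.seed,
        group_by_subject=config.cv.group_by_subject,
    )
    reports: dict[str, dict[str, EvalReport]] = {}
    for sel in selections:
        cols = FEATURE_SELECTIONS[sel]
        reports[sel] = {}
        for clf in classifiers:
            t0 = time.time()
            report = cross_validate(
                table, classifier=clf, cfg=cv, feature_cols=cols,
                rrf_extractor=extractor,
            )
            log.info(
                "%s / %s: acc=%.2f%% auc=%.2f%% (%.1f s)",
                sel, clf, report.summary["accuracy"], report.summary["auc"],
                time.time() - t0,
            )
            reports[sel][clf] = report
    return reports, table


def report_frame(reports: dict[str, dict[str, EvalReport]]) -> pd.DataFrame:
    """Flatten nested evaluation reports into one tidy DataFrame."""
    rows = []
    for sel, by_clf in reports.items():
        for clf, rep in by_clf.items():
            rows.append({"selection": sel, "classifier": clf, **rep.summary})
    return pd.DataFrame(rows)
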