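"""Portable end-to-end predictor bundles (``*.imseeker`` files).

A bundle is a ZIP archive holding everything needed to go from raw DNA to
scored i-motifs: ``manifest.json`` (detection parameters, ordered feature
names, normalization vectors, label calibration range and provenance — a
standalone, cross-language contract), ``model.bin`` (the fitted pipeline as
an opaque, format-tagged byte stream) and ``checksum`` (SHA-256 of both
members; loading refuses tampered archives).  Predictions after a
save/load round trip are bit-identical to the in-memory pipeline's.

The stability score of a motif is the predicted label min-max calibrated
against the training-label range and clamped to [0, 1].
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import asdict, dataclass, replace
from datetime import datetime, timezone
from typing import List, Optional, Sequence, Tuple

import joblib
import numpy as np

from .automl.workflow import AutoMLRun
from .detect import DetectionParams, IMotifCandidate, scan
from .features import (FEATURE_NAMES, Normalizer, apply_normalizer,
                       feature_matrix)

__all__ = ["ModelBundle", "ScoredMotif", "BundleError", "build_bundle",
           "save_bundle", "load_bundle", "score_sequence"]

SCHEMA_VERSION = 1
MODEL_FORMAT = "joblib-pickle"


class BundleError(ValueError):
    """Raised for inconsistent, tampered or unsupported bundle files."""


@dataclass(frozen=True)
class ScoredMotif:
    candidate: IMotifCandidate
    predicted_label: float
    stability_score: float


@dataclass
class ModelBundle:
    """Self-contained end-to-end predictor."""

    detection_params: DetectionParams
    feature_names: Tuple[str, ...]
    normalizer: Normalizer
    model_family: str
    pipeline: object  # fitted sklearn pipeline
    label_kind: str
    label_min: float
    label_max: float
    schema_version: int = SCHEMA_VERSION
    created: str = ""
    provenance: str = ""

    def __post_init__(self):
        if not self.feature_names:
            raise BundleError("feature_names must be non-empty")
        unknown = set(self.feature_names) - set(FEATURE_NAMES)
        if unknown:
            raise BundleError(f"unknown feature names: {sorted(unknown)}")
        if not self.label_min < self.label_max:
            raise BundleError("label_min must be < label_max")
        if self.normalizer.n_features != len(self.feature_names):
            raise BundleError("normalizer width does not match feature count")


def build_bundle(run: AutoMLRun, detection_params: Optional[DetectionParams]
                 = None, label_kind: str = "transition pH") -> ModelBundle:
    """Assemble a bundle from a finished AutoML run."""
    if detection_params is None:
        detection_params = DetectionParams()
    report = run.report()
    digest = hashlib.sha256(
        json.dumps(report, sort_keys=True, default=str).encode()).hexdigest()
    return ModelBundle(
        detection_params=detection_params,
        feature_names=tuple(run.feature_names),
        normalizer=run.normalizer,
        model_family=run.result.best_config.model,
        pipeline=run.fitted.pipeline,
        label_kind=label_kind,
        label_min=run.label_min,
        label_max=run.label_max,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        provenance=f"sha256:{digest}",
    )


def _manifest(bundle: ModelBundle) -> dict:
    return {
        "schema_version": bundle.schema_version,
        "detection_params": asdict(bundle.detection_params),
        "feature_names": list(bundle.feature_names),
        "normalizer": {
            "method": bundle.normalizer.method,
            "center": bundle.normalizer.center.tolist(),
            "scale": bundle.normalizer.scale.tolist(),
            "constant": bundle.normalizer.constant.tolist(),
        },
        "model_family": bundle.model_family,
        "model_format": MODEL_FORMAT,
        "label_kind": bundle.label_kind,
        "label_min": bundle.label_min,
        "label_max": bundle.label_max,
        "created": bundle.created,
        "provenance": bundle.provenance,
    }


def save_bundle(bundle: ModelBundle, path: str) -> str:
    """Write the bundle as a ZIP archive; returns the path."""
    manifest = json.dumps(_manifest(bundle), indent=2, sort_keys=True)
    blob = io.BytesIO()
    joblib.dump(bundle.pipeline, blob)
    model_bytes = blob.getvalue()
    checksum = json.dumps({
        "manifest.json": hashlib.sha256(manifest.encode()).hexdigest(),
        "model.bin": hashlib.sha256(model_bytes).hexdigest(),
    }, indent=2, sort_keys=True)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", manifest)
        zf.writestr("model.bin", model_bytes)
        zf.writestr("checksum", checksum)
    return path


def load_bundle(path: str) -> ModelBundle:
    """Load and checksum-verify a bundle file."""
    try:
        with zipfile.ZipFile(path) as zf:
            manifest_raw = zf.read("manifest.json")
            model_bytes = zf.read("model.bin")
            checksum = json.loads(zf.read("checksum"))
    except (zipfile.BadZipFile, KeyError) as exc:
        raise BundleError(f"not a readable bundle: {exc}") from exc
    if (hashlib.sha256(manifest_raw).hexdigest() != checksum.get("manifest.json")
            or hashlib.sha256(model_bytes).hexdigest() != checksum.get("model.bin")):
        raise BundleError("checksum mismatch: bundle corrupted or tampered")
    man = json.loads(manifest_raw)
    if man["schema_version"] > SCHEMA_VERSION:
        raise BundleError(
            f"bundle schema {man['schema_version']} is newer than this "
            f"reader (supports <= {SCHEMA_VERSION})")
    if man["model_format"] != MODEL_FORMAT:
        raise BundleError(f"unsupported model format {man['model_format']!r}")
    norm = Normalizer(center=np.asarray(man["normalizer"]["center"]),
                      scale=np.asarray(man["normalizer"]["scale"]),
                      method=man["normalizer"]["method"],
                      constant=np.asarray(man["normalizer"]["constant"],
                                          dtype=bool))
    pipeline = joblib.load(io.BytesIO(model_bytes))
    return ModelBundle(
        detection_params=DetectionParams(**man["detection_params"]),
        feature_names=tuple(man["feature_names"]),
        normalizer=norm,
        model_family=man["model_family"],
        pipeline=pipeline,
        label_kind=man["label_kind"],
        label_min=man["label_min"],
        label_max=man["label_max"],
        schema_version=man["schema_version"],
        created=man["created"],
        provenance=man["provenance"],
    )


def _predict(bundle: ModelBundle,
             candidates: Sequence[IMotifCandidate]) -> np.ndarray:
    X = feature_matrix(candidates)[list(bundle.feature_names)].to_numpy()
    Xn = apply_normalizer(bundle.normalizer, X)
    return np.asarray(bundle.pipeline.predict(Xn), dtype=float)


def score_candidates(bundle: ModelBundle,
                     candidates: Sequence[IMotifCandidate]
                     ) -> List[ScoredMotif]:
    if not candidates:
        return []
    preds = _predict(bundle, candidates)
    span = bundle.label_max - bundle.label_min
    out = []
    for cand, pred in zip(candidates, preds):
        score = float(np.clip((pred - bundle.label_min) / span, 0.0, 1.0))
        out.append(ScoredMotif(candidate=cand, predicted_label=float(pred),
                               stability_score=score))
    return out


def score_sequence(bundle: ModelBundle, dna: str,
                   seq_id: str = "query") -> List[ScoredMotif]:
    """Detect, featurize and score every i-motif in a DNA string."""
    cands = list(scan([(seq_id, dna)], bundle.detection_params))
    return score_candidates(bundle, cands)
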