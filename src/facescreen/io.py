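"""File formats, run configuration and the end-to-end pipeline driver.

Readers and writers cover the extractor-style per-frame CSV formats (AU
intensities, mesh landmarks) and a single YAML/JSON run configuration from
which both pipelines — mesh -> PCA -> recurrent classifier and AU -> clips
-> SVM -> voting — can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from . import au as au_mod
from . import evaluate, mesh, seqmodel, synthetic
from .au import AUSequence
from .mesh import MeshSequence

__all__ = [
    "RunConfig",
    "read_au_csv",
    "write_au_csv",
    "read_mesh_csv",
    "write_mesh_csv",
    "run_pipeline",
]

logger = logging.getLogger("facescreen")


# --------------------------------------------------------------------------
# CSV formats
# --------------------------------------------------------------------------

def write_au_csv(seq: AUSequence, path: str | Path, frame_rate: float = 30.0) -> None:
    """OpenFace-style per-frame AU CSV: frame, timestamp, <AU>_r columns.

    Floats are written with Python's shortest round-trip representation, so
    reading the file back reproduces the array bit-exactly.
    """
    frames = np.arange(1, seq.n_frames + 1)
    data = {"frame": frames, "timestamp": (frames - 1) / frame_rate}
    for j, au_id in enumerate(seq.au_ids):
        data[f"{au_id}_r"] = seq.values[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_au_csv(
    path: str | Path,
    au_ids: tuple[str, ...] = au_mod.AU_INTENSITY_IDS,
    column_table: Mapping[str, str] | None = None,
) -> AUSequence:
    """Read an OpenFace-style AU intensity CSV.

    ``column_table`` maps AU identifiers to CSV column names (default
    ``<AU>_r``).  Unrelated columns are ignored; values outside [0, 5] are
    clipped with a warning reporting how many cells were affected.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    table = column_table or {au_id: f"{au_id}_r" for au_id in au_ids}
    columns = []
    for au_id in au_ids:
        col = table.get(au_id, f"{au_id}_r")
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
        columns.append(col)
    block = df[columns]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & block.notna()
    if bad.to_numpy().any():
        row = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise ValueError(f"{path.name}: non-numeric AU cell in data row {row}")
    if numeric.isna().to_numpy().any():
        row = int(np.argmax(numeric.isna().any(axis=1).to_numpy()))
        raise ValueError(f"{path.name}: missing AU value in data row {row}")
    values = numeric.to_numpy(dtype=float)
    out_of_range = int(np.sum((values < 0.0) | (values > 5.0)))
    if out_of_range:
        warnings.warn(
            f"{path.name}: clipped {out_of_range} AU values to the [0, 5] scale",
            stacklevel=2,
        )
        values = np.clip(values, 0.0, 5.0)
    extra = [c for c in df.columns if c not in set(columns) | {"frame", "timestamp"}]
    if extra:
        logger.debug("%s: ignoring unrelated columns %s", path.name, extra)
    return AUSequence(values, tuple(au_ids))


def write_mesh_csv(seq: MeshSequence, path: str | Path) -> None:
    """Per-frame landmark CSV with x/y/z/v interleaved per landmark."""
    n = seq.n_landmarks
    vis = seq.visibility if seq.visibility is not None else np.ones(seq.coords.shape[:2])
    wide = np.concatenate([seq.coords, vis[:, :, None]], axis=2).reshape(seq.n_frames, n * 4)
    columns = [f"{axis}{i}" for i in range(n) for axis in ("x", "y", "z", "v")]
    pd.DataFrame(wide, columns=columns).to_csv(path, index=False)


def read_mesh_csv(path: str | Path, frame_rate: float = 30.0) -> MeshSequence:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] % 4:
        raise ValueError(f"{Path(path).name}: column count is not a multiple of 4")
    n = df.shape[1] // 4
    wide = df.to_numpy(dtype=float).reshape(len(df), n, 4)
    return MeshSequence(wide[:, :, :3], wide[:, :, 3], frame_rate=frame_rate)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshSettings:
    center_index: int = mesh.DEFAULT_CENTER_INDEX
    pca_k: int = 16


@dataclass(frozen=True)
class AUSettings:
    segment_len: int | Literal["all"] = 1024
    au_mode: Literal["all17", "significant11"] = "all17"
    variance_estimator: Literal["population", "sample"] = "population"


@dataclass(frozen=True)
class EvalSettings:
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    vote_polarity: Literal["dementia", "healthy"] = "dementia"


@dataclass(frozen=True)
class SeqSettings:
    hidden_dim: int = 32
    learning_rate: float = 0.001
    batch_size: int | Literal["full"] = "full"
    epochs: int = 20
    test_fraction: float = 0.3


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    mesh: MeshSettings = field(default_factory=MeshSettings)
    au: AUSettings = field(default_factory=AUSettings)
    eval: EvalSettings = field(default_factory=EvalSettings)
    seq: SeqSettings = field(default_factory=SeqSettings)
    branches: tuple[str, ...] = ("au",)
    out_dir: str = "runs/latest"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.branches) - {"au", "mesh"}
        if unknown:
            raise ValueError(f"unknown branches: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        def build(klass, payload):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**_tuplify(klass, payload))

        payload = dict(data)
        nested = {
            "cohort": synthetic.CohortConfig,
            "mesh": MeshSettings,
            "au": AUSettings,
            "eval": EvalSettings,
            "seq": SeqSettings,
        }
        kwargs = {}
        for key, klass in nested.items():
            if key in payload:
                kwargs[key] = build(klass, payload.pop(key))
        if "branches" in payload:
            kwargs["branches"] = tuple(payload.pop("branches"))
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - names
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs.update(payload)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir", None)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _tuplify(klass, payload: Mapping) -> dict:
    """YAML has no tuples; coerce list-valued fields whose defaults are tuples."""
    out = dict(payload)
    for f in dataclasses.fields(klass):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


# --------------------------------------------------------------------------
# Pipeline driver
# --------------------------------------------------------------------------

def _stage_seed(config: RunConfig, stage: str) -> int:
    """Derive a stage seed from the run seed by a keyed hash."""
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _run_au_branch(config: RunConfig, cohort: synthetic.Cohort, out: Path) -> dict:
    subset = au_mod.select_au_subset(config.au.au_mode)
    table = au_mod.cohort_feature_table(
        cohort, config.au.segment_len, subset, variance=config.au.variance_estimator
    )
    table.to_csv(out / "clip_features.csv", index=False)
    svm_cfg = evaluate.SVMConfig(C=config.eval.svm_c, gamma=config.eval.svm_gamma)
    result = evaluate.loso_evaluate(table, svm_cfg, polarity=config.eval.vote_polarity)
    preds, sweep, metrics = result["predictions"], result["sweep"], result["metrics"]
    decisions = pd.DataFrame(
        {
            "subject_id": preds.subjects,
            "label": [preds.labels[s] for s in preds.subjects],
            "dementia_fraction": [preds.fractions[s] for s in preds.subjects],
            "decision": [result["decisions"][s] for s in preds.subjects],
        }
    )
    decisions.to_csv(out / "subject_decisions.csv", index=False)
    report = {
        "n_clips": int(len(table)),
        "fractions": preds.fractions,
        "best_threshold": sweep.best_threshold,
        "eer_threshold": sweep.eer_threshold,
        "metrics": dataclasses.asdict(metrics),
        "sweep": sweep.table.to_dict(orient="records"),
    }
    (out / "au_report.json").write_text(json.dumps(report, indent=2))
    return report


def _run_mesh_branch(config: RunConfig, cohort: synthetic.Cohort, out: Path) -> dict:
    train, test = seqmodel.subject_disjoint_split(
        cohort, config.seq.test_fraction, _stage_seed(config, "split")
    )
    norm = {
        s.session_id: mesh.normalize_sequence(s.mesh, config.mesh.center_index)
        for s in (*train, *test)
    }
    pooled = np.vstack([norm[s.session_id] for s in train])
    model = mesh.fit_pca(pooled, config.mesh.pca_k)
    model.save(out / "pca_model.json", config={"center_index": config.mesh.center_index})
    variance_table = mesh.explained_variance_table(model)
    variance_table.to_csv(out / "explained_variance.csv", index=False)
    seq_cfg = seqmodel.SeqModelConfig(
        input_dim=config.mesh.pca_k,
        hidden_dim=config.seq.hidden_dim,
        learning_rate=config.seq.learning_rate,
        batch_size=config.seq.batch_size,
        epochs=config.seq.epochs,
        seed=_stage_seed(config, "seqmodel"),
    )
    trained = seqmodel.train_sequence_classifier(
        [mesh.transform_pca(model, norm[s.session_id]) for s in train],
        [s.label for s in train],
        seq_cfg,
    )
    (out / "seq_model.json").write_text(json.dumps(seqmodel.model_to_dict(trained)))
    probs, pred = seqmodel.predict_subjectwise(
        trained, [mesh.transform_pca(model, norm[s.session_id]) for s in test]
    )
    truth = np.array([s.label == synthetic.DEMENTIA for s in test], dtype=int)
    report = {
        "n_train_sessions": len(train),
        "n_test_sessions": len(test),
        "cumulative_explained_variance": variance_table[
            "cumulative_explained_variance"
        ].tolist(),
        "test_accuracy": float((pred == truth).mean()),
        "final_training_loss": trained.training_log[-1],
    }
    (out / "mesh_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Generate the cohort, run the configured branches, write a report.

    The report is fully determined by the config (timestamps are isolated
    in the single ``generated_at`` field).  A failing stage aborts with the
    stage name; partial outputs are flagged by an ``incomplete`` marker
    file in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "incomplete"
    marker.write_text("run in progress")
    cohort_cfg = dataclasses.replace(config.cohort, seed=_stage_seed(config, "cohort"))
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "branches": list(config.branches),
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    stage = "generate"
    try:
        logger.info("stage=%s seed=%s config=%s", stage, config.seed, config.config_hash())
        needed = set()
        if "au" in config.branches:
            needed.add("au")
        if "mesh" in config.branches:
            needed.add("mesh")
        cohort = synthetic.generate_cohort(
            dataclasses.replace(cohort_cfg, streams=tuple(sorted(needed)))
        )
        report["n_sessions"] = len(cohort)
        report["n_subjects"] = len(cohort.subject_labels)
        if "au" in config.branches:
            stage = "au_branch"
            logger.info("stage=%s seed=%s config=%s", stage, config.seed, config.config_hash())
            report["au"] = _run_au_branch(config, cohort, out)
        if "mesh" in config.branches:
            stage = "mesh_branch"
            logger.info("stage=%s seed=%s config=%s", stage, config.seed, config.config_hash())
            report["mesh"] = _run_mesh_branch(config, cohort, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    marker.unlink()
    (out / "report.json").write_text(json.dumps(report, indent=2))
    config.to_yaml(out / "config.yaml")
    return report
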