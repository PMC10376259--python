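"""Synthetic cohorts of per-subject, per-session facial-feature streams.

The generator emulates the statistical structure of a clinical interview
corpus — subjects contributing a variable number of ~10-minute, 30 FPS
sessions with a binary label — without any real video: action-unit
intensity channels follow an autocorrelated baseline whose per-channel mean
and variance shift for the positive class; mesh sessions are a fixed face
template plus smooth motion, observed under a random per-session camera
translation and scale; appearance descriptors carry an optional dynamic
class signal and an optional class-correlated constant offset that mimics
institutional bias.

Randomness is organized as keyed substreams of one global seed, so that
adding subjects or streams never perturbs previously generated data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .au import AU_INTENSITY_IDS, AUSequence
from .mesh import MeshSequence

__all__ = [
    "HEALTHY",
    "DEMENTIA",
    "LABELS",
    "CohortConfig",
    "Session",
    "Cohort",
    "hog_descriptor_length",
    "session_frame_count",
    "face_template",
    "generate_au_sequence",
    "generate_mesh_sequence",
    "generate_appearance_sequence",
    "generate_cohort",
    "write_cohort",
]

HEALTHY = "healthy"
DEMENTIA = "dementia"
LABELS = (HEALTHY, DEMENTIA)

# Substream codes for the keyed seeding scheme.
_STREAM_SESSION_COUNT = 0
_STREAM_AU = 1
_STREAM_MESH = 2
_STREAM_APPEARANCE = 3


def hog_descriptor_length(blocks_x: int = 12, blocks_y: int = 12, n_bins: int = 31) -> int:
    """Length of a per-frame appearance descriptor built from a grid of
    ``blocks_x`` x ``blocks_y`` blocks with ``n_bins``-bin histograms."""
    return blocks_x * blocks_y * n_bins


def session_frame_count(minutes: float = 10.0, fps: float = 30.0) -> int:
    """Number of frames in a session of the given duration and frame rate."""
    return int(round(minutes * 60.0 * fps))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``au_mean_shift`` and ``au_var_scale`` describe how the dementia class
    deviates from the healthy baseline process per AU channel (scalars
    broadcast to all channels).  ``mesh_motion_scale`` holds per-class
    motion amplitudes as ``(healthy, dementia)``.
    """

    n_subjects_per_class: int = 10
    sessions_per_subject_range: tuple[int, int] = (1, 10)
    frames_per_session: int = session_frame_count()
    n_landmarks: int = 478
    n_au: int = len(AU_INTENSITY_IDS)
    n_appearance_dims: int = hog_descriptor_length()
    au_mean_shift: float | tuple[float, ...] = 0.0
    au_var_scale: float | tuple[float, ...] = 1.0
    mesh_motion_scale: tuple[float, float] = (0.02, 0.02)
    noise_sd: float = 0.005
    seed: int = 0
    # Healthy AU baseline process: stationary AR(1) per channel.
    au_baseline_mean: float = 2.0
    au_baseline_sd: float = 0.4
    au_ar_coef: float = 0.9
    # Appearance-stream knobs: a per-frame class signal on the first
    # `appearance_signal_dims` dimensions and a constant class-correlated
    # offset ("institutional bias") on the last `appearance_bias_dims`.
    appearance_signal: float = 0.0
    appearance_signal_dims: int = 8
    appearance_bias: float = 0.0
    appearance_bias_dims: int = 8
    appearance_baseline: float = 1.0
    appearance_noise_sd: float = 1.0
    # Which streams generate_cohort materializes for every session.
    streams: tuple[str, ...] = ("au",)
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.sessions_per_subject_range
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if not (1 <= lo <= hi):
            raise ValueError("sessions_per_subject_range must satisfy 1 <= min <= max")
        for name in ("frames_per_session", "n_landmarks", "n_au", "n_appearance_dims"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if np.any(np.asarray(self.au_var_scale) <= 0):
            raise ValueError("au_var_scale entries must be > 0")
        if np.any(np.asarray(self.mesh_motion_scale) <= 0):
            raise ValueError("mesh_motion_scale entries must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.streams) - {"au", "mesh", "appearance"}
        if unknown:
            raise ValueError(f"unknown streams: {sorted(unknown)}")

    def au_ids(self) -> tuple[str, ...]:
        if self.n_au == len(AU_INTENSITY_IDS):
            return AU_INTENSITY_IDS
        return tuple(f"AU{k:02d}" for k in range(1, self.n_au + 1))


@dataclass(frozen=True)
class Session:
    """One recording session of one subject; the unit of split hygiene."""

    subject_id: str
    session_id: str
    label: str
    mesh: MeshSequence | None = None
    au: AUSequence | None = None
    appearance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        counts = {
            name: stream.n_frames if hasattr(stream, "n_frames") else stream.shape[0]
            for name, stream in (
                ("mesh", self.mesh), ("au", self.au), ("appearance", self.appearance)
            )
            if stream is not None
        }
        if len(set(counts.values())) > 1:
            raise ValueError(f"streams of one session must share a frame count, got {counts}")


@dataclass(frozen=True)
class Cohort:
    """Ordered sessions plus a per-subject label index."""

    sessions: tuple[Session, ...]

    def __post_init__(self) -> None:
        labels: dict[str, str] = {}
        counts: dict[str, int] = {}
        for s in self.sessions:
            if labels.setdefault(s.subject_id, s.label) != s.label:
                raise ValueError(f"subject {s.subject_id!r} carries two labels")
            counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
        object.__setattr__(self, "_labels", labels)

    def __iter__(self) -> Iterator[Session]:
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def subject_labels(self) -> dict[str, str]:
        return dict(self._labels)  # type: ignore[attr-defined]

    def subjects(self, label: str | None = None) -> list[str]:
        labels = self.subject_labels
        return [s for s, l in labels.items() if label is None or l == label]

    def sessions_for(self, subject_id: str) -> list[Session]:
        return [s for s in self.sessions if s.subject_id == subject_id]


def _rng(cfg: CohortConfig, *key: int) -> np.random.Generator:
    """Keyed substream of the cohort seed; independent per (key) tuple."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(cfg.seed), *key])))


def _class_index(class_label: str) -> int:
    if class_label not in LABELS:
        raise ValueError(f"class label must be one of {LABELS}, got {class_label!r}")
    return LABELS.index(class_label)


def generate_au_sequence(
    class_label: str, cfg: CohortConfig, rng: np.random.Generator
) -> AUSequence:
    """Draw one session's AU intensities.

    The healthy baseline is a stationary AR(1) process per channel (mean
    ``au_baseline_mean``, sd ``au_baseline_sd``, lag-1 coefficient
    ``au_ar_coef``); the dementia class shifts the mean by ``au_mean_shift``
    and multiplies the variance by ``au_var_scale``.  Values are clipped to
    the [0, 5] intensity scale after generation, so realized moments can
    deviate near the bounds.
    """
    is_case = _class_index(class_label) == 1
    shift = np.broadcast_to(np.asarray(cfg.au_mean_shift, dtype=float), (cfg.n_au,))
    var_scale = np.broadcast_to(np.asarray(cfg.au_var_scale, dtype=float), (cfg.n_au,))
    mu = cfg.au_baseline_mean + (shift if is_case else 0.0)
    sd = cfg.au_baseline_sd * (np.sqrt(var_scale) if is_case else 1.0)
    phi = cfg.au_ar_coef
    T = cfg.frames_per_session
    # Stationary AR(1): innovations scaled so the marginal sd equals `sd`.
    innov = rng.normal(0.0, 1.0, size=(T, cfg.n_au)) * (sd * np.sqrt(1.0 - phi**2))
    dev0 = rng.normal(0.0, 1.0, size=cfg.n_au) * sd
    dev, _ = lfilter([1.0], [1.0, -phi], innov, axis=0, zi=(phi * dev0)[None, :])
    values = np.clip(mu + dev, 0.0, 5.0)
    return AUSequence(values, cfg.au_ids())


_TEMPLATE_SEED = (734,)  # fixed entropy for the shared face template


def face_template(n_landmarks: int = 478) -> np.ndarray:
    """Deterministic face-like landmark template, roughly in [-1, 1]^3."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([*_TEMPLATE_SEED, n_landmarks])))
    # Points scattered over a flattened ellipsoid front: plausible depth
    # profile without modeling anatomy.
    theta = rng.uniform(0, 2 * np.pi, n_landmarks)
    r = np.sqrt(rng.uniform(0, 1, n_landmarks))
    x = r * np.cos(theta)
    y = 1.3 * r * np.sin(theta)
    z = 0.4 * (1 - r**2) + rng.normal(0, 0.02, n_landmarks)
    return np.column_stack([x, y, z])


def generate_mesh_sequence(
    class_label: str,
    cfg: CohortConfig,
    rng: np.random.Generator,
    transform: tuple[float, np.ndarray] | None = None,
) -> MeshSequence:
    """Draw one session's mesh frames.

    Frames are the shared template plus smooth sinusoidal per-landmark
    motion (amplitude given by the class entry of ``mesh_motion_scale``)
    plus white noise, then observed under a per-session camera transform
    (isotropic scale, global translation).  Pass ``transform=(scale,
    translation)`` to fix the camera; by default it is drawn from ``rng``
    after the motion, so identical rngs yield identical motion regardless
    of the transform.
    """
    amp = cfg.mesh_motion_scale[_class_index(class_label)]
    T, L = cfg.frames_per_session, cfg.n_landmarks
    template = face_template(L)
    t = np.arange(T)[:, None, None] / cfg.frame_rate
    freq = rng.uniform(0.1, 2.0, size=(1, L, 3))
    phase = rng.uniform(0, 2 * np.pi, size=(1, L, 3))
    motion = amp * np.sin(2 * np.pi * freq * t + phase)
    noise = rng.normal(0.0, cfg.noise_sd, size=(T, L, 3)) if cfg.noise_sd > 0 else 0.0
    coords = template[None, :, :] + motion + noise
    if transform is None:
        scale = rng.uniform(0.5, 2.0)
        translation = rng.uniform(-5.0, 5.0, size=3)
    else:
        scale, translation = transform
        translation = np.asarray(translation, dtype=float)
        if scale <= 0:
            raise ValueError("session transform scale must be positive")
    coords = coords * scale + translation
    visibility = np.ones((T, L))
    return MeshSequence(coords, visibility, frame_rate=cfg.frame_rate)


def generate_appearance_sequence(
    class_label: str, cfg: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one session's appearance descriptors, shape (frames, dims).

    Values are a nonnegative baseline plus frame-wise noise.  The dementia
    class additionally receives a per-frame mean shift of
    ``appearance_signal`` on the leading ``appearance_signal_dims``
    dimensions (dynamic class signal) and a constant offset of
    ``appearance_bias`` on the trailing ``appearance_bias_dims``
    (environment confound).  Output is clipped at zero, matching
    nonnegative gradient-histogram magnitudes.
    """
    is_case = _class_index(class_label) == 1
    T, D = cfg.frames_per_session, cfg.n_appearance_dims
    values = cfg.appearance_baseline + rng.normal(0.0, cfg.appearance_noise_sd, size=(T, D))
    if is_case:
        k = min(cfg.appearance_signal_dims, D)
        values[:, :k] += cfg.appearance_signal
        b = min(cfg.appearance_bias_dims, D)
        if b:
            values[:, D - b :] += cfg.appearance_bias
    return np.clip(values, 0.0, None)


def _subject_id(label: str, index: int) -> str:
    return f"{'D' if label == DEMENTIA else 'H'}{index:03d}"


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate the full cohort deterministically from ``cfg.seed``.

    Session counts per subject are uniform on
    ``sessions_per_subject_range``; class sizes are exactly
    ``n_subjects_per_class`` each.  Per-subject and per-session substreams
    derive from the global seed, so enlarging the cohort leaves existing
    subjects' data untouched.
    """
    lo, hi = cfg.sessions_per_subject_range
    sessions: list[Session] = []
    for class_idx, label in enumerate(LABELS):
        for subj_idx in range(cfg.n_subjects_per_class):
            subject = _subject_id(label, subj_idx)
            n_sessions = int(
                _rng(cfg, class_idx, subj_idx, _STREAM_SESSION_COUNT).integers(lo, hi + 1)
            )
            for sess_idx in range(n_sessions):
                key = (class_idx, subj_idx, sess_idx)
                au = mesh = appearance = None
                if "au" in cfg.streams:
                    au = generate_au_sequence(label, cfg, _rng(cfg, *key, _STREAM_AU))
                if "mesh" in cfg.streams:
                    mesh = generate_mesh_sequence(label, cfg, _rng(cfg, *key, _STREAM_MESH))
                if "appearance" in cfg.streams:
                    appearance = generate_appearance_sequence(
                        label, cfg, _rng(cfg, *key, _STREAM_APPEARANCE)
                    )
                sessions.append(
                    Session(subject, f"{subject}_s{sess_idx}", label, mesh, au, appearance)
                )
    return Cohort(tuple(sessions))


def write_cohort(cohort: Cohort, out_dir: str | Path, frame_rate: float = 30.0) -> Path:
    """Write a cohort to a directory: a metadata table plus per-session
    feature files (AU streams as OpenFace-style CSV)."""
    from .io import write_au_csv, write_mesh_csv  # local import avoids a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "session_id": s.session_id, "label": s.label}
            for s in cohort
        ]
    )
    meta.to_csv(out / "metadata.csv", index=False)
    for s in cohort:
        if s.au is not None:
            write_au_csv(s.au, out / f"{s.session_id}_au.csv", frame_rate=frame_rate)
        if s.mesh is not None:
            write_mesh_csv(s.mesh, out / f"{s.session_id}_mesh.csv")
        if s.appearance is not None:
            cols = [f"h{i}" for i in range(s.appearance.shape[1])]
            pd.DataFrame(s.appearance, columns=cols).to_csv(
                out / f"{s.session_id}_hog.csv", index=False
            )
    return out


def config_to_dict(cfg: CohortConfig) -> dict:
    return dataclasses.asdict(cfg)
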