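"""Action-unit intensity sequences and clip-level mean/variance features.

An :class:`AUSequence` holds per-frame intensities of facial action units
(AUs) on the 0-5 FACS scale.  Sessions are cut into fixed-length,
non-overlapping clips; each clip is summarised by the temporal mean and
variance of every selected channel, giving the feature vectors consumed by
the subject-level evaluator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AU_INTENSITY_IDS",
    "SIGNIFICANT_AU_POSITIONS",
    "AUSequence",
    "ClipFeature",
    "segment_sequence",
    "clip_features",
    "select_au_subset",
    "cohort_feature_table",
]

AU_SCALE = (0.0, 5.0)

#: The 17 AU intensity channels emitted by the OpenFace-style extractor,
#: in its column order.
AU_INTENSITY_IDS: tuple[str, ...] = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU45",
)

#: Published indices of the channels carrying a significant group
#: difference.  Interpreted as 1-based positions into the ordered
#: 17-channel list above; the mapping is a config table
#: (see :func:`select_au_subset`), not hard-wired semantics.
SIGNIFICANT_AU_POSITIONS: tuple[int, ...] = (2, 4, 5, 7, 8, 9, 10, 12, 14, 15, 16)

#: Default config table: printed 1-based position -> channel identifier.
DEFAULT_AU_INDEX_TABLE: Mapping[int, str] = {
    k + 1: au for k, au in enumerate(AU_INTENSITY_IDS)
}


@dataclass(frozen=True)
class AUSequence:
    """Time-ordered per-frame AU intensity vectors for one session.

    Parameters
    ----------
    values
        Array of shape ``(n_frames, n_au)``, each entry in ``[0, 5]``.
    au_ids
        Ordered channel identifiers, one per column.
    """

    values: np.ndarray
    au_ids: tuple[str, ...] = AU_INTENSITY_IDS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"AU values must be 2-D (frames x channels), got shape {values.shape}")
        if values.shape[1] != len(self.au_ids):
            raise ValueError(
                f"channel mismatch: {values.shape[1]} columns vs {len(self.au_ids)} au_ids"
            )
        lo, hi = AU_SCALE
        if values.size and (values.min() < lo or values.max() > hi):
            raise ValueError("AU intensities must lie within [0, 5]")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_au(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClipFeature:
    """Clip-level feature vector: per-channel means then variances."""

    subject_id: str
    session_id: str
    clip_index: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size % 2:
            raise ValueError("clip feature must be a flat mean||variance concatenation")
        half = values.size // 2
        if np.any(values[half:] < 0):
            raise ValueError("variances must be nonnegative")
        object.__setattr__(self, "values", values)


def segment_sequence(
    seq: AUSequence, segment_len: int | Literal["all"]
) -> list[AUSequence]:
    """Cut a sequence into consecutive non-overlapping fixed-length clips.

    The trailing remainder shorter than ``segment_len`` is discarded.
    ``"all"`` returns the whole sequence as a single clip.  A segment
    length exceeding the sequence yields zero clips with a warning.
    """
    if segment_len == "all":
        return [seq]
    segment_len = int(segment_len)
    if segment_len < 1:
        raise ValueError(f"segment_len must be >= 1 or 'all', got {segment_len}")
    n_clips = seq.n_frames // segment_len
    if n_clips == 0:
        warnings.warn(
            f"segment_len={segment_len} exceeds sequence length {seq.n_frames}; no clips produced",
            stacklevel=2,
        )
        return []
    return [
        AUSequence(seq.values[i * segment_len : (i + 1) * segment_len], seq.au_ids)
        for i in range(n_clips)
    ]


def clip_features(
    clip: AUSequence,
    au_subset: Sequence[str],
    variance: Literal["population", "sample"] = "population",
) -> np.ndarray:
    """Temporal mean and variance per selected channel over one clip.

    Returns all means in ``au_subset`` order followed by all variances,
    i.e. a vector of length ``2 * len(au_subset)``.  The default variance
    estimator divides by ``n`` (population); ``"sample"`` divides by
    ``n - 1``.
    """
    if clip.n_frames == 0:
        raise ValueError("cannot featurize an empty clip")
    subset = tuple(au_subset)
    if not subset:
        raise ValueError("au_subset must not be empty")
    missing = [au for au in subset if au not in clip.au_ids]
    if missing:
        raise ValueError(f"AU ids not present in sequence: {missing}")
    cols = [clip.au_ids.index(au) for au in subset]
    block = clip.values[:, cols]
    ddof = 0 if variance == "population" else 1
    return np.concatenate([block.mean(axis=0), block.var(axis=0, ddof=ddof)])


def select_au_subset(
    mode: Literal["all17", "significant11"],
    index_table: Mapping[int, str] | None = None,
) -> tuple[str, ...]:
    """Resolve an AU selection mode to concrete channel identifiers.

    ``all17`` returns every extracted intensity channel; ``significant11``
    maps the published index list through ``index_table`` (default: 1-based
    position in the extractor's channel order).
    """
    if mode == "all17":
        return AU_INTENSITY_IDS
    if mode == "significant11":
        table = DEFAULT_AU_INDEX_TABLE if index_table is None else index_table
        subset = []
        for pos in SIGNIFICANT_AU_POSITIONS:
            if pos not in table:
                raise ValueError(f"AU index {pos} missing from the index table")
            au = table[pos]
            if au not in AU_INTENSITY_IDS:
                raise ValueError(f"index table maps {pos} to unknown channel {au!r}")
            subset.append(au)
        return tuple(subset)
    raise ValueError(f"unknown AU subset mode {mode!r}")


def cohort_feature_table(
    cohort: "Iterable",
    segment_len: int | Literal["all"],
    au_subset: Sequence[str],
    variance: Literal["population", "sample"] = "population",
) -> pd.DataFrame:
    """Build the labeled clip-feature table for a whole cohort.

    One row per clip with ``subject_id``, ``session_id``, ``clip_index``,
    ``label`` carried through, then mean columns ``m_<AU>`` and variance
    columns ``v_<AU>``.
    """
    subset = tuple(au_subset)
    sessions = getattr(cohort, "sessions", cohort)
    rows: list[dict] = []
    for session in sessions:
        if session.au is None:
            raise ValueError(f"session {session.session_id!r} has no AU stream")
        for clip_index, clip in enumerate(segment_sequence(session.au, segment_len)):
            feats = clip_features(clip, subset, variance=variance)
            row: dict = {
                "subject_id": session.subject_id,
                "session_id": session.session_id,
                "clip_index": clip_index,
                "label": session.label,
            }
            half = len(subset)
            row.update({f"m_{au}": feats[i] for i, au in enumerate(subset)})
            row.update({f"v_{au}": feats[half + i] for i, au in enumerate(subset)})
            rows.append(row)
    columns = (
        ["subject_id", "session_id", "clip_index", "label"]
        + [f"m_{au}" for au in subset]
        + [f"v_{au}" for au in subset]
    )
    return pd.DataFrame(rows, columns=columns)
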