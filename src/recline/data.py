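"""Episode and dataset containers, normalization, segmentation and CSV I/O.

An *episode* is one subject's contiguous tri-axial recording held in a single
lying posture at one body site; it is the unit every classifier labels.
Accelerations are stored in g units (1 g = 9.81 m/s^2).  Episode files are
plain CSV (columns ``t,ax,ay,az``; ``t`` is optional and ignored for
computation) tied together by a manifest CSV with columns
``file,subject,site,posture,rate_hz``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from recline.errors import DegenerateInputError, ParseError, ValidationError

__all__ = [
    "AXES",
    "BodySite",
    "DEFAULT_LABELS",
    "Dataset",
    "Episode",
    "Recording",
    "integrate_datasets",
    "normalize_episode",
    "posture_axis_summary",
    "read_dataset",
    "resegment_episode",
    "segment_by_labels",
    "write_dataset",
]

AXES = ("x", "y", "z")

#: Canonical posture vocabulary, in tie-break order.
DEFAULT_LABELS = ("supine", "prone", "left", "right")


class BodySite(str, Enum):
    """The nine supported sensor wearing sites."""

    CHEST = "chest"
    THIGH_L = "thigh_L"
    THIGH_R = "thigh_R"
    ANKLE_L = "ankle_L"
    ANKLE_R = "ankle_R"
    ARM_L = "arm_L"
    ARM_R = "arm_R"
    WRIST_L = "wrist_L"
    WRIST_R = "wrist_R"


def _coerce_site(site: "BodySite | str") -> BodySite:
    try:
        return BodySite(site)
    except ValueError as exc:
        raise ValidationError(f"unknown body site {site!r}") from exc


def _coerce_samples(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError(
            f"samples must have shape (N, 3); got {arr.shape}"
        )
    if arr.shape[0] < 1:
        raise ValidationError("episode must contain at least one sample")
    if not np.isfinite(arr).all():
        raise ValidationError("samples contain non-finite values")
    return arr


@dataclass(frozen=True)
class Episode:
    """One contiguous tri-axial recording of a single posture.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    body_site
        One of the nine :class:`BodySite` values (strings accepted).
    posture
        Posture label; must belong to the dataset vocabulary when the
        episode is placed in a :class:`Dataset`.
    sampling_rate_hz
        Positive sampling rate.
    samples
        Array of shape ``(N, 3)`` holding per-sample (x, y, z) acceleration
        in g units.
    """

    subject_id: str
    body_site: BodySite
    posture: str
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "body_site", _coerce_site(self.body_site))
        object.__setattr__(self, "samples", _coerce_samples(self.samples))
        if not self.sampling_rate_hz > 0:
            raise ValidationError(
                f"sampling_rate_hz must be positive; got {self.sampling_rate_hz}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def axis(self, name: str) -> np.ndarray:
        """Return one axis series by name ('x', 'y' or 'z')."""
        return self.samples[:, AXES.index(name)]

    def with_samples(self, samples: np.ndarray) -> "Episode":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class Recording:
    """A raw continuous recording not yet split into posture episodes."""

    subject_id: str
    body_site: BodySite
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "body_site", _coerce_site(self.body_site))
        object.__setattr__(self, "samples", _coerce_samples(self.samples))
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")


@dataclass
class Dataset:
    """A named collection of episodes with an ordered label vocabulary."""

    name: str
    episodes: list[Episode] = field(default_factory=list)
    label_vocabulary: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        self.label_vocabulary = tuple(self.label_vocabulary)
        for ep in self.episodes:
            if ep.posture not in self.label_vocabulary:
                raise ValidationError(
                    f"episode posture {ep.posture!r} not in label vocabulary "
                    f"{self.label_vocabulary}"
                )

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)

    @property
    def subjects(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for ep in self.episodes:
            seen.setdefault(ep.subject_id, None)
        return list(seen)

    def filter(
        self,
        *,
        site: "BodySite | str | None" = None,
        subject_id: Optional[str] = None,
        posture: Optional[str] = None,
    ) -> "Dataset":
        """Return a shallow-filtered copy; keeps vocabulary and name."""
        eps = self.episodes
        if site is not None:
            s = _coerce_site(site)
            eps = [e for e in eps if e.body_site == s]
        if subject_id is not None:
            eps = [e for e in eps if e.subject_id == subject_id]
        if posture is not None:
            eps = [e for e in eps if e.posture == posture]
        return Dataset(self.name, list(eps), self.label_vocabulary)

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in self.label_vocabulary}
        for ep in self.episodes:
            counts[ep.posture] += 1
        return counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["file", "subject", "site", "posture", "rate_hz"]


def read_dataset(
    manifest_path: "str | os.PathLike",
    *,
    scale: float = 1.0,
    name: Optional[str] = None,
    label_vocabulary: Sequence[str] = DEFAULT_LABELS,
) -> Dataset:
    """Load a dataset from a manifest CSV.

    ``scale`` multiplies every acceleration value on read; use it to convert
    recordings stored on an m/s^2-like scale into g units (e.g.
    ``scale=1/9.81``).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ParseError(
            f"manifest {manifest_path} is missing columns {missing}"
        )
    episodes: list[Episode] = []
    base = manifest_path.parent
    vocab = tuple(label_vocabulary)
    for _, row in manifest.iterrows():
        posture = str(row["posture"])
        if posture not in vocab:
            raise ValidationError(
                f"unknown posture label {posture!r} in manifest "
                f"{manifest_path} (vocabulary: {vocab})"
            )
        ep_path = base / str(row["file"])
        if not ep_path.exists():
            raise FileNotFoundError(f"episode file not found: {ep_path}")
        table = pd.read_csv(ep_path)
        for col in ("ax", "ay", "az"):
            if col not in table.columns:
                raise ParseError(f"{ep_path}: missing column {col!r}")
        numeric = table[["ax", "ay", "az"]].apply(
            pd.to_numeric, errors="coerce"
        )
        bad = numeric.isna().any(axis=1)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{ep_path}: non-numeric acceleration value at data row {idx}"
            )
        episodes.append(
            Episode(
                subject_id=str(row["subject"]),
                body_site=str(row["site"]),
                posture=posture,
                sampling_rate_hz=float(row["rate_hz"]),
                samples=numeric.to_numpy() * scale,
            )
        )
    return Dataset(name or manifest_path.stem, episodes, vocab)


def write_dataset(dataset: Dataset, out_dir: "str | os.PathLike") -> Path:
    """Write episode CSVs plus a manifest; returns the manifest path.

    Values are printed with 12 significant digits, which round-trips float64
    accelerometer data to well below sensor resolution.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for i, ep in enumerate(dataset.episodes):
        fname = f"episode_{i:05d}.csv"
        t = np.arange(ep.n_samples) / ep.sampling_rate_hz
        frame = pd.DataFrame(
            {
                "t": t,
                "ax": ep.samples[:, 0],
                "ay": ep.samples[:, 1],
                "az": ep.samples[:, 2],
            }
        )
        frame.to_csv(out_dir / fname, index=False, float_format="%.12g")
        rows.append(
            {
                "file": fname,
                "subject": ep.subject_id,
                "site": ep.body_site.value,
                "posture": ep.posture,
                "rate_hz": ep.sampling_rate_hz,
            }
        )
    manifest = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False, float_format="%.12g")
    return manifest_path


# ---------------------------------------------------------------------------
# Normalization and segmentation
# ---------------------------------------------------------------------------


def normalize_episode(episode: Episode, target_gravity: float = 1.0) -> Episode:
    """Rescale an episode by one scalar so the median per-sample vector
    magnitude equals ``target_gravity``.

    Axis ratios (hence the gravity-orientation information) are unchanged;
    the operation is idempotent and invariant to prior uniform scaling.
    """
    magnitudes = np.linalg.norm(episode.samples, axis=1)
    med = float(np.median(magnitudes))
    if med <= 0.0:
        raise DegenerateInputError(
            "cannot normalize: median sample magnitude is zero"
        )
    return episode.with_samples(episode.samples * (target_gravity / med))


def segment_by_labels(
    recording: Recording, labels: Sequence[Optional[str]]
) -> list[Episode]:
    """Split a labeled continuous recording into posture episodes.

    One episode is produced per maximal run of a constant non-null label;
    null-labeled samples are discarded.  Concatenating the outputs in order
    reproduces the labeled subsequence of the input exactly.
    """
    labels = list(labels)
    if len(labels) != recording.samples.shape[0]:
        raise ValidationError(
            f"label track length {len(labels)} != recording length "
            f"{recording.samples.shape[0]}"
        )
    episodes: list[Episode] = []
    start = None
    current: Optional[str] = None

    def flush(end: int) -> None:
        if current is not None and start is not None:
            episodes.append(
                Episode(
                    subject_id=recording.subject_id,
                    body_site=recording.body_site,
                    posture=current,
                    sampling_rate_hz=recording.sampling_rate_hz,
                    samples=recording.samples[start:end],
                )
            )

    for i, lab in enumerate(labels):
        if lab != current:
            flush(i)
            current = lab
            start = i if lab is not None else None
    flush(len(labels))
    return episodes


def resegment_episode(episode: Episode, segment_seconds: float) -> list[Episode]:
    """Cut an episode into consecutive non-overlapping fixed-length segments.

    Segment length is ``floor(segment_seconds * sampling_rate_hz)`` samples;
    a trailing remainder shorter than one segment is dropped.  Metadata is
    inherited unchanged.
    """
    seg_len = int(np.floor(segment_seconds * episode.sampling_rate_hz))
    if seg_len < 1:
        raise ValidationError(
            "segment_seconds * sampling_rate_hz must be at least 1 sample"
        )
    n_segments = episode.n_samples // seg_len
    return [
        episode.with_samples(episode.samples[k * seg_len : (k + 1) * seg_len])
        for k in range(n_segments)
    ]


def integrate_datasets(
    primary: Dataset,
    secondary: Dataset,
    shared_sites: Iterable["BodySite | str"],
    resegment_seconds: float,
    subsample_counts: Mapping[str, int],
    seed: int,
) -> Dataset:
    """Merge two episode collections the way the study datasets were combined.

    The secondary dataset's episodes (restricted to ``shared_sites``) are cut
    into ``resegment_seconds`` pieces, then per-label uniform subsampling
    without replacement keeps ``subsample_counts[label]`` of them (labels not
    listed keep all candidates); the survivors are merged with the primary
    episodes restricted to the same sites.  Deterministic for a fixed seed.
    """
    sites = {_coerce_site(s) for s in shared_sites}
    rng = np.random.default_rng(seed)

    primary_eps = [e for e in primary.episodes if e.body_site in sites]
    candidates: list[Episode] = []
    for ep in secondary.episodes:
        if ep.body_site in sites:
            candidates.extend(resegment_episode(ep, resegment_seconds))

    vocab = tuple(primary.label_vocabulary)
    kept: list[Episode] = []
    for label in vocab:
        of_label = [e for e in candidates if e.posture == label]
        if label in subsample_counts:
            want = int(subsample_counts[label])
            if want > len(of_label):
                raise ValidationError(
                    f"requested {want} episodes of label {label!r} but only "
                    f"{len(of_label)} are available after resegmentation"
                )
            idx = rng.choice(len(of_label), size=want, replace=False)
            kept.extend(of_label[i] for i in sorted(idx))
        else:
            kept.extend(of_label)

    return Dataset(
        f"{primary.name}+{secondary.name}", primary_eps + kept, vocab
    )


def posture_axis_summary(
    dataset: Dataset, site: "BodySite | str"
) -> pd.DataFrame:
    """Pooled per-(posture, axis) mean and standard deviation at one site.

    Statistics pool all samples of all matching episodes.  Returns a frame
    indexed by (posture, axis) with columns ``mean`` and ``sd``; empty when
    no episode matches.
    """
    site = _coerce_site(site)
    rows = []
    for posture in dataset.label_vocabulary:
        eps = [
            e
            for e in dataset.episodes
            if e.body_site == site and e.posture == posture
        ]
        if not eps:
            continue
        pooled = np.concatenate([e.samples for e in eps], axis=0)
        for k, axis in enumerate(AXES):
            rows.append(
                {
                    "posture": posture,
                    "axis": axis,
                    "mean": float(pooled[:, k].mean()),
                    "sd": float(pooled[:, k].std(ddof=0)),
                }
            )
    frame = pd.DataFrame(rows, columns=["posture", "axis", "mean", "sd"])
    return frame.set_index(["posture", "axis"])
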