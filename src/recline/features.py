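"""Sliding-window segmentation and the 48 time-domain features.

The feature vector layout (1-based numbering, per-axis triples in x, y, z
order):

====== =========================== =======
family description                 numbers
====== =========================== =======
AMP    peak amplitude, max - mean  1-3
MED    median                      4-6
MEAN   mean                        7-9
MAX    maximum                     10-12
MIN    minimum                     13-15
VAR    sample variance (N-1)       16-18
STD    sqrt(VAR)                   19-21
RMS    root mean square            22-24
P2P    peak to peak, max - min     25-27
ZCR    zero-crossing rate          28-30
ENT    histogram entropy           31-33
SKN    skewness                    34-36
KRT    kurtosis                    37-39
MAG    mean vector magnitude       40
ENG    energy of the magnitude     41
RNG    range, max - min            42-44
ANG    max elevation angle         45
MAD    mean absolute deviation     46-48
====== =========================== =======

Conventions (where the printed formulas are ambiguous or degenerate):

* ZCR defaults to the rate of sign changes between consecutive samples
  divided by N; ``literal_zcr=True`` instead counts exact zeros as printed.
* ENT is the Shannon entropy (natural log) of a 16-bin histogram of the
  axis values over the window's own range.
* SKN/KRT standardize by the N-1 standard deviation and return 0 when the
  window is constant.
* ENG is the energy of the magnitude series, sum_i |s_i|^2 over all axes.
* ANG is the per-sample elevation atan2(s_z, sqrt(s_x^2 + s_y^2)) maximized
  over the window, in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from recline.data import Dataset, Episode
from recline.errors import ValidationError

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "WindowingSpec",
    "compute_window_features",
    "episode_meta_features",
    "feature_table",
    "sliding_windows",
    "training_window_length",
]

N_FEATURES = 48

_TRIPLES = [
    "amp", "med", "mean", "max", "min", "var", "std", "rms", "p2p",
    "zcr", "ent", "skn", "krt",
]

#: Column names ``f01_amp_x`` ... ``f48_mad_z`` in feature-number order.
FEATURE_NAMES: list[str] = []
for _fam in _TRIPLES:
    for _ax in "xyz":
        FEATURE_NAMES.append(f"f{len(FEATURE_NAMES) + 1:02d}_{_fam}_{_ax}")
FEATURE_NAMES.append("f40_mag")
FEATURE_NAMES.append("f41_eng")
for _ax in "xyz":
    FEATURE_NAMES.append(f"f{len(FEATURE_NAMES) + 1:02d}_rng_{_ax}")
FEATURE_NAMES.append("f45_ang")
for _ax in "xyz":
    FEATURE_NAMES.append(f"f{len(FEATURE_NAMES) + 1:02d}_mad_{_ax}")
assert len(FEATURE_NAMES) == N_FEATURES

_ENT_BINS = 16


@dataclass(frozen=True)
class WindowingSpec:
    """Sliding-window geometry: window length in samples and overlap."""

    window_samples: int
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_samples < 1:
            raise ValidationError("window_samples must be >= 1")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValidationError("overlap_fraction must be in [0, 1)")

    @property
    def step(self) -> int:
        return max(
            1, int(round(self.window_samples * (1.0 - self.overlap_fraction)))
        )


def training_window_length(training_episodes: list[Episode]) -> int:
    """Window length used for feature extraction: the minimum episode
    length (in samples) over the training set."""
    if not training_episodes:
        raise ValidationError("training episode list is empty")
    return min(ep.n_samples for ep in training_episodes)


def sliding_windows(episode: Episode, spec: WindowingSpec) -> list[np.ndarray]:
    """Full-length windows starting at 0, step, 2*step, ...

    An episode shorter than the window yields exactly one window covering
    the whole episode (test episodes may be shorter than the training
    minimum that fixed the window length).
    """
    n = episode.n_samples
    w = spec.window_samples
    if n < w:
        return [episode.samples]
    step = spec.step
    return [
        episode.samples[start : start + w]
        for start in range(0, n - w + 1, step)
    ]


def _axis_entropy(series: np.ndarray) -> float:
    counts, _ = np.histogram(series, bins=_ENT_BINS)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _sign_change_rate(series: np.ndarray) -> float:
    if series.size < 2:
        return 0.0
    s = np.sign(series)
    return float(np.count_nonzero(s[1:] != s[:-1])) / series.size


def _literal_zero_rate(series: np.ndarray) -> float:
    return float(np.count_nonzero(series == 0.0)) / series.size


def compute_window_features(
    window: np.ndarray, *, literal_zcr: bool = False
) -> np.ndarray:
    """Compute the 48-feature vector for one ``(W, 3)`` window."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValidationError(f"window must have shape (W, 3); got {window.shape}")
    w = window.shape[0]
    if w < 1:
        raise ValidationError("window is empty")

    mean = window.mean(axis=0)
    mx = window.max(axis=0)
    mn = window.min(axis=0)
    med = np.median(window, axis=0)
    var = window.var(axis=0, ddof=1) if w > 1 else np.zeros(3)
    std = np.sqrt(var)
    rms = np.sqrt((window**2).mean(axis=0))
    zcr_fn = _literal_zero_rate if literal_zcr else _sign_change_rate
    zcr = np.array([zcr_fn(window[:, k]) for k in range(3)])
    ent = np.array([_axis_entropy(window[:, k]) for k in range(3)])
    centered = window - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        skn = np.where(std > 0, (centered**3).mean(axis=0) / std**3, 0.0)
        krt = np.where(std > 0, (centered**4).mean(axis=0) / std**4, 0.0)
    mad = np.abs(centered).mean(axis=0)

    magnitudes = np.linalg.norm(window, axis=1)
    mag = magnitudes.mean()
    eng = float((window**2).sum())
    ang = float(
        np.arctan2(window[:, 2], np.hypot(window[:, 0], window[:, 1])).max()
    )

    out = np.empty(N_FEATURES)
    out[0:3] = mx - mean        # AMP
    out[3:6] = med              # MED
    out[6:9] = mean             # MEAN
    out[9:12] = mx              # MAX
    out[12:15] = mn             # MIN
    out[15:18] = var            # VAR
    out[18:21] = std            # STD
    out[21:24] = rms            # RMS
    out[24:27] = mx - mn        # P2P
    out[27:30] = zcr            # ZCR
    out[30:33] = ent            # ENT
    out[33:36] = skn            # SKN
    out[36:39] = krt            # KRT
    out[39] = mag               # MAG
    out[40] = eng               # ENG
    out[41:44] = mx - mn        # RNG
    out[44] = ang               # ANG
    out[45:48] = mad            # MAD
    return out


def episode_meta_features(
    episode: Episode, spec: WindowingSpec, *, literal_zcr: bool = False
) -> np.ndarray:
    """Per-episode meta-features: the component-wise mean of the per-window
    feature vectors over the episode's sliding windows."""
    windows = sliding_windows(episode, spec)
    feats = np.stack(
        [compute_window_features(w, literal_zcr=literal_zcr) for w in windows]
    )
    return feats.mean(axis=0)


def feature_table(
    dataset: Dataset, spec: WindowingSpec, *, literal_zcr: bool = False
) -> pd.DataFrame:
    """Meta-feature matrix for a whole dataset, keyed by subject/site/posture."""
    rows = []
    for ep in dataset.episodes:
        meta = episode_meta_features(ep, spec, literal_zcr=literal_zcr)
        row = {
            "subject": ep.subject_id,
            "site": ep.body_site.value,
            "posture": ep.posture,
        }
        row.update(dict(zip(FEATURE_NAMES, meta)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject", "site", "posture", *FEATURE_NAMES])
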