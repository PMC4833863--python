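"""Track-level migration statistics for random-migration and wound-healing assays.

Works on tracker output tables (cell_id, frame, x, y) at a fixed frame
interval (nominally 10 min).  Per cell it computes mean speed, the
directionality ratio (net displacement over path length) and, for
wound-healing assays, the mean cosine of step angles to the wound normal.
Groups are summarized by the box-and-whisker convention with adjacent-value
whiskers and compared by one-way ANOVA with per-group contrasts against a
reference (the starved condition), Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .invasion import AnovaResult, one_way_anova

__all__ = [
    "Track",
    "TrackMetrics",
    "BoxWhiskerSummary",
    "GroupComparison",
    "read_tracks",
    "mean_speed",
    "directionality_ratio",
    "wound_persistence",
    "track_metrics",
    "box_whisker",
    "compare_to_reference",
]


@dataclass
class Track:
    """One cell's ordered positions (µm) at strictly increasing times (min)."""

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError(f"track {self.cell_id}: t/x/y length mismatch")
        if len(self.t) < 2:
            raise ValueError(f"track {self.cell_id}: needs at least 2 frames")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.cell_id}: times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def steps(self) -> np.ndarray:
        """(n-1, 2) array of frame-to-frame displacement vectors."""
        return np.column_stack([np.diff(self.x), np.diff(self.y)])


@dataclass
class TrackMetrics:
    cell_id: str
    mean_speed: float                  # µm/min
    directionality_ratio: float        # net displacement / path length
    wound_persistence: float | None = None  # mean cos(angle to wound normal)


@dataclass
class BoxWhiskerSummary:
    """Box-and-whisker five-number summary with adjacent-value whiskers.

    The upper adjacent value is the largest observation at most
    Q3 + 1.5*IQR; the lower adjacent value is the smallest observation at
    least Q1 - 1.5*IQR.  Adjacent values are always actual observations.
    """

    median: float
    q1: float
    q3: float
    upper_adjacent: float
    lower_adjacent: float
    n: int


@dataclass
class GroupComparison:
    omnibus: AnovaResult
    reference_group: str
    contrast_p: dict[str, float]          # raw two-sided p vs reference
    contrast_p_adjusted: dict[str, float]  # Holm-adjusted


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks(path, *, dt: float = 10.0, pixel_size: float = 1.0,
                sep: str | None = None) -> list[Track]:
    """Read a delimited (cell_id, frame, x, y) table into tracks.

    ``t = frame * dt`` minutes; coordinates are multiplied by ``pixel_size``
    to convert tracker pixels to µm.  The delimiter is sniffed unless given.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = {"cell_id", "frame", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.duplicated(subset=["cell_id", "frame"]).any():
        dup = df[df.duplicated(subset=["cell_id", "frame"])].iloc[0]
        raise ValueError(f"{path}: duplicate (cell_id, frame) = "
                         f"({dup['cell_id']}, {dup['frame']})")
    tracks = []
    for cid, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(Track(
            cell_id=str(cid),
            t=sub["frame"].to_numpy(dtype=float) * dt,
            x=sub["x"].to_numpy(dtype=float) * pixel_size,
            y=sub["y"].to_numpy(dtype=float) * pixel_size,
        ))
    return tracks


# ---------------------------------------------------------------------------
# Per-track metrics
# ---------------------------------------------------------------------------

def mean_speed(track: Track) -> float:
    """Total path length divided by total elapsed time (µm/min)."""
    path = np.linalg.norm(track.steps(), axis=1).sum()
    return float(path / (track.t[-1] - track.t[0]))


def instantaneous_speeds(track: Track) -> np.ndarray:
    """Per-step speed (µm/min): step length over step duration."""
    return np.linalg.norm(track.steps(), axis=1) / np.diff(track.t)


def directionality_ratio(track: Track) -> float:
    """Net displacement over total path length; 1 means perfectly straight."""
    steps = track.steps()
    path = np.linalg.norm(steps, axis=1).sum()
    if path == 0:
        raise ValueError(f"track {track.cell_id}: zero path length")
    net = np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0])
    return float(net / path)


def wound_persistence(track: Track, wound_direction: tuple[float, float]) -> float:
    """Mean cosine of the angle between each nonzero step and the wound normal."""
    w = np.asarray(wound_direction, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("wound_direction must be a nonzero vector")
    w = w / norm
    steps = track.steps()
    lengths = np.linalg.norm(steps, axis=1)
    nonzero = lengths > 0
    if not nonzero.any():
        raise ValueError(f"track {track.cell_id}: all steps are zero")
    cos = (steps[nonzero] @ w) / lengths[nonzero]
    return float(cos.mean())


def track_metrics(track: Track,
                  wound_direction: tuple[float, float] | None = None) -> TrackMetrics:
    """All per-track metrics; wound persistence only if a wound axis is given."""
    wp = None
    if wound_direction is not None:
        wp = wound_persistence(track, wound_direction)
    return TrackMetrics(
        cell_id=track.cell_id,
        mean_speed=mean_speed(track),
        directionality_ratio=directionality_ratio(track),
        wound_persistence=wp,
    )


def metrics_table(tracks: list[Track],
                  wound_direction: tuple[float, float] | None = None) -> pd.DataFrame:
    rows = [track_metrics(tr, wound_direction) for tr in tracks]
    return pd.DataFrame([{
        "cell_id": m.cell_id,
        "mean_speed": m.mean_speed,
        "directionality_ratio": m.directionality_ratio,
        "wound_persistence": m.wound_persistence,
    } for m in rows])


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def box_whisker(values) -> BoxWhiskerSummary:
    """Five-number box summary with adjacent-value whiskers.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention); whiskers are the extreme observations inside the
    1.5*IQR fences, never the fences themselves.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError("box-whisker summary needs at least 4 observations")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    inside_hi = vals[vals <= q3 + 1.5 * iqr]
    inside_lo = vals[vals >= q1 - 1.5 * iqr]
    return BoxWhiskerSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        upper_adjacent=float(inside_hi.max()),
        lower_adjacent=float(inside_lo.min()),
        n=int(vals.size),
    )


def compare_to_reference(groups: dict[str, np.ndarray], reference: str) -> GroupComparison:
    """Omnibus ANOVA plus per-group two-sided contrasts against a reference.

    Contrasts are pooled-variance two-sample t tests of each non-reference
    group against the reference, Holm-adjusted across groups.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among groups")
    omnibus = one_way_anova(groups)

    labels = [g for g in groups if g != reference]
    ref_vals = np.asarray(groups[reference], dtype=float)
    raw = {}
    for g in labels:
        res = stats.ttest_ind(np.asarray(groups[g], dtype=float), ref_vals)
        raw[g] = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    if labels:
        adj = multipletests([raw[g] for g in labels], method="holm")[1]
        adjusted = {g: float(p) for g, p in zip(labels, adj)}
    else:
        adjusted = {}
    return GroupComparison(omnibus=omnibus, reference_group=reference,
                           contrast_p=raw, contrast_p_adjusted=adjusted)
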