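"""3D collagen-invasion quantification from confocal z-stacks.

The assay images a fluorescent cell layer at the bottom of a collagen-filled
well and acquires a z-stack upward into the collagen.  The readout is purely
intensity-profile based, with no segmentation:

1. subtract the Otsu threshold from every voxel (clipping at zero),
2. sum intensity over x and y to get a per-slice z-profile,
3. co-align all profiles of a plate on their maxima by zero-padding
   (correcting for variation of the cell-layer position between wells),
4. choose an invasion horizon above the shared maximum,
5. report per image the proportion of total intensity beyond the horizon,
6. compare condition groups by one-way ANOVA.

The horizon is an explicit, recorded rule (fixed offset above the aligned
maximum, or first slice where the mean profile falls below a fraction of its
peak) rather than a manual choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import tifffile

__all__ = [
    "ImageStack",
    "ZProfile",
    "AlignedProfileSet",
    "InvasionResult",
    "AnovaResult",
    "read_stack",
    "write_stack",
    "otsu_threshold",
    "subtract_threshold",
    "z_profile",
    "align_profiles",
    "parse_horizon_rule",
    "select_horizon",
    "invasion_value",
    "one_way_anova",
    "quantify_stacks",
    "run_invasion_pipeline",
]


@dataclass
class ImageStack:
    """A 3D intensity stack indexed (z, y, x); z=0 is the well bottom."""

    voxels: np.ndarray
    z_step: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("stack must be a 3D (z, y, x) array")
        if self.voxels.shape[0] < 2:
            raise ValueError("not a stack: fewer than 2 z-slices")
        if np.any(self.voxels < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def nz(self) -> int:
        return self.voxels.shape[0]


@dataclass
class ZProfile:
    """Per-slice total intensity of one stack."""

    intensity: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("profile must be 1D")
        if np.any(self.intensity < 0):
            raise ValueError("profile intensities must be non-negative")

    @property
    def max_index(self) -> int:
        """Argmax slice; ties broken toward the lowest z (nearest the bottom)."""
        return int(np.argmax(self.intensity))


@dataclass
class AlignedProfileSet:
    """Profiles zero-padded so every maximum sits at ``common_max_index``."""

    profiles: np.ndarray          # (n_profiles, length)
    common_max_index: int
    pad_offsets: np.ndarray       # leading-pad count per profile
    source_ids: list[str] = field(default_factory=list)
    horizon: int | None = None
    horizon_meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.profiles.shape[1]

    def mean_profile(self) -> np.ndarray:
        return self.profiles.mean(axis=0)


@dataclass
class InvasionResult:
    """Per-image invasion readout: fraction of intensity beyond the horizon."""

    invasion_value: float
    group: str
    source_id: str
    horizon_used: int


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    degenerate: bool = False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_stack(path, z_step: float = 1.0) -> ImageStack:
    """Read a multi-page TIFF; pages in file order map to ascending z."""
    try:
        vox = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
    vox = np.asarray(vox)
    if vox.ndim == 2 or (vox.ndim == 3 and vox.shape[0] < 2):
        raise ValueError(f"{path}: not a stack (single page)")
    if vox.ndim != 3:
        raise ValueError(f"{path}: expected a 3D single-channel stack, got shape {vox.shape}")
    return ImageStack(voxels=vox, z_step=z_step, source_id=str(path))


def write_stack(stack: ImageStack, path) -> None:
    """Write one TIFF page per z-slice, z ascending (away from the well bottom)."""
    tifffile.imwrite(path, np.asarray(stack.voxels), photometric="minisblack")


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(stack: ImageStack | np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold of the full-stack intensity histogram.

    The histogram uses ``n_bins`` equal-width bins over [min, max].  The
    returned value is the interior bin edge maximizing the between-class
    variance; ties break toward the lowest edge.

    Raises
    ------
    ValueError
        If the stack is constant (no threshold separates two classes).
    """
    vox = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    vals = vox.ravel().astype(np.float64)
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise ValueError("no Otsu threshold for constant image")

    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)                      # mass at or below bin k
    m0 = np.cumsum(counts * centers)
    w1 = total - w0
    mu_total = m0[-1]

    # split after bin k: classes {<=k}, {>k}; valid where both are non-empty
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0[:-1] / w0[:-1]
        mean1 = (mu_total - m0[:-1]) / w1[:-1]
        var_between = w0[:-1] * w1[:-1] * (mean0 - mean1) ** 2
    var_between[~valid] = -np.inf
    k = int(np.argmax(var_between))             # first (= lowest) maximizer
    return float(edges[k + 1])


def subtract_threshold(stack: ImageStack, thr: float) -> ImageStack:
    """Subtract ``thr`` from every voxel, clipping at zero."""
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    vox = np.clip(np.asarray(stack.voxels, dtype=np.float64) - thr, 0.0, None)
    return ImageStack(voxels=vox, z_step=stack.z_step, source_id=stack.source_id)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def z_profile(stack: ImageStack) -> ZProfile:
    """Sum intensity over x and y at each slice; conserves total intensity."""
    return ZProfile(
        intensity=np.asarray(stack.voxels, dtype=np.float64).sum(axis=(1, 2)),
        source_id=stack.source_id,
    )


def align_profiles(profiles: list[ZProfile]) -> AlignedProfileSet:
    """Co-align profiles on their maxima by zero-padding.

    Every profile receives leading zeros so its argmax lands at the largest
    original argmax, then trailing zeros equalize lengths.  Original
    intensity values are preserved; only zeros are added.
    """
    if not profiles:
        raise ValueError("cannot align an empty profile list")
    maxima = [p.max_index for p in profiles]
    common = max(maxima)
    pads = [common - m for m in maxima]
    length = max(pad + len(p.intensity) for pad, p in zip(pads, profiles))

    out = np.zeros((len(profiles), length), dtype=np.float64)
    for i, (pad, p) in enumerate(zip(pads, profiles)):
        out[i, pad:pad + len(p.intensity)] = p.intensity
    return AlignedProfileSet(
        profiles=out,
        common_max_index=common,
        pad_offsets=np.asarray(pads, dtype=int),
        source_ids=[p.source_id for p in profiles],
    )


def parse_horizon_rule(rule: str) -> tuple[str, float]:
    """Parse ``"fixed:K"`` or ``"frac:F"`` into (kind, parameter)."""
    try:
        kind, _, param = rule.partition(":")
        value = float(param)
    except ValueError as exc:
        raise ValueError(f"bad horizon rule {rule!r}; expected fixed:K or frac:F") from exc
    if kind == "fixed":
        if value < 1 or value != int(value):
            raise ValueError("fixed-offset rule needs a positive integer slice count")
        return "fixed", value
    if kind == "frac":
        if not 0 < value < 1:
            raise ValueError("fraction-of-max rule needs a fraction in (0, 1)")
        return "frac", value
    raise ValueError(f"unknown horizon rule kind {kind!r}")


def select_horizon(aligned: AlignedProfileSet, rule: str = "fixed:5") -> int:
    """Choose the invasion horizon above the shared aligned maximum.

    ``fixed:K`` puts the horizon K slices above ``common_max_index``.
    ``frac:F`` takes the first aligned slice above the maximum where the mean
    profile falls below F times its peak.  The rule and its parameters are
    recorded in ``aligned.horizon_meta``.
    """
    if aligned.profiles.size == 0:
        raise ValueError("empty aligned profile set")
    kind, param = parse_horizon_rule(rule)
    cmi = aligned.common_max_index
    if kind == "fixed":
        horizon = cmi + int(param)
        if horizon >= aligned.length:
            raise ValueError(
                f"fixed-offset horizon {horizon} beyond profile length {aligned.length}")
    else:
        mean = aligned.mean_profile()
        peak = mean[cmi]
        below = np.nonzero(mean[cmi + 1:] < param * peak)[0]
        if below.size == 0:
            raise ValueError(
                f"mean profile never falls below {param:g} of its peak above the maximum")
        horizon = cmi + 1 + int(below[0])
    aligned.horizon = horizon
    aligned.horizon_meta = {"rule": kind, "parameter": param, "horizon": horizon,
                            "common_max_index": cmi}
    return horizon


def invasion_value(profile: np.ndarray, horizon: int, *, group: str = "",
                   source_id: str = "") -> InvasionResult:
    """Proportion of total profile intensity strictly beyond the horizon.

    "Beyond" means z strictly greater than ``horizon`` — farther from the
    well bottom.
    """
    intensity = np.asarray(profile, dtype=np.float64)
    total = intensity.sum()
    if total <= 0:
        raise ValueError("no cell signal: all-zero profile")
    if not 0 <= horizon < len(intensity):
        raise ValueError(f"horizon {horizon} outside profile of length {len(intensity)}")
    value = float(intensity[horizon + 1:].sum() / total)
    return InvasionResult(invasion_value=value, group=group, source_id=source_id,
                          horizon_used=int(horizon))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over labelled groups.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom.  Two
    degenerate cases are resolved explicitly: zero between-group variance
    gives F=0, p=1; zero within-group variance with unequal means gives
    p=0 flagged degenerate.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")

    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    k = len(arrays)
    n_total = all_vals.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    means = {name: float(a.mean()) for name, a in arrays.items()}

    if ss_within <= 0:
        if ss_between <= 0:
            return AnovaResult(0.0, df_b, df_w, 1.0, means)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, means, degenerate=True)
    if ss_between <= 0:
        return AnovaResult(0.0, df_b, df_w, 1.0, means)

    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, means)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def quantify_stacks(stacks: list[ImageStack], groups: list[str], *,
                    horizon_rule: str = "fixed:5", n_bins: int = 256,
                    per_plate_otsu: bool = False,
                    ) -> tuple[pd.DataFrame, AnovaResult | None, AlignedProfileSet]:
    """Full quantification on in-memory stacks.

    Runs threshold subtraction and z-profiling per image, joint maxima
    alignment across the whole plate, one shared horizon, and a per-image
    invasion value; groups with >= 2 values are compared by one-way ANOVA.

    ``per_plate_otsu`` computes a single Otsu threshold from all stacks
    pooled instead of one per image.
    """
    if len(stacks) != len(groups):
        raise ValueError("one group label per stack required")
    if not stacks:
        raise ValueError("no stacks given")

    plate_thr = None
    if per_plate_otsu:
        pooled = np.concatenate([np.asarray(s.voxels).ravel() for s in stacks])
        plate_thr = otsu_threshold(pooled, n_bins=n_bins)

    profiles = []
    for s in stacks:
        try:
            thr = plate_thr if plate_thr is not None else otsu_threshold(s, n_bins=n_bins)
            profiles.append(z_profile(subtract_threshold(s, thr)))
        except ValueError as exc:
            raise ValueError(f"image {s.source_id or '<unnamed>'}: {exc}") from exc

    aligned = align_profiles(profiles)
    horizon = select_horizon(aligned, horizon_rule)

    results = []
    for i, (prof, grp) in enumerate(zip(aligned.profiles, groups)):
        sid = aligned.source_ids[i] or f"image{i}"
        try:
            results.append(invasion_value(prof, horizon, group=grp, source_id=sid))
        except ValueError as exc:
            raise ValueError(f"image {sid}: {exc}") from exc

    table = pd.DataFrame(
        [(r.source_id, r.group, r.invasion_value, r.horizon_used) for r in results],
        columns=["source_id", "group", "invasion_value", "horizon"],
    )
    by_group = {g: table.loc[table.group == g, "invasion_value"].to_numpy()
                for g in table.group.unique()}
    anova = None
    if len(by_group) >= 2 and all(v.size >= 2 for v in by_group.values()):
        anova = one_way_anova(by_group)
    return table, anova, aligned


def run_invasion_pipeline(manifest: pd.DataFrame, *, horizon_rule: str = "fixed:5",
                          n_bins: int = 256, per_plate_otsu: bool = False,
                          z_step: float = 1.0,
                          ) -> tuple[pd.DataFrame, AnovaResult | None, AlignedProfileSet]:
    """Run the pipeline from a (path, group) manifest of TIFF stacks."""
    for col in ("path", "group"):
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    stacks = [read_stack(p, z_step=z_step) for p in manifest["path"]]
    return quantify_stacks(stacks, list(manifest["group"]), horizon_rule=horizon_rule,
                           n_bins=n_bins, per_plate_otsu=per_plate_otsu)
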