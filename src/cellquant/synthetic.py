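"""Ground-truth-known synthetic inputs for every pipeline stage.

Four generators mirror the four assays the package quantifies:

* :func:`gen_invasion_stack` — a fluorescent cell monolayer at the bottom of
  a 3D confocal stack with a tunable fraction of cell intensity displaced
  upward into the collagen layer, plus background noise.
* :func:`gen_tracks` — persistent random walks with stated speed and
  directional persistence, optionally biased toward a wound axis.
* :func:`gen_decay_course` — qPCR Ct records for an exponential mRNA decay
  after transcriptional arrest, with measurement noise on the cycle scale.
* :func:`gen_survival_cohort` — exponential survival times under a two-group
  proportional-hazards model with independent exponential censoring.

All generators are bit-reproducible given their spec (which includes the
seed): the same spec always yields the same arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .invasion import ImageStack
from .migration import Track

__all__ = [
    "InvasionPhantomSpec",
    "TrackSimSpec",
    "DecaySimSpec",
    "SurvivalSimSpec",
    "gen_invasion_stack",
    "gen_tracks",
    "gen_decay_course",
    "gen_survival_cohort",
    "write_spec_sidecar",
]


class SpecValidationError(ValueError):
    """A simulation spec field violates its invariant."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise SpecValidationError(f"{field_name}: {msg}")


# ---------------------------------------------------------------------------
# Invasion phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InvasionPhantomSpec:
    """Geometry and intensity model of a 3D invasion phantom.

    Cells are isotropic 3D Gaussian blobs of equal amplitude.  A fraction
    ``invaded_fraction`` of the cells is displaced above the monolayer by a
    normally distributed depth (µm); the rest sit exactly at ``monolayer_z``.
    Background noise is additive Gaussian clipped at zero (``"gaussian"``)
    or Poisson shot noise (``"poisson"``).

    Defaults emulate the real assay's geometry: stacks cover 150 µm of
    collagen above the well bottom (50 slices x 3 µm).
    """

    nx: int = 192
    ny: int = 192
    nz: int = 50
    z_step: float = 3.0
    n_cells: int = 80
    monolayer_z: int = 5
    invaded_fraction: float = 0.0
    invasion_depth_mean: float = 60.0
    invasion_depth_sd: float = 15.0
    blob_sigma_xy: float = 1.5
    blob_sigma_z: float = 1.2
    blob_amplitude: float = 100.0
    noise_sd: float = 2.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.nx >= 8 and self.ny >= 8, "nx/ny", "lateral size must be >= 8 voxels")
        _require(self.nz >= 2, "nz", "a stack needs at least 2 slices")
        _require(self.z_step > 0, "z_step", "must be positive")
        _require(self.n_cells >= 1, "n_cells", "must be positive")
        _require(0 <= self.monolayer_z < self.nz, "monolayer_z", "must lie inside the stack")
        _require(0.0 <= self.invaded_fraction <= 1.0, "invaded_fraction", "must be in [0, 1]")
        _require(self.invasion_depth_mean > 0, "invasion_depth_mean", "must be positive")
        _require(self.invasion_depth_sd >= 0, "invasion_depth_sd", "must be non-negative")
        _require(self.blob_sigma_xy > 0, "blob_sigma_xy", "must be positive")
        _require(self.blob_sigma_z > 0, "blob_sigma_z", "must be positive")
        _require(self.blob_amplitude > 0, "blob_amplitude", "must be positive")
        _require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        _require(self.noise_model in ("gaussian", "poisson"), "noise_model",
                 "must be 'gaussian' or 'poisson'")


def gen_invasion_stack(spec: InvasionPhantomSpec) -> tuple[ImageStack, float]:
    """Render an invasion phantom and return it with its true invaded fraction.

    Returns
    -------
    stack : ImageStack
        float32 voxels indexed (z, y, x), z ascending from the well bottom.
    true_invaded_fraction : float
        Rendered intensity mass of invaded blobs divided by total blob mass
        (noise excluded).  Equals ``spec.invaded_fraction`` up to the 1/n_cells
        granularity of whole-cell assignment.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.nz, spec.ny, spec.nx

    n_inv = int(round(spec.invaded_fraction * spec.n_cells))
    # Cells originate in a monolayer and cannot overlap laterally: place them
    # on a jittered grid whose pitch keeps blob supports disjoint (>= 8.5
    # sigma separation where the grid allows it).  The lateral margin keeps
    # blob support inside the field so mass is conserved.
    mx = min(4.0 * spec.blob_sigma_xy, nx / 2 - 1)
    k = math.ceil(math.sqrt(spec.n_cells))
    pitch_x = (nx - 2 * mx) / k
    pitch_y = (ny - 2 * mx) / k
    jitter_x = max(0.0, (pitch_x - 8.5 * spec.blob_sigma_xy) / 2)
    jitter_y = max(0.0, (pitch_y - 8.5 * spec.blob_sigma_xy) / 2)
    sites = rng.permutation(k * k)[:spec.n_cells]
    gx, gy = sites % k, sites // k
    cx = mx + (gx + 0.5) * pitch_x + rng.uniform(-jitter_x, jitter_x, spec.n_cells)
    cy = mx + (gy + 0.5) * pitch_y + rng.uniform(-jitter_y, jitter_y, spec.n_cells)

    cz = np.full(spec.n_cells, float(spec.monolayer_z))
    if n_inv:
        depth_um = rng.normal(spec.invasion_depth_mean, spec.invasion_depth_sd, n_inv)
        depth_vox = depth_um / spec.z_step
        # keep invaded centres clearly above the monolayer and inside the stack
        lo = math.ceil(4.0 * spec.blob_sigma_z) + 4.0
        hi = max(lo + 1.0, nz - 1 - 4.0 * spec.blob_sigma_z - spec.monolayer_z)
        cz[:n_inv] = spec.monolayer_z + np.clip(depth_vox, lo, hi)
    invaded = np.zeros(spec.n_cells, dtype=bool)
    invaded[:n_inv] = True

    cells = np.zeros((nz, ny, nx), dtype=np.float64)
    z_ax = np.arange(nz, dtype=np.float64)
    y_ax = np.arange(ny, dtype=np.float64)
    x_ax = np.arange(nx, dtype=np.float64)
    invaded_mass = 0.0
    total_mass = 0.0
    for i in range(spec.n_cells):
        gz = np.exp(-0.5 * ((z_ax - cz[i]) / spec.blob_sigma_z) ** 2)
        gy = np.exp(-0.5 * ((y_ax - cy[i]) / spec.blob_sigma_xy) ** 2)
        gx = np.exp(-0.5 * ((x_ax - cx[i]) / spec.blob_sigma_xy) ** 2)
        blob = spec.blob_amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        cells += blob
        m = float(blob.sum())
        total_mass += m
        if invaded[i]:
            invaded_mass += m

    vox = cells
    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            vox = vox + rng.normal(0.0, spec.noise_sd, vox.shape)
        else:
            # noise_sd sets the background Poisson mean (shot-noise floor)
            vox = rng.poisson(vox + spec.noise_sd).astype(np.float64)
    vox = np.clip(vox, 0.0, None).astype(np.float32)

    stack = ImageStack(voxels=vox, z_step=spec.z_step)
    return stack, invaded_mass / total_mass


# ---------------------------------------------------------------------------
# Migration tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackSimSpec:
    """Persistent-random-walk simulation parameters.

    Each cell takes steps of constant length ``speed * dt`` with heading
    evolving by Gaussian angular increments whose variance is
    ``2 * dt / persistence_time``, so the directional autocorrelation decays
    as exp(-t / persistence_time).  ``persistence_time=inf`` gives straight
    (ballistic) tracks.  If a wound axis is given, each step direction is the
    renormalized mix ``(1 - wound_bias) * heading + wound_bias * wound_dir``.

    Defaults mirror the real experiments: 90 cells imaged every 10 min
    for 18 h (108 intervals).
    """

    n_cells: int = 90
    n_frames: int = 109
    dt: float = 10.0
    speed: float = 0.5
    persistence_time: float = 30.0
    wound_direction: tuple[float, float] | None = None
    wound_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells", "must be positive")
        _require(self.n_frames >= 2, "n_frames", "a track needs at least 2 frames")
        _require(self.dt > 0, "dt", "must be positive")
        _require(self.speed >= 0, "speed", "must be non-negative")
        _require(self.persistence_time > 0, "persistence_time", "must be positive (inf allowed)")
        _require(0.0 <= self.wound_bias <= 1.0, "wound_bias", "must be in [0, 1]")
        if self.wound_bias > 0:
            _require(self.wound_direction is not None, "wound_direction",
                     "required when wound_bias > 0")


def gen_tracks(spec: TrackSimSpec) -> list[Track]:
    """Simulate persistent random walks; one :class:`Track` per cell."""
    rng = np.random.default_rng(spec.seed)
    n_steps = spec.n_frames - 1
    step_len = spec.speed * spec.dt

    if math.isinf(spec.persistence_time):
        sigma = 0.0
    else:
        sigma = math.sqrt(2.0 * spec.dt / spec.persistence_time)

    theta0 = rng.uniform(0.0, 2.0 * math.pi, spec.n_cells)
    dtheta = rng.normal(0.0, sigma, (spec.n_cells, n_steps)) if sigma > 0 else np.zeros(
        (spec.n_cells, n_steps))
    theta = theta0[:, None] + np.concatenate(
        [np.zeros((spec.n_cells, 1)), np.cumsum(dtheta, axis=1)[:, :-1]], axis=1)

    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=-1)  # (cells, steps, 2)
    if spec.wound_bias > 0 and spec.wound_direction is not None:
        w = np.asarray(spec.wound_direction, dtype=float)
        w = w / np.linalg.norm(w)
        mix = (1.0 - spec.wound_bias) * dirs + spec.wound_bias * w
        norms = np.linalg.norm(mix, axis=-1, keepdims=True)
        # degenerate exact cancellation: fall back to the wound axis
        mix = np.where(norms > 1e-12, mix / np.where(norms == 0, 1.0, norms), w)
        dirs = mix

    steps = step_len * dirs
    pos = np.concatenate([np.zeros((spec.n_cells, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    t = np.arange(spec.n_frames, dtype=float) * spec.dt

    return [
        Track(cell_id=f"cell{i:03d}", t=t.copy(), x=pos[i, :, 0].copy(), y=pos[i, :, 1].copy())
        for i in range(spec.n_cells)
    ]


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tabulate tracks as (cell_id, frame, x, y) rows, the tracker file layout."""
    rows = []
    for tr in tracks:
        for j in range(len(tr.t)):
            rows.append((tr.cell_id, j, tr.x[j], tr.y[j]))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "x", "y"])


# ---------------------------------------------------------------------------
# qPCR decay course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecaySimSpec:
    """Actinomycin-D chase simulation on the Ct (cycle) scale.

    Target expression halves every ``half_life`` hours, so the target Ct
    rises by one cycle per half-life: ``ct(t) = baseline_target_ct +
    t / half_life + noise``.  The reference gene is constant at
    ``reference_ct`` plus the same noise.  Noise is Gaussian on the cycle
    scale, matching how qPCR measurement error behaves.
    """

    half_life: float = 2.0
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
    n_replicates: int = 3
    ct_noise_sd: float = 0.1
    reference_ct: float = 18.0
    baseline_target_ct: float = 26.0
    target_gene: str = "reln"
    reference_gene: str = "actin"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.half_life > 0, "half_life", "must be positive")
        tp = tuple(self.timepoints)
        _require(len(tp) >= 2, "timepoints", "need at least two timepoints")
        _require(tp[0] == 0.0, "timepoints", "first timepoint must be 0")
        _require(all(b > a for a, b in zip(tp, tp[1:])), "timepoints",
                 "must be strictly increasing")
        _require(self.n_replicates >= 1, "n_replicates", "must be positive")
        _require(self.ct_noise_sd >= 0, "ct_noise_sd", "must be non-negative")
        _require(self.reference_ct > 0, "reference_ct", "must be positive")
        _require(self.baseline_target_ct > 0, "baseline_target_ct", "must be positive")


def gen_decay_course(spec: DecaySimSpec) -> pd.DataFrame:
    """Simulated Ct table with columns (sample, gene, time_h, replicate, ct)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for t in spec.timepoints:
        sample = f"t{t:g}"
        true_target = spec.baseline_target_ct + t / spec.half_life
        for r in range(spec.n_replicates):
            rows.append((sample, spec.target_gene, t, r,
                         true_target + rng.normal(0.0, spec.ct_noise_sd)))
            rows.append((sample, spec.reference_gene, t, r,
                         spec.reference_ct + rng.normal(0.0, spec.ct_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "gene", "time_h", "replicate", "ct"])


# ---------------------------------------------------------------------------
# Survival cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalSimSpec:
    """Two-group proportional-hazards cohort.

    Half the patients form the latent low-expression group with hazard
    ``baseline_hazard``; the other half the high-expression group with hazard
    ``baseline_hazard * true_hr``.  Event times are exponential, censoring is
    independent exponential at ``censoring_rate``.  Expression is Gaussian
    around group means separated by ``expression_effect`` standard deviations,
    so a median split recovers the latent groups essentially perfectly at the
    default separation.

    Default cohort size matches the lung-adenocarcinoma cohort (n = 720).
    """

    n_patients: int = 720
    true_hr: float = 0.5
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.05
    expression_effect: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_patients >= 4, "n_patients", "need at least 4 patients")
        _require(self.true_hr > 0, "true_hr", "must be positive")
        _require(self.baseline_hazard > 0, "baseline_hazard", "must be positive")
        _require(self.censoring_rate >= 0, "censoring_rate", "must be non-negative")
        _require(self.expression_effect >= 0, "expression_effect", "must be non-negative")


def gen_survival_cohort(spec: SurvivalSimSpec) -> pd.DataFrame:
    """Simulated cohort table (patient_id, expression, time, event, true_group)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_high = n // 2
    group = np.array(["low"] * (n - n_high) + ["high"] * n_high)

    hazard = np.where(group == "high", spec.baseline_hazard * spec.true_hr,
                      spec.baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censoring_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    mean = np.where(group == "high", spec.expression_effect, 0.0)
    expression = rng.normal(mean, 1.0)

    return pd.DataFrame({
        "patient_id": [f"p{i:04d}" for i in range(n)],
        "expression": expression,
        "time": time,
        "event": event.astype(int),
        "true_group": group,
    })


# ---------------------------------------------------------------------------
# Sidecar
# ---------------------------------------------------------------------------

def write_spec_sidecar(spec, path) -> None:
    """Record the full simulation spec (including seed) as a JSON sidecar."""
    d = asdict(spec)
    d["spec_type"] = type(spec).__name__
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
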