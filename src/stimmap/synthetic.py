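"""Synthetic studies with planted ground truth.

Generates everything the mapping levels consume — bundle-structured
tractograms, bilateral point-source electrodes with placement jitter,
inverse-square E-fields, latent-network connectomes, flashback probes —
and outcomes as noisy monotone functions of field overlap with planted
sweet/sour regions. Every generator is a pure function of (spec, seed).

Planting choices (all recorded in the returned ground truth):

* one designated bundle passes through the sweet region; distractor
  bundles keep a margin away from it, so per-fiber recovery is scoreable;
* a mediolateral "crossing" bundle passes near the inferior contacts and
  can drive flashback-like events;
* one connectome component's loadings peak on the sweet region so the
  network level has a recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from stimmap.data_model import CohortTable, EFieldImage, Tractogram, VoxelGrid
from stimmap.efield import PointSource, efield_magnitude_at, simulate_efield
from stimmap.fiber_filtering import resample_streamline
from stimmap.flashback import ProbeSet
from stimmap.network_mapping import Connectome

__all__ = [
    "GridSpec",
    "Region",
    "TractogramSpec",
    "CohortSpec",
    "GroundTruth",
    "make_grid",
    "generate_tractogram",
    "generate_cohort",
    "generate_connectome",
    "generate_flashback_probes",
]


@dataclass(frozen=True)
class GridSpec:
    """Isotropic grid centred on the origin (mid-sagittal plane at x=0)."""

    shape: tuple[int, int, int] = (31, 31, 31)
    spacing: float = 2.0

    def build(self) -> VoxelGrid:
        if any(s % 2 == 0 for s in self.shape):
            raise ValueError("odd extents required so the grid is centred on 0")
        affine = np.diag([self.spacing] * 3 + [1.0])
        affine[:3, 3] = [-(s - 1) / 2.0 * self.spacing for s in self.shape]
        return VoxelGrid(affine, np.zeros(self.shape))

    @property
    def half_extent(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) / 2.0 * self.spacing


@dataclass(frozen=True)
class Region:
    """Spherical effect region: world-mm centre, radius, effect weight."""

    center: tuple[float, float, float]
    radius: float
    weight: float

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        d = np.linalg.norm(grid.world_coordinates() - np.asarray(self.center),
                           axis=-1)
        return d <= self.radius


@dataclass(frozen=True)
class TractogramSpec:
    """Centerline-based bundles: Bezier arcs plus smooth per-fiber jitter.

    The predictive bundle passes through ``through_point``; the crossing
    bundle runs mediolaterally through ``crossing_point`` (a stand-in for
    a commissural pathway near the inferior contacts); distractors keep
    ``avoid_radius`` mm from every ``avoid_points`` entry.
    """

    n_bundles: int = 10
    fibers_per_bundle: int = 50
    n_points: int = 40
    fiber_jitter_sd: float = 0.8
    predictive_index: int = 0
    crossing_index: int | None = 1
    through_point: tuple[float, float, float] = (6.0, 0.0, 0.0)
    crossing_point: tuple[float, float, float] = (0.0, 0.0, -4.0)
    avoid_points: tuple = ((6.0, 0.0, 0.0), (-6.0, 0.0, 0.0), (0.0, 0.0, -4.0),
                           (6.0, 0.0, -4.0), (-6.0, 0.0, -4.0))
    avoid_radius: float = 10.0
    extent: float = 26.0

    def __post_init__(self) -> None:
        if self.n_bundles < 2:
            raise ValueError("need at least 2 bundles so distractors exist")


@dataclass(frozen=True)
class ShellTractogramSpec:
    """Concentric shell bundles around a stimulation target.

    Each bundle's fibers are short arcs whose vertex sits on a sphere
    ("shell") around ``center``; the bundle index 0 shell lies inside the
    planted sweet region while distractor shells sit at graded larger
    radii. This geometry makes per-fiber weight profiles diverse enough
    that permuted-outcome fiber maps are uninformative, while keeping the
    predictive shell's outcome coupling homogeneous.
    """

    center: tuple[float, float, float] = (6.0, 0.0, 0.0)
    predictive_radius: float = 4.0
    distractor_radii: tuple = (5.5, 6.5, 7.5, 8.5, 10.0, 11.5, 13.0, 15.0, 17.0)
    fibers_per_bundle: int = 50
    n_points: int = 40
    arc_half_length: float = 14.0
    arc_bend: float = 8.0


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 60
    grid: GridSpec = field(default_factory=GridSpec)
    target_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lateral_offset: float = 6.0
    placement_jitter_sd: float = 2.0
    amplitude_range: tuple[float, float] = (2.0, 4.0)
    sweet: Region = Region((6.0, 0.0, 0.0), 4.0, 1.0)
    sour: Region = Region((-6.0, 0.0, 6.0), 3.0, 0.5)
    noise_sd_frac: float = 0.5          # x effect SD, on the % scale
    outcome_mean: float = -38.0         # cohort-regime % change
    outcome_sd: float = 45.0
    sigma: float = 0.2                  # S/m

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        half = GridSpec(self.grid.shape, self.grid.spacing).half_extent
        for reg in (self.sweet, self.sour):
            if np.any(np.abs(np.asarray(reg.center)) + reg.radius > half):
                raise ValueError("effect region outside grid")


@dataclass
class GroundTruth:
    """Everything a recovery test needs without re-deriving."""

    sweet_mask: np.ndarray | None = None
    sour_mask: np.ndarray | None = None
    effects: np.ndarray | None = None          # noiseless per-patient effect
    contacts: np.ndarray | None = None         # (N, 2, 3) left/right sources mm
    amplitudes: np.ndarray | None = None       # (N,) mA
    bundle_labels: np.ndarray | None = None
    predictive_fibers: np.ndarray | None = None
    crossing_fibers: np.ndarray | None = None
    network_loadings: np.ndarray | None = None  # (K, n_masked)
    coupled_component: int | None = None
    event_probability: np.ndarray | None = None


def make_grid(spec: GridSpec = GridSpec()) -> VoxelGrid:
    return spec.build()


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * p1 + (t**2) * p2


def _through_centerline(through: np.ndarray, p0: np.ndarray, p2: np.ndarray,
                        n: int) -> np.ndarray:
    # choose the middle control point so the curve hits `through` at t=0.5
    p1 = 2.0 * through - (p0 + p2) / 2.0
    return _bezier(p0, p1, p2, n)


def generate_tractogram(spec: TractogramSpec = TractogramSpec(),
                        seed: int = 0) -> tuple[Tractogram, GroundTruth]:
    """Bundle-structured streamlines: centreline + smooth per-fiber jitter."""
    rng = np.random.default_rng(seed)
    ext = spec.extent
    through = np.asarray(spec.through_point)
    crossing = np.asarray(spec.crossing_point)

    centerlines: list[np.ndarray] = []
    for b in range(spec.n_bundles):
        if b == spec.predictive_index:
            ang = rng.uniform(0, 2 * np.pi)
            span = np.array([0.0, np.cos(ang), np.sin(ang)]) * ext
            cl = _through_centerline(through, through + span - [2, 0, 0],
                                     through - span + [2, 0, 0], spec.n_points)
        elif b == spec.crossing_index:
            p0 = np.array([-ext, crossing[1], crossing[2]])
            p2 = np.array([ext, crossing[1], crossing[2]])
            cl = _through_centerline(crossing, p0, p2, spec.n_points)
        else:
            # distractors are random arcs keeping a margin from every
            # avoid point (planted regions, electrode tracks)
            avoid = np.atleast_2d(np.asarray(spec.avoid_points, dtype=float))
            for _ in range(200):
                p0 = rng.uniform(-ext, ext, 3)
                p2 = rng.uniform(-ext, ext, 3)
                p1 = (p0 + p2) / 2.0 + rng.uniform(-ext / 2, ext / 2, 3)
                cl = _bezier(p0, p1, p2, spec.n_points)
                d = np.linalg.norm(cl[:, None, :] - avoid[None], axis=-1)
                if (np.linalg.norm(p0 - p2) > ext
                        and d.min() >= spec.avoid_radius):
                    break
            else:
                raise RuntimeError("could not place a distractor bundle")
        centerlines.append(np.clip(cl, -ext - 2, ext + 2))

    streamlines, labels = [], []
    t = np.linspace(0.0, 1.0, spec.n_points)
    for b, cl in enumerate(centerlines):
        for _ in range(spec.fibers_per_bundle):
            offset = rng.normal(0.0, spec.fiber_jitter_sd, 3)
            amp = rng.normal(0.0, spec.fiber_jitter_sd / 2.0, 3)
            phase = rng.uniform(0, 2 * np.pi)
            wiggle = np.sin(2 * np.pi * t + phase)[:, None] * amp
            streamlines.append(cl + offset + wiggle)
            labels.append(b)
    labels = np.asarray(labels)
    tract = Tractogram(streamlines, bundle_labels=labels)
    truth = GroundTruth(
        bundle_labels=labels,
        predictive_fibers=np.flatnonzero(labels == spec.predictive_index),
        crossing_fibers=np.flatnonzero(labels == spec.crossing_index),
    )
    return tract, truth


def _vertex_arc(q: np.ndarray, radial: np.ndarray, rng: np.random.Generator,
                n_points: int, half_length: float, bend: float) -> np.ndarray:
    """Arc with vertex at ``q`` bending away from the shell centre.

    The tangent lies in the plane orthogonal to ``radial`` so the curve's
    closest approach to the centre is its vertex.
    """
    azim = np.array([0.0, -radial[2], radial[1]])
    n = np.linalg.norm(azim)
    azim = azim / n if n > 1e-9 else np.array([0.0, 1.0, 0.0])
    third = np.cross(radial, azim)
    third /= np.linalg.norm(third)
    psi = rng.uniform(0, 2 * np.pi)
    tangent = np.cos(psi) * third + np.sin(psi) * azim
    p0 = q - half_length * tangent + bend * radial
    p2 = q + half_length * tangent + bend * radial
    p1 = 2.0 * q - (p0 + p2) / 2.0
    return _bezier(p0, p1, p2, n_points)


def generate_shell_tractogram(spec: ShellTractogramSpec = ShellTractogramSpec(),
                              seed: int = 0) -> tuple[Tractogram, GroundTruth]:
    """Predictive shell bundle plus graded concentric distractor shells."""
    rng = np.random.default_rng(seed)
    center = np.asarray(spec.center, dtype=float)
    sls: list[np.ndarray] = []
    labels: list[int] = []
    radii = (spec.predictive_radius,) + tuple(spec.distractor_radii)
    for b, s in enumerate(radii):
        for _ in range(spec.fibers_per_bundle):
            v = rng.normal(0.0, 1.0, 3)
            v /= np.linalg.norm(v)
            sls.append(_vertex_arc(center + s * v, v, rng, spec.n_points,
                                   spec.arc_half_length, spec.arc_bend))
            labels.append(b)
    labels_arr = np.asarray(labels)
    tract = Tractogram(sls, bundle_labels=labels_arr)
    truth = GroundTruth(bundle_labels=labels_arr,
                        predictive_fibers=np.flatnonzero(labels_arr == 0))
    return tract, truth


def _place_contacts(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    half = spec.grid.half_extent - 2 * spec.grid.spacing
    target = np.asarray(spec.target_center)
    out = np.empty((spec.n_patients, 2, 3))
    for i in range(spec.n_patients):
        for side, sgn in enumerate((-1.0, 1.0)):
            base = target + np.array([sgn * spec.lateral_offset, 0.0, 0.0])
            for attempt in range(100):
                pos = base + rng.normal(0.0, spec.placement_jitter_sd, 3)
                if np.all(np.abs(pos) <= half):
                    break
            else:
                raise RuntimeError("contact jitter left the grid repeatedly")
            out[i, side] = pos
    return out


def generate_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0,
                    ) -> tuple[CohortTable, list[EFieldImage], GroundTruth]:
    """Bilateral jittered electrodes, analytic fields, planted outcomes.

    The noiseless effect is ``a * mean(E | sweet) - b * mean(E | sour)``;
    improvements are its cohort z-score mapped to the configured %
    regime plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid.build()
    sweet_mask = spec.sweet.mask(grid)
    sour_mask = spec.sour.mask(grid)

    contacts = _place_contacts(spec, rng)
    amplitudes = rng.uniform(*spec.amplitude_range, spec.n_patients)

    fields: list[EFieldImage] = []
    effects = np.empty(spec.n_patients)
    for i in range(spec.n_patients):
        sources = [PointSource(tuple(contacts[i, s]), float(amplitudes[i]),
                               spec.sigma) for s in range(2)]
        E = simulate_efield(sources, grid, patient_id=f"synth{i:03d}")
        fields.append(E)
        effects[i] = (spec.sweet.weight * E.values[sweet_mask].mean()
                      - spec.sour.weight * E.values[sour_mask].mean())

    sd = effects.std()
    if sd == 0:
        raise ValueError("degenerate cohort: no effect variance")
    z = (effects - effects.mean()) / sd
    noise = rng.normal(0.0, spec.noise_sd_frac * spec.outcome_sd,
                       spec.n_patients)
    improvement = spec.outcome_mean + spec.outcome_sd * z + noise

    baseline = rng.uniform(12.0, 24.0, spec.n_patients)
    followup = baseline * (1.0 - improvement / 100.0)
    age = rng.normal(67.0, 8.0, spec.n_patients).clip(45, 90)
    table = pd.DataFrame({
        "id": [f"synth{i:03d}" for i in range(spec.n_patients)],
        "baseline": baseline,
        "followup": followup,
        "age": age,
        "efield_path": [f"synth{i:03d}.nii" for i in range(spec.n_patients)],
    })
    truth = GroundTruth(sweet_mask=sweet_mask, sour_mask=sour_mask,
                        effects=effects, contacts=contacts,
                        amplitudes=amplitudes)
    return CohortTable(table), fields, truth


# Tuned regime for streamline-level recovery testing: a large cohort keeps
# the rank-correlation sampling noise well below the planted signal while
# the shell geometry keeps permuted-outcome fiber maps uninformative.
FIBER_BENCHMARK_COHORT = CohortSpec(
    n_patients=1400,
    amplitude_range=(3.0, 3.0),
    placement_jitter_sd=3.1,
    sweet=Region((6.0, 0.0, 0.0), 5.2, 1.0),
    sour=Region((-6.0, 0.0, 6.0), 3.0, 0.0),
    noise_sd_frac=0.5,
)
FIBER_BENCHMARK_E_THR = 0.02  # V/mm, matched to the synthetic field scale


def generate_fiber_study(cspec: CohortSpec = FIBER_BENCHMARK_COHORT,
                         tspec: ShellTractogramSpec = ShellTractogramSpec(),
                         seed: int = 0,
                         ) -> tuple[np.ndarray, np.ndarray, Tractogram, GroundTruth]:
    """Cohort improvements plus (patients x fibers) peak-weight matrix.

    Streams one field at a time so large benchmark cohorts fit in memory;
    outcome draws replicate :func:`generate_cohort` for the same spec and
    seed. Returns ``(improvements, W, tractogram, truth)``.
    """
    from stimmap.fiber_filtering import _resample_all, _segment_max

    tract, truth = generate_shell_tractogram(tspec, seed)
    rng = np.random.default_rng(seed)
    grid = cspec.grid.build()
    sweet_mask = cspec.sweet.mask(grid)
    sour_mask = cspec.sour.mask(grid)
    contacts = _place_contacts(cspec, rng)
    amplitudes = rng.uniform(*cspec.amplitude_range, cspec.n_patients)

    step = 0.5 * float(grid.spacing().min())
    pts, fid = _resample_all(tract, step)
    ijk, inside = grid.world_to_voxel(pts)
    ii = ijk[inside]

    W = np.zeros((cspec.n_patients, len(tract)))
    effects = np.empty(cspec.n_patients)
    for i in range(cspec.n_patients):
        sources = [PointSource(tuple(contacts[i, s]), float(amplitudes[i]),
                               cspec.sigma) for s in range(2)]
        E = simulate_efield(sources, grid)
        vals = np.zeros(len(pts))
        vals[inside] = E.values[ii[:, 0], ii[:, 1], ii[:, 2]]
        W[i] = _segment_max(vals, fid, len(tract))
        effects[i] = (cspec.sweet.weight * E.values[sweet_mask].mean()
                      - cspec.sour.weight * E.values[sour_mask].mean())

    sd = effects.std()
    if sd == 0:
        raise ValueError("degenerate cohort: no effect variance")
    z = (effects - effects.mean()) / sd
    noise = rng.normal(0.0, cspec.noise_sd_frac * cspec.outcome_sd,
                       cspec.n_patients)
    improvements = cspec.outcome_mean + cspec.outcome_sd * z + noise
    truth.sweet_mask = sweet_mask
    truth.sour_mask = sour_mask
    truth.effects = effects
    truth.contacts = contacts
    truth.amplitudes = amplitudes
    return improvements, W, tract, truth


# Regime for network-recovery testing: strong electrode placement variance
# and a moderate outcome noise floor so the voxel-wise R-map transition
# tracks the planted component's spatial extent.
NETWORK_BENCHMARK_COHORT = CohortSpec(
    n_patients=600,
    placement_jitter_sd=3.5,
    noise_sd_frac=0.25,
    sour=Region((-6.0, 0.0, 6.0), 3.0, 0.0),
)
NETWORK_BENCHMARK_CONNECTOME = dict(
    k_components=3,
    t_samples=500,
    noise_sd=1.2,
    component_width=4.5,
    mask_radius=12.0,
    mask_center=(7.0, 0.0, 0.0),
)

# Regime for probe-level event-contrast testing: the outcome-predictive
# bundle is routed away from the electrode tracks so the designated
# crossing bundle is the only pathway within probe reach, mirroring the
# coverage-filter mechanism that isolates it.
FLASHBACK_TRACTOGRAM = TractogramSpec(through_point=(0.0, 16.0, 0.0))

# Regime for cross-validation behaviour testing: fixed amplitude keeps
# patient weight profiles diverse, which keeps the permuted-outcome LOOCV
# null well calibrated.
CV_BENCHMARK_COHORT = CohortSpec(
    n_patients=60,
    amplitude_range=(3.0, 3.0),
    placement_jitter_sd=2.0,
)


def generate_connectome(grid: VoxelGrid, k_components: int = 3,
                        t_samples: int = 400, noise_sd: float = 0.3,
                        coupled_index: int = 0,
                        coupled_center: tuple[float, float, float] = (6.0, 0.0, 0.0),
                        component_width: float = 5.0,
                        mask_radius: float | None = 15.0,
                        mask_center: tuple[float, float, float] = (0.0, 0.0, 0.0),
                        global_loading: float = 1.0,
                        seed: int = 0) -> tuple[Connectome, GroundTruth]:
    """Latent-network BOLD stand-in on a spherical brain mask.

    Voxel series = sum_k loading_k(voxel) * latent_k(t) + noise, with
    orthogonal unit-variance latents; component ``coupled_index`` has
    Gaussian loadings centred on ``coupled_center`` (the planted sweet
    region) so network recovery is testable. ``mask_radius=None`` uses
    the full grid.
    """
    if k_components < 2:
        raise ValueError("need at least 2 components")
    if t_samples < 50:
        raise ValueError("need at least 50 time samples")
    rng = np.random.default_rng(seed)
    world = grid.world_coordinates()
    if mask_radius is None:
        mask_vals = np.ones(grid.shape, dtype=bool)
    else:
        mask_vals = np.linalg.norm(world - np.asarray(mask_center),
                                   axis=-1) <= mask_radius
    mask = VoxelGrid(grid.affine, mask_vals)
    flat = np.flatnonzero(mask_vals.ravel(order="F"))
    idx = np.stack(np.unravel_index(flat, grid.shape, order="F"), axis=1)
    coords = world[idx[:, 0], idx[:, 1], idx[:, 2]]

    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    centers = np.empty((k_components, 3))
    for k in range(k_components):
        if k == coupled_index:
            centers[k] = coupled_center
        else:
            for _ in range(200):
                c = rng.uniform(0.7 * lo, 0.7 * hi)
                if np.linalg.norm(c - np.asarray(coupled_center)) > 2 * component_width:
                    break
            centers[k] = c
    d = np.linalg.norm(coords[None] - centers[:, None], axis=-1)
    loadings = np.exp(-(d**2) / (2.0 * component_width**2))  # (K, n_masked)

    latents = rng.standard_normal((t_samples, k_components + 1))
    latents, _ = np.linalg.qr(latents)
    latents = latents.T * np.sqrt(t_samples)  # orthogonal, unit variance

    # a spatially flat "global signal" latent stabilises the baseline
    # correlation so distant voxels do not anti-correlate with the seed
    ts = loadings.T @ latents[:k_components]
    ts = ts + global_loading * latents[k_components]
    ts = ts + rng.normal(0.0, noise_sd, ts.shape)
    conn = Connectome(mask, ts)
    truth = GroundTruth(network_loadings=loadings,
                        coupled_component=coupled_index)
    return conn, truth


def _probe_weight_matrix(sources_xyz: np.ndarray, currents: np.ndarray,
                         tract: Tractogram, sigma: float, step: float,
                         chunk: int = 64) -> np.ndarray:
    """(n_probes, n_fibers) analytic peak weights for single-source probes."""
    pts_list = [resample_streamline(sl, step) for sl in tract.streamlines]
    starts = np.cumsum([0] + [len(p) for p in pts_list[:-1]])
    pts = np.concatenate(pts_list)
    n_probes = len(sources_xyz)
    W = np.empty((n_probes, len(pts_list)))
    for lo in range(0, n_probes, chunk):
        hi = min(lo + chunk, n_probes)
        d = np.linalg.norm(pts[None] - sources_xyz[lo:hi, None], axis=-1)
        d = np.maximum(d, 0.5)
        mag = currents[lo:hi, None] / (4.0 * np.pi * sigma * d**2)
        W[lo:hi] = np.maximum.reduceat(mag, starts, axis=1)
    return W


def generate_flashback_probes(cohort_truth: GroundTruth, tract: Tractogram,
                              bundle_fibers: np.ndarray,
                              n_amplitudes: int = 8,
                              amplitude_range: tuple[float, float] = (1.0, 4.0),
                              contact_offsets: Sequence[float] = (-4.0, -2.0, 2.0, 4.0),
                              beta: float = 150.0,
                              target_rate: float = 0.03,
                              sigma: float = 0.2,
                              step: float = 1.0,
                              seed: int = 0) -> tuple[ProbeSet, np.ndarray]:
    """Per patient x contact x amplitude probes with logistic event model.

    Contacts 0-1 sit on the left electrode, 2-3 on the right, displaced
    along z by ``contact_offsets``. Event probability is
    ``logistic(alpha + beta * peak E on the designated bundle)`` with
    alpha calibrated by bisection to the marginal ``target_rate``.
    Returns the probe table and the full (probes x fibers) weight matrix.
    """
    if cohort_truth.contacts is None:
        raise ValueError("cohort ground truth lacks contact positions")
    rng = np.random.default_rng(seed)
    contacts = cohort_truth.contacts
    n_pat = contacts.shape[0]
    amps = np.linspace(*amplitude_range, n_amplitudes)

    rows, sources, currents = [], [], []
    for i in range(n_pat):
        for c, dz in enumerate(contact_offsets):
            side = 0 if c < len(contact_offsets) / 2 else 1
            pos = contacts[i, side] + np.array([0.0, 0.0, dz])
            for a in amps:
                rows.append((f"synth{i:03d}", c, float(a)))
                sources.append(pos)
                currents.append(a)
    sources = np.asarray(sources)
    currents = np.asarray(currents, dtype=float)

    W = _probe_weight_matrix(sources, currents, tract, sigma, step)
    w_bundle = W[:, np.asarray(bundle_fibers)].max(axis=1)

    x = beta * w_bundle
    lo, hi = -float(np.max(x)) - 50.0, 50.0
    for _ in range(200):
        alpha = (lo + hi) / 2.0
        rate = float(np.mean(special.expit(alpha + x)))
        if rate > target_rate:
            hi = alpha
        else:
            lo = alpha
    prob = special.expit(alpha + x)
    events = rng.random(len(prob)) < prob
    intensity = np.where(events, rng.integers(1, 5, len(prob)), 0)

    table = pd.DataFrame(rows, columns=["patient", "contact", "amplitude"])
    table["event"] = events
    table["intensity"] = intensity
    probes = ProbeSet(table)
    probes.event_probability = prob  # type: ignore[attr-defined]
    return probes, W
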