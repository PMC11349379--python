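"""Desk-scale integrative rigid-body fitting into density.

The workflow mirrors standard integrative-modelling practice for fitting
subcomplex models into low-resolution (15–30 Å) maps:

1. ``simulate_density`` renders a model as a sum of per-atom Gaussians
   whose width follows the map resolution.
2. ``build_fit_library`` samples many rigid placements (quasi-uniform
   rotations x translations), scores each by normalized cross-correlation,
   keeps those sufficiently inside the map, locally refines the best, and
   greedily clusters them by rotation/shift tolerance.
3. ``score_configuration`` combines the density term with cross-link,
   connectivity, excluded-volume and discrete-contact restraints under
   fixed weights (defaults: connectivity 1, cross-link 30, discrete 10000,
   excluded volume 10, EM 1000).
4. ``anneal`` runs Metropolis Monte-Carlo over library exemplars (plus
   optional local perturbations) under a decreasing temperature schedule
   (default stages 75000/1000, 30000/800, 10000/800, 5000/500, 1000/500,
   300/300 steps).
5. ``score_histogram`` applies the convergence diagnostic used on
   ensembles of independent runs: a best-scoring mode separated from the
   main mass indicates convergence, a single near-Gaussian mass does not.

Temperatures are interpreted as an energy scale on the weighted total
score, so acceptance of a move with score increase dE has probability
exp(-dE / T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import qmc

from .core import (AssemblyModel, ChainMap, CrossLinkRecord, DensityGrid,
                   ThresholdPolicy)
from .validate import UNMAPPED, min_ca_distance

logger = logging.getLogger("trainxl")

DEFAULT_WEIGHTS: dict[str, float] = {
    "connectivity": 1.0,
    "xlink": 30.0,
    "discrete": 10000.0,
    "excluded_volume": 10.0,
    "em": 1000.0,
}

GAUSSIAN_CUTOFF_SIGMAS = 3.0
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# Poses and schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    """Rigid placement: x -> R (x - pivot) + translation.

    The pivot is the body's own centroid reference (stored so rotations do
    not translate the body's centre of mass).
    """

    rotation: np.ndarray
    translation: np.ndarray
    body_id: str = ""

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls, body_id: str = "") -> "Pose":
        return cls(np.eye(3), np.zeros(3), body_id)

    @classmethod
    def from_rotvec(cls, rotvec: np.ndarray, translation: np.ndarray,
                    body_id: str = "") -> "Pose":
        return cls(Rotation.from_rotvec(rotvec).as_matrix(), translation,
                   body_id)

    def apply(self, coords: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        return (coords - pivot) @ self.rotation.T + self.translation


def rotation_angle_deg(pose_a: Pose, pose_b: Pose) -> float:
    """Angle (degrees) of the relative rotation between two poses."""
    rel = Rotation.from_matrix(pose_a.rotation.T @ pose_b.rotation)
    return float(np.degrees(rel.magnitude()))


def shift_distance(pose_a: Pose, pose_b: Pose) -> float:
    return float(np.linalg.norm(pose_a.translation - pose_b.translation))


@dataclass(frozen=True)
class AnnealSchedule:
    """Ordered (temperature, step count) stages, strictly cooling."""

    stages: tuple[tuple[float, int], ...] = (
        (75000.0, 1000), (30000.0, 800), (10000.0, 800),
        (5000.0, 500), (1000.0, 500), (300.0, 300),
    )

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.stages]
        if any(t2 >= t1 for t1, t2 in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly decreasing")
        if any(n <= 0 for _, n in self.stages):
            raise ValueError("step counts must be positive")

    @property
    def total_steps(self) -> int:
        return sum(n for _, n in self.stages)


# ---------------------------------------------------------------------------
# Density simulation and correlation
# ---------------------------------------------------------------------------

def resolution_sigma(resolution: float) -> float:
    """Gaussian width for a nominal resolution (FWHM convention)."""
    return resolution / FWHM_TO_SIGMA


def simulate_density(model: AssemblyModel, resolution: float,
                     voxel: float, grid: DensityGrid | None = None,
                     padding: float | None = None) -> DensityGrid:
    """Render a model as a sum of per-atom Gaussians on a regular grid.

    sigma = resolution / (2 sqrt(2 ln 2)); each atom contributes the same
    total weight, so the integrated density is proportional to the atom
    count.  With ``grid`` given, the density is sampled on that grid's
    frame (used for correlation against a target map); otherwise a grid
    covering the model with ``padding`` (default: one resolution length)
    is created.
    """
    if resolution < 2.0 * voxel:
        raise ValueError("resolution must be at least twice the voxel size "
                         f"(got {resolution} vs voxel {voxel})")
    sigma = resolution_sigma(resolution)
    if grid is None:
        pad = resolution if padding is None else padding
        lo = model.coords.min(axis=0) - pad
        hi = model.coords.max(axis=0) + pad
        shape = np.ceil((hi - lo) / voxel).astype(int) + 1
        data = np.zeros(shape, dtype=np.float32)
        out = DensityGrid(data=data, voxel=voxel, origin=lo)
    else:
        out = DensityGrid(data=np.zeros(grid.shape, dtype=np.float32),
                          voxel=grid.voxel, origin=grid.origin)
    _splat(out, model.coords, sigma)
    return out


def _splat(grid: DensityGrid, coords: np.ndarray, sigma: float) -> None:
    """Accumulate Gaussians into ``grid.data`` (in place).

    The isotropic Gaussian is separable, so per-axis 1-D weight vectors
    are combined by outer product; out-of-grid samples get zero weight.
    """
    vx = grid.voxel
    cutoff = GAUSSIAN_CUTOFF_SIGMAS * sigma
    k = np.ceil(cutoff / vx).astype(int)
    shape = grid.data.shape
    frac = (coords - grid.origin) / vx            # (n, 3) in voxel units
    # floor(x + 0.5), not rint: banker's rounding of half-voxel fractions
    # would break the exact one-voxel shift property
    near = np.floor(frac + 0.5).astype(np.int64)
    axis_w, axis_i = [], []
    for a in range(3):
        offs = np.arange(-k[a], k[a] + 1)
        idx = near[:, a:a + 1] + offs[None, :]     # (n, m_a)
        delta = (idx - frac[:, a:a + 1]) * vx[a]
        w = np.exp(-delta * delta / (2.0 * sigma * sigma))
        w[(idx < 0) | (idx >= shape[a])] = 0.0
        axis_w.append(w)
        axis_i.append(np.clip(idx, 0, shape[a] - 1))
    weights = np.einsum("ni,nj,nk->nijk", *axis_w)
    flat = ((axis_i[0][:, :, None, None] * shape[1]
             + axis_i[1][:, None, :, None]) * shape[2]
            + axis_i[2][:, None, None, :])
    acc = np.bincount(flat.ravel(), weights=weights.ravel(),
                      minlength=shape[0] * shape[1] * shape[2])
    grid.data += acc.reshape(shape).astype(np.float32)


def cross_correlation(model: AssemblyModel, pose: Pose, grid: DensityGrid,
                      resolution: float, pivot: np.ndarray | None = None,
                      support_fraction: float = 0.1) -> float:
    """Normalized cross-correlation over the posed model's own support.

    The model is posed, rendered on the target grid's frame, and compared
    with the target over voxels where the simulated density exceeds
    ``support_fraction`` of its maximum -- the body's own footprint, so
    neighbouring bodies' density outside it does not dilute the score.
    Zero-variance overlap maps to 0.
    """
    pivot = model.coords.mean(axis=0) if pivot is None else pivot
    posed = model.transformed(np.eye(3), -pivot).transformed(
        pose.rotation, pose.translation)
    sim = simulate_density(posed, resolution, float(grid.voxel.max()),
                           grid=grid)
    s = sim.data.astype(float)
    smax = s.max()
    if smax <= 0:
        return 0.0
    mask = s > support_fraction * smax
    a = s[mask]
    b = grid.data.astype(float)[mask]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


# ---------------------------------------------------------------------------
# Fit libraries
# ---------------------------------------------------------------------------

@dataclass
class FitCluster:
    exemplar: Pose
    score: float
    size: int


def _halton_poses(n: int, grid: DensityGrid, level: float,
                  center: np.ndarray, radius: float,
                  body_id: str) -> list[Pose]:
    """Quasi-uniform SO(3) x density-weighted translation samples.

    Rotations come from the Shoemake map over a deterministic Halton
    sequence.  Translations (candidate centroid positions) are drawn from
    the map's support voxels with probability proportional to density --
    a body's centre of mass must sit in occupied density, so uniform box
    sampling would waste almost all placements on empty space.
    """
    sampler = qmc.Halton(d=7, scramble=False)
    sampler.fast_forward(1)  # skip the degenerate all-zero first point
    u = sampler.random(n)
    # Shoemake map: three uniforms -> uniform unit quaternion
    u1, u2, u3 = u[:, 0], u[:, 1], u[:, 2]
    quat = np.column_stack([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ])
    rots = Rotation.from_quat(quat).as_matrix()
    support = np.argwhere(grid.data > level)
    if len(support) == 0:
        return []
    w = grid.data[grid.data > level].astype(float)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    pick = np.searchsorted(cdf, u[:, 3])
    base = grid.origin + support[pick] * grid.voxel
    trans = base + (u[:, 4:7] - 0.5) * grid.voxel  # jitter within the voxel
    keep = np.linalg.norm(trans - center, axis=1) <= radius
    return [Pose(r, t, body_id) for r, t in zip(rots[keep], trans[keep])]


def _refine_pose(model: AssemblyModel, pose: Pose, grid: DensityGrid,
                 resolution: float, pivot: np.ndarray,
                 maxfev: int = 300) -> tuple[Pose, float]:
    """Local gradient-free maximization of the correlation around a pose."""

    def objective(x: np.ndarray) -> float:
        rot = Rotation.from_rotvec(x[:3]).as_matrix() @ pose.rotation
        p = Pose(rot, pose.translation + x[3:], pose.body_id)
        return -cross_correlation(model, p, grid, resolution, pivot)

    res = minimize(objective, np.zeros(6), method="Powell",
                   options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-6})
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix() @ pose.rotation
    refined = Pose(rot, pose.translation + res.x[3:], pose.body_id)
    return refined, float(-res.fun)


def _refine_pose_fast(centered: np.ndarray, pose: Pose, grid: DensityGrid,
                      maxfev: int = 400) -> Pose:
    """Local maximization of mean map density sampled at the atoms.

    Roughly 30x cheaper per evaluation than the correlation objective, so
    it can chase many search starts into their local basins; the winners
    are re-ranked and polished with the full correlation afterwards.
    """

    def objective(x: np.ndarray) -> float:
        rot = Rotation.from_rotvec(x[:3]).as_matrix() @ pose.rotation
        pts = centered @ rot.T + pose.translation + x[3:]
        return -float(grid.interpolate(pts).mean())

    res = minimize(objective, np.zeros(6), method="Powell",
                   options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-8})
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix() @ pose.rotation
    return Pose(rot, pose.translation + res.x[3:], pose.body_id)


def _greedy_clusters(scored: list[tuple[float, Pose]], cluster_angle: float,
                     cluster_shift: float) -> list[FitCluster]:
    """Greedy clustering in score order.

    The quaternion dot gives the rotation angle (theta <= a iff
    |q1.q2| >= cos(a/2)) without constructing per-pair rotation objects.
    """
    quats = Rotation.from_matrix(
        np.array([p.rotation for _, p in scored])).as_quat()
    trans = np.array([p.translation for _, p in scored])
    cos_half = np.cos(np.radians(cluster_angle) / 2.0)
    exemplar_idx: list[int] = []
    sizes: list[int] = []
    for i in range(len(scored)):
        if exemplar_idx:
            qdot = np.abs(quats[exemplar_idx] @ quats[i])
            tdist = np.linalg.norm(trans[exemplar_idx] - trans[i], axis=1)
            hits = np.nonzero((qdot >= cos_half) & (tdist <= cluster_shift))[0]
            if len(hits):
                sizes[int(hits[0])] += 1
                continue
        exemplar_idx.append(i)
        sizes.append(1)
    return [FitCluster(exemplar=scored[i][1], score=scored[i][0], size=s)
            for i, s in zip(exemplar_idx, sizes)]


def build_fit_library(model: AssemblyModel, grid: DensityGrid,
                      n_positions: int = 80000,
                      cluster_angle: float = 4.0,
                      cluster_shift: float = 3.0,
                      inside_threshold: float = 0.3,
                      radius: float = 200.0,
                      resolution: float | None = None,
                      support_level: float = 0.1,
                      refine_top: int = 12,
                      search_starts: int = 64) -> list[FitCluster]:
    """Sample, screen, locally optimize and cluster rigid placements.

    ``n_positions`` placements are drawn from a deterministic
    low-discrepancy sequence (rotations quasi-uniform over SO(3),
    translations density-weighted within the map and a sphere of
    ``radius`` around the map centre).  Every placement is screened with
    a cheap overlap objective (mean map density at the atom positions)
    and the inside-map filter; ``search_starts`` spatially and
    orientationally diverse survivors are then chased into their local
    basins with the cheap objective, re-scored with normalized
    cross-correlation, greedily clustered at the (angle, shift)
    tolerances, and the ``refine_top`` leading clusters are polished
    against the correlation.  Clusters are ranked by best member score.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if resolution is None:
        resolution = 3.0 * float(grid.voxel.max())
    pivot = model.coords.mean(axis=0)
    lo = grid.origin
    hi = grid.origin + (np.array(grid.shape) - 1) * grid.voxel
    center = 0.5 * (lo + hi)
    level = support_level * float(grid.data.max())
    poses = _halton_poses(n_positions, grid, level, center, radius,
                          body_id=poses_id(model))
    centered = model.coords - pivot
    if not poses:
        logger.warning("no translation samples in map support; empty library")
        return []

    # stage 1: cheap overlap screen of every placement
    n_poses = len(poses)
    fast = np.empty(n_poses)
    inside_frac = np.empty(n_poses)
    chunk = 512
    rots = np.array([p.rotation for p in poses])
    trs = np.array([p.translation for p in poses])
    for s in range(0, n_poses, chunk):
        pts = (np.einsum("pij,aj->pai", rots[s:s + chunk], centered)
               + trs[s:s + chunk][:, None, :])
        vals = grid.interpolate(pts.reshape(-1, 3)).reshape(len(pts), -1)
        fast[s:s + chunk] = vals.mean(axis=1)
        inside_frac[s:s + chunk] = (vals > level).mean(axis=1)
    keep = np.nonzero(inside_frac >= inside_threshold)[0]
    if len(keep) == 0:
        logger.warning("no pose passed the inside-map filter; empty library")
        return []
    keep = keep[np.argsort(-fast[keep])]

    # stage 2: pick search starts spread over map regions and orientations
    # (round-robin over coarse translation cells, skipping near-duplicate
    # rotations) and chase each into its local basin, cheap objective
    cell_size = 18.0
    by_cell: dict[tuple[int, int, int], list[int]] = {}
    for i in keep:
        by_cell.setdefault(
            tuple(np.floor(trs[i] / cell_size).astype(int)), []).append(int(i))
    cell_order = sorted(by_cell, key=lambda c: -fast[by_cell[c][0]])
    quats_all = Rotation.from_matrix(rots).as_quat()
    cos_sep = np.cos(np.radians(20.0) / 2.0)  # ~20 deg minimum separation
    taken: dict[tuple[int, int, int], list[int]] = {c: [] for c in cell_order}
    starts: list[int] = []
    progress = True
    while len(starts) < search_starts and progress:
        progress = False
        for cell in cell_order:
            if len(starts) >= search_starts:
                break
            for i in by_cell[cell]:
                prior = taken[cell]
                if prior and np.any(np.abs(
                        quats_all[prior] @ quats_all[i]) >= cos_sep):
                    continue
                by_cell[cell] = by_cell[cell][by_cell[cell].index(i) + 1:]
                taken[cell].append(i)
                starts.append(i)
                progress = True
                break
    optimized = [_refine_pose_fast(centered, poses[i], grid) for i in starts]

    # stage 3: exact correlation scores for optimized poses and the best
    # raw survivors, clustering, and final polish of the leading clusters
    rescore = optimized + [poses[i] for i in keep[:3 * search_starts]]
    scored = [(cross_correlation(model, p, grid, resolution, pivot), p)
              for p in rescore]
    scored.sort(key=lambda t: -t[0])
    clusters = _greedy_clusters(scored, cluster_angle, cluster_shift)
    for cl in clusters[:refine_top]:
        rp, rcc = _refine_pose(model, cl.exemplar, grid, resolution, pivot)
        if rcc > cl.score:
            cl.exemplar, cl.score = rp, rcc
    clusters.sort(key=lambda c: -c.score)
    return clusters


def poses_id(model: AssemblyModel) -> str:
    chains = model.chains()
    return chains[0] if len(chains) == 1 else "+".join(chains)


# ---------------------------------------------------------------------------
# Configuration scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectivityRestraint:
    """Declared chain continuation between rigid bodies.

    Penalizes the Cα–Cα gap between the last residue of one segment and
    the first residue of the next beyond ``max_gap`` Å.
    """

    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    max_gap: float = 5.0


@dataclass(frozen=True)
class DiscreteContact:
    """Declared required contact between two chains (0/1 penalty)."""

    chain_a: str
    chain_b: str
    cutoff: float = 10.0


@dataclass
class ScoreBreakdown:
    """Weighted restraint terms; ``total`` is their weighted sum."""

    terms: dict[str, float]
    weights: dict[str, float]
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        self.total = float(sum(self.weights[k] * self.terms[k]
                               for k in self.terms))


def _posed_bodies(bodies: Sequence[AssemblyModel],
                  poses: Sequence[Pose]) -> list[AssemblyModel]:
    out = []
    for body, pose in zip(bodies, poses):
        pivot = body.coords.mean(axis=0)
        out.append(body.transformed(np.eye(3), -pivot).transformed(
            pose.rotation, pose.translation))
    return out


def score_configuration(bodies: Sequence[AssemblyModel],
                        poses: Sequence[Pose],
                        grid: DensityGrid | None,
                        crosslinks: Sequence[CrossLinkRecord] = (),
                        chainmap: ChainMap | None = None,
                        policy: ThresholdPolicy | None = None,
                        weights: Mapping[str, float] | None = None,
                        connectivity: Sequence[ConnectivityRestraint] = (),
                        contacts: Sequence[DiscreteContact] = (),
                        resolution: float | None = None,
                        clash_distance: float = 3.0,
                        em_per_body: Sequence[float] | None = None
                        ) -> ScoreBreakdown:
    """Weighted restraint score of one multi-body configuration.

    Terms: EM = 1 - mean per-body correlation; cross-link = sum of
    flat-bottom quadratic violations max(0, d - threshold)^2; excluded
    volume = count of inter-body atom pairs closer than ``clash_distance``;
    connectivity = sum of max(0, gap - max_gap)^2 over declared chain
    continuations; discrete = count of declared contacts not realized.
    ``em_per_body`` allows callers with cached correlations to skip the
    density rendering.
    """
    if len(bodies) != len(poses):
        raise ValueError("one pose per rigid body required")
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    policy = policy or ThresholdPolicy()
    posed = _posed_bodies(bodies, poses)

    if em_per_body is not None:
        ccs = list(em_per_body)
    elif grid is not None:
        if resolution is None:
            resolution = 3.0 * float(grid.voxel.max())
        ccs = [cross_correlation(b, Pose.identity(),
                                 grid, resolution, pivot=np.zeros(3))
               for b in posed]
    else:
        ccs = []
    em_term = float(1.0 - np.mean(ccs)) if ccs else 0.0

    combined = AssemblyModel.concat(posed)
    ca = combined.ca_index()

    xl_term = 0.0
    if crosslinks:
        if chainmap is None:
            raise ValueError("cross-link scoring requires a chain map")
        for record in crosslinks:
            report = min_ca_distance(combined, chainmap, record, policy)
            if report.classification == UNMAPPED:
                continue
            xl_term += max(0.0, report.distance - policy.threshold) ** 2

    ev_term = 0.0
    if len(posed) > 1:
        trees = [cKDTree(b.coords) for b in posed]
        for i in range(len(posed)):
            for j in range(i + 1, len(posed)):
                ev_term += trees[i].count_neighbors(trees[j], clash_distance)

    conn_term = 0.0
    for r in connectivity:
        ia = ca.get((r.chain_a, r.residue_a))
        ib = ca.get((r.chain_b, r.residue_b))
        if ia is None or ib is None:
            continue
        gap = float(np.linalg.norm(combined.coords[ia] - combined.coords[ib]))
        conn_term += max(0.0, gap - r.max_gap) ** 2

    disc_term = 0.0
    for c in contacts:
        xa = combined.coords[combined.chain_mask(c.chain_a)]
        xb = combined.coords[combined.chain_mask(c.chain_b)]
        if len(xa) == 0 or len(xb) == 0:
            disc_term += 1.0
            continue
        dmin = cKDTree(xa).query(xb, k=1)[0].min()
        if dmin >= c.cutoff:
            disc_term += 1.0

    terms = {"em": em_term, "xlink": xl_term, "connectivity": conn_term,
             "excluded_volume": float(ev_term), "discrete": disc_term}
    return ScoreBreakdown(terms=terms, weights=weights)


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

@dataclass
class AnnealResult:
    poses: list[Pose]
    breakdown: ScoreBreakdown
    acceptance_rates: list[float]
    trace: list[float]
    seed: int


def anneal(bodies: Sequence[AssemblyModel], grid: DensityGrid,
           libraries: Sequence[Sequence[FitCluster]],
           crosslinks: Sequence[CrossLinkRecord] = (),
           chainmap: ChainMap | None = None,
           schedule: AnnealSchedule | None = None,
           seed: int = 0,
           policy: ThresholdPolicy | None = None,
           weights: Mapping[str, float] | None = None,
           connectivity: Sequence[ConnectivityRestraint] = (),
           contacts: Sequence[DiscreteContact] = (),
           resolution: float | None = None,
           perturb_angle: float = 0.0,
           perturb_shift: float = 0.0,
           exemplar_probability: float = 1.0,
           top_clusters: int = 10,
           top_probability: float = 0.5,
           temperature_scale: float | None = None,
           quench_top: int = 10
           ) -> AnnealResult:
    """Metropolis simulated annealing over fit-library exemplars.

    Moves re-pose one randomly chosen body: with probability
    ``exemplar_probability`` to a library exemplar, otherwise by a local
    perturbation (rotation up to ``perturb_angle`` degrees, shift up to
    ``perturb_shift`` Å).  Exemplar proposals are rank-biased: with
    probability ``top_probability`` they come from the body's
    ``top_clusters`` best-correlating clusters, otherwise uniformly from
    the whole library, so the chain concentrates on well-fitting
    placements while remaining ergodic over the full discrete space.
    With the default exemplar-only moves the search space is the discrete
    product of the libraries, which makes the exhaustive optimum a hard
    lower bound.  Reproducible given ``seed``.

    The schedule's temperatures are unitless scores from the source
    optimization protocol; what transfers across problems is the cooling
    *profile* (temperature ratios and step counts), not the absolute
    scale.  By default the scale is calibrated per problem so that the
    first stage matches the score spread of random configurations (and
    therefore accepts almost anything) while the last stage, 250x colder,
    is close to greedy.  Pass ``temperature_scale`` to override.

    After the schedule a zero-temperature quench hill-climbs from the
    best configuration over each body's ``quench_top`` leading exemplars
    until no single-body swap improves the score; the search never leaves
    the discrete exemplar space.
    """
    if any(len(lib) == 0 for lib in libraries):
        raise ValueError("every body needs a non-empty fit library")
    if len(libraries) != len(bodies):
        raise ValueError("one fit library per body required")
    schedule = schedule or AnnealSchedule()
    policy = policy or ThresholdPolicy()
    if resolution is None:
        resolution = 3.0 * float(grid.voxel.max())
    rng = np.random.default_rng(seed)

    pivots = [b.coords.mean(axis=0) for b in bodies]

    def body_cc(i: int, pose: Pose) -> float:
        return cross_correlation(bodies[i], pose, grid, resolution, pivots[i])

    def total_score(poses: list[Pose], ccs: list[float]) -> ScoreBreakdown:
        return score_configuration(
            bodies, poses, grid, crosslinks, chainmap, policy, weights,
            connectivity, contacts, resolution, em_per_body=ccs)

    poses = [lib[rng.integers(len(lib))].exemplar for lib in libraries]
    ccs = [body_cc(i, p) for i, p in enumerate(poses)]
    current = total_score(poses, ccs)
    best_poses, best = list(poses), current

    if temperature_scale is None:
        # calibrate the unitless schedule onto this problem's score range
        probe = []
        for _ in range(24):
            ps = [lib[int(rng.integers(len(lib)))].exemplar
                  for lib in libraries]
            pccs = [body_cc(i, p) for i, p in enumerate(ps)]
            probe.append(total_score(ps, pccs).total)
        spread = float(np.std(probe))
        temperature_scale = (spread / schedule.stages[0][0]
                             if spread > 0 else 1.0)

    acceptance: list[float] = []
    trace: list[float] = []

    for raw_temperature, n_steps in schedule.stages:
        temperature = raw_temperature * temperature_scale
        accepted = 0
        for _ in range(n_steps):
            i = int(rng.integers(len(bodies)))
            if rng.random() < exemplar_probability or (
                    perturb_angle == 0 and perturb_shift == 0):
                lib = libraries[i]
                if rng.random() < top_probability:
                    cand = lib[int(rng.integers(min(top_clusters,
                                                    len(lib))))].exemplar
                else:
                    cand = lib[int(rng.integers(len(lib)))].exemplar
            else:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = np.radians(rng.uniform(0, perturb_angle))
                rot = Rotation.from_rotvec(ang * axis).as_matrix()
                shift = rng.uniform(-perturb_shift, perturb_shift, size=3)
                cand = Pose(rot @ poses[i].rotation,
                            poses[i].translation + shift, poses[i].body_id)
            new_cc = body_cc(i, cand)
            trial_poses = list(poses)
            trial_poses[i] = cand
            trial_ccs = list(ccs)
            trial_ccs[i] = new_cc
            trial = total_score(trial_poses, trial_ccs)
            delta = trial.total - current.total
            if delta <= 0 or rng.random() < np.exp(-delta / temperature):
                poses, ccs, current = trial_poses, trial_ccs, trial
                accepted += 1
                if current.total < best.total:
                    best_poses, best = list(poses), current
        acceptance.append(accepted / n_steps)
        trace.append(best.total)

    # zero-temperature quench from the best-ever configuration
    poses = list(best_poses)
    ccs = [body_cc(i, p) for i, p in enumerate(poses)]
    current = total_score(poses, ccs)
    improved = True
    while improved:
        improved = False
        for i in range(len(bodies)):
            for cl in libraries[i][:quench_top]:
                if cl.exemplar is poses[i]:
                    continue
                trial_poses = list(poses)
                trial_poses[i] = cl.exemplar
                trial_ccs = list(ccs)
                trial_ccs[i] = body_cc(i, cl.exemplar)
                trial = total_score(trial_poses, trial_ccs)
                if trial.total < current.total - 1e-12:
                    poses, ccs, current = trial_poses, trial_ccs, trial
                    improved = True
    if current.total < best.total:
        best_poses, best = poses, current
        trace.append(best.total)
    return AnnealResult(poses=best_poses, breakdown=best,
                        acceptance_rates=acceptance, trace=trace, seed=seed)


def exhaustive_minimum(bodies: Sequence[AssemblyModel], grid: DensityGrid,
                       libraries: Sequence[Sequence[FitCluster]],
                       crosslinks: Sequence[CrossLinkRecord] = (),
                       chainmap: ChainMap | None = None,
                       policy: ThresholdPolicy | None = None,
                       weights: Mapping[str, float] | None = None,
                       connectivity: Sequence[ConnectivityRestraint] = (),
                       contacts: Sequence[DiscreteContact] = (),
                       resolution: float | None = None
                       ) -> tuple[list[Pose], ScoreBreakdown]:
    """Brute-force optimum over the product of library exemplars.

    Intended for small (2-body) problems as an oracle bound for annealing.
    """
    import itertools

    if resolution is None:
        resolution = 3.0 * float(grid.voxel.max())
    pivots = [b.coords.mean(axis=0) for b in bodies]
    cc_cache = [[cross_correlation(b, cl.exemplar, grid, resolution, pv)
                 for cl in lib]
                for b, lib, pv in zip(bodies, libraries, pivots)]
    best: tuple[list[Pose], ScoreBreakdown] | None = None
    for combo in itertools.product(*[range(len(lib)) for lib in libraries]):
        poses = [lib[i].exemplar for lib, i in zip(libraries, combo)]
        ccs = [cc_cache[b][i] for b, i in enumerate(combo)]
        bd = score_configuration(bodies, poses, grid, crosslinks, chainmap,
                                 policy, weights, connectivity, contacts,
                                 resolution, em_per_body=ccs)
        if best is None or bd.total < best[1].total:
            best = (poses, bd)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Run-ensemble convergence diagnostic
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceVerdict:
    converged: bool
    histogram: np.ndarray
    bin_edges: np.ndarray
    best_mode_mean: float
    main_mode_mean: float
    main_mode_sd: float


def score_histogram(scores: Sequence[float], n_bins: int = 20,
                    best_fraction: float = 0.05,
                    separation: float = 2.5) -> ConvergenceVerdict:
    """Histogram of run scores plus a convergence verdict.

    Verdict 'converged' iff the mean of the best (lowest-scoring)
    ``best_fraction`` of runs falls more than ``separation`` robust
    standard deviations (IQR-based) below the main mode's centre (the
    median).  A single near-Gaussian mass of scores therefore reads as not
    converged, while a separated low-score cluster reads as converged.
    Invariant under rescaling all scores by a positive constant.
    """
    scores_arr = np.sort(np.asarray(scores, dtype=float))
    if len(scores_arr) < 30:
        raise ValueError("need at least 30 independent run scores")
    hist, edges = np.histogram(scores_arr, bins=n_bins)
    k = max(1, int(np.floor(best_fraction * len(scores_arr))))
    best_mean = float(scores_arr[:k].mean())
    center = float(np.median(scores_arr))
    q75, q25 = np.percentile(scores_arr, [75, 25])
    sd = float((q75 - q25) / 1.349)
    if sd == 0:
        sd = float(scores_arr.std())
    converged = bool(best_mean < center - separation * sd) if sd > 0 else False
    return ConvergenceVerdict(converged=converged, histogram=hist,
                              bin_edges=edges, best_mode_mean=best_mean,
                              main_mode_mean=center, main_mode_sd=sd)
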