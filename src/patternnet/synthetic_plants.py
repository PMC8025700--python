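"""Procedural wheat-like point clouds with known phenotype ground truth.

Each plant emulates a pot-grown wheat individual as photogrammetry would
see it: a slightly curved vertical stem, a few drooping ribbon leaves, and
0–8 ears — compact elongated ellipsoidal clusters, each sitting atop its
own thin tiller.  Points are sampled on organ surfaces (a reconstruction
samples surfaces, not volumes), perturbed with Gaussian coordinate noise,
and a small fraction of uniform-box outliers stands in for stray
reconstruction artifacts.  Ears are labeled 2, everything else (stem,
leaves, tillers, outliers) 1, so the ear class is always the minority —
the situation the dynamic class weighting in the loss is designed for.

Point budget: ears get ``min(8%, 32%/n_ears)`` of the points each, keeping
the total ear fraction between roughly 5% and 32% at every count in
{0..8}; the remainder is split among stem, tillers and leaves.  Ear
centers are placed on a ring near the top of the canopy with pairwise
separation at least three times the ear radial spread, so individual ears
are recoverable by single-linkage clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pointcloud_io import EAR, NON_EAR, LabeledCloud

__all__ = ["PlantParams", "PhenotypeTruth", "generate_plant", "generate_dataset"]


@dataclass
class PlantParams:
    n_points: int = 2048
    n_ears: int = 3
    stem_height: float = 10.0
    ear_major_axis: float = 1.5
    ear_radial_spread: float = 0.25
    n_leaves: int = 4
    leaf_length: float = 4.0
    leaf_width: float = 0.6
    noise_sd: float | None = None     # default 0.02 * stem_height
    outlier_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_ears <= 8:
            raise ValueError("n_ears must lie in {0..8}")
        if self.n_points < 512:
            raise ValueError("n_points must be >= 512")
        if self.noise_sd is None:
            self.noise_sd = 0.02 * self.stem_height
        if self.stem_height <= 0 or self.ear_major_axis <= 0 or self.ear_radial_spread <= 0:
            raise ValueError("geometry parameters must be positive")
        # ears sit on a ring of radius ~0.25 * stem_height; the ring must be
        # able to hold n_ears centers at >= 3 * radial_spread separation
        if self.n_ears > 1:
            ring = 0.25 * self.stem_height
            chord = 2 * ring * np.sin(np.pi / self.n_ears)
            if chord < 3 * self.ear_radial_spread:
                raise ValueError(
                    f"infeasible geometry: {self.n_ears} ears with radial spread "
                    f"{self.ear_radial_spread} do not fit a stem of height {self.stem_height}"
                )


@dataclass
class PhenotypeTruth:
    """Ground truth consistent with the emitted cloud.

    ``ear_lengths`` are the realized extents of the emitted (noisy) ear
    points along each ear's nominal axis — the quantity a perfect segmenter
    could recover from the cloud itself.  The nominal ellipsoid major axis
    is recorded in the dataset manifest.
    """

    ear_count: int
    ear_lengths: list[float]
    plant_height: float
    ear_point_indices: list[np.ndarray]


def _unit_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _ear_cluster(rng, center, axis_dir, major, spread, n):
    """Area-uniform surface sample of an ellipsoid, semi-axes (major/2, spread, spread).

    Mapping sphere-uniform directions through the axis scaling would pile
    points up at the tips; rejection on the local area stretch factor keeps
    the surface density even, like a photogrammetric reconstruction of the
    organ surface.
    """
    ax, r = major / 2.0, spread
    pts = np.empty((0, 3))
    while pts.shape[0] < n:
        u = _unit_sphere(rng, max(2 * n, 64))
        # area element of the scaling map at direction u
        stretch = np.sqrt((r * r * u[:, 0]) ** 2 + (ax * r * u[:, 1]) ** 2
                          + (ax * r * u[:, 2]) ** 2)
        accept = rng.random(u.shape[0]) < stretch / stretch.max()
        pts = np.vstack([pts, u[accept]])
    u = pts[:n]
    a = axis_dir / np.linalg.norm(axis_dir)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    b = np.cross(a, helper)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    local = u * np.array([ax, r, r])
    return center + local @ np.stack([a, b, c])


def _point_budget(p: PlantParams) -> dict[str, int]:
    m = p.n_points
    n_out = int(round(p.outlier_fraction * m))
    if p.n_ears > 0:
        per_ear = int(round(min(0.08, 0.32 / p.n_ears) * m))
    else:
        per_ear = 0
    n_ear_total = per_ear * p.n_ears
    rest = m - n_out - n_ear_total
    n_tiller = int(round(0.04 * rest)) * p.n_ears if p.n_ears else 0
    n_leaf_total = int(round(0.50 * (rest - n_tiller))) if p.n_leaves else 0
    n_stem = rest - n_tiller - n_leaf_total
    return {"per_ear": per_ear, "outliers": n_out, "tillers": n_tiller,
            "leaves": n_leaf_total, "stem": n_stem}


def generate_plant(params: PlantParams) -> tuple[LabeledCloud, PhenotypeTruth]:
    """Build one labeled plant with exactly ``n_points`` points."""
    p = params
    rng = np.random.default_rng(p.seed)
    budget = _point_budget(p)
    h = p.stem_height
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    # main stem: slightly curved vertical polyline with radial jitter
    bend = rng.uniform(0.02, 0.06) * h
    phase = rng.uniform(0, 2 * np.pi)
    z = rng.uniform(0, h, budget["stem"])
    stem = np.column_stack([
        bend * np.sin(np.pi * z / h) * np.cos(phase),
        bend * np.sin(np.pi * z / h) * np.sin(phase),
        z,
    ])
    stem[:, :2] += rng.normal(0, 0.05, (budget["stem"], 2))
    chunks.append(stem)
    labels.append(np.full(budget["stem"], NON_EAR))

    # leaves: drooping ribbons attached along the lower stem
    if p.n_leaves > 0 and budget["leaves"] > 0:
        counts = np.full(p.n_leaves, budget["leaves"] // p.n_leaves)
        counts[: budget["leaves"] % p.n_leaves] += 1
        for i, n_l in enumerate(counts):
            if n_l == 0:
                continue
            attach = rng.uniform(0.15, 0.7) * h
            theta = rng.uniform(0, 2 * np.pi)
            out_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
            perp = np.array([-np.sin(theta), np.cos(theta), 0.0])
            s = rng.uniform(0, 1, n_l)
            w = rng.uniform(-0.5, 0.5, n_l) * p.leaf_width
            rise = rng.uniform(0.1, 0.3) * p.leaf_length
            droop = rng.uniform(0.3, 0.8) * p.leaf_length
            pts = (np.array([0, 0, attach])
                   + np.outer(s * p.leaf_length, out_dir)
                   + np.outer(w, perp))
            pts[:, 2] += rise * s - droop * s ** 2
            chunks.append(pts)
            labels.append(np.full(n_l, NON_EAR))

    # ears on a ring near the canopy top, each on its own tiller
    truth_indices: list[tuple[int, int]] = []
    ear_axes: list[np.ndarray] = []
    ear_lengths: list[float] = []
    if p.n_ears > 0:
        ring = 0.25 * h
        base_angle = rng.uniform(0, 2 * np.pi)
        angles = base_angle + 2 * np.pi * np.arange(p.n_ears) / max(p.n_ears, 1)
        centers = []
        for j in range(p.n_ears):
            r = ring * rng.uniform(0.85, 1.15)
            # tillers differ in height: alternate low/high around the ring so
            # angular neighbors are also vertically separated
            zc = h * (1.04 + 0.10 * (1 if j % 2 else -1) + rng.uniform(-0.02, 0.02))
            centers.append(np.array([r * np.cos(angles[j]), r * np.sin(angles[j]), zc]))
        centers = np.asarray(centers)
        if p.n_ears > 1:
            from scipy.spatial.distance import pdist
            if pdist(centers).min() < 3 * p.ear_radial_spread:
                raise ValueError("infeasible geometry: ear centers closer than 3x radial spread")
        n_tiller_each = budget["tillers"] // p.n_ears if p.n_ears else 0
        for j in range(p.n_ears):
            center = centers[j]
            if n_tiller_each > 0:
                t = rng.uniform(0, 1, n_tiller_each)
                base = np.array([center[0] * 0.3, center[1] * 0.3, 0.0])
                top = center - np.array([0, 0, p.ear_major_axis * 0.6])
                tiller = base + np.outer(t, top - base)
                tiller[:, :2] += rng.normal(0, 0.04, (n_tiller_each, 2))
                chunks.append(tiller)
                labels.append(np.full(n_tiller_each, NON_EAR))
            tilt = rng.uniform(0, 0.25)
            tilt_dir = rng.uniform(0, 2 * np.pi)
            axis = np.array([np.sin(tilt) * np.cos(tilt_dir),
                             np.sin(tilt) * np.sin(tilt_dir),
                             np.cos(tilt)])
            ear = _ear_cluster(rng, center, axis, p.ear_major_axis,
                               p.ear_radial_spread, budget["per_ear"])
            start = sum(c.shape[0] for c in chunks)
            chunks.append(ear)
            labels.append(np.full(budget["per_ear"], EAR))
            truth_indices.append((start, start + budget["per_ear"]))
            ear_axes.append(axis)

    coords = np.vstack(chunks)
    lab = np.concatenate(labels)
    coords += rng.normal(0, p.noise_sd, coords.shape)
    for (a, b), axis in zip(truth_indices, ear_axes):
        proj = coords[a:b] @ axis
        ear_lengths.append(float(proj.max() - proj.min()))

    # outliers: uniform in the slightly inflated bounding box, non-ear
    n_out = p.n_points - coords.shape[0]
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    outliers = rng.uniform(lo - 0.05 * span, hi + 0.05 * span, (n_out, 3))
    coords = np.vstack([coords, outliers])
    lab = np.concatenate([lab, np.full(n_out, NON_EAR)])

    cloud = LabeledCloud(coords, lab, f"plant_seed{p.seed}")
    truth = PhenotypeTruth(
        ear_count=p.n_ears,
        ear_lengths=ear_lengths,
        plant_height=float(np.ptp(coords[:, 2])),
        ear_point_indices=[np.arange(a, b) for a, b in truth_indices],
    )
    return cloud, truth


_INT_FIELDS = {"n_points", "n_ears", "n_leaves"}


def generate_dataset(n_plants: int, params_ranges: dict | None = None, seed: int = 0):
    """Draw ``n_plants`` plants with per-plant parameters from ranges.

    ``params_ranges`` maps :class:`PlantParams` field names either to a fixed
    value or to an inclusive ``(low, high)`` range (integer fields are drawn
    uniformly over the integers, float fields uniformly over the interval).
    Returns ``(plants, manifest)`` where ``plants`` is a list of
    ``(LabeledCloud, PhenotypeTruth)`` and ``manifest`` a DataFrame with one
    fully reproducible row per plant.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    params_ranges = dict(params_ranges or {})
    valid = set(PlantParams.__dataclass_fields__) - {"seed"}
    unknown = set(params_ranges) - valid
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    master = np.random.default_rng(seed)
    plant_seeds = master.integers(0, 2 ** 31 - 1, size=n_plants)
    plants = []
    rows = []
    for i in range(n_plants):
        rng = np.random.default_rng(plant_seeds[i])
        kwargs = {"seed": int(plant_seeds[i])}
        for name, spec in params_ranges.items():
            if isinstance(spec, (tuple, list)) and len(spec) == 2:
                lo, hi = spec
                if name in _INT_FIELDS:
                    kwargs[name] = int(rng.integers(lo, hi + 1))
                else:
                    kwargs[name] = float(rng.uniform(lo, hi))
            else:
                kwargs[name] = spec
        pp = PlantParams(**kwargs)
        cloud, truth = generate_plant(pp)
        cloud.id = f"plant_{i:04d}"
        plants.append((cloud, truth))
        row = asdict(pp)
        row.update(id=cloud.id, true_ear_count=truth.ear_count,
                   true_plant_height=truth.plant_height)
        rows.append(row)
    manifest = pd.DataFrame(rows).set_index("id")
    return plants, manifest
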