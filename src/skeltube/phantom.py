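"""Synthetic branching-tube phantoms with exact ground truth.

The generator grows a random binary tree of straight tube segments whose
radii taper geometrically per generation — emulating the trunk/distal
imbalance of airways and vessels, where distal branches are far thinner
than the main branch.  Each sample carries the grayscale image (bright
tube on dark background plus Gaussian noise, or the inverse), the exact
binary mask (a union of capsules), and the analytic centerline
decomposed into one branch per tree edge.  Every downstream module is
therefore testable without any external imaging data.

Not modelled: anatomically realistic airway/vessel shapes, stenoses,
contrast agents, CT reconstruction artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .skeleton import BranchSet
from .volumes import BinaryVolume, Geometry, VoxelGrid

__all__ = ["PhantomSpec", "PhantomSample", "GeometryError", "generate_phantom",
           "make_fixture", "FIXTURE_NAMES"]


class GeometryError(ValueError):
    """The requested tube tree cannot be placed inside the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a synthetic tubular tree.

    ``segment_length_vox`` is the root-generation length range; deeper
    generations shrink by ``radius_taper`` as well, keeping trees inside
    small grids.  Identical spec + seed gives bit-identical samples.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tree_depth: int = 3
    root_radius_vox: float = 2.5
    radius_taper: float = 0.6
    branch_angle_deg: tuple[float, float] = (25.0, 50.0)
    segment_length_vox: tuple[float, float] = (11.0, 15.0)
    n_children: int = 2
    tube_intensity: float = 0.8
    background_intensity: float = 0.2
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.tree_depth < 1:
            raise ValueError("tree_depth must be >= 1")
        if self.root_radius_vox < 1:
            raise ValueError("root_radius_vox must be >= 1")
        if not (0 < self.radius_taper <= 1):
            raise ValueError("radius_taper must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")


@dataclass
class PhantomSample:
    """A generated phantom: image, exact mask, analytic centerline, tree."""

    image: VoxelGrid
    mask: BinaryVolume
    centerline_branches: BranchSet
    tree_graph: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask.count() == 0:
            raise ValueError("phantom mask is empty")
        for branch in self.centerline_branches.branches:
            if not self.mask.values[tuple(branch.T)].all():
                raise ValueError("centerline voxel outside mask")


def _orthonormal_pair(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _capsule_fits(p0, p1, r, shape, margin=1.0) -> bool:
    lo = np.minimum(p0, p1) - r - margin
    hi = np.maximum(p0, p1) + r + margin
    return bool((lo >= 0).all() and (hi <= np.asarray(shape) - 1).all())


def _rasterize_capsule(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, r: float) -> None:
    """Mark voxels whose centers lie within distance r of segment p0-p1."""
    shape = mask.shape
    lo = np.maximum(np.floor(np.minimum(p0, p1) - r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + r + 1).astype(int) + 1, shape)
    zz, yy, xx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0.0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
        dist = np.linalg.norm(pts - p0 - t[..., None] * d, axis=-1)
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= dist <= r


def _discretize_segment(p0: np.ndarray, p1: np.ndarray, shape) -> np.ndarray:
    """Voxelize a segment: dense samples, rounded, deduplicated, in order."""
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(math.ceil(length * 3)) + 1, 2)
    pts = np.rint(np.linspace(p0, p1, n)).astype(np.intp)
    pts = np.clip(pts, 0, np.asarray(shape) - 1)
    keep = np.ones(len(pts), dtype=bool)
    seen: set[tuple[int, int, int]] = set()
    for i, v in enumerate(map(tuple, pts)):
        if v in seen:
            keep[i] = False
        seen.add(v)
    return pts[keep]


def _grow_tree(spec: PhantomSpec, rng: np.random.Generator):
    """Sample the segment tree; returns (segments, radii, nodes, parents).

    Child directions are re-drawn (deterministically, from the same seeded
    stream) up to a fixed number of times if the capsule would leave the
    grid, then the segment is shortened; only when nothing fits does the
    generator signal a GeometryError.
    """
    shape = np.asarray(spec.grid_shape, dtype=float)
    root = np.array([spec.root_radius_vox + 1.5, shape[1] / 2.0, shape[2] / 2.0])
    tilt = math.radians(8.0)
    theta = rng.uniform(0, tilt)
    phi = rng.uniform(0, 2 * math.pi)
    d0 = np.array([math.cos(theta),
                   math.sin(theta) * math.cos(phi),
                   math.sin(theta) * math.sin(phi)])

    segments: list[tuple[np.ndarray, np.ndarray]] = []
    radii: list[float] = []
    nodes: list[np.ndarray] = [root]
    parents: list[int] = [-1]

    def grow(pos: np.ndarray, direction: np.ndarray, gen: int, parent_node: int) -> None:
        if gen >= spec.tree_depth:
            return
        scale = spec.radius_taper ** gen
        radius = max(1.0, spec.root_radius_vox * scale)
        base_len = rng.uniform(*spec.segment_length_vox) * scale
        end = None
        for attempt in range(24):
            length = max(base_len * (0.85 ** attempt), 3.0)
            if attempt == 0:
                cand_dir = direction
            else:
                ang = math.radians(rng.uniform(*spec.branch_angle_deg))
                az = rng.uniform(0, 2 * math.pi)
                u, v = _orthonormal_pair(direction)
                cand_dir = (math.cos(ang) * direction
                            + math.sin(ang) * (math.cos(az) * u + math.sin(az) * v))
                cand_dir = cand_dir / np.linalg.norm(cand_dir)
            cand_end = pos + length * cand_dir
            if _capsule_fits(pos, cand_end, radius, spec.grid_shape):
                end, direction = cand_end, cand_dir
                break
        if end is None:
            raise GeometryError(
                f"segment at generation {gen} does not fit in grid {spec.grid_shape}"
            )
        segments.append((pos.copy(), end.copy()))
        radii.append(radius)
        nodes.append(end.copy())
        node_idx = len(nodes) - 1
        parents.append(parent_node)
        if gen + 1 >= spec.tree_depth:
            return
        base_az = rng.uniform(0, 2 * math.pi)
        for c in range(spec.n_children):
            ang = math.radians(rng.uniform(*spec.branch_angle_deg))
            az = base_az + 2 * math.pi * c / spec.n_children + rng.uniform(-0.4, 0.4)
            u, v = _orthonormal_pair(direction)
            child_dir = (math.cos(ang) * direction
                         + math.sin(ang) * (math.cos(az) * u + math.sin(az) * v))
            child_dir = child_dir / np.linalg.norm(child_dir)
            grow(end, child_dir, gen + 1, node_idx)

    if not _capsule_fits(root, root, max(1.0, spec.root_radius_vox), spec.grid_shape):
        raise GeometryError(f"root radius {spec.root_radius_vox} does not fit in grid")
    grow(root, d0, 0, 0)
    return segments, radii, nodes, parents


def _assemble(spec: PhantomSpec, segments, radii, nodes, parents,
              rng: np.random.Generator) -> PhantomSample:
    geom = Geometry(spec.grid_shape, spec.spacing_mm)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    branches = []
    for (p0, p1), r in zip(segments, radii):
        _rasterize_capsule(mask, p0, p1, r)
        branches.append(_discretize_segment(p0, p1, spec.grid_shape))
    # centerline voxels are guaranteed foreground even where rounding
    # pushes them past a sub-voxel radius
    for b in branches:
        mask[tuple(b.T)] = True
    # branch voxel sets must be pairwise disjoint; voxels shared at
    # junctions are assigned to the earlier (parent) branch
    claimed: set[tuple[int, int, int]] = set()
    clean_branches = []
    for b in branches:
        keep = [v for v in map(tuple, b) if v not in claimed]
        claimed.update(keep)
        clean_branches.append(np.asarray(keep, dtype=np.intp))
    bif_nodes = [nodes[i] for i in range(len(nodes))
                 if sum(1 for p in parents if p == i) >= 2]
    bif = np.rint(np.asarray(bif_nodes, dtype=float)).astype(np.intp).reshape(-1, 3)

    image = np.where(mask, spec.tube_intensity, spec.background_intensity).astype(np.float64)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    lo = min(spec.tube_intensity, spec.background_intensity) - 3.0 * spec.noise_sd
    hi = max(spec.tube_intensity, spec.background_intensity) + 3.0 * spec.noise_sd
    image = np.clip(image, lo, hi).astype(np.float32)

    return PhantomSample(
        image=VoxelGrid(image, geom),
        mask=BinaryVolume(mask.astype(np.uint8), geom),
        centerline_branches=BranchSet(clean_branches, bif, len(clean_branches)),
        tree_graph={"nodes": [list(map(float, n)) for n in nodes], "parents": parents},
    )


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom from a seeded spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    segments, radii, nodes, parents = _grow_tree(spec, rng)
    return _assemble(spec, segments, radii, nodes, parents, rng)


def _fixture_from_segments(shape, segments, radii) -> PhantomSample:
    spec = PhantomSpec(grid_shape=shape, noise_sd=0.0, tree_depth=1)
    segs = [(np.asarray(p0, float), np.asarray(p1, float)) for p0, p1 in segments]
    nodes = [segs[0][0]] + [s[1] for s in segs]
    parents = [-1] + [0] * len(segs)
    rng = np.random.default_rng(0)
    return _assemble(spec, segs, radii, nodes, parents, rng)


def _make_straight_tube() -> PhantomSample:
    return _fixture_from_segments((27, 15, 15), [((3, 7, 7), (22, 7, 7))], [2.0])


def _make_single_voxel() -> PhantomSample:
    shape = (9, 9, 9)
    return _fixture_from_segments(shape, [((4, 4, 4), (4, 4, 4))], [0.5])


def _make_y_junction() -> PhantomSample:
    segs = [((3, 10, 10), (15, 10, 10)),
            ((15, 10, 10), (27, 4, 10)),
            ((15, 10, 10), (27, 16, 10))]
    sample = _fixture_from_segments((33, 21, 21), segs, [2.0, 2.0, 2.0])
    # the meeting point is a bifurcation of the analytic tree
    sample.centerline_branches.bifurcation_points = np.array([[15, 10, 10]], dtype=np.intp)
    return sample


def _make_two_blobs() -> PhantomSample:
    segs = [((6, 7, 7), (6, 7, 7)), ((20, 7, 7), (20, 7, 7))]
    return _fixture_from_segments((27, 15, 15), segs, [3.0, 3.0])


_FIXTURES = {
    "straight_tube": _make_straight_tube,
    "single_voxel": _make_single_voxel,
    "y_junction": _make_y_junction,
    "two_blobs": _make_two_blobs,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> PhantomSample:
    """Small (<= 40^3) hand-specified deterministic volumes used as oracles.

    Registry: ``straight_tube`` (20-voxel-long radius-2 tube along z),
    ``y_junction`` (three tubes meeting at one point), ``single_voxel``,
    ``two_blobs`` (two disjoint spheres).
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}") from None
    return builder()
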