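"""Seeded synthetic black-blood-like volumes with known lesions.

The generator stands in for a clinical contrast-enhanced cohort: an
ellipsoidal "brain" of uniform tissue intensity inside a bright skull rim,
spherical hyperintense lesions (the detection targets), and curvilinear
hyperintense tubes emulating vessels.  In black-blood contrast most of each
vessel's length is suppressed to tissue intensity, leaving residual bright
segments — the dominant false-positive source for enhancing-lesion
detectors; a "gre" preset leaves the vessels fully bright, as in
gradient-echo contrast where vessels are not suppressed.

Ground truth (per-slice tight bounding boxes of every lesion cross-section)
is computed from the ball geometry before noise is added, so the truth is
exact regardless of the noise level.

Geometry defaults use a 256x256 in-plane matrix at 0.9 mm pixels and 3 mm
slices — a half-resolution version of a 512x512 / 0.45 mm axial
reconstruction covering the same 230 mm field of view, preserving the
relation between the 5 mm lesion-diameter floor and the two-slice minimum
extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .core import Box2D, Volume3D, write_boxes, write_volume, read_boxes, read_volume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "LesionSpec",
    "ScanRecord",
    "CohortManifest",
    "PlacementError",
    "generate_scan",
    "generate_cohort",
    "save_manifest",
    "load_manifest",
]

TISSUE_INTENSITY = 1.0
SKULL_INTENSITY = 2.0

# a lesion must be visible on at least two slices with this many voxels each
MIN_SLICE_VOXELS = 4


class PlacementError(RuntimeError):
    """Lesions could not be placed without overlap within the retry budget."""


@dataclass
class PhantomConfig:
    """Generative parameters of one synthetic scan.

    ``lesion_intensity`` and ``vessel_intensity`` are multiples of the tissue
    mean; ``vessel_suppression`` is the fraction of each vessel's length
    rendered at tissue intensity (high for the black-blood preset, 0 for the
    gradient-echo-like preset); ``noise_sigma`` is the standard deviation of
    additive Gaussian noise relative to tissue intensity 1.0.
    """

    grid: tuple[int, int, int] = (40, 256, 256)
    pixel_size_mm: tuple[float, float] = (0.9, 0.9)
    slice_thickness_mm: float = 3.0
    n_lesions: int = 5
    lesion_diameter_range_mm: tuple[float, float] = (5.0, 25.0)
    lesion_intensity: float = 3.0
    n_vessels: int = 6
    vessel_suppression: float = 0.85
    vessel_intensity: float = 2.8
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid) < 1:
            raise ValueError("grid dimensions must be >= 1")
        lo, hi = self.lesion_diameter_range_mm
        if lo < 5.0:
            raise ValueError("lesion diameters below the 5 mm floor are not generated")
        if lo > hi:
            raise ValueError("lesion_diameter_range_mm must be (low, high)")
        if not (0.0 <= self.vessel_suppression <= 1.0):
            raise ValueError("vessel_suppression must lie in [0, 1]")
        if self.n_lesions < 0 or self.n_vessels < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def preset(cls, name: str, **overrides) -> "PhantomConfig":
        """Contrast presets: ``bb`` (vessels mostly suppressed) or ``gre``."""
        if name == "bb":
            base = {"vessel_suppression": 0.85}
        elif name == "gre":
            base = {"vessel_suppression": 0.0}
        else:
            raise ValueError(f"unknown preset {name!r} (expected 'bb' or 'gre')")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def paper_geometry(cls, **overrides) -> "PhantomConfig":
        """Full-resolution axial geometry: 512x512 matrix, 0.45 mm pixels."""
        base = {"grid": (40, 512, 512), "pixel_size_mm": (0.45, 0.45)}
        base.update(overrides)
        return cls(**base)


@dataclass
class LesionSpec:
    lesion_id: int
    center_mm: tuple[float, float, float]  # (z, y, x)
    diameter_mm: float


@dataclass
class PhantomTruth:
    """Ground truth of one synthetic scan."""

    lesions: list[LesionSpec]
    gt_boxes: list[Box2D]
    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    vessel_mask: np.ndarray


def _coords_mm(config: PhantomConfig):
    ns, nr, nc = config.grid
    pr, pc = config.pixel_size_mm
    st = config.slice_thickness_mm
    z = (np.arange(ns) + 0.5) * st
    y = (np.arange(nr) + 0.5) * pr
    x = (np.arange(nc) + 0.5) * pc
    return z, y, x


def _ellipsoid_frame(config: PhantomConfig):
    """Centre and semi-axes (mm) of the brain ellipsoid for this grid."""
    z, y, x = _coords_mm(config)
    extents = (z[-1] + z[0], y[-1] + y[0], x[-1] + x[0])  # full extent in mm
    center = tuple(e / 2.0 for e in extents)
    semi = (0.40 * extents[0], 0.36 * extents[1], 0.40 * extents[2])
    return center, semi


def _norm_field(config: PhantomConfig):
    """sqrt of the ellipsoid quadratic form on the voxel-centre grid."""
    z, y, x = _coords_mm(config)
    (cz, cy, cx), (az, ay, ax) = _ellipsoid_frame(config)
    q = (
        ((z - cz) / az)[:, None, None] ** 2
        + ((y - cy) / ay)[None, :, None] ** 2
        + ((x - cx) / ax)[None, None, :] ** 2
    )
    return np.sqrt(q)


def _point_norm(p, config: PhantomConfig) -> float:
    (cz, cy, cx), (az, ay, ax) = _ellipsoid_frame(config)
    return float(np.sqrt(((p[0] - cz) / az) ** 2 + ((p[1] - cy) / ay) ** 2
                         + ((p[2] - cx) / ax) ** 2))


def _rasterize_ball(center, radius, config: PhantomConfig):
    """Per-slice pixel masks of a ball, keyed by slice index.

    A voxel belongs to the ball if its centre (evaluated in-plane at the
    slice-centre z position) lies strictly inside the sphere.
    """
    z, y, x = _coords_mm(config)
    cz, cy, cx = center
    out = {}
    for k in np.nonzero(np.abs(z - cz) < radius)[0]:
        r_k2 = radius**2 - (z[k] - cz) ** 2
        dy2 = (y - cy) ** 2
        dx2 = (x - cx) ** 2
        mask = dy2[:, None] + dx2[None, :] <= r_k2
        if mask.any():
            out[int(k)] = mask
    return out


def _tight_box(mask2d: np.ndarray, slice_index: int, lesion_id: int | None,
               scan_id: str | None) -> Box2D:
    rows = np.nonzero(mask2d.any(axis=1))[0]
    cols = np.nonzero(mask2d.any(axis=0))[0]
    return Box2D(
        slice_index=slice_index,
        x=float(cols[0]),
        y=float(rows[0]),
        w=float(cols[-1] - cols[0] + 1),
        h=float(rows[-1] - rows[0] + 1),
        lesion_id=lesion_id,
        scan_id=scan_id,
    )


def _place_lesions(config: PhantomConfig, rng: np.random.Generator,
                   scan_id: str):
    """Sample non-overlapping ball lesions whose rasters span >= 2 slices."""
    (cz, cy, cx), (az, ay, ax) = _ellipsoid_frame(config)
    min_semi = min(az, ay, ax)
    lo, hi = config.lesion_diameter_range_mm
    specs: list[LesionSpec] = []
    placed: list[tuple[tuple[float, float, float], float]] = []
    rasters: list[dict[int, np.ndarray]] = []
    max_tries = 400 * max(1, config.n_lesions)
    tries = 0
    while len(specs) < config.n_lesions:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {config.n_lesions} non-overlapping lesions "
                f"after {max_tries} attempts"
            )
        tries += 1
        diameter = float(rng.uniform(lo, hi))
        radius = diameter / 2.0
        # uniform in the ellipsoid bounding box, accept if the ball fits inside
        p = (
            cz + az * rng.uniform(-1, 1),
            cy + ay * rng.uniform(-1, 1),
            cx + ax * rng.uniform(-1, 1),
        )
        if _point_norm(p, config) > 1.0 - (radius + 2.0) / min_semi:
            continue
        if any(
            np.sqrt(sum((a - b) ** 2 for a, b in zip(p, q))) <= radius + r + 2.0
            for q, r in placed
        ):
            continue
        raster = _rasterize_ball(p, radius, config)
        visible = [k for k, m in raster.items() if int(m.sum()) >= MIN_SLICE_VOXELS]
        if len(visible) < 2:
            continue
        lesion_id = len(specs) + 1
        specs.append(LesionSpec(lesion_id=lesion_id, center_mm=p, diameter_mm=diameter))
        placed.append((p, radius))
        rasters.append(raster)
    return specs, rasters


def _walk_vessel(config: PhantomConfig, rng: np.random.Generator):
    """One random-walk tube: centreline points (mm) and radius."""
    (cz, cy, cx), (az, ay, ax) = _ellipsoid_frame(config)
    # start well inside the brain
    while True:
        p = np.array([
            cz + az * rng.uniform(-0.8, 0.8),
            cy + ay * rng.uniform(-0.8, 0.8),
            cx + ax * rng.uniform(-0.8, 0.8),
        ])
        if _point_norm(p, config) <= 0.8:
            break
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    n_steps = int(rng.integers(60, 160))
    radius = float(rng.uniform(0.6, 1.6))
    step = 1.0  # mm
    pts = [p.copy()]
    for _ in range(n_steps):
        d = d + rng.normal(0.0, 0.25, size=3)
        d /= np.linalg.norm(d)
        p = p + d * step
        if _point_norm(p, config) > 0.95:
            break
        pts.append(p.copy())
    return np.array(pts), radius


def _suppression_mask(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Mark random contiguous windows until `fraction` of the length is dark."""
    suppressed = np.zeros(n, dtype=bool)
    if fraction <= 0 or n == 0:
        return suppressed
    if fraction >= 0.999:
        suppressed[:] = True
        return suppressed
    for _ in range(200):
        if suppressed.mean() >= fraction:
            break
        start = int(rng.integers(0, n))
        length = max(1, int(rng.uniform(0.05, 0.25) * n))
        suppressed[start:start + length] = True
    return suppressed


def _stamp_balls(points_mm, radius, allowed: np.ndarray, target: np.ndarray,
                 config: PhantomConfig) -> None:
    """OR small balls at `points_mm` into `target`, restricted to `allowed`."""
    z, y, x = _coords_mm(config)
    st = config.slice_thickness_mm
    pr, pc = config.pixel_size_mm
    ns, nr, nc = config.grid
    for p in points_mm:
        k0 = max(0, int((p[0] - radius) / st))
        k1 = min(ns - 1, int((p[0] + radius) / st) + 1)
        i0 = max(0, int((p[1] - radius) / pr))
        i1 = min(nr - 1, int((p[1] + radius) / pr) + 1)
        j0 = max(0, int((p[2] - radius) / pc))
        j1 = min(nc - 1, int((p[2] + radius) / pc) + 1)
        if k1 < k0 or i1 < i0 or j1 < j0:
            continue
        zz = z[k0:k1 + 1] - p[0]
        yy = y[i0:i1 + 1] - p[1]
        xx = x[j0:j1 + 1] - p[2]
        ball = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
            <= radius**2
        )
        sub = target[k0:k1 + 1, i0:i1 + 1, j0:j1 + 1]
        sub |= ball & allowed[k0:k1 + 1, i0:i1 + 1, j0:j1 + 1]


def generate_scan(config: PhantomConfig, scan_id: str = "phantom") -> tuple[Volume3D, PhantomTruth]:
    """Generate one synthetic scan and its exact ground truth.

    Deterministic given ``config.seed``: the same configuration always
    produces a bit-identical volume.
    """
    rng = np.random.default_rng(config.seed)
    norm = _norm_field(config)
    brain_mask = norm <= 1.0
    skull_mask = (norm > 1.10) & (norm <= 1.22)

    specs, rasters = _place_lesions(config, rng, scan_id)

    lesion_mask = np.zeros(config.grid, dtype=bool)
    gt_boxes: list[Box2D] = []
    for spec, raster in zip(specs, rasters):
        for k in sorted(raster):
            m = raster[k]
            lesion_mask[k] |= m
            gt_boxes.append(_tight_box(m, k, spec.lesion_id, scan_id))

    vessel_mask = np.zeros(config.grid, dtype=bool)
    allowed = brain_mask & ~lesion_mask
    for _ in range(config.n_vessels):
        pts, radius = _walk_vessel(config, rng)
        dark = _suppression_mask(len(pts), config.vessel_suppression, rng)
        bright_pts = pts[~dark]
        if len(bright_pts):
            _stamp_balls(bright_pts, radius, allowed, vessel_mask, config)
    vessel_mask &= ~lesion_mask  # invariant: masks disjoint

    vol = np.zeros(config.grid, dtype=np.float32)
    vol[brain_mask] = TISSUE_INTENSITY
    vol[skull_mask] = SKULL_INTENSITY
    vol[vessel_mask] = config.vessel_intensity * TISSUE_INTENSITY
    vol[lesion_mask] = config.lesion_intensity * TISSUE_INTENSITY
    if config.noise_sigma > 0:
        vol = vol + rng.normal(0.0, config.noise_sigma, size=config.grid).astype(np.float32)

    volume = Volume3D(
        data=vol,
        pixel_size_mm=config.pixel_size_mm,
        slice_thickness_mm=config.slice_thickness_mm,
        scan_id=scan_id,
    )
    truth = PhantomTruth(
        lesions=specs,
        gt_boxes=gt_boxes,
        brain_mask=brain_mask,
        lesion_mask=lesion_mask,
        vessel_mask=vessel_mask,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class ScanRecord:
    """One scan of a cohort manifest (in memory or on disk)."""

    scan_id: str
    kind: str  # "lesion" | "normal"
    seed: int
    volume: Volume3D | None = None
    gt_boxes: list[Box2D] | None = None
    volume_path: str | None = None
    boxes_path: str | None = None

    def get_volume(self) -> Volume3D:
        if self.volume is not None:
            return self.volume
        return read_volume(self.volume_path)

    def get_gt_boxes(self) -> list[Box2D]:
        if self.gt_boxes is not None:
            return self.gt_boxes
        return read_boxes(self.boxes_path)


@dataclass
class CohortManifest:
    master_seed: int
    scans: list[ScanRecord] = field(default_factory=list)

    @property
    def lesion_scans(self) -> list[ScanRecord]:
        return [s for s in self.scans if s.kind == "lesion"]

    @property
    def normal_scans(self) -> list[ScanRecord]:
        return [s for s in self.scans if s.kind == "normal"]


def _scan_seed(master_seed: int, index: int) -> int:
    """Per-scan stream derived from (master seed, index): order-independent."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_cohort(
    n_scans: int,
    n_normals: int,
    config: PhantomConfig | None = None,
    out_dir: str | Path | None = None,
) -> CohortManifest:
    """Generate a cohort of lesion-bearing scans plus lesion-free normals.

    Normals use ``n_lesions=0`` but keep the vessels (their false-positive
    sources are the point of the normal arm).  With ``out_dir`` set, volumes
    are written as NIfTI, truth boxes as CSV, and a YAML manifest indexes
    them; otherwise everything stays in memory.
    """
    if n_scans < 0 or n_normals < 0:
        raise ValueError("cohort sizes must be non-negative")
    config = config or PhantomConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest = CohortManifest(master_seed=config.seed)
    for idx in range(n_scans + n_normals):
        is_normal = idx >= n_scans
        scan_id = f"normal{idx - n_scans:03d}" if is_normal else f"met{idx:03d}"
        seed = _scan_seed(config.seed, idx)
        cfg = replace(config, seed=seed, n_lesions=0 if is_normal else config.n_lesions)
        volume, truth = generate_scan(cfg, scan_id=scan_id)
        rec = ScanRecord(
            scan_id=scan_id,
            kind="normal" if is_normal else "lesion",
            seed=seed,
            volume=volume,
            gt_boxes=truth.gt_boxes,
        )
        if out_dir is not None:
            vol_path = out_dir / f"{scan_id}.nii.gz"
            box_path = out_dir / f"{scan_id}_truth.csv"
            write_volume(volume, vol_path)
            write_boxes(truth.gt_boxes, box_path)
            rec.volume_path = str(vol_path)
            rec.boxes_path = str(box_path)
            rec.volume = None
            rec.gt_boxes = None
        manifest.scans.append(rec)

    if out_dir is not None:
        save_manifest(manifest, out_dir / "manifest.yaml")
    return manifest


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    doc = {
        "master_seed": manifest.master_seed,
        "scans": [
            {
                "scan_id": s.scan_id,
                "kind": s.kind,
                "seed": s.seed,
                "volume": s.volume_path,
                "boxes": s.boxes_path,
            }
            for s in manifest.scans
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_manifest(path: str | Path) -> CohortManifest:
    doc = yaml.safe_load(Path(path).read_text())
    manifest = CohortManifest(master_seed=int(doc["master_seed"]))
    for s in doc["scans"]:
        manifest.scans.append(
            ScanRecord(
                scan_id=s["scan_id"],
                kind=s["kind"],
                seed=int(s["seed"]),
                volume_path=s["volume"],
                boxes_path=s["boxes"],
            )
        )
    return manifest
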