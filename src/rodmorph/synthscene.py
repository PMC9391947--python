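"""Synthetic monolayers of rod-shaped cells with exact ground truth.

Fission-yeast cells are, to a good approximation, 2D stadiums in a focal
plane: a rectangle of length ``L - W`` capped by two semicircles of diameter
``W``.  The stadium has closed-form area ``(L - W) * W + pi * (W / 2)**2``,
maximum Feret diameter ``L`` and minimum Feret diameter ``W``, which makes a
rendered scene an analytic oracle for every downstream stage (segmentation
refinement, morphometry, evaluation).

A scene is sampled from a single :class:`numpy.random.Generator` seeded from
:attr:`SceneSpec.seed`; draws happen in a fixed documented order (per cell:
length, width, orientation, center row, center col; then one noise field), so
an identical spec reproduces a bit-identical scene.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "ScenePlacementError",
    "sample_scene",
    "write_scene",
]

#: Calibration of the reference imaging setup: a 1920 x 1440 px frame spanning
#: 241.56 x 181.17 um, i.e. 241.56 / 1920 um per pixel.
DEFAULT_MICRONS_PER_PIXEL = 241.56 / 1920.0


class ScenePlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all requested cells."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic rod-cell scene.

    Defaults emulate a monolayer of fission-yeast-like cells: lengths
    7-20 um, widths 3-5 um, at 0.1258125 um/px, rendered darker than a
    bright background (brightfield-like contrast) with mild Gaussian noise.
    """

    image_height_px: int = 768
    image_width_px: int = 1024
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    n_cells: int = 40
    length_range_um: tuple[float, float] = (7.0, 20.0)
    width_range_um: tuple[float, float] = (3.0, 5.0)
    orientation: str = "uniform"  # uniform over [0, 180) degrees
    min_gap_px: int = 5
    background_level: int = 200
    cell_level: int = 90
    noise_sd: float = 4.0
    seed: int = 0
    allow_border_clip: bool = False
    max_attempts_per_cell: int = 500

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        for name in ("length_range_um", "width_range_um"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        if self.orientation != "uniform":
            raise ValueError("only the 'uniform' orientation distribution is supported")
        if self.min_gap_px < 0:
            raise ValueError("min_gap_px must be non-negative")
        for name in ("background_level", "cell_level"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SceneTruth:
    """Exact ground truth of a sampled scene.

    ``records`` has one row per cell with columns cell_id, center_row,
    center_col, orientation_deg, length_um, width_um.  ``labels`` is an
    integer instance image (0 = background) and ``mask`` its foreground.
    """

    records: pd.DataFrame
    mask: np.ndarray
    labels: np.ndarray


def _point_segment_distance(rows, cols, p, q):
    """Distance from pixel centers (rows, cols) to the segment p-q."""
    d = q - p
    den = float(d @ d)
    vr = rows - p[0]
    vc = cols - p[1]
    if den == 0.0:
        return np.hypot(vr, vc)
    t = np.clip((vr * d[0] + vc * d[1]) / den, 0.0, 1.0)
    return np.hypot(vr - t * d[0], vc - t * d[1])


def _segment_segment_distance(p1, q1, p2, q2):
    """Minimum distance between two 2D segments."""

    def pt_seg(pt, a, b):
        d = b - a
        den = float(d @ d)
        if den == 0.0:
            return float(np.hypot(*(pt - a)))
        t = min(1.0, max(0.0, float((pt - a) @ d) / den))
        return float(np.hypot(*(pt - a - t * d)))

    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    c = float(d1 @ r)
    b = float(d1 @ d2)
    den = a * e - b * b
    if den > 1e-12:
        s = min(1.0, max(0.0, (b * f - c * e) / den))
    else:
        s = 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    t = min(1.0, max(0.0, t))
    # re-clamp s for the clamped t
    if a > 1e-12:
        s = min(1.0, max(0.0, (b * t - c) / a))
    c1 = p1 + s * d1
    c2 = p2 + t * d2
    # candidate refinement: also check endpoint projections
    best = float(np.hypot(*(c1 - c2)))
    for pt, (aa, bb) in ((p1, (p2, q2)), (q1, (p2, q2)), (p2, (p1, q1)), (q2, (p1, q1))):
        best = min(best, pt_seg(pt, aa, bb))
    return best


@dataclass
class _Cell:
    center: np.ndarray  # (row, col)
    theta_deg: float
    length_px: float
    width_px: float

    @property
    def axis(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the central axis segment (length L - W)."""
        half = max(self.length_px - self.width_px, 0.0) / 2.0
        th = math.radians(self.theta_deg)
        # orientation measured from the column (x) axis; rows grow downward
        u = np.array([-math.sin(th), math.cos(th)])
        return self.center - half * u, self.center + half * u

    @property
    def radius(self) -> float:
        return self.width_px / 2.0


def _sample_cell(rng: np.random.Generator, spec: SceneSpec) -> tuple[float, float, float]:
    """Draw (length_um, width_um, orientation_deg) with length >= width."""
    for _ in range(100):
        length = rng.uniform(*spec.length_range_um)
        width = rng.uniform(*spec.width_range_um)
        if length >= width:
            break
    else:  # pragma: no cover - only reachable with pathological ranges
        raise ScenePlacementError("could not draw a cell with length >= width")
    theta = rng.uniform(0.0, 180.0)
    return length, width, theta


def _placement_bounds(cell_len_px, cell_wid_px, theta_deg, h, w, clip_ok):
    """Valid center range so the whole stadium fits inside the frame."""
    if clip_ok:
        return (0.0, h - 1.0), (0.0, w - 1.0)
    half = max(cell_len_px - cell_wid_px, 0.0) / 2.0
    r = cell_wid_px / 2.0
    th = math.radians(theta_deg)
    ext_r = abs(half * math.sin(th)) + r
    ext_c = abs(half * math.cos(th)) + r
    return (ext_r, h - 1.0 - ext_r), (ext_c, w - 1.0 - ext_c)


def sample_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render a synthetic scene and its exact ground truth.

    Returns the 8-bit image and a :class:`SceneTruth`.  Cells are placed by
    rejection sampling; boundaries of distinct cells are kept at least
    ``spec.min_gap_px`` apart (0 permits touching).  Raises
    :class:`ScenePlacementError` if a cell cannot be placed within
    ``spec.max_attempts_per_cell`` attempts, naming how many were placed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    mpp = spec.microns_per_pixel

    cells: list[_Cell] = []
    rows_truth = []
    for i in range(spec.n_cells):
        placed = False
        for _ in range(spec.max_attempts_per_cell):
            length_um, width_um, theta = _sample_cell(rng, spec)
            lpx, wpx = length_um / mpp, width_um / mpp
            (rlo, rhi), (clo, chi) = _placement_bounds(
                lpx, wpx, theta, h, w, spec.allow_border_clip
            )
            if rhi < rlo or chi < clo:
                continue  # cell too large for the frame at this orientation
            center = np.array([rng.uniform(rlo, rhi), rng.uniform(clo, chi)])
            cand = _Cell(center, theta, lpx, wpx)
            p1, q1 = cand.axis
            ok = True
            for other in cells:
                p2, q2 = other.axis
                gap = (
                    _segment_segment_distance(p1, q1, p2, q2)
                    - cand.radius
                    - other.radius
                )
                if gap < spec.min_gap_px:
                    ok = False
                    break
            if ok:
                cells.append(cand)
                rows_truth.append(
                    {
                        "cell_id": i + 1,
                        "center_row": center[0],
                        "center_col": center[1],
                        "orientation_deg": theta,
                        "length_um": length_um,
                        "width_um": width_um,
                    }
                )
                placed = True
                break
        if not placed:
            raise ScenePlacementError(
                f"placed {len(cells)} of {spec.n_cells} cells before exceeding "
                f"{spec.max_attempts_per_cell} attempts; reduce n_cells, cell "
                "size, or min_gap_px"
            )

    labels = np.zeros((h, w), dtype=np.int32)
    for idx, cell in enumerate(cells, start=1):
        p, q = cell.axis
        r = cell.radius
        r0 = max(int(math.floor(min(p[0], q[0]) - r - 1)), 0)
        r1 = min(int(math.ceil(max(p[0], q[0]) + r + 1)), h - 1)
        c0 = max(int(math.floor(min(p[1], q[1]) - r - 1)), 0)
        c1 = min(int(math.ceil(max(p[1], q[1]) + r + 1)), w - 1)
        rr, cc = np.meshgrid(
            np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
        )
        inside = _point_segment_distance(rr.astype(float), cc.astype(float), p, q) <= r
        sub = labels[r0 : r1 + 1, c0 : c1 + 1]
        sub[inside] = idx

    mask = labels > 0
    image = np.where(mask, float(spec.cell_level), float(spec.background_level))
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    records = pd.DataFrame(
        rows_truth,
        columns=[
            "cell_id",
            "center_row",
            "center_col",
            "orientation_deg",
            "length_um",
            "width_um",
        ],
    )
    return image, SceneTruth(records=records, mask=mask, labels=labels)


def stadium_area_um2(length_um: float, width_um: float) -> float:
    """Closed-form stadium area (L - W) * W + pi * (W / 2)**2."""
    return (length_um - width_um) * width_um + math.pi * (width_um / 2.0) ** 2


def write_scene(out_dir, image: np.ndarray, truth: SceneTruth, stem: str = "scene"):
    """Write image (TIFF), ground-truth mask (PNG 0/255) and truth CSV.

    Returns the three paths written.
    """
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}.tif"
    mask_path = out / f"{stem}_mask.png"
    csv_path = out / f"{stem}_truth.csv"
    tifffile.imwrite(img_path, image)
    iio.imwrite(mask_path, (truth.mask.astype(np.uint8) * 255))
    truth.records.to_csv(csv_path, index=False, float_format="%.6g")
    return img_path, mask_path, csv_path


def spec_from_mapping(mapping: dict) -> SceneSpec:
    """Build a SceneSpec from a flat config mapping (unknown keys rejected)."""
    fields = {f.name for f in dataclasses.fields(SceneSpec)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown scene parameters: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("length_range_um", "width_range_um"):
        if key in kwargs:
            lo, hi = kwargs[key]
            kwargs[key] = (float(lo), float(hi))
    return SceneSpec(**kwargs)
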