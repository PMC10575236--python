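"""Shared domain types for the landing-line pipeline.

Coordinates are continuous, 0-based pixels with half-open extents:
a box spans ``[x_min, x_max) x [y_min, y_max)`` so its width is simply
``x_max - x_min``.  Every other module builds on the types defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from PIL import Image
from shapely import geometry as sgeom

__all__ = [
    "BoundingBox",
    "PolygonMask",
    "SpeciesClass",
    "SpeciesCatalog",
    "CameraCalibration",
    "Detection",
    "LabeledImage",
    "box_iou",
    "read_labeled_dataset",
    "write_labeled_dataset",
    "read_detections",
    "write_detections",
    "load_catalog",
    "default_catalog",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if min(vals) < 0:
            raise ValueError(f"box coordinates must be >= 0, got {vals}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"box must have positive width and height, got {vals}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class PolygonMask:
    """Simple polygon (>= 3 vertices, positive area, no self-intersection)."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = sgeom.Polygon(verts)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValueError("polygon must enclose positive area")

    def to_shapely(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.to_shapely().area

    def bounding_box(self) -> BoundingBox:
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return BoundingBox(min(xs), min(ys), max(xs), max(ys))

    def clipped(self, width: float, height: float) -> "PolygonMask | None":
        """Intersect with the image rectangle; None if nothing remains.

        A multi-part intersection keeps its largest piece (labeling tools
        occasionally emit slightly out-of-bounds vertices; clipping, not
        rejection, is the friendly behaviour).
        """
        rect = sgeom.box(0.0, 0.0, float(width), float(height))
        inter = self.to_shapely().intersection(rect)
        if inter.is_empty:
            return None
        if inter.geom_type == "MultiPolygon":
            inter = max(inter.geoms, key=lambda g: g.area)
        if inter.geom_type != "Polygon" or inter.area <= 0:
            return None
        coords = list(inter.exterior.coords)[:-1]
        if len(coords) < 3:
            return None
        return PolygonMask(tuple(coords))

    def rasterize(self, height: int, width: int) -> np.ndarray:
        """Boolean H x W mask of pixels whose centers fall inside the polygon."""
        from PIL import ImageDraw

        img = Image.new("1", (int(width), int(height)), 0)
        ImageDraw.Draw(img).polygon([(x, y) for x, y in self.vertices], fill=1)
        return np.asarray(img, dtype=bool)


@dataclass(frozen=True)
class SpeciesClass:
    """One catalog entry: display color, optional size rule, optional allometry.

    ``size_rule`` is ``("max_length_cm", v)``, ``("min_length_cm", v)`` or None;
    ``lw_params`` is ``(a, b)`` of the allometric power law W = a L^b with a in
    g cm^-b and b dimensionless.
    """

    name: str
    display_color: tuple[int, int, int] = (255, 255, 255)
    size_rule: tuple[str, float] | None = None
    lw_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.size_rule is not None:
            kind, thr = self.size_rule
            if kind not in ("max_length_cm", "min_length_cm"):
                raise ValueError(f"unknown size rule kind {kind!r}")
            if thr <= 0:
                raise ValueError("size rule threshold must be > 0")
        if self.lw_params is not None:
            a, b = self.lw_params
            if a <= 0 or b <= 0:
                raise ValueError("length-weight parameters must be > 0")


class SpeciesCatalog:
    """Ordered species list; the order fixes class indices everywhere."""

    def __init__(self, classes: Sequence[SpeciesClass]):
        names = [c.name for c in classes]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique within a catalog")
        self.classes: tuple[SpeciesClass, ...] = tuple(classes)
        self._index = {c.name: i for i, c in enumerate(self.classes)}

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> SpeciesClass:
        try:
            return self.classes[self._index[name]]
        except KeyError:
            raise KeyError(f"species {name!r} not in catalog") from None

    def index(self, name: str) -> int:
        if name not in self._index:
            raise KeyError(f"species {name!r} not in catalog")
        return self._index[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)


@dataclass(frozen=True)
class CameraCalibration:
    """Pixel-to-world conversion: real length (cm) spanned by one pixel."""

    cm_per_pixel: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cm_per_pixel) and self.cm_per_pixel > 0):
            raise ValueError("cm_per_pixel must be finite and > 0")


@dataclass(frozen=True)
class Detection:
    """One predicted instance, in original-image coordinates."""

    box: BoundingBox
    species: str
    confidence: float
    frame_id: str = "frame-0"
    timestamp: str = "1970-01-01T00:00:00"
    mask: PolygonMask | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0,1], got {self.confidence}")

    def replace(self, **kw) -> "Detection":
        return replace(self, **kw)

    def to_record(self) -> dict:
        rec = {
            "frame_id": self.frame_id,
            "timestamp": self.timestamp,
            "species": self.species,
            "confidence": self.confidence,
            "box": list(self.box.as_tuple()),
        }
        if self.mask is not None:
            rec["mask"] = [list(v) for v in self.mask.vertices]
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Detection":
        mask = None
        if rec.get("mask"):
            mask = PolygonMask(tuple((x, y) for x, y in rec["mask"]))
        return cls(
            box=BoundingBox(*rec["box"]),
            species=rec["species"],
            confidence=float(rec["confidence"]),
            frame_id=str(rec.get("frame_id", "frame-0")),
            timestamp=str(rec.get("timestamp", "1970-01-01T00:00:00")),
            mask=mask,
        )


@dataclass
class LabeledImage:
    """Training-side record: an RGB raster plus polygon instances."""

    image: np.ndarray  # H x W x 3 uint8
    instances: list[tuple[PolygonMask, str]] = field(default_factory=list)
    image_id: str = "image-0"

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
            raise ValueError("image must be an H x W x 3 uint8 array")
        self.image = img

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def instance_mask(self) -> np.ndarray:
        """Union of rasterized instance polygons as a boolean H x W mask."""
        mask = np.zeros(self.image.shape[:2], dtype=bool)
        for poly, _ in self.instances:
            mask |= poly.rasterize(self.height, self.width)
        return mask


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when equal."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


# ---------------------------------------------------------------------------
# I/O: COCO-style labels, JSON-lines detections, catalog config
# ---------------------------------------------------------------------------


def read_labeled_dataset(
    annotation_path: str | Path,
    image_dir: str | Path,
    catalog: SpeciesCatalog,
) -> list[LabeledImage]:
    """Load a COCO-style instance-segmentation file plus its image directory.

    Polygons are clipped to image bounds; category names must all resolve in
    ``catalog``.  Missing image files and unknown categories are hard errors.
    """
    annotation_path = Path(annotation_path)
    image_dir = Path(image_dir)
    with open(annotation_path) as fh:
        coco = json.load(fh)

    cats = {c["id"]: c["name"] for c in coco.get("categories", [])}
    unknown = sorted({n for n in cats.values() if n not in catalog})
    if unknown:
        raise ValueError(f"annotation categories not in catalog: {unknown}")

    anns_by_image: dict[int, list[dict]] = {}
    for ann in coco.get("annotations", []):
        anns_by_image.setdefault(ann["image_id"], []).append(ann)

    out: list[LabeledImage] = []
    for img_rec in coco.get("images", []):
        path = image_dir / img_rec["file_name"]
        if not path.exists():
            raise FileNotFoundError(f"image file missing: {path}")
        raster = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
        h, w = raster.shape[:2]
        instances: list[tuple[PolygonMask, str]] = []
        for ann in anns_by_image.get(img_rec["id"], []):
            name = cats[ann["category_id"]]
            for seg in ann.get("segmentation", []):
                pts = tuple(zip(seg[0::2], seg[1::2]))
                clipped = PolygonMask(pts).clipped(w, h)
                if clipped is not None:
                    instances.append((clipped, name))
        out.append(LabeledImage(raster, instances, image_id=str(img_rec["id"])))
    return out


def write_labeled_dataset(
    images: Iterable[LabeledImage],
    annotation_path: str | Path,
    image_dir: str | Path,
    catalog: SpeciesCatalog,
) -> None:
    """Write images as PNG plus a COCO-style annotation file (inverse of read)."""
    annotation_path = Path(annotation_path)
    image_dir = Path(image_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    categories = [
        {"id": i + 1, "name": name} for i, name in enumerate(catalog.names)
    ]
    cat_id = {name: i + 1 for i, name in enumerate(catalog.names)}
    recs, anns = [], []
    ann_id = 1
    for idx, li in enumerate(images):
        file_name = f"{li.image_id or idx}.png"
        Image.fromarray(li.image).save(image_dir / file_name)
        recs.append(
            {"id": idx + 1, "file_name": file_name, "width": li.width, "height": li.height}
        )
        for poly, name in li.instances:
            seg = [float(c) for xy in poly.vertices for c in xy]
            bb = poly.bounding_box()
            anns.append(
                {
                    "id": ann_id,
                    "image_id": idx + 1,
                    "category_id": cat_id[name],
                    "segmentation": [seg],
                    "area": poly.area,
                    "bbox": [bb.x_min, bb.y_min, bb.width, bb.height],
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    with open(annotation_path, "w") as fh:
        json.dump({"images": recs, "annotations": anns, "categories": categories}, fh)


def read_detections(path: str | Path) -> list[Detection]:
    """Read a JSON-lines detection file, validating invariants per line."""
    out: list[Detection] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                out.append(Detection.from_record(rec))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"bad detection record at line {lineno}: {exc}") from exc
    return out


def write_detections(dets: Iterable[Detection], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in dets:
            fh.write(json.dumps(d.to_record()) + "\n")


def _class_from_config(rec: dict) -> SpeciesClass:
    size_rule = None
    sr = rec.get("size_rule")
    if sr:
        if "max_length_cm" in sr:
            size_rule = ("max_length_cm", float(sr["max_length_cm"]))
        elif "min_length_cm" in sr:
            size_rule = ("min_length_cm", float(sr["min_length_cm"]))
        else:
            raise ValueError(f"size_rule must give max_length_cm or min_length_cm: {sr}")
    lw = rec.get("lw_params")
    lw_params = (float(lw["a"]), float(lw["b"])) if lw else None
    return SpeciesClass(
        name=rec["name"],
        display_color=tuple(rec.get("display_color", (255, 255, 255))),
        size_rule=size_rule,
        lw_params=lw_params,
    )


def load_catalog(path: str | Path) -> tuple[SpeciesCatalog, CameraCalibration | None]:
    """Load a YAML catalog config; returns (catalog, calibration-or-None)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    catalog = SpeciesCatalog([_class_from_config(r) for r in cfg["classes"]])
    cal = None
    if cfg.get("calibration"):
        cal = CameraCalibration(float(cfg["calibration"]["cm_per_pixel"]))
    return catalog, cal


def default_catalog() -> tuple[SpeciesCatalog, CameraCalibration]:
    """Packaged catalog of the six monitored species with default calibration."""
    path = Path(__file__).parent / "data" / "default_catalog.yaml"
    catalog, cal = load_catalog(path)
    assert cal is not None
    return catalog, cal
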