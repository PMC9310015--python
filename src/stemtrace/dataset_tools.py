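"""Dataset bookkeeping: annotation I/O, cropping, augmentation, splits.

Annotations travel as Pascal VOC XML in the LabelImg dialect (1-based
inclusive pixel corners); internally every box is 0-based half-open
continuous pixels, and the conversion between the two dialects lives only
in this module.  A lightweight flat JSON dialect is provided for
detector output that carries confidences.

Image-set bookkeeping mirrors a typical acquisition campaign: a manifest
of (plant x view) records plus archive images, a four-variant geometric
augmentation {identity, horizontal flip, vertical flip, 180-degree
rotation}, and a seeded 80/10/10 split whose two 10% parts are floored
with the remainder going to training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from lxml import etree

from .errors import InputError
from .geometry import BBox

__all__ = [
    "ImageSize",
    "KNOWN_LABELS",
    "VARIANTS",
    "read_voc",
    "write_voc",
    "read_detections_json",
    "write_detections_json",
    "crop_to_plant",
    "transform_bbox",
    "augment_set",
    "split_dataset",
    "build_manifest",
]

KNOWN_LABELS = frozenset({"node", "label", "soybean"})
VARIANTS = ("identity", "hflip", "vflip", "rot180")
SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class ImageSize:
    width: int
    height: int
    depth: int = 3

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InputError(f"non-positive image size {self}")


# ---------------------------------------------------------------------------
# Pascal VOC XML


def read_voc(path: Union[str, Path]) -> tuple[ImageSize, list[BBox]]:
    """Read a LabelImg-style VOC annotation file.

    VOC stores 1-based inclusive corners; they are converted to 0-based
    half-open coordinates.  Unknown object labels are kept but flagged
    with a warning.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise InputError(f"cannot parse VOC file {path}: {exc}") from exc
    root = tree.getroot()
    size_el = root.find("size")
    if size_el is None:
        raise InputError(f"{path}: missing <size>")
    size = ImageSize(
        width=int(size_el.findtext("width")),
        height=int(size_el.findtext("height")),
        depth=int(size_el.findtext("depth") or 3),
    )
    boxes: list[BBox] = []
    for obj in root.iterfind("object"):
        name = (obj.findtext("name") or "").strip()
        if name not in KNOWN_LABELS:
            warnings.warn(f"{path}: unknown object label {name!r}", stacklevel=2)
        bnd = obj.find("bndbox")
        if bnd is None:
            raise InputError(f"{path}: object without <bndbox>")
        xmin = float(bnd.findtext("xmin"))
        ymin = float(bnd.findtext("ymin"))
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        if xmax <= xmin or ymax <= ymin:
            raise InputError(f"{path}: degenerate box ({xmin},{ymin},{xmax},{ymax})")
        conf = obj.findtext("confidence")
        boxes.append(
            BBox(
                left=xmin - 1.0,
                top=ymin - 1.0,
                right=xmax,
                bottom=ymax,
                label=name,
                confidence=float(conf) if conf is not None else 1.0,
            )
        )
    return size, boxes


def write_voc(
    path: Union[str, Path],
    size: ImageSize,
    boxes: Sequence[BBox],
    filename: str = "image.jpg",
    with_confidence: bool = False,
) -> None:
    """Write boxes as LabelImg-style VOC XML (inverse of :func:`read_voc`)."""
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "JPEGImages"
    etree.SubElement(root, "filename").text = filename
    size_el = etree.SubElement(root, "size")
    etree.SubElement(size_el, "width").text = str(size.width)
    etree.SubElement(size_el, "height").text = str(size.height)
    etree.SubElement(size_el, "depth").text = str(size.depth)
    for b in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        if with_confidence:
            etree.SubElement(obj, "confidence").text = repr(b.confidence)
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = _num(b.left + 1.0)
        etree.SubElement(bnd, "ymin").text = _num(b.top + 1.0)
        etree.SubElement(bnd, "xmax").text = _num(b.right)
        etree.SubElement(bnd, "ymax").text = _num(b.bottom)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, encoding="utf-8")


def _num(v: float) -> str:
    """Integers render as ints (LabelImg style), other values exactly."""
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# flat JSON dialect


def write_detections_json(
    path: Union[str, Path], size: ImageSize, boxes: Sequence[BBox]
) -> None:
    """0-based half-open boxes with confidences, one JSON document."""
    doc = {
        "image": {"width": size.width, "height": size.height},
        "boxes": [
            {
                "label": b.label,
                "confidence": b.confidence,
                "left": b.left,
                "top": b.top,
                "right": b.right,
                "bottom": b.bottom,
            }
            for b in boxes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_detections_json(path: Union[str, Path]) -> tuple[ImageSize, list[BBox]]:
    doc = json.loads(Path(path).read_text())
    size = ImageSize(
        width=int(doc["image"]["width"]), height=int(doc["image"]["height"])
    )
    boxes = [
        BBox(
            left=float(b["left"]),
            top=float(b["top"]),
            right=float(b["right"]),
            bottom=float(b["bottom"]),
            label=str(b.get("label", "node")),
            confidence=float(b.get("confidence", 1.0)),
        )
        for b in doc["boxes"]
    ]
    return size, boxes


# ---------------------------------------------------------------------------
# cropping


def crop_to_plant(
    image: Optional[np.ndarray],
    plant_box: BBox,
    annotations: Sequence[BBox],
) -> tuple[Optional[np.ndarray], list[BBox], int]:
    """Crop to the plant bounding box and shift annotations accordingly.

    Boxes fully outside the crop are dropped (the count is returned);
    boxes straddling the border are clipped to it.
    """
    left, top = plant_box.left, plant_box.top
    cw, ch = plant_box.width, plant_box.height
    cropped_img = None
    if image is not None:
        r0, r1 = int(round(top)), int(round(plant_box.bottom))
        c0, c1 = int(round(left)), int(round(plant_box.right))
        if r1 <= r0 or c1 <= c0:
            raise InputError("empty crop")
        cropped_img = np.asarray(image)[r0:r1, c0:c1]
    kept: list[BBox] = []
    dropped = 0
    for b in annotations:
        nl, nt = b.left - left, b.top - top
        nr, nb = b.right - left, b.bottom - top
        if nr <= 0 or nb <= 0 or nl >= cw or nt >= ch:
            dropped += 1
            continue
        kept.append(
            BBox(
                left=max(nl, 0.0),
                top=max(nt, 0.0),
                right=min(nr, cw),
                bottom=min(nb, ch),
                label=b.label,
                confidence=b.confidence,
            )
        )
    return cropped_img, kept, dropped


# ---------------------------------------------------------------------------
# augmentation


def transform_bbox(b: BBox, size: ImageSize, variant: str) -> BBox:
    """Map a 0-based half-open box through a flip/rotation variant."""
    w, h = float(size.width), float(size.height)
    if variant == "identity":
        left, top, right, bottom = b.left, b.top, b.right, b.bottom
    elif variant == "hflip":
        left, right = w - b.right, w - b.left
        top, bottom = b.top, b.bottom
    elif variant == "vflip":
        left, right = b.left, b.right
        top, bottom = h - b.bottom, h - b.top
    elif variant == "rot180":
        left, right = w - b.right, w - b.left
        top, bottom = h - b.bottom, h - b.top
    else:
        raise InputError(f"unknown variant {variant!r}")
    return BBox(left, top, right, bottom, label=b.label, confidence=b.confidence)


def augment_set(manifest: pd.DataFrame) -> pd.DataFrame:
    """Expand each original into its four deterministic variants.

    The output has exactly four rows per input row, with ``variant`` set
    and ``item_id`` suffixed by the variant tag.
    """
    _check_manifest(manifest)
    rows = []
    for rec in manifest.to_dict("records"):
        for variant in VARIANTS:
            out = dict(rec)
            out["variant"] = variant
            out["item_id"] = f"{rec['item_id']}__{variant}"
            rows.append(out)
    return pd.DataFrame(rows, columns=manifest.columns)


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Tag each record train/val/test with a seeded uniform shuffle.

    The validation and test parts each get ``floor(fraction * N)`` records;
    training takes the remainder, so the three sizes always sum to N.
    """
    _check_manifest(manifest)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InputError(f"fractions {fractions} must sum to 1")
    n = len(manifest)
    if n == 0:
        raise InputError("cannot split an empty manifest")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    tags = np.empty(n, dtype=object)
    tags[order[:n_train]] = "train"
    tags[order[n_train : n_train + n_val]] = "val"
    tags[order[n_train + n_val :]] = "test"
    out = manifest.copy()
    out["split"] = tags
    return out


# ---------------------------------------------------------------------------
# manifests


def build_manifest(
    n_plants: int, images_per_plant: int = 4, extra_images: int = 0
) -> pd.DataFrame:
    """Acquisition manifest: ``n_plants * images_per_plant`` plant views
    plus ``extra_images`` archive records."""
    if min(n_plants, images_per_plant, extra_images) < 0:
        raise InputError("manifest counts must be non-negative")
    rows = []
    for p in range(n_plants):
        for v in range(images_per_plant):
            rows.append(
                {
                    "item_id": f"plant{p:04d}_view{v}",
                    "source": "campaign",
                    "variant": "identity",
                    "split": "",
                }
            )
    for a in range(extra_images):
        rows.append(
            {
                "item_id": f"archive{a:04d}",
                "source": "archive",
                "variant": "identity",
                "split": "",
            }
        )
    return pd.DataFrame(
        rows, columns=["item_id", "source", "variant", "split"]
    )


def _check_manifest(manifest: pd.DataFrame) -> None:
    if "item_id" not in manifest.columns:
        raise InputError("manifest needs an 'item_id' column")
    if manifest["item_id"].duplicated().any():
        raise InputError("manifest item_ids must be unique")
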