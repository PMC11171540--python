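"""Detection-dataset preparation: VOC↔YOLO boxes, resizing, splitting.

Annotated endoscopy frames arrive as Pascal-VOC XML (LabelImg output);
detector training wants YOLO text labels, 640×640 images and a
train/validation/test split. Boxes are kept internally as 0-based,
half-open pixel intervals; VOC's 1-based inclusive corners are converted
on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

__all__ = [
    "VocBox",
    "YoloBox",
    "BoxTransform",
    "SplitPlan",
    "DEFAULT_CLASS_MAP",
    "voc_to_yolo",
    "yolo_to_voc",
    "read_voc_xml",
    "write_yolo_txt",
    "resize_image",
    "split_dataset",
]

#: Default class indices; frames without lesions get empty label files.
DEFAULT_CLASS_MAP = {"dysplasia": 0, "scc": 1}


@dataclass(frozen=True)
class VocBox:
    """An axis-aligned box in pixel coordinates, 0-based and half-open."""

    label: str
    xmin: int
    ymin: int
    xmax: int
    ymax: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (0 <= self.xmin < self.xmax <= self.width):
            raise ValueError(
                f"degenerate or out-of-image box in x: "
                f"[{self.xmin}, {self.xmax}) within width {self.width}"
            )
        if not (0 <= self.ymin < self.ymax <= self.height):
            raise ValueError(
                f"degenerate or out-of-image box in y: "
                f"[{self.ymin}, {self.ymax}) within height {self.height}"
            )


@dataclass(frozen=True)
class YoloBox:
    """A normalized box: class index plus centre/size fractions in [0, 1]."""

    class_index: int
    x_center: float
    y_center: float
    box_width: float
    box_height: float

    def __post_init__(self) -> None:
        for name in ("x_center", "y_center", "box_width", "box_height"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.x_center - self.box_width / 2 < -1e-9 or \
           self.x_center + self.box_width / 2 > 1 + 1e-9:
            raise ValueError("box exceeds image bounds in x")
        if self.y_center - self.box_height / 2 < -1e-9 or \
           self.y_center + self.box_height / 2 > 1 + 1e-9:
            raise ValueError("box exceeds image bounds in y")


def voc_to_yolo(box: VocBox, class_map: dict[str, int] = DEFAULT_CLASS_MAP) -> YoloBox:
    """Normalize a pixel box to YOLO centre/size fractions."""
    if box.label not in class_map:
        raise KeyError(
            f"unknown label {box.label!r}; known classes: {sorted(class_map)}"
        )
    return YoloBox(
        class_index=class_map[box.label],
        x_center=(box.xmin + box.xmax) / (2.0 * box.width),
        y_center=(box.ymin + box.ymax) / (2.0 * box.height),
        box_width=(box.xmax - box.xmin) / box.width,
        box_height=(box.ymax - box.ymin) / box.height,
    )


def yolo_to_voc(
    box: YoloBox,
    width: int,
    height: int,
    class_map: dict[str, int] = DEFAULT_CLASS_MAP,
) -> VocBox:
    """Denormalize a YOLO box back to integer pixel corners (≤0.5 px error)."""
    names = {v: k for k, v in class_map.items()}
    if box.class_index not in names:
        raise KeyError(f"unknown class index {box.class_index}")
    xmin = (box.x_center - box.box_width / 2.0) * width
    xmax = (box.x_center + box.box_width / 2.0) * width
    ymin = (box.y_center - box.box_height / 2.0) * height
    ymax = (box.y_center + box.box_height / 2.0) * height
    return VocBox(
        label=names[box.class_index],
        xmin=max(0, int(round(xmin))),
        ymin=max(0, int(round(ymin))),
        xmax=min(width, max(int(round(xmax)), int(round(xmin)) + 1)),
        ymax=min(height, max(int(round(ymax)), int(round(ymin)) + 1)),
        width=width,
        height=height,
    )


def read_voc_xml(path) -> list[VocBox]:
    """Parse a Pascal-VOC annotation file into boxes.

    VOC corners are 1-based inclusive; they are mapped to the internal
    0-based half-open convention (xmin-1, xmax kept).
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    size = root.find("size")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    boxes = []
    for obj in root.iter("object"):
        bb = obj.find("bndbox")
        boxes.append(
            VocBox(
                label=obj.findtext("name").strip(),
                xmin=int(float(bb.findtext("xmin"))) - 1,
                ymin=int(float(bb.findtext("ymin"))) - 1,
                xmax=int(float(bb.findtext("xmax"))),
                ymax=int(float(bb.findtext("ymax"))),
                width=width,
                height=height,
            )
        )
    return boxes


def write_yolo_txt(path, boxes: list[YoloBox]) -> None:
    """Write one ``class xc yc w h`` line per box (empty file when no boxes)."""
    lines = [
        f"{b.class_index} {b.x_center:.6f} {b.y_center:.6f} "
        f"{b.box_width:.6f} {b.box_height:.6f}"
        for b in boxes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass(frozen=True)
class BoxTransform:
    """Affine pixel-box map produced by a resize: p' = p·scale + pad."""

    scale_x: float
    scale_y: float
    pad_x: float = 0.0
    pad_y: float = 0.0

    def apply(self, box: VocBox, new_width: int, new_height: int) -> VocBox:
        return VocBox(
            label=box.label,
            xmin=int(round(box.xmin * self.scale_x + self.pad_x)),
            ymin=int(round(box.ymin * self.scale_y + self.pad_y)),
            xmax=int(round(box.xmax * self.scale_x + self.pad_x)),
            ymax=int(round(box.ymax * self.scale_y + self.pad_y)),
            width=new_width,
            height=new_height,
        )


def resize_image(
    image,
    target: tuple[int, int] = (640, 640),
    policy: str = "stretch",
    pad_value: int = 114,
) -> tuple[Image.Image, BoxTransform]:
    """Resize to ``target`` by stretching or letterboxing.

    ``image`` is a PIL image, an array, or a path (a broken file raises a
    format error naming it). Returns the resized image and the
    :class:`BoxTransform` carrying boxes into the new frame; letterboxing
    preserves aspect ratio and pads symmetrically with ``pad_value`` gray.
    """
    if isinstance(image, (str, Path)):
        try:
            img = Image.open(image)
            img.load()
        except Exception as exc:
            raise ValueError(f"cannot read image file {image}: {exc}") from exc
    elif isinstance(image, np.ndarray):
        img = Image.fromarray(image)
    else:
        img = image
    tw, th = target
    w, h = img.size
    if w == 0 or h == 0:
        raise ValueError("empty image")
    if policy == "stretch":
        out = img.resize((tw, th), Image.BILINEAR) if (w, h) != (tw, th) else img
        return out, BoxTransform(scale_x=tw / w, scale_y=th / h)
    if policy == "letterbox":
        scale = min(tw / w, th / h)
        nw, nh = int(round(w * scale)), int(round(h * scale))
        resized = img.resize((nw, nh), Image.BILINEAR) if (nw, nh) != (w, h) else img
        canvas = Image.new(img.mode, (tw, th), pad_value)
        px, py = (tw - nw) // 2, (th - nh) // 2
        canvas.paste(resized, (px, py))
        return canvas, BoxTransform(scale_x=scale, scale_y=scale, pad_x=px, pad_y=py)
    raise ValueError("policy must be 'stretch' or 'letterbox'")


@dataclass(frozen=True)
class SplitPlan:
    """A disjoint, exhaustive assignment of items to train/val/test."""

    ratios: tuple[float, float, float]
    seed: int
    assignment: dict[str, str]  # item id -> partition name

    def partition(self, name: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == name]


_PARTS = ("train", "val", "test")


def split_dataset(
    items,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    group_key=None,
) -> SplitPlan:
    """Seeded shuffle then contiguous cut into train/val/test.

    Partition sizes are ``floor(n·ratio)`` for train and val, with all
    remainders going to the last partition. With ``group_key`` set (a
    mapping or callable from item id to e.g. a patient id), whole groups
    are assigned to one partition using the same floor targets on item
    counts.
    """
    items = [str(i) for i in items]
    if not items:
        raise ValueError("no items to split")
    if len(set(items)) != len(items):
        raise ValueError("duplicate item ids")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("need three non-negative ratios")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios sum to {sum(ratios)}, expected 1")
    rng = np.random.default_rng(seed)
    n = len(items)
    n_train = math.floor(n * ratios[0])
    n_val = math.floor(n * ratios[1])
    targets = {"train": n_train, "val": n_val, "test": n - n_train - n_val}

    assignment: dict[str, str] = {}
    if group_key is None:
        order = [items[i] for i in rng.permutation(n)]
        bounds = (n_train, n_train + n_val, n)
        for idx, item in enumerate(order):
            part = _PARTS[int(np.searchsorted(bounds, idx, side="right"))]
            assignment[item] = part
    else:
        getter = group_key if callable(group_key) else group_key.__getitem__
        groups: dict[str, list[str]] = {}
        for item in items:
            groups.setdefault(str(getter(item)), []).append(item)
        keys = sorted(groups)
        order = [keys[i] for i in rng.permutation(len(keys))]
        part_iter = iter(_PARTS)
        part = next(part_iter)
        filled = 0
        for key in order:
            members = groups[key]
            # advance once the current partition has met its target
            while filled >= targets[part] and part != "test":
                part = next(part_iter)
                filled = 0
            for item in members:
                assignment[item] = part
            filled += len(members)
    return SplitPlan(ratios=ratios, seed=seed, assignment=assignment)
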