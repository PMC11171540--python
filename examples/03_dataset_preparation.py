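"""Prepare an annotated frame set for detector training.

Converts a Pascal-VOC annotation to a YOLO label, letterboxes a frame to
640x640 while carrying its boxes along, and splits 2741 frame ids 70:15:15
with patient-grouping so no patient appears in two partitions.
"""

from pathlib import Path

import numpy as np
from PIL import Image

from savehsi.datasets import (
    VocBox,
    resize_image,
    split_dataset,
    voc_to_yolo,
    write_yolo_txt,
)

scratch = Path("scratch")
scratch.mkdir(exist_ok=True)

# --- VOC box -> YOLO label -------------------------------------------------
box = VocBox("scc", xmin=100, ymin=200, xmax=300, ymax=400, width=640, height=640)
yolo = voc_to_yolo(box)
write_yolo_txt(scratch / "frame_0001.txt", [yolo])
print(f"VOC [{box.xmin},{box.ymin},{box.xmax},{box.ymax}] -> "
      f"YOLO {yolo.class_index} {yolo.x_center} {yolo.y_center} "
      f"{yolo.box_width} {yolo.box_height}")

# --- letterbox resize with box transform -----------------------------------
frame = Image.new("RGB", (800, 600), (120, 80, 70))
resized, transform = resize_image(frame, (640, 640), policy="letterbox")
moved = transform.apply(VocBox("scc", 100, 100, 200, 200, 800, 600), 640, 640)
print(f"letterbox 800x600 -> 640x640: scale {transform.scale_x:.2f}, "
      f"pad ({transform.pad_x:.0f}, {transform.pad_y:.0f})")
print(f"box follows: ({moved.xmin},{moved.ymin})-({moved.xmax},{moved.ymax})")

# --- patient-grouped 70:15:15 split ----------------------------------------
rng = np.random.default_rng(0)
frames = [f"frame_{i:04d}" for i in range(2741)]
patient_of = {f: f"patient_{rng.integers(0, 150):03d}" for f in frames}
plan = split_dataset(frames, ratios=(0.70, 0.15, 0.15), seed=1,
                     group_key=patient_of)
for part in ("train", "val", "test"):
    ids = plan.partition(part)
    print(f"{part:5s}: {len(ids):4d} frames, "
          f"{len({patient_of[i] for i in ids})} patients")
# Counts deviate slightly from an exact 70:15:15 because whole patients are
# assigned together; without grouping the split of 2741 is 1918/411/412.
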