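"""B-mode-like grayscale frame stacks and their on-disk PNG + manifest form.

Pixel/physical coordinate convention: the physical plane is x-right / y-up in
mm; image rows run downward, so ``x_mm = x0 + col * mm_per_px`` and
``y_mm = y0 + (H - 1 - row) * mm_per_px``. The manifest carries the mapping
so contours extracted from frames come back in the same mm coordinates the
frames were rendered from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

__all__ = ["FrameStack"]


@dataclass
class FrameStack:
    """A stack of 8-bit grayscale frames with timestamps and a geometry manifest.

    ``manifest`` holds mm_per_px, the (x0, y0) mm position of the bottom-left
    pixel center, the intensity levels used at render time, and per-frame
    provenance (the index of the source contour of each frame).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames: expected an (n, H, W) array")
        if len(self.frames) == 0:
            raise ValidationError("frames: empty stack")
        if len(self.frames) != len(self.timestamps):
            raise ValidationError("timestamps: length must match frames")
        if "mm_per_px" not in self.manifest:
            raise ValidationError("manifest: missing mm_per_px")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def mm_per_px(self) -> float:
        return float(self.manifest["mm_per_px"])

    def pixel_to_mm(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Map (row, col) pixel coordinates to (x, y) mm; accepts fractional pixels."""
        s = self.mm_per_px
        h = self.frames.shape[1]
        x0 = float(self.manifest.get("x0_mm", 0.0))
        y0 = float(self.manifest.get("y0_mm", 0.0))
        x = x0 + np.asarray(cols, dtype=float) * s
        y = y0 + (h - 1 - np.asarray(rows, dtype=float)) * s
        return np.column_stack([x, y])

    def mm_to_pixel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (x, y) mm coordinates to fractional (row, col) pixels."""
        pts = np.asarray(points_mm, dtype=float)
        s = self.mm_per_px
        h = self.frames.shape[1]
        x0 = float(self.manifest.get("x0_mm", 0.0))
        y0 = float(self.manifest.get("y0_mm", 0.0))
        cols = (pts[:, 0] - x0) / s
        rows = (h - 1) - (pts[:, 1] - y0) / s
        return np.column_stack([rows, cols])

    def save(self, out_dir: str | Path) -> Path:
        """Write one PNG per frame plus ``frames_manifest.json``; returns the dir."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = []
        for i, frame in enumerate(self.frames):
            name = f"frame_{i:04d}.png"
            iio.imwrite(out / name, frame.astype(np.uint8))
            names.append(name)
        manifest = dict(self.manifest)
        manifest["files"] = names
        manifest["timestamps"] = [float(t) for t in self.timestamps]
        (out / "frames_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "FrameStack":
        import imageio.v3 as iio

        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "frames_manifest.json").read_text())
        frames = np.stack([iio.imread(in_dir / name) for name in manifest.pop("files")])
        timestamps = np.asarray(manifest.pop("timestamps"), dtype=float)
        return cls(frames=frames, timestamps=timestamps, manifest=manifest)
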