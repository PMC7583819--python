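"""Point-cloud container and plain-text I/O.

Coordinates are metric (x, y in a local projected frame, z in metres).
Per-point classification follows the ASPRS LAS convention for the three
classes this pipeline uses: 1 = unclassified, 2 = ground, 5 = high
vegetation, 7 = noise.  ``tree_id`` is 0 for background points and k > 0
for points assigned to tree k by crown delineation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_UNCLASSIFIED = 1
CLASS_GROUND = 2
CLASS_VEGETATION = 5
CLASS_NOISE = 7

_VALID_CLASSES = frozenset(
    {CLASS_UNCLASSIFIED, CLASS_GROUND, CLASS_VEGETATION, CLASS_NOISE}
)


@dataclass
class PointCloud:
    """Columnar point cloud: x/y/z plus optional class and tree labels."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    classification: np.ndarray = field(default=None)  # type: ignore[assignment]
    tree_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.z = np.asarray(self.z, dtype=float).ravel()
        n = self.x.size
        if self.y.size != n or self.z.size != n:
            raise ValueError("x, y, z must have equal length")
        if not (
            np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
            and np.all(np.isfinite(self.z))
        ):
            raise ValueError("point coordinates must be finite")
        if self.classification is None:
            self.classification = np.full(n, CLASS_UNCLASSIFIED, dtype=np.uint8)
        else:
            self.classification = np.asarray(self.classification, dtype=np.uint8).ravel()
            if self.classification.size != n:
                raise ValueError("classification length mismatch")
            if n and not set(np.unique(self.classification)) <= _VALID_CLASSES:
                raise ValueError(f"class labels must be in {sorted(_VALID_CLASSES)}")
        if self.tree_id is None:
            self.tree_id = np.zeros(n, dtype=np.int32)
        else:
            self.tree_id = np.asarray(self.tree_id, dtype=np.int32).ravel()
            if self.tree_id.size != n:
                raise ValueError("tree_id length mismatch")

    def __len__(self) -> int:
        return self.x.size

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or index array, order preserved."""
        return PointCloud(
            self.x[mask],
            self.y[mask],
            self.z[mask],
            self.classification[mask],
            self.tree_id[mask],
        )

    def with_z(self, z: np.ndarray) -> "PointCloud":
        return PointCloud(self.x, self.y, z, self.classification, self.tree_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "classification": self.classification,
                "tree_id": self.tree_id,
            }
        )

    def to_csv(self, path) -> None:
        """Write as CSV; a ``.gz`` suffix triggers transparent compression."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointCloud":
        """Read a cloud from CSV with at least x,y,z columns (gzip transparent)."""
        df = pd.read_csv(path)
        missing = {"x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"point CSV missing columns: {sorted(missing)}")
        return cls(
            df["x"].to_numpy(),
            df["y"].to_numpy(),
            df["z"].to_numpy(),
            df["classification"].to_numpy() if "classification" in df else None,
            df["tree_id"].to_numpy() if "tree_id" in df else None,
        )
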