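"""Point-cloud container with ASCII PLY I/O.

Photogrammetric dense clouds are exchanged as PLY here; coordinates are
metres in the same local planar frame as the rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PointCloud:
    """A set of 3-D points with a date tag and a role.

    ``role`` is ``"terrain"`` for the pre-emergence reference flight and
    ``"canopy"`` for a study-date flight.
    """

    points: np.ndarray  # (N, 3) float64, metres
    date_tag: str = ""
    role: str = "canopy"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError(f"expected (N, 3) points, got {self.points.shape}")
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def select(self, mask_or_idx) -> "PointCloud":
        return PointCloud(self.points[mask_or_idx], self.date_tag, self.role)

    # -- I/O ---------------------------------------------------------------

    def to_ply(self, path) -> None:
        """Write an ASCII PLY (x, y, z float64)."""
        n = len(self)
        header = (
            "ply\nformat ascii 1.0\n"
            f"comment date_tag={self.date_tag} role={self.role}\n"
            f"element vertex {n}\n"
            "property double x\nproperty double y\nproperty double z\n"
            "end_header\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.points, fmt="%.6f")

    @classmethod
    def from_ply(cls, path) -> "PointCloud":
        date_tag, role, n = "", "canopy", 0
        with open(path) as fh:
            line = fh.readline().strip()
            if line != "ply":
                raise ValueError(f"{path}: not a PLY file")
            while True:
                line = fh.readline()
                if not line:
                    raise ValueError(f"{path}: truncated PLY header")
                line = line.strip()
                if line.startswith("comment"):
                    for token in line.split()[1:]:
                        if token.startswith("date_tag="):
                            date_tag = token.split("=", 1)[1]
                        elif token.startswith("role="):
                            role = token.split("=", 1)[1]
                elif line.startswith("element vertex"):
                    n = int(line.split()[-1])
                elif line == "end_header":
                    break
            pts = np.loadtxt(fh, max_rows=n) if n else np.empty((0, 3))
        return cls(np.atleast_2d(pts)[:, :3], date_tag=date_tag, role=role)
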