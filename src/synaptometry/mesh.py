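"""Tagged triangulated surfaces.

A :class:`TaggedMesh` is a closed trimesh surface (coordinates in µm)
together with named triangle regions — the mesh analogue of the hand-tagged
head / whole-spine / PSD / active-zone selections used in 3DEM spine
segmentation. Regions are stored as arrays of triangle indices and written
to disk as a JSON sidecar next to the PLY file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshError, TaggingError

__all__ = ["TaggedMesh"]


@dataclass
class TaggedMesh:
    """Closed triangulated surface (µm) with named triangle-region tags."""

    mesh: trimesh.Trimesh
    region_tags: dict[str, np.ndarray] = field(default_factory=dict)
    name: str = "mesh"
    #: analytic ground truths recorded by generators (e.g. head volume)
    ground_truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_tri = len(self.mesh.faces)
        clean = {}
        for region, idx in self.region_tags.items():
            idx = np.asarray(idx, dtype=int).reshape(-1)
            if idx.size and (idx.min() < 0 or idx.max() >= n_tri):
                raise TaggingError(
                    f"region {region!r} references triangle indices outside the mesh")
            clean[region] = np.unique(idx)
        self.region_tags = clean

    # -- region access -------------------------------------------------

    def region_faces(self, region: str) -> np.ndarray:
        """Triangle indices of a named region; TaggingError if unknown."""
        try:
            return self.region_tags[region]
        except KeyError:
            raise TaggingError(
                f"mesh {self.name!r} has no region {region!r}; "
                f"available: {sorted(self.region_tags)}") from None

    def region_triangles(self, region: str) -> np.ndarray:
        """(k, 3, 3) vertex coordinates of the region's triangles."""
        return self.mesh.triangles[self.region_faces(region)]

    def region_vertices(self, region: str) -> np.ndarray:
        """Unique vertex coordinates used by the region's triangles."""
        vids = np.unique(self.mesh.faces[self.region_faces(region)])
        return self.mesh.vertices[vids]

    def has_region(self, region: str) -> bool:
        return region in self.region_tags

    # -- validation ----------------------------------------------------

    def require_watertight(self) -> None:
        if not self.mesh.is_watertight:
            raise MeshError(f"mesh {self.name!r} is not watertight; "
                            "volume operations need a closed surface")

    def validate(self) -> None:
        """Watertightness plus the containment contract head ⊆ whole_spine."""
        self.require_watertight()
        if "head" in self.region_tags and "whole_spine" in self.region_tags:
            head = set(self.region_tags["head"].tolist())
            whole = set(self.region_tags["whole_spine"].tolist())
            if not head <= whole:
                raise TaggingError(
                    f"mesh {self.name!r}: 'head' region is not a subset of 'whole_spine'")

    # -- I/O -----------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write ASCII PLY plus a ``<stem>.regions.json`` sidecar; returns PLY path."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.mesh.export(path, encoding="ascii")
        sidecar = path.with_suffix(".regions.json")
        payload = {
            "name": self.name,
            "regions": {k: v.tolist() for k, v in self.region_tags.items()},
            "ground_truth": self.ground_truth,
        }
        sidecar.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TaggedMesh":
        path = Path(path)
        mesh = trimesh.load(path, process=False, force="mesh")
        sidecar = path.with_suffix(".regions.json")
        tags, name, truth = {}, path.stem, {}
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            tags = {k: np.asarray(v, dtype=int) for k, v in payload.get("regions", {}).items()}
            name = payload.get("name", name)
            truth = payload.get("ground_truth", {})
        return cls(mesh=mesh, region_tags=tags, name=name, ground_truth=truth)
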