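"""Phytomer template database: a directory with ``index.json`` plus one
subdirectory per template holding component OBJ meshes and a JSON document
with parameters and skeleton polylines.

All geometry is stored normalized (internode base at the origin, axis
vertical, leaf azimuth zero); assembly re-applies transforms from specs.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np

from .core import (
    AppendageParams,
    Component,
    InternodeParams,
    LeafParams,
    MeshModel,
    Phytomer,
    PhytomerId,
    PhytomerKind,
    SheathParams,
    SkeletonModel,
    morph_params,
    normalize_phytomer,
)
from .digitizer import read_obj, write_obj
from .errors import TemplateLookupError

__all__ = ["TemplateRecord", "TemplateDatabase", "KEYWORD_FIELDS"]

#: agronomic keyword schema; unknown filter keys are rejected
KEYWORD_FIELDS = (
    "phytomer_type",
    "variety",
    "growth_period",
    "ecological_point",
    "density",
    "row_spacing",
    "treatment",
    "stem_order",
)

_PARAM_CLASSES = {
    "leaf": LeafParams,
    "sheath": SheathParams,
    "internode": InternodeParams,
    "appendage": AppendageParams,
}


@dataclass
class TemplateRecord:
    id: int
    keywords: dict[str, str]
    mesh_paths: dict[str, str]  # organ -> OBJ file, relative to the db root
    json_path: str
    vertex_count: int
    mesh_count: int
    params: dict[str, float]
    access_time: str = ""
    entry_person: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateRecord":
        return cls(**d)


class TemplateDatabase:
    """Directory-backed template store with keyword queries."""

    def __init__(self, root: Union[str, Path]):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._records: list[TemplateRecord] = []
        index = self.root / "index.json"
        if index.exists():
            data = json.loads(index.read_text())
            self._records = [TemplateRecord.from_dict(d) for d in data["templates"]]

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[TemplateRecord]:
        return list(self._records)

    def _save_index(self) -> None:
        payload = {"templates": [r.to_dict() for r in self._records]}
        (self.root / "index.json").write_text(json.dumps(payload, indent=1))

    # -- ingest ------------------------------------------------------------

    def ingest(
        self,
        phytomer: Phytomer,
        keywords: Optional[dict[str, str]] = None,
        entry_person: str = "",
    ) -> TemplateRecord:
        """Normalize a phytomer and persist it; counts are recomputed."""
        normalized = normalize_phytomer(phytomer)
        tid = (max(r.id for r in self._records) + 1) if self._records else 1
        tdir = self.root / "templates" / str(tid)
        tdir.mkdir(parents=True, exist_ok=True)

        mesh_paths: dict[str, str] = {}
        vertex_count = 0
        mesh_count = 0
        doc: dict[str, Any] = {
            "id": tid,
            "phytomer_id": [normalized.id.plant, normalized.id.tiller, normalized.id.rank],
            "kind": normalized.kind.value,
            "components": {},
        }
        for organ, comp in normalized.components():
            centry: dict[str, Any] = {}
            if comp.mesh is not None:
                rel = f"templates/{tid}/{organ}.obj"
                write_obj(self.root / rel, [(organ, comp.mesh)])
                mesh_paths[organ] = rel
                vertex_count += comp.mesh.n_vertices
                mesh_count += comp.mesh.n_faces
            if comp.skeleton is not None:
                centry["skeleton"] = comp.skeleton.points.tolist()
            if comp.params is not None:
                centry["params"] = asdict(comp.params)
            doc["components"][organ] = centry
        json_rel = f"templates/{tid}/phytomer.json"
        (self.root / json_rel).write_text(json.dumps(doc))

        kw = {k: str(v) for k, v in (keywords or {}).items() if k in KEYWORD_FIELDS}
        kw.setdefault("phytomer_type", _type_name(normalized.kind))
        record = TemplateRecord(
            id=tid,
            keywords=kw,
            mesh_paths=mesh_paths,
            json_path=json_rel,
            vertex_count=vertex_count,
            mesh_count=mesh_count,
            params=morph_params(normalized),
            access_time=datetime.datetime.now().isoformat(timespec="seconds"),
            entry_person=entry_person,
        )
        self._records.append(record)
        self._save_index()
        return record

    # -- query / load ------------------------------------------------------

    def query(self, **filters: str) -> list[TemplateRecord]:
        """All records matching every keyword filter, ordered by id."""
        unknown = set(filters) - set(KEYWORD_FIELDS)
        if unknown:
            raise ValueError(
                f"unknown keywords {sorted(unknown)}; valid keys: {list(KEYWORD_FIELDS)}"
            )
        out = [
            r
            for r in self._records
            if all(r.keywords.get(k) == str(v) for k, v in filters.items())
        ]
        return sorted(out, key=lambda r: r.id)

    def load(self, ref: Union[int, str, TemplateRecord]) -> Phytomer:
        """Reload a template's normalized geometry from disk."""
        if isinstance(ref, TemplateRecord):
            record = ref
        else:
            matches = [r for r in self._records if r.id == int(ref)]
            if not matches:
                raise TemplateLookupError(f"template {ref!r} not found")
            record = matches[0]
        json_path = self.root / record.json_path
        if not json_path.exists():
            raise FileNotFoundError(f"template file missing: {json_path}")
        doc = json.loads(json_path.read_text())
        components: dict[str, Component] = {}
        for organ, centry in doc["components"].items():
            mesh = None
            if organ in record.mesh_paths:
                obj_path = self.root / record.mesh_paths[organ]
                if not obj_path.exists():
                    raise FileNotFoundError(f"template mesh missing: {obj_path}")
                mesh = read_obj(obj_path)[organ]
            skeleton = (
                SkeletonModel(np.asarray(centry["skeleton"])) if "skeleton" in centry else None
            )
            params = None
            if "params" in centry:
                params = _PARAM_CLASSES[organ](**centry["params"])
            components[organ] = Component(mesh=mesh, skeleton=skeleton, params=params)
        pid = doc.get("phytomer_id", [1, 1, 1])
        return Phytomer(
            id=PhytomerId(*pid),
            kind=PhytomerKind(doc["kind"]),
            internode=components["internode"],
            leaf=components.get("leaf"),
            sheath=components.get("sheath"),
            appendage=components.get("appendage"),
        )


def _type_name(kind: PhytomerKind) -> str:
    return {
        PhytomerKind.SPIKE_BEARING: "phytomers with spike",
        PhytomerKind.MIDDLE: "middle phytomers",
        PhytomerKind.BASAL: "first phytomer",
    }[kind]
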