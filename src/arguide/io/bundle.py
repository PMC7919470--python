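"""Per-patient case bundles: the file-system analogue of an app case.

Layout (one directory per case)::

    <case>/
      manifest.json        # case id, model roles, display hints, file refs
      models/*.stl|*.ply
      fiducials/*.fcsv
      transforms/*.json    # 4x4 row-major rigid transforms with frames

Saving is deterministic (sorted JSON keys, stable file names) so bundles
diff cleanly; loading validates every reference and frame and reports all
problems at once.
"""

from __future__ import annotations

import getpass
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from ..mesh import SurfaceMesh
from ..registration import FiducialSet
from ..transforms import RigidTransform
from .fcsv import read_fcsv, write_fcsv
from .meshes import read_mesh, write_mesh

__all__ = ["CaseBundle", "BundleValidationError", "load_bundle", "save_bundle"]

log = logging.getLogger(__name__)

_KNOWN_ROLES = ("bone", "tumor", "guide", "fragment", "cutting_plane", "support", "phantom_body", "other")


class BundleValidationError(ValueError):
    """Carries the full list of validation problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("case bundle failed validation:\n  - " + "\n  - ".join(problems))


@dataclass
class CaseBundle:
    """In-memory case: models, transforms and fiducial sets plus provenance."""

    case_id: str
    models: dict[str, SurfaceMesh] = field(default_factory=dict)          # name -> mesh
    roles: dict[str, str] = field(default_factory=dict)                   # name -> role
    display: dict[str, dict] = field(default_factory=dict)                # name -> hints
    transforms: dict[str, RigidTransform] = field(default_factory=dict)
    fiducials: dict[str, FiducialSet] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case id must be non-empty")

    def add_model(self, name: str, mesh: SurfaceMesh, role: str = "other",
                  color: str | None = None, opacity: float = 1.0) -> None:
        if role not in _KNOWN_ROLES:
            raise ValueError(f"unknown model role {role!r}")
        self.models[name] = mesh
        self.roles[name] = role
        self.display[name] = {"color": color or "#cccccc", "opacity": float(opacity)}

    def log_event(self, message: str) -> None:
        stamp = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        self.provenance.append(f"{stamp} {getpass.getuser()}: {message}")


def save_bundle(bundle: CaseBundle, root) -> Path:
    """Write the bundle directory; returns its path."""
    root = Path(root) / bundle.case_id
    (root / "models").mkdir(parents=True, exist_ok=True)
    (root / "fiducials").mkdir(exist_ok=True)
    (root / "transforms").mkdir(exist_ok=True)
    manifest = {
        "case_id": bundle.case_id,
        "models": {
            name: {"file": f"models/{name}.stl", "role": bundle.roles.get(name, "other"),
                   "display": bundle.display.get(name, {})}
            for name in sorted(bundle.models)
        },
        "fiducials": {name: f"fiducials/{name}.fcsv" for name in sorted(bundle.fiducials)},
        "transforms": {name: f"transforms/{name}.json" for name in sorted(bundle.transforms)},
        "provenance": bundle.provenance,
    }
    for name, mesh in bundle.models.items():
        write_mesh(mesh, root / "models" / f"{name}.stl")
    for name, fids in bundle.fiducials.items():
        write_fcsv(fids, root / "fiducials" / f"{name}.fcsv")
    for name, t in bundle.transforms.items():
        t.to_json(root / "transforms" / f"{name}.json")
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return root


def load_bundle(root) -> CaseBundle:
    """Load and validate a case bundle directory.

    All problems (missing files, dangling frames, bad manifest entries)
    are collected and raised together as :class:`BundleValidationError`.
    """
    root = Path(root)
    problems: list[str] = []
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise BundleValidationError([f"missing manifest: {manifest_path}"])
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    case_id = manifest.get("case_id", "")
    if not case_id:
        problems.append("manifest has no case_id")
    bundle = CaseBundle(case_id=case_id or "INVALID")

    for name, entry in sorted(manifest.get("models", {}).items()):
        f = root / entry.get("file", "")
        if not f.exists():
            problems.append(f"model {name!r}: missing file {entry.get('file')}")
            continue
        bundle.models[name] = read_mesh(f, label=name)
        role = entry.get("role", "other")
        if role not in _KNOWN_ROLES:
            problems.append(f"model {name!r}: unknown role {role!r}")
            role = "other"
        bundle.roles[name] = role
        bundle.display[name] = entry.get("display", {})

    for name, rel in sorted(manifest.get("fiducials", {}).items()):
        f = root / rel
        if not f.exists():
            problems.append(f"fiducial set {name!r}: missing file {rel}")
            continue
        bundle.fiducials[name] = read_fcsv(f)

    known_frames = {"anatomy", "guide", "marker", "world", "camera"}
    for name, rel in sorted(manifest.get("transforms", {}).items()):
        f = root / rel
        if not f.exists():
            problems.append(f"transform {name!r}: missing file {rel}")
            continue
        t = RigidTransform.from_json(f)
        bundle.transforms[name] = t
        known_frames.update((t.parent, t.child))
    # frame resolution: every transform's frames must connect to the chain
    for name, t in bundle.transforms.items():
        for fr in (t.parent, t.child):
            if fr not in known_frames:
                problems.append(f"transform {name!r}: dangling frame {fr!r}")

    bundle.provenance = list(manifest.get("provenance", []))
    if problems:
        raise BundleValidationError(problems)
    return bundle
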