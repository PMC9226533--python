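"""Workspace persistence: a plain directory holding the model, annotation
tables and configuration, described by a YAML manifest.

A workspace replaces a database-backed project: everything is diffable
text (SBML + TSV + YAML), so workspaces can be exported, imported and
cloned by copying the directory.
"""

from __future__ import annotations

import copy
import logging
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .model import MetabolicModel
from .sbml_io import read_sbml, write_sbml

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.yaml"


class WorkspaceError(ValueError):
    pass


@dataclass
class Workspace:
    name: str
    model: Optional[MetabolicModel] = None
    annotations: Optional["object"] = None  # AnnotationTable, kept loose to avoid cycle
    config: Dict = field(default_factory=dict)
    seed: Optional[int] = None

    def clone(self) -> "Workspace":
        return copy.deepcopy(self)


def save_workspace(ws: Workspace, directory) -> Path:
    from . import __version__
    from .annotation import AnnotationTable

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "workspace": ws.name,
        "tool_version": __version__,
        "seed": ws.seed,
        "files": {},
    }
    if ws.model is not None:
        write_sbml(ws.model, directory / "model.xml", "3.1")
        manifest["files"]["model"] = "model.xml"
    if ws.annotations is not None:
        assert isinstance(ws.annotations, AnnotationTable)
        ws.annotations.write_tsv(directory / "annotations.tsv")
        manifest["files"]["annotations"] = "annotations.tsv"
    if ws.config:
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(ws.config, fh, sort_keys=True)
        manifest["files"]["config"] = "config.yaml"
    with open(directory / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return directory


def load_workspace(directory) -> Workspace:
    from . import __version__
    from .annotation import AnnotationTable

    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise WorkspaceError(f"{directory}: missing manifest ({MANIFEST_NAME})")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("tool_version") != __version__:
        warnings.warn(
            f"workspace written by version {manifest.get('tool_version')}, "
            f"loading with {__version__} (best effort)",
            stacklevel=2,
        )
    files = manifest.get("files", {})
    ws = Workspace(name=manifest.get("workspace", directory.name), seed=manifest.get("seed"))
    if "model" in files:
        ws.model = read_sbml(directory / files["model"])
    if "annotations" in files:
        ws.annotations = AnnotationTable.read_tsv(directory / files["annotations"])
    if "config" in files:
        with open(directory / files["config"]) as fh:
            ws.config = yaml.safe_load(fh) or {}
    return ws


def clone_workspace(src_dir, dst_dir) -> Path:
    src_dir, dst_dir = Path(src_dir), Path(dst_dir)
    if not (src_dir / MANIFEST_NAME).exists():
        raise WorkspaceError(f"{src_dir}: missing manifest ({MANIFEST_NAME})")
    shutil.copytree(src_dir, dst_dir)
    return dst_dir


__all__ = ["Workspace", "save_workspace", "load_workspace", "clone_workspace", "WorkspaceError"]
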