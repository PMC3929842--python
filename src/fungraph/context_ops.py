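"""Declarative, concept-class-restricted operations on graph selections.

The extension point of the toolkit: operations (domain prediction, homology
search, literature scanning, ...) are registered in code and exposed through
*menu items* — small declarative files (YAML or XML) arranged in a nested
directory whose structure defines the menu hierarchy.  An item restricts
itself to selections of particular concept classes (subclasses included)
and names the registered operation it runs with default parameters.

Dispatch runs the operation either directly on the main graph or — the
default — on a temporary subgraph induced from the selection, which is
merged back only on success.  A failing operation therefore never leaves
partial results: the main graph is byte-identical before and after.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import yaml

from .graph_core import (ConceptClassRegistry, InformationGraph, MergeReport,
                         merge_into)

__all__ = [
    "MenuError",
    "MenuLoadError",
    "RegistrationError",
    "SelectionError",
    "MenuItem",
    "OpResult",
    "OPERATION_REGISTRY",
    "register_operation",
    "load_menu_tree",
    "applicable_items",
    "dispatch",
]


class MenuError(Exception):
    pass


class MenuLoadError(MenuError):
    pass


class RegistrationError(MenuError):
    pass


class SelectionError(MenuError):
    pass


# operation name -> callable(graph, selection_ids, params, context)
OPERATION_REGISTRY: dict[str, Callable] = {}


def register_operation(name: str):
    """Decorator registering a graph operation under ``name``."""

    def deco(func: Callable) -> Callable:
        OPERATION_REGISTRY[name] = func
        return func

    return deco


@dataclass
class MenuItem:
    id: str
    label: str
    operation: str
    applies_to: list[str] = field(default_factory=list)  # empty = all classes
    match: str = "all"  # "all" or "any" selected concepts must match
    params: dict = field(default_factory=dict)
    menu_path: list[str] = field(default_factory=list)
    source_file: str = ""


@dataclass
class OpResult:
    status: str  # "ok" | "error"
    message: str = ""
    merge_report: MergeReport | None = None


ITEM_SUFFIXES = (".yaml", ".yml", ".xml", ".item")


def _parse_item_xml(text: str, path: str) -> dict:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise MenuLoadError(f"{path}: malformed XML: {exc}") from exc
    data: dict = {"applies_to": [], "params": {}}
    for child in root:
        tag = child.tag.replace("-", "_")
        if tag == "applies_to":
            data["applies_to"].append((child.text or "").strip())
        elif tag == "param":
            data["params"][child.attrib.get("name", "")] = (child.text or "").strip()
        else:
            data[tag] = (child.text or "").strip()
    return data


def _parse_item_file(path: Path) -> dict:
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith("<"):
        return _parse_item_xml(text, str(path))
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise MenuLoadError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise MenuLoadError(f"{path}: item file must hold a mapping")
    data.setdefault("applies_to", [])
    data.setdefault("params", {})
    if isinstance(data["applies_to"], str):
        data["applies_to"] = [data["applies_to"]]
    return data


def load_menu_tree(directory, registry: dict[str, Callable] | None = None,
                   class_registry: ConceptClassRegistry | None = None
                   ) -> list[MenuItem]:
    """Load all menu items beneath ``directory`` (deterministic sorted walk).

    The relative directory path of each file becomes its ``menu_path``.
    Unknown operations and unregistered classes fail the load.
    """
    registry = OPERATION_REGISTRY if registry is None else registry
    base = Path(directory)
    if not base.is_dir():
        raise MenuLoadError(f"menu directory {directory!r} does not exist")
    items: list[MenuItem] = []
    seen_ids: set[str] = set()
    for dirpath, dirnames, filenames in os.walk(base):
        dirnames.sort()
        for fname in sorted(filenames):
            if not fname.endswith(ITEM_SUFFIXES):
                continue
            fpath = Path(dirpath) / fname
            data = _parse_item_file(fpath)
            for key in ("id", "label", "operation"):
                if not data.get(key):
                    raise MenuLoadError(f"{fpath}: missing field {key!r}")
            if data["id"] in seen_ids:
                raise MenuLoadError(f"{fpath}: duplicate item id {data['id']!r}")
            seen_ids.add(data["id"])
            if data["operation"] not in registry:
                raise RegistrationError(
                    f"{fpath}: unknown operation {data['operation']!r}")
            applies = [a for a in data["applies_to"] if a]
            if class_registry is not None:
                for cls in applies:
                    if cls not in class_registry:
                        raise RegistrationError(
                            f"{fpath}: unregistered concept class {cls!r}")
            match = str(data.get("match", "all")).lower()
            if match not in ("all", "any"):
                raise MenuLoadError(f"{fpath}: match must be 'all' or 'any'")
            rel = fpath.parent.relative_to(base)
            menu_path = [] if rel == Path(".") else list(rel.parts)
            items.append(MenuItem(
                id=data["id"], label=data["label"],
                operation=data["operation"], applies_to=applies,
                match=match, params=dict(data["params"]),
                menu_path=menu_path, source_file=str(fpath)))
    return items


def _concept_matches(cls: str, applies_to: list[str],
                     registry: ConceptClassRegistry) -> bool:
    return any(registry.is_a(cls, target) for target in applies_to)


def applicable_items(tree: list[MenuItem], selection,
                     class_registry: ConceptClassRegistry) -> list[MenuItem]:
    """Menu items applicable to a selection of concepts, in tree order.

    An unrestricted item (empty applies_to) always applies.  Restricted
    items apply when all (match=all) or at least one (match=any) selected
    concept's class is — or descends from — a listed class.
    """
    selection = list(selection)
    if not selection:
        raise SelectionError("selection must be non-empty")
    classes = [c.cls for c in selection]
    out = []
    for item in tree:
        if not item.applies_to:
            out.append(item)
            continue
        hits = [_concept_matches(cls, item.applies_to, class_registry)
                for cls in classes]
        if (all(hits) if item.match == "all" else any(hits)):
            out.append(item)
    return out


def dispatch(graph: InformationGraph, selection_ids, item: MenuItem,
             mode: str = "temp", context: dict | None = None) -> OpResult:
    """Run a menu item's operation on a selection.

    mode="temp": the operation runs on an induced temporary subgraph; on
    success the subgraph is merged back and the merge report returned; on
    failure the main graph is untouched.  mode="main": the operation runs
    on a working copy whose state replaces the main graph only on success,
    so failure likewise leaves the main graph unchanged.
    """
    if mode not in ("temp", "main"):
        raise ValueError(f"unknown dispatch mode {mode!r}")
    op = OPERATION_REGISTRY.get(item.operation)
    if op is None:
        raise RegistrationError(f"operation {item.operation!r} not registered")
    selection_ids = list(selection_ids)
    params = dict(item.params)
    if mode == "temp":
        temp = graph.induce_subgraph(selection_ids, with_relations=True)
        try:
            message = op(temp, selection_ids, params, context or {})
        except Exception as exc:
            return OpResult(status="error", message=f"{type(exc).__name__}: {exc}")
        report = merge_into(graph, temp)
        return OpResult(status="ok", message=str(message or ""),
                        merge_report=report)
    work = graph.copy()
    try:
        message = op(work, selection_ids, params, context or {})
    except Exception as exc:
        return OpResult(status="error", message=f"{type(exc).__name__}: {exc}")
    graph._replace_state_from(work)
    return OpResult(status="ok", message=str(message or ""))
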