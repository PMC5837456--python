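"""Hierarchical JSON export for the results browser.

Scan results are arranged on the biobank's hierarchical field-category
tree and written as a single JSON document: internal nodes are categories,
leaves are tested variables carrying their p-value, estimate (null for
unordered models), data type and significance flag. The document validates
against the schema shipped at ``phenoscan/data/viz_schema.json``.

Hierarchy input dialect: a category TSV with columns
``category_id  parent_id  title`` (root rows have an empty / ``NA``
parent), plus a field-to-category TSV with columns ``field_id  category_id``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .exceptions import InvalidHierarchy, SchemaError
from .results import ScanResults

logger = logging.getLogger("phenoscan")

__all__ = [
    "CategoryNode",
    "load_hierarchy",
    "load_field_categories",
    "export_viz_json",
    "validate_viz_document",
]

ROOT_ID = 0  #: synthetic root; categories with no parent attach here


@dataclass(frozen=True)
class CategoryNode:
    category_id: int
    parent_id: Optional[int]  # None = attaches to the synthetic root
    title: str


def load_hierarchy(path) -> List[CategoryNode]:
    table = pd.read_csv(path, sep="\t")
    required = {"category_id", "parent_id", "title"}
    if not required.issubset(table.columns):
        raise SchemaError(f"hierarchy file must have columns {sorted(required)}")
    nodes = []
    for _, row in table.iterrows():
        parent = row["parent_id"]
        parent_id = None if pd.isna(parent) else int(parent)
        nodes.append(
            CategoryNode(
                category_id=int(row["category_id"]),
                parent_id=parent_id,
                title=str(row["title"]),
            )
        )
    return nodes


def load_field_categories(path) -> Dict[int, int]:
    table = pd.read_csv(path, sep="\t")
    required = {"field_id", "category_id"}
    if not required.issubset(table.columns):
        raise SchemaError(f"field-category file must have columns {sorted(required)}")
    return {int(r["field_id"]): int(r["category_id"]) for _, r in table.iterrows()}


def _check_tree(nodes: List[CategoryNode]) -> None:
    ids = {n.category_id for n in nodes}
    if len(ids) != len(nodes):
        raise InvalidHierarchy("duplicate category ids")
    parents = {n.category_id: n.parent_id for n in nodes}
    for n in nodes:
        if n.parent_id == n.category_id:
            raise InvalidHierarchy(f"category {n.category_id} is its own parent")
        if n.parent_id is not None and n.parent_id not in ids:
            raise InvalidHierarchy(
                f"category {n.category_id} has unknown parent {n.parent_id}"
            )
        # walk to the root, detecting cycles
        seen = set()
        cur = n.category_id
        while cur is not None:
            if cur in seen:
                raise InvalidHierarchy(f"cycle through category {cur}")
            seen.add(cur)
            cur = parents.get(cur)


def export_viz_json(
    scan: ScanResults,
    hierarchy: List[CategoryNode],
    field_categories: Dict[int, int],
    path,
) -> dict:
    """Build and write the hierarchical results document.

    A result whose field id has no category mapping is attached directly to
    the root (logged). Returns the document that was written.
    """
    _check_tree(hierarchy)

    def node_doc(node: CategoryNode) -> dict:
        return {
            "category_id": node.category_id,
            "title": node.title,
            "children": [],
            "variables": [],
        }

    docs = {n.category_id: node_doc(n) for n in hierarchy}
    root = {
        "category_id": ROOT_ID,
        "title": "root",
        "children": [],
        "variables": [],
    }
    for n in sorted(hierarchy, key=lambda n: n.category_id):
        parent_doc = root if n.parent_id is None else docs[n.parent_id]
        parent_doc["children"].append(docs[n.category_id])

    for r in scan.results:
        leaf = {
            "name": r.name,
            "p": r.p_value,
            "estimate": r.estimate,
            "data_type": r.data_type.value,
            "below_threshold": r.below_threshold,
        }
        cat = field_categories.get(r.field_id)
        if cat is None or cat not in docs:
            logger.warning("field %d has no category mapping; attached to root", r.field_id)
            root["variables"].append(leaf)
        else:
            docs[cat]["variables"].append(leaf)

    document = {
        "alpha": scan.alpha,
        "m_tests": scan.m_tests,
        "threshold": scan.threshold,
        "tree": root,
    }
    validate_viz_document(document)
    Path(path).write_text(json.dumps(document, indent=1, allow_nan=False))
    return document


def _load_schema() -> dict:
    with resources.files("phenoscan.data").joinpath("viz_schema.json").open() as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


def _validate(instance, schema: dict, where: str, root: Optional[dict] = None) -> None:
    """Minimal structural validator for the subset of JSON-schema keywords
    the shipped schema uses (type, properties, required, items, enum, $ref)."""
    root = root if root is not None else schema
    if "$ref" in schema:
        ref = schema["$ref"]
        if not ref.startswith("#/$defs/"):
            raise SchemaError(f"unsupported $ref {ref!r}")
        schema = root["$defs"][ref.split("/")[-1]]
    stype = schema.get("type")
    if stype is not None:
        types = stype if isinstance(stype, list) else [stype]
        ok = any(
            isinstance(instance, _TYPES[t])
            and not (t in ("number", "integer") and isinstance(instance, bool))
            for t in types
        )
        if not ok:
            raise SchemaError(f"{where}: expected {stype}, got {type(instance).__name__}")
    if "enum" in schema and instance not in schema["enum"]:
        raise SchemaError(f"{where}: {instance!r} not in {schema['enum']}")
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise SchemaError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _validate(instance[key], sub, f"{where}.{key}", root)
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _validate(item, schema["items"], f"{where}[{i}]", root)


def validate_viz_document(document: dict) -> None:
    """Validate an export document against the published schema."""
    _validate(document, _load_schema(), "$")
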