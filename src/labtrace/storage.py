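"""Physical storage tree (up to five levels) and sample/DNA placements.

Locations form a forest stored as an adjacency list in the single
``storage`` relation; samples and DNA extractions are attached to leaf
nodes via ``storage_samples`` rows.  A placement with no ``date_out`` is
"open" (the item is physically there); re-placing an item requires an
explicit check-out, which preserves a complete movement history.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

from .errors import LimsError, NotFoundError
from .schema import Database

MAX_DEPTH = 5

#: item_type values accepted in placements.
ITEM_TYPES = ("sample", "dna")


@dataclass(frozen=True)
class StorageNode:
    storage_id: int
    storage_name: str
    parent_id: int | None
    level: int


def _node_row(db: Database, storage_id: int):
    row = db.one("SELECT * FROM storage WHERE storage_id=?", (storage_id,))
    if row is None:
        raise NotFoundError(f"no storage node {storage_id}")
    return row


def node_level(db: Database, storage_id: int) -> int:
    """Root distance + 1, walking parent links (cycle-safe)."""
    level, seen = 1, set()
    row = _node_row(db, storage_id)
    while row["parent_id"] is not None:
        if row["storage_id"] in seen:
            raise LimsError(f"cycle detected at storage node {row['storage_id']}")
        seen.add(row["storage_id"])
        row = _node_row(db, row["parent_id"])
        level += 1
    return level


def get_node(db: Database, storage_id: int) -> StorageNode:
    row = _node_row(db, storage_id)
    return StorageNode(row["storage_id"], row["storage_name"],
                       row["parent_id"], node_level(db, storage_id))


def add_node(db: Database, parent: int | StorageNode | None, name: str) -> StorageNode:
    parent_id = parent.storage_id if isinstance(parent, StorageNode) else parent
    if parent_id is not None:
        plevel = node_level(db, parent_id)
        if plevel >= MAX_DEPTH:
            raise LimsError(
                f"cannot add below level-{plevel} node: depth bound is {MAX_DEPTH}")
        level = plevel + 1
    else:
        level = 1
    sid = db.insert("storage", {"storage_name": name, "parent_id": parent_id})
    return StorageNode(sid, name, parent_id, level)


def rename_node(db: Database, storage_id: int, name: str) -> None:
    db.update("storage", storage_id, {"storage_name": name})


def children(db: Database, storage_id: int | None) -> list[StorageNode]:
    rows = db.query(
        "SELECT storage_id FROM storage WHERE parent_id IS ? ORDER BY storage_name",
        (storage_id,))
    return [get_node(db, r["storage_id"]) for r in rows]


def roots(db: Database) -> list[StorageNode]:
    return children(db, None)


def is_leaf(db: Database, storage_id: int) -> bool:
    return db.one("SELECT 1 FROM storage WHERE parent_id=? LIMIT 1",
                  (storage_id,)) is None


def _subtree_depth(db: Database, storage_id: int) -> int:
    kids = db.query("SELECT storage_id FROM storage WHERE parent_id=?", (storage_id,))
    if not kids:
        return 1
    return 1 + max(_subtree_depth(db, k["storage_id"]) for k in kids)


def move_node(db: Database, storage_id: int, new_parent: int | None) -> None:
    """Re-parent a node; refused if it would break the forest or depth bound."""
    _node_row(db, storage_id)
    if new_parent is not None:
        # new parent must not be inside the moved subtree (cycle guard)
        cursor = new_parent
        while cursor is not None:
            if cursor == storage_id:
                raise LimsError("cannot move a node into its own subtree")
            cursor = _node_row(db, cursor)["parent_id"]
        new_level = node_level(db, new_parent) + 1
    else:
        new_level = 1
    if new_level + _subtree_depth(db, storage_id) - 1 > MAX_DEPTH:
        raise LimsError(f"move would exceed depth bound {MAX_DEPTH}")
    db.update("storage", storage_id, {"parent_id": new_parent})


def remove_node(db: Database, storage_id: int) -> None:
    """Delete a node only when it is childless and hosts no open placement."""
    _node_row(db, storage_id)
    if not is_leaf(db, storage_id):
        raise LimsError(f"storage node {storage_id} has children")
    occupied = db.one(
        "SELECT 1 FROM storage_samples WHERE storage_id=? AND date_out IS NULL LIMIT 1",
        (storage_id,))
    if occupied:
        raise LimsError(f"storage node {storage_id} is occupied")
    db.delete("storage", storage_id)


# -- placements ----------------------------------------------------------


def _coerce_item(item) -> tuple[str, int]:
    if isinstance(item, tuple) and len(item) == 2 and item[0] in ITEM_TYPES:
        return item[0], int(item[1])
    raise NotFoundError(f"item must be ('sample'|'dna', id), got {item!r}")


def open_placement(db: Database, item) -> dict | None:
    item_type, item_id = _coerce_item(item)
    row = db.one(
        "SELECT * FROM storage_samples WHERE item_type=? AND item_id=? "
        "AND date_out IS NULL", (item_type, item_id))
    return dict(row) if row else None


def place_item(db: Database, item, node: int | StorageNode,
               date_in: str | _dt.date, position_label: str | None = None) -> int:
    """Open a placement of a sample/DNA at a leaf node."""
    item_type, item_id = _coerce_item(item)
    storage_id = node.storage_id if isinstance(node, StorageNode) else node
    _node_row(db, storage_id)
    if not is_leaf(db, storage_id):
        raise LimsError(f"storage node {storage_id} is not a leaf")
    if open_placement(db, (item_type, item_id)) is not None:
        raise LimsError(
            f"{item_type} {item_id} already has an open placement; check out first")
    table = "samples" if item_type == "sample" else "dna_extraction"
    col = "sample_id" if item_type == "sample" else "dna_id"
    if db.one(f"SELECT 1 FROM {table} WHERE {col}=? LIMIT 1", (item_id,)) is None:
        raise NotFoundError(f"no {item_type} with id {item_id}")
    return db.insert("storage_samples", {
        "item_type": item_type, "item_id": item_id, "storage_id": storage_id,
        "date_in": date_in, "position_label": position_label})


def check_out(db: Database, item, date_out: str | _dt.date) -> None:
    placement = open_placement(db, item)
    if placement is None:
        raise NotFoundError(f"{item} has no open placement")
    if str(date_out) < placement["date_in"]:
        raise LimsError("date_out precedes date_in")
    db.update("storage_samples", placement["placement_id"], {"date_out": date_out})


def locate_item(db: Database, item) -> list[StorageNode]:
    """Root-to-leaf path of the item's open placement."""
    placement = open_placement(db, item)
    if placement is None:
        raise NotFoundError(f"{item} is not in storage")
    path: list[StorageNode] = []
    sid = placement["storage_id"]
    while sid is not None:
        node = get_node(db, sid)
        path.append(node)
        sid = node.parent_id
    return list(reversed(path))


def format_path(path: list[StorageNode]) -> str:
    return " / ".join(n.storage_name for n in path)


def placement_history(db: Database, item) -> list[dict]:
    item_type, item_id = _coerce_item(item)
    rows = db.query(
        "SELECT * FROM storage_samples WHERE item_type=? AND item_id=? "
        "ORDER BY date_in, placement_id", (item_type, item_id))
    return [dict(r) for r in rows]


def list_subtree_items(db: Database, node: int | StorageNode) -> list[tuple[str, int]]:
    """All items with open placements at leaves under ``node`` (inclusive)."""
    storage_id = node.storage_id if isinstance(node, StorageNode) else node
    _node_row(db, storage_id)
    ids = [storage_id]
    frontier = [storage_id]
    while frontier:
        qmarks = ",".join("?" for _ in frontier)
        rows = db.query(
            f"SELECT storage_id FROM storage WHERE parent_id IN ({qmarks})", frontier)
        frontier = [r["storage_id"] for r in rows]
        ids.extend(frontier)
    qmarks = ",".join("?" for _ in ids)
    rows = db.query(
        f"SELECT item_type, item_id FROM storage_samples "
        f"WHERE storage_id IN ({qmarks}) AND date_out IS NULL "
        f"ORDER BY item_type, item_id", ids)
    return [(r["item_type"], r["item_id"]) for r in rows]
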