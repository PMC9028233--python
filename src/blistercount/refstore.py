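"""Persistence of blister reference records.

A store is a single human-readable JSON document keyed by blister id,
with a ``schema_version`` field::

    {
      "schema_version": 1,
      "records": {
        "mypills": {
          "blister_id": "mypills",
          "pill_centers": [[row, col], ...],
          "mean_radius": ...,
          "mean_circle_edge_ratio": ...,
          "mean_local_std": ...,
          "pill_count": ...,
          "image_height": ..., "image_width": ...,
          "config_digest": "...", "created_at": "..."
        }
      }
    }

Floats round-trip at full precision (JSON uses ``repr`` semantics).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

from .errors import (
    ReferenceConflictError,
    ReferenceNotFoundError,
    SchemaVersionError,
    StoreParseError,
)
from .registration import BlisterReference

__all__ = ["ReferenceStore", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def _to_record(ref: BlisterReference) -> dict:
    return {
        "blister_id": ref.blister_id,
        "pill_centers": [[r, c] for r, c in ref.pill_centers],
        "mean_radius": ref.mean_radius,
        "mean_circle_edge_ratio": ref.mean_circle_edge_ratio,
        "mean_local_std": ref.mean_local_std,
        "pill_count": ref.pill_count,
        "image_height": ref.image_height,
        "image_width": ref.image_width,
        "config_digest": ref.config_digest,
        "created_at": ref.created_at,
    }


def _from_record(rec: dict) -> BlisterReference:
    return BlisterReference(
        blister_id=rec["blister_id"],
        pill_centers=tuple((float(r), float(c)) for r, c in rec["pill_centers"]),
        mean_radius=float(rec["mean_radius"]),
        mean_circle_edge_ratio=float(rec["mean_circle_edge_ratio"]),
        mean_local_std=float(rec["mean_local_std"]),
        pill_count=int(rec["pill_count"]),
        image_height=int(rec["image_height"]),
        image_width=int(rec["image_width"]),
        config_digest=rec.get("config_digest", ""),
        created_at=rec.get("created_at", ""),
    )


class ReferenceStore:
    """Local database of :class:`BlisterReference` records in one JSON file.

    The file is created lazily on the first save.  Every save rewrites
    the document atomically (write-then-rename), so a crash never leaves
    a half-written store.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)

    # -- internal I/O ---------------------------------------------------
    def _read(self) -> dict:
        if not self.path.exists():
            return {"schema_version": SCHEMA_VERSION, "records": {}}
        try:
            doc = json.loads(self.path.read_text())
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise StoreParseError(f"cannot parse reference store {self.path}: {exc}") from exc
        version = doc.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"store schema version {version!r} is not supported "
                f"(expected {SCHEMA_VERSION}); migrate the store file"
            )
        return doc

    def _write(self, doc: dict) -> None:
        tmp = self.path.with_suffix(self.path.suffix + ".tmp")
        tmp.write_text(json.dumps(doc, indent=1, sort_keys=True))
        tmp.replace(self.path)

    # -- public API -----------------------------------------------------
    def list_ids(self) -> list[str]:
        return sorted(self._read()["records"])

    def save_reference(self, ref: BlisterReference, overwrite: bool = False) -> None:
        """Persist ``ref``; refuses to overwrite an id unless asked to."""
        doc = self._read()
        if ref.blister_id in doc["records"] and not overwrite:
            raise ReferenceConflictError(
                f"blister id {ref.blister_id!r} already registered; "
                "pass overwrite=True to replace it"
            )
        doc["records"][ref.blister_id] = _to_record(ref)
        self._write(doc)

    def load_reference(self, blister_id: str) -> BlisterReference:
        """Return the stored record for ``blister_id`` unmodified."""
        doc = self._read()
        if blister_id not in doc["records"]:
            available = ", ".join(sorted(doc["records"])) or "<none>"
            raise ReferenceNotFoundError(
                f"blister id {blister_id!r} not found; available: {available}"
            )
        return _from_record(doc["records"][blister_id])
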