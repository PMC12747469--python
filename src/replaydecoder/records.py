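"""Binary results log: fixed-schema records appended to a single file.

Each record on disk is a 4-byte little-endian record-type id followed by the
struct-packed payload for that type.  Supported per-field format codes are
``q`` (int64), ``d`` (float64), ``i`` (int32) and ``?`` (1-byte bool).  The
schemas are written to a JSON sidecar (``<path>.schema.json``) so a record
file is self-describing and can be loaded back into labeled DataFrames.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RecordSchema", "BinaryRecordWriter", "read_records"]

_ALLOWED_CODES = {"q", "d", "i", "?"}
_REC_ID_STRUCT = struct.Struct("<i")


@dataclass(frozen=True)
class RecordSchema:
    """Labeled binary layout for one record type."""

    rec_id: int
    labels: tuple[str, ...]
    format_codes: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        bad = set(self.format_codes) - _ALLOWED_CODES
        if bad:
            raise ValueError(f"unsupported format codes: {sorted(bad)}")
        if len(self.labels) != len(self.format_codes):
            raise ValueError(
                f"rec_id {self.rec_id}: {len(self.labels)} labels but "
                f"{len(self.format_codes)} format codes"
            )

    @property
    def struct(self) -> struct.Struct:
        return struct.Struct("<" + self.format_codes)


class RecordSchemaError(ValueError):
    pass


class BinaryRecordWriter:
    """Appends typed records to a binary file, schemas to a JSON sidecar."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._schemas: dict[int, RecordSchema] = {}
        self._structs: dict[int, struct.Struct] = {}
        self._fh = open(self.path, "wb")

    def register(self, schema: RecordSchema) -> None:
        if schema.rec_id in self._schemas:
            raise RecordSchemaError(f"rec_id {schema.rec_id} already registered")
        self._schemas[schema.rec_id] = schema
        self._structs[schema.rec_id] = schema.struct
        self._write_sidecar()

    def write_record(self, rec_id: int, *values) -> int:
        """Pack ``values`` per the registered schema; return bytes appended."""
        try:
            schema = self._schemas[rec_id]
        except KeyError:
            raise RecordSchemaError(f"rec_id {rec_id} not registered") from None
        if len(values) != len(schema.labels):
            raise RecordSchemaError(
                f"rec_id {rec_id} expects {len(schema.labels)} values, "
                f"got {len(values)}"
            )
        coerced = []
        for code, v in zip(schema.format_codes, values):
            if code in "qi":
                fv = float(v)
                if not np.isfinite(fv):
                    raise TypeError(f"non-finite value {v!r} for integer slot")
                coerced.append(int(v))
            elif code == "?":
                coerced.append(bool(v))
            else:
                coerced.append(float(v))
        payload = self._structs[rec_id].pack(*coerced)
        self._fh.write(_REC_ID_STRUCT.pack(rec_id))
        self._fh.write(payload)
        return len(payload)

    def _write_sidecar(self) -> None:
        sidecar = {
            str(s.rec_id): {"labels": list(s.labels), "format": s.format_codes}
            for s in self._schemas.values()
        }
        Path(str(self.path) + ".schema.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    def close(self) -> None:
        if not self._fh.closed:
            self._fh.close()

    def __enter__(self) -> "BinaryRecordWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _load_schemas(path: Path) -> dict[int, RecordSchema]:
    sidecar = Path(str(path) + ".schema.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"schema sidecar not found: {sidecar}")
    raw = json.loads(sidecar.read_text())
    return {
        int(k): RecordSchema(int(k), tuple(v["labels"]), v["format"])
        for k, v in raw.items()
    }


def read_records(
    path: str | Path,
    schemas: dict[int, RecordSchema] | Sequence[RecordSchema] | None = None,
) -> dict[int, pd.DataFrame]:
    """Parse a record file into one DataFrame per record id.

    Schemas default to the JSON sidecar written alongside the file.  A
    truncated trailing record raises a warning and is dropped; an unknown
    rec_id mid-file is an error (the file is then not self-consistent).
    """
    path = Path(path)
    if schemas is None:
        schemas = _load_schemas(path)
    elif not isinstance(schemas, dict):
        schemas = {s.rec_id: s for s in schemas}
    structs = {rid: s.struct for rid, s in schemas.items()}
    rows: dict[int, list[tuple]] = {rid: [] for rid in schemas}
    data = path.read_bytes()
    pos, n = 0, len(data)
    while pos < n:
        if pos + 4 > n:
            warnings.warn("truncated record id at end of file; dropped")
            break
        (rec_id,) = _REC_ID_STRUCT.unpack_from(data, pos)
        if rec_id not in structs:
            raise ValueError(
                f"unknown rec_id {rec_id} at byte {pos}; known ids: "
                f"{sorted(structs)}"
            )
        st = structs[rec_id]
        if pos + 4 + st.size > n:
            warnings.warn(f"truncated trailing record (rec_id {rec_id}); dropped")
            break
        rows[rec_id].append(st.unpack_from(data, pos + 4))
        pos += 4 + st.size
    return {
        rid: pd.DataFrame(rows[rid], columns=list(schemas[rid].labels))
        for rid in schemas
    }
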