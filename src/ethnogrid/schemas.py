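"""Minimal structural validation of artifact files against shipped schemas.

The schemas under ``ethnogrid/schemas/`` use a small JSON-Schema-like
subset — ``type``, ``required``, ``properties``, ``items``, ``enum`` —
which this module interprets directly.  Validation errors name the JSON
path of the offending value.
"""

from __future__ import annotations

import json
from importlib import resources

from .errors import ValidationError

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def load_schema(name: str) -> dict:
    """Load a shipped schema by stem, e.g. ``"cell_layer"``."""
    ref = resources.files("ethnogrid") / "schemas" / f"{name}.json"
    return json.loads(ref.read_text())


def _check(obj, schema: dict, path: str, errors: list[str]) -> None:
    t = schema.get("type")
    if t is not None:
        expected = _TYPES[t]
        ok = isinstance(obj, expected)
        if t == "number":
            ok = ok and not isinstance(obj, bool)
        if t == "integer":
            ok = ok and not isinstance(obj, bool)
        if not ok:
            errors.append(f"{path}: expected {t}, got {type(obj).__name__}")
            return
    if "enum" in schema and obj not in schema["enum"]:
        errors.append(f"{path}: {obj!r} not in {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check(obj[key], sub, f"{path}.{key}", errors)
    if isinstance(obj, list) and "items" in schema:
        for k, item in enumerate(obj):
            _check(item, schema["items"], f"{path}[{k}]", errors)


def validate_artifact(obj, schema: dict | str) -> None:
    """Raise ValidationError listing every structural mismatch."""
    if isinstance(schema, str):
        schema = load_schema(schema)
    errors: list[str] = []
    _check(obj, schema, "$", errors)
    if errors:
        raise ValidationError(errors)
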