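"""Versioned model persistence and canonical JSON reports."""

from __future__ import annotations

import json
from typing import Any

import joblib

FORMAT_TAG = "wildface-model"
FORMAT_VERSION = 1


def save_model(model: Any, path: str) -> None:
    joblib.dump(
        {"format": FORMAT_TAG, "format_version": FORMAT_VERSION, "class": type(model).__name__, "payload": model},
        path,
        compress=3,
    )


def load_model(path: str, expected_class: str | None = None) -> Any:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != FORMAT_TAG:
        raise ValueError(f"{path}: not a wildface model file")
    if expected_class is not None and blob.get("class") != expected_class:
        raise ValueError(f"{path}: expected a {expected_class}, found {blob.get('class')}")
    return blob["payload"]


def dump_json(obj: Any, path: str) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def dumps_json(obj: Any) -> str:
    return json.dumps(obj, sort_keys=True, indent=2) + "\n"
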