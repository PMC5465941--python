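"""Reading and writing item-response tables and study configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ItemResponseMatrix

__all__ = ["read_responses", "write_responses", "StudyConfig", "InputError"]


class InputError(ValueError):
    """Malformed input file (bad cell, missing header, wrong dialect)."""


def _delimiter_for(path: Path, text: str) -> str:
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    header = text.splitlines()[0] if text else ""
    return "\t" if header.count("\t") > header.count(",") else ","


def read_responses(path: str | Path, strict: bool = False) -> ItemResponseMatrix:
    """Read a headered CSV/TSV of integer-coded responses.

    The delimiter is taken from the extension (falling back to sniffing
    the header line).  Non-numeric cells raise :class:`InputError` naming
    the row and column; missing values are rejected in strict mode and
    kept as NaN otherwise (for pairwise-complete correlation handling).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    text = path.read_text()
    sep = _delimiter_for(path, text)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] == 0:
        raise InputError(f"{path}: no columns found")
    values = np.full(frame.shape, np.nan)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise InputError(
                    f"{path}: non-numeric cell at row {i + 2}, column {col}"
                ) from None
    if strict and np.isnan(values).any():
        raise InputError(f"{path}: missing values present in strict mode")
    return ItemResponseMatrix(values, tuple(map(str, frame.columns)))


def write_responses(data: ItemResponseMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = data.to_frame()
    if np.isnan(np.asarray(data.values, dtype=float)).any():
        frame.to_csv(path, sep=sep, index=False)
    else:
        frame.astype(int).to_csv(path, sep=sep, index=False)


_RANGES = {
    "gamma": (0.0, 2.0),
    "n_lambda": (1, 10_000),
    "lambda_min_ratio": (1e-6, 1.0),
    "walktrap_steps": (1, 100),
    "k_max": (1, 100),
    "pa_iterations": (1, 10_000),
    "reps": (1, 100_000),
}


@dataclass(frozen=True)
class StudyConfig:
    """All tunables of the pipeline and the Monte Carlo harness.

    Serializes losslessly to JSON; ``config_hash`` is embedded in output
    files for provenance.
    """

    seed: int = 0
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    walktrap_steps: int = 4
    k_max: int = 10
    pa_iterations: int = 20
    reps: int = 500
    methods: tuple[str, ...] = ("vss", "map", "bic", "ebic", "kaiser", "pa", "ega")

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        d = json.loads(text)
        d["methods"] = tuple(d.get("methods", cls.methods))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
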