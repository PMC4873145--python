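"""Plain-text serialization: generator/vector CSV files, config files, JSON.

A generator CSV is a square numeric block with an optional header row of
state labels; distributions and observables are single-row CSVs.  Config
files are INI-style key-value sections (``[three_state]``, ``[sensory]``,
``[fixtures]``); diagnostics go to JSON records.
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path
from typing import Any

import numpy as np

from .markov import (
    GeneratorMatrix,
    count_complex_eigenvalues,
    ddk_bound,
    is_detailed_balanced,
    validate_generator,
)

__all__ = [
    "read_generator_csv",
    "write_generator_csv",
    "read_vector_csv",
    "write_vector_csv",
    "generator_diagnostics",
    "read_config",
]


def _has_header(first_line: str) -> bool:
    for tok in first_line.split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_generator_csv(path: str | Path) -> GeneratorMatrix:
    """Read a generator matrix from CSV (optional header row of state labels)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    labels = None
    if lines[0].startswith("#"):
        labels = [tok.strip() for tok in lines[0].lstrip("#").split(",")]
        lines = lines[1:]
    elif _has_header(lines[0]):
        labels = [tok.strip() for tok in lines[0].split(",")]
        lines = lines[1:]
    rates = np.array([[float(tok) for tok in ln.split(",")] for ln in lines])
    return validate_generator(rates, labels)


def write_generator_csv(Q: GeneratorMatrix, path: str | Path) -> None:
    """Write a generator with its label header; values keep full precision."""
    with open(path, "w") as fh:
        fh.write("# " + ",".join(Q.labels) + "\n")
        for row in Q.rates:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def read_vector_csv(path: str | Path) -> np.ndarray:
    """Read a single-row CSV vector (distribution or observable)."""
    text = Path(path).read_text().strip()
    rows = [ln for ln in text.splitlines() if ln.strip()]
    if len(rows) != 1:
        raise ValueError(f"{path}: expected a single-row CSV vector")
    return np.array([float(tok) for tok in rows[0].split(",")])


def write_vector_csv(v: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(repr(float(x)) for x in np.asarray(v).ravel()) + "\n")


def generator_diagnostics(Q: GeneratorMatrix) -> dict[str, Any]:
    """Spectral and thermodynamic summary of a generator as a JSON-ready record."""
    lams = np.linalg.eigvals(Q.rates)
    order = np.argsort(lams.real)[::-1]
    lams = lams[order]
    db = is_detailed_balanced(Q)
    ddk = ddk_bound(Q)
    return {
        "n_states": Q.n,
        "labels": list(Q.labels),
        "eigenvalues_re": [float(l.real) for l in lams],
        "eigenvalues_im": [float(l.imag) for l in lams],
        "n_complex": count_complex_eigenvalues(Q),
        "ddk_min_ratio": None if np.isinf(ddk.min_ratio) else float(ddk.min_ratio),
        "ddk_bound": float(ddk.bound),
        "detailed_balanced": bool(db.balanced),
        "worst_cycle": None if db.worst_cycle is None else [int(i) for i in db.worst_cycle],
        "worst_cycle_log_ratio": (
            None if not np.isfinite(db.max_log_ratio) else float(db.max_log_ratio)
        ),
    }


def dump_json(record: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def read_config(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse an INI-style config into a dict of sections."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    return {sec: dict(cp.items(sec)) for sec in cp.sections()}
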