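"""Capture matrices: binary detection histories and their summaries.

A capture matrix records, for each photo-identified individual, whether it
was detected (1) or not (0) at each secondary occasion.  Rows are
individuals, columns are secondary occasions laid out primary by primary.
Matrices contain only animals photographed at least once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .design import SamplingDesign


class CaptureFormatError(ValueError):
    """Raised when a capture-history file does not parse."""


@dataclass(frozen=True)
class CaptureMatrix:
    """Binary detections per (individual, primary, secondary)."""

    design: SamplingDesign
    individual_ids: tuple[str, ...]
    detections: np.ndarray  # (n_individuals, total_secondaries) uint8

    def __post_init__(self) -> None:
        det = np.asarray(self.detections, dtype=np.uint8)
        object.__setattr__(self, "detections", det)
        if det.ndim != 2 or det.shape[1] != self.design.total_secondaries:
            raise ValueError(
                f"detections shape {det.shape} does not match design with "
                f"{self.design.total_secondaries} secondary occasions"
            )
        if det.shape[0] != len(self.individual_ids):
            raise ValueError("individual_ids length does not match detections")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        if not np.isin(det, (0, 1)).all():
            raise ValueError("detections must be 0/1")
        if (det.sum(axis=1) == 0).any():
            bad = [
                self.individual_ids[i]
                for i in np.flatnonzero(det.sum(axis=1) == 0)
            ]
            raise ValueError(
                f"individuals with no detections are not allowed: {bad[:5]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    def primary_block(self, t: int) -> np.ndarray:
        """Secondary detections within primary occasion ``t`` (0-based)."""
        return self.detections[:, self.design.column_slices[t]]


@dataclass(frozen=True)
class PrimaryHistoryMatrix:
    """Detected-at-least-once indicator per (individual, primary)."""

    design: SamplingDesign
    individual_ids: tuple[str, ...]
    detections: np.ndarray  # (n_individuals, n_primary) uint8

    def __post_init__(self) -> None:
        det = np.asarray(self.detections, dtype=np.uint8)
        object.__setattr__(self, "detections", det)
        if det.ndim != 2 or det.shape[1] != self.design.n_primary:
            raise ValueError("primary history shape does not match design")
        if (det.sum(axis=1) == 0).any():
            raise ValueError("primary histories must have at least one detection")

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]


def collapse_to_primary(m: CaptureMatrix) -> PrimaryHistoryMatrix:
    """Pool secondary detections: 1 iff detected in >=1 secondary of a primary."""
    cols = [m.primary_block(t).max(axis=1) for t in range(m.design.n_primary)]
    return PrimaryHistoryMatrix(
        m.design, m.individual_ids, np.column_stack(cols).astype(np.uint8)
    )


def _parse_history(token: str, row_no: int, width: int) -> np.ndarray:
    if not set(token) <= {"0", "1"}:
        raise CaptureFormatError(
            f"row {row_no}: non-binary character in history {token!r}"
        )
    if len(token) != width:
        raise CaptureFormatError(
            f"row {row_no}: history length {len(token)} != {width} secondary "
            "occasions in the design"
        )
    return np.frombuffer(token.encode(), dtype=np.uint8) - ord("0")


def read_capture_matrix(
    path: str | Path | io.TextIOBase,
    design: SamplingDesign,
    dialect: str = "plain01",
) -> CaptureMatrix:
    """Read a capture matrix from a plain-text file.

    Two dialects are accepted:

    ``plain01``
        One individual per line: a contiguous 0/1 string, optionally preceded
        by an ID token separated by whitespace.  Lines starting with ``#``
        and blank lines are ignored.
    ``mark_inp``
        MARK encounter-history format: ``/* comment */`` blocks ignored,
        each record ``<history> <frequency>;``.  Frequencies are expanded
        (each copy becomes one individual); the trailing ``;`` is optional.
    """
    if dialect not in ("plain01", "mark_inp"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    if dialect == "mark_inp":
        # strip /* ... */ comments, possibly spanning lines
        while True:
            lo = text.find("/*")
            if lo < 0:
                break
            hi = text.find("*/", lo)
            if hi < 0:
                raise CaptureFormatError("unterminated /* comment")
            text = text[:lo] + text[hi + 2 :]

    width = design.total_secondaries
    ids: list[str] = []
    rows: list[np.ndarray] = []
    auto = 0
    for row_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == "plain01":
            parts = line.split()
            if len(parts) == 1:
                token, label = parts[0], None
            elif len(parts) == 2:
                label, token = parts
            else:
                raise CaptureFormatError(
                    f"row {row_no}: expected '[id] history', got {len(parts)} tokens"
                )
            hist = _parse_history(token, row_no, width)
            auto += 1
            ids.append(label if label is not None else f"ind{auto}")
            rows.append(hist)
        else:  # mark_inp
            line = line.rstrip(";").strip()
            if not line:
                continue
            parts = line.split()
            token = parts[0]
            freq = 1
            if len(parts) > 1:
                try:
                    freq = int(float(parts[1]))
                except ValueError as exc:
                    raise CaptureFormatError(
                        f"row {row_no}: bad frequency {parts[1]!r}"
                    ) from exc
                if freq < 1:
                    raise CaptureFormatError(
                        f"row {row_no}: frequency must be >= 1 (losses on "
                        "capture are not modelled)"
                    )
            hist = _parse_history(token, row_no, width)
            for _ in range(freq):
                auto += 1
                ids.append(f"ind{auto}")
                rows.append(hist)

    if not rows:
        raise CaptureFormatError("no capture histories found in file")
    det = np.vstack(rows)
    zero = np.flatnonzero(det.sum(axis=1) == 0)
    if zero.size:
        raise CaptureFormatError(
            f"all-zero capture history at data row {zero[0] + 1}: capture "
            "matrices contain only photographed animals"
        )
    return CaptureMatrix(design, tuple(ids), det)


def write_capture_matrix(
    m: CaptureMatrix,
    path: str | Path,
    dialect: str = "plain01",
    include_ids: bool = True,
) -> None:
    """Write a capture matrix in one of the dialects `read_capture_matrix` accepts."""
    lines = []
    for ind, row in zip(m.individual_ids, m.detections):
        hist = "".join(map(str, row.tolist()))
        if dialect == "plain01":
            lines.append(f"{ind} {hist}" if include_ids else hist)
        elif dialect == "mark_inp":
            lines.append(f"{hist} 1;")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def summarize_catalog(m: CaptureMatrix) -> dict:
    """Catalog summary: per-primary counts, discovery curve, sighting histogram.

    Returns a dict with

    - ``n_per_primary``: individuals detected in each primary,
    - ``new_per_primary``: individuals first detected in each primary,
    - ``discovery_curve``: cumulative number of distinct individuals,
    - ``seen_in_k_primaries``: histogram over the number of primaries in
      which each individual was detected (index k-1 = seen in k primaries).
    """
    ph = collapse_to_primary(m).detections
    T = m.design.n_primary
    n_per = ph.sum(axis=0).astype(int)
    first = ph.argmax(axis=1)  # first primary with a 1
    new_per = np.bincount(first, minlength=T)
    seen_k = np.bincount(ph.sum(axis=1) - 1, minlength=T)
    return {
        "n_per_primary": n_per,
        "new_per_primary": new_per.astype(int),
        "discovery_curve": np.cumsum(new_per).astype(int),
        "seen_in_k_primaries": seen_k.astype(int),
        "total_individuals": int(m.n_individuals),
    }


def catalog_summary_frame(m: CaptureMatrix) -> pd.DataFrame:
    """Per-primary catalog summary as a DataFrame (for CSV export)."""
    s = summarize_catalog(m)
    return pd.DataFrame(
        {
            "primary": m.design.primary_labels,
            "n_detected": s["n_per_primary"],
            "n_new": s["new_per_primary"],
            "cumulative": s["discovery_curve"],
        }
    )
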