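"""Replicated expression matrices and fold-change computation.

This module consumes already-normalized, nonnegative probe intensities
(e.g. MAS 5.0 output) laid out probes x samples, with a sample -> condition
annotation that identifies treated and vehicle-control replicate columns.
Array preprocessing and probe annotation are out of scope; probe identifiers
are opaque strings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "FoldChangeVector",
    "average_replicates",
    "fold_change",
    "read_expression_tsv",
    "read_gct",
    "read_condition_map",
]


class ExpressionError(ValueError):
    """Invalid expression-matrix input."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probes x samples matrix of normalized intensities.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
        Entries must be finite and nonnegative.
    condition_map
        ``sample_id -> (condition_label, replicate_index)``. Every sample
        column must appear exactly once.
    """

    values: pd.DataFrame
    condition_map: Mapping[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ExpressionError("expression values must be finite")
        if (arr < 0).any():
            raise ExpressionError("expression values must be nonnegative")
        samples = list(self.values.columns)
        missing = [s for s in samples if s not in self.condition_map]
        if missing:
            raise ExpressionError(f"samples missing from condition_map: {missing}")
        extra = [s for s in self.condition_map if s not in set(samples)]
        if extra:
            raise ExpressionError(f"condition_map names unknown samples: {extra}")
        if self.values.index.has_duplicates:
            raise ExpressionError("duplicate probe ids")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond, _rep in self.condition_map.values():
            seen.setdefault(cond, None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids annotated with ``condition``, in column order."""
        return [s for s in self.values.columns
                if self.condition_map[s][0] == condition]


@dataclass(frozen=True)
class FoldChangeVector:
    """Per-probe treated/control intensity ratio.

    ``undefined`` flags probes whose control mean was zero; their ``fc``
    entry is NaN and they are excluded from signature building.
    """

    probe_ids: tuple[str, ...]
    fc: np.ndarray
    undefined: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.probe_ids) == self.fc.shape[0] == self.undefined.shape[0]):
            raise ExpressionError("fold-change fields must share length")
        defined = self.fc[~self.undefined]
        if defined.size and (not np.all(np.isfinite(defined)) or (defined < 0).any()):
            raise ExpressionError("defined fold changes must be finite and >= 0")

    def to_series(self) -> pd.Series:
        return pd.Series(self.fc, index=list(self.probe_ids), name="fc")

    @classmethod
    def from_log2(cls, probe_ids: Sequence[str],
                  log2_ratios: Sequence[float]) -> "FoldChangeVector":
        """Accept log2 ratios and exponentiate; the internal contract stays
        the plain ratio scale."""
        values = np.exp2(np.asarray(log2_ratios, dtype=float))
        undefined = ~np.isfinite(values)
        values = np.where(undefined, np.nan, values)
        return cls(tuple(probe_ids), values, undefined)


def average_replicates(matrix: ExpressionMatrix, condition: str) -> pd.Series:
    """Arithmetic mean of a condition's replicate columns, probe order kept.

    Raises
    ------
    ExpressionError
        If ``condition`` labels no sample.
    """
    cols = matrix.samples_for(condition)
    if not cols:
        raise ExpressionError(f"unknown condition label: {condition!r}")
    return matrix.values[cols].mean(axis=1)


def fold_change(treated_mean: pd.Series | Sequence[float],
                control_mean: pd.Series | Sequence[float],
                probe_ids: Sequence[str] | None = None) -> FoldChangeVector:
    """Elementwise treated/control ratio on the intensity scale.

    Control-mean zeros yield flagged-undefined entries rather than
    infinities. When both inputs are Series their indexes must agree
    positionally (probe order is meaningful).
    """
    t = np.asarray(treated_mean, dtype=float)
    c = np.asarray(control_mean, dtype=float)
    if t.shape != c.shape:
        raise ExpressionError(
            f"length mismatch: treated has {t.shape[0]}, control has {c.shape[0]}")
    if probe_ids is None:
        if isinstance(treated_mean, pd.Series):
            probe_ids = list(treated_mean.index)
            if isinstance(control_mean, pd.Series) and list(control_mean.index) != probe_ids:
                raise ExpressionError("treated/control probe order differs")
        else:
            probe_ids = [f"p{i}" for i in range(t.shape[0])]
    undefined = c == 0.0
    fc = np.full(t.shape, np.nan)
    np.divide(t, c, out=fc, where=~undefined)
    if undefined.any():
        logger.warning("fold_change: %d probes have zero control mean; flagged undefined",
                       int(undefined.sum()))
    return FoldChangeVector(tuple(probe_ids), fc, undefined)


# ---------------------------------------------------------------------------
# readers


def read_expression_tsv(path: str | Path,
                        condition_map: Mapping[str, tuple[str, int]] | None = None,
                        ) -> ExpressionMatrix:
    """Read a tab-delimited matrix: first column probe id, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, dict(condition_map or {}))


def read_gct(path: str | Path,
             condition_map: Mapping[str, tuple[str, int]] | None = None,
             ) -> ExpressionMatrix:
    """Read a GCT 1.2 file ("#1.2" line, dimensions line, Name/Description)."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ExpressionError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ExpressionError(f"{path}: malformed GCT dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=[c for c in df.columns if c.lower() == "description"])
    df.index = df.index.astype(str)
    if df.shape != (n_rows, n_cols):
        raise ExpressionError(
            f"{path}: header declares {n_rows}x{n_cols}, found {df.shape[0]}x{df.shape[1]}")
    return ExpressionMatrix(df, dict(condition_map or {}))


def read_condition_map(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a sidecar YAML/JSON sample -> condition/replicate mapping.

    Accepted layout::

        samples:
          trt_r1: {condition: nitidine, replicate: 1}
          ctl_r1: {condition: DMSO, replicate: 1}
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    samples = data.get("samples", data)
    out: dict[str, tuple[str, int]] = {}
    for sample, entry in samples.items():
        if isinstance(entry, Mapping):
            out[str(sample)] = (str(entry["condition"]), int(entry.get("replicate", 1)))
        else:  # bare condition label
            out[str(sample)] = (str(entry), 1)
    return out
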