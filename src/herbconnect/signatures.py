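"""Up/down tag-set signatures and the one-id-per-line ``.grp`` format.

A signature summarizes a treatment as two probe sets: probes whose
fold change passed the up threshold (default FC >= 2) and probes that
passed the down threshold (default FC <= 0.5). The ``.grp`` files written
here are the plain-text tag lists a connectivity query consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .expression import FoldChangeVector

logger = logging.getLogger(__name__)

__all__ = ["Signature", "build_signature", "write_grp", "read_grp", "write_signature", "read_signature"]

DEFAULT_UP_THRESHOLD = 2.0
DEFAULT_DOWN_THRESHOLD = 0.5


class GrpFormatError(ValueError):
    """Malformed .grp file."""


@dataclass(frozen=True)
class Signature:
    up_tags: tuple[str, ...]
    down_tags: tuple[str, ...]
    up_threshold: float = DEFAULT_UP_THRESHOLD
    down_threshold: float = DEFAULT_DOWN_THRESHOLD
    source_label: str = ""

    def __post_init__(self) -> None:
        if set(self.up_tags) & set(self.down_tags):
            raise ValueError("up_tags and down_tags overlap")

    def __len__(self) -> int:
        return len(self.up_tags) + len(self.down_tags)


def build_signature(fc: FoldChangeVector,
                    up_threshold: float = DEFAULT_UP_THRESHOLD,
                    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
                    source_label: str = "") -> Signature:
    """Select up/down tags from a fold-change vector by threshold.

    Up tags are probes with fc >= ``up_threshold``; down tags have
    fc <= ``down_threshold``. Flagged-undefined probes (zero control mean)
    never become tags. Log2-scale input should go through
    :meth:`FoldChangeVector.from_log2` first; thresholds always apply on
    the plain ratio scale.
    """
    if not (down_threshold < 1.0 < up_threshold):
        raise ValueError(
            f"thresholds must satisfy down < 1 < up, got down={down_threshold}, up={up_threshold}")
    values = fc.fc
    ok = ~fc.undefined
    up = [p for p, v, keep in zip(fc.probe_ids, values, ok) if keep and v >= up_threshold]
    down = [p for p, v, keep in zip(fc.probe_ids, values, ok) if keep and v <= down_threshold]
    return Signature(tuple(up), tuple(down), up_threshold, down_threshold, source_label)


def write_grp(tags: Sequence[str], destination: str | Path) -> Path:
    """Write a tag list, one identifier per line, no header."""
    destination = Path(destination)
    for tag in tags:
        if not tag or any(ch in tag for ch in "\r\n"):
            raise ValueError(f"invalid tag for .grp output: {tag!r}")
    if not tags:
        logger.warning("write_grp: writing empty tag list to %s", destination)
    destination.write_text("".join(f"{t}\n" for t in tags))
    return destination


def read_grp(source: str | Path) -> list[str]:
    """Read a .grp tag list; inverse of :func:`write_grp`.

    A trailing newline is tolerated; blank or whitespace-containing lines
    elsewhere raise with the offending line number.
    """
    lines = Path(source).read_text().split("\n")
    if lines and lines[-1] == "":
        lines = lines[:-1]
    tags: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        if line == "" or line != line.strip() or any(c.isspace() for c in line):
            raise GrpFormatError(f"{source}: malformed line {lineno}: {line!r}")
        tags.append(line)
    return tags


def write_signature(sig: Signature, directory: str | Path, label: str | None = None) -> tuple[Path, Path]:
    """Write paired ``<label>_up.grp`` / ``<label>_down.grp`` files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    label = label or sig.source_label or "signature"
    up = write_grp(sig.up_tags, directory / f"{label}_up.grp")
    down = write_grp(sig.down_tags, directory / f"{label}_down.grp")
    return up, down


def read_signature(up_path: str | Path, down_path: str | Path,
                   source_label: str = "") -> Signature:
    return Signature(tuple(read_grp(up_path)), tuple(read_grp(down_path)),
                     source_label=source_label)
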