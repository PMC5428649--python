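"""Connectivity scoring of a query signature against rank-ordered instances.

A reference *instance* is one treatment experiment: a total ordering of a
probe universe from most up- to most down-regulated, plus metadata
(compound, dose, cell line, batch). A query signature (up/down tag sets)
is scored against each instance with a Kolmogorov-Smirnov-style tag-set
enrichment statistic; instance scores are scaled so the best positive
instance gets exactly 1, and per-compound ("by name") enrichment with a
permutation p-value aggregates instances of the same compound.

The statistic for a tag set of size t in a ranking of n probes, with
V(j) the rank of the j-th best-ranked tag, is::

    a = max_j [ j/t - V(j)/n ]
    b = max_j [ V(j)/n - (j-1)/t ]
    ks = a      if a > b
       = -b     otherwise

An instance's raw score is ks_up - ks_down, forced to 0 when the two
statistics share a sign (the query pattern is not coherently induced or
reversed). Scaling divides positive raw scores by the collection maximum
and negative ones by the magnitude of the collection minimum, giving the
reported connectivity in [-1, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signatures import Signature

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceInstance",
    "InstanceScore",
    "NameEnrichment",
    "ks_enrichment",
    "instance_score",
    "scale_scores",
    "score_collection",
    "name_enrichment",
    "load_collection",
    "save_collection",
    "instance_report",
    "name_report",
]

EXACT_ENUMERATION_LIMIT = 10_000
DEFAULT_N_PERMUTATIONS = 100_000


class ConnectivityError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceInstance:
    """One treatment's full probe ranking plus metadata."""

    instance_id: str
    compound_name: str
    dose: str
    cell_line: str
    batch: str
    ranked_probes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ranked_probes)) != len(self.ranked_probes):
            raise ConnectivityError(
                f"instance {self.instance_id}: ranked_probes contains duplicates")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.ranked_probes)


@dataclass(frozen=True)
class InstanceScore:
    instance_id: str
    compound_name: str
    ks_up: float
    ks_down: float
    raw_score: float
    connectivity: float = float("nan")


@dataclass(frozen=True)
class NameEnrichment:
    compound_name: str
    n_instances: int
    enrichment: float
    p_value: float
    rank: int = 0


def _tag_positions(tags: Sequence[str], instance: ReferenceInstance,
                   on_missing: str = "drop") -> np.ndarray:
    """1-based ranks of the tags in the instance ordering, sorted ascending."""
    index = {p: i + 1 for i, p in enumerate(instance.ranked_probes)}
    positions, missing = [], 0
    for tag in tags:
        pos = index.get(tag)
        if pos is None:
            missing += 1
        else:
            positions.append(pos)
    if missing:
        if on_missing == "error":
            raise ConnectivityError(
                f"instance {instance.instance_id}: {missing} tags absent from universe")
        logger.warning("instance %s: dropped %d tags absent from universe",
                       instance.instance_id, missing)
    return np.sort(np.asarray(positions, dtype=float))


def _ks_from_positions(positions: np.ndarray, n: int) -> np.ndarray:
    """Vectorized statistic from sorted 1-based tag positions.

    ``positions`` has shape (..., t); returns shape (...,).
    """
    t = positions.shape[-1]
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - positions / n, axis=-1)
    b = np.max(positions / n - (j - 1) / t, axis=-1)
    return np.where(a > b, a, -b)


def ks_enrichment(tags: Sequence[str], ranked: ReferenceInstance | Sequence[str],
                  on_missing: str = "drop") -> float:
    """KS-style enrichment of a tag set in a ranked probe list, in [-1, 1].

    Approaches +1 when every tag leads the ranking, -1 when every tag
    trails it. Depends only on the tags' ranks, never on the identities of
    other probes. Tags missing from the universe are dropped with a logged
    count by default (``on_missing="error"`` raises instead).
    """
    if not isinstance(ranked, ReferenceInstance):
        ranked = ReferenceInstance("<anonymous>", "", "", "", "", tuple(ranked))
    if len(tags) == 0:
        raise ConnectivityError("tag set is empty")
    positions = _tag_positions(tags, ranked, on_missing=on_missing)
    if positions.size == 0:
        raise ConnectivityError("no query tags present in the instance universe")
    return float(_ks_from_positions(positions, len(ranked.ranked_probes)))


def instance_score(sig: Signature, ranked: ReferenceInstance,
                   on_missing: str = "drop") -> InstanceScore:
    """Raw connectivity of a signature to one instance.

    ks_up and ks_down are the tag enrichments of the two sets; the raw
    score is ks_up - ks_down, or 0 when both statistics have the same sign.
    An empty tag list contributes 0 on its side; both empty is an error.
    """
    if not sig.up_tags and not sig.down_tags:
        raise ConnectivityError("signature has no tags on either side")
    ks_up = ks_enrichment(sig.up_tags, ranked, on_missing) if sig.up_tags else 0.0
    ks_down = ks_enrichment(sig.down_tags, ranked, on_missing) if sig.down_tags else 0.0
    raw = 0.0 if ks_up * ks_down > 0 else ks_up - ks_down
    return InstanceScore(ranked.instance_id, ranked.compound_name, ks_up, ks_down, raw)


def scale_scores(raw: Iterable[InstanceScore]) -> list[InstanceScore]:
    """Fill ``connectivity`` so the best positive instance maps to exactly 1.

    With p the collection's maximum positive raw score and q its minimum
    negative raw score: positives divide by p, negatives by |q|, zeros stay
    zero. An all-zero collection returns all zeros.
    """
    scores = list(raw)
    if not scores:
        raise ConnectivityError("empty score collection")
    values = np.array([s.raw_score for s in scores])
    p = values[values > 0].max() if (values > 0).any() else None
    q = values[values < 0].min() if (values < 0).any() else None
    out = []
    for s in scores:
        if s.raw_score > 0:
            conn = s.raw_score / p
        elif s.raw_score < 0:
            conn = s.raw_score / abs(q)
        else:
            conn = 0.0
        out.append(replace(s, connectivity=conn))
    return out


def score_collection(sig: Signature, collection: Sequence[ReferenceInstance],
                     on_missing: str = "drop") -> list[InstanceScore]:
    """Score every instance and scale the results across the collection."""
    return scale_scores(instance_score(sig, inst, on_missing) for inst in collection)


def _null_statistics(n: int, k: int, n_permutations: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Null KS statistics for k uniformly placed tags among n positions.

    Enumerates all C(n, k) placements when that is cheap, otherwise draws
    ``n_permutations`` uniform k-subsets. Returns (statistics, exact).
    """
    if math.comb(n, k) <= EXACT_ENUMERATION_LIMIT:
        subsets = np.array(list(combinations(range(1, n + 1), k)), dtype=float)
        return _ks_from_positions(subsets, n), True
    # uniform k-subsets: first k entries of random permutations
    order = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :k]
    return _ks_from_positions(np.sort(order + 1.0, axis=1), n), False


def name_enrichment(scored: Sequence[InstanceScore],
                    n_permutations: int = DEFAULT_N_PERMUTATIONS,
                    seed: int | None = 0,
                    two_sided: bool = True) -> list[NameEnrichment]:
    """Aggregate instance scores into per-compound enrichment with a p-value.

    Instances are ordered by connectivity descending (ties broken by input
    order); each compound's instances occupy positions in that ordering and
    their KS enrichment is computed. The tail probability is the fraction of
    random same-size position subsets with a statistic at least as extreme
    on the observed side, with exact enumeration replacing sampling when the
    subset count is small. Because the side is chosen after seeing the sign,
    the default ``two_sided=True`` doubles that tail (capped at 1) so the
    reported p is valid under label shuffling; ``two_sided=False`` reports
    the one-sided tail. Sampled tails count the observed statistic as one
    permutation ((b+1)/(m+1)), so a sampled p is never 0 and its floor near
    1/n_permutations marks "below the permutation resolution"; exact
    enumeration already contains the observed subset. Rows are sorted by p
    ascending, then enrichment descending, and carry a 1-based rank.
    """
    if not scored:
        raise ConnectivityError("empty score collection")
    if any(not s.compound_name for s in scored):
        raise ConnectivityError("every instance needs a compound name")
    if n_permutations < 1:
        raise ConnectivityError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    order = sorted(range(len(scored)),
                   key=lambda i: (-scored[i].connectivity, i))
    position = {scored[i].instance_id: rank + 1 for rank, i in enumerate(order)}
    n = len(scored)

    by_name: dict[str, list[float]] = {}
    for s in scored:
        by_name.setdefault(s.compound_name, []).append(position[s.instance_id])

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, positions in by_name.items():
        k = len(positions)
        obs = float(_ks_from_positions(np.sort(np.asarray(positions, float)), n))
        if k not in null_cache:
            null_cache[k] = _null_statistics(n, k, n_permutations, rng)
        null, exact = null_cache[k]
        b = int(np.sum(null >= obs) if obs >= 0 else np.sum(null <= obs))
        tail = b / null.size if exact else (b + 1) / (null.size + 1)
        p = min(1.0, 2.0 * tail) if two_sided else tail
        rows.append(NameEnrichment(name, k, obs, float(p)))
    rows.sort(key=lambda r: (r.p_value, -r.enrichment))
    return [replace(r, rank=i + 1) for i, r in enumerate(rows)]


# ---------------------------------------------------------------------------
# collection and report IO


def save_collection(collection: Sequence[ReferenceInstance], directory: str | Path) -> Path:
    """Write one ranked-probe file per instance plus a metadata table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for inst in collection:
        (directory / f"{inst.instance_id}.rnk").write_text(
            "".join(f"{p}\n" for p in inst.ranked_probes))
        meta.append((inst.instance_id, inst.compound_name, inst.dose,
                     inst.cell_line, inst.batch))
    pd.DataFrame(meta, columns=["instance_id", "compound_name", "dose",
                                "cell_line", "batch"]
                 ).to_csv(directory / "metadata.tsv", sep="\t", index=False)
    return directory


def load_collection(directory: str | Path) -> list[ReferenceInstance]:
    """Read a collection written by :func:`save_collection`."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t", dtype=str).fillna("")
    out = []
    for row in meta.itertuples(index=False):
        ranked = tuple((directory / f"{row.instance_id}.rnk").read_text().split())
        out.append(ReferenceInstance(row.instance_id, row.compound_name,
                                     row.dose, row.cell_line, row.batch, ranked))
    if not out:
        raise ConnectivityError(f"no instances found under {directory}")
    return out


def instance_report(scored: Sequence[InstanceScore],
                    collection: Sequence[ReferenceInstance] | None = None) -> pd.DataFrame:
    """Instance-level results table, best connectivity first."""
    meta = {i.instance_id: i for i in collection} if collection else {}
    rows = sorted(scored, key=lambda s: -s.connectivity)
    df = pd.DataFrame({
        "rank": np.arange(1, len(rows) + 1),
        "batch": [meta[s.instance_id].batch if s.instance_id in meta else "" for s in rows],
        "cmap_name": [s.compound_name for s in rows],
        "dose": [meta[s.instance_id].dose if s.instance_id in meta else "" for s in rows],
        "cell": [meta[s.instance_id].cell_line if s.instance_id in meta else "" for s in rows],
        "score": [s.connectivity for s in rows],
        "instance_id": [s.instance_id for s in rows],
    })
    return df


def name_report(rows: Sequence[NameEnrichment],
                positive_p_filter: float | None = None) -> pd.DataFrame:
    """Compound-level results table; optionally keep only positive-enrichment
    rows below a p cutoff (the usual way such tables are reported)."""
    df = pd.DataFrame({
        "rank": [r.rank for r in rows],
        "cmap_name": [r.compound_name for r in rows],
        "n_instances": [r.n_instances for r in rows],
        "enrichment": [r.enrichment for r in rows],
        "p": [r.p_value for r in rows],
    })
    if positive_p_filter is not None:
        df = df[(df["enrichment"] > 0) & (df["p"] < positive_p_filter)]
    return df.reset_index(drop=True)
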