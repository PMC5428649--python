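"""Random-walk-with-restart scoring of drug/disease overlap on a PPI network.

The propagation operator is the column-normalized adjacency matrix P of an
undirected interaction network, built from a weighted edge list by keeping
high-confidence edges (default: confidence > 0.9 on the 0-1 scale), rescuing
otherwise-disconnected target genes through their single best edge, and
retaining the largest connected component. Edge weights select edges; they
do not enter P (propagation is over the unweighted retained graph).

A walker restarts to the seed distribution chi0 with probability r at each
step::

    chi_{t+1} = (1 - r) P chi_t + r chi0            (r = 0.3 by default)

The iteration is a contraction with factor (1 - r), so it converges to the
unique fixed point chi = r (I - (1-r) P)^{-1} chi0 from any start; we start
at chi0 and stop when the L1 change drops below ``tol``. Disease genes seed
with strength 1, drug targets with strength 0.01. The effect score of a
drug against a disease is the inner product of their steady-state vectors,

    s = <chi_disease, chi_drug>,

and significance is a z-score of s against random target sets of the same
size: Z = (s - mean_null) / sd_null, with Z > 3 read as a statistically
stronger-than-random effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationNetwork",
    "EffectVector",
    "SynergyResult",
    "build_network",
    "rwr",
    "effect_score",
    "z_score",
    "synergy_table",
    "synergy_frame",
    "read_edge_list",
    "read_gene_set",
    "RWRConvergenceError",
]

DEFAULT_RESTART = 0.3
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000
DISEASE_SEED_STRENGTH = 1.0
DRUG_SEED_STRENGTH = 0.01
DEFAULT_N_RANDOM = 1000


class NetworkError(ValueError):
    pass


class RWRConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(f"RWR did not converge in {max_iter} iterations "
                         f"(final L1 residual {residual:.3e})")


@dataclass(frozen=True)
class PropagationNetwork:
    """Column-normalized propagation operator over the retained component."""

    node_ids: tuple[str, ...]
    P: sp.csr_matrix
    n_edges: int
    component_info: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.node_ids)}

    def seed_vector(self, genes: Iterable[str], strength: float,
                    label: str = "") -> np.ndarray:
        """Node-indexed seed vector; genes outside the network are dropped
        with a logged count."""
        index = self.node_index
        chi0 = np.zeros(self.n_nodes)
        dropped = 0
        for g in genes:
            i = index.get(g)
            if i is None:
                dropped += 1
            else:
                chi0[i] = strength
        if dropped:
            logger.warning("seed_vector%s: dropped %d genes absent from network",
                           f" ({label})" if label else "", dropped)
        return chi0


@dataclass(frozen=True)
class EffectVector:
    """Steady-state propagation values with the provenance that made them."""

    values: np.ndarray
    node_ids: tuple[str, ...]
    r: float
    iterations_used: int
    residual: float
    seed_kind: str = ""

    def top_nodes(self, k: int = 20) -> pd.Series:
        order = np.argsort(self.values)[::-1][:k]
        return pd.Series(self.values[order], index=[self.node_ids[i] for i in order])


@dataclass(frozen=True)
class SynergyResult:
    label: str
    target_count: int
    effect_score: float
    null_mean: float
    null_sd: float
    z_score: float
    n_random: int
    seed: int
    flagged: str = ""


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (node_a, node_b, confidence) tab-delimited edge list.

    A header row is accepted if its third field is non-numeric.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 3:
        raise NetworkError(f"{path}: expected 3 columns, found {df.shape[1]}")
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:]
    out = df.iloc[:, :3].copy()
    out.columns = ["node_a", "node_b", "confidence"]
    out["confidence"] = out["confidence"].astype(float)
    return out.reset_index(drop=True)


def read_gene_set(path: str | Path, label: str | None = None) -> set[str]:
    """One-id-per-line gene set, or two-column (set_label, gene) table."""
    rows = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if rows and len(rows[0]) == 2:
        return {g for lab, g in rows if label is None or lab == label}
    return {r[0] for r in rows}


def build_network(edge_list: pd.DataFrame | Sequence[tuple[str, str, float]],
                  confidence_threshold: float = 0.9,
                  rescue_targets: Iterable[str] = ()) -> PropagationNetwork:
    """Build the propagation operator from a weighted edge list.

    Keeps edges with confidence strictly above ``confidence_threshold``
    (STRING-style 0-999 scores are auto-detected and divided by 1000);
    each ``rescue_targets`` node left without a surviving edge is re-attached
    through its single maximum-confidence edge; self-loops are dropped; only
    the largest connected component is retained; columns of P sum to 1.
    """
    if isinstance(edge_list, pd.DataFrame):
        triples = [(str(a), str(b), float(w)) for a, b, w in
                   edge_list.iloc[:, :3].itertuples(index=False)]
    else:
        triples = [(str(a), str(b), float(w)) for a, b, w in edge_list]
    if not triples:
        raise NetworkError("empty edge list")
    max_w = max(w for _, _, w in triples)
    scale = 1000.0 if max_w > 1.0 else 1.0
    triples = [(a, b, w / scale) for a, b, w in triples if a != b]

    g = nx.Graph()
    for a, b, w in triples:
        if w > confidence_threshold:
            # keep the strongest parallel edge
            if not g.has_edge(a, b) or g[a][b]["confidence"] < w:
                g.add_edge(a, b, confidence=w)
    rescue_set = {str(t) for t in rescue_targets}
    rescued = 0
    for target in rescue_set:
        if target in g and g.degree(target) > 0:
            continue
        best = None
        for a, b, w in triples:
            if target in (a, b) and (best is None or w > best[2]):
                best = (a, b, w)
        if best is not None:
            g.add_edge(best[0], best[1], confidence=best[2])
            rescued += 1
    if rescued:
        logger.info("build_network: rescued %d target nodes via their best edge", rescued)

    if g.number_of_nodes() == 0:
        raise NetworkError("no edges survive the confidence threshold")
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(components[0])
    nodes = tuple(sorted(giant.nodes()))
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for a, b in giant.edges():
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                        shape=(len(nodes), len(nodes)))
    degree = np.asarray(adj.sum(axis=0)).ravel()
    P = (adj @ sp.diags(1.0 / degree)).tocsr()
    info = {"n_components": len(components),
            "component_sizes": [len(c) for c in components[:5]],
            "rescued_targets": rescued,
            "weight_scale": scale}
    return PropagationNetwork(nodes, P, giant.number_of_edges(), info)


def _iterate(P: sp.csr_matrix, chi0: np.ndarray, r: float, tol: float,
             max_iter: int) -> tuple[np.ndarray, int, float]:
    """Run the restart iteration from chi0; chi0 may be (n,) or (n, m)."""
    chi = chi0.astype(float, copy=True)
    restart = r * chi0
    residual = np.inf
    for it in range(1, max_iter + 1):
        nxt = (1.0 - r) * (P @ chi) + restart
        residual = float(np.max(np.sum(np.abs(nxt - chi), axis=0)))
        chi = nxt
        if residual < tol:
            return chi, it, residual
    raise RWRConvergenceError(residual, max_iter)


def rwr(network: PropagationNetwork | sp.spmatrix, chi0: np.ndarray,
        r: float = DEFAULT_RESTART, tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER, seed_kind: str = "") -> EffectVector:
    """Propagate a seed vector to its steady state.

    The result satisfies chi = (1-r) P chi + r chi0 within ``tol`` (L1);
    because P is column-stochastic the total mass sum(chi) equals sum(chi0).
    Raises :class:`RWRConvergenceError` (carrying the final residual) if
    ``max_iter`` is hit first.
    """
    if not (0.0 < r < 1.0):
        raise NetworkError(f"restart probability must lie in (0, 1), got {r}")
    if isinstance(network, PropagationNetwork):
        P, node_ids = network.P, network.node_ids
    else:
        P, node_ids = sp.csr_matrix(network), tuple(f"n{i}" for i in range(network.shape[0]))
    chi0 = np.asarray(chi0, dtype=float)
    if chi0.shape[0] != P.shape[0]:
        raise NetworkError(f"seed vector length {chi0.shape[0]} != network size {P.shape[0]}")
    chi, iters, residual = _iterate(P, chi0, r, tol, max_iter)
    return EffectVector(chi, node_ids, r, iters, residual, seed_kind)


def effect_score(chi_disease: EffectVector, chi_drug: EffectVector,
                 normalized: bool = False) -> float:
    """Inner product of disease and drug steady-state vectors.

    Measures how much the drug-affected and disease-affected parts of the
    network overlap; nonnegative because both vectors are. ``normalized``
    returns the cosine variant s / (||chi_disease|| ||chi_drug||) instead.
    """
    if chi_disease.node_ids != chi_drug.node_ids:
        raise NetworkError("effect vectors index different node sets")
    s = float(np.dot(chi_disease.values, chi_drug.values))
    if normalized:
        denom = float(np.linalg.norm(chi_disease.values) * np.linalg.norm(chi_drug.values))
        return s / denom if denom else 0.0
    return s


def _degree_bins(network: PropagationNetwork, n_bins: int = 10) -> np.ndarray:
    degree = np.asarray((network.P > 0).sum(axis=0)).ravel()
    quantiles = np.quantile(degree, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(quantiles, degree, side="right")


def _sample_target_sets(network: PropagationNetwork, n_targets: int,
                        n_random: int, rng: np.random.Generator,
                        degree_matched_to: np.ndarray | None = None,
                        universe: np.ndarray | None = None) -> np.ndarray:
    """(n_random, n_targets) node indices, sampled without replacement."""
    if universe is None:
        universe = np.arange(network.n_nodes)
    if degree_matched_to is None:
        return np.stack([rng.choice(universe, size=n_targets, replace=False)
                         for _ in range(n_random)])
    bins = _degree_bins(network)
    pools = {b: universe[bins[universe] == b] for b in np.unique(bins[universe])}
    target_bins = bins[degree_matched_to]
    out = np.empty((n_random, n_targets), dtype=int)
    for i in range(n_random):
        picked: list[int] = []
        for b in target_bins:
            pool = pools.get(b, universe)
            choice = int(rng.choice(pool))
            while choice in picked:
                choice = int(rng.choice(pool if len(pool) > len(picked) else universe))
            picked.append(choice)
        out[i] = picked
    return out


def z_score(s: float, network: PropagationNetwork, chi_disease: EffectVector,
            n_targets: int, n_random: int = DEFAULT_N_RANDOM,
            rng_seed: int = 0, r: float = DEFAULT_RESTART,
            tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
            label: str = "", degree_matched: bool = False,
            degree_matched_to: Sequence[int] | None = None,
            universe: Sequence[int] | None = None) -> SynergyResult:
    """Standardize an effect score against count-matched random target sets.

    Draws ``n_random`` uniform node subsets of size ``n_targets`` from the
    retained network, builds drug seed vectors (strength 0.01), propagates
    each to steady state and scores it against ``chi_disease``; returns
    Z = (s - mean) / sd with the sample (n-1) standard deviation. Fully
    reproducible from ``rng_seed``. The random seed vectors iterate together
    as columns of one matrix — arithmetically the same update as one run
    per set. A degenerate null (sd = 0) yields a NaN Z with a warning.
    """
    if n_targets < 1:
        raise NetworkError("n_targets must be >= 1")
    if n_random < 2:
        raise NetworkError("n_random must be >= 2")
    if n_random < 100:
        logger.warning("z_score(%s): n_random=%d gives a low-precision null", label, n_random)
    rng = np.random.default_rng(rng_seed)
    matched = np.asarray(degree_matched_to, dtype=int) if degree_matched else None
    uni = np.asarray(universe, dtype=int) if universe is not None else None
    sets = _sample_target_sets(network, n_targets, n_random, rng, matched, uni)
    chi0 = np.zeros((network.n_nodes, n_random))
    for col, idx in enumerate(sets):
        chi0[idx, col] = DRUG_SEED_STRENGTH
    chi_null, _, _ = _iterate(network.P, chi0, r, tol, max_iter)
    s_null = chi_disease.values @ chi_null
    mean, sd = float(np.mean(s_null)), float(np.std(s_null, ddof=1))
    if sd == 0.0:
        logger.warning("z_score(%s): degenerate null (sd = 0); Z undefined", label)
        z = float("nan")
        flagged = "degenerate-null"
    else:
        z = (s - mean) / sd
        flagged = ""
    return SynergyResult(label, n_targets, s, mean, sd, z, n_random, rng_seed, flagged)


def null_calibration(network: PropagationNetwork, chi_disease: EffectVector,
                     n_targets: int, n_random: int = DEFAULT_N_RANDOM,
                     n_repetitions: int = 200, n_observed: int = 5,
                     rng_seed: int = 0, r: float = DEFAULT_RESTART,
                     tol: float = DEFAULT_TOL,
                     max_iter: int = DEFAULT_MAX_ITER) -> np.ndarray:
    """Empirical Z sample when targets are drawn by the null procedure itself.

    Self-diagnostic of the z-score: each repetition draws one bank of
    ``n_random`` random size-``n_targets`` counterparts plus ``n_observed``
    probe sets from the same uniform procedure, propagates them together,
    and standardizes each probe set against that repetition's bank. A
    calibrated null returns values with mean ~0 and sd ~1. Scoring several
    probe sets per bank reuses the expensive propagation and tightens the
    Monte-Carlo estimate of the mean without changing the null model.
    Returns the flat array of ``n_repetitions * n_observed`` z values.
    """
    rng = np.random.default_rng(rng_seed)
    zs = np.empty((n_repetitions, n_observed))
    for rep in range(n_repetitions):
        sets = _sample_target_sets(network, n_targets, n_random + n_observed, rng)
        chi0 = np.zeros((network.n_nodes, n_random + n_observed))
        for col, idx in enumerate(sets):
            chi0[idx, col] = DRUG_SEED_STRENGTH
        chi, _, _ = _iterate(network.P, chi0, r, tol, max_iter)
        s_all = chi_disease.values @ chi
        s_obs, s_null = s_all[:n_observed], s_all[n_observed:]
        zs[rep] = (s_obs - s_null.mean()) / s_null.std(ddof=1)
    return zs.ravel()


def score_targets(network: PropagationNetwork, chi_disease: EffectVector,
                  targets: Iterable[str], r: float = DEFAULT_RESTART,
                  tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                  ) -> tuple[float, int]:
    """Effect score of a named target set; returns (s, post-intersection count)."""
    chi0 = network.seed_vector(targets, DRUG_SEED_STRENGTH)
    count = int(np.count_nonzero(chi0))
    if count == 0:
        return float("nan"), 0
    chi_drug = rwr(network, chi0, r=r, tol=tol, max_iter=max_iter, seed_kind="drug")
    return effect_score(chi_disease, chi_drug), count


def synergy_table(component_target_sets: Mapping[str, Iterable[str]],
                  disease_genes: Iterable[str],
                  network: PropagationNetwork,
                  mixture_rule: str | Iterable[str] = "union",
                  mixture_label: str = "mixture",
                  r: float = DEFAULT_RESTART,
                  n_random: int = DEFAULT_N_RANDOM,
                  seed: int = 0,
                  tol: float = DEFAULT_TOL,
                  max_iter: int = DEFAULT_MAX_ITER) -> list[SynergyResult]:
    """Score a mixture and each component against a disease gene set.

    One :class:`SynergyResult` per component plus one for the mixture
    (listed first), all sharing the network, restart probability and RNG
    protocol (per-row child seeds spawned deterministically from ``seed``).
    ``mixture_rule`` is either ``"union"`` — the mixture's targets are the
    union of the component sets, a modelling choice for purely computational
    use — or an explicit iterable of mixture target genes (e.g. from a
    separately assayed mixture signature). Target genes absent from the
    network are dropped with a logged count and ``target_count`` reports the
    post-intersection size; a row whose set empties out is flagged and the
    others still compute.
    """
    components = {str(k): set(map(str, v)) for k, v in component_target_sets.items()}
    if not components:
        raise NetworkError("no component target sets supplied")
    if isinstance(mixture_rule, str):
        if mixture_rule != "union":
            raise NetworkError(f"unknown mixture_rule {mixture_rule!r}")
        mixture_targets = set().union(*components.values())
    else:
        mixture_targets = set(map(str, mixture_rule))

    chi0_d = network.seed_vector(disease_genes, DISEASE_SEED_STRENGTH, label="disease")
    if not np.count_nonzero(chi0_d):
        raise NetworkError("no disease genes present in the network")
    chi_disease = rwr(network, chi0_d, r=r, tol=tol, max_iter=max_iter, seed_kind="disease")

    rows = [(mixture_label, mixture_targets)] + list(components.items())
    child_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in np.random.SeedSequence(seed).spawn(len(rows))]
    results = []
    for (label, targets), row_seed in zip(rows, child_seeds):
        s, count = score_targets(network, chi_disease, targets, r, tol, max_iter)
        if count == 0:
            logger.warning("synergy_table: %r has no targets on the network; row flagged", label)
            results.append(SynergyResult(label, 0, float("nan"), float("nan"),
                                         float("nan"), float("nan"), n_random,
                                         row_seed, "empty-target-set"))
            continue
        results.append(z_score(s, network, chi_disease, count, n_random,
                               rng_seed=row_seed, r=r, tol=tol,
                               max_iter=max_iter, label=label))
    return results


def synergy_frame(results: Sequence[SynergyResult]) -> pd.DataFrame:
    """Tabular mixture-vs-components report."""
    return pd.DataFrame({
        "label": [r.label for r in results],
        "target_number": [r.target_count for r in results],
        "effect_score": [r.effect_score for r in results],
        "null_mean": [r.null_mean for r in results],
        "null_sd": [r.null_sd for r in results],
        "z_score": [r.z_score for r in results],
        "flagged": [r.flagged for r in results],
    })
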