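"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the data the pipeline consumes:

* replicated expression matrices with planted up/down-regulated probes on a
  multiplicative (MAS5-like, strictly positive) intensity scale,
* rank-ordered reference collections with planted concordant/discordant
  instances, and
* scale-free interaction networks with a densified disease module and
  component target sets at controlled overlap with that module.

Every generator is a pure function of its scenario (same seed, same
output), and each emits its ground truth so tests never re-derive it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .connectivity import ReferenceInstance
from .signatures import Signature

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionScenario",
    "ComponentSpec",
    "NetworkScenario",
    "SimulatedNetwork",
    "simulate_expression",
    "simulate_reference_collection",
    "simulate_network",
    "make_expression_scenario",
]


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionScenario:
    """Replicated treated-vs-control design with planted differential probes.

    Control intensities come from a log-normal baseline (exp(N(mu, sd)))
    shared across samples; each treated replicate multiplies planted up
    probes by ``effect_multiplier``, divides planted down probes by it, and
    every value then picks up log-normal multiplicative noise of sigma
    ``noise_sd`` (natural-log scale). Two biological replicates per
    condition is the default design.
    """

    n_probes: int
    planted: Mapping[str, tuple[frozenset[str], frozenset[str]]]  # treatment -> (up, down)
    n_replicates: int = 2
    effect_multiplier: float = 4.0
    noise_sd: float = 0.1
    control_label: str = "DMSO"
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_multiplier <= 1.0:
            raise ScenarioError("effect multiplier must exceed 1")
        if self.noise_sd < 0:
            raise ScenarioError("noise sd must be >= 0")
        if self.n_replicates < 1:
            raise ScenarioError("need at least one replicate")
        probes = set(self.probe_ids)
        for label, (up, down) in self.planted.items():
            if up & down:
                raise ScenarioError(f"{label}: planted up/down sets overlap")
            if not (up | down) <= probes:
                raise ScenarioError(f"{label}: planted sets exceed the probe universe")

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i:06d}" for i in range(self.n_probes))


def make_expression_scenario(n_probes: int, n_up: int, n_down: int,
                             treatment: str = "treated", rng_seed: int = 0,
                             **kwargs) -> ExpressionScenario:
    """Scenario with ``n_up``/``n_down`` planted probes chosen by the seed."""
    if n_up + n_down > n_probes:
        raise ScenarioError("planted sets exceed n_probes")
    rng = np.random.default_rng(rng_seed)
    ids = [f"P{i:06d}" for i in range(n_probes)]
    chosen = rng.choice(n_probes, size=n_up + n_down, replace=False)
    up = frozenset(ids[i] for i in chosen[:n_up])
    down = frozenset(ids[i] for i in chosen[n_up:])
    return ExpressionScenario(n_probes, {treatment: (up, down)},
                              rng_seed=rng_seed, **kwargs)


def simulate_expression(scenario: ExpressionScenario) -> ExpressionMatrix:
    """Draw a replicated expression matrix from the scenario."""
    rng = np.random.default_rng(scenario.rng_seed)
    probes = list(scenario.probe_ids)
    baseline = np.exp(rng.normal(scenario.baseline_log_mean,
                                 scenario.baseline_log_sd, scenario.n_probes))

    def noisy(values: np.ndarray) -> np.ndarray:
        if scenario.noise_sd == 0:
            return values.copy()
        return values * np.exp(rng.normal(0.0, scenario.noise_sd, values.shape))

    columns: dict[str, np.ndarray] = {}
    condition_map: dict[str, tuple[str, int]] = {}
    for rep in range(1, scenario.n_replicates + 1):
        sid = f"{scenario.control_label}_r{rep}"
        columns[sid] = noisy(baseline)
        condition_map[sid] = (scenario.control_label, rep)
    index = {p: i for i, p in enumerate(probes)}
    for label, (up, down) in scenario.planted.items():
        effect = np.ones(scenario.n_probes)
        effect[[index[p] for p in up]] = scenario.effect_multiplier
        effect[[index[p] for p in down]] = 1.0 / scenario.effect_multiplier
        for rep in range(1, scenario.n_replicates + 1):
            sid = f"{label}_r{rep}"
            columns[sid] = noisy(baseline * effect)
            condition_map[sid] = (label, rep)
    values = pd.DataFrame(columns, index=probes)
    return ExpressionMatrix(values, condition_map)


# ---------------------------------------------------------------------------
# reference collection


def simulate_reference_collection(signature: Signature,
                                  n_instances: int,
                                  universe: int | Sequence[str],
                                  planted: Mapping[int, int] | None = None,
                                  rng_seed: int = 0,
                                  decile: float = 0.1,
                                  names: Mapping[int, str] | None = None,
                                  cell_line: str = "MCF7",
                                  ) -> list[ReferenceInstance]:
    """Reference instances with planted concordance to a query signature.

    ``planted`` maps instance index to +1 (concordant: the query's up tags
    ranked in the top decile, down tags in the bottom decile), -1
    (discordant: the inverse placement) or 0/absent (uniform permutation).
    """
    if isinstance(universe, int):
        probes = [f"P{i:06d}" for i in range(universe)]
    else:
        probes = list(universe)
    n = len(probes)
    planted = dict(planted or {})
    tags = set(signature.up_tags) | set(signature.down_tags)
    if not tags <= set(probes):
        raise ScenarioError("universe does not cover the signature tags")
    for idx, direction in planted.items():
        if not (0 <= idx < n_instances):
            raise ScenarioError(f"planted index {idx} out of range")
        if direction not in (-1, 0, 1):
            raise ScenarioError(f"planted concordance must be -1, 0 or +1, got {direction}")
    band = int(np.floor(decile * n))
    if band < max(len(signature.up_tags), len(signature.down_tags)):
        raise ScenarioError("decile band too small for the signature tags")

    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n_instances):
        direction = planted.get(i, 0)
        if direction == 0:
            ranked = list(rng.permutation(probes))
        else:
            top_tags = list(signature.up_tags if direction > 0 else signature.down_tags)
            bottom_tags = list(signature.down_tags if direction > 0 else signature.up_tags)
            top_slots = rng.choice(band, size=len(top_tags), replace=False)
            bottom_slots = n - 1 - rng.choice(band, size=len(bottom_tags), replace=False)
            ranked_arr = np.empty(n, dtype=object)
            ranked_arr[top_slots] = top_tags
            ranked_arr[bottom_slots] = bottom_tags
            rest = [p for p in probes if p not in tags]
            free = [k for k in range(n) if ranked_arr[k] is None]
            ranked_arr[free] = list(rng.permutation(rest))
            ranked = list(ranked_arr)
        name = (names or {}).get(i, f"compound_{i:03d}")
        out.append(ReferenceInstance(
            instance_id=f"inst_{i:04d}", compound_name=name, dose="10uM",
            cell_line=cell_line, batch=f"b{i // 10:02d}", ranked_probes=tuple(ranked)))
    return out


# ---------------------------------------------------------------------------
# network


@dataclass(frozen=True)
class ComponentSpec:
    """One drug component's target-set recipe.

    ``overlap`` is the fraction of the component's ``n_targets`` that lie
    inside the disease module; module nodes are allocated disjointly across
    components in declaration order. Off-module targets can be forced at least
    ``min_distance`` hops from the module (negative-control placement).
    """

    label: str
    n_targets: int
    overlap: float
    min_distance: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ScenarioError(f"{self.label}: overlap must lie in [0, 1]")
        if self.n_targets < 1:
            raise ScenarioError(f"{self.label}: n_targets must be >= 1")


@dataclass(frozen=True)
class NetworkScenario:
    """Scale-free network with a planted, densified disease module.

    Preferential attachment supplies the degree heterogeneity that stresses
    count-matched propagation nulls; ``topology="erdos_renyi"`` gives a
    homogeneous contrast. Edge confidences are drawn above the default 0.9
    threshold so filtering keeps the planted structure intact.
    """

    n_nodes: int = 500
    attachment: int = 3
    module_size: int = 30
    module_density: float = 0.3
    components: tuple[ComponentSpec, ...] = ()
    topology: str = "barabasi_albert"
    confidence_range: tuple[float, float] = (0.905, 0.999)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_nodes:
            raise ScenarioError("module larger than the network")
        if self.topology not in ("barabasi_albert", "erdos_renyi"):
            raise ScenarioError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class SimulatedNetwork:
    edges: pd.DataFrame  # node_a, node_b, confidence
    disease_module: frozenset[str]
    component_targets: dict[str, frozenset[str]]
    manifest: dict

    def write(self, directory: str | Path) -> Path:
        """Write edges.tsv, disease_genes.txt, per-component target files
        and a JSON manifest of the planted truth."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.edges.to_csv(directory / "edges.tsv", sep="\t", index=False, header=False)
        (directory / "disease_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(self.disease_module)))
        comp_dir = directory / "components"
        comp_dir.mkdir(exist_ok=True)
        for label, targets in self.component_targets.items():
            (comp_dir / f"{label}.txt").write_text(
                "".join(f"{g}\n" for g in sorted(targets)))
        (directory / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return directory


def _node_name(i: int) -> str:
    return f"G{i:05d}"


def simulate_network(scenario: NetworkScenario) -> SimulatedNetwork:
    """Generate the network, disease module and component target sets.

    The module is densified by adding random intra-module edges until its
    internal density reaches ``module_density``; component target sets take
    their in-module share from disjoint slices of the module (so e.g. two
    components at overlap 0.5 cover complementary halves) and the remainder
    from off-module nodes, optionally at a minimum hop distance.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    seed_int = int(rng.integers(2**31))
    if scenario.topology == "barabasi_albert":
        g = nx.barabasi_albert_graph(scenario.n_nodes, scenario.attachment, seed=seed_int)
    else:
        p = 2 * scenario.attachment / (scenario.n_nodes - 1)
        g = nx.gnp_random_graph(scenario.n_nodes, p, seed=seed_int)
        if not nx.is_connected(g):  # keep the generator total: bridge stragglers
            comps = list(nx.connected_components(g))
            for comp in comps[1:]:
                g.add_edge(next(iter(comps[0])), next(iter(comp)))

    module = sorted(rng.choice(scenario.n_nodes, scenario.module_size, replace=False))
    module_set = set(module)
    m = len(module)
    possible = m * (m - 1) // 2
    wanted = int(np.ceil(scenario.module_density * possible))
    have = sum(1 for a in module for b in module if a < b and g.has_edge(a, b))
    pairs = [(a, b) for ai, a in enumerate(module) for b in module[ai + 1:]
             if not g.has_edge(a, b)]
    if wanted > have:
        extra = rng.choice(len(pairs), size=min(wanted - have, len(pairs)), replace=False)
        for k in extra:
            g.add_edge(*pairs[k])

    dist_from_module = {}
    for node, d in nx.multi_source_dijkstra_path_length(g, module_set).items():
        dist_from_module[node] = d

    module_pool = list(rng.permutation(module))
    taken_outside: set[int] = set()
    component_targets: dict[str, frozenset[str]] = {}
    for comp in scenario.components:
        n_in = int(round(comp.overlap * comp.n_targets))
        if n_in > len(module_pool):
            raise ScenarioError(
                f"{comp.label}: needs {n_in} module nodes but only "
                f"{len(module_pool)} remain unallocated")
        inside = [module_pool.pop() for _ in range(n_in)]
        outside_pool = [v for v in g.nodes
                        if v not in module_set and v not in taken_outside
                        and (comp.min_distance is None
                             or dist_from_module.get(v, np.inf) >= comp.min_distance)]
        n_out = comp.n_targets - n_in
        if n_out > len(outside_pool):
            raise ScenarioError(f"{comp.label}: cannot place {n_out} off-module targets "
                                f"under the distance constraint")
        outside = [outside_pool[k] for k in
                   rng.choice(len(outside_pool), size=n_out, replace=False)]
        taken_outside.update(outside)
        component_targets[comp.label] = frozenset(_node_name(v) for v in inside + outside)

    conf_lo, conf_hi = scenario.confidence_range
    records = [(_node_name(a), _node_name(b),
                round(float(rng.uniform(conf_lo, conf_hi)), 4))
               for a, b in g.edges()]
    edges = pd.DataFrame(records, columns=["node_a", "node_b", "confidence"])
    disease = frozenset(_node_name(v) for v in module)
    manifest = {
        "scenario": _scenario_dict(scenario),
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "disease_module": sorted(disease),
        "component_targets": {k: sorted(v) for k, v in component_targets.items()},
    }
    return SimulatedNetwork(edges, disease, component_targets, manifest)


def _scenario_dict(scenario) -> dict:
    d = dataclasses.asdict(scenario)

    def clean(x):
        if isinstance(x, frozenset):
            return sorted(x)
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        return x

    return clean(d)
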