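"""Configured end-to-end workflows with provenance capture.

Two workflows mirror the package's intended uses: a connectivity query
(replicate averaging -> fold change -> signature -> scoring against a
reference collection) and a synergy evaluation (network construction ->
propagation -> effect scores and z-scores for a mixture and its
components). Configuration is file-first (YAML/JSON) with keyword
overrides; every stochastic stage carries an explicit seed, and reports
embed the tool version and a hash of the resolved configuration so a
report can be regenerated from its own header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .connectivity import (instance_report, load_collection, name_enrichment,
                           name_report, score_collection)
from .expression import average_replicates, fold_change, read_condition_map, read_expression_tsv, read_gct
from .netprop import build_network, read_edge_list, read_gene_set, synergy_frame, synergy_table
from .signatures import build_signature, read_signature, write_signature

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_connectivity_workflow", "run_synergy_workflow", "PipelineError"]


class PipelineError(RuntimeError):
    """Workflow failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All thresholds, seeds and paths for one run.

    Unused fields are ignored by each workflow; ``out_dir`` receives the
    reports. Load from YAML/JSON with :meth:`from_file`; keyword arguments
    there override file values (flags > file > defaults).
    """

    # signature stage
    expression: str | None = None
    expression_format: str = "tsv"            # tsv | gct
    conditions: str | None = None             # sidecar condition map
    treatment: str | None = None
    control: str = "DMSO"
    fc_up: float = 2.0
    fc_down: float = 0.5
    # connectivity stage
    collection: str | None = None
    up_grp: str | None = None
    down_grp: str | None = None
    n_permutations: int = 100_000
    permutation_seed: int = 0
    filter_positive_p: float | None = None
    # synergy stage
    network: str | None = None
    confidence_threshold: float = 0.9
    disease_genes: str | None = None
    components_dir: str | None = None
    mixture: str = "union"                    # "union" or a gene-set path
    restart: float = 0.3
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 10_000
    n_random: int = 1000
    synergy_seed: int = 0
    # output
    out_dir: str = "."
    label: str = "query"

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else (yaml.safe_load(text) or {})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def provenance_header(self, seeds: dict[str, int]) -> str:
        lines = [f"# herbconnect {__version__}",
                 f"# config_hash {self.config_hash()}"]
        lines += [f"# seed {name} {value}" for name, value in sorted(seeds.items())]
        return "\n".join(lines) + "\n"


def _write_report(df: pd.DataFrame, path: Path, header: str) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
    return path


def _stage(name: str):
    """Wrap a stage body so failures carry the stage name."""
    class _ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s done in %.2fs", name, dt)
                return False
            if isinstance(exc, PipelineError):
                return False
            raise PipelineError(name, str(exc)) from exc
    return _ctx()


def run_connectivity_workflow(config: RunConfig) -> dict[str, Path]:
    """Signature extraction (optional) followed by a collection query.

    Either ``expression``+``conditions``+``treatment`` (the signature is
    computed and its .grp pair persisted) or pre-made ``up_grp``/``down_grp``
    paths must be supplied. Returns the written file paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if config.expression is not None:
        with _stage("signature"):
            cond_map = read_condition_map(config.conditions) if config.conditions else {}
            reader = read_gct if config.expression_format == "gct" else read_expression_tsv
            matrix = reader(config.expression, cond_map)
            if config.treatment is None:
                raise ValueError("treatment condition not named in config")
            treated = average_replicates(matrix, config.treatment)
            control = average_replicates(matrix, config.control)
            fc = fold_change(treated, control)
            sig = build_signature(fc, config.fc_up, config.fc_down,
                                  source_label=config.label)
            if len(sig) == 0:
                raise ValueError("empty signature: no probes pass the fold-change filter")
            up_path, down_path = write_signature(sig, out, config.label)
            outputs["up_grp"], outputs["down_grp"] = up_path, down_path
    elif config.up_grp and config.down_grp:
        with _stage("signature"):
            sig = read_signature(config.up_grp, config.down_grp, config.label)
            if len(sig) == 0:
                raise ValueError("empty signature: both .grp files are empty")
    else:
        raise PipelineError("signature", "need either an expression matrix or .grp paths")

    with _stage("query"):
        if config.collection is None:
            raise ValueError("no reference collection configured")
        collection = load_collection(config.collection)
        scored = score_collection(sig, collection)
        names = name_enrichment(scored, config.n_permutations, config.permutation_seed)
        header = config.provenance_header({"permutations": config.permutation_seed})
        outputs["instance_report"] = _write_report(
            instance_report(scored, collection), out / "instance_report.tsv", header)
        outputs["name_report"] = _write_report(
            name_report(names, config.filter_positive_p), out / "name_report.tsv", header)
    return outputs


def run_synergy_workflow(config: RunConfig) -> dict[str, Path]:
    """Network construction, propagation, and the mixture-vs-components table."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("network"):
        if not (config.network and config.disease_genes and config.components_dir):
            raise ValueError("network, disease_genes and components_dir are required")
        edges = read_edge_list(config.network)
        disease = read_gene_set(config.disease_genes)
        comp_dir = Path(config.components_dir)
        component_sets = {p.stem: read_gene_set(p)
                          for p in sorted(comp_dir.glob("*.txt"))}
        if not component_sets:
            raise ValueError(f"no component gene sets under {comp_dir}")
        rescue = set(disease).union(*component_sets.values())
        network = build_network(edges, config.confidence_threshold, rescue_targets=rescue)

    with _stage("synergy"):
        mixture_rule = (config.mixture if config.mixture == "union"
                        else read_gene_set(config.mixture))
        results = synergy_table(component_sets, disease, network,
                                mixture_rule=mixture_rule, r=config.restart,
                                n_random=config.n_random, seed=config.synergy_seed,
                                tol=config.rwr_tol, max_iter=config.rwr_max_iter)
        header = config.provenance_header({"synergy": config.synergy_seed})
        path = _write_report(synergy_frame(results), out / "synergy_report.tsv", header)
    return {"synergy_report": path}
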