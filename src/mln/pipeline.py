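"""End-to-end analysis pipeline and artifact management.

``run_mln`` drives the full chain — read inputs, map gain-loss scenarios over
the penalty grid, select the scheme by the ancestral size criterion, apply
the parallel-evolution allowance, build and export the lateral network, and
summarize — writing every artifact together with a manifest that records the
configuration hash, the seed, and a content hash of each output file, so a
run is reproducible and auditable from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from .characters import (
    CharacterMatrix,
    Wordlist,
    read_matrix,
    read_wordlist,
    to_character_matrix,
)
from .network import LateralNetwork, NetworkSummary, build_mln, export_network, summarize
from .parsimony import CostScheme, DEFAULT_GAIN_COSTS, ScenarioSet, map_all
from .selection import (
    AncestralSizeProfile,
    SelectionReport,
    apply_parallel_allowance,
    select_scheme,
)
from .simulate import SimulationParams, SimulationTruth, simulate
from .tree import ReferenceTree, read_newick

__all__ = ["RunConfig", "PipelineError", "MlnResult", "run_mln", "run_simulate"]

logger = logging.getLogger("mln")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run."""

    mode: Literal["language", "genome"] = "language"
    tree_path: str | None = None
    wordlist_path: str | None = None
    matrix_path: str | None = None
    gain_costs: tuple[float, ...] = DEFAULT_GAIN_COSTS
    loss_cost: float = 1.0
    alpha: float = 0.05
    statistic: str = "ks"
    tolerance: Literal["exact", "pvalue"] = "exact"
    parallel_fraction: float = 0.0
    seed: int = 0
    out_dir: str | None = None
    export_formats: tuple[str, ...] = ("edge-list", "gml", "dot")

    def __post_init__(self) -> None:
        if not self.gain_costs:
            raise PipelineError("config: gain-cost grid is empty")
        if self.mode not in ("language", "genome"):
            raise PipelineError(f"config: unknown mode {self.mode!r}")
        if self.wordlist_path and self.matrix_path:
            raise PipelineError("config: give either a wordlist or a matrix, not both")

    def grid(self) -> list[CostScheme]:
        return [CostScheme(g, self.loss_cost) for g in self.gain_costs]

    def to_json(self) -> dict:
        return {
            "mode": self.mode,
            "tree_path": self.tree_path,
            "wordlist_path": self.wordlist_path,
            "matrix_path": self.matrix_path,
            "gain_costs": ["inf" if math.isinf(g) else g for g in self.gain_costs],
            "loss_cost": self.loss_cost,
            "alpha": self.alpha,
            "statistic": self.statistic,
            "tolerance": self.tolerance,
            "parallel_fraction": self.parallel_fraction,
            "seed": self.seed,
        }


@dataclass
class MlnResult:
    """In-memory result bundle of a full analysis."""

    tree: ReferenceTree
    matrix: CharacterMatrix
    scenario_set: ScenarioSet
    selection: SelectionReport
    profiles: dict[CostScheme, AncestralSizeProfile]
    network: LateralNetwork
    summary: NetworkSummary
    artifacts: dict[str, str] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _sha256(data: str) -> str:
    return hashlib.sha256(data.encode()).hexdigest()


def _write_artifacts(
    out_dir: Path, files: dict[str, str], config: RunConfig
) -> dict[str, str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for name, content in files.items():
        (out_dir / name).write_text(content)
        hashes[name] = _sha256(content)
    config_json = json.dumps(config.to_json(), indent=2, sort_keys=True)
    manifest = {
        "config": config.to_json(),
        "config_hash": _sha256(config_json),
        "seed": config.seed,
        "files": hashes,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return hashes


def _load_inputs(
    config: RunConfig,
    tree: ReferenceTree | None = None,
    matrix: CharacterMatrix | None = None,
    wordlist: Wordlist | None = None,
):
    if tree is None:
        if not config.tree_path:
            raise PipelineError("stage 'read': no tree given")
        path = Path(config.tree_path)
        if not path.exists():
            raise PipelineError(f"stage 'read': tree file not found: {path}")
        tree = _stage("read")(read_newick)(path.read_text())
    if matrix is None:
        if wordlist is None:
            if config.wordlist_path:
                path = Path(config.wordlist_path)
                if not path.exists():
                    raise PipelineError(
                        f"stage 'read': wordlist file not found: {path}"
                    )
                wordlist = _stage("read")(read_wordlist)(path.read_text())
            elif config.matrix_path:
                path = Path(config.matrix_path)
                if not path.exists():
                    raise PipelineError(f"stage 'read': matrix file not found: {path}")
                matrix = _stage("read")(read_matrix)(path.read_text())
            else:
                raise PipelineError("stage 'read': no wordlist or matrix given")
        if matrix is None:
            matrix = _stage("read")(to_character_matrix)(wordlist, tree.taxa)
    return tree, matrix, wordlist


def run_mln(
    config: RunConfig,
    tree: ReferenceTree | None = None,
    matrix: CharacterMatrix | None = None,
    wordlist: Wordlist | None = None,
) -> MlnResult:
    """Execute the full pipeline; objects already in memory may be passed to
    skip file reading.  Artifacts are written when ``config.out_dir`` is set.
    """
    tree, matrix, wordlist = _load_inputs(config, tree, matrix, wordlist)
    logger.info(
        "read: %d taxa, %d characters", len(tree.taxa), matrix.n_characters
    )

    scenario_set = _stage("map_all")(map_all)(matrix, tree, config.grid())
    logger.info(
        "map_all: %d scenarios over %d schemes",
        matrix.n_characters * len(config.gain_costs),
        len(config.gain_costs),
    )

    selection, profiles = _stage("select_scheme")(select_scheme)(
        scenario_set,
        matrix,
        mode=config.mode,
        alpha=config.alpha,
        statistic=config.statistic,
        tolerance=config.tolerance,
    )
    logger.info(
        "select_scheme: gain_cost=%s selected (%d lateral events)",
        selection.selected.gain_cost,
        selection.row_for(selection.selected).total_lateral_events,
    )

    flagged = _stage("apply_parallel_allowance")(apply_parallel_allowance)(
        scenario_set, selection.selected, config.parallel_fraction
    )
    network = _stage("build_mln")(build_mln)(flagged, tree)
    summary = _stage("summarize")(summarize)(network, matrix)
    logger.info(
        "build_mln: %d lateral edges, total weight %g",
        summary.n_lateral_edges,
        summary.total_lateral_weight,
    )

    result = MlnResult(
        tree=tree,
        matrix=matrix,
        scenario_set=scenario_set,
        selection=selection,
        profiles=profiles,
        network=network,
        summary=summary,
    )
    if config.out_dir:
        files = {
            "scenarios.tsv": scenario_set.to_tsv(),
            "selection.tsv": selection.to_tsv(),
            "selection.json": json.dumps(
                _finite(selection.to_json()), indent=2, sort_keys=True
            ),
            "summary.json": json.dumps(summary.to_json(), indent=2, sort_keys=True),
            "tree.nwk": tree.write_newick(),
        }
        for fmt in config.export_formats:
            ext = {"edge-list": "edges.tsv", "gml": "network.gml", "dot": "network.dot"}
            files[ext.get(fmt, f"network.{fmt}")] = _stage("export")(export_network)(
                network, fmt
            )
        result.artifacts = _write_artifacts(Path(config.out_dir), files, config)
    return result


def _finite(obj):
    """Replace non-JSON floats (inf/nan) by strings, recursively."""
    if isinstance(obj, float):
        if math.isinf(obj) or math.isnan(obj):
            return repr(obj)
        return obj
    if isinstance(obj, dict):
        return {k: _finite(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_finite(v) for v in obj]
    return obj


def run_simulate(
    params: SimulationParams, out_dir: str | Path | None = None
) -> tuple[Wordlist, CharacterMatrix, SimulationTruth]:
    """Simulate a dataset and optionally write wordlist TSV + truth JSON."""
    wordlist, matrix, truth = simulate(params)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "wordlist.tsv").write_text(wordlist.write_tsv())
        (out / "truth.json").write_text(
            json.dumps(truth.to_json(), indent=2, sort_keys=True)
        )
        (out / "tree.nwk").write_text(params.tree.write_newick())
    return wordlist, matrix, truth
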