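"""Layered run configuration: defaults <- YAML file <- explicit overrides.

Defaults are the published operating point of the workflow: population 200,
5-way tournament, crossover 0.8, per-bit mutation 0.02, 10% initialization,
stagnation after 200 unchanged generations, SVM cost 1, confidence threshold
0.9, separation cutoff -0.6, 2/3 presence, 4-fold difference, top-100
candidates, 4 clusters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .nsga2 import GAConfig

__version__ = "0.1.0"


@dataclass
class RunConfig:
    # prefilter
    min_presence: float = 2.0 / 3.0
    min_fold: float = 4.0
    top_k: int = 100
    rank_stats: tuple = ("mean_diff", "welch_t", "rank_sum")
    # objectives / network
    confidence_threshold: float = 0.9
    penalty_form: str = "reciprocal"
    fallback_distance: float | None = None   # None -> max finite distance + 1
    svm_c: float = 1.0
    # genetic algorithm
    population_size: int = 200
    tournament_size: int = 5
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02
    init_set_fraction: float = 0.10
    stagnation_generations: int = 200
    max_generations: int = 5000
    seed: int = 0
    # postprocessing
    separation_cutoff: float = -0.6
    n_clusters: int = 4

    def __post_init__(self) -> None:
        self.rank_stats = tuple(self.rank_stats)
        self.ga_config()  # validates the GA block

    def ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            tournament_size=self.tournament_size,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            init_set_fraction=self.init_set_fraction,
            stagnation_generations=self.stagnation_generations,
            max_generations=self.max_generations,
            seed=self.seed,
        )


_VALID_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig with precedence defaults <- file <- overrides.

    Unknown keys are rejected with the list of valid keys, catching typos
    like ``poulation_size`` before a long run starts.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a key/value mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(data) - _VALID_KEYS)
    if unknown:
        raise ValueError(
            f"unknown config key(s): {', '.join(unknown)}; "
            f"valid keys: {', '.join(sorted(_VALID_KEYS))}"
        )
    return RunConfig(**data)


def manifest(config: RunConfig) -> dict:
    """Serializable manifest sufficient to reproduce the run."""
    return {
        "package": "paretosig",
        "version": __version__,
        "config": dataclasses.asdict(config),
    }


def write_manifest(config: RunConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest(config), fh, indent=2, sort_keys=True)
    return path
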