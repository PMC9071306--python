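"""Named hyperparameter presets and run configuration.

The six presets exercise the iterative search and its refinements: the plain
coordinate search, each refinement in isolation (restart, direction
permutation, grid refinement) and two combined settings, the second on a
denser 21-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .classifiers import ConfigurationError
from .optimizers import OptimizerConfig

#: name -> (gridsize, epochs, shift_epoch, shuffle_epoch, finer_epoch)
PRESETS: dict[str, tuple[int, int, int, int, int]] = {
    "iterative grid search": (11, 4, 4, 4, 4),
    "shift": (11, 8, 4, 8, 8),
    "shuffle": (11, 8, 8, 2, 8),
    "finer": (11, 8, 8, 8, 4),
    "combined 1": (11, 16, 8, 2, 4),
    "combined 2": (21, 16, 8, 2, 4),
}


def resolve_preset(name: str, seed: int = 42, start_policy: str = "mle") -> OptimizerConfig:
    """Look up a preset by (case-insensitive) name."""
    key = name.strip().lower()
    if key not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: "
            + ", ".join(sorted(PRESETS))
        )
    gridsize, epochs, shift, shuffle, finer = PRESETS[key]
    return OptimizerConfig(
        epochs=epochs,
        shift_epoch=shift,
        shuffle_epoch=shuffle,
        finer_epoch=finer,
        gridsize=gridsize,
        start_policy=start_policy,
        seed=seed,
    )


@dataclass
class RunConfig:
    """A fully resolvable description of one CLI run."""

    dataset: dict[str, Any] = field(default_factory=lambda: {"family": "random_linear"})
    classifier: str = "knn"
    optimizer: str = "iterative"
    preset: str | None = None
    kfolds: int = 10
    repetitions: int = 5
    gridsize: int = 11
    seed: int = 42
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))
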