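"""Packaged fixtures: the porphyrin metalation hierarchy and yield table."""

from __future__ import annotations

from importlib import resources
from typing import Literal

from .experiments import ExperimentRecord, parse_experiments
from .hierarchy import DecisionHierarchy, load_hierarchy

__all__ = [
    "load_porphyrin_hierarchy",
    "load_porphyrin_experiments",
    "porphyrin_hierarchy_path",
    "porphyrin_experiments_path",
]


def _data(name: str):
    return resources.files("ahprank.data").joinpath(name)


def porphyrin_hierarchy_path(variant: Literal["4", "5"] = "4") -> str:
    """Filesystem path of the packaged hierarchy config (4- or 5-criterion)."""
    name = "porphyrin_hierarchy.yaml" if variant == "4" else "porphyrin_hierarchy_1080.yaml"
    return str(_data(name))


def porphyrin_experiments_path() -> str:
    """Filesystem path of the packaged 25-experiment yield table."""
    return str(_data("porphyrin_experiments.csv"))


def load_porphyrin_hierarchy(
    variant: Literal["4", "5"] = "4",
    method: Literal["eigenvector", "column_norm"] = "eigenvector",
) -> DecisionHierarchy:
    """The Pd(II)/Pt(II) porphyrin-metalation decision hierarchy.

    ``variant="4"`` is the main model (metal salt, mole ratio, solvent,
    duration; 360 combinations); ``variant="5"`` adds reaction temperature
    as an independent criterion (1080 combinations).
    """
    name = "porphyrin_hierarchy.yaml" if variant == "4" else "porphyrin_hierarchy_1080.yaml"
    with resources.files("ahprank.data").joinpath(name).open("r") as fh:
        return load_hierarchy(fh, method=method)


def load_porphyrin_experiments() -> list[ExperimentRecord]:
    """The 25 laboratory metalation experiments with observed yields."""
    with resources.files("ahprank.data").joinpath("porphyrin_experiments.csv").open("r") as fh:
        return parse_experiments(fh)
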