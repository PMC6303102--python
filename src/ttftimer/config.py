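"""Loading and saving of the text configuration files.

Every biological table the analysis depends on -- the regulatory topology and
structural constants, the genotype phenotype table, the identity map, the
sampling ranges and the stage-to-minute table -- ships as an editable YAML
file under ``ttftimer/data`` and can be overridden by a user file of the same
layout.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .circuit import (
    CircuitTopology,
    Interaction,
    Perturbation,
    StructuralConstants,
)
from .errors import ConfigError
from .phenotype import GenotypeSpec, IdentityMap, PhenotypeTable


def _read_yaml(source: str | Path | None, default_name: str) -> dict:
    if source is None:
        text = resources.files("ttftimer.data").joinpath(default_name).read_text()
    else:
        text = Path(source).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at the top level of {source or default_name}")
    return data


def require(mapping: Mapping[str, Any], key: str, context: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing required key {key!r} in {context}")
    return mapping[key]


def load_topology(path: str | Path | None = None) -> tuple[CircuitTopology, StructuralConstants]:
    """Load the regulatory graph and structural constants."""
    data = _read_yaml(path, "topology.yaml")
    ttfs = tuple(require(data, "ttfs", "topology config"))
    interactions = []
    for entry in require(data, "interactions", "topology config"):
        interactions.append(
            Interaction(
                source=require(entry, "source", "interaction"),
                target=require(entry, "target", "interaction"),
                sign=require(entry, "sign", "interaction"),
                klass=entry.get("klass", "forward-relay"),
                has_threshold=bool(entry.get("has_threshold", True)),
            )
        )
    topology = CircuitTopology(ttfs, tuple(interactions))
    constants = StructuralConstants(**data.get("constants", {}))
    return topology, constants


def load_phenotype_table(path: str | Path | None = None) -> PhenotypeTable:
    """Load the genotype -> expected phase sequence table."""
    data = _read_yaml(path, "phenotypes.yaml")
    genotypes = []
    for entry in require(data, "genotypes", "phenotype config"):
        pert = entry.get("perturbation", {"kind": "none"})
        genotypes.append(
            GenotypeSpec(
                name=require(entry, "name", "genotype"),
                perturbation=Perturbation(pert.get("kind", "none"), pert.get("target")),
                expected=tuple(frozenset(s) for s in require(entry, "expected", "genotype")),
            )
        )
    return PhenotypeTable(tuple(genotypes))


def load_identity_map(path: str | Path | None = None) -> IdentityMap:
    data = _read_yaml(path, "identity.yaml")
    return IdentityMap(dict(require(data, "identity_map", "identity config")))


def load_ranges_config(path: str | Path | None = None) -> dict:
    """Raw sampling-range mapping (see :class:`ttftimer.screen.ParameterRanges`)."""
    return _read_yaml(path, "ranges.yaml")


def load_stage_table(path: str | Path | None = None):
    """Stage label -> (start, end) minute table, as an invivo.StageTable."""
    from .invivo import StageTable

    data = _read_yaml(path, "stages.yaml")
    stages = require(data, "stages", "stage config")
    return StageTable(tuple((name, float(lo), float(hi)) for name, (lo, hi) in stages.items()))


def dump_yaml(data: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
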