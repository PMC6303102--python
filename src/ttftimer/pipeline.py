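"""End-to-end pipeline: screen -> score -> position -> in-vivo demo.

Each stage reads its predecessor's tabular output and writes its own, so any
stage can be re-run in isolation; a manifest records configuration hashes,
seeds, record counts and output paths.  All randomness is seeded explicitly
from the master config (never from the clock), so a rerun with the same
config produces byte-identical record files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .config import load_identity_map, load_phenotype_table, load_stage_table, require
from .circuit import DEFAULT_CONSTANTS, build_default_topology
from .decay_relay import (
    compute_perturbation_shifts,
    deletion_sensitivity,
    density_map,
    significance_scores,
)
from .errors import TTFTimerError
from .invivo import position_from_measurements
from .robustness import score_records
from .screen import ParameterRanges, run_screen
from .synthetic import generate_staining_dataset, staining_config_from_circuit
from .circuit import ParameterSet

log = logging.getLogger(__name__)


def _config_hash(obj: Any) -> str:
    return hashlib.sha1(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_all(config: Mapping[str, Any] | str | Path) -> dict:
    """Run the full pipeline from a master config; returns the manifest.

    Required keys: ``seed``, ``outdir``, ``screen.n_circuits``.  Optional:
    ``robustness.{tol,eps}``, ``invivo.{enabled,n_per_stage,noise_sd,effect,
    robust_cutoff}``.  A stage failure aborts with the failing stage named;
    outputs of completed stages are preserved.
    """
    if not isinstance(config, Mapping):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    seed = require(config, "seed", "pipeline config")
    outdir = Path(require(config, "outdir", "pipeline config"))
    screen_cfg = require(config, "screen", "pipeline config")
    n_circuits = require(screen_cfg, "n_circuits", "pipeline config: screen")
    rob_cfg = config.get("robustness", {})
    invivo_cfg = config.get("invivo", {})

    outdir.mkdir(parents=True, exist_ok=True)
    topology = build_default_topology()
    constants = DEFAULT_CONSTANTS
    table = load_phenotype_table()
    identity_map = load_identity_map()
    stage_table = load_stage_table()
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(dict(config)),
        "stage_table_hash": stage_table.table_hash,
        "outputs": {},
        "counts": {},
    }

    def _stage(name: str, fn):
        try:
            return fn()
        except TTFTimerError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise TTFTimerError(f"pipeline stage {name!r} failed: {exc}") from exc

    # -- screen ----------------------------------------------------------
    records_path = outdir / "records.csv"

    def _screen():
        return run_screen(
            int(n_circuits),
            ParameterRanges.defaults(topology),
            topology,
            table,
            seed=int(seed),
            constants=constants,
            out=records_path,
            chunk_size=int(screen_cfg.get("chunk_size", 4000)),
        )

    records = _stage("screen", _screen)
    manifest["outputs"]["records"] = str(records_path)
    manifest["counts"]["circuits"] = len(records)
    manifest["counts"]["consistent"] = int(records["consistent"].sum())
    log.info("screen: %d/%d consistent", manifest["counts"]["consistent"], len(records))

    # -- score -----------------------------------------------------------
    scored_path = outdir / "scored.csv"

    def _score():
        cons = records[records["consistent"]].copy()
        cons = score_records(
            cons, topology, identity_map, constants,
            tol=float(rob_cfg.get("tol", 0.10)), eps=float(rob_cfg.get("eps", 0.2)),
        )
        return cons

    scored = _stage("score", _score)

    # -- position --------------------------------------------------------
    coords_path = outdir / "coords.csv"
    density_path = outdir / "density.json"

    def _position():
        if len(scored):
            out = compute_perturbation_shifts(scored, topology, constants)
            out = significance_scores(out)
            out = deletion_sensitivity(out)
        else:
            out = scored.copy()
            for col in ("decay_significance", "relay_significance",
                        "hb_deletion_shift", "kr_deletion_shift"):
                out[col] = pd.Series(dtype=float)
        out.to_csv(coords_path, index=False)
        dens = density_map(
            out["decay_significance"], out["relay_significance"],
            values=out["robustness_score"],
        )
        density_path.write_text(json.dumps(dens.to_json(), indent=1))
        return out

    coords = _stage("position", _position)
    coords.to_csv(scored_path, index=False)
    manifest["outputs"]["scored"] = str(scored_path)
    manifest["outputs"]["coords"] = str(coords_path)
    manifest["outputs"]["density"] = str(density_path)
    manifest["counts"]["robust"] = int((coords["robustness_score"] > 80).sum())

    # -- in-vivo demo ----------------------------------------------------
    if invivo_cfg.get("enabled", True):
        position_path = outdir / "position.json"
        staining_path = outdir / "staining.csv"

        def _invivo():
            from .synthetic import select_positioning_truth

            cutoff = float(invivo_cfg.get("robust_cutoff", 80.0))
            truth, sim_cfg = select_positioning_truth(
                coords, stage_table, topology, constants,
                effect=float(invivo_cfg.get("effect", 0.6)),
                noise_sd=float(invivo_cfg.get("noise_sd", 0.2)),
                n_per_stage=int(invivo_cfg.get("n_per_stage", 10)),
            )
            staining = generate_staining_dataset(sim_cfg, seed=int(seed) + 1)
            staining.to_csv(staining_path, index=False)
            pos = position_from_measurements(staining, coords, stage_table, cutoff)
            position_path.write_text(json.dumps(pos.to_json(), indent=1))
            return pos

        _stage("invivo", _invivo)
        manifest["outputs"]["staining"] = str(staining_path)
        manifest["outputs"]["position"] = str(position_path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
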