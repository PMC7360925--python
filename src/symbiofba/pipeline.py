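"""One-command reproduction of the biomass-ratio sweep experiment.

``run_fig3`` builds (toy mode) or loads (files mode) the organism models,
runs the ratio sweep, and writes ``fig3.tsv`` plus a machine-readable run
log with enough provenance (config hash, versions, solver, tolerances) to
re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy
import scipy
import yaml

from . import __version__
from .community import CommunitySpec
from .core import Medium, OrganismModel
from .errors import ConfigurationError
from .io import load_medium, load_model
from .sweep import DEFAULT_RATIOS, SweepResult, run_ratio_sweep, write_sweep_tsv
from .synth import ToyParams, make_toy_symbiosis


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one sweep run."""

    source: Literal["toy", "files"] = "toy"
    out_dir: str = "."
    ratios: Sequence[str] = DEFAULT_RATIOS
    hisd_reaction: str = "HisD"
    aicar_metabolite: str = "aicar"
    seed: int = 0
    # toy mode
    toy_params: ToyParams = field(default_factory=ToyParams)
    # files mode
    host_path: str | None = None
    buchnera_path: str | None = None
    hamiltonella_path: str | None = None
    model_format: str = "native-json"
    medium_path: str | None = None
    linked_mets: Sequence[str] | None = None
    files_ratio: str = "6.7:1"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "toy_params" in raw:
            raw["toy_params"] = ToyParams(**raw["toy_params"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in sorted(vars(self).items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


def _spec_from_config(config: RunConfig) -> CommunitySpec:
    if config.source == "toy":
        toy = make_toy_symbiosis(config.toy_params)
        from .sweep import parse_ratio

        return toy.spec(parse_ratio(config.files_ratio))
    if config.source != "files":
        raise ConfigurationError(f"unknown model source {config.source!r}")
    for name in ("host_path", "buchnera_path", "hamiltonella_path", "medium_path"):
        if getattr(config, name) is None:
            raise ConfigurationError(f"files mode requires {name}")
    fmt = config.model_format
    host = load_model(config.host_path, fmt)
    buchnera = load_model(config.buchnera_path, fmt)
    hamiltonella = load_model(config.hamiltonella_path, fmt)
    medium: Medium = load_medium(config.medium_path)
    from .sweep import parse_ratio

    linked = frozenset(config.linked_mets) if config.linked_mets else None
    spec = CommunitySpec(
        host=host,
        symbionts=[(buchnera, 1.0), (hamiltonella, parse_ratio(config.files_ratio))],
        medium=medium,
        reference=buchnera.id,
        linked_mets=linked,
    )
    _check_reaction_ids(spec, config)
    return spec


def _check_reaction_ids(spec: CommunitySpec, config: RunConfig) -> None:
    ref = next(m for m, _ in spec.symbionts if m.id == spec.reference_id)
    if config.hisd_reaction not in ref.reactions:
        near = sorted(
            r for r in ref.reactions if config.hisd_reaction.lower() in r.lower()
        )[:5]
        raise ConfigurationError(
            f"HisD reaction {config.hisd_reaction!r} not found in "
            f"{ref.id!r}; near matches: {near}"
        )
    if config.aicar_metabolite not in ref.metabolites:
        near = sorted(
            m for m in ref.metabolites if config.aicar_metabolite.lower() in m.lower()
        )[:5]
        raise ConfigurationError(
            f"AICAR metabolite {config.aicar_metabolite!r} not found in "
            f"{ref.id!r}; near matches: {near}"
        )


def run_fig3(config: RunConfig) -> SweepResult:
    """Run the ratio sweep per ``config``; write fig3.tsv and run_log.json."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = _spec_from_config(config)
    result = run_ratio_sweep(
        spec,
        ratios=config.ratios,
        hisd_reaction=config.hisd_reaction,
        aicar_metabolite=config.aicar_metabolite,
    )
    write_sweep_tsv(result, out_dir / "fig3.tsv")
    log = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "source": config.source,
        "ratios": list(config.ratios),
        "solver": "scipy.optimize.linprog(method='highs')",
        "reporting_tolerance": 1e-6,
        "objective": "pFBA (min total |v|) under pinned fixed demands",
        "versions": {
            "symbiofba": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    return result
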