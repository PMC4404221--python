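"""Run configuration: a validated YAML schema for the end-to-end pipeline.

``load_config`` validates eagerly and reports *every* violation at once, so
a user fixes a config file in one round trip rather than error-by-error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .markers import ConstructParts
from .simulate import DepthModel, SimConfig


@dataclass
class CallingSettings:
    method: str = "both"           # kmeans | dbscan | both
    k: int | None = None           # default: number of classes per marker
    eps: float = 0.1
    eps_per_locus: dict = field(default_factory=dict)
    min_pts: int = 5
    min_depth: int = 10
    seed: int = 1


@dataclass
class RunConfig:
    """Everything the pipeline needs: paths, construct parts, caller and
    (optionally) simulator settings.  When ``fastq`` is unset the pipeline
    simulates its input."""

    markers_tsv: str | None = None
    barcodes_tsv: str | None = None
    fastq: str | None = None
    outdir: str = "sgbs_out"
    parts: ConstructParts = field(default_factory=ConstructParts)
    calling: CallingSettings = field(default_factory=CallingSettings)
    simulate: SimConfig | None = None
    n_reads: int | None = None

    @property
    def methods(self) -> list[str]:
        if self.calling.method == "both":
            return ["kmeans", "dbscan"]
        return [self.calling.method]


def _build(raw: dict, errors: list[str]) -> RunConfig:
    cfg = RunConfig()
    known_top = {"markers_tsv", "barcodes_tsv", "fastq", "outdir",
                 "parts", "calling", "simulate", "n_reads"}
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown config key {key!r}")

    for key in ("markers_tsv", "barcodes_tsv", "fastq", "outdir"):
        if key in raw:
            setattr(cfg, key, str(raw[key]))
    if "n_reads" in raw and raw["n_reads"] is not None:
        cfg.n_reads = int(raw["n_reads"])

    if "parts" in raw:
        try:
            cfg.parts = ConstructParts(**raw["parts"])
        except (TypeError, ValueError) as exc:
            errors.append(f"parts: {exc}")

    call_raw = raw.get("calling", {})
    cfg.calling = CallingSettings(
        **{k: v for k, v in call_raw.items() if k in CallingSettings.__annotations__}
    )
    for key in call_raw:
        if key not in CallingSettings.__annotations__:
            errors.append(f"calling: unknown key {key!r}")

    if "simulate" in raw and raw["simulate"] is not None:
        sim_raw = dict(raw["simulate"])
        depth_raw = sim_raw.pop("depth", {})
        try:
            depth = DepthModel(**depth_raw) if depth_raw else DepthModel()
            cfg.simulate = SimConfig(depth=depth, **sim_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of violations; empty iff the config is runnable."""
    errors: list[str] = []
    c = cfg.calling
    if c.method not in ("kmeans", "dbscan", "both"):
        errors.append(f"calling.method must be kmeans|dbscan|both, got {c.method!r}")
    if c.eps <= 0:
        errors.append(f"calling.eps must be > 0, got {c.eps}")
    for locus, e in c.eps_per_locus.items():
        if e <= 0:
            errors.append(f"calling.eps_per_locus[{locus!r}] must be > 0, got {e}")
    if c.min_pts < 1:
        errors.append(f"calling.min_pts must be >= 1, got {c.min_pts}")
    if c.min_depth < 1:
        errors.append(f"calling.min_depth must be >= 1, got {c.min_depth}")
    if c.k is not None and c.k < 1:
        errors.append(f"calling.k must be >= 1, got {c.k}")

    if cfg.markers_tsv is None:
        errors.append("markers_tsv is required")
    elif not Path(cfg.markers_tsv).exists():
        errors.append(f"markers_tsv path does not exist: {cfg.markers_tsv}")
    for key in ("barcodes_tsv", "fastq"):
        path = getattr(cfg, key)
        if path is not None and not Path(path).exists():
            errors.append(f"{key} path does not exist: {path}")
    if cfg.fastq is None and cfg.simulate is None:
        errors.append("either fastq (count mode) or simulate settings are required")
    return errors


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run config.

    Raises :class:`ConfigError` whose message enumerates every violation.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file does not exist: {path}")
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    errors: list[str] = []
    cfg = _build(raw, errors)
    errors.extend(validate_config(cfg))
    if errors:
        raise ConfigError(
            f"invalid config {path}:\n" + "\n".join(f"  - {e}" for e in errors)
        )
    return cfg
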