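"""Run configuration: one declarative YAML file validated up front."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .genome_model import CircularGenome
from .window_tracks import WindowSpec


@dataclass(frozen=True)
class RunConfig:
    """Validated inputs for one end-to-end pipeline run."""

    length_bp: int
    origins: tuple[int, ...]
    genes_path: Path
    spots_path: Path
    outdir: Path
    spot_columns: dict[str, str] | None = None
    cog_matrix_path: Path | None = None
    excluded_genomes: tuple[str, ...] = ()
    window: WindowSpec = field(default_factory=WindowSpec)
    table_window: WindowSpec = field(
        default_factory=lambda: WindowSpec(100_000, 100_000, "nonoverlapping")
    )
    n_bins: int = 12
    alpha: float = 0.05
    exclude_categories: tuple[str, ...] = ("txn_translation",)
    condition: str = "exponential"
    seed: int = 0

    def genome(self) -> CircularGenome:
        return CircularGenome(self.length_bp, self.origins)

    def validate_paths(self) -> None:
        for p in (self.genes_path, self.spots_path, self.cog_matrix_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_bins < 1:
            raise ConfigError(f"n_bins must be >= 1, got {self.n_bins}")


def _window_spec(block: Mapping[str, Any], default: WindowSpec) -> WindowSpec:
    size = int(block.get("size_bp", default.size_bp))
    mode = str(block.get("mode", default.mode))
    # step is meaningless for abutting windows; default it to the size
    step_default = size if mode == "nonoverlapping" else default.step_bp
    return WindowSpec(size, int(block.get("step_bp", step_default)), mode)


def load_config(path, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``overrides`` (e.g. from CLI flags) replace top-level keys before
    validation.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    try:
        genome_block = raw["genome"]
        spots_block = raw["spots"]
        cfg = RunConfig(
            length_bp=int(genome_block["length_bp"]),
            origins=tuple(int(o) for o in genome_block["origins"]),
            genes_path=Path(genome_block["genes"]),
            spots_path=Path(spots_block["path"]),
            spot_columns=spots_block.get("columns"),
            cog_matrix_path=(
                Path(raw["cog"]["matrix"]) if raw.get("cog", {}).get("matrix") else None
            ),
            excluded_genomes=tuple(raw.get("cog", {}).get("excluded_genomes", ())),
            window=_window_spec(raw.get("windows", {}), WindowSpec()),
            table_window=_window_spec(
                raw.get("table_windows", {}),
                WindowSpec(100_000, 100_000, "nonoverlapping"),
            ),
            n_bins=int(raw.get("stats", {}).get("n_bins", 12)),
            alpha=float(raw.get("stats", {}).get("alpha", 0.05)),
            exclude_categories=tuple(
                raw.get("stats", {}).get("exclude_categories", ("txn_translation",))
            ),
            condition=str(raw.get("condition", "exponential")),
            outdir=Path(raw.get("outdir", "results/run")),
            seed=int(raw.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required config key {exc}") from exc
    cfg.validate_paths()
    return cfg
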