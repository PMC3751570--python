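"""Pipeline configuration: every tunable threshold in one text file.

The detection, linking and BSI parameters that the original publication left
unspecified are deliberately surfaced here so that users can see and override
each one.  Configuration lives in a TOML file; ``PipelineConfig.default()``
carries the package defaults and ``to_toml``/``from_toml`` round-trip them.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .bsi import VIEW_RULES, BsiError
from .detection import DetectionConfig
from .linking import LinkingConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    atlas_path: str | None = None          # None -> bundled synthetic atlas
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    view_rule: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.view_rule not in VIEW_RULES:
            raise ConfigError(f"view_rule must be one of {VIEW_RULES}")

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls()

    def load_atlas(self):
        from .atlas import default_atlas, load_atlas
        if self.atlas_path is None:
            return default_atlas()
        return load_atlas(self.atlas_path)

    # -- TOML round trip ------------------------------------------------------

    def to_toml(self) -> str:
        det, link = asdict(self.detection), asdict(self.linking)
        det.pop("region_offsets")
        lines = ["# bsitrack pipeline configuration (all thresholds overridable)", ""]
        if self.atlas_path is not None:
            lines.append(f'atlas_path = "{self.atlas_path}"')
        lines += [f'view_rule = "{self.view_rule}"', f"seed = {self.seed}", "",
                  "[detection]"]
        lines += [f"{k} = {v}" for k, v in det.items()]
        lines += ["", "[linking]"]
        lines += [f"{k} = {str(v).lower() if isinstance(v, bool) else v}"
                  for k, v in link.items()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = tomllib.loads(Path(path).read_text())
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        try:
            return cls(
                atlas_path=data.get("atlas_path"),
                detection=DetectionConfig(**data.get("detection", {})),
                linking=LinkingConfig(**data.get("linking", {})),
                view_rule=data.get("view_rule", "mean"),
                seed=int(data.get("seed", 0)),
            )
        except (TypeError, ValueError, BsiError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
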