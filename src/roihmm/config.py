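"""Project configuration: site metadata plus analysis parameters."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from zoneinfo import ZoneInfo

import yaml

__all__ = ["SiteInfo", "ProjectConfig", "load_config"]


@dataclass
class SiteInfo:
    """One recording site, as stored per study area (with its time zone)."""

    site_id: str = "site-1"
    name: str = ""
    longitude: float = 0.0
    latitude: float = 0.0
    elevation_m: float = 0.0
    time_zone: str = "UTC"

    def __post_init__(self) -> None:
        ZoneInfo(self.time_zone)  # raises if unresolvable
        if not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude out of range: {self.latitude}")


@dataclass
class ProjectConfig:
    site: SiteInfo = field(default_factory=SiteInfo)
    window_size: int = 512
    hop: int = 256
    roi_factor: float = 1.10
    connectivity: int = 8
    min_cells: int = 1
    exclude_dc: bool = True

    def __post_init__(self) -> None:
        if self.window_size < 2 or self.hop < 1:
            raise ValueError("window_size must be >= 2 and hop >= 1")
        if self.roi_factor <= 0:
            raise ValueError("roi_factor must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")


def load_config(path: str | Path) -> ProjectConfig:
    """Read a project YAML (all keys optional; sensible defaults)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    site = SiteInfo(**doc.get("site", {}))
    kwargs = {k: v for k, v in doc.items() if k != "site"}
    return ProjectConfig(site=site, **kwargs)
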