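"""Application configuration (YAML round-trip)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import Role
from .errors import MitoprofileError
from .exporters import DEFAULT_MANAGER_RANGES

__all__ = ["AppConfig"]


@dataclass
class AppConfig:
    """Paths, control-region ranges, acting user and log level."""

    database_path: str = "mitoprofile.db"
    reference_path: str | None = None
    control_region_ranges: tuple[tuple[int, int], ...] = DEFAULT_MANAGER_RANGES
    user_name: str = "system"
    user_role: Role = Role.ADMIN
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "database_path": self.database_path,
            "reference_path": self.reference_path,
            "control_region_ranges": [list(r) for r in self.control_region_ranges],
            "user": {"name": self.user_name, "role": self.user_role.value},
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AppConfig":
        user = data.get("user", {})
        ranges = data.get("control_region_ranges")
        return cls(
            database_path=data.get("database_path", "mitoprofile.db"),
            reference_path=data.get("reference_path"),
            control_region_ranges=tuple(
                (int(a), int(b)) for a, b in ranges
            ) if ranges else DEFAULT_MANAGER_RANGES,
            user_name=user.get("name", "system"),
            user_role=Role(user.get("role", "admin")),
            log_level=data.get("log_level", "INFO"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "AppConfig":
        path = Path(path)
        if not path.exists():
            raise MitoprofileError(f"config file {path} not found")
        data = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(data)
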