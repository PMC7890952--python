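"""Run configuration: schema-validated YAML that replaces interactive choices.

Unknown keys are rejected before any computation so that typos fail fast
with field-level messages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cernanet.network_build import ThresholdSpec


class ConfigError(ValueError):
    """Raised on schema violations, naming the offending field."""


# allowed keys per config section (None = free-form mapping)
_SCHEMA: dict[str, dict | None] = {
    "inputs": {
        "cerna_expr": None,
        "mirna_expr": None,
        "interactions": None,
        "annotation": None,
        "delimiter": None,
    },
    "grouping": {"attribute": None, "rule": None, "default_group": None},
    "sample_filter": {
        "cerna_detect_threshold": None,
        "mirna_detect_threshold": None,
        "drop_lowest": None,
        "min_ratio": None,
    },
    "gene_filter": {"groups": None, "mirna": None},
    "transform": {"log": None, "normalize": None},
    "measures": None,
    "discretization": {"n_bins": None, "method": None},
    "thresholds": None,
    "group_pairs": None,
    "modules": {"algorithm": None, "resolution": None, "seed": None},
    "out": None,
    "seed": None,
    "workers": None,
}

_VALID_MEASURES = {"MS", "PCC", "MI", "CMI", "LA"}


@dataclass
class RunConfig:
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        for key, value in raw.items():
            if key not in _SCHEMA:
                raise ConfigError(f"unknown config key {key!r}")
            sub = _SCHEMA[key]
            if sub is not None and isinstance(value, dict):
                for k in value:
                    if k not in sub:
                        raise ConfigError(f"unknown config key {key}.{k!r}")
        cfg = cls(raw)
        cfg._validate()
        return cfg

    def _validate(self) -> None:
        for m in self.measures:
            if m not in _VALID_MEASURES:
                raise ConfigError(f"measures: unknown measure {m!r}")
        computed = set(self.measures)
        for spec in self.thresholds:
            if spec.measure not in computed:
                raise ConfigError(
                    f"thresholds: measure {spec.measure!r} is not in the "
                    f"computed set {sorted(computed)}"
                )
        sf = self.raw.get("sample_filter")
        if sf and ("drop_lowest" in sf) == ("min_ratio" in sf):
            raise ConfigError(
                "sample_filter: specify exactly one of drop_lowest / min_ratio"
            )

    # -- typed accessors -------------------------------------------------
    def input_path(self, name: str) -> Path:
        inputs = self.raw.get("inputs") or {}
        if name not in inputs:
            raise ConfigError(f"inputs.{name} is required")
        return Path(inputs[name])

    @property
    def delimiter(self) -> str:
        return (self.raw.get("inputs") or {}).get("delimiter", "auto")

    @property
    def measures(self) -> list[str]:
        return list(self.raw.get("measures") or ["MS", "PCC"])

    @property
    def thresholds(self) -> list[ThresholdSpec]:
        out = []
        for item in self.raw.get("thresholds") or []:
            extra = set(item) - {"measure", "direction", "cutoff", "group_pair"}
            if extra:
                raise ConfigError(f"thresholds: unknown key(s) {sorted(extra)}")
            try:
                out.append(
                    ThresholdSpec(
                        measure=item["measure"],
                        direction=item["direction"],
                        cutoff=float(item["cutoff"]),
                        group_pair=item.get("group_pair", "all"),
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"thresholds: missing field {exc}") from exc
        return out

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def workers(self) -> int:
        return int(self.raw.get("workers", 1))

    @property
    def out(self) -> Path:
        return Path(self.raw.get("out", "cernanet_out"))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, config: RunConfig, inputs: dict[str, Path]) -> Path:
    """Record config echo, package version, input checksums and seed."""
    from cernanet import __version__

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.raw,
        "input_checksums": {
            name: sha256_of(p) for name, p in inputs.items() if Path(p).exists()
        },
    }
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
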