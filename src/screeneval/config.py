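"""Run configuration: one structured file holding every tunable convention.

All tunable conventions live here so they are visible and overridable in a
single place: the log-axis lower bound lambda, the qualitative enrichment
bands, the interaction-geometry cutoffs, region definitions and the generic
helix.position numbering map.  Unknown keys are rejected on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .enrichment import DEFAULT_BAND_EDGES, DEFAULT_BAND_LABELS, DEFAULT_LAMBDA
from .poses import DEFAULT_AROMATIC_CUTOFF, DEFAULT_SALT_BRIDGE_CUTOFF
from .structure import RegionDefinition

__all__ = ["ConfigError", "RunConfig", "parse_region"]


class ConfigError(ValueError):
    """Configuration file is malformed or holds unknown keys."""


@dataclass
class RunConfig:
    lam: float = DEFAULT_LAMBDA
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES
    band_labels: tuple[str, ...] = DEFAULT_BAND_LABELS
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF
    aromatic_cutoff: float = DEFAULT_AROMATIC_CUTOFF
    regions: dict = field(default_factory=dict)  # name -> selector spec
    numbering_map: dict = field(default_factory=dict)  # "3.32" -> [chain, resnum]
    seed: int = 0

    _KEY_ALIASES = {"lambda": "lam"}

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        kwargs = {}
        for key, value in data.items():
            name = cls._KEY_ALIASES.get(key, key)
            if name not in known:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[name] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
        return cls.from_mapping(data)

    def validate(self) -> None:
        if not 0.0 < self.lam < 1.0:
            raise ConfigError("lambda must lie in (0, 1)")
        self.band_edges = tuple(float(e) for e in self.band_edges)
        self.band_labels = tuple(str(l) for l in self.band_labels)
        if len(self.band_labels) != len(self.band_edges) + 1:
            raise ConfigError("need exactly one more band label than edge")
        if list(self.band_edges) != sorted(self.band_edges):
            raise ConfigError("band edges must be increasing")
        if self.salt_bridge_cutoff <= 0 or self.aromatic_cutoff <= 0:
            raise ConfigError("cutoffs must be positive")

    def region(self, name: str) -> RegionDefinition:
        if name not in self.regions:
            raise ConfigError(f"region {name!r} not defined in config")
        return parse_region(name, self.regions[name], self.numbering_map)

    def digest(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        payload = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if not f.name.startswith("_")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def parse_region(
    name: str, spec: dict | list, numbering_map: dict | None = None
) -> RegionDefinition:
    """Build a region from a config selector.

    Accepted forms::

        {chain: A, residues: [5, 6, "10-20"]}
        {bw: ["3.32", "5.46"]}            # resolved via the numbering map
        [["A", 5], ["A", 6]]              # explicit (chain, resnum) pairs

    Range strings like ``"10-20"`` are inclusive.
    """
    if isinstance(spec, list):
        return RegionDefinition(name, frozenset((str(c), int(n)) for c, n in spec))
    if not isinstance(spec, dict):
        raise ConfigError(f"region {name!r}: unsupported selector {spec!r}")
    if "bw" in spec:
        nmap = {
            str(k): (str(v[0]), int(v[1]))
            for k, v in (numbering_map or {}).items()
        }
        return RegionDefinition.from_bw(name, [str(p) for p in spec["bw"]], nmap)
    chain = str(spec.get("chain", "A"))
    residues: set[tuple[str, int]] = set()
    for item in spec.get("residues", []):
        if isinstance(item, str) and "-" in item:
            lo, hi = item.split("-", 1)
            residues.update((chain, n) for n in range(int(lo), int(hi) + 1))
        else:
            residues.add((chain, int(item)))
    return RegionDefinition(name, frozenset(residues))
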