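"""Threat taxonomy registry.

The registry binds IUCN-style threat codes (level 1 = threat class, level 2
= threat) to intensity estimates, data-source descriptors and availability
flags.  Two standard subsets exist: the "current" set of 16 threats and the
1990-2020 "timeseries" set of 12 (four threats have no multi-year sources:
tourism/recreation 1.3, mining/quarrying 3.2, roads/railways 4.1 and solid
waste 9.4).

The registry is data-driven: the default ships as YAML
(``hmod/data/registry.yaml``) and user configs may replace or extend it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class IntensitySpec:
    """Unitless land-use intensity weight in [0, 1] with uncertainty bounds.

    ``best`` is the point estimate used for standard runs; ``min``/``max``
    bracket it (nominally +/-10%) and drive the intensity Monte Carlo.
    """

    threat_code: str
    subtype: str
    best: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.min <= self.best <= self.max <= 1.0):
            raise RegistryError(
                f"intensity for {self.threat_code}/{self.subtype}: need "
                f"0 <= min <= best <= max <= 1, got "
                f"({self.min}, {self.best}, {self.max})"
            )


@dataclass(frozen=True)
class ThreatEntry:
    class_code: str
    class_name: str
    threat_code: str
    threat_name: str
    intensities: tuple[IntensitySpec, ...]
    sources: tuple[str, ...] = ()
    in_timeseries: bool = True
    in_current: bool = True

    def intensity(self, subtype: str | None = None) -> IntensitySpec:
        if subtype is None:
            return self.intensities[0]
        for spec in self.intensities:
            if spec.subtype == subtype:
                return spec
        raise RegistryError(
            f"threat {self.threat_code} has no intensity subtype '{subtype}'"
        )


@dataclass
class ThreatRegistry:
    entries: list[ThreatEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [e.threat_code for e in self.entries]
        if len(codes) != len(set(codes)):
            raise RegistryError("duplicate threat codes in registry")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, threat_code: str) -> ThreatEntry:
        for e in self.entries:
            if e.threat_code == threat_code:
                return e
        raise RegistryError(f"threat code '{threat_code}' not registered")

    def intensity(self, threat_code: str, subtype: str | None = None) -> IntensitySpec:
        return self.get(threat_code).intensity(subtype)

    def subset(self, mode: str) -> "ThreatRegistry":
        """Registry restricted to a run mode: 'current' or 'timeseries'."""
        if mode == "current":
            keep = [e for e in self.entries if e.in_current]
        elif mode == "timeseries":
            keep = [e for e in self.entries if e.in_timeseries]
        else:
            raise RegistryError(f"unknown mode '{mode}' (use current|timeseries)")
        return ThreatRegistry(keep)

    def threat_codes(self) -> list[str]:
        return [e.threat_code for e in self.entries]

    def class_codes(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.class_code not in out:
                out.append(e.class_code)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ThreatRegistry":
        entries = []
        for rec in data["threats"]:
            ints = tuple(
                IntensitySpec(
                    threat_code=rec["threat_code"],
                    subtype=i.get("subtype", "default"),
                    best=float(i["best"]),
                    min=float(i["min"]),
                    max=float(i["max"]),
                )
                for i in rec["intensities"]
            )
            entries.append(
                ThreatEntry(
                    class_code=str(rec["class_code"]),
                    class_name=rec["class_name"],
                    threat_code=str(rec["threat_code"]),
                    threat_name=rec["threat_name"],
                    intensities=ints,
                    sources=tuple(rec.get("sources", ())),
                    in_timeseries=bool(rec.get("in_timeseries", True)),
                    in_current=bool(rec.get("in_current", True)),
                )
            )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "ThreatRegistry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "threats": [
                {
                    "class_code": e.class_code,
                    "class_name": e.class_name,
                    "threat_code": e.threat_code,
                    "threat_name": e.threat_name,
                    "intensities": [
                        {"subtype": i.subtype, "best": i.best,
                         "min": i.min, "max": i.max}
                        for i in e.intensities
                    ],
                    "sources": list(e.sources),
                    "in_timeseries": e.in_timeseries,
                    "in_current": e.in_current,
                }
                for e in self.entries
            ]
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_registry() -> ThreatRegistry:
    """The standard 16-threat registry with published intensity values."""
    ref = importlib.resources.files("hmod.data").joinpath("registry.yaml")
    with ref.open() as fh:
        return ThreatRegistry.from_dict(yaml.safe_load(fh))
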