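"""Experiment configuration: one YAML/JSON document, strictly validated.

Schema (all sections optional — defaults reproduce the standard sweep):

.. code-block:: yaml

    rings: [8, 11, 12, 14, 17]
    fraction_psi: 0.5
    thermo:            # overrides for ThermoParams fields
      delta_g_atp: 40000.0
    kinetics:          # overrides for KineticParams fields
      g_atpase: 1500.0
    protocols:
      - name: static_100
        kind: static
        intensity: 100.0
        duration: 3600.0
    output:
      directory: results
      reporting_grid_s: 0.5
      log_level: INFO

Unknown keys anywhere raise :class:`~pmfsim.errors.ConfigError` carrying
the offending dotted key path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import yaml

from .errors import ConfigError, InvalidParameterError, PmfsimError
from .kinetics import KineticParams
from .light import LightProtocol
from .thermo import ThermoParams

__all__ = ["ExperimentSpec", "OutputSpec", "default_figure3_spec",
           "default_figure4_spec"]

DEFAULT_RINGS = (8, 11, 12, 14, 17)

_PROTOCOL_KEYS = {
    "static": {"intensity"},
    "sinusoidal": {"mean", "amplitude", "period"},
    "square_wave": {"low", "high", "period", "duty_fraction"},
}


@dataclass(frozen=True)
class OutputSpec:
    directory: str = "results"
    reporting_grid_s: float = 0.5
    log_level: str = "INFO"


@dataclass
class ExperimentSpec:
    """A validated experiment: rings x protocols with parameter overrides."""

    rings: tuple = DEFAULT_RINGS
    fraction_psi: float = 0.5
    thermo: ThermoParams = field(default_factory=ThermoParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    protocols: tuple = ()          # (name, LightProtocol) pairs
    output: OutputSpec = field(default_factory=OutputSpec)

    def __post_init__(self):
        if not self.rings:
            raise ConfigError("ring list must be non-empty", key_path="rings")
        for c in self.rings:
            if not isinstance(c, int) or c < 1:
                raise ConfigError(f"invalid c-subunit count {c!r}",
                                  key_path="rings")
        if not 0.0 <= self.fraction_psi <= 1.0:
            raise ConfigError("fraction_psi must lie in [0, 1]",
                              key_path="fraction_psi")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentSpec":
        if not isinstance(doc, dict):
            raise ConfigError("configuration document must be a mapping")
        doc = dict(doc)
        known = {"rings", "fraction_psi", "thermo", "kinetics", "protocols",
                 "output"}
        for key in doc:
            if key not in known:
                raise ConfigError("unknown configuration key", key_path=key)

        rings = tuple(doc.get("rings", DEFAULT_RINGS))
        fraction_psi = doc.get("fraction_psi", 0.5)
        thermo = _build_section(ThermoParams, doc.get("thermo", {}), "thermo")
        kin = _build_section(KineticParams, doc.get("kinetics", {}), "kinetics")
        output = _build_section(OutputSpec, doc.get("output", {}), "output")

        protocols = []
        for i, pd_ in enumerate(doc.get("protocols", [])):
            path = f"protocols[{i}]"
            if not isinstance(pd_, dict):
                raise ConfigError("protocol entry must be a mapping", key_path=path)
            kind = pd_.get("kind")
            if kind not in _PROTOCOL_KEYS:
                raise ConfigError(f"unknown protocol kind {kind!r}", key_path=path)
            allowed = _PROTOCOL_KEYS[kind] | {"kind", "duration", "name"}
            for key in pd_:
                if key not in allowed:
                    raise ConfigError("unknown protocol key",
                                      key_path=f"{path}.{key}")
            missing = (_PROTOCOL_KEYS[kind] | {"duration"}) - set(pd_)
            if missing:
                raise ConfigError(f"missing protocol keys {sorted(missing)}",
                                  key_path=path)
            name = pd_.get("name", f"{kind}_{i}")
            try:
                protocols.append((name, LightProtocol.from_dict(pd_)))
            except (InvalidParameterError, KeyError) as exc:
                raise ConfigError(str(exc), key_path=path) from exc

        return cls(rings=rings, fraction_psi=fraction_psi, thermo=thermo,
                   kinetics=kin, protocols=tuple(protocols), output=output)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc or {})

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rings": list(self.rings),
            "fraction_psi": self.fraction_psi,
            "thermo": {f.name: getattr(self.thermo, f.name)
                       for f in dc_fields(self.thermo)},
            "kinetics": {f.name: getattr(self.kinetics, f.name)
                         for f in dc_fields(self.kinetics)},
            "protocols": [{"name": name, **proto.to_dict()}
                          for name, proto in self.protocols],
            "output": {f.name: getattr(self.output, f.name)
                       for f in dc_fields(self.output)},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _build_section(cls, overrides: dict, section: str):
    if not isinstance(overrides, dict):
        raise ConfigError(f"section '{section}' must be a mapping",
                          key_path=section)
    valid = {f.name for f in dc_fields(cls)}
    for key in overrides:
        if key not in valid:
            raise ConfigError("unknown configuration key",
                              key_path=f"{section}.{key}")
    try:
        return cls(**overrides)
    except PmfsimError as exc:
        raise ConfigError(str(exc), key_path=section) from exc


# ---------------------------------------------------------------------------
# canned experiment fixtures
# ---------------------------------------------------------------------------

def default_figure3_spec(duration: float = 600.0) -> ExperimentSpec:
    """Ten minutes of static light at 20 / 100 / 1000 umol photons m-2 s-1."""
    doc = {
        "protocols": [
            {"name": f"static_{int(i)}", "kind": "static",
             "intensity": float(i), "duration": duration}
            for i in (20.0, 100.0, 1000.0)
        ],
    }
    return ExperimentSpec.from_dict(doc)


def default_figure4_spec(duration: float = 3600.0, mean: float = 100.0,
                         period: float = 600.0) -> ExperimentSpec:
    """One hour of static / sinusoidal / square-wave light at equal dose.

    The modulation period and depth are free choices (full-depth modulation
    around the mean); all three protocols integrate to the same photon dose
    when ``duration`` is a whole number of periods.
    """
    doc = {
        "protocols": [
            {"name": "static", "kind": "static", "intensity": mean,
             "duration": duration},
            {"name": "sinusoidal", "kind": "sinusoidal", "mean": mean,
             "amplitude": mean, "period": period, "duration": duration},
            {"name": "square_wave", "kind": "square_wave", "low": 0.0,
             "high": 2.0 * mean, "period": period, "duty_fraction": 0.5,
             "duration": duration},
        ],
    }
    return ExperimentSpec.from_dict(doc)
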