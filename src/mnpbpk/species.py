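"""Reference parameter sets for adult rat, rhesus monkey and adult human.

Physiological parameters (masses, flows, ventilation) come from standard
compendia values; the human set follows the stated Monte Carlo means
(70 kg body weight; blood 8%, bone 12%, brain 2%, liver 3%, lung 1% of body
weight; cardiac output 13 and ventilation 20 L/h/kg).  Kinetic constants
(binding, diffusional fluxes, dietary uptake, biliary clearance) are not
taken from any table — they are calibrated with :mod:`mnpbpk.calibrate`
against steady-state and inhalation time-course anchors and shipped as
versioned YAML files under ``mnpbpk/data`` with per-parameter provenance.

Cross-species rules: biliary clearance and target-region diffusional fluxes
scale allometrically with body weight (exponent 0.75), and within a species
total binding capacity scales with tissue volume.  Binding kinetics and
capacities themselves are calibrated per species — the anchor data demand
different proximity to binding-site saturation in monkey and human (see
``docs/methods.md``).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

from .core import ModelSpec, PbpkParams, TissueParams
from .fluxes import BiliaryParams, DepositionParams, ExposureSchedule, GutParams

SUPPORTED_SPECIES = ("rat", "monkey", "human")


def allometric_scale(value_ref: float, bw_ref: float, bw: float,
                     exponent: float = 0.75) -> float:
    """Scale a clearance/flux from a reference body weight: v·(bw/bw_ref)^e."""
    if bw_ref <= 0 or bw <= 0:
        raise ValueError("body weights must be > 0")
    return value_ref * (bw / bw_ref) ** exponent


def scale_binding_capacity(b_max_ref: float, mass_ref: float, mass: float) -> float:
    """Total binding capacity (μg) at a new tissue mass, per-gram b_max kept."""
    if mass_ref <= 0 or mass <= 0:
        raise ValueError("tissue masses must be > 0")
    return b_max_ref * mass


@dataclass
class SpeciesParameterSet(PbpkParams):
    """Complete, internally consistent parameter set for one species."""

    species: str = ""
    body_weight: float = 0.0          # kg
    target_tissue: str = ""           # brain region used for dose metrics
    default_diet: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    # -- defaults -----------------------------------------------------------

    def default_schedule(self, air_conc: float = 0.0, hours_per_day: float = 0.0,
                         days_per_week: int = 7, duration_days: float = 0.0,
                         ) -> ExposureSchedule:
        """Schedule with this species' default diet filled in."""
        return ExposureSchedule(air_conc=air_conc, hours_per_day=hours_per_day,
                                days_per_week=days_per_week,
                                duration_days=duration_days, **self.default_diet)

    # -- parameter paths ----------------------------------------------------
    #
    # Dotted paths address any scalar parameter, e.g. "gut.k_abs",
    # "bile.k_bile_c", "model.q_p", "dep.f_pulm",
    # "tissue.globus_pallidus.k_in".

    def get(self, path: str) -> float:
        obj, attr = self._resolve(path)
        return getattr(obj, attr)

    def set(self, path: str, value: float) -> None:
        value = float(value)   # numpy scalars break YAML serialization
        obj, attr = self._resolve(path)
        if dataclasses.is_dataclass(obj) and getattr(type(obj), "__dataclass_params__").frozen:
            # frozen flux dataclasses: rebuild and reattach
            new = dataclasses.replace(obj, **{attr: value})
            head = path.split(".")[0]
            setattr(self, head, new)
        else:
            setattr(obj, attr, value)

    def _resolve(self, path: str):
        parts = path.split(".")
        try:
            if parts[0] == "tissue":
                obj: Any = self.model[parts[1]]
                attr = parts[2]
            elif parts[0] in ("model", "dep", "gut", "bile"):
                obj = getattr(self, parts[0])
                attr = parts[1]
            elif len(parts) == 1:
                obj, attr = self, parts[0]
            else:
                raise KeyError(path)
            if not hasattr(obj, attr):
                raise KeyError(path)
        except (KeyError, IndexError):
            raise KeyError(f"unknown parameter path {path!r}")
        return obj, attr

    def copy(self) -> "SpeciesParameterSet":
        return copy.deepcopy(self)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "body_weight": self.body_weight,
            "target_tissue": self.target_tissue,
            "default_diet": dict(self.default_diet),
            "model": {
                "q_c": self.model.q_c,
                "q_p": self.model.q_p,
                "oral": self.model.oral,
                "inhalation": self.model.inhalation,
                "compartments": [dataclasses.asdict(c) for c in self.model.compartments],
            },
            "dep": dataclasses.asdict(self.dep),
            "gut": dataclasses.asdict(self.gut),
            "bile": dataclasses.asdict(self.bile),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesParameterSet":
        m = d["model"]
        model = ModelSpec(
            species=d["species"],
            compartments=[TissueParams(**c) for c in m["compartments"]],
            q_c=m["q_c"], q_p=m["q_p"],
            oral=m.get("oral", True), inhalation=m.get("inhalation", True),
        )
        return cls(
            model=model,
            dep=DepositionParams(**d["dep"]),
            gut=GutParams(**d["gut"]),
            bile=BiliaryParams(**d["bile"]),
            species=d["species"],
            body_weight=d["body_weight"],
            target_tissue=d["target_tissue"],
            default_diet=dict(d.get("default_diet", {})),
            provenance=dict(d.get("provenance", {})),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SpeciesParameterSet":
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text) as fh:
                    text = fh.read()
        return cls.from_dict(yaml.safe_load(text))


def load_species_defaults(species: str) -> SpeciesParameterSet:
    """Load the shipped calibrated parameter set for one species."""
    if species not in SUPPORTED_SPECIES:
        raise ValueError(
            f"unknown species {species!r}; supported: {list(SUPPORTED_SPECIES)}")
    text = resources.files("mnpbpk.data").joinpath(f"{species}.yaml").read_text()
    params = SpeciesParameterSet.from_yaml(text)
    if params.model.residual_flow < -1e-9:
        raise ValueError(f"{species}: residual blood flow is negative")
    rest = params.model["rest_of_body"]
    if rest.mass <= 0:
        raise ValueError(f"{species}: residual tissue mass is not positive")
    return params
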