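"""Named parameter sets and modifiers.

Presets ship as YAML files in the package data directory: the standard
30 C set and the optimized set (larger second sub-stroke, doubled
attachment prefactor) at four temperatures.  Modifiers encode drug
mechanisms (amrinone, blebbistatin, omecamtiv mecarbil) and solution
changes ([MgATP]) as sparse field overrides; scan helpers build parameter
grids for sensitivity analyses of the sub-stroke geometry and the
power-stroke free-energy split.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping

import yaml

from .parameters import ModelParameters, ParameterError

__all__ = [
    "PresetModifier",
    "available_presets",
    "available_modifiers",
    "load_preset",
    "load_modifier",
    "apply_modifier",
    "set_x2",
    "set_dG_split",
    "set_kon",
    "scan_grid",
    "amrinone_counterpart",
]

_DATA = importlib.resources.files("xbridge") / "data"


@dataclass(frozen=True)
class PresetModifier:
    """A named set of parameter-field overrides."""

    name: str
    overrides: Mapping[str, float]

    def __post_init__(self) -> None:
        valid = set(ModelParameters().to_dict())
        unknown = set(self.overrides) - valid
        if unknown:
            raise ParameterError(
                f"modifier {self.name!r} overrides unknown field(s): {sorted(unknown)}"
            )


def available_presets() -> list[str]:
    """Names of the parameter sets shipped with the package."""
    folder = _DATA / "presets"
    return sorted(f.name[: -len(".yaml")] for f in folder.iterdir()
                  if f.name.endswith(".yaml"))


def load_preset(name: str) -> ModelParameters:
    """Load a shipped parameter set by name."""
    path = _DATA / "presets" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    return ModelParameters.from_dict(yaml.safe_load(text))


def _modifier_table() -> dict[str, dict[str, float]]:
    return yaml.safe_load((_DATA / "modifiers.yaml").read_text())


def available_modifiers() -> list[str]:
    """Names of the shipped modifiers."""
    return sorted(_modifier_table())


def load_modifier(name: str) -> PresetModifier:
    table = _modifier_table()
    try:
        return PresetModifier(name, table[name])
    except KeyError:
        raise KeyError(
            f"unknown modifier {name!r}; available: {available_modifiers()}"
        ) from None


def apply_modifier(p: ModelParameters,
                   m: PresetModifier | str) -> ModelParameters:
    """Return a new parameter set with the modifier's overrides applied."""
    if isinstance(m, str):
        m = load_modifier(m)
    return p.replace(**dict(m.overrides))


# ---------------------------------------------------------------------------
# scan helpers
# ---------------------------------------------------------------------------

def set_x2(value: float) -> PresetModifier:
    """Modifier moving the AMD_H minimum (second sub-stroke d2 = x2 - x3)."""
    return PresetModifier(f"set_x2({value})", {"x2": float(value)})


def set_dG_split(dG_LH: float, dG_HD: float) -> PresetModifier:
    """Modifier fixing the power-stroke free-energy split (kBT)."""
    return PresetModifier(
        f"set_dG_split({dG_LH},{dG_HD})",
        {"dG_LH": float(dG_LH), "dG_HD": float(dG_HD)},
    )


def set_kon(value: float) -> PresetModifier:
    """Modifier setting the attachment prefactor kon' (s^-1)."""
    return PresetModifier(f"set_kon({value})", {"kon_prime": float(value)})


def amrinone_counterpart(p: ModelParameters) -> ModelParameters:
    """Amrinone version of an arbitrary set: dG_AMDH-AMD reduced to 25%."""
    return p.replace(dG_HD=0.25 * p.dG_HD)


def scan_grid(base: ModelParameters, field: str,
              values: Iterable[float]) -> list[ModelParameters]:
    """One parameter set per value of ``field``.

    Raises
    ------
    ParameterError
        If any value violates the parameter invariants; the message carries
        the offending index.
    """
    out = []
    for i, v in enumerate(values):
        try:
            out.append(base.replace(**{field: float(v)}))
        except ParameterError as exc:
            raise ParameterError(f"scan value #{i} ({field}={v}): {exc}") from exc
    return out
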