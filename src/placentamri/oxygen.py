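"""Oxygen delivery, consumption and extraction from flow, SO2 and Hb.

Fetal oxygen delivery is carried by the umbilical vein; consumption is
the arteriovenous difference across the fetal body; uterine-artery
delivery is the maternal supply side::

    fetal DO2  = k * Hb * Y_UV * Q_UV
    fetal VO2  = k * Hb * (Y_UV - Y_DAo) * Q_UV
    UtA   DO2  = k * Hb_maternal * Y_UtA * Q_UtA

with k = 1.36 mL O2 bound per gram of haemoglobin at one atmosphere.
Units are fixed as Hb in g/L, flow in mL/min, DO2/VO2 in mL O2/min (the
g/L -> g/mL conversion is handled internally).  Dissolved oxygen is
neglected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "HaemodynamicRecord",
    "OxygenTransportConstants",
    "fetal_do2",
    "fetal_vo2",
    "uta_do2",
    "oxygen_extraction_fraction",
    "uta_do2_fraction_of_available",
]

STATES = ("basal", "TAD1", "TAD2")


@dataclass(frozen=True)
class OxygenTransportConstants:
    """k_o2: oxygen-binding capacity of haemoglobin, mL O2 per g Hb."""

    k_o2: float = 1.36

    def __post_init__(self) -> None:
        if not self.k_o2 > 0:
            raise ValueError("k_o2 must be positive")


@dataclass
class HaemodynamicRecord:
    """One animal x one state: the row the transport equations consume.

    ``hb_fetal``/``hb_maternal`` in g/L; saturations as fractions in
    [0, 1]; flows in mL/min.  Fields not needed by a given equation may
    be None; using them raises an error naming the missing field.
    """

    animal_id: str
    state: str
    hb_fetal: float | None = None
    hb_maternal: float | None = None
    y_uv: float | None = None
    y_dao: float | None = None
    y_uta: float | None = None
    q_uv: float | None = None
    q_uta: float | None = None
    lvco: float | None = None
    maternal_weight: float | None = None
    y_arterial: float | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state {self.state!r} not in {STATES}")
        for name in ("hb_fetal", "hb_maternal"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ValueError(f"{name}={val!r} must be positive")
        for name in ("y_uv", "y_dao", "y_uta", "y_arterial"):
            val = getattr(self, name)
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val!r} must lie in [0, 1]")
        for name in ("q_uv", "q_uta", "lvco"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"{name}={val!r} must be >= 0")
        if (
            self.y_uv is not None
            and self.y_dao is not None
            and self.y_dao > self.y_uv
        ):
            warnings.warn(
                f"record {self.animal_id}/{self.state}: Y_DAo={self.y_dao} "
                f"> Y_UV={self.y_uv}; arterial saturation above umbilical "
                "venous is physiologically unexpected",
                stacklevel=2,
            )

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ValueError(f"record field {name!r} is missing")


def fetal_do2(rec: HaemodynamicRecord,
              k: OxygenTransportConstants = OxygenTransportConstants()) -> float:
    """Fetal oxygen delivery via the umbilical vein, mL O2/min."""
    rec.require("hb_fetal", "y_uv", "q_uv")
    return k.k_o2 * (rec.hb_fetal / 1000.0) * rec.y_uv * rec.q_uv


def fetal_vo2(rec: HaemodynamicRecord,
              k: OxygenTransportConstants = OxygenTransportConstants()) -> float:
    """Fetal oxygen consumption (umbilical venous-arterial difference), mL O2/min.

    May be negative when the flagged Y_DAo > Y_UV invariant is violated;
    the value is still returned (the warning fires at record creation).
    """
    rec.require("hb_fetal", "y_uv", "y_dao", "q_uv")
    return k.k_o2 * (rec.hb_fetal / 1000.0) * (rec.y_uv - rec.y_dao) * rec.q_uv


def uta_do2(rec: HaemodynamicRecord,
            k: OxygenTransportConstants = OxygenTransportConstants()) -> float:
    """Uterine artery oxygen delivery, mL O2/min (maternal Hb)."""
    rec.require("hb_maternal", "y_uta", "q_uta")
    return k.k_o2 * (rec.hb_maternal / 1000.0) * rec.y_uta * rec.q_uta


def oxygen_extraction_fraction(rec: HaemodynamicRecord) -> float:
    """Fetal oxygen extraction fraction (Y_UV - Y_DAo) / Y_UV = VO2/DO2.

    Independent of Hb and flow by construction.
    """
    rec.require("y_uv", "y_dao")
    if rec.y_uv == 0:
        raise ValueError("Y_UV is zero: extraction fraction undefined")
    return (rec.y_uv - rec.y_dao) / rec.y_uv


def uta_do2_fraction_of_available(
    rec: HaemodynamicRecord,
    k: OxygenTransportConstants = OxygenTransportConstants(),
) -> float:
    """Uterine-artery DO2 as a percentage of total available maternal DO2.

    Available DO2 is carried by the whole cardiac output at the maternal
    arterial saturation: k * Hb * Y_arterial * LVCO.
    """
    rec.require("hb_maternal", "y_uta", "q_uta", "lvco", "y_arterial")
    if not rec.lvco > 0:
        raise ValueError("LVCO must be positive")
    if not rec.y_arterial > 0:
        raise ValueError("Y_arterial must be positive")
    available = k.k_o2 * (rec.hb_maternal / 1000.0) * rec.y_arterial * rec.lvco
    return 100.0 * uta_do2(rec, k) / available
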