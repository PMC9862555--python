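"""Channel-role mapping between instrument dialects and the logical roles
used by the analysis.

The analysis never addresses instrument channel names directly; every
operation asks for a *role* (``FSC-A``, ``FVS510``, ``TCPP`` ...) and the
:class:`ChannelMap` resolves it for the tube at hand.  Two instrument
dialects ship built in (BD LSRII and Beckman Coulter Navios EX); any other
instrument needs a user-supplied map.

The blood and epithelial assay tubes use the same physical detectors for
different antibodies (the lineage pool and Pan-CK share a detector, CD206
and EpCAM share another), so the map is built per tube kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable

__all__ = [
    "ChannelMap",
    "ChannelMapError",
    "channel_map",
    "SCATTER_ROLES",
    "FLUOR_ROLES_BLOOD",
    "FLUOR_ROLES_EPITHELIAL",
]

SCATTER_ROLES = ("FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H")
FLUOR_ROLES_BLOOD = ("FVS510", "CD45", "TCPP", "LINEAGE", "CD206")
FLUOR_ROLES_EPITHELIAL = ("FVS510", "CD45", "TCPP", "PANCK", "EPCAM")


class ChannelMapError(ValueError):
    """A role cannot be resolved, or a map is internally inconsistent."""


# Physical detector names per dialect.  The five fluorescence detectors are
# listed in a fixed order; role assignment per tube kind reuses detectors the
# way the staining panel does (lineage pool / Pan-CK on the FITC detector,
# CD206 / EpCAM on the PE-CF594 detector).
_DIALECTS = {
    "lsrii": {
        "scatter": {
            "FSC-A": "FSC-A",
            "FSC-H": "FSC-H",
            "FSC-W": "FSC-W",
            "SSC-A": "SSC-A",
            "SSC-H": "SSC-H",
        },
        "detectors": ["FITC-A", "PE-A", "PE-CF594-A", "BV510-A", "PerCP-Cy5-5-A"],
        "time": "Time",
    },
    "navios": {
        "scatter": {
            "FSC-A": "FS-INT",
            "FSC-H": "FS-PEAK",
            "FSC-W": "FS-W",
            "SSC-A": "SS-INT",
            "SSC-H": "SS-PEAK",
        },
        "detectors": ["FL1-A", "FL2-A", "FL3-A", "FL4-A", "FL5-A"],
        "time": "TIME",
    },
}

# role -> detector slot (index into the dialect's detector list)
_DETECTOR_SLOTS = {
    "LINEAGE": 0,
    "PANCK": 0,
    "CD45": 1,
    "CD206": 2,
    "EPCAM": 2,
    "FVS510": 3,
    "TCPP": 4,
}


@dataclass
class ChannelMap:
    """Mapping from logical roles to instrument channel names."""

    roles: Dict[str, str] = field(default_factory=dict)

    def resolve(self, role: str) -> str:
        try:
            return self.roles[role]
        except KeyError:
            raise ChannelMapError(f"role {role!r} is not mapped") from None

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    def fluor_roles(self) -> tuple:
        return tuple(r for r in self.roles if r not in SCATTER_ROLES and r != "TIME")

    def validate(self, required: Iterable[str]) -> None:
        missing = [r for r in required if r not in self.roles]
        if missing:
            raise ChannelMapError(f"unmapped required roles: {missing}")

    @classmethod
    def from_dict(cls, d: Dict[str, str]) -> "ChannelMap":
        return cls(roles=dict(d))


def channel_map(dialect: str = "lsrii", tube: str = "blood") -> ChannelMap:
    """Build a :class:`ChannelMap` for one of the built-in dialects.

    Parameters
    ----------
    dialect : {"lsrii", "navios"}
    tube : {"blood", "epithelial", "control"}
        ``control`` maps all five detectors plus scatter and Time but no
        antibody roles beyond the shared ones; used for bead, unstained,
        isotype and compensation tubes.
    """
    key = dialect.lower()
    if key not in _DIALECTS:
        raise ChannelMapError(
            f"unknown instrument dialect {dialect!r}; supply an explicit map"
        )
    spec = _DIALECTS[key]
    roles: Dict[str, str] = dict(spec["scatter"])
    roles["TIME"] = spec["time"]
    if tube == "blood":
        fluor = FLUOR_ROLES_BLOOD
    elif tube == "epithelial":
        fluor = FLUOR_ROLES_EPITHELIAL
    elif tube == "control":
        fluor = ("FVS510", "CD45", "TCPP", "LINEAGE", "CD206")
    else:
        raise ChannelMapError(f"unknown tube kind {tube!r}")
    for role in fluor:
        roles[role] = spec["detectors"][_DETECTOR_SLOTS[role]]
    # sanity: each role resolves to exactly one channel
    return ChannelMap(roles=roles)


def detector_names(dialect: str = "lsrii") -> list:
    """The five fluorescence detector channel names of a dialect, in order."""
    return list(_DIALECTS[dialect.lower()]["detectors"])
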