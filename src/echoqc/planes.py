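"""Standard-plane registry and scan protocol.

The toolkit works with the eight standard planes of the 18--22 week fetal
echocardiography screening exam plus a ``NonHeart`` label for everything
else in a scan video.  Each plane is defined by a set of anatomical
features; a subset of those are the plane's *minimum required* features --
the landmarks whose visibility defines plane attainment.  28 features are
distributed over the eight planes.

The clinical identities of the features and the per-plane required subsets
are configuration, not code: :func:`default_protocol` ships a sensible
default registry and :meth:`PlaneProtocol.from_yaml` loads a corrected one
without code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import yaml

#: Canonical ordering of the eight standard planes.  Used for deterministic
#: tie-breaking and report ordering.
STANDARD_PLANES: Tuple[str, ...] = (
    "Situs", "4CV", "VSV", "RVOT", "LVOT", "3VV", "3VT", "Arch",
)

NONHEART = "NonHeart"

ALL_PLANES: Tuple[str, ...] = STANDARD_PLANES + (NONHEART,)

#: Default assignment of the 28 anatomical features to the eight planes.
#: Keys are plane names; values are globally unique feature identifiers.
DEFAULT_FEATURES: Dict[str, Tuple[str, ...]] = {
    "Situs": ("stomach", "situs_desc_aorta", "situs_spine"),
    "4CV": ("left_ventricle", "right_ventricle", "left_atrium",
            "right_atrium", "septal_crux"),
    "VSV": ("ventricular_septum", "vsv_lv_wall", "vsv_rv_wall"),
    "RVOT": ("rvot_pulmonary_artery", "rvot_infundibulum", "pulmonary_valve"),
    "LVOT": ("lvot_aortic_root", "lvot_outflow", "aortic_valve"),
    "3VV": ("threevv_pulmonary_trunk", "threevv_asc_aorta", "threevv_svc",
            "threevv_spine"),
    "3VT": ("threevt_ductal_arch", "threevt_aortic_arch", "threevt_svc",
            "trachea"),
    "Arch": ("aortic_arch", "head_neck_vessels", "arch_desc_aorta"),
}

#: Default minimum required features per plane (all of them, in the default
#: registry -- a stricter real protocol can drop optional ones via YAML).
DEFAULT_REQUIRED: Dict[str, Tuple[str, ...]] = {
    plane: feats for plane, feats in DEFAULT_FEATURES.items()
}

#: Planes a screening protocol does not insist on.  The sagittal aortic
#: arch is commonly captured opportunistically rather than required.
DEFAULT_NON_MANDATORY: Tuple[str, ...] = ("Arch",)


@dataclass(frozen=True)
class PlaneRequirement:
    """Required feature set and mandatory flag for one standard plane."""

    required: Tuple[str, ...]
    mandatory: bool = True


@dataclass
class PlaneProtocol:
    """Per-plane minimum required features and mandatory/non-mandatory flags.

    Invariants: all eight standard planes are present and every heart plane
    has a non-empty required set.
    """

    planes: Dict[str, PlaneRequirement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [p for p in STANDARD_PLANES if p not in self.planes]
        if missing:
            raise ValueError(f"protocol missing standard planes: {missing}")
        for plane, req in self.planes.items():
            if plane not in STANDARD_PLANES:
                raise ValueError(f"unknown plane {plane!r}")
            if not req.required:
                raise ValueError(f"plane {plane!r} has an empty required set")

    def required(self, plane: str) -> Tuple[str, ...]:
        return self.planes[plane].required

    def is_mandatory(self, plane: str) -> bool:
        return self.planes[plane].mandatory

    @property
    def mandatory_planes(self) -> Tuple[str, ...]:
        return tuple(p for p in STANDARD_PLANES if self.planes[p].mandatory)

    @property
    def feature_names(self) -> Tuple[str, ...]:
        """All feature names, in plane order then registry order."""
        names = []
        for plane in STANDARD_PLANES:
            names.extend(self.planes[plane].required)
        return tuple(dict.fromkeys(names))

    def plane_of_feature(self, name: str) -> str:
        for plane in STANDARD_PLANES:
            if name in self.planes[plane].required:
                return plane
        raise KeyError(name)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> Dict[str, dict]:
        return {
            plane: {"required": list(req.required), "mandatory": req.mandatory}
            for plane, req in self.planes.items()
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping]) -> "PlaneProtocol":
        planes = {
            plane: PlaneRequirement(
                required=tuple(entry["required"]),
                mandatory=bool(entry.get("mandatory", True)),
            )
            for plane, entry in data.items()
        }
        return cls(planes=planes)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PlaneProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_protocol(
    non_mandatory: Iterable[str] = DEFAULT_NON_MANDATORY,
) -> PlaneProtocol:
    """Protocol over the default 28-feature registry (Arch non-mandatory)."""
    non_mandatory = set(non_mandatory)
    return PlaneProtocol(
        planes={
            plane: PlaneRequirement(
                required=DEFAULT_REQUIRED[plane],
                mandatory=plane not in non_mandatory,
            )
            for plane in STANDARD_PLANES
        }
    )
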