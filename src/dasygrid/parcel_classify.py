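"""Residential parcel selection and small/large size classification.

The polygon-binary method treats parcels as populated/unpopulated with no
per-class density weights, so the only classification decisions are (a) is a
land-use class residential at all, and (b) is the parcel "small" enough that
its whole boundary can stand in for populated area, or "large" so that only
the building footprints inside it should count.  The small/large cut is an
area threshold: one acre (~4050 m2) for ordinary residential classes, ten
acres (~40,500 m2) for five high-density apartment classes whose parcels
legitimately cover a whole city block.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SMALL",
    "LARGE",
    "NONRESIDENTIAL",
    "HIGH_DENSITY_CLASSES",
    "DEFAULT_RESIDENTIAL_CLASSES",
    "ClassifierConfig",
    "is_residential",
    "size_class",
    "classify_area",
]

SMALL = "SMALL"
LARGE = "LARGE"
NONRESIDENTIAL = "NONRESIDENTIAL"

#: Apartment-style classes allowed to use the 10-acre "small" cutoff.
HIGH_DENSITY_CLASSES = frozenset(
    {
        "APARTMENT HOUSE (100+ UNITS)",
        "APARTMENT HOUSE (5+ UNITS)",
        "APARTMENTS (GENERIC)",
        "COOPERATIVE (RESIDENTIAL)",
        "HIGHRISE APARTMENTS",
    }
)

#: Residential classes named in the method description.  The full assessor
#: code list is jurisdiction-specific, so this set is a user-editable default,
#: not an authority.
DEFAULT_RESIDENTIAL_CLASSES = frozenset(
    {
        "SINGLE FAMILY RESIDENTIAL",
        "CONDOMINIUM (RESIDENTIAL)",
        "RURAL RESIDENCE (AGRICULTURAL)",
    }
    | HIGH_DENSITY_CLASSES
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Residential land-use list plus the two size thresholds (m2)."""

    residential_classes: frozenset[str] = DEFAULT_RESIDENTIAL_CLASSES
    high_density_classes: frozenset[str] = HIGH_DENSITY_CLASSES
    small_threshold_m2: float = 4050.0
    high_density_threshold_m2: float = 40500.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residential_classes", frozenset(self.residential_classes)
        )
        object.__setattr__(
            self, "high_density_classes", frozenset(self.high_density_classes)
        )
        if not self.high_density_classes <= self.residential_classes:
            raise ValueError(
                "high_density_classes must be a subset of residential_classes"
            )
        if self.small_threshold_m2 <= 0 or self.high_density_threshold_m2 <= 0:
            raise ValueError("size thresholds must be positive")
        if self.high_density_threshold_m2 < self.small_threshold_m2:
            raise ValueError(
                "high_density_threshold_m2 must be >= small_threshold_m2"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ClassifierConfig":
        """Build from a YAML/JSON ``classifier:`` mapping; missing keys default."""
        kwargs = {}
        if "residential_classes" in mapping:
            kwargs["residential_classes"] = frozenset(mapping["residential_classes"])
        if "high_density_classes" in mapping:
            kwargs["high_density_classes"] = frozenset(mapping["high_density_classes"])
        for key in ("small_threshold_m2", "high_density_threshold_m2"):
            if key in mapping:
                kwargs[key] = float(mapping[key])
        return cls(**kwargs)

    def to_mapping(self) -> dict:
        return {
            "residential_classes": sorted(self.residential_classes),
            "high_density_classes": sorted(self.high_density_classes),
            "small_threshold_m2": self.small_threshold_m2,
            "high_density_threshold_m2": self.high_density_threshold_m2,
        }


def is_residential(landuse_class: str, cfg: ClassifierConfig | None = None) -> bool:
    """Exact, case-sensitive membership test after whitespace trim.

    Fuzzy matching is deliberately not offered: a silently mis-matched label
    would corrupt the populated/unpopulated mask.
    """
    cfg = cfg or ClassifierConfig()
    return landuse_class.strip() in cfg.residential_classes


def classify_area(
    landuse_class: str, area_m2: float, cfg: ClassifierConfig | None = None
) -> str:
    """Classify a (land-use label, area) pair into SMALL/LARGE/NONRESIDENTIAL.

    Thresholds are inclusive: a parcel exactly at the cutoff is still SMALL.
    """
    cfg = cfg or ClassifierConfig()
    label = landuse_class.strip()
    if label not in cfg.residential_classes:
        return NONRESIDENTIAL
    if label in cfg.high_density_classes:
        threshold = cfg.high_density_threshold_m2
    else:
        threshold = cfg.small_threshold_m2
    return SMALL if area_m2 <= threshold else LARGE


def size_class(parcel, cfg: ClassifierConfig | None = None) -> str:
    """Classify a ParcelFeature (anything with landuse_class and area_m2)."""
    return classify_area(parcel.landuse_class, parcel.area_m2, cfg)
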