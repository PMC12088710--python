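"""Ten-class annotation schema for intravascular OCT cross-sections.

Each pixel of a segmentation mask carries one of ten integer codes covering
the vessel anatomy (lumen, intima, media), plaque tissue (lipid, calcium),
acute features (thrombus, plaque rupture) and imaging artefacts (guidewire
shadow, side branch), with background as code 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

BACKGROUND = 0
LUMEN = 1
GUIDEWIRE = 2
SIDE_BRANCH = 3
INTIMA = 4
MEDIA = 5
LIPID = 6
CALCIUM = 7
THROMBUS = 8
PLAQUE_RUPTURE = 9

_DEFAULT_CLASS_IDS: Mapping[str, int] = MappingProxyType(
    {
        "background": BACKGROUND,
        "lumen": LUMEN,
        "guidewire_artefact": GUIDEWIRE,
        "side_branch": SIDE_BRANCH,
        "intima": INTIMA,
        "media": MEDIA,
        "lipid": LIPID,
        "calcium": CALCIUM,
        "thrombus": THROMBUS,
        "plaque_rupture": PLAQUE_RUPTURE,
    }
)


@dataclass(frozen=True)
class LabelSchema:
    """Bijective mapping of the ten annotation classes to integer codes.

    ``plaque_classes`` are the tissue classes quantified by ray casting;
    ``cca_exempt_classes`` are never removed by connected-component
    filtering because even tiny thrombus or rupture predictions are
    clinically meaningful.
    """

    class_ids: Mapping[str, int] = field(default_factory=lambda: _DEFAULT_CLASS_IDS)
    plaque_classes: frozenset[str] = frozenset({"lipid", "calcium"})
    cca_exempt_classes: frozenset[str] = frozenset({"thrombus", "plaque_rupture"})

    def __post_init__(self) -> None:
        codes = sorted(self.class_ids.values())
        if codes != list(range(10)):
            raise ValueError("schema must map exactly 10 classes to codes 0..9")
        unknown = (self.plaque_classes | self.cca_exempt_classes) - set(self.class_ids)
        if unknown:
            raise ValueError(f"unknown class names: {sorted(unknown)}")

    def code(self, name: str) -> int:
        return self.class_ids[name]

    @property
    def cca_exempt_codes(self) -> frozenset[int]:
        return frozenset(self.class_ids[n] for n in self.cca_exempt_classes)

    @property
    def plaque_codes(self) -> frozenset[int]:
        return frozenset(self.class_ids[n] for n in self.plaque_classes)

    def name(self, code: int) -> str:
        for n, c in self.class_ids.items():
            if c == code:
                return n
        raise KeyError(code)


DEFAULT_SCHEMA = LabelSchema()
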