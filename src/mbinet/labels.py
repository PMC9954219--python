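"""The six diagnostic classes of a reconstructed microwave brain image.

NT: no tumor; BT/MT: a single benign / malignant tumor; BBT/MMT: two benign
/ two malignant tumors; BMT: one benign plus one malignant.  The ordinal
order is fixed and is used for confusion-matrix axes and score columns.
"""

from enum import IntEnum

__all__ = ["ClassLabel", "CLASS_NAMES"]


class ClassLabel(IntEnum):
    NT = 0
    BT = 1
    MT = 2
    BBT = 3
    MMT = 4
    BMT = 5

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown class {name!r}; expected one of {[c.name for c in cls]}"
            ) from None


CLASS_NAMES = [c.name for c in ClassLabel]
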