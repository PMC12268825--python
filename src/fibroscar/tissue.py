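"""Tissue class taxonomy for infarcted myocardium.

Histopathology distinguishes four tissue types along the fibrotic scarring
trajectory: healthy muscle, necrotic, granulated, and fibrotic tissue. For
binary image classification the three diseased types are pooled into a
single ``pathologic`` group.
"""

from __future__ import annotations

import enum


class TissueClass(str, enum.Enum):
    """One of the four histopathologic tissue types.

    The canonical class order used throughout the package (PLS-DA indicator
    columns, confusion matrices, generator parameter tables) is
    muscle → necrotic → granulated → fibrotic, i.e. increasing degree of
    fibrotic remodelling.
    """

    HEALTHY = "healthy"
    NECROTIC = "necrotic"
    GRANULATED = "granulated"
    FIBROTIC = "fibrotic"

    @property
    def binary_label(self) -> str:
        """Binary grouping: ``healthy`` or ``pathologic``."""
        return "healthy" if self is TissueClass.HEALTHY else "pathologic"

    @property
    def is_pathologic(self) -> bool:
        return self is not TissueClass.HEALTHY


#: canonical order: muscle(=healthy), necrotic, granulated, fibrotic
CLASS_ORDER: tuple[TissueClass, ...] = (
    TissueClass.HEALTHY,
    TissueClass.NECROTIC,
    TissueClass.GRANULATED,
    TissueClass.FIBROTIC,
)

CLASS_NAMES: tuple[str, ...] = tuple(c.value for c in CLASS_ORDER)

BINARY_POSITIVE = "pathologic"
BINARY_NEGATIVE = "healthy"


def as_tissue_class(value: "TissueClass | str") -> TissueClass:
    """Coerce a string or enum member to :class:`TissueClass`.

    ``muscle`` is accepted as an alias for ``healthy``.
    """
    if isinstance(value, TissueClass):
        return value
    v = str(value).strip().lower()
    if v == "muscle":
        return TissueClass.HEALTHY
    try:
        return TissueClass(v)
    except ValueError as exc:
        raise ValueError(f"unknown tissue class {value!r}") from exc
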