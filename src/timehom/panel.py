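"""Marker panel shared by the IHC and RNA-seq representations.

All feature vectors in the pipeline are positional over this panel, so the
panel fixes a single canonical ordering: the eight immunohistochemistry
markers followed (optionally) by the tertiary-lymphoid-structure count as a
ninth feature.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_MARKERS: tuple[str, ...] = (
    "CD4",
    "CD8",
    "Foxp3",
    "CD20",
    "CD68",
    "LAMP3",
    "PD-1",
    "PD-L1",
)

TLS_FEATURE = "TLS"


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered immune feature set.

    Parameters
    ----------
    markers
        Ordered, unique marker names quantified by IHC (positive index,
        ordinal score, cell density per mm^2).
    include_tls
        Whether the TLS count per section is carried as an extra feature
        after the markers (the nine-feature vector used by the similarity
        analysis).
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    include_tls: bool = True

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValueError("marker panel must contain at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if TLS_FEATURE in self.markers:
            raise ValueError(
                f"{TLS_FEATURE!r} is reserved for the TLS feature; "
                "set include_tls=True instead"
            )

    @property
    def features(self) -> tuple[str, ...]:
        """Markers plus the TLS feature when enabled (positional order)."""
        if self.include_tls:
            return self.markers + (TLS_FEATURE,)
        return self.markers

    @property
    def n_features(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)


DEFAULT_PANEL = MarkerPanel()
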