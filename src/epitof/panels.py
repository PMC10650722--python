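"""Marker panel metadata.

A panel separates the histone post-translational-modification (HPTM)
channels that carry biological signal from the total-histone channels
(H3, H4) that are used purely as regressors during normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

PANEL_NAMES = ("methylation", "acetylation_phospho_ubiq", "custom")

DEFAULT_REGRESSORS = ("H3", "H4")


class SchemaError(ValueError):
    """A table or panel violates the expected schema."""


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered set of HPTM markers plus the total-histone regressor channels.

    Parameters
    ----------
    hptm_markers : ordered marker names measured as histone marks.
    regressor_markers : total-histone channels regressed out during
        normalization (default ``("H3", "H4")``).
    panel_name : one of ``methylation``, ``acetylation_phospho_ubiq``,
        ``custom``.
    """

    hptm_markers: tuple[str, ...]
    regressor_markers: tuple[str, ...] = DEFAULT_REGRESSORS
    panel_name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hptm_markers", tuple(self.hptm_markers))
        object.__setattr__(self, "regressor_markers", tuple(self.regressor_markers))
        if self.panel_name not in PANEL_NAMES:
            raise SchemaError(
                f"panel_name must be one of {PANEL_NAMES}, got {self.panel_name!r}"
            )
        overlap = set(self.hptm_markers) & set(self.regressor_markers)
        if overlap:
            raise SchemaError(
                f"regressor markers must be disjoint from HPTM markers: {sorted(overlap)}"
            )
        dup = _duplicates(self.hptm_markers + self.regressor_markers)
        if dup:
            raise SchemaError(f"duplicate marker names in panel: {sorted(dup)}")

    @property
    def all_markers(self) -> tuple[str, ...]:
        return self.hptm_markers + self.regressor_markers

    def to_json(self, path: str | Path) -> None:
        payload = {
            "panel_name": self.panel_name,
            "hptm_markers": list(self.hptm_markers),
            "regressor_markers": list(self.regressor_markers),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerPanel":
        payload = json.loads(Path(path).read_text())
        return cls(
            hptm_markers=tuple(payload["hptm_markers"]),
            regressor_markers=tuple(payload.get("regressor_markers", DEFAULT_REGRESSORS)),
            panel_name=payload.get("panel_name", "custom"),
        )


def _duplicates(names) -> set:
    seen, dup = set(), set()
    for n in names:
        if n in seen:
            dup.add(n)
        seen.add(n)
    return dup
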