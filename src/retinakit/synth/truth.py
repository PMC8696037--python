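"""Ground-truth provenance records attached to every generated artifact."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

VALID_KINDS = ("mosaic", "train", "morphology", "section")


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters and seed that produced an artifact."""

    kind: str
    params: Mapping[str, object]
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown ground-truth kind {self.kind!r}")

    def as_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params), "seed": self.seed}
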