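"""Directed gene signatures: up/down gene sets with optional provenance.

A :class:`GeneSignature` is the object that flows between pipeline stages —
from DEG calling, through candidate selection, into all three drug engines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["GeneSignature"]

_PROVENANCE_TAGS = {"seed_candidate", "predicted_candidate"}


@dataclass
class GeneSignature:
    """Up- and down-regulated gene sets.

    ``provenance`` optionally tags each gene as a ``seed_candidate`` or
    ``predicted_candidate``; when present it must cover exactly the genes
    of the signature.  The up and down sets are disjoint by construction.
    """

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"up and down sets overlap: {sorted(overlap)[:5]}")
        if self.provenance:
            bad = set(self.provenance.values()) - _PROVENANCE_TAGS
            if bad:
                raise ValueError(f"unknown provenance tags: {sorted(bad)}")
            missing = self.genes - set(self.provenance)
            extra = set(self.provenance) - self.genes
            if missing or extra:
                raise ValueError(
                    "provenance must tag exactly the signature genes; "
                    f"missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]}"
                )

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def direction(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        raise KeyError(gene)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {"up": sorted(self.up), "down": sorted(self.down)}
        if self.provenance:
            d["provenance"] = dict(sorted(self.provenance.items()))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSignature":
        return cls(
            up=set(d.get("up", ())),
            down=set(d.get("down", ())),
            provenance=dict(d.get("provenance", {})),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneSignature":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_gmt(self, path: str | Path, name: str = "signature") -> None:
        """Write the signature as two GMT lines, ``<name>_up`` and ``<name>_down``."""
        from .io import write_gmt

        write_gmt(path, [(f"{name}_up", sorted(self.up)), (f"{name}_down", sorted(self.down))])
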