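"""Core domain types shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Fixed class order used everywhere: scores, labels, confusion matrices.
CLASSES = ("phage", "chromosome", "plasmid")

CLASS_TO_INDEX = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class DnaFragment:
    """A single DNA sequence with an identifier and optional true class label.

    The sequence is upper-cased on construction; any non-ACGT letter is
    tolerated and treated as ambiguous by the encoders.
    """

    id: str
    seq: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"fragment {self.id!r}: empty sequence")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(
                f"fragment {self.id!r}: label {self.label!r} not in {CLASSES}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ScoreTriple:
    """(phage, chromosome, plasmid) probability vector for one fragment."""

    phage: float
    chromosome: float
    plasmid: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phage, self.chromosome, self.plasmid)

    def argmax_class(self) -> str:
        # ties broken by fixed class order: phage > chromosome > plasmid
        best = max(self.as_tuple())
        for cls, val in zip(CLASSES, self.as_tuple()):
            if val == best:
                return cls
        raise AssertionError("unreachable")

    def max_score(self) -> float:
        return max(self.as_tuple())
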