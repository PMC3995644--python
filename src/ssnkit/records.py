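"""Core value types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)


class InputError(ValueError):
    """Raised when user-supplied data violates an operation's contract."""


class ConfigError(ValueError):
    """Raised when a configuration value is out of range; names the field."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with identifier and optional annotation payload.

    The atomic unit of all networks: every node in a full network, and every
    member behind a representative node, is one of these.
    """

    id: str
    sequence: str
    description: str = ""
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record requires a non-empty identifier")
        if not self.sequence:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - AMINO_ACID_SET
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def check_unique_ids(records) -> None:
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise InputError(f"duplicate sequence identifier: {rec.id!r}")
        seen.add(rec.id)
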