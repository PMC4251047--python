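"""Row-level import accounting shared by every parser and loader.

Every file that enters the system passes through a parser that either
accepts a row (after explicit typing and range/set-membership checks) or
rejects it with a named rule; nothing is silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ImportReport:
    """Bookkeeping for one parsed source.

    Invariant: ``rows_read == rows_accepted + rows_rejected``.
    """

    rows_read: int = 0
    rows_accepted: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejections)

    def accept(self) -> None:
        self.rows_read += 1
        self.rows_accepted += 1

    def reject(self, line_number: int, rule: str) -> None:
        self.rows_read += 1
        self.rejections.append((line_number, rule))

    def note(self, message: str) -> None:
        self.notes.append(message)

    def __repr__(self) -> str:  # pragma: no cover - convenience only
        return (
            f"ImportReport(read={self.rows_read}, accepted={self.rows_accepted}, "
            f"rejected={self.rows_rejected})"
        )
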