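"""IGV batch automation over the viewer's TCP command port.

One call assembles the full context of an experiment — variant calls,
RNA-seq alignments, WES alignments, the transcript assembly — into a
batch command script (``new`` / ``genome`` / ``load`` / ``goto`` /
``snapshot``) and sends it line-by-line to a listening IGV instance, so
a single action loads every track and jumps to the gene of interest.
``goto`` coordinates are rendered 1-based inclusive without thousands
separators for robustness across viewer versions.
"""

from __future__ import annotations

import socket
from dataclasses import dataclass

from .idmap import GenomicLocus, IdGraph

DEFAULT_IGV_PORT = 60151


@dataclass(frozen=True)
class IgvSession:
    """Everything needed to reconstruct one viewing session."""

    genome_id: str
    tracks: tuple[str, ...] = ()
    target: GenomicLocus | None = None
    snapshot_path: str | None = None

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if any(not t for t in self.tracks):
            raise ValueError("track paths must be non-empty strings")


@dataclass(frozen=True)
class IgvCommandScript:
    lines: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lines or self.lines[0] != "new":
            raise ValueError("an IGV script starts with 'new'")
        if any(not line.strip() for line in self.lines):
            raise ValueError("IGV scripts contain no empty lines")

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def build_script(session: IgvSession) -> IgvCommandScript:
    """Deterministically render a session as IGV batch commands."""
    lines = ["new", f"genome {session.genome_id}"]
    lines += [f"load {path}" for path in session.tracks]
    if session.target is not None:
        lines.append(f"goto {session.target.display()}")
    if session.snapshot_path:
        lines.append(f"snapshot {session.snapshot_path}")
    return IgvCommandScript(tuple(lines))


def locus_for_gene(gene: str, graph: IdGraph) -> GenomicLocus:
    """Look up a gene's locus in the association graph for a goto target."""
    from .idmap import resolve_row_identity

    identity = resolve_row_identity(gene, gene, None, graph)
    if identity.locus is None:
        raise ValueError(f"no locus known for gene {gene!r}")
    return identity.locus


@dataclass
class IgvSendError(RuntimeError):
    message: str
    failed_line: str | None = None

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return self.message


def send(
    script: IgvCommandScript,
    host: str = "127.0.0.1",
    port: int = DEFAULT_IGV_PORT,
    timeout: float = 30.0,
) -> list[str]:
    """Send a batch script to a listening IGV; one response per command.

    Raises IgvSendError naming host:port when the connection is refused,
    and surfaces the offending command when a per-line response is not
    ``OK``.
    """
    try:
        conn = socket.create_connection((host, port), timeout=timeout)
    except OSError as exc:
        raise IgvSendError(f"cannot connect to IGV at {host}:{port}: {exc}") from exc
    acks: list[str] = []
    with conn:
        reader = conn.makefile("r", encoding="ascii", newline="\n")
        for line in script.lines:
            conn.sendall((line + "\n").encode("ascii"))
            response = reader.readline().rstrip("\n")
            acks.append(response)
            if response != "OK":
                raise IgvSendError(
                    f"IGV rejected command {line!r} with response {response!r}",
                    failed_line=line,
                )
    return acks
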