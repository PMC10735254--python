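"""Core read container shared by the simulator and the processing stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class ReadRecord:
    """One sequenced read.

    ``bases`` and ``qualities`` always have equal length.  ``sample`` is only
    set once a read has been assigned by demultiplexing (or, for synthetic
    reads, carries the truth assignment).  ``flags`` collects boolean stage
    flags (``duplicate``, ``chimera``), ``meta`` free-form provenance.
    """

    read_id: str
    bases: str
    qualities: str
    sample: str | None = None
    orientation: str = "unknown"  # forward / reverse / unknown
    flags: dict = field(default_factory=dict)
    # Trimmed-off affixes retained so demultiplexing is reversible.
    trimmed_prefix: str = ""
    trimmed_suffix: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: bases ({len(self.bases)}) and qualities "
                f"({len(self.qualities)}) differ in length"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def copy(self, **changes) -> "ReadRecord":
        return replace(self, flags=dict(self.flags), meta=dict(self.meta), **changes)


def to_fastq(reads, handle) -> None:
    """Write reads as Sanger FASTQ (Phred+33)."""
    for r in reads:
        handle.write(f"@{r.read_id}\n{r.bases}\n+\n{r.qualities}\n")


def from_fastq(handle):
    """Read Sanger FASTQ into ReadRecords (plain text, four lines per read)."""
    out = []
    while True:
        header = handle.readline()
        if not header:
            break
        header = header.strip()
        if not header:
            continue
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ header: {header!r}")
        bases = handle.readline().strip()
        handle.readline()  # separator
        quals = handle.readline().strip()
        out.append(ReadRecord(read_id=header[1:].split()[0], bases=bases, qualities=quals))
    return out
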