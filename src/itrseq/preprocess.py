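"""Demultiplexing, UMI attachment, and ITR-prefix read selection.

Reads arrive with their dual sample indices and UMI already moved to
the header (Je-style extraction), as whitespace-separated tokens
``BC:<index1>+<index2>`` and ``UMI:<bases>``.  Demultiplexing assigns a
pair to the unique sample whose two indices are both within the
mismatch budget; selection keeps pairs whose read 2 begins with the
anchored-PCR primer plus the downstream ITR flank.

All mismatch counting is plain Hamming — no indels — and an N in the
read always counts as a mismatch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "SampleSheet",
    "TaggedReadPair",
    "hamming",
    "parse_header_tags",
    "demultiplex",
    "select_itr_reads",
]


def hamming(observed: str, expected: str) -> int:
    """Mismatches between equal-length strings; N in ``observed`` never matches."""
    if len(observed) != len(expected):
        raise ValueError(
            f"length mismatch: {len(observed)} vs {len(expected)}"
        )
    return sum(1 for a, b in zip(observed.upper(), expected.upper())
               if a == "N" or a != b)


@dataclass
class SampleSheet:
    """sample_id -> (index1, index2); all indices must share one length."""

    samples: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        lens = {len(i) for pair in self.samples.values() for i in pair}
        if len(lens) > 1:
            raise ValueError(f"sample sheet indices differ in length: {lens}")
        self.index_len = lens.pop() if lens else 0

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        samples: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"sample_id", "index1", "index2"}
            if not required <= set(reader.fieldnames or []):
                raise ValueError(f"sample sheet needs columns {sorted(required)}")
            for row in reader:
                sid = row["sample_id"]
                if sid in samples:
                    raise ValueError(f"duplicate sample_id {sid!r}")
                samples[sid] = (row["index1"].upper(), row["index2"].upper())
        return cls(samples)


@dataclass
class TaggedReadPair:
    """A demultiplexed read pair carrying its sample assignment and UMI."""

    read_id: str
    sample_id: str
    umi: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def parse_header_tags(header: str) -> tuple[str, str, str]:
    """Extract (index1, index2, umi) from BC:/UMI: header tokens."""
    index1 = index2 = umi = ""
    for token in header.split():
        if token.startswith("BC:"):
            barcodes = token[3:]
            if "+" not in barcodes:
                raise ValueError(f"malformed barcode token {token!r}")
            index1, index2 = barcodes.split("+", 1)
        elif token.startswith("UMI:"):
            umi = token[4:]
    return index1.upper(), index2.upper(), umi.upper()


def demultiplex(index1: str, index2: str, sheet: SampleSheet,
                max_index_mismatches: int = 1) -> str | None:
    """Assign a pair of observed indices to a sample, or None.

    A sample qualifies when both of its indices are within
    ``max_index_mismatches`` (Hamming) of the observed pair.  When no
    sample, or more than one sample, qualifies the pair is unassigned —
    the conservative tie rule standard demultiplexers use.
    """
    if len(index1) != sheet.index_len or len(index2) != sheet.index_len:
        raise ValueError(
            f"observed index lengths ({len(index1)},{len(index2)}) do not "
            f"match the sample sheet ({sheet.index_len})"
        )
    hits = [
        sid for sid, (e1, e2) in sheet.samples.items()
        if hamming(index1, e1) <= max_index_mismatches
        and hamming(index2, e2) <= max_index_mismatches
    ]
    return hits[0] if len(hits) == 1 else None


def select_itr_reads(seq2: str, expected_prefix: str,
                     max_prefix_mismatches: int = 5) -> bool:
    """True iff read 2 begins with the primer+ITR-flank prefix.

    The read-2 prefix must be within ``max_prefix_mismatches`` (Hamming)
    of the expected primer plus downstream ITR flank.  Reads shorter
    than the prefix are simply not selected.
    """
    if len(seq2) < len(expected_prefix):
        return False
    return hamming(seq2[:len(expected_prefix)], expected_prefix) \
        <= max_prefix_mismatches
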