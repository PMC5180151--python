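"""Sequence I/O, read merging, tag demultiplexing and primer trimming.

Coordinates are 0-based half-open throughout. Tag matching is exact
(9-bp tags leave no room for error tolerance); primer matching honours
IUPAC degeneracy, with inosine treated as N, and tolerates a small number
of mismatches at non-degenerate positions only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from edna._seqtools import IUPAC, matches_iupac, reverse_complement

TAG_LENGTH = 9

__all__ = [
    "PrimerPair", "COI_PRIMERS", "TaggedRead", "merge_pairs", "demultiplex",
    "trim_primers", "reverse_complement", "read_sequences", "write_fasta",
    "load_tag_map",
]


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if not p or any(b not in IUPAC for b in p):
                raise ValueError(f"invalid primer {p!r}")


#: degenerate metazoan COI primer pair framing the 313-bp barcode
COI_PRIMERS = PrimerPair(
    forward="GGWACWGGWTGAACWGTWTAYCCYCC",
    reverse="TAIACYTCIGGRTGICCRAARAAYCA",
)


@dataclass
class TaggedRead:
    read_id: str
    sequence: str
    fwd_tag: str | None = None
    rev_tag: str | None = None
    sample_id: str | None = None
    replicate_id: int | None = None


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)


def read_sequences(path: str | Path, fmt: str | None = None):
    """Yield (id, sequence) from FASTA or FASTQ, gzip transparent."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fasta(records, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def load_tag_map(path: str | Path) -> dict[tuple[str, str], tuple[str, int]]:
    """Read a TSV tag map (sample, replicate, fwd_tag, rev_tag) into a
    (fwd, rev) -> (sample, replicate) lookup; duplicate pairs are an error."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    lookup: dict[tuple[str, str], tuple[str, int]] = {}
    for row in df.itertuples():
        key = (row.fwd_tag, row.rev_tag)
        if key in lookup:
            raise ValueError(f"duplicate tag pair {key}")
        lookup[key] = (row.sample, int(row.replicate))
    return lookup


def tag_lookup_from_design(tag_map: dict) -> dict[tuple[str, str], tuple[str, int]]:
    """Invert a design's (sample, replicate) -> (fwd, rev) map."""
    lookup: dict[tuple[str, str], tuple[str, int]] = {}
    for (sample, rep), pair in tag_map.items():
        if pair in lookup:
            raise ValueError(f"duplicate tag pair {pair}")
        lookup[pair] = (sample, rep)
    return lookup


def merge_pairs(
    fwd_read: str,
    rev_read: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> str | None:
    """Merge a read pair by suffix-prefix overlap against revcomp(rev).

    The longest overlap with mismatch fraction <= ``max_mismatch_frac``
    wins; within the overlap the forward base is kept (no quality model).
    Returns None when no acceptable overlap of >= ``min_overlap`` exists.
    """
    if not fwd_read or not rev_read:
        raise ValueError("reads must be non-empty")
    rc = reverse_complement(rev_read)
    for ov in range(min(len(fwd_read), len(rc)), min_overlap - 1, -1):
        tail = fwd_read[len(fwd_read) - ov :]
        head = rc[:ov]
        mm = sum(a != b for a, b in zip(tail, head))
        if mm / ov <= max_mismatch_frac:
            return fwd_read + rc[ov:]
    return None


@dataclass
class DemuxResult:
    bins: dict[tuple[str, int], list[TaggedRead]]
    discarded: list[tuple[TaggedRead, str]] = field(default_factory=list)

    @property
    def n_binned(self) -> int:
        return sum(len(v) for v in self.bins.values())

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)


def demultiplex(reads, tag_lookup: dict[tuple[str, str], tuple[str, int]]) -> DemuxResult:
    """Assign reads to (sample, replicate) bins by their exact 9-bp tag pair.

    The forward tag is the first 9 bases; the reverse tag is the reverse
    complement of the last 9. Reads whose pair is not in the map go to the
    discard bin with reason ``tag_unknown``; too-short reads get
    ``too_short``. Binned + discarded always equals the input count.
    """
    result = DemuxResult(bins={key: [] for key in tag_lookup.values()})
    for rid, seq in reads:
        if len(seq) < 2 * TAG_LENGTH + 1:
            result.discarded.append((TaggedRead(rid, seq), "too_short"))
            continue
        fwd_tag = seq[:TAG_LENGTH]
        rev_tag = reverse_complement(seq[-TAG_LENGTH:])
        read = TaggedRead(rid, seq[TAG_LENGTH:-TAG_LENGTH], fwd_tag, rev_tag)
        hit = tag_lookup.get((fwd_tag, rev_tag))
        if hit is None:
            result.discarded.append((read, "tag_unknown"))
            continue
        read.sample_id, read.replicate_id = hit
        result.bins.setdefault(hit, []).append(read)
    return result


def _find_primer(seq: str, primer: str, max_mismatches: int) -> int:
    """Leftmost start of an IUPAC-compatible primer occurrence, else -1."""
    L = len(primer)
    for start in range(len(seq) - L + 1):
        mm = matches_iupac(primer, seq[start : start + L])
        if 0 <= mm <= max_mismatches:
            return start
    return -1


def trim_primers(
    read: str,
    primers: PrimerPair = COI_PRIMERS,
    max_mismatches: int = 2,
) -> str | None:
    """Extract the insert between the forward primer and the reverse
    complement of the reverse primer.

    The read is tried as given, then reverse-complemented. Degenerate
    primer positions must be compatible with the read; up to
    ``max_mismatches`` errors are tolerated at non-degenerate positions.
    Returns None when either primer cannot be located.
    """
    if len(read) <= len(primers.forward) + len(primers.reverse):
        raise ValueError("read shorter than combined primer length")
    rc_rev = reverse_complement(primers.reverse)
    for oriented in (read, reverse_complement(read)):
        f = _find_primer(oriented, primers.forward, max_mismatches)
        if f < 0:
            continue
        insert_start = f + len(primers.forward)
        r = _find_primer(oriented[insert_start:], rc_rev, max_mismatches)
        if r < 0:
            continue
        return oriented[insert_start : insert_start + r]
    return None
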