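"""Barcode extraction from raw reads, exact-collapse counting, and
representative-barcode selection.

Barcodes sit at the 5' end of each read, followed by a known constant adapter
(``GGCAAGCTAGAGA`` on 5'-side libraries, ``TAGCGCGGGGCGT`` on 3'-side ones).
Trimming removes the adapter and everything after it, tolerating mismatches up
to a fraction of the aligned adapter length; the remaining prefix is kept only
if its length falls in the expected barcode window (21-23 nt). Counting is
exact-match aggregation — no error correction — and one barcode per insertion
is then chosen by read support in the initial (pre-selection) samples.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from poolfit.screen_io import CountTable, InsertionAnnotation

ADAPTER_5PRIME = "GGCAAGCTAGAGA"
ADAPTER_3PRIME = "TAGCGCGGGGCGT"

_VALID = frozenset(b"ACGTN")


@dataclass(frozen=True)
class TrimSpec:
    """Adapter-trimming parameters.

    ``max_error_rate`` is the tolerated mismatch fraction of the aligned
    adapter portion (allowed errors = floor(rate x aligned length));
    ``min_len``/``max_len`` bound the retained barcode length.
    ``min_overlap`` is the shortest adapter suffix-partial match honoured at
    the read's 3' end, preventing spurious 1-2 nt "matches".
    """

    adapter: str = ADAPTER_5PRIME
    max_error_rate: float = 0.1
    min_len: int = 21
    max_len: int = 23
    min_overlap: int = 3

    def __post_init__(self):
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass(frozen=True)
class TrimResult:
    barcode: str | None
    reason: str | None  # None on success; 'too_short' or 'too_long' on reject
    adapter_found: bool

    @property
    def accepted(self) -> bool:
        return self.barcode is not None


def _find_adapter(read: str, spec: TrimSpec) -> int | None:
    """Return the start index of the best adapter occurrence, or None.

    Mismatch counting is per candidate offset (substitutions only; N counts
    as a mismatch). A full-length internal occurrence or a suffix-partial one
    at the read end qualifies when mismatches <= floor(rate x aligned length).
    Candidates are ranked by (start position, mismatch count): the earliest
    acceptable occurrence wins, ties broken by fewer mismatches.
    """
    n, alen = len(read), len(spec.adapter)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    a = np.frombuffer(spec.adapter.encode(), dtype=np.uint8)

    best: tuple[int, int] | None = None
    # full-length internal placements, vectorized over all offsets
    if n >= alen:
        windows = np.lib.stride_tricks.sliding_window_view(r, alen)
        errs = (windows != a).sum(axis=1)
        allowed = math.floor(spec.max_error_rate * alen)
        ok = np.nonzero(errs <= allowed)[0]
        if ok.size:
            i = int(ok[0])
            best = (i, int(errs[i]))
    # suffix-partial placements at the read end (adapter runs off the read)
    lo = max(spec.min_overlap, 1)
    for L in range(min(alen - 1, n), lo - 1, -1):
        i = n - L
        if best is not None and i > best[0]:
            break
        e = int((r[i:] != a[:L]).sum())
        if e <= math.floor(spec.max_error_rate * L):
            cand = (i, e)
            if best is None or cand < best:
                best = cand
    return None if best is None else best[0]


def trim_read(read: str, spec: TrimSpec | None = None) -> TrimResult:
    """Extract the barcode preceding the adapter from one read.

    If no adapter occurrence is found the whole read is retained; either way
    the candidate barcode is then subjected to the length window, and reads
    failing it are rejected with a reason (``too_short``/``too_long``).
    """
    spec = spec or TrimSpec()
    if set(read.encode()) - _VALID:
        raise ValueError(f"read contains non-ACGTN characters: {read!r}")
    pos = _find_adapter(read, spec)
    found = pos is not None
    candidate = read[:pos] if found else read
    if len(candidate) < spec.min_len:
        return TrimResult(None, "too_short", found)
    if len(candidate) > spec.max_len:
        return TrimResult(None, "too_long", found)
    return TrimResult(candidate, None, found)


def collapse_and_count(barcodes: Iterable[str], sample_id: str = "sample") -> CountTable:
    """Aggregate identical barcode sequences into a count table."""
    counts: dict[str, int] = {}
    for b in barcodes:
        counts[b] = counts.get(b, 0) + 1
    return CountTable(sample_id=sample_id, counts=counts)


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip allowed by suffix)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip().upper()


def count_fastq(path: str | Path, spec: TrimSpec | None = None, sample_id: str = "sample"):
    """Trim every read in a FASTQ file and count the accepted barcodes.

    Returns ``(CountTable, stats)`` where stats tallies accepted /
    too_short / too_long reads.
    """
    spec = spec or TrimSpec()
    stats = {"accepted": 0, "too_short": 0, "too_long": 0}
    counts: dict[str, int] = {}
    for read in iter_fastq(path):
        res = trim_read(read, spec)
        if res.accepted:
            stats["accepted"] += 1
            counts[res.barcode] = counts.get(res.barcode, 0) + 1
        else:
            stats[res.reason] += 1
    return CountTable(sample_id=sample_id, counts=counts), stats


def select_representative(
    annotations: Iterable[InsertionAnnotation],
    initial_counts: Iterable[CountTable],
) -> dict[tuple[str | None, str, str], str]:
    """Pick one representative barcode per putative insertion.

    Barcodes sharing (gene_id, plate, well) are assumed to tag the same
    insertion; the one with the highest summed raw read count across the
    initial samples represents it. Ties go to the lexicographically smallest
    barcode. Groups with no reads in any initial sample are excluded (they
    cannot be quantified downstream).
    """
    totals: dict[str, int] = {}
    for table in initial_counts:
        for b, c in table.counts.items():
            totals[b] = totals.get(b, 0) + c

    groups: dict[tuple[str | None, str, str], set[str]] = {}
    for a in annotations:
        groups.setdefault((a.gene_id, a.plate, a.well), set()).add(a.barcode)

    chosen: dict[tuple[str | None, str, str], str] = {}
    for key, barcodes in groups.items():
        present = [b for b in barcodes if totals.get(b, 0) > 0]
        if not present:
            continue
        chosen[key] = max(sorted(present), key=lambda b: totals[b])
    return chosen
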