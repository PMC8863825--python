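"""Small-RNA read processing: adapter trimming, collapsing, precursor-space
mapping, 5p/3p arm assignment and fractional (1/N) counting.

The mapper aligns reads end-to-end against the precursor sequences
themselves (sense strand only, substitutions only).  Reads from loci outside
the precursor set are simply unmapped; this reproduces the retained read set
of a genome-wide mapping followed by intersection with precursor loci, which
is the set the counting step consumes.

A read aligning to N loci — distinct (precursor, offset) sites at the
minimal observed mismatch count — contributes 1/N of its multiplicity to the
mature miRNA (precursor arm) of each locus.  Arm assignment uses the read
midpoint: first half of the precursor → 5p, second half → 3p, exact tie →
5p.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import PrecursorSet

__all__ = [
    "CollapsedRead",
    "Alignment",
    "trim_and_filter",
    "collapse",
    "PrecursorIndex",
    "map_reads",
    "assign_arm",
    "count",
    "quantify_sample",
    "quantify_samples",
]

MIN_READ_LEN = 15


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    multiplicity: int

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True)
class Alignment:
    """End-to-end hit of a read on a precursor.

    ``n_loci`` is shared across all retained alignments of the same read;
    the read's counting weight at this locus is ``1 / n_loci``.
    """

    sequence: str
    precursor_id: str
    start: int  # 0-based
    end: int  # exclusive
    mismatches: int
    n_loci: int

    @property
    def weight(self) -> float:
        return 1.0 / self.n_loci


# ---------------------------------------------------------------------------
# trimming / collapsing
# ---------------------------------------------------------------------------


def trim_and_filter(
    sequence: str,
    adapter: str,
    min_len: int = MIN_READ_LEN,
    min_overlap: int = 7,
    mismatch_frac: float = 0.1,
) -> str | None:
    """Remove the 3' adapter and drop short inserts.

    The leftmost occurrence of an adapter prefix of at least ``min_overlap``
    bases (tolerating ``mismatch_frac`` substitutions) marks the insert
    end.  Returns the insert, or ``None`` when it is shorter than
    ``min_len``.  Reads with no adapter hit are kept full length: the
    insert may fill the read.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    pos = _find_adapter(sequence, adapter, min_overlap, mismatch_frac)
    insert = sequence if pos is None else sequence[:pos]
    return insert if len(insert) >= min_len else None


def _find_adapter(
    sequence: str, adapter: str, min_overlap: int, mismatch_frac: float
) -> int | None:
    # leftmost start whose full available overlap with the adapter prefix
    # stays within the mismatch budget; the exact-equality slice compare is
    # the fast path, the counting loop exits at the first budget overrun
    for i in range(0, len(sequence) - min_overlap + 1):
        overlap = min(len(adapter), len(sequence) - i)
        if overlap < min_overlap:
            break
        seg = sequence[i : i + overlap]
        if seg == adapter[:overlap]:
            return i
        allowed = int(mismatch_frac * overlap)
        if allowed == 0:
            continue
        mm = 0
        for a, b in zip(seg, adapter):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        if mm <= allowed:
            return i
    return None


def collapse(sequences: Iterable[str]) -> list[CollapsedRead]:
    """One entry per distinct sequence; multiplicities conserve the input."""
    counter = Counter(sequences)
    return [CollapsedRead(seq, mult) for seq, mult in counter.items()]


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


class PrecursorIndex:
    """Concatenated-precursor text for exact-segment candidate lookup.

    For <= ``max_mismatches`` substitutions, any read split into
    ``max_mismatches + 1`` contiguous segments has at least one segment
    matching the reference exactly (pigeonhole); candidate offsets come
    from exact occurrences of each segment, then the full read is verified
    by Hamming distance.
    """

    def __init__(self, reference: PrecursorSet) -> None:
        self.reference = reference
        self._ids: list[str] = []
        self._starts: list[int] = []
        parts: list[str] = []
        offset = 0
        for prec in reference.precursors.values():
            self._ids.append(prec.id)
            self._starts.append(offset)
            parts.append(prec.sequence)
            offset += len(prec.sequence) + 1  # '#' separator blocks spill-over
        self._text = "#".join(parts)
        self._bounds = np.array(self._starts + [offset], dtype=np.int64)

    def _locate(self, concat_pos: int) -> tuple[int, int]:
        """Map a position in the concatenated text to (precursor idx, offset)."""
        k = int(np.searchsorted(self._bounds, concat_pos, side="right") - 1)
        return k, concat_pos - self._starts[k]

    def candidates(self, read: str, max_mismatches: int) -> set[tuple[int, int]]:
        n_seg = max_mismatches + 1
        L = len(read)
        cand: set[tuple[int, int]] = set()
        bounds = [round(i * L / n_seg) for i in range(n_seg + 1)]
        for s in range(n_seg):
            seg = read[bounds[s] : bounds[s + 1]]
            if not seg:
                continue
            start = self._text.find(seg)
            while start >= 0:
                k, off = self._locate(start)
                read_start = off - bounds[s]
                if read_start >= 0 and read_start + L <= len(
                    self.reference.precursors[self._ids[k]].sequence
                ):
                    cand.add((k, read_start))
                start = self._text.find(seg, start + 1)
        return cand

    def align(self, read: str, max_mismatches: int) -> list[tuple[str, int, int]]:
        """All end-to-end hits with <= max_mismatches substitutions, as
        (precursor id, start, mismatch count)."""
        hits = []
        for k, start in sorted(self.candidates(read, max_mismatches)):
            prec = self.reference.precursors[self._ids[k]]
            window = prec.sequence[start : start + len(read)]
            mm = sum(a != b for a, b in zip(read, window))
            if mm <= max_mismatches:
                hits.append((self._ids[k], start, mm))
        return hits


def map_reads(
    reads: Sequence[CollapsedRead],
    reference: PrecursorSet | PrecursorIndex,
    max_mismatches: int = 1,
) -> list[Alignment]:
    """Map collapsed reads end-to-end to precursors.

    Only alignments at the minimal observed mismatch count of each read are
    retained; ``n_loci`` counts the retained (precursor, offset) sites.
    Reads with more than 10% N bases are unmapped; N never matches.
    """
    index = (
        reference
        if isinstance(reference, PrecursorIndex)
        else PrecursorIndex(reference)
    )
    alignments: list[Alignment] = []
    for read in reads:
        seq = read.sequence
        if seq.count("N") > 0.1 * len(seq):
            continue
        hits = index.align(seq, max_mismatches)
        if not hits:
            continue
        best = min(mm for _, _, mm in hits)
        kept = [h for h in hits if h[2] == best]
        n = len(kept)
        for pid, start, mm in kept:
            alignments.append(Alignment(seq, pid, start, start + len(seq), mm, n))
    return alignments


def assign_arm(alignment: Alignment, reference: PrecursorSet) -> str:
    """5p/3p by read midpoint: first half of the precursor → 5p (ties → 5p)."""
    prec = reference.precursors[alignment.precursor_id]
    midpoint = (alignment.start + alignment.end - 1) / 2.0
    return "5p" if midpoint <= len(prec) / 2.0 else "3p"


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def count(
    alignments: Sequence[Alignment],
    reads: Sequence[CollapsedRead],
    reference: PrecursorSet,
    sample_id: str,
) -> pd.Series:
    """One fractional-count column: each collapsed read adds
    multiplicity x 1/N to the mature miRNA of each retained locus."""
    multiplicity = {r.sequence: r.multiplicity for r in reads}
    arm_lookup: dict[tuple[str, str], str] = {}
    for mid, arm in reference.matures.items():
        arm_lookup[(arm.precursor_id, arm.arm)] = mid
    values = pd.Series(0.0, index=reference.mature_ids(), name=sample_id)
    for aln in alignments:
        if aln.precursor_id not in reference.precursors:
            raise ValueError(f"alignment to unknown precursor {aln.precursor_id!r}")
        arm = assign_arm(aln, reference)
        mid = arm_lookup.get((aln.precursor_id, arm))
        if mid is None:
            # precursor annotated without this arm: the locus is not a
            # mature miRNA, the read's share at it is dropped
            continue
        values[mid] += multiplicity[aln.sequence] * aln.weight
    return values


# ---------------------------------------------------------------------------
# per-sample / multi-sample drivers
# ---------------------------------------------------------------------------


def _read_fastq_sequences(path: str | Path) -> Iterable[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for _, seq, _ in FastqGeneralIterator(fh):
            yield seq.upper()


def quantify_sample(
    fastq: str | Path,
    reference: PrecursorSet,
    adapter: str,
    sample_id: str,
    max_mismatches: int = 1,
    min_len: int = MIN_READ_LEN,
    index: PrecursorIndex | None = None,
) -> tuple[pd.Series, dict]:
    """FASTQ → fractional-count column + QC dictionary.

    Identical raw sequences are collapsed before trimming (trimming is a
    pure function of the sequence), which makes deep error-free libraries
    cheap to process.
    """
    raw = Counter(_read_fastq_sequences(fastq))
    n_in = sum(raw.values())
    trimmed: Counter[str] = Counter()
    n_discarded = 0
    for seq, mult in raw.items():
        insert = trim_and_filter(seq, adapter, min_len=min_len)
        if insert is None:
            n_discarded += mult
        else:
            trimmed[insert] += mult
    reads = [CollapsedRead(s, m) for s, m in trimmed.items()]
    alignments = map_reads(reads, index or reference, max_mismatches)
    column = count(alignments, reads, reference, sample_id)
    loci_per_seq: dict[str, int] = {}
    for a in alignments:
        loci_per_seq[a.sequence] = a.n_loci
    n_mapped = sum(trimmed[s] for s in loci_per_seq)
    multi = sum(trimmed[s] for s, n in loci_per_seq.items() if n > 1)
    qc = {
        "sample": sample_id,
        "reads_in": n_in,
        "reads_discarded_short": n_discarded,
        "reads_kept": n_in - n_discarded,
        "unique_sequences": len(trimmed),
        "reads_mapped": n_mapped,
        "multimapped_fraction": (multi / n_mapped) if n_mapped else 0.0,
    }
    return column, qc


def quantify_samples(
    fastq_paths: dict[str, str | Path],
    reference: PrecursorSet,
    adapter: str,
    max_mismatches: int = 1,
    min_len: int = MIN_READ_LEN,
) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify several samples against one shared index; columns follow
    the order of ``fastq_paths``."""
    index = PrecursorIndex(reference)
    columns = []
    qcs = []
    for sample_id, path in fastq_paths.items():
        col, qc = quantify_sample(
            path, reference, adapter, sample_id,
            max_mismatches=max_mismatches, min_len=min_len, index=index,
        )
        columns.append(col)
        qcs.append(qc)
    return pd.concat(columns, axis=1), qcs


def write_qc(qcs: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(qcs, indent=2) + "\n")
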