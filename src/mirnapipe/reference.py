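"""Precursor reference handling.

A :class:`PrecursorSet` holds miRNA precursor (hairpin) sequences together
with the coordinates of their mature 5p/3p arms, mirroring the content of a
miRBase-style FASTA + GFF3 annotation pair.  Coordinates are stored 0-based
half-open internally; GFF3 I/O converts to/from 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["MatureArm", "Precursor", "PrecursorSet"]


@dataclass(frozen=True)
class MatureArm:
    """One mature miRNA arm annotated on a precursor."""

    id: str
    precursor_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    arm: str  # "5p" | "3p"

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be '5p' or '3p', got {self.arm!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid arm coordinates [{self.start}, {self.end})")


@dataclass(frozen=True)
class Precursor:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrecursorSet:
    """Precursor sequences plus mature-arm annotation.

    Invariants enforced on construction: unique identifiers, arm
    coordinates within the precursor, at most one arm per label per
    precursor.
    """

    precursors: dict[str, Precursor] = field(default_factory=dict)
    matures: dict[str, MatureArm] = field(default_factory=dict)

    def add_precursor(self, precursor: Precursor) -> None:
        if precursor.id in self.precursors:
            raise ValueError(f"duplicate precursor id {precursor.id!r}")
        self.precursors[precursor.id] = precursor

    def add_mature(self, arm: MatureArm) -> None:
        if arm.id in self.matures:
            raise ValueError(f"duplicate mature id {arm.id!r}")
        prec = self.precursors.get(arm.precursor_id)
        if prec is None:
            raise ValueError(f"mature {arm.id!r} references unknown precursor {arm.precursor_id!r}")
        if arm.end > len(prec):
            raise ValueError(f"mature {arm.id!r} extends past precursor end")
        for other in self.matures.values():
            if other.precursor_id == arm.precursor_id and other.arm == arm.arm:
                raise ValueError(
                    f"precursor {arm.precursor_id!r} already has a {arm.arm} arm"
                )
        self.matures[arm.id] = arm

    # -- convenience ----------------------------------------------------

    def mature_ids(self) -> list[str]:
        """Mature ids in deterministic (insertion) order."""
        return list(self.matures)

    def arms_of(self, precursor_id: str) -> list[MatureArm]:
        return [m for m in self.matures.values() if m.precursor_id == precursor_id]

    def mature_sequence(self, mature_id: str) -> str:
        arm = self.matures[mature_id]
        return self.precursors[arm.precursor_id].sequence[arm.start : arm.end]

    def __len__(self) -> int:
        return len(self.precursors)

    # -- I/O ------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(p.sequence), id=p.id, description="")
            for p in self.precursors.values()
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gff3(self, path: str | Path) -> None:
        """Write a miRBase-dialect GFF3: precursors as
        ``miRNA_primary_transcript``, arms as ``miRNA`` with a
        ``Derives_from`` attribute; 1-based inclusive coordinates on the
        precursor's own sequence."""
        lines = ["##gff-version 3"]
        for prec in self.precursors.values():
            attrs = f"ID={prec.id};Name={prec.id}"
            lines.append(
                f"{prec.id}\t.\tmiRNA_primary_transcript\t1\t{len(prec)}\t.\t+\t.\t{attrs}"
            )
            for arm in self.arms_of(prec.id):
                attrs = f"ID={arm.id};Name={arm.id};Derives_from={prec.id}"
                lines.append(
                    f"{prec.id}\t.\tmiRNA\t{arm.start + 1}\t{arm.end}\t.\t+\t.\t{attrs}"
                )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path) -> "PrecursorSet":
        ref = cls()
        for rec in SeqIO.parse(str(fasta), "fasta"):
            ref.add_precursor(Precursor(rec.id, str(rec.seq).upper()))
        for seqid, ftype, start, end, attrs in _parse_gff3(gff3):
            if ftype != "miRNA":
                continue
            fid = attrs.get("ID") or attrs.get("Name")
            if fid is None:
                raise ValueError(f"miRNA feature on {seqid} lacks ID/Name attribute")
            prec_id = attrs.get("Derives_from", seqid)
            arm = _infer_arm_label(fid, start - 1, end, len(ref.precursors[prec_id]))
            ref.add_mature(MatureArm(fid, prec_id, start - 1, end, arm))
        return ref


def _parse_gff3(path: str | Path) -> Iterable[tuple[str, str, int, int, dict[str, str]]]:
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = dict(
            item.split("=", 1) for item in cols[8].strip().split(";") if "=" in item
        )
        yield cols[0], cols[2], int(cols[3]), int(cols[4]), attrs


def _infer_arm_label(feature_id: str, start: int, end: int, precursor_len: int) -> str:
    """Arm label from the id suffix when present, else from the midpoint
    (first half → 5p, exact tie → 5p)."""
    if feature_id.endswith("-5p"):
        return "5p"
    if feature_id.endswith("-3p"):
        return "3p"
    midpoint = (start + end - 1) / 2.0
    return "5p" if midpoint <= precursor_len / 2.0 else "3p"
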