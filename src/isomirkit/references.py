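"""miRNA reference handling: precursors, mature annotations and seeds.

A :class:`ReferenceSet` holds hairpin precursor sequences together with the
mature miRNAs excised from them.  Matures are located on their precursor
either by exact substring search or from an optional GFF3 file whose seqids
are precursor ids.  All sequences are normalised to the RNA alphabet
(A/C/G/U) internally; DNA input (T) is accepted and converted.

Coordinate conventions
----------------------
* Intervals on precursors are 0-based, half-open ``[start, end)``.
* Seed positions on matures are 1-based and inclusive, matching the
  field's "nucleotides 2-7" phrasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

MIN_PRECURSOR_LEN = 40
MIN_MATURE_LEN = 16
MAX_MATURE_LEN = 30


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent reference input."""


def normalize_rna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase, convert T to U and validate the A/C/G/U alphabet."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ReferenceError(
            f"{what} contains characters outside A/C/G/U(/T): {sorted(bad)}"
        )
    return s


def to_dna(seq: str) -> str:
    """Render an internal RNA string in the DNA alphabet (U -> T)."""
    return seq.replace("U", "T")


@dataclass(frozen=True)
class PrecursorRecord:
    """A hairpin precursor sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, what=f"precursor {self.id!r}"))
        if len(self.sequence) < MIN_PRECURSOR_LEN:
            raise ReferenceError(
                f"precursor {self.id!r} is {len(self.sequence)} nt; "
                f"hairpins must be >= {MIN_PRECURSOR_LEN} nt"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA placed on its precursor.

    ``start``/``end`` are 0-based half-open on the precursor; ``arm`` is
    "5p" or "3p" (inferred from position relative to the hairpin midpoint
    when not given explicitly).
    """

    id: str
    precursor_id: str
    start: int
    end: int
    arm: str
    sequence: str
    ambiguous_placement: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, what=f"mature {self.id!r}"))
        if self.arm not in ("5p", "3p"):
            raise ReferenceError(f"mature {self.id!r}: arm must be '5p' or '3p', got {self.arm!r}")
        if not (MIN_MATURE_LEN <= len(self.sequence) <= MAX_MATURE_LEN):
            raise ReferenceError(
                f"mature {self.id!r} is {len(self.sequence)} nt; expected "
                f"{MIN_MATURE_LEN}-{MAX_MATURE_LEN} nt"
            )
        if self.end - self.start != len(self.sequence):
            raise ReferenceError(f"mature {self.id!r}: interval does not match sequence length")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    """Precursors plus mature annotations, indexed both ways."""

    precursors: dict[str, PrecursorRecord] = field(default_factory=dict)
    matures: dict[str, MatureAnnotation] = field(default_factory=dict)

    def add_precursor(self, rec: PrecursorRecord) -> None:
        if rec.id in self.precursors:
            raise ReferenceError(f"duplicate precursor id {rec.id!r}")
        self.precursors[rec.id] = rec

    def add_mature(self, ann: MatureAnnotation) -> None:
        if ann.id in self.matures:
            raise ReferenceError(f"duplicate mature id {ann.id!r}")
        prec = self.precursors.get(ann.precursor_id)
        if prec is None:
            raise ReferenceError(
                f"mature {ann.id!r} refers to unknown precursor {ann.precursor_id!r}"
            )
        if prec.sequence[ann.start:ann.end] != ann.sequence:
            raise ReferenceError(
                f"mature {ann.id!r} sequence does not match precursor "
                f"{ann.precursor_id!r}[{ann.start}:{ann.end}]"
            )
        self.matures[ann.id] = ann

    def matures_of(self, precursor_id: str) -> list[MatureAnnotation]:
        """Matures on one precursor, 5p arm first, then by start."""
        out = [m for m in self.matures.values() if m.precursor_id == precursor_id]
        return sorted(out, key=lambda m: (m.arm != "5p", m.start, m.id))

    def validate(self) -> None:
        for ann in self.matures.values():
            prec = self.precursors[ann.precursor_id]
            assert prec.sequence[ann.start:ann.end] == ann.sequence


@dataclass(frozen=True)
class SeedSpec:
    """An inclusive 1-based span on the mature defining a seed."""

    start_pos: int
    end_pos: int
    label: str

    def __post_init__(self) -> None:
        if not (1 < self.start_pos <= self.end_pos <= 10):
            raise ReferenceError(
                f"seed span must satisfy 1 < start <= end <= 10, got "
                f"[{self.start_pos}, {self.end_pos}]"
            )

    def __len__(self) -> int:
        return self.end_pos - self.start_pos + 1


#: canonical seed, nucleotides 2-7
SEED_2_7 = SeedSpec(2, 7, "seed_2_7")
#: extended seed, nucleotides 2-8 (relevant for 7mer-m8/8mer sites)
SEED_2_8 = SeedSpec(2, 8, "seed_2_8")
#: the nucleotides structurally exposed for target pairing in Argonaute
EXPOSED_2_6 = SeedSpec(2, 6, "exposed_2_6")

SEED_SPECS = {s.label: s for s in (SEED_2_7, SEED_2_8, EXPOSED_2_6)}


def extract_seed(mature_seq: str, spec: SeedSpec) -> str:
    """Extract the seed span from a mature sequence (1-based inclusive)."""
    seq = normalize_rna(mature_seq, what="mature")
    if len(seq) < spec.end_pos:
        raise ReferenceError(
            f"sequence of length {len(seq)} too short for seed span "
            f"[{spec.start_pos}, {spec.end_pos}]"
        )
    return seq[spec.start_pos - 1 : spec.end_pos]


def locate_mature(precursor_seq: str, mature_seq: str) -> tuple[int, int, bool]:
    """Locate a mature on a precursor by exact substring search.

    Returns ``(start, end, ambiguous)`` for the first occurrence; the
    ambiguity flag is set when the mature occurs more than once.
    """
    prec = normalize_rna(precursor_seq, what="precursor")
    mat = normalize_rna(mature_seq, what="mature")
    if not prec or not mat:
        raise ReferenceError("empty sequence passed to locate_mature")
    i = prec.find(mat)
    if i < 0:
        raise ReferenceError("mature sequence not found on precursor")
    ambiguous = prec.find(mat, i + 1) >= 0
    return i, i + len(mat), ambiguous


def infer_arm(start: int, end: int, precursor_len: int) -> str:
    """Assign 5p/3p by the mature midpoint relative to the hairpin midpoint."""
    return "5p" if (start + end) / 2 <= precursor_len / 2 else "3p"


def _arm_from_id(mature_id: str) -> Optional[str]:
    lowered = mature_id.lower()
    if lowered.endswith("-5p") or "-5p" in lowered:
        return "5p"
    if lowered.endswith("-3p") or "-3p" in lowered:
        return "3p"
    return None


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise ReferenceError(f"FASTA file not found: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ReferenceError(f"no FASTA records in {path}")
    return records


def _load_gff_placements(gff_path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read mature placements from a GFF3 keyed on precursor seqids.

    Expects miRBase attribute style: feature type ``miRNA`` with an
    ``ID`` or ``Name`` attribute naming the mature; 1-based inclusive
    coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    placements: dict[str, tuple[str, int, int]] = {}
    for feat in db.all_features(featuretype="miRNA"):
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [None])[0]
        if name is None:
            raise ReferenceError(f"GFF3 miRNA feature without ID/Name at {feat.seqid}:{feat.start}")
        placements[name] = (feat.seqid, feat.start - 1, feat.end)
    return placements


def load_references(
    hairpin_path: str | Path,
    mature_path: str | Path,
    gff_path: Optional[str | Path] = None,
) -> ReferenceSet:
    """Build a :class:`ReferenceSet` from hairpin and mature FASTA files.

    Without a GFF3, each mature is placed on the first precursor that
    contains it as an exact substring (multiple hits are taken at the
    first occurrence and flagged).  With a GFF3, placements come from the
    file and are checked against the sequences.
    """
    refset = ReferenceSet()
    for pid, seq in _read_fasta(hairpin_path):
        refset.add_precursor(PrecursorRecord(pid, seq))

    placements = _load_gff_placements(gff_path) if gff_path is not None else None

    for mid, raw_seq in _read_fasta(mature_path):
        seq = normalize_rna(raw_seq, what=f"mature {mid!r}")
        if placements is not None:
            if mid not in placements:
                raise ReferenceError(f"mature {mid!r} has no GFF3 placement")
            pid, start, end = placements[mid]
            if pid not in refset.precursors:
                raise ReferenceError(
                    f"GFF3 places mature {mid!r} on unknown precursor {pid!r}"
                )
            ambiguous = False
        else:
            hit = None
            for pid in sorted(refset.precursors):
                try:
                    start, end, ambiguous = locate_mature(
                        refset.precursors[pid].sequence, seq
                    )
                except ReferenceError:
                    continue
                hit = (pid, start, end, ambiguous)
                break
            if hit is None:
                raise ReferenceError(
                    f"mature {mid!r} not found on any precursor"
                )
            pid, start, end, ambiguous = hit
            if ambiguous:
                logger.warning(
                    "mature %s occurs more than once on precursor %s; "
                    "using the first occurrence", mid, pid
                )
        prec = refset.precursors[pid]
        arm = _arm_from_id(mid) or infer_arm(start, end, len(prec))
        refset.add_mature(
            MatureAnnotation(
                id=mid, precursor_id=pid, start=start, end=end, arm=arm,
                sequence=seq, ambiguous_placement=ambiguous,
            )
        )
    return refset


def build_reference_set(
    hairpins: Iterable[tuple[str, str]],
    matures: Iterable[tuple[str, str]] | None = None,
) -> ReferenceSet:
    """Assemble a ReferenceSet from in-memory (id, sequence) pairs.

    Matures are placed by exact substring search, as in
    :func:`load_references` without a GFF3.
    """
    refset = ReferenceSet()
    for pid, seq in hairpins:
        refset.add_precursor(PrecursorRecord(pid, seq))
    for mid, seq in (matures or []):
        seq = normalize_rna(seq, what=f"mature {mid!r}")
        hit = None
        for pid in sorted(refset.precursors):
            try:
                start, end, amb = locate_mature(refset.precursors[pid].sequence, seq)
            except ReferenceError:
                continue
            hit = (pid, start, end, amb)
            break
        if hit is None:
            raise ReferenceError(f"mature {mid!r} not found on any precursor")
        pid, start, end, amb = hit
        arm = _arm_from_id(mid) or infer_arm(start, end, len(refset.precursors[pid]))
        refset.add_mature(
            MatureAnnotation(mid, pid, start, end, arm, seq, ambiguous_placement=amb)
        )
    return refset


def shift_mature(
    refset: ReferenceSet, mature_id: str, delta5: int, delta3: int,
    new_id: Optional[str] = None,
) -> MatureAnnotation:
    """Build the templated isomiR obtained by moving both mature termini.

    ``delta5``/``delta3`` move the 5' and 3' ends downstream (positive)
    along the precursor; the variant's sequence is read off the precursor
    so it is templated by construction.  A +1/+1 shift drops the first
    annotated nucleotide and extends one templated nucleotide at the 3'
    end, preserving length.
    """
    ann = refset.matures.get(mature_id)
    if ann is None:
        raise ReferenceError(f"unknown mature id {mature_id!r}")
    prec = refset.precursors[ann.precursor_id]
    start, end = ann.start + delta5, ann.end + delta3
    if not (0 <= start < end <= len(prec)):
        raise ReferenceError(
            f"shifted interval [{start}, {end}) escapes precursor "
            f"{prec.id!r} (length {len(prec)})"
        )
    if new_id is None:
        new_id = ann.id if (delta5 == 0 and delta3 == 0) else f"{ann.id}|{delta5:+d}{delta3:+d}"
    return replace(
        ann, id=new_id, start=start, end=end,
        sequence=prec.sequence[start:end], ambiguous_placement=False,
    )
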