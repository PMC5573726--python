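"""Read-to-precursor mapping, isomiR classification and profile tallies.

Mapping is performed in precursor space: a read is aligned ungapped as a
templated prefix starting at some precursor position, with a bounded
number of mismatches, and an optional short untemplated 3' remainder
(NTA).  Every admissible (precursor, start, split) candidate is scored

    score = templated_length - 2 * mismatches

and the best-scoring candidate wins; ties are broken by fewer NTA bases,
fewer mismatches, lexicographically smallest precursor id, then smallest
start.  Equal-score survivors on *different* precursors set the
``ambiguous`` flag; such reads are counted once, at the winner.

Reconstruction invariant: the precursor bases over the templated
interval, with the read's bases substituted at the recorded mismatch
positions, concatenated with the NTA suffix, equal the read exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .references import (
    MatureAnnotation,
    ReferenceError,
    ReferenceSet,
    normalize_rna,
)

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGU"


@dataclass(frozen=True)
class MapParams:
    """Mapping knobs: mismatch budget, NTA cap and templated-length floor."""

    max_mismatches: int = 1
    max_nta: int = 3
    min_templated: int = 16


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    read_seq: str
    precursor_id: str
    start: int            # templated interval on the precursor, 0-based
    end: int              # half-open
    mismatch_positions: tuple[int, ...]  # precursor coordinates
    nta: str
    score: int
    ambiguous: bool = False

    @property
    def templated_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IsomiRCall:
    """One read's classification against a mature annotation."""

    read_id: str
    mature_id: str
    arm: str
    offset5: int   # templated start - annotated start (positive = downstream)
    offset3: int   # templated end - annotated end
    nta: str
    n_subs: int


def _candidate_alignments(
    read_seq: str, refset: ReferenceSet, params: MapParams
) -> Iterator[tuple]:
    """Yield (-score, n_nta, n_mm, precursor_id, start, split) for every
    admissible candidate."""
    L = len(read_seq)
    lo_split = max(params.min_templated, L - params.max_nta)
    for pid in sorted(refset.precursors):
        prec = refset.precursors[pid].sequence
        plen = len(prec)
        for start in range(0, plen - params.min_templated + 1):
            max_split = min(L, plen - start)
            if max_split < lo_split:
                continue
            # cumulative mismatches along the candidate prefix
            mm = 0
            mm_at = [0] * (max_split + 1)
            for j in range(max_split):
                if read_seq[j] != prec[start + j]:
                    mm += 1
                mm_at[j + 1] = mm
            for split in range(lo_split, max_split + 1):
                n_mm = mm_at[split]
                if n_mm > params.max_mismatches:
                    continue
                score = split - 2 * n_mm
                yield (-score, L - split, n_mm, pid, start, split)


def map_read(
    read_seq: str,
    refset: ReferenceSet,
    params: MapParams = MapParams(),
    read_id: str = "read",
) -> Optional[ReadAlignment]:
    """Best templated-prefix alignment of a read, or None if unmapped."""
    seq = normalize_rna(read_seq, what=f"read {read_id!r}")
    if len(seq) < params.min_templated:
        return None
    candidates = list(_candidate_alignments(seq, refset, params))
    if not candidates:
        return None
    best = min(candidates)
    neg_score, _n_nta, _n_mm, pid, start, split = best
    # ambiguity: an equal-score survivor on a different precursor
    ambiguous = any(c[0] == neg_score and c[3] != pid for c in candidates)
    prec = refset.precursors[pid].sequence
    mismatches = tuple(
        start + j for j in range(split) if seq[j] != prec[start + j]
    )
    aln = ReadAlignment(
        read_id=read_id,
        read_seq=seq,
        precursor_id=pid,
        start=start,
        end=start + split,
        mismatch_positions=mismatches,
        nta=seq[split:],
        score=-neg_score,
        ambiguous=ambiguous,
    )
    assert reconstruct(aln, refset) == seq, "reconstruction invariant violated"
    return aln


def reconstruct(aln: ReadAlignment, refset: ReferenceSet) -> str:
    """Rebuild the read from its alignment (the reconstruction rule)."""
    prec = refset.precursors[aln.precursor_id].sequence
    core = list(prec[aln.start:aln.end])
    for pos in aln.mismatch_positions:
        core[pos - aln.start] = aln.read_seq[pos - aln.start]
    return "".join(core) + aln.nta


def classify_isomir(aln: ReadAlignment, refset: ReferenceSet) -> IsomiRCall:
    """Assign the alignment to the mature it overlaps most (ties -> 5p)."""
    matures = refset.matures_of(aln.precursor_id)
    best: Optional[MatureAnnotation] = None
    best_overlap = 0
    for m in matures:  # matures_of orders 5p first, so ties keep 5p
        overlap = min(aln.end, m.end) - max(aln.start, m.start)
        if overlap > best_overlap:
            best, best_overlap = m, overlap
    if best is None:
        return IsomiRCall(
            read_id=aln.read_id, mature_id="unassigned", arm="NA",
            offset5=0, offset3=0, nta=aln.nta,
            n_subs=len(aln.mismatch_positions),
        )
    return IsomiRCall(
        read_id=aln.read_id,
        mature_id=best.id,
        arm=best.arm,
        offset5=aln.start - best.start,
        offset3=aln.end - best.end,
        nta=aln.nta,
        n_subs=len(aln.mismatch_positions),
    )


ClassKey = tuple[str, int, int, str]  # (mature_id, offset5, offset3, nta)


@dataclass
class IsomiRProfile:
    """Per-miRNA isomiR tallies for one library.

    ``class_counts`` is keyed by (mature_id, offset5, offset3, nta);
    ``seq_counts`` by (mature_id, full read string).  RPM uses reads
    mapped to any precursor of the ReferenceSet as the denominator.
    """

    library_id: str
    total_mapped_reads: int = 0
    unmapped_reads: int = 0
    dropped_short_reads: int = 0
    ambiguous_reads: int = 0
    class_counts: dict[ClassKey, int] = field(default_factory=dict)
    seq_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    seq_class: dict[tuple[str, str], tuple[int, int, str, int]] = field(default_factory=dict)
    mature_index: dict[str, tuple[str, str]] = field(default_factory=dict)  # mature -> (precursor, arm)

    def rpm(self, key: ClassKey) -> float:
        if self.total_mapped_reads == 0:
            raise ValueError("profile has no mapped reads")
        return 1e6 * self.class_counts.get(key, 0) / self.total_mapped_reads

    def mature_reads(self, mature_id: str) -> int:
        return sum(
            c for k, c in self.class_counts.items() if k[0] == mature_id
        )

    def mature_rpm(self, mature_id: str) -> float:
        if self.total_mapped_reads == 0:
            raise ValueError("profile has no mapped reads")
        return 1e6 * self.mature_reads(mature_id) / self.total_mapped_reads

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (mid, o5, o3, nta), count in sorted(self.class_counts.items()):
            prec, arm = self.mature_index.get(mid, ("NA", "NA"))
            rows.append({
                "library_id": self.library_id,
                "mature_id": mid,
                "precursor_id": prec,
                "arm": arm,
                "offset5": o5,
                "offset3": o3,
                "nta": nta,
                "count": count,
                "rpm": 1e6 * count / self.total_mapped_reads,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def iter_reads(source) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTA/FASTQ path or an iterable."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield rec.id, str(rec.seq)
    else:
        for item in source:
            if hasattr(item, "read_id"):
                yield item.read_id, item.sequence
            else:
                yield item


def profile(
    reads, refset: ReferenceSet,
    params: MapParams = MapParams(),
    library_id: str = "library",
) -> IsomiRProfile:
    """Map and classify every read of a library into an IsomiRProfile.

    Reads shorter than ``params.min_templated`` are dropped (counted);
    unmapped reads are tallied separately; multimapping reads count once
    at the deterministic winner and increment ``ambiguous_reads``.
    """
    prof = IsomiRProfile(library_id=library_id)
    n_input = 0
    cache: dict[str, Optional[ReadAlignment]] = {}  # mapping is read-id independent
    for read_id, seq in iter_reads(reads):
        n_input += 1
        seq = normalize_rna(seq, what=f"read {read_id!r}")
        if len(seq) < params.min_templated:
            prof.dropped_short_reads += 1
            continue
        if seq in cache:
            aln = cache[seq]
        else:
            aln = map_read(seq, refset, params, read_id=read_id)
            cache[seq] = aln
        if aln is None:
            prof.unmapped_reads += 1
            continue
        if aln.ambiguous:
            prof.ambiguous_reads += 1
        call = classify_isomir(aln, refset)
        key = (call.mature_id, call.offset5, call.offset3, call.nta)
        prof.class_counts[key] = prof.class_counts.get(key, 0) + 1
        skey = (call.mature_id, seq)
        prof.seq_counts[skey] = prof.seq_counts.get(skey, 0) + 1
        prof.seq_class[skey] = (call.offset5, call.offset3, call.nta, call.n_subs)
        prof.total_mapped_reads += 1
        if call.mature_id != "unassigned":
            ann = refset.matures[call.mature_id]
            prof.mature_index[call.mature_id] = (ann.precursor_id, ann.arm)
    if n_input == 0:
        raise ValueError("empty read input")
    if prof.dropped_short_reads:
        logger.info(
            "dropped %d reads shorter than %d nt",
            prof.dropped_short_reads, params.min_templated,
        )
    return prof


def arm_fraction(prof: IsomiRProfile, precursor_id: str) -> Optional[float]:
    """Fraction of a precursor's assigned reads coming from the 5p arm.

    Returns None (missing) when the precursor has no reads.
    """
    n5 = n3 = 0
    for (mid, *_), count in prof.class_counts.items():
        info = prof.mature_index.get(mid)
        if info is None or info[0] != precursor_id:
            continue
        if info[1] == "5p":
            n5 += count
        else:
            n3 += count
    total = n5 + n3
    if total == 0:
        return None
    return n5 / total


@dataclass(frozen=True)
class FoldChange:
    """RPM-based expression ratio between two libraries (raw ratio kept)."""

    mature_id: str
    rpm_ratio: float
    raw_ratio: float
    infinite: bool


def fold_change(
    profile_a: IsomiRProfile,
    profile_b: IsomiRProfile,
    mature_id: str,
    pseudocount: float = 0.0,
) -> FoldChange:
    """RPM(a)/RPM(b) for one mature; +inf (flagged) when RPM(b) is 0.

    ``pseudocount`` (e.g. 0.5) is added to both raw counts before
    normalization when non-zero; the default adds none.
    """
    count_a = profile_a.mature_reads(mature_id)
    count_b = profile_b.mature_reads(mature_id)
    if count_a == 0 and count_b == 0 and pseudocount == 0.0:
        raise ValueError(f"mature {mature_id!r} absent from both profiles")
    rpm_a = 1e6 * (count_a + pseudocount) / profile_a.total_mapped_reads
    rpm_b = 1e6 * (count_b + pseudocount) / profile_b.total_mapped_reads
    if rpm_b == 0.0:
        return FoldChange(mature_id, math.inf, math.inf, True)
    raw = (count_a + pseudocount) / (count_b + pseudocount)
    return FoldChange(mature_id, rpm_a / rpm_b, raw, False)


@dataclass
class LogoMatrix:
    """Position-probability matrix of reads over a precursor window.

    ``matrix`` has one row per window position and one column per
    nucleotide (A, C, G, U); rows with positive ``support`` sum to 1.
    NTA bases are placed at the positions immediately past each read's
    templated end.
    """

    precursor_id: str
    window_start: int
    window_end: int
    matrix: np.ndarray
    support: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.matrix, columns=list(NUCLEOTIDES),
            index=pd.Index(
                range(self.window_start, self.window_end), name="position"
            ),
        )
        frame["support"] = self.support
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def plot(self, ax=None, annotated: Optional[str] = None):
        """Stacked-bar rendering of the probability matrix (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(0.35 * len(self.support), 2.2))
        colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
        x = np.arange(self.window_start, self.window_end)
        bottom = np.zeros(len(x))
        for j, nt in enumerate(NUCLEOTIDES):
            ax.bar(x, self.matrix[:, j], bottom=bottom,
                   color=colors[nt], label=nt, width=0.9)
            bottom += self.matrix[:, j]
        ax.set_xlabel("precursor position")
        ax.set_ylabel("probability")
        ax.legend(ncol=4, fontsize=8)
        return ax


def logo_matrix(
    prof: IsomiRProfile,
    refset: ReferenceSet,
    mature_id: str,
    flank: int = 2,
    params: MapParams = MapParams(),
) -> LogoMatrix:
    """Count-weighted per-position nucleotide probabilities for a mature.

    Each distinct read sequence assigned to the mature is re-placed at
    its precursor coordinates; the window spans the annotated mature
    plus ``flank`` positions on each side.
    """
    ann = refset.matures.get(mature_id)
    if ann is None:
        raise ReferenceError(f"unknown mature id {mature_id!r}")
    seqs = {
        seq: count for (mid, seq), count in prof.seq_counts.items()
        if mid == mature_id
    }
    if not seqs:
        raise ValueError(f"no reads assigned to {mature_id!r}")
    prec = refset.precursors[ann.precursor_id]
    w0 = max(0, ann.start - flank)
    w1 = min(len(prec), ann.end + flank)
    width = w1 - w0
    counts = np.zeros((width, 4), dtype=float)
    nt_index = {nt: j for j, nt in enumerate(NUCLEOTIDES)}
    for seq, count in sorted(seqs.items()):
        aln = map_read(seq, refset, params)
        if aln is None or aln.precursor_id != ann.precursor_id:
            continue
        for j, base in enumerate(seq):
            pos = aln.start + j  # NTA bases extend past the templated end
            if w0 <= pos < w1:
                counts[pos - w0, nt_index[base]] += count
    support = counts.sum(axis=1)
    matrix = np.zeros_like(counts)
    nz = support > 0
    matrix[nz] = counts[nz] / support[nz, None]
    return LogoMatrix(
        precursor_id=ann.precursor_id, window_start=w0, window_end=w1,
        matrix=matrix, support=support,
    )
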