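"""Seed-match site scanning and isoform target-repertoire overlap.

A miRNA represses an mRNA whose 3'UTR carries the exact Watson-Crick
reverse complement of the miRNA seed.  Site types follow the standard
canonical-site nomenclature; positions refer to the mature miRNA
(1-based, 5' to 3'):

=============  ==========================  ======================
site type      seed span on the mature     UTR motif
=============  ==========================  ======================
site_5mer_2_6  2-6 (Argonaute-exposed)     rc(2-6)
site_6mer_2_7  2-7 (canonical seed)        rc(2-7)
site_7mer_m8   2-8                         rc(2-8)
site_7mer_A1   2-7 + A opposite position 1 rc(2-7) + A
site_8mer      2-8 + A opposite position 1 rc(2-8) + A
=============  ==========================  ======================

Matching is exact in RNA space; G:U wobble pairing is not counted.
A 1-nt 5' shift of the mature changes the seed by one base, so on
random sequence only ~1/4 of one isoform's sites are, by chance, also
sites of the shifted isoform — the null the overlap statistics quantify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .references import ReferenceError, SeedSpec, normalize_rna

#: site type -> (seed span on the mature, anchored A opposite position 1)
SITE_TYPES: dict[str, tuple[SeedSpec, bool]] = {
    "site_5mer_2_6": (SeedSpec(2, 6, "exposed_2_6"), False),
    "site_6mer_2_7": (SeedSpec(2, 7, "seed_2_7"), False),
    "site_7mer_m8": (SeedSpec(2, 8, "seed_2_8"), False),
    "site_7mer_A1": (SeedSpec(2, 7, "seed_2_7"), True),
    "site_8mer": (SeedSpec(2, 8, "seed_2_8"), True),
}


class TargetingError(ValueError):
    pass


@dataclass(frozen=True)
class SeedMatch:
    utr_id: str
    start: int     # 0-based half-open on the UTR
    end: int
    site_type: str
    matched_seed: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _revcomp_rna(seq: str) -> str:
    return str(Seq(seq).reverse_complement_rna())


def seed_site(mature_seq: str, site_type: str) -> str:
    """UTR motif (5'->3') targeted by a mature's seed for one site type.

    The motif is the reverse complement of the seed span; A1-anchored
    types append the adenine opposite mature position 1 (3' of the
    seed-pairing bases on the UTR).
    """
    if site_type not in SITE_TYPES:
        raise TargetingError(f"unknown site type {site_type!r}")
    spec, anchored = SITE_TYPES[site_type]
    seq = normalize_rna(mature_seq, what="mature")
    if len(seq) < spec.end_pos:
        raise TargetingError(
            f"mature of length {len(seq)} too short for {site_type}"
        )
    seed = seq[spec.start_pos - 1 : spec.end_pos]
    motif = _revcomp_rna(seed)
    if anchored:
        motif += "A"
    return motif


def scan_utr(
    utr_seq: str,
    mature_seq: str,
    site_types: Iterable[str] = ("site_6mer_2_7",),
    utr_id: str = "utr",
) -> list[SeedMatch]:
    """All exact seed-site matches of a mature in one UTR.

    Overlapping occurrences are all reported; output is ordered by
    position, then by site type name.
    """
    utr = normalize_rna(utr_seq, what=f"UTR {utr_id!r}")
    if not utr:
        raise TargetingError("empty UTR")
    matches: list[SeedMatch] = []
    for site_type in sorted(site_types):
        motif = seed_site(mature_seq, site_type)
        seed = SITE_TYPES[site_type][0]
        seed_str = normalize_rna(mature_seq)[seed.start_pos - 1 : seed.end_pos]
        i = utr.find(motif)
        while i >= 0:
            matches.append(SeedMatch(utr_id, i, i + len(motif), site_type, seed_str))
            i = utr.find(motif, i + 1)
    return sorted(matches, key=lambda m: (m.start, m.site_type))


@dataclass(frozen=True)
class OverlapStats:
    """Target-site overlap between two miRNA isoforms over a UTR set."""

    n_sites_a: int
    n_sites_b: int
    n_shared: int          # one-to-one matched overlapping site pairs
    jaccard: float
    retention_a_in_b: float  # fraction of a's sites with >=1 overlapping b site

    def to_dict(self) -> dict:
        return asdict(self)


def _overlaps(a: SeedMatch, b: SeedMatch) -> bool:
    return a.start < b.end and b.start < a.end


def _match_one_to_one(sa: Sequence[SeedMatch], sb: Sequence[SeedMatch]) -> int:
    """Greedy one-to-one interval matching of two position-sorted lists."""
    i = j = shared = 0
    while i < len(sa) and j < len(sb):
        if _overlaps(sa[i], sb[j]):
            shared += 1
            i += 1
            j += 1
        elif sa[i].end <= sb[j].start:
            i += 1
        else:
            j += 1
    return shared


def _load_utrs(utrs) -> dict[str, str]:
    if isinstance(utrs, Mapping):
        if not utrs:
            raise TargetingError("empty UTR set")
        return {k: normalize_rna(v, what=f"UTR {k!r}") for k, v in utrs.items()}
    path = Path(utrs)
    if not path.exists():
        raise TargetingError(f"UTR FASTA not found: {path}")
    out = {
        rec.id: normalize_rna(str(rec.seq), what=f"UTR {rec.id!r}")
        for rec in SeqIO.parse(str(path), "fasta")
    }
    if not out:
        raise TargetingError(f"no UTR records in {path}")
    return out


def isoform_target_overlap(
    mature_a: str,
    mature_b: str,
    utrs,
    site_type: str = "site_6mer_2_7",
) -> OverlapStats:
    """Quantify how much of isoform a's site repertoire isoform b retains.

    ``utrs`` is a FASTA path or a mapping id -> sequence.  Sites overlap
    when they share at least one UTR position; ``n_shared`` counts
    one-to-one matched pairs (so it never exceeds either site total),
    while ``retention_a_in_b`` is the plain fraction of a's sites having
    any overlapping b site.
    """
    utr_map = _load_utrs(utrs)
    n_a = n_b = n_shared = n_retained = 0
    for utr_id in sorted(utr_map):
        sa = scan_utr(utr_map[utr_id], mature_a, [site_type], utr_id=utr_id)
        sb = scan_utr(utr_map[utr_id], mature_b, [site_type], utr_id=utr_id)
        n_a += len(sa)
        n_b += len(sb)
        n_shared += _match_one_to_one(sa, sb)
        n_retained += sum(1 for a in sa if any(_overlaps(a, b) for b in sb))
    union = n_a + n_b - n_shared
    jaccard = n_shared / union if union > 0 else 0.0
    retention = n_retained / n_a if n_a > 0 else 0.0
    return OverlapStats(n_a, n_b, n_shared, jaccard, retention)


def sites_to_frame(matches: Iterable[SeedMatch], isoform: str = "") -> pd.DataFrame:
    """BED-like table (utr_id, start, end, site_type, isoform)."""
    rows = [
        {
            "utr_id": m.utr_id, "start": m.start, "end": m.end,
            "site_type": m.site_type, "isoform": isoform,
        }
        for m in matches
    ]
    return pd.DataFrame(rows, columns=["utr_id", "start", "end", "site_type", "isoform"])


def write_overlap_json(stats: OverlapStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2))
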