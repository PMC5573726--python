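"""miR-34 family fixture sequences on synthetic hairpins.

The mature miR-34 family sequences below are the public miRBase
annotations.  The hairpins here are SYNTHETIC constructs: scaffolding
built around each mature so that the precursor-dependent operations
(templated shifts, non-templated-addition calls, logo windows) are
exercised without shipping full precursor databases.  They are not the
genomic hsa-mir-34 precursors.

The one biologically meaningful construction choice: the precursor base
immediately 3' of annotated miR-34b-5p is U, so the 1-nt 5'-shifted,
length-preserving variant of miR-34b-5p produced by
:func:`isomirkit.references.shift_mature` equals the endogenous variant
(the sequence curated by MiRGeneDB).  Everything downstream of the seed
comparison is insensitive to this base.
"""

from __future__ import annotations

from .references import ReferenceSet, build_reference_set, shift_mature

#: annotated mature sequences (miRBase)
MIR_34A_5P = "UGGCAGUGUCUUAGCUGGUUGU"
MIR_34B_5P = "UAGGCAGUGUCAUUAGCUGAUUG"
MIR_34C_5P = "AGGCAGUGUAGUUAGCUGAUUGC"

MATURES: dict[str, str] = {
    "hsa-miR-34a-5p": MIR_34A_5P,
    "hsa-miR-34b-5p": MIR_34B_5P,
    "hsa-miR-34c-5p": MIR_34C_5P,
}

# neutral stuffer keeping matures in the 5' half so arm inference says 5p;
# chosen free of every miR-34 seed-region substring
_STUFFER = "CCAACCAACCAACCAACCAACCAACCAACCAACCAACC"


def _synthetic_hairpin(mature: str, downstream: str = "UA") -> str:
    """5' flank + mature + templated downstream context + stuffer."""
    return "GCGGGC" + mature + downstream + _STUFFER


#: synthetic precursors (see module docstring)
HAIRPINS: dict[str, str] = {
    "syn-mir-34a": _synthetic_hairpin(MIR_34A_5P),
    "syn-mir-34b": _synthetic_hairpin(MIR_34B_5P, downstream="UA"),
    "syn-mir-34c": _synthetic_hairpin(MIR_34C_5P),
}


def build_mir34_reference() -> ReferenceSet:
    """ReferenceSet with the three miR-34 matures on synthetic hairpins."""
    return build_reference_set(sorted(HAIRPINS.items()), sorted(MATURES.items()))


def mir34b_shifted_variant(refset: ReferenceSet | None = None) -> str:
    """Sequence of the +1/+1-shifted (length-preserving) miR-34b-5p variant."""
    rs = refset if refset is not None else build_mir34_reference()
    return shift_mature(rs, "hsa-miR-34b-5p", +1, +1).sequence
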