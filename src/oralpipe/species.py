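"""Species-name assignment from type-strain 16S fragments.

A sequence variant receives a species name only when type-strain
fragments of exactly one described species align to it with at most two
mismatches.  When several species tie within the threshold no name is
assigned and the variant is annotated as related to the whole group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

MAX_MISMATCHES = 2

# IUPAC nucleotide ambiguity codes -> base sets
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

#: V1-V2 amplification primers (forward 27Fbif, reverse 338R), 5'->3'
FWD_PRIMER = "AGRGTTHGATYMTGGCTCAG"
REV_PRIMER = "TGCTGCCTCCCGTAGGAGT"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def bases_compatible(a: str, b: str) -> bool:
    """True when the base sets of two IUPAC codes intersect."""
    try:
        return bool(IUPAC[a.upper()] & IUPAC[b.upper()])
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc}") from None


@dataclass
class ReferenceFragment:
    """A trimmed type-strain 16S fragment carrying its species name."""

    species: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty reference sequence for {self.species!r}")
        bad = set(self.sequence) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in {self.species!r}: {sorted(bad)}")


@dataclass
class SpeciesCall:
    variant_id: str
    assigned: str | None
    candidates: dict[str, int] = field(default_factory=dict)  # species -> min mismatches (<= threshold)
    annotation: str | None = None


def _find_primer(seq: str, primer: str, max_mm: int = 1) -> tuple[int, int] | None:
    """Leftmost primer site with at most ``max_mm`` incompatible columns."""
    n, m = len(seq), len(primer)
    for start in range(n - m + 1):
        mm = 0
        for i in range(m):
            if not bases_compatible(primer[i], seq[start + i]):
                mm += 1
                if mm > max_mm:
                    break
        else:
            return start, start + m
    return None


def trim_to_region(reference: str, fwd_primer: str = FWD_PRIMER,
                   rev_primer: str = REV_PRIMER) -> str | None:
    """Extract the amplified region strictly between the primer sites.

    The reverse primer is matched as its reverse complement downstream of
    the forward site.  One mismatch is tolerated per primer (type-strain
    records may carry sequencing errors).  Returns ``None`` when either
    site is absent.
    """
    reference = reference.upper()
    fwd = _find_primer(reference, fwd_primer.upper())
    if fwd is None:
        log.info("forward primer not found; reference skipped")
        return None
    rev_site = reverse_complement(rev_primer)
    hit = _find_primer(reference[fwd[1]:], rev_site)
    if hit is None:
        log.info("reverse primer not found; reference skipped")
        return None
    start = fwd[1]
    return reference[start: start + hit[0]]


def count_mismatches(variant: str, fragment: str) -> int:
    """Mismatches in the best semi-global alignment of variant vs fragment.

    The shorter sequence is aligned in full against the longer with free
    end gaps on the longer only (trimmed extents may differ slightly at
    the ends); the count is substitution columns plus internal gap
    columns, all at unit weight.  An IUPAC ambiguity code compatible
    with the observed base is a match.
    """
    a, b = variant.upper(), fragment.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) > len(b):
        a, b = b, a  # a: shorter (fully aligned), b: longer (free ends)
    n, m = len(a), len(b)
    prev = [0] * (m + 1)  # cost of aligning a[:0] before any b position
    for i in range(1, n + 1):
        cur = [i] + [0] * m  # leading gap in b costs i
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if bases_compatible(ai, b[j - 1]) else 1)
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # trailing end of b is free


def assign_species(variant_id: str, variant_seq: str,
                   refs: list[ReferenceFragment],
                   max_mismatches: int = MAX_MISMATCHES) -> SpeciesCall:
    """Apply the single-species <=2-mismatch rule against references."""
    if not refs:
        raise ValueError("reference set is empty")
    best: dict[str, int] = {}
    for ref in refs:
        mm = count_mismatches(variant_seq, ref.sequence)
        if ref.species not in best or mm < best[ref.species]:
            best[ref.species] = mm
    candidates = {sp: mm for sp, mm in sorted(best.items()) if mm <= max_mismatches}
    if len(candidates) == 1:
        assigned = next(iter(candidates))
        return SpeciesCall(variant_id, assigned, candidates)
    annotation = None
    if len(candidates) > 1:
        annotation = "related to " + ", ".join(sorted(candidates))
    return SpeciesCall(variant_id, None, candidates, annotation)


def read_reference_fasta(path: str | Path, trim: bool = False) -> list[ReferenceFragment]:
    """Load references from FASTA with ``Species_name|strain`` headers.

    With ``trim=True`` each record is first reduced to its amplified
    region; records lacking a primer site are skipped with a log message.
    """
    refs: list[ReferenceFragment] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = rec.id.split("|")[0].replace("_", " ")
        seq = str(rec.seq)
        if trim:
            trimmed = trim_to_region(seq)
            if trimmed is None:
                log.warning("no primer sites in %s; skipped", rec.id)
                continue
            seq = trimmed
        refs.append(ReferenceFragment(species=species, sequence=seq))
    return refs


def assignment_table(calls: list[SpeciesCall]):
    """Tabulate calls: variant_id, call, candidates, mismatches."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "variant_id": c.variant_id,
            "call": c.assigned or "",
            "candidates": ";".join(sorted(c.candidates)),
            "mismatches": ";".join(str(c.candidates[s]) for s in sorted(c.candidates)),
            "annotation": c.annotation or "",
        })
    return pd.DataFrame(rows)
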