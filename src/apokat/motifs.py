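"""Classification of SNVs against the three APOBEC-like trinucleotide motifs.

The motifs — written 5'->3' with IUPAC ambiguity codes, ">" marking the
substitution — are::

    T(C>K)W   K = G/T,   W = A/T
    T(C>D)R   D = A/G/T, R = A/G
    T(C>D)D

A motif matches on the plus strand when the reference-strand triplet around
a C>alt substitution reads T, C, three-prime with alt in the allowed set; it
matches on the minus strand when the reverse complement of the triplet (a
G>alt change on the reference strand) does.  For a given SNV and motif class
at most one strand can match, because the center must be C on the matching
strand and G on the other.  T(C>K)W and T(C>D)R are both strict
specializations of T(C>D)D, so any match of either implies a T(C>D)D match
on the same strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import COMPLEMENT, VALID_BASES, SNVRecord

#: IUPAC ambiguity sets used by the motif definitions.
IUPAC = {
    "K": frozenset("GT"),
    "W": frozenset("AT"),
    "R": frozenset("AG"),
    "D": frozenset("AGT"),
}


@dataclass(frozen=True)
class MotifClass:
    """One APOBEC-like motif: required flanks and allowed substitution set."""

    name: str
    five_prime: frozenset[str]
    center_ref: frozenset[str]
    alt_set: frozenset[str]
    three_prime: frozenset[str]


MOTIF_CLASSES: dict[str, MotifClass] = {
    "TCKW": MotifClass("TCKW", frozenset("T"), frozenset("C"), IUPAC["K"], IUPAC["W"]),
    "TCDR": MotifClass("TCDR", frozenset("T"), frozenset("C"), IUPAC["D"], IUPAC["R"]),
    "TCDD": MotifClass("TCDD", frozenset("T"), frozenset("C"), IUPAC["D"], IUPAC["D"]),
}

MOTIF_NAMES = tuple(MOTIF_CLASSES)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class MotifEvent:
    """An SNV matched to a motif class on the strand where it reads 5'-TCN-3'."""

    snv: SNVRecord
    motif: str
    strand: str

    @property
    def chrom(self) -> str:
        return self.snv.chrom

    @property
    def pos(self) -> int:
        return self.snv.pos

    @property
    def cell_line_id(self) -> str:
        return self.snv.cell_line_id


def _matches_plus(
    mc: MotifClass, context5: str, ref: str, alt: str, context3: str
) -> bool:
    return (
        context5 in mc.five_prime
        and ref in mc.center_ref
        and alt in mc.alt_set
        and context3 in mc.three_prime
    )


def classify(
    context5: str, ref: str, alt: str, context3: str
) -> set[tuple[str, str]]:
    """Return every (motif name, strand) matching the given substitution.

    ``context5``/``context3`` are the reference-strand flanks; a minus-strand
    match tests the reverse-complemented triplet with the complemented
    substitution.  One SNV may match several motif classes but never both
    strands within one class.
    """
    for base in (context5, ref, alt, context3):
        if base not in VALID_BASES:
            raise ValueError(f"invalid base {base!r}; expected one of ACGT")
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    # Reverse complement: the minus-strand 5' flank is the complement of the
    # reference-strand 3' flank, and vice versa.
    rc5, rcref, rcalt, rc3 = (
        COMPLEMENT[context3],
        COMPLEMENT[ref],
        COMPLEMENT[alt],
        COMPLEMENT[context5],
    )
    hits: set[tuple[str, str]] = set()
    for name, mc in MOTIF_CLASSES.items():
        if _matches_plus(mc, context5, ref, alt, context3):
            hits.add((name, "+"))
        if _matches_plus(mc, rc5, rcref, rcalt, rc3):
            hits.add((name, "-"))
    return hits


def annotate_events(records: Iterable[SNVRecord]) -> list[MotifEvent]:
    """One MotifEvent per matching (record, motif class, strand).

    Records without full unambiguous context are skipped (they remain in the
    total SNV count but cannot be motif-classified).  Output is sorted by
    (chrom, pos, motif, strand) and is deterministic.
    """
    events: list[MotifEvent] = []
    for rec in records:
        if not rec.has_context:
            continue
        for motif, strand in classify(rec.context5, rec.ref, rec.alt, rec.context3):
            events.append(MotifEvent(snv=rec, motif=motif, strand=strand))
    events.sort(key=lambda e: (e.chrom, e.pos, e.motif, e.strand))
    return events


def events_to_frame(events: Sequence[MotifEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": [e.cell_line_id for e in events],
            "chrom": [e.chrom for e in events],
            "pos": [e.pos for e in events],
            "ref": [e.snv.ref for e in events],
            "alt": [e.snv.alt for e in events],
            "motif": [e.motif for e in events],
            "strand": [e.strand for e in events],
        }
    )


def write_events_tsv(events: Sequence[MotifEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def write_events_bed(events: Sequence[MotifEvent], path: str | Path) -> None:
    """BED export of event positions.

    BED is 0-based, half-open: a 1-based position p becomes the interval
    [p-1, p).  The conversion happens only here, at the export boundary.
    """
    with open(path, "w") as fh:
        for e in events:
            name = f"{e.cell_line_id}:{e.motif}"
            fh.write(
                f"{e.chrom}\t{e.pos - 1}\t{e.pos}\t{name}\t0\t{e.strand}\n"
            )
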