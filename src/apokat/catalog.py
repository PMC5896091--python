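"""Per-cell-line SNV catalogs: reading, population-AF filtering, mutation counts.

A catalog is a list of :class:`SNVRecord` — biallelic single-nucleotide
substitutions with their immediate 5'/3' reference-strand context, belonging
to one cell line.  Coordinates are 1-based, inclusive (VCF convention)
throughout the package.

The seven per-cell-line mutation-count categories live here: C>G, C>T and
C>K (= C>G or C>T) counted on the reference strand alone and on both strands
(i.e. additionally counting the reverse-complement change read on the
reference strand), plus the total SNV count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Column order of the canonical catalog TSV dialect.
CATALOG_COLUMNS = [
    "cell_line",
    "chrom",
    "pos",
    "ref",
    "alt",
    "context5",
    "context3",
    "pop_af",
]


@dataclass(frozen=True)
class SNVRecord:
    """One single-nucleotide substitution on the reference (plus) strand.

    Parameters
    ----------
    cell_line_id
        Owning cell line.
    chrom, pos
        Genomic location, 1-based.
    ref, alt
        Reference and alternate base, uppercase ACGT, ``ref != alt``.
    context5, context3
        Reference-strand bases immediately 5' and 3' of ``pos``.  ``None``
        when the flank is unavailable (chromosome edge or masked base);
        such records are excluded from motif analysis but still counted
        in the total SNV tally.
    pop_af
        Population (panel) allele frequency in [0, 1], or ``None`` when the
        variant is absent from the panel.
    """

    cell_line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context5: str | None = None
    context3: str | None = None
    pop_af: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(
                f"ref/alt must be single ACGT bases, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("context5", "context3"):
            base = getattr(self, name)
            if base is not None and base not in VALID_BASES:
                # N or other ambiguity codes: treat the flank as unavailable.
                object.__setattr__(self, name, None)
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"pop_af must lie in [0,1], got {self.pop_af}")

    @property
    def has_context(self) -> bool:
        """Whether both flanking bases are known unambiguous ACGT."""
        return self.context5 is not None and self.context3 is not None


@dataclass(frozen=True)
class MutationCounts:
    """The seven per-cell-line substitution-count categories."""

    cell_line_id: str
    c_to_g_ref: int
    c_to_t_ref: int
    c_to_k_ref: int
    c_to_g_both: int
    c_to_t_both: int
    c_to_k_both: int
    all_snv: int

    def __post_init__(self) -> None:
        assert self.c_to_k_ref == self.c_to_g_ref + self.c_to_t_ref
        assert self.c_to_k_both == self.c_to_g_both + self.c_to_t_both
        assert self.c_to_g_both >= self.c_to_g_ref
        assert self.c_to_t_both >= self.c_to_t_ref
        assert self.all_snv >= self.c_to_k_both


class RefMismatchError(ValueError):
    """Raised when a variant's REF base disagrees with the reference FASTA."""


def _sorted_records(records: Iterable[SNVRecord]) -> list[SNVRecord]:
    return sorted(records, key=lambda r: (r.chrom, r.pos))


def read_catalog(
    variant_file: str | Path,
    reference: str | Path | None,
    cell_line_id: str,
) -> list[SNVRecord]:
    """Read biallelic SNVs for one cell line from a VCF.

    Trinucleotide context is taken from ``reference`` (an indexed FASTA) at
    ``pos - 1`` and ``pos + 1``.  Indels and multiallelic sites are skipped
    with a logged count.  Population allele frequency is read from the AF
    INFO field when present.

    Raises
    ------
    ValueError
        If no context source is available (``reference`` is None).
    RefMismatchError
        If a record's REF base disagrees with the FASTA.
    """
    import pysam
    from cyvcf2 import VCF

    if reference is None:
        raise ValueError(
            "read_catalog requires a reference FASTA for trinucleotide context; "
            "use read_catalog_tsv for pre-annotated input"
        )

    fasta = pysam.FastaFile(str(reference))
    records: list[SNVRecord] = []
    n_skipped = 0
    try:
        for variant in VCF(str(variant_file)):
            ref = variant.REF.upper()
            alts = [a.upper() for a in variant.ALT]
            if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            alt = alts[0]
            if ref not in VALID_BASES or alt not in VALID_BASES or ref == alt:
                n_skipped += 1
                continue
            chrom = variant.CHROM
            pos = variant.POS  # 1-based
            if chrom not in fasta.references:
                raise ValueError(f"chromosome {chrom!r} absent from reference FASTA")
            chrom_len = fasta.get_reference_length(chrom)
            fasta_ref = fasta.fetch(chrom, pos - 1, pos).upper()
            if fasta_ref != ref:
                raise RefMismatchError(
                    f"REF mismatch at {chrom}:{pos}: VCF has {ref}, FASTA has {fasta_ref}"
                )
            context5 = fasta.fetch(chrom, pos - 2, pos - 1).upper() if pos >= 2 else None
            context3 = (
                fasta.fetch(chrom, pos, pos + 1).upper() if pos < chrom_len else None
            )
            af = variant.INFO.get("AF")
            if isinstance(af, (tuple, list)):
                af = af[0]
            records.append(
                SNVRecord(
                    cell_line_id=cell_line_id,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    context5=context5 if context5 in VALID_BASES else None,
                    context3=context3 if context3 in VALID_BASES else None,
                    pop_af=float(af) if af is not None else None,
                )
            )
    finally:
        fasta.close()
    if n_skipped:
        logger.info(
            "read_catalog(%s): skipped %d non-SNV/multiallelic records",
            variant_file,
            n_skipped,
        )
    return _sorted_records(records)


def read_catalog_tsv(path: str | Path) -> list[SNVRecord]:
    """Read a pre-annotated catalog TSV (columns as in ``CATALOG_COLUMNS``).

    May contain several cell lines; records are returned sorted by
    (cell_line, chrom, pos).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "cell_line": str},
        float_precision="round_trip",
    )
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog TSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SNVRecord(
                cell_line_id=row.cell_line,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                context5=None if pd.isna(row.context5) else str(row.context5),
                context3=None if pd.isna(row.context3) else str(row.context3),
                pop_af=None if pd.isna(row.pop_af) else float(row.pop_af),
            )
        )
    return sorted(records, key=lambda r: (r.cell_line_id, r.chrom, r.pos))


def write_catalog_tsv(records: Sequence[SNVRecord], path: str | Path) -> None:
    """Write records in the canonical catalog TSV dialect."""
    df = pd.DataFrame(
        {
            "cell_line": [r.cell_line_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "context5": [r.context5 if r.context5 else "" for r in records],
            "context3": [r.context3 if r.context3 else "" for r in records],
            "pop_af": ["" if r.pop_af is None else repr(r.pop_af) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def filter_common_variants(
    records: Sequence[SNVRecord], af_threshold: float = 0.01
) -> list[SNVRecord]:
    """Drop common population variants (panel allele frequency > threshold).

    The cut is strictly greater-than; a record exactly at the threshold is
    kept.  Records with no panel frequency are treated as rare and kept.
    Input order is preserved.
    """
    if not (0.0 < af_threshold < 1.0):
        raise ValueError(f"af_threshold must lie in (0,1), got {af_threshold}")
    return [r for r in records if r.pop_af is None or r.pop_af <= af_threshold]


def mutation_counts(records: Sequence[SNVRecord]) -> MutationCounts:
    """Compute the seven substitution-count categories for one cell line.

    Reference-strand counters count records whose (ref, alt) equals the named
    change; both-strand counters additionally count the reverse-complement
    change as it appears on the reference strand (C>T both = C>T + G>A;
    C>G both = C>G + G>C).  ``all_snv`` is the total record count.
    """
    ids = {r.cell_line_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"mutation_counts requires one cell line, got {sorted(ids)}")
    cell_line_id = next(iter(ids)) if ids else ""

    def count(ref: str, alt: str) -> int:
        return sum(1 for r in records if r.ref == ref and r.alt == alt)

    c_to_g_ref = count("C", "G")
    c_to_t_ref = count("C", "T")
    c_to_g_both = c_to_g_ref + count("G", "C")
    c_to_t_both = c_to_t_ref + count("G", "A")
    return MutationCounts(
        cell_line_id=cell_line_id,
        c_to_g_ref=c_to_g_ref,
        c_to_t_ref=c_to_t_ref,
        c_to_k_ref=c_to_g_ref + c_to_t_ref,
        c_to_g_both=c_to_g_both,
        c_to_t_both=c_to_t_both,
        c_to_k_both=c_to_g_both + c_to_t_both,
        all_snv=len(records),
    )


def counts_to_frame(counts: Iterable[MutationCounts]) -> pd.DataFrame:
    """One row per cell line, the seven category columns."""
    rows = [
        {
            "cell_line": c.cell_line_id,
            "c_to_g_ref": c.c_to_g_ref,
            "c_to_t_ref": c.c_to_t_ref,
            "c_to_k_ref": c.c_to_k_ref,
            "c_to_g_both": c.c_to_g_both,
            "c_to_t_both": c.c_to_t_both,
            "c_to_k_both": c.c_to_k_both,
            "all_snv": c.all_snv,
        }
        for c in counts
    ]
    return pd.DataFrame(rows).set_index("cell_line")
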