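"""Kataegis cluster detection and per-cell-line abundance measures.

A kataegis cluster under criterion (k, w) is a maximal region of same-motif,
same-strand events in which some run of k consecutive events fits inside a
w-bp window.  The two criteria used throughout are 5/1000 (at least five
events in a 1000-bp window) and 6/10000 (at least six in 10,000 bp).

Window arithmetic: k events "fit in a w-bp window" when the coordinate span
of the run satisfies ``pos[last] - pos[first] <= w - 1`` — a w-bp window
covers w bases, so the largest admissible coordinate difference is w - 1.
An event is *clustered* when it lies in at least one qualifying run;
qualifying runs that share an event merge transitively, which yields the
distinct, non-overlapping, maximal regions reported.  Cluster extent is
event-bounded: start/end are the first/last member positions (1-based,
inclusive), and the combined length of a cluster is ``end - start + 1``.

Four abundance measures summarize one (cell line, motif, criterion):
the total motif count in the catalog, the number of motifs inside distinct
clusters, the number of distinct clusters, and their combined length in bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .motifs import MOTIF_NAMES, MotifEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterCriterion:
    """Minimum event count k within a w-bp window, e.g. k=5, w=1000."""

    k: int
    w: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.w < self.k:
            raise ValueError(f"w must be >= k, got w={self.w}, k={self.k}")

    @property
    def label(self) -> str:
        return f"{self.k}/{self.w}"


#: The two criteria used in the analyses.
CRITERION_5_1000 = ClusterCriterion(k=5, w=1000)
CRITERION_6_10000 = ClusterCriterion(k=6, w=10000)


@dataclass(frozen=True)
class KataegisCluster:
    """A distinct non-overlapping region of same-motif same-strand events."""

    cell_line_id: str
    chrom: str
    strand: str
    motif: str
    start: int  # 1-based inclusive position of the first member event
    end: int  # 1-based inclusive position of the last member event
    n_motifs: int
    criterion: str  # label, e.g. "5/1000"

    def __post_init__(self) -> None:
        assert self.end >= self.start
        assert self.n_motifs >= 2

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ApobecMeasures:
    """The four abundance measures for one (cell line, motif, criterion)."""

    cell_line_id: str
    motif: str
    criterion: str
    total_motifs: int
    motifs_in_clusters: int
    n_clusters: int
    combined_length_bp: int

    def __post_init__(self) -> None:
        assert self.motifs_in_clusters <= self.total_motifs
        assert (self.combined_length_bp == 0) == (self.n_clusters == 0)


def _clustered_index_ranges(
    positions: Sequence[int], k: int, w: int
) -> list[tuple[int, int]]:
    """Merged index ranges [i, j] (inclusive) of clustered events.

    positions must be sorted ascending.  A window of k consecutive events
    starting at index i qualifies iff positions[i+k-1] - positions[i] <= w-1;
    qualifying windows that share at least one event merge transitively.
    """
    n = len(positions)
    ranges: list[tuple[int, int]] = []
    for i in range(n - k + 1):
        if positions[i + k - 1] - positions[i] <= w - 1:
            j = i + k - 1
            if ranges and i <= ranges[-1][1]:  # shares an event -> merge
                ranges[-1] = (ranges[-1][0], max(ranges[-1][1], j))
            else:
                ranges.append((i, j))
    return ranges


def find_clusters(
    events: Sequence[MotifEvent], criterion: ClusterCriterion
) -> list[KataegisCluster]:
    """Detect distinct non-overlapping kataegis clusters for one cell line.

    Events must be sorted by (chrom, pos) and belong to a single cell line;
    they are partitioned by (chrom, strand, motif) before windowing, so a
    cluster never mixes motifs, strands or chromosomes.  Events of one
    partition at identical positions are collapsed with a warning.  Clusters
    are returned sorted by (chrom, start, strand, motif).
    """
    if not events:
        return []
    cell_lines = {e.cell_line_id for e in events}
    if len(cell_lines) > 1:
        raise ValueError(
            f"find_clusters expects one cell line, got {sorted(cell_lines)}"
        )
    for prev, cur in zip(events, events[1:]):
        if (prev.chrom, prev.pos) > (cur.chrom, cur.pos):
            raise ValueError("events must be sorted by (chrom, pos)")
    cell_line_id = events[0].cell_line_id

    partitions: dict[tuple[str, str, str], list[int]] = {}
    for e in events:
        partitions.setdefault((e.chrom, e.strand, e.motif), []).append(e.pos)

    clusters: list[KataegisCluster] = []
    for (chrom, strand, motif), positions in partitions.items():
        unique = sorted(set(positions))
        if len(unique) < len(positions):
            logger.warning(
                "collapsed %d duplicate-position events at %s/%s/%s",
                len(positions) - len(unique),
                chrom,
                strand,
                motif,
            )
        for i, j in _clustered_index_ranges(unique, criterion.k, criterion.w):
            clusters.append(
                KataegisCluster(
                    cell_line_id=cell_line_id,
                    chrom=chrom,
                    strand=strand,
                    motif=motif,
                    start=unique[i],
                    end=unique[j],
                    n_motifs=j - i + 1,
                    criterion=criterion.label,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand, c.motif))
    return clusters


def clustered_events(
    events: Sequence[MotifEvent], criterion: ClusterCriterion
) -> set[tuple[str, str, str, int]]:
    """The set of (chrom, strand, motif, pos) keys of clustered events."""
    keys: set[tuple[str, str, str, int]] = set()
    for c in find_clusters(events, criterion):
        for e in events:
            if (
                e.chrom == c.chrom
                and e.strand == c.strand
                and e.motif == c.motif
                and c.start <= e.pos <= c.end
            ):
                keys.add((e.chrom, e.strand, e.motif, e.pos))
    return keys


def apobec_measures(
    events: Sequence[MotifEvent],
    clusters: Sequence[KataegisCluster],
    criterion: ClusterCriterion,
    cell_line_id: str | None = None,
) -> dict[str, ApobecMeasures]:
    """Compute the four abundance measures per motif class.

    ``clusters`` must have been produced from ``events`` under ``criterion``.
    One record is returned for every motif class, including classes with no
    events or no clusters.
    """
    for c in clusters:
        if c.criterion != criterion.label:
            raise ValueError(
                f"cluster criterion {c.criterion!r} != requested {criterion.label!r}"
            )
    if cell_line_id is None:
        ids = {e.cell_line_id for e in events} | {c.cell_line_id for c in clusters}
        if len(ids) > 1:
            raise ValueError(f"multiple cell lines: {sorted(ids)}")
        cell_line_id = next(iter(ids)) if ids else ""

    out: dict[str, ApobecMeasures] = {}
    for motif in MOTIF_NAMES:
        motif_events = [e for e in events if e.motif == motif]
        motif_clusters = [c for c in clusters if c.motif == motif]
        in_clusters = 0
        for e in motif_events:
            if any(
                c.chrom == e.chrom and c.strand == e.strand and c.start <= e.pos <= c.end
                for c in motif_clusters
            ):
                in_clusters += 1
        out[motif] = ApobecMeasures(
            cell_line_id=cell_line_id,
            motif=motif,
            criterion=criterion.label,
            total_motifs=len(motif_events),
            motifs_in_clusters=in_clusters,
            n_clusters=len(motif_clusters),
            combined_length_bp=sum(c.length_bp for c in motif_clusters),
        )
    return out


def clusters_to_frame(clusters: Iterable[KataegisCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_line": c.cell_line_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "motif": c.motif,
                "n_motifs": c.n_motifs,
                "criterion": c.criterion,
            }
            for c in clusters
        ],
        columns=[
            "cell_line",
            "chrom",
            "start",
            "end",
            "strand",
            "motif",
            "n_motifs",
            "criterion",
        ],
    )


def measures_to_frame(measures: Iterable[ApobecMeasures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_line": m.cell_line_id,
                "motif": m.motif,
                "criterion": m.criterion,
                "total_motifs": m.total_motifs,
                "motifs_in_clusters": m.motifs_in_clusters,
                "n_clusters": m.n_clusters,
                "combined_length_bp": m.combined_length_bp,
            }
            for m in measures
        ],
        columns=[
            "cell_line",
            "motif",
            "criterion",
            "total_motifs",
            "motifs_in_clusters",
            "n_clusters",
            "combined_length_bp",
        ],
    )


def write_clusters_tsv(clusters: Iterable[KataegisCluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def write_measures_tsv(measures: Iterable[ApobecMeasures], path: str | Path) -> None:
    measures_to_frame(measures).to_csv(path, sep="\t", index=False)
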