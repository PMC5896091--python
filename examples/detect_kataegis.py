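"""Detect kataegis clusters and compute the four abundance measures.

Builds a small catalog with five tightly spaced T(C>T)A substitutions
(a strand-coordinated cluster) plus two distant ones, then applies the
5/1000 criterion: at least five same-motif same-strand events within a
1000-bp window.
"""

from apokat import (
    CRITERION_5_1000,
    SNVRecord,
    annotate_events,
    apobec_measures,
    find_clusters,
)

positions = [10_100, 10_250, 10_400, 10_600, 10_800, 50_000, 90_000]
records = [
    SNVRecord("CL1", "chr1", pos, "C", "T", context5="T", context3="A")
    for pos in positions
]

events = annotate_events(records)
clusters = find_clusters(events, CRITERION_5_1000)
for c in clusters:
    print(
        f"cluster {c.motif}{c.strand} {c.chrom}:{c.start}-{c.end} "
        f"({c.n_motifs} motifs, {c.length_bp} bp, criterion {c.criterion})"
    )

measures = apobec_measures(events, clusters, CRITERION_5_1000, "CL1")
m = measures["TCKW"]
print(
    f"TCKW measures: total={m.total_motifs}, in_clusters={m.motifs_in_clusters}, "
    f"clusters={m.n_clusters}, combined_length={m.combined_length_bp} bp"
)

# The five clustered events span 10100..10800 (701 bp, inside one 1000-bp
# window); the two isolated events count toward total_motifs only.
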