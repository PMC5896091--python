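"""Classify single substitutions against the three APOBEC-like motifs.

The motifs, written 5'->3' with the substitution in parentheses, are
T(C>K)W, T(C>D)R and T(C>D)D (K=G/T, W=A/T, R=A/G, D=A/G/T).  A match is
reported on whichever genome strand the T-C-N triplet reads left-to-right,
so a G>A change in an A-G-A reference context is a minus-strand event.
"""

from apokat import classify

cases = [
    ("T", "C", "T", "A"),  # classic TCA context, C>T
    ("T", "C", "G", "T"),  # TCT context, C>G
    ("T", "G", "A", "A"),  # reverse complement of a TCA context, G>A
    ("A", "C", "T", "A"),  # 5' flank is not T on either strand
]

for c5, ref, alt, c3 in cases:
    hits = classify(c5, ref, alt, c3)
    pretty = ", ".join(f"{m}{s}" for m, s in sorted(hits)) or "no motif"
    print(f"{c5}({ref}>{alt}){c3}:  {pretty}")

# Each line lists every (motif, strand) the substitution matches.  Note the
# third case matches on the minus strand, and that any T(C>K)W or T(C>D)R
# match always implies a T(C>D)D match on the same strand.
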