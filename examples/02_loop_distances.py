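"""End-to-loop distances: the loop-counting rule's structural footprint.

Builds cohorts whose mature boundaries sit a designed number of paired
nucleotides (the "inset") from the terminal loop and shows that the signed
end-to-loop distance recovers the planted geometry exactly.  An inset of 2
is what the loop-counting rule predicts for precise Dicer cleavage.
"""

from mirfoot import HairpinRecord, MatureAnnotation, parse_dot_bracket
from mirfoot.loops import distance_histogram, end_distances_for_dataset


def inset_hairpin(i, inset, stem=20, loop=8):
    n = 2 * stem + loop
    db = "(" * stem + "." * loop + ")" * stem
    return HairpinRecord(
        f"hsa-ex{i}", "hsa", "A" * n, parse_dot_bracket(db),
        (MatureAnnotation("five_prime", 1, stem - inset),
         MatureAnnotation("three_prime", stem + loop + 1 + inset, n)),
    )


# 60% of ends planted at +2, the rest spread over 0..4
insets = [2] * 30 + [0] * 5 + [1] * 5 + [3] * 5 + [4] * 5
cohort = [inset_hairpin(i, k) for i, k in enumerate(insets)]
hist = distance_histogram(end_distances_for_dataset(cohort, ("5p_end", "3p_start")))
print("planted inset counts: ", {k: 2 * insets.count(k) for k in sorted(set(insets))})
print("recovered d histogram:", dict(sorted(hist.items())))
print()
print("Positive d counts nucleotides between a mature end and the nearest")
print("single-stranded region outside it; d=0 means the end abuts a loop;")
print("negative d would mean the nearest loop lies inside the miRNA.  The")
print("recovered histogram reproduces the planted insets exactly, with the")
print("+2 peak the loop-counting rule predicts.")
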