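"""Build monthly co-occurrence snapshots from a tiny hand-written corpus.

Four papers in one month over tags A, B, C. The association strength of an
edge is c_ij / (s_i * s_j): papers with both tags, normalized by how common
each tag is, so ubiquitous tags do not dominate just by frequency.
"""

import datetime as dt

from taggraph import Corpus, PaperRecord, build_taggraph

corpus = Corpus(
    [
        PaperRecord("P1", dt.date(2020, 3, 2), ("A", "B")),
        PaperRecord("P2", dt.date(2020, 3, 10), ("A", "B")),
        PaperRecord("P3", dt.date(2020, 3, 15), ("A", "C")),
        PaperRecord("P4", dt.date(2020, 3, 20), ("A",)),
    ]
)

series = build_taggraph(corpus)
snap = series[0]

print(f"month {snap.month}: {snap.n_nodes} tags, {snap.n_edges} co-occurrence edges")
for tag, s in sorted(snap.tag_frequencies.items()):
    print(f"  s_{tag} = {s}  (papers mentioning {tag})")
for (a, b), (c, w) in sorted(snap.edges.items()):
    print(f"  {a}--{b}: c={c} joint papers, association strength {w}")

# A--B: 2 joint papers / (4 * 2) = 0.25; A--C: 1 / (4 * 1) = 0.25.
# Although A and B co-occur twice as often, A and C are equally associated
# once tag frequency is accounted for: C never appears without A.
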