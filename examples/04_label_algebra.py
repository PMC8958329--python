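"""Edge labels record cross-aligner agreement.

A junction absent from any aligner is labeled 1; present everywhere with
identical supporting reads, 2+; present everywhere but supported by
different reads, 2-. Seeds and DP predecessors prefer 2+ over 2- over 1.
"""

from spliceweave import label_edge

cases = [
    ("both aligners, same reads ", [True, True],
     [frozenset({"r1", "r2"}), frozenset({"r1", "r2"})]),
    ("both aligners, reads differ", [True, True],
     [frozenset({"r1", "r2"}), frozenset({"r1", "r3"})]),
    ("one aligner only           ", [True, False],
     [frozenset({"r1", "r2"}), None]),
]
for desc, presence, sets in cases:
    print(f"{desc} -> {label_edge(presence, sets).name}")

print()
print("priority order:", " > ".join(
    l.name for l in sorted(__import__('spliceweave').Label, reverse=True)))
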