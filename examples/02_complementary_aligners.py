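"""Two aligners that each miss a different junction of the same transcript.

Aligner A never reports the first junction of a 6-exon transcript,
aligner B never reports the last. Neither single-aligner assembly can
produce the full intron chain; merging both alignments into the labeled
splice graph recovers it.
"""

import tempfile
from pathlib import Path

from spliceweave import assemble_files, intron_chain_match, write_gtf
from spliceweave.simulate import (
    AlignerProfile,
    emulate_aligner,
    make_linear_truth,
    simulate_fragments,
    write_truth_gtf,
)

with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp)
    truth = make_linear_truth(n_exons=6, rng_seed=0)
    junctions = truth.transcripts[0].junctions
    frags = simulate_fragments(truth, rng_seed=1)
    print(f"truth: one transcript, 6 exons, junctions {list(junctions)}")

    prof_a = AlignerProfile("A", junction_dropout=frozenset({junctions[0]}))
    prof_b = AlignerProfile("B", junction_dropout=frozenset({junctions[4]}))
    emulate_aligner(frags, prof_a, truth.genome, str(d / "a.sam"), rng_seed=2)
    emulate_aligner(frags, prof_b, truth.genome, str(d / "b.sam"), rng_seed=3)
    write_truth_gtf(truth, str(d / "truth.gtf"))

    for name, files in [("A alone", ["a.sam"]), ("B alone", ["b.sam"]),
                        ("A + B", ["a.sam", "b.sam"])]:
        out = d / f"{name.replace(' ', '')}.gtf"
        write_gtf(assemble_files([str(d / f) for f in files]), str(out))
        r = intron_chain_match(str(out), str(d / "truth.gtf"))
        print(f"{name:8s} -> full-chain recall {r.recall:.0%}")
    # only the integrated run reaches 100%: each aligner contributes the
    # junction the other one missed
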