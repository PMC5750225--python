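"""Rank the 10-mer enrichment landscape of the final selection round.

Reads the FASTQ rounds written by 01_simulate_selection.py, trims the
constant flanks, counts all overlapping 10-mers, computes enrichment of the
final round over the input library, and writes the ranked top 300 10-mers.
The top-ranked 10-mer should be the adenosine homopolymer — the selection
target planted in the simulation.
"""

import sys
from pathlib import Path

from seqrs_kit import (
    SelectionSimConfig,
    count_kmers,
    rank_kmers,
    selection_landscape,
    trim_reads,
)
from seqrs_kit.simulate import read_fastq_sequences

IN = Path("results/selection")
OUT = Path("results/landscape")
K = 10
TOP_N = 300


def main(n_rounds: int = 5) -> None:
    cfg = SelectionSimConfig()  # primer sequences only
    OUT.mkdir(parents=True, exist_ok=True)
    tables = {}
    for r in (0, n_rounds):
        reads = read_fastq_sequences(IN / f"round_{r}.fastq")
        regions, discarded = trim_reads(reads, cfg.primer_5, cfg.primer_3)
        tables[r] = count_kmers(regions, K, f"round_{r}")
        print(f"round {r}: {len(regions)} reads retained, {discarded} discarded")
    landscape = selection_landscape(tables[0], tables[n_rounds])
    ranked = rank_kmers(landscape, TOP_N)
    out = OUT / f"top_{TOP_N}_{K}mers.tsv"
    with open(out, "w") as fh:
        fh.write("rank\tkmer\tenrichment\n")
        for i, (m, s) in enumerate(ranked, 1):
            fh.write(f"{i}\t{m}\t{s:.4f}\n")
    print(f"top enriched {K}-mer: {ranked[0][0]} (enrichment {ranked[0][1]:.1f})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 5)
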