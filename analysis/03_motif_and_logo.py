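"""Build the motif model and sequence logo from the ranked landscape.

Takes the top-300 10-mers from 02_enrichment_landscape.py, builds the
enrichment-weighted position frequency matrix / log-odds model and the
equal-weight information-content logo matrix, and serializes both.
"""

from pathlib import Path

import pandas as pd

from seqrs_kit import build_logo, build_pfm

IN = Path("results/landscape/top_300_10mers.tsv")
OUT = Path("results/motif")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ranked = pd.read_csv(IN, sep="\t")
    kmers = ranked["kmer"].tolist()
    weights = ranked["enrichment"].tolist()
    model = build_pfm(list(zip(kmers, weights)))
    model.to_json(OUT / "motif_model.json")
    logo = build_logo(kmers)  # equal weighting for the logo
    logo.to_tsv(OUT / "logo_matrix.tsv")
    print("per-position dominant base:", "".join(logo.dominant_bases()))
    print("per-position information content (bits):",
          " ".join(f"{v:.2f}" for v in logo.total_ic_per_pos))
    print(f"wrote {OUT/'motif_model.json'} and {OUT/'logo_matrix.tsv'}")


if __name__ == "__main__":
    main()
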