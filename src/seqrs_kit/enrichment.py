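"""K-mer enrichment landscapes from per-round selection reads.

A round of sequencing becomes a `KmerCountTable` (all overlapping windows of
the random regions tallied), a selected round over a reference round becomes
an `EnrichmentTable` of pseudocounted frequency ratios, and replicate
agreement is summarized by a Pearson correlation over the most abundant
k-mers — the landscape-reproducibility statistic of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sequences import (
    code_to_kmer,
    encode_seqs,
    kmer_codes,
    kmer_to_code,
    normalize_rna,
)
from .simulate import SequencePool


def trim_constant_regions(read: str, primer_5: str, primer_3: str):
    """Random region strictly between exact primer matches, or None.

    The 5' primer must appear; the 3' primer is searched after it. Reads
    missing either primer are discarded (None), to be counted by the caller.
    """
    if not primer_5 or not primer_3:
        raise ValueError("primers must be nonempty")
    read = normalize_rna(read)
    p5, p3 = normalize_rna(primer_5), normalize_rna(primer_3)
    i = read.find(p5)
    if i < 0:
        return None
    start = i + len(p5)
    j = read.find(p3, start)
    if j < 0:
        return None
    return read[start:j]


def trim_reads(reads, primer_5: str, primer_3: str):
    """Trim a collection of reads; returns (regions, n_discarded)."""
    regions, discarded = [], 0
    for r in reads:
        region = trim_constant_regions(r, primer_5, primer_3)
        if region is None:
            discarded += 1
        else:
            regions.append(region)
    return regions, discarded


@dataclass
class KmerCountTable:
    """Counts of all length-k windows of a sample's random regions.

    `counts` is a dense vector indexed by base-4 k-mer code (A=0..U=3), so
    Σ counts = total_windows = Σ_reads (L_read − k + 1) over reads of length ≥ k.
    """

    k: int
    counts: np.ndarray
    total_windows: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError("counts must have length 4^k")
        if int(self.counts.sum()) != self.total_windows:
            raise ValueError("count table invariant violated: sum != total_windows")

    def __getitem__(self, kmer: str) -> int:
        return int(self.counts[kmer_to_code(kmer)])

    def frequencies(self) -> np.ndarray:
        return self.counts / max(self.total_windows, 1)

    def as_dict(self) -> dict:
        nz = np.nonzero(self.counts)[0]
        return {code_to_kmer(int(c), self.k): int(self.counts[c]) for c in nz}


def count_kmers(reads, k: int, sample_id: str = "", counts=None) -> KmerCountTable:
    """Tally every overlapping k-mer window of every read (region).

    `reads` may be a list of strings (variable lengths allowed; reads shorter
    than k contribute nothing) or a `SequencePool` whose molecule counts
    weight the tally.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vec = np.zeros(4**k, dtype=np.int64)
    if isinstance(reads, SequencePool):
        groups = {}
        for s, c in zip(reads.sequences, reads.counts):
            groups.setdefault(len(s), ([], []))[0].append(s)
            groups[len(s)][1].append(int(c))
        items = [
            (encode_seqs(seqs, L), np.asarray(ws, dtype=np.int64))
            for L, (seqs, ws) in groups.items()
        ]
    else:
        groups = {}
        for s in reads:
            s = normalize_rna(s)
            groups.setdefault(len(s), []).append(s)
        items = [
            (encode_seqs(seqs, L), np.ones(len(seqs), dtype=np.int64))
            for L, seqs in groups.items()
        ]
    total = 0
    for mat, weights in items:
        codes = kmer_codes(mat, k)
        if codes.shape[1] == 0:
            continue
        w = np.repeat(weights, codes.shape[1])
        vec += np.bincount(codes.ravel(), weights=w, minlength=4**k).astype(np.int64)
        total += int(w.sum())
    return KmerCountTable(k=k, counts=vec, total_windows=total, sample_id=sample_id)


@dataclass
class EnrichmentTable:
    """Pseudocounted frequency ratio of every k-mer, selected over reference."""

    k: int
    scores: np.ndarray
    reference_sample: str = ""
    selected_sample: str = ""
    pseudocount: float = 0.5
    abundance: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (4**self.k,):
            raise ValueError("scores must have length 4^k")
        if (self.scores <= 0).any():
            raise ValueError("enrichment scores must be positive")

    def __getitem__(self, kmer: str) -> float:
        return float(self.scores[kmer_to_code(kmer)])


def compute_enrichment(
    selected: KmerCountTable, reference: KmerCountTable, pseudocount: float = 0.5
) -> EnrichmentTable:
    """enrichment(m) = [(c_sel+p)/(T_sel+p·4^k)] / [(c_ref+p)/(T_ref+p·4^k)]."""
    if selected.k != reference.k:
        raise ValueError("selected and reference tables have different k")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    p = float(pseudocount)
    n = 4**selected.k
    f_sel = (selected.counts + p) / (selected.total_windows + p * n)
    f_ref = (reference.counts + p) / (reference.total_windows + p * n)
    return EnrichmentTable(
        k=selected.k,
        scores=f_sel / f_ref,
        reference_sample=reference.sample_id,
        selected_sample=selected.sample_id,
        pseudocount=p,
        abundance=selected.counts.copy(),
    )


def uniform_enrichment(
    selected: KmerCountTable, pseudocount: float = 0.5
) -> EnrichmentTable:
    """Enrichment over the analytically uniform input library:
    enrichment(m) = 4^k · (c_sel(m)+p)/(T_sel+p·4^k)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    p = float(pseudocount)
    n = 4**selected.k
    f_sel = (selected.counts + p) / (selected.total_windows + p * n)
    return EnrichmentTable(
        k=selected.k,
        scores=f_sel * n,
        reference_sample="uniform",
        selected_sample=selected.sample_id,
        pseudocount=p,
        abundance=selected.counts.copy(),
    )


def rank_kmers(table: EnrichmentTable, n: int):
    """Top-n (k-mer, score) pairs, descending score, lexicographic tie-break.

    Base-4 codes are lexicographic over ACGU, so a stable sort on −score
    yields the deterministic total order the landscape ranking requires.
    """
    if n > 4**table.k:
        raise ValueError("n exceeds the k-mer universe")
    order = np.argsort(-table.scores, kind="stable")[:n]
    return [(code_to_kmer(int(c), table.k), float(table.scores[c])) for c in order]


def pool_regions(pool: SequencePool, primer_5: str, primer_3: str) -> SequencePool:
    """Strip the constant flanks from every molecule of a pool."""
    f5, f3 = len(primer_5), len(primer_3)
    return SequencePool(
        [s[f5 : len(s) - f3] for s in pool.sequences], pool.counts.copy()
    )


def selection_landscape(
    round0: KmerCountTable,
    selected: KmerCountTable,
    pseudocount: float = 0.5,
    reference: str = "auto",
) -> EnrichmentTable:
    """Enrichment landscape of a selected round over the input library.

    The round-0 sample is the natural reference, but it only estimates k-mer
    frequencies when its depth covers the 4^k universe; with `reference=
    "auto"` the round-0 table is used when it holds at least ten windows per
    k-mer on average, otherwise the analytically uniform input library is
    substituted (the randomized region is uniform by construction, so the
    sequenced round 0 adds only shot noise).
    """
    if reference == "auto":
        reference = "round0" if round0.total_windows >= 10 * 4**round0.k else "uniform"
    if reference == "round0":
        return compute_enrichment(selected, round0, pseudocount)
    if reference == "uniform":
        return uniform_enrichment(selected, pseudocount)
    raise ValueError("reference must be auto, round0 or uniform")


def _top_codes_by_abundance(counts: np.ndarray, top_n: int) -> np.ndarray:
    order = np.argsort(-counts, kind="stable")
    return order[: min(top_n, len(order))]


def replicate_correlation(
    table_a,
    table_b,
    top_n: int = 120_000,
    space: str = "log_enrichment",
    pseudocount: float = 0.5,
) -> float:
    """Pearson r between two replicate landscapes.

    Restricted to the union of each replicate's `top_n` most abundant k-mers.
    `space` selects the values correlated: "log_enrichment" / "enrichment"
    for `EnrichmentTable` pairs, "log_counts" / "counts" for
    `KmerCountTable` pairs (log10, pseudocounted).
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    if table_a.k != table_b.k:
        raise ValueError("replicate tables have different k")
    if isinstance(table_a, EnrichmentTable):
        vals_a, vals_b = table_a.scores, table_b.scores
        ab_a = table_a.abundance if table_a.abundance is not None else vals_a
        ab_b = table_b.abundance if table_b.abundance is not None else vals_b
        if space not in ("log_enrichment", "enrichment"):
            raise ValueError("enrichment tables support log_enrichment/enrichment")
        log = space == "log_enrichment"
    else:
        vals_a = table_a.counts + pseudocount
        vals_b = table_b.counts + pseudocount
        ab_a, ab_b = table_a.counts, table_b.counts
        if space not in ("log_counts", "counts"):
            raise ValueError("count tables support log_counts/counts")
        log = space == "log_counts"
    idx = np.union1d(
        _top_codes_by_abundance(np.asarray(ab_a), top_n),
        _top_codes_by_abundance(np.asarray(ab_b), top_n),
    )
    x, y = np.asarray(vals_a, float)[idx], np.asarray(vals_b, float)[idx]
    if log:
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (zero-variance) values; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
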