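"""Specificity models built from ranked k-mers.

Three related objects: a `MotifModel` (weighted position frequency matrix and
log-odds derived from the top enriched k-mers, plus the raw k-mer hit set), a
`LogoMatrix` (per-position information content in bits for sequence-logo
rendering), and a `LikelihoodClassifier` (class-conditional k-mer frequency
models whose log-likelihood ratio scores arbitrary sequences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .sequences import RNA_BASES, encode_seq, encode_seqs, kmer_codes, normalize_rna
from .enrichment import count_kmers

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class MotifModel:
    """Weighted PFM / log-odds over the top k-mers, plus the hit set itself.

    `scoring_mode` selects how `score_sequence` aggregates over windows:
    the best sliding-window log-odds sum (continuous score for ROC work) or
    the number of windows matching a top k-mer (hit semantics for positional
    analyses).
    """

    k: int
    top_kmers: list  # ordered (kmer, weight) pairs
    pfm: np.ndarray
    log_odds: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    scoring_mode: str = "max_window_logodds"

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not self.top_kmers:
            raise ValueError("top_kmers must be nonempty")
        if self.pfm.shape != (self.k, 4) or self.log_odds.shape != (self.k, 4):
            raise ValueError("pfm/log_odds must be k x 4")
        if not np.allclose(self.pfm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pfm rows must sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if self.scoring_mode not in ("max_window_logodds", "hit_count"):
            raise ValueError("unknown scoring_mode")
        self._hit_set = {normalize_rna(m) for m, _ in self.top_kmers}

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "top_kmers": [[m, w] for m, w in self.top_kmers],
            "pfm": self.pfm.tolist(),
            "log_odds": self.log_odds.tolist(),
            "background": self.background.tolist(),
            "scoring_mode": self.scoring_mode,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MotifModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            k=d["k"],
            top_kmers=[(m, w) for m, w in d["top_kmers"]],
            pfm=np.array(d["pfm"]),
            log_odds=np.array(d["log_odds"]),
            background=np.array(d["background"]),
            scoring_mode=d["scoring_mode"],
        )


def build_pfm(
    top_kmers,
    background=None,
    pseudo: float = 1e-9,
    scoring_mode: str = "max_window_logodds",
) -> MotifModel:
    """Weighted per-position base frequencies of the top k-mers.

    `top_kmers` is an iterable of k-mer strings or (k-mer, weight) pairs
    (unit weights when bare strings are given). log-odds are log2 of PFM over
    background with a small additive pseudocount to keep unobserved bases
    finite.
    """
    pairs = []
    for item in top_kmers:
        if isinstance(item, str):
            pairs.append((normalize_rna(item), 1.0))
        else:
            m, w = item
            pairs.append((normalize_rna(m), float(w)))
    if not pairs:
        raise ValueError("no k-mers given")
    k = len(pairs[0][0])
    if any(len(m) != k for m, _ in pairs):
        raise ValueError("k-mers have mixed lengths")
    weights = np.array([w for _, w in pairs], dtype=float)
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    mat = encode_seqs([m for m, _ in pairs], k)
    pfm = np.zeros((k, 4))
    for b in range(4):
        pfm[:, b] = (weights[:, None] * (mat == b)).sum(axis=0)
    pfm /= weights.sum()
    bg = np.asarray(background, float) if background is not None else UNIFORM_BACKGROUND.copy()
    log_odds = np.log2((pfm + pseudo) / (bg[None, :] + pseudo))
    return MotifModel(
        k=k, top_kmers=pairs, pfm=pfm, log_odds=log_odds,
        background=bg, scoring_mode=scoring_mode,
    )


@dataclass
class LogoMatrix:
    """Per-position information content (bits) for a sequence logo.

    `info_content[j, b]` = f_{j,b} · (2 − H_j); total per-position IC is
    bounded by [0, 2] bits for the four-letter alphabet (no small-sample
    correction).
    """

    length: int
    info_content: np.ndarray
    total_ic_per_pos: np.ndarray

    def __post_init__(self) -> None:
        self.info_content = np.asarray(self.info_content, dtype=float)
        self.total_ic_per_pos = np.asarray(self.total_ic_per_pos, dtype=float)
        if self.info_content.shape != (self.length, 4):
            raise ValueError("info_content must be length x 4")
        if ((self.total_ic_per_pos < -1e-12) | (self.total_ic_per_pos > 2 + 1e-12)).any():
            raise ValueError("per-position IC must lie in [0, 2] bits")

    def dominant_bases(self) -> list:
        return [RNA_BASES[int(b)] for b in self.info_content.argmax(axis=1)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(RNA_BASES) + "\ttotal_ic\n")
            for j in range(self.length):
                row = "\t".join(f"{v:.6f}" for v in self.info_content[j])
                fh.write(f"{j}\t{row}\t{self.total_ic_per_pos[j]:.6f}\n")


def build_logo(top_seqs, weights=None) -> LogoMatrix:
    """Information-content matrix from equal-length sequences (equal weights
    by default; pass enrichment scores to weight by landscape strength)."""
    seqs = [normalize_rna(s) for s in top_seqs]
    if not seqs:
        raise ValueError("no sequences given")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences have mixed lengths")
    w = np.ones(len(seqs)) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    mat = encode_seqs(seqs, L)
    freq = np.zeros((L, 4))
    for b in range(4):
        freq[:, b] = (w[:, None] * (mat == b)).sum(axis=0)
    freq /= w.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    total_ic = 2.0 - entropy
    return LogoMatrix(length=L, info_content=freq * total_ic[:, None], total_ic_per_pos=total_ic)


def score_sequence(model: MotifModel, seq: str, mode: str | None = None) -> float:
    """Score a sequence against the motif model.

    max_window_logodds: maximum over sliding windows of the per-position
    log-odds sum. hit_count: number of windows whose k-mer belongs to the
    model's top set.
    """
    mode = mode or model.scoring_mode
    s = normalize_rna(seq)
    if len(s) < model.k:
        raise ValueError("sequence shorter than model k")
    if mode == "hit_count":
        return float(
            sum(1 for i in range(len(s) - model.k + 1) if s[i : i + model.k] in model._hit_set)
        )
    if mode != "max_window_logodds":
        raise ValueError("unknown scoring mode")
    codes = encode_seq(s)
    win = np.lib.stride_tricks.sliding_window_view(codes, model.k)
    scores = model.log_odds[np.arange(model.k)[None, :], win].sum(axis=1)
    return float(scores.max())


@dataclass
class LikelihoodClassifier:
    """Class-conditional k-mer frequency models; scores are mean per-window
    log-likelihood ratios (positive class over negative class)."""

    k: int
    log_freq_pos: np.ndarray
    log_freq_neg: np.ndarray
    pseudocount: float = 0.5
    trained_on: str = ""

    def __post_init__(self) -> None:
        self.log_freq_pos = np.asarray(self.log_freq_pos, dtype=float)
        self.log_freq_neg = np.asarray(self.log_freq_neg, dtype=float)
        for v in (self.log_freq_pos, self.log_freq_neg):
            if v.shape != (4**self.k,):
                raise ValueError("log frequency vectors must have length 4^k")
            if abs(np.exp(v).sum() - 1.0) > 1e-6:
                raise ValueError("stored frequencies must sum to 1")


def train_likelihood(
    train_pos, train_neg, k: int, pseudocount: float = 0.5, trained_on: str = ""
) -> LikelihoodClassifier:
    """Learn pseudocounted class-conditional k-mer frequencies from labeled
    sequence sets."""
    pos, neg = list(train_pos), list(train_neg)
    if not pos or not neg:
        raise ValueError("both classes must be nonempty")
    if min(len(s) for s in pos + neg) < k:
        raise ValueError("k exceeds the shortest training sequence")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logf = []
    for seqs in (pos, neg):
        table = count_kmers(seqs, k)
        f = (table.counts + pseudocount) / (table.total_windows + pseudocount * 4**k)
        logf.append(np.log(f))
    return LikelihoodClassifier(
        k=k, log_freq_pos=logf[0], log_freq_neg=logf[1],
        pseudocount=pseudocount, trained_on=trained_on,
    )


def score_llr(classifier: LikelihoodClassifier, seq: str) -> float:
    """Mean per-window log-likelihood ratio of a sequence."""
    s = normalize_rna(seq)
    if len(s) < classifier.k:
        raise ValueError("sequence shorter than classifier k")
    codes = kmer_codes(encode_seq(s)[None, :], classifier.k)[0]
    llr = classifier.log_freq_pos[codes] - classifier.log_freq_neg[codes]
    return float(llr.mean())
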