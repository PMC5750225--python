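"""Synthetic data generators for every pipeline input.

Covers iterative in vitro selection of a randomized RNA library against a
protein of known (ground-truth) specificity, labeled occupancy windows around
crosslink sites with composition-matched negative controls, equilibrium
binding and decay curves, and two-channel co-localization images. All
generators are pure functions of their configuration, including the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import (
    RNA_BASES,
    base_count_per_code,
    decode_matrix,
    encode_seqs,
    kmer_codes,
    kmer_to_code,
    normalize_rna,
)

# ---------------------------------------------------------------------------
# configs


@dataclass
class SelectionSimConfig:
    """Conditions of one simulated selection experiment.

    The library is a randomized 20-mer between two constant primer regions,
    carried through five rounds of affinity selection before sequencing.
    """

    random_region_len: int = 20
    n_rounds: int = 5
    pool_size: int = 1_000_000
    reads_per_round: int = 100_000
    nonspecific_fraction: float = 0.2
    primer_5: str = "GGGAAUGGA"
    primer_3: str = "UUCGACUGC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size <= 0:
            raise ValueError("pool_size must be positive")
        if self.reads_per_round <= 0:
            raise ValueError("reads_per_round must be positive")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not 0.0 <= self.nonspecific_fraction <= 1.0:
            raise ValueError("nonspecific_fraction must lie in [0, 1]")
        if self.random_region_len < 1:
            raise ValueError("random_region_len must be >= 1")
        self.primer_5 = normalize_rna(self.primer_5)
        self.primer_3 = normalize_rna(self.primer_3)


@dataclass
class OccupancySimConfig:
    """Labeled occupancy windows around a central crosslink site.

    Positives carry `motif` planted at the window center (jittered by at most
    `plant_offset_jitter` bases); negatives are drawn i.i.d. from
    `background_composition`.
    """

    n_positive: int = 200
    n_negative: int = 200
    window_len: int = 50
    motif: str = "AAAAAAAAAAAA"
    plant_offset_jitter: int = 0
    background_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        self.motif = normalize_rna(self.motif)
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("class sizes must be nonnegative")
        if self.window_len < len(self.motif):
            raise ValueError("motif longer than window")
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("background_composition must be 4 probabilities summing to 1")
        center = self.window_len // 2
        j = self.plant_offset_jitter
        if j < 0 or center - j < 0 or center + j + len(self.motif) > self.window_len:
            raise ValueError("jittered motif would not fit inside the window")


@dataclass
class CurveSimConfig:
    """One saturation-binding or decay curve with replicate Gaussian noise.

    `noise_model` is "additive" (noise_sd in signal units) or "proportional"
    (noise_sd is a coefficient of variation, the usual error structure of
    fluorescence-intensity quantification).
    """

    true_param: float  # K_d in nM, or half-life in hours
    x_values: tuple
    y_floor: float = 0.0
    y_ceiling: float = 1.0
    noise_sd: float = 0.0
    n_replicates: int = 1
    noise_model: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x_values, dtype=float)
        if x.ndim != 1 or len(x) == 0:
            raise ValueError("x_values must be a 1-D sequence")
        if (np.diff(x) <= 0).any():
            raise ValueError("x_values must be strictly ascending")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.true_param <= 0:
            raise ValueError("true_param must be positive")
        if self.noise_model not in ("additive", "proportional"):
            raise ValueError("noise_model must be additive or proportional")


# ---------------------------------------------------------------------------
# sequence pool and affinity model


@dataclass
class SequencePool:
    """Multiset of equal-length RNA molecules (unique sequence + count)."""

    sequences: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.sequences) != len(self.counts):
            raise ValueError("sequences and counts length mismatch")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict:
        return dict(zip(self.sequences, (int(c) for c in self.counts)))

    @classmethod
    def from_dict(cls, d: dict) -> "SequencePool":
        seqs = sorted(d)
        return cls(seqs, np.array([d[s] for s in seqs], dtype=np.int64))

    def encoded(self) -> np.ndarray:
        return encode_seqs(self.sequences)


@dataclass
class AffinityModel:
    """Ground-truth relative affinities of all length-k RNA windows.

    `weight_vector[code]` is the nonnegative relative affinity of the k-mer
    with that base-4 code; unspecified k-mers take the background value.
    A sequence's weight aggregates window affinities with either the best
    window (`max_window`, single dominant site) or the window sum
    (`sum_windows`, multi-site binding).
    """

    k: int
    weight_vector: np.ndarray
    aggregation: str = "max_window"

    def __post_init__(self) -> None:
        self.weight_vector = np.asarray(self.weight_vector, dtype=float)
        if self.weight_vector.shape != (4**self.k,):
            raise ValueError("weight_vector must have length 4^k")
        if (self.weight_vector < 0).any():
            raise ValueError("affinity weights must be nonnegative")
        if not (self.weight_vector > 0).any():
            raise ValueError("at least one affinity weight must be positive")
        if self.aggregation not in ("max_window", "sum_windows"):
            raise ValueError("aggregation must be max_window or sum_windows")

    @classmethod
    def from_weights(
        cls,
        k: int,
        weights: dict,
        background: float = 0.0,
        aggregation: str = "max_window",
    ) -> "AffinityModel":
        vec = np.full(4**k, float(background))
        for kmer, w in weights.items():
            km = normalize_rna(kmer)
            if len(km) != k:
                raise ValueError(f"k-mer {kmer!r} does not have length {k}")
            vec[kmer_to_code(km)] = float(w)
        return cls(k=k, weight_vector=vec, aggregation=aggregation)

    @classmethod
    def a_preferring(
        cls, k: int = 10, factor: float = 10.0, aggregation: str = "max_window"
    ) -> "AffinityModel":
        """Adenosine-homopolymer-preferring model: w(m) = factor^(#A in m)."""
        n_a = base_count_per_code(k, "A")
        return cls(k=k, weight_vector=np.power(float(factor), n_a), aggregation=aggregation)

    def kmer_weight(self, kmer: str) -> float:
        km = normalize_rna(kmer)
        if len(km) != self.k:
            raise ValueError("k-mer length mismatch")
        return float(self.weight_vector[kmer_to_code(km)])

    def sequence_weights(self, mat: np.ndarray) -> np.ndarray:
        """Aggregate window affinities for each row of an encoded matrix."""
        codes = kmer_codes(mat, self.k)
        if codes.shape[1] == 0:
            return np.zeros(mat.shape[0])
        w = self.weight_vector[codes]
        return w.max(axis=1) if self.aggregation == "max_window" else w.sum(axis=1)

    def describe(self) -> str:
        nz = int((self.weight_vector > 0).sum())
        return f"AffinityModel(k={self.k}, aggregation={self.aggregation}, nonzero={nz})"


# ---------------------------------------------------------------------------
# selection simulation


def _random_regions(rng: np.random.Generator, n: int, length: int) -> SequencePool:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    # collapse duplicates (rare at length 20 but required by the multiset type)
    view = np.ascontiguousarray(codes).view(
        np.dtype((np.void, codes.dtype.itemsize * length))
    )
    uniq, counts = np.unique(view, return_counts=True)
    mat = uniq.view(np.uint8).reshape(-1, length)
    return SequencePool(decode_matrix(mat), counts)


def generate_initial_library(config: SelectionSimConfig) -> SequencePool:
    """Unselected round-0 pool: i.i.d. uniform random regions with flanks."""
    rng = np.random.default_rng(config.seed)
    regions = _random_regions(rng, config.pool_size, config.random_region_len)
    seqs = [config.primer_5 + r + config.primer_3 for r in regions.sequences]
    return SequencePool(seqs, regions.counts)


def simulate_selection_round(
    pool: SequencePool,
    model: AffinityModel,
    nonspecific_fraction: float,
    reads_out: int,
    seed,
    flank_5: int = 0,
    flank_3: int = 0,
) -> SequencePool:
    """One round of affinity selection as multinomial resampling.

    Each molecule is captured with probability proportional to a mixture of
    its affinity (weight of its random region under `model`) and a uniform
    nonspecific term, so the unique-sequence sampling probability is

        p(s) ∝ (1 − β)·c(s)·w(s)/Σ c·w + β·c(s)/Σ c,   β = nonspecific_fraction.
    """
    if pool.total == 0:
        raise ValueError("pool is empty")
    if not 0.0 <= nonspecific_fraction <= 1.0:
        raise ValueError("nonspecific_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = pool.encoded()
    if flank_5 or flank_3:
        mat = mat[:, flank_5 : mat.shape[1] - flank_3 or None]
    beta = float(nonspecific_fraction)
    c = pool.counts.astype(float)
    p = beta * c / c.sum()
    if beta < 1.0:
        w = model.sequence_weights(mat)
        cw = c * w
        tot = cw.sum()
        if tot == 0.0:
            raise ValueError(
                "all molecules have zero affinity weight; give the AffinityModel "
                "a nonzero background weight so nonspecific capture is possible"
            )
        p = p + (1.0 - beta) * cw / tot
    new_counts = rng.multinomial(reads_out, p / p.sum())
    keep = new_counts > 0
    return SequencePool(
        [s for s, k in zip(pool.sequences, keep) if k], new_counts[keep]
    )


def run_selection(config: SelectionSimConfig, model: AffinityModel) -> list:
    """In-memory selection: returns pools for rounds 0..n_rounds.

    Round 0 is a sequencing sample of the unselected library (β = 1 resampling
    at the sequencing depth); each later round both selects and is sequenced.
    """
    rng = np.random.default_rng(config.seed)
    library = generate_initial_library(config)
    f5, f3 = len(config.primer_5), len(config.primer_3)
    round0 = simulate_selection_round(
        library, model, 1.0, config.reads_per_round, rng, f5, f3
    )
    pools = [round0]
    current = library
    for _ in range(config.n_rounds):
        current = simulate_selection_round(
            current,
            model,
            config.nonspecific_fraction,
            config.reads_per_round,
            rng,
            f5,
            f3,
        )
        pools.append(current)
    return pools


def write_pool_fastq(pool: SequencePool, path, quality: str = "I") -> None:
    """Write every molecule of a pool as one FASTQ read (constant quality)."""
    records = []
    i = 0
    for seq, count in zip(pool.sequences, pool.counts):
        q = [ord(quality) - 33] * len(seq)
        for _ in range(int(count)):
            rec = SeqRecord(Seq(seq), id=f"read_{i:07d}", description="")
            rec.letter_annotations["phred_quality"] = q
            records.append(rec)
            i += 1
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq_sequences(path) -> list:
    return [normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def simulate_seqrs(config: SelectionSimConfig, model: AffinityModel, out_dir) -> dict:
    """Run a full selection and write per-round FASTQ files plus a manifest.

    Returns a manifest dict: round index -> FASTQ path, plus run metadata.
    The manifest is also written as TSV next to the FASTQ files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pools = run_selection(config, model)
    rows = []
    for r, pool in enumerate(pools):
        path = out / f"round_{r}.fastq"
        write_pool_fastq(pool, path)
        rows.append((r, path.name, pool.total))
    manifest_path = out / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("round\tfastq\tn_reads\tseed\tnonspecific_fraction\tmodel\n")
        for r, name, n in rows:
            fh.write(
                f"{r}\t{name}\t{n}\t{config.seed}\t"
                f"{config.nonspecific_fraction}\t{model.describe()}\n"
            )
    return {
        "rounds": {r: out / name for r, name, _ in rows},
        "manifest": manifest_path,
        "pools": pools,
        "config": config,
    }


# ---------------------------------------------------------------------------
# occupancy sites and matched negatives


@dataclass
class LabeledSequenceSet:
    """Sequence windows with binary occupancy labels and crosslink centers."""

    sequences: list
    labels: np.ndarray
    centers: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centers = np.asarray(self.centers, dtype=int)
        if not self.ids:
            self.ids = [f"seq_{i:05d}" for i in range(len(self.sequences))]
        if not (len(self.sequences) == len(self.labels) == len(self.centers) == len(self.ids)):
            raise ValueError("field length mismatch")

    def subset(self, idx) -> "LabeledSequenceSet":
        idx = np.asarray(idx)
        return LabeledSequenceSet(
            [self.sequences[i] for i in idx],
            self.labels[idx],
            self.centers[idx],
            [self.ids[i] for i in idx],
        )

    def write(self, fasta_path, tsv_path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description="")
            for i, s in zip(self.ids, self.sequences)
        ]
        with open(fasta_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        with open(tsv_path, "w") as fh:
            fh.write("id\tlabel\tcenter\n")
            for i, lab, c in zip(self.ids, self.labels, self.centers):
                fh.write(f"{i}\t{lab}\t{c}\n")


def _iid_sequences(rng, n, length, composition) -> list:
    comp = np.asarray(composition, dtype=float)
    codes = rng.choice(4, size=(n, length), p=comp / comp.sum()).astype(np.uint8)
    return decode_matrix(codes) if n else []


def simulate_occupancy_sites(config: OccupancySimConfig) -> LabeledSequenceSet:
    """Windows centered on a crosslink site; positives carry the planted motif."""
    rng = np.random.default_rng(config.seed)
    L, center = config.window_len, config.window_len // 2
    motif = config.motif
    pos = _iid_sequences(rng, config.n_positive, L, config.background_composition)
    offsets = rng.integers(
        -config.plant_offset_jitter, config.plant_offset_jitter + 1, size=config.n_positive
    )
    planted = []
    for s, off in zip(pos, offsets):
        start = center + int(off)
        planted.append(s[:start] + motif + s[start + len(motif) :])
    neg = _iid_sequences(rng, config.n_negative, L, config.background_composition)
    seqs = planted + neg
    labels = np.r_[np.ones(config.n_positive, int), np.zeros(config.n_negative, int)]
    centers = np.full(len(seqs), center, dtype=int)
    ids = [f"pos_{i:05d}" for i in range(config.n_positive)] + [
        f"neg_{i:05d}" for i in range(config.n_negative)
    ]
    return LabeledSequenceSet(seqs, labels, centers, ids)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Eulerian-path (Altschul–Erickson) shuffle preserving dinucleotide counts."""
    if len(seq) <= 2:
        return seq
    # adjacency lists of the dinucleotide multigraph
    edges = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    # choose a random "last edge" per non-terminal vertex such that the chosen
    # edges form a tree directed toward the terminal vertex (rejection over a
    # <=4-vertex graph terminates almost immediately)
    while True:
        chosen = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen, u = {v}, v
            while u != last:
                u = chosen.get(u)
                if u is None or u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            break
    shuffled = {}
    for v, nbrs in edges.items():
        rest = list(nbrs)
        if v in chosen:
            rest.remove(chosen[v])
        perm = [rest[i] for i in rng.permutation(len(rest))]
        if v in chosen:
            perm.append(chosen[v])
        shuffled[v] = perm
    out = [seq[0]]
    ptr = {v: 0 for v in shuffled}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def make_matched_negatives(seqs, order: int, seed) -> list:
    """Composition-matched shuffles: order 0 preserves the base multiset of
    every sequence, order 1 its dinucleotide multiset (Eulerian-path shuffle)."""
    if order not in (0, 1):
        raise ValueError("order must be 0 (mono) or 1 (dinucleotide)")
    rng = np.random.default_rng(seed)
    out = []
    for s in seqs:
        s = normalize_rna(s)
        if len(s) < order + 2:
            warnings.warn(f"sequence of length {len(s)} too short to shuffle; returned unchanged")
            out.append(s)
        elif order == 0:
            out.append("".join(s[i] for i in rng.permutation(len(s))))
        else:
            out.append(_dinucleotide_shuffle(s, rng))
    return out


# ---------------------------------------------------------------------------
# curves


def binding_model(x, kd, floor, ceiling):
    """Hyperbolic saturation: y = floor + (ceiling − floor)·x/(K_d + x)."""
    x = np.asarray(x, dtype=float)
    return floor + (ceiling - floor) * x / (kd + x)


def decay_model(t, y0, t_half):
    """Exponential decay: y = y0·2^(−t/t_half)."""
    t = np.asarray(t, dtype=float)
    return y0 * np.power(2.0, -t / t_half)


def simulate_binding_curve(config: CurveSimConfig):
    """(concentration, anisotropy) observations; returns (x, y) arrays with
    replicates tiled along the first axis."""
    rng = np.random.default_rng(config.seed)
    x = np.tile(np.asarray(config.x_values, dtype=float), config.n_replicates)
    y = binding_model(x, config.true_param, config.y_floor, config.y_ceiling)
    return x, _add_noise(y, config, rng)


def simulate_decay(config: CurveSimConfig):
    """(time, intensity) observations for exponential decay, clipped at 0.

    `y_ceiling` plays the role of the initial intensity y0."""
    rng = np.random.default_rng(config.seed)
    t = np.tile(np.asarray(config.x_values, dtype=float), config.n_replicates)
    y = decay_model(t, config.y_ceiling, config.true_param)
    return t, np.clip(_add_noise(y, config, rng), 0.0, None)


def _add_noise(y: np.ndarray, config: CurveSimConfig, rng) -> np.ndarray:
    eps = rng.normal(0.0, config.noise_sd, size=y.shape)
    return y * (1.0 + eps) if config.noise_model == "proportional" else y + eps


# ---------------------------------------------------------------------------
# two-channel image fixture


def simulate_colocalization_image(
    shape=(64, 64),
    overlap_fraction: float = 0.5,
    signal: float = 100.0,
    background: float = 5.0,
    seed: int = 0,
    n_object_pixels: int = 200,
):
    """Two intensity matrices whose channel-A object overlaps channel B in the
    requested pixel fraction; returns (A, B, roi_mask, truth dict)."""
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pix = shape[0] * shape[1]
    if 2 * n_object_pixels > n_pix:
        raise ValueError("objects do not fit in the image")
    flat = rng.permutation(n_pix)
    a_idx = flat[:n_object_pixels]
    n_overlap = int(round(overlap_fraction * n_object_pixels))
    b_idx = np.concatenate(
        [a_idx[:n_overlap], flat[n_object_pixels : 2 * n_object_pixels - n_overlap]]
    )
    A = np.full(n_pix, background, dtype=float)
    B = np.full(n_pix, background, dtype=float)
    A[a_idx] = signal
    B[b_idx] = signal
    A, B = A.reshape(shape), B.reshape(shape)
    mask = np.zeros(n_pix, dtype=bool)
    mask[np.concatenate([a_idx, b_idx])] = True
    truth = {
        "m1": n_overlap / n_object_pixels,
        "threshold": (signal + background) / 2.0,
        "n_object_pixels": n_object_pixels,
    }
    return A, B, mask.reshape(shape), truth


def save_manifest_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
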