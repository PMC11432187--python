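"""HT-SELEX read processing, 10-mer enrichment, and seed-based motif discovery.

A SELEX experiment iteratively selects double-stranded DNA ligands (here
101 bp) bound by a protein; sequencing the selected pool and comparing
k-mer frequencies against a composition-preserving shuffled null reveals
the binding specificity. This module implements exact-duplicate removal,
per-read mononucleotide shuffling, double-strand k-mer counting with a
pseudocounted frequency-ratio enrichment score, locally-maximal-seed PWM
construction, and motif match fold-change evaluation.

All k-mers are handled as base-4 integer codes (A=0, C=1, G=2, T=3,
big-endian) so counting and neighborhood enumeration are array operations.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SelexLibrary",
    "read_library",
    "write_library",
    "dedupe_reads",
    "shuffle_library",
    "count_kmers",
    "KmerEnrichment",
    "kmer_enrichment",
    "find_seeds",
    "Motif",
    "build_motif",
    "count_matches",
    "motif_fold_change",
    "replicate_enrichment_correlation",
    "encode_reads",
    "decode_reads",
    "kmer_to_code",
    "code_to_kmer",
    "revcomp",
]

_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
    _ENCODE[b + 32] = i  # lowercase
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_SETS = {v: set(k) for k, v in IUPAC.items()}


def encode_reads(reads: list[str]) -> np.ndarray:
    """Encode equal-length ACGT reads into an (N, L) uint8 code array."""
    if not reads:
        return np.zeros((0, 0), dtype=np.uint8)
    lens = {len(r) for r in reads}
    if len(lens) != 1:
        raise ValueError(f"reads of unequal length: {sorted(lens)}")
    buf = np.frombuffer("".join(reads).encode(), dtype=np.uint8)
    arr = _ENCODE[buf].reshape(len(reads), lens.pop())
    if (arr > 3).any():
        bad = int(np.argwhere((arr > 3).any(axis=1))[0][0])
        raise ValueError(f"non-ACGT base in read {bad}: {reads[bad]!r}")
    return arr


def decode_reads(arr: np.ndarray) -> list[str]:
    chars = _DECODE[arr]
    return [row.tobytes().decode() for row in chars]


def kmer_to_code(kmer: str) -> int:
    arr = _ENCODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
    if (arr > 3).any():
        raise ValueError(f"non-ACGT k-mer {kmer!r}")
    code = 0
    for b in arr:
        code = (code << 2) | int(b)
    return code


def code_to_kmer(code: int, k: int) -> str:
    bases = []
    for i in range(k):
        bases.append("ACGT"[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(bases)


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of base-4 k-mer codes (vectorized)."""
    c = np.asarray(codes, dtype=np.int64).copy()
    out = np.zeros_like(c)
    for _ in range(k):
        out = (out << 2) | (3 - (c & 3))
        c >>= 2
    return out


@lru_cache(maxsize=4)
def _rc_table(k: int) -> np.ndarray:
    return revcomp_codes(np.arange(4**k, dtype=np.int64), k)


def window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all k-length windows of each row of a read array."""
    n, length = arr.shape
    if k > length:
        raise ValueError(f"k={k} exceeds read length {length}")
    w = length - k + 1
    codes = np.zeros((n, w), dtype=np.int64)
    for i in range(k):
        codes = (codes << 2) | arr[:, i : i + w].astype(np.int64)
    return codes


@dataclass
class SelexLibrary:
    """A round of SELEX ligand reads (uniform length after QC)."""

    reads: list[str]
    round_index: int = 0
    deduplicated: bool = False
    n_duplicates_removed: int = 0
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def read_length(self) -> int:
        return len(self.reads[0]) if self.reads else 0

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode_reads(self.reads)
        return self._codes

    def base_composition(self) -> np.ndarray:
        """Mononucleotide frequencies (A, C, G, T) over all reads."""
        counts = np.bincount(self.codes.ravel(), minlength=4).astype(float)
        return counts / counts.sum()


def read_library(path, round_index: int = 0) -> SelexLibrary:
    """Load a FASTA/FASTQ (optionally gzipped) read file."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        reads = [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]
    return SelexLibrary(reads, round_index=round_index)


def write_library(lib: SelexLibrary, path) -> None:
    """Write reads as FASTQ (.fastq/.fq) or FASTA based on the extension."""
    path = Path(path)
    fastq = path.name.endswith((".fastq", ".fq"))
    with open(path, "w") as fh:
        for i, r in enumerate(lib.reads):
            if fastq:
                fh.write(f"@r{lib.round_index}_{i}\n{r}\n+\n{'I' * len(r)}\n")
            else:
                fh.write(f">r{lib.round_index}_{i}\n{r}\n")


def dedupe_reads(lib: SelexLibrary) -> SelexLibrary:
    """Collapse exact sequence duplicates (PCR repeats), keeping first copies."""
    lens = {len(r) for r in lib.reads}
    if len(lens) > 1:
        raise ValueError(f"reads of unequal length after trimming: {sorted(lens)}")
    unique = list(dict.fromkeys(lib.reads))
    return SelexLibrary(
        unique,
        round_index=lib.round_index,
        deduplicated=True,
        n_duplicates_removed=len(lib.reads) - len(unique),
    )


def shuffle_library(lib: SelexLibrary, seed: int, repeats: int = 1) -> SelexLibrary:
    """Mononucleotide shuffle: independently permute the bases of each read.

    Per-read base composition and read length are preserved exactly, which
    makes the result the composition-matched null library for k-mer
    enrichment. With ``repeats > 1`` the null pools that many independent
    shuffles of the library (frequencies are normalized by library size, so
    this only sharpens the Monte-Carlo estimate of the null k-mer
    frequencies; individual null counts are otherwise small Poisson draws
    whose noise dominates the top of the enrichment ranking).
    """
    rng = np.random.default_rng(seed)
    arr = lib.codes
    out = []
    for _ in range(max(1, repeats)):
        perm = rng.random(arr.shape).argsort(axis=1)
        out.append(np.take_along_axis(arr, perm, axis=1))
    return SelexLibrary(decode_reads(np.vstack(out)), round_index=lib.round_index,
                        deduplicated=lib.deduplicated)


def count_kmers(lib: SelexLibrary, k: int = 10, both_strands: bool = True) -> tuple[np.ndarray, int]:
    """Count every k-length window of every read (double-strand by default).

    Returns (counts indexed by k-mer code, total window count). Under
    double-strand counting the total is 2 * n_reads * (L - k + 1) and
    counts[W] == counts[revcomp(W)] exactly.
    """
    codes = window_codes(lib.codes, k)
    counts = np.bincount(codes.ravel(), minlength=4**k)
    if both_strands:
        counts = counts + counts[_rc_table(k)]
    return counts.astype(np.int64), int(counts.sum())


@dataclass
class KmerEnrichment:
    """k-mer counts in a selected vs null library and the enrichment score.

    The enrichment of k-mer W is (f_sel(W) + eps) / (f_null(W) + eps) with
    frequencies f = count / total windows and a pseudocount eps (default
    one null window, 1/total_null).
    """

    k: int
    counts_selected: np.ndarray
    counts_null: np.ndarray
    total_selected: int
    total_null: int
    pseudocount: float
    _enrichment: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def enrichment(self) -> np.ndarray:
        if self._enrichment is None:
            eps = self.pseudocount
            f_sel = self.counts_selected / self.total_selected
            f_null = self.counts_null / self.total_null
            self._enrichment = (f_sel + eps) / (f_null + eps)
        return self._enrichment

    def enrichment_of(self, kmer: str) -> float:
        return float(self.enrichment[kmer_to_code(kmer)])

    def rank_of(self, kmer: str) -> int:
        """1-based competition rank of a k-mer by descending enrichment."""
        e = self.enrichment
        return int((e > e[kmer_to_code(kmer)]).sum()) + 1

    def top_table(self, n: int = 20) -> pd.DataFrame:
        e = self.enrichment
        order = np.argsort(-e, kind="stable")[:n]
        return pd.DataFrame(
            {
                "kmer": [code_to_kmer(int(c), self.k) for c in order],
                "count_selected": self.counts_selected[order],
                "count_null": self.counts_null[order],
                "enrichment": e[order],
            }
        )

    def to_tsv(self, path, n: int = 1000) -> None:
        self.top_table(n).to_csv(path, sep="\t", index=False)


def kmer_enrichment(
    selected: SelexLibrary,
    null: SelexLibrary,
    k: int = 10,
    pseudocount: float | None = None,
) -> KmerEnrichment:
    """Double-strand k-mer enrichment of a selected library over a null.

    The null is normally the mononucleotide shuffle of the selected library
    (round-4 vs shuffled round-4); passing the round-0 input library instead
    gives round-over-input enrichment.
    """
    if not selected.reads or not null.reads:
        raise ValueError("both libraries must be non-empty")
    c_sel, t_sel = count_kmers(selected, k)
    c_null, t_null = count_kmers(null, k)
    eps = 1.0 / t_null if pseudocount is None else float(pseudocount)
    return KmerEnrichment(k, c_sel, c_null, t_sel, t_null, eps)


def _single_sub_neighbors(code: int, k: int) -> np.ndarray:
    out = []
    for i in range(k):
        shift = 2 * (k - 1 - i)
        cur = (code >> shift) & 3
        for b in range(4):
            if b != cur:
                out.append(code + ((b - cur) << shift))
    return np.asarray(out, dtype=np.int64)


def _alignment_identity(a: str, b: str, max_shift: int = 3) -> float:
    """Best ungapped-overlap identity between two k-mers (incl. revcomp)."""
    best = 0.0
    for s in (b, revcomp(b)):
        for off in range(-max_shift, max_shift + 1):
            lo = max(0, off)
            hi = min(len(a), len(s) + off)
            if hi - lo < len(a) - max_shift:
                continue
            matches = sum(1 for i in range(lo, hi) if a[i] == s[i - off])
            best = max(best, matches / len(a))
    return best


def find_seeds(
    ke: KmerEnrichment,
    n: int = 1,
    min_enrichment: float = 1.0,
    max_candidates: int = 5000,
    distinct_identity: float = 0.7,
) -> list[str]:
    """Locally maximal enriched k-mers to seed motif construction.

    A seed is a k-mer with no single-substitution neighbor of higher
    enrichment. Candidates are taken in descending enrichment order;
    seeds too similar to an already chosen one (best ungapped/revcomp
    overlap identity >= ``distinct_identity``) are skipped so that distinct
    binding motifs yield distinct seeds.
    """
    e = ke.enrichment
    order = np.argsort(-e, kind="stable")[:max_candidates]
    seeds: list[str] = []
    for code in order:
        code = int(code)
        if e[code] <= min_enrichment:
            break
        if np.any(e[_single_sub_neighbors(code, ke.k)] > e[code]):
            continue
        kmer = code_to_kmer(code, ke.k)
        if any(_alignment_identity(kmer, s) >= distinct_identity for s in seeds):
            continue
        seeds.append(kmer)
        if len(seeds) == n:
            break
    return seeds


@dataclass
class Motif:
    """A position weight matrix with its seed and IUPAC consensus.

    ``pwm`` is 4 x L, column-stochastic (rows A, C, G, T). ``match_threshold``
    is the log-odds score (base 2, against ``background``) above which a
    window counts as a motif match.
    """

    pwm: np.ndarray
    seed: str
    consensus: str
    match_threshold: float = 0.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    core_offset: int = 0

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    def log_odds(self, floor: float = 1e-3) -> np.ndarray:
        p = np.maximum(self.pwm, floor)
        return np.log2(p / self.background[:, None])

    def to_meme(self, path, name: str = "motif") -> None:
        """Minimal MEME-format motif text output."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write(f"Background letter frequencies\nA {self.background[0]:.3f} "
                     f"C {self.background[1]:.3f} G {self.background[2]:.3f} "
                     f"T {self.background[3]:.3f}\n\n")
            fh.write(f"MOTIF {name} {self.consensus}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.length}\n")
            for col in self.pwm.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.pwm, index=list("ACGT")).to_csv(path, sep="\t")


def _consensus_from_pwm(pwm: np.ndarray, degenerate_fraction: float) -> str:
    letters = []
    for col in pwm.T:
        chosen = {b for b, p in zip("ACGT", col) if p >= degenerate_fraction}
        if not chosen:
            chosen = {"ACGT"[int(np.argmax(col))]}
        letters.append(IUPAC[frozenset(chosen)])
    return "".join(letters)


def _flank_frequencies(
    lib: SelexLibrary, seed_code: int, k: int, extend: int
) -> tuple[np.ndarray, np.ndarray]:
    """Base frequencies at the ``extend`` positions flanking aligned seed hits."""
    arr = lib.codes
    codes = window_codes(arr, k)
    left = np.zeros((4, extend))
    right = np.zeros((4, extend))
    # forward-strand occurrences
    for ri, p in zip(*np.nonzero(codes == seed_code)):
        for e in range(extend):
            lp, rp = p - extend + e, p + k + e
            if lp >= 0:
                left[arr[ri, lp], e] += 1
            if rp < arr.shape[1]:
                right[arr[ri, rp], e] += 1
    # reverse-strand occurrences: flanks read complemented and mirrored
    rc_code = int(revcomp_codes(np.array([seed_code]), k)[0])
    if rc_code != seed_code:
        for ri, p in zip(*np.nonzero(codes == rc_code)):
            for e in range(extend):
                lp, rp = p + k + (extend - 1 - e), p - 1 - (extend - 1 - e)
                if lp < arr.shape[1]:
                    left[3 - arr[ri, lp], e] += 1
                if rp >= 0:
                    right[3 - arr[ri, rp], e] += 1
    return left, right


def build_motif(
    ke: KmerEnrichment,
    selected: SelexLibrary | None = None,
    extend: int = 0,
    seed: str | None = None,
    degenerate_fraction: float = 0.25,
    match_threshold: float | None = None,
) -> Motif:
    """Construct a PWM around a locally maximal enriched seed k-mer.

    Core column j: the background-corrected selected-library counts of the
    seed with position j substituted to each base (count minus the
    depth-scaled null count, floored at 0), normalized to a probability
    column. With ``extend > 0`` flanking columns are estimated from the base
    frequencies at aligned exact seed occurrences in ``selected``.

    The default match threshold is half the maximum achievable log-odds
    score of the PWM, which keeps only strong windows; pass 0.0 for the
    permissive any-positive-score rule.

    Raises ``ValueError("no signal")`` when no k-mer is enriched above 1.
    """
    if seed is None:
        found = find_seeds(ke, n=1)
        if not found:
            raise ValueError("no signal: no k-mer enriched above 1")
        seed = found[0]
    k = ke.k
    seed_code = kmer_to_code(seed)
    scale = ke.total_selected / ke.total_null
    cols = np.zeros((4, k))
    for j in range(k):
        shift = 2 * (k - 1 - j)
        cur = (seed_code >> shift) & 3
        for b in range(4):
            v = seed_code + ((b - cur) << shift)
            corr = ke.counts_selected[v] - ke.counts_null[v] * scale
            cols[b, j] = max(corr, 0.0)
        if cols[:, j].sum() == 0:
            cols[cur, j] = 1.0
    cols /= cols.sum(axis=0, keepdims=True)

    offset = 0
    if extend > 0:
        if selected is None:
            raise ValueError("flank extension requires the selected library")
        left, right = _flank_frequencies(selected, seed_code, k, extend)
        left = np.where(left.sum(0) > 0, left, 0.25)
        right = np.where(right.sum(0) > 0, right, 0.25)
        left /= left.sum(axis=0, keepdims=True)
        right /= right.sum(axis=0, keepdims=True)
        cols = np.hstack([left, cols, right])
        offset = extend

    consensus = _consensus_from_pwm(cols, degenerate_fraction)
    bg = selected.base_composition() if selected is not None else np.full(4, 0.25)
    motif = Motif(cols, seed, consensus, 0.0, bg, offset)
    if match_threshold is None:
        match_threshold = 0.5 * float(motif.log_odds().max(axis=0).sum())
    motif.match_threshold = match_threshold
    return motif


def _window_scores(arr: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Per-position best-strand log-odds scores of a motif over a read array."""
    n, length = arr.shape
    lmot = lom.shape[1]
    w = length - lmot + 1
    if w <= 0:
        return np.zeros((n, 0))
    fwd = np.zeros((n, w))
    rev = np.zeros((n, w))
    lom_rc = lom[::-1, ::-1]  # complement rows, reverse columns
    for j in range(lmot):
        fwd += lom[:, j][arr[:, j : j + w]]
        rev += lom_rc[:, j][arr[:, j : j + w]]
    return np.maximum(fwd, rev)


def count_matches(motif: Motif, lib: SelexLibrary) -> tuple[int, int]:
    """Count window positions matching the motif (best strand, once per
    position). Returns (matches, total positions)."""
    scores = _window_scores(lib.codes, motif.log_odds())
    return int((scores > motif.match_threshold).sum()), int(scores.size)


def motif_fold_change(
    motif: Motif, selected: SelexLibrary, null: SelexLibrary
) -> float:
    """Fold change of motif match rate between the selected and null library."""
    m_sel, n_sel = count_matches(motif, selected)
    m_null, n_null = count_matches(motif, null)
    eps = 1.0 / n_null
    return float((m_sel / n_sel + eps) / (m_null / n_null + eps))


def replicate_enrichment_correlation(
    ke1: KmerEnrichment, ke2: KmerEnrichment, min_count: int = 10
) -> float:
    """Pearson correlation of log enrichment between two SELEX replicates.

    Restricted to k-mers with at least ``min_count`` selected-library
    occurrences in both replicates; at sequencing-scale depth the log ratio
    of near-zero counts is pure sampling noise, so an unfiltered correlation
    measures noise rather than reproducibility.
    """
    mask = (ke1.counts_selected >= min_count) & (ke2.counts_selected >= min_count)
    if mask.sum() < 3:
        raise ValueError("too few k-mers pass the count filter")
    a = np.log(ke1.enrichment[mask])
    b = np.log(ke2.enrichment[mask])
    return float(np.corrcoef(a, b)[0, 1])
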