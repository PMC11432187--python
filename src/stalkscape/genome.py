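"""Genome-wide affinity scoring with SELEX 10-mer enrichment and
promoter binding-site calling.

Every genome position is scored with the enrichment of the 10-mer starting
there (the better of the forward and reverse-complement orientation), the
strand-aware 2 kb promoter window of each annotated gene is extracted from
a GFF3, and high-affinity sites inside promoters are called against a
genome-wide score quantile and reported as BED-like intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selex import KmerEnrichment, _ENCODE, _rc_table

__all__ = [
    "read_genome",
    "read_annotation",
    "AffinityTrack",
    "score_genome",
    "promoter_windows",
    "call_sites",
    "write_bed",
]


def read_genome(path) -> dict[str, str]:
    """Load a FASTA genome into a chrom -> sequence dict (uppercased)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_annotation(path) -> pd.DataFrame:
    """Parse gene models from a GFF3 into (gene_id, chrom, strand, tss).

    The TSS is the 5' end of the gene: ``start`` for + genes, ``end`` for
    - genes, both 1-based. Genes without a strand raise an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene.id} has no strand")
        tss = gene.start if gene.strand == "+" else gene.end
        rows.append(
            {"gene_id": gene.id, "chrom": gene.seqid, "strand": gene.strand,
             "tss": int(tss), "start": int(gene.start), "end": int(gene.end)}
        )
    return pd.DataFrame(rows)


@dataclass
class AffinityTrack:
    """Per-position genome affinity scores (one per k-mer start position).

    ``scores[chrom][p]`` is the enrichment of the better-oriented 10-mer at
    0-based position p; ``strand[chrom][p]`` is +1 if the forward k-mer
    scored at least as high as its reverse complement, else -1. Windows
    containing non-ACGT bases score 0.
    """

    k: int
    scores: dict[str, np.ndarray]
    strand: dict[str, np.ndarray]

    def all_scores(self) -> np.ndarray:
        return np.concatenate([v for v in self.scores.values()]) if self.scores else np.array([])

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, sc in self.scores.items():
                for p, v in enumerate(sc):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:.4g}\n")


def _sequence_codes(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def score_genome(genome: dict[str, str] | str, ke: KmerEnrichment) -> AffinityTrack:
    """Slide a k-wide window over each chromosome and score every position.

    The score is max(enrichment(forward k-mer), enrichment(reverse
    complement)); k-mers never observed in either library fall back to the
    pseudocount-only enrichment. Chromosomes shorter than k yield empty
    tracks.
    """
    if isinstance(genome, str):
        genome = read_genome(genome)
    k = ke.k
    e = ke.enrichment
    e_both = np.maximum(e, e[_rc_table(k)])
    fwd_wins = e >= e[_rc_table(k)]
    scores: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        codes = _sequence_codes(seq)
        n = len(codes) - k + 1
        if n <= 0:
            scores[chrom] = np.zeros(0)
            strands[chrom] = np.zeros(0, dtype=np.int8)
            continue
        bad = codes > 3
        clean = np.where(bad, 0, codes)
        wcodes = np.zeros(n, dtype=np.int64)
        for i in range(k):
            wcodes = (wcodes << 2) | clean[i : i + n].astype(np.int64)
        track = e_both[wcodes]
        strand = np.where(fwd_wins[wcodes], 1, -1).astype(np.int8)
        if bad.any():
            badwin = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
            track = np.where(badwin, 0.0, track)
        scores[chrom] = track
        strands[chrom] = strand
    return AffinityTrack(k, scores, strands)


def promoter_windows(
    annotation: pd.DataFrame,
    span: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
    mode: str = "upstream",
) -> pd.DataFrame:
    """Strand-aware promoter intervals around each TSS (0-based half-open).

    In the default ``upstream`` mode a + gene at TSS t gets [t - span, t)
    and a - gene gets [t, t + span); ``downstream`` mirrors this and
    ``both`` covers [t - span, t + span). Intervals are clipped to
    chromosome bounds when sizes are provided.
    """
    if mode not in ("upstream", "downstream", "both"):
        raise ValueError(f"unknown promoter mode {mode!r}")
    rows = []
    for _, g in annotation.iterrows():
        t = int(g["tss"])
        plus = g["strand"] == "+"
        if mode == "upstream":
            start, end = (t - span, t) if plus else (t, t + span)
        elif mode == "downstream":
            start, end = (t, t + span) if plus else (t - span, t)
        else:
            start, end = t - span, t + span
        start = max(start, 0)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g["chrom"]])
        rows.append(
            {"chrom": g["chrom"], "start": start, "end": end,
             "gene_id": g["gene_id"], "strand": g["strand"], "tss": t}
        )
    return pd.DataFrame(rows)


def call_sites(
    track: AffinityTrack,
    windows: pd.DataFrame,
    threshold_quantile: float = 0.999,
    genome: dict[str, str] | None = None,
    orient_motif=None,
) -> pd.DataFrame:
    """Call high-affinity binding sites within promoter windows.

    The calling threshold is the genome-wide ``threshold_quantile`` quantile
    of the affinity track; promoter positions strictly above it are grouped
    into runs of consecutive above-threshold positions and each run is
    reduced to its local score maximum. Sites carry the owning gene and the
    signed distance of the site to the TSS along the gene's orientation
    (negative = upstream).

    Because double-strand k-mer counting makes enrichment exactly
    reverse-complement symmetric, the affinity track alone cannot orient a
    site; pass the ``genome`` sequences together with an ``orient_motif``
    (a :class:`~stalkscape.selex.Motif`) to set each site's strand to the
    orientation scoring higher under the motif's core columns.
    """
    if windows.empty:
        warnings.warn("no promoter windows; returning no sites", stacklevel=2)
        return pd.DataFrame(
            columns=["chrom", "start", "end", "gene_id", "score", "strand",
                     "distance_to_tss"]
        )
    k = track.k
    threshold = float(np.quantile(track.all_scores(), threshold_quantile))
    rows = []
    for _, w in windows.iterrows():
        sc = track.scores.get(w["chrom"])
        if sc is None or sc.size == 0:
            continue
        lo = int(w["start"])
        hi = min(int(w["end"]) - k + 1, sc.size)  # full k-mer inside window
        if hi <= lo:
            continue
        seg = sc[lo:hi]
        above = seg > threshold
        if not above.any():
            continue
        # split above-threshold positions into consecutive runs
        pos = np.nonzero(above)[0]
        splits = np.nonzero(np.diff(pos) > 1)[0] + 1
        for run in np.split(pos, splits):
            best = run[np.argmax(seg[run])]
            p = lo + int(best)
            tss0 = int(w["tss"]) - 1
            if w["strand"] == "+":
                dist = p - tss0
            else:
                dist = tss0 - (p + k - 1)
            strand = "+" if track.strand[w["chrom"]][p] > 0 else "-"
            if genome is not None and orient_motif is not None:
                strand = _orient_site(genome[w["chrom"]][p : p + k], orient_motif)
            rows.append(
                {
                    "chrom": w["chrom"],
                    "start": p,
                    "end": p + k,
                    "gene_id": w["gene_id"],
                    "score": float(sc[p]),
                    "strand": strand,
                    "distance_to_tss": int(dist),
                }
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "score", "strand",
                       "distance_to_tss"]
    )
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def _orient_site(kmer: str, motif) -> str:
    """Strand of the motif core's better-scoring orientation of a k-mer."""
    from .selex import revcomp, _ENCODE as enc

    lom = motif.log_odds()[:, motif.core_offset : motif.core_offset + len(kmer)]

    def score(s: str) -> float:
        codes = enc[np.frombuffer(s.encode(), dtype=np.uint8)]
        if (codes > 3).any():
            return -np.inf
        return float(lom[codes, np.arange(len(s))].sum())

    return "+" if score(kmer) >= score(revcomp(kmer)) else "-"


def write_bed(sites: pd.DataFrame, path) -> None:
    """BED6 export: chrom, start, end, name=gene_id, score, strand."""
    with open(path, "w") as fh:
        for _, s in sites.iterrows():
            fh.write(
                f"{s['chrom']}\t{s['start']}\t{s['end']}\t{s['gene_id']}\t"
                f"{s['score']:.4g}\t{s['strand']}\n"
            )
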