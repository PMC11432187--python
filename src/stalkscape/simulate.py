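"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the structure of the emulated study: a 19-internode,
two-replicate stalk transcriptome with four separable developmental zones
and 12 planted co-expression cluster archetypes; planted correlated gene
modules with trait vectors coupled to one module at a target correlation;
SELEX libraries evolved over four selection rounds from a hidden PWM by
logistic occupancy of the best-scoring ligand window; and a toy genome with
annotated genes and motif instances planted in known promoters.

Everything is driven by a single master seed through independent spawned
random streams, so all outputs are bit-reproducible and truth labels
round-trip through the pipeline for scoring.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, study_internodes, parse_internode_label
from .selex import SelexLibrary, decode_reads, kmer_to_code, revcomp, revcomp_codes

__all__ = [
    "SimConfig",
    "ZONE_OF",
    "simulate_expression",
    "simulate_module_expression",
    "simulate_traits",
    "simulate_tf_annotation",
    "simulate_selex",
    "simulate_genome",
    "write_genome_fasta",
    "write_gff3",
    "simulate_all",
]

#: developmental zone of each internode in the emulated 19-internode design:
#: Zone I the earliest-stage internodes, Zone II the basal internodes of the
#: two later stages, Zone III the upper internodes, Zone IV the two
#: fast-growing mid-stalk internodes of the last stage.
ZONE_OF = {
    "FS1": "I", "SS1": "I", "SS2": "I", "SS3": "I",
    "TS1": "II", "TS2": "II", "TS3": "II", "LS1": "II", "LS2": "II", "LS3": "II",
    "TS4": "III", "TS5": "III", "TS6": "III", "LS4": "III",
    "LS7": "III", "LS8": "III", "LS9": "III",
    "LS5": "IV", "LS6": "IV",
}

ZONES = ("I", "II", "III", "IV")


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults emulate the study design."""

    seed: int = 0
    # expression / clustering
    n_genes: int = 3000
    n_clusters: int = 12
    n_zones: int = 4
    amplitude: float = 4.5  # log2 dynamic range of cluster archetypes
    bio_noise_sd: float = 0.4  # per-internode biological noise, log2 scale
    rep_noise_sd: float = 0.25  # replicate (technical) noise, log2 scale
    flat_fraction: float = 0.2  # genes with no developmental signal
    # planted modules
    module_sizes: tuple[int, ...] = (100, 80, 60)
    module_loading_range: tuple[float, float] = (0.85, 0.95)
    trait_r_target: float = 0.9
    # TF annotation
    n_tfs: int = 240
    tf_families: tuple[str, ...] = (
        "MYB", "NAC", "bHLH", "WRKY", "AP2/ERF-ERF", "MADS-M-type",
        "C2H2", "bZIP", "GRAS", "ARF", "Whirly", "STAT",
    )
    # SELEX
    consensus: str = "TCACCTAACT"  # MYB-like AC-rich element
    pwm_dominant_p: float = 0.85
    selection_rounds: int = 4
    reads_per_round: int = 20000
    pool_size: int = 8_000_000  # distinct ligands in the virtual initial pool
    ligand_length: int = 101
    sel_midpoint_frac: float = 0.75  # logistic midpoint, fraction of max score
    sel_temperature_frac: float = 0.15  # logistic width, fraction of max score
    # genome
    genome_length: int = 1_000_000
    n_genes_annotated: int = 20
    n_planted_sites: int = 3
    promoter_span: int = 2000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig requires a seed")
        if not 0 < self.trait_r_target < 1:
            raise ValueError("trait_r_target must be in (0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for a named sub-stream of the master seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _cluster_archetypes(cfg: SimConfig) -> pd.DataFrame:
    """Cluster mean profiles over the 19 internodes on the log2 scale.

    Each archetype assigns one of four graded expression levels to each
    zone (a distinct permutation of 0..3 per cluster), giving profiles that
    are constant within a zone, mutually distinguishable, and broad enough
    that member genes clear a MAD cutoff of 1.
    """
    perms = list(itertools.permutations(range(4)))
    step = max(1, len(perms) // cfg.n_clusters)
    chosen = [perms[(i * step) % len(perms)] for i in range(cfg.n_clusters)]
    internodes = study_internodes()
    unit = cfg.amplitude / 3.0
    rows = []
    for ci, perm in enumerate(chosen):
        level = {z: perm[zi] * unit for zi, z in enumerate(ZONES)}
        # small deterministic within-zone tilt so internodes are not exact ties
        tilt = 0.05 * ((ci % 3) - 1)
        prof = [
            level[ZONE_OF[inn]] + tilt * j / len(internodes)
            for j, inn in enumerate(internodes)
        ]
        rows.append(prof)
    return pd.DataFrame(rows, index=[f"C{i + 1}" for i in range(cfg.n_clusters)],
                        columns=internodes)


def simulate_expression(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Two-replicate 19-internode TPM matrix with planted clusters and zones.

    Gene log2 profiles are cluster archetypes plus per-gene biological noise
    (shared between replicates); replicates add independent technical noise.
    A ``flat_fraction`` of genes has no developmental signal. Linear TPM is
    2^x - 1 clipped at 0. Returns the matrix, a sample sheet, and truth
    labels (gene cluster, internode zone, archetypes).
    """
    rng = cfg.rng(1)
    arch = _cluster_archetypes(cfg)
    internodes = study_internodes()
    n_flat = int(round(cfg.n_genes * cfg.flat_fraction))
    n_sig = cfg.n_genes - n_flat
    clusters = np.repeat(np.arange(cfg.n_clusters), np.diff(
        np.linspace(0, n_sig, cfg.n_clusters + 1).astype(int)))
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    truth_cluster = pd.Series(
        [f"C{c + 1}" for c in clusters] + ["flat"] * n_flat, index=gene_ids,
        name="cluster",
    )

    baseline = rng.uniform(2.0, 8.0, cfg.n_genes)
    scale = rng.uniform(0.8, 1.2, cfg.n_genes)
    profiles = np.tile(baseline[:, None], (1, len(internodes)))
    profiles[:n_sig] += scale[:n_sig, None] * arch.to_numpy()[clusters]
    profiles += rng.normal(0.0, cfg.bio_noise_sd, profiles.shape)

    cols, meta_rows = {}, []
    for rep in (1, 2):
        noise = rng.normal(0.0, cfg.rep_noise_sd, profiles.shape)
        vals = profiles + noise
        for j, inn in enumerate(internodes):
            sid = f"{inn}_r{rep}"
            cols[sid] = vals[:, j]
            stage, idx = parse_internode_label(inn)
            meta_rows.append(
                {"sample_id": sid, "stage": stage, "internode_index": idx,
                 "replicate": rep}
            )
    log = pd.DataFrame(cols, index=gene_ids)
    tpm = np.maximum(2.0**log - 1.0, 0.0)
    order = [f"{inn}_r{rep}" for inn in internodes for rep in (1, 2)]
    em = ExpressionMatrix(tpm[order])
    meta = pd.DataFrame(meta_rows)
    truth = {
        "cluster": truth_cluster,
        "zone": pd.Series(ZONE_OF, name="zone").loc[internodes],
        "archetypes": arch,
    }
    return em, meta, truth


def _module_factors(cfg: SimConfig) -> pd.DataFrame:
    """Standardized latent profiles of the planted modules over 19 internodes.

    Factor 1 peaks in Zone IV (the elongation-zone, length-coupled module),
    factor 2 decreases monotonically bottom-to-top (the diameter-coupled
    module), further factors are mid-stalk bumps.
    """
    internodes = study_internodes()
    n = len(internodes)
    pos = np.arange(n) / (n - 1)
    facs = [np.array([3.0 if ZONE_OF[i] == "IV" else (1.0 if ZONE_OF[i] == "III" else 0.0)
                      for i in internodes])]
    facs.append(-np.linspace(0, 3, n))
    for j in range(2, len(cfg.module_sizes)):
        center = 0.25 + 0.5 * (j - 2) / max(len(cfg.module_sizes) - 2, 1)
        facs.append(np.exp(-((pos - center) ** 2) / 0.02))
    out = pd.DataFrame(
        np.stack(facs[: len(cfg.module_sizes)]),
        index=[f"M{i + 1}" for i in range(len(cfg.module_sizes))],
        columns=internodes,
    )
    z = out.sub(out.mean(axis=1), axis=0).div(out.std(axis=1, ddof=0), axis=0)
    return z


def simulate_module_expression(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Log2 expression with planted correlated gene modules.

    Genes of module m follow x_g = lambda_g f_m + sqrt(1 - lambda_g^2) eps
    around a baseline, where f_m is the module's latent profile and
    lambda_g is drawn from ``module_loading_range`` (pairwise in-module
    correlation lambda_i lambda_j). Background genes are pure noise (truth
    label 0). Returns the log-scale matrix, truth labels, and the factors.
    """
    rng = cfg.rng(2)
    internodes = study_internodes()
    n = len(internodes)
    factors = _module_factors(cfg)
    sizes = cfg.module_sizes
    n_bg = cfg.n_genes - sum(sizes)
    if n_bg < 0:
        raise ValueError("module sizes exceed n_genes")
    labels, rows = [], []
    lo, hi = cfg.module_loading_range
    for mi, size in enumerate(sizes):
        f = factors.iloc[mi].to_numpy()
        lam = rng.uniform(lo, hi, size)
        eps = rng.normal(0.0, 1.0, (size, n))
        rows.append(lam[:, None] * f + np.sqrt(1 - lam[:, None] ** 2) * eps)
        labels.extend([mi + 1] * size)
    rows.append(rng.normal(0.0, 1.0, (n_bg, n)))
    labels.extend([0] * n_bg)
    x = np.vstack(rows) + 5.0
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    em = ExpressionMatrix(
        pd.DataFrame(x, index=gene_ids, columns=internodes), log_transformed=True
    )
    return em, pd.Series(labels, index=gene_ids, name="module"), factors


def simulate_traits(
    cfg: SimConfig, eigen_truth: pd.DataFrame
) -> pd.DataFrame:
    """Internode trait table coupled to planted module profiles.

    Internode length is coupled to the first latent module profile and stalk
    diameter to the second, each at population correlation
    ``trait_r_target``; the noise component is independent standard normal,
    so the realized sample correlation at n = 19 follows the ordinary
    sampling distribution of Pearson r around the target.
    """
    rng = cfg.rng(3)
    r = cfg.trait_r_target

    def couple(f: np.ndarray) -> np.ndarray:
        z = (f - f.mean()) / f.std()
        return r * z + np.sqrt(1 - r**2) * rng.normal(0.0, 1.0, f.size)

    f_len = eigen_truth.iloc[0].to_numpy()
    f_dia = eigen_truth.iloc[1].to_numpy() if len(eigen_truth) > 1 else -f_len
    length = 10.0 + 3.0 * couple(f_len)
    diameter = 12.0 + 2.5 * couple(f_dia)
    return pd.DataFrame(
        {"length_cm": np.maximum(length, 0.5), "diameter_mm": np.maximum(diameter, 0.5)},
        index=pd.Index(eigen_truth.columns, name="internode"),
    )


def simulate_tf_annotation(cfg: SimConfig, gene_ids) -> pd.Series:
    """Assign a TF family to a random subset of genes (one family each)."""
    rng = cfg.rng(4)
    genes = rng.choice(list(gene_ids), size=min(cfg.n_tfs, len(gene_ids)),
                       replace=False)
    fams = rng.choice(cfg.tf_families, size=len(genes))
    return pd.Series(fams, index=genes, name="family")


def _planted_pwm(cfg: SimConfig) -> np.ndarray:
    """Column-stochastic 4 x k PWM with the configured consensus dominance."""
    k = len(cfg.consensus)
    pwm = np.full((4, k), (1.0 - cfg.pwm_dominant_p) / 3.0)
    for j, b in enumerate(cfg.consensus):
        pwm["ACGT".index(b), j] = cfg.pwm_dominant_p
    return pwm


def _kmer_score_table(pwm: np.ndarray) -> np.ndarray:
    """Best-strand log2-odds score of every k-mer code under a PWM."""
    k = pwm.shape[1]
    lom = np.log2(pwm / 0.25)
    scores = np.zeros(4**k)
    for j in range(k):
        digit = (np.arange(4**k) >> (2 * (k - 1 - j))) & 3
        scores += lom[:, j][digit]
    rc = revcomp_codes(np.arange(4**k, dtype=np.int64), k)
    return np.maximum(scores, scores[rc])


def _best_window_scores(block: np.ndarray, table: np.ndarray, k: int) -> np.ndarray:
    """Best k-mer window score of each read (rolling base-4 code)."""
    n, length = block.shape
    mask = (1 << (2 * k)) - 1
    code = np.zeros(n, dtype=np.int64)
    best = np.full(n, -np.inf)
    for j in range(length):
        code = ((code << 2) & mask) | block[:, j].astype(np.int64)
        if j >= k - 1:
            np.maximum(best, table[code], out=best)
    return best


def simulate_selex(
    cfg: SimConfig,
    pwm: np.ndarray | None = None,
    replicate: int = 0,
) -> tuple[list[SelexLibrary], np.ndarray]:
    """Evolve SELEX libraries from a hidden PWM over selection rounds.

    The initial pool is a virtual library of ``pool_size`` distinct uniform
    random ligands (generated and scored in chunks, never held in memory).
    Each ligand's occupancy is a logistic function of its best
    double-strand PWM log-odds window. One round of selection plus
    amplification to depth multiplies a ligand's abundance by its
    occupancy, so the sequenced sample of round r is a with-replacement
    draw with probability proportional to occupancy^r (round 0 is a uniform
    draw of the input library); amplification duplicates arise naturally
    and are what :func:`~stalkscape.selex.dedupe_reads` removes. Returns
    the libraries for rounds 0..R and the ground-truth PWM.
    """
    if pwm is None:
        pwm = _planted_pwm(cfg)
    k = pwm.shape[1]
    table = _kmer_score_table(pwm)
    max_score = float(table.max())
    mid = cfg.sel_midpoint_frac * max_score
    temp = max(cfg.sel_temperature_frac * max_score, 1e-9)

    n = cfg.pool_size
    chunk = 250_000
    starts = list(range(0, n, chunk))
    root = np.random.SeedSequence([cfg.seed, 50 + replicate])
    chunk_seeds = root.spawn(len(starts))
    sample_rng = np.random.default_rng(root.spawn(len(starts) + 1)[-1])

    # pass 1: occupancy of every virtual ligand
    occupancy = np.empty(n)
    for ci, s in enumerate(starts):
        size = min(chunk, n - s)
        block = np.random.default_rng(chunk_seeds[ci]).integers(
            0, 4, (size, cfg.ligand_length), dtype=np.uint8
        )
        best = _best_window_scores(block, table, k)
        occupancy[s : s + size] = 1.0 / (1.0 + np.exp(-(best - mid) / temp))

    # per-round sequenced samples: indices into the virtual pool
    takes = [sample_rng.choice(n, size=min(cfg.reads_per_round, n), replace=False)]
    w = np.ones(n)
    for _ in range(cfg.selection_rounds):
        w = w * occupancy
        takes.append(
            sample_rng.choice(n, size=cfg.reads_per_round, replace=True,
                              p=w / w.sum())
        )

    # pass 2: materialize only the ligands any round sampled
    needed = np.unique(np.concatenate(takes))
    seqs: dict[int, str] = {}
    for ci, s in enumerate(starts):
        size = min(chunk, n - s)
        local = needed[(needed >= s) & (needed < s + size)]
        if local.size == 0:
            continue
        block = np.random.default_rng(chunk_seeds[ci]).integers(
            0, 4, (size, cfg.ligand_length), dtype=np.uint8
        )
        for gi, read in zip(local, decode_reads(block[local - s])):
            seqs[int(gi)] = read

    libs = [
        SelexLibrary([seqs[int(i)] for i in take], round_index=rnd)
        for rnd, take in enumerate(takes)
    ]
    return libs, pwm


def simulate_genome(
    cfg: SimConfig, consensus: str | None = None
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Random genome with annotated genes and motif sites planted in promoters.

    Genes are placed on both strands with a minimum spacing (bounded
    redraws), and the consensus (reverse-complemented for minus-strand
    genes) is written at a known offset inside the upstream promoter window
    of ``n_planted_sites`` genes. Returns the sequence dict, the gene table
    (gene_id, chrom, strand, tss, start, end), and the truth site table.
    """
    rng = cfg.rng(6)
    consensus = consensus or cfg.consensus
    k = len(consensus)
    span = cfg.promoter_span
    length = cfg.genome_length
    codes = rng.integers(0, 4, length, dtype=np.uint8)

    gene_len = 1500
    margin = span + gene_len + 50
    min_gap = 2 * span + gene_len
    tss_list: list[int] = []
    for _ in range(1000 * cfg.n_genes_annotated):
        t = int(rng.integers(margin, length - margin))
        if all(abs(t - u) >= min_gap for u in tss_list):
            tss_list.append(t)
        if len(tss_list) == cfg.n_genes_annotated:
            break
    else:
        raise RuntimeError("could not place genes with the required spacing")
    tss_list.sort()

    strands = rng.choice(["+", "-"], size=cfg.n_genes_annotated)
    genes = []
    for i, (t, s) in enumerate(zip(tss_list, strands)):
        gid = f"PMG{i + 1:03d}"
        if s == "+":
            start, end = t, t + gene_len - 1
        else:
            start, end = t - gene_len + 1, t
        genes.append({"gene_id": gid, "chrom": "chr1", "strand": s,
                      "tss": t, "start": start, "end": end})
    genes = pd.DataFrame(genes)

    planted = rng.choice(cfg.n_genes_annotated, size=cfg.n_planted_sites,
                         replace=False)
    cons_codes = np.array([("ACGT".index(b)) for b in consensus], dtype=np.uint8)
    truth = []
    for gi in planted:
        g = genes.iloc[gi]
        d = int(rng.integers(150, span - 150))
        if g["strand"] == "+":
            p = int(g["tss"]) - d - 1  # 0-based start inside [tss-span, tss)
            codes[p : p + k] = cons_codes
        else:
            p = int(g["tss"]) + d - 1  # inside [tss, tss+span)
            codes[p : p + k] = 3 - cons_codes[::-1]
        truth.append({"chrom": "chr1", "start": p, "end": p + k,
                      "gene_id": g["gene_id"], "strand": g["strand"]})
    seq = decode_reads(codes[None, :])[0]
    return {"chr1": seq}, genes, pd.DataFrame(truth)


def write_genome_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tstalkscape\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def simulate_all(out_dir, cfg: SimConfig) -> dict[str, Path]:
    """Write every synthetic input the pipeline consumes, plus truth files."""
    from .selex import write_library

    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    em, meta, truth = simulate_expression(cfg)
    em.to_tsv(out / "expr.tsv")
    meta.drop(columns=["internode"], errors="ignore").to_csv(
        out / "meta.tsv", sep="\t", index=False
    )
    ann = simulate_tf_annotation(cfg, em.gene_ids)
    ann.rename("family").to_csv(out / "tf_families.tsv", sep="\t",
                                index_label="gene_id")
    factors = _module_factors(cfg)
    traits = simulate_traits(cfg, factors)
    traits.to_csv(out / "traits.tsv", sep="\t")
    truth["cluster"].to_csv(out / "truth" / "clusters.tsv", sep="\t",
                            index_label="gene_id")
    truth["zone"].to_csv(out / "truth" / "zones.tsv", sep="\t",
                         index_label="internode")

    libs, pwm = simulate_selex(cfg)
    for lib in libs:
        p = out / f"r{lib.round_index}.fastq"
        write_library(lib, p)
        paths[f"r{lib.round_index}"] = p

    genome, genes, sites = simulate_genome(cfg)
    write_genome_fasta(genome, out / "genome.fa")
    write_gff3(genes, out / "genes.gff3")
    sites.to_csv(out / "truth" / "planted_sites.tsv", sep="\t", index=False)
    with open(out / "truth" / "pwm.json", "w") as fh:
        json.dump({"consensus": cfg.consensus, "pwm": pwm.tolist()}, fh, indent=1)

    for name in ("expr.tsv", "meta.tsv", "traits.tsv", "tf_families.tsv",
                 "genome.fa", "genes.gff3"):
        paths[name.split(".")[0]] = out / name
    return paths
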