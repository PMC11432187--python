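"""End-to-end pipeline orchestration from a single config file.

Stages run in dependency order (load -> hvg -> zones -> cluster -> tf ->
network -> module_trait -> hubs -> selex -> scan); each stage writes its
outputs plus a JSON manifest recording parameters, input file hashes, and
the package version, and a completed stage (manifest + outputs present) is
skipped on re-runs so a pipeline can resume after a failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, expression, genome, hvg, network, selex, tf

log = logging.getLogger("stalkscape")

DEFAULTS = {
    "log2_offset": 1.0,
    "mad_cutoff": 1.0,
    "zones": 4,
    "clusters": 12,
    "tf_groups": 6,
    "beta": 9,  # or "auto" to derive from the power scan
    "min_module_size": 50,
    "top_n": 100,
    "k": 10,
    "span": 2000,
    "quantile": 0.999,
    "seed": 0,
}

STAGE_ORDER = [
    "load", "hvg", "zones", "cluster", "tf", "network", "module_trait",
    "hubs", "selex", "scan",
]


def read_config(path) -> dict:
    """Read a TOML or YAML pipeline config and fill in defaults."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        cfg = tomllib.loads(path.read_text())
    else:
        import yaml

        cfg = yaml.safe_load(path.read_text())
    params = dict(DEFAULTS)
    params.update(cfg.get("params", {}))
    cfg["params"] = params
    if "inputs" not in cfg or "out_dir" not in cfg:
        raise ValueError("config must define 'inputs' and 'out_dir'")
    return cfg


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


class PipelineRun:
    """Stateful runner: executes stages, writes manifests, supports resume."""

    def __init__(self, config: dict):
        self.config = config
        self.params = config["params"]
        self.inputs = config["inputs"]
        self.out = Path(config["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}

    # -- manifest helpers ---------------------------------------------------
    def _manifest_path(self, stage: str) -> Path:
        return self.out / f"{stage}.manifest.json"

    def _write_manifest(self, stage: str, outputs: list[Path], params: dict) -> None:
        manifest = {
            "stage": stage,
            "version": __version__,
            "params": params,
            "inputs": {k: _hash_file(v) for k, v in self.inputs.items()
                       if Path(str(v)).is_file()},
            "outputs": [str(p) for p in outputs],
        }
        self._manifest_path(stage).write_text(json.dumps(manifest, indent=1))

    def _complete(self, stage: str) -> bool:
        mp = self._manifest_path(stage)
        if not mp.exists():
            return False
        try:
            manifest = json.loads(mp.read_text())
        except json.JSONDecodeError as err:
            raise RuntimeError(f"stage {stage}: corrupt manifest {mp}") from err
        missing = [p for p in manifest["outputs"] if not Path(p).exists()]
        if missing:
            raise RuntimeError(f"stage {stage}: missing outputs {missing}")
        return True

    def _require(self, key: str, stage: str):
        if key not in self.state:
            raise RuntimeError(
                f"stage {stage} needs '{key}' from an earlier stage; "
                "run the pipeline from the start"
            )
        return self.state[key]

    # -- stages -------------------------------------------------------------
    def stage_load(self) -> list[Path]:
        p = self.params
        em = expression.read_expression(self.inputs["expr"], log2_offset=0.0)
        meta = expression.read_samples(self.inputs["meta"])
        rep = expression.replicate_correlation(em, meta)
        collapsed = expression.collapse_replicates(em, meta).log2(p["log2_offset"])
        self.state["log_expr"] = collapsed
        out = [self.out / "replicate_correlation.tsv", self.out / "log_expr.tsv"]
        rep.to_csv(out[0], sep="\t", index=False)
        collapsed.to_tsv(out[1])
        return out

    def stage_hvg(self) -> list[Path]:
        em = self._require("log_expr", "hvg")
        hs = hvg.select_hvgs(em, cutoff=self.params["mad_cutoff"])
        self.state["hvgs"] = hs
        self.state["hvg_expr"] = em.subset_genes(hs.genes)
        out = [self.out / "hvgs.tsv"]
        hs.to_tsv(out[0])
        return out

    def stage_zones(self) -> list[Path]:
        za = hvg.assign_zones(self._require("hvg_expr", "zones"),
                              k=self.params["zones"])
        self.state["zones"] = za
        out = [self.out / "zones.tsv"]
        za.to_tsv(out[0])
        return out

    def stage_cluster(self) -> list[Path]:
        fc = hvg.fuzzy_cmeans(
            self._require("hvg_expr", "cluster"),
            c=self.params["clusters"],
            seed=self.params["seed"],
        )
        self.state["clustering"] = fc
        out = [self.out / "membership.tsv", self.out / "clusters.tsv"]
        fc.to_tsv(*out)
        return out

    def stage_tf(self) -> list[Path]:
        ann = expression.read_tf_annotation(self.inputs["tf_families"])
        hs = self._require("hvgs", "tf")
        ratios = tf.family_ratios(hs, ann)
        hvtfs = [g for g in hs.genes if g in set(ann.index)]
        out = [self.out / "tf_ratios.tsv"]
        ratios.to_tsv(out[0])
        if len(hvtfs) >= self.params["tf_groups"]:
            em = self._require("log_expr", "tf").subset_genes(hvtfs)
            groups, _ = tf.group_hvtfs(em, k=self.params["tf_groups"])
            enrich = tf.family_overrepresentation(groups, ann)
            out += [self.out / "tf_groups.tsv", self.out / "tf_enrichment.tsv"]
            groups.to_csv(out[1], sep="\t", index_label="gene_id")
            enrich.to_csv(out[2], sep="\t", index=False)
        return out

    def stage_network(self) -> list[Path]:
        x = self._require("hvg_expr", "network").data
        beta = self.params["beta"]
        scan = network.power_scan(x)
        if beta == "auto":
            beta = scan.chosen_beta or 9
        adj = network.adjacency_matrix(x, int(beta))
        tom = network.compute_tom(adj)
        labels = network.detect_modules(
            tom, gene_ids=x.index, min_module_size=self.params["min_module_size"]
        )
        mes = network.module_eigengene(x, labels)
        self.state.update({"tom": tom, "modules": labels, "eigengenes": mes,
                           "beta": int(beta)})
        out = [self.out / "power_scan.tsv", self.out / "modules.tsv",
               self.out / "eigengenes.tsv"]
        scan.table.to_csv(out[0], sep="\t", index=False)
        pd.DataFrame({"module": labels,
                      "color": network.module_colors(labels)}).to_csv(
            out[1], sep="\t", index_label="gene_id")
        mes.to_csv(out[2], sep="\t", index_label="sample")
        return out

    def stage_module_trait(self) -> list[Path]:
        traits = expression.read_traits(self.inputs["traits"])
        mes = self._require("eigengenes", "module_trait")
        res = network.module_trait(mes, traits)
        self.state["module_trait"] = res
        out = [self.out / "module_trait.tsv"]
        res.correlations.to_csv(out[0], sep="\t", index=False)
        return out

    def stage_hubs(self) -> list[Path]:
        labels = self._require("modules", "hubs")
        tom = self._require("tom", "hubs")
        res = self._require("module_trait", "hubs").correlations
        best = res.loc[res["r"].abs().idxmax(), "module"]
        module = int(str(best).removeprefix("ME"))
        hn = network.hub_network(tom, labels, module, top_n=self.params["top_n"])
        out = [self.out / "hub_nodes.tsv", self.out / "hub_edges.tsv"]
        hn.nodes.to_csv(out[0], sep="\t", index_label="gene_id")
        hn.edges.to_csv(out[1], sep="\t", index=False)
        return out

    def stage_selex(self) -> list[Path]:
        p = self.params
        selected = selex.read_library(self.inputs["selex_selected"],
                                      round_index=p.get("selex_round", 4))
        selected = selex.dedupe_reads(selected)
        null = selex.shuffle_library(selected, seed=p["seed"],
                                     repeats=p.get("null_shuffles", 10))
        ke = selex.kmer_enrichment(selected, null, k=p["k"])
        motif = selex.build_motif(ke, selected, extend=2)
        fold = selex.motif_fold_change(motif, selected, null)
        self.state["kmer_enrichment"] = ke
        out = [self.out / "kmers.tsv", self.out / "motif.meme",
               self.out / "motif_pwm.tsv"]
        ke.to_tsv(out[0])
        motif.to_meme(out[1])
        motif.to_tsv(out[2])
        (self.out / "motif_fold_change.txt").write_text(f"{fold:.4f}\n")
        return out + [self.out / "motif_fold_change.txt"]

    def stage_scan(self) -> list[Path]:
        p = self.params
        ke = self._require("kmer_enrichment", "scan")
        seqs = genome.read_genome(self.inputs["genome"])
        ann = genome.read_annotation(self.inputs["gff"])
        track = genome.score_genome(seqs, ke)
        windows = genome.promoter_windows(
            ann, span=p["span"],
            chrom_sizes={c: len(s) for c, s in seqs.items()},
        )
        sites = genome.call_sites(track, windows, threshold_quantile=p["quantile"])
        out = [self.out / "sites.bed", self.out / "sites.tsv"]
        genome.write_bed(sites, out[0])
        sites.to_csv(out[1], sep="\t", index=False)
        return out

    # -- driver -------------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> Path:
        stages = stages or [s for s in STAGE_ORDER if self._stage_enabled(s)]
        for stage in stages:
            fn = getattr(self, f"stage_{stage}")
            if self._complete(stage) and self._stage_resumable(stage):
                log.info("stage %s already complete; skipping", stage)
                continue
            log.info("running stage %s", stage)
            outputs = fn()
            self._write_manifest(stage, outputs, self.params)
        return self.out

    def _stage_enabled(self, stage: str) -> bool:
        if stage in ("selex", "scan"):
            need = {"selex": ["selex_selected"], "scan": ["genome", "gff"]}[stage]
            return all(k in self.inputs for k in need)
        if stage == "tf":
            return "tf_families" in self.inputs
        if stage == "module_trait" or stage == "hubs":
            return "traits" in self.inputs
        return True

    def _stage_resumable(self, stage: str) -> bool:
        # stages whose in-memory state later stages need cannot be skipped
        # unless that state is already present
        producers = {
            "load": "log_expr", "hvg": "hvgs", "network": "modules",
            "module_trait": "module_trait", "selex": "kmer_enrichment",
        }
        key = producers.get(stage)
        return key is None or key in self.state


def run_pipeline(config: dict | str | Path) -> Path:
    """Run every configured stage; returns the run directory."""
    if not isinstance(config, dict):
        config = read_config(config)
    else:
        params = dict(DEFAULTS)
        params.update(config.get("params", {}))
        config = {**config, "params": params}
    return PipelineRun(config).run()
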