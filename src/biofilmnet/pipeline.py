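"""End-to-end orchestration with a single config, structured logging
and per-stage seeds.

All randomness flows from one root seed, expanded per stage by a stable
label (CRC32 of the stage name), so any stage re-run in isolation
reproduces its in-pipeline output bit for bit.  The run manifest
records the config hash, package versions and every derived seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__, diversity, io, module_env, network, ordination, preprocess
from .exceptions import ConfigError, PipelineError

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline", "stage_seed"]

DEFAULT_ENV_VARIABLES = [
    "NDVI", "NDVI.R", "Altitude", "pH", "Cond", "DOC", "TN", "TP", "BFC", "BFN", "BFP",
]

DEFAULT_VPA_GROUPS = {
    "nutrients": ["DOC", "TN", "TP", "BFC", "BFN", "BFP"],
    "ndvi": ["NDVI", "NDVI.R"],
    "other": ["Altitude", "pH", "Cond"],
}


def default_config() -> dict:
    return {
        "inputs": {
            "otu_table": None,
            "table_format": "classic_tsv",
            "metadata": None,
            "tree": None,
        },
        "filter": {"remove_singletons": True, "exclude_lineage_keywords": []},
        "rarefaction": {"depth": 25884},
        "classes": {"low": 1e-4, "high": 1e-2},
        "ordination": {
            "variables": list(DEFAULT_ENV_VARIABLES),
            "n_permutations": 999,
            "vpa_groups": {k: list(v) for k, v in DEFAULT_VPA_GROUPS.items()},
        },
        "network": {
            "min_prevalence": 0.5,
            "min_mean_abundance": 1e-4,
            "r_threshold": 0.8,
            "alpha": 0.05,
            "n_random": 99,
            "algorithm": "louvain",
            "zi_threshold": 2.5,
            "pi_threshold": 0.62,
        },
        "module_env": {
            "variables": list(DEFAULT_ENV_VARIABLES),
            "control": "Altitude",
            "min_module_size": 50,
            "n_permutations": 999,
        },
        "seed": 42,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    return _merge(default_config(), config)


def validate_config(cfg: dict) -> None:
    net = cfg["network"]
    if not 0 <= net["r_threshold"] <= 1:
        raise ConfigError(f"r_threshold must lie in [0, 1], got {net['r_threshold']}")
    if not 0 < net["alpha"] <= 1:
        raise ConfigError(f"alpha must lie in (0, 1], got {net['alpha']}")
    if cfg["classes"]["low"] >= cfg["classes"]["high"]:
        raise ConfigError("class threshold 'low' must be < 'high'")
    if cfg["rarefaction"]["depth"] <= 0:
        raise ConfigError("rarefaction depth must be positive")
    if cfg["inputs"]["otu_table"] is None or cfg["inputs"]["metadata"] is None:
        raise ConfigError("config must name an otu_table and a metadata file")


def stage_seed(root_seed: int, label: str) -> int:
    """Stable per-stage seed derived from the root seed and a label."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return run

    return wrap


def run_pipeline(config, out_dir) -> Path:
    """Run every stage on the configured inputs and write all artifacts.

    Outputs under ``out_dir``: alpha.tsv, classes.tsv, dbrda.tsv,
    envfit.tsv, vpa.tsv, network.graphml, edges.tsv, topology.tsv (real
    vs random mean +/- sd with z and p), modules.tsv, roles.tsv,
    module_env.tsv, manifest.json and run.log.
    """
    cfg = load_config(config)
    validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root_logger = logging.getLogger("biofilmnet")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    seeds: dict[str, int] = {}

    def seed_for(label: str) -> int:
        seeds[label] = stage_seed(cfg["seed"], label)
        return seeds[label]

    try:
        # --- input + preprocess ------------------------------------------
        table = _stage("read")(io.read_otu_table)(
            cfg["inputs"]["otu_table"], cfg["inputs"]["table_format"]
        )
        meta = _stage("read")(io.read_metadata)(cfg["inputs"]["metadata"])
        missing = set(map(str, table.sample_ids)) - set(map(str, meta.index))
        if missing:
            raise PipelineError(
                f"stage 'read' failed: metadata lacks samples {sorted(missing)}"
            )
        tree = None
        if cfg["inputs"]["tree"]:
            tree = _stage("read")(io.read_tree)(cfg["inputs"]["tree"])

        table = _stage("filter")(preprocess.filter_otus)(
            table,
            cfg["filter"]["remove_singletons"],
            cfg["filter"]["exclude_lineage_keywords"],
        )
        table = _stage("rarefy")(preprocess.rarefy)(
            table, cfg["rarefaction"]["depth"], seed_for("rarefy")
        )
        rel = _stage("relative_abundance")(preprocess.relative_abundance)(table)
        meta = meta.loc[table.sample_ids]

        # --- diversity ----------------------------------------------------
        alpha = _stage("alpha")(diversity.alpha_diversity)(table, tree)
        alpha.to_csv(out_dir / "alpha.tsv", sep="\t", index_label="sample")
        classes = _stage("classify")(diversity.classify_abundance)(
            rel, cfg["classes"]["low"], cfg["classes"]["high"]
        )
        classes.rename("abundance_class").to_csv(
            out_dir / "classes.tsv", sep="\t", index_label="otu"
        )
        corr = _stage("alpha_env")(diversity.alpha_env_correlations)(
            alpha, meta, [v for v in ("BFC", "BFN", "BFP") if v in meta.columns]
        )
        corr.to_csv(out_dir / "alpha_env.tsv", sep="\t", index=False)

        # --- ordination ---------------------------------------------------
        dm = _stage("bray_curtis")(diversity.bray_curtis)(rel)
        variables = cfg["ordination"]["variables"]
        ordres = _stage("dbrda")(ordination.dbrda)(dm, meta, variables)
        coords = ordres.site_coordinates.copy()
        coords.to_csv(out_dir / "dbrda.tsv", sep="\t", index_label="sample")
        fit = _stage("envfit")(ordination.envfit)(
            ordres, meta, variables, cfg["ordination"]["n_permutations"],
            seed_for("envfit"),
        )
        fit.to_csv(out_dir / "envfit.tsv", sep="\t", index=False)
        vpa = _stage("vpa")(ordination.variation_partitioning)(
            dm, meta, cfg["ordination"]["vpa_groups"]
        )
        vpa.to_csv(out_dir / "vpa.tsv", sep="\t", index=False)

        # --- network ------------------------------------------------------
        netcfg = cfg["network"]
        keep = _stage("select_otus")(network.select_network_otus)(
            rel, netcfg["min_prevalence"], netcfg["min_mean_abundance"]
        )
        rho, p = _stage("spearman")(network.spearman_matrix)(rel[keep])
        iu = np.triu_indices(len(keep), k=1)
        padj_flat = network.bh_adjust(p.to_numpy()[iu])
        padj = np.ones_like(p.to_numpy())
        padj[iu] = padj_flat
        padj.T[iu] = padj_flat
        padj = pd.DataFrame(padj, index=p.index, columns=p.columns)
        net = _stage("build_network")(network.build_network)(
            rho, padj, netcfg["r_threshold"], netcfg["alpha"], classes
        )
        io.write_network(net, out_dir / "network.graphml", "graphml")
        io.write_network(net, out_dir / "edges.tsv", "edge_tsv")

        if net.number_of_nodes() == 0:
            logger.warning("empty network; topology/module stages skipped")
            partition = {}
        else:
            partition = _stage("modules")(network.detect_modules)(
                net, netcfg["algorithm"], seed_for("modules")
            )
            real_stats = _stage("topology")(network.topology)(net, partition)
            ensemble = _stage("er_ensemble")(network.er_random_ensemble)(
                net.number_of_nodes(),
                net.number_of_edges(),
                netcfg["n_random"],
                seed_for("er_ensemble"),
            )
            ens_stats = []
            mod_seed = seed_for("er_modules")
            for k, g in enumerate(ensemble):
                part_g = network.detect_modules(g, netcfg["algorithm"], mod_seed + k)
                ens_stats.append(network.topology(g, part_g))
            ztab = _stage("z_test")(network.z_test_topology)(real_stats, ens_stats)
            ztab.to_csv(out_dir / "topology.tsv", sep="\t", index=False)

            pd.Series(partition, name="module").to_csv(
                out_dir / "modules.tsv", sep="\t", index_label="node"
            )
            roles = _stage("zi_pi")(network.zi_pi)(net, partition)
            roles = network.classify_roles(
                roles, netcfg["zi_threshold"], netcfg["pi_threshold"]
            )
            roles.to_csv(out_dir / "roles.tsv", sep="\t", index_label="node")

            screen = _stage("module_env")(module_env.module_env_screen)(
                rel,
                partition,
                meta,
                cfg["module_env"]["variables"],
                cfg["module_env"]["control"],
                cfg["module_env"]["min_module_size"],
                cfg["module_env"]["n_permutations"],
                seed_for("module_env"),
            )
            screen.to_csv(out_dir / "module_env.tsv", sep="\t", index=False)

        manifest = {
            "biofilmnet_version": __version__,
            "networkx_version": nx.__version__,
            "numpy_version": np.__version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "root_seed": cfg["seed"],
            "stage_seeds": seeds,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return out_dir
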