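"""Pipeline orchestration: validated YAML configuration, stage ordering,
content-hash caching, and logging of every threshold used.

Stage order: qc -> prune -> structure -> consensus Q -> association (GWAS and
GEM per trait, with q-value FDR) -> plots. Each stage writes its outputs and
a manifest keyed by a hash of its inputs and parameters; re-running with
unchanged inputs reuses the cached outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import association as assoc
from . import io as bio
from . import qc as bqc
from . import structure as bstruct

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "inputs": {"markers": None, "expression": None, "phenotypes": None, "annotation": None},
    "qc": {"max_missing": 0.25, "max_states": 3, "min_maf": None},
    "prune": {"min_maf": 0.05, "min_distance_bp": 500},
    "structure": {
        "k_min": 1,
        "k_max": 6,
        "replicates": 10,
        "burnin": 10000,
        "mcmc": 10000,
        "seed": 0,
        "k_use": None,
    },
    "association": {
        "traits": None,
        "correction": "qmatrix",
        "n_pcs": 5,
        "min_maf": 0.05,
        "fdr": 0.05,
        "min_mean_rpkm": 0.5,
        "run_gem": True,
    },
    "plots": {"enabled": True, "format": "png"},
}

REQUIRED_KEYS = [("inputs", "markers"), ("inputs", "phenotypes")]


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline configuration (unknown keys rejected,
    missing required keys reported by name)."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in raw.items():
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ConfigError(f"unknown config key {section}.{key}")
            cfg[section][key] = val
    for section, key in REQUIRED_KEYS:
        if cfg[section][key] is None:
            raise ConfigError(f"missing required config key {section}.{key}")
    _check_ranges(cfg)
    return cfg


def _check_ranges(cfg: dict) -> None:
    qc = cfg["qc"]
    if not (0.0 <= float(qc["max_missing"]) <= 1.0):
        raise ConfigError("qc.max_missing must lie in [0, 1]")
    if int(qc["max_states"]) < 1:
        raise ConfigError("qc.max_states must be >= 1")
    st = cfg["structure"]
    if int(st["k_min"]) < 1 or int(st["k_max"]) < int(st["k_min"]):
        raise ConfigError("structure k range must satisfy 1 <= k_min <= k_max")
    if cfg["association"]["correction"] not in ("qmatrix", "pca", "none"):
        raise ConfigError("association.correction must be qmatrix, pca or none")


def _hash_stage(name: str, params: dict, input_paths: list[Path]) -> str:
    h = hashlib.sha256()
    h.update(name.encode())
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    for p in input_paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _stage_cached(stage_dir: Path, digest: str, outputs: list[str]) -> bool:
    manifest = stage_dir / "manifest.json"
    if not manifest.exists():
        return False
    try:
        recorded = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return False
    return recorded.get("digest") == digest and all((stage_dir / o).exists() for o in outputs)


def _record(stage_dir: Path, digest: str, params: dict) -> None:
    (stage_dir / "manifest.json").write_text(
        json.dumps({"digest": digest, "params": params}, sort_keys=True, default=str)
    )


def run_pipeline(config, out_dir) -> Path:
    """Execute the full pipeline; returns the results directory.

    Raises with the failing stage named; partial re-runs resume from cached
    stage outputs.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        markers_path = Path(cfg["inputs"]["markers"])
        pheno_path = Path(cfg["inputs"]["phenotypes"])
        ann = (
            bio.read_annotation(cfg["inputs"]["annotation"])
            if cfg["inputs"]["annotation"]
            else None
        )

        # ---- qc -----------------------------------------------------
        stage = "qc"
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        digest = _hash_stage("qc", cfg["qc"], [markers_path])
        if not _stage_cached(qc_dir, digest, ["markers.tsv"]):
            table = bio.read_marker_table(markers_path)
            log.info("qc thresholds: %s", cfg["qc"])
            filtered = bqc.filter_markers(
                table,
                max_missing=float(cfg["qc"]["max_missing"]),
                max_states=int(cfg["qc"]["max_states"]),
                min_maf=cfg["qc"]["min_maf"],
            )
            bio.write_marker_table(filtered, qc_dir / "markers.tsv")
            _record(qc_dir, digest, cfg["qc"])
        qc_markers = qc_dir / "markers.tsv"

        # ---- prune --------------------------------------------------
        stage = "prune"
        prune_dir = out / "prune"
        prune_dir.mkdir(exist_ok=True)
        digest = _hash_stage("prune", cfg["prune"], [qc_markers])
        if not _stage_cached(prune_dir, digest, ["markers.tsv"]):
            table = bio.read_marker_table(qc_markers)
            log.info("prune thresholds: %s", cfg["prune"])
            pruned = bqc.prune_for_structure(
                table,
                annotation=ann,
                min_maf=float(cfg["prune"]["min_maf"]),
                min_distance_bp=int(cfg["prune"]["min_distance_bp"]),
            )
            bio.write_marker_table(pruned, prune_dir / "markers.tsv")
            _record(prune_dir, digest, cfg["prune"])
        pruned_markers = prune_dir / "markers.tsv"

        # ---- structure + consensus Q -------------------------------
        stage = "structure"
        st = cfg["structure"]
        st_dir = out / "structure"
        st_dir.mkdir(exist_ok=True)
        digest = _hash_stage("structure", st, [pruned_markers])
        if not _stage_cached(st_dir, digest, ["evanno.tsv", "qmatrix.tsv"]):
            table = bio.read_marker_table(pruned_markers)
            log.info("structure settings: %s", st)
            ks = range(int(st["k_min"]), int(st["k_max"]) + 1)
            runs = bstruct.structure_replicates(
                table,
                ks,
                replicates=int(st["replicates"]),
                burnin=int(st["burnin"]),
                mcmc=int(st["mcmc"]),
                seed=int(st["seed"]),
            )
            if len(list(ks)) >= 3 and int(st["replicates"]) >= 2:
                evanno = bstruct.evanno_delta_k(runs)
            else:
                import pandas as pd

                evanno = pd.DataFrame(
                    {
                        "K": list(ks),
                        "mean_lnpd": [np.mean([r.lnpd for r in runs[k]]) for k in ks],
                    }
                ).set_index("K")
            evanno.to_csv(st_dir / "evanno.tsv", sep="\t", na_rep="NA")
            if st["k_use"] is not None:
                k_use = int(st["k_use"])
            elif "delta_k" in evanno.columns and evanno["delta_k"].notna().any():
                k_use = bstruct.best_k(evanno)
            else:
                k_use = int(st["k_max"])
            log.info("structure: consensus at K=%d", k_use)
            q = bstruct.consensus_q(runs[k_use])
            bio.write_qmatrix(q, st_dir / "qmatrix.tsv")
            _record(st_dir, digest, st)
        qmatrix_path = st_dir / "qmatrix.tsv"

        # ---- association -------------------------------------------
        stage = "association"
        ac = cfg["association"]
        as_dir = out / "association"
        as_dir.mkdir(exist_ok=True)
        geno = bio.read_marker_table(qc_markers)
        pheno = bio.read_phenotypes(pheno_path)
        pheno = bio.align_accessions(geno, pheno)
        if ac["correction"] == "qmatrix":
            correction = bio.align_accessions(geno, bio.read_qmatrix(qmatrix_path))
        elif ac["correction"] == "pca":
            correction = bstruct.pca_covariates(
                bio.read_marker_table(pruned_markers), n_pcs=int(ac["n_pcs"])
            )
        else:
            correction = None
        traits = ac["traits"] or pheno.traits
        expr = None
        if cfg["inputs"]["expression"] and ac["run_gem"]:
            expr = bio.align_accessions(geno, bio.read_expression(cfg["inputs"]["expression"]))
        for trait in traits:
            log.info("association scan: trait %r (correction=%s)", trait, ac["correction"])
            res = assoc.gwas_scan(
                pheno.trait(trait), geno, correction=correction, min_maf=float(ac["min_maf"])
            )
            safe = trait.replace(" ", "_").replace("/", "-")
            bio.write_results(res, as_dir / f"gwas_{safe}.tsv")
            hits, threshold = assoc.significant_hits(res, fdr=float(ac["fdr"]))
            bio.write_results(hits, as_dir / f"gwas_{safe}_hits.tsv")
            if cfg["plots"]["enabled"]:
                from .viz import render_manhattan, render_qq

                fmt = cfg["plots"]["format"]
                render_manhattan(res, threshold, as_dir / f"gwas_{safe}.{fmt}")
                render_qq(res["p_value"].to_numpy(), as_dir / f"gwas_{safe}_qq.{fmt}")
            if expr is not None:
                gres = assoc.gem_scan(
                    pheno.trait(trait), expr, min_mean_rpkm=float(ac["min_mean_rpkm"])
                )
                bio.write_results(gres, as_dir / f"gem_{safe}.tsv")
                ghits, gthr = assoc.significant_hits(gres, fdr=float(ac["fdr"]))
                bio.write_results(ghits, as_dir / f"gem_{safe}_hits.tsv")
                if cfg["plots"]["enabled"]:
                    render_manhattan(gres, gthr, as_dir / f"gem_{safe}.{cfg['plots']['format']}")
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise
    return out
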