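"""End-to-end orchestration with a single validated config and a manifest.

Stages run in dependency order (simulate -> call -> classify -> metagene /
conserve / evo / mutagenesis as enabled); every emitted table carries a
header comment with the config hash and seed, and the manifest records
output checksums so an unchanged re-run is a no-op unless forced.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caller import CallerConfig, call_sites, sites_to_frame
from .classify import classify_sites
from .conservation import conservation_summary, pair_sites
from .evo import StructureContext, build_design, fit_logistic, pairing_metaprofile
from .metagene import density_profile, derive_layout, gc_profile
from .models import SimulationConfig
from .mutagenesis import (
    AssignConfig,
    assign_reads,
    dedupe_barcodes,
    motif_series,
    variant_level_table,
)
from .synthetic import (
    make_species_pair,
    make_substrate_pool,
    make_transcriptome,
    plant_truth,
    simulate_amplicon_reads,
    simulate_replicates,
    LengthParams,
)
from . import io as m5cio

log = logging.getLogger("m5cdevmap")

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "outdir": str,
    "stages": {
        "simulate": bool, "call": bool, "classify": bool, "metagene": bool,
        "conserve": bool, "evo": bool, "mutagenesis": bool,
    },
    "simulate": {
        "n_genes": int, "n_sites": int, "type_mix": float,
        "level_low": float, "level_high": float,
        "coverage_mean": float, "conversion_rate": float,
        "bad_read_fraction": float, "read_len": int,
        "utr5_len": int, "cds_len": int, "utr3_len": int,
    },
    "caller": {
        "min_coverage": int, "min_level": float, "min_variant_reads": int,
        "min_base_qual": int, "c_cutoff": int, "min_signal_ratio": float,
        "p_threshold": float, "combined_p_threshold": float,
        "single_rep_min_variant": int,
        "resistant_gene_max_nonconversion": float, "min_gene_obs": int,
    },
    "classify": {"registration": str},
    "metagene": {"n_utr5": int},
    "conserve": {"sub_rate": float, "retention_logit": float},
    "evo": {"mode": str},
    "mutagenesis": {"reads_per_variant": int, "conversion_rate": float},
    "species": {"fold_temperature": float, "name": str},
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "outdir": "m5c_run",
    "stages": {
        "simulate": True, "call": True, "classify": True, "metagene": True,
        "conserve": True, "evo": False, "mutagenesis": False,
    },
    "simulate": {
        "n_genes": 60, "n_sites": 300, "type_mix": 0.237,
        "level_low": 0.2, "level_high": 0.8,
        "coverage_mean": 60.0, "conversion_rate": 0.995,
        "bad_read_fraction": 0.02, "read_len": 100,
        "utr5_len": 100, "cds_len": 500, "utr3_len": 400,
    },
    "caller": {},
    "classify": {"registration": "downstream"},
    "metagene": {"n_utr5": 10},
    "conserve": {"sub_rate": 0.02, "retention_logit": -1.386},
    "evo": {"mode": "TypeII"},
    "mutagenesis": {"reads_per_variant": 200, "conversion_rate": 0.999},
    "species": {"fold_temperature": 37.0, "name": "synthetic"},
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Schema-check a run config (unknown keys rejected) and fill defaults."""
    def check(node, schema, path):
        if not isinstance(node, dict):
            raise ConfigError(f"{path or 'config'}: expected a mapping")
        for key, value in node.items():
            if key not in schema:
                raise ConfigError(f"unknown config key {path + key!r}")
            spec = schema[key]
            if isinstance(spec, dict):
                check(value, spec, path + key + ".")
            elif spec is float:
                if not isinstance(value, (int, float)) or isinstance(value, bool):
                    raise ConfigError(f"{path + key}: expected a number")
            elif not isinstance(value, spec) or isinstance(value, bool) is not (spec is bool):
                raise ConfigError(f"{path + key}: expected {spec.__name__}")

    check(config, _SCHEMA, "")

    def merge(defaults, given):
        out = dict(defaults)
        for k, v in (given or {}).items():
            out[k] = merge(defaults.get(k, {}), v) if isinstance(v, dict) else v
        return out

    return merge(DEFAULT_CONFIG, config)


def config_hash(config: dict[str, Any]) -> str:
    """Content hash of the analysis config; the output location is not part
    of the analysis identity."""
    hashed = {k: v for k, v in config.items() if k != "outdir"}
    canonical = yaml.safe_dump(hashed, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, chash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# m5cdevmap {__version__} config={chash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict[str, Any], force: bool = False) -> dict[str, Any]:
    """Run enabled stages; returns the manifest (also written to outdir)."""
    cfg = validate_config(config)
    chash = config_hash(cfg)
    seed = cfg["seed"]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == chash and all(
            Path(e["path"]).exists() and _sha256(Path(e["path"])) == e["sha256"]
            for e in prev.get("outputs", {}).values()
        ):
            log.info("outputs up to date for config %s; skipping (use force)", chash)
            return prev

    outputs: dict[str, Path] = {}
    stages = cfg["stages"]
    t0 = time.time()

    def stage_done(name: str) -> None:
        log.info("stage %-12s done in %.1fs", name, time.time() - t0)

    rng_root = np.random.SeedSequence(seed)
    sub_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["transcriptome", "truth", "reads", "pair", "mutagenesis"],
            rng_root.spawn(5),
        )
    }

    sim = cfg["simulate"]
    transcriptome = truth = replicates = None
    if stages["simulate"]:
        transcriptome = make_transcriptome(
            sim["n_genes"],
            LengthParams(sim["utr5_len"], sim["cds_len"], sim["utr3_len"]),
            seed=sub_seeds["transcriptome"],
        )
        truth = plant_truth(
            transcriptome, sim["n_sites"], sim["type_mix"],
            (sim["level_low"], sim["level_high"]), seed=sub_seeds["truth"],
        )
        sim_cfg = SimulationConfig(
            n_genes=sim["n_genes"], coverage_mean=sim["coverage_mean"],
            conversion_rate=sim["conversion_rate"],
            bad_read_fraction=sim["bad_read_fraction"],
            read_len=sim["read_len"], seed=sub_seeds["reads"],
        )
        replicates = simulate_replicates(transcriptome, truth, sim_cfg)
        m5cio.write_fasta(transcriptome, str(outdir / "transcripts.fa"))
        m5cio.write_annotation(transcriptome, str(outdir / "annotation.tsv"))
        m5cio.write_truth(truth, str(outdir / "truth.tsv"))
        for i, rep in enumerate(replicates, start=1):
            rep.write_tsv(str(outdir / f"reads_rep{i}.tsv"))
        outputs.update(
            {
                "fasta": outdir / "transcripts.fa",
                "annotation": outdir / "annotation.tsv",
                "truth": outdir / "truth.tsv",
                "reads_rep1": outdir / "reads_rep1.tsv",
                "reads_rep2": outdir / "reads_rep2.tsv",
            }
        )
        stage_done("simulate")

    sites = None
    if stages["call"]:
        if replicates is None:
            raise ConfigError("call stage requires the simulate stage in this run mode")
        caller_cfg = CallerConfig(**cfg["caller"])
        sites, audit = call_sites(replicates, transcriptome, caller_cfg)
        if stages["classify"]:
            classify_sites(sites, transcriptome, cfg["classify"]["registration"])
            stage_done("classify")
        site_frame = sites_to_frame(sites)
        _write_table(site_frame, outdir / "sites.tsv", chash, seed)
        _write_table(audit, outdir / "filter_audit.tsv", chash, seed)
        rejected = audit[~audit.emitted]
        for name, count in rejected.first_fail.value_counts().items():
            log.info("filter %-14s rejected %d candidates", name, count)
        outputs["sites"] = outdir / "sites.tsv"
        outputs["filter_audit"] = outdir / "filter_audit.tsv"
        stage_done("call")

    if stages["metagene"]:
        if sites is None or transcriptome is None:
            raise ConfigError("metagene stage requires call + simulate stages")
        layout = derive_layout(transcriptome, cfg["metagene"]["n_utr5"])
        background = [
            (t.transcript_id, p)
            for t in transcriptome
            for p, b in enumerate(t.sequence)
            if b == "C"
        ]
        prof = density_profile(
            [(s.transcript_id, s.position) for s in sites],
            background, transcriptome, layout,
        )
        prof = prof.merge(gc_profile(transcriptome, layout), on="bin")
        _write_table(prof, outdir / "metagene_profile.tsv", chash, seed)
        outputs["metagene_profile"] = outdir / "metagene_profile.tsv"
        stage_done("metagene")

    pair = None
    if stages["conserve"] or stages["evo"]:
        if transcriptome is None or truth is None:
            raise ConfigError("conserve/evo stages require the simulate stage")
        conserve_cfg = cfg["conserve"]
        pair = make_species_pair(
            transcriptome, truth,
            sub_rate=conserve_cfg["sub_rate"],
            glm_coefs={"intercept": conserve_cfg["retention_logit"]},
            seed=sub_seeds["pair"],
        )

    if stages["conserve"]:
        site_map_a = {
            (s.transcript_id, s.position): (s.true_level, 50) for s in truth
        }
        site_map_b = {
            (r.transcript_id + ".sp2", r.position): (r.level_b, r.cov_b)
            for r in pair.sites
        }
        truth_keys = {(s.transcript_id, s.position) for s in truth}
        omap = pair.ortholog_map
        omap = omap[
            [
                (t, p) in truth_keys
                for t, p in zip(omap.tidA, omap.posA)
            ]
        ].reset_index(drop=True)
        calls = pair_sites(site_map_a, site_map_b, omap)
        types = {(s.transcript_id, s.position): s.planted_type for s in truth}
        summary = conservation_summary(calls, types)
        m5cio.write_ortholog_map(omap, str(outdir / "ortholog_map.tsv"))
        _write_table(summary, outdir / "conservation_summary.tsv", chash, seed)
        outputs["ortholog_map"] = outdir / "ortholog_map.tsv"
        outputs["conservation_summary"] = outdir / "conservation_summary.tsv"
        stage_done("conserve")

    if stages["evo"]:
        mode = cfg["evo"]["mode"]
        contexts = [StructureContext(r.context_b, r.struct_b) for r in pair.sites]
        profile = pairing_metaprofile(contexts, window=pair.window)
        _write_table(profile, outdir / "pairing_metaprofile.tsv", chash, seed)
        outputs["pairing_metaprofile"] = outdir / "pairing_metaprofile.tsv"
        try:
            X, y = build_design(pair.sites, mode)
            fit = fit_logistic(X, y)
            coef = pd.DataFrame(
                {"feature": fit.params.index, "estimate": fit.params.values,
                 "se": fit.bse.values, "z": fit.zvalues.values}
            )
            _write_table(coef, outdir / "glm_coefficients.tsv", chash, seed)
            outputs["glm_coefficients"] = outdir / "glm_coefficients.tsv"
        except ValueError as exc:
            log.warning("gain/loss GLM skipped: %s", exc)
        stage_done("evo")

    if stages["mutagenesis"]:
        mut = cfg["mutagenesis"]
        variants = make_substrate_pool(seed=sub_seeds["mutagenesis"])
        dna_reads, bs_reads = simulate_amplicon_reads(
            variants, mut["reads_per_variant"], mut["conversion_rate"],
            seed=sub_seeds["mutagenesis"],
        )
        assigned, _ = assign_reads(bs_reads, variants, AssignConfig())
        retained = dedupe_barcodes(dna_reads, assigned)
        levels = variant_level_table(retained, variants)
        by_g, by_tag = motif_series(levels, variants)
        _write_table(levels, outdir / "mutagenesis_levels.tsv", chash, seed)
        _write_table(by_g, outdir / "mutagenesis_by_gcount.tsv", chash, seed)
        outputs["mutagenesis_levels"] = outdir / "mutagenesis_levels.tsv"
        outputs["mutagenesis_by_gcount"] = outdir / "mutagenesis_by_gcount.tsv"
        stage_done("mutagenesis")

    manifest = {
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
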