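"""Pipeline driver: simulate -> abundance -> demography -> displacement -> metrics.

A single YAML config with per-stage sections drives the whole analysis and
every run writes a reproducibility manifest (config hash, seeds, package
version, input checksums, timestamps).  Stage outputs are pure functions of
(inputs, config, seed).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__, abundance, demography, displacement, metrics, simulate, tables

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

log = logging.getLogger("soilmerge")

DEFAULT_STAGES = ("simulate", "abundance", "demography", "displace", "metrics")

_KNOWN_TOP_KEYS = {"seed", "out", "stages", "inputs"} | set(DEFAULT_STAGES)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with Path(config).open("r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    cfg = dict(config)
    unknown = set(cfg) - _KNOWN_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    for stage in cfg.get("stages", DEFAULT_STAGES):
        if stage not in DEFAULT_STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid: {list(DEFAULT_STAGES)}")
    return cfg


def _load_inputs(paths: Mapping[str, str]) -> simulate.SyntheticExperiment:
    required = {"counts", "metadata"}
    missing = required - set(paths)
    if missing:
        raise ValueError(f"inputs section lacks {sorted(missing)}")
    counts = tables.read_count_table(paths["counts"])
    metadata = tables.read_metadata(paths["metadata"])
    taxonomy = (
        tables.read_taxonomy(paths["taxonomy"]) if "taxonomy" in paths else None
    )
    sizes = tables.read_sizes(paths["sizes"]) if "sizes" in paths else None
    members: frozenset[str] = frozenset()
    if "syncom_members" in paths:
        p = Path(paths["syncom_members"])
        if p.exists():
            members = frozenset(
                ln.strip() for ln in p.read_text(encoding="utf-8").splitlines() if ln.strip()
            )
        else:
            log.warning("exclusion file %s missing; proceeding with empty exclusion", p)
    return simulate.SyntheticExperiment(
        counts=counts,
        taxonomy=taxonomy,
        metadata=metadata,
        sizes=sizes,
        syncom_members=members,
        truth={},
    )


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Execute the configured stages in dependency order; returns the output dir."""
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    cfg = _load_config(config)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    outdir = Path(out if out is not None else cfg.get("out", "soilmerge_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", DEFAULT_STAGES))
    input_checksums: dict[str, str] = {}

    if "simulate" in stages:
        scn = dict(cfg.get("simulate", {}).get("scenario", {}))
        scn.setdefault("seed", seed)
        scenario = simulate.ScenarioConfig.from_dict(scn)
        exp = simulate.generate_coalescence_dataset(scenario)
        simulate.write_experiment(exp, outdir / "data")
        scenario.to_yaml(outdir / "data" / "scenario.yaml")
        log.info("simulate: %d samples, %d taxa", *exp.counts.shape)
    else:
        inputs = cfg.get("inputs", {})
        exp = _load_inputs(inputs)
        input_checksums = {k: _sha256(Path(v)) for k, v in inputs.items() if Path(v).exists()}
        log.info("loaded inputs: %d samples, %d taxa", *exp.counts.shape)

    rel = tables.relative_abundance(exp.counts)

    if "abundance" in stages:
        acfg = cfg.get("abundance", {})
        total = acfg.get("total", "fc")
        absolute = abundance.absolute_abundance(rel, exp.sizes, total=total)
        absolute.to_csv(outdir / "absolute.tsv", sep="\t", lineterminator="\n")
        if exp.syncom_members:
            syn_size = abundance.transplant_summed_size(
                exp.counts, exp.sizes, exp.syncom_members, total=acfg.get("syncom_total", "cfu")
            )
            syn_size.to_frame().to_csv(outdir / "syncom_size.tsv", sep="\t", lineterminator="\n")
        else:
            log.warning("no transplant members known; skipping syncom_size.tsv")

    if "demography" in stages:
        dcfg = cfg.get("demography", {})
        com_a = dcfg.get("community_a", "SC")
        com_b = dcfg.get("community_b", "LC")
        intervals = [tuple(iv) for iv in dcfg.get("intervals", demography.DEFAULT_INTERVALS)]
        genus_counts = tables.aggregate_to_rank(exp.counts, exp.taxonomy, "genus")
        genus_rel = tables.relative_abundance(genus_counts)
        genus_abs = abundance.absolute_abundance(genus_rel, exp.sizes, total="fc")
        presence_a = demography.presence_set(genus_counts, exp.metadata, com_a)
        presence_b = demography.presence_set(genus_counts, exp.metadata, com_b)
        # genera never detected in either community carry no demographic signal
        detected = [g for g in genus_abs.columns if g in presence_a | presence_b]
        genus_abs = genus_abs[detected]
        deltas_a = demography.interval_deltas(genus_abs, exp.metadata, com_a, intervals)
        deltas_b = demography.interval_deltas(genus_abs, exp.metadata, com_b, intervals)
        groups = demography.classify_taxa_groups(deltas_a, deltas_b, presence_a, presence_b)
        contrib = pd.concat(
            [
                demography.contribution_summary(deltas_a, groups).assign(community=com_a),
                demography.contribution_summary(deltas_b, groups).assign(community=com_b),
            ],
            ignore_index=True,
        )
        pd.concat([deltas_a, deltas_b], ignore_index=True).to_csv(
            outdir / "deltas.tsv", sep="\t", index=False, lineterminator="\n"
        )
        groups.to_csv(outdir / "groups.tsv", sep="\t", index=False, lineterminator="\n")
        contrib.to_csv(outdir / "contributions.tsv", sep="\t", index=False, lineterminator="\n")
        pie = {
            f"{row.community}|{row.day_a:g}-{row.day_b:g}|{row.group}": {
                "growth": row.growth_sum,
                "decline": row.decline_sum,
                "growth_share": None if pd.isna(row.growth_share) else row.growth_share,
                "decline_share": None if pd.isna(row.decline_share) else row.decline_share,
            }
            for row in contrib.itertuples()
        }
        (outdir / "contributions.json").write_text(json.dumps(pie, indent=1), encoding="utf-8")

    if "displace" in stages:
        pcfg = cfg.get("displace", {})
        merged = pcfg.get("merged", "SC+SynCom")
        control = pcfg.get("control", "SC")
        dconf = displacement.DisplacementConfig(
            k_sigma=float(pcfg.get("k_sigma", 3.0)),
            depth=int(pcfg.get("depth", 100_000)),
            seed=int(pcfg.get("seed", seed)),
            threshold_basis=pcfg.get("threshold_basis", "residual_sd"),
        )
        if not exp.syncom_members:
            log.warning("no transplant exclusion set; displacement runs without exclusion")
        comparisons = [
            displacement.Comparison("merged_vs_control", control, merged, "between"),
            displacement.Comparison("within_control", control, control, "within"),
            displacement.Comparison("within_merged", merged, merged, "within"),
        ]
        result = displacement.run_displacement(
            exp.counts, exp.metadata, comparisons, exclude=exp.syncom_members, config=dconf
        )
        result.points.to_csv(outdir / "pairs.tsv", sep="\t", index=False, lineterminator="\n")
        result.outliers.to_csv(outdir / "outliers.tsv", sep="\t", index=False, lineterminator="\n")
        result.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False, lineterminator="\n")
        (outdir / "baseline.json").write_text(
            json.dumps(result.baseline_params(), indent=1), encoding="utf-8"
        )
        if exp.taxonomy is not None and len(result.outliers):
            profile = displacement.outlier_phylum_profile(
                result.outliers, exp.taxonomy, rel, exp.metadata, merged
            )
            profile.to_csv(outdir / "phylum_profile.tsv", sep="\t", index=False, lineterminator="\n")

    if "metrics" in stages:
        mcfg = cfg.get("metrics", {})
        depth = mcfg.get("depth")
        base_counts = exp.counts
        if depth:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                base_counts = tables.rarefy(exp.counts, int(depth), seed=seed)
        mrel = tables.relative_abundance(base_counts)
        metrics.shannon_series(mrel).to_frame().to_csv(
            outdir / "diversity.tsv", sep="\t", lineterminator="\n"
        )
        metrics.bray_curtis_matrix(mrel).to_csv(
            outdir / "distances.tsv", sep="\t", lineterminator="\n"
        )

    manifest = {
        "soilmerge_version": __version__,
        "seed": seed,
        "stages": stages,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": input_checksums,
        "started_utc": started,
        "finished_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return outdir
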