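"""Stage orchestration: load inputs once, run analyses, write reports.

Reports are plot-ready TSV/JSON.  Every report carries a convention block
(coordinate base, sign conventions, tie rules) so downstream figures are
self-describing, and re-running with an identical config and seed
reproduces byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from . import branchpoints as bp
from . import loops, overhang_stats, simulate, snp
from .duplex import BEYOND_CLOSING_PAIR, SUSPECT_THRESHOLD, overhangs_for_dataset
from .ingest import (
    AuxTables,
    DatasetPartition,
    HairpinRecord,
    LoadResult,
    load_aux_tables,
    load_hairpins,
    partition_datasets,
)

logger = logging.getLogger(__name__)

#: the inferred conventions, echoed into every report
CONVENTIONS = {
    "coordinates": "1-based, inclusive, hairpin-relative",
    "overhang_sign": "positive = 3' overhang, negative = 5' overhang",
    "end_distance": "outside = |u-t|-1 (>=0), inside = -|u-t|; ties return outside",
    "unf_positions": "1-based from mature 5' end; negative = upstream flank; no position 0",
    "bp_offset": "0 = last intron nucleotide; counted upstream of the 3' splice site",
    "bp_mapping": "hairpin position = length - offset (3'-coterminal) unless explicit",
    "d_loop": "first nucleotide after the terminal loop = 1",
}


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run; echoed into reports."""

    fasta: str | None = None
    structures: str | None = None
    matures: str | None = None
    snps: str | None = None
    branchpoints: str | None = None
    rates: str | None = None
    mirtron_ids: str | None = None
    robust_ids: str | None = None
    disease_ids: str | None = None
    out_dir: str = "mirfoot-out"
    flank_width: int = 200
    unf_flank_width: int = 10
    overhang_variant: str = BEYOND_CLOSING_PAIR
    suspect_threshold: int = SUSPECT_THRESHOLD
    snp_flag_filter: str = "all"
    robust_only: bool = False
    common_only: bool = False
    seed: int = 0
    # simulate-only knobs
    n: int = 1000

    def validate(self) -> None:
        if self.flank_width < 0 or self.unf_flank_width < 0:
            raise ValueError("flank widths must be >= 0")
        if self.snp_flag_filter not in ("all", "common_only"):
            raise ValueError(f"unknown snp_flag_filter {self.snp_flag_filter!r}")
        if self.suspect_threshold < 0:
            raise ValueError("suspect_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _header_lines(config: RunConfig) -> list[str]:
    lines = ["# mirfoot report"]
    lines += [f"# convention {k}: {v}" for k, v in CONVENTIONS.items()]
    lines += [f"# config {k}: {v}" for k, v in sorted(config.as_dict().items())]
    return lines


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(config)) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_json(payload: dict, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"conventions": CONVENTIONS, "config": config.as_dict(), **payload}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


@dataclass
class Stage:
    """Loaded inputs shared by the analysis subcommands."""

    config: RunConfig
    load: LoadResult
    partition: DatasetPartition
    aux: AuxTables

    @property
    def records(self) -> list[HairpinRecord]:
        return self.partition.all_animal


def load_stage(config: RunConfig) -> Stage:
    """Load and validate all configured inputs; apply dataset restrictions."""
    config.validate()
    if not (config.fasta and config.structures):
        raise ValueError("missing required input: --fasta and --structures")
    result = load_hairpins(config.fasta, config.structures, config.matures)
    logger.info("loaded %d hairpins, excluded %d", len(result.records), len(result.excluded))

    aux = AuxTables()
    if config.snps:
        aux.snps = load_aux_tables("snp", config.snps)
    if config.branchpoints:
        aux.branchpoints = load_aux_tables("branchpoint", config.branchpoints)
    if config.rates:
        aux.substitution_rates = load_aux_tables("rates", config.rates)
    if config.mirtron_ids:
        aux.mirtron_ids = load_aux_tables("idlist", config.mirtron_ids)
    if config.robust_ids:
        aux.robust_ids = load_aux_tables("idlist", config.robust_ids)
    if config.disease_ids:
        aux.disease_ids = load_aux_tables("idlist", config.disease_ids)

    records = result.records
    if config.robust_only:
        records = [r for r in records if r.id in aux.robust_ids]
        logger.info("robust-only restriction: %d records kept", len(records))
    partition = partition_datasets(records, aux.mirtron_ids)
    orphan = aux.orphan_ids({r.id for r in records})
    if orphan:
        logger.warning("%d aux rows reference unknown hairpins", len(orphan))
    return Stage(config, result, partition, aux)


# ---------------------------------------------------------------------------
# subcommand implementations
# ---------------------------------------------------------------------------

def run_overhangs(stage: Stage) -> pd.DataFrame:
    cfg = stage.config
    pairs, failures = overhangs_for_dataset(
        stage.records, cfg.overhang_variant, cfg.suspect_threshold
    )
    logger.info("duplexes formed: %d; failures: %d", len(pairs), len(failures))
    df = pd.DataFrame(
        [(p.hairpin_id, p.basal, p.apical, p.variant, int(p.suspect)) for p in pairs],
        columns=["hairpin_id", "basal_overhang", "apical_overhang", "variant",
                 "suspect_flag"],
    )
    _write_tsv(df, Path(cfg.out_dir) / "overhangs.tsv", cfg)
    table = overhang_stats.joint_overhang_table(pairs)
    _write_tsv(table.to_frame(), Path(cfg.out_dir) / "overhangs_joint.tsv", cfg)
    return df


def run_fit_independence(stage: Stage) -> dict:
    cfg = stage.config
    pairs, _ = overhangs_for_dataset(
        stage.records, cfg.overhang_variant, cfg.suspect_threshold
    )
    if len(pairs) < 3:
        raise ValueError("too few duplexes to fit")
    full_corr = overhang_stats.overhang_correlation(pairs)
    near, fraction = overhang_stats.restrict_near_canonical(pairs)
    payload: dict = {
        "n_duplexes": len(pairs),
        "full_table_rho": full_corr.rho,
        "full_table_p": full_corr.p_value,
        "near_canonical_fraction": fraction,
    }
    if len(near) >= 3:
        table = overhang_stats.joint_overhang_table(near)
        fit = overhang_stats.fit_independence_model(table)
        near_corr = overhang_stats.overhang_correlation(near)
        payload.update(
            {
                "near_canonical_rho": near_corr.rho,
                "near_canonical_p": near_corr.p_value,
                "p_short": fit.p_short,
                "p_long": fit.p_long,
                "depletion_canonical_over_short": fit.depletion_factors()[0],
                "depletion_canonical_over_long": fit.depletion_factors()[1],
                "expected": fit.expected.tolist(),
                "observed": overhang_stats.class_counts(table).tolist(),
                "obs_over_exp": fit.obs_over_exp.tolist(),
                "gof_stat": fit.gof_stat,
                "gof_df": fit.gof_df,
                "gof_p": fit.gof_p,
            }
        )
    _write_json(payload, Path(cfg.out_dir) / "independence_fit.json", cfg)
    return payload


def run_distances(stage: Stage) -> pd.DataFrame:
    cfg = stage.config
    dists = loops.end_distances_for_dataset(stage.records)
    df = pd.DataFrame(
        [(d.hairpin_id, d.end_kind,
          "" if d.d is None else d.d, d.reason or "", int(d.tie)) for d in dists],
        columns=["hairpin_id", "end_kind", "distance", "undefined_reason", "tie"],
    )
    _write_tsv(df, Path(cfg.out_dir) / "end_distances.tsv", cfg)
    return df


def run_unf(stage: Stage) -> dict:
    cfg = stage.config
    out: dict = {}
    for arm in ("five_prime", "three_prime"):
        try:
            profile = loops.unf_profile(stage.records, arm, cfg.unf_flank_width)
        except ValueError:
            continue
        _write_tsv(profile.to_frame(), Path(cfg.out_dir) / f"unf_{arm}.tsv", cfg)
        out[arm] = profile
        if arm == "five_prime" and stage.aux.substitution_rates:
            corr, points = loops.correlate_unf_substitution(
                profile, stage.aux.substitution_rates, seed=cfg.seed
            )
            _write_json(
                {
                    "rho": corr.rho, "p_value": corr.p_value, "n": corr.n,
                    "method": corr.method,
                    "points": points.to_dict(orient="records"),
                },
                Path(cfg.out_dir) / "unf_substitution_correlation.json", cfg,
            )
    if not out:
        raise ValueError("no matures annotated; UNF undefined")
    return out


def _snp_filter(cfg: RunConfig) -> str:
    return "common_only" if cfg.common_only else cfg.snp_flag_filter


def run_snp_density(stage: Stage) -> pd.DataFrame:
    cfg = stage.config
    partitions = [
        snp.partition_regions(r, cfg.flank_width)
        for r in stage.records if r.matures
    ]
    densities = snp.snp_density(stage.aux.snps, partitions, _snp_filter(cfg))
    df = pd.DataFrame(
        [(d.region, d.n_snp, d.length, round(d.density, 4), d.flag_filter)
         for d in densities],
        columns=["region", "n_snp", "length", "density_per_kb", "filter"],
    )
    _write_tsv(df, Path(cfg.out_dir) / "snp_density.tsv", cfg)
    return df


def run_disease_occurrence(stage: Stage) -> dict:
    cfg = stage.config
    hs_mm = stage.partition.hs_mm_mirtrons + stage.partition.hs_mm_non_mirtrons
    groups = snp.snp_occurrence_by_disease(
        stage.aux.snps, hs_mm, stage.aux.disease_ids, _snp_filter(cfg)
    )
    payload = {
        "groups": [
            {"disease": g.disease, "mirtron": g.mirtron,
             "mean_snps_per_premirna": g.mean, "n_hairpins": g.n_hairpins}
            for g in groups
        ]
    }
    _write_json(payload, Path(cfg.out_dir) / "disease_occurrence.json", cfg)
    return payload


def run_branchpoints(stage: Stage) -> dict:
    cfg = stage.config
    if not stage.aux.branchpoints:
        raise ValueError("missing required input: --branchpoints")
    summary = bp.bp_offset_stats(stage.aux.branchpoints)
    located, skipped = bp.locate_branchpoints(stage.aux.branchpoints, stage.records)
    df = pd.DataFrame(
        [(l.hairpin_id, l.bp_position, l.compartment,
          "" if l.d_loop is None else l.d_loop,
          "" if l.d_dicer is None else l.d_dicer, l.d_3end) for l in located],
        columns=["hairpin_id", "bp_position", "compartment", "d_loop", "d_dicer",
                 "d_3end"],
    )
    _write_tsv(df, Path(cfg.out_dir) / "branchpoint_locations.tsv", cfg)

    def stats_dict(s):
        return None if s is None else {
            "n": s.n, "fraction_in_window": s.fraction_in_window,
            "window": list(s.window),
        }

    payload = {
        "overall": stats_dict(summary.overall),
        "mirtron_linked": stats_dict(summary.mirtron_linked),
        "plain_intron": stats_dict(summary.plain_intron),
        "compartment_frequencies": bp.compartment_frequencies(located),
        "n_located": len(located),
        "n_skipped": len(skipped),
    }
    _write_json(payload, Path(cfg.out_dir) / "branchpoint_summary.json", cfg)
    return payload


def run_simulate(config: RunConfig) -> dict:
    """Emit a synthetic cohort into out_dir in the exact ingest dialects."""
    config.validate()
    cohort = simulate.CohortSpec(n=config.n, seed=config.seed)
    paths = simulate.emit_cohort(cohort, config.out_dir)
    return {k: str(v) for k, v in paths.items()}


SUBCOMMANDS = (
    "overhangs", "distances", "unf", "snp-density", "disease-occurrence",
    "branchpoints", "fit-independence", "simulate", "all",
)


def run(subcommand: str, config: RunConfig):
    """Dispatch one pipeline subcommand; see :data:`SUBCOMMANDS`."""
    if subcommand not in SUBCOMMANDS:
        raise ValueError(f"unknown subcommand {subcommand!r}")
    if subcommand == "simulate":
        return run_simulate(config)
    stage = load_stage(config)
    dispatch = {
        "overhangs": run_overhangs,
        "distances": run_distances,
        "unf": run_unf,
        "snp-density": run_snp_density,
        "disease-occurrence": run_disease_occurrence,
        "branchpoints": run_branchpoints,
        "fit-independence": run_fit_independence,
    }
    if subcommand == "all":
        results = {}
        for name, fn in dispatch.items():
            try:
                results[name] = fn(stage)
            except ValueError as exc:
                logger.warning("stage %s skipped: %s", name, exc)
        return results
    return dispatch[subcommand](stage)
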