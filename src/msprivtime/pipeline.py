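"""End-to-end analysis and simulation-validation workflows.

``run_full_analysis`` chains load -> diversity -> F-statistics -> private
alleles -> divergence dating into a single report (JSON + TSV), a pure
function of its inputs, configuration and seed.  ``run_validation`` runs
replicate simulations and summarises estimator calibration: recovery of the
true split time under both P definitions, the invasive mtDNA haplotype
count distribution, and the direction of the inbreeding coefficient.

Undefined statistics (e.g. H_O in a unit with no typed females) are
reported as explicit nulls, never coerced to zero.  Significance flags use
per-test p-values; an optional Benjamini-Hochberg correction can be applied
uniformly (off by default).
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field as dataclass_field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diversity_stats, allele_accounting, divergence_dating, synthetic_data
from .genotype_io import (
    DEFAULT_GROUP_MAP,
    INVASIVE,
    NATIVE,
    GenotypeIOError,
    HaplotypeAlignment,
    MicrosatDataset,
    read_fasta_alignment,
    read_genepop,
    read_genotype_table,
    read_metadata,
    write_report,
)

logger = logging.getLogger("msprivtime")
if not logger.handlers:  # library default: stderr, overridable by callers
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass
class AnalysisConfig:
    """Configuration for one full analysis run."""

    genotypes: str  # GenePop or TSV genotype table path
    metadata: str | None = None  # sidecar TSV (required for GenePop input)
    mtdna: str | None = None  # aligned FASTA path
    group_map: dict[str, str] = dataclass_field(
        default_factory=lambda: dict(DEFAULT_GROUP_MAP)
    )
    focal_pair: tuple[str, str] = (NATIVE, INVASIVE)
    analysis_loci: list[str] | None = None  # None = all polymorphic loci
    dating_basis: str = "amplified"
    dating_focal_group: str = INVASIVE
    mu_values: list[float] = dataclass_field(default_factory=lambda: [1e-3, 1e-5])
    generations_per_year: float = 6.0
    rarefaction_g: int | None = None  # None = FSTAT convention (min copies)
    n_perm: int = 999
    bh_correction: bool = False
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.mu_values:
            raise PipelineError("config: mu list must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "focal_pair" in raw:
            raw["focal_pair"] = tuple(raw["focal_pair"])
        return cls(**raw)


def _load_inputs(
    config: AnalysisConfig,
) -> tuple[MicrosatDataset, HaplotypeAlignment | None]:
    path = Path(config.genotypes)
    if not path.exists():
        raise GenotypeIOError(f"genotype file not found: {path}")
    if path.suffix.lower() in (".tsv", ".txt"):
        dataset = read_genotype_table(path, config.group_map)
    else:
        if config.metadata is None:
            raise GenotypeIOError("GenePop input requires a metadata sidecar path")
        dataset = read_genepop(path, read_metadata(config.metadata))
    alignment = read_fasta_alignment(config.mtdna) if config.mtdna else None
    return dataset, alignment


def _benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adjusted[i] = running
    return adjusted.tolist()


def _units_of(dataset: MicrosatDataset) -> list[str]:
    """Populations followed by groups (the two reporting levels)."""
    units = dataset.populations()
    for g in dataset.groups():
        if g not in units:
            units.append(g)
    return units


def _mtdna_section(
    dataset: MicrosatDataset, alignment: HaplotypeAlignment
) -> pd.DataFrame:
    rows = []
    by_id = {s.sample_id: s for s in dataset.samples}
    for unit in _units_of(dataset):
        members = [
            sid
            for sid in alignment.ids
            if sid in by_id
            and (by_id[sid].population == unit or by_id[sid].group == unit)
        ]
        if not members:
            continue
        sub = alignment.subset(members)
        summary = diversity_stats.collapse_haplotypes(sub)
        rows.append(
            {
                "unit": unit,
                "n_individuals": summary.n_individuals,
                "n_haplotypes": summary.n_haplotypes,
                "n_segregating_sites": summary.n_segregating_sites,
                "haplotype_diversity": summary.haplotype_diversity,
                "nucleotide_diversity": summary.nucleotide_diversity,
            }
        )
    return pd.DataFrame(rows)


def _diversity_section(
    dataset: MicrosatDataset, config: AnalysisConfig
) -> pd.DataFrame:
    rows = []
    units = _units_of(dataset)
    for unit in units:
        per_locus: dict[str, dict[str, float | int | None]] = {}
        for locus in dataset.loci:
            cell: dict[str, float | int | None] = {}
            copies = dataset.gene_copies(
                diversity_stats._unit_samples(dataset, unit), locus
            )
            if not copies:
                continue
            cell["n_alleles"] = len(set(copies))
            try:
                cell["gene_diversity"] = diversity_stats.gene_diversity(
                    dataset, unit, locus
                )
            except diversity_stats.UndefinedStatistic:
                cell["gene_diversity"] = None
            g = config.rarefaction_g
            if g is None:
                g = diversity_stats.default_rarefaction_size(dataset, units, locus)
            try:
                cell["allelic_richness"] = diversity_stats.allelic_richness(
                    dataset, unit, locus, g
                )
            except diversity_stats.StatsError:
                cell["allelic_richness"] = None
            try:
                h_o, h_e = diversity_stats.heterozygosity(dataset, unit, locus)
                cell["H_O"], cell["H_E"] = h_o, h_e
            except diversity_stats.UndefinedStatistic:
                cell["H_O"] = cell["H_E"] = None
            per_locus[locus] = cell
        if not per_locus:
            continue
        row: dict[str, object] = {"unit": unit, "n_loci": len(per_locus)}
        for stat in ("n_alleles", "gene_diversity", "allelic_richness", "H_O", "H_E"):
            vals = [c[stat] for c in per_locus.values() if c.get(stat) is not None]
            row[f"{stat}_mean"] = float(np.mean(vals)) if vals else None
            row[f"{stat}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        rows.append(row)
    return pd.DataFrame(rows)


def _fstats_section(
    dataset: MicrosatDataset, config: AnalysisConfig, rng: np.random.Generator
) -> dict[str, object]:
    out: dict[str, object] = {"per_population": [], "multi_population": None}
    for pop in dataset.populations():
        females = dataset.select(population=pop, sex="female")
        if len(females) < 2:
            out["per_population"].append(
                {"population": pop, "f": None, "hwe_p_values": None}
            )
            continue
        try:
            res = diversity_stats.weir_cockerham(dataset, populations=[pop])
            f_overall = res.f_overall
        except diversity_stats.UndefinedStatistic:
            f_overall = None
        hwe: dict[str, float] = {}
        for locus in dataset.loci:
            try:
                hwe[locus] = diversity_stats.hwe_deficit_test(
                    dataset, pop, locus, n_perm=config.n_perm, seed=rng
                )
            except diversity_stats.UndefinedStatistic:
                continue
        if config.bh_correction and hwe:
            loci_order = list(hwe)
            adj = _benjamini_hochberg([hwe[l] for l in loci_order])
            hwe = dict(zip(loci_order, adj))
        out["per_population"].append(
            {"population": pop, "f": f_overall, "hwe_p_values": hwe or None}
        )
    pops = dataset.populations()
    if len(pops) >= 2:
        try:
            multi = diversity_stats.weir_cockerham(dataset, populations=pops)
            out["multi_population"] = {
                "populations": pops,
                "f": multi.f_overall,
                "theta": multi.theta_overall,
                "theta_per_locus": multi.theta_per_locus,
            }
        except diversity_stats.UndefinedStatistic:
            out["multi_population"] = None
    return out


def _private_allele_section(
    dataset: MicrosatDataset, config: AnalysisConfig
) -> tuple[dict[str, object], allele_accounting.PrivateAlleleSummary]:
    inventory = allele_accounting.allele_inventory(dataset)
    analysis_loci = config.analysis_loci
    if analysis_loci is None:
        # default analysis panel: amplified loci polymorphic across the pair
        analysis_loci = [
            locus
            for locus in inventory.amplified_loci
            if len(
                inventory.alleles(locus, config.focal_pair[0])
                | inventory.alleles(locus, config.focal_pair[1])
            )
            > 1
        ]
    summary = allele_accounting.classify_alleles(
        inventory, config.focal_pair, analysis_loci or None
    )
    section: dict[str, object] = {"focal_pair": list(config.focal_pair)}
    for group in config.focal_pair:
        prop, k, n = allele_accounting.locus_private_proportion(
            summary, group, basis="amplified"
        )
        section[f"locus_private_{group}"] = {"proportion": prop, "k": k, "n": n}
    if summary.analysis_loci:
        shared, priv_a, priv_b = allele_accounting.mean_allele_class_proportions(summary)
        section["mean_allele_class_proportions"] = {
            "n_analysis_loci": len(summary.analysis_loci),
            "shared": shared,
            f"private_{config.focal_pair[0]}": priv_a,
            f"private_{config.focal_pair[1]}": priv_b,
        }
    per_locus = pd.DataFrame(
        [
            {
                "locus": locus,
                "shared": sorted(cls.shared),
                f"private_{config.focal_pair[0]}": sorted(
                    cls.private[config.focal_pair[0]]
                ),
                f"private_{config.focal_pair[1]}": sorted(
                    cls.private[config.focal_pair[1]]
                ),
            }
            for locus, cls in summary.per_locus.items()
        ]
    )
    section["per_locus"] = per_locus.to_dict(orient="records")
    return section, summary


def _dating_section(
    summary: allele_accounting.PrivateAlleleSummary, config: AnalysisConfig
) -> dict[str, object]:
    _, k, n = allele_accounting.locus_private_proportion(
        summary, config.dating_focal_group, basis=config.dating_basis
    )
    estimates = divergence_dating.date_divergence(
        k,
        n,
        mu_values=tuple(config.mu_values),
        generations_per_year=config.generations_per_year,
    )
    t_values = [e.t_generations for e in estimates]
    return {
        "focal_group": config.dating_focal_group,
        "basis": config.dating_basis,
        "k": k,
        "n": n,
        "P": k / n,
        "estimates": [
            {
                "mu": e.mu,
                "t_generations": e.t_generations,
                "t_display": e.t_display,
                "t_years": e.t_years,
                "ci_P": list(e.ci_P) if e.ci_P else None,
                "ci_t_generations": list(e.ci_t) if e.ci_t else None,
            }
            for e in estimates
        ],
        "envelope_generations": [min(t_values), max(t_values)],
        "envelope_years": [
            min(t_values) / config.generations_per_year,
            max(t_values) / config.generations_per_year,
        ],
    }


def run_full_analysis(
    config: AnalysisConfig,
    dataset: MicrosatDataset | None = None,
    alignment: HaplotypeAlignment | None = None,
) -> dict[str, object]:
    """Run every analysis stage and return (and optionally write) the report.

    In-memory *dataset*/*alignment* override the configured file paths
    (the CLI always goes through files; tests and the simulator feed
    objects directly).  Any stage failure aborts with a stage-named
    :class:`PipelineError`, and partial outputs are removed.
    """
    rng = np.random.default_rng(config.seed)
    logger.info("analysis start: seed=%d mu=%s", config.seed, config.mu_values)
    stage = "load"
    out_dir = Path(config.output_dir) if config.output_dir else None
    try:
        if dataset is None:
            dataset, file_alignment = _load_inputs(config)
            alignment = alignment or file_alignment
        report: dict[str, object] = {
            "config": {
                **{
                    k: v
                    for k, v in asdict(config).items()
                    if k not in ("group_map",)
                },
                "focal_pair": list(config.focal_pair),
            },
            "n_samples": len(dataset.samples),
            "n_loci": len(dataset.loci),
        }
        if alignment is not None:
            stage = "mtdna"
            report["mtdna"] = _mtdna_section(dataset, alignment).to_dict(
                orient="records"
            )
        stage = "diversity"
        diversity = _diversity_section(dataset, config)
        report["diversity"] = diversity.to_dict(orient="records")
        stage = "fstats"
        report["fstats"] = _fstats_section(dataset, config, rng)
        stage = "private_alleles"
        private_section, summary = _private_allele_section(dataset, config)
        report["private_alleles"] = private_section
        stage = "dating"
        report["dating"] = _dating_section(summary, config)
        if out_dir is not None:
            stage = "write"
            out_dir.mkdir(parents=True, exist_ok=True)
            write_report({"report": report}, out_dir / "report")
        logger.info("analysis done: %d samples, %d loci",
                    len(dataset.samples), len(dataset.loci))
        return report
    except PipelineError:
        raise
    except Exception as exc:
        if stage == "write" and out_dir is not None and out_dir.exists():
            shutil.rmtree(out_dir, ignore_errors=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc


def run_validation(
    sim_config: synthetic_data.SimConfig,
    n_replicates: int,
    mu: float | None = None,
) -> dict[str, object]:
    """Estimator-calibration report over replicate simulations.

    Per replicate: t-hat under both P definitions (idealised any-mutation P
    and observable private-allele P), the invasive mtDNA haplotype count,
    and native/invasive mean gene diversity.  Replicate failures are
    logged and flagged, not fatal.
    """
    if n_replicates < 1:
        raise PipelineError("n_replicates must be >= 1")
    mu = mu if mu is not None else sim_config.mu_ms
    rows: list[dict[str, object]] = []
    failures: list[str] = []
    for rep_cfg in synthetic_data.replicate_configs(sim_config, n_replicates):
        try:
            result = synthetic_data.simulate(rep_cfg)
            p_any, p_obs = synthetic_data.expected_vs_realized_private(result)
            t_any = (
                divergence_dating.estimate_divergence_generations(p_any, mu)
                if p_any < 1
                else float("inf")
            )
            t_obs = (
                divergence_dating.estimate_divergence_generations(p_obs, mu)
                if p_obs < 1
                else float("inf")
            )
            inv_haps = diversity_stats.collapse_haplotypes(
                result.invasive_mt
            ).n_haplotypes
            gd = {}
            for group, ds in ((NATIVE, result.native), (INVASIVE, result.invasive)):
                vals = []
                for locus in ds.loci:
                    try:
                        vals.append(
                            diversity_stats.gene_diversity(ds, group, locus)
                        )
                    except diversity_stats.UndefinedStatistic:
                        continue
                gd[group] = float(np.mean(vals)) if vals else None
            fis = None
            try:
                fis = diversity_stats.weir_cockerham(
                    result.combined, populations=[NATIVE]
                ).f_overall
            except diversity_stats.UndefinedStatistic:
                pass
            rows.append(
                {
                    "seed": rep_cfg.seed,
                    "P_any": p_any,
                    "P_observable": p_obs,
                    "t_hat_any": t_any,
                    "t_hat_observable": t_obs,
                    "invasive_n_haplotypes": inv_haps,
                    "native_gene_diversity": gd[NATIVE],
                    "invasive_gene_diversity": gd[INVASIVE],
                    "native_f_is": fis,
                    "reseed_events": result.truth.reseed_events,
                }
            )
        except synthetic_data.SimulationError as exc:
            logger.warning("replicate failed: %s", exc)
            failures.append(str(exc))
    if not rows:
        raise PipelineError("validation: every replicate failed")
    t_any = [r["t_hat_any"] for r in rows]
    t_obs = [r["t_hat_observable"] for r in rows]
    return {
        "true_t_split": sim_config.t_split,
        "mu": mu,
        "n_replicates_requested": n_replicates,
        "n_replicates_completed": len(rows),
        "incomplete": bool(failures),
        "failures": failures,
        "replicates": rows,
        "median_t_hat_any": float(np.median(t_any)),
        "median_t_hat_observable": float(np.median(t_obs)),
        "n_observable_below_true": int(
            sum(1 for t in t_obs if t < sim_config.t_split)
        ),
        "invasive_haplotype_counts": {
            int(k): int(v)
            for k, v in zip(
                *np.unique(
                    [r["invasive_n_haplotypes"] for r in rows], return_counts=True
                )
            )
        },
        "median_native_f_is": (
            float(np.median(fis_vals)) if (
                fis_vals := [
                    r["native_f_is"] for r in rows if r["native_f_is"] is not None
                ]
            ) else None
        ),
    }
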