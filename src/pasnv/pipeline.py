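"""End-to-end orchestration: simulate -> classify -> statistics -> report.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so any stage can be re-run from its predecessors' files.  All
randomness flows from the single config seed, and a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, classify as C, enrichment as E, expression as X
from . import io, selection as S, simulate as sim
from .scoring import ExternalCommandScorer, Scorer, SurrogateScorer, WINDOW_FLANK

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


@dataclass
class RunConfig:
    """Resolved run configuration; thresholds default to the published values."""

    out_dir: str = "pasnv_run"
    seed: int = 7
    scorer: str = "surrogate"           # "surrogate" or "external-command"
    scorer_command: list[str] = field(default_factory=list)
    lor_up: float = 1.0
    lor_down: float = -1.0
    window_flank: int = WINDOW_FLANK
    conservation_half_width: int = 7
    annotated_half_width: int = 50
    bootstrap_iterations: int = 1000
    min_mean_fpkm: float = 1.0
    both_mode: str = "exclude"
    simulate: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> sim.SimConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        if "pas_offset_range" in params:
            params["pas_offset_range"] = tuple(params["pas_offset_range"])
        return sim.SimConfig(**params)

    def make_scorer(self) -> Scorer:
        if self.scorer == "surrogate":
            return SurrogateScorer(flank=self.window_flank)
        if self.scorer == "external-command":
            if not self.scorer_command:
                raise PipelineError("config: external-command scorer needs a command")
            return ExternalCommandScorer(self.scorer_command, flank=self.window_flank)
        raise PipelineError(f"config: unknown scorer {self.scorer!r}")


def _echo_config(config: RunConfig, out: Path) -> None:
    resolved = dataclasses.asdict(config)
    resolved["version"] = __version__
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True, default_flow_style=False)


def simulate_stage(config: RunConfig) -> None:
    """Generate the synthetic study and write every input file."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(config, out)
    sc = config.sim_config()
    scorer = config.make_scorer()
    genome, sites, roles = sim.make_genome(sc)
    normal = sim.make_normal_cohort(sc, genome, sites, scorer)
    cancer = sim.make_cancer_cohort(sc, genome, sites, roles, scorer)

    cancer_records, _ = C.build_records(cancer, sites, genome, scorer,
                                        flank=config.window_flank)
    down_events = cancer_records.loc[
        cancer_records["category"] == "DOWN", ["gene_id", "sample_id"]
    ].drop_duplicates()
    samples = sim.tumour_samples(sc)
    expr = sim.make_expression(sc, roles, samples, down_events)
    damaging, burden, conservation, cnv_calls = sim.make_aux_tables(
        sc, roles, samples, down_events, sites
    )

    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(sc.as_dict(), fh, sort_keys=True)
    io.write_genome(genome, out / "genome.fa")
    io.write_sites(sites, out / "sites.tsv")
    io.write_table(roles, out / "roles.tsv")
    io.write_vcf(normal, out / "normal.vcf", "normal", genome)
    io.write_vcf(cancer, out / "cancer.vcf", "cancer", genome)
    io.write_matrix(expr.fpkm, out / "fpkm.tsv")
    io.write_matrix(expr.cn, out / "cn.tsv")
    io.write_matrix(damaging, out / "damaging.tsv")
    io.write_table(burden, out / "burden.tsv")
    io.write_table(conservation, out / "conservation.tsv")
    io.write_table(cnv_calls, out / "cnv_calls.tsv")
    logger.info("simulate: %d genes, %d normal and %d cancer variants",
                sc.n_genes, len(normal), len(cancer))


def _load_inputs(out: Path, names: list[str], stage: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise PipelineError(f"stage {stage}: missing input file {name}")


def classify_stage(config: RunConfig) -> None:
    """Score, classify and deduplicate both cohorts; write the master table."""
    out = Path(config.out_dir)
    _load_inputs(out, ["genome.fa", "sites.tsv", "normal.vcf", "cancer.vcf"],
                 "classify")
    genome = io.read_genome(out / "genome.fa")
    sites = io.read_sites(out / "sites.tsv")
    scorer = config.make_scorer()
    frames, qc = [], {}
    for cohort in ("normal", "cancer"):
        variants = io.read_vcf(out / f"{cohort}.vcf", cohort)
        records, cohort_qc = C.build_records(
            variants, sites, genome, scorer, flank=config.window_flank
        )
        qc[cohort] = cohort_qc
        frames.append(records)
        logger.info("classify[%s]: %d variants -> %d scored pairs",
                    cohort, len(variants), len(records))
    records = pd.concat(
        [f.dropna(axis=1, how="all") for f in frames], ignore_index=True
    ).reindex(columns=C.RECORD_COLUMNS)
    resolved = C.dedupe_and_resolve(records)
    io.write_table(records, out / "records_raw.tsv")
    io.write_table(resolved, out / "records.tsv")
    io.write_table(C.positional_profile(resolved, flank=config.window_flank),
                   out / "positional_profile.tsv")
    io.write_json(qc, out / "qc.json")


def select_stage(config: RunConfig) -> None:
    """Selection diagnostics and cancer-vs-normal comparisons."""
    out = Path(config.out_dir)
    _load_inputs(out, ["records.tsv", "conservation.tsv"], "select")
    records = io.read_table(out / "records.tsv")
    normal = records[records["cohort"] == "normal"]
    cancer = records[records["cohort"] == "cancer"]
    n_down = normal[normal["category"] == "DOWN"]
    n_bg = normal[normal["category"] == "BG"]
    c_down = cancer[cancer["category"] == "DOWN"]
    track = io.read_conservation(out / "conservation.tsv")
    report = {
        "singleton_enrichment": S.singleton_enrichment(n_down["ac"], n_bg["ac"]),
        "af_comparison": S.af_comparison(n_down["af"], n_bg["af"]),
        "cohort_down_enrichment": S.cohort_down_enrichment(cancer, normal),
        "disrupted_signal_strength": S.disrupted_signal_strength(
            c_down["wt"], n_down["wt"]
        ),
        "lor_variance": {
            "cancer": S.lor_variance(cancer["lor"]),
            "normal": S.lor_variance(normal["lor"]),
        },
        "conservation": S.conservation_comparison(
            track, c_down, n_down, half_width=config.conservation_half_width
        ),
    }
    io.write_json(report, out / "selection.json")


def enrich_stage(config: RunConfig) -> None:
    """Census-role enrichment and bootstrap excess ratios."""
    out = Path(config.out_dir)
    _load_inputs(out, ["records.tsv", "roles.tsv", "burden.tsv"], "enrich")
    records = io.read_table(out / "records.tsv")
    roles = io.read_table(out / "roles.tsv")
    burden = io.read_table(out / "burden.tsv")
    cancer = records[records["cohort"] == "cancer"]
    down_genes = set(cancer.loc[cancer["category"] == "DOWN", "gene_id"])
    bg_genes = set(cancer.loc[cancer["category"] == "BG", "gene_id"])
    report = {
        "census": {
            role: E.census_enrichment(
                down_genes, bg_genes, roles, target_role=role,
                both_mode=config.both_mode,
            )
            for role in ("TSG", "oncogene")
        },
        "burden": E.burden_report(
            burden, roles, iterations=config.bootstrap_iterations,
            seed=config.seed, both_mode=config.both_mode,
        ),
    }
    io.write_json(report, out / "enrichment.json")


def express_stage(config: RunConfig) -> None:
    """Paired CNV-normalized expression differences for eligible TSGs."""
    out = Path(config.out_dir)
    _load_inputs(out, ["records_raw.tsv", "roles.tsv", "fpkm.tsv", "cn.tsv",
                       "damaging.tsv"], "express")
    records = io.read_table(out / "records_raw.tsv")
    roles = io.read_table(out / "roles.tsv")
    expr = X.ExpressionSet(io.read_matrix(out / "fpkm.tsv"),
                           io.read_matrix(out / "cn.tsv"))
    damaging = io.read_matrix(out / "damaging.tsv")
    cancer = records[records["cohort"] == "cancer"]
    down_events = cancer.loc[cancer["category"] == "DOWN",
                             ["gene_id", "sample_id"]].drop_duplicates()
    all_events = cancer[["gene_id", "sample_id"]].drop_duplicates()
    elig = X.select_eligible(down_events, all_events, damaging, roles, expr,
                             min_mean_fpkm=config.min_mean_fpkm)
    result = X.delta_expression(expr, elig)
    io.write_table(result.pop("pairs"), out / "delta_pairs.tsv")
    io.write_json(result, out / "expression.json")


def cooccur_stage(config: RunConfig) -> None:
    """Damaging-mutation co-occurrence and CNV direction analyses."""
    out = Path(config.out_dir)
    _load_inputs(out, ["records_raw.tsv", "roles.tsv", "damaging.tsv",
                       "cnv_calls.tsv"], "cooccur")
    records = io.read_table(out / "records_raw.tsv")
    roles = io.read_table(out / "roles.tsv")
    damaging = io.read_matrix(out / "damaging.tsv")
    cnv_calls = io.read_table(out / "cnv_calls.tsv")
    cancer = records[records["cohort"] == "cancer"]
    events = cancer[["gene_id", "sample_id", "category"]].drop_duplicates()
    down_genes = set(events.loc[events["category"] == "DOWN", "gene_id"])
    report = {
        "cooccurrence": X.cooccurrence_rate(events, damaging, roles),
        "damaging_frequency": X.damaging_frequency_compare(
            roles, down_genes, damaging
        ),
        "cnv_direction": X.cnv_direction(events, cnv_calls),
    }
    io.write_json(report, out / "cooccurrence.json")


def report_stage(config: RunConfig) -> dict:
    """Consolidate stage outputs into report.json and a text summary."""
    out = Path(config.out_dir)
    _load_inputs(out, ["selection.json", "enrichment.json", "expression.json",
                       "cooccurrence.json", "qc.json"], "report")
    report = {
        "version": __version__,
        "seed": config.seed,
        "qc": io.read_json(out / "qc.json"),
        "selection": io.read_json(out / "selection.json"),
        "enrichment": io.read_json(out / "enrichment.json"),
        "expression": io.read_json(out / "expression.json"),
        "cooccurrence": io.read_json(out / "cooccurrence.json"),
    }
    io.write_json(report, out / "report.json")

    sel = report["selection"]
    expr = report["expression"]
    lines = [
        f"pasnv {__version__} report (seed {config.seed})",
        "",
        "Population cohort (purifying selection):",
        f"  singleton fraction DOWN vs BG: "
        f"{_fmt(sel['singleton_enrichment']['down_singleton_fraction'])} vs "
        f"{_fmt(sel['singleton_enrichment']['bg_singleton_fraction'])} "
        f"(p={_fmt(sel['singleton_enrichment']['p_value'])})",
        f"  allele-frequency rank-sum p: {_fmt(sel['af_comparison']['p_value'])}",
        "",
        "Cancer vs normal:",
        f"  DOWN fraction: {_fmt(sel['cohort_down_enrichment']['cancer_down_fraction'])}"
        f" vs {_fmt(sel['cohort_down_enrichment']['normal_down_fraction'])} "
        f"(p={_fmt(sel['cohort_down_enrichment']['p_value'])})",
        f"  LOR variance: cancer {_fmt(sel['lor_variance']['cancer'])}, "
        f"normal {_fmt(sel['lor_variance']['normal'])}",
        "",
        "Gene-role enrichment (DOWN vs BG genes):",
        f"  TSG: OR={_fmt(report['enrichment']['census']['TSG']['odds_ratio'])} "
        f"(p={_fmt(report['enrichment']['census']['TSG']['p_value'])})",
        f"  oncogene: OR={_fmt(report['enrichment']['census']['oncogene']['odds_ratio'])} "
        f"(p={_fmt(report['enrichment']['census']['oncogene']['p_value'])})",
        "",
        "Expression (eligible tumour suppressors):",
        f"  pooled median dLog2(nFPKM): {_fmt(expr['pooled_median'])} "
        f"({_fmt(expr['pooled_fold'])}-fold), one-tailed p={_fmt(expr['p_value'])} "
        f"over {expr['n_pairs']} pairs in {expr['n_genes']} genes",
        "",
    ]
    (out / "summary.txt").write_text("\n".join(lines))
    return report


def _fmt(x) -> str:
    if x is None:
        return "NA"
    return f"{x:.4g}"


STAGES = {
    "simulate": simulate_stage,
    "classify": classify_stage,
    "select": select_stage,
    "enrich": enrich_stage,
    "express": express_stage,
    "cooccur": cooccur_stage,
}


def run_all(config: RunConfig, with_simulation: bool = True) -> dict:
    """Run every stage in order and return the consolidated report."""
    order = ["simulate"] if with_simulation else []
    order += ["classify", "select", "enrich", "express", "cooccur"]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(config, out)
    for name in order:
        try:
            STAGES[name](config)
        except PipelineError:
            raise
        except Exception as exc:  # attach the stage name for diagnosis
            raise PipelineError(f"stage {name} failed: {exc}") from exc
    return report_stage(config)
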