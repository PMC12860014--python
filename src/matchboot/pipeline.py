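"""Configuration-driven orchestration: generate/load -> impute -> match ->
analyze -> report, with named sub-seeds and plain CSV/JSON stage artifacts.

Every stage writes its artifact before the next stage starts, so any stage
can be audited or re-run in isolation; an identical config + master seed
yields byte-identical endpoint JSON.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    CohortTable,
    ValidationError,
    default_schema,
    load_cohort,
    ps_covariates,
    summarize_cohort,
    with_ps_set,
    write_cohort,
)
from .endpoints import (
    cif_from_cohort,
    cif_tidy,
    endpoint_panel,
    filter_complete_case,
    filter_micro_confirmed,
    filter_severe,
)
from .mi_boot import BootConfig, MiBootResult, run_mi_boot
from .mice_impute import ImputationConfig, ImputedCohorts, impute_chained, save_imputed
from .propensity_match import (
    average_and_logit,
    balance_table,
    compute_caliper,
    fit_propensity,
    match_caliper,
)
from .synthetic_cohort import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

# fixed order of named sub-seed streams derived from the master seed
_SEED_STREAMS = ("generation", "imputation", "boot_main", "boot_severe",
                 "boot_micro", "boot_complete_case")


@dataclass
class RunConfig:
    outdir: str = "matchboot_run"
    input_csv: str | None = None
    simulate: dict | None = None  # SimulationConfig overrides; used when no input_csv
    m: int = 50
    iterations: int = 5
    pmm_donors: int = 5
    B: int = 1000
    min_valid_fraction: float = 0.5
    caliper_multiplier: float = 0.05
    ps_covariate_names: list[str] | None = None  # None => registry default flags
    analyses: dict = field(
        default_factory=lambda: {
            "main": True, "severe": False, "micro": False,
            "complete_case": False, "cif": True,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.caliper_multiplier <= 0:
            raise ValidationError("caliper multiplier must be > 0")
        if self.input_csv is not None and self.simulate is not None:
            raise ValidationError("exactly one input source: input_csv OR simulate")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def fast(self) -> "RunConfig":
        """Reduced profile for tests/smoke runs."""
        cfg = RunConfig(**{**asdict(self), "m": 5, "B": 50})
        return cfg


def _sub_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_SEED_STREAMS))
    return {
        name: int(child.generate_state(1)[0])
        for name, child in zip(_SEED_STREAMS, children)
    }


def _write_json(obj, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _analysis_block(
    datasets: list[CohortTable],
    boot: BootConfig,
    covs,
    multiplier: float,
    outdir: str,
    name: str,
) -> dict:
    """Reference match + balance on dataset 1, MI-boot CIs, artifacts."""
    ref = datasets[0]
    ref.require_two_arms()
    fits = [fit_propensity(ds, covs, label=f"{name}:dataset{i+1}")
            for i, ds in enumerate(datasets)]
    same_patients = all(
        len(f.scores.index) == len(fits[0].scores.index)
        and (f.scores.index == fits[0].scores.index).all()
        for f in fits[1:]
    )
    if same_patients:
        scores = average_and_logit(fits)
    else:
        # subgroup membership varies across imputed datasets (filter inputs
        # were themselves imputed); the reference match then uses dataset 1
        scores = average_and_logit(fits[:1])
    width = compute_caliper(scores, multiplier)
    match = match_caliper(scores, ref.df["arm"], width)
    bal = balance_table(ref, match, covs)
    bal.to_csv(os.path.join(outdir, f"balance_{name}.csv"), index=False)
    pd.DataFrame(match.pairs, columns=["treated_id", "control_id"]).to_csv(
        os.path.join(outdir, f"pairs_{name}.csv"), index=False
    )
    scores.rename("logit_ps").to_frame().assign(id=scores.index).reindex(
        columns=["id", "logit_ps"]
    ).to_csv(os.path.join(outdir, f"scores_{name}.csv"), index=False)

    reference_panel = (
        endpoint_panel(ref, match).as_dict() if match.n_pairs else None
    )
    boot_result = run_mi_boot(datasets, boot, covs, multiplier)
    pooled_rows = []
    for key, dist in boot_result.distributions.items():
        for v in dist.estimates:
            pooled_rows.append({"endpoint": key, "estimate": v})
    pd.DataFrame(pooled_rows).to_csv(
        os.path.join(outdir, f"pooled_{name}.csv"), index=False
    )
    block = {
        "name": name,
        "caliper_width": width,
        "caliper_multiplier": multiplier,
        "n_pairs_reference": match.n_pairs,
        "n_unmatched_treated": len(match.unmatched_treated),
        "reference_panel": reference_panel,
        "endpoints": boot_result.summary,
        "n_replicates": boot_result.n_replicates,
        "n_invalid_replicates": boot_result.n_invalid_replicates,
        "balance_smd_lt_0.1_before": int(bal["balanced_before"].sum()),
        "balance_smd_lt_0.1_after": int(bal["balanced_after"].sum()),
    }
    _write_json(block, os.path.join(outdir, f"endpoints_{name}.json"))
    return block


def run_pipeline(config: RunConfig) -> dict:
    """Execute every requested analysis; returns the report dict (also
    written to ``<outdir>/report.json``)."""
    t0 = time.time()
    os.makedirs(config.outdir, exist_ok=True)
    seeds = _sub_seeds(config.seed)
    schema = default_schema()
    if config.ps_covariate_names is not None:
        schema = with_ps_set(schema, config.ps_covariate_names)
    covs = ps_covariates(schema)

    # stage 1: input cohort
    if config.input_csv is not None:
        cohort = load_cohort(config.input_csv, schema)
    else:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", seeds["generation"])
        sim = SimulationConfig(**sim_kwargs)
        cohort, truth = generate_cohort(sim)
        cohort = CohortTable(spec=schema, df=cohort.df)
        truth.to_csv(os.path.join(config.outdir, "truth.csv"), index=False)
    write_cohort(cohort, os.path.join(config.outdir, "cohort.csv"))
    cohort.require_two_arms()
    summarize_cohort(cohort).to_csv(
        os.path.join(config.outdir, "cohort_summary.csv"), index=False
    )
    logger.info("stage cohort: n=%d (%.1fs)", cohort.n, time.time() - t0)

    # stage 2: imputation
    imp_config = ImputationConfig(
        m=config.m, iterations=config.iterations,
        pmm_donors=config.pmm_donors, seed=seeds["imputation"],
    )
    imputed = impute_chained(cohort, imp_config)
    save_imputed(imputed, os.path.join(config.outdir, "imputed"))
    logger.info("stage imputation: m=%d (%.1fs)", imputed.m, time.time() - t0)

    report: dict = {
        "provenance": {
            "version": __version__,
            "master_seed": config.seed,
            "sub_seeds": seeds,
            "config": {
                k: v for k, v in asdict(config).items() if k != "analyses"
            },
            "analyses": dict(config.analyses),
        },
        "analyses": {},
    }

    def boot_for(stream: str) -> BootConfig:
        return BootConfig(
            B=config.B, seed=seeds[stream],
            min_valid_fraction=config.min_valid_fraction,
        )

    if config.analyses.get("main", True):
        report["analyses"]["main"] = _analysis_block(
            imputed.datasets, boot_for("boot_main"), covs,
            config.caliper_multiplier, config.outdir, "main",
        )
        logger.info("stage main analysis done (%.1fs)", time.time() - t0)

    if config.analyses.get("cif", True):
        ref = imputed.datasets[0]
        pairs_path = os.path.join(config.outdir, "pairs_main.csv")
        if os.path.exists(pairs_path):
            pairs = pd.read_csv(pairs_path, dtype=str)
            ids = pairs["treated_id"].tolist() + pairs["control_id"].tolist()
        else:
            ids = None
        curves = cif_from_cohort(ref, ids)
        cif_tidy(curves).to_csv(os.path.join(config.outdir, "cif.csv"), index=False)
        report["analyses"]["cif"] = {"written": "cif.csv"}

    def _subgroup_block(name: str, subsets: list[CohortTable], stream: str) -> dict:
        if any(ds.n == 0 for ds in subsets):
            return {"empty_subgroup": True}
        try:
            return _analysis_block(
                subsets, boot_for(stream), covs,
                config.caliper_multiplier, config.outdir, name,
            )
        except ValidationError as exc:
            # degenerate subgroup (e.g. too few treated for stable bootstrap
            # replicates); surface the abort in the report, keep the run alive
            logger.warning("analysis %s aborted: %s", name, exc)
            return {"aborted": str(exc)}

    if config.analyses.get("severe", False):
        report["analyses"]["severe"] = _subgroup_block(
            "severe", [filter_severe(ds) for ds in imputed.datasets], "boot_severe"
        )

    if config.analyses.get("micro", False):
        report["analyses"]["micro"] = _subgroup_block(
            "micro", [filter_micro_confirmed(ds) for ds in imputed.datasets],
            "boot_micro",
        )

    if config.analyses.get("complete_case", False):
        report["analyses"]["complete_case"] = _subgroup_block(
            "complete_case", [filter_complete_case(cohort)], "boot_complete_case"
        )

    _write_json(report, os.path.join(config.outdir, "report.json"))
    logger.info("pipeline complete (%.1fs)", time.time() - t0)
    return report


def build_report(outdir: str) -> str:
    """Regenerate a human-readable report from on-disk stage artifacts.
    Idempotent; errors name any missing artifact."""
    report_path = os.path.join(outdir, "report.json")
    if not os.path.exists(report_path):
        raise ValidationError(f"missing artifact: {report_path}")
    with open(report_path, "r", encoding="utf-8") as fh:
        report = json.load(fh)

    lines = [f"matchboot report (version {report['provenance']['version']})",
             f"master seed: {report['provenance']['master_seed']}", ""]
    for name, block in report.get("analyses", {}).items():
        if "endpoints" not in block:
            lines.append(f"[{name}] {block}")
            continue
        balance_path = os.path.join(outdir, f"balance_{name}.csv")
        if not os.path.exists(balance_path):
            raise ValidationError(f"missing artifact: {balance_path}")
        bal = pd.read_csv(balance_path)
        lines.append(f"[{name}] caliper width {block['caliper_width']:.5f} "
                     f"({block['n_pairs_reference']} reference pairs)")
        lines.append(f"  covariates with SMD<0.1: "
                     f"{block['balance_smd_lt_0.1_before']} before, "
                     f"{block['balance_smd_lt_0.1_after']} after "
                     f"(of {len(bal)})")
        for key, cell in sorted(block["endpoints"].items()):
            if cell["point"] is None:
                lines.append(f"  {key:24s} unavailable")
            else:
                lines.append(
                    f"  {key:24s} {cell['point']:8.2f} "
                    f"({cell['lower']:.2f} to {cell['upper']:.2f})"
                )
        lines.append("")
    text = "\n".join(lines)
    with open(os.path.join(outdir, "report.txt"), "w", encoding="utf-8") as fh:
        fh.write(text + "\n")
    return text
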