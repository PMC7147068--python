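"""End-to-end pipeline orchestration.

The analysis sequence: restrict to multimorbid patients -> stratify by age
-> stratified 80/20 train/test split -> per stratum, scan K and fit the
latent class model on the training split -> profile and label clusters ->
refit on the test split at fixed K and match clusters (stability) ->
outcome GLMs against the lowest-impact reference cluster.  Every stage
seed derives deterministically from the master seed by a fixed offset, so
a re-run with the same configuration is byte-identical and stages can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mio
from .cohort import (
    DEFAULT_AGE_STRATA,
    CohortTable,
    filter_multimorbid,
    is_multimorbid,
    split_train_test,
    stratify_by_age,
    summarize_demographics,
)
from .glm import choose_reference_cluster, fit_outcome_models
from .profiling import (
    build_profiles,
    cluster_outcome_summary,
    label_table,
    profiles_to_frame,
    report_markdown,
)
from .selection import relative_entropy, select_k
from .validation import replicate_on_test

log = logging.getLogger("mmclust")

# fixed stage-seed offsets from the master seed
_SEED_SPLIT = 1
_SEED_FIT = 1000  # + stratum index
_SEED_TEST = 2000  # + stratum index
_MOD = 2**31


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    cohort_path: str | None = None
    outdir: str = "mmclust_out"
    train_fraction: float = 0.8
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_restarts: int = 10
    max_iter: int = 1000
    tol: float = 1e-8
    entropy_floor: float = 0.8
    bootstrap_B: int = 0
    glm_family: str = "negative_binomial"
    imd_coding: str = "ordinal"
    reference: str = "lowest_impact"  # or "non_multimorbid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise PipelineError("train_fraction must be in (0, 1)")
        if min(self.k_range) < 1:
            raise PipelineError("k_range minimum must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class StratumResult:
    label: str
    selection: object
    profiles: list
    match: object
    outcome_summary: object
    outcome_models: dict = field(default_factory=dict)
    reference_cluster: int | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    strata: dict[str, StratumResult]
    report_path: Path


def run_pipeline(config: PipelineConfig, cohort: CohortTable | None = None) -> PipelineResult:
    """Run the full analysis; emits CSV/JSON/Markdown artefacts under
    ``config.outdir`` and returns the in-memory results."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        if config.cohort_path is None:
            raise PipelineError("no cohort given: set cohort_path or pass a CohortTable")
        cohort = mio.read_cohort(config.cohort_path)

    log.info("pipeline start: %d records, seed=%d", cohort.n, config.seed)
    summarize_demographics(cohort, "age_stratum").to_csv(out / "descriptives_all.csv", index=False)

    mm_mask = is_multimorbid(cohort)
    if not mm_mask.any():
        raise PipelineError("filter stage: cohort contains no multimorbid patients")
    mm = filter_multimorbid(cohort)
    non_mm = cohort.subset((~mm_mask).to_numpy())
    log.info("multimorbid: %d of %d", mm.n, cohort.n)

    train, test = split_train_test(mm, config.train_fraction, seed=(config.seed + _SEED_SPLIT) % _MOD)
    train_by = stratify_by_age(train)
    test_by = stratify_by_age(test)
    non_mm_by = stratify_by_age(non_mm)

    results: dict[str, StratumResult] = {}
    profiles_by, outcomes_by = {}, {}
    for si, stratum in enumerate(DEFAULT_AGE_STRATA):
        lab = stratum.label
        tr, te = train_by[lab], test_by[lab]
        if tr.n == 0:
            log.warning("stratum %s empty; skipped", lab)
            continue
        sdir = out / f"stratum_{lab.replace('+', 'plus')}"
        sdir.mkdir(exist_ok=True)
        y_tr = tr.condition_matrix()
        ks = [k for k in config.k_range if k < y_tr.shape[0]]
        try:
            sel = select_k(
                y_tr, ks,
                entropy_floor=config.entropy_floor,
                bootstrap_B=config.bootstrap_B,
                seed=(config.seed + _SEED_FIT + si) % _MOD,
                n_restarts=config.n_restarts,
                max_iter=config.max_iter,
                tol=config.tol,
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"model-selection stage failed in stratum {lab}: {e}") from e
        sel.table.to_csv(sdir / "selection.csv", index=False)
        fit = sel.chosen_fit
        mio.save_fit(fit, sdir / "model.json", condition_registry=tr.condition_registry,
                     extra={"stratum": lab, "selection_rule": sel.selection_rule,
                            "entropy": relative_entropy(fit)})
        log.info("stratum %s: chose K=%d (%s)", lab, sel.chosen_K, sel.selection_rule)

        profiles = build_profiles(fit.assignment, tr, stratum_label=lab)
        profiles_to_frame(profiles, tr.condition_registry).to_csv(sdir / "profiles.csv", index=False)
        label_table(profiles).to_csv(sdir / "labels.csv", index=False)

        match = None
        if te.n > sel.chosen_K:
            _, match = replicate_on_test(
                fit, y_tr, te.condition_matrix(),
                seed=(config.seed + _SEED_TEST + si) % _MOD,
                n_restarts=config.n_restarts, max_iter=config.max_iter, tol=config.tol,
            )
            mio.save_json(match.to_dict(), sdir / "match.json")
        else:
            log.warning("stratum %s: test split too small for validation", lab)

        osum = cluster_outcome_summary(fit.assignment, tr, non_multimorbid=non_mm_by.get(lab))
        osum.to_csv(sdir / "outcome_summary.csv", index=False)

        models = {}
        ref = None
        if sel.chosen_K >= 2:
            try:
                ref = choose_reference_cluster(osum)
                models = fit_outcome_models(
                    tr, fit.assignment, ref,
                    family=config.glm_family, imd_coding=config.imd_coding,
                )
                for name, m in models.items():
                    m.table.to_csv(sdir / f"glm_{name}.csv", index=False)
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"outcome-model stage failed in stratum {lab}: {e}") from e

        results[lab] = StratumResult(
            label=lab, selection=sel, profiles=profiles, match=match,
            outcome_summary=osum, outcome_models=models, reference_cluster=ref,
        )
        profiles_by[lab] = profiles
        outcomes_by[lab] = osum

    report = report_markdown(profiles_by, outcomes_by)
    report_path = out / "report.md"
    report_path.write_text(report)
    config.to_yaml(out / "config_used.yaml")
    log.info("pipeline done: outputs in %s", out)
    return PipelineResult(config=config, outdir=out, strata=results, report_path=report_path)
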