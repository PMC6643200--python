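"""End-to-end orchestration: simulate/load -> exclude -> fit -> summarize.

A single :class:`RunConfig` drives the full analysis: acquire the three input
tables (per-recall components, participant covariates, survey design) either
from CSV paths or from the synthetic generator; apply the cohort-assembly
exclusions; fit the measurement-error model; build the age/sex-standardized
pseudo-population; emit overall and subgroup summary tables (with Rao–Wu
bootstrap SEs); and fit the backward-selected survey regression of the
recall-average HEI total on participant characteristics.  Every output is
stamped with the seed and a hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import exclusions, me_model, pseudo, regression, survey
from .hei2010 import load_standards
from .synthetic import CohortConfig, generate_cohort, generate_recalls

__all__ = ["RunConfig", "load_tables", "run"]


@dataclass
class RunConfig:
    # exactly one of (simulate) or (recalls/covariates/design paths)
    simulate: dict | None = None
    recalls_path: str | None = None
    covariates_path: str | None = None
    design_path: str | None = None
    M: int = 100
    seed: int = 0
    bootstrap_replicates: int = 0       # 0 skips SE columns
    refit_per_replicate: bool = True    # bootstrap refits the ME model
    subgroups: list[str] = field(default_factory=lambda: ["heritage", "sex"])
    subgroup_share_model: bool = False
    run_regression: bool = True
    standardize: bool = True
    outdir: str = "dietqual_run"

    def validate(self) -> None:
        paths = (self.recalls_path, self.covariates_path, self.design_path)
        have_paths = all(p is not None for p in paths)
        if (self.simulate is None) == (not have_paths):
            raise ValueError("config must give either a simulate block or "
                             "all three input paths (recalls, covariates, "
                             "design)")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_tables(cfg: RunConfig):
    """Return (recalls, covariates, design) per the config."""
    cfg.validate()
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        cohort = generate_cohort(CohortConfig(**sim))
        recalls = generate_recalls(cohort)
        return recalls, cohort.covariates, cohort.design
    recalls = pd.read_csv(cfg.recalls_path)
    covars = pd.read_csv(cfg.covariates_path)
    design = pd.read_csv(cfg.design_path)
    return recalls, covars, design


def _roster(recalls: pd.DataFrame, covars: pd.DataFrame) -> pd.DataFrame:
    counts = recalls.groupby("participant_id").size()
    energy = recalls.groupby("participant_id")["energy"].mean()
    roster = covars[["id", "age", "heritage", "sex"]].copy()
    roster["n_recalls"] = roster["id"].map(counts).fillna(0).astype(int)
    roster["energy"] = roster["id"].map(energy)
    if "reliable" in covars.columns:
        roster["reliable"] = covars["reliable"]
    else:
        roster["reliable"] = True
    return roster


def _summary_with_se(pp: pseudo.PseudoPopulation, recalls, covars, design,
                     cfg: RunConfig, standards) -> pd.DataFrame:
    summ = pseudo.summarize(pp, standards=standards)
    if cfg.bootstrap_replicates <= 0:
        return summ
    repw = survey.rao_wu_replicate_weights(design, cfg.bootstrap_replicates,
                                           cfg.seed + 7)
    reps = []
    std_to = pp.standardization
    for r in range(cfg.bootstrap_replicates):
        wr = pd.Series(repw[r], index=design["id"].to_numpy())
        keep_ids = wr[wr > 0].index
        if cfg.refit_per_replicate:
            rec_r = recalls[recalls["participant_id"].isin(keep_ids)]
            cov_r = covars[covars["id"].isin(keep_ids)].reset_index(drop=True)
            model_r = me_model.fit(rec_r, cov_r)
            draws = me_model.draw_usual(
                model_r, rec_r, cov_r, M=max(pp.M // 2, 10),
                seed=cfg.seed + 100 + r,
                age_override=std_to.mean_age if std_to else None,
                pct_male=std_to.pct_male / 100.0 if std_to else None)
            from .hei2010 import score_frame
            scores = score_frame(draws, standards)
            w = wr.loc[draws["participant_id"]].to_numpy()
            reps.append(pseudo.score_summary(scores, w, standards))
        else:
            w = wr.loc[pp.frame["participant_id"]].to_numpy()
            reps.append(pseudo.score_summary(pp.frame, w, standards))
    stacked = pd.concat(reps)
    se = stacked.groupby(level=0).std(ddof=1)
    summ["mean_score_se"] = se["mean_score"]
    summ["pct_at_max_se"] = se["pct_at_max"]
    return summ


def run(cfg: RunConfig, me_config: me_model.MEConfig | None = None) -> dict:
    """Execute the pipeline; write CSVs under ``cfg.outdir``; return results.

    Deterministic under ``cfg.seed``.  Returns a dict of in-memory results
    (tables, model, audit) mirroring the files written.
    """
    cfg.validate()
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    standards = load_standards()

    recalls, covars, design = load_tables(cfg)
    roster = _roster(recalls, covars)
    retained, excl_counts = exclusions.apply_exclusions(roster)
    keep = set(retained)
    recalls = recalls[recalls["participant_id"].isin(keep)].reset_index(drop=True)
    covars = covars[covars["id"].isin(keep)].reset_index(drop=True)
    design = design[design["id"].isin(keep)].reset_index(drop=True)
    survey.validate_design(design)

    model = me_model.fit(recalls, covars, me_config)
    model.to_json(str(outdir / "me_model.json"))

    std_to = pseudo.Standardization() if cfg.standardize else None
    pp = pseudo.build(model, recalls, covars, design, M=cfg.M,
                      seed=cfg.seed + 1, standardize_to=std_to,
                      standards=standards)
    overall = _summary_with_se(pp, recalls, covars, design, cfg, standards)
    overall.to_csv(outdir / "summary_overall.csv")

    subgroup_tables = {}
    for var in cfg.subgroups:
        tab = pseudo.summarize_by(
            recalls, covars, design, by=var, M=cfg.M, seed=cfg.seed + 2,
            standardize_to=std_to, share_model=cfg.subgroup_share_model,
            me_config=me_config, standards=standards)
        tab.to_csv(outdir / f"summary_by_{var}.csv")
        subgroup_tables[var] = tab

    reg_result = None
    if cfg.run_regression:
        hei = regression.person_hei(recalls, standards)
        data = hei.merge(covars, left_on="participant_id", right_on="id")
        des = design.set_index("id").loc[data["participant_id"]].reset_index()
        spec = regression.RegressionSpec()
        reg_result = regression.backward_select(spec, data, des)
        reg_result.table.to_csv(outdir / "regression_table.csv")
        pd.DataFrame(reg_result.dropped,
                     columns=["term", "p_at_drop"]
                     ).to_csv(outdir / "regression_audit.csv", index=False)

    from . import __version__

    log = {
        "dietqual_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "exclusions": excl_counts.to_dict(),
        "n_analysis": len(covars),
        "model_converged": model.converged,
        "episodic_components": model.diagnostics["episodic_components"],
        "regression_r2": reg_result.r_squared if reg_result else None,
        "regression_selected": reg_result.selected if reg_result else None,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return {
        "overall": overall, "subgroups": subgroup_tables, "model": model,
        "regression": reg_result, "exclusions": excl_counts, "log": log,
        "pseudo_population": pp,
    }
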