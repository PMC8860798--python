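"""End-to-end orchestration: simulate -> measure -> preprocess -> select ->
fit -> compare, driven by one config with a single master seed.

Every stage writes plain-text intermediates (TSV + JSON metadata) into the
output directory so any stage can be re-run in isolation, and every report
embeds the config hash and package version.  Randomness flows from the
master seed through named per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, CohortTable, TruthRecord, generate_cohort, inject_missingness_and_outliers
from .elastic_net import ENConfig, cross_validate, select_mediators
from .irt import ItemFactorModel, SumScoreRule, build_sum_score_levels
from .model_selection import ComparisonRow, aic_from_df, comparison_table, likelihood_ratio_test, select_model
from .preprocess import PreprocessConfig, run_preprocess
from .sem import BiometricMediationModel, PathModelSpec, twin_saturated_correlations

__all__ = ["RunConfig", "run_pipeline", "validate_input"]

_STAGES = ("simulate", "measure", "preprocess", "select", "fit", "compare")


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of input_path / synthetic."""

    seed: int = 0
    outdir: str = "twinsem_out"
    input_path: str | None = None
    synthetic: dict | None = None
    n_quadrature: int = 49
    en: dict = field(default_factory=dict)
    n_starts: int = 3
    max_mediators: int = 2
    ci_level: float = 0.95
    fit_variants: tuple[str, ...] = ("biDir", "uniDir")

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence((int(self.seed), _STAGES.index(stage)))
        return int(ss.generate_state(1)[0] % (2**31))


def _truth_from_config(syn: dict) -> TruthRecord:
    t = syn.get("truth", {})
    return TruthRecord.standardized(
        exposure_props=tuple(t.get("exposure_props", (0.23, 0.62, 0.15, 0.01))),
        mediator_props={
            m: tuple(v) for m, v in t.get("mediator_props", {}).items()
        },
        outcome_props=tuple(t.get("outcome_props", (0.21, 0.18, 0.22, 0.005))),
        a={k: float(v) for k, v in t.get("a", {}).items()},
        b={k: float(v) for k, v in t.get("b", {}).items()},
        c=float(t.get("c", 0.9)),
    )


def validate_input(path: str | Path) -> tuple[CohortTable | None, list[str]]:
    """Schema / pedigree / item-coding checks on a cohort file.

    Returns (table, errors); the table is None when errors were found.
    """
    errors: list[str] = []
    try:
        table = CohortTable.read(path)
    except Exception as err:
        return None, [f"unreadable input: {err!r}"]
    df = table.data
    required = ["person_id", "family_id", "site_id", "relation"]
    for col in required:
        if col not in df.columns:
            errors.append(f"missing required column {col!r}")
    if errors:
        return None, errors
    bad_rel = set(df["relation"]) - {"MZ", "DZ", "SIB", "SINGLETON"}
    if bad_rel:
        errors.append(f"unknown relation labels: {sorted(bad_rel)}")
    for fam_id, fam in df.groupby("family_id"):
        rels = set(fam["relation"])
        ids = list(fam["person_id"])
        if rels & {"MZ", "DZ"}:
            if len(fam) != 2:
                errors.append(
                    f"twin family {fam_id} has {len(fam)} members ({ids}); expected a complete pair"
                )
            if len(rels) > 1:
                errors.append(
                    f"family {fam_id}: mismatched zygosity labels {sorted(rels)} for members {ids}"
                )
        if fam["site_id"].nunique() > 1:
            errors.append(f"family {fam_id}: members {ids} span multiple sites")
    # the same person listed under two families
    dup = df["person_id"][df["person_id"].duplicated()]
    for pid in dup:
        fams = sorted(df.loc[df["person_id"] == pid, "family_id"].unique())
        errors.append(f"person {pid} appears in families {fams}")
    item_cols = [c for c in df.columns if c.startswith(("te_item_", "ptsd_item_"))]
    for col in item_cols:
        vals = df[col].dropna().unique()
        bad = [v for v in vals if v not in (0, 1)]
        if bad:
            errors.append(f"item column {col}: non-binary value(s) {bad}")
    return (None, errors) if errors else (table, errors)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a report bundle (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    header = {"version": __version__, "config_hash": config.digest(), "seed": config.seed}

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3), **info})

        return done

    # -- simulate / load ----------------------------------------------------
    done = stage("simulate")
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        truth = _truth_from_config(syn)
        spec_kw = {k: v for k, v in syn.items() if k != "truth"}
        spec = CohortSpec(seed=config.stage_seed("simulate"), **spec_kw)
        table, truth = generate_cohort(spec, truth)
        table = inject_missingness_and_outliers(table, spec)
        table.write(out / "cohort.tsv")
        done(n_persons=len(table.data), source="synthetic")
    else:
        table, errors = validate_input(config.input_path)
        if errors:
            raise RuntimeError(f"stage simulate/load failed: {errors}")
        done(n_persons=len(table.data), source=config.input_path)

    df = table.data
    roi_cols = table.roi_columns

    # -- measure: item models and sum-score levels --------------------------
    done = stage("measure")
    te_cols = [c for c in df.columns if c.startswith("te_item_")]
    ptsd_cols = [c for c in df.columns if c.startswith("ptsd_item_")]
    reports = []
    for label, cols in (("te", te_cols), ("ptsdsx", ptsd_cols)):
        fit = ItemFactorModel(df[cols], n_quadrature=config.n_quadrature).fit()
        rep = fit.to_frame()
        rep.insert(0, "scale", label)
        reports.append(rep)
    item_report = pd.concat(reports, ignore_index=True)
    _write_tsv(item_report, out / "item_parameters.tsv")
    levels = build_sum_score_levels(df[te_cols], df[ptsd_cols], SumScoreRule())
    df = pd.concat([df, levels], axis=1)
    done(n_te_items=len(te_cols), n_ptsd_items=len(ptsd_cols))

    # -- preprocess ----------------------------------------------------------
    done = stage("preprocess")
    analysis = run_preprocess(df, config=PreprocessConfig())
    adf = analysis.data
    _write_tsv(adf, out / "analysis.tsv")
    (out / "preprocess_provenance.json").write_text(
        json.dumps({**header, "provenance": analysis.provenance}, indent=1, sort_keys=True)
    )
    done(n_masked_actions=len(analysis.provenance))

    # -- select: elastic-net mediator screen --------------------------------
    done = stage("select")
    selected: list[str] = []
    if roi_cols:
        sel_rows = adf[["ptsdsx_score", "te_score", *roi_cols]].dropna()
        en_cfg = ENConfig(seed=config.stage_seed("select"), **config.en)
        groups = adf.loc[sel_rows.index, "family_id"].to_numpy()
        path = cross_validate(
            sel_rows[["te_score", *roi_cols]].to_numpy(),
            sel_rows["ptsdsx_score"].to_numpy(),
            config=en_cfg,
            groups=groups,
            predictor_names=["te_score", *roi_cols],
        )
        selected = select_mediators(path, exclude=("te_score",))
        summary = {**header, **path.summary_dict(), "selected": selected}
        (out / "en_selection.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        _write_tsv(path.to_frame(), out / "en_path.tsv")
    mediators = selected[: config.max_mediators]
    done(n_selected=len(selected), mediators=mediators)

    # -- fit -----------------------------------------------------------------
    done = stage("fit")
    phenos = ["te_score", *mediators, "ptsdsx_score"]
    fits = {}
    # fit nested variants first and warm-start richer ones from their
    # solutions (extra paths start at zero), which both speeds up the
    # optimizer and keeps the nesting inequality on -2lnL honest
    order = sorted(
        config.fit_variants,
        key=lambda v: len(PathModelSpec(phenotypes=phenos, variant=v).free_path_names()),
    )
    prev = None
    for variant in order:
        model = BiometricMediationModel(adf, PathModelSpec(phenotypes=phenos, variant=variant))
        start = model.start_params()
        if prev is not None:
            start.update({k: v for k, v in prev.params.items() if k in start})
        fits[variant] = model.fit(
            start_params=start, n_starts=config.n_starts, seed=config.stage_seed("fit")
        )
        prev = fits[variant]
    base_name = config.fit_variants[0]
    base = fits[base_name]

    indirect = base.indirect_effects(level=config.ci_level)
    _write_tsv(indirect, out / "table2_indirect_effects.tsv")
    twin = twin_saturated_correlations(adf, phenos)
    twin.combined().round(4).to_csv(out / "table3_twin_correlations.tsv", sep="\t")
    proportions = fits.get("uniDir", base).variance_proportions(level=config.ci_level)
    _write_tsv(proportions.round(6), out / "table4_variance_components.tsv")
    done(phenotypes=phenos, minus2ll={k: round(v.minus2ll, 4) for k, v in fits.items()})

    # -- compare -------------------------------------------------------------
    done = stage("compare")
    rows = [
        ComparisonRow(
            base=base_name, comparison=None, ep=base.ep, minus2ll=base.minus2ll,
            df=base.df, aic=aic_from_df(base.minus2ll, base.df),
        )
    ]
    for name, fit in fits.items():
        if name == base_name:
            continue
        rows.append(likelihood_ratio_test(base, fit, base_name=base_name, nested_name=name))
    chosen = select_model(rows)
    _write_tsv(comparison_table(rows), out / "table1_model_comparison.tsv")
    done(selected_model=chosen)

    bundle = {
        **header,
        "selected_mediators": selected,
        "fitted_mediators": mediators,
        "selected_model": chosen,
        "comparison": [dataclasses.asdict(r) for r in rows],
        "log": log,
    }
    (out / "report.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return bundle
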