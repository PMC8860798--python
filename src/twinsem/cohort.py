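"""Synthetic multilevel twin cohorts with a mediation structure.

Emulates a family study nested in data-collection sites: monozygotic (MZ)
and dizygotic (DZ) twin pairs recruited at a small number of twin-hub sites,
plus sibling pairs and singletons spread over all sites.  Phenotypes are
generated on the liability scale from additive-genetic (A), family-shared
(C), unique (E) and site (S) Gaussian components; an exposure score (TEs,
lifetime traumatic events), mediator brain-ROI volumes and an outcome score
(PTSDsx, current PTSD symptoms) are linked by structural paths

    M_j = a_j * X + u_Mj        Y = c * X + sum_j b_j * M_j + u_Y

so the indirect effect of X on Y through mediator j is ``a_j * b_j``.
Binary questionnaire items arise from the latent scores via a two-parameter
logistic (2PL) response curve; most item difficulties sit two or more SD
above the population mean, which produces the heavily zero-inflated sum
scores seen in child trauma inventories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .components import VarianceComponents

__all__ = [
    "CohortSpec",
    "TruthRecord",
    "CohortTable",
    "generate_cohort",
    "generate_item_responses",
    "inject_missingness_and_outliers",
    "monte_carlo_implied_cov",
    "default_te_item_params",
    "default_ptsd_item_params",
    "calibrate_zero_rate",
]

RELATION_CODES = ("MZ", "DZ", "SIB", "SINGLETON")
#: additive-genetic correlation between family members by relation
GENETIC_R = {"MZ": 1.0, "DZ": 0.5, "SIB": 0.5, "SINGLETON": 0.0}

QC_THRESHOLD = 600.0
QC_SD = 150.0


def _validate_proportion(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class CohortSpec:
    """Design of a synthetic cohort: family counts, sites, nuisance rates."""

    n_mz_pairs: int = 330
    n_dz_pairs: int = 425
    n_sib_pairs: int = 400
    n_singletons: int = 4000
    n_sites: int = 20
    n_twin_hub_sites: int = 4
    covariate_model: dict[str, dict[str, float]] = field(default_factory=dict)
    zero_te_target: float | None = 0.6195
    qc_fail_rate: float = 0.068
    outlier_rate: float = 0.002
    generate_items: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_sib_pairs", "n_singletons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_mz_pairs + self.n_dz_pairs + self.n_sib_pairs + self.n_singletons == 0:
            raise ValueError("at least one family type must be nonzero")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if not (1 <= self.n_twin_hub_sites <= self.n_sites):
            raise ValueError("n_twin_hub_sites must be in [1, n_sites]")
        _validate_proportion("qc_fail_rate", self.qc_fail_rate)
        _validate_proportion("outlier_rate", self.outlier_rate)
        if self.zero_te_target is not None:
            _validate_proportion("zero_te_target", self.zero_te_target)


@dataclass
class TruthRecord:
    """Generating parameters of a synthetic cohort.

    ``components`` holds the A/C/E/S variances of each phenotype's
    *structural residual*; for the exposure the residual is the phenotype
    itself.  ``mediators`` lists the ROI phenotypes in column order; null
    ROIs (no mediation) simply carry ``a = b = 0``.  Phenotypes are built to
    unit total variance, so paths are standardized.
    """

    components: dict[str, VarianceComponents]
    a: dict[str, float] = field(default_factory=dict)
    b: dict[str, float] = field(default_factory=dict)
    c: float = 0.0
    exposure: str = "te"
    outcome: str = "ptsdsx"
    contralateral_corr: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    te_item_params: np.ndarray | None = None  # (n_items, 2): discrimination, difficulty
    ptsd_item_params: np.ndarray | None = None
    link: str = "logit"

    def __post_init__(self) -> None:
        for ph in (self.exposure, self.outcome):
            if ph not in self.components:
                raise ValueError(f"components missing phenotype {ph!r}")
        for m in self.a:
            if m not in self.components:
                raise ValueError(f"a-path names unknown mediator {m!r}")
        for pair, corrs in self.contralateral_corr.items():
            for comp, r in corrs.items():
                if not (-1.0 <= r <= 1.0):
                    raise ValueError(
                        f"contralateral correlation {comp} for {pair} out of [-1, 1]: {r}"
                    )

    @property
    def mediators(self) -> list[str]:
        return [ph for ph in self.components if ph not in (self.exposure, self.outcome)]

    @property
    def phenotypes(self) -> list[str]:
        """Order: exposure, mediators, outcome."""
        return [self.exposure, *self.mediators, self.outcome]

    @classmethod
    def standardized(
        cls,
        exposure_props: tuple[float, float, float, float],
        mediator_props: dict[str, tuple[float, float, float, float]] | None = None,
        outcome_props: tuple[float, float, float, float] | None = None,
        a: dict[str, float] | None = None,
        b: dict[str, float] | None = None,
        c: float = 0.0,
        **kwargs,
    ) -> "TruthRecord":
        """Build a truth record with unit-variance phenotypes.

        ``*_props`` give the *relative* A/C/E/S split of each structural
        residual; the residual's total variance is derived so that every
        phenotype has variance exactly 1 given the paths.
        """
        a = dict(a or {})
        b = dict(b or {})
        mediator_props = dict(mediator_props or {})
        comps: dict[str, VarianceComponents] = {
            "te": VarianceComponents.from_proportions(*exposure_props, total=1.0)
        }
        # mediators: Var(M_j) = a_j^2 + resid
        for m, props in mediator_props.items():
            resid = 1.0 - a.get(m, 0.0) ** 2
            if resid <= 0:
                raise ValueError(f"a-path for {m} too large for unit variance")
            comps[m] = VarianceComponents.from_proportions(*props, total=resid)
        # outcome: Var(Y) = c^2 + sum_j b_j^2 + 2c sum_j b_j a_j
        #          + sum_{j!=k} b_j b_k a_j a_k + resid   (mediator residuals
        # independent across j, so Cov(M_j, M_k) = a_j a_k)
        if outcome_props is not None:
            med = list(mediator_props)
            bv = np.array([b.get(m, 0.0) for m in med])
            av = np.array([a.get(m, 0.0) for m in med])
            var_m_part = bv @ bv + (bv @ av) ** 2 - (bv * av) @ (bv * av)
            explained = c**2 + var_m_part + 2 * c * (bv @ av)
            resid = 1.0 - explained
            if resid <= 0:
                raise ValueError("paths too large for a unit-variance outcome")
            comps["ptsdsx"] = VarianceComponents.from_proportions(*outcome_props, total=resid)
        else:
            comps["ptsdsx"] = VarianceComponents.from_proportions(1 / 3, 1 / 3, 1 / 3, 0.0)
        return cls(components=comps, a=a, b=b, c=c, **kwargs)

    def to_jsonable(self) -> dict:
        d = {
            "components": {ph: vc.as_dict() for ph, vc in self.components.items()},
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "contralateral_corr": {
                "|".join(pair): corrs for pair, corrs in self.contralateral_corr.items()
            },
            "link": self.link,
        }
        for name in ("te_item_params", "ptsd_item_params"):
            arr = getattr(self, name)
            d[name] = None if arr is None else np.asarray(arr).tolist()
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "TruthRecord":
        comps = {
            ph: VarianceComponents(v["A"], v["C"], v["E"], v["S"])
            for ph, v in d["components"].items()
        }
        return cls(
            components=comps,
            a=dict(d.get("a", {})),
            b=dict(d.get("b", {})),
            c=float(d.get("c", 0.0)),
            exposure=d.get("exposure", "te"),
            outcome=d.get("outcome", "ptsdsx"),
            contralateral_corr={
                tuple(k.split("|")): v for k, v in d.get("contralateral_corr", {}).items()
            },
            te_item_params=(
                None if d.get("te_item_params") is None else np.asarray(d["te_item_params"])
            ),
            ptsd_item_params=(
                None if d.get("ptsd_item_params") is None else np.asarray(d["ptsd_item_params"])
            ),
            link=d.get("link", "logit"),
        )


@dataclass
class CohortTable:
    """Long-format person table plus its generating metadata."""

    data: pd.DataFrame
    truth: TruthRecord | None = None
    seed: int | None = None

    @property
    def roi_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("roi_")]

    def write(self, path: str | Path) -> None:
        """Write the table as TSV with a JSON sidecar carrying truth + seed."""
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False)
        meta = {
            "seed": self.seed,
            "truth": None if self.truth is None else self.truth.to_jsonable(),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        data = pd.read_csv(path, sep="\t")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        truth = seed = None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            seed = meta.get("seed")
            if meta.get("truth") is not None:
                truth = TruthRecord.from_jsonable(meta["truth"])
        return cls(data=data, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# item parameter defaults

def default_te_item_params(rng: np.random.Generator | None = None) -> np.ndarray:
    """17 trauma-exposure items: extreme difficulties, 15/17 at >= +2 SD.

    Loadings span roughly 0.46-0.96 on the standardized-factor scale;
    discriminations follow from the logistic 2PL conversion.
    """
    rng = rng or np.random.default_rng(171)
    loadings = rng.uniform(0.46, 0.96, size=17)
    disc = 1.702 * loadings / np.sqrt(1.0 - loadings**2)
    diff = np.empty(17)
    # two comparatively common items (learning of death / witnessing at home)
    # anchor the zero-endorsement rate; the rest are rare direct-threat items
    diff[0] = 0.4
    diff[1] = 1.4
    diff[2:] = rng.uniform(2.0, 4.5, size=15)
    return np.column_stack([disc, diff])


def default_ptsd_item_params(rng: np.random.Generator | None = None) -> np.ndarray:
    """22 symptom items; every difficulty above +1.8 SD.

    Difficulties are placed so that about 95% of subjects report three or
    fewer symptoms while the ordinal symptom level still spreads over its
    four categories among exposure-endorsing subjects (keeping the
    standardized score within roughly +/-3.5 SD, as observed in cohorts of
    this kind).
    """
    rng = rng or np.random.default_rng(221)
    loadings = rng.uniform(0.40, 0.97, size=22)
    disc = 1.702 * loadings / np.sqrt(1.0 - loadings**2)
    diff = np.empty(22)
    diff[:3] = rng.uniform(1.8, 2.5, size=3)  # mood/reactivity items visible at home
    diff[3:] = rng.uniform(2.5, 4.2, size=19)
    return np.column_stack([disc, diff])


def _item_prob(theta: np.ndarray, params: np.ndarray) -> np.ndarray:
    """2PL endorsement probabilities, persons x items."""
    disc = params[:, 0]
    diff = params[:, 1]
    if np.any(disc <= 0):
        raise ValueError("discriminations must be > 0")
    from scipy.special import expit

    z = disc[None, :] * (np.asarray(theta, dtype=float)[:, None] - diff[None, :])
    return expit(z)


def generate_item_responses(
    liability: np.ndarray,
    item_params: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw binary responses from the 2PL curve given per-person liabilities.

    P(endorse | theta) = logistic(disc * (theta - difficulty)); the
    probability is exactly 0.5 at theta = difficulty.
    """
    item_params = np.asarray(item_params, dtype=float)
    if not np.all(np.isfinite(item_params)):
        raise ValueError("item parameters must be finite")
    p = _item_prob(liability, item_params)
    return (rng.random(p.shape) < p).astype(np.int64)


def calibrate_zero_rate(
    liability: np.ndarray, item_params: np.ndarray, target: float
) -> np.ndarray:
    """Shift all difficulties by a common offset so the expected fraction of
    persons endorsing *no* item equals ``target`` on this liability sample."""
    from scipy.optimize import brentq

    item_params = np.asarray(item_params, dtype=float)

    def zero_rate(delta: float) -> float:
        shifted = item_params.copy()
        shifted[:, 1] += delta
        p = _item_prob(liability, shifted)
        return float(np.mean(np.prod(1.0 - p, axis=1)))

    f = lambda d: zero_rate(d) - target
    lo, hi = -8.0, 12.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("zero-endorsement target not reachable by a difficulty shift")
    delta = brentq(f, lo, hi, xtol=1e-6)
    out = item_params.copy()
    out[:, 1] += delta
    return out


# ---------------------------------------------------------------------------
# component simulation helpers

def component_correlation(truth: TruthRecord, comp: str) -> np.ndarray:
    """Cross-phenotype correlation of one component's latent draws.

    Identity except for declared contralateral ROI pairs, whose A/C/E
    residual components may correlate between hemispheres.
    """
    phenos = truth.phenotypes
    idx = {ph: i for i, ph in enumerate(phenos)}
    R = np.eye(len(phenos))
    for (ph_i, ph_j), corrs in truth.contralateral_corr.items():
        r = corrs.get(comp, 0.0)
        i, j = idx[ph_i], idx[ph_j]
        R[i, j] = R[j, i] = r
    return R


def _component_chols(truth: TruthRecord) -> dict[str, np.ndarray]:
    chols = {}
    for comp in ("A", "C", "E", "S"):
        R = component_correlation(truth, comp) if comp != "S" else np.eye(len(truth.phenotypes))
        try:
            chols[comp] = np.linalg.cholesky(R)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"contralateral correlations make component {comp} non-PD") from err
    return chols


def _component_sds(truth: TruthRecord) -> dict[str, np.ndarray]:
    phenos = truth.phenotypes
    out = {}
    for comp, attr in zip(("A", "C", "E", "S"), ("var_a", "var_c", "var_e", "var_s")):
        out[comp] = np.sqrt(
            np.maximum([getattr(truth.components[ph], attr) for ph in phenos], 0.0)
        )
    return out


def _draw_pair_residuals(
    rng: np.random.Generator,
    n_pairs: int,
    truth: TruthRecord,
    chols: dict[str, np.ndarray],
    sds: dict[str, np.ndarray],
    r_a: float,
) -> tuple[np.ndarray, np.ndarray]:
    """A+C+E residual vectors (n_pairs x p, no site term) for both members."""
    p = len(truth.phenotypes)
    z1 = rng.standard_normal((n_pairs, p)) @ chols["A"].T
    z2 = rng.standard_normal((n_pairs, p)) @ chols["A"].T
    a1 = z1
    a2 = r_a * z1 + np.sqrt(max(0.0, 1.0 - r_a**2)) * z2
    c = rng.standard_normal((n_pairs, p)) @ chols["C"].T
    e1 = rng.standard_normal((n_pairs, p)) @ chols["E"].T
    e2 = rng.standard_normal((n_pairs, p)) @ chols["E"].T
    m1 = sds["A"] * a1 + sds["C"] * c + sds["E"] * e1
    m2 = sds["A"] * a2 + sds["C"] * c + sds["E"] * e2
    return m1, m2


def _structural_transform(truth: TruthRecord, resid: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Apply the recursive mediation paths to per-phenotype residuals."""
    x = resid[truth.exposure]
    out = {truth.exposure: x}
    for m in truth.mediators:
        out[m] = truth.a.get(m, 0.0) * x + resid[m]
    y = truth.c * x + resid[truth.outcome]
    for m in truth.mediators:
        y = y + truth.b.get(m, 0.0) * out[m]
    out[truth.outcome] = y
    return out


ANCESTRY_GROUPS = ("groupA", "groupB", "groupC", "groupD", "groupE")
ANCESTRY_PROBS = (0.52, 0.15, 0.20, 0.02, 0.11)
SCANNERS = ("scanner1", "scanner2", "scanner3")


def generate_cohort(spec: CohortSpec, truth: TruthRecord) -> tuple[CohortTable, TruthRecord]:
    """Simulate a cohort under ``spec`` and ``truth``.

    Latent A components correlate 1.0 within MZ pairs and 0.5 within DZ or
    sibling pairs; C is shared within family, S within site, E independent.
    The same seed reproduces the table bit for bit.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xC0)))
    phenos = truth.phenotypes

    fam_relations = (
        ["MZ"] * spec.n_mz_pairs
        + ["DZ"] * spec.n_dz_pairs
        + ["SIB"] * spec.n_sib_pairs
        + ["SINGLETON"] * spec.n_singletons
    )
    fam_sizes = [1 if r == "SINGLETON" else 2 for r in fam_relations]
    n_fam = len(fam_relations)

    # twins are recruited at the twin-hub sites only; sibs/singletons anywhere
    hub = np.arange(spec.n_twin_hub_sites)
    all_sites = np.arange(spec.n_sites)
    fam_site = np.empty(n_fam, dtype=np.int64)
    for i, rel in enumerate(fam_relations):
        fam_site[i] = rng.choice(hub) if rel in ("MZ", "DZ") else rng.choice(all_sites)

    # site effects per phenotype (structural-residual scale)
    sds = _component_sds(truth)
    chols = _component_chols(truth)
    site_draws = sds["S"][None, :] * rng.standard_normal((spec.n_sites, len(phenos)))

    # per-phenotype residuals, member-major layout
    person_fam: list[int] = []
    person_rel: list[str] = []
    for i, (rel, size) in enumerate(zip(fam_relations, fam_sizes)):
        person_fam.extend([i] * size)
        person_rel.extend([rel] * size)
    person_fam_arr = np.asarray(person_fam)
    n_person = len(person_fam)
    person_site = fam_site[person_fam_arr]

    pair_idx = np.asarray([i for i, s in enumerate(fam_sizes) if s == 2], dtype=np.int64)
    single_idx = np.asarray([i for i, s in enumerate(fam_sizes) if s == 1], dtype=np.int64)
    first_pos = np.cumsum([0] + fam_sizes[:-1])

    resid_mat = np.empty((n_person, len(phenos)))
    if len(pair_idx):
        r_vec = np.asarray([GENETIC_R[fam_relations[i]] for i in pair_idx])
        for r_a in np.unique(r_vec):
            sel = r_vec == r_a
            m1, m2 = _draw_pair_residuals(rng, int(sel.sum()), truth, chols, sds, float(r_a))
            rows = pair_idx[sel]
            resid_mat[first_pos[rows]] = m1
            resid_mat[first_pos[rows] + 1] = m2
    if len(single_idx):
        p = len(phenos)
        n1 = len(single_idx)
        vals = (
            sds["A"] * (rng.standard_normal((n1, p)) @ chols["A"].T)
            + sds["C"] * (rng.standard_normal((n1, p)) @ chols["C"].T)
            + sds["E"] * (rng.standard_normal((n1, p)) @ chols["E"].T)
        )
        resid_mat[first_pos[single_idx]] = vals
    resid_mat = resid_mat + site_draws[person_site]
    resid = {ph: resid_mat[:, k] for k, ph in enumerate(phenos)}

    scores = _structural_transform(truth, resid)

    # covariates: twins/sibs share age band and ancestry; scanner follows site
    fam_age = rng.normal(9.92, 0.62, size=n_fam)
    age = fam_age[person_fam_arr] + np.where(
        np.asarray(person_rel) == "SINGLETON", 0.0, rng.normal(0, 0.05, size=n_person)
    )
    sex = rng.integers(0, 2, size=n_person)
    fam_ancestry = rng.choice(len(ANCESTRY_GROUPS), size=n_fam, p=ANCESTRY_PROBS)
    ancestry = np.asarray(ANCESTRY_GROUPS)[fam_ancestry[person_fam_arr]]
    site_scanner = rng.integers(0, len(SCANNERS), size=spec.n_sites)
    scanner = np.asarray(SCANNERS)[site_scanner[person_site]]

    cov_effects = spec.covariate_model
    age_z = (age - 9.92) / 0.62
    sex_c = sex - 0.5
    for ph in phenos:
        eff = cov_effects.get(ph, {})
        scores[ph] = (
            scores[ph]
            + eff.get("age", 0.0) * age_z
            + eff.get("sex", 0.0) * sex_c
            + eff.get("ancestry", 0.0) * (fam_ancestry[person_fam_arr] - 2) / 2.0
            + eff.get("scanner", 0.0) * (site_scanner[person_site] - 1.0)
        )

    df = pd.DataFrame(
        {
            "person_id": [f"P{i:06d}" for i in range(n_person)],
            "family_id": [f"F{i:05d}" for i in person_fam],
            "site_id": [f"S{s:02d}" for s in person_site],
            "relation": person_rel,
            "age": age,
            "sex": np.where(sex == 1, "F", "M"),
            "ancestry": ancestry,
            "scanner": scanner,
        }
    )

    # binary items from the latent exposure / outcome scores
    if spec.generate_items:
        te_params = truth.te_item_params
        if te_params is None:
            te_params = default_te_item_params()
        te_params = np.asarray(te_params, dtype=float)
        if spec.zero_te_target is not None:
            te_params = calibrate_zero_rate(
                scores[truth.exposure], te_params, spec.zero_te_target
            )
        truth = dataclasses.replace(truth, te_item_params=te_params)
        te_items = generate_item_responses(scores[truth.exposure], te_params, rng)
        for j in range(te_items.shape[1]):
            df[f"te_item_{j + 1:02d}"] = te_items[:, j]

        ptsd_params = truth.ptsd_item_params
        if ptsd_params is None:
            ptsd_params = default_ptsd_item_params()
            truth = dataclasses.replace(truth, ptsd_item_params=np.asarray(ptsd_params))
        ptsd_items = generate_item_responses(
            scores[truth.outcome], np.asarray(ptsd_params, dtype=float), rng
        )
        for j in range(ptsd_items.shape[1]):
            df[f"ptsd_item_{j + 1:02d}"] = ptsd_items[:, j]

    for m in truth.mediators:
        df[f"roi_{m}"] = scores[m]
    # latent scores retained for validation and for analyses that skip the
    # item-measurement stage
    df["te_score_true"] = scores[truth.exposure]
    df["ptsdsx_score_true"] = scores[truth.outcome]

    roi_cols = [f"roi_{m}" for m in truth.mediators]
    if roi_cols:
        roi_mean = df[roi_cols].mean(axis=1)
        df["total_subcortical_volume"] = roi_mean + 0.5 * rng.standard_normal(n_person)
        df["total_cortical_volume"] = roi_mean + 0.5 * rng.standard_normal(n_person)
    else:
        df["total_subcortical_volume"] = rng.standard_normal(n_person)
        df["total_cortical_volume"] = rng.standard_normal(n_person)
    df["qc_score"] = np.full(n_person, QC_THRESHOLD + 2.0 * QC_SD)

    return CohortTable(data=df, truth=truth, seed=spec.seed), truth


def inject_missingness_and_outliers(table: CohortTable, spec: CohortSpec) -> CohortTable:
    """Draw QC scores so ``qc_fail_rate`` of subjects fall below 600, and
    replace ``outlier_rate`` of ROI datapoints with > 4 SD outliers.

    Deterministic under the spec seed; returns a new table.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA1)))
    df = table.data.copy()
    n = len(df)

    z = rng.standard_normal(n)
    if spec.qc_fail_rate <= 0.0:
        df["qc_score"] = QC_THRESHOLD + QC_SD * (np.abs(z) + 0.5)
    else:
        offset = norm.ppf(1.0 - spec.qc_fail_rate)
        df["qc_score"] = QC_THRESHOLD + QC_SD * (z + offset)

    if spec.outlier_rate > 0.0:
        for col in table.roi_columns:
            hit = rng.random(n) < spec.outlier_rate
            if not hit.any():
                continue
            sd = float(df[col].std(ddof=0))
            sign = np.where(rng.random(int(hit.sum())) < 0.5, -1.0, 1.0)
            df.loc[hit, col] = sign * (4.5 + np.abs(rng.standard_normal(int(hit.sum())))) * sd
    return CohortTable(data=df, truth=table.truth, seed=table.seed)


def monte_carlo_implied_cov(
    truth: TruthRecord,
    pair_type: str,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Brute-force pair covariance matrix by direct simulation.

    Simulates ``n_replicates`` clusters of two persons whose component
    sharing follows ``pair_type`` (``MZ``, ``DZ``, ``SIB``,
    ``UNRELATED_SAME_SITE`` or ``UNRELATED``) and returns the sample
    covariance of the stacked phenotype vectors (member 1 first).  Serves as
    the simulation oracle for the model-implied covariance.
    """
    if n_replicates < 1000:
        raise ValueError("n_replicates must be >= 1000 for a stable oracle")
    valid = {"MZ", "DZ", "SIB", "UNRELATED_SAME_SITE", "UNRELATED"}
    if pair_type not in valid:
        raise ValueError(f"unknown pair_type {pair_type!r}; expected one of {sorted(valid)}")
    rng = np.random.default_rng(seed)
    phenos = truth.phenotypes
    p = len(phenos)
    same_family = pair_type in ("MZ", "DZ", "SIB")
    same_site = pair_type != "UNRELATED"
    r_a = GENETIC_R.get(pair_type, 0.0)
    sds = _component_sds(truth)
    chols = _component_chols(truth)

    m1, m2 = _draw_pair_residuals(rng, n_replicates, truth, chols, sds, r_a)
    if not same_family:
        # unrelated persons share no A/C/E: rebuild both members independently
        c1 = rng.standard_normal((n_replicates, p)) @ chols["C"].T
        za1 = rng.standard_normal((n_replicates, p)) @ chols["A"].T
        za2 = rng.standard_normal((n_replicates, p)) @ chols["A"].T
        c2 = rng.standard_normal((n_replicates, p)) @ chols["C"].T
        e1 = rng.standard_normal((n_replicates, p)) @ chols["E"].T
        e2 = rng.standard_normal((n_replicates, p)) @ chols["E"].T
        m1 = sds["A"] * za1 + sds["C"] * c1 + sds["E"] * e1
        m2 = sds["A"] * za2 + sds["C"] * c2 + sds["E"] * e2
    s_draw1 = sds["S"] * rng.standard_normal((n_replicates, p))
    s_draw2 = s_draw1 if same_site else sds["S"] * rng.standard_normal((n_replicates, p))
    m1 = m1 + s_draw1
    m2 = m2 + s_draw2

    resid1 = {ph: m1[:, k] for k, ph in enumerate(phenos)}
    resid2 = {ph: m2[:, k] for k, ph in enumerate(phenos)}
    s1 = _structural_transform(truth, resid1)
    s2 = _structural_transform(truth, resid2)
    stacked = np.column_stack([s1[ph] for ph in phenos] + [s2[ph] for ph in phenos])
    return np.cov(stacked, rowvar=False)
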