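"""Multilevel trivariate variance-components mediation SEM.

The model decomposes each phenotype's structural residual into additive-
genetic (A), family-shared (C), unique (E) and site (S) Gaussian components
and links exposure X, mediators M_j and outcome Y through a path matrix B:

    P = B P + u,    Cov(u) = Psi_A + Psi_C + Psi_E + Psi_S

so the implied within-person covariance is G Psi G' with G = (I - B)^-1.
Between two members of the same cluster the A block is scaled by the
genetic relatedness r (1 for MZ twins, 0.5 for DZ twins and full siblings,
0 otherwise), the C block by a family-sharing indicator and the S block by
a site-sharing indicator.

Estimation is full-information maximum likelihood (FIML): the Gaussian
log-likelihood is evaluated on each family's observed entries only, and the
site factor — shared by every family in a site — is absorbed exactly
through a rank-p Woodbury update per site rather than by inverting the full
site covariance block.

The public surface follows the Model/Results convention:
``BiometricMediationModel(data, spec).fit()`` returns a
:class:`BiometricResults` with estimates, likelihood statistics,
delta-method and profile-likelihood confidence intervals and a ``summary()``
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .components import VarianceComponents

__all__ = [
    "PathModelSpec",
    "BiometricMediationModel",
    "BiometricResults",
    "TwinCorrelations",
    "build_implied_cov",
    "fiml_neg2ll",
    "fit_ml",
    "penalized_path_fit",
    "indirect_effect",
    "twin_saturated_correlations",
    "standardize_components",
]

VARIANTS = ("saturated", "biDir", "uniDir", "uniDir_reversed", "uniDir_no_mediation")

#: genetic relatedness by relation label
_REL_R = {"MZ": 1.0, "DZ": 0.5, "SIB": 0.5, "SINGLETON": 0.0}

_PENALTY = 1.0e12
_EIG_CLAMP = 1.0e-6  # spectrum floor for the non-PD continuation
_BARRIER = 1.0e6  # weight of the squared negative-eigenvalue barrier
_CHI2_95 = 3.841458820694124  # chi-square(1) 95% cutoff for profile CIs


# ---------------------------------------------------------------------------
# model specification


@dataclass
class PathModelSpec:
    """Path structure of the mediation model.

    ``phenotypes`` is ordered [exposure, mediators..., outcome].  The
    ``variant`` fixes subsets of paths at zero:

    - ``saturated``        : c, c_rev, a_j, b_j, a_rev_j, b_rev_j all free
    - ``biDir``            : c and c_rev free, forward a_j/b_j free
    - ``uniDir``           : forward paths only (c, a_j, b_j)
    - ``uniDir_reversed``  : reverse paths only (c_rev, a_rev_j, b_rev_j)
    - ``uniDir_no_mediation``: c only
    """

    phenotypes: list[str]
    variant: str = "uniDir"
    contralateral_pairs: list[tuple[str, str]] = field(default_factory=list)
    contralateral_components: tuple[str, ...] = ("A", "C", "E")
    estimate_site: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if len(self.phenotypes) < 1:
            raise ValueError("need at least one phenotype")
        for pair in self.contralateral_pairs:
            for ph in pair:
                if ph not in self.mediators:
                    raise ValueError(f"contralateral pair names non-mediator {ph!r}")

    @property
    def exposure(self) -> str:
        return self.phenotypes[0]

    @property
    def outcome(self) -> str:
        return self.phenotypes[-1]

    @property
    def mediators(self) -> list[str]:
        return self.phenotypes[1:-1]

    def free_path_names(self) -> list[str]:
        if len(self.phenotypes) == 1:
            return []  # univariate variance decomposition: no paths
        med = self.mediators
        fwd = [f"a_{m}" for m in med] + [f"b_{m}" for m in med] + ["c"]
        rev = [f"a_rev_{m}" for m in med] + [f"b_rev_{m}" for m in med] + ["c_rev"]
        if self.variant == "saturated":
            return fwd + rev
        if self.variant == "biDir":
            return fwd + ["c_rev"]
        if self.variant == "uniDir":
            return fwd
        if self.variant == "uniDir_reversed":
            return rev
        return ["c"]  # uniDir_no_mediation


class _Parameterization:
    """Maps the optimizer vector to natural-scale parameters.

    E variances are log-transformed (kept positive — they absorb measurement
    error); A, C and S variances are unconstrained so a negative C remains
    representable; contralateral correlations are atanh-transformed.
    """

    def __init__(self, spec: PathModelSpec):
        self.spec = spec
        names: list[tuple[str, str]] = []  # (name, kind)
        for ph in spec.phenotypes:
            names.append((f"mean_{ph}", "raw"))
        for ph in spec.phenotypes:
            names.append((f"var_A_{ph}", "raw"))
            names.append((f"var_C_{ph}", "raw"))
            names.append((f"var_E_{ph}", "log"))
            if spec.estimate_site:
                names.append((f"var_S_{ph}", "raw"))
        for name in spec.free_path_names():
            names.append((name, "raw"))
        for ph_i, ph_j in spec.contralateral_pairs:
            for comp in spec.contralateral_components:
                names.append((f"r{comp}_{ph_i}|{ph_j}", "atanh"))
        self.names = [n for n, _ in names]
        self.kinds = dict(names)

    @property
    def k(self) -> int:
        return len(self.names)

    def unpack(self, theta: np.ndarray) -> dict[str, float]:
        out = {}
        for name, val in zip(self.names, theta):
            kind = self.kinds[name]
            if kind == "log":
                out[name] = float(np.exp(np.clip(val, -60.0, 60.0)))
            elif kind == "atanh":
                out[name] = float(np.tanh(val))
            else:
                out[name] = float(val)
        return out

    def pack(self, params: dict[str, float]) -> np.ndarray:
        theta = np.empty(self.k)
        for i, name in enumerate(self.names):
            val = params[name]
            kind = self.kinds[name]
            if kind == "log":
                theta[i] = np.log(max(val, 1e-10))
            elif kind == "atanh":
                theta[i] = np.arctanh(np.clip(val, -0.9999, 0.9999))
            else:
                theta[i] = val
        return theta

    def jacobian_diag(self, theta: np.ndarray) -> np.ndarray:
        """d(natural)/d(optimizer) per coordinate (transforms are scalar)."""
        j = np.ones(self.k)
        for i, name in enumerate(self.names):
            kind = self.kinds[name]
            if kind == "log":
                j[i] = np.exp(theta[i])
            elif kind == "atanh":
                j[i] = 1.0 - np.tanh(theta[i]) ** 2
        return j


# ---------------------------------------------------------------------------
# implied moments


def _path_matrix(spec: PathModelSpec, params: dict[str, float]) -> np.ndarray:
    p = len(spec.phenotypes)
    idx = {ph: i for i, ph in enumerate(spec.phenotypes)}
    B = np.zeros((p, p))
    g = params.get
    for m in spec.mediators:
        B[idx[m], idx[spec.exposure]] = g(f"a_{m}", 0.0)
        B[idx[spec.outcome], idx[m]] = g(f"b_{m}", 0.0)
        B[idx[m], idx[spec.outcome]] = g(f"a_rev_{m}", 0.0)
        B[idx[spec.exposure], idx[m]] = g(f"b_rev_{m}", 0.0)
    if spec.exposure != spec.outcome:
        B[idx[spec.outcome], idx[spec.exposure]] = g("c", 0.0)
        B[idx[spec.exposure], idx[spec.outcome]] = g("c_rev", 0.0)
    return B


def _psi_matrices(spec: PathModelSpec, params: dict[str, float]) -> dict[str, np.ndarray]:
    p = len(spec.phenotypes)
    idx = {ph: i for i, ph in enumerate(spec.phenotypes)}
    psis: dict[str, np.ndarray] = {}
    for comp in ("A", "C", "E", "S"):
        v = np.array(
            [params.get(f"var_{comp}_{ph}", 0.0) for ph in spec.phenotypes]
        )
        psi = np.diag(v)
        if comp in spec.contralateral_components:
            for ph_i, ph_j in spec.contralateral_pairs:
                r = params.get(f"r{comp}_{ph_i}|{ph_j}", 0.0)
                i, j = idx[ph_i], idx[ph_j]
                scale = np.sqrt(max(v[i], 0.0) * max(v[j], 0.0))
                psi[i, j] = psi[j, i] = r * scale
        psis[comp] = psi
    return psis


def _transform(spec: PathModelSpec, params: dict[str, float]):
    """G = (I-B)^-1, component Psis, and the site loading term."""
    B = _path_matrix(spec, params)
    p = B.shape[0]
    ImB = np.eye(p) - B
    det = np.linalg.det(ImB)
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError(
            "singular (I - B): the reciprocal paths form an explosive feedback loop"
        )
    G = np.linalg.inv(ImB)
    psis = _psi_matrices(spec, params)
    return G, psis


def build_implied_cov(
    spec: PathModelSpec,
    components: dict[str, VarianceComponents],
    pair_type: str,
    paths: dict[str, float] | None = None,
    means: dict[str, float] | None = None,
    contralateral: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix for one cluster.

    ``pair_type``: ``MZ``, ``DZ``, ``SIB`` (same family and site),
    ``UNRELATED_SAME_SITE``, ``UNRELATED`` (two persons), or ``SINGLETON``
    (one person).  Phenotypes are stacked member-major.
    """
    valid = {"MZ", "DZ", "SIB", "UNRELATED_SAME_SITE", "UNRELATED", "SINGLETON"}
    if pair_type not in valid:
        raise ValueError(f"unknown pair_type {pair_type!r}")
    params: dict[str, float] = {}
    for ph, vc in components.items():
        params[f"var_A_{ph}"] = vc.var_a
        params[f"var_C_{ph}"] = vc.var_c
        params[f"var_E_{ph}"] = vc.var_e
        params[f"var_S_{ph}"] = vc.var_s
    params.update(paths or {})
    params.update(contralateral or {})
    G, psis = _transform(spec, params)
    within = G @ (psis["A"] + psis["C"] + psis["E"] + psis["S"]) @ G.T
    p = len(spec.phenotypes)
    mu_1 = np.array([(means or {}).get(ph, 0.0) for ph in spec.phenotypes])
    if pair_type == "SINGLETON":
        return mu_1, within
    r_a = _REL_R.get(pair_type, 0.0)
    fam = 1.0 if pair_type in ("MZ", "DZ", "SIB") else 0.0
    site = 0.0 if pair_type == "UNRELATED" else 1.0
    cross = G @ (r_a * psis["A"] + fam * psis["C"] + site * psis["S"]) @ G.T
    sigma = np.empty((2 * p, 2 * p))
    sigma[:p, :p] = within
    sigma[p:, p:] = within
    sigma[:p, p:] = cross
    sigma[p:, :p] = cross.T
    return np.concatenate([mu_1, mu_1]), sigma


# ---------------------------------------------------------------------------
# FIML data preparation


class _Pattern:
    __slots__ = ("obs_member", "obs_pheno", "rel", "rows", "sites", "y")

    def __init__(self, obs_member, obs_pheno, rel):
        self.obs_member = obs_member  # member index per observed dim
        self.obs_pheno = obs_pheno  # phenotype index per observed dim
        self.rel = rel  # relation label per member (defines the r matrix)
        self.rows: list[np.ndarray] = []  # per-family observed value vectors
        self.sites: list[int] = []
        self.y: np.ndarray | None = None


class _FIMLData:
    """Families grouped by (relation, missingness pattern) for fast FIML."""

    def __init__(
        self,
        data: pd.DataFrame,
        phenotypes: list[str],
        family_col: str = "family_id",
        site_col: str = "site_id",
        relation_col: str = "relation",
    ):
        for col in (family_col, site_col, relation_col, *phenotypes):
            if col not in data.columns:
                raise ValueError(f"data lacks required column {col!r}")
        self.phenotypes = phenotypes
        p = len(phenotypes)
        y_all = data[phenotypes].to_numpy(dtype=float)
        sites = pd.Categorical(data[site_col])
        self.n_sites = len(sites.categories)
        site_codes = np.asarray(sites.codes)
        fam_codes = pd.Categorical(data[family_col]).codes
        rel_all = data[relation_col].to_numpy()

        patterns: dict[tuple, _Pattern] = {}
        order = np.argsort(fam_codes, kind="stable")
        boundaries = np.flatnonzero(np.diff(fam_codes[order])) + 1
        groups = np.split(order, boundaries)
        n_obs = 0
        for rows in groups:
            y_f = y_all[rows]
            obs = np.isfinite(y_f)
            keep = obs.any(axis=1)
            if not keep.any():
                continue
            rows = rows[keep]
            y_f = y_f[keep]
            obs = obs[keep]
            rel = tuple(rel_all[rows])
            mask_key = tuple(map(tuple, obs))
            key = (rel, mask_key)
            pat = patterns.get(key)
            if pat is None:
                member_idx, pheno_idx = np.nonzero(obs)
                pat = patterns[key] = _Pattern(member_idx, pheno_idx, rel)
            pat.rows.append(y_f[obs])
            pat.sites.append(int(site_codes[rows[0]]))
            n_obs += int(obs.sum())

        self.patterns = list(patterns.values())
        for pat in self.patterns:
            pat.y = np.vstack(pat.rows)
            pat.sites = np.asarray(pat.sites, dtype=np.int64)
            pat.rows = []
        self.n_obs_points = n_obs
        self.n_persons = int(len(data))
        # families-per-site count for each pattern, used for the site logdet
        self.site_counts = np.zeros((self.n_sites, len(self.patterns)))
        for j, pat in enumerate(self.patterns):
            np.add.at(self.site_counts[:, j], pat.sites, 1.0)
        self.p = p

    def relatedness(self, pat: _Pattern) -> np.ndarray:
        k = len(pat.rel)
        r = np.ones((k, k))
        for i in range(k):
            for j in range(k):
                if i != j:
                    both_mz = pat.rel[i] == "MZ" and pat.rel[j] == "MZ"
                    r[i, j] = 1.0 if both_mz else 0.5
        return r


# ---------------------------------------------------------------------------
# model


class BiometricMediationModel:
    """FIML estimator of the multilevel A/C/E/S mediation model.

    Parameters
    ----------
    data : DataFrame with family, site and relation columns plus one column
        per phenotype (missing entries as NaN).
    spec : PathModelSpec naming the phenotypes (exposure first, outcome
        last) and the path variant.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: PathModelSpec,
        family_col: str = "family_id",
        site_col: str = "site_id",
        relation_col: str = "relation",
    ):
        self.spec = spec
        self.parameterization = _Parameterization(spec)
        self._data = _FIMLData(data, spec.phenotypes, family_col, site_col, relation_col)
        self._df = data
        self._penalized_evals = 0
        self._penalty_fn = None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, phenotypes: list[str], variant: str = "uniDir", **kw):
        return cls(data, PathModelSpec(phenotypes=list(phenotypes), variant=variant), **kw)

    # -- likelihood ---------------------------------------------------------

    def neg2loglik(self, params: dict[str, float]) -> float:
        """-2 log L at natural-scale parameters (pattern-wise marginal MVN).

        A non-positive-definite implied covariance returns a large penalized
        value (recorded in ``_penalized_evals``) so optimizers stay in
        bounds rather than aborting.
        """
        d = self._data
        spec = self.spec
        try:
            G, psis = _transform(spec, params)
        except np.linalg.LinAlgError:
            self._penalized_evals += 1
            return _PENALTY
        within = G @ (psis["A"] + psis["C"] + psis["E"]) @ G.T
        cross_a = G @ psis["A"] @ G.T
        cross_c = G @ psis["C"] @ G.T
        lam = G @ psis["S"] @ G.T  # site-factor covariance on the phenotype scale
        use_site = spec.estimate_site and np.any(np.abs(psis["S"]) > 0)
        mu = np.array([params.get(f"mean_{ph}", 0.0) for ph in spec.phenotypes])

        p = d.p
        total = d.n_obs_points * np.log(2.0 * np.pi)
        w_stack = np.zeros((len(d.patterns), p, p))
        v_acc = np.zeros((d.n_sites, p))
        for j, pat in enumerate(d.patterns):
            k = len(pat.rel)
            r_mat = d.relatedness(pat)
            full = np.empty((k * p, k * p))
            for i in range(k):
                for l in range(k):
                    if i == l:
                        full[i * p : (i + 1) * p, l * p : (l + 1) * p] = within
                    else:
                        full[i * p : (i + 1) * p, l * p : (l + 1) * p] = (
                            r_mat[i, l] * cross_a + cross_c
                        )
            dims = pat.obs_member * p + pat.obs_pheno
            sigma = full[np.ix_(dims, dims)]
            n_f = pat.y.shape[0]
            resid = pat.y - mu[pat.obs_pheno]
            if not np.all(np.isfinite(sigma)):
                self._penalized_evals += 1
                return _PENALTY
            try:
                cf = cho_factor(sigma, lower=True)
                total += 2.0 * n_f * np.sum(np.log(np.diag(cf[0])))
                alpha = cho_solve(cf, resid.T)
                solve = lambda rhs: cho_solve(cf, rhs)
            except np.linalg.LinAlgError:
                # continuation beyond the PD boundary: clamp the spectrum and
                # add a barrier that grows with the violation, keeping the
                # surface continuous so finite-difference gradients point
                # back toward feasibility
                self._penalized_evals += 1
                eigval, eigvec = np.linalg.eigh(sigma)
                clamped = np.maximum(eigval, _EIG_CLAMP)
                total += 2.0 * n_f * np.sum(np.log(clamped))
                total += _BARRIER * n_f * float(np.sum(np.minimum(eigval, 0.0) ** 2))
                inv = (eigvec / clamped) @ eigvec.T
                alpha = inv @ resid.T
                solve = lambda rhs: inv @ rhs
            total += float(np.sum(resid.T * alpha))
            if use_site:
                # U maps the p site factors into this pattern's observed dims;
                # with lam already on the phenotype scale, U is a 0/1 selector
                u = np.zeros((len(dims), p))
                u[np.arange(len(dims)), pat.obs_pheno] = 1.0
                sinv_u = solve(u)
                w_stack[j] = u.T @ sinv_u
                np.add.at(v_acc, pat.sites, (sinv_u.T @ resid.T).T)
        if use_site:
            w_site = np.einsum("sj,jab->sab", d.site_counts, w_stack)
            eye = np.eye(p)
            for s in range(d.n_sites):
                m = eye + w_site[s] @ lam
                eigm = np.linalg.eigvals(m).real
                if np.any(eigm <= 0):
                    self._penalized_evals += 1
                    clamped = np.maximum(eigm, _EIG_CLAMP)
                    total += float(np.sum(np.log(clamped)))
                    total += _BARRIER * float(np.sum(np.minimum(eigm, 0.0) ** 2))
                    continue
                _, logdet = np.linalg.slogdet(m)
                total += logdet
                u_s = np.linalg.solve(m, v_acc[s])
                total -= float(v_acc[s] @ lam @ u_s)
        if self._penalty_fn is not None:
            total += self._penalty_fn(params)
        return float(total)

    def _objective(self, theta: np.ndarray) -> float:
        if not np.all(np.isfinite(theta)):
            return _PENALTY
        return self.neg2loglik(self.parameterization.unpack(theta))

    # -- starting values ----------------------------------------------------

    def start_params(self) -> dict[str, float]:
        spec = self.spec
        df = self._df
        params: dict[str, float] = {}
        variances = {}
        for ph in spec.phenotypes:
            col = df[ph].to_numpy(dtype=float)
            col = col[np.isfinite(col)]
            params[f"mean_{ph}"] = float(np.mean(col)) if len(col) else 0.0
            variances[ph] = float(np.var(col)) if len(col) > 1 else 1.0

        # crude OLS path starts on complete cases
        sub = df[spec.phenotypes].dropna()
        path_names = set(spec.free_path_names())
        x = sub[spec.exposure].to_numpy()
        y = sub[spec.outcome].to_numpy()
        resid_var = dict(variances)
        if len(sub) > len(spec.phenotypes) + 2:
            for m in spec.mediators:
                mm = sub[m].to_numpy()
                a_hat = float(np.cov(x, mm)[0, 1] / np.var(x)) if np.var(x) > 0 else 0.0
                if f"a_{m}" in path_names:
                    params[f"a_{m}"] = a_hat
                    resid_var[m] = max(variances[m] - a_hat**2 * np.var(x), 0.2 * variances[m])
            design = np.column_stack(
                [np.ones(len(sub)), x] + [sub[m].to_numpy() for m in spec.mediators]
            )
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            if "c" in path_names:
                params["c"] = float(coef[1])
            for i, m in enumerate(spec.mediators):
                if f"b_{m}" in path_names:
                    params[f"b_{m}"] = float(coef[2 + i])
            fitted = design @ coef
            resid_var[spec.outcome] = max(
                float(np.var(y - fitted)), 0.1 * variances[spec.outcome]
            )
        for name in path_names:
            params.setdefault(name, 0.0)

        for ph in spec.phenotypes:
            v = resid_var.get(ph, 1.0)
            params[f"var_A_{ph}"] = 0.30 * v
            params[f"var_C_{ph}"] = 0.25 * v
            params[f"var_E_{ph}"] = 0.40 * v
            if spec.estimate_site:
                params[f"var_S_{ph}"] = 0.05 * v
        for ph_i, ph_j in spec.contralateral_pairs:
            for comp in spec.contralateral_components:
                params[f"r{comp}_{ph_i}|{ph_j}"] = 0.0
        return params

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start_params: dict[str, float] | None = None,
        n_starts: int = 5,
        seed: int = 0,
        maxiter: int = 2000,
        jitter: float = 0.10,
        method: str = "L-BFGS-B",
    ) -> "BiometricResults":
        """Minimize the FIML deviance from ``n_starts`` jittered starts.

        Finite-difference gradients can brush the non-PD penalty region, so
        each run tracks the best point actually evaluated (the optimizer's
        own report can be poisoned by a penalty step) and the winner is
        polished by restarting until the deviance stops improving.
        """
        par = self.parameterization
        theta0 = par.pack(start_params or self.start_params())
        rng = np.random.default_rng(seed)
        attempts = []
        best_x: np.ndarray | None = None
        best_f = np.inf

        def tracked(theta: np.ndarray) -> float:
            nonlocal best_x, best_f
            f = self._objective(theta)
            if f < best_f:
                best_f = f
                best_x = theta.copy()
            return f

        for s in range(n_starts):
            theta = theta0 if s == 0 else theta0 + jitter * rng.standard_normal(par.k)
            try:
                res = optimize.minimize(
                    tracked, theta, method=method, options={"maxiter": maxiter}
                )
                attempts.append(
                    {"start": s, "fun": float(res.fun), "success": bool(res.success)}
                )
            except Exception as err:  # pragma: no cover - diagnostics path
                attempts.append({"start": s, "error": repr(err)})
        if best_x is None or best_f >= _PENALTY / 2:
            raise RuntimeError(f"all optimization starts failed: {attempts}")

        # polish: restarting resets the Hessian approximation and recovers
        # from penalty-induced early termination
        converged = False
        for round_ in range(4):
            f_before = best_f
            res = optimize.minimize(
                tracked, best_x, method=method, options={"maxiter": maxiter}
            )
            improvement = f_before - best_f
            attempts.append({"polish": round_, "fun": float(best_f),
                             "improvement": float(improvement)})
            if improvement < 1e-6:
                converged = True
                break
        grad = optimize.approx_fprime(best_x, self._objective, 1e-6)
        return BiometricResults(
            model=self,
            theta=np.asarray(best_x, dtype=float),
            minus2ll=float(best_f),
            converged=converged,
            grad_norm=float(np.linalg.norm(grad)),
            start_log=attempts,
        )

    def fit_penalized(
        self,
        lam: float,
        alpha: float = 0.5,
        eps: float = 1e-10,
        **fit_kw,
    ) -> "BiometricResults":
        """Fit with an elastic-net penalty on the mediator a/b paths.

        Adds ``lam * n_persons * sum_j [(1-alpha)/2 beta_j^2 +
        alpha * |beta_j|]`` over the forward a- and b-path coefficients to
        the deviance; the direct path c and the variance components are
        unpenalized.  |beta| is smoothed as sqrt(beta^2 + eps) so the
        quasi-Newton optimizer sees a differentiable objective.
        """
        targets = [
            n for n in self.spec.free_path_names() if n.startswith(("a_", "b_"))
            and not n.startswith(("a_rev", "b_rev"))
        ]
        scale = float(self._data.n_persons)

        def penalty(params: dict[str, float]) -> float:
            tot = 0.0
            for name in targets:
                beta = params.get(name, 0.0)
                tot += (1 - alpha) / 2.0 * beta**2 + alpha * np.sqrt(beta**2 + eps)
            return lam * scale * tot

        self._penalty_fn = penalty if lam > 0 else None
        try:
            res = self.fit(**fit_kw)
            res.penalty = {"lam": lam, "alpha": alpha}
            # report the unpenalized deviance at the penalized solution
            self._penalty_fn = None
            res.minus2ll = self.neg2loglik(res.params)
            return res
        finally:
            self._penalty_fn = None


# ---------------------------------------------------------------------------
# results


class BiometricResults:
    """Fit output: estimates, -2lnL, ep, df, AIC, CIs and summary table.

    The df convention counts observed data points minus estimated
    parameters, and ``aic = minus2ll - 2 * df``.
    """

    def __init__(self, model, theta, minus2ll, converged, grad_norm, start_log):
        self.model = model
        self.theta = theta
        self.minus2ll = minus2ll
        self.converged = converged
        self.grad_norm = grad_norm
        self.start_log = start_log
        self.penalty: dict | None = None
        self._cov_params: np.ndarray | None = None

    @property
    def params(self) -> dict[str, float]:
        return self.model.parameterization.unpack(self.theta)

    @property
    def ep(self) -> int:
        return self.model.parameterization.k

    @property
    def n_obs_points(self) -> int:
        return self.model._data.n_obs_points

    @property
    def df(self) -> int:
        return self.n_obs_points - self.ep

    @property
    def aic(self) -> float:
        return self.minus2ll - 2.0 * self.df

    # -- uncertainty --------------------------------------------------------

    def cov_params(self, step: float = 1e-4) -> np.ndarray:
        """Delta-method covariance of the natural-scale parameters from a
        central-difference Hessian of the deviance/2."""
        if self._cov_params is None:
            par = self.model.parameterization
            k = par.k
            f = lambda th: 0.5 * self.model._objective(th)
            h = np.zeros((k, k))
            e = np.eye(k) * step
            f0 = f(self.theta)
            fp = np.array([f(self.theta + e[i]) for i in range(k)])
            fm = np.array([f(self.theta - e[i]) for i in range(k)])
            for i in range(k):
                h[i, i] = (fp[i] - 2 * f0 + fm[i]) / step**2
                for j in range(i + 1, k):
                    fpp = f(self.theta + e[i] + e[j])
                    fmm = f(self.theta - e[i] - e[j])
                    h[i, j] = h[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                        2 * step**2
                    )
            try:
                cov_theta = np.linalg.inv(h)
            except np.linalg.LinAlgError:
                cov_theta = np.linalg.pinv(h)
            jd = par.jacobian_diag(self.theta)
            self._cov_params = cov_theta * np.outer(jd, jd)
        return self._cov_params

    def bse(self) -> dict[str, float]:
        cov = self.cov_params()
        d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return dict(zip(self.model.parameterization.names, d))

    def conf_int(self, name: str, level: float = 0.95, method: str = "delta") -> tuple[float, float]:
        """CI for one parameter; ``method`` is ``delta`` or ``profile``."""
        if method == "profile":
            return self._profile_ci(name, level)
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = self.params[name]
        se = self.bse()[name]
        return est - z * se, est + z * se

    def _profile_fixed(self, name: str, value: float) -> float:
        """Deviance re-minimized over all other parameters."""
        par = self.model.parameterization
        i = par.names.index(name)
        kind = par.kinds[name]
        if kind == "log":
            fixed = np.log(max(value, 1e-12))
        elif kind == "atanh":
            fixed = np.arctanh(np.clip(value, -0.9999, 0.9999))
        else:
            fixed = value
        free_idx = [j for j in range(par.k) if j != i]

        def obj(sub: np.ndarray) -> float:
            theta = self.theta.copy()
            theta[free_idx] = sub
            theta[i] = fixed
            return self.model._objective(theta)

        res = optimize.minimize(obj, self.theta[free_idx], method="L-BFGS-B",
                                options={"maxiter": 500})
        return float(res.fun)

    def _profile_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Profile-likelihood CI: deviance rise of chi2(1) at ``level``."""
        cutoff = stats.chi2.ppf(level, 1)
        target = self.minus2ll + cutoff
        est = self.params[name]
        se = self.bse()[name]
        if not np.isfinite(se) or se <= 0:
            se = max(abs(est), 0.1)
        bounds = []
        for direction in (-1.0, 1.0):
            g = lambda v: self._profile_fixed(name, v) - target
            step = direction * se
            lo_v = est
            hi_v = est + 2.0 * step
            val = g(hi_v)
            n_expand = 0
            while val < 0 and n_expand < 8:
                lo_v = hi_v
                hi_v = hi_v + 2.0 * step
                val = g(hi_v)
                n_expand += 1
            if val < 0:
                warnings.warn(f"profile CI for {name}: bound not bracketed; delta fallback")
                z = stats.norm.ppf(0.5 + level / 2.0)
                bounds.append(est + direction * z * se)
                continue
            a, b = sorted((lo_v, hi_v))
            bounds.append(optimize.brentq(g, a, b, xtol=1e-5))
        return min(bounds), max(bounds)

    # -- derived quantities -------------------------------------------------

    def variance_components(self, phenotype: str) -> VarianceComponents:
        p = self.params
        return VarianceComponents(
            var_a=p[f"var_A_{phenotype}"],
            var_c=p[f"var_C_{phenotype}"],
            var_e=p[f"var_E_{phenotype}"],
            var_s=p.get(f"var_S_{phenotype}", 0.0),
        )

    def variance_proportions(self, level: float = 0.95) -> pd.DataFrame:
        """Table of VA/VC/VE/VS proportions per phenotype with delta CIs."""
        rows = []
        names = self.model.parameterization.names
        cov = self.cov_params()
        comp_keys = ("A", "C", "E", "S")
        z = stats.norm.ppf(0.5 + level / 2.0)
        for ph in self.model.spec.phenotypes:
            vc = self.variance_components(ph)
            props = standardize_components(vc)
            v = np.array([vc.var_a, vc.var_c, vc.var_e, vc.var_s])
            tot = v.sum()
            idx = []
            for comp in comp_keys:
                nm = f"var_{comp}_{ph}"
                idx.append(names.index(nm) if nm in names else -1)
            sub = np.zeros((4, 4))
            for i, ii in enumerate(idx):
                for j, jj in enumerate(idx):
                    if ii >= 0 and jj >= 0:
                        sub[i, j] = cov[ii, jj]
            row = {"phenotype": ph}
            for i, comp in enumerate(comp_keys):
                # gradient of v_i / sum(v) wrt v
                grad = -v[i] / tot**2 * np.ones(4)
                grad[i] += 1.0 / tot
                se = float(np.sqrt(max(grad @ sub @ grad, 0.0)))
                est = props[f"V{comp}"]
                row[f"V{comp}"] = est
                row[f"V{comp}_lb"] = est - z * se
                row[f"V{comp}_ub"] = est + z * se
            rows.append(row)
        return pd.DataFrame(rows)

    def indirect_effects(self, level: float = 0.95) -> pd.DataFrame:
        """Per-mediator a*b products with delta-method CIs (Table-2 shape)."""
        names = self.model.parameterization.names
        cov = self.cov_params()
        p = self.params
        rows = []
        for m in self.model.spec.mediators:
            an, bn = f"a_{m}", f"b_{m}"
            if an not in names or bn not in names:
                continue
            ia, ib = names.index(an), names.index(bn)
            est, lo, hi = indirect_effect(
                p[an], p[bn], var_a=cov[ia, ia], var_b=cov[ib, ib],
                cov_ab=cov[ia, ib], level=level,
            )
            rows.append({"mediator": m, "lower": lo, "estimate": est, "upper": hi})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Multilevel A/C/E/S mediation model (FIML)",
            f"  variant: {self.model.spec.variant}",
            f"  phenotypes: {', '.join(self.model.spec.phenotypes)}",
            f"  -2lnL: {self.minus2ll:.3f}   ep: {self.ep}   df: {self.df}   AIC: {self.aic:.3f}",
            f"  converged: {self.converged}   |grad|: {self.grad_norm:.3g}",
            "",
            f"  {'parameter':<24}{'estimate':>12}",
        ]
        for name, val in self.params.items():
            lines.append(f"  {name:<24}{val:>12.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# module-level operations


def fiml_neg2ll(
    spec: PathModelSpec,
    data: pd.DataFrame,
    components: dict[str, VarianceComponents],
    paths: dict[str, float] | None = None,
    means: dict[str, float] | None = None,
    contralateral: dict[str, float] | None = None,
    **model_kw,
) -> float:
    """FIML -2 log L of ``data`` at fixed natural-scale parameters."""
    model = BiometricMediationModel(data, spec, **model_kw)
    params: dict[str, float] = {}
    for ph, vc in components.items():
        params[f"var_A_{ph}"] = vc.var_a
        params[f"var_C_{ph}"] = vc.var_c
        params[f"var_E_{ph}"] = vc.var_e
        params[f"var_S_{ph}"] = vc.var_s
    for ph in spec.phenotypes:
        params[f"mean_{ph}"] = (means or {}).get(ph, 0.0)
    params.update(paths or {})
    params.update(contralateral or {})
    return model.neg2loglik(params)


def fit_ml(
    spec: PathModelSpec,
    data: pd.DataFrame,
    n_starts: int = 5,
    seed: int = 0,
    **kw,
) -> BiometricResults:
    """Convenience wrapper: build the model and fit by FIML."""
    return BiometricMediationModel(data, spec).fit(n_starts=n_starts, seed=seed, **kw)


def penalized_path_fit(
    spec: PathModelSpec,
    data: pd.DataFrame,
    lam: float,
    alpha: float = 0.5,
    **kw,
) -> BiometricResults:
    """Convenience wrapper for the elastic-net-penalized path fit."""
    return BiometricMediationModel(data, spec).fit_penalized(lam=lam, alpha=alpha, **kw)


def indirect_effect(
    a: float,
    b: float,
    var_a: float | None = None,
    var_b: float | None = None,
    cov_ab: float = 0.0,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Indirect (mediated) effect a*b with a first-order delta-method CI.

    Returns ``(estimate, lower, upper)``; without variances the CI collapses
    to the estimate.
    """
    est = a * b
    if var_a is None or var_b is None:
        return est, est, est
    var = b**2 * var_a + a**2 * var_b + 2.0 * a * b * cov_ab
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return est, est - z * se, est + z * se


def standardize_components(vc: VarianceComponents) -> dict[str, float]:
    """VA/VC/VE/VS proportions: each component over the component sum."""
    return vc.proportions()


# ---------------------------------------------------------------------------
# saturated-model twin correlations


@dataclass
class TwinCorrelations:
    """Cross-twin and cross-trait correlations per zygosity group.

    ``mz``/``dz`` are (2p x 2p) correlation matrices over the stacked
    (twin-1, twin-2) trait vectors; ``mz_ci``/``dz_ci`` hold Fisher-z 95%
    intervals.  ``combined()`` formats the conventional triangular layout
    (MZ below the diagonal, DZ above).
    """

    labels: list[str]
    mz: pd.DataFrame
    dz: pd.DataFrame
    mz_ci: pd.DataFrame
    dz_ci: pd.DataFrame
    n_mz: int
    n_dz: int

    def combined(self) -> pd.DataFrame:
        out = self.mz.copy()
        iu = np.triu_indices(len(out), k=1)
        vals = out.to_numpy()
        vals[iu] = self.dz.to_numpy()[iu]
        return pd.DataFrame(vals, index=out.index, columns=out.columns)


def _fisher_ci(r: np.ndarray, n: int, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zr = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(max(n - 3, 1))
    return np.tanh(zr - z * se), np.tanh(zr + z * se)


def twin_saturated_correlations(
    data: pd.DataFrame,
    phenotypes: list[str],
    family_col: str = "family_id",
    relation_col: str = "relation",
    min_pairs: int = 3,
) -> TwinCorrelations:
    """ML correlations of the stacked twin-pair vectors per zygosity group.

    With complete data the saturated-model ML estimates coincide with the
    sample product-moment correlations, which is what is computed here on
    complete pairs; groups with fewer than ``min_pairs`` pairs yield NaN
    entries and a warning.
    """
    p = len(phenotypes)
    labels = [f"{ph}_T1" for ph in phenotypes] + [f"{ph}_T2" for ph in phenotypes]
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame, int]] = {}
    for zyg in ("MZ", "DZ"):
        sub = data[data[relation_col] == zyg]
        stacked = []
        for _, fam in sub.groupby(family_col):
            if len(fam) != 2:
                continue
            row = np.concatenate([fam.iloc[0][phenotypes].to_numpy(dtype=float),
                                  fam.iloc[1][phenotypes].to_numpy(dtype=float)])
            if np.all(np.isfinite(row)):
                stacked.append(row)
        n = len(stacked)
        if n < min_pairs:
            warnings.warn(f"{zyg} group has {n} complete pairs (<{min_pairs}); entries set NaN")
            corr = np.full((2 * p, 2 * p), np.nan)
            ci = np.full((2 * p, 2 * p), np.nan, dtype=object)
        else:
            arr = np.vstack(stacked)
            corr = np.corrcoef(arr, rowvar=False)
            lo, hi = _fisher_ci(corr, n)
            ci = np.empty((2 * p, 2 * p), dtype=object)
            for i in range(2 * p):
                for j in range(2 * p):
                    ci[i, j] = (float(lo[i, j]), float(hi[i, j]))
        out[zyg] = (
            pd.DataFrame(corr, index=labels, columns=labels),
            pd.DataFrame(ci, index=labels, columns=labels),
            n,
        )
    return TwinCorrelations(
        labels=labels,
        mz=out["MZ"][0], dz=out["DZ"][0],
        mz_ci=out["MZ"][1], dz_ci=out["DZ"][1],
        n_mz=out["MZ"][2], n_dz=out["DZ"][2],
    )
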