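"""Two-site additive + dominance linear mixed models fitted by AI-REML.

The model for a tree's phenotype is

    y = X beta + Z_b b(s) [+ Z_p p(s)] + Z_a a(s) + Z_d d(s) + e

with fixed overall mean and site effect; independent block-within-site
(and optionally plot-within-site) effects with heterogeneous per-site
variances; site-specific additive and dominance genetic effects with
covariances Va (x) K_a and Vd (x) K_d, where Va/Vd are 2x2 CORH matrices
(per-site variances sigma2_S1, sigma2_S2 plus one between-site correlation
r) and K_a/K_d are pedigree (A, D) or blended genomic (Ga, Gd) relationship
matrices; and heterogeneous per-site residuals.

Estimation is average-information REML on transformed parameters
(log-variances, scaled-atanh correlations) with step-halving and a
gradient-step fallback, then BLUP solution of the genetic effects at the
estimated components.  The restricted likelihood is exposed publicly
(``reml_loglik``, ``restricted_loglik``) so an independent derivative-free
optimizer can serve as an oracle for the fitted optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .containers import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "ModelFit",
    "GeneticValues",
    "ModelData",
    "restricted_loglik",
    "reml_loglik",
    "reml_fit",
    "solve_blups",
]

_CORR_BOUND = 0.999


@dataclass
class ModelSpec:
    """Which terms the model carries and which relationship matrices it uses.

    ``method`` is "ablup" (pedigree A/D) or "gblup" (blended genomic
    matrices); ``use_plot`` adds the plot-within-site term present in
    row-plot designs and absent from post-block-only designs.
    """

    method: str = "gblup"
    use_plot: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("ablup", "gblup"):
            raise ValueError("method must be 'ablup' or 'gblup'")


@dataclass
class VarianceComponents:
    """Per-site variance components and between-site genetic correlations."""

    block: tuple[float, float]
    additive: tuple[float, float]
    r_a: float
    dominance: tuple[float, float]
    r_d: float
    residual: tuple[float, float]
    plot: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for r in (self.r_a, self.r_d):
            if not -1.0 <= r <= 1.0:
                raise ValueError("genetic correlations must lie in [-1, 1]")

    def Va(self) -> np.ndarray:
        s1, s2 = self.additive
        c = self.r_a * np.sqrt(s1 * s2)
        return np.array([[s1, c], [c, s2]])

    def Vd(self) -> np.ndarray:
        s1, s2 = self.dominance
        c = self.r_d * np.sqrt(s1 * s2)
        return np.array([[s1, c], [c, s2]])

    def as_dict(self) -> dict[str, float]:
        out = {
            "block_S1": self.block[0], "block_S2": self.block[1],
            "additive_S1": self.additive[0], "additive_S2": self.additive[1],
            "r_a": self.r_a,
            "dominance_S1": self.dominance[0], "dominance_S2": self.dominance[1],
            "r_d": self.r_d,
            "residual_S1": self.residual[0], "residual_S2": self.residual[1],
        }
        if self.plot is not None:
            out["plot_S1"], out["plot_S2"] = self.plot
        return {k: float(v) for k, v in out.items()}


@dataclass
class ModelFit:
    """REML solution: components, likelihood, convergence, AI matrix."""

    components: VarianceComponents
    loglik: float
    beta: np.ndarray
    beta_names: list[str]
    converged: bool
    n_iter: int
    ai_matrix: np.ndarray  # average information, raw-component scale
    param_names: list[str]
    pinned: list[str] = field(default_factory=list)
    trace: list[float] = field(default_factory=list)

    def reported_components(self) -> dict[str, float]:
        """Component dict with boundary-pinned entries reported as 0.00."""
        out = self.components.as_dict()
        for name in self.pinned:
            out[name] = 0.0
        return out


@dataclass
class GeneticValues:
    """Site-specific BLUPs per genotype: EBV, EDV and their sum EGV."""

    table: pd.DataFrame  # genotype, site, ebv, edv, egv, home_site

    def at_home_site(self) -> pd.DataFrame:
        t = self.table
        return t[t["site"] == t["home_site"]].reset_index(drop=True)


class ModelData:
    """Phenotypes + design structure + relationship matrices, prepared for
    repeated likelihood evaluation.

    Builds the constant n x n structure matrices that make V(theta) a linear
    combination with scalar coefficients, so each REML iteration costs one
    dense factorization plus cheap contractions.  Block and plot labels are
    nested-coded (site:block, site:block:plot) so identical labels across
    sites never alias.
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        K_additive: RelationshipMatrix,
        K_dominance: RelationshipMatrix,
        spec: ModelSpec,
        response: str = "y",
    ) -> None:
        required = {"genotype", "site", "block", response}
        missing = required - set(phenotypes.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if spec.use_plot and "plot" not in phenotypes.columns:
            raise ValueError("use_plot=True requires a 'plot' column")
        df = phenotypes.reset_index(drop=True)
        self.spec = spec
        self.df = df
        self.y = df[response].to_numpy(dtype=float)
        if np.isnan(self.y).any():
            raise ValueError("phenotypes contain missing values; drop those rows")
        self.n = len(df)

        sites = sorted(df["site"].unique())
        if len(sites) != 2:
            raise ValueError(f"exactly two sites required, found {sites}")
        self.sites = sites
        site_idx = df["site"].map({sites[0]: 0, sites[1]: 1}).to_numpy()
        self.site_idx = site_idx

        for s in (0, 1):
            if (site_idx == s).sum() < 2:
                raise ValueError(f"site {sites[s]} has fewer than 2 records")
            if df.loc[site_idx == s, "genotype"].nunique() < 2:
                raise ValueError(f"site {sites[s]} has fewer than 2 genotypes")

        # fixed effects: overall mean + site contrast
        self.X = np.column_stack([np.ones(self.n), (site_idx == 1).astype(float)])
        self.beta_names = ["mean", f"site[{sites[1]}]"]

        self.genotype_ids = list(dict.fromkeys(df["genotype"]))
        gmap = {g: i for i, g in enumerate(self.genotype_ids)}
        self.geno_idx = df["genotype"].map(gmap).to_numpy()
        self.Ka = K_additive.align(self.genotype_ids)
        self.Kd = K_dominance.align(self.genotype_ids)
        self.K_additive = K_additive
        self.K_dominance = K_dominance

        # home site per genotype (site of its field records)
        home = df.groupby("genotype", sort=False)["site"].first()
        self.home_site = home.to_dict()

        def grouping(labels: pd.Series) -> np.ndarray:
            codes = labels.astype("category").cat.codes.to_numpy()
            Z = np.zeros((self.n, codes.max() + 1))
            Z[np.arange(self.n), codes] = 1.0
            return Z @ Z.T

        s_mask = [(site_idx == s).astype(float) for s in (0, 1)]
        structures: dict[str, np.ndarray] = {}
        nested_block = df["site"].astype(str) + ":" + df["block"].astype(str)
        BB = grouping(nested_block)
        structures["block_S1"] = BB * np.outer(s_mask[0], s_mask[0])
        structures["block_S2"] = BB * np.outer(s_mask[1], s_mask[1])
        if spec.use_plot:
            nested_plot = nested_block + ":" + df["plot"].astype(str)
            PP = grouping(nested_plot)
            structures["plot_S1"] = PP * np.outer(s_mask[0], s_mask[0])
            structures["plot_S2"] = PP * np.outer(s_mask[1], s_mask[1])

        Kobs_a = self.Ka[np.ix_(self.geno_idx, self.geno_idx)]
        Kobs_d = self.Kd[np.ix_(self.geno_idx, self.geno_idx)]
        for tag, Kobs in (("a", Kobs_a), ("d", Kobs_d)):
            structures[f"{tag}_11"] = Kobs * np.outer(s_mask[0], s_mask[0])
            structures[f"{tag}_22"] = Kobs * np.outer(s_mask[1], s_mask[1])
            cross = np.outer(s_mask[0], s_mask[1])
            structures[f"{tag}_12"] = Kobs * (cross + cross.T)
        structures["residual_S1"] = np.diag(s_mask[0])
        structures["residual_S2"] = np.diag(s_mask[1])
        self.structures = structures

        # raw parameter order
        names = ["block_S1", "block_S2"]
        if spec.use_plot:
            names += ["plot_S1", "plot_S2"]
        names += ["additive_S1", "additive_S2", "r_a",
                  "dominance_S1", "dominance_S2", "r_d",
                  "residual_S1", "residual_S2"]
        self.param_names = names
        self.var_y = float(np.var(self.y, ddof=1))
        self.var_floor = max(1e-10, 1e-8 * self.var_y)

    # ---- parameter plumbing -------------------------------------------------

    def components_to_theta(self, c: VarianceComponents) -> np.ndarray:
        vals = {**c.as_dict()}
        out = []
        for name in self.param_names:
            v = vals[name]
            out.append(v)
        return np.asarray(out, dtype=float)

    def theta_to_components(self, theta: np.ndarray) -> VarianceComponents:
        d = dict(zip(self.param_names, theta))
        return VarianceComponents(
            block=(d["block_S1"], d["block_S2"]),
            plot=(d["plot_S1"], d["plot_S2"]) if self.spec.use_plot else None,
            additive=(d["additive_S1"], d["additive_S2"]),
            r_a=float(np.clip(d["r_a"], -1.0, 1.0)),
            dominance=(d["dominance_S1"], d["dominance_S2"]),
            r_d=float(np.clip(d["r_d"], -1.0, 1.0)),
            residual=(d["residual_S1"], d["residual_S2"]),
        )

    def _coefficients(self, theta: np.ndarray) -> dict[str, float]:
        """Scalar multiplier of each structure matrix under raw theta."""
        d = dict(zip(self.param_names, theta))
        coefs = {
            "block_S1": d["block_S1"], "block_S2": d["block_S2"],
            "residual_S1": d["residual_S1"], "residual_S2": d["residual_S2"],
            "a_11": d["additive_S1"], "a_22": d["additive_S2"],
            "a_12": d["r_a"] * np.sqrt(d["additive_S1"] * d["additive_S2"]),
            "d_11": d["dominance_S1"], "d_22": d["dominance_S2"],
            "d_12": d["r_d"] * np.sqrt(d["dominance_S1"] * d["dominance_S2"]),
        }
        if self.spec.use_plot:
            coefs["plot_S1"] = d["plot_S1"]
            coefs["plot_S2"] = d["plot_S2"]
        return coefs

    def _coefficient_jacobian(self, theta: np.ndarray) -> dict[str, dict[str, float]]:
        """d coef / d raw-parameter, for score and AI assembly."""
        d = dict(zip(self.param_names, theta))
        sa1, sa2, ra = d["additive_S1"], d["additive_S2"], d["r_a"]
        sd1, sd2, rd = d["dominance_S1"], d["dominance_S2"], d["r_d"]
        jac: dict[str, dict[str, float]] = {
            name: {name: 1.0}
            for name in self.param_names if name not in (
                "additive_S1", "additive_S2", "r_a",
                "dominance_S1", "dominance_S2", "r_d",
            )
        }
        ga = np.sqrt(max(sa1 * sa2, 1e-300))
        gd = np.sqrt(max(sd1 * sd2, 1e-300))
        jac["additive_S1"] = {"a_11": 1.0, "a_12": 0.5 * ra * sa2 / ga}
        jac["additive_S2"] = {"a_22": 1.0, "a_12": 0.5 * ra * sa1 / ga}
        jac["r_a"] = {"a_12": ga}
        jac["dominance_S1"] = {"d_11": 1.0, "d_12": 0.5 * rd * sd2 / gd}
        jac["dominance_S2"] = {"d_22": 1.0, "d_12": 0.5 * rd * sd1 / gd}
        jac["r_d"] = {"d_12": gd}
        return jac

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        coefs = self._coefficients(theta)
        V = np.zeros((self.n, self.n))
        for key, c in coefs.items():
            if c != 0.0:
                V += c * self.structures[key]
        return V


def restricted_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood -0.5*(log|V| + log|X'V^-1 X| + y'Py),
    constant dropped.  Low-level evaluator shared by all model variants."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    c = cho_factor(V, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    XtViX = X.T @ Vi_X
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X singular: confounded fixed effects")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * (logdet_V + logdet_X + yPy)


def reml_loglik(components: VarianceComponents, data: ModelData) -> float:
    """Restricted log-likelihood of the two-site model at given components."""
    theta = data.components_to_theta(components)
    return restricted_loglik(data.y, data.X, data.build_V(theta))


# ---- transformed-scale optimization -----------------------------------------


def _to_transformed(data: ModelData, theta: np.ndarray) -> np.ndarray:
    t = np.empty_like(theta)
    for i, name in enumerate(data.param_names):
        if name in ("r_a", "r_d"):
            r = np.clip(theta[i] / _CORR_BOUND, -1 + 1e-10, 1 - 1e-10)
            t[i] = np.arctanh(r)
        else:
            t[i] = np.log(max(theta[i], data.var_floor))
    return t


def _to_raw(data: ModelData, t: np.ndarray) -> np.ndarray:
    theta = np.empty_like(t)
    for i, name in enumerate(data.param_names):
        if name in ("r_a", "r_d"):
            theta[i] = _CORR_BOUND * np.tanh(t[i])
        else:
            theta[i] = np.exp(t[i])
    return theta


def _transform_jacobian(data: ModelData, t: np.ndarray) -> np.ndarray:
    """d raw / d transformed (diagonal)."""
    jac = np.empty_like(t)
    for i, name in enumerate(data.param_names):
        if name in ("r_a", "r_d"):
            jac[i] = _CORR_BOUND * (1.0 - np.tanh(t[i]) ** 2)
        else:
            jac[i] = np.exp(t[i])
    return jac


def _score_and_ai(data: ModelData, theta: np.ndarray):
    """Restricted loglik, score vector and average-information matrix in the
    raw-component scale at theta."""
    V = data.build_V(theta)
    c = cho_factor(V, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Vi = cho_solve(c, np.eye(data.n))
    Vi_X = Vi @ data.X
    XtViX = data.X.T @ Vi_X
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vi - Vi_X @ XtViX_inv @ Vi_X.T
    Py = P @ data.y
    sign, logdet_X = np.linalg.slogdet(XtViX)
    loglik = -0.5 * (logdet_V + logdet_X + float(data.y @ Py))

    jac = data._coefficient_jacobian(theta)
    # per-structure contractions
    trP = {k: float(np.sum(P * M)) for k, M in data.structures.items()}
    w = {k: M @ Py for k, M in data.structures.items()}
    p = len(data.param_names)
    score = np.zeros(p)
    W = np.zeros((data.n, p))
    for i, name in enumerate(data.param_names):
        tr = 0.0
        quad = 0.0
        wi = np.zeros(data.n)
        for key, dc in jac[name].items():
            tr += dc * trP[key]
            quad += dc * float(Py @ w[key])
            wi += dc * w[key]
        score[i] = -0.5 * (tr - quad)
        W[:, i] = wi
    AI = 0.5 * (W.T @ (P @ W))
    return loglik, score, AI, P, Py, XtViX_inv, Vi_X


def _default_start(data: ModelData) -> VarianceComponents:
    """Half the phenotypic variance split equally among the genetic terms,
    correlations at 0.5; small block/plot, remainder residual."""
    v = data.var_y
    g = 0.25 * v
    small = 0.05 * v
    n_design = 1 + (1 if data.spec.use_plot else 0)
    resid = max(v - 2 * g - n_design * small, 0.1 * v)
    return VarianceComponents(
        block=(small, small),
        plot=(small, small) if data.spec.use_plot else None,
        additive=(g, g),
        r_a=0.5,
        dominance=(g, g),
        r_d=0.5,
        residual=(resid, resid),
    )


def reml_fit(
    data: ModelData,
    start: VarianceComponents | None = None,
    max_iter: int = 100,
    loglik_tol: float = 1e-6,
    grad_tol: float = 1e-3,
    restarts: bool = True,
) -> ModelFit:
    """Average-information REML on transformed parameters.

    AI (quasi-Newton) updates with an active set for floor-pinned
    components, step halving, and an L-BFGS polish with the analytic
    gradient for boundary cases.  The restricted likelihood can be
    multimodal in the sign of a type-B correlation when the paired genetic
    variance is near zero, so when a fit ends at a correlation bound or a
    pinned genetic variance, ``restarts`` triggers refits from
    flipped-correlation starting values and the best optimum is kept
    (disable for warm-started refits).  Components driven to the variance
    floor are pinned and reported as 0.00.
    """
    fit = _reml_fit_once(data, start, max_iter, loglik_tol, grad_tol)
    if not restarts:
        return fit
    c = fit.components
    flip_a = abs(c.r_a) > 0.95 or {"additive_S1", "additive_S2"} & set(fit.pinned)
    flip_d = abs(c.r_d) > 0.95 or {"dominance_S1", "dominance_S2"} & set(fit.pinned)
    base = start or _default_start(data)
    trials: list[VarianceComponents] = []
    if flip_a:
        trials.append(replace(base, r_a=-np.sign(c.r_a or 1.0) * 0.5))
    if flip_d:
        trials.append(replace(base, r_d=-np.sign(c.r_d or 1.0) * 0.5))
    if flip_a and flip_d:
        trials.append(
            replace(base, r_a=-np.sign(c.r_a or 1.0) * 0.5,
                    r_d=-np.sign(c.r_d or 1.0) * 0.5)
        )
    for alt_start in trials:
        alt = _reml_fit_once(data, alt_start, max_iter, loglik_tol, grad_tol)
        if alt.loglik > fit.loglik + 1e-10:
            fit = alt
    return fit


def _reml_fit_once(
    data: ModelData,
    start: VarianceComponents | None = None,
    max_iter: int = 100,
    loglik_tol: float = 1e-6,
    grad_tol: float = 1e-3,
) -> ModelFit:
    start = start or _default_start(data)
    t = _to_transformed(data, data.components_to_theta(start))
    # keep transformed variances in a numerically safe box
    lo = np.log(data.var_floor)
    hi = np.log(1e6 * max(data.var_y, 1e-12))

    def clamp(tv: np.ndarray) -> np.ndarray:
        out = tv.copy()
        for i, name in enumerate(data.param_names):
            if name in ("r_a", "r_d"):
                out[i] = np.clip(out[i], -8.0, 8.0)
            else:
                out[i] = np.clip(out[i], lo, hi)
        return out

    t = clamp(t)
    loglik, score, AI, *_ = _score_and_ai(data, _to_raw(data, t))
    trace = [loglik]
    converged = False
    it = 0

    def free_mask(tv: np.ndarray, score_t: np.ndarray) -> np.ndarray:
        """Active set: drop parameters sitting on the variance floor whose
        gradient points further out — their transformed rows of the AI
        matrix are numerically zero and corrupt the Newton direction."""
        free = np.ones(len(tv), dtype=bool)
        for i, name in enumerate(data.param_names):
            if name in ("r_a", "r_d"):
                continue
            if tv[i] <= lo + 1e-6 and score_t[i] <= 0.0:
                free[i] = False
        return free

    for it in range(1, max_iter + 1):
        J = _transform_jacobian(data, t)
        score_t = J * score
        AI_t = (AI * J[None, :]) * J[:, None]
        free = free_mask(t, score_t)
        delta = np.zeros(len(t))
        if free.any():
            sub = AI_t[np.ix_(free, free)]
            ridge = 1e-8 * max(1.0, float(np.trace(sub)) / int(free.sum()))
            try:
                delta[free] = np.linalg.solve(
                    sub + ridge * np.eye(int(free.sum())), score_t[free]
                )
            except np.linalg.LinAlgError:
                delta[free] = score_t[free]
        max_step = float(np.abs(delta).max())
        if max_step > 5.0:
            delta *= 5.0 / max_step

        improved = False
        gain = 0.0
        step = 1.0
        for _ in range(15):
            t_new = clamp(t + step * delta)
            try:
                out = _score_and_ai(data, _to_raw(data, t_new))
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if out[0] > loglik + 1e-12:
                gain = out[0] - loglik
                t, loglik, score, AI = t_new, out[0], out[1], out[2]
                trace.append(loglik)
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        J = _transform_jacobian(data, t)
        score_masked = (J * score)[free_mask(t, J * score)]
        grad_norm = float(np.abs(score_masked).max()) if score_masked.size else 0.0
        if gain < loglik_tol and grad_norm < grad_tol:
            converged = True
            break

    # quasi-Newton polish with the analytic gradient whenever the AI loop
    # stops short of the gradient tolerance (typically boundary cases)
    J = _transform_jacobian(data, t)
    score_t = J * score
    masked = score_t[free_mask(t, score_t)]
    if masked.size and float(np.abs(masked).max()) >= grad_tol:
        from scipy.optimize import minimize

        cache: dict = {}

        def fun_and_jac(tv: np.ndarray):
            tv = clamp(tv)
            key = tv.tobytes()
            if key not in cache:
                try:
                    ll, sc, _ = _score_and_ai(data, _to_raw(data, tv))[:3]
                except np.linalg.LinAlgError:
                    return 1e10, np.zeros(len(tv))
                cache[key] = (-ll, -(_transform_jacobian(data, tv) * sc))
            return cache[key]

        bounds = [
            (-8.0, 8.0) if name in ("r_a", "r_d") else (lo, hi)
            for name in data.param_names
        ]
        res = minimize(fun_and_jac, t, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 200, "ftol": 1e-12})
        if -res.fun > loglik:
            t = clamp(res.x)
            loglik, score, AI = _score_and_ai(data, _to_raw(data, t))[:3]
            trace.append(loglik)
        J = _transform_jacobian(data, t)
        score_t = J * score
        masked = score_t[free_mask(t, score_t)]
        if not masked.size or float(np.abs(masked).max()) < 10 * grad_tol:
            converged = True

    theta = _to_raw(data, t)
    loglik, score, AI, P, Py, XtViX_inv, Vi_X = _score_and_ai(data, theta)
    beta = XtViX_inv @ (Vi_X.T @ data.y)
    components = data.theta_to_components(theta)
    pinned = [
        name for name, v in zip(data.param_names, theta)
        if name not in ("r_a", "r_d") and v <= 2.0 * data.var_floor
    ]
    return ModelFit(
        components=components,
        loglik=float(loglik),
        beta=beta,
        beta_names=list(data.beta_names),
        converged=converged,
        n_iter=it,
        ai_matrix=AI,
        param_names=list(data.param_names),
        pinned=pinned,
        trace=trace,
    )


def solve_blups(
    fit: ModelFit, data: ModelData, force: bool = False
) -> tuple[GeneticValues, pd.DataFrame]:
    """BLUPs of the genetic effects (both sites, every genotype) plus
    block/plot effect predictions, at the fitted components.

    u_hat = Cov(u, y) V^-1 (y - X beta) evaluated through P y; for the
    additive term Cov(a_gs, y_i) = Va[s, s_i] * K_a[g, g_i], so the BLUP at
    site s is K_a @ t_s with t_s accumulating Va-weighted P-residuals per
    genotype.  EGV = EBV + EDV holds exactly by construction.
    """
    if not (fit.converged or force):
        raise ValueError("fit did not converge; pass force=True to solve anyway")
    theta = data.components_to_theta(fit.components)
    _, _, _, P, Py, _, _ = _score_and_ai(data, theta)

    Va = fit.components.Va()
    Vd = fit.components.Vd()
    n_g = len(data.genotype_ids)

    def genetic_blup(K: np.ndarray, Vmat: np.ndarray) -> np.ndarray:
        out = np.zeros((n_g, 2))
        for s in (0, 1):
            wts = Vmat[s, data.site_idx] * Py
            t_s = np.zeros(n_g)
            np.add.at(t_s, data.geno_idx, wts)
            out[:, s] = K @ t_s
        return out

    ebv = genetic_blup(data.Ka, Va)
    edv = genetic_blup(data.Kd, Vd)

    rows = []
    for s in (0, 1):
        for i, g in enumerate(data.genotype_ids):
            rows.append(
                {
                    "genotype": g,
                    "site": data.sites[s],
                    "ebv": ebv[i, s],
                    "edv": edv[i, s],
                    "egv": ebv[i, s] + edv[i, s],
                    "home_site": data.home_site[g],
                }
            )
    values = GeneticValues(table=pd.DataFrame(rows))

    # design-effect predictions: sigma^2 * Z' P y per nested level
    design_rows = []
    comp = fit.components.as_dict()
    terms = [("block", data.df["site"].astype(str) + ":" + data.df["block"].astype(str))]
    if data.spec.use_plot:
        terms.append(
            ("plot", data.df["site"].astype(str) + ":" + data.df["block"].astype(str)
             + ":" + data.df["plot"].astype(str))
        )
    for term, labels in terms:
        for level in labels.unique():
            mask = (labels == level).to_numpy()
            s = data.site_idx[mask][0]
            var = comp[f"{term}_S{s + 1}"]
            design_rows.append(
                {"term": term, "level": level, "site": data.sites[s],
                 "blup": float(var * Py[mask].sum())}
            )
    return values, pd.DataFrame(design_rows)


def predict_genetic_values(
    fit: ModelFit, data: ModelData, genotype_ids: list[str]
) -> pd.DataFrame:
    """Site-specific EBV/EDV/EGV for arbitrary genotypes covered by the
    relationship matrices — including genotypes with no phenotype records,
    whose predictions flow purely through kinship with the observed ones."""
    theta = data.components_to_theta(fit.components)
    _, _, _, P, Py, _, _ = _score_and_ai(data, theta)
    Va = fit.components.Va()
    Vd = fit.components.Vd()
    n_g = len(data.genotype_ids)

    def blup(K_full: RelationshipMatrix, Vmat: np.ndarray) -> np.ndarray:
        index = {g: i for i, g in enumerate(K_full.ids)}
        rows = np.asarray([index[g] for g in genotype_ids])
        cols = np.asarray([index[g] for g in data.genotype_ids])
        K_cross = K_full.values[np.ix_(rows, cols)]
        out = np.zeros((len(genotype_ids), 2))
        for s in (0, 1):
            wts = Vmat[s, data.site_idx] * Py
            t_s = np.zeros(n_g)
            np.add.at(t_s, data.geno_idx, wts)
            out[:, s] = K_cross @ t_s
        return out

    ebv = blup(data.K_additive, Va)
    edv = blup(data.K_dominance, Vd)
    rows = []
    for s in (0, 1):
        for i, g in enumerate(genotype_ids):
            rows.append(
                {"genotype": g, "site": data.sites[s],
                 "ebv": ebv[i, s], "edv": edv[i, s],
                 "egv": ebv[i, s] + edv[i, s]}
            )
    return pd.DataFrame(rows)


def fit_model(
    phenotypes: pd.DataFrame,
    K_additive: RelationshipMatrix,
    K_dominance: RelationshipMatrix,
    spec: ModelSpec | None = None,
    start: VarianceComponents | None = None,
    response: str = "y",
    **options,
) -> tuple[ModelFit, ModelData]:
    """Convenience wrapper: prepare the data object and run AI-REML."""
    spec = spec or ModelSpec()
    data = ModelData(phenotypes, K_additive, K_dominance, spec, response=response)
    fit = reml_fit(data, start=start, **options)
    return fit, data
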