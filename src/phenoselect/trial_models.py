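"""REML mixed models for multi-environment trials.

The general model for a plot observation (trait value or the reflectance
at one wavelength) is

    y_ijsh = mu + g_i + l_j + r_js + b_jsh + gl_ij + e_ijsh

with genotype ``g`` either fixed (adjusted means / BLUEs) or random
(variance components, BLUPs, Cullis heritability); environment ``l``,
replicate-within-environment ``r``, block-within-replicate ``b`` and the
genotype-by-environment interaction ``gl`` random.

The restricted log-likelihood is maximised on the log-variance scale
with analytic gradients (L-BFGS-B, bounds [-30, 12], max 200 iterations);
a component whose log-variance sits at the lower bound is reported as 0
with a boundary flag.  Everything is dense: the intended problem sizes
are a few hundred to ~1500 plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .containers import SpectraMatrix, validate_plot_table
from .errors import (ConfigError, SingularityError,
                     UndefinedHeritabilityError)

# term name -> variance component attribute
_TERM_SIGMA = {"genotype": "sigma2_g", "environment": "sigma2_l",
               "replicate": "sigma2_r", "block": "sigma2_b",
               "gxe": "sigma2_gl"}

_COND_LIMIT = 1e10  # fixed-design condition number beyond which we call it singular

_LOG_LOWER, _LOG_UPPER = -30.0, 12.0


@dataclass
class MixedModelSpec:
    """Which effects enter the model and how genotype is treated."""

    response: str
    genotype: str = "fixed"  # "fixed" (BLUEs) or "random" (variance comps)
    random_terms: tuple = ("environment", "replicate", "block", "gxe")

    def __post_init__(self) -> None:
        if self.genotype not in ("fixed", "random"):
            raise ConfigError("genotype must be 'fixed' or 'random'")
        bad = set(self.random_terms) - set(_TERM_SIGMA) - {"genotype"}
        if bad:
            raise ConfigError(f"unknown random terms {sorted(bad)}")
        if "genotype" in self.random_terms and self.genotype == "fixed":
            raise ConfigError("genotype cannot be both fixed and random")
        if "block" in self.random_terms and "replicate" not in self.random_terms \
                and "environment" in self.random_terms:
            # blocks are labelled within replicates; allow block without
            # replicate (the within-environment variant drops replicate)
            pass

    @classmethod
    def series(cls, response: str, genotype: str = "fixed"
               ) -> "MixedModelSpec":
        return cls(response, genotype,
                   ("environment", "replicate", "block", "gxe"))

    @classmethod
    def all_random(cls, response: str) -> "MixedModelSpec":
        return cls(response, "random",
                   ("genotype", "environment", "replicate", "block", "gxe"))

    @classmethod
    def within_environment(cls, response: str) -> "MixedModelSpec":
        # single environment: no environment / replicate / GxE terms
        return cls(response, "fixed", ("block",))


@dataclass
class VarianceComponents:
    sigma2_g: float = 0.0
    sigma2_l: float = 0.0
    sigma2_r: float = 0.0
    sigma2_b: float = 0.0
    sigma2_gl: float = 0.0
    sigma2_e: float = 0.0
    converged: bool = True
    loglik: float = np.nan
    boundary: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sigma2_g", "sigma2_l", "sigma2_r", "sigma2_b",
                 "sigma2_gl", "sigma2_e")}


@dataclass
class REMLFit:
    spec: MixedModelSpec
    components: VarianceComponents
    beta: np.ndarray
    beta_names: list
    cov_beta: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    x_opt: Optional[np.ndarray] = None       # optimizer state (scaled space)
    genotype_levels: Optional[list] = None
    blup_g: Optional[np.ndarray] = None      # genotype BLUPs (random model)
    pev_g: Optional[np.ndarray] = None       # their PEV matrix


@dataclass
class GenotypeBLUEs:
    genotypes: list
    values: np.ndarray
    sed: float
    dropped_wavelengths: list = field(default_factory=list)
    raw_fallback: bool = False
    components: Optional[VarianceComponents] = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.genotypes)


@dataclass
class H2Result:
    value: float
    theta_bar: float
    clamped: bool = False


def _levels_codes(values) -> tuple[np.ndarray, list]:
    values = list(values)
    if values and isinstance(values[0], tuple):
        values = ["|".join(map(str, v)) for v in values]
    arr = np.asarray(values, dtype=object)
    levels, codes = np.unique(arr, return_inverse=True)
    return codes, list(levels)


def _active_random_terms(records: pd.DataFrame, terms: Sequence[str]
                         ) -> list[str]:
    """Drop terms that are confounded by the design at hand.

    Environment/GxE need >1 environment; replicate needs >1 replicate in
    some environment; block must be coarser than plots and finer than
    its parent stratum.
    """
    n = len(records)
    env_levels = records["environment"].nunique()
    keep = []
    for t in terms:
        if t == "genotype":
            keep.append(t)
        elif t in ("environment", "gxe"):
            if env_levels > 1:
                keep.append(t)
        elif t == "replicate":
            reps = records.groupby("environment")["replicate"].nunique()
            n_levels = len(set(zip(records["environment"],
                                   records["replicate"])))
            if reps.max() > 1 and n_levels < n:
                keep.append(t)
        elif t == "block":
            if "block" not in records.columns:
                continue
            blk = list(zip(records["environment"], records["replicate"],
                           records["block"]))
            n_blk = len(set(blk))
            n_rep = len(set(zip(records["environment"],
                                records["replicate"])))
            if n_rep < n_blk < n:
                keep.append(t)
    return keep


def _random_code_sets(records: pd.DataFrame, terms: Sequence[str]
                      ) -> dict[str, np.ndarray]:
    codes = {}
    for t in terms:
        if t == "genotype":
            codes[t] = _levels_codes(records["genotype"])[0]
        elif t == "environment":
            codes[t] = _levels_codes(records["environment"])[0]
        elif t == "replicate":
            codes[t] = _levels_codes(
                list(zip(records["environment"], records["replicate"])))[0]
        elif t == "block":
            codes[t] = _levels_codes(
                list(zip(records["environment"], records["replicate"],
                         records["block"])))[0]
        elif t == "gxe":
            codes[t] = _levels_codes(
                list(zip(records["genotype"], records["environment"])))[0]
    return codes


def check_connectivity(records: pd.DataFrame) -> int:
    """Number of connected components of the genotype-environment graph."""
    genos = {g: i for i, g in enumerate(records["genotype"].unique())}
    parent = list(range(len(genos)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for _, sub in records.groupby("environment"):
        gs = [genos[g] for g in sub["genotype"].unique()]
        for other in gs[1:]:
            ra, rb = find(gs[0]), find(other)
            if ra != rb:
                parent[rb] = ra
    return len({find(i) for i in range(len(genos))})


class _MixedProblem:
    """Precomputed design pieces reused across responses (wavelengths)."""

    def __init__(self, records: pd.DataFrame, spec: MixedModelSpec):
        validate_plot_table(records)
        if "replicate" not in records.columns:
            records = records.assign(replicate=1)
        if "block" not in records.columns:
            records = records.assign(block=1)
        self.records = records
        self.spec = spec
        self.n = len(records)
        if records["genotype"].nunique() < 2:
            raise ConfigError("need at least 2 genotypes")

        terms = _active_random_terms(records, spec.random_terms)
        self.terms = terms
        code_sets = _random_code_sets(records, terms)
        self.G_list = []
        for t in terms:
            c = code_sets[t]
            self.G_list.append((c[:, None] == c[None, :]).astype(float))

        g_codes, g_levels = _levels_codes(records["genotype"])
        self.genotype_levels = g_levels
        self.g_codes = g_codes
        if spec.genotype == "fixed":
            # cell-means coding: one column per genotype
            X = np.zeros((self.n, len(g_levels)))
            X[np.arange(self.n), g_codes] = 1.0
            self.beta_names = list(g_levels)
            if "environment" in terms and check_connectivity(records) > 1:
                raise SingularityError(
                    "design is disconnected: genotype contrasts across "
                    "environments are not estimable")
        else:
            X = np.ones((self.n, 1))
            self.beta_names = ["mu"]
        self.X = X
        self.A_g = None
        if spec.genotype == "random":
            A = np.zeros((self.n, len(g_levels)))
            A[np.arange(self.n), g_codes] = 1.0
            self.A_g = A

    # -- restricted likelihood ------------------------------------------------
    def _neg_rell(self, x: np.ndarray, y: np.ndarray):
        sig = np.exp(x)
        n, X = self.n, self.X
        V = sig[-1] * np.eye(n)
        for s, G in zip(sig[:-1], self.G_list):
            V += s * G
        try:
            L = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(x)
        Vi_y = cho_solve(L, y, check_finite=False)
        Vi_X = cho_solve(L, X, check_finite=False)
        XtViX = X.T @ Vi_X
        try:
            Lx = cho_factor(XtViX, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            raise SingularityError("singular fixed-effects system")
        XtViy = X.T @ Vi_y
        beta = cho_solve(Lx, XtViy, check_finite=False)
        yPy = float(y @ Vi_y - XtViy @ beta)
        logdetV = 2.0 * np.log(np.diag(L[0])).sum()
        logdetX = 2.0 * np.log(np.diag(Lx[0])).sum()
        nll = 0.5 * (logdetV + logdetX + yPy)

        # gradient wrt log-variances: d/dsig = 0.5 (tr(P G) - y'P G P y)
        Vi = cho_solve(L, np.eye(n), check_finite=False)
        W = Vi_X @ cho_solve(Lx, Vi_X.T, check_finite=False)
        P = Vi - W
        Py = Vi_y - Vi_X @ beta
        grad = np.empty_like(x)
        for k, G in enumerate(self.G_list):
            trPG = float((P * G).sum())
            quad = float(Py @ (G @ Py))
            grad[k] = 0.5 * (trPG - quad) * sig[k]
        grad[-1] = 0.5 * (float(np.trace(P)) - float(Py @ Py)) * sig[-1]
        self._last = (beta, XtViX, Lx, P, Py, L)
        return nll, grad

    def fit(self, y: np.ndarray, x0: Optional[np.ndarray] = None,
            fixed_sigma: Optional[dict] = None) -> REMLFit:
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ConfigError("response contains non-finite values")
        shift = float(y.mean())
        scale = float(y.std())
        k = len(self.G_list)
        comp = VarianceComponents()
        if scale < 1e-13:
            # constant response: all components zero, mean reproduced
            beta = np.linalg.lstsq(self.X, y, rcond=None)[0]
            comp.loglik = np.nan
            return REMLFit(self.spec, comp, beta, list(self.beta_names),
                           np.zeros((self.X.shape[1],) * 2), np.nan, True,
                           self.n, None, self.genotype_levels,
                           np.zeros(len(self.genotype_levels))
                           if self.A_g is not None else None,
                           np.zeros((len(self.genotype_levels),) * 2)
                           if self.A_g is not None else None)

        ys = (y - shift) / scale
        if fixed_sigma is not None:
            # evaluate at user-supplied variances (oracle / test hook)
            s2 = scale ** 2
            vals = [fixed_sigma[t] / s2 for t in self.terms]
            vals.append(fixed_sigma["residual"] / s2)
            x_fix = np.log(np.clip(vals, np.exp(_LOG_LOWER), None))

            class _Res:  # minimal stand-in for an OptimizeResult
                x = x_fix
                success = True
                status = 0
            res = _Res()
        else:
            if x0 is None:
                x0 = np.full(k + 1, np.log(1.0 / (k + 1)))
            x0 = np.clip(x0, _LOG_LOWER, _LOG_UPPER)
            res = minimize(self._neg_rell, x0, args=(ys,), jac=True,
                           method="L-BFGS-B",
                           bounds=[(_LOG_LOWER, _LOG_UPPER)] * (k + 1),
                           options={"maxiter": 200, "ftol": 1e-12,
                                    "gtol": 1e-8})
        nll, _ = self._neg_rell(res.x, ys)  # refresh self._last at optimum
        beta_s, XtViX, Lx, P, Py, L = self._last
        converged = bool(res.success) or res.status == 0
        if not np.isfinite(nll):
            converged = False

        cond = np.linalg.cond(XtViX)
        if self.spec.genotype == "fixed" and cond > _COND_LIMIT:
            raise SingularityError(
                f"fixed-effects system ill conditioned (cond={cond:.2e})")

        sig_s = np.exp(res.x)
        boundary = {}
        names = list(self.terms) + ["residual"]
        for i, name in enumerate(names):
            if res.x[i] <= _LOG_LOWER + 1e-6:
                sig_s[i] = 0.0
                boundary[name] = True
        s2 = scale ** 2
        for i, t in enumerate(self.terms):
            setattr(comp, _TERM_SIGMA[t], float(sig_s[i] * s2))
        comp.sigma2_e = float(sig_s[-1] * s2)
        comp.converged = converged
        # restricted log-likelihood on the original response scale
        loglik = float(-nll - (self.n - self.X.shape[1]) * np.log(scale))
        comp.loglik = loglik
        comp.boundary = boundary

        cov_beta = np.linalg.inv(XtViX) * s2
        # cell-means / intercept coding: every column is a mean, so the
        # standardisation shift is added back to all coefficients
        beta = beta_s * scale + shift

        blup_g = pev_g = None
        if self.A_g is not None:
            idx = self.terms.index("genotype")
            sg = sig_s[idx]
            AtPy = self.A_g.T @ Py
            blup_g = sg * AtPy * scale
            AtPA = self.A_g.T @ (P @ self.A_g)
            pev_g = (sg * np.eye(self.A_g.shape[1]) - sg * sg * AtPA) * s2

        return REMLFit(self.spec, comp, beta, list(self.beta_names),
                       cov_beta, loglik, converged, self.n, res.x,
                       self.genotype_levels, blup_g, pev_g)


def fit_reml(records: pd.DataFrame, spec: MixedModelSpec,
             x0: Optional[np.ndarray] = None,
             fixed_sigma: Optional[dict] = None) -> REMLFit:
    """Fit the mixed model by REML and return components + fixed effects.

    ``fixed_sigma`` (term name -> variance, including ``"residual"``)
    skips estimation and evaluates BLUEs/BLUPs at the given components.
    """
    if spec.response not in records.columns:
        raise ConfigError(f"response column {spec.response!r} not found")
    problem = _MixedProblem(records, spec)
    return problem.fit(records[spec.response].to_numpy(dtype=float), x0=x0,
                       fixed_sigma=fixed_sigma)


def _mean_sed(cov: np.ndarray) -> float:
    """Mean standard error of a difference over all genotype pairs."""
    d = np.diag(cov)
    q = len(d)
    if q < 2:
        return float("nan")
    vd = d[:, None] + d[None, :] - 2.0 * cov
    iu = np.triu_indices(q, k=1)
    return float(np.sqrt(np.clip(vd[iu], 0.0, None)).mean())


def estimate_blues(records: pd.DataFrame, response: str,
                   variant: str = "series",
                   x0: Optional[np.ndarray] = None) -> GenotypeBLUEs:
    """Genotype adjusted means with genotype fixed, everything else random.

    ``variant='series'`` fits the full multi-environment model;
    ``variant='within_environment'`` expects a single environment and
    drops environment, replicate and interaction terms.  An unreplicated
    within-environment dataset falls back to the raw values (one plot
    per genotype), mirroring how single-replicate trials are handled.
    """
    if variant not in ("series", "within_environment"):
        raise ConfigError(f"unknown variant {variant!r}")
    if response not in records.columns:
        raise ConfigError(f"response column {response!r} not found")
    if variant == "within_environment":
        if records["environment"].nunique() != 1:
            raise ConfigError("within_environment variant requires exactly "
                              "one environment")
        counts = records.groupby("genotype")["plot_id"].count()
        if counts.max() == 1:
            means = records.groupby("genotype")[response].mean().sort_index()
            return GenotypeBLUEs(list(means.index), means.to_numpy(),
                                 float("nan"), raw_fallback=True)
        spec = MixedModelSpec.within_environment(response)
    else:
        spec = MixedModelSpec.series(response, genotype="fixed")
    fit = fit_reml(records, spec, x0=x0)
    if not fit.converged:
        raise SingularityError(f"REML did not converge for {response!r}")
    order = np.argsort(np.asarray(fit.beta_names, dtype=object))
    values = fit.beta[order]
    cov = fit.cov_beta[np.ix_(order, order)]
    genotypes = [fit.beta_names[i] for i in order]
    out = GenotypeBLUEs(genotypes, values, _mean_sed(cov),
                        components=fit.components)
    out._x_opt = fit.x_opt  # warm-start handle for per-wavelength loops
    return out


def spectra_blues(plot_spectra: SpectraMatrix, records: pd.DataFrame,
                  variant: str = "series") -> tuple[SpectraMatrix, list]:
    """Column-wise genotype BLUEs of a plot-level spectra matrix.

    Wavelengths whose fit is singular or non-convergent are dropped from
    the output entirely (and reported), so every retained column exists
    for every genotype.  Returns ``(genotype_spectra, dropped)``.
    """
    validate_plot_table(records)
    id_to_row = {rid: i for i, rid in enumerate(plot_spectra.row_ids)}
    missing = [p for p in records["plot_id"] if p not in id_to_row]
    if missing:
        raise ConfigError(f"plots missing from spectra: {missing[:5]}")
    rows = [id_to_row[p] for p in records["plot_id"]]
    values = plot_spectra.values[rows]

    work = records.copy()
    cols = []
    dropped = []
    genotypes = None
    x_warm = None
    for j, wl in enumerate(plot_spectra.wavelengths):
        work["_wl"] = values[:, j]
        try:
            blue = estimate_blues(work, "_wl", variant=variant, x0=x_warm)
        except (SingularityError, ConfigError):
            dropped.append(float(wl))
            continue
        x_warm = getattr(blue, "_x_opt", x_warm)
        if genotypes is None:
            genotypes = blue.genotypes
        cols.append((float(wl), blue.values))
    if not cols:
        raise SingularityError("every wavelength was dropped")
    wls = np.array([w for w, _ in cols])
    mat = np.column_stack([v for _, v in cols])
    return SpectraMatrix(mat, genotypes, wls), dropped


def cullis_h2(fit: REMLFit, max_exact: int = 2000, n_pairs: int = 10000,
              seed: int = 0) -> H2Result:
    """Cullis broad-sense heritability H2 = 1 - mean_PEV_diff / (2 sigma2_g).

    Uses the exact prediction-error-variance matrix of the genotype
    BLUPs up to ``max_exact`` genotypes, a seeded random sample of
    genotype pairs beyond that.  Values outside [0, 1] are clamped with
    a flag.
    """
    if fit.pev_g is None:
        raise ConfigError("cullis_h2 requires a fit with genotype random")
    sg = fit.components.sigma2_g
    if sg <= 0:
        raise UndefinedHeritabilityError("sigma2_g is zero")
    pev = fit.pev_g
    q = pev.shape[0]
    if q <= max_exact:
        d = np.diag(pev)
        m = d[:, None] + d[None, :] - 2.0 * pev
        iu = np.triu_indices(q, k=1)
        theta = float(m[iu].mean())
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, q, n_pairs)
        j = rng.integers(0, q, n_pairs)
        ok = i != j
        i, j = i[ok], j[ok]
        theta = float(np.mean(pev[i, i] + pev[j, j] - 2 * pev[i, j]))
    h2 = 1.0 - theta / (2.0 * sg)
    clamped = not (0.0 <= h2 <= 1.0)
    if clamped:
        warnings.warn(f"Cullis H2 = {h2:.3f} outside [0, 1]; clamped")
        h2 = min(1.0, max(0.0, h2))
    return H2Result(float(h2), theta, clamped)


def summarize_trait(records: pd.DataFrame, response: str) -> dict:
    """Table-2 style summary: min/mean/max of BLUEs, SED, variance
    components and Cullis heritability.  Key order is the report schema.
    """
    blues = estimate_blues(records, response, variant="series")
    rfit = fit_reml(records, MixedModelSpec.all_random(response))
    try:
        h2 = cullis_h2(rfit).value
    except UndefinedHeritabilityError:
        h2 = float("nan")
    comp = rfit.components
    return {
        "trait": response,
        "n_environments": int(records["environment"].nunique()),
        "min": float(np.min(blues.values)),
        "mean": float(np.mean(blues.values)),
        "max": float(np.max(blues.values)),
        "sed": float(blues.sed),
        "sigma2_g": comp.sigma2_g,
        "sigma2_gl": comp.sigma2_gl,
        "sigma2_e": comp.sigma2_e,
        "h2": h2,
    }
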