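"""Climate anomalies, exponential climate-fire fits, trend tests and
piecewise structural equation modeling.

Annual summer (June-September) climate means are converted to z-score
anomalies against a long-term baseline; peat burned area relates to those
anomalies exponentially, fit as ordinary least squares on log burned area
(a log-link GLM on the untransformed response is offered as an
alternative).  Monotone trends use the Mann-Kendall test with tie-corrected
variance and the Sen median-pairwise slope.  Causal structure among climate,
fire-weather and fire nodes is assessed with a piecewise structural
equation model: each endogenous node is fitted by its own regression
(linear mixed model with a random zone intercept, or ordinary regression),
and the global graph is evaluated with Fisher's C over the d-separation
basis set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

SUMMER_MONTHS = (6, 7, 8, 9)
BASELINE = (1958, 2023)


# ---------------------------------------------------------------------------
# anomalies


@dataclass
class ClimateAnomalies:
    """Summer means and z-score anomalies per year and variable."""

    summer_means: pd.DataFrame  # indexed by year
    z_scores: pd.DataFrame      # same shape
    baseline_mean: pd.Series
    baseline_sd: pd.Series
    baseline_years: tuple[int, int]


def summer_anomalies(monthly: pd.DataFrame,
                     variables: list[str] | None = None,
                     baseline_years: tuple[int, int] = BASELINE,
                     months: tuple[int, ...] = SUMMER_MONTHS) -> ClimateAnomalies:
    """Summer-mean z-scores against the long-term baseline.

    ``monthly`` needs ``year`` and ``month`` columns plus one column per
    climate variable.  z = (x - baseline mean) / baseline sd, with the
    baseline statistics computed once per variable over the baseline years'
    summer means.  A constant baseline raises (zero sd).
    """
    if variables is None:
        variables = [c for c in monthly.columns if c not in ("year", "month")]
    y0, y1 = baseline_years
    if y1 - y0 + 1 < 30:
        raise ValueError("baseline must cover at least 30 years")
    summer = (monthly[monthly["month"].isin(months)]
              .groupby("year")[variables].mean())
    base = summer.loc[(summer.index >= y0) & (summer.index <= y1)]
    if len(base) < 30:
        raise ValueError("baseline must cover at least 30 years of data")
    mean = base.mean()
    sd = base.std(ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        raise ValueError(f"zero baseline standard deviation for {degenerate}")
    z = (summer - mean) / sd
    return ClimateAnomalies(summer_means=summer, z_scores=z,
                            baseline_mean=mean, baseline_sd=sd,
                            baseline_years=baseline_years)


# ---------------------------------------------------------------------------
# exponential climate-fire fits


@dataclass
class ExponentialFit:
    """BA = exp(a + b z): coefficients and fit quality on the log scale."""

    a: float
    b: float
    r2: float
    p_value: float
    n: int
    model: str
    offset: float = 0.0


def fit_exponential(ba: np.ndarray, z: np.ndarray,
                    model: str = "log-ols") -> ExponentialFit:
    """Fit log(BA) = a + b z by OLS, or a log-link Gaussian GLM on BA.

    Zero burned-area years are offset by half the smallest positive annual
    value before the log transform (recorded in the result).
    """
    ba = np.asarray(ba, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(ba) & np.isfinite(z)
    ba, z = ba[ok], z[ok]
    if ba.size < 4:
        raise ValueError("need at least 4 observations")
    if np.any(ba < 0):
        raise ValueError("burned area must be non-negative")
    offset = 0.0
    if np.any(ba == 0):
        positive = ba[ba > 0]
        if positive.size == 0:
            raise ValueError("all burned areas are zero")
        offset = float(positive.min()) / 2.0
        ba = ba + offset
    exog = sm.add_constant(z)
    if model == "log-ols":
        res = sm.OLS(np.log(ba), exog).fit()
        a, b = res.params
        r2 = float(res.rsquared)
        p = float(res.pvalues[1])
    elif model == "glm-log":
        res = sm.GLM(ba, exog,
                     family=sm.families.Gaussian(sm.families.links.Log())).fit()
        a, b = res.params
        mu = res.fittedvalues
        r2 = float(1 - np.sum((ba - mu) ** 2) / np.sum((ba - ba.mean()) ** 2))
        p = float(res.pvalues[1])
    else:
        raise ValueError(f"unknown model {model!r}")
    return ExponentialFit(a=float(a), b=float(b), r2=r2, p_value=p,
                          n=int(ba.size), model=model, offset=offset)


# ---------------------------------------------------------------------------
# Mann-Kendall trend


@dataclass
class MannKendall:
    """Mann-Kendall test with tie-corrected variance plus the Sen slope."""

    s: int
    tau: float
    var_s: float
    z: float
    p_value: float
    sen_slope: float
    n: int


def mann_kendall(series: np.ndarray) -> MannKendall:
    """Two-sided Mann-Kendall trend test with continuity correction.

    S sums the signs of all forward pairwise differences; its variance is
    n(n-1)(2n+5)/18 minus the usual tie correction; z applies the ±1
    continuity correction; the Sen slope is the median pairwise slope.
    A constant series returns tau = 0, p = 1.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    diffs = x[None, :] - x[:, None]
    iu = np.triu_indices(n, k=1)
    signs = np.sign(diffs[iu])
    s = int(signs.sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:
        z = 0.0
        p = 1.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var_s)
        p = 2 * stats.norm.sf(abs(z))
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
        p = 2 * stats.norm.sf(abs(z))
    else:
        z, p = 0.0, 1.0
    tau = s / (0.5 * n * (n - 1))
    idx = np.arange(n)
    di = idx[None, :] - idx[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = diffs[iu] / di[iu]
    sen = float(np.median(slopes))
    return MannKendall(s=s, tau=float(tau), var_s=float(var_s), z=float(z),
                       p_value=float(p), sen_slope=sen, n=n)


# ---------------------------------------------------------------------------
# piecewise SEM


class CyclicGraphError(ValueError):
    """Raised when the path diagram contains a directed cycle."""


@dataclass
class SemSpec:
    """Path diagram of the piecewise SEM.

    ``paths`` are directed (cause, effect) pairs; ``ols_nodes`` lists
    endogenous nodes fitted by ordinary regression instead of a mixed model
    with a random ``group`` intercept; ``correlated_errors`` pairs are
    treated as free covariances and excluded from the independence basis.
    """

    nodes: list[str]
    paths: list[tuple[str, str]]
    group: str = "zone"
    ols_nodes: tuple[str, ...] = ()
    correlated_errors: tuple[tuple[str, str], ...] = ()

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.paths)
        if not nx.is_directed_acyclic_graph(g):
            raise CyclicGraphError("SEM path diagram must be acyclic")
        return g

    def parents(self, node: str) -> list[str]:
        return [a for a, b in self.paths if b == node]

    @property
    def endogenous(self) -> list[str]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return sorted({b for _, b in self.paths}, key=order.get)


def default_sem_spec() -> SemSpec:
    """The climate-fire causal diagram used throughout the package.

    Water deficit drives the Drought Code (positively) and PDSI
    (negatively, dry = negative PDSI); minimum temperature modulates DC;
    DC drives total burned area; DC and PDSI drive peat burned area; peat
    burned area and water deficit drive belowground carbon combustion.  The
    DC and PDSI paths are plain regressions; fire and combustion nodes get
    zone random intercepts.  Total and peat burned area share a free error
    covariance.
    """
    return SemSpec(
        nodes=["water_deficit", "tmin", "dc", "pdsi",
               "log_total_ba", "log_peat_ba", "below_cc"],
        paths=[("water_deficit", "dc"), ("tmin", "dc"),
               ("water_deficit", "pdsi"),
               ("dc", "log_total_ba"),
               ("dc", "log_peat_ba"), ("pdsi", "log_peat_ba"),
               ("log_peat_ba", "below_cc"), ("water_deficit", "below_cc")],
        ols_nodes=("dc", "pdsi"),
        correlated_errors=(("log_total_ba", "log_peat_ba"),),
    )


@dataclass
class PathEstimate:
    source: str
    target: str
    beta: float
    p_value: float


@dataclass
class NodeFit:
    node: str
    family: str  # "lmm" | "ols"
    marginal_r2: float
    conditional_r2: float
    residuals: np.ndarray


@dataclass
class SemFit:
    """Standardized paths, per-node fits and the global Fisher's C test."""

    paths: list[PathEstimate]
    nodes: dict[str, NodeFit]
    fisher_c: float
    df: int
    p_value: float
    independence_claims: list[tuple[str, str, tuple[str, ...], float]]
    endogenous_cov: dict[str, float] = field(default_factory=dict)

    def beta(self, source: str, target: str) -> float:
        for p in self.paths:
            if p.source == source and p.target == target:
                return p.beta
        raise KeyError((source, target))


def _fit_node(data: pd.DataFrame, target: str, predictors: list[str],
              group: str, family: str):
    """Fit one node model; returns (params, pvalues, node_fit).

    Mixed models use restricted likelihood with a random intercept per
    group; an unidentifiable mixed fit falls back to ordinary regression
    with a warning.  Variables are assumed pre-standardized by the caller,
    so coefficients are standardized betas.
    """
    formula = f"{target} ~ " + (" + ".join(predictors) if predictors else "1")
    if family == "lmm":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(formula, data, groups=data[group]).fit(reml=True)
            if not np.isfinite(res.params[predictors]).all():
                raise ValueError("non-finite mixed-model estimates")
            fitted_fixed = res.predict(data)
            var_f = float(np.var(fitted_fixed, ddof=0))
            var_re = float(res.cov_re.to_numpy().trace())
            var_resid = float(res.scale)
            denom = var_f + var_re + var_resid
            node_fit = NodeFit(
                node=target, family="lmm",
                marginal_r2=var_f / denom,
                conditional_r2=(var_f + var_re) / denom,
                residuals=np.asarray(res.resid, dtype=float),
            )
            return res.params, res.pvalues, node_fit
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"mixed model for {target} unidentifiable ({exc}); "
                          "falling back to ordinary regression")
    res = smf.ols(formula, data).fit()
    r2 = float(res.rsquared)
    node_fit = NodeFit(node=target, family="ols", marginal_r2=r2,
                       conditional_r2=r2,
                       residuals=np.asarray(res.resid, dtype=float))
    return res.params, res.pvalues, node_fit


def piecewise_sem(data: pd.DataFrame, spec: SemSpec) -> SemFit:
    """Fit the piecewise SEM and test the graph with Fisher's C.

    All variables are standardized by their grand standard deviation before
    fitting, so path coefficients are standardized betas.  The basis set
    consists of all non-adjacent node pairs except declared correlated
    errors and pairs of exogenous nodes (which covary freely); each claim
    regresses the pair's downstream node on the other
    conditioned on the union of both nodes' parents, using that node's
    model family.  Fisher's C = -2 Σ ln p over the k claims, compared to
    chi-square with 2k degrees of freedom.
    """
    g = spec.graph()
    for node in spec.nodes:
        if node not in data.columns:
            raise ValueError(f"variable {node!r} missing from data")
    if spec.group in data.columns:
        if data.groupby(spec.group).size().min() < 2:
            raise ValueError("need at least 2 observations per group")
    work = data.copy()
    for node in spec.nodes:
        sd = work[node].std(ddof=1)
        if sd == 0:
            raise ValueError(f"variable {node!r} is constant")
        work[node] = (work[node] - work[node].mean()) / sd

    topo = list(nx.topological_sort(g))
    order = {n: i for i, n in enumerate(topo)}

    paths: list[PathEstimate] = []
    nodes: dict[str, NodeFit] = {}
    for target in spec.endogenous:
        parents = spec.parents(target)
        family = "ols" if target in spec.ols_nodes else "lmm"
        params, pvalues, node_fit = _fit_node(work, target, parents,
                                              spec.group, family)
        nodes[target] = node_fit
        for parent in parents:
            paths.append(PathEstimate(source=parent, target=target,
                                      beta=float(params[parent]),
                                      p_value=float(pvalues[parent])))

    # d-separation basis set: non-adjacent pairs, conditioned on the union
    # of both nodes' parents
    skip = {frozenset(p) for p in spec.correlated_errors}
    claims = []
    for u, v in itertools.combinations(spec.nodes, 2):
        if g.has_edge(u, v) or g.has_edge(v, u) or frozenset((u, v)) in skip:
            continue
        target, other = (v, u) if order[v] > order[u] else (u, v)
        if not spec.parents(target):
            if not spec.parents(other):
                # two exogenous nodes covary freely: not an independence claim
                continue
            target, other = other, target
        cond = tuple(sorted(set(spec.parents(target)) | set(spec.parents(other)),
                            key=order.get))
        family = "ols" if target in spec.ols_nodes else "lmm"
        predictors = [c for c in cond if c != target and c != other] + [other]
        params, pvalues, _ = _fit_node(work, target, predictors,
                                       spec.group, family)
        claims.append((other, target, cond, float(pvalues[other])))

    ps = np.clip(np.array([c[3] for c in claims], dtype=float), 1e-300, 1.0)
    c_stat = float(-2.0 * np.sum(np.log(ps))) if len(ps) else 0.0
    df = 2 * len(ps)
    p_global = float(stats.chi2.sf(c_stat, df)) if df else 1.0

    endo_cov: dict[str, float] = {}
    for a, b in spec.correlated_errors:
        r_raw = float(np.corrcoef(work[a], work[b])[0, 1])
        endo_cov[f"corr({a},{b})"] = r_raw
        if a in nodes and b in nodes:
            ra, rb = nodes[a].residuals, nodes[b].residuals
            if ra.size == rb.size:
                endo_cov[f"partial_corr({a},{b})"] = float(
                    np.corrcoef(ra, rb)[0, 1])
    return SemFit(paths=paths, nodes=nodes, fisher_c=c_stat, df=df,
                  p_value=p_global, independence_claims=claims,
                  endogenous_cov=endo_cov)


def fisher_c(p_values) -> tuple[float, int, float]:
    """Fisher's C = -2 Σ ln p with df = 2k and its chi-square p-value."""
    ps = np.clip(np.asarray(list(p_values), dtype=float), 1e-300, 1.0)
    c = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * len(ps)
    return c, df, float(stats.chi2.sf(c, df)) if df else 1.0
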