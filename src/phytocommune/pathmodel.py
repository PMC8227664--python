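"""Observed-variable path analysis (SEM without latent variables).

Models are systems of linear regressions among measured columns, fit
jointly to the sample covariance matrix by maximum likelihood. The
discrepancy minimized is

    F(theta) = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^-1) - p

with Sigma(theta) = (I - A)^-1 Psi (I - A)^-T, where A holds directed
path coefficients and Psi the exogenous (co)variances and endogenous
residual (co)variances. chi^2 = (n - 1) * F_min (Wishart convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

_NAME = r"[A-Za-z_][A-Za-z0-9_.]*"
_NAME_RE = re.compile(rf"^{_NAME}$")


class ModelSyntaxError(ValueError):
    pass


@dataclass
class PathModel:
    """Directed paths (regressions) plus unordered covariance paths.

    ``directed`` entries are (source, target): "target ~ source".
    ``covariances`` entries are unordered pairs (a, b): "a ~~ b".
    Every variable implicitly carries a free variance (exogenous) or
    residual-variance (endogenous) parameter.
    """

    variables: list = field(default_factory=list)
    directed: list = field(default_factory=list)
    covariances: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for edge in self.directed:
            if edge in seen:
                raise ModelSyntaxError(f"duplicate path {edge[1]} ~ {edge[0]}")
            seen.add(edge)
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.directed)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise ModelSyntaxError(f"directed structure is cyclic: {cycle}")
        for a, b in self.directed + [tuple(c) for c in self.covariances]:
            for v in (a, b):
                if v not in self.variables:
                    raise ModelSyntaxError(f"path references undeclared variable {v!r}")

    @property
    def endogenous(self) -> list:
        return [v for v in self.variables if any(d == v for _, d in self.directed)]

    @property
    def exogenous(self) -> list:
        endo = set(self.endogenous)
        return [v for v in self.variables if v not in endo]

    @property
    def n_free(self) -> int:
        # one (residual) variance per variable + paths + covariances
        return len(self.variables) + len(self.directed) + len(self.covariances)

    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free

    def topological_order(self) -> list:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.directed)
        return list(nx.topological_sort(g))

    def without_edge(self, edge, drop_isolated: bool = True) -> "PathModel":
        """Copy of the model with one directed edge removed.

        A variable left with no directed or covariance path is dropped
        from the variable set (it no longer constrains the fit).
        """
        directed = [e for e in self.directed if e != tuple(edge)]
        if len(directed) == len(self.directed):
            raise KeyError(f"edge {edge} not in model")
        variables = list(self.variables)
        if drop_isolated:
            used = {v for e in directed for v in e}
            used |= {v for c in self.covariances for v in c}
            variables = [v for v in variables if v in used]
        return PathModel(variables=variables, directed=directed,
                         covariances=list(self.covariances))


def parse_model(text: str) -> PathModel:
    """Parse a minimal path syntax: ``y ~ x1 + x2`` and ``a ~~ b``.

    Statements are separated by newlines or semicolons; ``#`` starts a
    comment. Variables are registered on first use.
    """
    if not text or not text.strip():
        raise ModelSyntaxError("empty model specification")
    variables: list = []
    directed: list = []
    covariances: list = []

    def register(name: str, lineno: int) -> None:
        if not _NAME_RE.match(name):
            raise ModelSyntaxError(f"line {lineno}: bad token {name!r}")
        if name not in variables:
            variables.append(name)

    for lineno, rawline in enumerate(text.splitlines(), start=1):
        line = rawline.split("#", 1)[0]
        for stmt in line.split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            if "~~" in stmt:
                lhs, rhs = (s.strip() for s in stmt.split("~~", 1))
                register(lhs, lineno)
                register(rhs, lineno)
                pair = (lhs, rhs)
                if pair in covariances or pair[::-1] in covariances:
                    raise ModelSyntaxError(f"line {lineno}: duplicate covariance {pair}")
                covariances.append(pair)
            elif "~" in stmt:
                lhs, rhs = (s.strip() for s in stmt.split("~", 1))
                register(lhs, lineno)
                for term in rhs.split("+"):
                    term = term.strip()
                    register(term, lineno)
                    directed.append((term, lhs))
            else:
                raise ModelSyntaxError(f"line {lineno}: cannot parse {stmt!r}")
    return PathModel(variables=variables, directed=directed, covariances=covariances)


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

@dataclass
class PathFit:
    model: PathModel
    params: pd.DataFrame          # name, kind, lhs, rhs, estimate, se, z, p
    chi2: float
    df: int
    p_value: float
    aic: float                    # chi2 - 2*df (difference-comparable)
    aic_deviance: float           # (n-1)*F_min + 2*k (difference-comparable)
    n: int
    fmin: float
    converged: bool
    sigma: pd.DataFrame           # fitted covariance matrix

    def coefficient(self, source: str, target: str) -> float:
        row = self.params[(self.params["kind"] == "path")
                          & (self.params["rhs"] == source)
                          & (self.params["lhs"] == target)]
        if row.empty:
            raise KeyError(f"no path {target} ~ {source}")
        return float(row["estimate"].iloc[0])

    def path_pvalue(self, source: str, target: str) -> float:
        row = self.params[(self.params["kind"] == "path")
                          & (self.params["rhs"] == source)
                          & (self.params["lhs"] == target)]
        if row.empty:
            raise KeyError(f"no path {target} ~ {source}")
        return float(row["p"].iloc[0])


def _build_matrices(model: PathModel, theta: np.ndarray, p: int,
                    idx: dict) -> tuple[np.ndarray, np.ndarray]:
    n_beta = len(model.directed)
    A = np.zeros((p, p))
    for k, (src, dst) in enumerate(model.directed):
        A[idx[dst], idx[src]] = theta[k]
    psi = np.zeros((p, p))
    diag = theta[n_beta:n_beta + p]
    psi[np.diag_indices(p)] = diag
    for k, (a, b) in enumerate(model.covariances):
        v = theta[n_beta + p + k]
        psi[idx[a], idx[b]] = v
        psi[idx[b], idx[a]] = v
    return A, psi


def _implied_sigma(model: PathModel, theta: np.ndarray, p: int, idx: dict) -> np.ndarray:
    A, psi = _build_matrices(model, theta, p, idx)
    ima_inv = np.linalg.inv(np.eye(p) - A)
    return ima_inv @ psi @ ima_inv.T


def fit_path_model(model: PathModel, data: pd.DataFrame, n: int | None = None,
                   standardize: bool = True, gtol: float = 1e-8,
                   compute_se: bool = True) -> PathFit:
    """Fit by minimizing the ML discrepancy over the free parameters.

    Complete cases only; by default columns are z-scored first so the
    estimates are standardized coefficients. Start values: paths and
    covariances 0, variances equal to the sample variances (identity
    under standardization).
    """
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    df_data = data[model.variables].dropna()
    if n is None:
        n = len(df_data)
    X = df_data.to_numpy(dtype=float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    p = len(model.variables)
    S = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    s_eigs = np.linalg.eigvalsh(S)
    if s_eigs.min() <= 1e-12:
        raise ValueError("sample covariance matrix is not positive definite")
    sign_s, logdet_s = np.linalg.slogdet(S)
    idx = {v: i for i, v in enumerate(model.variables)}
    n_beta = len(model.directed)
    k_free = model.n_free

    def discrepancy(theta: np.ndarray) -> float:
        diag = theta[n_beta:n_beta + p]
        if np.any(diag <= 1e-10):
            return 1e10 + float(np.sum(np.square(np.minimum(diag, 0))))
        sigma = _implied_sigma(model, theta, p, idx)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        try:
            sigma_inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return 1e10
        return float(logdet - logdet_s + np.trace(S @ sigma_inv) - p)

    theta0 = np.zeros(k_free)
    theta0[n_beta:n_beta + p] = np.diag(S)
    res = optimize.minimize(discrepancy, theta0, method="BFGS",
                            options={"gtol": gtol, "maxiter": 2000})
    if not res.success:
        # restart once from the current point; BFGS often reports benign
        # precision loss at an already-converged solution
        res2 = optimize.minimize(discrepancy, res.x, method="BFGS",
                                 options={"gtol": gtol, "maxiter": 2000})
        if res2.fun <= res.fun:
            res = res2
    if res.fun >= 1e9:  # stuck on the penalty plateau: derivative-free rescue
        res3 = optimize.minimize(discrepancy, theta0 + 0.01, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12,
                                          "maxiter": 20000, "maxfev": 40000})
        if res3.fun < res.fun:
            res = res3
    theta = res.x
    fmin = max(float(res.fun), 0.0)
    converged = bool(res.fun < 1e9)

    # standard errors from the numeric Hessian of F: cov(theta) = (2/(n-1)) H^-1
    se = np.full(k_free, np.nan)
    try:
        if not compute_se:
            raise RuntimeError("standard errors not requested")
        H = _numeric_hessian(discrepancy, theta)
        Hinv = np.linalg.pinv(H)
        var = (2.0 / (n - 1)) * np.diag(Hinv)
        se = np.sqrt(np.clip(var, 0, None))
    except Exception:  # noqa: BLE001 - SEs are diagnostics, never fatal
        pass


    rows = []
    for kk, (src, dst) in enumerate(model.directed):
        rows.append({"name": f"{dst}~{src}", "kind": "path", "lhs": dst, "rhs": src,
                     "estimate": theta[kk], "se": se[kk]})
    for i, v in enumerate(model.variables):
        kk = n_beta + i
        rows.append({"name": f"{v}~~{v}", "kind": "variance", "lhs": v, "rhs": v,
                     "estimate": theta[kk], "se": se[kk]})
    for j, (a, b) in enumerate(model.covariances):
        kk = n_beta + p + j
        rows.append({"name": f"{a}~~{b}", "kind": "covariance", "lhs": a, "rhs": b,
                     "estimate": theta[kk], "se": se[kk]})
    params = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        params["z"] = params["estimate"] / params["se"]
    params["p"] = 2 * stats.norm.sf(np.abs(params["z"]))

    chi2 = (n - 1) * fmin
    dof = model.df()
    if dof < 0:
        raise ValueError(f"model has negative degrees of freedom ({dof})")
    p_value = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    sigma = _implied_sigma(model, theta, p, idx)
    return PathFit(
        model=model,
        params=params,
        chi2=chi2,
        df=dof,
        p_value=p_value,
        aic=chi2 - 2 * dof,
        aic_deviance=chi2 + 2 * k_free,
        n=n,
        fmin=fmin,
        converged=converged,
        sigma=pd.DataFrame(sigma, index=model.variables, columns=model.variables),
    )


def _numeric_hessian(fun, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * eps * eps)
    del f0
    return H


# ---------------------------------------------------------------------------
# Effect decomposition
# ---------------------------------------------------------------------------

def effects_decomposition(fit: PathFit) -> pd.DataFrame:
    """Direct, indirect and total effects for every ordered variable pair.

    With B the directed-coefficient matrix (B[target, source]), the total
    effect matrix is (I - B)^-1 - I = sum_{k>=1} B^k; indirect = total -
    direct. Requires spectral radius of B below 1.
    """
    model = fit.model
    p = len(model.variables)
    idx = {v: i for i, v in enumerate(model.variables)}
    B = np.zeros((p, p))
    for _, row in fit.params[fit.params["kind"] == "path"].iterrows():
        B[idx[row["lhs"]], idx[row["rhs"]]] = row["estimate"]
    radius = np.max(np.abs(np.linalg.eigvals(B)))
    if radius >= 1:
        raise ValueError(f"effect series does not converge (spectral radius {radius:.3f})")
    total = np.linalg.inv(np.eye(p) - B) - np.eye(p)
    indirect = total - B
    rows = []
    for src in model.variables:
        for dst in model.variables:
            if src == dst:
                continue
            i, j = idx[dst], idx[src]
            rows.append({"source": src, "target": dst, "direct": B[i, j],
                         "indirect": indirect[i, j], "total": total[i, j]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Iterative pruning of tagged (chemistry) paths
# ---------------------------------------------------------------------------

def prune_paths(model: PathModel, data: pd.DataFrame, tagged: set,
                alpha: float = 0.05, protected: set | None = None,
                n: int | None = None) -> tuple[PathFit, list]:
    """Iteratively drop the least significant tagged directed path.

    Repeats {fit; remove the tagged edge with the largest p if p > alpha}
    until all remaining tagged edges are significant. Edges in
    ``protected`` are never candidates; a removal that would isolate a
    variable referenced by a protected edge is skipped and logged.
    Returns the final fit and an ordered removal log.
    """
    protected = set(protected or ())
    tagged = {tuple(e) for e in tagged} - {tuple(e) for e in protected}
    mandatory = {v for e in protected for v in e}
    log: list = []
    current = model
    skipped: set = set()
    fit = fit_path_model(current, data, n=n)
    while True:
        candidates = []
        for edge in current.directed:
            if tuple(edge) in tagged and tuple(edge) not in skipped:
                candidates.append((fit.path_pvalue(edge[0], edge[1]), tuple(edge)))
        candidates = [(pv, e) for pv, e in candidates if pv > alpha]
        if not candidates:
            break
        candidates.sort(key=lambda t: (-t[0], t[1]))
        pv, edge = candidates[0]
        trial = current.without_edge(edge)
        lost = set(current.variables) - set(trial.variables)
        if lost & mandatory:
            skipped.add(edge)
            log.append({"edge": edge, "p": pv, "action": "skipped",
                        "reason": f"would disconnect mandatory variable(s) {sorted(lost & mandatory)}"})
            continue
        log.append({"edge": edge, "p": pv, "action": "removed"})
        current = trial
        fit = fit_path_model(current, data, n=n)
    return fit, log


# ---------------------------------------------------------------------------
# Generative counterpart: implied covariance for planted coefficients
# ---------------------------------------------------------------------------

def standardized_implied_cov(model: PathModel, coefficients: dict,
                             resid_covs: dict | None = None) -> pd.DataFrame:
    """Population covariance of a standardized system with given paths.

    ``coefficients`` maps "source->target" to the standardized path
    coefficient. Residual (co)variances of the endogenous variables are
    chosen so every variable has unit variance; an infeasible coefficient
    set (implied residual variance <= 0) raises.
    """
    resid_covs = dict(resid_covs or {})
    p = len(model.variables)
    idx = {v: i for i, v in enumerate(model.variables)}
    A = np.zeros((p, p))
    for src, dst in model.directed:
        key = f"{src}->{dst}"
        if key not in coefficients:
            raise KeyError(f"no planted coefficient for path {key}")
        A[idx[dst], idx[src]] = coefficients[key]
    unknown = set(coefficients) - {f"{s}->{d}" for s, d in model.directed}
    if unknown:
        raise KeyError(f"coefficients reference unknown paths: {sorted(unknown)}")
    C = np.zeros((p, p))
    for (a, b), v in resid_covs.items():
        C[idx[a], idx[b]] = v
        C[idx[b], idx[a]] = v
    T = np.linalg.inv(np.eye(p) - A)
    # solve diag(T (D + C) T') = 1 for the diagonal D
    M = T ** 2
    rhs = 1.0 - np.diag(T @ C @ T.T)
    d = np.linalg.solve(M, rhs)
    if np.any(d <= 0):
        bad = [model.variables[i] for i in np.where(d <= 0)[0]]
        raise ValueError(f"planted coefficients imply non-positive residual variance for {bad}")
    psi = C + np.diag(d)
    sigma = T @ psi @ T.T
    return pd.DataFrame(sigma, index=model.variables, columns=model.variables)


def simulate_path_data(model: PathModel, coefficients: dict, n: int, seed: int,
                       resid_covs: dict | None = None) -> pd.DataFrame:
    """Draw n multivariate-normal rows from the planted standardized system."""
    sigma = standardized_implied_cov(model, coefficients, resid_covs)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(len(model.variables)), sigma.to_numpy(),
                                size=n, method="cholesky")
    return pd.DataFrame(X, columns=model.variables)
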