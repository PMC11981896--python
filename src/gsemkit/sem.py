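"""Structural equation models on genetic correlation matrices (genomic SEM).

A model is specified lavaan-style over observed traits and latent factors:

    F1 =~ SES + LED + ALC + SI      # factor loadings
    AD ~~ F1                        # covariance (factor-disorder correlation)
    AD ~~ b*LON                     # 'b*' = equality label shared across lines
    SCZ ~~ b*LON
    F1 ~~ 0.5*F2                    # '<number>*' = fixed value

and fitted to an LDSC :class:`~gsemkit.ldsc.CorrelationEstimate` by
diagonally weighted least squares: minimize (s - sigma(theta))' D^-1
(s - sigma(theta)) with D the diagonal of the sampling covariance V_R of the
half-vectorized observed correlations s.  Because the point estimator uses
only the diagonal of V_R, the model chi-square is the residual-based
quadratic form that remains asymptotically chi^2_df for any consistent
estimator:

    T = r' [ V+ - V+ D (D' V+ D)+ D' V+ ] r

(r the moment residual, D here the moment Jacobian at the solution, V+ a
rank-adjusted pseudo-inverse of V_R).  Parameter SEs come from the usual
sandwich using the full V_R.

Latent variables are scale-set by fixing their variance to 1 (standardized
solution).  Negative residual variances are reported with a Heywood flag,
never silently bounded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .ldsc import CorrelationEstimate, hvec_pairs
from .sumstats import InputError

__all__ = [
    "SemModel", "SemResults", "SemPath", "SemConvergenceError",
    "fit_dwls", "fit_indices", "compare_constrained",
]


class SemConvergenceError(RuntimeError):
    """Optimizer failed; carries the final gradient norm."""

    def __init__(self, grad_norm: float):
        super().__init__(f"DWLS optimization did not converge (|grad| = {grad_norm:.3e})")
        self.grad_norm = grad_norm


@dataclass(frozen=True)
class SemPath:
    """One model path.

    kind 'loading': lhs is a latent, rhs an indicator; 'covariance'/'variance'
    live in the symmetric part.  ``fixed`` pins the value (path not free);
    ``label`` shares one free parameter across paths.
    """

    lhs: str
    rhs: str
    kind: str  # loading | covariance | variance
    fixed: float | None = None
    label: str | None = None


_TERM_RE = re.compile(r"^(?:(?P<pre>[^*\s]+)\*)?(?P<var>\S+)$")


def _parse_term(term: str):
    m = _TERM_RE.match(term.strip())
    if not m:
        raise ValueError(f"cannot parse model term {term!r}")
    pre, var = m.group("pre"), m.group("var")
    if pre is None:
        return var, None, None
    try:
        return var, float(pre), None
    except ValueError:
        return var, None, pre


@dataclass
class SemModel:
    """Path model over observed traits and latent factors."""

    observed: list[str]
    latents: list[str]
    paths: list[SemPath]

    def __post_init__(self) -> None:
        names = set(self.observed) | set(self.latents)
        for p in self.paths:
            for v in (p.lhs, p.rhs):
                if v not in names:
                    raise InputError(f"model path references undeclared name {v!r}")
        if set(self.observed) & set(self.latents):
            raise InputError("a name cannot be both observed and latent")

    @classmethod
    def from_text(cls, text: str) -> "SemModel":
        """Parse the one-path-per-line model syntax (see module docstring)."""
        paths: list[SemPath] = []
        latents: list[str] = []
        mentioned: list[str] = []

        def note(v: str) -> None:
            if v not in mentioned:
                mentioned.append(v)

        for raw_line in text.splitlines():
            line = raw_line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=~" in line:
                lhs, rhs = [s.strip() for s in line.split("=~", 1)]
                if lhs not in latents:
                    latents.append(lhs)
                for term in rhs.split("+"):
                    var, fixed, label = _parse_term(term)
                    note(var)
                    paths.append(SemPath(lhs, var, "loading", fixed, label))
            elif "~~" in line:
                lhs, rhs = [s.strip() for s in line.split("~~", 1)]
                var, fixed, label = _parse_term(rhs)
                note(lhs)
                note(var)
                kind = "variance" if lhs == var else "covariance"
                paths.append(SemPath(lhs, var, kind, fixed, label))
            else:
                raise ValueError(f"unrecognized model line: {raw_line!r}")
        observed = [v for v in mentioned if v not in latents]
        return cls(observed, latents, paths)

    def to_text(self) -> str:
        lines = []
        by_latent: dict[str, list[str]] = {}
        for p in self.paths:
            if p.kind == "loading":
                term = p.rhs
                if p.fixed is not None:
                    term = f"{p.fixed:g}*{term}"
                elif p.label:
                    term = f"{p.label}*{term}"
                by_latent.setdefault(p.lhs, []).append(term)
        for lat, terms in by_latent.items():
            lines.append(f"{lat} =~ " + " + ".join(terms))
        for p in self.paths:
            if p.kind in ("covariance", "variance"):
                term = p.rhs
                if p.fixed is not None:
                    term = f"{p.fixed:g}*{term}"
                elif p.label:
                    term = f"{p.label}*{term}"
                lines.append(f"{p.lhs} ~~ {term}")
        return "\n".join(lines)

    # -- internal parameterization -----------------------------------------

    def _build(self, trait_order: list[str]):
        """Index the free parameters and return structures for sigma(theta).

        Observed variables are ordered as in ``trait_order``; auto-adds free
        residual variances for observed variables lacking one and fixes
        latent variances to 1 unless specified (scale setting).
        """
        obs = [t for t in trait_order if t in self.observed]
        nodes = obs + self.latents
        pos = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)

        have_var = {p.lhs for p in self.paths if p.kind == "variance"}
        paths = list(self.paths)
        for v in obs:
            if v not in have_var:
                paths.append(SemPath(v, v, "variance"))
        for f in self.latents:
            if f not in have_var:
                paths.append(SemPath(f, f, "variance", fixed=1.0))

        labels: dict[str, int] = {}
        free_idx: list[int] = []   # parameter index per path (-1 fixed)
        names: list[str] = []
        starts: list[float] = []
        entries = []  # (matrix 'A'|'S', i, j, param_index, fixed_value)
        q = 0
        for p in paths:
            if p.kind == "loading":
                mat, i, j = "A", pos[p.rhs], pos[p.lhs]
                default_start = 0.5
                pname = f"{p.lhs}=~{p.rhs}"
            else:
                mat, i, j = "S", pos[p.lhs], pos[p.rhs]
                default_start = 1.0 if p.kind == "variance" else 0.0
                pname = f"{p.lhs}~~{p.rhs}"
            if p.fixed is not None:
                entries.append((mat, i, j, -1, float(p.fixed)))
                continue
            if p.label is not None and p.label in labels:
                k = labels[p.label]
            else:
                k = q
                q += 1
                names.append(p.label or pname)
                starts.append(default_start)
                if p.label is not None:
                    labels[p.label] = k
            entries.append((mat, i, j, k, 0.0))
        return obs, nodes, n, entries, np.array(starts), names, paths

    def implied(self, theta: np.ndarray, build) -> np.ndarray:
        """Model-implied covariance over the observed variables."""
        obs, nodes, n, entries, _, _, _ = build
        A = np.zeros((n, n))
        S = np.zeros((n, n))
        for mat, i, j, k, fixed in entries:
            val = fixed if k < 0 else theta[k]
            if mat == "A":
                A[i, j] = val
            else:
                S[i, j] = val
                S[j, i] = val
        T = np.eye(n) + A  # loadings are latent -> observed only, so A^2 = 0
        sigma_full = T @ S @ T.T
        no = len(obs)
        return sigma_full[:no, :no]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class SemResults:
    """DWLS solution: estimates, sandwich SEs, fit statistics and residuals."""

    model: SemModel
    param_names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    chi2: float
    df: int
    p_value: float
    aic: float
    cfi: float
    srmr: float
    residuals: np.ndarray
    observed_order: list[str]
    heywood: list[str] = field(default_factory=list)
    cfi_clamped: bool = False
    n_iter: int = 0

    def estimate(self, name: str) -> tuple[float, float]:
        """(estimate, SE) for a parameter by name or equality label."""
        i = self.param_names.index(name)
        return float(self.estimates[i]), float(self.se[i])

    def summary(self) -> str:
        lines = [
            "DWLS structural equation model",
            f"  observed: {', '.join(self.observed_order)}",
            f"  latents:  {', '.join(self.model.latents) or '(none)'}",
            f"  chi2 = {self.chi2:.4f}  df = {self.df}  p = {self.p_value:.3g}",
            f"  AIC = {self.aic:.4f}  CFI = {self.cfi:.4f}  SRMR = {self.srmr:.4f}",
        ]
        if self.heywood:
            lines.append(f"  Heywood case(s): {', '.join(self.heywood)}")
        lines.append("  parameter                          est       SE        z")
        for n, e, s in zip(self.param_names, self.estimates, self.se):
            z = e / s if s > 0 else np.nan
            lines.append(f"  {n:<30} {e:9.4f} {s:8.4f} {z:8.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {n: {"est": float(e), "se": float(s)}
                       for n, e, s in zip(self.param_names, self.estimates, self.se)},
            "chi2": self.chi2, "df": self.df, "p": self.p_value,
            "aic": self.aic, "cfi": self.cfi, "srmr": self.srmr,
            "heywood": self.heywood,
        }


def _hvec(M: np.ndarray) -> np.ndarray:
    k = M.shape[0]
    return np.array([M[a, b] for a, b in hvec_pairs(k)])


def _jacobian(f, theta: np.ndarray, m: int) -> np.ndarray:
    """Central-difference Jacobian of the moment map (m x q)."""
    q = len(theta)
    J = np.empty((m, q))
    for j in range(q):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (f(tp) - f(tm)) / (2 * h)
    return J


def _browne_chi2(r: np.ndarray, V: np.ndarray, J: np.ndarray, df: int) -> float:
    """Residual-based test statistic r' [V+ - V+ J (J'V+J)+ J'V+] r."""
    if df <= 0:
        return 0.0
    Vp = np.linalg.pinv(V, rcond=1e-10, hermitian=True)
    if J.size:
        JtV = J.T @ Vp
        U = Vp - JtV.T @ np.linalg.pinv(JtV @ J, rcond=1e-10, hermitian=True) @ JtV
    else:
        U = Vp
    return float(max(r @ U @ r, 0.0))


def _dwls_minimize(sigma_fn, s, d_inv, starts, max_iter=500, gtol=1e-8):
    m = len(s)

    def obj(theta):
        r = s - sigma_fn(theta)
        return float(r @ (d_inv * r))

    def grad(theta):
        r = s - sigma_fn(theta)
        J = _jacobian(sigma_fn, theta, m)
        return -2.0 * (J.T @ (d_inv * r))

    res = optimize.minimize(obj, starts, jac=grad, method="BFGS",
                            options={"maxiter": max_iter, "gtol": gtol})
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    if not res.success and grad_norm > 1e-4 * max(1.0, abs(res.fun)):
        raise SemConvergenceError(grad_norm)
    return res


def fit_dwls(model: SemModel, corr: CorrelationEstimate,
             max_iter: int = 500, gtol: float = 1e-8,
             _with_independence: bool = True) -> SemResults:
    """Fit ``model`` to a genetic correlation estimate by DWLS.

    Moments are the half-vectorized correlations of the traits the model
    references (in ``corr``'s trait order); weights are the inverse diagonal
    of the corresponding block of V_R.
    """
    used = [t for t in corr.traits if t in model.observed]
    missing = set(model.observed) - set(used)
    if missing:
        raise InputError(f"model references traits absent from the estimate: {sorted(missing)}")
    sub = corr.subset(used)
    s = _hvec(sub.R)
    D = np.diag(sub.V_R).copy()
    if np.any(D <= 0):
        raise InputError("V_R diagonal must be strictly positive for DWLS")
    d_inv = 1.0 / D

    build = model._build(used)
    obs, nodes, n, entries, starts, names, paths = build
    # start covariances at the observed moments
    pos = {v: i for i, v in enumerate(obs)}
    start_map = dict.fromkeys(range(len(starts)))
    for mat, i, j, k, _f in entries:
        if k >= 0 and mat == "S" and i < len(obs) and j < len(obs) and start_map[k] is None:
            start_map[k] = sub.R[i, j]
    theta0 = np.array([start_map[k] if start_map[k] is not None else starts[k]
                       for k in range(len(starts))])

    sigma_fn = lambda th: _hvec(model.implied(th, build))
    m = len(s)
    q = len(theta0)
    df = m - q
    if q:
        res = _dwls_minimize(sigma_fn, s, d_inv, theta0, max_iter, gtol)
        theta = res.x
        n_iter = res.nit
    else:
        theta = theta0
        n_iter = 0
    r = s - sigma_fn(theta)
    J = _jacobian(sigma_fn, theta, m) if q else np.zeros((m, 0))

    chi2 = _browne_chi2(r, sub.V_R, J, df)
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    aic = chi2 + 2 * q

    # sandwich SEs with the full V_R
    if q:
        B = J.T @ (d_inv[:, None] * J)
        Binv = np.linalg.pinv(B, rcond=1e-12, hermitian=True)
        G = J.T * d_inv  # q x m
        cov = Binv @ (G @ sub.V_R @ G.T) @ Binv
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    else:
        se = np.zeros(0)

    srmr = float(np.sqrt(np.mean(r ** 2)))

    heywood = []
    for (mat, i, j, k, _f), p in [(e, p) for e, p in zip(entries, paths)]:
        if mat == "S" and i == j and k >= 0 and theta[k] < 0 and p.kind == "variance":
            heywood.append(nodes[i])

    cfi, clamped = 1.0, False
    if _with_independence and df > 0:
        indep = _independence_model(used)
        ifit = fit_dwls(indep, sub, max_iter, gtol, _with_independence=False)
        cfi, clamped = _cfi(chi2, df, ifit.chi2, ifit.df)

    return SemResults(
        model=model, param_names=names, estimates=np.asarray(theta, dtype=float),
        se=se, chi2=chi2, df=df, p_value=p_value, aic=aic, cfi=cfi,
        srmr=srmr, residuals=r, observed_order=used,
        heywood=sorted(set(heywood)), cfi_clamped=clamped, n_iter=n_iter,
    )


def _independence_model(traits: list[str]) -> SemModel:
    """Null model: free variances, all correlations fixed at zero."""
    lines = [f"{t} ~~ {t}" for t in traits]
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            lines.append(f"{a} ~~ 0*{b}")
    return SemModel.from_text("\n".join(lines))


def _cfi(chi2: float, df: int, chi2_i: float, df_i: int) -> tuple[float, bool]:
    num = max(chi2 - df, 0.0)
    den = max(chi2_i - df_i, chi2 - df, 0.0)
    if den == 0.0:
        return 1.0, False
    cfi = 1.0 - num / den
    return max(cfi, 0.0), bool(num >= den and num > 0)


def fit_indices(fit: SemResults, independence_fit: SemResults) -> tuple[float, float, float]:
    """(CFI, SRMR, AIC) of ``fit`` against an explicit independence fit."""
    cfi, _ = _cfi(fit.chi2, fit.df, independence_fit.chi2, independence_fit.df)
    return cfi, fit.srmr, fit.aic


def saturated_model(traits: list[str]) -> SemModel:
    """Just-identified model: every variance and pairwise covariance free."""
    lines = [f"{t} ~~ {t}" for t in traits]
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            lines.append(f"{a} ~~ {b}")
    return SemModel.from_text("\n".join(lines))


@dataclass
class ConstrainedComparison:
    """Saturated vs equality-constrained fit for one risk factor."""

    risk_factor: str
    outcomes: tuple[str, str]
    rg_1: float
    se_1: float
    rg_2: float
    se_2: float
    rg_constrained: float
    chi2_diff: float
    p_diff: float
    saturated: SemResults
    constrained: SemResults


def compare_constrained(corr: CorrelationEstimate, outcome_pair: tuple[str, str],
                        risk_factor: str) -> ConstrainedComparison:
    """Test whether two outcomes share the same correlation with a risk factor.

    Fits the saturated 3-trait model and the nested model with the two
    outcome-risk-factor correlations constrained equal; the chi-square
    difference on 1 df measures the decrement in fit, i.e. whether the two
    genetic correlations differ.
    """
    o1, o2 = outcome_pair
    for t in (o1, o2, risk_factor):
        if t not in corr.traits:
            raise InputError(f"trait {t!r} not present in the correlation estimate")
    sat = fit_dwls(saturated_model([o1, o2, risk_factor]), corr)
    lines = [
        f"{o1} ~~ b*{risk_factor}",
        f"{o2} ~~ b*{risk_factor}",
        f"{o1} ~~ {o2}",
        f"{o1} ~~ {o1}", f"{o2} ~~ {o2}", f"{risk_factor} ~~ {risk_factor}",
    ]
    con = fit_dwls(SemModel.from_text("\n".join(lines)), corr)
    chi2_diff = max(con.chi2 - sat.chi2, 0.0)
    rg1, se1 = sat.estimate(f"{o1}~~{risk_factor}")
    rg2, se2 = sat.estimate(f"{o2}~~{risk_factor}")
    rg_c, _ = con.estimate("b")
    return ConstrainedComparison(
        risk_factor=risk_factor, outcomes=(o1, o2),
        rg_1=rg1, se_1=se1, rg_2=rg2, se_2=se2, rg_constrained=rg_c,
        chi2_diff=chi2_diff, p_diff=float(stats.chi2.sf(chi2_diff, 1)),
        saturated=sat, constrained=con,
    )
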