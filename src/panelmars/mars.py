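"""Multivariate adaptive regression splines, built from scratch.

The model is an intercept plus a sum of basis terms, each term a product
of one-sided linear splines ("hinges") ``max(0, x - t)`` / ``max(0, t - x)``
with knots *t* placed at observed predictor values:

    f(X) = b0 + sum_m b_m * prod_k hinge_k(X)

Fitting is the classical two-stage procedure:

* **forward pass** — greedy growth: starting from the intercept, repeatedly
  add the reflected hinge pair (parent term x new predictor x knot) that
  maximally reduces the residual sum of squares, until the term budget is
  exhausted or no addition helps;
* **backward pass** — pruning: repeatedly delete the single term whose
  removal gives the lowest generalized cross-validation (GCV) score,
  recording every visited subset, and return the global GCV minimiser of
  the trace, refitted by ordinary least squares.

GCV is (RSS/N) / (1 - C/N)^2 with effective parameter count C.  Two
conventions for C are provided (see :func:`effective_params`); the default
``knot_penalty`` charges each of the (M-1)/2 hinge pairs a penalty *d* on
top of the M regression coefficients, C = M + d (M-1)/2, with d = 3.

Variable importance follows the pruning-subset reading: a predictor is
scored by the number of pruning subsets containing a term that uses it,
and by the GCV / RSS increase accumulated when terms using it are deleted
along the trace, rescaled so the top used variable scores 100.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .panel import DesignMatrix, PanelError

__all__ = [
    "MarsError",
    "Hinge",
    "BasisTerm",
    "FitConfig",
    "MarsModel",
    "PruneTrace",
    "ImportanceRow",
    "ImportanceTable",
    "hinge_eval",
    "candidate_knots",
    "basis_matrix",
    "ols_fit",
    "effective_params",
    "gcv",
    "fit_measures",
    "forward_pass",
    "backward_pass",
    "fit",
    "predict",
    "variable_importance",
    "model_report",
    "render_term",
    "parse_term",
    "term_signature",
    "model_to_json",
    "model_from_json",
]


class MarsError(ValueError):
    """Invalid input to the spline engine."""


# ---------------------------------------------------------------------------
# basis machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hinge:
    """One-sided linear spline factor.

    ``direction`` '+' evaluates max(0, x - knot), '-' evaluates
    max(0, knot - x).  A hinge flagged ``linear`` enters as the bare
    variable x: it arises when the knot sits at the observed minimum, where
    max(0, x - min) spans the same space as x once the parent term is in
    the model.
    """

    var: str
    knot: float
    direction: str = "+"
    linear: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("+", "-"):
            raise MarsError(f"direction must be '+' or '-', got {self.direction!r}")


def hinge_eval(h: Hinge, x):
    """Evaluate a hinge at scalar or array ``x``."""
    arr = np.asarray(x, dtype=float)
    if h.linear:
        out = arr
    elif h.direction == "+":
        out = np.maximum(0.0, arr - h.knot)
    else:
        out = np.maximum(0.0, h.knot - arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class BasisTerm:
    """Product of hinges with an optional fitted coefficient."""

    factors: tuple[Hinge, ...]
    coefficient: float | None = None

    def __post_init__(self) -> None:
        if not self.factors:
            raise MarsError("a basis term needs at least one factor")
        names = [f.var for f in self.factors]
        if len(set(names)) != len(names):
            raise MarsError(f"predictor appears twice in one term: {names}")

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(f.var for f in self.factors)


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the two-stage fit.

    max_terms counts the intercept; penalty is the GCV smoothing penalty d;
    gcv_convention selects the effective-parameter formula.
    """

    max_terms: int = 21
    max_degree: int = 3
    penalty: float = 3.0
    gcv_convention: str = "knot_penalty"
    forbid_self_interaction: bool = True
    rel_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_terms < 1:
            raise MarsError("max_terms must be >= 1")
        if self.max_degree < 1:
            raise MarsError("max_degree must be >= 1")
        if self.penalty < 0:
            raise MarsError("penalty must be >= 0")
        if self.gcv_convention not in ("knot_penalty", "eq4"):
            raise MarsError(
                f"gcv_convention must be 'knot_penalty' or 'eq4', got "
                f"{self.gcv_convention!r}"
            )


@dataclass
class MarsModel:
    intercept: float
    terms: list[BasisTerm]
    n_train: int
    rss: float
    gcv: float
    rsq: float
    grsq: float
    config: FitConfig
    predictor_names: list[str] = field(default_factory=list)

    @property
    def n_terms(self) -> int:
        """Model size including the intercept."""
        return 1 + len(self.terms)

    @property
    def used_variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.terms:
            for f in t.factors:
                seen.setdefault(f.var, None)
        return list(seen)


@dataclass
class PruneTrace:
    """Nested subset sequence visited by the backward pass.

    ``terms`` are the forward-pass terms; each subset is a frozenset of
    indices into it, paired with that subset's refitted RSS and GCV.
    Consecutive subsets differ by exactly one removed term.
    """

    terms: list[BasisTerm]
    subsets: list[tuple[frozenset[int], float, float]]
    best_index: int


@dataclass(frozen=True)
class ImportanceRow:
    var: str
    used: bool
    n_subsets: int | None = None
    gcv_score: float | None = None
    rss_score: float | None = None


@dataclass
class ImportanceTable:
    rows: list[ImportanceRow]

    def row(self, var: str) -> ImportanceRow:
        for r in self.rows:
            if r.var == var:
                return r
        raise KeyError(var)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def candidate_knots(D: DesignMatrix, var: str) -> np.ndarray:
    """Sorted unique observed values of ``var`` (the knot candidate set)."""
    return np.unique(D.column(var))


def basis_matrix(terms: list[BasisTerm], D: DesignMatrix) -> np.ndarray:
    """n x (1+M) matrix: all-ones intercept column, then one column per term
    (the row-wise product of its hinge evaluations)."""
    n = D.n
    cols = [np.ones(n)]
    for t in terms:
        col = np.ones(n)
        for h in t.factors:
            col = col * hinge_eval(h, D.column(h.var))
        cols.append(col)
    return np.column_stack(cols)


def ols_fit(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of y on B (minimum-norm if B is rank-deficient)."""
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if B.shape[0] != y.size:
        raise MarsError(
            f"dimension mismatch: B has {B.shape[0]} rows, y has {y.size}"
        )
    beta, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ beta
    return beta, float(resid @ resid)


def effective_params(n_terms: int, config: FitConfig) -> float:
    """Effective parameter count C for a model of ``n_terms`` terms
    (intercept included).

    ``knot_penalty``: C = M + d (M-1)/2 — the M coefficients plus penalty d
    for each of the (M-1)/2 reflected hinge pairs.  ``eq4``: C = (l+1) + d l
    with l = M - 1 non-intercept terms.
    """
    if n_terms < 1:
        raise MarsError("n_terms must be >= 1")
    m, d = n_terms, config.penalty
    if config.gcv_convention == "knot_penalty":
        return m + d * (m - 1) / 2.0
    return m + d * (m - 1)


def gcv(rss: float, n: int, eff: float) -> float:
    """Generalized cross-validation score (RSS/n) / (1 - eff/n)^2."""
    if eff >= n:
        raise MarsError(
            f"effective parameters ({eff}) must be below the sample size ({n})"
        )
    return (rss / n) / (1.0 - eff / n) ** 2


def _null_gcv(tss: float, n: int) -> float:
    # intercept-only model: one effective parameter
    return gcv(tss, n, 1.0)


def fit_measures(model: MarsModel, y: np.ndarray) -> tuple[float, float]:
    """(RSq, GRSq) of a fitted model against its training response.

    RSq = 1 - RSS/TSS; GRSq = 1 - GCV/GCV_null with the intercept-only
    model (one effective parameter) as reference.
    """
    y = np.asarray(y, dtype=float).ravel()
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0.0:
        raise MarsError("zero total sum of squares: response is constant")
    rsq = 1.0 - model.rss / tss
    grsq = 1.0 - model.gcv / _null_gcv(tss, y.size)
    return rsq, grsq


def predict(model: MarsModel, D: DesignMatrix) -> np.ndarray:
    coef = np.array(
        [model.intercept] + [t.coefficient for t in model.terms], dtype=float
    )
    if any(c is None for c in coef):
        raise MarsError("model has unfitted coefficients")
    return basis_matrix(model.terms, D) @ coef


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def _projected(Q: np.ndarray | None, C: np.ndarray) -> np.ndarray:
    """Component of the columns of C orthogonal to span(Q)."""
    if Q is None or Q.shape[1] == 0:
        return C
    return C - Q @ (Q.T @ C)


def forward_pass(
    D: DesignMatrix, config: FitConfig = FitConfig()
) -> tuple[list[BasisTerm], list[float]]:
    """Greedy growth of reflected hinge pairs.

    Returns the ordered list of created terms (without coefficients) and
    the RSS trace, one entry per accepted model state starting from the
    intercept-only fit.  Candidate scoring projects each hinge-pair onto
    the orthogonal complement of the current basis (all knots of one
    (parent, predictor) combination scored in a single batch); the accepted
    pair is then re-fitted exactly by least squares.  Ties are broken by
    (lower term degree, earlier predictor order, smaller knot).
    """
    y = D.y
    n = y.size
    if n < 2:
        raise MarsError("need at least 2 observations")
    names = list(D.column_names)
    if not names:
        raise MarsError("at least one predictor is required")
    cols = {nm: D.column(nm) for nm in names}
    knots = {nm: np.unique(cols[nm]) for nm in names}

    terms: list[BasisTerm] = []
    term_cols: list[np.ndarray] = []
    B = np.ones((n, 1))
    _, rss_prev = ols_fit(B, y)
    trace = [rss_prev]
    ones = np.ones(n)

    while True:
        m_now = 1 + len(terms)
        budget = config.max_terms - m_now
        if budget < 1 or rss_prev <= 0.0:
            break
        allow_pairs = budget >= 2

        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        rss_base = float(r @ r)

        # (reduction, new_terms, new_cols) of the current best candidate
        best: tuple[float, list[BasisTerm], list[np.ndarray]] | None = None

        parent_order = sorted(
            range(-1, len(terms)),
            key=lambda i: (0, -1) if i < 0 else (terms[i].degree, i),
        )
        for pi in parent_order:
            if pi < 0:
                pfac: tuple[Hinge, ...] = ()
                pdeg, pvars, pcol = 0, frozenset(), ones
            else:
                pt = terms[pi]
                pfac, pdeg, pvars, pcol = (
                    pt.factors,
                    pt.degree,
                    pt.variables,
                    term_cols[pi],
                )
            if pdeg >= config.max_degree:
                continue
            for nm in names:
                if config.forbid_self_interaction and nm in pvars:
                    continue
                x = cols[nm]
                kn = knots[nm]
                if kn.size < 2:
                    continue  # constant predictor contributes nothing
                use = kn if allow_pairs else kn[:1]
                # batched candidate columns over all knots of (parent, nm)
                Cp = pcol[:, None] * np.maximum(0.0, x[:, None] - use[None, :])
                Cm = pcol[:, None] * np.maximum(0.0, use[None, :] - x[:, None])
                Pp = _projected(Q, Cp)
                Pm = _projected(Q, Cm)
                a = np.einsum("ij,ij->j", Pp, Pp)
                c = np.einsum("ij,ij->j", Pm, Pm)
                b = np.einsum("ij,ij->j", Pp, Pm)
                g1 = Pp.T @ r
                g2 = Pm.T @ r
                red1 = np.where(a > 0, g1**2 / np.where(a > 0, a, 1.0), 0.0)
                red2 = np.where(c > 0, g2**2 / np.where(c > 0, c, 1.0), 0.0)
                det = a * c - b**2
                ok = det > 1e-12 * np.maximum(a * c, 1e-300)
                num = c * g1**2 - 2 * b * g1 * g2 + a * g2**2
                red_pair = np.where(
                    ok,
                    num / np.where(ok, det, 1.0),
                    np.maximum(red1, red2),  # near-collinear pair: rank-1 span
                )
                red_pair = np.clip(red_pair, 0.0, rss_base)
                # smallest knot wins among reductions tied within 1e-12
                kbest = int(np.argmax(red_pair > red_pair.max() - 1e-12))
                red = float(red_pair[kbest])
                if best is not None and red <= best[0] + 1e-12:
                    continue
                t_ = float(use[kbest])
                if kbest == 0:
                    # knot at the observed minimum: the mirror column is
                    # identically zero and the '+' branch spans the same
                    # space as the bare variable given the parent term.
                    nterms = [
                        BasisTerm(pfac + (Hinge(nm, t_, "+", linear=True),))
                    ]
                    ncols = [pcol * x]
                else:
                    nterms = [
                        BasisTerm(pfac + (Hinge(nm, t_, "+"),)),
                        BasisTerm(pfac + (Hinge(nm, t_, "-"),)),
                    ]
                    ncols = [
                        pcol * np.maximum(0.0, x - t_),
                        pcol * np.maximum(0.0, t_ - x),
                    ]
                if len(ncols) > budget:
                    continue
                best = (red, nterms, ncols)

        if best is None:
            break
        _, nterms, ncols = best
        B_new = np.column_stack([B] + ncols)
        _, rss_new = ols_fit(B_new, y)  # exact refit of the accepted state
        if rss_prev - rss_new <= config.rel_tol * rss_prev:
            break
        terms.extend(nterms)
        term_cols.extend(ncols)
        B = B_new
        rss_prev = rss_new
        trace.append(rss_new)

    return terms, trace


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------


def backward_pass(
    terms: list[BasisTerm], D: DesignMatrix, config: FitConfig = FitConfig()
) -> tuple[MarsModel, PruneTrace]:
    """GCV-driven pruning of the forward terms.

    Visits a nested sequence of subsets (full model down to intercept
    only), at each step deleting the term whose removal yields the lowest
    GCV, then returns the subset with the global minimum GCV over the
    whole trace, refitted by OLS.
    """
    y = D.y
    n = y.size
    term_cols = [basis_matrix([t], D)[:, 1] for t in terms]

    def fit_subset(idx: tuple[int, ...]) -> tuple[np.ndarray, float, float]:
        B = np.column_stack([np.ones(n)] + [term_cols[i] for i in idx])
        beta, rss = ols_fit(B, y)
        eff = effective_params(1 + len(idx), config)
        # an over-parameterised subset (eff >= n) can occur for very small
        # samples; it is traced but can never be selected
        g = gcv(rss, n, eff) if eff < n else float("inf")
        return beta, rss, g

    current = tuple(range(len(terms)))
    _, rss0, g0 = fit_subset(current)
    subsets: list[tuple[frozenset[int], float, float]] = [
        (frozenset(current), rss0, g0)
    ]
    while current:
        best: tuple[float, tuple[int, ...], float] | None = None
        for i in current:
            sub = tuple(j for j in current if j != i)
            _, rss_s, g_s = fit_subset(sub)
            if best is None or g_s < best[0]:
                best = (g_s, sub, rss_s)
        assert best is not None
        current = best[1]
        subsets.append((frozenset(current), best[2], best[0]))

    # Global GCV minimiser; differences below 1e-10 of the null-model GCV
    # are numerical noise (e.g. exact interpolation, where every super-set
    # of the true terms has RSS ~ 0), so among near-ties the smallest
    # subset wins.
    tss_ = float(((y - y.mean()) ** 2).sum())
    gmin = min(s[2] for s in subsets)
    tie_tol = 1e-10 * _null_gcv(tss_, n) if tss_ > 0 else 0.0
    best_index = max(
        k for k in range(len(subsets)) if subsets[k][2] <= gmin + tie_tol
    )
    chosen = sorted(subsets[best_index][0])
    beta, rss, g = fit_subset(tuple(chosen))
    fitted = [replace(terms[i], coefficient=float(beta[k + 1])) for k, i in enumerate(chosen)]

    tss = float(((y - y.mean()) ** 2).sum())
    if tss > 0.0:
        rsq = 1.0 - rss / tss
        grsq = 1.0 - g / _null_gcv(tss, n)
    else:
        # degenerate constant response: no variance to explain
        rsq = grsq = 0.0
    model = MarsModel(
        intercept=float(beta[0]),
        terms=fitted,
        n_train=n,
        rss=rss,
        gcv=g,
        rsq=rsq,
        grsq=grsq,
        config=config,
        predictor_names=list(D.column_names),
    )
    trace = PruneTrace(terms=list(terms), subsets=subsets, best_index=best_index)
    return model, trace


def fit(
    D: DesignMatrix, config: FitConfig = FitConfig()
) -> tuple[MarsModel, PruneTrace]:
    """Forward growth followed by backward pruning; fully deterministic."""
    terms, _ = forward_pass(D, config)
    return backward_pass(terms, D, config)


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------


def variable_importance(
    trace: PruneTrace,
    model: MarsModel,
    predictors: list[str] | None = None,
) -> ImportanceTable:
    """Score predictors from the pruning trace.

    n_subsets(v) counts trace subsets containing at least one term using v.
    The GCV (RSS) score of v accumulates the GCV (RSS) increase incurred
    whenever a term using v is deleted along the trace, rescaled so the
    maximum over used variables is 100.  Predictors absent from the final
    model are flagged unused and carry no scores.
    """
    terms = trace.terms
    if predictors is None:
        predictors = list(model.predictor_names) or sorted(
            {v for t in terms for v in t.variables}
        )
    acc_gcv: dict[str, float] = {v: 0.0 for v in predictors}
    acc_rss: dict[str, float] = {v: 0.0 for v in predictors}
    for k in range(1, len(trace.subsets)):
        prev_set, prev_rss, prev_gcv = trace.subsets[k - 1]
        cur_set, cur_rss, cur_gcv = trace.subsets[k]
        removed = prev_set - cur_set
        for i in removed:
            for v in terms[i].variables:
                if v in acc_gcv:
                    acc_gcv[v] += cur_gcv - prev_gcv
                    acc_rss[v] += cur_rss - prev_rss

    n_subsets = {
        v: sum(
            1
            for s, _, _ in trace.subsets
            if any(v in terms[i].variables for i in s)
        )
        for v in predictors
    }
    used = {v for t in model.terms for v in t.variables}

    def _scale(acc: dict[str, float]) -> dict[str, float]:
        # a variable whose deletions never cost GCV/RSS scores 0, not negative
        vals = {v: max(acc[v], 0.0) for v in used}
        top = max(vals.values()) if vals else 0.0
        if top <= 0.0:
            return {v: 100.0 for v in used}
        return {v: 100.0 * (vals[v] / top) for v in used}

    gcv_scores = _scale(acc_gcv)
    rss_scores = _scale(acc_rss)

    rows = []
    for v in predictors:
        if v in used:
            rows.append(
                ImportanceRow(
                    var=v,
                    used=True,
                    n_subsets=n_subsets[v],
                    gcv_score=gcv_scores[v],
                    rss_score=rss_scores[v],
                )
            )
        else:
            rows.append(ImportanceRow(var=v, used=False))
    rows.sort(
        key=lambda r: (
            not r.used,
            -(r.gcv_score or 0.0),
            -(r.n_subsets or 0),
            r.var,
        )
    )
    return ImportanceTable(rows)


# ---------------------------------------------------------------------------
# reporting and serialization
# ---------------------------------------------------------------------------


def render_factor(h: Hinge) -> str:
    if h.linear:
        return h.var
    k = f"{h.knot:.5f}"
    if h.direction == "+":
        return f"max({h.var}-{k})"
    return f"max({k}-{h.var})"


def render_term(term: BasisTerm) -> str:
    return " ".join(render_factor(f) for f in term.factors)


def term_signature(term: BasisTerm) -> tuple:
    """Canonical, render/parse-stable structure of a term.

    Linear factors carry no knot in the rendered grammar (the bare
    variable evaluates identically whatever the knot), so they are
    signed by name only; hinge factors by (var, direction, knot to 5
    decimals), matching the printed precision.
    """
    return tuple(
        (f.var, "lin") if f.linear else (f.var, f.direction, round(f.knot, 5))
        for f in term.factors
    )


_FACTOR_RE = re.compile(
    r"max\(([A-Za-z_]\w*)-(-?\d+(?:\.\d+)?)\)"  # max(VAR-knot)
    r"|max\((-?\d+(?:\.\d+)?)-([A-Za-z_]\w*)\)"  # max(knot-VAR)
    r"|([A-Za-z_]\w*)"  # bare VAR (linear factor)
)


def parse_term(text: str) -> BasisTerm:
    """Parse the rendered term grammar back into a BasisTerm (no coefficient)."""
    factors = []
    pos = 0
    s = text.strip()
    while pos < len(s):
        if s[pos].isspace():
            pos += 1
            continue
        m = _FACTOR_RE.match(s, pos)
        if not m:
            raise MarsError(f"cannot parse term {text!r} at offset {pos}")
        if m.group(1) is not None:
            factors.append(Hinge(m.group(1), float(m.group(2)), "+"))
        elif m.group(3) is not None:
            factors.append(Hinge(m.group(4), float(m.group(3)), "-"))
        else:
            factors.append(Hinge(m.group(5), 0.0, "+", linear=True))
        pos = m.end()
    if not factors:
        raise MarsError(f"empty term {text!r}")
    return BasisTerm(tuple(factors))


def model_report(
    model: MarsModel,
    importance: ImportanceTable | None = None,
    forward_n_terms: int | None = None,
) -> str:
    """Plain-text report: equations block, fit statistics, term and
    predictor counts, importance ranking.  Knots print to 5 decimals."""
    lines = ["Corresponding Equations of the Model"]
    lines.append(f"{'Intercept':<12} {'-':<55} {model.intercept:.5f}")
    for i, t in enumerate(model.terms, start=1):
        lines.append(f"{'BF' + str(i):<12} {render_term(t):<55} {t.coefficient:.5f}")
    lines.append("Main Features of the Model")
    lines.append(f"GCV:  {model.gcv:.8f}")
    lines.append(f"RSS:  {model.rss:.5f}")
    lines.append(f"GRSq: {model.grsq:.7f}")
    lines.append(f"RSq:  {model.rsq:.7f}")
    total = forward_n_terms if forward_n_terms is not None else model.n_terms
    lines.append(
        f"Terms (BFs): Selected {model.n_terms} of {total} "
        "(including the intercept term)"
    )
    n_preds = len(model.predictor_names) or len(model.used_variables)
    lines.append(
        f"Predictors: Selected {len(model.used_variables)} of {n_preds}"
    )
    if importance is not None:
        order = [r.var for r in importance.rows if r.used]
        unused = [r.var for r in importance.rows if not r.used]
        line = "Predictor importance (in order): " + ", ".join(order)
        if unused:
            line += f" (unused: {', '.join(unused)})"
        lines.append(line)
    return "\n".join(lines)


def parse_report_terms(report: str) -> tuple[float, list[BasisTerm]]:
    """Recover (intercept, terms with coefficients) from a report's
    equations block; inverse of the rendering up to 5-decimal knots."""
    intercept = None
    terms: list[BasisTerm] = []
    for line in report.splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "Intercept":
            intercept = float(parts[-1])
        elif re.fullmatch(r"BF\d+", parts[0]):
            coef = float(parts[-1])
            expr = " ".join(parts[1:-1])
            terms.append(replace(parse_term(expr), coefficient=coef))
        elif parts[0] == "Main":
            break
    if intercept is None:
        raise MarsError("no intercept line found in report")
    return intercept, terms


def model_to_json(model: MarsModel) -> str:
    payload = {
        "intercept": model.intercept,
        "terms": [
            {
                "coefficient": t.coefficient,
                "factors": [
                    {
                        "var": h.var,
                        "knot": h.knot,
                        "direction": h.direction,
                        "linear": h.linear,
                    }
                    for h in t.factors
                ],
            }
            for t in model.terms
        ],
        "n_train": model.n_train,
        "rss": model.rss,
        "gcv": model.gcv,
        "rsq": model.rsq,
        "grsq": model.grsq,
        "predictor_names": model.predictor_names,
        "config": {
            "max_terms": model.config.max_terms,
            "max_degree": model.config.max_degree,
            "penalty": model.config.penalty,
            "gcv_convention": model.config.gcv_convention,
            "forbid_self_interaction": model.config.forbid_self_interaction,
            "rel_tol": model.config.rel_tol,
        },
    }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> MarsModel:
    d = json.loads(text)
    terms = [
        BasisTerm(
            tuple(
                Hinge(f["var"], f["knot"], f["direction"], f["linear"])
                for f in t["factors"]
            ),
            coefficient=t["coefficient"],
        )
        for t in d["terms"]
    ]
    return MarsModel(
        intercept=d["intercept"],
        terms=terms,
        n_train=d["n_train"],
        rss=d["rss"],
        gcv=d["gcv"],
        rsq=d["rsq"],
        grsq=d["grsq"],
        config=FitConfig(**d["config"]),
        predictor_names=d["predictor_names"],
    )
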