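"""Nonlinear (logit-link) multivariate decomposition of a prevalence change.

The change in weighted mean predicted prevalence between a baseline survey
B and a comparison survey A is decomposed, on the probability scale, into

    total = E + C
    E = meanW_A[F(X_A b_A)] - meanW_B[F(X_B b_A)]   (endowments)
    C = meanW_B[F(X_B b_A)] - meanW_B[F(X_B b_B)]   (coefficients)

with F the logistic CDF and meanW a weight-normalized average over the
named survey's rows.  E is the part of the differential owing to
differences in covariate composition (evaluated at A's coefficients); C is
the part attributable to differences in the coefficients of effect,
including the intercept, evaluated at B's composition.

Detailed per-covariate contributions use first-order linearization shares

    E_k = E * (xbarA_k - xbarB_k) b_A,k / sum_j (xbarA_j - xbarB_j) b_A,j
    C_k = C * xbarB_k (b_A,k - b_B,k) / sum_j xbarB_j (b_A,j - b_B,j)

optionally after re-expressing each categorical variable's effects in
deviation-from-mean form (reference-category normalization), which makes
per-category rows invariant to the choice of omitted baseline.  Standard
errors come from the delta method, treating the two surveys' fits as
independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import ContractError, DesignMatrix, NutridecompError, Schema
from .weighted_logit import LogitFit

__all__ = [
    "DecompositionResult",
    "DegenerateAllocationError",
    "UndefinedPercentageError",
    "decompose",
    "normalize_categorical",
    "detailed_decompose",
    "delta_se",
    "pct_contribution",
    "Z_95",
]

Z_95 = 1.959964  # two-sided 95% normal quantile

_DENOM_TOL = 1e-12
_TOTAL_TOL = 1e-10


class DegenerateAllocationError(NutridecompError):
    """A linearization denominator vanishes while its component does not."""


class UndefinedPercentageError(NutridecompError):
    """Percentage contribution requested against a zero total."""


# ---------------------------------------------------------------------------
# totals

def _check_pair(design_A: DesignMatrix, design_B: DesignMatrix,
                fit_A: LogitFit, fit_B: LogitFit) -> None:
    if not design_A.same_structure(design_B):
        raise ContractError("survey designs have different column structure")
    for f, d, tag in ((fit_A, design_A, "A"), (fit_B, design_B, "B")):
        if f.n_params != d.n_cols:
            raise ContractError(f"fit {tag} dimension does not match its design")


def _components(beta_A: np.ndarray, beta_B: np.ndarray,
                design_A: DesignMatrix, design_B: DesignMatrix) -> tuple[float, float]:
    wA, wB = design_A.weights, design_B.weights
    mA_A = float((wA * expit(design_A.values @ beta_A)).sum() / wA.sum())
    mB_A = float((wB * expit(design_B.values @ beta_A)).sum() / wB.sum())
    mB_B = float((wB * expit(design_B.values @ beta_B)).sum() / wB.sum())
    return mA_A - mB_A, mB_A - mB_B


def decompose(design_A: DesignMatrix, design_B: DesignMatrix,
              fit_A: LogitFit, fit_B: LogitFit,
              composition_variance: bool = True) -> "DecompositionResult":
    """Two-component decomposition (totals only, with delta-method SEs).

    ``composition_variance`` (default) reports component SEs from full
    per-observation influence functions, which include the sampling noise
    of the covariate compositions on top of coefficient uncertainty; set
    it False for the classical composition-conditional variance.
    """
    _check_pair(design_A, design_B, fit_A, fit_B)
    E, C = _components(fit_A.beta, fit_B.beta, design_A, design_B)
    E_se, C_se = delta_se(design_A, design_B, fit_A, fit_B,
                          include_composition=composition_variance)
    total = E + C
    if abs(total) > _DENOM_TOL:
        pct_E = pct_contribution(E, total)
        pct_C = pct_contribution(C, total)
    else:
        pct_E = pct_C = float("nan")
    return DecompositionResult(
        total=total, E=E, C=C, E_se=E_se, C_se=C_se,
        pct_E=pct_E, pct_C=pct_C, detail=None, normalized=False,
    )


# ---------------------------------------------------------------------------
# reference-category normalization (deviation coding)

def _expansion(groups: dict[str, list[int]], columns: list[str], k: int,
               schema: Schema | None):
    """Build the linear map T from raw dummy coefficients to deviation-coded
    coefficients over an expanded column set that includes every category.

    Returns (T, expanded_labels, expanded_groups, expanded_var_of_col).
    """
    rows: list[np.ndarray] = []
    labels: list[str] = ["intercept"]
    exp_groups: dict[str, list[int]] = {}
    intercept_row = np.zeros(k)
    intercept_row[0] = 1.0
    for var, idx in groups.items():
        n_levels = len(idx) + 1
        intercept_row += _group_mean_row(idx, k, n_levels)
    rows.append(intercept_row)

    for var, idx in groups.items():
        n_levels = len(idx) + 1
        mean_row = _group_mean_row(idx, k, n_levels)
        if schema is not None:
            v = schema[var]
            cats = list(v.categories)
            ref = v.reference
        else:
            cats = None
            ref = None
        # deterministic order: reference first, then dummy order
        ordered: list[tuple[str, int | None]] = []
        if cats is not None:
            nonref = [c for c in cats if c != ref]
            ordered = [(ref, None)] + [
                (c, idx[i]) for i, c in enumerate(nonref)
            ]
        else:
            ordered = [("<reference>", None)] + [
                (columns[j].split("=", 1)[1] if "=" in columns[j] else columns[j], j)
                for j in idx
            ]
        exp_groups[var] = []
        for cat, j in ordered:
            row = -mean_row.copy()
            if j is not None:
                row[j] += 1.0
            exp_groups[var].append(len(labels))
            labels.append(f"{var}={cat}")
            rows.append(row)
    T = np.vstack(rows)
    return T, labels, exp_groups


def _group_mean_row(idx: list[int], k: int, n_levels: int) -> np.ndarray:
    row = np.zeros(k)
    for j in idx:
        row[j] = 1.0 / n_levels
    return row


def normalize_categorical(fit: LogitFit, schema: Schema | None = None) -> LogitFit:
    """Re-express categorical effects in deviation-from-mean form.

    For each categorical variable the per-category effects (reference
    effect 0) have their unweighted mean subtracted; the subtracted means
    are absorbed into the intercept.  The returned fit lives on an
    *expanded* column set with one coefficient per category (reference
    included), and its covariance is the corresponding linear transform
    T cov T' of the original.  Linear predictors are unchanged when the
    expanded design (one dummy per category) is used.
    """
    T, labels, exp_groups = _expansion(fit.groups, fit.columns, fit.n_params, schema)
    return LogitFit(
        beta=T @ fit.beta,
        cov=T @ fit.cov @ T.T,
        n_obs=fit.n_obs,
        converged=fit.converged,
        iterations=fit.iterations,
        loglik=fit.loglik,
        columns=labels,
        groups=exp_groups,
    )


def _expanded_means(design: DesignMatrix) -> np.ndarray:
    """Weighted column means on the expanded (all-categories) column set."""
    xbar = design.weighted_column_means()
    out = [1.0]
    for var, idx in design.groups.items():
        ref_share = 1.0 - sum(xbar[j] for j in idx)
        out.append(ref_share)
        out.extend(xbar[j] for j in idx)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# detailed decomposition

@dataclass
class DecompositionResult:
    """Totals, detailed per-category contributions, SEs and shares.

    ``detail`` is a DataFrame with one row per (variable, category) plus a
    ``Constant`` row for the intercept's C term; percentage shares are of
    the grand total (E + C) and are NaN when the total is numerically zero.
    """

    total: float
    E: float
    C: float
    E_se: float
    C_se: float
    pct_E: float
    pct_C: float
    detail: pd.DataFrame | None
    normalized: bool
    baseline_survey: str = ""
    comparison_survey: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Report table: detail rows plus component/total summary rows."""
        rows = [] if self.detail is None else [self.detail]
        summary = pd.DataFrame([
            {"variable": "Total", "category": "E", "E": self.E,
             "E_se": self.E_se, "E_pct": self.pct_E,
             "C": np.nan, "C_se": np.nan, "C_pct": np.nan},
            {"variable": "Total", "category": "C", "E": np.nan,
             "E_se": np.nan, "E_pct": np.nan,
             "C": self.C, "C_se": self.C_se, "C_pct": self.pct_C},
            {"variable": "Total", "category": "E+C", "E": self.total,
             "E_se": np.nan, "E_pct": np.nan, "C": np.nan,
             "C_se": np.nan, "C_pct": np.nan},
        ])
        rows.append(summary)
        out = pd.concat(rows, ignore_index=True)
        for comp in ("E", "C"):
            out[f"{comp}_ci_low"] = out[comp] - Z_95 * out[f"{comp}_se"]
            out[f"{comp}_ci_high"] = out[comp] + Z_95 * out[f"{comp}_se"]
        return out[["variable", "category",
                    "E", "E_se", "E_ci_low", "E_ci_high", "E_pct",
                    "C", "C_se", "C_ci_low", "C_ci_high", "C_pct"]]


def _allocate(total: float, numerators: np.ndarray) -> np.ndarray:
    """Split ``total`` across terms proportionally to ``numerators``."""
    denom = numerators.sum()
    if abs(denom) < _DENOM_TOL:
        if abs(total) > _TOTAL_TOL:
            raise DegenerateAllocationError(
                f"linearization denominator {denom:.3g} vanishes for a "
                f"component of size {total:.3g}"
            )
        return np.zeros_like(numerators)
    return total * numerators / denom


def _detail_terms(beta_A: np.ndarray, beta_B: np.ndarray,
                  design_A: DesignMatrix, design_B: DesignMatrix,
                  xbar_A: np.ndarray, xbar_B: np.ndarray,
                  T: np.ndarray | None) -> np.ndarray:
    """All detailed terms as one vector [E_1..E_K, C_0, C_1..C_K].

    ``xbar_*`` and ``T`` live on the reporting column set (expanded when
    normalization is on, raw otherwise); predictions always use the raw
    designs and coefficients so totals never depend on the coding.
    """
    E, C = _components(beta_A, beta_B, design_A, design_B)
    bA = T @ beta_A if T is not None else beta_A
    bB = T @ beta_B if T is not None else beta_B
    E_terms = _allocate(E, (xbar_A - xbar_B) * bA)
    C_terms = _allocate(C, xbar_B * (bA - bB))
    return np.concatenate([E_terms, C_terms])


def detailed_decompose(design_A: DesignMatrix, design_B: DesignMatrix,
                       fit_A: LogitFit, fit_B: LogitFit,
                       normalize: bool = True,
                       composition_variance: bool = True) -> DecompositionResult:
    """Decomposition with per-covariate detail, SEs and percentage shares.

    With ``normalize`` (default) every category of every variable gets a
    row and the rows are invariant to reference-category choice; without
    it only non-reference dummies appear, as in raw dummy coding.  The
    intercept contributes to C only (the ``Constant`` row).

    Component totals carry influence-function SEs by default (see
    :func:`decompose`); per-term detail SEs are always the classical
    coefficient-only delta method, conditional on composition.
    """
    _check_pair(design_A, design_B, fit_A, fit_B)
    schema = design_A.schema

    if normalize:
        T, labels, groups = _expansion(fit_A.groups, fit_A.columns,
                                       fit_A.n_params, schema)
        xbar_A = _expanded_means(design_A)
        xbar_B = _expanded_means(design_B)
    else:
        T, labels = None, list(fit_A.columns)
        groups = fit_A.groups
        xbar_A = design_A.weighted_column_means()
        xbar_B = design_B.weighted_column_means()

    E, C = _components(fit_A.beta, fit_B.beta, design_A, design_B)
    total = E + C
    terms = _detail_terms(fit_A.beta, fit_B.beta, design_A, design_B,
                          xbar_A, xbar_B, T)
    n_rep = len(labels)
    E_terms, C_terms = terms[:n_rep], terms[n_rep:]

    term_se = _delta_se_terms(design_A, design_B, fit_A, fit_B,
                              xbar_A, xbar_B, T)
    E_se_terms, C_se_terms = term_se[:n_rep], term_se[n_rep:]
    E_se, C_se = delta_se(design_A, design_B, fit_A, fit_B,
                          include_composition=composition_variance)

    def pct(x: np.ndarray | float):
        if abs(total) < _DENOM_TOL:
            return np.full_like(np.asarray(x, dtype=float), np.nan)
        return 100.0 * np.asarray(x, dtype=float) / total

    rows = []
    for var, idx in groups.items():
        for j in idx:
            cat = labels[j].split("=", 1)[1]
            rows.append({
                "variable": var, "category": cat,
                "E": E_terms[j], "E_se": E_se_terms[j],
                "E_pct": float(pct(E_terms[j])),
                "C": C_terms[j], "C_se": C_se_terms[j],
                "C_pct": float(pct(C_terms[j])),
            })
    rows.append({
        "variable": "Constant", "category": "",
        "E": 0.0, "E_se": 0.0, "E_pct": 0.0 if abs(total) >= _DENOM_TOL else np.nan,
        "C": C_terms[0], "C_se": C_se_terms[0], "C_pct": float(pct(C_terms[0])),
    })
    detail = pd.DataFrame(rows)

    if abs(total) >= _DENOM_TOL:
        pct_E, pct_C = pct_contribution(E, total), pct_contribution(C, total)
    else:
        pct_E = pct_C = float("nan")

    return DecompositionResult(
        total=total, E=E, C=C, E_se=E_se, C_se=C_se,
        pct_E=pct_E, pct_C=pct_C, detail=detail, normalized=normalize,
    )


# ---------------------------------------------------------------------------
# delta-method variance

def _grad_components(beta_A, beta_B, design_A, design_B):
    """Analytic gradients of (E, C) with respect to (beta_A, beta_B)."""
    wA, wB = design_A.weights, design_B.weights
    XA, XB = design_A.values, design_B.values
    pA_A = expit(XA @ beta_A)
    pB_A = expit(XB @ beta_A)
    pB_B = expit(XB @ beta_B)
    mA = lambda v, w: (w[:, None] * v).sum(axis=0) / w.sum()
    dA_A = mA(XA * (pA_A * (1 - pA_A))[:, None], wA)
    dB_A = mA(XB * (pB_A * (1 - pB_A))[:, None], wB)
    dB_B = mA(XB * (pB_B * (1 - pB_B))[:, None], wB)
    gE = np.concatenate([dA_A - dB_A, np.zeros_like(beta_B)])
    gC = np.concatenate([dB_A, -dB_B])
    return gE, gC


def delta_se(design_A: DesignMatrix, design_B: DesignMatrix,
             fit_A: LogitFit, fit_B: LogitFit,
             include_composition: bool = False) -> tuple[float, float]:
    """Delta-method standard errors of E and C.

    By default, analytic gradients with respect to the stacked coefficient
    vector and block-diagonal covariance (surveys independent): the
    classical variance for this decomposition, conditional on the realized
    covariate compositions.  With ``include_composition`` the variance is
    computed from full per-observation influence functions, which adds the
    sampling variability of the weighted covariate compositions (and its
    covariance with the coefficient estimates); this tracks a nonparametric
    bootstrap over children much more closely, especially for E.
    """
    if fit_A.cov is None or fit_B.cov is None:
        raise ContractError("fits must carry covariance matrices")
    if not include_composition:
        gE, gC = _grad_components(fit_A.beta, fit_B.beta, design_A, design_B)
        kA = fit_A.n_params

        def quad(g):
            return float(g[:kA] @ fit_A.cov @ g[:kA] + g[kA:] @ fit_B.cov @ g[kA:])

        return float(np.sqrt(quad(gE))), float(np.sqrt(quad(gC)))
    return _influence_se(design_A, design_B, fit_A, fit_B)


def _influence_se(design_A, design_B, fit_A, fit_B):
    """Full-linearization SEs of E and C via per-observation influence
    functions (coefficient + composition terms, per survey)."""
    wA, wB = design_A.weights, design_B.weights
    XA, XB = design_A.values, design_B.values
    bA, bB = fit_A.beta, fit_B.beta
    pA_A = expit(XA @ bA)
    pB_A = expit(XB @ bA)
    pB_B = expit(XB @ bB)
    mA_A = float((wA * pA_A).sum() / wA.sum())
    mB_A = float((wB * pB_A).sum() / wB.sum())
    mB_B = float((wB * pB_B).sum() / wB.sum())

    # beta influence: IF(beta_hat) per row = H^-1 w_i s_i  (sum convention)
    def beta_if(X, y, w, p):
        H = X.T @ (X * (w * p * (1 - p))[:, None])
        score_rows = ((w * (y - p))[:, None] * X)
        try:
            return np.linalg.solve(H, score_rows.T).T
        except np.linalg.LinAlgError:
            # degenerate design (e.g. constructed fixtures); estimated fits
            # cannot reach here because fitting rejects singular information
            return score_rows @ np.linalg.pinv(H)

    ifbA = beta_if(XA, design_A.outcome, wA, pA_A)
    ifbB = beta_if(XB, design_B.outcome, wB, pB_B)
    gE, gC = _grad_components(bA, bB, design_A, design_B)
    kA = fit_A.n_params

    # composition influence of a weighted mean m = sum w f / sum w:
    # per row (w_i / wbar_sum) * (f_i - m)
    compA_A = wA / wA.sum() * (pA_A - mA_A)
    compB_A = wB / wB.sum() * (pB_A - mB_A)
    compB_B = wB / wB.sum() * (pB_B - mB_B)

    E_ifA = compA_A + ifbA @ gE[:kA]
    E_ifB = -compB_A
    C_ifA = ifbA @ gC[:kA]
    C_ifB = (compB_A - compB_B) + ifbB @ gC[kA:]

    var_E = float((E_ifA ** 2).sum() + (E_ifB ** 2).sum())
    var_C = float((C_ifA ** 2).sum() + (C_ifB ** 2).sum())
    return float(np.sqrt(var_E)), float(np.sqrt(var_C))


def _delta_se_terms(design_A, design_B, fit_A, fit_B, xbar_A, xbar_B, T,
                    step: float = 1e-6) -> np.ndarray:
    """Delta-method SEs of every detailed term.

    Gradients by central finite differences (step 1e-6) in the stacked raw
    coefficient vector; covariance block-diagonal across surveys.
    """
    kA, kB = fit_A.n_params, fit_B.n_params
    theta = np.concatenate([fit_A.beta, fit_B.beta])

    def f(th):
        return _detail_terms(th[:kA], th[kA:], design_A, design_B,
                             xbar_A, xbar_B, T)

    m = len(f(theta))
    J = np.empty((m, kA + kB))
    for j in range(kA + kB):
        up, dn = theta.copy(), theta.copy()
        up[j] += step
        dn[j] -= step
        J[:, j] = (f(up) - f(dn)) / (2 * step)
    var = (J[:, :kA] @ fit_A.cov * J[:, :kA]).sum(axis=1) \
        + (J[:, kA:] @ fit_B.cov * J[:, kA:]).sum(axis=1)
    return np.sqrt(np.clip(var, 0.0, None))


# ---------------------------------------------------------------------------
# percentage shares

def pct_contribution(component: float, total: float) -> float:
    """Percentage contribution 100 * component / total."""
    if total == 0:
        raise UndefinedPercentageError("percentage undefined for zero total")
    return 100.0 * component / total
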