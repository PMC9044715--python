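"""MANOVA on the (cos, sin) embedding of a circular response.

The circular response theta is linearised into the two orthogonal channels
cos(theta) and sin(theta), which form the columns of an n x 2 response
matrix Y.  A multivariate linear model Y = X B + U is fitted by least
squares and each model term — including the intercept — is tested with
Pillai's trace on its sequential (Type-I) hypothesis SSCP.  Under the
intercept-only model, a significant intercept means the mean vector of the
sample differs from the centre of the unit circle, i.e. the sample is not
uniformly oriented; grouping factors and linear covariates are tested in
the same fit.

Theory p-values come from the standard Pillai approximate-F transform.
Because (cos, sin) pairs are not bivariate normal, the theory test is
slightly liberal at very small n; :func:`mc_calibrated_manova` corrects
this by ranking each term's observed p-value against the p-values obtained
from re-analyses of uniform random samples on the same design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import AngleSample, EmbeddedResponse, TWO_PI, embed
from .distributions import as_rng
from .uniformity import mc_pvalue

_RESPONSES = 2  # cos and sin channels


class DesignError(ValueError):
    """Invalid or rank-deficient design matrix."""


class DegenerateResponseError(ValueError):
    """Residual SSCP singular (e.g. all angles identical)."""


# ---------------------------------------------------------------------------
# model specification and design construction
# ---------------------------------------------------------------------------

TERM_KINDS = ("intercept", "covariate", "factor", "interaction")


@dataclass(frozen=True)
class Term:
    name: str
    kind: str
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered list of model terms; the order fixes the sequential partition."""

    terms: tuple[Term, ...]
    include_intercept: bool = True

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        if self.include_intercept:
            if not terms or terms[0].kind != "intercept":
                terms = (Term("(Intercept)", "intercept"),) + tuple(
                    t for t in terms if t.kind != "intercept"
                )
        seen: list[str] = []
        for t in terms:
            if t.kind == "intercept" and t is not terms[0]:
                raise ValueError("intercept must be the first term")
            if t.kind == "interaction":
                missing = [c for c in t.columns if c not in seen]
                if missing:
                    raise ValueError(
                        f"interaction {t.name!r} precedes its main effects {missing}"
                    )
            seen.extend(t.columns)
        object.__setattr__(self, "terms", terms)

    @classmethod
    def from_term_names(
        cls,
        names,
        data: pd.DataFrame,
        factors: tuple[str, ...] = (),
        include_intercept: bool = True,
    ) -> "ModelSpec":
        """Build a spec from names like ``["group", "age", "group:age"]``.

        Kinds are inferred from the data: non-numeric columns (or columns
        listed in `factors`) are treatment-coded factors, numeric columns
        are covariates used as-is, and colon-joined names are interactions.
        """

        def base_kind(col: str) -> str:
            if col not in data.columns:
                raise DesignError(
                    f"unknown column {col!r}; available: {list(data.columns)}"
                )
            if col in factors or not pd.api.types.is_numeric_dtype(data[col]):
                return "factor"
            return "covariate"

        terms = []
        for name in names:
            if ":" in name:
                cols = tuple(name.split(":"))
                for c in cols:
                    base_kind(c)
                terms.append(Term(name, "interaction", cols))
            else:
                terms.append(Term(name, base_kind(name), (name,)))
        return cls(tuple(terms), include_intercept=include_intercept)


def _code_column(data: pd.DataFrame, col: str, kind: str):
    """Coded columns and labels for a single variable."""
    if col not in data.columns:
        raise DesignError(
            f"unknown column {col!r}; available: {list(data.columns)}"
        )
    if kind == "factor":
        values = data[col].to_numpy()
        levels = sorted(pd.unique(values).tolist())
        if len(levels) < 2:
            raise DesignError(f"factor {col!r} has a single observed level")
        # treatment contrasts, first sorted level as reference
        cols = [
            (values == lev).astype(float) for lev in levels[1:]
        ]
        labels = [f"{col}[{lev}]" for lev in levels[1:]]
        return np.column_stack(cols), labels
    vals = pd.to_numeric(data[col]).to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DesignError(f"covariate {col!r} contains non-finite values")
    return vals[:, None], [col]


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Design matrix and per-term column blocks for a model spec.

    Returns ``(X, blocks, labels)`` where `blocks` maps each term to its
    contiguous column slice of X.  Factors use treatment contrasts with the
    first sorted level as reference; covariates enter uncentred, so the
    intercept hypothesis is "mean response = (0, 0) at covariate value 0
    and reference factor levels"; interactions are element-wise products of
    the coded columns of their constituents.
    """
    n = len(data)
    pieces: list[np.ndarray] = []
    labels: list[str] = []
    blocks: list[tuple[Term, slice]] = []
    coded_cache: dict[str, tuple[np.ndarray, list[str]]] = {}

    # resolve base-column coding first so interactions reuse it
    for term in spec.terms:
        for col, kind in zip(
            term.columns,
            [term.kind] * len(term.columns)
            if term.kind != "interaction"
            else [
                "factor"
                if not pd.api.types.is_numeric_dtype(data[col])
                else "covariate"
                for col in term.columns
            ],
        ):
            if col not in coded_cache:
                coded_cache[col] = _code_column(data, col, kind)

    start = 0
    for term in spec.terms:
        if term.kind == "intercept":
            mat, labs = np.ones((n, 1)), ["(Intercept)"]
        elif term.kind in ("factor", "covariate"):
            mat, labs = coded_cache[term.columns[0]]
        else:  # interaction: all pairwise products across constituents
            mat, labs = coded_cache[term.columns[0]]
            for col in term.columns[1:]:
                nxt, nxt_labs = coded_cache[col]
                mat = np.einsum("ni,nj->nij", mat, nxt).reshape(n, -1)
                labs = [f"{a}:{b}" for a in labs for b in nxt_labs]
        pieces.append(mat)
        labels.extend(labs)
        blocks.append((term, slice(start, start + mat.shape[1])))
        start += mat.shape[1]

    X = np.column_stack(pieces)
    return X, blocks, labels


# ---------------------------------------------------------------------------
# fitting and sequential SSCP partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FittedMlm:
    """A fitted multivariate linear model on the (cos, sin) response."""

    X: np.ndarray
    Y: EmbeddedResponse
    coefficients: np.ndarray
    E: np.ndarray  # residual SSCP, 2x2
    df_error: int
    term_names: tuple[str, ...]
    term_H: tuple[np.ndarray, ...]  # sequential hypothesis SSCPs, 2x2 each
    term_df: tuple[int, ...]
    column_labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.Y.n

    @property
    def k(self) -> int:
        return self.X.shape[1]


def _qr_with_rank_check(X: np.ndarray, blocks) -> tuple[np.ndarray, np.ndarray]:
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    deficient = np.flatnonzero(diag <= tol)
    if deficient.size:
        j = int(deficient[0])
        offender = next(
            (t.name for t, sl in blocks if sl.start <= j < sl.stop), "?"
        )
        raise DesignError(
            f"design matrix is rank deficient at term {offender!r} (column {j})"
        )
    return Q, R


def fit_mlm(X: np.ndarray, Y: EmbeddedResponse, blocks, labels=None) -> FittedMlm:
    """Least-squares fit with sequential (Type-I) SSCP partition.

    Term t's hypothesis SSCP H_t is the increment in explained SSCP when
    t's columns are added after all preceding terms, obtained from the QR
    decomposition of X (successive orthogonal projections in term order).
    With the intercept in the partition, sum_t H_t + E = Y'Y exactly.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise DesignError(
            f"insufficient residual df: n={n} observations for rank-{k} design"
        )
    Q, R = _qr_with_rank_check(X, blocks)
    Ym = Y.Y
    Z = Q.T @ Ym  # k x 2 coordinates in the successive orthogonal basis
    coef = np.linalg.solve(R, Z)
    E = Ym.T @ Ym - Z.T @ Z
    E = (E + E.T) / 2.0
    eigvals = np.linalg.eigvalsh(E)
    if eigvals[0] < -1e-8 * n or eigvals[-1] < 1e-12 * n or np.linalg.det(E) <= 1e-12 * n:
        raise DegenerateResponseError(
            "degenerate response: residual SSCP is singular "
            "(e.g. all angles identical or a perfect fit)"
        )
    term_H = []
    term_df = []
    names = []
    for term, sl in blocks:
        Zt = Z[sl]
        H = Zt.T @ Zt
        term_H.append((H + H.T) / 2.0)
        term_df.append(sl.stop - sl.start)
        names.append(term.name)
    return FittedMlm(
        X=X,
        Y=Y,
        coefficients=coef,
        E=E,
        df_error=n - k,
        term_names=tuple(names),
        term_H=tuple(term_H),
        term_df=tuple(term_df),
        column_labels=tuple(labels) if labels is not None else tuple(
            f"x{j}" for j in range(k)
        ),
    )


# ---------------------------------------------------------------------------
# Pillai trace tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManovaTermResult:
    """Pillai-trace test of one model term."""

    term: str
    pillai: float
    approx_f: float
    df1: float
    df2: float
    p_theory: float
    q: int
    p_mc: float | None = None
    degenerate: bool = False


def pillai_term_test(
    H: np.ndarray, E: np.ndarray, q: int, df_error: int, term: str = ""
) -> ManovaTermResult:
    """Pillai's trace V = tr(H (H+E)^-1) and its approximate F for one term.

    With p = 2 response channels: s = min(p, q), m = (|p - q| - 1)/2,
    n* = (df_error - p - 1)/2, F = ((2n* + s + 1)/(2m + s + 1)) *
    (V/s)/(1 - V/s) on (s(2m + s + 1), s(2n* + s + 1)) df.  A perfect fit
    (V/s = 1) is reported as p = 0 with a degeneracy flag.
    """
    if q < 1:
        raise ValueError("term df q must be >= 1")
    if df_error < _RESPONSES:
        raise ValueError("df_error must be >= 2 for a bivariate response")
    M = H + E
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    if det <= 0:
        raise DegenerateResponseError("H + E singular in Pillai test")
    V = (H[0, 0] * M[1, 1] + H[1, 1] * M[0, 0] - 2.0 * H[0, 1] * M[1, 0]) / det
    s = min(_RESPONSES, q)
    m = (abs(_RESPONSES - q) - 1) / 2.0
    nstar = (df_error - _RESPONSES - 1) / 2.0
    df1 = s * (2.0 * m + s + 1.0)
    df2 = s * (2.0 * nstar + s + 1.0)
    ratio = V / s
    if ratio >= 1.0 - 1e-12:
        return ManovaTermResult(term, float(V), np.inf, df1, df2, 0.0, q, degenerate=True)
    F = ((2.0 * nstar + s + 1.0) / (2.0 * m + s + 1.0)) * ratio / (1.0 - ratio)
    p = float(stats.f.sf(F, df1, df2))
    return ManovaTermResult(term, float(V), float(F), df1, df2, p, q)


def circular_manova(
    sample: AngleSample,
    data: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
) -> list[ManovaTermResult]:
    """Fit the circular MANOVA and test every term, intercept included.

    With no covariate table / spec, fits the intercept-only model, whose
    Pillai test of the intercept is the uniformity test: it asks whether
    the mean (cos, sin) vector differs from the centre (0, 0) of the unit
    circle.
    """
    if data is None:
        data = pd.DataFrame(index=range(sample.n))
    if spec is None:
        spec = ModelSpec(())
    if len(data) != sample.n:
        raise ValueError(
            f"covariate table has {len(data)} rows for {sample.n} angles"
        )
    X, blocks, labels = build_design(data, spec)
    fit = fit_mlm(X, embed(sample), blocks, labels)
    return term_tests(fit)


def term_tests(fit: FittedMlm) -> list[ManovaTermResult]:
    """Pillai test of every term of a fitted model, in term order."""
    return [
        pillai_term_test(H, fit.E, q, fit.df_error, term=name)
        for name, H, q in zip(fit.term_names, fit.term_H, fit.term_df)
    ]


# ---------------------------------------------------------------------------
# batched theory p-values (shared by Monte-Carlo calibration and the
# power harness; one QR of the fixed design serves every response draw)
# ---------------------------------------------------------------------------


def batch_term_pvalues(
    Q: np.ndarray, blocks, theta: np.ndarray, df_error: int
) -> np.ndarray:
    """Theory p-values of every term for each row of an (R, n) angle matrix.

    `Q` is the orthonormal basis of the fixed design (QR of X); the
    sequential SSCPs only need Q' Y, so a batch of responses reduces to one
    einsum.  Returns an (R, n_terms) array.
    """
    C = np.cos(theta)
    S = np.sin(theta)
    Y = np.stack([C, S], axis=-1)  # (R, n, 2)
    Z = np.einsum("nk,rnj->rkj", Q, Y)
    T00 = np.einsum("rn,rn->r", C, C)
    T01 = np.einsum("rn,rn->r", C, S)
    T11 = np.einsum("rn,rn->r", S, S)
    ZtZ = np.einsum("rkj,rkl->rjl", Z, Z)
    E00 = T00 - ZtZ[:, 0, 0]
    E01 = T01 - ZtZ[:, 0, 1]
    E11 = T11 - ZtZ[:, 1, 1]
    out = np.empty((theta.shape[0], len(blocks)))
    for t, (term, sl) in enumerate(blocks):
        Zt = Z[:, sl, :]
        H00 = np.einsum("rk,rk->r", Zt[:, :, 0], Zt[:, :, 0])
        H01 = np.einsum("rk,rk->r", Zt[:, :, 0], Zt[:, :, 1])
        H11 = np.einsum("rk,rk->r", Zt[:, :, 1], Zt[:, :, 1])
        M00 = H00 + E00
        M01 = H01 + E01
        M11 = H11 + E11
        det = M00 * M11 - M01 * M01
        with np.errstate(divide="ignore", invalid="ignore"):
            V = (H00 * M11 + H11 * M00 - 2.0 * H01 * M01) / det
        q = sl.stop - sl.start
        s = min(_RESPONSES, q)
        m = (abs(_RESPONSES - q) - 1) / 2.0
        nstar = (df_error - _RESPONSES - 1) / 2.0
        ratio = np.clip(V / s, 0.0, 1.0 - 1e-15)
        F = ((2.0 * nstar + s + 1.0) / (2.0 * m + s + 1.0)) * ratio / (1.0 - ratio)
        out[:, t] = stats.f.sf(F, s * (2 * m + s + 1), s * (2 * nstar + s + 1))
    return out


def intercept_theory_p_batch(theta: np.ndarray) -> np.ndarray:
    """Intercept-only theory p-value for each row of an (R, n) angle matrix.

    Specialisation of :func:`batch_term_pvalues` to the null model; the
    workhorse of the type-I-error and power simulations.
    """
    n = theta.shape[-1]
    C = np.cos(theta)
    S = np.sin(theta)
    mc = C.mean(axis=-1)
    ms = S.mean(axis=-1)
    H00 = n * mc * mc
    H01 = n * mc * ms
    H11 = n * ms * ms
    T00 = np.einsum("...n,...n->...", C, C)
    T01 = np.einsum("...n,...n->...", C, S)
    T11 = np.einsum("...n,...n->...", S, S)
    det = T00 * T11 - T01 * T01
    V = (H00 * T11 + H11 * T00 - 2.0 * H01 * T01) / det
    ratio = np.clip(V, 0.0, 1.0 - 1e-15)
    F = ((n - 2.0) / 2.0) * ratio / (1.0 - ratio)
    return stats.f.sf(F, 2.0, n - 2.0)


def null_term_pvalues(
    X: np.ndarray, blocks, B: int, rng, chunk: int = 512
) -> np.ndarray:
    """(B, n_terms) theory p-values for uniform random responses on a fixed design."""
    gen = as_rng(rng)
    n, k = X.shape
    Q, _ = np.linalg.qr(X)
    out = np.empty((B, len(blocks)))
    done = 0
    while done < B:
        m = min(chunk, B - done)
        theta = gen.uniform(0.0, TWO_PI, size=(m, n))
        out[done : done + m] = batch_term_pvalues(Q, blocks, theta, n - k)
        done += m
    return out


def mc_calibrated_manova(
    sample: AngleSample,
    data: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    B: int = 9999,
    rng=None,
    null_pvalues: np.ndarray | None = None,
) -> list[ManovaTermResult]:
    """Circular MANOVA with Monte-Carlo calibrated p-values per term.

    The design (covariate table) is held fixed; B replacement responses
    are drawn from Uniform[0, 2*pi), the full analysis is recomputed for
    each, and every term's observed theory p-value is ranked against its
    own null distribution of p-values (lower tail: smaller p is more
    extreme).  This is the small-sample correction for the liberal theory
    test.  `null_pvalues` may be supplied to reuse a precomputed (B,
    n_terms) null table for the same design.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if data is None:
        data = pd.DataFrame(index=range(sample.n))
    if spec is None:
        spec = ModelSpec(())
    if len(data) != sample.n:
        raise ValueError(
            f"covariate table has {len(data)} rows for {sample.n} angles"
        )
    X, blocks, labels = build_design(data, spec)
    fit = fit_mlm(X, embed(sample), blocks, labels)
    observed = term_tests(fit)
    if null_pvalues is None:
        null_pvalues = null_term_pvalues(X, blocks, B, rng)
    results = []
    for t, res in enumerate(observed):
        p_mc = mc_pvalue(res.p_theory, null_pvalues[:, t], tail="lower")
        results.append(replace(res, p_mc=p_mc))
    return results


def results_to_frame(results: list[ManovaTermResult]) -> pd.DataFrame:
    """Tidy per-term table (the machine-readable MANOVA table)."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "df": [r.q for r in results],
            "pillai": [r.pillai for r in results],
            "approx_f": [r.approx_f for r in results],
            "df1": [r.df1 for r in results],
            "df2": [r.df2 for r in results],
            "p_theory": [r.p_theory for r in results],
            "p_mc": [r.p_mc for r in results],
        }
    )
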