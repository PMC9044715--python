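"""Two-stage model selection: eta-squared screening, then exhaustive AIC.

Stage 1 fits the full model and ranks candidate variables by their partial
eta-squared on the two response channels (cos and sin), keeping the top_n.
Stage 2 enumerates every subset of the retained candidates (the intercept
is always included), fits each, and ranks the fits by the mean of the two
channels' Gaussian AICs.  Interactions are never generated automatically:
users list them as explicit candidates, and subsets that contain an
interaction without all of its main effects are not fitted (marginality).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AngleSample, embed
from .manova import (
    FittedMlm,
    ModelSpec,
    Term,
    build_design,
    fit_mlm,
)

MAX_TOP_N = 15  # 2^top_n exhaustive fits; hard guard

CHANNELS = ("cos", "sin")


def eta_squared_per_response(fit: FittedMlm) -> pd.DataFrame:
    """Partial eta-squared of every term on each response channel.

    For channel r and term t: eta2 = SS_t,r / (SS_t,r + SS_resid,r), where
    SS_t,r is the channel-r diagonal entry of the term's sequential
    hypothesis SSCP.  A zero residual SS on a channel is flagged degenerate.
    """
    rows = []
    for name, H in zip(fit.term_names, fit.term_H):
        row: dict = {"term": name}
        for r, channel in enumerate(CHANNELS):
            ss_t = H[r, r]
            ss_e = fit.E[r, r]
            if ss_e <= 0:
                row[f"eta2_{channel}"] = np.nan
                row["degenerate"] = True
            else:
                row[f"eta2_{channel}"] = ss_t / (ss_t + ss_e)
                row.setdefault("degenerate", False)
        rows.append(row)
    return pd.DataFrame(rows)


def mean_aic(fit: FittedMlm) -> float:
    """Mean of the two channels' Gaussian AICs.

    Per channel: AIC = n*log(2*pi*RSS/n) + n + 2*(k + 1), with k design
    columns plus one variance parameter — the conventional full-likelihood
    definition, so values are directly comparable across fits of the same
    data.  Zero residual SS yields -inf (a flagged perfect fit).
    """
    if fit.df_error < 1:
        raise ValueError("mean_aic requires df_error >= 1")
    n = fit.n
    k = fit.k
    aics = []
    for r in range(2):
        rss = fit.E[r, r]
        if rss <= 0:
            return float("-inf")
        aics.append(n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 1))
    return float(np.mean(aics))


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of the two-stage selection."""

    eta_table: pd.DataFrame
    candidate_order: tuple[str, ...]
    aic_table: pd.DataFrame
    best: ModelSpec


def _canonical_candidates(candidates) -> list[str]:
    mains = sorted(c for c in candidates if ":" not in c)
    inters = sorted(c for c in candidates if ":" in c)
    return mains + inters


def _subset_is_hierarchical(subset: tuple[str, ...]) -> bool:
    present = set(subset)
    for name in subset:
        if ":" in name and not all(c in present for c in name.split(":")):
            return False
    return True


def _order_terms(names, data, factors) -> ModelSpec:
    mains = [n for n in names if ":" not in n]
    inters = [n for n in names if ":" in n]
    return ModelSpec.from_term_names(mains + inters, data, factors=factors)


def select_model(
    sample: AngleSample,
    data: pd.DataFrame,
    candidates,
    top_n: int | None = None,
    factors: tuple[str, ...] = (),
    aggregate: str = "mean",
) -> SelectionReport:
    """Screen candidates by eta-squared, then rank all subsets by mean AIC.

    `aggregate` chooses how the two channels' eta-squared values are
    combined for the screening order ("mean" or "max").  The AIC table is
    sorted ascending; ties are broken by fewer terms, then lexicographic
    term names.  The intercept-only model is always among the fits, so
    `best` degrades gracefully to it when no candidate helps.
    """
    candidates = _canonical_candidates(candidates)
    if top_n is None:
        top_n = len(candidates)
    if top_n > MAX_TOP_N:
        raise ValueError(
            f"top_n={top_n} exceeds the exhaustive-enumeration guard {MAX_TOP_N}"
        )
    top_n = min(top_n, len(candidates))

    if candidates:
        full_spec = _order_terms(candidates, data, factors)
        X, blocks, labels = build_design(data, full_spec)
        full_fit = fit_mlm(X, embed(sample), blocks, labels)
        eta = eta_squared_per_response(full_fit)
    else:
        full_spec = ModelSpec(())
        X, blocks, labels = build_design(data, full_spec)
        full_fit = fit_mlm(X, embed(sample), blocks, labels)
        eta = eta_squared_per_response(full_fit)

    scored = eta[eta["term"] != "(Intercept)"].copy()
    if aggregate == "mean":
        scored["score"] = scored[["eta2_cos", "eta2_sin"]].mean(axis=1)
    elif aggregate == "max":
        scored["score"] = scored[["eta2_cos", "eta2_sin"]].max(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    scored = scored.sort_values(["score", "term"], ascending=[False, True])
    order = tuple(scored["term"].tolist()[:top_n])

    rows = []
    best_spec = None
    for size in range(len(order) + 1):
        for subset in itertools.combinations(order, size):
            if not _subset_is_hierarchical(subset):
                continue
            spec = _order_terms(subset, data, factors)
            Xs, bl, lb = build_design(data, spec)
            fit = fit_mlm(Xs, embed(sample), bl, lb)
            rows.append(
                {
                    "terms": " + ".join(subset) if subset else "(Intercept)",
                    "n_terms": len(subset),
                    "k": fit.k,
                    "mean_aic": mean_aic(fit),
                    "_spec": spec,
                    "_names": tuple(sorted(subset)),
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["mean_aic", "n_terms", "_names"], ascending=[True, True, True]
    )
    best_spec = table.iloc[0]["_spec"]
    table = table.drop(columns=["_spec", "_names"]).reset_index(drop=True)
    return SelectionReport(
        eta_table=eta,
        candidate_order=order,
        aic_table=table,
        best=best_spec,
    )
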