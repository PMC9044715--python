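"""CSV input, fixture generation and result serialization.

Input is a flat CSV with one angle column (degrees by default) and any
number of factor/covariate columns.  Outputs are tidy TSV or JSON; every
stochastic output embeds the seed and the configuration that produced it
so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AngleSample, axial_transform, to_radians
from .distributions import (
    MixtureSpec,
    sample_mixture,
    sample_uniform,
    sample_vonmises,
    sample_wrapped_skew_normal,
)
from .power import HypotheticalDesign, hypothetical_table, simulate_hypothetical

log = logging.getLogger("circmanova")

FIXTURE_KINDS = ("uniform", "vm", "wsn", "bimodal", "trimodal", "hypothetical")


def read_table(
    path,
    angle_column: str = "angle",
    unit: str = "degrees",
    axial: bool = False,
    factors: tuple[str, ...] = (),
) -> tuple[AngleSample, pd.DataFrame]:
    """Read a CSV into an :class:`AngleSample` plus its covariate table.

    Rows whose angle fails numeric parsing (e.g. "NA") are dropped with a
    logged warning reporting their count and line numbers.  Non-numeric
    covariate columns are treated as factors; numeric ones as covariates
    unless listed in `factors`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty input file")
    if angle_column not in df.columns:
        raise ValueError(
            f"{path}: missing angle column {angle_column!r}; "
            f"available columns: {list(df.columns)}"
        )
    raw = pd.to_numeric(df[angle_column], errors="coerce")
    bad = raw.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        log.warning(
            "%s: dropped %d row(s) with unparseable %r (lines %s)",
            path, int(bad.sum()), angle_column, lines,
        )
        df = df.loc[~bad].reset_index(drop=True)
        raw = raw[~bad]
    if df.empty:
        raise ValueError(f"{path}: no parseable angles in {angle_column!r}")
    sample = to_radians(raw.to_numpy(dtype=float), unit=unit)
    if axial:
        sample = axial_transform(sample)
    covariates = df.drop(columns=[angle_column])
    for col in factors:
        if col in covariates.columns:
            covariates[col] = covariates[col].astype(str)
    return sample, covariates


def generate_fixture(kind: str, params: dict, seed: int, path) -> Path:
    """Write a deterministic simulated CSV of the given kind.

    Columns: ``angle_deg`` (plus ``group`` and ``age`` for the
    hypothetical design).  Same seed, same file.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    n = int(params.get("n", 100))
    if kind == "hypothetical":
        design = HypotheticalDesign(
            group_means=tuple(params.get("group_means", (0.0, 0.0))),
            kappa_schedules=tuple(
                tuple(s) for s in params.get("kappa_schedules", ((0.0, 2.0), (0.0, 2.0)))
            ),
        )
        df = hypothetical_table(design, n)
        df["angle_deg"] = np.rad2deg(
            simulate_hypothetical(design, n, 1, rng)[0]
        )
        df = df[["angle_deg", "group", "age"]]
    else:
        if kind == "uniform":
            sample = sample_uniform(n, rng)
        elif kind == "vm":
            sample = sample_vonmises(
                n, params.get("mu", 0.0), params.get("kappa", 1.0), rng
            )
        elif kind == "wsn":
            sample = sample_wrapped_skew_normal(
                n,
                params.get("xi", 0.0),
                params.get("omega", 2.0),
                params.get("alpha", 30.0),
                rng,
            )
        elif kind == "bimodal":
            sample = sample_mixture(
                MixtureSpec.vonmises_modes(
                    params.get("modes_deg", [0.0, 180.0]), params.get("kappa", 1.0)
                ),
                n,
                rng,
            )
        else:  # trimodal
            sample = sample_mixture(
                MixtureSpec.vonmises_modes(
                    params.get("modes_deg", [0.0, 120.0, 240.0]),
                    params.get("kappa", 1.0),
                ),
                n,
                rng,
            )
        df = pd.DataFrame({"angle_deg": np.rad2deg(sample.angles)})
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_results(frame: pd.DataFrame, config: dict, out, fmt: str = "tsv") -> None:
    """Write a result table with its provenance (config incl. seed)."""
    out = Path(out) if not hasattr(out, "write") else out
    if fmt == "tsv":
        header = "# " + json.dumps(config, sort_keys=True, default=str)
        body = frame.to_csv(sep="\t", index=False)
        text = header + "\n" + body
        if hasattr(out, "write"):
            out.write(text)
        else:
            out.write_text(text)
    elif fmt == "json":
        payload = json.dumps(
            {"config": config, "results": frame.to_dict(orient="records")},
            indent=2,
            default=str,
        )
        if hasattr(out, "write"):
            out.write(payload + "\n")
        else:
            out.write_text(payload + "\n")
    else:
        raise ValueError(f"unknown output format {fmt!r}")
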