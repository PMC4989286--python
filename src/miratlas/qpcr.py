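"""qPCR delta-Ct workflow and serum biomarker-panel assessment.

Threshold-cycle (Ct) measurements run in technical triplicate; replicates
with Ct above the reliability cutoff (default 38 cycles) are censored before
averaging.  Relative expression follows the delta-Ct convention:
``dCt = Ct(target) - mean Ct(references)`` and ``rel_expr = 2**(-dCt)``.
The module also provides the cross-platform sequencing-vs-qPCR regression,
per-target %CV of reference miRNAs across tissues, and per-animal
correlation of a serum biomarker against clinical chemistry (ALT/AST) over
a dosing time course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

CT_CUTOFF_DEFAULT = 38.0

#: historical alias spellings -> canonical target name
TARGET_ALIASES = {"miR-855": "miR-885", "cfa-miR-855": "cfa-miR-885"}


def canonical_target(name: str) -> str:
    return TARGET_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DeltaCtResult:
    sample_id: str
    target: str
    mean_ct: float | None
    n_replicates_used: int
    delta_ct: float | None
    rel_expr: float | None
    censored: bool = False
    reason: str = ""


@dataclass
class PanelStudy:
    """Serum panel measurements plus clinical chemistry for a dosing study.

    ``measurements``: columns animal, day, phase, target, delta_ct, rel_expr,
    censored.  ``chemistry``: columns animal, day, phase, ALT, AST.
    """

    measurements: pd.DataFrame
    chemistry: pd.DataFrame
    panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = {"animal", "day", "phase"}
        for name, df, extra in (
            ("measurements", self.measurements, {"target", "delta_ct"}),
            ("chemistry", self.chemistry, {"ALT", "AST"}),
        ):
            missing = (keys | extra) - set(df.columns)
            if missing:
                raise DataError(f"panel {name} missing columns {sorted(missing)}")
        used = set(map(tuple, self.measurements[["animal", "day", "phase"]].values))
        have = set(map(tuple, self.chemistry[["animal", "day", "phase"]].values))
        if used - have:
            raise DataError(
                f"chemistry missing for timepoints {sorted(used - have)[:5]}"
            )


# ---------------------------------------------------------------------------
# Ct handling
# ---------------------------------------------------------------------------

def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Plate export CSV: sample_id, target, replicate, ct [, context]."""
    df = pd.read_csv(path)
    required = {"sample_id", "target", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: Ct table missing columns {sorted(missing)}")
    if ((df["ct"] <= 0) | (df["ct"] > 45)).any():
        raise DataError(f"{path}: Ct values outside (0, 45]")
    df["target"] = df["target"].map(canonical_target)
    return df


def average_ct(
    replicate_cts: Sequence[float], ct_cutoff: float = CT_CUTOFF_DEFAULT
) -> tuple[float | None, int]:
    """Mean of replicates after censoring Ct strictly above the cutoff.

    A replicate exactly at the cutoff is retained.  Returns ``(None, 0)``
    when every replicate is censored.
    """
    if len(replicate_cts) == 0:
        raise DataError("average_ct: empty replicate list")
    kept = [c for c in replicate_cts if c <= ct_cutoff]
    if not kept:
        return None, 0
    return float(np.mean(kept)), len(kept)


def mean_ct_table(
    ct: pd.DataFrame, ct_cutoff: float = CT_CUTOFF_DEFAULT
) -> pd.DataFrame:
    """Per-(sample, target) censored replicate average.

    Target names are canonicalized through the alias table first, so
    historical alias spellings pool with their canonical target.
    """
    ct = ct.assign(target=ct["target"].map(canonical_target))
    rows = []
    for (sample, target), grp in ct.groupby(["sample_id", "target"], sort=True):
        mean, n_used = average_ct(grp["ct"].tolist(), ct_cutoff)
        rows.append(
            {"sample_id": sample, "target": target, "mean_ct": mean, "n_used": n_used}
        )
    return pd.DataFrame(rows, columns=["sample_id", "target", "mean_ct", "n_used"])


def delta_ct(
    sample_id: str,
    target: str,
    references: Sequence[str],
    means: pd.DataFrame,
) -> DeltaCtResult:
    """dCt against the arithmetic mean of the reference mean Cts.

    ``means`` is a :func:`mean_ct_table` frame.  All references censored (or
    the target itself censored) yields a censored result with a reason.
    """
    target = canonical_target(target)
    sub = means[means["sample_id"] == sample_id].set_index("target")
    if target not in sub.index or sub.loc[target, "mean_ct"] is None or (
        isinstance(sub.loc[target, "mean_ct"], float)
        and math.isnan(sub.loc[target, "mean_ct"])
    ):
        return DeltaCtResult(sample_id, target, None, 0, None, None, True,
                             "target censored or missing")
    mean_ct = float(sub.loc[target, "mean_ct"])
    n_used = int(sub.loc[target, "n_used"])
    ref_cts = []
    for ref in map(canonical_target, references):
        if ref in sub.index:
            val = sub.loc[ref, "mean_ct"]
            if val is not None and not (isinstance(val, float) and math.isnan(val)):
                ref_cts.append(float(val))
    if not ref_cts:
        return DeltaCtResult(sample_id, target, mean_ct, n_used, None, None, True,
                             "all references censored")
    if len(ref_cts) < 2:
        import warnings

        warnings.warn(
            f"{sample_id}/{target}: only {len(ref_cts)} usable reference(s)"
        )
    dct = mean_ct - float(np.mean(ref_cts))
    return DeltaCtResult(sample_id, target, mean_ct, n_used, dct, 2.0 ** (-dct))


def delta_ct_table(
    ct: pd.DataFrame,
    references: Sequence[str],
    ct_cutoff: float = CT_CUTOFF_DEFAULT,
) -> pd.DataFrame:
    """delta-Ct for every (sample, target) in a plate export."""
    means = mean_ct_table(ct, ct_cutoff)
    refs = {canonical_target(r) for r in references}
    rows = []
    for sample in means["sample_id"].unique():
        sub = means[means["sample_id"] == sample]
        for target in sub["target"]:
            if target in refs:
                continue
            res = delta_ct(sample, target, list(refs), means)
            rows.append(vars(res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-platform and panel correlation
# ---------------------------------------------------------------------------

def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(r2, slope, intercept); degenerate variance gives r2=0."""
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0, 0.0, float(np.mean(y))
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.slope), float(res.intercept)


def platform_correlation(
    qpcr_rel_expr: Mapping[str, float] | pd.Series,
    seq_rpm: Mapping[str, float] | pd.Series,
) -> tuple[float, float, float, int]:
    """OLS of log2 qPCR relative expression on log2(RPM + 1) across samples.

    Returns (r_squared, slope, intercept, n).  Requires >= 3 paired samples
    with non-censored qPCR values and finite RPM.
    """
    q = pd.Series(qpcr_rel_expr, dtype=float).dropna()
    s = pd.Series(seq_rpm, dtype=float).dropna()
    common = q.index.intersection(s.index)
    q, s = q[common], s[common]
    keep = (q > 0) & np.isfinite(s)
    q, s = q[keep], s[keep]
    if len(q) < 3:
        raise DataError(f"platform_correlation needs >= 3 pairs, got {len(q)}")
    x = np.log2(s.to_numpy() + 1.0)
    y = np.log2(q.to_numpy())
    r2, slope, intercept = _ols_r2(x, y)
    return r2, slope, intercept, len(q)


def panel_correlate(
    study: PanelStudy,
    target: str,
    chemistry_analyte: str = "ALT",
    value: str = "neg_delta_ct",
    min_timepoints: int = 3,
) -> pd.DataFrame:
    """Per-animal OLS r2 of a serum target against ALT or AST.

    ``value`` selects the qPCR axis: ``neg_delta_ct`` (-dCt, linear in log2
    expression; default) or ``rel_expr``.  Animals with fewer than
    ``min_timepoints`` usable (non-censored, chemistry-matched) timepoints
    are flagged not-evaluable.
    """
    if chemistry_analyte not in ("ALT", "AST"):
        raise DataError(f"unknown analyte {chemistry_analyte!r}")
    if value not in ("neg_delta_ct", "rel_expr"):
        raise DataError(f"unknown value axis {value!r}")
    target = canonical_target(target)
    meas = study.measurements
    meas = meas[(meas["target"] == target) & (~meas["censored"].astype(bool))]
    merged = meas.merge(study.chemistry, on=["animal", "day", "phase"])
    rows = []
    for animal in sorted(study.chemistry["animal"].unique()):
        sub = merged[merged["animal"] == animal]
        if len(sub) < min_timepoints:
            rows.append({"animal": animal, "r2": np.nan, "slope": np.nan,
                         "n": len(sub), "evaluable": False})
            continue
        yvals = (
            -sub["delta_ct"].to_numpy(dtype=float)
            if value == "neg_delta_ct"
            else sub["rel_expr"].to_numpy(dtype=float)
        )
        r2, slope, _ = _ols_r2(sub[chemistry_analyte].to_numpy(dtype=float), yvals)
        rows.append({"animal": animal, "r2": r2, "slope": slope,
                     "n": len(sub), "evaluable": True})
    return pd.DataFrame(rows)


def reference_cv(
    means: pd.DataFrame,
    tissue_of: Mapping[str, str] | pd.Series,
    targets: Sequence[str] | None = None,
) -> pd.Series:
    """%CV (100 * sample SD / mean) of per-tissue mean Ct, per target.

    ``means`` is a :func:`mean_ct_table` frame; samples map to tissues via
    ``tissue_of``.  Requires measurements from >= 2 tissues.
    """
    tissue_of = pd.Series(tissue_of)
    df = means.dropna(subset=["mean_ct"]).copy()
    df["tissue"] = df["sample_id"].map(tissue_of)
    if targets is not None:
        wanted = {canonical_target(t) for t in targets}
        df = df[df["target"].isin(wanted)]
    out = {}
    for target, grp in df.groupby("target"):
        per_tissue = grp.groupby("tissue")["mean_ct"].mean()
        if len(per_tissue) < 2:
            raise DataError(f"reference_cv: target {target!r} seen in < 2 tissues")
        out[target] = float(100.0 * per_tissue.std(ddof=1) / per_tissue.mean())
    return pd.Series(out, name="cv_pct")
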