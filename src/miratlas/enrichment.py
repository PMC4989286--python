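"""Tissue-enrichment classification (TE / HTE) and sample-correlation QC.

An miRNA locus is *tissue enriched* (TE) in a tissue when its fold change
there exceeds ``fc_threshold`` (default 5) and the FDR-corrected one-sided
Wilcoxon rank-sum p-value against all other samples is below ``alpha``
(default 0.05).  It is *highly tissue enriched* (HTE) when its median RPM in
the tissue exceeds ``hte_fold`` (default 5) times the maximum RPM value
observed in any individual sample of any other tissue, and the locus is
detected (tissue median RPM > ``detection_rpm``) in at most
``hte_max_tissues`` tissues.  HTE loci are subdivided by how many tissues
satisfy the HTE inequality: HTE1 (exactly one) and HTE2 (two).

Also provided: the candidate abundance filter (max tissue-median RPM >
``candidate_rpm``), squared-Spearman sample-correlation QC, and a stability
score for picking ubiquitous reference miRNAs (low %CV and SD of log2 tissue
medians).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .quantify import ExpressionMatrix, SampleTable, tissue_medians, detection_matrix

CLASSES = ("none", "TE", "HTE2", "HTE1")


@dataclass
class EnrichmentConfig:
    fc_threshold: float = 5.0
    alpha: float = 0.05
    hte_fold: float = 5.0
    hte_max_tissues: int = 2
    candidate_rpm: float = 100.0
    detection_rpm: float = 100.0
    pseudocount: float = 1.0  # RPM added to both fold-change terms
    alternative: str = "greater"  # or "two_sided"
    fdr_scope: str = "per_tissue"  # or "global"
    hte_comparator: str = "sample_max"  # or "tissue_median_max"

    def validate(self) -> None:
        for name in ("fc_threshold", "hte_fold", "candidate_rpm",
                     "detection_rpm", "pseudocount"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")
        if not (0 < self.alpha < 1):
            raise DataError(f"alpha must be in (0,1), got {self.alpha}")
        if self.alternative not in ("greater", "two_sided"):
            raise DataError(f"unknown alternative {self.alternative!r}")
        if self.fdr_scope not in ("per_tissue", "global"):
            raise DataError(f"unknown fdr_scope {self.fdr_scope!r}")
        if self.hte_comparator not in ("sample_max", "tissue_median_max"):
            raise DataError(f"unknown hte_comparator {self.hte_comparator!r}")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def candidate_filter(
    expr: ExpressionMatrix, samples: SampleTable, candidate_rpm: float = 100.0
) -> list[str]:
    """Loci whose maximum tissue-median RPM is strictly above the cutoff."""
    if expr.values.empty:
        return []
    med = tissue_medians(expr, samples)
    keep = med.max(axis=1) > candidate_rpm
    return list(med.index[keep])


def tissue_fold_change(
    expr: ExpressionMatrix,
    samples: SampleTable,
    locus: str,
    tissue: str,
    pseudocount: float = 1.0,
) -> tuple[float, float, float]:
    """(tissue median, pooled-other median, pseudocounted fold change)."""
    tissue_of = samples.tissue_of()[expr.values.columns]
    if tissue not in set(tissue_of):
        raise DataError(f"unknown tissue {tissue!r}")
    row = expr.values.loc[locus]
    in_t = row[(tissue_of == tissue).values]
    out_t = row[(tissue_of != tissue).values]
    med_t = float(in_t.median())
    med_o = float(out_t.median())
    fold = (med_t + pseudocount) / (med_o + pseudocount)
    return med_t, med_o, fold


_EXACT_MAX_N = 12  # total sample size at or below which the exact null is used


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> float:
    """Rank-sum p-value for x shifted above y (or two-sided).

    Uses the exact permutation null when the pooled size is <= 12 and there
    are no ties, and the tie-corrected normal approximation on midranks
    otherwise.  Fully tied data (every value identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("wilcoxon_rank_sum needs >= 2 values per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = len(pooled)
    ties = len(np.unique(pooled)) < n
    method = "exact" if (n <= _EXACT_MAX_N and not ties) else "asymptotic"
    alt = {"greater": "greater", "two_sided": "two-sided"}[alternative]
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method)
    return float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))


def _rank_sum_pvalues_block(
    x: np.ndarray, y: np.ndarray, alternative: str
) -> np.ndarray:
    """Vectorized per-row rank-sum p-values, identical to wilcoxon_rank_sum.

    Rows where the asymptotic path applies are computed in one call; the
    exact-path and fully-tied rows fall back to the scalar routine.
    """
    m = x.shape[0]
    out = np.empty(m)
    pooled = np.concatenate([x, y], axis=1)
    all_tied = np.all(pooled == pooled[:, [0]], axis=1)
    n = pooled.shape[1]
    if n > _EXACT_MAX_N:
        alt = {"greater": "greater", "two_sided": "two-sided"}[alternative]
        res = stats.mannwhitneyu(x, y, alternative=alt, method="asymptotic", axis=1)
        out[:] = np.minimum(np.maximum(res.pvalue, np.finfo(float).tiny), 1.0)
    else:
        for i in range(m):
            out[i] = wilcoxon_rank_sum(x[i], y[i], alternative)
    out[all_tied] = 1.0
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_all(
    expr: ExpressionMatrix,
    samples: SampleTable,
    config: EnrichmentConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every (candidate locus, tissue) pair as none/TE/HTE2/HTE1.

    Returns the per-(locus, tissue) record table (columns: locus, tissue,
    tissue_median_rpm, other_median_rpm, fold_change, p_value, q_value,
    n_detected_tissues, te, hte, class) and a per-tissue tally of the three
    enriched classes.  q-values are computed per tissue across candidate
    loci by default.
    """
    config = config or EnrichmentConfig()
    config.validate()
    tissue_of = samples.tissue_of()[expr.values.columns]
    tissues = sorted(set(tissue_of))
    if len(tissues) < 2:
        raise DataError("classification needs >= 2 tissues")
    vc = tissue_of.value_counts()
    if (vc < 2).any():
        raise DataError(f"tissues with < 2 samples: {sorted(vc[vc < 2].index)}")

    candidates = candidate_filter(expr, samples, config.candidate_rpm)
    med = tissue_medians(expr, samples).loc[candidates]
    detected, n_det = detection_matrix(expr, samples, config.detection_rpm)
    n_det = n_det.loc[candidates] if candidates else n_det.iloc[:0]

    values = expr.values.loc[candidates]
    records: list[dict] = []
    pc = config.pseudocount
    for tissue in tissues:
        mask = (tissue_of == tissue).to_numpy()
        x = values.to_numpy()[:, mask]
        y = values.to_numpy()[:, ~mask]
        med_t = med[tissue].to_numpy()
        med_o = np.median(y, axis=1) if len(candidates) else np.array([])
        fold = (med_t + pc) / (med_o + pc)
        if config.hte_comparator == "sample_max":
            other_max = y.max(axis=1) if y.size else np.array([])
        else:
            other_max = med.drop(columns=tissue).max(axis=1).to_numpy()
        p = (
            _rank_sum_pvalues_block(x, y, config.alternative)
            if len(candidates)
            else np.array([])
        )
        for i, locus in enumerate(candidates):
            records.append(
                {
                    "locus": locus,
                    "tissue": tissue,
                    "tissue_median_rpm": med_t[i],
                    "other_median_rpm": med_o[i],
                    "fold_change": fold[i],
                    "p_value": p[i],
                    "hte_ineq": bool(
                        med_t[i] > config.hte_fold * other_max[i]
                        and n_det[locus] <= config.hte_max_tissues
                    ),
                    "n_detected_tissues": int(n_det[locus]),
                }
            )
    rec = pd.DataFrame(
        records,
        columns=["locus", "tissue", "tissue_median_rpm", "other_median_rpm",
                 "fold_change", "p_value", "hte_ineq", "n_detected_tissues"],
    )
    if len(rec):
        if config.fdr_scope == "per_tissue":
            rec["q_value"] = rec.groupby("tissue")["p_value"].transform(
                lambda s: bh_adjust(s.to_numpy())
            )
        else:
            rec["q_value"] = bh_adjust(rec["p_value"].to_numpy())
        rec["te"] = (rec["fold_change"] > config.fc_threshold) & (
            rec["q_value"] < config.alpha
        )
        n_hte_tissues = rec.groupby("locus")["hte_ineq"].transform("sum")
        hte_class = np.where(
            rec["hte_ineq"] & (n_hte_tissues == 1), "HTE1",
            np.where(rec["hte_ineq"] & (n_hte_tissues == 2), "HTE2", ""),
        )
        rec["class"] = np.where(
            hte_class != "", hte_class, np.where(rec["te"], "TE", "none")
        )
    else:
        rec["q_value"] = pd.Series(dtype=float)
        rec["te"] = pd.Series(dtype=bool)
        rec["class"] = pd.Series(dtype=str)
    rec = rec.rename(columns={"hte_ineq": "hte"})
    rec = rec.sort_values(["tissue", "locus"], kind="mergesort").reset_index(drop=True)

    tissue_list = tissues
    tally = pd.DataFrame(
        0, index=tissue_list, columns=["TE", "HTE2", "HTE1"], dtype=int
    )
    if len(rec):
        counts = (
            rec[rec["class"] != "none"]
            .groupby(["tissue", "class"])
            .size()
            .unstack(fill_value=0)
        )
        for cls in ("TE", "HTE2", "HTE1"):
            if cls in counts.columns:
                tally.loc[counts.index, cls] = counts[cls]
    tally.index.name = "tissue"
    return rec, tally


# ---------------------------------------------------------------------------
# QC and reference scoring
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    matrix: pd.DataFrame  # sample x sample squared Spearman rho
    within_tissue_mean: pd.Series
    between_tissue_mean: pd.DataFrame
    constant_samples: list[str]


def spearman_qc(expr: ExpressionMatrix, samples: SampleTable) -> CorrelationSummary:
    """Pairwise squared Spearman correlation of per-sample RPM vectors.

    Constant sample vectors have undefined rank correlation; they are
    flagged and excluded from the within/between means (their matrix entries
    are NaN, diagonal forced to 1).
    """
    vals = expr.values
    if vals.shape[1] < 2:
        raise DataError("spearman_qc needs >= 2 samples")
    constant = [c for c in vals.columns if vals[c].nunique() <= 1]
    rho = vals.corr(method="spearman")
    r2 = rho ** 2
    r2.loc[constant, :] = np.nan
    r2.loc[:, constant] = np.nan
    np.fill_diagonal(r2.values, 1.0)

    tissue_of = samples.tissue_of()[vals.columns]
    tissues = sorted(set(tissue_of))
    within = {}
    between = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for i, t1 in enumerate(tissues):
        c1 = [c for c in vals.columns if tissue_of[c] == t1 and c not in constant]
        sub = r2.loc[c1, c1].to_numpy()
        off = sub[~np.eye(len(c1), dtype=bool)] if len(c1) > 1 else np.array([])
        within[t1] = float(np.mean(off)) if off.size else np.nan
        for t2 in tissues[i:]:
            c2 = [c for c in vals.columns if tissue_of[c] == t2 and c not in constant]
            if t1 == t2:
                between.loc[t1, t2] = within[t1]
                continue
            block = r2.loc[c1, c2].to_numpy()
            val = float(np.mean(block)) if block.size else np.nan
            between.loc[t1, t2] = between.loc[t2, t1] = val
    return CorrelationSummary(r2, pd.Series(within), between, constant)


def reference_score(
    expr: ExpressionMatrix,
    samples: SampleTable,
    candidate_rpm: float = 100.0,
) -> pd.DataFrame:
    """Stability metrics for reference-miRNA selection.

    Per locus: mean log2(RPM+1) of tissue medians, %CV and SD of those log2
    medians (sample SD), mean raw tissue-median RPM, and ``is_stable``:
    CV% < 10 and SD <= 1 and mean RPM > candidate_rpm.
    """
    med = tissue_medians(expr, samples)
    log2m = np.log2(med + 1.0)
    mean_log2 = log2m.mean(axis=1)
    sd_log2 = log2m.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_pct = 100.0 * sd_log2 / mean_log2.replace(0, np.nan)
    mean_rpm = med.mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_log2_rpm": mean_log2,
            "cv_pct": cv_pct,
            "sd_log2": sd_log2,
            "mean_rpm": mean_rpm,
        }
    )
    out["is_stable"] = (
        (out["cv_pct"] < 10.0).fillna(False)
        & (out["sd_log2"] <= 1.0)
        & (out["mean_rpm"] > candidate_rpm)
    )
    return out
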