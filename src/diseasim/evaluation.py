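"""Benchmarking similarity matrices against external disease associations.

Three label sources are supported:

* ICD-9 chapter concordance - do same-chapter pairs score higher?
  (one-sided Mann-Whitney U test);
* comorbidity - pairs whose phi-correlation (Pearson correlation of the two
  binary disease-presence indicators across a patient population) exceeds a
  threshold and is significant at the 5% level (t >= 1.96);
* GWAS - pairs sharing at least one author-reported associated gene.

ROC analysis sweeps the similarity score as a decision threshold; ties are
handled by rank averaging so the AUC equals the Mann-Whitney statistic
U / (n_pos * n_neg).  A permutation baseline redraws scores from their own
empirical distribution to show what a random predictor achieves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import mannwhitneyu, rankdata
from sklearn.metrics import roc_curve

from .similarity import SimilarityMatrix

__all__ = [
    "ICD9_CHAPTERS",
    "icd9_chapter",
    "same_category",
    "category_score_test",
    "CategoryTestResult",
    "phi_correlation",
    "phi_t_statistic",
    "ComorbidityRecord",
    "load_comorbidity",
    "comorbidity_labels",
    "gwas_labels",
    "roc",
    "ROCResult",
    "randomized_baseline",
]


# ---------------------------------------------------------------------------
# ICD-9 chapters
# ---------------------------------------------------------------------------

#: The 17 standard ICD-9 chapters plus the E/V supplementary blocks,
#: as (label, first 3-digit code, last 3-digit code) with E/V kept apart.
ICD9_CHAPTERS: tuple[tuple[str, str, str], ...] = (
    ("infectious and parasitic diseases", "001", "139"),
    ("neoplasms", "140", "239"),
    ("endocrine, nutritional and metabolic diseases, and immunity disorders", "240", "279"),
    ("diseases of the blood and blood-forming organs", "280", "289"),
    ("mental disorders", "290", "319"),
    ("diseases of the nervous system and sense organs", "320", "389"),
    ("diseases of the circulatory system", "390", "459"),
    ("diseases of the respiratory system", "460", "519"),
    ("diseases of the digestive system", "520", "579"),
    ("diseases of the genitourinary system", "580", "629"),
    ("complications of pregnancy, childbirth, and the puerperium", "630", "679"),
    ("diseases of the skin and subcutaneous tissue", "680", "709"),
    ("diseases of the musculoskeletal system and connective tissue", "710", "739"),
    ("congenital anomalies", "740", "759"),
    ("certain conditions originating in the perinatal period", "760", "779"),
    ("symptoms, signs, and ill-defined conditions", "780", "799"),
    ("injury and poisoning", "800", "999"),
    ("external causes of injury and poisoning", "E800", "E999"),
    ("supplementary classification of factors influencing health status", "V01", "V91"),
)


def icd9_chapter(code: str, chapters=ICD9_CHAPTERS) -> str:
    """Chapter label of a 3-digit-level ICD-9 code; unknown codes raise."""
    code = str(code).strip().upper()
    prefix = code[0] if code[:1] in "EV" else ""
    digits = code[1:] if prefix else code
    if not digits.isdigit():
        raise ValueError(f"unknown ICD-9 code: {code!r}")
    value = int(digits)
    for label, lo, hi in chapters:
        lo_prefix = lo[0] if lo[:1] in "EV" else ""
        if lo_prefix != prefix:
            continue
        lo_v = int(lo[1:]) if lo_prefix else int(lo)
        hi_v = int(hi[1:]) if lo_prefix else int(hi)
        if lo_v <= value <= hi_v:
            return label
    raise ValueError(f"unknown ICD-9 code: {code!r}")


def same_category(a: str, b: str, chapters=ICD9_CHAPTERS) -> bool:
    """True when both codes fall in the same ICD-9 chapter."""
    return icd9_chapter(a, chapters) == icd9_chapter(b, chapters)


@dataclass
class CategoryTestResult:
    same_mean: float
    same_sd: float
    diff_mean: float
    diff_sd: float
    n_same: int
    n_diff: int
    p_value: float


def category_score_test(sim: SimilarityMatrix, chapters=ICD9_CHAPTERS) -> CategoryTestResult:
    """Do same-chapter disease pairs score higher than different-chapter pairs?

    Splits the defined (non-NaN) pair scores into same-/different-chapter
    groups and applies a one-sided Mann-Whitney U test (same > different):
    exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise.
    """
    same, diff = [], []
    for i, j in combinations(range(len(sim.diseases)), 2):
        score = sim.scores[i, j]
        if np.isnan(score):
            continue
        (same if same_category(sim.diseases[i], sim.diseases[j], chapters) else diff).append(score)
    if not same or not diff:
        raise ValueError("both same-chapter and different-chapter groups must be non-empty")
    same_a, diff_a = np.asarray(same), np.asarray(diff)
    exact_ok = (len(same) + len(diff) <= 12) and len(np.unique(np.r_[same_a, diff_a])) == len(same) + len(diff)
    res = mannwhitneyu(
        same_a, diff_a, alternative="greater", method="exact" if exact_ok else "asymptotic"
    )
    return CategoryTestResult(
        same_mean=float(same_a.mean()),
        same_sd=float(same_a.std(ddof=1)) if len(same) > 1 else 0.0,
        diff_mean=float(diff_a.mean()),
        diff_sd=float(diff_a.std(ddof=1)) if len(diff) > 1 else 0.0,
        n_same=len(same),
        n_diff=len(diff),
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Comorbidity
# ---------------------------------------------------------------------------


def phi_correlation(c_ij: float, p_i: float, p_j: float, n: float) -> float:
    """Pearson correlation of two binary disease indicators.

    ``c_ij`` patients have both diseases, ``p_i``/``p_j`` have each, out of
    ``n`` patients.  NaN when a prevalence is 0 or equals the population.
    """
    denom = p_i * p_j * (n - p_i) * (n - p_j)
    if denom <= 0:
        return float("nan")
    return (c_ij * n - p_i * p_j) / math.sqrt(denom)


def phi_t_statistic(phi: float, p_i: float, p_j: float) -> float:
    """t-statistic of a phi-correlation, with n = max(P_i, P_j) observations."""
    n = max(p_i, p_j)
    if n < 3:
        raise ValueError("need max(P_i, P_j) >= 3 observations")
    if abs(phi) >= 1.0:
        return math.copysign(math.inf, phi)
    return phi * math.sqrt(n - 2) / math.sqrt(1.0 - phi * phi)


@dataclass(frozen=True)
class ComorbidityRecord:
    """One disease pair's co-occurrence statistics."""

    a: str
    b: str
    phi: float
    t: float
    c_ij: int | None = None
    p_i: int | None = None
    p_j: int | None = None
    n: int | None = None

    @classmethod
    def from_counts(cls, a, b, c_ij, p_i, p_j, n) -> "ComorbidityRecord":
        if c_ij > min(p_i, p_j) or max(p_i, p_j) > n:
            raise ValueError(f"inconsistent counts for pair ({a}, {b})")
        phi = phi_correlation(c_ij, p_i, p_j, n)
        t = phi_t_statistic(phi, p_i, p_j) if not math.isnan(phi) else float("nan")
        return cls(a=a, b=b, phi=phi, t=t, c_ij=c_ij, p_i=p_i, p_j=p_j, n=n)


def load_comorbidity(path) -> list[ComorbidityRecord]:
    """Read a comorbidity TSV.

    Accepts either count columns (icd9_a, icd9_b, C_ij, P_i, P_j, N), from
    which phi and t are recomputed, or precomputed (icd9_a, icd9_b, phi, t).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = [c.lstrip("#").strip() for c in df.columns]
    cols = set(df.columns)
    records = []
    if {"C_ij", "P_i", "P_j", "N"} <= cols:
        for row in df.itertuples(index=False):
            records.append(
                ComorbidityRecord.from_counts(
                    str(row.icd9_a), str(row.icd9_b), int(row.C_ij), int(row.P_i), int(row.P_j), int(row.N)
                )
            )
    elif {"phi", "t"} <= cols:
        for row in df.itertuples(index=False):
            records.append(ComorbidityRecord(a=str(row.icd9_a), b=str(row.icd9_b), phi=float(row.phi), t=float(row.t)))
    else:
        raise ValueError(f"{path}: expected count columns (C_ij, P_i, P_j, N) or (phi, t)")
    return records


def comorbidity_labels(
    records: list[ComorbidityRecord],
    phi_threshold: float = 0.06,
    t_threshold: float = 1.96,
) -> set[frozenset]:
    """Positive pairs: phi above the threshold and significant at 5% (t >= 1.96)."""
    return {
        frozenset((r.a, r.b))
        for r in records
        if not math.isnan(r.phi) and r.phi > phi_threshold and r.t >= t_threshold
    }


def gwas_labels(gwas_table: dict) -> set[frozenset]:
    """Positive pairs: diseases sharing at least one GWAS-associated gene."""
    diseases = sorted(gwas_table, key=str)
    return {
        frozenset((a, b))
        for a, b in combinations(diseases, 2)
        if set(gwas_table[a]) & set(gwas_table[b])
    }


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    points: list[tuple[float, float]]  # (FPR, TPR), from (0,0) to (1,1)
    auc: float
    n_pos: int
    n_neg: int
    n_excluded: int = 0


def _collect_pair_scores(sim: SimilarityMatrix, dmap=None, min_genes: int = 1):
    diseases = sim.diseases
    if dmap is not None and min_genes > 1:
        keep = {d for d in diseases if len(dmap.get(d, ())) >= min_genes}
        diseases = [d for d in diseases if d in keep]
    index = {d: i for i, d in enumerate(sim.diseases)}
    pairs, scores = [], []
    for a, b in combinations(diseases, 2):
        pairs.append(frozenset((a, b)))
        scores.append(sim.scores[index[a], index[b]])
    return pairs, np.asarray(scores, dtype=float)


def _auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC = U / (n_pos * n_neg), ties get half credit."""
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc(
    sim: SimilarityMatrix,
    positives: set[frozenset],
    dmap: dict | None = None,
    min_genes: int = 1,
    zero_fill: bool = False,
) -> ROCResult:
    """ROC curve and AUC of one similarity matrix against a positive pair set.

    Pairs with an absent (NaN) score are excluded and counted, unless
    ``zero_fill`` scores them 0.  ``min_genes`` restricts the evaluation to
    diseases annotated with at least that many genes (requires ``dmap``).
    """
    pairs, scores = _collect_pair_scores(sim, dmap, min_genes)
    labels = np.array([p in positives for p in pairs])
    if zero_fill:
        scores = np.nan_to_num(scores, nan=0.0)
        defined = np.ones(len(scores), dtype=bool)
    else:
        defined = ~np.isnan(scores)
    n_excluded = int((~defined).sum())
    scores, labels = scores[defined], labels[defined]
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative pair")
    fpr, tpr, _ = roc_curve(labels.astype(int), scores, drop_intermediate=False)
    return ROCResult(
        points=list(zip(map(float, fpr), map(float, tpr))),
        auc=_auc_from_scores(scores, labels),
        n_pos=n_pos,
        n_neg=n_neg,
        n_excluded=n_excluded,
    )


def randomized_baseline(
    sim: SimilarityMatrix,
    positives: set[frozenset],
    reps: int = 30,
    seed: int = 0,
    dmap: dict | None = None,
    min_genes: int = 1,
    method: str = "permutation",
) -> tuple[float, float]:
    """Mean and sd of the AUC when scores are redrawn from their own
    empirical distribution (``permutation`` reshuffles the realised scores
    exactly; ``resample`` draws with replacement)."""
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    pairs, scores = _collect_pair_scores(sim, dmap, min_genes)
    labels = np.array([p in positives for p in pairs])
    defined = ~np.isnan(scores)
    scores, labels = scores[defined], labels[defined]
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ValueError("baseline needs at least one positive and one negative pair")
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(reps):
        if method == "permutation":
            drawn = rng.permutation(scores)
        elif method == "resample":
            drawn = rng.choice(scores, size=len(scores), replace=True)
        else:
            raise ValueError(f"unknown baseline method {method!r}")
        aucs.append(_auc_from_scores(drawn, labels))
    aucs = np.asarray(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1))
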