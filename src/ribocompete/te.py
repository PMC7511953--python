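"""Translation-efficiency estimation and permutation-based inference.

TE per gene and sample is the size-factor-normalized footprint count over
the normalized mRNA count (plus a pseudocount).  Differential TE between
knockdown and control is tested by permuting condition labels jointly
across both assays — the paired fp/mRNA structure of each sample is never
broken — with exhaustive enumeration whenever the label permutations are
few enough, and Benjamini-Hochberg correction across genes.  Class-level
enrichment (are TOP genes shifted up?) uses a normalized rank-sum statistic
with its own label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .synthetic import OmicsExperiment

__all__ = [
    "size_factors",
    "translation_efficiency",
    "differential_te",
    "class_enrichment",
    "EnrichmentResult",
]

EXHAUSTIVE_LIMIT = 10_000  # enumerate the label null exactly below this


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios scaling factors (one per sample).

    Each sample's factor is the median, over genes with all-positive
    counts, of its ratio to the per-gene geometric mean across samples.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("size_factors: no gene with all-positive counts")
    logc = np.log(arr[positive])
    log_ratio = logc - logc.mean(axis=1, keepdims=True)
    return pd.Series(np.exp(np.median(log_ratio, axis=0)), index=counts.columns)


def translation_efficiency(
    experiment: OmicsExperiment,
    pseudocount: float = 0.5,
    min_count: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene, per-sample TE matrix and the testable-gene filter.

    TE_gs = (fp_gs/sf_fp_s + pseudocount) / (mrna_gs/sf_mrna_s + pseudocount).
    Genes whose summed raw counts fall below ``min_count`` in either assay
    are flagged (False) and excluded from downstream testing.
    """
    fp, mrna = experiment.fp_counts, experiment.mrna_counts
    sf_fp = size_factors(fp)
    sf_mrna = size_factors(mrna)
    te = (fp / sf_fp + pseudocount) / (mrna / sf_mrna + pseudocount)
    keep = (fp.sum(axis=1) >= min_count) & (mrna.sum(axis=1) >= min_count)
    return te, keep


def _condition_masks(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cond = meta["condition"].to_numpy()
    ctrl, kd = cond == "control", cond == "knockdown"
    if ctrl.sum() < 2 or kd.sum() < 2:
        raise ValueError("need >= 2 replicates per condition")
    return ctrl, kd


def _label_permutations(n_samples: int, n_kd: int, n_perm: int, rng: np.random.Generator):
    """Knockdown-label assignments: exhaustive if few, else sampled.

    Returns (assignments: list of index tuples, exhaustive: bool).  The
    exhaustive set includes the observed labelling, so p-values lie on the
    grid k / n_combinations and are never zero.
    """
    from math import comb

    n_comb = comb(n_samples, n_kd)
    if n_comb <= EXHAUSTIVE_LIMIT:
        return list(combinations(range(n_samples), n_kd)), True
    picks = [tuple(np.sort(rng.choice(n_samples, n_kd, replace=False))) for _ in range(n_perm)]
    return picks, False


def differential_te(
    experiment: OmicsExperiment,
    n_perm: int = 10_000,
    seed: int = 0,
    pseudocount: float = 0.5,
    min_count: int = 10,
) -> pd.DataFrame:
    """Permutation test for per-gene log2 TE change (knockdown - control).

    The statistic is the difference of condition means of per-sample log2
    TE.  The null permutes condition labels across samples (each sample's
    fp/mRNA pair stays together); enumeration is exhaustive when the number
    of label assignments is at most ``EXHAUSTIVE_LIMIT``, in which case
    p = #{|stat_perm| >= |stat_obs|} / n_assignments; otherwise
    p = (1 + #exceeding) / (1 + n_perm).  BH q-values are appended.
    """
    te, keep = translation_efficiency(experiment, pseudocount, min_count)
    ctrl, kd = _condition_masks(experiment.sample_meta)
    log_te = np.log2(te.to_numpy())
    n_samples = log_te.shape[1]
    obs = log_te[:, kd].mean(axis=1) - log_te[:, ctrl].mean(axis=1)

    rng = np.random.default_rng(seed)
    assignments, exhaustive = _label_permutations(n_samples, int(kd.sum()), n_perm, rng)
    perm_stats = np.empty((len(assignments), log_te.shape[0]))
    for j, idx in enumerate(assignments):
        mask = np.zeros(n_samples, dtype=bool)
        mask[list(idx)] = True
        perm_stats[j] = log_te[:, mask].mean(axis=1) - log_te[:, ~mask].mean(axis=1)

    exceed = (np.abs(perm_stats) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        p = exceed / len(assignments)
    else:
        p = (1.0 + exceed) / (1.0 + len(assignments))

    result = pd.DataFrame(
        {
            "gene_id": te.index,
            "log2_te_change": obs,
            "p_value": p,
            "tested": keep.to_numpy(),
        }
    ).set_index("gene_id")
    q = np.full(len(result), np.nan)
    tested = result["tested"].to_numpy()
    if tested.any():
        q[tested] = multipletests(result.loc[tested, "p_value"], method="fdr_bh")[1]
    result["q_value"] = q
    result["n_perm"] = len(assignments)
    result["exhaustive"] = exhaustive
    if "class" in experiment.truth.columns:
        result["class"] = experiment.truth.set_index("gene_id")["class"]
    return result


@dataclass(frozen=True)
class EnrichmentResult:
    statistic: float      # standardized rank-sum of the focal class
    p_value: float
    n_focal: int
    n_other: int
    n_perm: int
    seed: int
    alternative: str


def class_enrichment(
    dte: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    focal: str = "TOP",
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Is the focal class shifted up in the TE-change ranking?

    The statistic is the focal genes' rank-sum, standardized by its exact
    null mean and variance (ties ignored in the variance, which only the
    standardization uses).  The p-value comes from permuting class labels;
    with the add-one convention the smallest attainable p is 1/(n_perm+1).
    ``alternative`` is "greater" (focal up, the primary direction),
    "less", or "two-sided".
    """
    values = np.asarray(dte, dtype=float)
    lab = np.asarray(labels)
    focal_mask = lab == focal
    n1, n2 = int(focal_mask.sum()), int((~focal_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"class_enrichment: empty class (focal={n1}, other={n2})")
    ranks = rankdata(values)
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)

    def stat(mask: np.ndarray) -> float:
        return (ranks[mask].sum() - mu) / sigma

    obs = stat(focal_mask)
    rng = np.random.default_rng(seed)
    n = n1 + n2
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, n1, replace=False)] = True
        s = stat(perm)
        if alternative == "greater":
            exceed += s >= obs - 1e-12
        elif alternative == "less":
            exceed += s <= obs + 1e-12
        else:
            exceed += abs(s) >= abs(obs) - 1e-12
    return EnrichmentResult(
        statistic=float(obs),
        p_value=(1.0 + exceed) / (1.0 + n_perm),
        n_focal=n1,
        n_other=n2,
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )
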