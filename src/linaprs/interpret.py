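"""Model-wise interpretation of a trained MTL LINA model.

Because the model is exactly linear in the genotype vector once the attention
vector A(x) is known, the instance-wise linear coefficient of SNP j for trait
t at subject x is c_tj(x) = K_tj * A_j(x) — no sampling or perturbation
approximation is involved.  First-order model-wise importance aggregates
these coefficients over an interpretation cohort (the test split, eval mode).

Second-order structure is equally exact: for the pre-sigmoid output
z_i = sum_j K_ij A_j(x) x_j + B_i of a piecewise-linear attention network,
the Hessian at kink-free points is

    H^(i)_kl = K_ik J_kl + K_il J_lk,     J_jk = dA_j / dx_k,

since the attention Jacobian J is locally constant.

False-discovery control uses frequency-matched decoy SNPs: the FDR at an
importance threshold is estimated as (#decoys above) / (#reals above), and
selection at a target FDR takes the smallest threshold meeting it.  Genetic
correlation between two traits is the Spearman correlation of their
importance scores over the union of their FDR-selected SNP sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._nn import BatchNorm, Dense, Dropout, LeakyReLU
from .linamodel import MTLModel

logger = logging.getLogger(__name__)

_AUTOSOMES = {str(c) for c in range(1, 23)}


def is_autosomal(chromosomes: np.ndarray) -> np.ndarray:
    """True for labels parsing to chromosomes 1-22 (non-sex chromosomes)."""
    return np.array([str(c) in _AUTOSOMES for c in chromosomes])


@dataclass
class ImportanceTable:
    """Trait x SNP nonnegative model-wise importance scores with provenance."""

    scores: np.ndarray
    snp_ids: np.ndarray
    is_decoy: np.ndarray
    chromosomes: np.ndarray
    trait_names: np.ndarray
    n_subjects_used: int
    aggregation: str = "signed_mean"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("importance scores must be nonnegative")
        if self.scores.shape != (len(self.trait_names), len(self.snp_ids)):
            raise ValueError("scores shape must be (n_traits, n_snps)")

    def trait_index(self, trait) -> int:
        idx = np.where(self.trait_names == trait)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown trait {trait!r}")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores.T, columns=list(self.trait_names))
        df.insert(0, "snp_id", self.snp_ids)
        df.insert(1, "chromosome", self.chromosomes)
        df.insert(2, "is_decoy", self.is_decoy)
        return df


def model_importance(model: MTLModel, X_interpret: np.ndarray,
                     snp_ids=None, chromosomes=None, is_decoy=None, trait_names=None,
                     aggregation: str = "signed_mean", mode: str = "eval",
                     drop_sex_chromosomes: bool = True,
                     batch_size: int = 2048) -> ImportanceTable:
    """First-order model-wise importance scores.

    ``aggregation="signed_mean"`` (default) scores SNP j for trait t as
    ``|mean_x K_tj A_j(x)|`` — the magnitude of the model-wise linear
    coefficient; ``"abs_mean"`` uses ``mean_x |K_tj A_j(x)|`` instead.
    Interpretation must be deterministic, so only eval mode is allowed.
    """
    if mode != "eval":
        raise ValueError("interpretation requires eval mode (dropout active in train mode)")
    if aggregation not in ("signed_mean", "abs_mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    X = np.asarray(X_interpret, dtype=float)
    n, m = X.shape
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(m)], dtype=object)
    if chromosomes is None:
        chromosomes = np.array(["1"] * m, dtype=object)
    if is_decoy is None:
        is_decoy = np.zeros(m, dtype=bool)
    d = model.config.n_traits
    if trait_names is None:
        trait_names = np.array([f"trait{t}" for t in range(d)], dtype=object)

    # |K_tj * a| factorizes, so both aggregations need only sums of A / |A|
    acc = np.zeros((d, m))
    for b0 in range(0, n, batch_size):
        A = model.attention(X[b0:b0 + batch_size], train=False)  # (b, m)
        if aggregation == "signed_mean":
            acc += model.K * A.sum(axis=0)
        else:
            acc += np.abs(model.K) * np.abs(A).sum(axis=0)
    scores = np.abs(acc / n) if aggregation == "signed_mean" else acc / n

    keep = is_autosomal(chromosomes) if drop_sex_chromosomes else np.ones(m, dtype=bool)
    return ImportanceTable(
        scores=scores[:, keep],
        snp_ids=np.asarray(snp_ids, dtype=object)[keep],
        is_decoy=np.asarray(is_decoy, dtype=bool)[keep],
        chromosomes=np.asarray(chromosomes, dtype=object)[keep],
        trait_names=np.asarray(trait_names, dtype=object),
        n_subjects_used=n,
        aggregation=aggregation,
    )


def importance_from_dataset(model, dataset, subject_idx, trait_names=None, **kw) -> ImportanceTable:
    """Convenience wrapper taking a GenotypeDataset and subject indices."""
    return model_importance(
        model,
        dataset.genotypes[subject_idx].astype(float),
        snp_ids=dataset.snp_ids,
        chromosomes=dataset.chromosomes,
        is_decoy=dataset.is_decoy,
        trait_names=trait_names,
        **kw,
    )


# ---------------------------------------------------------------------------
# Second-order: attention Jacobian and interaction Hessian
# ---------------------------------------------------------------------------

def attention_jacobian(model: MTLModel, x: np.ndarray) -> np.ndarray:
    """Exact eval-mode Jacobian J with J[j, k] = dA_j/dx_k at subject x.

    The eval-mode attention net is a chain of affine maps and diagonal
    leaky-ReLU slopes, so J is the product of the per-layer linear maps with
    slopes frozen at x's activation pattern (exact away from kinks).
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    m = model.config.n_snps
    G = np.eye(m)  # d(current layer output)/dx, shape (units, m)
    h = x
    for layer in model.net.layers:
        if isinstance(layer, Dense):
            h_new = layer.forward(h, train=False)
            G = layer.W.T @ G
        elif isinstance(layer, BatchNorm):
            h_new = layer.forward(h, train=False)
            G = layer.eval_scale()[:, None] * G
        elif isinstance(layer, LeakyReLU):
            slopes = layer.slopes_at(h)[0]
            h_new = h * slopes
            G = slopes[:, None] * G
        elif isinstance(layer, Dropout):
            h_new = h  # identity in eval mode
        else:  # pragma: no cover
            raise TypeError(f"unsupported layer {type(layer)}")
        h = h_new
    return G  # (m, m): rows attention units, columns inputs


@dataclass
class InteractionScores:
    """Symmetric second-order scores H for one trait at one subject (or the
    mean |H| over an interpretation cohort)."""

    matrix: np.ndarray
    trait: object

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("interaction matrix must be symmetric")


def interaction_scores(model: MTLModel, x: np.ndarray, trait: int) -> InteractionScores:
    """Exact Hessian of the trait's pre-sigmoid output at x:
    H_kl = K_tk J_kl + K_tl J_lk."""
    J = attention_jacobian(model, x)
    k_row = model.K[trait]
    T = k_row[:, None] * J
    return InteractionScores(matrix=T + T.T, trait=trait)


def interaction_importance(model: MTLModel, X: np.ndarray, trait: int) -> np.ndarray:
    """Model-wise interaction importance: mean |H| over subjects."""
    X = np.asarray(X, dtype=float)
    acc = np.zeros((model.config.n_snps, model.config.n_snps))
    for x in X:
        acc += np.abs(interaction_scores(model, x, trait).matrix)
    return acc / len(X)


# ---------------------------------------------------------------------------
# Decoy-based FDR
# ---------------------------------------------------------------------------

@dataclass
class FDRCurve:
    """Decoy/real counts and the FDR estimate at every distinct score.

    ``thresholds`` descend; counts are inclusive ("at or above"), so ties sit
    together on the selected side.  ``fdr_estimate`` is NaN where no real SNP
    clears the threshold.
    """

    thresholds: np.ndarray
    n_real_above: np.ndarray
    n_decoy_above: np.ndarray
    fdr_estimate: np.ndarray
    trait: object = None


def estimate_fdr(n_decoy_above: int, n_real_above: int) -> float:
    """Decoy-to-real count ratio; NaN when no real SNP is above."""
    if n_real_above == 0:
        return float("nan")
    return n_decoy_above / n_real_above


def fdr_curve(importance: ImportanceTable, trait, pseudocount: bool = False) -> FDRCurve:
    """Evaluate the decoy-estimated FDR at every distinct importance score.

    ``pseudocount=True`` adds 1 to the decoy count (conservative variant,
    off by default).
    """
    t = importance.trait_index(trait) if not isinstance(trait, (int, np.integer)) else int(trait)
    scores = importance.scores[t]
    decoy = importance.is_decoy
    if not decoy.any() or decoy.all():
        raise ValueError("FDR estimation needs both real and decoy SNPs; "
                         "build the interpretation panel with simdata.make_decoys")
    thresholds = np.unique(scores)[::-1]
    order = np.argsort(scores)[::-1]
    sorted_scores = scores[order]
    sorted_decoy = decoy[order].astype(int)
    cum_decoy = np.cumsum(sorted_decoy)
    cum_real = np.cumsum(1 - sorted_decoy)
    # rightmost index with sorted_scores >= threshold (inclusive counting)
    pos = len(sorted_scores) - np.searchsorted(sorted_scores[::-1], thresholds, side="left")
    n_decoy = cum_decoy[pos - 1]
    n_real = cum_real[pos - 1]
    num = n_decoy + (1 if pseudocount else 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_real > 0, num / np.maximum(n_real, 1), np.nan)
    return FDRCurve(thresholds=thresholds, n_real_above=n_real,
                    n_decoy_above=n_decoy, fdr_estimate=fdr,
                    trait=importance.trait_names[t])


def select_at_fdr(curve: FDRCurve, importance: ImportanceTable, trait,
                  target_fdr: float) -> tuple[list, float]:
    """Real SNPs at or above the smallest threshold with estimated FDR <=
    target.  Returns ``(snp_ids, threshold)``; an unreachable target yields an
    empty selection (with a warning) and an infinite threshold."""
    ok = np.where(np.nan_to_num(curve.fdr_estimate, nan=np.inf) <= target_fdr)[0]
    if len(ok) == 0:
        logger.warning("no importance threshold reaches FDR <= %g for trait %r",
                       target_fdr, curve.trait)
        return [], float("inf")
    threshold = float(curve.thresholds[ok].min())
    t = importance.trait_index(trait) if not isinstance(trait, (int, np.integer)) else int(trait)
    mask = (importance.scores[t] >= threshold) & ~importance.is_decoy
    return list(importance.snp_ids[mask]), threshold


# ---------------------------------------------------------------------------
# Overlaps and genetic correlation
# ---------------------------------------------------------------------------

def overlap_table(selected_sets: dict) -> pd.DataFrame:
    """Symmetric pairwise intersection-count matrix of per-trait SNP sets."""
    names = list(selected_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 traits")
    sets = {k: set(v) for k, v in selected_sets.items()}
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        mat.loc[a, a] = len(sets[a])
        for b in names:
            if a != b:
                mat.loc[a, b] = len(sets[a] & sets[b])
    return mat


def multiway_overlap(selected_sets: dict, traits: list) -> int:
    """Size of the intersection across the named traits (e.g. 3-way Venn)."""
    sets = [set(selected_sets[t]) for t in traits]
    return len(set.intersection(*sets)) if sets else 0


def genetic_correlation(importance: ImportanceTable, selected_sets: dict,
                        trait_a, trait_b) -> float:
    """Spearman correlation of two traits' importance scores over the union
    of their FDR-selected SNP sets (mid-rank ties)."""
    union = sorted(set(selected_sets[trait_a]) | set(selected_sets[trait_b]))
    if len(union) < 2:
        raise ValueError(f"union of selected SNPs for {trait_a!r}/{trait_b!r} "
                         "has fewer than 2 SNPs; correlation undefined")
    id_to_col = {s: j for j, s in enumerate(importance.snp_ids)}
    cols = [id_to_col[s] for s in union]
    ia = importance.trait_index(trait_a)
    ib = importance.trait_index(trait_b)
    rho = stats.spearmanr(importance.scores[ia, cols], importance.scores[ib, cols]).statistic
    return float(rho)


def correlation_report(importance: ImportanceTable, selected_sets: dict) -> pd.DataFrame:
    """All-pairs report: union size, intersection size, Spearman rho."""
    rows = []
    for a, b in combinations(list(selected_sets), 2):
        sa, sb = set(selected_sets[a]), set(selected_sets[b])
        union = sa | sb
        row = {"trait_a": a, "trait_b": b,
               "union_size": len(union), "intersection_size": len(sa & sb)}
        try:
            row["spearman_rho"] = genetic_correlation(importance, selected_sets, a, b)
        except ValueError:
            row["spearman_rho"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
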