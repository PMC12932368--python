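"""Ground-truth quantities and summary statistics of the breeding populations.

True GCA of a line is the mean genetic value of its hybrids with every line
of the opposite pool, computed exactly by per-locus marginalisation over the
partner pool's allele frequencies. Hybrid, GCA and SCA variances decompose the
genetic variance of the full factorial between pools; pool divergence is
tracked by Nei's minimum distance, mid-parent heterosis (Falconer's
``sum d (p_f - p_m)^2``), and fixed-allele fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rng import child_rng
from .trait import TraitArchitecture

__all__ = [
    "AlleleFrequencies",
    "true_gca",
    "line_values",
    "hybrid_value_matrix",
    "hybrid_values_pairs",
    "full_factorial_mean",
    "gca_sca_variances",
    "sca_gca_ratio",
    "prediction_accuracy",
    "nei_min_distance",
    "mid_parent_heterosis",
    "fixed_allele_fractions",
    "grm_pc_variance_fractions",
]

# exact enumeration of the hybrid matrix is a single BLAS product and stays
# cheap through the full 1,200 x 1,200 factorial; Monte-Carlo only beyond
_ENUMERATION_LIMIT = 2 * 10**6


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-QTN allele frequencies in the female and male pools."""

    p_female: np.ndarray
    p_male: np.ndarray

    def __post_init__(self) -> None:
        pf, pm = np.asarray(self.p_female), np.asarray(self.p_male)
        if pf.shape != pm.shape:
            raise ValueError("frequency vectors must have equal length")
        if (pf < 0).any() or (pf > 1).any() or (pm < 0).any() or (pm > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def polymorphic_in_union(self) -> np.ndarray:
        """Loci not fixed for the same allele in both pools."""
        return ~(((self.p_female == 0) & (self.p_male == 0))
                 | ((self.p_female == 1) & (self.p_male == 1)))

    @property
    def n_polymorphic(self) -> int:
        return int(np.count_nonzero(self.polymorphic_in_union))


def _alleles(x, trait: TraitArchitecture) -> np.ndarray:
    """Coerce a LinePopulation or a {0,1} allele array to QTN alleles."""
    if hasattr(x, "qtn_alleles"):
        return x.qtn_alleles(trait)
    return np.atleast_2d(np.asarray(x))


def line_values(B, trait: TraitArchitecture) -> np.ndarray:
    """Per-se genetic values of homozygous lines (allele matrix in {0,1})."""
    B = _alleles(B, trait)
    return (2.0 * B - 1.0) @ trait.a


def hybrid_value_matrix(pool_f, pool_m, trait: TraitArchitecture) -> np.ndarray:
    """Genetic values of all pairwise hybrids, shape (n_f, n_m).

    Per locus with parental alleles b_f, b_m: both 1 -> +a, both 0 -> -a,
    mixed -> d. The pair matrix factorises into two per-line terms plus a
    rank-m cross term, so the full factorial is a single matrix product.
    """
    Bf = _alleles(pool_f, trait).astype(float)
    Bm = _alleles(pool_m, trait).astype(float)
    ad = trait.a + trait.d
    const = float(np.sum(trait.a))
    u = Bf @ ad
    v = Bm @ ad
    # the cross term is the only O(n_f * n_m * m) cost; large products run in
    # float32 (< 1e-6 relative error on these sums), small ones stay exact
    if Bf.shape[0] * Bm.shape[0] * Bf.shape[1] > 5e7:
        cross = ((Bf * trait.d).astype(np.float32) @ Bm.T.astype(np.float32)).astype(float)
    else:
        cross = (Bf * trait.d) @ Bm.T
    return u[:, None] + v[None, :] - 2.0 * cross - const


def hybrid_values_pairs(
    pool_f, pool_m, i_idx: np.ndarray, j_idx: np.ndarray, trait: TraitArchitecture
) -> np.ndarray:
    """Genetic values of specific (female line, male line) hybrid pairs."""
    Bf = _alleles(pool_f, trait).astype(float)
    Bm = _alleles(pool_m, trait).astype(float)
    ad = trait.a + trait.d
    const = float(np.sum(trait.a))
    u = (Bf @ ad)[i_idx]
    v = (Bm @ ad)[j_idx]
    cross = np.empty(len(i_idx))
    step = max(1, 50_000_000 // max(Bf.shape[1], 1))  # cap scratch memory
    for lo in range(0, len(i_idx), step):
        sl = slice(lo, lo + step)
        cross[sl] = np.einsum(
            "ij,ij->i", Bf[i_idx[sl]] * trait.d, Bm[j_idx[sl]]
        )
    return u + v - 2.0 * cross - const


def true_gca(line, opposite_freqs: np.ndarray, trait: TraitArchitecture) -> np.ndarray:
    """True GCA: mean hybrid value of each line against the opposite pool.

    Exact per-locus marginalisation: a line allele b facing partner frequency
    p contributes ``b [p a + (1-p) d] + (1-b) [p d - (1-p) a]``, which equals
    the brute-force mean over all partner lines.
    """
    B = _alleles(line, trait).astype(float)
    p = np.asarray(opposite_freqs, dtype=float)
    coef = trait.a + trait.d - 2.0 * trait.d * p
    const = float(np.sum((trait.a + trait.d) * p - trait.a))
    out = B @ coef + const
    return out if out.shape[0] > 1 else out


def full_factorial_mean(
    freqs_f: np.ndarray, freqs_m: np.ndarray, trait: TraitArchitecture
) -> float:
    """Exact mean genetic value of all pairwise hybrids between two pools of
    homozygous lines, from the pools' allele frequencies (linearity of the
    mean per locus)."""
    pf = np.asarray(freqs_f, dtype=float)
    pm = np.asarray(freqs_m, dtype=float)
    het = pf * (1.0 - pm) + (1.0 - pf) * pm
    return float(
        np.sum(pf * pm * trait.a + het * trait.d - (1.0 - pf) * (1.0 - pm) * trait.a)
    )


def gca_sca_variances(
    pool_f,
    pool_m,
    trait: TraitArchitecture,
    n_sample_pairs: int = 100_000,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """(var_gca_f, var_gca_m, var_sca, var_hybrid) for the two pools.

    GCA variances are variances of true GCA over each pool's lines. The hybrid
    variance is over the genetic values of the full factorial (enumerated
    exactly up to 10^6 pairs, Monte-Carlo over ``n_sample_pairs`` uniform
    pairs beyond); the SCA variance is the remainder
    ``var_hybrid - var_gca_f - var_gca_m``, floored at zero.
    """
    Bf = _alleles(pool_f, trait)
    Bm = _alleles(pool_m, trait)
    pf = Bf.mean(axis=0)
    pm = Bm.mean(axis=0)
    var_gca_f = float(np.var(true_gca(Bf, pm, trait)))
    var_gca_m = float(np.var(true_gca(Bm, pf, trait)))
    n_pairs = Bf.shape[0] * Bm.shape[0]
    if n_pairs <= _ENUMERATION_LIMIT:
        var_hybrid = float(np.var(hybrid_value_matrix(Bf, Bm, trait)))
    else:
        rng = child_rng(seed, "hybrid_var_mc")
        i = rng.integers(0, Bf.shape[0], size=n_sample_pairs)
        j = rng.integers(0, Bm.shape[0], size=n_sample_pairs)
        var_hybrid = float(np.var(hybrid_values_pairs(Bf, Bm, i, j, trait)))
    var_sca = max(var_hybrid - var_gca_f - var_gca_m, 0.0)
    return var_gca_f, var_gca_m, var_sca, var_hybrid


def sca_gca_ratio(
    pool_f,
    pool_m,
    trait: TraitArchitecture,
    convention: str = "summed",
    n_sample_pairs: int = 100_000,
    seed: int = 0,
) -> float:
    """Ratio of SCA variance to GCA variance among all possible hybrids.

    ``convention="summed"`` (default) divides by the summed per-pool GCA
    variances — the GCA contribution to hybrid variance, which makes the
    ratio exactly 0 under pure additivity. ``"pooled-lines"`` divides by the
    variance of the concatenated GCA values of all lines from both pools
    (approximately half the summed value), kept for sensitivity analysis.
    """
    vf, vm, vs, _ = gca_sca_variances(
        pool_f, pool_m, trait, n_sample_pairs=n_sample_pairs, seed=seed
    )
    if convention == "summed":
        denom = vf + vm
    elif convention == "pooled-lines":
        Bf = _alleles(pool_f, trait)
        Bm = _alleles(pool_m, trait)
        gca = np.concatenate([
            true_gca(Bf, Bm.mean(axis=0), trait),
            true_gca(Bm, Bf.mean(axis=0), trait),
        ])
        denom = float(np.var(gca))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if denom <= 0:
        return float("nan")
    return vs / denom


def prediction_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between predicted and true values; NaN if either
    input is constant."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape or len(predicted) < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if np.std(predicted) == 0 or np.std(truth) == 0:
        return float("nan")
    return float(np.corrcoef(predicted, truth)[0, 1])


def nei_min_distance(freqs: AlleleFrequencies) -> float:
    """Nei's minimum genetic distance: mean squared frequency difference over
    QTN polymorphic in the union of the two pools; NaN if none are."""
    poly = freqs.polymorphic_in_union
    if not poly.any():
        return float("nan")
    diff = freqs.p_female[poly] - freqs.p_male[poly]
    return float(np.mean(diff**2))


def mid_parent_heterosis(freqs: AlleleFrequencies, trait: TraitArchitecture) -> float:
    """Mid-parent heterosis ``sum_i d_i (p_i^f - p_i^m)^2`` over all QTN.

    This is the classical hybrid-minus-midparent deviation for parental
    populations at Hardy-Weinberg proportions.
    """
    diff = np.asarray(freqs.p_female) - np.asarray(freqs.p_male)
    return float(np.sum(trait.d * diff**2))


def fixed_allele_fractions(
    freqs: AlleleFrequencies, n_total_qtn: int | None = None
) -> tuple[float, float]:
    """(frac_same, frac_opposite) fixed-allele fractions relative to all QTN.

    "Opposite" counts loci fixed at frequency 0 in one pool and 1 in the
    other; "same" counts loci fixed for the identical allele in both pools.
    """
    pf, pm = np.asarray(freqs.p_female), np.asarray(freqs.p_male)
    if n_total_qtn is None:
        n_total_qtn = len(pf)
    same = np.count_nonzero(((pf == 0) & (pm == 0)) | ((pf == 1) & (pm == 1)))
    opposite = np.count_nonzero(((pf == 0) & (pm == 1)) | ((pf == 1) & (pm == 0)))
    return same / n_total_qtn, opposite / n_total_qtn


def grm_pc_variance_fractions(genotypes: np.ndarray, n_components: int) -> np.ndarray:
    """Variance fractions of the leading principal components of a VanRaden
    genomic relationship matrix built from marker dosages.

    Returns NaN per component when the markers carry no variance.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n >= 2, m) dosage matrix")
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        return np.full(n_components, np.nan)
    M = X - 2.0 * p
    G = M @ M.T / denom
    ev = np.linalg.eigvalsh(G)[::-1]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        return np.full(n_components, np.nan)
    return ev[:n_components] / total
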