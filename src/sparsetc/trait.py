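"""Quantitative trait with directional dominance.

Each QTN carries a signed biological additive effect ``a`` (drawn standard
normal) and a dominance effect ``d = delta * |a|``, where the dominance degree
``delta`` is drawn from N(mu_delta, var_delta) independently of ``a``. Loci
with ``delta > 1`` are overdominant. Effects are rescaled once so that the
additive genetic variance in the founder population hits a target (20 by
default downstream), using the genic variance sum(2 p q alpha^2) with average
effects ``alpha = a + d (q - p)``; an empirical breeding-value variance basis
is available as an alternative. Genotype aa scores -a, Aa scores d, AA scores
+a, summed over QTN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .genome import HaplotypePopulation
from .rng import child_rng

__all__ = [
    "TraitArchitecture",
    "sample_trait",
    "genetic_value",
    "overdominance_fraction",
    "expected_overdominance_fraction",
    "average_effects",
    "genic_additive_variance",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """QTN effect sizes defining the genetic values of genotypes."""

    qtn_index: np.ndarray  # locus indices into the population's LocusMap
    a: np.ndarray  # signed additive effect per QTN (after scaling)
    delta: np.ndarray  # dominance degree per QTN
    d: np.ndarray  # dominance effect per QTN, d = delta * |a|
    mu_delta: float
    var_delta: float
    scale_factor: float

    def __post_init__(self) -> None:
        n = len(self.qtn_index)
        if not (len(self.a) == len(self.delta) == len(self.d) == n):
            raise ValueError("effect vectors must match the QTN count")

    @property
    def n_qtn(self) -> int:
        return len(self.qtn_index)


def average_effects(a: np.ndarray, d: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Average allele-substitution effects alpha = a + d(q - p)."""
    return a + d * (1.0 - 2.0 * np.asarray(p, dtype=float))


def genic_additive_variance(a: np.ndarray, d: np.ndarray, p: np.ndarray) -> float:
    """Genic additive variance sum_i 2 p_i q_i alpha_i^2."""
    p = np.asarray(p, dtype=float)
    alpha = average_effects(a, d, p)
    return float(np.sum(2.0 * p * (1.0 - p) * alpha**2))


def sample_trait(
    pop: HaplotypePopulation,
    mu_delta: float,
    var_delta: float,
    target_var_A: float,
    seed: int,
    scaling: str = "genic",
) -> TraitArchitecture:
    """Draw QTN effects and scale them to the target additive variance.

    ``scaling="genic"`` targets sum(2pq alpha^2) at founder allele frequencies;
    ``scaling="empirical"`` targets the variance of founder breeding values
    computed from the same average effects. Both alpha and d scale linearly
    with a, so a single closed-form rescaling is exact.
    """
    if target_var_A <= 0:
        raise ValueError("target_var_A must be positive")
    qtn = pop.loci.qtn_index
    if len(qtn) == 0:
        raise ValueError("no QTN assigned; call assign_loci first")
    rng = child_rng(seed, "trait")
    a = rng.standard_normal(len(qtn))
    delta = mu_delta + np.sqrt(var_delta) * rng.standard_normal(len(qtn))
    d = delta * np.abs(a)

    p = pop.allele_frequencies(qtn)
    if scaling == "genic":
        base = genic_additive_variance(a, d, p)
    elif scaling == "empirical":
        alpha = average_effects(a, d, p)
        bv = (pop.dosages(qtn) - 2.0 * p) @ alpha
        base = float(np.var(bv))
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if base <= 0:
        raise ValueError("founder population is monomorphic at all QTN; cannot scale")
    s = float(np.sqrt(target_var_A / base))
    a = a * s
    d = delta * np.abs(a)
    return TraitArchitecture(
        qtn_index=qtn,
        a=a,
        delta=delta,
        d=d,
        mu_delta=float(mu_delta),
        var_delta=float(var_delta),
        scale_factor=s,
    )


def genetic_value(genotype: np.ndarray, trait: TraitArchitecture) -> np.ndarray | float:
    """Total genetic value(s) of QTN dosage vector(s).

    ``genotype`` holds allele counts in {0, 1, 2} over the trait's QTN, in QTN
    order; a 2-D input (n, n_qtn) is scored row-wise. aa contributes -a, Aa
    contributes d, AA contributes +a.
    """
    x = np.asarray(genotype)
    if x.shape[-1] != trait.n_qtn:
        raise ValueError("genotype length must equal the QTN count")
    if x.size and (x.min() < 0 or x.max() > 2 or not np.issubdtype(x.dtype, np.integer)):
        if not np.isin(x, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
    val = (x - 1.0) @ trait.a + (x == 1) @ trait.d
    return float(val) if val.ndim == 0 else val


def overdominance_fraction(trait: TraitArchitecture) -> float:
    """Fraction of QTN with dominance degree above 1 (overdominant loci)."""
    return float(np.mean(trait.delta > 1.0))


def expected_overdominance_fraction(mu_delta: float, var_delta: float) -> float:
    """Closed form P(delta > 1) for delta ~ N(mu_delta, var_delta)."""
    if var_delta == 0:
        return float(mu_delta > 1.0)
    return float(norm.sf((1.0 - mu_delta) / np.sqrt(var_delta)))
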