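"""Hardy-Weinberg genotype-deviance statistic and its randomization test.

The statistic is the sum over the three diploid genotype classes of the
squared difference between observed and expected genotype *frequencies*
(not counts).  Its null distribution is obtained by repeatedly drawing
random panels of n diploid individuals at the stated population allele
frequency, with two independent alleles per individual.

The evaluation is one-sided on the upper tail of the (non-negative)
deviance; the Monte-Carlo p-value uses the add-one estimator
(1 + #{D_null >= D_obs}) / (1 + n_iter), so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed counts of the three genotype classes.

    ``n_pp``: homozygotes for the partial allele, ``n_pc``:
    heterozygotes, ``n_cc``: homozygotes for the complete allele.
    """

    n_pp: int
    n_pc: int
    n_cc: int

    def __post_init__(self) -> None:
        if min(self.n_pp, self.n_pc, self.n_cc) < 0:
            raise ValidationError("genotype counts must be non-negative")
        if self.n == 0:
            raise ValidationError("panel size must be positive")

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pc + self.n_cc

    def as_array(self) -> np.ndarray:
        return np.array([self.n_pp, self.n_pc, self.n_cc], dtype=np.int64)


@dataclass(frozen=True)
class McResult:
    """Randomization-test output.

    ``p_value`` is the upper-tail add-one Monte-Carlo estimate;
    ``percentile`` is the percent of null draws strictly below the
    observed deviance, so p_value ~ 1 - percentile/100 up to ties and
    the 1/(n_iter+1) correction.  ``p_mid`` counts ties at half weight
    (mid-p convention).
    """

    observed_deviance: float
    p_value: float
    percentile: float
    n_iter: int
    seed: int
    p_mid: float = field(default=float("nan"))
    tail: str = "upper"


def hwe_expected(p: float) -> np.ndarray:
    """Hardy-Weinberg genotype proportions (p^2, 2p(1-p), (1-p)^2)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"allele frequency must be in [0, 1], got {p}")
    q = 1.0 - p
    return np.array([p * p, 2.0 * p * q, q * q])


def genotype_deviance(obs: GenotypeCounts, expected: np.ndarray) -> float:
    """Sum of squared (observed - expected) genotype frequencies.

    Computed on proportions, so it is invariant to scaling the counts.
    """
    expected = np.asarray(expected, dtype=float)
    if expected.shape != (3,):
        raise ValidationError("expected proportions must have 3 entries")
    freqs = obs.as_array() / obs.n
    return float(((freqs - expected) ** 2).sum())


def mc_deviance_test(
    obs: GenotypeCounts,
    p: float,
    n_iter: int = 9_999,
    seed: int = 0,
) -> McResult:
    """Monte-Carlo upper-tail test of the genotype deviance.

    Each null draw assembles a panel of ``obs.n`` individuals, each
    receiving two independent alleles that are "partial" with
    probability ``p`` (equivalently a trinomial draw at HWE
    proportions), and its deviance is computed against hwe_expected(p).
    Fully reproducible given ``seed``.
    """
    if n_iter < 1:
        raise ConfigError(f"n_iter must be >= 1, got {n_iter}")
    if not 0.0 < p < 1.0:
        raise ValidationError(f"allele frequency must be in (0, 1), got {p}")
    expected = hwe_expected(p)
    d_obs = genotype_deviance(obs, expected)
    rng = np.random.default_rng(seed)
    null_counts = rng.multinomial(obs.n, expected, size=n_iter)
    d_null = (((null_counts / obs.n) - expected) ** 2).sum(axis=1)
    n_ge = int((d_null >= d_obs).sum())
    n_lt = int((d_null < d_obs).sum())
    n_eq = n_ge - int((d_null > d_obs).sum())
    p_value = (1 + n_ge) / (1 + n_iter)
    p_mid = (0.5 + (n_ge - n_eq) + 0.5 * n_eq) / (1 + n_iter)
    percentile = 100.0 * n_lt / n_iter
    return McResult(
        observed_deviance=d_obs,
        p_value=p_value,
        percentile=percentile,
        n_iter=n_iter,
        seed=seed,
        p_mid=p_mid,
    )


def p_value_from_percentile(percentile: float, n_iter: int = 9_999) -> float:
    """Add-one p-value implied by an observed statistic's null percentile.

    If the observed statistic sits at the given percentile of an
    ``n_iter``-draw null distribution, then round(percentile/100 *
    n_iter) draws fall below it and the remainder at or above it.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValidationError(f"percentile must be in [0, 100], got {percentile}")
    if n_iter < 1:
        raise ConfigError(f"n_iter must be >= 1, got {n_iter}")
    n_below = round(percentile / 100.0 * n_iter)
    return (1 + (n_iter - n_below)) / (1 + n_iter)


def exact_deviance_pvalue(obs: GenotypeCounts, p: float) -> float:
    """Exact upper-tail probability by complete trinomial enumeration.

    P(D_null >= D_obs) summed over all genotype-count triples of size n
    under HWE proportions.  Intended for small panels (cost O(n^2)).
    """
    from scipy.stats import multinomial

    expected = hwe_expected(p)
    d_obs = genotype_deviance(obs, expected)
    n = obs.n
    total = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            freqs = np.array([a, b, c]) / n
            d = float(((freqs - expected) ** 2).sum())
            if d >= d_obs - 1e-12:
                total += float(multinomial.pmf([a, b, c], n=n, p=expected))
    return total
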