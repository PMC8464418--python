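"""Agreement and comparison statistics for paired categorical readings.

When two imaging examinations (or two readers) classify the same patients,
their agreement beyond chance is summarized by Cohen's kappa on the k×k
contingency table of paired outcomes, and the difference between the two
methods' marginal distributions is tested with Pearson's χ².

Kappa interpretation uses the conventional bands: 0.41–0.60 moderate,
0.61–0.80 good, 0.81–1.00 very good (values below 0.41 are reported as
"below moderate").

A seeded synthetic generator produces rating tables with a configurable
true agreement probability, standing in for per-patient clinical readings
that are never published; it also drives the χ² type-I-error calibration
check (independent raters, nominal α recovered empirically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "cohen_kappa",
    "kappa_band",
    "chi_square_test",
    "simulate_rating_table",
    "chi_square_type1_rate",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Square table of paired counts: rows method A, columns method B."""

    counts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be a square 2D table, got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        if np.any(c != np.floor(c)):
            raise ValueError("counts must be integers")
        c = c.astype(np.int64)
        if c.sum() == 0:
            raise ValueError("table total must be positive")
        object.__setattr__(self, "counts", c)
        if self.labels is not None and len(self.labels) != c.shape[0]:
            raise ValueError("labels length must match table size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def cohen_kappa(table: ContingencyTable) -> float:
    """Chance-corrected agreement ``(p_o − p_e) / (1 − p_e)``.

    ``p_o`` is the observed agreement (diagonal fraction) and ``p_e`` the
    agreement expected from the marginal distributions alone.  Returns
    ``nan`` for the degenerate table whose margins force ``p_e = 1``
    (both raters use a single category), where kappa is undefined.
    """
    c = table.counts
    n = table.total
    p_o = np.trace(c) / n
    row = c.sum(axis=1) / n
    col = c.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


_BANDS = (
    (0.81, 1.00, "very good"),
    (0.61, 0.80, "good"),
    (0.41, 0.60, "moderate"),
)


def kappa_band(kappa: float) -> str:
    """Interpretation band for a kappa value.

    0.41–0.60 → "moderate", 0.61–0.80 → "good", 0.81–1.00 → "very good";
    anything smaller (including negative kappa) → "below moderate".
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    for lo, hi, label in _BANDS:
        if kappa >= lo:
            return label
    return "below moderate"


def chi_square_test(
    table: ContingencyTable, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson χ² test of independence on the contingency table.

    Returns ``(statistic, dof, p_value)`` with the statistic
    ``Σ (O − E)² / E``, expected counts from the margins and
    ``dof = (rows − 1)(cols − 1)``.  Yates' continuity correction is off by
    default and available as a flag.  Tables with a zero expected count are
    rejected — collapse sparse categories or collect more data.
    """
    c = table.counts
    expected = stats.contingency.expected_freq(c)
    if np.any(expected == 0):
        raise ValueError(
            "a zero expected count makes the chi-square approximation invalid; "
            "merge empty categories before testing"
        )
    res = stats.chi2_contingency(c, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def simulate_rating_table(
    n_patients: int,
    k: int = 2,
    agreement: float | None = None,
    probs_a=None,
    probs_b=None,
    seed: int = 0,
) -> ContingencyTable:
    """Synthetic paired-rating table for two methods over ``n_patients``.

    With ``agreement`` set, method B repeats method A's category with that
    probability and otherwise picks one of the remaining categories
    uniformly — a simple one-parameter model of inter-method concordance.
    With ``agreement=None`` the two methods rate independently with
    marginal probabilities ``probs_a`` / ``probs_b`` (uniform by default),
    the null model of the χ² calibration.
    """
    if n_patients < 1 or k < 2:
        raise ValueError("need n_patients >= 1 and k >= 2 categories")
    rng = np.random.default_rng(seed)
    pa = np.full(k, 1.0 / k) if probs_a is None else np.asarray(probs_a, float)
    if agreement is not None:
        if not 0.0 <= agreement <= 1.0:
            raise ValueError("agreement must be a probability")
        a = rng.choice(k, size=n_patients, p=pa)
        agree = rng.random(n_patients) < agreement
        shift = rng.integers(1, k, size=n_patients)
        b = np.where(agree, a, (a + shift) % k)
    else:
        pb = np.full(k, 1.0 / k) if probs_b is None else np.asarray(probs_b, float)
        a = rng.choice(k, size=n_patients, p=pa)
        b = rng.choice(k, size=n_patients, p=pb)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return ContingencyTable(counts=counts)


def chi_square_type1_rate(
    n_tables: int = 10_000,
    n_patients: int = 30,
    k: int = 2,
    alpha: float = 0.05,
    min_expected: float = 5.0,
    seed: int = 0,
) -> tuple[float, int]:
    """Empirical χ² rejection rate under independent ratings.

    Simulates ``n_tables`` tables of ``n_patients`` paired, *independent*
    uniform ratings, applies the (uncorrected) Pearson test at level
    ``alpha`` to every table whose expected counts all reach
    ``min_expected``, and returns ``(rejection_rate, n_valid_tables)``.
    A calibrated test recovers ``alpha`` up to Monte-Carlo and
    discreteness error.  Vectorized: cell counts are drawn multinomially
    under the independence null.
    """
    rng = np.random.default_rng(seed)
    p_cells = np.full(k * k, 1.0 / (k * k))
    counts = rng.multinomial(n_patients, p_cells, size=n_tables).reshape(
        n_tables, k, k
    )
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    expected = row * col / n_patients
    valid = (expected >= min_expected).all(axis=(1, 2))
    e = expected[valid]
    o = counts[valid]
    statistic = ((o - e) ** 2 / e).sum(axis=(1, 2))
    dof = (k - 1) ** 2
    pvals = stats.chi2.sf(statistic, dof)
    return float(np.mean(pvals < alpha)), int(valid.sum())
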