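"""Non-parametric test battery for expression and activity comparisons.

Implements the four tests of the study workflow with SPSS-compatible
conventions:

* one-sample Kolmogorov–Smirnov normality screen with parameters estimated
  from the sample and the classical (non-Lilliefors) asymptotic p-value;
* Mann–Whitney U with a tie-corrected normal approximation and, optionally,
  exact enumeration for small groups;
* Friedman's rank test with mid-ranks and tie correction;
* Wilcoxon signed-rank with zero-difference dropping (the SPSS convention)
  and a tie-corrected normal approximation.

Z statistics carry no continuity correction by default (matching the
reported conventions); a continuity-corrected variant is available.
``run_battery`` chains the tests in the study's order on a gene x sample
TPM matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "BatteryReport",
    "ks_normality",
    "mann_whitney",
    "friedman",
    "wilcoxon_signed_rank",
    "run_battery",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    z_value: float | None = None
    df: int | None = None
    n_effective: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def ks_normality(
    values: Sequence[float], method: str = "lilliefors", label: str = ""
) -> TestResult:
    """One-sample KS test against a normal fitted to the sample.

    D is the supremum distance between the empirical CDF and the normal CDF
    with the sample mean and SD.  Because the parameters are estimated from
    the same sample, the default p-value applies the Lilliefors correction
    (the null distribution of D under estimated parameters); the power of
    the screen at study-scale n (a dozen individuals) depends on it.
    ``method="classical"`` gives the uncorrected asymptotic Kolmogorov p of
    sqrt(n)*D instead, which is conservative for a fitted null.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"KS normality screen needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    m, s = x.mean(), x.std(ddof=1)
    xs = np.sort(x)
    cdf = stats.norm.cdf(xs, loc=m, scale=s)
    n = x.size
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    D = max(d_plus, d_minus)
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors as _lilliefors

        _, p = _lilliefors(x, dist="norm", pvalmethod="table")
    elif method == "classical":
        p = float(stats.kstwobign.sf(math.sqrt(n) * D))
    else:
        raise ValueError(f"unknown KS p-value method {method!r}")
    return TestResult(
        test_name="ks_normality",
        statistic=float(D),
        p_value=min(float(p), 1.0),
        n_effective=n,
        label=label,
    )


def _mw_exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided permutation p for Mann–Whitney on the pooled values."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0
        if abs(u1 - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    continuity_correction: bool = False,
    exact: bool = False,
    label: str = "",
) -> TestResult:
    """Mann–Whitney U with tie-corrected normal approximation.

    Reports the smaller of the two U statistics; Z is signed by the first
    group's rank sum relative to its expectation (so a stochastically smaller
    first group gives a negative Z).  With ``exact=True`` the p-value comes
    from full enumeration of group assignments (feasible for small groups).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        diff = u1 - mu
        if continuity_correction and diff != 0:
            diff -= 0.5 * np.sign(diff)
        z = diff / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    if exact:
        p = _mw_exact_p(x, y, u1)
    return TestResult(
        test_name="mann_whitney",
        statistic=float(u),
        p_value=min(p, 1.0),
        z_value=float(z),
        n_effective=n,
        label=label,
    )


def friedman(data: Sequence[Sequence[float]], label: str = "") -> TestResult:
    """Friedman rank test on a blocks x treatments table.

    Rows are blocks (e.g. individuals or replicates), columns treatments
    (e.g. genes).  Mid-ranks resolve within-block ties and the chi-square
    statistic carries the standard tie correction; df = k - 1.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("Friedman needs a rectangular blocks x treatments table")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError(f"Friedman needs >= 2 blocks and >= 2 treatments, got {arr.shape}")
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction: sum over blocks of (t^3 - t) for each tie group
    tie_sum = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += np.sum(counts**3 - counts)
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction > 0:
        chi2 /= correction
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return TestResult(
        test_name="friedman",
        statistic=float(chi2),
        p_value=p,
        df=df,
        n_effective=n,
        label=label,
    )


def _wilcoxon_exact_p(d: np.ndarray, w_plus: float) -> float:
    """Two-sided p by enumerating all 2^n sign assignments on |d| ranks."""
    ranks = stats.rankdata(np.abs(d))
    n = len(d)
    mu = n * (n + 1) / 4.0
    count = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_plus - mu) - 1e-12:
            count += 1
    return count / total


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    continuity_correction: bool = False,
    exact: bool = False,
    label: str = "",
) -> TestResult:
    """Wilcoxon signed-rank on paired samples, zero differences dropped.

    The statistic is the smaller signed-rank sum; Z is computed from the
    positive-rank sum W+ of the differences x - y, so swapping the two
    inputs negates Z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        diff = w_plus - mu
        if continuity_correction and diff != 0:
            diff -= 0.5 * np.sign(diff)
        z = diff / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    if exact:
        p = _wilcoxon_exact_p(d, w_plus)
    return TestResult(
        test_name="wilcoxon_signed_rank",
        statistic=float(min(w_plus, w_minus)),
        p_value=min(p, 1.0),
        z_value=float(z),
        n_effective=n,
        label=label,
    )


@dataclass
class BatteryReport:
    """Structured results of the full study-order test battery."""

    normality: list[TestResult] = field(default_factory=list)
    species_total: TestResult | None = None
    cross_species_pairs: list[TestResult] = field(default_factory=list)
    within_species: dict[str, TestResult] = field(default_factory=dict)
    pairwise_within: dict[str, list[TestResult]] = field(default_factory=dict)

    def all_results(self) -> list[TestResult]:
        out = list(self.normality)
        if self.species_total is not None:
            out.append(self.species_total)
        out.extend(self.cross_species_pairs)
        out.extend(self.within_species.values())
        for results in self.pairwise_within.values():
            out.extend(results)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test": r.test_name,
                "label": r.label,
                "statistic": r.statistic,
                "z": r.z_value,
                "df": r.df,
                "p": r.p_value,
                "n": r.n_effective,
            }
            for r in self.all_results()
        ]
        return pd.DataFrame(rows)


def run_battery(
    matrix: pd.DataFrame,
    species_of: Mapping[str, str],
    alpha: float = 0.05,
    continuity_correction: bool = False,
) -> BatteryReport:
    """Run the study's test sequence on a gene x sample TPM matrix.

    Order: per-gene KS normality screen; Mann–Whitney on per-sample species
    totals (summing each species' genes within a sample); Mann–Whitney on
    every cross-species gene pair; Friedman within each species (blocks =
    samples, treatments = genes); Wilcoxon pairwise within a species only
    when its Friedman test is significant at ``alpha``.
    """
    if matrix.isnull().any().any():
        raise ValueError("TPM matrix contains missing cells")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("TPM values must be >= 0")
    missing = [g for g in matrix.index if g not in species_of]
    if missing:
        raise ValueError(f"genes without a species tag: {missing}")
    species = sorted(set(species_of[g] for g in matrix.index))
    if len(species) != 2:
        raise ValueError(f"the battery compares exactly two species, got {species}")
    genes_by_species = {
        sp: [g for g in matrix.index if species_of[g] == sp] for sp in species
    }
    for sp, genes in genes_by_species.items():
        if len(genes) < 2:
            raise ValueError(f"species {sp!r} needs >= 2 genes, got {len(genes)}")

    report = BatteryReport()
    for gene in matrix.index:
        try:
            report.normality.append(ks_normality(matrix.loc[gene], label=gene))
        except ValueError:
            pass  # constant expression row: normality screen undefined

    sp_a, sp_b = species
    totals_a = matrix.loc[genes_by_species[sp_a]].sum(axis=0)
    totals_b = matrix.loc[genes_by_species[sp_b]].sum(axis=0)
    report.species_total = mann_whitney(
        totals_a,
        totals_b,
        continuity_correction=continuity_correction,
        label=f"{sp_a} vs {sp_b} (per-sample totals)",
    )

    for ga in genes_by_species[sp_a]:
        for gb in genes_by_species[sp_b]:
            report.cross_species_pairs.append(
                mann_whitney(
                    matrix.loc[ga],
                    matrix.loc[gb],
                    continuity_correction=continuity_correction,
                    label=f"{ga} vs {gb}",
                )
            )

    for sp in species:
        genes = genes_by_species[sp]
        table = matrix.loc[genes].to_numpy().T  # blocks = samples
        fr = friedman(table, label=sp)
        report.within_species[sp] = fr
        if fr.p_value < alpha:
            results = []
            for ga, gb in itertools.combinations(genes, 2):
                results.append(
                    wilcoxon_signed_rank(
                        matrix.loc[ga],
                        matrix.loc[gb],
                        continuity_correction=continuity_correction,
                        label=f"{ga} vs {gb}",
                    )
                )
            report.pairwise_within[sp] = results
    return report
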