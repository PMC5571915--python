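"""Enrichment and evaluation statistics for variant location analyses.

The regional preference of a variant class is summarized two ways:

* the observed/expected (O/E) ratio — the fraction of variants falling in
  a region divided by the region's share of all residues;
* the odds ratio OR_ij = [P_i/(1-P_i)] / [P_j/(1-P_j)], where
  P_i = n_i/N_i is the per-residue variant rate in region i, with a
  two-tailed Fisher exact p-value and a Wald 95% confidence interval on
  the log odds.

Interface predictions are evaluated by sensitivity TP/(TP+FN) and
precision TP/(TP+FP) against the true interface, with a seeded random
surface selection of matched size as the chance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "ContingencyCounts",
    "EnrichmentResult",
    "PredictionEval",
    "observed_expected_ratio",
    "odds_ratio",
    "two_tailed_p",
    "evaluate_prediction",
    "random_surface_baseline",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Variant and residue counts for two regions i and j."""

    n_i: int
    N_i: int
    n_j: int
    N_j: int
    label_i: str = "i"
    label_j: str = "j"

    def __post_init__(self) -> None:
        if not (0 <= self.n_i <= self.N_i and 0 <= self.n_j <= self.N_j):
            raise ValueError("counts must satisfy 0 <= n <= N")
        if self.N_i <= 0 or self.N_j <= 0:
            raise ValueError("region residue totals must be positive")

    def swapped(self) -> "ContingencyCounts":
        return ContingencyCounts(self.n_j, self.N_j, self.n_i, self.N_i,
                                 self.label_j, self.label_i)

    def table(self) -> np.ndarray:
        """2x2 table [[n_i, N_i - n_i], [n_j, N_j - n_j]]."""
        return np.array([[self.n_i, self.N_i - self.n_i],
                         [self.n_j, self.N_j - self.n_j]])


@dataclass
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    label_i: str = "i"
    label_j: str = "j"
    zero_cell_corrected: bool = False


def observed_expected_ratio(n_region: int, n_total_snps: int,
                            r_region: int, r_total: int) -> float:
    """(n_region/n_total_snps) / (r_region/r_total)."""
    if n_total_snps <= 0 or r_total <= 0 or r_region <= 0:
        raise ZeroDivisionError(
            "O/E ratio undefined: empty variant set or empty region")
    return (n_region / n_total_snps) / (r_region / r_total)


def two_tailed_p(counts: ContingencyCounts) -> float:
    """Fisher's exact two-tailed p on the 2x2 region table."""
    _, p = sp_stats.fisher_exact(counts.table(), alternative="two-sided")
    return float(p)


def odds_ratio(counts: ContingencyCounts) -> EnrichmentResult:
    """Odds ratio of per-residue variant rates with Fisher p and Wald CI.

    Zero cells are handled by the Haldane-Anscombe +0.5 correction, which
    is flagged on the result.
    """
    a, b = counts.n_i, counts.N_i - counts.n_i
    c, d = counts.n_j, counts.N_j - counts.n_j
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = np.log(oratio)
    return EnrichmentResult(
        odds_ratio=float(oratio),
        ci_low=float(np.exp(log_or - 1.959963984540054 * se)),
        ci_high=float(np.exp(log_or + 1.959963984540054 * se)),
        p_value=two_tailed_p(counts),
        label_i=counts.label_i,
        label_j=counts.label_j,
        zero_cell_corrected=corrected,
    )


@dataclass
class PredictionEval:
    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    precision: float | None


def evaluate_prediction(predicted: set, truth: set,
                        universe: set) -> PredictionEval:
    """Sensitivity and precision of a predicted residue set.

    Undefined ratios (empty truth or empty prediction) are reported as
    ``None`` rather than zero.
    """
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth must be subsets of the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    return PredictionEval(tp=tp, fp=fp, fn=fn, sensitivity=sens,
                          precision=prec)


def random_surface_baseline(surface_residues: set, fraction: float,
                            seed: int) -> set:
    """Uniform random selection of ``round(fraction * n)`` surface residues.

    Reproducible: the surface set is ordered canonically before sampling.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    ordered = sorted(surface_residues)
    size = int(round(fraction * len(ordered)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=size, replace=False)
    return {ordered[i] for i in idx}


def summarize_census(census) -> dict:
    """Headline enrichment statistics of one :class:`RegionCensus`.

    Returns, for the disease class: O/E ratios for core / interface /
    non-interacting surface, the interface-vs-surface odds ratio with its
    p-value, the interface hot-spot O/E and odds ratio, the observed and
    expected percentage distributions over the three regions, and the
    fraction of surface residues that are interface.
    """
    from .variants import VariantCategory  # local import to avoid a cycle

    rc = census.residue_counts
    dis = census.snp_counts[VariantCategory.DISEASE]
    n_dis = census.snp_total(VariantCategory.DISEASE)
    regions = ("core", "interface", "non_interface")

    oe = {r: observed_expected_ratio(dis[r], n_dis, rc[r], rc["total"])
          for r in regions}
    observed_pct = {r: 100.0 * dis[r] / n_dis for r in regions}
    expected_pct = {r: 100.0 * rc[r] / rc["total"] for r in regions}

    or_if = odds_ratio(ContingencyCounts(
        dis["interface"], rc["interface"],
        dis["non_interface"], rc["non_interface"],
        label_i="interface", label_j="non_interface"))

    hs = dis["interface_hotspot"]
    oe_hotspot = observed_expected_ratio(
        hs, n_dis, rc["hotspot_at_interface"], rc["total"])
    or_hotspot = odds_ratio(ContingencyCounts(
        hs, rc["hotspot_at_interface"],
        dis["non_interface"], rc["non_interface"],
        label_i="interface_hotspot", label_j="non_interface"))

    surface = rc["interface"] + rc["non_interface"]
    return {
        "context": census.context,
        "oe_disease": oe,
        "observed_pct_disease": observed_pct,
        "expected_pct": expected_pct,
        "or_interface_vs_surface": or_if,
        "oe_hotspot_disease": oe_hotspot,
        "or_hotspot_vs_surface": or_hotspot,
        "surface_interface_fraction": rc["interface"] / surface,
    }
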