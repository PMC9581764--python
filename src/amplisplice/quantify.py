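"""Per-allele splice quantification and the exact 2x2 association test.

Two quantification routes are provided, matching the two ways read evidence
is summarised in allele-resolved amplicon experiments:

* *read-proportion* counting (``per_allele_fractions``): each classified
  read votes once for its isoform within its allele group;
* *mean-depth inclusion* (``depth_inclusion``): per-base coverage of an
  alternate-exon region relative to a canonical anchor region, the metric of
  choice when isoform boundaries are read from a coverage track.  For
  full-length amplicon reads and whole-exon regions the two routes agree
  exactly.

The association test is Fisher's exact test on a 2x2 allele-count table
under the noncentral (Fisher) hypergeometric model: the two-sided p-value
sums point probabilities not exceeding the observed table's, the odds ratio
is the conditional maximum-likelihood estimate (CMLE, the psi solving
E_psi[K] = k_obs), and the confidence interval inverts the one-sided
conditional tail tests at (1 - conf)/2 per side.  This is the convention of
R's ``fisher.test``; roots here are solved to 1e-10 relative tolerance, so
the last printed digits can differ from implementations using looser root
tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .classify import AlignedRead


@dataclass
class QuantTable:
    """Per-allele splice-event read counts and fractions."""

    table: pd.DataFrame  # allele_id, event_id, read_count, fraction
    totals: dict[str, int]  # classified reads per allele
    excluded: dict[str, int]  # missing-allele / unclassified tallies

    def fraction(self, allele_id: str, event_id: str) -> float:
        rows = self.table[
            (self.table.allele_id == allele_id) & (self.table.event_id == event_id)
        ]
        if rows.empty:
            return 0.0
        return float(rows.fraction.iloc[0])

    def to_text(self) -> str:
        lines = ["allele_id\tevent_id\tread_count\tfraction_pct"]
        for r in self.table.itertuples():
            lines.append(
                f"{r.allele_id}\t{r.event_id}\t{r.read_count}\t{100 * r.fraction:.2f}"
            )
        return "\n".join(lines)


def per_allele_fractions(
    event_calls: pd.DataFrame,
    allele_calls: pd.DataFrame,
    allele_names: Optional[dict[str, str]] = None,
) -> QuantTable:
    """Aggregate per-read event and allele calls into per-allele fractions.

    Reads with a missing/other allele call or an unclassified event are
    tallied separately and excluded from the denominators.  ``allele_names``
    optionally renames the ``ref``/``alt`` statuses (or haplotype labels)
    into display allele ids.
    """
    merged = event_calls.merge(allele_calls, on="read_id", how="inner")
    allele_col = "status" if "status" in merged.columns else "haplotype"
    excluded = {
        "missing_allele": int((~merged[allele_col].isin(["ref", "alt"])).sum()),
        "unclassified_event": int((merged.event == "unclassified").sum()),
    }
    usable = merged[
        merged[allele_col].isin(["ref", "alt"]) & (merged.event != "unclassified")
    ]
    rows = []
    totals = {}
    for allele in merged.loc[merged[allele_col].isin(["ref", "alt"]), allele_col].unique():
        name = (allele_names or {}).get(allele, allele)
        grp = usable[usable[allele_col] == allele]
        totals[name] = len(grp)
        if len(grp) == 0:
            # no classified reads: the allele's fractions are undefined
            excluded[f"undefined_fraction:{name}"] = 0
            continue
        for event, sub in grp.groupby("event"):
            rows.append((name, event, len(sub), len(sub) / len(grp)))
    table = pd.DataFrame(
        rows, columns=["allele_id", "event_id", "read_count", "fraction"]
    ).sort_values(["allele_id", "event_id"], ignore_index=True)
    return QuantTable(table, totals, excluded)


@dataclass
class InclusionResult:
    allele_id: str
    mean_depth_alt: float
    mean_depth_anchor: float
    inclusion_fraction: float
    alt_region: tuple[int, int]
    anchor_region: tuple[int, int]
    convention: str


def _region_mean_depth(reads: Sequence[AlignedRead], region: tuple[int, int]) -> float:
    lo, hi = region
    if lo > hi:
        raise ValueError(f"empty region {region}")
    depth = np.zeros(hi - lo + 1, dtype=float)
    for read in reads:
        for bs, be in read.reference_blocks():
            a, b = max(bs, lo), min(be, hi)
            if a <= b:
                depth[a - lo : b - lo + 1] += 1
    return float(depth.mean())


def depth_inclusion(
    reads_by_allele: dict[str, Sequence[AlignedRead]],
    alt_region: tuple[int, int],
    anchor_region: tuple[int, int],
    convention: str = "anchor",
) -> list[InclusionResult]:
    """Mean-depth inclusion of an alternate region, per allele group.

    ``anchor`` convention: mean depth over ``alt_region`` divided by mean
    depth over ``anchor_region`` (a canonical exon covered by every
    isoform).  ``competing`` convention: alt / (alt + anchor).  Gaps in a
    read's alignment contribute zero depth.
    """
    if convention not in ("anchor", "competing"):
        raise ValueError(f"unknown convention {convention!r}")
    if max(alt_region[0], anchor_region[0]) <= min(alt_region[1], anchor_region[1]):
        raise ValueError("alt and anchor regions overlap")
    out = []
    for allele_id, reads in reads_by_allele.items():
        alt = _region_mean_depth(reads, alt_region)
        anchor = _region_mean_depth(reads, anchor_region)
        if convention == "anchor":
            if anchor == 0:
                raise ZeroDivisionError(
                    f"zero anchor depth for allele {allele_id!r}; inclusion undefined"
                )
            frac = alt / anchor
        else:
            if alt + anchor == 0:
                raise ZeroDivisionError(
                    f"zero depth in both regions for allele {allele_id!r}"
                )
            frac = alt / (alt + anchor)
        out.append(
            InclusionResult(allele_id, alt, anchor, frac, alt_region, anchor_region, convention)
        )
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test with conditional-MLE odds ratio and exact CI


@dataclass
class FisherResult:
    p_two_sided: float
    or_cmle: float
    ci_low: float
    ci_high: float
    conf_level: float
    or_sample: float
    method: str = (
        "two-sided exact p (point probabilities <= observed); conditional MLE OR; "
        "CI by inversion of one-sided conditional tail tests"
    )


class _CondDist:
    """Noncentral hypergeometric distribution conditional on 2x2 margins."""

    def __init__(self, a: int, b: int, c: int, d: int):
        if min(a, b, c, d) < 0:
            raise ValueError("negative counts in 2x2 table")
        self.a = a
        m1, m2 = a + b, c + d  # row margins
        n1 = a + c  # first column margin
        self.lo = max(0, n1 - m2)
        self.hi = min(n1, m1)
        self.support = np.arange(self.lo, self.hi + 1)
        k = self.support
        self.logw = (
            gammaln(m1 + 1) - gammaln(k + 1) - gammaln(m1 - k + 1)
            + gammaln(m2 + 1) - gammaln(n1 - k + 1) - gammaln(m2 - n1 + k + 1)
        )

    def logpmf(self, log_psi: float) -> np.ndarray:
        lw = self.logw + self.support * log_psi
        return lw - logsumexp(lw)

    def mean(self, log_psi: float) -> float:
        p = np.exp(self.logpmf(log_psi))
        return float(p @ self.support)

    def cdf_at_obs(self, log_psi: float) -> float:
        p = np.exp(self.logpmf(log_psi))
        return float(p[self.support <= self.a].sum())

    def sf_at_obs(self, log_psi: float) -> float:
        p = np.exp(self.logpmf(log_psi))
        return float(p[self.support >= self.a].sum())


_LOG_PSI_MAX = 80.0


def _solve(f, target: float, increasing: bool, xtol: float = 1e-12) -> float:
    """Solve f(log_psi) = target on [-80, 80], returning psi."""
    g = (lambda x: f(x) - target) if increasing else (lambda x: target - f(x))
    if g(-_LOG_PSI_MAX) >= 0:
        return 0.0
    if g(_LOG_PSI_MAX) <= 0:
        return math.inf
    return math.exp(brentq(g, -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=xtol, rtol=1e-14))


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], conf: float = 0.95
) -> FisherResult:
    """Exact test, conditional-MLE odds ratio and exact CI for a 2x2 table.

    Degenerate tables (a zero row or column margin) return p = 1 with an
    undefined (NaN) odds ratio.
    """
    (a, b), (c, d) = [list(map(int, row)) for row in table]
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts in 2x2 table")
    if not 0 < conf < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return FisherResult(1.0, math.nan, math.nan, math.nan, conf, math.nan)
    dist = _CondDist(a, b, c, d)
    # two-sided p at psi = 1: sum point probabilities <= observed (with the
    # customary relative epsilon guarding float ties)
    pmf = np.exp(dist.logpmf(0.0))
    p_obs = float(pmf[dist.support == a][0])
    p_two = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p_two = min(1.0, p_two)
    # conditional MLE: E_psi[K] = a (mean is increasing in psi)
    if a == dist.lo:
        or_cmle = 0.0
    elif a == dist.hi:
        or_cmle = math.inf
    else:
        or_cmle = _solve(dist.mean, float(a), increasing=True)
    alpha = (1 - conf) / 2
    # lower bound: P_psi(K >= a) = alpha (increasing in psi)
    ci_low = 0.0 if a == dist.lo else _solve(dist.sf_at_obs, alpha, increasing=True)
    # upper bound: P_psi(K <= a) = alpha (decreasing in psi)
    ci_high = math.inf if a == dist.hi else _solve(dist.cdf_at_obs, alpha, increasing=False)
    or_sample = math.inf if b * c == 0 else (a * d) / (b * c)
    return FisherResult(p_two, or_cmle, ci_low, ci_high, conf, or_sample)


# ---------------------------------------------------------------------------
# control comparison and reference-range flagging


@dataclass
class ControlComparison:
    case_fraction: float
    control_min: float
    control_max: float
    control_mean: float
    outside_range: bool


def compare_to_controls(
    case_fraction: float, control_fractions: Sequence[float]
) -> ControlComparison:
    """Flag a case inclusion fraction lying outside the control min–max range.

    Boundaries are inclusive: a case equal to a control extreme is not
    flagged.
    """
    if len(control_fractions) == 0:
        raise ValueError("at least one control is required")
    lo, hi = min(control_fractions), max(control_fractions)
    return ControlComparison(
        case_fraction, lo, hi, float(np.mean(control_fractions)),
        outside_range=not (lo <= case_fraction <= hi),
    )


def flag_plasma_coq10(
    value: float, reference_range: tuple[float, float] = (227.0, 1432.0)
) -> str:
    """Classify a plasma CoQ10 concentration (nmol/L) against a reference range.

    Boundaries are inclusive; the default range is the 227–1432 nmol/L
    tentative plasma reference range.
    """
    if value < 0:
        raise ValueError("concentration must be nonnegative")
    lo, hi = reference_range
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "within"
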