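"""Clinical-validation statistics.

Confusion-matrix metrics per variant class with exact (Clopper–Pearson)
95% binomial confidence intervals, and the genome-bucket helper used to
draw validation variants evenly across a truth set.

Formulas: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), accuracy = (TP+TN)/(TP+FP+FN+TN).  Intervals come from
beta-distribution quantiles with the closed forms at the boundaries
(k=0: [0, 1-(a/2)^(1/n)]; k=n: [(a/2)^(1/n), 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import beta


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricValue:
    point: float
    ci_low: Optional[float]
    ci_high: Optional[float]

    def rounded(self) -> str:
        """Display form: 5 d.p. point, 4 d.p. interval bounds."""
        if self.ci_low is None:
            return f"{self.point:.5f}"
        return f"{self.point:.5f} (95% CI = {self.ci_low:.4f}-{self.ci_high:.4f})"


@dataclass(frozen=True)
class MetricSet:
    sensitivity: Optional[MetricValue]
    specificity: Optional[MetricValue]
    ppv: Optional[MetricValue]
    accuracy: Optional[MetricValue]
    omitted: dict


def clopper_pearson(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0,1)")
    alpha = 1.0 - confidence
    if successes == 0:
        return 0.0, 1.0 - (alpha / 2) ** (1.0 / trials)
    if successes == trials:
        return (alpha / 2) ** (1.0 / trials), 1.0
    low = float(beta.ppf(alpha / 2, successes, trials - successes + 1))
    high = float(beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return low, high


def _metric(successes: int, trials: int, confidence: float,
            with_ci: bool = True) -> MetricValue:
    point = successes / trials
    if not with_ci:
        return MetricValue(point, None, None)
    low, high = clopper_pearson(successes, trials, confidence)
    return MetricValue(point, low, high)


def metrics(counts: ConfusionCounts, confidence: float = 0.95) -> MetricSet:
    """Sensitivity / specificity / PPV / accuracy with exact intervals.

    PPV is reported as a point estimate only.  A metric with a zero
    denominator is omitted, with the reason recorded.
    """
    omitted: dict[str, str] = {}
    sens = spec = ppv = acc = None
    if counts.tp + counts.fn >= 1:
        sens = _metric(counts.tp, counts.tp + counts.fn, confidence)
    else:
        omitted["sensitivity"] = "no positive truth calls (TP+FN=0)"
    if counts.tn + counts.fp >= 1:
        spec = _metric(counts.tn, counts.tn + counts.fp, confidence)
    else:
        omitted["specificity"] = "no negative truth calls (TN+FP=0)"
    if counts.tp + counts.fp >= 1:
        ppv = _metric(counts.tp, counts.tp + counts.fp, confidence, with_ci=False)
    else:
        omitted["ppv"] = "no positive calls (TP+FP=0)"
    total = counts.tp + counts.fp + counts.fn + counts.tn
    if total >= 1:
        acc = _metric(counts.tp + counts.tn, total, confidence)
    else:
        omitted["accuracy"] = "no calls at all"
    return MetricSet(sens, spec, ppv, acc, omitted)


def bucket_select(
    truth_variants: Sequence[tuple[str, int]],
    chrom_sizes: dict[str, int],
    n_buckets: int,
    per_bucket: int = 1,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Select validation variants evenly spread across the genome.

    The concatenated genome is partitioned into ``n_buckets`` equal spans
    and the first available variants are taken from each; chromosomes left
    unrepresented are topped up with their first available variants.
    ``truth_variants`` are (chrom, pos) sorted by genome coordinate.
    ``seed`` is accepted for interface stability; selection is
    deterministic ("first available").
    """
    if not truth_variants:
        raise ValueError("empty truth set")
    order = list(chrom_sizes)
    offsets = {}
    total = 0
    for c in order:
        offsets[c] = total
        total += chrom_sizes[c]
    span = total / n_buckets
    by_bucket: dict[int, list[tuple[str, int]]] = {}
    for chrom, pos in truth_variants:
        if chrom not in offsets:
            continue
        g = offsets[chrom] + pos
        b = min(int(g / span), n_buckets - 1)
        by_bucket.setdefault(b, []).append((chrom, pos))
    selected: list[tuple[str, int]] = []
    for b in sorted(by_bucket):
        picks = sorted(by_bucket[b])[:per_bucket]
        selected.extend(picks)
    represented = {c for c, _ in selected}
    for chrom in order:
        if chrom in represented:
            continue
        on_chrom = sorted(p for c, p in truth_variants if c == chrom)
        selected.extend((chrom, p) for p in on_chrom[:per_bucket])
    return sorted(selected, key=lambda cp: (offsets[cp[0]] + cp[1]))
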