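"""Test-set evaluation of impact-calling strategies.

Two approaches call a variant "positive" (predicted to change miRNA
expression in vivo):

* ddG approach — ddG = dG(variant structure) - dG(wild-type structure).
  Strategy ``abs_gt0``: positive iff |ddG| > 0. Strategy ``interval``:
  positive iff ddG falls outside a central interval; the default
  thresholds (-2.103226, 4.324731) are the intersection points of the
  kernel-density curves of ddG for expression-changing versus neutral
  variants in the published evaluation set, and can be recomputed from
  any two ddG samples with :func:`density_interval`.
* hairpin approach — positive iff the highest structural impact lies
  within the hairpin (seed, mature, arm or loop).

Variants farther from the hairpin than the folding flank carry no
structure prediction and are forced negative under both approaches.
Calls against observed outcomes (changed / unchanged expression) give a
2x2 contingency table, sensitivity = TP/(TP+FN)*100, specificity =
TN/(TN+FP)*100 and a two-tailed Fisher exact p-value.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde, hypergeom

from .variant_io import GenomicVariant

logger = logging.getLogger(__name__)

__all__ = [
    "DDG_INTERVAL",
    "TestSetEntry",
    "ContingencyTable",
    "read_testset_tsv",
    "call_ddg",
    "call_hairpin",
    "contingency",
    "sensitivity_specificity",
    "fisher_exact_two_tailed",
    "density_interval",
    "evaluate_records",
]

#: Default density-curve intersection thresholds for the "interval" strategy.
DDG_INTERVAL = (-2.103226, 4.324731)

HAIRPIN_CLASSES = frozenset({"seed", "mature", "arm", "loop"})

TESTSET_COLUMNS = ["chromosome", "begin", "end", "type", "ref", "alt",
                   "mirna", "outcome"]


@dataclass(frozen=True)
class TestSetEntry:
    """A functionally assayed variant: observed expression outcome."""

    variant: GenomicVariant
    mirna: str
    outcome: str  # changed | unchanged

    def __post_init__(self) -> None:
        if self.outcome not in ("changed", "unchanged"):
            raise ValueError(f"outcome must be changed/unchanged, got {self.outcome!r}")

    @property
    def changed(self) -> bool:
        return self.outcome == "changed"


def read_testset_tsv(path) -> list[TestSetEntry]:
    entries = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:8]] != TESTSET_COLUMNS:
            raise ValueError(f"{path}: expected header {TESTSET_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0]):
                continue
            row = row + [""] * (8 - len(row))
            try:
                entries.append(TestSetEntry(
                    GenomicVariant(row[0], int(row[1]), int(row[2]), row[3],
                                   row[4].upper(), row[5].upper()),
                    row[6], row[7],
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return entries


def call_ddg(ddg: Optional[float], strategy: str = "abs_gt0",
             thresholds: tuple[float, float] = DDG_INTERVAL) -> bool:
    """Positive/negative call from a ddG value (None = beyond flank -> negative)."""
    if ddg is None:
        return False
    if strategy == "abs_gt0":
        return abs(ddg) > 0
    if strategy == "interval":
        lower, upper = thresholds
        return ddg < lower or ddg > upper
    raise ValueError(f"unknown ddG strategy {strategy!r}")


def call_hairpin(highest_impact: Optional[str]) -> bool:
    """Positive iff the highest structural impact lies within the hairpin."""
    return (highest_impact or "none") in HAIRPIN_CLASSES


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return None if d == 0 else self.tp / d * 100.0

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return None if d == 0 else self.tn / d * 100.0


def contingency(calls: Sequence[bool], outcomes: Sequence[bool]) -> ContingencyTable:
    """Counts from parallel positive-call and changed-outcome flags."""
    if len(calls) != len(outcomes):
        raise ValueError("calls and outcomes differ in length")
    tp = sum(1 for c, o in zip(calls, outcomes) if c and o)
    fp = sum(1 for c, o in zip(calls, outcomes) if c and not o)
    tn = sum(1 for c, o in zip(calls, outcomes) if not c and not o)
    fn = sum(1 for c, o in zip(calls, outcomes) if not c and o)
    return ContingencyTable(tp, fp, tn, fn)


def sensitivity_specificity(table: ContingencyTable):
    """(sensitivity %, specificity %) rounded to integers; None when undefined."""
    sens, spec = table.sensitivity, table.specificity
    return (None if sens is None else round(sens),
            None if spec is None else round(spec))


def fisher_exact_two_tailed(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for the 2x2 table (calls x outcomes).

    Probability-mass rule: with margins fixed, sum the hypergeometric
    probabilities of all tables no more likely than the observed one
    (standard two-sided convention of R/scipy).
    """
    n = table.total
    if n == 0:
        return 1.0
    r1 = table.tp + table.fp          # positive calls
    c1 = table.tp + table.fn          # changed outcomes
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    observed = hypergeom.pmf(table.tp, n, c1, r1)
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def density_interval(ddg_changed: Sequence[float], ddg_unchanged: Sequence[float],
                     bw_method=None, gridsize: int = 4096):
    """Intersection thresholds of the two ddG density curves.

    Gaussian kernel density estimates of both groups are evaluated on a
    shared fine grid; crossings of the density difference are located by
    sign change with linear interpolation, and the two crossings
    bracketing the unchanged-group mode are returned as (lower, upper).
    When the groups are so well separated that all crossings lie on one
    side of the mode, the missing bound is -inf/+inf (the interval is
    effectively one-sided); identical or non-intersecting densities
    raise "degenerate densities". ``bw_method`` is passed to scipy's
    gaussian_kde (default: Scott's rule); the published thresholds
    depend on the bandwidth choice.
    """
    a = np.asarray(ddg_changed, dtype=float)
    b = np.asarray(ddg_unchanged, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two ddG values per group")
    try:
        ka = gaussian_kde(a, bw_method=bw_method)
        kb = gaussian_kde(b, bw_method=bw_method)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate densities") from exc
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.5 * (hi - lo) + 1.0
    grid = np.linspace(lo - pad, hi + pad, gridsize)
    da, db = ka(grid), kb(grid)
    diff = da - db
    sign = np.sign(diff)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    crossings = []
    for i in idx:
        x0, x1 = grid[i], grid[i + 1]
        y0, y1 = diff[i], diff[i + 1]
        crossings.append(x0 if y1 == y0 else x0 - y0 * (x1 - x0) / (y1 - y0))
    if not crossings:
        raise ValueError("degenerate densities")
    mode = grid[int(np.argmax(db))]
    lower = [x for x in crossings if x < mode]
    upper = [x for x in crossings if x > mode]
    return (max(lower) if lower else -np.inf,
            min(upper) if upper else np.inf)


def evaluate_records(records, testset: Sequence[TestSetEntry], approach: str,
                     strategy: str = "abs_gt0", representation: str = "MFE",
                     thresholds: tuple[float, float] = DDG_INTERVAL):
    """Join analysis records with a test set and score one configuration.

    ``approach`` is "ddg" (with ``strategy`` abs_gt0 or interval) or
    "hairpin" (with ``representation`` CEN/MEA/MFE). Test-set entries
    without a matching record are treated as negatives with a warning.
    Returns (ContingencyTable, calls list aligned with the test set).
    """
    by_key = {(rec.variant.key, rec.mir_name): rec for rec in records}
    calls = []
    for entry in testset:
        rec = by_key.get((entry.variant.key, entry.mirna))
        if rec is None:
            logger.warning("no analysis record for %s / %s; treated as negative",
                           entry.variant.key, entry.mirna)
            calls.append(False)
            continue
        rep = rec.by_representation.get(representation)
        if approach == "ddg":
            ddg = None if rep is None else rep.var_deltaG - rep.ref_deltaG
            calls.append(call_ddg(ddg, strategy, thresholds))
        elif approach == "hairpin":
            calls.append(call_hairpin(rep.highest_impact if rep else None))
        else:
            raise ValueError(f"unknown approach {approach!r}")
    table = contingency(calls, [e.changed for e in testset])
    return table, calls
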