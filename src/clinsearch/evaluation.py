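"""Eligibility-criteria support evaluation framework.

Quantifies how well a warehouse-based search system can automate clinical
trial prescreening: each eligibility criterion of a set of trials is graded
on a six-level support scale (full / accurate / broad / inaccurate / none /
not-applicable), tagged with the sources of information its search strategy
needs (P patient data, D coded diagnoses, S stay data, B biology, N clinical
narratives, I out-of-scope information), and with the obstacle categories
that lower search effectiveness.

This module computes the summary statistics of that framework: support-level
tables with Wald confidence intervals on the percentages, source-combination
cross tables, source involvement and single-vs-combined directive rates,
automation and prescreening rates, per-trial mean support scores, and an
exact two-sided Wilcoxon signed-rank comparison of inclusion versus
exclusion support.

A packaged 95-criterion, five-trial reference record set ships as a fixture
(``load_fixture("criteria_records")``); where the reference tables constrain
only the marginals, the per-record assignments were chosen deterministically
to be consistent with every constrained count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ClinSearchError, ConfigurationError, DegenerateInputError

SUPPORT_LEVELS = ("full", "accurate", "broad", "inaccurate", "none", "not_applicable")
SCORABLE_LEVELS = SUPPORT_LEVELS[:5]
SOURCES = ("P", "S", "B", "D", "N", "I")
OBSTACLES = ("o", "d", "s", "t", "c", "e")
CRITERION_TYPES = ("inclusion", "exclusion")

#: levels counted as contributing to prescreening (postfiltering allowed)
PRESCREEN_LEVELS = ("full", "accurate", "broad")
#: levels counted as fully automatable (no postfiltering)
AUTOMATED_LEVELS = ("full", "accurate")


@dataclass(frozen=True)
class CriterionRecord:
    id: str
    trial_id: str
    criterion_type: str
    support: str
    sources: frozenset[str]
    obstacles: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.criterion_type not in CRITERION_TYPES:
            raise ConfigurationError(f"unknown criterion type {self.criterion_type!r}")
        if self.support not in SUPPORT_LEVELS:
            raise ConfigurationError(f"unknown support level {self.support!r}")
        if not self.sources:
            raise ConfigurationError(f"record {self.id}: sources must be non-empty")
        bad = self.sources - set(SOURCES)
        if bad:
            raise ConfigurationError(f"record {self.id}: unknown sources {sorted(bad)}")
        if self.obstacles - set(OBSTACLES):
            raise ConfigurationError(f"record {self.id}: unknown obstacles")


@dataclass(frozen=True)
class SupportScoreMap:
    """Support level -> score in [0, 100]; ``full_double`` weights fully
    supported criteria twice as much in the per-trial means."""

    scores: tuple[tuple[str, float], ...] = (
        ("full", 100.0),
        ("accurate", 80.0),
        ("broad", 60.0),
        ("inaccurate", 40.0),
        ("none", 0.0),
    )
    weighting: str = "uniform"  # "uniform" | "full_double"

    def __post_init__(self):
        d = dict(self.scores)
        vals = [d[l] for l in SCORABLE_LEVELS]
        if any(not 0 <= v <= 100 for v in vals):
            raise ConfigurationError("scores must lie in [0, 100]")
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ConfigurationError("scores must be non-increasing from full to none")
        if self.weighting not in ("uniform", "full_double"):
            raise ConfigurationError(f"unknown weighting {self.weighting!r}")

    def score(self, level: str) -> float:
        return dict(self.scores)[level]

    def weight(self, level: str) -> float:
        return 2.0 if (self.weighting == "full_double" and level == "full") else 1.0


# ---------------------------------------------------------------------------
# proportions


def wald_ci(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wald (normal-approximation) confidence interval for a binomial
    percentage, truncated to [0, 100] and rounded to one decimal.

    With p̂ = k/n the interval is ``100·(p̂ ± z·sqrt(p̂(1−p̂)/n))``; p̂ of 0
    or 1 collapses it to a zero-width interval, which is reported as-is.
    """
    if n < 1:
        raise DegenerateInputError("wald_ci needs n >= 1")
    if not 0 <= k <= n:
        raise DegenerateInputError(f"k={k} outside [0, {n}]")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p = k / n
    half = z * np.sqrt(p * (1.0 - p) / n)
    lo = max(0.0, (p - half) * 100.0)
    hi = min(100.0, (p + half) * 100.0)
    return (round(lo, 1), round(hi, 1))


# ---------------------------------------------------------------------------
# tables


def tabulate_support(records: Iterable[CriterionRecord], confidence: float = 0.95) -> pd.DataFrame:
    """Counts, percentages and Wald CIs per support level and criterion type.

    Rows: the six support levels plus ``total``; columns: for each of
    inclusion / exclusion / total — ``n``, ``pct`` (2 decimals, of the column
    total) and ``ci`` (lo, hi in percent).
    """
    recs = list(records)
    cols = {}
    for ctype in ("inclusion", "exclusion", "total"):
        sub = recs if ctype == "total" else [r for r in recs if r.criterion_type == ctype]
        n_total = len(sub)
        n, pct, ci = {}, {}, {}
        for level in SUPPORT_LEVELS:
            k = sum(1 for r in sub if r.support == level)
            n[level] = k
            pct[level] = round(100.0 * k / n_total, 2) if n_total else 0.0
            ci[level] = wald_ci(k, n_total, confidence) if n_total else (0.0, 0.0)
        n["total"] = n_total
        pct["total"] = 100.0 if n_total else 0.0
        ci["total"] = None
        cols[(ctype, "n")] = n
        cols[(ctype, "pct")] = pct
        cols[(ctype, "ci")] = ci
    df = pd.DataFrame(cols)
    df.index.name = "support_level"
    return df


def canonical_combo(sources: Iterable[str]) -> str:
    """Canonical label of a source combination, ordered P, S, B, D, N, I."""
    s = set(sources)
    return "+".join(code for code in SOURCES if code in s)


def tabulate_sources(records: Iterable[CriterionRecord]) -> pd.DataFrame:
    """Support level x source-combination count matrix (plus a total row).

    Columns are canonical combination labels; the grand total equals the
    record count."""
    recs = list(records)
    combos = sorted(
        {canonical_combo(r.sources) for r in recs},
        key=lambda c: (c.count("+"), [SOURCES.index(x) for x in c.split("+")]),
    )
    data = {c: [0] * len(SUPPORT_LEVELS) for c in combos}
    for r in recs:
        data[canonical_combo(r.sources)][SUPPORT_LEVELS.index(r.support)] += 1
    df = pd.DataFrame(data, index=list(SUPPORT_LEVELS))
    df.loc["total"] = df.sum(axis=0)
    df.index.name = "support_level"
    return df


def involvement_count(records: Iterable[CriterionRecord], source: str) -> tuple[int, float]:
    """How many records involve a source, and the share of all records."""
    if source not in SOURCES:
        raise ConfigurationError(f"unknown source code {source!r}")
    recs = list(records)
    k = sum(1 for r in recs if source in r.sources)
    return k, (k / len(recs) if recs else 0.0)


def single_vs_combined(records: Iterable[CriterionRecord]) -> tuple[int, int, float, float]:
    """Over non-not-applicable records: how many criteria need a single
    search directive (one source) versus combined directives, and the share
    of fully supported criteria within each group (percent, 2 decimals;
    0 for an empty group)."""
    recs = [r for r in records if r.support != "not_applicable"]
    single = [r for r in recs if len(r.sources) == 1]
    combined = [r for r in recs if len(r.sources) > 1]

    def full_share(group):
        if not group:
            return 0.0
        return round(100.0 * sum(1 for r in group if r.support == "full") / len(group), 2)

    return len(single), len(combined), full_share(single), full_share(combined)


@dataclass
class AutomationRates:
    """Shares of criteria the system can answer, as fractions in [0, 1].

    ``full_automation`` counts full+accurate support, ``prescreen`` adds
    broad (postfiltering allowed); both are computed over non-not-applicable
    criteria.  ``contribution_incl_na`` keeps not-applicable criteria in the
    denominators, split by criterion type."""

    n_scorable: int
    full_automation: float
    prescreen: float
    prescreen_by_type: dict[str, float] = field(default_factory=dict)
    full_automation_by_type: dict[str, float] = field(default_factory=dict)
    contribution_incl_na: dict[str, float] = field(default_factory=dict)


def automation_rates(records: Iterable[CriterionRecord]) -> AutomationRates:
    recs = list(records)
    scorable = [r for r in recs if r.support != "not_applicable"]

    def rate(group, levels):
        if not group:
            return 0.0
        return sum(1 for r in group if r.support in levels) / len(group)

    by_type_pre, by_type_full, incl_na = {}, {}, {}
    for ctype in CRITERION_TYPES:
        sub_all = [r for r in recs if r.criterion_type == ctype]
        sub = [r for r in sub_all if r.support != "not_applicable"]
        by_type_pre[ctype] = rate(sub, PRESCREEN_LEVELS)
        by_type_full[ctype] = rate(sub, AUTOMATED_LEVELS)
        incl_na[ctype] = rate(sub_all, PRESCREEN_LEVELS)
    return AutomationRates(
        n_scorable=len(scorable),
        full_automation=rate(scorable, AUTOMATED_LEVELS),
        prescreen=rate(scorable, PRESCREEN_LEVELS),
        prescreen_by_type=by_type_pre,
        full_automation_by_type=by_type_full,
        contribution_incl_na=incl_na,
    )


def mean_support_scores(
    records: Iterable[CriterionRecord], score_map: SupportScoreMap = SupportScoreMap()
) -> pd.DataFrame:
    """Per-trial weighted mean support score of inclusion and of exclusion
    criteria (not-applicable records excluded).

    Trials lacking a scorable record of a type carry NaN for that column."""
    recs = [r for r in records if r.support != "not_applicable"]
    trials = sorted({r.trial_id for r in recs})
    out = {}
    for ctype in CRITERION_TYPES:
        col = []
        for trial in trials:
            sub = [r for r in recs if r.trial_id == trial and r.criterion_type == ctype]
            if not sub:
                col.append(float("nan"))
                continue
            w = np.array([score_map.weight(r.support) for r in sub])
            s = np.array([score_map.score(r.support) for r in sub])
            col.append(float((w * s).sum() / w.sum()))
        out[ctype] = col
    df = pd.DataFrame(out, index=pd.Index(trials, name="trial_id"))
    return df


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test


def wilcoxon_signed_rank_exact(pairs: Sequence) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test with an exact null distribution.

    ``pairs`` is a sequence of (x, y) pairs or of differences x−y.  Zero
    differences are dropped; tied absolute differences get mid-ranks.  The
    statistic T is the sum of the ranks of positive differences; for n ≤ 20
    the p value is computed by enumerating all 2^n sign assignments,
    two-sided as ``2·min(P(T ≤ t), P(T ≥ t))`` capped at 1.  Larger n falls
    back to the normal approximation with tie correction.
    """
    diffs = []
    for p in pairs:
        d = float(p[0]) - float(p[1]) if isinstance(p, (tuple, list, np.ndarray)) else float(p)
        diffs.append(d)
    diffs = [d for d in diffs if d != 0.0]
    n = len(diffs)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = stats.rankdata([abs(d) for d in diffs])
    t_obs = float(sum(r for d, r in zip(diffs, ranks) if d > 0))
    if n <= 20:
        le = ge = total = 0
        for signs in product((0, 1), repeat=n):
            t = sum(r for s, r in zip(signs, ranks) if s)
            total += 1
            if t <= t_obs + 1e-12:
                le += 1
            if t >= t_obs - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return t_obs, p
    res = stats.wilcoxon(diffs, alternative="two-sided", correction=False, mode="approx")
    # scipy reports the smaller rank sum; convert to the positive-rank sum
    return t_obs, float(res.pvalue)


# ---------------------------------------------------------------------------
# fixtures


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    ref = resources.files("clinsearch").joinpath("data", name)
    with ref.open(encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def load_fixture(name: str):
    """Packaged fixtures of the five-trial criteria assessment.

    * ``criteria_records`` — 95 :class:`CriterionRecord` rows.
    * ``table1_counts`` — DataFrame level x {inclusion, exclusion, total}.
    * ``table2_matrix`` — DataFrame level x source-combination counts.
    """
    if name == "criteria_records":
        return read_records_csv(resources.files("clinsearch").joinpath("data", "criteria_records.csv"))
    if name == "table1_counts":
        rows = _read_packaged_csv("table1_counts.csv")
        df = pd.DataFrame(rows).set_index("support_level").astype(int)
        return df
    if name == "table2_matrix":
        rows = _read_packaged_csv("table2_matrix.csv")
        df = pd.DataFrame(rows).set_index("support_level").astype(int)
        return df
    raise ClinSearchError(f"unknown fixture {name!r}")


def read_records_csv(path) -> list[CriterionRecord]:
    """Read criterion records from CSV with columns
    id, trial_id, type, support, sources, obstacles (codes joined by '+'
    for sources, ',' for obstacles)."""
    out = []
    opener = path.open("r", encoding="utf-8", newline="") if hasattr(path, "open") else open(path, encoding="utf-8", newline="")
    with opener as fh:
        for row in csv.DictReader(fh):
            out.append(
                CriterionRecord(
                    id=row["id"],
                    trial_id=row["trial_id"],
                    criterion_type=row["type"],
                    support=row["support"],
                    sources=frozenset(row["sources"].split("+")),
                    obstacles=frozenset(x for x in row.get("obstacles", "").split(",") if x),
                )
            )
    return out


def write_records_csv(records: Iterable[CriterionRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "trial_id", "type", "support", "sources", "obstacles"])
        for r in records:
            w.writerow(
                [
                    r.id,
                    r.trial_id,
                    r.criterion_type,
                    r.support,
                    canonical_combo(r.sources),
                    ",".join(o for o in OBSTACLES if o in r.obstacles),
                ]
            )


def render_tables_markdown(records: Iterable[CriterionRecord]) -> str:
    """Markdown rendering of the support and source tables."""
    recs = list(records)
    sup = tabulate_support(recs)
    src = tabulate_sources(recs)
    lines = ["### Support levels", ""]
    lines.append("| Support level | Inclusion n (%) | 95% CI | Exclusion n (%) | 95% CI | Total n (%) | 95% CI |")
    lines.append("|---|---|---|---|---|---|---|")
    for level in SUPPORT_LEVELS:
        cells = [level.replace("_", " ")]
        for ctype in ("inclusion", "exclusion", "total"):
            n = sup.loc[level, (ctype, "n")]
            pct = sup.loc[level, (ctype, "pct")]
            lo, hi = sup.loc[level, (ctype, "ci")]
            cells.append(f"{n} ({pct:.2f})")
            cells.append(f"({lo}-{hi})")
        lines.append("| " + " | ".join(str(c) for c in cells) + " |")
    lines += ["", "### Source combinations", ""]
    lines.append("| Support level | " + " | ".join(src.columns) + " |")
    lines.append("|" + "---|" * (len(src.columns) + 1))
    for level in src.index:
        lines.append(
            "| " + str(level).replace("_", " ") + " | " + " | ".join(str(v) for v in src.loc[level]) + " |"
        )
    return "\n".join(lines) + "\n"
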