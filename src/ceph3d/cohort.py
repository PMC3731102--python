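"""Cohort-level aggregation of per-subject symmetry reports.

Produces the cohort tables of the method: per-measurement mean and
standard deviation (mm), per-ratio minimum/maximum/mean, and the two
prevalence percentages — the fraction of subjects whose semiangle
discrepancy is within threshold, and the fraction whose largest
left-right millimetric discrepancy is within threshold.

Subjects whose semiangle geometry is degenerate (menton collinear with
the inter-condylar line) are excluded from the semiangle prevalence and
counted separately, mirroring exclusion-by-quality cohort curation.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .analysis import MANDIBLE_RATIO_DEFS, PatientReport
from .landmarks import MEASUREMENTS

__all__ = ["CohortSummary", "summarize_cohort", "prevalence"]

Criterion = Literal["semiangle_4deg", "discrepancy_5mm"]


@dataclass
class CohortSummary:
    """Aggregated statistics over a cohort of patient reports.

    Percentages are stored unrounded; ``round(x, 2)`` only at display
    time. ``sd_ddof`` records the standard-deviation convention used
    (1 = sample, 0 = population).
    """

    n_subjects: int
    measurement_stats: dict[str, dict[str, float]]
    ratio_stats: dict[str, dict[str, float]]
    mandible_ratio_stats: dict[str, dict[str, float]]
    pct_semiangle_symmetric: float
    pct_within_discrepancy: float
    excluded_semiangle: int = 0
    sd_ddof: int = 1

    @property
    def pct_within_5mm(self) -> float:
        return self.pct_within_discrepancy

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "excluded_semiangle": self.excluded_semiangle,
            "sd_ddof": self.sd_ddof,
            "measurement_stats": self.measurement_stats,
            "ratio_stats": self.ratio_stats,
            "mandible_ratio_stats": self.mandible_ratio_stats,
            "pct_semiangle_symmetric": self.pct_semiangle_symmetric,
            "pct_within_discrepancy": self.pct_within_discrepancy,
            "display": {
                "pct_semiangle_symmetric": round(self.pct_semiangle_symmetric, 2),
                "pct_within_discrepancy": round(self.pct_within_discrepancy, 2),
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2) + "\n"

    def to_csv(self) -> str:
        """Long-format table: one row per (table, code, statistic)."""
        buf = _io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["table", "code", "statistic", "value"])
        for code, st in self.measurement_stats.items():
            w.writerow(["measurements", code, "mean_mm", repr(st["mean"])])
            w.writerow(["measurements", code, "sd_mm", repr(st["sd"])])
        for code, st in self.ratio_stats.items():
            for k in ("min", "max", "mean"):
                w.writerow(["facial_ratios", code, k, repr(st[k])])
        for code, st in self.mandible_ratio_stats.items():
            for k in ("min", "max", "mean"):
                w.writerow(["mandible_ratios", code, k, repr(st[k])])
        w.writerow(["prevalence", "semiangle_symmetric", "percent",
                    repr(self.pct_semiangle_symmetric)])
        w.writerow(["prevalence", "within_discrepancy", "percent",
                    repr(self.pct_within_discrepancy)])
        return buf.getvalue()


def _min_max_mean(values: Sequence[float]) -> dict[str, float]:
    # sort before reducing: summation order no longer depends on subject
    # order, so the summary is exactly permutation invariant
    arr = np.sort(np.asarray(values, dtype=float))
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
    }


def summarize_cohort(
    reports: Iterable[PatientReport], sd_ddof: int = 1
) -> CohortSummary:
    """Aggregate patient reports into a cohort summary.

    Uses the sample (n-1 denominator) standard deviation by default;
    pass ``sd_ddof=0`` for the population convention. A single-subject
    cohort reports sd 0 under either convention.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("cannot summarize an empty cohort")
    n = len(reports)

    meas = {}
    for code in MEASUREMENTS:
        col = np.sort([r.measurements.values[code] for r in reports])
        sd = float(col.std(ddof=sd_ddof)) if n > sd_ddof else 0.0
        meas[code] = {"mean": float(col.mean()), "sd": sd}

    ratio_keys = list(reports[0].facial_ratios.entries)
    ratios = {
        f"{num}/{den}": _min_max_mean(
            [r.facial_ratios.entries[(num, den)].value for r in reports]
        )
        for num, den in ratio_keys
    }
    mand = {
        name: _min_max_mean([r.mandible_ratios.values[name] for r in reports])
        for name in MANDIBLE_RATIO_DEFS
    }

    valid_semi = [r for r in reports if not r.semiangle.degenerate]
    excluded = n - len(valid_semi)
    pct_semi = (
        100.0 * sum(r.semiangle.symmetric for r in valid_semi) / len(valid_semi)
        if valid_semi
        else 0.0
    )
    pct_disc = 100.0 * sum(r.discrepancy.within_threshold for r in reports) / n

    return CohortSummary(
        n_subjects=n,
        measurement_stats=meas,
        ratio_stats=ratios,
        mandible_ratio_stats=mand,
        pct_semiangle_symmetric=pct_semi,
        pct_within_discrepancy=pct_disc,
        excluded_semiangle=excluded,
        sd_ddof=sd_ddof,
    )


def prevalence(reports: Iterable[PatientReport], criterion: Criterion) -> float:
    """Percentage of subjects satisfying a symmetry criterion.

    ``semiangle_4deg`` counts subjects whose semiangle discrepancy is
    within the threshold recorded in their report (degenerate subjects
    excluded from the denominator); ``discrepancy_5mm`` counts subjects
    whose largest left-right distance difference is within threshold.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("cannot compute prevalence of an empty cohort")
    if criterion == "semiangle_4deg":
        valid = [r for r in reports if not r.semiangle.degenerate]
        if not valid:
            raise ValueError("all subjects degenerate for the semiangle test")
        return 100.0 * sum(r.semiangle.symmetric for r in valid) / len(valid)
    if criterion == "discrepancy_5mm":
        return 100.0 * sum(r.discrepancy.within_threshold for r in reports) / len(reports)
    raise ValueError(
        f"unknown criterion {criterion!r}; "
        "expected 'semiangle_4deg' or 'discrepancy_5mm'"
    )
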