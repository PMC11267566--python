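"""Cleavability readouts aggregated from fit outcomes.

The score is the conformational-selection proxy: the fraction of
conformers whose protease/POI interaction energy after grafting and
relaxation is strictly negative ("fraction fitted").  Alongside it the
report carries the median bulk interaction energy over retained outcomes
(protease vs POI excluding the N-terminal atoms), which compares how
compatibly the protein body sits in the active site.  The ratio is stored
exactly; percentages are a rendering concern.
"""

from __future__ import annotations

import dataclasses
import json
import statistics
from typing import Sequence

from .grafter import FitOutcome

SCHEMA_VERSION = 1


@dataclasses.dataclass
class CleavabilityReport:
    n_total: int
    n_retained: int
    fraction_fitted: float
    median_e_bulk: float | None  # kJ/mol over retained outcomes; None if empty
    mode: str = "complete"  # "complete" | "clustered"

    def __post_init__(self):
        if not 0 <= self.n_retained <= self.n_total:
            raise ValueError("n_retained must lie in [0, n_total]")
        if not 0.0 <= self.fraction_fitted <= 1.0:
            raise ValueError("fraction_fitted must lie in [0, 1]")

    @property
    def percent_fitted(self) -> float:
        return 100.0 * self.fraction_fitted


def cleavability_score(
    outcomes: Sequence[FitOutcome],
    mode: str = "complete",
    threshold: float | None = None,
) -> CleavabilityReport:
    """Fraction fitted and median bulk energy from a list of fit outcomes.

    The median over an even number of retained energies is the mean of the
    middle two.  Zero retained outcomes give fraction 0 and an undefined
    median (``None``).  ``threshold`` optionally re-derives retention as
    ``e_interaction < threshold`` instead of the stored flags (a
    convenience for sensitivity checks; the method itself imposes no
    classification boundary beyond zero).
    """
    if not outcomes:
        raise ValueError("no outcomes to score")
    if threshold is None:
        retained = [o for o in outcomes if o.retained]
    else:
        retained = [o for o in outcomes if o.e_interaction < threshold]
    n_total = len(outcomes)
    median = (
        float(statistics.median(o.e_bulk_interaction for o in retained))
        if retained
        else None
    )
    return CleavabilityReport(
        n_total=n_total,
        n_retained=len(retained),
        fraction_fitted=len(retained) / n_total,
        median_e_bulk=median,
        mode=mode,
    )


def write_report(report: CleavabilityReport, path, format: str = "json") -> None:
    """Serialize a report as JSON (lossless) or a fixed-header TSV."""
    if format == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "n_total": report.n_total,
            "n_retained": report.n_retained,
            "fraction_fitted": report.fraction_fitted,
            "median_e_bulk": report.median_e_bulk,
            "mode": report.mode,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("n_total\tn_retained\tfraction_fitted\tmedian_e_bulk\tmode\n")
            med = "NA" if report.median_e_bulk is None else f"{report.median_e_bulk:.6g}"
            fh.write(
                f"{report.n_total}\t{report.n_retained}\t"
                f"{report.fraction_fitted:.4f}\t{med}\t{report.mode}\n"
            )
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> CleavabilityReport:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema {payload.get('schema_version')!r}"
        )
    return CleavabilityReport(
        n_total=payload["n_total"],
        n_retained=payload["n_retained"],
        fraction_fitted=payload["fraction_fitted"],
        median_e_bulk=payload["median_e_bulk"],
        mode=payload["mode"],
    )
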