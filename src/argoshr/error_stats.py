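"""Per-location-class summaries of Argos location error.

The summary layout mirrors the standard accuracy-report table for Doppler
telemetry: per class, the count and proportion of fixes, mean +/- SD of the
total error and of the absolute longitudinal / latitudinal components, the
median, and the 68th and 90th error percentiles (the 68th being the Argos
system's advertised accuracy statistic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import ErrorRecord

logger = logging.getLogger(__name__)

LC_ORDER = ("3", "2", "1", "0", "A", "B")


@dataclass(frozen=True)
class LCErrorSummary:
    """Error statistics for one location class (or the pooled 'Total' row).

    Axis statistics (``mean_x``/``mean_y`` and their SDs) are computed on the
    absolute east/north error components, so they are non-negative magnitudes.
    All lengths in metres; ``proportion`` is a fraction of the summarized total.
    """

    lc: str
    n: int
    proportion: float
    mean: float
    sd: float
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    median: float
    p68: float
    p90: float


def percentile(values: Sequence[float], p: float) -> float:
    """Linear-interpolation quantile at fraction *p* (rank ``1 + p*(n-1)``).

    This is the common 'type 7' convention; at the sample sizes of telemetry
    accuracy studies the choice of rule is immaterial.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty list")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    return float(np.quantile(values, p, method="linear"))


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def _one_summary(lc: str, err: np.ndarray, ax: np.ndarray, ay: np.ndarray, n_total: int) -> LCErrorSummary:
    return LCErrorSummary(
        lc=lc,
        n=int(err.size),
        proportion=err.size / n_total,
        mean=float(err.mean()),
        sd=_sd(err),
        mean_x=float(ax.mean()),
        sd_x=_sd(ax),
        mean_y=float(ay.mean()),
        sd_y=_sd(ay),
        median=percentile(err, 0.5),
        p68=percentile(err, 0.68),
        p90=percentile(err, 0.90),
    )


def summarize_by_lc(records: Iterable[ErrorRecord]) -> list[LCErrorSummary]:
    """Summarize error records per location class, plus a pooled 'Total' row.

    Invalid (LCZ) records are excluded with a logged count. Returns an empty
    list for empty input. Classes appear in quality order (3, 2, 1, 0, A, B),
    'Total' last.
    """
    records = list(records)
    kept = [r for r in records if r.argos.lc != "Z"]
    n_z = len(records) - len(kept)
    if n_z:
        logger.info("excluded %d invalid (LCZ) records from the summary", n_z)
    if not kept:
        return []
    for r in kept:
        if r.argos.lc is None:
            raise ValueError("summary requires records with a location class")

    err = np.array([r.err_total for r in kept])
    ax = np.abs([r.err_x for r in kept])
    ay = np.abs([r.err_y for r in kept])
    lcs = np.array([r.argos.lc for r in kept])

    out: list[LCErrorSummary] = []
    for lc in LC_ORDER:
        mask = lcs == lc
        if mask.any():
            out.append(_one_summary(lc, err[mask], ax[mask], ay[mask], len(kept)))
    out.append(_one_summary("Total", err, ax, ay, len(kept)))
    return out


def summary_ratio(a: LCErrorSummary, b: LCErrorSummary) -> float:
    """Ratio of 68th error percentiles between two summaries of the same class
    (e.g. mobile vs static transmitters)."""
    if a.lc != b.lc:
        raise ValueError(f"cannot compare summaries of classes {a.lc!r} and {b.lc!r}")
    if b.p68 == 0:
        raise ValueError("reference 68th percentile is zero")
    return a.p68 / b.p68


def summaries_to_frame(summaries: Sequence[LCErrorSummary]) -> pd.DataFrame:
    """Tabulate summaries in the standard accuracy-table column order."""
    cols = ["lc", "n", "proportion", "mean", "sd", "mean_x", "sd_x",
            "mean_y", "sd_y", "median", "p68", "p90"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries], columns=cols)
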