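"""Lognormal tip distributions from family-level min/max/richness records.

The observed unit of data is a higher taxon (typically a family) for which
only the minimum and maximum adult body length (mm) and the described
species richness are known. Within each taxon, species are assumed to follow
a lognormal size distribution, so on the natural-log scale the distribution
is normal and symmetric:

* the mean-of-logs ``(ln min + ln max) / 2`` estimates the log-scale mean;
* the log-scale standard deviation is estimated from the log range with
  range-based rules whose form depends on sample size (small samples use the
  Hozo/Djulbegovic/Hozo small-sample estimator, moderate samples range/4,
  large samples range/6);
* the standard error of the mean-of-logs treats the corrected richness as
  the sample size: ``se = sd / sqrt(n_corrected)``.

Richness is increased by 2 everywhere ("corrected richness") so that
monotypic taxa (richness 1, min = max) still receive a defined, if zero,
spread instead of being dropped from the phylogeny.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "FamilyRecord",
    "TipDistribution",
    "corrected_richness",
    "hozo_sd",
    "estimate_log_sd",
    "build_tip_distribution",
    "build_tip_distributions",
    "load_family_table",
    "tip_distribution_table",
]

#: richness (already corrected) at or below which the small-sample estimator
#: applies; the range/4 rule covers (SMALL_MAX, MODERATE_MAX], range/6 above.
SMALL_MAX = 15
MODERATE_MAX = 70

DEFAULT_SE_FLOOR = 1e-6


@dataclass(frozen=True)
class FamilyRecord:
    """Raw observation for one terminal taxon.

    Attributes
    ----------
    taxon : str
        Unique terminal name (must match a tree tip label for tree-based
        analyses).
    min_mm, max_mm : float
        Minimum and maximum recorded adult body length in mm; both > 0 and
        ``min_mm <= max_mm``.
    richness : int
        Described species count, >= 1.
    clade : str
        Major-clade membership label (e.g. "Holometabola").
    """

    taxon: str
    min_mm: float
    max_mm: float
    richness: int
    clade: str = ""

    def __post_init__(self):
        if not self.taxon:
            raise ValueError("taxon name must be non-empty")
        if not (self.min_mm > 0 and self.max_mm > 0):
            raise ValueError(f"{self.taxon}: lengths must be positive")
        if self.min_mm > self.max_mm:
            raise ValueError(f"{self.taxon}: min_mm {self.min_mm} > max_mm {self.max_mm}")
        if int(self.richness) != self.richness or self.richness < 1:
            raise ValueError(f"{self.taxon}: richness must be an integer >= 1")


@dataclass(frozen=True)
class TipDistribution:
    """Derived lognormal description of a terminal taxon (log scale, ln mm)."""

    taxon: str
    log_mean: float
    log_sd: float
    corrected_richness: int
    se: float
    clade: str = ""


def corrected_richness(richness: int) -> int:
    """Described richness plus two (keeps monotypic taxa estimable)."""
    if int(richness) != richness or richness < 1:
        raise ValueError(f"richness must be an integer >= 1, got {richness!r}")
    return int(richness) + 2


def hozo_sd(low: float, median: float, high: float) -> float:
    """Small-sample SD estimate from (min, median, max).

    The three-point estimator
    ``sqrt([ (low - 2*median + high)^2 / 4 + (high - low)^2 ] / 12)``.
    When the median sits at the midpoint of the range the first term
    vanishes and the estimate reduces to ``range / sqrt(12)``.
    """
    if not (low <= median <= high):
        raise ValueError("need low <= median <= high")
    rng = high - low
    return math.sqrt(((low - 2.0 * median + high) ** 2 / 4.0 + rng ** 2) / 12.0)


def estimate_log_sd(log_range: float, n_corrected: int, median_offset: float | None = None) -> float:
    """Log-scale SD from the log range under the size-dependent rules.

    Parameters
    ----------
    log_range : float
        ``ln(max) - ln(min)`` >= 0.
    n_corrected : int
        Corrected richness (>= 3); selects the rule:
        ``<= 15`` small-sample estimator, ``16..70`` range/4, ``> 70``
        range/6.
    median_offset : float, optional
        Signed offset of the log-scale median from the midpoint of the log
        range, for callers who do have a median. Default None assumes the
        symmetric lognormal (median at midpoint), collapsing the
        small-sample estimator to ``log_range / sqrt(12)``.
    """
    if log_range < 0:
        raise ValueError("log range must be non-negative")
    if n_corrected < 3:
        raise ValueError("corrected richness must be >= 3")
    if n_corrected <= SMALL_MAX:
        mid = log_range / 2.0
        med = mid if median_offset is None else mid + median_offset
        return hozo_sd(0.0, med, log_range)
    if n_corrected <= MODERATE_MAX:
        return log_range / 4.0
    return log_range / 6.0


def build_tip_distribution(record: FamilyRecord, se_floor: float = DEFAULT_SE_FLOOR) -> TipDistribution:
    """Convert one raw record into its lognormal tip description.

    ``log_mean`` is the mean-of-logs; ``log_sd`` comes from
    :func:`estimate_log_sd` applied to the natural-log range with corrected
    richness; ``se = max(log_sd / sqrt(n_corrected), se_floor)``. The floor
    (default 1e-6 ln mm) keeps covariance matrices positive definite when
    min = max.
    """
    if se_floor < 0:
        raise ValueError("se_floor must be >= 0")
    lo, hi = math.log(record.min_mm), math.log(record.max_mm)
    nc = corrected_richness(record.richness)
    sd = estimate_log_sd(hi - lo, nc)
    se = max(sd / math.sqrt(nc), se_floor)
    return TipDistribution(
        taxon=record.taxon,
        log_mean=0.5 * (lo + hi),
        log_sd=sd,
        corrected_richness=nc,
        se=se,
        clade=record.clade,
    )


def build_tip_distributions(records, se_floor: float = DEFAULT_SE_FLOOR) -> list[TipDistribution]:
    return [build_tip_distribution(r, se_floor=se_floor) for r in records]


REQUIRED_COLUMNS = ("taxon", "min_mm", "max_mm", "richness", "clade")


def load_family_table(path) -> list[FamilyRecord]:
    """Read a delimited family table into records.

    The file must carry a header with columns ``taxon, min_mm, max_mm,
    richness, clade`` (extra columns are ignored; ``#`` lines skipped). The
    delimiter (comma or tab) is sniffed from the header. Errors name the
    offending row.
    """
    path = Path(path)
    sep = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sep = "\t" if "\t" in line else ","
                break
    if sep is None:
        raise ValueError(f"{path}: no data rows")
    df = pd.read_csv(path, sep=sep, comment="#", skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    seen: dict[str, int] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        taxon = str(d["taxon"]).strip()
        if taxon in seen:
            raise ValueError(
                f"{path}: duplicate taxon {taxon!r} at row {row_no} "
                f"(first seen at row {seen[taxon]})"
            )
        seen[taxon] = row_no
        try:
            rich = float(d["richness"])
            if not float(rich).is_integer():
                raise ValueError("richness is not an integer")
            rec = FamilyRecord(
                taxon=taxon,
                min_mm=float(d["min_mm"]),
                max_mm=float(d["max_mm"]),
                richness=int(rich),
                clade=str(d["clade"]).strip(),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {row_no} ({taxon!r}): {exc}") from exc
        records.append(rec)
    if not records:
        raise ValueError(f"{path}: no data rows")
    return records


def tip_distribution_table(tips: list[TipDistribution]) -> pd.DataFrame:
    """Derived per-tip table (one row per taxon), CSV-ready."""
    return pd.DataFrame(
        {
            "taxon": [t.taxon for t in tips],
            "clade": [t.clade for t in tips],
            "log_mean": [t.log_mean for t in tips],
            "log_sd": [t.log_sd for t in tips],
            "corrected_richness": [t.corrected_richness for t in tips],
            "se": [t.se for t in tips],
        }
    )
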