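"""Summary statistics over collections of code sets and their term sets.

The headline metric is *compression*: the number of inclusion plus
exclusion terms as a percentage of the code set size.  A collection is
summarised by the median and interquartile range of code-set sizes and
the mean compression, overall and for the subgroup whose term sets came
out larger than the code sets they represent (proportion > 100%).

Quartiles use Tukey hinges: medians of the lower and upper halves of
the sorted sizes, excluding the overall median itself when the count is
odd.  Rounding of proportions is half-up at one decimal.  Both choices
are plain-integer arithmetic until the final rounding step, so reports
are byte-identical across runs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import median

__all__ = [
    "SetStats",
    "CollectionSummary",
    "set_stats",
    "summarize",
    "read_stats_tsv",
    "published_survey_stats",
    "format_summary",
]


def _round1(v: Decimal) -> float:
    return float(v.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SetStats:
    label: str
    codeset_size: int
    n_inclusion: int
    n_exclusion: int
    proportion: float  # 100·(n_inclusion+n_exclusion)/codeset_size, 1 decimal


def set_stats(
    codeset_size: int, n_incl: int, n_excl: int, label: str = ""
) -> SetStats:
    if codeset_size < 1:
        raise ValueError("code set size must be >= 1")
    if n_incl < 0 or n_excl < 0:
        raise ValueError("term counts must be non-negative")
    prop = _round1(Decimal(100 * (n_incl + n_excl)) / Decimal(codeset_size))
    return SetStats(label, codeset_size, n_incl, n_excl, prop)


@dataclass(frozen=True)
class CollectionSummary:
    n_sets: int
    median_size: float
    iqr_low: float
    iqr_high: float
    mean_proportion_pct: float          # 1 decimal
    mean_proportion_pct_int: int        # half-up to integer
    subgroup_means: dict[str, float]    # e.g. {"proportion>100": 118.5}
    quartile_convention: str = "tukey-hinges (median of halves, odd-n median excluded)"


def _hinges(sizes: list[int]) -> tuple[float, float, float]:
    s = sorted(sizes)
    n = len(s)
    med = float(median(s))
    half = n // 2
    lower = s[:half]
    upper = s[half + 1 :] if n % 2 else s[half:]
    return float(median(lower)), med, float(median(upper))


def summarize(stats: list[SetStats]) -> CollectionSummary:
    """Median/IQR of code-set sizes and mean term-to-code proportions."""
    if not stats:
        raise ValueError("no code sets to summarize")
    sizes = [st.codeset_size for st in stats]
    if len(sizes) == 1:
        lo = mid = hi = float(sizes[0])
    else:
        lo, mid, hi = _hinges(sizes)
    props = [Decimal(str(st.proportion)) for st in stats]
    mean = sum(props) / len(props)
    over100 = [p for p in props if p > 100]
    subgroup: dict[str, float] = {}
    if over100:
        subgroup["proportion>100"] = _round1(sum(over100) / len(over100))
    return CollectionSummary(
        n_sets=len(stats),
        median_size=mid,
        iqr_low=lo,
        iqr_high=hi,
        mean_proportion_pct=_round1(mean),
        mean_proportion_pct_int=int(mean.quantize(Decimal("1"), rounding=ROUND_HALF_UP)),
        subgroup_means=subgroup,
    )


def read_stats_tsv(path: str) -> list[SetStats]:
    """Read (label, codeset_size, n_inclusion, n_exclusion[, proportion]).

    A header row is recognised by a non-numeric second column.  When a
    fifth column is present it is taken as the proportion *as published*
    and preserved instead of being recomputed, so that a transcription of
    a printed table is summarised exactly as printed; absent, the
    proportion is computed from the counts.
    """
    out: list[SetStats] = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if not out and len(row) > 1 and not row[1].strip().isdigit():
                continue  # header
            label = row[0].strip()
            size, ni, ne = (int(v) for v in row[1:4])
            if len(row) > 4 and row[4].strip():
                prop = _round1(Decimal(row[4].strip().rstrip("%")))
                out.append(SetStats(label, size, ni, ne, prop))
            else:
                out.append(set_stats(size, ni, ne, label))
    if not out:
        raise ValueError(f"no data rows in {path!r}")
    return out


def published_survey_stats() -> list[SetStats]:
    """The bundled survey of 31 published cohort-definition code sets and
    their term-set conversions (sizes and printed proportions)."""
    from importlib.resources import files

    return read_stats_tsv(str(files("termsets") / "data" / "published_codeset_survey.tsv"))


def format_summary(summary: CollectionSummary) -> str:
    lines = [
        f"code sets:            {summary.n_sets}",
        f"median code-set size: {summary.median_size:g}",
        f"IQR:                  [{summary.iqr_low:g}, {summary.iqr_high:g}]",
        f"mean proportion:      {summary.mean_proportion_pct}% "
        f"(integer: {summary.mean_proportion_pct_int}%)",
    ]
    for name, val in sorted(summary.subgroup_means.items()):
        lines.append(f"mean proportion, {name}: {val}%")
    lines.append(f"quartile convention:  {summary.quartile_convention}")
    return "\n".join(lines)
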