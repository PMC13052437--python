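"""Laboratory yield-table handling and model-vs-experiment concordance.

Parses delimited experiment tables (metal salt, mole ratio, solvent,
temperature, duration, heating mode, yield %), answers filtered best-yield
and success-count queries, and measures how well a hierarchy's priorities
agree with mean observed yields via a tie-corrected Kendall tau-b rank
correlation implemented by direct pair counting.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Callable, Iterable, Sequence

from .hierarchy import DecisionHierarchy

__all__ = [
    "ExperimentRecord",
    "ConcordanceReport",
    "ParseError",
    "NoDataError",
    "RT",
    "parse_experiments",
    "records_to_csv",
    "best_yield",
    "success_count",
    "kendall_tau_b",
    "concordance",
    "EXPERIMENT_HEADER",
]

#: Sentinel for "room temperature" rows; kept symbolic until a numeric
#: value is needed (then mapped to 25 degC by default).
RT = "RT"

EXPERIMENT_HEADER = (
    "index", "metal_salt", "mole_ratio", "solvent",
    "temperature", "duration", "heating_mode", "yield_percent",
)

_DURATION_RE = re.compile(
    r"^\s*(\d+(?:[.,]\d+)?)\s*(m|min|minute|minutes|h|hr|hour|hours|d|day|days)?\s*$",
    re.IGNORECASE,
)
_DURATION_UNIT_MIN = {None: 1, "m": 1, "min": 1, "minute": 1, "minutes": 1,
                      "h": 60, "hr": 60, "hour": 60, "hours": 60,
                      "d": 1440, "day": 1440, "days": 1440}


class ParseError(ValueError):
    """A table row could not be parsed; message carries the line number."""


class NoDataError(LookupError):
    """A query's filter left no records to answer from."""


@dataclass(frozen=True)
class ExperimentRecord:
    """One laboratory experiment: a condition tuple plus observed yield.

    ``mole_ratio`` is the equivalents of metal salt per porphyrin (e.g. a
    1:3 porphyrin:metal recipe is stored as 3.0). ``temperature`` is in
    degrees Celsius, or the symbolic sentinel ``"RT"``. ``duration_minutes``
    is the canonical duration unit (1 day = 1440).
    """

    index: int
    metal_salt: str
    mole_ratio: float
    solvent: str
    temperature: float | str
    duration_minutes: int
    heating_mode: str
    yield_percent: int

    def __post_init__(self) -> None:
        if not 0 <= self.yield_percent <= 100:
            raise ValueError(f"yield {self.yield_percent} outside [0, 100]")
        if self.duration_minutes <= 0:
            raise ValueError("duration must be positive")
        if self.mole_ratio <= 0:
            raise ValueError("mole ratio must be positive")

    def temperature_celsius(self, rt: float = 25.0) -> float:
        """Numeric temperature, mapping the RT sentinel to ``rt``."""
        return rt if self.temperature == RT else float(self.temperature)


def parse_duration_minutes(text: str | int | float) -> int:
    """Normalize a duration like '15 m', '24 h' or '1 day' to whole minutes."""
    if isinstance(text, (int, float)):
        minutes = float(text)
    else:
        m = _DURATION_RE.match(str(text))
        if not m:
            raise ValueError(f"cannot parse duration {text!r}")
        value = float(m.group(1).replace(",", "."))
        unit = m.group(2).lower() if m.group(2) else None
        minutes = value * _DURATION_UNIT_MIN[unit]
    if minutes <= 0 or abs(minutes - round(minutes)) > 1e-9:
        raise ValueError(f"duration {text!r} is not a positive whole number of minutes")
    return int(round(minutes))


def _parse_decimal(text: str) -> float:
    # decimal commas ("2,5") are accepted alongside points
    return float(str(text).strip().replace(",", "."))


def _parse_temperature(text: str) -> float | str:
    t = str(text).strip()
    if t.upper() == RT:
        return RT
    return _parse_decimal(t.rstrip("C").rstrip("°").strip())


def parse_experiments(source: str | Path | IO[str]) -> list[ExperimentRecord]:
    """Parse a delimited experiment table into records.

    The header row is required. Decimal commas are accepted in the mole
    ratio; durations are normalized to minutes; ``RT`` temperatures stay
    symbolic. Errors name the offending line; duplicate indices are
    rejected.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source  # inline CSV text
    else:
        text = Path(source).read_text()
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        return []
    missing = set(EXPERIMENT_HEADER) - set(reader.fieldnames)
    if missing:
        raise ParseError(f"table header missing columns: {sorted(missing)}")
    records: list[ExperimentRecord] = []
    seen: set[int] = set()
    for lineno, row in enumerate(reader, start=2):
        try:
            idx = int(row["index"])
            if idx in seen:
                raise ValueError(f"duplicate experiment index {idx}")
            seen.add(idx)
            rec = ExperimentRecord(
                index=idx,
                metal_salt=row["metal_salt"].strip(),
                mole_ratio=_parse_decimal(row["mole_ratio"]),
                solvent=row["solvent"].strip(),
                temperature=_parse_temperature(row["temperature"]),
                duration_minutes=parse_duration_minutes(row["duration"]),
                heating_mode=row["heating_mode"].strip(),
                yield_percent=int(row["yield_percent"]),
            )
        except (ValueError, KeyError) as e:
            raise ParseError(f"line {lineno}: {e}") from e
        records.append(rec)
    return records


def records_to_csv(records: Iterable[ExperimentRecord]) -> str:
    """Serialize records to the canonical CSV dialect (round-trip stable)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(EXPERIMENT_HEADER)
    for r in records:
        ratio = int(r.mole_ratio) if float(r.mole_ratio).is_integer() else r.mole_ratio
        temp = r.temperature if r.temperature == RT else (
            int(r.temperature) if float(r.temperature).is_integer() else r.temperature)
        w.writerow([r.index, r.metal_salt, ratio, r.solvent, temp,
                    r.duration_minutes, r.heating_mode, r.yield_percent])
    return buf.getvalue()


Predicate = Callable[[ExperimentRecord], bool]


def best_yield(
    records: Iterable[ExperimentRecord],
    where: Predicate | None = None,
) -> tuple[ExperimentRecord, int]:
    """Highest-yield record among those matching ``where``.

    Ties at the maximum resolve to the lowest experiment index.
    """
    pool = [r for r in records if where is None or where(r)]
    if not pool:
        raise NoDataError("no experiment records match the filter")
    best = max(pool, key=lambda r: (r.yield_percent, -r.index))
    return best, best.yield_percent


def success_count(
    records: Iterable[ExperimentRecord],
    where: Predicate | None = None,
    min_yield: float = 0,
) -> int:
    """Number of matching records with yield strictly above ``min_yield``."""
    return sum(1 for r in records
               if (where is None or where(r)) and r.yield_percent > min_yield)


# ---------------------------------------------------------------------------
# concordance

def _pair_counts(x: Sequence[float], y: Sequence[float]) -> tuple[int, int, int, int, int]:
    """Concordant/discordant/tie counts over all pairs (C, D, Tx, Ty, total)."""
    c = d = tx = ty = n0 = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            n0 += 1
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    return c, d, tx, ty, n0


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Kendall rank correlation by direct O(n^2) pair counting.

    tau_b = (C - D) / sqrt((n0 - Tx) (n0 - Ty)) where Tx, Ty count pairs
    tied in x and in y respectively. Undefined (raises) when either margin
    is entirely tied.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    c, d, tx, ty, n0 = _pair_counts(x, y)
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        raise ValueError("tau-b undefined: a margin is constant")
    return (c - d) / denom


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between hierarchy priorities and mean observed yields.

    ``per_criterion`` maps a criterion name to rows of
    (alternative, priority, mean observed yield, number of records);
    alternatives with no records are excluded. ``rank_correlation`` is a
    Kendall tau-b computed from pair counts pooled across criteria
    (within-criterion pairs only), ``pairs_used`` the number of pairs.
    """

    per_criterion: dict[str, list[tuple[str, float, float, int]]]
    rank_correlation: float
    pairs_used: int


def _record_label(criterion_name: str, record: ExperimentRecord,
                  alternatives: Sequence[str], rt: float) -> str | None:
    """Map a record to this criterion's alternative label, or None if absent."""
    if criterion_name == "metal_salt":
        lab = record.metal_salt
        return lab if lab in alternatives else None
    if criterion_name == "solvent":
        lab = record.solvent
        return lab if lab in alternatives else None
    if criterion_name == "mole_ratio":
        for alt in alternatives:
            target = alt.split(":")[-1] if ":" in alt else alt
            if abs(float(target) - record.mole_ratio) < 1e-9:
                return alt
        return None
    if criterion_name == "duration":
        for alt in alternatives:
            if parse_duration_minutes(alt) == record.duration_minutes:
                return alt
        return None
    if criterion_name == "temperature":
        for alt in alternatives:
            t = rt if str(alt).upper() == RT else _parse_temperature(str(alt))
            if abs(float(t) - record.temperature_celsius(rt)) < 1e-9:
                return alt
        return None
    raise KeyError(f"cannot join records on criterion {criterion_name!r}")


def concordance(
    h: DecisionHierarchy,
    records: Sequence[ExperimentRecord],
    rt_celsius: float = 25.0,
) -> ConcordanceReport:
    """Compare priorities with mean observed yields, per criterion and pooled.

    For each criterion, records are bucketed by the alternative they used
    (records whose condition is outside the alternative set are ignored)
    and the mean yield per alternative is computed. The pooled tau-b then
    asks: across criteria, do higher-priority alternatives achieve higher
    mean yields?
    """
    per: dict[str, list[tuple[str, float, float, int]]] = {}
    c_tot = d_tot = tx_tot = ty_tot = n0_tot = 0
    for crit in h.criteria:
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for r in records:
            lab = _record_label(crit.name, r, crit.alternatives, rt_celsius)
            if lab is None:
                continue
            sums[lab] = sums.get(lab, 0.0) + r.yield_percent
            counts[lab] = counts.get(lab, 0) + 1
        rows = [(alt, crit.priorities[alt], sums[alt] / counts[alt], counts[alt])
                for alt in crit.alternatives if alt in counts]
        if len(rows) < 2:
            raise NoDataError(
                f"criterion {crit.name!r}: fewer than 2 alternatives have records; "
                "rank correlation undefined")
        per[crit.name] = rows
        pr = [r[1] for r in rows]
        my = [r[2] for r in rows]
        c, d, tx, ty, n0 = _pair_counts(pr, my)
        c_tot += c; d_tot += d; tx_tot += tx; ty_tot += ty; n0_tot += n0
    denom = math.sqrt((n0_tot - tx_tot) * (n0_tot - ty_tot))
    if denom == 0:
        raise NoDataError("rank correlation undefined: all pooled pairs tied")
    tau = (c_tot - d_tot) / denom
    return ConcordanceReport(per_criterion=per, rank_correlation=tau, pairs_used=n0_tot)
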